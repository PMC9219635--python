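"""ERP component quantification.

Implements the measurement conventions of the analysis:

* the N1 window is 100 ms wide, centred on the **median** grand-average peak
  latency taken across all brain regions and stimuli (a 70 ms median gives
  the 20–120 ms window);
* component amplitude is the arithmetic mean over the (half-open) window;
* SPN amplitude is the mean over the final 500 ms of the pre-silence epoch,
  i.e. t ∈ [2280, 2780) ms after the anchoring white-noise onset;
* component latency is the **half-area latency**: the time point splitting
  the polarity-consistent area inside the window into two equal halves,
  interpolated linearly between samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate

from .preprocess import SubjectAverage

__all__ = [
    "ComponentWindow",
    "grand_average",
    "find_peak_latency",
    "define_n1_window",
    "mean_amplitude",
    "spn_amplitude",
    "half_area_latency",
    "SPN_WINDOW_MS",
]

#: SPN measurement window: last 500 ms before silence onset, relative to the
#: anchoring white-noise onset of the 2980 ms epoch.
SPN_WINDOW_MS = (2280.0, 2780.0)


@dataclass(frozen=True)
class ComponentWindow:
    """A measurement window for one (negative-polarity) ERP component."""

    component: str  # "N1" | "SPN"
    start_ms: float
    end_ms: float
    polarity: str = "negative"


def grand_average(averages: Sequence[SubjectAverage]) -> np.ndarray:
    """Unweighted mean across subjects of per-subject average waveforms."""
    if len(averages) < 2:
        raise ValueError("grand average requires at least 2 subjects")
    names = {a.spec.name for a in averages}
    shapes = {a.waveform.shape for a in averages}
    if len(names) != 1 or len(shapes) != 1:
        raise ValueError(f"mismatched epoch specs/shapes: {names}, {shapes}")
    return np.stack([a.waveform for a in averages]).mean(axis=0)


def _window_mask(times_ms: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    mask = (times_ms >= window[0]) & (times_ms < window[1])
    if not mask.any():
        raise ValueError(f"window {window} lies outside the waveform")
    return mask


def find_peak_latency(
    waveform: np.ndarray,
    times_ms: np.ndarray,
    window: tuple[float, float],
    polarity: str = "negative",
) -> float:
    """Time of the extreme sample inside the window; ties go to the earliest."""
    mask = _window_mask(np.asarray(times_ms), window)
    seg = np.asarray(waveform)[mask]
    idx = int(np.argmin(seg)) if polarity == "negative" else int(np.argmax(seg))
    return float(np.asarray(times_ms)[mask][idx])


def define_n1_window(peak_latencies_ms: Iterable[float], half_width_ms: float = 50.0) -> ComponentWindow:
    """N1 window: ``median ± half_width``, clipped to start no earlier than 0.

    The median is taken over the supplied grand-average peak latencies
    regardless of brain region and stimulus; an even count uses the mean of
    the two central values.
    """
    lat = np.asarray(list(peak_latencies_ms), dtype=float)
    if lat.size == 0:
        raise ValueError("at least one peak latency is required")
    mid = float(np.median(lat))
    start, end = mid - half_width_ms, mid + half_width_ms
    if start < 0:
        warnings.warn(f"N1 window start {start:.1f} ms clipped to 0", stacklevel=2)
        start = 0.0
    return ComponentWindow("N1", start, end)


def mean_amplitude(waveform: np.ndarray, times_ms: np.ndarray, window) -> float:
    """Arithmetic mean of the samples in the half-open window (µV)."""
    if isinstance(window, ComponentWindow):
        window = (window.start_ms, window.end_ms)
    mask = _window_mask(np.asarray(times_ms), window)
    return float(np.asarray(waveform)[mask].mean())


def spn_amplitude(average: SubjectAverage, channel: Optional[int] = None) -> float | np.ndarray:
    """Mean amplitude over the last 500 ms of the pre-silence (spn) epoch.

    Accepts only ``spn``-spec averages.  Returns a scalar for one channel or
    the per-channel vector when ``channel`` is None.
    """
    if average.spec.name != "spn":
        raise ValueError(f"spn_amplitude requires an 'spn' epoch average, got {average.spec.name!r}")
    mask = _window_mask(average.times_ms, SPN_WINDOW_MS)
    vals = average.waveform[:, mask].mean(axis=1)
    return vals if channel is None else float(vals[channel])


def half_area_latency(
    waveform: np.ndarray,
    times_ms: np.ndarray,
    window: tuple[float, float] | ComponentWindow,
    polarity: str = "negative",
) -> float:
    """Half-area latency of a component inside a window.

    The polarity-consistent part of the waveform (for negative components,
    ``|min(value, 0)|``) is integrated over the window with the trapezoid
    rule; the returned latency is the earliest time where the cumulative
    area reaches half the total, linearly interpolated between samples.

    Raises ``ValueError`` when the polarity-consistent area is zero.
    """
    if isinstance(window, ComponentWindow):
        window = (window.start_ms, window.end_ms)
    t = np.asarray(times_ms, dtype=float)
    w = np.asarray(waveform, dtype=float)
    mask = _window_mask(t, window)
    t, w = t[mask], w[mask]
    rect = np.maximum(-w, 0.0) if polarity == "negative" else np.maximum(w, 0.0)
    if t.size < 2:
        raise ValueError("window must contain at least two samples")
    cum = integrate.cumulative_trapezoid(rect, t, initial=0.0)
    total = cum[-1]
    if total <= 0.0:
        raise ValueError("zero polarity-consistent area in window; half-area latency undefined")
    half = total / 2.0
    k = int(np.searchsorted(cum, half))
    if k == 0:
        return float(t[0])
    # linear interpolation on the cumulative-area curve between samples k-1, k
    c0, c1 = cum[k - 1], cum[k]
    if c1 == c0:
        return float(t[k - 1])
    frac = (half - c0) / (c1 - c0)
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))
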