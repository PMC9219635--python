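"""Continuous-EEG conditioning and epoching.

The processing chain operates on continuous data first (zero-phase band-pass
0.25–25 Hz plus a 50 Hz notch), then cuts fixed-length epochs around schedule
events, baseline-corrects on a 200 ms pre-anchor window, rejects any epoch
whose absolute amplitude exceeds ±60 µV on any channel, and averages the
accepted epochs by stimulus condition.

Four epoch geometries are defined (durations in ms):

========  ===================================  ==========  ========
name      anchor                               window      duration
========  ===================================  ==========  ========
n1_target      target onset (voluntary)        −200…+500   700
spn            white noise before a silence    −200…+2780  2980
combined       white noise before a target     −200…+3280  3480
n1_reflexive   target onset (reflexive)        −200…+500   700
========  ===================================  ==========  ========

Windows are half-open ``[start, end)`` with t = 0 at the anchor onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import signal as sps

from .paradigm import PresentationEvent, Schedule
from .synth import EEGRecording

__all__ = [
    "EpochSpec",
    "EPOCH_SPECS",
    "Epoch",
    "SubjectAverage",
    "filter_continuous",
    "extract_epochs",
    "baseline_correct",
    "rebaseline",
    "reject_artifacts",
    "average_epochs",
    "write_epochs",
    "read_epochs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EpochSpec:
    """Geometry of one epoch type relative to its anchor event."""

    name: str
    anchor: str           # which events anchor the epoch (see extract_epochs)
    start_ms: float
    end_ms: float
    baseline: tuple[float, float] = (-200.0, 0.0)

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


EPOCH_SPECS: dict[str, EpochSpec] = {
    "n1_target": EpochSpec("n1_target", "target", -200.0, 500.0),
    "spn": EpochSpec("spn", "white_noise_before_silence", -200.0, 2780.0),
    "combined": EpochSpec("combined", "white_noise_before_target", -200.0, 3280.0),
    "n1_reflexive": EpochSpec("n1_reflexive", "target", -200.0, 500.0),
}


@dataclass
class Epoch:
    """One time-locked segment: channels × samples, with provenance."""

    data: np.ndarray
    anchor_event: PresentationEvent
    spec: EpochSpec
    condition: str
    fs_hz: float
    accepted: bool = True
    rejection_reason: Optional[str] = None

    @property
    def times_ms(self) -> np.ndarray:
        return self.spec.start_ms + np.arange(self.data.shape[1]) * (1000.0 / self.fs_hz)


@dataclass
class SubjectAverage:
    """Per-subject, per-condition average waveform (channels × samples)."""

    waveform: np.ndarray
    condition: str
    spec: EpochSpec
    n_accepted: int
    subject_id: int
    fs_hz: float
    sex: Optional[str] = None

    @property
    def times_ms(self) -> np.ndarray:
        return self.spec.start_ms + np.arange(self.waveform.shape[1]) * (1000.0 / self.fs_hz)


def filter_continuous(
    recording: EEGRecording,
    band: tuple[float, float] = (0.25, 25.0),
    notch_hz: Optional[float] = 50.0,
    notch_q: float = 30.0,
) -> EEGRecording:
    """Zero-phase band-pass plus notch on the continuous signal.

    A 4th-order Butterworth band-pass and a biquad notch, each applied
    forward–backward (``filtfilt``), so the passband is phase-neutral and DC
    is removed exactly.
    """
    nyq = recording.fs_hz / 2.0
    lo, hi = band
    if hi >= nyq:
        raise ValueError(f"band upper edge {hi} Hz must be below Nyquist ({nyq} Hz)")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=recording.fs_hz, output="sos")
    out = sps.sosfiltfilt(sos, recording.signal, axis=1)
    if notch_hz is not None:
        if notch_hz >= nyq:
            raise ValueError(f"notch frequency {notch_hz} Hz must be below Nyquist")
        b, a = sps.iirnotch(notch_hz, notch_q, fs=recording.fs_hz)
        out = sps.filtfilt(b, a, out, axis=1)
    return EEGRecording(out, recording.fs_hz, recording.schedule, recording.channel_map, recording.subject)


def _anchor_events(schedule: Schedule, spec: EpochSpec) -> list[PresentationEvent]:
    events = schedule.analysis_events()
    if spec.anchor == "target":
        return [ev for ev in events if ev.slot_role == "target"]
    follow = "silence_replacement" if spec.anchor.endswith("silence") else "target"
    out = []
    for prev, nxt in zip(events, events[1:]):
        if prev.slot_role == "white_noise" and nxt.slot_role == follow:
            out.append(prev)
    return out


def _condition_of(event: PresentationEvent, schedule: Schedule, spec: EpochSpec) -> str:
    # SPN/combined epochs are anchored on white noise but belong to the
    # session's target-stimulus condition
    if spec.anchor == "target":
        return event.stimulus
    return schedule.target or event.stimulus


def extract_epochs(recording: EEGRecording, spec: Union[str, EpochSpec]) -> list[Epoch]:
    """Cut epochs of the given geometry from a (filtered) recording.

    Familiarization events never anchor an epoch.  Epochs that would extend
    beyond either end of the recording are dropped with a logged warning.
    """
    if isinstance(spec, str):
        spec = EPOCH_SPECS[spec]
    fs = recording.fs_hz
    n_samp = int(round(spec.duration_ms * fs / 1000.0))
    epochs: list[Epoch] = []
    n_dropped = 0
    for ev in _anchor_events(recording.schedule, spec):
        a = int(round(ev.onset_ms * fs / 1000.0)) + int(round(spec.start_ms * fs / 1000.0))
        b = a + n_samp
        if a < 0 or b > recording.n_samples:
            n_dropped += 1
            continue
        epochs.append(
            Epoch(
                data=recording.signal[:, a:b].copy(),
                anchor_event=ev,
                spec=spec,
                condition=_condition_of(ev, recording.schedule, spec),
                fs_hz=fs,
            )
        )
    if n_dropped:
        logger.warning("%s: dropped %d epoch(s) extending past the recording", spec.name, n_dropped)
    return epochs


def baseline_correct(epochs: Sequence[Epoch]) -> list[Epoch]:
    """Subtract the per-channel mean of the baseline window from each epoch."""
    out = []
    for ep in epochs:
        t = ep.times_ms
        mask = (t >= ep.spec.baseline[0]) & (t < ep.spec.baseline[1])
        if not mask.any():
            raise ValueError("baseline window lies outside the epoch")
        corrected = ep.data - ep.data[:, mask].mean(axis=1, keepdims=True)
        out.append(replace(ep, data=corrected))
    return out


def rebaseline(epochs: Sequence[Epoch], window_ms: tuple[float, float]) -> list[Epoch]:
    """Re-reference each epoch to the mean over an arbitrary time window.

    Used on ``combined`` epochs to read out the N1 relative to the 200 ms
    immediately preceding the target, after the anticipatory ramp.
    """
    out = []
    for ep in epochs:
        t = ep.times_ms
        mask = (t >= window_ms[0]) & (t < window_ms[1])
        if not mask.any():
            raise ValueError("re-baseline window lies outside the epoch")
        out.append(replace(ep, data=ep.data - ep.data[:, mask].mean(axis=1, keepdims=True)))
    return out


def reject_artifacts(
    epochs: Sequence[Epoch], threshold_uV: float = 60.0
) -> tuple[list[Epoch], pd.DataFrame]:
    """Flag epochs whose absolute amplitude exceeds ±``threshold_uV``.

    The maximum is taken over all channels and samples of the
    baseline-corrected epoch; a single excursion rejects the whole epoch.
    Returns the accepted epochs and a per-condition report
    (n_total, n_accepted, accepted_fraction).
    """
    accepted: list[Epoch] = []
    rows: dict[str, list[int]] = {}
    for ep in epochs:
        peak = float(np.abs(ep.data).max()) if ep.data.size else 0.0
        ok = peak <= threshold_uV
        ep.accepted = ok
        ep.rejection_reason = None if ok else f"|amplitude| {peak:.1f} µV > {threshold_uV:g} µV"
        tot, acc = rows.setdefault(ep.condition, [0, 0])
        rows[ep.condition][0] += 1
        rows[ep.condition][1] += int(ok)
        if ok:
            accepted.append(ep)
    report = pd.DataFrame(
        [
            {"condition": c, "n_total": t, "n_accepted": a, "accepted_fraction": a / t if t else np.nan}
            for c, (t, a) in sorted(rows.items())
        ]
    )
    return accepted, report


def average_epochs(
    epochs: Sequence[Epoch],
    subject_id: int = 0,
    sex: Optional[str] = None,
) -> dict[str, SubjectAverage]:
    """Pointwise mean of accepted epochs, grouped by condition label.

    Conditions with no accepted epoch are absent from the result (flagged in
    the log), never zero-filled.
    """
    groups: dict[str, list[Epoch]] = {}
    for ep in epochs:
        if ep.accepted:
            groups.setdefault(ep.condition, []).append(ep)
    out: dict[str, SubjectAverage] = {}
    for cond, eps in sorted(groups.items()):
        stack = np.stack([ep.data for ep in eps])
        out[cond] = SubjectAverage(
            waveform=stack.mean(axis=0),
            condition=cond,
            spec=eps[0].spec,
            n_accepted=len(eps),
            subject_id=subject_id,
            fs_hz=eps[0].fs_hz,
            sex=sex,
        )
    return out


# ---------------------------------------------------------------------------
# Epoch persistence (delimited text + manifest)


def write_epochs(epochs: Sequence[Epoch], directory: Union[str, Path]) -> None:
    """Persist epochs as one TSV matrix each plus a TSV manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, ep in enumerate(epochs):
        fname = f"epoch_{i:05d}.tsv"
        np.savetxt(directory / fname, ep.data.T, fmt="%.17g", delimiter="\t")
        rows.append(
            {
                "file": fname,
                "spec": ep.spec.name,
                "condition": ep.condition,
                "anchor_onset_ms": ep.anchor_event.onset_ms,
                "fs_hz": ep.fs_hz,
                "accepted": int(ep.accepted),
                "rejection_reason": ep.rejection_reason or "",
            }
        )
    pd.DataFrame(rows).to_csv(directory / "manifest.tsv", sep="\t", index=False)


def read_epochs(directory: Union[str, Path]) -> list[Epoch]:
    """Load epochs written by :func:`write_epochs`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    epochs = []
    for row in manifest.itertuples():
        data = np.loadtxt(directory / row.file, delimiter="\t").T
        if data.ndim == 1:
            data = data[:, None]
        spec = EPOCH_SPECS[row.spec]
        ev = PresentationEvent(row.anchor_onset_ms, 1280.0, row.condition, spec.anchor, 0)
        epochs.append(
            Epoch(
                data=data,
                anchor_event=ev,
                spec=spec,
                condition=row.condition,
                fs_hz=row.fs_hz,
                accepted=bool(row.accepted),
                rejection_reason=row.rejection_reason if isinstance(row.rejection_reason, str) and row.rejection_reason else None,
            )
        )
    return epochs
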