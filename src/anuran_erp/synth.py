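"""Synthetic multi-channel EEG with known SPN/N1 ground truth.

Generates continuous 6-channel recordings aligned to a playback
:class:`~anuran_erp.paradigm.Schedule`:

* 1/f-weighted Gaussian background noise per channel,
* a negative-polarity N1 transient (raised-cosine lobe, peak ~70 ms) after
  every white-noise or target onset, with region- and stimulus-dependent
  amplitude,
* in voluntary schedules, a linear negative ramp (the SPN) growing toward
  every expected target onset, with region-dependent slope,
* sporadic high-amplitude square-pulse artifacts at Poisson times.

Every injected parameter is recorded in a :class:`GroundTruth` object so all
downstream stages (filtering, epoching, rejection, averaging, component
measurement, statistics) can be verified against known values.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .paradigm import Schedule

__all__ = [
    "REGIONS",
    "ChannelMap",
    "DEFAULT_CHANNEL_MAP",
    "SubjectProfile",
    "EEGRecording",
    "GroundTruth",
    "EffectConfig",
    "paper_effects",
    "null_effects",
    "simulate_recording",
    "make_cohort",
    "write_recording",
    "read_recording",
    "write_ground_truth",
]

REGIONS = ("telencephalon", "diencephalon", "mesencephalon")

#: Width of the raised-cosine N1 lobe (ms); band-limited well inside
#: 0.25–25 Hz so the analysis band-pass barely distorts it.
N1_KERNEL_WIDTH_MS = 60.0

#: Duration of an injected artifact pulse (ms).
ARTIFACT_WIDTH_MS = 100.0

#: Reference epoch length (ms) over which ``artifact_rate`` is defined as a
#: per-epoch contamination probability.
ARTIFACT_REF_EPOCH_MS = 700.0


@dataclass(frozen=True)
class ChannelMap:
    """Scalp montage: six channels, left/right over three brain regions."""

    channels: tuple[str, ...] = ("LT", "RT", "LD", "RD", "LM", "RM")
    region_of: dict[str, str] = field(
        default_factory=lambda: {
            "LT": "telencephalon",
            "RT": "telencephalon",
            "LD": "diencephalon",
            "RD": "diencephalon",
            "LM": "mesencephalon",
            "RM": "mesencephalon",
        }
    )
    side_of: dict[str, str] = field(
        default_factory=lambda: {
            "LT": "left", "RT": "right", "LD": "left",
            "RD": "right", "LM": "left", "RM": "right",
        }
    )

    def __post_init__(self) -> None:
        if len(self.channels) != 6 or len(set(self.channels)) != 6:
            raise ValueError("channel map must hold 6 distinct channels")
        regions = [self.region_of[c] for c in self.channels]
        for r in REGIONS:
            if regions.count(r) != 2:
                raise ValueError(f"region {r} must have exactly 2 channels")


DEFAULT_CHANNEL_MAP = ChannelMap()


@dataclass
class SubjectProfile:
    """Ground-truth generative parameters for one subject.

    ``n1_amplitude_uV`` maps ``(region, stimulus_label)`` to the (negative)
    peak amplitude of the injected N1; ``spn_slope_uV_per_s`` maps
    ``(region, stimulus_label)`` to the (negative) SPN ramp slope used in
    voluntary sessions with that target.
    """

    subject_id: int
    sex: str  # "female" | "male"
    n1_amplitude_uV: dict[tuple[str, str], float]
    spn_slope_uV_per_s: dict[tuple[str, str], float]
    n1_latency_ms: float = 70.0
    noise_sd_uV: float = 10.0
    artifact_rate: float = 0.05
    artifact_amplitude_uV: float = 120.0
    #: the anticipatory ramp ends at the expected target onset and spans the
    #: silent gap after the preceding white noise (the 1500 ms ISI) by default
    spn_ramp_span_ms: float = 1500.0

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must be a probability in [0, 1)")
        if abs(self.artifact_amplitude_uV) <= 60.0:
            raise ValueError("artifact amplitude must exceed the ±60 µV rejection threshold")


@dataclass
class EEGRecording:
    """Continuous referenced EEG: channels × samples, in µV."""

    signal: np.ndarray  # (n_channels, n_samples) float64
    fs_hz: float
    schedule: Schedule
    channel_map: ChannelMap = field(default_factory=ChannelMap)
    subject: Optional[SubjectProfile] = None

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * (1000.0 / self.fs_hz)


@dataclass
class GroundTruth:
    """Injected parameters, keyed by analysis-event index and channel."""

    n1: pd.DataFrame        # event_index, channel, amplitude_uV, latency_ms
    spn: pd.DataFrame       # event_index, channel, terminal_uV, slope_uV_per_s
    artifacts: pd.DataFrame  # onset_ms, channel, amplitude_uV


def _one_over_f_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float, sd: float) -> np.ndarray:
    """Gaussian noise with ~1/f power spectrum, scaled to time-domain sd.

    ``shape`` is (n_channels, n_samples); channels are independent.  The FFT
    runs on the next fast composite length and is truncated back.
    """
    n_ch, n = shape
    if sd == 0.0:
        return np.zeros(shape)
    from scipy import fft as sfft

    nf = sfft.next_fast_len(n, real=True)
    white = rng.standard_normal((n_ch, nf))
    spec = sfft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(nf, d=1.0 / fs)
    # amplitude ∝ f^{-1/2} (power ∝ 1/f); flatten below 0.25 Hz so the
    # unobservable ultra-slow band does not dominate the variance
    weights = 1.0 / np.sqrt(np.maximum(freqs, 0.25))
    weights[0] = 0.0  # no DC
    shaped = sfft.irfft(spec * weights, n=nf, axis=1)[:, :n]
    shaped *= sd / shaped.std(axis=1, keepdims=True)
    return shaped


def _n1_kernel(fs: float, latency_ms: float, width_ms: float = N1_KERNEL_WIDTH_MS):
    """Unit-depth negative raised-cosine lobe; returns (offset_samples, kernel).

    Odd length so the lobe attains exactly −1 at the latency sample.
    """
    half = max(int(round(width_ms / 2.0 * fs / 1000.0)), 1)
    lobe = -np.hanning(2 * half + 1)
    start = int(round(latency_ms * fs / 1000.0)) - half
    return start, lobe


def simulate_recording(
    schedule: Schedule,
    profile: SubjectProfile,
    channel_map: Optional[ChannelMap] = None,
    seed: int = 0,
    fs_hz: float = 1000.0,
) -> tuple[EEGRecording, GroundTruth]:
    """Synthesize one continuous recording aligned to ``schedule``.

    See the module docstring for the generative model.  All randomness is
    driven by ``seed``; identical arguments give bit-identical signals.
    """
    if not schedule.events:
        raise ValueError("schedule must contain at least one event")
    if fs_hz < 250.0:
        raise ValueError("sampling rate must be at least 250 Hz")
    cm = channel_map or DEFAULT_CHANNEL_MAP
    slot_span = schedule.events[0].duration_ms
    if not 0.0 <= profile.n1_latency_ms <= slot_span:
        raise ValueError("n1_latency_ms must lie within the stimulus slot")

    rng = np.random.default_rng(seed)
    n_samples = int(math.ceil(schedule.span_ms * fs_hz / 1000.0))
    sig = _one_over_f_noise(rng, (6, n_samples), fs_hz, profile.noise_sd_uV)

    k_start, kernel = _n1_kernel(fs_hz, profile.n1_latency_ms)
    klen = kernel.size

    n1_rows, spn_rows = [], []
    for idx, ev in enumerate(schedule.events):
        if ev.stimulus in ("silence",):
            continue
        onset = int(round(ev.onset_ms * fs_hz / 1000.0))
        for c, ch in enumerate(cm.channels):
            amp = profile.n1_amplitude_uV.get((cm.region_of[ch], ev.stimulus))
            if amp is None:
                continue
            a = onset + k_start
            b = min(a + klen, n_samples)
            if a < 0 or a >= n_samples:
                continue
            sig[c, a:b] += (-amp) * kernel[: b - a]  # kernel is unit-depth negative
            if ev.slot_role != "familiarization":
                n1_rows.append((idx, ch, amp, profile.n1_latency_ms))

    if schedule.paradigm == "voluntary" and schedule.target is not None:
        span_ms = profile.spn_ramp_span_ms
        for idx, ev in enumerate(schedule.events):
            if ev.slot_role not in ("target", "silence_replacement"):
                continue
            end = int(round(ev.onset_ms * fs_hz / 1000.0))
            start = int(round((ev.onset_ms - span_ms) * fs_hz / 1000.0))
            a = max(start, 0)
            if a >= end:
                continue
            t_rel = (np.arange(a, min(end, n_samples)) - start) / fs_hz  # seconds from ramp start
            for c, ch in enumerate(cm.channels):
                slope = profile.spn_slope_uV_per_s.get((cm.region_of[ch], schedule.target), 0.0)
                if slope == 0.0:
                    continue
                sig[c, a : a + t_rel.size] += slope * t_rel
                if ev.slot_role != "familiarization":
                    # closed-form mean of the ramp over its final 500 ms
                    expected_window = slope * (span_ms - 250.0) / 1000.0
                    spn_rows.append((idx, ch, slope * span_ms / 1000.0, slope, expected_window))

    # Poisson-timed square-pulse artifacts, one random channel each
    art_rows = []
    if profile.artifact_rate > 0.0:
        lam_per_s = -math.log(1.0 - profile.artifact_rate) / (ARTIFACT_REF_EPOCH_MS / 1000.0)
        dur_s = n_samples / fs_hz
        n_art = rng.poisson(lam_per_s * dur_s)
        width = int(round(ARTIFACT_WIDTH_MS * fs_hz / 1000.0))
        for _ in range(n_art):
            pos = int(rng.integers(0, n_samples))
            ch_idx = int(rng.integers(0, 6))
            amp = profile.artifact_amplitude_uV * (1 if rng.random() < 0.5 else -1)
            sig[ch_idx, pos : pos + width] += amp
            art_rows.append((pos * 1000.0 / fs_hz, cm.channels[ch_idx], amp))

    rec = EEGRecording(sig, fs_hz, schedule, cm, profile)
    gt = GroundTruth(
        n1=pd.DataFrame(n1_rows, columns=["event_index", "channel", "amplitude_uV", "latency_ms"]),
        spn=pd.DataFrame(
            spn_rows,
            columns=["event_index", "channel", "terminal_uV", "slope_uV_per_s", "expected_window_uV"],
        ),
        artifacts=pd.DataFrame(art_rows, columns=["onset_ms", "channel", "amplitude_uV"]),
    )
    return rec, gt


# ---------------------------------------------------------------------------
# Cohort construction


@dataclass(frozen=True)
class EffectConfig:
    """Population-level effect profile programmed into a cohort.

    ``n1_mean_uV`` and ``spn_slope_mean_uV_per_s`` give region × stimulus
    population means; ``jitter_sd`` scales i.i.d. Gaussian between-subject
    variation added to every mean.
    """

    n1_mean_uV: dict[tuple[str, str], float]
    spn_slope_mean_uV_per_s: dict[tuple[str, str], float]
    jitter_sd_uV: float = 0.8
    noise_sd_uV: float = 10.0
    artifact_rate: float = 0.05
    artifact_amplitude_uV: float = 120.0
    n1_latency_ms: float = 70.0


_TARGETS = ("conspecific_call", "pure_tone", "screech_call")


def paper_effects() -> EffectConfig:
    """Effect profile with the study's qualitative directions programmed.

    * N1 most negative in the mesencephalon for every stimulus;
    * in the telencephalon, the screech (distress) call evokes a larger N1
      than the conspecific advertisement call;
    * SPN most negative in the telencephalon, smallest in the mesencephalon,
      with the forebrain dominance strongest for conspecific calls.
    """
    n1 = {}
    for stim in _TARGETS + ("white_noise",):
        n1[("mesencephalon", stim)] = -12.0
        n1[("diencephalon", stim)] = -5.0
        n1[("telencephalon", stim)] = -5.0
    n1[("telencephalon", "screech_call")] = -9.0
    n1[("telencephalon", "conspecific_call")] = -4.0
    n1[("telencephalon", "pure_tone")] = -5.0
    n1[("telencephalon", "white_noise")] = -3.0
    n1[("diencephalon", "white_noise")] = -3.0
    n1[("mesencephalon", "white_noise")] = -5.0

    # stimulus-balanced slopes (equal stimulus marginals, so the stimulus
    # main effect is null while the forebrain dominance is strongest for
    # the conspecific call -> stimulus × region interaction only)
    # magnitudes sized so the filtered region contrasts are detected with
    # power ≈ 1 at the study's n = 16 (the analysis band-pass attenuates a
    # ramp of this period by roughly half)
    spn = {
        ("telencephalon", "conspecific_call"): -6.8,
        ("diencephalon", "conspecific_call"): -4.4,
        ("mesencephalon", "conspecific_call"): -0.8,
        ("telencephalon", "pure_tone"): -5.8,
        ("diencephalon", "pure_tone"): -4.6,
        ("mesencephalon", "pure_tone"): -1.6,
        ("telencephalon", "screech_call"): -5.8,
        ("diencephalon", "screech_call"): -4.6,
        ("mesencephalon", "screech_call"): -1.6,
    }
    return EffectConfig(n1_mean_uV=n1, spn_slope_mean_uV_per_s=spn)


def null_effects() -> EffectConfig:
    """All region × stimulus means equal: nothing to detect."""
    n1 = {(r, s): -6.0 for r in REGIONS for s in _TARGETS + ("white_noise",)}
    spn = {(r, s): -1.5 for r in REGIONS for s in _TARGETS}
    return EffectConfig(n1_mean_uV=n1, spn_slope_mean_uV_per_s=spn)


def make_cohort(
    n_subjects: int = 16,
    effect_config: Optional[EffectConfig] = None,
    seed: int = 0,
) -> list[SubjectProfile]:
    """Draw a sex-balanced cohort of subject profiles (default 16: 8 F, 8 M).

    Each subject's N1 amplitudes and SPN slopes are the configured population
    means plus i.i.d. Gaussian jitter of sd ``jitter_sd_uV`` (slope jitter is
    scaled by 1/1.25 so the SPN measurement-window mean jitters by the same
    sd under the default 1500 ms ramp span).
    """
    if n_subjects % 2 != 0:
        raise ValueError("n_subjects must be even for a sex-balanced cohort")
    cfg = effect_config or paper_effects()
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_subjects):
        n1 = {
            key: min(mu + cfg.jitter_sd_uV * rng.standard_normal(), 0.0)
            for key, mu in cfg.n1_mean_uV.items()
        }
        spn = {
            key: min(mu + cfg.jitter_sd_uV / 1.25 * rng.standard_normal(), 0.0)
            for key, mu in cfg.spn_slope_mean_uV_per_s.items()
        }
        profiles.append(
            SubjectProfile(
                subject_id=i,
                sex="female" if i < n_subjects // 2 else "male",
                n1_amplitude_uV=n1,
                spn_slope_uV_per_s=spn,
                n1_latency_ms=cfg.n1_latency_ms,
                noise_sd_uV=cfg.noise_sd_uV,
                artifact_rate=cfg.artifact_rate,
                artifact_amplitude_uV=cfg.artifact_amplitude_uV,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Recording I/O


def write_ground_truth(gt: GroundTruth, directory: Union[str, Path]) -> None:
    """Persist the injected parameters as TSVs keyed by event index/channel."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gt.n1.to_csv(directory / "ground_truth_n1.tsv", sep="\t", index=False)
    gt.spn.to_csv(directory / "ground_truth_spn.tsv", sep="\t", index=False)
    gt.artifacts.to_csv(directory / "ground_truth_artifacts.tsv", sep="\t", index=False)


def write_recording(recording: EEGRecording, path: Union[str, Path]) -> None:
    """Write a recording as delimited text plus a JSON metadata sidecar.

    ``path`` is the signal file (TSV, one column per channel, header row of
    channel labels, full float precision); ``path`` with suffix ``.json``
    holds the sampling rate and channel map.  The aligned event file should
    be written separately with :func:`anuran_erp.paradigm.write_schedule`.
    """
    path = Path(path)
    cm = recording.channel_map
    header = "\t".join(cm.channels)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, recording.signal.T, fmt="%.17g", delimiter="\t")
    meta = {
        "fs_hz": recording.fs_hz,
        "channels": list(cm.channels),
        "region_of": cm.region_of,
        "side_of": cm.side_of,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_recording(
    path: Union[str, Path],
    schedule: Optional[Schedule] = None,
) -> EEGRecording:
    """Read a recording from delimited text (+ sidecar) or an EDF file.

    EDF reading goes through :mod:`mne`; channel labels must match the
    six-channel montage.  ``schedule`` (if given) is attached and its span
    checked against the signal length.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        sig = raw.get_data() * 1e6  # volts -> µV
        fs = float(raw.info["sfreq"])
        labels = tuple(raw.ch_names)
        cm = ChannelMap(channels=labels) if set(labels) == set(DEFAULT_CHANNEL_MAP.channels) else None
        if cm is None:
            raise ValueError(f"{path}: unknown channel labels {labels}")
    else:
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        with path.open(encoding="utf-8") as fh:
            labels = tuple(fh.readline().rstrip("\n").split("\t"))
        if set(labels) != set(DEFAULT_CHANNEL_MAP.channels):
            raise ValueError(f"{path}: unknown channel labels {labels}")
        sig = np.loadtxt(path, delimiter="\t", skiprows=1).T
        if sig.ndim == 1:
            sig = sig[:, None]
        fs = float(meta["fs_hz"])
        cm = ChannelMap(channels=labels)

    if schedule is not None:
        expected = int(math.ceil(schedule.span_ms * fs / 1000.0))
        if abs(sig.shape[1] - expected) > fs:  # > 1 s discrepancy
            raise ValueError(
                f"{path}: signal length {sig.shape[1]} inconsistent with "
                f"schedule span ({expected} samples at fs={fs})"
            )
    dummy = schedule or Schedule("voluntary", [], 0, None)  # type: ignore[arg-type]
    return EEGRecording(sig, fs, dummy, cm)
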