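"""Playback schedule construction for the two auditory attention paradigms.

Two paradigms are supported:

* **voluntary** — a binary (antiphonal) playback of white noise alternating
  with a target sound at a fixed inter-stimulus interval, in which the target
  at the last position of every cycle of N presentations is replaced by
  silence.  The omission of a fully predictable stimulus isolates the
  stimulus-preceding negativity (SPN), an anticipatory slow potential.
* **reflexive** — an equiprobable random playback of white noise and the
  target with a jittered inter-stimulus interval, removing all predictability
  so that only stimulus-driven (reflexive) components such as the N1 remain.

Schedules are fully determined by their parameters and a seed, and round-trip
through a TSV event-file format.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "STIMULUS_LABELS",
    "StimulusSpec",
    "VoluntaryParams",
    "ReflexiveParams",
    "PresentationEvent",
    "Schedule",
    "build_voluntary_schedule",
    "build_reflexive_schedule",
    "expected_duration",
    "write_schedule",
    "read_schedule",
]

#: Recognised stimulus labels.  ``silence`` is only ever produced by the
#: voluntary paradigm's replacement rule.
STIMULUS_LABELS = ("white_noise", "pure_tone", "conspecific_call", "screech_call", "silence")

#: Slot roles carried by every event.
SLOT_ROLES = ("familiarization", "white_noise", "target", "silence_replacement")


@dataclass(frozen=True)
class StimulusSpec:
    """An acoustic stimulus: label, slot duration and on/off ramp time.

    All stimuli share the same 1280 ms slot duration (the mean advertisement
    call duration); silence occupies the same slot as the target it replaces
    so that downstream epoch timing is unchanged.
    """

    label: str
    duration_ms: float = 1280.0
    rise_fall_ms: float = 7.5

    def __post_init__(self) -> None:
        if self.label not in STIMULUS_LABELS:
            raise ValueError(f"unknown stimulus label {self.label!r}")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.rise_fall_ms < 0:
            raise ValueError("rise_fall_ms must be non-negative")


def _default_cycle_lengths() -> tuple[int, ...]:
    # 30 cycles of each length 3..6 -> 120 cycles, 540 targets.
    return tuple(n for n in (3, 4, 5, 6) for _ in range(30))


@dataclass(frozen=True)
class VoluntaryParams:
    """Parameters of the silence-replacement (voluntary attention) paradigm."""

    isi_ms: float = 1500.0
    familiarization_presentations: int = 20
    cycle_lengths: tuple[int, ...] = field(default_factory=_default_cycle_lengths)
    n_blocks: int = 4
    break_ms: float = 300_000.0

    def __post_init__(self) -> None:
        if self.isi_ms < 0:
            raise ValueError("isi_ms must be non-negative")
        if self.familiarization_presentations < 0:
            raise ValueError("familiarization_presentations must be non-negative")
        if self.familiarization_presentations % 2 != 0:
            raise ValueError(
                "familiarization_presentations must be even (white noise and "
                "target alternate in pairs)"
            )
        if any(n <= 0 for n in self.cycle_lengths):
            raise ValueError("cycle lengths must be positive integers")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")


@dataclass(frozen=True)
class ReflexiveParams:
    """Parameters of the equiprobable random (reflexive attention) paradigm."""

    n_per_stimulus: int = 100
    isi_choices_ms: tuple[float, ...] = (1100.0, 1300.0, 1500.0, 1700.0, 1900.0)
    p_target: float = 0.5

    def __post_init__(self) -> None:
        if self.n_per_stimulus < 1:
            raise ValueError("n_per_stimulus must be >= 1")
        if len(self.isi_choices_ms) == 0:
            raise ValueError("isi_choices_ms must not be empty")
        if any(isi <= 0 for isi in self.isi_choices_ms):
            raise ValueError("all ISI choices must be positive")
        if not 0.0 < self.p_target < 1.0:
            raise ValueError("p_target must lie strictly between 0 and 1")


@dataclass(frozen=True)
class PresentationEvent:
    """One presentation slot: onset, duration, label and bookkeeping fields."""

    onset_ms: float
    duration_ms: float
    stimulus: str
    slot_role: str
    block: int
    cycle: Optional[int] = None


@dataclass
class Schedule:
    """An ordered presentation sequence produced by one paradigm builder."""

    paradigm: str  # "voluntary" | "reflexive"
    events: list[PresentationEvent]
    seed: int
    params: Union[VoluntaryParams, ReflexiveParams]
    target: Optional[str] = None  # the session's target stimulus label

    @property
    def span_ms(self) -> float:
        """Last onset + last duration (0 for an empty schedule)."""
        if not self.events:
            return 0.0
        last = self.events[-1]
        return last.onset_ms + last.duration_ms

    def counts(self, include_familiarization: bool = False) -> dict[str, int]:
        """Event counts keyed by slot role."""
        out = {role: 0 for role in SLOT_ROLES}
        for ev in self.events:
            out[ev.slot_role] += 1
        if not include_familiarization:
            out.pop("familiarization")
        return out

    def analysis_events(self) -> list[PresentationEvent]:
        """Events entering analysis (familiarization excluded)."""
        return [ev for ev in self.events if ev.slot_role != "familiarization"]


def _as_spec(target: Union[str, StimulusSpec]) -> StimulusSpec:
    return target if isinstance(target, StimulusSpec) else StimulusSpec(target)


def build_voluntary_schedule(
    target: Union[str, StimulusSpec],
    params: Optional[VoluntaryParams] = None,
    seed: int = 0,
) -> Schedule:
    """Build the silence-replacement schedule.

    After an even number of familiarization presentations (white noise and
    target alternating, excluded from analysis), the sequence runs one cycle
    per entry of ``params.cycle_lengths``: a cycle of length N contributes N
    white-noise/target pairs followed by one white-noise/silence pair, i.e.
    the target in the last position of every N+1 presentations is replaced by
    silence.  The cycle-length multiset is shuffled by ``seed``.  Cycles are
    split into ``n_blocks`` contiguous blocks separated by ``break_ms``.

    Under default parameters the post-familiarization schedule holds exactly
    660 white-noise, 540 target and 120 silence presentations (1320 total).
    """
    params = params or VoluntaryParams()
    spec = _as_spec(target)
    if spec.label in ("white_noise", "silence"):
        raise ValueError("target stimulus must not be white_noise or silence")

    rng = np.random.default_rng(seed)
    order = np.array(params.cycle_lengths, dtype=int)
    rng.shuffle(order)

    slot_ms = spec.duration_ms + params.isi_ms
    events: list[PresentationEvent] = []
    t = 0.0

    for i in range(params.familiarization_presentations):
        label = "white_noise" if i % 2 == 0 else spec.label
        events.append(PresentationEvent(t, spec.duration_ms, label, "familiarization", 0))
        t += slot_ms

    n_cycles = len(order)
    # cycles split as evenly as possible into contiguous blocks
    per_block = np.full(params.n_blocks, n_cycles // params.n_blocks)
    per_block[: n_cycles % params.n_blocks] += 1
    boundaries = set(np.cumsum(per_block)[:-1].tolist())

    for ci, n in enumerate(order):
        block = int(np.searchsorted(np.cumsum(per_block), ci, side="right"))
        for _ in range(int(n)):
            events.append(PresentationEvent(t, spec.duration_ms, "white_noise", "white_noise", block, ci))
            t += slot_ms
            events.append(PresentationEvent(t, spec.duration_ms, spec.label, "target", block, ci))
            t += slot_ms
        events.append(PresentationEvent(t, spec.duration_ms, "white_noise", "white_noise", block, ci))
        t += slot_ms
        events.append(PresentationEvent(t, spec.duration_ms, "silence", "silence_replacement", block, ci))
        t += slot_ms
        if (ci + 1) in boundaries:
            t += params.break_ms

    return Schedule("voluntary", events, seed, params, target=spec.label)


def build_reflexive_schedule(
    target: Union[str, StimulusSpec],
    params: Optional[ReflexiveParams] = None,
    seed: int = 0,
) -> Schedule:
    """Build the equiprobable random schedule.

    White noise and the target are presented in random order (by default
    ``n_per_stimulus`` of each), with the ISI of every presentation drawn
    uniformly from ``isi_choices_ms``.  No silence events occur.
    """
    params = params or ReflexiveParams()
    spec = _as_spec(target)
    if spec.label in ("white_noise", "silence"):
        raise ValueError("target stimulus must not be white_noise or silence")

    rng = np.random.default_rng(seed)
    n_total = 2 * params.n_per_stimulus
    n_target = int(round(n_total * params.p_target))
    labels = np.array(["white_noise"] * (n_total - n_target) + [spec.label] * n_target)
    rng.shuffle(labels)
    isis = rng.choice(np.asarray(params.isi_choices_ms, dtype=float), size=n_total)

    events: list[PresentationEvent] = []
    t = 0.0
    for label, isi in zip(labels, isis):
        role = "white_noise" if label == "white_noise" else "target"
        events.append(PresentationEvent(t, spec.duration_ms, str(label), role, 0))
        t += spec.duration_ms + float(isi)

    return Schedule("reflexive", events, seed, params, target=spec.label)


def expected_duration(
    schedule_or_params: Union[Schedule, VoluntaryParams, ReflexiveParams],
    stimulus_duration_ms: float = 1280.0,
) -> float:
    """Analytic expected session span in **seconds**.

    Sums stimulus durations, expected ISIs (each presentation is followed by
    one ISI) and, for the voluntary paradigm, the between-block breaks.
    """
    if isinstance(schedule_or_params, Schedule):
        params = schedule_or_params.params
        if schedule_or_params.events:
            stimulus_duration_ms = schedule_or_params.events[0].duration_ms
        elif isinstance(params, VoluntaryParams) and not params.cycle_lengths and params.familiarization_presentations == 0:
            return 0.0
    else:
        params = schedule_or_params

    if isinstance(params, ReflexiveParams):
        mean_isi = float(np.mean(params.isi_choices_ms))
        n = 2 * params.n_per_stimulus
        return n * (stimulus_duration_ms + mean_isi) / 1000.0

    n_slots = params.familiarization_presentations + sum(2 * n + 2 for n in params.cycle_lengths)
    if n_slots == 0:
        return 0.0
    n_breaks = min(params.n_blocks, len(params.cycle_lengths)) - 1 if params.cycle_lengths else 0
    span_ms = n_slots * (stimulus_duration_ms + params.isi_ms) + max(n_breaks, 0) * params.break_ms
    return span_ms / 1000.0


_EVENT_COLUMNS = ("onset_ms", "duration_ms", "stimulus", "slot_role", "block", "cycle")


def write_schedule(schedule: Schedule, path: Union[str, Path]) -> None:
    """Write the event file: TSV, one row per presentation, full precision."""
    path = Path(path)
    lines = ["\t".join(_EVENT_COLUMNS)]
    lines.append(
        "# paradigm=%s seed=%d target=%s" % (schedule.paradigm, schedule.seed, schedule.target)
    )
    for ev in schedule.events:
        cyc = "" if ev.cycle is None else str(ev.cycle)
        lines.append(
            f"{ev.onset_ms!r}\t{ev.duration_ms!r}\t{ev.stimulus}\t{ev.slot_role}\t{ev.block}\t{cyc}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


class ScheduleParseError(ValueError):
    """Raised for malformed event-file rows; names the offending line."""


def read_schedule(path: Union[str, Path]) -> Schedule:
    """Read an event file written by :func:`write_schedule`.

    The returned :class:`Schedule` carries the events, paradigm, seed and
    target; builder parameters are not recoverable from the file and are left
    as defaults of the recorded paradigm.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != list(_EVENT_COLUMNS):
        raise ScheduleParseError(f"{path}: line 1: bad or missing header")

    paradigm, seed, target = "voluntary", 0, None
    events: list[PresentationEvent] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                key, _, val = tok.partition("=")
                if key == "paradigm":
                    paradigm = val
                elif key == "seed":
                    seed = int(val)
                elif key == "target" and val != "None":
                    target = val
            continue
        parts = line.split("\t")
        if len(parts) != len(_EVENT_COLUMNS):
            raise ScheduleParseError(f"{path}: line {lineno}: expected {len(_EVENT_COLUMNS)} fields, got {len(parts)}")
        try:
            ev = PresentationEvent(
                onset_ms=float(parts[0]),
                duration_ms=float(parts[1]),
                stimulus=parts[2],
                slot_role=parts[3],
                block=int(parts[4]),
                cycle=None if parts[5] == "" else int(parts[5]),
            )
        except ValueError as exc:
            raise ScheduleParseError(f"{path}: line {lineno}: {exc}") from exc
        if ev.stimulus not in STIMULUS_LABELS or ev.slot_role not in SLOT_ROLES:
            raise ScheduleParseError(f"{path}: line {lineno}: unknown label or role")
        events.append(ev)

    params: Union[VoluntaryParams, ReflexiveParams]
    params = VoluntaryParams() if paradigm == "voluntary" else ReflexiveParams()
    return Schedule(paradigm, events, seed, params, target=target)
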