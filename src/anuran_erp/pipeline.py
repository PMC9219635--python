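"""End-to-end orchestration: simulate → filter → epoch → measure → test.

`run_voluntary_experiment` and `run_reflexive_experiment` execute the whole
chain for a synthetic cohort and return a results bundle holding the
component measure tables (amplitude and latency, region-reduced), the mixed
three-way ANOVA with post-hoc and simple-effects output, and a run manifest
with resolved configuration, per-stage counts and content hashes (equal
configurations yield equal hashes).

All randomness descends from ``RunConfig.seed`` through per-subject,
per-session ``numpy`` seed sequences.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import measures as erp
from . import stats as st
from .paradigm import (
    ReflexiveParams,
    Schedule,
    VoluntaryParams,
    build_reflexive_schedule,
    build_voluntary_schedule,
)
from .preprocess import (
    EPOCH_SPECS,
    SubjectAverage,
    average_epochs,
    baseline_correct,
    extract_epochs,
    filter_continuous,
    rebaseline,
    reject_artifacts,
)
from .synth import (
    DEFAULT_CHANNEL_MAP,
    EffectConfig,
    make_cohort,
    null_effects,
    paper_effects,
    simulate_recording,
)

__all__ = ["RunConfig", "run_voluntary_experiment", "run_reflexive_experiment", "pattern_recovery"]

logger = logging.getLogger(__name__)

#: Search range (ms post-onset) for grand-average N1 peaks.
PEAK_SEARCH_MS = (10.0, 200.0)


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one experiment run.

    The defaults reproduce the study's parameter set: 16 subjects (8 per
    sex), three stimulus pairs, 1000 Hz sampling, 0.25–25 Hz band-pass with
    50 Hz notch, ±60 µV rejection, 200 ms baselines, 120 silence
    replacements per voluntary session and 100 presentations per stimulus in
    the reflexive sessions.  ``scaled()`` gives a smaller preset for
    simulation studies.
    """

    seed: int = 0
    n_subjects: int = 16
    stimulus_pairs: tuple[str, ...] = st.STIM_LEVELS
    effects: Union[str, EffectConfig] = "paper"  # "paper" | "null" | explicit
    fs_hz: float = 1000.0
    band_hz: tuple[float, float] = (0.25, 25.0)
    notch_hz: float = 50.0
    reject_uV: float = 60.0
    cycle_repeats: int = 30         # cycles per N in {3,4,5,6}: 30 -> 120 replacements
    familiarization: int = 20
    n_blocks: int = 4
    break_ms: float = 300_000.0
    reflexive_n_per_stimulus: int = 100

    @classmethod
    def scaled(cls, seed: int = 0, **overrides) -> "RunConfig":
        """Reduced problem size for multi-cohort simulation studies."""
        base = dict(seed=seed, fs_hz=500.0, cycle_repeats=3, familiarization=4,
                    break_ms=0.0, reflexive_n_per_stimulus=30)
        base.update(overrides)
        return cls(**base)

    def effect_config(self) -> EffectConfig:
        if isinstance(self.effects, EffectConfig):
            return self.effects
        return {"paper": paper_effects, "null": null_effects}[self.effects]()

    def voluntary_params(self) -> VoluntaryParams:
        return VoluntaryParams(
            familiarization_presentations=self.familiarization,
            cycle_lengths=tuple(n for n in (3, 4, 5, 6) for _ in range(self.cycle_repeats)),
            n_blocks=self.n_blocks,
            break_ms=self.break_ms,
        )

    def reflexive_params(self) -> ReflexiveParams:
        return ReflexiveParams(n_per_stimulus=self.reflexive_n_per_stimulus)


def _derive_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def _region_waveform(waveform: np.ndarray, region: str) -> np.ndarray:
    cm = DEFAULT_CHANNEL_MAP
    idx = [i for i, ch in enumerate(cm.channels) if cm.region_of[ch] == region]
    return waveform[idx].mean(axis=0)


def _latency_with_fallback(wave, times, window) -> tuple[float, bool]:
    """Half-area latency; falls back to the peak latency when the waveform
    never goes negative inside the window (flagged)."""
    try:
        return erp.half_area_latency(wave, times, window), False
    except ValueError:
        return erp.find_peak_latency(wave, times, (window.start_ms, window.end_ms) if isinstance(window, erp.ComponentWindow) else window), True


def _measures_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    return df.sort_values(["subject_id", "stimulus", "region", "side"]).reset_index(drop=True)


def _stats_bundle(channel_rows: list[dict], alpha: float = 0.05) -> dict:
    """Region-reduce one channel-level measure set and run the inference chain."""
    chan = _measures_frame(channel_rows)
    table = st.region_reduce(chan)
    anova = st.mixed_rm_anova(table)
    out = {
        "channel_measures": chan,
        "table": table,
        "anova": anova,
        "assumptions": st.assumption_checks(table),
        "pairwise_region": st.bonferroni_pairwise(table, "region", alpha=alpha),
        "pairwise_stimulus": st.bonferroni_pairwise(table, "stimulus", alpha=alpha),
    }
    if anova.effects["stimulus*region"].p < alpha:
        out["simple_region_by_stimulus"] = st.simple_effects(table, "region", "stimulus", alpha=alpha)
        out["simple_stimulus_by_region"] = st.simple_effects(table, "stimulus", "region", alpha=alpha)
    return out


def _hash_frames(*frames: pd.DataFrame) -> str:
    h = hashlib.sha256()
    for f in frames:
        h.update(f.round(10).to_csv(index=False).encode())
    return h.hexdigest()


def _simulate_subject_session(config, mode, subject, pair_idx, stim):
    if mode == "voluntary":
        sched = build_voluntary_schedule(
            stim, config.voluntary_params(),
            seed=_derive_seed(config.seed, subject.subject_id, pair_idx, 1),
        )
    else:
        sched = build_reflexive_schedule(
            stim, config.reflexive_params(),
            seed=_derive_seed(config.seed, subject.subject_id, pair_idx, 2),
        )
    rec, _ = simulate_recording(
        sched, subject, seed=_derive_seed(config.seed, subject.subject_id, pair_idx, 3),
        fs_hz=config.fs_hz,
    )
    return filter_continuous(rec, band=config.band_hz, notch_hz=config.notch_hz)


def _collect_averages(config: RunConfig, mode: str, specs: tuple[str, ...]):
    """Simulate and preprocess every subject × stimulus-pair session.

    Returns ``averages[spec_name][(subject_id, stimulus)] -> SubjectAverage``
    plus cohort profiles and stage counts.
    """
    cohort = make_cohort(config.n_subjects, config.effect_config(),
                         seed=_derive_seed(config.seed, 11))
    averages: dict[str, dict] = {name: {} for name in specs}
    counts = {"events": 0, "epochs": {n: 0 for n in specs}, "accepted": {n: 0 for n in specs}}
    for subject in cohort:
        for pair_idx, stim in enumerate(config.stimulus_pairs):
            filt = _simulate_subject_session(config, mode, subject, pair_idx, stim)
            counts["events"] += len(filt.schedule.events)
            for name in specs:
                eps = baseline_correct(extract_epochs(filt, name))
                accepted, _ = reject_artifacts(eps, threshold_uV=config.reject_uV)
                counts["epochs"][name] += len(eps)
                counts["accepted"][name] += len(accepted)
                avg = average_epochs(accepted, subject_id=subject.subject_id, sex=subject.sex)
                if stim not in avg:
                    logger.warning("subject %d %s: no accepted %s epochs", subject.subject_id, stim, name)
                    continue
                averages[name][(subject.subject_id, stim)] = avg[stim]
    return cohort, averages, counts


def _n1_window_from_grand(averages: dict, config: RunConfig) -> tuple[erp.ComponentWindow, list[float]]:
    """Define the N1 window from grand-average peak latencies.

    Peaks are read per brain region × stimulus from grand averages; the
    window is the 100 ms range centred on their overall median.
    """
    latencies = []
    for stim in config.stimulus_pairs:
        subj_avgs = [a for (sid, s), a in averages.items() if s == stim]
        if len(subj_avgs) < 2:
            continue
        ga = erp.grand_average(subj_avgs)
        times = subj_avgs[0].times_ms
        for region in st.REGION_LEVELS:
            latencies.append(erp.find_peak_latency(_region_waveform(ga, region), times, PEAK_SEARCH_MS))
    return erp.define_n1_window(latencies), latencies


def _component_rows(averages: dict, cohort, window, kind: str) -> tuple[list[dict], list[dict]]:
    """Per-channel amplitude and latency rows for one component ('n1'|'spn')."""
    cm = DEFAULT_CHANNEL_MAP
    sex_of = {p.subject_id: p.sex for p in cohort}
    amp_rows, lat_rows = [], []
    for (sid, stim), avg in averages.items():
        times = avg.times_ms
        for c, ch in enumerate(cm.channels):
            base = {
                "subject_id": sid, "sex": sex_of[sid], "stimulus": stim,
                "region": cm.region_of[ch], "side": cm.side_of[ch],
                "n_accepted": avg.n_accepted,
            }
            wave = avg.waveform[c]
            if kind == "n1":
                amp = erp.mean_amplitude(wave, times, window)
                lat, fb = _latency_with_fallback(wave, times, window)
            else:
                amp = float(erp.spn_amplitude(avg, channel=c))
                lat, fb = _latency_with_fallback(wave, times, erp.SPN_WINDOW_MS)
            amp_rows.append({**base, "value": amp})
            lat_rows.append({**base, "value": lat, "fallback": fb})
    return amp_rows, lat_rows


def run_voluntary_experiment(config: Optional[RunConfig] = None) -> dict:
    """Full voluntary-attention (silence replacement) analysis on a synthetic cohort.

    Produces SPN measures (pre-silence white-noise epochs), N1 measures
    (target-onset epochs), combined-epoch grand-average read-outs showing
    both components, per-component amplitude and latency ANOVAs with
    post-hocs, and the run manifest.
    """
    config = config or RunConfig()
    cohort, averages, counts = _collect_averages(config, "voluntary", ("n1_target", "spn", "combined"))

    window, peak_latencies = _n1_window_from_grand(averages["n1_target"], config)
    n1_amp, n1_lat = _component_rows(averages["n1_target"], cohort, window, "n1")
    spn_amp, spn_lat = _component_rows(averages["spn"], cohort, None, "spn")

    results = {
        "n1_window": window,
        "peak_latencies_ms": peak_latencies,
        "n1": {
            "amplitude": _stats_bundle(n1_amp),
            "latency": _stats_bundle(n1_lat),
        },
        "spn": {
            "amplitude": _stats_bundle(spn_amp),
            "latency": _stats_bundle(spn_lat),
        },
        "combined": _combined_readout(averages["combined"], window, config),
    }
    results["manifest"] = _manifest(config, counts, results)
    return results


def _combined_readout(averages: dict, window: erp.ComponentWindow, config: RunConfig) -> dict:
    """Grand-average SPN and N1 read-outs from the 3480 ms combined epochs.

    The SPN is the mean over the last 500 ms before the expected target
    onset (t ∈ [2280, 2780) of the epoch); the N1 is read in the
    median-centred window shifted to the target onset at 2780 ms, after
    re-baselining on the 200 ms immediately preceding the target.
    """
    out = {}
    target_on = 2780.0
    for stim in config.stimulus_pairs:
        subj_avgs = [a for (sid, s), a in averages.items() if s == stim]
        if len(subj_avgs) < 2:
            continue
        ga = erp.grand_average(subj_avgs)
        times = subj_avgs[0].times_ms
        pre_mask = (times >= target_on - 200.0) & (times < target_on)
        ga_rebase = ga - ga[:, pre_mask].mean(axis=1, keepdims=True)
        entry = {}
        for region in st.REGION_LEVELS:
            spn_uV = erp.mean_amplitude(_region_waveform(ga, region), times, erp.SPN_WINDOW_MS)
            n1_uV = erp.mean_amplitude(
                _region_waveform(ga_rebase, region), times,
                (target_on + window.start_ms, target_on + window.end_ms),
            )
            entry[region] = {"spn_uV": spn_uV, "n1_uV": n1_uV}
        out[stim] = entry
    return out


def run_reflexive_experiment(config: Optional[RunConfig] = None) -> dict:
    """Full reflexive-attention (equiprobable random) N1 analysis."""
    config = config or RunConfig()
    cohort, averages, counts = _collect_averages(config, "reflexive", ("n1_reflexive",))
    window, peak_latencies = _n1_window_from_grand(averages["n1_reflexive"], config)
    n1_amp, n1_lat = _component_rows(averages["n1_reflexive"], cohort, window, "n1")
    results = {
        "n1_window": window,
        "peak_latencies_ms": peak_latencies,
        "n1": {
            "amplitude": _stats_bundle(n1_amp),
            "latency": _stats_bundle(n1_lat),
        },
    }
    results["manifest"] = _manifest(config, counts, results)
    return results


def _manifest(config: RunConfig, counts: dict, results: dict) -> dict:
    frames = []
    for comp in ("n1", "spn"):
        if comp in results:
            for dv in ("amplitude", "latency"):
                frames.append(results[comp][dv]["table"])
    return {
        "config": dataclasses.asdict(config) | {"effects": str(config.effects)},
        "counts": counts,
        "measure_rows": sum(len(f) for f in frames),
        "hash": _hash_frames(*frames),
        "version": 1,
    }


# ---------------------------------------------------------------------------
# Multi-cohort pattern recovery


def _check_pair(pairwise: pd.DataFrame, a: str, b: str) -> bool:
    """True when level ``a`` is significantly more negative than ``b``."""
    row = pairwise[
        ((pairwise.level_a == a) & (pairwise.level_b == b))
        | ((pairwise.level_a == b) & (pairwise.level_b == a))
    ].iloc[0]
    mean_a = row.mean_a if row.level_a == a else row.mean_b
    mean_b = row.mean_b if row.level_a == a else row.mean_a
    return bool(row.significant and mean_a < mean_b)


def cohort_pattern_checks(vol: dict, refl: dict, alpha: float = 0.05) -> dict[str, bool]:
    """The study's headline qualitative orderings, as boolean checks.

    * voluntary SPN amplitude: significant brain-area main effect with the
      telencephalon more negative than the mesencephalon (TN > MN);
    * voluntary N1 amplitude: mesencephalon dominant (MN > TN and MN > DN);
    * reflexive N1 amplitude: mesencephalon dominant (MN > TN and MN > DN);
    * reflexive N1 in the telencephalon: screech call larger than the
      conspecific call (SC > MC).
    """
    spn = vol["spn"]["amplitude"]
    n1v = vol["n1"]["amplitude"]
    n1r = refl["n1"]["amplitude"]

    tn_table = n1r["table"]
    tn_pair = st.bonferroni_pairwise(tn_table[tn_table.region == "telencephalon"], "stimulus", alpha=alpha)
    return {
        "spn_telencephalon_dominant": bool(
            spn["anova"].effects["region"].p < alpha
            and _check_pair(spn["pairwise_region"], "telencephalon", "mesencephalon")
        ),
        "voluntary_n1_mesencephalon_dominant": bool(
            _check_pair(n1v["pairwise_region"], "mesencephalon", "telencephalon")
            and _check_pair(n1v["pairwise_region"], "mesencephalon", "diencephalon")
        ),
        "reflexive_n1_mesencephalon_dominant": bool(
            _check_pair(n1r["pairwise_region"], "mesencephalon", "telencephalon")
            and _check_pair(n1r["pairwise_region"], "mesencephalon", "diencephalon")
        ),
        "reflexive_screech_gt_conspecific_tn": _check_pair(tn_pair, "screech_call", "conspecific_call"),
    }


def pattern_recovery(n_cohorts: int = 100, base_seed: int = 0, config: Optional[RunConfig] = None) -> dict:
    """Run the full pipeline over seeded cohorts and score ordering recovery.

    Returns per-check success fractions and the fraction of cohorts passing
    all checks.  Uses the scaled problem size by default.
    """
    per_check: dict[str, int] = {}
    n_all = 0
    for i in range(n_cohorts):
        cfg = replace(config or RunConfig.scaled(), seed=_derive_seed(base_seed, i))
        vol = run_voluntary_experiment(cfg)
        refl = run_reflexive_experiment(cfg)
        checks = cohort_pattern_checks(vol, refl)
        for k, ok in checks.items():
            per_check[k] = per_check.get(k, 0) + int(ok)
        n_all += int(all(checks.values()))
    return {
        "n_cohorts": n_cohorts,
        "all_patterns_fraction": n_all / n_cohorts,
        "per_check_fraction": {k: v / n_cohorts for k, v in per_check.items()},
    }
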