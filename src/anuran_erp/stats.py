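"""Mixed repeated-measures inference on component measures.

The design is the study's: one between-subject factor (sex, 2 levels) and
two within-subject factors (acoustic stimulus: conspecific call / pure tone /
screech call; brain region: telencephalon / diencephalon / mesencephalon),
fully balanced.  The univariate split-plot decomposition gives, for 16
subjects, the degrees of freedom (1,14), (2,28), (2,28) and (4,56) for sex,
stimulus, region and stimulus×region.

Sphericity of each within effect is handled with the Greenhouse–Geisser ε
computed from the pooled within-group covariance of orthonormal contrast
scores (Box's formula); a Mauchly-style test decides whether the corrected
or uncorrected p is the headline value (both are always reported).  Effect
sizes are partial η² = SS_effect / (SS_effect + SS_error).  Post-hoc
machinery: Bonferroni-corrected paired comparisons on subject-level marginal
means, plus simple effects (one-way RM-ANOVA of one factor within each level
of the other) after a significant interaction.

Amplitudes here are negative-polarity: a "greater" component is a more
negative value.  Multiple-comparison ordering strings follow the field's
convention, e.g. ``"MN > TN, DN"`` (mesencephalon greater than both
telencephalon and diencephalon, which do not differ).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "STIM_LEVELS",
    "REGION_LEVELS",
    "ABBREV",
    "region_reduce",
    "assumption_checks",
    "mixed_rm_anova",
    "bonferroni_pairwise",
    "simple_effects",
    "one_way_rm_anova",
    "AnovaEffect",
    "AnovaResult",
]

STIM_LEVELS = ("conspecific_call", "pure_tone", "screech_call")
REGION_LEVELS = ("telencephalon", "diencephalon", "mesencephalon")

#: Field abbreviations used in ordering (MCBC) strings.
ABBREV = {
    "conspecific_call": "MC",
    "pure_tone": "PT",
    "screech_call": "SC",
    "telencephalon": "TN",
    "diencephalon": "DN",
    "mesencephalon": "MN",
}


@dataclass
class AnovaEffect:
    """One line of the ANOVA table."""

    effect: str
    ss: float
    ss_error: float
    df: tuple[int, int]
    F: float
    p_uncorrected: float
    gg_epsilon: Optional[float] = None
    p_gg: Optional[float] = None
    mauchly_p: Optional[float] = None
    partial_eta_sq: float = float("nan")

    @property
    def p(self) -> float:
        """Headline p: GG-corrected when the Mauchly check rejects sphericity."""
        if self.p_gg is not None and self.mauchly_p is not None and self.mauchly_p < 0.05:
            return self.p_gg
        return self.p_uncorrected


@dataclass
class AnovaResult:
    """Full mixed-ANOVA output: effects plus bookkeeping."""

    effects: dict[str, AnovaEffect]
    n_subjects: int
    between: str = "sex"
    within: tuple[str, str] = ("stimulus", "region")

    def table(self) -> pd.DataFrame:
        rows = []
        for e in self.effects.values():
            rows.append(
                {
                    "effect": e.effect,
                    "df1": e.df[0],
                    "df2": e.df[1],
                    "F": e.F,
                    "gg_epsilon": e.gg_epsilon,
                    "p_uncorrected": e.p_uncorrected,
                    "p_gg": e.p_gg,
                    "p": e.p,
                    "partial_eta_sq": e.partial_eta_sq,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Table construction


def region_reduce(channel_measures: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Average left/right channel measures into region-level rows.

    Expects columns ``subject_id, sex, stimulus, region, side, <value_col>``
    (one row per channel).  Rows whose region is missing one side are
    excluded with a warning column in the returned attrs.
    """
    key = ["subject_id", "sex", "stimulus", "region"]
    grouped = channel_measures.groupby(key, sort=True)[value_col]
    counts = grouped.size()
    out = grouped.mean().reset_index().rename(columns={value_col: "value"})
    incomplete = counts[counts < 2]
    if len(incomplete):
        bad = set(map(tuple, incomplete.reset_index()[key].itertuples(index=False)))
        import warnings

        warnings.warn(f"{len(bad)} region cell(s) missing one side; excluded", stacklevel=2)
        mask = out[key].apply(tuple, axis=1).isin(bad)
        out = out[~mask].reset_index(drop=True)
    return out


def _levels(observed: Iterable[str], canonical: Sequence[str]) -> list[str]:
    obs = set(observed)
    ordered = [l for l in canonical if l in obs]
    return ordered + sorted(obs - set(canonical))


def _pivot(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list]:
    """MeasureTable -> (Y[subject, stimulus, region], group codes, subject ids).

    Within-factor levels are taken from the table (canonical study levels
    first), so small designs (e.g. 2×2 within) are accepted when balanced.
    """
    subjects = sorted(table["subject_id"].unique())
    stim_lv = _levels(table["stimulus"], STIM_LEVELS)
    reg_lv = _levels(table["region"], REGION_LEVELS)
    piv = table.pivot_table(index="subject_id", columns=["stimulus", "region"], values="value")
    expected = [(s, r) for s in stim_lv for r in reg_lv]
    missing = [c for c in expected if c not in piv.columns]
    if missing or piv.isna().any().any():
        raise ValueError(f"unbalanced measure table (missing cells: {missing or 'NaNs'})")
    piv = piv.loc[subjects, expected]
    Y = piv.to_numpy().reshape(len(subjects), len(stim_lv), len(reg_lv))
    sex_of = table.drop_duplicates("subject_id").set_index("subject_id")["sex"]
    groups = np.asarray([0 if sex_of[s] == "female" else 1 for s in subjects])
    return Y, groups, subjects


# ---------------------------------------------------------------------------
# Assumption checks


def assumption_checks(table: pd.DataFrame) -> pd.DataFrame:
    """Shapiro–Wilk per stimulus × region cell and Levene across sexes.

    Advisory only — results never gate the ANOVA.  Degenerate (constant)
    cells are reported with ``note = 'skipped: constant'``.
    """
    rows = []
    for (stim, region), cell in table.groupby(["stimulus", "region"]):
        vals = cell["value"].to_numpy()
        row = {"stimulus": stim, "region": region, "n": len(vals)}
        # near-constant cells make the Shapiro W denominator degenerate
        if len(vals) < 3 or np.ptp(vals) <= 1e-10 * max(1.0, np.abs(vals).max()):
            row.update({"shapiro_W": np.nan, "shapiro_p": np.nan, "note": "skipped: constant or n<3"})
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                W, p = sstats.shapiro(vals)
            row.update({"shapiro_W": W, "shapiro_p": p, "note": ""})
        by_sex = [g["value"].to_numpy() for _, g in cell.groupby("sex")]
        scale = max(1.0, float(np.abs(vals).max()))
        degenerate = any(np.ptp(np.abs(g - np.median(g))) <= 1e-10 * scale for g in by_sex)
        if len(by_sex) == 2 and all(len(g) >= 2 for g in by_sex) and not degenerate:
            with np.errstate(divide="ignore", invalid="ignore"):
                _, lev_p = sstats.levene(*by_sex)
            row["levene_p"] = lev_p
        else:
            row["levene_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mixed three-way RM-ANOVA


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) × k orthonormal contrast matrix (Helmert, normalized)."""
    H = np.zeros((k - 1, k))
    for i in range(k - 1):
        H[i, : i + 1] = 1.0
        H[i, i + 1] = -(i + 1)
        H[i] /= np.linalg.norm(H[i])
    return H


def _gg_epsilon_and_mauchly(scores: np.ndarray, groups: np.ndarray) -> tuple[float, Optional[float]]:
    """Box's ε and Mauchly p from subject contrast scores (n × d).

    The covariance is pooled within between-subject groups (group means
    removed), with n − n_groups error degrees of freedom.
    """
    n, d = scores.shape
    if d == 1:
        return 1.0, None
    centered = scores.astype(float).copy()
    for g in np.unique(groups):
        centered[groups == g] -= centered[groups == g].mean(axis=0)
    n_groups = len(np.unique(groups))
    dfe = n - n_groups
    S = centered.T @ centered / dfe
    tr = np.trace(S)
    eps = tr**2 / (d * np.trace(S @ S))
    eps = float(min(1.0, max(1.0 / d, eps)))

    # Mauchly's sphericity test (chi-square approximation)
    det = np.linalg.det(S)
    mauchly_p: Optional[float] = None
    if det > 0 and dfe > d:
        W = det / (tr / d) ** d
        f = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * dfe)
        chi2 = -f * dfe * np.log(W)
        dof = d * (d + 1) // 2 - 1
        mauchly_p = float(sstats.chi2.sf(chi2, dof))
    return eps, mauchly_p


def mixed_rm_anova(table: pd.DataFrame) -> AnovaResult:
    """Mixed three-way RM-ANOVA: sex (between) × stimulus × region (within).

    ``table`` is a balanced MeasureTable with columns ``subject_id, sex,
    stimulus, region, value``.  Sums of squares follow the balanced
    split-plot decomposition with subjects nested in sex; each within effect
    carries its own error stratum, Greenhouse–Geisser ε and partial η².
    """
    Y, groups, subjects = _pivot(table)
    n, p, q = Y.shape
    a = len(np.unique(groups))
    if a < 2 or np.bincount(groups).min() < 2:
        raise ValueError("need at least 2 subjects per sex for the mixed design")

    m = Y.mean()
    m_i = Y.mean(axis=(1, 2))                      # subject
    m_j = Y.mean(axis=(0, 2))                      # stimulus
    m_k = Y.mean(axis=(0, 1))                      # region
    m_ij = Y.mean(axis=2)                          # subject × stimulus
    m_ik = Y.mean(axis=1)                          # subject × region
    m_jk = Y.mean(axis=0)                          # stimulus × region

    n_g = np.bincount(groups).astype(float)        # subjects per sex
    m_g = np.array([Y[groups == g].mean() for g in range(a)])
    m_gj = np.stack([Y[groups == g].mean(axis=(0, 2)) for g in range(a)])
    m_gk = np.stack([Y[groups == g].mean(axis=(0, 1)) for g in range(a)])
    m_gjk = np.stack([Y[groups == g].mean(axis=0) for g in range(a)])

    mg_i = m_g[groups]                             # sex mean per subject

    ss_sex = p * q * float(np.sum(n_g * (m_g - m) ** 2))
    ss_subj = p * q * float(np.sum((m_i - mg_i) ** 2))

    ss_B = n * q * float(np.sum((m_j - m) ** 2))
    ss_BxS = q * float(np.sum(n_g[:, None] * (m_gj - m_g[:, None] - m_j[None, :] + m) ** 2))
    ss_errB = q * float(np.sum((m_ij - m_i[:, None] - m_gj[groups] + mg_i[:, None]) ** 2))

    ss_C = n * p * float(np.sum((m_k - m) ** 2))
    ss_CxS = p * float(np.sum(n_g[:, None] * (m_gk - m_g[:, None] - m_k[None, :] + m) ** 2))
    ss_errC = p * float(np.sum((m_ik - m_i[:, None] - m_gk[groups] + mg_i[:, None]) ** 2))

    inter_jk = m_jk - m_j[:, None] - m_k[None, :] + m
    ss_BC = n * float(np.sum(inter_jk**2))
    inter_gjk = (
        m_gjk
        - m_gj[:, :, None]
        - m_gk[:, None, :]
        + m_g[:, None, None]
        - inter_jk[None, :, :]
    )
    ss_BCxS = float(np.sum(n_g[:, None, None] * inter_gjk**2))
    resid = (
        Y
        - m_ij[:, :, None]
        - m_ik[:, None, :]
        + m_i[:, None, None]
        - (m_gjk[groups] - m_gj[groups][:, :, None] - m_gk[groups][:, None, :] + mg_i[:, None, None])
    )
    ss_errBC = float(np.sum(resid**2))

    df_subj = n - a
    effects: dict[str, AnovaEffect] = {}

    def add(name: str, ss: float, df1: int, ss_err: float, df2: int, eps=None, mauchly=None):
        F = (ss / df1) / (ss_err / df2) if ss_err > 0 else np.inf
        p_unc = float(sstats.f.sf(F, df1, df2))
        p_gg = None
        if eps is not None:
            p_gg = float(sstats.f.sf(F, df1 * eps, df2 * eps))
        effects[name] = AnovaEffect(
            effect=name,
            ss=ss,
            ss_error=ss_err,
            df=(df1, df2),
            F=float(F),
            p_uncorrected=p_unc,
            gg_epsilon=eps,
            p_gg=p_gg,
            mauchly_p=mauchly,
            partial_eta_sq=ss / (ss + ss_err) if (ss + ss_err) > 0 else np.nan,
        )

    # contrast scores for ε: flatten within cells as (stimulus, region)
    flat = Y.reshape(n, p * q)
    C_B = np.kron(_orthonormal_contrasts(p), np.ones((1, q)) / np.sqrt(q))
    C_C = np.kron(np.ones((1, p)) / np.sqrt(p), _orthonormal_contrasts(q))
    C_BC = np.kron(_orthonormal_contrasts(p), _orthonormal_contrasts(q))

    eps_B, mau_B = _gg_epsilon_and_mauchly(flat @ C_B.T, groups)
    eps_C, mau_C = _gg_epsilon_and_mauchly(flat @ C_C.T, groups)
    eps_BC, mau_BC = _gg_epsilon_and_mauchly(flat @ C_BC.T, groups)

    add("sex", ss_sex, a - 1, ss_subj, df_subj)
    add("stimulus", ss_B, p - 1, ss_errB, (p - 1) * df_subj, eps_B, mau_B)
    add("stimulus*sex", ss_BxS, (a - 1) * (p - 1), ss_errB, (p - 1) * df_subj, eps_B, mau_B)
    add("region", ss_C, q - 1, ss_errC, (q - 1) * df_subj, eps_C, mau_C)
    add("region*sex", ss_CxS, (a - 1) * (q - 1), ss_errC, (q - 1) * df_subj, eps_C, mau_C)
    add("stimulus*region", ss_BC, (p - 1) * (q - 1), ss_errBC, (p - 1) * (q - 1) * df_subj, eps_BC, mau_BC)
    add("stimulus*region*sex", ss_BCxS, (a - 1) * (p - 1) * (q - 1), ss_errBC, (p - 1) * (q - 1) * df_subj, eps_BC, mau_BC)

    result = AnovaResult(effects=effects, n_subjects=n)
    # stash strata for the conservation invariant
    result.ss_components = {  # type: ignore[attr-defined]
        "sex": ss_sex, "subjects": ss_subj,
        "stimulus": ss_B, "stimulus*sex": ss_BxS, "err_stimulus": ss_errB,
        "region": ss_C, "region*sex": ss_CxS, "err_region": ss_errC,
        "stimulus*region": ss_BC, "stimulus*region*sex": ss_BCxS, "err_stimulus*region": ss_errBC,
    }
    result.ss_total = float(((Y - m) ** 2).sum())  # type: ignore[attr-defined]
    return result


def one_way_rm_anova(values: np.ndarray) -> AnovaEffect:
    """One-way repeated-measures ANOVA on ``values[subject, level]``.

    Error term is the subject × level interaction; GG ε and partial η² are
    reported as in the mixed model.
    """
    Y = np.asarray(values, dtype=float)
    n, k = Y.shape
    m = Y.mean()
    m_i = Y.mean(axis=1)
    m_j = Y.mean(axis=0)
    ss_lvl = n * float(np.sum((m_j - m) ** 2))
    resid = Y - m_i[:, None] - m_j[None, :] + m
    ss_err = float(np.sum(resid**2))
    df1, df2 = k - 1, (k - 1) * (n - 1)
    scores = Y @ _orthonormal_contrasts(k).T
    eps, mau = _gg_epsilon_and_mauchly(scores, np.zeros(n, dtype=int))
    F = (ss_lvl / df1) / (ss_err / df2) if ss_err > 0 else np.inf
    return AnovaEffect(
        effect="level",
        ss=ss_lvl,
        ss_error=ss_err,
        df=(df1, df2),
        F=float(F),
        p_uncorrected=float(sstats.f.sf(F, df1, df2)),
        gg_epsilon=eps,
        p_gg=float(sstats.f.sf(F, df1 * eps, df2 * eps)),
        mauchly_p=mau,
        partial_eta_sq=ss_lvl / (ss_lvl + ss_err) if (ss_lvl + ss_err) > 0 else np.nan,
    )


def pool_stimulus_pairs(table: pd.DataFrame, alpha: float = 0.05) -> tuple[pd.DataFrame, AnovaResult, bool]:
    """Preliminary exemplar ANOVA and pooling gate.

    When several exemplars of one stimulus class (e.g. four different
    conspecific advertisement calls) were presented, the same mixed design
    is first run with the exemplar ("stimulus pair") as the within factor.
    If its main effect is null (p ≥ alpha) the exemplars are pooled by
    subject × region averaging; otherwise the table is returned unpooled.

    Returns ``(table, preliminary_result, pooled)``.
    """
    prelim = mixed_rm_anova(table)
    pooled = prelim.effects["stimulus"].p >= alpha
    if not pooled:
        return table, prelim, False
    out = (
        table.groupby(["subject_id", "sex", "region"], as_index=False)["value"]
        .mean()
        .assign(stimulus="conspecific_call")
    )
    return out, prelim, True


# ---------------------------------------------------------------------------
# Post-hoc machinery


def _marginal_means(table: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Subject-level marginal means over the other within factor."""
    return (
        table.groupby(["subject_id", factor], sort=False)["value"]
        .mean()
        .unstack(factor)
    )


def _ordering_string(
    levels: Sequence[str],
    means: Mapping[str, float],
    sig: Mapping[frozenset, bool],
    negative: bool = True,
) -> str:
    """Assemble an ordering string such as ``"MN > TN, DN"``.

    Levels are sorted by component magnitude (most negative first for
    negative-polarity components) and grouped greedily: a new ``>`` group
    starts when a level differs significantly from every member of the
    current group.  Returns ``"ns"`` when nothing separates.
    """
    order = sorted(levels, key=lambda l: means[l], reverse=not negative)
    groups: list[list[str]] = [[order[0]]]
    for lvl in order[1:]:
        if all(sig.get(frozenset((lvl, g)), False) for g in groups[-1]):
            groups.append([lvl])
        else:
            groups[-1].append(lvl)
    if len(groups) == 1:
        return "ns"
    canonical = list(STIM_LEVELS + REGION_LEVELS)

    def canon_key(l: str):
        return (canonical.index(l), l) if l in canonical else (len(canonical), l)

    return " > ".join(
        ", ".join(ABBREV.get(l, l) for l in sorted(g, key=canon_key)) for g in groups
    )


def bonferroni_pairwise(
    table: pd.DataFrame,
    factor: str,
    alpha: float = 0.05,
    negative: bool = True,
) -> pd.DataFrame:
    """All pairwise paired t-tests on subject marginal means of ``factor``.

    Adjusted p = min(1, raw p × number of pairs).  The result carries the
    ordering string in ``attrs['ordering']`` (e.g. ``"MN > TN, DN"``).
    """
    marg = _marginal_means(table, factor)
    levels = list(marg.columns)
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    sig: dict[frozenset, bool] = {}
    for a_, b_ in pairs:
        t, praw = sstats.ttest_rel(marg[a_], marg[b_])
        padj = min(1.0, float(praw) * len(pairs))
        rows.append(
            {
                "level_a": a_,
                "level_b": b_,
                "mean_a": marg[a_].mean(),
                "mean_b": marg[b_].mean(),
                "t": float(t),
                "p_raw": float(praw),
                "p_bonferroni": padj,
                "significant": padj < alpha,
            }
        )
        sig[frozenset((a_, b_))] = padj < alpha
    out = pd.DataFrame(rows)
    out.attrs["ordering"] = _ordering_string(levels, marg.mean().to_dict(), sig, negative)
    return out


def simple_effects(
    table: pd.DataFrame,
    factor: str,
    conditioned_on: str,
    alpha: float = 0.05,
    negative: bool = True,
) -> pd.DataFrame:
    """Effect of ``factor`` within each level of ``conditioned_on``.

    For every conditioning level a one-way RM-ANOVA of ``factor`` is run on
    that level's subject × level matrix (error term computed within the
    level, not pooled), followed by Bonferroni pairwise comparisons.  Rows
    are labelled ``"<factor>|<LEVEL>"`` in the field's abbreviations.
    """
    rows = []
    cond_levels = sorted(table[conditioned_on].unique(), key=str)
    for lvl in cond_levels:
        sub = table[table[conditioned_on] == lvl]
        mat = sub.pivot_table(index="subject_id", columns=factor, values="value")
        eff = one_way_rm_anova(mat.to_numpy())
        ph = bonferroni_pairwise(sub, factor, alpha=alpha, negative=negative)
        rows.append(
            {
                "label": f"{factor}|{ABBREV.get(lvl, lvl)}",
                "conditioning_level": lvl,
                "F": eff.F,
                "df1": eff.df[0],
                "df2": eff.df[1],
                "p": eff.p,
                "p_gg": eff.p_gg,
                "partial_eta_sq": eff.partial_eta_sq,
                "significant": eff.p < alpha,
                "ordering": ph.attrs["ordering"] if eff.p < alpha else "ns",
            }
        )
    return pd.DataFrame(rows)
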