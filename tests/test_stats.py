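"""Mixed RM-ANOVA, sphericity correction, post-hocs and simple effects.

The mixed three-way decomposition is cross-checked against (a) an
independently coded textbook cell-means oracle (explicit Python loops), and
(b) pingouin's one-between/one-within mixed ANOVA on collapsed designs,
which shares the between and collapsed-within strata with the three-way
model on balanced data.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from anuran_erp.stats import (
    REGION_LEVELS,
    STIM_LEVELS,
    assumption_checks,
    bonferroni_pairwise,
    mixed_rm_anova,
    one_way_rm_anova,
    region_reduce,
    simple_effects,
)


def make_table(Y, sexes=None):
    """Build a MeasureTable from Y[subject, stimulus, region]."""
    n, p, q = Y.shape
    sexes = sexes or ["female"] * (n // 2) + ["male"] * (n - n // 2)
    rows = []
    for i in range(n):
        for j in range(p):
            for k in range(q):
                rows.append(
                    {
                        "subject_id": i,
                        "sex": sexes[i],
                        "stimulus": STIM_LEVELS[j] if p <= 3 else f"s{j}",
                        "region": REGION_LEVELS[k] if q <= 3 else f"r{k}",
                        "value": Y[i, j, k],
                    }
                )
    return pd.DataFrame(rows)


def null_table(rng, n=16, p=3, q=3, sd=1.0):
    return make_table(rng.normal(0.0, sd, (n, p, q)))


# ---------------------------------------------------------------------------
# Independent oracle: textbook cell-means sums of squares, explicit loops


def oracle_mixed_anova(Y, groups):
    """Split-plot SS computed the long way: loops over dictionary means."""
    n, p, q = Y.shape
    glv = sorted(set(groups))

    def mean(sel):
        vals = [Y[i, j, k] for i in range(n) for j in range(p) for k in range(q) if sel(i, j, k)]
        return sum(vals) / len(vals)

    m = mean(lambda i, j, k: True)
    subj = {i: mean(lambda i2, j, k: i2 == i) for i in range(n)}
    grp = {g: mean(lambda i, j, k: groups[i] == g) for g in glv}
    stim = {j: mean(lambda i, j2, k: j2 == j) for j in range(p)}
    reg = {k: mean(lambda i, j, k2: k2 == k) for k in range(q)}
    gs = {(g, j): mean(lambda i, j2, k: groups[i] == g and j2 == j) for g in glv for j in range(p)}
    gr = {(g, k): mean(lambda i, j, k2: groups[i] == g and k2 == k) for g in glv for k in range(q)}
    sr = {(j, k): mean(lambda i, j2, k2: j2 == j and k2 == k) for j in range(p) for k in range(q)}
    gsr = {
        (g, j, k): mean(lambda i, j2, k2: groups[i] == g and j2 == j and k2 == k)
        for g in glv for j in range(p) for k in range(q)
    }
    subj_stim = {(i, j): mean(lambda i2, j2, k: i2 == i and j2 == j) for i in range(n) for j in range(p)}
    subj_reg = {(i, k): mean(lambda i2, j, k2: i2 == i and k2 == k) for i in range(n) for k in range(q)}
    n_g = {g: sum(1 for i in range(n) if groups[i] == g) for g in glv}

    ss = {}
    ss["sex"] = p * q * sum(n_g[g] * (grp[g] - m) ** 2 for g in glv)
    ss["subjects"] = p * q * sum((subj[i] - grp[groups[i]]) ** 2 for i in range(n))
    ss["stimulus"] = n * q * sum((stim[j] - m) ** 2 for j in range(p))
    ss["stimulus*sex"] = q * sum(n_g[g] * (gs[g, j] - grp[g] - stim[j] + m) ** 2 for g in glv for j in range(p))
    ss["err_stimulus"] = q * sum(
        (subj_stim[i, j] - subj[i] - gs[groups[i], j] + grp[groups[i]]) ** 2
        for i in range(n) for j in range(p)
    )
    ss["region"] = n * p * sum((reg[k] - m) ** 2 for k in range(q))
    ss["region*sex"] = p * sum(n_g[g] * (gr[g, k] - grp[g] - reg[k] + m) ** 2 for g in glv for k in range(q))
    ss["err_region"] = p * sum(
        (subj_reg[i, k] - subj[i] - gr[groups[i], k] + grp[groups[i]]) ** 2
        for i in range(n) for k in range(q)
    )
    ss["stimulus*region"] = n * sum((sr[j, k] - stim[j] - reg[k] + m) ** 2 for j in range(p) for k in range(q))
    ss["stimulus*region*sex"] = sum(
        n_g[g]
        * (
            gsr[g, j, k] - gs[g, j] - gr[g, k] + grp[g]
            - (sr[j, k] - stim[j] - reg[k] + m)
        ) ** 2
        for g in glv for j in range(p) for k in range(q)
    )
    ss["err_stimulus*region"] = sum(
        (
            Y[i, j, k]
            - subj_stim[i, j] - subj_reg[i, k] + subj[i]
            - (gsr[groups[i], j, k] - gs[groups[i], j] - gr[groups[i], k] + grp[groups[i]])
        ) ** 2
        for i in range(n) for j in range(p) for k in range(q)
    )
    a = len(glv)
    df = {
        "sex": (a - 1, n - a),
        "stimulus": (p - 1, (p - 1) * (n - a)),
        "region": (q - 1, (q - 1) * (n - a)),
        "stimulus*region": ((p - 1) * (q - 1), (p - 1) * (q - 1) * (n - a)),
    }
    err_of = {"sex": "subjects", "stimulus": "err_stimulus", "region": "err_region",
              "stimulus*region": "err_stimulus*region"}
    F = {
        e: (ss[e] / df[e][0]) / (ss[err_of[e]] / df[e][1])
        for e in df
    }
    return ss, df, F


# ---------------------------------------------------------------------------


def test_region_reduce_means_and_shape():
    rows = []
    for sid in range(16):
        for stim in STIM_LEVELS:
            for region, (l, r) in zip(REGION_LEVELS, [(-4.0, -6.0), (-2.0, -2.0), (-8.0, -10.0)]):
                rows.append({"subject_id": sid, "sex": "female" if sid < 8 else "male",
                             "stimulus": stim, "region": region, "side": "left", "value": l})
                rows.append({"subject_id": sid, "sex": "female" if sid < 8 else "male",
                             "stimulus": stim, "region": region, "side": "right", "value": r})
    out = region_reduce(pd.DataFrame(rows))
    assert len(out) == 144  # 16 subjects × 3 stimuli × 3 regions
    tele = out[out.region == "telencephalon"].value
    assert np.allclose(tele, -5.0)
    assert np.allclose(out[out.region == "diencephalon"].value, -2.0)


def test_region_reduce_flags_missing_side():
    df = pd.DataFrame(
        [
            {"subject_id": 0, "sex": "female", "stimulus": "pure_tone", "region": "telencephalon",
             "side": "left", "value": -1.0},
            {"subject_id": 0, "sex": "female", "stimulus": "pure_tone", "region": "mesencephalon",
             "side": "left", "value": -1.0},
            {"subject_id": 0, "sex": "female", "stimulus": "pure_tone", "region": "mesencephalon",
             "side": "right", "value": -3.0},
        ]
    )
    with pytest.warns(UserWarning):
        out = region_reduce(df)
    assert list(out.region) == ["mesencephalon"]
    assert out.value.iloc[0] == -2.0


def test_design_degrees_of_freedom():
    """16 subjects, 2 sexes, 3×3 within: (1,14), (2,28), (2,28), (4,56)."""
    res = mixed_rm_anova(null_table(np.random.default_rng(0)))
    assert res.effects["sex"].df == (1, 14)
    assert res.effects["stimulus"].df == (2, 28)
    assert res.effects["region"].df == (2, 28)
    assert res.effects["stimulus*region"].df == (4, 56)


def test_ss_conservation():
    res = mixed_rm_anova(null_table(np.random.default_rng(1)))
    assert sum(res.ss_components.values()) == pytest.approx(res.ss_total, rel=1e-8)


@pytest.mark.parametrize("trial", range(5))
def test_matches_loop_oracle_small_designs(trial):
    """F on random small tables (n=6, 2×2 within) matches the loop oracle."""
    rng = np.random.default_rng(100 + trial)
    Y = rng.normal(0.0, 1.0, (6, 2, 2))
    groups = [0, 0, 0, 1, 1, 1]
    res = mixed_rm_anova(make_table(Y))
    ss, df, F = oracle_mixed_anova(Y, groups)
    for eff in ("sex", "stimulus", "region", "stimulus*region"):
        assert res.effects[eff].df == df[eff]
        assert res.effects[eff].F == pytest.approx(F[eff], rel=1e-8)
        assert res.effects[eff].ss == pytest.approx(ss[eff], rel=1e-8)


def test_matches_loop_oracle_full_design():
    rng = np.random.default_rng(7)
    Y = rng.normal(-5.0, 2.0, (16, 3, 3))
    res = mixed_rm_anova(make_table(Y))
    ss, df, F = oracle_mixed_anova(Y, [0] * 8 + [1] * 8)
    for eff in ("sex", "stimulus", "region", "stimulus*region"):
        assert res.effects[eff].F == pytest.approx(F[eff], rel=1e-8)


def test_matches_pingouin_collapsed_mixed_anova():
    """Collapsing one within factor reproduces pingouin's mixed ANOVA F."""
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(11)
    Y = rng.normal(0.0, 1.0, (16, 3, 3))
    table = make_table(Y)
    res = mixed_rm_anova(table)
    collapsed = table.groupby(["subject_id", "sex", "stimulus"], as_index=False)["value"].mean()
    aov = pg.mixed_anova(collapsed, dv="value", within="stimulus", subject="subject_id", between="sex")
    f_between = float(aov.loc[aov.Source == "sex", "F"].iloc[0])
    f_within = float(aov.loc[aov.Source == "stimulus", "F"].iloc[0])
    assert res.effects["sex"].F == pytest.approx(f_between, rel=1e-6)
    assert res.effects["stimulus"].F == pytest.approx(f_within, rel=1e-6)


def test_gg_epsilon_two_level_factor_is_one():
    rng = np.random.default_rng(3)
    eff = one_way_rm_anova(rng.normal(0.0, 1.0, (12, 2)))
    assert eff.gg_epsilon == 1.0
    Y = rng.normal(0.0, 1.0, (8, 2, 2))
    res = mixed_rm_anova(make_table(Y))
    assert res.effects["stimulus"].gg_epsilon == 1.0
    assert res.effects["region"].gg_epsilon == 1.0


def test_gg_epsilon_bounds_and_compound_symmetry():
    rng = np.random.default_rng(4)
    for _ in range(20):
        res = mixed_rm_anova(null_table(rng))
        for eff in ("stimulus", "region", "stimulus*region"):
            e = res.effects[eff]
            assert 1.0 / e.df[0] <= e.gg_epsilon <= 1.0
    # i.i.d. cells satisfy compound symmetry: ε near 1 for large n
    big = make_table(np.random.default_rng(5).normal(0.0, 1.0, (200, 3, 3)))
    res = mixed_rm_anova(big)
    assert res.effects["region"].gg_epsilon > 0.95


def test_gg_epsilon_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(6)
    # single-sex data: pooled covariance equals the plain covariance
    Y = rng.normal(0.0, 1.0, (12, 4))
    eff = one_way_rm_anova(Y)
    df = pd.DataFrame(Y, columns=list("abcd"))
    assert eff.gg_epsilon == pytest.approx(float(pg.epsilon(df, correction="gg")), rel=1e-6)


def test_unbalanced_and_degenerate_tables_rejected():
    t = null_table(np.random.default_rng(8))
    with pytest.raises(ValueError):
        mixed_rm_anova(t.iloc[:-1])
    single = t[t.subject_id == 0]
    with pytest.raises(ValueError):
        mixed_rm_anova(single)
    two = t[t.subject_id.isin([0, 8])]  # one subject per sex
    with pytest.raises(ValueError):
        mixed_rm_anova(two)


def test_assumption_checks_report():
    rng = np.random.default_rng(9)
    rep = assumption_checks(null_table(rng))
    assert len(rep) == 9
    assert (rep.note == "").all()
    # constant cell is skipped, not crashed
    t = null_table(rng)
    t.loc[t.region == "telencephalon", "value"] = -1.0
    rep2 = assumption_checks(t)
    skipped = rep2[rep2.region == "telencephalon"]
    assert (skipped.note != "").all()


def test_shapiro_calibration_on_normal_samples():
    """Normal samples of n=100 pass Shapiro–Wilk in ≥ 90 % of seeds."""
    from scipy import stats as ss

    rng = np.random.default_rng(10)
    passes = sum(ss.shapiro(rng.normal(size=100)).pvalue > 0.05 for _ in range(200))
    assert passes >= 180


def test_bonferroni_pairwise_counts_and_identical_means():
    rng = np.random.default_rng(12)
    t = null_table(rng)
    out = bonferroni_pairwise(t, "region")
    assert len(out) == 3  # C(3,2) pairs, multiplier 3
    assert np.allclose(out.p_bonferroni, np.minimum(1.0, out.p_raw * 3))
    # identical level means -> nothing significant
    Y = np.tile(rng.normal(0.0, 1.0, (16, 3, 1)), (1, 1, 3))
    same = bonferroni_pairwise(make_table(Y), "region")
    assert np.allclose(same.p_bonferroni, 1.0)
    assert same.attrs["ordering"] == "ns"


def test_bonferroni_programmed_effect_ordering():
    """Mesencephalon −10 vs others −3, sd 1, n 16: 'MN > TN, DN'."""
    rng = np.random.default_rng(13)
    Y = np.empty((16, 3, 3))
    Y[:, :, 0] = rng.normal(-3.0, 1.0, (16, 3))
    Y[:, :, 1] = rng.normal(-3.0, 1.0, (16, 3))
    Y[:, :, 2] = rng.normal(-10.0, 1.0, (16, 3))
    out = bonferroni_pairwise(make_table(Y), "region")
    assert out.attrs["ordering"] == "MN > TN, DN"


def test_simple_effects_degenerate_conditioning():
    """Conditioning on a single-level factor reproduces the overall one-way."""
    rng = np.random.default_rng(14)
    Y = rng.normal(0.0, 1.0, (10, 1, 3))
    t = make_table(Y)
    se = simple_effects(t, "region", "stimulus")
    assert len(se) == 1
    overall = one_way_rm_anova(Y[:, 0, :])
    assert se.F.iloc[0] == pytest.approx(overall.F, rel=1e-9)


def test_simple_effects_programmed_interaction():
    """A region effect present only for conspecific calls shows up only there."""
    rng = np.random.default_rng(15)
    Y = rng.normal(-3.0, 1.0, (16, 3, 3))
    Y[:, 0, 0] -= 6.0  # conspecific_call × telencephalon strongly negative
    se = simple_effects(make_table(Y), "region", "stimulus")
    mc = se[se.conditioning_level == "conspecific_call"].iloc[0]
    assert mc.significant and mc.ordering.startswith("TN")
    others = se[se.conditioning_level != "conspecific_call"]
    assert not others.significant.any()


def test_simple_effects_null_calibration():
    """Under a null, per-level simple-effect p-values look uniform."""
    rng = np.random.default_rng(16)
    pvals = []
    for _ in range(120):
        se = simple_effects(null_table(rng, n=10), "region", "stimulus")
        pvals.extend(se.p.tolist())
    frac = np.mean(np.asarray(pvals) < 0.05)
    assert 0.02 <= frac <= 0.09


def test_stimulus_pair_pooling_gate():
    """Exemplar pooling happens only when the pair main effect is null."""
    from anuran_erp.stats import pool_stimulus_pairs

    rng = np.random.default_rng(20)
    base = rng.normal(-4.0, 1.0, (16, 1, 3))
    Y_null = base + rng.normal(0.0, 0.3, (16, 4, 3))  # 4 exemplars, no pair effect
    t_null = make_table(Y_null)
    pooled_table, prelim, pooled = pool_stimulus_pairs(t_null)
    assert pooled
    assert prelim.effects["stimulus"].df == (3, 42)
    assert len(pooled_table) == 16 * 3
    assert set(pooled_table.stimulus) == {"conspecific_call"}

    Y_eff = Y_null.copy()
    Y_eff[:, 0, :] -= 5.0  # one exemplar strongly different
    same_table, prelim2, pooled2 = pool_stimulus_pairs(make_table(Y_eff))
    assert not pooled2
    assert len(same_table) == len(make_table(Y_eff))
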