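"""Threshold elevation, t-tests, Holm, and the aligned-rank machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import f as f_dist
from scipy.stats import rankdata, t as t_dist

import latmask as lm
from latmask.stats import _split_plot, art_analysis, diff_of_diffs_posthoc

from conftest import make_threshold_table


# ---------------------------------------------------------------------------
# TE
# ---------------------------------------------------------------------------


def _pair_rows(pid, coll, orth, sep=3.0, group="MD", phase="pre"):
    return [
        (pid, group, phase, "collinear", sep, coll),
        (pid, group, phase, "orthogonal", sep, orth),
    ]


@pytest.mark.parametrize(
    "coll,orth,expected",
    [
        (0.217, 0.229, math.log10(0.217 / 0.229)),  # ~ -0.0233
        (0.3, 0.3, 0.0),
        (0.2, 0.1, math.log10(2)),  # ~ 0.3010
    ],
)
def test_te_formula(coll, orth, expected):
    table = make_threshold_table(_pair_rows("P1", coll, orth))
    te = lm.compute_TE(table)
    assert te.loc[0, "te"] == pytest.approx(expected, abs=1e-12)


def test_te_of_first_patient_cell(te_table):
    row = te_table[
        (te_table["participant"] == "AMD1") & (te_table["separation"] == 3.0)
    ]
    assert row["te"].iloc[0] == pytest.approx(-0.0233, abs=5e-4)


def test_te_missing_partner_names_cell():
    table = make_threshold_table(
        _pair_rows("P1", 0.2, 0.1) + [("P2", "MD", "pre", "collinear", 3.0, 0.2)]
    )
    with pytest.raises(lm.PairingError, match="P2"):
        lm.compute_TE(table)


@given(
    coll=st.floats(0.01, 1.0),
    orth=st.floats(0.01, 1.0),
)
def test_te_antisymmetry(coll, orth):
    forward = lm.compute_TE(make_threshold_table(_pair_rows("P", coll, orth)))
    swapped = lm.compute_TE(make_threshold_table(_pair_rows("P", orth, coll)))
    assert forward.loc[0, "te"] == pytest.approx(-swapped.loc[0, "te"], abs=1e-9)


def test_group_summary_matches_reported_means(te_table):
    mean3, sd3, n3 = lm.group_te_summary(te_table, "MD", 3.0)
    assert (mean3, n3) == (pytest.approx(0.213, abs=2e-3), 5)
    assert sd3 == pytest.approx(0.156, abs=2e-3)
    mean8, _, _ = lm.group_te_summary(te_table, "MD", 8.0)
    assert mean8 == pytest.approx(-0.0836, abs=2e-3)


def test_group_summary_rejects_single_participant():
    table = make_threshold_table(_pair_rows("P1", 0.2, 0.1))
    te = lm.compute_TE(table)
    with pytest.raises(lm.ParameterError):
        lm.group_te_summary(te, "MD", 3.0)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------


def _t_oracle_one(values, mu):
    arr = np.asarray(values, float)
    n = arr.size
    t = (arr.mean() - mu) / (arr.std(ddof=1) / math.sqrt(n))
    return t, 2 * t_dist.sf(abs(t), n - 1)


def _t_oracle_two(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = a.size, b.size
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, 2 * t_dist.sf(abs(t), n1 + n2 - 2)


def test_t_tests_match_from_scratch_formulas(rng):
    for _ in range(20):
        a = rng.normal(size=rng.integers(3, 12))
        b = rng.normal(size=rng.integers(3, 12))
        r1 = lm.one_sample_t(a, mu=0.3)
        t, p = _t_oracle_one(a, 0.3)
        assert r1.statistic == pytest.approx(t, abs=1e-10)
        assert r1.p_value == pytest.approx(p, abs=1e-10)
        r2 = lm.two_sample_t(a, b)
        t, p = _t_oracle_two(a, b)
        assert r2.statistic == pytest.approx(t, abs=1e-10)
        assert r2.p_value == pytest.approx(p, abs=1e-10)
        c = rng.normal(size=a.size)
        r3 = lm.paired_t(a, a + c)
        t, p = _t_oracle_one(c, 0.0)
        assert r3.statistic == pytest.approx(t, abs=1e-10)


def test_one_sample_hand_example():
    report = lm.one_sample_t([1.0, 2.0, 3.0], mu=0.0)
    assert report.statistic == pytest.approx(2 / (1 / math.sqrt(3)))
    assert report.df == 2


def test_degenerate_t_inputs():
    flat = lm.one_sample_t([0.4, 0.4, 0.4], mu=0.4)
    assert (flat.statistic, flat.p_value) == (0.0, 1.0)
    inf = lm.one_sample_t([0.4, 0.4, 0.4], mu=0.0)
    assert math.isinf(inf.statistic) and inf.p_value == 0.0
    assert "zero variance" in inf.note
    same = lm.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert same.statistic == 0.0
    null = lm.paired_t([1.0, 2.0], [1.0, 2.0])
    assert (null.statistic, null.p_value) == (0.0, 1.0)
    with pytest.raises(lm.PairingError):
        lm.paired_t([1.0, 2.0], [1.0, 2.0, 3.0])
    with pytest.raises(lm.ParameterError):
        lm.one_sample_t([1.0])


def test_holm_step_down():
    adjusted = lm.holm_adjust([0.01, 0.04, 0.03])
    assert adjusted == pytest.approx([0.03, 0.06, 0.06])


@given(
    p=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8),
)
def test_holm_properties(p):
    adj = lm.holm_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# ART
# ---------------------------------------------------------------------------


def _mixed_design(rng, n_per_group=5, levels=(3.0, 4.0, 6.0, 8.0), effect=None):
    rows = []
    for g, gname in enumerate(("MD", "control")):
        for i in range(n_per_group):
            subject = f"{gname}{i}"
            for j, lev in enumerate(levels):
                y = rng.normal()
                if effect == "group":
                    y += 2.0 * g
                elif effect == "interaction":
                    y += g * j * 1.5
                rows.append((subject, gname, lev, y))
    return pd.DataFrame(rows, columns=["participant", "group", "separation", "y"])


def _oracle_art_mixed(df):
    """Brute-force oracle: explicit alignment, ranking and sums of
    squares, written independently of the implementation."""
    y = df["y"].to_numpy()
    grand = y.mean()
    out = {}
    cell = df.groupby(["group", "separation"])["y"].transform("mean").to_numpy()
    for factor in ("group", "separation"):
        marg = df.groupby(factor)["y"].transform("mean").to_numpy()
        aligned = y - cell + (marg - grand)
        r = rankdata(aligned)
        tmp = df.assign(r=r)
        if factor == "group":
            subj = tmp.groupby(["participant", "group"])["r"].mean().reset_index()
            groups = [
                subj[subj["group"] == g]["r"].to_numpy()
                for g in subj["group"].unique()
            ]
            gm = [x.mean() for x in groups]
            big = np.concatenate(groups)
            ssb = sum(len(x) * (x.mean() - big.mean()) ** 2 for x in groups)
            ssw = sum(((x - x.mean()) ** 2).sum() for x in groups)
            df1, df2 = len(groups) - 1, big.size - len(groups)
            F = (ssb / df1) / (ssw / df2)
        else:
            wide = tmp.pivot_table(index="participant", columns="separation", values="r")
            gmap = tmp.drop_duplicates("participant").set_index("participant")["group"]
            g = gmap.loc[wide.index].to_numpy()
            Y = wide.to_numpy()
            S, b = Y.shape
            lev = Y.mean(axis=0)
            ss_lev = S * ((lev - Y.mean()) ** 2).sum()
            ss_err = 0.0
            for lab in np.unique(g):
                blk = Y[g == lab]
                resid = (
                    blk
                    - blk.mean(axis=0)
                    - blk.mean(axis=1)[:, None]
                    + blk.mean()
                )
                ss_err += (resid**2).sum()
            a = len(np.unique(g))
            n = S // a
            df1 = b - 1
            df2 = a * (n - 1) * (b - 1)
            F = (ss_lev / df1) / (ss_err / df2)
        out[factor] = (F, df1, df2)
    return out


def test_art_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    df = _mixed_design(rng, n_per_group=3, levels=(3.0, 8.0), effect="group")
    df["y"] = np.round(df["y"] * 2) + df["y"].lt(0)  # induce ties
    art = art_analysis(df, "y", "participant", between="group", within=["separation"])
    oracle = _oracle_art_mixed(df)
    for factor in ("group", "separation"):
        F, df1, df2 = oracle[factor]
        assert art.effects[factor].F == pytest.approx(F, abs=1e-10)
        assert art.effects[factor].df == (df1, df2)
        assert art.effects[factor].p_value == pytest.approx(
            f_dist.sf(F, df1, df2), abs=1e-12
        )


def test_split_plot_engine_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(13)
    df = _mixed_design(rng, n_per_group=5, effect="interaction")
    wide = df.pivot_table(index="participant", columns="separation", values="y")
    gmap = df.drop_duplicates("participant").set_index("participant")["group"]
    Y = wide.to_numpy()
    res = _split_plot(Y, gmap.loc[wide.index].to_numpy())
    aov = pg.mixed_anova(
        data=df, dv="y", within="separation", between="group", subject="participant"
    ).set_index("Source")
    assert res["between"][0] == pytest.approx(aov.loc["group", "F"], rel=1e-9)
    assert res["within"][0] == pytest.approx(aov.loc["separation", "F"], rel=1e-9)
    assert res["interaction"][0] == pytest.approx(
        aov.loc["Interaction", "F"], rel=1e-9
    )


def test_art_reduces_to_rank_anova_for_single_between_factor():
    rng = np.random.default_rng(3)
    rows = [
        (f"s{i}", "A" if i < 6 else "B", rng.normal() + (0.8 if i < 6 else 0.0))
        for i in range(12)
    ]
    df = pd.DataFrame(rows, columns=["participant", "group", "y"])
    art = art_analysis(df, "y", "participant", between="group", within=[])
    r = rankdata(df["y"])
    a = r[df["group"] == "A"]
    b = r[df["group"] == "B"]
    ssb = len(a) * (a.mean() - r.mean()) ** 2 + len(b) * (b.mean() - r.mean()) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    F = ssb / (ssw / (len(r) - 2))
    assert art.effects["group"].F == pytest.approx(F, rel=1e-9)


def test_pure_main_effect_yields_tied_interaction():
    rng = np.random.default_rng(5)
    df = _mixed_design(rng, n_per_group=3, levels=(3.0, 8.0))
    df["y"] = np.where(df["group"] == "MD", 1.0, 0.0)  # pure group effect
    art = art_analysis(df, "y", "participant", between="group", within=["separation"])
    inter = art.effects["group:separation"]
    assert np.unique(inter.ranks).size == 1  # maximally tied
    assert inter.F == 0.0
    assert inter.p_value == 1.0


def test_two_within_factors_refuse_interaction(fixtures):
    with pytest.raises(lm.DesignError):
        art_analysis(
            fixtures.table2,
            "threshold",
            "participant",
            between="group",
            within=["orientation", "separation"],
            interaction=True,
        )
    # main effects remain available
    art = art_analysis(
        fixtures.table2,
        "threshold",
        "participant",
        between="group",
        within=["orientation", "separation"],
    )
    assert set(art.effects) == {"group", "orientation", "separation"}


def test_unbalanced_design_rejected():
    rng = np.random.default_rng(11)
    df = _mixed_design(rng, n_per_group=3, levels=(3.0, 8.0))
    df = df.iloc[:-2]  # drop one subject's cells
    with pytest.raises(lm.DesignError):
        art_analysis(df, "y", "participant", between="group", within=["separation"])


def test_diff_of_diffs_null_contrast():
    # (A-B) identical at both within levels -> estimate 0, p = 1
    rows = []
    for g, gname in enumerate(("MD", "control")):
        for i in range(3):
            base = 10 * g + i
            rows.append((f"{gname}{i}", gname, 3.0, base + 1.0))
            rows.append((f"{gname}{i}", gname, 8.0, base))
    df = pd.DataFrame(rows, columns=["participant", "group", "separation", "y"])
    art = art_analysis(df, "y", "participant", between="group", within=["separation"])
    posthoc = diff_of_diffs_posthoc(art)
    assert posthoc["estimate"].iloc[0] == pytest.approx(0.0)
    assert posthoc["p_holm"].iloc[0] == 1.0


def test_diff_of_diffs_unknown_level_rejected(te_table):
    art = art_analysis(
        te_table, "te", "participant", between="group", within=["separation"]
    )
    with pytest.raises(lm.DesignError, match="5.0"):
        diff_of_diffs_posthoc(art, level_pairs=[(3.0, 5.0)])


def test_art_type_one_error_calibrated_quick():
    """400 null simulations of the mixed 2-group x 4-level design keep
    each effect's false-positive rate near the nominal 5 %."""
    rng = np.random.default_rng(99)
    hits = {"group": 0, "separation": 0, "group:separation": 0}
    n_sim = 400
    for _ in range(n_sim):
        df = _mixed_design(rng)
        art = art_analysis(
            df, "y", "participant", between="group", within=["separation"]
        )
        for k in hits:
            hits[k] += art.effects[k].p_value < 0.05
    for k, h in hits.items():
        assert 0.02 <= h / n_sim <= 0.08, (k, h / n_sim)
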