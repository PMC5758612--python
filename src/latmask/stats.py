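"""Threshold-elevation statistics and the nonparametric test battery.

Threshold elevation (TE) quantifies lateral masking as a log threshold
ratio:

    TE = log10(CT_collinear / CT_orthogonal)

computed per participant, phase and target-to-flanker separation.
Positive TE means the collinear flankers impaired detection
(inhibition), negative TE means they helped (facilitation).

Group-level inference uses one-/two-sample and paired t-tests on TE and,
for factorial questions on small samples, the Aligned Rank Transform
(ART): per effect, all *other* estimated effects are stripped from each
response, the aligned responses are ranked (midranks on ties) and an
ordinary factorial ANOVA is run on the ranks, of which only the aligned
effect is interpreted.  Interactions between one between-subject and one
within-subject factor use aligned ranks of within-subject scores;
interactions involving more than one within factor are refused.
Interaction post-hocs compare differences of differences
(e.g. A-B|3lambda vs A-B|8lambda) with Holm adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .exceptions import DesignError, PairingError, ParameterError

__all__ = [
    "THRESHOLD_COLUMNS",
    "validate_threshold_table",
    "drop_incomplete_pairs",
    "compute_TE",
    "group_te_summary",
    "StatReport",
    "one_sample_t",
    "two_sample_t",
    "paired_t",
    "holm_adjust",
    "EffectResult",
    "ARTResult",
    "art_analysis",
    "diff_of_diffs_posthoc",
]

#: Canonical tidy schema for threshold tables.
THRESHOLD_COLUMNS = [
    "participant",
    "group",
    "phase",
    "orientation",
    "separation",
    "threshold",
]


def validate_threshold_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy threshold-table schema and invariants."""
    missing = [c for c in THRESHOLD_COLUMNS if c not in table.columns]
    if missing:
        raise ParameterError(f"threshold table missing columns {missing}")
    thr = table["threshold"].astype(float)
    if not ((thr > 0) & (thr <= 1)).all():
        bad = table.loc[~((thr > 0) & (thr <= 1))]
        raise ParameterError(
            f"thresholds must lie in (0, 1]; offending rows:\n{bad}"
        )
    key = ["participant", "phase", "orientation", "separation"]
    dup = table.duplicated(subset=key)
    if dup.any():
        raise ParameterError(
            f"duplicate threshold cells:\n{table.loc[dup, key]}"
        )
    return table


# ---------------------------------------------------------------------------
# Threshold elevation
# ---------------------------------------------------------------------------


def drop_incomplete_pairs(table: pd.DataFrame) -> pd.DataFrame:
    """Remove measurement cells without a usable collinear/orthogonal pair.

    Rows with non-finite thresholds or a falsy ``valid`` column (failed
    staircases) are dropped first; any (participant, phase, separation)
    cell then left with fewer than both orientations is removed as well,
    so the result is safe input for compute_TE.
    """
    t = table.copy()
    ok = np.isfinite(t["threshold"].astype(float))
    if "valid" in t.columns:
        ok &= t["valid"].astype(bool)
    t = t[ok]
    n_ori = t.groupby(["participant", "phase", "separation"])[
        "orientation"
    ].transform("nunique")
    return t[n_ori == 2].drop(columns="valid", errors="ignore").reset_index(drop=True)


def compute_TE(table: pd.DataFrame) -> pd.DataFrame:
    """TE = log10(collinear / orthogonal) per participant, phase, separation.

    Raises PairingError naming the first cell whose collinear or
    orthogonal partner row is absent; no imputation is performed.
    """
    validate_threshold_table(table)
    wide = table.pivot_table(
        index=["participant", "group", "phase", "separation"],
        columns="orientation",
        values="threshold",
        aggfunc="first",
    )
    for orientation in ("collinear", "orthogonal"):
        if orientation not in wide.columns:
            raise PairingError(f"table has no {orientation} rows at all")
        if wide[orientation].isna().any():
            cell = wide.index[wide[orientation].isna()][0]
            raise PairingError(
                f"missing {orientation} threshold for participant="
                f"{cell[0]}, phase={cell[2]}, separation={cell[3]}"
            )
    out = wide.reset_index()
    out["te"] = np.log10(out["collinear"] / out["orthogonal"])
    return out[["participant", "group", "phase", "separation", "te"]]


def group_te_summary(
    te: pd.DataFrame, group: str, separation: float, phase: str = "pre"
) -> tuple[float, float, int]:
    """(mean, sample SD, n) of TE for one group x separation cell."""
    sel = te[
        (te["group"] == group)
        & (te["separation"] == separation)
        & (te["phase"] == phase)
    ]["te"].to_numpy(dtype=float)
    if sel.size < 2:
        raise ParameterError(
            f"need >= 2 participants for a summary, got {sel.size} "
            f"({group}, {separation} lambda, {phase})"
        )
    return float(np.mean(sel)), float(np.std(sel, ddof=1)), int(sel.size)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StatReport:
    """One inferential result with its sample summaries."""

    test: str
    statistic: float
    df: float
    p_value: float
    summaries: tuple[dict, ...] = ()
    adjustment: str = "none"
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "summaries": list(self.summaries),
            "adjustment": self.adjustment,
            "note": self.note,
        }


def _summary(values: np.ndarray, label: str) -> dict:
    return {
        "label": label,
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)),
        "n": int(values.size),
    }


def _check_sample(values, name: str = "sample") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ParameterError(f"{name} needs n >= 2, got {arr.size}")
    if not np.isfinite(arr).all():
        raise ParameterError(f"{name} contains non-finite values")
    return arr


def one_sample_t(values: Sequence[float], mu: float = 0.0) -> StatReport:
    """Two-tailed one-sample t-test of mean(values) against mu."""
    arr = _check_sample(values)
    n = arr.size
    if np.all(arr == arr[0]):  # exactly constant: zero-variance branch
        if arr[0] == mu:
            t, p, note = 0.0, 1.0, ""
        else:
            t = math.copysign(math.inf, float(arr[0] - mu))
            p, note = 0.0, "zero variance: |t| infinite, p below machine resolution"
        return StatReport(
            "one_sample_t", t, n - 1, p, (_summary(arr, "sample"),), note=note
        )
    res = sps.ttest_1samp(arr, mu)
    return StatReport(
        "one_sample_t",
        float(res.statistic),
        n - 1,
        float(res.pvalue),
        (_summary(arr, "sample"),),
    )


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> StatReport:
    """Pooled-variance two-sample t-test, df = n1 + n2 - 2."""
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    res = sps.ttest_ind(a, b, equal_var=True)
    return StatReport(
        "two_sample_t",
        float(res.statistic),
        a.size + b.size - 2,
        float(res.pvalue),
        (_summary(a, "a"), _summary(b, "b")),
    )


def paired_t(pre: Sequence[float], post: Sequence[float]) -> StatReport:
    """Paired t-test on post - pre differences."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise PairingError(
            f"paired samples differ in length ({pre.size} vs {post.size})"
        )
    diff = _check_sample(post - pre, "differences")
    if np.all(diff == diff[0]):
        t = 0.0 if diff[0] == 0 else math.copysign(math.inf, float(diff[0]))
        p = 1.0 if t == 0.0 else 0.0
        return StatReport(
            "paired_t", t, diff.size - 1, p, (_summary(diff, "post-pre"),)
        )
    res = sps.ttest_rel(post, pre)
    return StatReport(
        "paired_t",
        float(res.statistic),
        diff.size - 1,
        float(res.pvalue),
        (_summary(diff, "post-pre"),),
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# Aligned Rank Transform
# ---------------------------------------------------------------------------


@dataclass
class EffectResult:
    """One effect of an ART analysis: aligned data, ranks, F test."""

    effect: str
    aligned: np.ndarray
    ranks: np.ndarray
    F: float
    df: tuple[float, float]
    p_value: float

    def as_dict(self) -> dict:
        return {
            "effect": self.effect,
            "F": self.F,
            "df": list(self.df),
            "p_value": self.p_value,
        }


@dataclass
class ARTResult:
    """All effects of one aligned-rank analysis plus design bookkeeping."""

    effects: dict[str, EffectResult]
    data: pd.DataFrame
    dv: str
    subject: str
    between: str | None
    within: tuple[str, ...]

    def as_dict(self) -> dict:
        return {name: eff.as_dict() for name, eff in self.effects.items()}


def _f_p(F: float, df1: float, df2: float) -> float:
    return float(sps.f.sf(F, df1, df2))


def _safe_ratio(ss_eff: float, df_eff: float, ss_err: float, df_err: float):
    """F ratio with the all-ties convention: 0/0 -> F = 0, p = 1."""
    ms_err = ss_err / df_err if df_err > 0 else 0.0
    ms_eff = ss_eff / df_eff
    if ms_err == 0.0:
        if ms_eff == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    F = ms_eff / ms_err
    return F, _f_p(F, df_eff, df_err)


def _oneway_between(values: np.ndarray, groups: np.ndarray):
    """One-way between-subjects ANOVA on one value per subject."""
    grand = values.mean()
    labels = pd.unique(groups)
    ss_b = sum(
        (values[groups == g].size) * (values[groups == g].mean() - grand) ** 2
        for g in labels
    )
    ss_w = sum(
        ((values[groups == g] - values[groups == g].mean()) ** 2).sum()
        for g in labels
    )
    df1 = len(labels) - 1
    df2 = values.size - len(labels)
    F, p = _safe_ratio(ss_b, df1, ss_w, df2)
    return F, (df1, df2), p


def _rm_oneway(Y: np.ndarray):
    """One-way repeated-measures ANOVA; Y is (subjects x levels)."""
    S, b = Y.shape
    grand = Y.mean()
    subj = Y.mean(axis=1)
    lev = Y.mean(axis=0)
    ss_lev = S * ((lev - grand) ** 2).sum()
    resid = Y - subj[:, None] - lev[None, :] + grand
    ss_err = (resid**2).sum()
    df1, df2 = b - 1, (S - 1) * (b - 1)
    F, p = _safe_ratio(ss_lev, df1, ss_err, df2)
    return F, (df1, df2), p


def _split_plot(Y: np.ndarray, groups: np.ndarray):
    """Balanced split-plot (mixed) ANOVA.

    Y is (subjects x within-levels); ``groups`` labels each subject's
    between-group.  Returns the three effects with their proper error
    terms: between vs subjects-within-groups, within and interaction vs
    the within x subject(group) residual.
    """
    S, b = Y.shape
    labels = pd.unique(groups)
    a = len(labels)
    n = S // a
    if n * a != S or any((groups == g).sum() != n for g in labels):
        raise DesignError("split-plot requires equal group sizes")
    grand = Y.mean()
    subj = Y.mean(axis=1)
    lev = Y.mean(axis=0)
    gmean = {g: Y[groups == g].mean() for g in labels}
    cell = {g: Y[groups == g].mean(axis=0) for g in labels}

    ss_a = n * b * sum((gmean[g] - grand) ** 2 for g in labels)
    ss_subj_w = b * sum(
        ((subj[groups == g] - gmean[g]) ** 2).sum() for g in labels
    )
    ss_b_ = S * ((lev - grand) ** 2).sum()
    ss_ab = n * sum(
        ((cell[g] - gmean[g] - lev + grand) ** 2).sum() for g in labels
    )
    ss_err = 0.0
    for g in labels:
        block = Y[groups == g]
        sm = subj[groups == g]
        resid = block - cell[g][None, :] - sm[:, None] + gmean[g]
        ss_err += (resid**2).sum()

    df_a, df_sw = a - 1, a * (n - 1)
    df_b, df_ab = b - 1, (a - 1) * (b - 1)
    df_err = a * (n - 1) * (b - 1)
    Fa, pa = _safe_ratio(ss_a, df_a, ss_subj_w, df_sw)
    Fb, pb = _safe_ratio(ss_b_, df_b, ss_err, df_err)
    Fab, pab = _safe_ratio(ss_ab, df_ab, ss_err, df_err)
    return {
        "between": (Fa, (df_a, df_sw), pa),
        "within": (Fb, (df_b, df_err), pb),
        "interaction": (Fab, (df_ab, df_err), pab),
    }


def _check_design(
    df: pd.DataFrame, dv: str, subject: str, between: str | None, within: Sequence[str]
) -> pd.DataFrame:
    factors = ([between] if between else []) + list(within)
    for col in [dv, subject] + factors:
        if col not in df.columns:
            raise DesignError(f"column {col!r} not in data")
    if not factors:
        raise DesignError("need at least one factor")
    # each subject must contribute exactly one observation per within-cell
    if within:
        counts = df.groupby([subject] + list(within), sort=False).size()
        if (counts != 1).any():
            raise DesignError(
                "design is not a complete balanced repeated-measures "
                "factorial (one observation per subject x within-cell)"
            )
        n_cells = int(np.prod([df[w].nunique() for w in within]))
        per_subj = df.groupby(subject, sort=False).size()
        if (per_subj != n_cells).any():
            raise DesignError("some subjects are missing within-cells")
    else:
        if (df.groupby(subject, sort=False).size() != 1).any():
            raise DesignError(
                "without within factors each subject contributes one row"
            )
    if between:
        g_per_subj = df.groupby(subject, sort=False)[between].nunique()
        if (g_per_subj != 1).any():
            raise DesignError("a subject appears in more than one group")
        sizes = df.drop_duplicates(subject)[between].value_counts()
        if sizes.nunique() != 1:
            raise DesignError(
                f"unbalanced between-groups ({dict(sizes)}); the aligned "
                "cell-mean estimates assume equal group sizes"
            )
    return df.reset_index(drop=True)


def _align(
    df: pd.DataFrame, dv: str, factors: list[str], effect_cols: list[str]
) -> np.ndarray:
    """Wobbrock-style alignment: response minus full-design cell mean,
    plus the estimated effect of interest (unweighted cell means)."""
    y = df[dv].to_numpy(dtype=float)
    grand = y.mean()
    cell_mean = df.groupby(factors, sort=False)[dv].transform("mean").to_numpy()
    if len(effect_cols) == 1:
        eff = (
            df.groupby(effect_cols, sort=False)[dv].transform("mean").to_numpy()
            - grand
        )
    else:  # two-way interaction effect estimate
        a, b = effect_cols
        eff = (
            df.groupby([a, b], sort=False)[dv].transform("mean").to_numpy()
            - df.groupby(a, sort=False)[dv].transform("mean").to_numpy()
            - df.groupby(b, sort=False)[dv].transform("mean").to_numpy()
            + grand
        )
    return y - cell_mean + eff


def _subject_matrix(
    df: pd.DataFrame, values: np.ndarray, subject: str, within_factor: str
):
    """Collapse ranks to a (subjects x levels) matrix by averaging over
    any other within factors; returns (matrix, subject ids, level ids)."""
    tmp = df[[subject, within_factor]].copy()
    tmp["_v"] = values
    wide = tmp.groupby([subject, within_factor], sort=False)["_v"].mean().unstack()
    return wide.to_numpy(), wide.index.to_numpy(), wide.columns.to_numpy()


def art_analysis(
    table: pd.DataFrame,
    dv: str,
    subject: str = "participant",
    between: str | None = None,
    within: Sequence[str] = (),
    interaction: bool | None = None,
) -> ARTResult:
    """Aligned Rank Transform analysis of a (possibly mixed) factorial.

    Main effects are computed for the between factor (at most one) and
    every within factor.  The group x within interaction is computed only
    for designs with exactly one within factor (``interaction=None``
    enables it automatically there); asking for an interaction in a
    design with several within factors raises DesignError, mirroring the
    restriction of repeated-measures aligned-rank interaction tests.

    Per effect: align (strip all other effects, estimated from cell
    means), rank with midranks, then run the rank ANOVA with the error
    term the design dictates (between effects against
    subjects-within-groups on subject-mean ranks; within effects against
    the effect x subject residual after collapsing over the other within
    factors).
    """
    within = list(within)
    df = _check_design(table, dv, subject, between, within)
    factors = ([between] if between else []) + within

    can_interact = between is not None and len(within) == 1
    if interaction is True and not can_interact:
        raise DesignError(
            "interaction tests are only supported for exactly one between "
            "x one within factor"
        )
    do_interaction = can_interact if interaction is None else interaction

    effects: dict[str, EffectResult] = {}
    groups_by_subject = (
        df.drop_duplicates(subject).set_index(subject)[between]
        if between
        else None
    )

    for factor in factors:
        aligned = _align(df, dv, factors, [factor])
        ranks = rankdata(aligned)
        if factor == between:
            tmp = df[[subject]].copy()
            tmp["_r"] = ranks
            subj_means = tmp.groupby(subject, sort=False)["_r"].mean()
            g = groups_by_subject.loc[subj_means.index].to_numpy()
            F, dfs, p = _oneway_between(subj_means.to_numpy(), g)
        else:
            Y, subj_ids, _ = _subject_matrix(df, ranks, subject, factor)
            if between:
                g = groups_by_subject.loc[subj_ids].to_numpy()
                F, dfs, p = _split_plot(Y, g)["within"]
            else:
                F, dfs, p = _rm_oneway(Y)
        effects[factor] = EffectResult(factor, aligned, ranks, F, dfs, p)

    if do_interaction:
        w = within[0]
        # repeated-measures interaction alignment: remove subject effects
        # (which absorb the group effect) and the within main effect
        y = df[dv].to_numpy(dtype=float)
        grand = y.mean()
        subj_mean = df.groupby(subject, sort=False)[dv].transform("mean").to_numpy()
        w_mean = df.groupby(w, sort=False)[dv].transform("mean").to_numpy()
        aligned = y - subj_mean - w_mean + grand
        ranks = rankdata(aligned)
        Y, subj_ids, _ = _subject_matrix(df, ranks, subject, w)
        g = groups_by_subject.loc[subj_ids].to_numpy()
        F, dfs, p = _split_plot(Y, g)["interaction"]
        name = f"{between}:{w}"
        effects[name] = EffectResult(name, aligned, ranks, F, dfs, p)

    return ARTResult(
        effects=effects,
        data=df,
        dv=dv,
        subject=subject,
        between=between,
        within=tuple(within),
    )


def diff_of_diffs_posthoc(
    art: ARTResult,
    level_pairs: Sequence[tuple] | None = None,
) -> pd.DataFrame:
    """Interaction post-hocs as differences of differences.

    For each pair (c, d) of within-factor levels, the per-subject
    difference of interaction-aligned ranks r(c) - r(d) is compared
    between the two groups with a pooled two-sample t-test; this asks
    whether the group difference at level c differs from the group
    difference at level d.  p-values are Holm-adjusted within the
    requested family.
    """
    if art.between is None or len(art.within) != 1:
        raise DesignError("post-hoc requires a one-between x one-within design")
    name = f"{art.between}:{art.within[0]}"
    if name not in art.effects:
        raise DesignError("ARTResult carries no interaction effect")
    w = art.within[0]
    ranks = art.effects[name].ranks
    Y, subj_ids, levels = _subject_matrix(art.data, ranks, art.subject, w)
    level_index = {lev: i for i, lev in enumerate(levels)}
    groups = (
        art.data.drop_duplicates(art.subject)
        .set_index(art.subject)[art.between]
        .loc[subj_ids]
        .to_numpy()
    )
    glabels = pd.unique(groups)
    if len(glabels) != 2:
        raise DesignError("post-hoc implemented for exactly two groups")

    if level_pairs is None:
        level_pairs = [
            (levels[i], levels[j])
            for i in range(len(levels))
            for j in range(i + 1, len(levels))
        ]
    rows = []
    for c, d in level_pairs:
        for lev in (c, d):
            if lev not in level_index:
                raise DesignError(
                    f"level {lev!r} not among within-factor levels "
                    f"{list(levels)}"
                )
        diff = Y[:, level_index[c]] - Y[:, level_index[d]]
        d0, d1 = diff[groups == glabels[0]], diff[groups == glabels[1]]
        estimate = float(np.mean(d0) - np.mean(d1))
        if np.std(d0, ddof=1) == 0 and np.std(d1, ddof=1) == 0:
            t = 0.0 if estimate == 0 else math.copysign(math.inf, estimate)
            p = 1.0 if t == 0.0 else 0.0
            dof = d0.size + d1.size - 2
        else:
            res = sps.ttest_ind(d0, d1, equal_var=True)
            t, p = float(res.statistic), float(res.pvalue)
            dof = d0.size + d1.size - 2
        rows.append(
            {
                "contrast": f"{glabels[0]}-{glabels[1]} | {c} vs {d}",
                "level_a": c,
                "level_b": d,
                "estimate": estimate,
                "t": t,
                "df": dof,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out
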