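"""Packaged threshold tables, reproduction pipelines and report I/O.

Two tidy CSV fixtures ship with the package: the baseline individual
Michelson contrast thresholds of the 10 participants (5 MD, 5 controls)
x 8 conditions, and the per-condition threshold *differences* after 12
training sessions for the 7 participants who trained.  The
``reproduce_experiment1`` / ``reproduce_experiment2`` pipelines run the
full statistical battery on those tables and emit JSON-serializable
report bundles.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import IntegrityError, PairingError
from .stats import (
    ARTResult,
    StatReport,
    art_analysis,
    compute_TE,
    diff_of_diffs_posthoc,
    group_te_summary,
    one_sample_t,
    paired_t,
    two_sample_t,
    validate_threshold_table,
)

__all__ = [
    "FIXTURE_CHECKSUMS",
    "FixtureSet",
    "load_fixtures",
    "load_threshold_table",
    "reproduce_experiment1",
    "reproduce_experiment2",
    "save_report",
    "report_to_text",
]

#: sha256 of the packaged CSV transcriptions; load_fixtures refuses to
#: return silently corrupted tables.
FIXTURE_CHECKSUMS = {
    "table2_thresholds.csv": "abd91f64937df64e0134755ead7bb9cc7fbdb62e9f0bacf4fd43d72522197870",
    "table3_differences.csv": "7dbf978546971527de3f4528368b633e063fd8911bbb7d741e5025aef4845ec5",
}

SEPARATIONS = (3.0, 4.0, 6.0, 8.0)
GROUPS = ("MD", "control")


@dataclass
class FixtureSet:
    """The two packaged tables plus participant metadata.

    ``table2``: 10 participants x 8 conditions baseline thresholds
    (80 cells, phase 'pre').  ``table3``: 7 trained participants x 8
    conditions threshold differences (56 cells).  ``raw2`` / ``raw3``
    keep the threshold/difference cells as the original strings so the
    transcription (including trailing zeros and signs) can be checked
    verbatim.
    """

    table2: pd.DataFrame
    table3: pd.DataFrame
    participants: pd.DataFrame
    raw2: pd.DataFrame
    raw3: pd.DataFrame


def _fixture_bytes(name: str) -> bytes:
    data = resources.files("latmask.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != FIXTURE_CHECKSUMS[name]:
        raise IntegrityError(
            f"fixture {name} is corrupted (sha256 {digest}, expected "
            f"{FIXTURE_CHECKSUMS[name]})"
        )
    return data


def load_threshold_table(path) -> pd.DataFrame:
    """Read and validate a tidy threshold CSV."""
    table = pd.read_csv(path)
    table["separation"] = table["separation"].astype(float)
    table["threshold"] = table["threshold"].astype(float)
    return validate_threshold_table(table)


def load_fixtures() -> FixtureSet:
    """Load and checksum-verify the packaged tables."""
    import io

    raw2 = pd.read_csv(
        io.BytesIO(_fixture_bytes("table2_thresholds.csv")), dtype=str
    )
    raw3 = pd.read_csv(
        io.BytesIO(_fixture_bytes("table3_differences.csv")), dtype=str
    )
    table2 = raw2.copy()
    table2["separation"] = table2["separation"].astype(float)
    table2["threshold"] = table2["threshold"].astype(float)
    validate_threshold_table(table2)
    table3 = raw3.copy()
    table3["separation"] = table3["separation"].astype(float)
    table3["difference"] = table3["difference"].astype(float)

    if len(table2) != 80:
        raise IntegrityError(f"baseline table has {len(table2)} cells, not 80")
    if len(table3) != 56:
        raise IntegrityError(f"training table has {len(table3)} cells, not 56")
    missing = set(table3["participant"]) - set(table2["participant"])
    if missing:
        raise IntegrityError(
            f"trained participants absent from the baseline table: {missing}"
        )

    participants = (
        table2.drop_duplicates("participant")[["participant", "group"]]
        .reset_index(drop=True)
        .assign(trained=lambda d: d["participant"].isin(set(table3["participant"])))
    )
    return FixtureSet(table2, table3, participants, raw2, raw3)


# ---------------------------------------------------------------------------
# Reproduction pipelines
# ---------------------------------------------------------------------------


def reproduce_experiment1(fixtures: FixtureSet | None = None) -> dict:
    """Full baseline analysis on the packaged threshold table.

    Computes per-participant TEs, group summaries, one-sample t-tests of
    TE against zero per group x separation, pooled two-sample t-tests
    MD vs control per separation, ART main effects on raw thresholds
    (group x orientation x separation; interaction unsupported with two
    within factors) and the ART on TE (group x separation) with its
    interaction and differences-of-differences post-hocs.  Deterministic:
    repeated runs produce identical reports.
    """
    fixtures = fixtures or load_fixtures()
    te = compute_TE(fixtures.table2)

    summaries = {}
    one_sample = {}
    for g in GROUPS:
        for sep in SEPARATIONS:
            mean, sd, n = group_te_summary(te, g, sep)
            summaries[f"{g}_{sep:g}"] = {"mean": mean, "sd": sd, "n": n}
            values = te[(te["group"] == g) & (te["separation"] == sep)]["te"]
            one_sample[f"{g}_{sep:g}"] = one_sample_t(values.to_numpy(), 0.0)

    two_sample = {}
    for sep in SEPARATIONS:
        a = te[(te["group"] == "MD") & (te["separation"] == sep)]["te"]
        b = te[(te["group"] == "control") & (te["separation"] == sep)]["te"]
        two_sample[f"{sep:g}"] = two_sample_t(a.to_numpy(), b.to_numpy())

    art_thresholds = art_analysis(
        fixtures.table2,
        dv="threshold",
        subject="participant",
        between="group",
        within=["orientation", "separation"],
    )
    art_te = art_analysis(
        te,
        dv="te",
        subject="participant",
        between="group",
        within=["separation"],
    )
    posthoc = diff_of_diffs_posthoc(art_te)

    return {
        "experiment": 1,
        "te": te,
        "group_summaries": summaries,
        "one_sample_t": one_sample,
        "two_sample_t": two_sample,
        "art_thresholds": art_thresholds,
        "art_te": art_te,
        "te_interaction_posthoc": posthoc,
        "significant_one_sample": {
            g: sorted(
                sep
                for sep in SEPARATIONS
                if one_sample[f"{g}_{sep:g}"].p_value < 0.05
            )
            for g in GROUPS
        },
    }


def reconstruct_post_thresholds(fixtures: FixtureSet) -> pd.DataFrame:
    """Post-training thresholds = baseline + per-condition difference.

    The sum is reported cell-by-cell even where it leaves the physical
    range: some control difference cells exceed the baseline threshold,
    which shows the trained participants' true pre-training values
    cannot all equal their baseline measurements.  Such cells carry
    ``physical = False`` and are excluded from downstream TE analysis.
    """
    pre = fixtures.table2.set_index(["participant", "orientation", "separation"])
    rows = []
    for _, row in fixtures.table3.iterrows():
        key = (row["participant"], row["orientation"], row["separation"])
        if key not in pre.index:
            raise PairingError(
                f"trained participant {key[0]} lacks a baseline value for "
                f"{key[1]} {key[2]:g} lambda"
            )
        thr = float(pre.loc[key, "threshold"]) + float(row["difference"])
        rows.append(
            {
                "participant": row["participant"],
                "group": row["group"],
                "phase": "post",
                "orientation": row["orientation"],
                "separation": row["separation"],
                "threshold": thr,
                "physical": 0.0 < thr <= 1.0,
            }
        )
    return pd.DataFrame(rows)


def reproduce_experiment2(fixtures: FixtureSet | None = None) -> dict:
    """Training analysis: reconstruct post thresholds, compute pre/post
    TEs for the 7 trained participants, and run paired t-tests per group
    x separation on TE (post vs pre).

    (participant, separation) pairs whose reconstructed post threshold
    falls outside (0, 1] in either orientation are excluded from the TE
    stage with a warning; the raw reconstruction keeps every cell.
    """
    fixtures = fixtures or load_fixtures()
    trained = sorted(set(fixtures.table3["participant"]))
    pre = fixtures.table2[fixtures.table2["participant"].isin(trained)]
    post = reconstruct_post_thresholds(fixtures)

    nonphysical = post[~post["physical"]]
    if len(nonphysical):
        warnings.warn(
            f"{len(nonphysical)} reconstructed post threshold(s) fall "
            "outside (0, 1] (difference larger than baseline); the "
            "affected participant x separation pairs are excluded from "
            "TE analysis",
            stacklevel=2,
        )
    bad_pairs = set(
        zip(nonphysical["participant"], nonphysical["separation"])
    )
    post_ok = post[
        ~post.apply(
            lambda r: (r["participant"], r["separation"]) in bad_pairs, axis=1
        )
    ].drop(columns="physical")
    both = pd.concat([pre, post_ok], ignore_index=True)
    te = compute_TE(both)

    paired = {}
    for g in GROUPS:
        for sep in SEPARATIONS:
            cell = te[(te["group"] == g) & (te["separation"] == sep)]
            wide = cell.pivot(
                index="participant", columns="phase", values="te"
            ).dropna()
            paired[f"{g}_{sep:g}"] = paired_t(
                wide["pre"].to_numpy(), wide["post"].to_numpy()
            )

    return {
        "experiment": 2,
        "post_thresholds": post,
        "excluded_pairs": sorted(bad_pairs),
        "pre_post_table": both,
        "te": te,
        "paired_t": paired,
    }


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, StatReport):
        return obj.as_dict()
    if isinstance(obj, ARTResult):
        return obj.as_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_report(report: dict, path) -> Path:
    """Write a report bundle as JSON; returns the path written."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    return path


def report_to_text(report: dict) -> str:
    """Human-readable rendering of a reproduction report."""
    lines = [f"Experiment {report.get('experiment', '?')} report", "=" * 32]
    if "group_summaries" in report:
        lines.append("\nGroup TE summaries (mean, SD, n):")
        for cell, s in report["group_summaries"].items():
            lines.append(
                f"  {cell:14s} {s['mean']:+.4f}  {s['sd']:.4f}  n={s['n']}"
            )
    for key, title in [
        ("one_sample_t", "One-sample t (TE vs 0)"),
        ("two_sample_t", "Two-sample t (MD vs control)"),
        ("paired_t", "Paired t (post vs pre TE)"),
    ]:
        if key in report:
            lines.append(f"\n{title}:")
            for cell, r in report[key].items():
                lines.append(
                    f"  {cell:14s} t({r.df:g}) = {r.statistic:+.3f}, "
                    f"p = {r.p_value:.4f}"
                )
    for key, title in [
        ("art_thresholds", "ART on thresholds"),
        ("art_te", "ART on TE"),
    ]:
        if key in report:
            lines.append(f"\n{title}:")
            for name, eff in report[key].effects.items():
                lines.append(
                    f"  {name:22s} F({eff.df[0]:g}, {eff.df[1]:g}) = "
                    f"{eff.F:.3f}, p = {eff.p_value:.4g}"
                )
    if "te_interaction_posthoc" in report:
        lines.append("\nInteraction post-hocs (differences of differences):")
        for _, row in report["te_interaction_posthoc"].iterrows():
            lines.append(
                f"  {row['contrast']:28s} t = {row['t']:+.3f}, "
                f"p_holm = {row['p_holm']:.4f}"
            )
    return "\n".join(lines) + "\n"
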