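"""Synthetic MD / control cohorts and end-to-end experiment simulation.

The generator emulates the study conditions of a small lateral-masking
cohort: two groups (5 macular-degeneration patients, 5 age-matched
controls), each observer measured in 8 conditions (collinear/orthogonal
x separations of 3, 4, 6, 8 lambda), with MD showing weaker collinear
inhibition at 3 lambda and weaker facilitation at 6-8 lambda than
controls, plus a 12-session training phase that lowers collinear
thresholds more in MD.

Default generating parameters are *computed from the packaged threshold
tables at run time* (group-mean orthogonal thresholds and TE profiles
per separation; training effect means/SDs from the difference table),
never hard-coded, so fixture corrections propagate automatically.

Between-subject variability acts on log10 thresholds (thresholds are
positive and the staircase is log-stepped): each observer receives one
scalar log-sensitivity offset applied to all separations, and a
per-separation TE jitter around the group profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError, StaircaseWarning
from .observer import LateralProfile, ObserverModel, PsychometricParams
from .staircase import StaircaseSettings, run_staircase
from .stats import compute_TE, validate_threshold_table

__all__ = [
    "CohortSpec",
    "TrainingSpec",
    "default_cohort_spec",
    "default_training_spec",
    "make_cohort",
    "simulate_experiment1",
    "simulate_training",
]

GROUPS = ("MD", "control")
SEPARATIONS = (3.0, 4.0, 6.0, 8.0)
ORIENTATIONS = ("collinear", "orthogonal")


@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters for one simulated cohort.

    ``orthogonal_threshold_means`` and ``te_profile_means`` are nested
    mappings group -> separation -> value (Michelson contrast and log10
    units respectively).  ``between_subject_sd`` is the SD of the
    observer-level log10-threshold offset; ``te_between_sd`` the SD of
    per-separation TE jitter.
    """

    orthogonal_threshold_means: Mapping[str, Mapping[float, float]]
    te_profile_means: Mapping[str, Mapping[float, float]]
    n_md: int = 5
    n_control: int = 5
    between_subject_sd: float = 0.15
    te_between_sd: float = 0.1
    psychometric: PsychometricParams = field(default_factory=PsychometricParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_md < 0 or self.n_control < 0:
            raise ParameterError("cohort sizes must be non-negative")
        if self.between_subject_sd < 0 or self.te_between_sd < 0:
            raise ParameterError("SDs must be non-negative")
        for g in GROUPS:
            if g not in self.orthogonal_threshold_means or g not in self.te_profile_means:
                raise ParameterError(f"spec missing parameters for group {g!r}")
            for sep, thr in self.orthogonal_threshold_means[g].items():
                if not 0 < thr <= 1:
                    raise ParameterError(
                        f"mean orthogonal threshold {thr} at {sep} lambda "
                        "outside (0, 1]"
                    )


@dataclass(frozen=True)
class TrainingSpec:
    """Per-condition training effects (Michelson threshold change).

    ``mean`` / ``sd`` map group -> (orientation, separation) -> value;
    negative means = improvement.  ``n_sessions`` is metadata describing
    the emulated regimen (effects are drawn per condition, not per
    session; the analysis only ever sees pre and post).
    """

    mean: Mapping[str, Mapping[tuple[str, float], float]]
    sd: Mapping[str, Mapping[tuple[str, float], float]]
    n_sessions: int = 12

    def __post_init__(self) -> None:
        if self.n_sessions <= 0:
            raise ParameterError("n_sessions must be positive")


def default_cohort_spec(
    table2: pd.DataFrame | None = None, seed: int = 0, **overrides
) -> CohortSpec:
    """Cohort spec whose group parameters are estimated from a threshold
    table (the packaged baseline table by default)."""
    if table2 is None:
        from .pipeline import load_fixtures

        table2 = load_fixtures().table2
    validate_threshold_table(table2)
    te = compute_TE(table2)
    orth = table2[table2["orientation"] == "orthogonal"]
    thr_means: dict[str, dict[float, float]] = {}
    te_means: dict[str, dict[float, float]] = {}
    log_sds = []
    te_sds = []
    for g in GROUPS:
        thr_means[g] = {}
        te_means[g] = {}
        for sep in SEPARATIONS:
            cell = orth[(orth["group"] == g) & (orth["separation"] == sep)][
                "threshold"
            ].astype(float)
            tecell = te[(te["group"] == g) & (te["separation"] == sep)]["te"]
            thr_means[g][sep] = float(10 ** np.log10(cell).mean())
            te_means[g][sep] = float(tecell.mean())
            log_sds.append(np.log10(cell).std(ddof=1))
            te_sds.append(tecell.std(ddof=1))
    defaults = dict(
        orthogonal_threshold_means=thr_means,
        te_profile_means=te_means,
        between_subject_sd=float(np.mean(log_sds)),
        te_between_sd=float(np.mean(te_sds)),
        seed=seed,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


def default_training_spec(
    table3: pd.DataFrame | None = None, n_sessions: int = 12
) -> TrainingSpec:
    """Training spec estimated from a difference table (packaged Table 3
    schema: participant, group, orientation, separation, difference)."""
    if table3 is None:
        from .pipeline import load_fixtures

        table3 = load_fixtures().table3
    mean: dict[str, dict[tuple[str, float], float]] = {}
    sd: dict[str, dict[tuple[str, float], float]] = {}
    for g in GROUPS:
        mean[g] = {}
        sd[g] = {}
        sub = table3[table3["group"] == g]
        for ori in ORIENTATIONS:
            for sep in SEPARATIONS:
                cell = sub[
                    (sub["orientation"] == ori) & (sub["separation"] == sep)
                ]["difference"].astype(float)
                mean[g][(ori, sep)] = float(cell.mean())
                sd[g][(ori, sep)] = float(cell.std(ddof=1))
    return TrainingSpec(mean=mean, sd=sd, n_sessions=n_sessions)


def make_cohort(spec: CohortSpec) -> list[ObserverModel]:
    """Draw a deterministic cohort of simulated observers.

    log10 orthogonal thresholds: group mean + observer offset
    ~ N(0, between_subject_sd); TE anchors: group mean + N(0,
    te_between_sd) per separation.  Thresholds are clipped to (0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    observers: list[ObserverModel] = []
    for group, n in (("MD", spec.n_md), ("control", spec.n_control)):
        thr_mean = spec.orthogonal_threshold_means[group]
        te_mean = spec.te_profile_means[group]
        for i in range(n):
            offset = rng.normal(0.0, spec.between_subject_sd)
            thresholds = {
                float(sep): float(
                    np.clip(10 ** (np.log10(m) + offset), 1e-6, 1.0)
                )
                for sep, m in thr_mean.items()
            }
            te = {
                float(sep): float(m + rng.normal(0.0, spec.te_between_sd))
                for sep, m in te_mean.items()
            }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # jittered TE may wiggle in sign
                profile = LateralProfile(te)
            observers.append(
                ObserverModel(
                    orthogonal_threshold=thresholds,
                    profile=profile,
                    psychometric=spec.psychometric,
                    group=group,
                    rng_seed=int(spec.seed),
                )
            )
    return observers


def _measure_phase(
    observers: Sequence[ObserverModel],
    ids: Sequence[str],
    settings: StaircaseSettings,
    seed: int,
    phase: str,
    threshold_overrides: Sequence[Mapping[tuple[str, float], float]] | None = None,
) -> pd.DataFrame:
    """One staircase per observer x condition; returns a tidy table."""
    seeds = np.random.SeedSequence(seed).spawn(len(observers))
    rows = []
    n_invalid = 0
    for obs, oid, sseq, overrides in zip(
        observers,
        ids,
        seeds,
        threshold_overrides or [None] * len(observers),
    ):
        cond_seeds = sseq.spawn(len(ORIENTATIONS) * len(SEPARATIONS))
        k = 0
        for ori in ORIENTATIONS:
            for sep in SEPARATIONS:
                rng = np.random.default_rng(cond_seeds[k])
                k += 1
                if overrides is not None:
                    true_thr = overrides[(ori, sep)]
                    alpha_obs = replace(
                        obs,
                        orthogonal_threshold={sep: true_thr},
                        profile=LateralProfile({sep: 0.0}),
                    )
                    fn = alpha_obs.respond_fn(("orthogonal", sep), rng)
                else:
                    fn = obs.respond_fn((ori, sep), rng)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", StaircaseWarning)
                    result = run_staircase(fn, settings)
                if not result.valid:
                    n_invalid += 1
                rows.append(
                    {
                        "participant": oid,
                        "group": obs.group,
                        "phase": phase,
                        "orientation": ori,
                        "separation": sep,
                        "threshold": result.threshold,
                        "valid": result.valid,
                    }
                )
    if n_invalid:
        warnings.warn(
            f"{n_invalid} staircase(s) ended without enough reversals; "
            "their rows carry NaN thresholds and valid=False",
            StaircaseWarning,
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def _observer_ids(observers: Sequence[ObserverModel]) -> list[str]:
    counts = {"MD": 0, "control": 0}
    ids = []
    for obs in observers:
        counts[obs.group] = counts.get(obs.group, 0) + 1
        prefix = "SMD" if obs.group == "MD" else "SC"
        ids.append(f"{prefix}{counts[obs.group]}")
    return ids


def simulate_experiment1(
    cohort: Sequence[ObserverModel],
    settings: StaircaseSettings | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Measure all 8 conditions per observer through staircases (phase
    'pre'); returns a tidy threshold table."""
    if not cohort:
        raise ParameterError("cohort is empty")
    settings = settings or StaircaseSettings()
    return _measure_phase(cohort, _observer_ids(cohort), settings, seed, "pre")


def simulate_training(
    cohort: Sequence[ObserverModel],
    training: TrainingSpec,
    settings: StaircaseSettings | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate pre and post phases around a training regimen.

    Each observer's post-phase true threshold per condition equals the
    pre-phase value plus a drawn per-condition training effect
    ~ N(mean, sd) for its group (clipped to stay positive); both phases
    are then re-measured through independent staircases.
    """
    if not cohort:
        raise ParameterError("cohort is empty")
    settings = settings or StaircaseSettings()
    ids = _observer_ids(cohort)
    pre = _measure_phase(cohort, ids, settings, seed, "pre")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    post_overrides = []
    for obs in cohort:
        overrides = {}
        for ori in ORIENTATIONS:
            for sep in SEPARATIONS:
                delta = rng.normal(
                    training.mean[obs.group][(ori, sep)],
                    training.sd[obs.group][(ori, sep)],
                )
                overrides[(ori, sep)] = float(
                    np.clip(obs.true_threshold((ori, sep)) + delta, 1e-6, 1.0)
                )
        post_overrides.append(overrides)
    post = _measure_phase(
        cohort, ids, settings, seed + 1, "post", threshold_overrides=post_overrides
    )
    return pd.concat([pre, post], ignore_index=True)
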