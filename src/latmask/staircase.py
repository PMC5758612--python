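"""Transformed up/down (3-down/1-up) staircase for contrast thresholds.

The rule: after every third consecutive correct response the target
contrast drops by one 0.1 log10 step; after every error it rises by one
step.  The run ends after 14 reversals or 120 trials, and the threshold
is the mean of the last 6 reversal contrasts.  The rule's equilibrium is
the contrast where p(correct)**3 = 0.5, i.e. 79.37 % correct.

Because the steps are log-spaced, the default "mean of reversals"
averages log10 contrasts and exponentiates (geometric mean); an
arithmetic-mean option is provided as the wording of threshold-averaging
conventions varies between labs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .exceptions import ParameterError, StaircaseWarning
from .observer import ObserverModel, Condition

__all__ = [
    "StaircaseSettings",
    "StaircaseResult",
    "ConvergenceReport",
    "run_staircase",
    "equilibrium_probability",
    "convergence_report",
]


def equilibrium_probability(n_down: int, n_up: int = 1) -> float:
    """Percent-correct level an n-down/1-up staircase converges to.

    At equilibrium the expected rates of up and down steps are equal,
    which for an n-down/1-up rule requires p**n_down = 0.5, i.e.
    p = 0.5**(1/n_down).  For 3-down/1-up this is ~0.7937.
    """
    if n_down < 1:
        raise ParameterError("n_down must be >= 1")
    if n_up != 1:
        raise NotImplementedError(
            "only 1-up rules have this closed-form equilibrium"
        )
    return 0.5 ** (1.0 / n_down)


@dataclass(frozen=True)
class StaircaseSettings:
    """Parameters of the adaptive rule.

    Contrasts move multiplicatively by 10**(+/- step_log10) and are
    clamped to [contrast_floor, contrast_ceiling].  The floor default of
    1e-4 is far below any plausible threshold and only keeps the log
    arithmetic finite.
    """

    step_log10: float = 0.1
    n_down: int = 3
    n_up: int = 1
    max_trials: int = 120
    max_reversals: int = 14
    n_reversals_for_threshold: int = 6
    start_contrast: float = 0.5
    contrast_ceiling: float = 1.0
    contrast_floor: float = 1e-4
    reversal_average: Literal["geometric", "linear"] = "geometric"

    def __post_init__(self) -> None:
        if self.step_log10 <= 0:
            raise ParameterError("step_log10 must be positive")
        if self.n_down < 1 or self.n_up != 1:
            raise ParameterError("rule must be n-down/1-up with n_down >= 1")
        if self.n_reversals_for_threshold > self.max_reversals:
            raise ParameterError(
                "n_reversals_for_threshold cannot exceed max_reversals"
            )
        if not 0 < self.contrast_floor < self.start_contrast <= self.contrast_ceiling <= 1:
            raise ParameterError(
                "need 0 < floor < start_contrast <= ceiling <= 1"
            )
        if self.reversal_average not in ("geometric", "linear"):
            raise ParameterError("reversal_average must be geometric|linear")


@dataclass
class StaircaseResult:
    """Trial-by-trial record and the reversal-derived threshold.

    ``threshold`` is NaN when fewer than ``n_reversals_for_threshold``
    reversals occurred (``valid`` is False and a StaircaseWarning was
    emitted); it is never silently substituted.
    """

    trials: list[tuple[int, float, bool]]
    reversal_contrasts: list[float]
    reversal_trials: list[int]
    threshold: float
    valid: bool
    n_trials_run: int
    termination_reason: Literal["reversals_reached", "trials_exhausted"]
    settings: StaircaseSettings

    def trial_log(self) -> "np.ndarray":
        """(trial, contrast, correct, reversal_flag) rows."""
        rev = set(self.reversal_trials)
        return np.array(
            [(i, c, int(ok), int(i in rev)) for i, c, ok in self.trials]
        )

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            self.trial_log(),
            fmt=("%d", "%.6g", "%d", "%d"),
            delimiter=",",
            header="trial,contrast,correct,reversal",
            comments="",
        )


def _reversal_mean(contrasts: Sequence[float], how: str) -> float:
    arr = np.asarray(contrasts, dtype=float)
    if how == "geometric":
        return float(10.0 ** np.mean(np.log10(arr)))
    return float(np.mean(arr))


def run_staircase(
    respond_fn: Callable[[float], bool],
    settings: StaircaseSettings | None = None,
) -> StaircaseResult:
    """Run one adaptive track against a contrast -> bool oracle.

    Counter semantics: the consecutive-correct counter resets on every
    error and on every executed down-step.  A reversal is logged at each
    trial whose step direction differs from the previous executed step;
    a step blocked by the contrast floor/ceiling is not executed and
    therefore cannot create a phantom reversal.
    """
    settings = settings or StaircaseSettings()
    s = settings
    contrast = s.start_contrast
    consecutive = 0
    last_direction = 0
    trials: list[tuple[int, float, bool]] = []
    reversal_contrasts: list[float] = []
    reversal_trials: list[int] = []
    factor_down = 10.0 ** (-s.step_log10)
    factor_up = 10.0**s.step_log10

    termination = "trials_exhausted"
    for trial in range(s.max_trials):
        correct = bool(respond_fn(contrast))
        trials.append((trial, contrast, correct))
        direction = 0
        if correct:
            consecutive += 1
            if consecutive >= s.n_down:
                direction = -1
                consecutive = 0
        else:
            consecutive = 0
            direction = +1
        if direction != 0:
            proposed = contrast * (factor_down if direction < 0 else factor_up)
            proposed = min(max(proposed, s.contrast_floor), s.contrast_ceiling)
            if proposed != contrast:  # clamp-blocked steps are not steps
                if last_direction != 0 and direction != last_direction:
                    reversal_contrasts.append(contrast)
                    reversal_trials.append(trial)
                last_direction = direction
                contrast = proposed
        if len(reversal_contrasts) >= s.max_reversals:
            termination = "reversals_reached"
            break

    n_run = len(trials)
    if len(reversal_contrasts) >= s.n_reversals_for_threshold:
        used = reversal_contrasts[-s.n_reversals_for_threshold :]
        threshold = _reversal_mean(used, s.reversal_average)
        valid = True
    else:
        warnings.warn(
            f"staircase ended with {len(reversal_contrasts)} reversal(s); "
            f"{s.n_reversals_for_threshold} needed for a threshold",
            StaircaseWarning,
            stacklevel=2,
        )
        threshold = float("nan")
        valid = False
    return StaircaseResult(
        trials=trials,
        reversal_contrasts=reversal_contrasts,
        reversal_trials=reversal_trials,
        threshold=threshold,
        valid=valid,
        n_trials_run=n_run,
        termination_reason=termination,
        settings=settings,
    )


@dataclass
class ConvergenceReport:
    """Monte-Carlo summary of staircase behaviour for one observer."""

    n_runs: int
    n_valid: int
    estimates: np.ndarray  # Michelson thresholds, NaN where invalid
    mean_log10_estimate: float
    sd_log10_estimate: float
    true_threshold: float
    bias_log10: float
    percent_correct_post_first_reversal: float


def convergence_report(
    observer: ObserverModel,
    condition: Condition,
    settings: StaircaseSettings | None = None,
    n_runs: int = 500,
    seed: int = 0,
) -> ConvergenceReport:
    """Replicate staircases against a simulated observer.

    Reports the distribution of threshold estimates, the bias relative
    to the observer's analytic 79.37 %-correct point, and the empirical
    percent correct over the post-convergence trials, i.e. from the
    first reversal onward (trials before it are start-contrast
    transients; the first-reversal trial itself belongs to the
    oscillatory regime).
    """
    if n_runs < 1:
        raise ParameterError("n_runs must be >= 1")
    settings = settings or StaircaseSettings()
    children = np.random.SeedSequence(seed).spawn(n_runs)
    estimates = np.full(n_runs, np.nan)
    n_correct_post = 0
    n_post = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", StaircaseWarning)
        for i, child in enumerate(children):
            rng = np.random.default_rng(child)
            result = run_staircase(observer.respond_fn(condition, rng), settings)
            if result.valid:
                estimates[i] = result.threshold
            if result.reversal_trials:
                first = result.reversal_trials[0]
                post = [ok for t, _, ok in result.trials if t >= first]
                n_correct_post += sum(post)
                n_post += len(post)
    valid = estimates[np.isfinite(estimates)]
    logs = np.log10(valid) if valid.size else np.array([np.nan])
    true_thr = observer.true_threshold(condition)
    return ConvergenceReport(
        n_runs=n_runs,
        n_valid=int(valid.size),
        estimates=estimates,
        mean_log10_estimate=float(np.mean(logs)),
        sd_log10_estimate=float(np.std(logs, ddof=1)) if valid.size > 1 else float("nan"),
        true_threshold=true_thr,
        bias_log10=float(np.mean(logs) - np.log10(true_thr)),
        percent_correct_post_first_reversal=(
            100.0 * n_correct_post / n_post if n_post else float("nan")
        ),
    )
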