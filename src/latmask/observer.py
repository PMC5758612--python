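"""Simulated two-interval forced-choice (2AFC) observers.

The observer detects a Gabor target with probability given by a Weibull
psychometric function (guess rate 0.5, optional lapse).  Its sensitivity
in each condition is set by an orthogonal-baseline contrast threshold per
separation plus a *lateral-interaction profile*: the threshold-elevation
(TE) shift, in log10 units, that collinear flankers induce at each
target-to-flanker separation.  Positive TE = inhibition (within the
perceptual field), negative TE = facilitation (outside it); the zero
crossing estimates the perceptual-field border.

Thresholds are parameterized at the 79.37 %-correct point — the
equilibrium of a 3-down/1-up staircase — so that staircase estimates are
unbiased by construction rather than through a fitted conversion.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Tuple

import numpy as np

from .exceptions import ConfigurationError, ParameterError

__all__ = [
    "P_3D1U",
    "PsychometricParams",
    "LateralProfile",
    "ObserverModel",
    "weibull_p_correct",
]

#: Convergence probability of the 3-down/1-up rule, 0.5**(1/3).
P_3D1U = 0.5 ** (1.0 / 3.0)

Condition = Tuple[str, float]  # (orientation, separation_lambda)


def weibull_p_correct(
    contrast: float | np.ndarray,
    alpha: float,
    beta: float,
    lapse: float = 0.0,
    guess: float = 0.5,
) -> float | np.ndarray:
    """Weibull psychometric function on linear contrast.

    P(c) = guess + (1 - guess - lapse) * (1 - exp(-(c / alpha)**beta))
    """
    c = np.asarray(contrast, dtype=float)
    p = guess + (1.0 - guess - lapse) * (1.0 - np.exp(-((c / alpha) ** beta)))
    return float(p) if np.isscalar(contrast) else p


@dataclass(frozen=True)
class PsychometricParams:
    """Shape of the observer's psychometric function.

    beta is the Weibull slope (dimensionless; ~3 is typical for contrast
    detection), lapse the stimulus-independent error rate, guess the 2AFC
    chance level (fixed at 0.5).
    """

    beta: float = 3.0
    lapse: float = 0.02
    guess: float = 0.5

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ParameterError("beta must be positive")
        if not 0 <= self.lapse <= 0.1:
            raise ParameterError("lapse must lie in [0, 0.1]")
        if self.guess != 0.5:
            raise ParameterError("guess is fixed at 0.5 for 2AFC")


@dataclass(frozen=True)
class LateralProfile:
    """Separation-dependent threshold-elevation profile (log10 units)."""

    te_by_separation: Mapping[float, float]

    def __post_init__(self) -> None:
        if not self.te_by_separation:
            raise ParameterError("te_by_separation must not be empty")
        te = [self.te_by_separation[s] for s in self.separations]
        signs = [v for v in te if v != 0]
        crossings = sum(
            1 for a, b in zip(signs, signs[1:]) if (a > 0) != (b > 0)
        )
        if crossings > 1:
            warnings.warn(
                "TE profile changes sign more than once; the "
                "perceptual-field border is ill-defined",
                stacklevel=2,
            )

    @property
    def separations(self) -> list[float]:
        return sorted(self.te_by_separation)

    def te(self, separation_lambda: float) -> float:
        """TE at any separation, piecewise-linear between anchors."""
        seps = self.separations
        vals = [self.te_by_separation[s] for s in seps]
        return float(np.interp(separation_lambda, seps, vals))

    @property
    def pf_border_lambda(self) -> float | None:
        """First zero crossing of the profile (inhibition->facilitation),
        or None if the profile never changes sign."""
        seps = self.separations
        vals = [self.te_by_separation[s] for s in seps]
        for (s0, v0), (s1, v1) in zip(zip(seps, vals), zip(seps[1:], vals[1:])):
            if v0 > 0 >= v1:
                return s1 if v0 == v1 else s0 + (s1 - s0) * v0 / (v0 - v1)
        return None


@dataclass(frozen=True)
class ObserverModel:
    """One simulated participant.

    ``orthogonal_threshold`` maps separation (in lambda) to the Michelson
    contrast at which the observer is 79.37 % correct in the orthogonal
    baseline condition.  Collinear thresholds follow from the profile:
    threshold_coll(d) = threshold_orth(d) * 10**TE(d).
    """

    orthogonal_threshold: Mapping[float, float]
    profile: LateralProfile
    psychometric: PsychometricParams = field(default_factory=PsychometricParams)
    group: str = "control"
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for sep, thr in self.orthogonal_threshold.items():
            if not 0 < thr <= 1:
                raise ParameterError(
                    f"orthogonal threshold at {sep} lambda must be in (0, 1]"
                )
        max_lapse = 1.0 - P_3D1U
        if self.psychometric.lapse >= max_lapse:
            raise ParameterError(
                f"lapse {self.psychometric.lapse} puts the 79.37% point out "
                f"of reach (must be < {max_lapse:.4f})"
            )

    # -- condition handling -------------------------------------------------

    def _check_condition(self, condition: Condition) -> Condition:
        orientation, sep = condition
        if orientation not in ("collinear", "orthogonal"):
            raise ConfigurationError(f"unknown orientation {orientation!r}")
        if sep not in self.orthogonal_threshold:
            raise ConfigurationError(
                f"no orthogonal threshold defined at {sep} lambda "
                f"(known: {sorted(self.orthogonal_threshold)})"
            )
        return orientation, float(sep)

    def true_threshold(self, condition: Condition) -> float:
        """Contrast of the 79.37 %-correct point in this condition."""
        orientation, sep = self._check_condition(condition)
        base = float(self.orthogonal_threshold[sep])
        if orientation == "orthogonal":
            return base
        return base * 10.0 ** self.profile.te(sep)

    def alpha(self, condition: Condition) -> float:
        """Weibull scale parameter implied by the condition threshold."""
        t = self.true_threshold(condition)
        ps = self.psychometric
        q = (P_3D1U - ps.guess) / (1.0 - ps.guess - ps.lapse)
        return t * (-math.log1p(-q)) ** (-1.0 / ps.beta)

    def p_correct(self, condition: Condition, contrast: float) -> float:
        """Probability of a correct 2AFC response at the given contrast."""
        if not 0 <= contrast <= 1:
            raise ParameterError(f"contrast must lie in [0, 1], got {contrast}")
        if contrast == 0:
            return self.psychometric.guess
        return weibull_p_correct(
            contrast,
            self.alpha(condition),
            self.psychometric.beta,
            self.psychometric.lapse,
            self.psychometric.guess,
        )

    def respond(
        self, condition: Condition, contrast: float, rng: np.random.Generator
    ) -> bool:
        """One Bernoulli trial; reproducible under a seeded generator."""
        return bool(rng.random() < self.p_correct(condition, contrast))

    def respond_fn(self, condition: Condition, rng: np.random.Generator):
        """Contrast -> bool oracle for the staircase engine."""
        condition = self._check_condition(condition)
        return lambda contrast: self.respond(condition, contrast, rng)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "rng_seed": self.rng_seed,
            "orthogonal_threshold": {
                str(k): v for k, v in sorted(self.orthogonal_threshold.items())
            },
            "te_by_separation": {
                str(k): v for k, v in sorted(self.profile.te_by_separation.items())
            },
            "psychometric": {
                "beta": self.psychometric.beta,
                "lapse": self.psychometric.lapse,
                "guess": self.psychometric.guess,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ObserverModel":
        ps = d.get("psychometric", {})
        return cls(
            orthogonal_threshold={
                float(k): float(v) for k, v in d["orthogonal_threshold"].items()
            },
            profile=LateralProfile(
                {float(k): float(v) for k, v in d["te_by_separation"].items()}
            ),
            psychometric=PsychometricParams(
                beta=ps.get("beta", 3.0),
                lapse=ps.get("lapse", 0.02),
                guess=ps.get("guess", 0.5),
            ),
            group=d.get("group", "control"),
            rng_seed=d.get("rng_seed"),
        )

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "ObserverModel":
        return cls.from_dict(json.loads(s))
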