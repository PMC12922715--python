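"""Psychometric-function fitting for speeded n-AFC identification.

Proportion correct is modelled as a function of log presentation time:

    psi(t) = gamma + (1 - gamma - lambda) * F(log t; m, s)

with ``F`` the reverse Gumbel (log-Weibull) CDF,

    F(z) = 1 - exp(-exp((z - m) / s)),

which is increasing in ``z``, so psi rises from the guess rate ``gamma``
(chance: 1/8 for the 8-way task, 1/2 for the binary animal task) towards
the lapse-limited ceiling ``1 - lambda``.  ``m`` is the location on log-ms
(F(m) = 1 - 1/e) and ``s`` the scale in log-ms units.

Fitting maximises the binomial likelihood penalised by a Beta(1.5, 20)
prior on the lapse rate (bounded to [0, 0.1]); the guess rate is fixed by
the task design.  A criterion threshold (e.g. the presentation time
needed for 75% correct) is the inverse of psi at that criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import beta as beta_dist

__all__ = [
    "DegenerateFitError",
    "PerformanceCurvePoint",
    "PsychometricFit",
    "ANIMAL_CLASSES",
    "NONANIMAL_CLASSES",
    "reverse_gumbel_cdf",
    "psychometric_function",
    "collapse_to_animal_task",
    "performance_points",
    "fit_psychometric",
    "threshold_at",
]

ANIMAL_CLASSES = frozenset({"bird", "dog", "bear", "elephant"})
NONANIMAL_CLASSES = frozenset({"bike", "car", "boat", "airplane"})

LAPSE_MAX = 0.1
_LAPSE_PRIOR = (1.5, 20.0)  # Beta shape parameters
# fixed multi-start offsets on (m, s) around a moment-based initial guess
_STARTS = ((0.0, 1.0), (-0.7, 0.5), (0.7, 0.5), (0.0, 2.0), (-1.5, 1.0))


class DegenerateFitError(RuntimeError):
    """The data carry no slope information (all-ceiling or all-floor)."""


@dataclass(frozen=True)
class PerformanceCurvePoint:
    """Binomial performance at one presentation time."""

    presentation_ms: float
    n_correct: int
    n_total: int

    def __post_init__(self) -> None:
        if self.presentation_ms <= 0:
            raise ValueError("presentation time must be positive")
        if not 0 <= self.n_correct <= self.n_total or self.n_total < 1:
            raise ValueError("invalid binomial counts")

    @property
    def proportion(self) -> float:
        return self.n_correct / self.n_total


@dataclass(frozen=True)
class PsychometricFit:
    """MAP estimate of the reverse-Gumbel psychometric function."""

    m: float            # location, log-ms
    s: float            # scale, log-ms units
    guess_rate: float   # gamma, fixed by task design
    lapse_rate: float   # lambda, MAP under Beta(1.5,20) on [0, 0.1]
    log_posterior: float
    converged: bool


def reverse_gumbel_cdf(z, m: float, s: float):
    """F(z) = 1 - exp(-exp((z - m)/s)); increasing in z."""
    u = np.clip((np.asarray(z, dtype=float) - m) / s, -700.0, 700.0)
    return -np.expm1(-np.exp(np.minimum(u, 30.0)))


def psychometric_function(t_ms, fit: PsychometricFit):
    """psi(t) on the millisecond axis."""
    F = reverse_gumbel_cdf(np.log(t_ms), fit.m, fit.s)
    return fit.guess_rate + (1.0 - fit.guess_rate - fit.lapse_rate) * F


def collapse_to_animal_task(trials):
    """Collapse 8-way truth/response labels to {animal, nonanimal}.

    The four animal categories (bird, dog, bear, elephant) map to
    ``animal`` and the rest to ``nonanimal``, turning the identification
    task into a crude animal-detection task.  A response that is wrong at
    the 8-way level but falls in the correct group becomes correct in the
    binary task, so per-trial correctness never decreases.

    Accepts and returns a pandas trial table with ``true_class`` and
    ``response_class`` columns; adds ``true_group``, ``response_group``
    and a binary ``correct`` column (missing responses stay incorrect).
    """
    import pandas as pd

    out = trials.copy()

    def to_group(label):
        if label in ANIMAL_CLASSES:
            return "animal"
        if label in NONANIMAL_CLASSES:
            return "nonanimal"
        if pd.isna(label) or label == "NO_RESPONSE":
            return "NO_RESPONSE"
        raise ValueError(f"unknown class label {label!r}")

    out["true_group"] = out["true_class"].map(to_group)
    out["response_group"] = out["response_class"].map(to_group)
    if (out["true_group"] == "NO_RESPONSE").any():
        raise ValueError("true_class contains missing labels")
    out["correct"] = (out["true_group"] == out["response_group"]) & (
        out["response_group"] != "NO_RESPONSE"
    )
    return out


def performance_points(
    trials, correct_col: str = "correct", time_col: str = "presentation_ms"
) -> list[PerformanceCurvePoint]:
    """Aggregate a trial table into per-time binomial curve points."""
    points = []
    for t, grp in trials.groupby(time_col):
        points.append(
            PerformanceCurvePoint(
                presentation_ms=float(t),
                n_correct=int(grp[correct_col].sum()),
                n_total=int(len(grp)),
            )
        )
    return sorted(points, key=lambda p: p.presentation_ms)


def _neg_log_posterior(theta, z, k, n, gamma):
    m, s, lam = theta
    F = reverse_gumbel_cdf(z, m, s)
    p = gamma + (1.0 - gamma - lam) * F
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    loglik = np.sum(k * np.log(p) + (n - k) * np.log1p(-p))
    # prior on lambda, rescaled to its [0, LAPSE_MAX] support; clipped away
    # from the support edges where the log density diverges to -inf
    logprior = beta_dist.logpdf(
        np.clip(lam / LAPSE_MAX, 1e-9, 1.0 - 1e-9), *_LAPSE_PRIOR
    )
    return -(loglik + logprior)


def fit_psychometric(
    points: Sequence[PerformanceCurvePoint],
    guess_rate: float,
    lapse_max: float = LAPSE_MAX,
) -> PsychometricFit:
    """MAP fit of the reverse-Gumbel psychometric function.

    Requires at least 3 distinct presentation times.  Deterministic:
    L-BFGS-B from 5 fixed starts around a moment-based initial location.

    Raises
    ------
    DegenerateFitError
        If observed proportions are flat (spread < 0.05), i.e. the data
        sit wholly at ceiling or floor and carry no slope information.
    """
    times = np.array([p.presentation_ms for p in points], dtype=float)
    if np.unique(times).size < 3:
        raise ValueError("need >= 3 distinct presentation times")
    if not 0.0 <= guess_rate < 1.0:
        raise ValueError("guess_rate must lie in [0, 1)")
    k = np.array([p.n_correct for p in points], dtype=float)
    n = np.array([p.n_total for p in points], dtype=float)
    props = k / n
    if props.max() - props.min() < 0.05:
        raise DegenerateFitError(
            f"proportions span only [{props.min():.3f}, {props.max():.3f}]; "
            "no slope information"
        )
    z = np.log(times)

    # moment-based anchor: log-time where performance crosses mid-range
    mid = guess_rate + (1.0 - guess_rate) * (1.0 - np.exp(-1.0))
    m0 = float(np.interp(mid, props, z)) if props[-1] > props[0] else float(z.mean())
    bounds = [
        (z.min() - 3.0, z.max() + 3.0),
        (1e-3, 10.0),
        (0.0, lapse_max),
    ]
    best = None
    for dm, s0 in _STARTS:
        res = optimize.minimize(
            _neg_log_posterior,
            x0=np.array([m0 + dm, s0, 0.02]),
            args=(z, k, n, guess_rate),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    m, s, lam = best.x
    return PsychometricFit(
        m=float(m),
        s=float(s),
        guess_rate=guess_rate,
        lapse_rate=float(lam),
        log_posterior=-float(best.fun),
        converged=bool(best.success),
    )


def threshold_at(fit: PsychometricFit, criterion: float) -> float:
    """Presentation time (ms) at which psi reaches ``criterion``.

    Inverts psi: with q = (criterion - gamma)/(1 - gamma - lambda),
    t = exp(m + s * log(-log(1 - q))).  Monotone in the criterion.

    Raises
    ------
    ValueError
        If the criterion lies outside the attainable range
        (guess_rate, 1 - lapse_rate).
    """
    lo, hi = fit.guess_rate, 1.0 - fit.lapse_rate
    if not lo < criterion < hi:
        raise ValueError(
            f"criterion {criterion} unattainable: psi spans ({lo:.4f}, {hi:.4f})"
        )
    q = (criterion - fit.guess_rate) / (1.0 - fit.guess_rate - fit.lapse_rate)
    return float(np.exp(fit.m + fit.s * np.log(-np.log1p(-q))))
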