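"""Error consistency: Cohen's kappa on joint correctness, and its reliability.

Error consistency (EC) measures trial-by-trial agreement between two
observers' correct/incorrect response patterns on a shared stimulus set.
Observed agreement ``p_o`` is the fraction of trials on which both were
jointly correct or jointly incorrect; expected agreement ``p_e`` assumes
the two observers are independent binomial responders with their marginal
accuracies, so ``p_e = p1*p2 + (1-p1)*(1-p2)``.  Cohen's kappa

    kappa = (p_o - p_e) / (1 - p_e)

is the chance-corrected agreement.  Near ceiling (or floor) ``p_e -> 1``
and the ``1/(1-p_e)`` factor amplifies single-trial changes, so two
diagnostics accompany every kappa here:

* ``kappa_max`` — the largest kappa attainable with both marginal
  accuracies held fixed (``p_o_max = 1 - |p1 - p2|``), and
* ``flips_to_kappa_max`` — how many trials would have to be flipped in one
  observer, always in accuracy-preserving pairs (one correct-to-incorrect
  together with one incorrect-to-correct), to reach ``kappa_max``.  A small
  flip distance means a handful of unlucky trials could have produced a
  drastically different kappa, flagging the condition as unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "AlignmentError",
    "UndefinedKappaError",
    "BinaryOutcomePair",
    "ContingencyCounts",
    "AgreementResult",
    "BootstrapInterval",
    "count_contingency",
    "expected_agreement",
    "observed_agreement",
    "cohens_kappa",
    "kappa_max",
    "flips_to_kappa_max",
    "stability_flag",
    "agreement_result",
    "bootstrap_kappa",
    "pairwise_kappa_matrix",
    "group_mean_kappa",
]

DEFAULT_FLIP_THRESHOLD = 10


class AlignmentError(ValueError):
    """Two outcome sequences are not aligned on the same items."""


class UndefinedKappaError(ArithmeticError):
    """kappa is undefined because expected agreement equals 1.

    Happens when both observers are at 0% or at 100% accuracy; the
    chance-correction denominator ``1 - p_e`` vanishes.  Callers must
    handle this explicitly -- it is never silently reported as 0.
    """


@dataclass(frozen=True)
class BinaryOutcomePair:
    """Aligned correct/incorrect sequences of two observers.

    Alignment is positional: ``outcomes_a[i]`` and ``outcomes_b[i]`` refer
    to the trial identified by ``item_ids[i]``.
    """

    item_ids: tuple
    outcomes_a: np.ndarray
    outcomes_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.outcomes_a, dtype=bool)
        b = np.asarray(self.outcomes_b, dtype=bool)
        ids = tuple(self.item_ids)
        if len(ids) != a.size or a.size != b.size:
            raise AlignmentError(
                f"misaligned pair: {len(ids)} items, {a.size} vs {b.size} outcomes"
            )
        if a.size < 1:
            raise AlignmentError("empty outcome pair")
        if len(set(ids)) != len(ids):
            raise AlignmentError("item_ids contain duplicates")
        object.__setattr__(self, "item_ids", ids)
        object.__setattr__(self, "outcomes_a", a)
        object.__setattr__(self, "outcomes_b", b)

    @property
    def n(self) -> int:
        return self.outcomes_a.size

    @classmethod
    def from_sequences(
        cls,
        outcomes_a: Sequence[int],
        outcomes_b: Sequence[int],
        item_ids: Sequence | None = None,
    ) -> "BinaryOutcomePair":
        a = np.asarray(outcomes_a)
        if item_ids is None:
            item_ids = tuple(range(len(a)))
        return cls(tuple(item_ids), a, np.asarray(outcomes_b))


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 joint correctness counts for one observer pair.

    ``n11``: both correct, ``n10``: only A correct, ``n01``: only B
    correct, ``n00``: both incorrect.  Every agreement statistic in this
    module is a function of these four numbers.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        for name in ("n11", "n10", "n01", "n00"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.n < 1:
            raise ValueError("contingency table must contain at least one trial")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def acc_a(self) -> float:
        """Marginal accuracy of observer A."""
        return (self.n11 + self.n10) / self.n

    @property
    def acc_b(self) -> float:
        """Marginal accuracy of observer B."""
        return (self.n11 + self.n01) / self.n


@dataclass(frozen=True)
class AgreementResult:
    """All agreement statistics for one observer pair on one condition."""

    n: int
    p_o: float
    p_e: float
    kappa: float
    kappa_max: float
    flip_distance: int
    flip_pairs: int
    stable: bool
    acc_a: float
    acc_b: float


@dataclass(frozen=True)
class BootstrapInterval:
    """Percentile bootstrap interval for kappa.

    ``n_effective`` counts the resamples that produced a defined kappa;
    degenerate resamples (p_e = 1) are dropped.
    """

    point: float
    lower: float
    upper: float
    coverage: float
    n_resamples: int
    n_effective: int
    seed: int


def count_contingency(pair: BinaryOutcomePair) -> ContingencyCounts:
    """Tabulate the four joint correctness outcomes of an aligned pair."""
    a, b = pair.outcomes_a, pair.outcomes_b
    return ContingencyCounts(
        n11=int(np.sum(a & b)),
        n10=int(np.sum(a & ~b)),
        n01=int(np.sum(~a & b)),
        n00=int(np.sum(~a & ~b)),
    )


def observed_agreement(counts: ContingencyCounts) -> float:
    """Fraction of trials on which both observers agree (p_o)."""
    return (counts.n11 + counts.n00) / counts.n


def expected_agreement(counts: ContingencyCounts) -> float:
    """Chance agreement p_e of independent binomial observers.

    With marginal accuracies p1 and p2, two independent observers agree
    (both correct, or both incorrect) with probability
    ``p1*p2 + (1-p1)*(1-p2)``.
    """
    p1, p2 = counts.acc_a, counts.acc_b
    return p1 * p2 + (1.0 - p1) * (1.0 - p2)


def cohens_kappa(counts: ContingencyCounts) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e).

    Raises
    ------
    UndefinedKappaError
        If ``p_e == 1`` (both observers all-correct or both all-wrong).
    """
    p_o = observed_agreement(counts)
    p_e = expected_agreement(counts)
    if p_e >= 1.0:
        raise UndefinedKappaError(
            "kappa undefined: expected agreement is 1 "
            f"(marginals {counts.acc_a:.3f}, {counts.acc_b:.3f})"
        )
    return (p_o - p_e) / (1.0 - p_e)


def kappa_max(counts: ContingencyCounts) -> float:
    """Largest kappa attainable with both marginal accuracies fixed.

    With marginals fixed, observed agreement is maximised by emptying the
    smaller off-diagonal cell, giving ``p_o_max = 1 - |p1 - p2|``; kappa_max
    plugs that into the kappa formula.  Equals 1 iff the marginals coincide.
    """
    p_e = expected_agreement(counts)
    if p_e >= 1.0:
        raise UndefinedKappaError("kappa_max undefined: expected agreement is 1")
    p_o_max = 1.0 - abs(counts.acc_a - counts.acc_b)
    return (p_o_max - p_e) / (1.0 - p_e)


def flips_to_kappa_max(counts: ContingencyCounts) -> int:
    """Number of trials to flip in one observer to reach kappa_max.

    Each accuracy-preserving modification flips a *pair* of trials in one
    observer -- one A-only-correct trial becomes both-incorrect while one
    B-only-correct trial becomes both-correct -- so it moves one trial out
    of each off-diagonal cell and flips two trials in total.  After
    ``min(n10, n01)`` such pair-flips the smaller off-diagonal cell is
    empty and kappa equals kappa_max, hence the distance ``2*min(n10, n01)``.
    """
    return 2 * min(counts.n10, counts.n01)


def stability_flag(
    counts: ContingencyCounts, threshold: int = DEFAULT_FLIP_THRESHOLD
) -> bool:
    """True (stable) when the flip distance is at least ``threshold`` trials.

    Conditions with fewer than ``threshold`` flips to kappa_max are treated
    as unreliable: a few unlucky trials could have produced a drastically
    different kappa.  The default threshold of 10 trials is conservative.
    """
    return flips_to_kappa_max(counts) >= threshold


def agreement_result(
    counts: ContingencyCounts, threshold: int = DEFAULT_FLIP_THRESHOLD
) -> AgreementResult:
    """Bundle every agreement statistic for one contingency table."""
    flips = flips_to_kappa_max(counts)
    return AgreementResult(
        n=counts.n,
        p_o=observed_agreement(counts),
        p_e=expected_agreement(counts),
        kappa=cohens_kappa(counts),
        kappa_max=kappa_max(counts),
        flip_distance=flips,
        flip_pairs=flips // 2,
        stable=stability_flag(counts, threshold),
        acc_a=counts.acc_a,
        acc_b=counts.acc_b,
    )


def _kappa_from_joint_arrays(
    n11: np.ndarray, n10: np.ndarray, n01: np.ndarray, n00: np.ndarray
) -> np.ndarray:
    """Vectorised kappa over stacked contingency tables; NaN where p_e = 1."""
    n = n11 + n10 + n01 + n00
    p1 = (n11 + n10) / n
    p2 = (n11 + n01) / n
    p_o = (n11 + n00) / n
    p_e = p1 * p2 + (1.0 - p1) * (1.0 - p2)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = (p_o - p_e) / (1.0 - p_e)
    return np.where(p_e >= 1.0, np.nan, k)


def bootstrap_kappa(
    pair: BinaryOutcomePair,
    n_resamples: int = 2000,
    coverage: float = 0.68,
    seed: int = 0,
) -> BootstrapInterval:
    """Percentile bootstrap interval for kappa under paired trial resampling.

    Trials are resampled with replacement; the same item index is drawn for
    both observers, preserving the joint correctness structure.  Resamples
    whose kappa is undefined (p_e = 1) are dropped and the effective count
    reported.

    Raises
    ------
    UndefinedKappaError
        If every resample is degenerate.
    """
    if pair.n < 2:
        raise ValueError("bootstrap requires at least 2 trials")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must lie in (0, 1)")

    point = cohens_kappa(count_contingency(pair))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pair.n, size=(n_resamples, pair.n))
    a = pair.outcomes_a[idx]
    b = pair.outcomes_b[idx]
    n11 = np.sum(a & b, axis=1)
    n10 = np.sum(a & ~b, axis=1)
    n01 = np.sum(~a & b, axis=1)
    n00 = np.sum(~a & ~b, axis=1)
    kappas = _kappa_from_joint_arrays(n11, n10, n01, n00)
    kappas = kappas[np.isfinite(kappas)]
    if kappas.size == 0:
        raise UndefinedKappaError("all bootstrap resamples had p_e = 1")
    alpha = (1.0 - coverage) / 2.0
    lower, upper = np.quantile(kappas, [alpha, 1.0 - alpha])
    return BootstrapInterval(
        point=point,
        lower=float(lower),
        upper=float(upper),
        coverage=coverage,
        n_resamples=n_resamples,
        n_effective=int(kappas.size),
        seed=seed,
    )


def pairwise_kappa_matrix(
    observers: dict[str, Sequence[int]],
    item_ids: Sequence | None = None,
    threshold: int = DEFAULT_FLIP_THRESHOLD,
) -> tuple[np.ndarray, list[str], dict[tuple[str, str], AgreementResult]]:
    """Symmetric kappa matrix over all observer pairs on a shared item set.

    Parameters
    ----------
    observers
        Mapping observer id -> correctness sequence; all sequences must be
        aligned on the same items (same length, same order).
    item_ids
        Optional shared item identifiers.
    threshold
        Flip-distance stability threshold passed through to the per-pair
        results.

    Returns
    -------
    matrix, labels, results
        ``matrix`` holds kappa (NaN where undefined); the diagonal is 1.0
        where a self-pair is non-degenerate, NaN otherwise.  ``results``
        maps each unordered pair (ordered lexically by position) to its
        full :class:`AgreementResult`.
    """
    labels = list(observers)
    if len(labels) < 2:
        raise ValueError("need at least 2 observers")
    lengths = {k: len(np.asarray(v)) for k, v in observers.items()}
    if len(set(lengths.values())) != 1:
        raise AlignmentError(f"observers disagree on item count: {lengths}")
    n_items = next(iter(lengths.values()))
    if item_ids is None:
        item_ids = tuple(range(n_items))

    m = len(labels)
    mat = np.full((m, m), np.nan)
    results: dict[tuple[str, str], AgreementResult] = {}
    for i, la in enumerate(labels):
        # diagonal: a deterministic record is perfectly self-consistent
        seq = np.asarray(observers[la], dtype=bool)
        degenerate = seq.all() or not seq.any()
        mat[i, i] = np.nan if degenerate else 1.0
        for j in range(i + 1, m):
            lb = labels[j]
            pair = BinaryOutcomePair(tuple(item_ids), seq, np.asarray(observers[lb]))
            counts = count_contingency(pair)
            try:
                res = agreement_result(counts, threshold)
                mat[i, j] = mat[j, i] = res.kappa
                results[(la, lb)] = res
            except UndefinedKappaError:
                mat[i, j] = mat[j, i] = np.nan
    return mat, labels, results


def group_mean_kappa(
    matrix: np.ndarray, rows: Sequence[int], cols: Sequence[int]
) -> float:
    """Unweighted mean kappa between two observer groups, skipping the
    diagonal and undefined (NaN) cells."""
    vals = []
    for i in rows:
        for j in cols:
            if i == j:
                continue
            v = matrix[i, j]
            if np.isfinite(v):
                vals.append(v)
    return float(np.mean(vals)) if vals else float("nan")
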