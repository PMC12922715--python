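"""Synthetic observers, trial tables, and test images.

Everything the analysis pipeline consumes can be generated here, fully
seeded, so every stage runs without external data:

* correlated binary observer pairs with specified marginal accuracies and
  a target kappa (the correlated generalisation of the independent
  binomial null behind expected agreement);
* complete trial tables emulating the speeded 8-way identification
  experiment — sessions/rounds/blocks/sets structure, balanced classes,
  per-image latent difficulty shared across observers (the source of
  above-chance between-observer error consistency), accuracy rising with
  presentation time via each observer's psychometric function, and
  shifted-lognormal response times admitting a median split;
* small synthetic images as fixtures for the corruption operators.

All randomness derives from one root seed via ``numpy.random.SeedSequence``
spawning: stream 0 drives image difficulties, stream 1 + k drives
observer k's responses, letting observers be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregation import SUPERCLASSES
from .consistency import BinaryOutcomePair
from .psychometrics import reverse_gumbel_cdf
from .trials import REFRESH_HZ, NO_RESPONSE, frames_to_ms

__all__ = [
    "PairCouplingSpec",
    "ObserverSkill",
    "DesignSpec",
    "feasible_kappa_range",
    "simulate_binary_pair",
    "simulate_trial_table",
    "expected_accuracy",
    "analytic_pair_kappa",
    "synth_image",
    "miniature_design",
]


# ---------------------------------------------------------------------------
# correlated binary pairs


@dataclass(frozen=True)
class PairCouplingSpec:
    """Two correlated Bernoulli observers with a target kappa."""

    p1: float
    p2: float
    kappa_target: float
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p1 < 1.0 and 0.0 < self.p2 < 1.0):
            raise ValueError("marginal accuracies must lie in (0, 1)")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        lo, hi = feasible_kappa_range(self.p1, self.p2)
        if not lo - 1e-12 <= self.kappa_target <= hi + 1e-12:
            raise ValueError(
                f"kappa_target {self.kappa_target} infeasible for marginals "
                f"({self.p1}, {self.p2}); valid range is [{lo:.4f}, {hi:.4f}]"
            )


def _kappa_of_joint(p11: float, p1: float, p2: float) -> float:
    p_o = 1.0 - p1 - p2 + 2.0 * p11
    p_e = p1 * p2 + (1.0 - p1) * (1.0 - p2)
    return (p_o - p_e) / (1.0 - p_e)


def feasible_kappa_range(p1: float, p2: float) -> tuple[float, float]:
    """Attainable kappa bounds for fixed marginals.

    The joint both-correct probability is constrained by the Frechet
    bounds ``max(0, p1+p2-1) <= p11 <= min(p1, p2)``; mapping the
    extremes through the kappa formula gives the range.  Equal marginals
    give an upper bound of 1; at p1 = p2 = 0.5 the full [-1, 1] range.
    """
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise ValueError("marginals must lie in (0, 1)")
    lo11 = max(0.0, p1 + p2 - 1.0)
    hi11 = min(p1, p2)
    return _kappa_of_joint(lo11, p1, p2), _kappa_of_joint(hi11, p1, p2)


def simulate_binary_pair(spec: PairCouplingSpec) -> BinaryOutcomePair:
    """Sample an aligned correctness pair with E[sample kappa] = target.

    Inverts the kappa formula: ``p_o = kappa*(1-p_e) + p_e`` fixes the
    joint both-correct cell ``p11 = (p_o + p1 + p2 - 1)/2``; trials are
    then drawn i.i.d. from the resulting 2x2 joint distribution.
    """
    p1, p2 = spec.p1, spec.p2
    p_e = p1 * p2 + (1.0 - p1) * (1.0 - p2)
    p_o = spec.kappa_target * (1.0 - p_e) + p_e
    p11 = (p_o + p1 + p2 - 1.0) / 2.0
    joint = np.array([p11, p1 - p11, p2 - p11, 1.0 - p1 - p2 + p11])
    joint = np.clip(joint, 0.0, None)
    joint = joint / joint.sum()
    rng = np.random.default_rng(spec.seed)
    cat = rng.choice(4, size=spec.n, p=joint)
    a = (cat == 0) | (cat == 1)
    b = (cat == 0) | (cat == 2)
    return BinaryOutcomePair(tuple(range(spec.n)), a, b)


# ---------------------------------------------------------------------------
# full trial tables


@dataclass(frozen=True)
class ObserverSkill:
    """Latent skill of one simulated observer.

    The probability of a correct 8-way response on an image with latent
    difficulty ``d`` at presentation time ``t`` ms under corruption ``c`` is

        gamma + (1 - gamma - lapse) * F(log t; m + offset_c + d_eff, s)

    with F the reverse-Gumbel CDF and ``d_eff`` the observer's view of the
    image difficulty: ``difficulty_loading * d_shared +
    sqrt(1 - loading^2) * d_private``.  A loading of 1 (human-like) means
    all observers see the same difficulty axis; a loading of 0 simulates a
    "model" observer whose errors are driven by an independent axis, so
    its error consistency with human-like observers is ~0.
    """

    observer_id: str
    location: float = 2.9          # log-ms; exp(2.9) ~ 18 ms
    scale: float = 0.7             # log-ms units
    lapse: float = 0.02
    corruption_offsets: dict = field(
        default_factory=lambda: {"none": 0.0, "noise": 0.9, "lowpass": 0.7,
                                 "grayscale": 0.15}
    )
    difficulty_loading: float = 1.0
    rt_shift_ms: float = 250.0
    rt_mu: float = 6.0             # log-ms of the lognormal component
    rt_slope: float = 0.08         # decrease in rt_mu per unit log-time
    rt_sigma: float = 0.25
    guess_bump: float = 0.15       # extra RT speed-up at the shortest time
    miss_rate: float = 0.0

    def p_correct(self, t_ms, corruption: str, d_eff, guess_rate: float):
        off = self.corruption_offsets.get(corruption, 0.0)
        F = reverse_gumbel_cdf(np.log(t_ms), self.location + off + d_eff, self.scale)
        return guess_rate + (1.0 - guess_rate - self.lapse) * F


@dataclass(frozen=True)
class DesignSpec:
    """Structure of one simulated study.

    Defaults reproduce the real experiment's design: 8 balanced classes,
    six presentation times {1,2,4,8,16,32} frames at 120 Hz, three
    corruption conditions per block, two sessions of two rounds, 96-image
    sets (48 at the two extreme times, where fewer images were allocated),
    and three practice trials at the start of each block's uncorrupted
    set — 2*2*(2*3*48 + 4*3*96) = 5,760 trials per observer.  Image pools
    hold 88 ids per class and time (44 at the extremes), 22 of them shared
    across corruptions (11 at the extremes); set slots beyond the pool
    reuse images, flagged as repeats.
    """

    observers: tuple
    classes: tuple = SUPERCLASSES
    presentation_frames: tuple = (1, 2, 4, 8, 16, 32)
    corruptions: tuple = ("none", "noise", "lowpass")
    sessions: int = 2
    rounds_per_session: int = 2
    set_size_full: int = 96
    set_size_reduced: int = 48
    images_per_class_per_time: int = 88
    shared_images_per_corruption: int = 22
    practice_per_block: int = 3
    difficulty_sd: float = 1.0
    guess_rate: float = 1.0 / 8.0
    refresh_hz: float = REFRESH_HZ

    def __post_init__(self) -> None:
        if len(self.classes) < 2 or len(self.observers) < 1:
            raise ValueError("need >= 2 classes and >= 1 observer")
        n_corr = len(self.corruptions)
        if self.shared_images_per_corruption * (n_corr + 1) > \
                self.images_per_class_per_time * n_corr:
            raise ValueError("shared images exceed the per-cell pool")
        if self.set_size_full % len(self.classes) or \
                self.set_size_reduced % len(self.classes):
            raise ValueError("set sizes must be divisible by the class count")

    def set_size(self, frames: int) -> int:
        extremes = (min(self.presentation_frames), max(self.presentation_frames))
        return self.set_size_reduced if frames in extremes else self.set_size_full

    def n_trials_per_observer(self) -> int:
        per_round = sum(
            len(self.corruptions) * self.set_size(f)
            for f in self.presentation_frames
        )
        return self.sessions * self.rounds_per_session * per_round


def _image_pools(design: DesignSpec) -> dict:
    """Distinct image ids per (class, frames, corruption); shared ids first."""
    pools: dict = {}
    extremes = (min(design.presentation_frames), max(design.presentation_frames))
    for cls in design.classes:
        for f in design.presentation_frames:
            half = 2 if f in extremes else 1
            n_shared = design.shared_images_per_corruption // half
            n_total = design.images_per_class_per_time // half
            n_own = (n_total - n_shared) // len(design.corruptions)
            shared = [f"{cls}_{f}f_sh{k}" for k in range(n_shared)]
            for corr in design.corruptions:
                own = [f"{cls}_{f}f_{corr}{k}" for k in range(n_own)]
                pools[(cls, f, corr)] = shared + own
    return pools


def simulate_trial_table(design: DesignSpec, seed: int = 0) -> pd.DataFrame:
    """Generate one complete study as a tidy trial table.

    Per image a latent difficulty is drawn once and shared across
    observers; per trial the correct-response probability follows the
    observer's psychometric function shifted by corruption and difficulty;
    wrong responses are uniform over the 7 other classes; response times
    are shifted-lognormal, faster at longer presentation times except for
    a guessing speed-up at the shortest.  Fully reproducible under seed.
    """
    root = np.random.SeedSequence(seed)
    streams = root.spawn(1 + len(design.observers))
    rng_d = np.random.default_rng(streams[0])

    pools = _image_pools(design)
    all_images = sorted({img for pool in pools.values() for img in pool})
    difficulty = dict(zip(all_images, rng_d.normal(0.0, design.difficulty_sd,
                                                   size=len(all_images))))

    ordered_frames = sorted(design.presentation_frames, reverse=True)
    rows = []
    for k, obs in enumerate(design.observers):
        rng = np.random.default_rng(streams[1 + k])
        # observer's private difficulty axis (used when loading < 1)
        rho = obs.difficulty_loading
        private = dict(zip(all_images,
                           rng.normal(0.0, design.difficulty_sd,
                                      size=len(all_images))))
        seen: dict = {}
        trial_index = 0
        for session in range(1, design.sessions + 1):
            for rnd in range(1, design.rounds_per_session + 1):
                for block, frames in enumerate(ordered_frames, start=1):
                    t_ms = frames_to_ms(frames, design.refresh_hz)
                    size = design.set_size(frames)
                    per_class = size // len(design.classes)
                    for set_index, corr in enumerate(design.corruptions, start=1):
                        imgs = []
                        for cls in design.classes:
                            pool = pools[(cls, frames, corr)]
                            start = seen.setdefault((cls, frames, corr), 0)
                            take = [pool[(start + j) % len(pool)]
                                    for j in range(per_class)]
                            seen[(cls, frames, corr)] = start + per_class
                            imgs.extend((cls, im) for im in take)
                        order = rng.permutation(len(imgs))
                        for present_rank, pos in enumerate(order):
                            cls, img = imgs[pos]
                            d_eff = rho * difficulty[img] + \
                                np.sqrt(max(0.0, 1 - rho ** 2)) * private[img]
                            p = obs.p_correct(t_ms, corr, d_eff,
                                              design.guess_rate)
                            correct = rng.random() < p
                            if correct:
                                resp = cls
                            else:
                                others = [c for c in design.classes if c != cls]
                                resp = others[rng.integers(len(others))]
                            if obs.miss_rate > 0 and rng.random() < obs.miss_rate:
                                resp, rt = NO_RESPONSE, np.nan
                            else:
                                mu = obs.rt_mu - obs.rt_slope * np.log(t_ms)
                                if frames == min(design.presentation_frames):
                                    mu -= obs.guess_bump
                                rt = obs.rt_shift_ms + rng.lognormal(mu, obs.rt_sigma)
                            is_practice = (
                                set_index == 1
                                and present_rank < design.practice_per_block
                            )
                            rows.append({
                                "observer_id": obs.observer_id,
                                "session": session,
                                "round": rnd,
                                "block": block,
                                "set_index": set_index,
                                "trial_index": trial_index,
                                "image_id": img,
                                "true_class": cls,
                                "response_class": resp,
                                "presentation_frames": frames,
                                "presentation_ms": round(t_ms, 2),
                                "corruption": corr,
                                "rt_ms": rt,
                                "is_practice": is_practice,
                                "is_repeat": False,
                            })
                            trial_index += 1
    df = pd.DataFrame(rows)
    # repeats: later presentations of the same image to the same observer
    # within a condition
    dup = df.duplicated(
        subset=["observer_id", "presentation_frames", "corruption", "image_id"],
        keep="first",
    )
    df["is_repeat"] = dup
    return df


# ---------------------------------------------------------------------------
# analytic expectations for the generator (oracles for recovery tests)

_GH_NODES = 61


def _gauss_hermite(sd: float):
    x, w = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    return x * sd, w / w.sum()


def expected_accuracy(
    skill: ObserverSkill,
    frames: int,
    corruption: str,
    difficulty_sd: float,
    guess_rate: float = 1.0 / 8.0,
    refresh_hz: float = REFRESH_HZ,
) -> float:
    """Difficulty-averaged probability of a correct response in one cell."""
    t_ms = frames_to_ms(frames, refresh_hz)
    d, w = _gauss_hermite(difficulty_sd)
    return float(np.sum(w * skill.p_correct(t_ms, corruption, d, guess_rate)))


def analytic_pair_kappa(
    skill_a: ObserverSkill,
    skill_b: ObserverSkill,
    frames: int,
    corruption: str,
    difficulty_sd: float,
    guess_rate: float = 1.0 / 8.0,
    refresh_hz: float = REFRESH_HZ,
) -> float:
    """Exact kappa implied by the generator's latent-difficulty mixture.

    Conditional on the shared difficulty d the two observers are
    independent, so ``p11 = E_d[ E[p_a | d] * E[p_b | d] ]`` where the
    inner expectations integrate each observer's private axis; the
    marginals integrate over everything.  Evaluated by Gauss-Hermite
    quadrature and mapped through the kappa formula.
    """
    t_ms = frames_to_ms(frames, refresh_hz)
    d, wd = _gauss_hermite(difficulty_sd)

    def cond_mean(skill: ObserverSkill):
        rho = skill.difficulty_loading
        if rho >= 1.0:
            return skill.p_correct(t_ms, corruption, d, guess_rate)
        e, we = _gauss_hermite(difficulty_sd * np.sqrt(1.0 - rho ** 2))
        grid = rho * d[:, None] + e[None, :]
        p = skill.p_correct(t_ms, corruption, grid, guess_rate)
        return p @ we

    pa, pb = cond_mean(skill_a), cond_mean(skill_b)
    p1 = float(np.sum(wd * pa))
    p2 = float(np.sum(wd * pb))
    p11 = float(np.sum(wd * pa * pb))
    return _kappa_of_joint(p11, p1, p2)


# ---------------------------------------------------------------------------
# synthetic images


def synth_image(
    height: int, width: int, kind: str = "smooth_field", seed: int = 0
) -> np.ndarray:
    """Seeded H x W x 3 test image in [0, 1].

    ``smooth_field``: sum of low-frequency sinusoids (low Laplacian
    energy); ``edges``: a sharp checker pattern; ``random``: i.i.d.
    uniform pixels.
    """
    if height < 8 or width < 8:
        raise ValueError("dimensions must be >= 8")
    rng = np.random.default_rng(seed)
    y = np.linspace(0.0, 1.0, height)[:, None]
    x = np.linspace(0.0, 1.0, width)[None, :]
    if kind == "smooth_field":
        img = np.zeros((height, width, 3))
        for c in range(3):
            ph = rng.uniform(0, 2 * np.pi, size=4)
            fy, fx = rng.uniform(0.5, 2.0, size=2)
            img[..., c] = (
                np.sin(2 * np.pi * fy * y + ph[0])
                + np.sin(2 * np.pi * fx * x + ph[1])
                + 0.5 * np.sin(2 * np.pi * (fy * y + fx * x) + ph[2])
            )
    elif kind == "edges":
        ny, nx = rng.integers(2, 5, size=2)
        checker = ((np.floor(y * ny) + np.floor(x * nx)) % 2).astype(float)
        img = np.repeat(checker[..., None], 3, axis=2)
    elif kind == "random":
        img = rng.uniform(size=(height, width, 3))
    else:
        raise ValueError(f"unknown kind {kind!r}")
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    return img


def miniature_design(
    seed: int = 0,
    n_human: int = 2,
    n_model: int = 0,
    difficulty_sd: float = 1.0,
) -> DesignSpec:
    """A small study (2 times x 2 corruptions, 40 images per cell pool)
    that generates in well under a second; used by tests and fixtures."""
    rng = np.random.default_rng(seed)
    observers = []
    for i in range(n_human):
        observers.append(ObserverSkill(
            observer_id=f"human{i}",
            location=2.9 + rng.normal(0, 0.15),
            scale=0.7,
            difficulty_loading=1.0,
        ))
    for i in range(n_model):
        observers.append(ObserverSkill(
            observer_id=f"model{i}",
            location=2.9 + rng.normal(0, 0.15),
            scale=0.7,
            difficulty_loading=0.0,
        ))
    return DesignSpec(
        observers=tuple(observers),
        presentation_frames=(4, 16),
        corruptions=("none", "noise"),
        sessions=1,
        rounds_per_session=1,
        set_size_full=40,
        set_size_reduced=40,
        images_per_class_per_time=20,
        shared_images_per_corruption=2,
        difficulty_sd=difficulty_sd,
    )
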