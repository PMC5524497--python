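"""Match-probability calculus for background-matching strategies.

A prey item resting on a heterogeneous background can adopt one of several
colouration strategies: *specialize* on one background variant, be a *random
sample* of the background, or carry the *central* (most probable) sample.
For a background with discrete variants occurring with probabilities
``p_1..p_K``, a specialist on variant ``k`` matches with probability ``p_k``,
while a random-sample phenotype (prey colour drawn from the same
distribution as the background) matches with probability ``sum(p_i**2)``.
Since ``max(p) >= sum(p**2)`` always, matching the most common variant never
does worse than sampling at random, with equality only for a uniform
background.

For continuously varying backgrounds the best single phenotype minimizes the
expected cost of deviation from a random background sample: the arithmetic
mean under squared-Euclidean cost, the coordinate-wise median under absolute
cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MatchModel",
    "match_prob_specialist",
    "match_prob_random_sample",
    "dominance_gap",
    "optimal_point",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class MatchModel:
    """Discrete background composition: probability of each variant.

    Parameters
    ----------
    probs
        Probability that a prey item lands on each background variant.
        Entries must lie in [0, 1] and sum to 1.
    """

    probs: np.ndarray = field()

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 1 or probs.size < 1:
            raise ValueError("probs must be a non-empty 1-D vector")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > max(_SUM_TOL, 1e-12 * probs.size):
            raise ValueError(f"probabilities must sum to 1 (got {probs.sum()!r})")
        object.__setattr__(self, "probs", probs)

    def __len__(self) -> int:
        return self.probs.size


def match_prob_specialist(model: MatchModel, k: int) -> float:
    """Probability that a specialist on variant ``k`` matches its background."""
    if not 0 <= k < len(model):
        raise IndexError(f"variant index {k} out of range for {len(model)} variants")
    return float(model.probs[k])


def match_prob_random_sample(model: MatchModel) -> float:
    """Probability that a random-sample phenotype matches its background.

    Prey colouration and resting background are independent draws from the
    same variant distribution, so the match probability is ``sum(p_i**2)``
    (for two variants: ``p**2 + (1-p)**2``).
    """
    p = model.probs
    return float(np.dot(p, p))


def dominance_gap(model: MatchModel) -> float:
    """Advantage of matching the most common variant over random sampling.

    Returns ``max(p) - sum(p**2)``, which is always >= 0 and equals 0 only
    when the distribution is uniform over its support.
    """
    p = model.probs
    gap = float(p.max() - np.dot(p, p))
    # guard against -1e-17 style rounding on uniform models
    return max(gap, 0.0)


def optimal_point(samples: np.ndarray, cost: str = "squared-euclidean") -> np.ndarray:
    """Best single phenotype for a cloud of background samples.

    Parameters
    ----------
    samples
        Array of shape (n, d) — n background samples in a d-dimensional
        perceptual feature space.  A 1-D array is treated as n samples in 1-D.
    cost
        ``"squared-euclidean"`` — minimize mean squared Euclidean distance;
        the optimum is the arithmetic mean (centroid).
        ``"absolute"`` — minimize mean absolute (L1) distance; the optimum is
        the coordinate-wise median (mid-point of the central pair for even n).

    Returns
    -------
    The optimal point, shape (d,).
    """
    pts = np.atleast_2d(np.asarray(samples, dtype=float).T).T
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] < 1:
        raise ValueError("need at least one sample")
    if cost == "squared-euclidean":
        return pts.mean(axis=0)
    if cost == "absolute":
        return np.median(pts, axis=0)
    raise ValueError(f"unknown cost {cost!r}")
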