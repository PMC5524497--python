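"""Typicality ranking of background samples and stimulus selection.

The central prediction under test is that the *most probable* background
sample — the one nearest the dense centre of the background feature
distribution — is the best single camouflage.  This module:

1. fits the feature distribution by maximum likelihood under a multivariate
   Gaussian (after per-dimension standardization, the ML location is the
   sample mean — the centroid);
2. ranks every sample by its Euclidean distance from the colour and texture
   centroids, separately for the two descriptor blocks;
3. cross-checks the ranking with a non-parametric typicality score
   (leave-one-out Gaussian kernel density); and
4. dichotomizes both rankings at their medians and selects the extremes of
   the four (colour x texture) cells as the 2x2 treatment stimuli:
   common/common, common/rare, rare/common, rare/rare.

Ties are broken by ascending provenance id throughout, so every ranking and
selection is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureVector

__all__ = [
    "FitError",
    "SelectionError",
    "DistributionFit",
    "RankedSample",
    "TreatmentSelection",
    "TREATMENTS",
    "fit_ml",
    "distances",
    "nonparametric_scores",
    "select_treatments",
    "ranks_to_frame",
    "selection_to_frame",
]

TREATMENTS = ("Col+Txt+", "Col+Txt-", "Col-Txt+", "Col-Txt-")


class FitError(ValueError):
    """Degenerate feature matrix: too few samples or a constant dimension."""


class SelectionError(ValueError):
    """A treatment cell cannot supply the requested number of stimuli."""


def _stack(features: list[FeatureVector]) -> tuple[np.ndarray, np.ndarray, list]:
    colour = np.array([f.colour for f in features], float)
    texture = np.array([f.texture for f in features], float)
    prov = [f.provenance for f in features]
    return colour, texture, prov


def _silverman(n: int, d: int) -> float:
    # normal-reference bandwidth for unit-variance data, product kernel
    return (4.0 / (d + 2.0)) ** (1.0 / (d + 4.0)) * n ** (-1.0 / (d + 4.0))


@dataclass(frozen=True)
class DistributionFit:
    """ML fit of the background feature distribution (standardized space).

    Raw features are standardized per dimension (mean 0, SD 1); centroids
    are the sample means mapped back to raw units, covariances are the ML
    (1/n) estimates on standardized data, and bandwidths follow the
    normal-reference rule for the kernel-density cross-check.
    """

    colour_mean: np.ndarray
    colour_sd: np.ndarray
    texture_mean: np.ndarray
    texture_sd: np.ndarray
    colour_cov: np.ndarray
    texture_cov: np.ndarray
    colour_bandwidth: float
    texture_bandwidth: float
    n: int

    @property
    def colour_centroid(self) -> np.ndarray:
        """ML location of the colour distribution, raw feature units."""
        return self.colour_mean

    @property
    def texture_centroid(self) -> np.ndarray:
        return self.texture_mean

    def standardize_colour(self, colour: np.ndarray) -> np.ndarray:
        return (colour - self.colour_mean) / self.colour_sd

    def standardize_texture(self, texture: np.ndarray) -> np.ndarray:
        return (texture - self.texture_mean) / self.texture_sd


def fit_ml(features: list[FeatureVector]) -> DistributionFit:
    """Fit centroids, covariances and KDE bandwidths by maximum likelihood."""
    colour, texture, _ = _stack(features)
    n = colour.shape[0]
    dim = colour.shape[1] + texture.shape[1]
    if n < dim + 1:
        raise FitError(f"need at least {dim + 1} samples for {dim} dimensions, got {n}")
    means, sds = [], []
    for block, name in ((colour, "colour"), (texture, "texture")):
        sd = block.std(axis=0)  # ML (1/n) scale
        dead = np.flatnonzero(sd <= 0)
        if dead.size:
            raise FitError(f"constant {name} dimension(s) {dead.tolist()}: degenerate features")
        means.append(block.mean(axis=0))
        sds.append(sd)
    zc = (colour - means[0]) / sds[0]
    zt = (texture - means[1]) / sds[1]
    return DistributionFit(
        colour_mean=means[0], colour_sd=sds[0],
        texture_mean=means[1], texture_sd=sds[1],
        colour_cov=zc.T @ zc / n, texture_cov=zt.T @ zt / n,
        colour_bandwidth=_silverman(n, colour.shape[1]),
        texture_bandwidth=_silverman(n, texture.shape[1]),
        n=n,
    )


@dataclass(frozen=True)
class RankedSample:
    """Distances from the centroids and the four typicality ranks (1 = most typical)."""

    provenance: tuple[int, int]
    d_colour: float
    d_texture: float
    colour_rank: int
    texture_rank: int
    np_colour_rank: int | None = None
    np_texture_rank: int | None = None


def _rank_ascending(values: np.ndarray, prov: list) -> np.ndarray:
    """Ranks 1..n ascending in value, ties broken by ascending provenance id."""
    order = sorted(range(len(prov)), key=lambda i: (values[i], prov[i]))
    ranks = np.empty(len(prov), dtype=int)
    ranks[order] = np.arange(1, len(prov) + 1)
    return ranks


def distances(fit: DistributionFit, features: list[FeatureVector]) -> list[RankedSample]:
    """Euclidean distance of each sample from the centroids, plus rankings.

    Distances are computed in standardized units, separately for the colour
    and texture blocks; each block gets its own ascending ranking.
    """
    colour, texture, prov = _stack(features)
    if colour.shape[1] != fit.colour_mean.size or texture.shape[1] != fit.texture_mean.size:
        raise ValueError("feature dimensions do not match the fitted model")
    d_col = np.linalg.norm(fit.standardize_colour(colour), axis=1)
    d_txt = np.linalg.norm(fit.standardize_texture(texture), axis=1)
    col_rank = _rank_ascending(d_col, prov)
    txt_rank = _rank_ascending(d_txt, prov)
    if len(features) >= 10:
        np_col, np_txt = nonparametric_scores(features, fit)
    else:  # KDE cross-check needs a minimal sample; ML ranking does not
        np_col = np_txt = [None] * len(features)
    return [
        RankedSample(
            provenance=prov[i],
            d_colour=float(d_col[i]), d_texture=float(d_txt[i]),
            colour_rank=int(col_rank[i]), texture_rank=int(txt_rank[i]),
            np_colour_rank=None if np_col[i] is None else int(np_col[i]),
            np_texture_rank=None if np_txt[i] is None else int(np_txt[i]),
        )
        for i in range(len(prov))
    ]


def _loo_kde_log_density(z: np.ndarray, h: float) -> np.ndarray:
    """Leave-one-out Gaussian product-kernel log density at each sample."""
    n = z.shape[0]
    sq = ((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2)
    k = np.exp(-sq / (2.0 * h * h))
    np.fill_diagonal(k, 0.0)
    dens = k.sum(axis=1)
    return np.log(np.maximum(dens, 1e-300))


def nonparametric_scores(
    features: list[FeatureVector], fit: DistributionFit | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Typicality ranks from a leave-one-out kernel density estimate.

    Returns (colour_ranks, texture_ranks), 1 = densest (most typical).
    Serves as a distribution-free cross-check on the ML distance ranking.
    """
    if len(features) < 10:
        raise FitError("need at least 10 samples for the kernel-density ranking")
    if fit is None:
        fit = fit_ml(features)
    colour, texture, prov = _stack(features)
    ranks = []
    for block, std, h in (
        (colour, fit.standardize_colour, fit.colour_bandwidth),
        (texture, fit.standardize_texture, fit.texture_bandwidth),
    ):
        logd = _loo_kde_log_density(std(block), h)
        # quantize so exact duplicates tie (and fall to the provenance rule)
        ranks.append(_rank_ascending(np.round(-logd, 9), prov))
    return ranks[0], ranks[1]


@dataclass(frozen=True)
class TreatmentSelection:
    """The four disjoint stimulus groups of the 2x2 common/rare design."""

    groups: dict[str, list[tuple[int, int]]]
    n_per_treatment: int

    def __post_init__(self) -> None:
        if set(self.groups) != set(TREATMENTS):
            raise ValueError(f"groups must be exactly {TREATMENTS}")
        all_ids = [p for g in self.groups.values() for p in g]
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("treatment groups must be pairwise disjoint")
        if any(len(g) != self.n_per_treatment for g in self.groups.values()):
            raise ValueError("every group must hold n_per_treatment stimuli")

    def all_targets(self) -> list[tuple[int, int]]:
        return [p for t in TREATMENTS for p in self.groups[t]]

    def treatment_of(self) -> dict[tuple[int, int], str]:
        return {p: t for t in TREATMENTS for p in self.groups[t]}


def select_treatments(ranked: list[RankedSample], n_per_treatment: int = 12) -> TreatmentSelection:
    """Pick the 2x2 treatment stimuli from the two typicality rankings.

    Each ranking is dichotomized at its median into a common half (ranks
    <= n/2) and a rare half.  Within each (colour-half x texture-half)
    cell, the ``n_per_treatment`` most extreme samples for that cell's
    definition are taken: smallest d_colour^2 + d_texture^2 for
    common/common, largest for rare/rare, and the signed difference of
    squared distances for the two mixed cells (matched distance small,
    mismatched large).
    """
    n = len(ranked)
    if n < 4 * n_per_treatment:
        raise SelectionError(f"{n} samples cannot supply 4 x {n_per_treatment} stimuli")
    half = n // 2
    cells: dict[str, list[RankedSample]] = {t: [] for t in TREATMENTS}
    for r in ranked:
        col = "+" if r.colour_rank <= half else "-"
        txt = "+" if r.texture_rank <= half else "-"
        cells[f"Col{col}Txt{txt}"].append(r)
    short = {t: len(c) for t, c in cells.items() if len(c) < n_per_treatment}
    if short:
        sizes = ", ".join(f"{t}: {k}" for t, k in sorted(short.items()))
        raise SelectionError(
            f"cell(s) too small for {n_per_treatment} stimuli per treatment ({sizes})"
        )
    score = {
        "Col+Txt+": lambda r: r.d_colour ** 2 + r.d_texture ** 2,
        "Col-Txt-": lambda r: -(r.d_colour ** 2 + r.d_texture ** 2),
        "Col+Txt-": lambda r: r.d_colour ** 2 - r.d_texture ** 2,
        "Col-Txt+": lambda r: r.d_texture ** 2 - r.d_colour ** 2,
    }
    groups = {
        t: [r.provenance for r in sorted(cells[t], key=lambda r: (score[t](r), r.provenance))
            [:n_per_treatment]]
        for t in TREATMENTS
    }
    return TreatmentSelection(groups=groups, n_per_treatment=n_per_treatment)


def ranks_to_frame(ranked: list[RankedSample]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "tree_id": r.provenance[0], "patch_id": r.provenance[1],
            "d_colour": r.d_colour, "d_texture": r.d_texture,
            "colour_rank": r.colour_rank, "texture_rank": r.texture_rank,
            "np_colour_rank": r.np_colour_rank, "np_texture_rank": r.np_texture_rank,
        }
        for r in ranked
    ])


def selection_to_frame(selection: TreatmentSelection) -> pd.DataFrame:
    return pd.DataFrame([
        {"treatment": t, "tree_id": p[0], "patch_id": p[1]}
        for t in TREATMENTS for p in selection.groups[t]
    ])
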