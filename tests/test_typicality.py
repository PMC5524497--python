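"""Distribution fit, typicality ranking, KDE cross-check, treatment selection."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from camotype import theory, typicality
from camotype.features import FeatureVector
from camotype.typicality import (
    FitError,
    SelectionError,
    TREATMENTS,
    distances,
    fit_ml,
    nonparametric_scores,
    select_treatments,
)

from conftest import gaussian_features


def cloud_at(colours, textures=None):
    """Wrap raw arrays as FeatureVectors with sequential provenance."""
    out = []
    for i, col in enumerate(colours):
        tex = textures[i] if textures is not None else np.full(6, 1 / 6)
        tex = np.asarray(tex, float)
        out.append(FeatureVector(colour=np.asarray(col, float), texture=tex,
                                 tree_id=i, patch_id=0, standardized=True))
    return out


class TestFitML:
    def test_centroid_recovers_generating_mean(self, feature_cloud):
        """At n=505 the fitted centroid sits within 3 SE of the true mean."""
        fit = fit_ml(feature_cloud)
        colours = np.array([f.colour for f in feature_cloud])
        se = colours.std(axis=0, ddof=1) / np.sqrt(len(feature_cloud))
        assert np.all(np.abs(fit.colour_centroid - [0.30, 0.25, 0.18]) < 3 * se + 1e-12)

    def test_centroid_is_the_squared_cost_optimal_point(self, feature_cloud):
        """Shared definition: ML location == arithmetic-mean optimum."""
        fit = fit_ml(feature_cloud)
        colours = np.array([f.colour for f in feature_cloud])
        np.testing.assert_allclose(
            fit.colour_centroid, theory.optimal_point(colours, "squared-euclidean")
        )

    def test_too_few_samples_rejected(self, feature_cloud):
        with pytest.raises(FitError, match="at least"):
            fit_ml(feature_cloud[:1])

    def test_constant_dimension_rejected(self):
        rng = np.random.default_rng(0)
        fvs = cloud_at(rng.normal(size=(30, 3)))  # constant texture block
        with pytest.raises(FitError, match="constant texture"):
            fit_ml(fvs)

    def test_covariances_are_ml_scale(self, feature_cloud):
        fit = fit_ml(feature_cloud)
        # standardized with the 1/n SD, so diagonal of the ML covariance is 1
        np.testing.assert_allclose(np.diag(fit.colour_cov), 1.0, rtol=1e-10)


class TestDistances:
    def test_sample_at_centroid_has_zero_distance_and_rank_one(self, feature_cloud):
        fit = fit_ml(feature_cloud)
        centre = FeatureVector(colour=fit.colour_centroid, texture=fit.texture_centroid,
                               tree_id=-1, patch_id=0, standardized=True)
        ranked = distances(fit, [centre] + list(feature_cloud))
        assert ranked[0].d_colour == pytest.approx(0.0)
        assert ranked[0].colour_rank == 1 and ranked[0].texture_rank == 1

    def test_distance_homogeneity(self, feature_cloud):
        """Doubling standardized coordinates doubles the distance."""
        fit = fit_ml(feature_cloud)
        f = feature_cloud[7]
        z = fit.standardize_colour(f.colour)
        doubled = FeatureVector(colour=fit.colour_mean + 2 * z * fit.colour_sd,
                                texture=f.texture, tree_id=-1, patch_id=0,
                                standardized=True)
        ranked = distances(fit, [f, doubled])
        assert ranked[1].d_colour == pytest.approx(2 * ranked[0].d_colour)

    def test_ranking_matches_brute_force_oracle(self, feature_cloud):
        """Rank order equals an independent argsort of recomputed distances."""
        fit = fit_ml(feature_cloud)
        ranked = distances(fit, feature_cloud)
        brute = np.array([
            np.sqrt((((f.colour - fit.colour_mean) / fit.colour_sd) ** 2).sum())
            for f in feature_cloud
        ])
        order = sorted(range(len(brute)),
                       key=lambda i: (brute[i], feature_cloud[i].provenance))
        expected = np.empty(len(brute), int)
        expected[order] = np.arange(1, len(brute) + 1)
        assert [r.colour_rank for r in ranked] == expected.tolist()

    def test_invariant_to_affine_feature_rescaling(self, feature_cloud):
        """Standardization absorbs per-dimension affine maps of raw features."""
        scaled = [
            FeatureVector(colour=f.colour * [2.0, 5.0, 0.5] + [1.0, 0.0, 3.0],
                          texture=f.texture, tree_id=f.tree_id, patch_id=f.patch_id,
                          standardized=True)
            for f in feature_cloud
        ]
        d0 = [r.d_colour for r in distances(fit_ml(feature_cloud), feature_cloud)]
        d1 = [r.d_colour for r in distances(fit_ml(scaled), scaled)]
        np.testing.assert_allclose(d0, d1, rtol=1e-9)

    def test_dimension_mismatch_rejected(self, feature_cloud):
        fit = fit_ml(feature_cloud)
        bad = [FeatureVector(colour=np.zeros(4), texture=np.full(6, 1 / 6),
                             tree_id=0, patch_id=0, standardized=True)]
        with pytest.raises(ValueError, match="dimension"):
            distances(fit, bad)


class TestNonparametricScores:
    def test_densest_sample_is_highly_typical_under_ml_ranking(self):
        """On unimodal clouds the KDE mode member falls in the first decile
        of the distance-from-centroid ranking."""
        for seed in (3, 4, 5):
            fvs = gaussian_features(seed=seed)
            fit = fit_ml(fvs)
            ranked = distances(fit, fvs)
            densest = min(ranked, key=lambda r: r.np_colour_rank)
            assert densest.colour_rank <= len(fvs) // 10

    def test_rankings_agree_with_ml_distances_overall(self):
        """Spearman agreement between KDE and ML rankings exceeds 0.9 for
        both descriptor blocks on elliptical unimodal data."""
        for seed in (6, 7, 8):
            fvs = gaussian_features(seed=seed)
            ranked = distances(fit_ml(fvs), fvs)
            for ml, np_ in (("colour_rank", "np_colour_rank"),
                            ("texture_rank", "np_texture_rank")):
                rho = spearmanr([getattr(r, ml) for r in ranked],
                                [getattr(r, np_) for r in ranked]).statistic
                assert rho > 0.9

    def test_duplicated_pair_gets_adjacent_ranks(self):
        rng = np.random.default_rng(2)
        colours = rng.normal(size=(30, 3))
        colours[11] = colours[10]
        textures = np.abs(rng.normal(0.2, 0.02, size=(30, 6)))
        fvs = cloud_at(colours, textures)
        col_ranks, _ = nonparametric_scores(fvs)
        assert abs(col_ranks[10] - col_ranks[11]) == 1
        assert col_ranks[10] < col_ranks[11]  # tie broken by provenance id

    def test_requires_enough_samples(self):
        fvs = gaussian_features(seed=0)[:5]
        with pytest.raises(FitError, match="at least 10"):
            nonparametric_scores(fvs)


class TestSelectTreatments:
    def test_study_scale_selection_sizes(self, cloud_selection):
        _, _, selection = cloud_selection
        assert {t: len(g) for t, g in selection.groups.items()} == {
            t: 12 for t in TREATMENTS
        }
        assert len(set(selection.all_targets())) == 48

    def test_selected_extremes_have_expected_distance_profile(self, cloud_selection):
        _, ranked, selection = cloud_selection
        by_prov = {r.provenance: r for r in ranked}
        mean_d = {
            t: np.mean([[by_prov[p].d_colour, by_prov[p].d_texture]
                        for p in selection.groups[t]], axis=0)
            for t in TREATMENTS
        }
        assert mean_d["Col+Txt+"][0] < mean_d["Col-Txt+"][0]
        assert mean_d["Col+Txt+"][1] < mean_d["Col+Txt-"][1]
        assert mean_d["Col-Txt-"][0] > mean_d["Col+Txt-"][0]
        assert mean_d["Col-Txt-"][1] > mean_d["Col-Txt+"][1]

    def test_four_separated_clusters_yield_their_extremal_members(self):
        """A central cluster plus colour-only, texture-only and doubly
        outlying satellites: each treatment's single pick must come from the
        qualitatively right cluster."""
        levels = (  # (colour level, texture level, cluster kind)
            [(0.001 * k, 0.001 * k, "central") for k in range(10)]
            + [(8.0, 0.0, "colour_far"), (8.001, 0.001, "colour_far")]
            + [(0.0, 8.0, "texture_far"), (0.001, 8.001, "texture_far")]
            + [(8.0, 8.0, "both_far"), (8.001, 8.001, "both_far")]
        )
        kind = [k for _, _, k in levels]
        rng = np.random.default_rng(0)
        # every dimension carries the cluster signal; jitter keeps SDs finite
        colours = (np.array([[c] * 3 for c, _, _ in levels])
                   + rng.normal(0, 0.01, (16, 3)))
        textures = (np.array([[t] * 6 for _, t, _ in levels])
                    + rng.normal(0, 0.01, (16, 6)))
        fvs = cloud_at(colours, textures)
        sel = select_treatments(distances(fit_ml(fvs), fvs), n_per_treatment=1)
        picked_kind = {t: kind[sel.groups[t][0][0]] for t in TREATMENTS}
        assert picked_kind == {
            "Col+Txt+": "central",
            "Col+Txt-": "texture_far",
            "Col-Txt+": "colour_far",
            "Col-Txt-": "both_far",
        }

    def test_selection_matches_independent_enumeration(self, cloud_selection):
        """Brute-force oracle: recompute cells and extremal scores directly
        from the distances and compare with the selection output."""
        _, ranked, selection = cloud_selection
        n = len(ranked)
        half = n // 2
        expected = {}
        for t, sign_c, sign_t in (("Col+Txt+", 1, 1), ("Col+Txt-", 1, -1),
                                  ("Col-Txt+", -1, 1), ("Col-Txt-", -1, -1)):
            cell = [r for r in ranked
                    if (r.colour_rank <= half) == (sign_c > 0)
                    and (r.texture_rank <= half) == (sign_t > 0)]
            score = sorted(cell, key=lambda r: (sign_c * r.d_colour ** 2
                                                + sign_t * r.d_texture ** 2,
                                                r.provenance))
            expected[t] = [r.provenance for r in score[:12]]
        assert expected == selection.groups

    def test_insufficient_cell_raises_selection_error(self):
        fvs = gaussian_features(seed=9)[:60]
        ranked = distances(fit_ml(fvs), fvs)
        with pytest.raises(SelectionError, match="cannot supply|cell"):
            select_treatments(ranked, n_per_treatment=20)

    def test_groups_are_disjoint_and_invariants_hold(self, cloud_selection):
        _, _, selection = cloud_selection
        ids = selection.all_targets()
        assert len(ids) == len(set(ids)) == 4 * selection.n_per_treatment
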