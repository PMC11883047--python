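"""PCA morphospace, confidence ellipses, centroid distances, harness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exinemorph.io import FEATURE_COLUMNS
from exinemorph.morphospace import (
    Morphospace,
    confidence_ellipse,
    reproduction_report,
)


def _table(X: np.ndarray, groups=None) -> pd.DataFrame:
    df = pd.DataFrame(X, columns=list(FEATURE_COLUMNS))
    df.insert(0, "grain_id", [f"g{i}" for i in range(len(df))])
    df.insert(1, "group", groups if groups is not None else "G3_extant")
    return df


def _random_table(n, rng, groups=None):
    return _table(rng.standard_normal((n, 40)) + rng.random(40) * 3, groups)


class TestFitPCA:
    def test_single_varying_feature_explains_everything(self):
        rng = np.random.default_rng(0)
        X = np.tile(rng.random(40), (10, 1))
        X[:, 0] = rng.standard_normal(10)
        res = Morphospace(_table(X), scaling="covariance").fit()
        assert res.explained_fraction[0] == pytest.approx(1.0)
        assert np.allclose(res.explained_fraction[1:], 0.0, atol=1e-12)

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        res = Morphospace(_random_table(60, rng)).fit()
        assert res.explained_fraction.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.explained_fraction) <= 1e-12)

    def test_eigenvalues_match_independent_eigendecomposition(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((12, 5))
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
        res = Morphospace(
            df, scaling="covariance", feature_cols=df.columns
        ).fit()
        # oracle: direct eigendecomposition of the sample covariance
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        got = res.explained_fraction * eigvals.sum()
        np.testing.assert_allclose(got, eigvals[: len(got)], atol=1e-10)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(3)
        res = Morphospace(_random_table(50, rng)).fit()
        gram = res.loadings.T @ res.loadings
        np.testing.assert_allclose(gram, np.eye(res.n_components), atol=1e-10)

    def test_constant_column_rejected_in_correlation_mode(self):
        rng = np.random.default_rng(4)
        tbl = _random_table(10, rng)
        tbl["sc3_19"] = 7.0
        with pytest.raises(ValueError, match="sc3_19"):
            Morphospace(tbl, scaling="correlation").fit()

    def test_explained_invariant_to_row_order_and_feature_rescaling(self):
        rng = np.random.default_rng(5)
        tbl = _random_table(40, rng)
        res = Morphospace(tbl).fit()
        shuffled = tbl.sample(frac=1.0, random_state=0)
        res_shuffled = Morphospace(shuffled).fit()
        np.testing.assert_allclose(
            res.explained_fraction, res_shuffled.explained_fraction, atol=1e-10
        )
        rescaled = tbl.copy()
        rescaled["log_size"] = 100.0 * rescaled["log_size"] - 3.0
        res_rescaled = Morphospace(rescaled, scaling="correlation").fit()
        np.testing.assert_allclose(
            res.explained_fraction, res_rescaled.explained_fraction, atol=1e-10
        )


class TestProject:
    def test_training_table_reproduces_scores(self):
        rng = np.random.default_rng(6)
        tbl = _random_table(30, rng)
        res = Morphospace(tbl).fit()
        np.testing.assert_allclose(res.project(tbl), res.scores, atol=1e-10)

    def test_center_projects_to_origin(self):
        rng = np.random.default_rng(7)
        res = Morphospace(_random_table(30, rng)).fit()
        np.testing.assert_allclose(res.project(res.center), 0.0, atol=1e-10)

    def test_full_rank_reconstruction_identity(self):
        rng = np.random.default_rng(8)
        tbl = _random_table(60, rng)
        res = Morphospace(tbl).fit()
        held_out = _random_table(5, rng)
        scores = res.project(held_out)
        reconstructed = scores @ res.loadings.T * res.scale + res.center
        np.testing.assert_allclose(
            reconstructed, held_out[list(FEATURE_COLUMNS)].to_numpy(), atol=1e-9
        )


class TestConfidenceEllipse:
    def test_isotropic_unit_variance_semi_axes(self):
        rng = np.random.default_rng(9)
        pts = rng.standard_normal((20000, 2))
        ell = confidence_ellipse(pts, level=0.5)
        target = float(np.sqrt(stats.chi2.ppf(0.5, 2)))  # ~1.17741
        assert ell.semi_axes[0] == pytest.approx(target, rel=0.03)
        assert ell.semi_axes[1] == pytest.approx(target, rel=0.03)

    def test_collinear_scores_flagged_degenerate(self):
        t = np.linspace(0, 1, 10)
        pts = np.column_stack([t, 2 * t])
        assert confidence_ellipse(pts).degenerate

    def test_monte_carlo_coverage_half(self):
        rng = np.random.default_rng(10)
        cov = np.array([[2.0, 0.7], [0.7, 1.0]])
        pts = rng.multivariate_normal([1.0, -2.0], cov, size=2000)
        ell = confidence_ellipse(pts, level=0.5)
        # Mahalanobis radius of each point wrt the fitted ellipse
        d = pts - np.array(ell.center)
        R = np.array(
            [
                [np.cos(ell.angle_rad), -np.sin(ell.angle_rad)],
                [np.sin(ell.angle_rad), np.cos(ell.angle_rad)],
            ]
        )
        local = d @ R
        inside = (local[:, 0] / ell.semi_axes[0]) ** 2 + (
            local[:, 1] / ell.semi_axes[1]
        ) ** 2 <= 1.0
        assert inside.mean() == pytest.approx(0.5, abs=0.03)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            confidence_ellipse(np.zeros((2, 2)))


class TestCentroidDistances:
    def test_single_coordinate_shift(self):
        rng = np.random.default_rng(11)
        X = np.tile(rng.random(40), (8, 1))
        X[4:, 0] += 5.0
        groups = ["G1_early_mid_miocene"] * 4 + ["G3_extant"] * 4
        res = Morphospace(_table(X, groups), scaling="covariance").fit()
        dm = res.centroid_distances(space="feature_40d")
        assert dm.between("G1_early_mid_miocene", "G3_extant") == pytest.approx(5.0)

    def test_identical_groups_zero_distance(self):
        rng = np.random.default_rng(12)
        block = rng.standard_normal((4, 40))
        X = np.vstack([block, block])
        groups = ["G1_early_mid_miocene"] * 4 + ["G3_extant"] * 4
        res = Morphospace(_table(X, groups), scaling="covariance").fit()
        dm = res.centroid_distances()
        assert dm.between("G1_early_mid_miocene", "G3_extant") == pytest.approx(
            0.0, abs=1e-10
        )

    def test_three_groups_match_hand_oracle(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((12, 40))
        groups = (
            ["G1_early_mid_miocene"] * 4
            + ["G2_late_miocene_pleistocene"] * 4
            + ["G3_extant"] * 4
        )
        res = Morphospace(_table(X, groups), scaling="covariance").fit()
        dm = res.centroid_distances(space="feature_40d")
        c = [X[i : i + 4].mean(axis=0) for i in (0, 4, 8)]
        for (i, a), (j, b) in [((0, c[0]), (1, c[1])), ((0, c[0]), (2, c[2])), ((1, c[1]), (2, c[2]))]:
            assert dm.distances[i, j] == pytest.approx(
                float(np.linalg.norm(a - b))
            )
        # symmetry and triangle inequality
        np.testing.assert_allclose(dm.distances, dm.distances.T)
        assert dm.distances[0, 2] <= dm.distances[0, 1] + dm.distances[1, 2] + 1e-12

    def test_pc_space_distance_equals_standardized_distance(self):
        rng = np.random.default_rng(14)
        groups = ["G1_early_mid_miocene"] * 10 + ["G3_extant"] * 10
        res = Morphospace(_random_table(20, rng, groups)).fit()
        d_pc = res.centroid_distances(space="pc_scores")
        d_std = res.centroid_distances(space="standardized_40d")
        np.testing.assert_allclose(d_pc.distances, d_std.distances, atol=1e-9)

    def test_unknown_space_rejected(self):
        rng = np.random.default_rng(15)
        groups = ["G1_early_mid_miocene", "G3_extant"] * 5
        res = Morphospace(_random_table(10, rng, groups)).fit()
        with pytest.raises(ValueError, match="space"):
            res.centroid_distances(space="manhattan")


class TestLoadingsReport:
    def test_single_varying_feature_tops_pc1(self):
        rng = np.random.default_rng(16)
        X = np.tile(rng.random(40), (10, 1))
        X[:, 3] = rng.standard_normal(10)
        res = Morphospace(_table(X), scaling="covariance").fit()
        report = res.loadings_report(top_n=1)
        pc1_top = report[report["component"] == "PC1"].iloc[0]
        assert pc1_top["feature"] == FEATURE_COLUMNS[3]

    def test_two_block_fixture_separates_axes(self):
        rng = np.random.default_rng(17)
        n = 200
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        X = 0.01 * rng.standard_normal((n, 40))
        X[:, :5] += 3.0 * a[:, None]   # block 1 -> PC1
        X[:, 5:8] += 1.5 * b[:, None]  # block 2 -> PC2
        res = Morphospace(_table(X), scaling="covariance").fit()
        report = res.loadings_report(top_n=5)
        pc1_feats = set(report[report["component"] == "PC1"]["feature"])
        pc2_feats = set(report[report["component"] == "PC2"]["feature"].head(3))
        assert pc1_feats == set(FEATURE_COLUMNS[:5])
        assert pc2_feats == set(FEATURE_COLUMNS[5:8])

    def test_report_stable_under_loading_sign_flip(self):
        rng = np.random.default_rng(18)
        res = Morphospace(_random_table(30, rng)).fit()
        report = res.loadings_report(top_n=40)
        flipped = report.copy()
        flipped["loading"] *= -1
        assert (report["abs_loading"] == flipped["loading"].abs()).all()


class TestReproductionHarness:
    def test_grid_recovers_generating_convention(self):
        rng = np.random.default_rng(19)
        groups = (
            ["G1_early_mid_miocene"] * 12
            + ["G2_late_miocene_pleistocene"] * 12
            + ["G3_extant"] * 12
        )
        tbl = _random_table(36, rng, groups)
        truth = Morphospace(tbl, scaling="covariance").fit()
        dm = truth.centroid_distances(space="feature_40d")
        reference = {
            "pc1_pct": 100.0 * truth.explained_fraction[0],
            "pc2_pct": 100.0 * truth.explained_fraction[1],
            "distances": sorted(
                [
                    dm.distances[0, 1],
                    dm.distances[1, 2],
                ]
            ),
        }
        report = reproduction_report(tbl, reference)
        best = report[report["best_match"]].iloc[0]
        assert best["scaling"] == "covariance"
        assert best["log_base"] == "e"
        assert best["mean_relative_deviation"] < 1e-10

    def test_report_covers_full_grid(self):
        rng = np.random.default_rng(20)
        groups = ["G1_early_mid_miocene"] * 6 + ["G3_extant"] * 6
        report = reproduction_report(
            _random_table(12, rng, groups), {"pc1_pct": 30.0}
        )
        assert len(report) == 8  # 2 scalings x 2 log bases x 2 spaces
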