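import math

import numpy as np
import pytest

from painnet.io import aggregate_experiments
from painnet.spatial import (
    DistanceMatrix,
    mds_embed_2d,
    pairwise_distances,
    projection_profile_correlations,
    strength_distance_correlation,
)

from conftest import make_catalog, make_table


class TestPairwiseDistances:
    def test_three_four_five_triangle(self):
        cat = make_catalog(["A", "B"], coords=np.array([[0, 0, 0], [3, 4, 0]], float))
        dm = pairwise_distances(cat)
        assert dm.lookup("A", "B") == pytest.approx(5.0)
        assert dm.lookup("A", "A") == 0.0

    def test_identical_coordinates_give_zero(self):
        cat = make_catalog(["A", "B"], coords=np.zeros((2, 3)))
        assert pairwise_distances(cat).lookup("A", "B") == 0.0

    def test_normalized_matrix_peaks_at_one(self):
        cat = make_catalog(["A", "B", "C"])
        dm = pairwise_distances(cat, normalize=True)
        assert dm.d.max() == pytest.approx(1.0)
        assert dm.normalized

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestMDS:
    def test_collinear_points_reconstructed(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.warns(RuntimeWarning, match="degenerate"):  # 1-D configuration
            coords = mds_embed_2d(DistanceMatrix(["A", "B", "C"], d))
        rec = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, d, atol=1e-9)

    def test_unit_square_recovered_up_to_rigid_motion(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        coords = mds_embed_2d(DistanceMatrix(list("ABCD"), d))
        rec = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, d, atol=1e-9)

    def test_duplicate_points_coincide(self):
        d = np.array(
            [[0, 0, 3], [0, 0, 3], [3, 3, 0]], dtype=float
        )
        with pytest.warns(RuntimeWarning, match="degenerate"):  # 1-D configuration
            coords = mds_embed_2d(DistanceMatrix(list("ABC"), d))
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-6)

    def test_degenerate_configuration_warns(self):
        d = np.zeros((3, 3))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            mds_embed_2d(DistanceMatrix(list("ABC"), d))


class TestStrengthDistance:
    def _setup(self, strengths):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        cat = make_catalog(list("ABCD"), coords=coords)
        rows = [
            ("A", t, "ipsi", "", s) for t, s in zip("BCD", strengths)
        ]
        table = aggregate_experiments(make_table(rows, cat))
        return table, pairwise_distances(cat)

    def test_exponential_decay_is_perfectly_anticorrelated(self):
        table, dm = self._setup([10.0 ** -d for d in (1, 2, 3)])
        out = strength_distance_correlation(table, dm)
        assert out.loc["A", "correlation"] == pytest.approx(-1.0, abs=1e-6)
        assert out.loc["A", "slope"] == pytest.approx(-1.0, abs=1e-3)

    def test_constant_strengths_flagged_undefined(self):
        table, dm = self._setup([0.5, 0.5, 0.5])
        out = strength_distance_correlation(table, dm)
        assert math.isnan(out.loc["A", "correlation"])

    def test_too_few_targets_flagged(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        cat = make_catalog(list("ABCD"), coords=coords)
        table = aggregate_experiments(
            make_table([("A", "B", "ipsi", "", 0.5), ("A", "C", "ipsi", "", 0.1)], cat)
        )
        out = strength_distance_correlation(table, pairwise_distances(cat))
        assert math.isnan(out.loc["A", "correlation"])
        assert out.loc["A", "n_targets"] == 2

    def test_generator_decay_recovered_in_sign(self):
        from painnet.synthetic import SyntheticConfig, generate_connectome

        neg = 0
        contra_rs = []
        seeds = range(15)
        for seed in seeds:
            table, cat, _ = generate_connectome(SyntheticConfig(seed=seed))
            agg = aggregate_experiments(table)
            dm = pairwise_distances(cat)
            ipsi = strength_distance_correlation(agg, dm, "ipsi")["correlation"]
            contra = strength_distance_correlation(agg, dm, "contra")["correlation"]
            neg += (ipsi.dropna() < 0).mean() > 0.5
            contra_rs.append(contra.dropna().mean())
        assert neg >= 0.95 * len(list(seeds))
        # contralateral profile has no distance term: centered on zero
        assert abs(np.mean(contra_rs)) < 0.1


class TestProfileCorrelations:
    def test_duplicated_outgoing_rows_correlate_perfectly(self):
        cat = make_catalog(list("ABCD"))
        rows = []
        for t, s in zip("CD", (0.5, 0.003)):
            rows.append(("A", t, "ipsi", "", s))
            rows.append(("B", t, "ipsi", "", s))
        table = aggregate_experiments(make_table(rows, cat))
        corr = projection_profile_correlations(table)
        i, j = corr.areas.index("A"), corr.areas.index("B")
        assert corr.source_corr[i, j] == pytest.approx(1.0)

    def test_disjoint_indicator_profiles_anticorrelate(self):
        cat = make_catalog(list("ABCD"))
        rows = [("A", "C", "ipsi", "", 1.0), ("B", "D", "ipsi", "", 1.0)]
        table = aggregate_experiments(make_table(rows, cat))
        corr = projection_profile_correlations(table)
        i, j = corr.areas.index("A"), corr.areas.index("B")
        assert corr.source_corr[i, j] < 0

    def test_matrices_symmetric_and_match_direct_recomputation(self, small_connectome):
        table, _, _ = small_connectome
        agg = aggregate_experiments(table)
        corr = projection_profile_correlations(agg)
        for mat in (corr.source_corr, corr.target_corr):
            np.testing.assert_allclose(mat, mat.T, equal_nan=True)

        # independent recomputation of one source pair with pandas
        from painnet.spatial import LOG_FLOOR

        areas = corr.areas
        i, j = 0, 1
        n = len(areas)
        piv_i = np.zeros(2 * n)
        piv_j = np.zeros(2 * n)
        for row in agg.records.itertuples():
            col = areas.index(row.target) + (0 if row.hemisphere == "ipsi" else n)
            if row.source == areas[i]:
                piv_i[col] = row.volume
            elif row.source == areas[j]:
                piv_j[col] = row.volume
        keep = np.ones(2 * n, bool)
        for k in (i, j):
            keep[k] = keep[n + k] = False
        xi = np.log10(piv_i[keep] + LOG_FLOOR)
        xj = np.log10(piv_j[keep] + LOG_FLOOR)
        expected = float(np.corrcoef(xi, xj)[0, 1])
        assert corr.source_corr[i, j] == pytest.approx(expected, abs=1e-12)
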