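import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cycleconn import (
    GrayMatterMask,
    HormonePanel,
    StatMap,
    VoxelGLM,
    build_design,
    form_clusters,
    fwe_adjust,
    zstandardize,
)

AFF3 = np.diag([3.0, 3.0, 3.0, 1.0])


def study_panel(n=32, sessions=2, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "scan_id": np.arange(1, n + 1),
            "session_id": np.repeat(np.arange(1, sessions + 1), n // sessions),
            "cycle_day": np.tile(np.arange(1, n // sessions + 1), sessions),
            "estradiol": rng.uniform(0.5, 3, n),
            "progesterone": rng.uniform(0.3, 3, n),
            "lh": rng.uniform(0.2, 5, n),
            "cortisol": rng.uniform(0.8, 1.2, n),
        }
    )
    return zstandardize(HormonePanel(df))


# --------------------------------------------------------------------------
# design matrix
# --------------------------------------------------------------------------

class TestDesign:
    def test_two_sessions_two_covariates_df28(self):
        dm = build_design(study_panel(), ["progesterone"], ["cortisol"])
        assert dm.matrix.shape == (32, 4)
        assert dm.columns == ["session_1", "session_2", "progesterone", "cortisol"]
        assert dm.rank == 4
        assert dm.df_residual == 28

    def test_duplicated_covariate_is_rank_deficient(self):
        panel = study_panel()
        panel.df["progesterone2"] = panel.df["progesterone"]
        with pytest.raises(ValueError, match="progesterone2"):
            build_design(panel, ["progesterone", "progesterone2"])

    def test_centered_covariates_have_zero_mean(self):
        dm = build_design(study_panel(), ["progesterone"], ["cortisol"], center=True)
        assert abs(dm.matrix[:, 2].mean()) < 1e-12
        assert abs(dm.matrix[:, 3].mean()) < 1e-12

    def test_session_indicators_partition_scans(self):
        dm = build_design(study_panel(), ["progesterone"])
        np.testing.assert_array_equal(dm.matrix[:, 0] + dm.matrix[:, 1], np.ones(32))

    def test_unknown_column(self):
        with pytest.raises(KeyError):
            build_design(study_panel(), ["serotonin"])


# --------------------------------------------------------------------------
# OLS fit and contrasts
# --------------------------------------------------------------------------

class TestFit:
    def test_exact_linear_maps_recovered(self):
        panel = study_panel()
        dm = build_design(panel, ["progesterone"], ["cortisol"])
        maps = np.outer(dm.matrix[:, 2], np.full(5, 2.0))  # y = 2 * progesterone
        res = VoxelGLM(maps, dm).fit()
        np.testing.assert_allclose(res.params[2], 2.0, atol=1e-10)
        np.testing.assert_allclose(res.sigma2, 0.0, atol=1e-20)

    def test_matches_closed_form_simple_regression(self, rng):
        n = 24
        x = rng.standard_normal(n)
        y = rng.standard_normal((n, 50))
        dm_mat = np.column_stack([np.ones(n), x])
        from cycleconn.glm import DesignMatrix

        dm = DesignMatrix(dm_mat, ["intercept", "x"])
        res = VoxelGLM(y, dm).fit()
        # textbook formulas
        sxx = np.sum((x - x.mean()) ** 2)
        slope = (x - x.mean()) @ (y - y.mean(axis=0)) / sxx
        intercept = y.mean(axis=0) - slope * x.mean()
        np.testing.assert_allclose(res.params[1], slope, atol=1e-10)
        np.testing.assert_allclose(res.params[0], intercept, atol=1e-10)
        resid = y - dm_mat @ res.params
        np.testing.assert_allclose(
            res.sigma2, (resid**2).sum(axis=0) / (n - 2), atol=1e-10
        )

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        panel = study_panel()
        dm = build_design(panel, ["progesterone"], ["cortisol"])
        y = rng.standard_normal((32, 3))
        res = VoxelGLM(y, dm).fit()
        stat = res.t_contrast("progesterone")
        for v in range(3):
            fit = sm.OLS(y[:, v], dm.matrix).fit()
            np.testing.assert_allclose(res.params[:, v], fit.params, atol=1e-10)
            np.testing.assert_allclose(stat.t[v], fit.tvalues[2], atol=1e-8)

    def test_orthogonal_column_leaves_coefficients_unchanged(self, rng):
        from cycleconn.glm import DesignMatrix

        n = 20
        x = rng.standard_normal((n, 2))
        y = rng.standard_normal((n, 4))
        dm1 = DesignMatrix(x, ["a", "b"])
        beta1 = VoxelGLM(y, dm1).fit().params
        # a column orthogonal to the existing design
        q, _ = np.linalg.qr(np.column_stack([x, rng.standard_normal(n)]))
        extra = q[:, 2]
        dm2 = DesignMatrix(np.column_stack([x, extra]), ["a", "b", "c"])
        beta2 = VoxelGLM(y, dm2).fit().params
        np.testing.assert_allclose(beta2[:2], beta1, atol=1e-10)

    def test_misaligned_shapes(self):
        dm = build_design(study_panel(), ["progesterone"])
        with pytest.raises(ValueError, match="rows"):
            VoxelGLM(np.zeros((10, 5)), dm)


class TestContrast:
    def test_zero_residual_positive_effect_gives_infinite_t(self):
        panel = study_panel()
        dm = build_design(panel, ["progesterone"])
        maps = np.outer(dm.matrix[:, 2], [3.0])
        stat = VoxelGLM(maps, dm).fit().t_contrast("progesterone")
        assert np.isposinf(stat.t[0])
        assert stat.p[0] == np.finfo(np.float64).tiny

    def test_zero_t_gives_half_p_and_zero_z(self):
        from cycleconn.glm import DesignMatrix

        rng = np.random.default_rng(3)
        n = 16
        x = rng.standard_normal(n)
        y = rng.standard_normal((n, 1))
        # orthogonalize y against [1, x] then add nothing: construct y with zero fit
        dm = DesignMatrix(np.column_stack([np.ones(n), x]), ["i", "x"])
        xc = x - x.mean()
        y0 = y - np.outer(xc, (xc @ y) / (xc @ xc)) - y.mean(axis=0)
        stat = VoxelGLM(y0, dm).fit().t_contrast("x")
        assert stat.t[0] == pytest.approx(0.0, abs=1e-12)
        assert stat.p[0] == pytest.approx(0.5, abs=1e-12)
        assert stat.z[0] == pytest.approx(0.0, abs=1e-12)

    def test_null_false_positive_rate_at_05(self, rng):
        panel = study_panel()
        dm = build_design(panel, ["progesterone"], ["cortisol"])
        maps = rng.standard_normal((32, 5000))
        stat = VoxelGLM(maps, dm).fit().t_contrast("progesterone")
        frac = np.mean(stat.p < 0.05)
        se = np.sqrt(0.05 * 0.95 / 5000)
        assert abs(frac - 0.05) < 3 * se

    def test_constant_shift_does_not_move_hormone_t(self, rng):
        panel = study_panel()
        dm = build_design(panel, ["progesterone"], ["cortisol"])
        maps = rng.standard_normal((32, 20))
        t1 = VoxelGLM(maps, dm).fit().t_contrast("progesterone").t
        t2 = VoxelGLM(maps + 11.5, dm).fit().t_contrast("progesterone").t
        np.testing.assert_allclose(t1, t2, atol=1e-8)

    def test_raw_vs_zscored_covariate_same_t(self, rng):
        panel = study_panel()
        maps = rng.standard_normal((32, 10))
        t_raw = (
            VoxelGLM(maps, build_design(panel, ["progesterone"], ["cortisol"]))
            .fit().t_contrast("progesterone").t
        )
        t_z = (
            VoxelGLM(maps, build_design(panel, ["z_progesterone"], ["z_cortisol"]))
            .fit().t_contrast("z_progesterone").t
        )
        np.testing.assert_allclose(t_raw, t_z, atol=1e-8)


# --------------------------------------------------------------------------
# FWE arithmetic
# --------------------------------------------------------------------------

class TestFWE:
    def test_bonferroni_on_reference_resel_count(self):
        assert fwe_adjust(0.001, 575) == pytest.approx(0.575)
        assert fwe_adjust(0.01, 575) == 1.0  # capped

    def test_sidak_direct_evaluation(self):
        assert fwe_adjust(0.001, 575, "sidak") == pytest.approx(1 - 0.999**575)

    def test_monotone_and_ordered_on_grid(self):
        ps = np.array([1e-6, 1e-4, 0.001, 0.01, 0.05, 0.5, 1.0])
        ns = [1, 10, 575, 61940]
        for n in ns:
            bon = fwe_adjust(ps, n)
            sid = fwe_adjust(ps, n, "sidak")
            assert np.all(np.diff(bon) >= 0) and np.all(np.diff(sid) >= 0)
            assert np.all(bon >= sid - 1e-15) and np.all(sid >= ps - 1e-15)
        for p in ps:
            vals = [fwe_adjust(p, n) for n in ns]
            assert np.all(np.diff(vals) >= 0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fwe_adjust(0.0, 575)
        with pytest.raises(ValueError):
            fwe_adjust(1.5, 575)


# --------------------------------------------------------------------------
# cluster formation
# --------------------------------------------------------------------------

NEIGHBORS = {
    6: [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
        if abs(i) + abs(j) + abs(k) == 1],
    18: [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
         if 1 <= abs(i) + abs(j) + abs(k) <= 2],
    26: [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
         if (i, j, k) != (0, 0, 0)],
}


def flood_fill_clusters(binary, connectivity):
    """Independent BFS connected-components oracle."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    comps = []
    offsets = NEIGHBORS[connectivity]
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            for di, dj, dk in offsets:
                w = (v[0] + di, v[1] + dj, v[2] + dk)
                if all(0 <= w[a] < binary.shape[a] for a in range(3)) and binary[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


def stat_from_binary(binary, t_peak=None):
    """Build a StatMap whose supra-threshold (p<0.001) set equals ``binary``."""
    shape = binary.shape
    mask = GrayMatterMask(np.ones(shape, dtype=bool), AFF3)
    flat = binary.ravel(order="F")[mask.ordering]
    t = np.where(flat, 5.0, 0.0)
    if t_peak is not None:
        t = t + t_peak
    p = np.where(flat, 1e-5, 0.5)
    return StatMap(t=t, z=t.copy(), p=p, p_fwe=None, df=28,
                   contrast=np.array([1.0]), mask=mask)


class TestClusters:
    def test_single_voxel_dropped_by_extent_filter(self):
        binary = np.zeros((8, 8, 8), dtype=bool)
        binary[4, 4, 4] = True
        table = form_clusters(stat_from_binary(binary), extent_threshold=20)
        assert table.empty

    def test_l_shaped_blob_is_one_cluster_under_any_connectivity(self):
        binary = np.zeros((10, 10, 6), dtype=bool)
        binary[2:7, 3, 2] = True  # 5 voxels
        binary[6, 3:8, 2] = True  # 4 more
        binary[6, 7, 2:5] = True  # vertical arm
        n_expected = binary.sum()
        for conn in (6, 18, 26):
            table = form_clusters(stat_from_binary(binary), connectivity=conn)
            assert len(table) == 1
            assert table.k_E.iloc[0] == n_expected
            oracle = flood_fill_clusters(binary, conn)
            assert len(oracle) == 1 and len(oracle[0]) == n_expected

    def test_corner_touching_blobs_discriminate_18_vs_26(self):
        binary = np.zeros((8, 8, 8), dtype=bool)
        binary[0:2, 0:2, 0:2] = True
        binary[2:4, 2:4, 2:4] = True
        stat = stat_from_binary(binary)
        assert len(form_clusters(stat, connectivity=18)) == 2
        assert len(form_clusters(stat, connectivity=26)) == 1
        assert len(flood_fill_clusters(binary, 18)) == 2
        assert len(flood_fill_clusters(binary, 26)) == 1

    @pytest.mark.parametrize("conn", [6, 18, 26])
    def test_random_volumes_match_flood_fill_oracle(self, rng, conn):
        for _ in range(5):
            binary = rng.uniform(size=(9, 9, 7)) < 0.25
            table = form_clusters(stat_from_binary(binary), connectivity=conn)
            oracle = flood_fill_clusters(binary, conn)
            assert len(table) == len(oracle)
            assert sorted(table.k_E) == sorted(len(c) for c in oracle)

    def test_extent_filter_drops_exactly_small_components(self, rng):
        binary = rng.uniform(size=(12, 12, 8)) < 0.3
        oracle_sizes = [len(c) for c in flood_fill_clusters(binary, 18)]
        k = 5
        table = form_clusters(stat_from_binary(binary), extent_threshold=k, connectivity=18)
        assert sorted(table.k_E) == sorted(s for s in oracle_sizes if s >= k)

    def test_mirror_symmetry(self, rng):
        binary = rng.uniform(size=(10, 9, 7)) < 0.25
        t1 = form_clusters(stat_from_binary(binary), connectivity=18)
        t2 = form_clusters(stat_from_binary(binary[::-1]), connectivity=18)
        assert sorted(t1.k_E) == sorted(t2.k_E)

    def test_empty_input_gives_empty_table(self):
        binary = np.zeros((6, 6, 6), dtype=bool)
        table = form_clusters(stat_from_binary(binary))
        assert table.empty

    def test_peak_is_cluster_member_and_fwe_p_filled(self, rng):
        binary = np.zeros((8, 8, 8), dtype=bool)
        binary[1:5, 1:5, 1:4] = True
        stat = stat_from_binary(binary, t_peak=rng.uniform(0, 1, 8 * 8 * 8))
        table = form_clusters(stat, fwe_n=575)
        row = table.iloc[0]
        assert row._peak_index in set(row._voxel_rows)
        assert row.peak_p_fwe == pytest.approx(min(1.0, 575 * row.peak_p_uncorr))
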