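import numpy as np
import pytest

from climconflict import fe_ols as fo
from climconflict.panel_core import geometry_from_centroids, panel_from_frame

from conftest import make_panel_frame

FE2 = fo.FixedEffectsSpec(include_region_month=False)


def dummy_expansion_slopes(panel, treatments, fes):
    """Oracle: normal equations on the full dummy-expanded design."""
    y = panel.column("conflict")
    X = np.column_stack([panel.column(c) for c in treatments])
    D = fo.fe_dummy_matrix(fo.fe_group_codes(panel, fes))
    full = np.hstack([X, D])
    beta = np.linalg.lstsq(full, y, rcond=None)[0]
    return beta[: X.shape[1]]


class TestFrischWaugh:
    @pytest.mark.parametrize("seed", range(6))
    def test_demeaning_equals_dummy_expansion(self, seed):
        rng = np.random.default_rng(seed)
        include_rm = bool(seed % 2)
        n_regions = int(rng.integers(3, 6))
        # region-month FEs need repeated calendar months to leave residual df
        n_periods = int(rng.integers(14, 21)) if include_rm else int(rng.integers(4, 9))
        panel = panel_from_frame(make_panel_frame(n_regions, n_periods, seed=seed))
        fes = fo.FixedEffectsSpec(include_region_month=include_rm)
        fit = fo.fit_fe_ols(panel, fes=fes)
        oracle = dummy_expansion_slopes(panel, fit.treatments, fes)
        assert np.allclose(fit.slopes, oracle, rtol=1e-8, atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self, toy_panel):
        fit = fo.fit_fe_ols(toy_panel, fes=FE2)
        assert np.allclose(fit.design_demeaned.T @ fit.residuals, 0.0, atol=1e-8)


class TestFitStatistics:
    def test_noise_free_slope_recovery(self):
        rng = np.random.default_rng(5)
        panel = panel_from_frame(make_panel_frame(4, 24, seed=5))
        slopes = np.array([1.0, 0.5, -0.25])
        X = np.column_stack([panel.column(c) for c in ("TA", "DL", "PA")])
        r, t = panel.region_codes(), panel.period_codes()
        fe = rng.normal(size=4)[r] + rng.normal(size=24)[t]
        y = X @ slopes + fe
        # noise-free continuous outcome: bypass the integer-count contract
        panel.data["conflict"] = y
        fit = fo.fit_fe_ols(panel, fes=FE2)
        assert np.allclose(fit.slopes, slopes, atol=1e-6)
        assert fit.within_r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_outcome_flags_r2(self, toy_panel):
        toy_panel.data["conflict"] = 3
        fit = fo.fit_fe_ols(toy_panel, fes=FE2)
        assert np.allclose(fit.slopes, 0.0)
        assert np.isnan(fit.r2)
        assert any("undefined" in f for f in fit.flags)

    def test_rank_deficient_treatments_rejected(self, toy_panel):
        panel = toy_panel.with_column("TA2", 2.0 * toy_panel.column("TA"))
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            fo.fit_fe_ols(panel, treatments=("TA", "TA2"), fes=FE2)

    def test_within_r2_bounds(self, study_synthetic):
        panel, _, _ = study_synthetic
        fit = fo.fit_fe_ols(panel)
        assert 0.0 <= fit.within_r2 <= 1.0
        assert fit.adj_within_r2 <= fit.within_r2


def hac_oracle(fit, dist, cfg):
    """Literal quadruple-loop double sum over all observation pairs."""
    X, e = fit.design_demeaned, fit.residuals
    r, t = fit.region_codes, fit.period_codes
    k = X.shape[1]
    M = np.zeros((k, k))
    for p in range(len(e)):
        for q in range(len(e)):
            if cfg.spatial_kernel == "uniform":
                ks = 1.0 if dist[r[p], r[q]] <= cfg.distance_cutoff_km else 0.0
            else:
                ks = max(0.0, 1.0 - dist[r[p], r[q]] / cfg.distance_cutoff_km)
            lag = abs(int(t[p]) - int(t[q]))
            if lag > cfg.lag_cutoff_months:
                kt = 0.0
            elif cfg.temporal_kernel == "uniform":
                kt = 1.0
            else:
                kt = 1.0 - lag / (cfg.lag_cutoff_months + 1.0)
            M += ks * kt * np.outer(X[p] * e[p], X[q] * e[q])
    M = 0.5 * (M + M.T)
    # same documented guard as the estimator: clip negative eigenvalues at 0
    w, V = np.linalg.eigh(M)
    M = (V * np.clip(w, 0.0, None)) @ V.T
    bread = np.linalg.pinv(X.T @ X)
    return bread @ M @ bread


@pytest.fixture
def toy_geometry():
    # 3 centroids ~150 km apart pairwise along a meridian
    return geometry_from_centroids(["G0", "G1", "G2"],
                                   np.array([0.0, 1.35, 2.7]), np.array([45.0] * 3))


class TestHAC:
    @pytest.mark.parametrize("skern,tkern", [("uniform", "uniform"),
                                             ("bartlett", "bartlett"),
                                             ("uniform", "bartlett")])
    def test_matches_brute_force_double_sum(self, toy_panel, toy_geometry, skern, tkern):
        fit = fo.fit_fe_ols(toy_panel, fes=FE2)
        cfg = fo.HACConfig(distance_cutoff_km=200.0, lag_cutoff_months=2,
                           spatial_kernel=skern, temporal_kernel=tkern)
        V, _ = fo.hac_vcov(fit, toy_geometry, toy_panel.regions, cfg)
        dist = toy_geometry.distances_for(toy_panel.regions)
        assert np.allclose(V, hac_oracle(fit, dist, cfg), atol=1e-10)

    def test_zero_cutoffs_equal_white_sandwich(self, toy_panel, toy_geometry):
        fit = fo.fit_fe_ols(toy_panel, fes=FE2)
        cfg = fo.HACConfig(distance_cutoff_km=0.0, lag_cutoff_months=0)
        V, _ = fo.hac_vcov(fit, toy_geometry, toy_panel.regions, cfg)
        X, e = fit.design_demeaned, fit.residuals
        bread = np.linalg.pinv(X.T @ X)
        white = bread @ (X.T @ np.diag(e**2) @ X) @ bread
        assert np.allclose(V, white, atol=1e-12)

    def test_everything_inside_cutoffs_is_summed_score_outer_product(
        self, toy_panel, toy_geometry
    ):
        fit = fo.fit_fe_ols(toy_panel, fes=FE2)
        cfg = fo.HACConfig(distance_cutoff_km=1e9, lag_cutoff_months=10**6)
        V, _ = fo.hac_vcov(fit, toy_geometry, toy_panel.regions, cfg)
        X, e = fit.design_demeaned, fit.residuals
        s = (X * e[:, None]).sum(axis=0)
        bread = np.linalg.pinv(X.T @ X)
        assert np.allclose(V, bread @ np.outer(s, s) @ bread, atol=1e-10)

    def test_cutoffs_change_vcov_not_slopes(self, small_synthetic):
        panel, geometry, _ = small_synthetic
        fit1 = fo.fit_fe_ols(panel, fes=FE2)
        fit2 = fo.fit_fe_ols(panel, fes=FE2)
        V1, _ = fo.hac_vcov(fit1, geometry, panel.regions,
                            fo.HACConfig(distance_cutoff_km=100, lag_cutoff_months=1))
        V2, _ = fo.hac_vcov(fit2, geometry, panel.regions,
                            fo.HACConfig(distance_cutoff_km=400, lag_cutoff_months=6))
        assert np.array_equal(fit1.slopes, fit2.slopes)
        assert not np.allclose(V1, V2)

    def test_missing_geometry_region(self, toy_panel):
        geom = geometry_from_centroids(["G0", "G1"], np.zeros(2), np.array([0.0, 1.0]))
        fit = fo.fit_fe_ols(toy_panel, fes=FE2)
        with pytest.raises(ValueError, match="G2"):
            fo.hac_vcov(fit, geom, toy_panel.regions)


class TestGaussianDiagnostics:
    def test_normal_residuals_pass_ks(self):
        # outcome = FE structure + exact normal noise: KS should not reject
        rng = np.random.default_rng(12)
        panel = panel_from_frame(make_panel_frame(6, 60, seed=12))
        panel.data["conflict"] = rng.normal(size=panel.n_obs)
        fit = fo.fit_fe_ols(panel, fes=FE2)
        rep = fo.gaussian_diagnostics(fit)
        assert rep.ks_p > 0.01
        assert len(rep.qq_theoretical) == panel.n_obs

    def test_constant_residuals_flagged(self, toy_panel):
        fit = fo.fit_fe_ols(toy_panel, fes=FE2)
        fit.residuals = np.zeros_like(fit.residuals)
        rep = fo.gaussian_diagnostics(fit)
        assert any("undefined" in f for f in rep.flags)
        assert np.isnan(rep.ks_p)

    def test_too_few_observations(self, toy_panel):
        fit = fo.fit_fe_ols(toy_panel, fes=FE2)
        fit.residuals = fit.residuals[:2]
        with pytest.raises(ValueError, match="n < 3"):
            fo.gaussian_diagnostics(fit)

    def test_outliers_flagged_beyond_three_sd(self, toy_panel):
        fit = fo.fit_fe_ols(toy_panel, fes=FE2)
        fit.residuals = np.r_[np.zeros(10) + 0.1, -0.1 * np.ones(1), 50.0]
        rep = fo.gaussian_diagnostics(fit)
        assert 11 in rep.outliers


class TestResidualizedCorrelation:
    def test_identical_columns_give_one(self, toy_panel):
        panel = toy_panel.with_column("TAcopy", toy_panel.column("TA"))
        r = fo.residualized_correlation(panel, ("TA", "TAcopy"), FE2)
        assert r == pytest.approx(1.0)

    def test_orthogonal_columns_give_zero(self):
        panel = panel_from_frame(make_panel_frame(2, 4, seed=0))
        a = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0, -1.0, -1.0, 1.0, 1.0])
        panel = panel.with_column("A", a).with_column("B", b)
        r = fo.residualized_correlation(panel, ("A", "B"),
                                        fo.FixedEffectsSpec(False, False, False))
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_is_nan(self, toy_panel):
        panel = toy_panel.with_column("Z", np.zeros(toy_panel.n_obs))
        assert np.isnan(fo.residualized_correlation(panel, ("TA", "Z"), FE2))
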