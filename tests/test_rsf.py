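"""Use-availability modelling: scaling, VIF, mixed fits, CV, projection."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from fawnsurv.grid import build_grid
from fawnsurv.rsf import (
    RsfFit,
    Scaler,
    build_use_avail,
    fit_rsf,
    kfold_error,
    select_additive,
    standardize,
    suitability_surface,
    vif_screen,
)

from conftest import make_landscape


def _mixed_logit_table(n_fawns=60, locs=10, betas=(0.0,), sd_fawn=0.4, sd_year=0.2, seed=0):
    """Rows drawn directly from the crossed random-intercept logistic model."""
    rng = np.random.default_rng(seed)
    n = n_fawns * locs
    fawn = np.repeat(np.arange(n_fawns), locs)
    year = fawn % 3
    X = rng.normal(size=(n, len(betas)))
    eta = X @ np.asarray(betas) + rng.normal(0, sd_fawn, n_fawns)[fawn]
    eta += rng.normal(0, sd_year, 3)[year]
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
    cols = {f"x{i}": X[:, i] for i in range(len(betas))}
    return pd.DataFrame({"fawn_id": fawn, "year": year, "response": y, **cols})


# -- standardize --------------------------------------------------------


def test_standardize_two_values():
    df = pd.DataFrame({"response": [1, 0, 1, 0], "a": [0.0, 1.0, 0.0, 1.0]})
    out, scaler = standardize(df, ["a"])
    np.testing.assert_allclose(sorted(out["a_z"].unique()), [-1.0, 1.0])


def test_standardize_moments_and_roundtrip():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"a": rng.gamma(2, 3, 500), "b": rng.normal(10, 2, 500)})
    out, scaler = standardize(df, ["a", "b"])
    for c in ("a", "b"):
        assert out[c + "_z"].mean() == pytest.approx(0.0, abs=1e-9)
        assert out[c + "_z"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        back = scaler.inverse_column(c, out[c + "_z"].to_numpy())
        np.testing.assert_allclose(back, df[c].to_numpy(), atol=1e-9)


def test_standardize_idempotent_on_standardized_input():
    rng = np.random.default_rng(2)
    z = rng.normal(size=400)
    z = (z - z.mean()) / z.std(ddof=0)
    df = pd.DataFrame({"a": z})
    out, _ = standardize(df, ["a"])
    np.testing.assert_allclose(out["a_z"], z, atol=1e-9)


def test_standardize_zero_variance_dropped():
    df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
    with pytest.warns(UserWarning, match="zero variance"):
        out, scaler = standardize(df, ["a", "b"])
    assert "a_z" not in out.columns and "b_z" in out.columns
    assert "a" not in scaler.means


# -- vif_screen ---------------------------------------------------------


def test_vif_orthogonal_covariates():
    n = 4000
    rng = np.random.default_rng(3)
    df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
    vif = vif_screen(df, ["a", "b", "c"])
    np.testing.assert_allclose(vif["vif"], 1.0, atol=0.05)
    assert not vif["flagged"].any()


def test_vif_correlated_pair_closed_form():
    # corr 0.9 -> VIF = 1 / (1 - 0.81) ~ 5.26, below the 7 threshold
    rng = np.random.default_rng(4)
    n = 200_00
    a = rng.normal(size=n)
    b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
    vif = vif_screen(pd.DataFrame({"a": a, "b": b}), ["a", "b"])
    np.testing.assert_allclose(vif["vif"], 1 / (1 - 0.81), rtol=0.05)
    assert not vif["flagged"].any()


def test_vif_duplicate_covariate_flagged():
    rng = np.random.default_rng(5)
    a = rng.normal(size=100)
    vif = vif_screen(pd.DataFrame({"a": a, "b": a.copy()}), ["a", "b"])
    assert np.isinf(vif["vif"]).all()
    assert vif["flagged"].all()


# -- fit_rsf ------------------------------------------------------------


def test_fit_rsf_zero_variance_equals_plain_logistic():
    df = _mixed_logit_table(n_fawns=40, locs=10, betas=(0.5,), seed=6)
    df, _ = standardize(df, ["x0"])
    fit = fit_rsf(df, ["x0"], re_sd_fixed={"fawn_id": 0.0, "year": 0.0})
    X = np.column_stack([np.ones(len(df)), df["x0_z"]])
    oracle = sm.Logit(df["response"].to_numpy(float), X).fit(disp=0)
    assert abs(fit.intercept - oracle.params[0]) < 1e-6
    assert abs(fit.coef[0] - oracle.params[1]) < 1e-6
    assert abs(fit.se[0] - oracle.bse[1]) < 1e-4


def test_fit_rsf_recovers_negative_effect():
    df = _mixed_logit_table(n_fawns=150, locs=15, betas=(-0.6,), seed=7)
    df, _ = standardize(df, ["x0"])
    fit = fit_rsf(df, ["x0"])
    lo, hi = fit.coef[0] - 1.96 * fit.se[0], fit.coef[0] + 1.96 * fit.se[0]
    # x0 is ~N(0,1) so the z-scale coefficient is ~ the raw -0.6
    assert lo <= -0.6 <= hi


def test_wald_pvalues_uniform_under_null():
    # pooled p-values across replicates of a null covariate should be uniform
    pvals = []
    for rep in range(120):
        df = _mixed_logit_table(n_fawns=30, locs=6, betas=(0.0,), seed=1000 + rep)
        df, _ = standardize(df, ["x0"])
        fit = fit_rsf(df, ["x0"], re_sd_fixed={"fawn_id": 0.3, "year": 0.2})
        pvals.append(fit.pvalues[0])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_fit_rsf_diagnostics_exportable():
    df = _mixed_logit_table(n_fawns=30, locs=8, betas=(0.4,), seed=17)
    df, _ = standardize(df, ["x0"])
    fit = fit_rsf(df, ["x0"])
    diag = fit.diagnostics()
    assert {"fitted", "std_residual"} <= set(diag.columns)
    assert len(diag) == len(df)
    assert diag["fitted"].between(0, 1).all()


# -- select_additive ----------------------------------------------------


def _mock_fit(name, p):
    return RsfFit(
        covariates=[name],
        coef=np.array([0.0]),
        se=np.array([1.0]),
        zvalues=np.array([0.0]),
        pvalues=np.array([p]),
        intercept=0.0,
        re_var={},
        loglik=0.0,
        n_obs=10,
    )


def test_select_additive_threshold_rule():
    df = _mixed_logit_table(n_fawns=30, locs=8, betas=(0.0, 0.0, 0.0), seed=8)
    df, _ = standardize(df, ["x0", "x1", "x2"])
    fits = {
        "x0": _mock_fit("x0", 0.001),
        "x1": _mock_fit("x1", 0.04),
        "x2": _mock_fit("x2", 0.51),
    }
    retained, additive = select_additive(df, fits, alpha=0.05)
    assert retained == ["x0", "x1"]
    assert additive.covariates == ["x0", "x1"]


def test_select_additive_published_pattern():
    # single-covariate p-value pattern: three dropped, six retained
    pattern = {
        "lowland_forest": 0.0005,
        "deciduous_forest": 0.043,
        "coniferous_forest": 0.0005,
        "mixed_forest": 0.774,
        "grass_shrub": 0.830,
        "pasture": 0.003,
        "cropland": 0.397,
        "wetland": 0.022,
        "distance_to_road": 0.0005,
    }
    rng = np.random.default_rng(9)
    n = 300
    df = pd.DataFrame({name: rng.normal(size=n) for name in pattern})
    df["response"] = rng.integers(0, 2, n)
    df["fawn_id"] = rng.integers(0, 20, n)
    df["year"] = rng.integers(0, 3, n)
    df, _ = standardize(df, list(pattern))
    fits = {name: _mock_fit(name, p) for name, p in pattern.items()}
    retained, _ = select_additive(df, fits, alpha=0.05)
    assert set(retained) == {
        "lowland_forest",
        "deciduous_forest",
        "coniferous_forest",
        "pasture",
        "wetland",
        "distance_to_road",
    }


def test_select_additive_none_significant_raises():
    df = _mixed_logit_table(n_fawns=20, locs=5, betas=(0.0,), seed=10)
    df, _ = standardize(df, ["x0"])
    with pytest.raises(ValueError, match="no covariate significant"):
        select_additive(df, {"x0": _mock_fit("x0", 0.5)}, alpha=0.05)


# -- kfold_error --------------------------------------------------------


def test_kfold_uninformative_near_quarter():
    df = _mixed_logit_table(n_fawns=100, locs=10, betas=(0.0,), sd_fawn=0.0, sd_year=0.0, seed=11)
    df, _ = standardize(df, ["x0"])
    err = kfold_error(df, ["x0"], k=5, seed=0)
    assert err == pytest.approx(0.25, abs=0.02)


def test_kfold_separating_covariate_small_error():
    n = 500
    rng = np.random.default_rng(12)
    y = rng.integers(0, 2, n)
    df = pd.DataFrame(
        {
            "response": y,
            "x0": y * 2.0 - 1.0 + rng.normal(0, 0.05, n),
            "fawn_id": rng.integers(0, 20, n),
            "year": rng.integers(0, 3, n),
        }
    )
    df, _ = standardize(df, ["x0"])
    err = kfold_error(df, ["x0"], k=5, seed=0)
    assert err < 0.05


def test_kfold_better_for_true_model_than_noise():
    df = _mixed_logit_table(n_fawns=100, locs=10, betas=(1.2,), sd_fawn=0.0, sd_year=0.0, seed=13)
    rng = np.random.default_rng(14)
    df["noise"] = rng.normal(size=len(df))
    df, _ = standardize(df, ["x0", "noise"])
    assert kfold_error(df, ["x0"], k=5, seed=0) < kfold_error(df, ["noise"], k=5, seed=0)


def test_kfold_k_too_small_rejected():
    df = _mixed_logit_table(n_fawns=10, locs=4, seed=15)
    df, _ = standardize(df, ["x0"])
    with pytest.raises(ValueError, match="k must be"):
        kfold_error(df, ["x0"], k=1)


def test_kfold_seed_reproducible():
    df = _mixed_logit_table(n_fawns=40, locs=8, betas=(0.3,), seed=16)
    df, _ = standardize(df, ["x0"])
    assert kfold_error(df, ["x0"], k=5, seed=42) == kfold_error(df, ["x0"], k=5, seed=42)


# -- suitability_surface ------------------------------------------------


def _grid_and_scaler():
    land = make_landscape(np.ones((20, 20)), n_classes=2)
    grid = build_grid(land, cell_area=2115.0, class_names=["a", "b"])
    frame = grid.to_frame()
    scaler = Scaler(
        means={"distance_to_road": float(frame["distance_to_road"].mean())},
        sds={"distance_to_road": float(frame["distance_to_road"].std(ddof=0))},
    )
    return grid, scaler


def _fit_with(covs, coef):
    return RsfFit(
        covariates=covs,
        coef=np.asarray(coef, dtype=float),
        se=np.ones(len(covs)),
        zvalues=np.zeros(len(covs)),
        pvalues=np.zeros(len(covs)),
        intercept=0.3,
        re_var={},
        loglik=0.0,
        n_obs=10,
    )


def test_suitability_zero_betas_degenerate():
    grid, scaler = _grid_and_scaler()
    with pytest.warns(UserWarning, match="degenerate"):
        surf = suitability_surface(_fit_with(["distance_to_road"], [0.0]), scaler, grid)
    np.testing.assert_array_equal(surf.values, 0.0)


def test_suitability_monotone_in_single_covariate():
    grid, scaler = _grid_and_scaler()
    surf = suitability_surface(_fit_with(["distance_to_road"], [-0.8]), scaler, grid)
    d = grid.distance_to_road.ravel()
    w = surf.values.ravel()
    order = np.argsort(d)
    assert np.all(np.diff(w[order]) <= 1e-12)  # strictly decreasing in distance


def test_suitability_stretch_contract():
    grid, scaler = _grid_and_scaler()
    surf = suitability_surface(_fit_with(["distance_to_road"], [-0.8]), scaler, grid)
    assert surf.values.min() == 0.0 and surf.values.max() == 1.0


def test_suitability_missing_covariate_raises():
    grid, scaler = _grid_and_scaler()
    with pytest.raises(KeyError, match="missing_cov"):
        suitability_surface(_fit_with(["missing_cov"], [1.0]), scaler, grid)


def test_suitability_invariant_to_affine_rescaling():
    # rescaling a raw covariate is absorbed by the scaler: same surface
    land = make_landscape(np.ones((15, 15)), n_classes=2)
    grid = build_grid(land, cell_area=2115.0, class_names=["a", "b"])
    d = grid.to_frame()["distance_to_road"].to_numpy()
    s1 = Scaler(
        means={"distance_to_road": float(d.mean())},
        sds={"distance_to_road": float(d.std(ddof=0))},
    )
    # affine map d -> 3d + 7 applied to both data and scaler
    grid2 = build_grid(land, cell_area=2115.0, class_names=["a", "b"])
    grid2.distance_to_road = 3.0 * grid2.distance_to_road + 7.0
    d2 = 3.0 * d + 7.0
    s2 = Scaler(
        means={"distance_to_road": float(d2.mean())},
        sds={"distance_to_road": float(d2.std(ddof=0))},
    )
    fit = _fit_with(["distance_to_road"], [-0.8])
    a = suitability_surface(fit, s1, grid)
    b = suitability_surface(fit, s2, grid2)
    np.testing.assert_allclose(a.values, b.values, atol=1e-9)


# -- build_use_avail ----------------------------------------------------


def test_build_use_avail_balanced(small_config, small_landscape):
    from fawnsurv.synthetic import generate_telemetry

    tele = generate_telemetry(small_config, small_landscape).head(40)
    table = build_use_avail(tele, small_landscape, seed=0)
    assert len(table) == 2 * len(tele)
    assert table["response"].sum() == len(tele)
    class_cols = [f"class_{k + 1}" for k in range(small_landscape.n_classes)]
    np.testing.assert_allclose(table[class_cols].sum(axis=1), 1.0, atol=1e-9)
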