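"""Use-availability resource selection: mixed logistic fits, screening,
cross-validation and projection onto the analysis grid.

Used telemetry locations (response 1) are paired 1:1 with availability
points (response 0) drawn within the cumulative mean step length; both are
summarized over telemetry-error discs. Candidate covariates are z-scored on
the pooled sample, screened for collinearity (VIF), fitted one at a time
with crossed fawn/year random intercepts, and the individually significant
set is refitted additively. The additive fit is projected per cell as
w = exp(sum beta_k z_k) and linearly stretched onto [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .glmm import MixedLogitFit, fit_mixed_logit
from .grid import (
    DEFAULT_AVAILABILITY_RADIUS,
    DEFAULT_BUFFER_RADIUS,
    Landscape,
    LandscapeGrid,
    extract_buffer,
    linear_stretch,
    sample_availability,
)
from .surfaces import RiskSurface

__all__ = [
    "DEFAULT_CLASS_NAMES",
    "Scaler",
    "RsfFit",
    "build_use_avail",
    "standardize",
    "vif_screen",
    "fit_rsf",
    "select_additive",
    "kfold_error",
    "suitability_surface",
]

DEFAULT_CLASS_NAMES = [
    "lowland_forest",
    "deciduous_forest",
    "coniferous_forest",
    "mixed_forest",
    "grass_shrub",
    "pasture",
    "cropland",
    "wetland",
]
DEFAULT_ALPHA = 0.05
DEFAULT_VIF_THRESHOLD = 7.0


@dataclass
class Scaler:
    """Per-covariate mean/SD learned on the pooled use + availability rows."""

    means: dict[str, float]
    sds: dict[str, float]

    def transform_column(self, name: str, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.means[name]) / self.sds[name]

    def inverse_column(self, name: str, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sds[name] + self.means[name]


@dataclass
class RsfFit:
    """One fitted use-availability model (single-covariate or additive)."""

    covariates: list[str]
    coef: np.ndarray  # z-scale, intercept excluded
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    intercept: float
    re_var: dict[str, float]
    loglik: float
    n_obs: int
    cv_error: float | None = None
    raw: MixedLogitFit | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.covariates,
                "coefficient": self.coef,
                "standard_error": self.se,
                "z_value": self.zvalues,
                "p_value": self.pvalues,
                "prediction_error": self.cv_error,
            }
        )

    def diagnostics(self) -> pd.DataFrame:
        """Standardized-vs-fitted residual table for fit checking."""
        if self.raw is None:
            raise ValueError("fit carries no per-row data")
        return self.raw.diagnostics()


def build_use_avail(
    telemetry: pd.DataFrame,
    landscape: Landscape,
    buffer_radius: float = DEFAULT_BUFFER_RADIUS,
    availability_radius: float = DEFAULT_AVAILABILITY_RADIUS,
    seed: int | np.random.Generator | None = None,
    class_names: list[str] | None = None,
) -> pd.DataFrame:
    """Paired used/available buffered samples for every telemetry row.

    Returns one row per point with ``response`` 1 (used) or 0 (available),
    class-proportion covariates, ``ndvi``, ``distance_to_road`` and
    per-species ``risk_*`` columns. The availability draw is shared across
    all downstream candidate models.
    """
    names = class_names or [f"class_{k + 1}" for k in range(landscape.n_classes)]
    if len(names) != landscape.n_classes:
        raise ValueError("class_names length must equal landscape.n_classes")
    used_xy = telemetry[["x", "y"]].to_numpy(dtype=float)
    avail_xy = sample_availability(
        used_xy, radius=availability_radius, extent=landscape.extent, seed=seed
    )
    rows = []
    for (response, xy), (_, trow) in zip(
        [(1, u) for u in used_xy] + [(0, a) for a in avail_xy],
        list(telemetry.iterrows()) * 2,
    ):
        buf = extract_buffer((xy[0], xy[1]), buffer_radius, landscape)
        row = {
            "fawn_id": trow["fawn_id"],
            "year": trow["year"],
            "response": response,
            "ndvi": buf.mean_ndvi,
            "distance_to_road": buf.distance_to_road,
        }
        row.update({name: p for name, p in zip(names, buf.class_proportions)})
        row.update({f"risk_{sp}": v for sp, v in buf.mean_risk.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def standardize(
    table: pd.DataFrame, covariates: list[str], suffix: str = "_z"
) -> tuple[pd.DataFrame, Scaler]:
    """Z-score each covariate over the pooled rows; keep the scaler.

    Zero-variance covariates are dropped with a warning (they cannot be
    scaled or fitted).
    """
    out = table.copy()
    means, sds = {}, {}
    for name in covariates:
        vals = out[name].to_numpy(dtype=float)
        mu, sd = float(vals.mean()), float(vals.std(ddof=0))
        if sd == 0:
            warnings.warn(f"covariate {name!r} has zero variance; dropped", stacklevel=2)
            continue
        means[name], sds[name] = mu, sd
        out[name + suffix] = (vals - mu) / sd
    return out, Scaler(means=means, sds=sds)


def vif_screen(
    table: pd.DataFrame, covariates: list[str], threshold: float = DEFAULT_VIF_THRESHOLD
) -> pd.DataFrame:
    """Variance inflation factors: VIF_k = 1 / (1 - R^2_k).

    Perfectly collinear covariates get VIF = inf and are flagged, not fatal.
    """
    if len(covariates) < 2:
        raise ValueError("vif_screen needs at least two covariates")
    Z = table[covariates].to_numpy(dtype=float)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=0)
    n, p = Z.shape
    vifs = []
    for k in range(p):
        yk = Z[:, k]
        Xk = np.column_stack([np.ones(n), np.delete(Z, k, axis=1)])
        coef, *_ = np.linalg.lstsq(Xk, yk, rcond=None)
        resid = yk - Xk @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(yk @ yk)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        vifs.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    return pd.DataFrame(
        {"covariate": covariates, "vif": vifs, "flagged": [v >= threshold for v in vifs]}
    )


def fit_rsf(
    table: pd.DataFrame,
    covariates: list[str],
    random_effects: tuple[str, ...] = ("fawn_id", "year"),
    re_sd_fixed: dict[str, float] | None = None,
    z_suffix: str = "_z",
) -> RsfFit:
    """Mixed-effects logistic use-availability fit on z-scored covariates.

    ``covariates`` name raw columns; the fit uses their ``_z`` versions (add
    them with :func:`standardize` first). ``re_sd_fixed`` pins the random
    intercept SDs (zeros reduce to plain logistic regression).
    """
    zcols = [c + z_suffix if c + z_suffix in table.columns else c for c in covariates]
    y = table["response"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in zcols])
    groups = {g: table[g].to_numpy() for g in random_effects}
    fixed = None
    if re_sd_fixed is not None:
        fixed = {g: float(re_sd_fixed.get(g, 0.0)) for g in random_effects}
    mfit = fit_mixed_logit(y, X, ["(intercept)"] + list(covariates), groups, re_sd_fixed=fixed)
    return RsfFit(
        covariates=list(covariates),
        coef=mfit.coef[1:],
        se=mfit.se[1:],
        zvalues=mfit.zvalues[1:],
        pvalues=mfit.pvalues[1:],
        intercept=float(mfit.coef[0]),
        re_var=mfit.re_var,
        loglik=mfit.loglik,
        n_obs=mfit.n_obs,
        raw=mfit,
    )


def select_additive(
    table: pd.DataFrame,
    single_fits: dict[str, RsfFit],
    alpha: float = DEFAULT_ALPHA,
    random_effects: tuple[str, ...] = ("fawn_id", "year"),
) -> tuple[list[str], RsfFit]:
    """Retain covariates individually significant at ``alpha`` (strict <) and
    fit the additive model on them."""
    retained = [
        name for name, f in single_fits.items() if float(f.pvalues[0]) < alpha
    ]
    if not retained:
        raise ValueError(
            f"no covariate significant at alpha={alpha}; relax alpha or revisit candidates"
        )
    additive = fit_rsf(table, retained, random_effects=random_effects)
    return retained, additive


def kfold_error(
    table: pd.DataFrame,
    covariates: list[str],
    k: int = 5,
    seed: int | None = None,
    by_fawn: bool = False,
    z_suffix: str = "_z",
) -> float:
    """k-fold cross-validated squared prediction error (Brier score).

    Folds are trained with plain logistic regression; error is the mean over
    held-out rows of (response - predicted probability)^2. ``by_fawn`` blocks
    folds by fawn instead of partitioning rows at random.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    zcols = [c + z_suffix if c + z_suffix in table.columns else c for c in covariates]
    y = table["response"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in zcols])
    if by_fawn:
        fawns = table["fawn_id"].to_numpy()
        uniq = np.unique(fawns)
        fold_of_fawn = dict(zip(uniq, rng.permuted(np.arange(len(uniq)) % k)))
        folds = np.array([fold_of_fawn[f] for f in fawns])
    else:
        folds = rng.permuted(np.arange(len(table)) % k)
    sq_errs = np.empty(len(table))
    for j in range(k):
        test = folds == j
        res = sm.GLM(y[~test], X[~test], family=sm.families.Binomial()).fit()
        p_hat = res.predict(X[test])
        sq_errs[test] = (y[test] - p_hat) ** 2
    return float(sq_errs.mean())


def suitability_surface(
    fit: RsfFit,
    scaler: Scaler,
    grid: LandscapeGrid,
    form: str = "exponential",
) -> RiskSurface:
    """Project the additive fit onto the grid and stretch to [0, 1].

    Per cell w = exp(sum beta_k z_k) on scaler-standardized cell covariates
    (intercept and random effects excluded); ``form="logistic"`` uses the
    inverse-logit instead. Both are rank-equivalent after the stretch.
    """
    frame = grid.to_frame()
    eta = np.zeros(len(frame))
    for name, beta in zip(fit.covariates, fit.coef):
        if name not in frame.columns:
            raise KeyError(f"grid lacks covariate {name!r}")
        eta += beta * scaler.transform_column(name, frame[name].to_numpy())
    if form == "exponential":
        w = np.exp(eta)
    elif form == "logistic":
        w = 1.0 / (1.0 + np.exp(-eta))
    else:
        raise ValueError(f"unknown RSF form {form!r}")
    values = linear_stretch(w).reshape(grid.nrows, grid.ncols)
    return RiskSurface(grid=grid, values=values, kind="suitability", provenance=f"rsf:{form}")
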