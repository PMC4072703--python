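"""The ranked Cox mixed-effects candidate set for neonatal survival.

Twelve candidate models combine resource use, composite predation risk,
birth mass, winter severity and vegetation growth (with the two interaction
structures); all carry fawn and year random intercepts. Models are ranked
by integrated deviance explained — the model-vs-null log-likelihood
difference, which equals half the likelihood-ratio chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .frailty import FrailtyCoxFit, breslow_baseline, fit_frailty_cox
from .synthetic import SEASON_END_DAY

__all__ = [
    "CoxFit",
    "MODEL_SET",
    "hazard_ratio",
    "deviance_from_chisq",
    "build_records",
    "fit_cox",
    "deviance_explained",
    "run_model_set",
]

# covariate aliases: model-term name -> fawn-covariate column
TERM_COLUMNS = {
    "resource_use": "mean_suitability",
    "predation_risk": "mean_composite_risk",
    "birth_mass": "birth_mass",
    "winter_severity": "winter_severity",
    "vegetation_growth": "mean_vegetation_growth",
}

# the 12 candidate models: name -> fixed-effect terms (":" marks interactions)
MODEL_SET: dict[str, list[str]] = {
    "Non-ideal resource use + Maternal effects": [
        "resource_use",
        "predation_risk",
        "birth_mass",
        "winter_severity",
        "birth_mass:winter_severity",
    ],
    "Maternal effects": ["birth_mass", "winter_severity", "birth_mass:winter_severity"],
    "Ecological trap + Maternal effects": [
        "resource_use",
        "predation_risk",
        "resource_use:predation_risk",
        "birth_mass",
        "winter_severity",
        "birth_mass:winter_severity",
    ],
    "Body mass": ["birth_mass"],
    "Ecological trap + Hiding cover": [
        "resource_use",
        "predation_risk",
        "resource_use:predation_risk",
        "vegetation_growth",
    ],
    "Ecological trap": ["resource_use", "predation_risk", "resource_use:predation_risk"],
    "Non-ideal resource use + Hiding cover": [
        "resource_use",
        "predation_risk",
        "vegetation_growth",
    ],
    "Resource use": ["resource_use"],
    "Non-ideal resource use": ["resource_use", "predation_risk"],
    "Predation risk": ["predation_risk"],
    "Winter severity index": ["winter_severity"],
    "Hiding cover": ["vegetation_growth"],
}


def hazard_ratio(coef: float | np.ndarray) -> float | np.ndarray:
    """exp(coefficient): multiplicative change in the hazard per unit."""
    return np.exp(coef)


def deviance_from_chisq(lr_chisq: float) -> float:
    """Integrated deviance explained from the LR chi-square: DE = chi2 / 2."""
    return lr_chisq / 2.0


@dataclass
class CoxFit:
    """One fitted survival model plus its comparison against the null."""

    name: str
    term_names: list[str]
    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    loglik: float
    re_var: dict[str, float]
    n_obs: int
    n_events: int
    baseline_survival: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    loglik_null: float | None = None
    raw: FrailtyCoxFit | None = field(default=None, repr=False)

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def lr_chisq(self) -> float | None:
        if self.loglik_null is None:
            return None
        return 2.0 * (self.loglik - self.loglik_null)

    @property
    def deviance_explained(self) -> float | None:
        if self.loglik_null is None:
            return None
        return self.loglik - self.loglik_null

    @property
    def lr_pvalue(self) -> float | None:
        chisq = self.lr_chisq
        if chisq is None:
            return None
        return float(stats.chi2.sf(max(chisq, 0.0), df=max(len(self.term_names), 1)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.name,
                "term": self.term_names,
                "estimate": self.coef,
                "se": self.se,
                "p_value": self.pvalues,
                "hazard_ratio": self.hazard_ratios,
            }
        )


def build_records(fawn_covariates: pd.DataFrame, fates: pd.DataFrame) -> pd.DataFrame:
    """Merge the covariate table with fates into survival records.

    Start time is birth (0); stop is days to death, censoring, or season end.
    """
    fates = fates[["fawn_id", "stop_day", "event"]]
    records = fawn_covariates.merge(fates, on="fawn_id", how="inner")
    if (records["stop_day"] <= 0).any():
        raise ValueError("stop_day must be positive (stop > start = 0)")
    return records


def _term_design(records: pd.DataFrame, terms: list[str], z_suffix: str = "_z"):
    """Design matrix for model terms; interactions are products of z-columns."""

    def col(term: str) -> np.ndarray:
        base = TERM_COLUMNS.get(term, term)
        for cand in (base + z_suffix, base, term + z_suffix, term):
            if cand in records.columns:
                return records[cand].to_numpy(dtype=float)
        raise KeyError(f"records lack covariate for term {term!r}")

    cols = []
    for term in terms:
        if ":" in term:
            a, b = term.split(":", 1)
            cols.append(col(a) * col(b))
        else:
            cols.append(col(term))
    return np.column_stack(cols) if cols else np.empty((len(records), 0))


def fit_cox(
    records: pd.DataFrame,
    terms: list[str],
    name: str | None = None,
    random_effects: tuple[str, ...] = ("fawn_id", "year"),
    re_sd_fixed: dict[str, float] | None = None,
    season_end: float = SEASON_END_DAY,
) -> CoxFit:
    """Fit one candidate model with Gaussian log-frailties.

    Records need ``stop_day``, ``event`` and z-scored covariate columns.
    Efron tie-handling; Breslow per-year baselines (the pooled baseline
    modulated by each year's fitted frailty).
    """
    time = records["stop_day"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    if event.sum() < 2 and terms:
        raise ValueError("need at least two events to fit a Cox model")
    X = _term_design(records, terms)
    groups = {g: records[g].to_numpy() for g in random_effects}
    fixed = None
    if re_sd_fixed is not None:
        fixed = {g: float(re_sd_fixed.get(g, 0.0)) for g in random_effects}
    fit = fit_frailty_cox(time, event, X, terms, groups, re_sd_fixed=fixed)

    # per-year baselines: pooled Breslow baseline on the full linear
    # predictor, with the year frailty mode acting as a year-specific
    # proportional shift
    eta = X @ fit.coef
    for g in random_effects:
        codes, uniq = pd.factorize(records[g].to_numpy())
        order = {val: i for i, val in enumerate(fit.re_levels[g])}
        eta = eta + fit.re_modes[g][[order[v] for v in uniq]][codes]
    times, s0 = breslow_baseline(time, event, eta)
    if times.max() < season_end:
        times = np.append(times, season_end)
        s0 = np.append(s0, s0[-1])
    baselines: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    if "year" in random_effects:
        order = {val: i for i, val in enumerate(fit.re_levels["year"])}
        for year in sorted(order):
            b_year = fit.re_modes["year"][order[year]]
            baselines[int(year)] = (times, s0 ** np.exp(b_year))
    else:
        baselines[0] = (times, s0)

    return CoxFit(
        name=name or "+".join(terms) or "(null)",
        term_names=list(terms),
        coef=fit.coef,
        se=fit.se,
        pvalues=fit.pvalues,
        loglik=fit.loglik,
        re_var=fit.re_var,
        n_obs=fit.n_obs,
        n_events=fit.n_events,
        baseline_survival=baselines,
        raw=fit,
    )


def deviance_explained(fit: CoxFit, null_fit: CoxFit) -> float:
    """DE = LL_model - LL_null (= lr_chisq / 2); both fits on the same records."""
    if fit.n_obs != null_fit.n_obs:
        raise ValueError("fits compare different record sets")
    return fit.loglik - null_fit.loglik


def run_model_set(
    records: pd.DataFrame,
    random_effects: tuple[str, ...] = ("fawn_id", "year"),
    model_set: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, CoxFit]]:
    """Fit and rank the candidate set; returns (report, fits).

    The null (random-effects-only) model is the likelihood reference but is
    excluded from the ranking. Models whose covariates are missing are
    skipped with a warning. The report mirrors the published table shape:
    one header row per model (ranked by deviance explained) followed by its
    term rows.
    """
    model_set = model_set or MODEL_SET
    null_fit = fit_cox(records, [], name="(null)", random_effects=random_effects)
    fits: dict[str, CoxFit] = {}
    for name, terms in model_set.items():
        try:
            fit = fit_cox(records, terms, name=name, random_effects=random_effects)
        except KeyError as err:
            warnings.warn(f"skipping model {name!r}: {err}", stacklevel=2)
            continue
        fit.loglik_null = null_fit.loglik
        fits[name] = fit

    ranked = sorted(fits.values(), key=lambda f: f.deviance_explained, reverse=True)
    rows = []
    for fit in ranked:
        rows.append(
            {
                "model": fit.name,
                "term": "",
                "estimate": np.nan,
                "se": np.nan,
                "p_value": np.nan,
                "df": fit.n_obs - len(fit.term_names),
                "hazard_ratio": np.nan,
                "deviance_explained": fit.deviance_explained,
                "lr_chisq": fit.lr_chisq,
                "chisq_p_value": fit.lr_pvalue,
            }
        )
        for i, term in enumerate(fit.term_names):
            rows.append(
                {
                    "model": fit.name,
                    "term": term,
                    "estimate": fit.coef[i],
                    "se": fit.se[i],
                    "p_value": fit.pvalues[i],
                    "df": np.nan,
                    "hazard_ratio": fit.hazard_ratios[i],
                    "deviance_explained": np.nan,
                    "lr_chisq": np.nan,
                    "chisq_p_value": np.nan,
                }
            )
    report = pd.DataFrame(rows)
    fits["(null)"] = null_fit
    return report, fits
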