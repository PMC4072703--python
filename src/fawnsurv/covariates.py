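"""Survival covariates: composite predation risk, winter severity index,
vegetation growth and back-calculated birth mass."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grid import DEFAULT_BUFFER_RADIUS, Landscape, extract_buffer, linear_stretch
from .rsf import Scaler
from .surfaces import RiskSurface
from .synthetic import PREDATOR_SPECIES

__all__ = [
    "composite_risk",
    "composite_risk_grid",
    "composite_risk_surface",
    "winter_severity",
    "birth_mass",
    "fawn_covariates",
    "DAILY_MASS_GAIN",
]

DAILY_MASS_GAIN = 0.2  # kg/day for northern newborn white-tailed fawns
SEVERITY_WINDOW_DAYS = 90  # 1 Jan .. 31 Mar


def composite_risk(mean_risk: dict[str, float], species: tuple[str, ...] = PREDATOR_SPECIES) -> float:
    """Sum of per-species buffer-mean predation risk.

    All four species layers must be present; each mean is in [0, 1], so the
    composite lies in [0, len(species)].
    """
    missing = [sp for sp in species if sp not in mean_risk]
    if missing:
        raise KeyError(f"missing predator risk layer(s): {missing}")
    return float(sum(mean_risk[sp] for sp in species))


def composite_risk_grid(grid, species: tuple[str, ...] = PREDATOR_SPECIES) -> np.ndarray:
    """Raw per-cell composite risk: the sum of the species surfaces.

    Bounded in [0, len(species)] since each layer lies in [0, 1].
    """
    missing = [sp for sp in species if sp not in grid.risk]
    if missing:
        raise KeyError(f"missing predator risk layer(s): {missing}")
    return np.sum(np.stack([grid.risk[sp] for sp in species]), axis=0)


def composite_risk_surface(grid, species: tuple[str, ...] = PREDATOR_SPECIES) -> RiskSurface:
    """Composite risk stretched onto [0, 1] for the three-panel output."""
    total = composite_risk_grid(grid, species)
    return RiskSurface(
        grid=grid, values=linear_stretch(total), kind="composite_risk", provenance="species sum"
    )


def winter_severity(
    weather: pd.DataFrame,
    literal: bool = False,
    expected_days: int | None = SEVERITY_WINDOW_DAYS,
) -> float:
    """Season-summed daily severity over the 1 Jan - 31 Mar window.

    Daily value d = (snow + wind + rain) - tmin, summed over the window;
    larger values mean a more severe winter. ``literal=True`` flips the sign
    convention to tmin - (snow + wind + rain). Missing days (fewer rows than
    ``expected_days``) raise unless ``expected_days`` is None.
    """
    required = {"snow_cm", "wind_kph", "rain_cm", "tmin_c"}
    missing = required - set(weather.columns)
    if missing:
        raise KeyError(f"weather table lacks columns: {sorted(missing)}")
    if expected_days is not None and len(weather) != expected_days:
        raise ValueError(
            f"severity window expects {expected_days} daily rows, got {len(weather)}; "
            "pass expected_days=None to tolerate gaps"
        )
    total = (weather["snow_cm"] + weather["wind_kph"] + weather["rain_cm"]).to_numpy(dtype=float)
    tmin = weather["tmin_c"].to_numpy(dtype=float)
    daily = tmin - total if literal else total - tmin
    return float(daily.sum())


def birth_mass(
    capture_mass,
    age_at_capture,
    daily_gain: float = DAILY_MASS_GAIN,
    mode: str = "per_day",
):
    """Back-calculate birth mass from capture mass.

    Default subtracts ``daily_gain`` per day of age; ``mode="literal"``
    subtracts it once regardless of age. Non-positive results are floored at
    0.1 kg with a warning.
    """
    capture_mass = np.asarray(capture_mass, dtype=float)
    age = np.asarray(age_at_capture, dtype=float)
    if np.any(capture_mass <= 0):
        raise ValueError("capture_mass must be positive")
    if np.any((age < 0) | (age > 15)):
        raise ValueError("age_at_capture must be within [0, 15] days")
    if mode == "per_day":
        mass = capture_mass - daily_gain * age
    elif mode == "literal":
        mass = capture_mass - daily_gain
    else:
        raise ValueError(f"unknown birth-mass mode {mode!r}")
    bad = mass <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(np.sum(bad))} back-calculated birth mass(es) <= 0; floored at 0.1 kg",
            stacklevel=2,
        )
        mass = np.where(bad, 0.1, mass)
    return mass if mass.ndim else float(mass)


def fawn_covariates(
    telemetry: pd.DataFrame,
    landscape: Landscape,
    suitability: RiskSurface,
    metadata: pd.DataFrame,
    weather: pd.DataFrame | None = None,
    buffer_radius: float = DEFAULT_BUFFER_RADIUS,
    birth_mass_mode: str = "per_day",
    severity_literal: bool = False,
    z_suffix: str = "_z",
) -> tuple[pd.DataFrame, "Scaler"]:
    """One covariate row per fawn for the survival models.

    Per-fawn means over retained locations of buffer-level suitability,
    composite predation risk and vegetation growth; year-level winter
    severity; birth mass back-calculated from capture mass. Each model
    covariate also gets a pooled z-scored ``_z`` column; the returned
    :class:`~fawnsurv.rsf.Scaler` carries the fawn-level means/SDs so the
    same standardization can be pushed onto grid cells. Fawns with zero
    retained locations are excluded with a warning.
    """
    suit_raster = suitability.to_raster()
    rows = []
    for fawn_id, locs in telemetry.groupby("fawn_id"):
        samples = [
            extract_buffer((r.x, r.y), buffer_radius, landscape) for r in locs.itertuples()
        ]
        comp = [composite_risk(s.mean_risk) for s in samples]
        suit = suit_raster.value_at(locs["x"].to_numpy(), locs["y"].to_numpy())
        rows.append(
            {
                "fawn_id": fawn_id,
                "year": int(locs["year"].iloc[0]),
                "mean_suitability": float(np.mean(suit)),
                "mean_composite_risk": float(np.mean(comp)),
                "mean_vegetation_growth": float(np.mean([s.mean_ndvi for s in samples])),
                "n_locations": len(locs),
            }
        )
    table = pd.DataFrame(rows)

    meta = metadata.set_index("fawn_id")
    dropped = set(meta.index) - set(table["fawn_id"])
    if dropped:
        warnings.warn(
            f"{len(dropped)} fawn(s) with zero retained locations excluded", stacklevel=2
        )
    table["birth_mass"] = birth_mass(
        meta.loc[table["fawn_id"], "capture_mass"].to_numpy(),
        meta.loc[table["fawn_id"], "age_at_capture"].to_numpy(),
        mode=birth_mass_mode,
    )

    if weather is not None:
        severity = {
            int(year): winter_severity(wy, literal=severity_literal, expected_days=None)
            for year, wy in weather.groupby("year")
        }
        table["winter_severity"] = table["year"].map(severity)

    model_covs = [
        c
        for c in (
            "mean_suitability",
            "mean_composite_risk",
            "birth_mass",
            "winter_severity",
            "mean_vegetation_growth",
        )
        if c in table.columns
    ]
    means, sds = {}, {}
    for c in model_covs:
        vals = table[c].to_numpy(dtype=float)
        mu, sd = float(vals.mean()), float(vals.std(ddof=0))
        if sd == 0:
            warnings.warn(f"covariate {c!r} has zero variance across fawns", stacklevel=2)
            table[c + z_suffix] = 0.0
            means[c], sds[c] = mu, 1.0
        else:
            table[c + z_suffix] = (vals - mu) / sd
            means[c], sds[c] = mu, sd
    return table, Scaler(means=means, sds=sds)
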