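"""Risk surfaces: per-cell values in [0, 1] on the analysis grid.

Holds the shared :class:`RiskSurface` container, the spatial extrapolation of
a fitted survival model to an end-of-season mortality surface, and the
three-panel bundling of suitability, composite risk and mortality.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import LandscapeGrid, linear_stretch
from .io import Raster, write_ascii_grid

__all__ = ["RiskSurface", "mortality_surface", "surface_panel"]


@dataclass
class RiskSurface:
    """A stretched per-cell surface co-registered with a LandscapeGrid."""

    grid: LandscapeGrid
    values: np.ndarray  # (nrows, ncols), in [0, 1]
    kind: str  # suitability | composite_risk | mortality
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError("surface shape does not match grid")

    def to_raster(self) -> Raster:
        return Raster(
            self.values,
            xll=self.grid.xll,
            yll=self.grid.yll,
            cellsize=self.grid.cell_side,
        )

    def write(self, path: str | Path) -> None:
        write_ascii_grid(self.to_raster(), path)


def _grid_linear_predictor(cox_fit, cell_z: dict[str, np.ndarray], grid: LandscapeGrid) -> np.ndarray:
    """beta . z(x) per cell for the covariates of a fitted survival model.

    ``cell_z`` maps each model term to its z-scored per-cell array
    (interactions are formed as products of their parts).
    """
    eta = np.zeros((grid.nrows, grid.ncols))

    def part(name: str) -> np.ndarray:
        if name not in cell_z:
            raise KeyError(f"grid lacks covariate {name!r} required by the survival model")
        arr = np.asarray(cell_z[name], dtype=float)
        if arr.shape != eta.shape:
            raise ValueError(f"cell covariate {name!r} shape {arr.shape} != grid shape")
        return arr

    for name, beta in zip(cox_fit.term_names, cox_fit.coef):
        if ":" in name and name not in cell_z:
            a, b = name.split(":", 1)
            eta += beta * part(a) * part(b)
        else:
            eta += beta * part(name)
    return eta


def mortality_surface(
    cox_fit,
    cell_z: dict[str, np.ndarray],
    grid: LandscapeGrid,
    horizon: float,
    per_year: bool = False,
) -> RiskSurface | dict[int, RiskSurface]:
    """Extrapolate a fitted survival model to a per-cell mortality surface.

    Per cell, S(te | x) = S0_j(te) ** exp(beta . x) with the year-j Breslow
    baseline; year surfaces are averaged with equal weight unless
    ``per_year``. The mapped value is linear_stretch(1 - S): cells nearer 1
    carry relatively greater mortality likelihood.
    """
    baselines = cox_fit.baseline_survival  # {year: (times, S0)}
    if not baselines:
        raise ValueError("survival fit carries no baseline curves")
    eta = _grid_linear_predictor(cox_fit, cell_z, grid)
    hr = np.exp(eta)
    per_year_S = {}
    for year, (times, s0) in baselines.items():
        if horizon > times.max() + 1e-9:
            raise ValueError(
                f"horizon {horizon} beyond observed follow-up ({times.max()}) for year {year}"
            )
        s0_te = float(np.interp(horizon, times, s0))
        per_year_S[year] = s0_te**hr
    if per_year:
        return {
            yr: RiskSurface(grid, linear_stretch(1.0 - S), "mortality", f"{cox_fit.name}:{yr}")
            for yr, S in per_year_S.items()
        }
    S_mean = np.mean(np.stack(list(per_year_S.values())), axis=0)
    years = ",".join(str(y) for y in per_year_S)
    return RiskSurface(grid, linear_stretch(1.0 - S_mean), "mortality", f"{cox_fit.name}:{years}")


def surface_panel(
    suitability: RiskSurface,
    composite_risk: RiskSurface,
    mortality: RiskSurface,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Bundle the three co-registered surfaces into one per-cell table.

    Optionally writes each surface as an ASCII grid plus the combined CSV.
    """
    ref = suitability.grid
    for s in (composite_risk, mortality):
        if (
            s.values.shape != suitability.values.shape
            or not np.isclose(s.grid.xll, ref.xll)
            or not np.isclose(s.grid.yll, ref.yll)
        ):
            raise ValueError("surfaces are not co-registered")
    frame = ref.to_frame()[["row", "col", "x", "y"]].copy()
    frame["suitability"] = suitability.values.ravel()
    frame["composite_risk"] = composite_risk.values.ravel()
    frame["mortality"] = mortality.values.ravel()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        suitability.write(out_dir / "suitability.asc")
        composite_risk.write(out_dir / "composite_risk.asc")
        mortality.write(out_dir / "mortality.asc")
        frame.to_csv(out_dir / "surface_panel.csv", index=False)
    return frame
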