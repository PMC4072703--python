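"""Synthetic landscapes, telemetry, weather and fates for pipeline testing.

Every generator is a pure function of a :class:`SimConfig`; a fixed seed
fixes all outputs bit-for-bit. The generators are deliberately simple —
clustered categorical patches, gamma step lengths, exponential event times
under a proportional-hazards model with Gaussian log-frailties — but carry
the statistical structure the downstream fitters assume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString

from .grid import Landscape, linear_stretch
from .io import Raster

__all__ = [
    "SimConfig",
    "generate_landscape",
    "generate_telemetry",
    "generate_weather",
    "generate_fates",
    "PREDATOR_SPECIES",
    "SEASON_END_DAY",
]

PREDATOR_SPECIES = ("coyote", "bobcat", "bear", "wolf")
SEASON_END_DAY = 109  # 14 May .. 31 Aug
CAUSE_PROBS = {"coyote": 0.47, "bobcat": 0.23, "bear": 0.08, "wolf": 0.08, "unknown": 0.14}

_DEFAULT_WEATHER = {
    "snow_cm": (12.0, 8.0),
    "wind_kph": (10.0, 4.0),
    "rain_cm": (0.3, 0.4),
    "tmin_c": (-8.0, 6.0),
}


@dataclass
class SimConfig:
    """Knobs for every synthetic generator.

    ``true_rsf_betas`` / ``true_cox_betas`` map covariate names to the
    coefficients the generators embed, so recovery can be tested downstream.
    """

    seed: int = 0
    extent: tuple[float, float] = (3000.0, 3000.0)
    n_classes: int = 8
    class_targets: tuple[float, ...] | None = None
    road_density: float = 1.68  # km / km^2
    n_fawns: int = 50
    n_years: int = 3
    mean_step: float = 415.0
    step_shape: float = 2.0
    mean_ellipse_area: float = 2115.0
    ellipse_shape: float = 4.0
    locs_per_fawn: tuple[int, int] = (2, 56)
    true_rsf_betas: dict[str, float] = field(default_factory=dict)
    true_cox_betas: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.01  # deaths / day at x = 0
    frailty_sd_fawn: float = 0.3
    frailty_sd_year: float = 0.2
    weather_params: dict | None = None
    patch_sigma: float = 4.0  # landcover cells; controls patch size
    landcover_cellsize: float = 30.0
    ndvi_cellsize: float = 250.0

    def __post_init__(self) -> None:
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValueError("extent must be positive")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if min(self.frailty_sd_fawn, self.frailty_sd_year) < 0:
            raise ValueError("frailty SDs must be non-negative")
        if self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be non-negative")
        if self.class_targets is not None:
            if len(self.class_targets) != self.n_classes:
                raise ValueError("class_targets length must equal n_classes")
            if abs(sum(self.class_targets) - 1) > 1e-6:
                raise ValueError("class_targets must sum to 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named sub-stream of the seed."""
        return np.random.default_rng([self.seed, stream])


# seeds for independent sub-streams
_S_LANDCOVER, _S_ROADS, _S_PREDATORS, _S_NDVI, _S_TELEMETRY, _S_WEATHER, _S_FATES = range(7)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    return (f - f.mean()) / (f.std() + 1e-12)


def _calibrated_argmax(
    fields: np.ndarray, targets: np.ndarray, n_iter: int = 200, lr: float = 4.0
) -> np.ndarray:
    """Argmax-classify K fields with per-class offsets tuned to hit target shares."""
    K = fields.shape[0]
    offsets = np.zeros(K)
    n = fields[0].size
    codes = None
    for _ in range(n_iter):
        codes = np.argmax(fields + offsets[:, None, None], axis=0)
        realized = np.bincount(codes.ravel(), minlength=K) / n
        err = targets - realized
        if np.abs(err).max() < 0.002:
            break
        offsets += lr * err
    return codes + 1  # class codes 1..K


def generate_landscape(config: SimConfig) -> Landscape:
    """Clustered categorical landcover, a road network, smooth predator and
    NDVI surfaces — all seeded from ``config.seed``."""
    w, h = config.extent
    cs = config.landcover_cellsize
    # ceil so every raster covers the full declared study window
    ncols, nrows = max(int(np.ceil(w / cs)), 1), max(int(np.ceil(h / cs)), 1)
    K = config.n_classes

    rng = config.rng(_S_LANDCOVER)
    if K == 1:
        codes = np.ones((nrows, ncols), dtype=int)
    else:
        fields = np.stack([_smooth_field(rng, (nrows, ncols), config.patch_sigma) for _ in range(K)])
        targets = np.asarray(config.class_targets if config.class_targets else [1.0 / K] * K)
        codes = _calibrated_argmax(fields, targets)
    landcover = Raster(codes.astype(float), xll=0.0, yll=0.0, cellsize=cs)

    roads = _generate_roads(config)

    prng = config.rng(_S_PREDATORS)
    predators = {}
    for sp in PREDATOR_SPECIES:
        f = _smooth_field(prng, (nrows, ncols), config.patch_sigma * 1.5)
        predators[sp] = Raster(linear_stretch(f), xll=0.0, yll=0.0, cellsize=cs)

    nrng = config.rng(_S_NDVI)
    ncs = config.ndvi_cellsize
    n_nc = max(int(np.ceil(ncols * cs / ncs)), 1)
    n_nr = max(int(np.ceil(nrows * cs / ncs)), 1)
    ndvi = Raster(
        np.clip(_smooth_field(nrng, (n_nr, n_nc), 1.5) * 0.3 + 0.4, -1, 1),
        xll=0.0,
        yll=0.0,
        cellsize=ncs,
    )

    return Landscape(
        landcover=landcover,
        roads=roads,
        predators=predators,
        ndvi=ndvi,
        n_classes=K,
        study_extent=(0.0, 0.0, float(w), float(h)),
    )


def _generate_roads(config: SimConfig) -> list[LineString]:
    """Wandering polylines until the target total length is reached."""
    w, h = config.extent
    target_m = config.road_density * (w * h / 1e6) * 1000.0
    rng = config.rng(_S_ROADS)
    roads: list[LineString] = []
    total = 0.0
    seg = 200.0
    while total < target_m:
        x, y = rng.uniform(0, w), rng.uniform(0, h)
        heading = rng.uniform(0, 2 * np.pi)
        pts = [(x, y)]
        for _ in range(rng.integers(5, 40)):
            heading += rng.normal(0, 0.25)
            x += seg * np.cos(heading)
            y += seg * np.sin(heading)
            if not (0 <= x <= w and 0 <= y <= h):
                break
            pts.append((x, y))
        if len(pts) >= 2:
            line = LineString(pts)
            roads.append(line)
            total += line.length
    if not roads:  # degenerate tiny extent: guarantee one road
        roads = [LineString([(0, h / 2), (w, h / 2)])]
    return roads


def _point_covariate(name: str, x: np.ndarray, y: np.ndarray, landscape: Landscape) -> np.ndarray:
    """Point-level covariate values used to weight habitat selection."""
    if name.startswith("class_"):
        code = int(name.split("_", 1)[1])
        return (landscape.landcover.value_at(x, y).astype(int) == code).astype(float)
    if name == "distance_to_road":
        from .grid import distance_to_roads

        return np.asarray(distance_to_roads(x, y, landscape.roads_union()), dtype=float)
    if name == "ndvi":
        return np.asarray(landscape.ndvi.value_at(x, y), dtype=float)
    raise KeyError(f"unknown telemetry selection covariate {name!r}")


def generate_telemetry(
    config: SimConfig, landscape: Landscape, n_candidates: int = 15
) -> pd.DataFrame:
    """Per-fawn location sequences with gamma step lengths and error ellipses.

    Returns columns: fawn_id, year, day (days since birth), x, y,
    ellipse_area. Location counts are uniform over ``config.locs_per_fawn``.
    When ``config.true_rsf_betas`` is non-empty, each step is chosen among
    ``n_candidates`` endpoints with probability proportional to
    exp(sum beta_k v_k(endpoint)), embedding habitat selection that a
    use-availability fit can recover (keys: ``class_<code>``,
    ``distance_to_road``, ``ndvi``).
    """
    if config.n_fawns == 0:
        warnings.warn("n_fawns=0: returning an empty telemetry table", stacklevel=2)
        return pd.DataFrame(columns=["fawn_id", "year", "day", "x", "y", "ellipse_area"])
    rng = config.rng(_S_TELEMETRY)
    xmin, ymin = 0.0, 0.0
    xmax, ymax = config.extent
    lo, hi = config.locs_per_fawn
    betas = config.true_rsf_betas
    rows = []
    for fawn in range(config.n_fawns):
        year = int(rng.integers(config.n_years))
        n_locs = int(rng.integers(lo, hi + 1))
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        day = 0
        for i in range(n_locs):
            if i > 0:
                m = n_candidates if betas else 1
                step = rng.gamma(config.step_shape, config.mean_step / config.step_shape, m)
                theta = rng.uniform(0, 2 * np.pi, m)
                cx = np.clip(x + step * np.cos(theta), xmin, xmax)
                cy = np.clip(y + step * np.sin(theta), ymin, ymax)
                if betas:
                    score = np.zeros(m)
                    for name, beta in betas.items():
                        score += beta * _point_covariate(name, cx, cy, landscape)
                    w = np.exp(score - score.max())
                    pick = rng.choice(m, p=w / w.sum())
                else:
                    pick = 0
                x, y = float(cx[pick]), float(cy[pick])
                day += int(rng.integers(1, 4))
            area = rng.gamma(config.ellipse_shape, config.mean_ellipse_area / config.ellipse_shape)
            rows.append((fawn, year, day, x, y, area))
    return pd.DataFrame(rows, columns=["fawn_id", "year", "day", "x", "y", "ellipse_area"])


def generate_weather(config: SimConfig) -> pd.DataFrame:
    """Daily winter weather (1 Jan – 31 Mar) per year.

    Columns: year, date (day-of-year 1..90), snow_cm, wind_kph, rain_cm,
    tmin_c. Non-negative variables are clipped at zero.
    """
    rng = config.rng(_S_WEATHER)
    params = config.weather_params or {}
    rows = []
    n_days = 90
    for year in range(config.n_years):
        yp = {**_DEFAULT_WEATHER, **params.get(year, {})}
        snow = np.clip(rng.normal(*yp["snow_cm"], n_days), 0, None)
        wind = np.clip(rng.normal(*yp["wind_kph"], n_days), 0, None)
        rain = np.clip(rng.normal(*yp["rain_cm"], n_days), 0, None)
        tmin = rng.normal(*yp["tmin_c"], n_days)
        for d in range(n_days):
            rows.append((year, d + 1, snow[d], wind[d], rain[d], tmin[d]))
    return pd.DataFrame(rows, columns=["year", "date", "snow_cm", "wind_kph", "rain_cm", "tmin_c"])


def generate_fates(
    config: SimConfig,
    per_fawn_covariates: pd.DataFrame,
    season_end: int = SEASON_END_DAY,
) -> pd.DataFrame:
    """Draw death/censoring times from h(t) = h0 * exp(X beta + b_fawn + b_year).

    ``per_fawn_covariates`` needs one row per fawn with a ``year`` column and
    every covariate named in ``config.true_cox_betas``. The baseline hazard is
    constant (exponential event times); administrative censoring at
    ``season_end`` days. Returns a fawn table with birth metadata, stop_day,
    event (1=death, 0=censored) and a cause label.
    """
    rng = config.rng(_S_FATES)
    df = per_fawn_covariates.reset_index(drop=True)
    missing = [c for c in config.true_cox_betas if c not in df.columns]
    if missing:
        raise KeyError(f"per_fawn_covariates lacks columns: {missing}")
    n = len(df)
    eta = np.zeros(n)
    for name, beta in config.true_cox_betas.items():
        eta += beta * df[name].to_numpy(dtype=float)
    b_fawn = rng.normal(0, config.frailty_sd_fawn, n)
    years = (
        df["year"].to_numpy(dtype=int) if "year" in df.columns else np.zeros(n, dtype=int)
    )
    b_year_levels = rng.normal(0, config.frailty_sd_year, config.n_years)
    eta = eta + b_fawn + b_year_levels[years % config.n_years]

    rate = config.baseline_hazard * np.exp(eta)
    u = rng.exponential(1.0, n)
    t_death = np.where(rate > 0, u / np.where(rate > 0, rate, 1.0), np.inf)
    event = (t_death <= season_end).astype(int)
    stop = np.minimum(t_death, season_end)

    causes = list(CAUSE_PROBS)
    cause_draw = rng.choice(causes, size=n, p=list(CAUSE_PROBS.values()))
    cause = np.where(event == 1, cause_draw, "censored")

    birth_date = rng.integers(0, 45, n)  # day index within the fawning season
    age_at_capture = rng.integers(0, 16, n)
    birth_mass = np.clip(rng.normal(3.5, 0.8, n), 0.8, None)
    capture_mass = birth_mass + 0.2 * age_at_capture + rng.normal(0, 0.05, n)

    out = pd.DataFrame(
        {
            "fawn_id": df["fawn_id"] if "fawn_id" in df.columns else np.arange(n),
            "year": years,
            "birth_date": birth_date,
            "capture_mass": capture_mass,
            "age_at_capture": age_at_capture,
            "stop_day": stop,
            "event": event,
            "cause": cause,
        }
    )
    return out
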