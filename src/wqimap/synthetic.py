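"""Synthetic monitoring data with the statistical structure the pipeline
assumes: spatially correlated latent quality, right-skewed concentration
marginals, zero-inflated microbial counts, stratified design, and
missing values.

The generator emulates a provincial monitoring design: ``n_points``
sites sampled in both a dry and a wet season each year over five years
(128 sites x 2 seasons x 5 years = 1280 records by default), stratified
by water source (groundwater/surface) and supply type
(centralized/decentralized) with year-specific proportions.

Each site carries a latent quality factor drawn from a Gaussian random
field; general-constituent concentrations are lognormal around a
fraction of their regulatory limit, shifted on the log scale by the
latent factor and by configurable group effects, which makes them
right-skewed and spatially correlated exactly as the index pipeline
expects.  All draws flow from a single seed, so every dataset is
reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigError
from .geostat import SpatialSample, VariogramModel, variogram_value
from .standards import MonitoringRecord, StandardsTable

#: per-year probability that a site draws groundwater / is centralized,
#: matching a realistic provincial stratification (≈256 samples/year).
DEFAULT_P_GROUND = {2007: 182 / 256, 2008: 208 / 256, 2009: 204 / 256,
                    2010: 202 / 256, 2011: 202 / 256}
DEFAULT_P_CENTRAL = {2007: 182 / 256, 2008: 196 / 256, 2009: 206 / 256,
                     2010: 208 / 256, 2011: 208 / 256}


@dataclass(frozen=True)
class IndicatorParams:
    """Lognormal marginal for a general constituent, relative to its limit:
    median = median_frac * Si, log-scale sigma."""

    median_frac: float = 0.4
    sigma: float = 0.6


@dataclass
class SyntheticConfig:
    """Full design of a synthetic monitoring campaign."""

    seed: int = 0
    n_points: int = 128
    years: tuple[int, ...] = (2007, 2008, 2009, 2010, 2011)
    seasons: tuple[str, ...] = ("dry", "wet")
    bbox: tuple[float, float, float, float] = (115.0, 122.5, 34.5, 38.5)
    # latent site-quality field (log-concentration scale, degrees of lon/lat)
    field_model: VariogramModel = field(
        default_factory=lambda: VariogramModel(
            family="spherical", nugget=0.02, partial_sill=0.25, range_param=2.0
        )
    )
    # additive shifts of the latent (log) quality factor; positive = worse water
    source_effect: float = 0.5  # surface vs groundwater
    supply_effect: float = 0.5  # decentralized vs centralized
    year_effects: Mapping[int, float] = field(default_factory=lambda: {2008: 0.5})
    season_effects: Mapping[str, float] = field(default_factory=dict)
    indicator_params: Mapping[str, IndicatorParams] = field(default_factory=dict)
    default_indicator: IndicatorParams = field(default_factory=IndicatorParams)
    p_groundwater: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_P_GROUND)
    )
    p_centralized: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_P_CENTRAL)
    )
    microbial_detect_prob: float = 0.2
    missing_rate: float = 0.05
    layout: str = "uniform"  # uniform | clustered
    n_clusters: int = 8
    hotspot: bool = False  # central-region bump in the latent field (demos)
    hotspot_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ConfigError("n_points must be >= 4")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.layout not in ("uniform", "clustered"):
            raise ConfigError("layout must be 'uniform' or 'clustered'")
        for p in self.indicator_params.values():
            if not p.sigma > 0:
                raise ConfigError("lognormal sigmas must be > 0")


def simulate_grf(
    locations: Sequence[tuple[float, float]],
    model: VariogramModel,
    mean: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One realization of a stationary Gaussian random field.

    The covariance implied by the variogram is C(h) = sill - gamma(h)
    (so C(0) = sill includes the nugget); the field is drawn by Cholesky
    factorization of the covariance matrix, with an escalating diagonal
    jitter retried a few times before giving up.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coords = np.asarray(locations, dtype=float)
    n = len(coords)
    d = squareform(pdist(coords)) if n > 1 else np.zeros((1, 1))
    cov = model.sill - np.asarray(variogram_value(model, d))
    np.fill_diagonal(cov, model.sill)
    z = rng.standard_normal(n)
    if model.sill == 0:
        return np.full(n, float(mean))
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            chol = np.linalg.cholesky(cov + jitter * np.eye(n))
            return mean + chol @ z
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "covariance matrix not positive semidefinite even after jitter "
        "(duplicate locations with zero nugget?)"
    )


def _site_coordinates(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    x0, x1, y0, y1 = config.bbox
    n = config.n_points
    if config.layout == "uniform":
        lon = rng.uniform(x0, x1, n)
        lat = rng.uniform(y0, y1, n)
    else:
        # settlement-like clusters: gaussian scatter around random centers
        centers = np.column_stack(
            [rng.uniform(x0, x1, config.n_clusters), rng.uniform(y0, y1, config.n_clusters)]
        )
        which = rng.integers(0, config.n_clusters, n)
        scale = 0.05 * min(x1 - x0, y1 - y0)
        pts = centers[which] + rng.normal(0.0, scale, (n, 2))
        lon = np.clip(pts[:, 0], x0, x1)
        lat = np.clip(pts[:, 1], y0, y1)
    return np.column_stack([lon, lat])


def simulate_monitoring(config: SyntheticConfig) -> list[MonitoringRecord]:
    """Generate the full record set for the configured design.

    Emits one record per site x year x season; a pure function of the
    config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    standards = StandardsTable.default()
    general = standards.codes_by_category("general")
    microbial = standards.codes_by_category("microbial")

    coords = _site_coordinates(config, rng)
    latent = simulate_grf(coords, config.field_model, mean=0.0, seed=rng)
    if config.hotspot:
        x0, x1, y0, y1 = config.bbox
        cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        w = 0.15 * min(x1 - x0, y1 - y0)
        r2 = (coords[:, 0] - cx) ** 2 + (coords[:, 1] - cy) ** 2
        latent = latent + config.hotspot_amplitude * np.exp(-r2 / (2.0 * w**2))

    records: list[MonitoringRecord] = []
    for year in config.years:
        pg = config.p_groundwater.get(year, 0.5)
        pc = config.p_centralized.get(year, 0.5)
        is_ground = rng.random(config.n_points) < pg
        is_central = rng.random(config.n_points) < pc
        for season in config.seasons:
            for i in range(config.n_points):
                source = "groundwater" if is_ground[i] else "surface"
                supply = "centralized" if is_central[i] else "decentralized"
                q = (
                    latent[i]
                    + (0.0 if is_ground[i] else config.source_effect)
                    + (0.0 if is_central[i] else config.supply_effect)
                    + config.year_effects.get(year, 0.0)
                    + config.season_effects.get(season, 0.0)
                )
                meas: dict[str, float] = {}
                for code in general:
                    p = config.indicator_params.get(code, config.default_indicator)
                    si = standards[code].limit
                    meas[code] = float(
                        p.median_frac * si * np.exp(q + p.sigma * rng.standard_normal())
                    )
                # pH around 7.4, truncated to a potable range
                a, b = (6.0 - 7.4) / 0.3, (9.0 - 7.4) / 0.3
                meas["ph"] = float(
                    stats.truncnorm.rvs(a, b, loc=7.4, scale=0.3, random_state=rng)
                )
                for code in microbial:
                    if rng.random() < config.microbial_detect_prob:
                        meas[code] = float(max(1, round(np.exp(rng.normal(1.0, 1.0)))))
                    else:
                        meas[code] = 0.0
                if config.missing_rate > 0:
                    keep = rng.random(len(meas)) >= config.missing_rate
                    meas = {c: v for (c, v), k in zip(meas.items(), keep) if k}
                records.append(
                    MonitoringRecord(
                        point_id=f"P{i + 1:03d}",
                        longitude=float(coords[i, 0]),
                        latitude=float(coords[i, 1]),
                        year=int(year),
                        season=season,
                        source=source,
                        supply=supply,
                        measurements=meas,
                    )
                )
    return records


def samples_from_grf(
    n: int,
    model: VariogramModel,
    mean: float = 0.0,
    seed: int | np.random.Generator = 0,
    bbox: tuple[float, float, float, float] = (0.0, 1.0, 0.0, 1.0),
) -> list[SpatialSample]:
    """Convenience: n uniform locations with one GRF draw as values."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x0, x1, y0, y1 = bbox
    xs = rng.uniform(x0, x1, n)
    ys = rng.uniform(y0, y1, n)
    vals = simulate_grf(np.column_stack([xs, ys]), model, mean=mean, seed=rng)
    return [
        SpatialSample(float(x), float(y), float(v), point_id=str(i))
        for i, (x, y, v) in enumerate(zip(xs, ys, vals))
    ]


FIXTURES = ("tiny", "paper_scale", "noisy")


def make_fixture(name: str, seed: int, out_dir: str | Path) -> dict[str, str]:
    """Write a self-contained dataset bundle (records CSV + standards JSON
    + sha256 manifest) for one of the named designs.

    ``tiny`` is 5 points, one year, one season, no missing values (for
    hand-checked tests); ``paper_scale`` is the full 1280-record design;
    ``noisy`` doubles the log-scale spread and missingness.
    """
    from .io import write_records_csv  # local import: io depends on standards only

    if name not in FIXTURES:
        raise ConfigError(f"unknown fixture {name!r}; choose from {FIXTURES}")
    if name == "tiny":
        config = SyntheticConfig(
            seed=seed, n_points=5, years=(2007,), seasons=("dry",), missing_rate=0.0
        )
    elif name == "paper_scale":
        config = SyntheticConfig(seed=seed)
    else:
        config = SyntheticConfig(
            seed=seed,
            default_indicator=IndicatorParams(median_frac=0.4, sigma=1.2),
            missing_rate=0.15,
        )
    records = simulate_monitoring(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec_path = out / f"{name}_records.csv"
    std_path = out / f"{name}_standards.json"
    write_records_csv(records, rec_path, standards=StandardsTable.default())
    StandardsTable.default().to_json(std_path)
    manifest = {
        "name": name,
        "seed": seed,
        "n_records": len(records),
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in (rec_path, std_path)
        },
    }
    man_path = out / f"{name}_manifest.json"
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return {"records": str(rec_path), "standards": str(std_path),
            "manifest": str(man_path)}
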