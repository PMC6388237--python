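"""Ordinary kriging from scratch: empirical semivariogram, model fitting,
and point/grid prediction.

The workflow is the classical geostatistical one: estimate the empirical
semivariogram with the Matheron (method-of-moments) estimator, fit a
permissible model (spherical, exponential, or Gaussian) by weighted
least squares, then solve the ordinary-kriging system

.. math::

    \\begin{pmatrix} \\Gamma & \\mathbf{1} \\\\ \\mathbf{1}^T & 0 \\end{pmatrix}
    \\begin{pmatrix} \\mathbf{w} \\\\ \\mu \\end{pmatrix}
    =
    \\begin{pmatrix} \\gamma_0 \\\\ 1 \\end{pmatrix}

per target, where :math:`\\Gamma_{ij} = \\gamma(\\|s_i - s_j\\|)` and the
unit row enforces unbiasedness (weights sum to 1) via the Lagrange
multiplier :math:`\\mu`.  The kriging variance is
:math:`\\sigma^2 = \\mathbf{w}^T \\gamma_0 + \\mu`.

Only isotropic variograms and global neighborhoods are supported: with
on the order of a hundred monitoring points, every sample can inform
every prediction and anisotropy cannot be resolved anyway.

Coordinates may be given in longitude/latitude; by default they are
mapped to planar kilometres by an equirectangular projection about the
data centroid, which is adequate at provincial scale.  Passing
``project=False`` to :func:`project_coordinates` callers keeps raw
degree Euclidean distances.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import InsufficientDataError, NearSingularSystemError

logger = logging.getLogger(__name__)

FAMILIES = ("spherical", "exponential", "gaussian")

#: kriging variances in [-VARIANCE_TOL, 0) are round-off and clamped to 0;
#: anything more negative raises.
VARIANCE_TOL = 1e-8

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class SpatialSample:
    """A located scalar observation (typically a WQI total)."""

    x: float
    y: float
    value: float
    point_id: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")


@dataclass
class EmpiricalVariogram:
    """Matheron semivariance estimates on distance bins."""

    bin_centers: np.ndarray
    gamma_hat: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.gamma_hat = np.asarray(self.gamma_hat, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)
        if not (
            len(self.bin_centers) == len(self.gamma_hat) == len(self.pair_counts)
        ):
            raise ValueError("bin_centers, gamma_hat, pair_counts must align")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")


@dataclass(frozen=True)
class VariogramModel:
    """Parametric semivariogram: family, nugget, partial sill, range.

    ``range_param`` is the *effective* range for the exponential and
    Gaussian families (distance at which ~95% of the sill is reached,
    i.e. gamma(h) = nugget + psill*(1 - exp(-3h/a)) etc.), and the exact
    range for the spherical family.  gamma(0) = 0 by convention; the
    nugget is the right-limit at the origin.
    """

    family: str = "spherical"
    nugget: float = 0.0
    partial_sill: float = 1.0
    range_param: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial_sill must be >= 0")
        if not self.range_param > 0:
            raise ValueError("range_param must be > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill


@dataclass
class KrigingPrediction:
    """Prediction and kriging variance at one target location."""

    x: float
    y: float
    predicted: float
    kriging_variance: float


@dataclass(frozen=True)
class GridSpec:
    """Regular grid over a bounding box; targets are cell centers."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    n_x: int
    n_y: int

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("grid bounds must satisfy max > min on both axes")
        if self.n_x < 2 or self.n_y < 2:
            raise ValueError("grid needs n_x, n_y >= 2")

    @property
    def cell_size(self) -> tuple[float, float]:
        return (
            (self.x_max - self.x_min) / self.n_x,
            (self.y_max - self.y_min) / self.n_y,
        )

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of cell-center coordinates (ascending)."""
        dx, dy = self.cell_size
        xs = self.x_min + dx * (np.arange(self.n_x) + 0.5)
        ys = self.y_min + dy * (np.arange(self.n_y) + 0.5)
        return xs, ys

    def targets(self) -> np.ndarray:
        """(n_y * n_x, 2) array of cell centers, row-major with the y axis
        varying slowest (top row first uses ascending y here)."""
        xs, ys = self.centers()
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class KrigingGrid:
    """Row-major grid of kriging output: 2-D arrays shaped (n_y, n_x)."""

    spec: GridSpec
    predicted: np.ndarray
    variance: np.ndarray


def project_coordinates(
    lon: np.ndarray, lat: np.ndarray, project: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Map lon/lat (degrees) to planar x/y.

    Default is an equirectangular projection about the data centroid,
    returning kilometres; ``project=False`` returns the degrees
    unchanged (Euclidean distance in raw degrees then mimics kriging
    directly on geographic coordinates).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if not project:
        return lon, lat
    lat0 = float(np.mean(lat))
    lon0 = float(np.mean(lon))
    k = math.pi / 180.0 * EARTH_RADIUS_KM
    x = (lon - lon0) * math.cos(math.radians(lat0)) * k
    y = (lat - lat0) * k
    return x, y


def _coords_values(samples: Sequence[SpatialSample]) -> tuple[np.ndarray, np.ndarray]:
    coords = np.array([[s.x, s.y] for s in samples], dtype=float)
    values = np.array([s.value for s in samples], dtype=float)
    return coords, values


def find_duplicate_locations(
    samples: Sequence[SpatialSample], tol: float = 1e-12
) -> list[tuple[int, int]]:
    """Index pairs of samples closer than ``tol`` (collocated)."""
    coords, _ = _coords_values(samples)
    d = squareform(pdist(coords))
    iu = np.triu_indices(len(samples), k=1)
    close = d[iu] < tol
    return [(int(i), int(j)) for i, j, c in zip(*iu, close) if c]


def empirical_variogram(
    samples: Sequence[SpatialSample],
    n_bins: int = 15,
    max_lag: float | None = None,
) -> EmpiricalVariogram:
    """Matheron estimator on equal-width distance bins.

    gamma_hat(h) = (1 / 2N(h)) * sum over pairs in the bin of (z_i - z_j)^2.
    ``max_lag`` defaults to half the maximum pairwise distance; bins with
    no pairs are dropped.
    """
    if len(samples) < 2:
        raise InsufficientDataError("empirical variogram needs >= 2 samples")
    coords, values = _coords_values(samples)
    d = pdist(coords)
    if max_lag is None:
        max_lag = float(d.max()) / 2.0
    if not max_lag > 0:
        raise ValueError("max_lag must be > 0 (are all samples collocated?)")
    sq = pdist(values[:, None], metric="sqeuclidean")

    edges = np.linspace(0.0, max_lag, n_bins + 1)
    # pairs at distance 0 (collocated) fall in the first bin
    idx = np.digitize(d, edges[1:-1], right=False)
    in_range = d <= max_lag
    counts = np.bincount(idx[in_range], minlength=n_bins)
    sums = np.bincount(idx[in_range], weights=sq[in_range], minlength=n_bins)

    occupied = counts > 0
    gamma = np.zeros(n_bins)
    gamma[occupied] = sums[occupied] / (2.0 * counts[occupied])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(
        bin_centers=centers[occupied],
        gamma_hat=gamma[occupied],
        pair_counts=counts[occupied],
    )


def variogram_value(model: VariogramModel, h) -> np.ndarray | float:
    """Evaluate gamma(h) for the model; gamma(0) = 0 exactly.

    Accepts a scalar or array of nonnegative lags.
    """
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0):
        raise ValueError("lag distances must be >= 0")
    a = model.range_param
    c0, c1 = model.nugget, model.partial_sill
    with np.errstate(over="ignore"):
        if model.family == "spherical":
            hr = np.minimum(h_arr / a, 1.0)
            structured = c1 * (1.5 * hr - 0.5 * hr**3)
        elif model.family == "exponential":
            structured = c1 * (1.0 - np.exp(-3.0 * h_arr / a))
        else:  # gaussian
            structured = c1 * (1.0 - np.exp(-3.0 * (h_arr / a) ** 2))
    gamma = np.where(h_arr == 0.0, 0.0, c0 + structured)
    return float(gamma) if np.isscalar(h) or gamma.ndim == 0 else gamma


def fit_variogram(
    empirical: EmpiricalVariogram,
    family: str = "spherical",
    weights: str = "npairs_over_h2",
) -> VariogramModel:
    """Weighted least-squares fit of a variogram model to the empirical
    semivariances.

    Default weights N(h)/h^2 emphasize short lags (where kriging weights
    are decided) and well-populated bins; ``weights="uniform"`` is the
    plain least-squares alternative.  The optimizer runs from a small
    deterministic grid of starting points (no randomness) and keeps the
    best bounded solution, so the fit is reproducible.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    if weights not in ("npairs_over_h2", "uniform"):
        raise ValueError("weights must be 'npairs_over_h2' or 'uniform'")
    h = empirical.bin_centers
    g = empirical.gamma_hat
    npairs = empirical.pair_counts
    if len(h) < 3:
        raise InsufficientDataError("variogram fit needs >= 3 occupied bins")

    if np.all(g == 0):
        warnings.warn(
            "all empirical semivariances are zero; returning a degenerate "
            "pure-nugget-zero model",
            stacklevel=2,
        )
        return VariogramModel(family=family, nugget=0.0, partial_sill=0.0,
                              range_param=float(h[-1]))

    if weights == "npairs_over_h2":
        w = np.sqrt(npairs / np.maximum(h, 1e-300) ** 2)
    else:
        w = np.ones_like(h)

    def residuals(theta: np.ndarray) -> np.ndarray:
        model = VariogramModel(
            family=family,
            nugget=theta[0],
            partial_sill=theta[1],
            range_param=theta[2],
        )
        return w * (variogram_value(model, h) - g)

    sill0 = float(np.max(g))
    hmax = float(h[-1])
    lower = np.array([0.0, 0.0, 1e-12 * hmax])
    upper = np.array([2.0 * sill0 + 1e-12, 2.0 * sill0 + 1e-12, 10.0 * hmax])
    # deterministic multi-start over plausible nugget fractions and ranges
    starts = [
        np.array([f0 * sill0, (1.0 - f0) * sill0, fr * hmax])
        for f0 in (0.0, 0.25, 0.5, 0.9)
        for fr in (0.2, 0.5, 1.0)
    ]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lower + 1e-15, upper - 1e-15)
        sol = least_squares(residuals, x0, bounds=(lower, upper), method="trf")
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    theta = best.x
    nugget, psill, rng_ = float(theta[0]), float(theta[1]), float(theta[2])
    # canonical form: a range at or below the shortest observed lag is
    # indistinguishable from pure nugget on these data — collapse it
    if rng_ <= float(h[0]) * (1.0 + 1e-3):
        m = VariogramModel(family, nugget, psill, rng_)
        nugget = float(variogram_value(m, float(h[0])))
        psill = 0.0
        rng_ = float(h[-1])
    return VariogramModel(
        family=family,
        nugget=nugget,
        partial_sill=psill,
        range_param=rng_,
    )


def _kriging_system(
    coords: np.ndarray, model: VariogramModel
) -> tuple[np.ndarray, tuple]:
    n = len(coords)
    d = squareform(pdist(coords))
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = variogram_value(model, d)
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    a[n, n] = 0.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # LinAlgWarning on near-singular
            lu = lu_factor(a)
    except Exception as exc:
        dup = [
            (i, j)
            for i, j in zip(*np.triu_indices(n, k=1))
            if d[i, j] < 1e-12
        ]
        if dup:
            raise NearSingularSystemError(
                f"kriging system singular: duplicate sample locations at index "
                f"pairs {dup[:5]}"
            ) from exc
        raise NearSingularSystemError(
            f"kriging system singular or near-singular: {exc}"
        ) from exc
    return d, lu


def ordinary_krige(
    samples: Sequence[SpatialSample],
    model: VariogramModel,
    targets: Iterable[tuple[float, float]],
) -> list[KrigingPrediction]:
    """Ordinary-kriging point predictions at arbitrary target locations.

    The (n+1) system is factorized once and reused for every target.
    Weights sum to 1 by construction; with a zero nugget the predictor
    interpolates the samples exactly.  Tiny negative variances from
    round-off are clamped to zero; values below -1e-8 raise.
    """
    targets = np.atleast_2d(np.asarray(list(targets), dtype=float))
    if targets.size == 0:
        return []
    if len(samples) < 2:
        raise InsufficientDataError("ordinary kriging needs >= 2 samples")
    coords, values = _coords_values(samples)
    _, lu = _kriging_system(coords, model)

    d0 = cdist(targets, coords)
    b = np.empty((len(targets), len(samples) + 1))
    b[:, :-1] = variogram_value(model, d0)
    b[:, -1] = 1.0
    sol = lu_solve(lu, b.T).T  # rows: (weights..., lagrange mu)
    w = sol[:, :-1]
    mu = sol[:, -1]
    preds = w @ values
    variances = np.einsum("ij,ij->i", w, b[:, :-1]) + mu

    out = []
    for k, (tx, ty) in enumerate(targets):
        var = float(variances[k])
        if var < -VARIANCE_TOL:
            raise NearSingularSystemError(
                f"kriging variance {var} at target ({tx}, {ty}) is negative "
                "beyond round-off tolerance"
            )
        if var < 0:
            logger.debug("clamping round-off kriging variance %g to 0", var)
            var = 0.0
        out.append(KrigingPrediction(float(tx), float(ty), float(preds[k]), var))
    return out


def kriging_weights(
    samples: Sequence[SpatialSample],
    model: VariogramModel,
    target: tuple[float, float],
) -> tuple[np.ndarray, float]:
    """Ordinary-kriging weights and Lagrange multiplier for one target.

    Mostly diagnostic: the weights always sum to 1 (unbiasedness).
    """
    coords, _ = _coords_values(samples)
    _, lu = _kriging_system(coords, model)
    d0 = cdist(np.atleast_2d(np.asarray(target, dtype=float)), coords)[0]
    b = np.append(np.asarray(variogram_value(model, d0)), 1.0)
    sol = lu_solve(lu, b)
    return sol[:-1], float(sol[-1])


def krige_grid(
    samples: Sequence[SpatialSample],
    model: VariogramModel,
    grid: GridSpec,
) -> KrigingGrid:
    """Kriging over the cell centers of a regular grid (row-major)."""
    preds = ordinary_krige(samples, model, grid.targets())
    z = np.array([p.predicted for p in preds]).reshape(grid.n_y, grid.n_x)
    v = np.array([p.kriging_variance for p in preds]).reshape(grid.n_y, grid.n_x)
    return KrigingGrid(spec=grid, predicted=z, variance=v)
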