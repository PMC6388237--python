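"""Leave-one-out cross-validation of the kriging interpolation and the
error/agreement metric suite.

For each sample the WQI is predicted by ordinary kriging from all the
other samples, and the paired observed/predicted values are summarized
by

* MAE  — mean absolute error,
* MRE  — mean relative error, mean of |o - e| / |o|,
* RMSE — root mean square error,
* AC   — agreement index,
  ``AC = 1 - n RMSE^2 / sum_i (|o_i - obar| + |e_i - obar|)^2``
  with ``obar`` the mean of the observed values.  Since
  ``n RMSE^2 = sum (o_i - e_i)^2``, AC is algebraically Willmott's
  index of agreement d: 1 for perfect predictions, smaller for worse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateDataError, InsufficientDataError
from .geostat import (
    SpatialSample,
    VariogramModel,
    empirical_variogram,
    fit_variogram,
    ordinary_krige,
)

REFIT_POLICIES = ("fit_once", "refit_per_fold")
ZERO_OBSERVED_POLICIES = ("error", "skip")


def error_metrics(
    observed: Sequence[float],
    predicted: Sequence[float],
    zero_observed: str = "error",
) -> tuple[float, float, float]:
    """(MAE, MRE, RMSE) between observed and predicted vectors.

    MRE divides by |observed|, so zero observed values are either a hard
    error (default) or skipped from the MRE average with a warning
    (``zero_observed="skip"``); MAE and RMSE always use all pairs.
    """
    if zero_observed not in ZERO_OBSERVED_POLICIES:
        raise ValueError(f"zero_observed must be one of {ZERO_OBSERVED_POLICIES}")
    o = np.asarray(observed, dtype=float)
    e = np.asarray(predicted, dtype=float)
    if o.shape != e.shape or o.ndim != 1 or len(o) == 0:
        raise ValueError("observed and predicted must be equal-length nonempty 1-D")
    resid = o - e
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid**2)))
    zero = o == 0
    if np.any(zero):
        if zero_observed == "error":
            raise DegenerateDataError(
                f"MRE undefined: observed value is zero at positions "
                f"{np.flatnonzero(zero).tolist()}"
            )
        import warnings

        warnings.warn(
            f"skipping {int(zero.sum())} zero observed values in MRE",
            stacklevel=2,
        )
        keep = ~zero
        if not np.any(keep):
            raise DegenerateDataError("MRE undefined: all observed values are zero")
        mre = float(np.mean(np.abs(resid[keep]) / np.abs(o[keep])))
    else:
        mre = float(np.mean(np.abs(resid) / np.abs(o)))
    return mae, mre, rmse


def accuracy_index(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Agreement index AC in (-inf, 1]; 1 iff predictions are perfect.

    ``1 - sum (o-e)^2 / sum (|o - obar| + |e - obar|)^2`` with obar the
    observed mean (both vectors centered on the observed mean, as in
    Willmott's d).
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(predicted, dtype=float)
    if o.shape != e.shape or o.ndim != 1 or len(o) < 2:
        raise ValueError("need equal-length 1-D vectors of length >= 2")
    obar = o.mean()
    denom = float(np.sum((np.abs(o - obar) + np.abs(e - obar)) ** 2))
    if denom == 0.0:
        raise DegenerateDataError(
            "agreement index undefined: observed and predicted are all equal "
            "to the observed mean"
        )
    return 1.0 - float(np.sum((o - e) ** 2)) / denom


@dataclass
class CrossValReport:
    """Paired LOOCV observations/predictions plus the metric suite."""

    pairs: list[tuple[str, float, float]]  # (point_id, observed, predicted)
    n: int
    mae: float
    mre: float
    rmse: float
    ac: float
    model: VariogramModel | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mae": self.mae,
            "mre": self.mre,
            "rmse": self.rmse,
            "ac": self.ac,
            "model": None
            if self.model is None
            else {
                "family": self.model.family,
                "nugget": self.model.nugget,
                "partial_sill": self.model.partial_sill,
                "range": self.model.range_param,
            },
            "pairs": [
                {"point_id": pid, "observed": o, "predicted": e}
                for pid, o, e in self.pairs
            ],
        }


def loocv(
    samples: Sequence[SpatialSample],
    family: str = "spherical",
    refit_policy: str = "fit_once",
    n_bins: int = 15,
    max_lag: float | None = None,
    model: VariogramModel | None = None,
) -> list[tuple[str, float, float]]:
    """Leave-one-out kriging predictions: ``(point_id, observed, predicted)``
    per sample.

    ``fit_once`` (default) fits the variogram on the full data and
    reuses it for every fold; ``refit_per_fold`` re-estimates it on each
    n-1 subset.  A pre-fitted ``model`` skips fitting entirely.
    """
    if refit_policy not in REFIT_POLICIES:
        raise ValueError(f"refit_policy must be one of {REFIT_POLICIES}")
    if len(samples) < 4:
        raise InsufficientDataError("leave-one-out CV needs >= 4 samples")

    shared = model
    if shared is None and refit_policy == "fit_once":
        shared = fit_variogram(
            empirical_variogram(samples, n_bins=n_bins, max_lag=max_lag), family
        )

    out = []
    for i, held in enumerate(samples):
        rest = [s for j, s in enumerate(samples) if j != i]
        m = shared
        if m is None:
            m = fit_variogram(
                empirical_variogram(rest, n_bins=n_bins, max_lag=max_lag), family
            )
        pred = ordinary_krige(rest, m, [(held.x, held.y)])[0]
        out.append((held.point_id or str(i), held.value, pred.predicted))
    return out


def crossval_report(
    samples: Sequence[SpatialSample],
    family: str = "spherical",
    refit_policy: str = "fit_once",
    n_bins: int = 15,
    max_lag: float | None = None,
    zero_observed: str = "error",
) -> CrossValReport:
    """LOOCV + metric suite in one serializable report."""
    fitted = None
    if refit_policy == "fit_once":
        fitted = fit_variogram(
            empirical_variogram(samples, n_bins=n_bins, max_lag=max_lag), family
        )
    pairs = loocv(
        samples,
        family=family,
        refit_policy=refit_policy,
        n_bins=n_bins,
        max_lag=max_lag,
        model=fitted,
    )
    obs = [o for _, o, _ in pairs]
    pred = [e for _, _, e in pairs]
    mae, mre, rmse = error_metrics(obs, pred, zero_observed=zero_observed)
    ac = accuracy_index(obs, pred)
    return CrossValReport(
        pairs=pairs, n=len(pairs), mae=mae, mre=mre, rmse=rmse, ac=ac, model=fitted
    )
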