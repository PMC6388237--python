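import numpy as np
import pytest

from wqimap import (
    MonitoringRecord,
    SpatialSample,
    StandardsTable,
    VariogramModel,
)


@pytest.fixture(scope="session")
def standards() -> StandardsTable:
    return StandardsTable.default()


@pytest.fixture
def at_limit_record(standards) -> MonitoringRecord:
    """Every general indicator exactly at its limit, pH neutral, coliforms
    absent: forces each sub-index to a known value."""
    meas = {c: standards[c].limit for c in standards.codes_by_category("general")}
    meas["ph"] = 7.0
    meas["tc"] = 0.0
    meas["tcb"] = 0.0
    return MonitoringRecord(
        point_id="AT_LIMIT",
        longitude=117.0,
        latitude=36.5,
        year=2007,
        season="dry",
        source="groundwater",
        supply="centralized",
        measurements=meas,
    )


@pytest.fixture
def square_samples() -> list[SpatialSample]:
    """Four unit-square corners plus center, distinct values."""
    pts = [(0, 0, 1.0), (1, 0, 2.0), (0, 1, 3.0), (1, 1, 4.0), (0.5, 0.5, 2.5)]
    return [SpatialSample(x, y, v, point_id=str(i)) for i, (x, y, v) in enumerate(pts)]


@pytest.fixture
def spherical_model() -> VariogramModel:
    return VariogramModel("spherical", nugget=0.0, partial_sill=2.0, range_param=1.5)


def brute_force_krige(samples, model, target):
    """Independent ordinary-kriging oracle: naive loop assembly of the
    semivariance system, solved with numpy.  Returns (prediction, variance)."""
    from wqimap import variogram_value

    n = len(samples)
    a = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            h = np.hypot(samples[i].x - samples[j].x, samples[i].y - samples[j].y)
            a[i, j] = variogram_value(model, h)
        a[i, n] = 1.0
        a[n, i] = 1.0
    b = np.zeros(n + 1)
    for i in range(n):
        h = np.hypot(samples[i].x - target[0], samples[i].y - target[1])
        b[i] = variogram_value(model, h)
    b[n] = 1.0
    sol = np.linalg.solve(a, b)
    w, mu = sol[:n], sol[n]
    pred = float(sum(wi * s.value for wi, s in zip(w, samples)))
    var = float(w @ b[:n] + mu)
    return pred, var


def covariance_form_krige(samples, model, targets):
    """Second independent oracle in the *covariance* formulation:
    C(h) = sill - gamma(h), bordered system solved by least squares.
    A genuinely different assembly path from the package's."""
    from wqimap import variogram_value

    n = len(samples)
    coords = np.array([[s.x, s.y] for s in samples])
    vals = np.array([s.value for s in samples])
    sill = model.sill
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    c = sill - np.asarray(variogram_value(model, d))
    np.fill_diagonal(c, sill)
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = c
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    preds, variances = [], []
    for t in np.atleast_2d(targets):
        d0 = np.sqrt(((coords - t) ** 2).sum(-1))
        c0 = sill - np.asarray(variogram_value(model, d0))
        rhs = np.append(c0, 1.0)
        sol, *_ = np.linalg.lstsq(a, rhs, rcond=None)
        w, nu = sol[:n], sol[n]
        preds.append(float(w @ vals))
        variances.append(float(sill - w @ c0 - nu))
    return np.array(preds), np.array(variances)
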