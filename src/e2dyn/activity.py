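"""Exponential model linking catalytic geometry to conjugation activity.

Activity falls off exponentially with the distance between the catalytic
cysteine and the substrate acceptor lysine: ``f(x) = b·exp(-c·x)`` with
amplitude ``b`` (activity units, the extrapolated activity at contact) and
decay rate ``c`` (1/nm).  The fit is unweighted nonlinear least squares,
initialised from the log-linear closed form when all activities are positive;
goodness of fit is reported as the Pearson correlation between observed and
fitted activities.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import InvalidArgumentError


@dataclass
class ActivityFit:
    """Fitted exponential activity-distance relation."""

    b: float                      # amplitude (activity units)
    c: float                      # decay rate (1/nm)
    correlation: float            # Pearson r of observed vs fitted, 0 when degenerate
    residuals: np.ndarray         # observed - fitted
    fitted: np.ndarray
    degenerate: bool = False      # fitted values carry (numerically) no variance
    distance_uncertainties: np.ndarray | None = None


def _model(x: np.ndarray, b: float, c: float) -> np.ndarray:
    # clipped exponent keeps the optimizer finite on unidentifiable ridges
    return b * np.exp(np.clip(-c * x, -700.0, 700.0))


def fit_exponential_activity(
    distances: np.ndarray,
    activities: np.ndarray,
    distance_uncertainties: np.ndarray | None = None,
) -> ActivityFit:
    """Least-squares fit of ``activity = b·exp(-c·distance)``.

    Distance uncertainties (e.g. replicate standard deviations) are carried
    into the result for reporting but do not weight the fit.
    """
    x = np.asarray(distances, dtype=np.float64).ravel()
    y = np.asarray(activities, dtype=np.float64).ravel()
    if x.size != y.size:
        raise InvalidArgumentError("distances and activities must have equal length")
    if x.size < 3:
        raise InvalidArgumentError("at least 3 points are required")
    if np.any(x <= 0):
        raise InvalidArgumentError("all distances must be positive")
    sd = None
    if distance_uncertainties is not None:
        sd = np.asarray(distance_uncertainties, dtype=np.float64).ravel()
        if sd.size != x.size:
            raise InvalidArgumentError("one uncertainty per distance required")

    if np.all(y > 0):
        # log-linear closed form as the starting point
        slope, intercept = np.polyfit(x, np.log(y), 1)
        p0 = (float(np.exp(np.clip(intercept, -700.0, 700.0))), float(-slope))
    else:
        p0 = (float(max(y.max(), 1.0)), 1.0)
    # order-invariant objective; sort for a deterministic optimizer path
    order = np.argsort(x, kind="stable")
    try:
        import warnings

        with np.errstate(over="ignore", invalid="ignore"), warnings.catch_warnings():
            # exact fits cannot estimate a parameter covariance; we never use it
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            params, _ = optimize.curve_fit(_model, x[order], y[order], p0=p0, maxfev=20000)
        b, c = (float(p) for p in params)
    except RuntimeError:
        b, c = np.nan, np.nan
    fitted = _model(x, b, c) if np.isfinite([b, c]).all() else np.full_like(y, np.nan)
    identifiable = (
        np.isfinite([b, c]).all()
        and np.all(np.isfinite(fitted))
        and np.std(fitted) > 1e-12 * max(1.0, abs(b))
        and np.std(y) > 0.0
    )
    if not identifiable:
        # ridge or constant data: report the best constant model, flagged
        b, c = float(y.mean()), 0.0
        fitted = np.full_like(y, b)
        degenerate = True
        corr = 0.0
    else:
        degenerate = False
        corr = float(stats.pearsonr(y, fitted).statistic)
    residuals = y - fitted
    return ActivityFit(
        b=b, c=c, correlation=corr, residuals=residuals, fitted=fitted,
        degenerate=degenerate, distance_uncertainties=sd,
    )


def predict_activity(x: float | np.ndarray, fit: ActivityFit) -> float | np.ndarray:
    """Evaluate the fitted relation b·exp(-c·x) at distance ``x`` (nm)."""
    value = fit.b * np.exp(-fit.c * np.asarray(x, dtype=np.float64))
    return float(value) if np.isscalar(x) or np.asarray(x).ndim == 0 else value
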