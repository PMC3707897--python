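"""Candidate models relating pattern correlation to mean modulation.

Four models of the (r, mean d_M) scatter across subjects are compared:

* ``CD`` -- the parameter-free decorrelation curve d_T(r),
* ``LINEAR_IDENTITY`` -- d = r, slope one, no offset, parameter-free,
* ``POLY3`` -- 3rd-order polynomial, four free parameters,
* ``LINFIT`` -- ordinary least-squares line, two free parameters,

scored by summed squared error, orthogonal-distance R-squared, leave-one-out
cross-validation error and AIC = n*ln(RSS/n) + 2k.  Because measurement error
affects both axes, goodness of fit uses the orthogonal distance from each
point to the curve; LOO and per-point errors default to the vertical
(predictive) metric with the orthogonal metric available via a switch.

The MAX and AVERAGE response models act at the voxel level: they predict the
combined response m(C, S) directly as max(C, S) or (C + S)/2 and are compared
through the Euclidean norm of their prediction error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar

from .core import cd_curve, theoretical_d

__all__ = [
    "ModelFitResult",
    "ComparisonResult",
    "orthogonal_distances",
    "orthogonal_r_squared",
    "fit_polynomial",
    "fit_linear",
    "loo_cv_error",
    "normalized_errors",
    "aic",
    "aicc",
    "response_model_prediction",
    "compare_models",
    "MODEL_PARAM_COUNTS",
]

MODEL_PARAM_COUNTS = {
    "CD": 0,
    "LINEAR_IDENTITY": 0,
    "POLY3": 4,
    "LINFIT": 2,
    "MAX": 0,
    "AVERAGE": 0,
}


def _as_points(r, d):
    r = np.asarray(r, dtype=float).ravel()
    d = np.asarray(d, dtype=float).ravel()
    if r.shape != d.shape:
        raise ValueError("r and d must have equal length")
    return r, d


def orthogonal_distances(r, d, curve: Callable, grid_step: float = 1e-3):
    """Minimum Euclidean distance from each (r, d) point to a curve on [-1, 1].

    Dense parameter grid followed by bounded local refinement to 1e-6; the r
    and d axes are treated as commensurate (both live in [-1, 1]).
    """
    r, d = _as_points(r, d)
    grid = np.linspace(-1.0, 1.0, int(round(2.0 / grid_step)) + 1)
    f = np.asarray(curve(grid), dtype=float)
    out = np.empty(r.size)
    for i in range(r.size):
        d2 = (grid - r[i]) ** 2 + (f - d[i]) ** 2
        j = int(np.argmin(d2))
        lo = max(grid[max(j - 1, 0)], -1.0)
        hi = min(grid[min(j + 1, grid.size - 1)], 1.0)
        res = minimize_scalar(
            lambda t: (t - r[i]) ** 2 + (float(curve(t)) - d[i]) ** 2,
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        out[i] = np.sqrt(min(res.fun, d2[j]))
    return out


def orthogonal_r_squared(r, d, curve: Callable, grid_step: float = 1e-3) -> float:
    """R-squared with orthogonal distances in the numerator.

    numerator = sum of squared minimum distances from the points to the curve;
    denominator = sum of squared Euclidean distances of the points to their
    centroid.
    """
    r, d = _as_points(r, d)
    if r.size < 3:
        raise ValueError("need at least 3 points")
    num = float(np.sum(orthogonal_distances(r, d, curve, grid_step) ** 2))
    centroid = (r.mean(), d.mean())
    den = float(np.sum((r - centroid[0]) ** 2 + (d - centroid[1]) ** 2))
    if den == 0.0:
        raise ValueError("all points identical; R-squared undefined")
    return 1.0 - num / den


def fit_polynomial(r, d, degree: int = 3) -> np.ndarray:
    """Least-squares polynomial of d on r; coefficients ascending (a1..a4)."""
    r, d = _as_points(r, d)
    if r.size < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    X = np.vander(r, degree + 1, increasing=True)
    if np.linalg.matrix_rank(X) < degree + 1:
        raise ValueError("rank-deficient design (degenerate r values)")
    coef, *_ = np.linalg.lstsq(X, d, rcond=None)
    return coef


def fit_linear(r, d) -> np.ndarray:
    """Ordinary least squares d = a1 + a2*r; coefficients (a1, a2)."""
    r, d = _as_points(r, d)
    if r.size < 3:
        raise ValueError("need at least 3 points")
    if np.all(r == r[0]):
        raise ValueError("degenerate design: all r equal")
    return fit_polynomial(r, d, degree=1)


def _poly_predictor(coef):
    return lambda x: np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), coef)


def loo_cv_error(
    r,
    d,
    fitter: Callable,
    error_metric: str = "vertical",
    grid_step: float = 1e-3,
) -> float:
    """Mean leave-one-out error of a fitted curve.

    ``fitter(r_train, d_train)`` must return a predictor callable.  Each point
    is held out in turn, the model refit on the rest, and the held-out point's
    error recorded (vertical absolute error by default, orthogonal distance
    with ``error_metric='orthogonal'``).  For parameter-free models the refit
    is a no-op and the LOO error equals the plain mean per-point error.
    """
    r, d = _as_points(r, d)
    errors = np.empty(r.size)
    for i in range(r.size):
        mask = np.ones(r.size, dtype=bool)
        mask[i] = False
        try:
            predict = fitter(r[mask], d[mask])
        except Exception as exc:
            raise RuntimeError(f"fitter failed on LOO fold {i}: {exc}") from exc
        if error_metric == "vertical":
            errors[i] = abs(float(predict(r[i])) - d[i])
        elif error_metric == "orthogonal":
            errors[i] = orthogonal_distances([r[i]], [d[i]], predict, grid_step)[0]
        else:
            raise ValueError("error_metric must be 'vertical' or 'orthogonal'")
    return float(errors.mean())


def normalized_errors(errors, groups=None):
    """Per-point errors scaled so each group's maximum equals exactly 1.

    ``groups`` assigns each error to a normalization group (one VOI/condition);
    with ``groups=None`` all errors form one group.  An all-zero group stays
    all zeros.
    """
    errors = np.asarray(errors, dtype=float).ravel()
    if groups is None:
        groups = np.zeros(errors.size, dtype=int)
    groups = np.asarray(groups).ravel()
    if groups.shape != errors.shape:
        raise ValueError("groups must align with errors")
    out = np.empty_like(errors)
    for g in np.unique(groups):
        mask = groups == g
        gmax = errors[mask].max()
        out[mask] = errors[mask] / gmax if gmax > 0 else 0.0
    return out


def aic(n: int, rss: float, k: int) -> float:
    """Least-squares AIC: n*ln(RSS/n) + 2k.  RSS = 0 returns -inf with a warning."""
    if n < 2:
        raise ValueError("need at least 2 points")
    if rss < 0:
        raise ValueError("RSS must be non-negative")
    if rss == 0.0:
        warnings.warn("RSS is zero; AIC is -inf", RuntimeWarning, stacklevel=2)
        return -np.inf
    return float(n * np.log(rss / n) + 2 * k)


def aicc(n: int, rss: float, k: int) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n - k - 1).

    Appropriate when n/k is small (here n ~ 15 subjects against up to 4
    polynomial coefficients); reduces the known overfitting probability of
    plain AIC for nested alternatives.
    """
    if n - k - 1 <= 0:
        raise ValueError("AICc requires n > k + 1")
    base = aic(n, rss, k)
    return base if base == -np.inf else float(base + 2 * k * (k + 1) / (n - k - 1))


def response_model_prediction(C, S, model: str, observed_m=None):
    """Voxel-level prediction of the combined response m(C, S).

    MAX predicts the voxel-wise maximum of the component responses, AVERAGE
    their mean, and CD the decorrelated sum (1 - d_T)(C + S) with d_T computed
    from the same voxels.  Returns ``(predicted, error_norm)`` where the error
    is the Euclidean norm of (predicted - observed); the norm is None when no
    observation is supplied.
    """
    C = np.asarray(C, dtype=float).ravel()
    S = np.asarray(S, dtype=float).ravel()
    if C.shape != S.shape:
        raise ValueError("C and S must be aligned")
    if model == "MAX":
        pred = np.maximum(C, S)
    elif model == "AVERAGE":
        pred = 0.5 * (C + S)
    elif model == "CD":
        d_t = theoretical_d(C, S).d_T
        pred = (1.0 - d_t) * (C + S)
    else:
        raise ValueError("model must be 'MAX', 'AVERAGE' or 'CD'")
    if observed_m is None:
        return pred, None
    m = np.asarray(observed_m, dtype=float).ravel()
    if m.shape != C.shape:
        raise ValueError("observed m must be aligned with C and S")
    return pred, float(np.linalg.norm(pred - m))


@dataclass
class ModelFitResult:
    """One candidate model's fit and scores on a (r, mean d_M) scatter."""

    name: str
    k: int
    coefficients: np.ndarray
    per_point_errors: np.ndarray
    rss: float
    orth_r2: float
    loo_error: float
    normalized_mean_error: float = np.nan
    aic: float = np.nan


@dataclass
class ComparisonResult:
    """Ranked model fits plus the pairwise AIC winners."""

    results: list
    pairwise_winners: dict = field(default_factory=dict)

    def best(self) -> ModelFitResult:
        return self.results[0]

    def wins(self, name: str) -> int:
        return sum(1 for w in self.pairwise_winners.values() if w == name)


def _model_specs(variance_ratio: float):
    cd_predict = lambda x: cd_curve(x, variance_ratio)
    identity = lambda x: np.asarray(x, dtype=float)
    return {
        "CD": {"k": 0, "fitter": lambda r, d: cd_predict},
        "LINEAR_IDENTITY": {"k": 0, "fitter": lambda r, d: identity},
        "POLY3": {"k": 4, "fitter": lambda r, d: _poly_predictor(fit_polynomial(r, d, 3))},
        "LINFIT": {"k": 2, "fitter": lambda r, d: _poly_predictor(fit_linear(r, d))},
    }


def compare_models(
    r,
    d,
    variance_ratio: float = 1.0,
    error_metric: str = "vertical",
    grid_step: float = 1e-3,
    criterion: str = "aic",
) -> ComparisonResult:
    """Fit and score the four scatter models; rank them by AIC.

    Pairwise winners are decided by the lower information criterion (plain
    AIC by default, the small-sample corrected AICc with
    ``criterion='aicc'``), ties broken toward fewer free parameters.
    Per-point errors use the chosen metric; the criterion always uses the
    vertical least-squares residuals; orthogonal R-squared always uses
    orthogonal distances.
    """
    r, d = _as_points(r, d)
    n = r.size
    if n < 6:
        raise ValueError("need at least 6 points to compare the four models")
    specs = _model_specs(variance_ratio)
    results = []
    for name, spec in specs.items():
        predict = spec["fitter"](r, d)
        coef = np.asarray([], dtype=float)
        if name == "POLY3":
            coef = fit_polynomial(r, d, 3)
            predict = _poly_predictor(coef)
        elif name == "LINFIT":
            coef = fit_linear(r, d)
            predict = _poly_predictor(coef)
        resid = np.asarray(predict(r), dtype=float) - d
        rss = float(np.sum(resid**2))
        if error_metric == "vertical":
            per_point = np.abs(resid)
        else:
            per_point = orthogonal_distances(r, d, predict, grid_step)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if criterion == "aic":
                aic_val = aic(n, rss, spec["k"])
            elif criterion == "aicc":
                aic_val = aicc(n, rss, spec["k"])
            else:
                raise ValueError("criterion must be 'aic' or 'aicc'")
        results.append(
            ModelFitResult(
                name=name,
                k=spec["k"],
                coefficients=coef,
                per_point_errors=per_point,
                rss=rss,
                orth_r2=orthogonal_r_squared(r, d, predict, grid_step),
                loo_error=loo_cv_error(r, d, spec["fitter"], error_metric, grid_step),
                aic=aic_val,
            )
        )
    all_errors = np.concatenate([res.per_point_errors for res in results])
    groups = np.zeros(all_errors.size, dtype=int)
    normed = normalized_errors(all_errors, groups)
    offset = 0
    for res in results:
        res.normalized_mean_error = float(normed[offset:offset + n].mean())
        offset += n
    pairwise = {}
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            a, b = results[i], results[j]
            if a.aic < b.aic or (a.aic == b.aic and a.k <= b.k):
                pairwise[(a.name, b.name)] = a.name
            else:
                pairwise[(a.name, b.name)] = b.name
    results.sort(key=lambda m: (m.aic, m.k))
    return ComparisonResult(results=results, pairwise_winners=pairwise)
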