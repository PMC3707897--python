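"""Measured and theoretical modulation coefficients.

The mathematical heart of the pattern-decorrelation (CD) analysis.  For each
voxel the measured modulation index

    d_M = ((C + S) - m(C, S)) / (C + S)

compares the response to simultaneous center-plus-surround stimulation,
m(C, S), with the unweighted sum of the component responses: d_M = 0 means no
interaction, d_M = 1 full suppression (m = 0), d_M = -1 response doubling.
Extreme values (|d_M| > 1) are retained; only voxels whose denominator is
exactly zero are excluded from means, and near-zero denominators are flagged
and counted.

The CD model posits that the combined response is the sum of decorrelated
component patterns C' = C - d*S and S' = S - d*C.  A single scalar d in
[-1, 1] removes the correlation between any two non-degenerate response
vectors; it solves

    (1 + d^2) * cov(C, S) - d * (var(C) + var(S)) = 0

and is computed here in the rationalized form
d_T = 2*cov / (V + sqrt(V^2 - 4*cov^2)) with V = var(C) + var(S), the root of
the quadratic that lies in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateInputError",
    "DecorrelationSolution",
    "ModulationResult",
    "pearson_correlation",
    "measured_d",
    "summarize_modulation",
    "theoretical_d",
    "d_T_oracle",
    "cd_curve",
    "voi_modulation",
    "subject_scatter",
]

SURROUND_COLUMNS = {"near": ("S_N", "m_C_SN"), "far": ("S_F", "m_C_SF")}


class DegenerateInputError(ValueError):
    """Raised when a pattern vector is constant or too short to correlate."""


def _validate_pair(x, y, min_len: int = 3):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("pattern vectors must have equal length")
    if x.size < min_len:
        raise DegenerateInputError(f"need at least {min_len} voxels, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("pattern vectors must be finite")
    return x, y


def pearson_correlation(x, y) -> float:
    """Pearson r between two voxel-pattern vectors (sample, n-1 moments)."""
    x, y = _validate_pair(x, y)
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(np.dot(xd, xd))
    sy = np.sqrt(np.dot(yd, yd))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    return float(np.clip(np.dot(xd, yd) / (sx * sy), -1.0, 1.0))


def measured_d(C, S, m, denom_epsilon: float = 1e-9):
    """Per-voxel measured modulation index d_M = ((C+S) - m) / (C+S).

    Returns ``(d, flagged)``: ``d`` is NaN where C+S is exactly zero
    (undefined, excluded from means downstream); ``flagged`` marks voxels with
    |C+S| < denom_epsilon, which are counted but retained.
    """
    C = np.asarray(C, dtype=float)
    S = np.asarray(S, dtype=float)
    m = np.asarray(m, dtype=float)
    if not (C.shape == S.shape == m.shape):
        raise ValueError("C, S and m must be aligned per voxel")
    denom = C + S
    flagged = np.abs(denom) < denom_epsilon
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom != 0.0, (denom - m) / denom, np.nan)
    return d, flagged


@dataclass
class ModulationResult:
    """Per-voxel d_M values with their VOI summary."""

    d: np.ndarray
    mean: float
    se: float
    n: int
    n_flagged: int


def summarize_modulation(d, flagged=None) -> ModulationResult:
    """Mean/SE of per-voxel d_M, excluding only exactly-undefined (NaN) voxels."""
    d = np.asarray(d, dtype=float)
    valid = np.isfinite(d)
    n = int(valid.sum())
    if n == 0:
        raise DegenerateInputError("no voxel has a defined modulation index")
    vals = d[valid]
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    n_flagged = int(np.asarray(flagged).sum()) if flagged is not None else 0
    return ModulationResult(d=d, mean=mean, se=se, n=n, n_flagged=n_flagged)


@dataclass
class DecorrelationSolution:
    """The fully decorrelating coefficient and the decorrelated pattern pair."""

    d_T: float
    residual_correlation: float
    C_prime: np.ndarray
    S_prime: np.ndarray


def theoretical_d(C, S) -> DecorrelationSolution:
    """Scalar d in [-1, 1] that decorrelates C' = C - d*S and S' = S - d*C."""
    C, S = _validate_pair(C, S)
    var_c = float(np.var(C, ddof=1))
    var_s = float(np.var(S, ddof=1))
    if var_c == 0.0 or var_s == 0.0:
        raise DegenerateInputError("variance of a pattern vector is zero")
    cov = float(np.cov(C, S, ddof=1)[0, 1])
    V = var_c + var_s
    if cov == 0.0:
        d = 0.0
    else:
        disc = max(V * V - 4.0 * cov * cov, 0.0)
        d = 2.0 * cov / (V + np.sqrt(disc))
        # one Newton step on g(d) = (1 + d^2) cov - d V sharpens the root
        gp = 2.0 * d * cov - V
        if gp != 0.0:
            d -= ((1.0 + d * d) * cov - d * V) / gp
        d = float(np.clip(d, -1.0, 1.0))
    C_prime = C - d * S
    S_prime = S - d * C
    try:
        resid = pearson_correlation(C_prime, S_prime)
    except DegenerateInputError:
        # |d| = 1 with C = +/-S collapses a decorrelated pattern to a constant
        resid = 0.0
    return DecorrelationSolution(
        d_T=d, residual_correlation=resid, C_prime=C_prime, S_prime=S_prime
    )


def _corr_profile(C, S, d_grid):
    """Literal Pearson correlation of (C - d S, S - d C) at each grid d."""
    Cd = C[None, :] - d_grid[:, None] * S[None, :]
    Sd = S[None, :] - d_grid[:, None] * C[None, :]
    Cd = Cd - Cd.mean(axis=1, keepdims=True)
    Sd = Sd - Sd.mean(axis=1, keepdims=True)
    num = (Cd * Sd).sum(axis=1)
    den = np.sqrt((Cd**2).sum(axis=1) * (Sd**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def d_T_oracle(C, S, grid_step: float = 1e-4) -> float:
    """Brute-force decorrelating coefficient, for verification only.

    Grid search over d in [-1, 1] minimizing |corr(C - d S, S - d C)|,
    followed by bisection on the sign change of the correlation, refined to
    1e-8.  Independent of the closed form in :func:`theoretical_d`.
    """
    C, S = _validate_pair(C, S)
    if np.var(C, ddof=1) == 0.0 or np.var(S, ddof=1) == 0.0:
        raise DegenerateInputError("variance of a pattern vector is zero")
    grid = np.linspace(-1.0, 1.0, int(round(2.0 / grid_step)) + 1)
    corr = _corr_profile(C, S, grid)
    best = int(np.nanargmin(np.abs(corr)))

    def corr_at(d):
        return float(_corr_profile(C, S, np.array([d]))[0])

    lo = max(best - 1, 0)
    hi = min(best + 1, grid.size - 1)
    a, b = grid[lo], grid[hi]
    fa, fb = corr[lo], corr[hi]
    if not (np.isfinite(fa) and np.isfinite(fb) and fa * fb <= 0):
        return float(grid[best])
    for _ in range(100):
        mid = 0.5 * (a + b)
        fm = corr_at(mid)
        if not np.isfinite(fm) or b - a < 1e-10:
            break
        if fa * fm <= 0:
            b, fb = mid, fm
        else:
            a, fa = mid, fm
        if abs(fm) < 1e-12:
            return float(mid)
    return float(0.5 * (a + b))


def cd_curve(r, variance_ratio: float = 1.0):
    """CD-model prediction d_T as a function of pattern correlation r.

    ``variance_ratio`` is var(S)/var(C); d_T depends on the variances only
    through this ratio.  For equal variances the curve reduces to
    (1 - sqrt(1 - r^2)) / r, continuously extended to 0 at r = 0.
    """
    if variance_ratio <= 0:
        raise ValueError("variance_ratio must be positive")
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1):
        raise ValueError("|r| must not exceed 1")
    rho = float(variance_ratio)
    V = 1.0 + rho
    cov = r_arr * np.sqrt(rho)
    disc = np.maximum(V * V - 4.0 * cov * cov, 0.0)
    d = 2.0 * cov / (V + np.sqrt(disc))
    return float(d) if np.isscalar(r) else d


def voi_modulation(
    table: pd.DataFrame,
    voi: str,
    surround: str = "near",
    theta: float = 0.25,
    denom_epsilon: float = 1e-9,
    geometry=None,
):
    """Mean measured modulation, pattern correlation and d_T within one VOI.

    Restricts the table to the VOI's voxels, computes per-voxel d_M for the
    chosen surround ('near' or 'far'), its mean and SE, the Pearson
    correlation between the C and S patterns over the same voxels, and the
    fully decorrelating d_T of those patterns.
    """
    from .voi import select_voi

    if surround not in SURROUND_COLUMNS:
        raise ValueError("surround must be 'near' or 'far'")
    s_col, m_col = SURROUND_COLUMNS[surround]
    rows = select_voi(table, voi, theta=theta, geometry=geometry)
    if len(rows) < 3:
        raise ValueError(f"VOI {voi!r} selects only {len(rows)} voxels (need >= 3)")
    C = rows["C"].to_numpy()
    S = rows[s_col].to_numpy()
    m = rows[m_col].to_numpy()
    d, flagged = measured_d(C, S, m, denom_epsilon=denom_epsilon)
    result = summarize_modulation(d, flagged)
    r = pearson_correlation(C, S)
    sol = theoretical_d(C, S)
    return {
        "voi": voi,
        "surround": surround,
        "n": result.n,
        "n_flagged": result.n_flagged,
        "mean_d": result.mean,
        "se_d": result.se,
        "r": r,
        "d_T": sol.d_T,
        "modulation": result,
        "solution": sol,
    }


def subject_scatter(
    table: pd.DataFrame,
    voi: str,
    surround: str = "near",
    theta: float = 0.25,
    denom_epsilon: float = 1e-9,
    geometry=None,
) -> pd.DataFrame:
    """One (r, mean d_M, SE) point per subject for a VOI/surround condition.

    The per-subject path: correlation and mean modulation are computed within
    each subject's own voxels, yielding the scatter that the model comparison
    consumes.
    """
    points = []
    for subject, rows in table.groupby("subject"):
        res = voi_modulation(
            rows, voi, surround=surround, theta=theta,
            denom_epsilon=denom_epsilon, geometry=geometry,
        )
        points.append(
            {
                "subject": subject,
                "condition": f"{voi}:{surround}",
                "r": res["r"],
                "mean_d": res["mean_d"],
                "se": res["se_d"],
            }
        )
    return pd.DataFrame(points)
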