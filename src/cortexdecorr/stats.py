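"""Nonparametric statistics for the interaction analysis.

The sign-versus-modulation contingency classifies each voxel by whether the
center and surround responses share a sign and by the sign of its measured
modulation index (positive = suppressive, negative = facilitative).  The
accompanying tests are the exact binomial sign test, the Mann-Whitney U test
(exact for small untied samples, normal approximation with tie correction
otherwise), the two-sample Kolmogorov-Smirnov test and the Friedman test, all
delegated to scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import SURROUND_COLUMNS, measured_d
from .voi import select_voi

__all__ = [
    "SignContingency",
    "sign_contingency",
    "sign_test",
    "mann_whitney_u",
    "ks_two_sample",
    "friedman",
    "chance_level",
]


@dataclass
class SignContingency:
    """2x2 voxel counts: (same vs. different C/S sign) x (suppressive vs. facilitative)."""

    n_suppression_same: int
    n_suppression_diff: int
    n_facilitation_same: int
    n_facilitation_diff: int
    n_excluded: int

    @property
    def total(self) -> int:
        return (
            self.n_suppression_same
            + self.n_suppression_diff
            + self.n_facilitation_same
            + self.n_facilitation_diff
        )

    def odds_ratio(self) -> float:
        """Association between same-sign responses and suppression (>1 = the
        suppressive-when-same / facilitative-when-different pattern)."""
        a, b = self.n_suppression_same, self.n_suppression_diff
        c, d = self.n_facilitation_same, self.n_facilitation_diff
        if b * c == 0:
            return np.inf if a * d > 0 else np.nan
        return (a * d) / (b * c)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "same_sign": [self.n_suppression_same, self.n_facilitation_same],
                "different_sign": [self.n_suppression_diff, self.n_facilitation_diff],
            },
            index=["suppression (d_M > 0)", "facilitation (d_M < 0)"],
        )


def sign_contingency(
    table: pd.DataFrame,
    voi: str = "VOI_AVA",
    surround: str = "near",
    theta: float = 0.25,
    denom_epsilon: float = 1e-9,
    geometry=None,
) -> SignContingency:
    """Classify VOI voxels by C/S response-sign agreement and modulation sign.

    Voxels with an exactly zero C or S response, or with a zero or undefined
    d_M, are excluded and counted; classification of the rest is exhaustive
    and exclusive.
    """
    if surround not in SURROUND_COLUMNS:
        raise ValueError("surround must be 'near' or 'far'")
    s_col, m_col = SURROUND_COLUMNS[surround]
    rows = select_voi(table, voi, theta=theta, geometry=geometry)
    if len(rows) == 0:
        raise ValueError(f"VOI {voi!r} selects no voxels")
    C = rows["C"].to_numpy()
    S = rows[s_col].to_numpy()
    m = rows[m_col].to_numpy()
    d, _ = measured_d(C, S, m, denom_epsilon=denom_epsilon)
    sign_ok = (C != 0) & (S != 0)
    d_ok = np.isfinite(d) & (d != 0)
    keep = sign_ok & d_ok
    same = np.sign(C[keep]) == np.sign(S[keep])
    supp = d[keep] > 0
    return SignContingency(
        n_suppression_same=int(np.sum(supp & same)),
        n_suppression_diff=int(np.sum(supp & ~same)),
        n_facilitation_same=int(np.sum(~supp & same)),
        n_facilitation_diff=int(np.sum(~supp & ~same)),
        n_excluded=int(np.sum(~keep)),
    )


def sign_test(values, hypothesized_median: float = 0.0) -> float:
    """Exact two-sided binomial sign test; exact zeros are dropped."""
    values = np.asarray(values, dtype=float).ravel()
    diffs = values - hypothesized_median
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        raise ValueError("sign test undefined: all values equal the hypothesized median")
    n_pos = int(np.sum(diffs > 0))
    return float(sps.binomtest(n_pos, diffs.size, 0.5).pvalue)


def mann_whitney_u(x, y):
    """Two-sided Mann-Whitney U test.

    Exact p-value for small samples (n*m <= 400 with no ties), normal
    approximation with tie correction otherwise.  Returns ``(U, p)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ks_two_sample(x, y):
    """Two-sided two-sample Kolmogorov-Smirnov test; asymptotic p.  Returns (D, p)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 observations")
    res = sps.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def friedman(blocked):
    """Friedman test on a complete subjects x conditions block design.

    Rows are blocks (subjects), columns conditions.  Fully tied data (every
    block constant) yield statistic 0, p 1.  Returns ``(chi2, p)``.
    """
    data = np.asarray(blocked, dtype=float)
    if data.ndim != 2:
        raise ValueError("blocked data must be 2-D (subjects x conditions)")
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if not np.all(np.isfinite(data)):
        raise ValueError("incomplete blocks: non-finite entries present")
    if np.all(data == data[:, [0]]):
        return 0.0, 1.0
    res = sps.friedmanchisquare(*(data[:, j] for j in range(data.shape[1])))
    return float(res.statistic), float(res.pvalue)


def chance_level(n_alternatives: int) -> float:
    """Guessing probability in percent among n equiprobable alternatives."""
    if n_alternatives < 2:
        raise ValueError("need at least 2 alternatives")
    return 100.0 / n_alternatives
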