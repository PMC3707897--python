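"""Eccentricity profiles of BOLD change, zero crossings and cortical spread.

For each functional area and stimulus condition, the per-ring mean percent
BOLD change describes how far the response spreads along the eccentricity
axis.  A 2nd-degree polynomial fit to the profile locates the eccentricity
where the positive signal turns negative, travelling centrally or
peripherally from a stimulus edge; crossings outside the sampled range
[1 deg, 12 deg] are censored as "<1" / ">12".  Visual-field extents convert
to cortical millimetres via the logarithmic magnification mapping, so
censored crossings yield lower bounds on the spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import SURROUND_COLUMNS, measured_d, summarize_modulation, theoretical_d
from .geometry import StudyGeometry, cortical_position, ring_midpoints
from .voi import select_voi

__all__ = [
    "EccentricityProfile",
    "CrossingEstimate",
    "SpreadEstimate",
    "profile",
    "zero_crossing",
    "spread_mm",
    "select_voi",
    "resampling_error",
]


@dataclass
class EccentricityProfile:
    """Per-ring mean +/- SE of one condition's BOLD change in one area."""

    area: str
    condition: str
    ring_ecc: np.ndarray
    means: np.ndarray
    ses: np.ndarray
    level: str
    n_per_ring: np.ndarray
    subject_means: Optional[np.ndarray] = None  # subjects x rings, group level


def profile(
    table: pd.DataFrame,
    area: str,
    condition: str,
    level: str = "group",
    subject=None,
    geometry: StudyGeometry | None = None,
    midpoint_scale: str = "linear",
) -> EccentricityProfile:
    """Eccentricity profile of one condition in one area.

    ``level='subject'`` averages across one subject's voxels per ring (SE
    across voxels); ``level='group'`` first averages within each subject and
    then across subjects (SE across subjects).
    """
    geometry = geometry or StudyGeometry()
    rows = table.loc[table["area"] == area]
    if condition not in table.columns:
        raise ValueError(f"unknown condition column {condition!r}")
    ring_ecc = ring_midpoints(geometry, scale=midpoint_scale)
    n_rings = geometry.n_rings

    if level == "subject":
        if subject is None:
            raise ValueError("subject-level profile requires a subject id")
        rows = rows.loc[rows["subject"] == subject]
        means = np.full(n_rings, np.nan)
        ses = np.full(n_rings, np.nan)
        counts = np.zeros(n_rings, dtype=int)
        for i in range(n_rings):
            vals = rows.loc[rows["ring"] == i + 1, condition].to_numpy()
            if vals.size == 0:
                raise ValueError(f"ring {i + 1} has no voxels for subject {subject}")
            counts[i] = vals.size
            means[i] = vals.mean()
            ses[i] = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        return EccentricityProfile(
            area, condition, ring_ecc, means, ses, "subject", counts
        )

    if level != "group":
        raise ValueError("level must be 'subject' or 'group'")
    subjects = sorted(rows["subject"].unique())
    subj_means = np.full((len(subjects), n_rings), np.nan)
    for si, subj in enumerate(subjects):
        sub = rows.loc[rows["subject"] == subj]
        for i in range(n_rings):
            vals = sub.loc[sub["ring"] == i + 1, condition].to_numpy()
            if vals.size == 0:
                raise ValueError(f"ring {i + 1} has no voxels for subject {subj}")
            subj_means[si, i] = vals.mean()
    if subj_means.shape[0] < 2:
        raise ValueError("group-level profile requires at least 2 subjects")
    means = subj_means.mean(axis=0)
    ses = subj_means.std(axis=0, ddof=1) / np.sqrt(subj_means.shape[0])
    counts = np.full(n_rings, subj_means.shape[0])
    return EccentricityProfile(
        area, condition, ring_ecc, means, ses, "group", counts, subj_means
    )


@dataclass
class CrossingEstimate:
    """Zero-crossing eccentricity of a profile, possibly censored.

    ``crossing`` is +inf when the signal stays positive out to the peripheral
    border (reported ">12") and -inf when it stays positive down to the
    central border ("<1"); the CI bounds use the same convention.
    """

    direction: str
    reference_edge: float
    crossing: float
    ci: tuple[float, float]
    lo_border: float = 1.0
    hi_border: float = 12.0

    def _fmt(self, value: float) -> str:
        if value == np.inf or (np.isfinite(value) and value > self.hi_border):
            return f">{self.hi_border:g}"
        if value == -np.inf or (np.isfinite(value) and value < self.lo_border):
            return f"<{self.lo_border:g}"
        if np.isnan(value):
            return "n/a"
        return f"{value:.1f}"

    @property
    def censored(self) -> bool:
        return not (
            np.isfinite(self.crossing)
            and self.lo_border <= self.crossing <= self.hi_border
        )

    def format_degrees(self) -> str:
        return f"{self._fmt(self.crossing)} ({self._fmt(self.ci[0])} - {self._fmt(self.ci[1])})"


def _crossing_from_means(ring_ecc, means, direction, reference_edge):
    """Root of the 2nd-degree polynomial fit nearest the edge in the travel direction.

    Returns +inf (peripheral travel, no crossing) or -inf (central travel, no
    crossing) when the fitted signal does not cross zero on the travel side.
    """
    finite = np.isfinite(means)
    if finite.sum() < 3:
        raise ValueError("need at least 3 rings with finite means")
    coeffs = np.polyfit(ring_ecc[finite], means[finite], 2)
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9].real
    if direction == "peripheral":
        cands = real[real >= reference_edge]
        return float(cands.min()) if cands.size else np.inf
    if direction == "central":
        cands = real[real <= reference_edge]
        return float(cands.max()) if cands.size else -np.inf
    raise ValueError("direction must be 'central' or 'peripheral'")


def zero_crossing(
    prof: EccentricityProfile,
    direction: str,
    reference_edge: float,
    n_boot: int = 1000,
    seed: int = 0,
    geometry: StudyGeometry | None = None,
) -> CrossingEstimate:
    """Eccentricity where the fitted profile crosses zero, with 95% bootstrap CI.

    The CI resamples subjects with replacement (group-level profiles only;
    subject-level profiles return a NaN CI).  Crossings outside the sampled
    eccentricities are censored, never raised.
    """
    geometry = geometry or StudyGeometry()
    crossing = _crossing_from_means(prof.ring_ecc, prof.means, direction, reference_edge)
    lo_b, hi_b = geometry.ring_borders[0], geometry.ring_borders[-1]
    ci = (np.nan, np.nan)
    if prof.subject_means is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        n_subj = prof.subject_means.shape[0]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.integers(0, n_subj, size=n_subj)
            means_b = prof.subject_means[pick].mean(axis=0)
            boots[b] = _crossing_from_means(
                prof.ring_ecc, means_b, direction, reference_edge
            )
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (float(lo), float(hi))
    return CrossingEstimate(
        direction=direction,
        reference_edge=reference_edge,
        crossing=crossing,
        ci=ci,
        lo_border=lo_b,
        hi_border=hi_b,
    )


@dataclass
class SpreadEstimate:
    """Cortical spread in mm; a lower bound when the crossing was censored."""

    mm: float
    is_lower_bound: bool

    def format_mm(self) -> str:
        prefix = ">" if self.is_lower_bound else ""
        return f"{prefix}{self.mm:.1f} mm"


def spread_mm(
    reference_edge: float,
    crossing: CrossingEstimate,
    geometry: StudyGeometry | None = None,
) -> SpreadEstimate:
    """Cortical distance between a stimulus edge and the zero crossing.

    Censored crossings are evaluated at the sampled-range border, giving a
    "greater-than" lower bound on the spread.
    """
    geometry = geometry or StudyGeometry()
    value = crossing.crossing
    censored = crossing.censored
    if not np.isfinite(value):
        value = crossing.hi_border if value > 0 else crossing.lo_border
    value = float(np.clip(value, crossing.lo_border, crossing.hi_border))
    mm = float(
        abs(
            cortical_position(value, geometry)
            - cortical_position(reference_edge, geometry)
        )
    )
    return SpreadEstimate(mm=mm, is_lower_bound=censored)


def resampling_error(
    table: pd.DataFrame,
    voi: str,
    surround: str = "near",
    n_voxels: int = 20,
    n_repeats: int = 100,
    seed: int = 0,
    theta: float = 0.25,
    geometry: StudyGeometry | None = None,
) -> float:
    """Fixed-size resampling error between mean d_M and d_T within a VOI.

    Per repeat, ``n_voxels`` suprathreshold voxels are drawn without
    replacement, the squared difference (mean d_M - d_T)^2 is computed with
    d_T evaluated on the same sampled voxels, and the repeats are averaged.
    A fixed selection size makes the error comparable across VOIs of
    different sizes.
    """
    if surround not in SURROUND_COLUMNS:
        raise ValueError("surround must be 'near' or 'far'")
    s_col, m_col = SURROUND_COLUMNS[surround]
    rows = select_voi(table, voi, theta=theta, geometry=geometry)
    if len(rows) < n_voxels:
        raise ValueError(
            f"VOI {voi!r} has only {len(rows)} suprathreshold voxels, need {n_voxels}"
        )
    C = rows["C"].to_numpy()
    S = rows[s_col].to_numpy()
    m = rows[m_col].to_numpy()
    rng = np.random.default_rng(seed)
    errors = np.empty(n_repeats)
    for rep in range(n_repeats):
        idx = rng.choice(C.size, size=n_voxels, replace=False)
        d, flagged = measured_d(C[idx], S[idx], m[idx])
        mean_d = summarize_modulation(d, flagged).mean
        d_t = theoretical_d(C[idx], S[idx]).d_T
        errors[rep] = (mean_d - d_t) ** 2
    return float(errors.mean())
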