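"""Visual-field geometry of the center--surround study and cortical magnification.

The study design samples five concentric eccentricity rings (borders at 1,
2.3, 4.0, 6.1, 8.7 and 12 degrees).  The center stimulus is an annulus from
1 to 2.3 deg, the near surround from 2.5 to 4.0 deg (a small gap separates
it from the center), and the far surround from 8.7 to 12 deg.  Cortical
position along the eccentricity axis follows the logarithmic magnification
mapping

    x(E) = k * ln((E + a) / a)

with generic human parameters a = 1 deg, k = 17 mm, so distances between
eccentricity representations are differences of positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StudyGeometry",
    "cortical_position",
    "eccentricity_at_position",
    "cortical_distance",
    "assign_ring",
    "ring_midpoints",
]


@dataclass(frozen=True)
class StudyGeometry:
    """Ring borders, stimulus extents, area labels and magnification constants."""

    ring_borders: tuple[float, ...] = (1.0, 2.3, 4.0, 6.1, 8.7, 12.0)
    center_stim: tuple[float, float] = (1.0, 2.3)
    near_surround_stim: tuple[float, float] = (2.5, 4.0)
    far_surround_stim: tuple[float, float] = (8.7, 12.0)
    areas: tuple[str, ...] = ("V1", "V2", "V3")
    magnification_a: float = 1.0
    magnification_k: float = 17.0

    def __post_init__(self) -> None:
        borders = np.asarray(self.ring_borders, dtype=float)
        if borders.size < 2 or np.any(np.diff(borders) <= 0):
            raise ValueError("ring borders must be strictly increasing")
        lo, hi = borders[0], borders[-1]
        for name in ("center_stim", "near_surround_stim", "far_surround_stim"):
            a, b = getattr(self, name)
            if not (lo <= a < b <= hi):
                raise ValueError(
                    f"{name}=({a}, {b}) must lie within the sampled range [{lo}, {hi}]"
                )
        if self.center_stim[1] >= self.near_surround_stim[0]:
            raise ValueError("center and near surround must be separated by a gap")
        if self.magnification_a <= 0 or self.magnification_k <= 0:
            raise ValueError("magnification parameters a and k must be positive")
        if not self.areas:
            raise ValueError("at least one area label is required")

    @property
    def n_rings(self) -> int:
        return len(self.ring_borders) - 1

    def stimulus_extent(self, condition: str) -> tuple[float, float]:
        """Stimulus annulus (deg) generating condition ``C``, ``S_N`` or ``S_F``."""
        try:
            return {
                "C": self.center_stim,
                "S_N": self.near_surround_stim,
                "S_F": self.far_surround_stim,
            }[condition]
        except KeyError:
            raise ValueError(f"unknown stimulus condition {condition!r}") from None


def cortical_position(eccentricity, geometry: StudyGeometry | None = None):
    """Cortical position in mm of an eccentricity: k * ln((E + a) / a).

    Strictly increasing in E; E = 0 maps to 0 mm.  Negative eccentricity is a
    domain error.
    """
    geometry = geometry or StudyGeometry()
    ecc = np.asarray(eccentricity, dtype=float)
    if np.any(ecc < 0):
        raise ValueError("eccentricity must be non-negative")
    pos = geometry.magnification_k * np.log(
        (ecc + geometry.magnification_a) / geometry.magnification_a
    )
    return float(pos) if np.isscalar(eccentricity) else pos


def eccentricity_at_position(position_mm, geometry: StudyGeometry | None = None):
    """Inverse magnification mapping: E = a * (exp(x / k) - 1)."""
    geometry = geometry or StudyGeometry()
    pos = np.asarray(position_mm, dtype=float)
    ecc = geometry.magnification_a * (
        np.exp(pos / geometry.magnification_k) - 1.0
    )
    return float(ecc) if np.isscalar(position_mm) else ecc


def cortical_distance(ecc_a, ecc_b, geometry: StudyGeometry | None = None):
    """Cortical distance (mm) between two eccentricity representations."""
    return np.abs(cortical_position(ecc_a, geometry) - cortical_position(ecc_b, geometry))


def assign_ring(eccentricity, geometry: StudyGeometry | None = None):
    """1-based ring index of each eccentricity; values outside the borders error."""
    geometry = geometry or StudyGeometry()
    ecc = np.atleast_1d(np.asarray(eccentricity, dtype=float))
    borders = np.asarray(geometry.ring_borders, dtype=float)
    if np.any(ecc < borders[0]) or np.any(ecc > borders[-1]):
        raise ValueError("eccentricity outside the sampled ring borders")
    idx = np.clip(np.searchsorted(borders, ecc, side="right") - 1, 0, geometry.n_rings - 1)
    rings = idx + 1
    return int(rings[0]) if np.isscalar(eccentricity) else rings


def ring_midpoints(geometry: StudyGeometry | None = None, scale: str = "linear"):
    """Representative eccentricity per ring.

    ``linear`` (default) is the arithmetic midpoint of the ring borders
    (1.65, 3.15, 5.05, 7.4, 10.35 deg for the default geometry); ``log`` is
    the geometric midpoint of (E + a), i.e. the midpoint on the cortical axis.
    """
    geometry = geometry or StudyGeometry()
    borders = np.asarray(geometry.ring_borders, dtype=float)
    if scale == "linear":
        return 0.5 * (borders[:-1] + borders[1:])
    if scale == "log":
        a = geometry.magnification_a
        return np.sqrt((borders[:-1] + a) * (borders[1:] + a)) - a
    raise ValueError("scale must be 'linear' or 'log'")
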