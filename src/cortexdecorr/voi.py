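"""Rule-based voxel-of-interest (VOI) selections.

Three families of selections, mirroring the study's Table-1 scheme:
condition-active sets (VOI_C, VOI_SN, VOI_SF and the any-condition union
VOI_AVA), eccentricity-ring sets (VOI_RING1..VOI_RING5), and functional-area
sets (VOI_V1, ...).  Activity thresholding is emulated by an absolute
percent-change criterion |response| >= theta on the rule's defining
condition(s); synthetic condition estimates carry no time series, so no
t-statistic is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import StudyGeometry

__all__ = ["voi_names", "select_voi"]

_CONDITION_VOIS = {
    "VOI_C": ("C",),
    "VOI_SN": ("S_N",),
    "VOI_SF": ("S_F",),
    "VOI_AVA": ("C", "S_N", "S_F", "m_C_SN", "m_C_SF"),
}


def voi_names(geometry: StudyGeometry | None = None) -> list[str]:
    """All valid VOI rule names for a geometry."""
    geometry = geometry or StudyGeometry()
    names = list(_CONDITION_VOIS)
    names += [f"VOI_RING{i}" for i in range(1, geometry.n_rings + 1)]
    names += [f"VOI_{a}" for a in geometry.areas]
    return names


def _threshold_mask(table: pd.DataFrame, columns, theta: float) -> np.ndarray:
    mask = np.zeros(len(table), dtype=bool)
    for col in columns:
        mask |= np.abs(table[col].to_numpy()) >= theta
    return mask


def select_voi(
    table: pd.DataFrame,
    rule: str,
    theta: float = 0.25,
    geometry: StudyGeometry | None = None,
) -> pd.DataFrame:
    """Rows of the table passing a named VOI rule.

    Ring and area VOIs additionally require the any-condition activity
    criterion, so with theta = 0 the ring VOIs partition the table and
    VOI_AVA returns every voxel.  Raising theta never grows a VOI.
    """
    geometry = geometry or StudyGeometry()
    valid = voi_names(geometry)
    if rule not in valid:
        raise ValueError(f"unknown VOI rule {rule!r}; valid names: {', '.join(valid)}")
    union_cols = _CONDITION_VOIS["VOI_AVA"]
    if rule in _CONDITION_VOIS:
        mask = _threshold_mask(table, _CONDITION_VOIS[rule], theta)
    elif rule.startswith("VOI_RING"):
        ring = int(rule[len("VOI_RING"):])
        mask = (table["ring"].to_numpy() == ring) & _threshold_mask(
            table, union_cols, theta
        )
    else:
        area = rule[len("VOI_"):]
        mask = (table["area"].to_numpy() == area) & _threshold_mask(
            table, union_cols, theta
        )
    return table.loc[mask]
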