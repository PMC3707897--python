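"""Readers and writers for the tabular exchange formats.

The canonical interchange object is the voxel table: comma-separated text,
one row per voxel, with columns subject, hemisphere, area, ring,
eccentricity_deg and the five condition estimates C, S_N, S_F, m_C_SN,
m_C_SF in percent BOLD change.  Configurations are YAML or JSON; nested
results are JSON.  An optional NIfTI adapter extracts masked per-condition
percent-change volumes into the same schema.
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np
import pandas as pd
import yaml

from .synth import TABLE_COLUMNS, GenerationConfig

__all__ = [
    "SchemaError",
    "read_voxel_table",
    "write_voxel_table",
    "read_generation_config",
    "import_nifti_summary",
]

_NUMERIC_COLUMNS = ["eccentricity_deg", "C", "S_N", "S_F", "m_C_SN", "m_C_SF"]
_KEY_COLUMNS = ["subject", "hemisphere", "area", "ring", "eccentricity_deg"]


class SchemaError(ValueError):
    """A voxel-table file violates the canonical schema."""


def read_voxel_table(path) -> pd.DataFrame:
    """Read and validate a voxel table; schema errors name the offending lines."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    table = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in _NUMERIC_COLUMNS:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[vals.isna()].to_numpy()
        if bad.size:
            lines = ", ".join(str(i + 2) for i in bad[:10])
            raise SchemaError(f"{path}: non-numeric or missing {col!r} at line(s) {lines}")
        table[col] = vals
        if not np.all(np.isfinite(vals.to_numpy())):
            raise SchemaError(f"{path}: non-finite values in column {col!r}")
    dup = table.duplicated(subset=_KEY_COLUMNS)
    if dup.any():
        lines = ", ".join(str(i + 2) for i in table.index[dup][:10])
        raise SchemaError(f"{path}: duplicated voxel keys at line(s) {lines}")
    return table[TABLE_COLUMNS]


def write_voxel_table(table: pd.DataFrame, path, overwrite: bool = False) -> None:
    """Write a voxel table as comma-separated text (refuses to clobber by default)."""
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cannot write table missing columns {missing}")
    table[TABLE_COLUMNS].to_csv(path, index=False)


def read_generation_config(path) -> GenerationConfig:
    """Load a GenerationConfig from a YAML or JSON mapping."""
    with open(path) as fh:
        if str(path).endswith(".json"):
            payload = json.load(fh)
        else:
            payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise SchemaError(f"{path}: expected a mapping of config fields")
    valid = {f.name for f in dataclasses.fields(GenerationConfig)}
    unknown = sorted(set(payload) - valid)
    if unknown:
        raise SchemaError(f"{path}: unknown config fields {unknown}")
    config = GenerationConfig(**payload)
    config.validate()
    return config


def import_nifti_summary(condition_volumes, mask_path, labels) -> pd.DataFrame:
    """Extract masked voxel values from per-condition NIfTI volumes.

    ``condition_volumes`` maps each condition column (C, S_N, S_F, m_C_SN,
    m_C_SF) to a NIfTI path holding that condition's percent-change map; all
    volumes and the mask must share a grid.  ``labels`` supplies the
    non-condition columns (subject, hemisphere, area, ring, eccentricity_deg)
    as scalars or per-voxel sequences aligned with the masked voxels in
    C-order.
    """
    import nibabel as nib

    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask selects no voxels")
    data = {}
    for cond in _NUMERIC_COLUMNS[1:]:
        if cond not in condition_volumes:
            raise SchemaError(f"missing volume for condition {cond!r}")
        img = nib.load(str(condition_volumes[cond]))
        if img.shape != mask_img.shape or not np.allclose(img.affine, mask_img.affine):
            raise ValueError(f"volume for {cond!r} does not share the mask's grid")
        data[cond] = np.asarray(img.dataobj)[mask].astype(float)
    for key in _KEY_COLUMNS:
        if key not in labels:
            raise SchemaError(f"missing label column {key!r}")
        val = labels[key]
        arr = np.repeat(val, n) if np.isscalar(val) else np.asarray(val)
        if arr.shape != (n,):
            raise ValueError(f"label {key!r} must be scalar or length {n}")
        data[key] = arr
    return pd.DataFrame(data)[TABLE_COLUMNS]
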