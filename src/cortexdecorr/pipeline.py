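"""Top-level analysis pipeline: generation -> modulation -> comparison -> spread -> signs.

One reproducible run writes, under an output directory: the (generated or
loaded) voxel table, the per-VOI modulation summary, the per-subject
(r, mean d_M) scatter with the four-model comparison, a Table-2-shaped spread
report with censored crossings rendered as "<1"/" >12" strings, the
Table-3-shaped sign contingency with the Mann-Whitney comparison, and a JSON
manifest carrying versions, seeds and the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .core import subject_scatter, voi_modulation
from .geometry import StudyGeometry
from .io import read_voxel_table, write_voxel_table
from .models import compare_models
from .spread import profile, spread_mm, zero_crossing
from .stats import mann_whitney_u, sign_contingency
from .synth import GenerationConfig, generate_study
from .core import SURROUND_COLUMNS, measured_d
from .voi import select_voi

logger = logging.getLogger("cortexdecorr")

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]

# (VOI, surround) pairs of the scatter/model-comparison stage: the center VOI
# under both surrounds plus each surround's own VOI.
SCATTER_CONDITIONS = (
    ("VOI_C", "near"),
    ("VOI_C", "far"),
    ("VOI_SN", "near"),
    ("VOI_SF", "far"),
)

# (condition, direction, reference edge attribute) rows of the spread report.
SPREAD_CASES = (
    ("C", "peripheral", lambda g: g.center_stim[1]),
    ("S_N", "central", lambda g: g.near_surround_stim[0]),
    ("S_N", "peripheral", lambda g: g.near_surround_stim[1]),
    ("S_F", "central", lambda g: g.far_surround_stim[0]),
)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    out_dir: str
    table_path: Optional[str] = None
    generation: Optional[GenerationConfig] = None
    geometry: StudyGeometry = field(default_factory=StudyGeometry)
    vois: tuple = ("VOI_C", "VOI_SN", "VOI_SF", "VOI_AVA")
    surrounds: tuple = ("near", "far")
    theta: float = 0.25
    error_metric: str = "vertical"
    n_boot: int = 1000
    seed: int = 0
    overwrite: bool = False

    def to_json_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        return payload

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_json_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("input")
def _load_or_generate(config: RunConfig):
    if config.table_path is not None:
        table = read_voxel_table(config.table_path)
        logger.info("loaded %d voxels from %s", len(table), config.table_path)
        return table, None
    gen = config.generation or GenerationConfig(seed=config.seed)
    table, truth = generate_study(gen, config.geometry)
    logger.info("generated %d voxels (rule %s)", len(table), gen.interaction_rule)
    return table, truth


@_stage("modulation")
def _modulation_report(table, config: RunConfig) -> pd.DataFrame:
    rows = []
    for voi in config.vois:
        for surround in config.surrounds:
            res = voi_modulation(
                table, voi, surround=surround, theta=config.theta,
                geometry=config.geometry,
            )
            rows.append({k: res[k] for k in
                         ("voi", "surround", "n", "n_flagged", "mean_d", "se_d", "r", "d_T")})
            logger.info("VOI %s/%s: n=%d mean d_M=%.3f d_T=%.3f",
                        voi, surround, res["n"], res["mean_d"], res["d_T"])
    return pd.DataFrame(rows)


@_stage("model_comparison")
def _comparison_report(table, config: RunConfig):
    scatter_frames = []
    comparison_rows = []
    for voi, surround in SCATTER_CONDITIONS:
        sc = subject_scatter(table, voi, surround=surround, theta=config.theta,
                             geometry=config.geometry)
        scatter_frames.append(sc)
        if len(sc) >= 6:
            comp = compare_models(sc["r"], sc["mean_d"],
                                  error_metric=config.error_metric)
            for rank, res in enumerate(comp.results, start=1):
                comparison_rows.append({
                    "condition": f"{voi}:{surround}",
                    "rank": rank,
                    "model": res.name,
                    "k": res.k,
                    "rss": res.rss,
                    "orth_r2": res.orth_r2,
                    "loo_error": res.loo_error,
                    "normalized_mean_error": res.normalized_mean_error,
                    "aic": res.aic,
                    "pairwise_wins": comp.wins(res.name),
                })
    return pd.concat(scatter_frames, ignore_index=True), pd.DataFrame(comparison_rows)


@_stage("spread")
def _spread_report(table, config: RunConfig) -> pd.DataFrame:
    rows = []
    for area in config.geometry.areas:
        for condition, direction, edge_of in SPREAD_CASES:
            edge = edge_of(config.geometry)
            prof = profile(table, area, condition, level="group",
                           geometry=config.geometry)
            crossing = zero_crossing(prof, direction, edge, n_boot=config.n_boot,
                                     seed=config.seed, geometry=config.geometry)
            spread = spread_mm(edge, crossing, config.geometry)
            rows.append({
                "area": area,
                "condition": condition,
                "direction": direction,
                "reference_edge_deg": edge,
                "crossing": crossing._fmt(crossing.crossing),
                "ci_low": crossing._fmt(crossing.ci[0]),
                "ci_high": crossing._fmt(crossing.ci[1]),
                "spread_mm": f"{'>' if spread.is_lower_bound else ''}{spread.mm:.1f}",
            })
    return pd.DataFrame(rows)


@_stage("signs")
def _signs_report(table, config: RunConfig) -> pd.DataFrame:
    rows = []
    for surround in config.surrounds:
        cont = sign_contingency(table, "VOI_AVA", surround=surround,
                                theta=config.theta, geometry=config.geometry)
        s_col, m_col = SURROUND_COLUMNS[surround]
        sel = select_voi(table, "VOI_AVA", theta=config.theta,
                         geometry=config.geometry)
        C = sel["C"].to_numpy()
        S = sel[s_col].to_numpy()
        d, _ = measured_d(C, S, sel[m_col].to_numpy())
        keep = np.isfinite(d) & (C != 0) & (S != 0)
        same = np.sign(C[keep]) == np.sign(S[keep])
        d_kept = d[keep]
        if same.any() and (~same).any():
            u_stat, p = mann_whitney_u(d_kept[same], d_kept[~same])
        else:
            u_stat, p = np.nan, np.nan
        rows.append({
            "surround": surround,
            "n_suppression_same": cont.n_suppression_same,
            "n_suppression_diff": cont.n_suppression_diff,
            "n_facilitation_same": cont.n_facilitation_same,
            "n_facilitation_diff": cont.n_facilitation_diff,
            "n_excluded": cont.n_excluded,
            "odds_ratio": cont.odds_ratio(),
            "mann_whitney_U": u_stat,
            "mann_whitney_p": p,
        })
    return pd.DataFrame(rows)


def _write_csv(frame: pd.DataFrame, path: str, overwrite: bool) -> str:
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True")
    frame.to_csv(path, index=False)
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full stage sequence; returns the paths of every report."""
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)
    paths = {}

    table, truth = _load_or_generate(config)
    if truth is not None:
        if os.path.exists(out("voxel_table.csv")) and not config.overwrite:
            raise FileExistsError(f"{out('voxel_table.csv')} exists; set overwrite")
        write_voxel_table(table, out("voxel_table.csv"), overwrite=config.overwrite)
        truth.write_json(out("ground_truth.json"))
        paths["voxel_table"] = out("voxel_table.csv")
        paths["ground_truth"] = out("ground_truth.json")

    paths["modulation"] = _write_csv(
        _modulation_report(table, config), out("modulation.csv"), config.overwrite)
    scatter, comparison = _comparison_report(table, config)
    paths["scatter"] = _write_csv(scatter, out("scatter.csv"), config.overwrite)
    paths["model_comparison"] = _write_csv(
        comparison, out("model_comparison.csv"), config.overwrite)
    paths["spread"] = _write_csv(
        _spread_report(table, config), out("spread.csv"), config.overwrite)
    paths["signs"] = _write_csv(
        _signs_report(table, config), out("signs.csv"), config.overwrite)

    manifest = {
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "config": config.to_json_dict(),
        "config_hash": config.config_hash(),
        "n_voxels": int(len(table)),
        "outputs": paths,
    }
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    paths["manifest"] = out("manifest.json")
    logger.info("pipeline complete: %d reports under %s", len(paths), config.out_dir)
    return paths
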