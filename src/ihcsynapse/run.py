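"""File-level pipeline runs: configuration, outputs, provenance.

A :class:`RunConfig` points at a directory of stacks (either written by the
``simulate`` stage, which leaves a ``manifest.csv``, or a set of OME-TIFFs),
carries the detection and pairing options, and fixes the output directory.
``run_pipeline`` executes every stage and writes five outputs — puncta,
pairs, per-cell and cohort CSVs plus a JSON statistics report — along with
a machine-readable provenance block recording the thresholds actually used
per stack.  Runs are deterministic given config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import pandas as pd
import yaml

from .detect import DetectionConfig
from .io import read_stack
from .pipeline import PipelineConfig, process_stack
from .stats import count_anova, summarize_cohort, volume_anova
from .volumetry import volume_correlation

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "run_stats", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and stack."""


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    input_dir: str = "."
    out_dir: str = "results"
    channel_map: Optional[List[str]] = None
    spacing_override: Optional[Tuple[float, float, float]] = None
    threshold_mode: str = "background"
    threshold_value: Optional[float] = None
    min_voxels: int = 5
    connectivity: int = 26
    split_enabled: bool = True
    split_min_separation_um: float = 0.6
    max_volume_um3: Optional[float] = 1.5
    max_gap_um: float = 0.0
    modiolar_direction: Optional[Tuple[float, float, float]] = None
    seed: int = 0
    log_level: str = "INFO"

    def detection_config(self) -> DetectionConfig:
        return DetectionConfig(
            threshold_mode=self.threshold_mode,
            threshold_value=self.threshold_value,
            min_voxels=self.min_voxels,
            connectivity=self.connectivity,
            split_enabled=self.split_enabled,
            split_min_separation_um=self.split_min_separation_um,
            max_volume_um3=self.max_volume_um3,
        )

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            detection=self.detection_config(),
            max_gap_um=self.max_gap_um,
            modiolar_direction=(
                tuple(self.modiolar_direction)
                if self.modiolar_direction is not None else None
            ),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        cfg = cls(**d)
        if cfg.spacing_override is not None:
            cfg.spacing_override = tuple(cfg.spacing_override)
        if cfg.modiolar_direction is not None:
            cfg.modiolar_direction = tuple(cfg.modiolar_direction)
        return cfg

    def validate(self) -> None:
        if not Path(self.input_dir).exists():
            raise FileNotFoundError(f"input_dir does not exist: {self.input_dir}")
        if self.spacing_override is not None and any(
            s <= 0 for s in self.spacing_override
        ):
            raise ValueError("spacing_override must be strictly positive")


def _load_stacks(cfg: RunConfig):
    """Yield (stack, meta) for every stack in the input directory."""
    root = Path(cfg.input_dir)
    manifest = root / "manifest.csv"
    if manifest.exists():
        man = pd.read_csv(manifest).fillna("")
        for row in man.itertuples(index=False):
            stack = read_stack(
                root / row.path,
                channel_map=cfg.channel_map,
                spacing_override=cfg.spacing_override,
                stack_id=row.stack_id,
            )
            stack.meta.update(
                animal_id=row.animal_id,
                age_group=row.age_group,
                location=row.location,
            )
            if getattr(row, "modiolar_direction", ""):
                stack.meta["modiolar_direction"] = json.loads(
                    row.modiolar_direction
                )
            yield stack
    else:
        paths = sorted(
            p for p in root.glob("*.tif*") if not p.stem.endswith("_labels")
        )
        if not paths:
            raise FileNotFoundError(f"no stacks found under {root}")
        for p in paths:
            yield read_stack(
                p, channel_map=cfg.channel_map,
                spacing_override=cfg.spacing_override,
            )


def _stats_report(cohort: pd.DataFrame, pairs: Optional[pd.DataFrame]) -> dict:
    """Run the statistical battery where the design allows it."""
    report: dict = {}

    def _try(name, fn):
        try:
            report[name] = fn()
        except Exception as exc:  # incomplete designs are expected downstream
            report[name] = {"error": f"{type(exc).__name__}: {exc}"}

    n_ages = cohort["age_group"].nunique()
    n_locs = cohort["location"].nunique()
    between = "age_group" if n_ages >= 2 else None
    within = ["location", "side"] if n_locs >= 2 else ["side"]

    def _tables(res):
        return {
            "effects": res["effects"].to_dict(orient="records"),
            "posthoc": res["posthoc"].to_dict(orient="records"),
        }

    _try("count_anova", lambda: _tables(
        count_anova(cohort, between=between, within=within)
    ))
    if cohort["median_norm_pre"].notna().any():
        _try("volume_anova_pre", lambda: _tables(
            volume_anova(cohort, "presynaptic", between=between, within=within)
        ))
        _try("volume_anova_post", lambda: _tables(
            volume_anova(cohort, "postsynaptic", between=between, within=within)
        ))
    if pairs is not None and len(pairs) >= 3:
        groupby = [
            c for c in ("age_group", "location", "side") if pairs[c].nunique() > 1
        ]
        _try("volume_correlation", lambda: volume_correlation(
            pairs, groupby=groupby or None
        ).to_dict(orient="records"))
    return report


def run_stats(cells: pd.DataFrame, pairs: Optional[pd.DataFrame], out_dir) -> dict:
    """Aggregate per-cell results and write cohort.csv + stats_report.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = summarize_cohort(cells, pairs if pairs is not None and len(pairs) else None)
    cohort.to_csv(out / "cohort.csv", index=False)
    report = _stats_report(cohort, pairs)
    with open(out / "stats_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage on the configured inputs.

    Writes puncta.csv, pairs.csv, cells.csv, cohort.csv,
    stats_report.json and provenance.json under ``cfg.out_dir``; every
    table row carries the stack id and the config hash.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pconf = cfg.pipeline_config()
    chash = pconf.config_hash()
    puncta, pairs, cells, prov = [], [], [], []
    for stack in _load_stacks(cfg):
        try:
            res = process_stack(stack, pconf)
        except Exception as exc:
            raise StageError(
                f"stage 'process_stack' failed on stack {stack.stack_id!r}: {exc}"
            ) from exc
        for df in (res.puncta, res.pairs, res.cells):
            if len(df):
                df["config_hash"] = chash
        puncta.append(res.puncta)
        pairs.append(res.pairs)
        cells.append(res.cells)
        prov.append(res.provenance)
    puncta_df = pd.concat(puncta, ignore_index=True)
    pairs_df = pd.concat([p for p in pairs if len(p)], ignore_index=True) \
        if any(len(p) for p in pairs) else pd.DataFrame()
    cells_df = pd.concat(cells, ignore_index=True)
    puncta_df.to_csv(out / "puncta.csv", index=False)
    pairs_df.to_csv(out / "pairs.csv", index=False)
    cells_df.to_csv(out / "cells.csv", index=False)
    report = run_stats(cells_df, pairs_df, out)
    with open(out / "provenance.json", "w") as fh:
        json.dump(
            {"config": cfg.to_dict(), "config_hash": chash, "stacks": prov},
            fh, indent=2, default=float,
        )
    return {
        "puncta": out / "puncta.csv",
        "pairs": out / "pairs.csv",
        "cells": out / "cells.csv",
        "cohort": out / "cohort.csv",
        "stats_report": out / "stats_report.json",
        "provenance": out / "provenance.json",
        "report": report,
    }
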