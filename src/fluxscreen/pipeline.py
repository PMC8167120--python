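"""End-to-end screen pipeline: read → normalize → SSMD → classify → export.

The pipeline consumes either a raw well table (per-replicate median
fluorescence) or an effect-summary table (compound, condition,
mean_difference, sd, n) — the latter is the bridge that makes published
summary tables directly executable, since screens publish summaries,
not raw wells.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from os import PathLike
from pathlib import Path

import pandas as pd

from . import effects, hits, io
from .effects import EffectSummary, ssmd_from_moments
from .hits import ConditionEffect, Thresholds
from .io import Condition, Dialect

__all__ = ["PipelineConfig", "PipelineError", "run_screen_pipeline",
           "read_summary_table", "effects_table"]

log = logging.getLogger("fluxscreen")


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run."""

    input_path: str
    out_dir: str
    input_kind: str = "wells"  # "wells" or "summary"
    delimiter: str = ","
    vehicle_id: str = io.DEFAULT_VEHICLE_ID
    effect_percent: float = 15.0
    ssmd_abs: float = 1.0
    autofluorescence_percent: float = 1000.0
    seed: int = 0
    verbosity: str = "INFO"

    def thresholds(self) -> Thresholds:
        return Thresholds(
            effect_percent=self.effect_percent,
            ssmd_abs=self.ssmd_abs,
            autofluorescence_percent=self.autofluorescence_percent,
        )

    def dialect(self) -> Dialect:
        return Dialect(delimiter=self.delimiter, vehicle_id=self.vehicle_id)

    def to_json(self, path: str | PathLike[str]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | PathLike[str]) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def read_summary_table(
    path: str | PathLike[str], delimiter: str = ","
) -> dict[Condition, list[ConditionEffect]]:
    """Read an effect-summary table into per-condition effect lists."""
    frame = pd.read_csv(path, sep=delimiter, dtype={"compound_id": str})
    required = {"compound_id", "condition", "mean_difference", "sd", "n"}
    missing = required - set(frame.columns)
    if missing:
        raise io.ScreenFormatError(
            f"summary table missing column(s) {sorted(missing)}"
        )
    out: dict[Condition, list[ConditionEffect]] = {}
    for row in frame.itertuples(index=False):
        cond = Condition.parse(row.condition)
        summary = EffectSummary.from_moments(
            row.compound_id, cond, row.mean_difference, row.sd, int(row.n)
        )
        ssmd = ssmd_from_moments(
            row.compound_id, cond, row.mean_difference, row.sd, int(row.n)
        )
        out.setdefault(cond, []).append(
            ConditionEffect(summary=summary, ssmd=ssmd)
        )
    return out


def effects_table(
    results: "list[ConditionEffect] | list[tuple]",
) -> pd.DataFrame:
    """Flat SSMD output table: one row per compound per condition."""
    rows = []
    for item in results:
        eff = (
            item
            if isinstance(item, ConditionEffect)
            else ConditionEffect(summary=item[0], ssmd=item[1])
        )
        rows.append(
            {
                "compound_id": eff.summary.compound_id,
                "condition": eff.summary.condition.value,
                "mean_difference": eff.summary.mean_difference,
                "sd": eff.summary.sd,
                "n": eff.summary.n,
                "ssmd_mm": eff.ssmd.ssmd_mm,
                "ssmd_umvue": eff.ssmd.ssmd_umvue,
                "degenerate_flag": int(eff.ssmd.degenerate),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "compound_id",
            "condition",
            "mean_difference",
            "sd",
            "n",
            "ssmd_mm",
            "ssmd_umvue",
            "degenerate_flag",
        ],
    )


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: %.3f s", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


def run_screen_pipeline(cfg: PipelineConfig) -> dict[str, object]:
    """Execute the full hit-calling pipeline and write all artifacts.

    Writes to ``cfg.out_dir``: ``effects.csv`` (per-condition SSMD
    table), ``hit_calls.csv`` (dual-flashlight export with categories),
    ``counts.json`` (category tallies incl. overlapping totals), and
    ``config.json`` (the resolved configuration).  Returns the counts
    dict plus the hit-call table for programmatic use.
    """
    logging.basicConfig(level=getattr(logging, cfg.verbosity.upper(), 20))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    th = cfg.thresholds()

    if cfg.input_kind == "wells":
        table = _stage("read")(io.read_screen_table)(
            cfg.input_path, cfg.dialect()
        )
        per_condition: dict[Condition, list[ConditionEffect]] = {}
        for cond in table.conditions():
            res = _stage(f"effects[{cond.value}]")(effects.screen_effects)(
                table, cond
            )
            per_condition[cond] = [
                ConditionEffect(summary=s, ssmd=r) for s, r in res
            ]
    elif cfg.input_kind == "summary":
        per_condition = _stage("read-summary")(read_summary_table)(
            cfg.input_path, cfg.delimiter
        )
    else:
        raise PipelineError(
            f"stage 'read' failed: unknown input_kind {cfg.input_kind!r}"
        )

    all_effects = [e for lst in per_condition.values() for e in lst]
    eff_frame = effects_table(all_effects)
    io.write_results_table(eff_frame, out_dir / "effects.csv", cfg.delimiter)
    log.info("effects table: %d rows", len(eff_frame))

    calls, counts = _stage("classify")(hits.classify_screen)(
        per_condition.get(Condition.FULL, []),
        per_condition.get(Condition.STARVATION, []),
        th,
    )
    export = hits.dual_flashlight_export(calls)
    io.write_results_table(export, out_dir / "hit_calls.csv", cfg.delimiter)
    counts_dict = hits.counts_to_dict(counts)
    (out_dir / "counts.json").write_text(
        json.dumps(counts_dict, indent=2, sort_keys=True) + "\n"
    )
    cfg.to_json(out_dir / "config.json")
    log.info("hit calls: %d compounds, counts %s", len(calls), counts_dict)
    return {"counts": counts_dict, "calls": calls, "export": export}
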