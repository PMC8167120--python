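"""Synthetic screens, dose-response tables, and OCR traces with known
ground truth.

The screen generator mimics the real readout chain: each well holds a
population of cells whose per-event reporter fluorescence is lognormal;
a cytometer records ~10,000 events and the well is summarized by its
median; wells come in biological triplicates with multiplicative
between-replicate noise; and a planted compound effect multiplies the
median fluorescence by a known fold-change in a chosen medium
condition.  Two generation modes are provided:

* ``events``  — literally draws every per-event fluorescence and takes
  the sample median (slow, faithful);
* ``wells``   — draws the well median directly, using the asymptotic
  sampling distribution of a lognormal sample median (the log-median is
  Normal with SD σ·√(π/(2N))); indistinguishable in practice and ~10^4×
  faster.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .doseresponse import ViabilityPoint, four_pl
from .hits import Category, Thresholds
from .io import (
    CompoundRecord,
    Condition,
    ScreenTable,
    WellMeasurement,
    DEFAULT_VEHICLE_ID,
)
from .ocr import Injection, OCRTrace

__all__ = [
    "ScreenSimConfig",
    "GroundTruth",
    "simulate_screen",
    "simulate_dose_response",
    "simulate_ocr_trace",
]


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study conditions for a simulated screen.

    Defaults mirror the screening campaign being emulated: 300 library
    compounds, biological triplicates, 10,000 cytometry events per well.
    ``vehicle_log_sd`` is the per-event lognormal shape (natural-log SD)
    of the reporter; ``replicate_cv`` the between-replicate coefficient
    of variation of the well median (multiplicative lognormal), chosen
    so a null screen shows percent-of-control SDs of roughly 5–10%.
    ``planted_effects`` maps compound_id -> {condition: fold-change on
    the median fluorescence}; fold 1.0 is no effect, 2.0 doubles the
    reporter signal (inhibitor-like), 0.7 removes 30% (inducer-like).
    """

    n_compounds: int = 300
    n_replicates: int = 3
    n_vehicle_replicates: int | None = None
    events_per_well: int = 10_000
    vehicle_log_mean: float = math.log(1000.0)
    vehicle_log_sd: float = 0.8
    replicate_cv: float = 0.07
    starvation_vehicle_factor: float = 0.6
    planted_effects: Mapping[str, Mapping[Condition, float]] = field(
        default_factory=dict
    )
    conditions: tuple[Condition, ...] = (Condition.FULL, Condition.STARVATION)
    mode: str = "wells"
    seed: int = 0
    vehicle_id: str = DEFAULT_VEHICLE_ID

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_replicates < 2:
            raise ValueError("need n_compounds >= 1 and n_replicates >= 2")
        if self.events_per_well < 1:
            raise ValueError("events_per_well must be positive")
        if self.replicate_cv < 0 or self.vehicle_log_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if self.mode not in ("wells", "events"):
            raise ValueError(f"mode must be 'wells' or 'events', got {self.mode!r}")
        for cid, effects in self.planted_effects.items():
            for cond, fold in effects.items():
                if not fold > 0:
                    raise ValueError(
                        f"planted fold-change must be > 0 "
                        f"({cid!r}, {Condition.parse(cond).value}: {fold})"
                    )

    def compound_ids(self) -> list[str]:
        """Plate-well style identifiers C001..C300 plus any planted ids."""
        ids = [f"C{i + 1:03d}" for i in range(self.n_compounds)]
        extra = [c for c in self.planted_effects if c not in set(ids)]
        return ids + extra


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for a simulated screen.

    ``true_percent`` holds the noise-free percent-of-control each
    compound would show in each condition (fold × 100);
    ``expected_category`` the dual-flashlight category those true
    effects imply under the given thresholds, assuming the noise is
    small enough that the SSMD criterion co-fires with the effect
    criterion.
    """

    true_percent: dict[str, dict[Condition, float]]
    expected_category: dict[str, Category]
    thresholds: Thresholds


def _expected_category(
    effects: Mapping[Condition, float], th: Thresholds
) -> Category:
    d_full = 100.0 * effects.get(Condition.FULL, 1.0) - 100.0
    d_starv = 100.0 * effects.get(Condition.STARVATION, 1.0) - 100.0
    inducer = d_full <= -th.effect_percent
    basal_inh = d_full >= th.effect_percent
    flux_inh = d_starv >= th.effect_percent
    if inducer and flux_inh:
        return Category.DUAL_MODULATOR
    if inducer:
        return Category.INDUCER
    if basal_inh:
        return Category.BASAL_INHIBITOR
    if flux_inh:
        return Category.FLUX_INHIBITOR
    return Category.NO_EFFECT


def _median_sampling_log_sd(log_sd: float, n_events: int) -> float:
    # asymptotic SD of the sample median of a lognormal, on the log scale
    return log_sd * math.sqrt(math.pi / (2.0 * n_events))


def simulate_screen(cfg: ScreenSimConfig) -> tuple[ScreenTable, GroundTruth]:
    """Generate a two-condition screen table plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    planted = {
        cid: {Condition.parse(c): f for c, f in eff.items()}
        for cid, eff in cfg.planted_effects.items()
    }
    ids = cfg.compound_ids()
    wells: list[WellMeasurement] = []
    rep_sigma = (
        math.sqrt(math.log(1.0 + cfg.replicate_cv**2))
        if cfg.replicate_cv > 0
        else 0.0
    )
    for cond in cfg.conditions:
        cond = Condition.parse(cond)
        cond_log_mean = cfg.vehicle_log_mean + (
            math.log(cfg.starvation_vehicle_factor)
            if cond is Condition.STARVATION
            else 0.0
        )
        for cid in [cfg.vehicle_id, *ids]:
            fold = planted.get(cid, {}).get(cond, 1.0)
            n_rep = (
                cfg.n_vehicle_replicates or cfg.n_replicates
                if cid == cfg.vehicle_id
                else cfg.n_replicates
            )
            for rep in range(1, n_rep + 1):
                log_shift = math.log(fold) + (
                    rng.normal(0.0, rep_sigma) if rep_sigma else 0.0
                )
                if cfg.mode == "events":
                    events = rng.lognormal(
                        cond_log_mean + log_shift,
                        cfg.vehicle_log_sd,
                        cfg.events_per_well,
                    )
                    median = float(np.median(events))
                else:
                    med_sd = _median_sampling_log_sd(
                        cfg.vehicle_log_sd, cfg.events_per_well
                    )
                    median = float(
                        math.exp(
                            cond_log_mean
                            + log_shift
                            + (rng.normal(0.0, med_sd) if med_sd else 0.0)
                        )
                    )
                wells.append(
                    WellMeasurement(
                        compound_id=cid,
                        condition=cond,
                        replicate=rep,
                        median_fluorescence=median,
                        event_count=cfg.events_per_well,
                    )
                )
    table = ScreenTable(
        compounds=[CompoundRecord(cid) for cid in ids],
        wells=wells,
        metadata={"seed": cfg.seed, "mode": cfg.mode},
        vehicle_id=cfg.vehicle_id,
    )
    th = Thresholds()
    truth = GroundTruth(
        true_percent={
            cid: {
                Condition.parse(c): 100.0 * f
                for c, f in planted.get(cid, {}).items()
            }
            for cid in ids
        },
        expected_category={
            cid: _expected_category(planted.get(cid, {}), th) for cid in ids
        },
        thresholds=th,
    )
    return table, truth


def simulate_dose_response(
    params: tuple[float, float, float, float],
    doses: Sequence[float],
    n_replicates: int = 3,
    noise_sd_percent: float = 5.0,
    seed: int = 0,
) -> list[ViabilityPoint]:
    """Viability points from a 4PL curve plus Gaussian noise.

    ``params`` is (bottom, top, log_ic50, hill_slope) in the same
    parameterization the fitter uses; noise is additive on the
    viability-percent scale.
    """
    if len(doses) == 0:
        raise ValueError("doses must be non-empty")
    bottom, top, log_ic50, hill = params
    rng = np.random.default_rng(seed)
    points: list[ViabilityPoint] = []
    for dose in doses:
        x = math.log10(dose) if dose > 0 else -math.inf
        mean = (
            float(four_pl(x, bottom, top, log_ic50, hill))
            if dose > 0
            else float(four_pl(-1e9, bottom, top, log_ic50, hill))
        )
        for rep in range(1, n_replicates + 1):
            v = mean + (
                rng.normal(0.0, noise_sd_percent) if noise_sd_percent else 0.0
            )
            points.append(
                ViabilityPoint(
                    dose=float(dose),
                    replicate=rep,
                    absorbance_measure=v / 100.0,
                    viability_percent=v,
                )
            )
    return points


def simulate_ocr_trace(
    segment_means: Sequence[float],
    noise_sd: float = 0.0,
    timepoints_per_segment: int = 3,
    seed: int = 0,
    include_treatment: "bool | None" = None,
    well: str = "well_1",
) -> OCRTrace:
    """Piecewise-constant OCR trace with injections at segment borders.

    ``segment_means`` has four entries (basal, post-oligomycin,
    post-FCCP, post-rotenone/antimycin) or five when a treatment
    segment follows the basal one.  Measurements are one minute apart;
    each injection lands half a minute after the previous segment's
    last measurement.
    """
    n_seg = len(segment_means)
    if include_treatment is None:
        include_treatment = n_seg == 5
    expected = 5 if include_treatment else 4
    if n_seg != expected:
        raise ValueError(
            f"expected {expected} segment means, got {n_seg}"
        )
    if timepoints_per_segment < 1:
        raise ValueError("timepoints_per_segment must be >= 1")
    labels = (
        [
            Injection.TREATMENT,
            Injection.OLIGOMYCIN,
            Injection.FCCP,
            Injection.ROTENONE_ANTIMYCIN,
        ]
        if include_treatment
        else [Injection.OLIGOMYCIN, Injection.FCCP, Injection.ROTENONE_ANTIMYCIN]
    )
    rng = np.random.default_rng(seed)
    times: list[float] = []
    values: list[float] = []
    injections: list[tuple[Injection, float]] = []
    t = 0.0
    for i, mean in enumerate(segment_means):
        if i > 0:
            injections.append((labels[i - 1], t + 0.5))
        for _ in range(timepoints_per_segment):
            t += 1.0
            times.append(t)
            values.append(
                float(mean + (rng.normal(0.0, noise_sd) if noise_sd else 0.0))
            )
    return OCRTrace(
        times=tuple(times),
        ocr=tuple(values),
        injections=tuple(injections),
        well=well,
    )
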