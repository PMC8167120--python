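"""Vehicle normalization and SSMD effect-size estimation.

Each compound's well medians are expressed as a percentage of the mean
vehicle (DMSO) median for the same medium condition.  The per-compound
effect is then summarized as the mean difference from 100% (d̄) with its
sample standard deviation (s, n−1 denominator), and the strictly
standardized mean difference (SSMD, β = δ/σ of the difference from
control) is estimated in two ways:

* method of moments:  β̂_MM = d̄ / s
* UMVUE:              β̂ = Γ((n−1)/2) / Γ((n−2)/2) · √(2/(n−1)) · d̄ / s

The UMVUE multiplier corrects the small-sample upward bias of |d̄/s|;
for biological triplicates (n = 3) it is exactly 1/√π ≈ 0.5642.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .io import Condition, ScreenTable

__all__ = [
    "EffectSummary",
    "SSMDResult",
    "umvue_correction_factor",
    "percent_of_control",
    "effect_summary",
    "ssmd_umvue",
    "ssmd_from_moments",
    "screen_effects",
]


@dataclass(frozen=True)
class EffectSummary:
    """Per-compound normalized effect under one medium condition.

    ``mean_difference`` is mean(percent_of_control) − 100, in percentage
    points of the vehicle signal; ``sd`` is the sample SD of the
    replicate percentages.  ``percent_of_control`` is None for
    summary-only records (published tables report d̄ ± s, not the
    replicate values).
    """

    compound_id: str
    condition: Condition
    percent_of_control: tuple[float, ...] | None
    mean_difference: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if (
            self.percent_of_control is not None
            and self.n != len(self.percent_of_control)
        ):
            raise ValueError("n must equal len(percent_of_control)")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @classmethod
    def from_moments(
        cls,
        compound_id: str,
        condition: "Condition | str",
        mean_difference: float,
        sd: float,
        n: int,
    ) -> "EffectSummary":
        """Summary-only record from published (d̄, s, n)."""
        return cls(
            compound_id=compound_id,
            condition=Condition.parse(condition),
            percent_of_control=None,
            mean_difference=float(mean_difference),
            sd=float(sd),
            n=int(n),
        )


@dataclass(frozen=True)
class SSMDResult:
    """SSMD point estimates attached to an effect summary.

    ``degenerate`` marks s = 0 inputs, where both estimates are reported
    as signed infinity (sign of d̄) rather than silently dropped.
    """

    compound_id: str
    condition: Condition
    ssmd_umvue: float
    ssmd_mm: float
    n: int
    correction_factor: float
    degenerate: bool = False


def umvue_correction_factor(n: int) -> float:
    """Multiplier turning the moment estimate d̄/s into the UMVUE.

    k(n) = Γ((n−1)/2) / Γ((n−2)/2) · √(2/(n−1)); k(3) = 1/√π, and
    k(n) → 1 monotonically from below as n → ∞.
    """
    if n < 3:
        raise ValueError(f"UMVUE correction needs n >= 3, got {n}")
    log_k = gammaln((n - 1) / 2.0) - gammaln((n - 2) / 2.0)
    return math.exp(log_k) * math.sqrt(2.0 / (n - 1))


def percent_of_control(
    table: ScreenTable, condition: Condition | str
) -> dict[str, list[float]]:
    """Normalize each well median to the condition's mean vehicle median.

    Returns per-compound replicate percentages (vehicle wells included
    under the vehicle id; they average 100% by construction).  Replicate
    order follows the replicate index.
    """
    cond = Condition.parse(condition)
    vehicle = table.vehicle_wells(cond)
    if not vehicle:
        raise ValueError(
            f"no vehicle ({table.vehicle_id!r}) well for condition "
            f"{cond.value!r}"
        )
    vehicle_mean = float(np.mean([w.median_fluorescence for w in vehicle]))
    out: dict[str, list[tuple[int, float]]] = {}
    for w in table.wells:
        if w.condition is not cond:
            continue
        out.setdefault(w.compound_id, []).append(
            (w.replicate, 100.0 * w.median_fluorescence / vehicle_mean)
        )
    return {
        cid: [p for _, p in sorted(pairs)] for cid, pairs in out.items()
    }


def effect_summary(
    compound_id: str,
    condition: Condition | str,
    percents: "list[float] | tuple[float, ...] | np.ndarray",
) -> EffectSummary:
    """Summarize replicate percent-of-control values as d̄ ± s (n)."""
    values = np.asarray(percents, dtype=float)
    if values.size < 2:
        raise ValueError(
            f"need >= 2 replicates to estimate SD, got {values.size} for "
            f"{compound_id!r}"
        )
    return EffectSummary(
        compound_id=compound_id,
        condition=Condition.parse(condition),
        percent_of_control=tuple(float(v) for v in values),
        mean_difference=float(values.mean() - 100.0),
        sd=float(values.std(ddof=1)),
        n=int(values.size),
    )


def ssmd_umvue(summary: EffectSummary) -> SSMDResult:
    """Estimate SSMD for one effect summary (UMVUE and moment forms)."""
    return ssmd_from_moments(
        summary.compound_id,
        summary.condition,
        summary.mean_difference,
        summary.sd,
        summary.n,
    )


def ssmd_from_moments(
    compound_id: str,
    condition: Condition | str,
    mean_difference: float,
    sd: float,
    n: int,
) -> SSMDResult:
    """SSMD from printed summary statistics (d̄, s, n) directly.

    This is the entry point for published tables, which report the
    summaries rather than replicate-level data.
    """
    if n < 3:
        raise ValueError(f"SSMD UMVUE requires n >= 3, got {n}")
    cond = Condition.parse(condition)
    k = umvue_correction_factor(n)
    if sd == 0.0:
        inf = math.copysign(math.inf, mean_difference) if mean_difference else 0.0
        return SSMDResult(
            compound_id=compound_id,
            condition=cond,
            ssmd_umvue=inf,
            ssmd_mm=inf,
            n=n,
            correction_factor=k,
            degenerate=True,
        )
    mm = mean_difference / sd
    return SSMDResult(
        compound_id=compound_id,
        condition=cond,
        ssmd_umvue=k * mm,
        ssmd_mm=mm,
        n=n,
        correction_factor=k,
    )


def screen_effects(
    table: ScreenTable, condition: Condition | str
) -> list[tuple[EffectSummary, SSMDResult]]:
    """Full per-condition effect pipeline: normalize → summarize → SSMD.

    Vehicle wells are excluded from the output (they are the reference,
    not a tested compound).
    """
    cond = Condition.parse(condition)
    percents = percent_of_control(table, cond)
    results = []
    for cid, vals in percents.items():
        if cid == table.vehicle_id:
            continue
        summ = effect_summary(cid, cond, vals)
        results.append((summ, ssmd_umvue(summ)))
    return results
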