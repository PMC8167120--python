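"""Dual-flashlight hit classification for the two-condition screen.

A compound qualifies as a hit when BOTH the effect size and the SSMD
score clear their thresholds (defaults: |d̄| ≥ 15 percentage points and
|β̂| ≥ 1, comparisons inclusive):

* inducer (full medium):        d̄ ≤ −15 and β̂ ≤ −1 — reporter loss,
  i.e. more autophagic flux under basal conditions;
* basal inhibitor (full):       d̄ ≥ +15 and β̂ ≥ +1;
* flux inhibitor (starvation):  d̄ ≥ +15 and β̂ ≥ +1 — reporter
  accumulation when starvation should be degrading it;
* dual modulator: inducer-qualifying in full medium AND
  flux-inhibitor-qualifying under starvation.

Categories are mutually exclusive (dual modulator takes precedence);
the summary counts additionally report the overlapping totals a
screener quotes, where dual modulators are counted among the
starvation-condition inhibitors.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import pandas as pd

from .effects import EffectSummary, SSMDResult

__all__ = [
    "Category",
    "Thresholds",
    "ConditionEffect",
    "HitCall",
    "CategoryCounts",
    "classify_compound",
    "classify_screen",
    "flag_autofluorescence",
    "dual_flashlight_export",
]


class Category(str, enum.Enum):
    INDUCER = "inducer"
    BASAL_INHIBITOR = "basal_inhibitor"
    FLUX_INHIBITOR = "flux_inhibitor"
    DUAL_MODULATOR = "dual_modulator"
    NO_EFFECT = "no_effect"


@dataclass(frozen=True)
class Thresholds:
    """Dual-flashlight cut-offs, all inclusive (≥)."""

    effect_percent: float = 15.0
    ssmd_abs: float = 1.0
    #: advisory |d̄| cut-off above which a signal is suspiciously large
    #: for a reporter readout and may reflect compound autofluorescence
    autofluorescence_percent: float = 1000.0

    def __post_init__(self) -> None:
        if not (
            self.effect_percent > 0
            and self.ssmd_abs > 0
            and self.autofluorescence_percent > 0
        ):
            raise ValueError("all thresholds must be strictly positive")


@dataclass(frozen=True)
class ConditionEffect:
    """Effect summary + SSMD estimate for one compound in one condition."""

    summary: EffectSummary
    ssmd: SSMDResult

    def __post_init__(self) -> None:
        if (
            self.summary.compound_id != self.ssmd.compound_id
            or self.summary.condition is not self.ssmd.condition
        ):
            raise ValueError("summary and ssmd must describe the same cell")


@dataclass(frozen=True)
class HitCall:
    compound_id: str
    category: Category
    full_effect: ConditionEffect | None = None
    starvation_effect: ConditionEffect | None = None
    flags: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class CategoryCounts:
    """Exclusive partition counts plus the overlapping screen totals.

    ``inducers_total`` counts every inducer-qualifying compound in full
    medium (dual modulators included); ``starvation_inhibitors_total``
    counts every inhibitor-qualifying compound under starvation (dual
    modulators included) — the headline numbers a screen reports.
    """

    inducer: int
    basal_inhibitor: int
    flux_inhibitor: int
    dual_modulator: int
    no_effect: int
    inducers_total: int
    starvation_inhibitors_total: int

    @property
    def n_compounds(self) -> int:
        return (
            self.inducer
            + self.basal_inhibitor
            + self.flux_inhibitor
            + self.dual_modulator
            + self.no_effect
        )


def _inducer_qualifying(eff: ConditionEffect | None, th: Thresholds) -> bool:
    if eff is None:
        return False
    return (
        eff.summary.mean_difference <= -th.effect_percent
        and eff.ssmd.ssmd_umvue <= -th.ssmd_abs
    )


def _inhibitor_qualifying(eff: ConditionEffect | None, th: Thresholds) -> bool:
    if eff is None:
        return False
    return (
        eff.summary.mean_difference >= th.effect_percent
        and eff.ssmd.ssmd_umvue >= th.ssmd_abs
    )


def classify_compound(
    full: ConditionEffect | None,
    starvation: ConditionEffect | None,
    thresholds: Thresholds | None = None,
) -> HitCall:
    """Assign the single dual-flashlight category for one compound.

    At least one condition must be present; a missing condition is
    flagged ``missing_condition`` and classification proceeds on the
    available data.
    """
    th = thresholds or Thresholds()
    if full is None and starvation is None:
        raise ValueError("at least one condition effect is required")
    compound_id = (full or starvation).summary.compound_id  # type: ignore[union-attr]

    inducer_q = _inducer_qualifying(full, th)
    basal_inh_q = _inhibitor_qualifying(full, th)
    flux_inh_q = _inhibitor_qualifying(starvation, th)

    if inducer_q and flux_inh_q:
        category = Category.DUAL_MODULATOR
    elif inducer_q:
        category = Category.INDUCER
    elif basal_inh_q:
        category = Category.BASAL_INHIBITOR
    elif flux_inh_q:
        category = Category.FLUX_INHIBITOR
    else:
        category = Category.NO_EFFECT

    flags: set[str] = set()
    if full is None or starvation is None:
        flags.add("missing_condition")
    for eff in (full, starvation):
        if eff is not None and eff.ssmd.degenerate:
            flags.add("degenerate_sd")

    call = HitCall(
        compound_id=compound_id,
        category=category,
        full_effect=full,
        starvation_effect=starvation,
        flags=frozenset(flags),
    )
    return flag_autofluorescence(call, th)


def flag_autofluorescence(call: HitCall, thresholds: Thresholds) -> HitCall:
    """Add the advisory ``autofluorescence_suspect`` flag.

    Set when any condition's |mean difference| reaches the configured
    cut-off; the category is never changed.
    """
    suspect = any(
        eff is not None
        and abs(eff.summary.mean_difference)
        >= thresholds.autofluorescence_percent
        for eff in (call.full_effect, call.starvation_effect)
    )
    if not suspect:
        return call
    return replace(call, flags=call.flags | {"autofluorescence_suspect"})


def classify_screen(
    full_results: "list[ConditionEffect] | list[tuple[EffectSummary, SSMDResult]]",
    starvation_results: "list[ConditionEffect] | list[tuple[EffectSummary, SSMDResult]]",
    thresholds: Thresholds | None = None,
) -> tuple[list[HitCall], CategoryCounts]:
    """Classify every compound in the union of both condition tables."""
    th = thresholds or Thresholds()
    full_map = _as_effect_map(full_results)
    starv_map = _as_effect_map(starvation_results)
    calls = [
        classify_compound(full_map.get(cid), starv_map.get(cid), th)
        for cid in dict.fromkeys([*full_map, *starv_map])
    ]
    tally = {cat: 0 for cat in Category}
    for call in calls:
        tally[call.category] += 1
    counts = CategoryCounts(
        inducer=tally[Category.INDUCER],
        basal_inhibitor=tally[Category.BASAL_INHIBITOR],
        flux_inhibitor=tally[Category.FLUX_INHIBITOR],
        dual_modulator=tally[Category.DUAL_MODULATOR],
        no_effect=tally[Category.NO_EFFECT],
        inducers_total=tally[Category.INDUCER] + tally[Category.DUAL_MODULATOR],
        starvation_inhibitors_total=(
            tally[Category.FLUX_INHIBITOR]
            + tally[Category.BASAL_INHIBITOR]
            + tally[Category.DUAL_MODULATOR]
        ),
    )
    return calls, counts


def _as_effect_map(
    results: "list[ConditionEffect] | list[tuple[EffectSummary, SSMDResult]]",
) -> dict[str, ConditionEffect]:
    out: dict[str, ConditionEffect] = {}
    for item in results:
        eff = (
            item
            if isinstance(item, ConditionEffect)
            else ConditionEffect(summary=item[0], ssmd=item[1])
        )
        out[eff.summary.compound_id] = eff
    return out


def dual_flashlight_export(calls: list[HitCall]) -> pd.DataFrame:
    """One row per compound per condition for a dual-flashlight scatter.

    Columns (compound_id, condition, mean_difference, sd, n, ssmd_umvue,
    category, flags) carry exactly the values classification used, so
    re-classifying from the export reproduces the categories.
    """
    rows = []
    for call in calls:
        for eff in (call.full_effect, call.starvation_effect):
            if eff is None:
                continue
            rows.append(
                {
                    "compound_id": call.compound_id,
                    "condition": eff.summary.condition.value,
                    "mean_difference": eff.summary.mean_difference,
                    "sd": eff.summary.sd,
                    "n": eff.summary.n,
                    "ssmd_umvue": eff.ssmd.ssmd_umvue,
                    "category": call.category.value,
                    "flags": ";".join(sorted(call.flags)),
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
            "ssmd_umvue",
            "category",
            "flags",
        ],
    )


def counts_to_dict(counts: CategoryCounts) -> dict[str, int]:
    """Machine-readable key/value form of the counts summary."""
    return {
        "inducer": counts.inducer,
        "basal_inhibitor": counts.basal_inhibitor,
        "flux_inhibitor": counts.flux_inhibitor,
        "dual_modulator": counts.dual_modulator,
        "no_effect": counts.no_effect,
        "inducers_total": counts.inducers_total,
        "starvation_inhibitors_total": counts.starvation_inhibitors_total,
        "n_compounds": counts.n_compounds,
    }
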