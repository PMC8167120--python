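"""Published hit tables of the 300-compound autophagy screen.

Two summary tables ship with the package as plain CSV: the eight
full-medium autophagy inducers and the 64 starvation-medium flux
inhibitors, each as (compound_id, mean difference % of control, SD,
n = 3, the printed SSMD score, and an autofluorescence footnote flag).
They serve as executable fixtures: recomputing the UMVUE SSMD from the
printed summary statistics and re-running the dual-flashlight
classification reproduces the published scores, memberships, and the
four dual modulators shared between the tables.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .effects import EffectSummary, ssmd_from_moments
from .hits import ConditionEffect
from .io import Condition

__all__ = [
    "load_published_hits",
    "published_condition_effects",
]


def load_published_hits(condition: Condition | str) -> pd.DataFrame:
    """Published hit summaries for one medium condition.

    Columns: compound_id, condition, mean_difference, sd, n,
    ssmd_printed, autofluorescence_note (1 where the original table
    footnotes the row as possibly autofluorescence-driven).
    """
    cond = Condition.parse(condition)
    name = (
        "screen_hits_full.csv"
        if cond is Condition.FULL
        else "screen_hits_starvation.csv"
    )
    path = resources.files("fluxscreen.data").joinpath(name)
    with path.open("r") as fh:
        return pd.read_csv(fh, dtype={"compound_id": str})


def published_condition_effects(
    condition: Condition | str,
) -> list[ConditionEffect]:
    """Published rows as (EffectSummary, SSMDResult) pairs, with the
    SSMD recomputed from the printed moments (not the printed score)."""
    cond = Condition.parse(condition)
    frame = load_published_hits(cond)
    out: list[ConditionEffect] = []
    for row in frame.itertuples(index=False):
        summary = EffectSummary.from_moments(
            row.compound_id, cond, row.mean_difference, row.sd, int(row.n)
        )
        out.append(
            ConditionEffect(summary=summary, ssmd=ssmd_from_moments(
                row.compound_id, cond, row.mean_difference, row.sd, int(row.n)
            ))
        )
    return out
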