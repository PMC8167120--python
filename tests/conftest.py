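import numpy as np
import pytest

from fluxscreen import (
    CompoundRecord,
    Condition,
    ScreenTable,
    WellMeasurement,
)


@pytest.fixture
def small_screen() -> ScreenTable:
    """Three compounds + vehicle, both conditions, triplicates.

    Vehicle medians are (800, 1000, 1200) in each condition (mean
    1000), so percent-of-control arithmetic is easy to do by hand.
    """
    wells = []
    vehicle = {"full": (800.0, 1000.0, 1200.0), "starvation": (800.0, 1000.0, 1200.0)}
    compounds = {
        "A1": {"full": (550.0, 990.0, 1100.0), "starvation": (2000.0, 2000.0, 2000.0)},
        "B2": {"full": (1000.0, 1000.0, 1000.0), "starvation": (1500.0, 1600.0, 1700.0)},
        "C3": {"full": (700.0, 750.0, 800.0), "starvation": (900.0, 1000.0, 1100.0)},
    }
    for cond in ("full", "starvation"):
        for rep, v in enumerate(vehicle[cond], start=1):
            wells.append(WellMeasurement("DMSO", Condition.parse(cond), rep, v))
        for cid, per_cond in compounds.items():
            for rep, v in enumerate(per_cond[cond], start=1):
                wells.append(WellMeasurement(cid, Condition.parse(cond), rep, v))
    return ScreenTable(
        compounds=[CompoundRecord(c) for c in compounds],
        wells=wells,
    )


def random_screen_table(rng: np.random.Generator, n_compounds: int = 5) -> ScreenTable:
    """Arbitrary valid screen table for round-trip properties."""
    wells = []
    ids = [f"K{i:02d}" for i in range(n_compounds)]
    for cond in (Condition.FULL, Condition.STARVATION):
        for cid in ["DMSO", *ids]:
            for rep in range(1, 4):
                wells.append(
                    WellMeasurement(
                        cid,
                        cond,
                        rep,
                        float(rng.lognormal(7.0, 0.5)),
                        event_count=10_000 if rng.random() < 0.5 else None,
                    )
                )
    return ScreenTable(compounds=[CompoundRecord(c) for c in ids], wells=wells)
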