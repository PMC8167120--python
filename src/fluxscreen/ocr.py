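"""Mitochondrial stress-test metrics from annotated OCR traces.

A mito-stress-test run measures the oxygen consumption rate (OCR,
pmol O2/min) over time while injecting, in order: optionally a
treatment compound, then oligomycin (ATP-synthase inhibitor), FCCP
(uncoupler), and rotenone/antimycin A (complex I/III inhibitors).
Segment statistics define the canonical metrics:

* non-mitochondrial respiration = minimum rate after rotenone/antimycin A
* basal respiration = last rate before the first injection − non-mito
* maximal respiration = maximum rate after FCCP − non-mito
* proton leak = minimum rate after oligomycin − non-mito
* post-treatment respiration = last rate in the treatment segment − non-mito
  (only when a treatment injection is present)

"After injection X" means measurements in the half-open window
(time_X, time of next injection], or to the end of the trace for the
final injection.  Normalized metrics divide by basal respiration.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Injection",
    "OCRTrace",
    "OCRMetrics",
    "compute_ocr_metrics",
    "aggregate_metrics",
]


class Injection(str, enum.Enum):
    TREATMENT = "treatment"
    OLIGOMYCIN = "oligomycin"
    FCCP = "FCCP"
    ROTENONE_ANTIMYCIN = "rotenone_antimycin"

    @classmethod
    def parse(cls, value: "str | Injection") -> "Injection":
        if isinstance(value, Injection):
            return value
        key = str(value).strip().lower().replace("/", "_").replace("-", "_")
        aliases = {
            "treatment": cls.TREATMENT,
            "oligomycin": cls.OLIGOMYCIN,
            "oligo": cls.OLIGOMYCIN,
            "fccp": cls.FCCP,
            "rotenone_antimycin": cls.ROTENONE_ANTIMYCIN,
            "rotenone_antimycin_a": cls.ROTENONE_ANTIMYCIN,
            "rot_aa": cls.ROTENONE_ANTIMYCIN,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown injection label {value!r}") from None


_CANONICAL_ORDER = [
    Injection.TREATMENT,
    Injection.OLIGOMYCIN,
    Injection.FCCP,
    Injection.ROTENONE_ANTIMYCIN,
]


@dataclass(frozen=True)
class OCRTrace:
    """One well's OCR time series with its injection schedule."""

    times: tuple[float, ...]
    ocr: tuple[float, ...]
    injections: tuple[tuple[Injection, float], ...]
    well: str = "well_1"

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        ocr = tuple(float(v) for v in self.ocr)
        inj = tuple(
            (Injection.parse(lab), float(t)) for lab, t in self.injections
        )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ocr", ocr)
        object.__setattr__(self, "injections", inj)
        if len(times) != len(ocr):
            raise ValueError("times and ocr must have equal length")
        if len(times) < 2:
            raise ValueError("trace needs at least two measurements")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        inj_times = [t for _, t in inj]
        if any(b <= a for a, b in zip(inj_times, inj_times[1:])):
            raise ValueError("injection times must be increasing")
        if inj and not (times[0] <= inj_times[0] and inj_times[-1] <= times[-1]):
            raise ValueError("injection times must lie within the trace span")
        labels = [lab for lab, _ in inj]
        order = [_CANONICAL_ORDER.index(lab) for lab in labels]
        if sorted(order) != order or len(set(labels)) != len(labels):
            raise ValueError(
                "injections must appear at most once each, in the order "
                "treatment?, oligomycin, FCCP, rotenone/antimycin"
            )


@dataclass(frozen=True)
class OCRMetrics:
    """Stress-test summary rates for one well (pmol O2/min), with the
    same five values normalized to basal respiration."""

    non_mitochondrial: float
    basal: float
    maximal: float
    proton_leak: float
    post_treatment: float | None
    well: str = "well_1"

    @property
    def normalized(self) -> dict[str, float | None]:
        if self.basal == 0:
            raise ZeroDivisionError("basal respiration is zero")
        return {
            "non_mitochondrial": self.non_mitochondrial / self.basal,
            "basal": 1.0,
            "maximal": self.maximal / self.basal,
            "proton_leak": self.proton_leak / self.basal,
            "post_treatment": (
                self.post_treatment / self.basal
                if self.post_treatment is not None
                else None
            ),
        }


def _segment(
    trace: OCRTrace, label: Injection
) -> np.ndarray:
    """OCR values in the half-open window (t_label, t_next]."""
    inj = dict((lab, t) for lab, t in trace.injections)
    start = inj[label]
    later = [t for _, t in trace.injections if t > start]
    end = later[0] if later else float(trace.times[-1])
    t = np.asarray(trace.times)
    v = np.asarray(trace.ocr)
    mask = (t > start) & (t <= end)
    values = v[mask]
    if values.size == 0:
        raise ValueError(
            f"no measurements in the window after {label.value} injection"
        )
    return values


def compute_ocr_metrics(trace: OCRTrace) -> OCRMetrics:
    """Segment-wise min/max/last metrics for one annotated trace."""
    present = {lab for lab, _ in trace.injections}
    missing = [
        lab.value
        for lab in (
            Injection.OLIGOMYCIN,
            Injection.FCCP,
            Injection.ROTENONE_ANTIMYCIN,
        )
        if lab not in present
    ]
    if missing:
        raise ValueError(f"missing required injection(s): {missing}")

    t = np.asarray(trace.times)
    v = np.asarray(trace.ocr)
    first_injection_time = trace.injections[0][1]
    pre = v[t <= first_injection_time]
    if pre.size == 0:
        raise ValueError("no measurements before the first injection")

    non_mito = float(_segment(trace, Injection.ROTENONE_ANTIMYCIN).min())
    basal = float(pre[-1]) - non_mito
    maximal = float(_segment(trace, Injection.FCCP).max()) - non_mito
    proton_leak = float(_segment(trace, Injection.OLIGOMYCIN).min()) - non_mito
    post_treatment = None
    if Injection.TREATMENT in present:
        post_treatment = (
            float(_segment(trace, Injection.TREATMENT)[-1]) - non_mito
        )
    return OCRMetrics(
        non_mitochondrial=non_mito,
        basal=basal,
        maximal=maximal,
        proton_leak=proton_leak,
        post_treatment=post_treatment,
        well=trace.well,
    )


def aggregate_metrics(per_well: Sequence[OCRMetrics]) -> OCRMetrics:
    """Average per-well metrics (wells measured in octuplicate or more).

    ``post_treatment`` is averaged over the wells that define it and is
    None when no well does.
    """
    if not per_well:
        raise ValueError("no per-well metrics to aggregate")
    post = [m.post_treatment for m in per_well if m.post_treatment is not None]
    return OCRMetrics(
        non_mitochondrial=float(np.mean([m.non_mitochondrial for m in per_well])),
        basal=float(np.mean([m.basal for m in per_well])),
        maximal=float(np.mean([m.maximal for m in per_well])),
        proton_leak=float(np.mean([m.proton_leak for m in per_well])),
        post_treatment=float(np.mean(post)) if post else None,
        well="aggregate",
    )
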