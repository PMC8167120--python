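"""Four-parameter logistic (4PL) viability fitting and IC50 shifts.

The model is the classic "log(inhibitor) vs. response — variable slope"
sigmoid, parameterized in log10-dose space:

    y(x) = Bottom + (Top − Bottom) / (1 + 10^((LogIC50 − x) · HillSlope))

with x = log10(dose).  At x = LogIC50 the curve passes exactly through
(Top + Bottom) / 2, so IC50 = 10^LogIC50 is the half-effect dose.
HillSlope is negative for inhibition curves read as raw response vs
log-dose in this parameterization when response falls with dose.

Absorbance-based viability readings (e.g. MTT at 570 nm with a 650 nm
reference) are first corrected (measure − reference) and scaled so the
mean untreated control is 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "ViabilityPoint",
    "DoseResponseFit",
    "four_pl",
    "normalize_viability",
    "fit_4pl",
    "ic50_shift",
]


@dataclass(frozen=True)
class ViabilityPoint:
    """One well of a viability assay at one dose."""

    dose: float
    replicate: int
    absorbance_measure: float
    absorbance_reference: float | None = None
    viability_percent: float | None = None

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")
        if self.viability_percent is not None and not np.isfinite(
            self.viability_percent
        ):
            raise ValueError("viability_percent must be finite")

    @property
    def corrected_absorbance(self) -> float:
        if self.absorbance_reference is None:
            return self.absorbance_measure
        return self.absorbance_measure - self.absorbance_reference


@dataclass(frozen=True)
class DoseResponseFit:
    bottom: float
    top: float
    log_ic50: float
    hill_slope: float
    residual_sum_squares: float
    converged: bool

    @property
    def ic50(self) -> float:
        return float(10.0 ** self.log_ic50)

    def predict(self, doses: "Sequence[float] | np.ndarray") -> np.ndarray:
        x = np.log10(np.asarray(doses, dtype=float))
        return four_pl(x, self.bottom, self.top, self.log_ic50, self.hill_slope)


def four_pl(
    log_dose: "float | np.ndarray",
    bottom: float,
    top: float,
    log_ic50: float,
    hill_slope: float,
) -> "float | np.ndarray":
    """Evaluate the 4PL at log10-dose ``log_dose``."""
    return bottom + (top - bottom) / (
        1.0 + 10.0 ** ((log_ic50 - np.asarray(log_dose)) * hill_slope)
    )


def normalize_viability(
    points: Sequence[ViabilityPoint],
    untreated: "Callable[[ViabilityPoint], bool] | None" = None,
) -> list[ViabilityPoint]:
    """Scale corrected absorbances so mean untreated control = 100%.

    ``untreated`` selects the control wells; by default dose == 0 wells
    are the controls.  Reference-wavelength subtraction happens per well
    before averaging.
    """
    if untreated is None:
        untreated = lambda p: p.dose == 0.0  # noqa: E731
    controls = [p.corrected_absorbance for p in points if untreated(p)]
    if not controls:
        raise ValueError("no untreated control wells found")
    control_mean = float(np.mean(controls))
    if control_mean <= 0:
        raise ValueError(
            f"untreated control mean must be positive, got {control_mean}"
        )
    return [
        replace(
            p,
            viability_percent=100.0 * p.corrected_absorbance / control_mean,
        )
        for p in points
    ]


def _initial_guess(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float]:
    """Deterministic starting point: Top/Bottom from extreme mean
    responses, LogIC50 from the dose bracketing the half-way crossing,
    Hill sign from the response direction."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    # mean response per distinct dose
    ux, inverse = np.unique(xs, return_inverse=True)
    uy = np.array([ys[inverse == i].mean() for i in range(len(ux))])
    top = float(uy.max())
    bottom = float(uy.min())
    decreasing = uy[-1] < uy[0]
    half = (top + bottom) / 2.0
    crossing = ux[int(np.argmin(np.abs(uy - half)))]
    hill = -1.0 if decreasing else 1.0
    return bottom, top, float(crossing), hill


def fit_4pl(
    doses: "Sequence[float] | np.ndarray",
    viabilities: "Sequence[float] | np.ndarray",
    init: "tuple[float, float, float, float] | None" = None,
    constrain_bottom_nonnegative: bool = False,
    zero_dose_decades_below: float = 2.0,
) -> DoseResponseFit:
    """Nonlinear least-squares 4PL fit in log10-dose space.

    Zero-dose (untreated) points are retained by mapping them to a
    pseudo-dose ``zero_dose_decades_below`` decades under the smallest
    positive dose; they anchor the Top plateau.  Requires ≥ 5 distinct
    doses.  Non-convergence returns ``converged=False`` with the
    best-effort parameters rather than raising.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(viabilities, dtype=float)
    if d.shape != y.shape:
        raise ValueError("doses and viabilities must have equal length")
    if len(np.unique(d)) < 5:
        raise ValueError(
            f"need >= 5 distinct doses for a 4-parameter fit, got "
            f"{len(np.unique(d))}"
        )
    positive = d[d > 0]
    if positive.size == 0:
        raise ValueError("all doses are zero")
    d = d.copy()
    d[d == 0] = positive.min() * 10.0 ** (-zero_dose_decades_below)
    x = np.log10(d)

    p0 = init if init is not None else _initial_guess(x, y)
    if constrain_bottom_nonnegative:
        lower = (0.0, -np.inf, -np.inf, -np.inf)
        upper = (np.inf, np.inf, np.inf, np.inf)
        p0 = (max(p0[0], 0.0), *p0[1:])
    else:
        lower, upper = (-np.inf,) * 4, (np.inf,) * 4

    def model(xv: np.ndarray, b: float, t: float, l50: float, h: float):
        return four_pl(xv, b, t, l50, h)

    try:
        popt, _ = optimize.curve_fit(
            model, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
        converged = bool(np.all(np.isfinite(popt)))
    except (RuntimeError, optimize.OptimizeWarning):
        popt, converged = np.asarray(p0, dtype=float), False
    resid = y - model(x, *popt)
    return DoseResponseFit(
        bottom=float(popt[0]),
        top=float(popt[1]),
        log_ic50=float(popt[2]),
        hill_slope=float(popt[3]),
        residual_sum_squares=float(np.sum(resid**2)),
        converged=converged,
    )


def ic50_shift(
    fit_mono: DoseResponseFit, fit_combo: DoseResponseFit
) -> float:
    """Fold change IC50_mono / IC50_combo; > 1 means the combination
    partner sensitizes (the half-effect dose dropped)."""
    if not (fit_mono.converged and fit_combo.converged):
        raise ValueError("both fits must have converged to compare IC50s")
    return fit_mono.ic50 / fit_combo.ic50
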