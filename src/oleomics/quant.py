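"""Calibration fitting, LOQ/LDR handling and back-calculation to mg/g.

Calibration is unweighted ordinary least squares.  The linear dynamic range
is the widest contiguous run of calibration levels whose back-calculated
concentrations stay within +/-20% of the nominal values; the curve is then
rebuilt on that run and the LOQ is its lowest level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .feature_io import ValidationError

__all__ = [
    "CalibrationCurve",
    "QuantResult",
    "SurrogateMap",
    "fit_calibration",
    "back_calculate",
    "rsd_percent",
    "validation_report",
    "ACCURACY_TOL",
    "DILUTIONS_G_PER_L",
]

ACCURACY_TOL = 0.20
#: sample preparations: 500 mg to 5 mL (100 g/L) and the diluted 2 g/L one
DILUTIONS_G_PER_L = (100.0, 2.0)

N_INTRA_RUNS = 7
N_INTER_DAYS = 5
N_REPEAT_PREPARATIONS = 7


@dataclass(frozen=True)
class CalibrationCurve:
    """Slope/intercept/R2 fit with linear dynamic range and LOQ (mg/L)."""

    analyte: str
    detector: str
    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    r2: float
    ldr: tuple[float, float]
    loq: float

    def __post_init__(self) -> None:
        in_ldr = [c for c, _ in self.points if self.ldr[0] <= c <= self.ldr[1]]
        if len(in_ldr) < 5:
            raise ValidationError("calibration needs >= 5 points within the LDR")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValidationError("r2 out of [0, 1]")
        if self.loq < self.ldr[0]:
            raise ValidationError("LOQ below the linear range")

    def predict_response(self, conc_mg_l: float) -> float:
        return self.slope * conc_mg_l + self.intercept

    def invert_response(self, response: float) -> float:
        return (response - self.intercept) / self.slope


@dataclass(frozen=True)
class QuantResult:
    """Back-calculated concentration of one compound in one replicate."""

    compound: str
    product: str
    replicate: str
    conc_mg_per_g: float
    censoring: str  # quantified | below_loq | not_detected

    def __post_init__(self) -> None:
        if self.conc_mg_per_g < 0:
            raise ValidationError("concentration must be >= 0")
        if self.censoring != "quantified" and self.conc_mg_per_g != 0:
            raise ValidationError("censored results must carry conc = 0")


class SurrogateMap(dict):
    """compound -> quantification standard; every compound maps to one standard."""

    def standard_for(self, compound: str) -> str:
        if compound not in self:
            raise ValidationError(f"no quantification standard for {compound!r}")
        return self[compound]


def _ols(points: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    xs = np.array([c for c, _ in points], dtype=float)
    ys = np.array([r for _, r in points], dtype=float)
    fit = sps.linregress(xs, ys)
    # guard the tiny negative excursions of r**2 in exact-fit cases
    r2 = min(1.0, float(fit.rvalue) ** 2)
    return float(fit.slope), float(fit.intercept), r2


def fit_calibration(
    points: Sequence[tuple[float, float]],
    analyte: str = "",
    detector: str = "MS",
) -> CalibrationCurve:
    """Fit an OLS line and determine LDR/LOQ by back-calculated accuracy."""
    pts = sorted((float(c), float(r)) for c, r in points)
    if len(pts) < 5:
        raise ValidationError("calibration requires >= 5 points")
    concs = [c for c, _ in pts]
    if len(set(concs)) < 5:
        raise ValidationError("calibration requires >= 5 distinct concentrations")
    responses = [r for _, r in pts]
    if len(set(responses)) == 1:
        raise ValidationError("constant responses: no concentration dependence")

    slope, intercept, _ = _ols(pts)
    if slope == 0:
        raise ValidationError("zero slope")

    def accurate(pt: tuple[float, float], s: float, b: float) -> bool:
        c, r = pt
        if c == 0:
            return False
        back = (r - b) / s
        return abs(back / c - 1.0) <= ACCURACY_TOL

    ok = [accurate(pt, slope, intercept) for pt in pts]
    # widest contiguous accurate run (ties -> wider concentration span)
    best_run: tuple[int, int] | None = None
    i = 0
    while i < len(pts):
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(pts) and ok[j + 1]:
            j += 1
        if best_run is None or (j - i) > (best_run[1] - best_run[0]):
            best_run = (i, j)
        i = j + 1
    if best_run is None or best_run[1] - best_run[0] + 1 < 5:
        raise ValidationError("no linear range covering >= 5 points")

    run = pts[best_run[0]:best_run[1] + 1]
    slope, intercept, r2 = _ols(run)  # curve rebuilt on the linear range
    ldr = (run[0][0], run[-1][0])
    return CalibrationCurve(analyte, detector, tuple(pts), slope, intercept,
                            r2, ldr, loq=ldr[0])


def back_calculate(
    response: float,
    curve: CalibrationCurve,
    dilution_g_per_l: float,
    compound: str = "",
    product: str = "",
    replicate: str = "",
) -> QuantResult:
    """Convert an instrument response to mg/g of product, with censoring."""
    if curve.slope <= 0:
        raise ValidationError("non-positive slope")
    if response < 0:
        raise ValidationError("negative response")
    if dilution_g_per_l <= 0:
        raise ValidationError("dilution must be positive")
    conc_mg_l = curve.invert_response(response)
    if conc_mg_l < curve.loq:
        return QuantResult(compound, product, replicate, 0.0, "below_loq")
    return QuantResult(compound, product, replicate,
                       conc_mg_l / dilution_g_per_l, "quantified")


def select_dilution(predicted_conc_mg_l: float, curve: CalibrationCurve) -> float:
    """Prefer the concentrated 100 g/L preparation unless it exceeds the LDR."""
    if predicted_conc_mg_l <= curve.ldr[1]:
        return DILUTIONS_G_PER_L[0]
    return DILUTIONS_G_PER_L[1]


def rsd_percent(values: Sequence[float]) -> float:
    """Relative standard deviation, 100 * sample sd / mean."""
    vals = [float(v) for v in values]
    if len(vals) < 2:
        raise ValidationError("RSD requires >= 2 values")
    mean = sum(vals) / len(vals)
    if mean == 0:
        raise ValidationError("RSD undefined for zero mean")
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
    return 100.0 * sd / mean


def validation_report(
    intra: Mapping[str, Sequence[float]],
    inter: Mapping[str, Sequence[float]],
    repeat: Mapping[str, Sequence[float]],
) -> dict[str, dict[str, float]]:
    """Per-compound intra-day / inter-day / repeatability RSD% table.

    ``intra`` carries 7 same-day runs, ``inter`` 5 daily values and
    ``repeat`` 7 independent preparations per compound.
    """
    compounds = set(intra) | set(inter) | set(repeat)
    out: dict[str, dict[str, float]] = {}
    for compound in sorted(compounds):
        sets = {
            "intra_day_rsd": (intra.get(compound), N_INTRA_RUNS),
            "inter_day_rsd": (inter.get(compound), N_INTER_DAYS),
            "repeatability_rsd": (repeat.get(compound), N_REPEAT_PREPARATIONS),
        }
        row: dict[str, float] = {}
        for label, (vals, expected_n) in sets.items():
            if vals is None or len(vals) != expected_n:
                raise ValidationError(
                    f"{compound}: {label} needs exactly {expected_n} replicates")
            row[label] = rsd_percent(vals)
        out[compound] = row
    return out
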