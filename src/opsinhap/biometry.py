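"""Spherical equivalent refraction (SER) from ocular biometry.

SER, in diopters, is estimated from axial length (AL, mm) and corneal
curvature (CC, diopters of keratometric power) with a linear formula
calibrated on 373 adults:

    SER = -(AL * 2.03 + 0.94 * CC) + 88.58

Longer eyes and steeper corneas are more myopic (more negative SER).
:func:`fit_ser_formula` re-derives such a formula from any calibration table
by ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import AnalysisError, ValidationError

__all__ = [
    "SerFormula",
    "PUBLISHED_SER_FORMULA",
    "BiometryRecord",
    "estimate_ser",
    "invert_axial_length",
    "fit_ser_formula",
    "SerFit",
    "AL_RANGE_MM",
    "CC_RANGE_D",
]

AL_RANGE_MM = (15.0, 35.0)
CC_RANGE_D = (35.0, 52.0)


@dataclass(frozen=True)
class SerFormula:
    """Linear SER estimator: SER = -(AL*al_coefficient + cc_coefficient*CC) + intercept."""

    al_coefficient: float  # D per mm, > 0
    cc_coefficient: float  # D per D
    intercept: float  # D

    def __post_init__(self) -> None:
        if not self.al_coefficient > 0:
            raise ValidationError("al_coefficient must be positive")

    def evaluate(self, al_mm: float, cc_d: float):
        return -(np.asarray(al_mm) * self.al_coefficient
                 + self.cc_coefficient * np.asarray(cc_d)) + self.intercept


#: Calibration published for the study cohort (373 adults).
PUBLISHED_SER_FORMULA = SerFormula(2.03, 0.94, 88.58)


@dataclass
class BiometryRecord:
    """Per-eye biometry. AL may be a pre-averaged value or replicate reads;
    CC a single keratometry mean or the two IOL-Master read-outs (averaged)."""

    subject_id: str
    eye: str  # "OD" or "OS"
    al_mm: float
    cc_d: float
    observed_ser: float | None = None

    @classmethod
    def from_readings(
        cls,
        subject_id: str,
        eye: str,
        al_reads_mm: Sequence[float],
        cc_reads_d: Sequence[float],
        observed_ser: float | None = None,
    ) -> "BiometryRecord":
        if len(al_reads_mm) == 0 or len(cc_reads_d) == 0:
            raise ValidationError("need at least one AL and one CC reading")
        return cls(
            subject_id,
            eye,
            float(np.mean(al_reads_mm)),
            float(np.mean(cc_reads_d)),
            observed_ser,
        )


class BiometryRangeWarning(UserWarning):
    """AL or CC outside the plausible adult range."""


def _check_ranges(al_mm: float, cc_d: float, on_out_of_range: str) -> None:
    msgs = []
    if not AL_RANGE_MM[0] < al_mm < AL_RANGE_MM[1]:
        msgs.append(f"AL {al_mm} mm outside {AL_RANGE_MM}")
    if not CC_RANGE_D[0] < cc_d < CC_RANGE_D[1]:
        msgs.append(f"CC {cc_d} D outside {CC_RANGE_D}")
    for m in msgs:
        if on_out_of_range == "error":
            raise ValidationError(m)
        elif on_out_of_range == "warn":
            warnings.warn(m, BiometryRangeWarning, stacklevel=3)


def estimate_ser(
    record: BiometryRecord | None = None,
    *,
    al_mm: float | None = None,
    cc_d: float | None = None,
    formula: SerFormula = PUBLISHED_SER_FORMULA,
    on_out_of_range: str = "warn",
) -> float:
    """Calculated SER in diopters for one eye.

    Accepts either a :class:`BiometryRecord` or bare ``al_mm``/``cc_d``
    keywords. ``on_out_of_range`` is "warn" (default), "error" or "ignore".
    """
    if record is not None:
        al_mm, cc_d = record.al_mm, record.cc_d
    if al_mm is None or cc_d is None:
        raise ValidationError("both AL and CC are required to estimate SER")
    al_mm, cc_d = float(al_mm), float(cc_d)
    if np.isnan(al_mm) or np.isnan(cc_d):
        raise ValidationError("AL/CC must not be NaN")
    if on_out_of_range != "ignore":
        _check_ranges(al_mm, cc_d, on_out_of_range)
    return float(formula.evaluate(al_mm, cc_d))


def invert_axial_length(
    ser_d: float, cc_d: float, formula: SerFormula = PUBLISHED_SER_FORMULA
) -> float:
    """AL (mm) that reproduces ``ser_d`` at a given CC under ``formula``."""
    return (formula.intercept - ser_d - formula.cc_coefficient * cc_d) / (
        formula.al_coefficient
    )


@dataclass(frozen=True)
class SerFit:
    formula: SerFormula | None
    r_squared: float
    n: int
    #: raw OLS coefficients (intercept, AL, CC) in the regression sign
    #: convention SER = b0 + b1*AL + b2*CC
    coefficients: tuple[float, float, float] = (0.0, 0.0, 0.0)


def fit_ser_formula(records: Iterable[BiometryRecord]) -> SerFit:
    """Ordinary least squares of observed SER on AL and CC.

    Returns the fitted :class:`SerFormula` (coefficients converted to the
    formula's sign convention) and the R-squared of the fit.  A degenerate fit
    with both slopes ~0 (e.g. all SERs equal) yields a formula-less
    :class:`SerFit` carrying the intercept in ``coefficients``, because
    :class:`SerFormula` requires a positive AL coefficient.
    """
    recs = [r for r in records if r.observed_ser is not None]
    if len(recs) < 3:
        raise ValidationError("need >= 3 records with observed SER")
    X = np.column_stack(
        [
            np.ones(len(recs)),
            [r.al_mm for r in recs],
            [r.cc_d for r in recs],
        ]
    )
    y = np.array([r.observed_ser for r in recs], dtype=float)
    if np.linalg.matrix_rank(X) < 3:
        raise AnalysisError("rank-deficient design: AL and CC are collinear")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if tss == 0 else 1.0 - float(np.sum(resid**2)) / tss
    b0, b1, b2 = (float(b) for b in beta)
    # snap numerically-zero slopes (e.g. constant SER) to exactly zero
    scale = max(1.0, float(np.abs(y).max()))
    b1 = 0.0 if abs(b1) < 1e-10 * scale else b1
    b2 = 0.0 if abs(b2) < 1e-10 * scale else b2
    formula = None
    if -b1 > 0:
        formula = SerFormula(-b1, -b2, b0)
    return SerFit(formula, r2, len(recs), (b0, b1, b2))
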