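"""Paired-eye crossover trial of contrast-reducing spectacle lenses.

Each participant wears the experimental lens on one eye and the control lens
on the other, so every subject-period contributes one eye per arm and the
arms can be compared within subject.  Axial-length trajectories are
normalized to µm of change from the first (baseline) visit, a growth rate is
fitted to each eye by ordinary least squares (µm/day), and the arms are
compared with a paired two-sided t-test on the within-subject-period
experimental-minus-control slope differences, pooled across periods (a
Wilcoxon signed-rank option is provided).  Re-enrolled subjects swap lenses
between eyes, and their second period enters as a new paired observation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import AnalysisError, ValidationError

__all__ = [
    "EyeTrajectory",
    "GrowthRate",
    "ArmSummary",
    "ArmComparison",
    "normalize_trajectory",
    "fit_growth_rate",
    "compare_arms",
]

MM_TO_UM = 1000.0


@dataclass(frozen=True)
class EyeTrajectory:
    """Dated axial-length series for one eye in one trial period.

    ``lengths`` are in mm when ``normalized`` is False (raw IOL-Master means,
    each typically the average of 20 reads) and in µm of change from baseline
    after :func:`normalize_trajectory`.
    """

    subject_id: str
    eye: str  # "dominant" | "non_dominant"
    arm: str  # "experimental" | "control"
    period: int  # 1 or 2
    days: tuple[int, ...]
    lengths: tuple[float, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.days) != len(self.lengths):
            raise ValidationError("days and lengths differ in length")
        if len(self.days) == 0:
            raise ValidationError("empty trajectory")
        d = np.asarray(self.days)
        if np.any(np.diff(d) <= 0):
            raise ValidationError("days must be strictly increasing")
        if d[0] != 0:
            raise ValidationError("first visit day must be 0")

    @property
    def baseline_mm(self) -> float:
        if self.normalized:
            raise AnalysisError("baseline is not retained after normalization")
        return self.lengths[0]


@dataclass(frozen=True)
class GrowthRate:
    slope: float  # µm/day
    intercept: float  # µm
    residual_sd: float  # µm
    n_points: int


@dataclass(frozen=True)
class ArmSummary:
    arm: str
    n_eyes: int
    mean_rate: float  # µm/day
    se_rate: float  # µm/day, SD of per-eye slopes / sqrt(n)


@dataclass(frozen=True)
class ArmComparison:
    experimental: ArmSummary
    control: ArmSummary
    mean_difference: float  # experimental - control, µm/day
    p_paired: float
    n_pairs: int
    per_period: dict  # period -> (mean_difference, p, n_pairs)


def normalize_trajectory(raw: EyeTrajectory) -> EyeTrajectory:
    """Re-express lengths as µm change from the baseline (first) visit."""
    if raw.normalized:
        return raw
    base = raw.lengths[0]
    um = tuple((v - base) * MM_TO_UM for v in raw.lengths)
    return replace(raw, lengths=um, normalized=True)


def fit_growth_rate(traj: EyeTrajectory) -> GrowthRate:
    """OLS growth rate (µm/day) of a trajectory; normalizes mm input first."""
    traj = normalize_trajectory(traj)
    if len(traj.days) < 3:
        raise AnalysisError("need >= 3 time points to fit a growth rate")
    x = np.asarray(traj.days, dtype=float)
    y = np.asarray(traj.lengths, dtype=float)
    if np.ptp(x) == 0:
        raise AnalysisError("zero time span")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sd = float(np.std(resid, ddof=2)) if len(x) > 2 else 0.0
    return GrowthRate(float(slope), float(intercept), sd, len(x))


def _paired_p(diffs: np.ndarray, test: str) -> float:
    if np.allclose(diffs, 0.0):
        return 1.0
    if test == "paired-t":
        return float(stats.ttest_rel(diffs, np.zeros_like(diffs)).pvalue)
    if test == "wilcoxon":
        return float(stats.wilcoxon(diffs).pvalue)
    raise ValidationError(f"unknown test {test!r}")


def compare_arms(
    trajectories: Iterable[EyeTrajectory], test: str = "paired-t"
) -> ArmComparison:
    """Fit per-eye growth rates and compare the arms within subject-periods.

    Every subject-period must contribute exactly one experimental and one
    control eye.  Pairs from all periods pool into the primary paired test;
    per-period differences and p-values are also reported.
    """
    slopes: dict[tuple[str, int], dict[str, float]] = {}
    for t in trajectories:
        if t.arm not in ("experimental", "control"):
            raise ValidationError(f"unknown arm {t.arm!r}")
        key = (t.subject_id, t.period)
        entry = slopes.setdefault(key, {})
        if t.arm in entry:
            raise ValidationError(
                f"duplicate {t.arm} eye for subject {t.subject_id} "
                f"period {t.period}"
            )
        entry[t.arm] = fit_growth_rate(t).slope
    unpaired = [k for k, v in slopes.items() if len(v) != 2]
    if unpaired:
        raise ValidationError(
            f"unpaired subject-periods (need one eye per arm): {unpaired}"
        )
    if not slopes:
        raise ValidationError("no trajectories supplied")
    keys = sorted(slopes)
    exp = np.array([slopes[k]["experimental"] for k in keys])
    ctl = np.array([slopes[k]["control"] for k in keys])
    diffs = exp - ctl
    per_period: dict[int, tuple[float, float, int]] = {}
    for period in sorted({k[1] for k in keys}):
        sel = np.array([k[1] == period for k in keys])
        if sel.sum() >= 2:
            per_period[period] = (
                float(diffs[sel].mean()),
                _paired_p(diffs[sel], test),
                int(sel.sum()),
            )

    def _summary(arm: str, vals: np.ndarray) -> ArmSummary:
        se = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
        return ArmSummary(arm, int(vals.size), float(vals.mean()), se)

    return ArmComparison(
        experimental=_summary("experimental", exp),
        control=_summary("control", ctl),
        mean_difference=float(diffs.mean()),
        p_paired=_paired_p(diffs, test),
        n_pairs=len(keys),
        per_period=per_period,
    )
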