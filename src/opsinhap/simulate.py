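"""Synthetic data generators matching the structure the analyses assume.

Three generators cover the three data domains:

* :func:`generate_cohort` — an adult-male association cohort with the
  published haplotype group sizes and group mean SERs (11 groups, 413
  subjects by default), Gaussian within-group spread, an L:M cone-ratio
  protective effect, and an *OPN1MW*-MVVVA effect.  CC is drawn and AL is
  solved from the SER formula, so biometry and phenotype are exactly
  consistent by construction.
* :func:`generate_assay` — the 128-minigene splicing assay, with a baseline
  skipping level multiplied by per-SNP effect factors (attached to allele 2
  of each configured SNP) and replicate noise at the assay's typical
  within-group SD.
* :func:`generate_trial` — the paired-eye crossover lens trial: 13 subjects
  for period 1, 7 re-enrolling with lenses swapped between eyes for period 2,
  biweekly visits over ~3 months.

All generators are deterministic given their spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .biometry import PUBLISHED_SER_FORMULA, SerFormula, invert_axial_length
from .cohort import Subject, classify_cone_ratio
from .errors import ValidationError
from .haplotypes import (
    allele_at,
    enumerate_minigene_haplotypes,
    load_snp_panel,
    parse_haplotype,
    _resolve_snp,
)
from .lens_trial import EyeTrajectory
from .splice import SpliceMeasurement
from .tables import load_table1_fixture

__all__ = [
    "CohortSpec",
    "AssaySpec",
    "TrialSpec",
    "generate_cohort",
    "generate_assay",
    "generate_trial",
]


def _table1_defaults() -> tuple[dict[str, int], dict[str, float]]:
    df = load_table1_fixture()
    sizes = dict(zip(df["haplotype"], df["n"].astype(int)))
    means = dict(zip(df["haplotype"], df["mean_ser_os"].astype(float)))
    return sizes, means


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for the synthetic association cohort.

    Group sizes and mean SERs default to the published 11-haplotype table
    (n = 413).  The within-group SER SD is not published; 2.0 D is used as a
    typical adult refraction spread.  Cone-ratio parameters emulate the
    ~2L:1M average; the 0.61 D cone-ratio effect and the 0.39 D
    *OPN1MW*-MVVVA effect (carrier frequency 64/413) match the reported
    group differences.
    """

    group_sizes: Mapping[str, int] | None = None
    group_mean_ser: Mapping[str, float] | None = None
    within_group_sd: float = 2.0  # D
    cc_mean: float = 43.5  # D
    cc_sd: float = 1.4  # D
    percent_l_mean: float = 67.0
    percent_l_sd: float = 12.0
    cone_ratio_effect: float = 0.61  # D of extra myopia in the balanced group
    opn1mw_mvvva_freq: float = 64 / 413
    opn1mw_mvvva_effect: float = 0.39  # D of extra myopia in MVVVA-only carriers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_group_sd < 0 or self.cc_sd <= 0 or self.percent_l_sd <= 0:
            raise ValidationError("spread parameters must be positive")
        if not 0 <= self.opn1mw_mvvva_freq <= 1:
            raise ValidationError("opn1mw_mvvva_freq must be in [0,1]")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _centered_offsets(indicator: np.ndarray, effect: float) -> np.ndarray:
    """Offsets making the flagged class ``effect`` D lower in SER (more
    myopic) than the rest, with zero mean at the realised class fractions so
    the configured group mean is preserved exactly."""
    f = indicator.mean()
    return np.where(indicator, -(1.0 - f) * effect, f * effect)


def generate_cohort(
    spec: CohortSpec = CohortSpec(), formula: SerFormula = PUBLISHED_SER_FORMULA
) -> list[Subject]:
    """Draw a synthetic cohort; all inclusion flags are set passing."""
    sizes, means = _table1_defaults()
    if spec.group_sizes is not None:
        sizes = dict(spec.group_sizes)
    if spec.group_mean_ser is not None:
        means = dict(spec.group_mean_ser)
    if set(sizes) != set(means):
        raise ValidationError("group_sizes and group_mean_ser keys differ")
    for h in sizes:
        parse_haplotype(h, strict=True)  # raises on off-panel spec haplotypes
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    subjects: list[Subject] = []
    idx = 0
    for hap in sorted(sizes):
        n = int(sizes[hap])
        if n < 1:
            raise ValidationError(f"group {hap}: size must be >= 1")
        ser = rng.normal(means[hap], spec.within_group_sd, n)
        pct_l = _truncated_normal(
            rng, spec.percent_l_mean, spec.percent_l_sd, 0.0, 100.0, n
        )
        skewed = np.array(
            [classify_cone_ratio(p) == "skewed" for p in pct_l]
        )
        mvvva = rng.random(n) < spec.opn1mw_mvvva_freq
        # balanced subjects are cone_ratio_effect D more myopic; MVVVA-only
        # carriers are opn1mw_mvvva_effect D more myopic; both offsets are
        # centred within the group so configured group means are preserved.
        ser = ser + _centered_offsets(skewed, -spec.cone_ratio_effect)
        ser = ser + _centered_offsets(mvvva, spec.opn1mw_mvvva_effect)
        cc = rng.normal(spec.cc_mean, spec.cc_sd, n)
        for j in range(n):
            al = invert_axial_length(float(ser[j]), float(cc[j]), formula)
            subjects.append(
                Subject(
                    subject_id=f"S{idx:04d}",
                    opn1lw_haplotype=hap,
                    calculated_ser=float(ser[j]),
                    opn1mw_amino_haplotypes=("MVVVA",)
                    if mvvva[j]
                    else ("MVAIS",),
                    al_mm=float(al),
                    cc_d=float(cc[j]),
                    percent_l=float(pct_l[j]),
                )
            )
            idx += 1
    return subjects


@dataclass(frozen=True)
class AssaySpec:
    """Study conditions for the synthetic 128-minigene splicing assay.

    ``snp_effects`` maps SNP ids to the multiplicative factor applied to
    haplotypes carrying allele 2 of that SNP; the dominant factor (12.7x at
    rs145009674) matches the reported allele-group ratio and the lesser
    factors encode the two additional SNPs that impair exon-3 inclusion to
    smaller degrees.  Replicate noise defaults to the assay's typical
    within-group SD of 1.5 percentage points.
    """

    baseline_skip: float = 1.0  # % exon-3 skipped with no effect allele
    snp_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "rs145009674": 12.7,
            "rs155715655": 3.0,
            "rs5986963": 2.0,
        }
    )
    replicate_sd: float = 1.5  # percentage points
    n_replicates: int = 2
    gain_range: tuple[float, float] = (0.5, 2.0)  # random AUC rescaling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_skip <= 0:
            raise ValidationError("baseline_skip must be positive")
        if any(f <= 0 for f in self.snp_effects.values()):
            raise ValidationError("snp effect factors must be positive")
        if self.replicate_sd < 0 or self.n_replicates < 1:
            raise ValidationError("bad replicate settings")


def true_skip_percent(haplotype: str, spec: AssaySpec) -> float:
    """Noise-free percent skipped for a haplotype under ``spec``."""
    panel = load_snp_panel()
    value = spec.baseline_skip
    for snp_id, factor in spec.snp_effects.items():
        snp = _resolve_snp(snp_id, panel)
        if allele_at(haplotype, snp_id) == snp.allele2:
            value *= factor
    return float(np.clip(value, 0.0, 100.0))


def generate_assay(spec: AssaySpec = AssaySpec()) -> list[SpliceMeasurement]:
    """Replicate AUC pairs for all 128 minigene haplotypes."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    out: list[SpliceMeasurement] = []
    for hap in enumerate_minigene_haplotypes():
        truth = true_skip_percent(str(hap), spec)
        for rep in range(1, spec.n_replicates + 1):
            pct = float(
                np.clip(rng.normal(truth, spec.replicate_sd), 0.0, 100.0)
            ) if spec.replicate_sd > 0 else truth
            gain = rng.uniform(*spec.gain_range)
            out.append(
                SpliceMeasurement(
                    haplotype=str(hap),
                    replicate_id=rep,
                    auc_a=pct * gain,
                    auc_t=(100.0 - pct) * gain,
                )
            )
    return out


@dataclass(frozen=True)
class TrialSpec:
    """Study conditions for the synthetic paired-eye crossover trial.

    Arm growth rates match the reported means (0.063 experimental, 1.43
    control, µm/day).  The between-eye rate SD and per-point measurement
    noise were back-solved once so simulated arm standard errors approximate
    the reported ±0.33/±0.24 µm/day at 20 eyes per arm.  Visits default to
    biweekly over ~3 months.
    """

    n_subjects: int = 13
    n_reenroll: int = 7
    rate_experimental: float = 0.063  # µm/day
    rate_control: float = 1.43  # µm/day
    visit_days: tuple[int, ...] = (0, 14, 28, 42, 56, 70, 84)
    point_noise_sd: float = 10.0  # µm
    between_eye_rate_sd: float = 1.2  # µm/day
    baseline_mm_mean: float = 24.5
    baseline_mm_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reenroll > self.n_subjects:
            raise ValidationError("n_reenroll cannot exceed n_subjects")
        if self.point_noise_sd < 0 or self.between_eye_rate_sd < 0:
            raise ValidationError("noise SDs must be non-negative")


def generate_trial(spec: TrialSpec = TrialSpec()) -> list[EyeTrajectory]:
    """Per-eye axial-length trajectories for both periods of the trial.

    Period 1: the dominant eye wears the experimental lens.  Period 2 (the
    first ``n_reenroll`` subjects): lenses swap, so the non-dominant eye
    wears the experimental lens.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    days = np.asarray(spec.visit_days, dtype=float)
    rates = {"experimental": spec.rate_experimental,
             "control": spec.rate_control}
    out: list[EyeTrajectory] = []
    for period in (1, 2):
        n = spec.n_subjects if period == 1 else spec.n_reenroll
        for i in range(n):
            sid = f"P{i + 1:02d}"
            for eye in ("dominant", "non_dominant"):
                if period == 1:
                    arm = "experimental" if eye == "dominant" else "control"
                else:
                    arm = "experimental" if eye == "non_dominant" else "control"
                slope = rng.normal(rates[arm], spec.between_eye_rate_sd)
                baseline = rng.normal(spec.baseline_mm_mean, spec.baseline_mm_sd)
                noise = (
                    rng.normal(0.0, spec.point_noise_sd, days.size)
                    if spec.point_noise_sd > 0
                    else np.zeros(days.size)
                )
                lengths_mm = baseline + (slope * days + noise) / 1000.0
                out.append(
                    EyeTrajectory(
                        subject_id=sid,
                        eye=eye,
                        arm=arm,
                        period=period,
                        days=tuple(int(d) for d in days),
                        lengths=tuple(float(v) for v in lengths_mm),
                    )
                )
    return out
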