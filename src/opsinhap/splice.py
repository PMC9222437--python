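"""Exon-3 skipping quantification from allele-specific primer extension.

A single-base extension assay distinguishes transcripts in which exon 4 is
spliced to exon 3 (T incorporated) from transcripts in which exon 3 was
skipped and exon 4 is spliced to exon 2 (A incorporated).  Mass-spectrometric
peak areas (AUC) of the two extension products give

    % exon 3 skipped = 100 * AUC_A / (AUC_A + AUC_T)

Per-haplotype skipping is the mean over biological replicates.  SNP effects
are assessed over the 128-minigene design by splitting the haplotypes into
the two allele groups of one SNP (64 matched pairs differing only at that
SNP) and comparing them with a two-sided Mann-Whitney U test, Bonferroni
corrected over the number of SNPs tested (7 in the full design: six free
SNPs plus the rs5986963/rs5986964 pair treated as one unit).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import AnalysisError, ValidationError
from .haplotypes import (
    CONSTRAINED_JOINT_STATES,
    CONSTRAINED_PAIR,
    SnpDef,
    _resolve_snp,
    load_snp_panel,
)

__all__ = [
    "SpliceMeasurement",
    "HaplotypeSkipping",
    "SnpEffect",
    "percent_exon3_skipped",
    "summarize_haplotype",
    "summarize_assay",
    "snp_effect",
    "joint_pair_effect",
    "all_snp_effects",
    "standard_curve",
]

DEFAULT_N_COMPARISONS = 7


def percent_exon3_skipped(auc_a: float, auc_t: float) -> float:
    """Percent of transcripts lacking exon 3, from the two extension AUCs.

    Invariant to common rescaling of both areas.
    """
    if auc_a < 0 or auc_t < 0:
        raise ValidationError("AUC values must be non-negative")
    total = auc_a + auc_t
    if total == 0:
        raise AnalysisError("both extension-product areas are zero")
    return 100.0 * auc_a / total


@dataclass(frozen=True)
class SpliceMeasurement:
    """One biological replicate of the splicing assay for one minigene."""

    haplotype: str
    replicate_id: int
    auc_a: float  # exon-3-skipped extension product
    auc_t: float  # exon-3-included extension product

    @property
    def percent_skipped(self) -> float:
        return percent_exon3_skipped(self.auc_a, self.auc_t)


@dataclass(frozen=True)
class HaplotypeSkipping:
    haplotype: str
    percent_skipped: float  # mean over replicates, 0..100
    n_replicates: int


def summarize_haplotype(
    measurements: Sequence[SpliceMeasurement],
) -> HaplotypeSkipping:
    """Mean percent skipped over the replicates of one haplotype."""
    if not measurements:
        raise ValidationError("no measurements supplied")
    haps = {m.haplotype for m in measurements}
    if len(haps) > 1:
        raise ValidationError(f"mixed haplotypes in one group: {sorted(haps)}")
    pct = [m.percent_skipped for m in measurements]
    return HaplotypeSkipping(
        measurements[0].haplotype, float(np.mean(pct)), len(pct)
    )


def summarize_assay(
    measurements: Iterable[SpliceMeasurement],
) -> list[HaplotypeSkipping]:
    """Group measurements by haplotype and summarize each."""
    groups: dict[str, list[SpliceMeasurement]] = defaultdict(list)
    for m in measurements:
        groups[m.haplotype].append(m)
    return [summarize_haplotype(groups[h]) for h in sorted(groups)]


@dataclass(frozen=True)
class SnpEffect:
    snp_id: str
    n_pairs: int
    median1: float  # allele-1 group median % skipped
    median2: float  # allele-2 group median % skipped
    fold: float  # allele-2 group mean / allele-1 group mean
    u_statistic: float
    p_raw: float
    p_adjusted: float  # Bonferroni: min(1, p_raw * n_comparisons)
    significant: bool


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration for small untied samples (min n <= 12 and both <= 20),
    otherwise the normal approximation with continuity and tie correction.
    """
    small = min(len(x), len(y)) <= 12 and max(len(x), len(y)) <= 20
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _allele_groups(
    table: Sequence[HaplotypeSkipping], snp: SnpDef
) -> tuple[np.ndarray, np.ndarray, int]:
    """Split summaries into allele-1/allele-2 groups of matched pairs.

    Haplotypes are paired by masking the SNP's position; every mask bucket
    must contain exactly one haplotype per allele.
    """
    pos = snp.position - 1
    buckets: dict[str, dict[str, float]] = defaultdict(dict)
    for row in table:
        h = row.haplotype
        key = h[:pos] + "." + h[pos + 1 :]
        buckets[key][h[pos]] = row.percent_skipped
    orphans = [
        k for k, d in buckets.items() if set(d) != set(snp.alleles)
    ]
    if orphans:
        raise ValidationError(
            f"{snp.snp_id}: {len(orphans)} haplotype(s) lack a partner "
            f"differing only at position {snp.position}: "
            f"{sorted(orphans)[:5]}"
        )
    g1 = np.array([d[snp.allele1] for d in buckets.values()])
    g2 = np.array([d[snp.allele2] for d in buckets.values()])
    return g1, g2, len(buckets)


def _effect_from_groups(
    snp_id: str,
    g1: np.ndarray,
    g2: np.ndarray,
    n_pairs: int,
    n_comparisons: int,
    alpha: float,
    fold_method: str,
) -> SnpEffect:
    if fold_method == "mean-ratio":
        m1, m2 = float(np.mean(g1)), float(np.mean(g2))
        if m1 <= 0 or m2 <= 0:
            raise AnalysisError(f"{snp_id}: non-positive group mean, no fold")
        fold = m2 / m1
    elif fold_method == "pair-ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = g2 / g1
        ok = np.isfinite(ratios)
        if not ok.any():
            raise AnalysisError(f"{snp_id}: no finite per-pair ratios")
        fold = float(np.mean(ratios[ok]))
    else:
        raise ValidationError(f"unknown fold_method {fold_method!r}")
    if np.array_equal(np.sort(g1), np.sort(g2)):
        # identical groups: U test is uninformative; report p = 1 directly
        u, p = float(len(g1) * len(g2)) / 2.0, 1.0
    else:
        u, p = _mannwhitney(g1, g2)
    p_adj = min(1.0, p * n_comparisons)
    return SnpEffect(
        snp_id=snp_id,
        n_pairs=n_pairs,
        median1=float(np.median(g1)),
        median2=float(np.median(g2)),
        fold=fold,
        u_statistic=u,
        p_raw=p,
        p_adjusted=p_adj,
        significant=p_adj < alpha,
    )


def snp_effect(
    table: Sequence[HaplotypeSkipping],
    snp_id: str,
    n_comparisons: int = DEFAULT_N_COMPARISONS,
    alpha: float = 0.05,
    fold_method: str = "mean-ratio",
) -> SnpEffect:
    """Allele effect of one unconstrained SNP on percent exon-3 skipping.

    ``fold_method`` "mean-ratio" (default) is the ratio of allele-group
    means; "pair-ratio" averages per-pair allele2/allele1 ratios instead.
    """
    panel = load_snp_panel()
    snp = _resolve_snp(snp_id, panel)
    if snp.snp_id in CONSTRAINED_PAIR:
        raise ValidationError(
            f"{snp.snp_id} varies jointly with its partner; use "
            "joint_pair_effect() to test (rs5986963, rs5986964) as one unit"
        )
    g1, g2, n_pairs = _allele_groups(table, snp)
    return _effect_from_groups(
        snp.snp_id, g1, g2, n_pairs, n_comparisons, alpha, fold_method
    )


def joint_pair_effect(
    table: Sequence[HaplotypeSkipping],
    n_comparisons: int = DEFAULT_N_COMPARISONS,
    alpha: float = 0.05,
    fold_method: str = "mean-ratio",
) -> SnpEffect:
    """Effect of the (rs5986963, rs5986964) joint states, tested as one unit.

    Group 1 is the (A,T) state and group 2 the (G,G) state; pairing masks
    both positions at once.
    """
    panel = load_snp_panel()
    p4, p5 = (_resolve_snp(s, panel).position - 1 for s in CONSTRAINED_PAIR)
    states = {"".join(s): i for i, s in enumerate(CONSTRAINED_JOINT_STATES)}
    buckets: dict[str, dict[int, float]] = defaultdict(dict)
    for row in table:
        h = row.haplotype
        state = h[p4] + h[p5]
        if state not in states:
            raise ValidationError(
                f"haplotype {h} carries joint state {state!r} outside "
                f"{list(states)}"
            )
        key = h[:p4] + "." + h[p4 + 1 : p5] + "." + h[p5 + 1 :]
        buckets[key][states[state]] = row.percent_skipped
    orphans = [k for k, d in buckets.items() if set(d) != {0, 1}]
    if orphans:
        raise ValidationError(
            f"joint pair: {len(orphans)} haplotype(s) lack the partner state"
        )
    g1 = np.array([d[0] for d in buckets.values()])
    g2 = np.array([d[1] for d in buckets.values()])
    return _effect_from_groups(
        "+".join(CONSTRAINED_PAIR),
        g1,
        g2,
        len(buckets),
        n_comparisons,
        alpha,
        fold_method,
    )


def all_snp_effects(
    table: Sequence[HaplotypeSkipping],
    n_comparisons: int = DEFAULT_N_COMPARISONS,
    alpha: float = 0.05,
    fold_method: str = "mean-ratio",
) -> list[SnpEffect]:
    """Effects for the six free SNPs plus the constrained pair (7 tests)."""
    panel = load_snp_panel()
    out = []
    for snp in panel:
        if snp.snp_id in CONSTRAINED_PAIR:
            continue
        out.append(
            snp_effect(table, snp.snp_id, n_comparisons, alpha, fold_method)
        )
    out.append(joint_pair_effect(table, n_comparisons, alpha, fold_method))
    return out


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float
    n: int


def standard_curve(
    known_fraction_skipped: Sequence[float],
    measured_percent: Sequence[float],
) -> StandardCurve:
    """Linear calibration of the assay against known template mixes.

    ``known_fraction_skipped`` are the true mixed fractions (0..1 or 0..100;
    percentages are detected and used as-is), ``measured_percent`` the assay
    read-outs.  A well-calibrated assay gives slope ~1, intercept ~0 on the
    percent scale.
    """
    x = np.asarray(known_fraction_skipped, dtype=float)
    y = np.asarray(measured_percent, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need >= 3 matched calibration points")
    if x.max() <= 1.0:
        x = 100.0 * x
    res = stats.linregress(x, y)
    return StandardCurve(
        float(res.slope), float(res.intercept), float(res.rvalue**2), x.size
    )
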