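"""Cohort filtering and haplotype-phenotype association tests.

The study design: adult males, European ancestry, normal trichromatic color
vision, no prior eye surgery or injury, a single *OPN1LW* gene sequence (so
the sequenced gene is known to be expressed), and an *OPN1LW* exon-3
haplotype shared by at least four retained participants.  Calculated SER of
the analysis eye (left, OS, by default) is the phenotype.

Tests: Kruskal-Wallis across haplotype groups (the group SER distributions
are non-Gaussian with unequal spreads), a Mann-Whitney allele dichotomy at a
chosen SNP, and a two-group comparison of skewed vs balanced L:M cone ratios.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import AnalysisError, ValidationError
from .haplotypes import allele_at, translate_haplotype

__all__ = [
    "Subject",
    "HaplotypeGroupSummary",
    "GroupTestResult",
    "FilterResult",
    "filter_cohort",
    "summarize_groups",
    "kruskal_wallis",
    "mann_whitney",
    "allele_dichotomy",
    "classify_cone_ratio",
    "cone_ratio_split",
]


@dataclass
class Subject:
    """One cohort member."""

    subject_id: str
    opn1lw_haplotype: str
    calculated_ser: float | None = None
    sex: str = "M"
    ancestry_european: bool = True
    color_vision_normal: bool = True
    prior_surgery_or_injury: bool = False
    single_opn1lw: bool = True
    opn1mw_amino_haplotypes: tuple[str, ...] = ()
    al_mm: float | None = None
    cc_d: float | None = None
    percent_l: float | None = None
    eye: str = "OS"

    def __post_init__(self) -> None:
        if self.percent_l is not None and not 0 <= self.percent_l <= 100:
            raise ValidationError(
                f"{self.subject_id}: percent_l {self.percent_l} outside [0,100]"
            )


@dataclass(frozen=True)
class HaplotypeGroupSummary:
    haplotype: str
    amino: str
    n: int
    median_ser: float
    mean_ser: float


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_value: float
    group_medians: dict = field(default_factory=dict)
    group_means: dict = field(default_factory=dict)
    group_sizes: dict = field(default_factory=dict)
    effect: float | None = None  # diopters, where meaningful


@dataclass(frozen=True)
class FilterResult:
    subjects: list[Subject]
    exclusions: Counter  # criterion -> number excluded by it

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)


def filter_cohort(
    subjects: Iterable[Subject], min_group_size: int = 4
) -> FilterResult:
    """Apply the inclusion criteria, then the haplotype group-size floor.

    Flag filters run first; the group-size filter is then applied once to the
    flag-passing set (haplotype counts are not re-iterated after small groups
    drop out). Returns the retained subjects plus a per-criterion exclusion
    tally.
    """
    exclusions: Counter = Counter()
    flagged: list[Subject] = []
    for s in subjects:
        if not s.ancestry_european:
            exclusions["ancestry_european"] += 1
        elif not s.color_vision_normal:
            exclusions["color_vision_normal"] += 1
        elif s.prior_surgery_or_injury:
            exclusions["prior_surgery_or_injury"] += 1
        elif not s.single_opn1lw:
            exclusions["single_opn1lw"] += 1
        else:
            flagged.append(s)
    counts = Counter(s.opn1lw_haplotype for s in flagged)
    kept = [s for s in flagged if counts[s.opn1lw_haplotype] >= min_group_size]
    exclusions["haplotype_group_size"] = len(flagged) - len(kept)
    return FilterResult(kept, exclusions)


def _grouped_sers(subjects: Iterable[Subject]) -> dict[str, np.ndarray]:
    groups: dict[str, list[float]] = defaultdict(list)
    for s in subjects:
        if s.calculated_ser is None:
            raise ValidationError(f"{s.subject_id}: calculated SER missing")
        groups[s.opn1lw_haplotype].append(s.calculated_ser)
    return {h: np.asarray(v) for h, v in sorted(groups.items())}


def summarize_groups(
    subjects: Iterable[Subject],
) -> list[HaplotypeGroupSummary]:
    """Per-haplotype n, median and mean calculated SER (analysis eye)."""
    return [
        HaplotypeGroupSummary(
            haplotype=h,
            amino=translate_haplotype(h),
            n=len(v),
            median_ser=float(np.median(v)),
            mean_ser=float(np.mean(v)),
        )
        for h, v in _grouped_sers(subjects).items()
    ]


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> GroupTestResult:
    """Kruskal-Wallis H across groups (tie-corrected, chi-square p, k-1 df).

    The all-tied case, where the tie correction makes H 0/0, is defined as
    H = 0, p = 1.
    """
    if len(groups) < 2:
        raise AnalysisError("Kruskal-Wallis needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("empty group supplied")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    meds = {i: float(np.median(a)) for i, a in enumerate(arrays)}
    means = {i: float(np.mean(a)) for i, a in enumerate(arrays)}
    sizes = {i: int(a.size) for i, a in enumerate(arrays)}
    return GroupTestResult(float(h), float(p), meds, means, sizes)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small untied samples
    (min n <= 12 and both <= 20), asymptotic with continuity and tie
    correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.array_equal(np.sort(x), np.sort(y)):
        return float(len(x) * len(y)) / 2.0, 1.0
    small = min(len(x), len(y)) <= 12 and max(len(x), len(y)) <= 20
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def allele_dichotomy(
    subjects: Sequence[Subject], snp_id: str, allele: str
) -> GroupTestResult:
    """Split the cohort by carrying ``allele`` at ``snp_id`` and compare SER.

    ``effect`` is the non-carrier mean minus the carrier mean (positive when
    carriers are more myopic). P-value from a two-sided Mann-Whitney U.
    """
    carriers, others = [], []
    for s in subjects:
        if s.calculated_ser is None:
            raise ValidationError(f"{s.subject_id}: calculated SER missing")
        (carriers if allele_at(s.opn1lw_haplotype, snp_id) == allele
         else others).append(s.calculated_ser)
    if not carriers or not others:
        raise AnalysisError(
            f"allele dichotomy at {snp_id}={allele}: one group is empty "
            f"(carriers={len(carriers)}, others={len(others)})"
        )
    u, p = mann_whitney(carriers, others)
    key_c, key_o = allele, f"not_{allele}"
    return GroupTestResult(
        statistic=u,
        p_value=p,
        group_medians={key_c: float(np.median(carriers)),
                       key_o: float(np.median(others))},
        group_means={key_c: float(np.mean(carriers)),
                     key_o: float(np.mean(others))},
        group_sizes={key_c: len(carriers), key_o: len(others)},
        effect=float(np.mean(others) - np.mean(carriers)),
    )


def classify_cone_ratio(percent_l: float) -> str:
    """"skewed" (>=67% or <=33% L cones) vs "balanced" (34-66%).

    Percentages are first rounded half-up to the nearest integer so the
    printed inequality thresholds partition the whole range (66.6 -> 67 ->
    skewed; 66.4 -> 66 -> balanced).
    """
    if not 0 <= percent_l <= 100:
        raise ValidationError(f"percent_l {percent_l} outside [0,100]")
    r = int(np.floor(percent_l + 0.5))
    return "skewed" if (r >= 67 or r <= 33) else "balanced"


def cone_ratio_split(
    subjects: Sequence[Subject], test: str = "welch"
) -> GroupTestResult:
    """Compare SER between skewed and balanced L:M cone-ratio groups.

    Subjects without a cone-ratio estimate are ignored. ``effect`` is the
    balanced-group mean minus the skewed-group mean (negative when skewed
    ratios are protective). ``test`` is "welch" (default) or "mannwhitney".
    """
    groups: dict[str, list[float]] = {"skewed": [], "balanced": []}
    for s in subjects:
        if s.percent_l is None:
            continue
        if s.calculated_ser is None:
            raise ValidationError(f"{s.subject_id}: calculated SER missing")
        groups[classify_cone_ratio(s.percent_l)].append(s.calculated_ser)
    if not groups["skewed"] and not groups["balanced"]:
        raise ValidationError("no subject carries a percent_l value")
    if not groups["skewed"] or not groups["balanced"]:
        raise AnalysisError("cone-ratio split left one group empty")
    sk = np.asarray(groups["skewed"])
    ba = np.asarray(groups["balanced"])
    if test == "welch":
        stat, p = stats.ttest_ind(ba, sk, equal_var=False)
    elif test == "mannwhitney":
        stat, p = mann_whitney(ba, sk)
    else:
        raise ValidationError(f"unknown test {test!r}")
    return GroupTestResult(
        statistic=float(stat),
        p_value=float(p),
        group_medians={"skewed": float(np.median(sk)),
                       "balanced": float(np.median(ba))},
        group_means={"skewed": float(np.mean(sk)),
                     "balanced": float(np.mean(ba))},
        group_sizes={"skewed": int(sk.size), "balanced": int(ba.size)},
        effect=float(np.mean(ba) - np.mean(sk)),
    )
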