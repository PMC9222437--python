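"""Split-halves risk ranking, correlations, and the scrambled-label null."""

import numpy as np
import pytest
from scipy import stats

from opsinhap import (
    AnalysisError,
    CohortSpec,
    SplitHalvesConfig,
    Subject,
    ValidationError,
    generate_cohort,
    rank_mean_correlation,
    scrambled_null,
    split_halves_rank,
    summarize_groups,
    variance_explained,
)

# frozen by independent computation (scipy.stats.pearsonr over the 11
# printed mean-SER / rank pairs of the bundled table)
TABLE1_PRINTED_R = 0.9331943469


def _subjects(groups: dict[str, list[float]]):
    return [
        Subject(f"s{h}{i}", h, calculated_ser=v)
        for h, vals in groups.items()
        for i, v in enumerate(vals)
    ]


class TestSplitHalvesRank:
    def test_separated_groups_rank_deterministically(self):
        rng = np.random.default_rng(0)
        subs = _subjects(
            {
                "AACGGTGG": list(rng.normal(-3.0, 0.1, 8)),
                "GCGGGCAT": list(rng.normal(0.0, 0.1, 8)),
            }
        )
        res = split_halves_rank(
            subs, SplitHalvesConfig(50, seed=0, keep_per_iteration=True)
        )
        assert res.final_ranks["AACGGTGG"] == 1.0
        assert res.final_ranks["GCGGGCAT"] == 2.0
        assert np.all(res.per_iteration_ranks == [1.0, 2.0])

    def test_rank_sums_invariant(self, cohort0, ranking0):
        k = len(ranking0.final_ranks)
        assert sum(ranking0.final_ranks.values()) == pytest.approx(
            k * (k + 1) / 2
        )

    def test_half_rank_sums_per_iteration(self):
        subs = generate_cohort(CohortSpec(seed=3))
        res = split_halves_rank(
            subs, SplitHalvesConfig(20, seed=3, keep_per_iteration=True)
        )
        k = len(res.final_ranks)
        sums = np.nansum(res.per_iteration_ranks, axis=1)
        assert np.allclose(sums, k * (k + 1) / 2)

    def test_reproducible_from_seed(self, cohort0):
        a = split_halves_rank(cohort0, SplitHalvesConfig(50, seed=9))
        b = split_halves_rank(cohort0, SplitHalvesConfig(50, seed=9))
        assert a.final_ranks == b.final_ranks

    def test_permutation_equivariance(self, cohort0):
        cfg = SplitHalvesConfig(100, seed=4)
        base = split_halves_rank(cohort0, cfg).final_ranks
        haps = sorted(base)
        relabel = {h: f"Z{len(haps) - i:02d}" for i, h in enumerate(haps)}
        renamed = [
            Subject(s.subject_id, relabel[s.opn1lw_haplotype],
                    calculated_ser=s.calculated_ser)
            for s in cohort0
        ]
        res = split_halves_rank(renamed, cfg).final_ranks
        for h in haps:
            assert res[relabel[h]] == pytest.approx(base[h], abs=1e-12)

    def test_seed_convergence_at_5000_iterations(self, cohort0):
        r1 = split_halves_rank(cohort0, SplitHalvesConfig(5000, seed=1))
        r2 = split_halves_rank(cohort0, SplitHalvesConfig(5000, seed=2))
        for h in r1.final_ranks:
            assert abs(r1.final_ranks[h] - r2.final_ranks[h]) < 0.1

    def test_recovers_published_rank_order(self, table1, cohort0, ranking0):
        t1 = dict(zip(table1["haplotype"], table1["split_halves_rank"]))
        haps = sorted(t1)
        rho = stats.spearmanr(
            [t1[h] for h in haps], [ranking0.final_ranks[h] for h in haps]
        ).statistic
        assert rho > 0.8

    def test_noise_free_cohort_reproduces_mean_order(self, table1):
        subs = generate_cohort(
            CohortSpec(
                seed=0,
                within_group_sd=0.0,
                cone_ratio_effect=0.0,
                opn1mw_mvvva_effect=0.0,
            )
        )
        res = split_halves_rank(subs, SplitHalvesConfig(20, seed=0))
        means = dict(zip(table1["haplotype"], table1["mean_ser_os"]))
        haps = sorted(means)
        expect = stats.rankdata([means[h] for h in haps])
        got = np.array([res.final_ranks[h] for h in haps])
        # most myopic (AACGGTGG) first, least myopic (GCCGGCAG) last
        assert res.final_ranks["AACGGTGG"] == min(res.final_ranks.values())
        assert res.final_ranks["GCCGGCAG"] == max(res.final_ranks.values())
        assert stats.spearmanr(expect, got).statistic > 0.99

    def test_scrambled_labels_flatten_ranks_in_expectation(self, cohort0):
        # under exchangeable labels each haplotype's expected final rank is
        # (k+1)/2; average over many scrambles approaches it
        rng = np.random.default_rng(123)
        labels = [s.opn1lw_haplotype for s in cohort0]
        sums = None
        n_scrambles = 60
        for i in range(n_scrambles):
            perm = rng.permutation(len(labels))
            scrambled = [
                Subject(s.subject_id, labels[perm[j]],
                        calculated_ser=s.calculated_ser)
                for j, s in enumerate(cohort0)
            ]
            res = split_halves_rank(scrambled, SplitHalvesConfig(30, seed=i))
            vec = np.array([res.final_ranks[h] for h in sorted(res.final_ranks)])
            sums = vec if sums is None else sums + vec
        mean_ranks = sums / n_scrambles
        assert np.all(np.abs(mean_ranks - 6.0) < 1.5)

    def test_single_group_rejected(self):
        subs = _subjects({"AACGGTGG": [-1.0, -2.0, -3.0, -4.0]})
        with pytest.raises(AnalysisError):
            split_halves_rank(subs, SplitHalvesConfig(5, seed=0))

    def test_non_stratified_mode_runs(self, cohort0):
        res = split_halves_rank(
            cohort0, SplitHalvesConfig(50, seed=0, stratified=False)
        )
        k = len(res.final_ranks)
        assert k == 11
        assert all(1 <= v <= k for v in res.final_ranks.values())


class TestRankMeanCorrelation:
    def test_published_table_columns(self, table1):
        means = dict(zip(table1["haplotype"], table1["mean_ser_os"]))
        ranks = dict(zip(table1["haplotype"], table1["split_halves_rank"]))
        res = rank_mean_correlation(means, ranks)
        assert res.r == pytest.approx(TABLE1_PRINTED_R, abs=1e-6)
        assert res.r_squared == pytest.approx(TABLE1_PRINTED_R**2, abs=1e-6)
        assert res.p_value < 0.001
        assert res.n == 11

    def test_exact_linear_relation(self):
        means = {f"h{i}": -3.0 + 0.5 * i for i in range(6)}
        ranks = {f"h{i}": 1.0 + i for i in range(6)}
        res = rank_mean_correlation(means, ranks)
        assert res.r == pytest.approx(1.0)

    def test_constant_means_degenerate(self):
        means = {f"h{i}": -1.0 for i in range(5)}
        ranks = {f"h{i}": 1.0 + i for i in range(5)}
        with pytest.raises(AnalysisError, match="zero variance"):
            rank_mean_correlation(means, ranks)

    def test_mismatched_haplotype_sets_rejected(self):
        with pytest.raises(ValidationError):
            rank_mean_correlation({"a": 1.0, "b": 2.0, "c": 3.0},
                                  {"a": 1.0, "b": 2.0, "d": 3.0})


class TestVarianceExplained:
    def test_exact_linear_cohort(self):
        ranks = {"AACGGTGG": 1.0, "GCGGGCAT": 2.0, "GCCGGCAG": 3.0}
        subs = []
        for h, r in ranks.items():
            for i in range(4):
                subs.append(Subject(f"{h}{i}", h, calculated_ser=-4.0 + r))
        res = variance_explained(subs, ranks)
        assert res.r_squared == pytest.approx(1.0)

    def test_default_cohort_band(self, cohort0, ranking0):
        res = variance_explained(cohort0, ranking0)
        assert 0.01 < res.r_squared < 0.15
        assert res.n == 413

    def test_opn1mw_indicator_never_lowers_r2(self, cohort0, ranking0):
        plain = variance_explained(cohort0, ranking0)
        aug = variance_explained(cohort0, ranking0, opn1mw_indicator=True)
        assert aug.r_squared >= plain.r_squared - 1e-12

    def test_missing_rank_rejected(self, cohort0, ranking0):
        ranks = dict(ranking0.final_ranks)
        ranks.pop("AACGGTGG")
        with pytest.raises(ValidationError, match="no final rank"):
            variance_explained(cohort0, ranks)


class TestScrambledNull:
    def test_null_is_mostly_non_significant(self, cohort0):
        r2s, ps = [], []
        for i in range(40):
            res = scrambled_null(cohort0, SplitHalvesConfig(100, seed=i))
            r2s.append(res.r_squared)
            ps.append(res.p_value)
        assert np.median(r2s) < 0.3
        assert np.mean(np.array(ps) > 0.05) > 0.7

    def test_exchangeable_cohort_unchanged_by_scrambling(self):
        # all groups drawn from one distribution: scrambling does not alter
        # the r^2 distribution (two-sample KS agreement)
        rng = np.random.default_rng(5)
        sizes = {"AACGGTGG": 20, "GCGGGCAT": 30, "GCCGGCAG": 25,
                 "GCGATCAT": 25, "AAGGGCAT": 20}
        subs = _subjects(
            {h: list(rng.normal(-1.0, 2.0, n)) for h, n in sizes.items()}
        )
        null_r2 = [
            scrambled_null(subs, SplitHalvesConfig(60, seed=i)).r_squared
            for i in range(30)
        ]
        # "scramble of a scramble": relabel first, then run the null again
        labels = [s.opn1lw_haplotype for s in subs]
        perm = rng.permutation(len(labels))
        re_subs = [
            Subject(s.subject_id, labels[perm[j]],
                    calculated_ser=s.calculated_ser)
            for j, s in enumerate(subs)
        ]
        null_r2_b = [
            scrambled_null(re_subs, SplitHalvesConfig(60, seed=i)).r_squared
            for i in range(30, 60)
        ]
        assert stats.ks_2samp(null_r2, null_r2_b).pvalue > 0.01

    def test_two_equal_groups_symmetric_ranks(self):
        rng = np.random.default_rng(8)
        subs = _subjects(
            {
                "AACGGTGG": list(rng.normal(-2, 1, 10)),
                "GCGGGCAT": list(rng.normal(-1, 1, 10)),
            }
        )
        rng2 = np.random.default_rng(99)
        labels = [s.opn1lw_haplotype for s in subs]
        totals = np.zeros(2)
        for i in range(80):
            perm = rng2.permutation(len(labels))
            scrambled = [
                Subject(s.subject_id, labels[perm[j]],
                        calculated_ser=s.calculated_ser)
                for j, s in enumerate(subs)
            ]
            res = split_halves_rank(scrambled, SplitHalvesConfig(10, seed=i))
            totals += [res.final_ranks[h] for h in sorted(res.final_ranks)]
        mean_ranks = totals / 80
        assert np.all(np.abs(mean_ranks - 1.5) < 0.25)
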