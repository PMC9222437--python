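"""Inclusion filters and cohort association tests."""

import numpy as np
import pytest
from scipy import stats

from opsinhap import (
    AnalysisError,
    Subject,
    ValidationError,
    allele_dichotomy,
    classify_cone_ratio,
    cone_ratio_split,
    filter_cohort,
    kruskal_wallis,
    mann_whitney,
    summarize_groups,
)


def _subject(i, hap, ser=-1.0, **kw):
    return Subject(f"s{i}", hap, calculated_ser=ser, **kw)


def _fixture_cohort(table1):
    """One subject per fixture count, SER = the group mean (noise-free)."""
    subs = []
    i = 0
    for _, row in table1.iterrows():
        for _ in range(int(row["n"])):
            subs.append(_subject(i, row["haplotype"], row["mean_ser_os"]))
            i += 1
    return subs


class TestFilter:
    def test_small_group_excluded(self):
        subs = [_subject(i, "AACGGTGG") for i in range(3)] + [
            _subject(i + 3, "GCGGGCAT") for i in range(4)
        ]
        kept = filter_cohort(subs)
        assert {s.opn1lw_haplotype for s in kept} == {"GCGGGCAT"}
        assert kept.exclusions["haplotype_group_size"] == 3

    def test_identity_when_all_pass(self):
        subs = [_subject(i, "AACGGTGG") for i in range(5)]
        kept = filter_cohort(subs)
        assert kept.subjects == subs

    def test_flag_filters(self):
        subs = [
            _subject(0, "AACGGTGG", ancestry_european=False),
            _subject(1, "AACGGTGG", color_vision_normal=False),
            _subject(2, "AACGGTGG", prior_surgery_or_injury=True),
            _subject(3, "AACGGTGG", single_opn1lw=False),
        ] + [_subject(i + 4, "AACGGTGG") for i in range(4)]
        kept = filter_cohort(subs)
        assert len(kept) == 4
        for crit in (
            "ancestry_european",
            "color_vision_normal",
            "prior_surgery_or_injury",
            "single_opn1lw",
        ):
            assert kept.exclusions[crit] == 1

    def test_fixture_cohort_fully_retained(self, table1):
        subs = _fixture_cohort(table1)
        kept = filter_cohort(subs)
        assert len(kept) == 413
        assert len({s.opn1lw_haplotype for s in kept}) == 11

    def test_idempotent(self, table1):
        subs = _fixture_cohort(table1)
        once = filter_cohort(subs).subjects
        twice = filter_cohort(once).subjects
        assert once == twice

    def test_empty_result_is_not_error(self):
        subs = [_subject(0, "AACGGTGG")]
        kept = filter_cohort(subs, min_group_size=4)
        assert len(kept) == 0


class TestSummarize:
    def test_noise_free_groups_match_configured(self, table1):
        groups = summarize_groups(_fixture_cohort(table1))
        expect = dict(zip(table1["haplotype"], table1["mean_ser_os"]))
        assert len(groups) == 11
        assert sum(g.n for g in groups) == 413
        for g in groups:
            assert g.mean_ser == pytest.approx(expect[g.haplotype])
            assert g.median_ser == pytest.approx(expect[g.haplotype])

    def test_singleton_group(self):
        groups = summarize_groups([_subject(0, "AACGGTGG", -2.5)])
        assert groups[0].median_ser == groups[0].mean_ser == -2.5

    def test_amino_column(self, table1):
        groups = summarize_groups(_fixture_cohort(table1))
        amino = dict(zip(table1["haplotype"], table1["amino_acids"]))
        for g in groups:
            assert g.amino == amino[g.haplotype]


class TestKruskalWallis:
    def test_all_tied_defined_as_null(self):
        res = kruskal_wallis([[1.0, 1.0], [1.0, 1.0, 1.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_complete_separation_closed_form(self):
        # two fully separated groups of 10: H = 12/(20*21)*2*10*25 = 14.2857
        res = kruskal_wallis([list(range(10)), list(range(100, 110))])
        assert res.statistic == pytest.approx(14.2857142857, abs=1e-6)
        assert res.p_value < 0.001

    def test_monotone_invariance(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(m, 1, 12) for m in (0.0, 0.5, 1.0)]
        res1 = kruskal_wallis(groups)
        res2 = kruskal_wallis([np.exp(g) for g in groups])
        assert res1.statistic == pytest.approx(res2.statistic)
        assert res1.p_value == pytest.approx(res2.p_value)

    def test_matches_scipy_on_untied_data(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(0, 1, 10) for _ in range(4)]
        res = kruskal_wallis(groups)
        h, p = stats.kruskal(*groups)
        assert res.statistic == pytest.approx(h)
        assert res.p_value == pytest.approx(p)

    def test_single_group_rejected(self):
        with pytest.raises(AnalysisError):
            kruskal_wallis([[1.0, 2.0]])


class TestAlleleDichotomy:
    def test_fixture_g_group_is_the_12_mvvva(self, table1):
        subs = _fixture_cohort(table1)
        res = allele_dichotomy(subs, "rs145009674", "G")
        assert res.group_sizes["G"] == 12
        assert res.group_sizes["not_G"] == 401
        assert res.group_means["G"] == pytest.approx(-3.14)

    def test_group_sizes_sum_to_cohort(self, cohort0):
        res = allele_dichotomy(cohort0, "rs145009674", "G")
        assert sum(res.group_sizes.values()) == len(cohort0)

    def test_shifted_group_mean_difference_recovered(self):
        rng = np.random.default_rng(7)
        subs = [
            _subject(i, "GCGGGCAT", rng.normal(-1.0, 2.0))
            for i in range(400)
        ] + [
            _subject(400 + i, "AACGGTGG", rng.normal(-1.0 - 1.36, 2.0))
            for i in range(12)
        ]
        res = allele_dichotomy(subs, "rs145009674", "G")
        # carrier group of 12 at SD 2: recovery within ~2 x 0.58 D
        assert res.effect == pytest.approx(1.36, abs=1.2)
        assert res.effect > 0

    def test_identical_groups_null(self):
        subs = [_subject(i, "GCGGGCAT", -1.0) for i in range(10)] + [
            _subject(10 + i, "AACGGTGG", -1.0) for i in range(10)
        ]
        res = allele_dichotomy(subs, "rs145009674", "G")
        assert res.effect == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        subs = [_subject(i, "GCGGGCAT") for i in range(5)]
        with pytest.raises(AnalysisError, match="empty"):
            allele_dichotomy(subs, "rs145009674", "G")


class TestMannWhitney:
    def test_exact_small_sample_against_scipy(self):
        x = [1.0, 2.0, 3.5, 7.0]
        y = [4.0, 5.0, 6.0, 8.0, 9.0]
        u, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestConeRatioSplit:
    @pytest.mark.parametrize(
        "pl,cls",
        [
            (67.0, "skewed"),
            (66.4, "balanced"),
            (66.6, "skewed"),  # rounds to 67
            (33.0, "skewed"),
            (33.5, "balanced"),  # rounds half-up to 34
            (50.0, "balanced"),
            (100.0, "skewed"),
            (0.0, "skewed"),
        ],
    )
    def test_classification(self, pl, cls):
        assert classify_cone_ratio(pl) == cls

    def test_all_balanced_is_degenerate(self):
        subs = [_subject(i, "GCGGGCAT", -1.0, percent_l=50.0) for i in range(6)]
        with pytest.raises(AnalysisError):
            cone_ratio_split(subs)

    def test_no_percent_l_rejected(self):
        subs = [_subject(i, "GCGGGCAT", -1.0) for i in range(6)]
        with pytest.raises(ValidationError):
            cone_ratio_split(subs)

    def test_protective_effect_recovered(self):
        rng = np.random.default_rng(11)
        subs = []
        for i in range(164):
            subs.append(
                _subject(i, "GCGGGCAT", rng.normal(-1.0, 2.0), percent_l=75.0)
            )
        for i in range(193):
            subs.append(
                _subject(
                    1000 + i,
                    "GCGGGCAT",
                    rng.normal(-1.61, 2.0),
                    percent_l=50.0,
                )
            )
        res = cone_ratio_split(subs)
        # balanced minus skewed: configured at -0.61, SE ~ 0.21
        assert res.effect == pytest.approx(-0.61, abs=0.45)
        assert res.group_sizes == {"skewed": 164, "balanced": 193}

    def test_welch_and_mannwhitney_agree_in_direction(self, cohort0):
        w = cone_ratio_split(cohort0, test="welch")
        m = cone_ratio_split(cohort0, test="mannwhitney")
        assert np.sign(w.effect) == np.sign(m.effect)
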