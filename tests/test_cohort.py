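import itertools
import math

import numpy as np
import pytest
from scipy.special import comb

import spliceotype as st
from spliceotype.cohort import CaseRecord


# ---------------------------------------------------------------------------
# Independent oracles

def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / comb(n, c1, exact=True)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


def km_oracle(times, events):
    """Hand-rolled product-limit estimator over distinct times."""
    order = sorted(zip(times, events))
    distinct = sorted({t for t, _ in order})
    s, out = 1.0, {}
    for t in distinct:
        at_risk = sum(1 for ti, _ in order if ti >= t)
        deaths = sum(1 for ti, ei in order if ti == t and ei)
        s *= 1 - deaths / at_risk
        out[t] = s
    return out


def logrank_oracle(ta, ea, tb, eb):
    """By-hand risk-table log-rank chi-square."""
    all_times = sorted({t for t, e in zip(list(ta) + list(tb), list(ea) + list(eb)) if e})
    o_minus_e = 0.0
    var = 0.0
    for t in all_times:
        n1 = sum(1 for x in ta if x >= t)
        n2 = sum(1 for x in tb if x >= t)
        d1 = sum(1 for x, e in zip(ta, ea) if x == t and e)
        d2 = sum(1 for x, e in zip(tb, eb) if x == t and e)
        n, d = n1 + n2, d1 + d2
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def case(case_id="c", variant="K700E", diagnosis="MDS-RS", **kw):
    kw.setdefault("panel_genes", frozenset())
    return CaseRecord(case_id=case_id, diagnosis=diagnosis, sf3b1_variant=variant, **kw)


# ---------------------------------------------------------------------------

class TestFormatPercent:
    @pytest.mark.parametrize(
        "num,den,value,text",
        [
            (28, 1327, 2.1, "2.1%"),
            (1, 1327, 0.08, "0.08%"),
            (103, 399, 25.8, "25.8%"),
            (1, 35, 2.9, "2.9%"),
            (0, 500, 0.0, "0.0%"),
            (1, 2000, 0.05, "0.05%"),
        ],
    )
    def test_rounding_rule(self, num, den, value, text):
        assert st.format_percent(num, den) == (value, text)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            st.format_percent(1, 0)


class TestFisherExact:
    def test_balanced_table(self):
        assert st.fisher_exact_two_sided([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)

    def test_zero_margin_degenerate(self):
        res = st.fisher_exact_two_sided([[0, 0], [3, 5]])
        assert res.p_value == 1.0 and res.degenerate

    def test_transposition_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a, b, c, d = rng.integers(0, 20, size=4)
            if (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            p1 = st.fisher_exact_two_sided([[a, b], [c, d]]).p_value
            p2 = st.fisher_exact_two_sided([[d, c], [b, a]]).p_value
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_matches_enumeration_oracle_small_margins(self):
        """All tables with margins <= 8 agree with enumeration to 1e-12."""
        for a, b, c, d in itertools.product(range(9), repeat=4):
            if max(a + b, c + d, a + c, b + d) > 8:
                continue
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            got = st.fisher_exact_two_sided([[a, b], [c, d]]).p_value
            assert got == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)

    def test_zero_cell_uses_conditional_mle(self):
        res = st.fisher_exact_two_sided([[0, 10], [5, 5]])
        assert math.isfinite(res.odds_ratio) and res.odds_ratio == 0
        assert res.odds_ratio_haldane == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))


class TestPartition:
    def _printed_cohort(self):
        """Cases reconstructing a small printed-count layout."""
        cases = []
        for dgn, variant_counts in {
            "MDS-RS": {"K666N": 28, "E592K": 1, "other": 1298},
            "AML": {"K666N": 103, "E592K": 10, "other": 286},
        }.items():
            for variant, n in variant_counts.items():
                for i in range(n):
                    cases.append(case(f"{dgn}-{variant}-{i}", variant, dgn))
        return cases

    def test_printed_percentages(self):
        part = st.partition_distribution(
            self._printed_cohort(), ["K666N", "E592K"], diagnoses=("MDS-RS", "AML")
        )
        assert part.percent.loc["K666N", "MDS-RS"] == 2.1
        assert part.percent_text.loc["E592K", "MDS-RS"] == "0.08%"
        assert part.percent.loc["K666N", "AML"] == 25.8
        assert part.percent.loc["E592K", "AML"] == 2.5

    def test_absent_variant_is_zero_percent(self):
        part = st.partition_distribution(
            self._printed_cohort(), ["K700E"], diagnoses=("MDS-RS",)
        )
        assert part.percent.loc["K700E", "MDS-RS"] == 0.0
        assert part.percent_text.loc["K700E", "MDS-RS"] == "0.0%"

    def test_pairwise_tests_present(self):
        part = st.partition_distribution(
            self._printed_cohort(), ["K666N", "E592K"], diagnoses=("MDS-RS", "AML")
        )
        t = next(x for x in part.tests if x.variant == "E592K")
        assert t.table == [[1, 1326], [10, 389]]
        assert t.p_value < 1e-4


class TestComutation:
    def _cohorts(self):
        panel = frozenset({"ASXL1", "DNMT3A", "RUNX1"})
        cases = []
        for i in range(35):
            muts = [("DNMT3A", 0.3)] if i == 0 else [("ASXL1", 0.4)]
            cases.append(
                case(f"e{i}", "E592K", comutations=muts, panel_genes=panel)
            )
        for i in range(100):
            muts = [("DNMT3A", 0.25)] if i < 21 else []
            cases.append(
                case(f"k{i}", "K700E", comutations=muts, panel_genes=panel)
            )
        # one case sequenced on a panel missing DNMT3A: excluded entirely
        cases.append(case("narrow", "K700E", panel_genes=frozenset({"ASXL1"})))
        return cases, panel

    def test_frequencies_and_exclusion(self):
        cases, panel = self._cohorts()
        land = st.comutation_landscape(
            cases, panel,
            lambda c: c.sf3b1_variant == "E592K",
            lambda c: c.sf3b1_variant == "K700E",
        )
        assert land.loc["DNMT3A", "n_a"] == 35
        assert land.loc["DNMT3A", "freq_a"] == 2.9  # 1/35
        assert land.loc["DNMT3A", "n_b"] == 100  # narrow-panel case excluded
        assert land.loc["DNMT3A", "freq_b"] == 21.0

    def test_unmutated_gene_p_one(self):
        cases, panel = self._cohorts()
        land = st.comutation_landscape(
            cases, panel,
            lambda c: c.sf3b1_variant == "E592K",
            lambda c: c.sf3b1_variant == "K700E",
        )
        assert land.loc["RUNX1", "p_value"] == 1.0
        assert land.loc["RUNX1", "freq_a"] == 0.0

    def test_empty_cohort_raises(self):
        cases, panel = self._cohorts()
        with pytest.raises(ValueError, match="panel"):
            st.comutation_landscape(
                cases, panel, lambda c: c.sf3b1_variant == "R625H",
                lambda c: True,
            )

    def test_denominators_never_exceed_cohort(self):
        cases, panel = self._cohorts()
        land = st.comutation_landscape(
            cases, panel, lambda c: c.sf3b1_variant == "E592K", lambda c: True
        )
        assert (land["n_a"] <= 35).all()
        assert (land["n_b"] <= len(cases)).all()

    def test_planted_enriched_gene_ranks_first(self):
        """A gene with 10x odds should usually attain the smallest q-value."""
        rng_genes = [f"G{i:02d}" for i in range(30)]
        panel = frozenset(rng_genes + ["HIT"])
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            cases = []
            for grp, p_hit in (("a", 0.4), ("b", 0.0625)):  # OR ~ 10
                for i in range(200):
                    muts = [(g, 0.3) for g in rng_genes if rng.random() < 0.10]
                    if rng.random() < p_hit:
                        muts.append(("HIT", 0.3))
                    cases.append(
                        case(f"{grp}{i}", "E592K" if grp == "a" else "K700E",
                             comutations=muts, panel_genes=panel)
                    )
            land = st.comutation_landscape(
                cases, panel,
                lambda c: c.sf3b1_variant == "E592K",
                lambda c: c.sf3b1_variant == "K700E",
            )
            wins += land["q_value"].idxmin() == "HIT"
        assert wins / n_seeds >= 0.9


class TestRsCriterion:
    def test_mutant_pathway_above_five(self):
        flags = st.apply_rs_criterion(case(rs_percent=8.0, blast_percent=2.0))
        assert flags.mutated_pathway is True

    def test_exactly_five_excluded(self):
        assert st.apply_rs_criterion(case(rs_percent=5.0)).mutated_pathway is False

    def test_wild_type_fourteen_percent_fails_both(self):
        flags = st.apply_rs_criterion(case(variant="WT", rs_percent=14.0))
        assert flags.mutated_pathway is False
        assert flags.unmutated_pathway is False

    def test_unknown_rs_gives_unknown_flags(self):
        flags = st.apply_rs_criterion(case(rs_percent=None))
        assert flags.mutated_pathway is None and flags.unmutated_pathway is None


class TestSummarizeRs:
    def test_single_case(self):
        s = st.summarize_rs([case(rs_percent=37.0)], lambda c: True)
        assert (s.mean, s.n) == (37.0, 1)

    def test_mean_of_known(self):
        cases = [case(f"c{i}", rs_percent=v) for i, v in enumerate((20.0, 40.0, 60.0))]
        cases.append(case("u", rs_percent=None))
        assert st.summarize_rs(cases, lambda c: True).mean == 40.0

    def test_no_known_rs_flagged(self):
        s = st.summarize_rs([case(rs_percent=None)], lambda c: True)
        assert not s.defined and s.mean is None

    def test_simulated_low_blast_mean_near_config(self):
        """Canonical-hotspot low-blast MDS draws RS around the 37% default."""
        cases = st.simulate_cohort(st.default_cohort_config(seed=3, n_cases=3000))
        s = st.summarize_rs(
            cases,
            lambda c: c.sf3b1_exon in (14, 15, 16)
            and c.blast_percent is not None
            and c.blast_percent < 5,
        )
        assert s.n >= 500
        assert s.mean == pytest.approx(37.0, abs=2.0)


class TestCompareClinical:
    def _cases(self, a_vals, b_vals, field="platelets"):
        cases = [
            case(f"a{i}", "E592K", **{field: v}) for i, v in enumerate(a_vals)
        ] + [
            case(f"b{i}", "K700E", **{field: v}) for i, v in enumerate(b_vals)
        ]
        return cases

    def test_identical_groups_p_one(self):
        cases = self._cases([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        cmp = st.compare_clinical(
            cases, lambda c: c.sf3b1_variant == "E592K",
            lambda c: c.sf3b1_variant == "K700E", "platelets",
        )
        assert cmp.p_value == pytest.approx(1.0)

    def test_all_tied_degenerate(self):
        cases = self._cases([5.0, 5.0], [5.0, 5.0])
        cmp = st.compare_clinical(
            cases, lambda c: c.sf3b1_variant == "E592K",
            lambda c: c.sf3b1_variant == "K700E", "platelets",
        )
        assert cmp.degenerate and cmp.p_value == 1.0

    def test_matches_exact_permutation_oracle(self):
        """Small untied samples: p equals full permutation enumeration."""
        a, b = [1.0, 2.0, 3.0], [101.0, 102.0, 103.0]
        cases = self._cases(a, b)
        cmp = st.compare_clinical(
            cases, lambda c: c.sf3b1_variant == "E592K",
            lambda c: c.sf3b1_variant == "K700E", "platelets",
        )
        pooled = a + b
        n_a = len(a)

        def u_stat(group_a, group_b):
            return sum(1 for x in group_a for y in group_b if x > y) + 0.5 * sum(
                1 for x in group_a for y in group_b if x == y
            )

        u_obs = u_stat(a, b)
        mean_u = n_a * len(b) / 2
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n_a):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
            total += 1
            if abs(u_stat(ga, gb) - mean_u) >= abs(u_obs - mean_u) - 1e-12:
                count += 1
        assert cmp.p_value == pytest.approx(count / total, abs=1e-12)

    def test_power_under_shift(self):
        """2-SD shift at n=50/50 is detected at alpha=0.05 >90% of the time."""
        rejections = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            cases = self._cases(
                list(rng.normal(0, 1, 50)), list(rng.normal(2, 1, 50))
            )
            cmp = st.compare_clinical(
                cases, lambda c: c.sf3b1_variant == "E592K",
                lambda c: c.sf3b1_variant == "K700E", "platelets",
            )
            rejections += cmp.p_value < 0.05
        assert rejections / n_sims > 0.9


class TestKaplanMeier:
    def test_uncensored_closed_form(self):
        curve = st.km_estimate([1, 2, 3, 4], [True] * 4)
        s = dict(zip(curve.times, curve.survival))
        assert s[2] == pytest.approx(0.5)
        assert curve.median == 2

    def test_all_censored_flat_curve(self):
        curve = st.km_estimate([1, 2, 3], [False] * 3)
        assert (curve.survival == 1.0).all()
        assert curve.median is None

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            st.km_estimate([], [])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(1, size=40)
        curve = st.km_estimate(t, [True] * 40)
        for time, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((t > time).mean(), abs=1e-12)

    def test_matches_product_limit_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(2, 11))
            t = np.round(rng.exponential(2, size=n), 1)
            e = rng.random(n) < 0.7
            curve = st.km_estimate(t, e)
            oracle = km_oracle(t, e)
            got = dict(zip(curve.times, curve.survival))
            for time, s in oracle.items():
                assert got[time] == pytest.approx(s, abs=1e-12)


class TestLogrank:
    def test_identical_groups(self):
        t, e = [1, 2, 3, 4], [True, True, False, True]
        res = st.logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_no_events_degenerate(self):
        res = st.logrank_test([1, 2], [False, False], [3], [False])
        assert res.degenerate

    def test_matches_risk_table_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(15):
            na, nb = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            ta = np.round(rng.exponential(2, na), 1) + 0.1
            tb = np.round(rng.exponential(3, nb), 1) + 0.1
            ea = rng.random(na) < 0.8
            eb = rng.random(nb) < 0.8
            if ea.sum() + eb.sum() == 0:
                continue
            res = st.logrank_test(ta, ea, tb, eb)
            assert res.statistic == pytest.approx(
                logrank_oracle(ta, ea, tb, eb), abs=1e-9
            )

    def test_type_one_error_calibrated(self):
        """Equal exponential arms: rejection rate near alpha = 0.05."""
        rejections = 0
        n_sims = 400
        rng = np.random.default_rng(2024)
        for _ in range(n_sims):
            ta = rng.exponential(1, 100)
            tb = rng.exponential(1, 100)
            res = st.logrank_test(ta, [True] * 100, tb, [True] * 100)
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / n_sims <= 0.07


class TestCohortIo:
    def test_round_trip(self, tmp_path):
        cases = st.simulate_cohort(st.default_cohort_config(seed=9, n_cases=25))
        p = tmp_path / "cohort.tsv"
        st.write_cohort_table(cases, p, header=" seed=9")
        assert st.read_cohort_table(p) == cases

    def test_oncoprint_matrix_shape(self):
        cases, panel = TestComutation()._cohorts()
        m = st.oncoprint_matrix(cases, sorted(panel))
        assert m.shape == (3, len(cases))
        assert m.loc["DNMT3A", "e0"] == 1.0
        assert math.isnan(m.loc["DNMT3A", "narrow"])
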