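
import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import comb

from corelearn import (ConsensusResult, GeneSetAnnotation, adjust_fdr,
                       compare_rates_ztest, drug_degree_ranksum,
                       druggable_excluding_targets, enrichment_by_cs_bin,
                       fisher_enrichment, tukey_groups)


def annotation(members, n):
    return GeneSetAnnotation(set(members), set(range(n)))


def hypergeom_two_sided_p(a, b, c, d):
    """Exact conditional two-sided p by full enumeration of tables."""
    n1, n2 = a + b, c + d
    m1 = a + c
    N = n1 + n2
    denom = comb(N, m1)
    p_obs = comb(n1, a) * comb(n2, m1 - a) / denom
    total = 0.0
    for x in range(max(0, m1 - n2), min(n1, m1) + 1):
        px = comb(n1, x) * comb(n2, m1 - x) / denom
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestFisher:
    def test_closed_form_odds_ratio(self):
        # a=10, b=90, c=10, d=890 -> OR = (10*890)/(90*10) = 9.888...
        n = 1000
        members = set(range(10)) | set(range(100, 110))
        test = set(range(100))
        res = fisher_enrichment(test, annotation(members, n), set())
        assert (res.a, res.b, res.c, res.d) == (10, 90, 10, 890)
        assert res.odds_ratio == pytest.approx(9.888888, abs=1e-5)

    def test_symmetric_null_table(self):
        n = 40
        members = set(range(10)) | set(range(20, 30))
        test = set(range(20))
        res = fisher_enrichment(test, annotation(members, n), set())
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_cell_haldane_corrected(self):
        n = 30
        members = set(range(10, 15))
        test = set(range(10))
        res = fisher_enrichment(test, annotation(members, n), set())
        assert res.a == 0 and res.haldane and np.isfinite(res.odds_ratio)

    def test_exclusions_removed_before_table(self):
        n = 20
        members = set(range(10))
        res = fisher_enrichment(set(range(5)), annotation(members, n),
                                exclusions={0, 1})
        assert res.a + res.b == 3

    def test_empty_after_exclusion_errors(self):
        with pytest.raises(ValueError):
            fisher_enrichment({0}, annotation({1}, 5), exclusions={0})

    def test_p_matches_enumeration_oracle_small_margins(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a, b, c, d = rng.integers(0, 15, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            n = a + b + c + d
            test = set(range(a + b))
            members = set(range(a)) | set(range(a + b, a + b + c))
            res = fisher_enrichment(test, annotation(members, n), set())
            want = hypergeom_two_sided_p(a, b, c, d)
            assert res.p_value == pytest.approx(want, abs=1e-9)


class TestEnrichmentByBin:
    def make_consensus(self, cs, positives):
        n = len(cs)
        cs = np.asarray(cs, dtype=float)
        flags = []
        for g in range(n):
            if g in positives:
                flags.append("positive-label")
            elif cs[g] > 0:
                flags.append("candidate")
            else:
                flags.append("non-candidate")
        cs[sorted(positives)] = np.nan
        return ConsensusResult(cs=cs, flags=flags, candidate_sets=[],
                               m=int(np.nanmax(cs)) if np.nanmax(cs) > 0 else 1)

    def test_bin_one_is_candidate_vs_noncandidate_split(self):
        cs = [0] * 50 + [1] * 10 + [2] * 5
        cons = self.make_consensus(cs, positives=set())
        members = set(range(50, 65)) | set(range(10))
        res = enrichment_by_cs_bin(cons, annotation(members, 65), set())
        r1 = res[0]
        assert r1.bin_label.startswith("CS>=1")
        assert r1.a + r1.b == 15  # all candidates
        assert r1.a == 15 and r1.c == 10

    def test_annotation_matching_top_bin_is_maximal(self):
        cs = [0] * 30 + [11] * 5
        cons = self.make_consensus(cs, positives=set())
        members = set(range(30, 35))
        res = enrichment_by_cs_bin(cons, annotation(members, 35), set())
        top = res[-1]
        assert top.haldane and top.odds_ratio > 100

    def test_null_annotation_rarely_significant(self):
        # annotation independent of CS: across 100 seeded draws, at most ~10%
        # of bins reach FDR < 0.05
        n = 400
        sig = total = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cs = rng.integers(0, 6, size=n)
            cons = self.make_consensus(list(cs), positives=set())
            members = set(np.flatnonzero(rng.random(n) < 0.2).tolist())
            res = enrichment_by_cs_bin(cons, annotation(members, n), set())
            total += len(res)
            sig += sum(r.fdr < 0.05 for r in res)
        assert sig / total <= 0.10


class TestTukey:
    def test_identical_groups_nothing_significant(self):
        v = np.array([1.0, 1.1, 0.9, 1.0])
        comp = tukey_groups({"a": v, "b": v, "c": v})
        assert all(c["p_adj"] > 0.9 for c in comp.comparisons)
        assert all(abs(c["diff"]) < 1e-12 for c in comp.comparisons)

    def test_separated_groups_match_studentized_range_oracle(self):
        rng = np.random.default_rng(1)
        groups = {"g0": 0 + 0.1 * rng.standard_normal(3),
                  "g5": 5 + 0.1 * rng.standard_normal(3),
                  "g10": 10 + 0.1 * rng.standard_normal(3)}
        comp = tukey_groups(groups)
        diffs = sorted(abs(c["diff"]) for c in comp.comparisons)
        assert np.allclose(diffs, [5, 5, 10], atol=0.5)
        assert all(c["p_adj"] < 1e-6 for c in comp.comparisons)
        # closed-form studentized-range oracle for one pair
        data = list(groups.values())
        k, N = 3, 9
        mse = sum(((v - v.mean()) ** 2).sum() for v in data) / (N - k)
        c01 = next(c for c in comp.comparisons
                   if {c["group1"], c["group2"]} == {"g0", "g5"})
        se = np.sqrt(mse / 2 * (1 / 3 + 1 / 3))
        q_obs = abs(c01["diff"]) / se
        p_want = sps.studentized_range.sf(q_obs, k, N - k)
        assert c01["p_adj"] == pytest.approx(p_want, rel=1e-3, abs=1e-12)

    def test_two_groups_reduce_to_t_with_q_scaling(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(8)
        b = rng.standard_normal(8) + 1.0
        comp = tukey_groups({"a": a, "b": b})
        t_stat, _ = sps.ttest_ind(b, a)
        q_obs = abs(t_stat) * np.sqrt(2)
        p_want = sps.studentized_range.sf(q_obs, 2, 14)
        assert comp.comparisons[0]["p_adj"] == pytest.approx(p_want, rel=1e-3)

    def test_insufficient_groups_rejected(self):
        with pytest.raises(ValueError):
            tukey_groups({"a": np.array([1.0, 2.0])})


class TestDrugDegree:
    def test_identical_distributions_null(self):
        v = np.arange(1, 21, dtype=float)
        res = drug_degree_ranksum({"cand": v, "noncand": v.copy()})
        assert res[0]["xdc"] == pytest.approx(1.0)
        assert res[0]["p_value"] > 0.9

    def test_doubled_counts_give_xdc_two(self):
        v = np.arange(1, 21, dtype=float)
        res = drug_degree_ranksum({"cand": 2 * v, "noncand": v})
        assert res[0]["xdc"] == pytest.approx(2.0)

    def test_empty_group_skipped(self):
        v = np.arange(1, 11, dtype=float)
        res = drug_degree_ranksum({"cand": v, "empty": np.array([]),
                                   "noncand": v})
        assert all("empty" not in (r["group1"], r["group2"]) for r in res)
        assert len(res) == 1


class TestDruggableExcludingTargets:
    def test_targets_removed_before_test(self):
        druggable = {0, 1, 2, 10, 11}
        targets = {0, 10}
        res = druggable_excluding_targets(druggable, targets,
                                          test_set={0, 1, 2, 3},
                                          background=set(range(20)))
        assert res.a + res.b == 3  # gene 0 removed as target

    def test_test_subset_of_targets_errors(self):
        with pytest.raises(ValueError):
            druggable_excluding_targets({0}, {1, 2}, {1, 2}, set(range(10)))

    def test_independent_druggability_or_near_one(self):
        rng = np.random.default_rng(3)
        n = 2000
        druggable = set(np.flatnonzero(rng.random(n) < 0.3).tolist())
        test = set(np.flatnonzero(rng.random(n) < 0.1).tolist())
        res = druggable_excluding_targets(druggable, set(), test, set(range(n)))
        assert 0.6 < res.odds_ratio < 1.6


class TestZTest:
    def test_equal_proportions(self):
        z, p = compare_rates_ztest(10, 100, 10, 100)
        assert z == 0.0 and p == 1.0

    def test_closed_form(self):
        # 50/100 vs 10/100, pooled p = 0.3 -> z = 0.4 / sqrt(0.21 * 0.02)
        z, p = compare_rates_ztest(50, 100, 10, 100)
        want = 0.4 / np.sqrt(0.3 * 0.7 * (1 / 100 + 1 / 100))
        assert z == pytest.approx(want, rel=1e-9)
        assert z == pytest.approx(6.17, abs=0.01)

    def test_zero_trials_error(self):
        with pytest.raises(ValueError):
            compare_rates_ztest(1, 10, 0, 0)


class TestFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_fdr([0.03]), [0.03])

    def test_textbook_example(self):
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        p = rng.random(20)
        perm = rng.permutation(20)
        adj = adjust_fdr(p)
        adj_perm = adjust_fdr(p[perm])
        np.testing.assert_allclose(adj_perm, adj[perm])

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])
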