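"""Welch/ANOVA/Tukey machinery, relevance filtering, and family enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from satrep.annotations import GenomicInterval, RepeatInstance
from satrep.differential import (
    anova_oneway,
    bonferroni,
    differential_stagewise,
    differential_two_group,
    family_overrepresentation,
    relevance_filter,
    tukey_hsd,
    welch_test,
)
from satrep.signal import EnrichmentMatrix


def textbook_welch(a, b):
    """Independent Welch computation from the defining formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_identical_vectors(self):
        t, df, p = welch_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_matches_textbook_formula(self):
        a, b = (1, 2, 3, 4), (2, 3, 4, 5)
        t, df, p = welch_test(a, b)
        te, dfe, pe = textbook_welch(a, b)
        assert t == pytest.approx(te, abs=1e-10)
        assert df == pytest.approx(dfe, abs=1e-10)
        assert p == pytest.approx(pe, abs=1e-10)

    def test_degenerate_constant_groups(self):
        assert welch_test([2, 2], [2, 2])[2] == 1.0
        assert welch_test([2, 2], [3, 3])[2] == 0.0

    def test_requires_two_per_group(self):
        with pytest.raises(ValueError):
            welch_test([1], [1, 2])


class TestAnova:
    def test_matches_manual_ss_decomposition(self):
        # 3 groups x 4 observations
        vals = np.array([3.1, 2.9, 3.4, 3.0, 4.2, 4.0, 4.5, 4.1, 2.0, 2.2, 1.9, 2.3])
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        F, dfb, dfw, p = anova_oneway(vals, labels)
        grand = vals.mean()
        groups = [vals[:4], vals[4:8], vals[8:]]
        ssb = sum(4 * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        F_ref = (ssb / 2) / (ssw / 9)
        assert (dfb, dfw) == (2, 9)
        assert F == pytest.approx(F_ref, abs=1e-10)
        assert p == pytest.approx(stats.f.sf(F_ref, 2, 9), abs=1e-12)

    def test_all_identical_degenerate(self):
        F, _, _, p = anova_oneway([2.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert F == 0.0 and p == 1.0

    def test_agrees_with_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=15)
        labels = np.repeat(["x", "y", "z"], 5)
        F, _, _, p = anova_oneway(vals, labels)
        ref = stats.f_oneway(vals[:5], vals[5:10], vals[10:])
        assert F == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestBonferroni:
    def test_examples_and_cap(self):
        out = bonferroni([0.001] + [1.0] * 9)
        assert out[0] == pytest.approx(0.01)
        assert bonferroni([0.5] * 10)[0] == 1.0

    def test_never_decreases_and_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        adj = bonferroni(p)
        assert np.all(adj >= p)
        # order-preserving up to ties introduced by the cap at 1
        assert np.all(np.diff(adj[np.argsort(p, kind="stable")]) >= 0)


class TestTukey:
    def test_two_identical_groups(self):
        out = tukey_hsd([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
        assert out[0][2] == 1.0

    def test_against_scipy_tukey_oracle(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(loc=m, size=n) for m, n in ((0, 5), (0.8, 7), (0.3, 4))]
        vals = np.concatenate(groups)
        labels = np.repeat(["g0", "g1", "g2"], [5, 7, 4])
        ours = {frozenset((a, b)): p for a, b, p in tukey_hsd(vals, labels)}
        ref = stats.tukey_hsd(*groups)
        for i in range(3):
            for j in range(i + 1, 3):
                key = frozenset((f"g{i}", f"g{j}"))
                assert ours[key] == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    def test_significant_pairs_have_differing_means(self):
        rng = np.random.default_rng(3)
        vals = np.r_[rng.normal(0, 0.1, 6), rng.normal(3, 0.1, 6)]
        labels = np.repeat(["lo", "hi"], 6)
        for a, b, p in tukey_hsd(vals, labels):
            if p < 0.05:
                assert abs(vals[labels == a].mean() - vals[labels == b].mean()) > 0


class TestRelevanceFilter:
    def test_near_zero_means_not_relevant(self):
        # raw ratio 0.1/0.01 is tenfold; shifted ratio 1.1/1.01 fails the cutoff
        [(a, b, ratio, relevant)] = relevance_filter({"s1": 0.1, "s2": 0.01})
        assert ratio == pytest.approx(1.1 / 1.01)
        assert ratio < 1.5 and not relevant

    def test_boundary_is_inclusive(self):
        [(_, _, ratio, relevant)] = relevance_filter({"s1": 2.0, "s2": 1.0})
        assert ratio == pytest.approx(1.5) and relevant

    def test_equal_means(self):
        [(_, _, ratio, relevant)] = relevance_filter({"s1": 0.7, "s2": 0.7})
        assert ratio == 1.0 and not relevant

    def test_symmetric_under_stage_swap(self):
        r1 = relevance_filter({"a": 0.3, "b": 1.9})[0]
        r2 = relevance_filter({"b": 1.9, "a": 0.3})[0]
        assert r1[2] == pytest.approx(r2[2]) and r1[3] == r2[3]


def matrix_from_array(X, groups, stages=None):
    cols = [f"s{i}" for i in range(X.shape[1])]
    meta = pd.DataFrame({
        "group": groups,
        "stage": stages if stages is not None else [""] * len(cols),
        "assay": "ChIP", "mark": "H3K9me3", "tissue": "", "sex": "",
    }, index=cols)
    return EnrichmentMatrix(pd.DataFrame(X, columns=cols,
                                         index=[f"e{i}" for i in range(X.shape[0])]),
                            meta)


class TestTwoGroup:
    def test_planted_effect_detected(self):
        rng = np.random.default_rng(4)
        X = np.maximum(0, rng.normal(0.6, 0.3, size=(50, 21)))
        X[7, :8] = np.maximum(0, rng.normal(1.6, 0.3, 8))  # planted row, group A
        m = matrix_from_array(X, ["A"] * 8 + ["B"] * 13)
        recs = differential_two_group(m, "group")
        assert recs[7].significant
        assert recs[7].group_means["A"] > recs[7].group_means["B"]

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(5)
        X = np.abs(rng.normal(1.0, 0.3, size=(200, 12)))
        m = matrix_from_array(X, ["A"] * 6 + ["B"] * 6)
        recs = differential_two_group(m, "group")
        n_sig = sum(r.significant for r in recs)
        # binomial 99.9% band around alpha=0.05, n=200
        assert n_sig <= 25

    def test_single_row_identical_groups(self):
        X = np.array([[1.0, 1.0, 1.0, 1.0]])
        m = matrix_from_array(X, ["A", "A", "B", "B"])
        recs = differential_two_group(m, "group")
        assert not recs[0].significant and recs[0].p == 1.0

    def test_all_zero_row_flagged(self):
        X = np.zeros((1, 4))
        m = matrix_from_array(X, ["A", "A", "B", "B"])
        recs = differential_two_group(m, "group")
        assert "all_zero" in recs[0].flags

    def test_p_adj_never_below_p(self):
        rng = np.random.default_rng(6)
        X = np.abs(rng.normal(0.5, 0.2, size=(30, 10)))
        m = matrix_from_array(X, ["A"] * 5 + ["B"] * 5)
        for r in differential_two_group(m, "group"):
            assert r.p_adj >= r.p


class TestStagewise:
    def make_matrix(self, seed=7, n_elements=120, n_true=12):
        rng = np.random.default_rng(seed)
        stages = np.repeat([f"S{k}" for k in range(4)], 6)
        X = np.maximum(0, rng.normal(0.6, 0.3, size=(n_elements, len(stages))))
        means = {"S0": 2.0, "S1": 0.5, "S2": 1.0, "S3": 0.5}
        for i in range(n_true):
            for j, s in enumerate(stages):
                X[i, j] = max(0, rng.normal(means[s], 0.3))
        m = matrix_from_array(X, stages, stages)
        return m, n_true

    def test_planted_elements_recovered(self):
        m, n_true = self.make_matrix()
        recs = differential_stagewise(m, "stage")
        hits = [r.element_id for r in recs if r.significant]
        true_ids = {f"e{i}" for i in range(n_true)}
        assert len(true_ids & set(hits)) >= n_true - 1
        assert len(set(hits) - true_ids) <= 3

    def test_monotone_filtering_chain(self):
        m, _ = self.make_matrix(seed=8)
        recs = differential_stagewise(m, "stage")
        sig = {r.element_id for r in recs if r.significant}
        adj = {r.element_id for r in recs if r.significant_adj}
        assert sig <= adj <= {r.element_id for r in recs}

    def test_anova_significant_but_irrelevant_excluded(self):
        # tiny but consistent differences: highly significant, ratios < 1.5
        rng = np.random.default_rng(9)
        stages = np.repeat(["a", "b", "c"], 30)
        means = {"a": 0.10, "b": 0.01, "c": 0.05}
        X = np.array([[max(0, rng.normal(means[s], 0.01)) for s in stages]])
        m = matrix_from_array(X, stages, stages)
        recs = differential_stagewise(m, "stage")
        assert recs[0].significant_adj  # ANOVA fires
        assert not recs[0].significant  # relevance filter removes it
        assert all(ratio < 1.5 for _, _, _, ratio, _ in recs[0].pairwise)

    def test_null_matrix_yields_no_hits(self):
        rng = np.random.default_rng(10)
        stages = np.repeat([f"S{k}" for k in range(4)], 5)
        X = np.abs(rng.normal(0.8, 0.3, size=(150, len(stages))))
        m = matrix_from_array(X, stages, stages)
        recs = differential_stagewise(m, "stage")
        assert sum(r.significant for r in recs) == 0


def make_family_instances(family_counts):
    out = []
    pos = 0
    for fam, n in family_counts.items():
        for k in range(n):
            iv = GenomicInterval("chr1", pos, pos + 10)
            out.append(RepeatInstance(iv, fam, "Satellite", f"{fam}_{k}"))
            pos += 20
    return out


class TestFamilyOverrepresentation:
    def test_exact_combinatorial_oracle(self):
        instances = make_family_instances({"MMSAT4": 10, "other": 90})
        diff = [f"MMSAT4_{k}" for k in range(10)]
        (fam_rec,) = [f for f in family_overrepresentation(instances, diff)
                      if f.family == "MMSAT4"]
        assert fam_rec.fold == pytest.approx(10.0)
        # exact tail: P(X >= 10) with N=100, K=10, n=10
        p_exact = math.comb(10, 10) * math.comb(90, 0) / math.comb(100, 10)
        assert fam_rec.p == pytest.approx(p_exact, rel=1e-10)

    def test_fold_one_at_expectation(self):
        instances = make_family_instances({"A": 20, "B": 80})
        diff = [f"A_{k}" for k in range(2)] + [f"B_{k}" for k in range(8)]
        (rec,) = [f for f in family_overrepresentation(instances, diff)
                  if f.family == "A"]
        assert rec.fold == pytest.approx(1.0)

    def test_absent_family(self):
        instances = make_family_instances({"A": 10, "B": 90})
        diff = [f"B_{k}" for k in range(5)]
        (rec,) = [f for f in family_overrepresentation(instances, diff)
                  if f.family == "A"]
        assert rec.fold == 0.0 and rec.p == 1.0

    def test_empty_differential_set(self):
        instances = make_family_instances({"A": 5})
        assert family_overrepresentation(instances, []) == []

    def test_k_bounded(self):
        instances = make_family_instances({"A": 3, "B": 7})
        diff = [f"A_{k}" for k in range(3)]
        for rec in family_overrepresentation(instances, diff):
            assert rec.k <= min(rec.K, rec.n)
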