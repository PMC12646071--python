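"""Unit tests for the triallelic-singleton recurrence estimator."""

import numpy as np
import pandas as pd
import pytest

import doubrcr.mutation_spectrum as ms
from doubrcr.datasets import ag1000g_3l_counts

BASES = "ACGT"


def small_counts(seed=0, low=5, high=60, trials=20_000):
    """A random small-integer count ledger with trial counts attached."""
    rng = np.random.default_rng(seed)
    counts = ms.MutationClassCounts()
    for x in BASES:
        for pair in ms.TRIALLELIC_PAIRS[x]:
            counts.triallelic[(x, pair)] = int(rng.integers(low, high))
        counts.sites_with_major[x] = trials
    for x, y in ms.MUTATION_CLASSES:
        counts.doubletons[(x, y)] = int(rng.integers(200, 800))
    return counts


class TestEstimateRecurrentCount:
    def test_published_worked_example(self):
        """The Ag1000G 3L counts reproduce the published per-class estimates."""
        c = ag1000g_3l_counts()
        assert ms.round_half_up(ms.estimate_recurrent_count(c, "A", "C")) == 2002
        assert ms.round_half_up(ms.estimate_recurrent_count(c, "C", "T")) == 53851

    def test_equal_counts_give_half(self):
        counts = ms.MutationClassCounts()
        for x in BASES:
            for pair in ms.TRIALLELIC_PAIRS[x]:
                counts.triallelic[(x, pair)] = 14
        for x, y in ms.MUTATION_CLASSES:
            assert ms.estimate_recurrent_count(counts, x, y) == pytest.approx(7.0)

    def test_matches_independent_recomputation(self):
        """N1·N2/(2·N3) recomputed literally, other-bases derived by hand."""
        c = small_counts(seed=3)
        for x, y in ms.MUTATION_CLASSES:
            others = [b for b in BASES if b not in (x, y)]
            n1 = c.triallelic[(x, tuple(sorted((y, others[0]))))]
            n2 = c.triallelic[(x, tuple(sorted((y, others[1]))))]
            n3 = c.triallelic[(x, tuple(sorted(others)))]
            assert ms.estimate_recurrent_count(c, x, y) == pytest.approx(n1 * n2 / (2 * n3))

    def test_pair_order_irrelevant(self):
        c = ms.MutationClassCounts(triallelic={("A", ("C", "G")): 9})
        assert c.triallelic_count("A", ("G", "C")) == 9

    def test_zero_denominator_is_an_error(self):
        c = ms.MutationClassCounts(
            triallelic={("A", ("C", "G")): 5, ("A", ("C", "T")): 5, ("A", ("G", "T")): 0}
        )
        with pytest.raises(ms.UndefinedEstimateError, match="A->C"):
            ms.estimate_recurrent_count(c, "A", "C")


class TestPriorRCR:
    def test_published_overall_proportion(self):
        est = ms.estimate_prior_rcr(ag1000g_3l_counts())
        assert ms.round_half_up(est.total_nest) == 183839
        assert est.total_d == 1_116_970
        assert round(est.proportion_recurrent, 3) == 0.165
        assert round(est.prior_rcr, 2) == 0.84

    def test_published_per_class_proportions(self):
        printed = {
            ("A", "C"): 0.050, ("A", "G"): 0.102, ("A", "T"): 0.132,
            ("C", "A"): 0.143, ("C", "G"): 0.085, ("C", "T"): 0.246,
            ("G", "A"): 0.248, ("G", "C"): 0.083, ("G", "T"): 0.139,
            ("T", "A"): 0.131, ("T", "C"): 0.101, ("T", "G"): 0.049,
        }
        est = ms.estimate_prior_rcr(ag1000g_3l_counts())
        by_class = est.per_class.set_index(["ancestral", "derived"])["proportion_recurrent"]
        for cls, want in printed.items():
            assert round(float(by_class.loc[cls]), 3) == want

    def test_zero_nest_means_prior_one(self):
        # zero numerators with positive denominators: Nest = 0 everywhere
        c2 = ms.MutationClassCounts(doubletons=dict(small_counts(seed=1).doubletons))
        for x in BASES:
            p1, p2, p3 = ms.TRIALLELIC_PAIRS[x]
            c2.triallelic[(x, p1)] = 0
            c2.triallelic[(x, p2)] = 0
            c2.triallelic[(x, p3)] = 10
        est = ms.estimate_prior_rcr(c2)
        defined = est.per_class["nest"].dropna()
        assert (defined == 0).all()
        assert est.prior_rcr == pytest.approx(1.0)

    def test_overall_is_ratio_of_sums(self):
        est = ms.estimate_prior_rcr(small_counts(seed=5))
        pc = est.per_class.dropna(subset=["nest"])
        assert est.proportion_recurrent == pytest.approx(
            pc["nest"].sum() / pc["doubletons"].sum()
        )


class TestBootstrap:
    def test_single_replicate_collapses(self):
        c = small_counts(seed=7)
        per_cls, overall = ms.bootstrap_ci(c, reps=1, seed=11)
        for lo, hi in per_cls.values():
            assert lo == hi
        assert overall[0] == overall[1]

    def test_all_zero_probabilities_give_zero_interval(self):
        c = small_counts(seed=9)
        for k in c.triallelic:
            c.triallelic[k] = 0
        per_cls, overall = ms.bootstrap_ci(c, reps=50, seed=1)
        assert overall == (0.0, 0.0)
        assert all(iv == (0.0, 0.0) for iv in per_cls.values())

    def test_deterministic_given_seed(self):
        c = small_counts(seed=2)
        assert ms.bootstrap_ci(c, reps=200, seed=5) == ms.bootstrap_ci(c, reps=200, seed=5)

    def test_missing_trial_counts_rejected(self):
        c = small_counts(seed=2)
        c.sites_with_major["G"] = 0
        with pytest.raises(ValueError, match="base composition"):
            ms.bootstrap_ci(c, reps=10, seed=1)

    def test_nominal_coverage_of_generating_value(self):
        """95% intervals cover the generating proportion ≈95% of the time.

        Counts are drawn from a known multinomial per base; the generating
        value is the estimator applied to the exact expected counts.
        """
        rng = np.random.default_rng(1234)
        trials = 20_000
        p_pair = 0.02  # expected 400 counts per cell: the estimator's
        # intended operating regime (published cells are in the thousands)
        template = small_counts(seed=0, trials=trials)
        true_counts = ms.MutationClassCounts(
            doubletons=dict(template.doubletons),
            sites_with_major=dict(template.sites_with_major),
        )
        for x in BASES:
            for pair in ms.TRIALLELIC_PAIRS[x]:
                true_counts.triallelic[(x, pair)] = trials * p_pair
        true_value = ms.estimate_prior_rcr(true_counts).proportion_recurrent

        n_exp, covered = 1000, 0
        probs = np.array([p_pair, p_pair, p_pair, 1 - 3 * p_pair])
        for _ in range(n_exp):
            obs = ms.MutationClassCounts(
                doubletons=dict(template.doubletons),
                sites_with_major=dict(template.sites_with_major),
            )
            for x in BASES:
                draw = rng.multinomial(trials, probs)
                for k, pair in enumerate(ms.TRIALLELIC_PAIRS[x]):
                    obs.triallelic[(x, pair)] = int(draw[k])
            _, (lo, hi) = ms.bootstrap_ci(obs, reps=1500, seed=int(rng.integers(1, 2**31)))
            covered += lo <= true_value <= hi
        assert abs(covered / n_exp - 0.95) <= 0.03


class TestSpectrumExpectations:
    def test_uniform_spectrum_stays_uniform(self):
        s = {cls: 100 for cls in ms.MUTATION_CLASSES}
        out = ms.spectrum_expectations(s)
        assert np.allclose(out["single_origin_expectation"], 1 / 12)
        assert np.allclose(out["recurrent_expectation"], 1 / 12)

    def test_published_fold_change(self):
        """A 3.75-fold singleton ratio implies a 3.75² = 14.06-fold
        recurrent-doubleton ratio."""
        s = {cls: 1 for cls in ms.MUTATION_CLASSES}
        s[("C", "T")] = 375
        s[("A", "C")] = 100
        out = ms.spectrum_expectations(s).set_index(["ancestral", "derived"])
        ratio = (
            out.loc[("C", "T"), "recurrent_expectation"]
            / out.loc[("A", "C"), "recurrent_expectation"]
        )
        assert ratio == pytest.approx(3.75**2)

    def test_recurrent_is_elementwise_square(self):
        rng = np.random.default_rng(0)
        s = {cls: int(rng.integers(1, 500)) for cls in ms.MUTATION_CLASSES}
        out = ms.spectrum_expectations(s)
        p = out["single_origin_expectation"].to_numpy()
        assert np.allclose(out["recurrent_expectation"], p**2 / (p**2).sum())


class TestGTest:
    def test_identical_proportions_give_zero(self):
        g, df, p = ms.spectrum_gtest([10, 20, 30], [10, 20, 30])
        assert g == pytest.approx(0.0, abs=1e-10)
        assert df == 2

    def test_proportional_rows_give_zero(self):
        g, _, _ = ms.spectrum_gtest([10, 20, 30], [20, 40, 60])
        assert g == pytest.approx(0.0, abs=1e-10)

    def test_matches_direct_formula(self):
        obs = np.array([[10.0, 20.0], [20.0, 10.0]])
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        exp = row * col / obs.sum()
        g_hand = 2 * np.sum(obs * np.log(obs / exp))
        g, df, _ = ms.spectrum_gtest(obs[0], obs[1])
        assert df == 1
        assert g == pytest.approx(g_hand)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError):
            ms.spectrum_gtest([0, 5], [0, 7])
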