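"""Unit tests for the RCR Bayes machinery: closed-form priors, Bayes
factors, posterior curves, threshold selection and calling."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import doubrcr as d
import doubrcr.rcr_bayes as rb
from doubrcr.genotypes import GenotypeTable


def rcr_probability_by_coalescent_recursion(m: int) -> Fraction:
    """Independent oracle: exact summation over the number of coalescence
    events preceding the focal pair's merge.

    P2[k] = 2/(k(k-1)) is the chance the next event merges the focal pair;
    P0[k] = (k-2)(k-3)/(k(k-1)) the chance it involves neither sequence.
    """
    total = Fraction(0)
    for t in range(0, m - 2):
        prod = Fraction(1)
        for i in range(t):
            k = m - i
            prod *= Fraction((k - 2) * (k - 3), k * (k - 1))
        k = m - t
        total += prod * Fraction(2, k * (k - 1))
    return total


class TestRandomPairPrior:
    @pytest.mark.parametrize("m", range(4, 51))
    def test_closed_form_equals_exact_summation(self, m):
        assert Fraction(2, 3 * (m - 1)) == rcr_probability_by_coalescent_recursion(m)
        assert rb.prob_rcr_random_pair(m, diploid=False) == pytest.approx(
            float(Fraction(2, 3 * (m - 1)))
        )

    def test_haploid_m3(self):
        assert rb.prob_rcr_random_pair(3, diploid=False) == pytest.approx(1 / 3)

    def test_published_diploid_value(self):
        """m = 2,284 haploid genomes gives P[RCR|¬d] = 0.0012 (2 s.f.)."""
        p = rb.prob_rcr_random_pair(2284, diploid=True)
        assert float(f"{p:.2g}") == 0.0012

    def test_diploid_is_four_times_haploid(self):
        assert rb.prob_rcr_random_pair(30, True) == pytest.approx(
            4 * rb.prob_rcr_random_pair(30, False)
        )

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            rb.prob_rcr_random_pair(3, diploid=True)


class TestBayesFactor:
    def test_equal_lrv_probabilities_give_unit_factor(self):
        assert rb.bayes_factor(0.3, 0.3, 0.8, 0.001) == pytest.approx(1.0)

    def test_zero_random_prior_specialization(self):
        pd_, pnd, prior = 0.5, 0.02, 0.8
        assert rb.bayes_factor(pd_, pnd, prior, 0.0) == pytest.approx(
            1 + (pd_ - pnd) / (prior * pnd)
        )

    def test_nonpositive_denominator_is_error(self):
        with pytest.raises(rb.UndefinedBayesFactorError):
            rb.bayes_factor(0.9, 0.0, 0.8, 0.01)

    def test_monotone_in_p_lrv_d(self):
        bfs = [rb.bayes_factor(p, 0.02, 0.8, 0.001) for p in np.linspace(0.05, 0.9, 20)]
        assert np.all(np.diff(bfs) > 0)


class TestPosterior:
    def test_unit_factor_returns_prior(self):
        assert rb.posterior_rcr(0.84, 1.0) == pytest.approx(0.84)

    def test_hand_arithmetic(self):
        assert rb.posterior_rcr(0.5, 3.0) == pytest.approx(0.75)

    def test_inverse_roundtrip(self):
        # solve for the factor that lifts 0.84 to 0.99, then check forwards
        prior, target = 0.84, 0.99
        bf = (target / (1 - target)) / (prior / (1 - prior))
        assert rb.posterior_rcr(prior, bf) == pytest.approx(target)

    def test_monotone_in_bayes_factor(self):
        posts = [rb.posterior_rcr(0.7, bf) for bf in np.linspace(0.5, 50, 40)]
        assert np.all(np.diff(posts) > 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            rb.posterior_rcr(0.5, 0.0)
        with pytest.raises(ValueError):
            rb.posterior_rcr(1.0, 2.0)


def toy_table():
    """8 diploid samples (m=16), hand-built allele counts.

    Sites (pos: per-sample genotypes as allele-index pairs over (A,C)):
      100: boundary marker (unused by profiling)
      140: C count 5, carried by samples 0 (het) and 1 (hom) and 2,3 (het)
      150: focal doubleton, samples 0 & 1
      160: C count 3, carried by samples 2,4 (not both focal carriers)
      200: boundary marker
    """
    def site(pairs):
        return np.array(pairs, dtype=np.int8)

    positions = [100, 140, 150, 160, 200]
    genotypes = np.stack(
        [
            site([(0, 0)] * 8),
            site([(0, 1), (1, 1), (0, 1), (0, 1), (0, 0), (0, 0), (0, 0), (0, 0)]),
            site([(0, 1), (0, 1), (0, 0), (0, 0), (0, 0), (0, 0), (0, 0), (0, 0)]),
            site([(0, 0), (0, 0), (0, 1), (0, 0), (1, 1), (0, 0), (0, 0), (0, 0)]),
            site([(0, 0)] * 8),
        ]
    )
    return GenotypeTable(
        contig="toy",
        positions=np.array(positions),
        sample_ids=[f"s{i}" for i in range(8)],
        genotypes=genotypes,
        alleles=[("A", "C")] * 5,
    )


class TestLRVProfiles:
    def test_shared_and_unshared_variants(self):
        gt = toy_table()
        seg = d.PairSegment(
            contig="toy", focal_pos=150, sample_a=0, sample_b=1,
            left_bound=100, right_bound=200, kind="doubleton",
        )
        (prof,) = rb.lrv_profiles([seg], gt, n_max=16)
        # pos 140 (count 5) is carried by both 0 and 1; pos 160 (count 3)
        # is not shared; the focal site itself is excluded
        assert prof.counts == {5: 1}
        assert prof.min_shared_count == 5

    def test_empty_interior_gives_infinite_min_count(self):
        gt = toy_table()
        seg = d.PairSegment(
            contig="toy", focal_pos=150, sample_a=6, sample_b=7,
            left_bound=100, right_bound=200, kind="random",
        )
        (prof,) = rb.lrv_profiles([seg], gt, n_max=16)
        assert prof.counts == {}
        assert math.isinf(prof.min_shared_count)

    def test_n_max_filters_high_counts(self):
        gt = toy_table()
        seg = d.PairSegment(
            contig="toy", focal_pos=150, sample_a=0, sample_b=1,
            left_bound=100, right_bound=200, kind="doubleton",
        )
        (prof,) = rb.lrv_profiles([seg], gt, n_max=4)
        assert prof.counts == {}

    def test_recount_against_brute_force(self, tiny_pipeline):
        """Profile totals equal a direct per-site recount over the interval."""
        gt = tiny_pipeline.gt
        segs = tiny_pipeline.segs_d[:20]
        profs = rb.lrv_profiles(segs, gt, n_max=8)
        for seg, prof in zip(segs, profs):
            expected = {}
            for i in range(gt.n_sites):
                pos = int(gt.positions[i])
                if not (seg.left_bound < pos < seg.right_bound) or pos in seg.focal_positions:
                    continue
                counts = np.bincount(gt.genotypes[i].ravel(), minlength=len(gt.alleles[i]))
                major = int(np.argmax(counts))
                for a in np.flatnonzero(counts):
                    if a == major or not (2 <= counts[a] <= 8):
                        continue
                    both = all(
                        a in gt.genotypes[i, s] for s in (seg.sample_a, seg.sample_b)
                    )
                    if both:
                        expected[int(counts[a])] = expected.get(int(counts[a]), 0) + 1
            assert prof.counts == expected


class TestEstimatePLRV:
    def _profiles(self, mins):
        return [
            rb.LRVProfile(segment_id=(i,), counts={} if m is None else {m: 1})
            for i, m in enumerate(mins)
        ]

    def test_all_doubleton_segments_shared_at_two(self):
        pd_, pnd = rb.estimate_p_lrv(
            self._profiles([2, 2, 2]), self._profiles([None, 5]), 2
        )
        assert pd_ == 1.0
        assert pnd == 0.0

    def test_cumulative_is_nondecreasing(self):
        profs = self._profiles([2, 3, 5, None, 7, 3])
        vals = [rb.estimate_p_lrv(profs, profs, n)[0] for n in range(2, 9)]
        assert vals == sorted(vals)


class TestThresholdAndCalling:
    def _curve(self, inc_posts):
        table = pd.DataFrame(
            {
                "n": range(2, 2 + len(inc_posts)),
                "posterior_inc": inc_posts,
                "posterior_cum": inc_posts,
            }
        )
        return rb.PosteriorCurve(
            table=table, prior_d=0.8, prior_nd=0.001, m=100,
            n_doubleton_segments=10, n_random_segments=10,
        )

    def test_largest_count_with_high_incremental_posterior(self):
        curve = self._curve([0.99, 0.98, 0.96, 0.94, 0.97])
        assert rb.select_threshold(curve, 0.95) == 4

    def test_all_counts_qualify(self):
        curve = self._curve([0.99, 0.98, 0.97])
        assert rb.select_threshold(curve, 0.95) == 4

    def test_no_threshold_gives_none(self):
        assert rb.select_threshold(self._curve([0.9, 0.99]), 0.95) is None

    def test_boundary_count_is_called(self, tiny_pipeline):
        gt = tiny_pipeline.gt
        segs = tiny_pipeline.segs_d
        profs = rb.lrv_profiles(segs, gt, n_max=8)
        curve = rb.posterior_curve(profs, rb.lrv_profiles(tiny_pipeline.segs_nd, gt, 8),
                                   prior_d=0.9, m=gt.haploid_size, n_max=8)
        n_star = 4
        callset = rb.call_rcr(segs, profs, curve, n_star, sample_ids=gt.sample_ids)
        by_pos = callset.set_index("pos")
        for seg, prof in zip(segs, profs):
            want = "RCR" if prof.min_shared_count <= n_star else "unclassified"
            for fp in seg.focal_positions:
                got = by_pos.loc[fp, "label"]
                got = got if isinstance(got, str) else got.iloc[0]
                assert got == want

    def test_called_fraction_matches_brute_force(self, tiny_pipeline):
        gt = tiny_pipeline.gt
        segs = tiny_pipeline.segs_d
        profs = rb.lrv_profiles(segs, gt, n_max=8)
        curve = rb.posterior_curve(
            profs, rb.lrv_profiles(tiny_pipeline.segs_nd, gt, 8),
            prior_d=0.9, m=gt.haploid_size, n_max=8,
        )
        callset = rb.call_rcr(segs, profs, curve, 3)
        expect = sum(
            seg.n_doubletons for seg, p in zip(segs, profs) if p.min_shared_count <= 3
        )
        assert int((callset["label"] == "RCR").sum()) == expect


from hypothesis import given, settings, strategies as st


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    prior=st.floats(0.01, 0.99),
    bf1=st.floats(0.01, 1e4),
    bf2=st.floats(0.01, 1e4),
)
def test_posterior_odds_update_properties(prior, bf1, bf2):
    """The odds update is a valid probability, fixes bf=1 at the prior, and
    is order-preserving in the Bayes factor."""
    p1 = rb.posterior_rcr(prior, bf1)
    assert 0.0 < p1 < 1.0
    assert rb.posterior_rcr(prior, 1.0) == pytest.approx(prior)
    p2 = rb.posterior_rcr(prior, bf2)
    if bf1 < bf2:
        assert p1 <= p2
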