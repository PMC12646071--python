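"""Bayesian single-origin (RCR) classification of doubletons from linked
rare variants.

Two haploid genomes are *reciprocal closest relatives* (RCR) at a site when
they coalesce with each other before either coalesces with any other
lineage — the signature of a single-origin doubleton.  The prior that a
doubleton pair is RCR, P[RCR|d], comes from the triallelic-singleton
estimator (:mod:`doubrcr.mutation_spectrum`).  The prior for an arbitrary
pair follows from coalescent symmetry alone: with m haploid genomes, two
random sequences are RCR with probability 2/(3(m−1)); for two *diploid*
individuals any of the 4 cross-individual sequence pairs may be RCR, giving
8/(3(m−1)).

Observing a linked rare variant (LRV) — a variant of low sample-wide allele
count carried by *both* individuals inside their shared segment — multiplies
the prior odds by a Bayes factor estimated from the doubleton and
matched-random segment sets:

    BF ≈ 1 + (P[LRV|d] − P[LRV|¬d]) / (P[RCR|d]·P[LRV|¬d] − P[LRV|d]·P[RCR|¬d])

P[LRV|d] and P[LRV|¬d] are the proportions of doubleton and random segments
carrying a shared variant of count ≤ n; sweeping the threshold n gives a
posterior curve, from which a calling threshold n* is chosen as the largest
n whose incremental posterior still clears a confidence floor (default
0.95).  Doubletons on segments with a shared variant of count ≤ n* form the
high-confidence RCR callset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

logger = logging.getLogger(__name__)


class UndefinedBayesFactorError(ValueError):
    """The Eq.-5 denominator is non-positive at this threshold."""


def prob_rcr_random_pair(m: int, diploid: bool = True) -> float:
    """Probability that a random pair is RCR at a site, P[RCR|¬d].

    ``m`` is the haploid sample size.  Haploid/phased data: 2/(3(m−1)).
    Unphased diploid individuals (4 candidate sequence pairs): 8/(3(m−1)).
    """
    if m < (4 if diploid else 3):
        raise ValueError("haploid sample size m too small for the closed form")
    if diploid:
        p = 8.0 / (3.0 * (m - 1))
        if p >= 1:
            raise ValueError(f"diploid closed form is not a probability for m={m}")
        return p
    return 2.0 / (3.0 * (m - 1))


def prior_from_estimate(proportion_recurrent: float) -> float:
    """P[RCR|d] = 1 − estimated recurrent proportion, kept a valid prior.

    Degenerate inputs (no triallelic evidence → NaN or 0 proportion) give a
    prior clamped just inside (0, 1) so the odds update stays defined.
    """
    prop = proportion_recurrent if np.isfinite(proportion_recurrent) else 0.0
    return float(min(max(1.0 - prop, 1e-9), 1.0 - 1e-9))


@dataclass
class LRVProfile:
    """Shared rare-variant inventory of one segment.

    ``counts[n]`` is the number of variants of haploid count exactly ``n``
    (2 ≤ n ≤ n_max) carried by both individuals strictly inside the segment
    bounds, the focal doubleton site(s) excluded.  ``min_shared_count`` is
    the smallest such n, or ``math.inf`` when the interior holds no shared
    rare variant.
    """

    segment_id: tuple
    counts: dict = field(default_factory=dict)

    @property
    def min_shared_count(self) -> float:
        return min(self.counts) if self.counts else math.inf


def lrv_profiles(segments, gt: GenotypeTable, n_max: int = 100) -> list:
    """Profile shared rare variants on each segment.

    Allele counts are taken on the **full** table (before the biallelic
    restriction used for scanning), so a rare allele at a multiallelic site
    still counts.  "Carries" means at least one copy of the minor allele in
    the unphased genotype; homozygous carriers count once.  Variants must
    not be the major allele and must have haploid count in [2, n_max].
    """
    from .genotypes import allele_count_matrix

    pos = gt.positions
    G = gt.genotypes
    # qualifying (site, allele) pairs with their counts, sorted by site
    counts_mat = allele_count_matrix(gt)
    major = np.argmax(counts_mat, axis=1)
    qual = (counts_mat >= 2) & (counts_mat <= n_max)
    qual[np.arange(len(major)), major] = False
    q_site, q_allele = np.nonzero(qual)
    q_count = counts_mat[q_site, q_allele].astype(np.int32)
    q_site = q_site.astype(np.int64)
    q_allele = q_allele.astype(np.int16)

    profiles = []
    for seg in segments:
        i0 = np.searchsorted(pos, seg.left_bound, side="right")
        i1 = np.searchsorted(pos, seg.right_bound, side="left")
        lo = np.searchsorted(q_site, i0, side="left")
        hi = np.searchsorted(q_site, i1, side="left")
        counts: dict = {}
        if hi > lo:
            s = q_site[lo:hi]
            a = q_allele[lo:hi]
            focal = np.isin(pos[s], np.asarray(seg.focal_positions))
            ga = G[s, seg.sample_a, :]
            gb = G[s, seg.sample_b, :]
            shared = (
                ((ga[:, 0] == a) | (ga[:, 1] == a))
                & ((gb[:, 0] == a) | (gb[:, 1] == a))
                & ~focal
            )
            for n in q_count[lo:hi][shared]:
                counts[int(n)] = counts.get(int(n), 0) + 1
        profiles.append(LRVProfile(segment_id=seg.segment_id, counts=counts))
    return profiles


def estimate_p_lrv(profiles_d, profiles_nd, n: int) -> tuple:
    """Cumulative (P[LRV|d], P[LRV|¬d]) at threshold ``n``.

    The cumulative proportion counts segments whose smallest shared-variant
    count is ≤ n.
    """
    if not profiles_d or not profiles_nd:
        raise ValueError("both profile sets must be non-empty")
    pd_ = np.mean([p.min_shared_count <= n for p in profiles_d])
    pnd = np.mean([p.min_shared_count <= n for p in profiles_nd])
    return float(pd_), float(pnd)


def bayes_factor(p_lrv_d: float, p_lrv_nd: float, prior_d: float, prior_nd: float) -> float:
    """BF ≈ 1 + (P[LRV|d]−P[LRV|¬d]) / (P[RCR|d]·P[LRV|¬d] − P[LRV|d]·P[RCR|¬d])."""
    for v in (p_lrv_d, p_lrv_nd, prior_d, prior_nd):
        if not (0.0 <= v <= 1.0):
            raise ValueError("all Bayes-factor inputs must be probabilities")
    den = prior_d * p_lrv_nd - p_lrv_d * prior_nd
    if den <= 0:
        raise UndefinedBayesFactorError(
            f"non-positive denominator {den:.3g} (P[LRV|d]={p_lrv_d:.3g}, "
            f"P[LRV|nd]={p_lrv_nd:.3g})"
        )
    return 1.0 + (p_lrv_d - p_lrv_nd) / den


def posterior_rcr(prior_d: float, bf: float) -> float:
    """Posterior P[RCR|d,LRV] from posterior odds = prior odds × BF."""
    if not (0.0 < prior_d < 1.0):
        raise ValueError("prior must be strictly between 0 and 1")
    if bf <= 0:
        raise ValueError("Bayes factor must be positive")
    odds = prior_d / (1.0 - prior_d) * bf
    return odds / (1.0 + odds)


@dataclass
class PosteriorCurve:
    """Per-threshold LRV proportions, Bayes factors and posteriors.

    ``table`` has one row per allele-count threshold n with cumulative and
    incremental P[LRV|d], P[LRV|¬d], BF and posterior (NaN where the BF
    denominator is non-positive), and the number of doubleton segments in
    the cumulative set.  ``prior_d`` is P[RCR|d]; ``prior_nd`` is P[RCR|¬d]
    for haploid sample size ``m``.
    """

    table: pd.DataFrame
    prior_d: float
    prior_nd: float
    m: int
    n_doubleton_segments: int
    n_random_segments: int


def posterior_curve(
    profiles_d,
    profiles_nd,
    prior_d: float,
    m: int,
    n_max: int = 100,
) -> PosteriorCurve:
    """Sweep the LRV threshold n = 2..n_max and evaluate the Bayes update.

    Cumulative rows use segments with min shared count ≤ n; incremental rows
    use segments with min shared count exactly n.  Thresholds where the BF
    denominator is non-positive are masked with NaN.
    """
    prior_nd = prob_rcr_random_pair(m, diploid=True)
    min_d = np.array([p.min_shared_count for p in profiles_d])
    min_nd = np.array([p.min_shared_count for p in profiles_nd])
    rows = []
    for n in range(2, n_max + 1):
        pd_c = float(np.mean(min_d <= n))
        pnd_c = float(np.mean(min_nd <= n))
        pd_i = float(np.mean(min_d == n))
        pnd_i = float(np.mean(min_nd == n))
        row = {
            "n": n,
            "p_lrv_d_cum": pd_c,
            "p_lrv_nd_cum": pnd_c,
            "p_lrv_d_inc": pd_i,
            "p_lrv_nd_inc": pnd_i,
            "n_segments_cum": int(np.sum(min_d <= n)),
        }
        for tag, a, b in (("cum", pd_c, pnd_c), ("inc", pd_i, pnd_i)):
            try:
                bf = bayes_factor(a, b, prior_d, prior_nd)
            except UndefinedBayesFactorError:
                bf = np.nan
            row[f"bf_{tag}"] = bf
            # the approximation can leave the odds update non-positive at
            # noisy thresholds; such points are masked, not errors
            row[f"posterior_{tag}"] = (
                posterior_rcr(prior_d, bf) if np.isfinite(bf) and bf > 0 else np.nan
            )
        rows.append(row)
    return PosteriorCurve(
        table=pd.DataFrame(rows),
        prior_d=prior_d,
        prior_nd=prior_nd,
        m=m,
        n_doubleton_segments=len(profiles_d),
        n_random_segments=len(profiles_nd),
    )


def select_threshold(curve: PosteriorCurve, min_incremental_posterior: float = 0.95):
    """Largest n whose incremental posterior, and that of every smaller
    count, is ≥ the floor.  Stops at the first failure (or NaN).  Returns
    None — an empty callset — when even n=2 fails.
    """
    n_star = None
    for row in curve.table.itertuples(index=False):
        post = row.posterior_inc
        if not np.isfinite(post) or post < min_incremental_posterior:
            break
        n_star = int(row.n)
    if n_star is None:
        logger.warning(
            "no LRV threshold reaches incremental posterior %.2f; empty callset",
            min_incremental_posterior,
        )
    return n_star


def call_rcr(segments, profiles, curve: PosteriorCurve, n_star, sample_ids=None) -> pd.DataFrame:
    """Label every doubleton RCR or unclassified at threshold ``n_star``.

    A doubleton is called RCR when its segment carries a shared variant of
    count ≤ n_star (boundary inclusive).  The attached posterior is the
    incremental posterior at the segment's minimum shared count; a segment
    with no shared rare variant keeps the prior.
    """
    tab = curve.table.set_index("n")
    rows = []
    for seg, prof in zip(segments, profiles):
        msc = prof.min_shared_count
        called = n_star is not None and msc <= n_star
        if np.isfinite(msc) and int(msc) in tab.index:
            post = float(tab.loc[int(msc), "posterior_inc"])
        else:
            post = curve.prior_d
        a, b = seg.sample_a, seg.sample_b
        for fp, fc in zip(seg.focal_positions, seg.focal_classes or [None] * len(seg.focal_positions)):
            rows.append(
                {
                    "contig": seg.contig,
                    "pos": fp,
                    "focal_class": fc,
                    "sample_a": sample_ids[a] if sample_ids is not None else a,
                    "sample_b": sample_ids[b] if sample_ids is not None else b,
                    "left_bound": seg.left_bound,
                    "right_bound": seg.right_bound,
                    "length": seg.length,
                    "min_shared_count": msc,
                    "posterior": post,
                    "label": "RCR" if called else "unclassified",
                }
            )
    return pd.DataFrame(rows)
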