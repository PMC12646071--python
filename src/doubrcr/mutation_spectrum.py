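"""Recurrent-doubleton estimation from triallelic singleton sites.

The estimator rests on a simple identity for finite-site mutation on the
external branches of a genealogy.  Condition on a site whose ancestral base
is X and on exactly two external-branch mutations having occurred there.
If P[X→Y] is the probability a mutation of X yields Y, the chance that the
two hits produce two *different* singletons Y and Z is
P[X→Y,Z] = 2 P[X→Y] P[X→Z], while the chance both hits produce the same
base Y — a recurrent doubleton masquerading as an ordinary doubleton — is
P[X→Y,Y] = P[X→Y]².  Eliminating the unknown per-class probabilities gives

    P[X→Y,Y] = P[X→Y,Z1] · P[X→Y,Z2] / (2 · P[X→Z1,Z2])

so the *number* of recurrent X→Y doubletons can be estimated from observed
triallelic singleton counts alone:

    Nest[X→Y,Y] = N[X→Y,Z1] · N[X→Y,Z2] / (2 · N[X→Z1,Z2])

and the single-origin ("reciprocal closest relative", RCR) prior for the
class is P[RCR|d] = 1 − Nest/D, with D the observed doubleton count.
Uncertainty comes from a per-base multinomial bootstrap over the triallelic
pair counts; doubleton counts are held fixed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import (
    BASES,
    KIND_DOUBLETON,
    KIND_SINGLETON,
    KIND_TRIALLELIC_SINGLETON,
)

logger = logging.getLogger(__name__)

#: the 12 ordered ancestral→derived base pairs
MUTATION_CLASSES = tuple(
    (x, y) for x in BASES for y in BASES if x != y
)

#: per major base, the 3 unordered singleton pairs, in a fixed order
TRIALLELIC_PAIRS = {
    x: tuple(
        tuple(sorted(p)) for p in itertools.combinations([b for b in BASES if b != x], 2)
    )
    for x in BASES
}


class UndefinedEstimateError(ValueError):
    """Raised when the denominator triallelic count of a class is zero."""


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (display only)."""
    return int(math.floor(x + 0.5))


@dataclass
class MutationClassCounts:
    """The 12-class ledger of singleton, doubleton and triallelic counts.

    ``triallelic[(X, (Y, Z))]`` is N[X→Y,Z], the number of sites whose major
    allele is X carrying two different singletons Y and Z (the pair key is
    sorted).  ``doubletons[(X, Y)]`` is D[X→Y]; ``singletons[(X, Y)]`` is
    S[X→Y].  ``sites_with_major[X]`` is the number of genome sites whose
    major allele is X — the multinomial trial count for the bootstrap.
    """

    triallelic: dict = field(default_factory=dict)
    doubletons: dict = field(default_factory=dict)
    singletons: dict = field(default_factory=dict)
    sites_with_major: dict = field(default_factory=dict)

    def triallelic_count(self, major: str, pair) -> int:
        return int(self.triallelic.get((major, tuple(sorted(pair))), 0))

    def __add__(self, other: "MutationClassCounts") -> "MutationClassCounts":
        def merge(a, b):
            out = dict(a)
            for k, v in b.items():
                out[k] = out.get(k, 0) + v
            return out

        return MutationClassCounts(
            triallelic=merge(self.triallelic, other.triallelic),
            doubletons=merge(self.doubletons, other.doubletons),
            singletons=merge(self.singletons, other.singletons),
            sites_with_major=merge(self.sites_with_major, other.sites_with_major),
        )

    @classmethod
    def from_classification(
        cls, classes: pd.DataFrame, monomorphic_per_base: dict | None = None
    ) -> "MutationClassCounts":
        """Tally counts from a :func:`~doubrcr.genotypes.classify_sites` table.

        ``sites_with_major`` defaults to the number of retained sites with
        each major allele.  For variant-only inputs (e.g. simulator output)
        pass ``monomorphic_per_base`` to add the invariant genome sites per
        base, since those are valid multinomial trials too.
        """
        counts = cls()
        maj = classes["major"]
        for x in BASES:
            counts.sites_with_major[x] = int((maj == x).sum()) + int(
                (monomorphic_per_base or {}).get(x, 0)
            )
        for kind, target in (
            (KIND_SINGLETON, counts.singletons),
            (KIND_DOUBLETON, counts.doubletons),
        ):
            sub = classes[classes["kind"] == kind]
            for (x, y), n in sub.groupby(["major", "minor_bases"]).size().items():
                target[(x, y)] = int(n)
        tri = classes[classes["kind"] == KIND_TRIALLELIC_SINGLETON]
        for (x, pair_str), n in tri.groupby(["major", "minor_bases"]).size().items():
            key = (x, tuple(sorted(pair_str.split(","))))
            counts.triallelic[key] = counts.triallelic.get(key, 0) + int(n)
        return counts


@dataclass
class RecurrenceEstimate:
    """Per-class and overall recurrent-doubleton estimates.

    ``per_class`` has one row per mutation class: ancestral, derived, the
    three triallelic inputs, D, nest (real-valued), proportion_recurrent and
    (when bootstrapped) ci_low/ci_high.  The overall proportion is
    Σ Nest / Σ D — a ratio of sums, never an average of ratios — and
    ``prior_rcr`` is its complement, the prior P[RCR|d] used downstream.
    """

    per_class: pd.DataFrame
    total_nest: float
    total_d: int
    proportion_recurrent: float
    prior_rcr: float
    ci_overall: tuple | None = None

    def summary(self) -> dict:
        return {
            "total_nest": self.total_nest,
            "total_doubletons": self.total_d,
            "proportion_recurrent": self.proportion_recurrent,
            "prior_rcr": self.prior_rcr,
            "ci_overall": list(self.ci_overall) if self.ci_overall else None,
        }


def estimate_recurrent_count(counts: MutationClassCounts, ancestral: str, derived: str) -> float:
    """Nest[X→Y,Y] = N[X→Y,Z1]·N[X→Y,Z2] / (2·N[X→Z1,Z2]).

    Z1, Z2 are the two bases other than X and Y.  Kept real-valued; round
    only for display.  Raises :class:`UndefinedEstimateError` when the
    denominator count is zero.
    """
    if ancestral == derived or ancestral not in BASES or derived not in BASES:
        raise ValueError(f"invalid mutation class {ancestral}->{derived}")
    z1, z2 = [b for b in BASES if b not in (ancestral, derived)]
    n1 = counts.triallelic_count(ancestral, (derived, z1))
    n2 = counts.triallelic_count(ancestral, (derived, z2))
    den = counts.triallelic_count(ancestral, (z1, z2))
    if den == 0:
        raise UndefinedEstimateError(
            f"N[{ancestral}->{z1},{z2}] = 0: recurrent count for "
            f"{ancestral}->{derived} is undefined"
        )
    return n1 * n2 / (2.0 * den)


def estimate_prior_rcr(
    counts: MutationClassCounts,
    bootstrap_reps: int | None = None,
    seed: int | None = None,
) -> RecurrenceEstimate:
    """Per-class and overall recurrent proportions, and the RCR prior.

    Classes with a zero triallelic denominator are reported with NaN and
    excluded (with a warning) from the overall sums.  When
    ``bootstrap_reps`` is given, percentile confidence intervals from
    :func:`bootstrap_ci` are attached.
    """
    rows = []
    total_nest = 0.0
    total_d = 0
    for x, y in MUTATION_CLASSES:
        d = int(counts.doubletons.get((x, y), 0))
        z1, z2 = [b for b in BASES if b not in (x, y)]
        try:
            nest = estimate_recurrent_count(counts, x, y)
        except UndefinedEstimateError:
            logger.warning("class %s->%s has zero triallelic denominator; excluded", x, y)
            nest = np.nan
        prop = nest / d if d > 0 and np.isfinite(nest) else np.nan
        if np.isfinite(nest):
            total_nest += nest
            total_d += d
        rows.append(
            {
                "ancestral": x,
                "derived": y,
                "n_pair_1": counts.triallelic_count(x, (y, z1)),
                "n_pair_2": counts.triallelic_count(x, (y, z2)),
                "n_denominator": counts.triallelic_count(x, (z1, z2)),
                "doubletons": d,
                "nest": nest,
                "proportion_recurrent": prop,
            }
        )
    per_class = pd.DataFrame(rows)
    overall = total_nest / total_d if total_d > 0 else np.nan
    est = RecurrenceEstimate(
        per_class=per_class,
        total_nest=total_nest,
        total_d=total_d,
        proportion_recurrent=overall,
        prior_rcr=1.0 - overall,
    )
    if bootstrap_reps:
        per_cls_ci, overall_ci = bootstrap_ci(counts, reps=bootstrap_reps, seed=seed or 0)
        per_class["ci_low"] = [per_cls_ci[(x, y)][0] for x, y in MUTATION_CLASSES]
        per_class["ci_high"] = [per_cls_ci[(x, y)][1] for x, y in MUTATION_CLASSES]
        est.ci_overall = overall_ci
    return est


def bootstrap_ci(
    counts: MutationClassCounts, reps: int = 10_000, seed: int = 0
) -> tuple:
    """Multinomial-bootstrap 95% CIs for the recurrent proportions.

    For each major base X the three triallelic pair counts are resampled as
    a multinomial with trials = ``sites_with_major[X]`` and event
    probabilities N/trials (the remaining mass is "no triallelic singleton").
    Per replicate the estimator is recomputed; intervals are 2.5th/97.5th
    percentiles.  Doubleton counts are held fixed.  Deterministic given
    ``seed``.

    Returns ``(per_class, overall)`` where ``per_class`` maps the 12 classes
    to (low, high) on the proportion-recurrent scale and ``overall`` is the
    interval for Σ Nest / Σ D.
    """
    for x in BASES:
        if counts.sites_with_major.get(x, 0) <= 0:
            raise ValueError(
                f"sites_with_major[{x}] unknown or zero — supply the genome "
                "base composition to define the multinomial trial counts"
            )
    rng = np.random.default_rng(seed)
    # resampled triallelic counts per base: (reps, 3) in TRIALLELIC_PAIRS order
    resampled = {}
    for x in BASES:
        trials = int(counts.sites_with_major[x])
        n = np.array([counts.triallelic_count(x, p) for p in TRIALLELIC_PAIRS[x]], float)
        p = n / trials
        if p.sum() > 1:
            raise ValueError(f"triallelic counts for major {x} exceed sites_with_major")
        probs = np.concatenate([p, [1.0 - p.sum()]])
        resampled[x] = rng.multinomial(trials, probs, size=reps)[:, :3].astype(float)

    per_class_props = {}
    nest_mat = np.full((reps, len(MUTATION_CLASSES)), np.nan)
    d_vec = np.zeros(len(MUTATION_CLASSES))
    with np.errstate(divide="ignore", invalid="ignore"):
        for ci, (x, y) in enumerate(MUTATION_CLASSES):
            z1, z2 = [b for b in BASES if b not in (x, y)]
            pairs = TRIALLELIC_PAIRS[x]
            i1 = pairs.index(tuple(sorted((y, z1))))
            i2 = pairs.index(tuple(sorted((y, z2))))
            iden = pairs.index(tuple(sorted((z1, z2))))
            r = resampled[x]
            # zero numerator counts mean no triallelic evidence at all:
            # the replicate estimate is 0, not undefined
            nest = np.where(
                r[:, iden] > 0,
                r[:, i1] * r[:, i2] / (2.0 * r[:, iden]),
                np.where((r[:, i1] == 0) & (r[:, i2] == 0), 0.0, np.nan),
            )
            d = int(counts.doubletons.get((x, y), 0))
            per_class_props[(x, y)] = nest / d if d > 0 else np.full(reps, np.nan)
            nest_mat[:, ci] = nest
            d_vec[ci] = d
    # overall per replicate over the classes defined in that replicate, as in
    # the point estimate (ratio of sums, excluded classes dropped from both)
    defined = np.isfinite(nest_mat)
    d_sum = defined @ d_vec
    with np.errstate(divide="ignore", invalid="ignore"):
        overall = np.where(d_sum > 0, np.nansum(nest_mat, axis=1) / d_sum, np.nan)

    def interval(v):
        if np.all(np.isnan(v)):
            return (np.nan, np.nan)
        return tuple(np.nanpercentile(v, [2.5, 97.5]))

    return {k: interval(v) for k, v in per_class_props.items()}, interval(overall)


def spectrum_expectations(singletons: dict) -> pd.DataFrame:
    """Doubleton-spectrum expectations from the singleton spectrum.

    If every doubleton has a single origin, the doubleton class proportions
    should mirror the singleton proportions p_i; if every doubleton is
    recurrent (two independent hits of the same class), they should follow
    p_i² renormalized.  A 3.75-fold singleton ratio therefore becomes a
    3.75² ≈ 14.1-fold recurrent-doubleton ratio.  Classes with zero
    singleton counts are excluded with a warning.
    """
    items = [((x, y), singletons.get((x, y), 0)) for x, y in MUTATION_CLASSES]
    nonzero = [(k, c) for k, c in items if c > 0]
    if len(nonzero) < len(items):
        logger.warning("%d singleton classes have zero counts; excluded", len(items) - len(nonzero))
    keys = [k for k, _ in nonzero]
    c = np.array([v for _, v in nonzero], float)
    p = c / c.sum()
    p2 = p**2 / (p**2).sum()
    return pd.DataFrame(
        {
            "ancestral": [k[0] for k in keys],
            "derived": [k[1] for k in keys],
            "single_origin_expectation": p,
            "recurrent_expectation": p2,
        }
    )


def spectrum_gtest(observed, reference) -> tuple:
    """Log-likelihood-ratio G test on the 2×k table of class counts.

    Returns ``(G, df, p)``.  Zero rows/columns are a hard error (expected
    cell counts must be positive).
    """
    obs = np.asarray(observed, float)
    ref = np.asarray(reference, float)
    if obs.shape != ref.shape or obs.ndim != 1:
        raise ValueError("observed and reference must be equal-length 1-D count vectors")
    table = np.vstack([obs, ref])
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row or column total in contingency table")
    g, p, df, _ = stats.chi2_contingency(table, correction=False, lambda_="log-likelihood")
    return float(g), int(df), float(p)


def recurrence_table(est: RecurrenceEstimate) -> pd.DataFrame:
    """Display table with integer (half-up) Nest values."""
    out = est.per_class.copy()
    out["nest_rounded"] = [
        round_half_up(v) if np.isfinite(v) else -1 for v in out["nest"]
    ]
    return out
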