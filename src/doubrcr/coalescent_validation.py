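"""Coalescent simulation with exact mutation-origin truth, and end-to-end
validation of the recurrence estimator and the RCR posterior.

Genotype data are simulated with msprime under four demographic scenarios —
constant-size or instantaneous-expansion, panmictic or 5-deme island — with
finite-site mutations (Jukes–Cantor kernel by default, so recurrent and
triallelic configurations arise naturally).  Because every mutation event is
recorded in the tree sequence, the number of independent origins of each
doubleton's minor allele is known exactly: each carrier genome's allele is
traced to the mutation event nearest it on the path to the root, and the
site's origin count is the number of distinct such events.  Apparent
doubletons whose minor allele is the *ancestral* state (zero origins; e.g.
a back-mutation elsewhere) are flagged separately.

Desk-scale presets are diffusion rescalings of the reference scenarios
(population sizes and times divided by 1000, mutation rate multiplied by
1000), which leave θ = 4Nμ per bp — and hence the site-frequency and
triallelic/doubleton count distributions — unchanged, on a 300 kb genome
with 50 diploid samples.  The scaled recombination rate is set below the
strict rescaling (ρ = 0.06/bp instead of 0.72/bp): per-site count
distributions are independent of recombination, genealogies still turn
over every few tens of bp (far shorter than the spacing between the rare
triallelic sites, so pooled counts remain quasi-independent and the
multinomial bootstrap valid), and the saving buys an order of magnitude
more sequence per CPU-second — which the small-count-sensitive ratio
estimator needs.  Shared segments are correspondingly longer than under
the strict rescaling.  The reference (cluster-scale) configurations are
included but are far beyond desk scale.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import haplotype_scan, mutation_spectrum, rcr_bayes
from .genotypes import BASES, GenotypeTable, classify_sites, restrict_biallelic

logger = logging.getLogger(__name__)


@dataclass
class ScenarioConfig:
    """One demographic scenario for the validation simulations.

    Sizes are diploid effective sizes; ``expansion_time`` is the number of
    generations ago at which the population grew instantaneously from
    ``deme_size_initial`` to ``deme_size_current`` (0 means constant size).
    ``migration_rate`` is the symmetric per-generation island-model rate.
    """

    name: str
    n_demes: int
    deme_size_initial: float
    deme_size_current: float
    expansion_time: float
    migration_rate: float
    samples_per_deme: int
    genome_length: float
    recombination_rate: float
    mutation_rate: float
    n_replicates: int = 1

    def __post_init__(self):
        if self.samples_per_deme < 2 and self.n_demes == 1:
            raise ValueError("need at least 2 diploid samples")
        for f in ("migration_rate", "recombination_rate", "mutation_rate", "expansion_time"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.n_demes * self.samples_per_deme

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


def _desk(name, **kw):
    base = dict(
        n_demes=1,
        deme_size_initial=1e4,
        deme_size_current=1e4,
        expansion_time=0.0,
        migration_rate=0.0,
        samples_per_deme=50,
        genome_length=3e5,
        recombination_rate=1.5e-6,
        mutation_rate=1.125e-6,
        n_replicates=1,
    )
    base.update(kw)
    return ScenarioConfig(name=name, **base)


#: desk-scale presets: 1/1000 diffusion rescalings of the reference
#: scenarios (θ per bp preserved; reduced ρ and the island migration-rate
#: caveat are explained in the module docstring).
DESK_SCENARIOS = {
    "panmictic_constant": _desk("panmictic_constant", n_replicates=2),
    "panmictic_expansion": _desk(
        "panmictic_expansion",
        deme_size_initial=1e3,
        deme_size_current=1e5,
        expansion_time=10.0,
        mutation_rate=3.125e-6,
        n_replicates=4,
    ),
    "island_constant": _desk(
        "island_constant",
        n_demes=5,
        deme_size_initial=1e3,
        deme_size_current=1e3,
        migration_rate=0.05,
        samples_per_deme=10,
        mutation_rate=3.125e-6,
        n_replicates=2,
    ),
    "island_expansion": _desk(
        "island_expansion",
        n_demes=5,
        deme_size_initial=1e3,
        deme_size_current=1e5,
        expansion_time=10.0,
        migration_rate=0.05,
        samples_per_deme=10,
        mutation_rate=3.125e-6,
        n_replicates=2,
    ),
}

#: presets for validating the *count-based estimator* (as opposed to the
#: segment pipeline): the ratio Nest = N1·N2/(2·N3) needs its plug-in bias
#: (∝ 1 / per-cell triallelic count) and the ancestral-singleton
#: contamination of triallelic sites (∝ 1/m, the share of sites where one
#: "singleton" is the ancestral base stranded on one genome) both small
#: relative to the bootstrap CI width, as they are at published scale.
#: Hence: larger haploid samples (m = 300; 600 for the higher-diversity
#: island scenarios), more pooled sequence, and a further-reduced
#: recombination rate to keep ancestry simulation at desk cost (per-site
#: counts are recombination-independent).
ESTIMATOR_SCENARIOS = {
    "panmictic_constant": _desk(
        "panmictic_constant",
        samples_per_deme=150,
        genome_length=5e5,
        recombination_rate=3e-7,
        n_replicates=3,
    ),
    "panmictic_expansion": _desk(
        "panmictic_expansion",
        deme_size_initial=1e3,
        deme_size_current=1e5,
        expansion_time=10.0,
        mutation_rate=3.125e-6,
        samples_per_deme=150,
        genome_length=1.5e6,
        recombination_rate=1e-7,
        n_replicates=3,
    ),
    "island_constant": _desk(
        "island_constant",
        n_demes=5,
        deme_size_initial=1e3,
        deme_size_current=1e3,
        migration_rate=0.05,
        samples_per_deme=60,
        mutation_rate=3.125e-6,
        genome_length=5e5,
        recombination_rate=3e-7,
        n_replicates=3,
    ),
    "island_expansion": _desk(
        "island_expansion",
        n_demes=5,
        deme_size_initial=1e3,
        deme_size_current=1e5,
        expansion_time=10.0,
        migration_rate=0.05,
        samples_per_deme=60,
        mutation_rate=3.125e-6,
        genome_length=5e5,
        recombination_rate=3e-7,
        n_replicates=3,
    ),
}

#: reference configurations at published scale (cluster-scale: do not run
#: on a single CPU).
FULL_SCENARIOS = {
    "panmictic_constant": ScenarioConfig(
        "panmictic_constant", 1, 1e7, 1e7, 0.0, 0.0, 1000, 1e6, 1.8e-8, 1.125e-9, 70
    ),
    "panmictic_expansion": ScenarioConfig(
        "panmictic_expansion", 1, 1e6, 1e8, 1e4, 0.0, 1000, 1e6, 1.8e-8, 3.125e-9, 70
    ),
    "island_constant": ScenarioConfig(
        "island_constant", 5, 1e6, 1e6, 0.0, 0.01, 200, 1e6, 1.8e-8, 3.125e-9, 70
    ),
    "island_expansion": ScenarioConfig(
        "island_expansion", 5, 1e6, 1e8, 1e4, 0.01, 200, 1e6, 1.8e-8, 3.125e-9, 70
    ),
}


def _demography(cfg: ScenarioConfig):
    import msprime

    if cfg.n_demes == 1:
        dem = msprime.Demography()
        dem.add_population(name="p0", initial_size=cfg.deme_size_current)
        if cfg.expansion_time > 0 and cfg.deme_size_initial != cfg.deme_size_current:
            dem.add_population_parameters_change(
                time=cfg.expansion_time, population="p0", initial_size=cfg.deme_size_initial
            )
        return dem
    dem = msprime.Demography.island_model(
        [cfg.deme_size_current] * cfg.n_demes, migration_rate=cfg.migration_rate
    )
    if cfg.expansion_time > 0 and cfg.deme_size_initial != cfg.deme_size_current:
        for i in range(cfg.n_demes):
            dem.add_population_parameters_change(
                time=cfg.expansion_time, population=i, initial_size=cfg.deme_size_initial
            )
    return dem


def simulate_tree_sequence(cfg: ScenarioConfig, seed: int):
    """One mutated tree sequence under ``cfg`` (deterministic given seed)."""
    import msprime

    rng = np.random.default_rng(seed)
    s_anc, s_mut = (int(x) for x in rng.integers(1, 2**31 - 1, size=2))
    ts = msprime.sim_ancestry(
        samples={i: cfg.samples_per_deme for i in range(cfg.n_demes)},
        demography=_demography(cfg),
        sequence_length=cfg.genome_length,
        recombination_rate=cfg.recombination_rate,
        ploidy=2,
        random_seed=s_anc,
    )
    return msprime.sim_mutations(
        ts, rate=cfg.mutation_rate, model=msprime.JC69(), random_seed=s_mut
    )


def tree_sequence_to_table(ts, contig: str = "sim") -> GenotypeTable:
    """Export a mutated tree sequence to the internal genotype table.

    Positions become 1-based; alleles keep the site's ancestral state first,
    so the table matches what :func:`~doubrcr.genotypes.load_vcf` would read
    from the simulator's VCF output.
    """
    n_dip = ts.num_individuals if ts.num_individuals else ts.num_samples // 2
    positions, genos, alleles = [], [], []
    for var in ts.variants():
        if any(a is None or a not in BASES for a in var.alleles):
            continue
        positions.append(int(var.site.position) + 1)
        genos.append(var.genotypes.reshape(n_dip, 2).astype(np.int8))
        alleles.append(tuple(var.alleles))
    gmat = np.stack(genos) if genos else np.empty((0, n_dip, 2), dtype=np.int8)
    return GenotypeTable(
        contig=contig,
        positions=np.array(positions, dtype=np.int64),
        sample_ids=[f"ind{i}" for i in range(n_dip)],
        genotypes=gmat,
        alleles=alleles,
    )


def doubleton_truth(ts) -> pd.DataFrame:
    """Exact per-doubleton mutation-origin counts from the tree sequence.

    A site enters the truth table when it has a strict major allele and a
    single other allele at haploid count 2.  For each of the two carrier
    genomes the governing mutation (the event nearest the sample on its
    path to the root) is identified; ``origins`` is the number of distinct
    governing events.  Carriers whose allele is the untouched ancestral
    state contribute no event; such sites get ``origins`` = the number of
    mutation-derived carriers' events and ``ancestral_minor`` = True.

    Columns: pos (1-based), minor, origins, ancestral_minor,
    carrier_node_a/b (haploid), carrier_a/b (diploid individual indices).
    """
    # candidate doubleton sites from the genotype configuration
    candidates = {}
    for var in ts.variants():
        g = var.genotypes
        counts = np.bincount(g, minlength=len(var.alleles))
        order = np.argsort(counts)[::-1]
        if len(counts) < 2 or counts[order[0]] == counts[order[1]]:
            continue
        minors = counts[np.arange(len(counts)) != order[0]]
        if sorted(minors[minors > 0].tolist()) != [2]:
            continue
        minor_idx = [i for i in range(len(counts)) if i != order[0] and counts[i] == 2][0]
        carriers = np.flatnonzero(g == minor_idx)
        candidates[var.site.id] = (var.alleles[minor_idx], carriers)

    node_individual = {u: ts.node(u).individual for u in ts.samples()}
    rows = []
    for tree in ts.trees():
        for site in tree.sites():
            if site.id not in candidates:
                continue
            minor, carriers = candidates[site.id]
            newest = {}
            for mut in site.mutations:  # parents precede children
                newest[mut.node] = mut.id
            origins = set()
            n_ancestral = 0
            for u in carriers:
                v = int(u)
                found = None
                while v != -1:
                    if v in newest:
                        found = newest[v]
                        break
                    v = tree.parent(v)
                if found is None:
                    n_ancestral += 1
                else:
                    origins.add(found)
            ind = [node_individual[int(u)] for u in carriers]
            rows.append(
                {
                    "pos": int(site.position) + 1,
                    "minor": minor,
                    "origins": len(origins),
                    "ancestral_minor": n_ancestral > 0,
                    "carrier_node_a": int(carriers[0]),
                    "carrier_node_b": int(carriers[1]),
                    "carrier_a": ind[0],
                    "carrier_b": ind[1],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "pos", "minor", "origins", "ancestral_minor",
            "carrier_node_a", "carrier_node_b", "carrier_a", "carrier_b",
        ],
    )


def simulate_scenario(cfg: ScenarioConfig, seed: int):
    """Simulate one replicate: returns ``(GenotypeTable, truth DataFrame)``."""
    ts = simulate_tree_sequence(cfg, seed)
    return tree_sequence_to_table(ts), doubleton_truth(ts)


def true_recurrent_proportion(truth: pd.DataFrame) -> float:
    """Fraction of doubleton sites with two or more mutation origins."""
    if len(truth) == 0:
        raise ValueError("truth table is empty")
    return float((truth["origins"] >= 2).mean())


def _monomorphic_per_base(cfg: ScenarioConfig, n_variant_sites: int) -> dict:
    # invariant genome positions are valid multinomial trials; the JC69 root
    # distribution is uniform over bases
    per = max(0.0, cfg.genome_length - n_variant_sites) / 4.0
    return {b: int(round(per)) for b in BASES}


def simulate_replicates(cfg: ScenarioConfig, seed: int) -> list:
    """``cfg.n_replicates`` independent ``(GenotypeTable, truth)`` pairs with
    per-replicate seeds derived from ``seed``."""
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(1, 2**31 - 1, size=cfg.n_replicates)
    return [simulate_scenario(cfg, int(rs)) for rs in rep_seeds]


def validate_estimator(
    cfg: ScenarioConfig, seed: int, bootstrap_reps: int = 1000, replicates=None
) -> dict:
    """Pooled-replicate comparison of the triallelic-singleton estimate
    (with its bootstrap 95% CI) against the tree-sequence truth.

    Runs ``cfg.n_replicates`` simulations with seeds derived from ``seed``
    (or reuses ``replicates``, a list of ``(GenotypeTable, truth)`` pairs),
    pools the class counts and truth tables, and reports whether the true
    recurrent proportion falls inside the pooled estimate's bootstrap CI.

    Note the comparison is conservative by construction: the "truth" is
    itself a realized proportion over the run's finite set of doubletons,
    whose sampling noise is comparable to the estimator's for these θ, so
    even an unbiased estimator's nominal-95% interval covers it less than
    95% of the time (see docs/methods.md).
    """
    rng = np.random.default_rng(seed)
    rng.integers(1, 2**31 - 1, size=cfg.n_replicates)  # keep seed stream stable
    if replicates is None:
        replicates = simulate_replicates(cfg, seed)
    counts = mutation_spectrum.MutationClassCounts()
    truths = []
    for gt, truth in replicates:
        classes = classify_sites(gt)
        counts = counts + mutation_spectrum.MutationClassCounts.from_classification(
            classes, monomorphic_per_base=_monomorphic_per_base(cfg, gt.n_sites)
        )
        truths.append(truth)
    truth = pd.concat(truths, ignore_index=True)
    est = mutation_spectrum.estimate_prior_rcr(
        counts, bootstrap_reps=bootstrap_reps, seed=int(rng.integers(1, 2**31 - 1))
    )
    lo, hi = est.ci_overall
    true_prop = true_recurrent_proportion(truth)
    return {
        "scenario": cfg.name,
        "n_replicates": cfg.n_replicates,
        "estimated_recurrent_proportion": est.proportion_recurrent,
        "ci_low": lo,
        "ci_high": hi,
        "true_recurrent_proportion": true_prop,
        "n_doubletons": int(len(truth)),
        "covered": bool(lo <= true_prop <= hi),
    }


def _pipeline_one_replicate(cfg: ScenarioConfig, seed: int, n_max: int, rep=None):
    """Simulate (or reuse), classify, scan and profile one replicate."""
    gt, truth = simulate_scenario(cfg, seed) if rep is None else rep
    classes = classify_sites(gt)
    counts = mutation_spectrum.MutationClassCounts.from_classification(
        classes, monomorphic_per_base=_monomorphic_per_base(cfg, gt.n_sites)
    )
    bi = restrict_biallelic(gt)
    segs_d, _ = haplotype_scan.doubleton_segments(bi, classes)
    segs_nd, _ = haplotype_scan.random_pair_segments(bi, classes, seed=seed)
    prof_d = rcr_bayes.lrv_profiles(segs_d, gt, n_max=n_max)
    prof_nd = rcr_bayes.lrv_profiles(segs_nd, gt, n_max=n_max)
    rcr_by_pos = dict(zip(truth["pos"], truth["origins"] == 1))
    # per scanned doubleton: (segment min shared count, truly single origin)
    doubleton_points = []
    for seg, prof in zip(segs_d, prof_d):
        for fp in seg.focal_positions:
            if fp in rcr_by_pos:
                doubleton_points.append((prof.min_shared_count, bool(rcr_by_pos[fp])))
    return counts, prof_d, prof_nd, doubleton_points


def validate_calibration(
    cfg: ScenarioConfig,
    seed: int,
    n_max: int = 10,
    min_doubletons: int = 100,
    replicates=None,
) -> dict:
    """Inferred posterior vs. true RCR fraction across LRV thresholds.

    Pools ``cfg.n_replicates`` replicates, runs the full calling pipeline,
    and for every threshold n compares the cumulative posterior
    P[RCR|d,LRV≤n] with the true single-origin fraction among doubletons
    whose segment shares a variant of count ≤ n.  Thresholds whose
    cumulative doubleton set is smaller than ``min_doubletons``, or whose
    Bayes factor is undefined, are excluded from the summary.

    Returns a dict with the per-threshold ``curve`` DataFrame and summary
    statistics (max_abs_deviation, mean_deviation; deviation = inferred −
    true, so a negative mean is underestimation).
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(1, 2**31 - 1, size=cfg.n_replicates)
    counts = mutation_spectrum.MutationClassCounts()
    prof_d, prof_nd, points = [], [], []
    for i, rs in enumerate(rep_seeds):
        rep = replicates[i] if replicates is not None else None
        c, pd_, pnd_, pts = _pipeline_one_replicate(cfg, int(rs), n_max, rep=rep)
        counts = counts + c
        prof_d.extend(pd_)
        prof_nd.extend(pnd_)
        points.extend(pts)
    est = mutation_spectrum.estimate_prior_rcr(counts)
    prior = rcr_bayes.prior_from_estimate(est.proportion_recurrent)
    m = 2 * cfg.n_samples
    curve = rcr_bayes.posterior_curve(prof_d, prof_nd, prior, m, n_max=n_max)
    msc = np.array([p for p, _ in points])
    is_rcr = np.array([r for _, r in points])
    rows = []
    for row in curve.table.itertuples(index=False):
        sel = msc <= row.n
        n_in = int(sel.sum())
        true_frac = float(is_rcr[sel].mean()) if n_in else np.nan
        rows.append(
            {
                "n": row.n,
                "posterior_cum": row.posterior_cum,
                "true_rcr_fraction": true_frac,
                "n_doubletons": n_in,
            }
        )
    out = pd.DataFrame(rows)
    ok = (
        (out["n_doubletons"] >= min_doubletons)
        & np.isfinite(out["posterior_cum"])
        & np.isfinite(out["true_rcr_fraction"])
    )
    dev = out.loc[ok, "posterior_cum"] - out.loc[ok, "true_rcr_fraction"]
    return {
        "scenario": cfg.name,
        "curve": out,
        "prior_rcr": prior,
        "n_thresholds_compared": int(ok.sum()),
        "max_abs_deviation": float(dev.abs().max()) if ok.any() else np.nan,
        "mean_deviation": float(dev.mean()) if ok.any() else np.nan,
    }
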