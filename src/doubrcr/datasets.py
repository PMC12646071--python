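"""Published count tables usable as worked-example inputs.

The triallelic-singleton and doubleton counts below were tabulated from the
Anopheles gambiae 1000 Genomes (Ag1000G) Phase 2 AR1 release, chromosome
arm 3L (1,142 diploid individuals, m = 2,284 haploid genomes; 10,219,040
fully-called accessible sites).  They are the canonical worked example for
the recurrence estimator: feeding them through
:func:`doubrcr.mutation_spectrum.estimate_prior_rcr` reproduces the
published per-class recurrent-doubleton estimates.
"""

from .mutation_spectrum import MutationClassCounts

#: haploid sample size of the Ag1000G Phase 2 3L dataset
AG1000G_3L_HAPLOID_SIZE = 2284

#: fully-called accessible sites analyzed on 3L
AG1000G_3L_N_SITES = 10_219_040

#: N[X→Y,Z]: triallelic singleton sites by major allele and singleton pair
AG1000G_3L_TRIALLELIC = {
    ("A", ("C", "T")): 10_620,
    ("A", ("C", "G")): 8_649,
    ("A", ("G", "T")): 22_938,
    ("C", ("A", "T")): 46_232,
    ("C", ("A", "G")): 10_219,
    ("C", ("G", "T")): 23_806,
    ("G", ("A", "C")): 23_608,
    ("G", ("A", "T")): 45_742,
    ("G", ("C", "T")): 9_901,
    ("T", ("A", "C")): 22_846,
    ("T", ("A", "G")): 10_554,
    ("T", ("C", "G")): 8_553,
}

#: D[X→Y]: doubleton sites by major (ancestral) and doubleton allele
AG1000G_3L_DOUBLETONS = {
    ("A", "C"): 40_394,
    ("A", "G"): 92_019,
    ("A", "T"): 106_529,
    ("C", "A"): 69_276,
    ("C", "G"): 30_777,
    ("C", "T"): 219_184,
    ("G", "A"): 220_013,
    ("G", "C"): 30_621,
    ("G", "T"): 68_860,
    ("T", "A"): 107_488,
    ("T", "C"): 91_580,
    ("T", "G"): 40_229,
}


def ag1000g_3l_counts() -> MutationClassCounts:
    """The Ag1000G 3L count ledger (no genome base composition attached)."""
    return MutationClassCounts(
        triallelic={(x, tuple(sorted(p))): c for (x, p), c in AG1000G_3L_TRIALLELIC.items()},
        doubletons=dict(AG1000G_3L_DOUBLETONS),
    )
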