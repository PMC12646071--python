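"""Genotype tables, site filters, and allele-configuration classification.

This module reads multi-sample unphased diploid VCFs into an in-memory
:class:`GenotypeTable` and classifies every retained site by its allele-count
configuration: monomorphic, singleton, doubleton, triallelic singleton
(one major base plus two *different* bases each seen once), or other
polymorphic.  The major (most frequent) allele at a site is taken as the
ancestral state throughout; no outgroup polarization is attempted.

Coordinates are 1-based inclusive, as in VCF.  BED inputs (accessibility
masks) are 0-based half-open and converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

KIND_MONOMORPHIC = "monomorphic"
KIND_SINGLETON = "singleton"
KIND_DOUBLETON = "doubleton"
KIND_TRIALLELIC_SINGLETON = "triallelic_singleton"
KIND_OTHER = "other_polymorphic"
SITE_KINDS = (
    KIND_MONOMORPHIC,
    KIND_SINGLETON,
    KIND_DOUBLETON,
    KIND_TRIALLELIC_SINGLETON,
    KIND_OTHER,
)


class UnsortedVCFError(ValueError):
    """Raised when site positions do not increase along the contig."""


@dataclass
class GenotypeTable:
    """Per-site diploid genotypes for all samples on one contig.

    Attributes
    ----------
    contig : str
        Contig / chromosome-arm identifier.
    positions : numpy.ndarray of int64
        1-based site coordinates, strictly increasing.
    sample_ids : list of str
        Ordered diploid sample identifiers.
    genotypes : numpy.ndarray of int8, shape (n_sites, n_samples, 2)
        Unordered pairs of per-site allele indices (no phase information).
        After filtering there are no missing calls.
    alleles : list of tuple of str
        Per-site bases; the VCF REF is first, followed by ALTs.
    """

    contig: str
    positions: np.ndarray
    sample_ids: list
    genotypes: np.ndarray
    alleles: list

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (n_sites, n_samples, 2)")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise UnsortedVCFError(f"positions not strictly increasing on {self.contig}")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    @property
    def haploid_size(self) -> int:
        """m, the number of haploid genomes (2 per diploid sample)."""
        return 2 * self.n_samples

    def site_base_counts(self, i: int) -> dict:
        """Haploid count of each observed base at site ``i``."""
        alleles = self.alleles[i]
        counts = np.bincount(self.genotypes[i].ravel(), minlength=len(alleles))
        return {alleles[k]: int(counts[k]) for k in range(len(alleles)) if counts[k] > 0}

    def take(self, idx) -> "GenotypeTable":
        """New table restricted to the site indices ``idx`` (order preserved)."""
        idx = np.asarray(idx)
        return GenotypeTable(
            contig=self.contig,
            positions=self.positions[idx],
            sample_ids=list(self.sample_ids),
            genotypes=self.genotypes[idx],
            alleles=[self.alleles[k] for k in idx],
        )


def allele_count_matrix(gt: GenotypeTable) -> np.ndarray:
    """Haploid allele counts, shape (n_sites, max alleles per site).

    Column ``a`` holds the count of allele index ``a`` at each site (0 where
    the site has fewer alleles).
    """
    n_alleles = max((len(a) for a in gt.alleles), default=1)
    counts = np.zeros((gt.n_sites, n_alleles), dtype=np.int32)
    for a in range(n_alleles):
        counts[:, a] = (gt.genotypes == a).sum(axis=(1, 2))
    return counts


def read_bed_mask(path) -> list:
    """Read a BED accessibility mask into a list of (start, end) 1-based
    inclusive intervals."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            start, end = int(parts[1]), int(parts[2])
            intervals.append((start + 1, end))  # BED is 0-based half-open
    return sorted(intervals)


def _mask_arrays(intervals):
    starts = np.array([a for a, _ in intervals], dtype=np.int64)
    ends = np.array([b for _, b in intervals], dtype=np.int64)
    return starts, ends


def _in_mask(pos: int, starts, ends) -> bool:
    k = np.searchsorted(starts, pos, side="right") - 1
    return k >= 0 and pos <= ends[k]


def load_vcf(path, contig: str, site_mask=None) -> GenotypeTable:
    """Read one contig of a multi-sample VCF into a :class:`GenotypeTable`.

    Applies the site filters used throughout: only SNP records are kept
    (indels and other non-SNPs are skipped with a logged count), any site
    with a missing genotype in any sample is dropped, and — when
    ``site_mask`` is given (a BED path or a list of 1-based inclusive
    ``(start, end)`` intervals) — only sites inside the mask are retained.
    Multiallelic SNPs are kept so that triallelic singleton sites can be
    counted.

    Raises
    ------
    UnsortedVCFError
        If positions do not increase along the contig.
    ValueError
        If the contig has no records in the VCF.
    """
    from cyvcf2 import VCF

    if site_mask is not None and not isinstance(site_mask, (list, tuple)):
        site_mask = read_bed_mask(site_mask)
    mask_arr = _mask_arrays(site_mask) if site_mask else None

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    positions, genos, alleles = [], [], []
    n_skipped_nonsnp = n_missing = n_masked = n_dup = 0
    last_pos = -1
    found_contig = False
    for rec in vcf:
        if rec.CHROM != contig:
            continue
        found_contig = True
        pos = rec.POS
        if pos < last_pos:
            raise UnsortedVCFError(f"unsorted VCF at {contig}:{pos}")
        if pos == last_pos:
            n_dup += 1
            continue
        allele_set = [rec.REF] + list(rec.ALT)
        if any(len(a) != 1 or a not in BASES for a in allele_set):
            n_skipped_nonsnp += 1
            continue
        last_pos = pos
        if mask_arr is not None and not _in_mask(pos, *mask_arr):
            n_masked += 1
            continue
        g = np.array(rec.genotypes, dtype=np.int64)[:, :2]
        if np.any(g < 0):
            n_missing += 1
            continue
        positions.append(pos)
        genos.append(g.astype(np.int8))
        alleles.append(tuple(allele_set))
    if not found_contig:
        raise ValueError(f"contig {contig!r} has no records in {path}")
    if n_skipped_nonsnp or n_missing or n_masked or n_dup:
        logger.info(
            "load_vcf %s:%s — skipped %d non-SNP, %d with missing genotypes, "
            "%d outside mask, %d duplicate-position records",
            path, contig, n_skipped_nonsnp, n_missing, n_masked, n_dup,
        )
    gmat = (
        np.stack(genos) if genos
        else np.empty((0, len(sample_ids), 2), dtype=np.int8)
    )
    return GenotypeTable(
        contig=contig,
        positions=np.array(positions, dtype=np.int64),
        sample_ids=sample_ids,
        genotypes=gmat,
        alleles=alleles,
    )


def write_vcf(gt: GenotypeTable, path) -> None:
    """Write a table back out as a minimal unphased multi-sample VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={gt.contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in gt.sample_ids)
            + "\n"
        )
        for i in range(gt.n_sites):
            ref = gt.alleles[i][0]
            alts = gt.alleles[i][1:]
            alt_field = ",".join(alts) if alts else "."
            gts = "\t".join(
                f"{a}/{b}" for a, b in gt.genotypes[i]
            )
            fh.write(
                f"{gt.contig}\t{gt.positions[i]}\t.\t{ref}\t{alt_field}\t.\tPASS\t.\tGT\t"
                + gts + "\n"
            )


def classify_sites(gt: GenotypeTable) -> pd.DataFrame:
    """Assign every site exactly one allele-configuration kind.

    The major allele (strict plurality of haploid counts; ties are classed
    ``other_polymorphic``) stands in for the ancestral state.  Kinds:

    - ``singleton``: one non-major base at haploid count 1;
    - ``doubleton``: one non-major base at haploid count 2.  The two carrier
      samples are recorded; a doubleton carried as a single homozygote is
      flagged (``single_homozygote``) for exclusion from haplotype scans;
    - ``triallelic_singleton``: two distinct non-major bases, each count 1;
    - ``monomorphic`` / ``other_polymorphic`` otherwise.

    Returns a DataFrame with one row per site: ``site_index``, ``pos``,
    ``kind``, ``major``, ``minor_bases`` ("," joined), ``minor_counts``,
    ``carrier_a``/``carrier_b`` (sample indices for doubletons, else -1)
    and ``single_homozygote``.
    """
    cols = [
        "site_index", "pos", "kind", "major", "minor_bases", "minor_counts",
        "carrier_a", "carrier_b", "single_homozygote",
    ]
    if gt.n_sites == 0:
        return pd.DataFrame(columns=cols)
    G = gt.genotypes
    counts = allele_count_matrix(gt)
    n_alleles = counts.shape[1]
    # sort allele indices per site by descending count (stable: ties keep
    # the lower allele index, i.e. the REF-first VCF order)
    order = np.argsort(-counts, axis=1, kind="stable")
    ordered = np.take_along_axis(counts, order, axis=1)
    n_obs = (counts > 0).sum(axis=1)
    cmax = ordered[:, 0]
    second = ordered[:, 1] if n_alleles > 1 else np.zeros(len(counts), dtype=counts.dtype)
    third = ordered[:, 2] if n_alleles > 2 else np.zeros(len(counts), dtype=counts.dtype)
    tie = (n_obs > 1) & (second == cmax)

    kind = np.full(gt.n_sites, KIND_OTHER, dtype=object)
    kind[n_obs == 1] = KIND_MONOMORPHIC
    kind[~tie & (n_obs == 2) & (second == 1)] = KIND_SINGLETON
    kind[~tie & (n_obs == 2) & (second == 2)] = KIND_DOUBLETON
    kind[~tie & (n_obs == 3) & (second == 1) & (third == 1)] = KIND_TRIALLELIC_SINGLETON

    major = [gt.alleles[i][order[i, 0]] for i in range(gt.n_sites)]
    minor_bases = []
    minor_counts = []
    for i in range(gt.n_sites):
        ks = [k for k in order[i, 1:] if counts[i, k] > 0]
        minor_bases.append(",".join(gt.alleles[i][k] for k in ks))
        minor_counts.append(",".join(str(counts[i, k]) for k in ks))

    ca = np.full(gt.n_sites, -1, dtype=np.int64)
    cb = np.full(gt.n_sites, -1, dtype=np.int64)
    single_hom = np.zeros(gt.n_sites, dtype=bool)
    for i in np.flatnonzero(kind == KIND_DOUBLETON):
        aidx = order[i, 1]
        hits = np.flatnonzero((G[i] == aidx).any(axis=1))
        if len(hits) == 1:
            ca[i] = cb[i] = hits[0]
            single_hom[i] = True
        else:
            ca[i], cb[i] = hits[0], hits[1]

    return pd.DataFrame(
        {
            "site_index": np.arange(gt.n_sites),
            "pos": gt.positions,
            "kind": kind,
            "major": major,
            "minor_bases": minor_bases,
            "minor_counts": minor_counts,
            "carrier_a": ca,
            "carrier_b": cb,
            "single_homozygote": single_hom,
        }
    )


def restrict_biallelic(gt: GenotypeTable) -> GenotypeTable:
    """Sites with exactly two *observed* bases (the haplotype-scan substrate).

    The input table is untouched.  Note the criterion is on observed bases,
    not on the VCF ALT list: a triallelic record where one alternate was
    never called is biallelic in practice.
    """
    counts = allele_count_matrix(gt)
    keep = np.flatnonzero((counts > 0).sum(axis=1) == 2)
    return gt.take(keep)


def classification_to_tsv(classes: pd.DataFrame, gt: GenotypeTable, path) -> None:
    """Write the per-site classification with carrier sample ids."""
    out = classes.copy()
    out.insert(0, "contig", gt.contig)
    ids = np.array([str(s) for s in gt.sample_ids])

    def _name(ix):
        return ids[ix] if ix >= 0 else "."

    out["carrier_a"] = out["carrier_a"].map(_name)
    out["carrier_b"] = out["carrier_b"].map(_name)
    out.to_csv(path, sep="\t", index=False)
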