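"""Shared-segment detection around focal sites on unphased genotypes.

Two diploid individuals that are identical by descent around a focal site
cannot be homozygous for *different* alleles anywhere inside the shared
tract.  The scan therefore walks outward from the focal site in both
directions over the biallelic-restricted site table until it meets an
"inconsistent homozygote" site — one individual hom-ref, the other hom-alt.
Those two flanking positions bound the candidate shared segment; its length
is simply their coordinate difference (which overcounts by the two boundary
sites, a deliberate bit-compatibility choice with the difference-of-positions
definition).  Heterozygous sites never terminate a scan.  Scans that reach
a contig end are discarded and counted.

For every eligible doubleton (two distinct carriers; doubletons carried as
a single homozygote are excluded) one segment is produced; a matched
"random" segment is produced from the same focal position for a seeded
random pair of non-carriers.  Segments are deduplicated on
(pair, left bound, right bound), keeping the list of focal doubletons a
segment carries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import KIND_DOUBLETON, GenotypeTable

logger = logging.getLogger(__name__)


class ContigEndError(ValueError):
    """Scan reached a contig end before finding an inconsistent homozygote."""


@dataclass
class PairSegment:
    """A shared haplotype segment between two individuals around a focal site.

    Bounds are the positions of the two flanking inconsistent-homozygote
    sites themselves (1-based); every retained biallelic site strictly
    between them is consistent for the pair.  ``kind`` is "doubleton" or
    "random"; ``focal_positions``/``focal_classes`` list every focal
    doubleton the (deduplicated) segment carries.
    """

    contig: str
    focal_pos: int
    sample_a: int
    sample_b: int
    left_bound: int
    right_bound: int
    kind: str
    focal_class: str | None = None
    focal_positions: list = field(default_factory=list)
    focal_classes: list = field(default_factory=list)

    def __post_init__(self):
        if not (self.left_bound < self.focal_pos < self.right_bound):
            raise ValueError("focal position must lie strictly inside the bounds")
        if not self.focal_positions:
            self.focal_positions = [self.focal_pos]
        if not self.focal_classes and self.focal_class is not None:
            self.focal_classes = [self.focal_class]

    @property
    def length(self) -> int:
        return int(self.right_bound - self.left_bound)

    @property
    def segment_id(self) -> tuple:
        a, b = sorted((self.sample_a, self.sample_b))
        return (a, b, int(self.left_bound), int(self.right_bound))

    @property
    def n_doubletons(self) -> int:
        return len(self.focal_positions)


def _alt_dosage(gt: GenotypeTable) -> np.ndarray:
    """Per-site dosage (0/1/2) of the second observed allele, biallelic sites.

    Opposite homozygotes differ in dosage by exactly 2, whichever of the two
    observed alleles is used as the reference point.
    """
    from .genotypes import allele_count_matrix

    counts = allele_count_matrix(gt)
    observed = counts > 0
    if np.any(observed.sum(axis=1) != 2):
        raise ValueError("scan substrate must be biallelic-restricted")
    # the higher observed allele index per site; dosage differences of 2
    # identify opposite homozygotes whichever of the two alleles is used
    n_alleles = counts.shape[1]
    alt = (n_alleles - 1) - np.argmax(observed[:, ::-1], axis=1)
    return (gt.genotypes == alt[:, None, None]).sum(axis=2, dtype=np.int8)


class SegmentScanner:
    """Reusable scanner over one biallelic genotype table."""

    def __init__(self, gt: GenotypeTable):
        if gt.n_sites == 0:
            raise ValueError("cannot scan an empty (no biallelic sites) table")
        self.gt = gt
        self.dosage = _alt_dosage(gt)

    def scan(self, focal_pos: int, sample_a: int, sample_b: int) -> PairSegment:
        """Bound the shared segment of a sample pair around ``focal_pos``.

        Raises :class:`ContigEndError` if no inconsistent homozygote site
        exists on either side (the segment would run off the contig).
        """
        if sample_a == sample_b:
            raise ValueError("pair must be two distinct samples")
        pos = self.gt.positions
        fi = np.searchsorted(pos, focal_pos)
        if fi >= len(pos) or pos[fi] != focal_pos:
            # focal site need not be in the biallelic table (e.g. a
            # triallelic focal); fi is then the insertion index
            fi_left, fi_right = fi - 1, fi
        else:
            fi_left, fi_right = fi - 1, fi + 1
        incons = np.abs(
            self.dosage[:, sample_a].astype(np.int16)
            - self.dosage[:, sample_b].astype(np.int16)
        ) == 2
        left_hits = np.flatnonzero(incons[: fi_left + 1])
        right_hits = np.flatnonzero(incons[fi_right:])
        if len(left_hits) == 0 or len(right_hits) == 0:
            raise ContigEndError(
                f"scan from {self.gt.contig}:{focal_pos} reached a contig end"
            )
        left = int(pos[left_hits[-1]])
        right = int(pos[fi_right + right_hits[0]])
        return PairSegment(
            contig=self.gt.contig,
            focal_pos=int(focal_pos),
            sample_a=int(sample_a),
            sample_b=int(sample_b),
            left_bound=left,
            right_bound=right,
            kind="doubleton",
        )


def scan_segment(gt: GenotypeTable, focal_pos: int, pair) -> PairSegment:
    """One-off scan; see :meth:`SegmentScanner.scan`."""
    return SegmentScanner(gt).scan(focal_pos, *pair)


def _dedup(segments) -> list:
    merged = {}
    for seg in segments:
        key = seg.segment_id
        if key in merged:
            merged[key].focal_positions.extend(seg.focal_positions)
            merged[key].focal_classes.extend(seg.focal_classes)
        else:
            merged[key] = seg
    return list(merged.values())


def doubleton_segments(gt_biallelic: GenotypeTable, site_classes: pd.DataFrame):
    """Scan every eligible doubleton; return (unique segments, discard stats).

    Eligible doubletons have two distinct carrier samples.  Segments are
    deduplicated on (pair, bounds); a unique segment may carry several
    doubletons.  ``stats`` counts contig-end discards and single-homozygote
    exclusions.
    """
    scanner = SegmentScanner(gt_biallelic)
    doub = site_classes[site_classes["kind"] == KIND_DOUBLETON]
    raw = []
    stats = {"contig_end_discarded": 0, "single_homozygote_excluded": 0, "scanned": 0}
    for row in doub.itertuples(index=False):
        if row.single_homozygote:
            stats["single_homozygote_excluded"] += 1
            continue
        stats["scanned"] += 1
        try:
            seg = scanner.scan(row.pos, row.carrier_a, row.carrier_b)
        except ContigEndError:
            stats["contig_end_discarded"] += 1
            continue
        seg.focal_class = f"{row.major}>{row.minor_bases}"
        seg.focal_classes = [seg.focal_class]
        raw.append(seg)
    return _dedup(raw), stats


def random_pair_segments(
    gt_biallelic: GenotypeTable, site_classes: pd.DataFrame, seed: int
):
    """Matched random-pair segments: at each eligible doubleton focal site,
    scan from the same position for a seeded uniform pair of non-carriers.

    The same non-carrier pair may recur across focal sites (sampling is with
    replacement across sites, without replacement within a site).
    """
    scanner = SegmentScanner(gt_biallelic)
    rng = np.random.default_rng(seed)
    n = gt_biallelic.n_samples
    doub = site_classes[site_classes["kind"] == KIND_DOUBLETON]
    raw = []
    stats = {"contig_end_discarded": 0, "too_few_noncarriers": 0, "scanned": 0}
    for row in doub.itertuples(index=False):
        if row.single_homozygote:
            continue
        carriers = {row.carrier_a, row.carrier_b}
        pool = [i for i in range(n) if i not in carriers]
        if len(pool) < 2:
            stats["too_few_noncarriers"] += 1
            logger.info("fewer than 2 non-carriers at %s; skipped", row.pos)
            continue
        a, b = rng.choice(pool, size=2, replace=False)
        stats["scanned"] += 1
        try:
            seg = scanner.scan(row.pos, int(a), int(b))
        except ContigEndError:
            stats["contig_end_discarded"] += 1
            continue
        seg.kind = "random"
        raw.append(seg)
    return _dedup(raw), stats


def segments_to_frame(segments, sample_ids=None) -> pd.DataFrame:
    """Tabulate segments (TSV-ready; 1-based inclusive bounds)."""
    rows = []
    for s in segments:
        a, b = s.sample_a, s.sample_b
        rows.append(
            {
                "contig": s.contig,
                "focal_positions": ",".join(str(p) for p in s.focal_positions),
                "sample_a": sample_ids[a] if sample_ids is not None else a,
                "sample_b": sample_ids[b] if sample_ids is not None else b,
                "left_bound": s.left_bound,
                "right_bound": s.right_bound,
                "length": s.length,
                "kind": s.kind,
                "n_doubletons": s.n_doubletons,
                "focal_classes": ",".join(s.focal_classes),
            }
        )
    return pd.DataFrame(rows)


def frame_to_segments(df: pd.DataFrame, sample_ids=None) -> list:
    """Rebuild :class:`PairSegment` objects from a segment table.

    ``sample_ids`` maps the table's sample columns back to indices when the
    table was written with names.
    """
    index = {str(s): i for i, s in enumerate(sample_ids)} if sample_ids is not None else None
    segs = []
    for row in df.itertuples(index=False):
        a = index[str(row.sample_a)] if index else int(row.sample_a)
        b = index[str(row.sample_b)] if index else int(row.sample_b)
        focal = [int(p) for p in str(row.focal_positions).split(",")]
        classes = (
            str(row.focal_classes).split(",")
            if isinstance(row.focal_classes, str) and row.focal_classes
            else []
        )
        segs.append(
            PairSegment(
                contig=row.contig,
                focal_pos=focal[0],
                sample_a=a,
                sample_b=b,
                left_bound=int(row.left_bound),
                right_bound=int(row.right_bound),
                kind=row.kind,
                focal_positions=focal,
                focal_classes=classes,
            )
        )
    return segs


def segments_to_bed(segments, path) -> None:
    """BED export (0-based half-open) of segment intervals."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.contig}\t{s.left_bound - 1}\t{s.right_bound}\t{s.kind}\n")
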