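"""Allele counting at known SNP sites from aligned reads.

Counts, for every SNP site, the number of aligned reads supporting the
reference allele, the alternative allele, or any other base.  Reads are
scanned sequentially, so plain SAM works as well as indexed BAM.  Bases are
resolved through the CIGAR string: soft-clipped bases, deletions and splice
gaps (CIGAR D/N) spanning a site contribute nothing.

Duplicate reads are intentionally not removed — PCR amplification bias is
handled downstream by the compound binomial model rather than by
deduplication — and overlapping mates of a pair both count.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd
import pysam

from .variant_io import SnpSite, normalize_chrom

__all__ = [
    "AlleleCount",
    "count_alleles",
    "filter_by_coverage",
    "write_counts_tsv",
    "read_counts_tsv",
    "COUNTS_COLUMNS",
]

logger = logging.getLogger(__name__)

COUNTS_COLUMNS = ["chrom", "pos", "snp_id", "ref", "alt", "n_ref", "n_alt", "n_other"]


@dataclass
class AlleleCount:
    """Observed read support at one SNP site."""

    site: SnpSite
    n_ref: int = 0
    n_alt: int = 0
    n_other: int = 0

    @property
    def depth(self) -> int:
        return self.n_ref + self.n_alt + self.n_other

    @property
    def informative_depth(self) -> int:
        """Reads carrying either of the two SNP alleles (the model's N)."""
        return self.n_ref + self.n_alt

    @property
    def ref_fraction(self) -> float | None:
        """n_ref / (n_ref + n_alt), or None when no informative reads."""
        inf = self.informative_depth
        return self.n_ref / inf if inf > 0 else None


def count_alleles(
    bam_path: str | Path,
    sites: Sequence[SnpSite],
    min_mapq: int = 0,
    min_baseq: int = 0,
) -> list[AlleleCount]:
    """Enumerate ref/alt/other base support at each site.

    The alignment file is scanned once; each primary aligned read
    contributes at most one base per overlapping site.  Sites on
    chromosomes absent from the header receive depth-0 counts with a
    logged warning.

    Parameters
    ----------
    bam_path : path
        SAM or BAM file; no index required.
    sites : sequence of SnpSite
        Sites to interrogate, sorted by (chrom, pos).
    min_mapq, min_baseq : int
        Minimum mapping / base quality for a read or base to count.
        Defaults are 0 (no filtering); reads with no quality string pass
        the base-quality filter.
    """
    counts = [AlleleCount(site=s) for s in sites]

    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for i, site in enumerate(sites):
        positions, idxs = by_chrom.setdefault(normalize_chrom(site.chrom), ([], []))
        positions.append(site.pos)
        idxs.append(i)

    mode = "r" if str(bam_path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(bam_path), mode, check_sq=False) as af:
        header_chroms = {normalize_chrom(r) for r in af.references}
        missing = set(by_chrom) - header_chroms
        if missing:
            logger.warning(
                "chromosomes %s carry SNP sites but are absent from %s; "
                "their sites get depth 0",
                sorted(missing),
                bam_path,
            )
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            chrom_key = normalize_chrom(read.reference_name)
            entry = by_chrom.get(chrom_key)
            if entry is None:
                continue
            positions, idxs = entry
            # candidate sites overlapping the reference span of this read
            lo = bisect.bisect_left(positions, read.reference_start + 1)
            hi = bisect.bisect_right(positions, read.reference_end)
            if lo == hi:
                continue
            aligned = {
                rpos: qpos
                for qpos, rpos in read.get_aligned_pairs(matches_only=True)
            }
            seq = read.query_sequence
            quals = read.query_qualities
            for j in range(lo, hi):
                qpos = aligned.get(positions[j] - 1)  # pysam ref coords are 0-based
                if qpos is None:
                    continue
                if quals is not None and quals[qpos] < min_baseq:
                    continue
                base = seq[qpos].upper()
                count = counts[idxs[j]]
                if base == count.site.ref_allele:
                    count.n_ref += 1
                elif base == count.site.alt_allele:
                    count.n_alt += 1
                else:
                    count.n_other += 1
    return counts


def filter_by_coverage(counts: Iterable[AlleleCount], min_depth: int = 20) -> list[AlleleCount]:
    """Keep sites whose informative depth (n_ref + n_alt) is >= min_depth.

    The default of 20 retains only well-covered sites; the boundary is
    inclusive.  The informative depth excludes n_other because the model's
    read count N is defined over the two SNP alleles.
    """
    if min_depth < 1:
        raise ValueError(f"min_depth must be >= 1, got {min_depth}")
    return [c for c in counts if c.informative_depth >= min_depth]


def write_counts_tsv(counts: Iterable[AlleleCount], path: str | Path | TextIO) -> None:
    """Write the tab-separated counts table (the pipeline's interchange format)."""
    rows = [
        (
            c.site.chrom,
            c.site.pos,
            c.site.snp_id,
            c.site.ref_allele,
            c.site.alt_allele,
            c.n_ref,
            c.n_alt,
            c.n_other,
        )
        for c in counts
    ]
    df = pd.DataFrame(rows, columns=COUNTS_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path | TextIO) -> list[AlleleCount]:
    """Read a counts table written by :func:`write_counts_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str}, keep_default_na=False)
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table {path} lacks columns {sorted(missing)}")
    counts = []
    for row in df.itertuples(index=False):
        site = SnpSite(
            chrom=row.chrom,
            pos=int(row.pos),
            ref_allele=row.ref,
            alt_allele=row.alt,
            snp_id=str(row.snp_id),
        )
        counts.append(
            AlleleCount(site=site, n_ref=int(row.n_ref), n_alt=int(row.n_alt), n_other=int(row.n_other))
        )
    return counts
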