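"""Reading and filtering of SNP variant and exon annotation files.

The downstream allele-counting and QC steps operate on a list of known
biallelic exonic SNPs.  This module loads candidate sites from a VCF
(dbSNP-style, optionally carrying genotype columns for inbred strains),
builds a queryable exon index from a GTF, and restricts the site list to
exonic positions.

All public coordinates are 1-based, matching VCF/GTF conventions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from intervaltree import IntervalTree

__all__ = [
    "SnpSite",
    "ExonIndex",
    "VcfParseError",
    "StrainNotFoundError",
    "EmptyAnnotationError",
    "load_snps",
    "build_exon_index",
    "filter_exonic",
    "normalize_chrom",
]

_BASES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Raised when a VCF file cannot be parsed."""


class StrainNotFoundError(KeyError):
    """Raised when a requested strain sample is absent from the VCF header."""


class EmptyAnnotationError(ValueError):
    """Raised when a GTF contains no exon features."""


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix so that ``chr8`` and ``8`` compare equal.

    VCF and GTF sources frequently disagree on the prefix; all internal
    chromosome keys go through this function.
    """
    return name[3:] if name.startswith("chr") else name


@dataclass(frozen=True)
class SnpSite:
    """One known biallelic SNP.

    Attributes
    ----------
    chrom : str
        Chromosome name as given in the source file.
    pos : int
        1-based genomic coordinate.
    ref_allele, alt_allele : str
        The two single-base alleles; the reference allele corresponds to
        the reference-strain (e.g. B6) genotype in dbSNP-style inputs.
    strain_genotypes : mapping
        strain name -> allele pair, e.g. ``{"B6": ("A", "A")}``.  Strains
        with missing genotypes at this site are omitted.
    snp_id : str
        dbSNP-style identifier; may be empty.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    strain_genotypes: Mapping[str, tuple[str, str]] = field(default_factory=dict)
    snp_id: str = ""

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles are identical at {self.chrom}:{self.pos}")
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(f"non-ACGT allele at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for strain, pair in self.strain_genotypes.items():
            for allele in pair:
                if allele not in (self.ref_allele, self.alt_allele):
                    raise ValueError(
                        f"strain {strain} carries allele {allele!r} which is neither "
                        f"ref nor alt at {self.chrom}:{self.pos}"
                    )


_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


class ExonIndex:
    """Point-in-exon membership queries over merged per-gene exon intervals."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self.n_exons = 0

    def _add_merged(self, chrom: str, gene_id: str, intervals: list[tuple[int, int]]) -> None:
        tree = self._trees.setdefault(normalize_chrom(chrom), IntervalTree())
        intervals.sort()
        cur_start, cur_end = intervals[0]
        merged = []
        for start, end in intervals[1:]:
            if start <= cur_end + 1:
                cur_end = max(cur_end, end)
            else:
                merged.append((cur_start, cur_end))
                cur_start, cur_end = start, end
        merged.append((cur_start, cur_end))
        for start, end in merged:
            # intervaltree is half-open; store [start, end+1) for 1-based inclusive ends
            tree.addi(start, end + 1, gene_id)
            self.n_exons += 1

    def contains(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(normalize_chrom(chrom))
        return bool(tree is not None and tree.overlaps_point(pos))

    def gene_at(self, chrom: str, pos: int) -> str | None:
        """Gene id of an exon covering (chrom, pos), or None.

        When exons of several genes overlap the position, the
        lexicographically smallest gene id is returned so the query is
        deterministic.
        """
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return None
        hits = tree[pos]
        if not hits:
            return None
        return min(iv.data for iv in hits)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._trees)


def load_snps(vcf_path: str | Path, strains: Sequence[str] = ()) -> list[SnpSite]:
    """Load biallelic SNPs from a VCF, optionally with per-strain genotypes.

    Multi-allelic records and indels are dropped.  Genotypes follow standard
    VCF semantics: ``0/0`` -> (ref, ref), ``1/1`` -> (alt, alt), ``0/1`` or
    ``1/0`` -> (ref, alt); a missing genotype omits the strain at that site.

    Parameters
    ----------
    vcf_path : path
        VCF v4.x file, plain or bgzip-compressed.
    strains : sequence of str
        Sample names whose genotypes to retain.  Default: none
        (genotype-free mode).

    Raises
    ------
    StrainNotFoundError
        If a requested strain is not a sample column of the VCF.
    VcfParseError
        If the file cannot be parsed as VCF.
    """
    vcf_path = str(vcf_path)
    try:
        vf = pysam.VariantFile(vcf_path)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF {vcf_path}: {exc}") from exc

    header_samples = set(vf.header.samples)
    for strain in strains:
        if strain not in header_samples:
            raise StrainNotFoundError(
                f"strain {strain!r} is not a sample of {vcf_path}; "
                f"available: {sorted(header_samples)}"
            )

    sites: list[SnpSite] = []
    try:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            if ref not in _BASES or alt not in _BASES:
                continue
            genotypes: dict[str, tuple[str, str]] = {}
            for strain in strains:
                gt = rec.samples[strain].get("GT")
                if gt is None or any(a is None for a in gt) or len(gt) != 2:
                    continue
                alleles = tuple(sorted(ref if a == 0 else alt for a in gt))
                genotypes[strain] = alleles  # type: ignore[assignment]
            sites.append(
                SnpSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    strain_genotypes=genotypes,
                    snp_id=rec.id or "",
                )
            )
    except (ValueError, OSError) as exc:
        raise VcfParseError(
            f"malformed record in {vcf_path} after {len(sites)} parsed sites: {exc}"
        ) from exc
    return sites


def build_exon_index(gtf_path: str | Path) -> ExonIndex:
    """Build an :class:`ExonIndex` from the exon features of a GTF file.

    Overlapping or adjacent exons of the same gene are merged, so membership
    queries are insensitive to transcript redundancy.  Strand is ignored:
    allele counting is strand-agnostic.

    Raises
    ------
    EmptyAnnotationError
        If the GTF has no exon features.
    """
    per_gene: dict[tuple[str, str], list[tuple[int, int]]] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise VcfParseError(f"{gtf_path} line {lineno}: expected 9 columns, got {len(fields)}")
            if fields[2] != "exon":
                continue
            chrom, start, end, attrs = fields[0], int(fields[3]), int(fields[4]), fields[8]
            m = _GENE_ID_RE.search(attrs)
            gene_id = m.group(1) if m else f"__anon_{lineno}"
            per_gene.setdefault((chrom, gene_id), []).append((start, end))

    if not per_gene:
        raise EmptyAnnotationError(f"no exon features found in {gtf_path}")

    index = ExonIndex()
    for (chrom, gene_id), intervals in per_gene.items():
        index._add_merged(chrom, gene_id, intervals)
    return index


def filter_exonic(sites: Iterable[SnpSite], index: ExonIndex) -> list[SnpSite]:
    """Keep sites whose position falls inside any exon; order preserved."""
    return [s for s in sites if index.contains(s.chrom, s.pos)]
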