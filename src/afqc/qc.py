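"""Sample-level quality control: genotype calls, chromosome screening, reports.

A sample heterozygous at its informative SNPs should show an allele-
frequency peak near 50% on every autosome.  A chromosome whose peak sits
elsewhere (e.g. ~33% or ~67%) indicates unequal haplotype dosage —
trisomy or other aneuploidy — while a genome-wide shift points to
contamination by cells of a different genotype.  Distributions built from
fewer than about a thousand SNPs are too noisy to call, so such
chromosomes are flagged as low-SNP and never marked skewed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

from .afmodel import estimate_contamination, find_peak, histogram
from .pileup import AlleleCount
from .variant_io import SnpSite

__all__ = ["GenotypeCall", "ChromosomeReport", "call_genotypes", "per_chromosome_screen", "qc_report"]

HOM_REF = "hom_ref"
HOM_ALT = "hom_alt"
HET = "het"


@dataclass
class GenotypeCall:
    site: SnpSite
    call: str  # one of hom_ref / hom_alt / het
    ref_fraction: float
    informative_depth: int


@dataclass
class ChromosomeReport:
    chrom: str
    n_snps: int
    peak_pct: float | None
    skew_flag: bool
    inferred_copy_ratio: float | None
    low_snp_warning: bool


def call_genotypes(counts: Iterable[AlleleCount], hom_threshold: float = 0.95) -> list[GenotypeCall]:
    """Classify each covered site as homozygous or heterozygous.

    A site is called homozygous for an allele when that allele accounts
    for at least ``hom_threshold`` of the informative reads (default 95%,
    boundary inclusive); anything in between is heterozygous.  Sites with
    no informative reads are skipped.
    """
    if not 0.5 < hom_threshold <= 1.0:
        raise ValueError(f"hom_threshold must be in (0.5, 1], got {hom_threshold}")
    calls = []
    for c in counts:
        frac = c.ref_fraction
        if frac is None:
            continue
        if frac >= hom_threshold:
            call = HOM_REF
        elif frac <= 1.0 - hom_threshold:
            call = HOM_ALT
        else:
            call = HET
        calls.append(
            GenotypeCall(site=c.site, call=call, ref_fraction=frac, informative_depth=c.informative_depth)
        )
    return calls


def per_chromosome_screen(
    counts: Sequence[AlleleCount],
    min_snps_per_chrom: int = 1000,
    skew_tolerance_pct: float = 10.0,
    bin_width_pct: float = 1.0,
    search_lo_pct: float = 5.0,
    search_hi_pct: float = 95.0,
    smooth_window_bins: int = 15,
) -> list[ChromosomeReport]:
    """Screen each chromosome's allele-frequency peak for dosage skew.

    Per chromosome, the reference-allele fractions of all covered sites
    are histogrammed and the smoothed-mode peak located inside
    [search_lo_pct, search_hi_pct] (excluding the homozygote peaks at
    0/100%).  ``skew_flag`` is raised when the peak deviates from 50% by
    more than ``skew_tolerance_pct`` points and the chromosome is not
    low-SNP.  ``inferred_copy_ratio`` = peak/(100-peak) estimates the
    reference:alternative haplotype dosage — 1 for a balanced diploid,
    ~0.5 when the alternative haplotype is duplicated.

    The default smoothing window here (15 bins) is wider than the display
    default (5): at fixed read depth the allele fractions live on a k/N
    lattice, and with realistic PCR bias the per-chromosome distribution
    is nearly flat around its mode, so the few-thousand-SNP mode estimate
    needs heavier averaging to keep the skew call's false-positive rate
    negligible without affecting the diploid/trisomy separation.
    """
    by_chrom: dict[str, list[AlleleCount]] = {}
    for c in counts:
        by_chrom.setdefault(c.site.chrom, []).append(c)

    reports = []
    for chrom in sorted(by_chrom):
        chrom_counts = by_chrom[chrom]
        dist = histogram(chrom_counts, bin_width_pct=bin_width_pct, scope=chrom)
        peak = find_peak(dist, search_lo_pct, search_hi_pct, smooth_window_bins)
        n_snps = dist.n_snps
        low = n_snps < min_snps_per_chrom
        skew = peak is not None and abs(peak - 50.0) > skew_tolerance_pct and not low
        ratio = peak / (100.0 - peak) if peak is not None and 0.0 < peak < 100.0 else None
        reports.append(
            ChromosomeReport(
                chrom=chrom,
                n_snps=n_snps,
                peak_pct=peak,
                skew_flag=skew,
                inferred_copy_ratio=ratio,
                low_snp_warning=low,
            )
        )
    return reports


def qc_report(
    counts: Sequence[AlleleCount],
    calls: Sequence[GenotypeCall],
    chrom_reports: Sequence[ChromosomeReport],
    contaminant_zygosity: str | None = None,
    min_total_het_snps: int = 1000,
    bin_width_pct: float = 1.0,
    smooth_window_bins: int = 15,
) -> dict:
    """Assemble a JSON-serializable sample QC summary.

    Includes total/het/hom SNP counts, the genome-wide smoothed peak, a
    low-SNP warning when fewer than ``min_total_het_snps`` heterozygous
    sites are available, the per-chromosome table, and — when
    ``contaminant_zygosity`` is given — a contamination estimate from the
    genome-wide peak position.
    """
    n_het = sum(1 for c in calls if c.call == HET)
    n_hom_ref = sum(1 for c in calls if c.call == HOM_REF)
    n_hom_alt = sum(1 for c in calls if c.call == HOM_ALT)

    dist = histogram(list(counts), bin_width_pct=bin_width_pct)
    genome_peak = (
        find_peak(dist, smooth_window_bins=smooth_window_bins) if dist.n_snps else None
    )

    report = {
        "n_snps": len(counts),
        "n_called": len(calls),
        "n_het": n_het,
        "n_hom_ref": n_hom_ref,
        "n_hom_alt": n_hom_alt,
        "genome_peak_pct": genome_peak,
        "low_snp_warning": n_het < min_total_het_snps,
        "flagged_chromosomes": [r.chrom for r in chrom_reports if r.skew_flag],
        "chromosomes": [asdict_no_site(r) for r in chrom_reports],
    }
    if contaminant_zygosity is not None and genome_peak is not None:
        report["contamination_estimate"] = estimate_contamination(
            genome_peak, contaminant_zygosity
        )
    return report


def asdict_no_site(report: ChromosomeReport) -> dict:
    return asdict(report)
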