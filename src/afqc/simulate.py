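"""Synthetic fixture generation with known ground truth.

Generates toy genomes (VCF + GTF), allele-count tables, SAM alignments and
FPKM tables emulating the real inputs of the pipeline: two inbred parental
strains, F1-heterozygous sites, cell mixtures at chosen proportions,
whole-chromosome duplications, and compound-binomial read sampling with
PCR-bias dispersion.  Every generator is deterministic given its seed and
writes a JSON "truth sidecar" holding the parameters recovery tests assert
against.

Fixture geometry: chromosomes are named ``chr1..chrN``, SNPs are spaced
1000 bp apart (so a 50 bp read overlaps exactly one site), and one gene
spans every 10 consecutive SNPs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .afmodel import PcrBiasModel, sample_counts
from .pileup import AlleleCount, write_counts_tsv
from .variant_io import SnpSite

__all__ = [
    "Population",
    "MixtureSpec",
    "make_genome_fixture",
    "simulate_counts",
    "make_sam",
    "simulate_fpkm",
]

SNP_SPACING = 1000
SNPS_PER_GENE = 10
_OTHER = {"A": "G", "C": "T", "G": "A", "T": "C"}  # a base that is neither ref nor alt is picked at runtime


@dataclass(frozen=True)
class Population:
    """One cell population of a mixture.

    ``genotype`` is either one of the constants ``"hom_ref"``,
    ``"hom_alt"``, ``"het"`` applied at every site, or the name of a
    strain whose genotype is read from each site's ``strain_genotypes``.
    """

    name: str
    genotype: str
    proportion: float


@dataclass
class MixtureSpec:
    """Ground truth for a simulated sample.

    ``chrom_copy_numbers`` maps (population name, chromosome) to the copy
    number of the (reference haplotype, alternative haplotype); unlisted
    chromosomes are diploid (1, 1).  A population heterozygous at a site
    with copies (1, 2) contributes allele dose ref=1, alt=2 — the
    mechanism that moves the trisomy peak to ~33%.
    """

    populations: Sequence[Population]
    chrom_copy_numbers: Mapping[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    sigma: float = 1.0
    depth: int = 50                      # reads per site (N)
    depth_dispersion: float | None = None  # negative-binomial dispersion; None = fixed depth
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p.proportion for p in self.populations)
        if abs(total - 1.0) > 1e-9 or any(p.proportion < 0 for p in self.populations):
            raise ValueError("population proportions must be non-negative and sum to 1")
        for (pop, chrom), copies in self.chrom_copy_numbers.items():
            if min(copies) < 0 or sum(copies) == 0:
                raise ValueError(f"invalid copy numbers {copies} for ({pop}, {chrom})")


def _allele_doses(pop: Population, site: SnpSite, copies: tuple[int, int]) -> tuple[float, float]:
    """Copy-weighted (ref, alt) allele dose contributed by one population."""
    gt = pop.genotype
    if gt not in ("hom_ref", "hom_alt", "het"):
        pair = site.strain_genotypes.get(gt)
        if pair is None:
            raise KeyError(f"site {site.chrom}:{site.pos} has no genotype for strain {gt!r}")
        n_ref = sum(1 for a in pair if a == site.ref_allele)
        gt = {2: "hom_ref", 1: "het", 0: "hom_alt"}[n_ref]
    ref_hap, alt_hap = copies
    if gt == "hom_ref":
        return float(ref_hap + alt_hap), 0.0
    if gt == "hom_alt":
        return 0.0, float(ref_hap + alt_hap)
    return float(ref_hap), float(alt_hap)


def make_genome_fixture(
    n_chroms: int,
    snps_per_chrom: int,
    seed: int,
    out_dir: str | Path,
) -> tuple[Path, Path, list[SnpSite]]:
    """Write a toy VCF + GTF pair and return the site list.

    The VCF carries two inbred strains: ``refstrain`` homozygous-reference
    and ``altstrain`` homozygous-alternative at every site (so their F1 is
    heterozygous everywhere).  The GTF defines one gene per 10 SNPs with a
    single exon covering those SNP positions, so every site is exonic.
    """
    if n_chroms < 1 or snps_per_chrom < 1:
        raise ValueError("need n_chroms >= 1 and snps_per_chrom >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    sites: list[SnpSite] = []
    vcf_path = out_dir / "fixture.vcf"
    gtf_path = out_dir / "fixture.gtf"
    with open(vcf_path, "w") as vcf, open(gtf_path, "w") as gtf:
        vcf.write("##fileformat=VCFv4.2\n")
        for c in range(1, n_chroms + 1):
            length = (snps_per_chrom + 2) * SNP_SPACING
            vcf.write(f"##contig=<ID=chr{c},length={length}>\n")
        vcf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        vcf.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\trefstrain\taltstrain\n"
        )
        snp_serial = 0
        for c in range(1, n_chroms + 1):
            chrom = f"chr{c}"
            for i in range(snps_per_chrom):
                pos = (i + 1) * SNP_SPACING
                ref, alt = rng.choice(bases, size=2, replace=False)
                snp_serial += 1
                snp_id = f"rs{snp_serial}"
                vcf.write(
                    f"{chrom}\t{pos}\t{snp_id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t0/0\t1/1\n"
                )
                sites.append(
                    SnpSite(
                        chrom=chrom,
                        pos=pos,
                        ref_allele=str(ref),
                        alt_allele=str(alt),
                        strain_genotypes={
                            "refstrain": (str(ref), str(ref)),
                            "altstrain": (str(alt), str(alt)),
                        },
                        snp_id=snp_id,
                    )
                )
            n_genes = (snps_per_chrom + SNPS_PER_GENE - 1) // SNPS_PER_GENE
            for g in range(n_genes):
                first = (g * SNPS_PER_GENE + 1) * SNP_SPACING
                last_idx = min((g + 1) * SNPS_PER_GENE, snps_per_chrom)
                last = last_idx * SNP_SPACING
                gene_id = f"gene_{chrom}_{g + 1}"
                attrs = f'gene_id "{gene_id}"; transcript_id "{gene_id}.t1";'
                gtf.write(
                    f"{chrom}\tsim\texon\t{first - 100}\t{last + 100}\t.\t+\t.\t{attrs}\n"
                )
    return vcf_path, gtf_path, sites


def simulate_counts(
    spec: MixtureSpec,
    sites: Sequence[SnpSite],
    out_tsv: str | Path | None = None,
    truth_json: str | Path | None = None,
) -> list[AlleleCount]:
    """Draw allele counts for every site under a mixture specification.

    At each site the effective allele abundances are the proportion-
    weighted, copy-number-weighted sums over populations; k is then drawn
    from the compound binomial with the spec's sigma and depth model.
    Optionally writes the pileup-compatible counts TSV and a JSON truth
    sidecar.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(sites)
    dose_ref = np.zeros(n)
    dose_alt = np.zeros(n)
    for pop in spec.populations:
        for i, site in enumerate(sites):
            copies = spec.chrom_copy_numbers.get((pop.name, site.chrom), (1, 1))
            d_ref, d_alt = _allele_doses(pop, site, copies)
            total = d_ref + d_alt
            if total == 0:
                continue
            dose_ref[i] += pop.proportion * d_ref / total
            dose_alt[i] += pop.proportion * d_alt / total

    if spec.depth_dispersion is None:
        depth = np.full(n, spec.depth, dtype=np.int64)
    else:
        # negative binomial parameterized by mean and dispersion r (var = m + m^2/r)
        r = spec.depth_dispersion
        p = r / (r + spec.depth)
        depth = rng.negative_binomial(r, p, size=n) + 1  # keep every site covered

    delta = rng.normal(0.0, spec.sigma, size=n)
    denom = dose_ref + dose_alt * np.exp2(delta)
    with np.errstate(invalid="ignore"):
        prob = np.where(denom > 0, dose_ref / np.where(denom > 0, denom, 1.0), 0.0)
    k = rng.binomial(depth, prob)

    counts = [
        AlleleCount(site=s, n_ref=int(k[i]), n_alt=int(depth[i] - k[i]), n_other=0)
        for i, s in enumerate(sites)
    ]
    if out_tsv is not None:
        write_counts_tsv(counts, out_tsv)
    if truth_json is not None:
        truth = {
            "populations": [
                {"name": p.name, "genotype": p.genotype, "proportion": p.proportion}
                for p in spec.populations
            ],
            "chrom_copy_numbers": {
                f"{pop}:{chrom}": list(copies)
                for (pop, chrom), copies in spec.chrom_copy_numbers.items()
            },
            "sigma": spec.sigma,
            "depth": spec.depth,
            "depth_dispersion": spec.depth_dispersion,
            "seed": spec.seed,
            "n_sites": n,
        }
        Path(truth_json).write_text(json.dumps(truth, indent=2))
    return counts


def make_sam(
    counts_truth: Sequence[AlleleCount],
    read_length: int = 50,
    seed: int = 0,
    path: str | Path = "fixture.sam",
    with_edge_cases: bool = True,
) -> Path:
    """Write a SAM file whose pileup exactly reproduces ``counts_truth``.

    For every site, emits n_ref / n_alt / n_other single-end reads whose
    CIGAR places the corresponding base on the site.  With
    ``with_edge_cases`` each site additionally gets one soft-clipped read
    whose clip covers the site, one spliced read whose N gap spans it, and
    one read with a deletion over it — none of which may be counted.

    Sites must be spaced at least ``read_length`` apart on each chromosome
    so no read overlaps a second site.
    """
    rng = np.random.default_rng(seed)
    bases = "ACGT"

    by_chrom: dict[str, list[AlleleCount]] = {}
    for c in counts_truth:
        by_chrom.setdefault(c.site.chrom, []).append(c)
    for chrom, lst in by_chrom.items():
        lst.sort(key=lambda c: c.site.pos)
        for a, b in zip(lst, lst[1:]):
            if b.site.pos - a.site.pos < read_length:
                raise ValueError(
                    f"sites {chrom}:{a.site.pos} and {chrom}:{b.site.pos} closer than read length"
                )

    chroms = sorted(by_chrom)
    lengths = {
        chrom: max(c.site.pos for c in by_chrom[chrom]) + 10 * read_length
        for chrom in chroms
    }
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": lengths[chrom]} for chrom in chroms],
    }

    path = Path(path)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        serial = 0
        for tid, chrom in enumerate(chroms):
            records = []
            for count in by_chrom[chrom]:
                site = count.site
                other = next(b for b in bases if b not in (site.ref_allele, site.alt_allele))
                planted = (
                    [site.ref_allele] * count.n_ref
                    + [site.alt_allele] * count.n_alt
                    + [other] * count.n_other
                )
                for base in planted:
                    offset = int(rng.integers(0, read_length))  # site index within the read
                    start0 = site.pos - 1 - offset
                    if start0 < 0:
                        offset += start0
                        start0 = 0
                    seq = rng.choice(list(bases), size=read_length)
                    seq[offset] = base
                    records.append((start0, "".join(seq), f"{read_length}M", None))
                if with_edge_cases:
                    if site.pos <= read_length + 10:
                        raise ValueError(
                            f"site {chrom}:{site.pos} too close to the chromosome start "
                            "for edge-case reads"
                        )
                    # soft-clip covering the site: 25S25M with the M block downstream
                    clip = read_length // 2
                    seq = "".join(rng.choice(list(bases), size=read_length))
                    records.append((site.pos, seq, f"{clip}S{read_length - clip}M", None))
                    # splice gap spanning the site
                    half = read_length // 2
                    seq = "".join(rng.choice(list(bases), size=read_length))
                    records.append(
                        (site.pos - 1 - half - 5, seq, f"{half}M10N{read_length - half}M", "splice")
                    )
                    # deletion spanning the site
                    seq = "".join(rng.choice(list(bases), size=read_length))
                    records.append(
                        (site.pos - 1 - half - 2, seq, f"{half}M5D{read_length - half}M", None)
                    )
            records.sort(key=lambda r: r[0])
            for start0, seq, cigar, _tag in records:
                serial += 1
                a = pysam.AlignedSegment()
                a.query_name = f"read{serial}"
                a.query_sequence = seq
                a.flag = 0
                a.reference_id = tid
                a.reference_start = start0
                a.mapping_quality = 60
                a.cigarstring = cigar
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                out.write(a)
    return path


def simulate_fpkm(
    n_genes_per_chrom: int = 200,
    planted_chrom_folds: Mapping[str, float] | None = None,
    noise_sd_log2: float = 0.3,
    n_samples_per_group: int = 2,
    seed: int = 0,
    n_chroms: int = 20,
    pseudogene_fraction: float = 0.05,
    subthreshold_fraction: float = 0.1,
    min_fpkm: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a two-group FPKM table with planted chromosome-wide folds.

    Baseline FPKM is log-uniform in [0.1, 1000]; group-1 samples replicate
    the baseline, and each group-2 value is baseline x fold(chrom) x
    2^Normal(0, noise_sd_log2), with independent noise per gene and
    sample.  ``n_chroms`` defaults to 20, a mouse-like autosome count.  A
    fraction of genes is flagged as pseudogenes, and another fraction is
    forced below ``min_fpkm`` in one sample, to exercise the expression
    filters.  Returns the table plus a truth dict naming the affected
    genes and folds.
    """
    if planted_chrom_folds is None:
        planted_chrom_folds = {}
    if any(f <= 0 for f in planted_chrom_folds.values()):
        raise ValueError("folds must be positive")
    if noise_sd_log2 < 0:
        raise ValueError("noise sd must be non-negative")
    rng = np.random.default_rng(seed)

    chroms = [f"chr{i}" for i in range(1, n_chroms + 1)]
    genes, gene_chrom = [], []
    for chrom in chroms:
        for g in range(n_genes_per_chrom):
            genes.append(f"{chrom}_g{g + 1}")
            gene_chrom.append(chrom)
    n_genes = len(genes)

    baseline = 10.0 ** rng.uniform(-1, 3, size=n_genes)
    folds = np.array([planted_chrom_folds.get(c, 1.0) for c in gene_chrom])

    data = {"gene": genes, "chrom": gene_chrom}
    is_pseudo = rng.random(n_genes) < pseudogene_fraction
    data["biotype"] = np.where(is_pseudo, "pseudogene", "protein_coding")

    g1_cols = [f"ctrl_{i + 1}" for i in range(n_samples_per_group)]
    g2_cols = [f"case_{i + 1}" for i in range(n_samples_per_group)]
    for col in g1_cols:
        data[col] = baseline.copy()
    for col in g2_cols:
        noise = 2.0 ** rng.normal(0.0, noise_sd_log2, size=n_genes)
        data[col] = baseline * folds * noise

    # force a fraction of non-pseudo genes under the expression threshold in one sample
    eligible = np.flatnonzero(~is_pseudo)
    n_sub = int(round(subthreshold_fraction * n_genes))
    sub_idx = rng.choice(eligible, size=min(n_sub, eligible.size), replace=False)
    df = pd.DataFrame(data).set_index("gene")
    df.loc[np.array(genes)[sub_idx], g1_cols[0]] = min_fpkm / 2.0

    df["pseudogene"] = is_pseudo
    truth = {
        "planted_chrom_folds": dict(planted_chrom_folds),
        "noise_sd_log2": noise_sd_log2,
        "group1": g1_cols,
        "group2": g2_cols,
        "pseudogenes": [genes[i] for i in np.flatnonzero(is_pseudo)],
        "subthreshold_genes": [genes[i] for i in sub_idx],
        "seed": seed,
    }
    return df, truth
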