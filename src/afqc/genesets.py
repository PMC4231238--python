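"""Gene-set and expression analyses supporting contamination/aneuploidy calls.

Three complementary lines of evidence:

* genotype-by-gene-set heterogeneity — if a sample is a mixture of two
  cell types with different genotypes, SNP genotypes stratify by which
  cell type expresses the gene; association is tested with a Monte-Carlo
  Fisher exact test on the 3x3 expression-class x genotype-class table;
* contaminant-specific SNPs — sites where both parental strains share an
  allele but the sample shows the other allele can only come from a third
  genotype, i.e. a contaminant;
* chromosome-wise expression — a trisomic chromosome expresses its genes
  ~1.5x relative to a diploid control; per-chromosome mean log2 FPKM
  ratios are t-tested against the all-genes mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .pileup import AlleleCount
from .qc import HET, HOM_ALT, HOM_REF, GenotypeCall

__all__ = [
    "GeneSetLabeling",
    "ContaminantSnp",
    "genotype_by_geneset_table",
    "fisher_mc_test",
    "contaminant_specific_snps",
    "chromosome_expression_test",
    "marker_logratio_matrix",
    "read_fpkm_table",
    "read_gene_list",
]

logger = logging.getLogger(__name__)

EXPRESSION_CLASSES = ["setA_specific", "setB_specific", "other"]
GENOTYPE_CLASSES = [HOM_REF, HOM_ALT, HET]


@dataclass
class GeneSetLabeling:
    """Exhaustive, mutually exclusive gene labels: setA / setB / other.

    Typical use labels genes by expression specificity, e.g. setA =
    TSC-specific and setB = ESC-specific marker genes; every other gene
    is "other".  Genes listed in both sets raise an error.
    """

    set_a: frozenset
    set_b: frozenset
    name_a: str = "setA_specific"
    name_b: str = "setB_specific"

    def __post_init__(self) -> None:
        overlap = self.set_a & self.set_b
        if overlap:
            raise ValueError(f"genes in both sets: {sorted(overlap)[:5]}")

    def label(self, gene: str) -> str:
        if gene in self.set_a:
            return "setA_specific"
        if gene in self.set_b:
            return "setB_specific"
        return "other"


def read_gene_list(path: str | Path) -> frozenset:
    """Read a gene-set file: one gene symbol per line, blank lines ignored."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def genotype_by_geneset_table(
    calls: Sequence[GenotypeCall],
    labeling: GeneSetLabeling,
    site_to_gene: Mapping[tuple[str, int], str],
) -> pd.DataFrame:
    """3x3 contingency table: expression class (rows) x genotype (columns).

    ``site_to_gene`` maps (chrom, pos) to a gene id; calls at unmapped
    sites are dropped (count logged).  Raises on an empty table.
    """
    table = pd.DataFrame(0, index=EXPRESSION_CLASSES, columns=GENOTYPE_CLASSES, dtype=int)
    n_unmapped = 0
    for call in calls:
        gene = site_to_gene.get((call.site.chrom, call.site.pos))
        if gene is None:
            n_unmapped += 1
            continue
        table.loc[labeling.label(gene), call.call] += 1
    if n_unmapped:
        logger.info("dropped %d calls at sites with no gene mapping", n_unmapped)
    if int(table.values.sum()) == 0:
        raise ValueError("no calls could be mapped to genes; contingency table is empty")
    return table


def _log_table_prob(table: np.ndarray) -> float:
    """Log null probability of a contingency table given its margins.

    Multivariate hypergeometric: log P = sum log r_i! + sum log c_j!
    - log n! - sum log a_ij!.
    """
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def fisher_mc_test(
    table,
    n_replicates: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Monte-Carlo Fisher exact test for an r x c contingency table.

    Estimates the probability, under fixed margins, of a table at most as
    probable as the observed one, by sampling margin-fixed tables with
    Patefield's algorithm.  The observed table is included in the count
    ((b+1)/(m+1)), so the estimate is never exactly zero and the test is
    valid at any replicate number.

    Zero rows/columns are removed before testing; fewer than two nonzero
    rows or columns leaves the test undefined and raises ValueError.
    """
    arr = np.asarray(table, dtype=np.int64)
    if np.any(arr < 0):
        raise ValueError("contingency table cells must be non-negative")
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(
            "test undefined: need at least 2 nonzero rows and columns after "
            f"removing empty margins (got shape {arr.shape})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    logp_obs = _log_table_prob(arr)
    dist = stats.random_table(arr.sum(axis=1), arr.sum(axis=0), seed=rng)
    samples = dist.rvs(n_replicates, method="patefield")
    logp = (
        gammaln(arr.sum(axis=1) + 1).sum()
        + gammaln(arr.sum(axis=0) + 1).sum()
        - gammaln(arr.sum() + 1)
        - gammaln(samples + 1).sum(axis=(1, 2))
    )
    b = int(np.count_nonzero(logp <= logp_obs + 1e-9))
    return (b + 1) / (n_replicates + 1)


@dataclass
class ContaminantSnp:
    """A site where the sample shows an allele neither parental strain carries."""

    count: AlleleCount
    shared_allele: str      # allele common to strains A and B
    off_strain_allele: str  # the allele the pure sample should never show
    sample_call: str        # het / hom of the off-strain allele
    ref_fraction: float
    matches_contaminant: bool | None  # None when no contaminant genotype given


def contaminant_specific_snps(
    counts_sample: Iterable[AlleleCount],
    genotypes_strain_a: Mapping[tuple[str, int], tuple[str, str]],
    genotypes_strain_b: Mapping[tuple[str, int], tuple[str, str]],
    genotypes_contaminant: Mapping[tuple[str, int], tuple[str, str]] | None = None,
    hom_threshold: float = 0.95,
) -> list[ContaminantSnp]:
    """Find SNPs whose observed alleles implicate a third genotype.

    Restricted to sites where strains A and B are homozygous for the
    *same* allele; a pure sample of either strain (or their F1) can then
    only show that allele.  Sites where the sample nonetheless shows the
    other allele — heterozygous or homozygous by the usual threshold —
    are returned.  When ``genotypes_contaminant`` is supplied, each hit
    is annotated with whether the off-strain allele matches the putative
    contaminant's genotype.
    """
    hits = []
    for c in counts_sample:
        key = (c.site.chrom, c.site.pos)
        gt_a = genotypes_strain_a.get(key)
        gt_b = genotypes_strain_b.get(key)
        if gt_a is None or gt_b is None:
            continue
        if len(set(gt_a)) != 1 or len(set(gt_b)) != 1 or gt_a[0] != gt_b[0]:
            continue  # strains differ or are het: not informative
        shared = gt_a[0]
        off = c.site.alt_allele if shared == c.site.ref_allele else c.site.ref_allele
        frac = c.ref_fraction
        if frac is None:
            continue
        off_frac = 1.0 - frac if off == c.site.alt_allele else frac
        if off_frac <= 1.0 - hom_threshold:
            continue  # sample consistent with the shared allele
        sample_call = "hom" if off_frac >= hom_threshold else "het"
        matches = None
        if genotypes_contaminant is not None:
            gt_c = genotypes_contaminant.get(key)
            matches = gt_c is not None and off in gt_c
        hits.append(
            ContaminantSnp(
                count=c,
                shared_allele=shared,
                off_strain_allele=off,
                sample_call=sample_call,
                ref_fraction=frac,
                matches_contaminant=matches,
            )
        )
    return hits


def read_fpkm_table(path: str | Path) -> pd.DataFrame:
    """Read a gene-level FPKM table.

    Expected tab-separated columns: ``gene``, ``chrom``, ``biotype``, then
    one column per sample.  Returns a DataFrame indexed by gene with a
    boolean ``pseudogene`` column (biotype containing "pseudogene") plus
    the sample columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "biotype": str})
    for col in ("gene", "chrom", "biotype"):
        if col not in df.columns:
            raise ValueError(f"FPKM table {path} lacks column {col!r}")
    df = df.set_index("gene")
    df["pseudogene"] = df["biotype"].str.contains("pseudogene", case=False, na=False)
    return df


def chromosome_expression_test(
    expr: pd.DataFrame,
    group1: Sequence[str],
    group2: Sequence[str],
    min_fpkm: float = 0.01,
    tail: str = "two-sided",
) -> pd.DataFrame:
    """Per-chromosome expression shift between two sample groups.

    Genes must exceed ``min_fpkm`` in every sample of both groups;
    pseudogenes are excluded.  Per gene the log2 ratio of group means
    (group2 over group1) is computed; per chromosome the mean log-ratio,
    its fold-change ``2**mean``, and a one-sample t-test of that
    chromosome's gene log-ratios against the mean log-ratio of all
    surviving genes are reported.

    ``tail``: "two-sided", "greater" (chromosome expressed above the
    genome average — the expected direction for a chromosomal gain), or
    "less".  Chromosomes with fewer than two surviving genes get NaN
    p-values.

    Returns a DataFrame indexed by chromosome with columns
    ``n_genes``, ``mean_log_ratio``, ``fold_change``, ``p_value``.
    """
    if tail not in ("two-sided", "greater", "less"):
        raise ValueError(f"tail must be two-sided/greater/less, got {tail!r}")
    if not group1 or not group2:
        raise ValueError("both groups need at least one sample")
    samples = list(group1) + list(group2)
    missing = [s for s in samples if s not in expr.columns]
    if missing:
        raise ValueError(f"samples missing from expression table: {missing}")

    keep = (expr[samples] > min_fpkm).all(axis=1)
    if "pseudogene" in expr.columns:
        keep &= ~expr["pseudogene"].astype(bool)
    sub = expr.loc[keep]
    log_ratio = np.log2(sub[list(group2)].mean(axis=1) / sub[list(group1)].mean(axis=1))
    overall_mean = float(log_ratio.mean())

    rows = {}
    for chrom, values in log_ratio.groupby(sub["chrom"]):
        mean = float(values.mean())
        if len(values) >= 2:
            alternative = tail if tail != "two-sided" else "two-sided"
            p = float(stats.ttest_1samp(values, overall_mean, alternative=alternative).pvalue)
        else:
            p = float("nan")
        rows[chrom] = {
            "n_genes": len(values),
            "mean_log_ratio": mean,
            "fold_change": float(2.0 ** mean),
            "p_value": p,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "chrom"
    out.attrs["overall_mean_log_ratio"] = overall_mean
    out.attrs["n_genes_tested"] = int(keep.sum())
    return out


def marker_logratio_matrix(
    expr: pd.DataFrame,
    marker_genes: Sequence[str],
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Median-normalized log2 expression of marker genes across samples.

    entry(g, s) = log2((FPKM(g, s) + eps) / (median_s FPKM(g, .) + eps));
    the pseudo-FPKM ``eps`` keeps unexpressed genes finite.  Markers absent
    from the table are logged and skipped.
    """
    sample_cols = [c for c in expr.columns if c not in ("chrom", "biotype", "pseudogene")]
    present = [g for g in marker_genes if g in expr.index]
    absent = [g for g in marker_genes if g not in expr.index]
    if absent:
        logger.warning("markers not in expression table, skipped: %s", absent)
    values = expr.loc[present, sample_cols].astype(float)
    med = values.median(axis=1)
    return np.log2(values.add(eps).div(med + eps, axis=0))
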