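"""Gene-set genotype heterogeneity, Fisher MC test, expression analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from afqc.genesets import (
    GeneSetLabeling,
    chromosome_expression_test,
    contaminant_specific_snps,
    fisher_mc_test,
    genotype_by_geneset_table,
    marker_logratio_matrix,
    read_fpkm_table,
    read_gene_list,
)
from afqc.pileup import AlleleCount
from afqc.qc import call_genotypes
from afqc.simulate import MixtureSpec, Population, make_genome_fixture, simulate_counts
from afqc.variant_io import SnpSite


def _call(chrom, pos, call):
    from afqc.qc import GenotypeCall

    return GenotypeCall(SnpSite(chrom, pos, "A", "G"), call, {"hom_ref": 1.0, "hom_alt": 0.0, "het": 0.5}[call], 30)


LABELING = GeneSetLabeling(set_a=frozenset({"Elf5", "Sox21"}), set_b=frozenset({"Sall4", "Klf4"}))


class TestContingencyTable:
    def test_hand_computed_table(self):
        calls = [
            _call("chr1", 1, "hom_ref"),
            _call("chr1", 2, "het"),
            _call("chr1", 3, "het"),
            _call("chr1", 4, "hom_alt"),
            _call("chr1", 5, "hom_ref"),
            _call("chr1", 6, "het"),
        ]
        site_to_gene = {
            ("chr1", 1): "Elf5",
            ("chr1", 2): "Elf5",
            ("chr1", 3): "Sall4",
            ("chr1", 4): "Actb",
            ("chr1", 5): "Actb",
            ("chr1", 6): "Actb",
        }
        table = genotype_by_geneset_table(calls, LABELING, site_to_gene)
        assert table.loc["setA_specific", "hom_ref"] == 1
        assert table.loc["setA_specific", "het"] == 1
        assert table.loc["setB_specific", "het"] == 1
        assert table.loc["other", "hom_alt"] == 1
        assert table.loc["other", "hom_ref"] == 1
        assert table.loc["other", "het"] == 1
        assert table.values.sum() == 6

    def test_unmapped_sites_dropped_and_total_conserved(self):
        calls = [_call("chr1", i, "het") for i in range(1, 6)]
        site_to_gene = {("chr1", 1): "Elf5", ("chr1", 2): "Actb"}
        table = genotype_by_geneset_table(calls, LABELING, site_to_gene)
        assert table.values.sum() == 2

    def test_single_class_and_empty(self):
        calls = [_call("chr1", i, "hom_ref") for i in range(1, 4)]
        table = genotype_by_geneset_table(calls, LABELING, {("chr1", i): "Elf5" for i in range(1, 4)})
        assert table.loc["setA_specific", "hom_ref"] == 3
        assert table.values.sum() == 3
        with pytest.raises(ValueError):
            genotype_by_geneset_table(calls, LABELING, {})

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            GeneSetLabeling(set_a=frozenset({"A"}), set_b=frozenset({"A"}))


def _enumerate_exact_p(table):
    """Brute-force Fisher p: enumerate all tables with the observed margins."""
    table = np.asarray(table)
    rows, cols = table.sum(axis=1), table.sum(axis=0)

    def log_prob(t):
        return (
            gammaln(rows + 1).sum()
            + gammaln(cols + 1).sum()
            - gammaln(rows.sum() + 1)
            - gammaln(np.asarray(t) + 1).sum()
        )

    def fill(partial, remaining_rows):
        if len(remaining_rows) == 1:
            last = cols - np.sum(partial, axis=0) if partial else cols
            if np.all(last >= 0):
                yield partial + [list(last)]
            return
        r = remaining_rows[0]
        free = cols - (np.sum(partial, axis=0) if partial else np.zeros_like(cols))
        ranges = [range(int(min(r, f)) + 1) for f in free]
        for combo in itertools.product(*ranges):
            if sum(combo) == r:
                yield from fill(partial + [list(combo)], remaining_rows[1:])

    lp_obs = log_prob(table)
    total = 0.0
    for t in fill([], list(rows)):
        lp = log_prob(t)
        if lp <= lp_obs + 1e-9:
            total += np.exp(lp)
    return total


class TestFisherMc:
    def test_matches_exact_2x2(self):
        table = [[10, 0], [0, 10]]
        exact = stats.fisher_exact(table).pvalue
        m = 200_000
        p = fisher_mc_test(table, n_replicates=m, seed=0)
        assert abs(p - exact) <= 3 * np.sqrt(exact * (1 - exact) / m) + 2 / m

    def test_no_association_gives_large_p(self):
        assert fisher_mc_test([[5, 5], [5, 5]], n_replicates=20_000, seed=1) >= 0.99

    @pytest.mark.parametrize(
        "table",
        [
            [[3, 1, 2], [1, 3, 1], [2, 1, 3]],
            [[4, 0], [1, 3], [0, 4]],
            [[2, 5], [5, 2]],
        ],
    )
    def test_matches_enumeration_on_small_tables(self, table):
        exact = _enumerate_exact_p(table)
        m = 50_000
        p = fisher_mc_test(table, n_replicates=m, seed=2)
        assert abs(p - exact) <= 3 * np.sqrt(exact * (1 - exact) / m) + 2 / m

    def test_degenerate_margins_raise(self):
        with pytest.raises(ValueError):
            fisher_mc_test([[5, 5], [0, 0]])
        with pytest.raises(ValueError):
            fisher_mc_test([[5, 0], [5, 0]])
        with pytest.raises(ValueError):
            fisher_mc_test([[5, 5], [5, -1]])

    def test_reproducible_and_row_permutation_invariant_total(self):
        t = [[8, 2, 1], [2, 8, 2], [1, 1, 9]]
        p1 = fisher_mc_test(t, n_replicates=10_000, seed=3)
        p2 = fisher_mc_test(t, n_replicates=10_000, seed=3)
        assert p1 == p2


class TestContaminantSnps:
    def _fixture(self, tmp_path):
        vcf, gtf, sites = make_genome_fixture(1, 40, seed=5, out_dir=tmp_path)
        return sites

    def test_planted_contaminant_detected(self):
        site = SnpSite("chr1", 1000, "A", "G")
        shared = {("chr1", 1000): ("A", "A")}  # both strains hom-ref
        count = AlleleCount(site, n_ref=27, n_alt=3)  # 10% alt reads -> het call
        (hit,) = contaminant_specific_snps([count], shared, shared)
        assert hit.off_strain_allele == "G"
        assert hit.sample_call == "het"

    def test_differing_strains_not_informative(self):
        site = SnpSite("chr1", 1000, "A", "G")
        count = AlleleCount(site, n_ref=15, n_alt=15)
        hits = contaminant_specific_snps(
            [count], {("chr1", 1000): ("A", "A")}, {("chr1", 1000): ("G", "G")}
        )
        assert hits == []

    def test_contaminant_genotype_annotation(self):
        site = SnpSite("chr1", 1000, "A", "G")
        shared = {("chr1", 1000): ("A", "A")}
        count = AlleleCount(site, n_ref=20, n_alt=10)
        (hit,) = contaminant_specific_snps(
            [count], shared, shared, genotypes_contaminant={("chr1", 1000): ("A", "G")}
        )
        assert hit.matches_contaminant is True

    def test_pure_sample_yields_almost_no_hits(self, tmp_path):
        sites = self._fixture(tmp_path)
        spec = MixtureSpec(
            populations=[Population("pure", "hom_ref", 1.0)], sigma=1.0, depth=50, seed=6
        )
        counts = simulate_counts(spec, sites)
        shared = {(s.chrom, s.pos): (s.ref_allele, s.ref_allele) for s in sites}
        hits = contaminant_specific_snps(counts, shared, shared)
        # a pure hom-ref sample shows the alt allele only via the binomial tail
        assert len(hits) <= 2


def _expr_table():
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2", "chr2"],
            "biotype": ["protein_coding"] * 4,
            "pseudogene": [False] * 4,
            "s1": [10.0, 20.0, 5.0, 1.0],
            "s2": [10.0, 20.0, 5.0, 1.0],
            "s3": [10.0, 20.0, 5.0, 1.0],
            "s4": [10.0, 20.0, 5.0, 1.0],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene"),
    )


class TestChromosomeExpression:
    def test_identical_groups_give_zero_ratios(self):
        res = chromosome_expression_test(_expr_table(), ["s1", "s2"], ["s3", "s4"])
        assert np.allclose(res["mean_log_ratio"], 0.0)
        assert np.allclose(res["fold_change"], 1.0)

    def test_subthreshold_gene_excluded(self):
        expr = _expr_table()
        expr.loc["g4", "s2"] = 0.005
        res = chromosome_expression_test(expr, ["s1", "s2"], ["s3", "s4"], min_fpkm=0.01)
        assert res.loc["chr2", "n_genes"] == 1
        assert res.attrs["n_genes_tested"] == 3

    def test_pseudogenes_excluded(self):
        expr = _expr_table()
        expr.loc["g1", "pseudogene"] = True
        res = chromosome_expression_test(expr, ["s1", "s2"], ["s3", "s4"])
        assert res.loc["chr1", "n_genes"] == 1

    def test_single_gene_chromosome_p_undefined(self):
        expr = _expr_table().drop(index="g2")
        res = chromosome_expression_test(expr, ["s1", "s2"], ["s3", "s4"])
        assert np.isnan(res.loc["chr1", "p_value"])

    def test_validation(self):
        with pytest.raises(ValueError):
            chromosome_expression_test(_expr_table(), [], ["s3"])
        with pytest.raises(ValueError):
            chromosome_expression_test(_expr_table(), ["s1"], ["nope"])
        with pytest.raises(ValueError):
            chromosome_expression_test(_expr_table(), ["s1"], ["s3"], tail="sideways")


class TestMarkerMatrix:
    def test_constant_gene_is_zero_row(self):
        matrix = marker_logratio_matrix(_expr_table(), ["g1"])
        assert np.allclose(matrix.loc["g1"], 0.0)

    def test_single_sample_expression_sign(self):
        expr = _expr_table()
        expr.loc["g3", ["s1", "s2", "s3", "s4"]] = [100.0, 0.0, 0.0, 0.0]
        matrix = marker_logratio_matrix(expr, ["g3"])
        assert matrix.loc["g3", "s1"] > 5  # far above the (zero) median
        assert (matrix.loc["g3", ["s2", "s3", "s4"]] <= 0).all()
        # when the gene is expressed in most samples, the silent one is negative
        expr.loc["g3", ["s1", "s2", "s3", "s4"]] = [100.0, 90.0, 110.0, 0.0]
        matrix = marker_logratio_matrix(expr, ["g3"])
        assert matrix.loc["g3", "s4"] < -5

    def test_missing_marker_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            matrix = marker_logratio_matrix(_expr_table(), ["g1", "Missing"])
        assert list(matrix.index) == ["g1"]


def test_fpkm_table_reader_and_gene_list(tmp_path):
    fpkm = tmp_path / "expr.tsv"
    fpkm.write_text(
        "gene\tchrom\tbiotype\ts1\ts2\n"
        "g1\tchr1\tprotein_coding\t1.5\t2.5\n"
        "g2\tchr2\tprocessed_pseudogene\t0.1\t0.2\n"
    )
    expr = read_fpkm_table(fpkm)
    assert list(expr.index) == ["g1", "g2"]
    assert expr["pseudogene"].tolist() == [False, True]

    genes = tmp_path / "genes.txt"
    genes.write_text("Sall4\n\nKlf4\n")
    assert read_gene_list(genes) == frozenset({"Sall4", "Klf4"})
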