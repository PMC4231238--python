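import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from afqc import simulate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def genome_fixture(tmp_path_factory):
    """Small two-strain toy genome: (vcf_path, gtf_path, sites)."""
    out = tmp_path_factory.mktemp("genome")
    return simulate.make_genome_fixture(n_chroms=2, snps_per_chrom=30, seed=11, out_dir=out)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def write_vcf(path, records, samples=()):
    """Minimal VCF writer for hand-built test records.

    Each record: (chrom, pos, snp_id, ref, alt, genotype strings per sample).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({r[0] for r in records})
        for c in chroms:
            fh.write(f"##contig=<ID={c},length=10000000>\n")
        if samples:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if samples:
            cols += "\tFORMAT\t" + "\t".join(samples)
        fh.write(cols + "\n")
        for rec in records:
            chrom, pos, snp_id, ref, alt = rec[:5]
            line = f"{chrom}\t{pos}\t{snp_id}\t{ref}\t{alt}\t.\tPASS\t."
            if samples:
                line += "\tGT\t" + "\t".join(rec[5])
            fh.write(line + "\n")
    return path
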