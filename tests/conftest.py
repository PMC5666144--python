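import pytest

import tricross as tc


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced breeding configuration for fast simulation tests."""
    return tc.SimConfig(
        markers_per_group=100, bp_per_group=100_000, n_genes=700, seed=11
    )


@pytest.fixture(scope="session")
def small_map(small_cfg):
    return tc.make_genome_map(small_cfg)


@pytest.fixture(scope="session")
def coding_catalog():
    """Synthetic genes + genome + SNPs with planted coding-effect truth."""
    return tc.simulate_coding_catalog(n_genes=50, codons_per_gene=40, seed=5)


def brute_force_effect(snp, gene, seq):
    """Independent oracle: substitute the allele in the full genomic
    sequence, rebuild and translate the whole protein, compare."""
    from Bio.Seq import Seq

    assert seq[snp.position - 1] == snp.ref_allele

    def protein(s):
        cds = "".join(s[a - 1 : b] for a, b in gene.cds_segments)
        if gene.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return str(Seq(cds).translate())

    if not gene.in_cds(snp.position):
        return "noncoding"
    mutated = seq[: snp.position - 1] + snp.alt_allele + seq[snp.position :]
    return "synonymous" if protein(seq) == protein(mutated) else "nonsynonymous"


@pytest.fixture(scope="session")
def oracle_effect():
    return brute_force_effect
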