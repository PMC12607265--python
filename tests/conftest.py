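import numpy as np
import pandas as pd
import pytest

from teqhot.genotypes import GenotypeMatrix, snp_ids
from teqhot.pipeline import StudyDesign, regulator_recovery_study


def make_genotypes(dosage, chrom="1", pos_start=100_000, spacing=10_000,
                   line_ids=None):
    """Small GenotypeMatrix with evenly spaced SNPs on one chromosome."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_snps = dosage.shape[1]
    pos = np.arange(n_snps) * spacing + pos_start
    snp_map = pd.DataFrame({
        "chrom": chrom, "pos": pos, "ref": "A", "alt": "T", "maf": 0.0,
    })
    snp_map.insert(0, "snp", snp_ids(snp_map["chrom"], snp_map["pos"]))
    gt = GenotypeMatrix(dosage=dosage, snp_map=snp_map, line_ids=line_ids)
    gt.snp_map["maf"] = gt.maf()
    return gt


def make_assoc(rows):
    """Association table from (snp, chrom, pos, gene, tissue, beta, p) tuples."""
    df = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "gene",
                                     "tissue", "beta", "p_value"])
    df["n"] = 300
    return df


@pytest.fixture(scope="session")
def panel10():
    """Ten genes on two chromosomes with alternating strands."""
    rows = []
    for i in range(10):
        chrom = "1" if i < 5 else "2"
        start = 1_000_000 * (i % 5 + 1)
        strand = "+" if i % 2 == 0 else "-"
        rows.append({
            "gene": f"g{i:03d}", "chrom": chrom, "start": start,
            "end": start + 4_999, "strand": strand,
            "tss": start if strand == "+" else start + 4_999,
            "branch": ["porphyrin", "chlorophyll"][i % 2],
        })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def recovery_study():
    """100 seeded replicates of the planted-regulator recovery study:
    300 lines, 1,200 SNPs, one trans regulator with 10 of 70 panel genes at
    +0.5 expression units per allele, noise SD 0.5."""
    return regulator_recovery_study(n_replicates=100, base_seed=7,
                                    design=StudyDesign())
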