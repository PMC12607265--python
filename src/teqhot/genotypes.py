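"""Genotype container, allele recoding/filtering, and genotype file I/O.

Genotypes are held as a dense lines x SNPs dosage matrix counting copies of
the alternate allele (0/1/2) for biallelic SNPs, together with a SNP map
(chromosome, 1-based position, ref, alt, minor-allele frequency). Inbred
diversity panels are effectively homozygous, but heterozygous calls (dosage
1) are representable and handled throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("teqhot")

SNP_MAP_COLUMNS = ["snp", "chrom", "pos", "ref", "alt", "maf"]


def snp_ids(chrom: np.ndarray | pd.Series, pos: np.ndarray | pd.Series) -> pd.Series:
    """Canonical SNP identifiers, ``"<chrom>-<pos>"``."""
    return pd.Series(chrom).astype(str) + "-" + pd.Series(pos).astype(str)


@dataclass
class GenotypeMatrix:
    """Lines x SNPs alternate-allele dosage with a SNP map.

    Attributes
    ----------
    dosage
        Integer array of shape (n_lines, n_snps) with values in {0, 1, 2}.
    snp_map
        DataFrame with columns snp, chrom, pos, ref, alt, maf; positions are
        1-based and strictly increasing within each chromosome.
    line_ids
        Sample identifiers, one per dosage row.
    """

    dosage: np.ndarray
    snp_map: pd.DataFrame
    line_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (lines x SNPs)")
        if len(self.snp_map) != self.dosage.shape[1]:
            raise ValueError(
                f"snp_map has {len(self.snp_map)} rows but dosage has "
                f"{self.dosage.shape[1]} columns"
            )
        if not self.line_ids:
            self.line_ids = [f"line{i}" for i in range(self.dosage.shape[0])]
        if len(self.line_ids) != self.dosage.shape[0]:
            raise ValueError("line_ids length does not match dosage rows")
        missing = [c for c in SNP_MAP_COLUMNS if c not in self.snp_map.columns]
        if missing:
            raise ValueError(f"snp_map missing columns: {missing}")
        vals = np.unique(self.dosage)
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosages must be in {0, 1, 2}")
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions must be increasing within chromosome")

    @property
    def n_lines(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def alt_freq(self) -> np.ndarray:
        """Empirical alternate-allele frequency per SNP."""
        return self.dosage.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Empirical minor-allele frequency per SNP."""
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the SNPs at the given column indices (order preserved)."""
        return GenotypeMatrix(
            dosage=self.dosage[:, index],
            snp_map=self.snp_map.iloc[np.asarray(index)].reset_index(drop=True),
            line_ids=list(self.line_ids),
        )


def recode_and_filter(genotypes: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Remove SNPs below a minor-allele-frequency threshold.

    Monomorphic SNPs are always removed (zero variance is untestable), so
    ``maf_min = 0`` removes exactly the monomorphic sites. Dosages already
    count the alternate allele; multi-allelic records are excluded at read
    time (see :func:`read_vcf`). The stored ``maf`` column is refreshed from
    the dosage matrix.

    Raises
    ------
    ValueError
        If no SNP survives the filter.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    f = genotypes.alt_freq()
    mf = np.minimum(f, 1.0 - f)
    keep = (mf >= maf_min) & (f > 0.0) & (f < 1.0)
    n_removed = int((~keep).sum())
    logger.info(
        "MAF filter (>= %.3g): %d of %d SNPs removed, %d retained",
        maf_min, n_removed, genotypes.n_snps, int(keep.sum()),
    )
    if not keep.any():
        raise ValueError(f"no SNPs remain after MAF filter at {maf_min}")
    out = genotypes.take_snps(np.flatnonzero(keep))
    out.snp_map = out.snp_map.copy()
    out.snp_map["maf"] = out.maf()
    return out


# ---------------------------------------------------------------------------
# I/O: VCF and TSV dosage matrices
# ---------------------------------------------------------------------------

def write_vcf(genotypes: GenotypeMatrix, path: str | Path,
              chrom_lengths: dict[str, int] | None = None) -> None:
    """Write genotypes as an uncompressed biallelic VCF with GT fields.

    Dosage 0 -> 0/0, 1 -> 0/1, 2 -> 1/1.
    """
    path = Path(path)
    gt_strings = np.array(["0/0", "0/1", "1/1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=teqhot\n")
        if chrom_lengths:
            for chrom, length in chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in pd.unique(genotypes.snp_map["chrom"].astype(str)):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.line_ids) + "\n")
        sm = genotypes.snp_map
        for j in range(genotypes.n_snps):
            row = sm.iloc[j]
            calls = "\t".join(gt_strings[genotypes.dosage[:, j]])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp}\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix, dropping non-biallelic records.

    The count of dropped multi-allelic records is logged. Missing genotypes
    are not supported (inputs are assumed complete/imputed).
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        line_ids = list(vf.header.samples)
        rows = []
        dosages = []
        n_multi = 0
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multi += 1
                continue
            d = np.empty(len(line_ids), dtype=np.int8)
            for i, sample in enumerate(rec.samples.values()):
                alleles = sample["GT"]
                if alleles is None or any(a is None for a in alleles):
                    raise ValueError(
                        f"missing genotype at {rec.chrom}:{rec.pos}; "
                        "complete (imputed) inputs are required"
                    )
                d[i] = sum(1 for a in alleles if a != 0)
            dosages.append(d)
            rows.append((rec.chrom, rec.pos, rec.ref, rec.alts[0]))
    if n_multi:
        logger.info("dropped %d non-biallelic VCF records", n_multi)
    if not rows:
        raise ValueError(f"no biallelic SNPs in {path}")
    snp_map = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    snp_map.insert(0, "snp", snp_ids(snp_map["chrom"], snp_map["pos"]))
    dosage = np.column_stack(dosages)
    gt = GenotypeMatrix(dosage=dosage, snp_map=snp_map.assign(maf=0.0),
                        line_ids=line_ids)
    gt.snp_map["maf"] = gt.maf()
    return gt


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write the dosage matrix as TSV, lines x SNPs, header = "chrom-pos" ids."""
    df = pd.DataFrame(genotypes.dosage, index=genotypes.line_ids,
                      columns=genotypes.snp_map["snp"].tolist())
    df.index.name = "line"
    df.to_csv(path, sep="\t")


def read_dosage_tsv(path: str | Path, ref: str = "A", alt: str = "T") -> GenotypeMatrix:
    """Read a lines x SNPs dosage TSV whose header holds "chrom-pos" SNP ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    parts = pd.Series(df.columns).str.rsplit("-", n=1)
    snp_map = pd.DataFrame({
        "snp": df.columns,
        "chrom": parts.str[0].values,
        "pos": parts.str[1].astype(int).values,
        "ref": ref,
        "alt": alt,
        "maf": 0.0,
    })
    gt = GenotypeMatrix(dosage=df.to_numpy(dtype=np.int8), snp_map=snp_map,
                        line_ids=[str(i) for i in df.index])
    gt.snp_map["maf"] = gt.maf()
    return gt
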