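"""Synthetic genotypes, gene panel, expression, and phenotypes with planted
regulatory architecture.

The generator emulates the inputs of a gene-panel expression GWAS on a
diversity panel of inbred lines: biallelic SNPs at configurable allele
frequencies on a toy multi-chromosome genome, a panel of genes laid out with
pathway-branch labels, expression built from planted cis effects plus planted
trans "regulator" SNPs that coordinately shift many panel genes (optionally
with a per-tissue sign flip at one gene), and a paired mutant/wild-type
phenotype whose dependence on a focal variant exists only in mutant samples
(epistasis). A single global seed determines every output; per-stage
substreams are derived deterministically from it.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, snp_ids

BRANCHES = ("porphyrin", "chlorophyll", "heme", "siroheme", "bilin", "catabolism")

# substream tags so stages never share random state
_STAGE_GENOTYPES = 1
_STAGE_PANEL = 2
_STAGE_CIS = 3
_STAGE_EXPRESSION = 4
_STAGE_PHENOTYPE = 5


def _rng(seed: int, stage: int, label: str = "") -> np.random.Generator:
    tag = zlib.crc32(label.encode()) if label else 0
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage, tag]))


@dataclass
class PlantedRegulator:
    """A trans-acting SNP planted to shift the expression of many panel genes.

    ``effect_sizes`` maps each target gene to its (nonzero) per-allele effect;
    genes in ``sign_flip_genes`` have their effect negated in ``flip_tissue``
    only, emulating a target whose direction of co-regulation reverses in one
    tissue.
    """

    snp_index: int
    effect_sizes: dict[str, float]
    sign_flip_genes: frozenset[str] = frozenset()
    flip_tissue: str = ""

    def __post_init__(self) -> None:
        self.sign_flip_genes = frozenset(self.sign_flip_genes)
        if not self.effect_sizes:
            raise ValueError("regulator must target at least one gene")
        zero = [g for g, b in self.effect_sizes.items() if b == 0]
        if zero:
            raise ValueError(f"regulator effects must be nonzero; zero at {zero}")
        if not self.sign_flip_genes <= set(self.effect_sizes):
            raise ValueError("sign_flip_genes must be a subset of target genes")

    @property
    def target_genes(self) -> frozenset[str]:
        return frozenset(self.effect_sizes)


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic data generator.

    Defaults are a desk-scale stand-in for a large crop genome and a
    ~70-gene biosynthetic panel scanned in ~300 inbred lines: 10 chromosomes
    of 20 Mb, allele frequencies uniform on (0.02, 0.5] so the 0.05 MAF
    filter has work to do, cis effects of SD 0.5 and residual noise SD 0.5
    in expression units.
    """

    n_lines: int = 300
    n_chromosomes: int = 10
    chrom_length_bp: int = 20_000_000
    n_snps: int = 5_000
    maf_range: tuple[float, float] = (0.02, 0.5)
    n_panel_genes: int = 70
    cis_effect_sd: float = 0.5
    regulator_spec: tuple[PlantedRegulator, ...] = ()
    noise_sd: float = 0.5
    seed: int = 0
    gene_length_bp: int = 4_000
    cis_window_bp: int = 50_000

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        for name in ("n_chromosomes", "chrom_length_bp", "n_snps",
                     "n_panel_genes", "gene_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.cis_effect_sd < 0 or self.noise_sd < 0:
            raise ValueError("effect/noise SDs must be nonnegative")
        self.regulator_spec = tuple(self.regulator_spec)

    @property
    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names}


@dataclass
class PhenotypeSimSpec:
    """Mutant-only (epistatic) phenotype model for paired MT/WT trait values."""

    focal_snp: int
    mutant_effect: float
    wt_effect: float = 0.0
    trait_mean: float = 30.0
    trait_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.trait_sd < 0:
            raise ValueError("trait_sd must be nonnegative")


def _split_counts(total: int, k: int) -> np.ndarray:
    """Split `total` items over `k` groups as evenly as possible."""
    base = total // k
    out = np.full(k, base, dtype=int)
    out[: total - base * k] += 1
    return out


def _sample_positions(rng: np.random.Generator, length: int, k: int,
                      chrom: str) -> np.ndarray:
    """k distinct 1-based positions, uniform without replacement, sorted."""
    if k > length:
        raise ValueError(
            f"cannot place {k} SNPs on chromosome {chrom} of length {length} bp"
        )
    # rejection loop keeps memory flat even for large chromosomes
    draw = max(16, int(k * 1.25))
    pool = np.unique(rng.integers(1, length + 1, size=draw))
    while pool.size < k:
        extra = rng.integers(1, length + 1, size=draw)
        pool = np.unique(np.concatenate([pool, extra]))
    return np.sort(rng.choice(pool, size=k, replace=False))


def _draw_dosages(rng: np.random.Generator, freqs: np.ndarray,
                  n_lines: int) -> np.ndarray:
    """Dosages as two independent allele draws per line at each SNP frequency."""
    return rng.binomial(2, freqs, size=(n_lines, freqs.size)).astype(np.int8)


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Biallelic SNP genotypes on the toy genome.

    Per-SNP alternate-allele frequencies are uniform over ``maf_range``;
    positions are uniform without replacement along each chromosome; each
    line's dosage is Binomial(2, f). Fully determined by ``config.seed``.
    """
    rng = _rng(config.seed, _STAGE_GENOTYPES)
    counts = _split_counts(config.n_snps, config.n_chromosomes)
    chroms, positions = [], []
    for chrom, k in zip(config.chrom_names, counts):
        pos = _sample_positions(rng, config.chrom_length_bp, int(k), chrom)
        chroms.extend([chrom] * int(k))
        positions.append(pos)
    pos_arr = np.concatenate(positions) if positions else np.array([], dtype=int)
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    dosage = _draw_dosages(rng, freqs, config.n_lines)
    snp_map = pd.DataFrame({
        "chrom": chroms,
        "pos": pos_arr,
        "ref": "A",
        "alt": "T",
    })
    snp_map.insert(0, "snp", snp_ids(snp_map["chrom"], snp_map["pos"]))
    snp_map["maf"] = 0.0
    gt = GenotypeMatrix(dosage=dosage, snp_map=snp_map,
                        line_ids=[f"line{i}" for i in range(config.n_lines)])
    gt.snp_map["maf"] = gt.maf()
    return gt


def simulate_gene_panel(config: SimConfig) -> pd.DataFrame:
    """Panel gene annotation: non-overlapping gene bodies, alternating strand,
    branch labels cycled over the six pathway branches.

    Returns a DataFrame with columns gene, chrom, start, end, strand, tss,
    branch (1-based inclusive coordinates; TSS = start on +, end on -).
    """
    counts = _split_counts(config.n_panel_genes, config.n_chromosomes)
    rows = []
    g = 0
    for chrom, k in zip(config.chrom_names, counts):
        if k == 0:
            continue
        spacing = config.chrom_length_bp // (int(k) + 1)
        if spacing <= config.gene_length_bp:
            raise ValueError(
                f"genome too small: {k} genes of {config.gene_length_bp} bp do "
                f"not fit on a {config.chrom_length_bp} bp chromosome"
            )
        for i in range(int(k)):
            start = spacing * (i + 1)
            end = start + config.gene_length_bp - 1
            strand = "+" if g % 2 == 0 else "-"
            rows.append({
                "gene": f"g{g:03d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "tss": start if strand == "+" else end,
                "branch": BRANCHES[g % len(BRANCHES)],
            })
            g += 1
    return pd.DataFrame(rows)


def cis_architecture(genotypes: GenotypeMatrix, panel: pd.DataFrame,
                     config: SimConfig) -> pd.DataFrame:
    """Planted cis assignment: for each panel gene, the nearest SNP within the
    cis window (same chromosome) and its per-allele effect ~ N(0, cis_effect_sd).

    Shared across tissues (keyed by the global seed only). Genes with no SNP
    in their cis window get no cis term. Returns columns gene, cis_snp_index
    (-1 if none), cis_effect.
    """
    rng = _rng(config.seed, _STAGE_CIS)
    sm = genotypes.snp_map
    rows = []
    for rec in panel.itertuples():
        same = sm.index[(sm["chrom"].astype(str) == str(rec.chrom))]
        idx, eff = -1, 0.0
        if len(same):
            pos = sm.loc[same, "pos"].to_numpy()
            dist = np.where((pos >= rec.start) & (pos <= rec.end), 0,
                            np.minimum(np.abs(pos - rec.start), np.abs(pos - rec.end)))
            j = int(np.argmin(dist))
            if dist[j] <= config.cis_window_bp:
                idx = int(same[j])
                eff = float(rng.normal(0.0, config.cis_effect_sd)) if config.cis_effect_sd > 0 else 0.0
        rows.append({"gene": rec.gene, "cis_snp_index": idx, "cis_effect": eff})
    return pd.DataFrame(rows)


def simulate_expression(genotypes: GenotypeMatrix, panel: pd.DataFrame,
                        config: SimConfig, tissue: str,
                        return_truth: bool = False):
    """Expression matrix (genes x lines) from planted architecture.

    expression(gene, line) = cis_effect * dosage(cis SNP)
                             + sum over regulators of effect * dosage(regulator)
                             + N(0, noise_sd)

    Baseline is 0 (indices standardize it away regardless). Regulator effects
    on ``sign_flip_genes`` are negated when ``tissue`` equals the regulator's
    ``flip_tissue``. Noise draws are tissue-specific; cis architecture is
    shared across tissues.
    """
    genes = panel["gene"].tolist()
    gene_pos = {g: i for i, g in enumerate(genes)}
    for reg in config.regulator_spec:
        if not 0 <= reg.snp_index < genotypes.n_snps:
            raise ValueError(f"regulator SNP index {reg.snp_index} does not exist")
        missing = [g for g in reg.effect_sizes if g not in gene_pos]
        if missing:
            raise ValueError(f"regulator targets absent from panel: {missing}")

    n_genes, n_lines = len(genes), genotypes.n_lines
    expr = np.zeros((n_genes, n_lines))

    cis = cis_architecture(genotypes, panel, config)
    for rec in cis.itertuples():
        if rec.cis_snp_index >= 0 and rec.cis_effect != 0.0:
            expr[gene_pos[rec.gene]] += rec.cis_effect * genotypes.dosage[:, rec.cis_snp_index]

    for reg in config.regulator_spec:
        d = genotypes.dosage[:, reg.snp_index].astype(float)
        for gene, beta in reg.effect_sizes.items():
            b = -beta if (gene in reg.sign_flip_genes and tissue == reg.flip_tissue) else beta
            expr[gene_pos[gene]] += b * d

    if config.noise_sd > 0:
        rng = _rng(config.seed, _STAGE_EXPRESSION, tissue)
        expr += rng.normal(0.0, config.noise_sd, size=expr.shape)

    out = pd.DataFrame(expr, index=genes, columns=genotypes.line_ids)
    out.index.name = "gene"
    if return_truth:
        return out, cis
    return out


def simulate_phenotypes(genotypes: GenotypeMatrix, spec: PhenotypeSimSpec,
                        seed: int) -> pd.DataFrame:
    """Paired mutant (MT) and wild-type (WT) chlorophyll-meter traits at two
    timepoints per line.

    MT = trait_mean + mutant_effect * dosage(focal SNP) + noise;
    WT = trait_mean + wt_effect * dosage(focal SNP) + noise.
    Independent noise per column. The default wt_effect = 0 makes the focal
    variant's phenotypic effect conditional on the mutant background.
    """
    if not 0 <= spec.focal_snp < genotypes.n_snps:
        raise ValueError(f"focal SNP index {spec.focal_snp} does not exist")
    rng = _rng(seed, _STAGE_PHENOTYPE)
    d = genotypes.dosage[:, spec.focal_snp].astype(float)
    n = genotypes.n_lines
    out = {"line": genotypes.line_ids}
    for tp in ("CCMI", "CCMII"):
        out[f"MT_{tp}"] = spec.trait_mean + spec.mutant_effect * d + rng.normal(0, spec.trait_sd, n)
        out[f"WT_{tp}"] = spec.trait_mean + spec.wt_effect * d + rng.normal(0, spec.trait_sd, n)
    return pd.DataFrame(out)


def trans_snp_candidates(genotypes: GenotypeMatrix, panel: pd.DataFrame,
                         target_genes: list[str], trans_mb: float = 1.0,
                         min_maf: float = 0.1) -> np.ndarray:
    """SNP indices that are trans (>= trans_mb away or another chromosome) to
    every listed target gene and common enough to survive MAF filtering.

    A planted regulator drawn from these candidates is trans-acting on all of
    its targets by construction, so its full target set is recoverable by the
    hotspot tiers.
    """
    targets = panel[panel["gene"].isin(target_genes)]
    missing = set(target_genes) - set(targets["gene"])
    if missing:
        raise ValueError(f"target genes absent from panel: {sorted(missing)}")
    sm = genotypes.snp_map
    ok = genotypes.maf() >= min_maf
    pos = sm["pos"].to_numpy()
    chrom = sm["chrom"].astype(str).to_numpy()
    for rec in targets.itertuples():
        same = chrom == str(rec.chrom)
        dist = np.minimum(np.abs(pos - rec.start), np.abs(pos - rec.end))
        inside = (pos >= rec.start) & (pos <= rec.end)
        near = same & (inside | (dist < trans_mb * 1_000_000))
        ok &= ~near
    return np.flatnonzero(ok)


# ---------------------------------------------------------------------------
# Writers for the panel, expression, and phenotype tables
# ---------------------------------------------------------------------------

def write_panel_bed(panel: pd.DataFrame, path: str | Path) -> None:
    """BED6 (0-based half-open) with "gene:branch" in the name field."""
    bed = pd.DataFrame({
        "chrom": panel["chrom"],
        "start": panel["start"] - 1,
        "end": panel["end"],
        "name": panel["gene"].astype(str) + ":" + panel["branch"].astype(str),
        "score": 0,
        "strand": panel["strand"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_panel_gff3(panel: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in panel.itertuples():
            attrs = f"ID={rec.gene};branch={rec.branch}"
            fh.write(f"{rec.chrom}\tteqhot\tgene\t{rec.start}\t{rec.end}\t.\t"
                     f"{rec.strand}\t.\t{attrs}\n")


def read_panel_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"],
                      dtype={"chrom": str})
    name = bed["name"].str.split(":", n=1)
    panel = pd.DataFrame({
        "gene": name.str[0],
        "chrom": bed["chrom"],
        "start": bed["start"] + 1,
        "end": bed["end"],
        "strand": bed["strand"],
        "branch": name.str[1],
    })
    panel["tss"] = np.where(panel["strand"] == "+", panel["start"], panel["end"])
    return panel[["gene", "chrom", "start", "end", "strand", "tss", "branch"]]


def write_expression_tsv(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_phenotypes_tsv(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"line": str})
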