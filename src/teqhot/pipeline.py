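"""End-to-end orchestration and seeded validation studies.

``run_pipeline`` drives the full analysis from one config: simulate (or
load) inputs, MAF-filter, scan every panel gene per tissue, classify
cis/trans, call the three hotspot tiers, compute analytic and permutation
nulls, build the pathway expression index and map it, annotate candidate
genes, and test hotspot-SNP overlap with the phenotype traits. Every stage
writes TSV outputs plus a manifest with parameter values and output hashes;
identical configs produce byte-identical outputs.

The module also hosts the planted-regulator studies used to validate the
method end to end on synthetic data: regulator recovery across seeds, the
null false-positive rate of the scan, and per-tissue sign-flip divergence.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import candidates as cand
from . import hotspots as hs
from . import indices as ix
from . import nulls, scan, sim
from .genotypes import GenotypeMatrix, recode_and_filter, write_dosage_tsv, write_vcf

logger = logging.getLogger("teqhot")


@dataclass
class Thresholds:
    """All genomic and statistical cutoffs, defaulting to the values used
    throughout: 50 kb cis, 1 Mb trans, 250 kb top-SNP windows, 40 kb hotspot
    windows, 125 kb candidate windows, 8 genes, p <= 1e-4, MAF >= 0.05."""

    cis_kb: float = 50.0
    trans_mb: float = 1.0
    topsnp_window_kb: float = 250.0
    hotspot_window_kb: float = 40.0
    candidate_window_kb: float = 125.0
    max_candidates_per_side: int = 3
    min_genes: int = 8
    p_max: float = 1e-4
    maf_min: float = 0.05

    def __post_init__(self) -> None:
        for name in ("cis_kb", "trans_mb", "topsnp_window_kb",
                     "hotspot_window_kb", "candidate_window_kb", "p_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineConfig:
    sim: sim.SimConfig | None = None
    input_paths: dict | None = None          # genotypes/annotation/expression/phenotypes
    thresholds: Thresholds = field(default_factory=Thresholds)
    tissues: tuple[str, ...] = ("L3Base", "LMAD", "LMAN")
    index_branch: str = "chlorophyll"
    n_permutations: int = 1000
    count_mode: str = "associations"
    phenotype: sim.PhenotypeSimSpec | None = None
    out_dir: str = "teqhot_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.input_paths is None):
            raise ValueError("config must provide exactly one of sim / input_paths")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = dict(raw)
        if "sim" in kwargs and kwargs["sim"] is not None:
            simkw = dict(kwargs["sim"])
            regs = [
                sim.PlantedRegulator(
                    snp_index=r["snp_index"],
                    effect_sizes=dict(r["effect_sizes"]),
                    sign_flip_genes=frozenset(r.get("sign_flip_genes", ())),
                    flip_tissue=r.get("flip_tissue", ""),
                )
                for r in simkw.pop("regulator_spec", [])
            ]
            simkw["maf_range"] = tuple(simkw.get("maf_range", (0.02, 0.5)))
            kwargs["sim"] = sim.SimConfig(regulator_spec=tuple(regs), **simkw)
        if "thresholds" in kwargs and kwargs["thresholds"] is not None:
            kwargs["thresholds"] = Thresholds(**kwargs["thresholds"])
        if "phenotype" in kwargs and kwargs["phenotype"] is not None:
            kwargs["phenotype"] = sim.PhenotypeSimSpec(**kwargs["phenotype"])
        if "tissues" in kwargs:
            kwargs["tissues"] = tuple(kwargs["tissues"])
        return cls(**kwargs)


def demo_config(out_dir: str = "teqhot_demo", seed: int = 1) -> PipelineConfig:
    """A bundled desk-scale run: 300 lines, 1,200 SNPs, 70 panel genes, one
    planted trans regulator with 10 targets (one with a daytime sign flip),
    and a mutant-only phenotype at the regulator SNP."""
    base = sim.SimConfig(n_lines=300, n_snps=1200, n_panel_genes=70,
                         cis_effect_sd=0.5, noise_sd=0.5, seed=seed)
    gt = sim.simulate_genotypes(base)
    panel = sim.simulate_gene_panel(base)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    targets = sorted(rng.choice(panel["gene"].to_numpy(), size=10, replace=False))
    pool = sim.trans_snp_candidates(gt, panel, targets)
    snp_index = int(pool[rng.integers(len(pool))])
    reg = sim.PlantedRegulator(
        snp_index=snp_index,
        effect_sizes={g: 0.5 for g in targets},
        sign_flip_genes=frozenset({targets[0]}),
        flip_tissue="LMAD",
    )
    cfg = dataclasses.replace(base, regulator_spec=(reg,))
    pheno = sim.PhenotypeSimSpec(focal_snp=snp_index, mutant_effect=2.0,
                                 wt_effect=0.0, trait_mean=30.0, trait_sd=1.0)
    return PipelineConfig(sim=cfg, phenotype=pheno, out_dir=out_dir,
                          tissues=("L3Base", "LMAD", "LMAN"))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _StageWriter:
    """Tracks files written per stage so failures leave no partial outputs."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.manifest: list[dict] = []

    def run(self, name: str, params: dict, fn, inputs: list[Path] = ()):
        written: list[Path] = []

        def emit(filename: str, writer) -> Path:
            path = self.out_dir / filename
            writer(path)
            written.append(path)
            return path

        try:
            result = fn(emit)
        except Exception as exc:
            for path in written:
                path.unlink(missing_ok=True)
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        self.manifest.append({
            "stage": name,
            "parameters": params,
            "inputs": {str(p.name): _sha256(Path(p)) for p in inputs},
            "outputs": {p.name: _sha256(p) for p in written},
        })
        return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write outputs + manifest.json + summary.json under
    ``config.out_dir``, and return the summary dict."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    stages = _StageWriter(out_dir)
    summary: dict = {"tissues": list(config.tissues)}

    # ---- inputs: simulate or load -------------------------------------
    if config.sim is not None:
        sc = config.sim

        def _simulate(emit):
            gt = sim.simulate_genotypes(sc)
            panel = sim.simulate_gene_panel(sc)
            expr = {t: sim.simulate_expression(gt, panel, sc, t)
                    for t in config.tissues}
            emit("genotypes.vcf", lambda p: write_vcf(gt, p, sc.chrom_lengths))
            emit("genotypes.dosage.tsv", lambda p: write_dosage_tsv(gt, p))
            emit("panel.bed", lambda p: sim.write_panel_bed(panel, p))
            emit("panel.gff3", lambda p: sim.write_panel_gff3(panel, p))
            for t in config.tissues:
                emit(f"expression.{t}.tsv",
                     lambda p, t=t: sim.write_expression_tsv(expr[t], p))
            pheno = None
            if config.phenotype is not None:
                pheno = sim.simulate_phenotypes(gt, config.phenotype, sc.seed)
                emit("phenotypes.tsv", lambda p: sim.write_phenotypes_tsv(pheno, p))
            return gt, panel, expr, pheno, sc.chrom_lengths

        gt, panel, expr, pheno, chrom_lengths = stages.run(
            "simulate", {"seed": sc.seed, "n_lines": sc.n_lines,
                         "n_snps": sc.n_snps, "n_panel_genes": sc.n_panel_genes},
            _simulate)
    else:
        paths = config.input_paths

        def _load(emit):
            from .genotypes import read_dosage_tsv, read_vcf

            gpath = Path(paths["genotypes"])
            gt = read_vcf(gpath) if gpath.suffix == ".vcf" else read_dosage_tsv(gpath)
            panel = sim.read_panel_bed(paths["annotation"])
            expr = {t: sim.read_expression_tsv(paths["expression"][t])
                    for t in config.tissues}
            pheno = (sim.read_phenotypes_tsv(paths["phenotypes"])
                     if paths.get("phenotypes") else None)
            lengths = {}
            for chrom, grp in gt.snp_map.groupby("chrom", sort=False):
                lengths[str(chrom)] = int(grp["pos"].max())
            return gt, panel, expr, pheno, lengths

        gt, panel, expr, pheno, chrom_lengths = stages.run(
            "load", {"paths": {k: str(v) for k, v in paths.items()
                               if not isinstance(v, dict)}}, _load)

    # ---- MAF filter ----------------------------------------------------
    def _filter(emit):
        filtered = recode_and_filter(gt, th.maf_min)
        emit("genotypes.filtered.dosage.tsv", lambda p: write_dosage_tsv(filtered, p))
        return filtered

    filtered = stages.run("filter", {"maf_min": th.maf_min}, _filter)
    summary["n_snps_raw"] = gt.n_snps
    summary["n_snps_filtered"] = filtered.n_snps

    # ---- association scans --------------------------------------------
    def _scan(emit):
        tables = {}
        for t in config.tissues:
            tab = scan.scan_panel(filtered, expr[t], t,
                                  scan.ScanConfig(maf_min=th.maf_min,
                                                  p_report_max=th.p_max))
            tables[t] = tab
            emit(f"associations.{t}.tsv",
                 lambda p, tab=tab: scan.write_association_tsv(tab, p))
        return tables

    assoc = stages.run("scan", {"p_max": th.p_max}, _scan)
    summary["n_associations"] = {t: len(a) for t, a in assoc.items()}

    # ---- cis/trans classification -------------------------------------
    def _classify(emit):
        out = {}
        for t in config.tissues:
            cls = hs.classify_cis_trans(assoc[t], panel, th.cis_kb, th.trans_mb)
            out[t] = cls
            emit(f"classified.{t}.tsv", lambda p, cls=cls: cls.to_csv(p, sep="\t", index=False))
        return out

    classified = stages.run("classify", {"cis_kb": th.cis_kb, "trans_mb": th.trans_mb},
                            _classify)
    summary["n_cis"] = {t: int((c["class"] == hs.CIS).sum()) for t, c in classified.items()}
    summary["n_trans"] = {t: int((c["class"] == hs.TRANS).sum()) for t, c in classified.items()}

    # ---- hotspot tiers -------------------------------------------------
    def _hotspots(emit):
        tiers = {"hot_snp": [], "hot_top_snp": [], "window_hotspot": []}
        tops = {}
        for t in config.tissues:
            trans = classified[t][classified[t]["class"] == hs.TRANS]
            top = hs.select_top_snps(trans, th.topsnp_window_kb)
            tops[t] = top
            emit(f"top_snps.{t}.tsv", lambda p, top=top: top.to_csv(p, sep="\t", index=False))
            tiers["hot_snp"] += hs.detect_hot_snps(trans, th.p_max, th.min_genes)
            tiers["hot_top_snp"] += hs.detect_hot_top_snps(top, th.min_genes, th.p_max)
            tiers["window_hotspot"] += hs.detect_hotspot_windows(
                top, th.hotspot_window_kb, th.min_genes, th.p_max)
        for tier, calls in tiers.items():
            emit(f"{tier}s.tsv", lambda p, calls=calls: hs.write_calls_tsv(calls, p))
            emit(f"{tier}s.bed", lambda p, calls=calls: hs.write_calls_bed(calls, p))
        return tiers, tops

    (tiers, tops) = stages.run(
        "hotspots", {"min_genes": th.min_genes,
                     "topsnp_window_kb": th.topsnp_window_kb,
                     "hotspot_window_kb": th.hotspot_window_kb}, _hotspots)
    summary["hotspot_counts"] = {
        tier: {t: sum(1 for c in calls if c.tissue == t) for t in config.tissues}
        for tier, calls in tiers.items()
    }

    # ---- null models ---------------------------------------------------
    def _nulls(emit):
        n_windows = hs.n_windows_in_genome(chrom_lengths, th.hotspot_window_kb)
        n_genes = len(panel)
        rows = []
        for t in config.tissues:
            n_top = len(tops[t])
            ncfg = nulls.NullConfig(
                n_genes=n_genes, n_windows=n_windows, min_genes=th.min_genes,
                n_permutations=config.n_permutations,
                seed=(config.sim.seed if config.sim else 0),
                count_mode=config.count_mode)
            analytic = nulls.binomial_hotspot_expectation(n_top, ncfg)
            observed = summary["hotspot_counts"]["window_hotspot"][t]
            tallies = (tops[t].groupby("gene").size()
                       .reindex(panel["gene"], fill_value=0).to_numpy())
            perm = nulls.permutation_fdr(tallies, observed, ncfg)
            rows.append({
                "tissue": t, "n_top_snps": n_top, "n_windows": n_windows,
                "per_window_prob": analytic.per_window_prob,
                "tail_prob": analytic.tail_prob,
                "expected_windows": analytic.expected_windows,
                "observed_windows": observed,
                "null_mean_per_perm": perm.null_mean_per_perm,
                "permutation_fdr": perm.fdr,
            })
        out = pd.DataFrame(rows)
        emit("null_models.tsv", lambda p: out.to_csv(p, sep="\t", index=False))
        return out

    null_table = stages.run("null", {"n_permutations": config.n_permutations,
                                     "count_mode": config.count_mode}, _nulls)
    summary["null_models"] = null_table.to_dict(orient="records")

    # ---- expression index + index GWAS --------------------------------
    def _index(emit):
        gene_set = panel.loc[panel["branch"] == config.index_branch, "gene"].tolist()
        hits = {}
        for t in config.tissues:
            z = ix.zscore_matrix(expr[t])
            idx = ix.expression_index(z, gene_set, f"{config.index_branch}_index")
            frame = idx.rename("index").rename_axis("line").reset_index()
            frame["set"] = config.index_branch
            emit(f"index.{t}.tsv", lambda p, f=frame: f.to_csv(p, sep="\t", index=False))
            res = scan.scan_gene(filtered, idx.reindex(filtered.line_ids).to_numpy())
            sig = res[res["p_value"] <= th.p_max]
            emit(f"index_gwas.{t}.tsv", lambda p, s=sig: s.to_csv(p, sep="\t", index=False))
            hits[t] = sig["snp"].tolist()
        return hits

    index_hits = stages.run("index", {"branch": config.index_branch}, _index)
    summary["index_gwas_hits"] = {t: len(v) for t, v in index_hits.items()}

    # ---- candidate genes ----------------------------------------------
    def _candidates(emit):
        frames = []
        for call in tiers["hot_snp"] + tiers["hot_top_snp"]:
            frames.append(cand.annotate_hot_snp(
                call.chrom, call.start, panel,
                th.max_candidates_per_side, th.candidate_window_kb))
        for call in tiers["window_hotspot"]:
            top = tops[call.tissue]
            members = top[(top["chrom"].astype(str) == call.chrom)
                          & (top["pos"] >= call.start) & (top["pos"] < call.end)]
            if members.empty:
                continue
            frames.append(cand.annotate_hotspot(
                call, members["pos"].unique(), panel, th.candidate_window_kb))
        table = (pd.concat(frames, ignore_index=True) if frames
                 else pd.DataFrame(columns=cand.CANDIDATE_COLUMNS))
        table = table.drop_duplicates().reset_index(drop=True)
        emit("candidates.tsv", lambda p: table.to_csv(p, sep="\t", index=False))
        return table

    cand_table = stages.run("candidates",
                            {"window_kb": th.candidate_window_kb}, _candidates)
    summary["n_candidates"] = len(cand_table)

    # ---- hotspot-SNP x phenotype overlap -------------------------------
    if pheno is not None:
        def _overlap(emit):
            traits = ix.derive_ccm_traits(pheno).set_index("line")
            trait_cols = ["MT_CCMI", "WT_CCMI", "MT_CCMII", "WT_CCMII",
                          "Ratio_CCMI", "Diff_CCMI", "Ratio_CCMII", "Diff_CCMII"]
            member = set()
            for call in tiers["window_hotspot"]:
                top = tops[call.tissue]
                inside = top[(top["chrom"].astype(str) == call.chrom)
                             & (top["pos"] >= call.start) & (top["pos"] < call.end)]
                member |= set(inside["snp"])
            rows = []
            observed = 0
            if member:
                keep = np.flatnonzero(filtered.snp_map["snp"].isin(member))
                sub = filtered.take_snps(keep)
                aligned = traits.reindex(sub.line_ids)
                for col in trait_cols:
                    y = aligned[col].to_numpy(dtype=float)
                    res = scan.scan_gene(sub, y)
                    res["trait"] = col
                    rows.append(res)
                all_res = pd.concat(rows, ignore_index=True)
                observed = int((all_res["p_value"] <= th.p_max).sum())
                emit("overlap_scan.tsv",
                     lambda p: all_res.to_csv(p, sep="\t", index=False))
            result = nulls.overlap_fdr(len(member), len(trait_cols), th.p_max, observed)
            report = {
                "n_hotspot_snps": len(member), "n_traits": len(trait_cols),
                "p_threshold": th.p_max, "observed_hits": observed,
                "expected_hits": result.expected_windows, "fdr": result.fdr,
            }
            emit("overlap.json", lambda p: Path(p).write_text(
                json.dumps(report, indent=2, sort_keys=True)))
            return report

        summary["phenotype_overlap"] = stages.run(
            "overlap", {"p_max": th.p_max}, _overlap)

    # ---- manifest + summary -------------------------------------------
    (out_dir / "manifest.json").write_text(
        json.dumps(stages.manifest, indent=2, sort_keys=True, default=str))
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str))
    return summary


# ---------------------------------------------------------------------------
# Seeded validation studies (also used by scripts/acceptance.py)
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """Simulation design for the planted-regulator studies: 300 lines,
    1,200 SNPs on 10 x 20 Mb chromosomes, 70 panel genes, a regulator with
    10 targets at +0.5 expression units per allele, cis SD 0.5, noise SD 0.5."""

    n_lines: int = 300
    n_snps: int = 1200
    n_panel_genes: int = 70
    n_targets: int = 10
    effect: float = 0.5
    cis_effect_sd: float = 0.5
    noise_sd: float = 0.5


def _planted_setup(seed: int, design: StudyDesign, flip_first: bool = False,
                   flip_tissue: str = ""):
    base = sim.SimConfig(
        n_lines=design.n_lines, n_snps=design.n_snps,
        n_panel_genes=design.n_panel_genes, cis_effect_sd=design.cis_effect_sd,
        noise_sd=design.noise_sd, seed=seed)
    gt = sim.simulate_genotypes(base)
    panel = sim.simulate_gene_panel(base)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    targets = sorted(rng.choice(panel["gene"].to_numpy(), size=design.n_targets,
                                replace=False))
    pool = sim.trans_snp_candidates(gt, panel, targets)
    if not len(pool):
        raise RuntimeError("no trans SNP candidate for the drawn target set")
    snp_index = int(pool[rng.integers(len(pool))])
    reg = sim.PlantedRegulator(
        snp_index=snp_index,
        effect_sizes={g: design.effect for g in targets},
        sign_flip_genes=frozenset({targets[0]}) if flip_first else frozenset(),
        flip_tissue=flip_tissue)
    cfg = dataclasses.replace(base, regulator_spec=(reg,))
    return cfg, gt, panel, reg


def _tiers_for(filtered: GenotypeMatrix, expr: pd.DataFrame, panel: pd.DataFrame,
               tissue: str, th: Thresholds):
    table = scan.scan_panel(filtered, expr, tissue,
                            scan.ScanConfig(maf_min=th.maf_min, p_report_max=th.p_max))
    classified = hs.classify_cis_trans(table, panel, th.cis_kb, th.trans_mb)
    trans = classified[classified["class"] == hs.TRANS]
    top = hs.select_top_snps(trans, th.topsnp_window_kb)
    return {
        "trans": trans,
        "top": top,
        "hot_snps": hs.detect_hot_snps(trans, th.p_max, th.min_genes),
        "hot_top_snps": hs.detect_hot_top_snps(top, th.min_genes, th.p_max),
        "window_hotspots": hs.detect_hotspot_windows(
            top, th.hotspot_window_kb, th.min_genes, th.p_max),
    }


def regulator_recovery_replicate(seed: int, design: StudyDesign | None = None,
                                 tissue: str = "L3Base") -> dict:
    """One seeded replicate of the recovery study.

    Simulates the planted architecture, runs the scan and all three hotspot
    tiers, and reports whether the regulator was recovered at each tier with
    exactly its target-gene set, whether every recovered effect lies within
    3 SEs of the planted value, and the index-GWAS p-value at the regulator.
    """
    design = design or StudyDesign()
    th = Thresholds()
    cfg, gt, panel, reg = _planted_setup(seed, design)
    expr = sim.simulate_expression(gt, panel, cfg, tissue)
    filtered = recode_and_filter(gt, th.maf_min)
    reg_snp = gt.snp_map.loc[reg.snp_index, "snp"]
    res = _tiers_for(filtered, expr, panel, tissue, th)
    targets = set(reg.target_genes)

    reg_chrom, reg_pos = reg_snp.rsplit("-", 1)
    reg_pos = int(reg_pos)

    def tier_hit(calls, exact: bool):
        for c in calls:
            at_reg = c.snp == reg_snp or (
                c.snp is None and c.chrom == reg_chrom and c.start <= reg_pos < c.end)
            if at_reg and (not exact or set(c.genes) == targets):
                return True
        return False

    # planted-effect recovery: |beta_hat - beta| <= 3 SE, using the scan SE
    n_within = 0
    j = int(np.flatnonzero(filtered.snp_map["snp"] == reg_snp)[0])
    for gene in sorted(targets):
        g = scan.scan_gene(filtered, expr.loc[gene].reindex(filtered.line_ids).to_numpy())
        row = g.iloc[j]
        if abs(row["beta"] - design.effect) <= 3 * row["se"]:
            n_within += 1

    z = ix.zscore_matrix(expr)
    idx = ix.expression_index(z, sorted(targets), "planted_set")
    index_scan = scan.scan_gene(filtered, idx.reindex(filtered.line_ids).to_numpy())
    index_p = float(index_scan.iloc[j]["p_value"])

    return {
        "seed": seed,
        "hot_snp": tier_hit(res["hot_snps"], exact=False),
        "hot_snp_exact": tier_hit(res["hot_snps"], exact=True),
        "hot_top_snp": tier_hit(res["hot_top_snps"], exact=False),
        "hot_top_snp_exact": tier_hit(res["hot_top_snps"], exact=True),
        "window_hotspot": tier_hit(res["window_hotspots"], exact=False),
        "window_hotspot_exact": tier_hit(res["window_hotspots"], exact=True),
        "n_targets": len(targets),
        "n_targets_within_3se": n_within,
        "index_p": index_p,
        "index_detected": index_p <= th.p_max,
    }


def regulator_recovery_study(n_replicates: int = 100, base_seed: int = 0,
                             design: StudyDesign | None = None) -> pd.DataFrame:
    """Run ``regulator_recovery_replicate`` across seeds; one row per seed."""
    rows = [regulator_recovery_replicate(base_seed * 100_000 + i, design)
            for i in range(n_replicates)]
    return pd.DataFrame(rows)


def null_scan_positive_rate(seed: int = 0, n_lines: int = 300,
                            n_snps: int = 5000, n_genes: int = 20,
                            p_max: float = 1e-4):
    """Fraction of scan tests at p <= p_max under a null simulation with no
    planted effects. Returns (rate, n_tests)."""
    cfg = sim.SimConfig(n_lines=n_lines, n_snps=n_snps, n_panel_genes=n_genes,
                        cis_effect_sd=0.0, noise_sd=1.0, seed=seed)
    gt = sim.simulate_genotypes(cfg)
    panel = sim.simulate_gene_panel(cfg)
    expr = sim.simulate_expression(gt, panel, cfg, "null")
    filtered = recode_and_filter(gt, 0.05)
    table = scan.scan_panel(filtered, expr, "null",
                            scan.ScanConfig(p_report_max=p_max))
    n_tests = table.attrs["n_tests"]
    return len(table) / n_tests, n_tests


def sign_flip_divergence(seed: int = 0, design: StudyDesign | None = None,
                         flip_tissue: str = "LMAD",
                         other_tissue: str = "LMAN") -> dict:
    """Divergence fractions for a planted focal-gene sign flip.

    The regulator's first target has its effect sign inverted in
    ``flip_tissue`` only; the divergence tabulation over window-hotspot SNPs
    should report fraction 1.0 there and 0.0 in ``other_tissue``.
    """
    design = design or StudyDesign()
    th = Thresholds()
    cfg, gt, panel, reg = _planted_setup(seed, design, flip_first=True,
                                         flip_tissue=flip_tissue)
    focal = sorted(reg.sign_flip_genes)[0]
    filtered = recode_and_filter(gt, th.maf_min)
    out = {"focal_gene": focal}
    for tissue in (flip_tissue, other_tissue):
        expr = sim.simulate_expression(gt, panel, cfg, tissue)
        res = _tiers_for(filtered, expr, panel, tissue, th)
        _, summary = hs.divergence_tabulation(
            res["window_hotspots"], res["trans"], focal,
            min_other=2, p_max=th.p_max, panel=panel)
        out[tissue] = summary.get(tissue, float("nan"))
    return out
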