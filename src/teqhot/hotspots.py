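"""Cis/trans classification and trans-regulatory hotspot detection.

Three tiers of hotspot, from single positions to genomic windows:

* hot SNP - a single trans-acting SNP associated (p <= p_max) with
  ``min_genes`` or more distinct panel genes in one tissue;
* hot top SNP - a position that is the per-(gene, 250 kb window) best trans
  SNP for ``min_genes`` or more genes;
* window hotspot - a 40 kb exclusive window containing top SNPs for
  ``min_genes`` or more genes.

Classification uses gene-body edges: within ``cis_kb`` of the gene is cis;
at least ``trans_mb`` away, or on another chromosome, is trans; the band in
between is "proximal-excluded" (neither class is claimed for it). All
windows are half-open, anchored at coordinate 0, over 1-based positions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

logger = logging.getLogger("teqhot")

CIS, TRANS, PROXIMAL = "cis", "trans", "proximal-excluded"


@dataclass
class HotspotCall:
    """One hotspot at any tier, with its member genes and signed effects.

    ``start``/``end`` delimit the locus: for single-SNP tiers both equal the
    SNP position; for window hotspots they are the half-open window bounds.
    """

    tier: str
    chrom: str
    start: int
    end: int
    tissue: str
    genes: tuple[str, ...]
    signed_effects: dict[str, float] = field(default_factory=dict)
    snp: str | None = None

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def classify_cis_trans(associations: pd.DataFrame, panel: pd.DataFrame,
                       cis_kb: float = 50, trans_mb: float = 1) -> pd.DataFrame:
    """Label each association cis / trans / proximal-excluded.

    Distance is from the SNP to the nearest gene-body edge (0 inside the
    gene); it is left NaN for different-chromosome pairs, which are trans.

    Raises
    ------
    KeyError
        If an association's gene is missing from the annotation.
    """
    missing = set(associations["gene"]) - set(panel["gene"])
    if missing:
        raise KeyError(f"genes absent from annotation: {sorted(missing)}")
    out = associations.merge(
        panel[["gene", "chrom", "start", "end"]].rename(columns={
            "chrom": "gene_chrom", "start": "gene_start", "end": "gene_end"}),
        on="gene", how="left",
    )
    same = out["chrom"].astype(str).to_numpy() == out["gene_chrom"].astype(str).to_numpy()
    pos = out["pos"].to_numpy()
    inside = (pos >= out["gene_start"].to_numpy()) & (pos <= out["gene_end"].to_numpy())
    edge = np.minimum(np.abs(pos - out["gene_start"].to_numpy()),
                      np.abs(pos - out["gene_end"].to_numpy()))
    dist = np.where(inside, 0, edge).astype(float)
    dist[~same] = np.nan

    cls = np.full(len(out), PROXIMAL, dtype=object)
    cls[same & (dist <= cis_kb * 1_000)] = CIS
    cls[~same | (dist >= trans_mb * 1_000_000)] = TRANS
    out = out.drop(columns=["gene_chrom", "gene_start", "gene_end"])
    out["class"] = cls
    out["distance"] = dist
    return out


def window_index(pos: np.ndarray | pd.Series, window_bp: int) -> np.ndarray:
    """Index of the half-open window [i*W, (i+1)*W) containing each position."""
    return np.asarray(pos) // window_bp


def n_windows_in_genome(chrom_lengths: dict[str, int], window_kb: float = 40) -> int:
    """Total exclusive windows tiling a genome (ceiling per chromosome)."""
    w = int(window_kb * 1_000)
    return sum(math.ceil(length / w) for length in chrom_lengths.values())


def select_top_snps(trans_assoc: pd.DataFrame, window_kb: float = 250) -> pd.DataFrame:
    """Per (gene, tissue, 250 kb window), keep the single lowest-p trans SNP.

    Ties break to the smaller position, then lexicographic SNP id, so the
    result is deterministic. Input rows must all be classified trans.
    """
    if "class" in trans_assoc.columns and not (trans_assoc["class"] == TRANS).all():
        raise ValueError("select_top_snps expects trans-classified associations only")
    if trans_assoc.empty:
        out = trans_assoc.copy()
        out["window_index"] = pd.Series(dtype=int)
        return out
    out = trans_assoc.copy()
    out["window_index"] = window_index(out["pos"], int(window_kb * 1_000))
    out = out.sort_values(["p_value", "pos", "snp"], kind="mergesort")
    out = out.groupby(["gene", "tissue", "chrom", "window_index"], sort=False,
                      as_index=False).head(1)
    return out.reset_index(drop=True)


def _calls_from_groups(grouped, tier: str, tissue_col: str = "tissue") -> list[HotspotCall]:
    calls = []
    for (chrom, start, end, tissue, snp), grp in grouped:
        dedup = grp.sort_values("p_value", kind="mergesort").drop_duplicates("gene")
        calls.append(HotspotCall(
            tier=tier, chrom=str(chrom), start=int(start), end=int(end),
            tissue=tissue, genes=tuple(sorted(dedup["gene"])),
            signed_effects=dict(zip(dedup["gene"], dedup["beta"])),
            snp=snp,
        ))
    calls.sort(key=lambda c: (c.tissue, c.chrom, c.start, c.end))
    return calls


def detect_hot_snps(trans_assoc: pd.DataFrame, p_max: float = 1e-4,
                    min_genes: int = 8) -> list[HotspotCall]:
    """Single SNPs with trans associations to >= min_genes distinct genes."""
    sig = trans_assoc[trans_assoc["p_value"] <= p_max]
    if sig.empty:
        return []
    counts = sig.groupby(["snp", "tissue"])["gene"].nunique()
    hot = set(counts[counts >= min_genes].index)
    if not hot:
        return []
    key = list(zip(sig["snp"], sig["tissue"]))
    sig = sig[[k in hot for k in key]]
    grouped = (
        ((chrom, pos, pos, tissue, snp), grp)
        for (snp, tissue, chrom, pos), grp in
        sig.groupby(["snp", "tissue", "chrom", "pos"], sort=False)
    )
    calls = _calls_from_groups(grouped, "hot_snp")
    logger.info("detect_hot_snps: %d calls (p <= %g, >= %d genes)",
                len(calls), p_max, min_genes)
    return calls


def detect_hot_top_snps(top_snps: pd.DataFrame, min_genes: int = 8,
                        p_max: float = 1e-4) -> list[HotspotCall]:
    """Positions that are the top trans SNP for >= min_genes genes (per tissue)."""
    sig = top_snps[top_snps["p_value"] <= p_max]
    if sig.empty:
        return []
    counts = sig.groupby(["chrom", "pos", "tissue"])["gene"].nunique()
    hot = set(counts[counts >= min_genes].index)
    if not hot:
        return []
    key = list(zip(sig["chrom"], sig["pos"], sig["tissue"]))
    sig = sig[[k in hot for k in key]]
    grouped = (
        ((chrom, pos, pos, tissue, snp), grp)
        for (chrom, pos, tissue, snp), grp in
        sig.groupby(["chrom", "pos", "tissue", "snp"], sort=False)
    )
    return _calls_from_groups(grouped, "hot_top_snp")


def detect_hotspot_windows(top_snps: pd.DataFrame, window_kb: float = 40,
                           min_genes: int = 8, p_max: float = 1e-4) -> list[HotspotCall]:
    """Exclusive windows whose resident top SNPs cover >= min_genes genes."""
    sig = top_snps[top_snps["p_value"] <= p_max]
    if sig.empty:
        return []
    w = int(window_kb * 1_000)
    sig = sig.assign(hotspot_window=window_index(sig["pos"], w))
    counts = sig.groupby(["chrom", "hotspot_window", "tissue"])["gene"].nunique()
    hot = set(counts[counts >= min_genes].index)
    if not hot:
        return []
    key = list(zip(sig["chrom"], sig["hotspot_window"], sig["tissue"]))
    sig = sig[[k in hot for k in key]]
    grouped = (
        ((chrom, int(win) * w, (int(win) + 1) * w, tissue, None), grp)
        for (chrom, win, tissue), grp in
        sig.groupby(["chrom", "hotspot_window", "tissue"], sort=False)
    )
    return _calls_from_groups(grouped, "window_hotspot")


def effect_direction_matrix(calls: list[HotspotCall]):
    """Signed effect matrix over hotspot calls, with concordance flags and a
    Ward-linkage dendrogram row order.

    Rows are calls (label "tier:chrom:start-end:tissue"), columns the union
    of member genes; entries are the member betas, 0 where a gene is not a
    significant member of the call. A row is concordant when all its nonzero
    entries share one sign. Row order comes from agglomerative clustering
    with Ward linkage on Euclidean distances between effect rows.

    Returns (matrix, concordant, order): DataFrame, boolean Series aligned to
    the matrix rows, and the leaf-order list of row labels.
    """
    if not calls:
        raise ValueError("effect_direction_matrix requires at least one call")
    genes = sorted({g for c in calls for g in c.genes})
    labels = [f"{c.tier}:{c.chrom}:{c.start}-{c.end}:{c.tissue}" for c in calls]
    mat = pd.DataFrame(0.0, index=labels, columns=genes)
    for lab, c in zip(labels, calls):
        for g, b in c.signed_effects.items():
            mat.loc[lab, g] = b
    signs = np.sign(mat.to_numpy())
    concordant = pd.Series(
        [(row[row != 0].size == 0) or (len(set(row[row != 0])) == 1) for row in signs],
        index=labels,
    )
    if len(calls) > 1:
        link = hierarchy.ward(mat.to_numpy())
        order = [labels[i] for i in hierarchy.leaves_list(link)]
    else:
        order = list(labels)
    return mat, concordant, order


def divergence_tabulation(hotspots: list[HotspotCall], associations: pd.DataFrame,
                          focal_gene: str, min_other: int = 2,
                          p_max: float = 1e-4, panel: pd.DataFrame | None = None):
    """Per-SNP sign-divergence report for one focal gene inside hotspots.

    For every SNP inside any window hotspot that affects the focal gene and
    at least ``min_other`` other genes at p <= p_max (same tissue as the
    hotspot), reports whether the focal-gene effect sign opposes the majority
    sign of the other genes. Returns (table, summary) where summary maps
    tissue -> divergent fraction.
    """
    if panel is not None and focal_gene not in set(panel["gene"]):
        raise KeyError(f"focal gene {focal_gene!r} absent from panel")
    if panel is None and focal_gene not in set(associations["gene"]):
        raise KeyError(f"focal gene {focal_gene!r} absent from associations")
    sig = associations[associations["p_value"] <= p_max]
    rows = []
    for call in hotspots:
        inside = sig[(sig["tissue"] == call.tissue)
                     & (sig["chrom"].astype(str) == call.chrom)
                     & (sig["pos"] >= call.start) & (sig["pos"] < call.end)]
        for snp, grp in inside.groupby("snp", sort=False):
            focal = grp[grp["gene"] == focal_gene]
            others = grp[grp["gene"] != focal_gene].drop_duplicates("gene")
            if focal.empty or len(others) < min_other:
                continue
            focal_sign = int(np.sign(focal["beta"].iloc[0]))
            pos_n = int((others["beta"] > 0).sum())
            neg_n = int((others["beta"] < 0).sum())
            majority = 1 if pos_n > neg_n else (-1 if neg_n > pos_n else 0)
            rows.append({
                "tissue": call.tissue, "snp": snp,
                "chrom": call.chrom, "pos": int(focal["pos"].iloc[0]),
                "focal_sign": focal_sign, "n_other": len(others),
                "majority_sign": majority,
                "divergent": majority != 0 and focal_sign == -majority,
            })
    table = pd.DataFrame(rows, columns=["tissue", "snp", "chrom", "pos",
                                        "focal_sign", "n_other",
                                        "majority_sign", "divergent"])
    table = table.drop_duplicates(["tissue", "snp"]).reset_index(drop=True)
    summary = {t: float(grp["divergent"].mean())
               for t, grp in table.groupby("tissue")}
    return table, summary


# ---------------------------------------------------------------------------
# Tabular export of hotspot calls
# ---------------------------------------------------------------------------

def calls_to_frame(calls: list[HotspotCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "tier": c.tier, "chrom": c.chrom, "start": c.start, "end": c.end,
        "tissue": c.tissue, "n_genes": c.n_genes,
        "genes": ";".join(c.genes),
        "snp": c.snp if c.snp is not None else "",
    } for c in calls], columns=["tier", "chrom", "start", "end", "tissue",
                                "n_genes", "genes", "snp"])


def write_calls_tsv(calls: list[HotspotCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def write_calls_bed(calls: list[HotspotCall], path) -> None:
    """BED (0-based half-open) intervals for genome-browser use."""
    with open(path, "w") as fh:
        for c in calls:
            start0 = max(c.start - 1, 0) if c.tier != "window_hotspot" else c.start
            end0 = c.end if c.tier != "window_hotspot" else c.end
            name = f"{c.tier}|{c.tissue}|{c.n_genes}"
            fh.write(f"{c.chrom}\t{start0}\t{end0}\t{name}\n")
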