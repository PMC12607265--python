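"""Candidate-gene annotation around hot SNPs and window hotspots.

Hot SNPs get up to 3 genes per side whose transcription start sites lie
within 125 kb of the SNP, ranked 1..3 by TSS distance (1 = closest);
window hotspots keep every gene overlapping the SNP-defined boundary as
"inside" plus the nearest flanking gene on each side within 125 kb of the
edge. Upstream/downstream is the genome's + orientation relative to the
locus, not gene strand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hotspots import HotspotCall

CANDIDATE_COLUMNS = ["locus", "gene", "side", "tss_distance", "rank"]


def _empty() -> pd.DataFrame:
    return pd.DataFrame(columns=CANDIDATE_COLUMNS)


def annotate_hot_snp(chrom: str, pos: int, annotation: pd.DataFrame,
                     max_per_side: int = 3, window_kb: float = 125) -> pd.DataFrame:
    """Candidates for a single hot (top) SNP position.

    A gene whose body overlaps the SNP is a single "inside" record with
    distance 0 and rank 1. Flanking genes are ranked per side by TSS
    distance (boundary inclusive at window_kb); ties break by lower gene
    start, then lexicographic id.
    """
    locus = f"{chrom}-{pos}"
    ann = annotation[annotation["chrom"].astype(str) == str(chrom)]
    if ann.empty:
        return _empty()
    ann = ann.sort_values(["start", "gene"], kind="mergesort")
    rows = []
    inside = ann[(ann["start"] <= pos) & (ann["end"] >= pos)]
    for rec in inside.itertuples():
        rows.append({"locus": locus, "gene": rec.gene, "side": "inside",
                     "tss_distance": 0, "rank": 1})
    flank = ann[~ann["gene"].isin(inside["gene"])].copy()
    flank["tss_distance"] = (flank["tss"] - pos).abs()
    flank = flank[flank["tss_distance"] <= int(window_kb * 1_000)]
    flank["side"] = np.where(flank["tss"] < pos, "upstream", "downstream")
    for side, grp in flank.groupby("side"):
        grp = grp.sort_values(["tss_distance", "start", "gene"], kind="mergesort")
        for rank, rec in enumerate(grp.head(max_per_side).itertuples(), start=1):
            rows.append({"locus": locus, "gene": rec.gene, "side": side,
                         "tss_distance": int(rec.tss_distance), "rank": rank})
    out = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    return out.sort_values(["side", "rank"], kind="mergesort").reset_index(drop=True)


def annotate_hotspot(hotspot: HotspotCall, member_snps, annotation: pd.DataFrame,
                     window_kb: float = 125) -> pd.DataFrame:
    """Candidates for a window hotspot.

    The boundary is [min, max] of the member SNP positions. Genes whose body
    intersects the boundary are "inside" (no rank); the nearest gene on each
    side is a flanking candidate if its TSS is within window_kb of the edge.
    """
    member_snps = sorted(int(p) for p in member_snps)
    if not member_snps:
        raise ValueError("hotspot has no member SNPs")
    if hotspot.tier == "window_hotspot":
        bad = [p for p in member_snps if not hotspot.start <= p < hotspot.end]
        if bad:
            raise ValueError(f"member SNPs outside the hotspot window: {bad}")
    lo, hi = member_snps[0], member_snps[-1]
    locus = f"{hotspot.chrom}:{lo}-{hi}:{hotspot.tissue}"
    ann = annotation[annotation["chrom"].astype(str) == str(hotspot.chrom)]
    ann = ann.sort_values(["start", "gene"], kind="mergesort")
    rows = []
    inside = ann[(ann["start"] <= hi) & (ann["end"] >= lo)]
    for rec in inside.itertuples():
        rows.append({"locus": locus, "gene": rec.gene, "side": "inside",
                     "tss_distance": 0, "rank": np.nan})
    flank = ann[~ann["gene"].isin(inside["gene"])].copy()
    max_d = int(window_kb * 1_000)
    left = flank[flank["tss"] < lo].assign(tss_distance=lambda d: lo - d["tss"])
    right = flank[flank["tss"] > hi].assign(tss_distance=lambda d: d["tss"] - hi)
    for side, grp in (("upstream", left), ("downstream", right)):
        grp = grp[grp["tss_distance"] <= max_d]
        if grp.empty:
            continue
        grp = grp.sort_values(["tss_distance", "start", "gene"], kind="mergesort")
        rec = next(grp.itertuples())
        rows.append({"locus": locus, "gene": rec.gene, "side": side,
                     "tss_distance": int(rec.tss_distance), "rank": 1})
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
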