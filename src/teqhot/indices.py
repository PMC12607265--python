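"""Z-score standardization, gene-set expression indices, and derived
chlorophyll-meter traits.

An expression index is the per-sample mean of per-gene Z-scores over a named
gene set; it aggregates coordinate expression shifts into a single trait that
can be mapped by GWAS exactly like a gene's expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("teqhot")


def zscore_matrix(expression: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene (row) to mean 0, SD 1 across samples.

    Sample SD (n-1 denominator) is used. Zero-variance genes become all-zero
    rows (logged), so they contribute nothing to any index without changing
    gene-set sizes.
    """
    if expression.shape[1] < 2:
        raise ValueError("Z-scores need at least 2 samples")
    vals = expression.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        logger.warning("%d zero-variance genes set to all-zero Z rows: %s",
                       flat.sum(), list(expression.index[flat][:5]))
    sd[flat] = 1.0
    z = (vals - mean) / sd
    z[flat, :] = 0.0
    return pd.DataFrame(z, index=expression.index, columns=expression.columns)


def expression_index(z: pd.DataFrame, gene_set, name: str,
                     direction: str = "none") -> pd.Series:
    """Per-sample unweighted mean of Z-scores over a gene set.

    ``direction`` tags the set ("induced", "repressed", or "none") and is
    carried in ``Series.attrs``.
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("gene set is empty")
    missing = [g for g in genes if g not in z.index]
    if missing:
        raise KeyError(f"genes absent from Z matrix: {missing}")
    idx = z.loc[genes].mean(axis=0)
    idx.name = name
    idx.attrs["gene_set_name"] = name
    idx.attrs["direction"] = direction
    return idx


def read_gene_set(path) -> tuple[list[str], str]:
    """Gene-set file: one id per line, optional tab-separated direction column."""
    genes, direction = [], "none"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            genes.append(parts[0])
            if len(parts) > 1:
                direction = parts[1]
    return genes, direction


def derive_ccm_traits(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Add Ratio_CCM (= MT/WT) and Diff_CCM (= WT - MT) per timepoint.

    Families with WT = 0 get a missing ratio (logged) rather than an error.
    """
    out = phenotypes.copy()
    for tp in ("CCMI", "CCMII"):
        mt, wt = out[f"MT_{tp}"], out[f"WT_{tp}"]
        zero = wt == 0
        if zero.any():
            logger.warning("%d families with WT_%s = 0; ratio set to NA",
                           int(zero.sum()), tp)
        out[f"Ratio_{tp}"] = np.where(zero, np.nan, mt / wt.replace(0, np.nan))
        out[f"Diff_{tp}"] = wt - mt
    return out
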