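"""Null models for hotspot counts and overlap testing.

Analytic null: if each of ``n_genes`` genes independently drops a top SNP
into a genomic window with probability p (the per-gene top-SNP count divided
by the number of windows), the number of genes co-occurring in one window is
Binomial(n_genes, p); the expected number of hotspot-containing windows is
the window count times the upper tail at ``min_genes``.

Permutation null: tallied associations are assigned independently and
uniformly to windows; a window is a null hotspot when it collects at least
``min_genes`` associations (count_mode="associations", the permissive
reading) or associations from at least ``min_genes`` distinct genes
(count_mode="genes", the criterion the hotspot definition actually uses).
Both modes are exposed because they differ and the choice matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class NullConfig:
    n_genes: int = 70
    n_windows: int = 62_500
    min_genes: int = 8
    n_permutations: int = 1_000
    seed: int = 0
    count_mode: str = "associations"

    def __post_init__(self) -> None:
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if not 0 < self.min_genes <= self.n_genes:
            raise ValueError("min_genes must be in [1, n_genes]")
        if self.count_mode not in ("associations", "genes"):
            raise ValueError("count_mode must be 'associations' or 'genes'")


@dataclass
class NullResult:
    """Null expectations; ``fdr`` is None when the observed count is zero."""

    per_window_prob: float | None = None
    tail_prob: float | None = None
    expected_windows: float | None = None
    null_mean_per_perm: float | None = None
    fdr: float | None = None
    null_counts: np.ndarray | None = None


def round_sig(x: float, sig_figs: int) -> float:
    """Round to a number of significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + sig_figs - 1)


def binomial_hotspot_expectation(n_top_snps: float, config: NullConfig,
                                 per_window_prob: float | None = None,
                                 rate_sig_figs: int | None = None) -> NullResult:
    """Expected hotspot-containing windows under independent co-occurrence.

    p = (n_top_snps / n_genes) / n_windows unless given directly;
    ``rate_sig_figs`` optionally rounds p to that many significant figures
    before the tail, so a reported tail corresponds to a reported rate.
    The tail P(X >= min_genes), X ~ Binomial(n_genes, p), is computed with
    the regularized incomplete beta function, stable down to ~1e-30.
    """
    if per_window_prob is None:
        if n_top_snps < 0:
            raise ValueError("n_top_snps must be nonnegative")
        per_window_prob = (n_top_snps / config.n_genes) / config.n_windows
    if rate_sig_figs is not None:
        per_window_prob = round_sig(per_window_prob, rate_sig_figs)
    if per_window_prob > 1:
        raise ValueError(f"per-window probability {per_window_prob} exceeds 1")
    tail = float(stats.binom.sf(config.min_genes - 1, config.n_genes, per_window_prob))
    return NullResult(
        per_window_prob=float(per_window_prob),
        tail_prob=tail,
        expected_windows=float(config.n_windows * tail),
    )


def permutation_fdr(per_gene_tallies, observed_hotspots: int,
                    config: NullConfig) -> NullResult:
    """Permutation FDR: mean null hotspot-window count / observed count.

    Each tallied association is dropped independently and uniformly into one
    of ``n_windows`` bins, ``n_permutations`` times; see the module docstring
    for the two bin-counting modes.
    """
    tallies = np.asarray(per_gene_tallies, dtype=np.int64)
    if tallies.ndim != 1 or len(tallies) != config.n_genes:
        raise ValueError(f"expected {config.n_genes} per-gene tallies, got {tallies.shape}")
    if (tallies < 0).any():
        raise ValueError("tallies must be nonnegative")
    if observed_hotspots < 0:
        raise ValueError("observed_hotspots must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 97]))
    total = int(tallies.sum())
    counts = np.zeros(config.n_permutations, dtype=np.int64)
    gene_of = np.repeat(np.arange(config.n_genes), tallies)
    for i in range(config.n_permutations):
        if total == 0:
            break
        bins = rng.integers(0, config.n_windows, size=total)
        if config.count_mode == "associations":
            per_bin = np.bincount(bins, minlength=config.n_windows)
            counts[i] = int((per_bin >= config.min_genes).sum())
        else:
            pairs = np.unique(bins.astype(np.int64) * config.n_genes + gene_of)
            per_bin = np.bincount(pairs // config.n_genes,
                                  minlength=config.n_windows)
            counts[i] = int((per_bin >= config.min_genes).sum())
    null_mean = float(counts.mean())
    return NullResult(
        null_mean_per_perm=null_mean,
        fdr=fdr_from_null_mean(null_mean, observed_hotspots),
        null_counts=counts,
    )


def fdr_from_null_mean(null_mean_per_perm: float, observed: int) -> float | None:
    """FDR = mean null calls per permutation / observed calls (None if 0 observed)."""
    if observed == 0:
        return None
    return float(null_mean_per_perm) / observed


def bonferroni_threshold(alpha: float, n_tests: float) -> float:
    """Family-wise threshold alpha / n_tests."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def overlap_fdr(n_hotspot_snps: int, n_traits: int, p_threshold: float,
                observed_hits: int) -> NullResult:
    """FDR for hotspot-SNP x phenotype overlap at a p-value threshold.

    Expected chance hits = n_hotspot_snps * n_traits * p_threshold (each test
    has probability p_threshold of a chance hit under a uniform null); FDR is
    expected / observed. Reuses NullResult with ``expected_windows`` holding
    the expected hit count and ``per_window_prob`` the per-test threshold.
    """
    if min(n_hotspot_snps, n_traits, observed_hits) < 0 or p_threshold < 0:
        raise ValueError("counts and p_threshold must be nonnegative")
    expected = n_hotspot_snps * n_traits * p_threshold
    return NullResult(
        per_window_prob=p_threshold,
        expected_windows=float(expected),
        fdr=fdr_from_null_mean(expected, observed_hits),
    )
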