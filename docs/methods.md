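# Methods

## Statistical model

Each expression trait *y* (one gene in one tissue, or a gene-set index) is
regressed on alternate-allele dosage *g* ∈ {0, 1, 2} one SNP at a time:

y = α + β·g + (Cγ) + ε,  ε ~ N(0, σ²)

β is the SNP effect per alternate allele and the reported p-value is the
two-sided t-test on β with n − 2 − k degrees of freedom (k covariates). The
scan is plain OLS: no kinship or mixed model is fitted, and covariates
(e.g. expression principal components) are opt-in, entering through exact
Frisch–Waugh residualization of both y and g. Effects are stored raw;
normalization by the trait mean is a presentation option on exported tables
only. Missing genotypes are not supported — inputs are assumed complete
(imputed); the simulator emits complete data.

Degenerate fits follow thresholding-friendly conventions: a perfect fit
(zero residual, nonzero slope) reports p = 0, and a flat trait reports
β = 0, p = 1. Zero-variance SNPs are a contract violation (the MAF filter
must remove them) and raise an error rather than returning NaN.

Before scanning, SNPs are recoded to count the alternate allele and filtered
at minor-allele frequency ≥ 0.05 (configurable). Monomorphic SNPs are always
removed, so `maf_min = 0` prunes exactly the untestable sites. Multi-allelic
VCF records are dropped at read time with a logged count.

## Cis/trans classification and hotspot tiers

Distances are measured in base pairs from the SNP to the nearest gene-body
edge (0 inside the body), on 1-based positions. A SNP is **cis** to a gene
within 50 kb, **trans** at ≥ 1 Mb or on another chromosome, and
**proximal-excluded** in between — the band is deliberately left out of
both classes rather than silently assigned. All windows (250 kb top-SNP
tiles, 40 kb hotspot windows) are exclusive, half-open, and anchored at
coordinate 0, so a genome of length L tiles into ⌈L/W⌉ windows per
chromosome (a 2.5 Gb genome yields 62,500 windows of 40 kb).

Top-SNP selection keeps, per (gene, tissue, 250 kb window), the single
lowest-p trans SNP; ties break to the smaller position, then lexicographic
SNP id, so results are order-independent and fully deterministic. Gene
counting at every tier is per tissue and by distinct gene, never by
association count. The tier definitions (≥ 8 genes at p ≤ 1 × 10⁻⁴) are
configuration parameters with those defaults.

Effect-direction analysis arranges hotspot calls as a signed effect matrix
(0 where a gene is not a significant member), flags rows whose nonzero
entries share one sign as concordant, and orders rows by agglomerative
clustering with Ward linkage on Euclidean distances. The divergence
tabulation considers every SNP inside a window hotspot that affects a focal
gene plus at least 2 other genes and asks whether the focal sign opposes
the majority sign of the others; a tied majority counts as not divergent.

## Null models

**Analytic.** If each of n genes independently lands a top SNP in a given
window with probability p = (top SNPs / n) / windows, the gene count per
window is Binomial(n, p) and the expected number of hotspot windows is
N·P(X ≥ 8). The tail is computed through `scipy.stats.binom.sf`
(regularized incomplete beta), which is accurate at tail masses of 10⁻²³
and below; a brute-force enumeration oracle guards this in the tests. The
`rate_sig_figs` option rounds p to a given number of significant figures
before the tail so that a reported tail corresponds to a reported rate —
with 48,734 top SNPs the exact rate 0.011139 gives a tail of 1.21 × 10⁻⁶,
while the 3-significant-figure rate 0.0111 gives 1.18 × 10⁻⁶; both are
exposed, and the two-stage (reported-rate) variant is what the acceptance
script prints alongside the exact rate.

**Permutation.** Per-gene association tallies are dropped independently and
uniformly into N windows (a multinomial assignment, matching "randomly
assigned to bins" rather than a positional shuffle), 1,000 times by
default. Two bin criteria are exposed because they genuinely differ:
`count_mode="associations"` calls a bin a null hotspot at ≥ 8 total
assignments (the permissive reading), `count_mode="genes"` at ≥ 8 distinct
contributing genes (the criterion the hotspot definition actually uses, and
never larger than the former). FDR = mean null count per permutation /
observed count; it is reported as not-applicable when nothing was observed.
The null assumes expression is independent across genes within a sample;
real co-expression violates this, so these FDRs are best viewed as lower
bounds on the true false-discovery rate.

**Overlap.** For hotspot-resident SNPs tested against m phenotype traits at
threshold t, the chance expectation is SNPs·m·t hits and the FDR is
expected/observed.

## Expression indices and phenotype traits

Z-scores standardize each gene across samples using the sample SD (n − 1
denominator; the choice only rescales indices uniformly and never changes
GWAS rank order). Zero-variance genes become all-zero rows with a logged
warning, contributing 0 to indices instead of shrinking the set. An index
is the unweighted per-sample mean of Z over a named gene set and can be fed
straight back into the scan as a trait. Paired mutant/wild-type chlorophyll
meter readings yield Ratio = MT/WT and Diff = WT − MT per timepoint;
a zero WT gives a missing ratio, not an error.

## Candidate annotation

Hot (top) SNPs collect up to 3 genes per side whose TSS lies within an
inclusive 125 kb window, ranked by TSS distance (1 = closest; ties break by
lower gene start, then id). Upstream/downstream refers to the + orientation
of the genome relative to the locus, not gene strand, since ranking is by
TSS distance irrespective of strand. A gene whose body overlaps the SNP is
a single "inside" record at distance 0. Window hotspots use the [min, max]
of their member SNP positions as the boundary; genes intersecting it are
"inside", and the single nearest gene on each side is kept if its TSS is
within 125 kb of the edge.

## Synthetic data: what it emulates and what it does not

The generator stands in for a diversity-panel eGWAS: biallelic SNPs with
per-SNP alternate-allele frequencies uniform on (0.02, 0.5] (below the 0.05
MAF cutoff on purpose, so the filter is exercised), positions uniform
without replacement on a 10 × 20 Mb toy genome, and dosages drawn as two
independent allele draws — Binomial(2, f). The gene panel lays
non-overlapping gene bodies evenly along chromosomes with alternating
strand and branch labels cycling over porphyrin, chlorophyll, heme,
siroheme, bilin, catabolism. Expression is an exact linear function of
planted dosages plus homoscedastic Gaussian noise:
cis term (nearest SNP within 50 kb, effect ~ N(0, cis SD)), trans
regulator terms, and N(0, noise SD). A regulator's targets may include one
gene whose effect sign is inverted in a designated tissue, emulating a
target whose direction of co-regulation reverses between conditions.
Phenotypes are paired mutant/wild-type traits whose dependence on a focal
SNP exists only in the mutant column (epistasis), with independent noise.

One global seed determines everything; stages draw from substreams derived
deterministically from (seed, stage tag, tissue tag), so adding a tissue or
stage never perturbs the others. Planted regulators for the validation
studies are drawn from SNPs that are trans (≥ 1 Mb or another chromosome)
to every target by construction — that is what a trans regulator is, and it
makes exact target-set recovery a well-posed criterion.

Deliberately not modeled: linkage disequilibrium, population structure,
kinship, realistic recombination, read-level data, and inter-gene
expression correlation beyond the planted architecture. Passing tests
therefore show the machinery is correct and calibrated under independence,
not that real-data hotspot counts are unbiased — on real panels, LD spreads
hotspot signals across neighboring SNPs and co-expression inflates null
co-occurrence.

## Study designs and problem sizes

The validation studies use desk-scale designs chosen to keep the full suite
fast while leaving the statistics well-powered:

* **Recovery study** — 100 seeded replicates of 300 lines × 1,200 SNPs,
  70 panel genes, one regulator with 10 targets at +0.5 expression units
  per allele, cis SD 0.5, noise SD 0.5. At these settings the regulator's
  per-gene t-statistic is ≈ 11, so detection is essentially certain and the
  observed failures of *exact* set recovery (a few per hundred) come from
  chance extra genes at the permissive p ≤ 1 × 10⁻⁴ cutoff.
* **Null calibration** — 300 lines × 5,000 SNPs × 20 genes with no planted
  effects; the fraction of tests at p ≤ 1 × 10⁻⁴ is compared with 1 × 10⁻⁴
  within 3 binomial SEs (~10⁵ tests).
* **Permutation check** — uniform tallies totalling 48,734 over 70 genes
  into 62,500 bins, 1,000 permutations, compared with the analytic
  multinomial-bin expectation within 3 Monte-Carlo SEs.

## Known limitations

* No mixed-model correction: on structured panels the scan's p-values are
  anti-conservative; the package targets the hotspot logic downstream of
  any association engine, and the scan is the transparent default.
* The permutation and binomial nulls share the independence assumption
  discussed above.
* Hotspot windows are fixed tiles; a signal straddling a window boundary
  can split below the gene threshold (the 4/4 split case in the tests).
  The three tiers exist precisely because each is vulnerable to a
  different artifact.
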