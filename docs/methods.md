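# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `beanld`. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Data model and coding

Genotypes are held as an accessions × loci integer matrix of ALT-allele
dosages {0, 1, 2} with −1 as the missing sentinel, paired with a locus
table (`chrom`, 1-based `pos`, `ref`, `alt`, `maf`, `missing_rate`).
Dosage counts the ALT allele rather than the minor allele so the coding is
stable under filtering; every statistic in the package is invariant under
the flip `x → 2 − x` (asserted by property tests), so the choice carries no
analytic consequence. MAF is recomputed from non-missing calls after every
filtering step. Distances are `|pos_i − pos_j|` in bp, 1-based fully-closed
coordinates as in VCF.

I/O: VCF v4.2 (GT-only semantics; diploid `0/0 | 0/1 | 1/1 | ./.` →
0/1/2/missing, haploid `0 | 1` → 0/2, phased separators treated as
unphased; multi-allelic and indel records skipped with a warning) via
cyvcf2, and a plain TSV dialect (`chrom pos ref alt` + one column per
accession, `NA` for missing). Both round-trip losslessly; gzip is
transparent. In tabular LD output, cross-chromosome pairs carry
`distance_bp = −1`; the `same_chrom` flag is authoritative.

## Filter chain

1. **Heterozygote → missing.** The panels targeted are predominantly
   autogamous, so heterozygous calls are treated as sequencing errors and
   set to missing.
2. **Missing-data filter** at 10%: a locus is kept when its missing
   fraction is ≤ 0.10. The MAF side of the chain is inclusive by its
   printed convention (MAF ≥ 0.05); the missing side is chosen
   symmetric-inclusive. The boundary choice moves individual loci only at
   exact equality.
3. **Window imputation** (below), chromosome by chromosome.
4. **MAF filter** at 5%: kept when MAF ≥ 0.05; all-missing loci (MAF
   undefined) are dropped.

A `QcReport` records counts at every stage; the pipeline summary is
audit-checked in the tests by re-applying the chain independently.

## Nearest-neighbour window imputation

For a missing call (line *i*, locus *j*): take the up-to-*w* nearest loci
on each side of *j* on the same chromosome (≤ 2*w* flanking loci, truncated
at chromosome ends, *j* excluded). For every candidate line *h* with an
observed call at *j*, the distance d(i,h) is the fraction of window loci,
observed in both lines, at which they differ; lines with no comparable
locus are excluded. The imputed call is the majority call at *j* among all
lines attaining the minimum distance. Tie-break chain (fixed here because
no published convention exists): minimum-distance set → majority call →
locus-wise major call (excluding the target's own entry) → code 0 on a
full tie. If no candidate line exists the locus major call is used.
Predictions use observed data only, so imputation never alters observed
calls and is idempotent.

**Window-size selection** is leave-one-out self-prediction: for each
candidate *w* (default 5–150 loci per flank) every observed call is masked
one at a time and predicted by the rule above; accuracy is the fraction
recovered. The per-chromosome argmax is chosen, smallest candidate on
ties. Candidates spanning a whole chromosome are equivalent and evaluated
once. *w* counts loci per flank; the tests validate the rule against an
exhaustively hand-coded leave-one-out loop, so the convention is pinned.

Sliding pairwise mismatch/comparable counts make selection
O(candidates × loci × lines²) with small constants; panels of a few
hundred lines × a few hundred loci per chromosome run in seconds.

## Structure and kinship

**PCA** mean-centres loci without variance scaling (the common default for
dosage PCA) and eigendecomposes the accession covariance via SVD;
deterministic sign convention (largest-magnitude loading positive).
`build_S(pca, k)` returns the first *k* column-centred score columns;
*k* = 4 is the pipeline default, `auto` uses the Tracy–Widom count.

**Tracy–Widom count**: the leading eigenvalue is standardized with the
effective-size normalization estimated from the remaining spectrum
(effective marker count `n' = (m+1)S₁²/((m−1)S₂ − S₁²)`, clamped to
[2, n_loci]), compared to the embedded TW1 upper-tail critical values
{0.10: 0.4501, 0.05: 0.9793, 0.01: 2.0234}; accepted components are removed
and the procedure repeats, stopping at the first non-significant
eigenvalue. Only those three α levels are supported. Calibration on
iid-noise matrices and detection of planted k-pool structure are exercised
in the acceptance tests.

**Kinship** is the simple-matching (identity-by-state) coefficient — the
fraction of loci with identical codes — rescaled as
`V = (s − s_min)/(1 − s_min)` with `s_min` the off-diagonal minimum, so the
least related pair anchors 0 and identical lines 1. The diagonal is forced
to 1. Complete (imputed) data is expected; with missing entries a
pairwise-complete comparison is used and a warning logged. All lines
identical (`s_min = 1`) is an error.

**Nucleotide diversity** π treats each inbred line as one haploid sequence
over the SNP sites: the mean over unordered line pairs of their pairwise
difference fraction, computed as the per-locus `2p(1−p)·n/(n−1)` average.
It is reported over whatever locus set the caller supplies (the pipeline
uses the post-filter SNP set), which is a per-polymorphic-site convention —
values are per SNP site, not per genomic bp.

## LD estimators

All four estimators operate on complete (imputed) dosage columns:

* `r2` — squared Pearson correlation over jointly observed entries
  (≥ 3 required; zero variance is an error).
* `r2_s` — OLS-residualize both vectors on `[1, S]`, correlate residuals.
* `r2_v` — ridge-regularize `V ← V + εI` with `ε = 10⁻⁶·tr(V)/n` (the
  rescaled simple-matching matrix is not guaranteed positive definite),
  Cholesky-whiten, center by the generalized mean, correlate.
* `r2_vs` — GLS-residualize on `[1, S]` under the V-metric (equivalently,
  OLS on the whitened design), correlate residuals under V.

The ridge is a uniform spectral shift; with `V = I` it rescales all inner
products equally, so the reduction identities `r2_v ≡ r2` and
`r2_vs ≡ r2_s` hold to 10⁻¹⁰, as does `S = ∅ ⇒ r2_s ≡ r2, r2_vs ≡ r2_v`.
Residuals with norm below 10⁻⁹ (structure-confounded or monomorphic loci)
raise a degeneracy error per pair; the pairwise stream converts these into
flagged records (`status = "degenerate"`, NaN measures) rather than
aborting.

**Fisher exact test**: homozygous lines contribute one haplotype each, so
the 2×2 joint allele-count table over jointly observed lines is exact; the
two-sided p sums hypergeometric probabilities of all tables (margins
fixed) no more probable than the observed one — the convention matched by
the enumeration oracle in the tests. Any empty margin is a degenerate
table. FDR is Benjamini–Hochberg step-up at 5% over the emitted pair set.

`pairwise_ld` residualizes all columns once per measure and reduces each
pair to a dot product, in chromosome-blocked deterministic order
(`a` before `b`, positions ascending); the batch size only chunks
iteration and provably does not affect results (asserted in tests).

## Decay model

`expected_r2(C, n)` is the drift–recombination expectation with
finite-sample correction (formula in the README); it is strictly
decreasing in C for fixed n ≥ 2 (verified on a dense grid) and decreases
toward the large-n curve as n grows. Its large-C limit is the sampling
floor 1/n, not 0 — thresholds at or below the floor are reported
"unreachable" rather than solved. n is the number of accessions (inbred
lines ≈ haploid samples, consistent with the Fisher-test treatment).

`fit_C` fits the single parameter ρ (per bp, `C = ρ·d`) by least squares:
a 240-point log-spaced grid scan over ρ ∈ [10⁻⁹, 1] followed by
golden-section refinement between the neighbouring grid points — the
objective is one-dimensional and this is deterministic and bracketing-
robust. A custom golden-section loop (120 iterations, interval tolerance
10⁻¹⁵ in log₁₀ρ) is used because library scalar minimizers stop at a
√ε·|x| relative floor, short of the noiseless-recovery precision the tests
demand. Fits pinned at either grid end are flagged (`at_lower_bound`: no
decay signal; `at_upper_bound`: the data sit at or below the curve's
floor at all observed distances, typical when a correction has absorbed
the local LD — the fit is then not interpretable as a decay scale).
Fitting uses unbinned pairs; `binned_decay_profile` is for display.
`decay_distance` inverts the fitted curve by bisection after numerically
asserting monotonicity.

## Synthetic panels

The generator plants every feature the pipeline must detect:

* **Pool divergence**: Balding–Nichols — ancestral frequency
  p ~ Uniform(0.1, 0.9) (avoids monomorphic loci while exercising the MAF
  filter), pool frequency Beta(p(1−F)/F, (1−p)(1−F)/F). The realized
  between-pool differentiation matches Hudson's Fst ≈ F (oracle-checked).
* **Kinship/families**: each pool holds `n_founder_haplotypes` founder
  haplotypes per chromosome; lines are founder mosaics, so few founders ⇒
  strong within-pool relatedness.
* **Distance decay**: between consecutive loci the founder is redrawn with
  probability 1 − exp(−ρ_sim·gap_bp). With the default
  `recomb_rate_per_bp = 10⁻⁶` and founder resampling, r² decays over
  hundreds of kb to ~1 Mb — the physical scale of interest.
* **RILs**: one parent line from each of the first two pools, F1, then
  `selfing_generations` (default 9, i.e. ~F10) meioses with the same
  crossover process; residual heterozygous loci fixed to a random parental
  allele.
* **Noise**: heterozygous error calls (dosage 1, default 0.5%) then
  missingness (default 8% per entry), independent Bernoulli per entry.

Default panel composition is 139 + 27 pure-pool lines plus 14 inter-pool
RILs (180 accessions in two unbalanced gene pools), 11 chromosomes at the
common-bean reference pseudomolecule lengths, 40 loci each at uniformly
drawn positions. Everything is deterministic given the spec seed.

What the generator does **not** emulate: read-level GBS artefacts
(coverage-dependent missingness, allele dropout correlated with depth),
selection, mutation, realistic site-frequency spectra, centromeric
recombination suppression, or locus-wise (column-correlated) missingness —
missingness here is entry-wise iid. Passing tests therefore demonstrate
correctness of the statistics under a clean generative model, not
robustness to every artefact of real GBS data.

## Problem sizes used in tests and the acceptance script

Experiments are scaled so the full suite and the acceptance script each
run in tens of seconds on one CPU, while keeping Monte-Carlo error well
inside the asserted margins: 500 unlinked locus pairs on 100+100-line
panels for the bias-removal experiments; a 90-line, 360-locus,
3-chromosome high-LD panel with 5% masking for imputation; 100 noise
replicates (50 × 500) and 20 planted 3-pool replicates for Tracy–Widom;
a 180-line panel with 3 dense chromosomes plus 300 unlinked background
loci for the decay experiment. In that experiment S and V are estimated
from the background loci only: kinship estimated from the dense linked
loci themselves absorbs the local LD being measured and pins the corrected
decay fit at its upper bound — mirroring the practice of estimating
genome-wide kinship from markers spread across chromosomes.

## Known limitations

* The corrected estimators require complete (imputed) data; there is no
  pairwise-complete fallback for rS²/rV²/rVS².
* The Tracy–Widom table covers α ∈ {0.01, 0.05, 0.10} only.
* The imputation is the nearest-neighbour window method; no HMM/phasing
  imputation is provided.
* `s_min` rescaling ties the kinship scale to the least related pair in
  the panel, so V (and hence rV²) is panel-relative.
* Heatmap/inter-chromosomal outputs are matrices and tables; no figure
  rendering is included.
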