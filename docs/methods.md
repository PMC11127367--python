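# Methods

## The generative model behind the synthetic data

The synth module simulates the data-generating process the analysis
assumes. A pool contains `n_clones` clones; clone `c` carries
`offset + Poisson(rate)` integrated reporters (default 1 + Poisson(4),
i.e. five on average, matching the pooled design the assay targets), each
tagged by a unique random 16-mer locBC. The latent UMI count of location
`k` in cell `j` is

    X_jk ~ Poisson(s_j · E_j · I_jk · mu_k)

* `mu_k` — base expression of the location, log-normal across locations
  (default meanlog = log 50, sdlog = 1.0: tens to a few hundred UMIs per
  location per cell, consistent with a few hundred reporter UMIs per cell
  spread over ~3–5 integrations).
* `E_j` — extrinsic factor, one draw per cell, shared by all reporters in
  that cell; unit-mean log-normal with scale `sigma_ext` (default 0.45).
* `I_jk` — intrinsic factor, independent per (cell, location); unit-mean
  log-normal with scale `sigma_int` (default 0.45).
* `s_j` — capture efficiency per cell, unit-mean log-normal with scale
  `capture_scale` (default 0.35). Like `E_j` it multiplies every reporter
  in the cell, but it models a technical effect, which is why the
  normalization step exists.

Unit-mean log-normal means `exp(N(−σ²/2, σ))`, chosen because the
dual-reporter decomposition then has closed-form truth: for an equal-mean
reporter pair,

    eta_ext → exp(σ_ext²) − 1
    eta_int → 1/μ + exp(σ_ext² + σ_int²) − exp(σ_ext²)

as the number of cells grows. These limits anchor the parameter-recovery
tests. Observation layers: dropout zeroes each observed entry
independently (default rate 0.3, droplet-typical); each surviving UMI
emits `1 + Poisson(pcr_dup_mean)` read pairs (default 8.5, giving a mean
trio read depth of ~9.5); substitutions hit each base of the barcode
segments independently (default 0.5%/base). Errors are confined to the
barcode segments — the constant and filler carry none — because the
correction stages are the machinery under test; the Levenshtein tolerance
of the constant match is exercised by dedicated parse tests instead.

What the generator does *not* emulate: chimeric reads, indels (barcode
correction is Hamming-based, so substitutions are the matched error
model), UMI collisions across molecules beyond uniform sampling,
transcriptome realism beyond one spiked gene plus substate labels, and
ambient/background barcodes. Passing tests therefore demonstrate
correctness of the algorithms under the model's assumptions, not
robustness to every artifact of real droplet data.

## Pipeline order and the definition of trio recovery

Raw reads are parsed, collapsed, corrected (cell barcodes, then locBCs),
re-collapsed, and only then filtered to trios with ≥2 supporting reads.
Correction precedes the singleton filter because a read whose only defect
is a correctable barcode substitution starts life as a singleton trio: at
0.5–1%/base error rates a third of reads carry some barcode error, and
filtering first would discard the very reads correction exists to rescue
(cell-barcode correction recovers ~15% of reads in the default synthetic
pool). The single-read filter applied to a *corrected* table then removes
almost exclusively UMI-errored fragments and PCR artifacts. The
filter-first variant remains available by calling
`collapse_and_filter_trios(min_reads=2)` before the correction functions.

End-to-end recovery is measured on the corrected, re-collapsed trio table
*before* the read-support threshold. The threshold deliberately discards
genuine trios whose read support was eroded to one (UMIs are not
error-corrected, so a UMI-errored duplicate is lost evidence); counting
those as recovery failures would conflate a QC policy with parsing and
correction fidelity. At 1%/base errors and PCR duplication mean 5 the
analytic expectation is ~99.8% recovery before the threshold and ~98.2%
after; the measured values match both.

## Quantification choices

* Variance uses the sample (n−1) convention everywhere (location
  statistics, ρ, per-cell CV); declared so every worked value is exactly
  reproducible.
* "Expressing" means raw count ≥ 1; statistics for a location use only its
  expressing cells.
* Normalization: `factor_j = total UMIs_j / detected locations_j`;
  normalized entries of a cell sum to its number of detected locations
  (asserted as an algebraic identity).
* QC filter order: trio-level read support, then cells (≥5 locations and
  ≥10 UMIs), then locations (≥5 expressing cells), then one cell re-check —
  not a fixed-point iteration; a single re-check is deterministic and in
  practice removes the handful of cells pushed below threshold by the
  location filter.
* MIN: OLS with intercept of log2 variance on log2 mean, fitted per pool;
  at least 3 usable locations per pool; zero-variance locations are
  excluded from the fit (log2 undefined) and flagged rather than
  pseudo-counted. Residual orthogonality to log2 mean is an OLS identity
  and is asserted to 1e-8.

## Clone inference

The knee of a cell's ranked locBC counts is the point of maximum
perpendicular distance to the chord of the (rank, log1p count) curve —
a parameter-free operationalization of "inflection of the ordered counts".
Cells with ≤2 locBCs keep everything, as does a flat curve. LocBCs
retained in **more than five** cells become graph nodes; co-occurrence in
at least `edge_min` cells (default 1) makes an edge; connected components
are clones. Community detection is deliberately not used: true clones
share *all* their locBCs, so any co-occurrence path should unite them.
Cells whose retained locBCs span two or more components are presumptive
doublets and are excluded from per-clone statistics rather than
reassigned. On synthetic pools with 20 cells/clone the recovered partition
is identical to truth (ARI 1.0) up to 30% dropout and ≥0.95 at 50%.

## Noise decomposition

The dual-reporter estimators are implemented exactly as printed, with
their two distinct `a` factors (including the ρ/(1−ρ) middle term of the
intrinsic factor as typeset); a scalar transcription of the formulas
serves as the oracle in tests, agreeing to 1e-10 relative error.
Degenerate inputs (ρ = 0 or ±1, zero variance, nonpositive mean) raise an
error naming the offending quantity. Finite-sample estimates can be
negative; raw values are always reported, and zero-clipped copies are used
only when forming the pooled fraction `Σ eta_int / Σ (eta_int + eta_ext)`
so it stays in [0, 1].

Two properties of the pooled fraction deserve note. First, when the paired
locations have *unequal* means — the normal case for real pairs — the
between-location difference loads onto the intrinsic term (reporters at
different locations fluctuate independently by construction of the
framework), so the default-pool pooled fraction (~0.9) sits well above the
equal-mean analytic value (~0.57 at the default scales); the equal-mean
parameter-recovery experiments are the controlled check of the estimators
themselves. Second, per-cell normalization couples reporters within a cell
through the shared factor, which is why the per-cell-CV shuffled-null
*calibration* experiment is run on unscaled counts with capture noise off:
per-cell CV is invariant to per-cell scaling, so observed CVs are
unaffected, but a null built by shuffling normalized columns would mix
values scaled by different cells' factors and reject even with no
extrinsic noise. The extrinsic demonstration uses sigma_int = 0.1 (an
extrinsic-dominated regime): with five reporters per cell the CV estimator
has ~40% relative sampling error, and a larger intrinsic scale would bury
the observed median inside the null's lower tail regardless of sample
size.

## Stratified and comparative analyses

* Stratified statistics keep a location only if every stratum has at least
  `min_cells` expressing cells (15 for cell-cycle phases, 30 for
  substates) and refit MIN within each stratum by default; a global-fit
  variant (`refit_min_per_stratum=False`) is available for comparing
  strata against a common mean-variance line.
* The permutation test uses the add-one estimator
  `(1 + #{|perm| ≥ |obs|})/(n_perm + 1)`, which is valid (type-I error ≤ α
  up to the Monte-Carlo tolerance, verified at α ∈ {0.01, 0.05}).
* The extreme-location classifier standardizes features once over the
  retained locations, fits unpenalized logistic regression, and reports
  LOOCV accuracy; weights and Wald p-values come from a statsmodels fit,
  with perfect separation flagged instead of raised. On
  label-independent features LOOCV accuracy is 0.5 within Monte-Carlo
  error at the test's design (200 locations, 20% tails, 15 features);
  much smaller balanced designs would show the known pessimistic bias of
  leave-one-out with an intercept.
* The insertion test builds the 2×2 table (focal gene, all other genes) ×
  (insertion-clone pseudobulk, control pseudobulk), with the control an
  equal-size random cell draw from all other clones, repeated 25 times by
  default with median p and log2FC reported (single-draw mode:
  `n_resample=1`). Fisher's exact test is the named procedure; the 2×2
  construction is the standard pseudobulk proportion test. The
  shuffled-gene-label screen permutes gene identities so each insertion is
  evaluated at a random gene; on unspiked data it flags nothing at the
  |log2FC| > 0.5, p < 0.05 cutoffs. Pseudobulk Fisher tests ignore
  biological overdispersion across cells, so the fold-change cutoff — not
  the p-value — is what keeps the null screen clean; this mirrors the
  procedure's design rather than a calibrated error rate.

## Problem sizes used in validation

Monte-Carlo experiments are sized so the full suite runs in about a
minute: equal-mean parameter recovery at 50,000 cells × 8 seeds per noise
combination, end-to-end round trips at 200 cells / 20 clones (~75,000
trios, ~450,000 reads), clone recovery at 20 clones × 20 cells, CV-null
calibration at 20 seeds × 300 cells, permutation calibration at 300 null
datasets, and LOOCV calibration at 12 repeats of 200 locations. These
sizes give standard errors comfortably tighter than the tolerances they
are tested against.

## Known limitations

* UMIs are never error-corrected (no whitelist exists and the procedure
  defines none); a trio all of whose reads carry UMI errors is
  unrecoverable in principle.
* The locBC greedy correction can absorb a genuine low-abundance location
  lying within Hamming distance 4 of an abundant one; with random 16-mers
  this is rare (P ≈ 1e-5 per pair) but not impossible in a large pool.
* Clone calling assumes disjoint locBC sets between clones; shared
  integrations (e.g. a common landing pad) would merge clones into one
  component.
* The dual-reporter framework attributes between-location expression
  differences to intrinsic noise; the pooled intrinsic fraction is
  therefore design-dependent and should be compared only across data
  processed identically.
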