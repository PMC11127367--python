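# scnoise

Tools for measuring the **mean and cell-to-cell noise of reporter gene
expression at many genomic locations at once**, from pooled single-cell
reporter-capture data.

The experimental design this package analyzes: a common reporter gene,
tagged in its 3'UTR with a random 16-bp *location barcode* (locBC), is
integrated at many genomic sites across a pool of cells. Droplet scRNA-seq
captures reporter transcripts together with a 16-bp cell barcode and a
12-bp UMI, so each read pair encodes a *trio* (cell barcode, UMI, locBC) —
one transcript molecule of one integrated reporter (IR) in one cell. Cells
grown from the same founder clone share an identical set of integrations,
which makes clonal structure recoverable from locBC co-occurrence, and
pairs of reporters inside the same cells support a dual-reporter
decomposition of expression noise into intrinsic and extrinsic parts.

The package covers the full computational workflow, plus a ground-truthed
synthetic-data generator used to validate every stage:

1. **synth** — simulate clones, cells, latent counts
   `X_jk ~ Poisson(s_j E_j I_jk mu_k)` (unit-mean log-normal extrinsic
   factor `E_j`, intrinsic factor `I_jk`, capture efficiency `s_j`),
   dropout, PCR read duplication, substitution errors; emit paired FASTQ,
   trio tables, and gene×cell transcriptomes with substate labels.
2. **parse** — locate the reporter constant in read 2 by best Levenshtein
   match (cutoff 2), extract trios by position, collapse identical trios
   and drop single-read trios.
3. **correct** — cell barcodes: abundance-ranked scan against the 10x-style
   whitelist within Hamming distance 2; locBCs: greedy abundance-ranked
   absorption within Hamming distance 4.
4. **quant** — QC filters (cells: ≥5 locations and ≥10 UMIs; locations:
   ≥5 expressing cells), per-cell normalization
   (`factor_j = UMIs_j / locations_j`), per-location mean and sample
   variance over expressing cells, and **mean-independent noise (MIN)**:
   the residual of a per-pool OLS fit of log2 variance on log2 mean.
5. **clones** — knee-point filtering of each cell's ranked locBC counts,
   a co-occurrence graph over locBCs seen in more than five cells, and
   connected components as clones (multi-component cells are flagged as
   presumptive doublets).
6. **noise** — per-cell CV with a shuffled-label null, and the
   dual-reporter estimators for reporter pair (C, Y) over n cells:

   ```
   eta_ext = (Σ C_i Y_i − n C̄ Ȳ) / (a C̄ Ȳ),
       a = (n−1)(1 + 1/n) + 1/ρ²
   eta_int = (Σ (C_i−Y_i)² − n (C̄−Ȳ)²) / (2a C̄ Ȳ),
       a = (2n³−7n+6)/(2(n²−n)) + ((2−n)/(n²−n))·ρ/(1−ρ)
           + (1/(2(n²−n)))·(2/(1−ρ))²
   ```

   with ρ the sample correlation of C and Y. Clone-level summaries pool
   `Σ eta_int / Σ (eta_int + eta_ext)` over all IR pairs.
7. **strata** — substate/phase-stratified mean and MIN with minimum-cell
   filters, binomial phase-composition tests, label-permutation
   significance, LOOCV logistic classification of top/bottom-quantile
   locations, and the pseudobulk Fisher's-exact transgene insertion test
   (cutoffs |log2FC| > 0.5, p < 0.05) with a shuffled-gene-label null.

## Worked example

`examples/04_noise_decomposition.py` simulates equal-mean reporter pairs
(50,000 cells, mu = 100) at known noise scales and compares the estimators
with their closed-form limits
`eta_ext → exp(σ_ext²)−1` and
`eta_int → 1/μ + exp(σ_ext²+σ_int²) − exp(σ_ext²)`:

```
sigma_ext sigma_int | eta_ext (analytic) | eta_int (analytic)
   0.0      0.6    |  -0.0016 ( 0.0000) |   0.4424 ( 0.4433)
   0.3      0.3    |   0.0930 ( 0.0942) |   0.1128 ( 0.1130)
   0.6      0.0    |   0.4308 ( 0.4333) |   0.0098 ( 0.0100)

extrinsic clone: observed median CV 0.175 vs null median 0.536 (null 5th pct 0.240)
```

Each estimate sits within Monte-Carlo error of its analytic value, and in
the extrinsic-dominated clone the observed per-cell CVs collapse well
below the shuffled null — the signature of reporters co-fluctuating with a
shared cellular state. `examples/01_simulate_and_parse.py` runs the read
pipeline end to end (with 0.5%/base barcode errors it recovers 100.00% of
19,032 ground-truth trios at mean read depth 9.5), and the other examples
demonstrate MIN, clone calling, and the substate/insertion analyses.

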