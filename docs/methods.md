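# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `xqtl`.

## Scope and data model

The package targets all-female cohorts genotyped as ALT-allele dosages in
[0, 2] (typically imputed), with pre-adjusted phenotypes ("yield
deviations") and per-variant metadata including MAF and an imputation-R²
quality score.  Because every analyzed individual is female, X-linked
dosages need no hemizygosity coding or dosage-compensation assumption and
are treated exactly like autosomal dosages throughout.  Coordinates are
1-based; the effect allele is ALT everywhere; MAF is the folded frequency
`min(p, 1−p)` with `p` the mean dosage over 2.  Missing dosages are
rejected, never imputed: the intended inputs are fully imputed, so
missingness signals an upstream problem.

Variant QC has two stages.  `chip_qc` mimics array QC — MAF > 1% and a
1-df Hardy-Weinberg chi-square with p > 1e-4 on hard-called genotypes
(dosages rounded to the nearest class; rounding is confined to this stage
because it is only meaningful for array-quality calls).  `sequence_filter`
is the imputed-sequence filter — MAF ≥ 0.005 and imputation R² ≥ 0.20; a
variant without a quality score cannot pass a quality filter and is
removed.

## Genomic relationship matrices

`G = W W′ / m` with `w_ij = (x_ij − 2p_i) / sqrt(2 p_i (1 − p_i))` and
allele frequencies computed from the analyzed cohort itself.  The same
(VanRaden) estimator is used on diagonals and off-diagonals, which makes G
positive semi-definite by construction and keeps the brute-force oracle
trivial; tools that use a different diagonal estimator differ by O(1/m).
Monomorphic SNPs are a hard error — QC belongs upstream, and silently
dropping SNPs would desynchronize `n_snps`.

## Two-component REML

The partition model `y = 1μ + g_A + g_X + e` is fitted by
average-information REML:

* one Cholesky of `V = σ²_A G_A + σ²_X G_X + σ²_e I` per likelihood
  evaluation; dense algebra, since target cohorts are n ≤ ~5000 (no
  low-rank tricks, whose bookkeeping would dwarf the gain at this scale);
* the first step is EM-REML (robust far from the optimum), later steps are
  AI with step-halving, falling back to EM whenever an AI step fails to
  increase the restricted likelihood — so the accepted log-likelihood
  sequence is non-decreasing;
* initialization at equal thirds of the phenotypic variance (a neutral,
  reproducible start);
* convergence requires both |Δ logL| < 1e-6 and max |Δθ| / var(y) < 1e-8,
  within 200 iterations;
* negative proposals are clamped to 1e-8 × var(y); a genetic component
  clamped three consecutive iterations is fixed at zero (boundary REML);
  the residual is floored but never fixed at zero;
* standard errors come from the inverse AI matrix restricted to free
  components; a boundary component reports its conditional curvature.
  If the final AI matrix is near-singular (condition number > 1e8) the fit
  is flagged non-converged — this is how an unidentifiable model (e.g.
  both GRMs equal) is surfaced rather than returning an arbitrary split.

Heritabilities are the variance ratios; `h² = h²_AUT + h²_X` holds exactly
by construction, and the SEs of the ratios come from the delta method on
the AI covariance.

The association scan's null model (one GRM) is solved differently: the
GRM is eigendecomposed once and the restricted likelihood is profiled over
the ratio σ²_g/σ²_e on a log grid refined by bounded scalar optimization.
This is faster and has no convergence failure modes.

## Association scan

EMMAX-style approximation: variance components are estimated once under
the no-marker null and held fixed for every variant.  After rotating into
the GRM eigenbasis the covariance is diagonal and each variant is a
two-parameter weighted least squares; `b/se` is referred to the standard
normal (two-sided).  The normal rather than the t reference is a
deliberate choice for cohorts in the thousands — the small-n test oracles
use the same reference so the comparison is exact.  Scanning the X with an
autosomal GRM gives leave-one-chromosome-out control by construction.
Variants with zero dosage variance are skipped with a warning rather than
emitted as NaN rows.  −log₁₀(p) is computed from the normal log-survival
function, so it stays accurate when p underflows a double (|z| > 38).

## Meta-analysis

Inverse-variance fixed effects (the METAL "STDERR" scheme):
`w_i = 1/se_i²`, `b_meta = Σ w_i b_i / Σ w_i`, `se_meta = (Σ w_i)^(−1/2)`.
A sample-size-weighted z-score scheme is available behind a flag for
comparison; it combines evidence but reports no pooled effect.  Variants
are matched by (chrom, pos, allele pair): a REF/ALT swap flips the sign
and frequency, anything else drops the variant with a warning.  Variants
absent from some studies are combined over the studies that carry them,
with `?` in the direction string.

## QTL peeling

Per chromosome, iteratively: (1) lead = variant with maximal −log₁₀(p)
≥ threshold (default 7.3 = 0.05 Bonferroni-corrected for ~1e6 tests); ties
break to smallest position, then smallest id, making calls deterministic;
(2) window = lead ± 10 Mb, clipped implicitly to the data extent; (3)
signed Pearson correlation r of dosages between lead and window variants,
computed in the scan cohort itself; (4) CI = window variants with
|r| ≥ 0.7 (lead included), CI bounds = min/max member positions; (5) for
window variants outside the CI, `T_NEW = (b_i − b_LEAD·r)/SE_i`; a variant
is *explained* and removed when −log₁₀(p_NEW) < threshold AND T_NEW keeps
the sign of T_i = b_i/SE_i.  The sub-threshold condition is read as a
significance statement on p_NEW (the literal reading "log₁₀(P) < 7.3" is
vacuously true for every p ≤ 1 and would delete the entire window).
(6) CI members and explained variants leave the working set; repeat.
Termination is guaranteed because the lead removes itself (r = 1).
Step-5 removals are hard-limited to the window, and an optional trace
records every removal with its conditional p for audit.

## Synthetic cohorts

The generator emulates the *structure* of a multi-breed dairy evaluation
cohort, not its demography:

* **Genotypes** are two-level founder mosaics.  A small ancestral pool
  (default 6 haplotypes, independent alleles at Uniform(0.05, 0.95)
  frequencies) is shared by all populations; each population draws a
  founder pool (default 60) as slow mosaics of the ancestors, and each
  sampled haplotype is a mosaic of its population's founders with per-bp
  switch probability `1 − exp(−rate·gap)`.  The default effective switch
  rate 1.2e-6/bp (a per-meiosis 1e-8 times ~100 generations of ancestry)
  with the 6-haplotype ancestral pool yields short-range r² around
  0.15–0.2 decaying to ~0.001 beyond a few Mb — the magnitude seen in
  50k-density cattle panels.
* **X transmission**: X mosaics use 2/3 of the autosomal switch rate (the
  X recombines only in females), and every daughter gets one maternal
  recombined X plus her sire's single X copied intact, with ~40 daughters
  per sire by default.  Both mechanisms raise X LD above autosomal LD at
  matched distance, which is the property the LD tests assert.
* **Phenotypes**: every variant is causal; effects on standardized dosages
  (binomial scaling by `sqrt(2p̂(1−p̂))`, matching the GRM) are i.i.d.
  Gaussian with variance `h²_target/m` per chromosome set, so the implied
  genetic covariance is *exactly* `h² G` — the REML model is correctly
  specified and recovery is unbiased by construction.  Planted major QTL
  (effects in phenotypic SD on the standardized dosage) are added on top
  and counted inside the realized σ²_A or σ²_X.  Residuals are Gaussian
  with variance `1 − h²_AUT − h²_X`, giving unit phenotypic variance in
  expectation.  The Gaussian effect-size choice is a modelling
  convenience, not an empirical claim about real traits.
* One integer seed drives a single PCG64 generator; identical seeds give
  byte-identical cohorts.  Variants monomorphic in the emitted cohort are
  dropped (planted QTL are kept polymorphic by re-seeding their column).

What the generator does **not** model: mutation, selection and drift
dynamics, pedigree depth beyond one sire generation, male phenotypes, the
pseudoautosomal region, allele-frequency ascertainment of array SNPs, and
imputation error (the simulated imputation-R² column is decoration for the
QC path).  Tests passing on these cohorts show the estimators are correct
under their assumed models, not that real data meet those assumptions.

The published six-breed heritability table ships as a verbatim fixture
(65 breed × trait rows) for table-level checks; clinical mastitis is
absent for one breed.  Six of the Holstein rows are internally
inconsistent beyond 3-decimal rounding (h²_AUT + h²_X differs from the
printed h² by up to 0.004); the fixture reproduces the print faithfully
rather than repairing it, and the corresponding consistency test documents
the discrepancy by failing on those rows.

## Experiment sizes

The simulation-based checks use desk-scale versions of the study design,
chosen once for statistical adequacy:

* REML recovery: 100 cohorts of n = 2000 (600 autosomal + 200 X SNPs,
  all causal), targets (0.30, 0.02); means must land within 2 Monte-Carlo
  SEs.
* Null calibration: 100 independent cohorts of n = 800 contributing 200 X
  tests each (20,000 total).  For this experiment the generator is
  configured for near-independent variants (ancestral pool 100, switch
  rate 5e-5), because the binomial reference bands for the rejection rate
  and the median-based λ presuppose approximately independent tests; under
  the default high-LD configuration the effective test count would be far
  below 20,000 and the bands would be uninformative about calibration.
* QTL recovery: one n = 2000 cohort, three X QTL of 0.2 SD planted ≥ 35 Mb
  apart (expected −log₁₀(p) ≈ 15–30).
* Meta gain: three populations of n = 1500 sharing one 0.115-SD X QTL —
  sized so each within-population scan hovers around −log₁₀(p) ≈ 4–5
  (sub-threshold) while the pooled evidence clears 7.3 decisively.
* LD contrast: 20 seeds × n = 300, matched log-ish distance bins to 10 Mb.

`scripts/acceptance.py` re-runs the same experiments (40 recovery
replicates) from a single command-line seed via spawned `SeedSequence`
streams.

## Known limitations

* The AI-REML covariance (hence the delta-method heritability SEs) is
  asymptotic; at n in the hundreds the SEs are indicative only.
* The EMMAX approximation holds the null variance components fixed per
  scan; for very large single-variant effects the per-variant REML
  likelihood would differ slightly.
* LOCO here is "autosomal GRM while scanning X"; generic LOCO for
  autosomal scans exists but is not exercised by the shipped experiments.
* The peeling procedure conditions only on the current lead (no joint
  multi-SNP refit) and never reaches outside the 20-Mb window, so very
  long-range LD can split one signal into several regions.
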