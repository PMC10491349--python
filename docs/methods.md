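# Methods

`mrmediate` implements two-sample Mendelian randomization (MR) on GWAS
summary statistics, multivariable MR (MVMR), heterogeneity/outlier/cluster
decomposition of per-variant estimates, and two-step MR mediation analysis,
together with a summary-statistics generator that provides ground truth for
every estimator. This note records the models, the numerical choices, and
what the synthetic data do and do not emulate.

## Data model and harmonization

A trait's summary statistics are per-SNP effect estimates `beta` with
standard errors, effect-allele frequencies, p-values and sample sizes.
Continuous traits are in SD units; binary traits are on the log-odds scale
throughout, with odds ratios formed only at reporting time.

Harmonization orients every trait to the first exposure's effect allele:
swapped alleles negate the beta and complement the frequency. Palindromic
(A/T, C/G) variants cannot be strand-resolved from allele labels; they are
retained, oriented as-is, only when every trait's effect-allele frequency
lies outside `[0.5 − w, 0.5 + w]` (default `w = 0.08`) **and** on the same
side of 0.5 — otherwise they are dropped with reason
`palindromic_ambiguous`. This is a deterministic, documented stand-in for
the conventions of the standard harmonization toolchains; other choices
(e.g. always dropping palindromes) are available by lowering `w` to 0.5.
Variants missing from any trait are dropped (`missing`); only SNV alleles
A/C/G/T are accepted; coordinates, when present, are 1-based on the forward
strand.

Instrument selection keeps variants with `p < 5e-8` (the conventional
genome-wide threshold). LD clumping against a genotype reference panel is
out of scope; when positions are available a greedy positional pruning
stands in: smallest-p variant first, all others within 10 Mb on the same
chromosome removed (ties on p broken by variant id). Without positions,
pruning is skipped with a warning. Synthetic variants are generated in
linkage equilibrium, so pruning is a no-op there by construction.

## Univariable estimators

With per-SNP exposure association `b_Xj` (SE `s_Xj`) and outcome association
`b_Yj` (SE `s_Yj`), the Wald ratio is `b_Yj / b_Xj` with first-order SE
`s_Yj / |b_Xj|` (a second-order option adds the exposure-noise term).

* **IVW** — weighted least squares of `b_Y` on `b_X` through the origin,
  weights `1/s_Y²`. The fixed-effect SE is the analytic WLS SE; the
  multiplicative random-effects (MRE) flavor — the package default —
  multiplies it by `max(1, sqrt(Q/(L−1)))`, where Q is Cochran's Q over the
  ratios with weights `b_X²/s_Y²`.
* **MR-Egger** — WLS with intercept after orienting all `b_X ≥ 0`; the
  intercept estimates average directional pleiotropy (meaningful only in
  that orientation, which is why orientation is applied before the fit).
  Both SEs carry the `max(1, sqrt(Q/(L−2)))` scaling.
* **Weighted median** — order the ratios, form cumulative weight midpoints
  `p_j = (S_j − w_j/2)/S_L` from normalized inverse-variance weights, and
  linearly interpolate at `p = 0.5`; consistent when ≥50 % of instrument
  weight is valid. SE by seeded parametric bootstrap (default 1000 draws,
  resampling `b_X` and `b_Y` from their SEs).

Instrument strength is the mean per-SNP `(b_X/s_X)²` (F); below 10 the
summary flags weak instruments but nothing is auto-rejected — the same
policy applies to the Egger intercept, which is reported, never used as a
decision rule.

**Steiger directionality filtering** computes per-SNP variance explained as
`r² = t²/(t² + n − 2)` with `t = beta/se` for each trait — chosen over
`2p(1−p)β²` because it needs no trait-variance assumption (a documented
deviation risk versus analyses that used the frequency-based formula). For a
binary outcome this r² is on the observed log-odds scale and approximate. A
SNP is removed when the outcome r² exceeds the exposure r² and the one-sided
two-sample test on the Fisher-transformed correlations rejects at `alpha`
(default 0.05).

## Multivariable MR

Direct effects are WLS of `b_Y` on the K exposure columns without intercept,
weights `1/s_Y²`; rank deficiency of the exposure matrix is a hard error
("collinear exposures"). Cross-exposure sampling covariances are set to zero
— valid for non-overlapping GWAS samples, a documented limitation otherwise.
Heterogeneity uses the adapted statistic `Q_A = Σ (b_Yj − Σ_k b_kj β_k)² /
s_Yj²` at the plug-in estimates, on `L − K` df (the minimization variant is
noted as an extension, not implemented); SEs carry `max(1, sqrt(Q_A/(L−K)))`.
Conditional instrument strength for exposure k regresses its associations on
the other exposures' associations with weights `1/s_Xk²` and divides the
weighted residual sum of squares by `L − K + 1`. The instrument set is the
union of per-exposure instruments, re-harmonized; variants missing in any
trait are dropped.

## Heterogeneity decomposition

* **Radial outliers.** The radial estimate is the weighted mean of ratios;
  per-SNP contribution `Q_j = w_j (ratio_j − β̂)²`. First-order weights
  `b_X²/s_Y²` make `Σ Q_j` equal Cochran's Q exactly. Modified second-order
  weights `w_j = b_Xj²/(s_Yj² + β̂² s_Xj²)` are iterated with the estimate to
  a tolerance of 1e-8 (max 100 iterations; non-convergence is a hard error
  with the iteration trace). A SNP is flagged when the chi-square(1) upper
  tail of `Q_j` falls below `alpha` (default Bonferroni, `0.05/L`; ties at
  the threshold flag all tied SNPs). The corrected estimate is IVW-MRE on
  the unflagged set.
* **Simulation-based (PRESSO-style) tests.** The observed statistic is the
  sum of squared leave-one-out residuals, each standardized by
  `sqrt(s_Y² + β̂₋ⱼ² s_X²)`; its null distribution comes from `n_sim`
  parametric draws under the LOO-fitted model with each SNP's own SEs, the
  statistic recomputed identically per draw (so the empirical p-value is
  calibrated by exchangeability). Per-SNP outlier tests compare each
  observed squared residual to its own simulated null, Bonferroni-corrected
  — note the empirical p-value floor `1/(n_sim+1)` means `n_sim` must exceed
  `L/alpha` for any flag to be reachable (the default `n_sim = 1000`
  suffices for the 21-instrument setting). The distortion test compares the
  estimate change after outlier removal to removal of random subsets of the
  same size; it is skipped when nothing is flagged.
* **Ratio clustering.** Per-SNP ratios with known first-order SEs are fit by
  EM to a mixture of K free Normal components (putative mechanisms), a null
  component fixed at mean 0, and a junk component uniform over the observed
  ratio range ±10 SDs. K is selected over 0..max_K by BIC with `2K + 1` free
  parameters (K means, K+1 free mixing proportions). Twenty seeded restarts
  per K; the first restart uses a deterministic quantile initialization so
  results are invariant to SNP order. SNPs are labeled with their
  highest-posterior component only at conditional probability ≥ 0.9
  (configurable), else "unassigned"; per-cluster IVW estimates are computed
  on assigned members. The clustering contract is behavioral — recover
  planted mechanisms and isolate null variants — not numerical identity with
  any particular published implementation, whose selection settings are not
  reproducible from the outside.

## Mediation

Two-step MR with a single mediator. The total effect is univariable IVW of
exposure on outcome; step 1 is univariable IVW of exposure on mediator; the
exposure's and mediator's direct effects come from MVMR of both on the
outcome.

* Product method: `indirect = β_EM · β_MY`, Sobel SE
  `sqrt(β_EM² se_MY² + β_MY² se_EM²)` (the second-order `se²se²` term is
  omitted by default, matching the Sobel convention; an exact flag adds it).
* Difference method: `indirect = β_total − β_direct`, propagation-of-errors
  SE `sqrt(se_total² + se_dir²)`. The covariance between total and direct
  estimates — which share instruments — is ignored; this is
  anti-conservative and is documented rather than guessed at.
* Proportion mediated: `indirect/total`, delta-method ratio CI with the
  indirect/total covariance set to zero (not estimable from the two separate
  fits); values outside [0, 1] are reported as computed with a warning, and
  a weakly determined total (`|β| < 10·SE`) triggers an instability warning.
  A Fieller interval is a noted alternative, not the default.

Mediation of a binary outcome is computed on the log-odds scale. Log-odds
effects are non-collapsible, so product and difference decompositions need
not agree exactly there; the equality property is asserted only on the
continuous scale.

## Synthetic data generator

Summary statistics are generated directly from the asymptotic sampling
distribution of GWAS effect estimates — not via individual-level genotypes —
because the estimators consume only summary data and this makes the noise
model exact. Per SNP j with MAF `p_j ~ U(maf_range)`:

* exposure effect `γ_j ~ N(0, gamma_sd²)` (or, for
  `gamma_dist="uniform_magnitude"`, `|γ| ~ U(range)` with random sign —
  emulating curated instrument lists whose effects are bounded away from
  zero);
* mediator effect `α·γ_j + δ_j`, where `δ_j ~ N(0, delta_sd²)` on a
  designated `mediator_snp_fraction` of SNPs which have `γ_j = 0` — distinct
  instrument sets for exposure and mediator, as in real curated instrument
  lists (e.g. 115 body-size vs 21 density instruments);
* outcome effect `beta_direct·γ_j + beta_med·(α·γ_j + δ_j) + θ_j` — the
  structural model, so mediator-specific effects propagate to the outcome
  (without this, joint MVMR of exposure and mediator would be rank
  deficient);
* `θ_j` collects horizontal pleiotropy — `N(mean, sd)` on a
  `pleiotropy_fraction` of SNPs, sign-aligned with `γ_j` so a directional
  mean is directional in the exposure-increasing orientation (otherwise it
  cancels in the IVW slope) — and planted outliers, which shift `θ_j` by
  `outlier_effect` multiples of that SNP's outcome SE (so "a 5-SE ratio
  shift" means exactly that);
* observed betas are truth plus independent Normal noise with
  `se = 1/sqrt(2p(1−p)n)` for standardized continuous traits and
  `se = 1/sqrt(2p(1−p)·n·cf·(1−cf))` on the log-odds scale for a binary
  outcome with case fraction `cf` (logistic-score approximation);
* the three samples use independent child noise streams from one master
  seed (non-overlap); identical seed gives byte-identical output.

`cluster_spec` replaces the single-mechanism outcome slope with per-cluster
slopes `slope_k · γ_j`, the remaining SNPs being null.

What is *not* emulated: LD between variants (the post-clumping regime is
assumed), sample overlap, allele-frequency sampling noise (eaf is emitted
exactly), palindromic variants, winner's curse beyond what `p < 5e-8`
selection on the exposure sample itself induces, and — for binary outcomes —
non-collapsibility: the generator plants a linear structural model on the
log-odds scale, so passing tests show estimator correctness under that
model, not robustness to the odds-ratio non-collapsibility of real
case-control data.

### Scenario presets and their parameter choices

`dense_area_default` is the package's anchor scenario: a protective
continuous exposure acting on a binary outcome partly through a continuous
mediator — `α = −0.56`, `β_med = 0.41`, `β_direct = −0.1804`, hence total
effect −0.41 on the log-odds scale and proportion mediated exactly 0.56;
100 candidate SNPs (25 % mediator-specific), n = 50 000 per sample, MAF in
(0.1, 0.45), case fraction 0.5. `gamma_sd = delta_sd = 0.08` was fixed by a
design calculation before any estimator was run on the scenario: at these
sample sizes it yields mean F ≈ 200 with ~60 % of candidates genome-wide
significant, and makes the selection (winner's-curse) bias of IVW ≈ 0.004 —
negligible against the −0.41 truth, which is the regime a well-powered MR
study assumes. `null_mediation` sets `α = 0` with the same machinery;
`continuous_mediation` swaps the outcome to a continuous trait (the
collapsible scale on which product and difference must agree).

`invalid_40pct` plants directional pleiotropy (`mean 0.04, sd 0.005`,
exposure-increasing orientation) on 40 % of 100 instruments for a true
effect of 0.4, with n = 300 000 per sample: large samples keep the valid
ratios tight enough (ratio SE ≈ 0.04) that the weighted median stays within
0.05 of truth while IVW is biased by ≈ 0.16. `outliers_21` plants 3 of 21
instruments with +5 outcome-SE shifts; the exposure GWAS is set ten times
larger than the outcome sample (1 M vs 100 k) so exposure-side noise barely
dilutes the planted shift under modified second-order weights — mirroring
the real asymmetry between large exposure GWAS and outcome samples.
`clustered_dense_area` plants two mechanisms (slopes +0.4 and −0.3, ten SNPs
each) plus five null SNPs with instrument strengths chosen so ratio SEs are
≈ 0.02.

## Numerical and testing notes

* Cochran's Q (and Q_A) are chi-square calibrated when exposure-side noise
  is negligible relative to outcome-side noise (the NOME regime); with a
  nonzero slope and noisy `b_X`, first-order Q inflates by roughly
  `1 + β² s_X²/s_Y²`. Calibration checks therefore use large exposure
  samples.
* All empirical p-values use the add-one estimator `(1 + #{T* ≥ T})/(n+1)`.
* Degenerate inputs: single-instrument IVW reduces exactly to the Wald
  ratio (MRE scaling is 1 when df = 0); all-zero exposure associations are a
  hard error for ratios; Egger and the weighted median require ≥3
  instruments, PRESSO-style testing ≥4, MVMR ≥ K+1.
* The pipeline derives one child seed per step from the plan's global seed,
  so re-running an identical plan reproduces every output byte for byte.
* Test and acceptance problem sizes (200 replicates for recovery and
  concordance, 500–1000 for null calibration, 100 seeds for outlier
  detection, 20 for cluster recovery) were chosen so Monte-Carlo error is
  well inside each asserted tolerance — e.g. the binomial SE of a 5 %
  rejection rate over 1000 replicates is 0.7 percentage points against a
  ±2-point band.

## Known limitations

* No LD modeling or reference-panel clumping; positional pruning is a
  stand-in and proxy-SNP substitution is unsupported (missing outcome SNPs
  are dropped).
* Difference-method and proportion-mediated CIs ignore covariances between
  estimates sharing instruments (anti-conservative for the difference
  method; conservative or anti-conservative for the ratio depending on
  signs).
* MVMR assumes non-overlapping samples; no weak-instrument-robust
  (minimized-Q) MVMR estimator — conditional F < 10 is flagged, nothing
  more.
* Binary-outcome Steiger r² is an observed-scale approximation; liability-
  scale conversion is not attempted.
* Only single-mediator decompositions; no exposure–mediator interaction or
  counterfactual (natural-effects) machinery.
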