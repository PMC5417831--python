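# Methods

## The linear response model and the log-ratio scale

A proteolytic peptide's measured abundance is modelled as y = αz + e: the
protein concentration z scaled by a peptide-specific ionization efficiency
α, plus measurement error. Ratios between two measurements of the same
peptide cancel α, so all analysis happens on the scale
x = log₂(y) − log₂(y′) against a common reference. The reference can be a
designated reference sample (or the mean of several), the peptide's own
mean across samples (`reference="mean"`), or the input may already be
relative (pre-computed ratio tables; `--flip-sign` accommodates
reference-to-sample ratios such as H/L SILAC output). The residual
log-ratio error is assumed zero-centered Gaussian, the assumption
underlying both the factor model and the ANOVA.

Zeros, negative values and empty cells in a raw intensity table are
non-detections and become missing values on ingest. Raw tables are
normalized per run by dividing each sample column by the mean of its finite
entries (idempotent; appropriate when samples contain comparable total
amounts and many peptides — for small or compositionally unbalanced tables
it should be disabled, as the column mean then tracks the few dominant
proteins). Clinical ratio data can instead be zero-centered per sample by a
two-component Gaussian mixture: the mean of the larger-weight component
(the unregulated bulk) is subtracted. If the mixture fit does not converge,
or a sample has fewer than 20 finite values, the sample median is
subtracted instead (logged). With a single very tight symmetric mode the
two fitted components straddle the mode and the major-component mean is
still within a fraction of its width; for diffuse single-mode data the
residual offset scales with that width (≈0.6 σ) — mixture centering is
meant for data that genuinely contain a dominant null component.

## Factor analysis of one protein's peptides

For K peptides over S samples, zero-mean log-ratios are modelled with one
latent factor, x = λz + ε, x ~ N(0, λλᵀ + Ψ), λ ≥ 0, Ψ diagonal. Fitting:

* Rows are standardized to zero mean and unit variance over their finite
  entries. Missing entries are then set to 0 — the null value on the
  centered scale — **for covariance estimation only**; summarization never
  imputes this way. This biases sparse peptides toward the null, which is
  conservative. Constant rows carry no covariation signal and get loading 0.
* EM on the S-averaged covariance C: the E-step gives the posterior of z
  (variance ξ = 1/(1 + λᵀΨ⁻¹λ), mean aᵀx with a = ξΨ⁻¹λ); the M-step
  maximizes the posterior under a zero-mean Gaussian prior of strength
  `prior_weight` and rectifies λ at 0. Ψ is updated as the residual
  variance, floored at `psi_floor`. Iteration stops at max|Δλ| < `tol`.
* The standardized-scale loadings are rescaled by each peptide's standard
  deviation, so reported loadings live on the observed log-ratio scale and
  track the generative λ directly (a peptide twice as responsive gets twice
  the loading, not a near-equal correlation). They are then max-normalized
  to [0, 1].

Defaults: `prior_weight` 0.1, `psi_floor` 1e-4, `tol` 1e-6, `max_iter`
1000. The fit is deterministic — there is no random initialization
(λ₀ = √(0.75·diag C)).

Degenerate case: with exactly duplicated rows Ψ collapses to its floor and
the EM fixed point leaves the *common scale* of λ under-determined (the
loadings stop short of the maximum-likelihood scale). Max-normalization
makes the reported loadings well-defined regardless, and the S/N remains
far above any realistic threshold, so informative calls and weights are
unaffected.

### Signal-to-noise and the informative call

S/N (dB) = 10·log₁₀((Σλ)²/ΣΨ), computed from the pre-normalization
loadings: the summed signal covariance λλᵀ over the summed noise variance,
capped at ±100 dB. Summing the full rank-one signal matrix makes the S/N
grow with the number of coherent peptides — k identical peptides give
k·λ²/σ² — matching the observation that protein coverage drives
quantification certainty; a per-peptide ratio (Σλ²/ΣΨ) would be flat in k.
A set of peptides is *informative* iff S/N > −20 dB (signal at least 1% of
noise); single-peptide groups have undefined covariation and are always
non-informative (S/N = NaN), though they are carried through the report
with weight 1 unless `--exclude-singletons` is set.

### Peptide weights

w = λ/max(λ); peptides with w ≤ `weight_cutoff` (default 0.5 — half of the
maximum) are considered falsely identified or unreliably quantified and are
excluded (w = 0) from summarization and testing. When several loadings tie
at the maximum, all are normalized to 1. The cutoff is applied after
max-normalization, which makes the "0.5" and "half of the maximum"
phrasings coincide.

## Summarization and missing values

Protein abundance per sample group is the weighted arithmetic mean of
finite peptide log₂-ratios (a weighted geometric mean on the raw scale):
log₂(z/z′) = Σwᵢxᵢ/Σwᵢ, missing observations omitted from numerator and
denominator. The estimate is invariant to rescaling all weights and equals
the plain mean under uniform weights with complete data.

When the missing fraction within one sample group exceeds
`impute_threshold` (default 0.70; recommended 0.95 for sparse MaxQuant-like
tables), absences are interpreted as below-detection and filled with
log₂(min/2) = (minimum finite log₂ value) − 1. The minimum is taken over
the protein's weighted peptide set across all samples (per-protein scope;
the natural alternatives — per-peptide or global — are less stable for
sparse proteins and not clearly preferable). Imputation happens after the
weight filter, so excluded peptides contribute neither values nor minima.

Baselines implemented for comparison: **Top-3** (per-sample arithmetic mean
of the three peptides with the highest overall mean abundance), **Median**
(per-sample median of non-missing values), and a simplified **PQPQ**
(complete-linkage clustering of log₂, zero-filled rows under correlation
distance 1 − r, tree cut at 0.4, per-sample average of the largest cluster;
constant rows are singletons since their correlation is undefined).

## Significance

### Weighted ANOVA

With I conditions, the fitted value of condition i is the weighted summary
x̂ᵢ. Over the finite entries of the weighted peptides: TSS = Σ(x − x̄)²,
RSS = Σ(x − x̂ᵢ)², ESS = TSS − RSS, and F = (ESS/(I−1)) / (RSS/df₂) with
df₂ = (number of finite cells) − I, i.e. IJK − I − m with m missing cells.
Because x̂ᵢ is a weighted (not least-squares) fit, ESS can be marginally
negative; F clamps it at 0. If RSS = 0 with constant data, F = 0.

### Sequential Monte-Carlo permutation FDR

Batches of 100 sample-label shuffles are applied identically to every
protein (shared shuffles preserve between-protein dependence and are
cheaper). Each protein's ESS is recomputed per shuffle with weights and
summarization fixed; T counts shuffles with ESS ≥ observed (ties count —
with strong signals the only exceedances are shuffles recreating the
observed grouping, so P_mc floors near the tie rate rather than at 1/(N+1)).
P_mc = (T+1)/(N+1) is never 0 and never above 1. After each batch,
π̂₀ = min(1, (2/m)·ΣP_mc) over all m tested proteins (equal to 1 in
expectation under a uniform p distribution) and step-up q-values
q(i) = min_{j≥i} m·π̂₀·p(j)/j are refreshed. A protein stops accumulating
permutations once T ≥ 200 (its p-value is then resolved to a few percent
relative error); the procedure stops when all remaining proteins have
q below the FDR threshold (default 0.05), or at `max_permutations`
(default 10,000, logged; results are returned at the achieved resolution).
Only informative proteins enter the testing set. At least ~10 samples
(5+5) are needed for a meaningful permutation distribution.

### PECA-style order-statistic test

Each weighted peptide gets an ordinary one-way ANOVA over its finite values
(F with (Iₖ−1, nₖ−Iₖ) degrees of freedom, where nₖ is the peptide's finite
count and Iₖ its observed conditions). Under the protein null the K
p-values are uniform, and the median of K uniforms follows
Beta((K+1)/2, (K+1)/2); the protein p is that CDF at the observed median.
For even K the lower of the two central order statistics is used, keeping
the integer-parameter beta exact for odd K and conservative for even K.
q-values use the same step-up rule. Peptide-level tests ignore the
covariation between peptides, so protein-level calibration can be
optimistic when peptides are strongly dependent; both procedures are
reported, and the permutation test is the safer default.

## Synthetic benchmark and the FQR statistic

The generator emulates a controlled mixture experiment: protein
concentration trajectories across samples from four families — linearly
decreasing (to 10%), exponentially increasing (over four orders of
magnitude, the span of the linear electrospray range), nonlinearly
(quadratically) increasing, and constant (null) — with per-protein random
starting amounts. Peptides are drawn as y = α·z·exp(ε): α log-uniform over
four decades, ε ~ N(0, noise_sd²). Multiplicative log-normal error is used
rather than additive error so that readouts stay positive while matching
the log-scale Gaussian assumption of the downstream models. Incoherent
peptides (probability `incoherent_fraction`) get a replacement trajectory:
*anticorrelated* (geometric reflection, the default and the canonical
contradicting-peptide behavior), *independent* (shuffled), or *swap*
(another protein's trajectory). Missing values are missing-completely-at-
random at `missing_rate`, plus a detection floor (default effectively off;
the floor in real data is instrument- and sample-specific).

Defaults are the benchmark study conditions: 20 samples, 500 proteins, 3–10
peptides per protein, noise_sd 0.2, 11% incoherent, 12% missing.

What the generator does **not** emulate: correlated (structured)
missingness at low abundance, retention-time or charge-state artifacts,
shared peptides between proteins, run-level intensity drift, batch effects,
or identification errors beyond the incoherent-trajectory abstraction.
Passing tests therefore demonstrate the statistical machinery under the
stated generative assumptions, not performance on any particular
instrument's output.

**FQR** (false quantification rate): per protein, the Spearman rank
correlation between all C(n,2) pairwise sample abundance ratios of the
estimates and of the true concentrations (ratios of log-scale estimates are
differences; ranks are unaffected). Pairs with missing estimates are
excluded; proteins with fewer than two valid pairs or a constant ratio
vector (e.g. null proteins) are excluded from the denominator. FQR is the
fraction of proteins with correlation below 0. Noise-only estimates give
50% by symmetry.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on simulated data:
10,000-protein noise designs for the FQR baseline (×3 replicates in the
acceptance script), 100 seeds for loading recovery and incoherent-peptide
exclusion, 1000 proteins (5+5 design) for permutation calibration, 2000
proteins for order-statistic uniformity, and the 500-protein default
benchmark for the summarizer comparison. These sizes give Monte-Carlo
standard errors comfortably inside the asserted tolerances while keeping
the whole suite under a minute of compute.

## Known limitations

* One latent factor per protein: a protein expressed as two proteoforms
  with different regulation is summarized to the dominant covariation
  pattern; the minority form's peptides are down-weighted, not deconvolved.
* Zero-filling missing entries (centered scale) for covariance estimation
  attenuates loadings of sparsely observed peptides; a full-information EM
  over arbitrary missing patterns would be less conservative but is not
  implemented.
* The dB scale of the S/N is a definition, not a law: alternative
  definitions (e.g. per-peptide signal ratios or variance explained) shift
  the distribution and would require re-choosing the informative threshold.
* Pairwise post-hoc contrasts between specific condition pairs are not
  provided; the ANOVA answers "any difference among conditions".
* Spectral processing, feature finding, identity propagation and PSM-level
  FDR control are upstream of this tool; table rows are taken as final
  peptide units (charge states and modified forms pre-summed).
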