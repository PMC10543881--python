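# Methods

## Fragment profiles

A sample enters the pipeline as an integer histogram of fragment lengths
(bp). Proportions are computed over the full recorded support (default
[50, 400] bp in the simulator), not just the analysis windows, with an
additive pseudocount (default 0.5) applied to every bin before
normalization so that the log-profile is finite even for empty bins. The
pseudocount is recorded on the profile. The feature pipeline requires
the support to contain [81, 336] bp.

When histograms are derived from alignments, the absolute template
length of first-in-pair, properly-paired, primary, non-duplicate,
non-supplementary records with MAPQ ≥ 30 (configurable) is counted.
These filters are this package's choice; fragment-size profiles are
sensitive to extraction and library chemistry, and cross-protocol
harmonization is deliberately out of scope — profiles from different
protocols should not be pooled without upstream correction.

## Fourier features

The 81–141 bp window of log p_j is detrended by a quadratic OLS fit
(length and length² regressors plus intercept), and the 61 residuals are
transformed with the unnormalized negative-exponent DFT,
F_k = Σ_{n=0}^{60} ε̂_n exp(−2πikn/61). Because the residuals are
centred, F_0 = 0; conjugate symmetry makes |F_{61−k}| = |F_k|, so only
the magnitudes |F_1|..|F_30| are emitted as features. Magnitudes rather
than real/imaginary parts are used, making the features invariant to
translations of the oscillation phase.

## Wavelet features

Log p_j over 81–336 bp (exactly 256 points) is decomposed with a
decimated orthonormal DWT using the 10-tap (five-vanishing-moment)
Daubechies filter; the filter length matches the 10 bp nucleosomal
oscillation period. The transform uses periodic boundary handling and 6
decomposition levels by default (both configurable), yielding
128+64+32+16+8+4 detail coefficients (scales 1–6, scale 1 finest) plus 4
approximation coefficients labelled scale 7 — 256 coefficients in
total, conserving the energy of the input exactly. At this depth every
coefficient's support wraps the periodic boundary; that is accepted by
design, since the profile's endpoints are smooth and low-amplitude. The
choice of a decimated (rather than maximal-overlap) transform keeps the
feature set the same size as the input and the coefficients orthonormal.

Feature names ("F1".."F30", "W{scale}_{location}" with 1-based
locations) are a stable public contract: model serialization and
selection reports refer to them. The canonical order is the Fourier
block then the wavelet block, lexicographically sorted within each.

## Labels from panel sequencing

A heterozygous clonal SNV in a copy-number-neutral region (diploid, no
loss of heterozygosity) has expected VAF θ/2, where θ is the tumour
fraction. Mutations flagged copy-number neutral are clustered by allele
frequency under a Dirichlet-process binomial mixture: CRP prior with
concentration α = 1 over partitions, Binomial(alt | depth, v_c)
likelihood, Beta(1, 1) base measure on each cluster VAF. Mutations whose
copy-number status is unknown are excluded (conservative). Inference is
collapsed Gibbs sampling (default 2000 sweeps) from a one-cluster
initial state; the reported partition is the visited state with the
highest joint posterior score, and cluster VAFs are the conjugate
posterior means (1 + Σalt)/(2 + Σdepth) given that partition. A
brute-force enumeration over all partitions (feasible to n ≈ 7)
validates the sampler in the test suite.

The tumour-content label doubles the VAF of the cluster with the largest
posterior-mean VAF; if that cluster contains only non-annotated variants
and another cluster exists, the second-largest is used instead
("maximal" is read as maximal in allele frequency, not in membership).
Because doubling can exceed 1, labels are clipped into (ε, 1−ε) with
ε = 1e-3 — the downstream beta regression needs an open-interval
response. Whether a variant counts as "annotated" is supplied by the
caller; the package imposes no database definition.

Surrogate labels (from an external copy-number tool) are consumed as a
CSV; zero-valued entries are dropped, since a response of exactly zero
is both uninformative and inadmissible for the beta likelihood.

## Beta regression by component-wise boosting

The response is modelled as Beta(μφ, (1−μ)φ) with logit link for μ.
Features are standardized (mean 0, sd 1; constant columns dropped with a
warning) and the linear predictor is built iteratively: at each step the
negative gradient of the summed negative log-likelihood with respect to
η is computed, each feature is fitted to it by simple linear regression
(intercept plus one slope), the best-fitting feature's coefficient and
the shared intercept each move by ν times their fitted values (ν = 0.1
default), and the scalar precision φ is refreshed by bounded
one-dimensional likelihood maximization on log φ ∈ [−4, 8] (tolerance
1e-4). Including the intercept in every base learner makes the procedure
converge, as iterations grow, to the joint maximum-likelihood fit — the
test suite verifies agreement with direct numerical optimization to
1e-3 in the single-feature case. Ties in the base-learner comparison
resolve to the smallest column index. Fitted means are clipped to
[1e-12, 1−1e-12] before likelihood evaluation to avoid log-gamma
overflow at extreme linear predictors.

The stopping iteration mstop — the only regularization — is tuned by
bootstrap cross-validation: 25 resamples of size n with replacement, one
boosting path fitted per resample, out-of-bag negative log-likelihood
evaluated at every candidate mstop (default grid 0..500), averaged
across resamples; ties go to the smallest mstop. Resamples with an
empty out-of-bag set are redrawn.

## Stability selection

Complementary-pairs stability selection: B = 50 pairs of disjoint
half-samples of size ⌊n/2⌋ (for odd n one sample per pair is left out
at random); on each half the boosting learner runs until q distinct
features have entered, capped at 10q iterations; a feature's selection
frequency is its proportion over the 2B runs, and features at or above
the cutoff are selected. Of the three control parameters, the
per-family error budget PFER = 1 and cutoff = 0.75 are the defaults and
q is derived from the Meinshausen–Bühlmann bound
PFER ≥ q²/((2·cutoff−1)·p) (q = 11 for the default 286 features). The
sharper Shah–Samworth bound for unimodal selection distributions is
available as an option. The budget is validated empirically in the test
suite: under a global null with PFER = 1, the mean number of selected
features over 20 replicates stays ≤ 1.5.

In the end-to-end pipeline, selection runs on the surrogate-labelled
cohort and the final model is trained on the panel-labelled cohort
restricted to the selected features. With noisy surrogate labels and
half-samples of ~35, selection frequencies can be diffuse and the
cutoff occasionally selects nothing; the pipeline then falls back to
the single most frequent feature, with a warning, rather than failing —
a pragmatic choice documented here because it changes the PFER
interpretation of that run.

## Dilution-series evaluation

Predictions are regressed on the known spike-in concentration by OLS
with a free intercept (R² = 1 − RSS/TSS, TSS about the mean) and
through the origin (R² = 1 − RSS₀/Σy², the uncentred convention; the
two conventions are not comparable and both are reported). Concentration
is the x-variable throughout.

## Synthetic data

The generator emulates the structure the method assumes, not any real
cohort:

- healthy fragment-length density: truncated-normal peaks at 166 bp
  (sd 9) and 332 bp (sd 20), weights 0.88/0.12, cosine oscillation of
  amplitude 0.05 and period 10 bp on the short side of each peak;
- tumour density: peaks at 145 bp (sd 12) and 300 bp (sd 25), weights
  0.90/0.10, amplitude 0.15;
- a uniform floor of 1e-6 is added before renormalization so the log
  density is bounded;
- a sample at tumour fraction θ draws 5×10⁵ fragments multinomially
  from (1−θ)·healthy + θ·tumour;
- panel samples carry 1 + Poisson(4) clonal mutations with
  alt ~ Binomial(600, θ/2) and 0–3 subclonal mutations at θ/4, all
  copy-number neutral, 20% non-annotated;
- surrogate labels are logistic(logit(θ) + N(0, 0.5));
- cohort tumour fractions are Beta(2.0, 3.5), a stage-IV-like law with
  lower quartile ≈ 0.19;
- the dilution series mixes a θ = 0.6 patient at concentrations
  (0, 0.05, 0.1, 0.25, 0.5, 1.0).

One global seed spawns independent per-sample child streams, so cohorts
are reproducible sample-by-sample.

What the generator does **not** emulate: GC and library-preparation
bias, batch effects between protocols, per-cancer-type fragment
signatures, sequencing error in read counts, and subclonal copy-number
structure. Passing tests on synthetic data therefore demonstrate the
correctness and internal consistency of the pipeline, not clinical
performance.

## Known limitations

- Predictions extrapolate poorly below the training range of θ: the
  log-profile features saturate at very low tumour fractions (the log of
  a small mixture weight changes fastest near zero), and training
  cohorts drawn from Beta(2.0, 3.5) contain almost no near-zero samples.
  The dilution evaluation shows this as an elevated intercept —
  tumour-free samples predicted around 0.2 rather than 0.
- Which feature survives stability selection varies with the seed among
  a correlated set of coarse wavelet coefficients; the prediction
  quality is similar, but the named feature in reports is not stable.
- The Gibbs point estimate is the best visited state, not a certified
  MAP; for ≥ 8 mutations no exhaustive check is feasible.
- The beta likelihood treats labels as exact; uncertainty in the
  panel-derived labels (finite depth, clustering error) is not
  propagated.

## Problem sizes in tests

The test suite and validation scripts use the simulator at its default
scale for the end-to-end experiment (41 + 71 training samples, 5×10⁵
fragments per sample, six dilution points) and smaller fragment budgets
(5×10⁴–10⁵) for unit tests, with 10–50 replicates for stochastic
assertions; partition-enumeration oracles run at n ≤ 7 mutations where
the Bell number stays below 900.
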