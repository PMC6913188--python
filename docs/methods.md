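# Methods

## Models

Phenotypes are per-environment adjusted line means (BLUEs) in trait units
(e.g. grain yield, ton/ha). The single-environment model is a Gaussian
process regression on a genomic kernel,

    y = μ1 + u + ε,   u ~ N(0, σu² K),   ε ~ N(0, σε² I).

The multi-environment model adds environment intercepts and a G×E
interaction component,

    y = Z_E β_E + u1 + u2 + ε,
    u1 ~ N(0, σu1² K1),  K1 = Zg G Zg',
    u2 ~ N(0, σu2² K2),  K2 = K1 ∘ (Z_E Z_E'),

so two observations share interaction covariance only when they belong to
the same environment; K2 is positive semidefinite by the Schur product
theorem. Writing the fixed part as μ1 + Z_E β_E would be rank deficient
(the intercept is the sum of the environment columns), so the implementation
uses the cell-means parameterisation — one intercept per environment — and
reports μ as their mean. Only environment intercepts are supported as fixed
effects.

## Kernels

All three kernels are built from the same standardized marker matrix X
(mean-imputed, centered, unit variance per marker; constant markers are
centered to zero and left unscaled). Using one shared X keeps the methods
comparable; note the arc-cosine kernel is norm-dependent, so its values
change materially under different scalings.

- **GB**: G = XX'/p. With standardized markers the diagonal averages exactly 1.
- **GK**: exp(−h·d²ᵢᵢ'/q), where d²ᵢᵢ' = Σₖ(xᵢₖ−xᵢ'ₖ)² and q is the median
  of the n(n−1)/2 off-diagonal squared distances (structural diagonal zeros
  are excluded because they would bias q downward; an even count is resolved
  by the midpoint). Dividing by q standardizes the bandwidth grid across
  data sets. The exponent is negative: a similarity kernel must decay with
  distance. The diagonal is exactly 1.
- **AK**: AK1(x,x') = (1/π)‖x‖‖x'‖J(θ), J(θ) = sin θ + (π−θ)cos θ, with θ the
  angle between marker vectors. This equals 2·E[relu(w·x)·relu(w·x')] for
  standard-normal weights w — the covariance function of an infinitely wide
  single-hidden-layer ReLU network — which the test suite verifies by Monte
  Carlo. Depth is added by the recursion
  AK^(l+1)(x,x') = (1/π)·√(AK^l(x,x)·AK^l(x',x'))·J(θ^l) with θ^l the angle
  implied by the layer-l kernel. The diagonal is invariant under the
  recursion and, unlike GK, heterogeneous across lines. Zero-norm marker
  vectors are rejected by name.

Numerical choices: arccos arguments are clipped to [−1,1] only when the
overshoot is ≤ 1e-12 (anything larger is an error, not rounding); kernels
are validated symmetric (1e-10) and PSD (λ_min ≥ −1e-8·max(1, λ_max)); tiny
negative eigenvalues are repaired by adding (|λ_min|+1e-10)·I, with a log
message.

## Quality control

GBS-style genotype QC mirrors standard practice: markers with minor allele
frequency strictly below `maf_min` (default 0.05) or with a missing fraction
strictly above `max_missing_marker` (default 0.60) are removed first; then
lines with fewer than `min_called_per_line` called markers (counted on
surviving markers) are removed. The filter is idempotent and preserves row
and column order. Missing calls are imputed with the per-marker mean of
observed calls, which preserves the expectation of the relationship matrix.

## Estimation

All fits maximise the exact Gaussian marginal likelihood (ML, not REML),
which makes every reported likelihood a single deterministic number suitable
for model selection. Fixed effects are profiled out by GLS and the residual
variance in closed form, leaving only the variance ratios λ_r = σ_r²/σε²:

- one kernel: eigendecompose K once; a bounded 1-D search over log λ
  (λ ∈ [e⁻²⁵, e²⁵], xatol 1e-8);
- several kernels: L-BFGS-B over log λ_r with the analytic gradient of the
  profiled likelihood (envelope theorem), three starts by default, with a
  Nelder–Mead fallback.

Variances carry a floor of 1e-10; estimates are non-negative by
construction (log-scale search). Approximate standard errors come from the
numerically differentiated observed information at the optimum and are
omitted (None) when the information matrix is not positive definite, as
happens at boundary estimates. BLUPs are û_r = σ̂_r² K_r V̂⁻¹(y − Fβ̂);
predictions for unobserved line×environment cells use the conditional
Gaussian formula under the fitted components without retraining, with
covariance entries σ̂u1²·G[l,l'] + σ̂u2²·G[l,l']·1[same environment].

For complete balanced trials (every line in every environment) the
observation kernels have Kronecker structure (K1 = J_m ⊗ G, K2 = I_m ⊗ G)
and are simultaneously diagonalizable; `fit_complete_gxe` exploits this to
reduce each likelihood evaluation to O(nm) after one eigendecomposition of
G. It returns exactly the same estimates as the dense path (tested).

Heritability is reported as the genomic main-effect share of total variance,
σu1²/(σu1²+σu2²+σε²) (σu²/(σu²+σε²) for one kernel). This is this package's
convention for a narrow-sense summary of the fitted components.

## Model selection

The AK depth l (default grid 1..8) and the GK bandwidth h (default grid
{0.1, 0.25, 0.5, 0.75, 1, 1.5, 2.5, 5}) are chosen by maximum marginal
likelihood under the model being evaluated, once per training set (not
nested). Ties within 1e-9 resolve toward the simpler candidate (smaller l,
smaller h), which also makes selection invariant to grid order. Candidates
whose fit fails are recorded and skipped.

## Cross-validation

CV2 sparse testing: within each replicate, lines are partitioned into k
folds (default 5) independently per environment, so a line masked in one
environment is typically observed in the others. Fold sizes differ by at
most one line; plans are fully reproducible from their seed. Genomic
kernels are built once from all genotyped lines — marker data are never
masked, only phenotypes — consistent with genomic-prediction practice, and
masked phenotypes never enter any training likelihood (a perturbation test
asserts this). All methods are scored on identical masks. Accuracy is MSEP
per environment over masked cells; variability across partitions is
summarised as the standard deviation (labeled as such in output).

## Neural-network baseline

A feed-forward regression network on marker dosages (plus a one-hot
environment block in the multi-environment model): ReLU hidden layers with
inverted dropout, linear output, MSE loss, RMSprop (lr 1e-3, ρ 0.9, ε 1e-7),
mini-batches of 56. The reference grid is 1–4 layers × {80..400} units ×
dropout {0,.05,.10,.20,.25,.35} (120 configurations) at 1,000 epochs, tuned
by inner fivefold CV on the training set only and refit on the full training
set; ties resolve toward fewer layers, then fewer units, then lower dropout.
The response is centered during training. Both the grid and the epoch count
are reducible for desk-scale runs; the full profile is deliberately slow and
is not exercised by the default test suite. The network is implemented
directly on numpy arrays; given a seed, training is bit-reproducible.

## Synthetic data

The generator emulates a multi-environment elite yield trial: allele
frequencies uniform on `maf_range` (default 0.05–0.5), genotypes
Binomial(2, f) independent across lines and markers, optional uniform
missingness (GBS-like), environment intercepts in trait units with irrigated
environments out-yielding droughted ones, and

    y(line, env) = env_mean + u1 + u2 + ε,

with u1 an additive marker signal plus an optional epistatic part built from
products of random marker pairs (empirically standardized so `var_epistatic`
is the exact in-sample epistatic fraction), u2 ~ N(0, σ² G) independently
per environment, and iid noise. Defaults (500 lines, 2,000 markers, 4
environments, variances 0.75/0.25/0.5) put per-environment heritability at
0.5, inside the 0.45–0.75 range typical of well-replicated yield BLUEs.
What it does not emulate: linkage disequilibrium, pedigree/family structure,
higher-order epistasis, heterogeneous error variances across environments,
and environment-specific heritabilities. Passing benchmarks on these data
therefore demonstrate correctness of the machinery and qualitative method
orderings, not expected accuracies on real trials.

## Evaluation experiment sizes

The evaluation module re-runs the package's claims at desk scale, sizes
chosen as the package's own defaults:

- Single-kernel recovery: n=500 lines, p=300 markers, 100 replicates,
  σu²=2, σε²=1. p is deliberately below n: a rank-deficient GRM pins σε²
  through its null-space directions. With p ≫ n *independent* simulated
  markers the GRM spectrum is bounded away from zero and maximum likelihood
  can legitimately push σε² to the boundary by absorbing noise into σu²K —
  an identifiability property of that simulation design, not an estimator
  defect; real GRMs have concentrated spectra through relatedness and LD.
- Null-G×E recovery: n=400 lines, m=4 environments, 100 replicates, via the
  Kronecker fast path; at this size the null interaction-share estimate is
  concentrated well below 5%.
- Paired benchmarks: fivefold CV2, 20 data replicates, selection grids
  h ∈ {0.5, 1, 2.5} and l ≤ 3. The G×E comparison uses 150 lines × 300
  markers × 3 environments. The epistasis comparison uses 300 lines × a
  30-marker panel: with independent simulated markers, pairwise relatedness
  scales as 1/√p, so for p ≫ n the Hadamard-square (pairwise-epistatic)
  covariance is nearly diagonal and the epistatic component is unpredictable
  by any kernel — including the generating one, which an oracle fit
  confirms. A low-dimensional panel keeps the p(p+1)/2 interaction space
  identifiable at desk-scale sample sizes, the regime in which nonlinear
  kernels can express their advantage; in real elite panels family
  relatedness plays that role. These runs compare method orderings (G×E
  model vs single-environment; nonlinear kernels vs GBLUP under ≥50%
  epistatic variance); the absolute MSEPs are specific to the generator.

## Known limitations

Single trait only; environment intercepts are the only fixed effects; no
pedigree kernels; no CV1/leave-one-environment-out schemes; no Bayesian
uncertainty beyond the observed-information standard errors; the ML (rather
than REML) criterion slightly biases variance components downward in small
samples, which the recovery tests quantify.
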