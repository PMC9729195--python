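# Methods

## Model family

All models describe regional pathology x(t) ∈ ℝⁿ on a weighted connectome C
as a linear time-invariant system seeded at the injection site(s):

    dx/dt = A x,     x(0) = γ · 1_seed

with A depending on the variant:

| variant         | A                                | free parameters |
|-----------------|----------------------------------|-----------------|
| NDM             | −β L                             | γ, β            |
| Nexis:global    | α I − β L                        | γ, α, β         |
| Nexis:microglia | Λ(u) − β L̃(u)                    | γ, α, β, p, b   |
| two-gene        | additive in u₁, u₂ (see below)   | 7               |

L = D − C is the graph Laplacian of the (by default symmetrized) connectome;
Λ(u) = diag(α + p·uᵢ) is local accumulation (α, p > 0) or clearance (< 0);
L̃(u) = (D − C)·diag(1 + b·uᵢ) is the modulated Laplacian, the unique linear
operator reproducing the pairwise flux β c_ij[(1 + uⱼb)xⱼ − (1 + uᵢb)xᵢ].
The factor (1 + b·uᵢ) acts as an edge conductance on the donor side: a
region's expression scales how readily pathology leaves (and enters) it.

Assumptions: dynamics are first-order and linear (no saturation or
aggregation kinetics); the modulator field u is static over the experiment;
time is measured in weeks and all rates are per week. Because the system is
linear, x(t) = exp(At)·x(0) is exact; `scipy.linalg.expm` is the solver, and
adaptive ODE integration (`solve_ivp`, LSODA at rtol 1e-10) is retained purely
as an independent cross-check in the test suite. Solutions that overflow
(extreme α·t) raise an explicit error rather than returning inf.

Useful exact properties, all enforced by tests: the microglia variant reduces
elementwise to global (p = b = 0) and NDM (additionally α = 0); symmetric C
with α = p = 0 conserves total pathology for any b (1ᵀ(D − C) = 0); A is
Metzler on the off-diagonal when all conductances are positive, so
nonnegative seeds stay nonnegative; solutions are linear in γ.

### Conventions and open choices

* **Laplacian orientation.** The pairwise model is symmetric in (i, j), so the
  default symmetrizes C ← (C + Cᵀ)/2; `symmetrize=False` uses row sums of the
  raw directed matrix. Directed atlas connectomes are therefore supported but
  the orientation convention is the caller's responsibility.
* **Modulator scaling.** Raw expression is min-max normalized to [0, 1]
  before fitting, so the conductance spans [1, 1 + b] and fitted (p, b) are
  comparable across genes. This is the single most consequential convention
  in the package; it is explicit in `normalize_gene` and surfaced in the CLI.
* **Negative conductance.** 1 + b·uᵢ ≤ 0 is physically dubious but reachable
  when b < −1 is explored during optimization; it is permitted, warned about,
  and flagged in fit results.
* **Homeostasis signature.** The first principal component of the eight
  homeostatic-microglia genes (P2ry12, Cx3cr1, Fcrls, Olfml3, Hexb, Siglech,
  Sox5, Jun), computed on column-standardized expression so per-gene affine
  rescalings are irrelevant, sign-fixed to correlate positively with mean
  standardized expression ("high score = high homeostatic abundance"), then
  min-max normalized. Regions with missing expression receive the gene median
  at load time (logged).
* **Two-gene extension.** Accumulation α + p₁u₁ᵢ + p₂u₂ᵢ and conductance
  1 + b₁u₁ᵢ + b₂u₂ᵢ — the minimal additive extension of the single-gene
  form; it reduces exactly to the single-gene model when either modulator or
  its coefficients vanish. Near-collinear modulators (|r| > 0.99) trigger an
  unidentifiability warning.

## Estimation

The objective is the pooled sum of squared residuals over all quantified
region–timepoint pairs jointly (missing observations are excluded via a
mask, never imputed). A scale-sensitive loss is deliberate: rank-preserving
but mis-scaled predictions (the classic failure mode of pure diffusion)
score poorly, which per-timepoint correlation would hide. The headline fit
statistic is the pooled R² = 1 − SS_res/SS_tot, which may be negative.

Optimization is bounded multistart trust-region least squares
(`scipy.optimize.least_squares`, TRF, tolerances 1e-8). Default bounds keep
γ > 0 and α, β ≥ 0 while (p, b) are unbounded. Rates draw log-uniform random
starts (10 by default); because the model is linear in γ, every start sets γ
at its closed-form optimum ⟨x̂₁, y⟩/⟨x̂₁, x̂₁⟩ given the rates (x̂₁ the
unit-seed prediction). A near-diffusion start (α ≈ 0, β = 1, p = b = 0) is
always included so richer models can never score below their nested
reductions when given the nested solution as an extra start.

The two-stage strategy for gene models: (1) fit Nexis:global and bootstrap
it; (2) fit the gene model with (γ, α, β) initialized at the global
bootstrap means and box-bounded by the global 95% CIs ("anchoring"), with
(p, b) free. Anchoring prevents degenerate optima in which implausible
global rates compensate for extreme modulator effects; it can be disabled
(`anchor=False`), which is also how nested-model R² dominance is verified.

**Bootstrap.** 100 iterations; each draws ⌊0.8 · n_quantified⌋ regions
without replacement, keeping all timepoints of a sampled region together
(observations of one region share anatomy, so regions are the exchangeable
unit), refits warm-started from the full-data solution, and records
parameters, pooled R² and pooled Pearson r on the subsample. 95% CIs are
empirical 2.5/97.5 percentiles. Degenerate subsamples are skipped and
logged. Everything is reproducible from a single integer seed.

**Model comparison.** AIC = n ln(SSE/n) + 2k and BIC = n ln(SSE/n) + k ln n,
with k counting all fitted parameters including γ (NDM 2, global 3,
microglia 5, two-gene 7). Additive constants are dropped, so only
differences between models on the same data are meaningful. Significance of
fit differences uses a two-sample Student's t test on arctanh-transformed
bootstrap correlations (Fisher R-to-Z); |r| ≥ 1 draws are clipped to
1 − 1e-12 and logged.

**Dilution transfer.** When the same injectate is used at lower
concentration, the strain-specific rates (α, β, p, b) are carried over fixed
and only γ is refit. Linearity in γ makes this a closed-form projection.

## Synthetic data generator

The generator emulates the structure of seeded mouse tauopathy studies so
the whole pipeline is testable without external data:

* **Connectome** — bihemispheric (default 20 regions per hemisphere, 426-region
  atlas structure scaled to desk size), left/right intra-hemisphere blocks
  exactly mirrored, symmetric inter-hemisphere block whose diagonal carries
  homotopic connections; lognormal weights (σ = 1) at edge density 0.25,
  rescaled to mean node degree 1 so diffusion rates are O(1)/week;
  disconnected draws rejected. Density 0.25 approximates mesoscale
  connectome sparsity after thresholding; degree normalization matches the
  convention of atlas connectivity matrices.
* **Modulator** — i.i.d. lognormal (σ = 1) regional expression min-max
  normalized (right-skewed, as atlas expression maps are), or an 8-gene
  table sharing one lognormal latent factor (loadings uniform in [0.5, 1.5],
  5–10% noise) for signature-recovery tests.
* **Pathology** — simulated from the generating parameters seeded at one
  region (standing in for the hippocampal injection), observed at 4, 8 and
  12 weeks, each observation multiplied by exp(N(0, σ²)) with σ = 0.10 by
  default (pathology is nonnegative and spans orders of magnitude, so
  multiplicative noise is the natural model for semi-quantitative regional
  scores); 10% of non-seed regions are left unquantified at all timepoints.
  Default generating parameters are a realistic gene-modulated regime for a
  medium-to-high-seeding tau strain: γ = 2.48, α = 0.25, β = 1.30,
  p = −0.29, b = 1.33.

All generators are pure functions of the integer seed.

What the generator does **not** emulate: image-based extraction artifacts,
atlas registration error, spatially correlated noise, inter-animal
variability (timepoints come from different animals in the real designs),
activation-dependent changes in the modulator field, and any nonlinearity of
aggregation. Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness to
real-data misspecification.

## Problem sizes and numerical choices

Test-suite and acceptance runs use 20–40-region systems, 3 timepoints and
10–100 fit/bootstrap repetitions — sizes chosen so the full pipeline
(including 20-replicate recovery and calibration studies) completes in
minutes on one core while keeping ≥ 100 pooled observations per fit.
Optimizer tolerances are 1e-8 on the loss; reduction identities are asserted
to 1e-12, conservation to 1e-9 relative, solver cross-checks to 1e-6
relative. Ties and degenerate inputs fail fast: constant gene vectors,
zero-variance observations, empty seeds, unknown region labels and
non-numeric cells all raise named errors.

## Known limitations

* The Fisher R-to-Z bootstrap comparison is anticonservative for nested
  models when fits are very good: near |r| = 1 the z-transform amplifies
  differences by 1/(1 − r²), and the extra (p, b) parameters systematically
  absorb part of the value-proportional residual noise, so a t test across
  bootstrap draws can flag an irrelevant modulator as significant. On clean
  synthetic data (pooled r ≈ 0.98) this happens in roughly half of null
  replicates; at the mediocre fit levels typical of real semi-quantitative
  data (r ≈ 0.4–0.8) the amplification is tenfold smaller. Treat the test as
  a ranking heuristic when fits are near-perfect, and prefer ΔAIC/ΔBIC there.
* Absolute AIC/BIC values are meaningless across datasets (additive
  constants dropped; k-counting conventions differ between publications).
* Anchoring makes the gene model's (γ, α, β) inherit the global model's
  bootstrap uncertainty; nested-model dominance of in-sample R² is only
  guaranteed with anchoring disabled.
* The exact solver cost is O(n³) per matrix exponential; the package is
  designed for region-level parcellations (hundreds of nodes), not
  voxel-level systems.
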