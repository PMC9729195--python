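# nexis

Connectome-based, gene-modulated network models of pathology spread — for
computational neuroscientists studying how a misfolded protein (tau in the
motivating application) propagates through the brain's anatomical network and
how molecular players such as microglial genes modulate that spread.

## The models

Pathology is a vector x(t) over n brain regions connected by a weighted
connectome C. All models are linear dynamical systems solved exactly with the
matrix exponential:

* **NDM** (network diffusion model) — pure diffusion along connections,
  `dx/dt = −β L x`, with `L = D − C` the graph Laplacian and β the global
  diffusivity (per week).
* **Nexis:global** — adds a global accumulation/clearance rate α:
  `dx/dt = (αI − βL) x`.
* **Nexis:microglia** — a regional modulator expression vector u (normalized
  to [0, 1]) alters both local accumulation and inter-regional conductance:

  `dx/dt = [Λ(u) − β L̃(u)] x`,  `Λ(u) = diag(α + p·uᵢ)`,
  `L̃(u) = (D − C)·diag(1 + b·uᵢ)`

  so that region i obeys the pairwise form
  `dxᵢ/dt = β Σⱼ c_ij[(1 + uⱼb)xⱼ − (1 + uᵢb)xᵢ] + (α + p·uᵢ)xᵢ`.
  Setting p = b = 0 recovers Nexis:global; additionally α = 0 recovers the NDM.

The initial condition is a binary indicator of the seed (injection) regions
scaled by a fitted parameter γ, since the injected amount is unknown.

Fitting minimizes the pooled sum of squared residuals over every quantified
region–timepoint pair jointly (bounded multistart trust-region least
squares), and uncertainty comes from a 100-iteration bootstrap that resamples
80% of the quantified regions. Gene models are fit in two stages: the global
parameters (γ, α, β) are first estimated and bootstrapped, then anchored —
initialized at their bootstrap means and box-bounded by their 95% CIs — while
(p, b) are fit free. Models are compared by pooled R², AIC/BIC (Gaussian
least-squares form), and a Student's t test on Fisher R-to-Z transformed
bootstrap correlations.

## Worked example

```python
from nexis import SyntheticSpec, make_dataset, fit_global, fit_microglia

ds = make_dataset(SyntheticSpec(rng_seed=0))       # 40 regions, 3 timepoints
glob = fit_global(ds.connectome, ds.data, rng_seed=0, n_boot=100)
gene = fit_microglia(ds.connectome, ds.gene, ds.data, glob, rng_seed=1, n_boot=100)
print(f"global: R2={glob.r2:.3f} alpha={glob.point.alpha:.3f} beta={glob.point.beta:.3f}")
print(f"gene:   R2={gene.r2:.3f} p={gene.point.p:.3f} b={gene.point.b:.3f}")
print("gene p 95% CI:", tuple(round(v, 3) for v in gene.ci95["p"]))
```

prints

```
global: R2=0.877 alpha=0.217 beta=1.261
gene:   R2=0.979 p=-0.072 b=1.701
gene p 95% CI: (-0.084, -0.045)
```

The synthetic study was generated with a gene effect (p = −0.29, b = 1.33):
the gene model raises pooled R² from 0.88 to 0.98, recovers the signs of the
modulator effects (negative p: the modulator clears pathology locally;
positive b: it boosts inter-regional spread), and its bootstrap CI for p
excludes zero. Estimator classes (`NDM`, `NexisGlobal`, `NexisMicroglia`,
`NexisTwoGene`) expose the same pipeline with a scikit-learn-style
`fit`/`predict`/`score` interface.

A CLI covers the scripted workflows end to end:

```bash
nexis synth --config synth.yaml --out data/
nexis fit --config fit.yaml --out results/ --seed 3
nexis compare|dose-response|dilution --config cfg.yaml --out results/
```

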