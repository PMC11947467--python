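# crowdcycle

Reaction–diffusion modelling of collective cell migration with cell-cycle
dynamics and density-dependent ("crowding") regulation — simulation,
traveling-wave analytics, Bayesian calibration, and a synthetic-data
generator, in one tested pipeline.

## The scientific problem

Epithelial cells sense local tissue density and slow their cell cycle when
crowded (contact inhibition of proliferation). FUCCI reporters make the
cycle visible: red nuclei are in G0/G1, green nuclei in S/G2/M. In tissue
expansion experiments, the crowded centre is G1-rich while the free edge is
full of cycling and freshly divided cells. `crowdcycle` implements a
minimal two-compartment continuum model that quantifies this coupling and
lets you ask how crowding shapes invasion fronts and what kinds of
experiments can (or cannot) constrain the crowding parameters.

The model tracks the densities ρ₁(x, t) of G0/G1 (plus post-mitotic) cells
and ρ₂(x, t) of S/G2/M cells (cells/mm²):

    ∂ₜρ₁ = D Δρ₁ − k₁ ρ₁ f(ρ) + 2 k₂ ρ₂ g(ρ)
    ∂ₜρ₂ = D Δρ₂ + k₁ ρ₁ f(ρ) − k₂ ρ₂ g(ρ),     ρ = ρ₁ + ρ₂

with shared diffusivity D (μm²/h), intrinsic G1→S rate k₁ and division
rate k₂ (1/h; the factor 2 is the two daughters of a division), and
crowding functions f(ρ) = (1 − ρ/K₁)₊ and g(ρ) = (1 − ρ/K₂)₊ that switch
the transitions off as density approaches the thresholds K₁ and K₂
(cells/mm²). Heaviside and constant (exponential-growth) variants of f and
g are also available.

Key quantities the package computes:

- **Local kinetics** — growth matrix, its dominant eigenvalue λ(ρ), stage
  durations 1/(k₁f(ρ)) and 1/(k₂g(ρ)), doubling time ln 2 / λ(ρ).
- **Pulled-front speed** — c_min = 2 √(D λ(0)) with
  λ(0) = (−k₁−k₂+√(k₁²+k₂²+6k₁k₂))/2, independent of K₁, K₂; plus the
  single-rate Fisher–KPP-style approximation √(2 D r), r⁻¹ = k₁⁻¹ + k₂⁻¹.
- **Tissue composition** — the reduced (Heaviside) model's closed-form
  S/G2/M bulk density and edge excess, which on the supercritical branch
  (K₁/K₂ > α_κ, α_κ = 2/(√(κ²+6κ+1) − κ + 1), κ = k₁/k₂) equals K₂ − K₁.
- **Bayesian calibration** — seeded ensemble MCMC for
  θ = (D, k₁, k₂, K₁, K₂) plus a noise scale σ against replicated density
  profiles, with convergence diagnostics and a practical-identifiability
  report (posterior/prior sd ratio per parameter).

## Worked example

The calibrated reference parameters for expanding MDCK tissue are
`crowdcycle.POSTERIOR_MODES`: D = 1300 μm²/h, k₁ = 0.612 /h, k₂ = 0.457 /h,
K₁ = 4965, K₂ = 5435 cells/mm². The wave report evaluates every closed
form at once:

```sh
$ crowdcycle --quiet wave --D 1300 --k1 0.612 --k2 0.457 --K1 4965 --K2 5435
{
  "cmin_um_per_h": 33.62367276996346,
  "fkpp_cmin_um_per_h": 26.081444002102312,
  "intrinsic_rate_per_h": 0.2616314312441534,
  "regime_4r_over_k1_plus_k2": 0.9789763563859809,
  "alpha_kappa": 0.6776255924053517,
  "branch": "supercritical",
  "rho2_bulk": 1892.0550221927954,
  "rho2_edge": 2362.055022192795,
  "edge_minus_bulk": 469.9999999999998
}
```

Reading the numbers: the tissue edge should advance at ≈ 33.6 μm/h (the
single-rate approximation says 26.1 μm/h, and 4r/(k₁+k₂) ≈ 0.98 warns that
this reduction is only marginally valid here); K₁/K₂ ≈ 0.914 exceeds
α_κ ≈ 0.678, so the invaded bulk keeps a frozen S/G2/M population of
≈ 1892 cells/mm² (≈ 0.35 K₂) and the edge peak exceeds the bulk by exactly
K₂ − K₁ = 470 cells/mm².

The same pipeline from Python, including a full synthetic-data → MCMC
round trip:

```python
import crowdcycle as cc

data = cc.expansion_scenario(cc.expansion_spec(seed=11))   # 11 noisy replicates
samples = cc.sample_posterior(
    data.observations, cc.PriorSpec(),
    cc.InferenceSettings(model="full", grid_n=250, seed=3),
)
print(cc.posterior_summary(samples)["D"].mode)   # ≈ 1291 (truth 1300)
```

The other subcommands — `crowdcycle simulate`, `synth`, `fit` — are thin
YAML-configured wrappers over the same functions; see
`examples/colonization.yaml` for a complete barrier-release simulation
configuration.

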