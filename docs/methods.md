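# Methods

## The model

`soilsem` fits a hierarchical Bayesian structural equation model (SEM)
relating five latent soil constructs measured on depth-increment samples
from replicated soil pits under three land-use classes (managed pasture
MP, pristine grassland PG, pristine forest PF).

**Latent structure.** Two exogenous latents — *weathering* (ξ₁) and
*acidification* (ξ₂) — are bivariate standard normal with free correlation
ϕ.  Three endogenous latents — *fertility* (η₁), *microorganisms* (η₂) and
*SOC persistence* (η₃) — follow recursive structural equations

    η = Σ_parents γ·parent + ς,    ς ~ N(0, 1/τ_ς),

over an acyclic path set.  Two path presets are built in:

* `figure3` (default): acidification→fertility, fertility→microorganisms,
  weathering→SOC, acidification→SOC — the edge set carrying the four
  reported effect sizes;
* `methods`: fertility ← weathering + acidification + microorganisms,
  microorganisms ← acidification, SOC ← weathering + microorganisms — the
  recursive system written out in the equations of the source analysis.

The two presets disagree in the original description; rather than guessing
a single intent, both are implemented and the preset is a declared option.
Coefficients are keyed by edge, never by symbol subscript (the original
equations reuse one subscript for two different coefficients).

**Measurement model.** Each of p = 19 manifest variables loads on exactly
one latent (simple structure):

    y_i = α_{j(i)} + Λ ω_i + ε_i,

with a soil-pit-specific intercept α_j per manifest (j = 1…9),
ε ~ N(0, diag(1/τ_ε)).  The 19 manifests are: Al_o/Al_tot, Fe_o/Fe_tot,
Fe_d/Fe_tot and silt % (weathering); 10^−pH and Al saturation
(acidification); N_t/P_total, δ¹⁵N, P_Bray and summed exchangeable base
cations Ca+K+Mg (fertility); basal respiration, qCO₂, C_mic, N_mic, P_mic
(microorganisms); T50, C_pyro, and carbon in the < 63 µm fraction per soil
and per fraction (SOC persistence).  The exchangeable base cations enter
as a single summed manifest (cmol_c kg⁻¹), matching their presentation as
one composite indicator.

**Identification.** Manifests are column-standardized before fitting; one
anchor loading per latent (the first listed manifest) is fixed to +1;
exogenous latent variances are fixed to 1 with ϕ free on (−1, 1).  This is
the standard scale/sign resolution for latent-variable models; the
original analysis does not state its identification choices, so numerical
equivalence with it is not claimed.  Raw-scale fitting is possible through
the array interface but is not the default.

**Priors.** N(0, 100) — read as mean 0, *variance* 100 — on all free
loadings and path coefficients; Gamma(shape 6, rate 10) on all error
*precisions* (measurement and structural), the stated-engine convention
for error terms; α_j ~ N(0, σ_α²) with σ_α ~ U(0, 100); ϕ ~ U(−1, 1).
Both distribution-parameterization readings are recorded in `PriorSpec`
and can be changed there.

## Sampling

Systematic-scan Metropolis-within-Gibbs with fixed update order:
intercepts, latent scores, loadings, path coefficients, precisions, ϕ,
σ_α.  Latent scores are sampled jointly per observation (the conditional
is multivariate normal with a precision shared across observations, so
one Cholesky factorization serves the whole scan); loadings, path
coefficients, precisions and intercepts use their conjugate
Normal/Gamma conditionals.

ϕ takes Gaussian random-walk Metropolis steps on the Fisher-z scale
(`atanh ϕ`), refreshed 10 times per scan; the z-scale walk behaves well
when the posterior concentrates near ±1, which happens whenever the two
exogenous blocks share strong group structure.  Step sizes adapt toward
44% acceptance during burn-in only and are frozen afterwards, preserving
detailed balance of the post-burn-in chain.

σ_α is updated from its conditional with the intercepts *marginalized
out*: per (pit, manifest) cell the pit mean of the measurement residuals
is N(0, σ_α² + 1/(n_j τ_m)), a one-dimensional target sampled by
Metropolis, after which the intercepts are redrawn — a joint
(σ_α, α) block.  A naive update conditioning on all 171 intercepts is the
classic hierarchical funnel and mixed more than an order of magnitude
worse in effective draws; the collapsed block removes the funnel without
changing the posterior.

Chain c uses seed `base_seed + c`; all draws flow through one
`numpy.random.Generator` per chain in fixed order, so runs are
bit-reproducible.  The default schedule is 3 chains × 50,000 iterations,
30,000 burn-in, thinning 16 — retaining 1,250 draws per chain, 3,750
total.  Convergence gates: split-chain R̂ < 1.1 and ESS > 500 for every
monitored parameter (paths, free loadings, precisions, ϕ, σ_α).

## Diagnostics

R̂ is the classic Gelman–Rubin statistic on split chains (each chain
halved), not the rank-normalized variant; the ESS uses the
initial-positive-sequence autocorrelation estimator (Geyer truncation at
the first non-positive paired sum), computed per chain and summed, capped
at the chain length.  Both match `arviz`'s corresponding estimators on
test fixtures, but the original analysis does not state which variants its
engine used, so exact numerical agreement with it is not claimed.

## Synthetic data

The generator emulates the study design so that every downstream stage is
testable without field data: 9 pits (3 per land use), increments
0–5/5–10/10–20/20–30/30–40 cm, truncated at bedrock.  The published
material states only the total n = 39; the per-pit bedrock depths are
fixed by convention here as six pits to 40 cm and the third pit of each
land-use class to 20 cm (6×5 + 3×3 = 39).  Which pits were actually
shallower is unknowable from the published record; any consistent choice
yields the same total.

Default generating parameters (the conditions under which all recovery
results are reported):

| parameter | default | rationale |
|---|---|---|
| path coefficients | −0.75, 0.71, 0.69, 0.44 on the `figure3` edges | the reported posterior medians, used as ground truth for recovery |
| ϕ | 0.5 | weathering and acidification are described as interdependent; moderate positive value |
| loadings | anchor 1.0, others 0.8 | typical well-measured indicators |
| measurement error sd | 0.5 | indicator reliability ≈ 0.7–0.8 on the latent scale |
| structural noise sd | 0.5 | endogenous latents keep near-unit variance |
| pit intercept sd | 0.3 | between-pit variation smaller than within-profile variation |
| land-use latent shifts | weathering: MP +0.8, PG/PF −0.4; acidification: MP +0.6, PG/PF −0.3 | pastoralism accelerates both weathering and acidification; contrasts roughly centred |

Because the MP-versus-pristine contrast shifts both exogenous latents in
the same direction, the fitted ϕ posterior concentrates well above the
within-group value of 0.5 — the model sees the combined within- plus
between-group correlation.  This is a property of the emulated design,
not an artifact; it widens the credible intervals of the two SOC paths
(which share correlated parents), exactly as the wide reported intervals
for those effects suggest.

Noise is Gaussian throughout, matching the model's likelihood.  The
generator does **not** emulate spatial autocorrelation, depth
autocorrelation beyond the deterministic depth trends, erosion, or
instrument-specific error structure; passing recovery tests therefore
demonstrates correctness of the estimation machinery under the model's
own assumptions, not robustness to real-data violations of them.

A second route, `emit_profile_table`, back-transforms to a
measurement-scale depth-increment table calibrated to the published group
values (e.g. MP SOC stock ≈ 21.6 kg m⁻², MP effective CEC ≈ 140 mol_c
m⁻², MP T50 ≈ 344 °C, MP Δδ¹³C within 0.9–1.5 ‰) so the indicator
arithmetic runs on realistic input.  The profile route carries a
deliberately attenuated imprint of the latent structure; quantitative
recovery experiments use the direct manifest route.

## Indicators

Fine-earth mass per increment is bulk density × thickness × (1 − stone
volume fraction), with the stone correction volumetric on fine-earth bulk
density; areal stocks are concentration × fine-earth mass, and
whole-profile statistics use summed stocks or soil-mass-weighted mean
concentrations.  Effective CEC is the plain sum of the eight quantified
exchangeable cations; Al saturation is the exchangeable-Al share of it.
T50 is the linearly interpolated first crossing of 50% cumulative evolved
CO₂ on the ramped-combustion curve (140–900 °C).  Microbial biomass uses
chloroform-fumigation conversion factors 0.45 (C) and 0.4 (N); a
fumigated extract below its control raises a negative-flush error rather
than returning a negative biomass.  Organic matter is 1.724 × organic C
(van Bemmelen).  Fraction carbon shares report recovery against a
configurable 85–115% quality band — the published record reports achieved
recoveries, not a threshold, so the band is a repository choice.

Δδ¹³C is returned as a non-negative enrichment magnitude together with
the raw signed soil-minus-plant difference: the definition (plant minus
soil, "more negative = more enriched") and the reported usage (positive
"enriched by 0.9–1.5" values) use opposite signs, and keeping both
reconciles them without discarding information.  qCO₂ follows the
composite-table units (µg CO₂-C mg⁻¹ C_mic day⁻¹); the running-text unit
string (mg CO₂-C kg⁻¹ C_mic⁻¹ day⁻¹) differs by a factor 1000 and both
conventions are documented at the function.  P_mic is generated and passed
through; no measurement protocol for it is described in the source
material.

## Problem sizes in the test suite

The pytest suite sizes its MCMC runs to the property being checked: the
bookkeeping and determinism contracts use a few hundred iterations, the
convergence-gate check uses a 20,000-iteration schedule (which passes the
full gates R̂ < 1.1, ESS > 500), and the 20-replicate recovery experiment
uses single chains of 5,000 iterations.  `scripts/acceptance.py` runs the
complete published schedule (3 × 50,000, burn-in 30,000, thin 16).

## Known limitations

* Latent scores are sampled, not marginalized; with far larger p the
  collapsed alternative could mix better.
* Only 1 or 2 exogenous latents are supported (ϕ is a scalar correlation).
* No missing-data handling: the pipeline expects complete tables.
* The whole-profile group statistics operate on n = 3 pits per class —
  with such sizes the ANOVA/Tukey machinery is exact but weakly powered,
  as in the emulated study.
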