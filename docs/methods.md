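# Methods

`desolv` models the saturation mole fraction of crystalline drugs —
non-selective COX inhibitors of the profen family and close analogs —
in deep eutectic solvent (DES)–water mixtures and conventional
solvents. It couples three layers: a simplified COSMO-RS sigma-potential
engine that produces solvent-sensitive molecular descriptors, a
solid–liquid-equilibrium (SLE) solubility calculation from fusion data,
and a tuned, ensemble-weighted regression model on top of both. A
synthetic-data generator with a known ground-truth surface makes every
stage testable without proprietary inputs.

## Sigma-profiles and sigma-potentials

A compound's sigma-profile p(σ) is the histogram of its COSMO
screening-charge density over the molecular surface, discretised on the
canonical grid of 61 points from −0.03 to +0.03 e/Å² (step 0.001). The
sigma-potential μ_S(σ) of a liquid S — the affinity of the phase for
surface of polarity σ — is obtained from the segment self-consistency
equation

    ln Γ_S(σ_m) = −ln Σ_n p_S(σ_n) Γ_S(σ_n) exp(−ΔW(σ_m,σ_n)/RT)
    μ_S(σ) = RT ln Γ_S(σ) / a_eff

with the exchange energy

    ΔW(m,n) = (α′/2)(σ_m+σ_n)² + c_hb · max(0, σ_acc−σ_hb) · min(0, σ_don+σ_hb).

The interaction constants are the widely used published segment-model
parametrisation (α′ = 16 466.72 kcal·Å⁴·mol⁻¹·e⁻², c_hb = 85 580
kcal·Å⁴·mol⁻¹·e⁻², σ_hb = 0.0084 e/Å², a_eff = 7.5 Å²), stored as a
versioned frozen dataclass in `config.py`. This reproduces the
*structure* of commercial COSMO-RS sigma-potentials — temperature
dependence, misfit curvature, hydrogen-bond wings — which is what the
descriptor pipeline needs; absolute agreement with any commercial
parametrisation is not claimed and not required downstream.

Numerics: the self-consistency equation is solved by damped fixed-point
iteration (damping 0.5, tolerance 1e−10 on the max-abs change of ln Γ,
cap 10 000 iterations; non-convergence raises with the final residual).
Tests cross-check the fixed point against an independent dense
nonlinear solve (`scipy.optimize.root`) on small profiles, agreeing to
better than 1e−8 kJ/(mol·Å²). The Boltzmann kernel is cached per
(grid, T), and activity evaluations warm-start from the previous
composition, which matters because a full SLE solve evaluates the
mixture fixed point tens of times.

For multicomponent solvents the default convention is mole-fraction
weighting of the *pure-component sigma-potentials* using the
solute-free composition; the alternative (mix the profiles first, then
solve once) is available behind `EngineConfig.mix_profiles_not_potentials`.
A DES with HBA:HBD ratio 1:k contributes fractions (1/(1+k), k/(1+k));
choline chloride is one component (ion pair); water enters through
x*_DES, the solute-free DES mole fraction, e.g. ChCl:TEG 1:2 at
x*_DES = 0.9 → (0.30, 0.60, 0.10).

The descriptor family used by the model is the *relative*
sigma-potential Δμ(σ) = μ_solute(σ) − μ_solvent(σ), pointwise at the
record's temperature.

## SLE solubility

Ideal solubility follows the Schröder–van Laar form
ln x_ideal = −(ΔH_m/R)(1/T − 1/T_m), with the ΔC_p correction terms
added only when a heat-capacity change is supplied (the study compounds
use the two-parameter form). Literature-mean fusion data are built in:
ibuprofen/dexibuprofen T_m = 348.64 K, ΔH_m = 26.69 kJ/mol; ketoprofen
367.99 K, 25.52 kJ/mol; flurbiprofen 387.34 K, 27.86 kJ/mol. At
298.15 K these give ideal solubilities of 0.210 and 0.142 for ibuprofen
and ketoprofen.

Saturation solves ln(x·γ(x,T)) = ln x_ideal(T) *fully* — a bracketed
Brent root solve in ln x seeded by the dilute-limit estimate
x_ideal/γ_∞ — rather than by successive substitution
x ← x_ideal/γ(x), which oscillates or diverges when γ varies steeply
near a large x_ideal (a test constructs exactly such a
counterexample). With constant γ = c the solver reproduces the closed
form x_ideal/c to 1e−10. The default activity model is the segment
(residual) COSMO-style γ of the solute in the saturated mixture; ideal
and constant-γ models are provided for testing. The Staverman–
Guggenheim combinatorial contribution is omitted: for the descriptor
role the potential plays here, the residual term carries the
solvent-discriminating signal, and the omission is uniform across all
records.

## Descriptor selection and feature table

For every grid point, the log10 experimental solubility is regressed
(univariate OLS) on Δμ(σ) separately within the non-DES and the DES
subsets; a point is kept when R² > 0.4 in *either* subset (strict
inequality; threshold configurable). Log-scale solubility is the
default (a linear-scale flag exists) — the regression form is a design
choice of this package. Each record's feature row is then: log10 of
the fully solved SLE solubility, the temperature, and Δμ at the
selected points, in a fixed column order.

## Model selection

The data are shuffled (seeded) and split 70/15/15 into
train/test/validation using two-stage ceiling rounding — the test
fraction is split off first, then validation from the remainder — so
581 records yield (406, 88, 87).

Candidate regressors are tuned by minimising a custom score with a
tree-structured Parzen estimator (TPE) implemented in `tpe.py`
(univariate Parzen densities, γ = 0.25 good/bad split, 10 random
startup trials, 24 candidate draws; fully seeded). The score is

    total = CV-MAE + λ · (MAE_val@largest + max(0, MAE_val − MAE_train)@largest)

where the penalty terms come from a two-point learning-curve analysis
(50% and 100% of the LCA training partition) during tuning and a
20-point curve for final audits; λ defaults to 1. The penalty ranks a
memorising model strictly below an equally accurate regularised one.

The reference network architecture is a feed-forward MLP with hidden
layers (64, 17, 45, 54, 18, 14, 45, 61), ReLU activation, L-BFGS
solver, adaptive learning rate and L2 penalty α = 0.045 (an alternative
reported value of 0.024 is accepted in config; 0.045 is the default as
the tuned value). Desk-scale runs cap L-BFGS at 10 000 iterations; the reference
protocol's cap of 928 539 is available via `FULL_SCALE_MAX_ITER`.
Features are z-scored with training-set statistics inside each model
pipeline. The desk-scale tuning space spans a ridge family and small
MLPs (1–2 hidden layers, 4–64 units); the default trial count is 100,
with the same machinery scaling to thousands of trials.

Ensemble weights minimise the validation RMSD over the probability
simplex (SLSQP with analytic gradient, uniform start); members below
1% weight are pruned, the weights re-optimised and renormalised. When
one model dominates, the optimum collapses onto it, reproducing
single-best selection. Exactly degenerate members keep the uniform
start, i.e. equal weights. Analog prediction builds descriptor rows
for new (compound, system, T) combinations and requires fusion data;
compounds without it are skipped with a warning, since the SLE
descriptor cannot be formed.

## Synthetic data: what it emulates and what it does not

The generator emulates the study conditions: 600 records by default,
~30% in conventional (non-DES) solvents; DES systems drawn from the
ChCl/BI × six-polyol × {1:1, 1:2} grid at x*_DES ∈ {0.6, 0.8, 0.9, 1};
temperatures 298.15–313.15 K; solutes form a close analog family with
nearly identical apolar sigma-profiles (≥80% of surface within
|σ| ≤ 0.005, plus a small carboxylic donor/acceptor pair) but distinct
fusion data (T_m 330–400 K, ΔH_m 20–30 kJ/mol) — as for the profen
analogs, where lattice effects are not readable off the surface
polarity. The true surface is

    log10 x = −1.5 + log10 x_ideal(T) + Σ_i β_i z_i + 0.15 (z_0² − 1) + ε

with z_i the relative potential at planted grid indices (defaults 16
and 44, i.e. σ = −0.014 and +0.014) standardised over the dataset,
β = (0.6, −0.6) dex, and ε Gaussian with SD 0.1 dex (typical
inter-laboratory solubility scatter). The −1.5 dex baseline keeps the
noisy observations below saturation.

Physically generated Δμ columns are smooth in σ, so neighbouring grid
points are nearly collinear: selection then recovers contiguous bands
(as real studies report), and *exact* index recovery is not a
well-posed target. A decorrelated mode (`gen_planted_features`)
therefore exercises the R² > 0.4 rule in isolation: i.i.d. per-point
features except a shared latent factor at the planted indices,
calibrated to a per-point R² of ~0.7 so the threshold is exercised
from both sides. Passing tests on synthetic data demonstrate that the
machinery recovers a known surface under realistic noise; they do not
certify accuracy on laboratory data, whose activity coefficients,
measurement-error structure and solvent chemistry are richer than the
generator's.

Calibration series mirror the reference UV setup: 11 levels from
0.0126 to 0.0504 mg/mL on the line A = 27.268·C + 0.001 with Gaussian
absorbance noise. Cosolvency curves are unimodal in x*_DES with the
maximum pinned at the requested grid point, exceeding the neat-DES
value by a chosen amplitude.

## Wet-lab data reduction

Calibration fits are OLS; detection limits follow the ICH convention
LOD = 3.3·s/slope, LOQ = 10·s/slope with s the residual SD — chosen
because the reported LOQ/LOD ratios of such curves equal 10/3.3 ≈ 3.03.
Mole fractions from absorbance use the measured density: C mg of
solute per mL of saturated solution, solvent mass 1000·ρ − C mg,
apportioned by the solute-free composition and the component molar
masses (computed from structures via rdkit; ibuprofen 206.28 and
ketoprofen 254.28 g/mol to the printed precision). Replicates
aggregate as mean and sample SD (n−1). The optimal DES–water
composition is reported on the measured grid without interpolation;
ties resolve toward the neat DES, and "apparent cosolvency" requires
the maximum to strictly exceed the neat-DES value.

## Problem sizes and determinism

Default desk-scale sizes — 600 synthetic records, 100 TPE trials,
61-point grid, 5-seed recovery suites — run the full pipeline in tens
of seconds per seed on one CPU. Every stochastic step (generation,
splitting, tuning, network initialisation) takes an explicit seed, and
the pipeline writes a manifest with config hash and output digests;
re-running with the same config reproduces identical artifacts.

## Known limitations

- The sigma-potential engine is a simplified segment model on
  user-supplied or synthetic profiles; it does not generate profiles
  from quantum chemistry, handle conformer ensembles, or reproduce any
  commercial parametrisation's absolute values.
- The activity model omits the combinatorial term and treats ChCl as a
  neutral ion pair.
- Polymorphism, solvates and enantiomer-specific melting are outside
  the SLE model.
- The ensemble machinery implements two regressor families at desk
  scale, not a broad model zoo; the interfaces accept additional
  families through the same search-space/params mechanism.
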