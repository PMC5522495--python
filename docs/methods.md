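# Methods

This note documents the models implemented in porekin, their assumptions,
the defaults that matter, and the numerical choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Units and constants

Package-wide: current in pA, voltage in mV (*trans*-positive, *cis*
grounded), time in s, temperature in K, concentration in mol/L, length in
nm (cm²/s for diffusion coefficients, following electrophysiology
convention). Energies are reported in both k_BT and kcal/mol. Physical
constants are CODATA 2018 values centralized in `constants.py`; temperature
is always an explicit parameter, never baked into a formula (295 K default
for kinetics/energetics/selectivity, 300 K for the screening-length
estimates, matching the conventions of the reference system).

## Synthetic traces

The generator draws a two-state continuous-time renewal process: open
intervals ~ Exp(rate_on), blocked intervals ~ Exp(rate_off), alternating,
starting open. The sequence is then sampled onto the uniform grid (80 kHz
default), per-sample Gaussian noise is added, and the result is passed
through a causal 4-pole Bessel digital low-pass (−3 dB at 10 kHz default),
the patch-clamp hardware convention. The unfiltered continuous-time state
sequence is retained as ground truth, so events shorter than the sampling
interval or filter rise time are *deliberately* present in the truth but
invisible in the samples — this exercises the censoring corrections
downstream.

What the generator emulates: two-level traces, exponential waiting times
with concentration- and voltage-dependent rates, ~100 pA open current at
+100 mV in 1 M KCl (linear conductance, scaled with salt), filter rise
time ≈ 0.34/cutoff. What it does not emulate: baseline drift, 1/f and
excess noise, sub-conductance states, multi-channel activity. A green
recovery test therefore establishes correctness of the estimators under
the stated statistical model, not robustness to every artifact of real
recordings.

The noise amplitude is not constrained by the reference system's reports;
the default 1.5 pA RMS (pre-filter) is typical of an Axopatch-class
recording at 10 kHz bandwidth and is a fixture parameter, not a claim.

## Event detection

Levels come from the all-points histogram: a mode is accepted when its
prominence exceeds 5 Poisson standard deviations of its own height
(prominence ≥ 5√h), which keeps a sparsely occupied blocked level
detectable beside an open peak three orders of magnitude taller while
rejecting counting fluctuations; the two most prominent well-separated
modes are the levels, larger magnitude = open. A unimodal histogram raises
a distinct "no blockades" condition.

Idealization uses hysteresis thresholds at 75% (entry) and 25% (exit) of
the level gap. Entry and exit delays through the filter cancel to first
order, so dwell durations of events ≫ rise time are unbiased (measured
residual bias < 1 µs at 10 kHz). Events shorter than `min_duration`
(default 2 × rise time ≈ 68 µs at 10 kHz) are discarded and the cutoff is
recorded as the censoring floor. Event amplitude is the mean of the event
*core* — half the censoring floor is trimmed from each end — because the
filter's settling edges otherwise dilute the mean toward the open level by
a few percent.

The thresholds and minimum duration are documented choices validated
against the generator; the original analyses of this kind of data leave
their scheme unstated (commercial-software defaults).

## Rate estimation

The estimator of record is the shifted-exponential MLE: for durations
observed above a floor c, rate = n/Σ(tᵢ − c), exact for exponential data by
memorylessness, with confidence intervals from the χ²(2n) distribution of
2·rate·Σ. A histogram path (mono-exponential least squares on binned
counts, the classical display-oriented analysis) is retained for QC; the
two agree within a few percent on clean samples. Divergence from the
source analysis mechanics (histogram fits), not from its model — the MLE
is statistically equivalent and better behaved at small n.

Two corrections connect detection to estimation:

- **Dwell analysis threshold.** Detection near the floor is soft (noise
  and attenuation smear which borderline events survive), so dwell fits
  drop events below 1.5 × the floor and evaluate the shifted MLE there,
  where retention is effectively complete. Without this the escape rate
  reads several percent low.
- **Missed-event correction for capture.** Events shorter than the floor
  merge adjacent gaps, thinning the observed capture sequence by the
  detection probability q = exp(−rate_off·floor); the observed rate_on is
  divided by q (≈ 0.86 at rate_off = 2.2 × 10³ s⁻¹ and a 68 µs floor).
  Without it k_on recovers ~14% low at the reference conditions.

k_on is the slope of rate_on vs concentration by inverse-variance weighted
least squares **through the origin** — the bimolecular model presumes
proportionality; a free-intercept variant exists behind a flag for
diagnostics. k_off is the inverse-variance weighted mean of rate_off. Fits
with slope SE > 50% of the slope are flagged rather than refused.

## Voltage-dependence energetics

Both voltage laws are fitted as weighted linear regressions in log space
(exact for multiplicative error, which is what rate estimates carry):
ln τ_on = ln a − ΔV/b, and ln rate_on = ln r₀ + z_eff·ΔV/V_T with
V_T = k_BT/e (25.4 mV at 295 K). The prefactor A and barrier height U* in
r₀ = A·exp(−U*/k_BT) are not separately identifiable and are never
reported; only r₀ and barrier *differences* between conditions with equal
prefactor (same analyte concentration and bulk diffusivity) are exposed:
ΔU* = k_BT·ln(r₀ᴬ/r₀ᴮ), antisymmetric under swapping, reported in k_BT and
kcal/mol. From the published zero-voltage rates 1.40 and 0.08 s⁻¹ the
package computes 1.678 kcal/mol at 295 K, consistent with the printed
1.69 within rounding of the two-significant-figure inputs.

A qualitative monotonicity classifier tags the escape branch:
τ_off decreasing with voltage = translocation; increasing =
return-to-*trans* (the signature of a larger analyte that cannot pass, as
for generation-2 dendrimers); no quantitative fit is attached to the
latter.

## Drift–diffusion transport

Residence times are modelled as the mean first passage time of a particle
drifting and diffusing on [0, L] (L = pore length, default 10 nm),
**reflecting at the entry, absorbing at the exit, constant drift**:

    τ(v, D) = L/v − (D/v²)(1 − e^(−vL/D)),

evaluated as (D/v²)(u + expm1(−u)) with u = vL/D, and by series for
|u| < 10⁻⁴ (limits L²/2D as v → 0 and L/v as u → ∞). The drift velocity is
Einstein mobility times the electrophoretic force minus an electro-osmotic
slip: v = (D/k_BT)(z_eff·e·ΔV/L) − v_eo, with the potential assumed to
drop uniformly along the pore. v_eo is an explicit per-condition scalar
(default 0); no microscopic water-flux model is attempted. The boundary
conditions are a declared stand-in for an unavailable original formalism;
the variant is labelled in every report so a two-absorbing (inverse
Gaussian) alternative can be swapped in.

The inversion for D minimizes squared log-residuals of modelled vs
observed τ over log₁₀D ∈ [−14, −1] (bounded scalar minimization, exact on
noiseless forward data); a per-point bisection solve supplies a
scatter-based SE. Because in-pore interactions not in the model can only
lengthen the dwell, the result is a lower-limit estimate. The published D
values (3.04, 1.78, 1.12 × 10⁻⁸ cm²/s) are used as fixture ground truth
for recovery tests, not re-derived from data.

The closed form is validated against an independent Euler–Maruyama
first-passage simulation with Brownian-bridge absorption (2% tolerance at
u ∈ {0, 1, 5}). Note the ballistic limit converges slowly: τ = (1 − 1/u)·L/v,
so 1% agreement with L/v requires u ≈ 100, not u = 10.

## Charge and screening

Analyte net charge uses Henderson–Hasselbalch protonated fractions summed
over basic groups. The default generation-1 PAMAM model (8 primary amines
pKa 9.0; 4 outer tertiary pKa 6.0; 2 core tertiary pKa 1.5) is a
*calibration* chosen to reproduce the reported net charges (+12 at pH 3,
+8 at pH 7, ≈ 0 at pH 10.3), not a literature pKa table, and is fully
overridable. Debye (κ⁻¹ = √(ε₀ε_r k_BT / 2N_A e² I·10³)) and Bjerrum
(e²/4πε₀ε_r k_BT) lengths default to 300 K, ε_r = 78. The excluded-volume
blockade relation ΔI ~ σΔV·δ/l_p² is implemented as an order-of-magnitude
proportionality only and is never inverted for an analyte volume.

## Ion selectivity

Pitzer 1:1-electrolyte activity coefficients with standard KCl 25 °C
coefficients (β⁰ = 0.04835, β¹ = 0.2122, C^φ = −0.00084, A_φ = 0.392,
b = 1.2, α = 2.0), valid for 0 < m ≤ 6 mol/kg; molarity and molality are
treated interchangeably for KCl ≤ 3 M (≲ 2% at 3 M, a documented
approximation the reference analysis also makes). The reversal potential
is the zero-current crossing of the I–V series by linear interpolation
(linear-fit root available), and the permeability ratio follows the
printed GHK form exactly; its closed-form inverse
(exp(ψF/RT) = (a_Cl^t + r·a_K^c)/(a_Cl^c + r·a_K^t)) makes the pair
mutually inverse to 10⁻⁹. Symmetric activities at zero potential make the
equation 0/0 — any ratio reverses at 0 mV — and the non-selective limit 1
is returned for that degenerate case. The reference ratios 0.453 (pH 3)
and 0.703 (pH 7) are verified by roundtrip only, since the underlying
reversal potentials are not published.

## Pipeline determinism and scaling

All randomness flows from explicit integer seeds (config-listed; no hidden
entropy); identical config + seeds give identical outputs, and the run
manifest records the package version and a SHA-256 of the canonical config.
Test-suite recovery runs are scaled down (shorter traces, fewer seeds)
relative to the full acceptance runs to stay within a CPU-minutes budget;
the acceptance checks themselves use the stated trace lengths and
10-seed ensembles.

## Known limitations

- Single-channel, two-level idealization only: no HMM, no baseline
  correction, no sub-states, no multi-channel recordings.
- ABF ingestion is not included (no offline-capable reader available);
  user traces enter as CSV/NPZ.
- The Pitzer A_φ is fixed at its 25 °C value; the few-kelvin difference to
  295 K is below the model's own accuracy here.
- The MFPT boundary conditions and v_eo are modelling choices, not
  measurements; D estimates are lower limits conditional on them.
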