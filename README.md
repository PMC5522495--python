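# porekin

Single-molecule nanopore blockade kinetics: simulation and analysis of
two-state current recordings of reversible analyte capture by a protein
nanopore (the α-hemolysin / PAMAM-G1 dendrimer system is the built-in
reference parameterization).

## What it does

A charged analyte added on the *trans* side of an α-hemolysin pore under a
positive transmembrane potential produces stochastic, downward current
blockades. From such two-level traces the package extracts, per experimental
condition (pH, salt, voltage, concentration, temperature):

- **Event statistics** — all-points histograms, open/blocked levels I_o and
  I_blocked, event tables with inter-event times τ_on, dwell times τ_off and
  blockade amplitudes ΔI_block; the relative blockade ΔI_block/I_o.
- **Bimolecular kinetics** — censored-exponential maximum-likelihood rates
  (rate = n/Σ(tᵢ − c) for dwells observed above a censoring floor c, with a
  missed-event correction for the capture rate), and the rate constants
  k_on = rate_on/[C] (through-origin weighted fit vs concentration) and
  k_off = rate_off (weighted mean).
- **Capture energetics** — van't Hoff–Arrhenius fits τ_on = a·exp(−ΔV/b) and
  the Kramers form rate_on = r₀·exp(z_eff·e·ΔV/k_BT), giving the
  zero-voltage capture rate r₀ and effective valence z_eff, plus barrier
  differences between conditions ΔU* = k_BT·ln(r₀ᴬ/r₀ᴮ).
- **Transport** — a 1-D drift–diffusion mean-first-passage model
  (reflecting entry, absorbing exit, constant drift from electrophoresis
  minus electro-osmosis) inverted for a lower-limit intrapore diffusion
  coefficient D; Stokes–Einstein radius conversion; Debye/Bjerrum screening
  lengths; a Henderson–Hasselbalch net-charge model for the dendrimer.
- **Ion selectivity** — Pitzer activity coefficients for KCl, reversal
  potentials from I–V data, and the Goldman–Hodgkin–Katz permeability ratio
  P_K⁺/P_Cl⁻ under a salt gradient.

Because no public recordings exist for the reference system, the package
ships a synthetic trace generator (two-state renewal process, exponential
dwells, Gaussian noise, 4-pole Bessel low-pass at 10 kHz, 80 kHz sampling)
whose ground truth makes every stage testable by parameter recovery.

## Worked example

```python
import numpy as np
import porekin as pk
from porekin.pipeline import ConditionConfig, simulate_condition_trace

# acidic, 1 M KCl, +100 mV: generator truth k_on = 12.2e3 /s/M, k_off = 2.2e3 /s
cond = ConditionConfig(label="pH3_1M", pH=3.0, salt_M=1.0,
                       k_on_per_s_M=12.2e3, k_off_per_s=2.2e3,
                       blockade_fraction=0.39, duration_s=60.0)
points = []
for conc in cond.concentrations_M:          # 100-600 uM
    trace = simulate_condition_trace(cond, conc, seed=1)
    table = pk.detect_events(trace, filter_cutoff_Hz=10e3)
    points.append(pk.rates_from_events(table))
fit = pk.fit_bimolecular(points)
print(f"k_on  = {fit.k_on_per_s_M:.3g} /s/M")
print(f"k_off = {fit.k_off_per_s:.3g} /s")
```

prints

```
k_on  = 1.21e+04 /s/M
k_off = 2.11e+03 /s
```

i.e. the full simulate → detect → fit chain recovers the generator's
bimolecular constants (12.2×10³ s⁻¹M⁻¹ and 2.2×10³ s⁻¹) to within a few
percent from a single 6-concentration series. Deterministic physics is one
call each:

```python
pk.pitzer_activity(3.0)[1]              # 1.705  (KCl activity at 3 mol/L)
pk.debye_length_nm(1.0, 300.0)          # 0.304  nm
pk.barrier_difference(1.40, 0.08, 295)  # 1.68   kcal/mol
pk.net_charge(pk.pamam_g1_charge_model(), 3.0)  # +12.1 |e|
```

## Command line

```bash
porekin make-fixtures --out replica.yaml       # reference-condition config
porekin simulate --config replica.yaml --seed 1 --out demo
porekin detect --trace demo_trace.csv --out events.csv
porekin rates --events events.csv --out rates.json
porekin run --config replica.yaml              # full pipeline + summary.csv
porekin selectivity --iv iv.csv --out sel.json
```

## Acceptance script

`scripts/acceptance.py` re-runs the package end to end and reports the
recovered quantities as JSON: the Pitzer activities at 0.1 and 3 mol/L, the
pipeline-recovered k_on (pH 3, 1 M) and k_off (pH 7, 1 M), the Kramers
effective valence for the 0.5 M condition, and the mean relative blockade on
0.5 M fixtures. Every number is computed at run time from seeded synthetic
data or closed-form evaluation:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/porekin/synthetic.py` — trace generator, Bessel filtering, trace I/O
- `src/porekin/events.py` — histograms, level detection, event idealization
- `src/porekin/kinetics.py` — censored-exponential MLE, bimolecular fits
- `src/porekin/energetics.py` — Arrhenius/Kramers voltage fits, ΔU*
- `src/porekin/transport.py` — charge, screening, MFPT inversion for D
- `src/porekin/selectivity.py` — Pitzer, reversal potential, GHK ratio
- `src/porekin/pipeline.py` — validated run configs, orchestration
- `src/porekin/cli.py` — `porekin` console entry point

See `docs/methods.md` for the models, their assumptions and the numerical
choices.
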