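# patrolfret

Analysis toolkit for single-molecule FRET recordings of **periodic DNA
patrolling** — a helicase monomer anchored at a 3′ ss–dsDNA junction that
repeatedly reels in the 3′ ssDNA tail in 1-nt steps, producing sawtooth FRET
traces, and uses the same activity to unwind a G-quadruplex (G4) in three
discrete steps on every pass.

The package is written for single-molecule biophysicists who have
donor/acceptor intensity traces (or want calibrated synthetic ones) and need
the standard kinetic chain:

* **fret** — apparent FRET `E = I_A/(I_A + I_D)` from background/cross-talk
  corrected channels; per-molecule initial-window histograms; two-population
  (bound/free) decomposition and `f = c/(c+K_D)` binding fits.
* **cycles** — hysteresis detection of repetition cycles; Γ-distribution
  hidden-step fits `p(Δt) ∝ (Δt)^(n−1) e^(−kΔt)` (shape n counts the hidden
  1-nt steps, bounding the kinetic step size by N/n); period-vs-length
  regression `τ = N/v + b`; Michaelis–Menten ATP coupling
  `1/τ = r_max·S/(K_M+S)` and saturation extrapolation.
* **steps** — chi-square step finding on stepwise G4-unwinding ladders
  (greedy placement, BIC step count, DP oracle), five-dwell cycle
  classification (folded, two intermediates, unfolded, refolding), and
  BIC-selected Gaussian-mixture analysis of pooled plateau levels.
* **unwinding** — ensemble spot-count survival fits (single/bi-exponential
  with model selection) and the cycles-per-unwinding ratio.
* **simulate** — a ground-truth-carrying stochastic simulator of all of the
  above (Poisson 1-nt stepping, Γ-distributed unwinding stages, exponential
  refolding, binomial spot survival, binding titrations), used throughout the
  tests for parameter recovery.

## Worked example

```python
import numpy as np
import patrolfret as pf

cons  = pf.ConstructSpec(track_length_nt=40, fret_anchor_low=0.30, fret_anchor_high=0.80)
kin   = pf.KineticParams()        # k_step_max 85/s, K_M 110 uM, K_D 7 nM ...
noise = pf.NoiseModel()           # 30-ms frames, Gaussian SNR 5

# simulate one minute of patrolling at 20 uM ATP and recover the period
trace, truth = pf.simulate_patrol_trace(cons, kin, 20.0, noise, 60.0, seed=1)
fret  = pf.compute_fret(trace)
rec   = pf.detect_cycles(fret, anchors=(0.30, 0.80))
print(f"{len(rec.dwells)} cycles, mean period {rec.dwells.mean():.2f} s")

# hidden-step counting on a long single-molecule record (32-nt track)
c32 = pf.ConstructSpec(track_length_nt=32, fret_anchor_low=0.30, fret_anchor_high=0.80)
tr, _ = pf.simulate_patrol_trace(c32, kin, 60.0, noise, 220.0, seed=424242)
g   = pf.fit_gamma(pf.detect_cycles(pf.compute_fret(tr), anchors=(0.30, 0.80)).dwells)
upper, step = pf.infer_step_size(32, g)
print(f"Gamma shape n = {g.n:.0f}, step-size bound {upper:.2f} nt -> {step} nt")
```

prints (machine-exact values vary with the seed):

```
18 cycles, mean period 2.98 s
Gamma shape n = 30, step-size bound 1.05 nt -> 1 nt
```

A period of ~3 s for 40 nt at 20 μM ATP is the expected 13 nt/s; a Γ shape
of ~30 hidden steps over a 32-nt track bounds the kinetic step size below
2 nt, so the only consistent integer step is 1 nt.

The numbered drivers under `analysis/` run the full campaign and narrate the
findings (binding K_D ≈ 7 nM, K_M ≈ 100 μM, v ≈ 13 nt/s → ~80 nt/s
saturated, modal three-step G4 unwinding with a four-component plateau-level
mixture, t_unwind ≈ 6.3 min ≈ "about 200" patrol cycles):

```sh
python analysis/01_simulate_dataset.py    # synthetic campaign + truth sidecars
python analysis/02_binding_titration.py
python analysis/03_patrol_kinetics.py
python analysis/04_g4_stepping.py
python analysis/05_unwinding_survival.py
```

A thin CLI wraps the same library (`patrolfret simulate|fret|cycles|steps|
unwind|pipeline|fixtures`); see `patrolfret --help`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main results from scratch at the given seed — the
patrol-kinetics chain (cycle detection → Michaelis–Menten and
period-vs-length fits, single-molecule Γ fit and step-size bound), the G4
chain (step finding → cycle classification → plateau-level mixture → dwell
fits), and the ensemble fits (binding K_D, unwinding survival,
cycles-per-unwinding) — prints the summary, and writes the results file.

## Layout

```
src/patrolfret/    simulate, fret, cycles, steps, unwinding, io, pipeline, cli
analysis/          numbered narrative drivers (write under results/)
tests/             pytest suite incl. acceptance-grade recovery tests
docs/methods.md    model, estimators, simulator defaults, limitations
```
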