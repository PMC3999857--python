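#!/usr/bin/env python
"""Stepwise G4 unwinding: step finding, intermediates, dwell kinetics.

Each patrol cycle unwinds the intramolecular G4 in discrete stages. This
script segments simulated unwinding cycles with the chi-square step finder,
classifies each into the five dwells (folded, two intermediates, unfolded,
refolding) and asks the population-level questions:

* How many downward steps does a cycle take? (modal count 3 -> the G4
  unravels one strand at a time through two intermediates.)
* How many FRET levels do pooled plateaus occupy? (a BIC-selected normal
  mixture: four components = folded + 2 intermediates + unfolded.)
* Are the stage dwells multi-step? (Gamma shape > 1 for each unwinding
  stage; single-exponential refolding.)
* Does the G4 cycle period follow the same ATP coupling as bare patrolling?
  (Michaelis-Menten fit of the G4 cycle rate, expected K_M ~ 110-120 uM.)

Writes results/g4_levels.csv, results/g4_dwell_fits.json; prints the summary.
"""

import json
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

import patrolfret as pf
from patrolfret.io import read_traces

DATA = Path("results/data")
FOLDED, UNFOLDED = 0.75, 0.30


def main() -> None:
    if not DATA.exists():
        raise SystemExit("run analysis/01_simulate_dataset.py first")

    cycles = []
    for tr in read_traces(DATA / "g4_cycles.csv"):
        ft = pf.compute_fret(tr)
        cycs, _ = pf.analyze_g4_trace(ft, folded_level=FOLDED, unfolded_level=UNFOLDED)
        cycles += cycs
    counts = Counter(c.n_down_steps for c in cycles)
    modal = counts.most_common(1)[0][0]
    canonical = [c for c in cycles if c.canonical]
    levels = []
    for c in canonical:
        levels += [c.level_folded, c.level_I1, c.level_I2, c.level_unfolded]
    dist = pf.fit_level_distribution(levels)
    dwell_fits = pf.fit_dwell_distributions(canonical)

    # ATP dependence of the G4 unwinding period (simulated on the fly)
    cons = pf.ConstructSpec(
        track_length_nt=40, payload="G4_TP", fret_anchor_low=UNFOLDED, fret_anchor_high=FOLDED
    )
    kin, noise = pf.KineticParams(), pf.NoiseModel()
    atps = [5.0, 20.0, 50.0, 110.0, 500.0]
    taus = []
    for i, atp in enumerate(atps):
        dwells = []
        for s in pf.spawn_seeds(777 + i, 4):
            tr, _ = pf.simulate_g4_trace(cons, kin, atp, noise, 12, seed=s)
            rec = pf.detect_cycles(
                pf.compute_fret(tr), polarity="falling_sawtooth",
                anchors=(UNFOLDED, FOLDED),
            )
            dwells += rec.dwells.tolist()
        taus.append(float(np.mean(dwells)))
    mm = pf.fit_michaelis_menten(atps, [1.0 / t for t in taus])

    pd.DataFrame({"plateau_level": levels}).to_csv("results/g4_levels.csv", index=False)
    out = {
        "n_cycles": len(cycles),
        "down_step_counts": dict(sorted(counts.items())),
        "modal_down_steps": modal,
        "level_mixture": {
            "n_components": dist.n_components,
            "means": dist.means.tolist(),
            "weights": dist.weights.tolist(),
        },
        "gamma_shapes": {
            k: {"n": dwell_fits[k].n, "n_se": dwell_fits[k].n_se,
                "mean_s": dwell_fits[k].mean_dwell}
            for k in ("dt1", "dt2", "dt3", "dt4")
        },
        "refolding": dwell_fits["dt5"],
        "michaelis_menten_g4": {"K_M_uM": mm.K_M, "K_M_se_uM": mm.K_M_se,
                                "rate_max_per_s": mm.rate_max},
    }
    Path("results/g4_dwell_fits.json").write_text(json.dumps(out, indent=1))

    print(f"{len(cycles)} unwinding cycles; downward-step counts {dict(sorted(counts.items()))}")
    print(f"modal downward steps per cycle = {modal} (three-step unwinding)")
    print(f"plateau-level mixture: {dist.n_components} components at "
          + ", ".join(f"{m:.2f}" for m in dist.means))
    for k in ("dt1", "dt2", "dt3", "dt4"):
        f = dwell_fits[k]
        print(f"  {k}: Gamma shape n = {f.n:.1f} ± {f.n_se:.1f}, mean {f.mean_dwell:.2f} s")
    print(f"  dt5 (refolding): exponential mean {dwell_fits['dt5']['mean_s']:.2f} s")
    print(f"G4 cycle ATP coupling: K_M = {mm.K_M:.0f} ± {mm.K_M_se:.0f} uM "
          f"(bare patrolling calibration 110 uM)")


if __name__ == "__main__":
    main()
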