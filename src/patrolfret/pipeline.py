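"""End-to-end pipeline: simulate → FRET → cycles → steps/unwind.

Each stage reads the artifacts of its predecessors from the configured output
directory and writes new artifacts keyed by the config hash; no stage mutates
its inputs. A RunReport (JSON) records the tool version, config hash, seeds
and per-stage summaries.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cycles import detect_cycles, fit_gamma, fit_michaelis_menten
from .fret import CorrectionParams, build_histogram, compute_fret
from .io import ExperimentConfig, config_hash, read_traces, write_traces, write_truth
from .simulate import (
    ConstructSpec,
    simulate_g4_trace,
    simulate_patrol_trace,
    simulate_titration,
    simulate_unwinding_assay,
    spawn_seeds,
)
from .steps import analyze_g4_trace, fit_level_distribution
from .unwinding import fit_unwinding_curve

__all__ = ["RunReport", "run_pipeline", "make_fixtures", "STAGES"]

STAGES = ("simulate", "fret", "cycles", "steps", "unwind")
_DEPS = {"fret": "simulate", "cycles": "fret", "steps": "cycles"}


@dataclass
class RunReport:
    version: str
    config_hash: str
    seed: int
    stages: list = field(default_factory=list)
    summaries: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, default=str))


def _trace_path(outdir: Path, chash: str, atp: float) -> Path:
    return outdir / f"traces_{chash}_atp{atp:g}.csv"


def run_pipeline(config: ExperimentConfig, stages=STAGES) -> RunReport:
    """Execute the requested stages in order with dependency checking.

    Stage dependencies: fret needs simulated traces, cycles needs FRET
    output, steps needs cycle boundaries. A requested stage whose dependency
    was neither requested nor previously materialised raises ValueError
    naming the stage.
    """
    stages = [s for s in STAGES if s in stages]
    if not stages:
        raise ValueError(f"no valid stages requested; choose from {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    report = RunReport(version=__version__, config_hash=chash, seed=config.seed)
    is_g4 = config.construct.payload in ("G4_TP", "G4_TEL")

    for stage in stages:
        dep = _DEPS.get(stage)
        if dep and dep not in stages:
            dep_artifact = (
                _trace_path(outdir, chash, config.atp_series[0])
                if dep == "simulate"
                else outdir / f"{dep}_{chash}.csv"
            )
            if not dep_artifact.exists():
                raise ValueError(
                    f"stage '{stage}' requires stage '{dep}' (artifact "
                    f"{dep_artifact.name} not found)"
                )

    try:
        if "simulate" in stages:
            seeds = spawn_seeds(config.seed, config.n_molecules * len(config.atp_series))
            si = 0
            for atp in config.atp_series:
                traces, truths = [], {}
                for i in range(config.n_molecules):
                    mid = f"atp{atp:g}_m{i:03d}"
                    if is_g4:
                        n_cyc = max(3, int(config.duration_s / 3.0))
                        tr, truth = simulate_g4_trace(
                            config.construct, config.kinetics, atp, config.noise,
                            n_cycles=n_cyc, seed=seeds[si], molecule_id=mid,
                        )
                    else:
                        tr, truth = simulate_patrol_trace(
                            config.construct, config.kinetics, atp, config.noise,
                            duration_s=config.duration_s, seed=seeds[si], molecule_id=mid,
                        )
                    traces.append(tr)
                    truths[mid] = truth
                    si += 1
                write_traces(traces, _trace_path(outdir, chash, atp))
                write_truth(truths, outdir / f"truth_{chash}_atp{atp:g}.json")
            report.summaries["simulate"] = {
                "n_molecules": config.n_molecules,
                "atp_series_uM": list(config.atp_series),
                "construct": dataclasses.asdict(config.construct),
            }
            report.stages.append("simulate")

        corr = CorrectionParams(
            background_donor=config.noise.background_donor,
            background_acceptor=config.noise.background_acceptor,
            leakage=config.noise.leakage,
        )
        fret_by_atp = {}
        if "fret" in stages or "cycles" in stages or "steps" in stages:
            for atp in config.atp_series:
                traces = read_traces(_trace_path(outdir, chash, atp))
                fret_by_atp[atp] = [compute_fret(tr, corr) for tr in traces]

        if "fret" in stages:
            all_fret = [f for fs in fret_by_atp.values() for f in fs]
            hist = build_histogram(all_fret)
            pd.DataFrame(
                {"bin_left": hist.bin_edges[:-1], "bin_right": hist.bin_edges[1:],
                 "density": hist.densities}
            ).to_csv(outdir / f"fret_{chash}.csv", index=False)
            report.summaries["fret"] = {
                "n_molecules": hist.n_molecules, "window_s": hist.window_s,
            }
            report.stages.append("fret")

        cycle_rows = []
        if "cycles" in stages:
            anchors = (config.construct.fret_anchor_low, config.construct.fret_anchor_high)
            polarity = "falling_sawtooth" if is_g4 else "rising_sawtooth"
            mm_points = []
            for atp, fts in fret_by_atp.items():
                dwells = []
                for ft in fts:
                    rec = detect_cycles(ft, polarity=polarity, anchors=anchors)
                    # truncated first/last dwells are already excluded: dwells
                    # are differences of interior boundaries
                    dwells.extend(rec.dwells.tolist())
                    for b, d in zip(rec.boundary_times[1:], rec.dwells):
                        cycle_rows.append(
                            {"atp_uM": atp, "molecule_id": ft.molecule_id,
                             "boundary_time_s": b, "dwell_s": d}
                        )
                if dwells:
                    mm_points.append((atp, 1.0 / float(np.mean(dwells)), len(dwells)))
            pd.DataFrame(cycle_rows).to_csv(outdir / f"cycles_{chash}.csv", index=False)
            summary = {"n_dwells": len(cycle_rows)}
            all_dwells = [row["dwell_s"] for row in cycle_rows]
            if len(all_dwells) >= 30:
                g = fit_gamma(all_dwells)
                summary["gamma_pooled"] = {
                    "n": g.n, "k_per_s": g.k, "n_se": g.n_se, "k_se": g.k_se,
                }
            if len(mm_points) >= 4:
                mm = fit_michaelis_menten(
                    [p[0] for p in mm_points], [p[1] for p in mm_points]
                )
                summary["michaelis_menten"] = {
                    "rate_max_per_s": mm.rate_max, "K_M_uM": mm.K_M,
                    "rate_max_se": mm.rate_max_se, "K_M_se": mm.K_M_se,
                }
            report.summaries["cycles"] = summary
            report.stages.append("cycles")

        if "steps" in stages:
            if not is_g4:
                raise ValueError("stage 'steps' requires a G4 payload construct")
            levels, n_down = [], []
            for fts in fret_by_atp.values():
                for ft in fts:
                    cycs, _fits = analyze_g4_trace(
                        ft,
                        folded_level=config.construct.fret_anchor_high,
                        unfolded_level=config.construct.fret_anchor_low,
                    )
                    for c in cycs:
                        n_down.append(c.n_down_steps)
                        if c.canonical:
                            levels.extend(
                                [c.level_folded, c.level_I1, c.level_I2, c.level_unfolded]
                            )
            summary = {"n_cycles": len(n_down)}
            if n_down:
                vals, counts = np.unique(n_down, return_counts=True)
                summary["modal_down_steps"] = int(vals[np.argmax(counts)])
            if len(levels) >= 100:
                dist = fit_level_distribution(levels)
                summary["level_components"] = int(dist.n_components)
                summary["level_means"] = [float(m) for m in dist.means]
            pd.DataFrame({"plateau_level": levels}).to_csv(
                outdir / f"steps_{chash}.csv", index=False
            )
            report.summaries["steps"] = summary
            report.stages.append("steps")

        if "unwind" in stages:
            series = simulate_unwinding_assay(
                n_spots=500,
                t_unwind_min=config.kinetics.t_unwind,
                obs_times=np.linspace(0.0, 4.0 * config.kinetics.t_unwind, 10),
                seed=config.seed + 1,
            )
            fit = fit_unwinding_curve(series, model="auto")
            pd.DataFrame({"time_min": series.times / 60.0, "count": series.counts}).to_csv(
                outdir / f"unwind_{chash}.csv", index=False
            )
            report.summaries["unwind"] = {
                "model": fit.model, "t_unwind_min": fit.t_unwind,
                "t_unwind_se_min": fit.t_unwind_se,
            }
            report.stages.append("unwind")
    except Exception as err:
        report.warnings.append(f"aborted in stage pipeline: {err}")
        report.write(Path(config.outdir) / f"report_{chash}.json")
        raise
    report.write(outdir / f"report_{chash}.json")
    return report


def make_fixtures(seed: int, outdir="results/fixtures") -> dict:
    """Generate the frozen small datasets the analysis scripts consume.

    Covers patrol traces for track lengths 32/40/56/72 nt at 20 uM ATP, an
    ATP series on the 40-nt track, repetitive G4 unwinding traces, a binding
    titration and a spot-count unwinding assay — each with truth sidecars.
    Regeneration with the same seed is byte-identical.
    """
    from .simulate import KineticParams, NoiseModel

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kin = KineticParams()
    noise = NoiseModel()
    manifest = {}

    sawtooth = ConstructSpec(track_length_nt=40, fret_anchor_low=0.30, fret_anchor_high=0.80)
    # patrol traces across track lengths at 20 uM ATP
    for j, N in enumerate((32, 40, 56, 72)):
        cons = dataclasses.replace(sawtooth, track_length_nt=N)
        seeds = spawn_seeds(seed + j, 8)
        traces, truths = [], {}
        for i, s in enumerate(seeds):
            mid = f"N{N}_m{i:02d}"
            tr, truth = simulate_patrol_trace(
                cons, kin, 20.0, noise, duration_s=60.0, seed=s, molecule_id=mid
            )
            traces.append(tr)
            truths[mid] = truth
        write_traces(traces, outdir / f"patrol_N{N}.csv")
        write_truth(truths, outdir / f"patrol_N{N}_truth.json")
        manifest[f"patrol_N{N}"] = str(outdir / f"patrol_N{N}.csv")

    # ATP series on the 40-nt track
    for j, atp in enumerate((5.0, 20.0, 50.0, 110.0, 250.0, 500.0)):
        seeds = spawn_seeds(seed + 100 + j, 6)
        traces, truths = [], {}
        for i, s in enumerate(seeds):
            mid = f"atp{atp:g}_m{i:02d}"
            tr, truth = simulate_patrol_trace(
                sawtooth, kin, atp, noise, duration_s=60.0, seed=s, molecule_id=mid
            )
            traces.append(tr)
            truths[mid] = truth
        write_traces(traces, outdir / f"patrol_atp{atp:g}.csv")
        write_truth(truths, outdir / f"patrol_atp{atp:g}_truth.json")
        manifest[f"patrol_atp{atp:g}"] = str(outdir / f"patrol_atp{atp:g}.csv")

    # repetitive G4 unwinding traces
    g4 = ConstructSpec(
        track_length_nt=40, payload="G4_TP", fret_anchor_low=0.30, fret_anchor_high=0.75
    )
    seeds = spawn_seeds(seed + 200, 10)
    traces, truths = [], {}
    for i, s in enumerate(seeds):
        mid = f"g4_m{i:02d}"
        tr, truth = simulate_g4_trace(g4, kin, 20.0, noise, n_cycles=15, seed=s, molecule_id=mid)
        traces.append(tr)
        truths[mid] = truth
    write_traces(traces, outdir / "g4_cycles.csv")
    write_truth(truths, outdir / "g4_cycles_truth.json")
    manifest["g4_cycles"] = str(outdir / "g4_cycles.csv")

    # binding titration and unwinding assay
    df, truth = simulate_titration(
        kin.K_D, (1.0, 3.0, 7.0, 15.0, 40.0, 100.0), 1000, seed=seed + 300
    )
    df.to_csv(outdir / "titration.csv", index=False)
    Path(outdir / "titration_truth.json").write_text(json.dumps(truth, indent=1))
    manifest["titration"] = str(outdir / "titration.csv")

    series = simulate_unwinding_assay(
        500, kin.t_unwind, np.linspace(0.0, 25.0, 11), seed=seed + 400
    )
    pd.DataFrame({"time_min": series.times / 60.0, "count": series.counts}).to_csv(
        outdir / "unwinding_assay.csv", index=False
    )
    manifest["unwinding_assay"] = str(outdir / "unwinding_assay.csv")
    return manifest
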