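"""Trace tables, truth sidecars and experiment configuration.

On-disk formats are plain delimited text so every artifact is diffable:

* trace table (CSV): ``molecule_id, frame_index, time_s, intensity_donor,
  intensity_acceptor``; one header line; times serialized with 6 decimals.
* truth sidecar (JSON): per-molecule ground truth keyed by molecule_id.
* config (YAML): nested sections mirroring ConstructSpec / KineticParams /
  NoiseModel field names exactly; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fret import IntensityTrace
from .simulate import ConstructSpec, KineticParams, NoiseModel, SimTruth

__all__ = [
    "TRACE_COLUMNS",
    "write_traces",
    "read_traces",
    "iter_traces",
    "write_truth",
    "read_truth",
    "ExperimentConfig",
    "load_config",
    "config_hash",
]

TRACE_COLUMNS = ["molecule_id", "frame_index", "time_s", "intensity_donor", "intensity_acceptor"]


def write_traces(traces, path) -> None:
    """Write intensity traces to the standard delimited trace table."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "molecule_id": tr.molecule_id,
                    "frame_index": np.arange(len(tr)),
                    # full precision: the write->read round trip is lossless
                    "time_s": tr.time_s,
                    "intensity_donor": tr.I_D,
                    "intensity_acceptor": tr.I_A,
                }
            )
        )
    # %.17g keeps the write->read round trip bit-exact for float64
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def _trace_from_group(mol: str, g: pd.DataFrame) -> IntensityTrace:
    fi = g["frame_index"].to_numpy()
    if np.any(np.diff(fi) != 1):
        raise ValueError(f"molecule {mol}: gap in frame_index")
    t = g["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"molecule {mol}: non-monotone time_s")
        if dt.max() - dt.min() > 1e-6:
            raise ValueError(f"molecule {mol}: mixed frame intervals")
        interval = float(np.median(dt))
    else:
        interval = 0.030
    return IntensityTrace(
        molecule_id=str(mol),
        time_s=t,
        I_D=g["intensity_donor"].to_numpy(dtype=float),
        I_A=g["intensity_acceptor"].to_numpy(dtype=float),
        frame_interval=interval,
    )


def iter_traces(path, chunksize: int = 200_000):
    """Stream traces from a trace table without loading the whole file.

    Rows of one molecule must be contiguous (as written by write_traces); the
    working set is bounded by the chunk size plus one molecule.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pending: pd.DataFrame | None = None
    reader = pd.read_csv(path, chunksize=chunksize, float_precision="round_trip")
    for chunk in reader:
        missing = set(TRACE_COLUMNS) - set(chunk.columns)
        if missing:
            raise ValueError(f"trace table missing column(s): {sorted(missing)}")
        if pending is not None:
            chunk = pd.concat([pending, chunk], ignore_index=True)
        last_mol = chunk["molecule_id"].iloc[-1]
        done = chunk[chunk["molecule_id"] != last_mol]
        pending = chunk[chunk["molecule_id"] == last_mol]
        for mol, g in done.groupby("molecule_id", sort=False):
            yield _trace_from_group(mol, g)
    if pending is not None and len(pending):
        for mol, g in pending.groupby("molecule_id", sort=False):
            yield _trace_from_group(mol, g)


def read_traces(path) -> list:
    """Read all traces from a trace table, grouped by molecule_id."""
    return list(iter_traces(path))


def write_truth(truths: dict, path) -> None:
    """Write ground-truth sidecar, keyed by molecule_id, as JSON."""
    out = {}
    for mol, truth in truths.items():
        entry = {
            "seed": int(truth.seed),
            "event_times": np.round(truth.event_times, 6).tolist(),
            "params_used": dataclasses.asdict(truth.params_used),
        }
        if truth.cycle_dwells is not None:
            entry["cycle_dwells"] = {
                c: np.round(truth.cycle_dwells[c].to_numpy(), 6).tolist()
                for c in truth.cycle_dwells.columns
            }
        out[str(mol)] = entry
    Path(path).write_text(json.dumps(out, indent=1))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


@dataclass
class ExperimentConfig:
    """Validated configuration for a full simulate→analyze pipeline run."""

    construct: ConstructSpec = field(default_factory=ConstructSpec)
    kinetics: KineticParams = field(default_factory=KineticParams)
    noise: NoiseModel = field(default_factory=NoiseModel)
    atp_series: tuple = (5.0, 20.0, 50.0, 110.0, 250.0, 500.0)
    protein_nM: float = 10.0
    n_molecules: int = 20
    duration_s: float = 60.0
    seed: int = 0
    outdir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.atp_series):
            raise ValueError("atp_series concentrations must be positive")
        if self.n_molecules < 1 or self.duration_s <= 0:
            raise ValueError("n_molecules ≥ 1 and duration_s > 0 required")


def _build_section(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in section '{section}': {sorted(unknown)}")
    if "g4_stage_substeps" in data:
        data = {**data, "g4_stage_substeps": tuple(data["g4_stage_substeps"])}
    return cls(**data)


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment configuration; unknown keys fail."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    top = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(raw) - top
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = dict(raw)
    if "construct" in kwargs:
        kwargs["construct"] = _build_section(ConstructSpec, kwargs["construct"], "construct")
    if "kinetics" in kwargs:
        kwargs["kinetics"] = _build_section(KineticParams, kwargs["kinetics"], "kinetics")
    if "noise" in kwargs:
        kwargs["noise"] = _build_section(NoiseModel, kwargs["noise"], "noise")
    if "atp_series" in kwargs:
        kwargs["atp_series"] = tuple(float(x) for x in kwargs["atp_series"])
    return ExperimentConfig(**kwargs)


def config_hash(config: ExperimentConfig) -> str:
    """Stable short hash of the scientific configuration (keys analysis
    outputs). The output location is excluded so the same experiment hashes
    identically wherever it is written."""
    payload = dataclasses.asdict(config)
    payload.pop("outdir", None)
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
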