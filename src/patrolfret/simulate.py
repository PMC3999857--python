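"""Stochastic simulator for periodic-patrolling smFRET experiments.

Emulates the raw observables of a junction-anchored reeling translocase
(Pif1-like) studied by single-molecule FRET:

* sawtooth patrol traces — the enzyme stays anchored at the 3' ss-dsDNA
  junction and reels in the 3' ssDNA tail in hidden 1-nt Poisson steps whose
  rate follows Michaelis–Menten ATP dependence, then abruptly releases the
  extruded loop and starts over;
* stepwise G-quadruplex unwinding ladders — on each patrol the enzyme unwinds
  an intramolecular G4 in three discrete stages (folded → two intermediates →
  unfolded), each stage a sum of several 1-nt waits, followed by fast
  exponential refolding once the loop is released;
* ensemble spot-count unwinding assays (binomial survival with exponential
  decay) and two-population binding titrations.

Every simulated record carries a ``SimTruth`` sidecar with the hidden state
path, event times and parameters, so analysis routines can be scored against
ground truth. Identical seed + parameters give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fret import IntensityTrace

__all__ = [
    "ConstructSpec",
    "KineticParams",
    "NoiseModel",
    "SimTruth",
    "SpotCountSeries",
    "simulate_patrol_trace",
    "simulate_g4_trace",
    "simulate_unwinding_assay",
    "simulate_titration",
    "michaelis_menten_rate",
]

LABELING_SCHEMES = ("junction_end", "mid_end", "junction_mid")
PAYLOADS = ("none", "dsDNA_duplex", "RNA_DNA_hybrid", "G4_TP", "G4_TEL")
G4_PAYLOADS = ("G4_TP", "G4_TEL")
# G4 motif lengths (nt): TP is the 31-nt mouse immunoglobulin-locus sequence,
# TEL the 21-nt human telomeric repeat.
G4_LENGTH_NT = {"G4_TP": 31, "G4_TEL": 21}


@dataclass(frozen=True)
class ConstructSpec:
    """DNA construct geometry: ssDNA track, dye placement and FRET anchors.

    ``fret_anchor_low``/``fret_anchor_high`` are the two extreme apparent-FRET
    levels the construct can visit (stretched/far vs compact/folded). For a
    mid-labeled patrol substrate these are the printed 0.37/0.58 populations;
    for end-labeled full-amplitude sawtooth substrates a wider (0.30, 0.80)
    default is used; for G4 substrates (0.30, 0.75) folded/unfolded.
    """

    track_length_nt: int = 40
    labeling_scheme: str = "junction_end"
    payload: str = "none"
    fret_anchor_low: float = 0.30
    fret_anchor_high: float = 0.80
    polarity: str = "three_prime"
    g4_length_nt: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.fret_anchor_low < self.fret_anchor_high < 1.0):
            raise ValueError("require 0 < fret_anchor_low < fret_anchor_high < 1")
        if self.track_length_nt < 0:
            raise ValueError("track_length_nt must be non-negative")
        if self.labeling_scheme not in LABELING_SCHEMES:
            raise ValueError(f"labeling_scheme must be one of {LABELING_SCHEMES}")
        if self.payload not in PAYLOADS:
            raise ValueError(f"payload must be one of {PAYLOADS}")
        if self.polarity not in ("three_prime", "five_prime"):
            raise ValueError("polarity must be three_prime or five_prime")

    @property
    def g4_nt(self) -> int:
        if self.g4_length_nt is not None:
            return self.g4_length_nt
        return G4_LENGTH_NT.get(self.payload, 0)


# Defaults are the study's stated world: saturated speed 85 nt/s (13 nt/s at
# 20 uM ATP with K_M = 110 uM), refolding ~0.2 s, K_D = 7 nM, t_unwind 6.3 min.
@dataclass(frozen=True)
class KineticParams:
    k_step_max: float = 85.0          # per-nt stepping rate at saturating ATP, 1/s
    K_M: float = 110.0                # Michaelis constant for ATP, uM
    release_time: float = 0.0         # mean loop-release/reset dwell, s
    g4_stage_substeps: tuple = (4, 8, 9)  # hidden 1-nt steps per unfolding stage
    refold_rate: float = 5.0          # G4 refolding rate after release, 1/s
    t_unwind: float = 6.3             # ensemble unwinding time constant, min
    K_D: float = 7.0                  # binding constant, nM

    def __post_init__(self) -> None:
        for name in ("k_step_max", "K_M", "refold_rate", "t_unwind", "K_D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.release_time < 0:
            raise ValueError("release_time must be non-negative")
        if any(s < 1 for s in self.g4_stage_substeps) or len(self.g4_stage_substeps) != 3:
            raise ValueError("g4_stage_substeps must be three integers ≥ 1")


@dataclass(frozen=True)
class NoiseModel:
    """Detection-noise model for the two channels.

    Gaussian noise applies a per-channel sigma of channel_intensity / snr
    (with a floor of 5% of the photon budget so dark channels still carry
    detector noise); at the default snr = 5 this gives a FRET noise of
    ~0.05-0.07 per 30-ms frame, typical of Cy3/Cy5 TIRF recordings.
    ``poisson`` draws photon-exact counts; ``none`` returns the ideal
    intensities.
    """

    frame_interval: float = 0.030
    total_photons_mean: float = 600.0
    background_donor: float = 0.0
    background_acceptor: float = 0.0
    leakage: float = 0.0
    bleach_rate_donor: float = 0.0
    bleach_rate_acceptor: float = 0.0
    noise_kind: str = "gaussian"
    snr: float = 5.0
    pife_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not (0.0 <= self.leakage <= 0.3):
            raise ValueError("leakage must lie in [0, 0.3]")
        if self.pife_gain < 1.0:
            raise ValueError("pife_gain must be ≥ 1")
        if self.noise_kind not in ("gaussian", "poisson", "none"):
            raise ValueError("noise_kind must be gaussian, poisson or none")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass
class SimTruth:
    """Ground truth attached to every simulated record."""

    event_times: np.ndarray                 # cycle-boundary (reset/recovery) times, s
    state_times: np.ndarray                 # change-point times of the hidden state
    state_path: np.ndarray                  # hidden state value after each change point
    params_used: KineticParams = field(default_factory=KineticParams)
    seed: int = 0
    cycle_dwells: pd.DataFrame | None = None  # per-cycle dt1..dt5 for G4 records
    e_ideal: np.ndarray | None = None         # pre-noise FRET per frame


@dataclass
class SpotCountSeries:
    times: np.ndarray       # s
    counts: np.ndarray      # surviving fluorescent spots
    n_initial: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts > self.n_initial):
            raise ValueError("counts cannot exceed n_initial")


def michaelis_menten_rate(k_max: float, atp_uM: float, K_M_uM: float) -> float:
    """Per-nt stepping rate r = k_max * S / (K_M + S)."""
    return k_max * atp_uM / (K_M_uM + atp_uM)


def _fret_of_position(construct: ConstructSpec, pos: np.ndarray) -> np.ndarray:
    """Linear FRET-vs-position map between the construct anchors.

    The enzyme reeling in the tail brings the dyes together, so for
    junction_end and junction_mid schemes E rises with position; the mid_end
    scheme reports the opposite orientation.
    """
    n = max(construct.track_length_nt, 1)
    frac = np.asarray(pos, dtype=float) / n
    lo, hi = construct.fret_anchor_low, construct.fret_anchor_high
    if construct.labeling_scheme == "mid_end":
        return hi - (hi - lo) * frac
    return lo + (hi - lo) * frac


def _render_intensities(
    construct: ConstructSpec,
    e_ideal: np.ndarray,
    at_end: np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator,
    molecule_id: str,
    times: np.ndarray,
) -> IntensityTrace:
    """Partition a fixed photon budget by FRET, then corrupt per NoiseModel."""
    total = noise.total_photons_mean
    I_A = e_ideal * total
    I_D = (1.0 - e_ideal) * total
    if noise.pife_gain > 1.0:
        # donor brightens when the translocase sits next to it (track end)
        I_D = np.where(at_end, I_D * noise.pife_gain, I_D)

    # photobleaching: after an exponential bleach time the dye goes dark
    duration = times[-1] + noise.frame_interval if len(times) else 0.0
    if noise.bleach_rate_donor > 0:
        t_bleach = rng.exponential(1.0 / noise.bleach_rate_donor)
        dark = times >= t_bleach
        I_D = np.where(dark, 0.0, I_D)
        I_A = np.where(dark, 0.0, I_A)   # no donor, no FRET
    if noise.bleach_rate_acceptor > 0:
        t_bleach = rng.exponential(1.0 / noise.bleach_rate_acceptor)
        dark = times >= t_bleach
        I_D = np.where(dark, I_D + I_A, I_D)  # energy stays on the donor
        I_A = np.where(dark, 0.0, I_A)

    obs_D = I_D + noise.background_donor
    obs_A = I_A + noise.leakage * I_D + noise.background_acceptor
    if noise.noise_kind == "gaussian":
        floor = 0.05 * total
        obs_D = obs_D + rng.normal(0.0, 1.0, size=obs_D.shape) * np.maximum(obs_D, floor) / noise.snr
        obs_A = obs_A + rng.normal(0.0, 1.0, size=obs_A.shape) * np.maximum(obs_A, floor) / noise.snr
        obs_D = np.clip(obs_D, 0.0, None)
        obs_A = np.clip(obs_A, 0.0, None)
    elif noise.noise_kind == "poisson":
        obs_D = rng.poisson(obs_D).astype(float)
        obs_A = rng.poisson(obs_A).astype(float)
    return IntensityTrace(
        molecule_id=molecule_id,
        time_s=times,
        I_D=obs_D,
        I_A=obs_A,
        frame_interval=noise.frame_interval,
    )


def _frame_states(times: np.ndarray, change_times: np.ndarray, states: np.ndarray) -> np.ndarray:
    """Hidden state at each frame time (piecewise-constant interpolation)."""
    idx = np.searchsorted(change_times, times, side="right") - 1
    idx = np.clip(idx, 0, len(states) - 1)
    return states[idx]


def simulate_patrol_trace(
    construct: ConstructSpec,
    kin: KineticParams,
    atp_uM: float,
    noise: NoiseModel,
    duration_s: float,
    seed: int,
    molecule_id: str = "mol0",
):
    """Simulate one sawtooth patrol trace.

    The hidden position advances 0→N by exponential 1-nt waits at the
    Michaelis–Menten rate, resets after an (optionally zero) exponential
    release dwell, and repeats for ``duration_s``. Returns the noisy
    ``IntensityTrace`` and its ``SimTruth`` (reset times = cycle boundaries).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be strictly positive")
    if atp_uM <= 0:
        raise ValueError("atp_uM must be strictly positive")
    if construct.track_length_nt < 1:
        raise ValueError("track_length_nt must be ≥ 1 for patrol simulation")

    rng = np.random.default_rng(seed)
    r = michaelis_menten_rate(kin.k_step_max, atp_uM, kin.K_M)
    N = construct.track_length_nt

    t = 0.0
    pos = 0
    change_times = [0.0]
    states = [0]
    events = []
    while t < duration_s:
        if pos < N:
            t += rng.exponential(1.0 / r)
            pos += 1
        else:
            if kin.release_time > 0:
                t += rng.exponential(kin.release_time)
            pos = 0
            events.append(t)
        change_times.append(t)
        states.append(pos)

    change_times = np.array(change_times)
    states = np.array(states)
    n_frames = int(np.floor(duration_s / noise.frame_interval))
    times = np.arange(n_frames) * noise.frame_interval
    frame_pos = _frame_states(times, change_times, states)
    e_ideal = _fret_of_position(construct, frame_pos)
    trace = _render_intensities(
        construct, e_ideal, frame_pos >= N, noise, rng, molecule_id, times
    )
    truth = SimTruth(
        event_times=np.array([e for e in events if e <= duration_s]),
        state_times=change_times,
        state_path=states,
        params_used=kin,
        seed=seed,
        e_ideal=e_ideal,
    )
    return trace, truth


def simulate_g4_trace(
    construct: ConstructSpec,
    kin: KineticParams,
    atp_uM: float,
    noise: NoiseModel,
    n_cycles: int,
    seed: int,
    molecule_id: str = "mol0",
    intermediate_levels: tuple = (0.60, 0.45),
    released_level: float = 0.38,
):
    """Simulate repetitive stepwise G4 unwinding.

    Each cycle: patrol over the ssDNA track at the folded FRET level (the dyes
    flank the G4, so patrolling upstream does not move them), then a
    descending four-level ladder folded → I1 → I2 → unfolded whose three stage
    dwells are Gamma-distributed sums of ``g4_stage_substeps`` exponential
    1-nt waits at the patrol rate, then reeling of the residual unfolded
    nucleotides (dt4), loop release to a slightly relaxed ``released_level``
    and exponential refolding (dt5) back to the folded level.

    ``SimTruth.cycle_dwells`` holds per-cycle dt1..dt5; ``event_times`` are
    the folded-recovery times (cycle boundaries).
    """
    if construct.payload not in G4_PAYLOADS:
        raise ValueError(f"payload must be one of {G4_PAYLOADS}, got {construct.payload!r}")
    if n_cycles < 1:
        raise ValueError("n_cycles must be ≥ 1")
    if atp_uM <= 0:
        raise ValueError("atp_uM must be strictly positive")

    rng = np.random.default_rng(seed)
    r = michaelis_menten_rate(kin.k_step_max, atp_uM, kin.K_M)
    folded = construct.fret_anchor_high
    unfolded = construct.fret_anchor_low
    i1, i2 = intermediate_levels
    if not (unfolded < released_level < i2 < i1 < folded):
        raise ValueError("require unfolded < released_level < I2 < I1 < folded levels")
    subs = kin.g4_stage_substeps
    residual_nt = max(construct.g4_nt - sum(subs), 1)

    levels = []        # (E level, stage index) change points
    seg_times = [0.0]
    dwell_rows = []
    t = 0.0
    # stage codes: 0 folded(+patrol), 1 I1, 2 I2, 3 unfolded, 4 released/refolding
    for _ in range(n_cycles):
        patrol = (
            rng.gamma(construct.track_length_nt, 1.0 / r)
            if construct.track_length_nt > 0
            else 0.0
        )
        dt1 = patrol + rng.gamma(subs[0], 1.0 / r)
        dt2 = rng.gamma(subs[1], 1.0 / r)
        dt3 = rng.gamma(subs[2], 1.0 / r)
        dt4 = rng.gamma(residual_nt, 1.0 / r)
        dt5 = rng.exponential(1.0 / kin.refold_rate)
        for lvl, stage, dt in (
            (folded, 0, dt1), (i1, 1, dt2), (i2, 2, dt3),
            (unfolded, 3, dt4), (released_level, 4, dt5),
        ):
            levels.append((lvl, stage))
            t += dt
            seg_times.append(t)
        dwell_rows.append({"dt1": dt1, "dt2": dt2, "dt3": dt3, "dt4": dt4, "dt5": dt5})

    seg_times = np.array(seg_times)
    level_arr = np.array([lv for lv, _ in levels])
    stage_arr = np.array([st for _, st in levels])
    duration = seg_times[-1]
    n_frames = int(np.floor(duration / noise.frame_interval))
    times = np.arange(n_frames) * noise.frame_interval
    seg_idx = np.clip(np.searchsorted(seg_times, times, side="right") - 1, 0, len(levels) - 1)
    e_ideal = level_arr[seg_idx]
    trace = _render_intensities(
        construct, e_ideal, np.zeros(len(times), dtype=bool), noise, rng, molecule_id, times
    )
    cycle_starts = seg_times[:-1][::5]  # folded-recovery boundary of each cycle
    truth = SimTruth(
        event_times=cycle_starts,
        state_times=seg_times[:-1],
        state_path=stage_arr,
        params_used=kin,
        seed=seed,
        cycle_dwells=pd.DataFrame(dwell_rows),
        e_ideal=e_ideal,
    )
    return trace, truth


def simulate_unwinding_assay(
    n_spots: int,
    t_unwind_min,
    obs_times,
    mode: str = "single",
    seed: int = 0,
    weight: float = 0.5,
) -> SpotCountSeries:
    """Simulate a surface spot-count unwinding assay.

    Each tethered molecule carries an exponential unwinding time (single) or a
    two-phase mixture (double: ``t_unwind_min`` is a (tau1, tau2) pair mixed
    with ``weight``); the count at time t is the number of molecules whose
    strand has not yet been released, so counts are monotone non-increasing
    and binomially distributed with survival exp(-t/tau).

    ``obs_times`` and ``t_unwind_min`` are in minutes.
    """
    obs_times = np.asarray(obs_times, dtype=float)
    if obs_times.size == 0:
        raise ValueError("obs_times must be non-empty")
    if np.any(obs_times < 0) or np.any(np.diff(obs_times) <= 0):
        raise ValueError("obs_times must be non-negative and increasing")
    if n_spots < 1:
        raise ValueError("n_spots must be ≥ 1")
    rng = np.random.default_rng(seed)
    if mode == "single":
        tau = float(t_unwind_min)
        if tau <= 0:
            raise ValueError("t_unwind_min must be positive")
        lifetimes = rng.exponential(tau, size=n_spots)
    elif mode == "double":
        tau1, tau2 = (float(x) for x in t_unwind_min)
        if tau1 <= 0 or tau2 <= 0 or not (0 < weight < 1):
            raise ValueError("double mode needs positive taus and weight in (0,1)")
        fast = rng.random(n_spots) < weight
        lifetimes = np.where(
            fast, rng.exponential(tau1, n_spots), rng.exponential(tau2, n_spots)
        )
    else:
        raise ValueError("mode must be 'single' or 'double'")
    counts = (lifetimes[None, :] > obs_times[:, None]).sum(axis=1)
    counts[obs_times == 0.0] = n_spots
    return SpotCountSeries(times=obs_times * 60.0, counts=counts, n_initial=n_spots)


def simulate_titration(
    K_D_nM: float,
    concentrations,
    n_molecules: int,
    anchors: tuple = (0.37, 0.58),
    seed: int = 0,
    sigma_E: float = 0.05,
):
    """Simulate per-molecule FRET samples across a protein titration.

    Each molecule is bound with probability c/(c+K_D); bound molecules sample
    the low-FRET (stretched) anchor and unbound the high anchor, with Gaussian
    spread ``sigma_E``. Returns (DataFrame[concentration_nM, molecule, bound,
    E], truth dict).
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be ≥ 1")
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations <= 0):
        raise ValueError("concentrations must be positive")
    lo, hi = anchors
    rng = np.random.default_rng(seed)
    rows = []
    truth_fractions = {}
    for c in concentrations:
        p = c / (c + K_D_nM)
        bound = rng.random(n_molecules) < p
        e = np.where(bound, lo, hi) + rng.normal(0.0, sigma_E, n_molecules)
        truth_fractions[float(c)] = float(bound.mean())
        for i in range(n_molecules):
            rows.append(
                {"concentration_nM": c, "molecule": i, "bound": bool(bound[i]), "E": e[i]}
            )
    df = pd.DataFrame(rows)
    truth = {
        "K_D_nM": K_D_nM,
        "anchors": anchors,
        "bound_fractions": truth_fractions,
        "seed": seed,
    }
    return df, truth


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n per-molecule seeds from one master seed (counter-based)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]
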