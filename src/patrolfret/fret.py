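"""Two-channel intensity traces, apparent-FRET conversion, histograms and binding fits.

The apparent FRET efficiency of a single donor/acceptor pair is computed as
``E = I_A / (I_A + I_D)`` from background- and cross-talk-corrected channel
intensities. No gamma (detection-efficiency) correction is applied, so E is
apparent rather than absolute — sufficient for the relative-state analysis the
patrolling pipeline performs (anchored low/high states, sawtooth cycles,
plateau ladders).

Ensemble histograms follow the standard convention for surface-immobilised
molecules: one value per molecule, the mean E over a short initial window
(default 0.15 s, i.e. five 30-ms frames), pooled over the field of view.
Binding titrations are then read off the histogram as the weight of the
low-E (protein-bound, ssDNA-stretched) population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "IntensityTrace",
    "CorrectionParams",
    "FretTrace",
    "FretHistogram",
    "TwoPopulationFit",
    "BindingFit",
    "compute_fret",
    "build_histogram",
    "fit_two_populations",
    "fit_binding_curve",
]

HIST_EDGES = np.round(np.arange(-0.1, 1.1 + 1e-9, 0.025), 10)


@dataclass
class IntensityTrace:
    """Per-molecule donor/acceptor intensity series at a fixed frame interval."""

    molecule_id: str
    time_s: np.ndarray
    I_D: np.ndarray
    I_A: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.I_D = np.asarray(self.I_D, dtype=float)
        self.I_A = np.asarray(self.I_A, dtype=float)
        if not (len(self.time_s) == len(self.I_D) == len(self.I_A)):
            raise ValueError("time_s, I_D and I_A must have equal lengths")
        if len(self.time_s) > 1:
            dt = np.diff(self.time_s)
            if np.any(np.abs(dt - self.frame_interval) > 1e-9):
                raise ValueError(
                    f"molecule {self.molecule_id}: time step not constant "
                    f"within 1e-9 of frame_interval={self.frame_interval}"
                )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass(frozen=True)
class CorrectionParams:
    """Background and donor→acceptor cross-talk (leakage) corrections.

    The raw study never states its numeric values, so defaults are zero; real
    data require measured backgrounds and a leakage fraction (typically ~0.1
    for Cy3/Cy5 on common TIRF setups).
    """

    background_donor: float = 0.0
    background_acceptor: float = 0.0
    leakage: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.leakage <= 0.3):
            raise ValueError("leakage must lie in [0, 0.3]")


@dataclass
class FretTrace:
    """Corrected FRET-efficiency series with a validity mask.

    Frames whose corrected total intensity is non-positive (bleached, blinking
    or empty) are flagged in ``valid`` rather than dropped, so frame indexing
    stays aligned with the parent intensity trace for cycle detection.
    """

    molecule_id: str
    time_s: np.ndarray
    E: np.ndarray
    valid: np.ndarray
    frame_interval: float
    clipped_fraction: float = 0.0

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class FretHistogram:
    bin_edges: np.ndarray
    densities: np.ndarray
    n_molecules: int
    window_s: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class TwoPopulationFit:
    means: tuple
    sds: tuple
    weights: tuple
    n_components: int
    fraction_bound: float
    sse: float


@dataclass
class BindingFit:
    K_D: float
    K_D_se: float
    concentrations: np.ndarray = field(default_factory=lambda: np.array([]))
    fractions_bound: np.ndarray = field(default_factory=lambda: np.array([]))


def compute_fret(trace: IntensityTrace, corr: CorrectionParams | None = None) -> FretTrace:
    """Convert a two-channel intensity trace to apparent FRET.

    ``D = I_D - bg_D``; ``A = I_A - bg_A - leakage * D``; ``E = A / (A + D)``.
    Frames with non-positive corrected total are marked invalid (mask), and
    E values are clipped to [-0.1, 1.1] with the clipped fraction reported.

    Raises ``ValueError`` if the trace is empty or if more than half the
    frames have non-positive corrected total (bleached/empty molecule).
    """
    if len(trace) == 0:
        raise ValueError("empty intensity trace")
    corr = corr or CorrectionParams()
    D = trace.I_D - corr.background_donor
    A = trace.I_A - corr.background_acceptor - corr.leakage * D
    total = D + A
    valid = total > 0
    if valid.mean() < 0.5:
        raise ValueError(
            f"molecule {trace.molecule_id}: corrected total non-positive on "
            f"{(~valid).mean():.0%} of frames; trace rejected as bleached/empty"
        )
    E = np.full(len(trace), np.nan)
    E[valid] = A[valid] / total[valid]
    out_of_range = valid & ((E < -0.1) | (E > 1.1))
    clipped_fraction = float(out_of_range.mean())
    E = np.clip(E, -0.1, 1.1)
    return FretTrace(
        molecule_id=trace.molecule_id,
        time_s=trace.time_s.copy(),
        E=E,
        valid=valid,
        frame_interval=trace.frame_interval,
        clipped_fraction=clipped_fraction,
    )


def initial_window_mean(trace: FretTrace, window_s: float = 0.15) -> float:
    """Mean E over the first ``window_s`` seconds of valid frames."""
    n_frames = max(1, int(round(window_s / trace.frame_interval)))
    sel = slice(0, n_frames)
    e = trace.E[sel][trace.valid[sel]]
    if e.size == 0:
        return np.nan
    return float(e.mean())


def build_histogram(traces, window_s: float = 0.15) -> FretHistogram:
    """Ensemble FRET histogram: one initial-window mean E per molecule.

    With 30-ms frames and the default 0.15-s window exactly five frames are
    averaged per molecule. Densities are normalised to integrate to 1.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("build_histogram requires at least one trace")
    values = []
    for tr in traces:
        if tr.time_s[-1] - tr.time_s[0] + tr.frame_interval < window_s - 1e-9:
            raise ValueError(f"molecule {tr.molecule_id}: trace shorter than window")
        v = initial_window_mean(tr, window_s)
        if np.isfinite(v):
            values.append(v)
    densities, edges = np.histogram(values, bins=HIST_EDGES, density=True)
    return FretHistogram(
        bin_edges=edges, densities=densities, n_molecules=len(values), window_s=window_s
    )


def _gauss(x, mu, sigma, w):
    return w * np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


def _sse_bic(sse: float, n: int, n_params: int) -> float:
    # Gaussian-residual BIC on binned densities
    return n * np.log(max(sse, 1e-300) / n) + n_params * np.log(n)


def fit_two_populations(hist: FretHistogram, min_molecules: int = 100) -> TwoPopulationFit:
    """Weighted least-squares two-Gaussian decomposition of a FRET histogram.

    The low-E component weight is reported as the fraction bound (protein
    binding stretches the ssDNA and lowers E). Falls back to a single
    component when BIC prefers it or when the histogram is degenerate.
    """
    if hist.n_molecules < min_molecules:
        raise ValueError(f"need ≥{min_molecules} molecules, got {hist.n_molecules}")
    x, y = hist.centers, hist.densities
    occupied = np.flatnonzero(y > 0)
    if occupied.size <= 1:
        mu = float(x[occupied[0]]) if occupied.size else np.nan
        warnings.warn("degenerate histogram: single component returned")
        return TwoPopulationFit((mu,), (hist.bin_edges[1] - hist.bin_edges[0],), (1.0,), 1, 0.0, 0.0)

    mean0 = float(np.sum(x * y) / np.sum(y))
    sd0 = float(np.sqrt(np.sum(y * (x - mean0) ** 2) / np.sum(y))) or 0.05
    # single-component fit
    try:
        p1, _ = curve_fit(_gauss, x, y, p0=[mean0, sd0, 1.0], maxfev=10000)
        sse1 = float(np.sum((y - _gauss(x, *p1)) ** 2))
    except RuntimeError:
        p1, sse1 = [mean0, sd0, 1.0], np.inf

    # two-component fit, initialised at the two half-range density peaks
    lo_half = x < mean0
    mu_lo = float(x[lo_half][np.argmax(y[lo_half])]) if lo_half.any() else mean0 - sd0
    mu_hi = float(x[~lo_half][np.argmax(y[~lo_half])]) if (~lo_half).any() else mean0 + sd0

    def two(xx, m1, s1, w1, m2, s2, w2):
        return _gauss(xx, m1, s1, w1) + _gauss(xx, m2, s2, w2)

    try:
        p2, _ = curve_fit(
            two, x, y,
            p0=[mu_lo, sd0 / 2, 0.5, mu_hi, sd0 / 2, 0.5],
            bounds=([-0.1, 1e-3, 0, -0.1, 1e-3, 0], [1.1, 0.5, 2, 1.1, 0.5, 2]),
            maxfev=20000,
        )
        sse2 = float(np.sum((y - two(x, *p2)) ** 2))
    except RuntimeError:
        p2, sse2 = None, np.inf

    n = len(x)
    # collapse to one population when the components are not resolved:
    # closer than one bin pair or than the larger component width
    if p2 is not None:
        sep = abs(p2[3] - p2[0])
        if sep < max(0.05, abs(p2[1]), abs(p2[4])):
            p2 = None
    if p2 is None or _sse_bic(sse1, n, 3) < _sse_bic(sse2, n, 6):
        return TwoPopulationFit(
            (float(p1[0]),), (float(abs(p1[1])),), (1.0,), 1, 0.0, sse1
        )
    comps = sorted(
        [(p2[0], abs(p2[1]), p2[2]), (p2[3], abs(p2[4]), p2[5])], key=lambda c: c[0]
    )
    wsum = comps[0][2] + comps[1][2]
    weights = (comps[0][2] / wsum, comps[1][2] / wsum)
    return TwoPopulationFit(
        means=(float(comps[0][0]), float(comps[1][0])),
        sds=(float(comps[0][1]), float(comps[1][1])),
        weights=weights,
        n_components=2,
        fraction_bound=float(weights[0]),
        sse=sse2,
    )


def fit_binding_curve(concentrations, fractions_bound) -> BindingFit:
    """Hyperbolic (single-site) binding fit: f = c / (c + K_D).

    ``concentrations`` in nM; ≥4 points are required unless a point sits
    exactly at half occupancy (then K_D = c directly).
    """
    c = np.asarray(concentrations, dtype=float)
    f = np.asarray(fractions_bound, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fractions_bound must lie in [0, 1]")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if c.size == 1:
        if abs(f[0] - 0.5) < 1e-12:
            return BindingFit(float(c[0]), 0.0, c, f)
        raise ValueError("single-point fit only defined at half occupancy")
    if c.size < 4:
        raise ValueError("need ≥4 concentrations spanning the transition")

    def hyperbola(cc, kd):
        return cc / (cc + kd)

    popt, pcov = curve_fit(hyperbola, c, f, p0=[np.median(c)], bounds=(1e-9, np.inf))
    return BindingFit(float(popt[0]), float(np.sqrt(pcov[0, 0])), c, f)
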