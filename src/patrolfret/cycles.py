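"""Patrolling-cycle detection and kinetic inference.

A reeling translocase produces periodic sawtooth FRET traces; the repetition
period Δt of one cycle is the observable. The kinetic machinery here:

* hysteresis cycle detector (automated replacement for visual peak picking);
* Γ-distribution hidden-step fit: if a cycle is composed of n hidden
  irreversible Poisson steps of identical rate k, Δt ~ Γ(n, k); the continuous
  shape estimate bounds the kinetic step size from above by track/n;
* period-vs-track-length regression giving the translocation speed;
* Michaelis–Menten fit of repetition rate (1/τ) vs [ATP].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from scipy.ndimage import median_filter
from scipy.optimize import brentq, curve_fit

__all__ = [
    "CycleRecord",
    "GammaFitResult",
    "SpeedFit",
    "MMFitResult",
    "detect_cycles",
    "fit_gamma",
    "infer_step_size",
    "fit_period_vs_length",
    "fit_michaelis_menten",
    "extrapolate_speed",
]


@dataclass
class CycleRecord:
    molecule_id: str
    boundary_times: np.ndarray
    dwells: np.ndarray
    diagnostic: str = ""

    def __post_init__(self) -> None:
        self.boundary_times = np.asarray(self.boundary_times, dtype=float)
        self.dwells = np.asarray(self.dwells, dtype=float)
        if self.boundary_times.size > 1 and np.any(np.diff(self.boundary_times) <= 0):
            raise ValueError("boundary_times must be strictly increasing")
        if np.any(self.dwells <= 0):
            raise ValueError("dwells must be strictly positive")


@dataclass
class GammaFitResult:
    n: float              # shape (number of hidden rate-limiting steps)
    k: float              # per-step rate, 1/s
    n_se: float
    k_se: float
    n_events: int
    method: str = "mle"

    @property
    def mean_dwell(self) -> float:
        return self.n / self.k


@dataclass
class SpeedFit:
    v: float              # nt/s
    intercept: float      # s
    v_se: float
    intercept_se: float


@dataclass
class MMFitResult:
    rate_max: float       # 1/s at saturating substrate
    K_M: float            # uM
    rate_max_se: float
    K_M_se: float


def default_thresholds(anchor_low: float, anchor_high: float) -> tuple:
    """Hysteresis thresholds at anchors ± 25% of the anchor span."""
    span = anchor_high - anchor_low
    return anchor_low + 0.25 * span, anchor_high - 0.25 * span


def detect_cycles(
    trace,
    polarity: str = "rising_sawtooth",
    high_thresh: float | None = None,
    low_thresh: float | None = None,
    min_dwell_s: float = 0.15,
    anchors: tuple | None = None,
    smooth_frames: int = 3,
) -> CycleRecord:
    """Detect cycle boundaries in a sawtooth FRET trace by hysteresis.

    ``rising_sawtooth``: E builds up gradually and collapses abruptly; a
    boundary is the downward crossing of ``low_thresh`` after an excursion
    above ``high_thresh``. ``falling_sawtooth`` (G4 unwinding cycles): E
    decreases stepwise and recovers abruptly; a boundary is the upward
    crossing of ``high_thresh`` after an excursion below ``low_thresh``.

    A short centered running-median filter (``smooth_frames``, default 3)
    suppresses shot-noise re-crossings when the trace lingers between the
    thresholds (slow stepping); wider windows bias against cycles shorter
    than ~20 frames, so keep the window small. Boundaries closer than
    ``min_dwell_s`` are merged. Fewer than two boundaries yields an empty
    dwell list with a diagnostic, not a failure.
    """
    if anchors is not None and (high_thresh is None or low_thresh is None):
        low_thresh, high_thresh = default_thresholds(*anchors)
    if high_thresh is None or low_thresh is None:
        raise ValueError("provide high_thresh/low_thresh or anchors")
    if not low_thresh < high_thresh:
        raise ValueError("require low_thresh < high_thresh")
    if polarity not in ("rising_sawtooth", "falling_sawtooth"):
        raise ValueError("polarity must be rising_sawtooth or falling_sawtooth")

    t = trace.time_s[trace.valid]
    e = trace.E[trace.valid]
    if smooth_frames > 1 and e.size >= smooth_frames:
        e = median_filter(e, size=smooth_frames, mode="nearest")

    boundaries = []
    armed = False
    if polarity == "rising_sawtooth":
        for ti, ei in zip(t, e):
            if ei > high_thresh:
                armed = True
            elif armed and ei < low_thresh:
                boundaries.append(ti)
                armed = False
    else:
        for ti, ei in zip(t, e):
            if ei < low_thresh:
                armed = True
            elif armed and ei > high_thresh:
                boundaries.append(ti)
                armed = False

    merged = []
    for b in boundaries:
        if merged and b - merged[-1] < min_dwell_s:
            continue
        merged.append(b)
    merged = np.array(merged)
    if merged.size < 2:
        return CycleRecord(
            molecule_id=trace.molecule_id,
            boundary_times=merged,
            dwells=np.array([]),
            diagnostic=f"only {merged.size} boundary(ies) detected",
        )
    return CycleRecord(
        molecule_id=trace.molecule_id,
        boundary_times=merged,
        dwells=np.diff(merged),
    )


def _gamma_mle(dwells: np.ndarray) -> tuple:
    """Profile-likelihood MLE for Gamma(shape n, rate k) with location 0.

    Solves log(n) - psi(n) = log(mean) - mean(log) for n; k = n / mean.
    Exactly scale-equivariant: rescaling dwells leaves n unchanged.
    """
    mean = dwells.mean()
    s = math.log(mean) - np.log(dwells).mean()
    if s <= 0:  # degenerate (all dwells identical)
        return np.inf, np.inf

    def f(n):
        return math.log(n) - special.digamma(n) - s

    # log(n)-psi(n) ~ 1/(2n) for large n; bracket around the moment start
    lo, hi = 1e-6, max(4.0, 2.0 / s)
    while f(hi) > 0:
        hi *= 2
    n_hat = brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    return n_hat, n_hat / mean


def fit_gamma(
    dwells,
    method: str = "mle",
    n_boot: int = 0,
    seed: int = 0,
    min_events: int = 30,
    bins: int = 30,
) -> GammaFitResult:
    """Fit the Γ density (Δt)^(n-1) e^(-k Δt) to a dwell-time sample.

    ``mle`` (default) maximises the likelihood with the shape continuous;
    standard errors come from the observed information matrix, or from a
    nonparametric bootstrap when ``n_boot`` > 0. ``binned_ls`` least-squares
    fits the density to a histogram as a cross-check.
    """
    dwells = np.asarray(dwells, dtype=float)
    if np.any(dwells <= 0):
        raise ValueError("all dwells must be strictly positive")
    if dwells.size < min_events:
        raise ValueError(f"need ≥{min_events} dwells, got {dwells.size}")

    if method == "mle":
        n_hat, k_hat = _gamma_mle(dwells)
        m = dwells.size
        # observed information per event: [[psi'(n), -1/k], [-1/k, n/k^2]]
        info = m * np.array(
            [[special.polygamma(1, n_hat), -1.0 / k_hat],
             [-1.0 / k_hat, n_hat / k_hat**2]]
        )
        cov = np.linalg.inv(info)
        n_se, k_se = np.sqrt(np.diag(cov))
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            reps = np.array(
                [_gamma_mle(rng.choice(dwells, m, replace=True)) for _ in range(n_boot)]
            )
            n_se, k_se = reps[:, 0].std(ddof=1), reps[:, 1].std(ddof=1)
        return GammaFitResult(n_hat, k_hat, float(n_se), float(k_se), m, "mle")

    if method == "binned_ls":
        dens, edges = np.histogram(dwells, bins=bins, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mean, var = dwells.mean(), dwells.var(ddof=1)
        p0 = [mean**2 / var, mean / var]  # moment start, independent of the MLE

        def pdf(x, n, k):
            return stats.gamma.pdf(x, a=n, scale=1.0 / k)

        popt, pcov = curve_fit(pdf, centers, dens, p0=p0, bounds=(1e-9, np.inf), maxfev=20000)
        se = np.sqrt(np.diag(pcov))
        return GammaFitResult(
            float(popt[0]), float(popt[1]), float(se[0]), float(se[1]), dwells.size, "binned_ls"
        )

    raise ValueError("method must be 'mle' or 'binned_ls'")


def infer_step_size(track_length_nt: int, gamma_fit: GammaFitResult):
    """Kinetic step-size bound from the hidden-step count.

    n hidden steps over a track of N nt bound the step size by N/n nt; when
    the bound is below 2 nt the only consistent integer step is reported,
    otherwise the integer step is undetermined.

    Returns ``(upper_limit_nt, integer_step_nt or None)``.
    """
    if gamma_fit.n <= 0:
        raise ValueError("gamma_fit.n must be positive")
    upper = track_length_nt / gamma_fit.n
    if upper < 2.0:
        return upper, max(1, int(math.floor(upper)))
    return upper, None


def fit_period_vs_length(pairs, tau_se=None) -> SpeedFit:
    """Weighted linear regression τ = N / v + b over (track length, period).

    The translocation speed is 1/slope with its SE by error propagation.
    A non-positive slope is flagged (no speed is reported).
    """
    pairs = sorted(pairs)
    N = np.array([p[0] for p in pairs], dtype=float)
    tau = np.array([p[1] for p in pairs], dtype=float)
    if np.unique(N).size < 3:
        raise ValueError("need ≥3 distinct track lengths")
    w = None if tau_se is None else 1.0 / np.asarray(tau_se, dtype=float) ** 2
    coeffs, cov = np.polyfit(N, tau, 1, w=None if w is None else np.sqrt(w), cov=True)
    slope, intercept = coeffs
    slope_se, intercept_se = np.sqrt(np.diag(cov))
    if slope <= 0:
        raise ValueError(f"non-positive slope {slope:.3g}: no speed reported")
    v = 1.0 / slope
    return SpeedFit(
        v=float(v),
        intercept=float(intercept),
        v_se=float(slope_se / slope**2),
        intercept_se=float(intercept_se),
    )


def fit_michaelis_menten(atp_uM, rates_per_s, rate_se=None) -> MMFitResult:
    """Nonlinear least squares of r = r_max * S / (K_M + S)."""
    S = np.asarray(atp_uM, dtype=float)
    r = np.asarray(rates_per_s, dtype=float)
    if S.size < 4:
        raise ValueError("need ≥4 substrate concentrations")
    if np.any(S <= 0) or np.any(r < 0):
        raise ValueError("concentrations must be positive, rates non-negative")

    def mm(s, rmax, km):
        return rmax * s / (km + s)

    sigma = None if rate_se is None else np.asarray(rate_se, dtype=float)
    try:
        popt, pcov = curve_fit(
            mm, S, r, p0=[r.max() * 1.5, np.median(S)],
            sigma=sigma, bounds=(1e-12, np.inf), maxfev=20000,
        )
    except RuntimeError as err:
        resid = r - mm(S, r.max(), np.median(S))
        raise RuntimeError(
            f"Michaelis–Menten fit did not converge: {err}; residuals at the "
            f"starting point: {np.array2string(resid, precision=4)}"
        ) from err
    se = np.sqrt(np.diag(pcov))
    return MMFitResult(float(popt[0]), float(popt[1]), float(se[0]), float(se[1]))


def extrapolate_speed(v_obs: float, S_uM: float, K_M_uM: float) -> float:
    """Saturating-ATP speed from a speed observed at substrate S:
    v_max = v_obs * (K_M + S) / S."""
    if v_obs <= 0 or S_uM <= 0 or K_M_uM <= 0:
        raise ValueError("all inputs must be strictly positive")
    return v_obs * (K_M_uM + S_uM) / S_uM
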