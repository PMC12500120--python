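"""Whole-brain Stuart-Landau (Hopf) model with heterogeneous bifurcation.

Each region is a Stuart-Landau oscillator — the normal form of the
supercritical Hopf bifurcation — diffusively coupled through the structural
connectome:

.. math::

    \\dot x_i = [a_i - (x_i^2 + y_i^2)]\\,x_i - \\omega y_i
               + G \\sum_j M_{ij} (x_j - x_i) + \\gamma\\,\\eta_i(t)

and symmetrically for :math:`y_i` with :math:`+\\omega x_i`.  For
:math:`a_i > 0` the node sits on a limit cycle of radius
:math:`\\sqrt{a_i}`; for :math:`a_i < 0` it relaxes to a fixed point and is
noise-driven; near :math:`a_i = 0` both behaviours coexist.  The real part
``x`` plays the role of the BOLD-like signal.

Regional heterogeneity and stimulation enter through the bifurcation
parameter, ``a_i = bias + scale * (beta_i + alpha * [i == target])``: the
heterogeneity vector ``beta`` comes from a communication model of the
connectome and ``alpha`` is the stimulation intensity applied at one target
region.

Integration is Euler-Maruyama with independent Gaussian increments of
standard deviation ``gamma_noise * sqrt(dt)`` per node and component.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .exceptions import DivergenceError

__all__ = [
    "HopfConfig",
    "SimOutput",
    "bifurcation_vector",
    "simulate",
    "preprocess",
    "decimate_series",
    "fc_matrix",
    "kop",
]

_DIVERGENCE_BOUND = 1e6
_CHECK_EVERY = 200  # steps between divergence checks


@dataclass(frozen=True)
class HopfConfig:
    """Full parameterization of one simulation.

    Defaults follow the study protocol: intrinsic frequency 0.05 Hz, noise
    SD 0.02, global coupling 0.16, 1100 s at dt = 0.1 s with 100 s trimmed
    at each end (15 min retained), band-pass 0.001-0.01 Hz for the
    BOLD-like output and 0.01-0.1 Hz for phase/synchrony estimation.
    """

    omega: float = 2 * np.pi * 0.05  # rad/s
    gamma_noise: float = 0.02
    G: float = 0.16
    bias: float = -0.17
    scale: float = 0.24
    beta: np.ndarray | None = None  # per-region heterogeneity in [0, 1]
    alpha: float = 0.0
    target: int | None = None
    dt: float = 0.1  # s
    duration: float = 1100.0  # s
    trim: float = 100.0  # s removed at each end
    band: tuple[float, float] = (0.001, 0.01)  # Hz
    kop_band: tuple[float, float] = (0.01, 0.1)  # Hz
    seed: int = 0
    as_printed_nonlinearity: bool = field(default=False, repr=False)

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= 2 * self.trim:
            raise ValueError("duration must exceed 2 * trim")
        if not self.band[0] < self.band[1]:
            raise ValueError("band must be (low, high) with low < high")

    def with_(self, **kw) -> "HopfConfig":
        return replace(self, **kw)


@dataclass
class SimOutput:
    """Raw simulation output plus FC/synchrony summaries.

    ``fc`` is the Pearson matrix of the raw real component; ``kop_mean`` /
    ``kop_std`` summarize the Kuramoto order parameter computed in the
    configured synchrony band.
    """

    x: np.ndarray  # T x N, BOLD-like real component
    y: np.ndarray  # T x N, imaginary component
    dt_sample: float
    a_used: np.ndarray
    fc: np.ndarray
    kop_mean: float
    kop_std: float


def bifurcation_vector(
    bias: float,
    scale: float,
    beta: np.ndarray,
    alpha: float = 0.0,
    target: int | None = None,
) -> np.ndarray:
    """Per-region bifurcation parameters, ``a_i = bias + scale*(beta_i + alpha*1_target)``."""
    beta = np.asarray(beta, float)
    stim = np.zeros_like(beta)
    if target is not None and alpha != 0.0:
        stim[target] = alpha
    return bias + scale * (beta + stim)


def simulate(connectome, config: HopfConfig) -> SimOutput:
    """Integrate the coupled system and return the raw series with summaries.

    ``connectome`` may be a :class:`~tusnet.synthetic.Connectome` or a plain
    symmetric weight matrix.  Initial conditions are uniform(-0.1, 0.1) per
    node and component, drawn from ``config.seed``.  Raises
    :class:`DivergenceError` if the state magnitude exceeds 1e6.
    """
    config.validate()
    M = getattr(connectome, "weights", connectome)
    M = np.asarray(M, float)
    n = M.shape[0]
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("weights must be symmetric")
    beta = np.zeros(n) if config.beta is None else np.asarray(config.beta, float)
    if len(beta) != n:
        raise ValueError("beta length must match the region count")
    a = bifurcation_vector(config.bias, config.scale, beta, config.alpha, config.target)

    rng = np.random.default_rng(config.seed)
    steps = int(round(config.duration / config.dt))
    dt, omega, G = config.dt, config.omega, config.G
    row = M.sum(axis=1)
    sq_sign = -1.0 if config.as_printed_nonlinearity else 1.0

    x = rng.uniform(-0.1, 0.1, n)
    y = rng.uniform(-0.1, 0.1, n)
    noise = rng.standard_normal((steps, 2, n)) * (config.gamma_noise * np.sqrt(dt))
    xs = np.empty((steps, n))
    ys = np.empty((steps, n))
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(steps):
            r2 = x * x + sq_sign * y * y
            cx = M @ x - row * x
            cy = M @ y - row * y
            dx = (a - r2) * x - omega * y + G * cx
            dy = (a - r2) * y + omega * x + G * cy
            x = x + dt * dx + noise[t, 0]
            y = y + dt * dy + noise[t, 1]
            xs[t] = x
            ys[t] = y
            if t % _CHECK_EVERY == 0 and not np.all(np.abs(x) < _DIVERGENCE_BOUND):
                raise DivergenceError(t, _DIVERGENCE_BOUND)
    if not np.all(np.isfinite(xs)):
        raise DivergenceError(steps, _DIVERGENCE_BOUND)

    kop_mean, kop_std = kop(xs, config.kop_band, dt)
    return SimOutput(
        x=xs,
        y=ys,
        dt_sample=dt,
        a_used=a,
        fc=fc_matrix(xs),
        kop_mean=kop_mean,
        kop_std=kop_std,
    )


def _bandpass_sos(band: tuple[float, float], dt: float):
    nyq = 0.5 / dt
    if not 0 < band[0] < band[1] < nyq:
        raise ValueError(f"band {band} outside (0, Nyquist={nyq:g}) Hz")
    return butter(2, band, btype="bandpass", fs=1.0 / dt, output="sos")


def preprocess(raw, config: HopfConfig) -> np.ndarray:
    """Zero-phase band-pass then trim the transients.

    Applies a 2nd-order Butterworth filter (forward-backward) in
    ``config.band`` and removes ``config.trim`` seconds at each end; the
    default protocol keeps ``1100 - 2*100 = 900`` s, i.e. 15 minutes.
    """
    series = raw.x if isinstance(raw, SimOutput) else np.asarray(raw, float)
    n_trim = int(round(config.trim / config.dt))
    if series.shape[0] <= 2 * n_trim:
        raise ValueError("series shorter than twice the trim window")
    sos = _bandpass_sos(config.band, config.dt)
    filtered = sosfiltfilt(sos, series, axis=0)
    return filtered[n_trim : series.shape[0] - n_trim]


def decimate_series(series: np.ndarray, dt: float, tr: float) -> tuple[np.ndarray, float]:
    """Subsample a band-limited series to an fMRI-like sampling interval.

    Safe without an extra anti-alias filter as long as the series was
    band-passed well below the new Nyquist frequency.
    """
    stride = max(1, int(round(tr / dt)))
    return series[::stride], dt * stride


def fc_matrix(series: np.ndarray) -> np.ndarray:
    """Pearson functional connectivity across time; unit diagonal."""
    fc = np.corrcoef(np.asarray(series, float), rowvar=False)
    np.fill_diagonal(fc, 1.0)
    return fc


def kop(
    series: np.ndarray, kop_band: tuple[float, float] = (0.01, 0.1), dt_sample: float = 0.1
) -> tuple[float, float]:
    """Mean and SD of the Kuramoto order parameter.

    Phases are the analytic-signal angles of the band-passed series;
    :math:`R(t) = |N^{-1}\\sum_j e^{i\\theta_j(t)}|`.  The first and last
    10% of samples are discarded to avoid filter and Hilbert edge effects.
    """
    X = np.asarray(series, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a T x N series with N >= 2 regions")
    if X.shape[0] < 30:
        raise ValueError("series too short for filtering")
    sos = _bandpass_sos(kop_band, dt_sample)
    filtered = sosfiltfilt(sos, X, axis=0)
    theta = np.angle(hilbert(filtered, axis=0))
    r = np.abs(np.exp(1j * theta).mean(axis=1))
    edge = max(1, int(0.1 * len(r)))
    r = r[edge:-edge]
    return float(r.mean()), float(r.std())
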