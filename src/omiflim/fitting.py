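"""Per-pixel two-component lifetime fitting with IRF deconvolution.

Each pixel's TCSPC histogram is fit by nonlinear least squares to the
IRF-convolved two-component decay (see :mod:`omiflim.model`). The default
objective is Neyman-weighted least squares (per-bin weights 1/max(count, 1));
a Poisson maximum-likelihood objective is available as an alternative.
Optimization uses a bounded trust-region reflective solver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft, ndimage, optimize

from .axes import IRFKernel, TimeAxis
from .model import DecayModelParams, mean_lifetime

__all__ = [
    "FitBounds",
    "FitOptions",
    "PixelFitResult",
    "ParameterMaps",
    "fit_pixel",
    "fit_image",
    "DEFAULT_BOUNDS",
    "CHANNEL_INITS",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the decay parameters (ns for lifetimes).

    The default ranges enforce tau1 < tau2 by construction: the short
    component lives in [0.05, 1.0] ns and the long one in [1.0, 6.0] ns.
    """

    tau1: tuple[float, float] = (0.05, 1.0)
    tau2: tuple[float, float] = (1.0, 6.0)
    alpha1: tuple[float, float] = (0.0, 1.0)
    amplitude: tuple[float, float] = (0.0, np.inf)
    offset: tuple[float, float] = (0.0, np.inf)


DEFAULT_BOUNDS = FitBounds()

# Literature-typical free/bound lifetimes used to initialize the solver.
CHANNEL_INITS: dict[str, tuple[float, float]] = {
    "nadph": (0.4, 2.5),
    "fad": (0.4, 2.0),
}


@dataclass(frozen=True)
class FitOptions:
    """Solver settings for per-pixel fits.

    objective : "wls" (Neyman-weighted least squares, default) or "poisson"
        (maximum likelihood, minimized with L-BFGS-B).
    """

    channel: str = "nadph"
    bounds: FitBounds = field(default_factory=FitBounds)
    objective: str = "wls"
    wrap: bool = False
    alpha1_init: float = 0.7
    tau_init: tuple[float, float] | None = None  # defaults per channel
    n_prepeak_bins: int = 10
    ftol: float = 1e-8
    xtol: float = 1e-8
    max_nfev: int = 400

    def tau_inits(self) -> tuple[float, float]:
        if self.tau_init is not None:
            return self.tau_init
        return CHANNEL_INITS.get(self.channel, CHANNEL_INITS["nadph"])


@dataclass(frozen=True)
class PixelFitResult:
    """Fit outcome for one pixel."""

    params: DecayModelParams
    tau_mean: float
    reduced_chi2: float
    n_photons: float
    converged: bool


@dataclass
class ParameterMaps:
    """Per-pixel maps of fitted decay parameters over a field of view.

    Values are defined only where ``valid`` is set. ``intensity`` holds the
    fitted decay-component photon count (amplitude; background offset
    excluded), which is the intensity used for the optical redox ratio.
    """

    tau1: np.ndarray
    tau2: np.ndarray
    alpha1: np.ndarray
    tau_mean: np.ndarray
    intensity: np.ndarray
    offset: np.ndarray
    chi2: np.ndarray
    valid: np.ndarray
    n_photons: np.ndarray
    settings: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape


def _fold(full: np.ndarray, n: int, wrap: bool) -> np.ndarray:
    y = full[:n].copy()
    if wrap:
        tail = full[n:]
        y[: tail.size] += tail
    return y


class _ConvCache:
    """FFT-based linear convolution with a fixed IRF (hot path)."""

    def __init__(self, irf_values: np.ndarray):
        self.n = irf_values.size
        self.m = sfft.next_fast_len(2 * self.n - 1)
        self.F = sfft.rfft(irf_values, self.m)

    def __call__(self, d: np.ndarray) -> np.ndarray:
        full = sfft.irfft(sfft.rfft(d, self.m) * self.F, self.m)
        return full[: 2 * self.n - 1]


def _normalized_curve(
    theta: np.ndarray, t: np.ndarray, conv: "_ConvCache", wrap: bool
) -> np.ndarray:
    """IRF-convolved bi-exponential normalized to unit sum in the window."""
    a1, t1, t2 = theta
    d = a1 * np.exp(-t / t1) + (1.0 - a1) * np.exp(-t / t2)
    c = _fold(conv(d), t.size, wrap)
    s = c.sum()
    return c / s if s > 0 else np.full(t.size, 1.0 / t.size)


def _solve_linear(
    g: np.ndarray, y: np.ndarray, w2: np.ndarray, fit_offset: bool
) -> tuple[float, float]:
    """Weighted least-squares amplitude/offset for fixed shape g (sum 1),
    constrained nonnegative."""
    sgg = float(np.dot(w2, g * g))
    sgy = float(np.dot(w2, g * y))
    if not fit_offset:
        return (max(sgy / sgg, 0.0) if sgg > 0 else 0.0), 0.0
    sg = float(np.dot(w2, g))
    sw = float(w2.sum())
    sy = float(np.dot(w2, y))
    det = sgg * sw - sg * sg
    if det <= 0:
        return (max(sgy / sgg, 0.0) if sgg > 0 else 0.0), 0.0
    amp = (sgy * sw - sg * sy) / det
    off = (sgg * sy - sg * sgy) / det
    if off < 0.0:
        off = 0.0
        amp = sgy / sgg if sgg > 0 else 0.0
    if amp < 0.0:
        amp = 0.0
        off = max(sy / sw, 0.0)
    return amp, off


def _curve_raw(x: np.ndarray, t: np.ndarray, irf_values: np.ndarray, wrap: bool) -> np.ndarray:
    """Model curve without parameter-object overhead (hot path)."""
    amp, a1, t1, t2, off = x
    n = t.size
    d = a1 * np.exp(-t / t1) + (1.0 - a1) * np.exp(-t / t2)
    y = _fold(np.convolve(d, irf_values), n, wrap)
    s = y.sum()
    if amp == 0.0 or s <= 0.0:
        return np.full(n, off)
    return amp * (y / s) + off


def _model_curve(x: np.ndarray, time_axis: TimeAxis, irf: IRFKernel, wrap: bool) -> np.ndarray:
    return _curve_raw(x, time_axis.centers, irf.values, wrap)


def fit_pixel(
    decay: np.ndarray,
    irf: IRFKernel,
    time_axis: TimeAxis,
    options: FitOptions | None = None,
) -> PixelFitResult:
    """Fit one pixel's decay histogram.

    Never raises on optimizer failure: ``converged=False`` is returned with
    the best-effort parameters. Raises only on malformed input (shape
    mismatch, all-zero histogram).
    """
    opt = options or FitOptions()
    y = np.asarray(decay, dtype=float)
    n = time_axis.n_bins
    if y.shape != (n,):
        raise ValueError(f"decay has shape {y.shape}, expected ({n},)")
    total = float(y.sum())
    if total <= 0:
        raise ValueError("decay is below threshold (no photons)")

    b = opt.bounds
    peak = int(np.argmax(y))
    pre = y[max(0, peak - opt.n_prepeak_bins) : peak]
    off0 = float(pre.mean()) if pre.size else 0.0
    amp0 = max(total - off0 * n, 1.0)
    t1_0, t2_0 = opt.tau_inits()
    lo = np.array([b.amplitude[0], b.alpha1[0], b.tau1[0], b.tau2[0], b.offset[0]])
    hi = np.array([b.amplitude[1], b.alpha1[1], b.tau1[1], b.tau2[1], b.offset[1]])
    x0 = np.clip(np.array([amp0, opt.alpha1_init, t1_0, t2_0, off0]), lo, hi)

    t = time_axis.centers
    iv = irf.values
    if opt.objective == "wls":
        w = 1.0 / np.sqrt(np.maximum(y, 1.0))
        w2 = w * w
        conv = _ConvCache(iv)
        # amplitude and offset enter linearly: solve them exactly per shape
        # (separable / variable-projection least squares) and optimize only
        # the nonlinear shape parameters (alpha1, tau1, tau2)
        theta0 = x0[1:4]
        tlo, thi = lo[1:4], hi[1:4]

        def residuals(theta: np.ndarray) -> np.ndarray:
            g = _normalized_curve(theta, t, conv, opt.wrap)
            amp, off = _solve_linear(g, y, w2, fit_offset=True)
            return (amp * g + off - y) * w

        try:
            res = optimize.least_squares(
                residuals,
                theta0,
                bounds=(tlo, thi),
                method="trf",
                ftol=opt.ftol,
                xtol=opt.xtol,
                max_nfev=opt.max_nfev,
            )
            theta, success = res.x, bool(res.success)
        except Exception:  # pragma: no cover - defensive
            theta, success = theta0, False
        g = _normalized_curve(theta, t, conv, opt.wrap)
        amp, off = _solve_linear(g, y, w2, fit_offset=True)
        x = np.array([amp, theta[0], theta[1], theta[2], off])
        chi2 = float(np.sum(((amp * g + off - y) * w) ** 2))
    elif opt.objective == "poisson":

        def nll(x: np.ndarray) -> float:
            mu = np.maximum(_model_curve(x, time_axis, irf, opt.wrap), 1e-12)
            return float(np.sum(mu - y * np.log(mu)))

        try:
            res = optimize.minimize(
                nll,
                x0,
                method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
                options={"maxfun": 4 * opt.max_nfev, "ftol": opt.ftol},
            )
            x, success = res.x, bool(res.success)
        except Exception:  # pragma: no cover - defensive
            x, success = x0, False
        w = 1.0 / np.sqrt(np.maximum(y, 1.0))
        chi2 = float(np.sum(((_model_curve(x, time_axis, irf, opt.wrap) - y) * w) ** 2))
    else:
        raise ValueError(f"unknown objective {opt.objective!r}")

    amp, a1, t1, t2, off = x
    t1, t2 = min(t1, t2), max(t1, t2)
    params = DecayModelParams(
        amplitude=float(amp), alpha1=float(a1), tau1=float(t1), tau2=float(t2), offset=float(off)
    )
    dof = max(n - 5, 1)
    return PixelFitResult(
        params=params,
        tau_mean=float(mean_lifetime(t1, t2, a1)),
        reduced_chi2=chi2 / dof,
        n_photons=total,
        converged=success,
    )


def _binned_cube(cube: np.ndarray, binning: int) -> np.ndarray:
    """k x k spatial sum-binning of a (rows, cols, bins) cube, reported on
    the original grid (each pixel pools its k x k neighborhood; the field
    edge is zero-padded)."""
    k = binning
    kernel_sum = ndimage.uniform_filter(
        cube.astype(float), size=(k, k, 1), mode="constant", cval=0.0
    )
    return kernel_sum * (k * k)


def fit_image(
    cube: np.ndarray,
    irf: IRFKernel,
    time_axis: TimeAxis,
    threshold: float = 500.0,
    binning: int = 1,
    options: FitOptions | None = None,
) -> ParameterMaps:
    """Fit every above-threshold pixel of a decay cube independently.

    Parameters
    ----------
    cube : (rows, cols, n_bins) photon counts
    threshold : minimum total photons per (binned) pixel; pixels below it
        are excluded from the validity mask (background exclusion).
    binning : odd k >= 1; k x k spatial sum-binning pools neighboring
        photons before fitting while results stay on the original grid.
    """
    opt = options or FitOptions()
    arr = np.asarray(cube)
    if arr.ndim != 3 or arr.shape[2] != time_axis.n_bins:
        raise ValueError(
            f"cube shape {arr.shape} incompatible with {time_axis.n_bins}-bin axis"
        )
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if binning < 1 or binning % 2 == 0:
        raise ValueError(f"binning must be an odd integer >= 1, got {binning}")
    if binning > min(arr.shape[:2]):
        raise ValueError(
            f"binning {binning} larger than image {arr.shape[:2]}"
        )

    work = _binned_cube(arr, binning) if binning > 1 else arr.astype(float)
    totals = work.sum(axis=2)
    valid = totals >= threshold

    shape = arr.shape[:2]
    nan = np.full(shape, np.nan)
    maps = ParameterMaps(
        tau1=nan.copy(),
        tau2=nan.copy(),
        alpha1=nan.copy(),
        tau_mean=nan.copy(),
        intensity=nan.copy(),
        offset=nan.copy(),
        chi2=nan.copy(),
        valid=np.zeros(shape, dtype=bool),
        n_photons=totals.copy(),
        settings={
            "threshold": threshold,
            "binning": binning,
            "channel": opt.channel,
            "objective": opt.objective,
            "wrap": opt.wrap,
        },
    )
    n_failed = 0
    for r, c in zip(*np.nonzero(valid)):
        try:
            res = fit_pixel(work[r, c], irf, time_axis, opt)
        except ValueError:
            continue
        if not res.converged:
            n_failed += 1
            continue  # non-convergent pixels stay invalid (manual-QC analogue)
        p = res.params
        maps.tau1[r, c] = p.tau1
        maps.tau2[r, c] = p.tau2
        maps.alpha1[r, c] = p.alpha1
        maps.tau_mean[r, c] = res.tau_mean
        maps.intensity[r, c] = p.amplitude
        maps.offset[r, c] = p.offset
        maps.chi2[r, c] = res.reduced_chi2
        maps.valid[r, c] = True
    if n_failed:
        log.warning("fit_image: %d pixels failed to converge and were excluded", n_failed)
    return maps
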