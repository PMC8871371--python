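"""Two-component fluorescence decay model.

The per-pixel decay is modeled as

    I(t) = alpha1 * exp(-t / tau1) + alpha2 * exp(-t / tau2) + C,

with alpha1 + alpha2 = 1, tau1 < tau2, and a constant background C per bin.
For NAD(P)H the short component tau1 is the free coenzyme and tau2 the
protein-bound form; for FAD the assignment is reversed. The observed TCSPC
histogram is this decay convolved with the instrument response function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .axes import IRFKernel, TimeAxis

__all__ = ["DecayModelParams", "mean_lifetime", "model_decay"]


def mean_lifetime(tau1: float, tau2: float, alpha1: float):
    """Amplitude-weighted mean lifetime tau_m = alpha1*tau1 + (1-alpha1)*tau2.

    Accepts scalars or arrays; ``alpha1`` must lie in [0, 1].
    """
    a = np.asarray(alpha1)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("alpha1 must lie in [0, 1]")
    out = alpha1 * tau1 + (1.0 - alpha1) * tau2
    return out


@dataclass(frozen=True)
class DecayModelParams:
    """Parameters of one pixel's two-component decay.

    amplitude : expected decay-component photons collected in the window
    alpha1    : fractional contribution of the short-lifetime component
    tau1/tau2 : short/long lifetimes in ns (tau1 < tau2 by convention)
    offset    : constant background, counts per bin
    """

    amplitude: float
    alpha1: float
    tau1: float
    tau2: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha1 <= 1.0):
            raise ValueError(f"alpha1 must be in [0,1], got {self.alpha1}")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("lifetimes must be positive")
        if self.tau1 > self.tau2:
            raise ValueError(
                f"ordering convention tau1 <= tau2 violated: {self.tau1} > {self.tau2}"
            )
        if self.amplitude < 0 or self.offset < 0:
            raise ValueError("amplitude and offset must be nonnegative")

    @property
    def alpha2(self) -> float:
        return 1.0 - self.alpha1

    @property
    def tau_mean(self) -> float:
        return float(mean_lifetime(self.tau1, self.tau2, self.alpha1))


def _biexp(alpha1: float, tau1: float, tau2: float, t: np.ndarray) -> np.ndarray:
    return alpha1 * np.exp(-t / tau1) + (1.0 - alpha1) * np.exp(-t / tau2)


def model_decay(
    params: DecayModelParams,
    time_axis: TimeAxis,
    irf: IRFKernel,
    wrap: bool = False,
) -> np.ndarray:
    """Expected counts per time bin for a two-component decay under an IRF.

    The bi-exponential is evaluated at bin centers, convolved with the IRF
    kernel, and scaled so the decay-component counts inside the measurement
    window sum exactly to ``params.amplitude``; ``params.offset`` counts are
    added to every bin. With ``wrap=True`` the convolution tail beyond the
    window is folded back once (incomplete-decay / periodic excitation).
    """
    n = time_axis.n_bins
    if len(irf.values) != n:
        raise ValueError("IRF length does not match the time axis")
    d = _biexp(params.alpha1, params.tau1, params.tau2, time_axis.centers)
    full = np.convolve(d, irf.values)
    y = full[:n].copy()
    if wrap:
        tail = full[n:]
        y[: tail.size] += tail
    s = y.sum()
    if params.amplitude == 0.0 or s <= 0.0:
        return np.full(n, params.offset, dtype=float)
    return params.amplitude * (y / s) + params.offset
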