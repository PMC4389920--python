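"""Bipolar-coordinate eccentric annulus: coordinate map, grid, quadrature.

Curves of constant tau are nested nonconcentric circles of radius
``d/sinh(tau)`` centered at ``(d/tanh(tau), 0)``; greater tau means a
smaller circle.  The computational domain ``tau_ext < tau < tau_int``,
``-pi <= sigma < pi`` is the off-center annulus between the two circles.
The metric scale factor is ``h = d/(cosh(tau) - cos(sigma))`` and the area
element is ``h^2 dtau dsigma``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "BipolarGrid",
    "bipolar_to_cartesian",
    "make_grid",
    "area_weights",
    "annulus_area",
    "circle_for_tau",
]


def bipolar_to_cartesian(tau, sigma, d):
    """Map (tau, sigma) to Cartesian (x, y); singular at tau=0, sigma=0 (mod 2pi)."""
    tau = np.asarray(tau, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    denom = np.cosh(tau) - np.cos(sigma)
    if np.any(denom <= 1e-300):
        raise ConfigurationError("bipolar map singular at tau = 0, sigma = 0 (mod 2*pi)")
    x = d * np.sinh(tau) / denom
    y = d * np.sin(sigma) / denom
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


@dataclass(frozen=True)
class BipolarGrid:
    d: float
    tau_ext: float
    tau_int: float
    m: int
    n: int
    dtau: float
    dsigma: float
    tau_values: np.ndarray  # (m,)
    sigma_values: np.ndarray  # (n,), periodic with sigma_{n+k} = sigma_k
    h: np.ndarray  # (m, n) metric scale factors

    @property
    def shape(self) -> tuple[int, int]:
        return (self.m, self.n)

    def cache_key(self) -> tuple:
        return (self.d, self.tau_ext, self.tau_int, self.m, self.n)


def make_grid(tau_ext: float, tau_int: float, m: int, n: int, d: float) -> BipolarGrid:
    """Build the discrete annulus grid with uniform spacing in tau and sigma."""
    if not (0 < tau_ext < tau_int):
        raise ConfigurationError(
            f"need 0 < tau_ext < tau_int, got tau_ext={tau_ext}, tau_int={tau_int}"
        )
    if m < 4 or n < 4:
        raise ConfigurationError(f"need m >= 4 and n >= 4 grid levels, got m={m}, n={n}")
    if d <= 0:
        raise ConfigurationError(f"focal scale d must be positive, got {d}")
    dtau = (tau_int - tau_ext) / (m - 1)
    dsigma = 2.0 * np.pi / n
    tau_values = tau_ext + dtau * np.arange(m)
    sigma_values = -np.pi + dsigma * np.arange(n)
    h = d / (np.cosh(tau_values)[:, None] - np.cos(sigma_values)[None, :])
    return BipolarGrid(
        d=d, tau_ext=tau_ext, tau_int=tau_int, m=m, n=n,
        dtau=dtau, dsigma=dsigma,
        tau_values=tau_values, sigma_values=sigma_values, h=h,
    )


def area_weights(grid: BipolarGrid, metric: bool = True) -> np.ndarray:
    """Quadrature weights for Riemann sums over the grid.

    With ``metric=True`` (default) each cell weighs ``h^2 dtau dsigma``, the
    bipolar area element, so sums approximate true area integrals; with
    ``metric=False`` the bare coordinate cell ``dtau dsigma`` is used.  The
    first and last tau rows get half weight (trapezoid rule in tau; sigma is
    periodic and needs no correction).
    """
    base = grid.h**2 if metric else np.ones(grid.shape)
    w = base * (grid.dtau * grid.dsigma)
    w = w.copy()
    w[0, :] *= 0.5
    w[-1, :] *= 0.5
    return w


def annulus_area(tau_ext: float, tau_int: float, d: float) -> float:
    """Exact area between the constant-tau circles: pi d^2 (sinh^-2 tau_ext - sinh^-2 tau_int)."""
    return np.pi * d**2 * (1.0 / np.sinh(tau_ext) ** 2 - 1.0 / np.sinh(tau_int) ** 2)


def circle_for_tau(tau: float, d: float) -> tuple[tuple[float, float], float]:
    """Center and radius of the circle traced by a constant-tau coordinate line."""
    return (d / np.tanh(tau), 0.0), d / abs(np.sinh(tau))
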