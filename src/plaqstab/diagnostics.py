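"""Energy diagnostics: perturbation fixtures, energy time series, classification.

The scalar diagnostic is the metric-weighted Riemann sum
``I(t) = sum_ij (a^2 + b^2 + c^2) w_ij`` of squared perturbations; when an
energy certificate is available the weighted functional
``phi(t) = 1/2 sum_ij (x a^2 + y b^2 + z c^2) w_ij`` is tracked alongside
and compared against its exponential decay bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np

from .discretization import StateField, Trajectory, integrate
from .errors import ConfigurationError
from .geometry import BipolarGrid, area_weights
from .model import (
    Equilibrium,
    LinearCoefficients,
    ModelParameters,
    compute_equilibrium,
    linearize,
)
from .stability import EnergyCertificate

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationSpec",
    "EnergyTimeSeries",
    "energy_integral",
    "weighted_functional",
    "make_perturbation",
    "run_experiment",
    "check_decay_bound",
]

DECAY_FACTOR = 1e-3
GROWTH_FACTOR = 10.0
PLATEAU_RTOL = 1e-4
PLATEAU_CAP = 2.0
DECAY_BOUND_SLACK = 1.05


@dataclass(frozen=True)
class PerturbationSpec:
    """Deterministic initial-perturbation recipe.

    Patterns: ``fourier`` (params ``k_tau``, ``k_sigma``) is
    ``cos(k_tau*pi*s) * cos(k_sigma*sigma)`` with ``s`` the normalized tau
    coordinate; ``gaussian`` (params ``center``, ``width``) is a sigma bump
    windowed by ``sin^2(pi*s)`` in tau; ``random`` (param ``seed``) is a
    seeded combination of low-order boundary-compatible modes.  All patterns
    have zero normal derivative at the tau boundaries.
    """

    amplitude: float
    pattern: str = "fourier"
    k_tau: int = 0
    k_sigma: int = 1
    center: float = 0.0
    width: float = 0.5
    seed: int = 0
    species_mask: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self):
        if self.pattern not in ("fourier", "gaussian", "random"):
            raise ConfigurationError(f"unknown perturbation pattern {self.pattern!r}")
        if not np.isfinite(self.amplitude) or self.amplitude < 0:
            raise ConfigurationError("amplitude must be finite and nonnegative")
        if self.pattern == "gaussian" and self.width <= 0:
            raise ConfigurationError("gaussian width must be positive")
        if not any(self.species_mask):
            raise ConfigurationError("at least one species must be perturbed")


@dataclass
class EnergyTimeSeries:
    times: np.ndarray
    I_values: np.ndarray
    phi_values: np.ndarray | None
    classification: str  # "stable" | "unstable" | "inconclusive"
    trajectory: Trajectory | None = None


def _perturbations(state: StateField, eq: Equilibrium | None):
    if state.mode == "linearized":
        return state.a, state.b, state.c
    if eq is None:
        raise ConfigurationError("nonlinear-mode energy needs the equilibrium to subtract")
    return state.L - eq.L_e, state.M - eq.M_e, state.N - eq.N_e


def energy_integral(
    state: StateField,
    eq: Equilibrium | None,
    grid: BipolarGrid,
    weighting: str = "metric",
) -> float:
    """Riemann sum of a^2 + b^2 + c^2 over the annulus."""
    if state.grid.shape != grid.shape:
        raise ConfigurationError("state and grid shapes disagree")
    a, b, c = _perturbations(state, eq)
    w = area_weights(grid, metric=(weighting == "metric"))
    return float(np.sum((a**2 + b**2 + c**2) * w))


def weighted_functional(
    state: StateField,
    eq: Equilibrium | None,
    cert: EnergyCertificate,
    grid: BipolarGrid,
) -> float:
    """Certificate functional phi = 1/2 * sum(x a^2 + y b^2 + z c^2) * w."""
    a, b, c = _perturbations(state, eq)
    w = area_weights(grid, metric=True)
    return float(0.5 * np.sum((cert.x * a**2 + cert.y * b**2 + cert.z * c**2) * w))


def _pattern_field(spec: PerturbationSpec, grid: BipolarGrid) -> np.ndarray:
    s = (grid.tau_values - grid.tau_ext) / (grid.tau_int - grid.tau_ext)  # (m,)
    sig = grid.sigma_values  # (n,)
    if spec.pattern == "fourier":
        return np.cos(spec.k_tau * np.pi * s)[:, None] * np.cos(spec.k_sigma * sig)[None, :]
    if spec.pattern == "gaussian":
        dphi = np.angle(np.exp(1j * (sig - spec.center)))  # wrapped distance
        window = np.sin(np.pi * s) ** 2
        return window[:, None] * np.exp(-0.5 * (dphi / spec.width) ** 2)[None, :]
    # random: seeded combination of boundary-compatible separable modes
    rng = np.random.default_rng(spec.seed)
    field = np.zeros(grid.shape)
    for kt in range(3):
        for ks in range(4):
            amp = rng.standard_normal()
            phase = rng.uniform(0, 2 * np.pi)
            field += amp * np.cos(kt * np.pi * s)[:, None] * np.cos(ks * sig + phase)[None, :]
    peak = np.abs(field).max()
    return field / peak if peak > 0 else field


def make_perturbation(
    spec: PerturbationSpec,
    grid: BipolarGrid,
    eq: Equilibrium | None = None,
    mode: str = "linearized",
) -> StateField:
    """Build the initial state for an experiment; reproducible from the spec."""
    field = spec.amplitude * _pattern_field(spec, grid)
    parts = [field.copy() if on else np.zeros(grid.shape) for on in spec.species_mask]
    if mode == "linearized":
        return StateField(grid=grid, mode="linearized", L=parts[0], M=parts[1], N=parts[2])
    if eq is None:
        raise ConfigurationError("nonlinear-mode perturbation needs the equilibrium")
    floor = min(eq.L_e, eq.M_e, eq.N_e)
    if spec.amplitude > 0.1 * floor:
        logger.warning(
            "perturbation amplitude %.3g exceeds 10%% of the smallest equilibrium value %.3g",
            spec.amplitude, floor,
        )
    return StateField(
        grid=grid,
        mode="nonlinear",
        L=eq.L_e + parts[0],
        M=eq.M_e + parts[1],
        N=eq.N_e + parts[2],
    )


def _classify(times: np.ndarray, I: np.ndarray) -> str:
    I0 = I[0]
    if I0 == 0.0:
        return "stable"
    if I[-1] < DECAY_FACTOR * I0:
        return "stable"
    if I[-1] > GROWTH_FACTOR * I0:
        return "unstable"
    # plateau: bounded overall and flat over the last 10% of the run
    tail = times >= times[-1] - 0.1 * (times[-1] - times[0])
    tail_vals = I[tail]
    if tail_vals.size >= 2 and np.max(I) <= PLATEAU_CAP * I0:
        lo, hi = tail_vals.min(), tail_vals.max()
        ref = max(abs(hi), abs(lo), 1e-300)
        if (hi - lo) / ref < PLATEAU_RTOL:
            return "stable"
    return "inconclusive"


def run_experiment(
    model: Union[ModelParameters, LinearCoefficients],
    spec: PerturbationSpec,
    t_end: float,
    grid: BipolarGrid,
    mode: str = "linearized",
    *,
    cert: EnergyCertificate | None = None,
    n_outputs: int = 33,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
    divergence: str = "faithful",
    keep_trajectory: bool = False,
) -> EnergyTimeSeries:
    """Integrate a perturbed state and classify its energy history.

    ``model`` may be ModelParameters (equilibrium and linearization are
    derived as needed) or, in linearized mode, LinearCoefficients directly.
    """
    eq = None
    if isinstance(model, ModelParameters):
        eq = compute_equilibrium(model)
        dyn = linearize(model, eq) if mode == "linearized" else model
    else:
        if mode != "linearized":
            raise ConfigurationError("nonlinear mode requires full ModelParameters")
        dyn = model
    state0 = make_perturbation(spec, grid, eq=eq, mode=mode)
    output_times = np.linspace(0.0, t_end, n_outputs)
    traj = integrate(
        state0, dyn, t_end, output_times,
        rtol=rtol, atol=atol, method=method, divergence=divergence,
    )
    I = np.array([energy_integral(st, eq, grid) for st in traj.states])
    phi = None
    if cert is not None:
        phi = np.array([weighted_functional(st, eq, cert, grid) for st in traj.states])
    return EnergyTimeSeries(
        times=traj.times,
        I_values=I,
        phi_values=phi,
        classification=_classify(traj.times, I),
        trajectory=traj if keep_trajectory else None,
    )


def check_decay_bound(series: EnergyTimeSeries, cert: EnergyCertificate) -> bool:
    """True iff phi(t) <= 1.05 * phi(0) * exp(-M t) at every output time."""
    if series.phi_values is None:
        raise ConfigurationError("series carries no weighted-functional values")
    phi = series.phi_values
    if phi[0] <= 0:
        raise ConfigurationError("decay check requires phi(0) > 0")
    M = cert.decay_rate_bound
    bound = DECAY_BOUND_SLACK * phi[0] * np.exp(-M * series.times)
    return bool(np.all(phi <= bound))
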