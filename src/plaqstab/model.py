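"""Physical model: parameters, macrophage response functions, equilibrium, linearization.

The model tracks three species in the arterial intima: oxidized LDL ``L``,
macrophages ``M`` and necrotic lipids ``N``.  LDL enters at a constant rate
``L0``, macrophages enter at a concentration-dependent rate ``f(L)``,
macrophages consume LDL (``L + M -> N``, first order in each reactant) and
necrotic material is cleared at rate ``k_N``.  Macrophages diffuse and move
chemotactically up the LDL gradient; LDL diffuses; necrotic lipids are
immobile (no diffusion, no chemotaxis — these are structural, not
parameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import bisect

from .errors import EquilibriumNotFoundError, ResponseDomainError

__all__ = [
    "ResponseFunction",
    "ModelParameters",
    "Equilibrium",
    "LinearCoefficients",
    "evaluate_response",
    "compute_equilibrium",
    "homogeneous_rhs",
    "linearize",
]

_BRACKET_LO = 1e-12
_BRACKET_HI = 1e12


@dataclass(frozen=True)
class ResponseFunction:
    """Macrophage influx response ``f(L)`` with an analytic derivative.

    Families
    --------
    ``identity``
        ``f(L) = L``; testing convenience.
    ``logistic``
        ``f(L) = offset + amplitude / (1 + exp(-steepness*(L - center)))``,
        a bounded monotone-increasing sigmoid (the default physical choice).
    ``pinned``
        A logistic re-parameterized so the caller directly controls the
        value and the slope at a chosen point ``L_star``; the slope may be
        of either sign, which is how unstable configurations are produced.
    """

    family: str
    parameters: Mapping[str, float] = field(default_factory=dict)
    domain: tuple[float, float] = (-math.inf, math.inf)

    # -- constructors ----------------------------------------------------
    @classmethod
    def identity(cls) -> "ResponseFunction":
        return cls("identity", {}, (0.0, math.inf))

    @classmethod
    def logistic(
        cls,
        offset: float = 0.0,
        amplitude: float = 1.0,
        steepness: float = 1.0,
        center: float = 0.0,
    ) -> "ResponseFunction":
        if amplitude <= 0 or steepness <= 0 or offset < 0:
            raise ValueError("logistic response requires amplitude, steepness > 0 and offset >= 0")
        return cls(
            "logistic",
            {"offset": offset, "amplitude": amplitude, "steepness": steepness, "center": center},
        )

    @classmethod
    def pinned(cls, L_star: float, value: float, slope: float) -> "ResponseFunction":
        """Sigmoid with ``f(L_star) = value`` and ``f'(L_star) = slope``.

        Built as ``value/2 + value / (1 + exp(-s*(L - L_star)))`` with
        ``s = 4*slope/value``, so the value stays in ``(value/2, 3*value/2)``
        and is therefore nonnegative for any slope sign.
        """
        if value <= 0:
            raise ValueError("pinned response requires a strictly positive pinned value")
        return cls("pinned", {"L_star": L_star, "value": value, "slope": slope})

    # -- evaluation ------------------------------------------------------
    def __call__(self, L):
        """Return ``(f(L), f'(L))``; accepts scalars or ndarrays."""
        L = np.asarray(L, dtype=float)
        lo, hi = self.domain
        if np.any(L < lo) or np.any(L > hi):
            raise ResponseDomainError(f"concentration outside response domain [{lo}, {hi}]")
        p = self.parameters
        if self.family == "identity":
            value, deriv = L, np.ones_like(L)
        elif self.family == "logistic":
            u = p["steepness"] * (L - p["center"])
            g = _expit(u)
            value = p["offset"] + p["amplitude"] * g
            deriv = p["amplitude"] * p["steepness"] * g * (1.0 - g)
        elif self.family == "pinned":
            s = 4.0 * p["slope"] / p["value"]
            g = _expit(s * (L - p["L_star"]))
            value = 0.5 * p["value"] + p["value"] * g
            deriv = p["value"] * s * g * (1.0 - g)
        else:
            raise ValueError(f"unknown response family {self.family!r}")
        if value.ndim == 0:
            return float(value), float(deriv)
        return value, deriv


def _expit(u):
    # numerically safe logistic
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    e = np.exp(u[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def evaluate_response(rf: ResponseFunction, L: float):
    """Evaluate ``(f(L), f'(L))``, raising on out-of-domain input."""
    return rf(L)


@dataclass(frozen=True)
class ModelParameters:
    """Physical constants of the nonlinear system.

    Units: diffusion in length^2/time, ``mu`` in length^2/(time*conc),
    ``k_L``/``k_M`` in 1/(time*conc), ``k_N`` in 1/time, ``L0`` in conc/time.
    """

    D_L: float
    D_M: float
    mu: float
    k_L: float
    k_M: float
    k_N: float
    L0: float
    response: ResponseFunction

    def __post_init__(self):
        for name in ("D_L", "D_M", "k_L", "k_M", "k_N", "L0"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {v}")
        if not (np.isfinite(self.mu) and self.mu >= 0):
            raise ValueError(f"mu must be nonnegative and finite, got {self.mu}")


@dataclass(frozen=True)
class Equilibrium:
    """Spatially homogeneous steady state ``(L_e, M_e, N_e)``."""

    L_e: float
    M_e: float
    N_e: float

    def __post_init__(self):
        if not all(np.isfinite(v) and v > 0 for v in (self.L_e, self.M_e, self.N_e)):
            raise ValueError("equilibrium concentrations must be strictly positive")


def homogeneous_rhs(params: ModelParameters, L, M, N):
    """Reaction/source right-hand sides with all spatial terms dropped."""
    fL, _ = params.response(L)
    dL = -params.k_L * L * M + params.L0
    dM = -params.k_M * L * M + fL
    dN = params.k_M * L * M - params.k_N * N
    return dL, dM, dN


def compute_equilibrium(params: ModelParameters) -> Equilibrium:
    """Solve ``f(L_e) = k_M*L0/k_L`` for the homogeneous steady state.

    ``M_e = L0/(k_L*L_e)`` and ``N_e = k_M*L0/(k_L*k_N)`` then follow.  The
    root is found by an expanding bracket from near zero followed by
    bisection; for the pinned family the pin point is used directly when it
    balances the influx, since the family exists precisely to place the
    equilibrium there.
    """
    target = params.k_M * params.L0 / params.k_L
    rf = params.response

    L_e = None
    if rf.family == "pinned":
        L_star = rf.parameters["L_star"]
        if L_star > 0:
            val, _ = rf(L_star)
            if abs(val - target) <= 1e-9 * max(1.0, abs(target)):
                L_e = L_star
    if L_e is None:
        L_e = _bracketed_root(rf, target)
    if L_e <= 0:
        raise EquilibriumNotFoundError(f"equilibrium root L_e = {L_e} is not positive")

    M_e = params.L0 / (params.k_L * L_e)
    N_e = params.k_M * params.L0 / (params.k_L * params.k_N)
    return Equilibrium(L_e, M_e, N_e)


def _bracketed_root(rf: ResponseFunction, target: float) -> float:
    lo_dom, hi_dom = rf.domain
    a = max(lo_dom, _BRACKET_LO)
    hi = min(hi_dom, _BRACKET_HI)
    if a >= hi:
        raise EquilibriumNotFoundError("response domain admits no positive concentration")

    def g(L):
        return rf(L)[0] - target

    ga = g(a)
    if ga == 0.0:
        return a
    b = a
    # geometric expansion; the first sign change is taken (monotonicity is
    # not assumed for the pinned family)
    while b < hi:
        b_next = min(b * 2.0 if b > 0 else _BRACKET_LO, hi)
        gb = g(b_next)
        if gb == 0.0:
            return b_next
        if np.sign(gb) != np.sign(ga):
            return float(bisect(g, b, b_next, xtol=1e-12))
        b = b_next
        ga = gb
        if b >= hi:
            break
    raise EquilibriumNotFoundError(
        f"no sign change of f(L) - {target:g} found in ({a:g}, {hi:g})"
    )


@dataclass(frozen=True)
class LinearCoefficients:
    """Constant coefficients of the system linearized about equilibrium.

    ``k1..k6`` couple the perturbations (a, b, c) of (L, M, N); ``chi_a`` is
    the linearized chemotactic coefficient and ``D_a``, ``D_b`` the
    diffusivities of a and b.  The algebraic identity
    ``k1*k4 - k2*k3 = k_L*L_e*f'(L_e)`` ties the spectral stability of the
    space-integrated system to the sign of the response slope.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    chi_a: float
    D_a: float
    D_b: float
    fprime_at_Le: float

    def __post_init__(self):
        vals = [self.k1, self.k2, self.k3, self.k4, self.k5, self.k6,
                self.chi_a, self.D_a, self.D_b, self.fprime_at_Le]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("linear coefficients must all be finite")
        if self.D_a <= 0 or self.D_b <= 0:
            raise ValueError("diffusivities D_a, D_b must be strictly positive")


def linearize(params: ModelParameters, eq: Equilibrium) -> LinearCoefficients:
    """First-order coefficients of the dynamics of perturbations about ``eq``."""
    _, fprime = params.response(eq.L_e)
    return LinearCoefficients(
        k1=params.k_L * eq.M_e,
        k2=params.k_L * eq.L_e,
        k3=params.k_M * eq.M_e - fprime,
        k4=params.k_M * eq.L_e,
        k5=params.k_N,
        k6=params.k_M * eq.M_e,
        chi_a=params.mu * eq.M_e,
        D_a=params.D_L,
        D_b=params.D_M,
        fprime_at_Le=fprime,
    )
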