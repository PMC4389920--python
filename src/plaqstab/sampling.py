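"""Seeded random model generators for property sweeps and validation runs.

Models are built around the pinned response family: the equilibrium LDL
level is placed at a chosen point and the response slope there is set
directly, which gives independent control over criterion 1 (slope sign)
and criterion 2 (chemotactic sensitivity relative to the diffusion bound).
"""

from __future__ import annotations

import numpy as np

from .model import ModelParameters, ResponseFunction

__all__ = ["sample_model", "reaction_time_scale"]


def sample_model(
    rng: np.random.Generator,
    slope_sign: int = 1,
    chemotaxis: str = "subcritical",
) -> ModelParameters:
    """Draw a random model with the pinned response family.

    ``slope_sign`` sets the sign of f'(L_e) (criterion 1).  ``chemotaxis``
    is ``"subcritical"`` (criterion 2 holds, margin 5-90%), ``"supercritical"``
    (criterion 2 violated by 5-40%) or ``"none"`` (mu = 0).
    """
    k_L, k_M, k_N, L0, D_L, D_M = np.exp(rng.uniform(np.log(0.3), np.log(3.0), size=6))
    L_star = rng.uniform(0.5, 2.0)
    target = k_M * L0 / k_L
    M_e = L0 / (k_L * L_star)
    if slope_sign > 0:
        slope = rng.uniform(0.05, 0.9) * k_M * M_e  # keeps k3 > 0 as well
    else:
        slope = -rng.uniform(0.1, 2.0) * k_M * M_e
    k2 = k_L * L_star
    k3 = k_M * M_e - slope
    if chemotaxis == "none":
        mu = 0.0
    else:
        if k3 <= 0:
            raise ValueError("chemotaxis margin needs k3 > 0")
        chi_max = np.sqrt(4.0 * D_M * D_L * k3 / k2)
        frac = rng.uniform(0.05, 0.9) if chemotaxis == "subcritical" else rng.uniform(1.05, 1.4)
        mu = frac * chi_max / M_e
    return ModelParameters(
        D_L=D_L, D_M=D_M, mu=mu, k_L=k_L, k_M=k_M, k_N=k_N, L0=L0,
        response=ResponseFunction.pinned(L_star=L_star, value=target, slope=slope),
    )


def reaction_time_scale(lc) -> float:
    """Slowest time scale of the space-integrated linear system, 1/|Re lambda|_min."""
    from .stability import spectral_analysis

    rep = spectral_analysis(lc)
    rates = [abs(lam.real) for lam in rep.eigenvalues if lam.real != 0]
    return 1.0 / min(rates) if rates else 1.0
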