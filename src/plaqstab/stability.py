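"""Stability criteria for the linearized system.

Two routes are implemented.  The spectral route integrates the linearized
equations over the domain (no-flux boundaries kill the spatial terms) and
asks whether the resulting 3x3 ODE system is stable: that happens exactly
when ``k1*k4 > k2*k3``, equivalently when the response slope at equilibrium
is positive.  The energy route constructs an explicit quadratic functional
``phi = 1/2 * int(x a^2 + y b^2 + z c^2)`` whose time derivative is bounded
by five bracketed coefficients; when all five are strictly negative the
functional — and hence every perturbation in L2 — decays exponentially.
Stability of the full PDE additionally requires the chemotaxis bound
``chi_a^2 < 4 D_b D_a k3 / k2``.

The certificate construction is fully explicit: the Cauchy weights are
``eps1 = k6/k5``, ``eps2 = k4/k5``, ``eps4 = eps5 = k1/(2 k2)``; the species
weights x, y, z and the gradient weight eps3 are picked inside the open
intervals the two criteria guarantee nonempty (geometric mean for ratio
intervals, half of the minimum upper bound for z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CertificateUnavailableError, InvalidCoefficientsError
from .model import LinearCoefficients

__all__ = [
    "SpectralReport",
    "EnergyCertificate",
    "StabilityReport",
    "spectral_analysis",
    "check_criteria",
    "construct_certificate",
    "verify_certificate",
    "reaction_matrix",
]

_SIGN_BAND = 1e-12


def reaction_matrix(lc: LinearCoefficients) -> np.ndarray:
    """Coefficient matrix of the space-integrated (homogeneous) linear system."""
    return np.array(
        [
            [-lc.k1, -lc.k2, 0.0],
            [-lc.k3, -lc.k4, 0.0],
            [lc.k6, lc.k4, -lc.k5],
        ]
    )


@dataclass(frozen=True)
class SpectralReport:
    jacobian: np.ndarray
    lambda1: complex
    lambda2: complex
    lambda3: complex
    stable: bool

    @property
    def eigenvalues(self) -> tuple[complex, complex, complex]:
        return (self.lambda1, self.lambda2, self.lambda3)


def spectral_analysis(lc: LinearCoefficients) -> SpectralReport:
    """Closed-form eigenvalues of the space-integrated linear system.

    ``lambda1 = -k5``; the remaining pair are the roots of
    ``lambda^2 + (k1+k4) lambda + (k1 k4 - k2 k3)``, written via the
    discriminant ``(k1-k4)^2 + 4 k2 k3``.  The discriminant is nonnegative
    whenever ``k2 k3 >= 0``; for ``k3 < 0`` a complex pair can occur and the
    stability flag uses real parts.  Stability is strict: every eigenvalue
    must have negative real part.
    """
    A = reaction_matrix(lc)
    lam1 = complex(-lc.k5)
    disc = (lc.k1 - lc.k4) ** 2 + 4.0 * lc.k2 * lc.k3
    root = np.sqrt(complex(disc))
    lam2 = (-(lc.k1 + lc.k4) - root) / 2.0
    lam3 = (-(lc.k1 + lc.k4) + root) / 2.0
    if disc >= 0:
        lam2, lam3 = complex(lam2.real), complex(lam3.real)
    stable = all(lam.real < 0 for lam in (lam1, lam2, lam3))
    return SpectralReport(jacobian=A, lambda1=lam1, lambda2=lam2, lambda3=lam3, stable=stable)


@dataclass(frozen=True)
class EnergyCertificate:
    """Constructive witness of exponential decay of the energy functional.

    ``coeff_a``, ``coeff_b``, ``coeff_c`` multiply the squared-perturbation
    integrals, ``coeff_grad_a``/``coeff_grad_b`` the squared-gradient
    integrals; all five must be strictly negative.  ``decay_rate_bound`` is
    the weight-normalized rate M with d(phi)/dt < -M*phi.
    """

    x: float
    y: float
    z: float
    eps1: float
    eps2: float
    eps3: float
    eps4: float
    eps5: float
    coeff_a: float
    coeff_b: float
    coeff_c: float
    coeff_grad_a: float
    coeff_grad_b: float
    decay_rate_bound: float

    def weights(self) -> tuple[float, ...]:
        return (self.x, self.y, self.z, self.eps1, self.eps2, self.eps3, self.eps4, self.eps5)


@dataclass(frozen=True)
class StabilityReport:
    criterion1: bool
    criterion2: bool
    ode_stable: bool
    spectral: SpectralReport
    certificate: EnergyCertificate | None


def _lemma_coefficients(lc: LinearCoefficients, x, y, z, eps1, eps2, eps3, eps4, eps5):
    """The five bracketed right-hand-side coefficients of the energy bound."""
    coeff_a = lc.k6 * eps1 * z + lc.k3 * eps4 * y + (lc.k2 * eps5 - lc.k1) * x
    coeff_b = lc.k4 * eps2 * z + (lc.k3 / (4.0 * eps4) - lc.k4) * y + lc.k2 / (4.0 * eps5) * x
    coeff_c = (lc.k6 / (4.0 * eps1) + lc.k4 / (4.0 * eps2) - lc.k5) * z
    coeff_grad_a = lc.chi_a * eps3 * y - lc.D_a * x
    coeff_grad_b = (lc.chi_a / (4.0 * eps3) - lc.D_b) * y
    return coeff_a, coeff_b, coeff_c, coeff_grad_a, coeff_grad_b


def check_criteria(lc: LinearCoefficients) -> StabilityReport:
    """Evaluate both sufficient stability criteria and attach a certificate.

    Criterion 1: ``f'(L_e) > 0`` (equivalent to spectral stability of the
    space-integrated system).  Criterion 2: ``chi_a^2 < 4 D_b D_a k3 / k2``
    (diffusion dominates chemotaxis).  Both inequalities are strict; ties
    are classified not stable.  A certificate is constructed exactly when
    both hold (which forces ``k3 > 0``).
    """
    if lc.k2 <= 0:
        raise InvalidCoefficientsError(f"k2 must be strictly positive, got {lc.k2}")
    spec = spectral_analysis(lc)
    criterion1 = lc.fprime_at_Le > 0
    criterion2 = lc.chi_a**2 < 4.0 * lc.D_b * lc.D_a * lc.k3 / lc.k2

    # sign(k1 k4 - k2 k3) = sign(f'(L_e)) for model-derived coefficients;
    # flag hand-built coefficient sets that break the identity.
    det = lc.k1 * lc.k4 - lc.k2 * lc.k3
    if abs(det) > _SIGN_BAND and abs(lc.fprime_at_Le) > _SIGN_BAND:
        if np.sign(det) != np.sign(lc.fprime_at_Le):
            raise InvalidCoefficientsError(
                "sign(k1*k4 - k2*k3) disagrees with sign(f'(L_e)); "
                "coefficients are inconsistent with any model linearization"
            )
    certificate = None
    if criterion1 and criterion2 and lc.k3 > 0:
        certificate = construct_certificate(lc)
    return StabilityReport(
        criterion1=criterion1,
        criterion2=criterion2,
        ode_stable=spec.stable,
        spectral=spec,
        certificate=certificate,
    )


def construct_certificate(lc: LinearCoefficients) -> EnergyCertificate:
    """Build the explicit energy certificate; raises when a criterion fails."""
    if lc.k2 <= 0 or lc.k1 <= 0 or lc.k4 <= 0 or lc.k5 <= 0 or lc.k6 <= 0:
        raise CertificateUnavailableError(
            "coefficients", "k1, k2, k4, k5, k6 must be strictly positive"
        )
    if lc.chi_a < 0:
        raise CertificateUnavailableError("coefficients", "chi_a must be nonnegative")
    if lc.k3 <= 0:
        raise CertificateUnavailableError(
            "criterion2", f"k3 = {lc.k3} <= 0: chemotaxis bound cannot hold"
        )
    if not (lc.k1 * lc.k4 > lc.k2 * lc.k3):
        raise CertificateUnavailableError(
            "criterion1", f"k1*k4 = {lc.k1 * lc.k4} <= k2*k3 = {lc.k2 * lc.k3}"
        )
    if not (lc.chi_a**2 < 4.0 * lc.D_b * lc.D_a * lc.k3 / lc.k2):
        raise CertificateUnavailableError(
            "criterion2",
            f"chi_a^2 = {lc.chi_a**2} >= 4*D_b*D_a*k3/k2 = "
            f"{4.0 * lc.D_b * lc.D_a * lc.k3 / lc.k2}",
        )

    eps1 = lc.k6 / lc.k5
    eps2 = lc.k4 / lc.k5
    eps4 = eps5 = lc.k1 / (2.0 * lc.k2)

    x = 1.0
    y_upper = (lc.k1 - lc.k2 * eps5) / (lc.k3 * eps4)
    y_lower = (lc.k2 / (4.0 * eps5)) / (lc.k4 - lc.k3 / (4.0 * eps4))
    y = float(np.sqrt(y_lower * y_upper))

    z_upper_a = ((lc.k1 - lc.k2 * eps5) * x - lc.k3 * eps4 * y) / (lc.k6 * eps1)
    z_upper_b = ((lc.k4 - lc.k3 / (4.0 * eps4)) * y - lc.k2 / (4.0 * eps5) * x) / (lc.k4 * eps2)
    z = 0.5 * min(z_upper_a, z_upper_b)

    if lc.chi_a > 0:
        eps3 = float(np.sqrt((lc.chi_a / (4.0 * lc.D_b)) * (lc.D_a * lc.k3 / (lc.chi_a * lc.k2))))
    else:
        eps3 = 1.0  # unused: both gradient coefficients lose their chi_a term

    coeffs = _lemma_coefficients(lc, x, y, z, eps1, eps2, eps3, eps4, eps5)
    if not all(c < 0 for c in coeffs):
        raise CertificateUnavailableError(
            "construction", f"a bracketed coefficient failed to be negative: {coeffs}"
        )
    decay = 2.0 * min(abs(coeffs[0]) / x, abs(coeffs[1]) / y, abs(coeffs[2]) / z)
    return EnergyCertificate(
        x=x, y=y, z=z,
        eps1=eps1, eps2=eps2, eps3=eps3, eps4=eps4, eps5=eps5,
        coeff_a=coeffs[0], coeff_b=coeffs[1], coeff_c=coeffs[2],
        coeff_grad_a=coeffs[3], coeff_grad_b=coeffs[4],
        decay_rate_bound=decay,
    )


def verify_certificate(cert: EnergyCertificate, lc: LinearCoefficients) -> bool:
    """Independently recheck a certificate: positive weights, negative coefficients."""
    if not all(np.isfinite(w) and w > 0 for w in cert.weights()):
        return False
    coeffs = _lemma_coefficients(
        lc, cert.x, cert.y, cert.z, cert.eps1, cert.eps2, cert.eps3, cert.eps4, cert.eps5
    )
    return bool(all(np.isfinite(c) and c < 0 for c in coeffs))
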