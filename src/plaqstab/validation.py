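"""Seeded end-to-end validation sweeps.

Each function recomputes one headline property of the package from scratch
— sampling models, running the relevant analysis or simulation, and
measuring the result against an independent oracle (numeric eigensolver,
stand-alone ODE solve, analytic geometry).  They are deterministic given
their seed and are shared by the acceptance test suite and the acceptance
report script.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .diagnostics import PerturbationSpec, check_decay_bound, run_experiment
from .discretization import StateField, integrate
from .geometry import BipolarGrid, annulus_area, area_weights, make_grid
from .model import compute_equilibrium, homogeneous_rhs, linearize
from .sampling import reaction_time_scale, sample_model
from .stability import (
    construct_certificate,
    reaction_matrix,
    spectral_analysis,
    verify_certificate,
)

__all__ = [
    "equilibrium_residual_sweep",
    "theorem2_sweep",
    "certificate_sweep",
    "dichotomy_sweep",
    "homogeneous_reduction_check",
    "laplacian_convergence_order",
    "quadrature_area_error",
    "sufficiency_probe",
    "default_grid",
]

SIGN_BAND = 1e-12


def default_grid(mn: int = 24) -> BipolarGrid:
    return make_grid(1.0, 2.0, mn, mn, 1.0)


def equilibrium_residual_sweep(seed: int, n: int = 200) -> float:
    """Largest homogeneous residual at the computed equilibrium over n models."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for k in range(n):
        params = sample_model(rng, slope_sign=1 if k % 2 == 0 else -1)
        eq = compute_equilibrium(params)
        res = homogeneous_rhs(params, eq.L_e, eq.M_e, eq.N_e)
        worst = max(worst, max(abs(r) for r in res))
    return worst


def theorem2_sweep(seed: int, n: int = 1000) -> dict:
    """Spectral-criterion equivalence and closed-form eigenvalue accuracy.

    Checks, per sampled model, that (k1 k4 > k2 k3), negativity of every
    numerically computed eigenvalue, and sign(f'(L_e)) > 0 all agree, and
    records the worst relative deviation between the closed-form and
    numeric eigenvalues.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    considered = 0
    max_dev = 0.0
    for k in range(n):
        params = sample_model(rng, slope_sign=1 if k % 2 == 0 else -1)
        eq = compute_equilibrium(params)
        lc = linearize(params, eq)
        rep = spectral_analysis(lc)
        numeric = np.sort(np.linalg.eigvals(reaction_matrix(lc)).real)
        closed = np.sort([lam.real for lam in rep.eigenvalues])
        scale = max(np.abs(numeric).max(), 1.0)
        max_dev = max(max_dev, float(np.abs(closed - numeric).max() / scale))
        det = lc.k1 * lc.k4 - lc.k2 * lc.k3
        if abs(det) <= SIGN_BAND or abs(lc.fprime_at_Le) <= SIGN_BAND:
            continue  # equality band excluded
        considered += 1
        if (det > 0) == bool(numeric.max() < 0) == (lc.fprime_at_Le > 0):
            agree += 1
    return {
        "n": n,
        "n_considered": considered,
        "agreement_fraction": agree / considered if considered else float("nan"),
        "max_eig_relative_deviation": max_dev,
    }


def certificate_sweep(
    seed: int,
    n: int = 500,
    grid: BipolarGrid | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-12,
) -> dict:
    """Certificate existence + soundness on simulation for n admissible models.

    Every sampled model satisfies both criteria by construction; for each,
    the certificate is built, independently verified, and its decay bound
    checked against a linearized simulation of a seeded random perturbation.
    """
    grid = grid if grid is not None else default_grid()
    rng = np.random.default_rng(seed)
    n_constructed = n_verified = n_decay_ok = 0
    for k in range(n):
        params = sample_model(rng, slope_sign=1, chemotaxis="subcritical")
        eq = compute_equilibrium(params)
        lc = linearize(params, eq)
        cert = construct_certificate(lc)
        n_constructed += 1
        if verify_certificate(cert, lc):
            n_verified += 1
        t_end = 1.5 / cert.decay_rate_bound
        spec = PerturbationSpec(amplitude=0.01, pattern="random", seed=int(rng.integers(2**31)))
        series = run_experiment(
            lc, spec, t_end, grid, "linearized",
            cert=cert, n_outputs=6, rtol=rtol, atol=atol,
        )
        if check_decay_bound(series, cert):
            n_decay_ok += 1
    return {
        "n": n,
        "n_constructed": n_constructed,
        "n_verified": n_verified,
        "n_decay_ok": n_decay_ok,
    }


def dichotomy_sweep(
    seed: int,
    n_per_side: int = 20,
    grid: BipolarGrid | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-12,
) -> dict:
    """Stability dichotomy: positive-slope runs decay, negative-slope runs grow."""
    grid = grid if grid is not None else default_grid()
    rng = np.random.default_rng(seed)
    stable_ok = unstable_ok = 0
    for side in (1, -1):
        for _ in range(n_per_side):
            params = sample_model(rng, slope_sign=side, chemotaxis="subcritical")
            eq = compute_equilibrium(params)
            lc = linearize(params, eq)
            spec = PerturbationSpec(
                amplitude=0.01, pattern="random", seed=int(rng.integers(2**31))
            )
            if side > 0:
                t_end = 5.0 * reaction_time_scale(lc)
            else:
                # long horizon: the unstable-mode projection of a random
                # perturbation can be ~1e-4 of I(0), and stable modes decay
                # first, so growth must make up several orders of magnitude
                lam_plus = max(l.real for l in spectral_analysis(lc).eigenvalues)
                t_end = 12.0 / lam_plus
            series = run_experiment(
                lc, spec, t_end, grid, "linearized",
                n_outputs=17, rtol=rtol, atol=atol,
            )
            if side > 0 and series.classification == "stable":
                stable_ok += 1
            if side < 0 and series.classification == "unstable":
                unstable_ok += 1
    return {"n_per_side": n_per_side, "stable_ok": stable_ok, "unstable_ok": unstable_ok}


def homogeneous_reduction_check(seed: int, mn: int = 12, t_end: float = 5.0) -> float:
    """Max deviation between a uniform-data PDE run and a stand-alone ODE solve."""
    rng = np.random.default_rng(seed)
    params = sample_model(rng, slope_sign=1)
    eq = compute_equilibrium(params)
    grid = make_grid(1.0, 2.0, mn, mn, 1.0)
    y0 = (1.3 * eq.L_e, 0.8 * eq.M_e, 1.1 * eq.N_e)
    times = np.linspace(0.0, t_end, 6)
    traj = integrate(
        StateField.uniform(grid, y0, "nonlinear"), params, t_end, times,
        rtol=1e-8, atol=1e-10,
    )
    ode = solve_ivp(
        lambda t, y: homogeneous_rhs(params, *y), (0.0, t_end), y0,
        t_eval=times, rtol=1e-10, atol=1e-12,
    )
    dev = 0.0
    for k in range(len(times)):
        pde = np.array([traj[k].L.mean(), traj[k].M.mean(), traj[k].N.mean()])
        dev = max(dev, float(np.abs(pde - ode.y[:, k]).max()))
    return dev


def laplacian_convergence_order(resolutions=(32, 64, 128)) -> tuple[float, float]:
    """Observed order range of the interior Laplacian on a smooth manufactured field."""
    from .discretization import laplacian

    errs = []
    for mn in resolutions:
        g = make_grid(1.0, 2.0, mn, mn, 1.0)
        f = np.sin(g.tau_values)[:, None] * np.cos(g.sigma_values)[None, :]
        exact = -2.0 * f / g.h**2
        errs.append(np.abs(laplacian(f, g) - exact)[1:-1].max())
    orders = [np.log2(errs[i] / errs[i + 1]) for i in range(len(errs) - 1)]
    return float(min(orders)), float(max(orders))


def quadrature_area_error(mn: int = 200) -> float:
    """Relative error of the metric quadrature against the analytic annulus area."""
    g = make_grid(1.0, 2.0, mn, mn, 1.0)
    exact = annulus_area(1.0, 2.0, 1.0)
    return float(abs(area_weights(g).sum() - exact) / exact)


def sufficiency_probe(
    seed: int,
    n: int = 6,
    grid: BipolarGrid | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-12,
) -> dict:
    """Criterion 2 is sufficient, not necessary: supercritical chemotaxis with a
    positive slope can still simulate stable.  Returns the count of stable runs."""
    grid = grid if grid is not None else default_grid()
    rng = np.random.default_rng(seed)
    n_stable = 0
    for _ in range(n):
        params = sample_model(rng, slope_sign=1, chemotaxis="supercritical")
        eq = compute_equilibrium(params)
        lc = linearize(params, eq)
        assert lc.chi_a**2 >= 4.0 * lc.D_b * lc.D_a * lc.k3 / lc.k2
        spec = PerturbationSpec(
            amplitude=0.01, pattern="random", seed=int(rng.integers(2**31))
        )
        series = run_experiment(
            lc, spec, 5.0 * reaction_time_scale(lc), grid, "linearized",
            n_outputs=17, rtol=rtol, atol=atol,
        )
        if series.classification == "stable":
            n_stable += 1
    return {"n": n, "n_stable": n_stable}
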