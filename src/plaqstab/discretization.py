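"""Method-of-lines spatial discretization on the bipolar annulus grid.

Interior points use the standard 5-point stencil written in bipolar
coordinates: the Laplacian is ``(1/h^2)(d^2/dtau^2 + d^2/dsigma^2)`` with
centered second differences, periodic in sigma.  At the two tau boundaries
the time derivative is reconstructed from flux components: the tau-flux F
vanishes on the boundary row itself (no-flux), and the divergence is
approximated with the one-sided 3-point formula ``(-3F1 + 4F2 - F3)/(2
dtau)`` (mirrored at the last row) plus a centered sigma-difference of G,
all scaled by ``1/h`` ("faithful" mode).  The geometrically exact
curvilinear divergence ``(1/h^2)(d(hF)/dtau + d(hG)/dsigma)`` is available
behind ``divergence="curvilinear"``.

F and G are full flux components: diffusive ``D * grad`` plus, for the
macrophage species, the chemotactic ``-mu M grad L`` (linearized:
``-chi_a grad a``), so that F = 0 encodes zero *total* normal flux.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.sparse.linalg import expm_multiply

from .errors import ConfigurationError, SolverError
from .geometry import BipolarGrid
from .model import LinearCoefficients, ModelParameters

logger = logging.getLogger(__name__)

__all__ = [
    "StateField",
    "Trajectory",
    "laplacian",
    "gradient_dot",
    "rhs_nonlinear",
    "rhs_linearized",
    "boundary_rhs",
    "integrate",
    "diffusion_operator_matrix",
    "linear_operator",
]

_NEG_TOL = -1e-8


@dataclass
class StateField:
    """Concentrations (nonlinear mode) or perturbations (linearized mode) on a grid."""

    grid: BipolarGrid
    mode: str  # "nonlinear" | "linearized"
    L: np.ndarray
    M: np.ndarray
    N: np.ndarray

    def __post_init__(self):
        if self.mode not in ("nonlinear", "linearized"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        for name in ("L", "M", "N"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ConfigurationError(
                    f"field {name} has shape {arr.shape}, grid is {self.grid.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ConfigurationError(f"field {name} contains non-finite values")
            object.__setattr__(self, name, arr)

    # perturbation aliases
    @property
    def a(self) -> np.ndarray:
        return self.L

    @property
    def b(self) -> np.ndarray:
        return self.M

    @property
    def c(self) -> np.ndarray:
        return self.N

    @classmethod
    def uniform(cls, grid: BipolarGrid, values: Sequence[float], mode: str) -> "StateField":
        vL, vM, vN = values
        full = np.full(grid.shape, float(vL)), np.full(grid.shape, float(vM)), np.full(
            grid.shape, float(vN)
        )
        return cls(grid=grid, mode=mode, L=full[0], M=full[1], N=full[2])

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.L.ravel(), self.M.ravel(), self.N.ravel()])

    @classmethod
    def from_vector(cls, v: np.ndarray, grid: BipolarGrid, mode: str) -> "StateField":
        mn = grid.m * grid.n
        return cls(
            grid=grid,
            mode=mode,
            L=v[:mn].reshape(grid.shape),
            M=v[mn : 2 * mn].reshape(grid.shape),
            N=v[2 * mn :].reshape(grid.shape),
        )


@dataclass
class Trajectory:
    times: np.ndarray
    states: list[StateField]

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i: int) -> StateField:
        return self.states[i]


# ---------------------------------------------------------------------------
# stencils
# ---------------------------------------------------------------------------

def _check_shape(f: np.ndarray, grid: BipolarGrid) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.shape != grid.shape:
        raise ConfigurationError(f"field shape {f.shape} does not match grid {grid.shape}")
    return f


def laplacian(f: np.ndarray, grid: BipolarGrid) -> np.ndarray:
    """5-point bipolar Laplacian on interior tau rows; boundary rows left zero."""
    f = _check_shape(f, grid)
    out = np.zeros_like(f)
    d2t = (f[2:, :] - 2.0 * f[1:-1, :] + f[:-2, :]) / grid.dtau**2
    d2s = (np.roll(f, -1, axis=1) - 2.0 * f + np.roll(f, 1, axis=1)) / grid.dsigma**2
    out[1:-1, :] = (d2t + d2s[1:-1, :]) / grid.h[1:-1, :] ** 2
    return out


def gradient_dot(fa: np.ndarray, fb: np.ndarray, grid: BipolarGrid) -> np.ndarray:
    """Dot product of the two fields' gradients on interior rows (zero on boundary rows)."""
    fa = _check_shape(fa, grid)
    fb = _check_shape(fb, grid)
    out = np.zeros(grid.shape)
    dat = (fa[2:, :] - fa[:-2, :]) / (2.0 * grid.dtau)
    dbt = (fb[2:, :] - fb[:-2, :]) / (2.0 * grid.dtau)
    das = (np.roll(fa, -1, axis=1) - np.roll(fa, 1, axis=1)) / (2.0 * grid.dsigma)
    dbs = (np.roll(fb, -1, axis=1) - np.roll(fb, 1, axis=1)) / (2.0 * grid.dsigma)
    out[1:-1, :] = (dat * dbt + das[1:-1, :] * dbs[1:-1, :]) / grid.h[1:-1, :] ** 2
    return out


def _grad_tau(f: np.ndarray, grid: BipolarGrid) -> np.ndarray:
    """Physical tau-gradient component (1/h) df/dtau, centered; zero on boundary rows."""
    out = np.zeros(grid.shape)
    out[1:-1, :] = (f[2:, :] - f[:-2, :]) / (2.0 * grid.dtau * grid.h[1:-1, :])
    return out


def _grad_sigma(f: np.ndarray, grid: BipolarGrid) -> np.ndarray:
    """Physical sigma-gradient component (1/h) df/dsigma, centered and periodic."""
    return (np.roll(f, -1, axis=1) - np.roll(f, 1, axis=1)) / (2.0 * grid.dsigma * grid.h)


def _boundary_divergence(F, G, grid: BipolarGrid, divergence: str):
    """One-sided divergence of the flux (F, G) at the first and last tau rows.

    F is zero on the boundary rows themselves (no-flux).  Returns the two
    rows (first, last), each of length n.
    """
    two_dt = 2.0 * grid.dtau
    two_ds = 2.0 * grid.dsigma
    if divergence == "faithful":
        dF0 = (-3.0 * F[0] + 4.0 * F[1] - F[2]) / two_dt
        dFm = (3.0 * F[-1] - 4.0 * F[-2] + F[-3]) / two_dt
        dG0 = (np.roll(G[0], -1) - np.roll(G[0], 1)) / two_ds
        dGm = (np.roll(G[-1], -1) - np.roll(G[-1], 1)) / two_ds
        return (dF0 + dG0) / grid.h[0], (dFm + dGm) / grid.h[-1]
    elif divergence == "curvilinear":
        hF = grid.h * F
        hG = grid.h * G
        dF0 = (-3.0 * hF[0] + 4.0 * hF[1] - hF[2]) / two_dt
        dFm = (3.0 * hF[-1] - 4.0 * hF[-2] + hF[-3]) / two_dt
        dG0 = (np.roll(hG[0], -1) - np.roll(hG[0], 1)) / two_ds
        dGm = (np.roll(hG[-1], -1) - np.roll(hG[-1], 1)) / two_ds
        return (dF0 + dG0) / grid.h[0] ** 2, (dFm + dGm) / grid.h[-1] ** 2
    raise ConfigurationError(f"unknown divergence mode {divergence!r}")


def _apply_diffusion(f: np.ndarray, grid: BipolarGrid, divergence: str) -> np.ndarray:
    """Unit-diffusivity spatial operator: interior Laplacian plus flux-form boundary rows."""
    out = laplacian(f, grid)
    F = _grad_tau(f, grid)
    G = _grad_sigma(f, grid)
    r0, rm = _boundary_divergence(F, G, grid, divergence)
    out[0] = r0
    out[-1] = rm
    return out


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------

def rhs_nonlinear(
    state: StateField, params: ModelParameters, divergence: str = "faithful"
) -> StateField:
    """Time derivative of the full nonlinear system at the given state."""
    if state.mode != "nonlinear":
        raise ConfigurationError("rhs_nonlinear requires a nonlinear-mode state")
    grid = state.grid
    L, M, N = state.L, state.M, state.N
    low = min(L.min(), M.min(), N.min())
    if low < _NEG_TOL:
        logger.warning("negative concentration %.3e encountered during evaluation", low)

    fL, _ = params.response(L)
    reactL = -params.k_L * L * M + params.L0
    reactM = -params.k_M * L * M + fL
    dN = params.k_M * L * M - params.k_N * N  # pointwise everywhere

    dL = reactL + params.D_L * laplacian(L, grid)
    dM = (
        reactM
        + params.D_M * laplacian(M, grid)
        - params.mu * gradient_dot(M, L, grid)
        - params.mu * M * laplacian(L, grid)
    )

    # boundary rows via flux divergence (total flux: diffusive + chemotactic)
    gtL, gsL = _grad_tau(L, grid), _grad_sigma(L, grid)
    gtM, gsM = _grad_tau(M, grid), _grad_sigma(M, grid)
    FL, GL = params.D_L * gtL, params.D_L * gsL
    FM = params.D_M * gtM - params.mu * M * gtL
    GM = params.D_M * gsM - params.mu * M * gsL
    r0, rm = _boundary_divergence(FL, GL, grid, divergence)
    dL[0], dL[-1] = r0 + reactL[0], rm + reactL[-1]
    r0, rm = _boundary_divergence(FM, GM, grid, divergence)
    dM[0], dM[-1] = r0 + reactM[0], rm + reactM[-1]

    return StateField(grid=grid, mode="nonlinear", L=dL, M=dM, N=dN)


def rhs_linearized(
    state: StateField, lc: LinearCoefficients, divergence: str = "faithful"
) -> StateField:
    """Time derivative of the linearized perturbation system at the given state."""
    if state.mode != "linearized":
        raise ConfigurationError("rhs_linearized requires a linearized-mode state")
    grid = state.grid
    a, b, c = state.a, state.b, state.c
    Pa = _apply_diffusion(a, grid, divergence)
    Pb = _apply_diffusion(b, grid, divergence)
    da = lc.D_a * Pa - lc.k1 * a - lc.k2 * b
    db = lc.D_b * Pb - lc.chi_a * Pa - lc.k3 * a - lc.k4 * b
    dc = lc.k6 * a + lc.k4 * b - lc.k5 * c
    return StateField(grid=grid, mode="linearized", L=da, M=db, N=dc)


def boundary_rhs(
    state: StateField,
    model: Union[ModelParameters, LinearCoefficients],
    divergence: str = "faithful",
):
    """Boundary (first/last tau) rows of the derivative, per species.

    Returns three (2, n) arrays for the species in state order.
    """
    if state.mode == "nonlinear":
        d = rhs_nonlinear(state, model, divergence)
    else:
        d = rhs_linearized(state, model, divergence)
    pick = lambda arr: np.stack([arr[0], arr[-1]])
    return pick(d.L), pick(d.M), pick(d.N)


# ---------------------------------------------------------------------------
# sparse operators
# ---------------------------------------------------------------------------

_P_CACHE: dict[tuple, sparse.csr_matrix] = {}


def diffusion_operator_matrix(grid: BipolarGrid, divergence: str = "faithful") -> sparse.csr_matrix:
    """Sparse matrix of the unit-diffusivity spatial operator (probed columnwise, cached)."""
    key = (grid.cache_key(), divergence)
    if key in _P_CACHE:
        return _P_CACHE[key]
    mn = grid.m * grid.n
    rows, cols, data = [], [], []
    e = np.zeros(grid.shape)
    flat = e.ravel()
    for k in range(mn):
        flat[k] = 1.0
        col = _apply_diffusion(e, grid, divergence).ravel()
        nz = np.nonzero(col)[0]
        rows.append(nz)
        cols.append(np.full(nz.size, k))
        data.append(col[nz])
        flat[k] = 0.0
    P = sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))), shape=(mn, mn)
    )
    _P_CACHE[key] = P
    return P


def linear_operator(
    lc: LinearCoefficients, grid: BipolarGrid, divergence: str = "faithful"
) -> sparse.csc_matrix:
    """Full sparse operator of the linearized semi-discrete system (3mn x 3mn)."""
    P = diffusion_operator_matrix(grid, divergence)
    mn = grid.m * grid.n
    I = sparse.identity(mn, format="csr")
    A = sparse.bmat(
        [
            [lc.D_a * P - lc.k1 * I, -lc.k2 * I, None],
            [-lc.chi_a * P - lc.k3 * I, lc.D_b * P - lc.k4 * I, None],
            [lc.k6 * I, lc.k4 * I, -lc.k5 * I],
        ],
        format="csc",
    )
    return A


def _jacobian_sparsity(grid: BipolarGrid, divergence: str) -> sparse.csr_matrix:
    P = diffusion_operator_matrix(grid, divergence)
    mn = grid.m * grid.n
    Q = (abs(P) + sparse.identity(mn, format="csr")).sign()
    return sparse.bmat([[Q, Q, None], [Q, Q, None], [Q, Q, Q]], format="csr")


# ---------------------------------------------------------------------------
# time integration
# ---------------------------------------------------------------------------

def integrate(
    state0: StateField,
    model: Union[ModelParameters, LinearCoefficients],
    t_end: float,
    output_times: Sequence[float] | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
    divergence: str = "faithful",
) -> Trajectory:
    """Integrate the semi-discrete system; deterministic given its inputs.

    ``method`` is any stiff-capable solve_ivp method ("BDF", "Radau",
    "LSODA"), or "expm" for exact matrix-exponential stepping, valid only in
    linearized mode.  In linearized mode the (constant, sparse) operator is
    supplied to the implicit solver as the exact Jacobian.
    """
    if not (np.isfinite(t_end) and t_end > 0):
        raise ConfigurationError(f"t_end must be positive, got {t_end}")
    if output_times is None:
        output_times = np.linspace(0.0, t_end, 11)
    output_times = np.asarray(output_times, dtype=float)
    if output_times.ndim != 1 or np.any(output_times < 0) or np.any(output_times > t_end):
        raise ConfigurationError("output_times must lie within [0, t_end]")
    grid = state0.grid
    mode = state0.mode
    if mode == "nonlinear" and min(state0.L.min(), state0.M.min(), state0.N.min()) < _NEG_TOL:
        raise ConfigurationError("nonlinear mode requires nonnegative initial concentrations")
    y0 = state0.to_vector()

    if mode == "linearized":
        A = linear_operator(model, grid, divergence)
        if method == "expm":
            times, ys = _expm_trajectory(A, y0, output_times)
            states = [StateField.from_vector(y, grid, mode) for y in ys]
            return Trajectory(times=np.asarray(times), states=states)
        fun = lambda t, y: A.dot(y)
        kwargs = {"jac": A} if method in ("BDF", "Radau") else {}
        sol = solve_ivp(
            fun, (0.0, t_end), y0, method=method, t_eval=output_times,
            rtol=rtol, atol=atol, **kwargs,
        )
    else:
        if method == "expm":
            raise ConfigurationError("expm stepping is only available in linearized mode")

        def fun(t, y):
            st = StateField.from_vector(y, grid, mode)
            return rhs_nonlinear(st, model, divergence).to_vector()

        sol = solve_ivp(
            fun, (0.0, t_end), y0, method=method, t_eval=output_times,
            rtol=rtol, atol=atol, jac_sparsity=_jacobian_sparsity(grid, divergence),
        )
    if not sol.success:
        raise SolverError(f"time integration failed: {sol.message}")
    states = [StateField.from_vector(sol.y[:, k], grid, mode) for k in range(sol.y.shape[1])]
    return Trajectory(times=sol.t, states=states)


def _expm_trajectory(A, y0, output_times):
    ys = []
    v = y0.copy()
    t_prev = 0.0
    for t in output_times:
        dt = t - t_prev
        if dt > 0:
            v = expm_multiply(A * dt, v)
        elif dt < 0:
            raise ConfigurationError("output_times must be nondecreasing for expm stepping")
        ys.append(v.copy())
        t_prev = t
    return list(output_times), ys
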