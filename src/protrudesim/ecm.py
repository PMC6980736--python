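"""Non-inertial SPH representation of the degradable viscoelastic matrix.

The matrix is a 2D continuum discretised into material points carrying
mass, density, an in-plane stress tensor and a degradation factor
``f_degr`` in [0, 1] (1 = intact solid, 0 = fully fluidised).  Because the
cell operates at vanishing Reynolds number the momentum balance is
overdamped: a pairwise Monaghan-type viscous operator applied to the
velocities equals the divergence of the (effective) stress plus body
forces, and velocities are obtained from a sparse linear solve instead of
time integration of momentum.

Stress follows a small-strain hypoelastic plane-stress law with a Jaumann
spin correction; degraded material blends towards a weakly compressible
fluid that carries pressure only.  Density is evaluated by kernel
summation, and density, stress and positions are advanced with explicit
Euler steps.

Stresses, elastic moduli and viscosities are in model units
(nN/um^2 = kPa, see :mod:`protrudesim.units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg, spsolve
from scipy.spatial import cKDTree

from .kernel import KernelSpec, wendland_kernel

__all__ = [
    "FLUID_THRESHOLD",
    "EcmMaterial",
    "EcmDomain",
    "initialize_ecm_disk",
    "initialize_ecm_block",
    "carve_hole",
    "compute_pairs",
    "PairTable",
    "compute_density",
    "velocity_gradients",
    "update_stress",
    "hydrostatic_pressure",
    "effective_stress",
    "internal_forces",
    "solve_ecm_velocities",
    "apply_degradation",
]

#: particles with f_degr below this value are classified as fully degraded
#: (fluid): they carry no solid stress and pass freely through the cell.
FLUID_THRESHOLD = 0.05


@dataclass
class EcmMaterial:
    """Constitutive parameters of the matrix, in model units.

    Parameters
    ----------
    E : float
        Young's modulus (nN/um^2; 1 Pa = 1e-3).
    nu : float
        Poisson's ratio, in [0, 0.5).
    mu : float
        Dynamic viscosity (nN*s/um^2).
    rho0 : float
        Rest density (model units / um^2).
    K_fluid : float
        Bulk stiffness of the fluidised fraction (nN/um^2); the fluid
        pressure is ``K_fluid * (rho/rho0 - 1)``.
    """

    E: float
    nu: float
    mu: float
    rho0: float = 1.0
    K_fluid: float = 2.0

    def __post_init__(self) -> None:
        if self.E < 0:
            raise ValueError("Young's modulus must be non-negative")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError("Poisson's ratio must lie in [0, 0.5)")
        if self.mu < 0:
            raise ValueError("viscosity must be non-negative")
        if self.rho0 <= 0:
            raise ValueError("rest density must be positive")


@dataclass
class EcmDomain:
    """Struct-of-arrays container for the SPH particle set."""

    kernel: KernelSpec
    material: EcmMaterial
    dp: float
    x: np.ndarray                 # (N, 2) positions, um
    x0: np.ndarray                # (N, 2) initial positions
    fixed: np.ndarray             # (N,) bool, Dirichlet (zero-velocity)
    radius: float | None = None
    v: np.ndarray = field(default=None)          # (N, 2) um/s
    m: np.ndarray = field(default=None)          # (N,)
    rho: np.ndarray = field(default=None)        # (N,)
    sigma: np.ndarray = field(default=None)      # (N, 3) Voigt [xx, yy, xy]
    f_degr: np.ndarray = field(default=None)     # (N,)
    f_body: np.ndarray = field(default=None)     # (N, 2) accumulated nN
    fixed_x: np.ndarray = field(default=None)    # per-component Dirichlet
    fixed_y: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.x)
        if self.v is None:
            self.v = np.zeros((n, 2))
        if self.m is None:
            self.m = np.full(n, self.material.rho0 * self.dp**2)
        if self.rho is None:
            self.rho = np.full(n, self.material.rho0)
        if self.sigma is None:
            self.sigma = np.zeros((n, 3))
        if self.f_degr is None:
            self.f_degr = np.ones(n)
        if self.f_body is None:
            self.f_body = np.zeros((n, 2))
        if self.fixed_x is None:
            self.fixed_x = self.fixed.copy()
        if self.fixed_y is None:
            self.fixed_y = self.fixed.copy()

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def solid(self) -> np.ndarray:
        """Boolean mask of particles still behaving as solid matrix."""
        return self.f_degr >= FLUID_THRESHOLD

    def tree(self) -> cKDTree:
        return cKDTree(self.x)


def _lattice(radius: float, dp: float) -> np.ndarray:
    k = int(np.floor(radius / dp))
    ax = np.arange(-k, k + 1) * dp
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def initialize_ecm_disk(
    radius: float,
    dp: float,
    material: EcmMaterial,
    kernel: KernelSpec | None = None,
    boundary_band: float | None = None,
    center=(0.0, 0.0),
) -> EcmDomain:
    """Build a circular matrix domain on a regular square lattice.

    Lattice points within ``radius`` of the centre are kept; particles
    within ``boundary_band`` (default: one kernel support) of the rim are
    flagged fixed, giving a zero-displacement boundary condition.
    """
    if radius <= 2 * dp:
        raise ValueError("domain radius must exceed 2*dp")
    if kernel is None:
        kernel = KernelSpec(h=1.3 * dp)
    if boundary_band is None:
        boundary_band = kernel.support_radius
    pts = _lattice(radius, dp) + np.asarray(center, dtype=float)
    r = np.linalg.norm(pts - center, axis=1)
    keep = r <= radius
    pts = pts[keep]
    fixed = np.linalg.norm(pts - center, axis=1) > radius - boundary_band
    return EcmDomain(
        kernel=kernel,
        material=material,
        dp=dp,
        x=pts.copy(),
        x0=pts.copy(),
        fixed=fixed,
        radius=radius,
    )


def initialize_ecm_block(
    lx: float,
    ly: float,
    dp: float,
    material: EcmMaterial,
    kernel: KernelSpec | None = None,
) -> EcmDomain:
    """Rectangular lattice block (no fixed particles); used by the
    quasi-static stretch harnesses, which set their own Dirichlet masks."""
    if kernel is None:
        kernel = KernelSpec(h=1.3 * dp)
    nx = int(round(lx / dp)) + 1
    ny = int(round(ly / dp)) + 1
    ax = np.arange(nx) * dp
    ay = np.arange(ny) * dp
    gx, gy = np.meshgrid(ax, ay, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    fixed = np.zeros(len(pts), dtype=bool)
    return EcmDomain(
        kernel=kernel, material=material, dp=dp,
        x=pts.copy(), x0=pts.copy(), fixed=fixed,
    )


def carve_hole(domain: EcmDomain, center, radius: float) -> EcmDomain:
    """Return a copy of the domain with particles inside a disk removed
    (used to embed the cell without overlapping solid matrix)."""
    keep = np.linalg.norm(domain.x - np.asarray(center), axis=1) > radius
    return EcmDomain(
        kernel=domain.kernel,
        material=domain.material,
        dp=domain.dp,
        x=domain.x[keep].copy(),
        x0=domain.x0[keep].copy(),
        fixed=domain.fixed[keep].copy(),
        radius=domain.radius,
        v=domain.v[keep].copy(),
        m=domain.m[keep].copy(),
        rho=domain.rho[keep].copy(),
        sigma=domain.sigma[keep].copy(),
        f_degr=domain.f_degr[keep].copy(),
        f_body=domain.f_body[keep].copy(),
        fixed_x=domain.fixed_x[keep].copy(),
        fixed_y=domain.fixed_y[keep].copy(),
    )


@dataclass
class PairTable:
    """Interacting particle pairs (i < j) within kernel support, with
    cached geometry evaluated at the positions used to build it."""

    i: np.ndarray
    j: np.ndarray
    dx: np.ndarray       # x_i - x_j
    r: np.ndarray
    w: np.ndarray
    dw_dr: np.ndarray

    @property
    def grad_i(self) -> np.ndarray:
        """grad_i W_ij = dW/dr * (x_i - x_j)/r  (antisymmetric in i<->j)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            g = (self.dw_dr / np.maximum(self.r, 1e-12))[:, None] * self.dx
        return g


def compute_pairs(domain: EcmDomain, positions: np.ndarray | None = None) -> PairTable:
    x = domain.x if positions is None else positions
    tree = cKDTree(x)
    pairs = tree.query_pairs(domain.kernel.support_radius, output_type="ndarray")
    if len(pairs) == 0:
        pairs = np.empty((0, 2), dtype=int)
    i, j = pairs[:, 0], pairs[:, 1]
    dx = x[i] - x[j]
    r = np.linalg.norm(dx, axis=1)
    w, dw = wendland_kernel(r, domain.kernel)
    return PairTable(i=i, j=j, dx=dx, r=r, w=np.atleast_1d(w), dw_dr=np.atleast_1d(dw))


def refresh_pairs(domain: EcmDomain, table: PairTable) -> PairTable:
    """Re-evaluate the geometry of an existing pair list at the current
    positions (cheap; pair membership is refreshed only when particles
    have moved more than the neighbour-list skin)."""
    dx = domain.x[table.i] - domain.x[table.j]
    r = np.linalg.norm(dx, axis=1)
    w, dw = wendland_kernel(r, domain.kernel)
    return PairTable(i=table.i, j=table.j, dx=dx, r=r,
                     w=np.atleast_1d(w), dw_dr=np.atleast_1d(dw))


def compute_density(domain: EcmDomain, pairs: PairTable | None = None) -> np.ndarray:
    """Summation density rho_i = sum_j m_j W_ij, self term included."""
    if pairs is None:
        pairs = compute_pairs(domain)
    n = domain.n
    rho = domain.m * domain.kernel.w0
    rho += np.bincount(pairs.i, weights=domain.m[pairs.j] * pairs.w, minlength=n)
    rho += np.bincount(pairs.j, weights=domain.m[pairs.i] * pairs.w, minlength=n)
    return rho


def velocity_gradients(
    domain: EcmDomain, pairs: PairTable, v: np.ndarray | None = None
) -> np.ndarray:
    """Per-particle velocity gradient L_i = sum_j V_j (v_j - v_i) x grad_i W_ij."""
    if v is None:
        v = domain.v
    n = domain.n
    g = pairs.grad_i
    vij = v[pairs.j] - v[pairs.i]           # v_j - v_i
    volj = (domain.m / domain.rho)[pairs.j]
    voli = (domain.m / domain.rho)[pairs.i]
    L = np.zeros((n, 2, 2))
    for a in range(2):
        for b in range(2):
            L[:, a, b] += np.bincount(
                pairs.i, weights=volj * vij[:, a] * g[:, b], minlength=n)
            # for particle j: (v_i - v_j) x grad_j W = (-vij) x (-g) = vij x g
            L[:, a, b] += np.bincount(
                pairs.j, weights=voli * vij[:, a] * g[:, b], minlength=n)
    return L


def update_stress(domain: EcmDomain, velocity_gradients: np.ndarray, dt: float) -> np.ndarray:
    """One explicit-Euler hypoelastic plane-stress update with Jaumann spin.

    sigma <- sigma + dt * (C : eps_dot + spin*sigma - sigma*spin) with
    eps_dot / spin the symmetric / antisymmetric parts of the velocity
    gradient.  Returns the new Voigt stress array; does not mutate.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    L = np.asarray(velocity_gradients)
    if not np.all(np.isfinite(L)):
        raise ValueError("non-finite velocity gradient")
    E, nu = domain.material.E, domain.material.nu
    exx = L[:, 0, 0]
    eyy = L[:, 1, 1]
    exy = 0.5 * (L[:, 0, 1] + L[:, 1, 0])
    spin = 0.5 * (L[:, 0, 1] - L[:, 1, 0])   # omega_xy
    c = E / (1.0 - nu**2)
    sxx, syy, sxy = domain.sigma[:, 0], domain.sigma[:, 1], domain.sigma[:, 2]
    dxx = c * (exx + nu * eyy) + 2.0 * spin * sxy
    dyy = c * (eyy + nu * exx) - 2.0 * spin * sxy
    dxy = E / (1.0 + nu) * exy - spin * (sxx - syy)
    out = np.empty_like(domain.sigma)
    out[:, 0] = sxx + dt * dxx
    out[:, 1] = syy + dt * dyy
    out[:, 2] = sxy + dt * dxy
    return out


def hydrostatic_pressure(sigma: np.ndarray) -> np.ndarray | float:
    """Hydrostatic pressure p = -(s_xx + s_yy)/2, compression positive.

    Accepts a 2x2 tensor, an (N, 2, 2) stack, or Voigt (N, 3) / (3,) arrays.
    """
    s = np.asarray(sigma, dtype=float)
    if s.shape[-1] == 2:
        p = -0.5 * (s[..., 0, 0] + s[..., 1, 1])
    else:
        p = -0.5 * (s[..., 0] + s[..., 1])
    return float(p) if p.ndim == 0 else p


def fluid_pressure(domain: EcmDomain) -> np.ndarray:
    """Weakly compressible pressure of the fluidised fraction."""
    mat = domain.material
    return mat.K_fluid * (domain.rho / mat.rho0 - 1.0)


def effective_stress(domain: EcmDomain) -> np.ndarray:
    """Blend solid stress and fluid pressure through the degradation factor.

    Fully degraded particles (f_degr < FLUID_THRESHOLD) carry pure
    pressure; partially degraded material interpolates
    f*sigma_solid - (1-f)*p_fluid*I.
    """
    f = domain.f_degr
    pf = fluid_pressure(domain)
    out = domain.sigma * f[:, None]
    fluid_part = -(1.0 - f) * pf
    fully = f < FLUID_THRESHOLD
    out[fully] = 0.0
    fluid_part = np.where(fully, -pf, fluid_part)
    out[:, 0] += fluid_part
    out[:, 1] += fluid_part
    return out


def internal_forces(
    domain: EcmDomain, pairs: PairTable, sigma: np.ndarray | None = None
) -> np.ndarray:
    """Stress-divergence force in symmetric SPH form.

    F_i = m_i sum_j m_j (sigma_i/rho_i^2 + sigma_j/rho_j^2) . grad_i W_ij;
    pairwise contributions are exactly antisymmetric.
    """
    if sigma is None:
        sigma = effective_stress(domain)
    n = domain.n
    shat = sigma / (domain.rho**2)[:, None]
    s = shat[pairs.i] + shat[pairs.j]            # (P, 3) Voigt
    g = pairs.grad_i
    mm = domain.m[pairs.i] * domain.m[pairs.j]
    fx = mm * (s[:, 0] * g[:, 0] + s[:, 2] * g[:, 1])
    fy = mm * (s[:, 2] * g[:, 0] + s[:, 1] * g[:, 1])
    F = np.zeros((n, 2))
    F[:, 0] = np.bincount(pairs.i, weights=fx, minlength=n)
    F[:, 1] = np.bincount(pairs.i, weights=fy, minlength=n)
    F[:, 0] -= np.bincount(pairs.j, weights=fx, minlength=n)
    F[:, 1] -= np.bincount(pairs.j, weights=fy, minlength=n)
    return F


def viscous_coefficients(domain: EcmDomain, pairs: PairTable) -> np.ndarray:
    """Non-negative pair coefficients a_ij of the overdamped viscous
    operator sum_j a_ij (v_i - v_j) from the Monaghan-type term."""
    mat = domain.material
    mu = np.full(domain.n, mat.mu)
    xdg = np.einsum("pk,pk->p", pairs.dx, pairs.grad_i)   # x_ij . grad_i W_ij <= 0
    denom = pairs.r**2 + domain.kernel.eta_corr
    a = -(domain.m[pairs.i] * domain.m[pairs.j]
          * (mu[pairs.i] + mu[pairs.j])
          / (domain.rho[pairs.i] * domain.rho[pairs.j])) * xdg / denom
    return a


def _component_solve(a, pairs, n, free, rhs, x0, tol, maxiter, extra_diag=None):
    """CG solve of the graph-Laplacian system restricted to free nodes."""
    idx = -np.ones(n, dtype=int)
    free_ids = np.flatnonzero(free)
    idx[free_ids] = np.arange(len(free_ids))
    nf = len(free_ids)
    if nf == 0:
        return np.zeros(0), free_ids
    # diagonal: sum over all neighbours (fixed neighbours contribute too)
    diag = np.bincount(pairs.i, weights=a, minlength=n) + \
        np.bincount(pairs.j, weights=a, minlength=n)
    if extra_diag is not None:
        diag = diag + extra_diag
    if np.any(diag[free_ids] <= 0.0):
        diag = diag.copy()
        lone = free & (diag <= 0.0)
        diag[lone] = 1.0   # isolated particles: regular row, stays at rest
    both = free[pairs.i] & free[pairs.j]
    ii = idx[pairs.i[both]]
    jj = idx[pairs.j[both]]
    av = a[both]
    rows = np.concatenate([ii, jj, np.arange(nf)])
    cols = np.concatenate([jj, ii, np.arange(nf)])
    vals = np.concatenate([-av, -av, diag[free_ids]])
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(nf, nf))
    b = rhs[free_ids]
    # small systems (and those without a warm start) use a direct solve;
    # large time-stepped systems converge in a few warm-started CG
    # iterations because velocities change little between steps
    if nf < 600 or x0 is None:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = spsolve(A.tocsc(), b)
        if np.all(np.isfinite(sol)):
            return sol, free_ids
        # no Dirichlet anchor: the operator has a rigid-translation null
        # space; CG finds the solution when the net force vanishes
    d = A.diagonal()
    d[d <= 0] = 1.0
    M = sparse.diags(1.0 / d)
    sol, info = cg(A, b, x0=x0[free_ids] if x0 is not None else None,
                   rtol=tol, atol=0.0, maxiter=maxiter, M=M)
    if info != 0:
        res = np.linalg.norm(A @ sol - b)
        raise RuntimeError(
            f"ECM velocity solve did not converge (info={info}, residual={res:.3e})")
    return sol, free_ids


class SolverCache:
    """Reusable LU preconditioner for the time-stepped velocity solves.

    The overdamped operator changes slowly between steps, so an LU
    factorisation of a recent operator is an excellent preconditioner:
    CG then reaches the 1e-8 relative residual in a handful of
    iterations, and the factorisation is refreshed only when iteration
    counts creep up."""

    def __init__(self, refresh_iters: int = 12):
        self.factor = None
        self.refresh_iters = refresh_iters
        self.last_iters = np.inf

    def preconditioner(self, A):
        from scipy.sparse.linalg import LinearOperator, splu
        if self.factor is None or self.last_iters > self.refresh_iters:
            self.factor = splu(A.tocsc())
            self.last_iters = 0
        f = self.factor
        return LinearOperator(A.shape, matvec=f.solve)


def solve_ecm_velocities(
    domain: EcmDomain,
    external_forces: np.ndarray,
    pairs: PairTable | None = None,
    x0: np.ndarray | None = None,
    tol: float = 1e-8,
    maxiter: int = 2000,
    implicit_springs=None,
    a_scale: float = 1.0,
    extra_diag: np.ndarray | None = None,
    cache: SolverCache | None = None,
) -> np.ndarray:
    """Solve the overdamped momentum balance for particle velocities.

    The viscous operator couples x and y identically, so the two
    components are solved against the same graph Laplacian with
    per-component Dirichlet masks (fixed particles have zero velocity).

    ``implicit_springs`` is an optional ``(i, j, coef)`` triple of extra
    pairwise couplings (units nN*s/um, i.e. dt * spring constant) used to
    take fiber-spring forces with a backward-Euler linearisation; the
    vector-difference spring force of the fiber network linearises
    exactly to such an isotropic pairwise coupling.
    """
    if pairs is None:
        pairs = compute_pairs(domain)
    a = viscous_coefficients(domain, pairs) * a_scale
    n = domain.n
    pi, pj = pairs.i, pairs.j
    if implicit_springs is not None:
        si, sj, sc = implicit_springs
        pi = np.concatenate([pi, si])
        pj = np.concatenate([pj, sj])
        a = np.concatenate([a, sc])

    class _P:
        i = pi
        j = pj

    v = np.zeros((n, 2))
    if cache is not None and np.array_equal(domain.fixed_x, domain.fixed_y):
        return _cached_solve(a, _P, n, ~domain.fixed_x, external_forces,
                             x0, tol, maxiter, extra_diag, cache)
    for c, fixed_c in ((0, domain.fixed_x), (1, domain.fixed_y)):
        free = ~fixed_c
        sol, free_ids = _component_solve(
            a, _P, n, free, external_forces[:, c],
            x0[:, c] if x0 is not None else None, tol, maxiter, extra_diag)
        v[free_ids, c] = sol
    return v


def _assemble_laplacian(a, pairs, n, free, extra_diag):
    idx = -np.ones(n, dtype=int)
    free_ids = np.flatnonzero(free)
    idx[free_ids] = np.arange(len(free_ids))
    nf = len(free_ids)
    diag = np.bincount(pairs.i, weights=a, minlength=n) + \
        np.bincount(pairs.j, weights=a, minlength=n)
    if extra_diag is not None:
        diag = diag + extra_diag
    both = free[pairs.i] & free[pairs.j]
    ii = idx[pairs.i[both]]
    jj = idx[pairs.j[both]]
    av = a[both]
    rows = np.concatenate([ii, jj, np.arange(nf)])
    cols = np.concatenate([jj, ii, np.arange(nf)])
    dvals = diag[free_ids]
    # an isolated (out-of-support) particle has no interactions and no
    # forces; a unit diagonal keeps the operator regular and leaves it
    # at rest.  Detached clumps of fluid particles carry a rigid-motion
    # null space, removed by a tiny Tikhonov term (relative 1e-8).
    dvals = np.where(dvals <= 0.0, 1.0, dvals)
    dvals = dvals + 1e-8 * dvals.max()
    vals = np.concatenate([-av, -av, dvals])
    return sparse.csr_matrix((vals, (rows, cols)), shape=(nf, nf)), free_ids


def _cached_solve(a, pairs, n, free, forces, x0, tol, maxiter,
                  extra_diag, cache: SolverCache):
    A, free_ids = _assemble_laplacian(a, pairs, n, free, extra_diag)
    M = cache.preconditioner(A)
    v = np.zeros((n, 2))
    iters = 0
    for c in range(2):
        b = forces[free_ids, c]
        count = [0]

        def cb(xk):
            count[0] += 1

        sol, info = cg(A, b, x0=x0[free_ids, c] if x0 is not None else None,
                       rtol=tol, atol=0.0, maxiter=maxiter, M=M, callback=cb)
        if info != 0:
            cache.factor = None
            M = cache.preconditioner(A)
            sol, info = cg(A, b, rtol=tol, atol=0.0, maxiter=maxiter, M=M)
            if info != 0:
                raise RuntimeError(
                    f"ECM velocity solve did not converge (info={info})")
        iters = max(iters, count[0])
        v[free_ids, c] = sol
    cache.last_iters = iters
    return v


def stabilization_coefficients(domain: EcmDomain, pairs: PairTable,
                               dt: float) -> np.ndarray:
    """Backward-Euler pair couplings for the stress response.

    The stress-divergence force responds to relative motion roughly like
    pairwise springs with the local elastic stiffness (solid modulus
    blended with the fluid bulk stiffness through f_degr); taking that
    tangent implicitly keeps the published time step stable even for
    stiff matrices and the weakly compressible fluid fraction.
    """
    mat = domain.material
    ehat = domain.f_degr * mat.E + (1.0 - domain.f_degr) * mat.K_fluid
    a = viscous_coefficients(domain, pairs)
    scale = dt * (ehat[pairs.i] + ehat[pairs.j]) / (2.0 * mat.mu)
    return a * scale


def apply_degradation(domain: EcmDomain, targets, rates, dt: float) -> np.ndarray:
    """Exponential decay of the degradation factor for targeted particles.

    ``f_degr <- f_degr * exp(-rate*dt)``, clamped to [0, 1]; untargeted
    particles are untouched.  Returns the updated array (also written back
    to the domain).
    """
    targets = np.asarray(targets, dtype=int)
    rates = np.broadcast_to(np.asarray(rates, dtype=float), targets.shape)
    if np.any(rates < 0):
        raise ValueError("degradation rates must be non-negative")
    if len(targets):
        domain.f_degr[targets] = np.clip(
            domain.f_degr[targets] * np.exp(-rates * dt), 0.0, 1.0)
    return domain.f_degr
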