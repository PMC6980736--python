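"""Quasi-static uniaxial stretch harness for the matrix models.

A rectangular particle block is loaded in displacement control: the left
edge is held, the right edge is displaced in increments, and after each
increment the interior is relaxed through the overdamped SPH dynamics
until velocities vanish.  Lateral contraction is free (only the
horizontal midline is constrained vertically, as a symmetry plane), so
the measured slope of nominal stress versus strain is the plane-stress
Young's modulus.

Used both as the elastic patch test of the homogeneous matrix and as the
validation of the strain-stiffening fiber network against extensional
rheometry of collagen gels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ecm as ecm_mod
from . import fibers as fibers_mod
from .ecm import EcmDomain, EcmMaterial, initialize_ecm_block
from .fibers import (FiberParams, SpringNetwork, build_spring_network,
                     fiber_forces, fiber_pair_stiffness)
from .units import PA

__all__ = ["StretchResult", "uniaxial_stretch_test"]


@dataclass
class StretchResult:
    """Stress-strain curve from a displacement-controlled stretch."""

    strain: np.ndarray
    stress: np.ndarray          # nominal stress, model units (nN/um^2)

    @property
    def stress_pa(self) -> np.ndarray:
        return self.stress / PA

    def initial_slope(self, upto: float = 0.02) -> float:
        """Least-squares slope of the small-strain part (model units)."""
        m = self.strain <= upto + 1e-12
        if m.sum() < 2:
            m = slice(0, 2)
        return float(np.polyfit(self.strain[m], self.stress[m], 1)[0])


def _section_force(domain: EcmDomain, pairs, xcut: float,
                   net=None, params=None) -> float:
    """Axial force transmitted across the material plane x0 = xcut
    (momentum flux of pairwise interactions whose reference endpoints
    straddle the cut); an exact, boundary-layer-free nominal-stress
    measurement."""
    sigma = ecm_mod.effective_stress(domain)
    shat = sigma / (domain.rho**2)[:, None]
    s = shat[pairs.i] + shat[pairs.j]
    g = pairs.grad_i
    mm = domain.m[pairs.i] * domain.m[pairs.j]
    fx = mm * (s[:, 0] * g[:, 0] + s[:, 2] * g[:, 1])   # x-force on i from j
    xi = domain.x0[pairs.i, 0]
    xj = domain.x0[pairs.j, 0]
    total = fx[(xi < xcut) & (xj >= xcut)].sum()
    total -= fx[(xj < xcut) & (xi >= xcut)].sum()
    if net is not None and net.n_springs:
        fvec, *_ = fibers_mod._spring_force_vectors(domain, net, params)
        xi = domain.x0[net.i, 0]
        xj = domain.x0[net.j, 0]
        total += fvec[(xi < xcut) & (xj >= xcut), 0].sum()
        total -= fvec[(xj < xcut) & (xi >= xcut), 0].sum()
    # force exerted by the right half on the left half, i.e. the tension
    return float(total)


def _edge_masks(domain: EcmDomain, lx: float, ly: float):
    tol = 0.5 * domain.dp
    left = domain.x0[:, 0] < tol
    right = domain.x0[:, 0] > lx - tol
    mid = np.abs(domain.x0[:, 1] - ly / 2) < tol
    return left, right, mid


def uniaxial_stretch_test(
    block_size=(40.0, 20.0),
    params: FiberParams | None = None,
    matrix_material: EcmMaterial | None = None,
    strain_max: float = 0.15,
    n_steps: int = 15,
    dp: float = 2.0,
    dt: float = 0.4,
    rel_tol: float = 1e-6,
    max_relax: int = 600,
    mu_relax: float | None = None,
) -> StretchResult:
    """Displacement-controlled uniaxial stretch of a particle block.

    Each strain increment is applied as a homogeneous (affine)
    deformation, with the matching stress increment, and then relaxed
    until the largest net force on a free particle falls below
    ``rel_tol`` times the edge reaction.  The quasi-static equilibrium
    is independent of the matrix viscosity, so relaxation runs with a
    reduced pseudo-viscosity ``mu_relax`` to reach it in fewer sweeps.
    Returns nominal stress (edge reaction per unit reference
    cross-section) versus applied strain.
    """
    lx, ly = block_size
    if matrix_material is None:
        matrix_material = EcmMaterial(E=200 * PA, nu=0.45, mu=1000 * PA)
    if mu_relax is not None:
        matrix_material = EcmMaterial(
            E=matrix_material.E, nu=matrix_material.nu,
            mu=min(matrix_material.mu, mu_relax),
            rho0=matrix_material.rho0, K_fluid=matrix_material.K_fluid)
    domain = initialize_ecm_block(lx, ly, dp, matrix_material)
    left, right, mid = _edge_masks(domain, lx, ly)
    domain.fixed_x = left | right
    domain.fixed_y = mid.copy()
    domain.fixed = left | right   # bookkeeping only

    net: SpringNetwork | None = None
    if params is not None and params.k0 > 0:
        net = build_spring_network(domain, params)

    pairs = ecm_mod.compute_pairs(domain)
    domain.rho = ecm_mod.compute_density(domain, pairs)
    rho_ref = domain.rho.copy()

    strains = np.linspace(0.0, strain_max, n_steps + 1)[1:]
    out_eps, out_sig = [0.0], [0.0]
    eps_prev = 0.0
    v_guess = None
    for eps in strains:
        # affine increment relative to current configuration
        scale = (1.0 + eps) / (1.0 + eps_prev)
        domain.x[:, 0] *= scale
        L_aff = np.zeros((domain.n, 2, 2))
        L_aff[:, 0, 0] = np.log(scale)
        domain.sigma = ecm_mod.update_stress(domain, L_aff, 1.0)
        eps_prev = eps
        pairs = ecm_mod.compute_pairs(domain)
        free = ~(domain.fixed_x | domain.fixed_y)
        mat = matrix_material
        # damped-Newton relaxation: a large pseudo-step dt_n with the
        # matrix and fiber tangents taken implicitly (the matrix tangent
        # is the viscous Laplacian rescaled by E/mu) converges to the
        # same quasi-static equilibrium in few sweeps, independent of mu
        dt_n = 100.0 * mat.mu / max(mat.E, 1e-9)
        for it in range(max_relax):
            domain.rho = ecm_mod.compute_density(domain, pairs)
            F = ecm_mod.internal_forces(domain, pairs)
            impl = None
            if net is not None:
                F = F + fiber_forces(domain, net, params)
                kp = fiber_pair_stiffness(domain, net, params)
                impl = (net.i, net.j, dt_n * kp)
            load = max(np.abs(F[right, 0].sum()), 1e-9)
            if np.abs(F[free]).max() < rel_tol * load:
                break
            afac = 1.0 + dt_n * mat.E / max(mat.mu, 1e-12)
            v = ecm_mod.solve_ecm_velocities(
                domain, F, pairs, implicit_springs=impl, a_scale=afac)
            vmax = np.abs(v).max()
            dt_eff = dt_n if vmax * dt_n <= 0.1 * dp else 0.1 * dp / vmax
            domain.x += dt_eff * v
            L = ecm_mod.velocity_gradients(domain, pairs, v)
            domain.sigma = ecm_mod.update_stress(domain, L, dt_eff)
            pairs = ecm_mod.compute_pairs(domain)
        # nominal stress: momentum flux across a mid-block material cut;
        # each of the ny particle rows carries dp of cross-section width
        domain.rho = ecm_mod.compute_density(domain, pairs)
        width = ly + dp
        sig = _section_force(domain, pairs, lx / 2 + dp / 4, net, params) / width
        out_eps.append(eps)
        out_sig.append(sig)
    return StretchResult(strain=np.asarray(out_eps), stress=np.asarray(out_sig))
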