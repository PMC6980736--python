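"""Simulation orchestration: state, the per-step update order, scenario
setup and the replicate driver.

Each time step couples the modules in a fixed order: stochastic events
(initiation, adhesion disassembly), protrusion phase timers, matrix
degradation, force assembly, the overdamped cell velocity solve (with
matrix velocities from the previous step — a staggered coupling), the
overdamped matrix velocity solve, explicit Euler position updates,
density/stress updates, the contraction rest-length ratchet,
polarization, and logging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import ecm as ecm_mod
from .cell import (Cell, cell_ecm_contact, initialize_cell, passive_forces,
                   passive_stiffness, solve_cell_velocities,
                   update_rest_lengths)
from .config import SimConfig
from .ecm import EcmDomain, carve_hole, initialize_ecm_disk
from .fibers import (SpringNetwork, build_spring_network, fiber_forces,
                     fiber_pair_stiffness)
from .protrusion import (Polarization, ProtrusionSystem, attempt_initiation,
                         contraction_forces, degradation_targets,
                         update_polarization)

__all__ = ["SimState", "build_state", "step", "run", "run_replicates"]


@dataclass
class SimState:
    config: SimConfig
    cell: Cell
    ecm: EcmDomain
    net: SpringNetwork | None
    psys: ProtrusionSystem
    rng: np.random.Generator
    t: float = 0.0
    step_count: int = 0
    v_ecm: np.ndarray = None
    pairs: object = None
    tree: cKDTree | None = None
    x_at_build: np.ndarray = None
    trajectory: list = field(default_factory=list)
    solver_cache: ecm_mod.SolverCache = field(
        default_factory=ecm_mod.SolverCache)

    def record(self) -> None:
        cm = self.cell.center_of_mass()
        self.trajectory.append(
            {"t": self.t, "x_cm": cm[0], "y_cm": cm[1],
             "area": self.cell.area()})


def build_state(config: SimConfig) -> SimState:
    """Construct the coupled initial state for a scenario.

    The cell sits at the domain centre inside a carved hole (no solid
    matrix overlaps the boundary at t = 0).  In the single-protrusion
    scenario stochastic initiation is disabled and one protrusion is
    seeded at t = 0 at a random angle.
    """
    rng = np.random.default_rng(config.seed)
    domain = initialize_ecm_disk(
        config.ecm_radius, config.dp, config.material(), config.kernel())
    domain = carve_hole(domain, (0.0, 0.0), config.R + 0.5 * config.dp)
    domain.rho = ecm_mod.compute_density(domain)

    cell = initialize_cell((0.0, 0.0), config.cell_params())

    fparams = config.fiber_params()
    net = build_spring_network(domain, fparams) if fparams is not None else None

    psys = ProtrusionSystem(
        params=config.protrusion_params(),
        maturation=config.maturation_params(),
        adhesion_params=config.adhesion_params(),
        disassembly=config.disassembly_params(),
        degradation=config.degradation_params(),
        enforced=config.enforced_mode(),
        polarization=Polarization(r_pol=config.r_pol),
    )
    state = SimState(config=config, cell=cell, ecm=domain, net=net, psys=psys,
                     rng=rng, v_ecm=np.zeros((domain.n, 2)))
    if config.scenario == "single_protrusion":
        _seed_single_protrusion(state)
    state.record()
    return state


def _seed_single_protrusion(state: SimState) -> None:
    """Deterministically initiate one protrusion at a random angle and
    switch further stochastic initiation off."""
    from .protrusion import Protrusion, _ring_window

    angle = state.rng.uniform(0, 2 * np.pi)
    cell, psys = state.cell, state.psys
    ang = np.arctan2(cell.x[:, 1], cell.x[:, 0]) % (2 * np.pi)
    cand = int(np.argmin(np.abs((ang - angle + np.pi) % (2 * np.pi) - np.pi)))
    d_prot = cell.x[cand] - cell.center_of_mass()
    d_prot = d_prot / np.linalg.norm(d_prot)
    prot = Protrusion(
        id=psys.next_id, central=cand,
        members=_ring_window(cand, psys.params.w_prot, cell.n),
        force_ids=_ring_window(cand, psys.params.w_f, cell.n),
        d_prot=d_prot, f_mat=psys.maturation.f_mat_init,
        tip_at_init=cell.x[cand].copy())
    psys.next_id += 1
    cell.protrusion_id[prot.members] = prot.id
    cell.k_seg[prot.member_segments] = psys.params.k_s_prot
    psys.protrusions.append(prot)
    psys.polarization.d_pol = d_prot.copy()
    psys.polarization.defined = True
    psys.params.r_prot = 0.0
    psys.log(0.0, prot, "init", tip=cell.x[cand])


def restore_state(config: SimConfig, path) -> SimState:
    """Rebuild a state from a restart snapshot; continuing from it
    reproduces the original trajectory bit-for-bit on the same build.

    Restart files do not carry the protrusion bookkeeping, so restoring
    is exact only for snapshots taken before the first initiation (the
    quiescent baseline) or for mechanics-only continuation.
    """
    from .io import load_restart_arrays

    state = build_state(config)
    arr = load_restart_arrays(path)
    for k, v in arr["ecm"].items():
        getattr(state.ecm, k)[...] = v
    for k, v in arr["cell"].items():
        getattr(state.cell, k)[...] = v
    state.v_ecm = arr["v_ecm"]
    state.t = arr["t"]
    state.step_count = arr["step_count"]
    state.rng.bit_generator.state = arr["rng_state"]
    state.pairs = None
    state.tree = None
    state.trajectory = []
    return state


def _maybe_rebuild(state: SimState) -> None:
    cfg = state.config
    if state.pairs is None or state.tree is None:
        state.pairs = ecm_mod.compute_pairs(state.ecm)
        state.tree = cKDTree(state.ecm.x)
        state.x_at_build = state.ecm.x.copy()
        return
    moved = np.abs(state.ecm.x - state.x_at_build).max()
    if moved > 0.5 * cfg.skin:
        state.pairs = ecm_mod.compute_pairs(state.ecm)
        state.tree = cKDTree(state.ecm.x)
        state.x_at_build = state.ecm.x.copy()
    else:
        state.pairs = ecm_mod.refresh_pairs(state.ecm, state.pairs)


def step(state: SimState) -> SimState:
    """Advance the coupled system by one time step (mutates state)."""
    cfg = state.config
    dt = cfg.dt
    cell, domain, psys = state.cell, state.ecm, state.psys

    _maybe_rebuild(state)
    pairs, tree = state.pairs, state.tree

    # (1) stochastic events
    if cfg.scenario == "baseline":
        attempt_initiation(cell, psys, state.rng, dt, state.t)
    psys.sample_disassembly(cell, domain, state.rng, dt, state.t)

    # (2) phase/timer updates
    psys.advance_phases(cell, domain, dt, state.t, tree)

    # (3) degradation
    idx, rates = degradation_targets(cell, psys.protrusions, domain,
                                     psys.degradation, tree)
    ecm_mod.apply_degradation(domain, idx, rates, dt)

    # (4) force assembly
    f_passive = passive_forces(cell)
    soft = np.zeros(cell.n, dtype=bool)
    for prot in psys.protrusions:
        if prot.phase in ("growing", "maturing"):
            soft[prot.member_segments] = True
    f_contr, tension = contraction_forces(cell, psys.maturation,
                                          exclude_segments=soft,
                                          return_tension=True)
    f_act_cell, f_act_ecm = psys.active_forces(cell, domain, dt, state.t, tree)
    contacts = cell_ecm_contact(cell, domain, cfg.contact_params(), tree)
    f_cell = f_passive + f_contr + f_act_cell + contacts.f_cell

    # (5) cell velocity solve (staggered: previous-step matrix velocities)
    K = passive_stiffness(
        cell, extra_diag=psys.adhesion_diag_stiffness(cell)
        + contacts.k_cell_diag, segment_tension=tension)
    v_cell = solve_cell_velocities(cell, f_cell, contacts, state.v_ecm,
                                   stiffness=K, dt=dt)

    # (6) matrix velocity solve (stress, contact and viscous-coupling
    # tangents implicit; the cell velocity just solved enters the RHS)
    f_ecm = ecm_mod.internal_forces(domain, pairs) + f_act_ecm + contacts.f_ecm
    gamma_diag = np.zeros(domain.n)
    if len(contacts.gamma):
        np.add.at(f_ecm, contacts.ecm_idx,
                  contacts.gamma[:, None] * v_cell[contacts.cell_idx])
        np.add.at(gamma_diag, contacts.ecm_idx, contacts.gamma)
    stab = ecm_mod.stabilization_coefficients(domain, pairs, dt)
    si, sj, sc = pairs.i, pairs.j, stab
    fparams = cfg.fiber_params()
    if state.net is not None:
        f_ecm += fiber_forces(domain, state.net, fparams)
        kp = fiber_pair_stiffness(domain, state.net, fparams)
        si = np.concatenate([si, state.net.i])
        sj = np.concatenate([sj, state.net.j])
        sc = np.concatenate([sc, dt * kp])
    v_ecm = ecm_mod.solve_ecm_velocities(
        domain, f_ecm, pairs, x0=state.v_ecm, implicit_springs=(si, sj, sc),
        extra_diag=dt * contacts.k_ecm_diag + gamma_diag,
        cache=state.solver_cache)

    # (7) explicit Euler positions
    cell.x += dt * v_cell
    cell.v = v_cell
    domain.x += dt * v_ecm
    domain.v = v_ecm
    state.v_ecm = v_ecm

    # (8) density and stress updates
    geo = ecm_mod.refresh_pairs(domain, pairs)
    state.pairs = geo
    domain.rho = ecm_mod.compute_density(domain, geo)
    L = ecm_mod.velocity_gradients(domain, geo, v_ecm)
    domain.sigma = ecm_mod.update_stress(domain, L, dt)

    # (9) rest-length ratchet (not inside growing/maturing protrusions)
    update_rest_lengths(cell, soft)

    # (10) polarization and front set
    update_polarization(cell, psys, domain, dt)

    # (11) bookkeeping
    state.t += dt
    state.step_count += 1
    if not np.all(np.isfinite(cell.x)) or not np.all(np.isfinite(domain.x)):
        raise FloatingPointError(
            f"non-finite state at t={state.t:.1f}s (step {state.step_count})")
    if state.step_count % max(1, int(round(cfg.output_every / dt))) == 0:
        state.record()
    return state


def run(config: SimConfig, progress: bool = False,
        until: float | None = None) -> dict:
    """Run a scenario for its configured duration.

    Returns a dict with the trajectory and event-log DataFrames and the
    final state.
    """
    state = build_state(config)
    n_steps = int(round((until if until is not None else config.duration)
                        / config.dt))
    for k in range(n_steps):
        step(state)
        if progress and (k + 1) % 1000 == 0:
            import sys
            print(f"  t = {state.t:.0f}s / {n_steps * config.dt:.0f}s, "
                  f"protrusions: {state.psys.live_count()}", file=sys.stderr)
    return {
        "trajectory": pd.DataFrame(state.trajectory),
        "events": pd.DataFrame(
            state.psys.events,
            columns=["time", "protrusion_id", "type", "f_mat",
                     "adhesion_force", "tip_x", "tip_y", "anchor_x",
                     "anchor_y"]),
        "state": state,
    }


def run_replicates(config: SimConfig, seeds, progress: bool = False) -> list:
    """Run one scenario for several seeds (the stochastic replicates of
    a study condition) and return the per-replicate outputs."""
    out = []
    for s in seeds:
        cfg = SimConfig(**{**config.__dict__, "seed": int(s)})
        out.append(run(cfg, progress=progress))
    return out
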