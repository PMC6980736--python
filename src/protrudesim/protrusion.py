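"""Protrusion life cycle, polarization, adhesion mechanics and matrix
degradation targeting.

A protrusion is a 41-particle window of the cell boundary that passes
through four phases:

* growing   — cortex springs weakened, an actin polymerisation force
              pushes the central 7 particles outward along the growth
              direction while matrix ahead of the tip is fluidised;
* maturing  — a kernel-anchored adhesion spring connects the tip to the
              matrix and a stepwise mechanosensing clock raises the
              maturation factor f_mat each time the adhesion stretch
              completes 98% of one force step (stiff matrix: frequent
              steps, strong protrusion; soft matrix: few steps);
* contracting — cortex contraction at strength f_mat * F_am pulls the
              cell body towards the adhesion until the adhesion
              disassembles with a force-dependent stochastic rate;
* finishing — after disassembly the protrusion keeps contracting for a
              fixed time, then its particles are released.

Forces are in nN, lengths in um, times in s, rates in 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cell import Cell, cortex_curvature
from .ecm import FLUID_THRESHOLD, EcmDomain, hydrostatic_pressure
from .kernel import wendland_kernel

__all__ = [
    "ProtrusionParams",
    "MaturationParams",
    "AdhesionParams",
    "DisassemblyParams",
    "DegradationParams",
    "EnforcedProtrusionMode",
    "Adhesion",
    "Protrusion",
    "Polarization",
    "ProtrusionSystem",
    "attempt_initiation",
    "update_polarization",
    "growth_forces",
    "deflect_growth_direction",
    "form_adhesion",
    "maturation_step",
    "finalize_maturation",
    "contraction_forces",
    "curvature_factor",
    "disassembly_rate",
    "adhesion_disassembly",
    "degradation_targets",
    "protrusion_force_scaling",
]


@dataclass
class ProtrusionParams:
    r_prot: float = 6e-5        # per-particle initiation rate, 1/s
    w_prot: int = 20            # member half-window (41 particles total)
    w_f: int = 3                # force half-window (7 central particles)
    k_s_prot: float = 2.8e-3    # weakened cortex stiffness, nN/um
    F_prot: float = 0.32        # protrusion force, nN
    T_prot: float = 400.0       # growth time, s
    r_defl: float = 0.1         # deflection rate, 1/s
    T_finish: float = 400.0     # post-disassembly contraction time, s

    @property
    def window(self) -> int:
        return 2 * self.w_prot + 1

    @property
    def force_window(self) -> int:
        return 2 * self.w_f + 1


@dataclass
class MaturationParams:
    F_am: float = 0.6           # reference actomyosin force, nN
    T_mat: float = 600.0        # maturation time, s
    kappa0: float = -0.15       # optimal cortex curvature (dimensionless)
    kappa_w: float = 0.25       # curvature range
    f_mat_body: float = 0.05
    f_mat_init: float = 0.1
    step: float = 0.1
    threshold_frac: float = 0.98
    max_steps: int = 10
    base_width: int = 4         # particles fixed on each side of the window
    base_drag_mult: float = 1e6


@dataclass
class AdhesionParams:
    k_ad: float = 2.0           # adhesion spring stiffness, nN/um (2e-3 N/m)
    rest_length: float = 5.0    # um


@dataclass
class DisassemblyParams:
    r_off_min: float = 2.778e-4
    r_off_0: float = 0.2
    zeta_hat: float = 20.0      # dimensionless decay constant (zeta_diss/1000)
    f_rupt: float = 1.0
    r_rupture: float = 1e6
    force_dependent: bool = True
    r_off_const: float = 5.56e-4   # used when force_dependent is False


@dataclass
class DegradationParams:
    r_tip: float = 0.2
    d_tip: float = 2.4
    r_prot: float = 0.033
    d_prot: float = 1.4
    r_cell: float = 0.033
    d_cell: float = 1.9
    p_th: float = 0.02          # 20 Pa in nN/um^2


@dataclass
class EnforcedProtrusionMode:
    enabled: bool = False
    n_prot: int = 1
    rear_rate_factor: float = 0.01
    area_cap_factor: float = 2.0


@dataclass
class Adhesion:
    """Kernel-distributed anchor spring between the protrusion tip and a
    material point of the matrix 5 um beyond the tip."""

    tip_particle: int
    anchor0: np.ndarray
    particle_ids: np.ndarray
    weights: np.ndarray
    x_ref: np.ndarray           # matrix positions at formation
    k_ad: float
    rest_length: float
    formed_at: float
    mature: bool = False
    ext_at_last_step: float = 0.0

    def anchor_position(self, ecm: EcmDomain) -> np.ndarray:
        disp = self.weights[:, None] * (ecm.x[self.particle_ids] - self.x_ref)
        return self.anchor0 + disp.sum(axis=0)

    def force(self, cell: Cell, ecm: EcmDomain):
        """Spring force on the tip particle and its magnitude
        |k_ad * (length - rest_length)|."""
        anchor = self.anchor_position(ecm)
        d = anchor - cell.x[self.tip_particle]
        length = float(np.linalg.norm(d))
        if length < 1e-9:
            return np.zeros(2), 0.0
        fmag = self.k_ad * (length - self.rest_length)
        return fmag * d / length, abs(fmag)

    def extension(self, cell: Cell, ecm: EcmDomain) -> float:
        anchor = self.anchor_position(ecm)
        return float(np.linalg.norm(anchor - cell.x[self.tip_particle])
                     - self.rest_length)


@dataclass
class Protrusion:
    id: int
    central: int
    members: np.ndarray         # 41 particle ids, ring order
    force_ids: np.ndarray       # 7 central particle ids
    d_prot: np.ndarray          # unit growth direction
    phase: str = "growing"      # growing|maturing|contracting|finishing|done
    f_mat: float = 0.1
    adhesion: Adhesion | None = None
    t_phase: float = 0.0        # start time of the current phase
    t_init: float = 0.0
    tip_at_init: np.ndarray | None = None
    maturation_step_times: list = field(default_factory=list)

    @property
    def member_segments(self) -> np.ndarray:
        """Segment ids inside the window (segment i joins particles i,
        i+1), i.e. all members except the last."""
        return self.members[:-1]

    def base_ids(self, width: int) -> np.ndarray:
        return np.concatenate([self.members[:width], self.members[-width:]])


@dataclass
class Polarization:
    d_pol: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    defined: bool = False
    r_pol: float = 1.1e-3


def _ring_window(center: int, half: int, n: int) -> np.ndarray:
    return (np.arange(center - half, center + half + 1)) % n


def _rotate_towards(d: np.ndarray, target: np.ndarray, frac: float) -> np.ndarray:
    """Rotate unit vector d towards unit vector target by ``frac`` of the
    signed angle between them."""
    ang = np.arctan2(d[0] * target[1] - d[1] * target[0], float(d @ target))
    a = frac * ang
    c, s = np.cos(a), np.sin(a)
    return np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])


# --------------------------------------------------------------------------
# initiation and polarization

def attempt_initiation(cell: Cell, system: "ProtrusionSystem", rng,
                       dt: float, t: float = 0.0) -> list:
    """Stochastic protrusion initiation.

    Each eligible boundary particle fires with probability
    ``1 - exp(-r*dt)``; eligibility requires the front half of a
    polarized cell (with rear particles allowed at a strongly reduced
    rate in enforced-count mode), a 41-particle window free of other
    protrusions, and the enforced-mode count and area gates.  The first
    initiation polarizes the cell along the growth direction.

    One uniform draw per boundary particle is consumed every call, in
    particle order, so trajectories are reproducible for a fixed seed.
    """
    p = system.params
    enforced = system.enforced
    n = cell.n
    rates = np.zeros(n)
    if not system.polarization.defined:
        rates[:] = p.r_prot
    else:
        rates[cell.front] = p.r_prot
        if enforced.enabled:
            rates[~cell.front] = p.r_prot * enforced.rear_rate_factor
    u = rng.random(n)
    fire = u < -np.expm1(-rates * dt)
    created = []
    if not np.any(fire):
        return created
    area = cell.area()
    for cand in np.flatnonzero(fire):
        if enforced.enabled:
            if system.live_count() >= enforced.n_prot:
                continue
            if area > enforced.area_cap_factor * cell.A0:
                continue
        members = _ring_window(cand, p.w_prot, n)
        if np.any(cell.protrusion_id[members] >= 0):
            continue
        d_prot = cell.x[cand] - cell.center_of_mass()
        nrm = np.linalg.norm(d_prot)
        if nrm < 1e-9:
            continue
        d_prot = d_prot / nrm
        prot = Protrusion(
            id=system.next_id, central=cand, members=members,
            force_ids=_ring_window(cand, p.w_f, n), d_prot=d_prot,
            f_mat=system.maturation.f_mat_init, t_phase=t, t_init=t,
            tip_at_init=cell.x[cand].copy())
        system.next_id += 1
        cell.protrusion_id[members] = prot.id
        cell.k_seg[prot.member_segments] = p.k_s_prot
        system.protrusions.append(prot)
        created.append(prot)
        if not system.polarization.defined:
            system.polarization.d_pol = d_prot.copy()
            system.polarization.defined = True
        system.log(t, prot, "init", tip=cell.x[cand])
    return created


def update_front(cell: Cell, d_pol: np.ndarray) -> np.ndarray:
    """The front is the half of the boundary particles (118 of 235) with
    the largest projection onto the polarization direction."""
    proj = (cell.x - cell.center_of_mass()) @ d_pol
    k = int(np.ceil(cell.n / 2))
    order = np.argsort(-proj, kind="stable")
    front = np.zeros(cell.n, dtype=bool)
    front[order[:k]] = True
    cell.front = front
    return front


def update_polarization(cell: Cell, system: "ProtrusionSystem",
                        ecm: EcmDomain, dt: float) -> np.ndarray:
    """Rotate the polarization direction towards the mean direction of
    mature adhesions (seen from the cell centre of mass) with exponential
    angular relaxation at rate r_pol; unchanged when no mature adhesion
    exists.  Recomputes the front set."""
    pol = system.polarization
    if not pol.defined:
        return pol.d_pol
    cm = cell.center_of_mass()
    dirs = []
    for prot in system.protrusions:
        if prot.adhesion is not None and prot.adhesion.mature:
            d = prot.adhesion.anchor_position(ecm) - cm
            nrm = np.linalg.norm(d)
            if nrm > 1e-9:
                dirs.append(d / nrm)
    if dirs:
        target = np.mean(dirs, axis=0)
        nrm = np.linalg.norm(target)
        if nrm > 1e-9:
            target = target / nrm
            frac = -np.expm1(-pol.r_pol * dt)
            pol.d_pol = _rotate_towards(pol.d_pol, target, frac)
            pol.d_pol /= np.linalg.norm(pol.d_pol)
    update_front(cell, pol.d_pol)
    return pol.d_pol


# --------------------------------------------------------------------------
# growth

def growth_forces(prot: Protrusion, cell: Cell, params: ProtrusionParams,
                  scale: float = 1.0) -> np.ndarray:
    """Actin polymerisation force on the 7 central particles: magnitude
    ``F_prot * max(0, n_hat . d_prot)`` along the growth direction, so
    particles whose outward normal turns away from the growth direction
    receive less push (thin, sharp protrusions)."""
    F = np.zeros((cell.n, 2))
    normals = cell.outward_normals()
    for i in prot.force_ids:
        c = float(normals[i] @ prot.d_prot)
        if c > 0:
            F[i] += params.F_prot * scale * c * prot.d_prot
    return F


def deflect_growth_direction(prot: Protrusion, cell: Cell, ecm: EcmDomain,
                             deg: DegradationParams,
                             params: ProtrusionParams, dt: float,
                             ecm_tree: cKDTree | None = None) -> np.ndarray:
    """Rotate the growth direction towards degraded matrix ahead of the
    tip: within a sensing disk of radius 2*d_tip ahead of the tip the
    degradation-weighted mean direction (weights 1 - f_degr) is the
    target; intact or symmetric surroundings leave the direction
    unchanged."""
    tip = cell.x[prot.central]
    center = tip + deg.d_tip * prot.d_prot
    radius = 2.0 * deg.d_tip
    if ecm_tree is None:
        ecm_tree = cKDTree(ecm.x)
    idx = ecm_tree.query_ball_point(center, radius)
    if not idx:
        return prot.d_prot
    idx = np.asarray(idx)
    wdeg = 1.0 - ecm.f_degr[idx]
    rel = ecm.x[idx] - tip
    nrm = np.linalg.norm(rel, axis=1)
    # only matrix ahead of the tip steers the growth direction; the
    # freshly carved tunnel behind the tip must not pull it backwards
    ok = (nrm > 1e-9) & (rel @ prot.d_prot > 0)
    if not np.any(ok) or wdeg[ok].sum() < 1e-12:
        return prot.d_prot
    target = (wdeg[ok, None] * rel[ok] / nrm[ok, None]).sum(axis=0)
    tn = np.linalg.norm(target)
    if tn < 1e-9:
        return prot.d_prot
    frac = -np.expm1(-params.r_defl * dt)
    prot.d_prot = _rotate_towards(prot.d_prot, target / tn, frac)
    prot.d_prot /= np.linalg.norm(prot.d_prot)
    return prot.d_prot


# --------------------------------------------------------------------------
# adhesion and maturation

def form_adhesion(prot: Protrusion, cell: Cell, ecm: EcmDomain,
                  params: AdhesionParams, t: float,
                  ecm_tree: cKDTree | None = None) -> Adhesion | None:
    """Anchor an adhesion spring at a material point ``rest_length``
    beyond the tip, distributing it over solid matrix particles with
    normalized kernel weights.  Returns None (protrusion aborts) when no
    solid particle supports the anchor."""
    tip = cell.x[prot.central]
    anchor0 = tip + params.rest_length * prot.d_prot
    if ecm_tree is None:
        ecm_tree = cKDTree(ecm.x)
    idx = np.asarray(ecm_tree.query_ball_point(anchor0, ecm.kernel.support_radius),
                     dtype=int)
    if idx.size:
        idx = idx[ecm.f_degr[idx] >= FLUID_THRESHOLD]
    if idx.size == 0:
        return None
    r = np.linalg.norm(ecm.x[idx] - anchor0, axis=1)
    w, _ = wendland_kernel(r, ecm.kernel)
    w = np.atleast_1d(w)
    if w.sum() <= 0:
        return None
    w = w / w.sum()
    return Adhesion(
        tip_particle=prot.central, anchor0=anchor0.copy(), particle_ids=idx,
        weights=w, x_ref=ecm.x[idx].copy(), k_ad=params.k_ad,
        rest_length=params.rest_length, formed_at=t)


def maturation_step(prot: Protrusion, cell: Cell, ecm: EcmDomain,
                    mat: MaturationParams, dt: float, t: float,
                    system: "ProtrusionSystem | None" = None) -> bool:
    """Mechanosensing clock: raise f_mat by one step whenever the
    adhesion has stretched by at least ``threshold_frac`` of one force
    step (0.1 F_am / k_ad) since the previous increment.  Returns True
    if a step was taken."""
    adh = prot.adhesion
    ext = adh.extension(cell, ecm)
    threshold = mat.threshold_frac * (mat.step * mat.F_am) / adh.k_ad
    took = False
    if (ext - adh.ext_at_last_step >= threshold
            and len(prot.maturation_step_times) < mat.max_steps
            and prot.f_mat < 1.0 - 1e-12):
        prot.f_mat = min(1.0, prot.f_mat + mat.step)
        prot.maturation_step_times.append(t)
        adh.ext_at_last_step = ext
        took = True
        if system is not None:
            system.log(t, prot, "mat_step")
    return took


def maturation_force(prot: Protrusion, cell: Cell, mat: MaturationParams) -> np.ndarray:
    """Contractile point force f_mat*F_am on the adhesion boundary
    particle, opposite to the growth direction."""
    F = np.zeros((cell.n, 2))
    F[prot.central] = -prot.f_mat * mat.F_am * prot.d_prot
    return F


def finalize_maturation(prot: Protrusion, cell: Cell,
                        params: ProtrusionParams, mat: MaturationParams,
                        t: float, system: "ProtrusionSystem | None" = None) -> float:
    """Close the maturation phase: set the final maturation factor from
    the average time per step (0.1 * T_mat / mean step interval, at most
    1), restore cortex stiffness, reset member rest lengths to the grown
    geometry, release the base and switch to cortex-driven contraction."""
    times = prot.maturation_step_times
    if times:
        rel = np.asarray(times) - prot.t_phase
        mean_interval = max(rel[-1], 1e-9) / len(rel)
        prot.f_mat = min(1.0, mat.step * mat.T_mat / mean_interval)
    # zero steps: f_mat stays at its initial value
    segs = prot.member_segments
    cell.k_seg[segs] = cell.params.k_s
    cell.k_seg_comp[segs] = cell.params.k_s
    ln = cell.segment_lengths()
    cell.l0[segs] = ln[segs]
    cell.drag_mult[prot.base_ids(mat.base_width)] = 1.0
    cell.f_mat[prot.members] = prot.f_mat
    if prot.adhesion is not None:
        prot.adhesion.mature = True
    prot.phase = "contracting"
    prot.t_phase = t
    if system is not None:
        system.log(t, prot, "mat_done")
    return prot.f_mat


# --------------------------------------------------------------------------
# contraction

def curvature_factor(kappa, mat: MaturationParams):
    """Myosin-curvature coupling: a Gaussian bell in the local curvature
    centred on the optimal curvature kappa0, in [0, 1]."""
    kappa = np.asarray(kappa, dtype=float)
    out = np.exp(-((kappa - mat.kappa0) ** 2) / (2.0 * mat.kappa_w**2))
    return float(out) if out.ndim == 0 else out


def contraction_forces(cell: Cell, mat: MaturationParams,
                       exclude_segments: np.ndarray | None = None,
                       return_tension: bool = False):
    """Actomyosin tension on the cortex segments: the two particles of a
    segment are pulled together with force
    ``min(f_mat_i, f_mat_j) * f_curv_ij * F_am``, with the curvature
    factor averaged over the pair.  Contraction acts on the cell body
    and on mature protrusions only; segments of growing or maturing
    protrusions (whose cortex is not yet restored) are passed in
    ``exclude_segments``.  The internal sum is exactly zero."""
    n = cell.n
    t = cell.segment_vectors()
    ln = np.linalg.norm(t, axis=1)
    u = t / np.maximum(ln, 1e-12)[:, None]
    fc = curvature_factor(cortex_curvature(cell), mat)
    fm = cell.f_mat
    jn = np.arange(1, n + 1) % n
    tension = np.minimum(fm, fm[jn]) * 0.5 * (fc + fc[jn]) * mat.F_am
    if exclude_segments is not None:
        tension = np.where(exclude_segments, 0.0, tension)
    F = tension[:, None] * u
    F = F - np.roll(F, 1, axis=0)
    return (F, tension) if return_tension else F


# --------------------------------------------------------------------------
# disassembly

def disassembly_rate(force_mag: float, f_mat: float,
                     params: DisassemblyParams, F_am: float) -> float:
    """Force-dependent adhesion disassembly rate: high at low load
    (r_off_min + r_off_0), decaying exponentially with the load relative
    to the protrusion's contractile strength, and immediate rupture when
    the load reaches f_rupt times that strength."""
    if not params.force_dependent:
        return params.r_off_const
    fscale = max(f_mat * F_am, 1e-12)
    if force_mag >= params.f_rupt * fscale:
        return params.r_rupture
    return params.r_off_min + params.r_off_0 * np.exp(
        -params.zeta_hat * force_mag / fscale)


def adhesion_disassembly(force_mag: float, f_mat: float,
                         params: DisassemblyParams, F_am: float,
                         rng, dt: float):
    """Sample whether the adhesion detaches during this step
    (probability 1 - exp(-r_off dt))."""
    r = disassembly_rate(force_mag, f_mat, params, F_am)
    return r, bool(rng.random() < -np.expm1(-r * dt))


# --------------------------------------------------------------------------
# degradation targeting

def degradation_targets(cell: Cell, protrusions, ecm: EcmDomain,
                        deg: DegradationParams,
                        ecm_tree: cKDTree | None = None):
    """Select matrix particles to fluidise this step.

    * tip zone: solid particles within d_tip of the force particles of a
      growing protrusion, at rate r_tip, with no pressure gate;
    * protrusion shaft: within d_prot of any live protrusion particle,
      gated on solid hydrostatic pressure above p_th, rate r_prot;
    * cell body: within d_cell of non-protrusion boundary particles,
      same pressure gate, rate r_cell.

    A particle selected by several rules degrades at the fastest rate.
    """
    if ecm_tree is None:
        ecm_tree = cKDTree(ecm.x)
    solid = ecm.solid
    p_solid = hydrostatic_pressure(ecm.sigma)
    rates: dict[int, float] = {}

    def add(ids, rate):
        for k in ids:
            if rates.get(k, 0.0) < rate:
                rates[k] = rate

    member_mask = cell.protrusion_id >= 0
    for prot in protrusions:
        if prot.phase == "growing":
            for lst in ecm_tree.query_ball_point(cell.x[prot.force_ids], deg.d_tip):
                add([k for k in lst if solid[k]], deg.r_tip)
    prot_pts = cell.x[member_mask]
    if len(prot_pts):
        hits = set()
        for lst in ecm_tree.query_ball_point(prot_pts, deg.d_prot):
            hits.update(lst)
        add([k for k in hits if solid[k] and p_solid[k] > deg.p_th], deg.r_prot)
    body_pts = cell.x[~member_mask]
    if len(body_pts):
        hits = set()
        for lst in ecm_tree.query_ball_point(body_pts, deg.d_cell):
            hits.update(lst)
        add([k for k in hits if solid[k] and p_solid[k] > deg.p_th], deg.r_cell)
    if not rates:
        return np.empty(0, dtype=int), np.empty(0)
    idx = np.fromiter(rates.keys(), dtype=int)
    rr = np.fromiter(rates.values(), dtype=float)
    return idx, rr


def protrusion_force_scaling(area: float, area0: float,
                             enforced: EnforcedProtrusionMode) -> float:
    """Enforced-count mode: the growth force is scaled by A0/A once the
    cell has grown beyond its initial area (less actin available)."""
    if not enforced.enabled or area <= area0:
        return 1.0
    return area0 / area


# --------------------------------------------------------------------------
# orchestration

@dataclass
class ProtrusionSystem:
    """Owns the live protrusions, the polarization state, the event log
    and the per-step phase bookkeeping."""

    params: ProtrusionParams = field(default_factory=ProtrusionParams)
    maturation: MaturationParams = field(default_factory=MaturationParams)
    adhesion_params: AdhesionParams = field(default_factory=AdhesionParams)
    disassembly: DisassemblyParams = field(default_factory=DisassemblyParams)
    degradation: DegradationParams = field(default_factory=DegradationParams)
    enforced: EnforcedProtrusionMode = field(default_factory=EnforcedProtrusionMode)
    polarization: Polarization = field(default_factory=Polarization)
    protrusions: list = field(default_factory=list)
    events: list = field(default_factory=list)
    next_id: int = 0

    def live_count(self) -> int:
        return sum(1 for p in self.protrusions if p.phase != "done")

    def log(self, t: float, prot: Protrusion, etype: str,
            force: float = np.nan, tip=None, anchor=None):
        self.events.append({
            "time": t, "protrusion_id": prot.id, "type": etype,
            "f_mat": prot.f_mat, "adhesion_force": force,
            "tip_x": np.nan if tip is None else tip[0],
            "tip_y": np.nan if tip is None else tip[1],
            "anchor_x": np.nan if anchor is None else anchor[0],
            "anchor_y": np.nan if anchor is None else anchor[1],
        })

    # -- per-step stages -----------------------------------------------

    def sample_disassembly(self, cell: Cell, ecm: EcmDomain, rng,
                           dt: float, t: float):
        """Stage 1b: stochastic disassembly of mature adhesions."""
        for prot in self.protrusions:
            if prot.phase != "contracting" or prot.adhesion is None:
                continue
            _, fmag = prot.adhesion.force(cell, ecm)
            r, off = adhesion_disassembly(
                fmag, prot.f_mat, self.disassembly, self.maturation.F_am,
                rng, dt)
            if off:
                etype = "rupture" if (
                    self.disassembly.force_dependent
                    and fmag >= self.disassembly.f_rupt * prot.f_mat
                    * self.maturation.F_am) else "disassemble"
                self.log(t, prot, etype, force=fmag,
                         tip=cell.x[prot.central],
                         anchor=prot.adhesion.anchor_position(ecm))
                prot.adhesion = None
                prot.phase = "finishing"
                prot.t_phase = t

    def advance_phases(self, cell: Cell, ecm: EcmDomain, dt: float,
                       t: float, ecm_tree=None):
        """Stage 2: timer-driven phase transitions."""
        p = self.params
        for prot in self.protrusions:
            elapsed = t - prot.t_phase
            if prot.phase == "growing" and elapsed >= p.T_prot - 1e-9:
                adh = form_adhesion(prot, cell, ecm, self.adhesion_params,
                                    t, ecm_tree)
                if adh is None:
                    prot.phase = "finishing"
                    prot.t_phase = t
                    self.log(t, prot, "abort", tip=cell.x[prot.central])
                else:
                    prot.adhesion = adh
                    prot.phase = "maturing"
                    prot.t_phase = t
                    cell.drag_mult[prot.base_ids(self.maturation.base_width)] \
                        = self.maturation.base_drag_mult
                    # un-restored cortex buckles at a bending-limited
                    # load: weak enough that the maturation force loads
                    # the adhesion spring (not a cortex chain to the
                    # fixed base), stiff enough to keep the membrane
                    # from crumpling
                    cell.k_seg_comp[prot.member_segments] = \
                        0.1 * cell.params.k_s
                    self.log(t, prot, "adhesion", tip=cell.x[prot.central],
                             anchor=adh.anchor0)
            elif prot.phase == "maturing" and elapsed >= self.maturation.T_mat - 1e-9:
                finalize_maturation(prot, cell, p, self.maturation, t, self)
            elif prot.phase == "finishing" and elapsed >= p.T_finish - 1e-9:
                prot.phase = "done"
                cell.protrusion_id[prot.members] = -1
                cell.f_mat[prot.members] = self.maturation.f_mat_body
                cell.k_seg[prot.member_segments] = cell.params.k_s
                cell.k_seg_comp[prot.member_segments] = cell.params.k_s
                cell.drag_mult[prot.base_ids(self.maturation.base_width)] = 1.0
                self.log(t, prot, "finish", tip=cell.x[prot.central])
        self.protrusions = [q for q in self.protrusions if q.phase != "done"]

    def active_forces(self, cell: Cell, ecm: EcmDomain, dt: float, t: float,
                      ecm_tree=None):
        """Stage 4: growth, maturation and adhesion forces on the cell,
        with the reaction of adhesion springs on the matrix."""
        F_cell = np.zeros((cell.n, 2))
        F_ecm = np.zeros((ecm.n, 2))
        scale = protrusion_force_scaling(cell.area(), cell.A0, self.enforced)
        for prot in self.protrusions:
            if prot.phase == "growing":
                deflect_growth_direction(prot, cell, ecm, self.degradation,
                                         self.params, dt, ecm_tree)
                F_cell += growth_forces(prot, cell, self.params, scale)
            elif prot.phase == "maturing":
                maturation_step(prot, cell, ecm, self.maturation, dt, t, self)
                F_cell += maturation_force(prot, cell, self.maturation)
            if prot.adhesion is not None:
                fvec, _ = prot.adhesion.force(cell, ecm)
                F_cell[prot.adhesion.tip_particle] += fvec
                # reaction distributed over the anchor's kernel weights
                F_ecm[prot.adhesion.particle_ids] -= \
                    prot.adhesion.weights[:, None] * fvec
        return F_cell, F_ecm

    def adhesion_diag_stiffness(self, cell: Cell) -> np.ndarray:
        """Per-particle stiffness of active adhesion springs, used in the
        semi-implicit cell velocity solve."""
        diag = np.zeros(cell.n)
        for prot in self.protrusions:
            if prot.adhesion is not None:
                diag[prot.adhesion.tip_particle] += prot.adhesion.k_ad
        return diag
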