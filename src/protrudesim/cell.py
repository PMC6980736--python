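"""Deformable boundary-particle cell with overdamped cortex mechanics.

The cell is a closed ring of particles joined by viscoelastic segments
(the actin cortex).  Passive mechanics comprises linear segment springs,
a weak bending penalty on the turning angle, a weak area-conservation
force and a Hertz-like self-repulsion that prevents the boundary from
penetrating itself.  Velocities follow from an overdamped force balance:
cortex viscous coupling between ring neighbours, viscous coupling to
contacting matrix particles, and drag from the culture medium.

All quantities are in model units (um, s, nN); see
:mod:`protrudesim.units` for the conversion from the published SI values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree

from .ecm import EcmDomain
from .kernel import wendland_kernel

__all__ = [
    "CellParams",
    "ContactParams",
    "Cell",
    "initialize_cell",
    "passive_forces",
    "cortex_curvature",
    "cell_ecm_contact",
    "passive_stiffness",
    "solve_cell_velocities",
    "update_rest_lengths",
]


@dataclass
class CellParams:
    """Cortex and drag parameters (model units; defaults are the
    published baseline converted from SI)."""

    R: float = 15.0                 # initial radius, um
    n_particles: int = 235
    k_s: float = 2.8                # cortex stiffness, nN/um (2.8e-3 N/m)
    eta_c: float = 2.5              # cortex viscosity, nN*s/um (2.5e-3 Ns/m)
    k_bend: float = 2.0             # bending constant, nN*um (2e-15 Nm)
    k_A: float = 7.1e-4             # area constraint, nN/um^3 (0.71 N/m^2)
    k_rep: float = 1.4              # self-repulsion, nN/um^1.5
    d_rep: float = 0.2              # repulsion onset distance, um
    gamma_liquid: float = 0.04      # medium drag, nN*s/um^2 (40 Pa*s)

    def __post_init__(self) -> None:
        for name in ("k_s", "eta_c", "k_bend", "k_A", "k_rep", "d_rep",
                     "gamma_liquid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def l0_init(self) -> float:
        return 2.0 * np.pi * self.R / self.n_particles

    @property
    def A0(self) -> float:
        return np.pi * self.R**2


@dataclass
class ContactParams:
    """Cell-matrix contact: Hertz-like normal repulsion plus a
    kernel-weighted viscous coupling (both scaled by f_degr, so fully
    degraded particles pass freely through the boundary)."""

    k_con: float = 1.4        # nN/um^1.5
    d_contact: float = 1.0    # standoff distance, um
    gamma0: float = 0.7       # viscous coupling scale, nN*s/um
    fluid_drag_frac: float = 0.15  # residual coupling of fluidised gel


@dataclass
class Cell:
    """Closed ring of boundary particles (segment i joins particles
    i and i+1 mod n, with counter-clockwise orientation)."""

    params: CellParams
    x: np.ndarray                              # (n, 2)
    v: np.ndarray = field(default=None)
    l0: np.ndarray = field(default=None)       # (n,) segment rest lengths
    k_seg: np.ndarray = field(default=None)    # (n,) segment stiffness
    f_mat: np.ndarray = field(default=None)    # (n,) contraction factor
    drag_mult: np.ndarray = field(default=None)
    protrusion_id: np.ndarray = field(default=None)
    front: np.ndarray = field(default=None)    # bool mask
    A0: float = None
    l0_floor: float = None     # initial (chord) rest length, ratchet floor
    k_seg_comp: np.ndarray = field(default=None)   # compression stiffness

    def __post_init__(self) -> None:
        n = len(self.x)
        if self.v is None:
            self.v = np.zeros((n, 2))
        seg = np.linalg.norm(np.roll(self.x, -1, axis=0) - self.x, axis=1)
        if self.l0 is None:
            self.l0 = seg.copy()
        if self.k_seg is None:
            self.k_seg = np.full(n, self.params.k_s)
        if self.f_mat is None:
            self.f_mat = np.full(n, 0.05)
        if self.drag_mult is None:
            self.drag_mult = np.ones(n)
        if self.protrusion_id is None:
            self.protrusion_id = np.full(n, -1, dtype=int)
        if self.front is None:
            self.front = np.ones(n, dtype=bool)
        if self.A0 is None:
            self.A0 = self.area()
        if self.l0_floor is None:
            self.l0_floor = float(self.l0.min())
        if self.k_seg_comp is None:
            self.k_seg_comp = np.full(n, self.params.k_s)

    @property
    def n(self) -> int:
        return len(self.x)

    def segment_vectors(self) -> np.ndarray:
        return np.roll(self.x, -1, axis=0) - self.x

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.segment_vectors(), axis=1)

    def area(self) -> float:
        x, y = self.x[:, 0], self.x[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def center_of_mass(self) -> np.ndarray:
        return self.x.mean(axis=0)

    def outward_normals(self) -> np.ndarray:
        """Per-particle outward unit normals (mean of adjacent segment
        normals; segment normal of a CCW ring is (t_y, -t_x))."""
        t = self.segment_vectors()
        ln = np.linalg.norm(t, axis=1, keepdims=True)
        nseg = np.column_stack([t[:, 1], -t[:, 0]]) / np.maximum(ln, 1e-12)
        npart = nseg + np.roll(nseg, 1, axis=0)
        norm = np.linalg.norm(npart, axis=1, keepdims=True)
        return npart / np.maximum(norm, 1e-12)

    def particle_weights(self) -> np.ndarray:
        """Arclength weight per particle: half the sum of its two
        adjacent segment lengths (used to dimensionalise line drags)."""
        seg = self.segment_lengths()
        return 0.5 * (seg + np.roll(seg, 1))


def initialize_cell(center=(0.0, 0.0), params: CellParams | None = None) -> Cell:
    """Place ``n_particles`` equally on a circle (counter-clockwise);
    rest lengths equal current lengths so all passive forces vanish."""
    if params is None:
        params = CellParams()
    n = params.n_particles
    ang = 2.0 * np.pi * np.arange(n) / n
    x = np.asarray(center, dtype=float) + params.R * np.column_stack(
        [np.cos(ang), np.sin(ang)])
    return Cell(params=params, x=x)


def _turning_angles(x: np.ndarray):
    """Signed turning angle at each particle (positive = CCW turn), with
    the segment vectors used to compute it."""
    a = x - np.roll(x, 1, axis=0)        # incoming segment at particle i
    b = np.roll(x, -1, axis=0) - x       # outgoing segment
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = np.einsum("ij,ij->i", a, b)
    return np.arctan2(cross, dot), a, b


def cortex_curvature(cell: Cell, i: int | None = None):
    """Dimensionless signed local curvature: minus the CCW turning angle,
    so an outward-bulging (convex) boundary is negative.  A rest circle
    of n particles has kappa = -2*pi/n everywhere."""
    theta, _, _ = _turning_angles(cell.x)
    kappa = -theta
    return kappa if i is None else float(kappa[i])


def passive_forces(cell: Cell, parts: bool = False):
    """Passive cortex forces per particle (nN).

    Returns the summed force array; with ``parts=True`` returns a dict
    with the individual spring / bend / area / repulsion contributions.
    """
    p = cell.params
    x = cell.x
    n = cell.n
    t = cell.segment_vectors()
    ln = np.linalg.norm(t, axis=1)
    if np.any(ln < 1e-9):
        raise ValueError("degenerate zero-length cortex segment")
    u = t / ln[:, None]

    # (a) linear segment springs; a weakened (growing) segment keeps the
    # full cortex stiffness under compression, which stops boundary
    # particles from bunching into a slack reservoir that would feed a
    # single runaway spike.  During maturation the window's compression
    # stiffness is weakened too, so the mechanosensing force loads the
    # adhesion spring instead of a parasitic cortex chain to the base.
    k_used = np.where(ln >= cell.l0, cell.k_seg,
                      np.maximum(cell.k_seg, cell.k_seg_comp))
    fmag = k_used * (ln - cell.l0)
    fs = fmag[:, None] * u
    f_spring = fs - np.roll(fs, 1, axis=0)   # +f on i (toward i+1), -f on i+1

    # (b) bending penalty on turning angles: U = k_bend/(2 l0) sum theta^2;
    # the 1/l lever arms are floored at half the resolution so bunched
    # (slack) boundary particles cannot produce unbounded moments
    theta, a, b = _turning_angles(x)
    lmin2 = (0.5 * p.l0_init) ** 2
    la2 = np.maximum(np.einsum("ij,ij->i", a, a), lmin2)
    lb2 = np.maximum(np.einsum("ij,ij->i", b, b), lmin2)
    aperp = np.column_stack([-a[:, 1], a[:, 0]]) / la2[:, None]
    bperp = np.column_stack([-b[:, 1], b[:, 0]]) / lb2[:, None]
    coef = (p.k_bend / p.l0_init) * theta
    # dtheta_k/dx_{k-1} = aperp_k ; dtheta_k/dx_{k+1} = bperp_k ;
    # dtheta_k/dx_k = -(aperp + bperp)_k ;  grad_i U = sum_k coef_k dtheta_k/dx_i
    gU = (np.roll(coef[:, None] * aperp, -1, axis=0)      # k = i+1 term
          + np.roll(coef[:, None] * bperp, 1, axis=0)     # k = i-1 term
          - coef[:, None] * (aperp + bperp))              # k = i term
    f_bend = -gU

    # (c) area conservation: U = k_A/2 (A - A0)^2, grad_i A = 0.5*(y_{i+1}-y_{i-1}, x_{i-1}-x_{i+1})
    A = cell.area()
    gA = 0.5 * np.column_stack([
        np.roll(x[:, 1], -1) - np.roll(x[:, 1], 1),
        np.roll(x[:, 0], 1) - np.roll(x[:, 0], -1)])
    f_area = -p.k_A * (A - cell.A0) * gA

    # (d) Hertz-like self repulsion, point against non-adjacent segment
    f_rep = np.zeros_like(x)
    if p.k_rep > 0:
        pi_, si_ = _repulsion_candidates(x, ln, p.d_rep)
        if pi_.size:
            s0 = x[si_]
            d = t[si_]
            L2 = np.maximum(np.einsum("ij,ij->i", d, d), 1e-18)
            tpar = np.clip(np.einsum("ij,ij->i", x[pi_] - s0, d) / L2, 0.0, 1.0)
            closest = s0 + tpar[:, None] * d
            dvec = x[pi_] - closest
            dist = np.linalg.norm(dvec, axis=1)
            hit = (dist < p.d_rep) & (dist > 1e-9)
            if np.any(hit):
                pi_, si_, tpar = pi_[hit], si_[hit], tpar[hit]
                dist, dvec = dist[hit], dvec[hit]
                mag = p.k_rep * (p.d_rep - dist) ** 1.5
                fvec = mag[:, None] * dvec / dist[:, None]
                np.add.at(f_rep, pi_, fvec)
                np.add.at(f_rep, si_, -(1 - tpar)[:, None] * fvec)
                np.add.at(f_rep, (si_ + 1) % n, -tpar[:, None] * fvec)

    total = f_spring + f_bend + f_area + f_rep
    if parts:
        return {"spring": f_spring, "bend": f_bend, "area": f_area,
                "rep": f_rep, "total": total}
    return total


def _repulsion_candidates(x, ln, d_rep, sub: float = 0.5):
    """Candidate (particle, segment) pairs for self-repulsion, found by
    subsampling segments into points no further than ``sub`` apart so
    that stretched segments stay cheap to search against."""
    n = len(x)
    nsub = np.maximum(1, np.ceil(ln / sub).astype(int))
    seg_ids = np.repeat(np.arange(n), nsub)
    frac = np.concatenate([np.arange(k) / k for k in nsub])
    pts = x[seg_ids] + frac[:, None] * (x[(seg_ids + 1) % n] - x[seg_ids])
    tree_pts = cKDTree(pts)
    tree_x = cKDTree(x)
    cand = tree_x.query_ball_tree(tree_pts, d_rep + sub)
    pi, si = [], []
    for particle, lst in enumerate(cand):
        if not lst:
            continue
        for sub_idx in lst:
            s = seg_ids[sub_idx]
            ring = min((particle - s) % n, (s - particle) % n)
            ring2 = min((particle - (s + 1)) % n, ((s + 1) - particle) % n)
            if min(ring, ring2) <= 2:
                continue
            pi.append(particle)
            si.append(s)
    if not pi:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    pairs = np.unique(np.column_stack([pi, si]), axis=0)
    return pairs[:, 0], pairs[:, 1]


def _point_segment(pt, s0, s1):
    d = s1 - s0
    L2 = float(d @ d)
    t = 0.0 if L2 == 0 else float(np.clip((pt - s0) @ d / L2, 0.0, 1.0))
    closest = s0 + t * d
    return float(np.linalg.norm(pt - closest)), t, closest


@dataclass
class ContactSet:
    """Cell-ECM contact interactions for one step."""

    f_cell: np.ndarray       # (n, 2) position-dependent contact force on cell
    f_ecm: np.ndarray        # (N, 2) reaction on matrix particles
    cell_idx: np.ndarray     # viscous coupling pairs (cell particle,
    ecm_idx: np.ndarray      # matrix particle, coefficient nN*s/um)
    gamma: np.ndarray
    k_cell_diag: np.ndarray = None   # contact tangent stiffness, nN/um
    k_ecm_diag: np.ndarray = None


def cell_ecm_contact(cell: Cell, ecm: EcmDomain,
                     contact: ContactParams | None = None,
                     ecm_tree: cKDTree | None = None) -> ContactSet:
    """Normal repulsion and viscous coupling between the boundary and
    solid matrix particles.

    Solid particles closer than the standoff distance to the boundary
    polyline are pushed out along the local outward normal with a
    Hertz-like force scaled by f_degr; an equal and opposite force acts on
    the boundary segment.  Fully degraded particles are ignored.
    """
    if contact is None:
        contact = ContactParams()
    n = cell.n
    f_cell = np.zeros((n, 2))
    f_ecm = np.zeros((ecm.n, 2))
    k_cell = np.zeros(n)
    k_ecm = np.zeros(ecm.n)
    empty = ContactSet(
        f_cell=f_cell, f_ecm=f_ecm, cell_idx=np.empty(0, dtype=int),
        ecm_idx=np.empty(0, dtype=int), gamma=np.empty(0),
        k_cell_diag=k_cell, k_ecm_diag=k_ecm)
    if ecm_tree is None:
        ecm_tree = cKDTree(ecm.x)
    seg = cell.segment_vectors()
    ln = np.linalg.norm(seg, axis=1)
    reach = contact.d_contact + ecm.kernel.h + ln.max()
    cell_tree = cKDTree(cell.x)
    cand = cell_tree.query_ball_tree(ecm_tree, reach)
    kk = np.unique(np.fromiter(
        (k for lst in cand for k in lst), dtype=int, count=sum(map(len, cand)))
    ) if any(cand) else np.empty(0, dtype=int)
    if kk.size == 0:
        return empty
    xk = ecm.x[kk]
    _, p_near = cell_tree.query(xk)
    nseg = np.column_stack([seg[:, 1], -seg[:, 0]]) \
        / np.maximum(ln, 1e-12)[:, None]

    # point-segment projection for the two segments adjacent to the
    # nearest boundary particle; pick the closer one
    def proj(sid):
        s0 = cell.x[sid]
        d = seg[sid]
        L2 = np.maximum(np.einsum("ij,ij->i", d, d), 1e-18)
        tpar = np.clip(np.einsum("ij,ij->i", xk - s0, d) / L2, 0.0, 1.0)
        closest = s0 + tpar[:, None] * d
        dist = np.linalg.norm(xk - closest, axis=1)
        return tpar, closest, dist

    sA = p_near
    sB = (p_near - 1) % n
    tA, cA, dA = proj(sA)
    tB, cB, dB = proj(sB)
    useA = dA <= dB
    sid = np.where(useA, sA, sB)
    tpar = np.where(useA, tA, tB)
    closest = np.where(useA[:, None], cA, cB)
    dist = np.where(useA, dA, dB)
    rel = xk - closest
    side = np.einsum("ij,ij->i", rel, nseg[sid])
    sdist = np.where(side >= 0, dist, -dist)

    fd = ecm.f_degr[kk]
    nrm = nseg[sid]
    jn = (sid + 1) % n

    # Hertz-like normal repulsion below the standoff distance; only
    # solid particles push back (fluidised material passes freely)
    pen = (sdist < contact.d_contact) & ecm.solid[kk]
    if np.any(pen):
        delta = contact.d_contact - sdist[pen]
        mag = contact.k_con * fd[pen] * delta ** 1.5
        fvec = mag[:, None] * nrm[pen]
        np.add.at(f_ecm, kk[pen], fvec)
        np.add.at(f_cell, sid[pen], -(1 - tpar[pen])[:, None] * fvec)
        np.add.at(f_cell, jn[pen], -tpar[pen][:, None] * fvec)
        ktan = 1.5 * contact.k_con * fd[pen] * delta ** 0.5
        np.add.at(k_ecm, kk[pen], ktan)
        np.add.at(k_cell, sid[pen], (1 - tpar[pen]) * ktan)
        np.add.at(k_cell, jn[pen], tpar[pen] * ktan)

    # kernel-weighted viscous coupling within one support of the surface,
    # scaled by the degradation factor so fluidised particles slip
    # through the boundary with only a weak residual drag
    w, _ = wendland_kernel(np.abs(sdist), ecm.kernel)
    w = np.atleast_1d(w)
    g = contact.gamma0 * np.maximum(fd, contact.fluid_drag_frac) \
        * w / ecm.kernel.w0
    act = g > 0
    ci = np.concatenate([sid[act], jn[act]])
    ei = np.concatenate([kk[act], kk[act]])
    gv = np.concatenate([(1 - tpar[act]) * g[act], tpar[act] * g[act]])
    pos = gv > 0
    return ContactSet(
        f_cell=f_cell, f_ecm=f_ecm, cell_idx=ci[pos], ecm_idx=ei[pos],
        gamma=gv[pos], k_cell_diag=k_cell, k_ecm_diag=k_ecm)


def _block_coo(I, J, B, acc):
    """Append 2x2 blocks B (m,2,2) at block positions (I, J) to the COO
    accumulator."""
    rows, cols, vals = acc
    for a in range(2):
        for b in range(2):
            rows.append(2 * I + a)
            cols.append(2 * J + b)
            vals.append(B[:, a, b])


def _coo_to_csr(acc, n):
    rows = np.concatenate(acc[0])
    cols = np.concatenate(acc[1])
    vals = np.concatenate(acc[2])
    return sparse.csr_matrix((vals, (rows, cols)), shape=(2 * n, 2 * n))


def passive_stiffness(cell: Cell, extra_diag: np.ndarray | None = None,
                      segment_tension: np.ndarray | None = None):
    """Positive-semidefinite linearisation of the stiff passive forces
    (segment springs and bending), used for semi-implicit velocity
    updates: solving ``(Gamma + dt K) v = F`` is a backward-Euler step in
    the linearised forces, which keeps the published time step stable
    despite the stiff cortex constants.

    ``extra_diag`` optionally adds per-particle isotropic stiffness
    (adhesion springs, contact) as an (n,) array in nN/um.
    """
    p = cell.params
    n = cell.n
    t = cell.segment_vectors()
    ln = np.linalg.norm(t, axis=1)
    u = t / np.maximum(ln, 1e-12)[:, None]
    acc = ([], [], [])
    idx = np.arange(n)
    jdx = (idx + 1) % n

    # axial spring stiffness + transverse geometric term under tension
    uu = u[:, :, None] * u[:, None, :]
    k_used = np.where(ln >= cell.l0, cell.k_seg,
                      np.maximum(cell.k_seg, cell.k_seg_comp))
    fmag = k_used * (ln - cell.l0)
    # geometric stiffness: taut segments resist transverse motion with
    # T/l; actomyosin tension is passed in so that contracting cortex
    # stays implicit at the production time step
    total_T = np.maximum(fmag, 0.0)
    if segment_tension is not None:
        total_T = total_T + np.maximum(segment_tension, 0.0)
    tens = total_T / np.maximum(ln, 1e-12)
    P = k_used[:, None, None] * uu + \
        tens[:, None, None] * (np.eye(2)[None] - uu)
    _block_coo(idx, idx, P, acc)
    _block_coo(jdx, jdx, P, acc)
    _block_coo(idx, jdx, -P, acc)
    _block_coo(jdx, idx, -P, acc)

    # bending: Gauss-Newton K = (k_bend/l0) sum_k grad(theta_k) grad(theta_k)^T
    theta, a, b = _turning_angles(cell.x)
    lmin2 = (0.5 * p.l0_init) ** 2
    la2 = np.maximum(np.einsum("ij,ij->i", a, a), lmin2)
    lb2 = np.maximum(np.einsum("ij,ij->i", b, b), lmin2)
    aperp = np.column_stack([-a[:, 1], a[:, 0]]) / la2[:, None]
    bperp = np.column_stack([-b[:, 1], b[:, 0]]) / lb2[:, None]
    kb = p.k_bend / p.l0_init
    km, kp_ = (idx - 1) % n, (idx + 1) % n
    grads = (aperp, bperp, -(aperp + bperp))
    nodes = (km, kp_, idx)
    for gi, ni in zip(grads, nodes):
        for gj, nj in zip(grads, nodes):
            _block_coo(ni, nj, kb * gi[:, :, None] * gj[:, None, :], acc)
    if extra_diag is not None:
        nz = np.flatnonzero(extra_diag)
        if nz.size:
            blocks = extra_diag[nz, None, None] * np.eye(2)[None]
            _block_coo(nz, nz, blocks, acc)
    return _coo_to_csr(acc, n)


def solve_cell_velocities(cell: Cell, forces: np.ndarray,
                          contacts: ContactSet | None = None,
                          ecm_velocities: np.ndarray | None = None,
                          stiffness=None, dt: float | None = None) -> np.ndarray:
    """Solve the overdamped cortex force balance for particle velocities.

    The left-hand side couples ring neighbours through the axial cortex
    viscosity, contacting matrix particles through the viscous
    coefficients (matrix velocities treated as known), and the medium
    through a per-particle drag ``gamma_liquid * l_i * drag_mult``.
    """
    p = cell.params
    n = cell.n
    t = cell.segment_vectors()
    ln = np.linalg.norm(t, axis=1)
    u = t / np.maximum(ln, 1e-12)[:, None]

    drag = p.gamma_liquid * cell.particle_weights() * cell.drag_mult
    rhs = forces.copy()

    idx = np.arange(n)
    jdx = (idx + 1) % n
    acc = ([], [], [])
    eye = np.eye(2)[None]
    # axial cortex viscosity along each segment
    P = p.eta_c * u[:, :, None] * u[:, None, :]
    diag_blocks = drag[:, None, None] * eye + P + np.roll(P, 1, axis=0)
    _block_coo(idx, jdx, -P, acc)
    _block_coo(jdx, idx, -P, acc)
    if contacts is not None and len(contacts.gamma):
        gsum = np.bincount(contacts.cell_idx, weights=contacts.gamma, minlength=n)
        diag_blocks = diag_blocks + gsum[:, None, None] * eye
        if ecm_velocities is not None:
            vk = ecm_velocities[contacts.ecm_idx]
            np.add.at(rhs, contacts.cell_idx, contacts.gamma[:, None] * vk)
    _block_coo(idx, idx, diag_blocks, acc)
    A = _coo_to_csr(acc, n)
    if stiffness is not None:
        if dt is None:
            raise ValueError("dt required with implicit stiffness")
        A = A + dt * stiffness
    sol = spsolve(A.tocsc(), rhs.ravel())
    return sol.reshape(n, 2)


def update_rest_lengths(cell: Cell, exclude: np.ndarray | None = None) -> np.ndarray:
    """Contraction ratchet: a segment's rest length is set to its current
    length when that is shorter than the current rest length but not
    below the initial rest length; it never increases.

    ``exclude`` masks segments of growing or maturing protrusions.
    """
    ln = cell.segment_lengths()
    new = np.where((ln < cell.l0) & (ln >= cell.l0_floor), ln, cell.l0)
    if exclude is not None:
        new = np.where(exclude, cell.l0, new)
    cell.l0 = new
    return new
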