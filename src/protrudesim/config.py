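"""Configuration: published parameter table in SI units, TOML loading,
validation, and conversion to the model's internal unit system."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path

from . import units as U
from .cell import CellParams, ContactParams
from .ecm import EcmMaterial
from .fibers import FiberParams
from .kernel import KernelSpec
from .protrusion import (AdhesionParams, DegradationParams, DisassemblyParams,
                         EnforcedProtrusionMode, MaturationParams,
                         ProtrusionParams)

__all__ = ["SimConfig", "load_config"]


@dataclass
class SimConfig:
    """All tunable parameters, keyed by their published symbols.

    Mechanical constants are stored in the SI units of the parameter
    table (N/m, Pa, Pa*s, N*m ...); forces in nN; lengths in um; times
    in s.  ``to_model_params`` converts to the internal um/s/nN system.
    """

    # cell
    R: float = 15.0                  # um
    n_particles: int = 235
    k_s: float = 2.8e-3              # N/m
    eta_c: float = 2.5e-3            # N*s/m
    k_bend: float = 2e-15            # N*m
    k_A: float = 0.71                # N/m^2
    k_rep: float = 1.4               # N/m^1.5
    d_rep: float = 0.2               # um
    gamma_liquid: float = 40.0       # Pa*s
    r_pol: float = 1.1e-3            # 1/s
    # cell-ECM contact (reconstructed)
    k_con: float = 1.4               # N/m^1.5
    d_contact: float = 1.0           # um
    gamma_contact: float = 7e-4      # N*s/m
    fluid_drag_frac: float = 0.15
    # protrusion
    r_prot: float = 6e-5             # 1/s
    w_prot: int = 20
    w_f: int = 3
    k_s_prot: float = 2.8e-6         # N/m
    F_prot: float = 0.32             # nN
    T_prot: float = 400.0            # s
    r_defl: float = 0.1              # 1/s
    T_finish: float = 400.0          # s
    # adhesion
    k_ad: float = 2e-3               # N/m
    l0_adh: float = 5.0              # um
    r_off_min: float = 2.778e-4      # 1/s
    r_off_0: float = 0.2             # 1/s
    zeta_diss: float = 2e4           # dimensionless (zeta_hat = zeta_diss/1000)
    f_rupt: float = 1.0
    disassembly_mode: str = "force_dependent"   # or "force_independent"
    r_off_const: float = 5.56e-4     # 1/s, force-independent mode
    # maturation and contraction
    F_am: float = 0.6                # nN
    T_mat: float = 600.0             # s
    kappa0: float = -0.15
    kappa_w: float = 0.25
    # ECM degradation
    r_degr_tip: float = 0.2          # 1/s
    d_degr_tip: float = 2.4          # um
    r_degr_prot: float = 0.033
    d_degr_prot: float = 1.4
    r_degr_cell: float = 0.033
    d_degr_cell: float = 1.9
    p_th_degr: float = 20.0          # Pa
    # ECM SPH
    dp: float = 2.0                  # um
    h: float = 2.6                   # um
    rho0: float = 1.0                # model units
    ecm_radius: float = 150.0        # um
    E: float = 200.0                 # Pa
    nu: float = 0.45
    mu: float = 1000.0               # Pa*s
    K_fluid: float = 2000.0          # Pa, weakly compressible fluid stiffness
    # strain stiffening
    fibers_enabled: bool = False
    k0: float = 1645.0               # Pa
    eps_s: float = 0.075
    d_s: float = 0.033
    fiber_mode: str = "isotropic"    # or "uniaxial"
    fiber_dir: tuple = (1.0, 0.0)
    half_angle: float = 30.0         # degrees
    k0_uniaxial: float = 10000.0     # Pa
    fiber_axial_force: bool = False
    # enforced protrusion count mode
    enforced_enabled: bool = False
    n_prot: int = 1
    rear_rate_factor: float = 0.01
    # simulation
    dt: float = 0.4                  # s
    duration: float = 21600.0        # s (6 h)
    seed: int = 0
    output_every: float = 60.0       # s
    scenario: str = "baseline"       # or "single_protrusion"
    skin: float = 0.5                # neighbour-list skin, um

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("sim.dt must be positive")
        ratio = self.duration / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("sim.duration must be a multiple of sim.dt")
        if not 0 <= self.nu < 0.5:
            raise ValueError("ecm.nu must lie in [0, 0.5)")
        for key in ("k_s", "eta_c", "k_bend", "k_A", "k_rep", "gamma_liquid",
                    "k_ad", "k_con", "E", "mu", "k0", "F_prot", "F_am",
                    "r_prot", "r_off_min", "r_off_0", "f_rupt"):
            if getattr(self, key) < 0:
                raise ValueError(f"{key} must be non-negative")
        if self.disassembly_mode not in ("force_dependent", "force_independent"):
            raise ValueError("disassembly_mode must be force_dependent or "
                             "force_independent")
        if self.fiber_mode not in ("isotropic", "uniaxial"):
            raise ValueError("fiber_mode must be isotropic or uniaxial")
        if self.scenario not in ("baseline", "single_protrusion"):
            raise ValueError("scenario must be baseline or single_protrusion")
        if self.n_prot not in (1, 2, 3, 4):
            raise ValueError("n_prot must be 1..4")

    # -- conversion to model units -------------------------------------

    def kernel(self) -> KernelSpec:
        return KernelSpec(h=self.h)

    def material(self) -> EcmMaterial:
        return EcmMaterial(E=self.E * U.PA, nu=self.nu, mu=self.mu * U.PA_S,
                           rho0=self.rho0, K_fluid=self.K_fluid * U.PA)

    def cell_params(self) -> CellParams:
        return CellParams(
            R=self.R, n_particles=self.n_particles,
            k_s=self.k_s * U.N_PER_M, eta_c=self.eta_c * U.NS_PER_M,
            k_bend=self.k_bend * U.N_M, k_A=self.k_A * U.N_PER_M2,
            k_rep=self.k_rep * U.N_PER_M15, d_rep=self.d_rep,
            gamma_liquid=self.gamma_liquid * U.PA_S)

    def contact_params(self) -> ContactParams:
        return ContactParams(k_con=self.k_con * U.N_PER_M15,
                             d_contact=self.d_contact,
                             gamma0=self.gamma_contact * U.NS_PER_M,
                             fluid_drag_frac=self.fluid_drag_frac)

    def protrusion_params(self) -> ProtrusionParams:
        return ProtrusionParams(
            r_prot=self.r_prot, w_prot=self.w_prot, w_f=self.w_f,
            k_s_prot=self.k_s_prot * U.N_PER_M, F_prot=self.F_prot,
            T_prot=self.T_prot, r_defl=self.r_defl, T_finish=self.T_finish)

    def maturation_params(self) -> MaturationParams:
        return MaturationParams(F_am=self.F_am, T_mat=self.T_mat,
                                kappa0=self.kappa0, kappa_w=self.kappa_w)

    def adhesion_params(self) -> AdhesionParams:
        return AdhesionParams(k_ad=self.k_ad * U.N_PER_M,
                              rest_length=self.l0_adh)

    def disassembly_params(self) -> DisassemblyParams:
        return DisassemblyParams(
            r_off_min=self.r_off_min, r_off_0=self.r_off_0,
            zeta_hat=self.zeta_diss / 1000.0, f_rupt=self.f_rupt,
            force_dependent=self.disassembly_mode == "force_dependent",
            r_off_const=self.r_off_const)

    def degradation_params(self) -> DegradationParams:
        return DegradationParams(
            r_tip=self.r_degr_tip, d_tip=self.d_degr_tip,
            r_prot=self.r_degr_prot, d_prot=self.d_degr_prot,
            r_cell=self.r_degr_cell, d_cell=self.d_degr_cell,
            p_th=self.p_th_degr * U.PA)

    def enforced_mode(self) -> EnforcedProtrusionMode:
        return EnforcedProtrusionMode(
            enabled=self.enforced_enabled, n_prot=self.n_prot,
            rear_rate_factor=self.rear_rate_factor)

    def fiber_params(self) -> FiberParams | None:
        if not self.fibers_enabled:
            return None
        k0 = self.k0_uniaxial if self.fiber_mode == "uniaxial" else self.k0
        return FiberParams(
            k0=k0 * U.PA, eps_s=self.eps_s, d_s=self.d_s,
            mode=self.fiber_mode, fiber_dir=tuple(self.fiber_dir),
            half_angle=self.half_angle, axial_force=self.fiber_axial_force)


# nested TOML block -> flat attribute names
_BLOCK_KEYS = {
    "cell": {"R": "R", "n_particles": "n_particles", "k_s": "k_s",
             "eta_c": "eta_c", "k_bend": "k_bend", "k_A": "k_A",
             "k_rep": "k_rep", "d_rep": "d_rep",
             "gamma_liquid": "gamma_liquid", "r_pol": "r_pol"},
    "contact": {"k_con": "k_con", "d_contact": "d_contact",
                "gamma_contact": "gamma_contact",
                "fluid_drag_frac": "fluid_drag_frac"},
    "protrusion": {"r_prot": "r_prot", "w_prot": "w_prot", "w_f": "w_f",
                   "k_s_prot": "k_s_prot", "F_prot": "F_prot",
                   "T_prot": "T_prot", "r_defl": "r_defl",
                   "T_finish": "T_finish"},
    "adhesion": {"k_ad": "k_ad", "l0_adh": "l0_adh",
                 "r_off_min": "r_off_min", "r_off_0": "r_off_0",
                 "zeta_diss": "zeta_diss", "f_rupt": "f_rupt",
                 "mode": "disassembly_mode", "r_off_const": "r_off_const"},
    "maturation": {"F_am": "F_am", "T_mat": "T_mat", "kappa0": "kappa0",
                   "kappa_w": "kappa_w"},
    "degradation": {"r_degr_tip": "r_degr_tip", "d_degr_tip": "d_degr_tip",
                    "r_degr_prot": "r_degr_prot",
                    "d_degr_prot": "d_degr_prot",
                    "r_degr_cell": "r_degr_cell",
                    "d_degr_cell": "d_degr_cell", "p_th_degr": "p_th_degr"},
    "ecm": {"dp": "dp", "h": "h", "rho0": "rho0", "radius": "ecm_radius",
            "E": "E", "nu": "nu", "mu": "mu", "K_fluid": "K_fluid"},
    "fibers": {"enabled": "fibers_enabled", "k0": "k0", "eps_s": "eps_s",
               "d_s": "d_s", "mode": "fiber_mode", "fiber_dir": "fiber_dir",
               "half_angle": "half_angle", "k0_uniaxial": "k0_uniaxial",
               "axial_force": "fiber_axial_force"},
    "enforced": {"enabled": "enforced_enabled", "n_prot": "n_prot",
                 "rear_rate_factor": "rear_rate_factor"},
    "sim": {"dt": "dt", "duration": "duration", "seed": "seed",
            "output_every": "output_every", "scenario": "scenario",
            "skin": "skin"},
}


def load_config(path: str | Path | None = None, overrides: dict | None = None
                ) -> SimConfig:
    """Load a TOML configuration.  Missing keys take the published
    defaults; unknown blocks or keys are rejected by name."""
    data: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    if overrides:
        for blk, kv in overrides.items():
            data.setdefault(blk, {}).update(kv)
    kwargs = {}
    for blk, kv in data.items():
        if blk not in _BLOCK_KEYS:
            raise KeyError(f"unknown config block '{blk}'")
        if not isinstance(kv, dict):
            raise KeyError(f"config block '{blk}' must be a table")
        for key, val in kv.items():
            if key not in _BLOCK_KEYS[blk]:
                raise KeyError(f"unknown config key '{blk}.{key}'")
            kwargs[_BLOCK_KEYS[blk][key]] = val
    return SimConfig(**kwargs)
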