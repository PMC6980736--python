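import numpy as np
import pytest
from scipy import stats

from protrudesim.cell import initialize_cell
from protrudesim.config import SimConfig
from protrudesim.protrusion import (Adhesion, DegradationParams,
                                    DisassemblyParams, EnforcedProtrusionMode,
                                    MaturationParams, Polarization,
                                    Protrusion, ProtrusionParams,
                                    ProtrusionSystem, _ring_window,
                                    adhesion_disassembly, attempt_initiation,
                                    contraction_forces, curvature_factor,
                                    degradation_targets, disassembly_rate,
                                    form_adhesion, growth_forces,
                                    maturation_step, finalize_maturation,
                                    protrusion_force_scaling,
                                    update_polarization, update_front)


def make_system(**kw):
    return ProtrusionSystem(**kw)


def polarized_system(cell, direction=(1.0, 0.0)):
    sys_ = make_system()
    sys_.polarization.d_pol = np.asarray(direction, dtype=float)
    sys_.polarization.defined = True
    update_front(cell, sys_.polarization.d_pol)
    return sys_


def make_protrusion(cell, sys_, central=0):
    p = sys_.params
    prot = Protrusion(
        id=sys_.next_id, central=central,
        members=_ring_window(central, p.w_prot, cell.n),
        force_ids=_ring_window(central, p.w_f, cell.n),
        d_prot=cell.x[central] / np.linalg.norm(cell.x[central]),
        f_mat=sys_.maturation.f_mat_init,
        tip_at_init=cell.x[central].copy())
    sys_.next_id += 1
    cell.protrusion_id[prot.members] = prot.id
    sys_.protrusions.append(prot)
    return prot


class TestInitiation:
    def test_rear_particle_never_initiates_baseline(self, cell, rng):
        """With the cell polarized along +x, rear (-x) particles cannot
        initiate in baseline mode even with certain firing."""
        sys_ = polarized_system(cell)
        sys_.params.r_prot = 1e9      # every eligible particle fires
        attempt_initiation(cell, sys_, rng, 0.4)
        for prot in sys_.protrusions:
            assert cell.front[prot.central]

    def test_window_overlap_rejected(self, cell, rng):
        sys_ = polarized_system(cell)
        make_protrusion(cell, sys_, central=0)
        sys_.params.r_prot = 1e9
        before = len(sys_.protrusions)
        attempt_initiation(cell, sys_, rng, 0.4)
        for prot in sys_.protrusions[before:]:
            assert not np.any(np.isin(prot.members,
                                      sys_.protrusions[0].members))

    def test_first_initiation_polarizes(self, cell, rng):
        sys_ = make_system()
        sys_.params.r_prot = 1e9
        created = attempt_initiation(cell, sys_, rng, 0.4)
        assert sys_.polarization.defined
        assert np.allclose(sys_.polarization.d_pol, created[0].d_prot)

    def test_firing_probability_matches_closed_form(self, cell):
        """Monte Carlo initiation frequency equals 1-exp(-r dt) within
        3 binomial sigma."""
        r_prot, dt = 6e-5, 0.4
        p_expected = 1 - np.exp(-r_prot * dt)
        n_trials = 10**6
        rng = np.random.default_rng(7)
        hits = int(np.sum(rng.random(n_trials) < p_expected))
        sigma = np.sqrt(n_trials * p_expected * (1 - p_expected))
        assert abs(hits - n_trials * p_expected) < 3 * sigma

    def test_enforced_mode_gates(self, cell, rng):
        sys_ = polarized_system(cell)
        sys_.enforced = EnforcedProtrusionMode(enabled=True, n_prot=1)
        make_protrusion(cell, sys_, central=0)
        sys_.params.r_prot = 1e9
        created = attempt_initiation(cell, sys_, rng, 0.4)
        assert created == []          # count cap
        sys_.enforced.n_prot = 4
        cell.A0 = cell.area() / 2.1   # area above the 2 A0 cap
        created = attempt_initiation(cell, sys_, rng, 0.4)
        assert created == []


class TestPolarization:
    def test_front_is_half_of_particles(self, cell):
        update_front(cell, np.array([1.0, 0.0]))
        assert cell.front.sum() == int(np.ceil(235 / 2))
        # the frontmost particle is along +x
        assert cell.front[np.argmax(cell.x[:, 0])]

    def test_no_mature_adhesion_leaves_direction(self, cell, small_disk):
        sys_ = polarized_system(cell)
        d0 = sys_.polarization.d_pol.copy()
        update_polarization(cell, sys_, small_disk, 0.4)
        assert np.allclose(sys_.polarization.d_pol, d0)

    def test_rotation_follows_exponential_law(self, cell, small_disk):
        """Target at +90 degrees: one step rotates the polarization by
        90 deg * (1 - exp(-r_pol dt))."""
        sys_ = polarized_system(cell, (1.0, 0.0))
        prot = make_protrusion(cell, sys_, central=0)
        prot.phase = "contracting"
        anchor = np.array([0.0, 40.0])    # +90 degrees from +x
        prot.adhesion = Adhesion(
            tip_particle=prot.central, anchor0=anchor,
            particle_ids=np.array([0]), weights=np.array([1.0]),
            x_ref=small_disk.x[:1].copy(), k_ad=2.0, rest_length=5.0,
            formed_at=0.0, mature=True)
        r_pol, dt = 1.1e-3, 0.4
        update_polarization(cell, sys_, small_disk, dt)
        ang = np.arctan2(sys_.polarization.d_pol[1],
                         sys_.polarization.d_pol[0])
        expected = (np.pi / 2) * (1 - np.exp(-r_pol * dt))
        assert ang == pytest.approx(expected, rel=1e-6)


class TestGrowth:
    def test_force_magnitude_and_clipping(self, cell):
        sys_ = polarized_system(cell)
        prot = make_protrusion(cell, sys_, central=0)
        F = growth_forces(prot, cell, sys_.params)
        # central particle: outward normal parallel to d_prot
        assert np.linalg.norm(F[prot.central]) == pytest.approx(0.32,
                                                                rel=1e-3)
        # a particle with normal perpendicular to d_prot feels nothing
        side = (prot.central + 58) % cell.n     # ~90 degrees away
        assert np.linalg.norm(F[side]) == 0.0
        # forces act only on the 7 force particles
        mask = np.zeros(cell.n, dtype=bool)
        mask[prot.force_ids] = True
        assert np.all(F[~mask] == 0.0)

    def test_deflection_unchanged_in_intact_symmetric_ecm(self, cell,
                                                          small_disk):
        from protrudesim.protrusion import deflect_growth_direction
        sys_ = polarized_system(cell)
        prot = make_protrusion(cell, sys_, central=0)
        d0 = prot.d_prot.copy()
        deflect_growth_direction(prot, cell, small_disk, sys_.degradation,
                                 sys_.params, 0.4)
        assert np.allclose(prot.d_prot, d0)

    def test_deflection_rotates_towards_degraded_side(self, cell,
                                                      small_disk):
        from protrudesim.protrusion import deflect_growth_direction
        sys_ = polarized_system(cell)
        prot = make_protrusion(cell, sys_, central=0)
        tip = cell.x[prot.central]
        ahead = tip + 2.0 * prot.d_prot
        side = np.array([-prot.d_prot[1], prot.d_prot[0]])
        sel = np.linalg.norm(small_disk.x - (ahead + 2 * side), axis=1) < 2.5
        small_disk.f_degr[sel] = 0.0
        d0 = prot.d_prot.copy()
        deflect_growth_direction(prot, cell, small_disk, sys_.degradation,
                                 sys_.params, 0.4)
        cross = d0[0] * prot.d_prot[1] - d0[1] * prot.d_prot[0]
        assert cross > 0   # rotated toward the degraded (+) side


class TestAdhesion:
    def test_formation_geometry(self, cell, small_disk):
        sys_ = polarized_system(cell)
        prot = make_protrusion(cell, sys_, central=0)
        adh = form_adhesion(prot, cell, small_disk, sys_.adhesion_params, 0.0)
        assert adh is not None
        assert np.linalg.norm(adh.anchor0 - cell.x[prot.central]) == \
            pytest.approx(5.0)
        assert adh.weights.sum() == pytest.approx(1.0)
        _, fmag = adh.force(cell, small_disk)
        assert fmag == pytest.approx(0.0, abs=1e-12)

    def test_rigid_ecm_hooke(self, cell, small_disk):
        """Pulling the tip 1 um back from a pinned anchor gives
        k_ad * 1 um = 2 nN."""
        sys_ = polarized_system(cell)
        prot = make_protrusion(cell, sys_, central=0)
        adh = form_adhesion(prot, cell, small_disk, sys_.adhesion_params, 0.0)
        cell.x[prot.central] -= 1.0 * prot.d_prot
        fvec, fmag = adh.force(cell, small_disk)
        assert fmag == pytest.approx(2.0, rel=1e-6)
        assert fvec @ prot.d_prot > 0    # pulls the tip towards the anchor

    def test_aborts_in_fully_degraded_region(self, cell, small_disk):
        sys_ = polarized_system(cell)
        prot = make_protrusion(cell, sys_, central=0)
        anchor = cell.x[prot.central] + 5.0 * prot.d_prot
        near = np.linalg.norm(small_disk.x - anchor, axis=1) < \
            small_disk.kernel.support_radius + 0.1
        small_disk.f_degr[near] = 0.01
        assert form_adhesion(prot, cell, small_disk,
                             sys_.adhesion_params, 0.0) is None


class TestMaturationClock:
    def _scalar_oracle(self, k_ecm, mu_ecm, T_mat=600.0, dt=0.4,
                       k_ad=2.0, F_am=0.6, gamma_tip=2.0):
        """Independent 1-DOF mechanosensing oracle: adhesion spring in
        series with a Kelvin-Voigt matrix point, force stepped by
        0.1*F_am at each threshold crossing of the spring extension."""
        u_t = u_a = 0.0
        f_mat = 0.1
        ext_last = 0.0
        steps = []
        thr = 0.98 * 0.1 * F_am / k_ad
        t = 0.0
        while t < T_mat:
            F = f_mat * F_am
            T = k_ad * (u_t - u_a)
            u_t += dt * (F - T) / gamma_tip
            u_a += dt * (T - k_ecm * u_a) / mu_ecm
            ext = u_t - u_a
            if ext - ext_last >= thr and f_mat < 1.0 and len(steps) < 10:
                f_mat = min(1.0, f_mat + 0.1)
                steps.append(t)
                ext_last = ext
            t += dt
        return f_mat, steps

    def test_rigid_ecm_saturates(self):
        f_mat, steps = self._scalar_oracle(k_ecm=1e3, mu_ecm=1.0)
        assert f_mat == pytest.approx(1.0)
        assert len(steps) == 9 or len(steps) == 10

    def test_final_fmat_monotone_in_stiffness(self):
        """Mechanosensing: the final maturation factor is non-decreasing
        in matrix stiffness for a soft, viscous matrix point."""
        finals = [self._scalar_oracle(k, mu_ecm=50.0)[0]
                  for k in (0.02, 0.1, 0.5, 2.0, 10.0)]
        assert all(b >= a - 1e-12 for a, b in zip(finals, finals[1:]))
        assert finals[0] < finals[-1]

    def test_package_clock_against_oracle_updates(self, cell, small_disk):
        """The package's maturation_step fires exactly when the measured
        extension increment crosses 98% of one force step."""
        sys_ = polarized_system(cell)
        prot = make_protrusion(cell, sys_, central=0)
        prot.phase = "maturing"
        prot.t_phase = 0.0
        adh = form_adhesion(prot, cell, small_disk, sys_.adhesion_params, 0.0)
        prot.adhesion = adh
        thr = 0.98 * 0.1 * 0.6 / 2.0
        cell.x[prot.central] -= (thr - 1e-4) * prot.d_prot
        assert not maturation_step(prot, cell, small_disk,
                                   sys_.maturation, 0.4, 1.0)
        cell.x[prot.central] -= 2e-4 * prot.d_prot
        assert maturation_step(prot, cell, small_disk,
                               sys_.maturation, 0.4, 1.4)
        assert prot.f_mat == pytest.approx(0.2)

    def test_fmat_never_exceeds_one(self, cell, small_disk):
        sys_ = polarized_system(cell)
        prot = make_protrusion(cell, sys_, central=0)
        prot.phase = "maturing"
        adh = form_adhesion(prot, cell, small_disk, sys_.adhesion_params, 0.0)
        prot.adhesion = adh
        for k in range(40):
            cell.x[prot.central] -= 0.05 * prot.d_prot
            maturation_step(prot, cell, small_disk, sys_.maturation,
                            0.4, 0.4 * k)
        assert prot.f_mat <= 1.0
        assert len(prot.maturation_step_times) <= 10


class TestFinalize:
    @pytest.mark.parametrize("times,expected", [
        (list(np.arange(60.0, 601.0, 60.0)), 1.0),     # mean 60 s
        ([200.0, 400.0, 600.0], 0.3),                  # mean 200 s
    ])
    def test_final_fmat_from_mean_interval(self, cell, times, expected):
        sys_ = polarized_system(cell)
        prot = make_protrusion(cell, sys_, central=0)
        prot.phase = "maturing"
        prot.t_phase = 0.0
        prot.maturation_step_times = times
        finalize_maturation(prot, cell, sys_.params, sys_.maturation, 600.0)
        assert prot.f_mat == pytest.approx(expected)
        assert prot.phase == "contracting"
        # cortex stiffness restored in the window
        assert np.all(cell.k_seg[prot.member_segments] == cell.params.k_s)

    def test_zero_steps_keeps_initial_fmat(self, cell):
        sys_ = polarized_system(cell)
        prot = make_protrusion(cell, sys_, central=0)
        prot.phase = "maturing"
        finalize_maturation(prot, cell, sys_.params, sys_.maturation, 600.0)
        assert prot.f_mat == pytest.approx(0.1)


class TestContraction:
    def test_pair_tension_uses_minimum_fmat(self, cell):
        mat = MaturationParams()
        cell.f_mat[:] = 0.05
        cell.f_mat[10] = 1.0
        F = contraction_forces(cell, mat)
        # segment 9-10 and 10-11 both limited by min = 0.05: symmetric
        # neighbours cancel, so particle 10 feels only curvature residue
        base = contraction_forces(initialize_cell((0, 0), cell.params), mat)
        assert np.allclose(F[10], base[10], atol=1e-12)

    def test_curvature_factor_peaks_at_optimum(self):
        mat = MaturationParams()
        assert curvature_factor(mat.kappa0, mat) == pytest.approx(1.0)
        assert curvature_factor(mat.kappa0 + 0.5, mat) < 1.0
        assert 0.0 <= curvature_factor(5.0, mat) <= 1.0

    def test_straight_uniform_run_balances(self, cell):
        mat = MaturationParams()
        F = contraction_forces(cell, mat)
        # uniform ring: net force on each particle is purely radial and
        # tiny; total internal force vanishes
        assert np.linalg.norm(F.sum(axis=0)) < 1e-10

    def test_excluded_segments_carry_no_tension(self, cell):
        mat = MaturationParams()
        mask = np.zeros(cell.n, dtype=bool)
        mask[:] = True
        F = contraction_forces(cell, mat, exclude_segments=mask)
        assert np.allclose(F, 0.0)


class TestDisassembly:
    def test_zero_force_rate(self):
        p = DisassemblyParams()
        r = disassembly_rate(0.0, 0.5, p, F_am=0.6)
        assert r == pytest.approx(2.778e-4 + 0.2, rel=1e-9)

    def test_rupture_branch(self):
        p = DisassemblyParams(f_rupt=1.0)
        r = disassembly_rate(0.5 * 0.6 * 1.0, 0.5, p, F_am=0.6)
        assert r == 1e6

    def test_force_dependence_decays(self):
        p = DisassemblyParams(f_rupt=1e9)
        rates = [disassembly_rate(f, 1.0, p, F_am=0.6)
                 for f in (0.0, 0.1, 0.3, 0.55)]
        assert all(b < a for a, b in zip(rates, rates[1:]))
        assert rates[-1] == pytest.approx(p.r_off_min, rel=0.5)

    def test_force_independent_mode(self):
        p = DisassemblyParams(force_dependent=False)
        assert disassembly_rate(123.0, 0.9, p, F_am=0.6) == p.r_off_const

    def test_lifetimes_are_exponential_with_mean_one_over_rate(self):
        """At constant rate 5.56e-4/s sampled lifetimes average 30 min
        and pass a KS test against the exponential law."""
        r, dt = 5.56e-4, 0.4
        rng = np.random.default_rng(11)
        n = 10**4
        # per-step geometric sampling, as the simulation does
        u = rng.random((n, 1))
        lifetimes = (np.ceil(np.log(u) / np.log(np.exp(-r * dt)))
                     .ravel() * dt)
        mean = lifetimes.mean()
        expect = 1.0 / r
        sigma = expect / np.sqrt(n)
        assert abs(mean - expect) < 3.5 * sigma
        ks = stats.kstest(lifetimes, "expon", args=(0, 1 / r))
        assert ks.pvalue > 0.01


class TestDegradationTargets:
    def test_tip_zone_rules(self, cell, small_disk):
        sys_ = polarized_system(cell)
        prot = make_protrusion(cell, sys_, central=0)
        prot.phase = "growing"
        small_disk.sigma[:] = 0.0      # no pressure anywhere
        idx, rates = degradation_targets(cell, [prot], small_disk,
                                         sys_.degradation)
        # only the ungated tip rule fires without pressure
        assert np.all(rates == sys_.degradation.r_tip)
        tips = cell.x[prot.force_ids]
        for k in idx:
            d = np.linalg.norm(small_disk.x[k] - tips, axis=1).min()
            assert d <= sys_.degradation.d_tip + 1e-9

    def test_pressure_gate_blocks_body_rule(self, cell, small_disk):
        sys_ = make_system()
        small_disk.sigma[:, 0] = -2 * 0.01   # 10 Pa < 20 Pa threshold
        small_disk.sigma[:, 1] = -2 * 0.01
        idx, rates = degradation_targets(cell, [], small_disk,
                                         sys_.degradation)
        assert len(idx) == 0
        small_disk.sigma[:, 0] = -0.03       # 25 Pa > threshold
        small_disk.sigma[:, 1] = -0.02
        idx, rates = degradation_targets(cell, [], small_disk,
                                         sys_.degradation)
        assert len(idx) > 0
        assert np.all(rates == sys_.degradation.r_cell)

    def test_tip_rule_only_while_growing(self, cell, small_disk):
        sys_ = polarized_system(cell)
        prot = make_protrusion(cell, sys_, central=0)
        prot.phase = "maturing"
        small_disk.sigma[:] = 0.0
        idx, _ = degradation_targets(cell, [prot], small_disk,
                                     sys_.degradation)
        assert len(idx) == 0


class TestEnforcedScaling:
    @pytest.mark.parametrize("ratio,expected", [
        (1.0, 1.0), (2.0, 0.5), (0.8, 1.0)])
    def test_area_scaling(self, ratio, expected):
        mode = EnforcedProtrusionMode(enabled=True)
        assert protrusion_force_scaling(ratio * 100.0, 100.0, mode) == \
            pytest.approx(expected)

    def test_disabled_mode_never_scales(self):
        mode = EnforcedProtrusionMode(enabled=False)
        assert protrusion_force_scaling(500.0, 100.0, mode) == 1.0
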