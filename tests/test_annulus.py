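"""Analytic annulus flow, particle advection, and operating-point arithmetic."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from dtekit import (
    AnnulusFlowConfig,
    PumpCurve,
    SeedConfig,
    advect,
    analytic_sa,
    annulus_stress,
    annulus_velocity,
    calibrate_rpm,
    choose_duration,
    exit_fraction,
    mass_flow,
    rotations,
    sa_ensemble,
    scalar_stress,
    seed_particles,
    stress_accumulation,
    two_device_ensembles,
)
from dtekit.errors import ValidationError


class TestVelocityField:
    def test_no_slip_at_rotating_inner_wall(self, annulus_cfg):
        u_t, u_z = annulus_velocity(annulus_cfg.r_inner, annulus_cfg)
        assert u_t == pytest.approx(annulus_cfg.omega * annulus_cfg.r_inner,
                                    rel=1e-12)
        assert u_z == pytest.approx(0.0, abs=1e-12)

    def test_no_slip_at_fixed_outer_wall(self, annulus_cfg):
        u_t, u_z = annulus_velocity(annulus_cfg.r_outer, annulus_cfg)
        assert u_t == pytest.approx(0.0, abs=1e-9)
        assert u_z == pytest.approx(0.0, abs=1e-12)

    def test_flow_rate_quadrature(self, annulus_cfg):
        """2 pi Int u_z r dr over the annulus equals q (numerical oracle)."""
        val, _ = integrate.quad(
            lambda r: annulus_velocity(r, annulus_cfg)[1] * r,
            annulus_cfg.r_inner, annulus_cfg.r_outer, epsabs=1e-14,
        )
        assert 2 * math.pi * val == pytest.approx(annulus_cfg.q_m3s, rel=1e-6)

    def test_radius_outside_annulus_rejected(self, annulus_cfg):
        with pytest.raises(ValidationError):
            annulus_velocity(annulus_cfg.r_outer * 1.5, annulus_cfg)


class TestStressField:
    def test_theta_invariance_of_scalar_stress(self, annulus_cfg):
        r = 0.0045
        sig = [
            scalar_stress(annulus_stress(r, th, annulus_cfg))
            for th in np.linspace(0, 2 * math.pi, 17)
        ]
        np.testing.assert_allclose(sig, sig[0], rtol=1e-12)

    def test_finite_difference_oracle(self, annulus_cfg):
        """sigma from the tensor matches mu * |velocity gradient| built by
        central differences of the velocity field."""
        cfg = annulus_cfg
        for r in (0.0035, 0.0045, 0.0055):
            dr = 1e-7
            (ut_p, uz_p) = annulus_velocity(r + dr, cfg)
            (ut_m, uz_m) = annulus_velocity(r - dr, cfg)
            # swirl shear uses d(u_theta/r)/dr, axial uses du_z/dr
            d_omega = (ut_p / (r + dr) - ut_m / (r - dr)) / (2 * dr)
            tau_rt = cfg.mu * r * d_omega
            tau_rz = cfg.mu * (uz_p - uz_m) / (2 * dr)
            expect = math.hypot(tau_rt, tau_rz)
            got = scalar_stress(annulus_stress(r, 0.3, cfg))
            assert got == pytest.approx(expect, rel=1e-6)

    def test_zero_rotation_no_swirl_stress(self):
        cfg = AnnulusFlowConfig(omega=0.0)
        tau = annulus_stress(0.0045, 0.0, cfg)
        # at theta=0: tau12 carries the full swirl shear
        assert tau[3] == 0.0
        assert tau[0] == tau[1] == 0.0


class TestSeeding:
    def test_deterministic(self, annulus_cfg):
        sc = SeedConfig(n_particles=100, seed=5)
        np.testing.assert_array_equal(
            seed_particles(annulus_cfg, sc), seed_particles(annulus_cfg, sc)
        )

    def test_support_and_plane(self, annulus_cfg):
        sc = SeedConfig(n_particles=500, seed=5)
        pos = seed_particles(annulus_cfg, sc)
        r = np.hypot(pos[:, 0], pos[:, 1])
        assert np.all((r >= annulus_cfg.r_inner) & (r <= annulus_cfg.r_outer))
        assert np.all(pos[:, 2] == 0.0)

    def test_area_uniform_radii(self, annulus_cfg):
        """r^2 uniform on [ri^2, ro^2]: KS test at alpha = 0.01, n = 9800."""
        sc = SeedConfig(n_particles=9800, seed=11)
        pos = seed_particles(annulus_cfg, sc)
        r2 = pos[:, 0] ** 2 + pos[:, 1] ** 2
        u = (r2 - annulus_cfg.r_inner**2) / (
            annulus_cfg.r_outer**2 - annulus_cfg.r_inner**2
        )
        assert stats.kstest(u, "uniform").pvalue > 0.01


class TestAdvection:
    def test_radius_conserved(self, advected):
        for tr in advected.trajectories[:50]:
            r = tr.radius()
            np.testing.assert_allclose(r, r[0], rtol=1e-9)

    def test_exited_iff_reached_length(self, advected, annulus_cfg):
        for tr in advected:
            final_z = tr.pos[-1, 2]
            if tr.exited:
                assert final_z == pytest.approx(annulus_cfg.length, rel=1e-12)
            else:
                assert final_z < annulus_cfg.length

    def test_sa_matches_closed_form(self, advected, annulus_cfg):
        sa = sa_ensemble(advected, completed_only=True)
        ids = {tr.particle_id: tr for tr in advected}
        for pid, value in zip(sa.particle_ids, sa.values):
            r = ids[pid].radius()[0]
            assert value == pytest.approx(analytic_sa(r, annulus_cfg),
                                          rel=1e-3)

    def test_deterministic(self, annulus_cfg):
        sc = SeedConfig(n_particles=20, seed=3, max_duration=0.05)
        seeds = seed_particles(annulus_cfg, sc)
        e1 = advect(annulus_cfg, seeds, sc)
        e2 = advect(annulus_cfg, seeds, sc)
        for t1, t2 in zip(e1, e2):
            np.testing.assert_array_equal(t1.t, t2.t)
            np.testing.assert_array_equal(t1.tau, t2.tau)

    def test_bad_dt_rejected(self, annulus_cfg):
        with pytest.raises(ValidationError):
            SeedConfig(dt=0.0)


class TestAnalyticSA:
    def test_linear_in_length(self, annulus_cfg):
        import dataclasses

        double = dataclasses.replace(annulus_cfg, length=2 * annulus_cfg.length)
        assert analytic_sa(0.0045, double) == pytest.approx(
            2 * analytic_sa(0.0045, annulus_cfg), rel=1e-12
        )

    def test_linear_in_viscosity(self, annulus_cfg):
        import dataclasses

        thick = dataclasses.replace(annulus_cfg, mu=2 * annulus_cfg.mu)
        assert analytic_sa(0.0045, thick) == pytest.approx(
            2 * analytic_sa(0.0045, annulus_cfg), rel=1e-12
        )

    def test_midgap_matches_dense_quadrature(self, annulus_cfg):
        """SA = Int sigma dt along the transit, by dense time sampling."""
        r = 0.5 * (annulus_cfg.r_inner + annulus_cfg.r_outer)
        _, u_z = annulus_velocity(r, annulus_cfg)
        transit = annulus_cfg.length / u_z
        t = np.linspace(0, transit, 200_001)
        sigma = scalar_stress(annulus_stress(r, 0.0, annulus_cfg))  # constant
        quad = np.trapezoid(np.full_like(t, sigma), t) * 10.0  # Pa.s -> CGS
        assert analytic_sa(r, annulus_cfg) == pytest.approx(quad, rel=1e-8)

    def test_wall_radius_rejected(self, annulus_cfg):
        with pytest.raises(ValidationError):
            analytic_sa(annulus_cfg.r_outer, annulus_cfg)


class TestOperatingPoint:
    def test_calibrate_rpm_closed_form_trivial(self):
        curve = PumpCurve(head_coefficient=1.0)
        assert calibrate_rpm(curve, 5.3, 10_000.0) == pytest.approx(100.0)

    def test_calibrate_rpm_matches_closed_form_randomized(self, rng):
        for _ in range(25):
            a = rng.uniform(1e-4, 10.0)
            b = rng.uniform(0.0, 5.0)
            q = rng.uniform(0.5, 10.0)
            head = rng.uniform(0.0, 2e4)
            expect = math.sqrt((head + b * q**2) / a)
            assert calibrate_rpm(PumpCurve(a, b), q, head) == pytest.approx(
                expect, rel=1e-8
            )

    def test_zero_head_zero_loss(self):
        assert calibrate_rpm(PumpCurve(1.0, 0.0), 5.0, 0.0) == 0.0

    def test_unachievable_head(self):
        with pytest.raises(ValidationError):
            calibrate_rpm(PumpCurve(1.0, 10.0), 10.0, -2000.0)

    def test_rotations_printed_values(self):
        assert rotations(10_600, 0.105) == pytest.approx(18.55, abs=1e-10)
        assert rotations(11_600, 0.105) == pytest.approx(20.3, abs=1e-10)
        assert rotations(5_000, 0.0) == 0.0

    def test_mass_flow_values(self):
        # 5.3 L/min of 1080 kg/m^3 blood analog: 9.54e-2 kg/s
        assert mass_flow(5.3, 1080.0) == pytest.approx(9.548e-2, rel=1e-3)
        assert mass_flow(60.0, 1000.0) == pytest.approx(1.0, rel=1e-12)

    def test_mass_flow_linearity(self):
        assert mass_flow(10.6, 1080.0) == pytest.approx(
            2 * mass_flow(5.3, 1080.0), rel=1e-12
        )


class TestChooseDuration:
    def test_plug_flow_single_transit_time(self):
        cfg = AnnulusFlowConfig(plug_flow=True)
        sc = SeedConfig(n_particles=200, seed=0, max_duration=1.0)
        u_z = cfg.q_m3s / cfg.annulus_area
        transit = cfg.length / u_z
        for target in (0.1, 0.5, 0.9):
            dur = choose_duration(cfg, sc, target)
            assert dur == pytest.approx(transit, rel=1e-2)

    def test_unreachable_target_returns_cap_with_warning(self, annulus_cfg):
        sc = SeedConfig(n_particles=100, seed=0, max_duration=1e-4)
        with pytest.warns(UserWarning, match="cap|max_duration"):
            dur = choose_duration(annulus_cfg, sc, 1.0)
        assert dur == sc.max_duration

    def test_monotone_in_target(self, annulus_cfg):
        sc = SeedConfig(n_particles=300, seed=2, max_duration=10.0)
        durs = [choose_duration(annulus_cfg, sc, x)
                for x in (0.2, 0.5, 0.8, 0.9)]
        assert durs == sorted(durs)

    def test_duration_is_multiple_of_dt(self, annulus_cfg):
        sc = SeedConfig(n_particles=300, seed=2, max_duration=10.0)
        dur = choose_duration(annulus_cfg, sc, 0.9)
        assert dur / sc.dt == pytest.approx(round(dur / sc.dt), abs=1e-9)

    def test_achieved_exit_fraction(self, annulus_cfg):
        """Advecting for the chosen duration reaches the exit target."""
        sc = SeedConfig(n_particles=200, seed=4, max_duration=2.0)
        dur = choose_duration(annulus_cfg, sc, 0.9)
        sc_run = SeedConfig(n_particles=200, seed=4, max_duration=dur)
        ens = advect(annulus_cfg, seed_particles(annulus_cfg, sc_run), sc_run)
        assert exit_fraction(ens) >= 0.9


class TestTwoDevices:
    def test_recirculation_scales_sa_subpopulation(self, annulus_cfg):
        sc = SeedConfig(n_particles=100, seed=9, max_duration=0.28)
        ens_min, ens_max = two_device_ensembles(
            annulus_cfg, sc, recirc_fraction=0.3, residence_multiplier=5.0,
            seed=17,
        )
        ratios = np.array([
            stress_accumulation(b, "Pa") / stress_accumulation(a, "Pa")
            for a, b in zip(ens_min, ens_max)
        ])
        n_scaled = int(np.sum(np.isclose(ratios, 5.0, rtol=1e-9)))
        n_same = int(np.sum(np.isclose(ratios, 1.0, rtol=1e-9)))
        assert n_scaled == 30
        assert n_same == 70

    def test_zero_fraction_identical(self, annulus_cfg):
        sc = SeedConfig(n_particles=30, seed=9, max_duration=0.1)
        ens_min, ens_max = two_device_ensembles(
            annulus_cfg, sc, recirc_fraction=0.0
        )
        for a, b in zip(ens_min, ens_max):
            np.testing.assert_array_equal(a.t, b.t)
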