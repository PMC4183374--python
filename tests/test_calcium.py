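"""Calcium trace propagation and stationary shot-noise statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synca import calcium as cs
from synca.params import PlasticityParams


class TestDecayAndJump:
    def test_jump_from_zero(self, in_vitro):
        s = cs.CalciumState()
        s = cs.decay_and_jump(s, 0.0, in_vitro.C_post, in_vitro.tau_ca_s)
        assert s.c == pytest.approx(1.23964)

    def test_lone_post_spike_time_above_threshold(self, in_vitro):
        # c = C_post decays to theta_d = 1 after tau_Ca ln(C_post) ~ 4.875 ms
        t_cross = in_vitro.tau_ca_s * math.log(in_vitro.C_post)
        assert t_cross == pytest.approx(4.875e-3, rel=1e-3)
        s = cs.CalciumState(c=in_vitro.C_post, t_last=0.0)
        s = cs.decay_and_jump(s, t_cross, 0.0, in_vitro.tau_ca_s)
        assert s.c == pytest.approx(in_vitro.theta_d)

    def test_single_in_vivo_pre_spike_never_crosses(self, in_vivo):
        # 0.33705 < theta_d and the decay is monotone
        assert in_vivo.C_pre < in_vivo.theta_d

    def test_event_ordering_enforced(self, in_vitro):
        s = cs.CalciumState(c=1.0, t_last=1.0)
        with pytest.raises(ValueError, match="ordering"):
            cs.decay_and_jump(s, 0.5, 1.0, in_vitro.tau_ca_s)


class TestThresholdPartition:
    TAU = 0.0226936

    def test_below_threshold(self):
        assert cs.threshold_crossing_partition(0.5, 1.0, 1.0, 1.3, self.TAU) \
            == (0.0, 0.0, 1.0)

    def test_closed_form_long_interval(self):
        c0, dt = 2.0, 10.0
        t_p, t_b, t_lo = cs.threshold_crossing_partition(c0, dt, 1.0, 1.3,
                                                         self.TAU)
        assert t_p == pytest.approx(self.TAU * math.log(c0 / 1.3))
        assert t_b == pytest.approx(self.TAU * math.log(1.3 / 1.0))
        assert t_p + t_b + t_lo == pytest.approx(dt)

    @pytest.mark.parametrize("seed", range(5))
    def test_against_dense_sampling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        c0 = float(rng.uniform(0.0, 4.0))
        dt = float(rng.uniform(0.0, 0.2))
        t_p, t_b, t_lo = cs.threshold_crossing_partition(c0, dt, 1.0, 1.3,
                                                         self.TAU)
        s = np.linspace(0.0, dt, 200_001)
        c = c0 * np.exp(-s / self.TAU)
        h = dt / 200_000 if dt > 0 else 0.0
        assert t_p == pytest.approx(np.sum(c > 1.3) * h, abs=2 * h + 1e-12)
        assert t_b == pytest.approx(np.sum((c > 1.0) & (c <= 1.3)) * h,
                                    abs=2 * h + 1e-12)
        assert t_p + t_b + t_lo == pytest.approx(dt)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(0.0, 10.0), st.floats(0.0, 1.0))
    def test_partition_nonnegative_and_sums(self, c0, dt):
        t_p, t_b, t_lo = cs.threshold_crossing_partition(c0, dt, 1.0, 1.3,
                                                         self.TAU)
        assert t_p >= 0 and t_b >= -1e-15 and t_lo >= -1e-12
        assert t_p + t_b + t_lo == pytest.approx(dt, abs=1e-12)

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            cs.threshold_crossing_partition(1.0, -0.1, 1.0, 1.3, self.TAU)


class TestMinSpikes:
    def test_presets(self, in_vitro, in_vivo):
        assert cs.min_spikes_to_cross(in_vitro, in_vitro.theta_d) == 1
        assert cs.min_spikes_to_cross(in_vivo, in_vivo.theta_d) == 2
        # two post jumps clear the threshold: 2 * 0.74378 = 1.48756 >= 1
        assert 2 * in_vivo.C_post >= in_vivo.theta_d

    def test_artificial_three_spike_parameters(self, in_vitro):
        import dataclasses
        p3 = dataclasses.replace(in_vitro, C_pre=1.0 / 3, C_post=1.0 / 3)
        assert cs.min_spikes_to_cross(p3, 1.0) == 3

    def test_single_jump_sufficient(self, in_vitro):
        assert cs.min_spikes_to_cross(in_vitro, 1.2) == 1


class TestStationaryPDF:
    def test_zero_rate_degenerate(self, in_vitro):
        pdf = cs.stationary_pdf_numeric(0.0, 0.0, in_vitro)
        assert pdf.point_mass_at_zero == 1.0
        assert pdf.alpha_d == 0.0 and pdf.alpha_p == 0.0

    def test_closed_form_matches_numeric(self, equal_amp_params):
        cf = cs.stationary_pdf_closed_form(2.0, 1.0, 22.6936)
        nm = cs.stationary_pdf_numeric(1.0, 1.0, equal_amp_params)
        # compare at shared grid nodes (the density has infinite-slope cusps
        # at the jump-amplitude lattice points, so interpolating onto an
        # unrelated grid would only measure interpolation error)
        step = round(nm.grid[1] / cf.grid[1])
        n_common = min(cf.grid.size // step, nm.grid.size)
        d_cf = cf.density[::step][:n_common]
        d_nm = nm.density[:n_common]
        sel = (nm.grid[:n_common] >= 0.05) & (nm.grid[:n_common] <= 5.0)
        assert np.allclose(cf.grid[::step][:n_common], nm.grid[:n_common])
        assert np.max(np.abs(d_cf[sel] - d_nm[sel])) < 1e-4
        assert nm.alpha_d == pytest.approx(cf.alpha_d, abs=1e-6)
        assert nm.alpha_p == pytest.approx(cf.alpha_p, abs=1e-6)

    def test_closed_form_guard(self, in_vitro):
        with pytest.raises(ValueError, match="stationary_pdf_numeric"):
            cs.closed_form_guard(in_vitro)

    def test_density_consistent_with_cdf(self, in_vitro):
        # away from the near-zero singularity the density must integrate to
        # the stored cumulative differences
        pdf = cs.stationary_pdf_numeric(1.0, 1.0, in_vitro)
        from scipy.integrate import simpson
        lo = np.searchsorted(pdf.grid, 0.6)
        hi = np.searchsorted(pdf.grid, 3.0)
        mass = simpson(pdf.density[lo:hi + 1], x=pdf.grid[lo:hi + 1])
        expected = (pdf.cdf_values[hi] - pdf.cdf_values[lo]) / pdf.Z
        # Simpson crosses the infinite-slope cusps at the jump-amplitude
        # lattice points, so quadrature (not solver) error dominates here
        assert mass == pytest.approx(expected, abs=5e-5)

    def test_total_probability(self, in_vitro):
        pdf = cs.stationary_pdf_numeric(1.0, 1.0, in_vitro)
        from scipy.integrate import simpson
        tail = simpson(pdf.density[1:], x=pdf.grid[1:])
        # point mass covers [0, h); Simpson of the singular head carries the
        # only quadrature error
        assert pdf.point_mass_at_zero + tail == pytest.approx(1.0, abs=5e-3)
        # the cumulative representation itself is exactly normalised
        assert pdf.cdf_values[-1] / pdf.Z == pytest.approx(1.0, abs=1e-9)

    def test_alpha_ordering(self, in_vitro, in_vivo):
        for p in (in_vitro, in_vivo):
            pdf = cs.stationary_pdf_numeric(1.3, 0.7, p)
            assert 0.0 <= pdf.alpha_p <= pdf.alpha_d <= 1.0

    def test_lone_post_spike_lower_bound(self, in_vitro):
        # independent lower bound: isolated post spikes alone keep calcium
        # above theta_d a fraction nu_post * tau_Ca * ln(C_post / theta_d)
        pdf = cs.stationary_pdf_numeric(1.0, 1.0, in_vitro)
        bound = 1.0 * in_vitro.tau_ca_s * math.log(
            in_vitro.C_post / in_vitro.theta_d)
        assert bound == pytest.approx(0.004875, rel=1e-3)
        assert pdf.alpha_d >= bound

    def test_monotone_in_rate(self, in_vivo):
        rates = [0.5, 1.0, 2.0, 4.0]
        a_d = [cs.stationary_pdf_numeric(nu, nu, in_vivo).alpha_d
               for nu in rates]
        a_p = [cs.stationary_pdf_numeric(nu, nu, in_vivo).alpha_p
               for nu in rates]
        assert np.all(np.diff(a_d) > 0) and np.all(np.diff(a_p) > 0)

    def test_coarse_grid_rejected(self, in_vitro):
        with pytest.raises(ValueError, match="coarse"):
            cs.stationary_pdf_numeric(1.0, 1.0, in_vitro, points_per_panel=2)

    @pytest.mark.parametrize("seed", range(5))
    def test_monte_carlo_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = PlasticityParams(
            C_pre=float(rng.uniform(0.3, 1.2)),
            C_post=float(rng.uniform(0.3, 1.5)),
            tau_Ca=float(rng.uniform(10.0, 40.0)), D=4.6,
            theta_d=1.0, theta_p=1.3, gamma_d=100.0, gamma_p=300.0,
            sigma=1.0, tau_rho=100.0)
        nu_pre = float(rng.uniform(0.5, 3.0))
        nu_post = float(rng.uniform(0.5, 3.0))
        pdf = cs.stationary_pdf_numeric(nu_pre, nu_post, p)
        ad, ap, sd, sp = cs.monte_carlo_alpha(nu_pre, nu_post, p,
                                              n_events=600_000, seed=seed)
        assert abs(pdf.alpha_d - ad) < 3.0 * sd
        assert abs(pdf.alpha_p - ap) < 3.0 * sp


class TestLowRateAsymptotics:
    def test_single_spike_law(self, equal_amp_params):
        import dataclasses
        p = dataclasses.replace(equal_amp_params, C_pre=1.2, C_post=1.2)
        for nu in (0.05, 0.02):
            exact = cs.stationary_pdf_numeric(nu, nu, p).alpha_d
            asym = cs.low_rate_alpha(1.0, 1.2, 2 * nu, p.tau_ca_s)
            assert exact / asym == pytest.approx(1.0, abs=0.05)

    def test_two_spike_law_dilogarithm_integral(self, equal_amp_params):
        import dataclasses
        p = dataclasses.replace(equal_amp_params, C_pre=0.6, C_post=0.6)
        ratios = []
        for nu in (0.1, 0.05, 0.02):
            exact = cs.stationary_pdf_numeric(nu, nu, p).alpha_d
            asym = cs.low_rate_alpha(1.0, 0.6, 2 * nu, p.tau_ca_s)
            ratios.append(exact / asym)
        # ratio approaches 1 from above as the rate decreases
        assert ratios[-1] == pytest.approx(1.0, abs=0.02)
        assert ratios[0] >= ratios[-1] - 1e-9
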