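"""Physics kernel: Langevin statics, Néel time, Debye response, loss power."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ferroheat.constants import Environment
from ferroheat.slp import (
    FieldSpec,
    ParticleSpec,
    debye_components,
    initial_susceptibility,
    langevin,
    magnetization,
    neel_relaxation_time,
    specific_loss_power,
    static_susceptibility,
    xi_argument,
)

ENV = Environment()
ANCHOR_X = (0.0, 0.05, 0.1, 0.2, 0.4, 0.67, 0.8, 1.0)


class TestLangevin:
    def test_zero_and_saturation(self):
        assert langevin(0.0) == 0.0
        assert langevin(1e3) >= 0.999  # = 1 - 1/1e3 to machine precision
        assert langevin(1e4) > 0.999

    def test_frozen_value(self):
        # coth(8.034) - 1/8.034 evaluated independently
        assert langevin(8.034) == pytest.approx(0.8755292120169474, abs=1e-12)

    def test_odd(self):
        xs = np.linspace(-5, 5, 101)
        assert np.allclose(langevin(xs), -langevin(-xs), atol=1e-15)

    def test_strictly_increasing_and_bounded(self):
        xs = np.linspace(0.0, 50, 5001)
        L = langevin(xs)
        assert np.all(np.diff(L) > 0)
        assert np.all(L <= np.minimum(1.0, xs / 3) + 1e-15)

    def test_series_matches_closed_form_at_switch(self):
        # just above the switch both branches are accurate; they must agree
        xi = 1.2e-4
        series = xi / 3 - xi**3 / 45
        assert langevin(xi) == pytest.approx(series, rel=1e-8)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            langevin(np.inf)


class TestMagnetization:
    def test_limits(self):
        assert magnetization(480e3, 0.0) == 0.0
        assert magnetization(480e3, 1e4) == pytest.approx(480e3, rel=1e-3)

    def test_frozen_value(self):
        assert magnetization(480e3, 8.034) == pytest.approx(420254.02, abs=1.0)

    def test_negative_msat_rejected(self):
        with pytest.raises(ValueError):
            magnetization(-1.0, 1.0)


class TestNeelTime:
    def test_zero_barrier_gives_attempt_time(self):
        assert neel_relaxation_time(0.0, 10e-9, ENV, tau0=1e-9) == pytest.approx(1e-9)

    @pytest.mark.parametrize(
        "K, D_nm, expected_s",
        [(11e3, 17.4, 1.5184623397e-06), (200e3, 6.7, 2.0064288229e-06)],
    )
    def test_frozen_values(self, K, D_nm, expected_s):
        assert neel_relaxation_time(K, D_nm * 1e-9, ENV) == pytest.approx(
            expected_s, rel=1e-9
        )

    def test_monotone_in_K_and_D(self):
        t1 = neel_relaxation_time(100e3, 10e-9, ENV)
        assert neel_relaxation_time(200e3, 10e-9, ENV) > t1
        assert neel_relaxation_time(100e3, 11e-9, ENV) > t1

    def test_overflow_reported_with_exponent(self):
        with pytest.raises(OverflowError, match="exponent"):
            neel_relaxation_time(294e3, 60e-9, ENV)


class TestSusceptibilities:
    def test_xi_frozen_value_and_linearity(self):
        xi = xi_argument(480e3, 17.4e-9, 20e3, ENV)
        assert xi == pytest.approx(8.0338353503, rel=1e-9)
        assert xi_argument(480e3, 17.4e-9, 40e3, ENV) == pytest.approx(2 * xi, rel=1e-12)
        assert xi_argument(480e3, 17.4e-9, 0.0, ENV) == 0.0

    def test_chi_i_frozen_value_and_cubic_scaling(self):
        chi = initial_susceptibility(480e3, 17.4e-9, 0.1, ENV)
        assert chi == pytest.approx(6.4270682802, rel=1e-9)
        assert initial_susceptibility(480e3, 34.8e-9, 0.1, ENV) == pytest.approx(
            8 * chi, rel=1e-12
        )
        assert initial_susceptibility(480e3, 17.4e-9, 0.0, ENV) == 0.0

    def test_static_limit_and_composite(self):
        assert static_susceptibility(6.43, 1e-8) == pytest.approx(6.43, rel=1e-9)
        assert static_susceptibility(6.4270682802, 8.0338353503) == pytest.approx(
            2.1012639867, rel=1e-6
        )

    def test_static_ratio_nonincreasing_in_xi(self):
        xs = np.linspace(1e-6, 50, 2000)
        ratio = static_susceptibility(np.ones_like(xs), xs)
        assert np.all(np.diff(ratio) < 1e-15)
        assert np.all(ratio <= 1.0 + 1e-12)


class TestDebye:
    def test_peak_at_omega_tau_one(self):
        chi_r, chi_im = debye_components(2.0, 1.0 / (2 * np.pi), 1.0)  # u = 1
        assert chi_im == pytest.approx(1.0, rel=1e-12)
        assert chi_r == pytest.approx(1.0, rel=1e-12)

    def test_static_limit(self):
        chi_r, chi_im = debye_components(2.0, 0.0, 1.0)
        assert (chi_r, chi_im) == (2.0, 0.0)

    def test_large_omega_tau_no_overflow(self):
        chi_r, chi_im = debye_components(1.0, 1e6 / (2 * np.pi), 1.0)  # u = 1e6
        assert chi_im == pytest.approx(1e-6, rel=1e-6)
        assert chi_r == pytest.approx(1e-12, rel=1e-6)
        _, huge = debye_components(1.0, 1e150, 1e150)
        assert np.isfinite(huge) and huge >= 0

    def test_imag_bounded_by_half_static(self):
        u = np.logspace(-6, 6, 1001)
        _, chi_im = debye_components(np.full_like(u, 3.0), u / (2 * np.pi), np.ones_like(u))
        assert np.all(chi_im <= 1.5 + 1e-12)


def _ps_composite(x, D, H, f, epsilon=0.1, tau0=1e-9, env=ENV):
    """Independent single-expression route: saturation-corrected Debye loss."""
    from ferroheat.materials import anisotropy_constant, density, spontaneous_magnetization

    Ms = spontaneous_magnetization(x)
    K = anisotropy_constant(x)
    rho = density(x)
    xi = np.pi * env.mu0 * Ms * D**3 * H / (6 * env.kB * env.T)
    chi_i = epsilon * np.pi * env.mu0 * Ms**2 * D**3 / (18 * env.kB * env.T)
    tau = tau0 * np.exp(np.pi * K * D**3 / (6 * env.kB * env.T))
    u = 2 * np.pi * f * tau
    # own stable Langevin branch: the closed form alone loses ~1e-8 relative
    # accuracy near xi ~ 1e-4 to cancellation
    L = np.where(xi < 1e-4, xi / 3 - xi**3 / 45, 1 / np.tanh(xi) - 1 / xi)
    return 3 * np.pi * env.mu0 * chi_i / (rho * xi) * L * (u / (1 + u**2)) * f * H**2


class TestSpecificLossPower:
    def test_zero_field_gives_zero(self):
        res = specific_loss_power(0.0, ParticleSpec(D=16e-9), FieldSpec(H=0.0, f=500e3))
        assert res.Ps == 0.0

    def test_table_point_bio_limit_x0(self):
        res = specific_loss_power(0.0, ParticleSpec(D=16.1e-9), FieldSpec(H=10e3, f=500e3))
        assert res.Ps_W_per_g == pytest.approx(62.29, abs=0.1)

    def test_table_point_low_frequency_x0(self):
        res = specific_loss_power(0.0, ParticleSpec(D=17.4e-9), FieldSpec(H=20e3, f=100e3))
        assert res.Ps_W_per_g == pytest.approx(31.69, abs=0.3)

    def test_result_internal_consistency(self):
        res = specific_loss_power(0.2, ParticleSpec(D=7e-9), FieldSpec(H=20e3, f=250e3))
        u = res.omega_tau
        assert res.chi_real == pytest.approx(res.chi0 / (1 + u**2), rel=1e-12)
        assert res.chi_imag == pytest.approx(res.chi0 * u / (1 + u**2), rel=1e-12)
        assert 0 <= res.langevin < 1
        assert res.chi0 <= res.chi_i

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        x=st.sampled_from(ANCHOR_X),
        D_nm=st.floats(1.0, 20.0),
        H_kA=st.floats(1.0, 50.0),
        f_kHz=st.floats(100.0, 500.0),
    )
    def test_route_equivalence(self, x, D_nm, H_kA, f_kHz):
        """The composed Debye route equals the single-expression form to 1e-12."""
        res = specific_loss_power(
            x, ParticleSpec(D=D_nm * 1e-9), FieldSpec(H=H_kA * 1e3, f=f_kHz * 1e3)
        )
        expected = _ps_composite(x, D_nm * 1e-9, H_kA * 1e3, f_kHz * 1e3)
        assert res.Ps == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_H_and_f(self):
        H = np.linspace(5e3, 50e3, 30)
        ps_H = [
            specific_loss_power(0.1, ParticleSpec(D=9e-9), FieldSpec(H=h, f=250e3)).Ps
            for h in H
        ]
        assert np.all(np.diff(ps_H) > 0)
        f = np.linspace(100e3, 500e3, 30)
        ps_f = [
            specific_loss_power(0.1, ParticleSpec(D=9e-9), FieldSpec(H=20e3, f=fi)).Ps
            for fi in f
        ]
        assert np.all(np.diff(ps_f) > 0)

    def test_linear_response_limit(self):
        """As H → 0, Ps/H² approaches the χ_i-based linear-response constant."""
        x, D, f = 0.0, 16e-9, 500e3
        from ferroheat.materials import anisotropy_constant, density, spontaneous_magnetization

        rho = density(x)
        chi_i = initial_susceptibility(spontaneous_magnetization(x), D, 0.1, ENV)
        tau = neel_relaxation_time(anisotropy_constant(x), D, ENV)
        u = 2 * np.pi * f * tau
        limit = np.pi * ENV.mu0 * chi_i * (u / (1 + u**2)) * f / rho
        H = 1.0  # xi ~ 4e-4 here: deep in the linear regime
        ps = specific_loss_power(x, ParticleSpec(D=D), FieldSpec(H=H, f=f)).Ps
        assert ps / H**2 == pytest.approx(limit, rel=1e-4)

    def test_no_overflow_on_study_box(self):
        D = np.linspace(1e-9, 20e-9, 200)
        for x in ANCHOR_X:
            for H in (10e3, 50e3):
                for f in (100e3, 500e3):
                    res = specific_loss_power(
                        x, ParticleSpec(D=D), FieldSpec(H=H, f=f)
                    )
                    assert np.all(np.isfinite(res.Ps)) and np.all(res.Ps >= 0)

    def test_single_interior_peak_over_diameter(self):
        """P_s(D) rises to one interior maximum and falls, for every anchor."""
        D = np.linspace(1e-9, 20e-9, 19001)
        for x in ANCHOR_X:
            ps = specific_loss_power(x, ParticleSpec(D=D), FieldSpec(H=20e3, f=500e3)).Ps
            i = int(np.argmax(ps))
            assert 0 < i < len(D) - 1
            sign_changes = np.sum(np.diff(np.sign(np.diff(ps))) != 0)
            assert sign_changes == 1


class TestSpecValidation:
    def test_particle_spec_rejects_bad_values(self):
        with pytest.raises(ValueError):
            ParticleSpec(D=-1e-9)
        with pytest.raises(ValueError):
            ParticleSpec(D=1e-9, epsilon=0.0)
        with pytest.raises(ValueError):
            ParticleSpec(D=1e-9, tau0=0.0)

    def test_field_spec_rejects_negative(self):
        with pytest.raises(ValueError):
            FieldSpec(H=-1.0, f=100e3)

    def test_environment_requires_positive_temperature(self):
        with pytest.raises(ValueError):
            Environment(T=0.0)
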