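"""Unit and property tests for the EPG operators."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st
from scipy.integrate import solve_ivp

from afisim.epg import (ConfigurationStateSet, TissueComponent,
                        cartesian_pulse_rotation, diffusion_damping,
                        excitation_matrix, gradient_shift, precess, relax,
                        rf_rotation)


def random_state(seed: int, n: int = 6) -> ConfigurationStateSet:
    rng = np.random.default_rng(seed)
    fp = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    fm = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    fm[0] = np.conj(fp[0])
    z = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    z[0] = rng.uniform(0, 1)
    s = ConfigurationStateSet(f_plus=fp, f_minus=fm, z=z)
    # normalize so the invariants about m0 make sense
    scale = max(np.sqrt(s.transverse_energy()), 1.0)
    s.f_plus /= scale
    s.f_minus /= scale
    s.z /= scale
    return s


class TestTissueComponent:
    def test_validation(self):
        with pytest.raises(ValueError):
            TissueComponent(t1_ms=-1, t2_ms=100)
        with pytest.raises(ValueError):
            TissueComponent(t1_ms=100, t2_ms=50, adc_um2_s=-5)
        with pytest.warns(UserWarning):
            TissueComponent(t1_ms=100, t2_ms=200)


class TestRFRotation:
    def test_zero_rotation_is_identity(self):
        s = random_state(3)
        out = rf_rotation(s, 0.0, 45.0)
        np.testing.assert_allclose(out.f_plus, s.f_plus, atol=1e-14)
        np.testing.assert_allclose(out.z, s.z, atol=1e-14)

    def test_inversion(self):
        s = ConfigurationStateSet.equilibrium()
        out = rf_rotation(s, 180.0, 0.0)
        assert out.z[0] == pytest.approx(-1.0, abs=1e-12)
        assert abs(out.f_plus[0]) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("flip,phase,dnu", [
        (60.0, 0.0, 747.0),
        (60.0, 117.0, 320.0),
        (90.0, 30.0, -500.0),
        (20.0, 250.0, 0.0),
    ])
    def test_matches_bloch_integration(self, flip, phase, dnu):
        """Hard-pulse rotation equals stepwise Bloch integration to 1e-9.

        The oracle integrates the rotating-frame Bloch equations for
        the same rectangular pulse with an adaptive ODE solver.
        """
        tau = 0.5e-3
        w1 = np.deg2rad(flip) / tau
        dw = 2 * np.pi * dnu
        p = np.deg2rad(phase)
        b_x, b_y = w1 * np.cos(p), w1 * np.sin(p)

        def rhs(_t, m):
            mx, my, mz = m
            return [dw * my + b_y * mz,
                    -dw * mx - b_x * mz,
                    b_x * my - b_y * mx]

        sol = solve_ivp(rhs, (0, tau), [0.0, 0.0, 1.0], rtol=1e-12,
                        atol=1e-14, dense_output=False)
        mx, my, mz = sol.y[:, -1]
        state = rf_rotation(ConfigurationStateSet.equilibrium(), flip, phase,
                            0.5, dnu)
        assert state.f_plus[0] == pytest.approx(mx + 1j * my, abs=1e-9)
        assert state.z[0].real == pytest.approx(mz, abs=1e-9)

    def test_off_resonance_continuity(self):
        """The off-resonant matrix tends to the on-resonant one as Δν→0."""
        t_on = excitation_matrix(60.0, 30.0, 0.5, 0.0)
        t_near = excitation_matrix(60.0, 30.0, 0.5, 1e-6)
        np.testing.assert_allclose(t_near, t_on, atol=1e-8)

    def test_off_resonant_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            cartesian_pulse_rotation(60.0, 0.0, 0.0, 320.0)

    def test_conjugate_symmetry_preserved(self):
        """f_minus[0] stays the conjugate of f_plus[0] through a pulse."""
        out = rf_rotation(random_state(11), 47.0, 123.0, 0.5, 320.0)
        assert out.f_minus[0] == pytest.approx(np.conj(out.f_plus[0]),
                                               abs=1e-12)


class TestRelax:
    def test_zero_duration_identity(self):
        s = random_state(5)
        out = relax(s, 0.0, 1000.0, 100.0)
        np.testing.assert_allclose(out.f_plus, s.f_plus)
        np.testing.assert_allclose(out.z, s.z)

    def test_equilibrium_fixed_point(self):
        s = ConfigurationStateSet.equilibrium()
        out = relax(s, 137.0, 800.0, 80.0)
        assert out.z[0] == pytest.approx(1.0)
        assert out.transverse_energy() == 0.0

    def test_half_recovery(self):
        s = ConfigurationStateSet.equilibrium()
        s.z[0] = 0.0
        t1 = 900.0
        out = relax(s, t1 * np.log(2.0), t1, 90.0)
        assert out.z[0].real == pytest.approx(0.5, rel=1e-12)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            relax(ConfigurationStateSet.equilibrium(), -1.0, 100.0, 10.0)


class TestGradientShift:
    def test_zero_shift_identity(self):
        s = random_state(7)
        out = gradient_shift(s, 0)
        np.testing.assert_allclose(out.f_plus, s.f_plus)

    def test_shift_definition(self):
        s = ConfigurationStateSet.equilibrium()
        s = rf_rotation(s, 90.0, 0.0)   # pure F(0)
        c = s.f_plus[0]
        out = gradient_shift(s, 1)
        assert out.f_plus[1] == pytest.approx(c)
        assert out.f_plus[0] == pytest.approx(0.0)
        # F(-1) is conj(f_minus[1]); the old F(0) left nothing behind
        assert out.f_minus[1] == pytest.approx(0.0)

    @hsettings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10 ** 6), st.integers(1, 5))
    def test_invertibility(self, seed, dk):
        """shift(+k) then shift(-k) restores the state below k_max."""
        s = random_state(seed)
        out = gradient_shift(gradient_shift(s, dk), -dk)
        np.testing.assert_allclose(out.f_plus[: s.n_orders], s.f_plus,
                                   atol=1e-14)
        np.testing.assert_allclose(out.f_minus[: s.n_orders], s.f_minus,
                                   atol=1e-14)
        assert out.truncation_loss == 0.0

    def test_truncation_accounting(self):
        s = random_state(9)
        s.k_max = 8
        # energy over signed orders, counting k = 0 once
        signed_before = s.transverse_energy() - abs(s.f_plus[0]) ** 2
        out = gradient_shift(s, 6)
        assert out.truncation_loss > 0
        signed_after = out.transverse_energy() - abs(out.f_plus[0]) ** 2
        # a pure shift conserves energy: kept + lost = before
        assert signed_after + out.truncation_loss == pytest.approx(
            signed_before, rel=1e-9)


class TestDiffusion:
    def test_zero_adc_identity(self):
        s = random_state(13)
        out = diffusion_damping(s, 3, 10.0, 0.0, 2.0)
        np.testing.assert_allclose(out.f_plus, s.f_plus)

    def test_order_zero_static_unattenuated(self):
        s = ConfigurationStateSet.equilibrium()
        s = rf_rotation(s, 90.0, 0.0)
        out = diffusion_damping(s, 0, 50.0, 2000.0, 2.0)
        assert abs(out.f_plus[0]) == pytest.approx(abs(s.f_plus[0]))

    def test_scalar_closed_form(self):
        """Attenuation of a lone F(k=10) state matches scalar arithmetic."""
        n = 11
        s = ConfigurationStateSet(f_plus=np.zeros(n, complex),
                                  f_minus=np.zeros(n, complex),
                                  z=np.zeros(n, complex))
        s.z[0] = 1.0
        s.f_plus[10] = 0.5 + 0.1j
        adc, interval, voxel = 1930.0, 23.1, 2.0
        out = diffusion_damping(s, 0, interval, adc, voxel)
        expected = np.exp(-adc * 1e-12 * (2 * np.pi * 10 / (voxel * 1e-3)) ** 2
                          * interval * 1e-3)
        assert abs(out.f_plus[10]) / abs(s.f_plus[10]) == pytest.approx(
            expected, rel=1e-12)

    def test_negative_adc_rejected(self):
        with pytest.raises(ValueError):
            diffusion_damping(random_state(1), 0, 1.0, -1.0, 2.0)


class TestPrecess:
    def test_zero_offset_identity(self):
        s = random_state(17)
        out = precess(s, 0.0, 5.0)
        np.testing.assert_allclose(out.f_plus, s.f_plus)

    def test_full_revolution_identity(self):
        s = random_state(19)
        out = precess(s, 320.0, 1e3 / 320.0)
        np.testing.assert_allclose(out.f_plus, s.f_plus, atol=1e-12)

    def test_scalar_phase(self):
        """320 Hz over 1.9 ms advances the F+ phase by -2π·0.608 rad."""
        s = ConfigurationStateSet.equilibrium()
        s = rf_rotation(s, 90.0, 0.0)
        out = precess(s, 320.0, 1.9)
        expected = s.f_plus[0] * np.exp(-2j * np.pi * 0.608)
        assert out.f_plus[0] == pytest.approx(expected, abs=1e-12)


class TestGlobalInvariants:
    @hsettings(derandomize=True, max_examples=20)
    @given(st.integers(0, 10 ** 6))
    def test_composition_bounded_from_equilibrium(self, seed):
        """No operator sequence from equilibrium exceeds m0 in any channel."""
        rng = np.random.default_rng(seed)
        s = ConfigurationStateSet.equilibrium()
        for _ in range(12):
            op = rng.integers(0, 5)
            if op == 0:
                s = rf_rotation(s, rng.uniform(0, 180), rng.uniform(0, 360),
                                0.5, rng.choice([0.0, 320.0]))
            elif op == 1:
                s = relax(s, rng.uniform(0, 50), 1000.0, 100.0)
            elif op == 2:
                s = gradient_shift(s, int(rng.integers(-3, 4)))
            elif op == 3:
                s = diffusion_damping(s, int(rng.integers(-2, 3)),
                                      rng.uniform(0, 20), 1000.0, 2.0)
            else:
                s = precess(s, 320.0, rng.uniform(0, 5))
            assert abs(s.z[0]) <= 1.0 + 1e-9
            assert s.transverse_energy() <= 2.0 + 1e-9

    @hsettings(derandomize=True, max_examples=20)
    @given(st.integers(0, 10 ** 6))
    def test_relax_and_diffusion_never_gain_transverse_energy(self, seed):
        s = random_state(seed)
        e0 = s.transverse_energy()
        rng = np.random.default_rng(seed + 1)
        s1 = relax(s, rng.uniform(0, 100), 1500.0, 80.0)
        assert s1.transverse_energy() <= e0 + 1e-12
        s2 = diffusion_damping(s, int(rng.integers(-3, 4)),
                               rng.uniform(0, 50), 2000.0, 2.0)
        assert s2.transverse_energy() <= e0 + 1e-12
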