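import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.constants import epsilon_0

from cellspin.electro import (DielectricSpec, RotationConditions,
                              cm_factor, complex_permittivity,
                              imag_cm_from_velocity, solve_cell_dielectrics,
                              steady_state_velocity)


def _cond(omega=2 * np.pi * 1e5):
    return RotationConditions(r=5e-6, eta=1e-3, e_rms=2e4, omega=omega)


class TestComplexPermittivity:
    def test_lossless_medium_is_real(self):
        spec = DielectricSpec(eps=3.5 * epsilon_0, sigma=0.0)
        assert complex_permittivity(spec, 1e5) == complex(3.5 * epsilon_0, 0)

    def test_unit_values(self):
        assert complex_permittivity(DielectricSpec(1.0, 1.0), 1.0) == 1 - 1j

    @given(eps=st.floats(1e-12, 1e-8), sigma=st.floats(0.0, 10.0),
           omega=st.floats(1e2, 1e9))
    @settings(max_examples=50, deadline=None)
    def test_imaginary_part_closed_form(self, eps, sigma, omega):
        got = complex_permittivity(DielectricSpec(eps, sigma), omega)
        assert got.imag == pytest.approx(-sigma / omega)

    def test_invalid_omega(self):
        with pytest.raises(ValueError):
            complex_permittivity(DielectricSpec(1.0, 1.0), 0.0)


class TestCmFactor:
    def test_index_matched_gives_zero(self):
        spec = DielectricSpec.from_relative(78.0, 1e-3)
        assert cm_factor(spec, spec, 1e5) == 0

    def test_lossless_hand_arithmetic(self):
        cell = DielectricSpec(eps=2.0, sigma=0.0)
        medium = DielectricSpec(eps=1.0, sigma=0.0)
        k = cm_factor(cell, medium, 1e5)
        assert k == pytest.approx(0.25)
        assert k.imag == 0.0

    def test_real_part_bounded_over_physical_sweep(self):
        rng = np.random.default_rng(0)
        n = 10_000
        for _ in range(n // 100):
            eps_p = rng.uniform(1, 100, 100) * epsilon_0
            eps_m = rng.uniform(1, 100, 100) * epsilon_0
            sig_p = rng.uniform(0, 2, 100)
            sig_m = rng.uniform(1e-5, 2, 100)
            omega = 10 ** rng.uniform(3, 9, 100)
            for args in zip(eps_p, sig_p, eps_m, sig_m, omega):
                k = cm_factor(DielectricSpec(args[0], args[1]),
                              DielectricSpec(args[2], args[3]), args[4])
                assert -0.5 - 1e-12 <= k.real <= 1.0 + 1e-12

    def test_imag_vanishes_at_high_frequency(self):
        cell = DielectricSpec.from_relative(60.0, 0.3)
        medium = DielectricSpec.from_relative(78.0, 1e-3)
        ims = [abs(cm_factor(cell, medium, w).imag)
               for w in (1e6, 1e9, 1e12, 1e15)]
        assert ims[-1] < 1e-6
        assert ims[-1] < ims[0]


class TestTorqueBalance:
    cell = DielectricSpec.from_relative(60.0, 0.25)
    medium = DielectricSpec.from_relative(78.0, 1e-3)

    def test_matched_lossless_no_rotation(self):
        spec = DielectricSpec(eps=2 * epsilon_0, sigma=0.0)
        assert steady_state_velocity(spec, spec, _cond()) == 0.0

    def test_field_squared_scaling(self):
        c1 = _cond()
        c2 = RotationConditions(c1.r, c1.eta, 2 * c1.e_rms, c1.omega)
        v1 = steady_state_velocity(self.cell, self.medium, c1)
        v2 = steady_state_velocity(self.cell, self.medium, c2)
        assert v2 == pytest.approx(4 * v1)

    def test_explicit_torque_balance_oracle(self):
        # independent route: compute both torques and verify they cancel
        rng = np.random.default_rng(1)
        for _ in range(20):
            cell = DielectricSpec(rng.uniform(1, 100) * epsilon_0,
                                  rng.uniform(0, 1))
            medium = DielectricSpec(rng.uniform(1, 100) * epsilon_0,
                                    rng.uniform(1e-5, 1))
            cond = _cond(10 ** rng.uniform(4, 8))
            v = steady_state_velocity(cell, medium, cond)
            im_k = cm_factor(cell, medium, cond.omega).imag
            gamma_dep = 4 * np.pi * cond.r ** 3 * medium.eps * im_k \
                * cond.e_rms ** 2
            gamma_drag = -8 * np.pi * cond.eta * v * cond.r ** 3
            assert gamma_dep + gamma_drag == pytest.approx(
                0.0, abs=1e-12 * max(abs(gamma_dep), 1e-30))

    @given(v=st.floats(-50.0, 50.0))
    @settings(max_examples=40, deadline=None)
    def test_velocity_imk_round_trip(self, v):
        im_k = imag_cm_from_velocity(v, self.medium, _cond())
        back = self.medium.eps * im_k * _cond().e_rms ** 2 / (2 * _cond().eta)
        assert back == pytest.approx(v, rel=1e-12, abs=1e-15)

    def test_zero_velocity_zero_imk(self):
        assert imag_cm_from_velocity(0.0, self.medium, _cond()) == 0.0


class TestSolveCellDielectrics:
    medium = DielectricSpec.from_relative(78.0, 1e-3)

    def _forward(self, cell, omegas):
        return [(w, steady_state_velocity(cell, self.medium, _cond(w)))
                for w in omegas]

    def test_noise_free_round_trip(self):
        cell = DielectricSpec.from_relative(60.0, 0.25)
        meas = self._forward(cell, (2 * np.pi * 4e4, 2 * np.pi * 4e6))
        rec = solve_cell_dielectrics(meas, self.medium, _cond())
        assert rec.eps == pytest.approx(cell.eps, rel=1e-3)
        assert rec.sigma == pytest.approx(cell.sigma, rel=1e-3)

    def test_identical_frequencies_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            solve_cell_dielectrics([(1e5, 1.0), (1e5, 2.0)],
                                   self.medium, _cond())

    def test_zero_rotation_admits_medium_matched_root(self):
        meas = [(2 * np.pi * 4e4, 0.0), (2 * np.pi * 4e6, 0.0)]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = solve_cell_dielectrics(meas, self.medium, _cond())
        for w in (2 * np.pi * 4e4, 2 * np.pi * 4e6):
            assert cm_factor(rec, self.medium, w).imag == pytest.approx(
                0.0, abs=1e-9)

    def test_noisy_recovery_median_error(self):
        # 1% multiplicative measurement noise: median relative error < 5%.
        # Frequencies straddle the Maxwell-Wagner relaxation (~26 MHz for
        # these specs) so both parameters are actually identifiable.
        rng = np.random.default_rng(7)
        cell = DielectricSpec.from_relative(55.0, 0.3)
        errs = []
        for _ in range(100):
            meas = [
                (w, v * (1 + rng.normal(0, 0.01)))
                for w, v in self._forward(cell,
                                          (2 * np.pi * 1e6, 2 * np.pi * 5e7))
            ]
            try:
                rec = solve_cell_dielectrics(meas, self.medium, _cond(),
                                             rel_tol=0.05)
            except Exception:
                continue
            errs.append(max(abs(rec.eps - cell.eps) / cell.eps,
                            abs(rec.sigma - cell.sigma) / cell.sigma))
        assert len(errs) >= 50
        assert np.median(errs) < 0.05
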