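"""Charge model, screening lengths, first-passage transport, blockade scaling."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from porekin import (
    PoreModel,
    bjerrum_length_nm,
    debye_length_nm,
    drift_velocity_cm_s,
    estimate_diffusion,
    excluded_volume_blockade_pA,
    mean_first_passage_time,
    net_charge,
    pamam_g1_charge_model,
    stokes_einstein_diffusion_cm2_s,
    stokes_einstein_radius_nm,
)
from porekin.transport import _tau_model
from conftest import mfpt_monte_carlo


class TestNetCharge:
    def test_dendrimer_charge_vs_pH(self):
        """Default protonation model gives ~+12 at pH 3, ~+8 at pH 7 and
        near zero at pH 10.3."""
        model = pamam_g1_charge_model()
        assert round(net_charge(model, 3.0)) == 12
        assert round(net_charge(model, 7.0)) == 8
        assert net_charge(model, 10.3) < 1.0

    def test_monotone_decreasing_in_pH(self):
        model = pamam_g1_charge_model()
        charges = [net_charge(model, p) for p in np.linspace(1, 13, 25)]
        assert np.all(np.diff(charges) < 0)

    def test_ph_range_checked(self):
        with pytest.raises(ValueError):
            net_charge(pamam_g1_charge_model(), 0.0)


class TestScreeningLengths:
    def test_debye_values(self):
        """~3 A at 1 M and ~4 A at 0.5 M KCl (300 K, eps_r = 78)."""
        assert debye_length_nm(1.0, 300.0) == pytest.approx(0.30, abs=0.02)
        assert debye_length_nm(0.5, 300.0) == pytest.approx(0.43, abs=0.02)

    def test_inverse_sqrt_scaling(self):
        assert debye_length_nm(4.0, 300.0) == pytest.approx(
            debye_length_nm(1.0, 300.0) / 2, rel=1e-12
        )

    def test_bjerrum_value_and_scaling(self):
        assert bjerrum_length_nm(300.0) == pytest.approx(0.714, abs=0.02)
        assert bjerrum_length_nm(300.0, 156.0) == pytest.approx(
            bjerrum_length_nm(300.0, 78.0) / 2, rel=1e-12
        )

    def test_debye_bjerrum_identity(self):
        """kappa^2 = 8*pi*l_B*NA*I*1e3 reproduces the Debye length."""
        from porekin.constants import AVOGADRO_PER_MOL

        ionic = 0.75
        l_b_m = bjerrum_length_nm(300.0) * 1e-9
        kappa2 = 8 * np.pi * l_b_m * AVOGADRO_PER_MOL * ionic * 1e3
        assert 1e9 / np.sqrt(kappa2) == pytest.approx(
            debye_length_nm(ionic, 300.0), rel=1e-9
        )


class TestMeanFirstPassage:
    def test_diffusive_limit(self):
        assert mean_first_passage_time(0.0, 1e-8, 1e-6) == pytest.approx(5e-5)

    def test_closed_form_value(self):
        assert mean_first_passage_time(0.01, 1e-8, 1e-6) == pytest.approx(
            3.68e-5, rel=1e-3
        )

    def test_ballistic_limit(self):
        """Strong drift: tau -> L/v. The deficit is exactly (1 - 1/u)
        for u = vL/D >> 1, so 1% agreement needs u = 100."""
        v, D, L = 1.0, 1e-8, 1e-6  # vL/D = 100
        assert mean_first_passage_time(v, D, L) == pytest.approx(L / v, rel=0.01)
        v10 = 0.1  # u = 10: closed form sits at 0.9*L/v, not yet ballistic
        assert mean_first_passage_time(v10, D, L) == pytest.approx(
            0.9 * L / v10, rel=1e-4
        )

    def test_series_continuity_at_small_drift(self):
        """Series and closed-form branches agree across the switchover."""
        D, L = 1e-8, 1e-6
        v_edge = 1.0001e-4 * D / L
        v_small = 0.9999e-4 * D / L
        assert mean_first_passage_time(v_small, D, L) == pytest.approx(
            mean_first_passage_time(v_edge, D, L), rel=1e-6
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        u=st.floats(-20.0, 20.0),
        D=st.floats(1e-10, 1e-6),
        L=st.floats(1e-8, 1e-5),
    )
    def test_positive_and_monotone_in_drift(self, u, D, L):
        """MFPT is positive and non-increasing as drift toward the
        absorbing boundary grows, for any (D, L)."""
        v = u * D / L
        tau = mean_first_passage_time(v, D, L)
        assert tau > 0
        tau_faster = mean_first_passage_time(v + 0.1 * D / L, D, L)
        assert tau_faster <= tau * (1 + 1e-9)

    @pytest.mark.parametrize("u", [0.0, 1.0, 5.0])
    def test_against_monte_carlo_oracle(self, u):
        """Closed form vs Euler-Maruyama first-passage simulation within
        2% at vL/D in {0, 1, 5} (natural units L = D = 1)."""
        mc = mfpt_monte_carlo(u, 1.0, 1.0, n_walkers=20_000, seed=int(u))
        assert mean_first_passage_time(u, 1.0, 1.0) == pytest.approx(mc, rel=0.02)


class TestDriftVelocity:
    def test_zero_voltage_zero_eo(self):
        assert drift_velocity_cm_s(0.49, 0.0, PoreModel(), 1e-8) == 0.0

    def test_linear_in_voltage(self):
        pore = PoreModel()
        v1 = drift_velocity_cm_s(0.49, 50.0, pore, 1e-8, 295.0, 1e-3)
        v2 = drift_velocity_cm_s(0.49, 100.0, pore, 1e-8, 295.0, 1e-3)
        v0 = drift_velocity_cm_s(0.49, 0.0, pore, 1e-8, 295.0, 1e-3)
        assert v2 - v0 == pytest.approx(2 * (v1 - v0), rel=1e-12)

    def test_formula_oracle(self):
        """Direct evaluation of v = (D/kBT)*(z*e*dV/l_p) - v_eo."""
        from porekin.constants import ELEMENTARY_CHARGE_C, thermal_energy_J

        z, dV, D, T = 0.49, 100.0, 1.78e-8, 295.0
        pore = PoreModel(length_nm=10.0)
        expected = (
            (D * 1e-4)
            / thermal_energy_J(T)
            * (z * ELEMENTARY_CHARGE_C * dV * 1e-3 / 10e-9)
        ) * 1e2
        assert drift_velocity_cm_s(z, dV, pore, D, T) == pytest.approx(
            expected, rel=1e-12
        )


class TestEstimateDiffusion:
    volts = [50.0, 60.0, 70.0, 80.0, 90.0, 100.0]

    def forward_taus(self, D, z=0.49, v_eo=0.0):
        pore = PoreModel()
        return [(v, _tau_model(D, v, z, pore, 295.0, v_eo)) for v in self.volts]

    def test_roundtrip_exact(self):
        """Noiseless forward data at D = 3.04e-8 cm^2/s inverts to 4+
        significant figures."""
        est = estimate_diffusion(self.forward_taus(3.04e-8), 0.49)
        assert est.D_cm2_s == pytest.approx(3.04e-8, rel=1e-4)

    def test_scaled_tau_re_solve(self):
        """Doubling all tau: the inverted D satisfies the closed form
        exactly at each voltage (oracle re-solve)."""
        pts = [(v, 2 * tau) for v, tau in self.forward_taus(3.04e-8)]
        est = estimate_diffusion(pts, 0.49)
        pore = PoreModel()
        for (v, tau), d_i in zip(pts, est.per_point_D):
            assert _tau_model(d_i, v, 0.49, pore, 295.0, 0.0) == pytest.approx(
                tau, rel=1e-8
            )

    def test_single_point_matches_series(self):
        pts = self.forward_taus(1.78e-8)
        single = estimate_diffusion([pts[0]], 0.49)
        series = estimate_diffusion(pts, 0.49)
        assert single.D_cm2_s == pytest.approx(series.D_cm2_s, rel=1e-4)

    def test_noise_recovery(self, rng):
        """10% multiplicative noise on tau: median recovered D within 15%
        of truth over 50 seeds."""
        true_d = 1.78e-8
        clean = self.forward_taus(true_d)
        estimates = []
        for _ in range(50):
            noisy = [(v, tau * rng.lognormal(0, 0.10)) for v, tau in clean]
            estimates.append(estimate_diffusion(noisy, 0.49).D_cm2_s)
        assert np.median(estimates) == pytest.approx(true_d, rel=0.15)

    def test_condition_ordering_consistency(self):
        """Fixtures built from the reference D values keep their ordering
        through the inversion: D(pH3, 1M) > D(pH7, 1M) > D(pH7, 0.5M)."""
        from porekin.pipeline import REFERENCE_DIFFUSION, REFERENCE_VOLTAGE_FITS

        z_by_cond = {(7.0, 1.0): 0.49, (7.0, 0.5): 0.94, (3.0, 1.0): 0.49}
        recovered = {}
        for key, d_true in REFERENCE_DIFFUSION.items():
            z = z_by_cond[key]
            pts = self.forward_taus(d_true, z=z)
            recovered[key] = estimate_diffusion(pts, z).D_cm2_s
        assert recovered[(3.0, 1.0)] > recovered[(7.0, 1.0)] > recovered[(7.0, 0.5)]

    def test_unreachable_tau_diagnostic(self):
        with pytest.raises(ValueError, match="no D"):
            estimate_diffusion([(100.0, 1e12)], 0.49)


class TestStokesEinstein:
    def test_radius_value(self):
        """A 1 nm sphere in water at 295 K has D ~ 2.4e-6 cm^2/s."""
        d = stokes_einstein_diffusion_cm2_s(1.0, 8.9e-4, 295.0)
        assert d == pytest.approx(2.4e-6, rel=0.02)

    def test_roundtrip_and_scaling(self):
        d = stokes_einstein_diffusion_cm2_s(1.3)
        assert stokes_einstein_radius_nm(d) == pytest.approx(1.3, rel=1e-12)
        assert stokes_einstein_radius_nm(d / 2) == pytest.approx(2.6, rel=1e-12)


class TestExcludedVolumeBlockade:
    def test_zero_volume(self):
        assert excluded_volume_blockade_pA(0.1, 100.0, 0.0, 10.0) == 0.0

    def test_linearity(self):
        base = excluded_volume_blockade_pA(0.1, 100.0, 3.0, 10.0)
        assert excluded_volume_blockade_pA(0.1, 200.0, 3.0, 10.0) == pytest.approx(
            2 * base
        )
        assert excluded_volume_blockade_pA(0.1, 100.0, 6.0, 10.0) == pytest.approx(
            2 * base
        )

    def test_dimensional_analysis_oracle(self):
        """Independent unit bookkeeping: sigma [S/m] * V [V] * delta [m^3]
        / l^2 [m^2] -> amps, for one parameter set."""
        sigma_S_cm, dV_mV, delta_nm3, lp_nm = 0.112, 100.0, 3.0, 10.0
        amps = (sigma_S_cm * 100) * (dV_mV / 1e3) * (delta_nm3 * 1e-27) / (
            (lp_nm * 1e-9) ** 2
        )
        assert excluded_volume_blockade_pA(
            sigma_S_cm, dV_mV, delta_nm3, lp_nm
        ) == pytest.approx(amps * 1e12, rel=1e-12)
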