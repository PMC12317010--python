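"""Single-field calibration fit, inversion, and Mason-Schamp physics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dtims.calibration import (
    DA_KG,
    E_CHARGE,
    KB,
    NITROGEN,
    TORR_PA,
    BufferGas,
    CalibrationError,
    InstrumentGeometry,
    SingleFieldCalibration,
    ccs_from_arrival,
    fit_single_field,
    mason_schamp_drift_time,
    reduced_mass,
)


def make_calibrants(n=10, mz_lo=118.0, mz_hi=1522.0):
    mz = np.linspace(mz_lo, mz_hi, n)
    ccs = 9.8 * mz**0.5 * (1 + 0.02 * np.sin(np.arange(n)))
    return pd.DataFrame({
        "calibrant_id": [f"CAL{i:02d}" for i in range(n)],
        "mz": mz, "z": 1, "ccs_ref": ccs,
    })


def gamma(mz, z=1, gas=NITROGEN):
    m = np.asarray(mz, dtype=float) * abs(z)
    mu = m * gas.molar_mass_da / (m + gas.molar_mass_da)
    return np.sqrt(mu) / abs(z)


class TestReducedMass:
    def test_equal_masses_halve(self):
        assert reduced_mass(28.0134) == pytest.approx(14.0067, abs=1e-9)

    def test_heavy_ion_limit_is_gas_mass(self):
        assert reduced_mass(1e9) == pytest.approx(28.0134, rel=1e-6)

    def test_hand_arithmetic(self):
        assert reduced_mass(100.0) == pytest.approx(100 * 28.0134 / 128.0134, abs=1e-9)
        assert reduced_mass(100.0) == pytest.approx(21.8832, abs=1e-4)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            reduced_mass(0.0)


class TestMasonSchamp:
    def test_proportional_to_ccs(self):
        t1 = mason_schamp_drift_time(150.0, 300.0, 1)
        t2 = mason_schamp_drift_time(300.0, 300.0, 1)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_inverse_in_field(self):
        g1 = InstrumentGeometry(field_v_per_cm=17.0)
        g2 = InstrumentGeometry(field_v_per_cm=34.0)
        t1 = mason_schamp_drift_time(150.0, 300.0, 1, g1)
        t2 = mason_schamp_drift_time(150.0, 300.0, 1, g2)
        assert t1 == pytest.approx(2 * t2, rel=1e-12)

    def test_unit_conversions_against_stepwise_evaluation(self):
        # independent constant-by-constant route via the mobility coefficient:
        # K = 3 z e / (16 N) * sqrt(2 pi / (mu k T)) / Omega ; t = L / (K E)
        geom = InstrumentGeometry()  # 78.24 cm, 17 V/cm, 3.95 torr, 300 K
        mu = reduced_mass(300.0) * DA_KG
        n_density = geom.pressure_torr * TORR_PA / (KB * geom.temperature_k)
        k_mob = (3 * E_CHARGE / (16 * n_density)) * np.sqrt(
            2 * np.pi / (mu * KB * geom.temperature_k)
        ) / (150.0 * 1e-20)
        t_expected_ms = (0.7824 / (k_mob * 1700.0)) * 1e3
        got = mason_schamp_drift_time(150.0, 300.0, 1, geom)
        assert got == pytest.approx(t_expected_ms, rel=1e-12)
        # magnitude sanity: drift times in this geometry are tens of ms
        assert 5.0 < got < 60.0


class TestSingleFieldFit:
    def test_exact_recovery_of_injected_parameters(self):
        beta0, t0 = 0.27, 0.15
        table = make_calibrants()
        x = gamma(table["mz"].to_numpy()) * table["ccs_ref"].to_numpy()
        arrivals = pd.DataFrame({
            "calibrant_id": table["calibrant_id"],
            "arrival_time_ms": beta0 * x + t0,
        })
        fit = fit_single_field(arrivals, table)
        assert fit.beta == pytest.approx(beta0, rel=1e-9)
        assert fit.t_fix == pytest.approx(t0, rel=1e-9)
        assert fit.residual_rms < 1e-10
        assert fit.n_calibrants == 10

    def test_two_points_zero_residual(self):
        table = make_calibrants(n=2)
        x = gamma(table["mz"].to_numpy()) * table["ccs_ref"].to_numpy()
        arrivals = pd.DataFrame({
            "calibrant_id": table["calibrant_id"],
            "arrival_time_ms": 0.02 * x + 0.3,
        })
        fit = fit_single_field(arrivals, table)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(fit.beta_se)

    def test_noisy_recovery_is_unbiased(self, rng):
        beta0, t0, sigma = 0.0204, 0.25, 0.01
        table = make_calibrants()
        x = gamma(table["mz"].to_numpy()) * table["ccs_ref"].to_numpy()
        betas = []
        for _ in range(100):
            arrivals = pd.DataFrame({
                "calibrant_id": table["calibrant_id"],
                "arrival_time_ms": beta0 * x + t0 + rng.normal(0, sigma, len(x)),
            })
            betas.append(fit_single_field(arrivals, table).beta)
        bias = np.mean(betas) - beta0
        se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(bias) < 3 * se

    def test_unmatched_calibrant_listed(self):
        table = make_calibrants(n=3)
        arrivals = pd.DataFrame({
            "calibrant_id": ["CAL00", "CAL01", "NOPE"],
            "arrival_time_ms": [10.0, 12.0, 14.0],
        })
        with pytest.raises(CalibrationError, match="NOPE"):
            fit_single_field(arrivals, table)

    def test_fewer_than_two_calibrants_rejected(self):
        table = make_calibrants(n=3)
        arrivals = pd.DataFrame({
            "calibrant_id": ["CAL00"], "arrival_time_ms": [10.0],
        })
        with pytest.raises(CalibrationError):
            fit_single_field(arrivals, table)

    def test_rank_deficient_design_rejected(self):
        table = make_calibrants(n=3)
        table["ccs_ref"] = 150.0
        table["mz"] = 300.0
        arrivals = pd.DataFrame({
            "calibrant_id": table["calibrant_id"],
            "arrival_time_ms": [10.0, 10.1, 9.9],
        })
        with pytest.raises(CalibrationError, match="rank"):
            fit_single_field(arrivals, table)

    def test_row_order_invariance(self):
        table = make_calibrants()
        x = gamma(table["mz"].to_numpy()) * table["ccs_ref"].to_numpy()
        arrivals = pd.DataFrame({
            "calibrant_id": table["calibrant_id"],
            "arrival_time_ms": 0.021 * x + 0.2,
        })
        fit1 = fit_single_field(arrivals, table)
        shuffled = arrivals.sample(frac=1, random_state=3)
        fit2 = fit_single_field(shuffled, table)
        omega1 = ccs_from_arrival(15.0, 300.0, 1, fit1)
        omega2 = ccs_from_arrival(15.0, 300.0, 1, fit2)
        assert omega1 == pytest.approx(omega2, rel=1e-12)

    def test_summary_mentions_parameters(self):
        table = make_calibrants()
        x = gamma(table["mz"].to_numpy()) * table["ccs_ref"].to_numpy()
        fit = fit_single_field(
            pd.DataFrame({"calibrant_id": table["calibrant_id"],
                          "arrival_time_ms": 0.02 * x + 0.1}),
            table,
        )
        text = fit.summary()
        assert "beta" in text and "t_fix" in text


class TestCcsFromArrival:
    def test_algebraic_inversion(self):
        table = make_calibrants()
        x = gamma(table["mz"].to_numpy()) * table["ccs_ref"].to_numpy()
        fit = fit_single_field(
            pd.DataFrame({"calibrant_id": table["calibrant_id"],
                          "arrival_time_ms": 0.02 * x + 0.1}),
            table,
        )
        g = gamma(300.0)
        t_a = fit.t_fix + fit.beta * g * 150.0
        assert ccs_from_arrival(t_a, 300.0, 1, fit) == pytest.approx(150.0, rel=1e-9)

    def test_physics_roundtrip_recovers_true_ccs(self):
        # arrivals generated from first principles (t_fix = 0): inversion
        # through a fit on those same physics must recover every CCS
        geom = InstrumentGeometry()
        table = make_calibrants()
        arrivals = pd.DataFrame({
            "calibrant_id": table["calibrant_id"],
            "arrival_time_ms": [
                mason_schamp_drift_time(c, m, 1, geom)
                for c, m in zip(table["ccs_ref"], table["mz"])
            ],
        })
        fit = fit_single_field(arrivals, table)
        assert abs(fit.t_fix) < 1e-9
        for omega_true, mz in [(120.0, 180.0), (200.0, 450.0), (310.0, 1400.0)]:
            t = mason_schamp_drift_time(omega_true, mz, 1, geom)
            assert ccs_from_arrival(t, mz, 1, fit) == pytest.approx(omega_true, rel=1e-6)

    def test_beta_scales_with_geometry(self):
        # beta tracks L * N / E when the generating geometry changes
        def beta_for(geom):
            table = make_calibrants()
            arrivals = pd.DataFrame({
                "calibrant_id": table["calibrant_id"],
                "arrival_time_ms": [
                    mason_schamp_drift_time(c, m, 1, geom)
                    for c, m in zip(table["ccs_ref"], table["mz"])
                ],
            })
            return fit_single_field(arrivals, table).beta

        g1 = InstrumentGeometry()
        g2 = InstrumentGeometry(drift_length_cm=78.24 * 2, field_v_per_cm=17.0 * 2,
                                pressure_torr=3.95 * 1.5)
        ratio = (2 * 1.5) / 2  # (L x N) / E factor change
        assert beta_for(g2) / beta_for(g1) == pytest.approx(ratio, rel=1e-9)

    def test_arrival_at_or_below_offset_is_nonphysical(self):
        table = make_calibrants()
        x = gamma(table["mz"].to_numpy()) * table["ccs_ref"].to_numpy()
        fit = fit_single_field(
            pd.DataFrame({"calibrant_id": table["calibrant_id"],
                          "arrival_time_ms": 0.02 * x + 0.5}),
            table,
        )
        with pytest.raises(CalibrationError):
            ccs_from_arrival(fit.t_fix, 300.0, 1, fit)


def test_geometry_validates_positivity():
    with pytest.raises(ValueError):
        InstrumentGeometry(pressure_torr=-1.0)
    with pytest.raises(ValueError):
        BufferGas(molar_mass_da=0.0)
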