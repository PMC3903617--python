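"""Kinetic/thermodynamic analysis: K_D, van't Hoff, Eyring, deltas, fits."""

import math

import numpy as np
import pytest

from affimut.constants import R_KCAL, T_REF
from affimut.kinthermo import (ActivationParams, KineticRecord, ThermoParams,
                               compensation_summary, delta_table, eyring_fit,
                               fit_sensorgram, gibbs_from_kd, kd_from_rates,
                               kinetic_summary, vant_hoff_fit)
from affimut.synth import (KineticsSimSpec, VariantThermo, simulate_kinetics,
                           simulate_sensorgram)


def _round_sf(x, sf=2):
    return float(f"{x:.{sf}g}")


class TestKdFromRates:
    @pytest.mark.parametrize("kon, koff, kd_nm", [
        (13e4, 0.22e-4, 0.17),   # published L-N31R rates
        (7.3e4, 0.14e-4, 0.19),  # published L-S53E rates
        (22e4, 0.86e-4, 0.39),   # published L-T56D rates
    ])
    def test_published_rates_reproduce_kd_2sf(self, kon, koff, kd_nm):
        assert _round_sf(kd_from_rates(kon, koff) * 1e9) == kd_nm

    def test_equal_rates_give_one_molar(self):
        assert kd_from_rates(3.3e4, 3.3e4) == 1.0

    def test_identity_kd_times_kon_is_koff(self):
        kon, koff = 9.0e4, 0.55e-4
        assert kd_from_rates(kon, koff) * kon == koff

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            kd_from_rates(0.0, 1e-4)


class TestGibbs:
    def test_one_molar_standard_state_is_zero(self):
        assert gibbs_from_kd(1.0, 298.15) == 0.0

    def test_point_eight_nanomolar(self):
        # direct evaluation of R*T*ln(0.8e-9)
        assert gibbs_from_kd(0.8e-9, 298.15) == pytest.approx(-12.41, abs=0.01)

    def test_monotone_in_kd(self):
        kds = np.logspace(-12, -3, 30)
        gs = [gibbs_from_kd(k) for k in kds]
        assert all(a < b for a, b in zip(gs, gs[1:]))


class TestVantHoff:
    def test_noiseless_recovery_is_exact(self):
        # generating values: published L-N31R equilibrium parameters
        truth = VariantThermo.from_minus_t_ds(-25.6, 12.3, 3.4, 6.8)
        spec = KineticsSimSpec({"V": truth}, noise_cv=0.0, seed=0)
        fit = vant_hoff_fit(simulate_kinetics(spec))
        assert fit.dh == pytest.approx(truth.dh, rel=1e-6)
        assert fit.ds == pytest.approx(truth.ds, rel=1e-6)
        assert fit.dg(T_REF) == pytest.approx(truth.dh - T_REF * truth.ds, rel=1e-6)

    def test_temperature_independent_kd_gives_zero_enthalpy(self):
        records = [KineticRecord("V", t, 1e5, 1e-4)
                   for t in (283.0, 298.0, 313.0)]
        fit = vant_hoff_fit(records)
        assert fit.dh == pytest.approx(0.0, abs=1e-9)

    def test_needs_three_temperatures(self):
        records = [KineticRecord("V", t, 1e5, 1e-4) for t in (283.0, 298.0)]
        with pytest.raises(ValueError):
            vant_hoff_fit(records)

    def test_median_bias_small_at_five_percent_noise(self):
        truth = VariantThermo.from_minus_t_ds(-7.3, -5.0, 11.4, -0.8)
        errs = []
        for seed in range(200):
            spec = KineticsSimSpec({"V": truth}, noise_cv=0.05, seed=seed)
            fit = vant_hoff_fit(simulate_kinetics(spec))
            errs.append((fit.dh - truth.dh) / truth.dh)
        assert abs(np.median(errs)) < 0.10


class TestEyring:
    def test_noiseless_recovery_is_exact(self):
        # generating values: published WT activation parameters
        truth = VariantThermo.from_minus_t_ds(-7.3, -5.0, 11.4, -0.8)
        spec = KineticsSimSpec({"V": truth}, noise_cv=0.0, seed=0)
        fit = eyring_fit(simulate_kinetics(spec))
        assert fit.dh == pytest.approx(truth.dh_act, rel=1e-6)
        assert fit.ds == pytest.approx(truth.ds_act, rel=1e-6)

    def test_prefactor_only_rates_give_zero_activation_enthalpy(self):
        from affimut.constants import KB_OVER_H
        records = [KineticRecord("V", t, KB_OVER_H * t * 1e-8, 1e-4)
                   for t in np.linspace(283, 313, 7)]
        fit = eyring_fit(records)
        assert abs(fit.dh) < 1e-6

    def test_recovery_error_grows_with_noise(self):
        truth = VariantThermo.from_minus_t_ds(-7.3, -5.0, 11.4, -0.8)
        spread = []
        for cv in (0.02, 0.10, 0.40):
            errs = []
            for seed in range(60):
                spec = KineticsSimSpec({"V": truth}, noise_cv=cv, seed=seed)
                fit = eyring_fit(simulate_kinetics(spec))
                errs.append(abs(fit.dh - truth.dh_act))
            spread.append(np.median(errs))
        assert spread[0] < spread[1] < spread[2]


class TestDeltaTable:
    def _published_params(self):
        return {
            "WT": ThermoParams(-7.3, -(-5.0) / T_REF),
            "L-N31R": ThermoParams(-25.6, -12.3 / T_REF),
            "L-S53D": ThermoParams(-13.3, -0.6 / T_REF),
            "L-S53E": ThermoParams(-15.1, -2.4 / T_REF),
            "L-T56D": ThermoParams(-11.7, -(-1.1) / T_REF),
            "L-T56E": ThermoParams(-14.5, -1.9 / T_REF),
        }

    def test_published_equilibrium_deltas(self):
        df = delta_table(self._published_params(), "WT")
        assert df.loc["L-N31R", "ddH"] == pytest.approx(-18.3, abs=0.05)
        assert df.loc["L-N31R", "ddG"] == pytest.approx(-1.0, abs=0.05)
        assert df.loc["WT", "dG"] == pytest.approx(-12.3, abs=0.05)

    def test_reference_vs_itself_is_zero(self):
        df = delta_table(self._published_params(), "WT")
        for col in ("ddH", "mTddS", "ddG"):
            assert df.loc["WT", col] == 0.0

    def test_identity_ddg_equals_ddh_plus_mtdds(self):
        df = delta_table(self._published_params(), "WT")
        np.testing.assert_allclose(df["ddG"], df["ddH"] + df["mTddS"], atol=1e-12)

    def test_published_activation_delta(self):
        params = {"WT": ActivationParams(11.4, -(-0.8) / T_REF),
                  "L-T56E": ActivationParams(0.7, -9.9 / T_REF)}
        df = delta_table(params, "WT")
        assert df.loc["L-T56E", "ddH"] == pytest.approx(-10.7, abs=0.05)
        assert df.loc["WT", "dG"] == pytest.approx(10.6, abs=0.05)

    def test_missing_reference_rejected(self):
        with pytest.raises(KeyError):
            delta_table({"A": ThermoParams(-1.0, 0.0)}, "WT")


class TestCompensation:
    def test_perfect_compensation_slope_minus_one(self):
        params = {"WT": ThermoParams(-5.0, 0.0)}
        for i, dh in enumerate((-8.0, -11.0, -15.0)):
            # -T*ddS = -ddH exactly, so ddG vanishes for every mutein
            params[f"M{i}"] = ThermoParams(dh, (dh + 5.0) / T_REF)
        df = delta_table(params, "WT")
        summ = compensation_summary(df, "WT")
        assert summ.slope == pytest.approx(-1.0, abs=1e-9)
        assert all(abs(e) < 1e-9 for e in summ.efficiency.values())

    def test_published_muteins_efficiency_band(self):
        params = TestDeltaTable()._published_params()
        df = delta_table(params, "WT")
        summ = compensation_summary(df, "WT")
        assert summ.efficiency["L-N31R"] == pytest.approx(1.0 / 18.3, abs=0.005)
        assert all(0.0 < e < 0.12 for e in summ.efficiency.values())

    def test_single_variant_rejected(self):
        params = {"WT": ThermoParams(-5.0, 0.0), "M": ThermoParams(-8.0, 0.0)}
        df = delta_table(params, "WT")
        with pytest.raises(ValueError):
            compensation_summary(df, "WT")


class TestSensorgramFit:
    def test_noiseless_global_fit_recovers_rates(self):
        kon, koff = 1.4e5, 1.0e-4
        sgs = simulate_sensorgram(kon, koff, 120.0, [1e-9, 3e-9, 1e-8, 3e-8, 1e-7])
        fit = fit_sensorgram(sgs)
        assert fit.k_on == pytest.approx(kon, rel=1e-3)
        assert fit.k_off == pytest.approx(koff, rel=1e-3)

    def test_two_percent_noise_recovery_within_ten_percent(self):
        kon, koff, rmax = 1.4e5, 1.0e-4, 120.0
        errs_on, errs_off = [], []
        for seed in range(100):
            sgs = simulate_sensorgram(kon, koff, rmax,
                                      [1e-9, 3e-9, 1e-8, 3e-8, 1e-7],
                                      noise=0.02 * rmax, seed=seed)
            fit = fit_sensorgram(sgs)
            errs_on.append(abs(fit.k_on - kon) / kon)
            errs_off.append(abs(fit.k_off - koff) / koff)
        assert np.median(errs_on) < 0.10
        assert np.median(errs_off) < 0.10

    def test_scale_equivariance_in_rmax(self):
        sgs1 = simulate_sensorgram(1.4e5, 1.0e-4, 100.0, [1e-9, 1e-8, 1e-7])
        sgs2 = simulate_sensorgram(1.4e5, 1.0e-4, 200.0, [1e-9, 1e-8, 1e-7])
        f1, f2 = fit_sensorgram(sgs1), fit_sensorgram(sgs2)
        assert f2.r_max == pytest.approx(2 * f1.r_max, rel=1e-6)
        assert f2.k_on == pytest.approx(f1.k_on, rel=1e-8)
        assert f2.k_off == pytest.approx(f1.k_off, rel=1e-8)

    def test_all_zero_response_is_an_error(self):
        sgs = simulate_sensorgram(1e5, 1e-4, 100.0, [0.0, 0.0])
        with pytest.raises(ValueError):
            fit_sensorgram(sgs)


class TestKineticSummary:
    def _records(self):
        from affimut.kinthermo import read_kinetic_table
        from importlib import resources
        ref = resources.files("affimut.data") / "kinetics_11k2_25c.tsv"
        with resources.as_file(ref) as path:
            return read_kinetic_table(path)

    def test_inconsistent_rows_flagged_not_corrected(self):
        df = kinetic_summary(self._records())
        assert not df.loc["WT", "kd_consistent"]
        assert not df.loc["H-N28D", "kd_consistent"]
        consistent = df.index.difference(["WT", "H-N28D"])
        assert df.loc[consistent, "kd_consistent"].all()
        # the printed value is reported alongside, never overwritten
        assert df.loc["WT", "KD_printed_nM"] == pytest.approx(0.80)
        assert df.loc["WT", "KD_nM"] == pytest.approx(1.0e-4 / 14e4 * 1e9, rel=1e-9)

    def test_five_of_twelve_muteins_improved(self):
        df = kinetic_summary(self._records())
        muteins = df.drop(index="WT")
        assert int(muteins["improved"].sum()) == 5
        vl = muteins[muteins.index.str.startswith("L-")]
        assert len(vl) == 7 and int(vl["improved"].sum()) == 5
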