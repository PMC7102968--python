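"""Thermodynamic identities, fold changes, ITC model and isotherm fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aptastruct.pipeline import load_binding_table, thermo_table
from aptastruct.thermo import (
    BindingParameters, ITCProtocol, derive_thermo, fit_fraction_bound, fit_itc,
    fold_change, present_fold, simulate_itc,
)


class TestDeriveThermo:
    def test_unit_kd_gives_zero_free_energy(self):
        p = BindingParameters(k_d=1.0, delta_h=-10.0, delta_s=0.0, temperature=298.0)
        assert derive_thermo(p).delta_g_from_kd == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "kd_nm,dh,ds,printed_minus_tds,printed_dg",
        [tuple(r) for r in load_binding_table()[
            ["kd_nm", "delta_h_kj_mol", "delta_s_j_mol_k",
             "printed_minus_tds_kj_mol", "printed_dg_kj_mol"]].to_numpy()],
    )
    def test_tabulated_rows_reproduced(self, kd_nm, dh, ds, printed_minus_tds, printed_dg):
        """Every measured row satisfies the ΔG = ΔH − TΔS bookkeeping at 298 K
        to within the printing precision."""
        d = derive_thermo(BindingParameters(
            k_d=kd_nm * 1e-9, delta_h=dh, delta_s=ds, temperature=298.0))
        assert d.minus_t_delta_s == pytest.approx(printed_minus_tds, abs=0.15)
        assert d.delta_g == pytest.approx(printed_dg, abs=0.15)

    def test_consistency_residual_surfaced_not_hidden(self):
        # operator-DNA row: RT ln Kd disagrees with dH - TdS by ~1 kJ/mol due
        # to printed-precision rounding; the residual must report it
        d = derive_thermo(BindingParameters(
            k_d=51.1e-9, delta_h=57.7, delta_s=336.4, temperature=298.0))
        assert d.delta_g_from_kd == pytest.approx(-41.6, abs=0.1)
        assert d.residual == pytest.approx(d.delta_g - d.delta_g_from_kd, abs=1e-12)

    def test_invalid_kd_rejected(self):
        with pytest.raises(ValueError):
            BindingParameters(k_d=0.0, delta_h=-10.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=-25, max_value=0),
           st.floats(min_value=0.001, max_value=10))
    def test_free_energy_increases_with_kd(self, log_kd, factor):
        p1 = BindingParameters(k_d=math.exp(log_kd), delta_h=0.0, delta_s=0.0)
        p2 = BindingParameters(k_d=math.exp(log_kd) * (1 + factor), delta_h=0.0,
                               delta_s=0.0)
        assert derive_thermo(p2).delta_g_from_kd > derive_thermo(p1).delta_g_from_kd


class TestFoldChange:
    @pytest.mark.parametrize("variant,reference,ratio,presented", [
        (432.7, 51.1, 8.47, "8.5-fold"),
        (13900.0, 5.6, 2482.1, "2500-fold"),
        (26.2, 5.6, 4.68, "4.7-fold"),
        (5.6, 5.6, 1.0, "1-fold"),
    ])
    def test_ratios_and_presentation(self, variant, reference, ratio, presented):
        r = fold_change(variant, reference)
        assert r == pytest.approx(ratio, abs=0.05)
        assert present_fold(r) == presented

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_change(-1.0, 5.0)


class TestSimulateItc:
    def test_zero_enthalpy_gives_zero_heats(self):
        sim = simulate_itc(BindingParameters(k_d=1e-8, delta_h=0.0, n=1.0))
        np.testing.assert_allclose(sim.heats, 0.0)

    def test_tight_binding_total_heat_is_stoichiometric(self):
        # negligible-dilution protocol: integrated heat = dH x moles of sites
        proto = ITCProtocol(cell_volume=1.0, cell_concentration=15e-6,
                            syringe_concentration=175e-6,
                            injection_volumes=(5e-6,) * 35 * 4)
        p = BindingParameters(k_d=1e-15, delta_h=-100.0, n=1.0)
        sim = simulate_itc(p, proto)
        total_kj = sim.heats.sum() * 1e-9
        site_moles = p.n * proto.cell_concentration * proto.cell_volume
        titrant_moles = proto.syringe_concentration * sum(proto.injection_volumes)
        expected = p.delta_h * min(site_moles, titrant_moles)
        assert total_kj == pytest.approx(expected, rel=1e-3)

    def test_sigmoid_with_equivalence_near_molar_ratio_one(self):
        sim = simulate_itc(BindingParameters(k_d=5.6e-9, delta_h=-156.0, n=1.0))
        heats = sim.heats[1:]
        ratios = sim.molar_ratios[1:]
        # steepest change bracketing molar ratio 1
        step = np.abs(np.diff(heats))
        inflection = ratios[1 + int(np.argmax(step))]
        assert 0.8 < inflection < 1.2
        assert abs(heats[0]) > 10 * abs(heats[-1])   # saturation reached

    def test_deterministic_for_fixed_seed(self):
        p = BindingParameters(k_d=5.6e-9, delta_h=-156.0, n=1.0)
        s1 = simulate_itc(p, noise_sigma=5.0, seed=42)
        s2 = simulate_itc(p, noise_sigma=5.0, seed=42)
        np.testing.assert_array_equal(s1.heats, s2.heats)

    def test_saturation_warning_for_weak_syringe(self):
        proto = ITCProtocol(syringe_concentration=10e-6)
        sim = simulate_itc(BindingParameters(k_d=1e-8, delta_h=-50.0), proto)
        assert sim.saturation_warning


class TestFitItc:
    def test_noiseless_round_trip_recovers_parameters(self):
        truth = BindingParameters(k_d=5.6e-9, delta_h=-156.0, n=0.96)
        fit = fit_itc(simulate_itc(truth))
        assert fit["converged"]
        assert fit["params"].k_d == pytest.approx(truth.k_d, rel=1e-3)
        assert fit["params"].delta_h == pytest.approx(truth.delta_h, rel=1e-3)
        assert fit["params"].n == pytest.approx(truth.n, rel=1e-3)

    def test_sub_unity_stoichiometry_recovered(self):
        truth = BindingParameters(k_d=51.1e-9, delta_h=57.7, n=0.96)
        fit = fit_itc(simulate_itc(truth))
        assert fit["params"].n == pytest.approx(0.96, abs=0.01)

    def test_entropy_derived_consistently(self):
        truth = BindingParameters(k_d=5.6e-9, delta_h=-156.0, n=1.0)
        fit = fit_itc(simulate_itc(truth))
        d = derive_thermo(fit["params"])
        # by construction dG(from fitted Kd) = dH - TdS
        assert d.residual == pytest.approx(0.0, abs=1e-9)

    def test_noisy_replicates_median_kd_close(self):
        truth = BindingParameters(k_d=5.6e-9, delta_h=-156.0, n=0.96)
        clean = simulate_itc(truth)
        sigma = 0.02 * float(np.max(np.abs(clean.heats)))
        fitted = []
        for seed in range(1, 26):
            sim = simulate_itc(truth, noise_sigma=sigma, seed=seed)
            fitted.append(fit_itc(sim)["params"].k_d)
        assert np.median(fitted) == pytest.approx(truth.k_d, rel=0.15)

    def test_too_few_injections_rejected(self):
        proto = ITCProtocol(injection_volumes=(5e-6,) * 8)
        sim = simulate_itc(BindingParameters(k_d=1e-8, delta_h=-50.0), proto)
        with pytest.raises(ValueError, match="10"):
            fit_itc(sim)


class TestFractionBound:
    def test_exact_hyperbola_recovered(self):
        kd = 80e-9
        conc = np.array([5, 20, 50, 80, 200, 800]) * 1e-9
        frac = conc / (kd + conc)
        res = fit_fraction_bound(conc, frac)
        assert res["k_d"] == pytest.approx(kd, rel=1e-6)

    def test_half_saturation_at_kd(self):
        kd = 80e-9
        assert kd / (kd + kd) == pytest.approx(0.5)
        conc = np.array([10, 40, 80, 160, 640]) * 1e-9
        frac = conc / (kd + conc)
        res = fit_fraction_bound(conc, frac)
        fitted = res["k_d"]
        assert fitted / (fitted + fitted) == pytest.approx(0.5)

    def test_noisy_titration_within_quarter(self):
        rng = np.random.default_rng(5)
        kd = 80e-9
        conc = np.geomspace(5e-9, 1000e-9, 10)
        frac = np.clip(conc / (kd + conc) + rng.normal(0, 0.05, conc.size), 0, 1)
        res = fit_fraction_bound(conc, frac)
        assert res["k_d"] == pytest.approx(kd, rel=0.25)

    def test_no_transition_rejected(self):
        conc = np.array([1, 2, 3, 4]) * 1e-9
        with pytest.raises(ValueError, match="transition"):
            fit_fraction_bound(conc, np.full(4, 0.01))


class TestThermoTable:
    def test_bundled_table_round_trips_printed_columns(self):
        df = thermo_table()
        np.testing.assert_allclose(df["minus_t_delta_s_kj_mol"],
                                   df["printed_minus_tds_kj_mol"], atol=0.1)
        np.testing.assert_allclose(df["delta_g_kj_mol"], df["printed_dg_kj_mol"],
                                   atol=0.1)

    def test_fold_changes_per_complex_group(self):
        df = thermo_table()
        by = df.set_index(["complex", "construct"])
        assert by.loc[("tetO_DNA", "TetR-Q38A"), "fold_change_presented"] == "8.5-fold"
        assert by.loc[("RNA_aptamer", "TetR-Y42A"), "fold_change_presented"] == "2500-fold"
        assert by.loc[("RNA_aptamer", "TetR"), "fold_change"] == pytest.approx(1.0)

    def test_micromolar_column_normalized(self):
        import pandas as pd
        df = pd.DataFrame({
            "complex": ["x"], "construct": ["TetR"], "kd_um": [0.0056],
            "delta_h_kj_mol": [-156.0], "delta_s_j_mol_k": [-365.2],
        })
        out = thermo_table(df)
        assert out["kd_nm"].iloc[0] == pytest.approx(5.6)
        assert out["delta_g_kj_mol"].iloc[0] == pytest.approx(-47.2, abs=0.1)

    def test_missing_reference_rejected(self):
        import pandas as pd
        df = pd.DataFrame({
            "complex": ["x"], "construct": ["variant"], "kd_nm": [5.0],
            "delta_h_kj_mol": [-10.0], "delta_s_j_mol_k": [0.0],
        })
        with pytest.raises(ValueError, match="reference"):
            thermo_table(df)
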