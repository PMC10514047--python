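import math

import numpy as np
import pytest

from condensotherm import synth
from condensotherm.ledger import (
    apply_cancellation,
    assemble_ledger,
    interface_penalty,
    mixing_free_energy,
    protein_energy_change,
    solvation_energy_changes,
    solvation_entropy_changes,
    water_budget,
)
from condensotherm.trajectory import ConcentrationRecord, ConcentrationSeries


def make_series(rows, bulk_s=54.7, bulk_eww=-46.0):
    """rows: list of (rho, n_waters, n_chains, s_tot, e_pp, e_pw, e_ww)."""
    records = [
        ConcentrationRecord(
            rho=1.0, n_chains=0, n_waters=10000,
            s_tot=bulk_s, s_tr=bulk_s * 0.8, s_rot=bulk_s * 0.2,
            e_pp=0.0, e_pw=0.0, e_ww=bulk_eww,
        )
    ]
    for rho, nw, nc, s, epp, epw, eww in rows:
        records.append(
            ConcentrationRecord(
                rho=rho, n_chains=nc, n_waters=nw,
                s_tot=s, s_tr=s * 0.8, s_rot=s * 0.2,
                e_pp=epp, e_pw=epw, e_ww=eww,
            )
        )
    return ConcentrationSeries(records)


class TestWaterBudget:
    def test_zero_release_at_cond(self):
        series = make_series([
            (100.0, 40000, 8, 54.0, -100.0, -200.0, -45.9),
            (350.0, 16509, 8, 52.0, -300.0, -400.0, -45.5),
        ])
        budgets = water_budget(series, 350.0)
        cond = [b for b in budgets if b.rho == 350.0][0]
        assert cond.released == 0.0

    def test_table2_row_gives_2064_retained(self):
        # all-atom condensate composition: 16,509 waters over 8 chains
        series = make_series([(350.0, 16509, 8, 52.0, -300.0, -400.0, -45.5),
                              (25.0, 304821, 8, 54.5, -50.0, -80.0, -46.0)])
        budgets = water_budget(series, 350.0)
        retained = budgets[0].retained
        assert round(retained) == 2064

    def test_release_is_subtraction(self):
        series = make_series([
            (25.0, 5000 * 8, 8, 54.5, -50.0, -80.0, -46.0),
            (350.0, 2000 * 8, 8, 52.0, -300.0, -400.0, -45.5),
        ])
        budgets = water_budget(series, 350.0)
        assert budgets[0].released == pytest.approx(3000.0)

    def test_rows_above_cond_rejected(self):
        series = make_series([
            (350.0, 16509, 8, 52.0, -300.0, -400.0, -45.5),
            (525.0, 9273, 8, 51.0, -350.0, -420.0, -45.2),
        ])
        with pytest.raises(ValueError, match="exceeds"):
            water_budget(series, 350.0)
        budgets = water_budget(series, 350.0, allow_above_cond=True)
        assert len(budgets) == 2


class TestSolvationChanges:
    def _series(self):
        return make_series([
            (25.0, 304821, 8, 54.5, -50.0, -80.0, -45.95),
            (145.0, 47752, 8, 53.5, -150.0, -200.0, -45.6),
            (350.0, 16509, 8, 52.0, -300.0, -400.0, -45.3),
        ])

    def test_flat_entropy_gives_zero_release_term(self):
        series = make_series([
            (25.0, 304821, 8, 54.7, -50.0, -80.0, -46.0),
            (350.0, 16509, 8, 54.7, -300.0, -400.0, -46.0),
        ])
        budgets = water_budget(series, 350.0)
        tug, _ = solvation_entropy_changes(series, budgets, 350.0)
        np.testing.assert_allclose(tug.released, 0.0, atol=1e-9)
        np.testing.assert_allclose(tug.retained, 0.0, atol=1e-9)

    def test_retained_zero_at_cond(self):
        series = self._series()
        budgets = water_budget(series, 350.0)
        tug, _ = solvation_entropy_changes(series, budgets, 350.0)
        idx = [i for i, b in enumerate(budgets) if b.rho == 350.0][0]
        assert tug.retained[idx] == pytest.approx(0.0)
        assert tug.released[idx] == pytest.approx(0.0)

    def test_missing_bulk_reference(self):
        records = [r for r in self._series().records if not r.is_bulk]
        series = ConcentrationSeries(records)
        budgets = water_budget(series, 350.0)
        with pytest.raises(ValueError, match="bulk"):
            solvation_entropy_changes(series, budgets, 350.0)

    def test_spreadsheet_oracle(self):
        # independent arithmetic: plain per-row loops
        series = self._series()
        budgets = water_budget(series, 350.0)
        tug, t_ds = solvation_entropy_changes(series, budgets, 350.0, T=300.0)
        s_dil = 54.7
        s_cond = 52.0
        for i, (rho, nw) in enumerate([(25.0, 304821), (145.0, 47752), (350.0, 16509)]):
            s_rho = series.get(rho).s_tot
            n_w = nw / 8
            released = n_w - 16509 / 8
            expect_rele = (s_dil - s_rho) * released
            expect_reta = (s_cond - s_rho) * (16509 / 8)
            assert tug.released[i] == pytest.approx(expect_rele, abs=1e-9)
            assert tug.retained[i] == pytest.approx(expect_reta, abs=1e-9)
            assert t_ds[i] == pytest.approx(
                300.0 * (expect_rele + expect_reta) / 1000.0, abs=1e-9
            )

    def test_energy_flat_gives_zero(self):
        series = make_series([
            (25.0, 304821, 8, 54.5, -50.0, 0.0, -46.0),
            (350.0, 16509, 8, 52.0, -300.0, 0.0, -46.0),
        ])
        budgets = water_budget(series, 350.0)
        energies = solvation_energy_changes(series, budgets, 350.0)
        np.testing.assert_allclose(energies["WW"].total, 0.0, atol=1e-9)
        np.testing.assert_allclose(energies["PW"].total, 0.0, atol=1e-9)

    def test_energy_spreadsheet_oracle(self):
        series = self._series()
        budgets = water_budget(series, 350.0)
        energies = solvation_energy_changes(series, budgets, 350.0)
        e_ww_dil, e_ww_cond = -46.0, -45.3
        for i, rho in enumerate([25.0, 145.0, 350.0]):
            rec = series.get(rho)
            b = budgets[i]
            expect = (e_ww_dil - rec.e_ww) * b.released + (
                e_ww_cond - rec.e_ww
            ) * b.retained
            assert energies["WW"].total[i] == pytest.approx(expect, abs=1e-9)
            e_pw_rho = rec.e_pw / rec.waters_per_chain
            e_pw_cond = series.get(350.0).e_pw / series.get(350.0).waters_per_chain
            expect_pw = (0.0 - e_pw_rho) * b.released + (
                e_pw_cond - e_pw_rho
            ) * b.retained
            assert energies["PW"].total[i] == pytest.approx(expect_pw, abs=1e-9)

    def test_released_retained_opposite_signs_for_monotone_energy(self):
        # e_ww increases monotonically from bulk to condensate
        series = make_series([
            (25.0, 304821, 8, 54.5, -50.0, -80.0, -45.9),
            (145.0, 47752, 8, 53.5, -150.0, -200.0, -45.6),
            (350.0, 16509, 8, 52.0, -300.0, -400.0, -45.3),
        ], bulk_eww=-46.0)
        budgets = water_budget(series, 350.0)
        energies = solvation_energy_changes(series, budgets, 350.0)
        ww = energies["WW"]
        for i, b in enumerate(budgets):
            if b.rho == 350.0:
                continue
            assert ww.released[i] < 0      # bulk value below e_ww(rho)
            assert ww.retained[i] > 0      # condensate value above e_ww(rho)


class TestCancellation:
    def test_zero_ww_energy(self):
        t_pw, t_ww = apply_cancellation(123.4, 0.0)
        assert t_pw == 123.4
        assert t_ww == 0.0

    def test_full_cancellation(self):
        t_pw, t_ww = apply_cancellation(50.0, 50.0)
        assert t_pw == 0.0
        assert t_ww == 50.0

    def test_identity_on_random_ledgers(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            tables = synth.gen_concentration_tables(
                noise_sd=float(rng.uniform(0, 1)), seed=trial, n_replicates=1
            )
            led = assemble_ledger(tables.series)
            t = led.table
            np.testing.assert_allclose(t["dE_WW"] - t["TdS_WW"], 0.0, atol=1e-9)
            np.testing.assert_allclose(
                t["dH_solv"] - t["TdS_solv"], t["dE_PW"] - t["TdS_PW"], atol=1e-9
            )


class TestProteinEnergy:
    def test_zero_at_cond(self):
        tables = synth.gen_concentration_tables(seed=1)
        de = protein_energy_change(tables.series, 350.0)
        rhos = tables.series.rhos
        assert de[np.isclose(rhos, 350.0)][0] == pytest.approx(0.0)

    def test_negative_for_decreasing_epp(self):
        tables = synth.gen_concentration_tables(seed=1)
        de = protein_energy_change(tables.series, 350.0)
        rhos = tables.series.rhos
        assert np.all(de[rhos < 350.0] < 0)

    def test_oracle(self):
        tables = synth.gen_concentration_tables(seed=2)
        de = protein_energy_change(tables.series, 350.0)
        e_cond = tables.series.get(350.0).e_pp
        for i, rho in enumerate(tables.series.rhos):
            assert de[i] == pytest.approx(
                e_cond - tables.series.get(rho).e_pp, abs=1e-12
            )


class TestAnalyticEstimators:
    def test_mixing_penalty_350_over_1(self):
        # RT ln(350/1) at 300 K: 0.0083145*300*ln(350) = 14.61 kJ/mol,
        # printed as ~14.5
        val = mixing_free_energy(350.0, 1.0, 300.0)
        assert val == pytest.approx(14.61, abs=0.01)
        assert 14.0 < val < 15.0

    def test_mixing_zero_at_equal(self):
        assert mixing_free_energy(100.0, 100.0, 300.0) == 0.0

    def test_mixing_linear_in_t(self):
        assert mixing_free_energy(350.0, 1.0, 600.0) == pytest.approx(
            2.0 * mixing_free_energy(350.0, 1.0, 300.0)
        )

    def test_mixing_validation(self):
        with pytest.raises(ValueError):
            mixing_free_energy(350.0, 0.0, 300.0)

    def test_interface_nanodroplet(self):
        # 3*gamma*M/(c*r): 20 nm droplet, 0.5 mN/m -> 3.69, printed as 4
        val = interface_penalty(20.0, 0.5, 350.0, 17.2)
        assert val == pytest.approx(3.686, abs=0.01)
        assert round(val) == 4

    def test_interface_scaling(self):
        v20 = interface_penalty(20.0, 0.5)
        assert interface_penalty(40.0, 0.5) == pytest.approx(v20 / 2)
        assert interface_penalty(5000.0, 0.5) < 0.02
        with pytest.raises(ValueError):
            interface_penalty(-1.0, 0.5)


class TestAssembleLedger:
    def test_reference_state_nullity(self):
        tables = synth.gen_concentration_tables(noise_sd=0.4, seed=9)
        led = assemble_ledger(tables.series)
        row = led.row(350.0)
        for col in ("dS_tot", "TdS_solv", "dE_WW", "dE_PW", "dH_solv",
                    "dG_solv", "dE_PP", "TdS_P", "dG_total"):
            assert row[col] == pytest.approx(0.0, abs=1e-9), col

    def test_all_flat_inputs_zero(self):
        series = make_series([
            (25.0, 304821, 8, 54.7, -100.0, 0.0, -46.0),
            (145.0, 47752, 8, 54.7, -100.0, 0.0, -46.0),
            (350.0, 16509, 8, 54.7, -100.0, 0.0, -46.0),
        ])
        led = assemble_ledger(series)
        for col in ("TdS_solv", "dE_WW", "dH_solv", "dG_solv", "dE_PP",
                    "dG_total"):
            np.testing.assert_allclose(led.table[col], 0.0, atol=1e-9)

    def test_fig8_like_scenario_negative_dg(self):
        # decreasing S(rho), decreasing E_PP, small dS_P: dG < 0 at low rho
        tables = synth.gen_concentration_tables(noise_sd=0.0, seed=0)
        led = assemble_ledger(tables.series, ds_p=-200.0)
        low = led.row(25.0)
        assert low["dG_solv"] < 0
        assert low["dE_PP"] < 0
        assert low["TdS_P"] < 0          # -T dS_P > 0, unfavourable
        assert low["dG_total"] < 0

    def test_mix_and_interface_flags(self):
        tables = synth.gen_concentration_tables(seed=3)
        base = assemble_ledger(tables.series)
        with_mix = assemble_ledger(tables.series, include_mix=True)
        diff = with_mix.row(25.0)["dG_total"] - base.row(25.0)["dG_total"]
        assert diff == pytest.approx(base.row(25.0)["dG_mix"])
        # reported even when excluded
        assert base.row(25.0)["dG_mix"] == pytest.approx(14.61, abs=0.01)

    def test_replicate_sd_propagation(self):
        tables = synth.gen_concentration_tables(noise_sd=0.5, seed=4)
        led = assemble_ledger(tables.series, replicates=tables.replicates)
        assert "sd_dG_total" in led.table.columns
        assert np.all(led.table["sd_dG_total"] >= 0)
        sd_at_cond = led.row(350.0)["sd_TdS_solv"]
        assert sd_at_cond == pytest.approx(0.0, abs=1e-9)

    def test_inconsistent_replicates_rejected(self):
        tables = synth.gen_concentration_tables(noise_sd=0.5, seed=4)
        short = ConcentrationSeries(tables.replicates[0].records[:-1])
        with pytest.raises(ValueError, match="replicate"):
            assemble_ledger(tables.series, replicates=[tables.replicates[0], short])

    def test_rho_cond_525_sensitivity(self):
        grid = list(synth.DEFAULT_RHO_SERIES)
        tables = synth.gen_concentration_tables(rho_grid=grid, seed=5)
        led350 = assemble_ledger(tables.series, rho_cond=350.0,
                                 allow_above_cond=True)
        led525 = assemble_ledger(tables.series, rho_cond=525.0)
        # same signs, larger magnitudes at low rho for the deeper reference
        a, b = led350.row(25.0), led525.row(25.0)
        assert np.sign(a["dG_solv"]) == np.sign(b["dG_solv"])
        assert abs(b["dE_PP"]) > abs(a["dE_PP"])
        assert abs(b["dG_total"]) > abs(a["dG_total"])
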