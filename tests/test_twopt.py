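import math

import numpy as np
import pytest

from condensotherm import synth, twopt
from condensotherm.constants import KB, H_PLANCK, R_GAS
from condensotherm.trajectory import VelocitySeries

from conftest import constant_velocity_series

NU_BHV1 = KB * 300.0 / H_PLANCK        # ~6.251 THz: h nu = kB T at 300 K
HO_S_BHV1 = 1.0 / (math.e - 1.0) - math.log(1.0 - 1.0 / math.e)  # 1.0407 kB


class TestVACF:
    def test_constant_velocities_flat(self):
        series = constant_velocity_series(n_mol=6, n_frames=40)
        c = twopt.compute_vacf(series, max_lag=0.15)
        expected = float(
            np.sum(series.masses[:, None] * series.com_velocities[0] ** 2)
        )
        np.testing.assert_allclose(c.values, expected, rtol=1e-12)

    def test_cosine_velocity_gives_cosine_vacf(self):
        nu0, dt, n = 2.5, 0.004, 2001
        t = np.arange(n) * dt
        v = np.zeros((n, 1, 3))
        v[:, 0, 0] = np.cos(2 * np.pi * nu0 * t)
        series = VelocitySeries(dt=dt, com_velocities=v, masses=np.array([1.0]))
        c = twopt.compute_vacf(series, max_lag=2.0)
        # the finite time-origin average leaves an O(1/(nu0 T)) cross term
        ref = 0.5 * np.cos(2 * np.pi * nu0 * c.lags)
        np.testing.assert_allclose(c.values, ref, atol=8e-3)

    def test_bruteforce_equivalence(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(100, 10, 3))
        w = rng.normal(size=(100, 10, 3))
        series = VelocitySeries(
            dt=0.01, com_velocities=v, masses=rng.uniform(1, 20, 10),
            angular_velocities=w, principal_moments=np.array([0.006, 0.012, 0.018]),
        )
        for kind in ("translational", "rotational"):
            fast = twopt.compute_vacf(series, kind, max_lag=0.3)
            slow = twopt.compute_vacf_bruteforce(series, kind, max_lag=0.3)
            np.testing.assert_allclose(fast.values, slow.values, atol=1e-10)

    def test_max_lag_limit(self):
        series = constant_velocity_series(n_frames=20, dt=0.1)
        with pytest.raises(ValueError, match="max_lag"):
            twopt.compute_vacf(series, max_lag=1.5)

    def test_rotational_requires_angular(self):
        series = constant_velocity_series()
        with pytest.raises(ValueError, match="angular"):
            twopt.compute_vacf(series, "rotational")


class TestDoS:
    def test_cosine_peak_and_integral(self):
        # frequency on the spectral grid: 25 cycles over the 2 s window
        dt, L = 0.004, 500
        nu0 = 25 / (2 * L * dt)
        n_mol, mass, T = 20, 18.0, 300.0
        series = synth.gen_harmonic_ensemble(
            [nu0], T=T, n_molecules=n_mol, duration=2 * L * dt, dt=dt, seed=1
        )
        c = twopt.compute_vacf(series, max_lag=L * dt)
        dos = twopt.compute_dos(c, T, zero_padding=1)
        peak = dos.frequencies[np.argmax(dos.intensity)]
        assert peak == pytest.approx(nu0, abs=1e-9)
        assert dos.integral() == pytest.approx(3 * n_mol, rel=0.02)

    def test_flat_vacf_zero_bin(self):
        series = constant_velocity_series(n_mol=8, n_frames=200, dt=0.02)
        c = twopt.compute_vacf(series, max_lag=1.0)
        dos = twopt.compute_dos(c, 300.0, zero_padding=1)
        assert dos.s0 == pytest.approx(dos.intensity.sum(), rel=1e-6)

    def test_matches_naive_dft_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=65)
        vals[0] = abs(vals[0]) + 2.0
        c = twopt.Correlogram(
            lags=np.arange(65) * 0.004, values=vals, kind="translational",
            n_molecules=1,
        )
        dos = twopt.compute_dos(c, 300.0, zero_padding=1)
        oracle = twopt.dos_bruteforce(c, 300.0)
        np.testing.assert_allclose(dos.intensity, oracle, atol=1e-9)

    def test_temperature_validation(self):
        c = twopt.Correlogram(
            lags=np.arange(10) * 0.1, values=np.ones(10), kind="translational",
            n_molecules=1,
        )
        with pytest.raises(ValueError, match="temperature"):
            twopt.compute_dos(c, -5.0)


class TestFluidicity:
    def _dos_with_s0(self, s0, n_mol=100):
        freqs = np.linspace(0, 50, 200)
        return twopt.DensityOfStates(
            frequencies=freqs, intensity=np.full(200, s0), kind="translational",
            temperature=300.0, n_molecules=n_mol,
        )

    def test_zero_s0_pure_solid(self):
        dos = self._dos_with_s0(0.0)
        assert twopt.solve_fluidicity(dos, 33.3, 18.0, 300.0) == 0.0

    def test_delta_one_vs_grid_scan(self):
        grid = np.linspace(1e-9, 1.0, 10 ** 6)
        vals = twopt.fluidicity_polynomial(grid, 1.0)
        f_grid = grid[np.argmin(np.abs(vals))]
        from scipy.optimize import brentq

        f_root = brentq(twopt.fluidicity_polynomial, 1e-300, 1.0, args=(1.0,),
                        xtol=1e-12)
        assert f_root == pytest.approx(f_grid, abs=2e-6)
        assert twopt.fluidicity_polynomial(f_root, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_delta(self):
        from scipy.optimize import brentq

        deltas = np.logspace(-4, 1, 60)
        roots = [
            brentq(twopt.fluidicity_polynomial, 1e-300, 1.0, args=(d,), xtol=1e-12)
            for d in deltas
        ]
        assert np.all(np.diff(roots) >= -1e-12)
        assert all(0.0 <= r <= 1.0 for r in roots)

    def test_solver_uses_normalized_diffusivity(self):
        # the solver's f must satisfy the polynomial at the Delta built
        # from (s0, T, m, rho)
        dos = self._dos_with_s0(5.0)
        f = twopt.solve_fluidicity(dos, 33.3, 18.0, 300.0)
        delta = twopt.normalized_diffusivity(5.0, 300.0, 18.0, 33.3, 100)
        assert twopt.fluidicity_polynomial(f, delta) == pytest.approx(0.0, abs=1e-9)


class TestPartition:
    def _broad_dos(self, n_mol=50, T=300.0):
        # Lorentzian-like liquid DoS, resolvable on the grid
        freqs = np.linspace(0, 100, 4001)
        s0 = 8.0
        intensity = s0 / (1.0 + (freqs / 8.0) ** 2)
        # rescale to 3N states
        intensity *= 3 * n_mol / np.trapezoid(intensity, freqs)
        return twopt.DensityOfStates(
            frequencies=freqs, intensity=intensity, kind="translational",
            temperature=T, n_molecules=n_mol,
        )

    def test_f_zero_identity(self):
        dos = self._broad_dos()
        solid, gas = twopt.partition_dos(dos, 0.0)
        np.testing.assert_array_equal(gas.intensity, 0.0)
        np.testing.assert_allclose(solid.intensity, dos.intensity, atol=1e-12)

    def test_gas_integral_matches_f_dof(self):
        dos = self._broad_dos()
        f = 0.3
        solid, gas = twopt.partition_dos(dos, f)
        gas_quad = float(np.trapezoid(gas.intensity, gas.frequencies))
        gas_analytic = twopt.gas_dof_analytic(
            dos.s0, f, dos.dof, float(dos.frequencies[-1])
        )
        assert gas_quad == pytest.approx(gas_analytic, rel=0.01)
        # truncated integral approaches f * dof for wide grids
        assert gas_analytic == pytest.approx(f * dos.dof, rel=0.15)

    def test_solid_plus_gas_reconstructs(self):
        dos = self._broad_dos()
        solid, gas = twopt.partition_dos(dos, 0.2)
        unclipped = solid.intensity > 0
        np.testing.assert_allclose(
            (solid.intensity + gas.intensity)[unclipped],
            dos.intensity[unclipped],
            rtol=1e-9,
        )

    def test_ideal_gas_limit_solid_vanishes(self):
        series = synth.gen_ideal_gas(density=0.05, n=100, duration=100.0,
                                     dt=0.1, seed=4)
        c = twopt.compute_vacf(series)
        dos = twopt.compute_dos(c, 300.0, zero_padding=1)
        f = twopt.solve_fluidicity(dos, 0.05, 18.0153, 300.0)
        assert f > 0.99
        solid, _ = twopt.partition_dos(dos, f)
        assert solid.intensity.sum() < 1e-6 * dos.s0


class TestEntropy:
    def test_pure_ho_delta_dos(self):
        # all solid weight at h nu = kB T, f = 0 -> S = 1.0407 R per dof
        n_mol, T = 10, 300.0
        freqs = np.linspace(0, 20, 100001)
        intensity = np.zeros_like(freqs)
        i0 = int(np.argmin(np.abs(freqs - NU_BHV1)))
        dnu = freqs[1] - freqs[0]
        intensity[i0] = 3 * n_mol / dnu  # delta carrying 3N dof
        mk = lambda inten: twopt.DensityOfStates(
            frequencies=freqs, intensity=inten, kind="translational",
            temperature=T, n_molecules=n_mol,
        )
        breakdown = twopt.entropy_2pt(
            mk(intensity), mk(np.zeros_like(freqs)), 0.0, T, 18.0, 33.3
        )
        per_dof = breakdown.s_tr / (3 * R_GAS)
        assert per_dof == pytest.approx(HO_S_BHV1, rel=2e-3)

    def test_harmonic_pipeline_recovers_ground_truth(self):
        # on-grid frequency avoids spectral leakage
        nu = 6.25
        series = synth.gen_harmonic_ensemble(
            [nu], T=300.0, n_molecules=100, duration=40.0, dt=0.004, seed=7
        )
        eb = twopt.entropy_pipeline(series, 300.0, n_density=33.3, zero_padding=1)
        gt = series.meta["ground_truth"]["entropy_per_dof_kb"]
        assert eb.s_tr / (3 * R_GAS) == pytest.approx(gt, rel=0.01)
        assert eb.f_tr < 1e-3

    def test_ideal_gas_sackur_tetrode(self):
        series = synth.gen_ideal_gas(
            density=0.05, n=400, duration=400.0, dt=0.1, seed=2
        )
        eb = twopt.entropy_pipeline(series, 300.0, n_density=0.05, zero_padding=1)
        st_val = series.meta["ground_truth"]["sackur_tetrode"]
        assert eb.s_tr == pytest.approx(st_val, rel=0.02)

    def test_rotational_requires_moments(self):
        freqs = np.linspace(0, 20, 100)
        mk = lambda: twopt.DensityOfStates(
            frequencies=freqs, intensity=np.ones(100), kind="rotational",
            temperature=300.0, n_molecules=5,
        )
        with pytest.raises(ValueError, match="principal"):
            twopt.entropy_2pt(
                mk(), mk(), 0.1, 300.0, 18.0, 33.3,
                solid_rot=mk(), gas_rot=mk(), f_rot=0.1,
            )

    def test_s_tot_additive_and_validated(self):
        eb = twopt.EntropyBreakdown(s_tr=40.0, s_rot=10.0, s_tr_ho=30.0,
                                    s_tr_hs=10.0, s_rot_ho=8.0, s_rot_rr=2.0,
                                    f_tr=0.3, f_rot=0.1)
        assert eb.s_tot == 50.0
        bad = twopt.EntropyBreakdown(s_tr_ho=-1.0)
        with pytest.raises(ValueError):
            bad.validate()


class TestInvariantsAndProperties:
    def test_dos_normalization_within_2pc(self):
        series = synth.gen_harmonic_ensemble(
            [3.75, 6.25, 12.5], T=300.0, n_molecules=50, duration=40.0,
            dt=0.004, seed=9,
        )
        c = twopt.compute_vacf(series)
        dos = twopt.compute_dos(c, 300.0, zero_padding=1)
        assert dos.integral() == pytest.approx(dos.dof, rel=0.02)

    def test_entropy_intensive(self):
        results = []
        for n_mol, seed in ((50, 1), (100, 2)):
            series = synth.gen_harmonic_ensemble(
                [6.25], T=300.0, n_molecules=n_mol, duration=40.0, dt=0.004,
                seed=seed,
            )
            eb = twopt.entropy_pipeline(series, 300.0, 33.3, zero_padding=1)
            results.append(eb.s_tr)
        # per-molecule entropy is intensive
        assert abs(results[1] - results[0]) / results[0] < 0.01

    def test_more_diffusive_weight_never_decreases_s_tr(self):
        # take a harmonic DoS and plant increasing zero-frequency weight
        series = synth.gen_harmonic_ensemble(
            [6.25], T=300.0, n_molecules=50, duration=40.0, dt=0.004, seed=3
        )
        c = twopt.compute_vacf(series)
        dos = twopt.compute_dos(c, 300.0, zero_padding=1)
        # weights chosen to stay out of the near-solid packing pathology
        # (y ~ 1) where the hard-sphere weight is clamped
        entropies = []
        for extra in (0.0, 8.0, 30.0, 100.0, 300.0):
            dos_mod = twopt.DensityOfStates(
                frequencies=dos.frequencies,
                intensity=dos.intensity + np.where(
                    np.arange(len(dos.intensity)) == 0, extra, 0.0
                ),
                kind="translational", temperature=300.0,
                n_molecules=dos.n_molecules,
            )
            f = twopt.solve_fluidicity(dos_mod, 33.3, 18.0153, 300.0)
            solid, gas = twopt.partition_dos(dos_mod, f)
            eb = twopt.entropy_2pt(solid, gas, f, 300.0, 18.0153, 33.3)
            entropies.append(eb.s_tr)
        assert np.all(np.diff(entropies) >= -1e-9)

    def test_replicate_sd_reported(self):
        values = []
        for seed in (1, 2, 3):
            series = synth.gen_harmonic_ensemble(
                [6.25, 12.5], T=300.0, n_molecules=30, duration=40.0,
                dt=0.004, seed=seed,
            )
            eb = twopt.entropy_pipeline(series, 300.0, 33.3, zero_padding=1)
            values.append(eb.s_tot)
        sd = float(np.std(values))
        assert sd >= 0.0
        assert sd < 0.05 * np.mean(values)
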