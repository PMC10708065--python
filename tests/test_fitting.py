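"""Least-squares rate-constant estimation and its degeneracy structure."""

import dataclasses

import numpy as np
import pytest

import placond as pc
from placond.fitting import GPCDataset


class TestGPCDataset:
    def test_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            GPCDataset(time_h=np.array([1.0, 1.0]), mn=np.array([10.0, 20.0]))
        with pytest.raises(ValueError, match="positive"):
            GPCDataset(time_h=np.array([1.0, 2.0]), mn=np.array([10.0, 0.0]))
        with pytest.raises(ValueError, match="Mw"):
            GPCDataset(
                time_h=np.array([1.0]),
                mn=np.array([100.0]),
                mw=np.array([90.0]),
            )
        with pytest.raises(ValueError, match="dispersity"):
            GPCDataset(
                time_h=np.array([1.0]),
                mn=np.array([100.0]),
                mw=np.array([150.0]),
                dispersity=np.array([2.0]),
            )

    def test_missing_mw_entries_allowed(self):
        d = GPCDataset(
            time_h=np.array([1.0, 2.0]),
            mn=np.array([100.0, 200.0]),
            mw=np.array([np.nan, 250.0]),
        )
        assert len(d) == 2
        np.testing.assert_allclose(d.time_s, [3600.0, 7200.0])


class TestObjective:
    def test_single_observation_hand_value(self, table_params, upper_init):
        traj = pc.simulate(
            table_params, upper_init, sample_times=np.array([36_000.0])
        )
        data = GPCDataset(time_h=np.array([10.0]), mn=np.array([traj.mn[0] + 100.0]))
        assert pc.objective(table_params, data, upper_init) == pytest.approx(
            10_000.0, rel=1e-9
        )

    def test_noiseless_self_consistency(
        self, table_params, upper_init, smooth_fit_integrator
    ):
        spec = pc.SyntheticSpec(
            true_params=table_params,
            init=upper_init,
            sample_times_h=np.linspace(20.0, 200.0, 10),
            noise_cv=0.0,
            integrator=smooth_fit_integrator,
        )
        data = pc.simulate_dataset(spec)[0]
        F = pc.objective(table_params, data, upper_init, smooth_fit_integrator)
        assert F <= 1e-6 * np.sum(data.mn**2)

    def test_unstable_parameters_hit_penalty(self, upper_init):
        data = pc.reference_dataset()
        bad = pc.KineticParameters(1e30, 1e-300, 0.0)
        settings = pc.IntegratorSettings(max_steps=100_000)
        F = pc.objective(bad, data, upper_init, settings)
        assert F == pytest.approx(1e6 * np.sum(data.mn**2))


class TestFit:
    def test_noiseless_refit_recovers_keq_and_kw(
        self, table_params, upper_init, smooth_fit_integrator
    ):
        """From a moderately perturbed start, the simplex must walk back to
        the generating constants: keq within 2%, kw within 5%."""
        spec = pc.SyntheticSpec(
            true_params=table_params,
            init=upper_init,
            sample_times_h=np.linspace(20.0, 200.0, 10),
            noise_cv=0.0,
            integrator=smooth_fit_integrator,
        )
        data = pc.simulate_dataset(spec)[0]
        start = pc.KineticParameters(
            table_params.k1 * 1.2, table_params.k_neg1, table_params.kw * 1.1
        )
        settings = pc.FitSettings(
            n_starts=1,
            start_params=start,
            maxiter=800,
            integrator=smooth_fit_integrator,
        )
        result = pc.fit(data, upper_init, settings)
        assert result.params.keq == pytest.approx(table_params.keq, rel=0.02)
        assert result.params.kw == pytest.approx(table_params.kw, rel=0.05)
        # descent: the returned optimum beats the start
        F_start = pc.objective(start, data, upper_init, smooth_fit_integrator)
        assert result.F <= F_start

    def test_reproducible_under_seed(self, upper_init, smooth_fit_integrator):
        data = pc.reference_dataset()
        settings = pc.FitSettings(
            n_starts=2, seed=5, maxiter=60, integrator=smooth_fit_integrator
        )
        a = pc.fit(data, upper_init, settings)
        b = pc.fit(data, upper_init, settings)
        assert a.params == b.params
        assert a.F == b.F
        assert a.start_F == b.start_F

    def test_objective_weighting_favors_high_mw_points(
        self, table_params, upper_init, smooth_fit_integrator
    ):
        """Dropping the largest-Mn observation moves the fitted kw more than
        dropping the smallest: the absolute-squares objective is dominated
        by the high-molecular-weight tail."""
        spec = pc.SyntheticSpec(
            true_params=table_params,
            init=upper_init,
            sample_times_h=np.linspace(20.0, 200.0, 10),
            noise_cv=0.0,
            integrator=smooth_fit_integrator,
        )
        data = pc.simulate_dataset(spec)[0]
        start = pc.KineticParameters(
            table_params.k1 * 1.15, table_params.k_neg1, table_params.kw * 0.95
        )
        settings = pc.FitSettings(
            n_starts=1,
            start_params=start,
            maxiter=400,
            integrator=smooth_fit_integrator,
        )

        def refit(drop: int) -> float:
            keep = np.ones(len(data), dtype=bool)
            keep[drop] = False
            sub = GPCDataset(time_h=data.time_h[keep], mn=data.mn[keep])
            return pc.fit(sub, upper_init, settings).params.kw

        kw_full = pc.fit(data, upper_init, settings).params.kw
        shift_drop_largest = abs(refit(int(np.argmax(data.mn))) - kw_full)
        shift_drop_smallest = abs(refit(int(np.argmin(data.mn))) - kw_full)
        assert shift_drop_largest >= shift_drop_smallest


class TestDegeneracyScan:
    def test_identity_factor_reproduces_objective(self, table_params, upper_init):
        data = pc.reference_dataset()
        table = pc.degeneracy_scan(table_params, data, upper_init, [(1.0, 1.0)])
        assert table.F[0] == pytest.approx(
            pc.objective(table_params, data, upper_init), rel=1e-12
        )

    def test_uniform_ray_flat_nonuniform_steep(self, table_params, upper_init):
        """Scaling both constants 10x down barely moves F; scaling k1 alone
        10x up inflates it by orders of magnitude."""
        data = pc.reference_dataset()
        table = pc.degeneracy_scan(
            table_params,
            data,
            upper_init,
            [(1.0, 1.0), (0.1, 0.1), (10.0, 1.0)],
        )
        F0 = table.F[0]
        assert abs(table.F[1] - F0) / F0 < 0.05
        assert table.F[2] >= 2.0 * F0

    def test_rejects_nonpositive_factors(self, table_params, upper_init):
        with pytest.raises(ValueError):
            pc.degeneracy_scan(
                table_params, pc.reference_dataset(), upper_init, [(0.0, 1.0)]
            )
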