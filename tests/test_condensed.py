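"""Condensed three-variable model: rates, Mn estimator, limits, trajectories."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import placond as pc
from placond.condensed import ZeroChainEndsError
from placond.integrator import integrate
from placond.mass_balance import FW_MONO


def state(a, c, w, S=0.0, C=0.0, t=0.0):
    return pc.MixtureState(t=t, a=a, c=c, w=w, S=S, C=C)


class TestWaterMoleFraction:
    def test_examples(self):
        assert pc.water_mole_fraction(state(1.0, 0.0, 0.0)) == 0.0
        assert pc.water_mole_fraction(state(1.0, 0.0, 2.0)) == pytest.approx(0.5)
        # hand evaluation of the bond-counting formula
        s = state(0.37, 5.2, 5.2, S=9.4, C=0.007)
        expect = 5.2 / (2 * 0.37 + 5.2 + 5.2 + 9.4 + 0.007)
        assert pc.water_mole_fraction(s) == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(0.253, abs=5e-3)

    @given(
        a=st.floats(1e-6, 100.0),
        c=st.floats(0.0, 100.0),
        w=st.floats(0.0, 100.0),
        S=st.floats(0.0, 100.0),
    )
    def test_bounded(self, a, c, w, S):
        assert 0.0 <= pc.water_mole_fraction(state(a, c, w, S=S)) < 1.0


class TestRhs:
    def test_pure_depolymerization(self):
        p = pc.KineticParameters(1.0, 0.3, 0.0)
        dc, da, dw = pc.rhs(state(0.0, 2.0, 1.5), p)
        assert dc == pytest.approx(-0.3 * 2.0 * 1.5)
        assert da == -dc
        assert dc < 0

    def test_irreversible_closed_system(self):
        p = pc.KineticParameters(0.5, 1e-300, 0.0)
        dc, da, dw = pc.rhs(state(2.0, 0.0, 0.0), p)
        assert dc == pytest.approx(2.0)
        assert dw == pytest.approx(2.0)
        assert da == pytest.approx(-2.0)

    def test_equilibrium_balance(self):
        # k1 a^2 = k_-1 c w makes every derivative vanish (kw = 0)
        p = pc.KineticParameters(2.0, 0.5, 0.0)
        a, w = 1.0, 0.8
        c = p.k1 * a**2 / (p.k_neg1 * w)
        dc, da, dw = pc.rhs(state(a, c, w), p)
        assert dc == pytest.approx(0.0, abs=1e-14)
        assert da == pytest.approx(0.0, abs=1e-14)
        assert dw == pytest.approx(0.0, abs=1e-14)

    def test_stepwise_variant_switches_k1(self):
        p = pc.KineticParameters(1.0, 1e-300, 0.0, variant_enabled=True)
        low = state(1.0, 10.0, 0.0)        # Mn = 720 Da, below threshold
        high = state(1.0, 200.0, 0.0)      # Mn = 14412 Da, above threshold
        assert pc.rhs(low, p)[0] == pytest.approx(1.0)
        assert pc.rhs(high, p)[0] == pytest.approx(p.k1_reduction_factor)


class TestNumberAverageMw:
    def test_printed_and_corrected_modes(self):
        assert pc.number_average_mw(state(1.0, 0.0, 0.0)) == 0.0
        assert pc.number_average_mw(state(1.0, 1000.0, 0.0)) == pytest.approx(
            72_060.0
        )
        assert pc.number_average_mw(
            state(1.0, 1000.0, 0.0), corrected=True
        ) == pytest.approx(1001 * FW_MONO)

    def test_no_chain_ends_signalled(self):
        with pytest.raises(ZeroChainEndsError):
            pc.number_average_mw(state(0.0, 1.0, 0.0))

    def test_agrees_with_chain_resolved_moments(self):
        """(sum i P_i / sum P_i) * FW equals the corrected estimator on the
        aggregated state, for an arbitrary resolved distribution."""
        rng = np.random.default_rng(3)
        P = np.zeros(64)
        P[:20] = rng.uniform(0, 0.3, 20)
        cs = pc.ChainState(P=P, W=0.1, S=9.4, C=0.007)
        mn, _, _ = pc.distribution_moments(cs)
        assert mn == pytest.approx(
            pc.number_average_mw(pc.aggregate(cs), corrected=True), rel=1e-12
        )


class TestAnalyticZeroWater:
    def test_initial_condition(self):
        assert pc.analytic_zero_water(5.0, 0.01, 0.0) == (5.0, 0.0, 0.0)

    def test_closed_form_values(self):
        a, c, mn = pc.analytic_zero_water(5.0, 0.01, 100.0)
        assert a == pytest.approx(5.0 / 6.0, rel=1e-12)
        assert c == pytest.approx(5.0 - 5.0 / 6.0, rel=1e-12)
        assert mn == pytest.approx(5.0 * FW_MONO, rel=1e-12)
        # internal consistency: Mn = (c/a) FW exactly
        assert mn == pytest.approx(c / a * FW_MONO, rel=1e-12)


class TestEquilibriumDp:
    @pytest.mark.parametrize(
        "keq, expected", [(232.8, 15.26), (246.0, 15.68), (1.0, 1.0)]
    )
    def test_sqrt_keq(self, keq, expected):
        p = pc.KineticParameters(keq, 1.0, 0.0)
        assert pc.equilibrium_dp(p) == pytest.approx(expected, abs=5e-3)


class TestTrajectoryProperties:
    def test_chain_end_ester_sum_conserved(self, reference_trajectory, upper_init):
        drift = np.abs(
            reference_trajectory.a + reference_trajectory.c - upper_init.a0
        )
        assert drift.max() <= 1e-9 * upper_init.a0

    def test_removed_water_nondecreasing(self, reference_trajectory):
        assert np.min(np.diff(reference_trajectory.removed_water)) >= -1e-12

    def test_faster_removal_raises_mn(self, table_params, upper_init, hourly_200h):
        """Past the transient, a larger water-removal coefficient shifts the
        equilibrium further toward polymer at every sample."""
        lo = pc.simulate(table_params, upper_init, sample_times=hourly_200h)
        hi = pc.simulate(
            pc.KineticParameters(15.06, 6.47e-2, 6e-4),
            upper_init,
            sample_times=hourly_200h,
        )
        past = hourly_200h >= 10 * 3600.0
        assert np.all(hi.mn[past] >= lo.mn[past])

    def test_early_transient_dp_near_sqrt_keq(self, table_params, upper_init):
        # 0.1 s base step resolves the sub-second relaxation; the 1 s
        # default leaves a few-percent step bias on c/a in this window
        traj = pc.simulate(
            table_params,
            upper_init,
            pc.IntegratorSettings(base_step=0.1, t_end=300.0),
            sample_times=np.array([120.0, 300.0]),
        )
        dp = traj.c / traj.a
        target = pc.equilibrium_dp(table_params)
        assert np.all(np.abs(dp - target) <= 0.05 * target)

    def test_stepwise_variant_caps_growth(
        self, table_params, upper_init, hourly_200h
    ):
        import dataclasses

        variant = dataclasses.replace(table_params, variant_enabled=True)
        plain = pc.simulate(table_params, upper_init, sample_times=hourly_200h)
        slowed = pc.simulate(variant, upper_init, sample_times=hourly_200h)
        late = plain.mn > 2 * variant.me_threshold
        assert np.all(slowed.mn[late] <= plain.mn[late])

    def test_compiled_and_generic_paths_agree(self, table_params, upper_init):
        """The numba kernel and the generic pure-Python integrator are the
        same algorithm; their trajectories must agree to machine precision."""
        samples = np.array([1.0, 10.0, 60.0, 300.0, 600.0])
        fast = pc.simulate(table_params, upper_init, sample_times=samples)

        S, C = upper_init.S, upper_init.C
        p = table_params

        def rhs_acw(y):
            a, c, w = y
            r = p.k1 * a * a - p.k_neg1 * c * w
            xw = w / (2.0 * a + c + w + S + C)
            return np.array([-r, r, r - p.kw * xw])

        res = integrate(
            rhs_acw,
            [upper_init.a0, upper_init.c0, upper_init.w0],
            pc.IntegratorSettings(),
            samples,
            positive_indices=(0,),
        )
        assert res.stable and fast.stable
        np.testing.assert_allclose(res.y[:, 0], fast.a, rtol=1e-12)
        np.testing.assert_allclose(res.y[:, 1], fast.c, rtol=1e-12)
        np.testing.assert_allclose(res.y[:, 2], fast.w, rtol=1e-12)

    def test_export_columns(self, reference_trajectory):
        frame = reference_trajectory.to_frame()
        assert list(frame.columns) == [
            "time_s",
            "a_mol_L",
            "c_mol_L",
            "w_mol_L",
            "xw",
            "Mn_Da",
        ]
        assert len(frame) == reference_trajectory.t.size


def test_keq_is_ratio_and_validated():
    p = pc.KineticParameters(15.06, 6.47e-2, 4.85e-4)
    assert p.keq == pytest.approx(232.8, abs=0.05)
    with pytest.raises(ValueError):
        pc.KineticParameters(-1.0, 1.0, 0.0)
    with pytest.raises(ValueError):
        pc.KineticParameters(1.0, 1.0, -1e-6)
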