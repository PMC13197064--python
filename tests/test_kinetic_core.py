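import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from levandmm.kinetic_core import (
    FermentationState,
    KineticParameterSet,
    growth_rate,
    hydrolysis_rate,
    levan_degradation_rate,
    rates,
    rhs,
    transfructosylation_rate,
)


class TestGrowthRate:
    def test_zero_substrate_gives_zero_growth(self, simple_params):
        assert growth_rate(simple_params, 0.0) == 0.0

    def test_half_saturation(self, simple_params):
        mu = growth_rate(simple_params, simple_params.Ks)
        assert mu == pytest.approx(simple_params.mu_max / 2)

    def test_saturates_at_mu_max(self, low_params):
        # fitted low-regime value 0.2454 1/h recovered at saturating sucrose
        mu = growth_rate(low_params, 1e6 * low_params.Ks)
        assert mu == pytest.approx(0.2454, rel=1e-5)

    def test_monod_limit_and_origin(self, low_params):
        assert growth_rate(low_params, 0.0) == 0.0
        mu = growth_rate(low_params, 1e9 * low_params.Ks)
        assert abs(mu - low_params.mu_max) / low_params.mu_max < 1e-6

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(s1=st.floats(0, 1e4), s2=st.floats(0, 1e4))
    def test_monotone_and_bounded(self, simple_params, s1, s2):
        lo, hi = sorted((s1, s2))
        m1, m2 = growth_rate(simple_params, lo), growth_rate(simple_params, hi)
        assert 0.0 <= m1 <= m2 <= simple_params.mu_max

    def test_negative_substrate_rejected(self, simple_params):
        with pytest.raises(ValueError):
            growth_rate(simple_params, -1.0)


class TestEnzymaticRates:
    def test_hydrolysis_examples(self, simple_params):
        assert hydrolysis_rate(simple_params, 0.0) == 0.0
        assert hydrolysis_rate(simple_params, simple_params.KM_hyd) == \
            pytest.approx(simple_params.vmax_hyd / 2)
        # vmax=2, KM=10, S=30 -> 2*30/40 = 1.5
        assert hydrolysis_rate(simple_params, 30.0) == pytest.approx(1.5)

    def test_transfructosylation_vanishes_without_sucrose(self, simple_params):
        assert transfructosylation_rate(simple_params, 0.0, 50.0) == 0.0

    def test_transfructosylation_single_substrate_limit(self, simple_params):
        # F=0 reduces to the sucrose-only Michaelis-Menten form
        p = simple_params
        for S in (1.0, 50.0, 500.0):
            expected = p.vmax_trans1 * (S / p.KM_trans1) / (1 + S / p.KM_trans1)
            assert transfructosylation_rate(p, S, 0.0) == pytest.approx(expected)

    def test_transfructosylation_saturates_at_fitted_vmax(self, low_params):
        # fitted value 6.42 mmol/(mg h) at saturating sucrose
        v = transfructosylation_rate(low_params, 1e9, 0.0)
        assert v == pytest.approx(6.42, rel=1e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(S=st.floats(0, 1e5), F=st.floats(0, 1e4))
    def test_transfructosylation_bounded(self, simple_params, S, F):
        v = transfructosylation_rate(simple_params, S, F)
        assert 0.0 <= v <= max(simple_params.vmax_trans1,
                               simple_params.vmax_trans2) + 1e-12

    def test_degradation_gated_before_onset(self, simple_params):
        assert levan_degradation_rate(simple_params, 100.0,
                                      simple_params.t_levdeg_onset - 1e-6) == 0.0
        assert levan_degradation_rate(simple_params, 0.0, 100.0) == 0.0

    def test_degradation_half_saturation_on_degradable_fraction(self, simple_params):
        p = simple_params
        # 0.67*L = KM -> half vmax
        L = p.KM_levdeg / (1 - p.degradable_fraction_complement)
        v = levan_degradation_rate(p, L, p.t_levdeg_onset + 1.0)
        assert v == pytest.approx(p.vmax_levdeg / 2)

    def test_negative_inputs_rejected(self, simple_params):
        with pytest.raises(ValueError):
            hydrolysis_rate(simple_params, -1.0)
        with pytest.raises(ValueError):
            transfructosylation_rate(simple_params, 10.0, -1.0)
        with pytest.raises(ValueError):
            levan_degradation_rate(simple_params, -1.0, 100.0)


class TestRhs:
    def test_washout_state_is_absorbing(self, simple_params):
        state = FermentationState(X=0.0, E=0.0, S_cell=0.0, Glc=5.0, Fru=5.0,
                                  S_reactor=100.0, Levan=5.0, t=20.0)
        dy, rv = rhs(state, simple_params)
        assert np.all(dy == 0.0)

    def test_glucosyl_balance_identity(self, simple_params):
        # glucose gain always equals enzymatic sucrose consumption
        state = FermentationState(X=1.3, E=10.0, S_cell=2.0, Glc=1.0, Fru=7.0,
                                  S_reactor=150.0, Levan=30.0, t=20.0)
        dy, rv = rhs(state, simple_params)
        e_pool = simple_params.alpha * state.X
        assert dy[3] == pytest.approx((rv.v3 + rv.v4) * e_pool)
        # and the reactor sucrose drain is growth + the same enzymatic term
        assert dy[5] == pytest.approx(-rv.v1 - (rv.v3 + rv.v4) * e_pool)

    def test_full_state_against_hand_evaluation(self, simple_params):
        # every term evaluated by hand from the rate laws:
        # mu=0.2*100/110=2/11, v1=mu/0.05=40/11, v2=20*mu=40/11,
        # v3=2*100/110=20/11, v4=(4*1+4*1)/(1+1+1)=8/3,
        # v5=0.5*3.35/23.35, E_pool=20
        state = FermentationState(X=1.0, E=5.0, S_cell=0.0, Glc=0.0, Fru=10.0,
                                  S_reactor=100.0, Levan=5.0, t=13.0)
        dy, rv = rhs(state, simple_params)
        assert rv.mu == pytest.approx(2 / 11)
        assert rv.v4 == pytest.approx(8 / 3)
        v5 = 0.5 * 3.35 / 23.35
        expected = np.array([
            2 / 11 - 0.01,          # dX
            40 / 11,                # dE
            40 / 11,                # dS_cell (cumulative consumed)
            (20 / 11 + 8 / 3) * 20,             # dGlc = 89.69697
            (20 / 11 - 8 / 3 + v5) * 20,        # dFru = -15.535007
            -40 / 11 - (20 / 11 + 8 / 3) * 20,  # dS_reactor = -93.33333
            (8 / 3 - v5) * 20,                  # dLevan = 51.898644
        ])
        np.testing.assert_allclose(dy, expected, rtol=1e-12)

    def test_as_printed_variant_leaves_v3_bare(self, simple_params):
        state = FermentationState(X=1.0, E=5.0, S_cell=0.0, Glc=0.0, Fru=10.0,
                                  S_reactor=100.0, Levan=5.0, t=13.0)
        dy, rv = rhs(state, simple_params, equations="as_printed")
        e_pool = simple_params.alpha * state.X
        assert dy[3] == pytest.approx(rv.v3 + rv.v4 * e_pool)
        assert dy[5] == pytest.approx(-rv.v1 - rv.v3 - rv.v4 * e_pool)

    def test_non_finite_state_rejected(self, simple_params):
        state = FermentationState(X=np.nan, E=0.0, S_cell=0.0, Glc=0.0,
                                  Fru=0.0, S_reactor=10.0, Levan=0.0)
        with pytest.raises(ValueError):
            rhs(state, simple_params)

    def test_degradation_flux_zero_before_onset(self, simple_params):
        state = FermentationState(X=1.0, E=5.0, S_cell=0.0, Glc=0.0, Fru=1.0,
                                  S_reactor=50.0, Levan=100.0, t=0.0)
        rv = rates(state, simple_params, t=simple_params.t_levdeg_onset / 2)
        assert rv.v5_vol == 0.0
        rv2 = rates(state, simple_params, t=simple_params.t_levdeg_onset + 1)
        assert rv2.v5_vol > 0.0


class TestParameterValidation:
    @pytest.mark.parametrize("field,value", [
        ("mu_max", -0.1), ("Ks", 0.0), ("Y_XS", -1.0), ("KM_hyd", 0.0),
        ("degradable_fraction_complement", 1.0), ("t_levdeg_onset", -1.0),
    ])
    def test_invalid_parameters_rejected(self, simple_params, field, value):
        with pytest.raises(ValueError):
            simple_params.with_updates(**{field: value})

    def test_json_round_trip(self, tmp_path, low_params):
        path = tmp_path / "params.json"
        low_params.to_json(path)
        back = KineticParameterSet.from_json(path)
        assert back == low_params
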