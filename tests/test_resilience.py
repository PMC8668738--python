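import numpy as np
import pandas as pd
import pytest

from irakit import (
    DataError,
    assign_regimes,
    build_attractors,
    compute_resilience,
    detect_regimes_sequential,
    fit_pca,
    insert_repulsion_states,
    interpolate_landscape,
    orient_components,
    place_tipping_points,
)
from irakit.resilience import Attractor, SystemStates


@pytest.fixture(scope="module")
def preset_resilience(noisy_scenario):
    stressors, system, truth = noisy_scenario
    pc1sys = orient_components(fit_pca(system, scale=True)).score_series(1)
    pc1str = orient_components(fit_pca(stressors, scale=True)).score_series(1)
    seq = detect_regimes_sequential(pc1sys, pc1str)
    assert len(seq.stages) == 2
    years = pc1sys.years
    states = assign_regimes(
        years, pc1str.values, pc1sys.values, seq.threshold_years,
        exclude_years=(int(years[-1]),),
    )
    attractors = build_attractors(seq.stages, states)
    tips = place_tipping_points(attractors, states)
    res = compute_resilience(states, attractors, tips)
    return states, attractors, tips, res


def linear_attractor(regime=1, slope=2.0, intercept=1.0):
    cx = np.linspace(0.0, 1.0, 50)
    return Attractor(regime=regime, year_range=(2000, 2010),
                     curve_x=cx, curve_y=intercept + slope * cx,
                     end_slopes=(slope, slope))


class TestAttractors:
    def test_branch_counts(self, noise_free_scores):
        pc1sys, pc1str, truth = noise_free_scores
        seq = detect_regimes_sequential(pc1sys, pc1str)
        states = assign_regimes(pc1sys.years, pc1str.values, pc1sys.values,
                                seq.threshold_years)
        atts = build_attractors(seq.stages, states)
        assert [a.regime for a in atts] == [1, 2, 3]
        states2 = assign_regimes(pc1sys.years, pc1str.values, pc1sys.values,
                                 [seq.threshold_years[0]])
        atts2 = build_attractors(seq.stages[:1], states2)
        assert [a.regime for a in atts2] == [1, 2]

    def test_linear_extension_of_end_slopes(self):
        a = linear_attractor(slope=2.0, intercept=1.0)
        assert a.value(1.5)[0] == pytest.approx(1.0 + 2.0 * 1.5, abs=1e-10)
        assert a.value(-0.5)[0] == pytest.approx(1.0 - 1.0, abs=1e-10)


class TestTippingPoints:
    def test_single_year_regime_is_binding(self):
        # regime 2 has one year; its tipping point sits exactly vComp away
        att1 = linear_attractor(regime=1, slope=0.0, intercept=1.0)
        att2 = Attractor(regime=2, year_range=(2011, 2011),
                         curve_x=np.array([2.0, 2.1]),
                         curve_y=np.array([-1.0, -1.0]), end_slopes=(0.0, 0.0))
        states = SystemStates(
            years=np.array([2009, 2010, 2011]),
            x=np.array([0.2, 0.8, 2.0]),
            y=np.array([1.0, 1.0, -0.7]),  # last year sits 0.3 off its attractor
            regime=np.array([1, 1, 2]),
        )
        tips = place_tipping_points([att1, att2], states)
        f2 = next(t for t in tips if t.regime == 2)
        assert f2.x == pytest.approx(2.0 - 0.3)
        res = compute_resilience(states, [att1, att2], tips)
        assert res.table.loc[res.table.regime == 2, "res"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_vcomp_puts_tip_at_extreme(self):
        att = linear_attractor(regime=1, slope=0.0, intercept=0.0)
        att2 = Attractor(regime=2, year_range=(2012, 2013),
                         curve_x=np.array([3.0, 3.1]),
                         curve_y=np.array([0.0, 0.0]), end_slopes=(0.0, 0.0))
        states = SystemStates(
            years=np.arange(2009, 2014),
            x=np.array([0.1, 0.9, 0.5, 3.0, 3.1]),
            y=np.zeros(5),
            regime=np.array([1, 1, 1, 2, 2]),
        )
        tips = place_tipping_points([att, att2], states)
        f1 = next(t for t in tips if t.regime == 1)
        assert f1.x == pytest.approx(0.9)  # regime 1's extreme toward regime 2

    def test_binding_property_on_preset(self, preset_resilience):
        states, attractors, tips, res = preset_resilience
        tab = res.table[res.table.regime > 0]
        for regime, grp in tab.groupby("regime"):
            own = [t for t in tips if t.regime == regime]
            gaps = [
                min(abs(r.x - t.x) for t in own) - r.vcomp
                for r in grp.itertuples()
            ]
            assert min(gaps) == pytest.approx(0.0, abs=1e-8)

    def test_four_points_for_three_regimes(self, preset_resilience):
        _, _, tips, _ = preset_resilience
        assert [t.label for t in tips] == ["F1", "F2", "F3", "F4"]
        assert [t.regime for t in tips] == [1, 2, 2, 3]


class TestResilienceSeries:
    def test_invariants_on_preset(self, preset_resilience):
        _, _, _, res = preset_resilience
        tab = res.table[res.table.regime > 0]
        per_regime_min = tab.groupby("regime")["res"].min()
        assert np.allclose(per_regime_min, 0.0, atol=1e-8)
        assert (tab["res"] >= -1e-8).all()
        assert tab["rres"].max() == pytest.approx(1.0, abs=1e-12)

    def test_axis_scaling_equivariance(self, preset_resilience):
        states, attractors, tips, res = preset_resilience
        scaled_states = SystemStates(states.years, 2 * states.x, 2 * states.y,
                                     states.regime)
        scaled_atts = [
            Attractor(a.regime, a.year_range, 2 * a.curve_x, 2 * a.curve_y,
                      a.end_slopes)
            for a in attractors
        ]
        scaled_tips = place_tipping_points(scaled_atts, scaled_states)
        res2 = compute_resilience(scaled_states, scaled_atts, scaled_tips)
        mask = res.table.regime > 0
        assert np.allclose(res2.table.loc[mask, "res"],
                           2 * res.table.loc[mask, "res"], atol=1e-8)
        assert np.allclose(res2.table.loc[mask, "rres"],
                           res.table.loc[mask, "rres"], atol=1e-8)

    def test_excluded_year_carries_no_resilience(self, preset_resilience):
        states, _, _, res = preset_resilience
        last = res.table.iloc[-1]
        assert last["regime"] == 0 and np.isnan(last["res"])


class TestRepulsionStates:
    def test_two_synthetic_states_keep_corridors_low(self, preset_resilience):
        states, attractors, tips, res = preset_resilience
        pts = insert_repulsion_states(tips, attractors, res)
        synth = pts[pts.kind == "repulsion"]
        assert len(synth) == 2
        tab = res.table[res.table.regime > 0]
        # every repulsion state sits well below the typical basin altitude
        for i, (_, row) in enumerate(synth.iterrows()):
            adjacent = tab[tab.regime.isin([i + 1, i + 2])]
            assert row.rres < adjacent["rres"].mean()
        # the first fold is sharp: its repulsion state is below even the
        # binding (zero-resilience) years
        assert synth.iloc[0].rres < tab["rres"].min()

    def test_symmetric_fold_midpoint(self):
        flat_low = Attractor(1, (2000, 2001), np.array([0.0, 1.0]),
                             np.array([0.0, 0.0]), (0.0, 0.0))
        flat_high = Attractor(2, (2002, 2003), np.array([0.0, 1.0]),
                              np.array([2.0, 2.0]), (0.0, 0.0))
        from irakit.resilience import TippingPoint

        tips = [TippingPoint("F1", 0.4, 1, 1), TippingPoint("F2", 0.6, 2, -1)]
        res_tab = pd.DataFrame(
            {"x": [0.0, 1.0], "y": [0.0, 2.0], "regime": [1, 2],
             "res": [1.0, 1.0], "rres": [1.0, 1.0]}
        )
        pts = insert_repulsion_states(
            tips, [flat_low, flat_high],
            type("R", (), {"table": res_tab})(),
        )
        synth = pts[pts.kind == "repulsion"].iloc[0]
        assert synth.x == pytest.approx(0.5)
        assert synth.y == pytest.approx(1.0)  # midway between the attractors


class TestLandscape:
    def test_barycentric_identity_on_triangle(self):
        pts = pd.DataFrame(
            {"x": [0.0, 1.0, 0.0], "y": [0.0, 0.0, 1.0], "rres": [0.0, 0.0, 1.0]}
        )
        ls = interpolate_landscape(pts, grid_n=100)
        assert ls.rres.shape == (100, 100)
        from scipy.interpolate import LinearNDInterpolator

        interp = LinearNDInterpolator(pts[["x", "y"]].to_numpy(),
                                      pts["rres"].to_numpy())
        assert interp(1 / 3, 1 / 3) == pytest.approx(1 / 3, abs=1e-12)

    def test_surface_reproduces_input_points(self, preset_resilience):
        states, attractors, tips, res = preset_resilience
        pts = insert_repulsion_states(tips, attractors, res)
        ls = interpolate_landscape(pts)
        from scipy.interpolate import LinearNDInterpolator

        interp = LinearNDInterpolator(pts[["x", "y"]].to_numpy(),
                                      pts["rres"].to_numpy())
        got = interp(pts["x"].to_numpy(), pts["y"].to_numpy())
        assert np.allclose(got, pts["rres"], atol=1e-10)
        assert ls.rres.shape == (100, 100)
        assert np.isnan(ls.rres).any()  # corners outside the hull are missing

    def test_collinear_points_rejected(self):
        pts = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 1.0, 2.0],
                            "rres": [0.0, 0.5, 1.0]})
        with pytest.raises(DataError):
            interpolate_landscape(pts)
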