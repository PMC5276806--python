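"""Exchange-flux estimation and uptake/release deconvolution."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acetrace.exchange import (
    EmptyARangeError,
    GrowthCurve,
    SingularExchangeSystemError,
    deconvolve,
    deconvolve_with_uncertainty,
    integrated_cell_volume,
    net_exchange,
    release_uptake_ratio,
)
from acetrace.quant import AcetateConcentrations
from acetrace.simulate import get_preset, simulate_growth, simulate_medium_acetate


def series(points):
    return [
        AcetateConcentrations(f"s{i}", t, c12, c13)
        for i, (t, c12, c13) in enumerate(points)
    ]


class TestIntegratedCellVolume:
    def test_constant_pcv(self):
        g = GrowthCurve([0.0, 24.0], [3.0, 3.0], medium_volume_ml=3.0)
        assert integrated_cell_volume(g, 0, 24) == pytest.approx(0.024)

    def test_zero_length_interval(self):
        g = GrowthCurve([0.0, 24.0], [3.0, 3.0], 3.0)
        assert integrated_cell_volume(g, 5, 5) == 0.0

    def test_linear_growth_equals_midpoint_constant(self):
        lin = GrowthCurve([0.0, 24.0], [2.0, 4.0], 3.0)
        const = GrowthCurve([0.0, 24.0], [3.0, 3.0], 3.0)
        assert integrated_cell_volume(lin, 0, 24) == pytest.approx(
            integrated_cell_volume(const, 0, 24)
        )

    def test_reversed_interval_rejected(self):
        g = GrowthCurve([0.0, 24.0], [3.0, 3.0], 3.0)
        with pytest.raises(ValueError):
            integrated_cell_volume(g, 10, 5)


class TestNetExchange:
    def test_unchanged_total_gives_zero(self):
        g = GrowthCurve([0.0, 24.0], [3.0, 3.0], 3.0)
        s = series([(0, 15, 90), (24, 40, 65)])
        assert net_exchange(s, g) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # ΔC_total = −24 μM over ∫pcv dt = 9 μL·hr in 3 mL → −8 mmol/hr/L cell
        g = GrowthCurve([0.0, 3.0], [3.0, 3.0], 3.0)
        s = series([(0, 15, 90), (3, 15, 66)])
        assert net_exchange(s, g) == pytest.approx(-8.0)

    def test_linearity_in_medium_volume(self):
        s = series([(0, 15, 90), (24, 15, 66)])
        e1 = net_exchange(s, GrowthCurve([0.0, 24.0], [3.0, 3.0], 3.0))
        e2 = net_exchange(s, GrowthCurve([0.0, 24.0], [3.0, 3.0], 6.0))
        assert e2 == pytest.approx(2 * e1)


class TestDeconvolve:
    def test_label_composition_unchanged_means_pure_uptake(self):
        # x = b forces r = 0, u = −e
        d_total, t_int, b = -30.0, 0.01, 0.25
        d_c12 = b * d_total
        r, u = deconvolve(d_total, d_c12, t_int, a=0.9, b=b)
        assert r == pytest.approx(0.0, abs=1e-9)
        assert u == pytest.approx(-d_total / 1e3 / t_int)

    def test_hand_solved_balanced_exchange(self):
        # e = 0, xe = 2, a = 1, b = 0.5 → r = u = 4
        t_int = 1e-3
        r, u = deconvolve(0.0, 2.0 * 1e3 * t_int, t_int, a=1.0, b=0.5)
        assert (r, u) == (pytest.approx(4.0), pytest.approx(4.0))

    def test_hand_solved_net_uptake(self):
        # a = 1, b = 0, e = −1, xe = 3 → r = 3, u = 4
        t_int = 1e-3
        r, u = deconvolve(-1.0 * 1e3 * t_int, 3.0 * 1e3 * t_int, t_int, a=1.0, b=0.0)
        assert (r, u) == (pytest.approx(3.0), pytest.approx(4.0))

    def test_singular_system_rejected(self):
        with pytest.raises(SingularExchangeSystemError):
            deconvolve(1.0, 1.0, 0.01, a=0.5, b=0.5)

    @given(
        a=st.floats(0.3, 1.0),
        b=st.floats(0.0, 0.25),
        d_total=st.floats(-50, 50),
        d_c12=st.floats(-50, 50),
    )
    def test_balance_identity_r_minus_u_equals_e(self, a, b, d_total, d_c12):
        t_int = 0.01
        r, u = deconvolve(d_total, d_c12, t_int, a, b)
        assert r - u == pytest.approx(d_total / 1e3 / t_int, rel=1e-9, abs=1e-9)

    def test_release_magnitude_monotone_in_a_minus_b(self):
        t_int, b = 0.01, 0.2
        rs = [abs(deconvolve(-10.0, 5.0, t_int, a, b)[0]) for a in np.linspace(0.4, 1.0, 20)]
        assert np.all(np.diff(rs) <= 1e-12)


class TestDeconvolveWithUncertainty:
    def test_simulator_roundtrip_recovers_fluxes(self):
        """(r, u, a) = (4, 4, 0.9), zero noise, dense sampling: r and u at
        the true a are recovered within 1% and the scan brackets them."""
        cfg = get_preset(
            "MDA468_normoxia", u=4.0, r=4.0, a=0.9,
            medium_times=tuple(np.linspace(0, 24, 25)),
        )
        truth, _ = simulate_medium_acetate(cfg, noise_cv=0.0)
        growth = simulate_growth(cfg, cfg.medium_times)
        est = deconvolve_with_uncertainty(truth, growth)
        grid = np.array([0.9])
        est_true_a = deconvolve_with_uncertainty(truth, growth, a_grid=grid)
        assert est_true_a.r_q05 == pytest.approx(4.0, rel=0.01)
        assert est_true_a.u_q05 == pytest.approx(4.0, rel=0.01)
        # the a-scan lower bounds must not exceed the true fluxes
        assert est.r_q05 <= 4.0 and est.u_q05 <= 4.0
        assert est.e_median == pytest.approx(0.0, abs=0.05)

    def test_pure_uptake_series_has_zero_release_bound(self):
        cfg = get_preset("BT474_lowserum")
        truth, _ = simulate_medium_acetate(cfg, noise_cv=0.0)
        growth = simulate_growth(cfg, cfg.medium_times)
        est = deconvolve_with_uncertainty(truth, growth)
        assert est.r_q05 == pytest.approx(0.0, abs=0.2)

    def test_e_is_independent_of_a_grid(self):
        cfg = get_preset("MDA468_normoxia")
        truth, _ = simulate_medium_acetate(cfg, noise_cv=0.0)
        growth = simulate_growth(cfg, cfg.medium_times)
        e1 = deconvolve_with_uncertainty(truth, growth, a_grid=np.array([0.8])).e_median
        e2 = deconvolve_with_uncertainty(truth, growth, a_grid=np.array([0.99])).e_median
        assert e1 == pytest.approx(e2, abs=1e-12)
        assert e1 == pytest.approx(net_exchange(truth, growth), abs=1e-12)

    def test_volume_scaling_leaves_fluxes_unchanged(self):
        cfg = get_preset("MDA468_normoxia")
        truth, _ = simulate_medium_acetate(cfg, noise_cv=0.0)
        g1 = simulate_growth(cfg, cfg.medium_times)
        g2 = GrowthCurve(g1.times, g1.pcv * 10, g1.medium_volume_ml * 10)
        e1 = deconvolve_with_uncertainty(truth, g1)
        e2 = deconvolve_with_uncertainty(truth, g2)
        assert e1.r_q05 == pytest.approx(e2.r_q05, rel=1e-9)
        assert e1.u_q05 == pytest.approx(e2.u_q05, rel=1e-9)

    def test_empty_retained_range_is_diagnosed(self):
        # total acetate increases while the unlabeled share of the increase
        # exceeds what any a in the scanned band can release
        s = series([(0, 15, 90), (24, 10, 120)])
        growth = GrowthCurve([0.0, 24.0], [3.0, 3.0], 3.0)
        with pytest.raises(EmptyARangeError):
            deconvolve_with_uncertainty(s, growth, a_grid=np.array([0.5, 0.7, 0.9]))

    def test_bootstrap_over_wells_is_seeded(self, rng):
        cfg = get_preset("MDA468_normoxia")
        growth = simulate_growth(cfg, cfg.medium_times)
        wells = []
        for w in range(3):
            truth, _ = simulate_medium_acetate(cfg, noise_cv=0.0)
            noisy = [
                AcetateConcentrations(
                    c.sample_id, c.time_hr,
                    c.c12 * rng.lognormal(0, 0.02), c.c13 * rng.lognormal(0, 0.02),
                )
                for c in truth
            ]
            wells.append(noisy)
        est1 = deconvolve_with_uncertainty(wells, growth, n_boot=200, seed=7)
        est2 = deconvolve_with_uncertainty(wells, growth, n_boot=200, seed=7)
        assert est1 == est2
        assert est1.n_boot == 200


class TestReleaseUptakeRatio:
    def test_no_accumulation_gives_zero(self):
        s = series([(0, 15, 90), (24, 15, 60)])
        assert release_uptake_ratio(s) == pytest.approx(0.0)

    def test_balanced_exchange_gives_one(self):
        s = series([(0, 15, 90), (24, 45, 60)])
        assert release_uptake_ratio(s) == pytest.approx(1.0)

    def test_no_consumption_rejected(self):
        s = series([(0, 15, 90), (24, 20, 95)])
        with pytest.raises(ValueError):
            release_uptake_ratio(s)

    def test_high_capture_scenario_lowers_ratio(self):
        """Cells retaining endogenous acetate (high uptake, a near 1 so
        little unlabeled release) show a smaller released/consumed ratio —
        the direction of the ACSS2 anticorrelation."""
        high = get_preset("MDA468_normoxia", u=6.0, r=1.0, a=0.95)
        low = get_preset("MDA468_normoxia", u=2.0, r=3.5, a=0.85)
        ratios = {}
        for name, cfg in (("high", high), ("low", low)):
            truth, _ = simulate_medium_acetate(cfg, noise_cv=0.0)
            ratios[name] = release_uptake_ratio(truth)
        assert ratios["high"] < ratios["low"]


class TestGrowthCurve:
    def test_invariants(self):
        with pytest.raises(ValueError):
            GrowthCurve([0.0], [1.0], 3.0)
        with pytest.raises(ValueError):
            GrowthCurve([0.0, 0.0], [1.0, 1.0], 3.0)
        with pytest.raises(ValueError):
            GrowthCurve([0.0, 1.0], [1.0, -1.0], 3.0)
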