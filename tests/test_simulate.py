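"""Synthetic-data generator: growth, medium dynamics, MIDs, determinism."""

import numpy as np
import pandas as pd
import pytest

from acetrace import io as aio
from acetrace.exchange import integrated_cell_volume, net_exchange
from acetrace.histones import histone_fraction_labeled
from acetrace.isa import fit_enrichment
from acetrace.mid import PALMITATE_METHYL_ESTER, forward_convolve, na_correct
from acetrace.mid import MassIsotopomerDistribution
from acetrace.quant import quantify
from acetrace.simulate import (
    ScenarioConfig,
    get_preset,
    simulate_growth,
    simulate_histone_hydrolysate,
    simulate_medium_acetate,
    simulate_palmitate_mids,
    write_bundle,
)


class TestGrowth:
    def test_doubling(self):
        cfg = ScenarioConfig(doubling_time_hr=30.0, pcv0_ul=2.0)
        g = simulate_growth(cfg, [0.0, 30.0, 60.0])
        np.testing.assert_allclose(g.pcv, [2.0, 4.0, 8.0])

    def test_integral_closed_form(self):
        cfg = ScenarioConfig(doubling_time_hr=24.0, pcv0_ul=1.0, medium_volume_ml=3.0)
        g = simulate_growth(cfg, np.linspace(0, 24, 241))
        expected = 1.0 * 24.0 / np.log(2) * (2 - 1) / 3.0 * 1e-3  # ∫pcv0·2^(t/td)
        assert integrated_cell_volume(g, 0, 24) == pytest.approx(expected, rel=1e-4)


class TestMediumDynamics:
    def test_no_fluxes_constant_concentrations(self):
        cfg = ScenarioConfig(u=0.0, r=0.0)
        truth, _ = simulate_medium_acetate(cfg, noise_cv=0.0)
        assert all(c.c_total == pytest.approx(105.0, rel=1e-9) for c in truth)
        assert all(c.c12 == pytest.approx(15.0, rel=1e-9) for c in truth)

    def test_pure_uptake_preserves_composition(self):
        cfg = ScenarioConfig(u=5.0, r=0.0)
        truth, _ = simulate_medium_acetate(cfg, noise_cv=0.0)
        fracs = [c.fraction_12c for c in truth]
        np.testing.assert_allclose(fracs, fracs[0], rtol=1e-8)

    def test_hypoxic_cells_deplete_tracer(self):
        """Most of the tracer is consumed by 72 h; complete depletion is
        impossible because release at unlabeled fraction a keeps a floor of
        (1−a)·c_total ≈ 10.5 μM in the medium."""
        cfg = get_preset("MDA468_hypoxia", pcv0_ul=3.0)
        truth, _ = simulate_medium_acetate(cfg, times=np.linspace(0, 72, 19), noise_cv=0.0)
        floor = (1 - cfg.a) * truth[-1].c_total
        assert truth[-1].c13 < 0.2 * truth[0].c13
        assert truth[-1].c13 == pytest.approx(floor, rel=0.25)

    def test_mass_balance_matches_net_flux(self):
        """ΔC_total equals ∫(r−u)·V_cell dt within integrator tolerance."""
        cfg = ScenarioConfig(u=3.0, r=1.5)
        times = np.linspace(0, 24, 49)
        truth, _ = simulate_medium_acetate(cfg, times=times, noise_cv=0.0)
        growth = simulate_growth(cfg, times)
        e = net_exchange(truth, growth)
        assert e == pytest.approx(cfg.r - cfg.u, rel=5e-3)

    def test_concentrations_never_negative_under_avid_uptake(self):
        cfg = ScenarioConfig(u=20.0, r=0.0, pcv0_ul=5.0)
        truth, _ = simulate_medium_acetate(cfg, times=np.linspace(0, 72, 25), noise_cv=0.0)
        assert all(c.c12 >= 0 and c.c13 >= 0 for c in truth)

    def test_zero_noise_intensities_invert_exactly(self):
        cfg = get_preset("MDA468_normoxia")
        truth, sim = simulate_medium_acetate(cfg, noise_cv=0.0)
        for true_c, m in zip(truth, aio.sim_measurements_from_table(sim)):
            c = quantify(m)
            assert c.c_total == pytest.approx(true_c.c_total, rel=1e-12, abs=1e-9)


class TestPalmitateMids:
    def test_unenriched_matches_natural_abundance_pattern(self):
        cfg = ScenarioConfig(d_acetate=0.0)
        df = simulate_palmitate_mids(cfg, times=[0.0, 24.0], noise_cv=0.0)
        natural = forward_convolve(
            MassIsotopomerDistribution("palmitate", np.eye(17)[0]),
            PALMITATE_METHYL_ESTER,
        )
        for _, m in aio.mids_from_table(df).items():
            np.testing.assert_allclose(m.fractions, natural.fractions, atol=1e-12)

    def test_roundtrip_recovery_at_long_time(self):
        cfg = ScenarioConfig(d_acetate=0.30, g_turnover_k=0.1)
        df = simulate_palmitate_mids(cfg, times=[96.0], noise_cv=0.0)
        raw = list(aio.mids_from_table(df).values())[0]
        fit = fit_enrichment(na_correct(raw, PALMITATE_METHYL_ESTER))
        assert fit.d == pytest.approx(0.30, abs=0.005)
        assert fit.g == pytest.approx(1.0, abs=0.005)

    def test_frozen_turnover_is_time_invariant(self):
        cfg = ScenarioConfig(g_turnover_k=0.0, d_acetate=0.5)
        df = simulate_palmitate_mids(cfg, times=[0.0, 24.0, 48.0], noise_cv=0.0)
        mids = list(aio.mids_from_table(df).values())
        for m in mids[1:]:
            np.testing.assert_allclose(m.fractions, mids[0].fractions, atol=1e-12)


class TestHistoneHydrolysate:
    def test_zero_noise_inversion(self):
        cfg = get_preset("histone_hypoxia_lowserum")
        df = simulate_histone_hydrolysate(cfg, noise_cv=0.0)
        meas = aio.sim_measurements_from_table(df)
        by_tracer = dict(zip(df["tracer"], meas))
        assert histone_fraction_labeled(by_tracer["acetate"]) == pytest.approx(15.0)

    def test_monte_carlo_mean_close_to_preset(self):
        cfg = get_preset("histone_normoxia")
        vals = []
        for seed in range(200):
            df = simulate_histone_hydrolysate(cfg, seed=seed, noise_cv=0.02)
            meas = aio.sim_measurements_from_table(df)
            by_tracer = dict(zip(df["tracer"], meas))
            vals.append(histone_fraction_labeled(by_tracer["acetate"]))
        assert np.mean(vals) == pytest.approx(8.0, abs=0.5)


class TestDeterminism:
    def test_fixed_seed_bitwise_identical_bundles(self, tmp_path):
        cfg = get_preset("MDA468_normoxia")
        d1 = write_bundle(cfg, tmp_path / "a", seed=11)
        d2 = write_bundle(cfg, tmp_path / "b", seed=11)
        for name in ("growth.csv", "medium_sim.csv", "palmitate_mids.csv",
                     "histone_sim.csv", "manifest.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        cfg = get_preset("MDA468_normoxia")
        d1 = write_bundle(cfg, tmp_path / "a", seed=1)
        d2 = write_bundle(cfg, tmp_path / "b", seed=2)
        assert (d1 / "medium_sim.csv").read_bytes() != (d2 / "medium_sim.csv").read_bytes()

    def test_bundle_passes_validation(self, tmp_path):
        cfg = get_preset("BT474_lowserum")
        out = write_bundle(cfg, tmp_path / "bundle", seed=0)
        assert aio.validate_bundle(out) == []
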