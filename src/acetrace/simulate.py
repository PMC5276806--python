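"""Seeded simulator for 13C-acetate tracing experiments.

Generates every input the analysis pipeline consumes — growth curves,
medium-acetate SIM intensity tables, palmitate MID time courses and
histone-hydrolysate SIM tables — with the statistical structure the
analysis assumes:

* exponential cell growth (packed cell volume doubling at a fixed rate);
* medium acetate obeying the uptake/release balance
  d(c_total)/dt·V_med = (r − u)·V_cell and
  d(c12)/dt·V_med = (a·r − b(t)·u)·V_cell with b(t) = c12/c_total,
  integrated by fixed-step RK4 with a linear substrate-limited uptake
  taper below a small concentration to keep pools non-negative;
* binomial palmitate labeling from a two-state acetyl-unit precursor with
  first-order pool turnover g(t) = 1 − exp(−k·t), convolved with natural
  isotopic abundance;
* multiplicative lognormal measurement noise on every intensity channel.

Condition presets encode the study design: 90 μM U-13C-acetate on ~15 μM
residual unlabeled acetate in 3 mL of medium per well (500 μM tracer for
the avidly-consuming BT-474 conditions so the substrate is non-limiting
over a 48 h window), with uptake/release magnitudes, lipogenic
enrichments and histone-labeling panels for normoxic, hypoxic/low-serum,
synthetase-silenced and fatty-acid-supplemented scenarios.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import isa, mid
from .exchange import GrowthCurve
from .quant import AcetateConcentrations, effective_is_concentration

#: Arbitrary-unit intensity of the internal-standard channel.
_I64_BASE = 1e6
#: Nominal acetate concentration of the histone hydrolysate (μM).
_HYDROLYSATE_TOTAL_UM = 50.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete parameterization of one simulated tracing experiment.

    Fluxes u (uptake) and r (release) are mmol/hr/L cell volume; a is the
    unlabeled fraction of intracellular acetate; c13_0/c12_0 the initial
    medium tracer and residual unlabeled acetate (μM); D_* the lipogenic
    AcCoA enrichment reached with each tracer; g_turnover_k the
    first-order palmitate-pool turnover (1/hr); palmitate_pool in mmol/L
    cell volume; histone_fractions the per-tracer percent labeling of
    histone-bound acetate.
    """

    name: str = "custom"
    doubling_time_hr: float = 40.0
    pcv0_ul: float = 1.0
    medium_volume_ml: float = 3.0
    u: float = 3.5
    r: float = 3.5
    a: float = 0.9
    c13_0: float = 90.0
    c12_0: float = 15.0
    d_acetate: float = 0.05
    d_glucose: float = 0.45
    d_glutamine: float = 0.15
    g_turnover_k: float = 0.03
    palmitate_pool: float = 25.0
    histone_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"glucose": 50.0, "glutamine": 12.0, "acetate": 8.0}
    )
    noise_cv: float = 0.02
    taper_um: float = 5.0
    medium_times: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
    kfp_times: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0, 48.0)
    is_volume_ml: float = 0.040
    is_conc_um: float = 1000.0
    sample_volume_ml: float = 0.200

    def __post_init__(self):
        if self.doubling_time_hr <= 0 or self.pcv0_ul <= 0 or self.medium_volume_ml <= 0:
            raise ValueError("growth and volume parameters must be positive")
        if self.u < 0 or self.r < 0:
            raise ValueError("fluxes must be non-negative")
        for frac in (self.a, self.d_acetate, self.d_glucose, self.d_glutamine):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.c13_0 < 0 or self.c12_0 < 0:
            raise ValueError("initial concentrations must be non-negative")


PRESETS: dict[str, ScenarioConfig] = {
    # uptake and release both ~3-4 mmol/hr/L cell, net exchange ~0
    "MDA468_normoxia": ScenarioConfig(
        name="MDA468_normoxia", doubling_time_hr=40.0, u=3.5, r=3.5, a=0.9,
        d_acetate=0.05, d_glucose=0.45, d_glutamine=0.15, g_turnover_k=0.03,
        histone_fractions={"glucose": 50.0, "glutamine": 12.0, "acetate": 8.0},
    ),
    # hypoxia: lipogenic AcCoA ~30% from 90 μM tracer; slower growth
    "MDA468_hypoxia": ScenarioConfig(
        name="MDA468_hypoxia", doubling_time_hr=60.0, u=3.5, r=3.5, a=0.9,
        d_acetate=0.30, d_glucose=0.20, d_glutamine=0.30, g_turnover_k=0.02,
        histone_fractions={"glucose": 30.0, "glutamine": 25.0, "acetate": 8.0},
    ),
    # highest ACSS2, most avid net uptake (~8), negligible release; 500 μM
    # tracer so the medium pool is non-limiting over 48 h
    "BT474_lowserum": ScenarioConfig(
        name="BT474_lowserum", doubling_time_hr=55.0, u=8.0, r=0.0, a=0.9,
        c13_0=500.0, d_acetate=0.30, g_turnover_k=0.04,
        medium_times=(0.0, 8.0, 16.0, 24.0, 32.0, 40.0, 48.0),
        histone_fractions={"glucose": 35.0, "glutamine": 20.0, "acetate": 12.0},
    ),
    # ACSS1 silencing scales uptake by 0.7 (~30% net-uptake reduction)
    "BT474_siACSS1": ScenarioConfig(
        name="BT474_siACSS1", doubling_time_hr=55.0, u=5.6, r=0.0, a=0.9,
        c13_0=500.0, d_acetate=0.30, g_turnover_k=0.04,
        medium_times=(0.0, 8.0, 16.0, 24.0, 32.0, 40.0, 48.0),
        histone_fractions={"glucose": 35.0, "glutamine": 20.0, "acetate": 12.0},
    ),
    # hypoxia + low serum: induced lipogenesis; acetyl demand 8·k·P = 10
    # vs net uptake 4 → demand/uptake 2.5-fold
    "hypoxia_lowserum_demand": ScenarioConfig(
        name="hypoxia_lowserum_demand", doubling_time_hr=60.0, u=5.0, r=1.0,
        a=0.9, d_acetate=0.30, g_turnover_k=0.05, palmitate_pool=25.0,
        histone_fractions={"glucose": 30.0, "glutamine": 25.0, "acetate": 15.0},
    ),
    # free fatty acid supplementation halves de novo lipogenesis
    "FFA_supplement": ScenarioConfig(
        name="FFA_supplement", doubling_time_hr=60.0, u=5.0, r=1.0,
        a=0.9, d_acetate=0.30, g_turnover_k=0.025, palmitate_pool=25.0,
        histone_fractions={"glucose": 30.0, "glutamine": 25.0, "acetate": 18.0},
    ),
    # histone-bound acetate panels: acetate <10% in normoxia, ~15% in
    # hypoxia/low serum
    "histone_normoxia": ScenarioConfig(
        name="histone_normoxia",
        histone_fractions={"glucose": 55.0, "glutamine": 12.0, "acetate": 8.0},
    ),
    "histone_hypoxia_lowserum": ScenarioConfig(
        name="histone_hypoxia_lowserum", doubling_time_hr=60.0, d_acetate=0.30,
        histone_fractions={"glucose": 30.0, "glutamine": 25.0, "acetate": 15.0},
    ),
}


def get_preset(name: str, **overrides) -> ScenarioConfig:
    """Fetch a condition preset, optionally overriding fields."""
    try:
        cfg = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return replace(cfg, **overrides) if overrides else cfg


def _noise_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-1 multiplicative lognormal factors with the given CV."""
    if cv <= 0:
        return np.ones(n)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def simulate_growth(cfg: ScenarioConfig, times: Sequence[float]) -> GrowthCurve:
    """Exponential growth curve pcv(t) = pcv0 · 2^(t/doubling_time)."""
    t = np.asarray(times, float)
    pcv = cfg.pcv0_ul * 2.0 ** (t / cfg.doubling_time_hr)
    return GrowthCurve(times=t, pcv=pcv, medium_volume_ml=cfg.medium_volume_ml)


def _medium_ode(cfg: ScenarioConfig, t_end: float, dt: float = 0.1):
    """Fixed-step RK4 integration of the medium acetate balance.

    Returns (grid times, c_total, c12). Uptake is linearly tapered below
    ``taper_um`` total acetate so the medium pool cannot go negative.
    """

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        c_total, c12 = y
        c_total = max(c_total, 0.0)
        b = c12 / c_total if c_total > 1e-12 else 0.0
        u_eff = cfg.u * min(1.0, c_total / cfg.taper_um)
        # V_cell/V_medium; ×1e3 turns mmol/hr/L_medium into μM/hr
        scale = (
            cfg.pcv0_ul * 2.0 ** (t / cfg.doubling_time_hr) * 1e-6
            / (cfg.medium_volume_ml * 1e-3)
            * 1e3
        )
        return np.array(
            [(cfg.r - u_eff) * scale, (cfg.a * cfg.r - b * u_eff) * scale]
        )

    n_steps = max(1, int(np.ceil(t_end / dt)))
    ts = np.linspace(0.0, t_end, n_steps + 1)
    h = ts[1] - ts[0] if n_steps > 0 else dt
    ys = np.empty((n_steps + 1, 2))
    ys[0] = (cfg.c13_0 + cfg.c12_0, cfg.c12_0)
    y = ys[0].copy()
    for i, t in enumerate(ts[:-1]):
        k1 = rhs(t, y)
        k2 = rhs(t + h / 2, y + h / 2 * k1)
        k3 = rhs(t + h / 2, y + h / 2 * k2)
        k4 = rhs(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        y = np.clip(y, 0.0, None)
        y[1] = min(y[1], y[0])
        ys[i + 1] = y
    return ts, ys[:, 0], ys[:, 1]


def simulate_medium_acetate(
    cfg: ScenarioConfig,
    times: Sequence[float] | None = None,
    *,
    seed: int | None = 0,
    n_wells: int = 1,
    noise_cv: float | None = None,
) -> tuple[list[AcetateConcentrations], pd.DataFrame]:
    """Medium acetate time course plus SIM intensity table.

    Returns the true (noise-free) concentration series and a long-format
    SIM table (one row per well × time) whose intensities invert exactly
    to the true concentrations at zero noise.
    """
    times = np.asarray(cfg.medium_times if times is None else times, float)
    cv = cfg.noise_cv if noise_cv is None else noise_cv
    rng = np.random.default_rng(seed)
    ts, c_tot, c12 = _medium_ode(cfg, float(times.max()) if times.size else 0.0)
    c_tot_s = np.interp(times, ts, c_tot)
    c12_s = np.interp(times, ts, c12)
    c13_s = np.clip(c_tot_s - c12_s, 0.0, None)

    truth = [
        AcetateConcentrations(f"{cfg.name}_t{t:g}", float(t), float(a), float(b))
        for t, a, b in zip(times, c12_s, c13_s)
    ]
    c_is = effective_is_concentration(
        cfg.is_volume_ml, cfg.is_conc_um, cfg.sample_volume_ml
    )
    rows = []
    for w in range(n_wells):
        f61 = _noise_factors(rng, cv, times.size)
        f63 = _noise_factors(rng, cv, times.size)
        f64 = _noise_factors(rng, cv, times.size)
        for i, t in enumerate(times):
            rows.append(
                {
                    "sample_id": f"{cfg.name}_w{w}_t{t:g}",
                    "condition": cfg.name,
                    "well": w,
                    "sample_type": "medium",
                    "time_hr": float(t),
                    "mz61": c12_s[i] / c_is * _I64_BASE * f61[i],
                    "mz63": c13_s[i] / c_is * _I64_BASE * f63[i],
                    "mz64": _I64_BASE * f64[i],
                }
            )
    return truth, pd.DataFrame(rows)


def simulate_palmitate_mids(
    cfg: ScenarioConfig,
    times: Sequence[float] | None = None,
    *,
    seed: int | None = 0,
    tracer: str = "acetate",
    noise_cv: float | None = None,
) -> pd.DataFrame:
    """Raw palmitate MID time course (natural abundance + noise applied).

    g(t) = 1 − exp(−g_turnover_k·t); the tracer-only MID forward_mid(D,
    g(t)) is convolved with the natural-abundance matrix of the palmitate
    methyl ester and scaled to arbitrary intensities with multiplicative
    noise. Long format: sample_id, analyte, time_hr, mass_shift, intensity.
    """
    times = np.asarray(cfg.kfp_times if times is None else times, float)
    cv = cfg.noise_cv if noise_cv is None else noise_cv
    rng = np.random.default_rng(seed)
    d = {"acetate": cfg.d_acetate, "glucose": cfg.d_glucose,
         "glutamine": cfg.d_glutamine}[tracer]
    rows = []
    for t in times:
        g = 1.0 - np.exp(-cfg.g_turnover_k * t)
        tracer_mid = isa.forward_mid(d, g)
        raw = mid.forward_convolve(tracer_mid, mid.PALMITATE_METHYL_ESTER)
        intens = raw.fractions * 1e6 * _noise_factors(rng, cv, raw.fractions.size)
        for shift, val in enumerate(intens):
            rows.append(
                {
                    "sample_id": f"{cfg.name}_{tracer}_t{t:g}",
                    "condition": cfg.name,
                    "tracer": tracer,
                    "analyte": "palmitate",
                    "time_hr": float(t),
                    "mass_shift": shift,
                    "intensity": float(val),
                }
            )
    return pd.DataFrame(rows)


def simulate_histone_hydrolysate(
    cfg: ScenarioConfig,
    *,
    seed: int | None = 0,
    noise_cv: float | None = None,
) -> pd.DataFrame:
    """Histone-hydrolysate SIM intensities, one row per tracer experiment.

    The hydrolysate's labeled fraction c13/(c12+c13) equals the preset
    per-tracer percent; intensities are generated by inverting the
    internal-standard quantification, with multiplicative noise.
    """
    cv = cfg.noise_cv if noise_cv is None else noise_cv
    rng = np.random.default_rng(seed)
    c_is = effective_is_concentration(
        cfg.is_volume_ml, cfg.is_conc_um, cfg.sample_volume_ml
    )
    rows = []
    for tracer, pct in cfg.histone_fractions.items():
        c13 = pct / 100.0 * _HYDROLYSATE_TOTAL_UM
        c12 = _HYDROLYSATE_TOTAL_UM - c13
        f = _noise_factors(rng, cv, 3)
        rows.append(
            {
                "sample_id": f"{cfg.name}_histone_{tracer}",
                "condition": cfg.name,
                "tracer": tracer,
                "sample_type": "histone_hydrolysate",
                "time_hr": 48.0,
                "mz61": c12 / c_is * _I64_BASE * f[0],
                "mz63": c13 / c_is * _I64_BASE * f[1],
                "mz64": _I64_BASE * f[2],
            }
        )
    return pd.DataFrame(rows)


def write_bundle(
    cfg: ScenarioConfig,
    out_dir: str | Path,
    *,
    seed: int = 0,
    n_wells: int = 3,
    noise_cv: float | None = None,
) -> Path:
    """Write the full CSV bundle one experiment produces, plus a manifest
    of true parameters for recovery tests. Fixed seed ⇒ identical bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cv = cfg.noise_cv if noise_cv is None else noise_cv
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)

    all_times = sorted(set(cfg.medium_times) | set(cfg.kfp_times))
    growth = simulate_growth(cfg, all_times)
    pd.DataFrame(
        {"time_hr": growth.times, "pcv_ul": growth.pcv}
    ).to_csv(out / "growth.csv", index=False)

    _, sim = simulate_medium_acetate(
        cfg, seed=int(seeds[0]), n_wells=n_wells, noise_cv=cv
    )
    sim.to_csv(out / "medium_sim.csv", index=False)

    mids = simulate_palmitate_mids(cfg, seed=int(seeds[1]), noise_cv=cv)
    mids.to_csv(out / "palmitate_mids.csv", index=False)

    hist = simulate_histone_hydrolysate(cfg, seed=int(seeds[2]), noise_cv=cv)
    hist.to_csv(out / "histone_sim.csv", index=False)

    manifest = {
        "condition": cfg.name,
        "seed": seed,
        "n_wells": n_wells,
        "noise_cv": cv,
        "files": {
            "growth": "growth.csv",
            "medium_sim": "medium_sim.csv",
            "palmitate_mids": "palmitate_mids.csv",
            "histone_sim": "histone_sim.csv",
        },
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
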