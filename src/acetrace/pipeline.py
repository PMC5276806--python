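"""End-to-end analysis of one experiment bundle.

Composes the stages — SIM quantification, exchange-flux deconvolution,
isotopomer spectral analysis, kinetic flux profiling and histone-acetate
labeling — into a deterministic run over a simulated (or equivalently
formatted real) CSV bundle, writing result tables and a JSON summary.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .exchange import deconvolve_with_uncertainty, net_exchange, release_uptake_ratio
from .histones import HistoneAcetatePanel, histone_fraction_labeled
from .isa import fit_enrichment
from .kfp import NetReleaseError, demand_vs_uptake, fit_synthesis, newly_synthesized_series
from .mid import PALMITATE_METHYL_ESTER, na_correct
from .quant import quantify

logger = logging.getLogger(__name__)


def run_pipeline(
    bundle_dir: str | Path,
    out_dir: str | Path,
    *,
    seed: int = 0,
    n_boot: int = 1000,
) -> dict:
    """Run every analysis stage on a bundle and write results.

    Outputs fluxes.csv, isa.csv, kfp.csv, histone.csv and summary.json in
    ``out_dir``; returns the summary dict. Deterministic for a fixed seed.
    """
    bundle = Path(bundle_dir)
    out = Path(out_dir)
    issues = io.validate_bundle(bundle)
    if issues:
        raise io.BundleValidationError(issues)
    out.mkdir(parents=True, exist_ok=True)
    manifest = json.loads((bundle / "manifest.json").read_text())
    cfg = manifest["config"]
    condition = manifest["condition"]
    t_start = time.perf_counter()

    growth = io.growth_from_table(
        io.read_table(bundle / manifest["files"]["growth"]), cfg["medium_volume_ml"]
    )

    # --- exchange fluxes ---------------------------------------------------
    sim_df = io.read_table(bundle / manifest["files"]["medium_sim"])
    wells = []
    for _, well_df in sim_df.groupby("well"):
        meas = io.sim_measurements_from_table(
            well_df,
            is_volume_ml=cfg["is_volume_ml"],
            is_conc_um=cfg["is_conc_um"],
            sample_volume_ml=cfg["sample_volume_ml"],
        )
        wells.append([quantify(m) for m in meas])
    est = deconvolve_with_uncertainty(wells, growth, n_boot=n_boot, seed=seed)
    mean_series = wells[0] if len(wells) == 1 else _mean_series(wells)
    e_point = net_exchange(mean_series, growth)
    try:
        ratio = release_uptake_ratio(mean_series)
    except ValueError:
        ratio = float("nan")
    flux_row = {
        "condition": condition,
        "e_median": est.e_median,
        "e_ci_lo": est.e_ci95[0],
        "e_ci_hi": est.e_ci95[1],
        "r_q05": est.r_q05,
        "u_q05": est.u_q05,
        "a_lo": est.a_retained[0],
        "a_hi": est.a_retained[1],
        "release_uptake_ratio": ratio,
        "n_boot": est.n_boot,
        "seed": seed,
    }
    pd.DataFrame([flux_row]).to_csv(out / "fluxes.csv", index=False)
    logger.info("exchange stage done (%.2fs)", time.perf_counter() - t_start)

    # --- ISA + KFP on the palmitate time course ----------------------------
    mid_df = io.read_table(bundle / manifest["files"]["palmitate_mids"])
    raw_mids = io.mids_from_table(mid_df)
    times = {
        sid: float(grp["time_hr"].iloc[0])
        for sid, grp in mid_df.groupby("sample_id", sort=False)
    }
    corrected = {
        sid: na_correct(m, PALMITATE_METHYL_ESTER) for sid, m in raw_mids.items()
    }
    isa_rows = []
    for sid, m in corrected.items():
        fit = fit_enrichment(m)
        isa_rows.append(
            {
                "sample_id": sid,
                "condition": condition,
                "time_hr": times[sid],
                "D_percent": fit.d_percent,
                "g": fit.g,
                "ssr": fit.ssr,
            }
        )
    isa_df = pd.DataFrame(isa_rows).sort_values("time_hr")
    isa_df.to_csv(out / "isa.csv", index=False)

    order = sorted(corrected, key=lambda s: times[s])
    t_arr = [times[s] for s in order]
    d_shared, gs = newly_synthesized_series(t_arr, [corrected[s] for s in order])
    kfit = fit_synthesis(t_arr, gs, cfg["palmitate_pool"])
    kfp_row = {
        "condition": condition,
        "D_shared_percent": 100.0 * d_shared,
        "k_per_hr": kfit.k,
        "J_syn": kfit.j_syn,
        "acetyl_demand": kfit.acetyl_demand,
        "rss": kfit.rss,
    }
    pd.DataFrame([kfp_row]).to_csv(out / "kfp.csv", index=False)

    # --- histone-bound acetate ---------------------------------------------
    hist_df = io.read_table(bundle / manifest["files"]["histone_sim"])
    hist_meas = io.sim_measurements_from_table(
        hist_df,
        is_volume_ml=cfg["is_volume_ml"],
        is_conc_um=cfg["is_conc_um"],
        sample_volume_ml=cfg["sample_volume_ml"],
    )
    hist_rows = []
    contributions = {}
    for meas, tracer in zip(hist_meas, hist_df["tracer"]):
        pct = histone_fraction_labeled(meas)
        contributions[str(tracer)] = pct
        hist_rows.append(
            {"condition": condition, "tracer": tracer, "labeled_percent": pct}
        )
    panel = HistoneAcetatePanel(condition, contributions)
    pd.DataFrame(hist_rows).to_csv(out / "histone.csv", index=False)

    # --- summary -----------------------------------------------------------
    summary = {
        "condition": condition,
        "seed": seed,
        "exchange": flux_row,
        "net_exchange_point": e_point,
        "isa_final": isa_rows[-1] if isa_rows else None,
        "kfp": kfp_row,
        "histone_panel": {**contributions, "unlabeled": panel.unlabeled_percent},
    }
    if est.e_median < 0:
        cmp_ = demand_vs_uptake(kfit, est)
        summary["demand_vs_net_uptake"] = cmp_.vs_net_uptake
        summary["demand_vs_uptake_q05"] = cmp_.vs_uptake_q05
    else:
        summary["demand_vs_net_uptake"] = None

    cov_path = bundle / "covariates.csv"
    if cov_path.exists():
        summary["correlation"] = _correlation_summary(io.read_table(cov_path))

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline done (%.2fs)", time.perf_counter() - t_start)
    return summary


def _mean_series(wells):
    from .exchange import _average_wells

    return _average_wells(wells)


def _correlation_summary(df: pd.DataFrame) -> dict:
    """Plain Pearson correlation between an expression covariate and a
    response column — descriptive plumbing only."""
    num = df.select_dtypes("number")
    cols = list(num.columns)
    if len(cols) < 2:
        return {}
    r = float(np.corrcoef(num[cols[0]], num[cols[1]])[0, 1])
    return {"x": cols[0], "y": cols[1], "pearson_r": r, "n": int(len(num))}
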