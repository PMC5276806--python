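"""Kinetic flux profiling (KFP) of palmitate synthesis.

The fraction of the palmitate pool newly synthesized since tracer
addition, g(t), is extracted from a time course of corrected palmitate
MIDs (shared precursor enrichment D, per-time g; see :mod:`acetrace.isa`).
At constant pool size P the label balance dg/dt = (J_syn/P)(1 − g) gives

    g(t) = 1 − exp(−k·t),  k = J_syn / P,

so a least-squares fit of the incorporation curve yields the first-order
rate k, the synthesis flux J_syn = k·P, and the two-carbon acetyl demand
8·J_syn (palmitate consumes 8 acetyl units per molecule). Growth dilution
of the pool is folded into k; the model function is pluggable for other
kinetic assumptions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .exchange import ExchangeFluxEstimate
from .isa import fit_enrichment_shared
from .mid import MassIsotopomerDistribution

logger = logging.getLogger(__name__)


class UnidentifiableRateError(ValueError):
    """Raised when too few informative (t > 0) points exist to fit k."""


class NetReleaseError(ValueError):
    """Raised when comparing acetyl demand against uptake under a
    condition that shows net acetate release (no net uptake to compare)."""


@dataclass(frozen=True)
class KFPFit:
    """First-order label-incorporation fit of palmitate synthesis.

    k in 1/hr; pool size P and synthesis flux J_syn = k·P in mmol (/hr)
    per L cell volume; acetyl_demand = n_units·J_syn in mmol two-carbon
    units/hr/L cell volume.
    """

    k: float
    pool_size: float
    rss: float
    n_units: int = 8

    @property
    def j_syn(self) -> float:
        return self.k * self.pool_size

    @property
    def acetyl_demand(self) -> float:
        return self.n_units * self.j_syn


def newly_synthesized_series(
    times: Sequence[float],
    mids: Sequence[MassIsotopomerDistribution],
    *,
    grid_resolution: float = 0.005,
    monotone_tol: float = 0.05,
) -> tuple[float, np.ndarray]:
    """Per-time fraction newly synthesized g(t) with one shared D.

    Jointly fits the time course (single precursor enrichment D, one g per
    time point) and warns when g(t) decreases beyond ``monotone_tol``,
    which the first-order model cannot produce.
    """
    times = np.asarray(times, float)
    if times.size != len(mids):
        raise ValueError("times and MIDs must align")
    if times.size < 3:
        raise ValueError("need at least 3 time points for kinetic profiling")
    order = np.argsort(times)
    d, g, _ = fit_enrichment_shared(
        [mids[i] for i in order], grid_resolution=grid_resolution
    )
    if np.any(np.diff(g) < -monotone_tol):
        logger.warning(
            "newly_synthesized_series: g(t) decreases beyond tolerance; "
            "label incorporation should be monotone"
        )
    out = np.empty_like(g)
    out[order] = g
    return d, out


def first_order_model(t: np.ndarray, k: float) -> np.ndarray:
    """Constant-pool incorporation curve g(t) = 1 − exp(−k·t)."""
    return 1.0 - np.exp(-k * t)


def fit_synthesis(
    times: Sequence[float],
    gs: Sequence[float],
    pool_size: float,
    *,
    n_units: int = 8,
    model: Callable[[np.ndarray, float], np.ndarray] = first_order_model,
) -> KFPFit:
    """Least-squares fit of the incorporation time course.

    ``pool_size`` is the palmitate pool in mmol per L cell volume
    (supplied by configuration; absolute palmitate quantification is out
    of scope here). Requires at least two informative (t > 0) points.
    """
    t = np.asarray(times, float)
    g = np.asarray(gs, float)
    if t.size != g.size:
        raise ValueError("times and g values must align")
    if np.any((g < -1e-9) | (g > 1 + 1e-9)):
        raise ValueError("g values must lie in [0, 1]")
    if pool_size <= 0:
        raise ValueError("pool size must be positive")
    informative = t > 0
    if informative.sum() < 2:
        raise UnidentifiableRateError(
            "need at least two time points after tracer addition to fit a rate"
        )
    if np.all(g[informative] < 1e-12):
        return KFPFit(k=0.0, pool_size=pool_size, rss=float((g**2).sum()), n_units=n_units)
    # initial rate from the first informative point with appreciable labeling
    gi = np.clip(g[informative], 0.0, 1.0 - 1e-12)
    k0 = float(np.median(-np.log1p(-gi) / t[informative]))
    k0 = max(k0, 1e-9)
    popt, _ = curve_fit(model, t, g, p0=[k0], bounds=(0.0, np.inf), maxfev=10000)
    k = float(popt[0])
    rss = float(((g - model(t, k)) ** 2).sum())
    return KFPFit(k=k, pool_size=pool_size, rss=rss, n_units=n_units)


@dataclass(frozen=True)
class DemandUptakeComparison:
    """Acetyl demand for palmitate synthesis relative to exogenous acetate
    uptake: against the net uptake (−e) and against the conservative
    uptake lower bound u_q05."""

    vs_net_uptake: float
    vs_uptake_q05: float


def demand_vs_uptake(
    kfp: KFPFit, flux: ExchangeFluxEstimate
) -> DemandUptakeComparison:
    """Fold-excess of the two-carbon acetyl demand over acetate uptake.

    Only defined under net uptake (e < 0); a net-release condition raises
    :class:`NetReleaseError` rather than reporting a meaningless ratio.
    """
    if flux.e_median >= 0:
        raise NetReleaseError(
            f"net exchange e = {flux.e_median:.3f} >= 0 (net release); "
            "demand/uptake ratio undefined"
        )
    return DemandUptakeComparison(
        vs_net_uptake=kfp.acetyl_demand / flux.net_uptake,
        vs_uptake_q05=kfp.acetyl_demand / flux.u_q05 if flux.u_q05 > 0 else float("inf"),
    )
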