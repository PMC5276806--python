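"""Growth-normalized acetate exchange fluxes and uptake/release deconvolution.

Cells simultaneously take up and release acetate. The net exchange flux e
(release-positive, mmol/hr/L cell volume) follows from the change in total
medium acetate divided by the growth-integrated cell volume. The isotope
balance splits e into gross release r and gross uptake u:

    e  = r − u                     (total acetate)
    xe = a·r − b·u                 (12C-acetate; x = ΔC12/ΔCtotal)

where a is the average unlabeled fraction of intracellular acetate and b
the average unlabeled fraction in the medium. b is measurable; a is not
(the intracellular free pool is too small to quantify), so r and u are
reported as one-sided bounds over all biologically plausible a: because
endogenously produced acetate is unlabeled, a cannot fall below b, and the
scan over a ∈ [b, 1] yields 5% quantiles that lower-bound both fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .quant import AcetateConcentrations

#: μM per (mmol per L of medium)
_UM_PER_MMOL_L = 1e3


class SingularExchangeSystemError(ValueError):
    """Raised when a ≈ b, making the uptake/release balance unsolvable."""


class EmptyARangeError(RuntimeError):
    """Raised when no scanned intracellular fraction yields physical
    (non-negative) uptake and release fluxes."""


@dataclass(frozen=True)
class GrowthCurve:
    """Packed-cell-volume growth measurements for one well.

    times in hours, pcv in μL of cells per well, medium volume in mL.
    """

    times: np.ndarray
    pcv: np.ndarray
    medium_volume_ml: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.pcv, dtype=float)
        if t.size < 2 or t.size != v.size:
            raise ValueError("growth curve needs >= 2 matching (time, pcv) points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("growth-curve times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("packed cell volume must be positive")
        if self.medium_volume_ml <= 0:
            raise ValueError("medium volume must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "pcv", v)

    def pcv_at(self, t: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of PCV (μL) within the measured span."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            raise ValueError("requested time outside the growth curve's span")
        return np.interp(t, self.times, self.pcv)


def integrated_cell_volume(g: GrowthCurve, t0: float, t1: float) -> float:
    """Area under the cell growth curve per medium volume over [t0, t1].

    Trapezoidal integral of pcv(t)/medium_volume, returned in
    L_cell·hr / L_medium (pcv is μL, medium is mL, hence the 1e-3).
    """
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    if t1 == t0:
        return 0.0
    knots = g.times[(g.times > t0) & (g.times < t1)]
    ts = np.concatenate(([t0], knots, [t1]))
    vs = g.pcv_at(ts)
    return float(np.trapezoid(vs, ts) / g.medium_volume_ml * 1e-3)


def net_exchange(
    series: Sequence[AcetateConcentrations], g: GrowthCurve
) -> float:
    """Net exchange flux e (mmol/hr/L cell volume, release-positive).

    e = ΔC_total / T over the first-to-last interval of the series, where
    T is the growth-integrated cell volume per medium volume.
    """
    series = sorted(series, key=lambda c: c.time_hr)
    if len(series) < 2:
        raise ValueError("need at least two quantified time points")
    t_int = integrated_cell_volume(g, series[0].time_hr, series[-1].time_hr)
    if t_int <= 0:
        raise ValueError("growth-integrated cell volume is zero")
    d_total = series[-1].c_total - series[0].c_total
    return d_total / _UM_PER_MMOL_L / t_int


def deconvolve(
    d_c_total: float,
    d_c12: float,
    t_integral: float,
    a: float,
    b: float,
    *,
    singular_tol: float = 1e-6,
) -> tuple[float, float]:
    """Solve the isotope balance for (release r, uptake u).

    Parameters are the medium concentration changes (μM), the
    growth-integrated cell volume T (L_cell·hr/L_medium) and the average
    unlabeled fractions a (intracellular) and b (medium). Solves

        r − u = ΔC_total/T',   a·r − b·u = ΔC12/T'

    directly from the Δ-quantities so the net-zero-exchange case is
    well-defined. Fluxes in mmol/hr/L cell volume.
    """
    if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
        raise ValueError("a and b must be fractions in [0, 1]")
    if abs(a - b) < singular_tol:
        raise SingularExchangeSystemError(
            f"a={a:.4g} and b={b:.4g} coincide; uptake and release are not separable"
        )
    if t_integral <= 0:
        raise ValueError("t_integral must be positive")
    e = d_c_total / _UM_PER_MMOL_L / t_integral
    xe = d_c12 / _UM_PER_MMOL_L / t_integral
    r = (xe - b * e) / (a - b)
    u = r - e
    return r, u


def _mean_b(
    series: Sequence[AcetateConcentrations],
    g: GrowthCurve,
    mode: str,
) -> float:
    """Average unlabeled medium fraction b over the series.

    ``volume_weighted`` (default with ≥3 points): trapezoidal time average
    of b(t) weighted by cell volume, matching the weighting with which
    uptake samples the medium. ``endpoint_mean``: mean of the first and
    last fractions.
    """
    fracs = np.array([c.fraction_12c for c in series])
    times = np.array([c.time_hr for c in series])
    if mode == "endpoint_mean" or len(series) < 3:
        return float((fracs[0] + fracs[-1]) / 2.0)
    if mode != "volume_weighted":
        raise ValueError(f"unknown b_mode {mode!r}")
    w = g.pcv_at(times)
    num = np.trapezoid(fracs * w, times)
    den = np.trapezoid(w, times)
    return float(num / den)


@dataclass(frozen=True)
class ExchangeFluxEstimate:
    """Deconvolved exchange fluxes with uncertainty over the unidentifiable
    intracellular unlabeled fraction a (and bootstrap over wells, if any).

    All fluxes in mmol/hr/L cell volume, release-positive e.
    """

    e_median: float
    e_ci95: tuple[float, float]
    r_q05: float
    u_q05: float
    a_retained: tuple[float, float]
    b: float
    n_excluded_a: int
    n_boot: int
    seed: int | None

    @property
    def net_uptake(self) -> float:
        """Net uptake magnitude −e (positive when cells consume acetate)."""
        return -self.e_median


def deconvolve_with_uncertainty(
    series: Sequence[AcetateConcentrations] | Sequence[Sequence[AcetateConcentrations]],
    g: GrowthCurve,
    a_grid: np.ndarray | None = None,
    *,
    n_boot: int = 1000,
    seed: int | None = 0,
    b_mode: str = "volume_weighted",
    negativity_tol: float = 1e-9,
) -> ExchangeFluxEstimate:
    """Scan the intracellular unlabeled fraction (and bootstrap replicate
    wells) to bound uptake and release.

    ``series`` is either a single time series or a list of replicate-well
    series sharing time points. For every a on the grid (default: 101
    uniform points on [b, 1]) the balance is solved; a-values yielding a
    negative r or u are excluded as unphysical. With ≥3 wells, a seeded
    nonparametric bootstrap over wells propagates measurement error. The
    5% quantiles of r and u over all retained solutions are one-sided
    lower bounds; e is a-independent, so its median and CI reflect only
    replicate variation.
    """
    wells = _as_wells(series)
    rng = np.random.default_rng(seed)
    draws: list[Sequence[AcetateConcentrations]] = []
    if len(wells) >= 3:
        idx_all = rng.integers(0, len(wells), size=(n_boot, len(wells)))
        for idx in idx_all:
            draws.append(_average_wells([wells[i] for i in idx]))
        n_boot_used = n_boot
    else:
        draws.append(_average_wells(wells))
        n_boot_used = 0

    all_r: list[np.ndarray] = []
    all_u: list[np.ndarray] = []
    all_e: list[float] = []
    retained_a: list[np.ndarray] = []
    n_excluded = 0
    b_report = np.nan
    for draw in draws:
        draw = sorted(draw, key=lambda c: c.time_hr)
        t0, t1 = draw[0].time_hr, draw[-1].time_hr
        t_int = integrated_cell_volume(g, t0, t1)
        b = _mean_b(draw, g, b_mode)
        b_report = b
        grid = np.linspace(b, 1.0, 101) if a_grid is None else np.asarray(a_grid, float)
        d_total = draw[-1].c_total - draw[0].c_total
        d_c12 = draw[-1].c12 - draw[0].c12
        all_e.append(d_total / _UM_PER_MMOL_L / t_int)
        rs, us, aok = [], [], []
        for a in grid:
            if abs(a - b) < 1e-6:
                n_excluded += 1
                continue
            r, u = deconvolve(d_total, d_c12, t_int, a, b)
            if r < -negativity_tol or u < -negativity_tol:
                n_excluded += 1
                continue
            rs.append(r)
            us.append(u)
            aok.append(a)
        all_r.append(np.array(rs))
        all_u.append(np.array(us))
        retained_a.append(np.array(aok))

    r_flat = np.concatenate(all_r)
    u_flat = np.concatenate(all_u)
    a_flat = np.concatenate(retained_a)
    if r_flat.size == 0:
        raise EmptyARangeError(
            "no scanned intracellular fraction satisfies r >= 0 and u >= 0; "
            f"b = {b_report:.3f}, e = {np.median(all_e):.3f} mmol/hr/L cell"
        )
    e_arr = np.array(all_e)
    return ExchangeFluxEstimate(
        e_median=float(np.median(e_arr)),
        e_ci95=(float(np.quantile(e_arr, 0.025)), float(np.quantile(e_arr, 0.975))),
        r_q05=float(np.quantile(r_flat, 0.05)),
        u_q05=float(np.quantile(u_flat, 0.05)),
        a_retained=(float(a_flat.min()), float(a_flat.max())),
        b=float(b_report),
        n_excluded_a=n_excluded,
        n_boot=n_boot_used,
        seed=seed,
    )


def release_uptake_ratio(series: Sequence[AcetateConcentrations]) -> float:
    """Ratio of unlabeled acetate released to labeled acetate consumed.

    Δc12 (accumulated) divided by −Δc13 (consumed) over the series span;
    cell-number independent by construction. Requires net 13C consumption.
    """
    series = sorted(series, key=lambda c: c.time_hr)
    if len(series) < 2:
        raise ValueError("need at least two time points")
    d12 = series[-1].c12 - series[0].c12
    d13 = series[-1].c13 - series[0].c13
    if -d13 <= 0:
        raise ValueError("labeled acetate was not consumed; ratio undefined")
    return d12 / (-d13)


def _as_wells(series) -> list[list[AcetateConcentrations]]:
    seq = list(series)
    if not seq:
        raise ValueError("empty concentration series")
    if isinstance(seq[0], AcetateConcentrations):
        return [seq]
    return [list(w) for w in seq]


def _average_wells(
    wells: Sequence[Sequence[AcetateConcentrations]],
) -> list[AcetateConcentrations]:
    if len(wells) == 1:
        return sorted(wells[0], key=lambda c: c.time_hr)
    sorted_wells = [sorted(w, key=lambda c: c.time_hr) for w in wells]
    times = [tuple(c.time_hr for c in w) for w in sorted_wells]
    if len(set(times)) != 1:
        raise ValueError("replicate wells must share sampling time points")
    out = []
    for i, t in enumerate(times[0]):
        out.append(
            AcetateConcentrations(
                sample_id=f"mean_{i}",
                time_hr=t,
                c12=float(np.mean([w[i].c12 for w in sorted_wells])),
                c13=float(np.mean([w[i].c13 for w in sorted_wells])),
            )
        )
    return out
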