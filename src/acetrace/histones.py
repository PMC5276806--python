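"""Tracer contributions to the aggregate histone-bound acetate pool.

Histones are hydrolyzed in bulk and the released acetate quantified by the
same internal-standard SIM pathway as medium acetate, so the measured
labeling reflects the aggregate of the entire histone-bound acetate pool
(no per-site resolution). Comparing this panel with lipogenic AcCoA
enrichment contrasts the nuclear and cytosolic acetyl-CoA pools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .quant import AcetateConcentrations, SimMeasurement, quantify


@dataclass(frozen=True)
class HistoneAcetatePanel:
    """Per-tracer labeled percent of histone-bound acetate for one
    condition; the remainder is unlabeled."""

    condition: str
    contributions: Mapping[str, float]

    def __post_init__(self):
        for tracer, pct in self.contributions.items():
            if pct < 0:
                raise ValueError(f"negative contribution for {tracer}")
        total = sum(self.contributions.values())
        if total > 100.0 + 1e-6:
            raise ValueError(
                f"tracer contributions sum to {total:.1f}% > 100%"
            )
        object.__setattr__(self, "contributions", dict(self.contributions))

    @property
    def unlabeled_percent(self) -> float:
        return 100.0 - sum(self.contributions.values())


def histone_fraction_labeled(
    meas: SimMeasurement | AcetateConcentrations,
) -> float:
    """Percent of histone-bound acetate carrying tracer label.

    Accepts either a quantified hydrolysate or its raw SIM measurement
    (quantified on the fly): 100·c13/(c12 + c13).
    """
    conc = quantify(meas) if isinstance(meas, SimMeasurement) else meas
    total = conc.c_total
    if total <= 0:
        raise ZeroDivisionError(
            f"{conc.sample_id}: hydrolysate contains no quantifiable acetate"
        )
    return 100.0 * conc.c13 / total


def compartment_contrast(
    histone: HistoneAcetatePanel, lipogenic_percent: Mapping[str, float]
) -> dict[str, float]:
    """Per-tracer ratio of lipogenic AcCoA enrichment to histone-bound
    acetate labeling (both in percent).

    A ratio well above 1 for the acetate tracer means exogenous acetate
    labels the cytosolic (lipogenic) pool multiple-fold more than the
    nuclear (histone) pool. Zero histone labeling with nonzero lipogenic
    labeling is flagged as an infinite ratio.
    """
    if set(histone.contributions) != set(lipogenic_percent):
        raise ValueError(
            f"tracer sets differ: histone {sorted(histone.contributions)} vs "
            f"lipogenic {sorted(lipogenic_percent)}"
        )
    out: dict[str, float] = {}
    for tracer, h_pct in histone.contributions.items():
        l_pct = lipogenic_percent[tracer]
        if h_pct == 0:
            out[tracer] = math.inf if l_pct > 0 else math.nan
        else:
            out[tracer] = l_pct / h_pct
    return out
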