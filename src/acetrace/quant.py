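"""Internal-standard GC-MS quantification of derivatized acetate.

Medium or hydrolysate acetate is esterified and measured by selected ion
monitoring (SIM) at m/z 61 (12C-acetate ester fragment), m/z 63
(U-13C-acetate, +2 Da) and m/z 64 (2H3-acetate internal standard, +3 Da).
Adding a known amount of 2H3-acetate to every sample before derivatization
turns intensity ratios directly into concentrations: the three esters are
chemically identical up to isotopic substitution, so equal MS response
factors are assumed (single-point isotope-dilution quantification).
"""

from __future__ import annotations

from dataclasses import dataclass, field

logger = __import__("logging").getLogger(__name__)


class UnquantifiableSampleError(ValueError):
    """Raised when the internal-standard channel (m/z 64) carries no
    signal, so concentrations cannot be derived for the sample."""


@dataclass(frozen=True)
class SimMeasurement:
    """One SIM acquisition of a derivatized acetate sample.

    Intensities are in arbitrary units; dilution context records how much
    internal standard was added to how much sample.
    """

    sample_id: str
    time_hr: float
    i61: float
    i63: float
    i64: float
    is_volume_ml: float = 0.040
    is_conc_um: float = 1000.0
    sample_volume_ml: float = 0.200
    sample_type: str = "medium"

    def __post_init__(self):
        if min(self.i61, self.i63, self.i64) < 0:
            raise ValueError("ion intensities must be non-negative")
        if self.is_volume_ml < 0:
            raise ValueError("internal-standard volume must be non-negative")
        if self.sample_volume_ml <= 0:
            raise ValueError("sample volume must be positive")


@dataclass(frozen=True)
class AcetateConcentrations:
    """12C-, 13C- and total acetate concentration (μM) at one time point."""

    sample_id: str
    time_hr: float
    c12: float
    c13: float

    def __post_init__(self):
        if self.c12 < 0 or self.c13 < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def c_total(self) -> float:
        return self.c12 + self.c13

    @property
    def fraction_12c(self) -> float:
        """Unlabeled fraction b = c12/c_total of this pool."""
        if self.c_total == 0:
            raise ZeroDivisionError(f"{self.sample_id}: total acetate is zero")
        return self.c12 / self.c_total


def effective_is_concentration(
    is_volume_ml: float, is_conc_um: float, sample_volume_ml: float
) -> float:
    """Internal-standard amount expressed as a concentration in the
    original sample volume (μM).

    The protocol default, 40 μL of 1 mM 2H3-acetate into 200 μL of medium,
    corresponds to 200 μM.
    """
    if sample_volume_ml <= 0:
        raise ValueError("sample volume must be positive")
    if is_volume_ml < 0 or is_conc_um < 0:
        raise ValueError("internal-standard volume and concentration must be >= 0")
    return is_volume_ml * is_conc_um / sample_volume_ml


def quantify(meas: SimMeasurement) -> AcetateConcentrations:
    """Convert one SIM measurement into absolute acetate concentrations.

    c12 = (I61/I64)·C_IS and c13 = (I63/I64)·C_IS, where C_IS is the
    effective internal-standard concentration in the sample. Natural
    M+2 cross-talk from the light ester into m/z 63 (<0.1% for a
    two-carbon fragment) is neglected.
    """
    if meas.i64 <= 0:
        raise UnquantifiableSampleError(
            f"{meas.sample_id}: internal-standard intensity (m/z 64) is zero"
        )
    c_is = effective_is_concentration(
        meas.is_volume_ml, meas.is_conc_um, meas.sample_volume_ml
    )
    return AcetateConcentrations(
        sample_id=meas.sample_id,
        time_hr=meas.time_hr,
        c12=meas.i61 / meas.i64 * c_is,
        c13=meas.i63 / meas.i64 * c_is,
    )
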