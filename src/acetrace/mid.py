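"""Mass isotopomer distributions (MIDs) and natural-abundance correction.

A mass isotopomer distribution holds the fractional abundances of an
analyte's mass shifts M+0..M+n, where n is the number of carbon positions
that can carry tracer label. Raw GC-MS MIDs are convolved with the natural
isotopic abundance of every atom in the measured ion; the correction
implemented here removes that contribution by inverting a per-atom
convolution matrix, leaving the tracer-only distribution that downstream
enrichment analyses consume.

Shifts are indexed by integer mass shift relative to the monoisotopic ion,
not by m/z; mapping raw m/z channels to shifts is the reader's job.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: Natural isotopic abundances as per-atom mass-shift distributions
#: (index = mass shift in Da relative to the lightest isotope).
NATURAL_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "O": (0.99757, 0.00038, 0.00205),
    "N": (0.99636, 0.00364),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "Si": (0.92223, 0.04685, 0.03092),
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class IllConditionedCorrectionError(RuntimeError):
    """Raised when the natural-abundance correction matrix cannot be
    inverted reliably (condition number above the configured threshold)."""


@dataclass(frozen=True)
class ElementalFormula:
    """Elemental composition of the measured ion or derivative fragment.

    E.g. palmitate methyl ester C17H34O2, where only 16 of the 17 carbons
    are tracer positions (the methyl carbon comes from derivatization).
    """

    counts: Mapping[str, int]

    def __post_init__(self):
        for elem, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative atom count for {elem}: {n}")
            if elem not in NATURAL_ABUNDANCE:
                raise ValueError(f"no natural-abundance data for element {elem!r}")
        object.__setattr__(self, "counts", dict(self.counts))

    @classmethod
    def from_string(cls, formula: str) -> "ElementalFormula":
        """Parse e.g. ``"C17H34O2"``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula) or not counts:
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts)

    @property
    def n_carbons(self) -> int:
        return self.counts.get("C", 0)


#: Derivatized ions used throughout the pipeline.
PALMITATE_METHYL_ESTER = ElementalFormula.from_string("C17H34O2")


@dataclass
class MassIsotopomerDistribution:
    """Normalized fractional abundances M+0..M+n for one analyte fragment.

    Parameters
    ----------
    analyte
        Analyte identifier, e.g. ``"palmitate"``.
    fractions
        Abundances indexed by integer mass shift; normalized to sum to 1.
    """

    analyte: str
    fractions: np.ndarray = field()

    def __post_init__(self):
        fr = np.asarray(self.fractions, dtype=float)
        if fr.ndim != 1 or fr.size < 1:
            raise ValueError("fractions must be a non-empty 1-D vector")
        if np.any(fr < 0):
            raise ValueError("fractions must be non-negative")
        total = fr.sum()
        if total <= 0:
            raise ValueError("fractions must have positive total")
        self.fractions = fr / total

    @property
    def n_tracer_carbons(self) -> int:
        return self.fractions.size - 1

    def __len__(self) -> int:
        return self.fractions.size


def _atom_distributions(
    formula: ElementalFormula,
    n_labeled: int,
    abundances: Mapping[str, tuple[float, ...]],
) -> list[tuple[float, ...]]:
    """Per-atom shift distributions for a molecule with ``n_labeled`` carbons
    pinned to tracer 13C (these contribute no *natural* shift)."""
    dists: list[tuple[float, ...]] = []
    for elem, count in formula.counts.items():
        n = count - n_labeled if elem == "C" else count
        dists.extend([tuple(abundances[elem])] * n)
    return dists


def correction_matrix(
    formula: ElementalFormula,
    n_tracer_carbons: int,
    abundances: Mapping[str, tuple[float, ...]] | None = None,
) -> np.ndarray:
    """Natural-abundance convolution matrix for a measured ion.

    Column ``j`` is the mass-shift distribution of a molecule carrying
    exactly ``j`` tracer-labeled carbons: the labeled positions are fixed
    at +1 Da each, and every remaining atom (including the unlabeled
    tracer-position carbons) contributes its natural isotope distribution.
    A raw MID is the matrix product ``M @ tracer_mid``; shifts beyond the
    measured window M+n are truncated, so columns sum to ≤ 1.
    """
    if n_tracer_carbons < 0:
        raise ValueError("n_tracer_carbons must be non-negative")
    if formula.n_carbons < n_tracer_carbons:
        raise ValueError(
            f"formula has {formula.n_carbons} carbons, fewer than "
            f"{n_tracer_carbons} tracer carbons"
        )
    abund = dict(NATURAL_ABUNDANCE) if abundances is None else dict(abundances)
    size = n_tracer_carbons + 1
    mat = np.zeros((size, size))
    for j in range(size):
        dist = np.array([1.0])
        for atom_dist in _atom_distributions(formula, j, abund):
            dist = np.convolve(dist, atom_dist)
        n_keep = size - j
        mat[j:, j] = dist[:n_keep]
    return mat


def na_correct(
    raw: MassIsotopomerDistribution,
    formula: ElementalFormula,
    *,
    abundances: Mapping[str, tuple[float, ...]] | None = None,
    cond_threshold: float = 1e8,
    clip_warn: float = 1e-3,
) -> MassIsotopomerDistribution:
    """Remove natural-abundance contributions, returning the tracer-only MID.

    Solves ``M x = raw`` where ``M`` is :func:`correction_matrix`. Small
    negative solution components (noise artifacts) are clipped to zero and
    the result renormalized; clipped mass above ``clip_warn`` is logged.

    Raises
    ------
    IllConditionedCorrectionError
        If the correction matrix's condition number exceeds
        ``cond_threshold``; the correction then cannot be trusted and no
        silent output is produced.
    """
    mat = correction_matrix(formula, raw.n_tracer_carbons, abundances=abundances)
    cond = np.linalg.cond(mat)
    if not np.isfinite(cond) or cond > cond_threshold:
        raise IllConditionedCorrectionError(
            f"correction matrix for {raw.analyte} is ill-conditioned "
            f"(cond={cond:.3g} > {cond_threshold:.3g})"
        )
    x = np.linalg.solve(mat, raw.fractions)
    clipped = -x[x < 0].sum()
    if clipped > clip_warn:
        logger.warning(
            "na_correct(%s): clipped %.4f negative corrected mass", raw.analyte, clipped
        )
    x = np.clip(x, 0.0, None)
    return MassIsotopomerDistribution(raw.analyte, x)


def forward_convolve(
    mid: MassIsotopomerDistribution,
    formula: ElementalFormula,
    *,
    abundances: Mapping[str, tuple[float, ...]] | None = None,
) -> MassIsotopomerDistribution:
    """Apply natural abundance to a tracer-only MID (inverse of
    :func:`na_correct`); used to emulate raw measurements."""
    mat = correction_matrix(formula, mid.n_tracer_carbons, abundances=abundances)
    return MassIsotopomerDistribution(mid.analyte, mat @ mid.fractions)


def fraction_labeled(mid: MassIsotopomerDistribution) -> float:
    """Fraction of molecules carrying at least one tracer carbon: 1 − M+0."""
    return float(1.0 - mid.fractions[0])


def carbon_weighted_enrichment(mid: MassIsotopomerDistribution) -> float:
    """Average fraction of labeled carbons per molecule: Σ k·f_k / n.

    Distinct from :func:`fraction_labeled`, which counts molecules, not
    carbons.
    """
    n = mid.n_tracer_carbons
    if n == 0:
        return 0.0
    k = np.arange(n + 1)
    return float((k * mid.fractions).sum() / n)
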