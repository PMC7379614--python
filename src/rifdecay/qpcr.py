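"""qPCR absolute quantification.

Standard-curve fitting (Cq vs log10 copies over a dilution series),
amplification efficiency, inverse quantification of unknowns, and
subtraction of the undigested-DNA background measured in no-reverse-
transcription (RNA) controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import CurveRejectedError, ValidationError

__all__ = [
    "PlateRecord",
    "StandardCurve",
    "Quantification",
    "fit_standard_curve",
    "quantify",
    "quantify_triplicate",
    "subtract_dna_background",
    "EFFICIENCY_REFERENCE_RANGE",
]

# Dilution-series efficiencies observed across assays of this kind; a fitted
# efficiency outside this range triggers a warning, not an error.
EFFICIENCY_REFERENCE_RANGE = (0.687, 0.989)

MATERIALS = ("cDNA", "RNA_noRT", "standard", "NTC")

#: genes with taxon-specific assays in the isolate experiments
KNOWN_GENES = (
    "16S rRNA", "atpF", "dnaK", "hflB", "pykA", "rpoB",
    "pssA", "pepA", "recA", "thyA", "clpP",
)


@dataclass
class PlateRecord:
    """One well group on a qPCR plate: a sample × gene × material triplicate."""

    sample_id: str
    gene: str
    material: str
    cq_values: list[float]
    known_copies: float | None = None

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise ValidationError(f"unknown material {self.material!r}")
        if self.material == "standard":
            if self.known_copies is None or self.known_copies <= 0:
                raise ValidationError("standards must carry known_copies > 0")
        if not self.cq_values or any(c <= 0 for c in self.cq_values):
            raise ValidationError("cq_values must be non-empty and positive")


@dataclass(frozen=True)
class StandardCurve:
    """Cq = slope·log10(copies) + intercept, with efficiency 10^(−1/slope) − 1."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float


@dataclass
class Quantification:
    """Triplicate-aggregated copy number for one sample × gene."""

    sample_id: str
    gene: str
    copies_mean: float
    copies_sd: float
    n_replicates: int
    background_fraction: float | None = None
    over_background: bool = False


def fit_standard_curve(
    standards: Sequence[tuple[float, float]], warn_efficiency: bool = True
) -> StandardCurve:
    """Least-squares line of Cq on log10(known copies).

    ``standards`` are (known_copies, mean Cq) pairs over >= 3 distinct
    dilution levels; the amplification efficiency is the per-cycle fold
    increase minus one, 10^(−1/slope) − 1 (1.0 for perfect doubling at
    slope −3.3219).  A positive or non-monotone curve is rejected; an
    efficiency outside the 68.7–98.9% range observed for assays of this
    kind warns but proceeds.
    """
    pairs = sorted(standards)
    copies = np.array([c for c, _ in pairs], dtype=float)
    cq = np.array([q for _, q in pairs], dtype=float)
    if np.any(copies <= 0):
        raise ValidationError("standard copies must be positive")
    if len(np.unique(copies)) < 3:
        raise ValidationError("need >= 3 distinct dilution levels")
    res = stats.linregress(np.log10(copies), cq)
    if res.slope >= 0:
        raise CurveRejectedError(f"standard-curve slope {res.slope:.3f} is not negative")
    if np.any(np.diff(cq) >= 0):
        raise CurveRejectedError("Cq does not decrease monotonically with copies")
    efficiency = 10.0 ** (-1.0 / res.slope) - 1.0
    lo, hi = EFFICIENCY_REFERENCE_RANGE
    if warn_efficiency and not lo <= efficiency <= hi:
        warnings.warn(
            f"amplification efficiency {efficiency:.1%} outside the "
            f"{lo:.1%}-{hi:.1%} range observed for these assays",
            stacklevel=2,
        )
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=float(efficiency),
    )


def quantify(cq: float, curve: StandardCurve) -> float:
    """Invert the standard curve: copies = 10^((cq − intercept)/slope)."""
    if cq <= 0:
        raise ValidationError("Cq must be positive")
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def quantify_triplicate(
    sample_id: str, gene: str, cq_values: Iterable[float], curve: StandardCurve
) -> Quantification:
    """Quantify each replicate then average on the copies scale.

    Averaging Cq before exponentiation biases the copy number low, so each
    replicate is converted first; the SD is the replicate SD of copies.
    """
    copies = np.array([quantify(c, curve) for c in cq_values])
    sd = float(np.std(copies, ddof=1)) if len(copies) > 1 else 0.0
    return Quantification(
        sample_id=sample_id,
        gene=gene,
        copies_mean=float(np.mean(copies)),
        copies_sd=sd,
        n_replicates=len(copies),
    )


def subtract_dna_background(
    cdna_copies: float, rna_copies: float
) -> tuple[float, float, bool]:
    """Correct a cDNA quantification for undigested genomic DNA.

    The no-RT control (``rna_copies``) measures residual DNA; it is
    subtracted from the cDNA signal, floored at zero.  Returns
    ``(corrected_copies, background_fraction, over_background)`` where the
    background fraction rna/cdna is the QC metric (typically a few percent)
    and the flag marks controls exceeding the cDNA signal.
    """
    if cdna_copies < 0 or rna_copies < 0:
        raise ValidationError("copy numbers must be non-negative")
    frac = rna_copies / cdna_copies if cdna_copies > 0 else float("inf")
    corrected = max(cdna_copies - rna_copies, 0.0)
    return corrected, frac, rna_copies > cdna_copies
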