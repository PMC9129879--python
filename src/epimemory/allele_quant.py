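"""Allele-ratio quantification from chromatogram peak areas.

Relative abundance of two strains differing at a single SNP is estimated
from the area under the curve of the two allele channels at the SNP
basecall, then calibrated against a standard curve built from mixtures of
known composition (as estimated by optical density).

The integration window runs from the midpoint to the previous basecall
peak to the midpoint to the next one, and each channel is corrected by
subtracting its within-window minimum before summation. Both rules are
this package's own (deterministic and parameter-free); see
``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import (
    AmbiguousLocusError,
    DegenerateSignalError,
    LocusNotFoundError,
    RankDeficiencyError,
    UnusableCurveError,
    ValidationError,
)
from .trace_io import SNPLocus, TraceSignal


@dataclass(frozen=True)
class AlleleQuantification:
    """Peak areas and primary-allele fraction at one SNP basecall."""

    area_primary: float
    area_secondary: float
    fraction_primary: float
    snp_index: int

    def __post_init__(self) -> None:
        if self.area_primary < 0 or self.area_secondary < 0:
            raise ValidationError("areas must be nonnegative")
        if not 0.0 <= self.fraction_primary <= 1.0:
            raise ValidationError("fraction_primary must lie in [0, 1]")


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration: measured fraction ~ slope * true + intercept."""

    design_fractions: tuple[float, ...]
    measured_fractions: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if len(self.design_fractions) != len(self.measured_fractions):
            raise ValidationError("design and measured sequences must match in length")
        if len(self.design_fractions) < 2:
            raise ValidationError("a standard curve needs at least 2 points")


class CalibratedFraction(NamedTuple):
    value: float
    clamped: bool


def locate_snp_peak(trace: TraceSignal, locus: SNPLocus) -> int:
    """Find the basecall index of the SNP by its flanking context.

    The called-base sequence is searched for ``flank_left + ? + flank_right``
    with the SNP position a wildcard; exactly one match is required.
    """
    calls = "".join(trace.called_bases)
    left, right = locus.flank_left.upper(), locus.flank_right.upper()
    matches = []
    for i in range(len(left), len(calls) - len(right)):
        if calls[i - len(left) : i] == left and calls[i + 1 : i + 1 + len(right)] == right:
            matches.append(i)
    if not matches:
        raise LocusNotFoundError(
            f"locus context {left}?{right} not found in called bases"
        )
    if len(matches) > 1:
        raise AmbiguousLocusError(
            f"locus context {left}?{right} matches at basecalls {matches}"
        )
    return matches[0]


def integration_window(trace: TraceSignal, snp_index: int) -> tuple[int, int]:
    """Half-open scan-index window ``[lo, hi)`` around one basecall peak.

    Bounds are the midpoints to the neighbouring peaks; the trace ends
    clamp to the array bounds.
    """
    peaks = trace.peak_positions
    if not 0 <= snp_index < len(peaks):
        raise ValidationError(f"snp_index {snp_index} out of range")
    p = int(peaks[snp_index])
    lo = 0 if snp_index == 0 else (int(peaks[snp_index - 1]) + p + 1) // 2
    hi = (
        trace.length
        if snp_index == len(peaks) - 1
        else (p + int(peaks[snp_index + 1]) + 1) // 2
    )
    return lo, hi


def quantify_allele_fraction(
    trace: TraceSignal, snp_index: int, locus: SNPLocus
) -> AlleleQuantification:
    """Area-under-the-curve allele quantification at one basecall.

    Each allele channel is integrated over the inter-peak-midpoint window
    after subtracting its within-window minimum (baseline correction);
    ``fraction_primary = area_primary / (area_primary + area_secondary)``.
    """
    lo, hi = integration_window(trace, snp_index)
    areas = {}
    for allele in (locus.allele_primary, locus.allele_secondary):
        seg = trace.channel(allele)[lo:hi]
        areas[allele] = float(np.sum(seg - seg.min()))
    a_p = areas[locus.allele_primary]
    a_s = areas[locus.allele_secondary]
    total = a_p + a_s
    if total == 0.0:
        raise DegenerateSignalError(
            f"both allele channels have zero corrected area in window [{lo}, {hi})"
        )
    return AlleleQuantification(
        area_primary=a_p,
        area_secondary=a_s,
        fraction_primary=a_p / total,
        snp_index=snp_index,
    )


def fit_standard_curve(
    pairs: Sequence[tuple[float, float]]
) -> StandardCurve:
    """Ordinary least-squares line of measured fraction on true fraction."""
    if len(pairs) < 2:
        raise RankDeficiencyError("need at least 2 calibration points")
    true = np.asarray([p[0] for p in pairs], dtype=float)
    measured = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(true) == 0:
        raise RankDeficiencyError("all true fractions are equal; cannot fit a line")
    fit = stats.linregress(true, measured)
    return StandardCurve(
        design_fractions=tuple(true),
        measured_fractions=tuple(measured),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def calibrate_fraction(curve: StandardCurve, measured: float) -> CalibratedFraction:
    """Invert the standard curve: (measured - intercept) / slope, clamped to [0, 1]."""
    if curve.slope <= 0:
        raise UnusableCurveError(f"standard curve slope {curve.slope} is not positive")
    raw = (measured - curve.intercept) / curve.slope
    clamped = raw < 0.0 or raw > 1.0
    return CalibratedFraction(value=float(min(1.0, max(0.0, raw))), clamped=clamped)
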