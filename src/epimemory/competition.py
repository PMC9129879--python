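"""Pooled two-strain competition fitness from allele fractions.

The readout is the log2 change in the odds of strain A between the start
of the competition and its end, normalized to the starting mixture:

    log2[ (f_t / (1 - f_t)) / (f_0 / (1 - f_0)) ]

Computed per biological replicate and summarized as mean +/- SEM, with an
optional conversion to selection per generation when the culture doubling
time is known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import PairingError, UnboundedRatioError, ValidationError


@dataclass(frozen=True)
class CompetitionSample:
    """One measured allele fraction in one replicate at one timepoint."""

    replicate_id: str
    timepoint: float  # minutes since mixing
    fraction_primary: float

    def __post_init__(self) -> None:
        if self.timepoint < 0:
            raise ValidationError("timepoint must be >= 0")
        if not 0.0 <= self.fraction_primary <= 1.0:
            raise ValidationError("fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CompetitionResult:
    log2_ratios: tuple[float, ...]
    mean_log2_ratio: float
    sem: float | None
    n_replicates: int
    duration: float  # minutes
    selection_per_generation: float | None = None


def log2_abundance_ratio(fraction_t: float, fraction_0: float) -> float:
    """t0-normalized log2 odds change of the primary strain.

    Fractions of exactly 0 or 1 mean one strain is extinct or fixed at
    measurement resolution and the odds ratio is unbounded.
    """
    for f in (fraction_t, fraction_0):
        if not 0.0 < f < 1.0:
            raise UnboundedRatioError(
                f"fraction {f} is at the boundary; odds ratio is unbounded"
            )
    odds_t = fraction_t / (1.0 - fraction_t)
    odds_0 = fraction_0 / (1.0 - fraction_0)
    return math.log2(odds_t / odds_0)


def estimate_fitness(
    samples: Iterable[CompetitionSample],
    doubling_time: float | None = None,
) -> CompetitionResult:
    """Per-replicate log2 ratios and replicate-level summary.

    Each replicate must contribute exactly one t=0 sample and one
    end-point sample; all replicates must share the same end timepoint.
    """
    by_rep: dict[str, list[CompetitionSample]] = {}
    for s in samples:
        by_rep.setdefault(s.replicate_id, []).append(s)
    if not by_rep:
        raise PairingError("no samples provided")

    ratios: list[float] = []
    durations: set[float] = set()
    for rep, rows in sorted(by_rep.items()):
        start = [s for s in rows if s.timepoint == 0]
        end = [s for s in rows if s.timepoint > 0]
        if len(start) != 1 or len(end) != 1:
            raise PairingError(
                f"replicate {rep!r} needs exactly one t=0 and one end-point sample, "
                f"got {len(start)} and {len(end)}"
            )
        ratios.append(
            log2_abundance_ratio(end[0].fraction_primary, start[0].fraction_primary)
        )
        durations.add(end[0].timepoint)
    if len(durations) != 1:
        raise PairingError(f"replicates have inconsistent end timepoints: {sorted(durations)}")
    duration = durations.pop()

    arr = np.asarray(ratios)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) >= 2 else None
    selection = None
    if doubling_time is not None:
        generations = duration / doubling_time
        if generations <= 0:
            raise ValidationError("duration and doubling time must be positive")
        selection = mean / generations
    return CompetitionResult(
        log2_ratios=tuple(ratios),
        mean_log2_ratio=mean,
        sem=sem,
        n_replicates=len(arr),
        duration=duration,
        selection_per_generation=selection,
    )
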