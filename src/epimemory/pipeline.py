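"""End-to-end glue: trace -> allele fraction -> calibration -> fitness.

These helpers chain the per-module operations exactly the way the
analysis scripts and acceptance checks run them, so the full pipeline is
exercised through one code path.
"""

from __future__ import annotations

import numpy as np

from .allele_quant import (
    StandardCurve,
    calibrate_fraction,
    fit_standard_curve,
    locate_snp_peak,
    quantify_allele_fraction,
)
from .competition import CompetitionResult, CompetitionSample, estimate_fitness
from .synthetic_data import (
    DEFAULT_LOCUS,
    DESIGN_FRACTIONS,
    CompetitionGenSpec,
    TraceGenSpec,
    simulate_competition,
    simulate_trace,
)
from .trace_io import SNPLocus, TraceSignal


def measure_fraction(
    trace: TraceSignal,
    locus: SNPLocus = DEFAULT_LOCUS,
    curve: StandardCurve | None = None,
) -> float:
    """Locate the SNP, quantify the allele fraction, optionally calibrate."""
    idx = locate_snp_peak(trace, locus)
    quant = quantify_allele_fraction(trace, idx, locus)
    if curve is None:
        return quant.fraction_primary
    return calibrate_fraction(curve, quant.fraction_primary).value


def synthetic_standard_curve(
    seed: int,
    noise_sd: float = 0.05,
    replicates_per_point: int = 10,
    design_fractions: tuple[float, ...] = DESIGN_FRACTIONS,
) -> tuple[StandardCurve, dict[float, float]]:
    """Fit a calibration curve on synthetic traces at the mixture design.

    Each design fraction is rendered as ``replicates_per_point``
    independent noisy traces and quantified; the curve regresses the
    per-trace measured fraction on the true fraction. Returns the curve
    and the per-design-point mean measured fraction.
    """
    rng = np.random.default_rng(seed)
    pairs: list[tuple[float, float]] = []
    means: dict[float, float] = {}
    for f in design_fractions:
        measured = []
        for _ in range(replicates_per_point):
            trace, _ = simulate_trace(
                TraceGenSpec(fraction_primary=f, noise_sd=noise_sd, seed=int(rng.integers(2**31)))
            )
            measured.append(measure_fraction(trace))
        pairs.extend((f, m) for m in measured)
        means[f] = float(np.mean(measured))
    return fit_standard_curve(pairs), means


def competition_via_traces(
    spec: CompetitionGenSpec,
    curve: StandardCurve | None = None,
    trace_noise_sd: float = 0.0,
    doubling_time: float | None = None,
) -> CompetitionResult:
    """Run a simulated competition through the full chromatogram pipeline.

    Each simulated sample's measured fraction is rendered as a synthetic
    trace, re-quantified from its peak areas, optionally calibrated, and
    the replicate log2 ratios summarized.
    """
    samples, _ = simulate_competition(spec)
    rng = np.random.default_rng(spec.seed + 1)
    requant: list[CompetitionSample] = []
    for s in samples:
        trace, _ = simulate_trace(
            TraceGenSpec(
                fraction_primary=s.fraction_primary,
                noise_sd=trace_noise_sd,
                seed=int(rng.integers(2**31)),
            )
        )
        f = measure_fraction(trace, curve=curve)
        requant.append(
            CompetitionSample(
                replicate_id=s.replicate_id,
                timepoint=s.timepoint,
                fraction_primary=f,
            )
        )
    return estimate_fitness(requant, doubling_time=doubling_time)
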