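"""Synthetic assay data with the statistical structure the analyses assume.

Every generator is deterministic under a fixed seed and returns (or
writes, for the fixture suite) a ground-truth record sufficient to score
downstream estimates; ground truth is never embedded in the data files
themselves.

Generators
----------
- chromatogram traces: one Gaussian peak per called base in its channel,
  with the two allele channels at the SNP split in proportion to the
  mixture fraction (emulating Sanger traces of pooled strains);
- two-strain competitions: deterministic exponential growth with additive
  Gaussian assay noise on the measured fraction;
- ChIP decay time courses under the passive-dilution / maintained /
  actively-removed regimes, with multiplicative replicate noise and a
  negative-control locus;
- binomial peripheral-localization counts.

Noise defaults (5% multiplicative on peak amplitudes and ChIP signals,
additive sd 0.02 on measured fractions) are the package's documented
study conditions; see docs/methods.md.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .competition import CompetitionSample
from .errors import ValidationError
from .inheritance import ChipTimecourse, MarkDecayParams, expected_signal
from .localization import LocalizationDataset
from .trace_io import SNPLocus, TraceSignal, write_locus, write_trace

#: The calibration mixture design: fraction of strain 'A' in each pool.
DESIGN_FRACTIONS = (0.0, 0.05, 0.25, 0.40, 0.50, 0.60, 0.75, 0.90, 1.0)

# Default sequence context: A/C-free flanks so the SNP window sees only
# the two allele peaks; SNP at basecall 20 of 41.
_DEFAULT_SEQUENCE = "GT" * 8 + "GGTT" + "A" + "TGGT" + "GT" * 8
_DEFAULT_SNP_POSITION = 20

DEFAULT_LOCUS = SNPLocus(
    allele_primary="A",
    allele_secondary="C",
    flank_left="GGTT",
    flank_right="TGGT",
    label="integrated-plasmid A/C SNP",
)


@dataclass(frozen=True)
class TraceGenSpec:
    """Parameters of a synthetic chromatogram around one SNP."""

    fraction_primary: float = 0.5
    sequence: str = _DEFAULT_SEQUENCE
    snp_position: int = _DEFAULT_SNP_POSITION
    allele_primary: str = "A"
    allele_secondary: str = "C"
    spacing: int = 10  # scan indices per base
    peak_width: float = 1.8  # Gaussian sd, scan indices
    amplitude: float = 1000.0
    noise_sd: float = 0.0  # multiplicative, on peak amplitudes
    baseline: float = 0.0  # additive, all channels
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_primary <= 1.0:
            raise ValidationError("fraction_primary must lie in [0, 1]")
        if not 0 <= self.snp_position < len(self.sequence):
            raise ValidationError("snp_position outside the sequence")
        if self.spacing <= 4 * self.peak_width:
            import warnings

            warnings.warn(
                "peak spacing <= 4x peak width; neighbouring peaks will overlap",
                stacklevel=2,
            )


@dataclass(frozen=True)
class CompetitionGenSpec:
    """Parameters of a simulated two-strain competition."""

    initial_fraction: float = 0.5
    selection_per_generation: float = 0.0  # log2 odds gain of strain A per generation
    duration: float = 180.0  # minutes
    doubling_time: float = 120.0  # minutes
    noise_sd: float = 0.02  # additive, on measured fraction
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.initial_fraction < 1.0:
            raise ValidationError("initial_fraction must lie in (0, 1)")
        if self.duration < 0 or self.doubling_time <= 0:
            raise ValidationError("duration >= 0 and doubling_time > 0 required")


@dataclass(frozen=True)
class ChipGenSpec:
    """Parameters of a simulated ChIP decay time course."""

    params: MarkDecayParams = field(
        default_factory=lambda: MarkDecayParams(s0=10.0, background=1.0, doubling_time=120.0)
    )
    timepoints: tuple[float, ...] = (0.0, 60.0, 120.0, 240.0, 360.0, 480.0)
    noise_sd: float = 0.05  # multiplicative, per replicate
    n_replicates: int = 3
    include_control: bool = True
    seed: int = 0


def simulate_trace(spec: TraceGenSpec) -> tuple[TraceSignal, dict]:
    """Render a four-channel trace from the generating spec.

    Returns the trace and a ground-truth record holding the SNP basecall
    index, the generating fraction, and every Gaussian component
    (channel, center, sd, realized amplitude) so an oracle can integrate
    the generating model directly.
    """
    rng = np.random.default_rng(spec.seed)
    n_bases = len(spec.sequence)
    L = n_bases * spec.spacing
    x = np.arange(L, dtype=float)
    channels = {b: np.full(L, float(spec.baseline)) for b in "ACGT"}
    peak_positions = spec.spacing // 2 + spec.spacing * np.arange(n_bases)

    def noisy(amp: float) -> float:
        if spec.noise_sd == 0 or amp == 0:
            return amp
        return max(0.0, amp * (1.0 + rng.normal(0.0, spec.noise_sd)))

    components: list[dict] = []
    called = []
    for i, base in enumerate(spec.sequence.upper()):
        center = float(peak_positions[i])
        if i == spec.snp_position:
            f = spec.fraction_primary
            for allele, weight in (
                (spec.allele_primary, f),
                (spec.allele_secondary, 1.0 - f),
            ):
                amp = noisy(spec.amplitude * weight)
                if amp > 0:
                    channels[allele] += amp * np.exp(
                        -((x - center) ** 2) / (2 * spec.peak_width**2)
                    )
                components.append(
                    {"channel": allele, "center": center, "sd": spec.peak_width, "amplitude": amp}
                )
            called.append(spec.allele_primary if f >= 0.5 else spec.allele_secondary)
        else:
            amp = noisy(spec.amplitude)
            channels[base] += amp * np.exp(-((x - center) ** 2) / (2 * spec.peak_width**2))
            components.append(
                {"channel": base, "center": center, "sd": spec.peak_width, "amplitude": amp}
            )
            called.append(base)

    trace = TraceSignal(
        intensities=np.stack([channels[b] for b in "ACGT"]),
        called_bases=tuple(called),
        peak_positions=peak_positions,
        channel_order=("A", "C", "G", "T"),
    )
    truth = {
        "snp_index": spec.snp_position,
        "fraction_primary": spec.fraction_primary,
        "baseline": spec.baseline,
        "components": components,
    }
    return trace, truth


def simulate_competition(
    spec: CompetitionGenSpec,
) -> tuple[list[CompetitionSample], dict]:
    """Two-strain exponential competition sampled at t=0 and the end point.

    The true fraction evolves by odds(t) = odds(0) * 2^(s * t / T_d);
    measured fractions add Gaussian assay noise, clamped inside (0, 1).
    """
    rng = np.random.default_rng(spec.seed)
    odds0 = spec.initial_fraction / (1.0 - spec.initial_fraction)
    generations = spec.duration / spec.doubling_time
    odds_end = odds0 * 2.0 ** (spec.selection_per_generation * generations)
    true_end = odds_end / (1.0 + odds_end)

    eps = 1e-9
    samples: list[CompetitionSample] = []
    for r in range(spec.n_replicates):
        rep = f"rep{r + 1}"
        for t, true in ((0.0, spec.initial_fraction), (spec.duration, true_end)):
            measured = true + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0)
            measured = float(np.clip(measured, eps, 1.0 - eps))
            samples.append(
                CompetitionSample(replicate_id=rep, timepoint=t, fraction_primary=measured)
            )
    truth = {
        "initial_fraction": spec.initial_fraction,
        "true_end_fraction": true_end,
        "true_log2_ratio": spec.selection_per_generation * generations,
        "generations": generations,
    }
    return samples, truth


def simulate_chip_timecourse(spec: ChipGenSpec) -> tuple[ChipTimecourse, dict]:
    """ChIP decay time course with multiplicative replicate noise.

    Per-replicate signal at each time is the model expectation times
    (1 + eps), eps ~ N(0, noise_sd); the table carries the replicate
    mean and SEM. When ``include_control`` is set, a negative-control
    locus at the background level (with the same noise) is attached.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.timepoints, dtype=float)
    mu = expected_signal(spec.params, times)
    reps = np.maximum(
        0.0, mu[None, :] * (1.0 + rng.normal(0.0, spec.noise_sd, (spec.n_replicates, len(times))))
    )
    signals = reps.mean(axis=0)
    if spec.n_replicates >= 2:
        sems = reps.std(axis=0, ddof=1) / math.sqrt(spec.n_replicates)
    else:
        sems = np.zeros_like(signals)
    control = None
    if spec.include_control:
        ctrl_reps = np.maximum(
            0.0,
            spec.params.background
            * (1.0 + rng.normal(0.0, spec.noise_sd, (spec.n_replicates, len(times)))),
        )
        control = ctrl_reps.mean(axis=0)
    tc = ChipTimecourse(
        times=times,
        signals=signals,
        sems=sems,
        n_replicates=spec.n_replicates,
        locus="synthetic",
        control_signals=control,
    )
    truth = {
        "params": spec.params,
        "expected_signals": mu,
    }
    return tc, truth


def simulate_localization_counts(
    p: float,
    n_cells: int = 30,
    n_replicates: int = 3,
    seed: int | np.random.Generator = 0,
    condition: str = "",
    timepoint: float | None = None,
) -> LocalizationDataset:
    """Binomial peripheral-cell counts per biological replicate."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError("p must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.binomial(n_cells, p, size=n_replicates)
    return LocalizationDataset(
        n_cells=np.full(n_replicates, n_cells),
        n_peripheral=counts,
        condition=condition,
        timepoint=timepoint,
    )


# ---------------------------------------------------------------------------
# Fixture suite


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture_suite(seed: int, out_dir: str | Path) -> dict:
    """Write the full synthetic fixture suite plus a ground-truth manifest.

    Emits one calibration trace per design mixture fraction (5% peak
    noise), a 1:1-start 3-hr competition table, ChIP time courses for the
    passive / maintained / actively-removed regimes (T_d = 120 min), and
    localization counts at the random baseline and an enriched
    probability. Returns the manifest (also written as manifest.json).
    """
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "files": {}, "ground_truth": {}}

    write_locus(DEFAULT_LOCUS, out / "locus.txt")
    manifest["files"]["locus.txt"] = _sha256(out / "locus.txt")

    for f in DESIGN_FRACTIONS:
        spec = TraceGenSpec(
            fraction_primary=f, noise_sd=0.05, seed=int(rng.integers(2**31))
        )
        trace, truth = simulate_trace(spec)
        name = f"traces/frac_{int(round(100 * f)):03d}.tsv"
        write_trace(trace, out / name)
        manifest["files"][name] = _sha256(out / name)
        manifest["ground_truth"][name] = {
            "fraction_primary": f,
            "snp_index": truth["snp_index"],
        }

    comp_spec = CompetitionGenSpec(seed=int(rng.integers(2**31)))
    samples, comp_truth = simulate_competition(comp_spec)
    comp_path = out / "competition.tsv"
    lines = ["replicate\ttimepoint_min\tfraction"]
    lines += [
        f"{s.replicate_id}\t{s.timepoint:g}\t{float(s.fraction_primary)!r}"
        for s in samples
    ]
    comp_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    manifest["files"]["competition.tsv"] = _sha256(comp_path)
    manifest["ground_truth"]["competition.tsv"] = {
        "initial_fraction": comp_spec.initial_fraction,
        "true_log2_ratio": comp_truth["true_log2_ratio"],
    }

    regimes = {
        "chip_passive.tsv": MarkDecayParams(s0=10.0, background=1.0, doubling_time=120.0),
        "chip_maintained.tsv": MarkDecayParams(
            s0=10.0, background=1.0, doubling_time=120.0, maintenance_prob=0.95
        ),
        "chip_removed.tsv": MarkDecayParams(
            s0=10.0, background=1.0, doubling_time=120.0, removal_rate=0.03
        ),
    }
    for name, params in regimes.items():
        tc, _ = simulate_chip_timecourse(
            ChipGenSpec(params=params, seed=int(rng.integers(2**31)))
        )
        lines = ["time_min\tsignal\tsem\tn\tcontrol"]
        for i in range(len(tc.times)):
            lines.append(
                f"{tc.times[i]:g}\t{float(tc.signals[i])!r}\t{float(tc.sems[i])!r}\t"
                f"{tc.n_replicates}\t{float(tc.control_signals[i])!r}"
            )
        (out / name).write_text("\n".join(lines) + "\n", encoding="utf-8")
        manifest["files"][name] = _sha256(out / name)
        manifest["ground_truth"][name] = {
            "maintenance_prob": params.maintenance_prob,
            "removal_rate": params.removal_rate,
        }

    loc_sets = {
        "localization_baseline.tsv": 0.271,
        "localization_enriched.tsv": 0.60,
    }
    for name, p in loc_sets.items():
        ds = simulate_localization_counts(
            p, n_cells=30, n_replicates=3, seed=int(rng.integers(2**31))
        )
        lines = ["replicate\tn_cells\tn_peripheral"]
        lines += [
            f"rep{i + 1}\t{int(ds.n_cells[i])}\t{int(ds.n_peripheral[i])}"
            for i in range(ds.n_replicates)
        ]
        (out / name).write_text("\n".join(lines) + "\n", encoding="utf-8")
        manifest["files"][name] = _sha256(out / name)
        manifest["ground_truth"][name] = {"p": p}

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
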