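"""Competition-fitness readout: null calibration and selection recovery.

Runs simulated two-strain competitions (1:1 start, 3 hr, T_d = 120 min)
through the full chromatogram pipeline: each measured fraction is
rendered as a synthetic trace, re-quantified by peak area, calibrated,
and converted to a t0-normalized log2 odds ratio.

Findings: (1) with no selection the mean log2 ratio across 200
competitions is statistically indistinguishable from 0 (the assay does
not manufacture fitness differences); (2) true selection coefficients of
0.1-0.5 per generation are recovered without systematic bias.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from epimemory.pipeline import competition_via_traces, synthetic_standard_curve
from epimemory.synthetic_data import CompetitionGenSpec

SEED = 20260928
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rng = np.random.default_rng(SEED)
    curve, _ = synthetic_standard_curve(seed=SEED, replicates_per_point=5)

    rows = []
    null_means = []
    for _ in range(200):
        res = competition_via_traces(
            CompetitionGenSpec(noise_sd=0.02, seed=int(rng.integers(2**31))), curve=curve
        )
        null_means.append(res.mean_log2_ratio)
    null_means = np.asarray(null_means)
    sem = null_means.std(ddof=1) / np.sqrt(len(null_means))
    rows.append(
        {
            "selection_per_generation": 0.0,
            "mean_log2_ratio": null_means.mean(),
            "sem": sem,
            "n_simulations": len(null_means),
            "mean_selection_estimate": null_means.mean() / 1.5,
        }
    )
    print(
        f"null competitions: mean log2 ratio = {null_means.mean():+.4f} "
        f"+/- {sem:.4f} SEM (within {abs(null_means.mean()) / sem:.1f} SEM of 0)"
    )

    for s in (0.1, 0.25, 0.5):
        ests = []
        for _ in range(100):
            res = competition_via_traces(
                CompetitionGenSpec(
                    selection_per_generation=s, noise_sd=0.02, seed=int(rng.integers(2**31))
                ),
                curve=curve,
                doubling_time=120.0,
            )
            ests.append(res.selection_per_generation)
        ests = np.asarray(ests)
        rows.append(
            {
                "selection_per_generation": s,
                "mean_log2_ratio": ests.mean() * 1.5,
                "sem": ests.std(ddof=1) / np.sqrt(len(ests)) * 1.5,
                "n_simulations": len(ests),
                "mean_selection_estimate": ests.mean(),
            }
        )
        print(
            f"s = {s:.2f}/generation: recovered {ests.mean():.4f} "
            f"({100 * (ests.mean() - s) / s:+.1f}% bias)"
        )

    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "competition_fitness.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'competition_fitness.tsv'}")


if __name__ == "__main__":
    sys.exit(main())
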