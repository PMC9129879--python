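"""Nuclear-periphery localization: random baseline and enrichment testing.

Computes the expected colocalization frequency of a randomly positioned
gene with the nuclear envelope under the spherical-shell model,
cross-checks it by Monte Carlo, and exercises the replicate-level
one-tailed t-test on simulated cell counts (>= 30 cells per replicate,
3 replicates), including its type-I error rate at the baseline.

Findings: a shell 10% of the nuclear radius yields a 27.1% baseline; the
test rejects at ~5% when the truth is the baseline and detects a 60%
peripheral condition decisively.
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from epimemory.localization import (
    enrichment_test,
    peripheral_baseline_analytic,
    peripheral_baseline_mc,
)
from epimemory.synthetic_data import simulate_localization_counts

SEED = 20260928
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    p0 = peripheral_baseline_analytic(0.1)
    mc = peripheral_baseline_mc(1.0, 0.1, n_points=1_000_000, seed=SEED)
    print(f"analytic baseline (shell = 10% of radius): {100 * p0:.1f}%")
    print(f"Monte-Carlo baseline (n = 10^6): {100 * mc.value:.2f}% +/- {100 * mc.se:.2f}%")

    rng = np.random.default_rng(SEED)
    enriched = simulate_localization_counts(
        0.60, n_cells=30, n_replicates=3, seed=rng, condition="memory"
    )
    res = enrichment_test(enriched, p0, alternative="greater")
    print(
        f"enriched condition: {res.mean_percent:.1f}% +/- {res.sem_percent:.1f}% "
        f"peripheral, one-tailed p = {res.p_value:.2g}"
    )

    n_sims = 2000
    rejections = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(n_sims):
            ds = simulate_localization_counts(p0, n_cells=30, n_replicates=3, seed=rng)
            rejections += enrichment_test(ds, p0, alternative="greater").p_value < 0.05
    print(f"type-I rate at baseline (alpha = 0.05): {rejections / n_sims:.3f}")

    pd.DataFrame(
        [
            {"quantity": "baseline_analytic_percent", "value": 100 * p0},
            {"quantity": "baseline_mc_percent", "value": 100 * mc.value},
            {"quantity": "baseline_mc_se_percent", "value": 100 * mc.se},
            {"quantity": "enriched_mean_percent", "value": res.mean_percent},
            {"quantity": "enriched_p_value", "value": res.p_value},
            {"quantity": "type_I_rate", "value": rejections / n_sims},
        ]
    ).to_csv(OUT / "localization.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'localization.tsv'}")


if __name__ == "__main__":
    sys.exit(main())
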