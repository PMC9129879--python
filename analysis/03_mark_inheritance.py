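"""Histone-mark inheritance: decay fits, persistence, and regime calling.

Simulates ChIP time courses (T_d = 120 min, 6 timepoints over 8 hr, 5%
replicate noise, negative-control locus) under three regimes — passive
replication dilution, reader-writer maintenance, and active removal —
fits the nested persistence models, and classifies each course by AICc.

Findings: the passive-dilution fit recovers a signal half-life equal to
the doubling time; the maintained regime stays detectably above
background for ~4 generations (8 hr) while the passive expectation decays
away; regime classification is >= 95% accurate in all three regimes.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from epimemory.inheritance import (
    MarkDecayParams,
    classify_heritability,
    fit_decay,
    half_life,
    persistence_generations,
)
from epimemory.synthetic_data import ChipGenSpec, simulate_chip_timecourse

SEED = 20260928
TD = 120.0
OUT = Path(__file__).resolve().parents[1] / "results"

REGIMES = {
    "passive_dilution": MarkDecayParams(s0=10.0, background=1.0, doubling_time=TD),
    "heritable": MarkDecayParams(
        s0=10.0, background=1.0, doubling_time=TD, maintenance_prob=0.9
    ),
    "active_removal": MarkDecayParams(
        s0=10.0, background=1.0, doubling_time=TD, removal_rate=0.03
    ),
}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)

    # noise-free half-life check
    tc0, _ = simulate_chip_timecourse(
        ChipGenSpec(params=REGIMES["passive_dilution"], noise_sd=0.0)
    )
    fit0 = fit_decay(tc0, TD, model="maintenance")
    print(
        f"passive dilution, noise-free: fitted half-life "
        f"{half_life(fit0.params):.2f} min (doubling time {TD:.0f} min)"
    )

    rows = []
    for name, params in REGIMES.items():
        tc, _ = simulate_chip_timecourse(
            ChipGenSpec(params=params, noise_sd=0.05, seed=int(rng.integers(2**31)))
        )
        report = classify_heritability(tc, TD)
        pers = persistence_generations(tc, TD)
        sel = report.selected.params
        rows.append(
            {
                "regime": name,
                "classified_as": report.label,
                "fitted_m": sel.maintenance_prob,
                "fitted_k_per_min": sel.removal_rate,
                "half_life_min": half_life(sel),
                "persistence_generations": pers.generations,
            }
        )
        print(
            f"{name}: classified {report.label}, m = {sel.maintenance_prob:.2f}, "
            f"k = {sel.removal_rate:.4f}/min, persists {pers.generations:.1f} generations"
        )
    pd.DataFrame(rows).to_csv(OUT / "inheritance_fits.tsv", sep="\t", index=False)

    acc_rows = []
    for name, params in REGIMES.items():
        correct = 0
        n = 100
        for _ in range(n):
            tc, _ = simulate_chip_timecourse(
                ChipGenSpec(params=params, noise_sd=0.05, seed=int(rng.integers(2**31)))
            )
            correct += classify_heritability(tc, TD).label == name
        acc_rows.append({"regime": name, "accuracy": correct / n, "n_timecourses": n})
        print(f"classification accuracy, {name}: {correct}/{n}")
    pd.DataFrame(acc_rows).to_csv(
        OUT / "inheritance_classification.tsv", sep="\t", index=False
    )
    print(f"wrote {OUT / 'inheritance_fits.tsv'} and classification table")


if __name__ == "__main__":
    sys.exit(main())
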