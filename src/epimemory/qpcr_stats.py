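"""qPCR arithmetic and the replicate-level one-tailed t-tests.

Relative expression follows the comparative-Ct method (target normalized
to a reference transcript, e.g. a memory gene's mRNA relative to ACT1):
efficiency^(Ct_ref - Ct_target). ChIP recovery relative to input scales
the same arithmetic by the fraction of chromatin saved as input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class QpcrSample:
    ct_target: float
    ct_reference: float
    condition: str = ""
    timepoint: float | None = None
    replicate: str = ""
    efficiency: float = 2.0  # amplification factor per cycle

    def __post_init__(self) -> None:
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ValidationError("Ct values must be > 0")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValidationError("efficiency must lie in (1, 2]")


class TTestResult(NamedTuple):
    t: float
    df: float
    p_value: float


def relative_expression(sample: QpcrSample) -> float:
    """Target abundance relative to the reference: E^(Ct_ref - Ct_target)."""
    return sample.efficiency ** (sample.ct_reference - sample.ct_target)


def chip_recovery(
    ct_ip: float,
    ct_input: float,
    input_fraction: float,
    efficiency: float = 2.0,
) -> float:
    """ChIP recovery relative to input: input_fraction * E^(Ct_input - Ct_ip)."""
    if not 0.0 < input_fraction <= 1.0:
        raise ValidationError("input_fraction must lie in (0, 1]")
    if not 1.0 < efficiency <= 2.0:
        raise ValidationError("efficiency must lie in (1, 2]")
    return input_fraction * efficiency ** (ct_input - ct_ip)


def one_tailed_t(
    group_a: Sequence[float],
    group_b: Sequence[float] | float,
    alternative: str = "greater",
) -> TTestResult:
    """One-tailed t-test: Welch two-sample, or one-sample against a scalar.

    Zero-variance data exactly at the null give t = 0, p = 0.5 rather
    than an undefined statistic.
    """
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    a = np.asarray(group_a, dtype=float)
    if a.size < 2:
        raise ValidationError("group_a needs at least 2 values")
    if np.isscalar(group_b) or isinstance(group_b, float | int):
        mu = float(group_b)
        if a.std(ddof=1) == 0 and a.mean() == mu:
            df = float(a.size - 1)
            return TTestResult(0.0, df, 0.5)
        res = stats.ttest_1samp(a, mu, alternative=alternative)
        return TTestResult(float(res.statistic), float(a.size - 1), float(res.pvalue))
    b = np.asarray(group_b, dtype=float)
    if b.size < 2:
        raise ValidationError("group_b needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        df = float(a.size + b.size - 2)
        return TTestResult(0.0, df, 0.5)
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))
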