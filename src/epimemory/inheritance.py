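"""Histone-mark persistence through DNA replication.

Model
-----
Nucleosomes are randomly segregated to the two daughter chromatids at
replication, so without re-deposition a chromatin mark's locus-level
signal halves every cell division: f(t) = 2^(-t/T_d), i.e. the signal
half-life equals the culture doubling time T_d. A reader-writer
maintenance loop (a complex that binds the mark on retained nucleosomes
and recruits the writer to re-methylate neighbours) re-marks each newly
unmarked nucleosome with per-division probability m, giving the marked
fraction a per-division factor (1 + m)/2. Treating replication as a
continuous dilution process and allowing a first-order active-removal
(demethylation) rate k (per minute):

    f(t) = ((1 + m) / 2)^(t / T_d) * exp(-k t)

m = 0, k = 0 recovers passive dilution (half-life = T_d); m = 1, k = 0 is
perfect inheritance (flat signal). The ChIP signal is assumed linear in
the marked-nucleosome fraction: signal(t) = background + s0 * f(t).

Fitting
-------
T_d is measured from the culture and supplied, never fitted. For a given
(m, k) the model is linear in (s0, background), so fits profile the
linear part with nonnegative weighted least squares and search (m, k) by
a deterministic grid plus local refinement. Three nested models
(dilution-only, maintenance, maintenance + removal) are compared by AICc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .errors import IdentifiabilityError, ValidationError

ModelName = Literal["dilution_only", "maintenance", "maintenance_plus_removal"]
MODELS: tuple[ModelName, ...] = ("dilution_only", "maintenance", "maintenance_plus_removal")

_M_GRID = np.linspace(0.0, 1.0, 11)
_K_GRID = np.array([0.0, 1e-4, 3e-4, 1e-3, 3e-3, 0.01, 0.03, 0.1])
_RSS_TIE_TOL = 1e-9


@dataclass(frozen=True)
class MarkDecayParams:
    """Parameters of the mark-persistence model.

    s0 : initial signal above background (ChIP recovery units)
    background : baseline signal, e.g. the negative-control locus level
    doubling_time : culture doubling time T_d, minutes
    maintenance_prob : m, per-division re-marking probability in [0, 1]
    removal_rate : k, active removal rate per minute, >= 0
    """

    s0: float
    background: float
    doubling_time: float
    maintenance_prob: float = 0.0
    removal_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.s0 < 0 or self.background < 0:
            raise ValidationError("s0 and background must be >= 0")
        if self.doubling_time <= 0:
            raise ValidationError("doubling_time must be > 0")
        if not 0.0 <= self.maintenance_prob <= 1.0:
            raise ValidationError("maintenance_prob must lie in [0, 1]")
        if self.removal_rate < 0:
            raise ValidationError("removal_rate must be >= 0")


@dataclass(frozen=True)
class ChipTimecourse:
    """Mean ChIP recovery over time with replicate-level uncertainty."""

    times: np.ndarray  # minutes, strictly increasing
    signals: np.ndarray
    sems: np.ndarray
    n_replicates: int = 1
    locus: str = ""
    control_signals: np.ndarray | None = None  # negative-control locus

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "signals", np.asarray(self.signals, dtype=float))
        object.__setattr__(self, "sems", np.asarray(self.sems, dtype=float))
        if self.control_signals is not None:
            object.__setattr__(
                self, "control_signals", np.asarray(self.control_signals, dtype=float)
            )
        if not (len(self.times) == len(self.signals) == len(self.sems)):
            raise ValidationError("times, signals, sems must have equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise ValidationError("times must be >= 0")
        if np.any(self.signals < 0):
            raise ValidationError("signals must be >= 0")
        if np.any(self.sems < 0):
            raise ValidationError("sems must be >= 0")
        if self.control_signals is not None and len(self.control_signals) != len(self.times):
            raise ValidationError("control_signals must match times in length")


@dataclass(frozen=True)
class DecayFit:
    """Result of fitting one persistence model to a time course."""

    params: MarkDecayParams
    rss: float
    model: ModelName
    n_free: int
    background_fixed: bool
    aicc: float = math.nan


@dataclass(frozen=True)
class HeritabilityReport:
    label: Literal["passive_dilution", "heritable", "active_removal"]
    selected: DecayFit
    fits: dict[ModelName, DecayFit]


@dataclass(frozen=True)
class PersistenceResult:
    t_star: float  # minutes
    generations: float
    detected: np.ndarray  # per-timepoint detection flags


def mark_fraction(params: MarkDecayParams, t: float | np.ndarray) -> float | np.ndarray:
    """Fraction of nucleosomes still marked at time t (minutes)."""
    t = np.asarray(t, dtype=float)
    per_div = (1.0 + params.maintenance_prob) / 2.0
    out = per_div ** (t / params.doubling_time) * np.exp(-params.removal_rate * t)
    return float(out) if out.ndim == 0 else out


def expected_signal(params: MarkDecayParams, t: float | np.ndarray) -> float | np.ndarray:
    """Predicted ChIP signal: background + s0 * mark_fraction(t)."""
    return params.background + params.s0 * mark_fraction(params, t)


def half_life(params: MarkDecayParams) -> float:
    """Time for the above-background signal to halve; inf if never."""
    rate = params.removal_rate + math.log(
        2.0 / (1.0 + params.maintenance_prob)
    ) / params.doubling_time
    if rate <= 0:
        return math.inf
    return math.log(2.0) / rate


def simulate_locus_divisions(
    params: MarkDecayParams,
    n_nucleosomes: int,
    n_divisions: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Stochastic per-division mark trajectory at one locus.

    Each division, every marked nucleosome is retained with probability
    1/2 (random segregation of old nucleosomes to the daughters); each
    position that just lost its mark is re-marked with probability m
    (reader-writer copying from the retained neighbours). Returns marked
    fractions at divisions 0..n_divisions; the mean over seeds converges
    to ((1 + m) / 2)^division.
    """
    if n_nucleosomes < 1:
        raise ValidationError("n_nucleosomes must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = params.maintenance_prob
    marked = np.ones(n_nucleosomes, dtype=bool)
    fractions = [1.0]
    for _ in range(n_divisions):
        retained = marked & (rng.random(n_nucleosomes) < 0.5)
        lost = marked & ~retained
        remarked = lost & (rng.random(n_nucleosomes) < m)
        marked = retained | remarked
        fractions.append(marked.mean())
    return np.asarray(fractions)


# ---------------------------------------------------------------------------
# Fitting


def _weights(tc: ChipTimecourse) -> np.ndarray:
    if np.all(tc.sems > 0):
        return 1.0 / tc.sems**2
    return np.ones_like(tc.signals)


def _linear_solve(
    phi: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    background: float | None,
) -> tuple[float, float, float]:
    """Profile (s0, background >= 0) for fixed decay shape phi(t).

    Returns (s0, background, weighted RSS).
    """
    sw = np.sqrt(w)
    if background is not None:
        resid_target = (y - background) * sw
        col = phi * sw
        denom = float(col @ col)
        s0 = max(0.0, float(col @ resid_target) / denom) if denom > 0 else 0.0
        r = resid_target - s0 * col
        return s0, background, float(r @ r)
    design = np.column_stack([np.ones_like(phi), phi]) * sw[:, None]
    coef, _ = optimize.nnls(design, y * sw)
    r = y * sw - design @ coef
    return float(coef[1]), float(coef[0]), float(r @ r)


def _model_free_params(model: ModelName, background_fixed: bool) -> int:
    n = 1 if background_fixed else 2  # s0 (+ background)
    if model == "maintenance":
        n += 1
    elif model == "maintenance_plus_removal":
        n += 2
    return n


def _rss_for(
    m: float,
    k: float,
    tc: ChipTimecourse,
    doubling_time: float,
    w: np.ndarray,
    background: float | None,
) -> tuple[float, float, float]:
    phi = ((1.0 + m) / 2.0) ** (tc.times / doubling_time) * np.exp(-k * tc.times)
    return _linear_solve(phi, tc.signals, w, background)


def fit_decay(
    tc: ChipTimecourse,
    doubling_time: float,
    model: ModelName = "maintenance",
    background: float | None = None,
) -> DecayFit:
    """Weighted least-squares fit of one persistence model.

    Weights are 1/sem^2 when all SEMs are positive, else unweighted.
    If ``background`` is not given and the time course carries a
    negative-control locus, the background is fixed to the control mean;
    otherwise it is a free (nonnegative) parameter. The (m, k) search is
    a deterministic grid followed by local refinement; ties in RSS go to
    the smaller m, then the smaller k.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if doubling_time <= 0:
        raise ValidationError("doubling_time must be > 0")
    if background is None and tc.control_signals is not None:
        background = float(np.mean(tc.control_signals))
    background_fixed = background is not None
    n_free = _model_free_params(model, background_fixed)
    if len(tc.times) < n_free:
        raise IdentifiabilityError(
            f"{len(tc.times)} timepoints cannot identify {n_free} free parameters"
        )
    if len(tc.times) < 3:
        raise IdentifiabilityError("need at least 3 timepoints")
    w = _weights(tc)

    m_vals = _M_GRID if model != "dilution_only" else np.array([0.0])
    k_vals = _K_GRID if model == "maintenance_plus_removal" else np.array([0.0])

    best: tuple[float, float, float] | None = None  # (rss, m, k)
    for m in m_vals:
        for k in k_vals:
            _, _, rss = _rss_for(m, k, tc, doubling_time, w, background)
            cand = (rss, m, k)
            if best is None or _better(cand, best):
                best = cand
    assert best is not None
    _, m0, k0 = best

    # Local refinement over the model's free nonlinear parameters.
    if model != "dilution_only":
        if model == "maintenance":
            x0, bounds = [m0], [(0.0, 1.0)]

            def obj(x: np.ndarray) -> float:
                return _rss_for(x[0], 0.0, tc, doubling_time, w, background)[2]

        else:
            x0, bounds = [m0, k0], [(0.0, 1.0), (0.0, 1.0)]

            def obj(x: np.ndarray) -> float:
                return _rss_for(x[0], x[1], tc, doubling_time, w, background)[2]

        res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds)
        m_ref = float(res.x[0])
        k_ref = float(res.x[1]) if model == "maintenance_plus_removal" else 0.0
        cand = (float(res.fun), m_ref, k_ref)
        if _better(cand, best):
            best = cand

    rss, m_fit, k_fit = best
    s0, bg, rss = _rss_for(m_fit, k_fit, tc, doubling_time, w, background)
    params = MarkDecayParams(
        s0=s0,
        background=bg,
        doubling_time=doubling_time,
        maintenance_prob=m_fit,
        removal_rate=k_fit,
    )
    fit = DecayFit(
        params=params,
        rss=rss,
        model=model,
        n_free=n_free,
        background_fixed=background_fixed,
    )
    return replace(fit, aicc=_aicc(rss, len(tc.times), n_free))


def _better(cand: tuple[float, float, float], best: tuple[float, float, float]) -> bool:
    """RSS comparison with deterministic tie-break: smaller m, then smaller k."""
    if cand[0] < best[0] - _RSS_TIE_TOL:
        return True
    if cand[0] > best[0] + _RSS_TIE_TOL:
        return False
    return (cand[1], cand[2]) < (best[1], best[2])


def _aicc(rss: float, n: int, k: int) -> float:
    """Small-sample-corrected AIC for a least-squares fit with k mean parameters."""
    if n - k - 1 <= 0:
        return math.inf
    rss = max(rss, 1e-12)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def classify_heritability(
    tc: ChipTimecourse,
    doubling_time: float,
    background: float | None = None,
    heritable_m: float = 0.5,
) -> HeritabilityReport:
    """Fit all three nested models, select by AICc, and label the regime.

    heritable : selected model's maintenance probability m >= ``heritable_m``
    active_removal : selected removal rate k > 0 and fitted half-life < T_d
    passive_dilution : otherwise
    """
    fits = {
        model: fit_decay(tc, doubling_time, model=model, background=background)
        for model in MODELS
    }
    selected = min(fits.values(), key=lambda f: (f.aicc, f.n_free))
    if not math.isfinite(selected.aicc):
        # Fall back to raw RSS with a preference for fewer parameters.
        selected = min(fits.values(), key=lambda f: (f.n_free, f.rss))
    p = selected.params
    if p.maintenance_prob >= heritable_m:
        label = "heritable"
    elif p.removal_rate > 0 and half_life(p) < doubling_time:
        label = "active_removal"
    else:
        label = "passive_dilution"
    return HeritabilityReport(label=label, selected=selected, fits=fits)


def persistence_generations(
    tc: ChipTimecourse,
    doubling_time: float,
    threshold: float | None = None,
    background: float | None = None,
) -> PersistenceResult:
    """How long the mark stays detectably above background, in generations.

    A timepoint is detected when ``signal - sem >= background`` (default
    rule) or, with an explicit ``threshold``, when
    ``signal - background >= threshold``. The persistence time t* is the
    last detected timepoint; generations = t* / T_d. A time course
    already below threshold at t=0 yields zero persistence.
    """
    if background is None:
        if tc.control_signals is None:
            raise ValidationError(
                "background must be given or derivable from control_signals"
            )
        background = float(np.mean(tc.control_signals))
    if threshold is None:
        detected = (tc.signals - tc.sems) >= background
    else:
        detected = (tc.signals - background) >= threshold
    if not detected.any():
        return PersistenceResult(t_star=0.0, generations=0.0, detected=detected)
    t_star = float(tc.times[detected].max())
    return PersistenceResult(
        t_star=t_star, generations=t_star / doubling_time, detected=detected
    )
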