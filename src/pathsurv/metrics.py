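"""Censoring-aware model performance: IPCW Brier score / IBS, concordance
index, the corrected resampled t-test, bootstrap confidence intervals and
median risk-group splitting.

Censoring weights use the reverse Kaplan–Meier estimate G(t) of the
censoring distribution.  An event before t* contributes with weight
1/G(T_i^-), a survivor past t* with weight 1/G(t*), and a subject
censored before t* contributes nothing; the left limit at the subject's
own time avoids weighting an observation by its own censoring step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "StepFunction",
    "km_estimator",
    "censoring_model",
    "brier_score_ipcw",
    "integrated_brier_score",
    "concordance_index",
    "corrected_resampled_ttest",
    "bootstrap_metric_ci",
    "risk_group_split",
    "MetricResult",
]


@dataclass
class MetricResult:
    """A point estimate with optional bootstrap CI and metadata."""

    name: str
    estimate: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    level: float | None = None
    n_boot: int | None = None
    n_pairs: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ci_lower is not None and not (
            self.ci_lower <= self.estimate <= self.ci_upper
        ):
            raise ValueError("CI must bracket the point estimate")

    def __float__(self) -> float:
        return float(self.estimate)


class StepFunction:
    """Right-continuous step function with left-limit evaluation."""

    def __init__(self, times: np.ndarray, values: np.ndarray, start_value: float = 1.0):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.start_value = float(start_value)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        vals = np.concatenate([[self.start_value], self.values])
        return vals[idx]

    def left_limit(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left")
        vals = np.concatenate([[self.start_value], self.values])
        return vals[idx]


def km_estimator(times, indicators) -> StepFunction:
    """Kaplan–Meier product-limit estimate of the survival function.

    ``indicators`` flags the events being modelled (deaths for the
    ordinary KM, censorings for the reverse KM).
    """
    times = np.asarray(times, dtype=float)
    indicators = np.asarray(indicators)
    if len(times) == 0:
        raise ValueError("empty survival input")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    order = np.argsort(times, kind="stable")
    t, d = times[order], indicators[order].astype(float)
    n = len(t)
    uniq_t, surv = [], []
    s = 1.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        events = d[i:j].sum()
        at_risk = n - i
        if events > 0:
            s *= 1.0 - events / at_risk
            uniq_t.append(t[i])
            surv.append(s)
        i = j
    return StepFunction(np.asarray(uniq_t), np.asarray(surv))


def censoring_model(surv: SurvivalTable) -> StepFunction:
    """Reverse-KM estimate G(t) of the censoring distribution (events and
    censorings swapped)."""
    return km_estimator(surv.time, 1 - surv.event)


def brier_score_ipcw(pi: np.ndarray, surv: SurvivalTable, t_star: float,
                     G: StepFunction | None = None,
                     left_limit: bool = True) -> float:
    """Censoring-weighted Brier score at ``t_star``.

    BS(t*) = (1/n) sum_i W_i (I(T_i > t*) - pi_i)^2 with the observed
    event before t* weighted 1/G(T_i^-), the survivor past t* weighted
    1/G(t*) and the subject censored before t* weighted 0.
    ``left_limit=False`` evaluates G at T_i itself instead of the left
    limit (the unrefined convention).
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (surv.n,):
        raise ValueError("pi must give one survival probability per subject")
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("survival probabilities must lie in [0, 1]")
    if G is None:
        G = censoring_model(surv)
    t, d = surv.time, surv.event
    died = (t <= t_star) & (d == 1)
    alive = t > t_star
    w = np.zeros(surv.n)
    if died.any():
        g_at_death = G.left_limit(t[died]) if left_limit else G(t[died])
        if np.any(g_at_death <= 0):
            raise ValueError(
                "censoring survival G is 0 at an event time before t*; "
                "choose a smaller t*")
        w[died] = 1.0 / g_at_death
    if alive.any():
        g_star = float(G(t_star))
        if g_star <= 0:
            raise ValueError("censoring survival G(t*) is 0; choose a smaller t*")
        w[alive] = 1.0 / g_star
    resid = (alive.astype(float) - pi) ** 2
    return float(np.mean(w * resid))


def integrated_brier_score(pi, surv: SurvivalTable, times=None,
                           t_max: float | None = None,
                           G: StepFunction | None = None) -> float:
    """IBS = (1/t_max) * integral_0^t_max BS(t) dt, trapezoidal rule.

    ``pi`` is either a callable ``pi(times) -> samples x times`` matrix of
    survival probabilities, or a precomputed samples x times matrix with
    ``times`` supplying the matching grid.  The default grid is the unique
    observed event times up to ``t_max`` (largest observed event time by
    default), plus the endpoints 0 and t_max.
    """
    if t_max is None:
        etimes = surv.time[surv.event == 1]
        if len(etimes) == 0:
            raise ValueError("no events: IBS integration range undefined")
        t_max = float(etimes.max())
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    if G is None:
        G = censoring_model(surv)
    if callable(pi):
        grid = np.unique(np.concatenate(
            [[0.0], surv.time[(surv.event == 1) & (surv.time <= t_max)], [t_max]]))
        pi_mat = np.asarray(pi(grid), dtype=float)
    else:
        if times is None:
            raise ValueError("a precomputed pi matrix needs its time grid")
        grid = np.asarray(times, dtype=float)
        pi_mat = np.asarray(pi, dtype=float)
        keep = grid <= t_max
        grid, pi_mat = grid[keep], pi_mat[:, keep]
    if len(grid) == 0:
        raise ValueError("empty integration grid")
    bs = np.array([brier_score_ipcw(pi_mat[:, k], surv, t, G=G)
                   for k, t in enumerate(grid)])
    return float(np.trapezoid(bs, grid) / t_max)


def concordance_index(risk, surv: SurvivalTable) -> MetricResult:
    """Harrell-style concordance restricted to pairs whose ordering the
    censoring leaves unambiguous.

    An ordered pair (i, j) is usable iff the strictly smaller observed
    time belongs to an event; pairs with tied observed times are excluded
    (two tied events never establish T_i < T_j, and a subject censored at
    exactly T_i is not known to outlive i).  Concordant pairs score 1,
    risk ties 0.5.
    """
    risk = np.asarray(risk, dtype=float)
    if risk.shape != (surv.n,):
        raise ValueError("risk must align with the survival table")
    t, d = surv.time, surv.event
    # usable[i, j]: i is the earlier event, j survives longer
    earlier_event = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    n_pairs = int(earlier_event.sum())
    if n_pairs == 0:
        raise ValueError("no usable pairs (all censored or all times tied)")
    higher = risk[:, None] > risk[None, :]
    tied = risk[:, None] == risk[None, :]
    score = (earlier_event * (higher + 0.5 * tied)).sum()
    return MetricResult("cindex", float(score / n_pairs), n_pairs=n_pairs)


def corrected_resampled_ttest(diffs, n_train: int, n_test: int
                              ) -> tuple[float, float]:
    """Corrected resampled t-test for repeated random train/test splits.

    t = mean(d) / sqrt((1/J + n_test/n_train) * var(d)) with the unbiased
    sample variance; two-sided p from Student t with J-1 df.  The
    n_test/n_train inflation accounts for the overlap between training
    sets of different repeats that makes the J differences dependent.
    """
    d = np.asarray(diffs, dtype=float)
    j = len(d)
    if j < 2:
        raise ValueError("need at least two paired differences")
    if n_train <= 0 or n_test <= 0:
        raise ValueError("n_train and n_test must be positive")
    var = d.var(ddof=1)
    mean = d.mean()
    if var == 0:
        if mean == 0:
            return 0.0, 1.0
        logger.warning("zero variance with non-zero mean difference; p = 0")
        return np.inf if mean > 0 else -np.inf, 0.0
    t = mean / np.sqrt((1.0 / j + n_test / n_train) * var)
    p = 2.0 * stats.t.sf(abs(t), df=j - 1)
    return float(t), float(p)


def bootstrap_metric_ci(metric_fn, predictions, surv: SurvivalTable,
                        B: int = 1000, level: float = 0.95,
                        seed: int = 0, name: str = "metric",
                        max_redraws: int = 100) -> MetricResult:
    """Percentile bootstrap CI over resampled evaluation subjects.

    ``metric_fn(predictions_subset, surv_subset) -> float``;
    ``predictions`` is indexed along its first axis.  Resamples on which
    the metric is undefined (e.g. no usable pairs) are redrawn, with the
    redraw count logged.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    predictions = np.asarray(predictions, dtype=float)
    estimate = float(metric_fn(predictions, surv))
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    redraws = 0
    for b in range(B):
        for _ in range(max_redraws):
            idx = rng.integers(0, surv.n, size=surv.n)
            sub = SurvivalTable([f"b{k}" for k in range(surv.n)],
                                surv.time[idx], surv.event[idx])
            try:
                vals[b] = float(metric_fn(predictions[idx], sub))
                break
            except ValueError:
                redraws += 1
        else:
            raise RuntimeError("bootstrap metric undefined on every redraw")
    if redraws:
        logger.info("bootstrap: %d resamples redrawn (metric undefined)", redraws)
    alpha = 1.0 - level
    lo, hi = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
    return MetricResult(name, estimate,
                        ci_lower=float(min(lo, estimate)),
                        ci_upper=float(max(hi, estimate)),
                        level=level, n_boot=B,
                        extras={"redraws": redraws})


def risk_group_split(risk, surv: SurvivalTable | None = None):
    """Split subjects at the median linear predictor.

    high = risk > median, low = risk <= median.  When a survival table is
    supplied, per-group KM curves are returned alongside the labels.
    """
    risk = np.asarray(risk, dtype=float)
    if len(risk) < 2:
        raise ValueError("need >=2 samples to split")
    if np.all(risk == risk[0]):
        raise ValueError("all risks identical: no split possible")
    med = float(np.median(risk))
    high = risk > med
    if surv is None:
        return high
    curves = {
        "high": km_estimator(surv.time[high], surv.event[high]),
        "low": km_estimator(surv.time[~high], surv.event[~high]),
    }
    return high, curves


def plot_km_groups(high: np.ndarray, surv: SurvivalTable, ax=None):
    """Kaplan–Meier curves for the high/low risk groups (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, mask, color in (("high risk", high, "tab:red"),
                               ("low risk", ~high, "tab:blue")):
        sf = km_estimator(surv.time[mask], surv.event[mask])
        t = np.concatenate([[0.0], np.repeat(sf.times, 2)])
        s = np.concatenate([[1.0, 1.0], np.repeat(sf.values, 2)[:-1]]) \
            if len(sf.times) else np.array([1.0])
        ax.step(np.append(t, surv.time[mask].max()),
                np.append(s, sf.values[-1] if len(sf.values) else 1.0),
                where="post", label=label, color=color)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax
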