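"""Lasso and group-lasso penalized Cox proportional-hazards models.

The model minimises

    (1/n) * negative log partial likelihood (Breslow ties)
        + lambda * sum_j |beta_j|                      (lasso)
        + lambda * sum_g m_g * ||beta_g||_2            (group lasso)

by monotone accelerated proximal gradient descent with backtracking line
search.  Predictors are standardised internally and coefficients returned
on the original scale; the penalty applies on the standardised scale so
that features of different units are penalised comparably.  A Breslow
cumulative baseline hazard fitted on the training data turns linear
predictors into absolute survival probabilities pi(x, t) =
exp(-H0(t) * exp(lp)).

With every group a singleton and m_g = 1, the group penalty coincides
with the lasso.  ``loss="squared_error"`` exposes the same penalties for
continuous outcomes (ordinary penalised least squares with an
unpenalised intercept).

The public surface follows the Model/Results convention:
``PenalizedCoxPH(X, time, event, ...).fit(lam)`` or ``.fit_cv(...)``
return a :class:`PenalizedCoxResults`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "GroupStructure",
    "PenalizedCoxPH",
    "PenalizedCoxResults",
    "build_grouped_design",
    "fit_penalized_cox",
    "cv_lambda",
]


# ---------------------------------------------------------------------------
# group structure
# ---------------------------------------------------------------------------

@dataclass
class GroupStructure:
    """Partition of the predictor indices into named groups.

    ``weights`` holds the per-group penalty multiplier m_g; by default
    m_g = sqrt(T_g) with T_g the group cardinality (``from_sizes``), the
    usual normalisation so large groups are not favoured.
    """

    groups: dict[str, list[int]]
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.weights:
            self.weights = {g: float(np.sqrt(len(idx))) for g, idx in self.groups.items()}
        for g, w in self.weights.items():
            if w <= 0:
                raise ValueError(f"group {g!r}: weight m_g must be > 0")
        if set(self.weights) != set(self.groups):
            raise ValueError("weights must cover exactly the groups")

    def validate_partition(self, p: int) -> None:
        seen: list[int] = []
        for idx in self.groups.values():
            seen.extend(idx)
        if sorted(seen) != list(range(p)):
            raise ValueError(
                "groups must partition the predictor indices 0..p-1 "
                "(no overlap, no gaps); overlapping pathways must be expanded "
                "into duplicated columns first (see build_grouped_design)"
            )

    @classmethod
    def singletons(cls, names: Sequence[str], weight: float = 1.0) -> "GroupStructure":
        return cls({n: [i] for i, n in enumerate(names)},
                   {n: weight for n in names})

    def with_weight_rule(self, rule: Literal["sqrt", "size", "one"]) -> "GroupStructure":
        fn = {"sqrt": lambda k: float(np.sqrt(k)),
              "size": float,
              "one": lambda k: 1.0}[rule]
        return GroupStructure(dict(self.groups),
                              {g: fn(len(idx)) for g, idx in self.groups.items()})


def build_grouped_design(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    weight_rule: Literal["sqrt", "size", "one"] = "sqrt",
) -> tuple[pd.DataFrame, GroupStructure]:
    """Expand pathway membership into a grouped design matrix.

    Pathways overlap, but the group penalty needs a partition of the
    predictor indices, so a gene belonging to k pathways contributes one
    column per pathway (column name ``pathway::gene``).  Returns the
    samples x columns design and the matching :class:`GroupStructure`.
    """
    expr_genes = set(expr.gene_ids)
    frame = expr.to_frame().T  # samples x genes
    cols: list[pd.Series] = []
    names: list[str] = []
    groups: dict[str, list[int]] = {}
    for pathway in sets.names:
        members = sorted(g for g in sets[pathway] if g in expr_genes)
        if not members:
            continue
        idx0 = len(names)
        for g in members:
            cols.append(frame[g])
            names.append(f"{pathway}::{g}")
        groups[pathway] = list(range(idx0, len(names)))
    if not groups:
        raise ValueError("no pathway has genes present in the expression matrix")
    design = pd.concat(cols, axis=1)
    design.columns = names
    gs = GroupStructure(groups).with_weight_rule(weight_rule)
    return design, gs


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties)
# ---------------------------------------------------------------------------

class _CoxLoss:
    """Averaged negative log partial likelihood and its gradient.

    Precomputes the time ordering and tie blocks once; evaluation is
    O(n log n) independent of p after the matrix products.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        self.n = len(time)
        order = np.argsort(time, kind="stable")
        self.order = order
        t = time[order]
        self.delta = event[order].astype(float)
        # block_start[i] = first index of i's tie block, block_end likewise
        new_block = np.empty(self.n, dtype=bool)
        new_block[0] = True
        new_block[1:] = t[1:] != t[:-1]
        block_id = np.cumsum(new_block) - 1
        starts = np.flatnonzero(new_block)
        ends = np.append(starts[1:], self.n) - 1
        self.block_start = starts[block_id]
        self.block_end = ends[block_id]
        self.inv_order = np.argsort(order)

    def value_grad(self, lp: np.ndarray) -> tuple[float, np.ndarray]:
        lp_s = lp[self.order]
        shift = lp_s.max()
        e = np.exp(lp_s - shift)
        suffix = np.cumsum(e[::-1])[::-1]
        risk = suffix[self.block_start]                 # sum over t_j >= t_i
        log_risk = np.log(risk) + shift
        nll = -(self.delta * (lp_s - log_risk)).sum() / self.n
        h = self.delta / risk
        cum_h = np.cumsum(h)
        a = cum_h[self.block_end]
        g_s = -(self.delta - e * a) / self.n
        return nll, g_s[self.inv_order]

    def value(self, lp: np.ndarray) -> float:
        lp_s = lp[self.order]
        shift = lp_s.max()
        e = np.exp(lp_s - shift)
        suffix = np.cumsum(e[::-1])[::-1]
        log_risk = np.log(suffix[self.block_start]) + shift
        return -(self.delta * (lp_s - log_risk)).sum() / self.n


class _SquaredLoss:
    """(1/2n) ||y_c - lp||^2 on a centred response (intercept handled
    outside the solver)."""

    def __init__(self, y: np.ndarray):
        self.y = y - y.mean()
        self.n = len(y)

    def value_grad(self, lp: np.ndarray) -> tuple[float, np.ndarray]:
        r = lp - self.y
        return 0.5 * (r @ r) / self.n, r / self.n

    def value(self, lp: np.ndarray) -> float:
        r = lp - self.y
        return 0.5 * (r @ r) / self.n


# ---------------------------------------------------------------------------
# proximal operators
# ---------------------------------------------------------------------------

def _prox_lasso(b: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(b) * np.maximum(np.abs(b) - thr, 0.0)


class _GroupProx:
    def __init__(self, gidx: np.ndarray, m: np.ndarray):
        self.gidx = gidx
        self.m = m
        self.n_groups = len(m)

    @classmethod
    def from_structure(cls, groups: GroupStructure, p: int) -> "_GroupProx":
        groups.validate_partition(p)
        gidx = np.empty(p, dtype=int)
        for k, idx in enumerate(groups.groups.values()):
            gidx[np.asarray(idx, dtype=int)] = k
        m = np.array([groups.weights[g] for g in groups.groups])
        return cls(gidx, m)

    def _norms(self, b: np.ndarray) -> np.ndarray:
        return np.sqrt(np.bincount(self.gidx, weights=b * b,
                                   minlength=self.n_groups))

    def __call__(self, b: np.ndarray, thr: float) -> np.ndarray:
        norm = self._norms(b)
        scale = np.zeros(self.n_groups)
        alive = norm > thr * self.m
        scale[alive] = 1.0 - thr * self.m[alive] / norm[alive]
        return b * scale[self.gidx]

    def penalty(self, b: np.ndarray) -> float:
        return float(self.m @ self._norms(b))

    def dual_norms(self, g: np.ndarray) -> np.ndarray:
        return self._norms(g) / self.m


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def _solve_prox(loss, X: np.ndarray, lam: float, prox, penalty_fn,
                beta0: np.ndarray | None, tol: float, max_iter: int):
    """Monotone FISTA with backtracking line search.

    The iterate sequence is forced non-increasing in the objective (the
    accelerated step is only accepted when it improves), so the monotone
    descent contract holds while keeping the accelerated rate.
    """
    p = X.shape[1]
    x = np.zeros(p) if beta0 is None else beta0.copy()
    x_prev = x.copy()
    y = x.copy()
    f_x, _ = loss.value_grad(X @ x)
    obj_x = f_x + lam * penalty_fn(x)
    t_mom = 1.0
    step = 1.0
    history = [obj_x]
    stalls = 0
    for it in range(max_iter):
        f_y, g_lp = loss.value_grad(X @ y)
        grad = X.T @ g_lp
        while True:
            z = prox(y - step * grad, step * lam)
            d = z - y
            f_z = loss.value(X @ z)
            if f_z <= f_y + grad @ d + (d @ d) / (2.0 * step) + 1e-12:
                break
            step *= 0.5
            if step < 1e-16:
                raise RuntimeError("backtracking line search failed (step underflow)")
        obj_z = f_z + lam * penalty_fn(z)
        if obj_z > obj_x + 1e-10 * max(1.0, abs(obj_x)):
            # momentum overshoot: restart from the best iterate (the prox
            # step from x itself descends by the backtracking condition);
            # a second consecutive stall means the objective is flat to
            # working precision — converged
            stalls += 1
            if stalls >= 2:
                return x, np.array(history), it + 1
            y = x.copy()
            t_mom = 1.0
            continue
        stalls = 0
        rel = (obj_x - obj_z) / max(1.0, abs(obj_x))
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
        y = z + ((t_mom - 1.0) / t_next) * (z - x)
        x_prev, x, obj_x, t_mom = x, z, obj_z, t_next
        history.append(obj_x)
        step *= 1.5  # let the step grow back between iterations
        if rel < tol:
            return x, np.array(history), it + 1
    _, g_lp = loss.value_grad(X @ x)
    gnorm = float(np.linalg.norm(X.T @ g_lp))
    raise RuntimeError(
        f"proximal gradient did not converge in {max_iter} iterations "
        f"(final gradient norm {gnorm:.3e})"
    )


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class PenalizedCoxPH:
    """Penalized Cox proportional-hazards model.

    Parameters
    ----------
    X : array or DataFrame, samples x predictors
        Predictor matrix (gene expression or pathway scores).  A DataFrame
        supplies feature names.
    time, event : arrays
        Observed follow-up (months) and event indicator, aligned to rows
        of ``X``.  A :class:`SurvivalTable` may be passed as ``time`` with
        ``event=None``.
    penalty : {"lasso", "group"}
    groups : GroupStructure, required for the group penalty
    loss : {"cox", "squared_error"}
        ``squared_error`` treats ``time`` as a continuous response and
        fits the penalised least-squares analogue (with intercept).
    standardize : bool
        Standardise predictors internally (coefficients are always
        reported on the original scale).
    """

    def __init__(self, X, time, event=None, *,
                 penalty: Literal["lasso", "group"] = "lasso",
                 groups: GroupStructure | None = None,
                 loss: Literal["cox", "squared_error"] = "cox",
                 standardize: bool = True,
                 feature_names: Sequence[str] | None = None):
        if isinstance(X, pd.DataFrame):
            feature_names = list(map(str, X.columns))
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x predictors)")
        if isinstance(time, SurvivalTable):
            event = time.event
            time = time.time
        time = np.asarray(time, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains missing/non-finite values; impute first")
        if loss == "cox":
            event = np.asarray(event)
            if event is None or len(event) != len(time):
                raise ValueError("event indicator required and aligned for Cox loss")
            if event.sum() < 1:
                raise ValueError("Cox fit needs at least one observed event")
        if len(time) != X.shape[0]:
            raise ValueError("X rows must align with the survival table")
        if penalty not in ("lasso", "group"):
            raise ValueError(f"unknown penalty {penalty!r}")
        if penalty == "group":
            if groups is None:
                raise ValueError("group penalty requires a GroupStructure")
            groups.validate_partition(X.shape[1])
        # canonical sample order (by time): makes the fit invariant to the
        # order samples arrive in — for tie-free times, bitwise so
        order = np.argsort(time, kind="stable")
        X = X[order]
        time = time[order]
        self.X = X
        self.time = time
        self.event = (None if event is None
                      else np.asarray(event, dtype=int)[order])
        self.penalty = penalty
        self.groups = groups
        self.loss_kind = loss
        self.feature_names = (list(feature_names) if feature_names is not None
                              else [f"x{i}" for i in range(X.shape[1])])
        self.standardize = standardize
        # squared-error always centres predictors so the intercept separates
        self._mu = (X.mean(axis=0) if standardize or loss == "squared_error"
                    else np.zeros(X.shape[1]))
        sd = X.std(axis=0) if standardize else np.ones(X.shape[1])
        sd[sd == 0] = 1.0
        self._sd = sd
        self._Xs = (X - self._mu) / self._sd
        if loss == "cox":
            self._loss = _CoxLoss(self.time, self.event)
        else:
            self._loss = _SquaredLoss(self.time)
        if penalty == "group":
            self._prox_obj = _GroupProx.from_structure(groups, X.shape[1])
            self._prox = self._prox_obj
            self._penalty_fn = self._prox_obj.penalty
        else:
            self._prox_obj = None
            self._prox = _prox_lasso
            self._penalty_fn = lambda b: float(np.abs(b).sum())

    # -- penalty path ------------------------------------------------------

    def lambda_max(self) -> float:
        """Smallest lambda whose solution is identically zero, from the
        stationarity condition at the null model."""
        _, g_lp = self._loss.value_grad(np.zeros(self.X.shape[0]))
        grad = self._Xs.T @ g_lp
        if self.penalty == "lasso":
            return float(np.max(np.abs(grad)))
        return float(np.max(self._prox_obj.dual_norms(grad)))

    def lambda_grid(self, n_lambda: int = 100, ratio: float = 0.01) -> np.ndarray:
        lmax = self.lambda_max()
        return np.geomspace(lmax, ratio * lmax, n_lambda)

    # -- path solver (internal) -------------------------------------------

    def _solve_path(self, grid: np.ndarray, tol: float = 1e-7,
                    max_iter: int = 100_000) -> np.ndarray:
        """Warm-started solutions along a decreasing lambda grid, with
        sequential strong-rule screening.

        Screening only restricts which columns enter the inner solver; the
        KKT conditions of every discarded feature/group are verified at
        the candidate solution and violators re-admitted, so the returned
        coefficients are the same solutions the full solver produces.
        Returns an array of standardised-scale coefficients, one row per
        lambda.
        """
        Xs, loss = self._Xs, self._loss
        p = Xs.shape[1]
        beta = np.zeros(p)
        betas = np.empty((len(grid), p))
        lam_prev: float | None = None
        is_group = self.penalty == "group"
        if is_group:
            gidx, m = self._prox_obj.gidx, self._prox_obj.m
            n_g = self._prox_obj.n_groups
        for k, lam in enumerate(grid):
            _, g_lp = loss.value_grad(Xs @ beta)
            grad = Xs.T @ g_lp
            thr = 2.0 * lam - (lam_prev if lam_prev is not None else lam)
            if is_group:
                gn = np.sqrt(np.bincount(gidx, weights=grad * grad, minlength=n_g))
                active_g = np.bincount(gidx, weights=beta * beta, minlength=n_g) > 0
                keep_g = (gn >= m * thr) | active_g
                keep = keep_g[gidx]
            else:
                keep = (np.abs(grad) >= thr) | (beta != 0)
            while True:
                cols = np.flatnonzero(keep)
                beta_new = np.zeros(p)
                if len(cols):
                    if is_group:
                        sub_labels, sub_gidx = np.unique(gidx[cols],
                                                         return_inverse=True)
                        sub_prox = _GroupProx(sub_gidx, m[sub_labels])
                        sub_pen = sub_prox.penalty
                    else:
                        sub_prox = _prox_lasso
                        sub_pen = lambda b: float(np.abs(b).sum())
                    sol, _, _ = _solve_prox(loss, Xs[:, cols], lam, sub_prox,
                                            sub_pen, beta[cols], tol, max_iter)
                    beta_new[cols] = sol
                _, g_lp = loss.value_grad(Xs @ beta_new)
                grad = Xs.T @ g_lp
                if is_group:
                    gn = np.sqrt(np.bincount(gidx, weights=grad * grad,
                                             minlength=n_g))
                    viol_g = ~keep_g & (gn > lam * m + 1e-9)
                    if not viol_g.any():
                        break
                    keep_g |= viol_g
                    keep = keep_g[gidx]
                else:
                    viol = ~keep & (np.abs(grad) > lam + 1e-9)
                    if not viol.any():
                        break
                    keep |= viol
            beta = beta_new
            betas[k] = beta
            lam_prev = float(lam)
        return betas

    # -- fitting -----------------------------------------------------------

    def fit(self, lam: float, *, beta0: np.ndarray | None = None,
            tol: float = 1e-7, max_iter: int = 100_000) -> "PenalizedCoxResults":
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        beta_std, history, n_iter = _solve_prox(
            self._loss, self._Xs, lam, self._prox, self._penalty_fn,
            beta0, tol, max_iter,
        )
        beta = beta_std / self._sd
        res = PenalizedCoxResults(
            params=pd.Series(beta, index=self.feature_names),
            lam=float(lam),
            penalty_kind=self.penalty,
            loss=self.loss_kind,
            group_structure=self.groups,
            standardization={"center": self._mu.tolist(), "scale": self._sd.tolist()},
            model=self,
            n_iter=n_iter,
            objective_path=history,
        )
        res._beta_std = beta_std
        if self.loss_kind == "cox":
            res._fit_breslow(self.X, self.time, self.event)
        else:
            lp = self.X @ beta
            res.intercept = float(self.time.mean() - lp.mean())
        return res

    def cv_lambda(self, *, n_folds: int = 10,
                  lambda_grid: np.ndarray | None = None,
                  n_lambda: int = 100, seed: int = 0,
                  tol: float = 1e-7) -> tuple[float, np.ndarray, np.ndarray]:
        """Choose lambda by n-fold cross-validated partial-likelihood
        deviance (Verweij & van Houwelingen construction).

        Folds are stratified by the event indicator.  Returns
        ``(best_lambda, grid, cv_deviance_curve)``; the chosen lambda
        minimises the summed cross-validated deviance.
        """
        if self.loss_kind != "cox":
            raise NotImplementedError("cv_lambda is defined for the Cox loss")
        if n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.event.sum() < n_folds:
            raise ValueError(
                f"{int(self.event.sum())} events cannot stratify into "
                f"{n_folds} folds with >=1 event each"
            )
        grid = (np.asarray(lambda_grid, dtype=float) if lambda_grid is not None
                else self.lambda_grid(n_lambda))
        rng = np.random.default_rng(seed)
        folds = _stratified_folds(self.event, n_folds, rng)
        n = self.X.shape[0]
        deviance = np.zeros_like(grid)
        full_loss = _CoxLoss(self.time, self.event)
        for k in range(n_folds):
            test = folds == k
            train = ~test
            sub = PenalizedCoxPH(
                self.X[train], self.time[train], self.event[train],
                penalty=self.penalty,
                groups=self.groups, loss="cox",
                standardize=self.standardize,
                feature_names=self.feature_names,
            )
            train_loss = sub._loss
            betas = sub._solve_path(grid, tol=tol)
            for i in range(len(grid)):
                # likelihoods must use identical covariate scaling; map the
                # fold-standardised coefficients back to the original scale
                beta_orig = betas[i] / sub._sd
                lp_all = (self.X - sub._mu) @ beta_orig
                nll_all = full_loss.value(lp_all) * n
                nll_train = train_loss.value(lp_all[train]) * train.sum()
                deviance[i] += 2.0 * (nll_all - nll_train)
        best = int(np.argmin(deviance))
        return float(grid[best]), grid, deviance

    def fit_cv(self, *, n_folds: int = 10, lambda_grid: np.ndarray | None = None,
               n_lambda: int = 100, seed: int = 0,
               tol: float = 1e-7) -> "PenalizedCoxResults":
        lam, grid, curve = self.cv_lambda(n_folds=n_folds, lambda_grid=lambda_grid,
                                          n_lambda=n_lambda, seed=seed, tol=tol)
        # warm start down the path for the final fit as well
        best = int(np.argmin(curve))
        betas = self._solve_path(grid[: best + 1], tol=tol)
        res = self.fit(lam, beta0=betas[best], tol=tol)
        res.cv_lambdas = grid
        res.cv_deviance = curve
        res.cv_seed = seed
        res.cv_folds = n_folds
        return res


def _stratified_folds(event: np.ndarray, n_folds: int, rng) -> np.ndarray:
    folds = np.empty(len(event), dtype=int)
    for flag in (1, 0):
        idx = np.flatnonzero(event == flag)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


class PenalizedCoxResults:
    """Fitted penalised Cox model: coefficients, penalty, baseline hazard,
    and prediction methods.  Serialisable to JSON and reconstructable
    without the training data."""

    def __init__(self, *, params: pd.Series, lam: float, penalty_kind: str,
                 loss: str, group_structure: GroupStructure | None,
                 standardization: dict, model: PenalizedCoxPH | None = None,
                 n_iter: int = 0, objective_path: np.ndarray | None = None):
        self.params = params
        self.lam = lam
        self.penalty_kind = penalty_kind
        self.loss = loss
        self.group_structure = group_structure
        self.standardization = standardization
        self.model = model
        self.n_iter = n_iter
        self.objective_path = objective_path
        self.baseline_times: np.ndarray | None = None
        self.baseline_cumhaz: np.ndarray | None = None
        self.intercept: float = 0.0
        self.feature_space: dict = {}
        self.cv_lambdas: np.ndarray | None = None
        self.cv_deviance: np.ndarray | None = None
        self.cv_seed: int | None = None
        self.cv_folds: int | None = None
        self._beta_std: np.ndarray | None = None

    # -- baseline ----------------------------------------------------------

    def _fit_breslow(self, X: np.ndarray, time: np.ndarray, event: np.ndarray) -> None:
        lp = X @ self.params.to_numpy()
        order = np.argsort(time, kind="stable")
        t, d, lp_s = time[order], event[order], lp[order]
        e = np.exp(lp_s - lp_s.max())
        scale = np.exp(lp_s.max())
        suffix = np.cumsum(e[::-1])[::-1] * scale
        etimes = []
        steps = []
        i = 0
        n = len(t)
        while i < n:
            j = i
            while j < n and t[j] == t[i]:
                j += 1
            dcount = d[i:j].sum()
            if dcount > 0:
                etimes.append(t[i])
                steps.append(dcount / suffix[i])
            i = j
        self.baseline_times = np.asarray(etimes)
        self.baseline_cumhaz = np.cumsum(steps)

    def cumulative_baseline_hazard(self, times) -> np.ndarray:
        """H0(t): right-continuous step function, 0 before the first
        training event; flat (with a warning) beyond the last."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if np.any(times < 0):
            raise ValueError("times must be >= 0")
        if self.baseline_times is None:
            raise ValueError("no Breslow baseline stored (squared-error fit?)")
        if len(self.baseline_times) and np.any(times > self.model_t_max()):
            warnings.warn(
                "extrapolating the baseline hazard flat beyond the last "
                "training event time; transporting a baseline hazard to a "
                "different population is an approximation", stacklevel=2)
        idx = np.searchsorted(self.baseline_times, times, side="right")
        h = np.concatenate([[0.0], self.baseline_cumhaz])
        return h[idx]

    def model_t_max(self) -> float:
        return float(self.baseline_times[-1]) if len(self.baseline_times) else 0.0

    # -- prediction --------------------------------------------------------

    def _align(self, X_new) -> np.ndarray:
        if isinstance(X_new, pd.DataFrame):
            missing = [f for f in self.params.index if f not in X_new.columns]
            if missing:
                raise KeyError(f"features absent from new data: {missing[:5]} "
                               f"({len(missing)} total)")
            X_new = X_new.loc[:, list(self.params.index)].to_numpy(dtype=float)
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        if X_new.shape[1] != len(self.params):
            raise ValueError(
                f"expected {len(self.params)} features, got {X_new.shape[1]}")
        return X_new

    def predict_risk(self, X_new) -> np.ndarray:
        """Linear predictor lp_i = sum_j beta_j x_ij (no baseline)."""
        return self._align(X_new) @ self.params.to_numpy()

    def predict_survival(self, X_new, times) -> np.ndarray:
        """pi(x, t) = exp(-H0(t) exp(lp)); samples x times."""
        lp = self.predict_risk(X_new)
        h0 = self.cumulative_baseline_hazard(times)
        return np.exp(-np.outer(np.exp(lp), h0))

    def predict(self, X_new) -> np.ndarray:
        if self.loss == "squared_error":
            return self.intercept + self.predict_risk(X_new)
        return self.predict_risk(X_new)

    # -- diagnostics -------------------------------------------------------

    def nonzero_groups(self) -> list[str]:
        if self.group_structure is None:
            return [f for f, b in self.params.items() if b != 0]
        beta = self.params.to_numpy()
        return [g for g, idx in self.group_structure.groups.items()
                if np.linalg.norm(beta[idx]) > 0]

    def kkt_violation(self) -> float:
        """Max violation of the stationarity conditions at the solution
        (standardised scale); ~0 at convergence.  For the lasso this is
        max(|grad_j| - lambda, 0) over zero coefficients."""
        if self.model is None:
            raise ValueError("KKT check needs the attached training model")
        m = self.model
        beta_std = self._beta_std
        _, g_lp = m._loss.value_grad(m._Xs @ beta_std)
        grad = m._Xs.T @ g_lp
        if self.penalty_kind == "lasso":
            zero = beta_std == 0
            v_zero = np.max(np.abs(grad[zero]) - self.lam, initial=0.0)
            v_act = np.max(np.abs(grad[~zero] + self.lam * np.sign(beta_std[~zero])),
                           initial=0.0)
            return float(max(v_zero, v_act))
        viol = 0.0
        for g, idx in self.group_structure.groups.items():
            m_g = self.group_structure.weights[g]
            b = beta_std[idx]
            if np.all(b == 0):
                viol = max(viol, float(np.linalg.norm(grad[idx]) - self.lam * m_g))
            else:
                viol = max(viol, float(np.linalg.norm(
                    grad[idx] + self.lam * m_g * b / np.linalg.norm(b))))
        return viol

    def summary(self) -> str:
        lines = [
            "Penalized Cox proportional hazards"
            if self.loss == "cox" else "Penalized least squares",
            f"  penalty: {self.penalty_kind}   lambda: {self.lam:.6g}",
            f"  predictors: {len(self.params)}   "
            f"non-zero: {int((self.params != 0).sum())}",
        ]
        if self.group_structure is not None:
            nz = self.nonzero_groups()
            lines.append(f"  groups: {len(self.group_structure.groups)}   "
                         f"non-zero groups: {len(nz)}")
        if self.cv_lambdas is not None:
            lines.append(f"  lambda chosen by {self.cv_folds}-fold CV "
                         f"(seed {self.cv_seed})")
        nz = self.params[self.params != 0]
        head = nz.reindex(nz.abs().sort_values(ascending=False).index).head(15)
        if len(head):
            lines.append("  largest coefficients:")
            for name, b in head.items():
                lines.append(f"    {name:<40s} {b:+.4f}")
        return "\n".join(lines)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "params": {str(k): float(v) for k, v in self.params.items()},
            "lambda": self.lam,
            "penalty_kind": self.penalty_kind,
            "loss": self.loss,
            "intercept": self.intercept,
            "standardization": self.standardization,
            "feature_space": self.feature_space,
            "baseline_times": (None if self.baseline_times is None
                               else self.baseline_times.tolist()),
            "baseline_cumhaz": (None if self.baseline_cumhaz is None
                                else self.baseline_cumhaz.tolist()),
            "groups": (None if self.group_structure is None else {
                "groups": {g: list(map(int, idx))
                           for g, idx in self.group_structure.groups.items()},
                "weights": {g: float(w)
                            for g, w in self.group_structure.weights.items()},
            }),
            "cv": (None if self.cv_lambdas is None else {
                "lambdas": self.cv_lambdas.tolist(),
                "deviance": self.cv_deviance.tolist(),
                "seed": self.cv_seed,
                "n_folds": self.cv_folds,
            }),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PenalizedCoxResults":
        gs = None
        if d.get("groups"):
            gs = GroupStructure({g: list(idx) for g, idx in d["groups"]["groups"].items()},
                                {g: float(w) for g, w in d["groups"]["weights"].items()})
        res = cls(
            params=pd.Series(d["params"], dtype=float),
            lam=float(d["lambda"]),
            penalty_kind=d["penalty_kind"],
            loss=d.get("loss", "cox"),
            group_structure=gs,
            standardization=d.get("standardization", {}),
        )
        res.intercept = float(d.get("intercept", 0.0))
        res.feature_space = d.get("feature_space", {})
        if d.get("baseline_times") is not None:
            res.baseline_times = np.asarray(d["baseline_times"], dtype=float)
            res.baseline_cumhaz = np.asarray(d["baseline_cumhaz"], dtype=float)
        if d.get("cv"):
            res.cv_lambdas = np.asarray(d["cv"]["lambdas"], dtype=float)
            res.cv_deviance = np.asarray(d["cv"]["deviance"], dtype=float)
            res.cv_seed = d["cv"]["seed"]
            res.cv_folds = d["cv"]["n_folds"]
        return res

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PenalizedCoxResults":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# functional wrappers (predictors x samples orientation)
# ---------------------------------------------------------------------------

def fit_penalized_cox(X, surv: SurvivalTable, penalty_kind: str, lam: float,
                      groups: GroupStructure | None = None,
                      **kw) -> PenalizedCoxResults:
    """Functional wrapper taking a predictors x samples matrix/DataFrame."""
    if isinstance(X, pd.DataFrame):
        X = X.T
    else:
        X = np.asarray(X, dtype=float).T
    model = PenalizedCoxPH(X, surv.time, surv.event, penalty=penalty_kind,
                           groups=groups)
    return model.fit(lam, **kw)


def cv_lambda(X, surv: SurvivalTable, penalty_kind: str = "lasso",
              groups: GroupStructure | None = None, n_folds: int = 10,
              lambda_grid=None, seed: int = 0):
    """Functional wrapper for lambda selection (predictors x samples input)."""
    if isinstance(X, pd.DataFrame):
        X = X.T
    else:
        X = np.asarray(X, dtype=float).T
    model = PenalizedCoxPH(X, surv.time, surv.event, penalty=penalty_kind,
                           groups=groups)
    return model.cv_lambda(n_folds=n_folds, lambda_grid=lambda_grid, seed=seed)
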