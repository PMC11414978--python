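"""End-to-end modelling harnesses.

Ties the pieces together: per-config feature construction (genes, pathway
scores, or grouped pathway designs), the repeated 70/30 internal
validation with corrected resampled t-tests, external validation of a
frozen model on a new cohort, reference-based location/scale alignment,
KNN missing-value imputation for new patients, the missing-value
robustness experiment and a structured model report.

Anything that uses background-sample statistics (z-score standardisation,
the GSVA kernel CDF, predictor standardisation) is fitted on the training
split only and replayed on held-out data; the stored training reference
travels with the fitted model so it can be applied to new cohorts.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .containers import ExpressionMatrix, GeneSetCollection, SurvivalTable
from .coxnet import (GroupStructure, PenalizedCoxPH, PenalizedCoxResults,
                     build_grouped_design)
from .metrics import (MetricResult, bootstrap_metric_ci, concordance_index,
                      corrected_resampled_ttest, integrated_brier_score)
from .scoring import restrict_to_universe, score_pathways
from .selection import select_distinct_pathways

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "FeatureConstructor",
    "PrognosticModel",
    "fit_prognostic_model",
    "internal_validation",
    "external_validation",
    "ValidationReport",
    "reference_align",
    "knn_impute_new_samples",
    "mask_random_genes",
    "missing_robustness_experiment",
    "model_report",
]

#: fraction of missing values beyond which imputation is discouraged
MISSING_ALLOWANCE = 0.05


# ---------------------------------------------------------------------------
# model configuration and feature construction
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Specification of one candidate model.

    ``feature_space``:
      * ``genes`` — lasso on individual genes;
      * ``pathway_scores`` — lasso on sample-wise pathway scores
        (``method`` one of ssgsea/gsva/zscore);
      * ``grouped_genes`` — group lasso on a pathway-expanded gene design.
    """

    name: str
    feature_space: Literal["genes", "pathway_scores", "grouped_genes"]
    sets: GeneSetCollection | None = None
    method: str | None = None
    scoring_params: dict = field(default_factory=dict)
    n_select: int = 100
    min_size: int = 5
    max_size: int = 500
    group_weight_rule: Literal["sqrt", "size", "one"] = "sqrt"

    def __post_init__(self) -> None:
        if self.feature_space in ("pathway_scores", "grouped_genes") and self.sets is None:
            raise ValueError(f"config {self.name!r}: a gene-set collection is required")
        if self.feature_space == "pathway_scores" and self.method not in (
            "ssgsea", "gsva", "zscore",
        ):
            raise ValueError(f"config {self.name!r}: unknown scoring method "
                             f"{self.method!r}")

    @property
    def penalty(self) -> str:
        return "group" if self.feature_space == "grouped_genes" else "lasso"


class FeatureConstructor:
    """Fits feature-construction statistics on a training cohort and
    replays them on any other cohort (no held-out statistics used)."""

    def __init__(self, config: ModelConfig, store_reference: bool = True):
        self.config = config
        self.store_reference = store_reference
        self.fitted = False
        self.genes_: list[str] | None = None
        self.sets_: GeneSetCollection | None = None
        self.reference_: ExpressionMatrix | None = None
        self.columns_: list[tuple[str, str]] | None = None
        self.groups_: GroupStructure | None = None

    # -- fitting -----------------------------------------------------------

    def fit(self, expr_train: ExpressionMatrix) -> "FeatureConstructor":
        cfg = self.config
        if np.any(np.isnan(expr_train.values)):
            raise ValueError("training expression must be complete")
        if cfg.feature_space == "genes":
            self.genes_ = sorted(expr_train.gene_ids)
        else:
            sets = restrict_to_universe(cfg.sets, expr_train.gene_ids,
                                        cfg.min_size, cfg.max_size)
            if cfg.feature_space == "grouped_genes":
                sets = select_distinct_pathways(sets, cfg.n_select)
                self.columns_ = [(p, g) for p in sets.names
                                 for g in sorted(sets[p])]
                groups: dict[str, list[int]] = {}
                for i, (p, _) in enumerate(self.columns_):
                    groups.setdefault(p, []).append(i)
                self.groups_ = GroupStructure(groups).with_weight_rule(
                    cfg.group_weight_rule)
            self.sets_ = sets
            self.genes_ = sorted(sets.universe() & set(expr_train.gene_ids))
            needs_background = (cfg.feature_space == "pathway_scores"
                                and cfg.method in ("zscore", "gsva"))
            if needs_background and self.store_reference:
                self.reference_ = expr_train.subset_genes(self.genes_)
        self.fitted = True
        return self

    # -- transform ---------------------------------------------------------

    def transform(self, expr: ExpressionMatrix) -> pd.DataFrame:
        """Samples x features design for any cohort, using only statistics
        stored at fit time."""
        if not self.fitted:
            raise RuntimeError("constructor not fitted")
        cfg = self.config
        sub = expr.subset_genes(self.genes_)
        if cfg.feature_space == "genes":
            return sub.to_frame().T
        if cfg.feature_space == "grouped_genes":
            frame = sub.to_frame().T
            cols = [frame[g] for _, g in self.columns_]
            design = pd.concat(cols, axis=1)
            design.columns = [f"{p}::{g}" for p, g in self.columns_]
            return design
        # pathway scores
        reference = self.reference_
        if cfg.method in ("zscore", "gsva") and reference is None \
                and sub.n_samples < (2 if cfg.method == "zscore" else 3):
            raise ValueError(
                f"{cfg.method} scores depend on background samples; scoring "
                f"{sub.n_samples} new sample(s) requires a stored training "
                "reference (fit with store_reference=True)")
        scores = score_pathways(sub, self.sets_, cfg.method,
                                reference=reference, **cfg.scoring_params)
        return scores.to_frame().T

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "config": {
                "name": self.config.name,
                "feature_space": self.config.feature_space,
                "method": self.config.method,
                "scoring_params": self.config.scoring_params,
                "n_select": self.config.n_select,
                "min_size": self.config.min_size,
                "max_size": self.config.max_size,
                "group_weight_rule": self.config.group_weight_rule,
            },
            "genes": self.genes_,
            "sets": (None if self.sets_ is None
                     else {n: sorted(self.sets_[n]) for n in self.sets_.names}),
            "columns": self.columns_,
            "reference": (None if self.reference_ is None else {
                "gene_ids": self.reference_.gene_ids,
                "sample_ids": self.reference_.sample_ids,
                "values": self.reference_.values.tolist(),
            }),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConstructor":
        cd = d["config"]
        sets = None
        if d["sets"] is not None:
            sets = GeneSetCollection({n: frozenset(g) for n, g in d["sets"].items()})
        cfg = ModelConfig(name=cd["name"], feature_space=cd["feature_space"],
                          sets=sets, method=cd["method"],
                          scoring_params=cd["scoring_params"],
                          n_select=cd["n_select"], min_size=cd["min_size"],
                          max_size=cd["max_size"],
                          group_weight_rule=cd["group_weight_rule"])
        self = cls(cfg)
        self.genes_ = d["genes"]
        self.sets_ = sets
        self.columns_ = ([tuple(c) for c in d["columns"]]
                         if d["columns"] is not None else None)
        if self.columns_ is not None:
            groups: dict[str, list[int]] = {}
            for i, (p, _) in enumerate(self.columns_):
                groups.setdefault(p, []).append(i)
            self.groups_ = GroupStructure(groups).with_weight_rule(
                cfg.group_weight_rule)
        if d["reference"] is not None:
            r = d["reference"]
            self.reference_ = ExpressionMatrix(r["gene_ids"], r["sample_ids"],
                                               np.asarray(r["values"]))
        self.fitted = True
        return self


# ---------------------------------------------------------------------------
# fitted end-to-end model
# ---------------------------------------------------------------------------

@dataclass
class PrognosticModel:
    """A frozen pipeline: feature constructor + fitted penalised Cox model
    + the training reference needed for alignment and imputation."""

    constructor: FeatureConstructor
    results: PenalizedCoxResults
    reference_expr: ExpressionMatrix | None = None

    @property
    def config(self) -> ModelConfig:
        return self.constructor.config

    def predict_risk(self, expr: ExpressionMatrix) -> np.ndarray:
        return self.results.predict_risk(self.constructor.transform(expr))

    def predict_survival(self, expr: ExpressionMatrix, times) -> np.ndarray:
        return self.results.predict_survival(self.constructor.transform(expr), times)

    def to_dict(self) -> dict:
        return {
            "constructor": self.constructor.to_dict(),
            "results": self.results.to_dict(),
            "reference_expr": (None if self.reference_expr is None else {
                "gene_ids": self.reference_expr.gene_ids,
                "sample_ids": self.reference_expr.sample_ids,
                "values": self.reference_expr.values.tolist(),
            }),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PrognosticModel":
        ref = None
        if d["reference_expr"] is not None:
            r = d["reference_expr"]
            ref = ExpressionMatrix(r["gene_ids"], r["sample_ids"],
                                   np.asarray(r["values"]))
        return cls(FeatureConstructor.from_dict(d["constructor"]),
                   PenalizedCoxResults.from_dict(d["results"]),
                   ref)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PrognosticModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_prognostic_model(expr: ExpressionMatrix, surv: SurvivalTable,
                         config: ModelConfig, *, seed: int = 0,
                         n_folds: int = 10, n_lambda: int = 100,
                         lam: float | None = None,
                         keep_reference: bool = True) -> PrognosticModel:
    """Fit one configured model on a full cohort (CV-tuned lambda unless
    ``lam`` is given)."""
    surv = surv.aligned_to(expr.sample_ids)
    ctor = FeatureConstructor(config).fit(expr)
    X = ctor.transform(expr)
    model = PenalizedCoxPH(X, surv.time, surv.event,
                           penalty=config.penalty, groups=ctor.groups_)
    if lam is None:
        res = model.fit_cv(n_folds=n_folds, n_lambda=n_lambda, seed=seed)
    else:
        res = model.fit(lam)
    res.feature_space = {"kind": config.feature_space, "method": config.method,
                         "config": config.name}
    return PrognosticModel(ctor, res,
                           expr.copy() if keep_reference else None)


# ---------------------------------------------------------------------------
# internal validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Per-repeat metric records, per-config summaries and the pairwise
    corrected-resampled-t-test matrices."""

    records: pd.DataFrame
    summaries: pd.DataFrame
    pairwise_p: dict[str, pd.DataFrame]
    n_train: int
    n_test: int
    n_repeats: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "records": self.records.to_dict(orient="list"),
            "summaries": self.summaries.to_dict(orient="list"),
            "pairwise_p": {m: df.to_dict(orient="split")
                           for m, df in self.pairwise_p.items()},
            "n_train": self.n_train, "n_test": self.n_test,
            "n_repeats": self.n_repeats, "seed": self.seed,
        }


def _stratified_split(event: np.ndarray, train_frac: float, rng):
    train_idx: list[int] = []
    for flag in (1, 0):
        idx = rng.permutation(np.flatnonzero(event == flag))
        n_tr = int(round(train_frac * len(idx)))
        train_idx.extend(idx[:n_tr])
    mask = np.zeros(len(event), dtype=bool)
    mask[train_idx] = True
    return mask


def internal_validation(expr: ExpressionMatrix, surv: SurvivalTable,
                        configs: Sequence[ModelConfig], *,
                        n_repeats: int = 100, train_frac: float = 0.7,
                        seed: int = 0, n_folds: int = 10,
                        n_lambda: int = 100,
                        metrics: Sequence[str] = ("cindex", "ibs"),
                        leak_validation_statistics: bool = False
                        ) -> ValidationReport:
    """Repeated random 70/30 internal validation.

    Each repeat splits the cohort (stratified by the event indicator),
    fits every config on the training split — including all
    background-dependent feature statistics and the CV choice of lambda —
    and measures the held-out split.  Model pairs are compared with the
    corrected resampled t-test using the n_test/n_train variance
    inflation.

    ``leak_validation_statistics`` is an audit hook: when True, held-out
    features are (incorrectly) built from held-out-split statistics, which
    must change the results; it exists so the no-leakage property can be
    demonstrated and is never appropriate for real evaluation.
    """
    surv = surv.aligned_to(expr.sample_ids)
    names = [c.name for c in configs]
    if len(set(names)) != len(names):
        raise ValueError("config names must be unique")
    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s.generate_state(1)[0] % 2_147_483_647)
                    for s in ss.spawn(n_repeats)]
    rows = []
    for r in range(n_repeats):
        rng = np.random.default_rng(repeat_seeds[r])
        train_mask = _stratified_split(surv.event, train_frac, rng)
        tr_ids = [s for s, m in zip(expr.sample_ids, train_mask) if m]
        va_ids = [s for s, m in zip(expr.sample_ids, train_mask) if not m]
        expr_tr, expr_va = expr.subset_samples(tr_ids), expr.subset_samples(va_ids)
        surv_tr, surv_va = surv.subset(tr_ids), surv.subset(va_ids)
        for cfg in configs:
            ctor = FeatureConstructor(cfg).fit(expr_tr)
            X_tr = ctor.transform(expr_tr)
            if leak_validation_statistics:
                X_va = FeatureConstructor(cfg).fit(expr_va).transform(expr_va)
            else:
                X_va = ctor.transform(expr_va)
            model = PenalizedCoxPH(X_tr, surv_tr.time, surv_tr.event,
                                   penalty=cfg.penalty, groups=ctor.groups_)
            res = model.fit_cv(n_folds=n_folds, n_lambda=n_lambda,
                               seed=repeat_seeds[r])
            rec = {"repeat": r, "seed": repeat_seeds[r], "config": cfg.name,
                   "lambda": res.lam}
            risk = res.predict_risk(X_va)
            if "cindex" in metrics:
                rec["cindex"] = concordance_index(risk, surv_va).estimate
            if "ibs" in metrics:
                X_va_arr = X_va.to_numpy(dtype=float)
                ev = surv_va.time[surv_va.event == 1]
                # integrate only where the training baseline hazard is defined
                t_max = min(float(ev.max()), res.model_t_max())
                rec["ibs"] = integrated_brier_score(
                    lambda ts: res.predict_survival(X_va_arr, ts), surv_va,
                    t_max=t_max)
            rows.append(rec)
    records = pd.DataFrame(rows)
    metric_cols = [m for m in ("cindex", "ibs") if m in records.columns]
    summaries = (records.groupby("config", sort=False)[metric_cols]
                 .agg(["mean", "sem"]))
    summaries.columns = [f"{m}_{s}" for m, s in summaries.columns]
    summaries = summaries.reset_index()
    n_test = int((~_stratified_split(surv.event, train_frac,
                                     np.random.default_rng(0))).sum())
    n_train = surv.n - n_test
    pairwise: dict[str, pd.DataFrame] = {}
    for m in metric_cols:
        mat = pd.DataFrame(np.ones((len(names), len(names))),
                           index=names, columns=names)
        wide = records.pivot(index="repeat", columns="config", values=m)
        for a in names:
            for b in names:
                if a == b:
                    continue
                _, p = corrected_resampled_ttest(
                    (wide[a] - wide[b]).to_numpy(), n_train, n_test)
                mat.loc[a, b] = p
        pairwise[m] = mat
    return ValidationReport(records, summaries, pairwise,
                            n_train, n_test, n_repeats, seed)


# ---------------------------------------------------------------------------
# external validation
# ---------------------------------------------------------------------------

def external_validation(model: PrognosticModel, expr_new: ExpressionMatrix,
                        surv_new: SurvivalTable, *, align: bool = False,
                        metrics: Sequence[str] = ("cindex", "ibs"),
                        n_boot: int = 1000, level: float = 0.95,
                        seed: int = 0) -> dict[str, MetricResult]:
    """Evaluate a frozen model on an external cohort.

    Feature construction is replayed with the stored training statistics;
    ``align=True`` first rescales the new cohort per gene to the training
    reference's location and scale.  C-index and IBS are reported with
    percentile bootstrap confidence intervals.
    """
    surv_new = surv_new.aligned_to(expr_new.sample_ids)
    needed = set(model.constructor.genes_ or [])
    missing = sorted(needed - set(expr_new.gene_ids))
    if missing:
        raise KeyError(f"external cohort lacks {len(missing)} model genes, "
                       f"e.g. {missing[:5]}")
    if align:
        if model.reference_expr is None:
            raise ValueError("alignment requested but the model stores no "
                             "training reference")
        ref = model.reference_expr.subset_genes(
            sorted(needed & set(model.reference_expr.gene_ids)))
        expr_new = reference_align(expr_new.subset_genes(ref.gene_ids), ref)
    X = model.constructor.transform(expr_new)
    risk = model.results.predict_risk(X)
    out: dict[str, MetricResult] = {}
    if "cindex" in metrics:
        out["cindex"] = bootstrap_metric_ci(
            lambda r, s: concordance_index(r, s).estimate,
            risk, surv_new, B=n_boot, level=level, seed=seed, name="cindex")
    if "ibs" in metrics:
        warnings.warn(
            "IBS on an external cohort assumes the training baseline hazard "
            "transports to the new population; interpret with caution",
            stacklevel=2)
        X_arr = X.to_numpy(dtype=float)

        def _ibs(pred_rows, s):
            ev = s.time[s.event == 1]
            if len(ev) == 0:
                raise ValueError("no events in resample")
            t_max = min(float(ev.max()), model.results.model_t_max())
            return integrated_brier_score(
                lambda ts: model.results.predict_survival(pred_rows, ts), s,
                t_max=t_max)

        out["ibs"] = bootstrap_metric_ci(_ibs, X_arr, surv_new, B=n_boot,
                                         level=level, seed=seed, name="ibs")
    return out


def reference_align(expr_new: ExpressionMatrix,
                    reference: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene location/scale alignment of a new batch to a reference.

    Each gene in the new batch is rescaled to the reference gene's mean
    and standard deviation; genes with zero variance in the new batch are
    shifted to the reference mean only.
    """
    if expr_new.n_samples < 2:
        raise ValueError("alignment needs >=2 new samples (a batch, not a "
                         "single patient)")
    missing = sorted(set(reference.gene_ids) - set(expr_new.gene_ids))
    if missing:
        raise KeyError(f"new batch lacks reference genes, e.g. {missing[:5]}")
    sub = expr_new.subset_genes(reference.gene_ids)
    x = sub.values
    mu_new, sd_new = x.mean(axis=1), x.std(axis=1, ddof=1)
    mu_ref, sd_ref = (reference.values.mean(axis=1),
                      reference.values.std(axis=1, ddof=1))
    out = np.empty_like(x)
    nz = sd_new > 0
    out[nz] = ((x[nz] - mu_new[nz, None]) / sd_new[nz, None]
               * sd_ref[nz, None] + mu_ref[nz, None])
    out[~nz] = x[~nz] - mu_new[~nz, None] + mu_ref[~nz, None]
    return ExpressionMatrix(list(sub.gene_ids), list(sub.sample_ids), out,
                            allow_missing=sub.allow_missing)


# ---------------------------------------------------------------------------
# KNN imputation and the robustness experiment
# ---------------------------------------------------------------------------

class _GeneNeighbourIndex:
    """Lazily computed gene-gene Euclidean distances on a reference
    cohort, with cached sorted neighbour lists per query gene."""

    def __init__(self, reference: ExpressionMatrix):
        if np.any(np.isnan(reference.values)):
            raise ValueError("imputation reference must be complete")
        self.ref = reference
        self.pos = {g: i for i, g in enumerate(reference.gene_ids)}
        self._cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def neighbours(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        if gene in self._cache:
            return self._cache[gene]
        i = self.pos[gene]
        diff = self.ref.values - self.ref.values[i][None, :]
        d = np.sqrt((diff * diff).sum(axis=1))
        d[i] = np.inf  # never its own neighbour
        order = np.argsort(d, kind="stable")
        self._cache[gene] = (order, d[order])
        return self._cache[gene]


def knn_impute_new_samples(expr_new: ExpressionMatrix,
                           reference: ExpressionMatrix, K: int = 10,
                           eps: float = 1e-6,
                           index: "_GeneNeighbourIndex | None" = None
                           ) -> ExpressionMatrix:
    """Impute missing genes of new samples from their nearest reference
    neighbours.

    Gene-gene Euclidean distances are computed on the (complete) reference
    matrix.  A missing gene m in a sample is imputed as the
    inverse-distance-weighted average ``sum w_g y_g / sum w_g`` with
    ``w_g = 1/(d(m,g) + eps)`` over the K nearest neighbour genes that are
    observed in that sample (all observed genes if fewer than K exist).
    A warning is issued when a sample is missing more than 5% of its
    genes, the allowance beyond which imputed predictions become
    unreliable.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    missing_mask = expr_new.missing_mask
    if not missing_mask.any():
        return expr_new.copy()
    absent = sorted({g for g, row in zip(expr_new.gene_ids, missing_mask)
                     if row.any()} - set(reference.gene_ids))
    if absent:
        raise KeyError(f"missing genes absent from the reference, "
                       f"e.g. {absent[:5]}")
    idx = index if index is not None else _GeneNeighbourIndex(reference)
    values = expr_new.values.copy()
    gene_row = {g: i for i, g in enumerate(expr_new.gene_ids)}
    frac = missing_mask.mean(axis=0)
    for j, sample in enumerate(expr_new.sample_ids):
        col_missing = np.flatnonzero(missing_mask[:, j])
        if len(col_missing) == 0:
            continue
        if len(col_missing) == expr_new.n_genes:
            raise ValueError(f"sample {sample!r} has no observed genes")
        if frac[j] > MISSING_ALLOWANCE:
            warnings.warn(
                f"sample {sample!r}: {frac[j]:.1%} of genes missing exceeds "
                f"the {MISSING_ALLOWANCE:.0%} allowance", stacklevel=2)
        observed = ~missing_mask[:, j]
        for gi in col_missing:
            order, dists = idx.neighbours(expr_new.gene_ids[gi])
            got_v, got_w = [], []
            for o, d in zip(order, dists):
                row = gene_row.get(idx.ref.gene_ids[o])
                if row is None or not observed[row]:
                    continue
                got_v.append(values[row, j])
                got_w.append(1.0 / (d + eps))
                if len(got_v) == K:
                    break
            values[gi, j] = float(np.dot(got_w, got_v) / np.sum(got_w))
    return ExpressionMatrix(list(expr_new.gene_ids), list(expr_new.sample_ids),
                            values, allow_missing=False)


def mask_random_genes(expr: ExpressionMatrix, fraction: float, seed: int = 0,
                      shared_mask: bool = False
                      ) -> tuple[ExpressionMatrix, np.ndarray]:
    """Mask ``floor(fraction * n_genes)`` genes as missing.

    By default a fresh gene draw is made per sample; ``shared_mask=True``
    masks the same genes in every sample.  Returns the masked matrix and
    the boolean mask for audit.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_mask = int(fraction * expr.n_genes)
    mask = np.zeros(expr.values.shape, dtype=bool)
    if n_mask:
        if shared_mask:
            rows = rng.choice(expr.n_genes, size=n_mask, replace=False)
            mask[rows, :] = True
        else:
            for j in range(expr.n_samples):
                rows = rng.choice(expr.n_genes, size=n_mask, replace=False)
                mask[rows, j] = True
    values = expr.values.copy()
    values[mask] = np.nan
    return (ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids),
                             values, allow_missing=True), mask)


def missing_robustness_experiment(model: PrognosticModel,
                                  expr_test: ExpressionMatrix,
                                  surv_test: SurvivalTable,
                                  fractions: Sequence[float] =
                                  (0.01, 0.02, 0.05, 0.10, 0.20, 0.30),
                                  n_reps: int = 20, seed: int = 0,
                                  K: int = 10,
                                  shared_mask: bool = False) -> pd.DataFrame:
    """Mask -> impute -> predict -> C-index, per missing fraction.

    The returned frame has one row per (fraction, rep) plus the
    no-missing baseline at fraction 0.0 (rep -1).
    """
    if model.reference_expr is None:
        raise ValueError("model stores no reference cohort for imputation")
    surv_test = surv_test.aligned_to(expr_test.sample_ids)
    reference = model.reference_expr.subset_genes(
        [g for g in expr_test.gene_ids
         if g in set(model.reference_expr.gene_ids)])
    index = _GeneNeighbourIndex(reference)
    baseline = concordance_index(model.predict_risk(expr_test),
                                 surv_test).estimate
    rows = [{"fraction": 0.0, "rep": -1, "cindex": baseline}]
    ss = np.random.SeedSequence(seed)
    sub_seeds = iter(int(s.generate_state(1)[0] % 2_147_483_647)
                     for s in ss.spawn(len(fractions) * n_reps))
    for frac in fractions:
        for rep in range(n_reps):
            s = next(sub_seeds)
            if frac == 0.0:
                rows.append({"fraction": 0.0, "rep": rep, "cindex": baseline})
                continue
            masked, _ = mask_random_genes(expr_test, frac, seed=s,
                                          shared_mask=shared_mask)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                imputed = knn_impute_new_samples(masked, reference, K=K,
                                                 index=index)
            c = concordance_index(model.predict_risk(imputed),
                                  surv_test).estimate
            rows.append({"fraction": frac, "rep": rep, "cindex": c})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model report
# ---------------------------------------------------------------------------

def model_report(model: PrognosticModel,
                 validation: dict | None = None,
                 provenance: dict | None = None) -> dict:
    """Structured (JSON-serialisable) report of a fitted model: feature
    space, selected pathways/genes with coefficients, penalty and CV
    curve, evaluation metrics, missing-data policy and software versions."""
    import scipy

    res = model.results
    nz = res.params[res.params != 0]
    report = {
        "title": f"Prognostic survival model [{model.config.name}]",
        "data_provenance": provenance or {},
        "feature_space": {
            "kind": model.config.feature_space,
            "scoring_method": model.config.method,
            "scoring_params": model.config.scoring_params,
            "n_features": int(len(res.params)),
        },
        "model": {
            "penalty": res.penalty_kind,
            "lambda": res.lam,
            "n_selected_features": int(len(nz)),
            "selected": {str(k): float(v) for k, v in nz.items()},
            "selected_pathways": res.nonzero_groups()
            if res.group_structure is not None else None,
            "cv": (None if res.cv_lambdas is None else {
                "lambdas": res.cv_lambdas.tolist(),
                "deviance": res.cv_deviance.tolist(),
                "seed": res.cv_seed, "n_folds": res.cv_folds,
            }),
        },
        "validation": validation or {},
        "missing_data_policy": (
            f"KNN imputation (gene neighbours, K=10) is provided; at most "
            f"{MISSING_ALLOWANCE:.0%} missing values should be imputed"),
        "software": {
            "pathsurv": _pkg_version,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    return report
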