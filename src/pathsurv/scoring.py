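"""Sample-wise pathway scoring: ssGSEA, GSVA and z-score.

Each scorer converts a gene-level :class:`ExpressionMatrix` into a
pathways x samples :class:`PathwayScoreMatrix`.  ssGSEA is computed per
sample from gene ranks alone and needs no background cohort; z-score and
GSVA standardise against the sample distribution and therefore accept a
``reference`` matrix so that new samples can be scored against a stored
training cohort without leakage.

Rank ties are always broken by lexicographic gene id, so scores are
deterministic across runs and platforms.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
from scipy.special import ndtr

from .containers import ExpressionMatrix, GeneSetCollection, PathwayScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "restrict_to_universe",
    "zscore_scores",
    "ssgsea_scores",
    "gsva_scores",
    "score_pathways",
]


def restrict_to_universe(
    sets: GeneSetCollection,
    genes: list[str],
    min_size: int = 5,
    max_size: int = 500,
) -> GeneSetCollection:
    """Intersect every set with the measured gene universe and drop sets
    whose post-intersection size falls outside ``[min_size, max_size]``."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    universe = set(genes)
    out: dict[str, frozenset[str]] = {}
    dropped = 0
    for name in sets.names:
        inter = sets[name] & universe
        if min_size <= len(inter) <= max_size:
            out[name] = frozenset(inter)
        else:
            dropped += 1
    if dropped:
        logger.info("restrict_to_universe: dropped %d/%d sets outside [%d, %d]",
                    dropped, len(sets), min_size, max_size)
    if not out:
        raise ValueError("all gene sets dropped after universe restriction")
    return GeneSetCollection(out, sets.source_name)


def _require_complete(expr: ExpressionMatrix, method: str) -> None:
    if np.any(np.isnan(expr.values)):
        raise ValueError(f"{method} requires a complete matrix; impute missing "
                         "values first")


def _member_indices(sets: GeneSetCollection, gene_ids: list[str]) -> dict[str, np.ndarray]:
    pos = {g: i for i, g in enumerate(gene_ids)}
    out = {}
    for name in sets.names:
        idx = np.array(sorted(pos[g] for g in sets[name] if g in pos), dtype=int)
        out[name] = idx
    return out


# ---------------------------------------------------------------------------
# z-score
# ---------------------------------------------------------------------------

def zscore_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    denominator: Literal["sqrt", "count"] = "sqrt",
    reference: ExpressionMatrix | None = None,
) -> PathwayScoreMatrix:
    """Combined z-score pathway activity.

    Every gene is standardised over samples (mean 0, sd 1, ddof=1); the
    score of sample i for set J is ``sum_{j in J} z_ij / D`` with
    ``D = sqrt(|J|)`` (default) or ``|J|``.  When ``reference`` is given,
    the per-gene mean/sd come from the reference cohort instead of
    ``expr`` itself (scoring new samples against a stored background).
    """
    _require_complete(expr, "zscore")
    if denominator not in ("sqrt", "count"):
        raise ValueError(f"unknown denominator {denominator!r}")
    background = reference if reference is not None else expr
    if background.n_samples < 2:
        raise ValueError("z-score needs >=2 background samples to standardise")
    if reference is not None:
        expr = expr.subset_genes(reference.gene_ids)
    mu = background.values.mean(axis=1)
    sd = background.values.std(axis=1, ddof=1)
    ok = sd > 0
    if not ok.all():
        logger.warning("zscore: %d zero-variance genes dropped from all sets",
                       int((~ok).sum()))
    z = np.zeros_like(expr.values)
    z[ok] = (expr.values[ok] - mu[ok, None]) / sd[ok, None]
    usable = [g for g, keep in zip(expr.gene_ids, ok) if keep]
    members = _member_indices(sets, expr.gene_ids)
    usable_set = set(usable)
    scores = np.empty((len(sets), expr.n_samples))
    for r, name in enumerate(sets.names):
        genes = [g for g in sets[name] if g in usable_set]
        if not genes:
            raise ValueError(f"gene set {name!r}: all member genes have zero variance")
        idx = members[name]
        idx = idx[ok[idx]]
        total = z[idx].sum(axis=0)
        d = np.sqrt(len(idx)) if denominator == "sqrt" else float(len(idx))
        scores[r] = total / d
    return PathwayScoreMatrix(
        sets.names, list(expr.sample_ids), scores, "zscore",
        {"denominator": denominator, "ddof": 1,
         "reference": "external" if reference is not None else "self"},
    )


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def _rank_descending(column: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Positions (0-based) of genes ordered by expression descending,
    ties broken by ascending gene id."""
    # lexsort: last key is primary
    return np.lexsort((gene_ids, -column))


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> PathwayScoreMatrix:
    """Single-sample GSEA enrichment scores.

    Per sample, genes are ranked by expression (descending) and assigned
    rank scores ``s_g = N - position + 1``.  Walking down the ranked list,
    ``ES(J) = sum_i [P_in(i) - P_out(i)]`` where P_in accumulates
    ``s_g**alpha`` over in-set genes and P_out accumulates the uniform
    out-of-set step.  Only ranks matter, so any per-sample strictly
    monotone transform of expression leaves the scores unchanged.

    With ``normalize=True`` the whole score matrix is divided by its range
    (max - min), the customary normalisation.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    _require_complete(expr, "ssGSEA")
    n_genes = expr.n_genes
    gene_arr = np.array(expr.gene_ids)
    members = _member_indices(sets, expr.gene_ids)
    for name, idx in members.items():
        if len(idx) == 0:
            raise ValueError(f"gene set {name!r} has no genes in the matrix")
        if len(idx) >= n_genes:
            raise ValueError(f"gene set {name!r} covers the whole gene universe; "
                             "the out-of-set walk is undefined")
    in_set = np.zeros((len(sets), n_genes), dtype=bool)
    for r, name in enumerate(sets.names):
        in_set[r, members[name]] = True
    sizes = in_set.sum(axis=1)

    scores = np.empty((len(sets), expr.n_samples))
    rank_weight = (np.arange(n_genes, 0, -1, dtype=float)) ** alpha  # s^alpha by position
    for j in range(expr.n_samples):
        order = _rank_descending(expr.values[:, j], gene_arr)
        in_ordered = in_set[:, order]                       # sets x positions
        w = np.where(in_ordered, rank_weight[None, :], 0.0)
        p_in = np.cumsum(w, axis=1) / w.sum(axis=1, keepdims=True)
        p_out = np.cumsum(~in_ordered, axis=1) / (n_genes - sizes)[:, None]
        scores[:, j] = (p_in - p_out).sum(axis=1)
    if normalize:
        rng = scores.max() - scores.min()
        if rng > 0:
            scores = scores / rng
    return PathwayScoreMatrix(
        sets.names, list(expr.sample_ids), scores, "ssgsea",
        {"alpha": alpha, "normalize": normalize},
    )


# ---------------------------------------------------------------------------
# GSVA
# ---------------------------------------------------------------------------

def _gsva_kcdf(values: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Gaussian-kernel CDF estimate of each entry against the background
    sample distribution of its gene; bandwidth h_g = sd_g / 4."""
    n_genes, _ = values.shape
    sd = background.std(axis=1, ddof=1)
    out = np.empty_like(values)
    for g in range(n_genes):
        if sd[g] == 0:
            out[g] = 0.5
            continue
        h = sd[g] / 4.0
        diff = (values[g][:, None] - background[g][None, :]) / h
        out[g] = ndtr(diff).mean(axis=1)
    return out


def gsva_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    tau: float = 1.0,
    es_mode: Literal["max_diff", "max_abs"] = "max_diff",
    reference: ExpressionMatrix | None = None,
) -> PathwayScoreMatrix:
    """Gene Set Variation Analysis enrichment scores.

    Three steps per the method's construction: (1) a Gaussian-kernel CDF
    estimate of each expression value against the cohort distribution of
    its gene (bandwidth sd/4; zero-variance genes pinned at 0.5);
    (2) per-sample ranking of the CDF values into the symmetrised rank
    statistic ``r_g = |N/2 - rho_g|``; (3) a Kolmogorov–Smirnov-like walk
    with in-set steps proportional to ``r_g**tau`` and uniform out-of-set
    steps.  ``max_diff`` returns (largest positive deviation) + (largest
    negative deviation); ``max_abs`` the signed extreme deviation.
    Scores lie in (-1, 1).
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if es_mode not in ("max_diff", "max_abs"):
        raise ValueError(f"unknown es_mode {es_mode!r}")
    _require_complete(expr, "GSVA")
    background = reference if reference is not None else expr
    if background.n_samples < 3:
        raise ValueError("GSVA needs >=3 background samples for the kernel CDF")
    if reference is not None:
        expr = expr.subset_genes(reference.gene_ids)
    n_genes = expr.n_genes
    gene_arr = np.array(expr.gene_ids)
    members = _member_indices(sets, expr.gene_ids)
    for name, idx in members.items():
        if len(idx) == 0:
            raise ValueError(f"gene set {name!r} has no genes in the matrix")
        if len(idx) >= n_genes:
            raise ValueError(f"gene set {name!r} covers the whole gene universe")
    kcdf = _gsva_kcdf(expr.values, background.values)

    in_set = np.zeros((len(sets), n_genes), dtype=bool)
    for r, name in enumerate(sets.names):
        in_set[r, members[name]] = True
    sizes = in_set.sum(axis=1)

    scores = np.empty((len(sets), expr.n_samples))
    for j in range(expr.n_samples):
        order = _rank_descending(kcdf[:, j], gene_arr)
        rho = np.empty(n_genes)
        rho[order] = np.arange(1, n_genes + 1)             # 1-based rank by kcdf desc
        r_stat = np.abs(n_genes / 2.0 - rho) ** tau
        in_ordered = in_set[:, order]                      # sets x positions
        w = np.where(in_ordered, r_stat[order][None, :], 0.0)
        v = (np.cumsum(w, axis=1) / w.sum(axis=1, keepdims=True)
             - np.cumsum(~in_ordered, axis=1) / (n_genes - sizes)[:, None])
        if es_mode == "max_diff":
            scores[:, j] = np.maximum(v, 0).max(axis=1) + np.minimum(v, 0).min(axis=1)
        else:
            pick = np.abs(v).argmax(axis=1)
            scores[:, j] = v[np.arange(v.shape[0]), pick]
    return PathwayScoreMatrix(
        sets.names, list(expr.sample_ids), scores, "gsva",
        {"tau": tau, "es_mode": es_mode, "bandwidth": "sd/4",
         "reference": "external" if reference is not None else "self"},
    )


def score_pathways(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    method: str,
    reference: ExpressionMatrix | None = None,
    **params,
) -> PathwayScoreMatrix:
    """Dispatch to one of the three scorers by name."""
    if method == "zscore":
        return zscore_scores(expr, sets, reference=reference, **params)
    if method == "ssgsea":
        if reference is not None:
            pass  # rank-based; a background cohort is irrelevant
        return ssgsea_scores(expr, sets, **params)
    if method == "gsva":
        return gsva_scores(expr, sets, reference=reference, **params)
    raise ValueError(f"unknown scoring method {method!r}")
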