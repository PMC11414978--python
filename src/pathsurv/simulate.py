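"""Synthetic pathway-structured expression/survival cohorts.

The generator emulates a log2-microarray cohort in which latent pathway
activities drive both gene expression and a proportional-hazards survival
outcome:

* gene sets of varying size with controllable overlap between sets;
* per-sample latent activity A_p ~ N(0, 1) per pathway;
* expression x_gj = mu_g + sum_p lambda_gp A_pj + eps, mu_g ~ N(8, 2)
  (log2-intensity-like), eps ~ N(0, noise_sd);
* event times Weibull with shape rho = 1.5 and the scale set so the
  median survival at lp = 0 is ~90 months, under the Cox linear predictor
  lp_j = sum_{p active} gamma_p A_pj;
* independent uniform censoring whose upper bound is calibrated by
  bisection so the realised event rate lands within +/-3 percentage
  points of the target (0.44 by default, a typical myeloma-cohort rate).

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import ExpressionMatrix, GeneSetCollection, SurvivalTable
from .io import write_expression_table, write_gmt, write_survival_table

__all__ = [
    "SyntheticTruth",
    "simulate_gene_sets",
    "simulate_cohort",
    "write_fixture_bundle",
    "PRESETS",
]

#: Weibull shape for the baseline event-time distribution
WEIBULL_SHAPE = 1.5
#: target median survival (months) at lp = 0
MEDIAN_SURVIVAL_MONTHS = 90.0


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort."""

    active_pathways: dict[str, float]            # name -> effect size gamma_p
    loadings: dict[str, float]                   # pathway -> loading strength
    baseline_shape: float
    baseline_scale: float                        # kappa of h0(t) = kappa*rho*t^(rho-1)
    target_event_rate: float
    realized_event_rate: float
    censor_upper: float
    seed: int
    params: dict = field(default_factory=dict)
    linear_predictor: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def simulate_gene_sets(n_genes: int, n_pathways: int,
                       size_range: tuple[int, int] = (10, 40),
                       overlap_frac: float = 0.25,
                       seed: int = 0) -> GeneSetCollection:
    """Draw overlapping gene sets over a universe of ``n_genes`` genes.

    Each set's size is uniform in ``size_range``; a fraction
    ``overlap_frac`` of its members is drawn from genes already used by
    earlier sets (creating the overlap that motivates distinct-pathway
    selection), the rest from unused genes while any remain.
    """
    lo, hi = size_range
    if not (2 <= lo <= hi <= n_genes):
        raise ValueError(f"size_range {size_range} infeasible for {n_genes} genes")
    if not 0.0 <= overlap_frac <= 1.0:
        raise ValueError("overlap_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    unused = list(range(n_genes))
    used: list[int] = []
    sets: dict[str, frozenset[str]] = {}
    for p in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        n_old = min(int(round(overlap_frac * size)), len(used)) if used else 0
        n_new = min(size - n_old, len(unused))
        chosen: list[int] = []
        if n_old:
            chosen.extend(rng.choice(len(used), size=n_old, replace=False))
            chosen = [used[i] for i in chosen]
        if n_new:
            pick = rng.choice(len(unused), size=n_new, replace=False)
            newly = [unused[i] for i in pick]
            chosen.extend(newly)
            for g in newly:
                used.append(g)
            unused = [g for g in unused if g not in set(newly)]
        elif len(chosen) < size and used:
            # universe exhausted: top up from used genes
            extra = [g for g in used if g not in set(chosen)]
            need = min(size - len(chosen), len(extra))
            pick = rng.choice(len(extra), size=need, replace=False)
            chosen.extend(extra[i] for i in pick)
        sets[f"PW{p:03d}"] = frozenset(genes[i] for i in chosen)
    return GeneSetCollection(sets, "synthetic")


def _calibrate_censoring(t_event: np.ndarray, rng, target: float,
                         tol: float = 0.03, max_iter: int = 200):
    """Bisection on the uniform-censoring upper bound so the realised
    event rate P(T <= C) hits the target within ``tol``."""
    u = rng.uniform(size=len(t_event))  # C = u * c_max
    lo, hi = 1e-6, float(t_event.max()) * 4.0
    rate = lambda c: float(np.mean(t_event <= u * c))
    while rate(hi) < target and hi < 1e9:
        hi *= 2.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = rate(mid)
        if abs(r - target) <= tol:
            return u * mid, mid, r
        if r < target:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("censoring calibration failed to reach the target rate")


def simulate_cohort(sets: GeneSetCollection, n_samples: int,
                    n_active: int = 3, effect_size: float = 1.0,
                    noise_sd: float = 1.0, loading: float = 1.0,
                    target_event_rate: float = 0.44,
                    n_genes: int | None = None,
                    seed: int = 0):
    """Simulate (expression, survival, truth) for a gene-set collection.

    ``n_active`` pathways are drawn at random to carry survival signal
    with effect sizes of magnitude ``effect_size`` and alternating sign.
    ``n_genes`` sets the measured universe size (named ``G00000...``);
    genes beyond the set membership are pure-noise genes, as on a real
    array.  Returns ``(ExpressionMatrix, SurvivalTable, SyntheticTruth)``.
    """
    if n_active > len(sets):
        raise ValueError("n_active exceeds the number of pathways")
    rng = np.random.default_rng(seed)
    names = sets.names
    member_genes = sets.universe()
    if n_genes is None:
        genes = sorted(member_genes)
    else:
        genes = sorted(member_genes | {f"G{i:05d}" for i in range(n_genes)})
    n_g = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_p = len(names)

    activities = rng.standard_normal((n_p, n_samples))
    mu = rng.normal(8.0, 2.0, size=n_g)
    expr = mu[:, None] + rng.normal(0.0, noise_sd, size=(n_g, n_samples))
    for p, name in enumerate(names):
        idx = [gene_pos[g] for g in sorted(sets[name])]
        expr[idx, :] += loading * activities[p][None, :]

    active_idx = rng.choice(n_p, size=n_active, replace=False)
    gammas = {names[p]: float(effect_size * (-1) ** k)
              for k, p in enumerate(sorted(active_idx))}
    lp = np.zeros(n_samples)
    for name, g in gammas.items():
        lp += g * activities[names.index(name)]

    kappa = np.log(2.0) / MEDIAN_SURVIVAL_MONTHS ** WEIBULL_SHAPE
    u = rng.uniform(size=n_samples)
    t_event = (-np.log(u) / (kappa * np.exp(lp))) ** (1.0 / WEIBULL_SHAPE)
    censor, c_max, realized = _calibrate_censoring(t_event, rng, target_event_rate)
    observed = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)

    sample_ids = [f"S{j:04d}" for j in range(n_samples)]
    expr_m = ExpressionMatrix(genes, sample_ids, expr)
    surv = SurvivalTable(sample_ids, observed, event)
    truth = SyntheticTruth(
        active_pathways=gammas,
        loadings={name: loading for name in names},
        baseline_shape=WEIBULL_SHAPE,
        baseline_scale=float(kappa),
        target_event_rate=target_event_rate,
        realized_event_rate=realized,
        censor_upper=float(c_max),
        seed=seed,
        params={"n_samples": n_samples, "n_active": n_active,
                "effect_size": effect_size, "noise_sd": noise_sd,
                "loading": loading},
        linear_predictor=lp.tolist(),
    )
    return expr_m, surv, truth


PRESETS = {
    # fast unit-test fixture
    "tiny": {"n_genes": 50, "n_pathways": 6, "size_range": (4, 8),
             "overlap_frac": 0.2, "n_samples": 30, "n_active": 2},
    # the study-scale cohort used for parameter recovery and robustness
    "default": {"n_genes": 2000, "n_pathways": 60, "size_range": (10, 40),
                "overlap_frac": 0.25, "n_samples": 400, "n_active": 3},
}


def simulate_preset(preset: str, seed: int = 0):
    """Simulate one of the named presets; returns (expr, surv, sets, truth)."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; options: {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    sets = simulate_gene_sets(cfg["n_genes"], cfg["n_pathways"],
                              cfg["size_range"], cfg["overlap_frac"], seed=seed)
    expr, surv, truth = simulate_cohort(
        sets, cfg["n_samples"], n_active=cfg["n_active"],
        n_genes=cfg["n_genes"], seed=seed + 1)
    # record the preset-level seed: it alone regenerates the whole bundle
    truth.params["preset"] = preset
    truth.params["cohort_seed"] = truth.seed
    truth.seed = seed
    return expr, surv, sets, truth


def write_fixture_bundle(out_dir: str | Path, preset: str = "tiny",
                         seed: int = 0) -> dict[str, Path]:
    """Write expr.tsv / surv.tsv / sets.gmt / truth.json for a preset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, surv, sets, truth = simulate_preset(preset, seed=seed)
    paths = {
        "expr": out / "expr.tsv",
        "surv": out / "surv.tsv",
        "sets": out / "sets.gmt",
        "truth": out / "truth.json",
    }
    write_expression_table(expr, paths["expr"])
    write_survival_table(surv, paths["surv"])
    write_gmt(sets, paths["sets"])
    truth.to_json(paths["truth"])
    return paths
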