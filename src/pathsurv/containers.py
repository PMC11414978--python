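"""In-memory containers for expression, gene-set, survival and score data.

All matrices are stored genes/pathways in rows, samples in columns, the
orientation microarray and RNA-seq text exports use.  Missing expression
values are represented as NaN and are only legal in prediction-time inputs
(``allow_missing=True``); training-path constructors reject them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "SurvivalTable",
    "PathwayScoreMatrix",
]


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} id: {dup!r}")


@dataclass
class ExpressionMatrix:
    """Genes x samples continuous expression on log2 scale.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique row / column identifiers.
    values
        2-D float array, shape ``(len(gene_ids), len(sample_ids))``.
    allow_missing
        Whether NaN entries are tolerated.  Only prediction-time inputs may
        carry missingness; training inputs must be complete.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    allow_missing: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not self.allow_missing and not np.all(np.isfinite(self.values)):
            raise ValueError(
                "non-finite expression values found; missingness is only "
                "allowed in prediction-time inputs (allow_missing=True)"
            )
        if self.allow_missing and np.any(np.isinf(self.values)):
            raise ValueError("infinite expression values are never allowed")

    # -- convenience -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, allow_missing: bool = False) -> "ExpressionMatrix":
        return cls(
            list(map(str, frame.index)),
            list(map(str, frame.columns)),
            frame.to_numpy(dtype=float),
            allow_missing=allow_missing,
        )

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        idx = [pos[g] for g in genes]
        return ExpressionMatrix(genes, list(self.sample_ids), self.values[idx, :],
                                allow_missing=self.allow_missing)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        idx = [pos[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), samples, self.values[:, idx],
                                allow_missing=self.allow_missing)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(list(self.gene_ids), list(self.sample_ids),
                                self.values.copy(), allow_missing=self.allow_missing)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) over a gene universe.

    ``sets`` preserves insertion order; genes within a set are held as
    frozensets (membership only — no within-set order is meaningful).
    """

    sets: dict[str, frozenset[str]]
    source_name: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, genes in self.sets.items():
            if name in clean:
                raise ValueError(f"duplicate gene-set name: {name!r}")
            clean[str(name)] = frozenset(map(str, genes))
        self.sets = clean

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return out

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names}, self.source_name)


@dataclass
class SurvivalTable:
    """Right-censored survival outcomes, time in months.

    ``time`` is the observed time min(T_i, C_i); ``event`` is 1 when the
    event was observed (T_i <= C_i) and 0 when censored.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.shape != (len(self.sample_ids),) or self.event.shape != self.time.shape:
            raise ValueError("time/event length must match sample_ids")
        if np.any(~np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValueError("follow-up times must be finite and >= 0")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicator must be 0 or 1")
        self.event = self.event.astype(int)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, samples: Iterable[str]) -> "SurvivalTable":
        samples = list(samples)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in samples]
        return SurvivalTable(samples, self.time[idx], self.event[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "time": self.time, "event": self.event}
        )

    def aligned_to(self, sample_ids: list[str]) -> "SurvivalTable":
        """Reorder to match an expression matrix's sample order."""
        return self.subset(sample_ids)


@dataclass
class PathwayScoreMatrix:
    """Pathways x samples scores produced by one scoring method."""

    pathway_ids: list[str]
    sample_ids: list[str]
    scores: np.ndarray
    method: str
    method_params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pathway_ids = [str(p) for p in self.pathway_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.pathway_ids), len(self.sample_ids)):
            raise ValueError("scores shape does not match id lists")
        _check_unique(self.pathway_ids, "pathway")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("pathway scores must be finite")
        self.method_params = dict(self.method_params)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.pathway_ids, columns=self.sample_ids)
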