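"""Readers/writers for GMT gene sets, expression tables and survival tables,
plus the probe-to-gene harmonisation steps applied before modelling.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_expression_table",
    "write_expression_table",
    "read_survival_table",
    "write_survival_table",
    "collapse_probes",
    "intersect_gene_universe",
]

#: values above this suggest raw (non-log) intensities
_LOG2_SANITY_MAX = 30.0


def read_gmt(path: str | Path, source_name: str | None = None) -> GeneSetCollection:
    """Parse an MSigDB-dialect GMT file.

    Each line is ``name<TAB>description<TAB>gene<TAB>gene...``.  The
    description field is ignored.  Duplicate genes within a line are
    deduplicated with a warning; duplicate set names are an error.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if len(set(genes)) != len(genes):
                logger.warning("GMT set %r (line %d): duplicate genes deduplicated",
                               name, lineno)
            sets[name] = frozenset(genes)
    return GeneSetCollection(sets, source_name or path.stem)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    """Write a collection to GMT; genes sorted for a stable round-trip."""
    path = Path(path)
    with path.open("w") as fh:
        for name in sets.names:
            genes = sorted(sets[name])
            fh.write("\t".join([name, sets.source_name or "na", *genes]) + "\n")


def read_expression_table(
    path: str | Path,
    missing_token: str = "NA",
    allow_missing: bool = False,
) -> ExpressionMatrix:
    """Read a genes-in-rows TSV; first column gene id, header row sample ids.

    Cells equal to ``missing_token`` become NaN (legal only with
    ``allow_missing=True``); any other non-numeric cell is an error that
    names its coordinates.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    gene_ids = list(map(str, frame.index))
    if len(set(gene_ids)) != len(gene_ids):
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    values = np.empty(frame.shape, dtype=float)
    raw = frame.to_numpy()
    for j in range(frame.shape[1]):
        col = raw[:, j]
        miss = col == missing_token
        col = np.where(miss, "nan", col)
        try:
            values[:, j] = col.astype(float)
        except ValueError:
            for i, cell in enumerate(col):
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {raw[i, j]!r} at gene "
                        f"{gene_ids[i]!r}, sample {frame.columns[j]!r}"
                    ) from None
            raise
    if np.nanmax(values, initial=0.0) > _LOG2_SANITY_MAX:
        logger.warning("%s: max value %.1f > %.0f; expression may not be log2 scale",
                       path, np.nanmax(values), _LOG2_SANITY_MAX)
    return ExpressionMatrix(gene_ids, list(map(str, frame.columns)), values,
                            allow_missing=allow_missing)


def _roundtrip_float(v: float) -> str:
    # shortest representation that parses back to the identical double
    return repr(float(v))


def write_expression_table(expr: ExpressionMatrix, path: str | Path,
                           missing_token: str = "NA") -> None:
    frame = expr.to_frame()
    frame.to_csv(path, sep="\t", na_rep=missing_token,
                 float_format=_roundtrip_float)


def read_survival_table(path: str | Path) -> SurvivalTable:
    """Read a TSV with columns ``sample_id``, ``time`` (months), ``event``."""
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"sample_id", "time", "event"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, "
                         f"got {list(frame.columns)}")
    return SurvivalTable(
        list(map(str, frame["sample_id"])),
        frame["time"].to_numpy(dtype=float),
        frame["event"].to_numpy(),
    )


def write_survival_table(surv: SurvivalTable, path: str | Path) -> None:
    surv.to_frame().to_csv(path, sep="\t", index=False,
                           float_format=_roundtrip_float)


def collapse_probes(
    probe_expr: ExpressionMatrix,
    probe_map: Mapping[str, Sequence[str]],
) -> ExpressionMatrix:
    """Collapse probe-level rows to gene symbols.

    Probes mapping to zero or more than one symbol are removed.  When
    several surviving probes target the same gene, the probe with the
    highest mean expression across samples represents the gene (a common
    microarray convention; logged per gene).
    """
    keep: dict[str, list[int]] = {}
    for i, probe in enumerate(probe_expr.gene_ids):
        symbols = [s for s in probe_map.get(probe, ()) if s]
        if len(symbols) != 1:
            continue
        keep.setdefault(symbols[0], []).append(i)
    if not keep:
        raise ValueError("no probes survive filtering (all unmapped or multi-mapped)")
    genes = sorted(keep)
    rows = np.empty((len(genes), probe_expr.n_samples))
    means = np.nanmean(probe_expr.values, axis=1)
    for gi, gene in enumerate(genes):
        idx = keep[gene]
        best = max(idx, key=lambda i: (means[i], probe_expr.gene_ids[i]))
        if len(idx) > 1:
            logger.info("gene %s: %d probes, kept %s (max mean expression)",
                        gene, len(idx), probe_expr.gene_ids[best])
        rows[gi] = probe_expr.values[best]
    return ExpressionMatrix(genes, list(probe_expr.sample_ids), rows,
                            allow_missing=probe_expr.allow_missing)


def intersect_gene_universe(
    matrices: Iterable[ExpressionMatrix],
) -> list[ExpressionMatrix]:
    """Restrict every matrix to the shared gene universe, in lexicographic
    order, so coefficients fitted on one cohort port to the others."""
    matrices = list(matrices)
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    shared = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        shared &= set(m.gene_ids)
    if not shared:
        raise ValueError("gene universes have empty intersection")
    order = sorted(shared)
    return [m.subset_genes(order) for m in matrices]
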