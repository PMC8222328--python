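"""Reading, writing and aligning expression data and gene-ID lists.

File formats:

* expression matrix — TSV, UTF-8, header row ``gene_id<TAB>sample1<TAB>...``,
  one gene per row, genes as rows and samples as columns (the dominant
  convention of expression compendia);
* ID lists — plain text, one ID per line, blank lines and ``#`` comments
  ignored;
* rankings / networks / summaries — TSV, SIF and JSON writers at the bottom.

The loader is strict: duplicate gene IDs, non-numeric cells, missing values
and empty matrices are hard errors rather than silently imputed, because the
engines expect complete, already-normalized matrices.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetSpec",
    "AlignmentReport",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_id_list",
    "write_id_list",
    "assemble_design",
    "write_ranking_tsv",
    "read_ranking_tsv",
    "write_network_sif",
    "write_edge_list_tsv",
    "write_summary_json",
    "atomic_write_text",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """A named genes x samples grid of normalized expression values.

    Invariants enforced at construction: unique gene and sample IDs, shape
    consistent with the axes, and all values finite.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for axis_name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                seen: set = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise ValueError(f"duplicate {axis_name} ID: {dup!r}")
        if len(self.gene_ids) == 0 or len(self.sample_ids) == 0:
            raise ValueError("expression matrix is empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains NaN/Inf values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Row subset in the given order; all IDs must be present."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[rows])

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSetSpec:
    """Pathway-gene, transcription-factor and optional positive-regulator IDs."""

    pathway_ids: list
    tf_ids: list
    positive_ids: list | None = None

    def __post_init__(self) -> None:
        self.pathway_ids = [str(g) for g in self.pathway_ids]
        self.tf_ids = [str(g) for g in self.tf_ids]
        if self.positive_ids is not None:
            self.positive_ids = [str(g) for g in self.positive_ids]
            missing = set(self.positive_ids) - set(self.tf_ids)
            if missing:
                raise ValueError(
                    f"positive IDs not in the TF list: {sorted(missing)[:5]}"
                )


@dataclass
class AlignmentReport:
    """Bookkeeping from :func:`assemble_design`."""

    n_pathway_found: int = 0
    n_tf_found: int = 0
    dropped_missing: list = field(default_factory=list)
    dropped_overlap: list = field(default_factory=list)


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a genes x samples TSV; strict about duplicates and bad cells."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    dup = frame.index[frame.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene ID: {dup[0]!r}")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        column = frame[col].to_numpy(dtype=object)
        try:
            # numpy's str->float conversion is correctly rounded, so writes at
            # 17 significant digits round-trip exactly
            values[:, j] = np.asarray(column, dtype="U32").astype(np.float64)
        except ValueError:
            for i, cell in enumerate(column):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell at gene {frame.index[i]!r}, "
                        f"sample {col!r}"
                    ) from None
            raise
    return ExpressionMatrix(list(frame.index), list(frame.columns), values)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix at full precision (17 significant digits) for exact round-trips."""
    frame = matrix.to_dataframe()
    frame.index.name = "gene_id"
    atomic_write_text(path, frame.to_csv(sep="\t", float_format="%.17g"))


def read_id_list(path) -> list:
    """Read one-ID-per-line text; dedup preserving first occurrence, warn on dups."""
    path = Path(path)
    ids: list = []
    seen: set = set()
    n_dup = 0
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line in seen:
            n_dup += 1
            continue
        seen.add(line)
        ids.append(line)
    if n_dup:
        logger.warning("%s: %d duplicate ID(s) removed", path, n_dup)
    if not ids:
        raise ValueError(f"{path}: no IDs found")
    return ids


def write_id_list(ids: Iterable[str], path) -> None:
    atomic_write_text(path, "".join(f"{i}\n" for i in ids))


def assemble_design(
    expr: ExpressionMatrix, spec: GeneSetSpec
) -> tuple[ExpressionMatrix, ExpressionMatrix, AlignmentReport]:
    """Split ``expr`` into TF-predictor and pathway-response blocks.

    A gene listed both as TF and pathway gene is treated as a pathway gene
    (response) and removed from the predictor side — otherwise it would
    trivially "regulate" itself.  IDs absent from the matrix are dropped and
    recorded.  Sample order is inherited from ``expr`` unchanged.
    """
    if not spec.pathway_ids or not spec.tf_ids:
        raise ValueError("pathway and TF ID lists must be nonempty")
    present = set(expr.gene_ids)
    pathway_set = set(spec.pathway_ids)
    report = AlignmentReport()

    pathway_kept = [g for g in spec.pathway_ids if g in present]
    report.dropped_missing.extend(g for g in spec.pathway_ids if g not in present)

    tf_kept = []
    for g in spec.tf_ids:
        if g in pathway_set:
            if g not in report.dropped_overlap:
                report.dropped_overlap.append(g)
        elif g not in present:
            if g not in report.dropped_missing:
                report.dropped_missing.append(g)
        else:
            tf_kept.append(g)

    if len(pathway_kept) < 2:
        raise ValueError(
            f"need at least 2 pathway genes in the matrix, found {len(pathway_kept)}"
        )
    if not tf_kept:
        raise ValueError("no TF IDs found in the expression matrix")

    report.n_pathway_found = len(pathway_kept)
    report.n_tf_found = len(tf_kept)
    return expr.subset(tf_kept), expr.subset(pathway_kept), report


# ---------------------------------------------------------------------------
# ranking / network / summary serialization

_RANKING_COLUMNS = ["rank", "tf_id", "connectivity", "n_triplets", "strength", "method"]


def write_ranking_tsv(ranking: pd.DataFrame, path) -> None:
    frame = ranking.loc[:, _RANKING_COLUMNS]
    atomic_write_text(path, frame.to_csv(sep="\t", index=False, float_format="%.17g"))


def read_ranking_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"tf_id": str})
    missing = set(_RANKING_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: ranking file missing columns {sorted(missing)}")
    return frame


def write_network_sif(edges: pd.DataFrame, path) -> None:
    """SIF export: ``tf<TAB>regulates<TAB>gene`` per edge."""
    lines = [f"{t}\tregulates\t{g}\n" for t, g in zip(edges["tf_id"], edges["gene_id"])]
    atomic_write_text(path, "".join(lines))


def write_edge_list_tsv(edges: pd.DataFrame, path) -> None:
    frame = edges.loc[:, ["tf_id", "gene_id", "weight", "support"]]
    atomic_write_text(path, frame.to_csv(sep="\t", index=False, float_format="%.17g"))


def write_summary_json(summary: dict, path) -> None:
    atomic_write_text(path, json.dumps(summary, indent=2, sort_keys=True) + "\n")


def atomic_write_text(path, text: str) -> None:
    """Write via a temp file + rename so readers never see partial output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
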