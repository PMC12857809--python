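"""Domain types, file readers/writers, and expression normalization.

Containers are thin, validated wrappers around pandas/numpy objects:

* :class:`CellTable` — one or more ROIs' cells with μm coordinates and
  categorical type labels (EPI / IMM / MLC / ...).
* :class:`ExpressionMatrix` — genes × units (cells or ROIs) with an explicit
  normalization state.
* :class:`GeneSet` / :class:`LRPanel` — gene signatures (GMT) and
  ligand-receptor pair panels (two-column TSV).

Coordinates are taken verbatim as μm; distances downstream are Euclidean in
the input frame. Gene identifiers match by exact, case-sensitive string
equality — no symbol aliasing is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

NormState = Literal["raw_counts", "log_cpm", "arbitrary"]

CELL_TABLE_COLUMNS = ("roi_id", "cell_id", "x", "y", "cell_type")


class SchemaError(ValueError):
    """Input violates the expected schema or a container invariant."""


@dataclass
class CellTable:
    """Cells of one or more ROIs: id, x/y position in μm, and type label.

    ``data`` holds columns ``roi_id, cell_id, x, y, cell_type``. ``cell_id``
    must be unique within each ``roi_id`` and coordinates must be finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CELL_TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cell table missing column(s): {', '.join(missing)}")
        if len(self.data) == 0:
            raise SchemaError("cell table has no rows")
        df = self.data.loc[:, list(CELL_TABLE_COLUMNS)].copy()
        for col in ("x", "y"):
            try:
                df[col] = pd.to_numeric(df[col], errors="raise")
            except (ValueError, TypeError) as exc:
                bad = pd.to_numeric(df[col], errors="coerce")
                rows = df.index[bad.isna()].tolist()
                raise SchemaError(
                    f"non-numeric coordinate in column {col!r} at row(s) {rows[:5]}"
                ) from exc
        if not np.isfinite(df[["x", "y"]].to_numpy(float)).all():
            raise SchemaError("non-finite coordinates in cell table")
        df["roi_id"] = df["roi_id"].astype(str)
        df["cell_id"] = df["cell_id"].astype(str)
        df["cell_type"] = df["cell_type"].astype(str)
        dup = df.duplicated(subset=["roi_id", "cell_id"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["roi_id", "cell_id"]]
            raise SchemaError(
                f"duplicate cell_id {pair['cell_id']!r} within ROI {pair['roi_id']!r}"
            )
        self.data = df.reset_index(drop=True)

    @property
    def roi_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["roi_id"]))

    def for_roi(self, roi_id: str) -> "CellTable":
        sub = self.data[self.data["roi_id"] == roi_id]
        if len(sub) == 0:
            raise SchemaError(f"ROI {roi_id!r} not present in cell table")
        return CellTable(sub)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ExpressionMatrix:
    """Genes × units expression with explicit normalization state.

    ``values`` is dense float64, genes on rows. ``norm_state`` is one of
    ``raw_counts`` (non-negative integral), ``log_cpm`` (natural-log CPM with
    a +1 pseudocount) or ``arbitrary`` (anything the caller supplies, e.g.
    Q3-normalized region counts).
    """

    gene_ids: list[str]
    unit_ids: list[str]
    values: np.ndarray
    norm_state: NormState = "arbitrary"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.unit_ids = [str(u) for u in self.unit_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.unit_ids)):
            raise SchemaError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.unit_ids)} units"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise SchemaError("duplicate gene ids in expression matrix")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise SchemaError("duplicate unit ids in expression matrix")
        if not np.isfinite(self.values).all():
            raise SchemaError("non-finite expression values")
        if self.norm_state == "raw_counts":
            if (self.values < 0).any() or not np.allclose(
                self.values, np.round(self.values)
            ):
                raise SchemaError("raw_counts requires non-negative integral values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.unit_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_units(self, unit_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {u: i for i, u in enumerate(self.unit_ids)}
        missing = [u for u in unit_ids if u not in idx]
        if missing:
            raise SchemaError(f"unit id(s) not in matrix: {missing[:5]}")
        cols = [idx[u] for u in unit_ids]
        return ExpressionMatrix(
            self.gene_ids, list(unit_ids), self.values[:, cols], self.norm_state
        )


@dataclass(frozen=True)
class GeneSet:
    """A named, duplicate-free gene signature."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise SchemaError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise SchemaError(f"gene set {self.name!r} contains duplicate genes")


@dataclass(frozen=True)
class LRPanel:
    """Ordered (ligand, receptor) gene pairs to score per ROI."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.pairs) == 0:
            raise SchemaError("ligand-receptor panel is empty")
        if len(set(self.pairs)) != len(self.pairs):
            raise SchemaError("duplicate ligand-receptor pairs in panel")


def read_cell_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> CellTable:
    """Read a CSV/TSV cell table into a validated :class:`CellTable`.

    ``column_map`` maps file column names to the canonical names
    ``roi_id, cell_id, x, y, cell_type`` (e.g. ``{"X_um": "x"}``).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing column(s) {', '.join(missing)} "
            f"(available: {', '.join(map(str, df.columns))})"
        )
    return CellTable(df)


def write_cell_table(table: CellTable, path: str | Path, header: str | None = None) -> None:
    """Write a cell table as TSV with an optional commented provenance header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        table.data.to_csv(fh, sep="\t", index=False)


def _infer_norm_state(values: np.ndarray) -> NormState:
    if (values >= 0).all() and np.allclose(values, np.round(values)):
        return "raw_counts"
    return "arbitrary"


def read_expression(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    units_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from MTX triplet or dense CSV.

    MTX input requires one-column ``genes_path`` / ``units_path`` annotation
    files (rows = genes, columns = units). Dense CSV input has unit ids in the
    header row and gene ids in the first column. ``norm_state`` is inferred:
    ``raw_counts`` if every entry is a non-negative integer, else
    ``arbitrary``.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or units_path is None:
            raise SchemaError("MTX input requires genes_path and units_path")
        mat = scipy.io.mmread(matrix_path)
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        genes = pd.read_csv(genes_path, header=None, sep="\t")[0].astype(str).tolist()
        units = pd.read_csv(units_path, header=None, sep="\t")[0].astype(str).tolist()
        if values.shape != (len(genes), len(units)):
            raise SchemaError(
                f"matrix shape {values.shape} does not match annotations "
                f"({len(genes)} genes, {len(units)} units)"
            )
    else:
        sep = "\t" if matrix_path.suffix.lower() in {".tsv", ".txt"} else ","
        df = pd.read_csv(matrix_path, sep=sep, index_col=0, comment="#")
        genes = [str(g) for g in df.index]
        units = [str(u) for u in df.columns]
        values = df.to_numpy(dtype=float)
    return ExpressionMatrix(genes, units, values, _infer_norm_state(values))


def write_expression(
    m: ExpressionMatrix, path: str | Path, header: str | None = None
) -> None:
    """Write a dense TSV rendering (genes on rows) with optional header comment."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        m.to_frame().to_csv(fh, sep="\t")


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one gene set per line (name, description, genes...).

    Descriptions are discarded; duplicate genes within a line are dropped with
    a warning. Empty files yield an empty list.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{Path(path).name}:{lineno}: GMT line has {len(fields)} "
                    "field(s); need name, description, and >=1 gene"
                )
            name, genes = fields[0], fields[2:]
            unique = list(dict.fromkeys(g for g in genes if g))
            if len(unique) < sum(1 for g in genes if g):
                logger.warning(
                    "GMT set %r (line %d): duplicate genes dropped", name, lineno
                )
            sets.append(GeneSet(name=name, genes=tuple(unique)))
    return sets


def read_lr_panel(path: str | Path) -> LRPanel:
    """Read a two-column (ligand, receptor) TSV panel; comment lines allowed."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["ligand", "receptor"])
    if df.isna().any().any():
        raise SchemaError(f"{Path(path).name}: malformed ligand-receptor row")
    pairs = tuple((str(l), str(r)) for l, r in zip(df["ligand"], df["receptor"]))
    return LRPanel(pairs=pairs)


def default_lr_panel() -> LRPanel:
    """The packaged four-pair recruitment panel.

    CCL26-CCR3 (eosinophil chemotaxis), CCL20-CCR6 (Th17/DC recruitment),
    TSLP-IL7R and IL33-IL1RL1 (epithelial alarmins acting on type-2 immune
    cells).
    """
    ref = resources.files("epimm.data").joinpath("lr_panel_default.tsv")
    with resources.as_file(ref) as p:
        return read_lr_panel(p)


def example_signature_sets() -> list[GeneSet]:
    """Illustrative packaged gene sets (Th1/Th2/M2/eosinophil/tuft).

    These are small, generic marker lists for demos and tests only — they
    are NOT curated signatures; supply your own GMT for real analyses.
    """
    ref = resources.files("epimm.data").joinpath("example_signatures.gmt")
    with resources.as_file(ref) as p:
        return read_gene_sets(p)


def normalize_log_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Natural-log counts-per-million normalization with a +1 pseudocount.

    Each count is divided by its unit's total, scaled by 1e6, and transformed
    as ``ln(1 + CPM)``. Requires ``norm_state == "raw_counts"`` and a positive
    total per unit. Zero counts map to exactly 0, and the transform is
    monotone within each unit.
    """
    if m.norm_state != "raw_counts":
        raise SchemaError(
            f"normalize_log_cpm requires raw_counts input, got {m.norm_state!r}"
        )
    totals = m.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [m.unit_ids[i] for i in zero[:5]]
        raise SchemaError(f"unit(s) with zero total count: {names}")
    cpm = m.values / totals[np.newaxis, :] * 1e6
    return ExpressionMatrix(m.gene_ids, m.unit_ids, np.log1p(cpm), "log_cpm")
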