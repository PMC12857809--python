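"""Delaunay proximity graphs over one ROI's cells.

The cell-contact graph is the Delaunay triangulation of the cell centroids,
pruned to edges no longer than a distance cutoff (default 50 μm, inclusive).
Degenerate inputs (<3 cells, or all cells collinear) fall back to the
complete graph pruned at the same cutoff, so downstream edge counts remain
defined. Exact duplicate coordinates are deterministically jittered by
1e-6 μm (seeded from the ROI id) before triangulation.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from epimm.io import CellTable, SchemaError

logger = logging.getLogger(__name__)

DEFAULT_MAX_EDGE_LEN = 50.0


@dataclass
class SpatialGraph:
    """Pruned proximity graph for one ROI.

    ``nodes`` has columns ``cell_id, x, y, cell_type``; ``edges`` has columns
    ``cell_a, cell_b, length_um`` with ``cell_a < cell_b`` lexicographically
    and each length ≤ ``max_edge_len``.
    """

    roi_id: str
    nodes: pd.DataFrame
    edges: pd.DataFrame
    max_edge_len: float
    jittered_cells: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_index_pairs(self) -> np.ndarray:
        """Edges as integer (i, j) index pairs into ``nodes`` rows."""
        pos = {c: i for i, c in enumerate(self.nodes["cell_id"])}
        if len(self.edges) == 0:
            return np.empty((0, 2), dtype=int)
        return np.array(
            [[pos[a], pos[b]] for a, b in zip(self.edges["cell_a"], self.edges["cell_b"])],
            dtype=int,
        )


@dataclass(frozen=True)
class EdgeCounts:
    """Two-type edge summary: node counts nA/nB and edge counts eAA/eBB/eAB."""

    type_a: str
    type_b: str
    nA: int
    nB: int
    eAA: int
    eBB: int
    eAB: int
    roi_id: str = ""

    def __post_init__(self) -> None:
        for name in ("nA", "nB", "eAA", "eBB", "eAB"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} is negative")
        if self.eAA > self.nA * (self.nA - 1) // 2:
            raise ValueError("eAA exceeds possible within-type pairs")
        if self.eBB > self.nB * (self.nB - 1) // 2:
            raise ValueError("eBB exceeds possible within-type pairs")
        if self.eAB > self.nA * self.nB:
            raise ValueError("eAB exceeds possible across-type pairs")


def _jitter_duplicates(
    coords: np.ndarray, cell_ids: list[str], roi_id: str
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Perturb exact duplicate coordinates by 1e-6 μm, seeded from the ROI id."""
    df = pd.DataFrame(coords)
    dup = df.duplicated(keep="first").to_numpy()
    if not dup.any():
        return coords, ()
    seed = zlib.crc32(roi_id.encode("utf-8")) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    out = coords.copy()
    out[dup] += rng.uniform(-1e-6, 1e-6, size=(int(dup.sum()), 2))
    jittered = tuple(cid for cid, d in zip(cell_ids, dup) if d)
    logger.warning(
        "ROI %s: %d duplicate coordinate(s) jittered by <=1e-6 um", roi_id, len(jittered)
    )
    return out, jittered


def _all_pairs_edges(coords: np.ndarray) -> np.ndarray:
    n = len(coords)
    i, j = np.triu_indices(n, k=1)
    return np.column_stack([i, j])


def _delaunay_edges(coords: np.ndarray) -> np.ndarray:
    tri = Delaunay(coords)
    simp = tri.simplices
    pairs = np.vstack([simp[:, [0, 1]], simp[:, [1, 2]], simp[:, [0, 2]]])
    pairs = np.sort(pairs, axis=1)
    return np.unique(pairs, axis=0)


def build_proximity_graph(
    cells: CellTable, max_edge_len: float = DEFAULT_MAX_EDGE_LEN
) -> SpatialGraph:
    """Build the pruned Delaunay proximity graph for a single-ROI cell table.

    Parameters
    ----------
    cells
        Cell table containing exactly one ROI.
    max_edge_len
        Distance cutoff in μm; edges with length ≤ cutoff (inclusive) are kept.
    """
    if max_edge_len <= 0:
        raise ValueError("max_edge_len must be positive")
    rois = cells.roi_ids
    if len(rois) != 1:
        raise SchemaError(
            f"build_proximity_graph expects a single ROI, got {len(rois)}: {rois[:5]}"
        )
    roi_id = rois[0]
    nodes = cells.data.loc[:, ["cell_id", "x", "y", "cell_type"]].reset_index(drop=True)
    cell_ids = nodes["cell_id"].tolist()
    coords = nodes[["x", "y"]].to_numpy(dtype=float)
    coords, jittered = _jitter_duplicates(coords, cell_ids, roi_id)
    nodes = nodes.assign(x=coords[:, 0], y=coords[:, 1])

    if len(nodes) < 3:
        idx_pairs = _all_pairs_edges(coords)
    else:
        try:
            idx_pairs = _delaunay_edges(coords)
        except QhullError:
            # collinear input: triangulation undefined, use complete graph
            idx_pairs = _all_pairs_edges(coords)

    if len(idx_pairs):
        lengths = np.linalg.norm(coords[idx_pairs[:, 0]] - coords[idx_pairs[:, 1]], axis=1)
        keep = lengths <= max_edge_len
        idx_pairs, lengths = idx_pairs[keep], lengths[keep]
    else:
        lengths = np.empty(0)

    names = np.array(cell_ids, dtype=object)
    a = names[idx_pairs[:, 0]] if len(idx_pairs) else np.empty(0, dtype=object)
    b = names[idx_pairs[:, 1]] if len(idx_pairs) else np.empty(0, dtype=object)
    swap = a > b
    a[swap], b[swap] = b[swap], a[swap].copy()
    edges = (
        pd.DataFrame({"cell_a": a, "cell_b": b, "length_um": lengths})
        .sort_values(["cell_a", "cell_b"])
        .reset_index(drop=True)
    )
    return SpatialGraph(
        roi_id=roi_id,
        nodes=nodes,
        edges=edges,
        max_edge_len=float(max_edge_len),
        jittered_cells=jittered,
    )


def classify_edges(g: SpatialGraph, type_a: str, type_b: str) -> EdgeCounts:
    """Count within- and across-type edges for a pair of cell-type labels.

    Edges touching any other label are ignored; ``nA``/``nB`` are the node
    counts of each label in the ROI. Symmetric: swapping the labels swaps
    (eAA, nA) with (eBB, nB) and fixes eAB.
    """
    if type_a == type_b:
        raise ValueError("type_a and type_b must differ")
    types = g.nodes.set_index("cell_id")["cell_type"]
    nA = int((types == type_a).sum())
    nB = int((types == type_b).sum())
    for label, n in ((type_a, nA), (type_b, nB)):
        if n == 0:
            raise ValueError(f"cell type {label!r} absent from ROI {g.roi_id!r}")
    ta = types.loc[g.edges["cell_a"]].to_numpy() if len(g.edges) else np.empty(0, object)
    tb = types.loc[g.edges["cell_b"]].to_numpy() if len(g.edges) else np.empty(0, object)
    eAA = int(((ta == type_a) & (tb == type_a)).sum())
    eBB = int(((ta == type_b) & (tb == type_b)).sum())
    eAB = int(
        (((ta == type_a) & (tb == type_b)) | ((ta == type_b) & (tb == type_a))).sum()
    )
    return EdgeCounts(
        type_a=type_a, type_b=type_b, nA=nA, nB=nB, eAA=eAA, eBB=eBB, eAB=eAB,
        roi_id=g.roi_id,
    )


def write_edge_list(g: SpatialGraph, path, type_a: str | None = None,
                    type_b: str | None = None, header: str | None = None) -> None:
    """Write the edge list as TSV (roi_id, cell_a, cell_b, length_um, pair_class)."""
    types = g.nodes.set_index("cell_id")["cell_type"]
    rows = g.edges.copy()
    rows.insert(0, "roi_id", g.roi_id)
    cls = [
        "-".join(sorted((types[a], types[b])))
        for a, b in zip(rows["cell_a"], rows["cell_b"])
    ]
    rows["pair_class"] = cls
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        rows.to_csv(fh, sep="\t", index=False)
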