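"""The basal transition continuum.

Basal epithelial cells in chronic rhinosinusitis shift between a healthy-like
state and a remodeled, immune-permissive state. The continuum orders samples
along that shift:

1. Per-sample differential expression of basal cells against a reference is
   filtered (Padj ≤ 0.05, |log2FC| ≥ 0.5 in at least two samples; samples
   need more than 50 basal cells) to pick the transition genes.
2. Per-sample pseudobulk profiles (mean log-normalized basal expression over
   the selected genes) are z-scored per gene and reduced by PCA.
3. A loess spline (degree 2, tricube weights) of PC2 on PC1 traces the
   continuum through the point cloud; its arc length is the scalar
   continuum coordinate.
4. Any profile over the same genes — a training sample, an external cohort,
   or a spatial epithelial ROI transcriptome — is standardized with the
   training parameters, projected onto the two loadings, and assigned the
   arc length of the nearest spline vertex.

Immune composition can then be read along the coordinate with
:func:`fraction_trend`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from epimm.io import ExpressionMatrix, GeneSet, SchemaError
from epimm.signatures import adjust_pvalues

GRID_POINTS = 200


@dataclass
class ContinuumModel:
    """Fitted continuum: standardization, 2-D loadings, spline, arc lengths."""

    genes: list[str]
    gene_means: np.ndarray
    gene_sds: np.ndarray
    pc_loadings: np.ndarray  # (2, n_genes), rows orthonormal
    spline_points: np.ndarray  # (grid, 2) polyline in PC space
    arc_lengths: np.ndarray  # (grid,) cumulative, starts at 0
    span: float
    training_sample_ids: list[str]
    training_coordinates: np.ndarray
    explained_variance_ratio: tuple[float, float] = (float("nan"), float("nan"))

    @property
    def total_arc_length(self) -> float:
        return float(self.arc_lengths[-1])

    def to_json(self, path: str | Path) -> None:
        doc = {
            "schema": "epimm.continuum/1",
            "genes": self.genes,
            "gene_means": self.gene_means.tolist(),
            "gene_sds": self.gene_sds.tolist(),
            "pc_loadings": self.pc_loadings.tolist(),
            "spline_points": self.spline_points.tolist(),
            "arc_lengths": self.arc_lengths.tolist(),
            "span": self.span,
            "training_sample_ids": self.training_sample_ids,
            "training_coordinates": self.training_coordinates.tolist(),
            "explained_variance_ratio": list(self.explained_variance_ratio),
        }
        Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "ContinuumModel":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        if doc.get("schema") != "epimm.continuum/1":
            raise SchemaError(f"unrecognized continuum model schema in {path}")
        return cls(
            genes=list(doc["genes"]),
            gene_means=np.asarray(doc["gene_means"], dtype=float),
            gene_sds=np.asarray(doc["gene_sds"], dtype=float),
            pc_loadings=np.asarray(doc["pc_loadings"], dtype=float),
            spline_points=np.asarray(doc["spline_points"], dtype=float),
            arc_lengths=np.asarray(doc["arc_lengths"], dtype=float),
            span=float(doc["span"]),
            training_sample_ids=list(doc["training_sample_ids"]),
            training_coordinates=np.asarray(doc["training_coordinates"], dtype=float),
            explained_variance_ratio=tuple(doc["explained_variance_ratio"]),
        )


@dataclass(frozen=True)
class ContinuumPlacement:
    """One profile's position on the continuum."""

    sample_id: str
    coordinate: float
    normalized: float
    residual_distance: float


def select_continuum_genes(
    de_tables: Mapping[str, pd.DataFrame],
    basal_cell_counts: Mapping[str, int],
    min_cells: int = 50,
    max_padj: float = 0.05,
    min_abs_lfc: float = 0.5,
    min_samples: int = 2,
    name: str = "continuum",
) -> GeneSet:
    """Select transition genes from per-sample differential-expression tables.

    Samples with basal-cell counts ≤ ``min_cells`` are dropped (the filter is
    strictly "more than"). Each surviving sample's table (columns ``gene``,
    ``log_fc`` on the log2 scale, and ``p``) is BH-adjusted; a gene is
    selected iff it shows p_adj ≤ ``max_padj`` and |log2FC| ≥ ``min_abs_lfc``
    in at least ``min_samples`` surviving samples.
    """
    surviving = [s for s in de_tables if basal_cell_counts.get(s, 0) > min_cells]
    if len(surviving) < 2:
        raise ValueError(
            f"only {len(surviving)} sample(s) have more than {min_cells} basal cells; "
            "need at least 2"
        )
    hits: dict[str, int] = {}
    for s in surviving:
        tab = de_tables[s]
        if len(tab) == 0:
            continue
        padj = adjust_pvalues(tab["p"].to_numpy(float), "bh")
        passing = tab.loc[
            (padj <= max_padj) & (tab["log_fc"].abs() >= min_abs_lfc), "gene"
        ]
        for g in passing:
            hits[g] = hits.get(g, 0) + 1
    selected = sorted(g for g, k in hits.items() if k >= min_samples)
    if not selected:
        raise ValueError(
            "no gene passed the continuum filters "
            f"(p_adj <= {max_padj}, |log2FC| >= {min_abs_lfc} in >= {min_samples} "
            "samples); consider relaxing thresholds"
        )
    return GeneSet(name=name, genes=tuple(selected))


def _loess(
    x: np.ndarray, y: np.ndarray, x_grid: np.ndarray, span: float, degree: int = 2
) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    For each grid point, the ``span`` fraction of nearest training points is
    fit with a weighted degree-``degree`` polynomial. The local degree drops
    when the window holds too few distinct points for the requested degree.
    """
    n = len(x)
    k = max(degree + 1, int(math.ceil(span * n)))
    k = min(k, n)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    out = np.empty(len(x_grid))
    for gi, x0 in enumerate(x_grid):
        d = np.abs(xs - x0)
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[gi] = float(ys[idx].mean())
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.maximum(w, 1e-9)
        deg = min(degree, len(np.unique(xs[idx])) - 1)
        coeffs = np.polynomial.polynomial.polyfit(
            xs[idx] - x0, ys[idx], deg=max(deg, 0), w=np.sqrt(w)
        )
        out[gi] = float(coeffs[0])
    return out


def _standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=0)
    return (values - means[:, None]), means, sds


def fit_continuum(pseudobulk: ExpressionMatrix, span: float = 0.75) -> ContinuumModel:
    """Fit the continuum to sample pseudobulk profiles over selected genes.

    Genes are z-scored over samples (zero-variance genes dropped with a
    warning), samples are reduced to the first two principal components, and
    a loess curve of PC2 on PC1 is evaluated on a 200-point grid over the
    PC1 range to form the spline polyline. Each training sample's coordinate
    is the cumulative arc length of its nearest spline vertex. The coordinate
    direction is fixed so the training sample with the lexicographically
    smallest id lies in the lower half.
    """
    if len(pseudobulk.unit_ids) < 4:
        raise ValueError("continuum fit requires at least 4 samples")
    values = pseudobulk.values.astype(float)
    sds = values.std(axis=1, ddof=0)
    keep = sds > 0
    if not keep.any():
        raise ValueError("all genes have zero variance across samples")
    if not keep.all():
        import logging

        logging.getLogger(__name__).warning(
            "dropping %d zero-variance gene(s) before PCA", int((~keep).sum())
        )
    genes = [g for g, k in zip(pseudobulk.gene_ids, keep) if k]
    vals = values[keep]
    centered, means, sds = _standardize(vals)
    z = centered / sds[:, None]  # genes x samples

    # PCA over samples: SVD of the samples x genes matrix
    X = z.T
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    if len(S) < 2:
        raise ValueError("fewer than 2 principal components available")
    loadings = Vt[:2]
    # deterministic sign: largest-|loading| entry of each PC is positive
    for i in range(2):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    scores = X @ loadings.T  # samples x 2
    total_var = float((S**2).sum())
    evr = (float(S[0] ** 2 / total_var), float(S[1] ** 2 / total_var))

    pc1, pc2 = scores[:, 0], scores[:, 1]
    if np.ptp(pc1) == 0:
        raise ValueError("PC1 is constant; no ordering is possible")
    grid = np.linspace(pc1.min(), pc1.max(), GRID_POINTS)
    smoothed = _loess(pc1, pc2, grid, span=span, degree=2)
    spline = np.column_stack([grid, smoothed])
    seg = np.linalg.norm(np.diff(spline, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])

    coords = np.array([_nearest_arc(spline, arc, p)[0] for p in scores])
    anchor = min(range(len(pseudobulk.unit_ids)), key=lambda i: pseudobulk.unit_ids[i])
    total = float(arc[-1])
    if total > 0 and coords[anchor] > total / 2:
        spline = spline[::-1].copy()
        seg = np.linalg.norm(np.diff(spline, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        coords = total - coords

    return ContinuumModel(
        genes=genes,
        gene_means=means,
        gene_sds=sds,
        pc_loadings=loadings,
        spline_points=spline,
        arc_lengths=arc,
        span=float(span),
        training_sample_ids=list(pseudobulk.unit_ids),
        training_coordinates=coords,
        explained_variance_ratio=evr,
    )


def _nearest_arc(
    spline: np.ndarray, arc: np.ndarray, point: np.ndarray
) -> tuple[float, float]:
    d = np.linalg.norm(spline - point[None, :], axis=1)
    best = float(d.min())
    # ties resolved toward the lower arc length
    i = int(np.flatnonzero(d <= best + 1e-12)[0])
    return float(arc[i]), best


def place_on_continuum(
    model: ContinuumModel, profiles: ExpressionMatrix
) -> list[ContinuumPlacement]:
    """Project profiles into the model's PC plane and read off arc lengths.

    Profiles must cover at least 50% of the model genes; absent genes are
    imputed at the training mean (z = 0). Each standardized profile is
    projected onto the training loadings and assigned the arc length of the
    nearest spline vertex (ties to the lower arc length); the residual is
    its distance to that vertex.
    """
    gene_pos = {g: i for i, g in enumerate(profiles.gene_ids)}
    present = [g for g in model.genes if g in gene_pos]
    overlap = len(present) / len(model.genes)
    if overlap < 0.5:
        raise SchemaError(
            f"profiles cover only {overlap:.1%} of the {len(model.genes)} model genes; "
            "need at least 50%"
        )
    n_units = len(profiles.unit_ids)
    z = np.zeros((len(model.genes), n_units))
    for mi, g in enumerate(model.genes):
        if g in gene_pos:
            z[mi] = (profiles.values[gene_pos[g]] - model.gene_means[mi]) / model.gene_sds[mi]
    scores = z.T @ model.pc_loadings.T
    total = model.total_arc_length
    out = []
    for sid, p in zip(profiles.unit_ids, scores):
        coord, resid = _nearest_arc(model.spline_points, model.arc_lengths, p)
        out.append(
            ContinuumPlacement(
                sample_id=sid,
                coordinate=coord,
                normalized=coord / total if total > 0 else 0.0,
                residual_distance=resid,
            )
        )
    return out


def fraction_trend(
    placements: Sequence[ContinuumPlacement],
    fractions: Mapping[str, Mapping[str, float]],
    grid_points: int = 50,
    span: float = 0.75,
) -> pd.DataFrame:
    """Immune-population fraction trends along the continuum coordinate.

    ``fractions`` maps population name → {sample_id → fraction in [0, 1]}.
    For each population, Spearman rho of fraction versus normalized
    coordinate is computed (constant inputs give rho = 0, p = 1) together
    with a loess-smoothed curve sampled at ``grid_points`` grid positions.

    Returns a tidy DataFrame with one row per (population, grid point),
    carrying ``rho`` and ``p`` on every row of its population.
    """
    coord = {p.sample_id: p.normalized for p in placements}
    rows = []
    for pop, by_sample in fractions.items():
        shared = [s for s in by_sample if s in coord]
        if len(shared) < 3:
            raise ValueError(f"population {pop!r}: need >=3 placed samples with fractions")
        f = np.array([by_sample[s] for s in shared], dtype=float)
        if ((f < 0) | (f > 1)).any():
            raise ValueError(f"population {pop!r}: fraction outside [0, 1]")
        x = np.array([coord[s] for s in shared])
        if np.ptp(f) == 0 or np.ptp(x) == 0:
            rho, p = 0.0, 1.0
        else:
            rho, p = stats.spearmanr(x, f)
            rho, p = float(rho), float(p)
        grid = np.linspace(x.min(), x.max(), grid_points)
        curve = _loess(x, f, grid, span=span, degree=2)
        for gx, gy in zip(grid, curve):
            rows.append(
                {"population": pop, "coordinate": gx, "smoothed_fraction": gy,
                 "rho": rho, "p": p}
            )
    return pd.DataFrame(rows)


def fit_cohort_continuum(
    counts_per_sample: Mapping[str, ExpressionMatrix],
    reference_sample: str | None = None,
    min_cells: int = 50,
    max_padj: float = 0.05,
    min_abs_lfc: float = 0.5,
    min_samples: int = 2,
    span: float = 0.75,
) -> tuple[ContinuumModel, list[ContinuumPlacement], GeneSet]:
    """End-to-end continuum fit from per-sample basal-cell count matrices.

    Each sample's cells are log-CPM normalized; every non-reference sample is
    tested against the reference sample's cells with the Wilcoxon engine (no
    pre-filter thresholds, so every informative gene is tested) and the
    natural-log fold changes are converted to log2 before the continuum gene
    filter. Pseudobulk is the per-sample mean of log-normalized expression
    over the selected genes. Returns the fitted model, training placements,
    and the selected gene set.
    """
    from epimm.io import normalize_log_cpm
    from epimm.signatures import rank_de_test

    sample_ids = list(counts_per_sample)
    if reference_sample is None:
        reference_sample = sample_ids[0]
    if reference_sample not in counts_per_sample:
        raise ValueError(f"reference sample {reference_sample!r} not in cohort")

    logged = {s: normalize_log_cpm(m) for s, m in counts_per_sample.items()}
    cell_counts = {s: len(m.unit_ids) for s, m in counts_per_sample.items()}

    ref = logged[reference_sample]
    de_tables: dict[str, pd.DataFrame] = {}
    for s in sample_ids:
        if s == reference_sample:
            continue
        samp = logged[s]
        genes = [g for g in samp.gene_ids if g in set(ref.gene_ids)]
        merged = ExpressionMatrix(
            genes,
            [f"{s}:{u}" for u in samp.unit_ids] + [f"ref:{u}" for u in ref.unit_ids],
            np.hstack(
                [
                    samp.to_frame().loc[genes].to_numpy(),
                    ref.to_frame().loc[genes].to_numpy(),
                ]
            ),
            "log_cpm",
        )
        tab = rank_de_test(
            merged,
            group_a=[f"{s}:{u}" for u in samp.unit_ids],
            group_b=[f"ref:{u}" for u in ref.unit_ids],
            min_lfc=0.0,
            min_pct=0.0,
            correction="bh",
        )
        tab = tab.assign(log_fc=tab["log_fc"] / math.log(2))  # natural log -> log2
        de_tables[s] = tab

    selected = select_continuum_genes(
        de_tables,
        {s: cell_counts[s] for s in de_tables},
        min_cells=min_cells,
        max_padj=max_padj,
        min_abs_lfc=min_abs_lfc,
        min_samples=min_samples,
    )

    cols = []
    for s in sample_ids:
        frame = logged[s].to_frame()
        cols.append(frame.reindex(list(selected.genes)).mean(axis=1).to_numpy())
    pseudobulk = ExpressionMatrix(
        list(selected.genes), sample_ids, np.column_stack(cols), "arbitrary"
    )
    model = fit_continuum(pseudobulk, span=span)
    placements = [
        ContinuumPlacement(
            sample_id=sid,
            coordinate=float(c),
            normalized=float(c) / model.total_arc_length if model.total_arc_length else 0.0,
            residual_distance=0.0,
        )
        for sid, c in zip(model.training_sample_ids, model.training_coordinates)
    ]
    return model, placements, selected
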