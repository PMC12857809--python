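"""Ligand-receptor weighted co-expression scores.

For ligand-receptor pair i in ROI j, the weighted co-expression score is

    P_ij = L_ij · R_ij / OR*_j

with L the ligand's expression in the ROI's epithelial region, R the
receptor's expression in the immune region, and OR*_j the ROI's geometric
interaction odds ratio. The per-ROI interaction score is the geometric mean
of the P values over the pairs scored, (∏ P_ij)^(1/n).

The OR* in the denominator must be positive: when a ROI's raw OR* is zero
(no across-type contacts) the Haldane-Anscombe-corrected OR* is used.
A zero ligand or receptor value propagates to a zero score (geometric-mean
semantics); an optional floor ε > 0 added to L and R keeps scores strictly
positive for callers who need that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from epimm.io import ExpressionMatrix, LRPanel, SchemaError
from epimm.odds import OddsResult


@dataclass(frozen=True)
class PairScore:
    """One ligand-receptor pair's weighted co-expression in one ROI."""

    roi_id: str
    ligand: str
    receptor: str
    L: float
    R: float
    or_star_used: float
    P: float


@dataclass(frozen=True)
class ROIInteractionScore:
    """Per-ROI geometric mean of weighted co-expression scores."""

    roi_id: str
    n_pairs_used: int
    score: float
    pair_scores: tuple[PairScore, ...] = ()
    skipped_pairs: tuple[tuple[str, str, str], ...] = ()


def pair_score(
    L: float, R: float, or_star: float, roi_id: str = "", ligand: str = "", receptor: str = ""
) -> PairScore:
    """Compute P = L·R / OR* for one pair in one ROI."""
    if L < 0 or R < 0:
        raise ValueError("ligand and receptor expression must be non-negative")
    if not or_star > 0:
        raise ValueError(
            "or_star must be positive; pass the Haldane-Anscombe-corrected OR* "
            "when the raw value is 0"
        )
    return PairScore(
        roi_id=roi_id, ligand=ligand, receptor=receptor,
        L=float(L), R=float(R), or_star_used=float(or_star),
        P=float(L) * float(R) / float(or_star),
    )


def _geometric_mean(values: list[float]) -> float:
    if any(v == 0 for v in values):
        return 0.0
    return math.exp(sum(math.log(v) for v in values) / len(values))


def aggregate_cells_to_roi(
    m: ExpressionMatrix, cells, cell_type: str
) -> ExpressionMatrix:
    """Collapse a cell-level matrix to ROI level by averaging one cell type.

    ``cells`` is a :class:`~epimm.io.CellTable` whose ``cell_id`` values match
    the matrix unit ids; per ROI, the mean expression over cells of
    ``cell_type`` becomes that ROI's column (region transcriptomes are
    aggregates, so ROI-level inputs are the native case and this helper covers
    cell-level ones).
    """
    sub = cells.data[cells.data["cell_type"] == cell_type]
    if len(sub) == 0:
        raise SchemaError(f"no cells of type {cell_type!r} in cell table")
    unit_pos = {u: i for i, u in enumerate(m.unit_ids)}
    missing = [c for c in sub["cell_id"] if c not in unit_pos]
    if missing:
        raise SchemaError(f"cell id(s) not in expression matrix: {missing[:5]}")
    rois = list(dict.fromkeys(sub["roi_id"]))
    cols = []
    for roi in rois:
        ids = sub.loc[sub["roi_id"] == roi, "cell_id"]
        cols.append(m.values[:, [unit_pos[c] for c in ids]].mean(axis=1))
    return ExpressionMatrix(m.gene_ids, rois, np.column_stack(cols), m.norm_state)


def roi_interaction_score(
    epi_expr: ExpressionMatrix,
    imm_expr: ExpressionMatrix,
    panel: LRPanel,
    odds: dict[str, OddsResult],
    floor: float = 0.0,
) -> list[ROIInteractionScore]:
    """Score every ROI shared by the two region matrices against a panel.

    Parameters
    ----------
    epi_expr, imm_expr
        ROI-level matrices (units are ROI ids) for the epithelial and immune
        regions; ligands are looked up in ``epi_expr``, receptors in
        ``imm_expr``. Unit ids must match and every ROI needs an entry in
        ``odds``.
    panel
        Ligand-receptor pairs. A pair whose ligand or receptor is absent from
        its matrix is skipped (with a reason) and n adjusted.
    floor
        Optional ε ≥ 0 added to every L and R before scoring (default 0).

    Returns one :class:`ROIInteractionScore` per ROI; ROIs with no usable
    pair get ``n_pairs_used=0`` and a NaN score with every pair listed as
    skipped.
    """
    if floor < 0:
        raise ValueError("floor must be non-negative")
    if set(epi_expr.unit_ids) != set(imm_expr.unit_ids):
        raise SchemaError("EPI and IMM matrices must share the same ROI ids")
    missing = [r for r in epi_expr.unit_ids if r not in odds]
    if missing:
        raise SchemaError(f"no odds result for ROI(s): {missing[:5]}")

    epi = epi_expr.to_frame()
    imm = imm_expr.to_frame()
    out: list[ROIInteractionScore] = []
    for roi in epi_expr.unit_ids:
        or_star = odds[roi].OR_star
        used: list[PairScore] = []
        skipped: list[tuple[str, str, str]] = []
        for lig, rec in panel.pairs:
            if lig not in epi.index:
                skipped.append((lig, rec, f"ligand {lig!r} absent from EPI matrix"))
                continue
            if rec not in imm.index:
                skipped.append((lig, rec, f"receptor {rec!r} absent from IMM matrix"))
                continue
            L = float(epi.at[lig, roi]) + floor
            R = float(imm.at[rec, roi]) + floor
            used.append(pair_score(L, R, or_star, roi_id=roi, ligand=lig, receptor=rec))
        if not used:
            out.append(ROIInteractionScore(
                roi_id=roi, n_pairs_used=0, score=math.nan,
                pair_scores=(), skipped_pairs=tuple(skipped),
            ))
            continue
        score = _geometric_mean([p.P for p in used])
        out.append(ROIInteractionScore(
            roi_id=roi, n_pairs_used=len(used), score=score,
            pair_scores=tuple(used), skipped_pairs=tuple(skipped),
        ))
    return out
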