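"""Gene-signature scoring, marker differential expression, and correlation.

Two single-sample scoring schemes are provided:

* :func:`module_score` — the binned-control scheme: genes are binned by
  average expression, each signature gene draws control genes from its own
  bin, and a unit's score is mean(signature) − mean(controls). The score is
  centered near zero for an uninformative signature and is invariant to
  adding a constant to the whole matrix.
* :func:`ssgsea_score` — a single-sample rank-enrichment statistic: per unit,
  genes are ranked by expression and the score is the sum over the ranked
  list of the gap between the weighted in-set cumulative fraction and the
  uniform out-of-set cumulative fraction (weights rank^alpha). Depends only
  on each unit's gene ranking, so it is invariant to per-unit monotone
  transforms.

Marker genes are found with a two-sided Wilcoxon rank-sum test gated by the
usual single-cell pre-filters (|log fold change| and percent-expressed), and
cross-region association uses Spearman correlation with an exact permutation
p-value at small n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from epimm.io import ExpressionMatrix, GeneSet, SchemaError


@dataclass
class SignatureScores:
    """Per-unit scores for one signature, with the parameters that made them."""

    signature: str
    unit_ids: list[str]
    scores: np.ndarray
    method: Literal["module_score", "ssgsea"]
    params: dict

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.unit_ids, name=self.signature)


def adjust_pvalues(p: np.ndarray, method: Literal["bonferroni", "bh"]) -> np.ndarray:
    """Multiple-testing adjustment over the tested genes only."""
    p = np.asarray(p, dtype=float)
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * p.size / (np.arange(p.size) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown correction {method!r}")


def module_score(
    m: ExpressionMatrix,
    sig: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> SignatureScores:
    """Binned-control module score per unit.

    All genes are cut into ``n_bins`` bins of equal size by their average
    expression across units; for each signature gene present, ``n_ctrl``
    control genes are drawn with replacement from its bin; the unit score is
    the mean over signature genes minus the mean over the pooled control
    draws. Input should be log-scale expression.
    """
    present = [g for g in sig.genes if g in set(m.gene_ids)]
    missing = [g for g in sig.genes if g not in set(m.gene_ids)]
    if not present:
        raise SchemaError(
            f"no gene of signature {sig.name!r} present in matrix; missing: {missing}"
        )
    if len(m.gene_ids) <= n_bins:
        raise SchemaError(
            f"matrix has {len(m.gene_ids)} genes; need more genes than n_bins={n_bins}"
        )
    gene_pos = m.gene_index()
    avg = m.values.mean(axis=1)
    # rank-based equal-size bins; ties broken by stable gene order
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(len(avg), dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(len(avg)) * n_bins) // len(avg), n_bins - 1
    )
    bins_members: dict[int, np.ndarray] = {
        b: np.flatnonzero(bin_of == b) for b in range(n_bins)
    }
    rng = np.random.default_rng(seed)
    ctrl_rows: list[np.ndarray] = []
    for g in present:
        gi = gene_pos[g]
        members = bins_members[bin_of[gi]]
        ctrl_rows.append(rng.choice(members, size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_rows)
    sig_idx = np.array([gene_pos[g] for g in present])
    scores = m.values[sig_idx].mean(axis=0) - m.values[ctrl_idx].mean(axis=0)
    return SignatureScores(
        signature=sig.name,
        unit_ids=list(m.unit_ids),
        scores=scores,
        method="module_score",
        params={
            "n_bins": n_bins,
            "n_ctrl": n_ctrl,
            "seed": seed,
            "n_genes_used": len(present),
            "missing_genes": missing,
        },
    )


def ssgsea_score(m: ExpressionMatrix, sig: GeneSet, alpha: float = 0.25) -> SignatureScores:
    """Single-sample rank-enrichment score per unit.

    Per unit, genes get ascending ranks by expression (highest expression =
    rank N, ties averaged). Walking the genes in descending expression order,
    the score accumulates, at each position, the difference between the
    in-set cumulative fraction of rank^alpha weights and the out-of-set
    uniform cumulative fraction.
    """
    gene_set = set(sig.genes)
    in_set = np.array([g in gene_set for g in m.gene_ids])
    if not in_set.any():
        raise SchemaError(f"no gene of signature {sig.name!r} present in matrix")
    if in_set.all():
        raise SchemaError(
            f"signature {sig.name!r} covers every matrix gene; complement is empty"
        )
    n_genes, n_units = m.shape
    n_out = int((~in_set).sum())
    scores = np.empty(n_units)
    for u in range(n_units):
        x = m.values[:, u]
        ranks = stats.rankdata(x)  # ascending, ties -> average rank
        order = np.argsort(-x, kind="stable")  # descending expression
        inset_ord = in_set[order]
        w = np.where(inset_ord, np.abs(ranks[order]) ** alpha, 0.0)
        w_total = w.sum()
        p_in = np.cumsum(w) / w_total
        p_out = np.cumsum(~inset_ord) / n_out
        scores[u] = float(np.sum(p_in - p_out))
    return SignatureScores(
        signature=sig.name,
        unit_ids=list(m.unit_ids),
        scores=scores,
        method="ssgsea",
        params={"alpha": alpha, "n_genes_used": int(in_set.sum())},
    )


def rank_de_test(
    m: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_lfc: float = 0.25,
    min_pct: float = 0.25,
    correction: Literal["bonferroni", "bh"] = "bonferroni",
) -> pd.DataFrame:
    """Threshold-gated two-sided Wilcoxon rank-sum differential expression.

    ``log_fc`` is the difference of group means of the (log-scale) input —
    group A minus group B — and ``pct_a``/``pct_b`` are the fractions of
    units with nonzero expression. Only genes with |log_fc| > ``min_lfc`` and
    max(pct) > ``min_pct`` are tested; the multiple-testing correction is
    applied over tested genes only. Set both thresholds to 0 to test every
    gene (the pre-filters then keep genes with any nonzero difference).

    Returns a DataFrame with columns gene, log_fc, pct_a, pct_b, p, p_adj,
    sorted by p then gene.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 units")
    A = m.subset_units(group_a).values
    B = m.subset_units(group_b).values
    log_fc = A.mean(axis=1) - B.mean(axis=1)
    pct_a = (A > 0).mean(axis=1)
    pct_b = (B > 0).mean(axis=1)
    tested = (np.abs(log_fc) > min_lfc) & (np.maximum(pct_a, pct_b) > min_pct)
    idx = np.flatnonzero(tested)
    if idx.size == 0:
        return pd.DataFrame(
            columns=["gene", "log_fc", "pct_a", "pct_b", "p", "p_adj"]
        ).astype({"gene": str})
    res = stats.mannwhitneyu(A[idx], B[idx], axis=1, alternative="two-sided")
    p = np.atleast_1d(res.pvalue)
    p_adj = adjust_pvalues(p, correction)
    out = pd.DataFrame(
        {
            "gene": [m.gene_ids[i] for i in idx],
            "log_fc": log_fc[idx],
            "pct_a": pct_a[idx],
            "pct_b": pct_b[idx],
            "p": p,
            "p_adj": p_adj,
        }
    )
    out.attrs["method"] = "wilcoxon"
    out.attrs["correction"] = correction
    return out.sort_values(["p", "gene"]).reset_index(drop=True)


def _spearman_rho(ra: np.ndarray, rb: np.ndarray) -> float:
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = math.sqrt(float(ra @ ra) * float(rb @ rb))
    if denom == 0:
        return 0.0
    return float(ra @ rb) / denom


def region_score_correlation(
    scores_a: SignatureScores,
    scores_b: SignatureScores,
    pairing: Mapping[str, str] | None = None,
) -> tuple[float, float]:
    """Spearman correlation of two signature scores over paired ROIs.

    ``pairing`` maps ``scores_a`` unit ids to ``scores_b`` unit ids (identity
    if omitted); units without a partner are dropped. Tie-corrected ranks are
    used; the two-sided p-value comes from the t approximation for n ≥ 10 and
    from the exact permutation distribution for n < 10. Constant inputs give
    rho = 0, p = 1.
    """
    sa = scores_a.to_series()
    sb = scores_b.to_series()
    if pairing is None:
        shared = [u for u in sa.index if u in set(sb.index)]
        pairs = [(u, u) for u in shared]
    else:
        pairs = [(a, b) for a, b in pairing.items() if a in sa.index and b in sb.index]
    if len(pairs) < 3:
        raise ValueError(f"need >=3 paired ROIs, got {len(pairs)}")
    x = np.array([sa[a] for a, _ in pairs], dtype=float)
    y = np.array([sb[b] for _, b in pairs], dtype=float)
    n = len(x)
    ra, rb = stats.rankdata(x), stats.rankdata(y)
    rho = _spearman_rho(ra, rb)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    if n >= 10:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        return rho, min(p, 1.0)
    # exact permutation: all n! orderings of one rank vector
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = _spearman_rho(ra, rb[list(perm)])
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / total
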