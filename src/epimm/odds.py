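"""Interaction odds, odds ratios, and the geometric odds ratio OR*.

For a two-type ROI with nA and nB cells of the two types, the possible
contact counts are NAB = nA·nB, NAA = nA(nA−1)/2 and NBB = nB(nB−1)/2. The
odds of each interaction class are the observed contacts over the remaining
possible contacts, Odds_XY = e_XY / (N_XY − e_XY), and the geometric odds
ratio compares across-type odds to the geometric mean of the within-type
odds::

    OR* = sqrt( (Odds_AB/Odds_AA) · (Odds_AB/Odds_BB) )
        = Odds_AB / sqrt(Odds_AA · Odds_BB)

OR* > 1 means the two types touch more than their within-type clustering
predicts; OR* < 1 means they segregate. When any odds is degenerate (a zero
or saturated count, or an empty denominator) a Haldane-Anscombe half-count
correction, odds = (e + 0.5)/(N − e + 0.5), is applied to all three odds so
the statistic stays finite and A↔B symmetric; the raw odds are still
reported alongside.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np

from epimm.spatial import EdgeCounts, SpatialGraph, classify_edges


@dataclass(frozen=True)
class OddsResult:
    """All odds / odds-ratio quantities for one ROI's two-type edge counts.

    ``odds_*`` are the values actually used downstream (corrected if
    ``corrected`` is set); ``odds_*_raw`` are the uncorrected ratios, which
    may be 0, inf, or nan in degenerate ROIs.
    """

    roi_id: str
    nA: int
    nB: int
    NAA: int
    NBB: int
    NAB: int
    eAA: int
    eBB: int
    eAB: int
    odds_AA: float
    odds_BB: float
    odds_AB: float
    odds_AA_raw: float
    odds_BB_raw: float
    odds_AB_raw: float
    OR_AB_AA: float
    OR_AB_BB: float
    OR_star: float
    corrected: bool


@dataclass(frozen=True)
class NullDistribution:
    """Label-permutation null for OR* on a fixed graph."""

    roi_id: str
    n_perm: int
    seed: int
    or_star_samples: np.ndarray
    observed_or_star: float
    empirical_p: float


def _raw_odds(e: int, N: int) -> float:
    if N == 0:
        return math.nan
    rem = N - e
    if rem == 0:
        return math.inf if e > 0 else math.nan
    return e / rem


def compute_interaction_odds(c: EdgeCounts) -> OddsResult:
    """Evaluate the odds, odds ratios, and OR* for one ROI's edge counts.

    The Haldane-Anscombe correction (add 0.5 to every numerator and
    remaining-possible denominator) triggers whenever any observed count is 0
    or saturates its possible-pair total, or any possible-pair total is 0;
    it is then applied to all three odds and ``corrected`` is set.
    """
    if c.nA < 1 or c.nB < 1:
        raise ValueError("both cell types must have at least one cell")
    NAA = c.nA * (c.nA - 1) // 2
    NBB = c.nB * (c.nB - 1) // 2
    NAB = c.nA * c.nB
    triples = ((c.eAB, NAB), (c.eAA, NAA), (c.eBB, NBB))
    corrected = any(N == 0 or e == 0 or e == N for e, N in triples)
    raw = [_raw_odds(e, N) for e, N in triples]
    if corrected:
        odds = [(e + 0.5) / (N - e + 0.5) for e, N in triples]
    else:
        odds = raw
    odds_AB, odds_AA, odds_BB = odds
    or_ab_aa = odds_AB / odds_AA
    or_ab_bb = odds_AB / odds_BB
    or_star = math.sqrt(or_ab_aa * or_ab_bb)
    return OddsResult(
        roi_id=c.roi_id,
        nA=c.nA, nB=c.nB, NAA=NAA, NBB=NBB, NAB=NAB,
        eAA=c.eAA, eBB=c.eBB, eAB=c.eAB,
        odds_AA=odds_AA, odds_BB=odds_BB, odds_AB=odds_AB,
        odds_AA_raw=raw[1], odds_BB_raw=raw[2], odds_AB_raw=raw[0],
        OR_AB_AA=or_ab_aa, OR_AB_BB=or_ab_bb, OR_star=or_star,
        corrected=corrected,
    )


def pool_edge_counts(counts: list[EdgeCounts], pooled_id: str = "pooled") -> EdgeCounts:
    """Sum edge and node counts across ROIs (e.g. all ROIs of one individual).

    All counts must use the same (type_a, type_b) labels. The pooled counts
    can then be passed to :func:`compute_interaction_odds` for a per-individual
    OR*.
    """
    if not counts:
        raise ValueError("no edge counts to pool")
    labels = {(c.type_a, c.type_b) for c in counts}
    if len(labels) > 1:
        raise ValueError(f"inconsistent type labels across ROIs: {sorted(labels)}")
    return EdgeCounts(
        type_a=counts[0].type_a,
        type_b=counts[0].type_b,
        nA=sum(c.nA for c in counts),
        nB=sum(c.nB for c in counts),
        eAA=sum(c.eAA for c in counts),
        eBB=sum(c.eBB for c in counts),
        eAB=sum(c.eAB for c in counts),
        roi_id=pooled_id,
    )


def _classify_fast(edge_types_a: np.ndarray, edge_types_b: np.ndarray,
                   labels: np.ndarray, type_a: str, type_b: str) -> tuple[int, int, int, int, int]:
    nA = int((labels == type_a).sum())
    nB = int((labels == type_b).sum())
    isa_a, isa_b = edge_types_a == type_a, edge_types_b == type_a
    isb_a, isb_b = edge_types_a == type_b, edge_types_b == type_b
    eAA = int((isa_a & isa_b).sum())
    eBB = int((isb_a & isb_b).sum())
    eAB = int(((isa_a & isb_b) | (isb_a & isa_b)).sum())
    return nA, nB, eAA, eBB, eAB


def permutation_null(
    g: SpatialGraph, type_a: str, type_b: str, n_perm: int, seed: int
) -> NullDistribution:
    """Random-labeling null distribution of OR* on a fixed proximity graph.

    The full cell-type label vector is permuted uniformly at random over the
    graph's nodes (the geometry never changes) ``n_perm`` times, recomputing
    OR* with the same correction policy each round. The one-sided empirical
    p-value uses the add-one convention,
    p = (1 + #{permuted OR* ≥ observed}) / (1 + n_perm), so it is never zero.

    Randomness comes from a counter-based Philox stream keyed by
    (seed, crc32(roi_id)), so different ROIs under one seed are independent
    and every run is reproducible.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = g.nodes["cell_type"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("permutation null requires at least 2 labels present")
    observed = compute_interaction_odds(classify_edges(g, type_a, type_b)).OR_star

    key = (int(seed) << 32) | zlib.crc32(g.roi_id.encode("utf-8"))
    rng = np.random.Generator(np.random.Philox(key=key))
    idx_pairs = g.edge_index_pairs()
    samples = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(labels)
        ta = perm[idx_pairs[:, 0]] if len(idx_pairs) else np.empty(0, object)
        tb = perm[idx_pairs[:, 1]] if len(idx_pairs) else np.empty(0, object)
        nA, nB, eAA, eBB, eAB = _classify_fast(ta, tb, perm, type_a, type_b)
        counts = EdgeCounts(type_a=type_a, type_b=type_b, nA=nA, nB=nB,
                            eAA=eAA, eBB=eBB, eAB=eAB, roi_id=g.roi_id)
        samples[k] = compute_interaction_odds(counts).OR_star
    empirical_p = (1 + int((samples >= observed).sum())) / (1 + n_perm)
    return NullDistribution(
        roi_id=g.roi_id, n_perm=n_perm, seed=int(seed),
        or_star_samples=samples, observed_or_star=observed, empirical_p=empirical_p,
    )
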