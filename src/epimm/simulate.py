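"""Seeded synthetic-data generators with known ground truth.

Three generators cover the pipeline's stages:

* :func:`simulate_spatial_roi` — two-type spatial point patterns with a
  mixing parameter λ: λ=0 places EPI and IMM in two well-separated Gaussian
  clusters (no across-type contacts at the default cutoff), λ=1 scatters
  both types uniformly (complete spatial randomness of labels), and
  intermediate λ contaminates each cell's cluster placement with uniform
  placement at probability λ. Across-type contact frequency rises
  monotonically with λ, which is what makes the pattern a usable ground
  truth for OR*.
* :func:`simulate_roi_expression` — paired EPI/IMM region expression whose
  ligand/receptor levels are log-linearly coupled (strength κ) to the ROI's
  geometric mixedness eAB/NAB, plus i.i.d. log-normal filler genes.
* :func:`simulate_continuum_cohort` — per-sample basal-cell count matrices
  whose two opposing gene modules shift log-linearly along a latent disease
  axis t ∈ [0, 1] (negative-binomial counts), with a designated immune
  population's fraction rising as 0.1 + 0.5·t plus Gaussian noise.

All generators are bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from epimm.io import CellTable, ExpressionMatrix, LRPanel
from epimm.spatial import build_proximity_graph, classify_edges


@dataclass(frozen=True)
class SpatialSimConfig:
    """Two-type spatial point pattern settings."""

    n_epi: int = 100
    n_imm: int = 100
    mixing: float = 0.5
    field_size: float = 1000.0
    cluster_sd: float = 50.0
    seed: int = 0
    roi_id: str = "sim_roi"
    type_a: str = "EPI"
    type_b: str = "IMM"

    def __post_init__(self) -> None:
        if self.n_epi < 1 or self.n_imm < 1:
            raise ValueError("cell counts must be >= 1")
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing must lie in [0, 1]")
        if self.field_size <= 0 or self.cluster_sd <= 0:
            raise ValueError("field_size and cluster_sd must be positive")


@dataclass(frozen=True)
class ContinuumSimConfig:
    """Continuum cohort settings.

    ``effect_size`` is the per-unit-t shift of module genes' log mean
    expression: module-A genes gain ``effect_size * t``, module-B genes lose
    it. ``nb_dispersion`` parameterizes negative-binomial counts with
    variance mean + mean²/dispersion.
    """

    n_samples: int = 20
    cells_per_sample: int = 200
    n_genes: int = 100
    module_size: int = 15
    effect_size: float = 1.5
    nb_dispersion: float = 10.0
    noise_sd: float = 0.02
    base_log_mean: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if 2 * self.module_size > self.n_genes:
            raise ValueError("need 2*module_size <= n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_samples < 2 or self.cells_per_sample < 1:
            raise ValueError("need >=2 samples and >=1 cell per sample")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


def simulate_spatial_roi(cfg: SpatialSimConfig) -> CellTable:
    """Draw one two-type ROI with mixing level λ.

    λ=0: the two types come from two Gaussian clusters whose centers sit
    ``8*cluster_sd + 50`` μm apart, so at the default 50 μm cutoff the types
    essentially never touch. λ=1: both types are uniform over the square
    field. In between, each cell is placed from its own type's cluster with
    probability 1−λ and uniformly otherwise.
    """
    rng = np.random.default_rng(cfg.seed)
    # 8 sd + cutoff: cells within 4 sd of their own center cannot form
    # across-type contacts at the default 50 um cutoff
    sep = 8 * cfg.cluster_sd + 50.0
    margin = 2 * cfg.cluster_sd
    if cfg.field_size < sep + 2 * margin:
        raise ValueError(
            f"field_size {cfg.field_size} too small to separate clusters "
            f"(need >= {sep + 2 * margin:.0f} um)"
        )
    mid = cfg.field_size / 2
    center_a = np.array([mid - sep / 2, mid])
    center_b = np.array([mid + sep / 2, mid])

    rows = []
    for label, n, center in (
        (cfg.type_a, cfg.n_epi, center_a),
        (cfg.type_b, cfg.n_imm, center_b),
    ):
        from_cluster = rng.random(n) >= cfg.mixing
        xy = np.empty((n, 2))
        k = int(from_cluster.sum())
        xy[from_cluster] = rng.normal(center, cfg.cluster_sd, size=(k, 2))
        xy[~from_cluster] = rng.uniform(0, cfg.field_size, size=(n - k, 2))
        for i, (x, y) in enumerate(xy):
            rows.append(
                {
                    "roi_id": cfg.roi_id,
                    "cell_id": f"{label}_{i}",
                    "x": x,
                    "y": y,
                    "cell_type": label,
                }
            )
    return CellTable(pd.DataFrame(rows))


def simulate_roi_expression(
    cells_by_roi: dict[str, CellTable] | CellTable,
    panel: LRPanel,
    coupling: float = 2.0,
    base: float = 10.0,
    seed: int = 0,
    n_filler_genes: int = 10,
    max_edge_len: float = 50.0,
    type_a: str = "EPI",
    type_b: str = "IMM",
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Generate paired ROI-level EPI/IMM matrices coupled to spatial mixing.

    Each ROI's geometric mixedness is eAB/NAB from its pruned Delaunay graph.
    Ligand values (EPI matrix) and receptor values (IMM matrix) are
    ``base * exp(coupling * mixedness + noise)`` with log-normal noise of
    sd 0.1; filler genes are i.i.d. log-normal around ``base``.
    """
    if coupling < 0:
        raise ValueError("coupling must be >= 0")
    if isinstance(cells_by_roi, CellTable):
        cells_by_roi = {r: cells_by_roi.for_roi(r) for r in cells_by_roi.roi_ids}
    rng = np.random.default_rng(seed)
    roi_ids = list(cells_by_roi)
    mixedness = {}
    for roi, tab in cells_by_roi.items():
        g = build_proximity_graph(tab, max_edge_len=max_edge_len)
        c = classify_edges(g, type_a, type_b)
        nab = c.nA * c.nB
        mixedness[roi] = c.eAB / nab if nab else 0.0

    ligands = [l for l, _ in panel.pairs]
    receptors = [r for _, r in panel.pairs]
    fillers = [f"FILLER{i}" for i in range(n_filler_genes)]

    def _matrix(signal_genes: list[str]) -> ExpressionMatrix:
        genes = list(dict.fromkeys(signal_genes)) + fillers
        vals = np.empty((len(genes), len(roi_ids)))
        for j, roi in enumerate(roi_ids):
            mix = mixedness[roi]
            for i, g in enumerate(genes):
                noise = rng.normal(0.0, 0.1)
                if g in signal_genes:
                    vals[i, j] = base * np.exp(coupling * mix + noise)
                else:
                    vals[i, j] = base * np.exp(noise)
        return ExpressionMatrix(genes, roi_ids, vals, "arbitrary")

    return _matrix(ligands), _matrix(receptors)


def simulate_continuum_cohort(
    cfg: ContinuumSimConfig,
) -> tuple[dict[str, ExpressionMatrix], dict[str, float], dict[str, dict[str, float]]]:
    """Generate a continuum cohort with known latent disease positions.

    Samples receive evenly spaced latent positions t ∈ [0, 1] (t_1 = 0,
    t_n = 1). Gene log-means start at ``base_log_mean``; the first
    ``module_size`` genes (module A) gain ``effect_size * t`` and the next
    ``module_size`` (module B) lose it. Counts are negative binomial with
    the configured dispersion. The tracked immune population's fraction is
    0.1 + 0.5·t + N(0, noise_sd), truncated to [0, 1].

    Returns (counts per sample, true t per sample, immune fractions per
    population per sample).
    """
    rng = np.random.default_rng(cfg.seed)
    t_values = np.linspace(0.0, 1.0, cfg.n_samples)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    log_mu0 = np.full(cfg.n_genes, cfg.base_log_mean)
    direction = np.zeros(cfg.n_genes)
    direction[: cfg.module_size] = 1.0
    direction[cfg.module_size : 2 * cfg.module_size] = -1.0

    counts: dict[str, ExpressionMatrix] = {}
    true_t: dict[str, float] = {}
    fractions: dict[str, float] = {}
    for i, t in enumerate(t_values):
        sid = f"S{i:02d}"
        mu = np.exp(log_mu0 + cfg.effect_size * t * direction)
        # NB(mean, dispersion): var = mu + mu^2/dispersion
        p = cfg.nb_dispersion / (cfg.nb_dispersion + mu)
        vals = rng.negative_binomial(
            cfg.nb_dispersion, p[:, None], size=(cfg.n_genes, cfg.cells_per_sample)
        ).astype(float)
        counts[sid] = ExpressionMatrix(
            genes, [f"{sid}_c{j}" for j in range(cfg.cells_per_sample)], vals, "raw_counts"
        )
        true_t[sid] = float(t)
        frac = float(np.clip(0.1 + 0.5 * t + rng.normal(0.0, cfg.noise_sd), 0.0, 1.0))
        fractions[sid] = frac
    return counts, true_t, {"tracked_population": fractions}
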