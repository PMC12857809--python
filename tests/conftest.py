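import numpy as np
import pandas as pd
import pytest

from epimm import CellTable, ExpressionMatrix
from epimm.spatial import EdgeCounts

# 6-cell ROI whose pruned (50 um) Delaunay graph has, for types A/B,
# nA=3, nB=3, eAA=2, eBB=1, eAB=4 -- the hand-worked odds example.
FIXTURE_6CELL = pd.DataFrame(
    {
        "roi_id": "fix",
        "cell_id": [f"c{i}" for i in range(6)],
        "x": [112.9, 110.6, 91.7, 66.2, 46.3, 116.0],
        "y": [66.1, 40.4, 91.6, 20.9, 34.9, 77.4],
        "cell_type": ["A", "A", "A", "B", "B", "B"],
    }
)


@pytest.fixture
def six_cell_table() -> CellTable:
    return CellTable(FIXTURE_6CELL.copy())


@pytest.fixture
def worked_counts() -> EdgeCounts:
    """Edge counts of the hand-worked odds example."""
    return EdgeCounts(type_a="A", type_b="B", nA=3, nB=3, eAA=2, eBB=1, eAB=4)


@pytest.fixture
def right_triangle() -> CellTable:
    """Cells at (0,0), (30,0), (0,40): edge lengths 30, 40, 50."""
    return CellTable(
        pd.DataFrame(
            {
                "roi_id": "tri",
                "cell_id": ["a", "b", "c"],
                "x": [0.0, 30.0, 0.0],
                "y": [0.0, 0.0, 40.0],
                "cell_type": ["A", "A", "B"],
            }
        )
    )


def make_matrix(values, genes=None, units=None, norm_state="arbitrary"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    units = units or [f"u{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, units, values, norm_state)


@pytest.fixture
def matrix_factory():
    return make_matrix
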