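import numpy as np
import pandas as pd
import pytest

from senuro.spatial_enrichment import SpatialField
from senuro.synthetic_data import SimConfig


@pytest.fixture
def small_cfg():
    """Default study-condition configuration with a fixed seed."""
    return SimConfig(seed=1)


def random_small_field(rng: np.random.Generator) -> SpatialField:
    """A random field with <= 200 cells and <= 2000 CLU transcripts."""
    n_cells = int(rng.integers(20, 201))
    n_tx = int(rng.integers(100, 2001))
    size = 300.0
    cell_ids = [f"c{i}" for i in range(n_cells)]
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "x": rng.uniform(0, size, n_cells),
            "y": rng.uniform(0, size, n_cells),
            "cell_type": rng.choice(["PT", "LOH_DCT", "other"], n_cells),
        }
    )
    counts = pd.DataFrame(
        {"CDKN1A": rng.integers(0, 5, n_cells), "CLU": 0},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    transcripts = pd.DataFrame(
        {"gene": "CLU", "x": rng.uniform(0, size, n_tx),
         "y": rng.uniform(0, size, n_tx)}
    )
    return SpatialField(cells=cells, counts=counts, transcripts=transcripts)


def brute_force_profile(
    field: SpatialField,
    query_ids,
    gene: str = "CLU",
    r_max: float = 50.0,
    step: float = 1.0,
    n_background: int = 10_000,
    seed: int = 0,
):
    """Independent quadratic-time radial-enrichment reference.

    Computes every cell-transcript distance directly (no spatial index) and
    applies the annulus/density definitions from first principles:
    annulus k covers ((k-1)*step, k*step]; density = (count + 1) / (annulus
    area * number of centroids); enrichment = log2(query / background).
    """
    cells = field.cells.set_index("cell_id")
    q_xy = cells.loc[list(query_ids), ["x", "y"]].to_numpy(float)
    tx = field.transcripts[field.transcripts["gene"] == gene]
    t_xy = tx[["x", "y"]].to_numpy(float)
    n_pop = len(field.cells)
    if n_background >= n_pop:
        b_xy = field.cells[["x", "y"]].to_numpy(float)
    else:
        pick = np.random.default_rng(seed).choice(
            n_pop, size=n_background, replace=False
        )
        b_xy = field.cells[["x", "y"]].to_numpy(float)[pick]

    n_bins = int(round(r_max / step))

    def density(centroids):
        total = np.zeros(n_bins)
        for cx, cy in centroids:
            d = np.sqrt((t_xy[:, 0] - cx) ** 2 + (t_xy[:, 1] - cy) ** 2)
            d = d[d <= r_max]
            k = np.maximum(np.ceil(d / step).astype(int), 1)
            np.add.at(total, k - 1, 1.0)
        dens = np.empty(n_bins)
        for k in range(1, n_bins + 1):
            area = np.pi * ((k * step) ** 2 - ((k - 1) * step) ** 2)
            dens[k - 1] = (total[k - 1] + 1.0) / (float(len(centroids)) * area)
        return dens

    q = density(q_xy)
    b = density(b_xy)
    return q, b, np.log2(q / b)
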