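"""Positivity rule, radial enrichment vs brute force, Wilcoxon DE."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from senuro.core_io import InputError
from senuro.spatial_enrichment import (
    GeneNotFoundError,
    SpatialField,
    classify_positive,
    de_wilcoxon,
    radial_enrichment,
)

from conftest import brute_force_profile, random_small_field


def tiny_field(cell_xy, tx_xy, cdkn1a=None):
    n = len(cell_xy)
    ids = [f"c{i}" for i in range(n)]
    cells = pd.DataFrame(
        {"cell_id": ids, "x": [p[0] for p in cell_xy],
         "y": [p[1] for p in cell_xy], "cell_type": "PT"}
    )
    counts = pd.DataFrame(
        {"CDKN1A": cdkn1a if cdkn1a is not None else [0] * n, "CLU": 0},
        index=pd.Index(ids, name="cell_id"),
    )
    transcripts = pd.DataFrame(
        {"gene": "CLU", "x": [p[0] for p in tx_xy], "y": [p[1] for p in tx_xy]}
    )
    return SpatialField(cells=cells, counts=counts, transcripts=transcripts)


class TestClassifyPositive:
    def test_threshold_inclusive(self):
        field = tiny_field([(0, 0), (1, 1), (2, 2)], [(0, 0)], cdkn1a=[2, 1, 3])
        assert classify_positive(field) == {"c0", "c2"}

    def test_empty_field(self):
        field = tiny_field([(0, 0)], [(0, 0)], cdkn1a=[0])
        assert classify_positive(field) == set()

    def test_absent_gene(self):
        field = tiny_field([(0, 0)], [(0, 0)])
        with pytest.raises(GeneNotFoundError):
            classify_positive(field, gene="NOPE")


class TestRadialEnrichment:
    def test_self_comparison_is_zero(self):
        rng = np.random.default_rng(0)
        field = random_small_field(rng)
        all_ids = field.cells["cell_id"].tolist()
        prof = radial_enrichment(field, all_ids, n_background=10**9, seed=0)
        assert np.allclose(prof.e, 0.0)

    def test_single_cell_first_annulus_density(self):
        # one query cell at the origin, one transcript at distance 0.5:
        # T(1) = 1 so q(1) = (1+1)/(pi*1) = 2/pi
        field = tiny_field([(0.0, 0.0), (100.0, 100.0), (200.0, 0.0)],
                           [(0.5, 0.0)])
        prof = radial_enrichment(field, ["c0"], r_max=5, step=1,
                                 n_background=10**9, seed=0)
        assert prof.q[0] == pytest.approx(2.0 / math.pi)
        q, b, e = brute_force_profile(field, ["c0"], r_max=5, step=1, seed=0)
        np.testing.assert_array_equal(prof.e, e)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        field = random_small_field(rng)
        query = field.cells["cell_id"].tolist()[:10]
        prof = radial_enrichment(field, query, n_background=50, seed=9)
        shifted = SpatialField(
            cells=field.cells.assign(x=field.cells.x + 1000,
                                     y=field.cells.y + 1000),
            counts=field.counts,
            transcripts=field.transcripts.assign(
                x=field.transcripts.x + 1000, y=field.transcripts.y + 1000
            ),
        )
        prof2 = radial_enrichment(shifted, query, n_background=50, seed=9)
        np.testing.assert_allclose(prof.e, prof2.e, atol=1e-9)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(4)
        field = random_small_field(rng)
        query = field.cells["cell_id"].tolist()[:8]
        prof = radial_enrichment(field, query, n_background=10**9, seed=0)
        c, s = math.cos(0.7), math.sin(0.7)
        rot_cells = field.cells.assign(
            x=c * field.cells.x - s * field.cells.y,
            y=s * field.cells.x + c * field.cells.y,
        )
        rot_tx = field.transcripts.assign(
            x=c * field.transcripts.x - s * field.transcripts.y,
            y=s * field.transcripts.x + c * field.transcripts.y,
        )
        rotated = SpatialField(cells=rot_cells, counts=field.counts,
                               transcripts=rot_tx)
        prof2 = radial_enrichment(rotated, query, n_background=10**9, seed=0)
        np.testing.assert_allclose(prof.e, prof2.e, atol=1e-7)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        field = random_small_field(rng)
        n_query = int(rng.integers(1, 15))
        query = list(rng.choice(field.cells["cell_id"], n_query, replace=False))
        n_bg = int(rng.integers(10, len(field.cells) + 50))
        prof = radial_enrichment(field, query, n_background=n_bg, seed=seed)
        q, b, e = brute_force_profile(field, query, n_background=n_bg, seed=seed)
        np.testing.assert_array_equal(prof.q, q)
        np.testing.assert_array_equal(prof.b, b)
        np.testing.assert_array_equal(prof.e, e)

    def test_annulus_cells_normalization_option(self):
        rng = np.random.default_rng(11)
        field = random_small_field(rng)
        query = field.cells["cell_id"].tolist()[:5]
        prof = radial_enrichment(field, query, n_background=10**9, seed=0,
                                 normalize_by="annulus_cells")
        assert np.all(np.isfinite(prof.e))

    def test_empty_query_rejected(self):
        rng = np.random.default_rng(12)
        field = random_small_field(rng)
        with pytest.raises(InputError):
            radial_enrichment(field, [], seed=0)

    def test_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(13)
        field = random_small_field(rng)
        field.to_csv(tmp_path / "cells.csv", tmp_path / "tx.csv")
        back = SpatialField.from_csv(tmp_path / "cells.csv", tmp_path / "tx.csv")
        pd.testing.assert_frame_equal(
            back.counts, field.counts, check_dtype=False
        )
        assert len(back.transcripts) == len(field.transcripts)


def wilcoxon_exact_oracle(pos, neg):
    """Two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([pos, neg])
    n1 = len(pos)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    centre = n1 * (len(neg)) / 2.0
    dev = abs(u_obs - centre)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        hits += abs(u - centre) >= dev - 1e-12
        total += 1
    return hits / total


class TestDeWilcoxon:
    def test_identical_groups(self):
        out = de_wilcoxon(pd.DataFrame({"G": [1, 2, 3, 4]}),
                          pd.DataFrame({"G": [1, 2, 3, 4]}))
        assert out.loc[0, "p"] == pytest.approx(1.0, abs=0.05)
        assert out.loc[0, "log2fc"] == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "pos,neg",
        [((5, 6, 7), (1, 2, 3)), ((1, 4, 6, 9), (2, 3, 5)), ((10, 20), (1, 2, 3, 4))],
    )
    def test_matches_exact_enumeration(self, pos, neg):
        out = de_wilcoxon(pd.DataFrame({"G": list(pos)}),
                          pd.DataFrame({"G": list(neg)}))
        assert out.loc[0, "p"] == pytest.approx(
            wilcoxon_exact_oracle(np.array(pos, float), np.array(neg, float)),
            rel=1e-9,
        )

    def test_shift_invariance_of_ranks(self):
        pos, neg = [3.0, 7.0, 9.0, 4.0], [1.0, 2.0, 8.0]
        a = de_wilcoxon(pd.DataFrame({"G": pos}), pd.DataFrame({"G": neg}))
        b = de_wilcoxon(pd.DataFrame({"G": [v + 100 for v in pos]}),
                        pd.DataFrame({"G": [v + 100 for v in neg]}))
        assert a.loc[0, "statistic"] == b.loc[0, "statistic"]
        assert a.loc[0, "p"] == b.loc[0, "p"]

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            de_wilcoxon(pd.DataFrame({"G": []}), pd.DataFrame({"G": [1.0]}))

    def test_bh_across_genes(self):
        rng = np.random.default_rng(2)
        pos = pd.DataFrame(rng.poisson(3, size=(20, 4)), columns=list("ABCD"))
        neg = pd.DataFrame(rng.poisson(3, size=(20, 4)), columns=list("ABCD"))
        out = de_wilcoxon(pos, neg)
        assert (out["p_adj"] >= out["p"] - 1e-12).all()
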