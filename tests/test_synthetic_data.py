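import numpy as np
import pytest

import topoga as tg
from topoga.distmap_core import binarize_cells, map_cells, top_k_bins
from topoga.synthetic_data import (
    SyntheticConfig,
    make_atlas,
    make_cells,
    make_geometry,
    make_instance,
    write_instance,
)


class TestGeometry:
    def test_deterministic_under_seed(self):
        cfg = SyntheticConfig(n_bins=50, seed=3)
        g1 = make_geometry(cfg, np.random.default_rng(3))
        g2 = make_geometry(cfg, np.random.default_rng(3))
        np.testing.assert_array_equal(g1.coords, g2.coords)

    def test_half_embryo_convention(self):
        cfg = SyntheticConfig(n_bins=80, seed=1)
        geom = make_geometry(cfg, np.random.default_rng(1))
        assert (geom.coords[:, 1] >= 0).all()

    def test_pairwise_distances_positive(self):
        cfg = SyntheticConfig(n_bins=40, seed=2)
        geom = make_geometry(cfg, np.random.default_rng(2))
        from scipy.spatial.distance import pdist

        assert (pdist(geom.coords) > 0).all()


class TestAtlas:
    def test_informative_genes_have_moderate_prevalence(self):
        cfg = SyntheticConfig(n_bins=150, n_informative_genes=15, seed=4)
        rng = np.random.default_rng(4)
        geom = make_geometry(cfg, rng)
        atlas, flags = make_atlas(cfg, geom, rng)
        for g, row in zip(atlas.gene_ids, atlas.values):
            if flags[g]:
                assert 0.1 <= row.mean() <= 0.9

    def test_gradient_gene_splits_bins_near_median(self):
        cfg = SyntheticConfig(
            n_bins=100, n_informative_genes=1, n_noise_genes=0,
            pattern_kinds=("gradient",), seed=6,
        )
        rng = np.random.default_rng(6)
        geom = make_geometry(cfg, rng)
        atlas, _ = make_atlas(cfg, geom, rng)
        # a monotone field thresholded at quantile q leaves ~(1-q) positives;
        # whatever q was drawn, positives must match the field's order stat
        frac = atlas.values[0].mean()
        assert 0.1 <= frac <= 0.9

    def test_noise_genes_lack_spatial_autocorrelation(self):
        """Join-count check: a noise gene's positives are not spatially
        clustered relative to permutations of the same labels."""
        cfg = SyntheticConfig(
            n_bins=150, n_informative_genes=1, n_noise_genes=1, seed=8
        )
        rng = np.random.default_rng(8)
        geom = make_geometry(cfg, rng)
        atlas, flags = make_atlas(cfg, geom, rng)
        noise_row = atlas.values[
            [i for i, g in enumerate(atlas.gene_ids) if not flags[g]][0]
        ]
        from scipy.spatial import cKDTree

        tree = cKDTree(geom.coords)
        pairs = tree.query_pairs(r=0.4, output_type="ndarray")

        def join_count(labels):
            return int((labels[pairs[:, 0]] == labels[pairs[:, 1]]).sum())

        observed = join_count(noise_row)
        perm_rng = np.random.default_rng(99)
        perms = np.array(
            [join_count(perm_rng.permutation(noise_row)) for _ in range(200)]
        )
        p = (perms >= observed).mean()
        assert p > 0.01  # not significantly clustered

    def test_stripe_gene_alternates_along_x(self):
        cfg = SyntheticConfig(
            n_bins=200, n_informative_genes=2, n_noise_genes=0,
            pattern_kinds=("stripe",), seed=12,
        )
        rng = np.random.default_rng(12)
        geom = make_geometry(cfg, rng)
        atlas, _ = make_atlas(cfg, geom, rng)
        order = np.argsort(geom.coords[:, 0])
        calls = atlas.values[0][order]
        transitions = int(np.abs(np.diff(calls.astype(int))).sum())
        # a striped pattern changes state along x more than a single gradient
        assert transitions >= 3


class TestCells:
    def test_noiseless_cells_recover_atlas_columns(self):
        cfg = SyntheticConfig(
            n_bins=40, n_cells=60, n_informative_genes=10, n_noise_genes=0,
            dropout_rate=0.0, flip_rate=0.0, seed=21,
        )
        atlas, geom, expr, truth = make_instance(cfg)
        # each gene's separating quantile is its off-state fraction over the
        # sampled cells; binarizing there recovers the atlas column almost
        # perfectly (residual errors are the on/off count-overlap tails)
        latent = atlas.values[:, truth.true_bins]
        recovered = np.zeros_like(latent)
        for gi in range(latent.shape[0]):
            q = latent[gi].mean()
            off_frac = 1.0 - q
            if off_frac <= 0.0 or off_frac >= 1.0:
                recovered[gi] = int(off_frac <= 0.0)
                continue
            thr = np.quantile(expr.values[gi], off_frac, method="lower")
            recovered[gi] = expr.values[gi] > thr
        agreement = np.mean(recovered == latent)
        # the emission model's intrinsic confusion at these defaults:
        # P(on-count <= 2) ~ 0.13 and P(off-count > 2) ~ 0.027 for
        # NB(size 2, mu 10 / 0.5), so per-entry Bayes error is ~8%
        assert agreement > 0.88

    def test_heavy_dropout_yields_mostly_zeros(self):
        cfg = SyntheticConfig(
            n_bins=30, n_cells=100, n_informative_genes=10,
            n_noise_genes=10, dropout_rate=0.8, seed=22,
        )
        _, _, expr, _ = make_instance(cfg)
        assert (expr.values == 0).mean() >= 0.7

    def test_same_seed_identical_matrix(self):
        cfg = SyntheticConfig(n_bins=25, n_cells=30, seed=5)
        _, _, e1, t1 = make_instance(cfg)
        _, _, e2, t2 = make_instance(cfg)
        np.testing.assert_array_equal(e1.values, e2.values)
        np.testing.assert_array_equal(t1.true_bins, t2.true_bins)

    def test_rates_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(dropout_rate=1.0)
        with pytest.raises(ValueError):
            SyntheticConfig(flip_rate=-0.1)


class TestEndToEndRecovery:
    def test_gold_mapping_ranks_true_bin_in_top10(self):
        """With >=20 informative genes and moderate noise, the full-panel
        mapping puts most cells' true bin within their top-10 candidates —
        the property that makes the gold standard meaningful."""
        # informative-only panel: decoy genes carry no positional signal by
        # construction, so they do not belong in a gold-meaningfulness check
        cfg = SyntheticConfig(
            n_bins=100, n_cells=150, n_informative_genes=30,
            n_noise_genes=0, dropout_rate=0.2, flip_rate=0.02, seed=33,
        )
        atlas, geom, expr, truth = make_instance(cfg)
        cells = binarize_cells(expr)
        gold = map_cells(cells, atlas)
        top10 = top_k_bins(gold, 10)
        hit = np.mean(
            [truth.true_bins[i] in top10[i] for i in range(cfg.n_cells)]
        )
        assert hit >= 0.8

    def test_informative_subset_beats_noise_subset(self):
        """Fitness separation: informative genes reproduce the gold mapping
        strictly better than an equal-size noise subset."""
        cfg = SyntheticConfig(
            n_bins=80, n_cells=100, n_informative_genes=12, n_noise_genes=12,
            dropout_rate=0.2, flip_rate=0.02, seed=44,
        )
        atlas, geom, expr, truth = make_instance(cfg)
        ev = tg.build_evaluator(atlas, geom, expr)
        info_idx = tuple(
            i for i, g in enumerate(atlas.gene_ids) if truth.informative[g]
        )[:8]
        noise_idx = tuple(
            i for i, g in enumerate(atlas.gene_ids) if not truth.informative[g]
        )[:8]
        assert (
            ev.fitness(info_idx).composite < ev.fitness(noise_idx).composite
        )


class TestWriteInstance:
    def test_files_written_and_readable(self, tmp_path):
        from topoga.io_formats import read_atlas, read_geometry, read_matrix

        cfg = SyntheticConfig(n_bins=20, n_cells=15, n_informative_genes=6,
                              n_noise_genes=2, seed=9)
        atlas, geom, expr, truth = write_instance(cfg, tmp_path)
        back_atlas = read_atlas(tmp_path / "atlas.tsv")
        back_geom = read_geometry(tmp_path / "geometry.tsv")
        back_expr = read_matrix(tmp_path / "dge.tsv")
        np.testing.assert_array_equal(back_atlas.values, atlas.values)
        np.testing.assert_allclose(back_geom.coords, geom.coords, atol=1e-9)
        assert back_expr.gene_ids == expr.gene_ids
        assert (tmp_path / "truth.tsv").exists()
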