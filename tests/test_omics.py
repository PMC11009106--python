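"""Spot-table filtering, normalization, gene selection, rasterization."""

import numpy as np
import pytest

from landreg.omics import (
    SpotTable,
    filter_spots_genes,
    normalize_log,
    pca_rgb,
    raster_transform,
    rasterize_spots,
    read_spot_csv,
    select_genes,
)


def _table(counts, coords=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    if coords is None:
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, size=(n, 2))
    return SpotTable(
        spot_ids=np.array([f"s{i}" for i in range(n)]),
        coordinates=coords,
        counts=counts,
        gene_ids=np.array([f"g{j}" for j in range(g)]),
    )


def _brute_force_filter(counts, min_genes, min_spots):
    """Exhaustive recount oracle: repeat both passes until stable."""
    counts = np.asarray(counts)
    spots = np.ones(counts.shape[0], bool)
    genes = np.ones(counts.shape[1], bool)
    changed = True
    while changed:
        changed = False
        for i in np.flatnonzero(spots):
            if (counts[i][genes] > 0).sum() < min_genes:
                spots[i] = False
                changed = True
        for j in np.flatnonzero(genes):
            if (counts[:, j][spots] > 0).sum() < min_spots:
                genes[j] = False
                changed = True
    return spots, genes


class TestFiltering:
    def test_underdetected_spot_removed(self):
        counts = np.array([
            [5, 3, 2, 0, 1],
            [1, 1, 1, 1, 0],
            [2, 0, 3, 4, 5],
            [0, 7, 0, 0, 2],  # spot D: 2 detected genes
        ])
        out = filter_spots_genes(_table(counts), min_genes_per_spot=3, min_spots_per_gene=2)
        assert "s3" not in out.spot_ids

    def test_permissive_thresholds_identity(self):
        counts = np.ones((4, 5), int)
        out = filter_spots_genes(_table(counts), 1, 1)
        assert out.counts.shape == (4, 5)

    def test_cascade_matches_brute_force(self):
        gen = np.random.default_rng(13)
        counts = (gen.uniform(size=(6, 6)) > 0.5).astype(int) * gen.integers(1, 5, (6, 6))
        # craft a cascade: removing a spot drops a gene below threshold
        counts[0] = [1, 1, 0, 0, 0, 0]
        counts[:, 0] = [1, 1, 0, 0, 0, 0]
        t = _table(counts)
        spots, genes = _brute_force_filter(counts, 3, 2)
        if not spots.any() or not genes.any():
            pytest.skip("degenerate craft")
        out = filter_spots_genes(t, 3, 2)
        assert list(out.spot_ids) == [f"s{i}" for i in np.flatnonzero(spots)]
        assert list(out.gene_ids) == [f"g{j}" for j in np.flatnonzero(genes)]

    def test_idempotent_fixed_point(self):
        gen = np.random.default_rng(17)
        counts = gen.integers(0, 3, size=(10, 8))
        counts[counts.sum(axis=1) == 0, 0] = 1
        out = filter_spots_genes(_table(counts), 2, 2)
        again = filter_spots_genes(out, 2, 2)
        assert np.array_equal(out.counts, again.counts)

    def test_all_filtered_raises(self):
        counts = np.zeros((3, 3), int)
        counts[0, 0] = 1
        with pytest.raises(ValueError, match="thresholds"):
            filter_spots_genes(_table(counts), 3, 3)


class TestNormalize:
    def test_single_spot_log1p_only(self):
        counts = np.array([[1, 2, 3]])
        out = normalize_log(_table(counts))
        assert np.allclose(out, np.log1p([1, 2, 3]))

    def test_totals_scaled_to_median(self):
        counts = np.array([[50, 50], [150, 150]])
        out = normalize_log(_table(counts))
        # median total = 200; both spots scaled to total 200 pre-log
        assert np.allclose(np.expm1(out).sum(axis=1), 200.0)

    def test_matches_direct_loop(self, rng):
        counts = rng.integers(0, 20, size=(6, 5))
        counts[:, 0] += 1
        t = _table(counts)
        out = normalize_log(t)
        totals = counts.sum(axis=1).astype(float)
        target = np.median(totals)
        want = np.empty_like(out)
        for i in range(6):
            for j in range(5):
                want[i, j] = np.log1p(counts[i, j] * target / totals[i])
        assert np.allclose(out, want, atol=1e-10)

    def test_zeros_preserved(self, rng):
        counts = rng.integers(0, 5, size=(5, 6))
        counts[:, 0] += 1
        out = normalize_log(_table(counts))
        assert np.all((out == 0) == (counts == 0))


class TestSelectGenes:
    def test_two_forced_clusters_match_t_ranking(self):
        """With a forced two-group labeling the per-cluster |t| rankings
        coincide, so the union equals the global top-n by |t|."""
        gen = np.random.default_rng(5)
        base = gen.integers(1, 10, size=(20, 12))
        base[:10, :3] += 30  # genes 0-2 mark group 1
        t = _table(base)
        labels = np.array([1] * 10 + [0] * 10)
        got = select_genes([t], n_top=3, cluster_labels=[labels])
        # brute-force Welch t on the normalized matrix
        expr = normalize_log(t)
        m1, m2 = expr[:10], expr[10:]
        tt = (m1.mean(0) - m2.mean(0)) / np.sqrt(m1.var(0, ddof=1) / 10 + m2.var(0, ddof=1) / 10)
        want = sorted(t.gene_ids[np.argsort(np.abs(tt))[::-1][:3]])
        assert got == want

    def test_full_n_top_gives_shared_genes(self):
        gen = np.random.default_rng(6)
        t1 = _table(gen.integers(1, 9, size=(12, 6)))
        t2 = _table(gen.integers(1, 9, size=(12, 6)))
        labels = [np.array([0] * 6 + [1] * 6)] * 2
        got = select_genes([t1, t2], n_top=6, cluster_labels=labels)
        assert got == sorted(t1.gene_ids)

    def test_identical_samples_idempotent(self):
        gen = np.random.default_rng(7)
        counts = gen.integers(1, 9, size=(14, 8))
        counts[:7, :2] += 25
        t = _table(counts)
        labels = np.array([0] * 7 + [1] * 7)
        single = select_genes([t], n_top=2, cluster_labels=[labels])
        double = select_genes([t, t], n_top=2, cluster_labels=[labels, labels])
        assert single == double

    def test_leiden_path_runs_deterministically(self):
        gen = np.random.default_rng(8)
        counts = gen.integers(0, 6, size=(60, 20))
        counts[:30, :5] += 20
        counts[30:, 5:10] += 20
        counts[counts.sum(axis=1) == 0, 0] += 1
        t = _table(counts)
        g1 = select_genes([t], n_top=5, seed=0)
        g2 = select_genes([t], n_top=5, seed=0)
        assert g1 == g2 and len(g1) >= 5


class TestRasterize:
    def test_barycentric_centroid_third(self):
        coords = np.array([[0.0, 0.0], [30.0, 0.0], [0.0, 30.0]])
        t = _table(np.ones((3, 1), int), coords)
        img = rasterize_spots(t, np.array([0.0, 0.0, 1.0]), grid_size=64, margin=0.0)
        origin, spacing = raster_transform(coords, 64, margin=0.0)
        centroid_px = ((coords.mean(axis=0) - origin) / spacing).astype(int)
        got = img[centroid_px[1], centroid_px[0], 0]
        assert got == pytest.approx(1 / 3, abs=0.05)

    def test_spot_pixel_value(self):
        coords = np.array([[0.0, 0.0], [15.0, 0.0], [0.0, 15.0], [15.0, 15.0]])
        vals = np.array([0.0, 2.0, 6.0, 8.0])
        t = _table(np.ones((4, 1), int), coords)
        img = rasterize_spots(t, vals, grid_size=16, margin=0.0)
        # grid aligns exactly with the spot lattice here
        assert img[0, 0, 0] == pytest.approx(0.0, abs=1e-6)
        assert img[0, 15, 0] == pytest.approx(0.25, abs=1e-6)
        assert img[15, 0, 0] == pytest.approx(0.75, abs=1e-6)
        assert img[15, 15, 0] == pytest.approx(1.0, abs=1e-6)

    def test_constant_channel_maps_to_zero(self):
        coords = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        t = _table(np.ones((3, 1), int), coords)
        img = rasterize_spots(t, np.full(3, 5.0), grid_size=8)
        assert np.all(img == 0.0)

    def test_output_in_unit_interval(self, rng):
        coords = rng.uniform(0, 50, size=(20, 2))
        t = _table(np.ones((20, 2), int), coords)
        img = rasterize_spots(t, rng.uniform(-5, 5, size=(20, 2)), grid_size=32)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_collinear_rejected(self):
        coords = np.stack([np.arange(5.0), np.arange(5.0)], axis=1)
        t = _table(np.ones((5, 1), int), coords)
        with pytest.raises(ValueError, match="collinear"):
            rasterize_spots(t, np.arange(5.0), grid_size=8)


class TestPcaRgb:
    def test_duplicate_channels_first_component_dominates(self, rng):
        base = rng.uniform(0.2, 1.0, size=(16, 16, 1))
        img = np.repeat(base, 4, axis=2)
        with pytest.warns(RuntimeWarning, match="rank"):
            out = pca_rgb(img)
        assert out.shape == (16, 16, 3)
        # a single underlying channel: everything lands in component 1
        assert np.all(out[:, :, 1:] == 0.0)

    def test_matches_covariance_eigen_oracle(self, rng):
        img = rng.uniform(0.15, 1.0, size=(12, 12, 5))
        out = pca_rgb(img, threshold=0.1)
        pixels = img.reshape(-1, 5)
        centered = pixels - pixels.mean(axis=0)
        cov = centered.T @ centered / len(pixels)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:3]
        for c, oi in enumerate(order):
            vec = evecs[:, oi]
            if vec.sum() < 0:
                vec = -vec
            proj = centered @ vec
            want = (proj - proj.min()) / (proj.max() - proj.min())
            assert np.allclose(out[:, :, c].ravel(), want, atol=1e-8)

    def test_rank_deficient_pads_and_warns(self, rng):
        ch = rng.uniform(0.2, 1.0, size=(8, 8))
        img = np.stack([ch, ch, ch], axis=2)
        with pytest.warns(RuntimeWarning, match="rank"):
            out = pca_rgb(img)
        assert np.all(out[:, :, 1:] == 0.0)

    def test_background_stays_zero(self, rng):
        img = rng.uniform(0.3, 1.0, size=(10, 10, 4))
        img[:3, :3] = 0.0
        out = pca_rgb(img)
        assert np.all(out[:3, :3] == 0.0)


class TestIO:
    def test_csv_roundtrip(self, tmp_path, rng):
        import pandas as pd

        counts = rng.integers(0, 9, size=(5, 4))
        ids = [f"s{i}" for i in range(5)]
        genes = [f"g{j}" for j in range(4)]
        pd.DataFrame(counts, index=ids, columns=genes).to_csv(tmp_path / "c.csv")
        pd.DataFrame(
            {"spot_id": ids, "x": rng.uniform(size=5), "y": rng.uniform(size=5)}
        ).to_csv(tmp_path / "xy.csv", index=False)
        t = read_spot_csv(tmp_path / "c.csv", tmp_path / "xy.csv")
        assert np.array_equal(t.counts, counts)
        assert list(t.gene_ids) == genes
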