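"""Vegetation/soil classification, audit statistics and row extraction."""

import numpy as np
import pytest

from rugosa.cloud import ColoredPointCloud
from rugosa.segment import (audit_classification, classify_vegetation,
                            drop_border_rows, extract_rows)
from rugosa.synth import FieldSpec, generate_field


def cloud_with_green(greens):
    g = np.asarray(greens, dtype=np.uint8)
    rgb = np.column_stack([np.full_like(g, 80), g, np.full_like(g, 60)])
    xyz = np.column_stack([np.arange(len(g), dtype=float),
                           np.zeros(len(g)), np.zeros(len(g))])
    return ColoredPointCloud(xyz, rgb)


def ridge_cloud(centers, length=2.0, width=0.3, pts_per_ridge=400, seed=0,
                z=0.5):
    rng = np.random.default_rng(seed)
    parts = []
    for c in centers:
        x = rng.uniform(c - width / 2, c + width / 2, pts_per_ridge)
        y = rng.uniform(0, length, pts_per_ridge)
        parts.append(np.column_stack([x, y, np.full(pts_per_ridge, z)]))
    xyz = np.vstack(parts)
    return ColoredPointCloud(xyz, np.full((len(xyz), 3), 150, dtype=np.uint8))


class TestClassify:
    def test_cutoff_sides(self):
        cl = classify_vegetation(cloud_with_green([200, 50]))
        assert cl.n_vegetation == 1 and cl.n_soil == 1
        assert cl.vegetation.rgb[0, 1] == 200

    def test_boundary_value_is_vegetation(self):
        cl = classify_vegetation(cloud_with_green([115]))
        assert cl.n_vegetation == 1

    def test_direction_flag_inverts(self):
        cl = classify_vegetation(cloud_with_green([200, 50]),
                                 direction="veg_lt_cutoff")
        assert cl.vegetation.rgb[0, 1] == 50

    def test_exact_partition_and_idempotence(self):
        cloud = cloud_with_green(np.linspace(0, 255, 64).astype(int))
        cl = classify_vegetation(cloud)
        assert cl.n_vegetation + cl.n_soil == len(cloud)
        again = classify_vegetation(cl.vegetation)
        assert again.n_vegetation == cl.n_vegetation

    def test_generator_labels_recovered_exactly(self):
        spec = FieldSpec(n_plots=2, row_length=1.0, base_density=200,
                         n_outliers=0, dropout_fraction=0.0, seed=8)
        cloud, _, truth = generate_field(spec)
        cl = classify_vegetation(cloud)
        np.testing.assert_array_equal(cl.vegetation_mask,
                                      truth.vegetation_mask)


class TestAudit:
    def test_perfect_agreement(self):
        cloud = cloud_with_green([200] * 30 + [50] * 30)
        cl = classify_vegetation(cloud)
        acc, kappa = audit_classification(cl, cl.vegetation_mask, n_sample=60)
        assert acc == 1.0 and kappa == 1.0

    def test_all_one_class_prediction_has_zero_kappa(self):
        cloud = cloud_with_green([200] * 50)  # predicts all vegetation
        cl = classify_vegetation(cloud)
        truth = np.zeros(50, dtype=bool)
        truth[:25] = True  # balanced truth
        acc, kappa = audit_classification(cl, truth, n_sample=50)
        assert acc == pytest.approx(0.5)
        assert kappa == pytest.approx(0.0)

    def test_known_error_rate_matches_confusion_arithmetic(self):
        rng = np.random.default_rng(3)
        n = 4000
        greens = np.where(rng.random(n) < 0.5, 200, 50).astype(int)
        cloud = cloud_with_green(greens)
        cl = classify_vegetation(cloud)
        truth = cl.vegetation_mask.copy()
        flip = rng.random(n) < 0.05
        truth = truth ^ flip  # 5% symmetric label error
        acc, kappa = audit_classification(cl, truth, n_sample=1000, seed=11)
        assert abs(acc - 0.95) < 3 * np.sqrt(0.05 * 0.95 / 1000)
        # hand-computed kappa on the realized sampled table
        idx = np.random.default_rng(11).choice(n, size=1000, replace=False)
        t, p = truth[idx], cl.vegetation_mask[idx]
        po = (t == p).mean()
        pe = t.mean() * p.mean() + (1 - t.mean()) * (1 - p.mean())
        assert kappa == pytest.approx((po - pe) / (1 - pe), abs=1e-12)

    def test_sample_capped_at_population(self):
        cloud = cloud_with_green([200, 50, 120])
        cl = classify_vegetation(cloud)
        acc, _ = audit_classification(cl, cl.vegetation_mask, n_sample=10_000)
        assert acc == 1.0


class TestExtractRows:
    def test_two_ridges_at_row_spacing(self):
        cloud = ridge_cloud([0.0, 0.76])
        rows = extract_rows(cloud, grid_step=0.15, min_cluster_size=50)
        assert len(rows) == 2
        assert rows[0].mean_cross_row < rows[1].mean_cross_row

    def test_cluster_size_threshold_boundary(self):
        rng = np.random.default_rng(0)
        big = rng.uniform(0, 0.1, size=(50, 3))
        small = rng.uniform(0, 0.1, size=(49, 3)) + [5.0, 0, 0]
        xyz = np.vstack([big, small])
        cloud = ColoredPointCloud(xyz, np.zeros((99, 3), dtype=np.uint8))
        rows = extract_rows(cloud, grid_step=0.15, min_cluster_size=50)
        assert len(rows) == 1
        assert len(rows[0].points) == 50

    def test_single_ridge_single_cluster(self):
        cloud = ridge_cloud([0.0])
        rows = extract_rows(cloud)
        assert len(rows) == 1
        assert len(rows[0].points) == len(cloud)

    def test_matches_brute_force_flood_fill(self):
        cloud = ridge_cloud([0.0, 0.76, 1.52], pts_per_ridge=150, seed=4)
        rows = extract_rows(cloud, min_cluster_size=1)

        # independent 26-connectivity flood fill over occupied voxels
        origin = cloud.xyz.min(axis=0)
        vox = np.floor((cloud.xyz - origin) / 0.15).astype(int)
        cells = {tuple(v) for v in vox}
        comp_of = {}
        comp = 0
        for cell in sorted(cells):
            if cell in comp_of:
                continue
            stack = [cell]
            comp_of[cell] = comp
            while stack:
                cx, cy, cz = stack.pop()
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            nb = (cx + dx, cy + dy, cz + dz)
                            if nb in cells and nb not in comp_of:
                                comp_of[nb] = comp
                                stack.append(nb)
            comp += 1
        assert len(rows) == comp
        # same point partition (compare as sets of frozensets)
        got = {frozenset(map(tuple, r.points.xyz)) for r in rows}
        want = {}
        for p, v in zip(cloud.xyz, vox):
            want.setdefault(comp_of[tuple(v)], []).append(tuple(p))
        assert got == {frozenset(v) for v in want.values()}

    def test_translation_by_grid_multiple_is_invariant(self):
        cloud = ridge_cloud([0.0, 0.76], seed=2)
        rows_a = extract_rows(cloud)
        rows_b = extract_rows(cloud.translated([0.45, 0.15, 0.3]))
        assert len(rows_a) == len(rows_b)
        for a, b in zip(rows_a, rows_b):
            np.testing.assert_allclose(b.points.xyz - [0.45, 0.15, 0.3],
                                       a.points.xyz, atol=1e-12)

    def test_bad_inputs(self):
        cloud = ridge_cloud([0.0])
        with pytest.raises(ValueError):
            extract_rows(cloud, grid_step=0.0)
        from rugosa.cloud import empty_cloud
        with pytest.raises(ValueError):
            extract_rows(empty_cloud())


class TestDropBorderRows:
    def test_eight_rows_give_six(self):
        cloud = ridge_cloud([i * 0.76 for i in range(8)], pts_per_ridge=120)
        rows = extract_rows(cloud)
        assert len(rows) == 8
        interior = drop_border_rows(rows)
        assert len(interior) == 6
        outer = [r.mean_cross_row for r in rows]
        inner = [r.mean_cross_row for r in interior]
        assert min(inner) > min(outer) and max(inner) < max(outer)

    def test_three_rows_give_one(self):
        cloud = ridge_cloud([0, 0.76, 1.52])
        assert len(drop_border_rows(extract_rows(cloud))) == 1

    def test_fewer_than_three_rows_rejected(self):
        cloud = ridge_cloud([0, 0.76])
        with pytest.raises(ValueError):
            drop_border_rows(extract_rows(cloud))
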