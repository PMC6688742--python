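"""Resampling inference: permutation null, bootstrap ratios, clustering."""

from collections import deque

import numpy as np
import pytest

from plscvbm import (
    BootstrapResult,
    CohortSpec,
    ConfoundSpec,
    PlantedComponent,
    bootstrap_weights,
    cluster_z_map,
    default_u_true,
    fit_plsc,
    generate_cohort,
    permutation_test,
    prepare_blocks,
)
from plscvbm.inference import Z_CAP
from plscvbm.plsc import cross_product_svd
from plscvbm.preprocess import build_voxel_block


class TestPermutation:
    def test_strong_signal_reaches_formula_boundary(self, small_blocks):
        xb, yb, _, _ = small_blocks
        res = permutation_test(xb.X, yb.Y, R=2, n_permutations=200, seed=0)
        assert res.p_values[0] == 0.0
        assert res.resolution == pytest.approx(1 / 200)
        assert res.summary()["p_display"].iloc[0] == "<0.005"
        assert res.null_delta.shape == (200, 2)
        # null rows are sorted non-negative singular values
        assert (res.null_delta >= 0).all()
        assert (np.diff(res.null_delta, axis=1) <= 1e-9).all()

    def test_joint_permutation_leaves_delta_unchanged(self, random_blocks):
        x, y = random_blocks
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(x))
        _, s0, _ = cross_product_svd(x, y)
        _, s1, _ = cross_product_svd(x[perm], y[perm])
        np.testing.assert_allclose(s0, s1, atol=1e-9)

    def test_determinism(self, random_blocks):
        x, y = random_blocks
        a = permutation_test(x, y, n_permutations=50, seed=3)
        b = permutation_test(x, y, n_permutations=50, seed=3)
        np.testing.assert_array_equal(a.null_delta, b.null_delta)
        np.testing.assert_array_equal(a.p_values, b.p_values)

    def test_p_value_monotone_in_planted_rho(self):
        medians = []
        for rho in (0.0, 0.3, 0.6):
            ps = []
            for seed in range(5):
                spec = CohortSpec(
                    n_subjects=120,
                    grid_shape=(8, 8, 6),
                    planted_components=(
                        PlantedComponent(default_u_true(), rho=rho),
                    ),
                    seed=300 + seed,
                )
                c = generate_cohort(spec)
                xb, yb, _, _ = prepare_blocks(
                    c.table, c.gmv, c.mask_probability, c.affine
                )
                ps.append(
                    permutation_test(
                        xb.X, yb.Y, R=1, n_permutations=100, seed=seed
                    ).p_values[0]
                )
            medians.append(np.median(ps))
        assert medians[0] >= medians[1] >= medians[2]

    def test_invalid_parameters(self, random_blocks):
        x, y = random_blocks
        with pytest.raises(ValueError, match="n_permutations"):
            permutation_test(x, y, n_permutations=0)
        with pytest.raises(ValueError, match="R must lie"):
            permutation_test(x, y, R=50, n_permutations=10)


class TestBootstrap:
    def test_stability_threshold_arithmetic(self):
        res = BootstrapResult(
            n_bootstraps=10,
            se_u=np.array([[0.25]]),
            se_v=np.array([[0.1]]),
            z_u=np.array([[0.5 / 0.25]]),
            z_v=np.array([[3.0]]),
            z_threshold=2.3,
            seed=0,
        )
        assert res.z_u[0, 0] == pytest.approx(2.0)
        assert not res.stable_mask_u[0, 0]  # Z = 2.0 < 2.3 -> unstable
        assert res.stable_mask_v[0, 0]

    def test_noiseless_rank_one_data_caps_z_and_flags(self):
        spec = CohortSpec(
            n_subjects=60,
            grid_shape=(8, 8, 6),
            planted_components=(PlantedComponent(default_u_true(), rho=1.0),),
            confounds=ConfoundSpec(
                age_on_x=0.0, sex_on_x=0.0, age_on_y=0.0, sex_on_y=0.0, tiv_on_y=0.0
            ),
            x_noise_sd=0.0,
            y_noise_sd=0.0,
            seed=17,
        )
        c = generate_cohort(spec)
        xb, yb, _, _ = prepare_blocks(c.table, c.gmv, c.mask_probability, c.affine)
        model = fit_plsc(xb.X, yb.Y, R=1)
        res = bootstrap_weights(xb.X, yb.Y, n_bootstraps=30, seed=1, model=model)
        # weights are identical in every resample: SE ~ 0, Z capped + flagged
        nonzero = np.abs(model.U[:, 0]) > 1e-6
        assert (np.abs(res.z_u[nonzero, 0]) == Z_CAP).all()
        assert res.degenerate_u[nonzero, 0].all()

    def test_alignment_keeps_bootstrap_mean_close_to_original(self, small_blocks):
        xb, yb, _, _ = small_blocks
        model = fit_plsc(xb.X, yb.Y, R=2, column_names=xb.column_names)
        res = bootstrap_weights(xb.X, yb.Y, n_bootstraps=100, seed=2, model=model)
        r = np.corrcoef(res.mean_u[:, 0], model.U[:, 0])[0, 1]
        assert r > 0.9

    def test_determinism_and_seed_sensitivity(self, small_blocks):
        xb, yb, _, _ = small_blocks
        a = bootstrap_weights(xb.X, yb.Y, R=1, n_bootstraps=20, seed=5)
        b = bootstrap_weights(xb.X, yb.Y, R=1, n_bootstraps=20, seed=5)
        c = bootstrap_weights(xb.X, yb.Y, R=1, n_bootstraps=20, seed=6)
        np.testing.assert_array_equal(a.z_u, b.z_u)
        assert not np.array_equal(a.z_u, c.z_u)


def _flood_fill_clusters(binary: np.ndarray, connectivity: int):
    """Brute-force BFS labeling oracle."""
    if connectivity == 6:
        offsets = [
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
        ]
    else:
        offsets = [
            (i, j, k)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
    visited = np.zeros_like(binary, dtype=bool)
    clusters = []
    for start in map(tuple, np.argwhere(binary)):
        if visited[start]:
            continue
        queue, members = deque([start]), []
        visited[start] = True
        while queue:
            pos = queue.popleft()
            members.append(pos)
            for off in offsets:
                nb = tuple(p + o for p, o in zip(pos, off))
                if all(0 <= n < s for n, s in zip(nb, binary.shape)):
                    if binary[nb] and not visited[nb]:
                        visited[nb] = True
                        queue.append(nb)
        clusters.append(frozenset(members))
    return set(clusters)


def _full_block(shape=(16, 16, 16)):
    imgs = np.zeros((2, *shape))
    _, block = build_voxel_block(imgs, np.ones(shape), np.diag([2.0, 2.0, 2.0, 1.0]))
    return block


class TestClusters:
    def test_subthreshold_map_yields_empty_set(self):
        block = _full_block((6, 6, 6))
        cs = cluster_z_map(np.full(block.v, 3.0), block, threshold=5.0)
        assert len(cs) == 0 and cs.total_voxels == 0

    def test_single_contiguous_block(self):
        block = _full_block((8, 8, 8))
        z = np.zeros(block.v)
        vol = block.to_volume(z)
        vol[2:4, 3:8, 4] = 6.0
        vol[3, 3, 4] = 7.5
        cs = cluster_z_map(vol[block.mask], block, threshold=5.0)
        assert len(cs) == 1
        c = cs.clusters[0]
        assert c.size == 10
        assert c.peak_index == (3, 3, 4)
        assert c.peak_abs_z == pytest.approx(7.5)
        np.testing.assert_allclose(c.peak_mm, block.peak_mm((3, 3, 4)))

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_agrees_with_flood_fill_oracle(self, connectivity):
        block = _full_block()
        rng = np.random.default_rng(11)
        for _ in range(5):
            z = rng.normal(0, 3, size=block.v)
            cs = cluster_z_map(z, block, threshold=5.0, connectivity=connectivity)
            binary = np.abs(block.to_volume(z)) > 5.0
            oracle = _flood_fill_clusters(binary, connectivity)
            found = {
                frozenset(map(tuple, np.argwhere(cs.label_volume == lab)))
                for lab in range(1, len(cs) + 1)
            }
            assert found == oracle
            assert cs.total_voxels == int(binary.sum())

    def test_negative_peaks_counted_by_absolute_value(self):
        block = _full_block((6, 6, 6))
        vol = np.zeros((6, 6, 6))
        vol[1, 1, 1] = -8.0
        cs = cluster_z_map(vol[block.mask], block, threshold=5.0)
        assert len(cs) == 1
        assert cs.clusters[0].peak_z == pytest.approx(-8.0)
        assert cs.clusters[0].peak_abs_z == pytest.approx(8.0)

    def test_sorted_by_size_descending(self):
        block = _full_block((10, 10, 10))
        vol = np.zeros((10, 10, 10))
        vol[0:2, 0, 0] = 6.0  # size 2
        vol[5:9, 5, 5] = 6.0  # size 4
        cs = cluster_z_map(vol[block.mask], block, threshold=5.0)
        assert [c.size for c in cs.clusters] == [4, 2]

    def test_invalid_inputs(self):
        block = _full_block((4, 4, 4))
        with pytest.raises(ValueError, match="threshold"):
            cluster_z_map(np.zeros(block.v), block, threshold=0.0)
        with pytest.raises(ValueError, match="connectivity"):
            cluster_z_map(np.zeros(block.v), block, connectivity=18)
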