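"""Voxel-wise analysis, FWE/FDR correction, normalization, image I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import kinherit as kh
from kinherit.imagewise import (
    ImageStack,
    _label_clusters,
    _connectivity_structure,
    forming_threshold,
    read_image_stack,
    write_stat_image,
)


@pytest.fixture(scope="module")
def small_stack(eig138, design138):
    """A 5x5x2 (=50 voxel) stack with mixed null/heritable voxels."""
    X, beta = design138
    stack = kh.simulate_image(
        0.3, (5, 5, 2), fwhm_mm=0.0, eig=eig138, X=X, beta=beta, seed=61,
        domain="original",
    )
    return stack


class TestVoxelwise:
    def test_vectorized_equals_per_voxel_loop(self, small_stack, eig138, design138):
        """The image engine reproduces the univariate pipeline voxel by voxel."""
        X, _ = design138
        stat = kh.voxelwise_analysis(small_stack, X, eig138, test_kind="score")
        Y = small_stack.flat()
        Xs, lam = eig138.S.T @ X, eig138.lambda_g
        got_T = stat.maps["stat"][small_stack.mask]
        got_h2 = stat.maps["h2_wls"][small_stack.mask]
        got_h2ml = stat.maps["h2_ml"][small_stack.mask]
        for v in range(Y.shape[1]):
            tm = kh.TransformedModel(eig138.S.T @ Y[:, v], Xs[:, :], lam)
            assert got_T[v] == pytest.approx(
                kh.compute_test(tm, "score").statistic, abs=1e-10
            )
            assert got_h2[v] == pytest.approx(kh.fit(tm, "wls").h2, abs=1e-10)
            assert got_h2ml[v] == pytest.approx(kh.fit(tm, "ml").h2, abs=1e-10)

    def test_duplicated_voxels_identical(self, eig138, design138):
        X, beta = design138
        y = kh.simulate_phenotype(0.4, eig138, X, beta, seed=3)
        data = np.tile(y, (1, 2, 1, 1)).transpose(1, 2, 0, 3).reshape(1, 2, 1, 138)
        data = np.broadcast_to(y, (1, 2, 1, 138)).copy()
        stack = ImageStack(data=data, mask=np.ones((1, 2, 1), bool))
        stat = kh.voxelwise_analysis(
            stack, X, eig138, test_kind="score",
            plan=kh.PermutationPlan(m=50, seed=4),
        )
        flat = stat.maps["stat"][stack.mask]
        assert flat[0] == flat[1]
        assert (
            stat.maps["p_perm"][stack.mask][0] == stat.maps["p_perm"][stack.mask][1]
        )

    def test_masked_voxels_are_nan(self, eig138, design138, rng):
        X, _ = design138
        data = rng.standard_normal((3, 3, 1, 138))
        mask = np.zeros((3, 3, 1), bool)
        mask[0, :2, 0] = True
        stack = ImageStack(data=data, mask=mask)
        stat = kh.voxelwise_analysis(stack, X, eig138, test_kind="score")
        assert np.isnan(stat.maps["stat"][~mask]).all()
        assert np.isfinite(stat.maps["stat"][mask]).all()

    def test_empty_mask_raises(self, rng):
        with pytest.raises(ValueError, match="empty"):
            ImageStack(data=rng.standard_normal((2, 2, 1, 5)), mask=np.zeros((2, 2, 1), bool))


class TestVoxelFWE:
    def test_single_voxel_equals_uncorrected(self, eig138, design138):
        X, beta = design138
        y = kh.simulate_phenotype(0.5, eig138, X, beta, seed=8)
        stack = ImageStack(data=y.reshape(1, 1, 1, 138), mask=np.ones((1, 1, 1), bool))
        plan = kh.PermutationPlan(m=100, seed=9)
        stat = kh.voxelwise_analysis(stack, X, eig138, test_kind="score", plan=plan)
        assert stat.maps["p_fwe"][0, 0, 0] == stat.maps["p_perm"][0, 0, 0]

    def test_fwe_dominates_uncorrected(self, small_stack, eig138, design138):
        X, _ = design138
        plan = kh.PermutationPlan(m=60, seed=10)
        stat = kh.voxelwise_analysis(small_stack, X, eig138, test_kind="score", plan=plan)
        mask = small_stack.mask
        assert np.all(stat.maps["p_fwe"][mask] >= stat.maps["p_perm"][mask] - 1e-12)

    def test_voxel_fwe_counts(self):
        p = kh.voxel_fwe(np.array([5.0, 1.0, 0.0]), np.array([0.5, 2.0, 6.0, 1.0]))
        assert np.allclose(p, [1 / 4, 3 / 4, 1.0])


def flood_fill_components(binary, connectivity):
    """BFS connected-components oracle over an explicit neighbor stencil."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(binary, dtype=bool)
    sizes = []
    dims = binary.shape
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        size = 0
        while queue:
            pos = queue.pop()
            size += 1
            for off in offsets:
                nb = tuple(p + o for p, o in zip(pos, off))
                if all(0 <= n < d for n, d in zip(nb, dims)) and binary[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        sizes.append(size)
    return sorted(sizes)


class TestClusters:
    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_labeling_matches_flood_fill(self, connectivity, rng):
        for _ in range(5):
            binary = rng.random((10, 10, 5)) < 0.35
            labels, n = _label_clusters(
                binary.astype(float), np.ones_like(binary, dtype=bool), 0.5,
                _connectivity_structure(connectivity),
            )
            sizes = sorted(np.bincount(labels.ravel())[1:].tolist()) if n else []
            assert sizes == flood_fill_components(binary, connectivity)

    def test_empty_and_singleton(self):
        mask = np.ones((4, 4, 2), bool)
        perm_maps = np.zeros((10, 32))
        flat_stat = np.zeros(32)
        stat_map = np.zeros((4, 4, 2))
        table = kh.cluster_fwe(
            stat_map, mask, forming_p=0.01, connectivity=26,
            perm_stat_maps=perm_maps, kind="score", X=np.ones((20, 1)),
            lam=np.linspace(0.5, 1.5, 20),
        )
        assert len(table) == 0
        stat_map[1, 1, 1] = 50.0
        table = kh.cluster_fwe(
            stat_map, mask, forming_p=0.01, connectivity=26,
            perm_stat_maps=perm_maps, kind="score", X=np.ones((20, 1)),
            lam=np.linspace(0.5, 1.5, 20),
        )
        assert len(table) == 1
        assert table.table["size"].iloc[0] == 1

    def test_forming_threshold_matches_parametric_p(self):
        thr = forming_threshold("score", 0.01, np.ones((20, 3)), np.linspace(0.5, 1.5, 20))
        # p of the threshold statistic must equal the forming p
        assert 0.5 * sps.chi2.sf(thr, 1) == pytest.approx(0.01)
        lam = np.linspace(0.5, 1.5, 20)
        thr_gq = forming_threshold("gq", 0.05, np.ones((20, 3)), lam)
        n_A = int(np.sum(lam > 1))
        assert sps.f.sf(thr_gq, n_A - 3, 20 - n_A - 3) == pytest.approx(0.05)

    def test_invalid_forming_p(self):
        with pytest.raises(ValueError):
            forming_threshold("score", 0.7, np.ones((10, 1)), np.ones(10))


class TestFDR:
    def test_known_cases(self):
        q = kh.fdr_bh(np.full(100, 0.01))
        assert np.all(q <= 0.05)
        q = kh.fdr_bh(np.array([0.001, 0.02, 0.8]))
        assert (q[:2] <= 0.05).all() and q[2] > 0.05

    def test_monotone_in_rank(self, rng):
        p = rng.random(200)
        q = kh.fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_matches_independent_step_up(self, rng):
        """BH decisions match a hand-rolled step-up rule on 1000 vectors."""
        alpha = 0.05
        for _ in range(1000):
            m = int(rng.integers(3, 40))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            q = kh.fdr_bh(p, alpha=alpha)
            srt = np.sort(p)
            passing = np.nonzero(srt <= (np.arange(1, m + 1) / m) * alpha)[0]
            k = passing[-1] + 1 if len(passing) else 0
            expect = p <= (srt[k - 1] if k else -1.0)
            assert np.array_equal(q <= alpha, expect)

    def test_empty(self):
        assert kh.fdr_bh(np.array([])).size == 0


class TestInverseNormal:
    def test_rank_preserving_and_centered(self, rng):
        x = rng.standard_normal(101) ** 3
        z = kh.inverse_normal_transform(x)
        assert np.array_equal(np.argsort(z), np.argsort(x))
        assert abs(z.mean()) < 1e-10
        assert np.allclose(np.sort(z), -np.sort(z)[::-1])  # symmetric score set

    def test_blom_n3_oracle(self):
        z = kh.inverse_normal_transform(np.array([10.0, -5.0, 3.0]))
        q = sps.norm.ppf((1 - 3 / 8) / 3.25)
        assert z[1] == pytest.approx(q)
        assert z[2] == pytest.approx(0.0)
        assert z[0] == pytest.approx(-q)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            kh.inverse_normal_transform(np.ones(5))
        with pytest.raises(ValueError):
            kh.inverse_normal_transform(np.array([1.0]))


class TestImageIO:
    def _write(self, tmp_path, data, mask, affine=None, ids=None):
        import nibabel as nib

        affine = np.eye(4) if affine is None else affine
        nib.save(nib.Nifti1Image(data.astype(np.float32), affine), tmp_path / "stack.nii.gz")
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), tmp_path / "mask.nii.gz")
        if ids is not None:
            pd.DataFrame({"volume": range(len(ids)), "id": ids}).to_csv(
                tmp_path / "side.csv", index=False
            )

    def test_round_trip_and_analysis(self, tmp_path, eig138, design138, rng):
        X, _ = design138
        data = rng.standard_normal((3, 2, 2, 138))
        mask = np.ones((3, 2, 2), bool)
        self._write(tmp_path, data, mask, ids=eig138.subject_order)
        stack = read_image_stack(
            tmp_path / "stack.nii.gz", tmp_path / "mask.nii.gz",
            tmp_path / "side.csv", subject_ids=eig138.subject_order,
        )
        assert np.allclose(stack.data, data, atol=1e-6)
        stat = kh.voxelwise_analysis(stack, X, eig138, test_kind="score")
        paths = write_stat_image(stat, tmp_path / "out")
        import nibabel as nib

        back = np.asarray(nib.load(str((tmp_path / "out" / "kinherit_stat.nii.gz"))).dataobj)
        assert np.allclose(back[mask], stat.maps["stat"][mask], atol=1e-5)
        assert any(str(p).endswith("run.json") for p in paths)

    def test_grid_mismatch_raises(self, tmp_path, rng):
        import nibabel as nib

        data = rng.standard_normal((3, 2, 2, 4))
        nib.save(nib.Nifti1Image(data.astype(np.float32), np.eye(4)), tmp_path / "stack.nii.gz")
        nib.save(
            nib.Nifti1Image(np.ones((2, 2, 2), np.uint8), np.eye(4)), tmp_path / "mask.nii.gz"
        )
        with pytest.raises(ValueError, match="does not match"):
            read_image_stack(tmp_path / "stack.nii.gz", tmp_path / "mask.nii.gz")

    def test_missing_subject_in_sidecar(self, tmp_path, rng):
        data = rng.standard_normal((2, 2, 1, 3))
        mask = np.ones((2, 2, 1), bool)
        self._write(tmp_path, data, mask, ids=["a", "b", "c"])
        with pytest.raises(KeyError, match="missing"):
            read_image_stack(
                tmp_path / "stack.nii.gz", tmp_path / "mask.nii.gz",
                tmp_path / "side.csv", subject_ids=["a", "b", "zzz"],
            )
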