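import numpy as np
import pytest
from scipy import stats

from samit.grid import BrainMask, ImageVolume, VolumeGrid
from samit.vba import (
    Cluster,
    ClusterTable,
    TMap,
    cluster_fwe,
    mip_glass_brain,
    report_peaks_paxinos,
    threshold_and_cluster,
    two_sample_tmap,
)

from conftest import wide_grid


def _grid(n=16, voxel=1.0):
    return VolumeGrid(
        dims=(n, n, n), voxel_size=(voxel,) * 3,
        origin_world=tuple(-(n - 1) * voxel / 2 for _ in range(3)),
    )


def _cohort(grid, n, rng, effect=None):
    out = []
    for _ in range(n):
        v = rng.normal(1.0, 0.1, size=grid.dims)
        if effect is not None:
            v += effect
        out.append(ImageVolume(grid=grid, values=v))
    return out


@pytest.fixture
def full_mask():
    g = _grid()
    return BrainMask(grid=g, mask=np.ones(g.dims, dtype=bool))


class TestTwoSampleTMap:
    def test_identical_groups_zero(self, full_mask):
        g = full_mask.grid
        rng = np.random.default_rng(0)
        group = _cohort(g, 4, rng)
        tmap = two_sample_tmap(group, list(group), full_mask, smoothing_fwhm=0)
        assert np.abs(tmap.t_values[tmap.mask.mask]).max() < 1e-9
        assert tmap.df == 6

    def test_group_swap_negates(self, full_mask):
        g = full_mask.grid
        rng = np.random.default_rng(1)
        a = _cohort(g, 4, rng)
        b = _cohort(g, 5, rng)
        t1 = two_sample_tmap(a, b, full_mask, smoothing_fwhm=0)
        t2 = two_sample_tmap(b, a, full_mask, smoothing_fwhm=0)
        assert np.allclose(t1.t_values, -t2.t_values)

    def test_hand_computed_pooled_t(self):
        g = VolumeGrid(dims=(2, 1, 1), voxel_size=(1, 1, 1), origin_world=(0, 0, 0))
        mask = BrainMask(grid=g, mask=np.ones((2, 1, 1), dtype=bool))
        a = [ImageVolume(grid=g, values=np.full((2, 1, 1), float(v))) for v in (1, 2, 3)]
        b = [ImageVolume(grid=g, values=np.full((2, 1, 1), float(v))) for v in (4, 5, 6)]
        tmap = two_sample_tmap(a, b, mask, smoothing_fwhm=0)
        # textbook pooled t: means 2 and 5, sp2 = 1, se = sqrt(2/3)
        expected = 3.0 / np.sqrt(2.0 / 3.0)
        assert tmap.t_values[0, 0, 0] == pytest.approx(expected, abs=1e-12)
        assert tmap.df == 4

    def test_scipy_ttest_oracle(self, full_mask):
        g = full_mask.grid
        rng = np.random.default_rng(2)
        a = _cohort(g, 5, rng)
        b = _cohort(g, 7, rng)
        tmap = two_sample_tmap(a, b, full_mask, smoothing_fwhm=0)
        da = np.stack([x.values for x in a])
        db = np.stack([x.values for x in b])
        ref = stats.ttest_ind(db, da, axis=0, equal_var=True).statistic
        assert np.abs(tmap.t_values - ref).max() < 1e-10

    def test_small_group_rejected(self, full_mask):
        g = full_mask.grid
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            two_sample_tmap(_cohort(g, 1, rng), _cohort(g, 4, rng), full_mask)

    def test_zero_variance_voxels_masked_out(self, full_mask):
        g = full_mask.grid
        rng = np.random.default_rng(4)
        a = _cohort(g, 3, rng)
        b = _cohort(g, 3, rng)
        for img in a + b:
            img.values[0, 0, 0] = 5.0  # constant across everyone
        tmap = two_sample_tmap(a, b, full_mask, smoothing_fwhm=0)
        assert not tmap.mask.mask[0, 0, 0]


class TestThresholdAndCluster:
    def _tmap_from_field(self, field, df=10):
        g = VolumeGrid(
            dims=field.shape, voxel_size=(1, 1, 1),
            origin_world=tuple(-(d - 1) / 2 for d in field.shape),
        )
        mask = BrainMask(grid=g, mask=np.ones(field.shape, dtype=bool))
        return TMap(grid=g, t_values=field, df=df, n_per_group=(6, 6), mask=mask)

    def test_zero_map_empty(self):
        tmap = self._tmap_from_field(np.zeros((8, 8, 8)))
        table = threshold_and_cluster(tmap, voxel_p=0.001, extent_k=0)
        assert table.clusters == []

    def test_single_blob_counted_once(self):
        field = np.zeros((20, 20, 20))
        field[2:12, 2:7, 2:7] = 10.0  # 250 suprathreshold voxels
        tmap = self._tmap_from_field(field)
        table = threshold_and_cluster(tmap, voxel_p=0.001, extent_k=200)
        assert len(table.clusters) == 1
        assert table.clusters[0].extent == 250

    def test_extent_threshold_drops_small_blob(self):
        field = np.zeros((24, 24, 24))
        field[1:11, 1:6, 1:6] = 10.0   # 250 voxels
        field[14:20, 14:19, 14:19] = 10.0  # 150 voxels
        tmap = self._tmap_from_field(field)
        table = threshold_and_cluster(tmap, voxel_p=0.001, extent_k=200)
        assert len(table.clusters) == 1
        assert table.clusters[0].extent == 250

    def test_monotone_in_extent_threshold(self):
        rng = np.random.default_rng(5)
        field = rng.normal(size=(16, 16, 16)) * 3
        tmap = self._tmap_from_field(field)
        counts = [
            len(threshold_and_cluster(tmap, voxel_p=0.01, extent_k=k).clusters)
            for k in (0, 1, 2, 4, 8, 16)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_cluster_labels_match_flood_fill_oracle(self):
        rng = np.random.default_rng(6)
        for trial in range(3):
            binary = rng.random((12, 12, 12)) < 0.25
            field = np.where(binary, 10.0, 0.0)
            tmap = self._tmap_from_field(field)
            table = threshold_and_cluster(tmap, voxel_p=0.001, extent_k=1)
            # brute-force 18-connected flood fill
            neighbours = [
                (i, j, k)
                for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                if (i, j, k) != (0, 0, 0) and abs(i) + abs(j) + abs(k) <= 2
            ]
            seen = np.zeros_like(binary)
            sizes = []
            for start in np.argwhere(binary):
                start = tuple(start)
                if seen[start]:
                    continue
                stack, comp = [start], 0
                seen[start] = True
                while stack:
                    cur = stack.pop()
                    comp += 1
                    for d in neighbours:
                        nxt = tuple(np.array(cur) + d)
                        if any(v < 0 or v >= 12 for v in nxt):
                            continue
                        if binary[nxt] and not seen[nxt]:
                            seen[nxt] = True
                            stack.append(nxt)
                sizes.append(comp)
            assert sorted(c.extent for c in table.clusters) == sorted(sizes)

    def test_peak_coordinates_in_world_mm(self):
        field = np.zeros((9, 9, 9))
        field[6, 4, 2] = 8.0
        tmap = self._tmap_from_field(field)
        table = threshold_and_cluster(tmap, voxel_p=0.01, extent_k=0)
        assert table.clusters[0].peak_xyz == (2.0, 0.0, -2.0)


class TestClusterFWE:
    def _groups(self, effect_vox=None, n=(6, 6), seed=0, dims=(14, 14, 14)):
        g = VolumeGrid(
            dims=dims, voxel_size=(1, 1, 1),
            origin_world=tuple(-(d - 1) / 2 for d in dims),
        )
        mask = BrainMask(grid=g, mask=np.ones(dims, dtype=bool))
        rng = np.random.default_rng(seed)
        a = _cohort(g, n[0], rng)
        effect = np.zeros(dims)
        if effect_vox:
            sl = tuple(slice(s, e) for s, e in effect_vox)
            effect[sl] = 0.4
        b = _cohort(g, n[1], rng, effect=effect)
        return a, b, mask

    def test_deterministic_for_fixed_seed(self):
        a, b, mask = self._groups(effect_vox=[(2, 9), (2, 9), (2, 9)])
        tmap = two_sample_tmap(a, b, mask, smoothing_fwhm=0)
        table = threshold_and_cluster(tmap, voxel_p=0.01, extent_k=5)
        assert table.clusters
        r1 = cluster_fwe(table, a, b, mask, n_permutations=150, seed=9, smoothing_fwhm=0)
        r2 = cluster_fwe(table, a, b, mask, n_permutations=150, seed=9, smoothing_fwhm=0)
        assert [c.p_fwe for c in r1.clusters] == [c.p_fwe for c in r2.clusters]
        assert [c.p_uncorrected for c in r1.clusters] == [
            c.p_uncorrected for c in r2.clusters
        ]

    def test_strong_effect_significant(self):
        a, b, mask = self._groups(effect_vox=[(2, 10), (2, 10), (2, 10)])
        tmap = two_sample_tmap(a, b, mask, smoothing_fwhm=0)
        table = threshold_and_cluster(tmap, voxel_p=0.01, extent_k=10)
        out = cluster_fwe(table, a, b, mask, n_permutations=200, seed=1, smoothing_fwhm=0)
        assert out.clusters[0].p_fwe < 0.05

    def test_pvalues_have_plus_one_smoothing(self):
        a, b, mask = self._groups(effect_vox=[(2, 10), (2, 10), (2, 10)])
        tmap = two_sample_tmap(a, b, mask, smoothing_fwhm=0)
        table = threshold_and_cluster(tmap, voxel_p=0.01, extent_k=10)
        out = cluster_fwe(table, a, b, mask, n_permutations=150, seed=2, smoothing_fwhm=0)
        for c in out.clusters:
            assert c.p_fwe >= 1.0 / 151.0

    def test_too_few_permutations_rejected(self):
        a, b, mask = self._groups()
        tmap = two_sample_tmap(a, b, mask, smoothing_fwhm=0)
        table = threshold_and_cluster(tmap, voxel_p=0.01, extent_k=0)
        with pytest.raises(ValueError):
            cluster_fwe(table, a, b, mask, n_permutations=50, seed=0)

    def test_warns_on_few_distinct_relabellings(self):
        a, b, mask = self._groups(n=(3, 3))
        tmap = two_sample_tmap(a, b, mask, smoothing_fwhm=0)
        table = threshold_and_cluster(tmap, voxel_p=0.05, extent_k=0)
        with pytest.warns(UserWarning, match="distinct"):
            cluster_fwe(table, a, b, mask, n_permutations=100, seed=0, smoothing_fwhm=0)


class TestReporting:
    def _sig_table(self):
        field = np.zeros((30, 30, 30))
        field[4:10, 4:10, 4:10] = 6.0
        field[4, 4, 4] = 9.0
        g = VolumeGrid(dims=(30, 30, 30), voxel_size=(1, 1, 1), origin_world=(-14.5, -14.5, -14.5))
        from samit.vba import TMap

        mask = BrainMask(grid=g, mask=np.ones((30, 30, 30), dtype=bool))
        tmap = TMap(grid=g, t_values=field, df=10, n_per_group=(6, 6), mask=mask)
        return tmap, threshold_and_cluster(tmap, voxel_p=0.01, extent_k=0)

    def test_empty_input_header_only(self):
        table = ClusterTable(
            clusters=[], voxel_p=0.001, extent_k=200, alpha=0.05,
            t_threshold=3.5, df=19,
        )
        df = report_peaks_paxinos(table)
        assert len(df) == 0
        assert list(df.columns) == [
            "cluster_p_fwe", "cluster_p_uncorr", "extent_voxels",
            "peak_t", "x", "y", "z",
        ]

    def test_peak_coordinates_rounded_to_tenth(self):
        g = VolumeGrid(dims=(9, 9, 9), voxel_size=(0.37, 0.37, 0.37), origin_world=(-1.48, -1.48, -1.48))
        from samit.vba import TMap

        field = np.zeros((9, 9, 9))
        field[7, 4, 1] = 9.0
        mask = BrainMask(grid=g, mask=np.ones((9, 9, 9), dtype=bool))
        tmap = TMap(grid=g, t_values=field, df=12, n_per_group=(7, 7), mask=mask)
        table = threshold_and_cluster(tmap, voxel_p=0.01, extent_k=0)
        df = report_peaks_paxinos(table, tmap)
        for col in ("x", "y", "z"):
            v = df[col].iloc[0]
            assert v == round(v, 1)

    def test_local_peaks_respect_separation(self):
        tmap, table = self._sig_table()
        df = report_peaks_paxinos(tmap=tmap, table=table, min_separation_mm=8.0)
        coords = df[["x", "y", "z"]].to_numpy()
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                assert np.linalg.norm(coords[i] - coords[j]) >= 8.0
        assert len(df) <= 3 * len(table.clusters)

    def test_constructed_peak_printed(self):
        tmap, table = self._sig_table()
        df = report_peaks_paxinos(tmap=tmap, table=table)
        assert df[["x", "y", "z"]].iloc[0].tolist() == [-10.5, -10.5, -10.5]


class TestGlassBrain:
    def test_single_voxel_projections(self):
        field = np.zeros((9, 9, 9))
        field[6, 4, 2] = 5.0
        g = VolumeGrid(dims=(9, 9, 9), voxel_size=(1, 1, 1), origin_world=(-4, -4, -4))
        from samit.vba import TMap

        mask = BrainMask(grid=g, mask=np.ones((9, 9, 9), dtype=bool))
        tmap = TMap(grid=g, t_values=field, df=10, n_per_group=(6, 6), mask=mask)
        table = threshold_and_cluster(tmap, voxel_p=0.01, extent_k=0)
        proj = mip_glass_brain(tmap, table)
        assert proj["sagittal"]["mip"][4, 2] == 5.0  # (y, z)
        assert proj["coronal"]["mip"][6, 2] == 5.0  # (x, z)
        assert proj["axial"]["mip"][6, 4] == 5.0  # (x, y)

    def test_empty_table_outline_only(self):
        g = VolumeGrid(dims=(6, 6, 6), voxel_size=(1, 1, 1), origin_world=(0, 0, 0))
        from samit.vba import TMap

        mask = BrainMask(grid=g, mask=np.ones((6, 6, 6), dtype=bool))
        tmap = TMap(grid=g, t_values=np.zeros((6, 6, 6)), df=8, n_per_group=(5, 5), mask=mask)
        table = threshold_and_cluster(tmap, voxel_p=0.001, extent_k=0)
        proj = mip_glass_brain(tmap, table)
        for p in proj.values():
            assert p["mip"].max() == 0.0
            assert p["outline"].any()

    def test_mip_is_maximum_along_ray(self):
        field = np.zeros((7, 7, 7))
        field[3, 3, 1] = 2.0
        field[3, 3, 5] = 7.0  # same (x, y) ray, different z
        g = VolumeGrid(dims=(7, 7, 7), voxel_size=(1, 1, 1), origin_world=(-3, -3, -3))
        from samit.vba import TMap

        mask = BrainMask(grid=g, mask=np.ones((7, 7, 7), dtype=bool))
        tmap = TMap(grid=g, t_values=field, df=10, n_per_group=(6, 6), mask=mask)
        table = threshold_and_cluster(tmap, voxel_p=0.05, extent_k=0)
        proj = mip_glass_brain(tmap, table)
        assert proj["axial"]["mip"][3, 3] == 7.0

    def test_save_png(self, tmp_path):
        tmap_field = np.zeros((9, 9, 9))
        tmap_field[4, 4, 4] = 6.0
        g = VolumeGrid(dims=(9, 9, 9), voxel_size=(1, 1, 1), origin_world=(-4, -4, -4))
        from samit.vba import TMap, save_glass_brain

        mask = BrainMask(grid=g, mask=np.ones((9, 9, 9), dtype=bool))
        tmap = TMap(grid=g, t_values=tmap_field, df=10, n_per_group=(6, 6), mask=mask)
        table = threshold_and_cluster(tmap, voxel_p=0.01, extent_k=0)
        out = tmp_path / "glass.png"
        save_glass_brain(mip_glass_brain(tmap, table), out)
        assert out.exists() and out.stat().st_size > 0
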