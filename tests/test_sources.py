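"""Source projection, repartition, localization, radii, topographies."""

import numpy as np
import pytest

from neuroscene import (
    SourceSet,
    filter_sources_by_volume,
    locate_sources,
    make_synthetic_atlas,
    marker_radii,
    project_data,
    project_repartition,
    topo_map,
    voxel_to_world,
)
from neuroscene.mesh import make_icosphere


def brute_force_projection(src, mesh, radius):
    """O(N*V) double-loop reimplementation of the projection contract."""
    n_v = mesh.n_vertices
    values = np.full(n_v, np.nan)
    touched = np.zeros(n_v, dtype=bool)
    counts = np.zeros(n_v, dtype=np.int64)
    active = range(len(src)) if src.mask is None else np.flatnonzero(src.mask)
    for v in range(n_v):
        w_sum, acc, members = 0.0, 0.0, []
        for i in active:
            d = float(np.linalg.norm(src.pos[i] - mesh.vertices[v]))
            if d < radius:
                members.append(i)
                w = 1.0 - d / radius
                w_sum += w
                acc += w * (src.data[i] if src.data is not None else 0.0)
        counts[v] = len(members)
        if members:
            touched[v] = True
            if src.data is not None:
                if w_sum < 1e-12:
                    values[v] = float(np.mean([src.data[i] for i in members]))
                else:
                    values[v] = acc / w_sum
    return values, touched, counts


@pytest.fixture(scope="module")
def lobe():
    """Single 2562-vertex lobe standing in for a cortical surface."""
    return make_icosphere(subdiv=4, radius=40.0)


@pytest.fixture(scope="module")
def random_sources(lobe):
    rng = np.random.default_rng(42)
    picks = rng.choice(lobe.n_vertices, 100, replace=False)
    pos = lobe.vertices[picks] * rng.uniform(0.9, 1.05, (100, 1))
    return SourceSet(pos=pos, data=rng.normal(size=100))


class TestProjectData:
    def test_single_source_exactness(self):
        mesh = make_icosphere(subdiv=0, radius=20.0)
        target = mesh.vertices[0]
        src = SourceSet(pos=[target + [3.0, 0, 0]], data=[5.0])
        values, touched = project_data(src, mesh, radius=10.0)
        assert touched[0]
        assert values[0] == pytest.approx(5.0)

    def test_equidistant_pair_averages(self):
        mesh = make_icosphere(subdiv=0, radius=20.0)
        target = mesh.vertices[0]
        src = SourceSet(
            pos=[target + [4.0, 0, 0], target - [4.0, 0, 0]], data=[2.0, 4.0]
        )
        values, _ = project_data(src, mesh, radius=30.0)
        assert values[0] == pytest.approx(3.0)

    def test_source_at_exact_radius_excluded(self):
        from neuroscene import TriMesh

        # Axis-aligned construction so the 10 mm distance is exact in floats.
        mesh = TriMesh(
            vertices=[[0.0, 0.0, 0.0], [100.0, 0.0, 0.0], [0.0, 100.0, 0.0]],
            faces=[[0, 1, 2]],
        )
        src = SourceSet(pos=[[0.0, 0.0, 10.0]], data=[1.0])
        values, touched = project_data(src, mesh)  # default radius 10 mm
        assert not touched[0]
        assert np.isnan(values[0])

    def test_oracle_equivalence(self, lobe, random_sources):
        values, touched = project_data(random_sources, lobe, radius=10.0)
        want_v, want_t, _ = brute_force_projection(random_sources, lobe, 10.0)
        np.testing.assert_array_equal(touched, want_t)
        np.testing.assert_allclose(
            values[touched], want_v[want_t], atol=1e-9, rtol=0
        )

    def test_constant_field_preserved(self, lobe, random_sources):
        src = SourceSet(pos=random_sources.pos, data=np.full(100, 3.25))
        values, touched = project_data(src, lobe, radius=12.0)
        np.testing.assert_allclose(values[touched], 3.25, atol=1e-12)

    def test_convexity_bounds(self, lobe, random_sources):
        values, touched = project_data(random_sources, lobe, radius=10.0)
        assert values[touched].min() >= random_sources.data.min() - 1e-12
        assert values[touched].max() <= random_sources.data.max() + 1e-12

    def test_masked_sources_excluded(self, lobe, random_sources):
        mask = np.zeros(100, dtype=bool)
        mask[:50] = True
        masked = SourceSet(pos=random_sources.pos, data=random_sources.data, mask=mask)
        sub = SourceSet(pos=random_sources.pos[:50], data=random_sources.data[:50])
        v_masked, t_masked = project_data(masked, lobe, radius=10.0)
        v_sub, t_sub = project_data(sub, lobe, radius=10.0)
        np.testing.assert_array_equal(t_masked, t_sub)
        np.testing.assert_allclose(v_masked[t_masked], v_sub[t_sub], atol=1e-12)

    def test_touched_set_monotone_in_radius(self, lobe, random_sources):
        _, t5 = project_data(random_sources, lobe, radius=5.0)
        _, t10 = project_data(random_sources, lobe, radius=10.0)
        _, t20 = project_data(random_sources, lobe, radius=20.0)
        assert np.all(t10[t5]) and np.all(t20[t10])

    def test_missing_data_rejected(self, lobe):
        with pytest.raises(ValueError, match="data"):
            project_data(SourceSet(pos=[[0, 0, 0]]), lobe)

    def test_nonpositive_radius_rejected(self, lobe, random_sources):
        with pytest.raises(ValueError, match="radius"):
            project_data(random_sources, lobe, radius=0.0)


class TestProjectRepartition:
    def test_no_sources_all_zero(self, lobe):
        src = SourceSet(pos=np.empty((0, 3)))
        assert project_repartition(src, lobe).sum() == 0

    def test_oracle_equivalence(self, lobe, random_sources):
        counts = project_repartition(random_sources, lobe, radius=10.0)
        _, _, want = brute_force_projection(random_sources, lobe, 10.0)
        np.testing.assert_array_equal(counts, want)

    def test_double_counting_identity(self, lobe, random_sources):
        counts = project_repartition(random_sources, lobe, radius=10.0)
        per_source = sum(
            int(
                np.sum(
                    np.linalg.norm(lobe.vertices - random_sources.pos[i], axis=1)
                    < 10.0
                )
            )
            for i in range(100)
        )
        assert counts.sum() == per_source

    def test_membership_agrees_with_projection(self, lobe, random_sources):
        counts = project_repartition(random_sources, lobe, radius=10.0)
        _, touched = project_data(random_sources, lobe, radius=10.0)
        np.testing.assert_array_equal(counts > 0, touched)


class TestLocateSources:
    def test_source_at_voxel_center(self, atlas):
        vox = np.array(np.nonzero(atlas.labels == 3)).T[0]
        world = voxel_to_world(atlas.affine, vox.astype(float))[0]
        table = locate_sources(SourceSet(pos=[world]), atlas)
        assert table.loc[0, "id"] == 3
        assert table.loc[0, "name"] == atlas.table[3]

    def test_far_outside_not_found(self, atlas):
        table = locate_sources(SourceSet(pos=[[1000.0, 0, 0]]), atlas)
        assert table.loc[0, "id"] == 0
        assert table.loc[0, "name"] == "Not found"

    def test_random_sources_vs_nearest_voxel_oracle(self, atlas, rng):
        pos = rng.uniform(-45, 45, size=(200, 3))
        table = locate_sources(SourceSet(pos=pos), atlas)
        inv = np.linalg.inv(atlas.affine)
        for n in range(200):
            ijk = np.rint(inv[:3, :3] @ pos[n] + inv[:3, 3]).astype(int)
            inside = all(0 <= ijk[a] < atlas.labels.shape[a] for a in range(3))
            want = int(atlas.labels[tuple(ijk)]) if inside else 0
            assert table.loc[n, "id"] == want

    def test_csv_round_trip(self, atlas, rng, tmp_path):
        import pandas as pd

        pos = rng.uniform(-40, 40, size=(10, 3))
        table = locate_sources(SourceSet(pos=pos), atlas)
        path = tmp_path / "loc.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert list(back["id"]) == list(table["id"])
        assert list(back["name"]) == list(table["name"])


class TestFilterByVolume:
    def test_partition(self, atlas, rng):
        pos = rng.uniform(-45, 45, size=(150, 3))
        src = SourceSet(pos=pos, data=rng.normal(size=150))
        inside, idx = filter_sources_by_volume(src, atlas, sorted(atlas.table))
        table = locate_sources(src, atlas)
        np.testing.assert_array_equal(idx, np.flatnonzero(table["id"] > 0))
        assert len(inside) + int((table["id"] == 0).sum()) == 150
        np.testing.assert_array_equal(inside.data, src.data[idx])

    def test_empty_result_allowed(self, atlas):
        src = SourceSet(pos=[[500.0, 0, 0]])
        sub, idx = filter_sources_by_volume(src, atlas, [1])
        assert len(sub) == 0 and len(idx) == 0

    def test_unknown_id_rejected(self, atlas):
        with pytest.raises(KeyError):
            filter_sources_by_volume(SourceSet(pos=[[0, 0, 0]]), atlas, [42])


class TestMarkerRadii:
    def test_linear_map(self):
        np.testing.assert_allclose(
            marker_radii([0.0, 0.5, 1.0], 1.0, 11.0), [1.0, 6.0, 11.0]
        )

    def test_constant_data_midpoint(self):
        np.testing.assert_allclose(marker_radii([7.0, 7.0, 7.0], 2.0, 10.0), 6.0)

    def test_monotone_against_sort_oracle(self, rng):
        data = rng.normal(size=200)
        radii = marker_radii(data, 3.0, 9.0)
        np.testing.assert_array_equal(np.argsort(radii, kind="stable"), np.argsort(data, kind="stable"))
        assert radii.min() == pytest.approx(3.0)
        assert radii.max() == pytest.approx(9.0)

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            marker_radii([1.0], 5.0, 2.0)


class TestTopoMap:
    def head(self, n, rng):
        """n channels on the upper hemisphere of a radius-9 head sphere."""
        theta = rng.uniform(0.05, np.pi / 2 - 0.05, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        return 9.0 * np.column_stack(
            [
                np.sin(theta) * np.cos(phi),
                np.sin(theta) * np.sin(phi),
                np.cos(theta),
            ]
        )

    def test_constant_values_give_constant_map(self, rng):
        pos = self.head(12, rng)
        grid, _ = topo_map(pos, np.full(12, 4.5), grid_n=32)
        inside = np.isfinite(grid)
        np.testing.assert_allclose(grid[inside], 4.5, atol=1e-9)

    def test_apex_channel_peaks_at_center(self, rng):
        pos = np.vstack([[0.0, 0.0, 9.0], self.head(8, rng)])
        values = np.zeros(9)
        values[0] = 1.0
        grid, _ = topo_map(pos, values, grid_n=33)
        r, c = np.unravel_index(np.nanargmax(grid), grid.shape)
        assert (r, c) == (16, 16)

    def test_idw_oracle(self, rng):
        pos = self.head(6, rng)
        values = rng.normal(size=6)
        grid_n = 17
        grid, pts = topo_map(pos, values, grid_n=grid_n)
        ax = np.linspace(-1, 1, grid_n)
        for r in range(grid_n):
            for c in range(grid_n):
                x, y = ax[c], ax[grid_n - 1 - r]
                if x * x + y * y > 1:
                    assert np.isnan(grid[r, c])
                    continue
                d2 = (pts[:, 0] - x) ** 2 + (pts[:, 1] - y) ** 2
                if d2.min() < 1e-18:
                    want = values[np.argmin(d2)]
                else:
                    w = 1.0 / d2
                    want = (w * values).sum() / w.sum()
                assert grid[r, c] == pytest.approx(want, abs=1e-9)

    def test_duplicate_channels_rejected(self):
        pos = np.array([[0, 0, 9.0], [0, 0, 9.0]])
        with pytest.raises(ValueError, match="duplicate"):
            topo_map(pos, [1.0, 2.0])
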