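"""Mesh handling, cluster formation, area accounting, map assignment."""

import numpy as np
import pytest

from numtune.surface import (
    ClusterRecord,
    MapAtlas,
    MAP_NAMES,
    SurfaceMesh,
    assign_maps,
    cluster_area,
    clusters_to_frame,
    connected_clusters,
    filter_clusters,
    load_mesh_tsv,
    save_mesh_tsv,
)
from numtune.synthetic import make_mesh


@pytest.fixture
def strip_mesh():
    """Six vertices in a triangulated strip: 0-1-2-3-4-5."""
    coords = np.column_stack([np.arange(6.0), np.tile([0.0, 1.0], 3), np.zeros(6)])
    tris = np.array([[0, 1, 2], [1, 2, 3], [2, 3, 4], [3, 4, 5]])
    return SurfaceMesh(coords, tris)


@pytest.fixture
def unit_square_mesh():
    coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
    tris = np.array([[0, 1, 2], [1, 3, 2]])
    return SurfaceMesh(coords, tris)


def union_find_clusters(mesh, mask):
    """Independent oracle: plain union-find over selected-vertex edges."""
    parent = list(range(mesh.n_vertices))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in mesh.edges():
        if mask[a] and mask[b]:
            parent[find(a)] = find(b)
    groups = {}
    for v in np.flatnonzero(mask):
        groups.setdefault(find(v), set()).add(v)
    return {frozenset(g) for g in groups.values()}


class TestConnectedClusters:
    def test_empty_mask(self, strip_mesh):
        assert connected_clusters(strip_mesh, np.zeros(6, bool)) == []

    def test_two_separate_clusters(self, strip_mesh):
        mask = np.array([True, True, False, False, True, True])
        clusters = connected_clusters(strip_mesh, mask)
        assert len(clusters) == 2
        sets = {frozenset(c.vertices.tolist()) for c in clusters}
        assert sets == {frozenset({0, 1}), frozenset({4, 5})}

    def test_fully_selected_is_one_cluster(self, strip_mesh):
        clusters = connected_clusters(strip_mesh, np.ones(6, bool))
        assert len(clusters) == 1
        assert clusters[0].n_vertices == 6

    def test_matches_union_find_oracle_on_random_meshes(self, rng):
        for _ in range(10):
            nx = int(rng.integers(3, 15))
            ny = int(rng.integers(3, 15))
            mesh = make_mesh(nx, ny)
            mask = rng.random(mesh.n_vertices) < 0.45
            ours = {
                frozenset(c.vertices.tolist())
                for c in connected_clusters(mesh, mask)
            }
            assert ours == union_find_clusters(mesh, mask)

    def test_ordering_by_decreasing_area(self, rng):
        mesh = make_mesh(12, 12)
        mask = np.zeros(mesh.n_vertices, bool)
        mask[:30] = True   # big patch (rows 0-2)
        mask[-13:] = True  # small patch
        clusters = connected_clusters(mesh, mask)
        areas = [c.area_mm2 for c in clusters]
        assert areas == sorted(areas, reverse=True)

    def test_empty_mesh_rejected(self):
        mesh = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError):
            connected_clusters(mesh, np.array([], dtype=bool))


class TestClusterArea:
    def test_unit_square(self, unit_square_mesh):
        rec = ClusterRecord(vertices=np.arange(4))
        assert cluster_area(unit_square_mesh, rec) == pytest.approx(1.0)

    def test_partial_triangle_contributes_nothing(self, unit_square_mesh):
        rec = ClusterRecord(vertices=np.array([0, 1, 2]))  # vertex 3 outside
        assert cluster_area(unit_square_mesh, rec) == pytest.approx(0.5)

    def test_single_vertex_zero_area(self, unit_square_mesh):
        assert cluster_area(unit_square_mesh, ClusterRecord(np.array([0]))) == 0.0

    def test_invariant_to_rigid_motion_and_relabeling(self, rng):
        mesh = make_mesh(6, 6)
        # random rotation + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = SurfaceMesh(
            mesh.vertex_coords_native @ q.T + rng.normal(size=3),
            mesh.triangles,
        )
        perm = rng.permutation(mesh.n_vertices)
        inv = np.argsort(perm)
        relabeled = SurfaceMesh(
            moved.vertex_coords_native[perm], inv[mesh.triangles]
        )
        rec = ClusterRecord(np.arange(12))
        rec_moved = ClusterRecord(np.arange(12))
        rec_relab = ClusterRecord(np.sort(inv[np.arange(12)]))
        a = cluster_area(mesh, rec)
        assert cluster_area(moved, rec_moved) == pytest.approx(a)
        assert cluster_area(relabeled, rec_relab) == pytest.approx(a)

    def test_cluster_areas_bounded_by_mesh_total(self, rng):
        mesh = make_mesh(10, 10)
        mask = rng.random(mesh.n_vertices) < 0.7
        total = sum(c.area_mm2 for c in connected_clusters(mesh, mask))
        assert total <= mesh.total_area + 1e-9


class TestFilterClusters:
    def test_boundary_inclusive(self):
        clusters = [
            ClusterRecord(np.array([0]), area_mm2=a) for a in (49.9, 50.0, 120.0)
        ]
        kept = filter_clusters(clusters, a_min=50.0)
        assert [c.area_mm2 for c in kept] == [50.0, 120.0]

    def test_empty_input(self):
        assert filter_clusters([], a_min=50.0) == []

    def test_all_large_identity(self):
        clusters = [ClusterRecord(np.array([0]), area_mm2=100.0)]
        assert filter_clusters(clusters) == clusters


class TestAssignMaps:
    @pytest.fixture
    def atlas(self):
        centers = {n: [1e4 * (i + 1), 1e4, 1e4] for i, n in enumerate(MAP_NAMES)}
        centers["NPO"] = [10.0, 0.0, 0.0]
        centers["NPC1"] = [4.0, 0.0, 0.0]
        centers["NPC2"] = [18.0, 0.0, 0.0]
        return MapAtlas({"L": centers})

    @pytest.fixture
    def line_mesh(self):
        coords = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        tris = np.array([[0, 1, 2], [1, 2, 3]])
        return SurfaceMesh(coords, tris)

    def test_closest_center_wins(self, atlas, line_mesh):
        # vertex 3 at x=3: NPC1 at 1 mm, NPO at 7 mm, NPC2 at 15 mm
        rec = ClusterRecord(np.array([3]))
        (out,) = assign_maps([rec], atlas, line_mesh, hemi="L")
        assert out.assigned_map == "NPC1"
        assert out.candidate_maps == ["NPC1", "NPO", "NPC2"]

    def test_unassigned_when_all_far(self, line_mesh):
        centers = {n: [1e3, 1e3, 1e3] for n in MAP_NAMES}
        atlas = MapAtlas({"L": centers})
        rec = ClusterRecord(np.array([0, 1]))
        (out,) = assign_maps([rec], atlas, line_mesh, hemi="L")
        assert out.assigned_map == "unassigned"
        assert out.candidate_maps == []

    def test_d_max_strictly_exclusive(self, line_mesh):
        centers = {n: [1e3, 1e3, 1e3] for n in MAP_NAMES}
        centers["NTO"] = [25.0, 0.0, 0.0]  # exactly d_max from vertex 0
        atlas = MapAtlas({"L": centers})
        rec = ClusterRecord(np.array([0]))
        (out,) = assign_maps([rec], atlas, line_mesh, hemi="L", d_max=25.0)
        assert out.assigned_map == "unassigned"

    def test_missing_hemisphere(self, atlas, line_mesh):
        with pytest.raises(ValueError, match="hemisphere"):
            assign_maps([ClusterRecord(np.array([0]))], atlas, line_mesh, hemi="R")

    def test_malformed_atlas_rejected(self):
        with pytest.raises(ValueError, match="must define"):
            MapAtlas({"L": {"NTO": [0, 0, 0]}})
        with pytest.raises(ValueError, match="triple"):
            MapAtlas({"L": {n: [0, 0] for n in MAP_NAMES}})


class TestMeshIO:
    def test_tsv_round_trip(self, tmp_path, rng):
        mesh = make_mesh(4, 5, spacing=1.5)
        v_path, t_path = tmp_path / "v.tsv", tmp_path / "t.tsv"
        save_mesh_tsv(mesh, v_path, t_path)
        back = load_mesh_tsv(v_path, t_path)
        assert np.allclose(back.vertex_coords_native, mesh.vertex_coords_native)
        assert np.array_equal(back.triangles, mesh.triangles)
        assert np.allclose(back.vertex_coords_standard, mesh.vertex_coords_standard)

    def test_atlas_file_round_trip(self, tmp_path):
        import json

        centers = {"L": {n: [float(i), 0.0, 0.0] for i, n in enumerate(MAP_NAMES)}}
        path = tmp_path / "atlas.json"
        path.write_text(json.dumps(centers))
        atlas = MapAtlas.from_file(path)
        assert np.allclose(atlas.hemisphere("L")["NPO"], [1.0, 0.0, 0.0])

    def test_cluster_table_schema(self, strip_mesh):
        clusters = connected_clusters(strip_mesh, np.ones(6, bool))
        frame = clusters_to_frame(clusters, hemi="R")
        assert list(frame["hemi"]) == ["R"]
        assert frame.loc[0, "n_vertices"] == 6


def test_gifti_round_trip(tmp_path):
    import nibabel as nib

    mesh = make_mesh(3, 3)
    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                mesh.vertex_coords_native.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            ),
            nib.gifti.GiftiDataArray(
                mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
    )
    path = tmp_path / "surf.gii"
    nib.save(img, path)
    from numtune.surface import load_mesh_gifti

    back = load_mesh_gifti(path)
    assert np.allclose(back.vertex_coords_native, mesh.vertex_coords_native)
    assert np.array_equal(back.triangles, mesh.triangles)
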