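"""Cortical surface meshes, clustering, area accounting, map assignment.

Selected vertices are grouped into clusters of directly connected mesh
vertices (edge distance 1 on the triangle graph).  Cluster area is the
summed native-space area of triangles whose three nodes all belong to the
cluster; clusters below a minimum area (default 50 mm^2) are discarded.
Surviving clusters are assigned to one of six previously reported
topographic numerosity maps (NTO, NPO, NPC1-3, NF) when at least one
vertex lies within d_max (default 25 mm) of the map's standard-space
center, taking the map with the closest center when several qualify.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "SurfaceMesh",
    "ClusterRecord",
    "MapAtlas",
    "MAP_NAMES",
    "connected_clusters",
    "cluster_area",
    "filter_clusters",
    "assign_maps",
    "clusters_to_frame",
    "load_mesh_tsv",
    "save_mesh_tsv",
    "load_mesh_gifti",
]

MAP_NAMES = ("NTO", "NPO", "NPC1", "NPC2", "NPC3", "NF")


@dataclass
class SurfaceMesh:
    """Triangulated cortical surface with native and standard coordinates."""

    vertex_coords_native: np.ndarray  # V x 3, mm (pial, native space)
    triangles: np.ndarray  # T x 3 vertex indices
    vertex_coords_standard: np.ndarray | None = None  # V x 3, mm

    def __post_init__(self):
        self.vertex_coords_native = np.asarray(self.vertex_coords_native, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.vertex_coords_native.ndim != 2 or self.vertex_coords_native.shape[1] != 3:
            raise ValueError("vertex coordinates must be V x 3")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be T x 3")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= self.n_vertices
        ):
            raise ValueError("triangle indices out of range")
        if self.vertex_coords_standard is None:
            self.vertex_coords_standard = self.vertex_coords_native
        else:
            self.vertex_coords_standard = np.asarray(
                self.vertex_coords_standard, dtype=float
            )
            if self.vertex_coords_standard.shape != self.vertex_coords_native.shape:
                raise ValueError("native and standard coordinates must match in shape")

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords_native.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges from the triangle list."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def adjacency(self):
        """Symmetric sparse vertex adjacency matrix."""
        e = self.edges()
        ij = np.concatenate([e, e[:, ::-1]])
        data = np.ones(len(ij), dtype=np.int8)
        return coo_matrix(
            (data, (ij[:, 0], ij[:, 1])), shape=(self.n_vertices, self.n_vertices)
        ).tocsr()

    def triangle_areas(self) -> np.ndarray:
        """Native-space triangle areas, mm^2 (half cross-product norm)."""
        p = self.vertex_coords_native[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    @property
    def total_area(self) -> float:
        return float(self.triangle_areas().sum())


@dataclass
class ClusterRecord:
    """A connected supra-threshold vertex set."""

    vertices: np.ndarray
    area_mm2: float = np.nan
    assigned_map: str = "unassigned"
    candidate_maps: list = field(default_factory=list)
    mu_range: tuple = (np.nan, np.nan)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=int)

    @property
    def n_vertices(self) -> int:
        return self.vertices.size


@dataclass
class MapAtlas:
    """Standard-space center coordinates of the six numerosity maps,
    per hemisphere: ``{"L": {"NTO": [x, y, z], ...}, "R": {...}}``."""

    centers: dict

    def __post_init__(self):
        for hemi, maps in self.centers.items():
            if set(maps) != set(MAP_NAMES):
                raise ValueError(
                    f"atlas hemisphere {hemi!r} must define exactly {MAP_NAMES}, "
                    f"got {sorted(maps)}"
                )
            for name, xyz in maps.items():
                arr = np.asarray(xyz, dtype=float)
                if arr.shape != (3,):
                    raise ValueError(f"center {hemi}/{name} must be an (x, y, z) triple")
                maps[name] = arr

    @classmethod
    def from_file(cls, path) -> "MapAtlas":
        """Load from YAML or JSON: {hemi: {MAP: [x, y, z]}}."""
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls(raw)

    def hemisphere(self, hemi: str) -> dict:
        if hemi not in self.centers:
            raise ValueError(f"atlas has no hemisphere {hemi!r}")
        return self.centers[hemi]


def connected_clusters(mesh: SurfaceMesh, mask) -> list[ClusterRecord]:
    """Connected components of selected vertices on the mesh edge graph.

    Two selected vertices belong to the same cluster iff they are joined
    by a path of directly connected (edge distance 1) selected vertices.
    Clusters are returned with areas computed, ordered by decreasing
    area (ties: by smallest contained vertex id).
    """
    if mesh.n_vertices == 0:
        raise ValueError("mesh has no vertices")
    mask = np.asarray(mask, dtype=bool)
    if mask.size != mesh.n_vertices:
        raise ValueError("mask length must equal vertex count")
    sel = np.flatnonzero(mask)
    if sel.size == 0:
        return []
    sub = mesh.adjacency()[sel][:, sel]
    n_comp, labels = connected_components(sub, directed=False)
    clusters = []
    for c in range(n_comp):
        verts = sel[labels == c]
        rec = ClusterRecord(vertices=verts)
        rec.area_mm2 = cluster_area(mesh, rec)
        clusters.append(rec)
    clusters.sort(key=lambda r: (-r.area_mm2, int(r.vertices.min())))
    return clusters


def cluster_area(mesh: SurfaceMesh, cluster: ClusterRecord) -> float:
    """Summed native-space area of triangles fully inside the cluster."""
    inside = np.zeros(mesh.n_vertices, dtype=bool)
    inside[cluster.vertices] = True
    full = inside[mesh.triangles].all(axis=1)
    return float(mesh.triangle_areas()[full].sum())


def filter_clusters(clusters, a_min: float = 50.0) -> list[ClusterRecord]:
    """Retain clusters with area >= a_min mm^2 (boundary inclusive)."""
    return [c for c in clusters if c.area_mm2 >= a_min]


def assign_maps(
    clusters,
    atlas: MapAtlas,
    mesh: SurfaceMesh,
    hemi: str = "L",
    d_max: float = 25.0,
) -> list[ClusterRecord]:
    """Label clusters with topographic map names.

    A map is a candidate when its center lies strictly within ``d_max``
    (Euclidean distance, standard space) of at least one cluster vertex;
    the cluster is assigned to the candidate with the smallest
    center-to-nearest-vertex distance, or left "unassigned".
    """
    if d_max <= 0:
        raise ValueError("d_max must be > 0")
    centers = atlas.hemisphere(hemi)
    coords = mesh.vertex_coords_standard
    for rec in clusters:
        pts = coords[rec.vertices]
        candidates = []
        for name, center in centers.items():
            d = float(np.min(np.linalg.norm(pts - center[None, :], axis=1)))
            if d < d_max:
                candidates.append((d, name))
        candidates.sort()
        rec.candidate_maps = [name for _, name in candidates]
        rec.assigned_map = candidates[0][1] if candidates else "unassigned"
    return clusters


def clusters_to_frame(clusters, hemi: str = "L") -> pd.DataFrame:
    """Cluster table: id, hemi, n_vertices, area, map labels, mu range."""
    rows = [
        {
            "cluster_id": i,
            "hemi": hemi,
            "n_vertices": c.n_vertices,
            "area_mm2": c.area_mm2,
            "assigned_map": c.assigned_map,
            "candidate_maps": ",".join(c.candidate_maps),
            "mu_min": c.mu_range[0],
            "mu_max": c.mu_range[1],
        }
        for i, c in enumerate(clusters)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "hemi",
            "n_vertices",
            "area_mm2",
            "assigned_map",
            "candidate_maps",
            "mu_min",
            "mu_max",
        ],
    )


def load_mesh_tsv(vertices_path, triangles_path) -> SurfaceMesh:
    """Read a mesh from vertex/triangle TSV tables.

    The vertex table needs columns x, y, z (native, mm) and optionally
    std_x, std_y, std_z; the triangle table needs columns v0, v1, v2.
    """
    v = pd.read_csv(vertices_path, sep="\t", float_precision="round_trip")
    t = pd.read_csv(triangles_path, sep="\t")
    native = v[["x", "y", "z"]].to_numpy(dtype=float)
    std = None
    if {"std_x", "std_y", "std_z"} <= set(v.columns):
        std = v[["std_x", "std_y", "std_z"]].to_numpy(dtype=float)
    return SurfaceMesh(native, t[["v0", "v1", "v2"]].to_numpy(dtype=int), std)


def save_mesh_tsv(mesh: SurfaceMesh, vertices_path, triangles_path) -> None:
    v = pd.DataFrame(mesh.vertex_coords_native, columns=["x", "y", "z"])
    for i, c in enumerate(["std_x", "std_y", "std_z"]):
        v[c] = mesh.vertex_coords_standard[:, i]
    v.to_csv(vertices_path, sep="\t", index=False)
    pd.DataFrame(mesh.triangles, columns=["v0", "v1", "v2"]).to_csv(
        triangles_path, sep="\t", index=False
    )


def load_mesh_gifti(native_path, standard_path=None) -> SurfaceMesh:
    """Read a surface from GIFTI files (pointset + triangle arrays)."""
    import nibabel as nib

    def _read(path):
        img = nib.load(str(path))
        coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
        tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
        return np.asarray(coords, dtype=float), np.asarray(tris, dtype=int)

    native, tris = _read(native_path)
    std = _read(standard_path)[0] if standard_path else None
    return SurfaceMesh(native, tris, std)
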