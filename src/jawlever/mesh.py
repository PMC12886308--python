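"""Tooth surface areas from triangle meshes.

Dental scans arrive as STL triangle meshes (units mm).  This module replaces
the manual envelope-and-measure step with two deterministic quantities per
tooth: total surface area, and the area of the distal tip that concentrates
stress at puncture.

"Distal 10% of tooth area" is interpreted as an *area quantile*: walk the
faces in order of distance from the tip along the tooth axis and accumulate
area until exactly 10% of the total is reached, counting the boundary face
fractionally so the result does not jump with mesh resolution.  An
alternative *height* interpretation (all area within 10% of the tooth's
axial length from the tip) is available via ``mode="height"``; the two
differ on tapered teeth.

Triangle bookkeeping (area sums, STL parsing for both binary and ASCII) is
delegated to :mod:`trimesh`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

__all__ = [
    "MeshError",
    "ToothMesh",
    "TipCut",
    "mesh_surface_area",
    "tip10_area",
    "tip_cut",
    "estimate_tip_and_axis",
    "load_tooth_stl",
    "save_tooth_stl",
    "read_tip_overrides_csv",
]

#: Faces below this area (mm^2) are treated as degenerate and ignored.
DEGENERATE_FACE_AREA = 1e-12

#: Minimum ratio of first to second principal extent for the tooth axis to
#: be considered well defined.
MIN_ANISOTROPY = 1.05


class MeshError(ValueError):
    """Invalid or degenerate tooth mesh."""


@dataclass
class ToothMesh:
    """A single tooth as a triangle mesh plus its tip/base axis.

    ``tip_point`` is the apex (the point that first contacts prey);
    ``base_point`` is a cervical reference at the other end of the crown.
    Either may be omitted and recovered with :func:`estimate_tip_and_axis`.
    """

    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (m, 3) int
    tip_point: np.ndarray | None = None
    base_point: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) index array")
        if len(self.faces) < 4:
            raise MeshError(f"a tooth mesh needs at least 4 faces, got {len(self.faces)}")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshError("non-finite vertex coordinates")
        for name in ("tip_point", "base_point"):
            p = getattr(self, name)
            if p is not None:
                setattr(self, name, np.asarray(p, dtype=float).reshape(3))
        if (
            self.tip_point is not None
            and self.base_point is not None
            and np.allclose(self.tip_point, self.base_point)
        ):
            raise MeshError("tip and base points coincide; tooth axis undefined")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def with_axis(self) -> "ToothMesh":
        """Return self, estimating tip/base from the vertex cloud if unset."""
        if self.tip_point is not None and self.base_point is not None:
            return self
        tip, base = estimate_tip_and_axis(self)
        return ToothMesh(self.vertices, self.faces, tip_point=tip, base_point=base)


def _face_areas_centroids(mesh: ToothMesh) -> tuple[np.ndarray, np.ndarray]:
    tm = mesh.as_trimesh()
    areas = tm.area_faces
    keep = areas > DEGENERATE_FACE_AREA
    return areas[keep], tm.triangles_center[keep]


def mesh_surface_area(mesh: ToothMesh) -> float:
    """Total surface area (mm^2): sum of triangle areas, degenerate faces
    excluded."""
    areas, _ = _face_areas_centroids(mesh)
    if len(areas) == 0:
        raise MeshError("mesh has no non-degenerate faces")
    return float(areas.sum())


@dataclass(frozen=True)
class TipCut:
    """Result of the distal-tip area cut."""

    area_mm2: float
    cut_height_mm: float  # axial distance from the tip to the cut
    fraction: float  # achieved area fraction (exact up to arithmetic)
    axis_length_mm: float


def tip_cut(mesh: ToothMesh, fraction: float = 0.10, mode: str = "area") -> TipCut:
    """Area of the distal portion of the tooth nearest the tip.

    ``mode="area"`` (default): accumulate face areas in order of axial
    distance from the tip until ``fraction`` of the total area is reached,
    the boundary face counted fractionally.  ``mode="height"``: sum the
    faces whose centroid lies within ``fraction`` of the axial length from
    the tip.
    """
    if not 0 < fraction <= 1:
        raise MeshError(f"fraction must be in (0, 1], got {fraction}")
    mesh = mesh.with_axis()
    if mesh.tip_point is None or mesh.base_point is None:
        raise MeshError("tooth axis (tip and base points) is undefined")
    axis = mesh.base_point - mesh.tip_point
    axis_len = float(np.linalg.norm(axis))
    if axis_len == 0.0:
        raise MeshError("tooth axis has zero length")
    u = axis / axis_len

    areas, centroids = _face_areas_centroids(mesh)
    if len(areas) == 0:
        raise MeshError("mesh has no non-degenerate faces")
    dist = (centroids - mesh.tip_point) @ u
    order = np.argsort(dist, kind="stable")
    areas, dist = areas[order], dist[order]
    total = areas.sum()

    if mode == "height":
        h = fraction * axis_len
        sel = dist <= h
        area = float(areas[sel].sum())
        return TipCut(area, h, area / total, axis_len)
    if mode != "area":
        raise MeshError(f"unknown tip-cut mode {mode!r}")

    target = fraction * total
    cum = np.cumsum(areas)
    k = int(np.searchsorted(cum, target))
    if k >= len(areas):
        return TipCut(float(total), float(dist[-1]), 1.0, axis_len)
    # the boundary face is counted fractionally, landing exactly on target
    area = float(target)
    cut_height = float(dist[k])
    return TipCut(area, cut_height, area / total, axis_len)


def tip10_area(mesh: ToothMesh, fraction: float = 0.10, mode: str = "area") -> float:
    """Surface area (mm^2) of the distal ``fraction`` of the tooth.

    See :func:`tip_cut` for the cut semantics and diagnostics.
    """
    return tip_cut(mesh, fraction=fraction, mode=mode).area_mm2


def estimate_tip_and_axis(mesh: ToothMesh) -> tuple[np.ndarray, np.ndarray]:
    """Recover (tip, base) from the vertex cloud of an isolated tooth.

    The tooth axis is the first principal component of the vertices; the tip
    is the extreme vertex on the side farther from the centroid (the pointed
    end carries less surface, so the centroid sits toward the base).
    Deterministic for a fixed mesh.  Raises for nearly isotropic meshes
    where the axis is ill defined.
    """
    v = np.asarray(mesh.vertices, dtype=float)
    centroid = v.mean(axis=0)
    centered = v - centroid
    cov = centered.T @ centered / len(v)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    s1, s2 = np.sqrt(evals[-1]), np.sqrt(max(evals[-2], 0.0))
    if s2 > 0 and s1 / s2 < MIN_ANISOTROPY:
        raise MeshError(
            "vertex cloud is nearly isotropic "
            f"(anisotropy {s1 / s2:.3f} < {MIN_ANISOTROPY}); specify the tip manually"
        )
    axis = evecs[:, -1]
    proj = centered @ axis
    lo, hi = v[int(np.argmin(proj))], v[int(np.argmax(proj))]
    # pointed end = extreme farther from the centroid along the axis (the
    # wide end carries more surface, pulling the centroid toward it)
    if proj.max() >= -proj.min():
        return hi.copy(), lo.copy()
    return lo.copy(), hi.copy()


# ---------------------------------------------------------------------------
# file formats

def load_tooth_stl(
    path,
    tip_point=None,
    base_point=None,
    scale_mm_per_unit: float = 1.0,
) -> ToothMesh:
    """Load an STL file (binary or ASCII) as a :class:`ToothMesh`.

    Coordinates are assumed mm (the dental-scanner convention); pass
    ``scale_mm_per_unit`` to override.
    """
    tm = trimesh.load_mesh(path, file_type="stl", process=False)
    if isinstance(tm, trimesh.Scene):  # pragma: no cover - multi-body stl
        tm = tm.to_mesh()
    return ToothMesh(
        vertices=np.asarray(tm.vertices, dtype=float) * scale_mm_per_unit,
        faces=np.asarray(tm.faces, dtype=int),
        tip_point=None if tip_point is None else np.asarray(tip_point, float) * scale_mm_per_unit,
        base_point=None if base_point is None else np.asarray(base_point, float) * scale_mm_per_unit,
    )


def save_tooth_stl(mesh: ToothMesh, path, ascii_stl: bool = True) -> None:
    """Write a tooth mesh as STL (ASCII by default, so fixtures stay text)."""
    tm = mesh.as_trimesh()
    with open(path, "wb") as fh:
        fh.write(
            trimesh.exchange.stl.export_stl_ascii(tm).encode()
            if ascii_stl
            else trimesh.exchange.stl.export_stl(tm)
        )


def read_tip_overrides_csv(path_or_buf) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Read manual tip/base overrides: CSV columns
    ``tooth_index,tip_x,tip_y,tip_z,base_x,base_y,base_z``."""
    import pandas as pd

    df = pd.read_csv(path_or_buf)
    need = {"tooth_index", "tip_x", "tip_y", "tip_z", "base_x", "base_y", "base_z"}
    missing = need - set(df.columns)
    if missing:
        raise MeshError(f"tip override CSV is missing columns {sorted(missing)}")
    return {
        int(r.tooth_index): (
            np.array([r.tip_x, r.tip_y, r.tip_z], dtype=float),
            np.array([r.base_x, r.base_y, r.base_z], dtype=float),
        )
        for r in df.itertuples()
    }
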