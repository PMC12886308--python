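"""Landmark geometry of the jaw system.

A specimen is digitized as a set of named 2D landmarks on a lateral image of
the head (coordinates in mm after scaling), plus an ordered row of lower-jaw
tooth tips.  All lever quantities derive from distances and angles measured
in this plane:

* the articular-quadrate (AQ) jaw joint is the pivot of the mandibular lever;
* the *inlever* of a muscle is the distance from AQ to its tendon insertion;
* the *outlever* of a tooth is the distance from AQ to its tip;
* the *attachment angle* is the interior angle at the insertion point between
  the muscle's line of action and the inlever.

The module also provides the two rigid motions the workflow needs: rotating a
whole specimen to a standard horizontal pose, and rotating the lower-jaw
point set about AQ to open or close the mouth.

Conventions (not all of which are universal in the literature, so they are
stated here once): x increases rostrally, y increases dorsally; positive jaw
rotation closes the mouth (lower tooth tips move dorsally, i.e. the rotation
is counter-clockwise in this frame); angles are degrees at the API surface
and radians internally.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AQ_JOINT_ID",
    "DEFAULT_HORIZONTAL_AXIS",
    "DEFAULT_LOWER_JAW_IDS",
    "LANDMARK_NAMES",
    "GeometryError",
    "LandmarkSet",
    "JawPartition",
    "rotate_to_horizontal",
    "rotate_jaw",
    "compute_gape_to_closure",
    "inlever",
    "outlevers",
    "attachment_angle",
    "muscle_line_length",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_shapes_txt",
]

#: Landmark ID of the articular-quadrate joint, the lower-jaw pivot.
AQ_JOINT_ID = "7"

#: Axis used to rotate a specimen to the horizontal: AQ joint -> pectoral
#: fin origin.  Overridable in :func:`rotate_to_horizontal`.
DEFAULT_HORIZONTAL_AXIS = ("7", "9")

#: Landmarks that ride on the mandible (tooth tips are always included):
#: rostral lower tooth tip (2), ventral edge of the dentary (3), insertion of
#: the interoperculo-mandibular ligament (11), and the four adductor tendon
#: insertions (12, 13, 15, 18).  The coronoid process (12) is part of the
#: dentary, hence mandibular.
DEFAULT_LOWER_JAW_IDS = frozenset({"2", "3", "11", "12", "13", "15", "18"})

#: Reference names for the 19 cranial landmarks of the digitizing scheme.
LANDMARK_NAMES = {
    "1": "upper_rostral_tooth_tip",
    "2": "lower_rostral_tooth_tip",
    "3": "lower_jaw_ventral_edge",
    "4": "skull_dorsal_edge",
    "5": "eye_center",
    "6": "mouth_corner",
    "7": "articular_quadrate_joint",
    "8": "dorsal_edge_above_pectoral",
    "9": "pectoral_fin_origin",
    "10": "skull_ventral_edge",
    "11": "iop_ligament_insertion",
    "12": "rictalis_lateral_insertion",
    "13": "rictalis_medial_insertion",
    "14": "rictalis_origin",
    "15": "malaris_insertion",
    "16": "malaris_lateral_origin",
    "17": "malaris_medial_origin",
    "18": "stegalis_insertion",
    "19": "stegalis_origin",
}


class GeometryError(ValueError):
    """Invalid or degenerate landmark geometry."""


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(2)
    if not np.all(np.isfinite(a)):
        raise GeometryError(f"non-finite coordinate: {p!r}")
    return a


@dataclass
class LandmarkSet:
    """Named 2D landmarks plus the ordered tooth-tip row of one specimen.

    Parameters
    ----------
    points
        Mapping from landmark ID (``"1"``–``"19"`` for cranial landmarks,
        ``"T1"``…``"TN"`` for tooth tips, anterior to posterior) to 2D
        coordinates.  Coordinates are multiplied by ``scale_mm_per_unit`` on
        construction, so stored values are always mm.
    scale_mm_per_unit
        Image scale factor; must be positive.
    names
        Optional human-readable names per landmark ID.
    """

    points: dict[str, np.ndarray]
    scale_mm_per_unit: float = 1.0
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.scale_mm_per_unit > 0:
            raise GeometryError(
                f"scale_mm_per_unit must be positive, got {self.scale_mm_per_unit}"
            )
        self.points = {
            str(k): _as_point(v) * self.scale_mm_per_unit
            for k, v in self.points.items()
        }
        self.scale_mm_per_unit = 1.0  # coordinates are now mm
        if not self.names:
            self.names = {
                k: LANDMARK_NAMES.get(k, f"tooth_{k[1:]}" if k.startswith("T") else k)
                for k in self.points
            }

    # -- access -----------------------------------------------------------
    @property
    def tooth_ids(self) -> list[str]:
        ids = [k for k in self.points if k.startswith("T")]
        return sorted(ids, key=lambda k: int(k[1:]))

    @property
    def tooth_tips(self) -> list[np.ndarray]:
        """Tooth-tip coordinates, anterior (T1) to posterior (TN)."""
        return [self.points[k] for k in self.tooth_ids]

    @property
    def n_teeth(self) -> int:
        return len(self.tooth_ids)

    def __contains__(self, landmark_id: str) -> bool:
        return str(landmark_id) in self.points

    def point(self, landmark_id: str) -> np.ndarray:
        key = str(landmark_id)
        if key not in self.points:
            raise GeometryError(f"landmark {key!r} is missing from the set")
        return self.points[key]

    @property
    def aq(self) -> np.ndarray:
        """Coordinate of the articular-quadrate joint (landmark 7)."""
        return self.point(AQ_JOINT_ID)

    # -- transforms -------------------------------------------------------
    def transformed(self, func) -> "LandmarkSet":
        """New set with ``func`` applied to every coordinate."""
        new_points = {k: _as_point(func(v)) for k, v in self.points.items()}
        return LandmarkSet(points=new_points, names=dict(self.names))

    def copy(self) -> "LandmarkSet":
        return self.transformed(lambda p: p.copy())


@dataclass(frozen=True)
class JawPartition:
    """Split of landmark IDs into mandibular (rotating) and cranial (fixed).

    Tooth tips always belong to the mandible.  The AQ joint is the pivot and
    must remain cranial.
    """

    lower_jaw_ids: frozenset[str] = DEFAULT_LOWER_JAW_IDS

    def __post_init__(self) -> None:
        ids = frozenset(str(i) for i in self.lower_jaw_ids)
        object.__setattr__(self, "lower_jaw_ids", ids)
        if AQ_JOINT_ID in ids:
            raise GeometryError("the AQ joint (landmark 7) is the pivot and cannot rotate with the jaw")

    def rotating_ids(self, lm: LandmarkSet) -> set[str]:
        present = {i for i in self.lower_jaw_ids if i in lm.points}
        return present | set(lm.tooth_ids)

    def cranial_ids(self, lm: LandmarkSet) -> set[str]:
        return set(lm.points) - self.rotating_ids(lm)


def _rotation(theta_rad: float) -> np.ndarray:
    c, s = math.cos(theta_rad), math.sin(theta_rad)
    return np.array([[c, -s], [s, c]])


def rotate_to_horizontal(
    lm: LandmarkSet, axis_ids: tuple[str, str] = DEFAULT_HORIZONTAL_AXIS
) -> LandmarkSet:
    """Rigidly rotate the whole specimen so a reference axis lies horizontal.

    The specimen is rotated about the first axis landmark until the vector
    from ``axis_ids[0]`` to ``axis_ids[1]`` has zero vertical component and
    positive horizontal component.  Pairwise distances are preserved.
    """
    a_id, b_id = (str(i) for i in axis_ids)
    if a_id == b_id:
        raise GeometryError(f"axis landmarks must be distinct, got {a_id!r} twice")
    a, b = lm.point(a_id), lm.point(b_id)
    v = b - a
    if np.hypot(*v) == 0.0:
        raise GeometryError(f"axis landmarks {a_id!r} and {b_id!r} are coincident")
    theta = -math.atan2(v[1], v[0])
    rot = _rotation(theta)
    return lm.transformed(lambda p: a + rot @ (p - a))


def rotate_jaw(lm: LandmarkSet, degrees: float, part: JawPartition | None = None) -> LandmarkSet:
    """Rotate the mandibular landmarks rigidly about the AQ joint.

    Positive ``degrees`` close the jaw (tooth tips move dorsally); negative
    open it.  Cranial landmarks are untouched.
    """
    if part is None:
        part = JawPartition()
    if not math.isfinite(degrees):
        raise GeometryError(f"rotation angle must be finite, got {degrees}")
    if abs(degrees) > 120:
        warnings.warn(
            f"jaw rotation of {degrees:g} degrees exceeds any physiological gape",
            stacklevel=2,
        )
    pivot = lm.aq
    rot = _rotation(math.radians(degrees))
    moving = part.rotating_ids(lm)

    def move(key_point):
        key, p = key_point
        return pivot + rot @ (p - pivot) if key in moving else p.copy()

    new_points = {k: move((k, v)) for k, v in lm.points.items()}
    return LandmarkSet(points=new_points, names=dict(lm.names))


def compute_gape_to_closure(lm: LandmarkSet) -> float:
    """Signed jaw rotation (degrees) that closes the mouth.

    Measured at the AQ joint as the angle from the ray AQ->lower rostral
    tooth tip (landmark 2) to the ray AQ->upper rostral tooth tip (landmark
    1); applying :func:`rotate_jaw` with the returned angle brings landmark 2
    onto the upper ray.  Zero when the two tips are already collinear with
    the joint.
    """
    aq = lm.aq
    upper = lm.point("1") - aq
    lower = lm.point("2") - aq
    if np.hypot(*upper) == 0.0 or np.hypot(*lower) == 0.0:
        raise GeometryError("rostral tooth tip coincides with the AQ joint; gape undefined")
    ang = math.atan2(upper[1], upper[0]) - math.atan2(lower[1], lower[0])
    # wrap to (-180, 180]
    ang = math.remainder(ang, 2 * math.pi)
    return math.degrees(ang)


def inlever(lm: LandmarkSet, insertion_id: str) -> float:
    """Distance (mm) from the AQ joint to a muscle's tendon insertion."""
    d = float(np.hypot(*(lm.point(insertion_id) - lm.aq)))
    if d == 0.0:
        raise GeometryError(
            f"insertion landmark {insertion_id!r} coincides with the AQ joint (zero inlever)"
        )
    return d


def outlevers(lm: LandmarkSet) -> np.ndarray:
    """Per-tooth distance (mm) from the AQ joint to each tooth tip.

    Ordered anterior (tooth 1) to posterior; all strictly positive.
    """
    tips = lm.tooth_tips
    if not tips:
        raise GeometryError("no tooth tips digitized; outlevers undefined")
    aq = lm.aq
    out = np.array([np.hypot(*(t - aq)) for t in tips])
    if np.any(out == 0.0):
        bad = [tid for tid, o in zip(lm.tooth_ids, out) if o == 0.0]
        raise GeometryError(f"tooth tip(s) {bad} coincide with the AQ joint")
    return out


def _interior_angle(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.hypot(*v1), np.hypot(*v2)
    if n1 == 0.0 or n2 == 0.0:
        raise GeometryError("zero-length vector; angle undefined")
    c = float(np.dot(v1, v2) / (n1 * n2))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def attachment_angle(lm: LandmarkSet, insertion_id: str, origin_id: str) -> float:
    """Interior angle (degrees, 0–180) at the insertion between the muscle
    line of action (insertion->origin) and the inlever (insertion->AQ)."""
    ins = lm.point(insertion_id)
    return _interior_angle(lm.point(origin_id) - ins, lm.aq - ins)


def muscle_line_length(lm: LandmarkSet, insertion_id: str, origin_id: str) -> float:
    """Straight-line distance (mm) from insertion to origin landmark."""
    return float(np.hypot(*(lm.point(origin_id) - lm.point(insertion_id))))


# ---------------------------------------------------------------------------
# file formats

def read_landmarks_csv(path_or_buf, scale_mm_per_unit: float = 1.0) -> LandmarkSet:
    """Read a landmark CSV with columns ``landmark_id,name,x,y``.

    Tooth tips use IDs ``T1``…``TN``; anything else is a named cranial
    landmark.  The ``name`` column is optional.
    """
    df = pd.read_csv(path_or_buf, dtype={"landmark_id": str}, float_precision="round_trip")
    missing = {"landmark_id", "x", "y"} - set(df.columns)
    if missing:
        raise GeometryError(f"landmark CSV is missing columns {sorted(missing)}")
    points = {str(r.landmark_id): (r.x, r.y) for r in df.itertuples()}
    names = (
        {str(r.landmark_id): str(r.name) for r in df.itertuples()}
        if "name" in df.columns
        else {}
    )
    return LandmarkSet(points=points, names=names, scale_mm_per_unit=scale_mm_per_unit)


def write_landmarks_csv(lm: LandmarkSet, path_or_buf) -> None:
    rows = [
        {"landmark_id": k, "name": lm.names.get(k, k), "x": p[0], "y": p[1]}
        for k, p in lm.points.items()
    ]
    pd.DataFrame(rows).to_csv(path_or_buf, index=False)


def read_shapes_txt(path_or_buf, scale_mm_per_unit: float = 1.0) -> LandmarkSet:
    """Read the two-column text dialect exported by 2D digitizing tools.

    The format alternates a header line holding the landmark ID/name with a
    line of tab- (or whitespace-) separated ``x y`` coordinates.
    """
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf, encoding="utf-8") as fh:
            text = fh.read()
    lines = [ln.strip() for ln in io.StringIO(text) if ln.strip()]
    if len(lines) % 2:
        raise GeometryError("shapes file must alternate name and coordinate lines")
    points: dict[str, tuple[float, float]] = {}
    for name_line, coord_line in zip(lines[::2], lines[1::2]):
        parts = coord_line.replace("\t", " ").split()
        if len(parts) != 2:
            raise GeometryError(f"expected 'x y' after {name_line!r}, got {coord_line!r}")
        points[name_line] = (float(parts[0]), float(parts[1]))
    return LandmarkSet(points=points, scale_mm_per_unit=scale_mm_per_unit)
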