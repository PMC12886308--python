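"""Deterministic synthetic specimens and tooth meshes for testing and demos.

Real morphometric inputs (digitized landmark files, dissected muscle masses,
scanned tooth meshes) are study data; this module fabricates structurally
faithful stand-ins whose lever solutions are analytically known, so every
stage of the pipeline can be exercised and cross-checked without any
download.

The generated jaw mimics a generic short-snouted piranha: seven lower-jaw
teeth whose outlevers shrink toward the articular-quadrate joint, five
adductor subdivisions inserting between the coronoid region and the medial
dentary with origins on the suspensorium (so every muscle produces closing
torque), body sizes spanning roughly 0.03–1.2 kg / 105–298 mm standard
length.  It does **not** emulate interspecific covariance of muscle
architecture, bone compliance, or real tooth shapes — synthetic results
validate the mechanics, not piranha biology.

``textbook=True`` collapses the jaw to a single perpendicular muscle with a
prescribed force and inlever, for which the bite force at every tooth has
the closed form ``F * L_in / L_out``.
"""

from __future__ import annotations

import math

import numpy as np

from .geometry import GeometryError, LandmarkSet, rotate_jaw
from .io import Specimen
from .mesh import ToothMesh
from .muscles import MuscleArchitecture
from .stress import ToothRecord

__all__ = ["make_specimen", "make_textbook_specimen", "make_cone_tooth"]

# relative landmark layout (units of jaw length L, closed pose, AQ at origin)
_CRANIAL_LAYOUT = {
    "4": (0.30, 0.90),
    "5": (0.35, 0.60),
    "6": (0.70, 0.20),
    "7": (0.00, 0.00),
    "8": (-1.20, 0.40),
    "9": (-1.00, -0.10),
    "10": (0.10, -0.20),
    "14": (0.15, 0.45),
    "16": (-0.05, 0.50),
    "17": (-0.10, 0.60),
    "19": (-0.08, 0.40),
}
_MANDIBLE_LAYOUT = {
    "3": (0.90, -0.10),
    "11": (0.15, -0.05),
    "12": (0.45, 0.15),
    "13": (0.42, 0.10),
    "15": (0.35, 0.11),
    "18": (0.33, 0.10),
}

# mass fractions of the adductor complex; the malaris subdivisions dominate
_MASS_FRACTIONS = {
    "rictalis_lateral": 0.04,
    "rictalis_medial": 0.04,
    "malaris_lateral": 0.45,
    "malaris_medial": 0.38,
    "stegalis": 0.09,
}


def make_specimen(
    seed: int,
    n_teeth: int = 7,
    body_scale_mm: float | None = None,
    *,
    gape_deg: float = 0.0,
    rictalis_mass_split: float = 0.5,
    adductor_mass_fraction: float = 0.02,
    jitter: float = 0.05,
    specimen_id: str | None = None,
) -> Specimen:
    """Generate a reproducible synthetic specimen.

    Parameters
    ----------
    seed
        Seeds all randomness; the same seed yields a byte-identical specimen.
    n_teeth
        Number of lower-jaw teeth (anterior to posterior), default 7.
    body_scale_mm
        Standard length in mm; drawn from 105–298 mm when omitted.
    gape_deg
        If positive, the mandible is rotated open by this angle, so
        the specimen arrives with the mouth ajar.
    rictalis_mass_split
        Fraction of the (shared) rictalis dissected mass assigned to the
        lateral portion; the remainder goes to the medial portion.
    adductor_mass_fraction
        Adductor complex mass as a fraction of body mass.
    jitter
        Relative geometric noise on landmark positions (kept small enough
        that all invariants — decreasing outlevers, closing torques —
        hold for every seed).
    """
    if n_teeth < 1:
        raise GeometryError(f"n_teeth must be >= 1, got {n_teeth}")
    if not 0.0 <= rictalis_mass_split <= 1.0:
        raise GeometryError("rictalis_mass_split must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sl = float(body_scale_mm) if body_scale_mm is not None else float(rng.uniform(105.0, 298.0))
    if sl <= 0:
        raise GeometryError(f"body_scale_mm must be positive, got {body_scale_mm}")
    body_mass_kg = 3.5e-8 * sl**3 * float(rng.lognormal(0.0, 0.15))
    jaw_len = 0.18 * sl * float(rng.uniform(0.9, 1.1))

    def jit(xy):
        return np.asarray(xy) + rng.uniform(-jitter, jitter, size=2) * 0.5

    points: dict[str, tuple[float, float]] = {}
    for k, xy in {**_CRANIAL_LAYOUT, **_MANDIBLE_LAYOUT}.items():
        p = jit(xy) if k != "7" else np.asarray(xy, float)
        points[k] = (p[0] * jaw_len, p[1] * jaw_len)

    # tooth row: outlevers strictly decreasing from anterior (T1) to
    # posterior (TN); constant height keeps the ordering exact
    x_front, x_back = 0.90, 0.30
    y_tooth = 0.04
    xs = np.linspace(x_front, x_back, n_teeth)
    if n_teeth > 1:
        spacing = (x_front - x_back) / (n_teeth - 1)
        xs = xs + rng.uniform(-0.3, 0.3, size=n_teeth) * spacing
        xs = np.sort(xs)[::-1]
    for i, x in enumerate(xs, start=1):
        points[f"T{i}"] = (float(x) * jaw_len, y_tooth * jaw_len)
    points["2"] = points["T1"]
    # upper rostral tooth tip: collinear with AQ -> T1 so the closed pose
    # has zero residual gape
    points["1"] = tuple(1.02 * np.asarray(points["T1"]))

    lm = LandmarkSet(points=points)
    if gape_deg:
        lm = rotate_jaw(lm, -abs(gape_deg))

    am_mass_g = adductor_mass_fraction * body_mass_kg * 1000.0
    fracs = dict(_MASS_FRACTIONS)
    ric_total = fracs.pop("rictalis_lateral") + fracs.pop("rictalis_medial")
    fracs["rictalis_lateral"] = ric_total * rictalis_mass_split
    fracs["rictalis_medial"] = ric_total * (1.0 - rictalis_mass_split)
    muscles = []
    for name, frac in fracs.items():
        penn = rng.uniform(8.0, 28.0)
        muscles.append(
            MuscleArchitecture(
                name=name,
                mass_g=max(am_mass_g * frac * float(rng.lognormal(0.0, 0.05)), 1e-6),
                pennation_deg=tuple(
                    float(np.clip(penn + d, 0.0, 90.0))
                    for d in rng.uniform(-4.0, 4.0, size=3)
                ),
                tendon_length_mm=float(rng.uniform(0.05, 0.15)) * jaw_len,
            )
        )
    muscles.sort(key=lambda m: m.name)

    # tooth areas: anterior teeth larger (outlever-ranked), total scaled so
    # the dental area : standard length ratio lands in a realistic band
    total_area = 0.0021 * sl**2 * float(rng.lognormal(0.0, 0.1))
    weights = xs**1.5
    weights = weights / weights.sum()
    teeth = [
        ToothRecord(
            tooth_index=i,
            surface_area_mm2=float(total_area * w),
            tip10_area_mm2=float(total_area * w * 0.10),
        )
        for i, w in enumerate(weights, start=1)
    ]

    return Specimen(
        specimen_id=specimen_id or f"synthetic-{seed}",
        landmarks=lm,
        muscles=muscles,
        teeth=teeth,
        body_mass_kg=body_mass_kg,
        standard_length_mm=sl,
        species="synthetic",
        diet_guild="synthetic",
    )


def make_textbook_specimen(
    force_n: float = 100.0,
    inlever_mm: float = 5.0,
    anterior_outlever_mm: float = 10.0,
    posterior_outlever_mm: float = 5.0,
    n_teeth: int = 6,
    specific_tension_kpa: float = 300.0,
) -> Specimen:
    """Single perpendicular-muscle jaw with a closed-form solution.

    One muscle of maximum force ``force_n`` inserts at distance
    ``inlever_mm`` straight above the joint with its line of action
    perpendicular to the inlever; teeth lie on the horizontal axis with
    outlevers linearly spaced from anterior to posterior.  At full
    activation the bite force at a tooth with outlever ``L`` is exactly
    ``force_n * inlever_mm / L``.
    """
    if inlever_mm > anterior_outlever_mm:
        raise GeometryError(
            "textbook specimen expects inlever <= anterior outlever "
            f"(got {inlever_mm} > {anterior_outlever_mm})"
        )
    if not posterior_outlever_mm > 0 or posterior_outlever_mm > anterior_outlever_mm:
        raise GeometryError("need 0 < posterior outlever <= anterior outlever")
    outs = np.linspace(anterior_outlever_mm, posterior_outlever_mm, n_teeth)
    points: dict[str, tuple[float, float]] = {
        "7": (0.0, 0.0),
        "9": (-20.0, 0.0),
        "3": (anterior_outlever_mm, -1.0),
        "15": (0.0, inlever_mm),
        "16": (-inlever_mm, inlever_mm),
    }
    for i, L in enumerate(outs, start=1):
        points[f"T{i}"] = (float(L), 0.0)
    points["2"] = points["T1"]
    points["1"] = (points["T1"][0], 0.5)

    # mass chosen so PCSA * specific tension = force_n at fiber length
    # = whole length (tendon 0, pennation 0)
    whole_mm = inlever_mm  # |insertion - origin|
    pcsa_cm2 = force_n / (specific_tension_kpa * 0.1)
    mass_g = pcsa_cm2 * 1.06 * (whole_mm / 10.0)
    muscle = MuscleArchitecture(
        name="malaris_lateral",
        mass_g=mass_g,
        pennation_deg=(0.0, 0.0, 0.0),
        tendon_length_mm=0.0,
        insertion_id="15",
        origin_id="16",
    )
    teeth = [
        ToothRecord(tooth_index=i, surface_area_mm2=10.0, tip10_area_mm2=1.0)
        for i in range(1, n_teeth + 1)
    ]
    return Specimen(
        specimen_id="textbook",
        landmarks=LandmarkSet(points=points),
        muscles=[muscle],
        teeth=teeth,
        body_mass_kg=0.1,
        standard_length_mm=100.0,
        species="textbook",
        diet_guild="textbook",
    )


def make_cone_tooth(
    height_mm: float,
    radius_mm: float,
    n_segments: int = 64,
    n_rings: int = 32,
    seed: int = 0,
) -> ToothMesh:
    """Triangulated open cone with the apex tagged as the tooth tip.

    Lateral surface area has the closed form ``pi * r * sqrt(r^2 + h^2)``;
    the ``seed`` only rotates the azimuthal starting angle, so geometry-level
    quantities are unchanged across seeds.
    """
    if not (height_mm > 0 and radius_mm > 0):
        raise GeometryError("cone dimensions must be positive")
    if n_segments < 8:
        raise GeometryError(f"n_segments must be >= 8, got {n_segments}")
    if n_rings < 1:
        raise GeometryError(f"n_rings must be >= 1, got {n_rings}")
    phase = (seed % 360) * math.pi / 180.0
    apex = np.array([0.0, 0.0, height_mm])
    verts = [apex]
    for j in range(1, n_rings + 1):
        f = j / n_rings
        z = height_mm * (1.0 - f)
        r = radius_mm * f
        ang = phase + 2.0 * np.pi * np.arange(n_segments) / n_segments
        ring = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.full(n_segments, z)])
        verts.append(ring)
    vertices = np.vstack([verts[0][None, :], *verts[1:]])

    def ring_start(j):  # 1-based ring index
        return 1 + (j - 1) * n_segments

    faces = []
    # apex fan to ring 1
    s1 = ring_start(1)
    for i in range(n_segments):
        faces.append([0, s1 + i, s1 + (i + 1) % n_segments])
    # quads between consecutive rings
    for j in range(1, n_rings):
        a, b = ring_start(j), ring_start(j + 1)
        for i in range(n_segments):
            i2 = (i + 1) % n_segments
            faces.append([a + i, b + i, b + i2])
            faces.append([a + i, b + i2, a + i2])
    return ToothMesh(
        vertices=vertices,
        faces=np.asarray(faces, dtype=int),
        tip_point=apex,
        base_point=np.array([0.0, 0.0, 0.0]),
    )
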