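"""Adductor muscle architecture, PCSA, maximum force and length–tension scaling.

The jaw-closing adductor mandibulae complex is modelled as five independent
subdivisions (pars rictalis lateral/medial, pars malaris lateral/medial, pars
stegalis), each reduced to a straight line of action between its tendon
insertion on the mandible and its origin on the suspensorium.

Force capacity follows the standard physiological cross-sectional area
route::

    PCSA [cm^2] = mass [g] * cos(mean pennation) / (density [g/cm^3] * fiber length [cm])
    F_max [N]   = PCSA [m^2] * specific tension [Pa]

with a specific tension of 300 kPa by default (30 N per cm^2).

Length–tension behaviour across the gape cycle uses a Hill-type activation
factor.  With ``k`` the curvature constant and ``V`` a velocity surrogate in
muscle lengths per second, the activation is the quotient
``(k - k*V) / (k + V)``: it is maximal at the closed jaw (``V = minV``) and
minimal at full gape (``V = maxV``).  With the default ``maxV = 8`` the raw
open-jaw value is negative (−0.212…); since muscle cannot push, it is clamped
to zero unless ``clamp_negative`` is disabled.  An optional
``normalize_velocity`` flag divides the surrogate by ``maxV`` before the
quotient, which pins the open-jaw activation at exactly zero instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .geometry import LandmarkSet, muscle_line_length

__all__ = [
    "MUSCLE_NAMES",
    "DEFAULT_MUSCLE_ATTACHMENTS",
    "MuscleError",
    "MuscleArchitecture",
    "HillParameters",
    "muscle_length",
    "fiber_length",
    "pcsa",
    "max_muscle_force",
    "hill_bounds",
    "activation_at_gape",
    "read_muscles_csv",
    "write_muscles_csv",
]

#: The five adductor mandibulae subdivisions modelled.
MUSCLE_NAMES = (
    "rictalis_lateral",
    "rictalis_medial",
    "malaris_lateral",
    "malaris_medial",
    "stegalis",
)

#: Default (insertion, origin) landmark IDs per subdivision.  The malaris
#: subdivisions and the stegalis act through a shared tendon complex on the
#: medial dentary (insertions 15/18) but keep their own origins (16, 17, 19)
#: and hence their own attachment angles; both rictalis portions share the
#: origin on the malaris surface (14).
DEFAULT_MUSCLE_ATTACHMENTS = {
    "rictalis_lateral": ("12", "14"),
    "rictalis_medial": ("13", "14"),
    "malaris_lateral": ("15", "16"),
    "malaris_medial": ("15", "17"),
    "stegalis": ("18", "19"),
}


class MuscleError(ValueError):
    """Invalid muscle architecture or Hill parameters."""


@dataclass
class MuscleArchitecture:
    """Dissection-level architecture of one adductor subdivision.

    ``pennation_deg`` holds the three protractor measurements taken dorsal
    to, in line with, and ventral to the tendon; they are combined as an
    arithmetic mean.  ``tendon_length_mm`` is subtracted from the whole
    muscle path to approximate fiber length (see :func:`fiber_length`).
    """

    name: str
    mass_g: float
    pennation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tendon_length_mm: float = 0.0
    insertion_id: str | None = None
    origin_id: str | None = None
    density_g_per_cm3: float = 1.06

    def __post_init__(self) -> None:
        if self.name not in MUSCLE_NAMES:
            warnings.warn(
                f"unrecognized muscle name {self.name!r}; expected one of {MUSCLE_NAMES}",
                stacklevel=2,
            )
        if not self.mass_g > 0:
            raise MuscleError(f"{self.name}: mass must be positive, got {self.mass_g}")
        self.pennation_deg = tuple(float(a) for a in self.pennation_deg)
        if len(self.pennation_deg) != 3:
            raise MuscleError(f"{self.name}: three pennation angles required")
        for a in self.pennation_deg:
            if not 0.0 <= a <= 90.0:
                raise MuscleError(
                    f"{self.name}: pennation angle {a} outside [0, 90] degrees"
                )
        if self.tendon_length_mm < 0:
            raise MuscleError(f"{self.name}: tendon length cannot be negative")
        if not self.density_g_per_cm3 > 0:
            raise MuscleError(f"{self.name}: density must be positive")
        if self.insertion_id is None or self.origin_id is None:
            default = DEFAULT_MUSCLE_ATTACHMENTS.get(self.name)
            if default is None:
                raise MuscleError(
                    f"{self.name}: insertion/origin landmarks required (no default known)"
                )
            ins, org = default
            self.insertion_id = self.insertion_id or ins
            self.origin_id = self.origin_id or org
        self.insertion_id = str(self.insertion_id)
        self.origin_id = str(self.origin_id)

    @property
    def mean_pennation_deg(self) -> float:
        return sum(self.pennation_deg) / 3.0


@dataclass(frozen=True)
class HillParameters:
    """Parameters of the Hill-type length–tension scaling.

    Defaults: ``k = 0.25``, ``maxV = 8`` and ``minV = 0.05`` muscle lengths
    per second, specific tension 300 kPa.  All are user-tunable.
    """

    k: float = 0.25
    max_v: float = 8.0
    min_v: float = 0.05
    specific_tension_kpa: float = 300.0
    clamp_negative: bool = True
    normalize_velocity: bool = False

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise MuscleError(f"k must be positive, got {self.k}")
        if not (self.max_v > self.min_v > 0):
            raise MuscleError(
                f"need maxV > minV > 0, got maxV={self.max_v}, minV={self.min_v}"
            )
        if not self.specific_tension_kpa > 0:
            raise MuscleError("specific tension must be positive")


def muscle_length(lm: LandmarkSet, m: MuscleArchitecture) -> float:
    """Whole-muscle path length (mm): insertion to origin at the current
    jaw position."""
    for lid in (m.insertion_id, m.origin_id):
        if lid not in lm:
            raise MuscleError(f"muscle {m.name}: landmark {lid!r} missing from specimen")
    return muscle_line_length(lm, m.insertion_id, m.origin_id)


def fiber_length(m: MuscleArchitecture, whole_length_mm: float, *, use_whole: bool = False) -> float:
    """Fiber length (mm) available for force generation.

    By default the tendon is treated as inextensible in series, so fiber
    length is whole-muscle path length minus tendon length; ``use_whole``
    skips the subtraction.
    """
    if use_whole:
        fl = float(whole_length_mm)
    else:
        fl = float(whole_length_mm) - m.tendon_length_mm
    if not fl > 0:
        raise MuscleError(
            f"muscle {m.name}: non-positive fiber length "
            f"(whole {whole_length_mm} mm, tendon {m.tendon_length_mm} mm)"
        )
    return fl


def pcsa(m: MuscleArchitecture, fiber_length_mm: float) -> float:
    """Physiological cross-sectional area (cm^2).

    ``mass * cos(mean pennation) / (density * fiber length)`` with fiber
    length in cm.  A mean pennation of 90 degrees yields zero area (with a
    warning) rather than an error.
    """
    if not fiber_length_mm > 0:
        raise MuscleError(f"muscle {m.name}: fiber length must be positive")
    theta = m.mean_pennation_deg
    if theta >= 90.0:
        warnings.warn(
            f"muscle {m.name}: mean pennation {theta} deg >= 90; PCSA set to 0",
            stacklevel=2,
        )
        return 0.0
    fiber_cm = fiber_length_mm / 10.0
    return m.mass_g * math.cos(math.radians(theta)) / (m.density_g_per_cm3 * fiber_cm)


def max_muscle_force(pcsa_cm2: float, hp: HillParameters | None = None) -> float:
    """Maximum isometric force (N) = PCSA (m^2) x specific tension (Pa).

    With the default 300 kPa this is 30 N per cm^2.
    """
    if hp is None:
        hp = HillParameters()
    if pcsa_cm2 < 0:
        raise MuscleError(f"PCSA cannot be negative, got {pcsa_cm2}")
    # 1 cm^2 = 1e-4 m^2; 1 kPa = 1e3 Pa  ->  0.1 N per (cm^2 * kPa)
    return pcsa_cm2 * 1e-4 * hp.specific_tension_kpa * 1e3


def _hill_quotient(k: float, v: float) -> float:
    denom = k + v
    if denom == 0.0:
        raise MuscleError("Hill quotient undefined: k + V = 0")
    return (k - k * v) / denom


def hill_bounds(hp: HillParameters | None = None) -> tuple[float, float]:
    """Activation bounds ``(minF, maxF)`` of the length–tension curve.

    ``minF = (k - k*maxV)/(k + maxV)`` (jaws fully open, muscle at maximum
    stretch) and ``maxF = (k - k*minV)/(k + minV)`` (jaws closed).  With the
    printed defaults maxF = 0.79167 and the raw minF = -0.21212, clamped to
    0 when ``clamp_negative`` is set.
    """
    if hp is None:
        hp = HillParameters()
    if hp.normalize_velocity:
        min_f = _hill_quotient(hp.k, 1.0)
        max_f = _hill_quotient(hp.k, hp.min_v / hp.max_v)
    else:
        min_f = _hill_quotient(hp.k, hp.max_v)
        max_f = _hill_quotient(hp.k, hp.min_v)
    if hp.clamp_negative:
        min_f = max(0.0, min_f)
    return min_f, max_f


def activation_at_gape(
    gape_deg: float, max_gape_deg: float, hp: HillParameters | None = None
) -> float:
    """Activation factor at a given gape, in ``[minF_clamped, maxF]``.

    The gape fraction maps linearly onto the velocity surrogate,
    ``V(g) = minV + (maxV - minV) * g / max_gape``, which is fed through the
    Hill quotient.  Monotone non-increasing in gape: maximal with the jaw
    closed (g = 0), minimal at full gape.
    """
    if hp is None:
        hp = HillParameters()
    if not max_gape_deg > 0:
        raise MuscleError(f"max_gape_deg must be positive, got {max_gape_deg}")
    if not 0.0 <= gape_deg <= max_gape_deg:
        raise MuscleError(
            f"gape {gape_deg} deg outside [0, {max_gape_deg}]"
        )
    v = hp.min_v + (hp.max_v - hp.min_v) * (gape_deg / max_gape_deg)
    if hp.normalize_velocity:
        v = v / hp.max_v
    act = _hill_quotient(hp.k, v)
    if hp.clamp_negative:
        act = max(0.0, act)
    return act


# ---------------------------------------------------------------------------
# file format

_MUSCLE_COLUMNS = [
    "specimen_id",
    "muscle",
    "mass_g",
    "penn_dorsal",
    "penn_inline",
    "penn_ventral",
    "tendon_mm",
    "insertion_id",
    "origin_id",
]


def read_muscles_csv(path_or_buf, specimen_id: str | None = None) -> list[MuscleArchitecture]:
    """Read a muscle-architecture CSV (one row per muscle subdivision).

    Columns: ``specimen_id,muscle,mass_g,penn_dorsal,penn_inline,
    penn_ventral,tendon_mm,insertion_id,origin_id``.  If ``specimen_id`` is
    given, only that specimen's rows are returned.
    """
    df = pd.read_csv(
        path_or_buf,
        dtype={"insertion_id": str, "origin_id": str, "specimen_id": str},
        float_precision="round_trip",
    )
    missing = set(_MUSCLE_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise MuscleError(f"muscle CSV is missing columns {sorted(missing)}")
    if specimen_id is not None:
        df = df[df["specimen_id"] == str(specimen_id)]
    def _id_or_none(value):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        return str(value)

    out = []
    for r in df.itertuples():
        out.append(
            MuscleArchitecture(
                name=str(r.muscle),
                mass_g=float(r.mass_g),
                pennation_deg=(float(r.penn_dorsal), float(r.penn_inline), float(r.penn_ventral)),
                tendon_length_mm=float(r.tendon_mm),
                insertion_id=_id_or_none(getattr(r, "insertion_id", None)),
                origin_id=_id_or_none(getattr(r, "origin_id", None)),
            )
        )
    return out


def write_muscles_csv(muscles: list[MuscleArchitecture], path_or_buf, specimen_id: str = "specimen") -> None:
    rows = [
        {
            "specimen_id": specimen_id,
            "muscle": m.name,
            "mass_g": m.mass_g,
            "penn_dorsal": m.pennation_deg[0],
            "penn_inline": m.pennation_deg[1],
            "penn_ventral": m.pennation_deg[2],
            "tendon_mm": m.tendon_length_mm,
            "insertion_id": m.insertion_id,
            "origin_id": m.origin_id,
        }
        for m in muscles
    ]
    pd.DataFrame(rows, columns=_MUSCLE_COLUMNS).to_csv(path_or_buf, index=False)
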