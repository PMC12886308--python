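"""Tooth stress and mass-specific performance metrics.

Bite force becomes ecologically meaningful once spread over the tooth
surface that delivers it: stress = force / area, reported in kPa.  Two
stresses are computed per tooth — over the whole tooth surface, and over the
distal 10% of that surface (the cutting tip engaged at initial puncture).
Dividing forces and stresses by body mass (kg) gives the mass-specific
metrics used for cross-taxon comparison.

Note on units: 1 N over 1 mm^2 is 1 MPa = 1000 kPa, so
``stress_kPa = 1000 * F[N] / A[mm^2]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lever import BiteProfile

__all__ = [
    "StressError",
    "ToothRecord",
    "tooth_stress",
    "tip_stress",
    "mass_specific",
    "summarize_specimen",
    "read_teeth_csv",
    "write_teeth_csv",
]


class StressError(ValueError):
    """Invalid tooth record or stress input."""


@dataclass(frozen=True)
class ToothRecord:
    """Surface-area record of one tooth (index 1 = anterior-most)."""

    tooth_index: int
    surface_area_mm2: float
    tip10_area_mm2: float

    def __post_init__(self) -> None:
        if not self.surface_area_mm2 > 0:
            raise StressError(
                f"tooth {self.tooth_index}: surface area must be positive"
            )
        if not 0 < self.tip10_area_mm2 <= self.surface_area_mm2:
            raise StressError(
                f"tooth {self.tooth_index}: tip area must be in (0, total area]"
            )


def tooth_stress(bite_force_n: float, area_mm2: float) -> float:
    """Stress (kPa) of a bite force spread over a tooth surface."""
    if not area_mm2 > 0:
        raise StressError(f"tooth area must be positive, got {area_mm2}")
    if bite_force_n < 0:
        raise StressError(f"bite force cannot be negative, got {bite_force_n}")
    return 1000.0 * bite_force_n / area_mm2


def tip_stress(bite_force_n: float, tip10_area_mm2: float) -> float:
    """Stress (kPa) concentrated on the distal 10% of the tooth surface —
    the relevant quantity at initial contact and puncture."""
    return tooth_stress(bite_force_n, tip10_area_mm2)


def mass_specific(value: float, body_mass_kg: float) -> float:
    """Performance metric divided by body mass (N/kg or kPa/kg)."""
    if not body_mass_kg > 0:
        raise StressError(f"body mass must be positive, got {body_mass_kg}")
    return value / body_mass_kg


def summarize_specimen(
    profile: BiteProfile,
    teeth: list[ToothRecord],
    body_mass_kg: float,
    standard_length_mm: float | None = None,
    specimen_id: str = "specimen",
) -> dict[str, float | str]:
    """Per-specimen summary row: anterior/posterior/mean bite force and
    stress, tip stresses, total dental surface area, SA:SL ratio and the
    mass-specific versions.

    ``teeth`` must align one-to-one with the profile's tooth indices.
    Anterior = tooth 1, posterior = tooth N (nearest the jaw joint); means
    are unweighted across tooth positions.
    """
    recs = sorted(teeth, key=lambda t: t.tooth_index)
    if [t.tooth_index for t in recs] != [t.tooth_index for t in profile.teeth]:
        raise StressError(
            "tooth records do not align with the bite profile "
            f"({[t.tooth_index for t in recs]} vs {[t.tooth_index for t in profile.teeth]})"
        )
    forces = profile.bite_forces_n
    areas = np.array([t.surface_area_mm2 for t in recs])
    tip_areas = np.array([t.tip10_area_mm2 for t in recs])
    stresses = np.array([tooth_stress(f, a) for f, a in zip(forces, areas)])
    tip_stresses = np.array([tip_stress(f, a) for f, a in zip(forces, tip_areas)])
    total_area = float(areas.sum())

    row: dict[str, float | str] = {
        "specimen_id": specimen_id,
        "body_mass_kg": body_mass_kg,
        "n_teeth": len(recs),
        "anterior_bite_force_N": float(forces[0]),
        "posterior_bite_force_N": float(forces[-1]),
        "mean_bite_force_N": float(forces.mean()),
        "anterior_bite_stress_kPa": float(stresses[0]),
        "posterior_bite_stress_kPa": float(stresses[-1]),
        "mean_bite_stress_kPa": float(stresses.mean()),
        "anterior_tip_stress_kPa": float(tip_stresses[0]),
        "posterior_tip_stress_kPa": float(tip_stresses[-1]),
        "mean_tip_stress_kPa": float(tip_stresses.mean()),
        "total_dental_area_mm2": total_area,
        "anterior_ms_force_N_per_kg": mass_specific(float(forces[0]), body_mass_kg),
        "posterior_ms_force_N_per_kg": mass_specific(float(forces[-1]), body_mass_kg),
        "mean_ms_stress_kPa_per_kg": mass_specific(float(stresses.mean()), body_mass_kg),
        "posterior_ms_tip_stress_kPa_per_kg": mass_specific(
            float(tip_stresses[-1]), body_mass_kg
        ),
    }
    if standard_length_mm is not None:
        row["standard_length_mm"] = standard_length_mm
        row["sa_sl_ratio"] = total_area / standard_length_mm
    return row


# ---------------------------------------------------------------------------
# file format

def read_teeth_csv(path_or_buf, specimen_id: str | None = None) -> list[ToothRecord]:
    """Read a tooth surface-area CSV with columns
    ``specimen_id,tooth_index,surface_area_mm2,tip10_area_mm2``."""
    df = pd.read_csv(path_or_buf, dtype={"specimen_id": str}, float_precision="round_trip")
    missing = {"tooth_index", "surface_area_mm2", "tip10_area_mm2"} - set(df.columns)
    if missing:
        raise StressError(f"tooth CSV is missing columns {sorted(missing)}")
    if specimen_id is not None and "specimen_id" in df.columns:
        df = df[df["specimen_id"] == str(specimen_id)]
    return [
        ToothRecord(
            tooth_index=int(r.tooth_index),
            surface_area_mm2=float(r.surface_area_mm2),
            tip10_area_mm2=float(r.tip10_area_mm2),
        )
        for r in df.itertuples()
    ]


def write_teeth_csv(teeth: list[ToothRecord], path_or_buf, specimen_id: str = "specimen") -> None:
    rows = [
        {
            "specimen_id": specimen_id,
            "tooth_index": t.tooth_index,
            "surface_area_mm2": t.surface_area_mm2,
            "tip10_area_mm2": t.tip10_area_mm2,
        }
        for t in teeth
    ]
    pd.DataFrame(rows).to_csv(path_or_buf, index=False)
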