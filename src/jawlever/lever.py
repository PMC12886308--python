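"""Static lever transmission of muscle force to every tooth of the mandible.

The lower jaw is treated as a rigid third-class/first-class lever pivoting at
the articular-quadrate (AQ) joint.  Each adductor subdivision applies its
force along the straight insertion->origin line; only the component
perpendicular to the inlever produces closing torque:

    torque_m      = F_m * inlever_m * sin(attachment angle)
    moment arm_m  = inlever_m * sin(attachment angle)

For a tooth with outlever L_i, the transmitted bite force is the summed
torque divided by the outlever, equivalently per muscle

    MA  = inlever / outlever                (mechanical advantage)
    EMA = MA * sin(attachment angle)        (effective mechanical advantage)
    F_bite(i) = sum_m F_m * EMA(m, i) = (sum_m torque_m) / L_i

Bite force at the tooth is taken perpendicular to the AQ->tip ray (pure
rotational statics).  Forces are for the muscles of one side of the head;
set ``bilateral=True`` to double them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import GeometryError, LandmarkSet, attachment_angle, inlever, outlevers
from .muscles import (
    HillParameters,
    MuscleArchitecture,
    activation_at_gape,
    fiber_length,
    hill_bounds,
    max_muscle_force,
    muscle_length,
    pcsa,
)

__all__ = [
    "MuscleState",
    "ToothForce",
    "BiteProfile",
    "mechanical_advantage",
    "effective_mechanical_advantage",
    "muscle_torque",
    "bite_force_profile",
]


def mechanical_advantage(inlever_mm: float, outlever_mm: float) -> float:
    """Lever ratio inlever/outlever; > 1 amplifies force at the tooth."""
    if not (inlever_mm > 0 and outlever_mm > 0):
        raise GeometryError(
            f"lever arms must be positive (inlever={inlever_mm}, outlever={outlever_mm})"
        )
    return inlever_mm / outlever_mm


def effective_mechanical_advantage(ma: float, attachment_angle_deg: float) -> float:
    """MA scaled by sin(attachment angle): the fraction of muscle force that
    acts perpendicular to the inlever.  Maximal at 90 degrees, zero when the
    line of action passes through the joint (0 or 180 degrees)."""
    if not ma > 0:
        raise GeometryError(f"mechanical advantage must be positive, got {ma}")
    if not 0.0 <= attachment_angle_deg <= 180.0:
        raise GeometryError(
            f"attachment angle {attachment_angle_deg} outside [0, 180] degrees"
        )
    return ma * math.sin(math.radians(attachment_angle_deg))


def muscle_torque(force_n: float, inlever_mm: float, attachment_angle_deg: float) -> float:
    """Closing torque (N*mm) of one muscle about the AQ joint."""
    if force_n < 0:
        raise GeometryError(f"muscle force cannot be negative, got {force_n}")
    if not inlever_mm > 0:
        raise GeometryError(f"inlever must be positive, got {inlever_mm}")
    return force_n * inlever_mm * math.sin(math.radians(attachment_angle_deg))


@dataclass
class MuscleState:
    """Resolved state of one muscle subdivision at one jaw position."""

    name: str
    inlever_mm: float
    attachment_angle_deg: float
    muscle_length_mm: float
    fiber_length_mm: float
    pcsa_cm2: float
    max_force_n: float
    activation: float
    force_n: float
    moment_arm_mm: float
    torque_nmm: float


@dataclass
class ToothForce:
    """Per-tooth lever output at one jaw position (index 1 = anterior)."""

    tooth_index: int
    outlever_mm: float
    bite_force_n: float
    ma: dict[str, float] = field(default_factory=dict)
    ema: dict[str, float] = field(default_factory=dict)
    force_n: dict[str, float] = field(default_factory=dict)
    torque_nmm: dict[str, float] = field(default_factory=dict)


@dataclass
class BiteProfile:
    """Complete static solution at one gape angle: one row per tooth with
    per-muscle mechanical advantage, effective mechanical advantage, force
    and torque contributions, plus summed bite force."""

    gape_deg: float
    muscles: list[MuscleState]
    teeth: list[ToothForce]
    bilateral: bool = False

    @property
    def bite_forces_n(self) -> np.ndarray:
        return np.array([t.bite_force_n for t in self.teeth])

    @property
    def outlevers_mm(self) -> np.ndarray:
        return np.array([t.outlever_mm for t in self.teeth])

    @property
    def total_torque_nmm(self) -> float:
        return sum(m.torque_nmm for m in self.muscles)

    def to_frame(self, specimen_id: str = "specimen") -> pd.DataFrame:
        """Tidy table: one row per tooth, per-muscle quantities as columns.

        This is the exportable form — writing the frames of a gape sweep
        yields one CSV row per (specimen, gape, tooth).
        """
        rows = []
        for t in self.teeth:
            row: dict[str, object] = {
                "specimen_id": specimen_id,
                "gape_deg": self.gape_deg,
                "tooth_index": t.tooth_index,
                "outlever_mm": t.outlever_mm,
                "bite_force_N": t.bite_force_n,
            }
            for m in self.muscles:
                p = m.name
                row[f"{p}_inlever_mm"] = m.inlever_mm
                row[f"{p}_angle_deg"] = m.attachment_angle_deg
                row[f"{p}_activation"] = m.activation
                row[f"{p}_force_N"] = m.force_n
                row[f"{p}_moment_arm_mm"] = m.moment_arm_mm
                row[f"{p}_torque_Nmm"] = m.torque_nmm
                row[f"{p}_MA"] = t.ma[p]
                row[f"{p}_EMA"] = t.ema[p]
                row[f"{p}_bite_N"] = t.force_n[p]
            rows.append(row)
        return pd.DataFrame(rows)


def bite_force_profile(
    lm: LandmarkSet,
    muscles: list[MuscleArchitecture],
    hp: HillParameters | None = None,
    gape_deg: float = 0.0,
    max_gape_deg: float | None = None,
    *,
    activation: float | None = None,
    bilateral: bool = False,
    use_whole_fiber: bool = False,
) -> BiteProfile:
    """Solve the static lever system at one jaw position.

    ``lm`` must already be posed at the requested gape (the gape sweep takes
    care of re-rotating the jaw).  The Hill activation factor is derived from
    ``gape_deg``/``max_gape_deg`` unless an explicit ``activation`` override
    is given; at ``gape_deg = 0`` it is the closed-jaw maximum regardless of
    ``max_gape_deg``.
    """
    if hp is None:
        hp = HillParameters()
    if not muscles:
        raise GeometryError("at least one muscle is required")
    out = outlevers(lm)

    if activation is None:
        if gape_deg == 0.0:
            activation = hill_bounds(hp)[1]
        else:
            if max_gape_deg is None:
                max_gape_deg = gape_deg
            activation = activation_at_gape(gape_deg, max_gape_deg, hp)
    if activation < 0:
        raise GeometryError(f"activation cannot be negative, got {activation}")

    side_factor = 2.0 if bilateral else 1.0
    states: list[MuscleState] = []
    for m in muscles:
        length = muscle_length(lm, m)
        fl = fiber_length(m, length, use_whole=use_whole_fiber)
        area = pcsa(m, fl)
        f_max = max_muscle_force(area, hp) * side_factor
        ang = attachment_angle(lm, m.insertion_id, m.origin_id)
        inl = inlever(lm, m.insertion_id)
        force = activation * f_max
        states.append(
            MuscleState(
                name=m.name,
                inlever_mm=inl,
                attachment_angle_deg=ang,
                muscle_length_mm=length,
                fiber_length_mm=fl,
                pcsa_cm2=area,
                max_force_n=f_max,
                activation=activation,
                force_n=force,
                moment_arm_mm=inl * math.sin(math.radians(ang)),
                torque_nmm=muscle_torque(force, inl, ang),
            )
        )

    teeth: list[ToothForce] = []
    for i, l_out in enumerate(out, start=1):
        tf = ToothForce(tooth_index=i, outlever_mm=float(l_out), bite_force_n=0.0)
        total = 0.0
        for s in states:
            ma = mechanical_advantage(s.inlever_mm, l_out)
            ema = effective_mechanical_advantage(ma, s.attachment_angle_deg)
            contrib = s.force_n * ema
            tf.ma[s.name] = ma
            tf.ema[s.name] = ema
            tf.force_n[s.name] = contrib
            tf.torque_nmm[s.name] = s.torque_nmm
            total += contrib
        tf.bite_force_n = total
        teeth.append(tf)

    return BiteProfile(gape_deg=gape_deg, muscles=states, teeth=teeth, bilateral=bilateral)
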