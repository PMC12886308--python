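"""Pseudodynamic gape sweep: serial static solutions while the jaw closes.

Instead of integrating jaw dynamics, the closing stroke is sampled as a
series of independent static solutions at fixed gape increments (1 degree by
default).  At each position the mandibular landmarks are re-rotated about
the AQ joint, muscle lengths, attachment angles and levers are re-measured
from the rotated geometry (never interpolated), and each muscle's maximum
force is scaled by the Hill length–tension activation for that gape.  The
final, closed-jaw row is exactly the static closed solution.
"""

from __future__ import annotations

import math

import pandas as pd

from .geometry import GeometryError, JawPartition, LandmarkSet, rotate_jaw
from .lever import BiteProfile, bite_force_profile
from .muscles import HillParameters, MuscleArchitecture

__all__ = ["sweep", "sweep_frame", "peak_profile"]


def sweep(
    lm_closed: LandmarkSet,
    muscles: list[MuscleArchitecture],
    hp: HillParameters | None = None,
    max_gape_deg: float = 30.0,
    step_deg: float = 1.0,
    *,
    part: JawPartition | None = None,
    bilateral: bool = False,
    use_whole_fiber: bool = False,
) -> list[BiteProfile]:
    """Static bite solutions at gapes ``max_gape, max_gape - step, ..., 0``.

    ``lm_closed`` is the specimen posed with the mouth closed; each sampled
    gape ``g`` re-opens the jaw by rotating the mandibular landmarks ``-g``
    degrees about the AQ joint.  Returns profiles ordered open -> closed,
    ``floor(max_gape/step) + 1`` rows; when ``step`` divides ``max_gape``
    the last row is the closed-jaw (gape 0) solution.
    """
    if not max_gape_deg > 0:
        raise GeometryError(f"max_gape_deg must be positive, got {max_gape_deg}")
    if not step_deg > 0:
        raise GeometryError(f"step_deg must be positive, got {step_deg}")
    n_steps = math.floor(max_gape_deg / step_deg + 1e-9)
    gapes = [max_gape_deg - i * step_deg for i in range(n_steps + 1)]
    gapes[-1] = max(gapes[-1], 0.0)
    if abs(gapes[-1]) < 1e-12:
        gapes[-1] = 0.0

    profiles: list[BiteProfile] = []
    for g in gapes:
        lm_g = lm_closed if g == 0.0 else rotate_jaw(lm_closed, -g, part)
        try:
            profiles.append(
                bite_force_profile(
                    lm_g,
                    muscles,
                    hp,
                    gape_deg=g,
                    max_gape_deg=max_gape_deg,
                    bilateral=bilateral,
                    use_whole_fiber=use_whole_fiber,
                )
            )
        except Exception as exc:
            raise type(exc)(f"at gape {g:g} deg: {exc}") from exc
    return profiles


def sweep_frame(profiles: list[BiteProfile], specimen_id: str = "specimen") -> pd.DataFrame:
    """Concatenate sweep profiles into one tidy table: one row per
    (specimen, gape, tooth) with all per-muscle columns — the exportable
    CSV form."""
    return pd.concat(
        [p.to_frame(specimen_id=specimen_id) for p in profiles], ignore_index=True
    )


def peak_profile(profiles: list[BiteProfile]) -> BiteProfile:
    """Profile with the greatest summed bite force across all teeth.

    With default Hill parameters and adductor geometry this is the closed
    jaw, so reported maxima correspond to the closed position.
    """
    if not profiles:
        raise GeometryError("empty sweep")
    return max(profiles, key=lambda p: float(p.bite_forces_n.sum()))
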