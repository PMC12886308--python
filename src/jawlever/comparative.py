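"""Cross-taxon performance comparison and size-trend regression.

Bite force and tooth stress scale strongly with body size, so raw values
from a 30 g piranha and a 5-tonne theropod are not comparable.  The simple
(if allometry-blind) remedy used here divides both metrics by body mass:

* force / mass   [N/kg]
* stress / mass  [kPa/kg]

:func:`performance_table` augments a table of published values with these
ratios and ranks taxa by mass-specific stress.  :func:`ols_fit` provides the
closed-form ordinary-least-squares line used to examine the (log-log) trend
of mass-specific stress against body mass.  A transcription of published
vertebrate values ships with the package (see :func:`load_vertebrate_table`);
cells whose printed ratio disagrees with the printed numerator/denominator
at printed precision carry ``*_consistent = False`` flags.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ComparativeError",
    "load_vertebrate_table",
    "load_piranha_table",
    "performance_table",
    "ols_fit",
]


class ComparativeError(ValueError):
    """Invalid comparative-table input."""


def _data_path(name: str):
    return resources.files("jawlever.data").joinpath(name)


def load_vertebrate_table() -> pd.DataFrame:
    """Published vertebrate bite force/stress values (one row per taxon),
    with body mass (kg), bite force (N), tooth/beak stress (kPa), printed
    mass-specific ratios, source tag and consistency flags."""
    with resources.as_file(_data_path("vertebrate_bite_performance.csv")) as p:
        return pd.read_csv(p)


def load_piranha_table() -> pd.DataFrame:
    """Published per-species piranha performance values: anterior/posterior/
    mean bite force (N) and stress (kPa), total dental area (mm^2), printed
    mass-specific forces and consistency flags."""
    with resources.as_file(_data_path("piranha_bite_performance.csv")) as p:
        return pd.read_csv(p)


def performance_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add mass-specific columns and a stress/mass ranking.

    Input columns: ``taxon`` (or ``species``), ``body_mass_kg``,
    ``bite_force_N``, ``bite_stress_kPa``.  Adds ``force_per_mass_N_per_kg``
    and ``stress_per_mass_kPa_per_kg`` (raw quotients; display rounding is
    2 dp for N/kg and nearest integer for kPa/kg), sorts descending by
    stress/mass and assigns 1-based ``rank``.  Rows with non-positive or
    missing mass are flagged ``excluded`` and left unranked at the bottom.
    """
    df = df.copy()
    if "taxon" not in df.columns:
        if "species" in df.columns:
            df["taxon"] = df["species"]
        else:
            raise ComparativeError("need a 'taxon' (or 'species') column")
    for col in ("body_mass_kg", "bite_stress_kPa"):
        if col not in df.columns:
            raise ComparativeError(f"missing column {col!r}")

    mass = pd.to_numeric(df["body_mass_kg"], errors="coerce")
    df["excluded"] = ~(mass > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if "bite_force_N" in df.columns:
            df["force_per_mass_N_per_kg"] = (
                pd.to_numeric(df["bite_force_N"], errors="coerce") / mass
            )
        df["stress_per_mass_kPa_per_kg"] = (
            pd.to_numeric(df["bite_stress_kPa"], errors="coerce") / mass
        )
    df.loc[df["excluded"], ["stress_per_mass_kPa_per_kg"]] = np.nan

    df = df.sort_values(
        "stress_per_mass_kPa_per_kg", ascending=False, na_position="last", kind="stable"
    ).reset_index(drop=True)
    ranked = ~df["excluded"] & df["stress_per_mass_kPa_per_kg"].notna()
    df["rank"] = np.nan
    df.loc[ranked, "rank"] = np.arange(1, int(ranked.sum()) + 1)
    return df


def ols_fit(x, y) -> dict[str, float]:
    """Closed-form ordinary least squares of ``y`` on ``x``.

    Returns ``{"slope", "intercept", "r2"}``.  Any transform (e.g. log10 for
    the mass-scaling trend) is applied by the caller.  ``r2`` is defined as
    0 when y has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ComparativeError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ComparativeError(f"need at least 3 points, got {n}")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise ComparativeError("zero variance in x; slope undefined")
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    syy = float(((y - ym) ** 2).sum())
    if syy == 0.0:
        r2 = 0.0
    else:
        resid = y - (intercept + slope * x)
        r2 = 1.0 - float((resid**2).sum()) / syy
    return {"slope": slope, "intercept": intercept, "r2": r2}
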