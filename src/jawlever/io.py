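"""Specimen container, on-disk layout and batch orchestration.

A specimen is the unit of batch processing: landmarks + muscle architecture
+ tooth surface areas + metadata.  On disk each specimen is three CSVs
(landmarks, muscles, teeth — the dialects of the respective modules) plus a
small JSON metadata file; a *manifest* CSV lists the files of many specimens
for batch runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .geometry import (
    LandmarkSet,
    read_landmarks_csv,
    write_landmarks_csv,
)
from .lever import bite_force_profile
from .muscles import (
    HillParameters,
    MuscleArchitecture,
    read_muscles_csv,
    write_muscles_csv,
)
from .stress import ToothRecord, read_teeth_csv, summarize_specimen, write_teeth_csv

logger = logging.getLogger("jawlever")

__all__ = ["Specimen", "load_specimen", "save_specimen", "run_batch", "BatchError"]


class BatchError(RuntimeError):
    """One or more specimens in a batch failed to process."""


@dataclass
class Specimen:
    """One fish: geometry, musculature, dentition and metadata."""

    specimen_id: str
    landmarks: LandmarkSet
    muscles: list[MuscleArchitecture]
    teeth: list[ToothRecord] = field(default_factory=list)
    body_mass_kg: float | None = None
    standard_length_mm: float | None = None
    species: str = ""
    diet_guild: str = ""

    def summary(
        self,
        hp: HillParameters | None = None,
        *,
        bilateral: bool = False,
        activation: float | None = None,
    ) -> dict:
        """Closed-jaw summary row (forces, stresses, mass-specific metrics)."""
        profile = bite_force_profile(
            self.landmarks,
            self.muscles,
            hp,
            gape_deg=0.0,
            bilateral=bilateral,
            activation=activation,
        )
        if self.body_mass_kg is None:
            raise BatchError(f"{self.specimen_id}: body mass required for a summary")
        row = summarize_specimen(
            profile,
            self.teeth,
            self.body_mass_kg,
            standard_length_mm=self.standard_length_mm,
            specimen_id=self.specimen_id,
        )
        if self.species:
            row["species"] = self.species
        if self.diet_guild:
            row["diet_guild"] = self.diet_guild
        return row


def save_specimen(sp: Specimen, directory) -> Path:
    """Write a specimen as landmarks/muscles/teeth CSVs + metadata JSON."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_landmarks_csv(sp.landmarks, d / "landmarks.csv")
    write_muscles_csv(sp.muscles, d / "muscles.csv", specimen_id=sp.specimen_id)
    write_teeth_csv(sp.teeth, d / "teeth.csv", specimen_id=sp.specimen_id)
    meta = {
        "specimen_id": sp.specimen_id,
        "body_mass_kg": sp.body_mass_kg,
        "standard_length_mm": sp.standard_length_mm,
        "species": sp.species,
        "diet_guild": sp.diet_guild,
    }
    (d / "metadata.json").write_text(json.dumps(meta, indent=2))
    return d


def load_specimen(directory) -> Specimen:
    """Load a specimen directory written by :func:`save_specimen`."""
    d = Path(directory)
    meta_path = d / "metadata.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    specimen_id = meta.get("specimen_id", d.name)
    teeth_path = d / "teeth.csv"
    return Specimen(
        specimen_id=specimen_id,
        landmarks=read_landmarks_csv(d / "landmarks.csv"),
        muscles=read_muscles_csv(d / "muscles.csv"),
        teeth=read_teeth_csv(teeth_path) if teeth_path.exists() else [],
        body_mass_kg=meta.get("body_mass_kg"),
        standard_length_mm=meta.get("standard_length_mm"),
        species=meta.get("species", ""),
        diet_guild=meta.get("diet_guild", ""),
    )


def run_batch(
    manifest_path,
    hp: HillParameters | None = None,
    out_csv=None,
    *,
    bilateral: bool = False,
    strict: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Process every specimen listed in a manifest CSV, in manifest order.

    The manifest either points at specimen directories (column
    ``directory``) or lists the files explicitly (columns ``specimen_id,
    landmarks, muscles, teeth, body_mass_kg, standard_length_mm``); paths
    are relative to the manifest's location.  Returns ``(summary table,
    list of failure messages)``: failures are isolated per specimen and
    logged, so one bad file never aborts the rest.  ``strict=True`` raises
    :class:`BatchError` at the end if anything failed.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    by_dir = "directory" in manifest.columns
    if not by_dir and not {"landmarks", "muscles"} <= set(manifest.columns):
        raise BatchError(
            f"{manifest_path}: manifest needs a 'directory' column or "
            "'landmarks'/'muscles' file columns"
        )
    root = manifest_path.parent
    rows: list[dict] = []
    failures: list[str] = []
    for r in manifest.itertuples():
        label = str(getattr(r, "directory", getattr(r, "specimen_id", r.Index)))
        try:
            if by_dir:
                sp = load_specimen(root / str(r.directory))
            else:
                sp = Specimen(
                    specimen_id=str(getattr(r, "specimen_id", r.Index)),
                    landmarks=read_landmarks_csv(root / str(r.landmarks)),
                    muscles=read_muscles_csv(root / str(r.muscles)),
                    teeth=read_teeth_csv(root / str(r.teeth))
                    if hasattr(r, "teeth")
                    else [],
                    body_mass_kg=float(r.body_mass_kg)
                    if hasattr(r, "body_mass_kg")
                    else None,
                    standard_length_mm=float(r.standard_length_mm)
                    if hasattr(r, "standard_length_mm")
                    else None,
                )
            rows.append(sp.summary(hp, bilateral=bilateral))
        except Exception as exc:  # noqa: BLE001 - per-specimen isolation
            msg = f"{label}: {exc}"
            logger.error("specimen failed: %s", msg)
            failures.append(msg)
    table = pd.DataFrame(rows)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    if strict and failures:
        raise BatchError(f"{len(failures)} specimen(s) failed: {failures}")
    return table, failures
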