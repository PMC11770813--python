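"""Lean-mass-normalized dose planning for the DeutG IP GTT/ITT.

Glucose is dosed at 0.5 g per kg *lean* mass and insulin (ITT only) at
0.75 U per kg lean mass, co-drawn into a single syringe and brought to a
150 uL total volume with physiological saline.  Normalizing to lean mass
rather than body mass means diet groups with similar lean mass receive
similar absolute doses despite different adiposity.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .partition import TestMode

__all__ = ["AnimalRecord", "DosePlan", "plan_dose", "dosing_sheet",
           "GLUCOSE_DOSE_G_PER_KG_LEAN", "INSULIN_DOSE_U_PER_KG_LEAN",
           "TOTAL_VOLUME_UL"]

GLUCOSE_DOSE_G_PER_KG_LEAN = 0.5
INSULIN_DOSE_U_PER_KG_LEAN = 0.75
TOTAL_VOLUME_UL = 150.0


@dataclass(frozen=True)
class AnimalRecord:
    animal_id: str
    group: str
    body_mass_g: float
    lean_mass_g: float

    def __post_init__(self) -> None:
        if self.lean_mass_g <= 0:
            raise ValueError(f"animal {self.animal_id}: lean mass must be positive")
        if self.lean_mass_g > self.body_mass_g:
            raise ValueError(
                f"animal {self.animal_id}: lean mass exceeds body mass"
            )


@dataclass(frozen=True)
class DosePlan:
    """One syringe per animal: glucose (mg), insulin (mU), saline to 150 uL."""

    animal_id: str
    mode: TestMode
    glucose_mg: float
    insulin_mU: float
    saline_to_volume_uL: float = TOTAL_VOLUME_UL


def plan_dose(a: AnimalRecord, mode: TestMode) -> DosePlan:
    """Compute the injectate for one animal.

    glucose_mg = 0.5 g/kg * lean_kg * 1000; insulin_mU = 750 mU/kg *
    lean_kg in ITT mode, 0 in GTT mode.  Doses depend only on lean mass,
    never on total body mass.
    """
    mode = TestMode(mode)
    lean_kg = a.lean_mass_g / 1000.0
    glucose_mg = GLUCOSE_DOSE_G_PER_KG_LEAN * lean_kg * 1000.0
    insulin_mU = INSULIN_DOSE_U_PER_KG_LEAN * 1000.0 * lean_kg if mode is TestMode.ITT else 0.0
    return DosePlan(
        animal_id=a.animal_id, mode=mode, glucose_mg=glucose_mg, insulin_mU=insulin_mU
    )


def dosing_sheet(manifest: pd.DataFrame, mode: TestMode) -> pd.DataFrame:
    """Dosing sheet for a whole cohort from the animal manifest.

    ``manifest`` columns: animal_id, group, body_mass_g, lean_mass_g.
    """
    rows = []
    for _, r in manifest.iterrows():
        rec = AnimalRecord(
            animal_id=str(r["animal_id"]),
            group=str(r["group"]),
            body_mass_g=float(r["body_mass_g"]),
            lean_mass_g=float(r["lean_mass_g"]),
        )
        plan = plan_dose(rec, mode)
        rows.append(
            {
                "animal_id": rec.animal_id,
                "group": rec.group,
                "mode": plan.mode.value,
                "lean_mass_g": rec.lean_mass_g,
                "glucose_mg": plan.glucose_mg,
                "insulin_mU": plan.insulin_mU,
                "total_volume_uL": plan.saline_to_volume_uL,
            }
        )
    return pd.DataFrame(rows)
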