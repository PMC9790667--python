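"""Regional spindle power asymmetry (SPA) indexes.

Event powers are aggregated into a mean spindle power per region, hemisphere
and frequency band (full 11-15 Hz, slow 11-13 Hz, fast 13-15 Hz), and the
SPA index is the ratio of the lesioned-hemisphere mean to the homologous
non-lesioned mean. Five regions x three bands give 15 indexes per subject.
SPA = 1 means interhemispheric symmetry; SPA < 1 means weaker spindles over
the lesioned hemisphere, the direction associated with unilateral CP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import SpindleEvent

__all__ = [
    "REGION_MAP",
    "REGIONS",
    "SPA_BANDS",
    "SPA_COLUMNS",
    "SPAIndexSet",
    "regional_band_power",
    "compute_spa",
    "spa_index_set",
    "spa_table",
]

#: region -> (left derivation, right derivation). Configurable because the
#: mapping of the centro-temporal region onto derivations is a montage choice.
REGION_MAP: dict[str, tuple[str, str]] = {
    "FC": ("Fp1-C3", "Fp2-C4"),
    "FT": ("Fp1-T3", "Fp2-T4"),
    "CT": ("C3-T3", "C4-T4"),
    "CO": ("C3-O1", "C4-O2"),
    "TO": ("T3-O1", "T4-O2"),
}
REGIONS = tuple(REGION_MAP)
SPA_BANDS = ("full", "slow", "fast")
#: tidy-table column names, <region>_<band>_SPA
SPA_COLUMNS = tuple(f"{r}_{b}_SPA" for r in REGIONS for b in SPA_BANDS)

#: reason codes for missing values
NO_EVENTS = "no events"
EXCLUDED_CHANNEL = "excluded channel"


@dataclass
class SPAIndexSet:
    """The 15 region x band SPA ratios for one subject.

    spa holds a value > 0 or None; missing entries carry a reason code in
    `reasons` (no events on a side, or a derivation excluded as bad).
    """

    subject_id: str
    lesion_side: str  # "left" | "right"
    spa: dict[tuple[str, str], float | None] = field(default_factory=dict)
    reasons: dict[tuple[str, str], str] = field(default_factory=dict)

    def as_row(self) -> dict[str, float | str | None]:
        row: dict[str, float | str | None] = {
            "subject_id": self.subject_id,
            "lesion_side": self.lesion_side,
        }
        for r in REGIONS:
            for b in SPA_BANDS:
                row[f"{r}_{b}_SPA"] = self.spa.get((r, b))
        return row


def regional_band_power(events: list[SpindleEvent], region: str, band: str,
                        side: str, region_map: dict | None = None,
                        excluded: set[str] | None = None) -> float | None:
    """Mean event power (uV^2) on one region's derivation for one side/band.

    Averages mean_power_uv2 over that derivation's events in the band
    ("full" takes every event). Returns None when the derivation is excluded
    or has no events in the band.
    """
    rmap = region_map or REGION_MAP
    if region not in rmap:
        raise ValueError(f"unknown region: {region}")
    if band not in SPA_BANDS:
        raise ValueError(f"unknown band: {band}")
    if side not in ("left", "right"):
        raise ValueError(f"side must be left or right, got {side}")
    deriv = rmap[region][0 if side == "left" else 1]
    if excluded and deriv in excluded:
        return None
    powers = [e.mean_power_uv2 for e in events
              if e.derivation == deriv and (band == "full" or e.band == band)]
    if not powers:
        return None
    return float(np.mean(powers))


def compute_spa(power_lesioned: float | None,
                power_nonlesioned: float | None) -> float | None:
    """SPA = P_lesioned / P_nonlesioned; None propagates as missing."""
    if power_lesioned is None or power_nonlesioned is None:
        return None
    if power_lesioned <= 0 or power_nonlesioned <= 0:
        raise ValueError("spindle powers must be strictly positive")
    return power_lesioned / power_nonlesioned


def spa_index_set(events: list[SpindleEvent], subject_id: str, lesion_side: str,
                  region_map: dict | None = None,
                  excluded: set[str] | None = None) -> SPAIndexSet:
    """Compute all 15 SPA indexes for one subject from its detected events."""
    if lesion_side not in ("left", "right"):
        raise ValueError(f"lesion_side must be left or right, got {lesion_side}")
    out = SPAIndexSet(subject_id=subject_id, lesion_side=lesion_side)
    les, non = lesion_side, ("right" if lesion_side == "left" else "left")
    for r in REGIONS:
        for b in SPA_BANDS:
            p_les = regional_band_power(events, r, b, les, region_map, excluded)
            p_non = regional_band_power(events, r, b, non, region_map, excluded)
            out.spa[(r, b)] = compute_spa(p_les, p_non)
            if out.spa[(r, b)] is None:
                rmap = region_map or REGION_MAP
                bad = excluded and any(d in excluded for d in rmap[r])
                out.reasons[(r, b)] = EXCLUDED_CHANNEL if bad else NO_EVENTS
    return out


def spa_table(index_sets: list[SPAIndexSet],
              outcomes: dict[str, str] | None = None) -> pd.DataFrame:
    """Tidy cohort table: one row per subject, 15 SPA columns plus metadata.

    outcomes maps subject_id -> outcome label ("UCP" | "typical"); missing
    SPA values become NaN and stay missing downstream (pairwise deletion).
    """
    if not index_sets:
        raise ValueError("need at least one subject")
    ids = [s.subject_id for s in index_sets]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject_id(s): {dupes}")
    rows = [s.as_row() for s in index_sets]
    df = pd.DataFrame(rows)
    if outcomes is not None:
        df["outcome"] = df["subject_id"].map(outcomes)
    for c in SPA_COLUMNS:
        df[c] = pd.to_numeric(df[c])
    cols = ["subject_id", "lesion_side"] + (["outcome"] if outcomes is not None else [])
    return df[cols + list(SPA_COLUMNS)]
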