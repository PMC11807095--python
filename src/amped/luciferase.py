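"""Dual-luciferase reporter normalisation.

A single transcript expresses Renilla (expression control), a target
cassette carrying the premature-stop mutation, then Firefly. Unedited
transcripts terminate before Firefly; A>G repair of the stop codon restores
Firefly activity, so the background-subtracted Firefly/Renilla ratio,
rescaled between the plate's negative (non-targeting) and positive
(in-frame) control ratios, estimates the fraction of repaired transcripts:

    E = (r_condition - r_neg) / (r_pos - r_neg)

Technical duplicate wells are averaged on the ratio scale before
normalisation. E outside [-0.05, 1.05] is flagged, never clamped — a
clamped value would hide assay failure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = ("sample", "positive_control", "negative_control", "background")

_WELL_COLUMNS = ["well_id", "condition", "role", "replicate", "firefly", "renilla"]


@dataclass
class LuciferasePlate:
    """Raw or background-subtracted luminescence for one plate.

    ``wells`` columns: well_id, condition, role, replicate, firefly, renilla
    (plus an optional boolean ``floored`` flag after background subtraction).
    """

    wells: pd.DataFrame
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in _WELL_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValueError(f"plate table missing columns: {missing}")
        bad_roles = sorted(set(self.wells["role"]) - set(ROLES))
        if bad_roles:
            raise ValueError(f"unknown well roles: {bad_roles}")
        for role in ("positive_control", "negative_control", "background"):
            if not (self.wells["role"] == role).any():
                raise ValueError(f"plate has no {role} well")
        if (self.wells[["firefly", "renilla"]].to_numpy(dtype=float) < 0).any():
            raise ValueError("raw luminescence must be non-negative")

    @classmethod
    def from_tsv(cls, path) -> "LuciferasePlate":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.wells.to_csv(path, sep="\t", index=False)


@dataclass
class EfficiencyResult:
    """Normalised editing efficiency for one condition replicate."""

    condition: str
    replicate: int
    efficiency: float
    raw_ratio: float
    n_wells: int
    flags: list[str] = field(default_factory=list)

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * self.efficiency


def subtract_background(plate: LuciferasePlate) -> LuciferasePlate:
    """Subtract mean background-well luminescence per channel, flooring at 0."""
    wells = plate.wells.copy()
    bg = wells[wells["role"] == "background"]
    if bg.empty:
        raise ValueError("plate has no background wells")
    f0 = bg["firefly"].mean()
    r0 = bg["renilla"].mean()
    f = wells["firefly"] - f0
    r = wells["renilla"] - r0
    floored = (f < 0) | (r < 0)
    wells["firefly"] = f.clip(lower=0.0)
    wells["renilla"] = r.clip(lower=0.0)
    wells["floored"] = floored
    return LuciferasePlate(wells, background_subtracted=True)


def editing_efficiency(plate: LuciferasePlate) -> list[EfficiencyResult]:
    """Normalise per-replicate Firefly/Renilla ratios between plate controls.

    Wells with zero Renilla are excluded (flagged); a degenerate plate
    (identical positive- and negative-control mean ratios) is rejected.
    """
    if not plate.background_subtracted:
        raise ValueError("subtract_background must be applied before normalisation")
    wells = plate.wells[plate.wells["role"] != "background"].copy()
    usable = wells["renilla"] > 0
    excluded_groups = {
        (row["condition"], row["replicate"])
        for _, row in wells.loc[~usable].iterrows()
    }
    wells = wells[usable]
    wells["ratio"] = wells["firefly"] / wells["renilla"]

    pos = wells.loc[wells["role"] == "positive_control", "ratio"]
    neg = wells.loc[wells["role"] == "negative_control", "ratio"]
    if pos.empty or neg.empty:
        raise ValueError("all control wells excluded (zero Renilla)")
    r_pos, r_neg = pos.mean(), neg.mean()
    if math.isclose(r_pos, r_neg):
        raise ValueError(
            f"degenerate dynamic range: positive ({r_pos:g}) equals "
            f"negative ({r_neg:g}) control ratio"
        )

    results = []
    samples = wells[wells["role"] == "sample"]
    for (cond, rep), grp in samples.groupby(["condition", "replicate"], sort=True):
        r = grp["ratio"].mean()  # technical duplicates averaged on ratios
        e = (r - r_neg) / (r_pos - r_neg)
        flags = []
        if not -0.05 <= e <= 1.05:
            flags.append("out_of_range")
        if (cond, rep) in excluded_groups:
            flags.append("wells_excluded_zero_renilla")
        results.append(
            EfficiencyResult(
                condition=cond,
                replicate=int(rep),
                efficiency=float(e),
                raw_ratio=float(r),
                n_wells=len(grp),
                flags=flags,
            )
        )
    return results


def summarize_efficiencies(results: list[EfficiencyResult]) -> pd.DataFrame:
    """Condition-level mean, SEM (over replicates) and flags."""
    rows = []
    df = pd.DataFrame(
        {
            "condition": [r.condition for r in results],
            "efficiency": [r.efficiency for r in results],
            "flags": [";".join(r.flags) for r in results],
        }
    )
    for cond, grp in df.groupby("condition", sort=True):
        e = grp["efficiency"].to_numpy()
        sem = float(np.std(e, ddof=1) / np.sqrt(len(e))) if len(e) > 1 else 0.0
        flags = ";".join(sorted({f for f in grp["flags"] if f}))
        rows.append(
            {
                "condition": cond,
                "efficiency": float(e.mean()),
                "efficiency_percent": 100.0 * float(e.mean()),
                "sem": sem,
                "n_replicates": len(e),
                "flags": flags,
            }
        )
    return pd.DataFrame(rows)
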