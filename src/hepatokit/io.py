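"""Readers and writers for the tidy TAC CSV dialect and result tables.

TAC CSV columns: ``animal_id, group, region, frame_start_min, frame_end_min,
value, unit`` — one row per (animal, region, frame), minutes for time.
Animals acquired on different frame schedules (e.g. PET and planar in one
file) parse into separate records; schedule inconsistency *within* one
animal is a hard error naming the animal.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tac import (
    KNOWN_UNITS,
    AnimalRecord,
    FrameSchedule,
    TimeActivityCurve,
)

__all__ = ["read_tacs", "write_tacs", "read_config", "tacs_to_frame"]

TAC_COLUMNS = [
    "animal_id", "group", "region", "frame_start_min", "frame_end_min",
    "value", "unit",
]

_MODALITY_BY_NFRAMES = {20: "PET", 54: "planar"}


def _schedule_from_rows(sub: pd.DataFrame, animal: str, region: str):
    sub = sub.sort_values("frame_start_min")
    starts = sub["frame_start_min"].to_numpy(dtype=float)
    ends = sub["frame_end_min"].to_numpy(dtype=float)
    if starts[0] != 0:
        raise ValueError(
            f"animal {animal!r} region {region!r}: first frame starts at "
            f"{starts[0]}, expected 0"
        )
    bad = np.flatnonzero(~np.isclose(starts[1:], ends[:-1], rtol=0, atol=1e-9))
    if bad.size:
        j = int(bad[0])
        raise ValueError(
            f"animal {animal!r} region {region!r}: frames {j} and {j + 1} "
            f"are not contiguous (end {ends[j]} vs start {starts[j + 1]})"
        )
    modality = _MODALITY_BY_NFRAMES.get(len(starts), "PET")
    return (
        FrameSchedule(np.column_stack([starts, ends]), modality=modality),
        sub["value"].to_numpy(dtype=float),
        sub["unit"].iloc[0],
    )


def read_tacs(path) -> list[AnimalRecord]:
    """Parse a tidy TAC CSV into validated animal records."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TAC file {path} missing columns: {missing}")
    bad_units = set(df["unit"]) - KNOWN_UNITS
    if bad_units:
        raise ValueError(f"unknown units in {path}: {sorted(bad_units)}")

    records = []
    for animal, adf in df.groupby("animal_id", sort=False):
        groups = adf["group"].unique()
        if len(groups) > 1:
            raise ValueError(
                f"animal {animal!r} assigned to multiple groups: {groups}"
            )
        rec = AnimalRecord(animal_id=str(animal), group=str(groups[0]))
        for region, rdf in adf.groupby("region", sort=False):
            if rdf["unit"].nunique() > 1:
                raise ValueError(
                    f"animal {animal!r} region {region!r}: mixed units"
                )
            schedule, values, unit = _schedule_from_rows(
                rdf, str(animal), str(region)
            )
            rec.tacs[str(region)] = TimeActivityCurve(
                schedule, values, unit, str(region), str(animal)
            )
        records.append(rec.validate())
    return records


def write_tacs(records: list[AnimalRecord], path) -> None:
    """Write records back to the tidy CSV dialect (lossless round trip)."""
    rows = []
    for rec in records:
        for region, tac in rec.tacs.items():
            s = tac.schedule
            for start, end, value in zip(s.starts, s.ends, tac.values):
                rows.append([rec.animal_id, rec.group, region, start, end,
                             value, tac.unit])
    # %.17g keeps the float64 round trip exact
    pd.DataFrame(rows, columns=TAC_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def tacs_to_frame(records: list[AnimalRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for region, tac in rec.tacs.items():
            s = tac.schedule
            for start, end, value in zip(s.starts, s.ends, tac.values):
                rows.append([rec.animal_id, rec.group, region, start, end,
                             value, tac.unit])
    return pd.DataFrame(rows, columns=TAC_COLUMNS)


def read_config(path) -> dict:
    """Load a YAML pipeline config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
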