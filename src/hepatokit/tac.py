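"""Frame schedules, time-activity curves, unit conversion and AUC.

A dynamic acquisition is a contiguous sequence of frames; the regional
time-activity curve (TAC) carries one value per frame.  PET-type studies
express blood and tissue in %ID/mL (percent of injected dose per mL) and the
intestine as an amount (%ID); planar gamma-camera studies express regions in
count rate (cps), with the blood pool converted to cps/mL through the heart
volume.  Model values attach to frame midtimes, with linear interpolation
between them and 0 at t = 0 (bolus injection convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .curves import PiecewiseLinearCurve

__all__ = [
    "PET_FRAME_SPEC",
    "PLANAR_FRAME_SPEC",
    "FrameSchedule",
    "TimeActivityCurve",
    "AnimalRecord",
    "build_schedule",
    "frame_midtimes",
    "convert_units",
    "trapezoid_auc",
    "auc_ratio",
    "curve_from_tac",
    "heart_volume_from_body_weight",
]

#: 40-min dynamic PET acquisition: 20 frames.
PET_FRAME_SPEC = [(3, 0.5), (5, 1.0), (5, 2.0), (3, 3.0), (3, 4.0), (1, 2.5)]
#: Dynamic planar scintigraphy: 54 frames over 38 min.
PLANAR_FRAME_SPEC = [(20, 0.25), (10, 0.5), (20, 1.0), (4, 2.0)]

CONCENTRATION_UNITS = {"MBq/mL", "%ID/mL", "cps/mL"}
AMOUNT_UNITS = {"MBq", "%ID", "cps", "cps/MBq"}
KNOWN_UNITS = CONCENTRATION_UNITS | AMOUNT_UNITS

REGIONS = {
    "blood",
    "liver",
    "intestine",
    "brain",
    "myocardium",
    "muscle",
    "kidney",
    "lung",
}


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered contiguous acquisition frames (start/end in minutes)."""

    frames: np.ndarray  # shape (n, 2)
    modality: str = "PET"

    def __post_init__(self):
        fr = np.asarray(self.frames, dtype=float)
        if fr.ndim != 2 or fr.shape[1] != 2 or fr.shape[0] == 0:
            raise ValueError("frames must be a nonempty (n, 2) array")
        if fr[0, 0] != 0.0:
            raise ValueError("first frame must start at 0")
        if np.any(fr[:, 1] <= fr[:, 0]):
            raise ValueError("all frame durations must be positive")
        if not np.allclose(fr[1:, 0], fr[:-1, 1], rtol=0, atol=1e-9):
            raise ValueError("frames must be contiguous (end_i == start_{i+1})")
        object.__setattr__(self, "frames", fr)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def starts(self) -> np.ndarray:
        return self.frames[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self.frames[:, 1]

    @property
    def durations(self) -> np.ndarray:
        return self.frames[:, 1] - self.frames[:, 0]

    @property
    def midtimes(self) -> np.ndarray:
        return 0.5 * (self.frames[:, 0] + self.frames[:, 1])

    @property
    def total_duration(self) -> float:
        return float(self.frames[-1, 1])

    def to_spec(self) -> list[tuple[int, float]]:
        """Compress back to a (count, duration) run-length spec."""
        spec: list[tuple[int, float]] = []
        for d in self.durations:
            if spec and np.isclose(spec[-1][1], d):
                spec[-1] = (spec[-1][0] + 1, spec[-1][1])
            else:
                spec.append((1, float(d)))
        return spec

    def __eq__(self, other):
        return (
            isinstance(other, FrameSchedule)
            and self.modality == other.modality
            and self.frames.shape == other.frames.shape
            and np.allclose(self.frames, other.frames)
        )

    def __hash__(self):
        return hash((self.modality, self.frames.shape[0], self.total_duration))


@dataclass
class TimeActivityCurve:
    """One region's frame-wise radioactivity values."""

    schedule: FrameSchedule
    values: np.ndarray
    unit: str
    region: str = ""
    animal_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != self.schedule.n_frames:
            raise ValueError(
                f"expected {self.schedule.n_frames} values, got {v.size}"
            )
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("TAC values must be finite and nonnegative")
        if self.unit not in KNOWN_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        self.values = v

    @property
    def midtimes(self) -> np.ndarray:
        return self.schedule.midtimes


@dataclass
class AnimalRecord:
    """All curves and physiology for one animal."""

    animal_id: str
    group: str
    tacs: dict[str, TimeActivityCurve] = field(default_factory=dict)
    body_weight_g: Optional[float] = None
    injected_activity_MBq: Optional[float] = None
    liver_roi_volume_mL: Optional[float] = None
    heart_volume_mL: Optional[float] = None
    true_params: Optional[dict] = None  # ground truth, synthetic animals only

    def __post_init__(self):
        for attr in ("body_weight_g", "injected_activity_MBq",
                     "liver_roi_volume_mL", "heart_volume_mL"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise ValueError(f"{attr} must be positive")

    def validate(self, require=("blood", "liver", "intestine")):
        for region in require:
            if region not in self.tacs:
                raise ValueError(
                    f"animal {self.animal_id!r}: missing {region!r} curve"
                )
        schedules = {self.tacs[r].schedule for r in require}
        if len(schedules) > 1:
            raise ValueError(
                f"animal {self.animal_id!r}: curves on inconsistent schedules"
            )
        return self

    @property
    def schedule(self) -> FrameSchedule:
        return next(iter(self.tacs.values())).schedule


def build_schedule(spec, modality: str = "PET") -> FrameSchedule:
    """Expand a run-length (count, duration_min) spec into explicit frames.

    Example: ``[(3, 0.5), (5, 1.0)]`` gives eight frames covering 0-6.5 min.
    """
    if not spec:
        raise ValueError("empty frame spec")
    durations = []
    for count, dur in spec:
        if count < 1 or int(count) != count:
            raise ValueError(f"frame count must be a positive integer, got {count}")
        if dur <= 0:
            raise ValueError(f"frame duration must be positive, got {dur}")
        durations.extend([float(dur)] * int(count))
    ends = np.cumsum(durations)
    starts = np.concatenate([[0.0], ends[:-1]])
    return FrameSchedule(np.column_stack([starts, ends]), modality=modality)


def frame_midtimes(schedule: FrameSchedule) -> np.ndarray:
    """Frame midpoints (start+end)/2 — the sampling times for fitting."""
    return schedule.midtimes


def curve_from_tac(tac: TimeActivityCurve) -> PiecewiseLinearCurve:
    """Continuous curve: 0 at t=0, linear through midtime samples, flat tail."""
    return PiecewiseLinearCurve(tac.midtimes, tac.values)


def heart_volume_from_body_weight(
    body_weight_g: float, specific_volume_uL_per_g: float = 5.0
) -> float:
    """Blood-pool (heart) volume in mL from body weight.

    Planar studies report the whole-heart count rate; dividing by this volume
    yields a blood concentration.  The allometric relation is configurable
    (default 5.0 uL blood-pool volume per gram body weight).
    """
    if body_weight_g <= 0:
        raise ValueError("body weight must be positive")
    return body_weight_g * specific_volume_uL_per_g / 1000.0


# -- unit conversion ---------------------------------------------------------

def _conversion_edges(injected_MBq, volume_mL):
    """Directed unit-conversion graph given the available context."""
    edges = {}
    if injected_MBq is not None:
        f = 100.0 / injected_MBq
        edges[("MBq/mL", "%ID/mL")] = f
        edges[("%ID/mL", "MBq/mL")] = 1.0 / f
        edges[("MBq", "%ID")] = f
        edges[("%ID", "MBq")] = 1.0 / f
        edges[("cps", "cps/MBq")] = 1.0 / injected_MBq
        edges[("cps/MBq", "cps")] = injected_MBq
    if volume_mL is not None:
        edges[("MBq/mL", "MBq")] = volume_mL
        edges[("MBq", "MBq/mL")] = 1.0 / volume_mL
        edges[("%ID/mL", "%ID")] = volume_mL
        edges[("%ID", "%ID/mL")] = 1.0 / volume_mL
        edges[("cps/mL", "cps")] = volume_mL
        edges[("cps", "cps/mL")] = 1.0 / volume_mL
    return edges


def convert_units(
    tac: TimeActivityCurve,
    target_unit: str,
    injected_MBq: Optional[float] = None,
    volume_mL: Optional[float] = None,
) -> TimeActivityCurve:
    """Rescale a TAC to ``target_unit``.

    Paths needing the injected dose (e.g. MBq/mL -> %ID/mL) or a region
    volume (concentration <-> amount) raise if that context is missing;
    physically undefined paths (e.g. cps -> MBq) always raise.
    """
    if target_unit not in KNOWN_UNITS:
        raise ValueError(f"unknown target unit {target_unit!r}")
    if tac.unit == target_unit:
        return replace(tac, values=tac.values.copy())
    if injected_MBq is not None and injected_MBq <= 0:
        raise ValueError("injected activity must be positive")
    if volume_mL is not None and volume_mL <= 0:
        raise ValueError("volume must be positive")
    edges = _conversion_edges(injected_MBq, volume_mL)
    # breadth-first search over the small unit graph
    frontier = {tac.unit: 1.0}
    seen = set()
    while frontier:
        nxt: dict[str, float] = {}
        for unit, factor in frontier.items():
            if unit == target_unit:
                return replace(tac, values=tac.values * factor, unit=target_unit)
            seen.add(unit)
            for (a, b), f in edges.items():
                if a == unit and b not in seen:
                    nxt.setdefault(b, factor * f)
        frontier = nxt
    needs = []
    if injected_MBq is None:
        needs.append("injected_MBq")
    if volume_mL is None:
        needs.append("volume_mL")
    hint = f" (missing context: {', '.join(needs)})" if needs else ""
    raise ValueError(
        f"no conversion path from {tac.unit!r} to {target_unit!r}{hint}"
    )


# -- AUC ---------------------------------------------------------------------

def trapezoid_auc(tac: TimeActivityCurve, t_end: Optional[float] = None) -> float:
    """Area under the TAC from 0 to ``t_end`` (unit x min).

    Trapezoid rule on the piecewise-linear curve through the midtime samples,
    including the 0-at-origin bolus segment; exact for that curve shape.
    """
    end = tac.schedule.total_duration
    if t_end is None:
        t_end = end
    if t_end < 0 or t_end > end + 1e-9:
        raise ValueError(f"t_end {t_end} outside schedule [0, {end}]")
    return curve_from_tac(tac).integral(t_end)


def auc_ratio(
    tissue: TimeActivityCurve,
    blood: TimeActivityCurve,
    t_end: Optional[float] = None,
) -> float:
    """Tissue-to-blood AUC ratio over [0, t_end]."""
    if tissue.schedule != blood.schedule:
        raise ValueError("tissue and blood must share one schedule")
    denom = trapezoid_auc(blood, t_end)
    if denom == 0:
        raise ValueError("blood AUC is zero")
    return trapezoid_auc(tissue, t_end) / denom
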