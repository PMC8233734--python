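"""Synthetic hepatobiliary imaging studies for wild-type vs knockout cohorts.

Two scenarios are emulated end to end:

* ``erlotinib``  — dynamic PET, 20 frames / 40 min; blood and liver in
  %ID/mL, intestine in %ID.
* ``mebrofenin`` — dynamic planar scintigraphy, 54 frames / 38 min; blood in
  cps/mL (whole-heart counts over the body-weight-derived heart volume),
  liver and intestine in cps.

Group kinetic means and between-animal CVs default to the study's reported
wild-type and Slco2b1-knockout values for each tracer.  Per-animal
parameters are drawn log-normally (independent across parameters); curves
come from the forward compartment model, frame-averaged, with multiplicative
Gaussian noise whose SD scales as noise_frac / sqrt(frame duration) to mimic
count-statistics-driven frame noise.  Every record carries its ground-truth
parameters so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import PiecewiseLinearCurve
from .hepatic_model import HepaticParams, simulate_hepatic, _frame_average
from .input_function import synthesize_arterial
from .tac import (
    PET_FRAME_SPEC,
    PLANAR_FRAME_SPEC,
    AnimalRecord,
    TimeActivityCurve,
    build_schedule,
    heart_volume_from_body_weight,
)

__all__ = [
    "GROUP_KINETICS",
    "ScenarioSpec",
    "scenario",
    "draw_animal_params",
    "generate_animal",
    "generate_study",
    "study_frames",
]

#: Reported group means and SDs (CL1 mL/min; k2, k3 1/min) per tracer.
GROUP_KINETICS = {
    "erlotinib": {
        "wild-type": {"cl1": (6.442, 1.675), "k2": (1.052, 0.196),
                      "k3": (0.013, 0.008)},
        "knockout": {"cl1": (3.748, 1.470), "k2": (0.565, 0.287),
                     "k3": (0.014, 0.010)},
    },
    "mebrofenin": {
        "wild-type": {"cl1": (0.144, 0.056), "k2": (0.215, 0.129),
                      "k3": (0.019, 0.009)},
        "knockout": {"cl1": (0.040, 0.016), "k2": (0.040, 0.012),
                     "k3": (0.027, 0.019)},
    },
}

_SCENARIO_DEFAULTS = {
    "erlotinib": dict(
        schedule_spec=PET_FRAME_SPEC,
        modality="PET",
        blood_unit="%ID/mL",
        liver_unit="%ID/mL",
        intestine_unit="%ID",
        arterial_scale=1.0,  # %ID/mL-scale bolus
        injected_MBq=7.6,
    ),
    "mebrofenin": dict(
        schedule_spec=PLANAR_FRAME_SPEC,
        modality="planar",
        blood_unit="cps/mL",
        liver_unit="cps",
        intestine_unit="cps",
        arterial_scale=2.0e3,  # cps/mL-scale bolus
        injected_MBq=7.2,
    ),
}


@dataclass
class ScenarioSpec:
    """Full description of one synthetic two-group study."""

    tracer: str
    schedule_spec: list
    modality: str
    blood_unit: str
    liver_unit: str
    intestine_unit: str
    group_kinetics: dict  # group -> param -> (mean, sd)
    n_wt: int = 5
    n_ko: int = 4
    noise_frac: float = 0.10
    seed: int = 1
    f_ha: float = 0.17
    k_pv_true: float = 2.0  # min^-1, gut transit
    v_liver_mL: float = 1.5
    body_weight_mean_g: float = 31.0
    body_weight_sd_g: float = 4.0
    heart_specific_volume_uL_per_g: float = 5.0
    arterial_amplitudes: tuple = (15.0, 4.0, 1.0)
    arterial_rates: tuple = (3.0, 0.4, 0.02)
    arterial_rise_rate: float = 20.0
    arterial_scale: float = 1.0
    injected_MBq: float = 7.6

    def __post_init__(self):
        if self.n_wt < 1 or self.n_ko < 1:
            raise ValueError("need at least one animal per group")
        if self.noise_frac < 0:
            raise ValueError("noise fraction must be nonnegative")
        for g, params in self.group_kinetics.items():
            for p, (m, s) in params.items():
                if m <= 0 or s < 0:
                    raise ValueError(f"bad {p} spec for group {g}")

    @property
    def schedule(self):
        return build_schedule(self.schedule_spec, modality=self.modality)

    def arterial_model(self):
        amps = self.arterial_scale * np.asarray(self.arterial_amplitudes)
        return synthesize_arterial(amps, self.arterial_rates,
                                   self.arterial_rise_rate)


def scenario(tracer: str, **overrides) -> ScenarioSpec:
    """Build a ScenarioSpec for ``'erlotinib'`` or ``'mebrofenin'`` with the
    study's default group kinetics; keyword overrides tweak any field."""
    if tracer not in _SCENARIO_DEFAULTS:
        raise ValueError(f"unknown tracer scenario {tracer!r}")
    kw = dict(_SCENARIO_DEFAULTS[tracer])
    kw["group_kinetics"] = {
        g: dict(p) for g, p in GROUP_KINETICS[tracer].items()
    }
    kw.update(overrides)
    return ScenarioSpec(tracer=tracer, **kw)


def _lognormal(rng, mean, cv):
    if cv == 0:
        return mean
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(np.exp(rng.normal(mu, np.sqrt(sigma2))))


def draw_animal_params(
    spec: ScenarioSpec, group: str, rng: np.random.Generator
) -> HepaticParams:
    """Log-normal per-animal kinetic parameters at the group mean and CV."""
    kin = spec.group_kinetics[group]
    drawn = {}
    for p, (mean, sd) in kin.items():
        drawn[p] = _lognormal(rng, mean, sd / mean)
    return HepaticParams(
        cl1=drawn["cl1"], k2=drawn["k2"], k3=drawn["k3"],
        k_pv=spec.k_pv_true, v_liver=spec.v_liver_mL,
    )


def _apply_noise(values, durations, noise_frac, rng):
    """Multiplicative Gaussian noise, SD = noise_frac / sqrt(frame length)."""
    if noise_frac == 0:
        return values.copy(), 0
    sd = noise_frac / np.sqrt(durations)
    noisy = values * (1.0 + sd * rng.standard_normal(values.shape))
    n_clipped = int(np.sum(noisy < 0))
    return np.maximum(noisy, 0.0), n_clipped


def generate_animal(
    spec: ScenarioSpec,
    params: HepaticParams,
    rng: np.random.Generator,
    animal_id: str = "A1",
    group: str = "wild-type",
) -> AnimalRecord:
    """Forward-simulate one animal's blood, liver and intestine TACs."""
    schedule = spec.schedule
    model = spec.arterial_model()
    # The measured blood TAC is the frame average of the continuous bolus
    # curve; the tissue compartments are then driven by the same midtime
    # piecewise-linear input-function reconstruction the analysis uses, so
    # that with zero noise the fit is a self-consistency check and noise is
    # the only source of estimation error.
    blood_vals = _frame_average(model, schedule)
    arterial = PiecewiseLinearCurve(schedule.midtimes, blood_vals)
    liver_output = (
        "amount" if spec.liver_unit in ("cps", "%ID", "MBq") else "concentration"
    )
    liver, intestine = simulate_hepatic(
        params, arterial, schedule, f_ha=spec.f_ha,
        liver_output=liver_output, liver_unit=spec.liver_unit,
        intestine_unit=spec.intestine_unit, animal_id=animal_id,
    )

    durations = schedule.durations
    noisy = {}
    n_clipped = 0
    for region, vals in (
        ("blood", blood_vals), ("liver", liver.values),
        ("intestine", intestine.values),
    ):
        v, nc = _apply_noise(np.asarray(vals, dtype=float), durations,
                             spec.noise_frac, rng)
        noisy[region] = v
        n_clipped += nc

    body_weight = float(
        np.clip(rng.normal(spec.body_weight_mean_g, spec.body_weight_sd_g),
                18.0, None)
    )
    record = AnimalRecord(
        animal_id=animal_id,
        group=group,
        body_weight_g=body_weight,
        injected_activity_MBq=spec.injected_MBq,
        liver_roi_volume_mL=spec.v_liver_mL,
        heart_volume_mL=heart_volume_from_body_weight(
            body_weight, spec.heart_specific_volume_uL_per_g
        ),
        true_params={**params.as_dict(), "n_clipped_frames": n_clipped},
    )
    record.tacs["blood"] = TimeActivityCurve(
        schedule, noisy["blood"], spec.blood_unit, "blood", animal_id
    )
    record.tacs["liver"] = TimeActivityCurve(
        schedule, noisy["liver"], spec.liver_unit, "liver", animal_id
    )
    record.tacs["intestine"] = TimeActivityCurve(
        schedule, noisy["intestine"], spec.intestine_unit, "intestine",
        animal_id,
    )
    return record.validate()


def generate_study(spec: ScenarioSpec) -> list[AnimalRecord]:
    """Generate the full two-group study, reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for group, n, tag in (
        ("wild-type", spec.n_wt, "WT"), ("knockout", spec.n_ko, "KO"),
    ):
        for i in range(n):
            params = draw_animal_params(spec, group, rng)
            rec = generate_animal(
                spec, params, rng,
                animal_id=f"{spec.tracer[:3].upper()}-{tag}{i + 1:02d}",
                group=group,
            )
            rec.true_params["study_seed"] = spec.seed
            records.append(rec)
    return records


def study_frames(records: list[AnimalRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy TAC table + ground-truth parameter table for a generated study."""
    tac_rows = []
    truth_rows = []
    for rec in records:
        for region, tac in rec.tacs.items():
            sched = tac.schedule
            for start, end, value in zip(sched.starts, sched.ends, tac.values):
                tac_rows.append({
                    "animal_id": rec.animal_id, "group": rec.group,
                    "region": region, "frame_start_min": start,
                    "frame_end_min": end, "value": value, "unit": tac.unit,
                })
        if rec.true_params is not None:
            truth_rows.append({"animal_id": rec.animal_id,
                               "group": rec.group, **rec.true_params})
    return pd.DataFrame(tac_rows), pd.DataFrame(truth_rows)
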