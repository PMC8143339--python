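"""Synthetic study generation emulating the ConA hepatitis trial design.

The design mirrors the animal experiments the model was built for: a PK study
(IP doses 50 and 100 mg·kg⁻¹, destructive serum sampling at 5–120 min, no
ConA) and a PD/disease-progression study (vehicle control plus the two dose
groups, IV ConA at 0.5 h after dosing, sampling at 1, 2, 4, 8, 24 h
post-ConA), plus healthy baseline animals.  Destructive sampling is encoded
explicitly: each animal contributes exactly one time point, which is why the
estimation layer pools naively rather than fitting per-animal effects.

Measurement noise is multiplicative log-normal with a stated coefficient of
variation and a mean-preserving correction (serum immunoassay and enzymatic
readouts have multiplicative error); the default CV is 20%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    DomainError,
    ModelParameters,
    OBSERVABLES,
    observable_index,
    pk_concentration,
)
from .simulate import states_at
from .io import validate_observation_table

__all__ = [
    "GroupSpec",
    "StudyDesign",
    "generate_study",
    "apply_proportional_noise",
    "DEFAULT_NOISE_CV",
]

DEFAULT_NOISE_CV = 0.20

PK_ANALYTES = ("GRMS55",)
PD_ANALYTES = ("TNFa", "IFNg", "IL6", "IL10", "ALT", "AST")

_UNITS = {"GRMS55": "mg/L", "TNFa": "ng/L", "IFNg": "ng/L",
          "IL6": "ng/L", "IL10": "ng/L", "ALT": "U/L", "AST": "U/L"}


@dataclass(frozen=True)
class GroupSpec:
    """One dose group: label, IP dose (mg/kg; 0 = vehicle), ConA challenge flag."""

    label: str
    dose: float
    cona: bool


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of the whole study.

    ``pk_sampling`` times are hours after the drug dose (PK groups);
    ``pd_sampling`` times are hours *post-ConA* (PD groups) and are converted
    to the model clock on generation.  ``n_pk/pd_per_timepoint`` animals are
    sacrificed per time point; ``n_healthy_baseline`` undosed, unchallenged
    animals provide the baseline measurements.
    """

    groups: tuple[GroupSpec, ...] = (
        GroupSpec("pk-50", 50.0, False),
        GroupSpec("pk-100", 100.0, False),
        GroupSpec("control", 0.0, True),
        GroupSpec("grms-50", 50.0, True),
        GroupSpec("grms-100", 100.0, True),
    )
    pk_sampling: tuple[float, ...] = (5 / 60, 15 / 60, 30 / 60, 1.0, 1.5, 2.0)
    pd_sampling: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 24.0)
    n_pk_per_timepoint: int = 4
    n_pd_per_timepoint: int = 5
    n_healthy_baseline: int = 4
    analytes: tuple[str, ...] = OBSERVABLES

    def __post_init__(self):
        for seq, what in ((self.pk_sampling, "pk_sampling"), (self.pd_sampling, "pd_sampling")):
            arr = np.asarray(seq, dtype=float)
            if arr.size and (np.any(arr <= 0) or np.any(np.diff(arr) <= 0)):
                raise DomainError(f"{what} times must be positive and strictly increasing")
        if min(self.n_pk_per_timepoint, self.n_pd_per_timepoint, self.n_healthy_baseline) < 1:
            raise DomainError("animal counts must be >= 1")
        for analyte in self.analytes:
            observable_index(analyte)  # raises SchemaError on unknown names


def apply_proportional_noise(value: float, cv: float, rng: np.random.Generator) -> float:
    """Multiplicative log-normal noise with mean-preserving correction.

    Returns ``value * exp(sigma*Z - sigma^2/2)`` with ``sigma^2 = ln(1+cv^2)``,
    so the expectation equals the noiseless value and the coefficient of
    variation of the draw equals ``cv``.
    """
    if not (value > 0):
        raise DomainError(f"value must be > 0, got {value!r}")
    if cv < 0:
        raise DomainError(f"cv must be >= 0, got {cv!r}")
    if cv == 0:
        return float(value)
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    return float(value * np.exp(sigma * rng.standard_normal() - 0.5 * sigma2))


def generate_study(
    design: StudyDesign,
    params: ModelParameters,
    noise_cv: float = DEFAULT_NOISE_CV,
    seed: int | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Simulate the study and return an animal-level observation table.

    PK groups (no ConA) are sampled for the drug only; ConA groups are
    sampled for the PD analytes of the design, plus the drug when dosed
    (the vehicle control has no drug to measure).  Healthy baseline animals
    are recorded at t = 0 at their baseline values.  Identical seed and
    design produce identical tables.
    """
    if noise_cv < 0:
        raise DomainError(f"noise_cv must be >= 0, got {noise_cv!r}")
    rng = np.random.default_rng(seed)
    rows = []
    animal = 0

    def emit(group: GroupSpec, time_h: float, analyte: str, value: float):
        nonlocal animal
        noisy = apply_proportional_noise(value, noise_cv, rng) if noise_cv > 0 else value
        rows.append({
            "group": group.label, "animal_id": f"m{animal:04d}",
            "dose_mg_per_kg": group.dose, "time_h": time_h,
            "analyte": analyte, "value": noisy, "unit": _UNITS[analyte],
            "cona": group.cona,
        })

    for group in design.groups:
        if group.cona:
            times = tuple(params.cona_time + t for t in design.pd_sampling)
            n_per = design.n_pd_per_timepoint
            analytes = [a for a in design.analytes if a in PD_ANALYTES]
            if group.dose > 0 and "GRMS55" in design.analytes:
                analytes = ["GRMS55"] + analytes
        else:
            times = design.pk_sampling
            n_per = design.n_pk_per_timepoint
            analytes = [a for a in design.analytes if a in PK_ANALYTES and group.dose > 0]
            if not analytes:
                continue
        states = states_at(params, group.dose, times, cona=group.cona, rtol=rtol, atol=atol)
        for j, t in enumerate(times):
            for _ in range(n_per):
                animal += 1
                for analyte in analytes:
                    idx = observable_index(analyte)
                    # drug concentrations come from the closed-form solution
                    # (exact, strictly positive at every t > 0)
                    value = pk_concentration(float(t), group.dose, params.pk) \
                        if idx is None else states[idx, j]
                    if value <= 0:  # e.g. a sampling time of exactly 0
                        continue
                    emit(group, float(t), analyte, float(value))

    healthy = GroupSpec("healthy", 0.0, False)
    baseline_values = {
        "TNFa": params.tnf.r0, "IFNg": params.ifn.r0, "IL6": params.il6.r0,
        "IL10": params.il10.r0, "ALT": params.disease.r0_alt, "AST": params.disease.r0_ast,
    }
    for _ in range(design.n_healthy_baseline):
        animal += 1
        for analyte in (a for a in design.analytes if a in PD_ANALYTES):
            emit(healthy, 0.0, analyte, baseline_values[analyte])

    table = pd.DataFrame(rows)
    return validate_observation_table(table)
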