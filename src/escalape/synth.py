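"""Synthetic-data generators and the embedded study fixtures.

Everything here is a pure function of its arguments and an explicit
seed: re-running with the same inputs yields identical output, and no
global random state is read or written.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .blrm import CohortRecord

__all__ = [
    "StudyFixture",
    "make_study_fixtures",
    "gen_tox_outcomes",
    "gen_pk_population",
    "gen_conc_dataset",
    "gen_lesion_series",
]


@dataclass(frozen=True)
class StudyFixture:
    """One study's printed dose ladder, cohort outcomes, and decisions."""

    schedule: str                       # "Q3W" or "QW"
    cohorts: tuple[CohortRecord, ...]   # enrollment order, final counts
    provisional_levels: tuple[float, ...]
    ref_dose_mg: float
    cap_threshold_mg: float
    declared_mtd_mg: float              # as reported
    top_dose_admissible: bool           # EWOC state of the highest dose
    notes: str = field(default="", repr=False)

    @property
    def total_patients(self) -> int:
        return sum(c.n_patients for c in self.cohorts)

    @property
    def total_dlt_patients(self) -> int:
        return sum(c.n_dlt_patients for c in self.cohorts)


def make_study_fixtures() -> tuple[StudyFixture, StudyFixture]:
    """The two studies' first-cycle cohort tables (Q3W, QW)."""
    q3w = StudyFixture(
        schedule="Q3W",
        cohorts=(
            CohortRecord(40.0, 3, 0),
            CohortRecord(120.0, 2, 0),
            CohortRecord(360.0, 2, 0),
            CohortRecord(720.0, 17, 0),
            CohortRecord(1000.0, 5, 1),
        ),
        provisional_levels=(40.0, 120.0, 360.0, 720.0, 1000.0),
        ref_dose_mg=720.0,
        cap_threshold_mg=120.0,
        declared_mtd_mg=720.0,
        top_dose_admissible=True,
        notes="1000 mg stayed admissible; 720 mg chosen on overall review",
    )
    qw = StudyFixture(
        schedule="QW",
        cohorts=(
            CohortRecord(40.0, 2, 0),
            CohortRecord(120.0, 5, 1),
            CohortRecord(150.0, 3, 0),
            CohortRecord(180.0, 11, 1),
            CohortRecord(240.0, 3, 2),
        ),
        provisional_levels=(40.0, 120.0, 150.0, 180.0, 240.0),
        ref_dose_mg=180.0,
        cap_threshold_mg=40.0,
        declared_mtd_mg=180.0,
        top_dose_admissible=False,
        notes="240 mg failed overdose control after 2/3 DLT patients",
    )
    return q3w, qw


def gen_tox_outcomes(scenario, n_per_dose, seed: int) -> list[CohortRecord]:
    """Binomial first-cycle DLT outcomes under a true dose-toxicity curve.

    ``scenario`` supplies parallel ``doses_mg`` / ``dlt_probs``
    sequences (see :class:`escalape.trial.ToxScenario`); ``n_per_dose``
    is an int applied to every dose or a per-dose sequence.
    """
    doses = list(scenario.doses_mg)
    probs = list(scenario.dlt_probs)
    if isinstance(n_per_dose, int):
        ns = [n_per_dose] * len(doses)
    else:
        ns = list(n_per_dose)
        if len(ns) != len(doses):
            raise ValueError("n_per_dose length must match the dose ladder")
    rng = np.random.default_rng(seed)
    return [
        CohortRecord(d, n, int(rng.binomial(n, p)))
        for d, n, p in zip(doses, ns, probs)
    ]


def gen_pk_population(
    base_params: dict[str, float],
    omegas: dict[str, float],
    n: int,
    seed: int,
) -> list[dict[str, float]]:
    """Per-subject parameter sets with lognormal inter-individual
    variability: value = base * exp(Normal(0, omega)).

    Parameters without an omega entry are copied unchanged.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if any(v < 0 for v in omegas.values()):
        raise ValueError("omegas must be nonnegative")
    rng = np.random.default_rng(seed)
    keys = list(base_params)
    subjects = []
    for _ in range(n):
        row = {}
        for k in keys:
            om = omegas.get(k, 0.0)
            eta = rng.normal(0.0, om) if om > 0 else 0.0
            row[k] = base_params[k] * float(np.exp(eta))
        subjects.append(row)
    return subjects


def gen_conc_dataset(
    profile,
    proportional_error_sd: float,
    lloq: float,
    seed: int,
    n_subjects: int = 1,
):
    """Noisy observed concentration series from a simulated truth profile.

    obs = truth * (1 + Normal(0, sd)), floored at zero; values below the
    quantification limit stay in the series flagged BLQ.  ``profile``
    needs ``times`` and ``drug_central`` attributes.
    """
    from .nca import ConcentrationSeries

    if proportional_error_sd < 0:
        raise ValueError("proportional_error_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    truth = np.asarray(profile.drug_central, dtype=float)
    times = np.asarray(profile.times, dtype=float)
    out = []
    for i in range(n_subjects):
        eps = rng.normal(0.0, proportional_error_sd, size=truth.size)
        obs = np.clip(truth * (1.0 + eps), 0.0, None)
        out.append(
            ConcentrationSeries(
                subject=f"S{i + 1:03d}",
                times=times.copy(),
                concentrations=obs,
                lloq=lloq,
            )
        )
    return out


def gen_lesion_series(
    kind: str,
    noise_sd: float,
    seed: int,
    baseline_mm: float = 60.0,
    assessment_weeks: Sequence[float] = (6.0, 12.0, 18.0, 24.0),
    subject: str = "S001",
):
    """Target-lesion sum trajectory of a known response class.

    ``responder`` shrinks past -30% with a confirming assessment,
    ``stable`` drifts within (-30%, +20%), ``progressor`` grows past
    +20% over nadir.  Gaussian measurement noise (mm) is added on top.
    """
    from .endpoints import LesionSeries

    if baseline_mm <= 0:
        raise ValueError("baseline_mm must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    weeks = np.asarray(assessment_weeks, dtype=float)
    if kind == "responder":
        frac = np.clip(1.0 - 0.11 * weeks / 6.0, 0.35, None)
    elif kind == "stable":
        frac = 1.0 - 0.05 * np.sin(weeks / 10.0)
    elif kind == "progressor":
        # crosses +20% over nadir already at the first assessment, so the
        # best overall response is progression rather than transient SD
        frac = 1.0 + 0.30 * weeks / 6.0
    else:
        raise ValueError(f"unknown trajectory class {kind!r}")
    rng = np.random.default_rng(seed)
    sums = np.clip(baseline_mm * frac + rng.normal(0.0, noise_sd, weeks.size), 0.0, None)
    return LesionSeries(
        subject=subject,
        baseline_mm=baseline_mm,
        weeks=weeks,
        target_sums_mm=sums,
    )
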