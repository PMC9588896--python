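"""Escalation-trial replay and operating-characteristics simulation.

``replay`` walks printed cohort tables through the dose-toxicity model
step by step and is fully deterministic; ``simulate_trial`` draws
patient outcomes from an assumed truth and follows the same decision
logic, so operating characteristics of the design can be estimated by
repetition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import blrm
from .blrm import (
    BLRMPrior,
    CohortRecord,
    EscalationRules,
    GridSpec,
    MtdRule,
    PosteriorGrid,
    ToxicityIntervals,
)

__all__ = [
    "ToxScenario",
    "DesignConfig",
    "DecisionRecord",
    "TrialResult",
    "OperatingCharacteristics",
    "replay",
    "simulate_trial",
    "operating_characteristics",
]


@dataclass(frozen=True)
class ToxScenario:
    """Assumed true DLT probability at each provisional dose."""

    doses_mg: tuple[float, ...]
    dlt_probs: tuple[float, ...]

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses_mg)
        probs = tuple(float(p) for p in self.dlt_probs)
        object.__setattr__(self, "doses_mg", doses)
        object.__setattr__(self, "dlt_probs", probs)
        if len(doses) != len(probs):
            raise ValueError("doses and probabilities must align")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must be in [0, 1]")
        if any(b < a for a, b in zip(probs, probs[1:])):
            raise ValueError("true DLT probabilities must be nondecreasing in dose")

    def prob_at(self, dose_mg: float) -> float:
        try:
            return self.dlt_probs[self.doses_mg.index(float(dose_mg))]
        except ValueError:
            raise KeyError(f"dose {dose_mg} not in scenario ladder") from None


@dataclass(frozen=True)
class DesignConfig:
    """Everything that defines one escalation design."""

    prior: BLRMPrior
    rules: EscalationRules
    provisional_levels: tuple[float, ...]
    start_dose_mg: float
    schedule: str = "Q3W"
    mtd_rule: MtdRule = MtdRule()
    intervals: ToxicityIntervals = ToxicityIntervals()
    cohort_size: int = 3
    max_patients: int = 30
    dlt_window_days: float = 21.0
    grid_spec: GridSpec = GridSpec()
    expand_at_mtd: bool = True

    def __post_init__(self) -> None:
        levels = tuple(float(d) for d in self.provisional_levels)
        object.__setattr__(self, "provisional_levels", levels)
        if float(self.start_dose_mg) not in levels:
            raise ValueError("start_dose_mg must be one of the provisional levels")
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if self.max_patients < self.cohort_size:
            raise ValueError("max_patients must allow at least one cohort")


@dataclass(frozen=True)
class DecisionRecord:
    """One interim decision: evidence seen and action taken."""

    step: int
    cohort: CohortRecord
    dose_table: tuple[dict, ...]
    recommended_dose_mg: Optional[float]
    action: str  # "escalate" | "stay" | "de-escalate" | "stop" | "expand"


@dataclass(frozen=True)
class TrialResult:
    decisions: tuple[DecisionRecord, ...]
    mtd_mg: Optional[float]  # None == "not determined"
    total_patients: int
    total_dlt_patients: int
    final_posterior: Optional[PosteriorGrid] = field(default=None, repr=False, compare=False)

    @property
    def mtd_determined(self) -> bool:
        return self.mtd_mg is not None


def _fit(design: DesignConfig, cohorts: Sequence[CohortRecord]) -> PosteriorGrid:
    return blrm.fit_posterior(design.prior, cohorts, design.grid_spec)


def _action(current: float, nxt: Optional[float]) -> str:
    if nxt is None:
        return "stop"
    if nxt > current:
        return "escalate"
    if nxt < current:
        return "de-escalate"
    return "stay"


def replay(cohorts: Sequence[CohortRecord], design: DesignConfig) -> TrialResult:
    """Deterministic step-by-step replay of observed cohort outcomes.

    Cohorts are consumed in enrollment order; after each one the
    posterior is refit to everything seen so far and the model's
    recommendation recorded.  The MTD declaration uses the full data.
    """
    levels = set(design.provisional_levels)
    for c in cohorts:
        if c.dose_mg not in levels:
            raise ValueError(f"cohort dose {c.dose_mg} not a provisional level")

    decisions: list[DecisionRecord] = []
    post: Optional[PosteriorGrid] = None
    for i in range(len(cohorts)):
        seen = list(cohorts[: i + 1])
        post = _fit(design, seen)
        rec = blrm.recommend_next_dose(
            post,
            tested_doses=[c.dose_mg for c in seen],
            provisional_levels=design.provisional_levels,
            rules=design.rules,
            intervals=design.intervals,
        )
        decisions.append(
            DecisionRecord(
                step=i + 1,
                cohort=cohorts[i],
                dose_table=rec.table,
                recommended_dose_mg=rec.dose_mg,
                action=_action(cohorts[i].dose_mg, rec.dose_mg),
            )
        )

    if post is None:
        return TrialResult(decisions=(), mtd_mg=None, total_patients=0, total_dlt_patients=0)

    mtd = blrm.declare_mtd(
        post, list(cohorts), design.rules, design.mtd_rule, design.intervals
    )
    return TrialResult(
        decisions=tuple(decisions),
        mtd_mg=mtd.dose_mg,
        total_patients=sum(c.n_patients for c in cohorts),
        total_dlt_patients=sum(c.n_dlt_patients for c in cohorts),
        final_posterior=post,
    )


def simulate_trial(scenario: ToxScenario, design: DesignConfig, seed: int) -> TrialResult:
    """One seeded trial under an assumed truth.

    Cohort DLT counts are binomial draws from the scenario.  Escalation
    follows the model recommendation under the caps and no-skip rule;
    the trial ends at the patient ceiling, on MTD declaration (the MTD
    is a recommended dose already carrying enough patients), or when no
    dose is admissible.  Once the MTD is declared, remaining patients
    (up to the ceiling) enroll at it as a safety-expansion cohort.
    """
    if not set(scenario.doses_mg) >= set(design.provisional_levels):
        raise ValueError("scenario must cover every provisional level")
    rng = np.random.default_rng(seed)
    cohorts: list[CohortRecord] = []
    decisions: list[DecisionRecord] = []
    current = float(design.start_dose_mg)
    n_total = 0
    mtd: Optional[float] = None
    post: Optional[PosteriorGrid] = None
    step = 0

    while n_total + design.cohort_size <= design.max_patients:
        step += 1
        n = design.cohort_size
        n_dlt = int(rng.binomial(n, scenario.prob_at(current)))
        cohort = CohortRecord(current, n, n_dlt)
        cohorts.append(cohort)
        n_total += n

        post = _fit(design, cohorts)
        rec = blrm.recommend_next_dose(
            post,
            tested_doses=[c.dose_mg for c in cohorts],
            provisional_levels=design.provisional_levels,
            rules=design.rules,
            intervals=design.intervals,
        )
        decisions.append(
            DecisionRecord(
                step=step,
                cohort=cohort,
                dose_table=rec.table,
                recommended_dose_mg=rec.dose_mg,
                action=_action(current, rec.dose_mg),
            )
        )
        if rec.dose_mg is None:
            break  # nothing admissible: stop, MTD not determined

        n_at_rec = sum(c.n_patients for c in cohorts if c.dose_mg == rec.dose_mg)
        if n_at_rec >= design.mtd_rule.min_patients_at_mtd:
            candidate = blrm.declare_mtd(
                post, cohorts, design.rules, design.mtd_rule, design.intervals
            )
            if candidate.dose_mg == rec.dose_mg:
                mtd = candidate.dose_mg
                break
        current = rec.dose_mg
    else:
        # patient ceiling reached without an early declaration: take the
        # highest admissible dose with enough patients (the target-interval
        # gate only governs early stopping)
        if post is not None:
            final = blrm.declare_mtd(
                post,
                cohorts,
                design.rules,
                replace(design.mtd_rule, min_target_interval_prob=0.0),
                design.intervals,
            )
            mtd = final.dose_mg

    if mtd is not None and design.expand_at_mtd:
        # safety expansion at the declared MTD; outcomes counted in the
        # totals but no further dose decisions are made
        while n_total + design.cohort_size <= design.max_patients:
            step += 1
            n = design.cohort_size
            n_dlt = int(rng.binomial(n, scenario.prob_at(mtd)))
            cohort = CohortRecord(mtd, n, n_dlt)
            cohorts.append(cohort)
            n_total += n
            decisions.append(
                DecisionRecord(
                    step=step,
                    cohort=cohort,
                    dose_table=(),
                    recommended_dose_mg=mtd,
                    action="expand",
                )
            )

    return TrialResult(
        decisions=tuple(decisions),
        mtd_mg=mtd,
        total_patients=n_total,
        total_dlt_patients=sum(c.n_dlt_patients for c in cohorts),
        final_posterior=post,
    )


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Design performance across seeded simulated trials."""

    n_sims: int
    selection_freq: dict[float, float]  # dose -> fraction of trials
    not_determined_freq: float
    mean_patients: float
    mean_dlt_patients: float

    @property
    def modal_mtd_mg(self) -> Optional[float]:
        """Most frequently selected dose (ties toward the higher dose);
        None when every trial ended without an MTD."""
        top = max(self.selection_freq.values(), default=0.0)
        if top == 0.0:
            return None
        return max(d for d, f in self.selection_freq.items() if f == top)


def operating_characteristics(
    scenario: ToxScenario,
    design: DesignConfig,
    n_sims: int,
    seed: int,
) -> OperatingCharacteristics:
    """Selection frequencies and resource use over ``n_sims`` trials.

    Per-trial seeds are spawned deterministically from ``seed``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(n_sims)
    counts: dict[float, int] = {d: 0 for d in design.provisional_levels}
    nd = 0
    patients = []
    dlts = []
    for s in seeds:
        res = simulate_trial(scenario, design, int(s))
        if res.mtd_mg is None:
            nd += 1
        else:
            counts[res.mtd_mg] += 1
        patients.append(res.total_patients)
        dlts.append(res.total_dlt_patients)
    return OperatingCharacteristics(
        n_sims=n_sims,
        selection_freq={d: c / n_sims for d, c in counts.items()},
        not_determined_freq=nd / n_sims,
        mean_patients=float(np.mean(patients)),
        mean_dlt_patients=float(np.mean(dlts)),
    )
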