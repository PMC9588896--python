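"""Two-parameter Bayesian logistic dose-toxicity model with overdose control.

The model relates dose ``d`` to the probability of a first-cycle
dose-limiting toxicity (DLT) through

    logit p(d) = log_alpha + exp(log_beta) * ln(d / d_ref)

with a bivariate normal prior on ``(log_alpha, log_beta)``.  Because the
slope ``exp(log_beta)`` is positive, ``p(d)`` is strictly increasing in
dose for every parameter value, which makes interval summaries and the
overdose-control (EWOC) rule monotone in dose.

The posterior is computed by deterministic tensor-product quadrature on a
rectangular grid, so every decision derived from it is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit, xlogy
from scipy.stats import multivariate_normal, norm

__all__ = [
    "CohortRecord",
    "ToxicityIntervals",
    "BLRMPrior",
    "GridSpec",
    "PosteriorGrid",
    "EscalationRules",
    "MtdRule",
    "DoseRecommendation",
    "MtdDecision",
    "dlt_probability",
    "fit_posterior",
    "interval_probabilities",
    "ewoc_admissible",
    "escalation_cap",
    "recommend_next_dose",
    "declare_mtd",
]

# Posterior weights are renormalized; this is the tolerance tests hold them to.
_NORM_TOL = 1e-10


@dataclass(frozen=True)
class CohortRecord:
    """First-cycle outcome of one dose level.

    A patient with multiple DLTs counts once in ``n_dlt_patients``.
    """

    dose_mg: float
    n_patients: int
    n_dlt_patients: int

    def __post_init__(self) -> None:
        if not self.dose_mg > 0:
            raise ValueError(f"dose_mg must be positive, got {self.dose_mg}")
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        if not 0 <= self.n_dlt_patients <= self.n_patients:
            raise ValueError(
                f"n_dlt_patients must be in [0, n_patients], got "
                f"{self.n_dlt_patients}/{self.n_patients}"
            )


@dataclass(frozen=True)
class ToxicityIntervals:
    """Partition of DLT probability into under / target / over toxicity."""

    under_upper: float = 0.16
    target_upper: float = 0.33

    def __post_init__(self) -> None:
        if not 0 < self.under_upper < self.target_upper < 1:
            raise ValueError(
                f"need 0 < under_upper < target_upper < 1, got "
                f"({self.under_upper}, {self.target_upper})"
            )


@dataclass(frozen=True)
class BLRMPrior:
    """Bivariate normal prior on (log_alpha, log_beta)."""

    ref_dose_mg: float
    mean_log_alpha: float
    sd_log_alpha: float
    mean_log_beta: float
    sd_log_beta: float
    correlation: float = 0.0

    def __post_init__(self) -> None:
        if not self.ref_dose_mg > 0:
            raise ValueError("ref_dose_mg must be positive")
        if not (self.sd_log_alpha > 0 and self.sd_log_beta > 0):
            raise ValueError("prior standard deviations must be positive")
        if not -1 < self.correlation < 1:
            raise ValueError("correlation must be in (-1, 1)")


def reference_prior(ref_dose_mg: float) -> BLRMPrior:
    """Weakly-informative default prior used by the fixtures.

    logit of 0.20 centers the intercept on a 20% DLT rate at the
    reference dose; unit-scale normal on the log-slope.
    """
    return BLRMPrior(
        ref_dose_mg=ref_dose_mg,
        mean_log_alpha=float(logit(0.2)),
        sd_log_alpha=2.0,
        mean_log_beta=0.0,
        sd_log_beta=1.0,
        correlation=0.0,
    )


@dataclass(frozen=True)
class GridSpec:
    """Quadrature grid: node counts and (optional) explicit bounds.

    Without explicit bounds each axis spans prior mean +/- n_sd standard
    deviations.
    """

    n_log_alpha: int = 401
    n_log_beta: int = 401
    n_sd: float = 6.0
    log_alpha_bounds: Optional[tuple[float, float]] = None
    log_beta_bounds: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.n_log_alpha < 2 or self.n_log_beta < 2:
            raise ValueError("grid needs at least 2 nodes per axis")
        if self.n_sd <= 0:
            raise ValueError("n_sd must be positive")


@dataclass(frozen=True)
class PosteriorGrid:
    """Normalized discrete posterior over (log_alpha, log_beta).

    ``weights[i, j]`` is the probability attached to node
    ``(log_alpha_nodes[i], log_beta_nodes[j])``.
    """

    log_alpha_nodes: np.ndarray
    log_beta_nodes: np.ndarray
    weights: np.ndarray
    ref_dose_mg: float

    def __post_init__(self) -> None:
        la = np.asarray(self.log_alpha_nodes, dtype=float)
        lb = np.asarray(self.log_beta_nodes, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "log_alpha_nodes", la)
        object.__setattr__(self, "log_beta_nodes", lb)
        object.__setattr__(self, "weights", w)
        if np.any(np.diff(la) <= 0) or np.any(np.diff(lb) <= 0):
            raise ValueError("node grids must be strictly increasing")
        if w.shape != (la.size, lb.size):
            raise ValueError("weights shape does not match node grids")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")

    def dlt_prob_nodes(self, dose_mg: float, ref_dose_mg: Optional[float] = None) -> np.ndarray:
        """p(dose) evaluated at every grid node (same shape as weights)."""
        ref = self.ref_dose_mg if ref_dose_mg is None else ref_dose_mg
        la = self.log_alpha_nodes[:, None]
        lb = self.log_beta_nodes[None, :]
        return dlt_probability(la, lb, dose_mg, ref)

    def mean_dlt_prob(self, dose_mg: float, ref_dose_mg: Optional[float] = None) -> float:
        return float(np.sum(self.weights * self.dlt_prob_nodes(dose_mg, ref_dose_mg)))


@dataclass(frozen=True)
class EscalationRules:
    """EWOC feasibility bound plus maximum-escalation caps."""

    cap_threshold_mg: float
    ewoc_feasibility: float = 0.25
    overdose_cutoff: float = 0.33
    max_increment_low: float = 2.0   # +200% at or below the threshold
    max_increment_high: float = 1.0  # +100% above it
    allow_skipping: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.ewoc_feasibility < 1:
            raise ValueError("ewoc_feasibility must be in (0, 1)")
        if not 0 < self.overdose_cutoff < 1:
            raise ValueError("overdose_cutoff must be in (0, 1)")
        if self.cap_threshold_mg <= 0:
            raise ValueError("cap_threshold_mg must be positive")
        if self.max_increment_low <= 0 or self.max_increment_high <= 0:
            raise ValueError("max increments must be positive")


@dataclass(frozen=True)
class MtdRule:
    """Declaration rule: minimum target-interval probability and patients."""

    min_target_interval_prob: float = 0.0
    min_patients_at_mtd: int = 6

    def __post_init__(self) -> None:
        if self.min_target_interval_prob < 0:
            raise ValueError("min_target_interval_prob must be >= 0")
        if self.min_patients_at_mtd < 0:
            raise ValueError("min_patients_at_mtd must be >= 0")


def dlt_probability(log_alpha, log_beta, dose_mg, ref_dose_mg):
    """DLT probability at ``dose_mg``; vectorized over the parameters.

    logit p = log_alpha + exp(log_beta) * ln(dose / ref_dose).
    """
    dose_mg = np.asarray(dose_mg, dtype=float)
    if np.any(dose_mg <= 0):
        raise ValueError("dose_mg must be positive")
    if ref_dose_mg <= 0:
        raise ValueError("ref_dose_mg must be positive")
    eta = log_alpha + np.exp(log_beta) * np.log(dose_mg / ref_dose_mg)
    return expit(eta)


def _prior_rect_mass(prior: BLRMPrior, alo, ahi, blo, bhi) -> float:
    mean = [prior.mean_log_alpha, prior.mean_log_beta]
    c = prior.correlation * prior.sd_log_alpha * prior.sd_log_beta
    cov = [[prior.sd_log_alpha**2, c], [c, prior.sd_log_beta**2]]
    if prior.correlation == 0.0:
        pa = norm.cdf(ahi, mean[0], prior.sd_log_alpha) - norm.cdf(alo, mean[0], prior.sd_log_alpha)
        pb = norm.cdf(bhi, mean[1], prior.sd_log_beta) - norm.cdf(blo, mean[1], prior.sd_log_beta)
        return float(pa * pb)
    mvn = multivariate_normal(mean=mean, cov=cov)
    return float(
        mvn.cdf([ahi, bhi]) - mvn.cdf([alo, bhi]) - mvn.cdf([ahi, blo]) + mvn.cdf([alo, blo])
    )


def fit_posterior(
    prior: BLRMPrior,
    cohorts: Sequence[CohortRecord],
    grid_spec: Optional[GridSpec] = None,
) -> PosteriorGrid:
    """Posterior over (log_alpha, log_beta) by grid quadrature.

    Weights are proportional to prior density x binomial likelihood at
    each node, then normalized.  With zero cohorts this returns the
    discretized prior.  Deterministic for a fixed ``grid_spec``.
    """
    spec = grid_spec or GridSpec()
    for c in cohorts:
        if not isinstance(c, CohortRecord):
            raise TypeError(f"expected CohortRecord, got {type(c).__name__}")

    if spec.log_alpha_bounds is not None:
        alo, ahi = spec.log_alpha_bounds
    else:
        alo = prior.mean_log_alpha - spec.n_sd * prior.sd_log_alpha
        ahi = prior.mean_log_alpha + spec.n_sd * prior.sd_log_alpha
    if spec.log_beta_bounds is not None:
        blo, bhi = spec.log_beta_bounds
    else:
        blo = prior.mean_log_beta - spec.n_sd * prior.sd_log_beta
        bhi = prior.mean_log_beta + spec.n_sd * prior.sd_log_beta

    truncated = 1.0 - _prior_rect_mass(prior, alo, ahi, blo, bhi)
    if truncated > 1e-6:
        warnings.warn(
            f"grid bounds truncate {truncated:.2e} of prior mass; "
            "widen the grid or supply explicit bounds",
            stacklevel=2,
        )

    la = np.linspace(alo, ahi, spec.n_log_alpha)
    lb = np.linspace(blo, bhi, spec.n_log_beta)
    A = la[:, None]
    B = lb[None, :]

    if prior.correlation == 0.0:
        logw = norm.logpdf(A, prior.mean_log_alpha, prior.sd_log_alpha) + norm.logpdf(
            B, prior.mean_log_beta, prior.sd_log_beta
        )
    else:
        c = prior.correlation * prior.sd_log_alpha * prior.sd_log_beta
        cov = [[prior.sd_log_alpha**2, c], [c, prior.sd_log_beta**2]]
        pts = np.stack(np.broadcast_arrays(A + 0 * B, B + 0 * A), axis=-1)
        logw = multivariate_normal(
            mean=[prior.mean_log_alpha, prior.mean_log_beta], cov=cov
        ).logpdf(pts)

    for cohort in cohorts:
        p = dlt_probability(A, B, cohort.dose_mg, prior.ref_dose_mg)
        # binomial coefficient is constant over the grid and cancels on
        # normalization; xlogy keeps k=0 / k=n cases exact
        logw = logw + xlogy(cohort.n_dlt_patients, p) + xlogy(
            cohort.n_patients - cohort.n_dlt_patients, 1.0 - p
        )

    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    return PosteriorGrid(la, lb, w, ref_dose_mg=prior.ref_dose_mg)


def interval_probabilities(
    post: PosteriorGrid,
    dose_mg: float,
    intervals: ToxicityIntervals = ToxicityIntervals(),
    ref_dose_mg: Optional[float] = None,
) -> tuple[float, float, float]:
    """(P under, P target, P over) for the DLT rate at ``dose_mg``.

    Under toxicity is [0, under_upper), target [under_upper,
    target_upper), over [target_upper, 1].
    """
    p = post.dlt_prob_nodes(dose_mg, ref_dose_mg)
    w = post.weights
    p_under = float(w[p < intervals.under_upper].sum())
    p_over = float(w[p >= intervals.target_upper].sum())
    p_target = float(max(0.0, 1.0 - p_under - p_over))
    return p_under, p_target, p_over


def ewoc_admissible(
    post: PosteriorGrid,
    dose_mg: float,
    rules: EscalationRules,
    ref_dose_mg: Optional[float] = None,
) -> tuple[bool, float]:
    """EWOC check: (admissible, overdose probability).

    Admissible iff P(p(dose) >= overdose_cutoff) < ewoc_feasibility.
    """
    p = post.dlt_prob_nodes(dose_mg, ref_dose_mg)
    p_over = float(post.weights[p >= rules.overdose_cutoff].sum())
    return p_over < rules.ewoc_feasibility, p_over


def escalation_cap(current_dose_mg: float, rules: EscalationRules) -> float:
    """Maximum next dose: +200% at or below the threshold, else +100%."""
    if current_dose_mg <= 0:
        raise ValueError("current_dose_mg must be positive")
    if current_dose_mg <= rules.cap_threshold_mg:
        return current_dose_mg * (1.0 + rules.max_increment_low)
    return current_dose_mg * (1.0 + rules.max_increment_high)


@dataclass(frozen=True)
class DoseRecommendation:
    """Next-dose decision with the per-level evidence behind it."""

    dose_mg: Optional[float]  # None == stop: no admissible level
    table: tuple[dict, ...] = field(default=(), repr=False)

    @property
    def stop(self) -> bool:
        return self.dose_mg is None


def recommend_next_dose(
    post: PosteriorGrid,
    tested_doses: Sequence[float],
    provisional_levels: Sequence[float],
    rules: EscalationRules,
    intervals: ToxicityIntervals = ToxicityIntervals(),
    ref_dose_mg: Optional[float] = None,
) -> DoseRecommendation:
    """Highest-target-probability dose among candidate levels.

    Candidates must be EWOC-admissible, lie at or below the escalation
    cap of the highest tested dose, and (unless skipping is allowed) not
    jump over an untested provisional level.  Ties in the
    target-interval probability break toward the higher dose.  Returns a
    stop signal when no level qualifies.
    """
    levels = [float(d) for d in provisional_levels]
    if not levels:
        raise ValueError("provisional_levels must be nonempty")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("provisional_levels must be strictly increasing")

    tested = set(float(d) for d in tested_doses)
    cap = escalation_cap(max(tested), rules) if tested else None
    if rules.allow_skipping:
        reachable = set(levels)
    else:
        # allowed: every tested level plus the lowest untested one
        reachable = set()
        for d in levels:
            reachable.add(d)
            if d not in tested:
                break

    table = []
    best: Optional[tuple[float, float]] = None  # (p_target, dose)
    for d in levels:
        admissible, p_over_ewoc = ewoc_admissible(post, d, rules, ref_dose_mg)
        p_under, p_target, p_over = interval_probabilities(post, d, intervals, ref_dose_mg)
        capped = cap is not None and d > cap
        skippable = d not in reachable
        candidate = admissible and not capped and not skippable
        table.append(
            dict(
                dose_mg=d,
                p_under=p_under,
                p_target=p_target,
                p_over=p_over,
                overdose_prob=p_over_ewoc,
                ewoc_admissible=admissible,
                within_cap=not capped,
                reachable=not skippable,
                candidate=candidate,
            )
        )
        if candidate and (best is None or (p_target, d) >= best):
            best = (p_target, d)

    return DoseRecommendation(dose_mg=None if best is None else best[1], table=tuple(table))


@dataclass(frozen=True)
class MtdDecision:
    """Outcome of an MTD declaration attempt."""

    dose_mg: Optional[float]  # None == "not determined"
    p_target: Optional[float] = None
    overdose_prob: Optional[float] = None

    @property
    def determined(self) -> bool:
        return self.dose_mg is not None


def declare_mtd(
    post: PosteriorGrid,
    tested_cohorts: Sequence[CohortRecord],
    rules: EscalationRules,
    mtd_rule: MtdRule = MtdRule(),
    intervals: ToxicityIntervals = ToxicityIntervals(),
    ref_dose_mg: Optional[float] = None,
) -> MtdDecision:
    """Highest tested dose passing EWOC with enough patients treated.

    Returns "not determined" (dose None) when no tested dose qualifies.
    """
    if not tested_cohorts:
        raise ValueError("declare_mtd needs at least one cohort")
    n_at_dose: dict[float, int] = {}
    for c in tested_cohorts:
        n_at_dose[c.dose_mg] = n_at_dose.get(c.dose_mg, 0) + c.n_patients

    for dose in sorted(n_at_dose, reverse=True):
        if n_at_dose[dose] < mtd_rule.min_patients_at_mtd:
            continue
        admissible, p_over = ewoc_admissible(post, dose, rules, ref_dose_mg)
        if not admissible:
            continue
        _, p_target, _ = interval_probabilities(post, dose, intervals, ref_dose_mg)
        if p_target < mtd_rule.min_target_interval_prob:
            continue
        return MtdDecision(dose_mg=dose, p_target=p_target, overdose_prob=p_over)
    return MtdDecision(dose_mg=None)
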