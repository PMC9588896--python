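"""Tumor-response endpoints from target-lesion measurements.

Implements the target-lesion arithmetic of standard solid-tumor
response criteria: percent change from baseline, best-overall-response
categorization (CR/PR/SD/PD/NE) with partial-response confirmation, and
duration of response.  Only target-lesion sums (plus an optional
new-lesion flag) are modelled; nodal rules and non-target assessment
are out of scope.

Thresholds (documented constants): PR at <= -30% versus baseline,
PD at >= +20% versus the nadir, where the nadir is the smallest sum
observed so far including baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LesionSeries",
    "BestOverallResponse",
    "DurationOfResponse",
    "percent_change_from_baseline",
    "best_overall_response",
    "duration_of_response",
]

PR_THRESHOLD_PCT = -30.0
PD_THRESHOLD_PCT = 20.0

_CATEGORY_ORDER = {"CR": 4, "PR": 3, "SD": 2, "PD": 1, "NE": 0}


@dataclass(frozen=True)
class LesionSeries:
    """Sum of target-lesion diameters over scheduled assessments."""

    subject: str
    baseline_mm: float
    weeks: np.ndarray
    target_sums_mm: np.ndarray
    new_lesion: Optional[np.ndarray] = None  # optional per-assessment flag

    def __post_init__(self) -> None:
        w = np.asarray(self.weeks, dtype=float)
        s = np.asarray(self.target_sums_mm, dtype=float)
        object.__setattr__(self, "weeks", w)
        object.__setattr__(self, "target_sums_mm", s)
        if self.baseline_mm <= 0:
            raise ValueError("baseline_mm must be positive")
        if w.shape != s.shape or w.ndim != 1:
            raise ValueError("weeks and target sums must be matching 1-D arrays")
        if np.any(np.diff(w) <= 0):
            raise ValueError("assessment weeks must be strictly increasing")
        if np.any(s < 0):
            raise ValueError("target sums must be nonnegative")
        if self.new_lesion is not None:
            nl = np.asarray(self.new_lesion, dtype=bool)
            if nl.shape != w.shape:
                raise ValueError("new_lesion must align with assessments")
            object.__setattr__(self, "new_lesion", nl)


def percent_change_from_baseline(series: LesionSeries) -> tuple[np.ndarray, Optional[float]]:
    """Per-assessment percent change and the best (most negative) change."""
    changes = 100.0 * (series.target_sums_mm - series.baseline_mm) / series.baseline_mm
    best = float(changes.min()) if changes.size else None
    return changes, best


def _classify(series: LesionSeries) -> list[str]:
    """Per-assessment category relative to baseline and running nadir."""
    cats = []
    nadir = series.baseline_mm
    for i, s in enumerate(series.target_sums_mm):
        change_bl = 100.0 * (s - series.baseline_mm) / series.baseline_mm
        if nadir > 0:
            change_nadir = 100.0 * (s - nadir) / nadir
        else:
            # nadir of zero (complete disappearance): any regrowth is
            # progression, continued absence is not
            change_nadir = np.inf if s > 0 else 0.0
        new_lesion = bool(series.new_lesion[i]) if series.new_lesion is not None else False
        if new_lesion or change_nadir >= PD_THRESHOLD_PCT:
            cats.append("PD")
        elif s == 0.0:
            cats.append("CR")
        elif change_bl <= PR_THRESHOLD_PCT:
            cats.append("PR")
        else:
            cats.append("SD")
        nadir = min(nadir, s)
    return cats


@dataclass(frozen=True)
class BestOverallResponse:
    category: str  # CR | PR | SD | PD | NE
    confirmed: bool
    first_response_week: Optional[float] = None
    trace: tuple[str, ...] = field(default=(), repr=False)


def best_overall_response(
    series: LesionSeries,
    confirmation_window_weeks: float = 4.0,
    min_sd_duration_weeks: float = 6.0,
) -> BestOverallResponse:
    """Best response from first dose until progression.

    A CR/PR is confirmed by a second qualifying assessment at least
    ``confirmation_window_weeks`` later and before progression.  SD
    counts only when a non-PD assessment occurs at or after
    ``min_sd_duration_weeks``; otherwise the best category falls through
    to PD (or NE).  Zero assessments give NE.
    """
    cats = _classify(series)
    if not cats:
        return BestOverallResponse(category="NE", confirmed=False)

    # assessments after the first PD don't count toward the best response
    horizon = cats.index("PD") + 1 if "PD" in cats else len(cats)
    window = cats[:horizon]
    weeks = series.weeks[:horizon]

    resp_weeks = [w for w, c in zip(weeks, window) if c in ("CR", "PR")]
    best_cat = "NE"
    for c, w in zip(window, weeks):
        if _CATEGORY_ORDER[c] > _CATEGORY_ORDER[best_cat]:
            if c == "SD" and w < min_sd_duration_weeks:
                continue  # too early to lock in stable disease
            best_cat = c

    if best_cat == "NE" and "PD" in window:
        best_cat = "PD"

    confirmed = False
    first_week = resp_weeks[0] if resp_weeks else None
    if best_cat in ("CR", "PR"):
        confirmed = any(
            w2 - resp_weeks[0] >= confirmation_window_weeks for w2 in resp_weeks[1:]
        )
    return BestOverallResponse(
        category=best_cat,
        confirmed=confirmed,
        first_response_week=first_week,
        trace=tuple(cats),
    )


@dataclass(frozen=True)
class DurationOfResponse:
    weeks: Optional[float]  # None == not available
    censored: bool
    reason: str = ""

    @property
    def available(self) -> bool:
        return self.weeks is not None


def duration_of_response(
    series: LesionSeries,
    confirmation_window_weeks: float = 4.0,
) -> DurationOfResponse:
    """Time from first CR/PR qualification to progression.

    Without an observed progression the duration is censored at the last
    assessment; when no imaging followed the qualifying assessment at
    all, the duration is reported as not available.  Raises when no
    response was achieved.
    """
    cats = _classify(series)
    try:
        i_resp = next(i for i, c in enumerate(cats) if c in ("CR", "PR"))
    except StopIteration:
        raise ValueError("no response achieved; duration of response not applicable")
    w_resp = float(series.weeks[i_resp])
    for j in range(i_resp + 1, len(cats)):
        if cats[j] == "PD":
            return DurationOfResponse(float(series.weeks[j]) - w_resp, censored=False)
    if i_resp == len(cats) - 1:
        return DurationOfResponse(None, censored=True, reason="no imaging after response")
    return DurationOfResponse(
        float(series.weeks[-1]) - w_resp, censored=True, reason="no progression observed"
    )
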