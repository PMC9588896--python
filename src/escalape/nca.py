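"""Noncompartmental exposure analysis.

Cmax/Tmax, AUC to the last quantifiable concentration (linear or
linear-up/log-down trapezoids), terminal half-life from a
best-adjusted-R2 log-linear fit, and a power-model dose-proportionality
check.

BLQ convention (documented default): values below the quantification
limit before Tmax are treated as zero; BLQ values after Tmax are
excluded from all calculations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcentrationSeries",
    "NCAResult",
    "DoseProportionalityResult",
    "auc_0_tz",
    "cmax_tmax",
    "terminal_half_life",
    "run_nca",
    "dose_proportionality",
]


@dataclass(frozen=True)
class ConcentrationSeries:
    """One subject's concentration-time course.

    Units default to days and nM; they are carried as labels, never
    converted implicitly.
    """

    subject: str
    times: np.ndarray
    concentrations: np.ndarray
    lloq: float = 0.0
    time_unit: str = "day"
    conc_unit: str = "nM"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and concentrations must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be nonnegative")
        if self.lloq < 0:
            raise ValueError("lloq must be nonnegative")

    @property
    def blq(self) -> np.ndarray:
        """Boolean mask of below-quantification-limit observations."""
        return self.concentrations < self.lloq


@dataclass(frozen=True)
class NCAResult:
    subject: str
    c_max: Optional[float] = None
    t_max: Optional[float] = None
    auc_0_tz: Optional[float] = None
    t_half: Optional[float] = None
    n_terminal_points: int = 0
    terminal_fit_r2: Optional[float] = None

    @property
    def evaluable(self) -> bool:
        return self.c_max is not None


def _quantifiable(series: ConcentrationSeries) -> tuple[np.ndarray, np.ndarray]:
    """Apply the BLQ convention; returns (times, concentrations)."""
    t = series.times
    c = series.concentrations.copy()
    blq = series.blq
    if (~blq).sum() == 0:
        return np.array([]), np.array([])
    tmax = t[~blq][np.argmax(c[~blq])]
    keep = np.ones_like(blq, dtype=bool)
    c[blq & (t <= tmax)] = 0.0       # pre-Tmax BLQ -> zero
    keep[blq & (t > tmax)] = False   # post-Tmax BLQ -> dropped
    return t[keep], c[keep]


def cmax_tmax(series: ConcentrationSeries) -> Optional[tuple[float, float]]:
    """Maximum observed concentration and its first occurrence time.

    Returns None (not evaluable) when every point is BLQ.
    """
    mask = ~series.blq
    if not mask.any():
        return None
    c = series.concentrations[mask]
    t = series.times[mask]
    i = int(np.argmax(c))  # argmax takes the first occurrence on ties
    return float(c[i]), float(t[i])


def auc_0_tz(series: ConcentrationSeries, method: str = "linuplogdown") -> Optional[float]:
    """Trapezoidal AUC from time zero to the last quantifiable point.

    ``linuplogdown`` uses the log trapezoid on strictly positive,
    strictly decreasing intervals and the linear trapezoid elsewhere;
    ``linear`` is all-linear.  Returns None with <2 quantifiable points.
    """
    if method not in ("linuplogdown", "linear"):
        raise ValueError(f"unknown AUC method {method!r}")
    t, c = _quantifiable(series)
    if t.size < 2:
        return None
    auc = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if method == "linuplogdown" and c1 > c2 > 0:
            auc += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            auc += dt * (c1 + c2) / 2.0
    return float(auc)


def terminal_half_life(
    series: ConcentrationSeries, min_points: int = 3
) -> Optional[tuple[float, int, float]]:
    """ln(2)/lambda_z from the terminal log-linear slope.

    The terminal window is the contiguous run of final quantifiable
    points (excluding Tmax, >= ``min_points`` long) maximizing adjusted
    R2, ties broken toward more points.  Returns (t_half, n_points, r2),
    or None when no window gives a negative slope.
    """
    t, c = _quantifiable(series)
    pos = c > 0
    t, c = t[pos], c[pos]
    if t.size < min_points:
        return None
    i_tmax = int(np.argmax(c))
    t_term, c_term = t[i_tmax + 1 :], c[i_tmax + 1 :]
    n = t_term.size
    if n < min_points:
        return None
    logc = np.log(c_term)
    best = None  # (adj_r2, n_pts, slope, r2)
    for k in range(min_points, n + 1):
        tt, yy = t_term[-k:], logc[-k:]
        slope, _, r, _, _ = stats.linregress(tt, yy)
        if slope >= 0:
            continue
        r2 = r * r
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2) if k > 2 else r2
        # tuple order implements: best adjusted R2, then more points
        cand = (round(adj, 12), k, slope, r2)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    _, k, slope, r2 = best
    return float(math.log(2.0) / -slope), int(k), float(r2)


def run_nca(series: ConcentrationSeries, method: str = "linuplogdown") -> NCAResult:
    """Full per-subject summary; never raises on sparse data."""
    peak = cmax_tmax(series)
    if peak is None:
        return NCAResult(subject=series.subject)
    c_max, t_max = peak
    auc = auc_0_tz(series, method=method)
    th = terminal_half_life(series)
    if th is None:
        return NCAResult(series.subject, c_max, t_max, auc)
    t_half, n_pts, r2 = th
    return NCAResult(series.subject, c_max, t_max, auc, t_half, n_pts, r2)


@dataclass(frozen=True)
class DoseProportionalityResult:
    slope: float
    ci_low: float
    ci_high: float
    proportional: bool
    n_obs: int = 0


def dose_proportionality(
    table: pd.DataFrame,
    dose_col: str = "dose_mg",
    auc_col: str = "auc",
    ci_level: float = 0.90,
) -> DoseProportionalityResult:
    """Power-model slope of ln(AUC) on ln(dose) with a confidence
    interval; flagged proportional when the CI contains 1."""
    df = table[[dose_col, auc_col]].dropna()
    doses = df[dose_col].to_numpy(dtype=float)
    aucs = df[auc_col].to_numpy(dtype=float)
    if np.unique(doses).size < 3:
        raise ValueError("need at least 3 distinct dose levels")
    if np.any(doses <= 0) or np.any(aucs <= 0):
        raise ValueError("doses and AUCs must be positive for the power model")
    x, y = np.log(doses), np.log(aucs)
    res = stats.linregress(x, y)
    dof = x.size - 2
    half = stats.t.ppf(0.5 + ci_level / 2.0, dof) * res.stderr if dof > 0 else 0.0
    lo, hi = res.slope - half, res.slope + half
    return DoseProportionalityResult(
        slope=float(res.slope),
        ci_low=float(lo),
        ci_high=float(hi),
        proportional=bool(lo <= 1.0 <= hi),
        n_obs=int(x.size),
    )


def read_concentration_csv(path) -> list[ConcentrationSeries]:
    """Long-format reader: columns subject,time,conc[,lloq]."""
    df = pd.read_csv(path)
    required = {"subject", "time", "conc"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")
    out = []
    for subj, grp in df.groupby("subject", sort=True):
        grp = grp.sort_values("time")
        lloq = float(grp["lloq"].iloc[0]) if "lloq" in grp.columns else 0.0
        out.append(
            ConcentrationSeries(
                subject=str(subj),
                times=grp["time"].to_numpy(dtype=float),
                concentrations=grp["conc"].to_numpy(dtype=float),
                lloq=lloq,
            )
        )
    return out


def nca_table(results: Sequence[NCAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                subject=r.subject,
                c_max=r.c_max,
                t_max=r.t_max,
                auc_0_tz=r.auc_0_tz,
                t_half=r.t_half,
                n_terminal_points=r.n_terminal_points,
                terminal_fit_r2=r.terminal_fit_r2,
            )
            for r in results
        ]
    )
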