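"""Method-agreement statistics for two paired RSS series.

Two speciation programs run on the same urine samples rarely print the same
RSS numbers — their coefficient tables differ — yet one program's output may
still predict the other's almost perfectly.  This module implements the
four-part agreement suite used to characterise that relationship:

1. paired t-test on the per-sample differences,
2. Lin's concordance correlation coefficient (CCC),
3. ordinary least squares of Control on New with a 95% CI for the slope
   and the r² statistic,
4. Bland–Altman analysis (difference vs. pair mean, reference limits at
   ±2 SD and ±3 SD of the differences).

Convention: series ``x`` is the "New" program, series ``y`` the "Control",
and every difference is Control − New.  CCC deliberately penalises both
imprecision and bias, so a pure constant-factor offset between programs
yields r² ≈ 1 with depressed CCC and a regression slope far from 1 — the
signature of coefficient-table disagreement rather than noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedSeries",
    "AgreementReport",
    "paired_t",
    "lins_ccc",
    "regress_control_on_new",
    "bland_altman",
    "agreement_report",
    "make_series",
]


@dataclass
class PairedSeries:
    """Paired RSS values from two programs; x = New, y = Control.

    Pairs where either member is missing (NaN) are dropped and counted in
    ``n_dropped``.
    """

    x: np.ndarray
    y: np.ndarray
    ids: list[str] = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not self.ids:
            self.ids = [str(i) for i in range(len(x))]
        elif len(self.ids) != len(x):
            raise ValueError("ids length must match series length")
        keep = np.isfinite(x) & np.isfinite(y)
        self.n_dropped += int(np.sum(~keep))
        self.x = x[keep]
        self.y = y[keep]
        self.ids = [i for i, k in zip(self.ids, keep) if k]

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass
class AgreementReport:
    """Bundle of the four agreement assessments plus per-series summaries."""

    n: int
    n_dropped: int
    summary_x: dict[str, float]
    summary_y: dict[str, float]
    mean_diff: float
    se_diff: float
    t_stat: float | None
    p_paired_t: float | None
    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    r2: float
    ccc: float
    ba: dict[str, object]
    diff_direction: str = "Control - New (y - x)"

    def to_dict(self) -> dict:
        d = {
            "diff_direction": self.diff_direction,
            "n": self.n,
            "n_dropped": self.n_dropped,
            "summary_new": self.summary_x,
            "summary_control": self.summary_y,
            "paired_t": {
                "mean_diff": self.mean_diff,
                "se": self.se_diff,
                "t": self.t_stat,
                "p": self.p_paired_t,
            },
            "regression": {
                "slope": self.slope,
                "intercept": self.intercept,
                "slope_ci95": list(self.slope_ci95),
                "r2": self.r2,
            },
            "ccc": self.ccc,
            "bland_altman": {
                "mean_diff": self.ba["mean_diff"],
                "sd_diff": self.ba["sd_diff"],
                "limits_2sd": list(self.ba["limits_2sd"]),
                "limits_3sd": list(self.ba["limits_3sd"]),
            },
        }
        return d


def _diffs(series: PairedSeries) -> np.ndarray:
    return series.y - series.x  # Control - New


def paired_t(series: PairedSeries) -> dict[str, float | None]:
    """Paired t-test on d = Control − New.

    Returns mean_diff, se (sample SD / sqrt(n)), t and two-sided p from the
    t distribution with n−1 df.  With zero-variance differences the t
    statistic is undefined and both t and p are returned as None — no
    fabricated p-value.
    """
    if series.n < 2:
        raise ValueError("paired t-test needs n >= 2 pairs")
    d = _diffs(series)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    se = sd / math.sqrt(series.n)
    if se == 0.0:
        return {"mean_diff": mean, "se": 0.0, "t": None, "p": None}
    t = mean / se
    p = 2.0 * float(stats.t.sf(abs(t), df=series.n - 1))
    return {"mean_diff": mean, "se": se, "t": t, "p": p}


def lins_ccc(series: PairedSeries, ddof: int = 0) -> float:
    """Lin's concordance correlation coefficient.

    rho_c = 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²), with moments using the 1/n
    (population) convention of the original estimator by default; pass
    ``ddof=1`` for the n−1 variant.  Undefined (ValueError) when both series
    are constant.
    """
    if series.n < 2:
        raise ValueError("CCC needs n >= 2 pairs")
    x, y = series.x, series.y
    sx2 = float(np.var(x, ddof=ddof))
    sy2 = float(np.var(y, ddof=ddof))
    mx, my = float(np.mean(x)), float(np.mean(y))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError("CCC undefined: both series constant and equal")
    sxy = float(np.mean((x - mx) * (y - my)))
    if ddof == 1:
        sxy *= series.n / (series.n - 1)
    return 2.0 * sxy / denom


def regress_control_on_new(series: PairedSeries) -> dict[str, object]:
    """OLS of Control (y) on New (x), with a 95% CI for the slope and r².

    The slope CI uses the t(0.975, n−2) quantile times the slope standard
    error; a CI containing 1 is read as agreement on scale.  r² is the
    proportion of Control variation explained by New.
    """
    if series.n < 3:
        raise ValueError("regression needs n >= 3 pairs")
    if float(np.var(series.x)) == 0.0:
        raise ValueError("regression undefined: New series has zero variance")
    fit = stats.linregress(series.x, series.y)
    tcrit = float(stats.t.ppf(0.975, df=series.n - 2))
    ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "slope_ci95": (float(ci[0]), float(ci[1])),
        "r2": float(fit.rvalue) ** 2,
    }


def bland_altman(series: PairedSeries) -> dict[str, object]:
    """Bland–Altman payload: pair means, differences, and reference limits.

    Differences are Control − New; limits are mean ± 2·SD and mean ± 3·SD of
    the differences (sample SD, literal multipliers).  Rendering is left to
    the caller; :func:`urisat.io.plot_bland_altman` draws the standard plot.
    """
    if series.n < 2:
        raise ValueError("Bland-Altman needs n >= 2 pairs")
    d = _diffs(series)
    m = (series.x + series.y) / 2.0
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return {
        "pair_means": m,
        "pair_diffs": d,
        "mean_diff": mean_diff,
        "sd_diff": sd,
        "limits_2sd": (mean_diff - 2.0 * sd, mean_diff + 2.0 * sd),
        "limits_3sd": (mean_diff - 3.0 * sd, mean_diff + 3.0 * sd),
    }


def _summary(v: np.ndarray) -> dict[str, float]:
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return {
        "mean": mean,
        "sd": sd,
        "cv_pct": 100.0 * sd / mean if mean != 0 else math.nan,
        "min": float(np.min(v)),
        "median": float(np.median(v)),
        "max": float(np.max(v)),
    }


def agreement_report(series: PairedSeries) -> AgreementReport:
    """Run all four assessments and the per-series summary table."""
    t = paired_t(series)
    reg = regress_control_on_new(series)
    ba = bland_altman(series)
    ccc = lins_ccc(series)
    return AgreementReport(
        n=series.n,
        n_dropped=series.n_dropped,
        summary_x=_summary(series.x),
        summary_y=_summary(series.y),
        mean_diff=t["mean_diff"],
        se_diff=t["se"],
        t_stat=t["t"],
        p_paired_t=t["p"],
        slope=reg["slope"],
        intercept=reg["intercept"],
        slope_ci95=reg["slope_ci95"],
        r2=reg["r2"],
        ccc=ccc,
        ba=ba,
    )


def make_series(
    x: Sequence[float], y: Sequence[float], ids: Sequence[str] | None = None
) -> PairedSeries:
    """Convenience constructor from any sequences."""
    return PairedSeries(
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        ids=list(ids) if ids is not None else [],
    )
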