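"""CSV / JSON input-output for panels, RSS results, and agreement reports.

File conventions (v1): comma-separated, period decimal, UTF-8, header
mandatory; all concentrations in mmol/L (a single unit system avoids the
classic silent mg/dL-vs-mmol/L unit bug in urine chemistry).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .compare import AgreementReport
from .rss import RSSResult
from .speciation import UrinePanel

__all__ = [
    "PANEL_COLUMNS",
    "read_panels",
    "write_panels",
    "write_rss",
    "read_rss_series",
    "write_agreement_json",
    "write_agreement_csv",
    "plot_scatter",
    "plot_bland_altman",
]

logger = logging.getLogger(__name__)

#: CSV column -> component id for panel files
PANEL_COLUMNS = {
    "ca": "Ca",
    "mg": "Mg",
    "na": "Na",
    "k": "K",
    "nh4": "NH4",
    "cl": "Cl",
    "so4": "SO4",
    "po4": "PO4",
    "oxalate": "Ox",
    "citrate": "Cit",
}
OPTIONAL_PANEL_COLUMNS = {
    "urate": "Ur",
    "pyrophosphate": "PyroP",
    "co2_total": "CO3",
}


def read_panels(path: str | Path) -> list[UrinePanel]:
    """Read urine panels from CSV.

    Required columns: ``sample_id``, ``ph`` and the ten measured analytes
    (see :data:`PANEL_COLUMNS`).  Missing optional columns default to zero
    with one summary warning; non-numeric or negative values raise with the
    offending row and column named.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in ["sample_id", "ph", *PANEL_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    absent_optional = [c for c in OPTIONAL_PANEL_COLUMNS if c not in df.columns]
    if absent_optional:
        logger.warning(
            "%s: optional columns %s absent; analytes default to 0",
            path,
            absent_optional,
        )
    numeric_cols = ["ph", *PANEL_COLUMNS, *(c for c in OPTIONAL_PANEL_COLUMNS if c in df.columns)]
    panels: list[UrinePanel] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        rec = row._asdict()
        totals: dict[str, float] = {}
        for col in numeric_cols:
            try:
                val = float(rec[col])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: row {row_no}, column {col!r}: non-numeric value {rec[col]!r}"
                ) from None
            if not np.isfinite(val):
                raise ValueError(f"{path}: row {row_no}, column {col!r}: non-finite value")
            if col != "ph":
                if val < 0:
                    raise ValueError(
                        f"{path}: row {row_no}, column {col!r}: negative concentration {val}"
                    )
                comp = PANEL_COLUMNS.get(col) or OPTIONAL_PANEL_COLUMNS[col]
                totals[comp] = val
        for col, comp in OPTIONAL_PANEL_COLUMNS.items():
            totals.setdefault(comp, 0.0)
        panels.append(UrinePanel(sample_id=str(rec["sample_id"]), ph=float(rec["ph"]), totals=totals))
    return panels


def write_panels(panels: Sequence[UrinePanel], path: str | Path) -> Path:
    """Write panels to the standard CSV schema (input order preserved)."""
    rows = []
    for p in panels:
        row = {"sample_id": p.sample_id, "ph": p.ph}
        for col, comp in {**PANEL_COLUMNS, **OPTIONAL_PANEL_COLUMNS}.items():
            row[col] = p.totals.get(comp, 0.0)
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_rss(results: Iterable[RSSResult], path: str | Path) -> Path:
    """Write RSS results to CSV, one row per sample, input order preserved."""
    rows = []
    for r in results:
        row = {"sample_id": r.sample_id}
        for sid, rec in r.salts.items():
            row[f"rss_{sid}"] = rec.rss
            row[f"iap_{sid}"] = rec.iap
        row["ionic_strength"] = r.speciation.ionic_strength
        row["converged"] = r.speciation.converged
        row["n_iter"] = r.speciation.n_iter
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_rss_series(path: str | Path, column: str) -> pd.Series:
    """Read one RSS column (indexed by sample_id) from a write_rss CSV."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if column not in df.columns:
        raise ValueError(f"{path}: no column {column!r}; found {list(df.columns)}")
    return df.set_index("sample_id")[column]


def write_agreement_json(report: AgreementReport, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    return path


def write_agreement_csv(report: AgreementReport, path: str | Path) -> Path:
    """Summary table: one statistic per row, New and Control columns."""
    d = report.to_dict()
    rows = [
        {"statistic": "N", "new": report.n, "control": report.n},
        *(
            {"statistic": k, "new": d["summary_new"][k], "control": d["summary_control"][k]}
            for k in ("mean", "sd", "cv_pct", "min", "median", "max")
        ),
        {"statistic": "difference (se)", "new": report.mean_diff, "control": report.se_diff},
        {"statistic": "p_paired_t", "new": report.p_paired_t, "control": ""},
        {"statistic": "slope", "new": report.slope, "control": ""},
        {"statistic": "slope_ci95_low", "new": report.slope_ci95[0], "control": ""},
        {"statistic": "slope_ci95_high", "new": report.slope_ci95[1], "control": ""},
        {"statistic": "r2", "new": report.r2, "control": ""},
        {"statistic": "ccc", "new": report.ccc, "control": ""},
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def plot_scatter(report: AgreementReport, series, path: str | Path) -> Path:
    """Scatter of Control vs New with best-fit and 1:1 lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(series.x, series.y, s=10, alpha=0.6)
    lo = float(min(series.x.min(), series.y.min()))
    hi = float(max(series.x.max(), series.y.max()))
    grid = np.linspace(lo, hi, 50)
    ax.plot(grid, report.intercept + report.slope * grid, "r-", label=f"fit (slope {report.slope:.3f})")
    ax.plot(grid, grid, "k-", lw=1, label="1:1")
    ax.set_xlabel("New program RSS")
    ax.set_ylabel("Control program RSS")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_bland_altman(report: AgreementReport, path: str | Path) -> Path:
    """Difference-vs-mean plot with ±2 SD (red dashed) and ±3 SD (green) lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = report.ba
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ba["pair_means"], ba["pair_diffs"], s=10, alpha=0.6)
    ax.axhline(ba["mean_diff"], color="red")
    for lim in ba["limits_2sd"]:
        ax.axhline(lim, color="red", linestyle="--")
    for lim in ba["limits_3sd"]:
        ax.axhline(lim, color="green")
    ax.set_xlabel("Mean of the two programs")
    ax.set_ylabel("Difference (Control − New)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
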