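"""Group-level summaries and derived statistics for ZAPPED cohorts.

A *cohort table* is a tidy DataFrame with one row per subject x tissue and
columns ``subject_id, age, sex, tissue, f_free, f_restricted, t2_free_us,
t2_restricted_us, nrmsd``.  This module computes tissue means/SDs, the
WM/GM restricted-fraction ratio, the ordinary-least-squares regression of a
parameter on age (with the classical t-test p-value on the slope), and the
predicted-fraction ratio between two ages — the summary quantities used to
characterize healthy gray and white matter and their change with aging.

Internal values stay at full precision; rounding to reporting precision
(fractions to 2 decimals, T2 to 3 significant figures) happens only in
:func:`round_for_report` and :func:`report`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fitting import FitConfig, fit_roi_mean
from .sampling import OffsetSchedule, default_schedule

__all__ = [
    "PARAM_COLUMNS",
    "RegressionResult",
    "summarize_tissue",
    "fraction_ratio",
    "age_regression",
    "regression_age_ratio",
    "round_for_report",
    "build_cohort_table",
    "report",
]

PARAM_COLUMNS = ("f_free", "t2_free_us", "f_restricted", "t2_restricted_us")


@dataclass(frozen=True)
class RegressionResult:
    """OLS regression of a cohort parameter on age."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    stderr: float = float("nan")

    def predict(self, age: float) -> float:
        return self.intercept + self.slope * age


def summarize_tissue(table: pd.DataFrame, tissue: str) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) of each parameter for a tissue.

    Returns a two-row DataFrame indexed ``mean``/``sd`` with the parameter
    columns present in the table, at full precision.
    """
    rows = table[table["tissue"] == tissue]
    if len(rows) < 2:
        raise ValueError(f"need at least 2 rows for tissue {tissue!r}, got {len(rows)}")
    cols = [c for c in PARAM_COLUMNS if c in table.columns]
    return pd.DataFrame(
        {c: [rows[c].mean(), rows[c].std(ddof=1)] for c in cols},
        index=["mean", "sd"],
    )


def fraction_ratio(table: pd.DataFrame, tissue_num: str, tissue_den: str) -> float:
    """Ratio of mean restricted fractions, e.g. WM over GM.

    Invariant to rescaling all F_r by a common positive constant; returned at
    full precision (round to 2 decimals for reporting).
    """
    num = summarize_tissue(table, tissue_num).loc["mean", "f_restricted"]
    den = summarize_tissue(table, tissue_den).loc["mean", "f_restricted"]
    if den == 0:
        raise ZeroDivisionError("denominator tissue has zero mean restricted fraction")
    return float(num / den)


def age_regression(
    table: pd.DataFrame, tissue: str, parameter: str = "f_restricted"
) -> RegressionResult:
    """OLS regression of ``parameter`` on age for one tissue.

    The slope p-value is the two-sided classical t test with n-2 degrees of
    freedom.
    """
    rows = table[table["tissue"] == tissue]
    ages = rows["age"].to_numpy(dtype=float)
    vals = rows[parameter].to_numpy(dtype=float)
    if len(rows) < 3 or np.unique(ages).size < 2:
        raise ValueError("need >= 3 rows with distinct ages")
    res = sps.linregress(ages, vals)
    r2 = float(res.rvalue**2)
    pv = float(res.pvalue)
    if np.isnan(r2):  # constant response: no age dependence at all
        r2, pv = 0.0, 1.0
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_value=pv,
        n=len(rows),
        stderr=float(res.stderr),
    )


def regression_age_ratio(
    r: RegressionResult, age_hi: float, age_lo: float
) -> float:
    """Ratio of regression-predicted values at two ages, hi over lo.

    Quantifies the relative parameter decline over an age span, e.g. WM F_r
    at 70 versus 35.
    """
    hi, lo = r.predict(age_hi), r.predict(age_lo)
    if hi <= 0 or lo <= 0:
        raise ValueError("regression predicts a non-positive value; ratio undefined")
    return float(hi / lo)


def _round_sig(x: float, sig: int) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return float(np.round(x, sig - 1 - int(np.floor(np.log10(abs(x))))))


def round_for_report(summary: pd.DataFrame) -> pd.DataFrame:
    """Apply reporting precision: fractions 2 dp, T2 values 3 sig figs."""
    out = summary.copy()
    for c in out.columns:
        if c.startswith("f_"):
            out[c] = out[c].round(2)
        else:
            out[c] = out[c].map(lambda v: _round_sig(v, 3))
    return out


def build_cohort_table(
    subjects,
    schedule: OffsetSchedule | None = None,
    tissues: dict[str, int] | None = None,
    config: FitConfig | None = None,
    reference: str = "separate",
) -> pd.DataFrame:
    """Fit tissue-mean spectra of each synthetic subject into a cohort table.

    Uses the segment-then-average approach: the per-tissue mean signal is
    normalized and fitted once per subject.  ``reference="separate"`` uses
    each phantom's unsaturated baseline volume as normalization reference;
    ``"outermost"`` uses the mean of the two outermost-offset volumes.
    """
    schedule = schedule or default_schedule()
    tissues = tissues or {"GM": 1, "WM": 2}
    records = []
    for sub in subjects:
        for tissue, label in tissues.items():
            ref = sub.truth["s0"] if reference == "separate" else "outermost"
            fit = fit_roi_mean(
                sub.stack, schedule, sub.labels, label, config=config, reference=ref
            )
            p = fit.params
            records.append(
                {
                    "subject_id": sub.subject_id,
                    "age": sub.age,
                    "sex": sub.sex,
                    "tissue": tissue,
                    "f_free": p.f_free,
                    "f_restricted": p.f_restricted,
                    "t2_free_us": p.t2_free_us,
                    "t2_restricted_us": p.t2_restricted_us,
                    "nrmsd": fit.nrmsd,
                }
            )
    return pd.DataFrame.from_records(records)


def report(
    table: pd.DataFrame,
    out_dir: str | Path | None = None,
    ratio_tissues: tuple[str, str] = ("WM", "GM"),
    regression_tissue: str = "WM",
    ratio_ages: tuple[float, float] = (70.0, 35.0),
) -> dict:
    """Assemble the standard cohort report.

    Per tissue: a per-subject table with appended Mean and SD rows (reporting
    precision).  Plus the restricted-fraction ratio between two tissues and
    the age regression of WM F_r with its predicted ratio between two ages.
    Tissues with fewer than 2 rows are omitted with a warning field.

    If ``out_dir`` is given, writes ``cohort_<tissue>.csv`` per tissue and a
    ``summary.json``; always returns the report dict.
    """
    if table.empty:
        raise ValueError("empty cohort table")
    out: dict = {"tissues": {}, "skipped": []}
    frames: dict[str, pd.DataFrame] = {}
    for tissue in table["tissue"].unique():
        rows = table[table["tissue"] == tissue]
        if len(rows) < 2:
            out["skipped"].append(str(tissue))
            continue
        summ = summarize_tissue(table, tissue)
        out["tissues"][tissue] = round_for_report(summ).to_dict()
        cols = ["subject_id", "age", "sex"] + [
            c for c in PARAM_COLUMNS if c in rows.columns
        ]
        body = rows[cols].reset_index(drop=True)
        extra = round_for_report(summ).reset_index(names="subject_id")
        extra["subject_id"] = ["Mean", "SD"]
        frames[tissue] = pd.concat([body, extra], ignore_index=True)
    num, den = ratio_tissues
    if num in out["tissues"] and den in out["tissues"]:
        out["fraction_ratio"] = {
            "tissues": [num, den],
            "value": round(fraction_ratio(table, num, den), 2),
        }
    if regression_tissue in out["tissues"]:
        reg = age_regression(table, regression_tissue, "f_restricted")
        out["age_regression"] = asdict(reg)
        out["age_regression"]["tissue"] = regression_tissue
        out["regression_age_ratio"] = {
            "ages": list(ratio_ages),
            "value": round(regression_age_ratio(reg, *ratio_ages), 2),
        }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for tissue, frame in frames.items():
            frame.to_csv(out_dir / f"cohort_{tissue}.csv", index=False)
        (out_dir / "summary.json").write_text(json.dumps(out, indent=2))
    return out
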