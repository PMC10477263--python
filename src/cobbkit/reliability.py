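"""Reliability statistics for Cobb-angle measurements.

Single-measures intraclass correlation coefficients from the two-way
ANOVA decomposition of an n-subjects x k-raters matrix (Shrout & Fleiss
notation):

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE)

with MSR the between-subject, MSC the between-rater and MSE the residual
mean square.  ICC(2,1) is the two-way random-effects absolute-agreement
model, ICC(3,1) the two-way mixed consistency model.  95% confidence
intervals use the F-based Shrout–Fleiss procedure; qualitative grades
follow the convention < 0.70 poor, 0.70–0.79 fair, 0.80–0.89 good,
0.90–0.99 excellent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_BANDS = ((0.0, 20.0), (20.0, 40.0), (40.0, np.inf))
RANKS = ("major", "minor1", "minor2")


@dataclass
class RatingsMatrix:
    """n_subjects x k_raters Cobb angles (degrees), no missing cells."""

    values: np.ndarray
    subject_ids: Optional[list] = None
    rater_ids: Optional[list] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2-D subjects x raters array")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError(f"need >= 2 subjects and >= 2 raters, got {n} x {k}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ratings contain missing or non-finite cells")
        if self.subject_ids is None:
            self.subject_ids = list(range(n))
        if self.rater_ids is None:
            self.rater_ids = list(range(k))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    model: str  # "ICC_2_1" or "ICC_3_1"
    grade: str
    n_subjects: int
    k_raters: int


def grade_icc(icc: float) -> str:
    if icc < 0.70:
        return "poor"
    if icc < 0.80:
        return "fair"
    if icc < 0.90:
        return "good"
    return "excellent"


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way subjects x raters decomposition."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc(matrix: RatingsMatrix, model: str = "ICC_2_1", alpha: float = 0.05) -> ICCResult:
    """Single-measures ICC with a Shrout–Fleiss 95% confidence interval."""
    x = matrix.values
    n, k = x.shape
    msr, msc, mse = _anova_mean_squares(x)
    if msr <= 0 or np.isclose(msr, 0):
        raise ValueError("zero between-subject variance: ICC undefined")

    if model == "ICC_3_1":
        est = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0:  # perfect consistency
            lo = hi = 1.0
        else:
            f_obs = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    elif model == "ICC_2_1":
        est = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        a = k * est / (n * (1 - est)) if est < 1 else np.inf
        b = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else np.inf
        if np.isfinite(a):
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
        else:
            lo = hi = 1.0
    else:
        raise ValueError(f"model must be 'ICC_2_1' or 'ICC_3_1', got {model!r}")

    lo = min(lo, est)
    hi = max(hi, est)
    return ICCResult(
        estimate=float(est),
        ci_low=float(lo),
        ci_high=float(hi),
        model=model,
        grade=grade_icc(float(est)),
        n_subjects=n,
        k_raters=k,
    )


@dataclass
class BandErrorRow:
    band: tuple[float, float]  # half-open [low, high)
    mean_diff: float
    ci_low: float
    ci_high: float
    n: int
    degenerate: bool = False


def band_errors(
    ai: Sequence[float],
    reference: Sequence[float],
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
    alpha: float = 0.05,
) -> list[BandErrorRow]:
    """Mean (AI - reference) per reference-angle band with t-based 95% CIs.

    Subjects are banded by the reference value (half-open intervals).
    Empty bands yield n=0 rows with NaN statistics; zero-variance bands
    are flagged degenerate (their CI collapses to the mean).
    """
    ai = np.asarray(ai, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if ai.shape != reference.shape:
        raise ValueError("ai and reference vectors must have equal length")
    rows = []
    for low, high in bands:
        sel = (reference >= low) & (reference < high)
        d = ai[sel] - reference[sel]
        if d.size == 0:
            rows.append(BandErrorRow((low, high), np.nan, np.nan, np.nan, 0, degenerate=True))
            continue
        m = float(d.mean())
        sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
        if d.size > 1 and sd > 0:
            half = stats.t.ppf(1 - alpha / 2, d.size - 1) * sd / np.sqrt(d.size)
            rows.append(BandErrorRow((low, high), m, m - half, m + half, int(d.size)))
        else:
            rows.append(BandErrorRow((low, high), m, m, m, int(d.size), degenerate=True))
    return rows


def ratings_from_long(df: pd.DataFrame, value_col: str = "cobb_angle") -> RatingsMatrix:
    """Pivot a long (subject_id, rater_id, value) table into a RatingsMatrix.

    Subjects with any missing rater are dropped (listwise deletion).
    """
    wide = df.pivot_table(index="subject_id", columns="rater_id", values=value_col)
    complete = wide.dropna()
    return RatingsMatrix(
        complete.to_numpy(), list(complete.index), list(complete.columns)
    )


def evaluate_run(
    ai_angles: pd.DataFrame,
    rater_angles: pd.DataFrame,
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
) -> dict:
    """Full reliability report comparing AI output against rater measurements.

    Both inputs are long tables with columns (subject_id, rank, cobb_angle)
    plus rater_id and optionally posture for the raters.  Curves are
    matched by rank label.  Per posture and rank the report contains the
    rater-only ICC(2,1), the raters-plus-AI ICC(3,1), mean +/- SD angle
    summaries and, pooled over ranks, the band-error table against the
    rater mean.  Subjects missing a rank on either side are excluded from
    that rank's tables, with the exclusion count logged in the report.
    """
    required_ai = {"subject_id", "rank", "cobb_angle"}
    required_rater = required_ai | {"rater_id"}
    if not required_ai.issubset(ai_angles.columns):
        raise ValueError(f"AI table needs columns {sorted(required_ai)}")
    if not required_rater.issubset(rater_angles.columns):
        raise ValueError(f"rater table needs columns {sorted(required_rater)}")

    common = set(ai_angles.subject_id) & set(rater_angles.subject_id)
    if not common:
        raise ValueError(
            "no common subjects between AI and rater tables: "
            f"AI-only={sorted(set(ai_angles.subject_id) - set(rater_angles.subject_id))[:5]}, "
            f"rater-only={sorted(set(rater_angles.subject_id) - set(ai_angles.subject_id))[:5]}"
        )

    if "posture" not in rater_angles.columns:
        rater_angles = rater_angles.assign(posture="all")
    postures = sorted(rater_angles.posture.unique())

    report: dict = {"postures": {}, "excluded": {}, "band_errors": None}
    all_ai, all_ref = [], []
    for posture in postures:
        sub = rater_angles[rater_angles.posture == posture]
        posture_report = {"ranks": {}, "n_subjects": int(sub.subject_id.nunique())}
        for rank in RANKS:
            r_sub = sub[sub["rank"] == rank]
            a_sub = ai_angles[ai_angles["rank"] == rank].set_index("subject_id")
            if r_sub.empty:
                continue
            wide = r_sub.pivot_table(index="subject_id", columns="rater_id", values="cobb_angle")
            wide = wide.dropna()
            keep = [s for s in wide.index if s in a_sub.index]
            excluded = int(len(set(sub.subject_id)) - len(keep))
            report["excluded"][f"{posture}/{rank}"] = excluded
            if len(keep) < 2:
                continue
            wide = wide.loc[keep]
            ai_vals = a_sub.loc[keep, "cobb_angle"].to_numpy(dtype=float)
            rater_vals = wide.to_numpy(dtype=float)
            ref = rater_vals.mean(axis=1)
            entry = {
                "n": len(keep),
                "manual_mean": float(ref.mean()),
                "manual_sd": float(ref.std(ddof=1)) if len(keep) > 1 else 0.0,
                "ai_mean": float(ai_vals.mean()),
                "ai_sd": float(ai_vals.std(ddof=1)) if len(keep) > 1 else 0.0,
                "mean_abs_diff": float(np.abs(ai_vals - ref).mean()),
                "mean_diff": float((ai_vals - ref).mean()),
            }
            try:
                entry["icc_raters_2_1"] = icc(RatingsMatrix(rater_vals), "ICC_2_1").__dict__
                with_ai = np.column_stack([rater_vals, ai_vals])
                entry["icc_with_ai_3_1"] = icc(RatingsMatrix(with_ai), "ICC_3_1").__dict__
            except ValueError as exc:
                entry["icc_error"] = str(exc)
            posture_report["ranks"][rank] = entry
            all_ai.append(ai_vals)
            all_ref.append(ref)
        report["postures"][posture] = posture_report

    if all_ai:
        report["band_errors"] = [
            row.__dict__ for row in band_errors(np.concatenate(all_ai), np.concatenate(all_ref), bands)
        ]
    return report
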