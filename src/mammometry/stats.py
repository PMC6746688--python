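"""Accuracy, reliability and agreement statistics for repeated measurements.

The battery mirrors standard practice for validating an indirect
measurement tool against direct anthropometry:

* accuracy — mean absolute difference (MAD) against reference values and
  the SD of the signed differences;
* relative reliability — intraclass correlation coefficients from the
  two-way ANOVA mean squares, with exact F-based 95% confidence intervals
  (McGraw & Wong conventions: ICC(2,1) absolute agreement by default,
  ICC(3,1) consistency as an option);
* absolute reliability — standard error of measurement SEM = SD*sqrt(1-ICC)
  and per-subject coefficients of variation;
* agreement — Bland–Altman bias and 1.96*SD limits;
* interpretation — Cicchetti bands and the >0.87 "clinical measures" band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateDataError,
    IncompleteDesignError,
    InvalidParameterError,
    MissingReferenceError,
)

__all__ = [
    "RepeatedMeasuresTable",
    "IccResult",
    "BlandAltmanResult",
    "AgreementSummary",
    "accuracy_summary",
    "icc",
    "sem",
    "cv_percent",
    "bland_altman",
    "effectiveness",
    "classify_icc",
    "icc_variance",
    "summary_tables",
]

ICC_MODELS = ("two-way-random-absolute", "two-way-mixed-consistency")

STUDY_COLUMNS = ["subject_id", "observer_id", "session", "measurement", "value_cm"]


class RepeatedMeasuresTable:
    """Long-format subject x observer x session x measurement records.

    Optionally carries direct-measurement reference values per
    (subject, measurement).  The (subject, observer, session, measurement)
    key must be unique and all values finite.
    """

    def __init__(self, data: pd.DataFrame, reference: Optional[pd.DataFrame] = None):
        missing = [c for c in STUDY_COLUMNS if c not in data.columns]
        if missing:
            raise InvalidParameterError(f"study table lacks column(s) {missing}")
        data = data.loc[:, STUDY_COLUMNS].copy()
        if not np.isfinite(data["value_cm"].to_numpy(dtype=float)).all():
            raise InvalidParameterError("study table contains non-finite values")
        key = ["subject_id", "observer_id", "session", "measurement"]
        if data.duplicated(subset=key).any():
            dupes = data[data.duplicated(subset=key)].head(3)
            raise InvalidParameterError(f"duplicate design keys, e.g.\n{dupes}")
        self.data = data.reset_index(drop=True)
        if reference is not None:
            ref_cols = ["subject_id", "measurement", "reference_cm"]
            missing = [c for c in ref_cols if c not in reference.columns]
            if missing:
                raise InvalidParameterError(f"reference table lacks column(s) {missing}")
            reference = reference.loc[:, ref_cols].copy()
            if reference.duplicated(subset=["subject_id", "measurement"]).any():
                raise InvalidParameterError("duplicate reference keys")
            reference = reference.reset_index(drop=True)
        self.reference = reference

    # -- construction / serialisation ------------------------------------

    @classmethod
    def from_csv(cls, path) -> "RepeatedMeasuresTable":
        """Read the long study CSV; a ``reference_cm`` column, if present,
        is split off into the reference table."""
        df = pd.read_csv(path)
        reference = None
        if "reference_cm" in df.columns:
            reference = (
                df.dropna(subset=["reference_cm"])
                .drop_duplicates(subset=["subject_id", "measurement"])
                .loc[:, ["subject_id", "measurement", "reference_cm"]]
            )
        return cls(df, reference)

    def to_csv(self, path) -> None:
        df = self.data
        if self.reference is not None:
            df = df.merge(self.reference, on=["subject_id", "measurement"], how="left")
        df.to_csv(path, index=False)

    # -- views ------------------------------------------------------------

    @property
    def measurements(self) -> Tuple[str, ...]:
        return tuple(pd.unique(self.data["measurement"]))

    @property
    def observers(self) -> Tuple[str, ...]:
        return tuple(pd.unique(self.data["observer_id"]))

    def pivot(
        self,
        measurement: str,
        observer: Optional[str] = None,
        columns: str = "session",
        aggregate_sessions: bool = False,
    ) -> pd.DataFrame:
        """Subjects-by-repeats wide matrix for one measurement.

        ``columns="session"`` (within one observer) gives the precision
        layout; ``columns="observer_id"`` with ``aggregate_sessions=True``
        averages sessions first and gives the inter-rater layout.
        """
        df = self.data[self.data["measurement"] == measurement]
        if observer is not None:
            df = df[df["observer_id"] == observer]
        if aggregate_sessions:
            df = df.groupby(["subject_id", columns], as_index=False)["value_cm"].mean()
        wide = df.pivot_table(
            index="subject_id", columns=columns, values="value_cm", aggfunc="first"
        )
        if wide.isna().any().any():
            raise IncompleteDesignError(
                f"incomplete design for measurement {measurement!r}"
                + (f", observer {observer!r}" if observer else "")
            )
        return wide


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str
    n_subjects: int
    n_raters: int

    def __iter__(self):
        return iter((self.icc, self.ci_low, self.ci_high))


def _anova_mean_squares(matrix: np.ndarray) -> Tuple[float, float, float, int, int]:
    """Two-way single-score ANOVA mean squares of an n x k complete matrix.

    Returns (MSR rows/subjects, MSC columns/raters, MSE residual, n, k).
    """
    y = np.asarray(matrix, dtype=float)
    if y.ndim != 2:
        raise InvalidParameterError("expected a 2-D subjects-by-raters matrix")
    if np.isnan(y).any():
        raise IncompleteDesignError("design matrix contains missing cells")
    n, k = y.shape
    if n < 2 or k < 2:
        raise IncompleteDesignError(f"need >=2 subjects and >=2 repeats, got {n}x{k}")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_total == 0.0:
        raise DegenerateDataError("data carry zero total variance; ICC undefined")
    return msr, msc, mse, n, k


def icc(
    matrix,
    model: str = "two-way-random-absolute",
    confidence: float = 0.95,
) -> IccResult:
    """Single-measurement intraclass correlation with exact F-based CI.

    ``matrix`` is an n-subjects x k-repeats array (sessions or raters as
    columns; complete design).  Models:

    * ``"two-way-random-absolute"`` — ICC(A,1) = ICC(2,1): raters are a
      random sample, absolute agreement.  CI via the Satterthwaite
      approximation of McGraw & Wong (1996).
    * ``"two-way-mixed-consistency"`` — ICC(C,1) = ICC(3,1): raters fixed,
      consistency of ranking.  Exact F CI.
    """
    if model not in ICC_MODELS:
        raise InvalidParameterError(f"unknown ICC model {model!r}; choose from {ICC_MODELS}")
    if not 0 < confidence < 1:
        raise InvalidParameterError("confidence must be in (0, 1)")
    if isinstance(matrix, pd.DataFrame):
        matrix = matrix.to_numpy()
    msr, msc, mse, n, k = _anova_mean_squares(matrix)
    alpha = 1.0 - confidence

    if model == "two-way-mixed-consistency":
        value = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0.0:
            return IccResult(1.0, 1.0, 1.0, model, n, k)
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
        low = (fl - 1) / (fl + k - 1)
        high = (fu - 1) / (fu + k - 1)
        return IccResult(value, low, high, model, n, k)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        raise DegenerateDataError("zero denominator in ICC(2,1)")
    value = (msr - mse) / denom
    if mse == 0.0 and msc == 0.0:
        return IccResult(1.0, 1.0, 1.0, model, n, k)
    # Satterthwaite df for the rater+error composite (McGraw & Wong 1996).
    a = (k * value) / (n * (1 - value)) if value < 1 else float("inf")
    b = 1 + (k * value * (n - 1)) / (n * (1 - value)) if value < 1 else float("inf")
    if math.isinf(a):
        low = high = 1.0
    else:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_star_low = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_star_high = sps.f.ppf(1 - alpha / 2, v, n - 1)
        low = (
            n * (msr - f_star_low * mse)
            / (f_star_low * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        high = (
            n * (f_star_high * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f_star_high * msr)
        )
    return IccResult(value, low, high, model, n, k)


def sem(sd_cm: float, icc_value: float) -> float:
    """Standard error of measurement: SD * sqrt(1 - ICC), same units as SD."""
    if sd_cm < 0 or not math.isfinite(sd_cm):
        raise InvalidParameterError(f"sd must be finite and >= 0, got {sd_cm}")
    if icc_value > 1 or not math.isfinite(icc_value):
        raise InvalidParameterError(f"icc must be <= 1, got {icc_value}")
    return sd_cm * math.sqrt(1.0 - icc_value)


def cv_percent(matrix, method: str = "mean-subject") -> float:
    """Coefficient of variation of repeated values, in percent.

    Default: per-subject CV (sample SD over mean of that subject's
    repeated values) averaged across subjects.  ``method="pooled"``
    instead pools all within-subject SDs against the grand mean.
    """
    if isinstance(matrix, pd.DataFrame):
        matrix = matrix.to_numpy()
    y = np.asarray(matrix, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise InvalidParameterError("expected a subjects-by-repeats matrix with >=2 repeats")
    means = y.mean(axis=1)
    if np.any(means == 0):
        bad = int(np.flatnonzero(means == 0)[0])
        raise DegenerateDataError(f"zero mean for subject index {bad}; CV undefined")
    sds = y.std(axis=1, ddof=1)
    if method == "mean-subject":
        return float(np.mean(100.0 * sds / np.abs(means)))
    if method == "pooled":
        return float(100.0 * math.sqrt(float(np.mean(sds**2))) / abs(float(means.mean())))
    raise InvalidParameterError(f"unknown CV method {method!r}")


@dataclass
class BlandAltmanResult:
    """Paired-difference agreement summary with 1.96*SD limits."""

    differences: np.ndarray
    means: np.ndarray
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float

    def proportion_within_limits(self) -> float:
        inside = (self.differences >= self.loa_low) & (self.differences <= self.loa_high)
        return float(np.mean(inside))

    def plot(self, ax=None, title: Optional[str] = None):
        """Scatter of differences vs pair means with bias and limit lines."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(self.means, self.differences, s=12, alpha=0.6, edgecolors="none")
        ax.axhline(self.bias, color="k", lw=1)
        for limit in (self.loa_low, self.loa_high):
            ax.axhline(limit, color="r", lw=1, ls="--")
        ax.set_xlabel("mean of paired measurements (cm)")
        ax.set_ylabel("difference, digital - reference (cm)")
        if title:
            ax.set_title(title)
        return ax


def bland_altman(reference: Sequence[float], digital: Sequence[float]) -> BlandAltmanResult:
    """Agreement between reference values and (session-averaged) digital values.

    Differences are digital minus reference, plotted against pair means;
    limits of agreement are bias +/- 1.96 * SD of the differences.
    """
    ref = np.asarray(reference, dtype=float)
    dig = np.asarray(digital, dtype=float)
    if ref.shape != dig.shape or ref.ndim != 1:
        raise InvalidParameterError("reference and digital must be 1-D and the same length")
    if ref.size < 2:
        raise InvalidParameterError("need >= 2 pairs for Bland-Altman")
    diffs = dig - ref
    means = (dig + ref) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        differences=diffs,
        means=means,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


def effectiveness(mads_cm: Sequence[float], threshold_cm: float = 1.0) -> float:
    """Percentage of MAD values strictly below the accepted deviation threshold.

    The 1-cm default is the accepted deviation bound for the thoracic region.
    """
    if threshold_cm <= 0:
        raise InvalidParameterError("threshold must be positive")
    mads = np.asarray(list(mads_cm), dtype=float)
    if mads.size == 0:
        raise InvalidParameterError("empty MAD list")
    return float(100.0 * np.count_nonzero(mads < threshold_cm) / mads.size)


#: (lower bound inclusive, label) — Cicchetti interpretation bands.
_CICCHETTI_BANDS = ((0.75, "excellent"), (0.60, "good"), (0.40, "fair"), (-1.0, "poor"))
#: Clinically oriented bands; "clinical" requires ICC strictly above 0.87.
_CLINICAL_BANDS = ((0.87, "clinical"), (0.75, "good"), (-1.0, "poor-to-moderate"))


def classify_icc(icc_value: float) -> Tuple[str, str]:
    """Interpretation labels: (Cicchetti band, clinical band)."""
    if not -1.0 <= icc_value <= 1.0:
        raise InvalidParameterError(f"icc must be in [-1, 1], got {icc_value}")
    cicchetti = next(label for low, label in _CICCHETTI_BANDS if icc_value >= low)
    if icc_value > 0.87:
        clinical = "clinical"
    elif icc_value >= 0.75:
        clinical = "good"
    else:
        clinical = "poor-to-moderate"
    return cicchetti, clinical


def icc_variance(iccs: Sequence[float]) -> float:
    """Sample variance (denominator n-1) of a list of ICC estimates."""
    values = np.asarray(list(iccs), dtype=float)
    if values.size < 2:
        raise InvalidParameterError("need >= 2 ICC values for a sample variance")
    return float(values.var(ddof=1))


def accuracy_summary(table: RepeatedMeasuresTable, sd_of: str = "signed") -> pd.DataFrame:
    """Per-(measurement, observer) MAD and SD of the digital-vs-reference differences.

    Differences d = digital - reference over all (subject, session)
    records.  ``mad_cm`` is mean(|d|).  ``sd_cm`` defaults to the sample SD
    of the signed differences; ``sd_of="absolute"`` uses SD of |d| instead
    (published validation tables are ambiguous on this point).
    """
    if sd_of not in ("signed", "absolute"):
        raise InvalidParameterError(f"sd_of must be 'signed' or 'absolute', got {sd_of!r}")
    if table.reference is None:
        raise MissingReferenceError("accuracy requires direct-measurement reference values")
    merged = table.data.merge(table.reference, on=["subject_id", "measurement"], how="left")
    missing = merged[merged["reference_cm"].isna()]
    if not missing.empty:
        row = missing.iloc[0]
        raise MissingReferenceError(
            f"no reference for subject {row['subject_id']!r}, "
            f"measurement {row['measurement']!r}"
        )
    merged["d"] = merged["value_cm"] - merged["reference_cm"]
    if sd_of == "absolute":
        merged["d_for_sd"] = merged["d"].abs()
    else:
        merged["d_for_sd"] = merged["d"]
    out = (
        merged.groupby(["measurement", "observer_id"])
        .agg(mad_cm=("d", lambda d: float(np.abs(d).mean())),
             sd_cm=("d_for_sd", lambda d: float(np.std(d, ddof=1))))
        .reset_index()
    )
    return out


@dataclass
class AgreementSummary:
    """The validation battery's output tables.

    ``per_observer`` — one row per (measurement, observer): accuracy
    (mad_cm, sd_cm) and precision across sessions (icc + CI + sem_cm).
    ``inter_rater`` — one row per measurement: cv_percent across all
    repeats and the between-observer ICC (+ CI + sem_cm) computed on
    session-averaged values.
    """

    per_observer: pd.DataFrame
    inter_rater: pd.DataFrame

    def rounded(self) -> "AgreementSummary":
        """Display precision: cm to 2 decimals, ICC to 3, CV to 1."""
        per_obs = self.per_observer.copy()
        inter = self.inter_rater.copy()
        for col in ("mad_cm", "sd_cm", "sem_cm"):
            per_obs[col] = per_obs[col].round(2)
        for col in ("icc", "ci_low", "ci_high"):
            per_obs[col] = per_obs[col].round(3)
            inter[col] = inter[col].round(3)
        inter["sem_cm"] = inter["sem_cm"].round(2)
        inter["cv_percent"] = inter["cv_percent"].round(1)
        return AgreementSummary(per_observer=per_obs, inter_rater=inter)


def summary_tables(
    table: RepeatedMeasuresTable,
    icc_model: str = "two-way-random-absolute",
    sd_of: str = "signed",
    cv_method: str = "mean-subject",
) -> AgreementSummary:
    """Full validation battery for one subject group.

    Requires a complete design and reference values.  The per-observer
    SEM pairs the accuracy SD column with the precision ICC; the
    inter-rater SEM pairs the SD of the session-averaged values (pooled
    over observers) with the inter-rater ICC.
    """
    acc = accuracy_summary(table, sd_of=sd_of)
    acc = acc.set_index(["measurement", "observer_id"])

    per_rows = []
    for measurement in table.measurements:
        for observer in table.observers:
            wide = table.pivot(measurement, observer=observer, columns="session")
            r = icc(wide, model=icc_model)
            mad_cm, sd_cm = acc.loc[(measurement, observer)]
            per_rows.append(
                {
                    "measurement": measurement,
                    "observer_id": observer,
                    "mad_cm": mad_cm,
                    "sd_cm": sd_cm,
                    "icc": r.icc,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "sem_cm": sem(sd_cm, min(r.icc, 1.0)),
                }
            )

    inter_rows = []
    for measurement in table.measurements:
        all_repeats = table.pivot(measurement, columns=["observer_id", "session"])
        cv = cv_percent(all_repeats, method=cv_method)
        by_observer = table.pivot(
            measurement, columns="observer_id", aggregate_sessions=True
        )
        r = icc(by_observer, model=icc_model)
        sd_avg = float(np.std(by_observer.to_numpy().ravel(), ddof=1))
        inter_rows.append(
            {
                "measurement": measurement,
                "cv_percent": cv,
                "icc": r.icc,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "sem_cm": sem(sd_avg, min(r.icc, 1.0)),
            }
        )
    return AgreementSummary(
        per_observer=pd.DataFrame(per_rows),
        inter_rater=pd.DataFrame(inter_rows),
    )
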