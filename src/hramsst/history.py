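"""Longitudinal SST records and the drift / calibration statistics.

Replicate-level mass errors from every suitability check are persisted as
a long-format CSV (one row per compound per replicate injection).  On top
of that history this module provides:

* per-mass summaries for the first-k-replicates comparison (how many
  injections does a meaningful SST need),
* an ordinary-least-squares error model per mass with phase (before vs
  after the sample batch), batch length in injections, and their
  interaction as predictors — the interaction is the within-batch drift
  rate in ppm per injection,
* a calibration model of the absolute mass error on calibration type
  (CalMix vs CalMix+FlexMix), calibration quality (rms threshold 0.3
  ppm), days since calibration, and the days x quality interaction,
* a per-batch drift analysis (POST minus PRE mean error against batch
  length, stratified by calibration quality), and
* batch-length advisories (~100 injections / 33 h in general; drift can
  start near ~60 injections / 20 h under poor calibration).

Model fits go through statsmodels OLS; coefficients, standard errors, t
statistics and two-sided p-values are exposed as a plain table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "HISTORY_COLUMNS",
    "CAL_RMS_THRESHOLD",
    "MINUTES_PER_INJECTION",
    "SSTRecord",
    "History",
    "LinearFit",
    "HistorySummary",
    "load_history",
    "append_record",
    "summarize_history",
    "fit_error_model",
    "fit_calibration_model",
    "drift_analysis",
    "batch_length_advisor",
]

#: Long-format history schema: one row per compound per replicate injection.
HISTORY_COLUMNS = [
    "batch_id",
    "date",
    "polarity",
    "phase",
    "replicate",
    "n_batch_injections",
    "cal_type",
    "cal_rms_ppm",
    "days_since_cal",
    "compound",
    "error_ppm",
]

_KEY = ["batch_id", "phase", "polarity", "replicate", "compound"]

#: Calibration-quality threshold: rms ppm error of the calibrant masses at
#: or below this value counts as a good calibration.
CAL_RMS_THRESHOLD = 0.3

#: Display convention for converting injection counts to wall time.
MINUTES_PER_INJECTION = 20.0


@dataclass(frozen=True)
class SSTRecord:
    """One replicate injection's worth of panel errors plus batch covariates."""

    batch_id: str
    date: str  # ISO-8601
    polarity: str
    phase: str  # PRE | POST
    replicate: int
    n_batch_injections: int
    cal_type: str  # CALMIX | CALMIX_FLEXMIX
    cal_rms_ppm: float
    days_since_cal: float
    errors: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.n_batch_injections < 0:
            raise ValueError("n_batch_injections must be non-negative")
        if self.days_since_cal < 0:
            raise ValueError("days_since_cal must be non-negative")
        if self.cal_type not in ("CALMIX", "CALMIX_FLEXMIX"):
            raise ValueError(f"unknown cal_type {self.cal_type!r}")

    @property
    def batch_hours(self) -> float:
        return self.n_batch_injections * MINUTES_PER_INJECTION / 60.0

    @property
    def cal_quality_flag(self) -> str:
        return "GOOD" if self.cal_rms_ppm <= CAL_RMS_THRESHOLD else "POOR"

    def to_rows(self) -> pd.DataFrame:
        rows = [
            {
                "batch_id": self.batch_id,
                "date": self.date,
                "polarity": self.polarity,
                "phase": self.phase,
                "replicate": self.replicate,
                "n_batch_injections": self.n_batch_injections,
                "cal_type": self.cal_type,
                "cal_rms_ppm": self.cal_rms_ppm,
                "days_since_cal": self.days_since_cal,
                "compound": name,
                "error_ppm": err,
            }
            for name, err in self.errors.items()
        ]
        return pd.DataFrame(rows, columns=HISTORY_COLUMNS)


class History:
    """A validated long-format table of SST replicate errors."""

    schema_version = 1

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=HISTORY_COLUMNS)
        missing = set(HISTORY_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"history missing columns: {sorted(missing)}")
        df = df[HISTORY_COLUMNS].copy()
        if len(df):
            dup = df.duplicated(subset=_KEY)
            if dup.any():
                first = df.loc[dup.idxmax(), _KEY].tolist()
                raise ValueError(f"duplicate history key {first}")
            if (df["n_batch_injections"] < 0).any() or (df["days_since_cal"] < 0).any():
                raise ValueError("negative n_batch_injections or days_since_cal")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def with_derived(self) -> pd.DataFrame:
        """The table plus derived columns ``batch_hours`` and
        ``cal_quality_flag`` (GOOD iff cal rms <= 0.3 ppm)."""
        df = self.df.copy()
        df["batch_hours"] = df["n_batch_injections"] * MINUTES_PER_INJECTION / 60.0
        df["cal_quality_flag"] = np.where(
            df["cal_rms_ppm"] <= CAL_RMS_THRESHOLD, "GOOD", "POOR"
        )
        return df

    def save(self, path) -> None:
        self.df.to_csv(path, index=False)


def load_history(path) -> History:
    df = pd.read_csv(path)
    if not len(df) and set(df.columns) >= set(HISTORY_COLUMNS):
        return History(df)
    return History(df)


def append_record(history: History, record: SSTRecord) -> History:
    """Return a new History with the record's rows appended (uniqueness of
    the (batch, phase, polarity, replicate, compound) key enforced)."""
    new_rows = record.to_rows()
    if not len(history.df):
        return History(new_rows)
    combined = pd.concat([history.df, new_rows], ignore_index=True)
    return History(combined)


@dataclass(frozen=True)
class HistorySummary:
    """Per-mass means/sds for the first k replicates, plus the
    polarity-level aggregate (mean and sd across per-compound means)."""

    polarity: str
    k: int
    per_compound: pd.DataFrame  # columns: compound, n, mean_error, sd_error
    mean_of_means: float
    sd_of_means: float


def summarize_history(history: History, k_injections: int, polarity: str) -> HistorySummary:
    """Summarize per-compound errors using only the first ``k_injections``
    replicates (the k lowest replicate indices) per batch and phase."""
    if not 2 <= k_injections <= 5:
        raise ValueError("k_injections must be between 2 and 5")
    df = history.df
    df = df[df["polarity"] == polarity]
    if not len(df):
        raise ValueError(f"history contains no {polarity} records")
    ranked = df.copy()
    ranked["rep_rank"] = ranked.groupby(["batch_id", "phase"])["replicate"].rank(method="dense")
    kept = ranked[ranked["rep_rank"] <= k_injections]
    per = (
        kept.groupby("compound")["error_ppm"]
        .agg(n="count", mean_error="mean", sd_error=lambda s: s.std(ddof=1))
        .reset_index()
        .sort_values("compound", ignore_index=True)
    )
    means = per["mean_error"].to_numpy()
    return HistorySummary(
        polarity=polarity,
        k=k_injections,
        per_compound=per,
        mean_of_means=float(np.mean(means)),
        sd_of_means=float(np.std(means, ddof=1)) if len(means) > 1 else float("nan"),
    )


@dataclass(frozen=True)
class LinearFit:
    """OLS coefficient table with two-sided t-test p-values."""

    terms: tuple[str, ...]
    estimates: tuple[float, ...]
    standard_errors: tuple[float, ...]
    t_values: tuple[float, ...]
    p_values: tuple[float, ...]
    r_squared: float
    n_obs: int

    def coef(self, term: str) -> float:
        return self.estimates[self.terms.index(term)]

    def se(self, term: str) -> float:
        return self.standard_errors[self.terms.index(term)]

    def p(self, term: str) -> float:
        return self.p_values[self.terms.index(term)]

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        i = self.terms.index(term)
        dof = self.n_obs - len(self.terms)
        t_crit = float(stats.t.ppf(0.5 + level / 2.0, dof))
        return (
            self.estimates[i] - t_crit * self.standard_errors[i],
            self.estimates[i] + t_crit * self.standard_errors[i],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.estimates,
                "std_error": self.standard_errors,
                "t_value": self.t_values,
                "p_value": self.p_values,
            }
        )

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "estimates": list(self.estimates),
            "standard_errors": list(self.standard_errors),
            "t_values": list(self.t_values),
            "p_values": list(self.p_values),
            "r_squared": self.r_squared,
            "n_obs": self.n_obs,
        }

    def to_markdown(self) -> str:
        lines = [
            "| term | estimate | SE | t | p |",
            "| --- | ---: | ---: | ---: | ---: |",
        ]
        for t, e, s, tv, p in zip(
            self.terms, self.estimates, self.standard_errors, self.t_values, self.p_values
        ):
            lines.append(f"| {t} | {e:.4g} | {s:.4g} | {tv:.3f} | {p:.3g} |")
        lines.append(f"\nR² = {self.r_squared:.4f}, n = {self.n_obs}")
        return "\n".join(lines)


class RankDeficiencyError(ValueError):
    """Raised when the model design matrix is not full rank."""


def _ols(y: np.ndarray, X: pd.DataFrame) -> LinearFit:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        degenerate = [c for c in X.columns if c != "Intercept" and X[c].nunique() <= 1]
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"constant/collinear terms: {degenerate or list(X.columns)}"
        )
    model = sm.OLS(y, X)
    res = model.fit()
    return LinearFit(
        terms=tuple(X.columns),
        estimates=tuple(float(v) for v in res.params),
        standard_errors=tuple(float(v) for v in res.bse),
        t_values=tuple(float(v) for v in res.tvalues),
        p_values=tuple(float(v) for v in res.pvalues),
        r_squared=float(res.rsquared),
        n_obs=int(res.nobs),
    )


def error_model_design(df: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Response and design matrix of the per-mass error model:
    error ~ 1 + phase_post + n_injections + phase_post:n_injections."""
    phase_post = (df["phase"] == "POST").astype(float).to_numpy()
    n_inj = df["n_batch_injections"].astype(float).to_numpy()
    X = pd.DataFrame(
        {
            "Intercept": np.ones(len(df)),
            "phase_post": phase_post,
            "n_injections": n_inj,
            "phase_post:n_injections": phase_post * n_inj,
        }
    )
    return df["error_ppm"].to_numpy(dtype=float), X


def fit_error_model(
    history: History,
    compound: str,
    max_hours: float | None = None,
    polarity: str | None = None,
) -> LinearFit:
    """Per-mass OLS of the signed error on phase, batch length and their
    interaction.  ``max_hours`` restricts to batches shorter than that
    wall time (the short-batch stratification); requires >= 10 rows."""
    df = history.with_derived()
    df = df[df["compound"] == compound]
    if polarity is not None:
        df = df[df["polarity"] == polarity]
    if max_hours is not None:
        df = df[df["batch_hours"] < max_hours]
    if len(df) < 10:
        raise ValueError(f"need >= 10 observations for {compound!r}, have {len(df)}")
    y, X = error_model_design(df)
    return _ols(y, X)


def default_calibration_exclusion(df: pd.DataFrame, max_days: float = 7.0) -> pd.Series:
    """Rows to exclude from the calibration model: CalMix-only
    calibrations with a long interval since calibration (sparse stratum;
    the cutoff of 7 days is this package's default, logged in reports)."""
    return (df["cal_type"] == "CALMIX") & (df["days_since_cal"] > max_days)


def calibration_model_design(df: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Response (|error|) and design of the calibration model:
    |error| ~ 1 + calmix_only + poor_cal + days_since_cal + days:poor_cal."""
    calmix = (df["cal_type"] == "CALMIX").astype(float).to_numpy()
    poor = (df["cal_quality_flag"] == "POOR").astype(float).to_numpy()
    days = df["days_since_cal"].astype(float).to_numpy()
    X = pd.DataFrame(
        {
            "Intercept": np.ones(len(df)),
            "calmix_only": calmix,
            "poor_cal": poor,
            "days_since_cal": days,
            "days_since_cal:poor_cal": days * poor,
        }
    )
    return np.abs(df["error_ppm"].to_numpy(dtype=float)), X


def fit_calibration_model(
    history: History,
    exclusions: Callable[[pd.DataFrame], pd.Series] | None = default_calibration_exclusion,
    compound: str | None = None,
    polarity: str | None = None,
) -> LinearFit:
    """OLS of the absolute mass error on calibration covariates.

    ``exclusions`` maps the derived table to a boolean mask of rows to
    drop (default: CalMix-only calibrations older than 7 days).  Raises
    :class:`RankDeficiencyError` when a covariate never varies (e.g. a
    single calibration type in the data)."""
    df = history.with_derived()
    if compound is not None:
        df = df[df["compound"] == compound]
    if polarity is not None:
        df = df[df["polarity"] == polarity]
    if exclusions is not None:
        df = df[~exclusions(df)]
    if len(df) < 10:
        raise ValueError(f"need >= 10 observations after filtering, have {len(df)}")
    y, X = calibration_model_design(df)
    return _ols(y, X)


@dataclass(frozen=True)
class DriftTrend:
    stratum: str  # cal_quality_flag value
    n_batches: int
    slope_ppm_per_hour: float | None
    intercept_ppm: float | None
    p_value: float | None


def drift_analysis(history: History) -> tuple[pd.DataFrame, list[DriftTrend]]:
    """Per-batch drift: mean POST error minus mean PRE error, per polarity.

    Returns the per-batch table (batch_id, polarity, batch_hours,
    n_batch_injections, cal_quality_flag, delta_ppm) and, per
    calibration-quality stratum, a linear trend of delta against batch
    hours.  Batches missing either phase are skipped with a warning.
    """
    df = history.with_derived()
    rows = []
    for (batch_id, polarity), group in df.groupby(["batch_id", "polarity"], sort=True):
        phases = set(group["phase"])
        if {"PRE", "POST"} - phases:
            warnings.warn(
                f"batch {batch_id!r} ({polarity}) missing phase "
                f"{sorted({'PRE', 'POST'} - phases)}; skipped in drift analysis",
                stacklevel=2,
            )
            continue
        pre = group.loc[group["phase"] == "PRE", "error_ppm"].mean()
        post = group.loc[group["phase"] == "POST", "error_ppm"].mean()
        rows.append(
            {
                "batch_id": batch_id,
                "polarity": polarity,
                "batch_hours": float(group["batch_hours"].iloc[0]),
                "n_batch_injections": int(group["n_batch_injections"].iloc[0]),
                "cal_quality_flag": group["cal_quality_flag"].iloc[0],
                "delta_ppm": float(post - pre),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "batch_id",
            "polarity",
            "batch_hours",
            "n_batch_injections",
            "cal_quality_flag",
            "delta_ppm",
        ],
    )
    trends: list[DriftTrend] = []
    for stratum, group in table.groupby("cal_quality_flag", sort=True):
        if len(group) >= 3 and group["batch_hours"].nunique() > 1:
            fit = stats.linregress(group["batch_hours"], group["delta_ppm"])
            trends.append(
                DriftTrend(
                    stratum=str(stratum),
                    n_batches=len(group),
                    slope_ppm_per_hour=float(fit.slope),
                    intercept_ppm=float(fit.intercept),
                    p_value=float(fit.pvalue),
                )
            )
        else:
            trends.append(
                DriftTrend(
                    stratum=str(stratum),
                    n_batches=len(group),
                    slope_ppm_per_hour=None,
                    intercept_ppm=None,
                    p_value=None,
                )
            )
    return table, trends


def batch_length_advisor(
    n_batch_injections: int,
    minutes_per_injection: float = MINUTES_PER_INJECTION,
    cal_quality_flag: str | None = None,
    max_injections: int = 100,
    poor_cal_onset_hours: float = 20.0,
) -> list[str]:
    """Advisories on batch length.

    Warns when a batch exceeds ~100 injections (~33 h at 20 min each,
    where drift becomes likely even under good calibration) and, under a
    POOR calibration flag, when it exceeds ~20 h (~60 injections), the
    earlier drift onset observed for poorly calibrated systems.
    """
    if n_batch_injections < 0:
        raise ValueError("n_batch_injections must be non-negative")
    hours = n_batch_injections * minutes_per_injection / 60.0
    max_hours = max_injections * minutes_per_injection / 60.0
    advisories = []
    if n_batch_injections > max_injections or hours > max_hours:
        advisories.append(
            f"batch of {n_batch_injections} injections (~{hours:.1f} h) exceeds "
            f"{max_injections} injections (~{max_hours:.0f} h); run an SST mid-batch "
            "or split the batch — mass-accuracy drift becomes likely beyond this length"
        )
    if cal_quality_flag == "POOR" and hours >= poor_cal_onset_hours:
        advisories.append(
            f"calibration quality is POOR and the batch spans ~{hours:.1f} h; drift can "
            f"begin after ~{poor_cal_onset_hours:.0f} h (~"
            f"{int(poor_cal_onset_hours * 60 / minutes_per_injection)} injections) under "
            "suboptimal calibration — recalibrate before a batch of this length"
        )
    return advisories
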