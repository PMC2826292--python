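"""Cohort evaluation of potassium control.

Builds each patient's piecewise-linear potassium curve from timestamped
measurements, then computes the field's standard time-in-range statistics:

* **prevalence** — duration spent hypokalemic (< 3.5 mmol/L) or hyperkalemic
  (> 5.0 mmol/L) divided by the duration of stay, from the interpolated
  curve (threshold crossings solved analytically per segment);
* **incidence** — fraction of individual measurements out of range, pooled
  over the cohort, excluding the first 8 h after admission;
* odds ratios with Woolf (log-normal) 95% confidence intervals;
* percentile bands (5/25/50/75/95) of the curves on a time grid;
* before/after arm comparison with chi-square and Mann-Whitney U tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """The requested quantity is undefined for this input (e.g. a
    zero-duration curve, or no measurements after the exclusion window)."""


@dataclass(frozen=True)
class PotassiumCurve:
    """A patient's linearly interpolated potassium trajectory.

    Defined only between the first and last knot; ``stay`` defaults to that
    span and acts as the prevalence denominator.
    """

    times: np.ndarray
    values: np.ndarray
    stay: Tuple[float, float]

    def __init__(self, times: Sequence[float], values: Sequence[float],
                 stay: Optional[Tuple[float, float]] = None) -> None:
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape or times.size == 0:
            raise UndefinedMetricError("curve needs matching, non-empty time/value arrays")
        if np.any(np.diff(times) <= 0):
            raise ValueError("measurement times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "stay",
                           stay if stay is not None else (float(times[0]), float(times[-1])))

    @property
    def duration(self) -> float:
        return self.stay[1] - self.stay[0]

    def value(self, t: float) -> float:
        """Curve value at time t (NaN outside the knot span)."""
        if t < self.times[0] or t > self.times[-1]:
            return float("nan")
        return float(np.interp(t, self.times, self.values))

    def covers(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (t >= self.times[0]) & (t <= self.times[-1])

    def duration_below(self, threshold: float) -> float:
        """Total time with K(t) < threshold, solved per linear segment."""
        return self._duration_outside(threshold, below=True)

    def duration_above(self, threshold: float) -> float:
        """Total time with K(t) > threshold, solved per linear segment."""
        return self._duration_outside(threshold, below=False)

    def _duration_outside(self, threshold: float, below: bool) -> float:
        t, v = self.times, self.values
        total = 0.0
        for i in range(len(t) - 1):
            dt = t[i + 1] - t[i]
            v0, v1 = v[i], v[i + 1]
            if below:
                a, b = threshold - v0, threshold - v1  # positive where K < threshold
            else:
                a, b = v0 - threshold, v1 - threshold
            if a <= 0 and b <= 0:
                continue
            if a > 0 and b > 0:
                total += dt
            else:
                # one crossing; the out-of-range side occupies |pos| / (|pos| + |neg|)
                total += dt * max(a, b) / (abs(a) + abs(b))
        return total


def interpolate(measurements, stay: Optional[Tuple[float, float]] = None) -> PotassiumCurve:
    """Build a patient's curve from (time, potassium) measurements.

    Accepts a DataFrame with ``time_h``/``potassium_mmol_l`` columns or a
    sequence of (time, value) pairs.  A single measurement yields a point
    curve with zero duration (prevalence undefined for it).
    """
    if isinstance(measurements, pd.DataFrame):
        times = measurements["time_h"].to_numpy(dtype=float)
        values = measurements["potassium_mmol_l"].to_numpy(dtype=float)
    else:
        pairs = list(measurements)
        if not pairs:
            raise UndefinedMetricError("at least one measurement is required")
        times = np.array([p[0] for p in pairs], dtype=float)
        values = np.array([p[1] for p in pairs], dtype=float)
    order = np.argsort(times, kind="stable")
    times, values = times[order], values[order]
    if np.any(np.diff(times) == 0):
        raise ValueError("duplicate measurement timestamps")
    return PotassiumCurve(times, values, stay)


def prevalence(curve: PotassiumCurve, low: float = 3.5, high: float = 5.0
               ) -> Tuple[float, float]:
    """(hypo %, hyper %): time below ``low`` / above ``high`` over the stay."""
    if curve.duration <= 0:
        raise UndefinedMetricError("prevalence undefined for a zero-duration curve")
    hypo = 100.0 * curve.duration_below(low) / curve.duration
    hyper = 100.0 * curve.duration_above(high) / curve.duration
    return hypo, hyper


def incidence(measurements, low: float = 3.5, high: float = 5.0,
              exclude_before: float = 8.0) -> Tuple[float, float]:
    """Pooled out-of-range measurement fractions (%), after the first
    ``exclude_before`` hours of admission.

    ``measurements`` is a DataFrame with ``time_h`` and ``potassium_mmol_l``
    (any number of patients pooled) or a sequence of (time, value) pairs.
    Thresholds are strict; values exactly at a threshold are in range.
    """
    if isinstance(measurements, pd.DataFrame):
        times = measurements["time_h"].to_numpy(dtype=float)
        values = measurements["potassium_mmol_l"].to_numpy(dtype=float)
    else:
        pairs = list(measurements)
        times = np.array([p[0] for p in pairs], dtype=float)
        values = np.array([p[1] for p in pairs], dtype=float)
    keep = times > exclude_before
    if not keep.any():
        raise UndefinedMetricError(
            f"no measurements after the {exclude_before} h exclusion window")
    values = values[keep]
    hypo = 100.0 * float(np.mean(values < low))
    hyper = 100.0 * float(np.mean(values > high))
    return hypo, hyper


@dataclass(frozen=True)
class OddsRatio:
    point: float
    ci_low: float
    ci_high: float


def odds_ratio(p1: float, n1: int, p2: float, n2: int) -> OddsRatio:
    """Odds ratio of two proportions with a Woolf 95% CI.

    The point estimate ``[p1/(1-p1)] / [p2/(1-p2)]`` depends only on the
    proportions; counts (reconstructed as round(p*n)) enter the CI.  A
    Haldane continuity correction (+0.5 per cell) is applied, with a
    warning, when any reconstructed cell is empty.
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportions must lie in [0, 1], got {p}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("counts must be positive")
    a = round(p1 * n1)
    b = n1 - a
    c = round(p2 * n2)
    d = n2 - c
    if min(a, b, c, d) == 0:
        warnings.warn("empty contingency cell; applying +0.5 continuity correction",
                      RuntimeWarning, stacklevel=2)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        point = (a / b) / (c / d)
    else:
        point = (p1 / (1.0 - p1)) / (p2 / (1.0 - p2))
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = stats.norm.ppf(0.975)
    log_or = np.log(point)  # center the CI on the point estimate
    return OddsRatio(point=float(point),
                     ci_low=float(np.exp(log_or - z * se)),
                     ci_high=float(np.exp(log_or + z * se)))


def percentile_bands(curves: Sequence[PotassiumCurve], time_grid: Sequence[float],
                     percentiles: Sequence[float] = (5, 25, 50, 75, 95)) -> pd.DataFrame:
    """Empirical percentile bands of the cohort's curves on a time grid.

    At each grid time, every curve whose span covers it is evaluated; grid
    points covered by no curve get NaN bands.  Uses the linear-interpolation
    percentile definition (numpy default).
    """
    curves = list(curves)
    if not curves:
        raise UndefinedMetricError("percentile bands need at least one curve")
    rows = []
    for t in time_grid:
        values = [c.value(t) for c in curves if c.covers(t)]
        row = {"time_h": float(t), "n": len(values)}
        for q in percentiles:
            row[f"p{q:g}"] = float(np.percentile(values, q)) if values else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EvalConfig:
    hypo_threshold: float = 3.5  # mmol/L
    hyper_threshold: float = 5.0  # mmol/L
    marked_hyper_threshold: float = 6.0  # mmol/L
    exclude_before: float = 8.0  # h, incidence exclusion window
    yates_correction: bool = False
    band_grid: Tuple[float, ...] = tuple(float(t) for t in range(0, 25, 2))
    percentiles: Tuple[float, ...] = (5, 25, 50, 75, 95)


@dataclass
class ArmSummary:
    """Aggregates for one study arm."""

    n_patients: int
    n_measurements: int
    total_stay_h: float
    incidence_hypo: float  # % of measurements
    incidence_hyper: float
    prevalence_hypo: float  # % of stay time, pooled over patients
    prevalence_hyper: float
    prevalence_marked_hyper: float
    measurements_per_patient_day: float
    per_patient_prevalence_hypo: List[float]
    per_patient_prevalence_hyper: List[float]
    bands: pd.DataFrame
    n_excluded_patients: int

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_measurements": self.n_measurements,
            "total_stay_h": self.total_stay_h,
            "incidence_hypo_pct": self.incidence_hypo,
            "incidence_hyper_pct": self.incidence_hyper,
            "prevalence_hypo_pct": self.prevalence_hypo,
            "prevalence_hyper_pct": self.prevalence_hyper,
            "prevalence_marked_hyper_pct": self.prevalence_marked_hyper,
            "measurements_per_patient_day": self.measurements_per_patient_day,
            "n_excluded_patients": self.n_excluded_patients,
        }


@dataclass
class CohortReport:
    """Before/after comparison of potassium control."""

    before: ArmSummary
    after: ArmSummary
    odds_ratios: Dict[str, OddsRatio]
    p_values: Dict[str, float]
    skewed_prevalence: bool  # True -> median (IQR) presentation advised

    def to_dict(self) -> dict:
        return {
            "before": self.before.to_dict(),
            "after": self.after.to_dict(),
            "odds_ratios": {
                key: {"or": orr.point, "ci_low": orr.ci_low, "ci_high": orr.ci_high}
                for key, orr in self.odds_ratios.items()},
            "p_values": self.p_values,
            "skewed_prevalence": self.skewed_prevalence,
        }


def _summarize_arm(measurements: pd.DataFrame, config: EvalConfig) -> ArmSummary:
    required = {"patient_id", "time_h", "potassium_mmol_l"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"arm measurements missing columns: {sorted(missing)}")
    if measurements.empty:
        raise ValueError("arm has no measurements")
    curves: List[PotassiumCurve] = []
    hypo_time = hyper_time = marked_time = total_stay = 0.0
    per_hypo: List[float] = []
    per_hyper: List[float] = []
    excluded = 0
    for _, group in measurements.groupby("patient_id"):
        curve = interpolate(group.sort_values("time_h"))
        if curve.duration <= 0:
            excluded += 1
            logger.info("patient with a zero-duration curve excluded from prevalence")
            continue
        curves.append(curve)
        below = curve.duration_below(config.hypo_threshold)
        above = curve.duration_above(config.hyper_threshold)
        marked = curve.duration_above(config.marked_hyper_threshold)
        hypo_time += below
        hyper_time += above
        marked_time += marked
        total_stay += curve.duration
        per_hypo.append(100.0 * below / curve.duration)
        per_hyper.append(100.0 * above / curve.duration)
    if total_stay <= 0:
        raise ValueError("arm has zero total stay; prevalence undefined")
    inc_hypo, inc_hyper = incidence(measurements, config.hypo_threshold,
                                    config.hyper_threshold, config.exclude_before)
    bands = percentile_bands(curves, config.band_grid, config.percentiles)
    return ArmSummary(
        n_patients=len(curves),
        n_measurements=len(measurements),
        total_stay_h=total_stay,
        incidence_hypo=inc_hypo,
        incidence_hyper=inc_hyper,
        prevalence_hypo=100.0 * hypo_time / total_stay,
        prevalence_hyper=100.0 * hyper_time / total_stay,
        prevalence_marked_hyper=100.0 * marked_time / total_stay,
        measurements_per_patient_day=len(measurements) / (total_stay / 24.0),
        per_patient_prevalence_hypo=per_hypo,
        per_patient_prevalence_hyper=per_hyper,
        bands=bands,
        n_excluded_patients=excluded,
    )


def _out_of_range_counts(measurements: pd.DataFrame, threshold: float, below: bool,
                         exclude_before: float) -> Tuple[int, int]:
    values = measurements.loc[measurements["time_h"] > exclude_before, "potassium_mmol_l"]
    out = int((values < threshold).sum() if below else (values > threshold).sum())
    return out, len(values) - out

def _chi2_p(table) -> float:
    arr = np.asarray(table, dtype=float)
    if (arr[0] == arr[1]).all() or arr.sum(axis=1).min() == 0 or arr.sum(axis=0).min() == 0:
        # identical rows or degenerate margins: no evidence of difference
        return 1.0
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(p)


def compare_arms(before: pd.DataFrame, after: pd.DataFrame,
                 config: EvalConfig = EvalConfig()) -> CohortReport:
    """Full before/after report from two arms' measurement tables.

    Odds ratios are before-vs-after (an OR > 1 means the 'after' arm has
    lower out-of-range odds).  Incidence ORs use pooled measurement counts;
    prevalence ORs use the time fractions with patient counts as the CI
    denominator.  Chi-square (without Yates by default) tests the pooled
    out-of-range counts; Mann-Whitney U compares per-patient prevalence
    distributions; kurtosis of those distributions flags skewness (median /
    IQR presentation).
    """
    before_summary = _summarize_arm(before, config)
    after_summary = _summarize_arm(after, config)

    ors: Dict[str, OddsRatio] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n_b = (before["time_h"] > config.exclude_before).sum()
        n_a = (after["time_h"] > config.exclude_before).sum()
        ors["incidence_hypo"] = odds_ratio(
            before_summary.incidence_hypo / 100.0, int(n_b),
            after_summary.incidence_hypo / 100.0, int(n_a))
        ors["incidence_hyper"] = odds_ratio(
            before_summary.incidence_hyper / 100.0, int(n_b),
            after_summary.incidence_hyper / 100.0, int(n_a))
        ors["prevalence_hypo"] = odds_ratio(
            before_summary.prevalence_hypo / 100.0, before_summary.n_patients,
            after_summary.prevalence_hypo / 100.0, after_summary.n_patients)
        ors["prevalence_hyper"] = odds_ratio(
            before_summary.prevalence_hyper / 100.0, before_summary.n_patients,
            after_summary.prevalence_hyper / 100.0, after_summary.n_patients)
        ors["prevalence_marked_hyper"] = odds_ratio(
            before_summary.prevalence_marked_hyper / 100.0, before_summary.n_patients,
            after_summary.prevalence_marked_hyper / 100.0, after_summary.n_patients)

    p_values: Dict[str, float] = {}
    for key, below, thr in (("hypo", True, config.hypo_threshold),
                            ("hyper", False, config.hyper_threshold)):
        tb = _out_of_range_counts(before, thr, below, config.exclude_before)
        ta = _out_of_range_counts(after, thr, below, config.exclude_before)
        p_values[f"chi2_incidence_{key}"] = _chi2_p([tb, ta])
    for key, b_vals, a_vals in (
            ("hypo", before_summary.per_patient_prevalence_hypo,
             after_summary.per_patient_prevalence_hypo),
            ("hyper", before_summary.per_patient_prevalence_hyper,
             after_summary.per_patient_prevalence_hyper)):
        if np.ptp(b_vals + a_vals) == 0:
            p_values[f"mannwhitney_prevalence_{key}"] = 1.0
        else:
            _, p = stats.mannwhitneyu(b_vals, a_vals, alternative="two-sided",
                                      method="asymptotic")
            p_values[f"mannwhitney_prevalence_{key}"] = float(p)

    pooled = (before_summary.per_patient_prevalence_hypo
              + after_summary.per_patient_prevalence_hypo
              + before_summary.per_patient_prevalence_hyper
              + after_summary.per_patient_prevalence_hyper)
    skewed = bool(abs(stats.kurtosis(pooled)) > 1.0) if len(pooled) > 3 else False

    return CohortReport(before=before_summary, after=after_summary,
                        odds_ratios=ors, p_values=p_values, skewed_prevalence=skewed)
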