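"""Potassium infusion advisory algorithm for ICU patients.

The advisor turns a single decision point — the latest blood potassium, the
patient's renal status and the recent infusion history — into a recommended
syringe-pump rate (mmol/h), a time to the next measurement, and any physician
alerts.  The algorithm:

1. estimates renal potassium-handling capacity as a *clearance fraction*
   (1.0 = normal), lowered linearly for reduced glomerular filtration or
   diuresis and raised by 0.5 on renal replacement therapy;
2. picks a target range (3.8–4.5 mmol/L by default, lowered by 0.2 mmol/L
   when renal function is impaired);
3. classifies the measurement as hypo-, normo- or hyperkalemia relative to
   that range;
4. doses: a linear sliding scale for hypokalemia (20 mmol/h at K=2.0 down to
   6 mmol/h at K=3.5), exponential smoothing of the recent mean rate toward
   4 x clearance for normokalemia, and zero for hyperkalemia;
5. raises alerts for markedly abnormal potassium (<2.8 or >6.0 mmol/L;
   <2.6 or >5.8 mmol/L in renal failure) and for advised rates above
   12 mmol/h.

All rates assume a one-to-one potassium chloride solution (1 mmol/mL), so
mmol/h and mL/h coincide on the pump.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Tuple

logger = logging.getLogger(__name__)

#: μmol/L of creatinine per mg/dL.
UMOL_L_PER_MG_DL = 88.4

#: Alert identifiers carried in :attr:`Advice.alerts`.
MARKED_ABNORMAL_POTASSIUM = "marked_abnormal_potassium"
HIGH_INFUSION_RATE = "high_infusion_rate"


class InvalidInputError(ValueError):
    """A clinical input is outside its physically meaningful domain."""


class ContractViolationError(RuntimeError):
    """An operation was called outside the state it is defined for."""


class KalemicState(str, Enum):
    HYPOKALEMIA = "hypokalemia"
    NORMOKALEMIA = "normokalemia"
    HYPERKALEMIA = "hyperkalemia"


@dataclass(frozen=True)
class TargetRange:
    """Preferred potassium band, inclusive at both ends (mmol/L)."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise InvalidInputError(f"target range requires low < high, got {self}")

    def contains(self, potassium: float) -> bool:
        return self.low <= potassium <= self.high


def _default_interval_table() -> dict:
    # Calibrated so a stable patient is sampled ~6x/day.
    return {
        "alert": 1.0,
        KalemicState.HYPOKALEMIA.value: 2.0,
        KalemicState.HYPERKALEMIA.value: 2.0,
        KalemicState.NORMOKALEMIA.value: 4.0,
    }


@dataclass(frozen=True)
class AdvisorConfig:
    """Tunable constants of the advisory algorithm.

    Defaults encode the protocol as used clinically; every threshold is
    overridable (e.g. for a diluted potassium solution, scale the rate
    constants accordingly).
    """

    #: mmol/h of infusion per unit clearance fraction; the within-range rate
    #: converges to ``pump_rate_per_clearance * clearance``.
    pump_rate_per_clearance: float = 4.0
    #: Exponential-smoothing weight pulling the 8-hour mean rate toward the
    #: clearance-matched rate; in (0, 1].
    convergence_weight: float = 0.25
    #: Sliding-scale anchor points (potassium mmol/L -> starting rate mmol/h).
    scale_low_k: float = 2.0
    scale_low_rate: float = 20.0
    scale_high_k: float = 3.5
    scale_high_rate: float = 6.0
    #: Marked-abnormal potassium alert window, normal renal function.
    alert_low: float = 2.8
    alert_high: float = 6.0
    #: Alert window in renal failure.
    alert_low_renal: float = 2.6
    alert_high_renal: float = 5.8
    #: Advised rates above this trigger a physician alert (mmol/h).
    high_rate_alert: float = 12.0
    #: Renal impairment cutoffs (strict <).
    renal_gfr_cutoff: float = 30.0  # mL/min
    renal_diuresis_cutoff: float = 30.0  # mL/h
    #: Linear clearance-fraction references: fraction 1.0 at or above these.
    clearance_gfr_ref: float = 100.0  # mL/min
    clearance_diuresis_ref: float = 60.0  # mL/h
    #: Added to the clearance fraction on hemofiltration / RRT.
    rrt_clearance_bonus: float = 0.5
    #: Default target range and its lowering under renal impairment (mmol/L).
    target_low: float = 3.8
    target_high: float = 4.5
    target_lowering: float = 0.2
    #: Lookback window for the within-range mean rate (h).
    mean_window: float = 8.0
    #: Next-measurement intervals (h) by situation.
    interval_table: dict = field(default_factory=_default_interval_table)
    #: Pump resolution; advised rates are rounded to multiples of this.
    rate_resolution: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.convergence_weight <= 1.0:
            raise InvalidInputError("convergence_weight must be in (0, 1]")
        if self.alert_low_renal >= self.alert_low:
            raise InvalidInputError("renal low alert threshold must sit below the normal one")
        if self.alert_high_renal >= self.alert_high:
            raise InvalidInputError("renal high alert threshold must sit below the normal one")
        for name in ("pump_rate_per_clearance", "high_rate_alert", "renal_gfr_cutoff",
                     "renal_diuresis_cutoff", "clearance_gfr_ref", "clearance_diuresis_ref",
                     "target_low", "target_high", "mean_window"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")


DEFAULT_CONFIG = AdvisorConfig()

#: Infusion-log entry: (start time h, end time h, rate mmol/h).
InfusionEntry = Tuple[float, float, float]


@dataclass(frozen=True)
class AdvisoryContext:
    """Clinical inputs at one decision point.

    Times are hours since an arbitrary origin (ICU admission by convention).
    ``creatinine`` and ``diuresis_6h`` may be ``None`` when unavailable; the
    advisor then falls back to the remaining renal signal, or assumes normal
    renal function when both are missing.
    """

    potassium: float  # mmol/L
    creatinine: Optional[float] = None  # μmol/L
    age: Optional[float] = None  # years
    weight: Optional[float] = None  # kg
    sex: Optional[str] = None  # "male" | "female"
    diuresis_6h: Optional[float] = None  # mL over the last 6 h
    on_rrt: bool = False
    infusion_log: Tuple[InfusionEntry, ...] = ()
    admission_time: float = 0.0
    now: float = 0.0

    def __post_init__(self) -> None:
        if not (self.potassium > 0 and math.isfinite(self.potassium)):
            raise InvalidInputError(f"potassium must be positive, got {self.potassium}")
        if self.creatinine is not None:
            if self.creatinine <= 0:
                raise InvalidInputError("creatinine must be positive when supplied")
            if self.age is None or self.weight is None or self.sex is None:
                raise InvalidInputError(
                    "creatinine clearance needs age, weight and sex alongside creatinine")
        if self.age is not None and self.age < 0:
            raise InvalidInputError("age must be >= 0")
        if self.weight is not None and self.weight <= 0:
            raise InvalidInputError("weight must be positive")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise InvalidInputError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.diuresis_6h is not None and self.diuresis_6h < 0:
            raise InvalidInputError("diuresis_6h must be >= 0")
        if self.now < self.admission_time:
            raise InvalidInputError("now must be at or after admission_time")
        object.__setattr__(self, "infusion_log", tuple(tuple(e) for e in self.infusion_log))
        _validate_log(self.infusion_log, self.admission_time, self.now)


@dataclass(frozen=True)
class Advice:
    """One recommendation: pump rate, next measurement, state and alerts."""

    rate: float  # mmol/h, >= 0
    next_interval: float  # h
    state: KalemicState
    alerts: Tuple[str, ...]
    clearance_fraction: float
    target: TargetRange

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise InvalidInputError("advised rate must be >= 0")
        if self.state is KalemicState.HYPERKALEMIA and self.rate != 0:
            raise InvalidInputError("hyperkalemia must advise zero infusion")


def _round_rate(rate: float, resolution: float) -> float:
    """Round half-up to the pump resolution."""
    if resolution <= 0:
        return rate
    return math.floor(rate / resolution + 0.5) * resolution


def _validate_log(log: Sequence[InfusionEntry], admission_time: float, now: float) -> None:
    eps = 1e-9
    entries = sorted(log)
    for start, end, rate in entries:
        if end < start:
            raise InvalidInputError(f"infusion interval has end < start: ({start}, {end})")
        if rate < 0:
            raise InvalidInputError(f"infusion rate must be >= 0, got {rate}")
        if start < admission_time - eps or end > now + eps:
            raise InvalidInputError(
                f"infusion interval ({start}, {end}) outside [{admission_time}, {now}]")
    for (s0, e0, _), (s1, e1, _) in zip(entries, entries[1:]):
        if s1 < e0 - eps:
            raise InvalidInputError(
                f"infusion intervals overlap: ({s0}, {e0}) and ({s1}, {e1})")


def cockcroft_gault(age: float, weight: float, sex: str, creatinine: float) -> float:
    """Estimated creatinine clearance (mL/min), Cockcroft–Gault.

    ``creatinine`` is in μmol/L (converted internally to mg/dL).  The female
    estimate is 0.85 x the male one.  Clamped at zero for age >= 140.
    """
    if creatinine <= 0:
        raise InvalidInputError("creatinine must be positive")
    if weight <= 0:
        raise InvalidInputError("weight must be positive")
    if age < 0:
        raise InvalidInputError("age must be >= 0")
    if sex not in ("male", "female"):
        raise InvalidInputError(f"sex must be 'male' or 'female', got {sex!r}")
    creatinine_mg_dl = creatinine / UMOL_L_PER_MG_DL
    clearance = (140.0 - age) * weight / (72.0 * creatinine_mg_dl)
    if sex == "female":
        clearance *= 0.85
    return max(0.0, clearance)


def clearance_fraction(
    gfr: Optional[float],
    diuresis_rate: Optional[float],
    on_rrt: bool = False,
    config: AdvisorConfig = DEFAULT_CONFIG,
) -> float:
    """Potassium clearance as a fraction of a normal person's.

    1.0 by default; lowered linearly below a GFR of 100 mL/min or a diuresis
    of 60 mL/h (the more impaired signal wins); +0.5 on hemofiltration.
    ``None`` inputs fall back to the other signal; with neither available the
    fraction defaults to 1 (logged).
    """
    components = [1.0]
    if gfr is not None:
        if gfr < 0:
            raise InvalidInputError("gfr must be >= 0")
        components.append(gfr / config.clearance_gfr_ref)
    if diuresis_rate is not None:
        if diuresis_rate < 0:
            raise InvalidInputError("diuresis_rate must be >= 0")
        components.append(diuresis_rate / config.clearance_diuresis_ref)
    if gfr is None and diuresis_rate is None:
        logger.warning("no renal data available; assuming normal potassium clearance")
    fraction = min(components)
    if on_rrt:
        fraction += config.rrt_clearance_bonus
    return fraction


def is_renal_impaired(
    gfr: Optional[float],
    diuresis_rate: Optional[float],
    config: AdvisorConfig = DEFAULT_CONFIG,
) -> bool:
    """Renal impairment: GFR < 30 mL/min or diuresis < 30 mL/h (strict)."""
    if gfr is not None and gfr < 0:
        raise InvalidInputError("gfr must be >= 0")
    if diuresis_rate is not None and diuresis_rate < 0:
        raise InvalidInputError("diuresis_rate must be >= 0")
    impaired = False
    if gfr is not None and gfr < config.renal_gfr_cutoff:
        impaired = True
    if diuresis_rate is not None and diuresis_rate < config.renal_diuresis_cutoff:
        impaired = True
    return impaired


def target_range(renal_impaired: bool, config: AdvisorConfig = DEFAULT_CONFIG) -> TargetRange:
    """Preferred range: (3.8, 4.5), both bounds 0.2 lower when impaired."""
    if renal_impaired:
        return TargetRange(config.target_low - config.target_lowering,
                           config.target_high - config.target_lowering)
    return TargetRange(config.target_low, config.target_high)


def classify(potassium: float, target: TargetRange) -> KalemicState:
    """Hypo- / normo- / hyperkalemia relative to the target range.

    The range is inclusive at both ends: classification uses strict
    inequalities (K < low, K > high).
    """
    if potassium <= 0:
        raise InvalidInputError("potassium must be positive")
    if potassium < target.low:
        return KalemicState.HYPOKALEMIA
    if potassium > target.high:
        return KalemicState.HYPERKALEMIA
    return KalemicState.NORMOKALEMIA


def sliding_scale_rate(
    potassium: float,
    target: TargetRange,
    config: AdvisorConfig = DEFAULT_CONFIG,
) -> float:
    """Starting infusion rate (mmol/h) for a hypokalemic measurement.

    Linear through the anchors (2.0 mmol/L -> 20 mmol/h) and
    (3.5 mmol/L -> 6 mmol/h), clamped at 20 below K=2.0 and extended
    linearly between 3.5 and the target lower bound; rounded to the pump
    resolution, never negative.
    """
    if potassium >= target.low:
        raise ContractViolationError(
            f"sliding scale applies only below the target range "
            f"(K={potassium}, target low={target.low})")
    slope = (config.scale_high_rate - config.scale_low_rate) / (
        config.scale_high_k - config.scale_low_k)
    k = max(potassium, config.scale_low_k)
    rate = config.scale_low_rate + slope * (k - config.scale_low_k)
    return max(0.0, _round_rate(rate, config.rate_resolution))


def mean_recent_rate(
    infusion_log: Sequence[InfusionEntry],
    admission_time: float,
    now: float,
    window: float = 8.0,
) -> float:
    """Time-weighted mean infusion rate over the last ``window`` hours,
    or since admission, whichever span is shorter.

    Gaps in the log count as rate 0.  Returns 0 for an empty lookback span.
    """
    if now < admission_time:
        raise InvalidInputError("now must be at or after admission_time")
    _validate_log(infusion_log, admission_time, now)
    span_start = max(now - window, admission_time)
    span = now - span_start
    if span <= 0:
        return 0.0
    total = 0.0
    for start, end, rate in infusion_log:
        overlap = min(end, now) - max(start, span_start)
        if overlap > 0:
            total += overlap * rate
    return total / span


def within_range_rate(
    mean_8h: float,
    clearance: float,
    config: AdvisorConfig = DEFAULT_CONFIG,
) -> float:
    """Within-range advice: the recent mean rate nudged toward clearance.

    Exponential smoothing ``(1 - λ)·mean_8h + λ·(4·clearance)`` with
    λ = ``convergence_weight``.  Repeated application converges geometrically
    to ``4·clearance``, which is an exact fixed point; a clearance of 1 makes
    the pump converge to 4 mmol/h, a clearance of 0.25 to 1 mmol/h.  The
    exact value is returned; rounding to the pump resolution happens when an
    :class:`Advice` is emitted, so the printed limits stay exact under
    iteration.
    """
    if mean_8h < 0:
        raise InvalidInputError("mean_8h must be >= 0")
    if clearance < 0:
        raise InvalidInputError("clearance must be >= 0")
    lam = config.convergence_weight
    return (1.0 - lam) * mean_8h + lam * config.pump_rate_per_clearance * clearance


def check_alerts(
    potassium: float,
    renal_impaired: bool,
    advised_rate: float,
    config: AdvisorConfig = DEFAULT_CONFIG,
) -> Tuple[str, ...]:
    """Physician-notification alerts for this decision point.

    ``marked_abnormal_potassium`` outside (2.8, 6.0) mmol/L — (2.6, 5.8) in
    renal failure — and ``high_infusion_rate`` for advised rates > 12 mmol/h.
    """
    low = config.alert_low_renal if renal_impaired else config.alert_low
    high = config.alert_high_renal if renal_impaired else config.alert_high
    alerts = []
    if potassium < low or potassium > high:
        alerts.append(MARKED_ABNORMAL_POTASSIUM)
    if advised_rate > config.high_rate_alert:
        alerts.append(HIGH_INFUSION_RATE)
    return tuple(alerts)


def next_interval(
    state: KalemicState,
    alerts: Sequence[str],
    config: AdvisorConfig = DEFAULT_CONFIG,
) -> float:
    """Hours to the next potassium measurement.

    1 h on a marked-abnormal alert, 2 h out of range, 4 h in range
    (a stable patient is sampled ~6x/day); table overridable via config.
    """
    if MARKED_ABNORMAL_POTASSIUM in alerts:
        return config.interval_table["alert"]
    return config.interval_table[state.value]


def advise(ctx: AdvisoryContext, config: AdvisorConfig = DEFAULT_CONFIG) -> Advice:
    """Full advisory pass for one decision point.

    Renal assessment -> target range -> classification -> dose -> alerts ->
    next measurement.  Pure function of (ctx, config): identical inputs give
    identical Advice.  Hyperkalemia always yields rate 0.
    """
    gfr = None
    if ctx.creatinine is not None:
        gfr = cockcroft_gault(ctx.age, ctx.weight, ctx.sex, ctx.creatinine)
    diuresis_rate = None
    if ctx.diuresis_6h is not None:
        diuresis_rate = ctx.diuresis_6h / 6.0
    fraction = clearance_fraction(gfr, diuresis_rate, ctx.on_rrt, config)
    impaired = is_renal_impaired(gfr, diuresis_rate, config)
    target = target_range(impaired, config)
    state = classify(ctx.potassium, target)

    if state is KalemicState.HYPOKALEMIA:
        rate = sliding_scale_rate(ctx.potassium, target, config)
    elif state is KalemicState.NORMOKALEMIA:
        mean_8h = mean_recent_rate(ctx.infusion_log, ctx.admission_time, ctx.now,
                                   config.mean_window)
        rate = _round_rate(within_range_rate(mean_8h, fraction, config),
                           config.rate_resolution)
    else:
        rate = 0.0

    alerts = check_alerts(ctx.potassium, impaired, rate, config)
    interval = next_interval(state, alerts, config)
    return Advice(rate=rate, next_interval=interval, state=state, alerts=alerts,
                  clearance_fraction=fraction, target=target)
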