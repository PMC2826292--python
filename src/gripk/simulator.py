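"""Virtual ICU patients with one-compartment potassium kinetics, and
closed-loop control by either the computerized advisor or a physician
emulator.

The plasma pool (volume ``V``) receives the pump infusion ``R`` and an
endogenous input ``B`` (diet, cell turnover), exchanges potassium with the
intracellular pool through a buffering term ``H (C_set - C)``, and loses
potassium renally at ``CL0 f C`` where ``f`` is the patient's clearance
fraction:

    dC/dt = (R + B + H (C_set - C) - CL0 f C) / V  + process noise

The closed-form steady state is ``C* = (R + B + H C_set) / (H + CL0 f)``.
Defaults are calibrated so a normal-clearance patient sits at 4.2 mmol/L on
a 2.3 mmol/h infusion and drifts to 3.5 mmol/L untreated — i.e. virtually
every untreated patient becomes hypokalemic, while renal failure produces
hyperkalemic accumulation.

This is a deliberately minimal stand-in for real potassium physiology: no
acid-base or insulin effects, no route-dependent absorption, a single
well-mixed compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from gripk.advisor import (
    DEFAULT_CONFIG,
    Advice,
    AdvisorConfig,
    AdvisoryContext,
    advise,
)

MEASUREMENT_RESOLUTION = 0.1  # mmol/L, point-of-care analyzer reporting step


class SimulationError(RuntimeError):
    """The integrator or a controller produced an unusable state."""


@dataclass(frozen=True)
class VirtualPatientParams:
    """Kinetic constants of the one-compartment potassium model.

    ``renal_clearance`` defaults to 16/7 L/h so that, with the other
    defaults, the steady state is exactly 4.2 mmol/L at a 2.3 mmol/h
    infusion and 3.5 mmol/L with the pump off.
    """

    volume: float = 15.0  # L, distribution volume for acute plasma changes
    renal_clearance: float = 16.0 / 7.0  # L/h at clearance fraction 1
    buffering: float = 1.0  # L/h, transcellular exchange toward the set point
    set_point: float = 4.2  # mmol/L
    endogenous_input: float = 7.3  # mmol/h
    clearance_fraction: float = 1.0
    process_noise_sd: float = 0.15  # mmol/L per sqrt(h)
    measurement_noise_sd: float = 0.05  # mmol/L
    initial_potassium: float = 4.0  # mmol/L

    def __post_init__(self) -> None:
        if min(self.volume, self.renal_clearance, self.buffering) <= 0:
            raise ValueError("volume, renal_clearance and buffering must be positive")
        if self.clearance_fraction < 0:
            raise ValueError("clearance_fraction must be >= 0")
        if min(self.process_noise_sd, self.measurement_noise_sd) < 0:
            raise ValueError("noise SDs must be >= 0")

    def steady_state(self, infusion_rate: float) -> float:
        """Closed-form fixed point C* at a constant infusion rate."""
        return (infusion_rate + self.endogenous_input + self.buffering * self.set_point) / (
            self.buffering + self.renal_clearance * self.clearance_fraction)


@dataclass(frozen=True)
class VirtualPatient:
    """A cohort member: kinetics plus the covariates the advisor sees."""

    patient_id: int
    params: VirtualPatientParams
    age: float
    weight: float
    sex: str
    creatinine: float  # μmol/L
    diuresis_6h: float  # mL / 6 h
    on_rrt: bool
    renal_impaired: bool
    admission_clock_hour: float = 0.0  # clock time of admission, for review phase


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 100
    duration: float = 120.0  # h
    dt: float = 0.05  # h
    seed: int = 0
    controller: str = "grip2"  # "grip2" | "physician"
    admission_potassium_mean: float = 4.0
    admission_potassium_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.controller not in ("grip2", "physician"):
            raise ValueError(f"unknown controller {self.controller!r}")


def step_patient(
    potassium: float,
    params: VirtualPatientParams,
    infusion_rate: float,
    dt: float,
    rng: np.random.Generator,
) -> float:
    """One Euler–Maruyama step of the kinetic model; floored at 0.5 mmol/L."""
    if not (0 < dt <= 0.25):
        raise SimulationError(f"dt must be in (0, 0.25] h, got {dt}")
    if not (math.isfinite(potassium) and math.isfinite(infusion_rate)):
        raise SimulationError("non-finite simulation state")
    drift = (infusion_rate + params.endogenous_input
             + params.buffering * (params.set_point - potassium)
             - params.renal_clearance * params.clearance_fraction * potassium
             ) / params.volume
    new = potassium + drift * dt
    if params.process_noise_sd > 0:
        new += rng.normal(0.0, params.process_noise_sd * math.sqrt(dt))
    if not math.isfinite(new):
        raise SimulationError("simulation diverged to a non-finite potassium")
    return max(new, 0.5)


def measure(potassium: float, params: VirtualPatientParams,
            rng: Optional[np.random.Generator] = None) -> float:
    """Point-of-care measurement: Gaussian noise, reported to 0.1 mmol/L."""
    if potassium <= 0:
        raise ValueError("potassium must be positive")
    value = potassium
    if params.measurement_noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when measurement noise is enabled")
        value += rng.normal(0.0, params.measurement_noise_sd)
    value = math.floor(value / MEASUREMENT_RESOLUTION + 0.5) * MEASUREMENT_RESOLUTION
    return max(round(value, 1), MEASUREMENT_RESOLUTION)


@dataclass
class ControllerDecision:
    """What a controller returns after seeing a measurement."""

    next_interval: float  # h until the next measurement
    rate_change: Optional[Tuple[float, float]] = None  # (effective time h, new rate)


class GripController:
    """Closed-loop wrapper around the advisory algorithm.

    Builds an :class:`~gripk.advisor.AdvisoryContext` from the patient's
    covariates and the infusion history accumulated so far, and applies the
    advised rate immediately.
    """

    def __init__(self, patient: VirtualPatient,
                 advisor_config: AdvisorConfig = DEFAULT_CONFIG) -> None:
        self.patient = patient
        self.config = advisor_config
        self._log: List[Tuple[float, float, float]] = []
        self._rate = 0.0
        self._since = 0.0
        self.last_advice: Optional[Advice] = None

    def on_measurement(self, t: float, potassium: float) -> ControllerDecision:
        if t > self._since:
            self._log.append((self._since, t, self._rate))
            self._since = t
        ctx = AdvisoryContext(
            potassium=potassium,
            creatinine=self.patient.creatinine,
            age=self.patient.age,
            weight=self.patient.weight,
            sex=self.patient.sex,
            diuresis_6h=self.patient.diuresis_6h,
            on_rrt=self.patient.on_rrt,
            infusion_log=tuple(self._log),
            admission_time=0.0,
            now=t,
        )
        adv = advise(ctx, self.config)
        self.last_advice = adv
        self._rate = adv.rate
        return ControllerDecision(next_interval=adv.next_interval, rate_change=(t, adv.rate))


class PhysicianController:
    """Pre-protocol baseline: physician-driven potassium dosing.

    The prescription is revised only at the daily morning review (08:00 ward
    clock), or — after a one-hour consult delay — when a measurement is
    markedly out of range (K < 3.0 or K > 5.5 mmol/L).  The dose choice is a
    coarse sliding scale rounded to 2 mmol/h for hypokalemia, a fixed
    2 mmol/h maintenance rate in range, and zero for hyperkalemia (K > 5.0).
    Measurements run on a fixed 4-hour schedule.
    """

    def __init__(self, patient: VirtualPatient,
                 review_clock_hour: float = 8.0,
                 measurement_interval: float = 4.0,
                 consult_low: float = 3.0,
                 consult_high: float = 5.5,
                 consult_delay: float = 1.0,
                 maintenance_rate: float = 2.0,
                 rate_resolution: float = 2.0) -> None:
        self.patient = patient
        self.measurement_interval = measurement_interval
        self.consult_low = consult_low
        self.consult_high = consult_high
        self.consult_delay = consult_delay
        self.maintenance_rate = maintenance_rate
        self.rate_resolution = rate_resolution
        offset = (review_clock_hour - patient.admission_clock_hour) % 24.0
        self._next_review = offset if offset > 0 else 24.0

    def _choose_rate(self, potassium: float) -> float:
        if potassium < 3.5:
            raw = 20.0 - (14.0 / 1.5) * (potassium - 2.0)
            raw = min(20.0, max(0.0, raw))
            return math.floor(raw / self.rate_resolution + 0.5) * self.rate_resolution
        if potassium <= 5.0:
            return self.maintenance_rate
        return 0.0

    def on_measurement(self, t: float, potassium: float) -> ControllerDecision:
        decide = False
        delay = 0.0
        if t == 0.0:  # admission orders
            decide = True
        elif t >= self._next_review:
            decide = True
            while self._next_review <= t:
                self._next_review += 24.0
        elif potassium < self.consult_low or potassium > self.consult_high:
            decide = True
            delay = self.consult_delay
        if not decide:
            return ControllerDecision(next_interval=self.measurement_interval)
        new_rate = self._choose_rate(potassium)
        return ControllerDecision(next_interval=self.measurement_interval,
                                  rate_change=(t + delay, new_rate))


Controller = Callable[[VirtualPatient], object]


@dataclass
class PatientRun:
    """Logs from one closed-loop run."""

    patient_id: int
    measurements: List[Tuple[float, float]]  # (time h, measured K)
    infusions: List[Tuple[float, float, float]]  # (start h, end h, rate mmol/h)
    times: np.ndarray  # simulation grid
    trajectory: np.ndarray  # true potassium on the grid


def run_closed_loop(
    patient: VirtualPatient,
    config: SimulationConfig,
    controller,
    rng: np.random.Generator,
) -> PatientRun:
    """Simulate one patient under a controller.

    Measurements occur at controller-scheduled times (starting at admission),
    rate changes take effect at the controller-specified time, and the
    infusion log tiles [0, duration] without overlap.  Fully reproducible
    given the rng state.
    """
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    potassium = patient.params.initial_potassium
    times = np.arange(n_steps + 1) * dt
    trajectory = np.empty(n_steps + 1)
    trajectory[0] = potassium

    measurements: List[Tuple[float, float]] = []
    infusions: List[Tuple[float, float, float]] = []
    rate = 0.0
    seg_start = 0.0
    next_meas = 0
    pending: Optional[Tuple[int, float]] = None

    def apply_rate(new_rate: float, t: float) -> None:
        nonlocal rate, seg_start
        if new_rate != rate:
            if t > seg_start:
                infusions.append((seg_start, t, rate))
            rate = new_rate
            seg_start = t

    for i in range(n_steps + 1):
        t = times[i]
        if pending is not None and i >= pending[0]:
            apply_rate(pending[1], t)
            pending = None
        if i == next_meas and i < n_steps:
            k_meas = measure(potassium, patient.params, rng)
            measurements.append((float(t), k_meas))
            try:
                decision = controller.on_measurement(float(t), k_meas)
            except Exception as exc:  # pragma: no cover - diagnostic path
                raise SimulationError(
                    f"controller failed at t={t:.2f} h for patient "
                    f"{patient.patient_id}: {exc}") from exc
            next_meas = i + max(1, int(round(decision.next_interval / dt)))
            if decision.rate_change is not None:
                eff_t, new_rate = decision.rate_change
                eff_i = int(round(eff_t / dt))
                if eff_i <= i:
                    apply_rate(new_rate, t)
                else:
                    pending = (eff_i, new_rate)
        if i < n_steps:
            potassium = step_patient(potassium, patient.params, rate, dt, rng)
            trajectory[i + 1] = potassium

    if config.duration > seg_start:
        infusions.append((seg_start, config.duration, rate))
    return PatientRun(patient.patient_id, measurements, infusions, times, trajectory)


def make_cohort(n: int, seed: int, arm: str = "grip2") -> List[VirtualPatient]:
    """Sample a heterogeneous virtual cohort.

    Admission potassium ~ Normal(4.0, 0.4) truncated to [2.0, 6.5]; ~11% of
    patients renally impaired (low GFR and oliguria), ~5% on RRT; ages and
    weights typical of an adult surgical ICU.  The composition depends only
    on (n, seed) — the ``arm`` argument is a label, so both arms of a
    before/after comparison can run on the identical cohort.

    Impaired patients get a reduced endogenous potassium input (dietary
    restriction), keeping their untreated steady states clinically plausible.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    cohort: List[VirtualPatient] = []
    for i in range(n):
        age = float(np.clip(rng.normal(62.0, 15.0), 18.0, 95.0))
        sex = "male" if rng.random() < 0.66 else "female"
        weight = float(np.clip(rng.normal(82.0 if sex == "male" else 72.0, 13.0), 45.0, 140.0))
        impaired = rng.random() < 0.11
        on_rrt = bool(impaired and rng.random() < 0.45)
        if impaired:
            gfr = float(rng.uniform(5.0, 28.0))
            diuresis_rate = float(rng.uniform(2.0, 25.0))  # mL/h
        else:
            gfr = float(rng.uniform(70.0, 130.0))
            diuresis_rate = float(rng.uniform(60.0, 150.0))
        # physiology consistent with the advisor's renal model
        f = min(1.0, gfr / 100.0, diuresis_rate / 60.0) + (0.5 if on_rrt else 0.0)
        sex_factor = 0.85 if sex == "female" else 1.0
        creatinine = (140.0 - age) * weight * sex_factor / (72.0 * gfr) * 88.4
        k0 = float(np.clip(rng.normal(4.0, 0.4), 2.0, 6.5))
        while not 2.0 < k0 < 6.5:  # resample hard clips at the bounds
            k0 = float(np.clip(rng.normal(4.0, 0.4), 2.0, 6.5))
        endogenous = float(np.clip(rng.normal(7.3, 0.7), 5.0, 9.5))
        if impaired:
            endogenous *= 0.4 + 0.6 * min(1.0, f)
        params = VirtualPatientParams(
            volume=float(np.clip(rng.normal(15.0, 2.0), 10.0, 22.0)),
            clearance_fraction=f,
            endogenous_input=endogenous,
            initial_potassium=k0,
        )
        cohort.append(VirtualPatient(
            patient_id=i,
            params=params,
            age=age,
            weight=weight,
            sex=sex,
            creatinine=creatinine,
            diuresis_6h=diuresis_rate * 6.0,
            on_rrt=on_rrt,
            renal_impaired=impaired,
            admission_clock_hour=float(rng.uniform(0.0, 24.0)),
        ))
    return cohort


def _make_controller(name: str, patient: VirtualPatient,
                     advisor_config: AdvisorConfig = DEFAULT_CONFIG):
    if name == "grip2":
        return GripController(patient, advisor_config)
    if name == "physician":
        return PhysicianController(patient)
    raise ValueError(f"unknown controller {name!r}")


def simulate_cohort(
    config: SimulationConfig,
    cohort: Optional[Sequence[VirtualPatient]] = None,
    advisor_config: AdvisorConfig = DEFAULT_CONFIG,
    keep_trajectories: bool = False,
) -> dict:
    """Run a whole cohort closed-loop; returns tidy per-run records.

    Output dict holds ``measurements`` (patient_id, time_h, potassium_mmol_l),
    ``infusions`` (patient_id, start_h, end_h, rate_mmol_h), ``patients``
    (covariates and kinetic parameters) as lists of dicts, plus the
    ``PatientRun`` objects when ``keep_trajectories`` is set.  One named RNG
    stream per patient is derived from the master seed, so results are
    reproducible patient-by-patient.
    """
    if cohort is None:
        cohort = make_cohort(config.n_patients, config.seed, config.controller)
    measurements = []
    infusions = []
    patients = []
    runs = []
    for patient in cohort:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(patient.patient_id,)))
        controller = _make_controller(config.controller, patient, advisor_config)
        run = run_closed_loop(patient, config, controller, rng)
        for t, k in run.measurements:
            measurements.append({"patient_id": patient.patient_id, "time_h": t,
                                 "potassium_mmol_l": k})
        for start, end, rate in run.infusions:
            infusions.append({"patient_id": patient.patient_id, "start_h": start,
                              "end_h": end, "rate_mmol_h": rate})
        record = {"patient_id": patient.patient_id, "age": patient.age,
                  "weight": patient.weight, "sex": patient.sex,
                  "creatinine": patient.creatinine, "diuresis_6h": patient.diuresis_6h,
                  "on_rrt": patient.on_rrt, "renal_impaired": patient.renal_impaired,
                  "admission_clock_hour": patient.admission_clock_hour}
        record.update({f"param_{k}": v for k, v in asdict(patient.params).items()})
        patients.append(record)
        if keep_trajectories:
            runs.append(run)
    out = {"measurements": measurements, "infusions": infusions, "patients": patients}
    if keep_trajectories:
        out["runs"] = runs
    return out
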