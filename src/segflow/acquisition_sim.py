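"""Simulator of the automated bioreactor-cytometer sampling interface.

The physical interface is two peristaltic pumps feeding a T-mixer: a
sampling pump draws culture from the reactor, a dilution pump drives
PI-laden diluent (stain in the reservoir at 10 mg/L), and the mixed,
diluted, stained stream reaches the cytometer, which records events for up
to one minute or 40,000 events on a 15-minute cycle.

Dilution model: equal co-pumping of two 32 mL/min pumps gives only a fixed
2× dilution, which cannot bring a dense culture (10^9 cells/mL and up)
into the instrument's linear range (< 3·10^6 cells/mL). The pump
sequencing is therefore modelled as duty-cycle modulation of the sampling
pump — intermittent sample injection into the continuous diluent flow —
so the effective diluted density is

    ρ_diluted = ρ_reactor · (d·Q_s) / (d·Q_s + Q_d)

with duty cycle d ∈ (0, 1]. This is an interpretation of the published
sequencing, not a documented fact about the hardware; tubing geometry is
not modelled.

The PI contact time is realized as an explicit stain-hold stage whose
length enforces the 3-minute minimum; a line flush is always scheduled
before acquisition (cross-contamination itself is not simulated). Event
arrival at the detector is Poisson; when driven by a simulated culture the
rate is diluted density × cytometer flow rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Union

import numpy as np
import pandas as pd

from .fcs_io import AcquisitionMeta, EventTable

__all__ = [
    "SamplerConfig",
    "SamplingSchedule",
    "ScheduledAction",
    "InfeasibleDilutionError",
    "InfeasibleScheduleError",
    "InvalidRateError",
    "ResidenceTimes",
    "plan_cycle",
    "acquire",
    "arrival_rate_from_density",
    "residence_times",
]


class InfeasibleDilutionError(ValueError):
    """No duty cycle within bounds reaches the target density."""

    def __init__(self, message: str, required_predilution: float):
        super().__init__(message)
        #: factor by which the sample must be pre-diluted before the
        #: in-line system can reach the linear range
        self.required_predilution = required_predilution


class InfeasibleScheduleError(ValueError):
    """The planned actions do not fit in the cycle period."""


class InvalidRateError(ValueError):
    pass


@dataclass(frozen=True)
class SamplerConfig:
    """Automated sampling interface settings (defaults = the published rig)."""

    sampling_pump_ml_min: float = 32.0
    dilution_pump_ml_min: float = 32.0
    cycle_period_min: float = 15.0
    fc_flow_ul_min: float = 33.0
    acquisition_duration_s: float = 60.0
    event_cap: int = 40_000
    target_max_density: float = 3.0e6  # cells/mL, linear-range ceiling
    pi_concentration_mg_l: float = 10.0
    min_contact_time_min: float = 3.0
    # lower bound sized so a stationary-phase E. coli culture (up to
    # ~1e10 cells/mL) can still be brought into the linear range in one pass
    duty_cycle_bounds: tuple[float, float] = (2e-4, 1.0)
    # fixed stage durations (s); the stain-hold stretches to meet the
    # contact-time minimum
    fill_line_s: float = 15.0
    mix_s: float = 30.0
    flush_s: float = 120.0

    def __post_init__(self) -> None:
        for name in ("sampling_pump_ml_min", "dilution_pump_ml_min", "fc_flow_ul_min",
                     "cycle_period_min", "target_max_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_contact_time_min < 0:
            raise ValueError("min contact time must be >= 0")
        lo, hi = self.duty_cycle_bounds
        if not 0 < lo <= hi <= 1:
            raise ValueError(f"duty cycle bounds must satisfy 0 < lo <= hi <= 1, got {self.duty_cycle_bounds}")


class ScheduledAction(NamedTuple):
    action: str
    start_s: float
    stop_s: float


@dataclass(frozen=True)
class SamplingSchedule:
    """Timed pump/stain/acquire plan for one cycle."""

    actions: tuple[ScheduledAction, ...]
    duty_cycle: float
    dilution_factor: float
    contact_time_min: float
    diluted_density: float  # cells/mL predicted at the cytometer

    def __post_init__(self) -> None:
        for a, b in zip(self.actions, self.actions[1:]):
            if b.start_s < a.stop_s - 1e-9:
                raise ValueError(f"overlapping actions {a} and {b}")

    def total_s(self) -> float:
        return self.actions[-1].stop_s if self.actions else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.actions, columns=["action", "start_s", "stop_s"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _diluted_density(reactor_density: float, duty: float, config: SamplerConfig) -> float:
    qs = duty * config.sampling_pump_ml_min
    return reactor_density * qs / (qs + config.dilution_pump_ml_min)


def plan_cycle(config: SamplerConfig, reactor_density: float) -> SamplingSchedule:
    """Plan one sampling cycle for the given culture density.

    Chooses the largest duty cycle within bounds whose predicted diluted
    density stays at or below the linear-range target, schedules the
    stain-hold to meet the PI contact-time minimum, and verifies the cycle
    fits its period. Deterministic in (config, density).
    """
    if reactor_density <= 0:
        raise ValueError(f"reactor density must be > 0, got {reactor_density}")
    lo, hi = config.duty_cycle_bounds
    target = config.target_max_density
    if _diluted_density(reactor_density, hi, config) <= target:
        duty = hi
    else:
        # invert rho*(d*Qs)/(d*Qs+Qd) = target for d
        duty = (
            target * config.dilution_pump_ml_min
            / (config.sampling_pump_ml_min * (reactor_density - target))
        )
        if duty < lo:
            achievable = _diluted_density(reactor_density, lo, config)
            required = achievable / target
            raise InfeasibleDilutionError(
                f"density {reactor_density:.3g} cells/mL needs duty cycle "
                f"{duty:.3g} below the bound {lo}; pre-dilute the sample "
                f"{required:.3g}-fold",
                required_predilution=required,
            )
    predicted = _diluted_density(reactor_density, duty, config)
    qs = duty * config.sampling_pump_ml_min
    dilution_factor = (qs + config.dilution_pump_ml_min) / qs

    hold_s = max(config.min_contact_time_min * 60.0, 0.0)
    t = 0.0
    actions = []
    for name, dur in (
        ("fill-line", config.fill_line_s),
        ("co-pump-dilute", config.mix_s),
        ("stain-hold", hold_s),
        ("acquire", config.acquisition_duration_s),
        ("flush", config.flush_s),
    ):
        actions.append(ScheduledAction(name, t, t + dur))
        t += dur
    if t > config.cycle_period_min * 60.0:
        raise InfeasibleScheduleError(
            f"cycle needs {t:.0f}s but the period is {config.cycle_period_min * 60:.0f}s"
        )
    return SamplingSchedule(
        actions=tuple(actions),
        duty_cycle=duty,
        dilution_factor=dilution_factor,
        contact_time_min=hold_s / 60.0,
        diluted_density=predicted,
    )


EventSource = Union[EventTable, Callable[[int, int], EventTable]]


def acquire(
    source: EventSource,
    config: SamplerConfig,
    arrival_rate: float,
    seed: int,
    time_h: float | None = None,
) -> EventTable:
    """Simulate one capped acquisition from an event source.

    The number of detector events over the acquisition window is Poisson
    with mean ``arrival_rate × duration``; recording stops at the event
    cap, and the truncated flag is set iff the cap was reached. ``source``
    is either an :class:`EventTable` (rows resampled with replacement) or
    a callable ``(n, seed) -> EventTable`` such as a closure over
    :func:`segflow.popdyn.sample_events`.
    """
    if arrival_rate < 0:
        raise InvalidRateError(f"arrival rate must be >= 0, got {arrival_rate}")
    rng = np.random.default_rng(seed)
    n_arrived = int(rng.poisson(arrival_rate * config.acquisition_duration_s))
    truncated = n_arrived >= config.event_cap
    n = min(n_arrived, config.event_cap)

    if n == 0:
        if isinstance(source, EventTable):
            events = source.events.iloc[0:0].copy()
        else:
            events = source(1, 0).events.iloc[0:0].copy()
    elif isinstance(source, EventTable):
        if source.n_events == 0:
            raise ValueError("cannot acquire from an empty source table")
        idx = rng.integers(0, source.n_events, size=n)
        events = source.events.iloc[idx].reset_index(drop=True)
    else:
        child_seed = int(rng.integers(0, 2**31 - 1))
        drawn = source(n, child_seed)
        events = drawn.events.reset_index(drop=True)
        if time_h is None:
            time_h = drawn.meta.time_h

    meta = AcquisitionMeta(
        time_h=time_h,
        duration_s=config.acquisition_duration_s,
        flow_rate_ul_min=config.fc_flow_ul_min,
        event_cap=config.event_cap,
        truncated=truncated,
    )
    return EventTable(events=events, meta=meta)


def arrival_rate_from_density(diluted_density: float, config: SamplerConfig) -> float:
    """Detector event rate (events/s) for a diluted sample.

    rate = density (cells/mL) × FC flow (μL/min → mL/s).
    """
    ml_per_s = config.fc_flow_ul_min * 1e-3 / 60.0
    return diluted_density * ml_per_s


class ResidenceTimes(NamedTuple):
    volumes: float
    nearest: int


def residence_times(stabilization_time_h: float, dilution_rate: float) -> ResidenceTimes:
    """Reactor volumes exchanged during a chemostat stabilization.

    volumes = t × D (e.g. 43 h at D = 0.14 h⁻¹ → 6.02, nearest 6).
    """
    if dilution_rate <= 0:
        raise InvalidRateError(f"dilution rate must be > 0, got {dilution_rate}")
    if stabilization_time_h < 0:
        raise ValueError("stabilization time must be >= 0")
    volumes = stabilization_time_h * dilution_rate
    return ResidenceTimes(volumes=volumes, nearest=int(round(volumes)))
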