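"""Pulse dosing of an antibody-drug conjugate (ADC) with first-order decay.

The drug is administered as instantaneous boluses (tail-vein injections) on a
fixed schedule and is eliminated with first-order kinetics at rate ``lam``
(day^-1).  Between boluses the drug mass A(t) therefore decays exponentially;
at each dose time it jumps up by the administered mass.  The quantity that
drives tumor kill in the growth model is the cumulative exposure
``E(t) = integral of A from 0 to t`` (mg*day), which has a closed form.

Conventions: time is measured in days, drug mass in mg.  A(t) is
right-continuous at dose instants — the value *at* a dose time includes the
bolus just given.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DoseSchedule",
    "weekly_schedule",
    "drug_concentration",
    "cumulative_exposure",
    "dose_from_body_weight",
    "decay_rate_from_half_life",
    "DEFAULT_DOSE_MG",
    "DEFAULT_DECAY_RATE",
]

#: Bolus mass for a 5 mg/kg dose in a 20 g animal.
DEFAULT_DOSE_MG = 0.1

#: First-order elimination rate for a 7-day drug half-life (day^-1).
DEFAULT_DECAY_RATE = float(np.log(2) / 7.0)


def dose_from_body_weight(dose_mg_per_kg: float, body_weight_g: float) -> float:
    """Bolus drug mass (mg) for a weight-adjusted dose.

    Parameters
    ----------
    dose_mg_per_kg : dose level in mg per kg body weight.
    body_weight_g : body weight in grams.
    """
    if dose_mg_per_kg < 0 or body_weight_g <= 0:
        raise ValueError("dose must be >= 0 and body weight > 0")
    return dose_mg_per_kg * body_weight_g / 1000.0


def decay_rate_from_half_life(half_life_days: float) -> float:
    """First-order decay rate (day^-1) from a half-life in days."""
    if half_life_days <= 0:
        raise ValueError("half-life must be positive")
    return float(np.log(2) / half_life_days)


@dataclass(frozen=True)
class DoseSchedule:
    """Timing and mass of ADC boluses.

    Parameters
    ----------
    dose_mass_per_admin
        Drug mass (mg) per administration.  A scalar applies the same mass to
        every dose; a sequence gives one entry per dose.
    first_dose_day
        Day of the first dose (n = 1).
    interval_days
        Spacing between consecutive doses (days).
    n_doses
        Number of doses N.  ``n_doses = 0`` is a valid no-treatment schedule.
    """

    dose_mass_per_admin: float | tuple[float, ...] = DEFAULT_DOSE_MG
    first_dose_day: float = 7.0
    interval_days: float = 7.0
    n_doses: int = 12
    _masses: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.interval_days <= 0:
            raise ValueError("interval_days must be > 0")
        if self.n_doses < 0:
            raise ValueError("n_doses must be >= 0")
        masses = np.broadcast_to(
            np.atleast_1d(np.asarray(self.dose_mass_per_admin, dtype=float)),
            (self.n_doses,),
        ).copy() if self.n_doses else np.empty(0)
        if np.any(masses < 0):
            raise ValueError("dose masses must be >= 0")
        object.__setattr__(self, "_masses", masses)

    @property
    def dose_times(self) -> np.ndarray:
        """Days of administration: first_dose_day + (n-1)*interval_days."""
        return self.first_dose_day + self.interval_days * np.arange(self.n_doses)

    @property
    def dose_masses(self) -> np.ndarray:
        """Per-dose bolus masses (mg), one entry per dose."""
        return self._masses

    @property
    def total_mass(self) -> float:
        return float(self._masses.sum())

    def anchored_at(self, first_dose_day: float) -> "DoseSchedule":
        """Copy of this schedule with the first dose moved to a new day."""
        return DoseSchedule(
            dose_mass_per_admin=self.dose_mass_per_admin,
            first_dose_day=float(first_dose_day),
            interval_days=self.interval_days,
            n_doses=self.n_doses,
        )


def weekly_schedule(
    n_doses: int = 12,
    dose_mg: float = DEFAULT_DOSE_MG,
    first_dose_day: float = 7.0,
) -> DoseSchedule:
    """Weekly bolus schedule (the experimental regimen: every 7 days)."""
    return DoseSchedule(
        dose_mass_per_admin=dose_mg,
        first_dose_day=first_dose_day,
        interval_days=7.0,
        n_doses=n_doses,
    )


def _check_times(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time not allowed")
    return t


def drug_concentration(schedule: DoseSchedule, lam: float, t) -> np.ndarray | float:
    """Drug mass A(t) in mg under pulse dosing with first-order decay.

    ``A(t) = sum_n A_dose(n) * exp(-lam*(t - t_n))`` over doses with
    ``t_n <= t``; right-continuous at dose times.
    """
    t = _check_times(t)
    scalar = t.ndim == 0
    tt = np.atleast_1d(t)
    times = schedule.dose_times
    masses = schedule.dose_masses
    dt = tt[:, None] - times[None, :]
    contrib = np.where(dt >= 0, masses[None, :] * np.exp(-lam * np.maximum(dt, 0.0)), 0.0)
    out = contrib.sum(axis=1)
    return float(out[0]) if scalar else out


def cumulative_exposure(schedule: DoseSchedule, lam: float, t) -> np.ndarray | float:
    """Cumulative drug exposure E(t) = integral_0^t A(s) ds (mg*day).

    Closed form ``E(t) = sum_n (A_dose(n)/lam) * (1 - exp(-lam*(t - t_n)))``
    over doses with ``t_n <= t``.  Non-decreasing in t, with limit
    (total dosed mass)/lam as t -> infinity.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0 (zero/negative decay not supported)")
    t = _check_times(t)
    scalar = t.ndim == 0
    tt = np.atleast_1d(t)
    times = schedule.dose_times
    masses = schedule.dose_masses
    dt = tt[:, None] - times[None, :]
    contrib = np.where(
        dt >= 0, (masses[None, :] / lam) * (-np.expm1(-lam * np.maximum(dt, 0.0))), 0.0
    )
    out = contrib.sum(axis=1)
    return float(out[0]) if scalar else out
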