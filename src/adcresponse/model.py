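"""Two-subpopulation tumor growth model under pulse-dosed ADC therapy.

The tumor consists of a high-sensitivity population H and a low-sensitivity
population L, both proliferating exponentially at net rate ``rho`` and killed
by the drug A in proportion to the exposed fraction ``gamma`` and their kill
rates ``mu_H`` and ``mu_L = z * mu_H``:

    dH/dt = rho*H - gamma*mu_H*A*H
    dL/dt = rho*L - gamma*z*mu_H*A*L
    dA/dt = (boluses) - lam*A

Because the kill terms are linear in A, the system integrates in closed form
in terms of the cumulative exposure E(t) = int_0^t A ds:

    H(t) = (1-q)*C0*exp(rho*t - gamma*mu_H*E(t))
    L(t) =     q*C0*exp(rho*t - gamma*z*mu_H*E(t))

with q = L0/C0 the initially low-sensitive fraction.  The observable is the
total C = H + L (bioluminescence flux is proportional to cell number).  The
closed form is the workhorse; a direct ODE integration is provided as an
independent numerical cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dosing import DEFAULT_DECAY_RATE, DoseSchedule, cumulative_exposure, drug_concentration

__all__ = [
    "ModelParams",
    "Trajectory",
    "analytic_trajectory",
    "numeric_trajectory",
    "log_total_cells",
    "log_frac_low",
]


@dataclass(frozen=True)
class ModelParams:
    """Biological/pharmacological constants for one subject.

    Attributes
    ----------
    rho : net proliferation rate (day^-1).
    mu_H : ADC kill rate of high-sensitivity cells (mg^-1 day^-1).
    z : relative sensitivity mu_L/mu_H, in [0, 1].
    q : initially low-sensitive fraction L0/C0, in [0, 1].
    gamma : fraction of tumor exposed to drug, in [0, 1] (1 in the flank,
        <= 1 intracranially where the blood-brain barrier limits delivery).
    lam : drug decay rate (day^-1), default ln(2)/7 for a 7-day half-life.
    C0 : initial tumor signal (cells, or flux-scale equivalent).
    """

    rho: float
    mu_H: float
    z: float
    q: float
    gamma: float = 1.0
    lam: float = DEFAULT_DECAY_RATE
    C0: float = 1e4

    def __post_init__(self) -> None:
        if self.rho < 0 or self.mu_H < 0:
            raise ValueError("rho and mu_H must be >= 0")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.C0 <= 0:
            raise ValueError("C0 must be > 0")
        for name in ("z", "q", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def mu_L(self) -> float:
        """Kill rate of the low-sensitivity population, z * mu_H."""
        return self.z * self.mu_H


_CSV_COLUMNS = ["day", "H", "L", "A", "C", "frac_low"]


@dataclass(frozen=True)
class Trajectory:
    """Time-gridded model state: H, L, drug A, total C = H + L, and L/C."""

    times: np.ndarray
    H: np.ndarray
    L: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "H", "L", "A"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.times.shape[0]
        if not all(getattr(self, k).shape == (n,) for k in ("H", "L", "A")):
            raise ValueError("times, H, L, A must have identical 1-d shapes")
        if np.any(self.H < 0) or np.any(self.L < 0) or np.any(self.A < 0):
            raise ValueError("H, L, A must be non-negative")

    @property
    def C(self) -> np.ndarray:
        """Total cell number, H + L."""
        return self.H + self.L

    @property
    def frac_low(self) -> np.ndarray:
        """Low-sensitivity fraction L/C."""
        return self.L / self.C

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.times,
                "H": self.H,
                "L": self.L,
                "A": self.A,
                "C": self.C,
                "frac_low": self.frac_low,
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "Trajectory":
        df = pd.read_csv(path_or_buf)
        if list(df.columns) != _CSV_COLUMNS:
            raise ValueError(f"expected columns {_CSV_COLUMNS}, got {list(df.columns)}")
        if df.isna().any().any():
            raise ValueError("missing values are not allowed in trajectory files")
        return cls(
            times=df["day"].to_numpy(),
            H=df["H"].to_numpy(),
            L=df["L"].to_numpy(),
            A=df["A"].to_numpy(),
        )


def _check_grid(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-d grid")
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted and non-negative")
    return t


def log_total_cells(rho, mu_H, z, q, gamma, C0, exposure, t):
    """log C(t) for (broadcastable) parameter arrays and exposure E(t).

    Evaluated in log space so ensembles spanning many decades neither
    overflow nor underflow.  All arguments broadcast together.
    """
    q = np.clip(np.asarray(q, dtype=float), 1e-300, 1.0 - 1e-16)
    kill = gamma * mu_H * exposure
    return (
        np.log(C0)
        + rho * t
        + np.logaddexp(np.log1p(-q) - kill, np.log(q) - z * kill)
    )


def log_frac_low(mu_H, z, q, gamma, exposure):
    """log of the low-sensitivity fraction L/C.

    log(L/C) = -log(1 + ((1-q)/q) * exp(-gamma*(1-z)*mu_H*E)).
    """
    q = np.clip(np.asarray(q, dtype=float), 1e-300, 1.0 - 1e-16)
    gap = gamma * (1.0 - z) * mu_H * exposure
    # log(H/L) = log((1-q)/q) - gap; frac_low = sigmoid(-log(H/L))
    log_h_over_l = np.log1p(-q) - np.log(q) - gap
    return -np.logaddexp(0.0, log_h_over_l)


def analytic_trajectory(params: ModelParams, schedule: DoseSchedule, times) -> Trajectory:
    """Closed-form solution of the growth/kill system on a time grid.

    H(t) = (1-q) C0 exp(rho t - gamma mu_H E(t)),
    L(t) = q C0 exp(rho t - gamma z mu_H E(t)), with E the cumulative drug
    exposure; A(t) follows the pulse-decay closed form.
    """
    t = _check_grid(times)
    E = np.asarray(cumulative_exposure(schedule, params.lam, t))
    growth = params.rho * t
    kill = params.gamma * params.mu_H * E
    H = (1.0 - params.q) * params.C0 * np.exp(growth - kill)
    L = params.q * params.C0 * np.exp(growth - params.z * kill)
    A = np.asarray(drug_concentration(schedule, params.lam, t))
    return Trajectory(times=t, H=H, L=L, A=A)


def numeric_trajectory(
    params: ModelParams,
    schedule: DoseSchedule,
    times,
    rtol: float = 1e-9,
) -> Trajectory:
    """Direct ODE integration of the coupled system; oracle for the closed form.

    Integrates piecewise between dose times (the bolus is a state jump
    ``A <- A + dose`` at each administration, so each segment is smooth and
    the adaptive integrator never steps across an impulse).
    """
    t = _check_grid(times)
    kill_H = params.gamma * params.mu_H
    kill_L = params.gamma * params.z * params.mu_H

    def rhs(_t, y):
        H, L, A = y
        return [
            params.rho * H - kill_H * A * H,
            params.rho * L - kill_L * A * L,
            -params.lam * A,
        ]

    dose_times = schedule.dose_times
    dose_masses = schedule.dose_masses
    t_end = t[-1]
    # segment boundaries: 0, each dose time in (0, t_end], t_end
    cuts = [0.0]
    jumps: dict[float, float] = {}
    for td, m in zip(dose_times, dose_masses):
        if td <= t_end:
            jumps[float(td)] = jumps.get(float(td), 0.0) + float(m)
    cuts.extend(td for td in sorted(jumps) if td > 0.0)
    if t_end > cuts[-1]:
        cuts.append(float(t_end))

    y = np.array([(1.0 - params.q) * params.C0, params.q * params.C0, 0.0])
    if cuts[0] in jumps:
        y[2] += jumps[cuts[0]]
    H_out = np.empty_like(t)
    L_out = np.empty_like(t)
    A_out = np.empty_like(t)
    # grid points at exactly t=0 before any dose
    mask0 = t == 0.0
    H_out[mask0], L_out[mask0], A_out[mask0] = y

    for a, b in zip(cuts[:-1], cuts[1:]):
        # right-continuity: a grid point at a dose time reports the post-dose
        # state, so it belongs to the segment starting at that dose.
        inside = (t >= a) & (t < b) if b < t_end else (t >= a) & (t <= b)
        eval_pts = t[inside & (t > a)]
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method="LSODA",
            rtol=rtol,
            # near-pure relative control: populations can transit very deep
            # troughs (strong kill) and regrow, so the absolute floor must sit
            # far below any trough that later matters
            atol=[1e-60 * params.C0, 1e-60 * params.C0, 1e-18],
            t_eval=np.concatenate([eval_pts, [b]]) if eval_pts.size == 0 or eval_pts[-1] < b else eval_pts,
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on segment [{a}, {b}]: {sol.message}")
        if eval_pts.size:
            k = eval_pts.size
            H_out[inside & (t > a)] = sol.y[0, :k]
            L_out[inside & (t > a)] = sol.y[1, :k]
            A_out[inside & (t > a)] = sol.y[2, :k]
        y = sol.y[:, -1].copy()
        if b in jumps:
            y[2] += jumps[b]
            at_dose = t == b
            H_out[at_dose], L_out[at_dose], A_out[at_dose] = y

    return Trajectory(times=t, H=np.maximum(H_out, 0.0), L=np.maximum(L_out, 0.0), A=np.maximum(A_out, 0.0))
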