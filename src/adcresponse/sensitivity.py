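"""Global sensitivity analysis: Latin hypercube sampling and time-resolved
partial rank correlation coefficients (PRCC).

The parameter space of the growth/kill model is explored with a Latin
hypercube design — for each parameter, exactly one draw falls in each of n
equiprobable strata of its marginal distribution, and the strata are paired
randomly across parameters.  Each sampled parameter set is pushed through the
closed-form model, and for every time point the PRCC between each parameter
and an outcome (total cells, or the low-sensitivity fraction L/C) is the
correlation of the rank residuals after linearly removing the rank effects of
all other sampled parameters.  |PRCC| below 0.5 is conventionally read as a
weak monotone association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dosing import DEFAULT_DECAY_RATE, DoseSchedule, cumulative_exposure

__all__ = [
    "ParamDistribution",
    "LHSDesign",
    "EnsembleOutcomes",
    "PRCCSeries",
    "default_lhs_distributions",
    "lhs_sample",
    "run_ensemble",
    "rank_transform",
    "prcc",
    "prcc_over_time",
    "MODEL_PARAMETERS",
]

#: parameter order expected by the model ensemble
MODEL_PARAMETERS = ("rho", "mu_H", "z", "q", "gamma", "C0")


@dataclass(frozen=True)
class ParamDistribution:
    """Marginal sampling distribution for one model parameter.

    kind 'uniform' draws uniformly on [lo, hi]; 'loguniform' uniformly in
    log10 on [lo, hi] (lo > 0).  lo == hi denotes a degenerate (constant)
    parameter, allowed for plain sampling but not for Latin hypercube
    stratification.
    """

    name: str
    kind: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "loguniform"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.lo > self.hi:
            raise ValueError(f"{self.name}: lo must be <= hi")
        if self.kind == "loguniform" and self.lo <= 0:
            raise ValueError(f"{self.name}: loguniform requires lo > 0")

    def ppf(self, u):
        """Quantile function: map u in [0, 1] to the parameter scale."""
        u = np.asarray(u, dtype=float)
        if self.kind == "uniform":
            return self.lo + (self.hi - self.lo) * u
        llo, lhi = np.log10(self.lo), np.log10(self.hi)
        return 10.0 ** (llo + (lhi - llo) * u)

    def sample(self, rng: np.random.Generator, size=None):
        return self.ppf(rng.uniform(size=size))


def default_lhs_distributions() -> list[ParamDistribution]:
    """Default sampled distributions for the sensitivity study.

    Unitless parameters (gamma, z, q) are uniform on [0, 1]; rho and mu_H
    are uniform over their tabulated ranges; C0 is log-uniform inside its
    fitting bound, with the upper end kept low enough that day-150 burdens
    stay finite in double precision.
    """
    return [
        ParamDistribution("rho", "uniform", 0.2, 0.5),
        ParamDistribution("mu_H", "uniform", 1.0, 10.0),
        ParamDistribution("z", "uniform", 0.0, 1.0),
        ParamDistribution("q", "uniform", 0.0, 1.0),
        ParamDistribution("gamma", "uniform", 0.0, 1.0),
        ParamDistribution("C0", "loguniform", 1e2, 1e6),
    ]


@dataclass(frozen=True)
class LHSDesign:
    """A realised Latin hypercube sample."""

    sample_matrix: np.ndarray  # n_samples x n_parameters
    parameter_order: tuple[str, ...]
    seed: int | None

    @property
    def n_samples(self) -> int:
        return int(self.sample_matrix.shape[0])

    def column(self, name: str) -> np.ndarray:
        return self.sample_matrix[:, self.parameter_order.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sample_matrix, columns=list(self.parameter_order))


def lhs_sample(
    distributions: list[ParamDistribution],
    n: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> LHSDesign:
    """Latin hypercube sample: one draw per equiprobable stratum per parameter.

    Each parameter's unit interval is split into n strata; a uniform draw is
    taken inside each stratum (not the midpoint) and the strata are permuted
    independently per parameter, which realises the random pairing.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not distributions:
        raise ValueError("at least one distribution required")
    for d in distributions:
        if d.lo >= d.hi:
            raise ValueError(f"{d.name}: LHS requires lo < hi")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = []
    for _d in distributions:
        strata = rng.permutation(n)
        u = (strata + rng.uniform(size=n)) / n
        cols.append(u)
    matrix = np.column_stack(
        [d.ppf(u) for d, u in zip(distributions, cols)]
    )
    return LHSDesign(
        sample_matrix=matrix,
        parameter_order=tuple(d.name for d in distributions),
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


#: reported cell counts are clipped at this value; log outcomes are exact
OVERFLOW_CLIP = 1e300


@dataclass(frozen=True)
class EnsembleOutcomes:
    """Model outcomes for every LHS sample on a shared time grid."""

    times: np.ndarray
    log_total_cells: np.ndarray  # natural log, n_samples x n_times
    frac_low: np.ndarray  # n_samples x n_times

    @property
    def total_cells(self) -> np.ndarray:
        """C(t), clipped at OVERFLOW_CLIP (see overflow_mask)."""
        with np.errstate(over="ignore"):
            return np.minimum(np.exp(self.log_total_cells), OVERFLOW_CLIP)

    @property
    def overflow_mask(self) -> np.ndarray:
        """True where total_cells was clipped to stay finite."""
        return self.log_total_cells > np.log(OVERFLOW_CLIP)


def run_ensemble(
    design: LHSDesign,
    schedule: DoseSchedule,
    times,
    lam: float = DEFAULT_DECAY_RATE,
) -> EnsembleOutcomes:
    """Evaluate the closed-form model at every design point.

    The drug decay rate lam is a known constant, supplied separately from
    the sampled parameters.  Outcomes are computed in log space, so the
    ensemble never fails on overflow; linear-scale cell counts are clipped
    on access and flagged.
    """
    from .model import log_frac_low, log_total_cells  # local import to avoid cycle

    missing = set(MODEL_PARAMETERS) - set(design.parameter_order)
    if missing:
        raise ValueError(f"design is missing model parameters: {sorted(missing)}")
    t = np.asarray(times, dtype=float)
    E = np.asarray(cumulative_exposure(schedule, lam, t))
    rho = design.column("rho")[:, None]
    mu_H = design.column("mu_H")[:, None]
    z = design.column("z")[:, None]
    q = design.column("q")[:, None]
    gamma = design.column("gamma")[:, None]
    C0 = design.column("C0")[:, None]
    logC = log_total_cells(rho, mu_H, z, q, gamma, C0, E[None, :], t[None, :])
    fl = np.exp(log_frac_low(mu_H, z, q, gamma, E[None, :]))
    return EnsembleOutcomes(times=t, log_total_cells=logC, frac_low=fl)


def rank_transform(values) -> np.ndarray:
    """Ranks 1..n with average ranks assigned to ties."""
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("cannot rank an empty vector")
    return rankdata(values, axis=0)


def _partial_residual(x: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    Z = np.column_stack([np.ones(len(x)), covariates])
    beta, *_ = np.linalg.lstsq(Z, x, rcond=None)
    return x - Z @ beta


def prcc(design: LHSDesign | np.ndarray, outcome, parameter_order=None) -> dict[str, float]:
    """Partial rank correlation of each parameter with one outcome vector.

    For parameter j: rank-transform every column and the outcome, regress
    both the parameter ranks and the outcome ranks on all other parameters'
    ranks, and correlate the two residual vectors.
    """
    if isinstance(design, LHSDesign):
        X = design.sample_matrix
        names = design.parameter_order
    else:
        X = np.asarray(design, dtype=float)
        names = tuple(parameter_order) if parameter_order else tuple(
            f"x{j}" for j in range(X.shape[1])
        )
    y = np.asarray(outcome, dtype=float)
    n, d = X.shape
    if y.shape != (n,):
        raise ValueError("outcome length must equal the number of samples")
    if n <= d + 2:
        raise ValueError("need n_samples > n_parameters + 2")
    R = rank_transform(X)
    if np.linalg.matrix_rank(R - R.mean(axis=0)) < d:
        raise ValueError("rank-deficient covariate matrix (duplicated or constant columns)")
    if np.ptp(y) == 0:
        warnings.warn("outcome has zero variance; PRCC undefined", stacklevel=2)
        return {name: float("nan") for name in names}
    ry = rank_transform(y)
    out: dict[str, float] = {}
    for j, name in enumerate(names):
        others = np.delete(R, j, axis=1)
        rx_res = _partial_residual(R[:, j], others)
        ry_res = _partial_residual(ry, others)
        denom = np.linalg.norm(rx_res) * np.linalg.norm(ry_res)
        out[name] = float(np.dot(rx_res, ry_res) / denom) if denom > 0 else float("nan")
    return out


@dataclass(frozen=True)
class PRCCSeries:
    """Per-parameter PRCC as a function of simulation time for one outcome."""

    times: np.ndarray
    outcome_label: str
    coefficients: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        """Long format: day, outcome, parameter, prcc."""
        frames = [
            pd.DataFrame(
                {
                    "day": self.times,
                    "outcome": self.outcome_label,
                    "parameter": name,
                    "prcc": series,
                }
            )
            for name, series in self.coefficients.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def at_day(self, day: float) -> dict[str, float]:
        idx = int(np.argmin(np.abs(self.times - day)))
        if abs(self.times[idx] - day) > 1e-9:
            raise ValueError(f"day {day} not on the evaluation grid")
        return {name: float(series[idx]) for name, series in self.coefficients.items()}


def prcc_over_time(
    design: LHSDesign,
    schedule: DoseSchedule,
    times,
    lam: float = DEFAULT_DECAY_RATE,
) -> tuple[PRCCSeries, PRCCSeries]:
    """PRCC of every parameter against both outcomes at each time point.

    Returns (total_cells series, frac_low series).  Time points where an
    outcome has zero variance across samples yield NaN coefficients.
    """
    ens = run_ensemble(design, schedule, times, lam=lam)
    names = design.parameter_order
    out = {}
    for label, matrix in (
        ("total_cells", ens.log_total_cells),
        ("frac_low", ens.frac_low),
    ):
        coeffs = {name: np.empty(ens.times.size) for name in names}
        for k in range(ens.times.size):
            col = matrix[:, k]
            if np.ptp(col) == 0:
                vals = {name: float("nan") for name in names}
                warnings.warn(
                    f"outcome {label} has zero variance at day {ens.times[k]:g}; PRCC undefined",
                    stacklevel=2,
                )
            else:
                vals = prcc(design, col)
            for name in names:
                coeffs[name][k] = vals[name]
        out[label] = PRCCSeries(times=ens.times, outcome_label=label, coefficients=coeffs)
    return out["total_cells"], out["frac_low"]
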