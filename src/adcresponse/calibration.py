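"""Staged nonlinear least-squares calibration of the growth/kill model.

The experimental design identifies parameters in three steps, each fitting at
most three free parameters to one arm of the cohort:

1. *Untreated* series (both sites): with no drug the model reduces to pure
   exponential growth ``C(t) = C0*exp(rho*t)``; per-subject fits give rho and
   C0, and the per-site mean rho is pooled.
2. *Treated flank* series: the flank has no blood-brain barrier, so the
   exposed fraction is fixed at ``gamma = 1``; with the pooled flank rho
   passed in and C0 anchored to the first pre-treatment observation, the fit
   estimates the kill rate ``mu_H``, the relative sensitivity ``z``, and the
   initially resistant fraction ``q``.  The mean mu_H is pooled.
3. *Treated intracranial* series: with the pooled intracranial rho and the
   pooled flank mu_H both fixed, the fit estimates the exposed fraction
   ``gamma`` (the barrier effect), plus ``z`` and ``q``.

Within one site gamma and mu_H enter the model only through their product,
so they are not separately identifiable from a single series — the staged
design resolves the confound by anchoring mu_H in the barrier-free flank.

Each step runs from several starting points spread across the bounded
parameter box (a multistart policy standing in for an interactive choice of
initial guesses); the lowest-residual solution wins and the spread of
estimates across starts is reported as a convergence diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .cohort import SubjectSeries
from .dosing import DoseSchedule, cumulative_exposure
from .model import log_total_cells

__all__ = [
    "FitParam",
    "StepFitResult",
    "CohortCalibration",
    "ExponentialGrowthModel",
    "TreatedResponseModel",
    "multistart_least_squares",
    "fit_untreated",
    "pool_growth_rate",
    "infer_C0",
    "fit_treated_flank",
    "fit_treated_ic",
    "run_pipeline",
]

LN10 = float(np.log(10.0))

#: fitting bounds used by the staged pipeline
RHO_BOUNDS = (0.0, np.inf)
RHO_SURROGATE_UPPER = 5.0  # optimizer surrogate for the unbounded rho upper limit
C0_BOUNDS = (1e2, 1e10)
MU_H_BOUNDS = (1.0, 10.0)
Z_BOUNDS = (0.0, 1.0)
Q_BOUNDS = (1e-10, 1e-2)
GAMMA_BOUNDS = (0.0, 1.0)

#: multistart policy: low-quartile, midpoint, high-quartile of each interval
START_FRACTIONS = (0.25, 0.5, 0.75)

_OPT_TOL = 1e-12


@dataclass(frozen=True)
class FitParam:
    """One free parameter of a least-squares step.

    Parameters spanning decades (C0, q) are optimised on the log10 scale;
    bounds and reported estimates stay on the natural scale.
    """

    name: str
    lo: float
    hi: float
    log10: bool = False

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"{self.name}: lo must be < hi")
        if self.log10 and self.lo <= 0:
            raise ValueError(f"{self.name}: log-scale parameter requires lo > 0")

    @property
    def internal_bounds(self) -> tuple[float, float]:
        if self.log10:
            return (np.log10(self.lo), np.log10(self.hi))
        return (self.lo, self.hi)

    def to_natural(self, x: float) -> float:
        return float(10.0**x) if self.log10 else float(x)


@dataclass(frozen=True)
class StepFitResult:
    """Result of one calibration step for one subject.

    Attributes
    ----------
    step_label : 'untreated', 'flank_treated' or 'ic_treated'.
    estimates : fitted parameter name -> value (natural scale).
    bounds_used : per-parameter (lo, hi) on the natural scale.
    residual_norm : sum of squared residuals on the fitting scale.
    converged : True if at least one start converged.
    multistart_spread : max pairwise relative difference of estimates
        across converged starts (0 when all starts agree).
    """

    step_label: str
    estimates: dict[str, float]
    bounds_used: dict[str, tuple[float, float]]
    residual_norm: float
    converged: bool
    multistart_spread: float
    subject_id: str = ""
    site: str = ""
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residual_norm < 0:
            raise ValueError("residual_norm must be >= 0")
        for name, v in self.estimates.items():
            lo, hi = self.bounds_used[name]
            if not (lo - 1e-12 <= v <= hi * (1 + 1e-12) + 1e-12):
                raise ValueError(f"estimate {name}={v} outside its bounds [{lo}, {hi}]")

    def summary(self) -> str:
        lines = [
            f"Step: {self.step_label}   subject: {self.subject_id or '-'}   site: {self.site or '-'}",
            f"converged: {self.converged}   SSR: {self.residual_norm:.6g}   "
            f"multistart spread: {self.multistart_spread:.3g}",
        ]
        for name, v in self.estimates.items():
            lo, hi = self.bounds_used[name]
            lines.append(f"  {name:>6s} = {v:<12.6g} bounds [{lo:g}, {hi:g}]")
        for name, v in self.fixed.items():
            lines.append(f"  {name:>6s} = {v:<12.6g} (fixed)")
        return "\n".join(lines)


def multistart_least_squares(
    residual,
    params: list[FitParam],
    start_fractions: tuple[float, ...] = START_FRACTIONS,
) -> tuple[dict[str, float], float, float, bool]:
    """Bounded least squares from several joint starting points.

    ``residual`` maps a dict of natural-scale parameter values to a residual
    vector.  Starts are placed at the given fractions of each (internal)
    bounded interval — by default the low quartile, midpoint and high
    quartile, jointly.  Returns (best estimates, SSR, spread, converged);
    the lowest-SSR start wins, exact ties going to the earliest start.
    """
    lo = np.array([p.internal_bounds[0] for p in params])
    hi = np.array([p.internal_bounds[1] for p in params])

    def fun(x):
        values = {p.name: p.to_natural(xi) for p, xi in zip(params, x)}
        return np.asarray(residual(values), dtype=float)

    results = []
    for frac in start_fractions:
        x0 = lo + frac * (hi - lo)
        try:
            res = least_squares(
                fun, x0, bounds=(lo, hi), method="trf",
                xtol=_OPT_TOL, ftol=_OPT_TOL, gtol=_OPT_TOL,
            )
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"least-squares start at fraction {frac} failed: {exc}", stacklevel=2)
            continue
        if res.status > 0:
            results.append((2.0 * res.cost, res.x))
    if not results:
        raise RuntimeError("all multistart least-squares attempts failed to converge")
    best_ssr, best_x = min(results, key=lambda r: r[0])
    naturals = [
        np.array([p.to_natural(xi) for p, xi in zip(params, x)]) for _, x in results
    ]
    spread = 0.0
    for i in range(len(naturals)):
        for j in range(i + 1, len(naturals)):
            denom = np.maximum(np.maximum(np.abs(naturals[i]), np.abs(naturals[j])), 1e-300)
            spread = max(spread, float(np.max(np.abs(naturals[i] - naturals[j]) / denom)))
    estimates = {p.name: p.to_natural(xi) for p, xi in zip(params, best_x)}
    return estimates, float(best_ssr), spread, True


def _residual_factory(model_log10, flux: np.ndarray, scale: str):
    """Residuals on log10 flux (default; multiplicative noise) or raw flux."""
    if scale == "log10":
        target = np.log10(flux)
        return lambda values: model_log10(values) - target
    if scale == "raw":
        return lambda values: 10.0 ** model_log10(values) - flux
    raise ValueError(f"unknown fitting scale {scale!r} (use 'log10' or 'raw')")


class ExponentialGrowthModel:
    """Untreated tumor growth, ``C(t) = C0*exp(rho*t)`` (Step 1).

    A Results-style :class:`StepFitResult` comes back from :meth:`fit`.
    rho is bounded below at 0 and unbounded above; the optimizer uses a
    finite surrogate upper limit and warns if the estimate touches it.
    """

    def __init__(self, series: SubjectSeries, scale: str = "log10"):
        if series.arm != "control":
            raise ValueError("Step 1 fits untreated (control) series only")
        if series.n_obs < 3:
            raise ValueError("need at least 3 observations to fit")
        self.series = series
        self.scale = scale

    def fit(self, start_fractions: tuple[float, ...] = START_FRACTIONS) -> StepFitResult:
        t = self.series.times
        params = [
            FitParam("rho", 0.0, RHO_SURROGATE_UPPER),
            FitParam("C0", *C0_BOUNDS, log10=True),
        ]

        def model_log10(v):
            return np.log10(v["C0"]) + v["rho"] * t / LN10

        residual = _residual_factory(model_log10, self.series.flux, self.scale)
        estimates, ssr, spread, converged = multistart_least_squares(
            residual, params, start_fractions
        )
        if estimates["rho"] >= RHO_SURROGATE_UPPER * (1 - 1e-9):
            warnings.warn(
                f"rho estimate reached the internal upper surrogate bound "
                f"{RHO_SURROGATE_UPPER}; the nominal bound is [0, inf)",
                stacklevel=2,
            )
        return StepFitResult(
            step_label="untreated",
            estimates=estimates,
            bounds_used={"rho": RHO_BOUNDS, "C0": C0_BOUNDS},
            residual_norm=ssr,
            converged=converged,
            multistart_spread=spread,
            subject_id=self.series.subject_id,
            site=self.series.site,
        )


class TreatedResponseModel:
    """Treated tumor response under the closed-form kill model (Steps 2-3).

    Flank mode (``mu_H=None``): gamma is fixed at 1 and (mu_H, z, q) are
    free.  Intracranial mode (``mu_H`` given): mu_H is fixed at the pooled
    flank value and (gamma, z, q) are free.  rho is always fixed at the
    pooled site-specific growth rate and C0 is anchored to the first
    pre-treatment observation via :func:`infer_C0`.
    """

    def __init__(
        self,
        series: SubjectSeries,
        rho: float,
        schedule: DoseSchedule,
        mu_H: float | None = None,
        scale: str = "log10",
        include_pretreatment: bool = False,
        lam: float | None = None,
    ):
        if series.arm != "treated":
            raise ValueError("treated-response fits require a treated series")
        self.series = series
        self.rho = float(rho)
        self.schedule = schedule.anchored_at(series.treatment_start_day)
        self.mu_H = None if mu_H is None else float(mu_H)
        self.scale = scale
        from .dosing import DEFAULT_DECAY_RATE

        self.lam = DEFAULT_DECAY_RATE if lam is None else float(lam)
        mask = np.ones(series.n_obs, dtype=bool)
        if not include_pretreatment:
            mask = series.times >= series.treatment_start_day
        if mask.sum() < 3:
            raise ValueError("need at least 3 in-window observations to fit")
        self._mask = mask
        self.C0 = infer_C0(series, self.rho)

    @property
    def step_label(self) -> str:
        return "flank_treated" if self.mu_H is None else "ic_treated"

    def fit(self, start_fractions: tuple[float, ...] = START_FRACTIONS) -> StepFitResult:
        t = self.series.times[self._mask]
        flux = self.series.flux[self._mask]
        E = np.asarray(cumulative_exposure(self.schedule, self.lam, t))
        rho, C0 = self.rho, self.C0
        if self.mu_H is None:
            params = [
                FitParam("mu_H", *MU_H_BOUNDS),
                FitParam("z", *Z_BOUNDS),
                FitParam("q", *Q_BOUNDS, log10=True),
            ]
            bounds_used = {"mu_H": MU_H_BOUNDS, "z": Z_BOUNDS, "q": Q_BOUNDS}
            fixed = {"gamma": 1.0, "rho": rho, "C0": C0}

            def model_log10(v):
                return (
                    log_total_cells(rho, v["mu_H"], v["z"], v["q"], 1.0, C0, E, t) / LN10
                )

        else:
            mu_H = self.mu_H
            params = [
                FitParam("gamma", *GAMMA_BOUNDS),
                FitParam("z", *Z_BOUNDS),
                FitParam("q", *Q_BOUNDS, log10=True),
            ]
            bounds_used = {"gamma": GAMMA_BOUNDS, "z": Z_BOUNDS, "q": Q_BOUNDS}
            fixed = {"mu_H": mu_H, "rho": rho, "C0": C0}

            def model_log10(v):
                return (
                    log_total_cells(rho, mu_H, v["z"], v["q"], v["gamma"], C0, E, t) / LN10
                )

        residual = _residual_factory(model_log10, flux, self.scale)
        estimates, ssr, spread, converged = multistart_least_squares(
            residual, params, start_fractions
        )
        return StepFitResult(
            step_label=self.step_label,
            estimates=estimates,
            bounds_used=bounds_used,
            residual_norm=ssr,
            converged=converged,
            multistart_spread=spread,
            subject_id=self.series.subject_id,
            site=self.series.site,
            fixed=fixed,
        )


def fit_untreated(series: SubjectSeries, scale: str = "log10") -> StepFitResult:
    """Step 1: exponential-growth fit of one untreated series ({rho, C0})."""
    return ExponentialGrowthModel(series, scale=scale).fit()


def pool_growth_rate(results: list[StepFitResult], site: str) -> float:
    """Arithmetic mean of per-subject rho estimates for one site.

    Summation runs in subject-id order so the pooled value is bit-identical
    under any input ordering.
    """
    sel = [r for r in results if r.step_label == "untreated" and r.site == site]
    if len(sel) != len(results):
        raise ValueError("all results must be untreated fits from the named site")
    if not sel:
        raise ValueError("cannot pool an empty collection")
    sel = sorted(sel, key=lambda r: r.subject_id)
    return float(np.mean([r.estimates["rho"] for r in sel]))


def infer_C0(series: SubjectSeries, rho: float) -> float:
    """Back-project the first observation to day 0: ``C0 = flux(t1)*exp(-rho*t1)``.

    The anchoring observation must not be later than the treatment start
    (at the first dose instant the accrued exposure is still zero, so the
    point is drug-free).  The result is clipped into the C0 fitting bound
    with a warning if it falls outside.
    """
    t1 = float(series.times[0])
    if series.treatment_start_day is not None and t1 > series.treatment_start_day:
        raise ValueError("no pre-treatment observation available to anchor C0")
    c0 = float(series.flux[0] * np.exp(-rho * t1))
    lo, hi = C0_BOUNDS
    if not lo <= c0 <= hi:
        warnings.warn(f"inferred C0={c0:g} outside [{lo:g}, {hi:g}]; clipping", stacklevel=2)
        c0 = float(np.clip(c0, lo, hi))
    return c0


def fit_treated_flank(
    series: SubjectSeries,
    rho_flank: float,
    schedule: DoseSchedule,
    scale: str = "log10",
    include_pretreatment: bool = False,
) -> StepFitResult:
    """Step 2: fit (mu_H, z, q) to one treated flank series with gamma = 1."""
    if series.site != "flank":
        raise ValueError("Step 2 fits flank series only")
    return TreatedResponseModel(
        series, rho_flank, schedule, scale=scale, include_pretreatment=include_pretreatment
    ).fit()


def fit_treated_ic(
    series: SubjectSeries,
    rho_ic: float,
    mu_H_mean: float,
    schedule: DoseSchedule,
    scale: str = "log10",
    include_pretreatment: bool = False,
) -> StepFitResult:
    """Step 3: fit (gamma, z, q) to one treated intracranial series.

    mu_H is fixed at the pooled flank value; within one site only the
    product gamma*mu_H is identifiable, so the fitted gamma scales inversely
    with the passed mu_H.
    """
    if series.site != "intracranial":
        raise ValueError("Step 3 fits intracranial series only")
    return TreatedResponseModel(
        series, rho_ic, schedule, mu_H=mu_H_mean, scale=scale,
        include_pretreatment=include_pretreatment,
    ).fit()


@dataclass(frozen=True)
class CohortCalibration:
    """All per-subject step results plus the pooled means passed between steps."""

    per_subject: tuple[StepFitResult, ...]
    rho_flank_mean: float | None = None
    rho_ic_mean: float | None = None
    mu_H_mean: float | None = None

    def results_for(self, step_label: str) -> list[StepFitResult]:
        return [r for r in self.per_subject if r.step_label == step_label]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.per_subject:
            row = {"subject_id": r.subject_id, "site": r.site, "step": r.step_label,
                   "residual_norm": r.residual_norm, "converged": r.converged,
                   "multistart_spread": r.multistart_spread}
            row.update(r.estimates)
            rows.append(row)
        return pd.DataFrame(rows)

    def pooled_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"quantity": "rho_flank_mean", "value": self.rho_flank_mean},
                {"quantity": "rho_ic_mean", "value": self.rho_ic_mean},
                {"quantity": "mu_H_mean", "value": self.mu_H_mean},
            ]
        )

    def summary(self) -> str:
        lines = ["Staged cohort calibration", "=" * 25]
        for name, v in (
            ("pooled rho (flank)", self.rho_flank_mean),
            ("pooled rho (intracranial)", self.rho_ic_mean),
            ("pooled mu_H (flank)", self.mu_H_mean),
        ):
            lines.append(f"{name:<28s}: {'-' if v is None else format(v, '.6g')}")
        lines.append("")
        for r in self.per_subject:
            lines.append(r.summary())
            lines.append("")
        return "\n".join(lines)


def run_pipeline(
    cohort: list[SubjectSeries],
    schedule: DoseSchedule,
    scale: str = "log10",
    include_pretreatment: bool = False,
) -> CohortCalibration:
    """Execute the three calibration steps on a full cohort.

    Step 1 runs per site on controls and pools rho; Step 2 runs on treated
    flank subjects with the pooled flank rho; Step 3 runs on treated
    intracranial subjects with the pooled intracranial rho and the pooled
    flank mu_H.  Steps with no subjects are skipped with a warning; treated
    subjects whose site has no controls are an error (no mean to pass).
    """
    groups: dict[tuple[str, str], list[SubjectSeries]] = {}
    for s in cohort:
        groups.setdefault((s.site, s.arm), []).append(s)

    per_subject: list[StepFitResult] = []
    rho_means: dict[str, float] = {}
    for site in ("flank", "intracranial"):
        controls = groups.get((site, "control"), [])
        if controls:
            fits = [fit_untreated(s, scale=scale) for s in controls]
            per_subject.extend(fits)
            rho_means[site] = pool_growth_rate(fits, site)
        elif groups.get((site, "treated")):
            raise ValueError(
                f"treated {site} subjects present but no untreated {site} subjects: "
                "the pooled growth rate cannot be passed"
            )
        else:
            warnings.warn(f"no {site} subjects; Step 1 ({site}) skipped", stacklevel=2)

    mu_H_mean: float | None = None
    flank_treated = groups.get(("flank", "treated"), [])
    if flank_treated:
        fits = [
            fit_treated_flank(
                s, rho_means["flank"], schedule, scale=scale,
                include_pretreatment=include_pretreatment,
            )
            for s in flank_treated
        ]
        per_subject.extend(fits)
        mu_H_mean = float(
            np.mean([r.estimates["mu_H"] for r in sorted(fits, key=lambda r: r.subject_id)])
        )
    else:
        warnings.warn("no treated flank subjects; Step 2 skipped", stacklevel=2)

    ic_treated = groups.get(("intracranial", "treated"), [])
    if ic_treated:
        if mu_H_mean is None:
            raise ValueError(
                "treated intracranial subjects present but Step 2 produced no pooled "
                "mu_H to pass"
            )
        fits = [
            fit_treated_ic(
                s, rho_means["intracranial"], mu_H_mean, schedule, scale=scale,
                include_pretreatment=include_pretreatment,
            )
            for s in ic_treated
        ]
        per_subject.extend(fits)
    else:
        warnings.warn("no treated intracranial subjects; Step 3 skipped", stacklevel=2)

    return CohortCalibration(
        per_subject=tuple(per_subject),
        rho_flank_mean=rho_means.get("flank"),
        rho_ic_mean=rho_means.get("intracranial"),
        mu_H_mean=mu_H_mean,
    )
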