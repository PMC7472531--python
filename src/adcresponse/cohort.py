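"""Synthetic PDX-like bioluminescence cohorts, plus cohort file I/O.

Emulates the statistical structure of a two-site xenograft efficacy study:
tumors implanted in the flank (no blood-brain barrier, full drug exposure,
``gamma = 1``) or intracranially (exposure limited, ``gamma <= 1``), each site
with a sham-control arm and a treated arm receiving weekly ADC boluses.
Tumor burden is read out as bioluminescence flux (photons/s), linearly
proportional to cell number, observed on a fixed imaging schedule with
multiplicative lognormal measurement noise.  Between-subject variability is
induced by drawing each subject's model parameters from configurable
ground-truth distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosing import DoseSchedule, weekly_schedule
from .model import ModelParams, analytic_trajectory
from .sensitivity import ParamDistribution

__all__ = [
    "SubjectSeries",
    "CohortDesign",
    "GroundTruthRecord",
    "default_truth_distributions",
    "sample_subjects",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "write_ground_truth",
    "read_ground_truth",
]

SITES = ("flank", "intracranial")
ARMS = ("control", "treated")


@dataclass(frozen=True)
class SubjectSeries:
    """One subject's observed (or synthetic) flux time series.

    ``treatment_start_day`` is the day of the first dose; it is required for
    treated subjects and must be absent (None) for controls.
    """

    subject_id: str
    site: str
    arm: str
    times: np.ndarray
    flux: np.ndarray
    treatment_start_day: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "flux", np.asarray(self.flux, dtype=float))
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if self.times.ndim != 1 or self.times.shape != self.flux.shape:
            raise ValueError("times and flux must be matching 1-d arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation days must be strictly increasing")
        if np.any(self.flux <= 0):
            raise ValueError("flux must be strictly positive")
        if self.arm == "treated" and self.treatment_start_day is None:
            raise ValueError("treated series must carry treatment_start_day")
        if self.arm == "control" and self.treatment_start_day is not None:
            raise ValueError("control series must not carry treatment_start_day")

    @property
    def n_obs(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class GroundTruthRecord:
    """Generating parameters for one synthetic subject (recovery bookkeeping)."""

    subject_id: str
    site: str
    arm: str
    params: ModelParams


def default_truth_distributions() -> dict[str, ParamDistribution]:
    """Between-subject parameter distributions used for cohort generation.

    Declared substitutes chosen inside the fitting-bound/tabulated ranges:
    site-specific growth rates, kill rate away from its bound edges, a
    log-spread resistant fraction, and partial intracranial exposure.
    """
    return {
        "rho_flank": ParamDistribution("rho_flank", "uniform", 0.2, 0.35),
        "rho_intracranial": ParamDistribution("rho_intracranial", "uniform", 0.3, 0.5),
        "mu_H": ParamDistribution("mu_H", "uniform", 2.0, 8.0),
        "z": ParamDistribution("z", "uniform", 0.0, 1.0),
        "q": ParamDistribution("q", "loguniform", 1e-6, 1e-2),
        "gamma": ParamDistribution("gamma", "uniform", 0.1, 1.0),
        "C0": ParamDistribution("C0", "loguniform", 1e3, 1e5),
    }


@dataclass(frozen=True)
class CohortDesign:
    """Study design for one synthetic cohort.

    Defaults mirror the emulated experiment: 4 sham-control and 5 treated
    animals per site, weekly imaging from day 0 to day 84, first dose on
    day 7, and multiplicative noise with sigma = 0.2 on the log10 scale.
    """

    n_control_per_site: int = 4
    n_treated_per_site: int = 5
    sites: tuple[str, ...] = SITES
    observation_days: tuple[float, ...] = tuple(float(d) for d in range(0, 85, 7))
    treatment_start_day: float = 7.0
    noise_sigma_log: float = 0.2
    flux_per_cell: float = 1.0
    truth_distributions: dict[str, ParamDistribution] = field(
        default_factory=default_truth_distributions
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control_per_site < 0 or self.n_treated_per_site < 0:
            raise ValueError("subject counts must be >= 0")
        if self.noise_sigma_log < 0:
            raise ValueError("noise_sigma_log must be >= 0")
        if self.flux_per_cell <= 0:
            raise ValueError("flux_per_cell must be > 0")
        for s in self.sites:
            if s not in SITES:
                raise ValueError(f"unknown site {s!r}")
        missing = {"mu_H", "z", "q", "gamma", "C0"} - set(self.truth_distributions)
        if missing:
            raise ValueError(f"truth_distributions missing entries: {sorted(missing)}")

    def schedule(self, n_doses: int = 12, dose_mg: float = 0.1) -> DoseSchedule:
        """Weekly dosing schedule anchored at this design's treatment start."""
        return weekly_schedule(n_doses=n_doses, dose_mg=dose_mg, first_dose_day=self.treatment_start_day)


def _rho_dist(design: CohortDesign, site: str) -> ParamDistribution:
    key = f"rho_{site}"
    if key in design.truth_distributions:
        return design.truth_distributions[key]
    if "rho" in design.truth_distributions:
        return design.truth_distributions["rho"]
    raise ValueError(f"no rho distribution for site {site!r}")


def sample_subjects(design: CohortDesign, rng: np.random.Generator | None = None) -> list[GroundTruthRecord]:
    """Draw per-subject ground-truth parameters.

    Flank subjects are forced ``gamma = 1`` (no barrier to drug delivery);
    intracranial subjects draw gamma from its truth distribution.  Controls
    draw the same growth parameters as treated subjects (their kill
    parameters are irrelevant because they receive no drug, but they are
    recorded for completeness).
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    d = design.truth_distributions
    records: list[GroundTruthRecord] = []
    for site in design.sites:
        rho_dist = _rho_dist(design, site)
        for arm, count in (("control", design.n_control_per_site), ("treated", design.n_treated_per_site)):
            for i in range(count):
                params = ModelParams(
                    rho=rho_dist.sample(rng),
                    mu_H=d["mu_H"].sample(rng),
                    z=d["z"].sample(rng),
                    q=d["q"].sample(rng),
                    gamma=1.0 if site == "flank" else d["gamma"].sample(rng),
                    C0=d["C0"].sample(rng),
                )
                sid = f"{site[:2]}-{arm[:4]}-{i + 1:02d}"
                records.append(GroundTruthRecord(sid, site, arm, params))
    return records


def simulate_cohort(
    design: CohortDesign,
    schedule: DoseSchedule | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[SubjectSeries], list[GroundTruthRecord]]:
    """Generate a noisy synthetic cohort with its ground truth.

    Noiseless flux is ``flux_per_cell * C(t)`` from the closed-form model
    (controls receive zero doses — the sham antibody is modelled as having no
    effect); observed flux multiplies in independent lognormal noise,
    ``flux_obs = flux * 10**eps`` with ``eps ~ Normal(0, noise_sigma_log)``.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    if schedule is None:
        schedule = design.schedule()
    schedule = schedule.anchored_at(design.treatment_start_day)
    no_dose = DoseSchedule(n_doses=0)
    truth = sample_subjects(design, rng)
    days = np.asarray(design.observation_days, dtype=float)
    series: list[SubjectSeries] = []
    for rec in truth:
        sched = schedule if rec.arm == "treated" else no_dose
        traj = analytic_trajectory(rec.params, sched, days)
        flux = design.flux_per_cell * traj.C
        if design.noise_sigma_log > 0:
            flux = flux * 10.0 ** rng.normal(0.0, design.noise_sigma_log, size=days.size)
        series.append(
            SubjectSeries(
                subject_id=rec.subject_id,
                site=rec.site,
                arm=rec.arm,
                times=days,
                flux=flux,
                treatment_start_day=design.treatment_start_day if rec.arm == "treated" else None,
            )
        )
    return series, truth


_COHORT_COLUMNS = ["subject_id", "site", "arm", "day", "flux", "treatment_start_day"]


def write_cohort(series: list[SubjectSeries], path, header_comment: str | None = None) -> None:
    """Write a cohort to CSV (one row per observation).

    ``treatment_start_day`` is left empty for controls.  An optional comment
    line (seed/design provenance) is written before the header, prefixed '#'.
    """
    rows = []
    for s in series:
        for t, f in zip(s.times, s.flux):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "site": s.site,
                    "arm": s.arm,
                    "day": t,
                    "flux": f,
                    "treatment_start_day": s.treatment_start_day,
                }
            )
    df = pd.DataFrame(rows, columns=_COHORT_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_cohort(path) -> list[SubjectSeries]:
    """Read a cohort CSV written by :func:`write_cohort`.

    Malformed rows are rejected with their file line number; unknown
    site/arm labels, non-positive flux, and controls carrying a treatment
    start day are all hard errors.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    start = 1 if lines and lines[0].startswith("#") else 0
    header = lines[start].strip().split(",")
    if header != _COHORT_COLUMNS:
        raise ValueError(f"expected header {_COHORT_COLUMNS}, got {header}")
    rows: dict[str, dict] = {}
    order: list[str] = []
    for lineno, raw in enumerate(lines[start + 1 :], start=start + 2):
        raw = raw.strip()
        if not raw:
            continue
        parts = raw.split(",")
        if len(parts) != 6:
            raise ValueError(f"line {lineno}: expected 6 fields, got {len(parts)}")
        sid, site, arm, day_s, flux_s, tsd_s = parts
        try:
            day = float(day_s)
            flux = float(flux_s)
            tsd = float(tsd_s) if tsd_s != "" else None
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric field ({exc})") from None
        if site not in SITES:
            raise ValueError(f"line {lineno}: unknown site {site!r}")
        if arm not in ARMS:
            raise ValueError(f"line {lineno}: unknown arm {arm!r}")
        if flux <= 0:
            raise ValueError(f"line {lineno}: flux must be positive, got {flux}")
        if arm == "control" and tsd is not None:
            raise ValueError(f"line {lineno}: control rows must have empty treatment_start_day")
        if arm == "treated" and tsd is None:
            raise ValueError(f"line {lineno}: treated rows must carry treatment_start_day")
        if sid not in rows:
            rows[sid] = {"site": site, "arm": arm, "tsd": tsd, "times": [], "flux": []}
            order.append(sid)
        rec = rows[sid]
        if (rec["site"], rec["arm"], rec["tsd"]) != (site, arm, tsd):
            raise ValueError(f"line {lineno}: inconsistent metadata for subject {sid!r}")
        rec["times"].append(day)
        rec["flux"].append(flux)
    return [
        SubjectSeries(
            subject_id=sid,
            site=rows[sid]["site"],
            arm=rows[sid]["arm"],
            times=np.array(rows[sid]["times"]),
            flux=np.array(rows[sid]["flux"]),
            treatment_start_day=rows[sid]["tsd"],
        )
        for sid in order
    ]


_TRUTH_COLUMNS = ["subject_id", "site", "arm", "rho", "mu_H", "z", "q", "gamma", "C0"]


def write_ground_truth(truth: list[GroundTruthRecord], path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "site": r.site,
                "arm": r.arm,
                "rho": r.params.rho,
                "mu_H": r.params.mu_H,
                "z": r.params.z,
                "q": r.params.q,
                "gamma": r.params.gamma,
                "C0": r.params.C0,
            }
            for r in truth
        ],
        columns=_TRUTH_COLUMNS,
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_ground_truth(path) -> list[GroundTruthRecord]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if list(df.columns) != _TRUTH_COLUMNS:
        raise ValueError(f"expected columns {_TRUTH_COLUMNS}, got {list(df.columns)}")
    return [
        GroundTruthRecord(
            str(row.subject_id),
            str(row.site),
            str(row.arm),
            ModelParams(rho=row.rho, mu_H=row.mu_H, z=row.z, q=row.q, gamma=row.gamma, C0=row.C0),
        )
        for row in df.itertuples(index=False)
    ]
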