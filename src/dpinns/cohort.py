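"""Virtual-cohort simulation and aggregation.

Generates the study conditions the estimators are evaluated on: individual
PK parameters drawn from a multivariate log-normal population, noise-free
concentration profiles, multiplicative log-normal measurement error, fixed
sampling schedules, optional missingness, and per-timepoint aggregation to
(mean, unbiased variance, n) summaries — the only data the estimators see.

Two cohorts are provided: the one-compartment IV-bolus study (30 subjects,
300 mg, 6 sampling times over 24 h, Vd mean 15 L at 10% CV, ke from a 6 h
mean half-life at 40% CV, residual sigma 0.1) and a body-weight-scaled
minimal-PBPK monoclonal-antibody cohort (1 mg/kg over a 1.5 h infusion,
weights uniform on 50-75 kg, clearance log-normal, sampling to 99 days).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pk_models as pk
from .moments import linear_to_log_moments, MomentPair, ResidualModel

__all__ = [
    "PopulationSpec", "SamplingSchedule", "CohortData", "AggregatedSeries",
    "sample_parameters", "simulate_observations", "aggregate", "mask_missing",
    "simulate_onecomp_cohort", "simulate_mab_cohort",
    "CASE1_SCHEDULE", "CASE1_POPULATION", "MAB_SCHEDULE",
]

# default study conditions (hours)
CASE1_SCHEDULE = np.array([0.5, 1.0, 2.0, 6.0, 12.0, 24.0])
KE_MEAN = np.log(2.0) / 6.0            # elimination rate from a 6 h half-life
CASE1_POPULATION = {
    "names": ["Vd", "ke"],
    "means": np.array([15.0, KE_MEAN]),
    "cvs": np.array([0.10, 0.40]),
    "rho": 0.0,
    "sigma": 0.1,
    "n_subjects": 30,
    "dose": 300.0,
}
# mAb sampling: one sample during the 1.5 h infusion, several over the first
# hours post-infusion, then sparse sampling out to 99 days (2376 h)
MAB_SCHEDULE = np.array([0.75, 1.5, 2.5, 3.5, 5.5, 9.5, 24.0, 72.0, 168.0,
                         336.0, 672.0, 1080.0, 1512.0, 1944.0, 2376.0])


@dataclass
class PopulationSpec:
    """Per-parameter linear-scale means and CVs, a log-scale correlation
    matrix, residual noise sigma, and the cohort size."""
    names: list
    means: np.ndarray
    cvs: np.ndarray
    rho: object = 0.0          # scalar (2 parameters) or full matrix
    sigma: float = 0.1
    n_subjects: int = 30

    def __post_init__(self):
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        self.cvs = np.atleast_1d(np.asarray(self.cvs, dtype=float))
        if np.any(self.cvs <= 0):
            raise ValueError("CVs must be positive")
        if self.n_subjects < 2:
            raise ValueError("cohort size must be at least 2")

    def correlation_matrix(self) -> np.ndarray:
        d = len(self.means)
        if np.ndim(self.rho) == 0:
            R = np.eye(d)
            if d == 2:
                R[0, 1] = R[1, 0] = float(self.rho)
        else:
            R = np.asarray(self.rho, dtype=float)
        if not np.allclose(R, R.T) or np.any(np.diag(R) != 1.0):
            raise ValueError("rho must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("rho must be positive semidefinite")
        return R

    def log_scale(self):
        """Log-scale mean vector and covariance implied by (mean, CV, rho)."""
        sd = self.cvs * self.means
        lm = linear_to_log_moments(MomentPair(self.means, sd ** 2))
        s = np.sqrt(lm.var_log)
        omega = self.correlation_matrix() * np.outer(s, s)
        return lm.mu_log, omega


@dataclass
class SamplingSchedule:
    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing and >= 0")


@dataclass
class CohortData:
    """Individual-level draws and profiles plus a missingness mask
    (True = observed)."""
    times: np.ndarray
    parameters: pd.DataFrame           # one row per subject
    profiles_true: np.ndarray          # (n_subjects, n_times)
    profiles_observed: np.ndarray      # true * exp(eps)
    mask: np.ndarray = None            # bool (n_subjects, n_times)

    def __post_init__(self):
        if self.mask is None:
            self.mask = np.ones(self.profiles_observed.shape, dtype=bool)


@dataclass
class AggregatedSeries:
    """Per-timepoint observed mean and unbiased variance of concentration —
    the estimator's entire view of the data."""
    times: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    n: np.ndarray = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if np.any(self.variance < 0):
            raise ValueError("variance must be nonnegative")
        if self.n is None:
            self.n = np.full(len(self.times), -1, dtype=int)
        else:
            self.n = np.asarray(self.n, dtype=int)

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.variance)

    def to_frame(self, dialect: str = "var") -> pd.DataFrame:
        if dialect == "var":
            spread = {"var": self.variance}
        elif dialect == "sd":
            spread = {"sd": self.sd}
        else:
            raise ValueError("dialect must be 'sd' or 'var'")
        return pd.DataFrame({"time": self.times, "mean": self.mean,
                             **spread, "n": self.n})


# ---------------------------------------------------------------------------

def sample_parameters(spec: PopulationSpec, seed) -> pd.DataFrame:
    """Joint multivariate log-normal draws of individual PK parameters."""
    rng = np.random.default_rng(seed)
    mu, omega = spec.log_scale()
    draws = np.exp(rng.multivariate_normal(mu, omega, size=spec.n_subjects,
                                           method="cholesky"))
    return pd.DataFrame(draws, columns=spec.names)


def simulate_observations(draws: pd.DataFrame, schedule: SamplingSchedule,
                          dose: float, rm: ResidualModel, seed,
                          eps: np.ndarray | None = None) -> CohortData:
    """Evaluate the one-compartment closed form per subject and apply
    multiplicative log-normal measurement error.

    `eps` allows a pre-generated residual matrix to be reused across
    scenarios (frozen-noise mode)."""
    rng = np.random.default_rng(seed)
    t = schedule.times
    profiles = np.stack([
        pk.onecomp_closed_form(t, pk.OneCompartmentParams(row.Vd, row.ke, dose))
        for row in draws.itertuples()])
    if eps is None:
        eps = rng.standard_normal(profiles.shape) * rm.sigma
    observed = profiles * np.exp(eps)
    return CohortData(times=t, parameters=draws.copy(),
                      profiles_true=profiles, profiles_observed=observed)


def aggregate(cohort: CohortData) -> AggregatedSeries:
    """Mean and unbiased (n-1) variance over unmasked observations per
    time point; time points with fewer than 2 observations are dropped."""
    import warnings
    keep, means, variances, counts = [], [], [], []
    for j, t in enumerate(cohort.times):
        vals = cohort.profiles_observed[cohort.mask[:, j], j]
        if len(vals) < 2:
            warnings.warn(f"dropping time {t}: fewer than 2 observations")
            continue
        keep.append(t)
        means.append(vals.mean())
        variances.append(vals.var(ddof=1))
        counts.append(len(vals))
    return AggregatedSeries(np.array(keep), np.array(means),
                            np.array(variances), np.array(counts))


def mask_missing(cohort: CohortData, fraction: float, seed) -> CohortData:
    """Randomly remove the given fraction of cells of the subject x time
    grid (uniformly, reproducibly)."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_cells = cohort.mask.size
    n_drop = int(round(fraction * n_cells))
    flat = np.ones(n_cells, dtype=bool)
    flat[rng.choice(n_cells, size=n_drop, replace=False)] = False
    return CohortData(times=cohort.times, parameters=cohort.parameters,
                      profiles_true=cohort.profiles_true,
                      profiles_observed=cohort.profiles_observed,
                      mask=flat.reshape(cohort.mask.shape))


def simulate_onecomp_cohort(seed, spec: PopulationSpec | None = None,
                            schedule: SamplingSchedule | None = None,
                            dose: float | None = None,
                            missing_fraction: float = 0.0,
                            eps: np.ndarray | None = None):
    """One call for the full proof-of-concept study: sample the cohort,
    simulate observations, optionally mask, and aggregate.

    Returns (CohortData, AggregatedSeries)."""
    cfg = CASE1_POPULATION
    if spec is None:
        spec = PopulationSpec(names=cfg["names"], means=cfg["means"],
                              cvs=cfg["cvs"], rho=cfg["rho"],
                              sigma=cfg["sigma"], n_subjects=cfg["n_subjects"])
    if schedule is None:
        schedule = SamplingSchedule(CASE1_SCHEDULE)
    if dose is None:
        dose = cfg["dose"]
    seeds = np.random.SeedSequence(seed).spawn(3)
    draws = sample_parameters(spec, seeds[0])
    cohort = simulate_observations(draws, schedule, dose,
                                   ResidualModel(spec.sigma), seeds[1], eps=eps)
    if missing_fraction > 0:
        cohort = mask_missing(cohort, missing_fraction, seeds[2])
    return cohort, aggregate(cohort)


def simulate_mab_cohort(seed, n_subjects: int = 49,
                        weight_range=(50.0, 75.0), dose_per_kg: float = 1.0,
                        cl_mean: float = 0.0115, cl_sd: float = 0.0041,
                        sigma1: float = 0.8378, sigma2: float = 0.7529,
                        sigma: float = 0.1, t_inf: float = 1.5,
                        schedule: SamplingSchedule | None = None):
    """Virtual monoclonal-antibody cohort under the minimal PBPK model.

    Body weight is uniform on `weight_range`; the dose is dose_per_kg x BW
    over a `t_inf`-hour infusion; physiology scales linearly with weight;
    individual clearance is log-normal with the given linear-scale mean/SD;
    reflection coefficients are population constants.

    Returns (CohortData, AggregatedSeries)."""
    if schedule is None:
        schedule = SamplingSchedule(MAB_SCHEDULE)
    rng = np.random.default_rng(seed)
    bw = rng.uniform(*weight_range, size=n_subjects)
    lm = linear_to_log_moments(MomentPair(cl_mean, cl_sd ** 2))
    cl = np.exp(rng.normal(lm.mu_log, np.sqrt(lm.var_log), size=n_subjects))
    t = schedule.times
    profiles = np.empty((n_subjects, len(t)))
    for k in range(n_subjects):
        phys = pk.scale_physiology(bw[k])
        est = pk.MPBPKEstimands(CLp=cl[k], sigma1=sigma1, sigma2=sigma2)
        inf = pk.InfusionSchedule(dose=dose_per_kg * bw[k], T_inf=t_inf)
        profiles[k] = pk.mpbpk_solve(t, phys, est, inf)[:, 0]
    eps = rng.standard_normal(profiles.shape) * sigma
    observed = profiles * np.exp(eps)
    params = pd.DataFrame({"CLp": cl, "body_weight": bw,
                           "dose": dose_per_kg * bw})
    cohort = CohortData(times=t, parameters=params, profiles_true=profiles,
                        profiles_observed=observed)
    return cohort, aggregate(cohort)
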