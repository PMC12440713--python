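"""Synthetic canine TDM data with the statistical structure of a
steady-state phenobarbital monitoring study.

The generator emulates a cohort of client-owned dogs on chronic oral
phenobarbital monotherapy: truncated-normal demographics (mean age
5.4 y, SD 3.5; mean weight 21.3 kg, SD 14.0; 57% male), tablet-based
q12h regimens, sparse predose sampling at steady state (>= 20 days on
therapy, ~1.2 samples per dog), log-normal interindividual variability
on CL/F, additive assay error, and a 1.1 mg/L lower limit of
quantification.  A rich early-sampling design (48 h / 168 h / 672 h) is
provided for parameter-recovery studies where the enzyme-turnover rate
must be identifiable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .io import EventTable, Observation, SubjectRecord
from .model import DoseEvent, PopulationParameters, SubjectCovariates
from ._ode import integrate_grid

__all__ = [
    "DemographicsConfig",
    "SamplingDesign",
    "sample_covariates",
    "build_regimen",
    "round_to_tablets",
    "generate_tdm_dataset",
]

#: Commercial tablet strengths (mg); halving is standard practice.
TABLET_STRENGTHS = (100.0, 40.0, 15.0)


@dataclass(frozen=True)
class DemographicsConfig:
    """Truncated-normal covariate distributions of the study cohort."""

    n_subjects: int = 100
    male_fraction: float = 0.57
    age_mean: float = 5.4  # years
    age_sd: float = 3.5
    weight_mean: float = 21.3  # kg
    weight_sd: float = 14.0
    age_bounds: tuple[float, float] = (0.3, 16.0)
    weight_bounds: tuple[float, float] = (2.0, 70.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        if self.age_sd < 0 or self.weight_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for lo, hi in (self.age_bounds, self.weight_bounds):
            if lo <= 0 or lo >= hi:
                raise ValueError("bounds must be positive with lower < upper")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def _matched_truncnorm(mean: float, sd: float, bounds: tuple[float, float]):
    """Truncated normal whose *realized* mean/SD equal the targets.

    Truncation shifts the moments of a normal; solve for the parent
    (mu, sigma) such that the truncated distribution has the requested
    mean and SD (moment matching).
    """
    lo, hi = bounds

    def moments(x):
        mu, log_sigma = x
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, math.sqrt(v) - sd]

    sol = optimize.fsolve(moments, [mean, math.log(max(sd, 1e-6))], full_output=True)
    x, _, ier, _ = sol
    if ier != 1:
        raise ValueError(f"infeasible truncation bounds {bounds} for mean={mean}, sd={sd}")
    mu, sigma = x[0], math.exp(x[1])
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm(a, b, loc=mu, scale=sigma)


def sample_covariates(
    config: DemographicsConfig, seed: int | np.random.Generator
) -> list[SubjectCovariates]:
    """Draw a virtual cohort; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    age_dist = _matched_truncnorm(config.age_mean, config.age_sd, config.age_bounds)
    wt_dist = _matched_truncnorm(config.weight_mean, config.weight_sd, config.weight_bounds)
    ages = age_dist.rvs(size=config.n_subjects, random_state=rng)
    weights = wt_dist.rvs(size=config.n_subjects, random_state=rng)
    sexes = (rng.random(config.n_subjects) < config.male_fraction).astype(int)
    return [
        SubjectCovariates(weight=float(w), age=float(a), sex=int(s))
        for w, a, s in zip(weights, ages, sexes)
    ]


def round_to_tablets(amount: float, strengths: Sequence[float] = TABLET_STRENGTHS) -> float:
    """Nearest dose achievable with whole and halved tablets.

    Exhaustive search over combinations of up to four units per strength
    (whole or half); ties resolved toward the lower dose.
    """
    if amount <= 0:
        raise ValueError("amount must be positive")
    units = [s for full in strengths for s in (full, full / 2.0)]
    best = None
    for counts in itertools.product(range(5), repeat=len(units)):
        total = sum(c * u for c, u in zip(counts, units))
        if total <= 0:
            continue
        key = (abs(total - amount), total)
        if best is None or key < best:
            best = key
    return best[1]


def build_regimen(
    cov: SubjectCovariates,
    dose_per_kg: float,
    interval: float = 12.0,
    duration_days: float = 30.0,
    tablet_rounding: bool = False,
) -> list[DoseEvent]:
    """Repeated oral doses of ``dose_per_kg`` x weight every ``interval`` h."""
    if dose_per_kg <= 0:
        raise ValueError("dose_per_kg must be positive")
    amount = dose_per_kg * cov.weight
    if tablet_rounding:
        amount = round_to_tablets(amount)
    n = int(round(duration_days * 24.0 / interval))
    return [DoseEvent(time=i * interval, amount=amount) for i in range(n)]


@dataclass(frozen=True)
class SamplingDesign:
    """When each virtual dog is sampled, and how the LLOQ is handled.

    With ``sample_times`` set, every subject is observed at those fixed
    times (predose when a time coincides with a dose).  Otherwise the
    sparse clinical rule applies: one predose sample at a random dosing
    time within ``predose_day_range``, and a ``repeat_fraction`` of dogs
    contribute a second predose sample on a later day in the window.
    """

    sample_times: tuple[float, ...] | None = None
    predose_day_range: tuple[float, float] = (20.0, 40.0)
    repeat_fraction: float = 0.2
    lloq: float = 1.1  # mg/L
    lloq_policy: str = "exclude"  # "exclude" | "flag"

    def __post_init__(self) -> None:
        if self.sample_times is not None and any(t < 0 for t in self.sample_times):
            raise ValueError("sample times must be non-negative")
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise ValueError("repeat_fraction must be in [0, 1]")
        if self.lloq_policy not in ("exclude", "flag"):
            raise ValueError("lloq_policy must be 'exclude' or 'flag'")

    @classmethod
    def sparse_tdm(cls) -> "SamplingDesign":
        """Default study-like design: sparse steady-state predose troughs."""
        return cls()

    @classmethod
    def rich(cls) -> "SamplingDesign":
        """Early + late sampling (48, 168, 672 h) for turnover identifiability."""
        return cls(sample_times=(48.0, 168.0, 672.0))


def _subject_sample_times(
    design: SamplingDesign, doses: list[DoseEvent], rng: np.random.Generator
) -> list[float]:
    if design.sample_times is not None:
        return sorted(design.sample_times)
    lo, hi = (d * 24.0 for d in design.predose_day_range)
    candidates = [d.time for d in doses if lo <= d.time <= hi]
    if not candidates:
        raise ValueError("regimen does not cover the predose sampling window")
    times = [float(rng.choice(candidates))]
    if rng.random() < design.repeat_fraction and len(candidates) > 1:
        later = [t for t in candidates if t != times[0]]
        times.append(float(rng.choice(later)))
    return sorted(times)


def generate_tdm_dataset(
    demog: DemographicsConfig,
    design: SamplingDesign,
    truth: PopulationParameters,
    seed: int,
    regimen: Callable[[SubjectCovariates], list[DoseEvent]] | None = None,
    dt: float = 0.5,
) -> EventTable:
    """Simulate a full sparse-TDM dataset from known population truth.

    For each dog: draw covariates, build the dosing history, draw
    eta ~ N(0, omega_CL^2) on log CL/F, integrate the autoinduction ODE,
    sample at the design times, add N(0, sigma_add^2) assay noise
    (negative results are truncated at zero and flagged below-LLOQ) and
    apply the LLOQ policy.  With omega_CL = sigma_add = 0 every
    observation equals the typical-subject model prediction exactly.
    """
    rng = np.random.default_rng(seed)
    covs = sample_covariates(demog, rng)
    if regimen is None:
        regimen = lambda cov: build_regimen(cov, dose_per_kg=5.0, interval=12.0, duration_days=42.0)

    doses_per_subj = [regimen(c) for c in covs]
    times_per_subj = [_subject_sample_times(design, d, rng) for d in doses_per_subj]
    etas = rng.normal(0.0, truth.omega_CL, size=len(covs))

    # shared-grid vectorized simulation over the union of event times
    from .model import individual_clearance, individual_volume

    union_doses = sorted({d.time for ds in doses_per_subj for d in ds})
    union_times = sorted({t for ts in times_per_subj for t in ts})
    d_index = {t: j for j, t in enumerate(union_doses)}
    r_index = {t: j for j, t in enumerate(union_times)}
    amounts = np.zeros((len(covs), len(union_doses)))
    for i, ds in enumerate(doses_per_subj):
        for d in ds:
            amounts[i, d_index[d.time]] += d.amount
    cl = np.array([individual_clearance(truth, c, e) for c, e in zip(covs, etas)])
    v = np.array([individual_volume(truth, c) for c in covs])
    conc = integrate_grid(
        cl, v, truth.ka, truth.Kenz, truth.IC50,
        np.asarray(union_doses), amounts, np.asarray(union_times, dtype=float), dt=dt,
    )

    records = []
    for i, (cov, doses, times) in enumerate(zip(covs, doses_per_subj, times_per_subj)):
        observations = []
        for t in times:
            c_true = conc[i, r_index[t]]
            c_obs = c_true + rng.normal(0.0, truth.sigma_add) if truth.sigma_add > 0 else c_true
            flagged = False
            if c_obs < 0:
                c_obs, flagged = 0.0, True
            if c_obs < design.lloq:
                if design.lloq_policy == "exclude":
                    continue
                flagged = True
            observations.append(Observation(time=t, conc=float(c_obs), below_lloq=flagged))
        records.append(
            SubjectRecord(id=i + 1, covariates=cov, doses=list(doses), observations=observations)
        )
    return EventTable(records)
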