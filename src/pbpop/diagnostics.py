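"""Model-evaluation toolbox: external-validation error metrics, normalized
prediction distribution errors (NPDE) and a predose visual predictive
check (VPC), all returning plot-ready numbers.

Prediction bias and precision are summarized as

* ME (mg/L)  = mean(pred - obs)                      — additive bias,
* MRE (%)    = 100 x mean((pred - obs)/obs)          — relative bias,
* RMSE (%)   = 100 x sqrt(mean(((pred - obs)/obs)^2)) — relative precision,

with overprediction positive.  Both the a-priori mode (covariates only,
eta = 0) and the Bayesian MAP-updated mode are reported for external
validation, mirroring how TDM models are assessed before and after
individual feedback.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from ._ode import integrate_grid
from .estimate import FitOptions, _LikelihoodData, map_individual, predict_observations
from .io import EventTable
from .model import PopulationParameters

__all__ = [
    "ValidationMetrics",
    "validation_metrics",
    "NpdeResult",
    "npde",
    "VpcResult",
    "vpc_predose",
    "external_validate",
]


@dataclass(frozen=True)
class ValidationMetrics:
    me: float  # mean error, mg/L
    mre_percent: float  # mean relative error, %
    rmse_percent: float  # relative root mean squared error, %
    n: int


def validation_metrics(observed, predicted) -> ValidationMetrics:
    """Bias/precision metrics of predictions against observations.

    Observations equal to zero cannot enter the relative metrics and are
    excluded with a warning.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have the same shape")
    if obs.size == 0:
        raise ValueError("at least one observation is required")
    keep = obs > 0
    if not np.all(keep):
        warnings.warn(f"excluding {int((~keep).sum())} observations with zero value")
        obs, pred = obs[keep], pred[keep]
        if obs.size == 0:
            raise ValueError("no non-zero observations left")
    err = pred - obs
    rel = err / obs
    return ValidationMetrics(
        me=float(np.mean(err)),
        mre_percent=float(100.0 * np.mean(rel)),
        rmse_percent=float(100.0 * math.sqrt(np.mean(rel**2))),
        n=int(obs.size),
    )


def _simulate_replicates(
    ld: _LikelihoodData, pop: PopulationParameters, K: int, rng: np.random.Generator, dt: float
) -> list[np.ndarray]:
    """K replicate observation vectors per subject under the model.

    Returns a list with one (K, n_i) array per subject (IIV on CL/F plus
    additive residual noise).
    """
    etas = rng.normal(0.0, pop.omega_CL, size=(ld.n, K))
    cl = (ld.typical_cl(pop)[:, None] * np.exp(etas)).ravel()
    v = np.repeat(ld.volumes(pop), K)
    conc = integrate_grid(
        cl, v, pop.ka, pop.Kenz, pop.IC50,
        ld.dose_times, np.repeat(ld.amounts, K, axis=0), ld.record_times, dt=dt,
    )
    sims = []
    for i in range(ld.n):
        block = conc[i * K : (i + 1) * K][:, ld.obs_cols[i]]
        sims.append(block + rng.normal(0.0, pop.sigma_add, size=block.shape))
    return sims


@dataclass
class NpdeResult:
    values: np.ndarray  # one NPDE per usable observation, subject order
    mean: float
    variance: float
    t_test_p: float  # H0: mean 0
    normality_p: float  # Shapiro-Wilk on the NPDE sample


def npde(
    data: EventTable,
    pop: PopulationParameters,
    K: int = 1000,
    seed: int = 0,
    dt: float = 0.5,
) -> NpdeResult:
    """Normalized prediction distribution errors.

    Simulates ``K`` replicates of the dataset under the model, decorrelates
    each subject's observation vector with the Cholesky factor of the
    empirical simulation covariance, and maps the rank of the decorrelated
    observation within the decorrelated simulations through the inverse
    normal CDF.  Under a correct model the NPDE are iid N(0, 1).  Rank ties
    are broken by uniform jitter; output is deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    ld = _LikelihoodData(data)
    sims = _simulate_replicates(ld, pop, K, rng, dt)
    out = []
    for i in range(ld.n):
        y = ld.obs_y[i]
        S = sims[i]  # (K, n_i)
        mu = S.mean(axis=0)
        if y.size == 1:
            y_star = (y - mu) / max(S.std(axis=0, ddof=1)[0], 1e-12)
            s_star = (S - mu) / max(S.std(axis=0, ddof=1)[0], 1e-12)
        else:
            C = np.cov(S, rowvar=False)
            C[np.diag_indices_from(C)] += 1e-10 * max(1.0, np.trace(C) / y.size)
            L = np.linalg.cholesky(C)
            y_star = solve_triangular(L, y - mu, lower=True)
            s_star = solve_triangular(L, (S - mu).T, lower=True).T
        less = (s_star < y_star[None, :]).sum(axis=0)
        ties = (s_star == y_star[None, :]).sum(axis=0)
        pde = (less + rng.random(y.size) * ties) / K
        pde = np.clip(pde, 1.0 / (2 * K), 1.0 - 1.0 / (2 * K))
        out.append(stats.norm.ppf(pde))
    values = np.concatenate(out)
    t_p = float(stats.ttest_1samp(values, 0.0).pvalue)
    sh_p = float(stats.shapiro(values).pvalue) if values.size >= 3 else float("nan")
    return NpdeResult(
        values=values,
        mean=float(values.mean()),
        variance=float(values.var(ddof=1)),
        t_test_p=t_p,
        normality_p=sh_p,
    )


@dataclass
class VpcResult:
    """Percentile overlay data for a (prediction-corrected) predose VPC."""

    bin_labels: list[str]
    bin_edges: np.ndarray  # weight-bin edges, kg
    observed: pd.DataFrame  # per bin: p5 / p50 / p95 of (corrected) observations
    simulated_low: pd.DataFrame  # lower envelope of the simulated percentile bands
    simulated_high: pd.DataFrame  # upper envelope
    n_per_bin: np.ndarray
    prediction_corrected: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b, label in enumerate(self.bin_labels):
            for q in ("p5", "p50", "p95"):
                rows.append(
                    {
                        "bin": label,
                        "percentile": q,
                        "observed": self.observed.loc[label, q],
                        "sim_low": self.simulated_low.loc[label, q],
                        "sim_high": self.simulated_high.loc[label, q],
                        "n": int(self.n_per_bin[b]),
                    }
                )
        return pd.DataFrame(rows)


def vpc_predose(
    data: EventTable,
    pop: PopulationParameters,
    K: int = 500,
    bins: int = 3,
    seed: int = 0,
    prediction_corrected: bool = False,
    dt: float = 0.5,
    band: float = 0.90,
) -> VpcResult:
    """Visual predictive check on predose (trough) concentrations.

    Observations are binned by body weight (default tertiles); observed
    5/50/95th percentiles are compared with the ``band`` (default 90%)
    envelope of the same percentiles across ``K`` simulated replicates.
    With ``prediction_corrected`` each value is rescaled by the ratio of
    its bin's median population prediction to its own population
    prediction, removing dose/covariate heterogeneity within bins.
    """
    rng = np.random.default_rng(seed)
    ld = _LikelihoodData(data)
    obs_all = np.concatenate(ld.obs_y)
    subj_of_obs = np.concatenate([np.full(y.size, i) for i, y in enumerate(ld.obs_y)])
    wt_of_obs = ld.wt[subj_of_obs]

    edges = np.quantile(wt_of_obs, np.linspace(0, 1, bins + 1))
    edges[0] -= 1e-9
    bin_of_obs = np.clip(np.searchsorted(edges, wt_of_obs, side="right") - 1, 0, bins - 1)
    # merge empty bins with their left neighbor
    counts = np.bincount(bin_of_obs, minlength=bins)
    if np.any(counts == 0):
        warnings.warn("empty VPC bin merged with neighbor")

    pc_factor = np.ones(obs_all.size)
    if prediction_corrected:
        pop_pred = predict_observations(data, pop, dt=dt)
        for b in range(bins):
            m = bin_of_obs == b
            if m.any():
                pc_factor[m] = np.median(pop_pred[m]) / pop_pred[m]

    sims = _simulate_replicates(ld, pop, K, rng, dt)
    sim_all = np.concatenate([s.T for s in sims], axis=0)  # (n_obs, K)
    sim_all = sim_all * pc_factor[:, None]
    obs_corr = obs_all * pc_factor

    qs = [5, 50, 95]
    labels, obs_rows, lo_rows, hi_rows, n_per_bin = [], [], [], [], []
    alpha = (1.0 - band) / 2.0
    for b in range(bins):
        m = bin_of_obs == b
        if not m.any():
            continue
        label = f"[{edges[b]:.1f}, {edges[b + 1]:.1f}] kg"
        labels.append(label)
        n_per_bin.append(int(m.sum()))
        obs_rows.append([np.percentile(obs_corr[m], q) for q in qs])
        rep_pcts = np.percentile(sim_all[m], qs, axis=0)  # (3, K)
        lo_rows.append(np.quantile(rep_pcts, alpha, axis=1))
        hi_rows.append(np.quantile(rep_pcts, 1.0 - alpha, axis=1))
    cols = ["p5", "p50", "p95"]
    return VpcResult(
        bin_labels=labels,
        bin_edges=edges,
        observed=pd.DataFrame(obs_rows, index=labels, columns=cols),
        simulated_low=pd.DataFrame(lo_rows, index=labels, columns=cols),
        simulated_high=pd.DataFrame(hi_rows, index=labels, columns=cols),
        n_per_bin=np.asarray(n_per_bin),
        prediction_corrected=prediction_corrected,
    )


def external_validate(
    validation_data: EventTable,
    pop: PopulationParameters,
    options: FitOptions | None = None,
) -> dict[str, ValidationMetrics]:
    """A-priori and MAP-updated predictive-performance metrics.

    A-priori predictions use covariates only (eta = 0); MAP-updated
    predictions re-use each subject's own observations for the Bayesian
    update and then predict those same observations (an in-sample
    shrinkage assessment, the usual TDM forecasting summary).
    """
    opts = options or FitOptions()
    usable = [r for r in validation_data.records if r.usable_observations]
    if not usable:
        raise ValueError("validation dataset has no usable observations")
    obs = np.concatenate([[o.conc for o in r.usable_observations] for r in usable])
    apriori = predict_observations(validation_data, pop, dt=opts.dt)
    map_pred = np.concatenate(
        [map_individual(r, pop, opts).predictions for r in usable]
    )
    return {
        "a_priori": validation_metrics(obs, apriori),
        "map_updated": validation_metrics(obs, map_pred),
    }
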