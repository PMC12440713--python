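"""NLME estimation: marginal-likelihood correctness against independent
oracles, MAP estimation, information criteria and covariate selection."""

import math

import numpy as np
import pytest
from scipy.special import logsumexp

from pbpop.datagen import (
    DemographicsConfig,
    SamplingDesign,
    build_regimen,
    generate_tdm_dataset,
)
from pbpop.estimate import (
    FitOptions,
    ModelSpec,
    _LikelihoodData,
    bicc,
    compute_rse,
    fit_model,
    lrt,
    map_individual,
    marginal_neg2loglik,
    predict_observations,
    stepwise_covariates,
)
from pbpop.model import PopulationParameters

FAST = FitOptions(gh_nodes=8, dt=1.0, maxiter=150)


def _toy_dataset(n=3, seed=7, omega=0.3, sigma=2.0):
    truth = PopulationParameters(omega_CL=omega, sigma_add=sigma)
    return (
        generate_tdm_dataset(
            DemographicsConfig(n_subjects=n),
            SamplingDesign(sample_times=(24.0, 48.0, 72.0)),
            truth,
            seed=seed,
            regimen=lambda c: build_regimen(c, 5.0, 12.0, 4.0),
        ),
        truth,
    )


class TestMarginalLikelihood:
    def test_degenerate_omega_equals_plain_gaussian(self):
        data, truth = _toy_dataset()
        p0 = truth.with_(omega_CL=0.0)
        ofv = marginal_neg2loglik(data, ModelSpec(), p0, FAST)
        pred = predict_observations(data, p0, dt=FAST.dt)
        obs = np.concatenate([[o.conc for o in r.usable_observations] for r in data])
        sig = p0.sigma_add
        expected = np.sum((obs - pred) ** 2 / sig**2 + math.log(2 * math.pi * sig**2))
        assert ofv == pytest.approx(expected, rel=1e-10)

    def test_agrees_with_monte_carlo_oracle(self):
        """Brute-force MC integration over eta on a 3-subject toy; the
        quadrature OFV must fall within 3 MC standard errors."""
        data, truth = _toy_dataset()
        ld = _LikelihoodData(data)
        ofv_q = marginal_neg2loglik(ld, ModelSpec(), truth, FitOptions(gh_nodes=32))
        rng = np.random.default_rng(123)
        M, B = 40_000, 40
        etas = rng.normal(0.0, truth.omega_CL, M)
        ll = ld.cond_loglik(truth, np.tile(etas, (ld.n, 1)), 0.5)
        log_mean = logsumexp(ll, axis=1) - math.log(M)
        batches = logsumexp(ll.reshape(ld.n, B, M // B), axis=2) - math.log(M // B)
        rel_se = np.std(np.exp(batches), axis=1, ddof=1) / math.sqrt(B) / np.exp(log_mean)
        ofv_mc = float(-2.0 * log_mean.sum())
        se_ofv = 2.0 * math.sqrt(float(np.sum(rel_se**2)))
        assert abs(ofv_q - ofv_mc) < 3.0 * se_ofv

    def test_independent_subjects_add(self):
        """Duplicating every subject doubles the OFV (likelihood
        factorizes over independent individuals)."""
        data, truth = _toy_dataset()
        from pbpop.io import EventTable, SubjectRecord

        doubled = EventTable(
            data.records
            + [
                SubjectRecord(id=r.id + 100, covariates=r.covariates,
                              doses=list(r.doses), observations=list(r.observations))
                for r in data.records
            ]
        )
        o1 = marginal_neg2loglik(data, ModelSpec(), truth, FAST)
        o2 = marginal_neg2loglik(doubled, ModelSpec(), truth, FAST)
        assert o2 == pytest.approx(2.0 * o1, rel=1e-8)

    def test_quadrature_node_count_stable(self, rich_dataset_small, pop_params):
        o32 = marginal_neg2loglik(rich_dataset_small, ModelSpec(), pop_params,
                                  FitOptions(gh_nodes=32))
        o64 = marginal_neg2loglik(rich_dataset_small, ModelSpec(), pop_params,
                                  FitOptions(gh_nodes=64))
        assert abs(o32 - o64) < 0.01


class TestFitModel:
    def test_noise_free_self_consistency(self):
        """Noise-free, IIV-free typical-subject data: the OFV-minimizing
        CL_pop reproduces the generating value to 4 significant digits."""
        truth = PopulationParameters(omega_CL=0.0, sigma_add=0.0)
        data = generate_tdm_dataset(
            DemographicsConfig(n_subjects=6), SamplingDesign.rich(), truth, seed=3,
            regimen=lambda c: build_regimen(c, 5.0, 12.0, 28.0),
        )
        spec = ModelSpec(fixed={"Kenz": 0.15, "IC50": 1.77, "omega_CL": 0.0,
                                "sigma_add": 1.0, "beta_age": -0.15})
        fit = fit_model(data, spec=spec, options=FitOptions(dt=0.5, maxiter=100))
        assert fit.estimates.CL_pop == pytest.approx(0.015, rel=5e-4)

    def test_recovery_small_cohort(self, rich_dataset_small):
        """20-dog rich-design fit lands near the generating values."""
        fit = fit_model(rich_dataset_small, options=FitOptions(gh_nodes=8, dt=0.5))
        assert fit.converged
        assert fit.estimates.CL_pop == pytest.approx(0.015, rel=0.2)
        assert fit.estimates.IC50 == pytest.approx(1.77, rel=0.3)
        assert 0.1 < fit.estimates.omega_CL < 0.6
        assert fit.eta_map.shape == (20,)

    def test_scale_invariance_of_clearance(self):
        """Scaling all concentrations and sigma_add by c leaves the
        clearance estimate unchanged (dose/volume units absorb it)."""
        data, truth = _toy_dataset(n=6, seed=11)
        spec = ModelSpec(fixed={"Kenz": 0.15, "IC50": 1.77, "beta_age": -0.15})
        fit1 = fit_model(data, spec=spec, options=FAST)
        from pbpop.io import EventTable, Observation, SubjectRecord

        c = 2.0
        scaled = EventTable(
            [
                SubjectRecord(
                    id=r.id, covariates=r.covariates,
                    doses=[type(d)(d.time, d.amount * c) for d in r.doses],
                    observations=[Observation(o.time, o.conc * c, o.below_lloq)
                                  for o in r.observations],
                )
                for r in data.records
            ]
        )
        # doubling doses and concentrations together: same CL/F, but IC50
        # doubles; fix it accordingly and compare CL
        spec2 = ModelSpec(fixed={"Kenz": 0.15, "IC50": 1.77 * c, "beta_age": -0.15})
        fit2 = fit_model(scaled, spec=spec2, options=FAST)
        assert fit2.estimates.CL_pop == pytest.approx(fit1.estimates.CL_pop, rel=1e-2)


class TestMapIndividual:
    def test_no_observations_returns_prior_mode(self, pop_params):
        from pbpop.io import SubjectRecord
        from pbpop.model import DoseEvent, SubjectCovariates

        rec = SubjectRecord(
            id=1, covariates=SubjectCovariates(weight=20, age=5),
            doses=[DoseEvent(0, 100)], observations=[],
        )
        est = map_individual(rec, pop_params)
        assert est.eta == 0.0
        assert est.CL_i == pytest.approx(0.015)

    def test_recovers_generating_eta_with_rich_noise_free_data(self, pop_params):
        from pbpop.io import Observation, SubjectRecord
        from pbpop.model import DoseEvent, IndividualParameters, SubjectCovariates, simulate_profile

        eta_true = 0.4
        cov = SubjectCovariates(weight=20, age=5)
        ind = IndividualParameters(CL_i=0.015 * math.exp(eta_true), V_i=20.0)
        doses = [DoseEvent(12.0 * i, 100.0) for i in range(56)]
        times = [48.0, 120.0, 240.0, 360.0, 480.0, 672.0]
        conc = simulate_profile(ind, doses, times)
        rec = SubjectRecord(
            id=1, covariates=cov, doses=doses,
            observations=[Observation(t, float(c)) for t, c in zip(times, conc)],
        )
        pop = pop_params.with_(sigma_add=1e-4)  # effectively noise-free
        est = map_individual(rec, pop, FitOptions(dt=0.25))
        assert est.eta == pytest.approx(eta_true, abs=1e-3)

    def test_degenerate_prior_forces_zero(self, pop_params):
        from pbpop.io import Observation, SubjectRecord
        from pbpop.model import DoseEvent, SubjectCovariates

        rec = SubjectRecord(
            id=1, covariates=SubjectCovariates(weight=20, age=5),
            doses=[DoseEvent(0, 100)], observations=[Observation(12.0, 99.0)],
        )
        est = map_individual(rec, pop_params.with_(omega_CL=0.0))
        assert est.eta == 0.0

    def test_map_shrinks_toward_prior(self, rich_dataset_small, pop_params):
        """|eta_MAP| <= |eta_ML| subject-wise: the prior penalty can only
        pull estimates toward zero."""
        opts = FitOptions(dt=1.0)
        unpenalized = pop_params.with_(omega_CL=1.99)  # near-flat prior
        for rec in rich_dataset_small.records[:8]:
            e_map = map_individual(rec, pop_params, opts).eta
            e_ml = map_individual(rec, unpenalized, opts).eta
            assert abs(e_map) <= abs(e_ml) + 1e-6


class TestInference:
    @pytest.mark.parametrize("delta,df,p", [(3.84, 1, 0.050), (6.63, 1, 0.010), (0.0, 1, 1.0)])
    def test_lrt_boundary_values(self, delta, df, p):
        d, pval = lrt(100.0 + delta, 100.0, df)
        assert d == pytest.approx(delta)
        assert pval == pytest.approx(p, abs=5e-4)

    def test_bicc_penalty_arithmetic(self, rich_dataset_small, pop_params):
        """One extra observation-level parameter costs exactly
        log(N_observations); matched OFVs isolate the penalty."""
        opts = FAST
        full = fit_model(rich_dataset_small, options=FitOptions(gh_nodes=8, dt=1.0, maxiter=2))
        reduced = fit_model(
            rich_dataset_small,
            spec=ModelSpec(fixed={"Kenz": full.estimates.Kenz}),
            options=FitOptions(gh_nodes=8, dt=1.0, maxiter=2),
        )
        b_full = bicc(full, rich_dataset_small)
        b_red = bicc(reduced, rich_dataset_small)
        n_obs = rich_dataset_small.n_usable_observations
        assert (b_full - full.ofv) - (b_red - reduced.ofv) == pytest.approx(math.log(n_obs))

    def test_bicc_reduces_to_bic_when_counts_match(self):
        """With one observation per subject the two penalty terms share
        the same log factor: BICc = OFV + p log N."""
        truth = PopulationParameters()
        data = generate_tdm_dataset(
            DemographicsConfig(n_subjects=12),
            SamplingDesign(sample_times=(672.0,)), truth, seed=5,
            regimen=lambda c: build_regimen(c, 5.0, 12.0, 28.0),
        )
        assert len(data) == data.n_usable_observations == 12
        fit = fit_model(data, options=FitOptions(gh_nodes=8, dt=1.0, maxiter=2))
        assert bicc(fit, data) == pytest.approx(
            fit.ofv + fit.n_estimated * math.log(12)
        )

    def test_rse_information_scaling(self):
        """Quadrupling the cohort roughly halves the SE (1/sqrt(n))."""
        spec = ModelSpec(fixed={"Kenz": 0.15, "IC50": 1.77, "beta_age": -0.15})
        opts = FitOptions(gh_nodes=8, dt=1.0)
        ses = {}
        for n, seed in ((24, 21), (96, 21)):
            truth = PopulationParameters()
            data = generate_tdm_dataset(
                DemographicsConfig(n_subjects=n), SamplingDesign.rich(), truth, seed=seed,
                regimen=lambda c: build_regimen(c, 5.0, 12.0, 28.0),
            )
            fit = compute_rse(fit_model(data, spec=spec, options=opts), data, opts)
            assert fit.se is not None
            ses[n] = fit.se["CL_pop"]
            assert 0.5 < fit.rse_percent["CL_pop"] < 15.0
        assert ses[24] / ses[96] == pytest.approx(2.0, rel=0.35)


class TestStepwise:
    OPTS = FitOptions(gh_nodes=6, dt=1.0, maxiter=80)
    FIXED = {"Kenz": 0.15, "IC50": 1.77, "sigma_add": 2.0}

    def _dataset(self, truth, n=16, seed=0):
        return generate_tdm_dataset(
            DemographicsConfig(n_subjects=n),
            SamplingDesign(sample_times=(168.0, 672.0)),
            truth, seed=seed,
            regimen=lambda c: build_regimen(c, 5.0, 12.0, 28.0),
        )

    def test_strong_weight_effect_selected_sex_not(self):
        truth = PopulationParameters(beta_age=0.0)  # allometric weight only
        data = self._dataset(truth, n=20, seed=14)
        spec, trace = stepwise_covariates(
            data, options=self.OPTS, fixed=self.FIXED
        )
        assert spec.allometric_weight  # weight retained
        assert not spec.sex_effect

    def test_null_covariates_mostly_rejected(self):
        """Type-I control at the 3.84/6.63 gates: with no true covariate
        effects the final set is almost always empty."""
        truth = PopulationParameters(beta_age=0.0, beta_wt=0.0)
        n_empty, n_selected_total = 0, 0
        for seed in range(5):
            # weight covariate absent from the truth: disable allometry
            data = self._dataset(truth, n=12, seed=100 + seed)
            spec, trace = stepwise_covariates(
                data, candidates=("age_power", "sex_exponential"),
                options=self.OPTS, fixed=self.FIXED,
            )
            k = int(spec.age_power) + int(spec.sex_effect)
            n_selected_total += k
            n_empty += k == 0
        assert n_empty >= 3
        assert n_selected_total <= 3

    def test_threshold_boundary_strict(self):
        """An OFV drop below 3.84 must not admit a covariate; the gate is
        checked with the documented >= convention."""
        from pbpop.estimate import ModelSpec as MS

        # direct check of the gate logic via lrt: delta = 3.83 -> p > 0.05
        _, p = lrt(103.83, 100.0, 1)
        assert p > 0.05
        _, p = lrt(103.85, 100.0, 1)
        assert p < 0.05
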