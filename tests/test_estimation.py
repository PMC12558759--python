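import numpy as np
import pytest

from matrine_pbpk import DoseRegimen
from matrine_pbpk.estimation import (
    PLAUSIBLE_BOUNDS,
    EstimationError,
    FitSpec,
    fit_nelder_mead,
    negative_log_likelihood,
    pooled_geometric_mean,
    sensitivity_nsc,
)
from matrine_pbpk.synthetic import (
    default_base_parameters,
    experiment_1_spec,
    generate_observations,
    sample_cohort,
)

NO_IIV = {"iiv_cv": {}, "lloq_ug_per_kg": 1e-6}


def make_dataset(seed, residual_cv=0.2, n=6, dose=40.0):
    """Study-1-style cohort with residual noise only (no IIV)."""
    spec = experiment_1_spec(dose_mg_per_kg=dose, seed=seed, n_subjects=n,
                            residual_cv=residual_cv, **NO_IIV)
    cohort = sample_cohort(spec, base=default_base_parameters())
    profiles = generate_observations(cohort, spec)
    bw = float(np.mean([p.BW for p in cohort]))
    return profiles, DoseRegimen.single_oral(dose, bw)


class TestNSC:
    def test_linear_response_has_unit_nsc(self, gen_params):
        rep = sensitivity_nsc(
            gen_params, response_fn=lambda p: np.array([2.0 * p.k_a, 5.0 * p.k_a]),
            param_names=["k_a"])
        np.testing.assert_allclose(rep.nsc.loc["k_a"], 1.0, rtol=1e-9)

    def test_constant_response_has_zero_nsc(self, gen_params):
        rep = sensitivity_nsc(gen_params, response_fn=lambda p: np.array([3.0, 3.0]),
                              param_names=["k_a", "F"])
        np.testing.assert_allclose(rep.nsc.to_numpy(), 0.0, atol=1e-12)

    def test_matches_analytic_one_compartment_sensitivity(self, gen_params):
        """For C(t) = (D/V)·exp(−ke·t), NSC of ke is −ke·t exactly."""
        times = np.array([1.0, 5.0, 10.0])
        p = gen_params.replace(k_e=0.1)
        rep = sensitivity_nsc(
            p, response_fn=lambda q: 100.0 * np.exp(-q.k_e * times),
            param_names=["k_e"], times=times)
        np.testing.assert_allclose(rep.nsc.loc["k_e"], -0.1 * times, atol=1e-4)

    def test_invariant_to_response_units(self, gen_params):
        from matrine_pbpk import simulate

        reg = DoseRegimen.single_oral(40.0, gen_params.BW)
        a = sensitivity_nsc(gen_params, reg, param_names=["k_a", "k_bi"])
        b = sensitivity_nsc(
            gen_params,
            response_fn=lambda p: 1e3 * simulate(p, reg, a.times, method="expm").c_int,
            param_names=["k_a", "k_bi"], times=a.times)
        np.testing.assert_allclose(a.nsc.to_numpy(), b.nsc.to_numpy(), rtol=1e-9)

    def test_zero_response_slice_skipped_with_warning(self, gen_params):
        times = np.array([1.0, 2.0, 3.0])
        with pytest.warns(RuntimeWarning, match="skipped"):
            rep = sensitivity_nsc(
                gen_params,
                response_fn=lambda p: np.array([0.0, p.k_a, 2.0 * p.k_a]),
                param_names=["k_a"], times=times)
        assert rep.times.tolist() == [2.0, 3.0]


class TestNLL:
    def test_empty_observations_rejected(self, gen_params, regimen40):
        with pytest.raises(EstimationError):
            negative_log_likelihood(gen_params, [], regimen40)

    def test_minimized_at_generating_parameters_noise_free(self):
        profiles, regimen = make_dataset(seed=7, residual_cv=0.0)
        truth = default_base_parameters()
        nll_truth = negative_log_likelihood(truth, profiles, regimen)
        nll_off = negative_log_likelihood(
            truth.replace(k_a=truth.k_a * 1.3), profiles, regimen)
        assert nll_truth < nll_off

    def test_generator_beats_rival_in_most_replicates(self):
        """Monte-Carlo: the generating parameters have lower NLL than a
        perturbed rival in at least 95 of 100 seeded replicates."""
        truth = default_base_parameters()
        rival = truth.replace(k_a=truth.k_a * 1.5, k_bi=truth.k_bi * 0.5)
        wins = 0
        for seed in range(100):
            profiles, regimen = make_dataset(seed=seed)
            if (negative_log_likelihood(truth, profiles, regimen)
                    < negative_log_likelihood(rival, profiles, regimen)):
                wins += 1
        assert wins >= 95

    def test_geometric_mean_pooling_requires_common_schedule(self):
        profiles, _ = make_dataset(seed=0)
        clipped = profiles[0].__class__(
            subject_id="odd", time=profiles[0].time[:-1],
            conc=profiles[0].conc[:-1], censored=profiles[0].censored[:-1])
        with pytest.raises(EstimationError, match="schedule"):
            pooled_geometric_mean([profiles[0], clipped])


class TestFit:
    def test_start_at_truth_stays_at_truth(self):
        profiles, regimen = make_dataset(seed=3, residual_cv=0.0)
        truth = default_base_parameters()
        spec = FitSpec(param_names=("k_a",),
                       bounds={"k_a": PLAUSIBLE_BOUNDS["k_a"]},
                       start=truth, observed=tuple(profiles), regimen=regimen,
                       max_restarts=0)
        res = fit_nelder_mead(spec)
        assert abs(res.params.k_a - truth.k_a) / truth.k_a < 1e-6

    def test_single_parameter_recovery(self):
        """k_a recovered within 5% from a distant start at 20% residual CV."""
        profiles, regimen = make_dataset(seed=11)
        truth = default_base_parameters()
        spec = FitSpec(param_names=("k_a",),
                       bounds={"k_a": PLAUSIBLE_BOUNDS["k_a"]},
                       start=truth.replace(k_a=0.3),
                       observed=tuple(profiles), regimen=regimen,
                       max_restarts=1, seed=0)
        res = fit_nelder_mead(spec)
        assert res.params.k_a == pytest.approx(truth.k_a, rel=0.05)

    def test_three_parameter_batch_recovery(self):
        """Median error over 10 seeds within 15% for (k_st, k_a, k_bi)."""
        truth = default_base_parameters()
        names = ("k_st", "k_a", "k_bi")
        start = truth.replace(k_st=0.1, k_a=0.3, k_bi=0.01)
        errors = {n: [] for n in names}
        for seed in range(10):
            profiles, regimen = make_dataset(seed=seed)
            spec = FitSpec(param_names=names,
                           bounds={n: PLAUSIBLE_BOUNDS[n] for n in names},
                           start=start, observed=tuple(profiles),
                           regimen=regimen, max_restarts=1, seed=seed)
            res = fit_nelder_mead(spec)
            for n in names:
                errors[n].append(abs(getattr(res.params, n) - getattr(truth, n))
                                 / getattr(truth, n))
        for n in names:
            assert np.median(errors[n]) < 0.15, (n, errors[n])

    def test_result_respects_bounds(self):
        profiles, regimen = make_dataset(seed=5)
        truth = default_base_parameters()
        bounds = {"k_a": (0.9, 2.0)}  # excludes the generating value 0.856
        spec = FitSpec(param_names=("k_a",), bounds=bounds,
                       start=truth.replace(k_a=1.5),
                       observed=tuple(profiles), regimen=regimen,
                       max_restarts=1)
        res = fit_nelder_mead(spec)
        assert 0.9 <= res.params.k_a <= 2.0

    def test_unknown_parameter_rejected(self, gen_params, regimen40):
        profiles, regimen = make_dataset(seed=0, n=2)
        with pytest.raises(EstimationError):
            FitSpec(param_names=("k_met",), bounds={"k_met": (0, 1)},
                    start=gen_params, observed=tuple(profiles), regimen=regimen)
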