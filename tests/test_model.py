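import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from siderotrait.bayes.model import (
    ModelData,
    ModelSpec,
    UnconstrainedPosterior,
    log_posterior,
    prepare_model_data,
)
from siderotrait.design import X1, X2
from siderotrait.synthetic import SyntheticConfig, simulate_siderophore


def scipy_log_posterior(params, table, spec):
    """Independent term-by-term oracle built on scipy distributions."""
    alpha = np.asarray(params["alpha"], float)
    beta = np.asarray(params["beta"], float)
    sigma = (np.asarray(spec.fixed_sigma, float) if spec.fixed_sigma is not None
             else np.asarray(params["sigma"], float))
    tau = (np.asarray(spec.fixed_tau, float) if spec.fixed_tau is not None
           else np.asarray(params["tau"], float))
    lam = np.asarray(params["lam"], float)
    md = prepare_model_data(table)
    cell_of = {lab: i for i, lab in enumerate(md.cell_labels)}
    vg = spec.vargroup

    total = 0.0
    for _, row in table.iterrows():
        g = 2 * (row.isolate_type == "SBW25") + int(row.copper)  # canonical order
        c = cell_of[(g + 1, row.replicate)]
        total += stats.norm.logpdf(row.siderophore, lam[c], sigma[vg[g]])
    for (g1, _), i in cell_of.items():
        j = g1 - 1
        nu_j = alpha[X1[j] - 1] + beta[X1[j] - 1] * X2[j]
        total += stats.norm.logpdf(lam[i], nu_j, tau[j])
    for a in alpha:
        total += stats.halfnorm.logpdf(a, scale=spec.prior_alpha_sd)
    for b in beta:
        total += stats.norm.logpdf(b, scale=spec.beta_sd)
    if spec.fixed_sigma is None:
        for s in sigma:
            total += stats.expon.logpdf(s, scale=spec.sigma_scale)
    if spec.fixed_tau is None:
        for t in tau:
            total += stats.expon.logpdf(t, scale=spec.tau_scale)
    return total


def random_params(rng, md, spec):
    return {
        "alpha": rng.uniform(0.05, 1.5, 2),
        "beta": rng.normal(0, 0.2, 2),
        "sigma": rng.uniform(0.02, 0.5, spec.n_sigma),
        "tau": rng.uniform(0.01, 0.3, 4),
        "lam": rng.normal(0.5, 0.3, md.n_cells),
    }


class TestPrepareModelData:
    def test_sufficient_statistics(self, small_isolates):
        md = prepare_model_data(small_isolates)
        assert md.n_obs == len(small_isolates)
        manual = small_isolates.groupby(["group", "replicate"])["siderophore"]
        np.testing.assert_allclose(sorted(md.cell_n), sorted(manual.count()))
        total = small_isolates["siderophore"]
        assert md.cell_sum.sum() == pytest.approx(total.sum())
        assert md.cell_sumsq.sum() == pytest.approx((total**2).sum())

    def test_unknown_isolate_type(self, cell_table_builder):
        table = cell_table_builder({("community", 0, 1): [0.1, 0.2]})
        table.loc[0, "isolate_type"] = "weird"
        with pytest.raises(ValueError, match="isolate_type"):
            prepare_model_data(table)

    def test_ragged_cells(self, cell_table_builder):
        table = cell_table_builder({
            ("community", 0, 1): [0.1, 0.2],
            ("community", 1, 1): [0.3],
            ("SBW25", 0, 2): [0.6, 0.7, 0.8],
            ("SBW25", 1, 1): [0.5],
        })
        md = prepare_model_data(table)
        assert md.n_cells == 4
        np.testing.assert_array_equal(np.sort(md.cell_group), [0, 1, 2, 3])

    def test_empty_table(self):
        with pytest.raises(ValueError):
            prepare_model_data(pd.DataFrame(columns=["siderophore", "replicate",
                                                     "isolate_type", "copper"]))

    def test_nonfinite_rejected(self, cell_table_builder):
        table = cell_table_builder({("community", 0, 1): [0.1, float("nan")]})
        with pytest.raises(ValueError, match="non-finite"):
            prepare_model_data(table)


class TestLogPosterior:
    def test_single_observation_likelihood_term(self, cell_table_builder):
        # y == lambda and all SDs 1: the data term is exactly -log sqrt(2 pi)
        table = cell_table_builder({("community", 0, 1): [0.4]})
        spec = ModelSpec(variance_structure="single")
        md = prepare_model_data(table)
        params = {"alpha": [0.4, 0.4], "beta": [0.0, 0.0], "sigma": [1.0],
                  "tau": [1.0] * 4, "lam": [0.4]}
        lp = log_posterior(params, md, spec)
        # subtract every non-data term computed independently
        rest = (stats.norm.logpdf(0.4, 0.4, 1.0)  # lambda | nu, tau
                + 2 * stats.halfnorm.logpdf(0.4, scale=1.0)
                + 2 * stats.norm.logpdf(0.0, scale=0.25)
                + stats.expon.logpdf(1.0, scale=0.2)
                + 4 * stats.expon.logpdf(1.0, scale=0.2))
        assert lp - rest == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-12)

    @pytest.mark.parametrize("structure", ["per_group", "by_isolate_type",
                                           "by_copper", "single"])
    def test_matches_scipy_oracle(self, structure, rng):
        cfg = SyntheticConfig(seed=17, n_replicates=2, n_isolates=3)
        table = simulate_siderophore(cfg)
        spec = ModelSpec(variance_structure=structure)
        md = prepare_model_data(table)
        for _ in range(3):
            params = random_params(rng, md, spec)
            assert log_posterior(params, md, spec) == pytest.approx(
                scipy_log_posterior(params, table, spec), abs=1e-9
            )

    def test_support_violations(self, small_isolates):
        md = prepare_model_data(small_isolates)
        spec = ModelSpec()
        good = {"alpha": [0.5, 0.7], "beta": [0.0, 0.0], "sigma": [0.1] * 4,
                "tau": [0.05] * 4, "lam": [0.5] * md.n_cells}
        assert np.isfinite(log_posterior(good, md, spec))
        bad_sigma = dict(good, sigma=[0.1, -0.1, 0.1, 0.1])
        assert log_posterior(bad_sigma, md, spec) == -np.inf
        bad_tau = dict(good, tau=[0.0, 0.05, 0.05, 0.05])
        assert log_posterior(bad_tau, md, spec) == -np.inf
        bad_alpha = dict(good, alpha=[-0.1, 0.7])
        assert log_posterior(bad_alpha, md, spec) == -np.inf

    def test_shape_errors(self, small_isolates):
        md = prepare_model_data(small_isolates)
        spec = ModelSpec()
        params = {"alpha": [0.5, 0.7], "beta": [0.0, 0.0], "sigma": [0.1] * 3,
                  "tau": [0.05] * 4, "lam": [0.5] * md.n_cells}
        with pytest.raises(ValueError, match="sigma"):
            log_posterior(params, md, spec)

    def test_fixed_sigma_tau(self, cell_table_builder, rng):
        table = cell_table_builder({
            ("community", 0, 1): [0.1, 0.2],
            ("community", 1, 1): [0.3, 0.1],
            ("SBW25", 0, 1): [0.6, 0.7],
            ("SBW25", 1, 1): [0.5, 0.4],
        })
        spec = ModelSpec(fixed_sigma=(0.1, 0.2, 0.1, 0.2), fixed_tau=(0.3,) * 4)
        md = prepare_model_data(table)
        params = random_params(rng, md, spec)
        assert log_posterior(params, md, spec) == pytest.approx(
            scipy_log_posterior(params, table, spec), abs=1e-9
        )

    def test_prior_parameterization_flags(self, cell_table_builder):
        table = cell_table_builder({
            ("community", 0, 1): [0.1], ("community", 1, 1): [0.3],
            ("SBW25", 0, 1): [0.6], ("SBW25", 1, 1): [0.5],
        })
        md = prepare_model_data(table)
        params = {"alpha": [0.5, 0.7], "beta": [0.2, -0.1], "sigma": [0.1] * 4,
                  "tau": [0.05] * 4, "lam": [0.4] * md.n_cells}
        sd_spec = ModelSpec(beta_prior_parameter="sd")
        var_spec = ModelSpec(beta_prior_parameter="variance")
        dlt = log_posterior(params, md, var_spec) - log_posterior(params, md, sd_spec)
        expect = (stats.norm.logpdf(params["beta"], scale=0.5).sum()
                  - stats.norm.logpdf(params["beta"], scale=0.25).sum())
        assert dlt == pytest.approx(expect, abs=1e-10)
        rate_spec = ModelSpec(exponential_parameterization="rate")
        dlt2 = log_posterior(params, md, rate_spec) - log_posterior(params, md, sd_spec)
        # sigma and tau priors both reinterpret 0.2: 4 sigmas at 0.1, 4 taus at 0.05
        expect2 = (4 * stats.expon.logpdf(0.1, scale=5.0)
                   + 4 * stats.expon.logpdf(0.05, scale=5.0)
                   - 4 * stats.expon.logpdf(0.1, scale=0.2)
                   - 4 * stats.expon.logpdf(0.05, scale=0.2))
        assert dlt2 == pytest.approx(expect2, abs=1e-10)


class TestUnconstrainedPosterior:
    def test_gradient_matches_finite_differences(self, small_isolates, rng):
        md = prepare_model_data(small_isolates)
        for structure in ("per_group", "single"):
            post = UnconstrainedPosterior(md, ModelSpec(variance_structure=structure))
            z = post.initial_point(rng, jitter=0.5)
            _, grad = post.value_and_grad(z)
            eps = 1e-6
            for i in range(0, post.dim, max(1, post.dim // 10)):
                zp, zm = z.copy(), z.copy()
                zp[i] += eps
                zm[i] -= eps
                fd = (post.value(zp) - post.value(zm)) / (2 * eps)
                assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)

    def test_transform_round_trip(self, small_isolates, rng):
        md = prepare_model_data(small_isolates)
        spec = ModelSpec()
        post = UnconstrainedPosterior(md, spec)
        params = random_params(rng, md, spec)
        out = post.unpack(post.pack(params))
        for key in ("alpha", "beta", "sigma", "tau", "lam"):
            np.testing.assert_allclose(out[key], params[key], rtol=1e-12)

    def test_jacobian_consistency(self, small_isolates, rng):
        # transformed density == natural density + log|J|
        md = prepare_model_data(small_isolates)
        spec = ModelSpec()
        post = UnconstrainedPosterior(md, spec)
        params = random_params(rng, md, spec)
        z = post.pack(params)
        lp_t = post.value(z)
        lp_n = log_posterior(params, md, spec)
        jac = (np.log(params["alpha"]).sum() + np.log(params["sigma"]).sum()
               + np.log(params["tau"]).sum())
        assert lp_t == pytest.approx(lp_n + jac, abs=1e-9)


class TestModelSpecValidation:
    def test_bad_structure(self):
        with pytest.raises(ValueError, match="variance_structure"):
            ModelSpec(variance_structure="bogus")

    def test_sigma_count_follows_structure(self):
        assert ModelSpec(variance_structure="single").n_sigma == 1
        assert ModelSpec(variance_structure="by_copper").n_sigma == 2
        assert ModelSpec(variance_structure="per_group").n_sigma == 4

    def test_fixed_sigma_length_checked(self):
        with pytest.raises(ValueError, match="fixed_sigma"):
            ModelSpec(variance_structure="single", fixed_sigma=(0.1, 0.2))

    def test_positive_priors_required(self):
        with pytest.raises(ValueError):
            ModelSpec(prior_alpha_sd=0.0)
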