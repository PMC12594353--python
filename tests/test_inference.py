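import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp, ndtr

from revlearn.inference import (
    HierarchicalModel,
    compare_models,
    compute_looic,
    compute_rhat,
    natural_to_unconstrained,
    transform_to_natural,
)
from revlearn.models import MODELS


class TestRhat:
    def test_identical_chains_are_converged(self):
        x = np.random.default_rng(0).standard_normal(1000)
        r = compute_rhat(np.stack([x, x]))
        assert r == pytest.approx(1.0, abs=0.01)

    def test_stationary_chains(self):
        rng = np.random.default_rng(1)
        r = compute_rhat(rng.standard_normal((3, 10_000)))
        assert r < 1.01

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(2)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert compute_rhat(chains) > 2.0

    def test_within_chain_drift_is_caught_by_splitting(self):
        # both chains identical but trending: split halves disagree
        trend = np.linspace(0, 5, 1000)
        r = compute_rhat(np.stack([trend, trend]))
        assert r > 1.1

    def test_constant_chains_undefined(self):
        assert np.isnan(compute_rhat(np.ones((2, 100))))

    def test_input_requirements(self):
        with pytest.raises(ValueError):
            compute_rhat(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            compute_rhat(np.zeros((2, 3)))

    def test_agrees_with_arviz(self):
        import arviz as az

        rng = np.random.default_rng(3)
        draws = rng.standard_normal((3, 2000)) + rng.normal(0, 0.05, (3, 1))
        ours = compute_rhat(draws)
        ref = az.rhat(az.convert_to_dataset(draws[:, :, None]))["x"].values.item()
        assert ours == pytest.approx(ref, abs=0.02)


class TestLoo:
    def test_constant_over_draws_degenerates_to_column_sums(self):
        ll = np.tile(np.array([[-1.2, -0.7, -2.0]]), (200, 1))
        res = compute_looic(ll)
        assert res.elpd_loo == pytest.approx(-3.9, abs=1e-9)
        assert res.looic == pytest.approx(7.8, abs=1e-9)

    def test_looic_is_minus_two_elpd_exactly(self):
        rng = np.random.default_rng(4)
        res = compute_looic(rng.normal(-1, 0.3, (2, 300, 20)))
        assert res.looic == -2.0 * res.elpd_loo

    def test_pointwise_dominance_orders_looic(self):
        rng = np.random.default_rng(5)
        b = rng.normal(-1.5, 0.2, (400, 15))
        a = b + 0.3  # A beats B on every observation and draw
        assert compute_looic(a).looic < compute_looic(b).looic

    def test_tiny_matrix_matches_importance_sampling_oracle(self):
        """With too few draws for tail smoothing, PSIS-LOO reduces to plain
        importance sampling: elpd_i = log S - logsumexp(-ll_i)."""
        rng = np.random.default_rng(6)
        ll = rng.normal(-1, 0.4, (4, 3))
        res = compute_looic(ll)
        expected = sum(
            np.log(4) - logsumexp(-ll[:, i]) for i in range(3)
        )
        assert res.elpd_loo == pytest.approx(expected, abs=1e-8)

    def test_non_finite_entries_rejected(self):
        ll = np.zeros((10, 4))
        ll[3, 2] = -np.inf
        with pytest.raises(ValueError):
            compute_looic(ll)


class TestTransforms:
    @pytest.mark.parametrize("model_id", ["RW", "FU_RP_IP", "EWA"])
    def test_round_trip(self, model_id):
        spec = MODELS[model_id]
        rng = np.random.default_rng(7)
        u = rng.normal(0, 1.5, (20, spec.n_params))
        back = natural_to_unconstrained(spec, transform_to_natural(spec, u))
        assert np.allclose(back, u, atol=1e-10)

    def test_bounds_map_to_infinities(self):
        spec = MODELS["RW"]
        theta = transform_to_natural(spec, np.array([-np.inf, np.inf]))
        assert theta[0] == 0.0   # lower bound of eta
        assert theta[1] == 10.0  # upper bound of beta
        u = natural_to_unconstrained(spec, np.array([0.0, 10.0]))
        assert u[0] == -np.inf and u[1] == np.inf

    def test_prior_predictive_centres(self):
        """Group means drawn from the prior centre bounded parameters near 0.5
        (learning rates) and 5 (value sensitivity)."""
        rng = np.random.default_rng(8)
        mu = rng.standard_normal(50_000)
        spec = MODELS["RW"]
        nat = transform_to_natural(spec, np.column_stack([mu, mu]))
        assert nat[:, 0].mean() == pytest.approx(0.5, abs=0.01)
        assert nat[:, 1].mean() == pytest.approx(5.0, abs=0.1)


class TestHierarchicalFit:
    def test_fit_contract(self, rw_fit, rw_cohort):
        post = rw_fit.idata_.posterior
        assert post.sizes["chain"] == 2 and post.sizes["draw"] == 500
        assert post.sizes["subject"] == 12
        assert {"mu_eta", "mu_beta", "sigma_eta", "sigma_beta", "eta", "beta"} <= set(
            post.data_vars
        )
        assert rw_fit.looic_ == -2.0 * rw_fit.elpd_loo_
        assert rw_fit.max_rhat_ < 1.1
        assert np.isfinite(rw_fit.looic_)
        assert rw_fit.rhat_.index.str.startswith(("mu_pr", "log_sigma", "z_")).all()
        # natural-scale subject draws respect the bounds
        assert float(post["eta"].min()) >= 0.0 and float(post["eta"].max()) <= 1.0
        assert float(post["beta"].max()) <= 10.0

    def test_group_means_recover_generating_values(self, rw_fit, rw_cohort):
        from revlearn.comparison import hdi

        for j, name in enumerate(("eta", "beta")):
            draws = rw_fit.group_posterior(name, scale="unconstrained")
            lo, hi = hdi(draws, 0.97)
            assert lo - 0.15 <= rw_cohort["mu_u"][j] <= hi + 0.15, name

    def test_shrinkage_toward_group_mean(self, rw_fit, rw_cohort):
        """Subject-level posterior medians vary less across subjects than the
        generating subject-level true values."""
        true = rw_cohort["true_params"]
        recovered = rw_fit.subject_params_
        assert recovered[:, 0].std() < true[:, 0].std()
        # and they still track individual differences
        assert np.corrcoef(true[:, 0], recovered[:, 0])[0, 1] > 0.3

    def test_reproducibility(self, rw_cohort):
        kwargs = dict(model="RW", chains=2, warmup=150, draws=150, seed=42)
        a = HierarchicalModel(**kwargs).fit(rw_cohort["data"])
        b = HierarchicalModel(**kwargs).fit(rw_cohort["data"])
        assert np.array_equal(a.group_means_, b.group_means_)

    def test_input_validation(self, rw_cohort):
        data = rw_cohort["data"]
        single = data[data["subjID"] == "s00"]
        with pytest.raises(ValueError, match="2 subjects"):
            HierarchicalModel(model="RW").fit(single)
        two_conditions = data.copy()
        two_conditions.loc[two_conditions.index[:100], "condition"] = "LVLN"
        two_conditions.loc[two_conditions.index[100:], "condition"] = "HVLN"
        with pytest.raises(ValueError, match="one condition"):
            HierarchicalModel(model="RW").fit(two_conditions)

    def test_single_choice_subject_warns(self):
        frames = []
        rng = np.random.default_rng(0)
        for sid in ("a", "b", "c"):
            frames.append(pd.DataFrame({
                "subjID": sid,
                "trial": np.arange(1, 41),
                "choice": np.ones(40, int) if sid == "a" else rng.integers(1, 3, 40),
                "outcome": rng.choice([-1, 1], 40),
            }))
        with pytest.warns(UserWarning, match="single unique choice"):
            HierarchicalModel(model="RW", chains=2, warmup=100, draws=100, seed=0).fit(
                pd.concat(frames)
            )

    def test_default_profile_schedule(self):
        est = HierarchicalModel()
        assert est._schedule() == (3, 2000, 2000)
        assert HierarchicalModel(profile="desk")._schedule() == (3, 1000, 1000)


class TestModelComparison:
    def test_ranking_and_dominance(self, rw_fit, rw_cohort):
        # an intentionally flat competitor: EWA with few draws on the same data
        other = HierarchicalModel(model="EWA", chains=2, warmup=250, draws=250,
                                  seed=5).fit(rw_cohort["data"])
        table = compare_models([other, rw_fit])
        assert list(table["model"]) == sorted(
            ["RW", "EWA"], key=lambda m: table.set_index("model")["looic"][m]
        )
        assert table["winner"].sum() == 1
        assert table.loc[0, "d_looic"] == 0.0
        assert (table["d_looic"] >= 0).all()

    def test_mismatched_data_rejected(self, rw_fit, rw_cohort):
        other_data = rw_cohort["data"].copy()
        other_data["choice"] = 3 - other_data["choice"]
        other = HierarchicalModel(model="RW", chains=2, warmup=100, draws=100,
                                  seed=1).fit(other_data)
        with pytest.raises(ValueError, match="different datasets"):
            compare_models([rw_fit, other])

    def test_empty_input(self):
        with pytest.raises(ValueError):
            compare_models([])


def test_hmc_matches_ensemble_sampler_on_small_model(rw_cohort):
    """Dual-route check of the posterior itself: the package's Hamiltonian
    sampler against an independent affine-invariant ensemble sampler (emcee)
    on a reduced hierarchical problem."""
    emcee = pytest.importorskip("emcee")
    data = rw_cohort["data"]
    keep = [f"s{i:02d}" for i in range(4)]
    small = data[data["subjID"].isin(keep)].groupby("subjID", group_keys=False).head(80)

    est = HierarchicalModel(model="RW", chains=3, warmup=700, draws=700, seed=9)
    est.fit(small)

    from revlearn.inference import _frame_to_arrays

    spec = MODELS["RW"]
    _, choices, outcomes, resets = _frame_to_arrays(small)
    logp_and_grad = est._logp_and_grad_factory(spec, choices, outcomes, resets)
    dim = 2 * 2 + 4 * 2
    rng = np.random.default_rng(10)
    p0 = 0.05 * rng.standard_normal((4 * dim, dim))
    p0[:, 2:4] += np.log(0.1)
    sampler = emcee.EnsembleSampler(4 * dim, dim, lambda q: logp_and_grad(q)[0])
    state = sampler.run_mcmc(p0, 3000, progress=False,
                             rstate0=np.random.RandomState(11).get_state())
    flat = sampler.get_chain(discard=1500, flat=True)

    for j, name in enumerate(("eta", "beta")):
        ours = est.group_posterior(name, scale="unconstrained")
        theirs = flat[:, j]
        assert ours.mean() == pytest.approx(theirs.mean(), abs=0.15)
        assert ours.std() == pytest.approx(theirs.std(), abs=0.15)
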