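import numpy as np
import pytest

from mgpm.likelihood import tip_moments
from mgpm.models import ModelSpec
from mgpm.pmc import WeightedSample
from mgpm.predictive import (
    PredictiveDraws,
    model_comparison,
    posterior_predictive_draws,
    ppl,
    predictive_density_at_tips,
    simulate_tips,
)
from mgpm.treeio import TraitData, paint_regimes, random_clade_painting, random_ultrametric_tree, read_newick


@pytest.fixture
def five_tip_spec():
    tree = random_ultrametric_tree(5, 13)
    painting = random_clade_painting(tree, 2, 4, min_frac=0.0, max_frac=1.0)
    return ModelSpec(tree, painting, ("OU", "BM"))


def atom_sample(spec, theta):
    """A degenerate one-atom posterior at theta (in unbounded coordinates)."""
    z = spec.transform.to_unbounded(np.asarray(theta, dtype=float))
    return WeightedSample(z[None, :], np.array([1.0]), 0.0, spec=spec)


class TestSimulateTips:
    def test_vanishing_diffusion_pins_tips_to_root(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        spec = ModelSpec(tree, paint_regimes(tree, default="G"), ("BM",))
        x = simulate_tips(spec, spec.pack(1.7, [(1e-12,)]), 0)
        assert np.allclose(list(x.values()), 1.7, atol=1e-9)

    def test_strong_pull_reaches_optimum(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        spec = ModelSpec(tree, paint_regimes(tree, default="G"), ("OU",))
        x = simulate_tips(spec, spec.pack(-5.0, [(60.0, 3.0, 0.05)]), 1)
        assert np.allclose(list(x.values()), 3.0, atol=0.1)

    def test_moments_match_analytic_oracle(self, five_tip_spec):
        spec = five_tip_spec
        theta = spec.pack(0.4, [(1.2, 1.0, 0.9), (0.7,)])
        mean, cov = tip_moments(spec, theta)
        rng = np.random.default_rng(2)
        reps = np.array(
            [list(simulate_tips(spec, theta, rng).values()) for _ in range(4000)]
        )
        se_mean = np.sqrt(np.diag(cov) / 4000)
        assert np.all(np.abs(reps.mean(axis=0) - mean) < 4 * se_mean)
        emp_cov = np.cov(reps.T)
        assert emp_cov == pytest.approx(cov, abs=0.15 * np.max(np.diag(cov)))

    def test_deterministic_given_seed(self, five_tip_spec):
        theta = five_tip_spec.pack(0.0, [(1.0, 0.0, 1.0), (1.0,)])
        a = simulate_tips(five_tip_spec, theta, 5)
        b = simulate_tips(five_tip_spec, theta, 5)
        assert dict(a) == dict(b)


class TestPpl:
    def test_hand_worked_example(self):
        # x = (1,2); replicates {(1,2),(3,4)}: means (2,3), SSE 2; variances (2,2)
        draws = PredictiveDraws(np.array([[1.0, 2.0], [3.0, 4.0]]), ("a", "b"))
        score = ppl(np.array([1.0, 2.0]), draws, 1.0)
        assert score.sse == pytest.approx(2.0)
        assert score.variance_term == pytest.approx(4.0)
        assert score.total == pytest.approx(6.0)

    def test_lambda_ln_p_variant(self):
        draws = PredictiveDraws(np.array([[1.0, 2.0], [3.0, 4.0]]), ("a", "b"))
        score = ppl(np.array([1.0, 2.0]), draws, np.log(4))
        assert score.total == pytest.approx(2.0 + np.log(4) * 4.0)

    def test_perfect_replicates_zero_loss(self):
        draws = PredictiveDraws(np.tile([0.5, -1.0], (10, 1)), ("a", "b"))
        assert ppl(np.array([0.5, -1.0]), draws, 1.0).total == pytest.approx(0.0)

    def test_invariant_to_replicate_and_tip_order(self):
        rng = np.random.default_rng(3)
        reps = rng.normal(size=(50, 4))
        labels = ("a", "b", "c", "d")
        x = TraitData(dict(zip(labels, [0.1, -0.2, 0.5, 1.0])))
        t1 = ppl(x, PredictiveDraws(reps, labels), 1.0).total
        t2 = ppl(x, PredictiveDraws(reps[::-1], labels), 1.0).total
        perm = [2, 0, 3, 1]
        t3 = ppl(x, PredictiveDraws(reps[:, perm], tuple(labels[i] for i in perm)), 1.0).total
        assert t1 == pytest.approx(t2, abs=1e-12)
        assert t1 == pytest.approx(t3, abs=1e-10)

    def test_tip_mismatch_rejected(self):
        draws = PredictiveDraws(np.zeros((3, 2)), ("a", "b"))
        with pytest.raises(ValueError):
            ppl(TraitData({"a": 0.0, "z": 1.0}), draws)


class TestPosteriorPredictiveDraws:
    def test_degenerate_posterior_gives_sampling_distribution(self, five_tip_spec):
        spec = five_tip_spec
        theta = spec.pack(0.2, [(1.0, 0.5, 0.8), (0.9,)])
        sample = atom_sample(spec, theta)
        draws = posterior_predictive_draws(sample, 3000, 7)
        mean, cov = tip_moments(spec, theta)
        se = np.sqrt(np.diag(cov) / 3000)
        assert np.all(np.abs(draws.tip_means - mean) < 4 * se)
        assert draws.tip_variances == pytest.approx(np.diag(cov), rel=0.2)

    def test_stored_moments_recomputable_from_replicates(self, five_tip_spec):
        theta = five_tip_spec.pack(0.0, [(1.0, 0.0, 1.0), (1.0,)])
        draws = posterior_predictive_draws(atom_sample(five_tip_spec, theta), 100, 1)
        assert draws.tip_means == pytest.approx(draws.replicates.mean(axis=0), abs=0)
        assert draws.tip_variances == pytest.approx(
            draws.replicates.var(axis=0, ddof=1), abs=0
        )


class TestPredictiveDensity:
    def test_one_atom_bm_single_tip_exact_normal(self):
        from scipy import stats

        tree = read_newick("(A:1.5);")
        spec = ModelSpec(tree, paint_regimes(tree, default="G"), ("BM",))
        theta = spec.pack(0.4, [(1.1,)])
        grid = np.linspace(-5, 6, 200)
        curves = predictive_density_at_tips(atom_sample(spec, theta), grid, 50, 0)
        expected = stats.norm.pdf(grid, 0.4, np.sqrt(1.1**2 * 1.5))
        assert curves[0] == pytest.approx(expected, abs=1e-12)

    def test_curves_integrate_to_one(self, five_tip_spec):
        spec = five_tip_spec
        rng = np.random.default_rng(4)
        z = spec.transform.to_unbounded(
            np.abs(rng.normal(0.8, 0.2, size=(40, spec.n_params))) + 0.05
        )
        w = rng.uniform(size=40)
        sample = WeightedSample(z, w / w.sum(), 0.0, spec=spec)
        grid = np.linspace(-12, 12, 600)
        curves = predictive_density_at_tips(sample, grid, 100, 1)
        totals = np.trapezoid(curves, grid, axis=1)
        assert totals == pytest.approx(np.ones(5), abs=1e-3)

    def test_mixture_means_match_predictive_draw_means(self, five_tip_spec):
        spec = five_tip_spec
        theta = spec.pack(0.3, [(1.5, 1.0, 0.7), (0.8,)])
        sample = atom_sample(spec, theta)
        grid = np.linspace(-10, 12, 1200)
        curves = predictive_density_at_tips(sample, grid, 20, 2)
        curve_means = np.trapezoid(curves * grid[None, :], grid, axis=1)
        draws = posterior_predictive_draws(sample, 4000, 3)
        se = np.sqrt(draws.tip_variances / 4000)
        assert np.all(np.abs(curve_means - draws.tip_means) < 4 * se)


class TestModelComparison:
    def test_identical_models_score_identically_up_to_noise(self, five_tip_spec):
        spec = five_tip_spec
        theta = spec.pack(0.0, [(1.0, 0.5, 0.9), (0.8,)])
        x = simulate_tips(spec, theta, 11)
        sample = atom_sample(spec, theta)
        table = model_comparison(x, [("m", sample), ("m2", sample)], 4000, seed=5)
        a, b = table["ppl"].values
        assert a == pytest.approx(b, rel=0.15)

    def test_lambda_one_column_is_the_plain_score(self, five_tip_spec):
        spec = five_tip_spec
        theta = spec.pack(0.0, [(1.0, 0.5, 0.9), (0.8,)])
        x = simulate_tips(spec, theta, 11)
        table = model_comparison(x, [("m", atom_sample(spec, theta))], 500, seed=6)
        row = table.iloc[0]
        assert row["ppl"] == pytest.approx(row["sse"] + row["variance_term"], abs=1e-12)
        assert row["ppl_p"] == pytest.approx(row["sse"] + row["p"] * row["variance_term"], abs=1e-10)
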