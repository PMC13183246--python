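import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metabovar import (
    PosteriorDraws,
    build_design,
    flag_individuals,
    hpd_interval,
    pair_flag_counts,
    predictive_draws,
    replicate_datasets,
    summarize_flags,
)

from conftest import make_dataset


def brute_force_hpd(samples, level):
    """Exhaustive window search: the independent oracle for hpd_interval."""
    s = np.sort(np.asarray(samples, dtype=float))
    k = int(np.ceil(level * len(s)))
    best = None
    for i in range(len(s) - k + 1):
        width = s[i + k - 1] - s[i]
        if best is None or width < best[0]:
            best = (width, s[i], s[i + k - 1])
    return best[1], best[2]


class TestHPDInterval:
    def test_integers_1_to_100(self):
        lo, hi = hpd_interval(np.arange(1, 101, dtype=float), 0.95)
        assert (lo, hi) == (1.0, 95.0)  # all windows tie; lowest start wins

    def test_level_to_one_limit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        lo, hi = hpd_interval(x, 0.999999)
        assert (lo, hi) == (x.min(), x.max())

    def test_normal_draws_match_quantile_oracle(self):
        # symmetric density: HPD coincides with the equal-tail interval
        x = np.random.default_rng(1).standard_normal(100_000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_central_interval_option(self):
        x = np.random.default_rng(2).standard_normal(50_000)
        lo, hi = hpd_interval(x, 0.95, method="central")
        assert lo == pytest.approx(np.quantile(x, 0.025))
        assert hi == pytest.approx(np.quantile(x, 0.975))

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match=">= 100"):
            hpd_interval(np.arange(50, dtype=float), 0.95)

    @given(st.integers(0, 2**31 - 1), st.floats(0.5, 0.99),
           st.integers(100, 400))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_search(self, seed, level, n):
        """Shortest-window output equals exhaustive window search."""
        rng = np.random.default_rng(seed)
        x = rng.gamma(2.0, 1.0, n)  # skewed, so HPD != equal-tail
        assert hpd_interval(x, level) == brute_force_hpd(x, level)


def manual_draws(beta, u, R, individuals, metabolites, covariates=(), S=200):
    """PosteriorDraws with every retained draw equal to the given state."""
    beta = np.asarray(beta, float)
    u = np.asarray(u, float)
    R = np.asarray(R, float)
    return PosteriorDraws(
        beta_draws=np.tile(beta, (1, S, 1, 1)),
        u_draws=np.tile(u, (1, S, 1, 1)),
        G_draws=np.tile(np.eye(len(metabolites)), (1, S, 1, 1)),
        R_draws=np.tile(R, (1, S, 1, 1)),
        individuals=list(individuals), metabolites=list(metabolites),
        covariates=list(covariates))


@pytest.fixture
def two_indiv_setup():
    df = pd.DataFrame({
        "id": ["A"] * 2 + ["B"] * 2, "time": [1, 2, 1, 2],
        "a": [5.0, 5.1, 0.2, -0.1], "b": [1.0, 0.9, 1.2, 0.8],
    })
    ds = make_dataset(df, ["a", "b"])
    return ds, build_design(ds)


class TestPredictiveDraws:
    def test_zero_noise_limit_equals_fitted_means(self, two_indiv_setup):
        ds, design = two_indiv_setup
        beta = np.array([[2.0, 1.0]])
        u = np.array([[3.0, 0.0], [-2.0, 0.2]])
        draws = manual_draws(beta, u, np.zeros((2, 2)), ["A", "B"], ["a", "b"])
        pred = predictive_draws(draws, design, seed=0)
        k = pred.cell_index()[("A", 1)]
        assert np.allclose(pred.draws[:, k, 0], 5.0)  # 2 + 3, exactly
        assert np.allclose(pred.draws[:, k, 1], 1.0)

    def test_random_effect_centres_each_individual(self, two_indiv_setup):
        ds, design = two_indiv_setup
        beta = np.zeros((1, 2))
        u = np.array([[8.0, 8.0], [0.0, 0.0]])
        draws = manual_draws(beta, u, 0.01 * np.eye(2), ["A", "B"], ["a", "b"],
                             S=500)
        pred = predictive_draws(draws, design, seed=1)
        idx = pred.cell_index()
        assert pred.draws[:, idx[("A", 1)], 0].mean() == pytest.approx(8.0, abs=0.05)
        assert pred.draws[:, idx[("B", 1)], 0].mean() == pytest.approx(0.0, abs=0.05)

    def test_unknown_individual_rejected(self, two_indiv_setup):
        ds, design = two_indiv_setup
        draws = manual_draws(np.zeros((1, 2)), np.zeros((2, 2)), np.eye(2),
                             ["A", "B"], ["a", "b"])
        with pytest.raises(ValueError, match="not in the fitted model"):
            predictive_draws(draws, design, targets=[("Z", 1)])

    def test_predictive_mean_matches_analytic(self, small_design, fast_mcmc):
        """Per-cell predictive mean agrees with beta'x + u_i from the draws."""
        from metabovar import fit_independent_model, independent_to_draws

        # small real fit so beta/u/R vary across draws
        fits = fit_independent_model(small_design, fast_mcmc)
        draws = independent_to_draws(fits, small_design)
        pred = predictive_draws(draws, small_design, seed=3)
        k = 0
        ind, t = pred.cells[k]
        r = int(np.flatnonzero(
            (small_design.row_index["individual"] == ind)
            & (small_design.row_index["timepoint"] == t))[0])
        x = small_design.X[r]
        i = small_design.individuals.index(ind)
        analytic = (np.einsum("j,sjm->sm", x, draws.beta_pooled)
                    + draws.u_pooled[:, i, :]).mean(axis=0)
        S = pred.draws.shape[0]
        mc_se = pred.draws[:, k, :].std(axis=0, ddof=1) / np.sqrt(S)
        assert np.all(np.abs(pred.draws[:, k, :].mean(axis=0) - analytic)
                      <= 3 * mc_se)


class TestFlagIndividuals:
    def test_interior_and_exterior_points(self, two_indiv_setup):
        ds, design = two_indiv_setup
        rng = np.random.default_rng(5)
        beta = np.array([[5.0, 1.0]])
        u = np.zeros((2, 2))
        draws = manual_draws(beta, u, np.eye(2), ["A", "B"], ["a", "b"], S=500)
        pred = predictive_draws(draws, design, seed=2)
        # individual A observes ~5 for metabolite a (interior) while B
        # observes ~0, far below the predictive distribution centred at 5
        flags = flag_individuals(ds, pred)
        fa = flags[(flags.individual == "A") & (flags.metabolite == "a")]
        fb = flags[(flags.individual == "B") & (flags.metabolite == "a")]
        assert not fa["flagged"].any()
        assert fb["flagged"].all()

    def test_missing_observation_marked_absent(self, two_indiv_setup):
        ds, design = two_indiv_setup
        ds.data.loc[0, "a"] = np.nan
        draws = manual_draws(np.zeros((1, 2)), np.zeros((2, 2)), np.eye(2),
                             ["A", "B"], ["a", "b"], S=200)
        pred = predictive_draws(draws, design, seed=0)
        flags = flag_individuals(ds, pred)
        cell = flags[(flags.individual == "A") & (flags.timepoint == 1)
                     & (flags.metabolite == "a")]
        assert cell["flagged"].isna().all()
        assert (cell["lower"] < cell["upper"]).all()

    def test_lower_below_upper_everywhere(self, two_indiv_setup):
        ds, design = two_indiv_setup
        draws = manual_draws(np.zeros((1, 2)), np.zeros((2, 2)), np.eye(2),
                             ["A", "B"], ["a", "b"], S=300)
        flags = flag_individuals(ds, predictive_draws(draws, design, seed=4))
        assert (flags["lower"] < flags["upper"]).all()


def constructed_flags(spec, levels=(0.95,), metabolites=("m1", "m2", "m3", "m4")):
    """Flag table from {individual: {timepoint: [flagged metabolites]}}."""
    rows = []
    for lev in levels:
        for ind, times in spec.items():
            for t in (1, 2):
                flagged_set = set(times.get(t, []))
                for m in metabolites:
                    rows.append((ind, t, m, lev, 0.0, 1.0, 0.5,
                                 m in flagged_set))
    df = pd.DataFrame(rows, columns=["individual", "timepoint", "metabolite",
                                     "level", "lower", "upper", "observed",
                                     "flagged"])
    df["flagged"] = df["flagged"].astype("boolean")
    return df


class TestSummarizeFlags:
    def test_three_of_ten_individuals(self):
        spec = {f"i{k}": {} for k in range(10)}
        for k in range(3):
            spec[f"i{k}"] = {1: ["m1", "m2", "m3", "m4"]}
        summary = summarize_flags(constructed_flags(spec), min_metabolites=4)
        assert summary.proportions["proportion"].iloc[0] == pytest.approx(0.30)

    def test_threshold_one_saturates(self):
        spec = {f"i{k}": {1: ["m1"]} for k in range(6)}
        summary = summarize_flags(constructed_flags(spec), min_metabolites=1)
        assert summary.proportions["proportion"].iloc[0] == 1.0

    def test_flags_split_across_timepoints_do_not_count(self):
        # 3 + 1 flags over two timepoints never reaches a threshold of 4
        spec = {"i0": {1: ["m1", "m2", "m3"], 2: ["m4"]},
                "i1": {}, "i2": {}}
        summary = summarize_flags(constructed_flags(spec), min_metabolites=4)
        assert summary.proportions["n_flagged"].iloc[0] == 0

    def test_threshold_above_m_rejected(self):
        spec = {"i0": {1: ["m1"]}}
        with pytest.raises(ValueError, match="exceeds M"):
            summarize_flags(constructed_flags(spec), min_metabolites=9)


class TestPairFlagCounts:
    def test_triple_flag_combinatorics(self):
        spec = {"i0": {2: ["m1", "m2", "m3"]}, "i1": {}}
        counts = pair_flag_counts(constructed_flags(spec), 3, 0.95)
        for a, b in (("m1", "m2"), ("m1", "m3"), ("m2", "m3")):
            assert counts.loc[a, b] == 1
        assert counts.loc["m1", "m1"] == 1
        assert counts.loc["m4", "m4"] == 0

    def test_empty_restricted_set(self):
        spec = {"i0": {1: ["m1"]}}
        counts = pair_flag_counts(constructed_flags(spec), 3, 0.95)
        assert (counts.to_numpy() == 0).all()

    def test_symmetry_on_random_tables(self):
        rng = np.random.default_rng(7)
        mets = ["m1", "m2", "m3", "m4"]
        for _ in range(5):
            spec = {
                f"i{k}": {t: [m for m in mets if rng.random() < 0.4]
                          for t in (1, 2)}
                for k in range(8)
            }
            counts = pair_flag_counts(constructed_flags(spec), 2, 0.95)
            assert np.array_equal(counts.to_numpy(), counts.to_numpy().T)


class TestReplicateDatasets:
    def test_zero_noise_limit(self, two_indiv_setup):
        ds, design = two_indiv_setup
        beta = np.array([[2.0, -1.0]])
        u = np.array([[1.0, 0.5], [-1.0, 0.0]])
        draws = manual_draws(beta, u, np.zeros((2, 2)), ["A", "B"], ["a", "b"])
        rep = replicate_datasets(draws, design, 1, seed=0)[0]
        expected = design.X @ beta + u[design.indiv_idx]
        assert np.array_equal(rep, expected)

    def test_shape_conserved(self, two_indiv_setup):
        ds, design = two_indiv_setup
        draws = manual_draws(np.zeros((1, 2)), np.zeros((2, 2)), np.eye(2),
                             ["A", "B"], ["a", "b"])
        reps = replicate_datasets(draws, design, 5, seed=1)
        assert len(reps) == 5
        assert all(r.shape == design.Y.shape for r in reps)

    def test_too_many_replicates_rejected(self, two_indiv_setup):
        ds, design = two_indiv_setup
        draws = manual_draws(np.zeros((1, 2)), np.zeros((2, 2)), np.eye(2),
                             ["A", "B"], ["a", "b"], S=50)
        with pytest.raises(ValueError, match="exceeds"):
            replicate_datasets(draws, design, 51)

    def test_replicate_mean_consistent_with_predictive(self, two_indiv_setup):
        ds, design = two_indiv_setup
        beta = np.array([[2.0, 1.0]])
        u = np.array([[1.0, 0.0], [0.0, 1.0]])
        draws = manual_draws(beta, u, np.eye(2), ["A", "B"], ["a", "b"], S=400)
        reps = np.stack(replicate_datasets(draws, design, 100, seed=3))
        pred = predictive_draws(draws, design, seed=4)
        idx = pred.cell_index()
        for r, (ind, t) in enumerate(zip(design.row_index["individual"],
                                         design.row_index["timepoint"])):
            cell = pred.draws[:, idx[(ind, int(t))], :]
            se = cell.std(axis=0, ddof=1) / np.sqrt(100)
            assert np.all(np.abs(reps[:, r, :].mean(axis=0)
                                 - cell.mean(axis=0)) <= 4 * se)
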