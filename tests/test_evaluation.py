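"""Accuracy/bias statistics, CV schemes and the experiment grid."""

import numpy as np
import pandas as pd
import pytest

import tetrags as tg


class TestAccuracyAndBias:
    def test_correlation_trivial_cases(self):
        y = np.array([1.0, 2.0, 4.0, 3.0])
        assert tg.prediction_correlation(y, y) == pytest.approx(1.0)
        assert tg.prediction_correlation(-y, y) == pytest.approx(-1.0)
        assert tg.prediction_correlation(2 * y + 3, y) == pytest.approx(1.0)

    def test_correlation_errors(self):
        with pytest.raises(ValueError):
            tg.prediction_correlation([1, 2], [1, 2])
        with pytest.raises(ValueError):
            tg.prediction_correlation([1, 1, 1], [1, 2, 3])

    def test_bias_closed_forms(self):
        """beta > 1 flags a deflated prediction scale."""
        y = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        assert tg.prediction_bias(y, y) == pytest.approx(1.0)
        assert tg.prediction_bias(y / 2, y) == pytest.approx(2.0)
        assert tg.prediction_bias(2 * y, y) == pytest.approx(0.5)

    def test_bias_agrees_with_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        g = rng.normal(0, 1, 50)
        y = 0.7 * g + rng.normal(0, 0.5, 50)
        slope = sm.OLS(y, sm.add_constant(g)).fit().params[1]
        assert tg.prediction_bias(g, y) == pytest.approx(slope)

    def test_bias_zero_variance_error(self):
        with pytest.raises(ValueError):
            tg.prediction_bias([1.0, 1.0, 1.0], [1, 2, 3])


class TestKFoldCV:
    def test_deterministic_for_fixed_seed(self, sim_fixture):
        scheme = tg.CVScheme(k=5, n_repeats=2, seed=7)
        a = tg.kfold_cv(sim_fixture["y"], sim_fixture["G"], scheme)
        b = tg.kfold_cv(sim_fixture["y"], sim_fixture["G"], scheme)
        assert np.array_equal(a.gebv.to_numpy(), b.gebv.to_numpy())
        assert a.r == b.r and a.beta == b.beta

    def test_accuracy_reflects_heritability(self, sim_fixture):
        ev = tg.kfold_cv(sim_fixture["y"], sim_fixture["G"],
                         tg.CVScheme(k=5, n_repeats=3, seed=1))
        bv = sim_fixture["true_bv"].loc[ev.ids]
        r_bv = tg.prediction_correlation(ev.gebv, bv)
        assert 0.3 < r_bv < 0.95
        assert ev.per_repeat.shape[0] == 3

    def test_null_trait_has_no_accuracy(self):
        """With h2 = 0 the CV correlation is pure sampling noise."""
        f = tg.simulate_founders(8, 400, seed=41)
        pop = tg.cross_diallel(f, 8, seed=42).subset(np.arange(200))
        arch = tg.TraitArchitecture(n_qtl=40, heritability=0.0, residual_sd=1.0)
        rec, _ = tg.simulate_phenotypes(pop, arch, seed=43)
        y = pd.Series(rec["value"].to_numpy(), index=rec["genotype_id"].to_numpy())
        G = tg.grm_from_af(tg.allele_frequencies_from_dosages(
            pop.dosages, sample_ids=pop.sample_ids))
        ev = tg.kfold_cv(y, G, tg.CVScheme(k=5, n_repeats=5, seed=2))
        assert abs(ev.per_repeat["r"].mean()) < 0.15

    def test_small_fold_guard(self, sim_fixture):
        # 2 individuals in 2 folds leaves a single training individual
        y = sim_fixture["y"].iloc[:2]
        with pytest.raises(ValueError):
            tg.kfold_cv(y, sim_fixture["G"], tg.CVScheme(k=2, n_repeats=1))


class TestLOOCV:
    def test_equals_kfold_with_k_equal_n(self, sim_fixture):
        y = sim_fixture["y"].iloc[:30]
        G = sim_fixture["G"]
        loo = tg.loocv(y, G)
        kf = tg.kfold_cv(y, G, tg.CVScheme(k=30, n_repeats=1, seed=99))
        np.testing.assert_allclose(loo.gebv.to_numpy(), kf.gebv.to_numpy(),
                                   atol=1e-10)

    def test_close_to_five_fold(self, sim_fixture):
        y = sim_fixture["y"].iloc[:80]
        G = sim_fixture["G"]
        loo = tg.loocv(y, G)
        kf = tg.kfold_cv(y, G, tg.CVScheme(k=5, n_repeats=10, seed=3))
        assert abs(loo.r - kf.r) < 0.05

    def test_minimal_n(self, sim_fixture):
        y = sim_fixture["y"].iloc[:3]
        out = tg.loocv(y, sim_fixture["G"])
        assert out.gebv.size == 3
        with pytest.raises(ValueError):
            tg.loocv(sim_fixture["y"].iloc[:2], sim_fixture["G"])


class TestCrossPopulation:
    def test_duplicated_population_reaches_within_ceiling(self, sim_fixture):
        """Training on an exact genetic copy of the test set performs at
        least as well as within-population CV."""
        pop = sim_fixture["pop"]
        dup = tg.with_duplicates(pop, pop.sample_ids, suffix="_c")
        af = tg.allele_frequencies_from_dosages(dup.dosages,
                                                sample_ids=dup.sample_ids)
        G = tg.grm_from_af(af)
        y = sim_fixture["y"]
        y_train = pd.Series(y.to_numpy(), index=[s + "_c" for s in y.index])
        ev = tg.cross_population(y_train, y, G)
        cv = tg.kfold_cv(y, sim_fixture["G"], tg.CVScheme(k=5, n_repeats=2, seed=4))
        assert ev.r >= cv.r - 0.02

    def test_overlap_rejected(self, sim_fixture):
        y = sim_fixture["y"]
        with pytest.raises(ValueError):
            tg.cross_population(y.iloc[:50], y.iloc[40:], sim_fixture["G"])


class TestCombinedCV:
    def test_single_population_degenerates_to_kfold(self, sim_fixture):
        y, G = sim_fixture["y"], sim_fixture["G"]
        scheme = tg.CVScheme(k=5, n_repeats=2, seed=11)
        combined = tg.combined_cv({"only": y}, G, scheme)
        direct = tg.kfold_cv(y.loc[sorted(y.index)], G, scheme)
        np.testing.assert_allclose(combined["only"].gebv.to_numpy(),
                                   direct.gebv.to_numpy(), atol=1e-12)

    def test_label_permutation_invariance(self, sim_fixture):
        y, G = sim_fixture["y"], sim_fixture["G"]
        pops = {"a": y.iloc[:70], "b": y.iloc[70:]}
        scheme = tg.CVScheme(k=5, n_repeats=2, seed=12)
        fwd = tg.combined_cv(pops, G, scheme)
        rev = tg.combined_cv({"b": y.iloc[70:], "a": y.iloc[:70]}, G, scheme)
        assert fwd["a"].r == rev["a"].r
        assert fwd["b"].beta == rev["b"].beta

    def test_shared_ids_rejected(self, sim_fixture):
        y = sim_fixture["y"]
        with pytest.raises(ValueError):
            tg.combined_cv({"a": y.iloc[:70], "b": y.iloc[60:]},
                           sim_fixture["G"])


class TestExperimentGrid:
    def _study(self):
        f = tg.simulate_founders(8, 300, seed=61)
        popA = tg.cross_diallel(f, 5, seed=62, label="A").subset(np.arange(80), "A")
        popB = tg.cross_diallel(f, 3, seed=63, label="B").subset(np.arange(40), "B")
        pop = tg.concat_populations([popA, popB])
        arch = tg.TraitArchitecture(n_qtl=40, heritability=0.5)
        rec, _ = tg.simulate_phenotypes(pop, arch, seed=64)
        y = pd.Series(rec["value"].to_numpy(), index=rec["genotype_id"].to_numpy())
        af = tg.allele_frequencies_from_dosages(pop.dosages,
                                                sample_ids=pop.sample_ids)
        pops = {"A": list(popA.sample_ids), "B": list(popB.sample_ids)}
        return af, y, pops

    def test_single_cell_matches_direct_call(self):
        af, y, pops = self._study()
        scheme = tg.CVScheme(k=5, n_repeats=2)
        grid = tg.run_experiment_grid(af, y, {"A": pops["A"]},
                                      scheme=scheme, seed=5)
        row = grid[(grid.training_set == "A") & (grid.prediction_set == "A")]
        G = tg.grm_from_af(af)
        from tetrags.evaluation import _grid_seed
        direct = tg.kfold_cv(y.loc[pops["A"]], G,
                             tg.CVScheme(k=5, n_repeats=2, seed=_grid_seed(5, 1)))
        assert row["r_mean"].iloc[0] == pytest.approx(direct.r)
        assert row["beta_mean"].iloc[0] == pytest.approx(direct.beta)

    def test_random_marker_cells_aggregate_over_sets(self):
        af, y, pops = self._study()
        grid = tg.run_experiment_grid(
            af, y, pops, marker_sets=("random",), n_random_markers=100,
            n_random_sets=3, scheme=tg.CVScheme(k=5, n_repeats=1), seed=6)
        row = grid[(grid.training_set == "A") & (grid.prediction_set == "B")]
        assert row["n_runs"].iloc[0] == 3
        assert row["r_sd"].iloc[0] >= 0

    def test_subsample_cells_and_infeasible_handling(self):
        af, y, pops = self._study()
        grid = tg.run_experiment_grid(
            af, y, pops, subsample_sizes=(20,), n_subsamples=2,
            scheme=tg.CVScheme(k=5, n_repeats=1), seed=7)
        sub = grid[grid.subsample_size == 20]
        single = sub[sub.training_set != "combined"]
        assert (single["n_train"] <= 20).all()
        assert set(sub["training_set"]) == {"A", "B", "combined"}
        full = grid[grid.subsample_size == 0]
        assert len(full) == 6  # 2x2 train/pred + combined x 2

    def test_bias_convention_deflated_predictions(self):
        rng = np.random.default_rng(8)
        y = rng.normal(0, 2, 100)
        gebv = 0.4 * y + rng.normal(0, 0.1, 100)  # deflated scale
        assert tg.prediction_bias(gebv, y) > 1.0


def test_config_loader(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("seed: 3\nscheme:\n  k: 5\n  n_repeats: 50\n")
    cfg = tg.load_config(p)
    assert cfg["seed"] == 3 and cfg["scheme"]["k"] == 5
    bad = tmp_path / "bad.yaml"
    bad.write_text("- 1\n- 2\n")
    with pytest.raises(ValueError):
        tg.load_config(bad)
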