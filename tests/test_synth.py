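import numpy as np
import pandas as pd
import pytest
from scipy import stats

import microdiet as md
from microdiet.compositions import clr, ensure_positive
from microdiet.synth import SSS_ITEM_WEIGHTS, CohortSpec, default_taxon_names


def _small_spec(**kw):
    defaults = dict(n_healthy=10, n_ibs=10, taxon_names=default_taxon_names(12),
                    log_sd=0.8, zero_inflation=0.1, seed=1)
    defaults.update(kw)
    return CohortSpec(**defaults)


class TestGenerateCohort:
    def test_rows_on_simplex(self):
        table, labels = md.generate_cohort(_small_spec())
        np.testing.assert_allclose(table.values.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(table.values >= 0)
        assert list(labels.unique()) == ["healthy", "ibs"]

    def test_deterministic_under_seed(self):
        t1, _ = md.generate_cohort(_small_spec(seed=42))
        t2, _ = md.generate_cohort(_small_spec(seed=42))
        assert t1.data.equals(t2.data)

    def test_injected_depletion_lowers_group_mean(self):
        # large-n check that a -1 log2 effect shows up with the right sign
        spec = _small_spec(n_healthy=500, n_ibs=500,
                           effect_taxa={"Faecalibacterium": -1.0}, seed=3)
        table, labels = md.generate_cohort(spec)
        col = table.data["Faecalibacterium"]
        assert col[labels == "ibs"].mean() < col[labels == "healthy"].mean()

    def test_null_spec_gives_nominal_type_i_error(self):
        # 200 replicate null cohorts; per-taxon Mann-Whitney at alpha=0.05
        alpha, n_rep = 0.05, 200
        rejections = total = 0
        for rep in range(n_rep):
            spec = _small_spec(n_healthy=50, n_ibs=50, effect_taxa={},
                               zero_inflation=0.0, seed=1000 + rep)
            table, labels = md.generate_cohort(spec)
            screen = md.taxon_screen(table, labels)
            rejections += int((screen["p_value"] < alpha).sum())
            total += len(screen)
        lo, hi = stats.binom.ppf([0.005, 0.995], total, alpha)
        assert lo <= rejections <= hi

    def test_invalid_specs_name_the_field(self):
        with pytest.raises(ValueError, match="n_healthy"):
            md.generate_cohort(_small_spec(n_healthy=1))
        with pytest.raises(ValueError, match="effect_taxa"):
            md.generate_cohort(_small_spec(effect_taxa={"NotATaxon": 1.0}))
        with pytest.raises(ValueError, match="log_sd"):
            md.generate_cohort(_small_spec(log_sd=0.0))
        with pytest.raises(ValueError, match="zero_inflation"):
            md.generate_cohort(_small_spec(zero_inflation=1.5))


class TestGenerateTree:
    def test_leaf_set_matches_input(self):
        tree = md.generate_tree(["A", "B", "C", "D"], seed=0)
        assert {t.name for t in tree.tips()} == {"A", "B", "C", "D"}
        assert len(list(tree.tips())) == 4

    def test_same_seed_same_newick(self):
        n1 = str(md.generate_tree(default_taxon_names(10), seed=5))
        n2 = str(md.generate_tree(default_taxon_names(10), seed=5))
        assert n1 == n2

    def test_newick_roundtrip_preserves_branch_lengths(self):
        from microdiet.io import read_tree
        tree = md.generate_tree(default_taxon_names(8), seed=7)
        back = read_tree(str(tree))
        total = sum(n.length or 0 for n in tree.traverse())
        total_back = sum(n.length or 0 for n in back.traverse())
        assert total_back == pytest.approx(total, abs=1e-12)

    def test_positive_branch_lengths(self):
        tree = md.generate_tree(default_taxon_names(15), seed=9)
        assert all(n.length > 0 for n in tree.traverse() if n.length is not None)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            md.generate_tree(["only_one"], seed=0)


class TestGenerateClinical:
    def test_noiseless_scores_perfectly_correlated(self):
        idx = pd.Series(np.linspace(0.1, 0.9, 30))
        clin = md.generate_clinical(idx, slope=300, intercept=100, noise_sd=0, seed=0)
        totals = clin.sum(axis=1)
        r = np.corrcoef(idx, totals)[0, 1]
        assert r**2 == pytest.approx(1.0, abs=1e-12)

    def test_item_allocation_weights(self):
        idx = pd.Series([0.5])
        clin = md.generate_clinical(idx, slope=200, intercept=100, noise_sd=0, seed=0)
        np.testing.assert_allclose(clin.iloc[0].to_numpy(), 200 * np.array(SSS_ITEM_WEIGHTS))

    def test_zero_slope_gives_null_omega_squared(self):
        rng = np.random.default_rng(4)
        idx = pd.Series(rng.uniform(0, 1, 200))
        clin = md.generate_clinical(idx, slope=0, intercept=250, noise_sd=30, seed=8)
        w2 = md.omega_squared(idx.to_numpy(), clin.sum(axis=1).to_numpy())
        assert abs(w2) < 0.05

    def test_r_squared_matches_closed_form(self):
        # R^2 -> slope^2 Var(x) / (slope^2 Var(x) + noise^2)
        rng = np.random.default_rng(10)
        idx = pd.Series(rng.uniform(0, 1, 100))
        clin = md.generate_clinical(idx, slope=300, intercept=150, noise_sd=40, seed=11)
        totals = clin.sum(axis=1).to_numpy()
        sv = 300**2 * idx.var(ddof=1)
        theory = sv / (sv + 40**2)
        r2 = np.corrcoef(idx, totals)[0, 1] ** 2
        assert r2 == pytest.approx(theory, abs=0.08)  # ~3 sigma of the sampling spread

    def test_totals_clipped_to_instrument_range(self):
        idx = pd.Series([0.0, 1.0])
        clin = md.generate_clinical(idx, slope=1000, intercept=-200, noise_sd=0, seed=0)
        totals = clin.sum(axis=1)
        assert totals.min() >= 0 and totals.max() <= 500


class TestSimulateIntervention:
    @pytest.fixture()
    def setup(self):
        table, _ = md.generate_cohort(_small_spec(zero_inflation=0.0))
        response = md.NutrientResponseModel.random(table.taxon_names, seed=2)
        return table, response

    def test_zero_doses_zero_noise_identity(self, setup):
        table, response = setup
        scen = md.InterventionScenario(baseline=table, nutrient_doses={},
                                       response=response, noise_sd=0, seed=0)
        post = md.simulate_intervention(scen)
        np.testing.assert_allclose(post.values, table.values, atol=1e-9)

    def test_clr_shift_equals_response_times_dose(self, setup):
        table, response = setup
        sample = table.sample_ids[0]
        doses = {sample: {"nutrient_01": 2.0, "nutrient_05": 1.0}}
        scen = md.InterventionScenario(baseline=table, nutrient_doses=doses,
                                       response=response, noise_sd=0, seed=0)
        post = md.simulate_intervention(scen)
        eta = np.zeros(len(response.nutrient_names))
        eta[0], eta[4] = 2.0, 1.0
        expected = response.B @ eta
        observed = clr(ensure_positive(post.values[0])) - clr(ensure_positive(table.values[0]))
        np.testing.assert_allclose(observed, expected, atol=1e-6)

    def test_rows_stay_on_simplex(self, setup):
        table, response = setup
        doses = {s: {"nutrient_02": 3.0} for s in table.sample_ids}
        scen = md.InterventionScenario(baseline=table, nutrient_doses=doses,
                                       response=response, noise_sd=0.2, seed=1)
        post = md.simulate_intervention(scen)
        np.testing.assert_allclose(post.values.sum(axis=1), 1.0, atol=1e-9)

    def test_unknown_nutrient_rejected(self, setup):
        table, response = setup
        scen = md.InterventionScenario(
            baseline=table, nutrient_doses={table.sample_ids[0]: {"unobtainium": 1.0}},
            response=response, noise_sd=0, seed=0)
        with pytest.raises(ValueError, match="unobtainium"):
            md.simulate_intervention(scen)

    def test_unknown_sample_rejected(self, setup):
        table, response = setup
        scen = md.InterventionScenario(baseline=table,
                                       nutrient_doses={"ghost": {"nutrient_01": 1.0}},
                                       response=response, noise_sd=0, seed=0)
        with pytest.raises(ValueError, match="ghost"):
            md.simulate_intervention(scen)
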