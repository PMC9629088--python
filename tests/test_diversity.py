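import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import microdiet as md
from microdiet.diversity import (PRESENCE_THRESHOLD, bh_qvalues, distance_matrix,
                                 observed_richness, paired_t_from_summary)
from microdiet.io import read_tree
from microdiet.synth import default_taxon_names

from _oracles import bh_stepup_oracle, unifrac_branch_set_oracle


# ------------------------------------------------------------------- alpha/beta

def test_shannon_analytic_values():
    assert md.shannon(np.full(8, 1 / 8)) == pytest.approx(3.0)
    assert md.shannon([1.0, 0.0, 0.0]) == pytest.approx(0.0)
    assert md.shannon([0.5, 0.25, 0.25]) == pytest.approx(1.5)
    with pytest.raises(ValueError):
        md.shannon([-0.1, 1.1])


def test_observed_richness_ignores_pseudocounts():
    comp = np.array([0.5, 0.5 - 2e-6, 1e-6, 1e-6])
    assert observed_richness(comp) == 2


def test_bray_curtis_analytic_values():
    v = np.array([0.3, 0.7])
    assert md.bray_curtis(v, v) == pytest.approx(0.0)
    assert md.bray_curtis([1, 0], [0, 1]) == pytest.approx(1.0)
    assert md.bray_curtis([1, 0], [0.5, 0.5]) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        md.bray_curtis([0, 0], [0, 0])


class TestUnifrac:
    def test_identical_presence_sets_give_zero(self, four_leaf_tree):
        a = np.array([0.5, 0.5, 0.0, 0.0])
        assert md.unweighted_unifrac(a, a, list("ABCD"), four_leaf_tree) == 0.0

    def test_disjoint_clades_give_one(self, four_leaf_tree):
        a = np.array([0.5, 0.5, 0.0, 0.0])
        b = np.array([0.0, 0.0, 0.5, 0.5])
        assert md.unweighted_unifrac(a, b, list("ABCD"), four_leaf_tree) == pytest.approx(1.0)

    def test_spec_example_against_branch_oracle(self, four_leaf_tree):
        a = np.array([0.5, 0.5, 0.0, 0.0])  # {A, B}
        b = np.array([0.5, 0.0, 0.5, 0.0])  # {A, C}
        got = md.unweighted_unifrac(a, b, list("ABCD"), four_leaf_tree)
        want = unifrac_branch_set_oracle(four_leaf_tree, {"A", "B"}, {"A", "C"})
        assert got == pytest.approx(want)
        assert got == pytest.approx(0.6)

    @pytest.mark.parametrize("n_leaves", [3, 4, 5, 6])
    def test_exhaustive_agreement_on_all_presence_pairs(self, n_leaves):
        taxa = [chr(ord("A") + i) for i in range(n_leaves)]
        tree = md.generate_tree(taxa, seed=n_leaves)
        nonempty = [s for r in range(1, n_leaves + 1)
                    for s in itertools.combinations(taxa, r)]
        for sa in nonempty:
            for sb in nonempty:
                a = np.array([1.0 if t in sa else 0.0 for t in taxa])
                b = np.array([1.0 if t in sb else 0.0 for t in taxa])
                got = md.unweighted_unifrac(a / a.sum(), b / b.sum(), taxa, tree)
                want = unifrac_branch_set_oracle(tree, set(sa), set(sb))
                assert got == pytest.approx(want, abs=1e-12), (sa, sb)

    def test_taxon_absent_from_tree_rejected(self, four_leaf_tree):
        with pytest.raises(ValueError, match="absent"):
            md.unweighted_unifrac([1, 0], [0, 1], ["A", "Zzz"], four_leaf_tree)

    def test_presence_threshold_excludes_pseudocounted_zeros(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1):0;")
        a = np.array([0.5, 0.5, PRESENCE_THRESHOLD, 0.0])  # C at exactly the pseudocount
        b = np.array([0.5, 0.5, 0.0, 0.0])
        assert md.unweighted_unifrac(a, b, list("ABCD"), tree) == 0.0


class TestPermanova:
    def test_type_i_error_nominal_under_null(self, null_cohort):
        table, labels = null_cohort
        rng = np.random.default_rng(7)
        n_rep, alpha, hits = 100, 0.05, 0
        dm = distance_matrix(table, metric="braycurtis")
        for rep in range(n_rep):
            perm_labels = pd.Series(rng.permutation(labels.to_numpy()),
                                    index=labels.index)
            res = md.permanova(dm, perm_labels, n_permutations=999, seed=rep)
            hits += res.p_value <= alpha
        lo, hi = stats.binom.ppf([0.005, 0.995], n_rep, alpha)
        assert lo <= hits <= hi

    def test_min_p_at_gross_separation(self):
        # two internally-tight, mutually-distant blobs
        spec = md.default_cohort_spec(
            15, 15, n_taxa=30, effect_taxa={t: 5.0 for t in ["Bacteroides", "Prevotella",
                                                             "Faecalibacterium"]},
            log_sd=0.2, zero_inflation=0.0, seed=2)
        table, labels = md.generate_cohort(spec)
        dm = distance_matrix(table, metric="braycurtis")
        res = md.permanova(dm, labels, n_permutations=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_pseudo_f_invariant_to_label_names(self, null_cohort):
        table, labels = null_cohort
        dm = distance_matrix(table, metric="braycurtis")
        f1 = md.permanova(dm, labels, n_permutations=99, seed=0).pseudo_f
        swapped = labels.map({"healthy": "ibs", "ibs": "healthy"})
        f2 = md.permanova(dm, swapped, n_permutations=99, seed=0).pseudo_f
        assert f1 == pytest.approx(f2)

    def test_tiny_group_rejected(self, null_cohort):
        table, labels = null_cohort
        dm = distance_matrix(table, metric="braycurtis")
        bad = labels.copy()
        bad.iloc[:] = "a"
        bad.iloc[0] = "b"
        with pytest.raises(ValueError, match="fewer than 2"):
            md.permanova(dm, bad, n_permutations=99, seed=0)


class TestScreenAndBH:
    def test_bh_hand_example(self):
        np.testing.assert_allclose(bh_qvalues([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_bh_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            m = rng.integers(1, 13)
            p = rng.random(m)
            np.testing.assert_allclose(bh_qvalues(p), bh_stepup_oracle(p), atol=1e-12)

    def test_disjoint_supports_reach_tiny_p(self):
        rng = np.random.default_rng(0)
        vals = np.vstack([rng.uniform(0.0, 0.1, (20, 1)), rng.uniform(0.5, 1.0, (20, 1))])
        data = np.hstack([vals, 1 - vals])
        table = md.AbundanceTable(pd.DataFrame(
            data, index=[f"s{i}" for i in range(40)], columns=["marker", "rest"]))
        labels = pd.Series(["healthy"] * 20 + ["ibs"] * 20, index=table.sample_ids)
        screen = md.taxon_screen(table, labels)
        assert screen.set_index("taxon").loc["marker", "p_value"] < 1e-6
        assert screen.set_index("taxon").loc["marker", "direction"] == 1

    def test_constant_taxon_records_p_one(self):
        data = pd.DataFrame({"flat": [0.5] * 8, "var": np.linspace(0.4, 0.6, 8)},
                            index=[f"s{i}" for i in range(8)])
        table = md.AbundanceTable(data)
        labels = pd.Series(["healthy"] * 4 + ["ibs"] * 4, index=table.sample_ids)
        screen = md.taxon_screen(table, labels).set_index("taxon")
        assert screen.loc["flat", "p_value"] == 1.0

    def test_null_split_rarely_discovers(self, null_cohort):
        table, labels = null_cohort
        screen = md.taxon_screen(table, labels)
        # a single null cohort: BH should control discoveries near zero
        assert (screen["q_value"] < 0.05).mean() <= 0.05


class TestPairedT:
    def test_no_change_gives_p_one(self):
        res = md.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.t, res.p_value) == (0.0, 1.0)

    def test_symmetric_differences_cancel(self):
        res = md.paired_t([0, 0, 0, 0], [1, -1, 1, -1])
        assert res.t == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_summary_form_matches_trial_scale_change(self):
        # a mean drop of 124.6 (sd 28.5) over 14 subjects is overwhelming evidence
        res = paired_t_from_summary(-124.6, 28.5, 14)
        assert abs(res.t) == pytest.approx(16.36, abs=0.01)
        assert res.p_value < 0.001

    def test_degenerate_variance_flagged(self):
        res = md.paired_t([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert res.degenerate_variance
        assert res.p_value == 0.0
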