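import math

import numpy as np
import pandas as pd
import pytest

from ancrec.genefam_bd import (
    BDFitConfig,
    BDRates,
    ancestral_content,
    bd_generator,
    bd_stationary,
    bd_transition_probs,
    call_events,
    compare_gain_rates,
    family_loglik,
    fit_rates,
    gain_rates,
    gains_vs_substitutions,
    node_posteriors,
)
from ancrec.phylo_core import parse_newick
from ancrec.synthetic_data import simulate_family_evolution, simulate_tree

from conftest import enumeration_bd


class TestGenerator:
    def test_rows_sum_to_zero(self):
        Q = bd_generator(BDRates(0.4, 0.3, 0.8, cmax=6))
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)

    def test_zero_gain_state_zero_absorbing(self):
        Q = bd_generator(BDRates(0.0, 0.5, 0.7, cmax=5))
        assert np.allclose(Q[0], 0)

    def test_truncation_no_up_from_cap(self):
        Q = bd_generator(BDRates(1.0, 1.0, 1.0, cmax=4))
        assert Q[4, :4].tolist() == [0, 0, 0, 4.0]

    @pytest.mark.parametrize(
        "rates",
        [BDRates(0.4, 0.3, 0.8, cmax=6), BDRates(2.0, 0.0, 1.0, cmax=8)],
    )
    def test_kernel_matches_expm(self, rates):
        from scipy.linalg import expm

        ts = np.array([0.05, 0.5, 2.0, 10.0])
        P = bd_transition_probs(rates, ts)
        for i, t in enumerate(ts):
            assert np.abs(P[i] - expm(bd_generator(rates) * t)).max() < 1e-9

    def test_stationary_detailed_balance(self):
        rates = BDRates(0.7, 0.2, 1.1, cmax=7)
        pi = bd_stationary(rates)
        Q = bd_generator(rates)
        assert np.abs(pi @ Q).max() < 1e-12


class TestFamilyLoglik:
    def test_pure_death_closed_form(self):
        tree = parse_newick("(X:0.7):0;")
        rates = BDRates(0.0, 0.0, 1.3, cmax=5)
        prior = np.zeros(6)
        prior[1] = 1.0
        got = family_loglik(tree, {"X": 0}, rates, prior)
        assert got == pytest.approx(math.log(1 - math.exp(-1.3 * 0.7)))

    def test_zero_branches_return_root_prior(self):
        tree = parse_newick("((A:0,B:0):0,C:0);")
        rates = BDRates(0.5, 0.1, 0.5, cmax=4)
        prior = bd_stationary(rates)
        for state in (0, 1, 2):
            got = family_loglik(tree, {l: state for l in "ABC"}, rates, "stationary")
            assert got == pytest.approx(math.log(prior[state]))

    def test_label_mismatch(self):
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(KeyError):
            family_loglik(tree, {"A": 1}, BDRates(1, 0, 1))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration(self, four_leaf_tree, seed):
        rng = np.random.default_rng(seed)
        rates = BDRates(
            float(rng.uniform(0.2, 2)),
            float(rng.uniform(0, 0.5)),
            float(rng.uniform(0.2, 2)),
            cmax=3,
        )
        counts = {lab: int(rng.integers(0, 4)) for lab in "ABCD"}
        prior = bd_stationary(rates)
        want, _, _ = enumeration_bd(
            four_leaf_tree, counts, bd_generator(rates), prior
        )
        got = family_loglik(four_leaf_tree, counts, rates, "stationary")
        assert got == pytest.approx(want, abs=1e-8)


class TestPosteriors:
    def test_zero_length_star_point_mass(self):
        tree = parse_newick("(A:0,B:0,C:0);")
        rates = BDRates(0.5, 0.1, 0.5, cmax=4)
        post = node_posteriors(tree, {l: 1 for l in "ABC"}, rates)
        root = post[tree.root]
        assert root[1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration(self, four_leaf_tree, seed):
        rng = np.random.default_rng(100 + seed)
        rates = BDRates(
            float(rng.uniform(0.2, 2)),
            float(rng.uniform(0, 0.5)),
            float(rng.uniform(0.2, 2)),
            cmax=3,
        )
        counts = {lab: int(rng.integers(0, 4)) for lab in "ABCD"}
        _, marg, _ = enumeration_bd(
            four_leaf_tree, counts, bd_generator(rates), bd_stationary(rates)
        )
        post = node_posteriors(four_leaf_tree, counts, rates)
        for nid, want in marg.items():
            assert np.abs(post[nid] - want).max() < 1e-8
        for v in post.values():
            assert v.sum() == pytest.approx(1.0, abs=1e-9)

    def test_truncation_stability(self):
        tree = simulate_tree(8, seed=3, scale=0.5)
        matrix, _ = simulate_family_evolution(
            tree, 30, rates=BDRates(1.0, 0.2, 1.0), seed=4
        )
        leaves = tree.leaf_labels()
        fams = [f for f in matrix.columns if 0 < matrix[f].max() <= 4][:10]
        for fam in fams:
            counts = {l: int(matrix.loc[l, fam]) for l in leaves}
            p8 = node_posteriors(tree, counts, BDRates(1.0, 0.2, 1.0, cmax=8))
            p12 = node_posteriors(tree, counts, BDRates(1.0, 0.2, 1.0, cmax=12))
            for nid in p8:
                a = 1 - p8[nid][0]
                b = 1 - p12[nid][0]
                assert abs(a - b) < 1e-6


class TestEvents:
    def test_forced_loss_on_stem_branch(self):
        # family fixed everywhere except absent in the (C,D) clade
        tree = parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1)CD:0.1);")
        rates = BDRates(1e-4, 0.0, 1e-4, cmax=3)
        counts = {"A": 1, "B": 1, "C": 0, "D": 0}
        prior = np.array([0.0, 1.0, 0.0, 0.0])  # root surely present
        events = call_events(tree, counts, rates, prior, tau=0.5)
        cd = tree.node_by_label("CD").id
        row = events[events["child"] == cd].iloc[0]
        assert row["P_loss"] > 0.99
        assert bool(row["call_loss"])

    def test_exactly_half_not_called(self):
        df = pd.DataFrame({"P_gain": [0.5]})
        assert not (df["P_gain"] > 0.5).iloc[0]

    @pytest.mark.parametrize("seed", range(3))
    def test_joint_matches_enumeration(self, four_leaf_tree, seed):
        rng = np.random.default_rng(200 + seed)
        rates = BDRates(
            float(rng.uniform(0.2, 2)),
            float(rng.uniform(0, 0.5)),
            float(rng.uniform(0.2, 2)),
            cmax=3,
        )
        counts = {lab: int(rng.integers(0, 4)) for lab in "ABCD"}
        _, _, joints = enumeration_bd(
            four_leaf_tree, counts, bd_generator(rates), bd_stationary(rates)
        )
        events = call_events(four_leaf_tree, counts, rates)
        C = rates.cmax
        i = np.arange(C + 1)[:, None]
        j = np.arange(C + 1)[None, :]
        for _, row in events.iterrows():
            J = joints[(row["parent"], row["child"])]
            assert row["P_gain"] == pytest.approx(
                J[(i == 0) & (j >= 1)].sum(), abs=1e-8
            )
            assert row["P_loss"] == pytest.approx(
                J[(i >= 1) & (j == 0)].sum(), abs=1e-8
            )
            assert row["P_expand"] == pytest.approx(
                J[(j > i) & (i >= 1)].sum(), abs=1e-8
            )
            assert row["P_contract"] == pytest.approx(
                J[(i > j) & (j >= 1)].sum(), abs=1e-8
            )
            # the four classes plus "no change class" partition the joint
            no_change = (
                J[np.eye(C + 1, dtype=bool)].sum()
                + J[0, 0]
                - J[0, 0]  # diagonal already includes (0,0)
            )
            total = (
                row["P_gain"]
                + row["P_loss"]
                + row["P_expand"]
                + row["P_contract"]
                + no_change
            )
            assert total == pytest.approx(1.0, abs=1e-9)


class TestFitRates:
    def test_no_loss_observed_hits_lower_bound(self):
        tree = simulate_tree(8, seed=5, scale=2.0)
        matrix = pd.DataFrame(
            {"FAM1": [1] * 8}, index=pd.Index(tree.leaf_labels(), name="genome")
        )
        rates = fit_rates(
            tree, matrix, BDFitConfig(cmax=4, multi_start=1, fit_duplication=False)
        )
        assert rates.loc["FAM1", "loss"] <= 1e-3

    def test_ascent_and_empty_family_rejected(self):
        tree = simulate_tree(6, seed=6, scale=0.8)
        matrix, _ = simulate_family_evolution(
            tree, 10, rates=BDRates(1.0, 0.0, 1.0), seed=7
        )
        keep = matrix.columns[matrix.sum(axis=0) > 0]
        config = BDFitConfig(cmax=5, multi_start=1, fit_duplication=False)
        rates = fit_rates(tree, matrix[keep], config)
        leaves = tree.leaf_labels()
        for fam in keep:
            counts = {l: int(matrix.loc[l, fam]) for l in leaves}
            init = BDRates(0.5, 0.0, 1.0, 5)
            assert rates.loc[fam, "loglik"] >= family_loglik(
                tree, counts, init
            ) - 1e-9
        if (matrix.sum(axis=0) == 0).any():
            with pytest.raises(ValueError, match="zero genomes"):
                fit_rates(tree, matrix, config)


class TestContent:
    def test_threshold_is_strict(self):
        post = {"F1": {0: np.array([0.49, 0.51])}, "F2": {0: np.array([0.5, 0.5])}}
        content = ancestral_content(post, tau=0.5)
        assert content[0].present == {"F1"}

    def test_multicopy_subset_of_present(self):
        post = {
            "F1": {0: np.array([0.1, 0.2, 0.7])},
            "F2": {0: np.array([0.2, 0.6, 0.2])},
        }
        content = ancestral_content(post, tau=0.5)
        assert content[0].multicopy <= content[0].present
        assert content[0].multicopy == {"F1"}

    def test_monotone_in_tau(self):
        rng = np.random.default_rng(8)
        post = {
            f"F{i}": {0: np.diff(np.concatenate([[0], np.sort(rng.random(3)), [1]]))}
            for i in range(40)
        }
        sizes = []
        for tau in (0.3, 0.5, 0.7, 0.9):
            sizes.append(len(ancestral_content(post, tau)[0].present))
        assert sizes == sorted(sizes, reverse=True)


class TestGainRates:
    def _events(self, tree, gains_by_child):
        rows = []
        for n in tree.nodes:
            if n.parent is None:
                continue
            g = gains_by_child.get(n.id, 0)
            for k in range(max(g, 1)):
                rows.append(
                    {
                        "family": f"F{n.id}_{k}",
                        "parent": n.parent,
                        "child": n.id,
                        "child_is_leaf": n.is_leaf,
                        "branch_length": n.branch_length,
                        "call_gain": k < g,
                        "call_loss": False,
                    }
                )
        return pd.DataFrame(rows)

    def test_rate_values_and_conservation(self):
        tree = parse_newick("((A:0.05,B:0.1):0.2,C:0.4);")
        gains = {tree.node_by_label("A").id: 10}
        df = gain_rates(self._events(tree, gains), tree)
        row = df[df["child"] == tree.node_by_label("A").id].iloc[0]
        assert row["gain_rate"] == pytest.approx(200.0)
        assert df["n_gains"].sum() == 10
        assert set(df["branch_class"]) == {"ancestral", "terminal"}

    def test_zero_length_branch_flagged(self):
        tree = parse_newick("((A:0,B:0.1):0.2,C:0.4);")
        df = gain_rates(self._events(tree, {}), tree)
        row = df[df["child"] == tree.node_by_label("A").id].iloc[0]
        assert not row["rate_defined"]
        assert np.isnan(row["gain_rate"])


class TestRankSum:
    def test_exact_one_sided_sixth(self):
        _, p = compare_gain_rates([1, 2], [3, 4], "rank-sum", alternative="less")
        assert p == pytest.approx(1 / 6)

    def test_identical_groups_p_one(self):
        _, p = compare_gain_rates([5, 5, 5], [5, 5, 5], "rank-sum")
        assert p == pytest.approx(1.0)

    def test_normal_approx_close_to_exact(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0.5, 1, 6)
            _, p_exact = compare_gain_rates(a, b, "rank-sum", exact_max_n=12)
            _, p_approx = compare_gain_rates(a, b, "rank-sum", exact_max_n=0)
            assert abs(p_exact - p_approx) < 0.01 + 0.05 * p_exact

    def test_signed_rank_available(self):
        a = [1.0, 2.0, 3.0, 4.0, 6.0, 8.0]
        b = [2.0, 3.0, 4.0, 5.0, 7.0, 10.0]
        stat, p = compare_gain_rates(a, b, "signed-rank")
        assert 0 <= p <= 1

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_gain_rates([1.0], [2.0, 3.0])


class TestGainsVsSubstitutions:
    def test_proportional_gives_unit_correlation(self):
        tree = simulate_tree(10, seed=13, scale=0.5)
        rows = []
        content = {}
        for n in tree.nodes:
            if n.parent is None:
                continue
            n_gains = max(1, round(n.branch_length * 100))
            if not n.is_leaf:
                from ancrec.genefam_bd import AncestralGenome

                content[n.id] = AncestralGenome(
                    n.id, {f"F{i}" for i in range(100)}, set()
                )
            for k in range(n_gains):
                rows.append(
                    {
                        "family": f"F{n.id}_{k}",
                        "parent": n.parent,
                        "child": n.id,
                        "child_is_leaf": n.is_leaf,
                        "branch_length": n.branch_length,
                        "call_gain": True,
                        "call_loss": False,
                    }
                )
        out = gains_vs_substitutions(pd.DataFrame(rows), tree, content)
        assert out["r_pearson"] == pytest.approx(1.0, abs=1e-3)

    def test_constant_y_flagged(self):
        tree = simulate_tree(10, seed=14, scale=0.5)
        from ancrec.genefam_bd import AncestralGenome

        rows = []
        content = {}
        for n in tree.nodes:
            if n.parent is None:
                continue
            if not n.is_leaf:
                content[n.id] = AncestralGenome(n.id, {"F1"}, set())
            rows.append(
                {
                    "family": "F1",
                    "parent": n.parent,
                    "child": n.id,
                    "child_is_leaf": n.is_leaf,
                    "branch_length": n.branch_length,
                    "call_gain": True,
                    "call_loss": False,
                }
            )
        out = gains_vs_substitutions(pd.DataFrame(rows), tree, content)
        assert out["degenerate"]
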