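import numpy as np
import pytest
from scipy.linalg import expm

from ancrec.phylo_core import parse_newick
from ancrec.synthetic_data import simulate_thermometer_dataset, simulate_tree
from ancrec.thermometer import (
    FitConfig,
    NonHomT92Model,
    StemAlignment,
    ThermometerCalibration,
    build_stem_mask,
    calibrate_thermometer,
    fit_nonhom_t92,
    pic_contrasts,
    pic_correlation,
    predict_ancestral_ogt,
    pruning_loglik,
    sample_ancestral_replicates,
    stem_gc,
    t92_generator,
    t92_stationary,
    t92_transition_probs,
    transition_matrix,
)

from conftest import enumeration_loglik_t92


class TestStemMask:
    def _aln(self, seqs):
        return StemAlignment([f"S{i}" for i in range(len(seqs))], seqs)

    def test_unanimous(self):
        aln = self._aln(["ACGT", "TGCA"])
        mask = build_stem_mask(aln, {"S0": {1, 2}, "S1": {1, 2}})
        assert mask.tolist() == [True, True, False, False]

    def test_strict_consensus_empty_raises(self):
        aln = self._aln(["ACGT", "TGCA"])
        with pytest.raises(ValueError, match="empty stem mask"):
            build_stem_mask(aln, {"S0": {1}, "S1": {2}})

    def test_half_consensus(self):
        aln = self._aln(["ACGT", "TGCA"])
        mask = build_stem_mask(
            aln, {"S0": {1}, "S1": {2}}, consensus_fraction=0.5
        )
        assert mask.tolist() == [True, True, False, False]

    def test_gaps_do_not_vote(self):
        # S1 has a gap in column 0: only S0 votes there, so its single
        # stem annotation carries the column under strict consensus
        aln = self._aln(["ACGT", "-GCA"])
        mask = build_stem_mask(aln, {"S0": {1}, "S1": {1}})
        assert mask.tolist() == [True, False, False, False]
        # at fraction 0.5, S1's stem residue (column 1) also qualifies
        half = build_stem_mask(
            aln, {"S0": {1}, "S1": {1}}, consensus_fraction=0.5
        )
        assert half.tolist() == [True, True, False, False]

    def test_position_beyond_sequence(self):
        aln = self._aln(["ACGT", "TGCA"])
        with pytest.raises(ValueError, match="beyond"):
            build_stem_mask(aln, {"S0": {9}})


class TestStemGC:
    @pytest.mark.parametrize(
        "seq,mask,expected",
        [
            ("GCGC", [True] * 4, 100.0),
            ("ATAT", [True] * 4, 0.0),
            ("GCAT", [True, True, False, True], pytest.approx(200 / 3)),
            ("GC-N", [True] * 4, 100.0),  # gap and N excluded
        ],
    )
    def test_values(self, seq, mask, expected):
        assert stem_gc(seq, np.array(mask)) == expected

    def test_no_counted_bases(self):
        with pytest.raises(ValueError):
            stem_gc("----", np.array([True] * 4))


class TestCalibration:
    def test_exact_collinear(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        calib = calibrate_thermometer(
            tree, {"A": 50, "B": 60, "C": 70}, {"A": 40, "B": 60, "C": 80}
        )
        assert calib.slope == pytest.approx(2.0)
        assert calib.intercept == pytest.approx(-60.0)
        assert calib.r_pearson == pytest.approx(1.0)

    def test_flat_response_flagged(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        calib = calibrate_thermometer(
            tree, {"A": 50, "B": 60, "C": 70}, {"A": 55, "B": 55, "C": 55}
        )
        assert calib.slope == 0.0
        assert np.isnan(calib.r_pearson)

    def test_degenerate_gc(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_thermometer(
                tree, {"A": 50, "B": 50, "C": 50}, {"A": 40, "B": 60, "C": 80}
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        tree = simulate_tree(12, seed=seed)
        taxa = tree.leaf_labels()
        gc = {t: float(rng.uniform(40, 70)) for t in taxa}
        ogt = {t: float(2.1 * gc[t] - 55 + rng.normal(0, 4)) for t in taxa}
        calib = calibrate_thermometer(tree, gc, ogt)
        x = np.array([gc[t] for t in sorted(taxa)])
        y = np.array([ogt[t] for t in sorted(taxa)])
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert calib.slope == pytest.approx(beta[0], abs=1e-10)
        assert calib.intercept == pytest.approx(beta[1], abs=1e-10)


class TestPIC:
    def test_linear_dependence_gives_unit_correlation(self):
        tree = simulate_tree(10, seed=2)
        x = {t: float(i) for i, t in enumerate(tree.leaf_labels())}
        y = {t: 2 * x[t] for t in x}
        assert pic_correlation(tree, x, y) == pytest.approx(1.0)

    def test_constant_trait_raises(self):
        tree = simulate_tree(6, seed=2)
        x = {t: 1.0 for t in tree.leaf_labels()}
        y = {t: float(i) for i, t in enumerate(tree.leaf_labels())}
        with pytest.raises(ValueError, match="zero variance"):
            pic_correlation(tree, x, y)

    def test_two_leaves_insufficient(self):
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            pic_contrasts(tree, {"A": 1.0, "B": 2.0})

    def test_brownian_simulation_recovers_correlation(self):
        # bivariate Brownian motion with true correlation 0.8
        rho, n_tips = 0.8, 200
        tree = simulate_tree(n_tips, seed=9, scale=1.0)
        rng = np.random.default_rng(9)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        vals = {tree.root: np.zeros(2)}
        for nid in tree.preorder():
            if nid == tree.root:
                continue
            t = tree.nodes[nid].branch_length
            step = rng.multivariate_normal([0, 0], cov * t)
            vals[nid] = vals[tree.nodes[nid].parent] + step
        x = {tree.nodes[l].label: vals[l][0] for l in tree.leaves()}
        y = {tree.nodes[l].label: vals[l][1] for l in tree.leaves()}
        assert pic_correlation(tree, x, y) == pytest.approx(rho, abs=0.1)


class TestT92:
    @pytest.mark.parametrize("theta,kappa", [(0.2, 0.5), (0.5, 1.0), (0.9, 10.0)])
    def test_generator_properties(self, theta, kappa):
        Q = t92_generator(theta, kappa)
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
        pi = t92_stationary(theta)
        assert np.allclose(pi @ Q, 0, atol=1e-12)
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_jukes_cantor_limit(self):
        Q = t92_generator(0.5, 1.0)
        off = Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_generator_bounds(self):
        with pytest.raises(ValueError):
            t92_generator(0.0, 1.0)
        with pytest.raises(ValueError):
            t92_generator(0.5, 0.0)

    def test_transition_matrix_identity_and_limit(self):
        Q = t92_generator(0.7, 2.0)
        assert np.allclose(transition_matrix(Q, 0.0), np.eye(4), atol=1e-12)
        P = transition_matrix(Q, 1e6)
        assert np.abs(P - t92_stationary(0.7)[None, :]).max() < 1e-8

    @pytest.mark.parametrize("theta,kappa,t", [(0.3, 2.0, 0.5), (0.8, 5.0, 2.0)])
    def test_power_series_oracle(self, theta, kappa, t):
        Q = t92_generator(theta, kappa)
        series = np.eye(4)
        term = np.eye(4)
        for k in range(1, 50):
            term = term @ (Q * t) / k
            series = series + term
        assert np.abs(transition_matrix(Q, t) - series).max() < 1e-10

    @pytest.mark.parametrize("seed", range(4))
    def test_closed_form_matches_expm(self, seed):
        rng = np.random.default_rng(seed)
        thetas = rng.uniform(0.05, 0.95, size=6)
        ts = rng.uniform(0, 3, size=6)
        kappa = float(rng.uniform(0.3, 8))
        P = t92_transition_probs(thetas, kappa, ts)
        for i in range(6):
            ref = expm(t92_generator(thetas[i], kappa) * ts[i])
            assert np.abs(P[i] - ref).max() < 1e-10
        assert np.allclose(P.sum(axis=2), 1, atol=1e-12)
        assert (P >= 0).all()


def _random_model(tree, rng, kappa=2.5, theta_root=0.55):
    return NonHomT92Model(
        kappa=kappa,
        theta_root=theta_root,
        theta_b={
            n.id: float(rng.uniform(0.2, 0.8))
            for n in tree.nodes
            if n.parent is not None
        },
    )


class TestPruningLoglik:
    def test_single_leaf_zero_branch(self):
        tree = parse_newick("(L:0):0;")
        aln = StemAlignment(["L"], ["G"])
        model = NonHomT92Model(2.0, 0.6, {tree.node_by_label("L").id: 0.5})
        assert pruning_loglik(tree, aln, model) == pytest.approx(np.log(0.3))

    def test_two_leaves_zero_branches(self):
        tree = parse_newick("(A:0,B:0);")
        ids = {lab: tree.node_by_label(lab).id for lab in "AB"}
        model = NonHomT92Model(1.0, 0.6, {ids["A"]: 0.5, ids["B"]: 0.5})
        same = StemAlignment(["A", "B"], ["G", "G"])
        assert pruning_loglik(tree, same, model) == pytest.approx(np.log(0.3))
        diff = StemAlignment(["A", "B"], ["G", "A"])
        assert pruning_loglik(tree, diff, model) == -np.inf

    def test_label_mismatch(self, four_leaf_tree, rng):
        aln = StemAlignment(["A", "B", "C", "X"], ["A", "C", "G", "T"])
        with pytest.raises(ValueError, match="mismatch"):
            pruning_loglik(four_leaf_tree, aln, _random_model(four_leaf_tree, rng))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration(self, four_leaf_tree, seed):
        rng = np.random.default_rng(seed)
        model = _random_model(four_leaf_tree, rng)
        seqs = ["".join(rng.choice(list("ACGT-"), 20)) for _ in range(4)]
        aln = StemAlignment(["A", "B", "C", "D"], seqs)
        got = pruning_loglik(four_leaf_tree, aln, model)
        want = enumeration_loglik_t92(four_leaf_tree, aln, model)
        assert got == pytest.approx(want, abs=1e-8)


class TestFit:
    def test_homogeneous_recovery_and_ascent(self):
        # data simulated under constant theta: fitted thetas near truth
        tree = simulate_tree(16, seed=6, scale=0.8)
        aln, _, _ = simulate_thermometer_dataset(
            tree, calibration=(2.0, -60.0), ogt_root=80.0, ogt_bm_variance=0.0,
            n_sites=1000, seed=7,
        )
        # ogt_bm_variance 0 -> every branch at theta = (80+60)/2/100 = 0.7
        config = FitConfig(multi_start=1, maxiter=100, seed=0)
        model = fit_nonhom_t92(tree, aln, config)
        thetas = np.array(list(model.theta_b.values()))
        assert abs(np.median(thetas) - 0.7) < 0.05
        init = NonHomT92Model(
            config.kappa_init, 0.5, {n: 0.5 for n in model.theta_b}
        )
        assert model.loglik >= pruning_loglik(tree, aln, init)

    def test_same_seed_same_result(self):
        tree = simulate_tree(8, seed=11, scale=0.5)
        aln, _, _ = simulate_thermometer_dataset(tree, n_sites=120, seed=12)
        config = FitConfig(multi_start=2, maxiter=40, seed=5)
        m1 = fit_nonhom_t92(tree, aln, config)
        m2 = fit_nonhom_t92(tree, aln, config)
        assert m1.kappa == m2.kappa
        assert m1.theta_b == m2.theta_b


class TestAncestralSampling:
    def test_zero_length_forcing(self):
        tree = parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
        seq = "ACGTG"
        aln = StemAlignment(list("ABCD"), [seq] * 4)
        rng = np.random.default_rng(0)
        model = _random_model(tree, rng)
        reps = sample_ancestral_replicates(tree, aln, model, R=20, seed=1)
        want = np.array([0, 1, 2, 3, 2])
        for nid in reps.node_ids:
            assert (reps.sequences[nid] == want[None, :]).all()

    def test_marginals_match_enumeration(self, four_leaf_tree):
        rng = np.random.default_rng(3)
        model = _random_model(four_leaf_tree, rng)
        seqs = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(4)]
        aln = StemAlignment(["A", "B", "C", "D"], seqs)
        reps = sample_ancestral_replicates(four_leaf_tree, aln, model, R=1, seed=0)
        # enumeration of per-site joint over the two internal nodes
        import itertools as it
        from ancrec.thermometer import t92_generator, t92_stationary
        from scipy.linalg import expm as sexpm

        enc = aln.encoded()
        row = {lab: i for i, lab in enumerate(aln.labels)}
        internals = [n.id for n in four_leaf_tree.nodes if not n.is_leaf]
        P = {
            n.id: sexpm(
                t92_generator(model.theta_b[n.id], model.kappa) * n.branch_length
            )
            for n in four_leaf_tree.nodes
            if n.parent is not None
        }
        pi = t92_stationary(model.theta_root)
        for site in range(enc.shape[1]):
            post = {nid: np.zeros(4) for nid in internals}
            tot = 0.0
            for assign in it.product(range(4), repeat=len(internals)):
                amap = dict(zip(internals, assign))
                p = pi[amap[four_leaf_tree.root]]
                for n in four_leaf_tree.nodes:
                    if n.parent is None:
                        continue
                    tgt = (
                        enc[row[n.label], site] if n.is_leaf else amap[n.id]
                    )
                    p *= P[n.id][amap[n.parent], tgt]
                tot += p
                for nid in internals:
                    post[nid][amap[nid]] += p
            for nid in internals:
                got = reps.marginals[nid][site]
                assert np.abs(got - post[nid] / tot).max() < 1e-8
                assert got.sum() == pytest.approx(1.0, abs=1e-12)

    def test_root_sampling_frequencies_match_posterior(self):
        tree = parse_newick("((A:0.4,B:0.4):0.3,C:0.7);")
        aln = StemAlignment(["A", "B", "C"], ["G", "G", "A"])
        rng = np.random.default_rng(4)
        model = _random_model(tree, rng)
        R = 10_000
        reps = sample_ancestral_replicates(tree, aln, model, R=R, seed=2)
        marg = reps.marginals[tree.root][0]
        freq = np.bincount(reps.sequences[tree.root][:, 0], minlength=4) / R
        se = np.sqrt(marg * (1 - marg) / R)
        assert (np.abs(freq - marg) <= 3 * np.maximum(se, 1.0 / R)).all()


class TestPredictOgt:
    def test_plug_in_point_and_degenerate_ci(self):
        tree = parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
        # force every replicate's stem GC to 55% via frozen tips
        seq = "GC" * 55 + "AT" * 45  # 200 sites, GC 55%
        aln = StemAlignment(list("ABCD"), [seq] * 4)
        rng = np.random.default_rng(0)
        model = _random_model(tree, rng)
        reps = sample_ancestral_replicates(tree, aln, model, R=10, seed=0)
        calib = ThermometerCalibration(2.0, -60.0, 1.0, 1.0, 1.0, 3)
        for est in predict_ancestral_ogt(reps, calib, tree):
            assert est.point == pytest.approx(50.0)
            assert (est.ci_low, est.ci_high) == (pytest.approx(50.0),) * 2
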