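"""Likelihood engine: pruning, optimizers, distances, BIONJ, tree building."""

import itertools

import numpy as np
import pytest

from aamatrix import (
    Alignment,
    AMINO_ACIDS,
    PhyloTree,
    RateMatrix,
    TreeLikelihood,
    UndefinedDistanceError,
    bionj_tree,
    build_ml_tree,
    discrete_gamma,
    distance_matrix,
    ml_distance,
    read_newick,
)
from aamatrix.likelihood import BuilderError
from aamatrix.simulate import SimulationSpec, evolve_alignment, random_tree
from conftest import random_alignment, random_reversible_model


def brute_force_site_loglik(aln, tree, model, rates):
    """Exhaustive sum over all internal-node state assignments.

    Deliberately avoids dynamic programming: every joint assignment of the
    internal nodes is enumerated and its probability accumulated.  Vectorized
    over assignments for speed, but mathematically a plain sum.
    """
    codes = aln.codes()
    taxrow = {t: i for i, t in enumerate(aln.taxa)}
    internal = [u for u in range(tree.n_nodes)
                if tree.children(u) and tree.labels[u] is None]
    pos = {u: i for i, u in enumerate(internal)}
    m = len(internal)
    # all 20^m joint assignments, one row each
    grids = np.meshgrid(*([np.arange(20)] * m), indexing="ij")
    assigns = np.stack([g.ravel() for g in grids], axis=1)  # (20^m, m)

    out = np.zeros(aln.s)
    for j in range(aln.s):
        tot = 0.0
        for c in range(rates.ncat):
            P = {v: model.transition_matrix(rates.rates[c] * tree.blen[v])
                 for v in range(tree.n_nodes) if tree.parent[v] >= 0}

            def state_of(v):
                if v in pos:
                    return assigns[:, pos[v]]
                code = codes[taxrow[tree.labels[v]], j]
                return np.full(assigns.shape[0], code)

            root_state = state_of(0)
            prob = np.where(root_state != 20, model.pi[root_state % 20], 1.0)
            for v in range(tree.n_nodes):
                if tree.parent[v] < 0:
                    continue
                sv = state_of(v)
                su = state_of(int(tree.parent[v]))
                factor = np.where(sv != 20, P[v][su % 20, sv % 20], 1.0)
                prob = prob * factor
            tot += prob.sum() / rates.ncat
        out[j] = np.log(tot)
    return out


class TestPruning:
    def test_two_identical_residues_zero_length(self, uniform_model):
        aln = Alignment("x", ["A", "B"], ["A", "A"])
        tree = read_newick("(A:0.0,B:0.0);")
        tl = TreeLikelihood(aln, tree, uniform_model, discrete_gamma(1.0, 1))
        sll = tl.site_log_likelihoods()
        assert sll.values[0] == pytest.approx(-np.log(20.0), abs=1e-12)

    @pytest.mark.parametrize("ncat", [1, 4])
    def test_matches_exhaustive_enumeration(self, ncat):
        rng = np.random.default_rng(11)
        model = random_reversible_model(rng)
        rates = discrete_gamma(0.7, ncat)
        tree = read_newick("((A:0.12,B:0.3):0.08,(C:0.05,D:0.4):0.2);")
        aln = random_alignment(rng, ["A", "B", "C", "D"], 10)
        mine = TreeLikelihood(aln, tree, model, rates).site_log_likelihoods().values
        oracle = brute_force_site_loglik(aln, tree, model, rates)
        assert np.abs((mine - oracle) / oracle).max() < 1e-12

    def test_missing_data_as_uniform_conditional(self):
        rng = np.random.default_rng(12)
        model = random_reversible_model(rng)
        rates = discrete_gamma(0.9, 2)
        tree = read_newick("((A:0.1,B:0.2):0.1,(C:0.3,D:0.1):0.05);")
        aln = Alignment("m", ["A", "B", "C", "D"], ["AX-R", "ARBR", "AZNR", "AR-R"])
        mine = TreeLikelihood(aln, tree, model, rates).site_log_likelihoods().values
        oracle = brute_force_site_loglik(aln, tree, model, rates)
        assert np.abs(mine - oracle).max() < 1e-10

    def test_single_gamma_category_equals_no_rate_variation(self):
        rng = np.random.default_rng(13)
        model = random_reversible_model(rng)
        tree = read_newick("((A:0.1,B:0.2):0.1,C:0.3);")
        aln = random_alignment(rng, ["A", "B", "C"], 30)
        v1 = TreeLikelihood(aln, tree, model, discrete_gamma(2.0, 1)).site_log_likelihoods()
        from aamatrix import RateModel

        v2 = TreeLikelihood(aln, tree, model, RateModel(1.0, 1, np.array([1.0]))).site_log_likelihoods()
        assert np.allclose(v1.values, v2.values, atol=0)

    def test_total_is_sum_of_values(self):
        rng = np.random.default_rng(14)
        model = random_reversible_model(rng)
        tree = read_newick("((A:0.1,B:0.2):0.1,C:0.3);")
        aln = random_alignment(rng, ["A", "B", "C"], 200)
        sll = TreeLikelihood(aln, tree, model, discrete_gamma(0.8, 4)).site_log_likelihoods()
        assert sll.total == pytest.approx(sll.values.sum(), abs=1e-9)

    def test_rerooting_invariance(self, lg_model, gamma4):
        """A reversible model's likelihood cannot depend on the stored root."""
        rng = np.random.default_rng(15)
        spec = SimulationSpec(n_taxa=8, s_sites=50, seed=4)
        tree = random_tree(spec)
        aln = evolve_alignment(tree, lg_model, gamma4, 50, seed=5)
        base = TreeLikelihood(aln, tree, lg_model, gamma4).log_likelihood()
        import dendropy

        d = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        for node in list(d.preorder_internal_node_iter())[1:3]:
            d.reroot_at_node(node, update_bipartitions=False)
            alt = read_newick(d.as_string(schema="newick"))
            ll = TreeLikelihood(aln, alt, lg_model, gamma4).log_likelihood()
            assert ll == pytest.approx(base, abs=1e-10 * abs(base))

    def test_leaf_taxon_mismatch_rejected(self, lg_model, gamma4):
        from aamatrix import ValidationError

        aln = Alignment("x", ["A", "B", "Z"], ["AR", "AR", "AR"])
        tree = read_newick("((A:0.1,B:0.2):0.1,C:0.3);")
        with pytest.raises(ValidationError):
            TreeLikelihood(aln, tree, lg_model, gamma4)


class TestBranchOptimization:
    def test_two_taxon_matches_closed_form_distance(self, uniform_model):
        rng = np.random.default_rng(16)
        s1 = "".join(rng.choice(list(AMINO_ACIDS), 400))
        s2 = list(s1)
        for i in range(190):  # p = 19/40 differences
            s2[i] = AMINO_ACIDS[(AMINO_ACIDS.index(s2[i]) + 1) % 20]
        aln = Alignment("p", ["a", "b"], [s1, "".join(s2)])
        tree = read_newick("(a:0.3,b:0.3);")
        rates = discrete_gamma(1.0, 1)
        tl = TreeLikelihood(aln, tree, uniform_model, rates)
        opt = tl.optimize_branch_lengths(tol=1e-9)
        t_hat = opt.blen.sum()
        closed = -(19.0 / 20.0) * np.log(1.0 - (20.0 / 19.0) * (190 / 400))
        assert t_hat == pytest.approx(closed, abs=1e-6)

    def test_fixed_point_and_monotonicity(self, lg_model, gamma4):
        spec = SimulationSpec(n_taxa=6, s_sites=300, seed=21)
        tree = random_tree(spec)
        aln = evolve_alignment(tree, lg_model, gamma4, 300, seed=22)
        tl = TreeLikelihood(aln, tree, lg_model, gamma4)
        ll0 = tl.log_likelihood()
        tl.optimize_branch_lengths()
        ll1 = tl.log_likelihood()
        assert ll1 >= ll0 - 1e-9
        # already at an optimum: another pass changes logL by < tol
        tl.optimize_branch_lengths(tol=1e-4)
        ll2 = tl.log_likelihood()
        assert ll2 >= ll1 - 1e-9
        assert ll2 - ll1 < 0.01


class TestAlphaOptimization:
    def test_no_rate_variation_pushes_alpha_high(self, lg_model):
        """Homogeneous data drive the shape toward the rate-homogeneous regime.

        With finite data the profile is flat above alpha ~ 20 (the four
        category rates are all within a few percent of 1 there), so the
        fitted value lands anywhere in that plateau rather than exactly at
        the search bound.
        """
        spec = SimulationSpec(n_taxa=8, s_sites=800, seed=31)
        tree = random_tree(spec)
        flat = discrete_gamma(1e9, 1)  # effectively rate-homogeneous
        aln = evolve_alignment(tree, lg_model, flat, 800, seed=32)
        tl = TreeLikelihood(aln, tree, lg_model, discrete_gamma(1.0, 4))
        fitted = tl.optimize_alpha()
        assert fitted.alpha > 10.0
        assert np.abs(discrete_gamma(fitted.alpha, 4).rates - 1.0).max() < 0.25

    def test_alpha_recovery_from_simulation(self, lg_model):
        spec = SimulationSpec(n_taxa=16, s_sites=2000, seed=33,
                              branch_length_mean=0.12)
        tree = random_tree(spec)
        aln = evolve_alignment(tree, lg_model, discrete_gamma(0.5, 4), 2000, seed=34)
        tl = TreeLikelihood(aln, tree, lg_model, discrete_gamma(1.0, 4))
        fitted = tl.optimize_alpha()
        assert 0.35 <= fitted.alpha <= 0.70

    def test_optimizer_contract(self, lg_model):
        spec = SimulationSpec(n_taxa=6, s_sites=200, seed=35)
        tree = random_tree(spec)
        aln = evolve_alignment(tree, lg_model, discrete_gamma(0.4, 4), 200, seed=36)
        tl = TreeLikelihood(aln, tree, lg_model, discrete_gamma(1.0, 4))
        ll_at_one = tl.log_likelihood()
        tl.optimize_alpha()
        assert tl.log_likelihood() >= ll_at_one - 1e-9


class TestMLDistance:
    def test_identical_sequences(self, uniform_model):
        codes = Alignment("i", ["a", "b"], ["ARNDC", "ARNDC"]).codes()
        assert ml_distance(codes[0], codes[1], uniform_model) == 0.0

    def test_uniform_closed_form(self, uniform_model):
        # 19 of 40 sites differ: t = -(19/20) ln(1 - (20/19) p)
        s1 = (AMINO_ACIDS * 2)
        s2 = list(s1)
        for i in range(19):
            s2[i] = AMINO_ACIDS[(AMINO_ACIDS.index(s2[i]) + 1) % 20]
        codes = Alignment("u", ["a", "b"], [s1, "".join(s2)]).codes()
        t_hat = ml_distance(codes[0], codes[1], uniform_model)
        assert t_hat == pytest.approx((19.0 / 20.0) * np.log(2.0), abs=1e-5)

    def test_saturation_returns_cap(self, uniform_model):
        # all sites differ: p = 1 >= 19/20 -> divergent closed form -> cap
        s1 = AMINO_ACIDS
        s2 = AMINO_ACIDS[1:] + AMINO_ACIDS[0]
        codes = Alignment("s", ["a", "b"], [s1, s2]).codes()
        assert ml_distance(codes[0], codes[1], uniform_model) == 10.0

    def test_monotone_in_differences(self, uniform_model):
        base = list(AMINO_ACIDS * 4)  # 80 sites
        prev = 0.0
        for ndiff in [4, 12, 24, 40, 56]:
            mutated = list(base)
            for i in range(ndiff):
                mutated[i] = AMINO_ACIDS[(AMINO_ACIDS.index(mutated[i]) + 1) % 20]
            codes = Alignment("m", ["a", "b"], ["".join(base), "".join(mutated)]).codes()
            d = ml_distance(codes[0], codes[1], uniform_model)
            assert d >= prev
            prev = d

    def test_no_coobserved_sites_rejected(self, uniform_model):
        codes = Alignment("n", ["a", "b"], ["AR--", "--AR"]).codes()
        with pytest.raises(UndefinedDistanceError):
            ml_distance(codes[0], codes[1], uniform_model)


class TestBIONJ:
    def test_three_taxon_pendant_lengths(self):
        D = np.array([[0.0, 0.3, 0.4], [0.3, 0.0, 0.5], [0.4, 0.5, 0.0]])
        tree = bionj_tree(D, ["A", "B", "C"])
        lengths = {tree.labels[v]: tree.blen[v] for v in range(tree.n_nodes)
                   if tree.labels[v] is not None}
        assert lengths["A"] == pytest.approx(0.1, abs=1e-12)
        assert lengths["B"] == pytest.approx(0.2, abs=1e-12)
        assert lengths["C"] == pytest.approx(0.3, abs=1e-12)

    @staticmethod
    def _tree_metric(tree):
        """Leaf-to-leaf path-length matrix of a PhyloTree."""
        n_nodes = tree.n_nodes
        chains = []
        for v in range(n_nodes):
            chain = {}
            x, dist = v, 0.0
            while x >= 0:
                chain[x] = dist
                dist += tree.blen[x]
                x = int(tree.parent[x])
            chains.append(chain)
        leaves = [v for v in range(n_nodes) if tree.labels[v] is not None]
        labels = [tree.labels[v] for v in leaves]
        n = len(leaves)
        D = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                va, vb = leaves[a], leaves[b]
                shared = set(chains[va]) & set(chains[vb])
                D[a, b] = D[b, a] = min(chains[va][c] + chains[vb][c] for c in shared)
        return D, labels

    def test_additive_distances_recover_tree_exactly(self):
        source = read_newick(
            "((A:0.11,B:0.23):0.07,(C:0.05,(D:0.3,E:0.17):0.09):0.13);"
        )
        D, labels = self._tree_metric(source)
        built = bionj_tree(D, labels)
        assert built.rf_distance(source) == 0
        D2, labels2 = self._tree_metric(built)
        order = [labels2.index(l) for l in labels]
        assert np.abs(D2[np.ix_(order, order)] - D).max() < 1e-10

    def test_taxon_order_invariance(self):
        source = read_newick(
            "((A:0.11,B:0.23):0.07,(C:0.05,(D:0.3,E:0.17):0.09):0.13);"
        )
        D, labels = self._tree_metric(source)
        t1 = bionj_tree(D, labels)
        perm = [3, 1, 4, 0, 2]
        Dp = D[np.ix_(perm, perm)]
        t2 = bionj_tree(Dp, [labels[i] for i in perm])
        assert t1.rf_distance(t2) == 0

    def test_two_taxon_trivial(self):
        tree = bionj_tree(np.array([[0.0, 0.7], [0.7, 0.0]]), ["a", "b"])
        assert tree.total_length() == pytest.approx(0.7)


class TestBuildMLTree:
    def test_recovers_generating_topology(self, lg_model, gamma4):
        spec = SimulationSpec(n_taxa=8, s_sites=1000, tree_shape="balanced",
                              branch_length_law="constant",
                              branch_length_mean=0.15, seed=41)
        tree = random_tree(spec)
        aln = evolve_alignment(tree, lg_model, gamma4, 1000, seed=42)
        built, rates, info = build_ml_tree(aln, lg_model)
        assert built.rf_distance(tree) == 0

    def test_two_taxon_degenerate(self, lg_model):
        rng = np.random.default_rng(43)
        aln = random_alignment(rng, ["a", "b"], 100)
        tree, rates, info = build_ml_tree(aln, lg_model, ncat=1)
        codes = aln.codes()
        assert tree.total_length() == pytest.approx(
            ml_distance(codes[0], codes[1], lg_model), abs=1e-6
        )

    def test_optimization_improves_on_bionj_start(self, lg_model, gamma4):
        spec = SimulationSpec(n_taxa=6, s_sites=300, seed=44)
        tree = random_tree(spec)
        aln = evolve_alignment(tree, lg_model, gamma4, 300, seed=45)
        _, _, info = build_ml_tree(aln, lg_model)
        assert info["loglik"] >= info["loglik_bionj"]

    def test_external_builder_roundtrip(self, lg_model, tmp_path):
        rng = np.random.default_rng(46)
        aln = random_alignment(rng, ["a", "b", "c", "d"], 60)
        # a trivial "builder": copies a pre-made Newick into place
        prebuilt = tmp_path / "fixed.nwk"
        prebuilt.write_text("((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05);\n")
        cmd = f"cp {prebuilt} {{tree}}"
        tree, rates, info = build_ml_tree(aln, lg_model, ncat=1, external_cmd=cmd)
        assert sorted(tree.leaf_labels) == ["a", "b", "c", "d"]

    def test_external_builder_failure_reported(self, lg_model):
        rng = np.random.default_rng(47)
        aln = random_alignment(rng, ["a", "b", "c"], 30)
        with pytest.raises(BuilderError):
            build_ml_tree(aln, lg_model, external_cmd="false")


class TestCostScaling:
    def test_pruning_cost_linear_in_taxa_and_sites(self, lg_model, gamma4):
        """Doubling n or s roughly doubles (never quadruples) pruning time."""
        import time

        def cost(n, s):
            spec = SimulationSpec(n_taxa=n, s_sites=1, seed=51,
                                  branch_length_mean=0.3)  # deep: few shared patterns
            tree = random_tree(spec)
            aln = evolve_alignment(tree, lg_model, gamma4, s, seed=52)
            tl = TreeLikelihood(aln, tree, lg_model, gamma4)
            tl.log_likelihood()  # warm buffers
            best = np.inf
            for _ in range(5):
                t0 = time.process_time()
                tl.log_likelihood()
                best = min(best, time.process_time() - t0)
            return best

        assert cost(32, 400) < 3.3 * cost(16, 400)
        assert cost(16, 800) < 3.3 * cost(16, 400)


class TestSufficientStatistics:
    def test_gradient_identity_against_finite_differences(self, gamma4):
        """d logL / d log r_xy = (C_xy + C_yx) - r_xy (pi_y T_x + pi_x T_y)."""
        rng = np.random.default_rng(48)
        model = random_reversible_model(rng, normalize=False)
        tree = read_newick("((A:0.12,B:0.3):0.08,(C:0.05,D:0.4):0.2);")
        aln = random_alignment(rng, ["A", "B", "C", "D"], 40)
        tl = TreeLikelihood(aln, tree, model, gamma4)
        C, T, ll = tl.sufficient_statistics()
        grad = (C + C.T) - model.R * (
            model.pi[None, :] * T[:, None] + model.pi[:, None] * T[None, :]
        )
        h = 1e-6
        for x, y in [(0, 1), (3, 7), (12, 19)]:
            fd = []
            for sign in (1, -1):
                R2 = model.R.copy()
                R2[x, y] *= np.exp(sign * h)
                R2[y, x] = R2[x, y]
                m2 = RateMatrix(R2, model.pi, normalize=False)
                fd.append(TreeLikelihood(aln, tree, m2, gamma4).log_likelihood())
            fd_grad = (fd[0] - fd[1]) / (2 * h)
            assert grad[x, y] == pytest.approx(fd_grad, abs=1e-4, rel=1e-4)

    def test_loglik_consistent_with_direct_evaluation(self, lg_model, gamma4):
        rng = np.random.default_rng(49)
        aln = random_alignment(rng, ["A", "B", "C", "D", "E"], 80)
        tree = read_newick("((A:0.1,B:0.2):0.1,(C:0.15,(D:0.1,E:0.3):0.05):0.1);")
        tl = TreeLikelihood(aln, tree, lg_model, gamma4)
        _, _, ll = tl.sufficient_statistics()
        assert ll == pytest.approx(tl.log_likelihood(), abs=1e-8)
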