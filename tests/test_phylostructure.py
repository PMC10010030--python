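"""Distances, PHI screen, trees, and lineage delineation."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from hostflux.errors import InputError
from hostflux.phylostructure import (
    Alignment,
    concatenate_recombination_free,
    core_identity,
    delineate_lineages,
    distance_tree,
    phi_recombination_test,
    snp_distances,
)
from hostflux.simulate import SimulationConfig, simulate_core_alignment, simulate_host_phylogeny


class TestSnpDistances:
    def test_single_difference(self):
        _, d = snp_distances(Alignment(["x", "y"], ["ACGT", "ACGA"]))
        assert d[0, 1] == 1

    def test_ambiguity_ignored(self):
        _, d = snp_distances(Alignment(["x", "y"], ["ACGN", "ACGA"]))
        assert d[0, 1] == 0

    def test_gap_ignored(self):
        _, d = snp_distances(Alignment(["x", "y"], ["AC-T", "ACGA"]))
        assert d[0, 1] == 1

    def test_self_zero(self):
        _, d = snp_distances(Alignment(["x", "y"], ["ACGT", "ACGT"]))
        assert d[0, 1] == 0

    def test_ragged_rejected(self):
        with pytest.raises(InputError):
            Alignment(["x", "y"], ["ACGT", "ACG"])

    def test_metric_on_clean_sequences(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(4)]
        _, d = snp_distances(Alignment(list("wxyz"), rows))
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    assert d[i, j] <= d[i, k] + d[k, j]


class TestCoreIdentity:
    def test_identical_rows(self):
        _, m, flagged = core_identity(Alignment(["x", "y"], ["ACGT", "ACGT"]))
        assert m[0, 1] == 100.0 and not flagged

    def test_one_mismatch_in_100(self):
        a = "A" * 100
        b = "A" * 99 + "C"
        _, m, _ = core_identity(Alignment(["x", "y"], [a, b]))
        assert m[0, 1] == pytest.approx(99.0)

    def test_algebraic_identity_with_snp(self):
        rng = np.random.default_rng(1)
        rows = ["".join(rng.choice(list("ACGTN-"), 200)) for _ in range(5)]
        aln = Alignment([f"s{i}" for i in range(5)], rows)
        _, snp = snp_distances(aln)
        _, ani, _ = core_identity(aln)
        mat = aln.matrix()
        valid = np.zeros(mat.shape, bool)
        for base in b"ACGT":
            valid |= mat == base
        for i in range(5):
            for j in range(i + 1, 5):
                comparable = np.count_nonzero(valid[i] & valid[j])
                if comparable:
                    assert ani[i, j] == pytest.approx(100 * (1 - snp[i, j] / comparable))

    def test_zero_comparable_flagged(self):
        _, m, flagged = core_identity(Alignment(["x", "y"], ["NNNN", "ACGT"]))
        assert np.isnan(m[0, 1]) and flagged == [("x", "y")]


class TestPhi:
    def test_uninformative_gene_not_testable(self):
        aln = Alignment(["a", "b", "c", "d"], ["ACGT", "ACGT", "ACGT", "ACGA"])
        res = phi_recombination_test(aln)
        assert res.p_value == 1.0 and not res.testable

    def test_requires_four_sequences(self):
        with pytest.raises(InputError):
            phi_recombination_test(Alignment(["a", "b"], ["AC", "AG"]))

    def test_clonal_genes_rarely_rejected(self):
        cfg = SimulationConfig(seed=21, n_genomes=15, n_core_genes=20,
                               gene_length=300, clock_rate=0.12)
        tree, _ = simulate_host_phylogeny(cfg)
        genes, _ = simulate_core_alignment(tree, cfg)
        ps = [phi_recombination_test(Alignment.from_dict(s), seed=5).p_value
              for s in genes.values()]
        assert np.mean(np.array(ps) >= 0.05) >= 0.9

    def test_mosaic_gene_detected(self):
        cfg = SimulationConfig(seed=11, n_genomes=20, n_core_genes=3,
                               gene_length=1000, clock_rate=0.15,
                               recombination_fraction=1.0)
        tree, _ = simulate_host_phylogeny(cfg)
        genes, truth = simulate_core_alignment(tree, cfg)
        assert truth.recombination
        for rec in truth.recombination:
            res = phi_recombination_test(Alignment.from_dict(genes[rec["gene"]]), seed=5)
            assert res.p_value < 0.05


class TestConcatenate:
    def _genes(self):
        g1 = Alignment(["a", "b"], ["ACGT", "ACGA"], ["g1"] * 4)
        g2 = Alignment(["a", "b"], ["TTTT", "TTTA"], ["g2"] * 4)
        return {"g1": g1, "g2": g2}

    def _phi(self, p1, p2):
        from hostflux.phylostructure import PhiResult
        return {"g1": PhiResult(0, p1, 5, True), "g2": PhiResult(0, p2, 5, True)}

    def test_all_pass_lengths_sum(self):
        out = concatenate_recombination_free(self._genes(), self._phi(0.5, 0.9))
        assert out.length == 8
        assert set(out.partitions) == {"g1", "g2"}

    def test_failing_gene_excluded(self):
        out = concatenate_recombination_free(self._genes(), self._phi(0.01, 0.9))
        assert out.length == 4 and set(out.partitions) == {"g2"}

    def test_all_rejected_raises(self):
        with pytest.raises(InputError):
            concatenate_recombination_free(self._genes(), self._phi(0.01, 0.01))

    def test_gap_columns_trimmed(self):
        g = {"g": Alignment(["a", "b"], ["A-GT", "A-GA"], ["g"] * 4)}
        from hostflux.phylostructure import PhiResult
        out = concatenate_recombination_free(g, {"g": PhiResult(0, 1.0, 0, False)})
        assert out.length == 3

    def test_exclusion_rate_tracks_recombination_fraction(self):
        cfg = SimulationConfig(seed=31, n_genomes=15, n_core_genes=40,
                               gene_length=600, clock_rate=0.15,
                               recombination_fraction=0.3)
        tree, _ = simulate_host_phylogeny(cfg)
        genes, truth = simulate_core_alignment(tree, cfg)
        alns = {g: Alignment.from_dict(s, partition=g) for g, s in genes.items()}
        phi = {g: phi_recombination_test(a, seed=2) for g, a in alns.items()}
        excluded = sum(1 for r in phi.values() if r.p_value < 0.05)
        n_mosaic = len(truth.recombination)
        se = np.sqrt(40 * 0.3 * 0.7)
        # excluded should track the true mosaic count within binomial noise
        assert abs(excluded - n_mosaic) <= 3 * se


class TestDistanceTree:
    def test_upgma_hand_example(self):
        labels = ["A", "B", "C"]
        m = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        tree = distance_tree(labels, m, method="upgma")
        names, coph = tree.cophenetic()
        idx = {n: i for i, n in enumerate(names)}
        assert coph[idx["A"], idx["B"]] == pytest.approx(2)
        assert coph[idx["A"], idx["C"]] == pytest.approx(4)
        assert tree.is_ultrametric(1e-9)

    def test_upgma_fixed_point_on_ultrametric_input(self, small_world):
        tree, _, _ = small_world
        names, coph = tree.cophenetic()
        rebuilt = distance_tree(names, coph, method="upgma")
        names2, coph2 = rebuilt.cophenetic()
        reorder = [names2.index(n) for n in names]
        assert np.allclose(coph2[np.ix_(reorder, reorder)], coph, atol=1e-9)

    def test_upgma_always_ultrametric(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = 8
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            tree = distance_tree([f"t{i}" for i in range(n)], m, method="upgma")
            depths = tree.depths()
            tip_depths = [depths[t] for t in tree.tips()]
            assert max(tip_depths) - min(tip_depths) < 1e-9

    def test_nj_with_outgroup_root(self):
        labels = ["A", "B", "C", "OUT"]
        m = np.array([
            [0, 2, 6, 10],
            [2, 0, 6, 10],
            [6, 6, 0, 10],
            [10, 10, 10, 0],
        ], float)
        tree = distance_tree(labels, m, method="nj", outgroup="OUT")
        root_children = tree.root.children
        sides = [set(n.name for n in (child.children and _tips_below(child) or [child]))
                 for child in root_children]
        assert {"OUT"} in [s for s in sides]

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [3, 0, 1], [2, 1, 0]], float)
        with pytest.raises(InputError):
            distance_tree(["a", "b", "c"], m)

    def test_bootstrap_supports_true_clades(self):
        cfg = SimulationConfig(seed=13, n_genomes=12, n_lineages=3,
                               n_core_genes=8, gene_length=400, clock_rate=0.08)
        tree, truth = simulate_host_phylogeny(cfg)
        genes, _ = simulate_core_alignment(tree, cfg)
        seqs = {name: "".join(genes[g][name] for g in sorted(genes))
                for name in tree.tip_names()}
        aln = Alignment.from_dict(seqs)
        labels, snp = snp_distances(aln)
        built = distance_tree(labels, snp, method="upgma",
                              bootstrap_alignment=aln, n_bootstrap=50, seed=3)
        # every deep (lineage) clade should be strongly supported
        lineage_tips = {}
        for tip, lin in truth.lineages.items():
            lineage_tips.setdefault(lin, set()).add(tip)
        supports = {}
        all_tips = set(built.tip_names())
        for node in built.postorder():
            if node.is_leaf or node is built.root or node.support is None:
                continue
            clade = {t.name for t in _tips_below(node)}
            for lin, tips in lineage_tips.items():
                if clade == tips or clade == all_tips - tips:
                    supports[lin] = node.support
        assert supports
        assert all(s > 90 for s in supports.values())


def _tips_below(node):
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


class TestDelineation:
    def test_two_clean_clades(self):
        n = 10
        m = np.full((n, n), 50.0)
        m[:5, :5] = 2.0
        m[5:, 5:] = 2.0
        np.fill_diagonal(m, 0)
        labels = [f"g{i}" for i in range(n)]
        assignment, thr = delineate_lineages(labels, m)
        assert len(set(assignment.values())) == 2
        assert len(set(assignment[f"g{i}"] for i in range(5))) == 1
        assert 2.0 < thr < 50.0

    def test_small_component_unassigned(self):
        n = 9
        m = np.full((n, n), 50.0)
        m[:6, :6] = 2.0
        m[6:, 6:] = 2.0
        np.fill_diagonal(m, 0)
        labels = [f"g{i}" for i in range(n)]
        assignment, _ = delineate_lineages(labels, m)
        assert all(assignment[f"g{i}"] == "unassigned" for i in range(6, 9))

    def test_degenerate_distances_raise(self):
        m = np.ones((5, 5))
        np.fill_diagonal(m, 0)
        with pytest.raises(InputError):
            delineate_lineages([f"g{i}" for i in range(5)], m)

    def test_simulated_lineage_recovery(self):
        cfg = SimulationConfig(seed=17, n_genomes=30, n_lineages=3,
                               n_core_genes=10, gene_length=400, clock_rate=0.05)
        tree, truth = simulate_host_phylogeny(cfg)
        genes, _ = simulate_core_alignment(tree, cfg)
        seqs = {name: "".join(genes[g][name] for g in sorted(genes))
                for name in tree.tip_names()}
        labels, snp = snp_distances(Alignment.from_dict(seqs))
        assignment, _ = delineate_lineages(labels, snp)
        ari = adjusted_rand_score([truth.lineages[g] for g in labels],
                                  [assignment[g] for g in labels])
        assert ari == pytest.approx(1.0)
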