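"""Trait-association scoring, empirical p, and specific-gene selection."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from hostflux.errors import InputError
from hostflux.pangenome import PresenceAbsenceMatrix
from hostflux.pangwas import (
    AssociationResult,
    empirical_p,
    score_family,
    select_specific_genes,
)


def brute_force_fisher(tp, fp, fn, tn):
    """Independent oracle: sum hypergeometric probabilities ≤ observed."""
    n = tp + fp + fn + tn
    n_present = tp + fp
    n_trait = tp + fn
    lo = max(0, n_present + n_trait - n)
    hi = min(n_present, n_trait)
    probs = {x: hypergeom.pmf(x, n, n_present, n_trait) for x in range(lo, hi + 1)}
    obs = probs[tp]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-9))


class TestScoreFamily:
    def test_perfect_association_worked_example(self):
        pres = np.array([1] * 5 + [0] * 5, bool)
        trait = np.array([1] * 5 + [0] * 5, bool)
        r = score_family(pres, trait)
        assert r.sensitivity == 100.0 and r.specificity == 100.0
        assert r.p_naive == pytest.approx(2 / 252, rel=1e-9)

    def test_two_by_two_enumeration(self):
        pres = np.array([1, 1, 0, 0], bool)
        trait = np.array([1, 1, 0, 0], bool)
        assert score_family(pres, trait).p_naive == pytest.approx(1 / 3, rel=1e-9)

    def test_constant_presence_flagged(self):
        pres = np.ones(6, bool)
        trait = np.array([1, 1, 1, 0, 0, 0], bool)
        r = score_family(pres, trait)
        assert r.flagged and r.p_naive == 1.0
        assert r.sensitivity == 100.0 and r.specificity == 0.0

    def test_counts_partition_genomes(self):
        rng = np.random.default_rng(0)
        pres = rng.random(20) < 0.4
        trait = np.array([1] * 8 + [0] * 12, bool)
        r = score_family(pres, trait)
        assert r.tp + r.fn == 8
        assert r.tn + r.fp == 12
        assert r.sensitivity == pytest.approx(100 * r.tp / 8)
        assert r.specificity == pytest.approx(100 * r.tn / 12)

    def test_invalid_trait(self):
        with pytest.raises(InputError):
            score_family(np.array([1, 0], bool), np.array([1, 1], bool))

    @pytest.mark.parametrize("seed", range(10))
    def test_fisher_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        pres = rng.random(n) < rng.uniform(0.2, 0.8)
        trait = np.zeros(n, bool)
        trait[: int(rng.integers(1, n))] = True
        rng.shuffle(trait)
        if not trait.any() or trait.all() or not pres.any() or pres.all():
            return
        r = score_family(pres, trait)
        oracle = brute_force_fisher(r.tp, r.fp, r.fn, r.tn)
        assert r.p_naive == pytest.approx(oracle, rel=1e-6)


class TestEmpiricalP:
    def test_perfect_association_small_p(self):
        pres = np.array([1] * 6 + [0] * 6, bool)
        trait = np.array([1] * 6 + [0] * 6, bool)
        assert empirical_p(pres, trait, n_permutations=1000, seed=1) <= 0.01

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        pres = rng.random(14) < 0.5
        trait = np.array([1] * 7 + [0] * 7, bool)
        a = empirical_p(pres, trait, seed=5)
        b = empirical_p(pres, trait, seed=5)
        assert a == b

    def test_null_super_uniform(self):
        # tie-inclusive p is valid: P(p <= t) <= t (+ Monte Carlo noise)
        rng = np.random.default_rng(3)
        trait = np.array([1] * 10 + [0] * 10, bool)
        ps = []
        for i in range(200):
            pres = rng.random(20) < 0.5
            if not pres.any() or pres.all():
                continue
            ps.append(empirical_p(pres, trait, n_permutations=199, seed=i))
        ps = np.array(ps)
        for t in (0.01, 0.05, 0.1, 0.25, 0.5):
            assert (ps <= t).mean() <= t + 3 * np.sqrt(t * (1 - t) / len(ps))

    def test_null_uniformity_randomized(self):
        # tie-randomized p is exactly uniform under the null
        from scipy.stats import kstest
        rng = np.random.default_rng(3)
        trait = np.array([1] * 10 + [0] * 10, bool)
        ps = []
        for i in range(200):
            pres = rng.random(20) < 0.5
            if not pres.any() or pres.all():
                continue
            ps.append(empirical_p(pres, trait, n_permutations=199, seed=i,
                                  randomized=True))
        assert kstest(ps, "uniform").pvalue > 0.01


class TestSelectSpecific:
    def _matrix(self, columns: dict[str, np.ndarray]) -> PresenceAbsenceMatrix:
        fams = list(columns)
        values = np.stack([columns[f] for f in fams], axis=1).astype(bool)
        return PresenceAbsenceMatrix([f"g{i}" for i in range(values.shape[0])],
                                     fams, values)

    def test_bh_and_bonferroni_textbook_example(self):
        from scipy.stats import false_discovery_control
        ps = np.array([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(false_discovery_control(ps, method="bh"), 0.04)
        assert np.allclose(np.minimum(1, 4 * ps), [0.04, 0.08, 0.12, 0.16])

    def test_threshold_strictness(self):
        # sens 71 / spec 69: rejected regardless of p
        trait = np.array([1] * 7 + [0] * 13, bool)
        pres = np.concatenate([np.ones(5), np.zeros(2), np.ones(4), np.zeros(9)]).astype(bool)
        r = score_family(pres, trait)
        assert r.sensitivity > 70 and r.specificity < 70
        m = self._matrix({"f": pres})
        out = select_specific_genes(m, dict(zip(m.genomes, trait.astype(int))),
                                    n_permutations=50, seed=0)
        assert not out[0].specific

    def test_perfect_gene_selected(self):
        trait = np.array([1] * 8 + [0] * 8, bool)
        cols = {"hit": trait.copy(),
                "noise": np.array([1, 0] * 8, bool),
                "allon": np.ones(16, bool)}
        m = self._matrix(cols)
        out = select_specific_genes(m, dict(zip(m.genomes, trait.astype(int))),
                                    n_permutations=500, seed=3)
        by_family = {r.family: r for r in out}
        assert by_family["hit"].specific
        assert not by_family["noise"].specific
        assert by_family["allon"].flagged and not by_family["allon"].specific

    def test_adjusted_at_least_naive(self):
        rng = np.random.default_rng(9)
        trait = np.array([1] * 6 + [0] * 6, bool)
        cols = {f"f{i}": rng.random(12) < 0.5 for i in range(12)}
        cols = {k: v for k, v in cols.items() if v.any() and not v.all()}
        m = self._matrix(cols)
        out = select_specific_genes(m, dict(zip(m.genomes, trait.astype(int))),
                                    n_permutations=50, seed=1)
        for r in out:
            assert r.p_bh >= r.p_naive - 1e-12
            assert r.p_bonferroni >= r.p_naive - 1e-12

    def test_order_invariance(self):
        rng = np.random.default_rng(11)
        trait = np.array([1] * 6 + [0] * 6, bool)
        cols = {f"f{i}": rng.random(12) < 0.5 for i in range(6)}
        cols = {k: v for k, v in cols.items() if v.any() and not v.all()}
        m = self._matrix(cols)
        out1 = {r.family: r.specific for r in select_specific_genes(
            m, dict(zip(m.genomes, trait.astype(int))), n_permutations=100, seed=2)}
        rev = list(cols)[::-1]
        m2 = m.subset_families(rev)
        out2 = {r.family: r.specific for r in select_specific_genes(
            m2, dict(zip(m2.genomes, trait.astype(int))), n_permutations=100, seed=2)}
        assert out1 == out2

    def test_simulated_innovations_recovered(self):
        from hostflux.simulate import SimulationConfig, simulate_gene_content, simulate_host_phylogeny
        cfg = SimulationConfig(seed=23, n_genomes=24, n_lineages=3,
                               root_family_count=150, gain_rate=0.02,
                               loss_rate=0.05, innovation_rate=40.0)
        tree, truth = simulate_host_phylogeny(cfg)
        genomes, families, values, content = simulate_gene_content(tree, cfg)
        m = PresenceAbsenceMatrix(genomes, families, values)
        lineages = truth.lineages
        # innovations that arose on a lineage stem are exactly lineage-wide
        target = sorted(set(lineages.values()))[0]
        trait = {g: int(lineages[g] == target) for g in genomes}
        out = select_specific_genes(m, trait, n_permutations=300, seed=4)
        specific = {r.family for r in out if r.specific}
        member_idx = [i for i, g in enumerate(genomes) if trait[g]]
        other_idx = [i for i, g in enumerate(genomes) if not trait[g]]
        truly = {
            f for j, f in enumerate(families)
            if values[member_idx, j].all() and not values[other_idx, j].any()
        }
        if truly:
            recovered = len(specific & truly) / len(truly)
            assert recovered >= 0.9
        false_hits = {
            f for f in specific
            if not values[member_idx, list(m.families).index(f)].mean() > 0.7
        }
        assert len(false_hits) <= max(1, int(0.05 * max(len(specific), 1)))
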