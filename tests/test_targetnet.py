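import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from gmpsig.targetnet import (
    build_target_network,
    candidate_edge_count,
    cluster_targets,
    gmp_overlap,
    hypergeom_pvalue,
    permutation_edge_null,
    _perm_pvalues,
)
from gmpsig.types import GeneModulePair, TargetSpace, ValidationError

from conftest import random_space


def brute_force_hypergeom_upper(k, M, na, nb):
    """Oracle: direct combinatorial summation of P[X >= k]."""
    total = 0.0
    for i in range(k, min(na, nb) + 1):
        total += math.comb(na, i) * math.comb(M - na, nb - i)
    return total / math.comb(M, nb)


def gmp_from(genes_up, genes_dn, tid="T"):
    return GeneModulePair(target_id=tid, up=frozenset(genes_up),
                          down=frozenset(genes_dn))


class TestGmpOverlap:
    def test_identical_pairs_full_overlap(self):
        space = random_space(2, module_size=250, universe_size=1000, seed=0)
        a = space.gmps["T001"]
        assert gmp_overlap(a, a) == 500

    def test_disjoint_zero(self):
        genes = [f"g{i}" for i in range(20)]
        a = gmp_from(genes[:5], genes[5:10])
        b = gmp_from(genes[10:15], genes[15:20])
        assert gmp_overlap(a, b) == 0

    def test_hand_built_37_shared(self):
        genes = [f"g{i:03d}" for i in range(300)]
        a = gmp_from(genes[:50], genes[50:100])
        # b shares 20 genes with a.up and 17 with a.down
        b_up = genes[:20] + genes[100:130]
        b_dn = genes[50:67] + genes[130:163]
        b = gmp_from(b_up, b_dn)
        assert gmp_overlap(a, b) == 37
        assert gmp_overlap(b, a) == 37

    def test_symmetric_bounded(self):
        space = random_space(6, module_size=30, universe_size=200, seed=1)
        tids = space.target_ids
        for i in range(len(tids)):
            for j in range(len(tids)):
                a, b = space.gmps[tids[i]], space.gmps[tids[j]]
                k = gmp_overlap(a, b)
                assert k == gmp_overlap(b, a)
                assert 0 <= k <= 2 * space.module_size


class TestHypergeomPvalue:
    def test_zero_overlap_p_one(self):
        assert hypergeom_pvalue(0, 1000, 50, 50) == pytest.approx(1.0)

    def test_maximal_overlap_tiny_p(self):
        p = hypergeom_pvalue(500, 10174, 500, 500)
        assert p < 1e-100

    def test_small_case_matches_enumeration(self):
        expected = brute_force_hypergeom_upper(3, 20, 5, 5)
        assert hypergeom_pvalue(3, 20, 5, 5) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("M,na,nb", [(10, 3, 4), (20, 5, 5), (30, 10, 7)])
    def test_matches_enumeration_small_universes(self, M, na, nb):
        for k in range(min(na, nb) + 1):
            expected = brute_force_hypergeom_upper(k, M, na, nb)
            assert hypergeom_pvalue(k, M, na, nb) == pytest.approx(
                expected, abs=1e-12
            )

    def test_strictly_decreasing_in_k(self):
        ps = [hypergeom_pvalue(k, 200, 30, 30) for k in range(31)]
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_impossible_k_errors(self):
        with pytest.raises(ValidationError):
            hypergeom_pvalue(6, 20, 5, 5)


def identical_space(n, module_size=10, universe_size=100):
    genes = [f"g{i:03d}" for i in range(universe_size)]
    up = frozenset(genes[:module_size])
    dn = frozenset(genes[module_size : 2 * module_size])
    gmps = {
        f"T{i:03d}": GeneModulePair(target_id=f"T{i:03d}", up=up, down=dn)
        for i in range(n)
    }
    return TargetSpace(gmps=gmps, universe=genes, module_size=module_size)


def disjoint_space(n, module_size=5):
    genes = [f"g{i:03d}" for i in range(2 * module_size * n)]
    gmps = {}
    for i in range(n):
        lo = 2 * module_size * i
        gmps[f"T{i:03d}"] = GeneModulePair(
            target_id=f"T{i:03d}",
            up=frozenset(genes[lo : lo + module_size]),
            down=frozenset(genes[lo + module_size : lo + 2 * module_size]),
        )
    return TargetSpace(gmps=gmps, universe=genes, module_size=module_size)


class TestPermutationNull:
    def test_identical_space_p_one(self):
        space = identical_space(5)
        res = permutation_edge_null(space, reps=50, seed=0)
        assert np.all(res["null"] == 20)
        assert np.allclose(_perm_pvalues(res), 1.0)

    def test_disjoint_space_p_one(self):
        space = disjoint_space(5)
        res = permutation_edge_null(space, reps=50, seed=1)
        p = _perm_pvalues(res)
        off = p[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 1.0)  # observed 0, every null >= 0

    def test_planted_shared_pair_significant(self):
        # two targets share 40 genes; 48 unrelated random targets
        space = random_space(48, module_size=50, universe_size=500, seed=2)
        genes = space.universe
        shared = genes[:40]
        a = gmp_from(shared[:20] + genes[100:130],
                     shared[20:] + genes[130:160], tid="TA")
        b = gmp_from(shared[:20] + genes[200:230],
                     shared[20:] + genes[230:260], tid="TB")
        gmps = dict(space.gmps)
        gmps["TA"] = a
        gmps["TB"] = b
        space2 = TargetSpace(gmps=gmps, universe=genes, module_size=50)
        res = permutation_edge_null(space2, reps=1000, seed=3)
        p = _perm_pvalues(res)
        targets = res["targets"]
        ia, ib = targets.index("TA"), targets.index("TB")
        assert res["observed"][ia, ib] >= 40
        assert p[ia, ib] <= 0.05

    def test_reps_validation(self):
        with pytest.raises(ValidationError):
            permutation_edge_null(disjoint_space(5), reps=0)

    def test_too_few_targets(self):
        with pytest.raises(ValidationError):
            permutation_edge_null(disjoint_space(2), reps=10)


class TestBuildTargetNetwork:
    def test_identical_pair_in_diverse_space(self):
        space = random_space(10, module_size=25, universe_size=1000, seed=4)
        twin = GeneModulePair(
            target_id="TWIN",
            up=space.gmps["T001"].up,
            down=space.gmps["T001"].down,
        )
        gmps = dict(space.gmps)
        gmps["TWIN"] = twin
        net = build_target_network(
            TargetSpace(gmps=gmps, universe=space.universe, module_size=25),
            alpha=0.05, reps=500, seed=5,
        )
        hit = net.edges[
            ((net.edges.t1 == "T001") & (net.edges.t2 == "TWIN"))
            | ((net.edges.t1 == "TWIN") & (net.edges.t2 == "T001"))
        ]
        assert len(hit) == 1
        assert hit.weight.iloc[0] == 50

    def test_random_space_low_edge_density(self):
        space = random_space(25, module_size=25, universe_size=1000, seed=6)
        net = build_target_network(space, alpha=0.05, reps=300, seed=7)
        density = net.n_edges / candidate_edge_count(25)
        assert density <= 0.10

    def test_candidate_edge_counts(self):
        assert candidate_edge_count(3275) == 5361175
        assert candidate_edge_count(1000) == 499500

    def test_every_edge_satisfies_rule(self):
        space = random_space(20, module_size=30, universe_size=600, seed=8)
        net = build_target_network(
            space, alpha=0.2, rule="hyper_and_perm", reps=200, seed=9
        )
        if len(net.edges):
            assert (net.edges.p_hyper < 0.2).all()
            assert (net.edges.p_perm < 0.2).all()
        net2 = build_target_network(space, alpha=0.2, rule="hyper",
                                    reps=200, seed=9)
        assert (net2.edges.p_hyper < 0.2).all()
        assert net2.n_edges >= net.n_edges


class TestClusterTargets:
    def test_two_disjoint_identical_blocks(self):
        genes = [f"g{i:03d}" for i in range(100)]
        gmps = {}
        for i in range(3):
            gmps[f"A{i}"] = gmp_from(genes[:10], genes[10:20], tid=f"A{i}")
        for i in range(3):
            gmps[f"B{i}"] = gmp_from(genes[50:60], genes[60:70], tid=f"B{i}")
        space = TargetSpace(gmps=gmps, universe=genes, module_size=10)
        sim = pd.DataFrame(0.0, index=sorted(gmps), columns=sorted(gmps))
        for a in gmps:
            for b in gmps:
                if a != b:
                    sim.loc[a, b] = gmp_overlap(gmps[a], gmps[b])
        comm = cluster_targets(sim, seed=0)
        assert comm.n_communities == 2
        labels = {t: comm.membership[t] for t in gmps}
        assert len({labels[f"A{i}"] for i in range(3)}) == 1
        assert len({labels[f"B{i}"] for i in range(3)}) == 1
        assert labels["A0"] != labels["B0"]

    def test_equal_similarity_clique_single_cluster(self):
        ids = [f"T{i}" for i in range(5)]
        sim = pd.DataFrame(10.0, index=ids, columns=ids)
        np.fill_diagonal(sim.values, 0.0)
        comm = cluster_targets(sim, seed=0)
        assert comm.n_communities == 1
        assert set(comm.membership) == set(ids)

    def test_planted_communities_recovered(self):
        # 4 groups of 15 targets; within-group GMPs share most genes
        rng = np.random.default_rng(10)
        genes = [f"g{i:04d}" for i in range(2000)]
        gmps, truth_labels = {}, {}
        for c in range(4):
            core = rng.choice(2000, size=80, replace=False)
            for i in range(15):
                tid = f"C{c}_{i:02d}"
                jitter = rng.choice(2000, size=20, replace=False)
                members = np.unique(np.concatenate([core, jitter]))[:80]
                up = frozenset(np.asarray(genes)[members[:40]])
                dn = frozenset(np.asarray(genes)[members[40:]]) - up
                gmps[tid] = GeneModulePair(
                    target_id=tid, up=up, down=frozenset(list(dn)[:40])
                )
                truth_labels[tid] = c
        ids = sorted(gmps)
        sim = pd.DataFrame(0.0, index=ids, columns=ids)
        for a in ids:
            for b in ids:
                if a != b:
                    sim.loc[a, b] = len(gmps[a].genes & gmps[b].genes)
        comm = cluster_targets(sim, seed=0)
        clustered = [t for t in ids if t in comm.membership]
        ari = adjusted_rand_score(
            [truth_labels[t] for t in clustered],
            [comm.membership[t] for t in clustered],
        )
        assert len(clustered) >= 0.9 * len(ids)
        assert ari >= 0.9

    def test_exemplar_in_own_cluster(self):
        space = random_space(8, module_size=20, universe_size=300, seed=11)
        sim = pd.DataFrame(
            0.0, index=space.target_ids, columns=space.target_ids
        )
        for a in space.target_ids:
            for b in space.target_ids:
                if a != b:
                    sim.loc[a, b] = gmp_overlap(space.gmps[a], space.gmps[b])
        comm = cluster_targets(sim, seed=1)
        for cid, ex in comm.exemplars.items():
            assert comm.membership[ex] == cid
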