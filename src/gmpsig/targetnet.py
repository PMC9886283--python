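"""GMP-overlap target network, significance nulls, and communities.

Two targets are linked when their gene module pairs share significantly
many genes: the overlap count is tested against a hypergeometric null
over the expression universe and a module-level permutation null that
re-pairs up and down modules across targets (keeping each 250-gene
module intact, so within-module gene correlations are preserved).
Communities come from affinity propagation on the overlap similarity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .types import GeneModulePair, TargetSpace, ValidationError

__all__ = [
    "TargetNetwork",
    "CommunityAssignment",
    "gmp_overlap",
    "hypergeom_pvalue",
    "permutation_edge_null",
    "build_target_network",
    "candidate_edge_count",
    "cluster_targets",
]


def candidate_edge_count(n_targets: int) -> int:
    """Edges of the complete graph over ``n_targets`` nodes: C(n, 2)."""
    return math.comb(n_targets, 2)


@dataclass
class TargetNetwork:
    """Weighted target graph; one row per significant edge."""

    nodes: list[str]
    edges: pd.DataFrame  # columns: t1, t2, weight, p_hyper, p_perm
    alpha: float = 0.05
    rule: str = "hyper_and_perm"

    def __post_init__(self) -> None:
        required = {"t1", "t2", "weight", "p_hyper", "p_perm"}
        if not required <= set(self.edges.columns):
            raise ValidationError(f"edge table missing columns {required}")
        pairs = set(map(frozenset, zip(self.edges.t1, self.edges.t2)))
        if len(pairs) != len(self.edges):
            raise ValidationError("duplicate edges in target network")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def similarity_matrix(self) -> pd.DataFrame:
        """Dense overlap-count similarity with zeros for missing edges."""
        sim = pd.DataFrame(
            0.0, index=self.nodes, columns=self.nodes, dtype=float
        )
        for row in self.edges.itertuples():
            sim.loc[row.t1, row.t2] = row.weight
            sim.loc[row.t2, row.t1] = row.weight
        return sim

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples():
            g.add_edge(
                row.t1, row.t2, weight=float(row.weight),
                p_hyper=float(row.p_hyper), p_perm=float(row.p_perm),
            )
        nx.write_graphml(g, path)


@dataclass
class CommunityAssignment:
    """Target -> community id, with one exemplar target per community."""

    membership: dict[str, int]
    exemplars: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, ex in self.exemplars.items():
            if self.membership.get(ex) != cid:
                raise ValidationError(f"exemplar {ex} not in its own cluster {cid}")

    @property
    def n_communities(self) -> int:
        return len(self.exemplars)


def gmp_overlap(a: GeneModulePair, b: GeneModulePair) -> int:
    """Number of shared genes between two module pairs (0..2*module_size)."""
    return len(a.genes & b.genes)


def hypergeom_pvalue(
    k: int, universe_size: int, size_a: int = 500, size_b: int = 500
) -> float:
    """Upper-tail P[X >= k] for overlap of two fixed-size sets.

    X ~ Hypergeometric(universe_size, size_a, size_b).
    """
    if not (0 <= k <= min(size_a, size_b) <= universe_size):
        raise ValidationError(
            f"impossible overlap k={k} for sizes {size_a}/{size_b} "
            f"in universe {universe_size}"
        )
    return float(hypergeom.sf(k - 1, universe_size, size_a, size_b))


def _membership_matrices(space: TargetSpace):
    targets = space.target_ids
    gene_index = {g: i for i, g in enumerate(space.universe)}
    n, u = len(targets), len(space.universe)
    up = np.zeros((n, u), dtype=bool)
    dn = np.zeros((n, u), dtype=bool)
    for t, tid in enumerate(targets):
        g = space.gmps[tid]
        up[t, [gene_index[x] for x in g.up]] = True
        dn[t, [gene_index[x] for x in g.down]] = True
    return targets, up, dn


def permutation_edge_null(
    space: TargetSpace,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Module-level permutation null for target-pair overlaps.

    Per repetition, one null GMP per target is built by pairing the
    up-module of a uniformly drawn target A with the down-module of a
    different target B (modules stay intact).  Returns per-ordered-pair
    null overlap counts ``null[r, i, j] = |GMP_i ∩ nullGMP_j^r|`` plus
    the observed overlap matrix.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    targets, up, dn = _membership_matrices(space)
    n = len(targets)
    if n < 3:
        raise ValidationError("need >= 3 targets for the permutation null")
    rng = np.random.default_rng(seed)
    obs_union = (up | dn).astype(np.int32)
    observed = obs_union @ obs_union.T
    null = np.empty((reps, n, n), dtype=np.int32)
    for r in range(reps):
        a = rng.integers(0, n, size=n)
        b = rng.integers(0, n - 1, size=n)
        b = np.where(b >= a, b + 1, b)  # ensure A != B
        null_union = (up[a] | dn[b]).astype(np.int32)
        null[r] = obs_union @ null_union.T
    return {"targets": targets, "observed": observed, "null": null}


def _perm_pvalues(null_result: dict) -> np.ndarray:
    """Symmetrised per-pair permutation p from the null overlap tensor."""
    observed = null_result["observed"]
    null = null_result["null"]
    reps = null.shape[0]
    ge = (null >= observed[None, :, :]).sum(axis=0)
    return (ge + ge.T) / (2.0 * reps)


def build_target_network(
    space: TargetSpace,
    alpha: float = 0.05,
    rule: str = "hyper_and_perm",
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> TargetNetwork:
    """Target graph keeping edges that pass the significance rule.

    rule: "hyper_and_perm" (both p < alpha), "hyper" or "perm" alone.
    """
    if rule not in {"hyper_and_perm", "hyper", "perm"}:
        raise ValidationError(f"unknown edge rule {rule!r}")
    nres = permutation_edge_null(space, reps=reps, seed=seed)
    targets = nres["targets"]
    observed = nres["observed"]
    p_perm = _perm_pvalues(nres)
    m = space.module_size
    uni = len(space.universe)
    # overlap counts are bounded by 2*module_size; cache the tail lookup
    sf_cache = {
        k: hypergeom_pvalue(k, uni, 2 * m, 2 * m) for k in range(2 * m + 1)
    }
    rows = []
    n = len(targets)
    for i in range(n):
        for j in range(i + 1, n):
            k = int(observed[i, j])
            ph = sf_cache[k]
            pp = float(p_perm[i, j])
            ok = {
                "hyper_and_perm": ph < alpha and pp < alpha,
                "hyper": ph < alpha,
                "perm": pp < alpha,
            }[rule]
            if ok:
                rows.append(
                    {"t1": targets[i], "t2": targets[j], "weight": k,
                     "p_hyper": ph, "p_perm": pp}
                )
    edges = pd.DataFrame(rows, columns=["t1", "t2", "weight", "p_hyper", "p_perm"])
    return TargetNetwork(nodes=targets, edges=edges, alpha=alpha, rule=rule)


def cluster_targets(
    net: TargetNetwork | pd.DataFrame,
    damping: float = 0.5,
    max_iter: int = 1000,
    preference: str | float = "median",
    seed: int = 0,
) -> CommunityAssignment:
    """Affinity-propagation communities on the overlap similarity matrix.

    Only communities with >= 2 members are reported, numbered by
    descending size (ties by smallest exemplar id).  Non-convergence
    yields a warning and the best-iterate assignment.
    """
    sim = net.similarity_matrix() if isinstance(net, TargetNetwork) else net
    ids = list(sim.index.astype(str))
    if len(ids) < 2:
        raise ValidationError("need >= 2 targets to cluster")
    S = sim.to_numpy(dtype=float)
    pref = np.median(S) if preference == "median" else float(preference)
    ap = AffinityPropagation(
        damping=damping, max_iter=max_iter, affinity="precomputed",
        preference=pref, random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        labels = ap.fit_predict(S)
    if np.all(labels == -1):  # AP failed outright: everything is a singleton
        warnings.warn("affinity propagation did not converge to any exemplar")
        return CommunityAssignment(membership={}, exemplars={})
    clusters: dict[int, list[str]] = {}
    for tid, lab in zip(ids, labels):
        clusters.setdefault(int(lab), []).append(tid)
    exemplar_of = {
        int(lab): ids[idx] for lab, idx in zip(
            range(len(ap.cluster_centers_indices_)), ap.cluster_centers_indices_
        )
    }
    keep = [
        (members, exemplar_of.get(lab, min(members)))
        for lab, members in clusters.items()
        if len(members) >= 2
    ]
    keep.sort(key=lambda pair: (-len(pair[0]), pair[1]))
    membership: dict[str, int] = {}
    exemplars: dict[int, str] = {}
    for cid, (members, ex) in enumerate(keep, start=1):
        for tid in members:
            membership[tid] = cid
        exemplars[cid] = ex
    return CommunityAssignment(membership=membership, exemplars=exemplars)
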