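"""Functional coherence of module gene sets in external gene networks.

The PPI ratio of a gene set is the number of network edges with both
endpoints in the set divided by the complete-graph edge count over the
full set (genes missing from the network still count in the
denominator).  Significance comes from random same-size gene sets drawn
from the network's nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .types import TargetSpace, ValidationError

__all__ = [
    "GeneNetwork",
    "EnrichmentResult",
    "PPIRatioParts",
    "ppi_ratio",
    "ppi_ratio_parts",
    "enrichment_pvalue",
    "characterize_space",
]


@dataclass
class GeneNetwork:
    """Undirected gene network: node set plus unordered edge pairs."""

    nodes: set[str]
    edges: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.nodes = set(map(str, self.nodes))
        clean: set[frozenset[str]] = set()
        for e in self.edges:
            pair = frozenset(map(str, e))
            if len(pair) != 2:
                raise ValidationError(f"self-loop or malformed edge: {set(e)}")
            clean.add(pair)
            self.nodes.update(pair)
        self.edges = clean

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @staticmethod
    def from_edge_list(pairs: Iterable[tuple[str, str]]) -> "GeneNetwork":
        return GeneNetwork(nodes=set(), edges={frozenset(p) for p in pairs})

    @staticmethod
    def from_tsv(path) -> "GeneNetwork":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ValidationError("edge list needs >= 2 columns")
        return GeneNetwork.from_edge_list(
            zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))
        )

    def to_tsv(self, path) -> None:
        rows = sorted(tuple(sorted(e)) for e in self.edges)
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


class PPIRatioParts(NamedTuple):
    ratio: float
    n_edges_within: int
    n_possible: int


@dataclass
class EnrichmentResult:
    gene_set_id: str
    observed_ratio: float
    null_ratios: np.ndarray
    p_value: float


def complete_graph_links(n: int) -> int:
    """Edge count of the complete graph over n nodes: C(n, 2)."""
    return math.comb(n, 2)


def ppi_ratio_parts(S: Iterable[str], net: GeneNetwork) -> PPIRatioParts:
    """PPI ratio with its numerator and complete-graph denominator."""
    S = set(map(str, S))
    if len(S & net.nodes) < 2:
        raise ValidationError("fewer than 2 set genes map onto the network")
    within = sum(1 for e in net.edges if e <= S)
    possible = complete_graph_links(len(S))
    return PPIRatioParts(within / possible, within, possible)


def ppi_ratio(S: Iterable[str], net: GeneNetwork) -> float:
    return ppi_ratio_parts(S, net).ratio


def _edge_count_within(members: np.ndarray, adj: dict[str, set[str]]) -> int:
    sset = set(members)
    count = 0
    for g in sset:
        count += len(adj.get(g, set()) & sset)
    return count // 2


def enrichment_pvalue(
    S: Iterable[str],
    net: GeneNetwork,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
    gene_set_id: str = "",
) -> EnrichmentResult:
    """Permutation p-value of the PPI ratio against random gene sets.

    Null sets are drawn uniformly without replacement from the network's
    nodes; p = (#null >= observed) / reps.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    S = set(map(str, S))
    observed = ppi_ratio(S, net)
    if len(net.nodes) <= len(S):
        raise ValidationError("network smaller than the gene set")
    rng = np.random.default_rng(seed)
    nodes = np.array(sorted(net.nodes))
    adj: dict[str, set[str]] = {}
    for e in net.edges:
        a, b = tuple(e)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    possible = complete_graph_links(len(S))
    null = np.empty(reps)
    for r in range(reps):
        draw = rng.choice(nodes, size=len(S), replace=False)
        null[r] = _edge_count_within(draw, adj) / possible
    p = float((null >= observed).sum() / reps)
    return EnrichmentResult(
        gene_set_id=gene_set_id, observed_ratio=observed, null_ratios=null, p_value=p
    )


def characterize_space(
    space: TargetSpace,
    nets: dict[str, GeneNetwork],
    mode: str = "pair",
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Enrichment of every GMP (or its up/down half) in each network.

    mode "pair" tests the combined 2x-module gene set, "up"/"down" the
    single modules.  Per-target errors (for example an empty network) are
    recorded in the ``error`` column and the run continues.
    """
    if mode not in {"pair", "up", "down"}:
        raise ValidationError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for net_name, net in sorted(nets.items()):
        for tid in space.target_ids:
            g = space.gmps[tid]
            genes = {"pair": g.genes, "up": g.up, "down": g.down}[mode]
            try:
                res = enrichment_pvalue(
                    genes, net, reps=reps, seed=rng, gene_set_id=tid
                )
                rows.append(
                    {
                        "target": tid,
                        "network": net_name,
                        "mode": mode,
                        "observed_ratio": res.observed_ratio,
                        "p": res.p_value,
                        "significant": res.p_value < alpha,
                        "error": "",
                    }
                )
            except ValidationError as exc:
                rows.append(
                    {
                        "target": tid,
                        "network": net_name,
                        "mode": mode,
                        "observed_ratio": np.nan,
                        "p": np.nan,
                        "significant": False,
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows)
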