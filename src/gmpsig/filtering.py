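"""Per-target outlier removal by hierarchical clustering of signatures.

Signatures of a target are clustered on their pairwise ITES distances;
the dendrogram is cut at a fixed height (default 0.8) and everything
outside the largest resulting cluster is flagged as an outlier.  Targets
keeping fewer than ``min_signatures`` retained signatures are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .distance import DistanceMatrix
from .types import ValidationError

__all__ = [
    "TargetSignatureGroup",
    "cluster_signatures",
    "remove_outliers",
    "retain_targets",
]


@dataclass
class TargetSignatureGroup:
    """Signatures annotated to one target, split into retained/removed."""

    target_id: str
    sig_ids: list[str]
    retained: list[str] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if set(self.retained) | set(self.removed) != set(self.sig_ids):
            raise ValidationError(f"{self.target_id}: retained+removed != sig_ids")
        if set(self.retained) & set(self.removed):
            raise ValidationError(f"{self.target_id}: retained/removed overlap")


def cluster_signatures(D: DistanceMatrix, method: str = "average") -> np.ndarray:
    """Agglomerative tree over signatures; returns a scipy linkage matrix."""
    if len(D.ids) < 2:
        raise ValidationError("need >= 2 signatures to cluster")
    condensed = squareform(D.d, checks=True)
    return linkage(condensed, method=method)


def remove_outliers(
    tree: np.ndarray | None, D: DistanceMatrix, threshold: float = 0.8
) -> tuple[list[str], list[str]]:
    """Cut the dendrogram at ``threshold`` and keep the largest cluster.

    Merges at height >= threshold are split.  Ties between equally large
    clusters are broken by smaller mean internal distance, then by the
    lexicographically smallest member id.  Returns (retained, removed)
    signature-id lists in input order.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValidationError("threshold must be in (0, 1]")
    ids = D.ids
    if len(ids) == 1:
        return list(ids), []
    if tree is None:
        tree = cluster_signatures(D)
    # strict cut: a merge at exactly the threshold height is split
    labels = fcluster(tree, t=threshold - 1e-12, criterion="distance")
    best_key, best_members = None, None
    for lab in np.unique(labels):
        members = [ids[i] for i in np.flatnonzero(labels == lab)]
        idx = np.flatnonzero(labels == lab)
        if len(idx) > 1:
            sub = D.d[np.ix_(idx, idx)]
            mean_internal = sub[np.triu_indices(len(idx), k=1)].mean()
        else:
            mean_internal = 0.0
        key = (-len(members), mean_internal, min(members))
        if best_key is None or key < best_key:
            best_key, best_members = key, set(members)
    retained = [s for s in ids if s in best_members]
    removed = [s for s in ids if s not in best_members]
    return retained, removed


def retain_targets(
    groups: dict[str, TargetSignatureGroup], min_signatures: int = 3
) -> dict[str, TargetSignatureGroup]:
    """Drop targets whose retained signature count is below the floor."""
    kept: dict[str, TargetSignatureGroup] = {}
    for tid, grp in groups.items():
        grp.validate()
        if len(grp.retained) >= min_signatures:
            kept[tid] = grp
    return kept
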