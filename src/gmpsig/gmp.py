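"""Borda merging of a target's signatures and module-pair extraction.

Each retained signature votes on the ordering of the target's
co-expressed genes; the consensus list is cut into the top/bottom
``module_size`` genes to form the gene module pair (GMP).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    Effect,
    EffectLabel,
    GeneModulePair,
    PerturbagenAnnotation,
    TargetSpace,
    ValidationError,
)

__all__ = [
    "MergedGeneList",
    "borda_merge",
    "extract_gmp",
    "specificity_filter",
    "annotate_effect",
]

_INHIBITORY = {Effect.INHIBIT, Effect.KNOCKDOWN}
_STIMULATORY = {Effect.ACTIVATE, Effect.OVEREXPRESS}


@dataclass
class MergedGeneList:
    """Consensus gene ordering for one target (position 1 = most up)."""

    target_id: str
    genes: list[str]
    merged_value: np.ndarray
    mode: str = "rank"

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.merged_value = np.asarray(self.merged_value, dtype=float)
        if len(self.genes) != len(self.merged_value):
            raise ValidationError("merged_value not parallel to genes")

    def __len__(self) -> int:
        return len(self.genes)


def borda_merge(
    signatures: pd.DataFrame, mode: str = "rank", target_id: str = ""
) -> MergedGeneList:
    """Merge per-signature gene orderings into a consensus list.

    Parameters
    ----------
    signatures : DataFrame, genes x signatures
        The target's retained signature columns restricted to its
        co-expressed genes; NaN entries are a universe mismatch.
    mode : {"rank", "value"}
        "rank": each gene's merging value is the sum of its within-
        signature ranks (1 = most upregulated); the list is sorted
        ascending so consistently-up genes lead.  "value": merging value
        is the sum of raw differential values, sorted descending.

    Ties are broken by smaller mean rank across signatures, then by
    lexicographic gene id.
    """
    if signatures.shape[0] < 1 or signatures.shape[1] < 1:
        raise ValidationError("need >= 1 gene and >= 1 signature")
    if signatures.isna().to_numpy().any():
        raise ValidationError("missing values: gene/signature universe mismatch")
    genes = np.asarray(signatures.index.astype(str))
    values = signatures.to_numpy(dtype=float)
    n, m = values.shape
    ranks = np.empty_like(values)
    for j in range(m):
        order = np.lexsort((genes, -values[:, j]))
        ranks[order, j] = np.arange(1, n + 1)
    mean_rank = ranks.mean(axis=1)
    if mode == "rank":
        merged = ranks.sum(axis=1)
        order = np.lexsort((genes, mean_rank, merged))
    elif mode == "value":
        merged = values.sum(axis=1)
        order = np.lexsort((genes, mean_rank, -merged))
    else:
        raise ValidationError(f"unknown borda mode {mode!r}")
    return MergedGeneList(
        target_id=target_id,
        genes=list(genes[order]),
        merged_value=merged[order],
        mode=mode,
    )


def extract_gmp(
    L: MergedGeneList,
    module_size: int = 250,
    effect_label: EffectLabel = EffectLabel.UNDETERMINED,
    provenance: dict | None = None,
) -> GeneModulePair | None:
    """Cut the merged list into its top/bottom ``module_size`` genes.

    Returns ``None`` (a dropped-target signal, not an exception) when the
    list is shorter than ``2 * module_size``.
    """
    if len(L) < 2 * module_size:
        return None
    return GeneModulePair(
        target_id=L.target_id,
        up=frozenset(L.genes[:module_size]),
        down=frozenset(L.genes[-module_size:]),
        effect_label=effect_label,
        provenance=provenance or {},
    )


def _targets_per_perturbagen(
    annotations: Sequence[PerturbagenAnnotation],
) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for a in annotations:
        out.setdefault(a.perturbagen_id, set()).add(a.target_gene)
    return out


def specificity_filter(
    space: TargetSpace,
    annotations: Sequence[PerturbagenAnnotation],
    min_perturbagens: int = 2,
) -> tuple[TargetSpace, list[str]]:
    """Flag (and remove) targets supported only by shared perturbagens.

    A target is flagged when it derives from fewer than
    ``min_perturbagens`` distinct perturbagens *and* every contributing
    perturbagen is annotated to more than one target — the situation in
    which target specificity of the GMP cannot be judged.
    """
    pert_targets = _targets_per_perturbagen(annotations)
    flagged: list[str] = []
    kept: dict[str, GeneModulePair] = {}
    for tid, g in space.gmps.items():
        perts = list(g.provenance.get("perturbagen_ids", []))
        multi_only = bool(perts) and all(
            len(pert_targets.get(p, set())) > 1 for p in perts
        )
        if len(set(perts)) < min_perturbagens and multi_only:
            flagged.append(tid)
        else:
            kept[tid] = g
    return (
        TargetSpace(gmps=kept, universe=space.universe, module_size=space.module_size),
        sorted(flagged),
    )


def annotate_effect(
    target_id: str,
    perturbagen_ids: Sequence[str],
    annotations: Sequence[PerturbagenAnnotation] | Mapping[tuple[str, str], Effect],
) -> EffectLabel:
    """Unanimous-vote effect label for a target's contributing perturbagens."""
    if not isinstance(annotations, Mapping):
        annotations = {
            (a.perturbagen_id, a.target_gene): a.effect for a in annotations
        }
    votes = set()
    for pid in perturbagen_ids:
        eff = annotations.get((pid, target_id), Effect.UNKNOWN)
        if eff in _INHIBITORY:
            votes.add(EffectLabel.INHIBITED)
        elif eff in _STIMULATORY:
            votes.add(EffectLabel.STIMULATED)
        else:
            votes.add(EffectLabel.UNDETERMINED)
    if votes == {EffectLabel.INHIBITED}:
        return EffectLabel.INHIBITED
    if votes == {EffectLabel.STIMULATED}:
        return EffectLabel.STIMULATED
    return EffectLabel.UNDETERMINED
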