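"""WGCNA-style co-expression module detection over a target's signatures.

Adjacency is |Pearson correlation across signatures| raised to a soft
power; similarity is the topological overlap measure (TOM); modules come
from a fixed-height cut of the average-linkage tree on 1 - TOM with a
minimum module size floor.  Genes falling in no module are reported as
unassigned (label 0) and excluded from downstream merging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .types import SignatureMatrix, ValidationError

__all__ = [
    "ModuleAssignment",
    "select_soft_power",
    "topological_overlap",
    "detect_modules",
    "correlation_adjacency",
]

logger = logging.getLogger(__name__)

DEFAULT_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10)
FALLBACK_POWER = 6


@dataclass
class ModuleAssignment:
    """Gene -> module label map for one target (0 = unassigned)."""

    target_id: str
    labels: dict[str, int]
    parameters: dict = field(default_factory=dict)

    @property
    def assigned(self) -> list[str]:
        return [g for g, m in self.labels.items() if m > 0]

    @property
    def n_modules(self) -> int:
        return len({m for m in self.labels.values() if m > 0})

    def module_members(self, label: int) -> list[str]:
        return sorted(g for g, m in self.labels.items() if m == label)


def _safe_corr(values: np.ndarray) -> np.ndarray:
    """Pearson correlation between gene rows; constant rows get 0."""
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{constant.sum()} constant gene rows; correlation set to 0")
    centered = values - values.mean(axis=1, keepdims=True)
    denom = np.where(constant, 1.0, sd * values.shape[1])
    normed = centered / denom[:, None]
    corr = normed @ normed.T * values.shape[1]
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    corr[constant, constant] = 1.0
    return corr


def correlation_adjacency(values: np.ndarray, soft_power: int) -> np.ndarray:
    """Unsigned soft-thresholded adjacency with zero diagonal."""
    adj = np.abs(_safe_corr(values)) ** soft_power
    np.fill_diagonal(adj, 0.0)
    return adj


def _scale_free_r2(adj: np.ndarray, n_bins: int = 10) -> float:
    """R-squared of log10 p(k) vs log10 k; 0 when the slope is positive."""
    k = adj.sum(axis=1)
    if np.allclose(k, 0) or len(k) < 4:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        km = k[mask].mean()
        if km <= 0:
            continue
        xs.append(np.log10(km))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0
    slope, _ = np.polyfit(xs, ys, 1)
    r = np.corrcoef(xs, ys)[0, 1]
    if not np.isfinite(r) or slope >= 0:
        return 0.0
    return float(r**2)


def select_soft_power(
    expr: SignatureMatrix | np.ndarray,
    candidate_powers=DEFAULT_POWERS,
    r2_cut: float = 0.8,
) -> int:
    """Smallest candidate power reaching the scale-free fit cut.

    Falls back to 6 (with a warning) when no candidate qualifies.
    """
    candidate_powers = tuple(candidate_powers)
    if not candidate_powers:
        raise ValidationError("candidate_powers is empty")
    values = expr.values if isinstance(expr, SignatureMatrix) else np.asarray(expr)
    if values.shape[1] < 3:
        raise ValidationError("need >= 3 signatures for correlation")
    for p in sorted(candidate_powers):
        if _scale_free_r2(correlation_adjacency(values, p)) >= r2_cut:
            return int(p)
    warnings.warn(
        f"no candidate power reached scale-free R^2 >= {r2_cut}; "
        f"falling back to {FALLBACK_POWER}"
    )
    return FALLBACK_POWER


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM[i, j] = (sum_u a[i,u] a[u,j] + a[i,j]) / (min(k_i, k_j) + 1 - a[i,j])
    with TOM[i, i] = 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValidationError("adjacency must be symmetric")
    if np.any(np.abs(np.diag(a)) > 1e-12):
        raise ValidationError("adjacency diagonal must be zero")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    shared = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return tom


def detect_modules(
    expr: SignatureMatrix,
    soft_power: int | None = None,
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> ModuleAssignment:
    """Detect co-expression modules across a target's retained signatures.

    Labels are renumbered by descending module size, ties by smallest
    member gene id; genes in clusters below ``min_module_size`` get 0.
    """
    if expr.n_signatures < 3:
        raise ValidationError("need >= 3 signatures for co-expression analysis")
    if expr.n_signatures < 6:
        logger.warning(
            "co-expression over only %d signatures is unstable", expr.n_signatures
        )
    if soft_power is None:
        soft_power = select_soft_power(expr)
    adj = correlation_adjacency(expr.values, soft_power)
    tom = topological_overlap(adj)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    tree = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(tree, t=cut_height, criterion="distance")
    genes = expr.gene_ids
    clusters: dict[int, list[str]] = {}
    for g, lab in zip(genes, raw):
        clusters.setdefault(int(lab), []).append(g)
    keep = [
        members for members in clusters.values() if len(members) >= min_module_size
    ]
    keep.sort(key=lambda members: (-len(members), min(members)))
    labels = {g: 0 for g in genes}
    for new_label, members in enumerate(keep, start=1):
        for g in members:
            labels[g] = new_label
    return ModuleAssignment(
        target_id="",
        labels=labels,
        parameters={
            "soft_power": int(soft_power),
            "min_module_size": int(min_module_size),
            "cut_height": float(cut_height),
        },
    )
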