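"""Running-sum enrichment score and the inverse-total-enrichment-score
(ITES) distance between perturbation signatures.

The distance between signatures X and Y is

    d(X, Y) = (ITES(X, Y) + ITES(Y, X)) / 2
    ITES(X, Y) = 1 - |ES_Y(X_up) - ES_Y(X_dn)| / 2

where X_up / X_dn are the ``n_extreme`` most up/down-regulated genes of X
and ES is the classic unweighted running-sum enrichment score of a gene
set against a ranked list.  Concordant signatures score near 0,
unrelated ones near 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import RankedGeneList, SignatureMatrix, ValidationError

__all__ = [
    "SignatureExtremes",
    "DistanceMatrix",
    "enrichment_score",
    "ites",
    "signature_distance",
    "pairwise_distances",
    "estimate_distance_threshold",
    "rank_matrix",
    "extreme_indices",
]


@dataclass
class SignatureExtremes:
    """Top/bottom ``n_extreme`` genes of a signature, most extreme first."""

    up: list[str]
    down: list[str]

    def __post_init__(self) -> None:
        self.up = [str(g) for g in self.up]
        self.down = [str(g) for g in self.down]
        if len(self.up) != len(self.down):
            raise ValidationError("up/down extremes differ in size")
        if set(self.up) & set(self.down):
            raise ValidationError("up/down extremes overlap")

    @staticmethod
    def from_values(values: pd.Series, n_extreme: int = 250) -> "SignatureExtremes":
        if 2 * n_extreme > len(values):
            raise ValidationError(
                f"need >= {2 * n_extreme} genes for n_extreme={n_extreme}, "
                f"got {len(values)}"
            )
        ranked = RankedGeneList.from_values(values)
        return SignatureExtremes(
            up=ranked.genes[:n_extreme], down=ranked.genes[-n_extreme:][::-1]
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise signature distances in [0, 1]."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(s) for s in self.ids]
        self.d = np.asarray(self.d, dtype=float)
        k = len(self.ids)
        if self.d.shape != (k, k):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValidationError("nonzero diagonal in distance matrix")
        if self.d.min() < -1e-12 or self.d.max() > 1 + 1e-12:
            raise ValidationError("distance entries outside [0, 1]")

    @property
    def n_pairs(self) -> int:
        """Number of unique unordered pairs the matrix holds."""
        k = len(self.ids)
        return k * (k - 1) // 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @staticmethod
    def from_tsv(path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return DistanceMatrix(ids=list(df.index.astype(str)), d=df.to_numpy())


def _es_from_sorted_positions(pos: np.ndarray, n_total: int) -> np.ndarray:
    """Signed max-deviation running sum from sorted 1-based hit positions.

    ``pos`` has shape (..., h) with positions sorted ascending along the
    last axis.  Vectorised over leading axes.
    """
    h = pos.shape[-1]
    miss = n_total - h
    i = np.arange(h, dtype=float)
    # misses encountered before the (i+1)-th hit
    misses_before = pos - 1 - i
    before = i / h - misses_before / miss
    after = (i + 1.0) / h - misses_before / miss
    max_dev = after.max(axis=-1)
    min_dev = np.minimum(before.min(axis=-1), 0.0)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


def enrichment_score(L: RankedGeneList, S, strict: bool = False) -> float:
    """Classic unweighted GSEA running-sum enrichment score.

    Walk ``L`` from top to bottom adding ``1/|S ∩ L|`` on a hit and
    subtracting ``1/(N - |S ∩ L|)`` on a miss; return the signed value of
    maximum absolute deviation of the running sum.

    Parameters
    ----------
    L : RankedGeneList
    S : iterable of gene ids
        Genes absent from ``L`` are dropped unless ``strict``.

    Returns
    -------
    float in [-1, 1]
    """
    if not isinstance(L, RankedGeneList):
        L = RankedGeneList(genes=list(L))
    S = set(map(str, S))
    present = S & set(L.genes)
    if strict and present != S:
        raise ValidationError("strict mode: set members absent from list")
    if not present:
        raise ValidationError("set absent from list")
    if len(present) == len(L.genes):
        raise ValidationError("set covers the whole list; miss step undefined")
    pos = np.sort([i + 1 for i, g in enumerate(L.genes) if g in present])
    return float(_es_from_sorted_positions(np.asarray(pos, dtype=float), len(L.genes)))


def ites(X: SignatureExtremes, Y: RankedGeneList) -> float:
    """Inverse total enrichment score of X's extremes against ranking Y."""
    es_up = enrichment_score(Y, X.up)
    es_dn = enrichment_score(Y, X.down)
    return 1.0 - abs(es_up - es_dn) / 2.0


def _as_series(sig) -> pd.Series:
    if isinstance(sig, pd.Series):
        return sig.astype(float)
    return pd.Series(dict(sig), dtype=float)


def signature_distance(X, Y, n_extreme: int = 250) -> float:
    """Symmetrised ITES distance between two signatures.

    ``X`` and ``Y`` are gene -> value mappings (or Series) over the same
    gene universe with at least ``2 * n_extreme`` genes.
    """
    xs, ys = _as_series(X), _as_series(Y)
    if set(xs.index) != set(ys.index):
        raise ValidationError("signatures are over different gene universes")
    ex_x = SignatureExtremes.from_values(xs, n_extreme)
    ex_y = SignatureExtremes.from_values(ys, n_extreme)
    rank_x = RankedGeneList.from_values(xs)
    rank_y = RankedGeneList.from_values(ys)
    return (ites(ex_x, rank_y) + ites(ex_y, rank_x)) / 2.0


def rank_matrix(M: SignatureMatrix) -> np.ndarray:
    """1-based rank of each gene within each signature (rank 1 = most up).

    Ties broken by descending value then lexicographic gene id; returns an
    array of shape (n_genes, n_signatures).
    """
    genes = np.asarray(M.gene_ids)
    n, k = M.values.shape
    ranks = np.empty((n, k), dtype=np.int64)
    for j in range(k):
        order = np.lexsort((genes, -M.values[:, j]))
        ranks[order, j] = np.arange(1, n + 1)
    return ranks


def extreme_indices(M: SignatureMatrix, n_extreme: int) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of the top/bottom ``n_extreme`` genes of each signature."""
    genes = np.asarray(M.gene_ids)
    n, k = M.values.shape
    up = np.empty((k, n_extreme), dtype=np.int64)
    dn = np.empty((k, n_extreme), dtype=np.int64)
    for j in range(k):
        order = np.lexsort((genes, -M.values[:, j]))
        up[j] = order[:n_extreme]
        dn[j] = order[-n_extreme:]
    return up, dn


def _ites_matrix(ranks: np.ndarray, up: np.ndarray, dn: np.ndarray) -> np.ndarray:
    """ITES(X_i, Y_j) for all signature pairs.

    ``ranks`` is genes x k from :func:`rank_matrix`; ``up``/``dn`` are
    k x n_extreme extreme-gene row indices.
    """
    n, k = ranks.shape
    out = np.empty((k, k), dtype=float)
    for i in range(k):
        pos_up = np.sort(ranks[up[i], :].T, axis=1).astype(float)
        pos_dn = np.sort(ranks[dn[i], :].T, axis=1).astype(float)
        es_up = _es_from_sorted_positions(pos_up, n)
        es_dn = _es_from_sorted_positions(pos_dn, n)
        out[i, :] = 1.0 - np.abs(es_up - es_dn) / 2.0
    return out


def pairwise_distances(M: SignatureMatrix, n_extreme: int = 250) -> DistanceMatrix:
    """All-vs-all signature distances; evaluates C(k, 2) unique pairs."""
    if M.n_signatures < 2:
        raise ValidationError("need >= 2 signatures for pairwise distances")
    if 2 * n_extreme > M.n_genes:
        raise ValidationError(
            f"universe of {M.n_genes} genes too small for n_extreme={n_extreme}"
        )
    ranks = rank_matrix(M)
    up, dn = extreme_indices(M, n_extreme)
    I = _ites_matrix(ranks, up, dn)
    d = (I + I.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    return DistanceMatrix(ids=list(M.sig_ids), d=d)


def estimate_distance_threshold(
    M: SignatureMatrix,
    sample_size: int = 1000,
    reps: int = 1000,
    quantile: float = 0.05,
    n_extreme: int = 250,
    seed: int | np.random.Generator = 0,
) -> float:
    """Resampling estimate of a distance-significance threshold.

    Per repetition, sample ``sample_size`` signatures, compute all
    pairwise distances and take the empirical ``quantile`` (higher
    interpolation); return the mean over repetitions.
    """
    if not (0.0 < quantile < 1.0):
        raise ValidationError("quantile must be in (0, 1)")
    rng = np.random.default_rng(seed)
    k = M.n_signatures
    replace = k < sample_size
    if replace:
        warnings.warn(
            f"only {k} signatures available; sampling {sample_size} with replacement"
        )
    thresholds = np.empty(reps)
    for r in range(reps):
        take = rng.choice(k, size=sample_size, replace=replace)
        sub = SignatureMatrix(
            gene_ids=list(M.gene_ids),
            sig_ids=[f"s{t}" for t in range(sample_size)],
            values=M.values[:, take],
        )
        D = pairwise_distances(sub, n_extreme=n_extreme)
        tri = D.d[np.triu_indices(sample_size, k=1)]
        thresholds[r] = np.quantile(tri, quantile, method="higher")
    return float(thresholds.mean())


def expected_pair_count(k: int) -> int:
    """C(k, 2): unique unordered pairs among k signatures."""
    return math.comb(k, 2)
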