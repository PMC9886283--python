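"""Core domain types shared across the pipeline.

Gene and signature identifiers are opaque strings throughout; no
symbol/accession translation is attempted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Effect",
    "EffectLabel",
    "SignatureMeta",
    "SignatureMatrix",
    "PerturbagenAnnotation",
    "RankedGeneList",
    "GeneModulePair",
    "TargetSpace",
    "PipelineConfig",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


class Effect(str, Enum):
    """Perturbation effect of a perturbagen on its annotated target."""

    INHIBIT = "inhibit"
    ACTIVATE = "activate"
    KNOCKDOWN = "knockdown"
    OVEREXPRESS = "overexpress"
    UNKNOWN = "unknown"


class EffectLabel(str, Enum):
    """Consensus direction label attached to an extracted module pair."""

    INHIBITED = "inhibited"
    STIMULATED = "stimulated"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class SignatureMeta:
    """Per-signature experimental metadata."""

    perturbagen_id: str | None = None
    cell_line: str | None = None
    dose: str | None = None
    time: str | None = None


@dataclass
class SignatureMatrix:
    """Genes x signatures differential-expression matrix with metadata.

    Parameters
    ----------
    gene_ids : sequence of str
        Row identifiers, unique.
    sig_ids : sequence of str
        Column identifiers, unique.
    values : ndarray of shape (n_genes, n_signatures)
        Finite z-like differential-expression scores.
    meta : mapping sig_id -> SignatureMeta
        A record must exist for every signature; missing entries are
        filled with empty records at construction.
    """

    gene_ids: list[str]
    sig_ids: list[str]
    values: np.ndarray
    meta: dict[str, SignatureMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sig_ids = [str(s) for s in self.sig_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene_ids in signature matrix")
        if len(set(self.sig_ids)) != len(self.sig_ids):
            raise ValidationError("duplicate sig_ids in signature matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sig_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sig_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite values in signature matrix")
        for sid in self.sig_ids:
            self.meta.setdefault(sid, SignatureMeta())

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_signatures(self) -> int:
        return len(self.sig_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sig_ids)

    def subset_signatures(self, sig_ids: Sequence[str]) -> "SignatureMatrix":
        sig_ids = [str(s) for s in sig_ids]
        idx = {s: j for j, s in enumerate(self.sig_ids)}
        missing = [s for s in sig_ids if s not in idx]
        if missing:
            raise KeyError(f"unknown sig_ids: {missing[:5]}")
        cols = [idx[s] for s in sig_ids]
        return SignatureMatrix(
            gene_ids=list(self.gene_ids),
            sig_ids=sig_ids,
            values=self.values[:, cols],
            meta={s: self.meta[s] for s in sig_ids},
        )

    def restrict_genes(self, universe: Iterable[str]) -> "SignatureMatrix":
        """Keep only genes present in ``universe`` (order preserved)."""
        allowed = set(map(str, universe))
        keep = [i for i, g in enumerate(self.gene_ids) if g in allowed]
        return SignatureMatrix(
            gene_ids=[self.gene_ids[i] for i in keep],
            sig_ids=list(self.sig_ids),
            values=self.values[keep, :],
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class PerturbagenAnnotation:
    """One perturbagen -> target mapping with its perturbation effect."""

    perturbagen_id: str
    target_gene: str
    effect: Effect = Effect.UNKNOWN

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect", Effect(self.effect))


def validate_annotations(annotations: Sequence[PerturbagenAnnotation]) -> None:
    pairs = [(a.perturbagen_id, a.target_gene) for a in annotations]
    if len(set(pairs)) != len(pairs):
        raise ValidationError("duplicate (perturbagen_id, target_gene) pairs")


@dataclass
class RankedGeneList:
    """An ordered gene list, position 1 = most upregulated.

    ``scores``, when given, must be parallel to ``genes`` and
    non-increasing.
    """

    genes: list[str]
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in ranked list")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if self.scores.shape != (len(self.genes),):
                raise ValidationError("scores not parallel to genes")
            if np.any(np.diff(self.scores) > 1e-12):
                raise ValidationError("scores not sorted non-increasing")

    def __len__(self) -> int:
        return len(self.genes)

    def reversed(self) -> "RankedGeneList":
        return RankedGeneList(genes=list(reversed(self.genes)))

    @staticmethod
    def from_values(values: Mapping[str, float] | pd.Series) -> "RankedGeneList":
        """Rank by descending value; ties broken by lexicographic gene id."""
        s = pd.Series(values, dtype=float)
        genes = np.asarray(s.index.astype(str))
        vals = s.to_numpy(dtype=float)
        order = np.lexsort((genes, -vals))
        return RankedGeneList(genes=list(genes[order]), scores=vals[order])


@dataclass
class GeneModulePair:
    """A target's signature: its up- and down-regulated gene modules."""

    target_id: str
    up: frozenset[str]
    down: frozenset[str]
    effect_label: EffectLabel = EffectLabel.UNDETERMINED
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.up = frozenset(map(str, self.up))
        self.down = frozenset(map(str, self.down))
        self.effect_label = EffectLabel(self.effect_label)
        if self.up & self.down:
            raise ValidationError(
                f"up/down modules of {self.target_id} are not disjoint"
            )

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down


@dataclass
class TargetSpace:
    """The collection of all gene module pairs over a fixed gene universe."""

    gmps: dict[str, GeneModulePair]
    universe: list[str]
    module_size: int = 250

    def __post_init__(self) -> None:
        self.universe = [str(g) for g in self.universe]
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ValidationError("duplicate genes in universe")
        for tid, g in self.gmps.items():
            if tid != g.target_id:
                raise ValidationError(f"key {tid} != target_id {g.target_id}")
            if len(g.up) != self.module_size or len(g.down) != self.module_size:
                raise ValidationError(
                    f"module pair of {tid} is not {self.module_size}/{self.module_size}"
                )
            if not (g.genes <= uni):
                raise ValidationError(f"genes of {tid} outside universe")

    def __len__(self) -> int:
        return len(self.gmps)

    @property
    def target_ids(self) -> list[str]:
        return sorted(self.gmps)


@dataclass
class PipelineConfig:
    """All tunable parameters of the extraction pipeline.

    Defaults mirror the reference analysis: 250-gene modules, 0.8
    dendrogram cut, at least 3 signatures per retained target, 1,000
    permutations and a 0.05 significance level.
    """

    module_size: int = 250
    n_extreme: int = 250
    outlier_threshold: float = 0.8
    linkage_method: str = "average"
    min_signatures: int = 3
    n_permutations: int = 1000
    alpha: float = 0.05
    rng_seed: int = 0
    soft_power: int | str = "auto"
    min_module_size: int = 30
    cut_height: float = 0.99
    borda_mode: str = "rank"
    min_perturbagens: int = 2
    edge_rule: str = "hyper_and_perm"
    damping: float = 0.5
    ap_max_iter: int = 1000
    run_coexpression: bool = True
    build_network: bool = False
    matrix_path: str | None = None
    matrix_format: str = "tsv"
    meta_path: str | None = None
    annotation_path: str | None = None
    universe_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.module_size < 1:
            raise ValidationError("module_size must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")

    @staticmethod
    def from_dict(d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return PipelineConfig(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
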