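"""Synthetic perturbation compendia with planted ground truth.

Emulates the statistical structure the pipeline assumes: every target
has a planted pair of up/down gene modules; each of its perturbagens
induces that signal (scaled per signature) on top of Gaussian noise;
a configurable fraction of signatures are outliers (pure noise or a
decoy target's signal); some perturbagens hit two targets.  Everything
is deterministic under the truth's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netchar import GeneNetwork
from .types import (
    Effect,
    PerturbagenAnnotation,
    RankedGeneList,
    SignatureMatrix,
    SignatureMeta,
    TargetSpace,
    ValidationError,
)

__all__ = [
    "SyntheticTruth",
    "simulate_compendium",
    "simulate_query",
    "simulate_gene_network",
    "recovery_report",
]

_CELLS = ("CL1", "CL2", "CL3")
_DOSES = ("1uM", "10uM")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic compendium."""

    n_genes: int = 1000
    n_targets: int = 20
    module_size: int = 50
    perts_per_target: int = 6
    sigs_per_pert: int = 2
    multi_target_frac: float = 0.1
    delta: float = 2.0
    outlier_frac: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0
    genes: list[str] = field(default_factory=list)
    targets: list[str] = field(default_factory=list)
    modules: dict[str, tuple[frozenset[str], frozenset[str]]] = field(
        default_factory=dict
    )
    pert_targets: dict[str, list[str]] = field(default_factory=dict)
    # filled by simulate_compendium: sig_id -> "clean" | "noise" | "decoy"
    outlier_sigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_targets, self.module_size,
               self.perts_per_target, self.sigs_per_pert) < 1:
            raise ValidationError("all size parameters must be >= 1")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if not (0.0 <= self.outlier_frac < 1.0):
            raise ValidationError("outlier_frac must be in [0, 1)")
        if 2 * self.module_size > self.n_genes:
            raise ValidationError("planted modules larger than the universe")
        if not self.genes:
            self._plant()

    def _plant(self) -> None:
        rng = np.random.default_rng(self.seed)
        width = len(str(self.n_genes))
        self.genes = [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]
        self.targets = [f"T{i + 1:03d}" for i in range(self.n_targets)]
        arr = np.asarray(self.genes)
        for tid in self.targets:
            pick = rng.choice(self.n_genes, size=2 * self.module_size, replace=False)
            self.modules[tid] = (
                frozenset(arr[pick[: self.module_size]]),
                frozenset(arr[pick[self.module_size:]]),
            )
        for t, tid in enumerate(self.targets):
            for k in range(self.perts_per_target):
                pid = f"P{t + 1:03d}_{k + 1}"
                hits = [tid]
                if self.n_targets > 1 and rng.random() < self.multi_target_frac:
                    other = int(rng.integers(0, self.n_targets - 1))
                    if other >= t:
                        other += 1
                    hits.append(self.targets[other])
                self.pert_targets[pid] = hits

    def signal_vector(self, target_id: str) -> np.ndarray:
        """+1 on the target's planted up genes, -1 on the down genes."""
        up, dn = self.modules[target_id]
        v = np.zeros(self.n_genes)
        idx = {g: i for i, g in enumerate(self.genes)}
        v[[idx[g] for g in up]] = 1.0
        v[[idx[g] for g in dn]] = -1.0
        return v


def simulate_compendium(
    truth: SyntheticTruth,
) -> tuple[SignatureMatrix, list[PerturbagenAnnotation]]:
    """Draw the full signature matrix plus its perturbagen annotations."""
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    signals = {tid: truth.signal_vector(tid) for tid in truth.targets}
    sig_ids, meta, columns = [], {}, []
    annotations = [
        PerturbagenAnnotation(pid, tid, Effect.INHIBIT)
        for pid, hits in sorted(truth.pert_targets.items())
        for tid in hits
    ]
    for pid, hits in sorted(truth.pert_targets.items()):
        for r in range(truth.sigs_per_pert):
            sid = f"{pid}_s{r + 1}"
            col = rng.normal(0.0, truth.noise_sd, size=truth.n_genes)
            scale = rng.uniform(0.5, 1.5)
            if rng.random() < truth.outlier_frac:
                if rng.random() < 0.5 and truth.n_targets > 1:
                    # decoy: the signal of an unrelated target
                    others = [t for t in truth.targets if t not in hits]
                    decoy = others[int(rng.integers(0, len(others)))]
                    col += truth.delta * scale * signals[decoy]
                    truth.outlier_sigs[sid] = "decoy"
                else:  # pure noise, no signal at all
                    truth.outlier_sigs[sid] = "noise"
            else:
                for tid in hits:
                    col += truth.delta * scale * signals[tid]
                truth.outlier_sigs[sid] = "clean"
            sig_ids.append(sid)
            columns.append(col)
            meta[sid] = SignatureMeta(
                perturbagen_id=pid,
                cell_line=_CELLS[r % len(_CELLS)],
                dose=_DOSES[r % len(_DOSES)],
                time="24h",
            )
    M = SignatureMatrix(
        gene_ids=list(truth.genes),
        sig_ids=sig_ids,
        values=np.column_stack(columns),
        meta=meta,
    )
    return M, annotations


def simulate_query(
    truth: SyntheticTruth,
    target: str,
    direction: str = "concordant",
    strength: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> RankedGeneList:
    """A single ranked query list carrying one target's planted signal."""
    if target not in truth.modules:
        raise ValidationError(f"unknown target {target!r}")
    if direction not in {"concordant", "reversed"}:
        raise ValidationError(f"unknown direction {direction!r}")
    if strength is None:
        strength = truth.delta
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(
            np.random.SeedSequence([truth.seed, 2, truth.targets.index(target)])
            if seed is None
            else seed
        )
    )
    values = rng.normal(0.0, truth.noise_sd, size=truth.n_genes)
    sign = 1.0 if direction == "concordant" else -1.0
    values += sign * strength * truth.signal_vector(target)
    return RankedGeneList.from_values(pd.Series(values, index=truth.genes))


def simulate_gene_network(
    truth: SyntheticTruth,
    within_module_p: float = 0.3,
    background_p: float = 0.01,
    seed: int | np.random.Generator | None = None,
) -> GeneNetwork:
    """Bernoulli gene network with elevated density inside planted modules."""
    if not (0.0 <= background_p <= within_module_p <= 1.0):
        raise ValidationError("need 0 <= background_p <= within_module_p <= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(
            np.random.SeedSequence([truth.seed, 3]) if seed is None else seed
        )
    )
    n = truth.n_genes
    idx = {g: i for i, g in enumerate(truth.genes)}
    prob = np.full((n, n), background_p)
    for up, dn in truth.modules.values():
        for members in (up, dn):
            m = [idx[g] for g in members]
            prob[np.ix_(m, m)] = within_module_p
    iu = np.triu_indices(n, k=1)
    hit = rng.random(iu[0].size) < prob[iu]
    arr = np.asarray(truth.genes)
    edges = {
        frozenset((arr[i], arr[j]))
        for i, j in zip(iu[0][hit], iu[1][hit])
    }
    return GeneNetwork(nodes=set(truth.genes), edges=edges)


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 1.0


def recovery_report(space: TargetSpace, truth: SyntheticTruth) -> pd.DataFrame:
    """Jaccard agreement of estimated vs planted modules, per shared target."""
    rows = []
    for tid in sorted(set(space.gmps) & set(truth.modules)):
        est = space.gmps[tid]
        up_true, dn_true = truth.modules[tid]
        j_up = _jaccard(est.up, up_true)
        j_dn = _jaccard(est.down, dn_true)
        swapped = (
            _jaccard(est.up, dn_true) > j_up and _jaccard(est.down, up_true) > j_dn
        )
        rows.append(
            {"target": tid, "jaccard_up": j_up, "jaccard_down": j_dn,
             "swapped": swapped}
        )
    return pd.DataFrame(rows)
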