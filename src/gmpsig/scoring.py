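"""Query scoring against a target space of gene module pairs (GMPTI).

A query ranked gene list L is compared with each target's module pair:

    TCS_L(t) = ES_L(t_up) - ES_L(t_down)      (zeroed when both share a sign)
    NCS_L(t) = TCS_L(t) / mean(|TCS_L|)       (over all targets)

Significance comes from re-pairing up and down modules across targets
(module-level permutation) and pooling the resulting |NCS| null scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distance import _es_from_sorted_positions
from .types import (
    EffectLabel,
    GeneModulePair,
    RankedGeneList,
    TargetSpace,
    ValidationError,
)

__all__ = [
    "Direction",
    "ScoreResult",
    "total_correlation_score",
    "normalize_scores",
    "score_pvalues",
    "query_targets",
    "self_recovery_ranks",
    "precision_recall_at_cutoffs",
]


class Direction(str, Enum):
    MIMICS_INHIBITION = "mimics_inhibition"
    MIMICS_STIMULATION = "mimics_stimulation"
    OPPOSES = "opposes"
    UNDETERMINED = "undetermined"


@dataclass
class ScoreResult:
    query_id: str
    target_id: str
    tcs: float
    ncs: float
    p: float
    direction: Direction

    def __post_init__(self) -> None:
        if not -2.0 - 1e-9 <= self.tcs <= 2.0 + 1e-9:
            raise ValidationError("TCS outside [-2, 2]")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError("p outside [0, 1]")


def _positions_of(L: RankedGeneList) -> dict[str, int]:
    return {g: i + 1 for i, g in enumerate(L.genes)}


def _es_one(pos_map: dict[str, int], n: int, S: frozenset[str] | set[str]) -> float:
    pos = sorted(pos_map[g] for g in S if g in pos_map)
    if not pos:
        raise ValidationError("set absent from list")
    if len(pos) == n:
        raise ValidationError("set covers the whole list; miss step undefined")
    return float(_es_from_sorted_positions(np.asarray(pos, dtype=float), n))


def _tcs_from_es(es_up: float, es_dn: float) -> float:
    if (es_up > 0 and es_dn > 0) or (es_up < 0 and es_dn < 0):
        return 0.0
    return es_up - es_dn


def total_correlation_score(L: RankedGeneList, g: GeneModulePair) -> float:
    """ES_L(t_up) - ES_L(t_down), zeroed when both ES share a sign.

    A zero ES never triggers the same-sign rule.  Range [-2, 2].
    """
    pos_map = _positions_of(L)
    n = len(L.genes)
    return _tcs_from_es(_es_one(pos_map, n, g.up), _es_one(pos_map, n, g.down))


def normalize_scores(tcs_vector: Sequence[float] | np.ndarray) -> np.ndarray:
    """NCS = TCS / mean(|TCS|) over all targets (zeros included in the mean)."""
    tcs = np.asarray(tcs_vector, dtype=float)
    if tcs.size == 0:
        raise ValidationError("empty TCS vector")
    mu = np.abs(tcs).mean()
    if mu == 0:
        warnings.warn("all TCS are zero; NCS set to 0")
        return np.zeros_like(tcs)
    return tcs / mu


def _score_all(L: RankedGeneList, pairs: Sequence[tuple[frozenset, frozenset]]):
    pos_map = _positions_of(L)
    n = len(L.genes)
    tcs = np.empty(len(pairs))
    for i, (up, dn) in enumerate(pairs):
        tcs[i] = _tcs_from_es(_es_one(pos_map, n, up), _es_one(pos_map, n, dn))
    return tcs


def score_pvalues(
    L: RankedGeneList,
    space: TargetSpace,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
    null_normalization: str = "null_mu",
) -> pd.DataFrame:
    """Permutation p-values for |NCS| of a query against every target.

    Per repetition a full null space is built by pairing the up-module of
    one uniformly drawn target with the down-module of a different
    target; the query is scored against it with the same normalization
    step (``null_normalization``: "null_mu" uses each null space's own
    mean |TCS|, "observed_mu" reuses the query's observed one).  The null
    |NCS| scores are pooled over repetitions and targets:
    p_i = #(|NCS_null| >= |NCS_i|) / #null.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    targets = space.target_ids
    if len(targets) < 3:
        raise ValidationError("need >= 3 targets for the permutation null")
    rng = np.random.default_rng(seed)
    ups = [space.gmps[t].up for t in targets]
    dns = [space.gmps[t].down for t in targets]

    tcs = _score_all(L, list(zip(ups, dns)))
    ncs = normalize_scores(tcs)
    obs_mu = np.abs(tcs).mean()

    n = len(targets)
    null_ncs = np.empty((reps, n))
    for r in range(reps):
        a = rng.integers(0, n, size=n)
        b = rng.integers(0, n - 1, size=n)
        b = np.where(b >= a, b + 1, b)
        null_tcs = _score_all(L, [(ups[i], dns[j]) for i, j in zip(a, b)])
        if null_normalization == "observed_mu" and obs_mu > 0:
            null_ncs[r] = null_tcs / obs_mu
        else:
            mu = np.abs(null_tcs).mean()
            null_ncs[r] = null_tcs / mu if mu > 0 else 0.0
    pooled = np.sort(np.abs(null_ncs).ravel())
    # p_i = fraction of pooled null |NCS| at or above |NCS_i|
    below = np.searchsorted(pooled, np.abs(ncs), side="left")
    p = (pooled.size - below) / pooled.size
    return pd.DataFrame({"target": targets, "tcs": tcs, "ncs": ncs, "p": p})


def _direction(ncs: float, label: EffectLabel) -> Direction:
    if ncs > 0 and label == EffectLabel.INHIBITED:
        return Direction.MIMICS_INHIBITION
    if ncs > 0 and label == EffectLabel.STIMULATED:
        return Direction.MIMICS_STIMULATION
    if ncs < 0 and label in (EffectLabel.INHIBITED, EffectLabel.STIMULATED):
        return Direction.OPPOSES
    return Direction.UNDETERMINED


def query_targets(
    L: RankedGeneList,
    space: TargetSpace,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
    query_id: str = "query",
) -> pd.DataFrame:
    """Score a query against every GMP; rows sorted by descending |NCS|."""
    if len(space) == 0:
        raise ValidationError("empty target space")
    df = score_pvalues(L, space, reps=reps, seed=seed)
    labels = {t: space.gmps[t].effect_label for t in df["target"]}
    df["direction"] = [
        _direction(row.ncs, labels[row.target]).value for row in df.itertuples()
    ]
    df.insert(0, "query", query_id)
    df = df.reindex(
        df["ncs"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def _rank_lists_from_matrix(M) -> dict[str, RankedGeneList]:
    frame = M.to_frame()
    return {
        sid: RankedGeneList.from_values(frame[sid]) for sid in frame.columns
    }


def self_recovery_ranks(
    space: TargetSpace,
    M,
    sig_groups: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Rank of each target's own GMP when scoring its signatures.

    For every target with signatures, the mean NCS of its signatures is
    computed against all GMPs; the own GMP's rank by descending |mean
    NCS| is reported (rank 1 = best; ties broken by target id).
    """
    targets = space.target_ids
    pairs = [(space.gmps[t].up, space.gmps[t].down) for t in targets]
    ranked = _rank_lists_from_matrix(M)
    rows = []
    for tid in sorted(sig_groups):
        sids = [s for s in sig_groups[tid] if s in ranked]
        if tid not in space.gmps or not sids:
            continue
        ncs_mat = np.vstack(
            [normalize_scores(_score_all(ranked[s], pairs)) for s in sids]
        )
        mean_ncs = ncs_mat.mean(axis=0)
        order = np.lexsort((np.asarray(targets), -np.abs(mean_ncs)))
        rank = int(np.flatnonzero(np.asarray(targets)[order] == tid)[0]) + 1
        rows.append(
            {
                "target": tid,
                "n_signatures": len(sids),
                "mean_ncs_self": mean_ncs[targets.index(tid)],
                "rank": rank,
            }
        )
    return pd.DataFrame(rows)


def precision_recall_at_cutoffs(
    results: pd.DataFrame,
    truth_pairs: set[tuple[str, str]],
    ncs_cutoffs: Sequence[float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Precision/recall of predicted (query, target) pairs vs a truth set.

    At cutoff c the prediction set is {pairs with |NCS| >= c and
    p < alpha}.  Precision is NaN (reported missing) when no predictions
    remain.
    """
    truth = {(str(q), str(t)) for q, t in truth_pairs}
    rows = []
    for c in ncs_cutoffs:
        pred = {
            (str(r.query), str(r.target))
            for r in results.itertuples()
            if abs(r.ncs) >= c and r.p < alpha
        }
        tp = len(pred & truth)
        fp = len(pred - truth)
        fn = len(truth - pred)
        precision = tp / (tp + fp) if pred else np.nan
        recall = tp / (tp + fn) if truth else np.nan
        rows.append(
            {"cutoff": c, "n_predicted": len(pred), "tp": tp,
             "precision": precision, "recall": recall}
        )
    return pd.DataFrame(rows)
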