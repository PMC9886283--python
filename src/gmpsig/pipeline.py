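"""End-to-end driver: compendium -> filtered targets -> GMP target space.

Stage order follows the extraction procedure: pairwise signature
distances, dendrogram outlier removal, target retention, co-expression
module detection, Borda merging, module-pair extraction, specificity
filtering, then (optionally) the target network and its communities.
All randomized stages draw from substreams of one seeded generator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .coexpression import detect_modules
from .distance import pairwise_distances
from .filtering import (
    TargetSignatureGroup,
    cluster_signatures,
    remove_outliers,
    retain_targets,
)
from .gmp import annotate_effect, borda_merge, extract_gmp, specificity_filter
from .io import read_annotations, read_signature_matrix, write_gmt
from .targetnet import TargetNetwork, build_target_network, cluster_targets
from .types import (
    GeneModulePair,
    PerturbagenAnnotation,
    PipelineConfig,
    SignatureMatrix,
    TargetSpace,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "group_signatures_by_target"]

# fixed offsets for per-stage RNG substreams
_STAGE_SEEDS = {"network": 11, "communities": 12}


@dataclass
class PipelineResult:
    space: TargetSpace
    network: TargetNetwork | None
    communities: object | None
    groups: dict[str, TargetSignatureGroup]
    filter_report: pd.DataFrame
    provenance: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def group_signatures_by_target(
    M: SignatureMatrix, annotations: Sequence[PerturbagenAnnotation]
) -> dict[str, list[str]]:
    """target -> signature ids of all perturbagens annotated to it."""
    by_pert: dict[str, list[str]] = {}
    for sid in M.sig_ids:
        pid = M.meta[sid].perturbagen_id
        if pid is None:
            raise ValidationError(f"signature {sid} has no perturbagen metadata")
        by_pert.setdefault(pid, []).append(sid)
    groups: dict[str, list[str]] = {}
    for a in annotations:
        for sid in by_pert.get(a.perturbagen_id, []):
            groups.setdefault(a.target_gene, []).append(sid)
    return {t: sorted(set(s)) for t, s in groups.items()}


def _filter_target(
    M: SignatureMatrix, sig_ids: list[str], cfg: PipelineConfig
) -> tuple[list[str], list[str]]:
    if len(sig_ids) == 1:  # singleton: bypass clustering
        return list(sig_ids), []
    sub = M.subset_signatures(sig_ids)
    D = pairwise_distances(sub, n_extreme=cfg.n_extreme)
    tree = cluster_signatures(D, method=cfg.linkage_method)
    return remove_outliers(tree, D, threshold=cfg.outlier_threshold)


def run_pipeline(
    config: PipelineConfig,
    M: SignatureMatrix | None = None,
    annotations: Sequence[PerturbagenAnnotation] | None = None,
) -> PipelineResult:
    """Execute the full extraction pipeline.

    Inputs may be passed in memory; otherwise they are read from the
    paths in ``config``.  Re-running with the same config and seed
    produces identical outputs.
    """
    cfg = config
    if M is None:
        if cfg.matrix_path is None:
            raise ValidationError("no signature matrix given")
        universe = None
        if cfg.universe_path:
            universe = [
                line.strip()
                for line in open(cfg.universe_path)
                if line.strip()
            ]
        M = read_signature_matrix(
            cfg.matrix_path, format=cfg.matrix_format,
            meta_path=cfg.meta_path, universe=universe,
        )
    if annotations is None:
        if cfg.annotation_path is None:
            raise ValidationError("no perturbagen annotations given")
        annotations = read_annotations(cfg.annotation_path)

    ann_map = {(a.perturbagen_id, a.target_gene): a.effect for a in annotations}
    stage_counts: dict[str, object] = {"signatures_in": M.n_signatures}

    # --- outlier filtering per target -------------------------------------
    sig_groups = group_signatures_by_target(M, annotations)
    stage_counts["targets_in"] = len(sig_groups)
    groups: dict[str, TargetSignatureGroup] = {}
    filter_rows = []
    for tid in sorted(sig_groups):
        retained, removed = _filter_target(M, sig_groups[tid], cfg)
        groups[tid] = TargetSignatureGroup(
            target_id=tid, sig_ids=sig_groups[tid],
            retained=retained, removed=removed,
        )
        for sid in retained:
            filter_rows.append({"target": tid, "sig_id": sid, "status": "retained"})
        for sid in removed:
            filter_rows.append({"target": tid, "sig_id": sid, "status": "outlier"})
    kept_groups = retain_targets(groups, min_signatures=cfg.min_signatures)
    dropped_few = sorted(set(groups) - set(kept_groups))
    for tid in dropped_few:
        logger.info("target %s dropped: <%d retained signatures", tid,
                    cfg.min_signatures)
    stage_counts["targets_after_retention"] = len(kept_groups)
    stage_counts["signatures_retained"] = sum(
        len(g.retained) for g in groups.values()
    )
    stage_counts["signatures_outlier"] = sum(
        len(g.removed) for g in groups.values()
    )

    # --- co-expression + Borda merge + extraction -------------------------
    frame = M.to_frame()
    gmps: dict[str, GeneModulePair] = {}
    prov_rows = []
    for tid, grp in sorted(kept_groups.items()):
        sub = M.subset_signatures(grp.retained)
        drop_reason = ""
        if cfg.run_coexpression:
            power = None if cfg.soft_power == "auto" else int(cfg.soft_power)
            assignment = detect_modules(
                sub, soft_power=power,
                min_module_size=cfg.min_module_size,
                cut_height=cfg.cut_height,
            )
            module_genes = sorted(assignment.assigned)
        else:
            module_genes = list(M.gene_ids)
        perts = sorted(
            {M.meta[s].perturbagen_id for s in grp.retained}
        )
        if len(module_genes) < 2 * cfg.module_size:
            drop_reason = (
                f"only {len(module_genes)} co-expressed genes "
                f"(< {2 * cfg.module_size})"
            )
            logger.info("target %s dropped: %s", tid, drop_reason)
        else:
            merged = borda_merge(
                frame.loc[module_genes, grp.retained],
                mode=cfg.borda_mode, target_id=tid,
            )
            label = annotate_effect(tid, perts, ann_map)
            g = extract_gmp(
                merged, module_size=cfg.module_size, effect_label=label,
                provenance={
                    "n_signatures": len(grp.retained),
                    "n_perturbagens": len(perts),
                    "perturbagen_ids": perts,
                },
            )
            if g is not None:
                gmps[tid] = g
        prov_rows.append(
            {
                "target": tid,
                "n_signatures": len(grp.retained),
                "n_perturbagens": len(perts),
                "effect_label": gmps[tid].effect_label.value if tid in gmps else "",
                "drop_reason": drop_reason,
            }
        )
    stage_counts["targets_with_gmp"] = len(gmps)

    space = TargetSpace(
        gmps=gmps, universe=list(M.gene_ids), module_size=cfg.module_size
    )
    space, flagged = specificity_filter(
        space, annotations, min_perturbagens=cfg.min_perturbagens
    )
    stage_counts["targets_flagged_unspecific"] = len(flagged)
    stage_counts["targets_final"] = len(space)

    # --- optional target network ------------------------------------------
    network = communities = None
    if cfg.build_network and len(space) >= 3:
        network = build_target_network(
            space, alpha=cfg.alpha, rule=cfg.edge_rule,
            reps=cfg.n_permutations,
            seed=np.random.default_rng(
                np.random.SeedSequence([cfg.rng_seed, _STAGE_SEEDS["network"]])
            ),
        )
        stage_counts["network_edges"] = network.n_edges
        if len(network.nodes) >= 2:
            communities = cluster_targets(
                network, damping=cfg.damping, max_iter=cfg.ap_max_iter,
                seed=cfg.rng_seed,
            )
            stage_counts["communities"] = communities.n_communities

    manifest = {
        "tool_version": __version__,
        "seed": cfg.rng_seed,
        "config": cfg.to_dict(),
        "stage_counts": stage_counts,
        "flagged_targets": flagged,
        "dropped_min_signatures": dropped_few,
    }
    result = PipelineResult(
        space=space,
        network=network,
        communities=communities,
        groups=groups,
        filter_report=pd.DataFrame(
            filter_rows, columns=["target", "sig_id", "status"]
        ),
        provenance=pd.DataFrame(prov_rows),
        manifest=manifest,
    )
    if cfg.out_dir:
        _write_artifacts(result, cfg)
    return result


def _write_artifacts(result: PipelineResult, cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gmt(result.space, out / "space.gmt")
    result.filter_report.to_csv(out / "filter_report.tsv", sep="\t", index=False)
    result.provenance.to_csv(out / "provenance.tsv", sep="\t", index=False)
    artifacts = ["space.gmt", "filter_report.tsv", "provenance.tsv"]
    if result.network is not None:
        result.network.to_tsv(out / "target_network.tsv")
        artifacts.append("target_network.tsv")
    if result.communities is not None:
        pd.DataFrame(
            [
                {"target": t, "cluster_id": c,
                 "exemplar": result.communities.exemplars[c]}
                for t, c in sorted(result.communities.membership.items())
            ]
        ).to_csv(out / "communities.tsv", sep="\t", index=False)
        artifacts.append("communities.tsv")
    result.manifest["artifacts"] = artifacts
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
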