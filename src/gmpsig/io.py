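"""Readers and writers for the plain-text formats the pipeline speaks.

Expression matrices travel as GCT 1.2 or headered TSV, module pairs as
GMT (two records per target, ``<target>_up`` / ``<target>_down``),
annotations and metadata as TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .types import (
    Effect,
    EffectLabel,
    GeneModulePair,
    PerturbagenAnnotation,
    PipelineConfig,
    SignatureMatrix,
    SignatureMeta,
    TargetSpace,
    ValidationError,
    validate_annotations,
)

__all__ = [
    "read_signature_matrix",
    "write_signature_matrix",
    "read_metadata",
    "write_metadata",
    "read_annotations",
    "write_annotations",
    "read_gmt",
    "write_gmt",
    "read_config",
]


class ParseError(ValidationError):
    """Malformed input file; the message names the offending line."""


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ParseError(f"{path}:1: expected '#1.2' header, got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2 or not all(d.isdigit() for d in dims):
            raise ParseError(f"{path}:2: expected '<nrows> <ncols>'")
        nrows, ncols = map(int, dims)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if df.shape[0] != nrows or df.shape[1] - 1 != ncols:
        raise ParseError(
            f"{path}:2: declared {nrows}x{ncols} but found "
            f"{df.shape[0]}x{df.shape[1] - 1}"
        )
    return df.drop(columns=df.columns[0])  # drop Description


def read_signature_matrix(
    path,
    format: str = "tsv",
    meta_path=None,
    universe: Sequence[str] | None = None,
) -> SignatureMatrix:
    """Read a genes x signatures matrix (GCT 1.2 or headered TSV).

    Metadata is joined from a sidecar TSV on sig_id when given; every
    signature must have a record.  When ``universe`` is given, rows are
    restricted to it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "gct":
        df = _read_gct(path)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    else:
        raise ValidationError(f"unknown matrix format {format!r}")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()][:3].tolist()
        raise ValidationError(f"duplicate gene ids in {path}: {dupes}")
    meta = read_metadata(meta_path) if meta_path else {}
    if meta_path:
        missing = [s for s in df.columns if str(s) not in meta]
        if missing:
            raise ValidationError(
                f"signatures without metadata records: {missing[:5]}"
            )
    M = SignatureMatrix(
        gene_ids=list(df.index.astype(str)),
        sig_ids=list(df.columns.astype(str)),
        values=df.to_numpy(dtype=float),
        meta=meta,
    )
    if universe is not None:
        M = M.restrict_genes(universe)
    return M


def write_signature_matrix(M: SignatureMatrix, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        M.to_frame().to_csv(path, sep="\t", index_label="gene")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{M.n_genes}\t{M.n_signatures}\n")
            fh.write("NAME\tDescription\t" + "\t".join(M.sig_ids) + "\n")
            for i, g in enumerate(M.gene_ids):
                vals = "\t".join(repr(float(v)) for v in M.values[i])
                fh.write(f"{g}\tna\t{vals}\n")
    else:
        raise ValidationError(f"unknown matrix format {format!r}")


def read_metadata(path) -> dict[str, SignatureMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sig_id" not in df.columns:
        raise ParseError(f"{path}: metadata needs a 'sig_id' column")
    if df["sig_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sig_id rows")
    out = {}
    for row in df.itertuples():
        out[str(row.sig_id)] = SignatureMeta(
            perturbagen_id=getattr(row, "pert_id", None),
            cell_line=getattr(row, "cell", None),
            dose=getattr(row, "dose", None),
            time=getattr(row, "time", None),
        )
    return out


def write_metadata(M: SignatureMatrix, path) -> None:
    rows = [
        {
            "sig_id": s,
            "pert_id": M.meta[s].perturbagen_id,
            "cell": M.meta[s].cell_line,
            "dose": M.meta[s].dose,
            "time": M.meta[s].time,
        }
        for s in M.sig_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> list[PerturbagenAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"pert_id", "target"}
    if not needed <= set(df.columns):
        raise ParseError(f"{path}: annotation TSV needs columns {sorted(needed)}")
    anns = [
        PerturbagenAnnotation(
            perturbagen_id=str(row.pert_id),
            target_gene=str(row.target),
            effect=Effect(getattr(row, "effect", "unknown") or "unknown"),
        )
        for row in df.itertuples()
    ]
    validate_annotations(anns)
    return anns


def write_annotations(annotations: Iterable[PerturbagenAnnotation], path) -> None:
    pd.DataFrame(
        [
            {"pert_id": a.perturbagen_id, "target": a.target_gene,
             "effect": a.effect.value}
            for a in annotations
        ]
    ).to_csv(path, sep="\t", index=False)


def write_gmt(space: TargetSpace, path) -> None:
    """Two GMT records per target; the description field carries the
    effect label so round-trips preserve it."""
    with open(path, "w") as fh:
        for tid in space.target_ids:
            g = space.gmps[tid]
            up = "\t".join(sorted(g.up))
            dn = "\t".join(sorted(g.down))
            fh.write(f"{tid}_up\t{g.effect_label.value}\t{up}\n")
            fh.write(f"{tid}_down\t{g.effect_label.value}\t{dn}\n")


def read_gmt(path, universe: Sequence[str] | None = None) -> TargetSpace:
    ups: dict[str, tuple[str, set[str]]] = {}
    downs: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT record needs >= 3 fields")
            name, desc, genes = parts[0], parts[1], set(parts[2:])
            if name.endswith("_up"):
                ups[name[:-3]] = (desc, genes)
            elif name.endswith("_down"):
                downs[name[:-5]] = (desc, genes)
            else:
                raise ParseError(
                    f"{path}:{lineno}: record {name!r} lacks _up/_down suffix"
                )
    orphans = set(ups) ^ set(downs)
    if orphans:
        raise ValidationError(f"unpaired GMT records for targets {sorted(orphans)}")
    sizes = {len(g) for _, g in ups.values()} | {len(g) for _, g in downs.values()}
    if len(sizes) > 1:
        raise ValidationError(f"inconsistent module sizes in {path}: {sorted(sizes)}")
    module_size = sizes.pop() if sizes else 0
    gmps = {
        tid: GeneModulePair(
            target_id=tid,
            up=frozenset(ups[tid][1]),
            down=frozenset(downs[tid][1]),
            effect_label=EffectLabel(ups[tid][0])
            if ups[tid][0] in EffectLabel._value2member_map_
            else EffectLabel.UNDETERMINED,
        )
        for tid in ups
    }
    if universe is None:
        universe = sorted(set().union(*(g.genes for g in gmps.values()), set()))
    return TargetSpace(gmps=gmps, universe=list(universe), module_size=module_size)


def read_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)
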