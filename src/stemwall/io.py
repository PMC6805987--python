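"""Readers and writers for the pipeline's plain-text formats.

Tables are tab-separated with a header row; lines starting with ``#`` are
metadata (config hash, seed, thresholds) and are skipped on read.  Sequences
are aligned FASTA (via Biopython), trees are Newick with bootstrap supports
as internal node labels.  Infinite expression ratios serialize as ``Inf``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import INTERNODES, InternodeCountMatrix
from .orthology import GeneAnnotation, OrthologCall, WallContext
from .phylogeny import Alignment

PathLike = Union[str, Path]

COUNT_COLUMNS = [f"i{i}" for i in INTERNODES]


class SchemaError(ValueError):
    """A table does not match its documented schema."""


def config_hash(config) -> str:
    """Stable short hash of a configuration dataclass or mapping."""
    obj = asdict(config) if is_dataclass(config) else dict(config)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: PathLike, meta: Optional[Mapping] = None,
               index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=index)


def _read_tsv(path: PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# counts / library sizes / ambiguous pairs
# ---------------------------------------------------------------------------


def write_counts(icm: InternodeCountMatrix, counts_path: PathLike,
                 libsizes_path: PathLike, ambiguous_path: PathLike,
                 meta: Optional[Mapping] = None) -> None:
    df = icm.counts.copy()
    df.columns = COUNT_COLUMNS
    df.index.name = "gene"
    _write_tsv(df, counts_path, meta)
    libs = icm.lib_sizes.rename("library_size").to_frame()
    libs.index = [f"i{i}" for i in libs.index]
    libs.index.name = "internode"
    _write_tsv(libs, libsizes_path, meta)
    amb = icm.ambiguous.copy()
    amb["internode"] = [f"i{int(i)}" for i in amb["internode"]]
    _write_tsv(amb, ambiguous_path, meta, index=False)


def _parse_internode(label) -> int:
    s = str(label).lstrip("i")
    try:
        val = int(s)
    except ValueError as exc:
        raise SchemaError(f"unparseable internode label {label!r}") from exc
    if val not in INTERNODES:
        raise SchemaError(
            f"internode i{val} not allowed; expected {{i4, i5, i6, i8}}"
        )
    return val


def read_counts(counts_path: PathLike, libsizes_path: PathLike,
                ambiguous_path: Optional[PathLike] = None) -> InternodeCountMatrix:
    df = _read_tsv(counts_path)
    if "gene" not in df.columns:
        raise SchemaError(f"{counts_path}: missing 'gene' column")
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise SchemaError(f"{counts_path}: duplicated gene ids {dups}")
    df = df.set_index("gene")
    df.columns = [_parse_internode(c) for c in df.columns]

    libs = _read_tsv(libsizes_path)
    if not {"internode", "library_size"} <= set(libs.columns):
        raise SchemaError(f"{libsizes_path}: need columns internode, library_size")
    lib_sizes = pd.Series(
        libs["library_size"].to_numpy(),
        index=[_parse_internode(i) for i in libs["internode"]],
    )

    if ambiguous_path is not None and Path(ambiguous_path).exists():
        amb = _read_tsv(ambiguous_path)
        need = {"gene_a", "gene_b", "internode", "count"}
        if len(amb) and not need <= set(amb.columns):
            raise SchemaError(f"{ambiguous_path}: need columns {sorted(need)}")
        if len(amb):
            amb["internode"] = [_parse_internode(i) for i in amb["internode"]]
        else:
            amb = pd.DataFrame(columns=["gene_a", "gene_b", "internode", "count"])
    else:
        amb = pd.DataFrame(columns=["gene_a", "gene_b", "internode", "count"])
    return InternodeCountMatrix(counts=df, lib_sizes=lib_sizes, ambiguous=amb)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def write_annotations(annotations: Iterable[GeneAnnotation], path: PathLike,
                      meta: Optional[Mapping] = None) -> None:
    df = pd.DataFrame([
        {
            "gene": a.gene, "species": a.species, "family": a.family,
            "subgroup": a.subgroup or "",
            "wall_context": a.wall_context.value,
        }
        for a in annotations
    ])
    _write_tsv(df, path, meta, index=False)


def read_annotations(path: PathLike) -> dict[str, GeneAnnotation]:
    df = _read_tsv(path, dtype=str).fillna("")
    need = {"gene", "species", "family"}
    if not need <= set(df.columns):
        raise SchemaError(f"{path}: need columns {sorted(need)}")
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise SchemaError(f"{path}: duplicated gene ids {dups}")
    out = {}
    for row in df.itertuples(index=False):
        ctx = getattr(row, "wall_context", "") or "unknown"
        out[row.gene] = GeneAnnotation(
            gene=row.gene, species=row.species, family=row.family,
            subgroup=(getattr(row, "subgroup", "") or None),
            wall_context=WallContext(ctx),
        )
    return out


# ---------------------------------------------------------------------------
# alignments / trees
# ---------------------------------------------------------------------------


def write_alignment(aln: Alignment, path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(s), id=gid, description="")
        for gid, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_alignment(path: PathLike) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    return Alignment(ids=[r.id for r in records], seqs=[str(r.seq) for r in records])


def write_newick(tree, path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# calls / orthologs / summaries
# ---------------------------------------------------------------------------


def write_calls(calls_frame: pd.DataFrame, path: PathLike,
                meta: Optional[Mapping] = None) -> None:
    df = calls_frame.copy()
    df["ratio"] = [
        "Inf" if isinstance(r, float) and math.isinf(r)
        else ("" if isinstance(r, float) and math.isnan(r) else r)
        for r in df["ratio"]
    ]
    _write_tsv(df, path, meta)


def read_calls(path: PathLike) -> pd.DataFrame:
    df = _read_tsv(path).set_index("gene")

    def parse_ratio(v):
        if pd.isna(v) or v == "":
            return math.nan
        if str(v) == "Inf":
            return math.inf
        return float(v)

    df["ratio"] = [parse_ratio(v) for v in df["ratio"]]
    return df


def write_orthologs(calls: Iterable[OrthologCall], path: PathLike,
                    meta: Optional[Mapping] = None) -> None:
    df = pd.DataFrame([
        {
            "maize_gene": c.maize_gene, "reference_gene": c.reference_gene,
            "identity": round(c.identity, 6), "maize_class": c.maize_class.value,
            "reference_context": c.reference_context.value, "verdict": c.verdict.value,
        }
        for c in calls
    ])
    _write_tsv(df, path, meta, index=False)


def write_summary(frame: pd.DataFrame, path: PathLike,
                  meta: Optional[Mapping] = None) -> None:
    _write_tsv(frame, path, meta)


def write_subgroups(labels: Mapping[str, str], supports: Mapping[str, Optional[float]],
                    family: str, path: PathLike, meta: Optional[Mapping] = None) -> None:
    df = pd.DataFrame([
        {
            "gene": g, "family": family, "subgroup": lab,
            "support": "" if supports.get(g) is None else f"{supports[g]:g}",
        }
        for g, lab in labels.items()
    ])
    _write_tsv(df, path, meta, index=False)


# ---------------------------------------------------------------------------
# ground truth (synthetic fixtures)
# ---------------------------------------------------------------------------


def write_truth(truth, path: PathLike, meta: Optional[Mapping] = None) -> None:
    _write_tsv(truth.genes, path, meta, index=False)


def read_truth_table(path: PathLike) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"gene": str})
    for col in ("wall_class", "partner", "closest_ref", "ref_context", "subgroup"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df
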