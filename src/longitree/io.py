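"""Readers and writers for the tool's tabular and VCF interfaces.

Inputs: a cell metadata table (TSV/CSV), one VCF per cell (named
``<cell_id>.vcf`` or ``.vcf.gz``), a variant annotation table and a
per-cell per-site read-depth table.  Outputs: the filtered mutation
matrix, the longitudinal clonal tree (DOT + JSON), a fishplot /
TimeScape-compatible prevalence table, and a per-time-point summary.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .matrix import CellMetadata, MutationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EXONIC_FUNCTIONS",
    "UNANNOTATED",
    "CallTable",
    "VariantAnnotation",
    "read_cell_metadata",
    "read_variant_calls",
    "read_annotation_table",
    "read_depth_table",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_outputs",
]

#: closed vocabulary of exonic functional classes understood by the
#: annotation back-ends this tool consumes tables from
EXONIC_FUNCTIONS = (
    "Frameshift insertion",
    "Frameshift deletion",
    "Frameshift block substitution",
    "Stopgain",
    "Stoploss",
    "Nonframeshift insertion",
    "Nonframeshift deletion",
    "Nonframeshift block substitution",
    "Nonsynonymous SNV",
    "Synonymous SNV",
    "Unknown",
)

UNANNOTATED = "unannotated"


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# call table


@dataclass
class CallTable:
    """Per-(cell, variant) read counts.

    ``total`` and ``alt`` map ``(cell_id, variant_key)`` to read counts;
    a missing pair means no reads observed (depth 0).  Variant keys are
    ``chrom:pos:ref:alt`` with a 1-based VCF position, kept verbatim
    (no indel normalization).
    """

    total: dict[tuple[str, str], int] = field(default_factory=dict)
    alt: dict[tuple[str, str], int] = field(default_factory=dict)

    def add(self, cell: str, variant: str, total: int, alt: int) -> None:
        if total < 0 or alt < 0:
            raise FormatError(
                f"negative depth for ({cell}, {variant}): total={total}, alt={alt}"
            )
        if alt > total:
            raise FormatError(
                f"alt depth {alt} exceeds total {total} for ({cell}, {variant})"
            )
        self.total[(cell, variant)] = total
        self.alt[(cell, variant)] = alt

    def variants(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, v in self.total:
            seen.setdefault(v)
        return list(seen)

    def get_alt(self, cell: str, variant: str) -> int:
        return self.alt.get((cell, variant), 0)

    def get_total(self, cell: str, variant: str) -> int:
        return self.total.get((cell, variant), 0)


@dataclass
class VariantAnnotation:
    """Gene symbol, exonic functional class and population MAF per variant."""

    gene: dict[str, str] = field(default_factory=dict)
    exonic_function: dict[str, str] = field(default_factory=dict)
    maf: dict[str, float] = field(default_factory=dict)  # absent key = missing

    def gene_of(self, variant: str) -> str | None:
        return self.gene.get(variant)

    def class_of(self, variant: str) -> str:
        return self.exonic_function.get(variant, UNANNOTATED)

    def maf_of(self, variant: str) -> float | None:
        return self.maf.get(variant)


# ---------------------------------------------------------------------------
# readers


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_cell_metadata(
    path: str | Path,
    cell_column: str,
    sample_column: str,
    sample_order: list[str],
) -> CellMetadata:
    """Parse the cell metadata table and attach the chronological order.

    ``sample_order`` is user-authoritative: position in the list is the
    time tag (1-based).  Extra columns are ignored.
    """
    df = _read_table(path)
    for col in (cell_column, sample_column):
        if col not in df.columns:
            raise FormatError(
                f"metadata file {path} lacks required column {col!r}; "
                f"found {list(df.columns)}"
            )
    cells = df[cell_column].tolist()
    samples = df[sample_column].tolist()
    present = set(samples)
    missing = sorted(present - set(sample_order))
    if missing:
        raise FormatError(
            f"samples {missing} present in metadata but absent from sample_order"
        )
    return CellMetadata(
        cells=cells,
        sample_of=dict(zip(cells, samples)),
        sample_order=list(sample_order),
    )


def _vcf_records(path: Path, cell: str, calls: CallTable) -> None:
    vcf = pysam.VariantFile(str(path))
    try:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None:
                continue
            sample_vals = rec.samples[0] if len(rec.samples) else None
            ad = None
            dp = None
            if sample_vals is not None:
                ad = sample_vals.get("AD")
                dp = sample_vals.get("DP")
            if ad is not None and all(a is not None for a in ad):
                total = int(sum(ad))
                alts = [int(a) for a in ad[1:]]
            elif dp is not None:
                # AD missing: total from DP, alt support unknown -> skip
                logger.warning(
                    "VCF %s: record %s:%s has DP but no AD; "
                    "using DP as total with zero alt support",
                    path.name, rec.chrom, rec.pos,
                )
                total = int(dp)
                alts = [0] * len(rec.alts)
            else:
                logger.warning(
                    "VCF %s: record %s:%s has neither AD nor DP; skipped",
                    path.name, rec.chrom, rec.pos,
                )
                continue
            for alt_allele, alt_count in zip(rec.alts, alts):
                key = f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt_allele}"
                calls.add(cell, key, total, alt_count)
    finally:
        vcf.close()


def read_variant_calls(vcf_dir: str | Path, metadata: CellMetadata) -> CallTable:
    """Read one VCF per cell from *vcf_dir*.

    Only files whose basename (minus a case-insensitive ``.vcf`` /
    ``.vcf.gz`` extension) matches a metadata cell id are analyzed;
    other files are skipped.  Multi-allelic records are split into one
    variant key per ALT allele, with alt depth taken from the matching
    AD slot and total depth from sum(AD) (DP is the fallback).
    """
    vcf_dir = Path(vcf_dir)
    files: dict[str, Path] = {}
    for p in sorted(vcf_dir.iterdir()):
        name = p.name
        lower = name.lower()
        if lower.endswith(".vcf.gz"):
            stem = name[: -len(".vcf.gz")]
        elif lower.endswith(".vcf"):
            stem = name[: -len(".vcf")]
        else:
            logger.info("skipping non-VCF file %s", name)
            continue
        if stem not in metadata.sample_of:
            logger.info("skipping VCF %s: no matching cell id", name)
            continue
        files[stem] = p

    calls = CallTable()
    for cell in metadata.cells:
        path = files.get(cell)
        if path is None:
            logger.warning(
                "cell %s has no VCF in %s; treated as having no calls",
                cell, vcf_dir,
            )
            continue
        try:
            _vcf_records(path, cell, calls)
        except (ValueError, OSError) as exc:
            raise FormatError(f"malformed VCF {path}: {exc}") from exc
    return calls


def _variant_key_column(df: pd.DataFrame, path: str | Path) -> pd.Series:
    if "variant_key" in df.columns:
        return df["variant_key"]
    parts = ("chrom", "pos", "ref", "alt")
    if all(c in df.columns for c in parts):
        return df[list(parts)].agg(":".join, axis=1)
    raise FormatError(
        f"{path}: need a variant_key column or chrom/pos/ref/alt columns; "
        f"found {list(df.columns)}"
    )


def read_annotation_table(path: str | Path) -> VariantAnnotation:
    """Read the variant annotation table (gene, exonic class, MAF).

    Unknown exonic-function strings fall back to ``unannotated`` with a
    warning; an empty MAF field means missing (no population record).
    """
    df = _read_table(path)
    keys = _variant_key_column(df, path)
    for col in ("gene", "exonic_function"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    ann = VariantAnnotation()
    vocab = set(EXONIC_FUNCTIONS) | {UNANNOTATED}
    for key, gene, func, maf in zip(
        keys, df["gene"], df["exonic_function"],
        df["maf"] if "maf" in df.columns else [""] * len(df),
    ):
        ann.gene[key] = gene
        if func not in vocab:
            logger.warning(
                "annotation %s: unknown exonic_function %r mapped to %r",
                key, func, UNANNOTATED,
            )
            func = UNANNOTATED
        ann.exonic_function[key] = func
        if maf != "":
            ann.maf[key] = float(maf)
    return ann


def read_depth_table(path: str | Path) -> CallTable:
    """Read per-(cell, variant) depths; absent pairs mean depth 0."""
    df = _read_table(path)
    for col in ("cell_id", "total_depth"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    keys = _variant_key_column(df, path)
    has_alt = "alt_depth" in df.columns
    table = CallTable()
    for i, (cell, key) in enumerate(zip(df["cell_id"], keys)):
        total = int(df["total_depth"].iloc[i])
        alt = int(df["alt_depth"].iloc[i]) if has_alt and df["alt_depth"].iloc[i] != "" else 0
        if total < 0 or alt < 0:
            raise FormatError(f"{path}: negative depth for ({cell}, {key})")
        table.add(cell, key, total, alt)
    return table


# ---------------------------------------------------------------------------
# mutation matrix TSV round trip


def write_matrix_tsv(matrix: MutationMatrix, path: str | Path) -> None:
    """Write the matrix as TSV: cell_id, sample, then one column per variant.

    Entries are ``0``, ``1`` or the literal ``NA``.
    """
    df = matrix.data.copy()
    out = pd.DataFrame(index=df.index)
    out["cell_id"] = df.index
    out["sample"] = [matrix.metadata.sample_of[c] for c in df.index]
    for v in df.columns:
        col = df[v]
        out[v] = [
            "NA" if (isinstance(x, float) and math.isnan(x)) else str(int(x))
            for x in col
        ]
    out.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path, sample_order: list[str]) -> MutationMatrix:
    """Read a matrix TSV written by :func:`write_matrix_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("cell_id", "sample"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    cells = df["cell_id"].tolist()
    meta = CellMetadata(
        cells=cells,
        sample_of=dict(zip(cells, df["sample"])),
        sample_order=list(sample_order),
    )
    variants = [c for c in df.columns if c not in ("cell_id", "sample")]
    data = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    for v in variants:
        data[v] = [np.nan if x == "NA" else float(x) for x in df[v]]
    return MutationMatrix(data=data, metadata=meta)


# ---------------------------------------------------------------------------
# output bundle


def _tree_json(longitudinal_tree, annotation: VariantAnnotation | None) -> dict:
    nodes = []
    for node in longitudinal_tree.nodes:
        muts = list(node.mutations)
        genes = []
        if annotation is not None:
            genes = sorted({
                g for g in (annotation.gene_of(m) for m in muts) if g
            })
        nodes.append({
            "clone": node.clone,
            "time_tag": node.time_tag,
            "prevalence": node.prevalence,
            "mutations": muts,
            "genes": genes,
        })
    edges = [
        {"from": e.parent_id, "to": e.child_id, "type": e.kind}
        for e in longitudinal_tree.edges
    ]
    return {"nodes": nodes, "edges": edges}


def _tree_dot(longitudinal_tree) -> str:
    def node_id(clone: str, t: int) -> str:
        return f'"{clone}@{t}"'

    lines = ["digraph longitudinal_clonal_tree {", "  rankdir=TB;"]
    for node in longitudinal_tree.nodes:
        label = f"{node.clone}\\nt={node.time_tag}\\np={node.prevalence:.3f}"
        lines.append(f'  {node_id(node.clone, node.time_tag)} [label="{label}"];')
    for e in longitudinal_tree.edges:
        style = "solid" if e.kind == "parental" else "dashed"
        pc, pt = e.parent
        cc, ct = e.child
        lines.append(f"  {node_id(pc, pt)} -> {node_id(cc, ct)} [style={style}];")
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_outputs(
    out_dir: str | Path,
    matrix: MutationMatrix,
    longitudinal_tree,
    fishplot: pd.DataFrame,
    summary: pd.DataFrame,
    annotation: VariantAnnotation | None = None,
) -> dict[str, Path]:
    """Write the full result bundle.

    Produces the filtered matrix TSV, the longitudinal clonal tree as
    DOT and JSON, the fishplot prevalence table (TimeScape-compatible
    columns ``timepoint, clone_id, parent, clonal_prev``) and the
    per-time-point summary table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "mutation_matrix.tsv",
        "tree_json": out_dir / "longitudinal_tree.json",
        "tree_dot": out_dir / "longitudinal_tree.dot",
        "fishplot": out_dir / "fishplot.tsv",
        "summary": out_dir / "summary.tsv",
    }
    write_matrix_tsv(matrix, paths["matrix"])
    paths["tree_json"].write_text(
        json.dumps(_tree_json(longitudinal_tree, annotation), indent=2) + "\n"
    )
    paths["tree_dot"].write_text(_tree_dot(longitudinal_tree))
    fishplot.to_csv(paths["fishplot"], sep="\t", index=False)
    summary.to_csv(paths["summary"], sep="\t", index=False)
    return paths
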