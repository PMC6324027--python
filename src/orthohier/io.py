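"""Readers and writers for the toolkit's on-disk formats.

* protein FASTA (via Biopython), one record per CDS translation;
* taxonomy TSV with columns ``organism_id, species_taxid, genus_taxid``
  plus optional higher ranks;
* ortholog-table TSV, one row per cluster, one member cell per column,
  cells semicolon-joined ``gene_id(domain_index):begin-end`` segments;
* Newick trees (via scikit-bio).

Table serialization round-trips exactly: ``read(write(t)) == t`` for any
valid table (the member merge tree is in-memory bookkeeping and is not
serialized).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, TextIO, Union

import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

from .model import (
    PAN_SEP,
    DomainSegment,
    GeneRecord,
    OrthologCluster,
    OrthologTable,
    Taxonomy,
)

PathLike = Union[str, Path]

_CELL_RE = re.compile(r"^(?P<gid>.+)\((?P<dom>\d+)\):(?P<begin>\d+)-(?P<end>\d+)$")
_EMPTY = "-"
_TABLE_MAGIC = "#orthohier-table"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_protein_fasta(path: PathLike, organism_id: str) -> list[GeneRecord]:
    """Read one organism's protein FASTA.

    Gene ids are the header token before the first whitespace; they must
    be unique, non-empty and must not contain ':' (reserved for
    pan-gene names).
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if gene_id in seen:
            raise ValueError(f"{path}: duplicate gene id {gene_id!r}")
        if PAN_SEP in gene_id:
            raise ValueError(
                f"{path}: gene id {gene_id!r} contains reserved ':'"
            )
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: gene {gene_id!r} has empty sequence")
        seen.add(gene_id)
        records.append(GeneRecord(gene_id, organism_id, seq))
    return records


def write_protein_fasta(records: Iterable[GeneRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Taxonomy TSV
# ---------------------------------------------------------------------------

def read_taxonomy(path: PathLike) -> Taxonomy:
    """Read a taxonomy table mapping organisms to species/genus (and up)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["organism_id", "species_taxid", "genus_taxid"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing taxonomy columns {missing}")
    higher = [c for c in df.columns if c not in required]
    rows = [
        tuple(row[c] for c in required + higher) for _, row in df.iterrows()
    ]
    return Taxonomy.from_rows(rows)


def write_taxonomy(taxonomy: Taxonomy, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("organism_id\tspecies_taxid\tgenus_taxid\n")
        for org, sp, genus in taxonomy.rows():
            fh.write(f"{org}\t{sp}\t{genus}\n")


# ---------------------------------------------------------------------------
# Ortholog-table TSV
# ---------------------------------------------------------------------------

def format_segment(seg: DomainSegment) -> str:
    return str(seg)


def parse_segment(cell: str, line_no: int | None = None) -> DomainSegment:
    """Parse ``gene_id(domain):begin-end``; pan-gene ids may contain ':'."""
    where = f" (line {line_no})" if line_no is not None else ""
    m = _CELL_RE.match(cell)
    if m is None:
        raise ValueError(f"malformed member cell {cell!r}{where}")
    dom = int(m.group("dom"))
    begin = int(m.group("begin"))
    end = int(m.group("end"))
    if dom < 1 or begin < 1 or begin > end:
        raise ValueError(
            f"invalid segment coordinates in cell {cell!r}{where}"
        )
    return DomainSegment(m.group("gid"), dom, begin, end)


def _format_flags(cluster: OrthologCluster) -> str:
    items = []
    for gene_id in sorted(cluster.flags):
        fl = cluster.flags[gene_id]
        if fl:
            items.append(f"{gene_id}={'|'.join(sorted(fl))}")
    return ";".join(items) if items else _EMPTY


def _parse_flags(cell: str, line_no: int) -> dict[str, frozenset[str]]:
    if cell == _EMPTY:
        return {}
    out: dict[str, frozenset[str]] = {}
    for item in cell.split(";"):
        gene_id, eq, flags = item.rpartition("=")
        if not eq or not gene_id:
            raise ValueError(f"malformed flags {item!r} (line {line_no})")
        out[gene_id] = frozenset(flags.split("|"))
    return out


def write_ortholog_table(table: OrthologTable, path: PathLike) -> None:
    """Serialize a table; row/column order is deterministic (sorted ids)."""
    cols = table.columns
    with open(path, "w") as fh:
        fh.write(f"{_TABLE_MAGIC}\t1\n")
        fh.write(f"#level\t{table.level}\n")
        fh.write(f"#scope\t{table.scope_taxid}\n")
        header = (
            ["cluster_id", "representative", "flags"]
            + [f"members:{c}" for c in cols]
            + [f"conservation:{c}" for c in cols]
        )
        fh.write("\t".join(header) + "\n")
        for cluster in table.clusters:
            by_col: dict[str, list[DomainSegment]] = {c: [] for c in cols}
            for seg in cluster.members:
                col = table.column_of(seg.gene_id)
                by_col[col].append(seg)
            cells = [
                ";".join(format_segment(s) for s in sorted(by_col[c])) or _EMPTY
                for c in cols
            ]
            cons = [
                repr(table.conservation[(cluster.cluster_id, c)])
                if (cluster.cluster_id, c) in table.conservation
                else _EMPTY
                for c in cols
            ]
            rep = cluster.representative or _EMPTY
            row = [cluster.cluster_id, rep, _format_flags(cluster)] + cells + cons
            fh.write("\t".join(row) + "\n")


def read_ortholog_table(path: PathLike) -> OrthologTable:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith(_TABLE_MAGIC):
        raise ValueError(f"{path}: not an ortholog-table file")
    meta: dict[str, str] = {}
    i = 1
    while i < len(lines) and lines[i].startswith("#"):
        key, _, value = lines[i][1:].partition("\t")
        meta[key] = value
        i += 1
    if i >= len(lines):
        raise ValueError(f"{path}: missing table header")
    header = lines[i].split("\t")
    cols = [h.split(":", 1)[1] for h in header if h.startswith("members:")]
    clusters: list[OrthologCluster] = []
    member_columns: dict[str, str] = {}
    conservation: dict[tuple[str, str], float] = {}
    level = meta.get("level", "")
    scope = meta.get("scope", "")
    for line_no, line in enumerate(lines[i + 1 :], start=i + 2):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 3 + 2 * len(cols):
            raise ValueError(f"{path}: wrong field count (line {line_no})")
        cluster_id, rep, flags_cell = fields[:3]
        members: list[DomainSegment] = []
        for col, cell in zip(cols, fields[3 : 3 + len(cols)]):
            if cell == _EMPTY:
                continue
            for item in cell.split(";"):
                seg = parse_segment(item, line_no)
                members.append(seg)
                member_columns[seg.gene_id] = col
        for col, cell in zip(cols, fields[3 + len(cols) :]):
            if cell != _EMPTY:
                conservation[(cluster_id, col)] = float(cell)
        clusters.append(
            OrthologCluster(
                cluster_id=cluster_id,
                level=level,
                scope_taxid=scope,
                members=tuple(members),
                representative=None if rep == _EMPTY else rep,
                flags=_parse_flags(flags_cell, line_no),
            )
        )
    return OrthologTable(
        level=level,
        scope_taxid=scope,
        columns=tuple(cols),
        clusters=clusters,
        member_columns=member_columns,
        conservation=conservation,
    )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(source: Union[PathLike, TextIO, str]) -> TreeNode:
    """Read a Newick tree from a path or a literal Newick string."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        import io as _io

        return TreeNode.read(_io.StringIO(source))
    return TreeNode.read(str(source))


def write_newick(tree: TreeNode, path: PathLike | None = None) -> str:
    """Serialize a tree; returns the Newick string (and writes if asked)."""
    import io as _io

    buf = _io.StringIO()
    tree.write(buf)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
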