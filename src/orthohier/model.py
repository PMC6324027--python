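"""Core domain types shared by every stage of the pipeline.

The toolkit models genes as amino-acid sequences that may be decomposed
into *domain segments*, each segment belonging to exactly one ortholog
cluster.  Clusters live at one of three levels -- ``species``, ``genus``
or ``standard`` (between-genus) -- and are collected into ortholog
tables whose columns are the sub-taxa of the table's scope.  A
*pan-genome* is the set of representative gene segments of a table, one
per cluster, each named ``taxid:clustid``.

Coordinates are 1-based and inclusive throughout.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Any, Iterable

LEVELS = ("species", "genus", "standard")
RANKS = ("organism", "species", "genus", "higher")

#: Separator between the taxon id and the cluster id in a pan-gene name.
#: Raw gene ids and taxids must not contain it.
PAN_SEP = ":"


def is_pan_gene_id(gene_id: str) -> bool:
    """A pan-gene is named ``taxid:clustid``; raw genes never contain ':'."""
    return PAN_SEP in gene_id


def split_pan_gene_id(gene_id: str) -> tuple[str, str]:
    """Split ``taxid:clustid`` into its two parts."""
    taxid, _, clustid = gene_id.rpartition(PAN_SEP)
    if not taxid or not clustid:
        raise ValueError(f"not a valid pan-gene id: {gene_id!r}")
    return taxid, clustid


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene (or a pan-gene standing in for a cluster).

    ``location`` is an optional ``(replicon_id, begin, end, strand)``
    tuple in nucleotide coordinates; it is carried through but never
    interpreted by the orthology stages.
    """

    gene_id: str
    organism_id: str
    sequence: str
    location: tuple[str, int, int, int] | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"gene {self.gene_id!r}: empty sequence")
        if any(c.isspace() for c in self.sequence):
            raise ValueError(f"gene {self.gene_id!r}: whitespace in sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TaxonomyNode:
    taxid: str
    rank: str
    parent_taxid: str | None
    name: str = ""

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")


class Taxonomy:
    """Index over a rank path organism -> species -> genus -> (higher...).

    Built from per-organism rows; every organism maps to exactly one
    species and every species to exactly one genus.  Queries for unknown
    taxids return empty results rather than raising.
    """

    def __init__(self) -> None:
        self._nodes: dict[str, TaxonomyNode] = {}
        self._children: dict[str, list[str]] = {}

    @classmethod
    def from_rows(cls, rows: Iterable[tuple]) -> "Taxonomy":
        """Build from ``(organism_id, species_taxid, genus_taxid, *higher)`` rows."""
        tax = cls()
        seen: dict[str, tuple] = {}
        for row in rows:
            if len(row) < 3:
                raise ValueError(f"taxonomy row too short: {row!r}")
            org, species, genus, *higher = (str(x) for x in row)
            for taxid in (org, species, genus, *higher):
                if PAN_SEP in taxid:
                    raise ValueError(f"taxid may not contain ':': {taxid!r}")
            if org in seen and seen[org] != tuple(row[1:]):
                raise ValueError(
                    f"organism {org!r} mapped to conflicting lineages"
                )
            seen[org] = tuple(row[1:])
            path = [org, species, genus, *higher]
            ranks = ["organism", "species", "genus"] + ["higher"] * len(higher)
            for i, (taxid, rank) in enumerate(zip(path, ranks)):
                parent = path[i + 1] if i + 1 < len(path) else None
                node = TaxonomyNode(taxid, rank, parent)
                prev = tax._nodes.get(taxid)
                if prev is not None and prev != node:
                    raise ValueError(
                        f"taxid {taxid!r} appears with conflicting rank/parent"
                    )
                tax._nodes[taxid] = node
                if parent is not None:
                    kids = tax._children.setdefault(parent, [])
                    if taxid not in kids:
                        kids.append(taxid)
        return tax

    # -- queries ---------------------------------------------------------
    def rank(self, taxid: str) -> str | None:
        node = self._nodes.get(taxid)
        return node.rank if node else None

    def parent(self, taxid: str) -> str | None:
        node = self._nodes.get(taxid)
        return node.parent_taxid if node else None

    def children(self, taxid: str) -> tuple[str, ...]:
        return tuple(sorted(self._children.get(taxid, ())))

    def organisms_of(self, taxid: str) -> tuple[str, ...]:
        """All organism ids in the subtree below ``taxid`` (or itself)."""
        node = self._nodes.get(taxid)
        if node is None:
            return ()
        if node.rank == "organism":
            return (taxid,)
        out: list[str] = []
        for child in self._children.get(taxid, ()):
            out.extend(self.organisms_of(child))
        return tuple(sorted(out))

    def species_of(self, genus_taxid: str) -> tuple[str, ...]:
        return tuple(
            sorted(
                t
                for t in self._children.get(genus_taxid, ())
                if self.rank(t) == "species"
            )
        )

    def genera(self) -> tuple[str, ...]:
        return tuple(
            sorted(t for t, n in self._nodes.items() if n.rank == "genus")
        )

    def species(self) -> tuple[str, ...]:
        return tuple(
            sorted(t for t, n in self._nodes.items() if n.rank == "species")
        )

    def all_organisms(self) -> tuple[str, ...]:
        return tuple(
            sorted(t for t, n in self._nodes.items() if n.rank == "organism")
        )

    def species_of_organism(self, organism_id: str) -> str | None:
        node = self._nodes.get(organism_id)
        return node.parent_taxid if node and node.rank == "organism" else None

    def genus_of_species(self, species_taxid: str) -> str | None:
        node = self._nodes.get(species_taxid)
        return node.parent_taxid if node and node.rank == "species" else None

    def rows(self) -> list[tuple[str, str, str]]:
        out = []
        for org in self.all_organisms():
            sp = self.species_of_organism(org)
            out.append((org, sp, self.genus_of_species(sp)))
        return out


@dataclass(frozen=True, order=True)
class DomainSegment:
    """A contiguous region of one gene assigned to one cluster.

    ``begin``/``end`` are 1-based inclusive residue positions;
    ``domain_index`` numbers a gene's segments 1..k left to right.
    """

    gene_id: str
    domain_index: int
    begin: int
    end: int

    def __post_init__(self) -> None:
        if self.domain_index < 1:
            raise ValueError(
                f"{self.gene_id}: domain_index must be >= 1, got {self.domain_index}"
            )
        if not (1 <= self.begin <= self.end):
            raise ValueError(
                f"{self.gene_id}: invalid span {self.begin}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.begin + 1

    def __str__(self) -> str:
        return f"{self.gene_id}({self.domain_index}):{self.begin}-{self.end}"


@dataclass
class OrthologCluster:
    """An ortholog cluster at one level.

    ``flags`` maps member gene ids to a subset of
    {"fusion", "fission", "outlier"}.  ``member_tree`` is the
    hierarchical merge tree over members (a ``clustering.MemberTreeNode``);
    it is bookkeeping and excluded from equality comparisons.
    """

    cluster_id: str
    level: str
    scope_taxid: str
    members: tuple[DomainSegment, ...]
    representative: str | None = None
    flags: dict[str, frozenset[str]] = field(default_factory=dict)
    member_tree: Any = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        self.members = tuple(sorted(self.members))
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id}: no members")
        member_genes = {m.gene_id for m in self.members}
        if self.representative is not None and self.representative not in member_genes:
            raise ValueError(
                f"cluster {self.cluster_id}: representative "
                f"{self.representative!r} is not a member"
            )

    @property
    def member_gene_ids(self) -> tuple[str, ...]:
        return tuple(sorted({m.gene_id for m in self.members}))

    def gene_flags(self, gene_id: str) -> frozenset[str]:
        return self.flags.get(gene_id, frozenset())

    def median_member_length(self) -> float:
        return float(statistics.median(m.length for m in self.members))


@dataclass
class PanGenome:
    """Representative-gene set of a taxon; entries are ``taxid:clustid``."""

    taxid: str
    entries: dict[str, tuple[str, GeneRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pan_id, (cluster_id, rec) in self.entries.items():
            taxid, clustid = split_pan_gene_id(pan_id)
            if taxid != self.taxid or clustid != cluster_id:
                raise ValueError(
                    f"pan-gene id {pan_id!r} does not match "
                    f"taxon {self.taxid!r} / cluster {cluster_id!r}"
                )

    @property
    def records(self) -> tuple[GeneRecord, ...]:
        return tuple(rec for _, (_, rec) in sorted(self.entries.items()))


@dataclass
class OrthologTable:
    """A set of clusters over one taxon scope.

    ``columns`` are the sub-taxon ids of the scope (organisms for a
    species table, species for a genus table, genera for the standard
    table).  ``member_columns`` records which column each member gene
    belongs to, and ``conservation`` maps ``(cluster_id, column)`` to the
    fraction of the column's sub-units possessing the cluster.
    """

    level: str
    scope_taxid: str
    columns: tuple[str, ...]
    clusters: list[OrthologCluster]
    member_columns: dict[str, str] = field(default_factory=dict)
    conservation: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        self.columns = tuple(sorted(self.columns))
        self.clusters = sorted(self.clusters, key=lambda c: c.cluster_id)
        ids = [c.cluster_id for c in self.clusters]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cluster ids in table")
        for value in self.conservation.values():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"conservation {value} outside [0, 1]")

    def cluster(self, cluster_id: str) -> OrthologCluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(f"no cluster {cluster_id!r} in table {self.scope_taxid}")

    def column_of(self, gene_id: str) -> str:
        try:
            return self.member_columns[gene_id]
        except KeyError:
            raise KeyError(
                f"gene {gene_id!r} has no column in table {self.scope_taxid}"
            ) from None
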