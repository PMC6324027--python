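"""Bottom-up hierarchical orthology construction.

The build proceeds species -> genus -> standard:

1. every species with at least two genomes gets a within-species
   ortholog table (fast-mode all-vs-all + clustering) and a species
   pan-genome -- one representative gene segment per cluster, named
   ``taxid:clustid``; a single-genome species passes its raw genes
   through;
2. every genus with at least two species-level units gets a
   within-genus table over those units and a genus pan-genome;
3. the standard (between-genus) table is clustered from the genus-level
   units with the sensitive similarity mode.

Because pan-genes carry their whole cluster with them, expanding every
standard cluster back down recovers every input gene segment: the
standard table covers the entire gene repertoire, unlike a
representative-genome approach.

Representative selection prefers members that are structurally typical:
fusion, fission and outlier members are excluded (falling back to the
whole membership if everything is flagged), and among the survivors the
gene whose segment length is closest to the cluster median wins, ties
broken lexicographically.

Expansion maps domain coordinates from a representative into each
member via the stored pairwise alignment; positions falling between
aligned anchor pairs are filled by simple linear interpolation
(:func:`map_boundary`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .clustering import ClusterForest, build_clusters, flag_members
from .config import PipelineConfig
from .model import (
    DomainSegment,
    GeneRecord,
    OrthologCluster,
    OrthologTable,
    PanGenome,
    Taxonomy,
    is_pan_gene_id,
    split_pan_gene_id,
)
from .similarity import ScoringScheme, SimilarityHit, align_pair, all_vs_all

STANDARD_SCOPE = "root"


# ---------------------------------------------------------------------------
# boundary mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundaryMap:
    """Position mapping from a representative gene onto a member gene.

    ``anchors`` are the aligned position pairs (rep_pos, member_pos),
    strictly increasing in both coordinates.
    """

    anchors: tuple[tuple[int, int], ...]
    member_length: int

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError("empty alignment map")
        prev = (0, 0)
        for pair in self.anchors:
            if pair[0] <= prev[0] or pair[1] <= prev[1]:
                raise ValueError("alignment anchors must be strictly increasing")
            prev = pair


def boundary_map_from_hit(
    hit: SimilarityHit, rep_id: str, member_length: int
) -> BoundaryMap:
    """Orient a pairwise hit so positions map representative -> member."""
    if hit.query_id == rep_id:
        anchors = hit.alignment_map
    elif hit.subject_id == rep_id:
        anchors = tuple((s, q) for q, s in hit.alignment_map)
    else:
        raise ValueError(f"hit does not involve representative {rep_id!r}")
    return BoundaryMap(anchors=anchors, member_length=member_length)


def map_boundary(bmap: BoundaryMap, rep_position: int) -> int:
    """Map one representative position into member coordinates.

    Aligned positions map to their partner; positions between anchors
    are linearly interpolated (round half up); positions outside the
    anchored range extrapolate by constant offset, clamped to the
    member's valid range.
    """
    anchors = bmap.anchors
    lo, hi = 0, len(anchors) - 1
    if rep_position <= anchors[0][0]:
        q = anchors[0][1] - (anchors[0][0] - rep_position)
    elif rep_position >= anchors[-1][0]:
        q = anchors[-1][1] + (rep_position - anchors[-1][0])
    else:
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if anchors[mid][0] <= rep_position:
                lo = mid
            else:
                hi = mid
        p1, q1 = anchors[lo]
        p2, q2 = anchors[hi]
        if rep_position == p1:
            q = q1
        else:
            q = q1 + math.floor(
                (rep_position - p1) * (q2 - q1) / (p2 - p1) + 0.5
            )
    return min(max(int(q), 1), bmap.member_length)


# ---------------------------------------------------------------------------
# representative selection and pan-genomes
# ---------------------------------------------------------------------------

def select_representative(cluster: OrthologCluster) -> str:
    """Gene whose segment length is closest to the cluster median.

    Members carrying any structural flag (fusion/fission/outlier) are
    excluded; if every member is flagged the full membership is used.
    Ties break lexicographically, so re-running is stable.
    """
    med = cluster.median_member_length()
    unflagged = [
        m for m in cluster.members if not cluster.gene_flags(m.gene_id)
    ]
    pool = unflagged or list(cluster.members)
    best = min(pool, key=lambda m: (abs(m.length - med), m.gene_id))
    return best.gene_id


def representative_segment(cluster: OrthologCluster) -> DomainSegment:
    """The representative gene's member segment within this cluster."""
    if cluster.representative is None:
        raise ValueError(f"cluster {cluster.cluster_id}: no representative set")
    for m in cluster.members:
        if m.gene_id == cluster.representative:
            return m
    raise ValueError(
        f"cluster {cluster.cluster_id}: representative not among members"
    )


def build_pangenome(
    table: OrthologTable, genes: Mapping[str, GeneRecord]
) -> PanGenome:
    """One pan-gene per cluster, named ``taxid:clustid``.

    The pan-gene sequence is the representative's sequence restricted to
    its domain segment in that cluster, so a fallback to a fusion
    representative cannot leak foreign domains upward.
    """
    entries: dict[str, tuple[str, GeneRecord]] = {}
    for cluster in table.clusters:
        seg = representative_segment(cluster)
        seq = genes[seg.gene_id].sequence[seg.begin - 1 : seg.end]
        pan_id = f"{table.scope_taxid}:{cluster.cluster_id}"
        entries[pan_id] = (
            cluster.cluster_id,
            GeneRecord(pan_id, table.scope_taxid, seq),
        )
    return PanGenome(taxid=table.scope_taxid, entries=entries)


# ---------------------------------------------------------------------------
# the hierarchical database
# ---------------------------------------------------------------------------

@dataclass
class HierarchicalOrthologyDB:
    """All tables and pan-genomes of one bottom-up build."""

    taxonomy: Taxonomy
    config: PipelineConfig
    species_tables: dict[str, OrthologTable] = field(default_factory=dict)
    genus_tables: dict[str, OrthologTable] = field(default_factory=dict)
    standard_table: OrthologTable | None = None
    pangenomes: dict[str, PanGenome] = field(default_factory=dict)
    genes: dict[str, GeneRecord] = field(default_factory=dict)
    #: pan_gene_id -> the representative gene id and its segment span
    pan_rep: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    _aln_cache: dict[tuple[str, str], SimilarityHit | None] = field(
        default_factory=dict, repr=False
    )

    def table_at(self, level: str, scope_taxid: str | None = None) -> OrthologTable:
        if level == "standard":
            if self.standard_table is None:
                raise KeyError("no standard table built")
            return self.standard_table
        pool = self.species_tables if level == "species" else self.genus_tables
        if scope_taxid is None:
            raise ValueError(f"{level}-level lookup requires a scope taxid")
        if scope_taxid not in pool:
            raise KeyError(f"no {level} table for taxon {scope_taxid!r}")
        return pool[scope_taxid]

    def source_cluster(self, pan_gene_id: str) -> OrthologCluster:
        """Resolve a pan-gene to the cluster it represents."""
        taxid, clustid = split_pan_gene_id(pan_gene_id)
        for pool in (self.species_tables, self.genus_tables):
            if taxid in pool:
                return pool[taxid].cluster(clustid)
        raise KeyError(f"dangling pan-gene reference {pan_gene_id!r}")

    def alignment(self, gene_a: str, gene_b: str) -> SimilarityHit:
        """Pairwise alignment between two stored genes (cached).

        Used for boundary mapping during expansion; computed in the
        sensitive mode with no score cutoff so homologous members always
        yield a map.
        """
        key = tuple(sorted((gene_a, gene_b)))
        if key not in self._aln_cache:
            scheme = ScoringScheme(
                matrix_name=self.config.scheme.matrix_name,
                gap_open=self.config.scheme.gap_open,
                gap_extend=self.config.scheme.gap_extend,
                score_cutoff=1.0,
            )
            self._aln_cache[key] = align_pair(
                self.genes[gene_a], self.genes[gene_b], scheme
            )
        hit = self._aln_cache[key]
        if hit is None:
            raise ValueError(
                f"no alignment between {gene_a!r} and {gene_b!r}"
            )
        return hit


# ---------------------------------------------------------------------------
# stepwise construction
# ---------------------------------------------------------------------------

def _make_table(
    forest: ClusterForest,
    level: str,
    scope_taxid: str,
    columns: Sequence[str],
    column_of,
) -> OrthologTable:
    member_columns: dict[str, str] = {}
    clusters: list[OrthologCluster] = []
    for cluster in forest.clusters:
        cluster.level = level
        cluster.scope_taxid = scope_taxid
        cluster.representative = select_representative(cluster)
        for gid in cluster.member_gene_ids:
            member_columns[gid] = column_of(gid)
        clusters.append(cluster)
    return OrthologTable(
        level=level,
        scope_taxid=scope_taxid,
        columns=tuple(columns),
        clusters=clusters,
        member_columns=member_columns,
    )


def build_hierarchy(
    genomes: Mapping[str, Sequence[GeneRecord]],
    taxonomy: Taxonomy,
    config: PipelineConfig = PipelineConfig(),
    annotate: bool = True,
) -> HierarchicalOrthologyDB:
    """Run the full species -> genus -> standard construction.

    ``genomes`` maps organism ids to their gene records; every organism
    must be present in the taxonomy.  With ``annotate`` the per-column
    conservation ratios of every table are filled in afterwards.
    """
    db = HierarchicalOrthologyDB(taxonomy=taxonomy, config=config)
    known = set(taxonomy.all_organisms())
    for org in genomes:
        if org not in known:
            raise KeyError(f"organism {org!r} missing from taxonomy")
    for org, recs in genomes.items():
        for rec in recs:
            if rec.gene_id in db.genes:
                raise ValueError(f"duplicate gene id {rec.gene_id!r}")
            db.genes[rec.gene_id] = rec

    def register_pangenome(table: OrthologTable) -> list[GeneRecord]:
        pan = build_pangenome(table, db.genes)
        db.pangenomes[table.scope_taxid] = pan
        out = []
        for pan_id, (cid, rec) in sorted(pan.entries.items()):
            db.genes[pan_id] = rec
            seg = representative_segment(table.cluster(cid))
            db.pan_rep[pan_id] = (seg.gene_id, seg.begin, seg.end)
            out.append(rec)
        return out

    def cluster_step(
        records: list[GeneRecord],
        mode: str,
        level: str,
        scope: str,
        columns: Sequence[str],
        column_of,
    ) -> OrthologTable:
        hits = all_vs_all(
            records, mode=mode, scheme=config.scheme, k=config.kmer_k
        )
        forest = build_clusters(
            hits,
            {r.gene_id: r for r in records},
            params=config.cluster,
            level=level,
            scope_taxid=scope,
        )
        flag_members(forest)
        return _make_table(forest, level, scope, columns, column_of)

    # --- species level ----------------------------------------------------
    species_units: dict[str, list[GeneRecord]] = {}
    for sp in taxonomy.species():
        orgs = [o for o in taxonomy.organisms_of(sp) if o in genomes]
        if not orgs:
            continue
        records = [g for o in sorted(orgs) for g in genomes[o]]
        if len(orgs) >= 2:
            table = cluster_step(
                records,
                config.mode_within_species,
                "species",
                sp,
                orgs,
                lambda gid: db.genes[gid].organism_id,
            )
            db.species_tables[sp] = table
            species_units[sp] = register_pangenome(table)
        else:
            species_units[sp] = records

    # --- genus level ------------------------------------------------------
    genus_units: dict[str, list[GeneRecord]] = {}
    for genus in taxonomy.genera():
        sps = [s for s in taxonomy.species_of(genus) if s in species_units]
        if not sps:
            continue
        if len(sps) >= 2:
            records = [g for s in sps for g in species_units[s]]

            def genus_column(gid: str, _genus: str = genus) -> str:
                if is_pan_gene_id(gid):
                    return split_pan_gene_id(gid)[0]
                return taxonomy.species_of_organism(db.genes[gid].organism_id)

            table = cluster_step(
                records,
                config.mode_within_genus,
                "genus",
                genus,
                sps,
                genus_column,
            )
            db.genus_tables[genus] = table
            genus_units[genus] = register_pangenome(table)
        else:
            genus_units[genus] = species_units[sps[0]]

    # --- standard level ---------------------------------------------------
    records = [g for genus in sorted(genus_units) for g in genus_units[genus]]

    def standard_column(gid: str) -> str:
        if is_pan_gene_id(gid):
            taxid = split_pan_gene_id(gid)[0]
            if taxonomy.rank(taxid) == "species":
                return taxonomy.genus_of_species(taxid)
            return taxid
        sp = taxonomy.species_of_organism(db.genes[gid].organism_id)
        return taxonomy.genus_of_species(sp)

    db.standard_table = cluster_step(
        records,
        config.mode_between_genus,
        "standard",
        STANDARD_SCOPE,
        sorted(genus_units),
        standard_column,
    )
    if annotate:
        annotate_conservation(db)
    return db


# ---------------------------------------------------------------------------
# expansion
# ---------------------------------------------------------------------------

def _expand_segment(
    db: HierarchicalOrthologyDB, seg: DomainSegment
) -> list[DomainSegment]:
    """Recursively replace a (possibly pan-gene) segment by raw-gene
    segments, mapping coordinates through representative alignments."""
    gid = seg.gene_id
    if not is_pan_gene_id(gid):
        return [seg]
    cluster = db.source_cluster(gid)
    rep_gid, rb, re_ = db.pan_rep[gid]
    pan_len = re_ - rb + 1
    if seg.begin == 1 and seg.end == pan_len:
        # full-coverage pan member: substitute the source cluster verbatim
        out: list[DomainSegment] = []
        for m in cluster.members:
            out.extend(_expand_segment(db, m))
        return out
    # the higher level assigned only part of the pan-gene: map the
    # sub-span through the representative into every member
    rep_b = rb + seg.begin - 1
    rep_e = rb + seg.end - 1
    out = []
    for m in cluster.members:
        if m.gene_id == rep_gid:
            sub = DomainSegment(m.gene_id, 1, rep_b, rep_e)
        else:
            hit = db.alignment(rep_gid, m.gene_id)
            bmap = boundary_map_from_hit(
                hit, rep_gid, db.genes[m.gene_id].length
            )
            mb = map_boundary(bmap, rep_b)
            me = map_boundary(bmap, rep_e)
            mb = min(max(mb, m.begin), m.end)
            me = min(max(me, m.begin), m.end)
            if me < mb:
                mb, me = me, mb
            sub = DomainSegment(m.gene_id, 1, mb, me)
        if is_pan_gene_id(sub.gene_id):
            out.extend(_expand_segment(db, sub))
        else:
            out.append(sub)
    return out


def _renumber(segments: Iterable[DomainSegment]) -> list[DomainSegment]:
    """Renumber domain indices per gene, left to right."""
    by_gene: dict[str, list[DomainSegment]] = {}
    for seg in segments:
        by_gene.setdefault(seg.gene_id, []).append(seg)
    out: list[DomainSegment] = []
    for gid in sorted(by_gene):
        for idx, seg in enumerate(
            sorted(by_gene[gid], key=lambda s: (s.begin, s.end)), start=1
        ):
            out.append(DomainSegment(gid, idx, seg.begin, seg.end))
    return sorted(out)


def expand_cluster(
    db: HierarchicalOrthologyDB,
    cluster_id: str,
    level: str = "standard",
    scope_taxid: str | None = None,
) -> list[DomainSegment]:
    """All raw-gene segments of one cluster, pan members fully expanded.

    Domain indices are renumbered per raw gene within the result.
    """
    table = db.table_at(level, scope_taxid)
    cluster = table.cluster(cluster_id)
    raw: list[DomainSegment] = []
    for m in cluster.members:
        raw.extend(_expand_segment(db, m))
    return _renumber(raw)


def expand_standard(
    db: HierarchicalOrthologyDB,
) -> dict[str, list[DomainSegment]]:
    """Expand every standard cluster; renumbers indices per raw gene
    across the whole table so each gene's segments are 1..k."""
    if db.standard_table is None:
        raise KeyError("no standard table built")
    raw_pairs: list[tuple[str, DomainSegment]] = []
    for cluster in db.standard_table.clusters:
        for m in cluster.members:
            for seg in _expand_segment(db, m):
                raw_pairs.append((cluster.cluster_id, seg))
    # renumber per gene across all clusters
    by_gene: dict[str, list[tuple[str, DomainSegment]]] = {}
    for cid, seg in raw_pairs:
        by_gene.setdefault(seg.gene_id, []).append((cid, seg))
    out: dict[str, list[DomainSegment]] = {
        c.cluster_id: [] for c in db.standard_table.clusters
    }
    for gid in sorted(by_gene):
        ordered = sorted(by_gene[gid], key=lambda p: (p[1].begin, p[1].end))
        for idx, (cid, seg) in enumerate(ordered, start=1):
            out[cid].append(DomainSegment(gid, idx, seg.begin, seg.end))
    for cid in out:
        out[cid].sort()
    return out


def db_member_flags(db: HierarchicalOrthologyDB) -> dict[str, frozenset[str]]:
    """Union of structural flags per gene across every table."""
    out: dict[str, set[str]] = {}
    tables = list(db.species_tables.values()) + list(db.genus_tables.values())
    if db.standard_table is not None:
        tables.append(db.standard_table)
    for table in tables:
        for cluster in table.clusters:
            for gid, fl in cluster.flags.items():
                out.setdefault(gid, set()).update(fl)
    return {g: frozenset(f) for g, f in out.items()}


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

def save_db(db: HierarchicalOrthologyDB, out_dir) -> None:
    """Write every table, pan-genome FASTA and the config to a directory."""
    from pathlib import Path

    from .io import write_ortholog_table, write_protein_fasta

    out = Path(out_dir)
    (out / "species").mkdir(parents=True, exist_ok=True)
    (out / "genus").mkdir(exist_ok=True)
    (out / "pangenome").mkdir(exist_ok=True)
    for sp, table in db.species_tables.items():
        write_ortholog_table(table, out / "species" / f"{sp}.tsv")
    for genus, table in db.genus_tables.items():
        write_ortholog_table(table, out / "genus" / f"{genus}.tsv")
    if db.standard_table is not None:
        write_ortholog_table(db.standard_table, out / "standard.tsv")
    for taxid, pan in db.pangenomes.items():
        write_protein_fasta(pan.records, out / "pangenome" / f"{taxid}.faa")
    db.config.to_yaml(out / "config.yaml")


def load_db(build_dir, genomes_dir) -> HierarchicalOrthologyDB:
    """Reload a saved build, given the original genome directory
    (per-organism ``<organism>.faa`` plus ``taxonomy.tsv``)."""
    from pathlib import Path

    from .io import read_ortholog_table, read_protein_fasta, read_taxonomy

    build = Path(build_dir)
    gdir = Path(genomes_dir)
    taxonomy = read_taxonomy(gdir / "taxonomy.tsv")
    config_path = build / "config.yaml"
    config = (
        PipelineConfig.from_yaml(config_path)
        if config_path.exists()
        else PipelineConfig()
    )
    db = HierarchicalOrthologyDB(taxonomy=taxonomy, config=config)
    for org in taxonomy.all_organisms():
        fasta = gdir / f"{org}.faa"
        if not fasta.exists():
            continue
        for rec in read_protein_fasta(fasta, org):
            db.genes[rec.gene_id] = rec

    def register(table: OrthologTable) -> None:
        pan = build_pangenome(table, db.genes)
        db.pangenomes[table.scope_taxid] = pan
        for pan_id, (cid, rec) in sorted(pan.entries.items()):
            db.genes[pan_id] = rec
            seg = representative_segment(table.cluster(cid))
            db.pan_rep[pan_id] = (seg.gene_id, seg.begin, seg.end)

    # species before genus: genus pan-genes may reference species pan-genes
    for path in sorted((build / "species").glob("*.tsv")):
        table = read_ortholog_table(path)
        db.species_tables[table.scope_taxid] = table
        register(table)
    for path in sorted((build / "genus").glob("*.tsv")):
        table = read_ortholog_table(path)
        db.genus_tables[table.scope_taxid] = table
        register(table)
    standard = build / "standard.tsv"
    if standard.exists():
        db.standard_table = read_ortholog_table(standard)
    return db


def _column_ratio(
    tax: Taxonomy, orgs_present: set[str], column_taxid: str
) -> float:
    rank = tax.rank(column_taxid)
    if rank == "genus":
        units = tax.species_of(column_taxid)
        unit_of = tax.species_of_organism
    elif rank == "species":
        units = tax.organisms_of(column_taxid)
        unit_of = lambda o: o
    elif rank == "organism":
        units = (column_taxid,)
        unit_of = lambda o: o
    else:
        raise ValueError(f"unsupported column taxon {column_taxid!r}")
    if not units:
        return 0.0
    present_units = {unit_of(o) for o in orgs_present} & set(units)
    return len(present_units) / len(units)


def conservation_ratio(
    db: HierarchicalOrthologyDB,
    level: str,
    cluster_id: str,
    column_taxid: str,
    scope_taxid: str | None = None,
) -> float:
    """Fraction of the column's sub-units possessing the cluster.

    For a genus column the sub-units are its species, for a species
    column its organisms; paralogs within one sub-unit count once.
    """
    segments = expand_cluster(db, cluster_id, level, scope_taxid)
    orgs_present = {db.genes[s.gene_id].organism_id for s in segments}
    return _column_ratio(db.taxonomy, orgs_present, column_taxid)


def annotate_conservation(db: HierarchicalOrthologyDB) -> None:
    """Fill the conservation map of every table in the database."""
    jobs: list[tuple[str, str | None, OrthologTable]] = []
    for sp, t in db.species_tables.items():
        jobs.append(("species", sp, t))
    for g, t in db.genus_tables.items():
        jobs.append(("genus", g, t))
    if db.standard_table is not None:
        jobs.append(("standard", None, db.standard_table))
    for level, scope, table in jobs:
        for cluster in table.clusters:
            segments = expand_cluster(db, cluster.cluster_id, level, scope)
            orgs = {db.genes[s.gene_id].organism_id for s in segments}
            for col in table.columns:
                table.conservation[(cluster.cluster_id, col)] = _column_ratio(
                    db.taxonomy, orgs, col
                )
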