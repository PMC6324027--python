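"""Representative selection, pan-genomes, the stepwise build,
expansion and boundary mapping."""

import random
from collections import Counter

import pytest

from orthohier.clustering import ClusterParams, build_clusters, flag_members
from orthohier.config import PipelineConfig
from orthohier.hierarchy import (
    BoundaryMap,
    build_hierarchy,
    build_pangenome,
    conservation_ratio,
    expand_cluster,
    expand_standard,
    map_boundary,
    select_representative,
)
from orthohier.model import (
    DomainSegment,
    GeneRecord,
    OrthologCluster,
    OrthologTable,
    Taxonomy,
)
from orthohier.similarity import ScoringScheme, all_vs_all
from orthohier.simulate import SimParams, simulate


def make_cluster(lengths, flags=None, level="species"):
    members = tuple(
        DomainSegment(f"g{i}", 1, 1, ln) for i, ln in enumerate(lengths)
    )
    return OrthologCluster(
        cluster_id="00001",
        level=level,
        scope_taxid="sp1",
        members=members,
        flags=flags or {},
    )


class TestRepresentative:
    def test_median_length_member_wins(self):
        c = make_cluster([300, 310, 500])
        assert select_representative(c) == "g1"  # the 310-residue gene

    def test_flagged_member_excluded(self):
        c = make_cluster([300, 310, 500], flags={"g1": frozenset({"fusion"})})
        assert select_representative(c) == "g0"  # closest unflagged to 310

    def test_singleton(self):
        assert select_representative(make_cluster([250])) == "g0"

    def test_all_flagged_falls_back_to_everyone(self):
        c = make_cluster(
            [300, 310],
            flags={"g0": frozenset({"outlier"}), "g1": frozenset({"fission"})},
        )
        # median 305: both are 5 away, lexicographic tie-break -> g0
        assert select_representative(c) == "g0"

    def test_selection_is_stable(self):
        c = make_cluster([100, 120, 140, 160])
        assert select_representative(c) == select_representative(c)


class TestPanGenome:
    def test_naming_and_count(self):
        genes = {
            "a": GeneRecord("a", "o1", "M" * 100),
            "b": GeneRecord("b", "o2", "K" * 100),
            "c": GeneRecord("c", "o1", "V" * 90),
        }
        t = OrthologTable(
            level="species",
            scope_taxid="44249",
            columns=("o1", "o2"),
            clusters=[
                OrthologCluster(
                    "7443", "species", "44249",
                    (DomainSegment("a", 1, 1, 100),
                     DomainSegment("b", 1, 1, 100)),
                    representative="a",
                ),
                OrthologCluster(
                    "7444", "species", "44249",
                    (DomainSegment("c", 1, 1, 90),),
                    representative="c",
                ),
            ],
            member_columns={"a": "o1", "b": "o2", "c": "o1"},
        )
        pan = build_pangenome(t, genes)
        assert sorted(pan.entries) == ["44249:7443", "44249:7444"]
        assert len(pan.entries) == len(t.clusters)

    def test_fusion_representative_emits_only_its_segment(self):
        # the representative's member segment is the second half of the gene
        genes = {"f": GeneRecord("f", "o1", "A" * 50 + "W" * 60)}
        t = OrthologTable(
            level="species",
            scope_taxid="sp1",
            columns=("o1",),
            clusters=[
                OrthologCluster(
                    "00001", "species", "sp1",
                    (DomainSegment("f", 2, 51, 110),),
                    representative="f",
                )
            ],
            member_columns={"f": "o1"},
        )
        pan = build_pangenome(t, genes)
        rec = pan.entries["sp1:00001"][1]
        assert rec.sequence == "W" * 60
        assert rec.length == 60


class TestBoundaryMap:
    def test_identity_alignment(self):
        bmap = BoundaryMap(tuple((i, i) for i in range(1, 101)), 100)
        assert map_boundary(bmap, 57) == 57

    def test_constant_offset(self):
        bmap = BoundaryMap(tuple((i, i + 5) for i in range(10, 21)), 40)
        assert map_boundary(bmap, 13) == 18

    def test_interpolation_rounds_half_up(self):
        bmap = BoundaryMap(((10, 10), (15, 11)), 50)
        assert map_boundary(bmap, 12) == 10  # 10 + round(2 * 1/5)

    def test_extrapolation_clamps(self):
        bmap = BoundaryMap(((10, 5), (20, 15)), 18)
        assert map_boundary(bmap, 3) == 1     # 5 - 7 clamped up
        assert map_boundary(bmap, 30) == 18   # 15 + 10 clamped down

    def test_empty_map_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            BoundaryMap((), 10)

    def test_monotone_and_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            rep_len = rng.randint(20, 120)
            anchors = []
            q = 0
            s = 0
            while True:
                q += rng.randint(1, 4)
                s += rng.randint(1, 4)
                if q > rep_len:
                    break
                anchors.append((q, s))
            if len(anchors) < 2:
                continue
            member_len = anchors[-1][1] + rng.randint(0, 10)
            bmap = BoundaryMap(tuple(anchors), member_len)

            def oracle(pos):
                import math
                for p, qq in anchors:
                    if p == pos:
                        return min(max(qq, 1), member_len)
                if pos < anchors[0][0]:
                    v = anchors[0][1] - (anchors[0][0] - pos)
                elif pos > anchors[-1][0]:
                    v = anchors[-1][1] + (pos - anchors[-1][0])
                else:
                    left = max(a for a in anchors if a[0] < pos)
                    right = min(a for a in anchors if a[0] > pos)
                    v = left[1] + math.floor(
                        (pos - left[0]) * (right[1] - left[1])
                        / (right[0] - left[0]) + 0.5
                    )
                return min(max(v, 1), member_len)

            prev = None
            for pos in range(1, rep_len + 1):
                got = map_boundary(bmap, pos)
                assert got == oracle(pos)
                if prev is not None:
                    assert got >= prev
                prev = got


def lossless_check(result, expanded):
    """Every residue of every input gene appears in exactly one expanded
    standard-cluster segment, with contiguous per-gene coverage."""
    coverage_want = {}
    for recs in result.genomes.values():
        for r in recs:
            coverage_want[r.gene_id] = r.length
    coverage_got = {}
    for segs in expanded.values():
        for s in segs:
            coverage_got.setdefault(s.gene_id, []).append((s.begin, s.end))
    assert set(coverage_want) == set(coverage_got)
    for gid, spans in coverage_got.items():
        spans.sort()
        assert spans[0][0] == 1
        assert spans[-1][1] == coverage_want[gid]
        for (b1, e1), (b2, e2) in zip(spans, spans[1:]):
            assert b2 == e1 + 1


class TestBuildHierarchy:
    def test_small_build_recovers_families_and_loses_nothing(self):
        res = simulate(SimParams(taxonomy=(2, 2, 2), n_families=20, seed=42))
        db = build_hierarchy(res.genomes, res.taxonomy, annotate=False)
        assert db.species_tables and db.genus_tables
        expanded = expand_standard(db)
        lossless_check(res, expanded)
        fam = {g: segs[0][0] for g, segs in res.truth.assignments.items()}
        for segs in expanded.values():
            assert len({fam[s.gene_id] for s in segs}) == 1

    def test_duplicate_genomes_collapse(self):
        res = simulate(
            SimParams(
                taxonomy=[[1]], n_families=12, p_loss=0.0, p_dup=0.0, seed=3
            )
        )
        (org,) = res.genomes
        twin = [
            GeneRecord(r.gene_id.replace("n01", "n02"), f"{org[:-3]}n02",
                       r.sequence)
            for r in res.genomes[org]
        ]
        genomes = {org: res.genomes[org], f"{org[:-3]}n02": twin}
        tax = Taxonomy.from_rows(
            [(o, "g01s01", "g01") for o in genomes]
        )
        db = build_hierarchy(genomes, tax, annotate=False)
        pan = db.pangenomes["g01s01"]
        assert len(pan.entries) == len(res.genomes[org])

    def test_organism_missing_from_taxonomy_is_error(self):
        res = simulate(SimParams(taxonomy=(1, 1, 2), n_families=5, seed=0))
        tax = Taxonomy.from_rows([("other", "sp", "ge")])
        with pytest.raises(KeyError, match="missing from taxonomy"):
            build_hierarchy(res.genomes, tax)

    def test_degenerate_hierarchy_equals_flat_clustering(self):
        res = simulate(
            SimParams(taxonomy=(3, 1, 1), n_families=15, seed=9)
        )
        config = PipelineConfig()
        db = build_hierarchy(res.genomes, res.taxonomy, config,
                             annotate=False)
        expanded = expand_standard(db)
        hier = {
            frozenset((s.gene_id, s.begin, s.end) for s in segs)
            for segs in expanded.values()
        }
        genes = [g for org in sorted(res.genomes) for g in res.genomes[org]]
        hits = all_vs_all(genes, mode="sensitive", scheme=config.scheme)
        forest = build_clusters(hits, genes, config.cluster)
        flat = {
            frozenset((m.gene_id, m.begin, m.end) for m in c.members)
            for c in forest.clusters
        }
        assert hier == flat

    def test_expansion_of_unknown_cluster_is_error(self):
        res = simulate(SimParams(taxonomy=(2, 1, 1), n_families=5, seed=0))
        db = build_hierarchy(res.genomes, res.taxonomy, annotate=False)
        with pytest.raises(KeyError):
            expand_cluster(db, "99999", "standard")

    def test_single_level_expansion_counts(self):
        res = simulate(
            SimParams(taxonomy=(1, 1, 3), n_families=8,
                      p_loss=0.0, p_dup=0.0, seed=4)
        )
        db = build_hierarchy(res.genomes, res.taxonomy, annotate=False)
        # one genus, one species: standard clusters hold species pan-genes
        for cluster in db.standard_table.clusters:
            segs = expand_cluster(db, cluster.cluster_id, "standard")
            assert len(segs) == 3  # one member per genome


class TestConservation:
    def _controlled_db(self):
        # 1 genus x 4 species x 1 genome, no randomness in gene content
        res = simulate(
            SimParams(
                taxonomy=(1, 4, 1), n_families=6,
                p_loss=0.0, p_dup=0.0, seed=8,
            )
        )
        genomes = {o: list(r) for o, r in res.genomes.items()}
        # remove family fam0001 from species 3 and 4
        fam1 = {
            g for g, segs in res.truth.assignments.items()
            if segs[0][0] == "fam0001"
        }
        for org in list(genomes):
            if org.startswith(("g01s03", "g01s04")):
                genomes[org] = [
                    r for r in genomes[org] if r.gene_id not in fam1
                ]
        # add a paralog of fam0001 in species 1
        donor = next(
            r for r in genomes["g01s01n01"] if r.gene_id in fam1
        )
        genomes["g01s01n01"].append(
            GeneRecord(donor.gene_id + "p", donor.organism_id, donor.sequence)
        )
        db = build_hierarchy(genomes, res.taxonomy, annotate=False)
        target = None
        for c in db.standard_table.clusters:
            segs = expand_cluster(db, c.cluster_id, "standard")
            if any(s.gene_id in fam1 for s in segs):
                target = c.cluster_id
        return db, target

    def test_ratio_counts_species_once(self):
        db, target = self._controlled_db()
        # fam0001 is in 2 of 4 species; the paralog must not inflate it
        assert conservation_ratio(db, "standard", target, "g01") == 0.5

    def test_full_presence_is_one(self):
        db, target = self._controlled_db()
        other = next(
            c.cluster_id
            for c in db.standard_table.clusters
            if c.cluster_id != target
        )
        assert conservation_ratio(db, "standard", other, "g01") == 1.0
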