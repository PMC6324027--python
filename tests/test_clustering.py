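"""Domain-aware clustering: partitions, splitting, member flags."""

import random

import networkx as nx
import pytest

from orthohier.clustering import ClusterParams, build_clusters, flag_members
from orthohier.model import GeneRecord
from orthohier.similarity import ScoringScheme, all_vs_all

from conftest import gene_family, mutate, random_protein


def cluster_gene_sets(forest):
    """Partition of gene ids (ignoring segmentation) for comparisons."""
    return {
        frozenset(c.member_gene_ids) for c in forest.clusters
    }


def params(**kw):
    defaults = dict(score_cutoff=60.0, min_domain_len=30)
    defaults.update(kw)
    return ClusterParams(**defaults)


@pytest.fixture
def scheme():
    return ScoringScheme(score_cutoff=60.0)


class TestBasicClustering:
    def test_one_hit_makes_one_two_member_cluster(self, rng, scheme):
        root = random_protein(rng, 100)
        genes = [
            GeneRecord("a", "o1", root),
            GeneRecord("b", "o2", mutate(rng, root, 3)),
        ]
        hits = all_vs_all(genes, mode="sensitive", scheme=scheme)
        assert len(hits) == 1
        forest = build_clusters(hits, genes, params())
        assert len(forest.clusters) == 1
        members = forest.clusters[0].members
        assert [(m.gene_id, m.domain_index, m.begin, m.end) for m in members] \
            == [("a", 1, 1, 100), ("b", 1, 1, 100)]

    def test_singletons_are_kept(self, rng, scheme):
        genes = [
            GeneRecord("a", "o", random_protein(rng, 80)),
            GeneRecord("b", "o", random_protein(rng, 80)),
        ]
        forest = build_clusters([], genes, params())
        assert cluster_gene_sets(forest) == {frozenset("a"), frozenset("b")}

    def test_unknown_gene_in_hits_is_error(self, rng, scheme):
        root = random_protein(rng, 100)
        genes = [GeneRecord("a", "o", root), GeneRecord("b", "o", root)]
        hits = all_vs_all(genes, mode="sensitive", scheme=scheme)
        with pytest.raises(KeyError, match="b"):
            build_clusters(hits, genes[:1], params())

    def test_single_linkage_equals_connected_components(self, rng, scheme):
        for trial in range(10):
            genes = []
            for f in range(rng.randint(2, 6)):
                genes.extend(
                    gene_family(
                        rng, f"f{f}",
                        [f"o{i}" for i in range(rng.randint(1, 4))],
                        length=rng.randint(70, 130),
                    )
                )
            hits = all_vs_all(genes, mode="sensitive", scheme=scheme)
            forest = build_clusters(
                hits, genes, params(linkage="single", split_domains=False)
            )
            graph = nx.Graph()
            graph.add_nodes_from(g.gene_id for g in genes)
            graph.add_edges_from(
                (h.query_id, h.subject_id)
                for h in hits
                if h.raw_score >= 60.0
            )
            expected = {
                frozenset(comp) for comp in nx.connected_components(graph)
            }
            assert cluster_gene_sets(forest) == expected

    def test_coverage_partition_no_overlap(self, rng, scheme):
        genes = gene_family(rng, "f", ["o1", "o2", "o3"], length=100)
        hits = all_vs_all(genes, mode="sensitive", scheme=scheme)
        forest = build_clusters(hits, genes, params())
        seen = {}
        for c in forest.clusters:
            for m in c.members:
                seen.setdefault(m.gene_id, []).append(m)
        for gid, segs in seen.items():
            assert tuple(sorted(segs)) == forest.gene_decomposition[gid]
            segs = sorted(segs, key=lambda s: s.begin)
            for s1, s2 in zip(segs, segs[1:]):
                assert s1.end < s2.begin

    def test_raising_cutoff_only_refines(self, rng):
        genes = []
        for f in range(4):
            genes.extend(gene_family(rng, f"f{f}", ["o1", "o2", "o3"],
                                     length=90, n_sub=12))
        scheme = ScoringScheme(score_cutoff=40.0)
        hits = all_vs_all(genes, mode="sensitive", scheme=scheme)
        low = build_clusters(
            hits, genes, params(score_cutoff=60, split_domains=False)
        )
        high = build_clusters(
            hits, genes, params(score_cutoff=200, split_domains=False)
        )
        coarse = cluster_gene_sets(low)
        for fine_set in cluster_gene_sets(high):
            assert any(fine_set <= c for c in coarse)


class TestDomainSplitting:
    def _fusion_setup(self, rng):
        """Families X and Y plus a gene that is an X-half + Y-half fusion."""
        orgs = ["o1", "o2", "o3"]
        fam_x = gene_family(rng, "x", orgs, length=120)
        fam_y = gene_family(rng, "y", orgs, length=140)
        fusion = GeneRecord(
            "o4_fus", "o4", fam_x[0].sequence + fam_y[0].sequence
        )
        return fam_x, fam_y, fusion

    def test_fusion_gene_splits_into_both_families(self, rng, scheme):
        fam_x, fam_y, fusion = self._fusion_setup(rng)
        genes = fam_x + fam_y + [fusion]
        hits = all_vs_all(genes, mode="sensitive", scheme=scheme)
        forest = build_clusters(hits, genes, params())
        segs = forest.gene_decomposition["o4_fus"]
        assert len(segs) == 2
        assert segs[0].begin == 1 and segs[1].end == fusion.length
        assert segs[0].end + 1 == segs[1].begin
        membership = forest.membership()
        cx = {membership[s] for s in forest.gene_decomposition["o1_x"]}
        cy = {membership[s] for s in forest.gene_decomposition["o1_y"]}
        assert membership[segs[0]] in cx
        assert membership[segs[1]] in cy

    def test_fusion_flag_on_both_segments(self, rng, scheme):
        fam_x, fam_y, fusion = self._fusion_setup(rng)
        genes = fam_x + fam_y + [fusion]
        hits = all_vs_all(genes, mode="sensitive", scheme=scheme)
        forest = flag_members(build_clusters(hits, genes, params()))
        flagged = [
            c for c in forest.clusters if "fusion" in c.gene_flags("o4_fus")
        ]
        assert len(flagged) == 2  # the X cluster and the Y cluster

    def test_near_identical_cluster_has_no_flags(self, rng, scheme):
        genes = gene_family(rng, "f", ["o1", "o2", "o3", "o4"], length=100)
        hits = all_vs_all(genes, mode="sensitive", scheme=scheme)
        forest = flag_members(build_clusters(hits, genes, params()))
        assert len(forest.clusters) == 1
        assert forest.clusters[0].flags == {}


class TestFlags:
    def test_outlier_attachment_height_vs_tree_walk_oracle(self, rng, scheme):
        root = random_protein(rng, 150)
        genes = [
            GeneRecord("a", "o1", root),
            GeneRecord("b", "o2", mutate(rng, root, 2)),
            GeneRecord("c", "o3", mutate(rng, root, 3)),
            GeneRecord("d", "o4", mutate(rng, root, 60)),  # far outlier
        ]
        hits = all_vs_all(genes, mode="sensitive", scheme=scheme)
        forest = flag_members(build_clusters(hits, genes, params()))
        (cluster,) = forest.clusters
        assert cluster.gene_flags("d") == {"outlier"}
        assert cluster.gene_flags("a") == frozenset()

        # independent recursive walk over the member tree
        def walk(node, parent_height, acc):
            if node.leaf is not None:
                acc[node.leaf.gene_id] = parent_height
            else:
                for child in node.children:
                    walk(child, node.height, acc)

        heights = {}
        walk(cluster.member_tree, 0.0, heights)
        import statistics

        med = statistics.median(heights.values())
        for gid, h in heights.items():
            expected = h > 3.0 * med
            assert ("outlier" in cluster.gene_flags(gid)) is expected

    def test_fission_fragment_flagged(self, rng, scheme):
        root = random_protein(rng, 300)
        genes = [
            GeneRecord("a", "o1", root),
            GeneRecord("b", "o2", mutate(rng, root, 3)),
            GeneRecord("c", "o3", mutate(rng, root, 3)),
            # organism o4 carries two complementary fragments
            GeneRecord("d1", "o4", root[:120]),
            GeneRecord("d2", "o4", mutate(rng, root[120:], 2)),
        ]
        hits = all_vs_all(genes, mode="sensitive", scheme=scheme)
        forest = flag_members(build_clusters(hits, genes, params()))
        (cluster,) = forest.clusters
        assert "fission" in cluster.gene_flags("d1")
        assert cluster.gene_flags("a") == frozenset()

    def test_deterministic_rerun(self, rng, scheme):
        genes = []
        for f in range(3):
            genes.extend(gene_family(rng, f"f{f}", ["o1", "o2"], length=80))
        hits = all_vs_all(genes, mode="sensitive", scheme=scheme)
        f1 = flag_members(build_clusters(hits, genes, params()))
        f2 = flag_members(build_clusters(hits, genes, params()))
        assert [c.members for c in f1.clusters] == [c.members for c in f2.clusters]
        assert [c.flags for c in f1.clusters] == [c.flags for c in f2.clusters]
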