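"""Domain-aware hierarchical ortholog clustering.

Genes are first decomposed into domain segments: when a gene's hits
fall into two (or more) regions that barely overlap -- each at least
``min_domain_len`` residues, pairwise overlap below it -- the gene is
split and each segment clusters independently.  This is what lets a
fusion gene place its halves into two different ortholog groups.

Segments are then clustered agglomeratively on the pairwise alignment
score graph (average linkage by default, single linkage available),
stopping when the best between-cluster average drops below
``score_cutoff``.  Every merge is recorded in a member tree whose node
heights are average alignment dissimilarities (1 - identity); the tree
drives outlier detection.  Tie-breaking is lexicographic throughout, so
output is deterministic for a fixed input.

Member flags:

* ``fusion``  -- the gene has segments in two or more clusters;
* ``fission`` -- the segment is much shorter than the cluster median
  while another gene of the same organism in the same cluster covers a
  complementary part of the family;
* ``outlier`` -- the member attaches to the member tree far above the
  cluster's median attachment height.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import DomainSegment, GeneRecord, OrthologCluster
from .similarity import SimilarityHit, hit_lookup


@dataclass(frozen=True)
class ClusterParams:
    score_cutoff: float = 100.0
    min_domain_len: int = 50
    split_score_margin: float = 0.0
    linkage: str = "average"
    split_domains: bool = True
    outlier_factor: float = 3.0
    fission_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.linkage not in ("average", "single"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.min_domain_len < 1:
            raise ValueError("min_domain_len must be >= 1")


@dataclass(frozen=True)
class MemberTreeNode:
    """Rooted binary merge tree; heights are average dissimilarities."""

    height: float
    children: tuple["MemberTreeNode", ...] = ()
    leaf: DomainSegment | None = None

    def leaves(self) -> list[DomainSegment]:
        if self.leaf is not None:
            return [self.leaf]
        out: list[DomainSegment] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def attachment_heights(self) -> dict[DomainSegment, float]:
        """Height of the internal node at which each leaf joins."""
        out: dict[DomainSegment, float] = {}

        def walk(node: "MemberTreeNode") -> None:
            if node.leaf is not None:
                out[node.leaf] = 0.0
                return
            for child in node.children:
                if child.leaf is not None:
                    out[child.leaf] = node.height
                else:
                    walk(child)

        walk(self)
        return out


@dataclass
class ClusterForest:
    """Clustering result: clusters plus each gene's segment decomposition."""

    clusters: list[OrthologCluster]
    gene_decomposition: dict[str, tuple[DomainSegment, ...]]
    hits: dict[tuple[str, str], SimilarityHit] = field(
        default_factory=dict, compare=False, repr=False
    )
    genes: dict[str, GeneRecord] = field(
        default_factory=dict, compare=False, repr=False
    )
    params: ClusterParams = field(default_factory=ClusterParams, compare=False)

    def cluster_of(self, segment: DomainSegment) -> OrthologCluster:
        for cluster in self.clusters:
            if segment in cluster.members:
                return cluster
        raise KeyError(f"segment {segment} not in any cluster")

    def membership(self) -> dict[DomainSegment, str]:
        return {
            seg: c.cluster_id for c in self.clusters for seg in c.members
        }


# ---------------------------------------------------------------------------
# Domain decomposition
# ---------------------------------------------------------------------------

def _group_spans(
    spans: Sequence[tuple[int, int]], min_domain_len: int
) -> list[tuple[int, int]]:
    """Single-linkage grouping of hit spans; spans overlapping by at
    least ``min_domain_len`` residues share a group.  Returns the group
    union spans sorted by begin."""
    groups: list[tuple[int, int]] = []
    for b, e in sorted(spans):
        if groups:
            gb, ge_ = groups[-1]
            if min(ge_, e) - b + 1 >= min_domain_len:
                groups[-1] = (gb, max(ge_, e))
                continue
        groups.append((b, e))
    return groups


def _decompose_gene(
    gene: GeneRecord,
    spans: Sequence[tuple[int, int]],
    min_domain_len: int,
) -> tuple[DomainSegment, ...]:
    """Split a gene into domains if its hit spans form >= 2 well-separated
    groups, each at least ``min_domain_len`` long; otherwise one
    full-length segment.  Splitting extends the outer segments to the
    gene ends and cuts between groups at the midpoint, rounding the
    boundary residue toward the longer segment."""
    length = gene.length
    full = (DomainSegment(gene.gene_id, 1, 1, length),)
    if not spans:
        return full
    groups = [
        g
        for g in _group_spans(spans, min_domain_len)
        if g[1] - g[0] + 1 >= min_domain_len
    ]
    if len(groups) < 2:
        return full
    cuts: list[int] = []
    for (b1, e1), (b2, e2) in zip(groups, groups[1:]):
        len1 = e1 - b1 + 1
        len2 = e2 - b2 + 1
        lo = min(e1, b2 - 1)
        hi = max(e1, b2 - 1)
        cut = (lo + hi + 1) // 2 if len1 >= len2 else (lo + hi) // 2
        cuts.append(min(max(cut, 1), length - 1))
    bounds = [1] + [c + 1 for c in cuts] + [length + 1]
    return tuple(
        DomainSegment(gene.gene_id, i + 1, bounds[i], bounds[i + 1] - 1)
        for i in range(len(groups))
    )


def _segment_for(
    segments: Sequence[DomainSegment], span: tuple[int, int]
) -> DomainSegment:
    """Segment with the largest overlap with ``span`` (ties -> leftmost)."""
    best = segments[0]
    best_ov = -1
    for seg in segments:
        ov = min(seg.end, span[1]) - max(seg.begin, span[0]) + 1
        if ov > best_ov:
            best_ov = ov
            best = seg
    return best


# ---------------------------------------------------------------------------
# Agglomerative clustering
# ---------------------------------------------------------------------------

def build_clusters(
    hits: Iterable[SimilarityHit],
    genes: Mapping[str, GeneRecord] | Sequence[GeneRecord],
    params: ClusterParams = ClusterParams(),
    level: str = "species",
    scope_taxid: str = "",
) -> ClusterForest:
    """Cluster genes (as domain segments) from a similarity hit set.

    Every gene appears somewhere in the result, singletons included.
    """
    if not isinstance(genes, Mapping):
        genes = {g.gene_id: g for g in genes}
    hits = list(hits)
    for h in hits:
        for gid in (h.query_id, h.subject_id):
            if gid not in genes:
                raise KeyError(f"hit references unknown gene {gid!r}")
    lookup = hit_lookup(hits)
    strong = [
        h
        for h in lookup.values()
        if h.raw_score >= params.score_cutoff + params.split_score_margin
    ]

    # 1. domain decomposition per gene
    spans_by_gene: dict[str, list[tuple[int, int]]] = {g: [] for g in genes}
    if params.split_domains:
        for h in strong:
            spans_by_gene[h.query_id].append(h.query_span)
            spans_by_gene[h.subject_id].append(h.subject_span)
    decomposition = {
        gid: _decompose_gene(genes[gid], spans_by_gene[gid], params.min_domain_len)
        for gid in sorted(genes)
    }

    # 2. clustering units = segments, sorted for deterministic tie-breaking
    units: list[DomainSegment] = [
        seg for gid in sorted(decomposition) for seg in decomposition[gid]
    ]
    index = {seg: i for i, seg in enumerate(units)}
    n = len(units)

    score = np.zeros((n, n), dtype=np.float64)
    ident = np.zeros((n, n), dtype=np.float64)
    for h in lookup.values():
        qseg = _segment_for(decomposition[h.query_id], h.query_span)
        sseg = _segment_for(decomposition[h.subject_id], h.subject_span)
        i, j = index[qseg], index[sseg]
        if i == j:
            continue
        if h.raw_score > score[i, j]:
            score[i, j] = score[j, i] = h.raw_score
            ident[i, j] = ident[j, i] = h.identity

    clusters, trees = _agglomerate(units, score, ident, params)

    ordered = sorted(range(len(clusters)), key=lambda c: min(clusters[c]))
    out: list[OrthologCluster] = []
    for rank, ci in enumerate(ordered, start=1):
        members = tuple(sorted(clusters[ci]))
        out.append(
            OrthologCluster(
                cluster_id=f"{rank:05d}",
                level=level,
                scope_taxid=scope_taxid,
                members=members,
                member_tree=trees[ci],
            )
        )
    return ClusterForest(
        clusters=out,
        gene_decomposition=decomposition,
        hits=lookup,
        genes=dict(genes),
        params=params,
    )


def _agglomerate(
    units: Sequence[DomainSegment],
    score: np.ndarray,
    ident: np.ndarray,
    params: ClusterParams,
) -> tuple[list[list[DomainSegment]], list[MemberTreeNode]]:
    n = len(units)
    members: dict[int, list[DomainSegment]] = {
        i: [units[i]] for i in range(n)
    }
    trees: dict[int, MemberTreeNode] = {
        i: MemberTreeNode(height=0.0, leaf=units[i]) for i in range(n)
    }
    sizes = np.ones(n, dtype=np.float64)
    active = np.ones(n, dtype=bool)
    S = score.copy()
    I = ident.copy()
    np.fill_diagonal(S, -np.inf)

    while len(members) > 1:
        masked = np.where(active[:, None] & active[None, :], S, -np.inf)
        flat = int(np.argmax(masked))
        i, j = divmod(flat, n)
        best = masked[i, j]
        if best < params.score_cutoff:
            break
        if j < i:
            i, j = j, i
        height = max(0.0, 1.0 - float(I[i, j]))
        trees[i] = MemberTreeNode(height=height, children=(trees[i], trees[j]))
        members[i].extend(members.pop(j))
        del trees[j]
        if params.linkage == "average":
            wi, wj = sizes[i], sizes[j]
            S[i, :] = (wi * S[i, :] + wj * S[j, :]) / (wi + wj)
            I[i, :] = (wi * I[i, :] + wj * I[j, :]) / (wi + wj)
        else:  # single linkage: similarity version takes the max
            S[i, :] = np.maximum(S[i, :], S[j, :])
            I[i, :] = np.maximum(I[i, :], I[j, :])
        S[:, i] = S[i, :]
        I[:, i] = I[i, :]
        S[i, i] = -np.inf
        sizes[i] += sizes[j]
        active[j] = False

    keys = sorted(members)
    return [members[k] for k in keys], [trees[k] for k in keys]


# ---------------------------------------------------------------------------
# Member flags
# ---------------------------------------------------------------------------

def flag_members(forest: ClusterForest) -> ClusterForest:
    """Annotate fusion/fission/outlier members in place (and return)."""
    params = forest.params
    segment_cluster = forest.membership()

    # fusion: segments of one gene land in >= 2 clusters
    gene_clusters: dict[str, set[str]] = {}
    for seg, cid in segment_cluster.items():
        gene_clusters.setdefault(seg.gene_id, set()).add(cid)
    fused = {g for g, cs in gene_clusters.items() if len(cs) > 1}

    for cluster in forest.clusters:
        flags: dict[str, set[str]] = {}
        for gid in cluster.member_gene_ids:
            if gid in fused:
                flags.setdefault(gid, set()).add("fusion")
        _flag_fission(forest, cluster, flags, params)
        _flag_outliers(cluster, flags, params)
        cluster.flags = {g: frozenset(f) for g, f in flags.items()}
    return forest


def _flag_fission(
    forest: ClusterForest,
    cluster: OrthologCluster,
    flags: dict[str, set[str]],
    params: ClusterParams,
) -> None:
    if len(cluster.members) < 2:
        return
    med = cluster.median_member_length()
    ref = max(cluster.members, key=lambda m: (m.length, m.gene_id))

    def ref_span(gene_id: str) -> tuple[int, int] | None:
        if gene_id == ref.gene_id:
            return None
        hit = forest.hits.get(tuple(sorted((gene_id, ref.gene_id))))
        if hit is None:
            return None
        return (
            hit.subject_span if hit.query_id == gene_id else hit.query_span
        )

    for seg in cluster.members:
        if seg.gene_id == ref.gene_id or seg.length >= params.fission_fraction * med:
            continue
        span_s = ref_span(seg.gene_id)
        if span_s is None:
            continue
        for other in cluster.members:
            if other.gene_id in (seg.gene_id, ref.gene_id):
                continue
            org_s = forest.genes[seg.gene_id].organism_id
            if forest.genes[other.gene_id].organism_id != org_s:
                continue
            span_o = ref_span(other.gene_id)
            if span_o is None:
                continue
            overlap = min(span_s[1], span_o[1]) - max(span_s[0], span_o[0]) + 1
            if overlap < params.min_domain_len:
                flags.setdefault(seg.gene_id, set()).add("fission")
                break


def _flag_outliers(
    cluster: OrthologCluster,
    flags: dict[str, set[str]],
    params: ClusterParams,
) -> None:
    if cluster.member_tree is None or len(cluster.members) < 3:
        return
    heights = cluster.member_tree.attachment_heights()
    values = [heights[m] for m in cluster.members if m in heights]
    if not values:
        return
    med = statistics.median(values)
    # identical siblings give a zero median; fall back to an absolute
    # dissimilarity floor so a single substitution is not an "outlier"
    threshold = params.outlier_factor * med if med > 0 else 0.05
    for seg in cluster.members:
        h = heights.get(seg, 0.0)
        if h > threshold:
            flags.setdefault(seg.gene_id, set()).add("outlier")
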