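"""Core-gene extraction and concatenated-alignment phylogeny.

From an expanded ortholog table, the conserved core is the set of
clusters present in (nearly) all organisms, optionally restricted to
one-to-one clusters (no paralogs in any organism).  Very sparse tables
-- typical for taxonomically broad scopes -- may leave too few core
genes; in that case organisms contributing fewest widely conserved
genes are eliminated one at a time until the near-universal one-to-one
core reaches a floor.

Each core cluster is aligned with a built-in progressive aligner
(guide tree from pairwise global alignment distances, profile-profile
Gotoh steps under the pipeline's scoring scheme), blocks are
concatenated in cluster-id order, and a neighbor-joining tree is built
from Poisson-corrected alignment distances.  The whole path is
deterministic, so a build can be reproduced byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from skbio.tree import nj

from ._kernels import nw_align_scored
from .io import write_newick
from .similarity import ScoringScheme, _matrix, encode

GAP = "-"


@dataclass(frozen=True)
class CoreGeneSet:
    cluster_ids: tuple[str, ...]
    organisms: tuple[str, ...]
    one_to_one: dict[str, bool]


@dataclass
class ConcatenatedAlignment:
    organisms: tuple[str, ...]
    blocks: tuple[tuple[str, int], ...]  # (cluster_id, width), in order
    rows: dict[str, str]

    def __post_init__(self) -> None:
        width = self.width
        for org in self.organisms:
            if len(self.rows[org]) != width:
                raise ValueError(f"row {org} length != alignment width")

    @property
    def width(self) -> int:
        return sum(w for _, w in self.blocks)


@dataclass(frozen=True)
class EliminationResult:
    retained: tuple[str, ...]
    removed: tuple[str, ...]  # in removal order
    core_count: int


# ---------------------------------------------------------------------------
# core extraction
# ---------------------------------------------------------------------------

def organism_presence(
    expanded: Mapping[str, Sequence], gene_organism: Mapping[str, str]
) -> pd.DataFrame:
    """Cluster x organism matrix of distinct member-gene counts."""
    orgs = sorted(set(gene_organism.values()))
    data = pd.DataFrame(
        0, index=sorted(expanded), columns=orgs, dtype=int
    )
    for cid, segs in expanded.items():
        genes_by_org: dict[str, set[str]] = {}
        for seg in segs:
            org = gene_organism[seg.gene_id]
            genes_by_org.setdefault(org, set()).add(seg.gene_id)
        for org, genes in genes_by_org.items():
            data.loc[cid, org] = len(genes)
    return data


def extract_core(
    presence: pd.DataFrame,
    core_frac: float = 1.0,
    require_one_to_one: bool = True,
) -> CoreGeneSet:
    """Clusters present in >= ``core_frac`` of organisms.

    With ``require_one_to_one`` a cluster is rejected if any organism
    holds more than one member (paralogs).
    """
    n = presence.shape[1]
    present = presence >= 1
    frac = present.sum(axis=1) / max(n, 1)
    keep = frac >= core_frac - 1e-12
    one2one = (presence <= 1).all(axis=1)
    if require_one_to_one:
        keep = keep & one2one
    ids = tuple(sorted(presence.index[keep]))
    return CoreGeneSet(
        cluster_ids=ids,
        organisms=tuple(presence.columns),
        one_to_one={cid: bool(one2one[cid]) for cid in ids},
    )


def eliminate_sparse_organisms(
    presence: pd.DataFrame,
    min_core: int = 50,
    core_frac: float = 0.99,
    elim_frac: float = 0.90,
    min_organisms: int = 4,
) -> EliminationResult:
    """Greedily drop organisms until the near-universal core is large enough.

    At each step the one-to-one clusters present in >= ``core_frac`` of
    the remaining organisms are counted; if fewer than ``min_core``, the
    organism possessing the fewest clusters conserved in >= ``elim_frac``
    of the remaining organisms is removed (ties: lexicographically last
    id).  Raises if the floor of ``min_organisms`` organisms would be
    crossed before reaching ``min_core``.
    """
    if presence.shape[1] < 2:
        raise ValueError("need at least two organisms")
    current = sorted(presence.columns)
    removed: list[str] = []

    def core_count(cols: list[str]) -> int:
        sub = presence[cols]
        frac = (sub >= 1).sum(axis=1) / len(cols)
        one2one = (sub <= 1).all(axis=1)
        return int(((frac >= core_frac - 1e-12) & one2one).sum())

    while True:
        core = core_count(current)
        if core >= min_core:
            return EliminationResult(tuple(current), tuple(removed), core)
        if len(current) <= min_organisms:
            raise ValueError(
                f"cannot reach {min_core} core genes with >= {min_organisms} "
                f"organisms (final core count {core})"
            )
        sub = presence[current]
        conserved = (sub >= 1).sum(axis=1) / len(current) >= elim_frac - 1e-12
        scores = (sub.loc[conserved] >= 1).sum(axis=0)
        worst = scores.min()
        victim = max(o for o in current if scores[o] == worst)
        current.remove(victim)
        removed.append(victim)


# ---------------------------------------------------------------------------
# progressive multiple alignment
# ---------------------------------------------------------------------------

def _profile(rows: list[str], sub_dim: int, index: Mapping[str, int]) -> np.ndarray:
    """Column residue-frequency matrix (gaps contribute nothing)."""
    width = len(rows[0])
    prof = np.zeros((width, sub_dim), dtype=np.float64)
    for row in rows:
        for j, ch in enumerate(row):
            if ch != GAP:
                prof[j, index[ch]] += 1.0
    return prof / len(rows)


def _merge_alignments(
    a_rows: list[str],
    b_rows: list[str],
    scheme: ScoringScheme,
) -> list[str]:
    alphabet, sub = _matrix(scheme.matrix_name)
    index = {c: i for i, c in enumerate(alphabet)}
    pa = _profile(a_rows, len(alphabet), index)
    pb = _profile(b_rows, len(alphabet), index)
    S = pa @ sub.astype(np.float64) @ pb.T
    _, acols, bcols = nw_align_scored(S, scheme.gap_open, scheme.gap_extend)
    out_a = ["" for _ in a_rows]
    out_b = ["" for _ in b_rows]
    for ac, bc in zip(acols, bcols):
        for i, row in enumerate(a_rows):
            out_a[i] += row[ac] if ac >= 0 else GAP
        for i, row in enumerate(b_rows):
            out_b[i] += row[bc] if bc >= 0 else GAP
    return out_a + out_b


def _pairwise_identity(
    seq_a: str, seq_b: str, scheme: ScoringScheme
) -> float:
    _, sub = _matrix(scheme.matrix_name)
    a = encode(seq_a, scheme.matrix_name).astype(np.int64)
    b = encode(seq_b, scheme.matrix_name).astype(np.int64)
    S = sub[np.ix_(a, b)].astype(np.float64)
    _, acols, bcols = nw_align_scored(S, scheme.gap_open, scheme.gap_extend)
    pairs = [(x, y) for x, y in zip(acols, bcols) if x >= 0 and y >= 0]
    if not pairs:
        return 0.0
    matches = sum(1 for x, y in pairs if seq_a[x] == seq_b[y])
    return matches / len(pairs)


def progressive_msa(
    sequences: Mapping[str, str], scheme: ScoringScheme = ScoringScheme()
) -> dict[str, str]:
    """Progressive multiple alignment under the pipeline scoring scheme.

    The guide tree is average-linkage over pairwise global-alignment
    distances (1 - identity); profiles are merged bottom-up with a
    profile-profile Gotoh step.  For two sequences this is exactly the
    optimal pairwise global alignment.
    """
    ids = sorted(sequences)
    if not ids:
        raise ValueError("no sequences to align")
    if len(ids) == 1:
        return {ids[0]: sequences[ids[0]]}
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - _pairwise_identity(
                sequences[ids[i]], sequences[ids[j]], scheme
            )
            dist[i, j] = dist[j, i] = d
    merges = linkage(squareform(dist, checks=False), method="average")
    groups: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [sequences[ids[i]]]) for i in range(n)
    }
    for step, (ia, ib, _, _) in enumerate(merges):
        a_ids, a_rows = groups.pop(int(ia))
        b_ids, b_rows = groups.pop(int(ib))
        merged = _merge_alignments(a_rows, b_rows, scheme)
        groups[n + step] = (a_ids + b_ids, merged)
    (final_ids, final_rows), = groups.values()
    return dict(zip(final_ids, final_rows))


def align_core_and_concatenate(
    core: CoreGeneSet,
    sequences: Mapping[str, Mapping[str, str]],
    scheme: ScoringScheme = ScoringScheme(),
) -> ConcatenatedAlignment:
    """Per-cluster MSAs concatenated in cluster-id order.

    ``sequences`` maps cluster id -> organism -> sequence.  Organisms
    missing a cluster (possible when ``core_frac`` < 1) get an all-gap
    row of the block width.
    """
    if not core.cluster_ids:
        raise ValueError("empty core gene set")
    rows: dict[str, list[str]] = {org: [] for org in core.organisms}
    blocks: list[tuple[str, int]] = []
    for cid in core.cluster_ids:
        seqs = {
            org: seq
            for org, seq in sequences[cid].items()
            if org in core.organisms
        }
        aligned = progressive_msa(seqs, scheme)
        width = len(next(iter(aligned.values())))
        blocks.append((cid, width))
        for org in core.organisms:
            rows[org].append(aligned.get(org, GAP * width))
    return ConcatenatedAlignment(
        organisms=tuple(core.organisms),
        blocks=tuple(blocks),
        rows={org: "".join(parts) for org, parts in rows.items()},
    )


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------

#: p-distances are capped below 1 so the Poisson correction stays finite.
MAX_P_DISTANCE = 0.95


def alignment_distances(
    concat: ConcatenatedAlignment,
) -> tuple[tuple[str, ...], np.ndarray]:
    """Poisson-corrected (-ln(1-p)) pairwise distances over shared
    non-gap columns."""
    orgs = concat.organisms
    n = len(orgs)
    mat = np.zeros((n, n))
    arrays = {
        org: np.frombuffer(concat.rows[org].encode(), dtype="S1")
        for org in orgs
    }
    gap = GAP.encode()
    for i in range(n):
        for j in range(i + 1, n):
            a = arrays[orgs[i]]
            b = arrays[orgs[j]]
            shared = (a != gap) & (b != gap)
            total = int(shared.sum())
            if total == 0:
                p = MAX_P_DISTANCE
            else:
                p = min(
                    float((a[shared] != b[shared]).sum()) / total,
                    MAX_P_DISTANCE,
                )
            d = -np.log(1.0 - p)
            mat[i, j] = mat[j, i] = d
    return orgs, mat


def build_tree(concat: ConcatenatedAlignment) -> str:
    """Neighbor-joining Newick tree from the concatenated alignment.

    Negative NJ branch lengths are clamped to zero.  Identical rows are
    legal and give zero-length branches.
    """
    orgs, mat = alignment_distances(concat)
    return nj_tree(orgs, mat)


def core_gene_tree(
    db,
    core_frac: float = 1.0,
    require_one_to_one: bool = True,
    eliminate: bool = False,
    min_core: int = 50,
    elim_core_frac: float = 0.99,
    elim_frac: float = 0.90,
    scheme: ScoringScheme | None = None,
) -> tuple[CoreGeneSet, ConcatenatedAlignment, str]:
    """Standard-table core extraction, concatenated MSA and NJ tree.

    With ``eliminate`` the sparse-organism elimination loop runs first
    and the core is extracted over the retained organisms only.
    """
    from .hierarchy import expand_standard

    expanded = expand_standard(db)
    gene_org = {
        seg.gene_id: db.genes[seg.gene_id].organism_id
        for segs in expanded.values()
        for seg in segs
    }
    presence = organism_presence(expanded, gene_org)
    if eliminate:
        result = eliminate_sparse_organisms(
            presence,
            min_core=min_core,
            core_frac=elim_core_frac,
            elim_frac=elim_frac,
        )
        presence = presence[list(result.retained)]
    core = extract_core(presence, core_frac, require_one_to_one)
    if not core.cluster_ids:
        raise ValueError("no core clusters at the requested conservation")
    scheme = scheme or db.config.scheme
    sequences: dict[str, dict[str, str]] = {}
    for cid in core.cluster_ids:
        per_org: dict[str, str] = {}
        for seg in sorted(expanded[cid]):
            org = gene_org[seg.gene_id]
            if org in per_org:
                continue  # paralogs only arise when one-to-one is off
            per_org[org] = db.genes[seg.gene_id].sequence[seg.begin - 1 : seg.end]
        sequences[cid] = per_org
    concat = align_core_and_concatenate(core, sequences, scheme)
    return core, concat, build_tree(concat)


def nj_tree(ids: Sequence[str], distances: np.ndarray) -> str:
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least three organisms")
    dm = DistanceMatrix(distances, ids=list(ids))
    tree = nj(dm)
    for node in tree.traverse(include_self=True):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return write_newick(tree).strip()
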