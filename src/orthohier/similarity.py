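"""All-against-all protein similarity.

Two modes mirror the cost strategy of the hierarchical build:

* ``sensitive`` -- optimal Smith-Waterman local alignment (affine gaps,
  BLOSUM by default) for every pair; used between genera where
  divergence is high.
* ``fast`` -- the same alignment, but only for pairs sharing at least
  one exact k-mer seed (k=6 by default); used within species and within
  genera where orthologs are close and seeds are essentially never
  missed.  Seeding only prunes, so fast-mode hits are a subset of
  sensitive-mode hits, and the two modes coincide as k -> 1.

Only the single best local alignment per unordered pair is kept, and
self-hits are excluded.  Output order is deterministic (sorted by
query then subject id, query being the lexicographically smaller).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from ._kernels import sw_align, sw_score
from .model import GeneRecord


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters (raw score units of the matrix)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    #: raw-score reporting threshold.  100 with BLOSUM62 11/1 is about
    #: 43 bits: unrelated proteins of typical length reach it with
    #: probability well below 1e-6 per pair, while even distant
    #: orthologs score several-fold higher.
    score_cutoff: float = 100.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


@dataclass(frozen=True)
class SimilarityHit:
    """Best local alignment between two genes.

    ``alignment_map`` lists the aligned residue pairs (1-based, strictly
    increasing in both coordinates); spans are its extremes.
    """

    query_id: str
    subject_id: str
    raw_score: float
    identity: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    alignment_map: tuple[tuple[int, int], ...]

    def swapped(self) -> "SimilarityHit":
        return SimilarityHit(
            query_id=self.subject_id,
            subject_id=self.query_id,
            raw_score=self.raw_score,
            identity=self.identity,
            query_span=self.subject_span,
            subject_span=self.query_span,
            alignment_map=tuple((s, q) for q, s in self.alignment_map),
        )


@lru_cache(maxsize=4)
def _matrix(name: str) -> tuple[str, np.ndarray]:
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    arr = np.asarray(mat, dtype=np.int32)
    return alphabet, arr


@lru_cache(maxsize=4)
def _alphabet_index(name: str) -> dict[str, int]:
    alphabet, _ = _matrix(name)
    return {c: i for i, c in enumerate(alphabet)}


def encode(sequence: str, matrix_name: str = "BLOSUM62") -> np.ndarray:
    """Encode residues as matrix indices; unknown characters are errors."""
    index = _alphabet_index(matrix_name)
    try:
        return np.fromiter(
            (index[c] for c in sequence), dtype=np.int8, count=len(sequence)
        )
    except KeyError as exc:
        raise ValueError(f"invalid residue {exc.args[0]!r} in sequence") from None


def _int_penalties(scheme: ScoringScheme) -> tuple[np.int32, np.int32]:
    return np.int32(round(scheme.gap_open)), np.int32(round(scheme.gap_extend))


def align_pair(
    gene_a: GeneRecord,
    gene_b: GeneRecord,
    scheme: ScoringScheme = ScoringScheme(),
) -> SimilarityHit | None:
    """Optimal local alignment of two genes; None if below the cutoff.

    Symmetric by construction: the pair is aligned in canonical
    (lexicographic gene id) order and swapped back, so
    ``score(a, b) == score(b, a)`` and spans exchange exactly.
    """
    if gene_b.gene_id < gene_a.gene_id:
        hit = align_pair(gene_b, gene_a, scheme)
        return None if hit is None else hit.swapped()
    _, sub = _matrix(scheme.matrix_name)
    a = encode(gene_a.sequence, scheme.matrix_name)
    b = encode(gene_b.sequence, scheme.matrix_name)
    go, ge = _int_penalties(scheme)
    score, qpos, spos = sw_align(
        a.astype(np.int64), b.astype(np.int64), sub, go, ge
    )
    if float(score) < scheme.score_cutoff or qpos.size == 0:
        return None
    return _hit_from_traceback(gene_a, gene_b, float(score), qpos, spos)


def _hit_from_traceback(
    gene_a: GeneRecord,
    gene_b: GeneRecord,
    score: float,
    qpos: np.ndarray,
    spos: np.ndarray,
) -> SimilarityHit:
    sa = gene_a.sequence
    sb = gene_b.sequence
    matches = sum(
        1 for q, s in zip(qpos, spos) if sa[q - 1] == sb[s - 1]
    )
    return SimilarityHit(
        query_id=gene_a.gene_id,
        subject_id=gene_b.gene_id,
        raw_score=score,
        identity=matches / len(qpos),
        query_span=(int(qpos[0]), int(qpos[-1])),
        subject_span=(int(spos[0]), int(spos[-1])),
        alignment_map=tuple(
            (int(q), int(s)) for q, s in zip(qpos, spos)
        ),
    )


def _kmer_candidates(
    genes: Sequence[GeneRecord], k: int
) -> set[tuple[int, int]]:
    """Unordered index pairs sharing at least one exact k-mer."""
    by_kmer: dict[str, list[int]] = {}
    for idx, gene in enumerate(genes):
        seq = gene.sequence
        seen: set[str] = set()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if kmer not in seen:
                seen.add(kmer)
                by_kmer.setdefault(kmer, []).append(idx)
    pairs: set[tuple[int, int]] = set()
    for idxs in by_kmer.values():
        if len(idxs) < 2:
            continue
        for i in range(len(idxs)):
            for j in range(i + 1, len(idxs)):
                pairs.add((idxs[i], idxs[j]))
    return pairs


def all_vs_all(
    genes: Sequence[GeneRecord],
    genes_b: Sequence[GeneRecord] | None = None,
    mode: str = "sensitive",
    scheme: ScoringScheme = ScoringScheme(),
    k: int = 6,
) -> list[SimilarityHit]:
    """All-against-all similarity over one gene set (or across two).

    With a single set, each unordered pair is reported once with the
    lexicographically smaller gene id as query; self-hits are excluded.
    """
    if mode not in ("fast", "sensitive"):
        raise ValueError(f"unknown mode {mode!r}")
    if genes_b is not None:
        pool = list(genes) + [g for g in genes_b if g not in genes]
    else:
        pool = list(genes)
    pool = sorted(pool, key=lambda g: g.gene_id)
    ids = [g.gene_id for g in pool]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in all-vs-all input")

    if mode == "fast":
        candidates = sorted(_kmer_candidates(pool, k))
    else:
        n = len(pool)
        candidates = [(i, j) for i in range(n) for j in range(i + 1, n)]

    _, sub = _matrix(scheme.matrix_name)
    go, ge = _int_penalties(scheme)
    encoded = [
        encode(g.sequence, scheme.matrix_name).astype(np.int64) for g in pool
    ]
    hits: list[SimilarityHit] = []
    for i, j in candidates:
        score = sw_score(encoded[i], encoded[j], sub, go, ge)
        if float(score) < scheme.score_cutoff:
            continue
        full, qpos, spos = sw_align(encoded[i], encoded[j], sub, go, ge)
        hits.append(
            _hit_from_traceback(pool[i], pool[j], float(full), qpos, spos)
        )
    hits.sort(key=lambda h: (h.query_id, h.subject_id))
    return hits


def _map_to_blocks(pairs: Sequence[tuple[int, int]]) -> str:
    """Compact an alignment map into gapless blocks ``qb-qe/sb-se``."""
    blocks: list[str] = []
    qb, sb = pairs[0]
    qe, se = qb, sb
    for q, s in pairs[1:]:
        if q == qe + 1 and s == se + 1:
            qe, se = q, s
        else:
            blocks.append(f"{qb}-{qe}/{sb}-{se}")
            qb, sb, qe, se = q, s, q, s
    blocks.append(f"{qb}-{qe}/{sb}-{se}")
    return ",".join(blocks)


def _blocks_to_map(text: str) -> tuple[tuple[int, int], ...]:
    pairs: list[tuple[int, int]] = []
    for block in text.split(","):
        qpart, spart = block.split("/")
        qb, qe = (int(x) for x in qpart.split("-"))
        sb, se = (int(x) for x in spart.split("-"))
        if qe - qb != se - sb:
            raise ValueError(f"unbalanced alignment block {block!r}")
        pairs.extend((qb + i, sb + i) for i in range(qe - qb + 1))
    return tuple(pairs)


HIT_HEADER = (
    "query\tsubject\tscore\tidentity\tqbegin\tqend\tsbegin\tsend\tblocks"
)


def write_hits(hits: Iterable[SimilarityHit], path) -> None:
    with open(path, "w") as fh:
        fh.write(HIT_HEADER + "\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.raw_score:g}\t"
                f"{h.identity!r}\t{h.query_span[0]}\t{h.query_span[1]}\t"
                f"{h.subject_span[0]}\t{h.subject_span[1]}\t"
                f"{_map_to_blocks(h.alignment_map)}\n"
            )


def read_hits(path) -> list[SimilarityHit]:
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != HIT_HEADER:
            raise ValueError(f"{path}: not a hit table")
        for line in fh:
            q, s, score, ident, qb, qe, sb, se, blocks = line.rstrip("\n").split("\t")
            hits.append(
                SimilarityHit(
                    query_id=q,
                    subject_id=s,
                    raw_score=float(score),
                    identity=float(ident),
                    query_span=(int(qb), int(qe)),
                    subject_span=(int(sb), int(se)),
                    alignment_map=_blocks_to_map(blocks),
                )
            )
    return hits


def hit_lookup(hits: Iterable[SimilarityHit]) -> dict[tuple[str, str], SimilarityHit]:
    """Index hits by unordered gene-id pair (sorted tuple key)."""
    out: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        key = tuple(sorted((h.query_id, h.subject_id)))
        prev = out.get(key)
        if prev is None or h.raw_score > prev.raw_score:
            out[key] = h
    return out
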