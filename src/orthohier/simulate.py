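"""Synthetic genomes with known orthology truth.

Gene families evolve along a randomly resolved binary species tree that
respects a genus/species/organism taxonomy: organisms of one species are
sisters, species of one genus form a subtree, genera form the backbone.
Branch lengths (expected substitutions per site) are drawn around the
per-level rates, so within-species pairs are nearly identical and
between-genus pairs are the most diverged.

Substitutions are uniform over the 20-residue alphabet with no indels by
default, which keeps the true family assignment unambiguous at low
divergence -- exactly the regime in which the hierarchical build should
recover families perfectly.  Per organism, each family may be lost
(probability ``p_loss``), duplicated (``p_dup``, a second independently
mutated copy), fused with another family into a single two-domain gene
(``p_fusion``) or split into two fragment genes (``p_fission``).  The
truth set records, for every emitted gene, its family segments, the
fusion/fission event labels, and the generating species tree.

Everything is reproducible from the seed: the same parameters give
byte-identical FASTA/TSV output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import write_protein_fasta, write_taxonomy
from .model import GeneRecord, Taxonomy

AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated data set.

    ``taxonomy`` is ``(n_genera, n_species_per_genus,
    n_genomes_per_species)`` or an explicit nested list
    ``[[genomes per species, ...] per genus]``.
    """

    taxonomy: tuple[int, int, int] | Sequence[Sequence[int]] = (3, 3, 2)
    n_families: int = 100
    mean_gene_len: int = 250
    len_sigma: float = 0.25
    rate_within_species: float = 0.005
    rate_within_genus: float = 0.01
    rate_between_genus: float = 0.03
    p_loss: float = 0.02
    p_dup: float = 0.02
    p_fusion: float = 0.0
    p_fission: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_loss", "p_dup", "p_fusion", "p_fission"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in (
            "rate_within_species",
            "rate_within_genus",
            "rate_between_genus",
            "indel_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        for counts in self.genome_counts():
            if not counts or any(c < 1 for c in counts):
                raise ValueError(f"invalid taxonomy spec {self.taxonomy!r}")

    def genome_counts(self) -> list[list[int]]:
        """Genome count per species, grouped by genus."""
        t = self.taxonomy
        if (
            isinstance(t, tuple)
            and len(t) == 3
            and all(isinstance(x, int) for x in t)
        ):
            ng, ns, no = t
            if ng < 1 or ns < 1 or no < 1:
                raise ValueError(f"invalid taxonomy spec {t!r}")
            return [[no] * ns for _ in range(ng)]
        return [list(counts) for counts in t]


@dataclass(frozen=True)
class TruthSet:
    """Ground truth for one simulation.

    ``assignments`` maps every emitted gene id to its family segments
    ``(family_id, begin, end)``; fused genes carry two entries.
    """

    assignments: dict[str, tuple[tuple[str, int, int], ...]]
    fusion_genes: frozenset[str]
    fission_genes: frozenset[str]
    tree_newick: str

    def family_of(self, gene_id: str) -> str:
        segs = self.assignments[gene_id]
        if len(segs) != 1:
            raise ValueError(f"gene {gene_id} spans multiple families")
        return segs[0][0]


@dataclass
class SimResult:
    genomes: dict[str, list[GeneRecord]]
    taxonomy: Taxonomy
    truth: TruthSet
    params: SimParams

    def all_genes(self) -> dict[str, GeneRecord]:
        return {
            g.gene_id: g
            for org in sorted(self.genomes)
            for g in self.genomes[org]
        }


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("name", "children", "edge")

    def __init__(self, name: str | None = None) -> None:
        self.name = name
        self.children: list[_Node] = []
        self.edge: float = 0.0

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.edge:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.edge:.6f}"


def _join_random(nodes: list[_Node], rate: float, rng: np.random.Generator) -> _Node:
    """Random binary coalescence; each joined child edge ~ rate * U(0.5, 1.5)."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a = nodes.pop(j)
        b = nodes.pop(i)
        for child in (a, b):
            child.edge = rate * rng.uniform(0.5, 1.5)
        parent = _Node()
        parent.children = [b, a]
        nodes.append(parent)
    return nodes[0]


def _build_tree(
    counts: list[list[int]], params: SimParams, rng: np.random.Generator
) -> tuple[_Node, Taxonomy]:
    rows = []
    genus_roots: list[_Node] = []
    for gi, genus in enumerate(counts, start=1):
        genus_id = f"g{gi:02d}"
        species_roots: list[_Node] = []
        for si, n_genomes in enumerate(genus, start=1):
            species_id = f"{genus_id}s{si:02d}"
            leaves = []
            for ni in range(1, n_genomes + 1):
                org = f"{species_id}n{ni:02d}"
                rows.append((org, species_id, genus_id))
                leaves.append(_Node(org))
            species_roots.append(
                _join_random(leaves, params.rate_within_species, rng)
            )
        genus_roots.append(
            _join_random(species_roots, params.rate_within_genus, rng)
        )
    root = _join_random(genus_roots, params.rate_between_genus, rng)
    return root, Taxonomy.from_rows(rows)


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _mutate(seq: str, branch_len: float, rng: np.random.Generator) -> str:
    n_sub = rng.poisson(len(seq) * branch_len)
    if n_sub == 0:
        return seq
    chars = list(seq)
    for _ in range(n_sub):
        pos = int(rng.integers(len(chars)))
        old = chars[pos]
        choices = [c for c in AA if c != old]
        chars[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def _indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_ev = rng.poisson(len(seq) * rate)
    for _ in range(n_ev):
        pos = int(rng.integers(len(seq)))
        size = int(rng.integers(1, 6))
        if rng.random() < 0.5 and len(seq) > size + 10:
            seq = seq[:pos] + seq[pos + size :]
        else:
            ins = "".join(AA[int(rng.integers(20))] for _ in range(size))
            seq = seq[:pos] + ins + seq[pos:]
    return seq


def simulate(params: SimParams) -> SimResult:
    """Generate genomes, taxonomy and truth for one parameter set."""
    rng = np.random.default_rng(params.seed)
    counts = params.genome_counts()
    root, taxonomy = _build_tree(counts, params, rng)

    families = [f"fam{f:04d}" for f in range(1, params.n_families + 1)]
    mu = math.log(params.mean_gene_len) - params.len_sigma**2 / 2
    lengths = {
        fam: max(60, int(round(rng.lognormal(mu, params.len_sigma))))
        for fam in families
    }
    root_seqs = {
        fam: "".join(AA[int(k)] for k in rng.integers(20, size=lengths[fam]))
        for fam in families
    }

    leaf_seqs: dict[str, dict[str, str]] = {}

    def descend(node: _Node, seqs: dict[str, str]) -> None:
        for child in node.children:
            mutated = {
                fam: _indels(
                    _mutate(seq, child.edge, rng), params.indel_rate, rng
                )
                for fam, seq in seqs.items()
            }
            if child.children:
                descend(child, mutated)
            else:
                leaf_seqs[child.name] = mutated

    if root.children:
        descend(root, root_seqs)
    else:  # single organism
        leaf_seqs[root.name] = dict(root_seqs)

    genomes: dict[str, list[GeneRecord]] = {}
    assignments: dict[str, tuple[tuple[str, int, int], ...]] = {}
    fusion_genes: set[str] = set()
    fission_genes: set[str] = set()

    for org in taxonomy.all_organisms():
        seqs = leaf_seqs[org]
        present = [fam for fam in families if rng.random() >= params.p_loss]
        fuse_pool = [fam for fam in present if rng.random() < params.p_fusion]
        if len(fuse_pool) % 2 == 1:
            fuse_pool.pop()
        fused_pairs = [
            (fuse_pool[i], fuse_pool[i + 1]) for i in range(0, len(fuse_pool), 2)
        ]
        in_fusion = {f for pair in fused_pairs for f in pair}

        serial = 0

        def emit(seq: str, segs: tuple[tuple[str, int, int], ...]) -> str:
            nonlocal serial
            serial += 1
            gid = f"{org}x{serial:05d}"
            genomes.setdefault(org, []).append(GeneRecord(gid, org, seq))
            assignments[gid] = segs
            return gid

        genomes.setdefault(org, [])
        for fam in present:
            if fam in in_fusion:
                continue
            seq = seqs[fam]
            if rng.random() < params.p_fission:
                cut = int(round(len(seq) * rng.uniform(0.4, 0.6)))
                cut = min(max(cut, 30), len(seq) - 30)
                g1 = emit(seq[:cut], ((fam, 1, cut),))
                g2 = emit(seq[cut:], ((fam, 1, len(seq) - cut),))
                fission_genes.update((g1, g2))
                continue
            emit(seq, ((fam, 1, len(seq)),))
            if rng.random() < params.p_dup:
                dup = _mutate(seq, params.rate_within_species, rng)
                emit(dup, ((fam, 1, len(dup)),))
        for fam_a, fam_b in fused_pairs:
            sa, sb = seqs[fam_a], seqs[fam_b]
            gid = emit(
                sa + sb,
                (
                    (fam_a, 1, len(sa)),
                    (fam_b, len(sa) + 1, len(sa) + len(sb)),
                ),
            )
            fusion_genes.add(gid)

    truth = TruthSet(
        assignments=assignments,
        fusion_genes=frozenset(fusion_genes),
        fission_genes=frozenset(fission_genes),
        tree_newick=root.newick()[: -len(":0.000000")] + ";",
    )
    return SimResult(genomes=genomes, taxonomy=taxonomy, truth=truth,
                     params=params)


# ---------------------------------------------------------------------------
# disk output / truth scoring
# ---------------------------------------------------------------------------

def write_simulation(result: SimResult, out_dir: str | Path) -> None:
    """Write per-organism FASTAs, taxonomy TSV, truth JSONL and true tree."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for org in sorted(result.genomes):
        write_protein_fasta(result.genomes[org], out / f"{org}.faa")
    write_taxonomy(result.taxonomy, out / "taxonomy.tsv")
    with open(out / "truth.jsonl", "w") as fh:
        for gid in sorted(result.truth.assignments):
            rec = {
                "gene_id": gid,
                "segments": [
                    list(seg) for seg in result.truth.assignments[gid]
                ],
                "fusion": gid in result.truth.fusion_genes,
                "fission": gid in result.truth.fission_genes,
            }
            fh.write(json.dumps(rec) + "\n")
    with open(out / "true_tree.nwk", "w") as fh:
        fh.write(result.truth.tree_newick + "\n")


def read_truth(path: str | Path) -> TruthSet:
    assignments: dict[str, tuple[tuple[str, int, int], ...]] = {}
    fusion: set[str] = set()
    fission: set[str] = set()
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            assignments[rec["gene_id"]] = tuple(
                (str(f), int(b), int(e)) for f, b, e in rec["segments"]
            )
            if rec.get("fusion"):
                fusion.add(rec["gene_id"])
            if rec.get("fission"):
                fission.add(rec["gene_id"])
    tree = ""
    tree_path = Path(path).with_name("true_tree.nwk")
    if tree_path.exists():
        tree = tree_path.read_text().strip()
    return TruthSet(assignments, frozenset(fusion), frozenset(fission), tree)


def score_against_truth(
    expanded: Mapping[str, Sequence],
    truth: TruthSet,
    flags_by_gene: Mapping[str, Iterable[str]] | None = None,
) -> dict[str, float | None]:
    """Compare an expanded standard table with the simulation truth.

    ``expanded`` maps standard cluster ids to raw-gene
    :class:`~orthohier.model.DomainSegment` lists.  Each truth segment is
    matched to the predicted cluster with the largest residue overlap;
    the adjusted Rand index is computed over those truth segments.
    Fusion/fission sensitivities use the member flags when provided and
    otherwise fall back to multi-cluster membership; they are ``None``
    when no such event was simulated.
    """
    from sklearn.metrics import adjusted_rand_score

    pred_by_gene: dict[str, list[tuple[str, int, int]]] = {}
    for cid, segs in expanded.items():
        for seg in segs:
            pred_by_gene.setdefault(seg.gene_id, []).append(
                (cid, seg.begin, seg.end)
            )
    missing = sorted(set(truth.assignments) - set(pred_by_gene))
    extra = sorted(set(pred_by_gene) - set(truth.assignments))
    if missing or extra:
        raise ValueError(
            f"gene coverage mismatch: missing={missing[:5]} extra={extra[:5]}"
        )

    true_labels: list[str] = []
    pred_labels: list[str] = []
    for gid in sorted(truth.assignments):
        for fam, b, e in truth.assignments[gid]:
            best_cid, best_ov = None, -1
            for cid, pb, pe in pred_by_gene[gid]:
                ov = min(e, pe) - max(b, pb) + 1
                if ov > best_ov:
                    best_ov, best_cid = ov, cid
            true_labels.append(fam)
            pred_labels.append(best_cid or "")
    ari = float(adjusted_rand_score(true_labels, pred_labels))

    def sensitivity(true_set: frozenset[str], flag: str) -> float | None:
        if not true_set:
            return None
        detected = 0
        for gid in true_set:
            if flags_by_gene is not None:
                hit = flag in set(flags_by_gene.get(gid, ()))
            else:
                hit = len({c for c, _, _ in pred_by_gene[gid]}) > 1
            if hit:
                detected += 1
        return detected / len(true_set)

    return {
        "adjusted_rand_index": ari,
        "fusion_sensitivity": sensitivity(truth.fusion_genes, "fusion"),
        "fission_sensitivity": sensitivity(truth.fission_genes, "fission"),
    }
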