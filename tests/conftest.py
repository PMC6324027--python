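"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import random

import numpy as np
import pytest
from hypothesis import settings

from orthohier.model import (
    DomainSegment,
    GeneRecord,
    OrthologCluster,
    OrthologTable,
)
from orthohier.similarity import ScoringScheme

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return random.Random(1234)


@pytest.fixture
def loose_scheme():
    """Scheme with a tiny cutoff so short test sequences still report."""
    return ScoringScheme(score_cutoff=1.0)


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA) for _ in range(length))


def mutate(rng: random.Random, seq: str, n_sub: int) -> str:
    chars = list(seq)
    for _ in range(n_sub):
        pos = rng.randrange(len(chars))
        chars[pos] = rng.choice([c for c in AA if c != chars[pos]])
    return "".join(chars)


def gene_family(
    rng: random.Random,
    family: str,
    organisms: list[str],
    length: int = 120,
    n_sub: int = 3,
) -> list[GeneRecord]:
    """One near-identical gene per organism, derived from a common root."""
    root = random_protein(rng, length)
    return [
        GeneRecord(f"{org}_{family}", org, mutate(rng, root, n_sub))
        for org in organisms
    ]


def random_ortholog_table(rng: random.Random) -> OrthologTable:
    """A random valid table for serialization round-trip tests."""
    level = rng.choice(["species", "genus", "standard"])
    columns = sorted(
        f"t{rng.randrange(100):02d}" for _ in range(rng.randint(2, 5))
    )
    columns = sorted(set(columns))
    clusters = []
    member_columns: dict[str, str] = {}
    conservation: dict[tuple[str, str], float] = {}
    n_clusters = rng.randint(1, 8)
    gene_serial = 0
    for ci in range(1, n_clusters + 1):
        cid = f"{ci:05d}"
        members: list[DomainSegment] = []
        flags: dict[str, frozenset[str]] = {}
        for _ in range(rng.randint(1, 5)):
            gene_serial += 1
            # occasionally a pan-gene-style id with a colon
            if rng.random() < 0.3:
                gid = f"tax{rng.randrange(99999)}:{gene_serial:05d}"
            else:
                gid = f"gene{gene_serial:05d}"
            n_dom = rng.randint(1, 3)
            pos = 1
            for dom in range(1, n_dom + 1):
                width = rng.randint(30, 400)
                members.append(DomainSegment(gid, dom, pos, pos + width - 1))
                pos += width
            member_columns[gid] = rng.choice(columns)
            if rng.random() < 0.25:
                flags[gid] = frozenset(
                    rng.sample(["fusion", "fission", "outlier"],
                               rng.randint(1, 2))
                )
        rep_pool = sorted({m.gene_id for m in members})
        clusters.append(
            OrthologCluster(
                cluster_id=cid,
                level=level,
                scope_taxid="scope1",
                members=tuple(members),
                representative=rng.choice(rep_pool),
                flags=flags,
            )
        )
        for col in columns:
            if rng.random() < 0.5:
                conservation[(cid, col)] = rng.randrange(0, 5) / 4
    return OrthologTable(
        level=level,
        scope_taxid="scope1",
        columns=tuple(columns),
        clusters=clusters,
        member_columns=member_columns,
        conservation=conservation,
    )
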