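"""Genome quality statistics and inclusion filters.

A genome enters the orthology build only if its assembly passes three
completeness checks: a low fraction of gap characters ('n'/'N'), enough
annotated CDS (both absolutely and per kilobase for prokaryotes), and a
small fraction of sequence on unlocalized scaffolds.  Ratio thresholds
are strict (<) and count thresholds inclusive (>=); boundary values such
as a gap ratio of exactly 1% therefore fail.

Whether a scaffold is "localized" is caller-provided metadata: assembly
reports, not sequence content, carry that information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

KINGDOMS = ("prokaryote", "eukaryote")

#: (gap_ratio <, cds_count >=, cds_per_kb >= or None, unlocalized_ratio <)
THRESHOLDS = {
    "prokaryote": (0.01, 100, 0.5, 0.05),
    "eukaryote": (0.20, 200, None, 0.25),
}


@dataclass(frozen=True)
class GenomeStats:
    organism_id: str
    kingdom: str
    gap_ratio: float
    cds_count: int
    cds_per_kb: float
    unlocalized_ratio: float

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise ValueError(f"unknown kingdom {self.kingdom!r}")
        for name in ("gap_ratio", "unlocalized_ratio"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.cds_count < 0 or self.cds_per_kb < 0:
            raise ValueError("CDS statistics must be non-negative")


@dataclass(frozen=True)
class QCVerdict:
    organism_id: str
    passed: bool
    failed_rules: frozenset[str]

    def __post_init__(self) -> None:
        if self.passed != (not self.failed_rules):
            raise ValueError("passed must mean no failed rules")


def compute_genome_stats(
    sequences: Mapping[str, str],
    localized: Mapping[str, bool],
    cds_count: int,
    kingdom: str,
    organism_id: str = "",
) -> GenomeStats:
    """Assembly-level statistics over all replicons/scaffolds.

    ``sequences`` maps sequence id to nucleotide string; gap counting is
    case-insensitive over 'n'.  ``localized`` flags each sequence id.
    """
    total = sum(len(s) for s in sequences.values())
    if total == 0:
        raise ValueError(f"{organism_id or 'assembly'}: zero-length assembly")
    gaps = sum(s.lower().count("n") for s in sequences.values())
    unloc = sum(
        len(s) for sid, s in sequences.items() if not localized.get(sid, True)
    )
    return GenomeStats(
        organism_id=organism_id,
        kingdom=kingdom,
        gap_ratio=gaps / total,
        cds_count=cds_count,
        cds_per_kb=cds_count / (total / 1000.0),
        unlocalized_ratio=unloc / total,
    )


def qc_filter(stats: GenomeStats) -> QCVerdict:
    """Apply the kingdom-specific inclusion rules to one genome."""
    gap_max, cds_min, per_kb_min, unloc_max = THRESHOLDS[stats.kingdom]
    failed: set[str] = set()
    if not (stats.gap_ratio < gap_max):
        failed.add("gap_ratio")
    cds_ok = stats.cds_count >= cds_min
    if per_kb_min is not None:
        cds_ok = cds_ok and stats.cds_per_kb >= per_kb_min
    if not cds_ok:
        failed.add("cds")
    if not (stats.unlocalized_ratio < unloc_max):
        failed.add("unlocalized")
    return QCVerdict(
        organism_id=stats.organism_id,
        passed=not failed,
        failed_rules=frozenset(failed),
    )
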