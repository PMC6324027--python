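"""Pipeline configuration: every threshold in one serializable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .clustering import ClusterParams
from .similarity import ScoringScheme


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the hierarchical build.

    The within-species and within-genus steps default to the fast
    (k-mer-seeded) similarity mode; the between-genus step uses the
    sensitive mode.  Core-gene extraction parameters feed the
    phylogeny stage.
    """

    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    kmer_k: int = 6
    mode_within_species: str = "fast"
    mode_within_genus: str = "fast"
    mode_between_genus: str = "sensitive"
    core_frac: float = 1.0
    require_one_to_one: bool = True
    min_core: int = 50
    elim_core_frac: float = 0.99
    elim_frac: float = 0.90

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "scheme": asdict(self.scheme),
            "cluster": asdict(self.cluster),
            **{
                k: getattr(self, k)
                for k in (
                    "kmer_k",
                    "mode_within_species",
                    "mode_within_genus",
                    "mode_between_genus",
                    "core_frac",
                    "require_one_to_one",
                    "min_core",
                    "elim_core_frac",
                    "elim_frac",
                )
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        scheme = ScoringScheme(**data.pop("scheme", {}))
        cluster = ClusterParams(**data.pop("cluster", {}))
        return cls(scheme=scheme, cluster=cluster, **data)
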