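"""Run configuration: the workflow's tunable parameters with their defaults.

Standard defaults: minimum fold change 2.0, k = 10 intermediate-path
extraction, 10,000 edge samplings for module z-scores, 10,000 control sets
for S/N, 1,000 degree-preserving permutations for enrichment, z > 3.0
(pathways/GO) and z > 2.0 (miRNA targets), GO size filter [50, 500].  The
clustering cutoff has no universal value — it is chosen per dataset from
the growth curve — so it defaults to ``"auto"`` (advisory suggestion,
never silently applied by the CLI).
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError

SUBSTREAMS = {"scoring": 0, "enrichment": 1, "evaluation": 2, "simulation": 3}


def substream_seed(seed: int, name: str) -> int:
    """Deterministic per-stage child seed fanned out from the global seed."""
    try:
        idx = SUBSTREAMS[name]
    except KeyError:
        raise ConfigurationError(f"unknown substream {name!r}") from None
    return int(np.random.SeedSequence((seed, idx)).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    min_fold: float = 2.0
    signal_floor: float = 1.0
    correlation_scale: str = "log2"        # "log2" | "raw"
    cutoff: float | str = "auto"
    cutoff_grid_points: int = 100
    k: int = 10
    min_de: int = 5
    n_edge_samples: int = 10000
    n_perm: int = 1000
    n_controls: int = 10000
    z_pathway: float = 3.0
    z_mirna: float = 2.0
    go_min_size: int = 50
    go_max_size: int = 500
    universe_mode: str = "intersection"    # "intersection" | "expression"
    retain_unmeasured: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_fold < 1.0:
            raise ConfigurationError("min_fold must be >= 1")
        if self.correlation_scale not in ("log2", "raw"):
            raise ConfigurationError(f"unknown correlation_scale {self.correlation_scale!r}")
        if isinstance(self.cutoff, str):
            if self.cutoff != "auto":
                raise ConfigurationError("cutoff must be a number or 'auto'")
        elif self.cutoff < 0:
            raise ConfigurationError("cutoff must be >= 0")
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.min_de < 1:
            raise ConfigurationError("min_de must be >= 1")
        if self.universe_mode not in ("intersection", "expression"):
            raise ConfigurationError(f"unknown universe_mode {self.universe_mode!r}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with Path(path).open("rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **changes) -> "RunConfig":
        return dataclasses.replace(self, **changes)
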