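"""Run configuration: every tunable of the pipeline in one auditable record."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters with their working defaults.

    Attributes
    ----------
    pd_cutoff
        Inclusive property-distance bound under which two amino acids are
        treated as identical (unitless PD; default 8).
    adjacency
        Distance cutoff for surface-map adjacency, Angstrom (default 4.0).
    adjacency_metric
        ``'ca'`` for alpha-carbon pairs, ``'any-atom'`` for minimum
        heavy-atom distance.
    nn_step
        Backbone N-to-N spacing assumed per residue of an extended
        mimotope gap, Angstrom (default 3.5).
    avg_pd_max
        Upper bound on the average PD of longest seed connections admitted
        into the prediction (default 2.0).
    surface_fraction
        Fraction of the Gly-X-Gly maximal SASA above which a residue
        counts as surface (default 0.05, strict inequality).
    epitope_delta
        SASA loss (Angstrom^2) above which a residue belongs to the true
        epitope of a complex (default 10, strict inequality).
    min_seed_len
        Minimum matched length of a seed (default 2).
    probe_radius
        Solvent probe radius for SASA, Angstrom (default 1.4).
    max_seeds_per_position
        Enumeration guard: hard error when the DFS emits more seeds than
        this from a single mimotope start position.
    max_connections
        Enumeration guard for the seed-connection chaining step.
    """

    pd_cutoff: float = 8.0
    adjacency: float = 4.0
    adjacency_metric: str = "ca"
    nn_step: float = 3.5
    avg_pd_max: float = 2.0
    surface_fraction: float = 0.05
    epitope_delta: float = 10.0
    min_seed_len: int = 2
    probe_radius: float = 1.4
    max_seeds_per_position: int = 100_000
    max_connections: int = 2_000_000

    def __post_init__(self) -> None:
        for name in (
            "pd_cutoff", "adjacency", "nn_step", "avg_pd_max",
            "surface_fraction", "epitope_delta", "min_seed_len", "probe_radius",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.min_seed_len < 1:
            raise ValueError("min_seed_len must be at least 1")
        if self.adjacency_metric not in ("ca", "any-atom"):
            raise ValueError("adjacency_metric must be 'ca' or 'any-atom'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
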