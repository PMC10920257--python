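"""The MimoTree mapping algorithm.

Pipeline: surface map -> depth-first seed search -> geometry-constrained
seed connection -> prediction selection.

A *seed* is a contiguous stretch of a mimotope matched residue-by-residue
(under the property-distance cutoff) onto a simple path of adjacent
antigen surface residues.  Seeds from one mimotope are chained into *seed
connections* when the mimotope gap between them, assumed to be in an
extended linear conformation at 3.5 Angstrom per residue (N-to-N), can
physically span the 3D distance between the seed termini on the antigen.
Gaps carry no penalty.  The final prediction is the union of the antigen
residues of (i) all seed connections with average PD exactly 0 and (ii)
the seed connections of the overall longest matched length with average
PD greater than 0 but at most 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np

from .config import RunConfig
from .descriptors import AMINO_ACIDS, DescriptorTable, MatchPolicy, property_distance
from .structure import (
    AntigenStructure,
    ResidueId,
    SurfaceMap,
    build_surface_map,
    compute_sasa,
    select_surface_residues,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Mimotope",
    "Seed",
    "SeedConnection",
    "Prediction",
    "SeedExplosionError",
    "load_mimotopes",
    "find_seeds",
    "gap_span_limit",
    "connect_seeds",
    "select_prediction",
    "run_mimotree",
]


class SeedExplosionError(RuntimeError):
    """The search space exceeded the configured enumeration ceiling.

    Raised instead of silently truncating; lowering ``pd_cutoff`` (fewer
    residue pairs treated as identical) is the standard remedy.
    """


@dataclass(frozen=True)
class Mimotope:
    """A phage-display peptide: label plus one-letter sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError(f"mimotope {self.id}: length must be >= 2")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"mimotope {self.id}: non-standard residue(s) {sorted(bad)} rejected"
            )


def load_mimotopes(text: str) -> list[Mimotope]:
    """Parse a mimotope set from plain text (one per line) or FASTA.

    Sequences are upper-cased; duplicate sequences are removed with a
    logged count (the algorithm is frequency-blind).
    """
    lines = [ln.strip() for ln in text.splitlines()]
    records: list[tuple[str, str]] = []
    if any(ln.startswith(">") for ln in lines):
        name, chunks = None, []
        for ln in lines:
            if ln.startswith(">"):
                if name is not None and chunks:
                    records.append((name, "".join(chunks)))
                name, chunks = ln[1:].split()[0] if ln[1:].split() else "seq", []
            elif ln:
                chunks.append(ln)
        if name is not None and chunks:
            records.append((name, "".join(chunks)))
    else:
        records = [
            (f"m{i + 1}", ln) for i, ln in enumerate(ln for ln in lines if ln and not ln.startswith("#"))
        ]
    seen: dict[str, str] = {}
    out: list[Mimotope] = []
    dropped = 0
    for name, seq in records:
        seq = seq.upper()
        if seq in seen:
            dropped += 1
            continue
        seen[seq] = name
        out.append(Mimotope(id=name, sequence=seq))
    if dropped:
        logger.info("dropped %d duplicate mimotope sequence(s)", dropped)
    return out


@dataclass(frozen=True)
class Seed:
    """A matched segment: mimotope span [i, j] (1-based, inclusive) mapped
    onto a simple surface path of equal length."""

    mimotope_id: str
    span: tuple[int, int]
    path: tuple[ResidueId, ...]
    pd_values: tuple[float, ...]

    def __post_init__(self) -> None:
        i, j = self.span
        if j - i + 1 != len(self.path) or len(self.path) != len(self.pd_values):
            raise ValueError("span, path and pd_values lengths disagree")
        if len(set(self.path)) != len(self.path):
            raise ValueError("seed path residues must be pairwise distinct")

    @property
    def length(self) -> int:
        return len(self.path)


@dataclass(frozen=True)
class SeedConnection:
    """An ordered chain of seeds from one mimotope with bridgeable gaps."""

    mimotope_id: str
    seeds: tuple[Seed, ...]

    @property
    def matched_length(self) -> int:
        return sum(s.length for s in self.seeds)

    @property
    def pd_values(self) -> tuple[float, ...]:
        return tuple(v for s in self.seeds for v in s.pd_values)

    @property
    def avg_pd(self) -> float:
        vals = self.pd_values
        return float(sum(vals) / len(vals)) if vals else 0.0

    @property
    def is_perfect(self) -> bool:
        """True when every matched position has PD exactly zero."""
        return all(v == 0.0 for v in self.pd_values)

    def residues(self) -> tuple[ResidueId, ...]:
        return tuple(r for s in self.seeds for r in s.path)


@dataclass
class Prediction:
    """A predicted epitope: antigen surface residues plus provenance."""

    residue_ids: set[ResidueId]
    provenance: dict[ResidueId, list[dict]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.residue_ids)


# ---------------------------------------------------------------------------
# seed search


def find_seeds(
    mimotope: Mimotope,
    surface_map: SurfaceMap,
    structure: AntigenStructure,
    policy: MatchPolicy | None = None,
    min_seed_len: int = 2,
    max_seeds_per_position: int = 100_000,
) -> list[Seed]:
    """Depth-first search for all maximal matched paths.

    For every mimotope start position, every surface residue matching that
    position roots a DFS over the surface map; a path is extended while the
    next mimotope residue matches an unvisited adjacent surface residue and
    emitted when it cannot be extended (maximality).  Paths shorter than
    ``min_seed_len`` are discarded.
    """
    policy = policy or MatchPolicy()
    table = policy.table
    seq = mimotope.sequence
    n = len(seq)

    # PD from each mimotope position to each surface residue, cached by aa
    pd_cache: dict[tuple[str, str], float] = {}

    def pd(mchar: str, rid: ResidueId) -> float | None:
        aa = structure.by_id[rid].aa1
        if aa is None:
            return None  # non-standard residue: never matches
        key = (mchar, aa)
        if key not in pd_cache:
            pd_cache[key] = property_distance(mchar, aa, table)
        return pd_cache[key]

    seeds: set[Seed] = set()
    surface_ids = list(surface_map.adjacency)

    for start in range(n):  # 0-based start position
        emitted = 0

        def dfs(path: list[ResidueId], pds: list[float], visited: set[ResidueId]) -> None:
            nonlocal emitted
            nxt = start + len(path)
            extensions: list[tuple[ResidueId, float]] = []
            if nxt < n:
                for nb in surface_map.neighbors(path[-1]):
                    if nb in visited:
                        continue
                    d = pd(seq[nxt], nb)
                    if d is not None and d <= policy.pd_cutoff:
                        extensions.append((nb, d))
            if not extensions:
                if len(path) >= min_seed_len:
                    emitted += 1
                    if emitted > max_seeds_per_position:
                        raise SeedExplosionError(
                            f"mimotope {mimotope.id}: more than "
                            f"{max_seeds_per_position} seeds from position "
                            f"{start + 1}; lower pd_cutoff to shrink the search"
                        )
                    seeds.add(
                        Seed(
                            mimotope_id=mimotope.id,
                            span=(start + 1, start + len(path)),
                            path=tuple(path),
                            pd_values=tuple(pds),
                        )
                    )
                return
            for nb, d in extensions:
                path.append(nb)
                pds.append(d)
                visited.add(nb)
                dfs(path, pds, visited)
                visited.remove(nb)
                pds.pop()
                path.pop()

        for rid in surface_ids:
            d0 = pd(seq[start], rid)
            if d0 is not None and d0 <= policy.pd_cutoff:
                dfs([rid], [d0], {rid})

    return sorted(seeds, key=lambda s: (s.span, s.path))


# ---------------------------------------------------------------------------
# seed connection


def gap_span_limit(gap_len: int, nn_step: float = 3.5) -> float:
    """Maximum antigen-surface span an extended mimotope gap can bridge.

    A gap of ``g`` residues separates flanking matched residues by ``g + 1``
    backbone steps, so the limit is ``(g + 1) * nn_step`` (e.g. a
    two-residue gap at the default 3.5 Angstrom step bridges at most
    10.5 Angstrom).
    """
    if gap_len < 0:
        raise ValueError(f"gap length must be non-negative, got {gap_len}")
    return (gap_len + 1) * nn_step


def _nn_distance(structure: AntigenStructure, a: ResidueId, b: ResidueId) -> float | None:
    ra, rb = structure.by_id[a], structure.by_id[b]
    if ra.n_xyz is None or rb.n_xyz is None:
        return None
    return float(np.linalg.norm(ra.n_xyz - rb.n_xyz))


def connect_seeds(
    seeds: Sequence[Seed],
    structure: AntigenStructure,
    nn_step: float = 3.5,
    max_connections: int = 2_000_000,
) -> list[SeedConnection]:
    """All valid chains of one or more seeds from a single mimotope.

    Chains follow mimotope sequence order with strictly increasing,
    non-overlapping spans and pairwise-distinct antigen residues; each
    consecutive pair must satisfy the gap geometry rule: the backbone
    N-to-N distance from the last residue of the earlier seed to the first
    residue of the later seed may not exceed
    :func:`gap_span_limit` of the intervening mimotope gap (inclusive).
    Single seeds are themselves connections.
    """
    if not seeds:
        return []
    mids = {s.mimotope_id for s in seeds}
    if len(mids) > 1:
        raise ValueError(f"seeds must come from a single mimotope, got {sorted(mids)}")
    ordered = sorted(seeds, key=lambda s: (s.span, s.path))

    # pairwise compatibility: ordered[i] can be followed by ordered[j]
    n = len(ordered)
    residue_sets = [frozenset(s.path) for s in ordered]
    compat: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        si = ordered[i]
        for j in range(n):
            sj = ordered[j]
            gap = sj.span[0] - si.span[1] - 1
            if gap < 0:
                continue
            if residue_sets[i] & residue_sets[j]:
                continue
            dist = _nn_distance(structure, si.path[-1], sj.path[0])
            if dist is None:
                logger.warning(
                    "missing backbone N atom between seeds %s and %s; candidate skipped",
                    si.span, sj.span,
                )
                continue
            if dist <= gap_span_limit(gap, nn_step):
                compat[i].append(j)

    out: list[SeedConnection] = []

    def extend(chain: list[int], used: frozenset) -> None:
        if len(out) >= max_connections:
            raise SeedExplosionError(
                f"more than {max_connections} seed connections; lower pd_cutoff "
                f"or raise max_connections"
            )
        out.append(
            SeedConnection(
                mimotope_id=ordered[chain[0]].mimotope_id,
                seeds=tuple(ordered[k] for k in chain),
            )
        )
        for j in compat[chain[-1]]:
            if residue_sets[j] & used:
                continue
            extend(chain + [j], used | residue_sets[j])

    for i in range(n):
        extend([i], residue_sets[i])
    return out


# ---------------------------------------------------------------------------
# prediction selection


def select_prediction(
    connections: Sequence[SeedConnection],
    avg_pd_max: float = 2.0,
    params: dict | None = None,
) -> Prediction:
    """Union of (i) perfect-match connections and (ii) overall-longest
    connections with ``0 < avg_pd <= avg_pd_max``.

    The "overall longest" length is the global maximum matched length over
    the whole connection pool (ties included); gap positions contribute no
    residues.  An empty pool yields an empty prediction.
    """
    residues: set[ResidueId] = set()
    provenance: dict[ResidueId, list[dict]] = {}
    if connections:
        longest = max(c.matched_length for c in connections)
        for conn in connections:
            perfect = conn.is_perfect
            long_inexact = (
                conn.matched_length == longest and 0.0 < conn.avg_pd <= avg_pd_max
            )
            if not (perfect or long_inexact):
                continue
            why = "perfect" if perfect else "longest"
            for rid in conn.residues():
                residues.add(rid)
                provenance.setdefault(rid, []).append(
                    {
                        "mimotope": conn.mimotope_id,
                        "rule": why,
                        "matched_length": conn.matched_length,
                        "avg_pd": round(conn.avg_pd, 4),
                        "spans": [list(s.span) for s in conn.seeds],
                    }
                )
    return Prediction(residue_ids=residues, provenance=provenance, params=params or {})


# ---------------------------------------------------------------------------
# end-to-end


def run_mimotree(
    structure: AntigenStructure,
    mimotopes: Sequence[Mimotope],
    params: RunConfig | None = None,
    table: DescriptorTable | None = None,
) -> Prediction:
    """Full pipeline on a parsed antigen structure and mimotope set.

    Deterministic for fixed inputs and parameters: SASA, surface selection,
    surface map, per-mimotope seed search and connection, then selection.
    """
    params = params or RunConfig()
    policy = MatchPolicy(pd_cutoff=params.pd_cutoff, table=table or MatchPolicy().table)
    compute_sasa(structure, probe_radius=params.probe_radius)
    surface = select_surface_residues(structure, fraction=params.surface_fraction)
    surface_map = build_surface_map(
        structure, surface, cutoff=params.adjacency, metric=params.adjacency_metric
    )
    all_connections: list[SeedConnection] = []
    for mimo in mimotopes:
        seeds = find_seeds(
            mimo,
            surface_map,
            structure,
            policy=policy,
            min_seed_len=params.min_seed_len,
            max_seeds_per_position=params.max_seeds_per_position,
        )
        all_connections.extend(
            connect_seeds(
                seeds, structure, nn_step=params.nn_step,
                max_connections=params.max_connections,
            )
        )
    return select_prediction(
        all_connections, avg_pd_max=params.avg_pd_max, params=params.to_dict()
    )


# ---------------------------------------------------------------------------
# prediction I/O (shared residue TSV dialect)


def write_prediction_tsv(prediction: Prediction, structure: AntigenStructure, path_or_buf) -> None:
    """Write chain, seqnum, icode, name3 rows in structure order."""
    import pandas as pd

    rows = [
        {"chain": r.id.chain, "seqnum": r.id.seqnum, "icode": r.id.icode, "name3": r.name3}
        for r in structure.residues
        if r.id in prediction.residue_ids
    ]
    pd.DataFrame(rows, columns=["chain", "seqnum", "icode", "name3"]).to_csv(
        path_or_buf, sep="\t", index=False
    )


def read_residue_tsv(path_or_buf) -> set[ResidueId]:
    """Read the shared residue TSV dialect back into a set of ids."""
    import pandas as pd

    df = pd.read_csv(path_or_buf, sep="\t", dtype={"chain": str})
    icode = df["icode"].fillna("") if "icode" in df else [""] * len(df)
    return {
        ResidueId(str(c), int(s), str(i).strip())
        for c, s, i in zip(df["chain"], df["seqnum"], icode)
    }
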