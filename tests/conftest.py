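"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive every quantity from first principles
(exhaustive enumeration, direct formula evaluation) without touching the
implementation's search code, so that implementation and oracle can only
agree by both being right.
"""

from __future__ import annotations

import itertools
import math

import biotite.structure as struc
import numpy as np
import pytest

from mimotree.core import Mimotope, Seed, SeedConnection
from mimotree.descriptors import MatchPolicy, default_table, property_distance
from mimotree.fixtures import FixtureSpec, make_toy_antigen
from mimotree.structure import AntigenResidue, AntigenStructure, ResidueId, SurfaceMap

# ---------------------------------------------------------------------------
# synthetic structure helpers


def graph_structure(nodes):
    """Build an AntigenStructure from (rid, aa1, n_xyz) triples.

    Only the fields used by the seed search and connection steps are
    populated; the atom array stays empty.
    """
    residues = []
    for rid, aa1, n_xyz in nodes:
        residues.append(
            AntigenResidue(
                id=rid,
                name3="XXX" if aa1 is None else aa1,
                aa1=aa1,
                ca_xyz=None if n_xyz is None else np.asarray(n_xyz, float),
                n_xyz=None if n_xyz is None else np.asarray(n_xyz, float),
            )
        )
    return AntigenStructure(residues=residues, atoms=struc.AtomArray(0))


def random_toy_surface(rng, n_max=12, aa_pool="ACDEFGHIKLMNPQRSTVWY"):
    """A random toy surface graph: structure + symmetric SurfaceMap."""
    n = int(rng.integers(4, n_max + 1))
    rids = [ResidueId("A", i + 1, "") for i in range(n)]
    aas = [aa_pool[rng.integers(len(aa_pool))] for _ in range(n)]
    coords = rng.uniform(0, 25, size=(n, 3))
    structure = graph_structure(list(zip(rids, aas, coords)))
    adjacency = {rid: [] for rid in rids}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.35:
                adjacency[rids[i]].append(rids[j])
                adjacency[rids[j]].append(rids[i])
    return structure, SurfaceMap(adjacency=adjacency)


# ---------------------------------------------------------------------------
# brute-force oracles


def oracle_seeds(mimotope, surface_map, structure, policy, min_seed_len=2):
    """Exhaustive simple-path enumeration filtered by the match predicate.

    Iterative frontier expansion (not the implementation's recursive DFS):
    enumerate ALL matching simple paths per start position, then keep the
    maximal ones.
    """
    seq = mimotope.sequence
    table = policy.table

    def matches(mchar, rid):
        aa = structure.by_id[rid].aa1
        return aa is not None and property_distance(mchar, aa, table) <= policy.pd_cutoff

    found = set()
    for start in range(len(seq)):
        # all matching simple paths starting at this mimotope position
        frontier = [
            (rid,) for rid in surface_map.adjacency if matches(seq[start], rid)
        ]
        all_paths = list(frontier)
        while frontier:
            new = []
            for path in frontier:
                pos = start + len(path)
                if pos >= len(seq):
                    continue
                for nb in surface_map.adjacency[path[-1]]:
                    if nb not in path and matches(seq[pos], nb):
                        new.append(path + (nb,))
            all_paths.extend(new)
            frontier = new

        path_set = set(all_paths)
        for path in all_paths:
            if len(path) < min_seed_len:
                continue
            pos = start + len(path)
            extendable = pos < len(seq) and any(
                nb not in path and matches(seq[pos], nb)
                for nb in surface_map.adjacency[path[-1]]
            )
            if extendable:
                continue
            found.add(
                Seed(
                    mimotope_id=mimotope.id,
                    span=(start + 1, start + len(path)),
                    path=path,
                    pd_values=tuple(
                        property_distance(seq[start + k], structure.by_id[r].aa1, table)
                        for k, r in enumerate(path)
                    ),
                )
            )
    return found


def oracle_connections(seeds, structure, nn_step=3.5):
    """Exhaustive enumeration over all seed subsets with the pairwise test."""
    seeds = sorted(seeds, key=lambda s: (s.span, s.path))
    valid = set()
    for r in range(1, len(seeds) + 1):
        for combo in itertools.combinations(seeds, r):
            chain = sorted(combo, key=lambda s: (s.span, s.path))
            residues = [rid for s in chain for rid in s.path]
            if len(set(residues)) != len(residues):
                continue
            ok = True
            for a, b in zip(chain, chain[1:]):
                gap = b.span[0] - a.span[1] - 1
                if gap < 0:
                    ok = False
                    break
                na = structure.by_id[a.path[-1]].n_xyz
                nb = structure.by_id[b.path[0]].n_xyz
                if na is None or nb is None:
                    ok = False
                    break
                if float(np.linalg.norm(na - nb)) > (gap + 1) * nn_step:
                    ok = False
                    break
            if ok:
                valid.add(tuple(chain))
    return {SeedConnection(mimotope_id=c[0].mimotope_id, seeds=c) for c in valid}


def oracle_selection(connections, avg_pd_max=2.0):
    """Direct filter-then-union of the two selection clauses."""
    if not connections:
        return set()
    longest = max(c.matched_length for c in connections)
    picked = [
        c
        for c in connections
        if all(v == 0.0 for v in c.pd_values)
        or (c.matched_length == longest and 0.0 < c.avg_pd <= avg_pd_max)
    ]
    out = set()
    for c in picked:
        out.update(c.residues())
    return out


def oracle_hypergeom_tail(k, n, N, M):
    """Upper-tail hypergeometric probability via math.comb."""
    total = math.comb(N, n)
    return sum(
        math.comb(M, x) * math.comb(N - M, n - x)
        for x in range(k, min(n, M) + 1)
    ) / total


def oracle_wilcoxon_greater(a, b):
    """Exact one-sided signed-rank p by enumerating all sign assignments."""
    from scipy.stats import rankdata

    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-9:
            count += 1
    return count / 2**n


# ---------------------------------------------------------------------------
# pytest fixtures


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def policy(table):
    return MatchPolicy(pd_cutoff=8.0, table=table)


#: chain sequence whose epitope block (positions 15-26) splits into two
#: halves with disjoint letter sets ({A,C} then {K,W}), so no k-mer of one
#: half can match the other in either path direction, and whose flanks use
#: letters that cannot exactly match the epitope at all
DESIGNED_SEQUENCE = "GPGPGPGPGPGPGP" + "ACACCA" + "KWKKWW" + "GPGPGPGPGPGPGP"


@pytest.fixture(scope="session")
def designed_toy():
    spec = FixtureSpec(
        length=len(DESIGNED_SEQUENCE),
        geometry="extended",
        epitope_positions=tuple(range(15, 27)),
        sequence=DESIGNED_SEQUENCE,
        seed=0,
    )
    return make_toy_antigen(spec)


TWO_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.800   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.200   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.400   0.800   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.400   2.000   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.800   0.800   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       5.000   0.000   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       6.200   0.800   0.000  1.00  0.00           C
ATOM      8  O   GLY A   2       6.200   2.000   0.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.800   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.200   0.000   0.000  0.40  0.00           C
ATOM      3  CA BALA A   1       1.300   0.100   0.000  0.60  0.00           C
ATOM      4  C   ALA A   1       2.400   0.800   0.000  1.00  0.00           C
ATOM      5  O   ALA A   1       2.400   2.000   0.000  1.00  0.00           O
END
"""
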