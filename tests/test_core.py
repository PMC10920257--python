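"""Seed search, gap geometry, seed connection and prediction selection."""

import numpy as np
import pytest

from conftest import (
    graph_structure,
    oracle_connections,
    oracle_seeds,
    oracle_selection,
    random_toy_surface,
)
from mimotree.config import RunConfig
from mimotree.core import (
    Mimotope,
    Seed,
    SeedConnection,
    connect_seeds,
    find_seeds,
    gap_span_limit,
    load_mimotopes,
    run_mimotree,
    select_prediction,
)
from mimotree.descriptors import MatchPolicy
from mimotree.fixtures import FixtureSpec, make_toy_antigen
from mimotree.structure import ResidueId, SurfaceMap, parse_structure


def rid(i):
    return ResidueId("A", i, "")


def path_map(*ids):
    """Linear surface map over the given residue ids."""
    adjacency = {r: [] for r in ids}
    for a, b in zip(ids, ids[1:]):
        adjacency[a].append(b)
        adjacency[b].append(a)
    return SurfaceMap(adjacency=adjacency)


# ---------------------------------------------------------------------------
# mimotope loading


def test_load_mimotopes_plain_fasta_and_dedup():
    plain = load_mimotopes("ACDEF\nKLMNP\nACDEF\n")
    assert [m.sequence for m in plain] == ["ACDEF", "KLMNP"]
    fasta = load_mimotopes(">pep1\nACD\nEF\n>pep2\nKLMNP\n")
    assert [(m.id, m.sequence) for m in fasta] == [("pep1", "ACDEF"), ("pep2", "KLMNP")]
    with pytest.raises(ValueError, match="length"):
        Mimotope(id="x", sequence="A")
    with pytest.raises(ValueError, match="non-standard"):
        Mimotope(id="x", sequence="ACXZ")


# ---------------------------------------------------------------------------
# seed search


def test_exact_match_recovered_as_full_seed(policy):
    ids = [rid(i) for i in range(1, 6)]
    coords = [(3.8 * i, 0, 0) for i in range(5)]
    structure = graph_structure(list(zip(ids, "ACKWG", coords)))
    seeds = find_seeds(Mimotope("m", "ACKWG"), path_map(*ids), structure, policy)
    full = [s for s in seeds if s.span == (1, 5)]
    assert len(full) == 1
    assert full[0].path == tuple(ids)
    assert all(v == 0.0 for v in full[0].pd_values)


def test_no_match_gives_empty_list(policy):
    ids = [rid(1), rid(2)]
    structure = graph_structure([(ids[0], "G", (0, 0, 0)), (ids[1], "P", (3.8, 0, 0))])
    # A and C match neither G nor P at cutoff 8
    assert find_seeds(Mimotope("m", "AC"), path_map(*ids), structure, policy) == []


def test_nonstandard_residues_never_match(policy):
    ids = [rid(1), rid(2), rid(3)]
    structure = graph_structure(
        [(ids[0], "A", (0, 0, 0)), (ids[1], None, (3.8, 0, 0)), (ids[2], "A", (7.6, 0, 0))]
    )
    seeds = find_seeds(Mimotope("m", "AA"), path_map(*ids), structure, policy)
    assert seeds == []  # the only adjacent pairs run through the unknown residue


@pytest.mark.parametrize("seed", range(25))
def test_seed_search_equals_exhaustive_enumeration(seed, policy):
    rng = np.random.default_rng(seed)
    structure, smap = random_toy_surface(rng)
    seq = "".join(
        "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)] for _ in range(int(rng.integers(3, 7)))
    )
    mimo = Mimotope("m", seq)
    got = set(find_seeds(mimo, smap, structure, policy))
    assert got == oracle_seeds(mimo, smap, structure, policy)


def test_seed_set_monotone_in_pd_cutoff(table):
    rng = np.random.default_rng(123)
    structure, smap = random_toy_surface(rng)
    mimo = Mimotope("m", "ACKW")
    spans_by_cutoff = []
    for cutoff in (2.0, 5.0, 8.0, 12.0):
        seeds = find_seeds(mimo, smap, structure, MatchPolicy(cutoff, table))
        spans_by_cutoff.append({(s.span, s.path) for s in seeds})
    # a seed found at a lower cutoff survives (possibly extended) at a higher
    # one: every lower-cutoff path is a prefix of some higher-cutoff path
    for lo, hi in zip(spans_by_cutoff, spans_by_cutoff[1:]):
        for span, path in lo:
            assert any(
                h_span[0] == span[0]
                and h_span[1] >= span[1]
                and h_path[: len(path)] == path
                for h_span, h_path in hi
            )


# ---------------------------------------------------------------------------
# gap geometry


def test_gap_span_limit_worked_example():
    assert gap_span_limit(2, 3.5) == pytest.approx(10.5)
    assert gap_span_limit(0) == pytest.approx(3.5)
    for nn in (3.4, 3.5, 3.6, 3.7, 3.8):
        assert gap_span_limit(5, nn) == pytest.approx(6 * nn)
    with pytest.raises(ValueError):
        gap_span_limit(-1)


def _two_seed_case(nn_distance):
    """Two seeds from a 7-residue mimotope (spans 1-3 and 6-7, gap 2);
    the flanking N-N distance is set directly."""
    a = [rid(i) for i in (1, 2, 3)]
    b = [rid(i) for i in (10, 11)]
    coords = {
        1: (0, 0, 0), 2: (3.5, 0, 0), 3: (7, 0, 0),
        10: (7 + nn_distance, 0, 0), 11: (7 + nn_distance + 3.5, 0, 0),
    }
    structure = graph_structure([(r, "A", coords[r.seqnum]) for r in a + b])
    seeds = [
        Seed("m", (1, 3), tuple(a), (0.0, 0.0, 0.0)),
        Seed("m", (6, 7), tuple(b), (0.0, 0.0)),
    ]
    return seeds, structure


def test_connection_boundary_inclusive_at_gap_limit():
    seeds, structure = _two_seed_case(10.4)
    lengths = {c.matched_length for c in connect_seeds(seeds, structure)}
    assert 5 in lengths  # the 3+2 chain was made
    seeds, structure = _two_seed_case(10.5)
    assert 5 in {c.matched_length for c in connect_seeds(seeds, structure)}
    seeds, structure = _two_seed_case(10.6)
    assert 5 not in {c.matched_length for c in connect_seeds(seeds, structure)}


def test_single_seeds_are_connections():
    seeds, structure = _two_seed_case(50.0)
    conns = connect_seeds(seeds, structure)
    assert {c.matched_length for c in conns} == {2, 3}


def test_overlapping_spans_never_chain():
    a = [rid(1), rid(2)]
    b = [rid(5), rid(6)]
    structure = graph_structure(
        [(r, "A", (r.seqnum, 0, 0)) for r in a + b]
    )
    seeds = [
        Seed("m", (1, 2), tuple(a), (0.0, 0.0)),
        Seed("m", (2, 3), tuple(b), (0.0, 0.0)),
    ]
    assert all(len(c.seeds) == 1 for c in connect_seeds(seeds, structure))


@pytest.mark.parametrize("seed", range(20))
def test_connections_equal_bruteforce_subsets(seed, policy):
    rng = np.random.default_rng(1000 + seed)
    structure, smap = random_toy_surface(rng)
    seq = "".join("ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)] for _ in range(5))
    seeds = find_seeds(Mimotope("m", seq), smap, structure, policy)
    if len(seeds) > 9:  # keep the 2^n subset oracle tractable
        seeds = seeds[:: max(1, len(seeds) // 9)][:9]
    got = set(connect_seeds(seeds, structure))
    assert got == oracle_connections(seeds, structure)


def test_connection_set_monotone_in_nn_step():
    seeds, structure = _two_seed_case(12.0)
    small = set(connect_seeds(seeds, structure, nn_step=3.4))
    large = set(connect_seeds(seeds, structure, nn_step=4.1))
    assert small <= large


# ---------------------------------------------------------------------------
# prediction selection


def _conn(ids, pds):
    path = tuple(rid(i) for i in ids)
    return SeedConnection(
        mimotope_id="m",
        seeds=(Seed("m", (1, len(ids)), path, tuple(pds)),),
    )


def test_single_perfect_connection_is_the_prediction():
    c = _conn([1, 2, 3], [0.0, 0.0, 0.0])
    pred = select_prediction([c])
    assert pred.residue_ids == {rid(1), rid(2), rid(3)}


def test_short_inexact_connection_contributes_nothing():
    long_perfect = _conn([1, 2, 3, 4], [0.0] * 4)
    short_bad = _conn([8, 9], [2.5, 2.5])
    pred = select_prediction([long_perfect, short_bad])
    assert pred.residue_ids == {rid(1), rid(2), rid(3), rid(4)}


def test_longest_inexact_within_avg_bound_included():
    longest = _conn([1, 2, 3, 4], [1.0, 1.0, 1.0, 1.0])
    shorter = _conn([8, 9, 10], [0.5, 0.5, 0.5])
    pred = select_prediction([longest, shorter])
    assert pred.residue_ids == {rid(1), rid(2), rid(3), rid(4)}


def test_empty_pool_gives_empty_prediction():
    assert select_prediction([]).residue_ids == set()


@pytest.mark.parametrize("seed", range(20))
def test_selection_equals_bruteforce_filter_union(seed):
    rng = np.random.default_rng(2000 + seed)
    pool = []
    for _ in range(int(rng.integers(2, 8))):
        length = int(rng.integers(2, 6))
        ids = list(rng.choice(np.arange(1, 40), size=length, replace=False))
        pds = [float(rng.choice([0.0, 0.0, 0.7, 1.8, 3.0])) for _ in range(length)]
        pool.append(_conn([int(i) for i in ids], pds))
    pred = select_prediction(pool)
    assert pred.residue_ids == oracle_selection(pool)


# ---------------------------------------------------------------------------
# end-to-end


def test_near_exact_epitope_fraction_recovers_matching_sensitivity(designed_toy):
    """Feeding part of the epitope's own antigen sequence as the sole
    mimotope yields sensitivity equal to the fraction supplied."""
    s = parse_structure(designed_toy.pdb_text)
    half = designed_toy.epitope_sequence[:6]  # 6 of 12 epitope residues
    pred = run_mimotree(s, [Mimotope("near_exact", half)])
    epitope = {rid(p) for p in designed_toy.epitope_positions}
    covered = pred.residue_ids & epitope
    assert len(covered) / len(epitope) == pytest.approx(0.5)
    assert pred.residue_ids <= epitope  # designed flanks cannot match exactly


def test_near_exact_with_natural_gap(designed_toy):
    """The supplied stretch may carry a non-matching insertion; the gap is
    bridged on the structure and sensitivity is unchanged."""
    s = parse_structure(designed_toy.pdb_text)
    half = designed_toy.epitope_sequence[:6]
    gapped = half[:3] + "RR" + half[3:]  # R matches only K among chain letters
    pred = run_mimotree(s, [Mimotope("gapped", gapped)])
    epitope = {rid(p) for p in designed_toy.epitope_positions}
    assert len(pred.residue_ids & epitope) / len(epitope) == pytest.approx(0.5)


def test_empty_mimotope_set_gives_empty_prediction(designed_toy):
    s = parse_structure(designed_toy.pdb_text)
    assert run_mimotree(s, []).residue_ids == set()


def test_planted_epitope_contained_in_prediction(designed_toy):
    s = parse_structure(designed_toy.pdb_text)
    pred = run_mimotree(s, [Mimotope("full", designed_toy.epitope_sequence)])
    epitope = {rid(p) for p in designed_toy.epitope_positions}
    assert epitope <= pred.residue_ids


def test_determinism(designed_toy):
    mimos = [Mimotope("m1", designed_toy.epitope_sequence[:7]),
             Mimotope("m2", designed_toy.epitope_sequence[4:])]
    runs = []
    for _ in range(2):
        s = parse_structure(designed_toy.pdb_text)
        runs.append(run_mimotree(s, mimos).residue_ids)
    assert runs[0] == runs[1]


def test_bridgeable_gap_carries_no_penalty():
    """Inserting a bridgeable gap leaves the matched positions' average PD
    untouched (no gap penalty anywhere in the scoring)."""
    ids = [rid(i) for i in range(1, 7)]
    coords = [(3.4 * i, 0, 0) for i in range(6)]
    structure = graph_structure(list(zip(ids, "ACKWCA", coords)))
    smap = path_map(*ids)
    policy = MatchPolicy()
    plain = Mimotope("plain", "ACKWCA")
    gapped = Mimotope("gapped", "ACK" + "RR" + "WCA")

    def best_avg(mimo):
        seeds = find_seeds(mimo, smap, structure, policy)
        conns = connect_seeds(seeds, structure)
        full = [c for c in conns if c.matched_length == 6]
        assert full
        return min(c.avg_pd for c in full)

    assert best_avg(gapped) == pytest.approx(best_avg(plain))


def test_prediction_residues_are_surface_residues(designed_toy):
    from mimotree.structure import compute_sasa, select_surface_residues

    s = parse_structure(designed_toy.pdb_text)
    pred = run_mimotree(s, [Mimotope("m", designed_toy.epitope_sequence[:8])])
    s2 = parse_structure(designed_toy.pdb_text)
    compute_sasa(s2)
    surface = select_surface_residues(s2)
    assert pred.residue_ids <= surface
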