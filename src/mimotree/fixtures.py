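"""Synthetic toy antigens with planted epitopes, and derived mimotope sets.

These generators make every pipeline stage testable without downloading
structures.  A toy antigen is a single backbone-only chain (N, CA, C, O
atoms) laid out on one of three geometries:

``extended``
    a straight chain, 3.8 Angstrom CA spacing; every residue is exposed.
``helical``
    an ideal alpha-helix (2.3 Angstrom radius, 100 degrees and 1.5
    Angstrom rise per residue); every residue is exposed.
``lattice-fold``
    a serpentine fold through a cubic lattice at 3.4 Angstrom spacing;
    interior lattice cells are packed tightly enough that a 1.4 Angstrom
    probe cannot reach them, giving genuinely buried core residues.

The planted epitope is a set of residue positions guaranteed to be
surface-exposed.  By default the epitope sequence is drawn from the
alphabet {A, C, K, W} -- mutually non-matching at the default PD cutoff
of 8 -- and the remaining chain from {G, P}, whose PD to every epitope
letter exceeds 8, so exact (PD = 0) mimotope matches off the epitope
cannot occur by construction.

Mimotopes are derived from the epitope sequence as sliding windows with
PD-bounded substitutions and optional inserted gap runs, emulating
phage-display peptides that are similar but not identical to the epitope.
Side chains are not modelled; the 5% surface threshold still applies via
the standard Gly-X-Gly maximal-SASA table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Mimotope
from .descriptors import AMINO_ACIDS, matching_partners

__all__ = [
    "FixtureSpec",
    "GapSpec",
    "ToyAntigen",
    "MimotopeTruth",
    "make_toy_antigen",
    "make_mimotopes",
]

#: Epitope alphabet: pairwise PD > 8 (no two letters match each other).
EPITOPE_ALPHABET = "ACKW"
#: Flank alphabet: PD > 8 to every epitope letter.
FLANK_ALPHABET = "GP"

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


@dataclass(frozen=True)
class GapSpec:
    """Inserted gap runs per mimotope: how many, how long, drawn from where."""

    count: int = 0
    length: int = 2
    alphabet: str = "".join(AMINO_ACIDS)

    def __post_init__(self) -> None:
        if self.count < 0 or self.length < 1:
            raise ValueError("gap count must be >= 0 and gap length >= 1")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a toy antigen."""

    length: int = 40
    geometry: str = "extended"
    epitope_positions: tuple[int, ...] = tuple(range(15, 27))  # 1-based resnums
    sequence: str | None = None  # optional explicit chain sequence
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("extended", "helical", "lattice-fold"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.length < 2:
            raise ValueError("chain length must be >= 2")
        if not self.epitope_positions:
            raise ValueError("planted epitope must be non-empty")
        if min(self.epitope_positions) < 1 or max(self.epitope_positions) > self.length:
            raise ValueError("planted epitope positions must lie within the chain")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("explicit sequence length must equal chain length")


@dataclass
class ToyAntigen:
    """Generated structure plus its ground truth."""

    pdb_text: str
    sequence: str
    epitope_positions: tuple[int, ...]  # 1-based residue numbers, chain A
    core_positions: tuple[int, ...]  # expected buried residues (lattice-fold)
    spec: FixtureSpec

    @property
    def epitope_sequence(self) -> str:
        return "".join(self.sequence[p - 1] for p in sorted(self.epitope_positions))


def _ca_trace(spec: FixtureSpec) -> tuple[np.ndarray, tuple[int, ...]]:
    """CA coordinates for the chosen geometry plus buried-core annotation."""
    L = spec.length
    if spec.geometry == "extended":
        ca = np.stack([[3.8 * i, 0.0, 0.0] for i in range(L)])
        return ca, ()
    if spec.geometry == "helical":
        theta = np.deg2rad(100.0) * np.arange(L)
        ca = np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * np.arange(L)], axis=1)
        return ca, ()
    # lattice-fold: boustrophedon walk through a cube, 3.4 A spacing
    side = max(2, math.ceil(L ** (1 / 3)))
    cells: list[tuple[int, int, int]] = []
    for iz in range(side):
        for iy in range(side):
            ys = iy if iz % 2 == 0 else side - 1 - iy
            xr = range(side) if ys % 2 == 0 else range(side - 1, -1, -1)
            for ix in xr:
                cells.append((ix, ys, iz))
    cells = cells[:L]
    occupied = set(cells)
    core = tuple(
        i + 1
        for i, (x, y, z) in enumerate(cells)
        if all(
            (x + dx, y + dy, z + dz) in occupied
            for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        )
    )
    ca = 3.4 * np.asarray(cells, dtype=float)
    return ca, core


def _backbone(ca: np.ndarray) -> dict[str, np.ndarray]:
    """Place N, C, O around each CA along the local chain direction."""
    L = len(ca)
    n = np.empty_like(ca)
    c = np.empty_like(ca)
    for i in range(L):
        prev_dir = ca[i - 1] - ca[i] if i > 0 else ca[i] - ca[i + 1]
        next_dir = ca[i + 1] - ca[i] if i < L - 1 else ca[i] - ca[i - 1]
        n[i] = ca[i] + 1.45 * prev_dir / np.linalg.norm(prev_dir)
        c[i] = ca[i] + 1.52 * next_dir / np.linalg.norm(next_dir)
    # carbonyl O: offset perpendicular to the CA->C direction
    o = np.empty_like(ca)
    for i in range(L):
        d = c[i] - ca[i]
        perp = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(d, [0.0, 1.0, 0.0])
        o[i] = c[i] + 1.23 * perp / np.linalg.norm(perp)
    return {"N": n, "CA": ca, "C": c, "O": o}


def _chain_sequence(spec: FixtureSpec, rng: np.random.Generator) -> str:
    if spec.sequence is not None:
        return spec.sequence.upper()
    epi = set(spec.epitope_positions)
    letters = [
        (EPITOPE_ALPHABET if (i + 1) in epi else FLANK_ALPHABET) for i in range(spec.length)
    ]
    return "".join(alpha[rng.integers(len(alpha))] for alpha in letters)


def make_toy_antigen(spec: FixtureSpec) -> ToyAntigen:
    """Generate a toy antigen; deterministic under ``spec.seed``.

    Raises ``ValueError`` if a planted epitope position falls on a buried
    lattice core cell (the epitope must be surface-exposed).
    """
    rng = np.random.default_rng(spec.seed)
    ca, core = _ca_trace(spec)
    clash = set(spec.epitope_positions) & set(core)
    if clash:
        raise ValueError(
            f"planted epitope positions {sorted(clash)} are buried core cells; "
            f"choose surface positions"
        )
    seq = _chain_sequence(spec, rng)
    atoms = _backbone(ca)

    lines: list[str] = []
    serial = 1
    for i in range(spec.length):
        res3 = _AA3[seq[i]]
        for name in ("N", "CA", "C", "O"):
            x, y, z = atoms[name][i]
            element = name[0]
            lines.append(
                f"ATOM  {serial:>5} {name.center(4)} {res3:>3} A{i + 1:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2}"
            )
            serial += 1
    lines.append("END")
    return ToyAntigen(
        pdb_text="\n".join(lines) + "\n",
        sequence=seq,
        epitope_positions=tuple(sorted(spec.epitope_positions)),
        core_positions=core,
        spec=spec,
    )


def make_toy_complex(
    length: int = 30,
    contact_start: int = 10,
    contact_end: int = 20,
    gap: float = 4.8,
    seed: int = 0,
) -> tuple[str, tuple[int, ...]]:
    """Two-chain contact fixture for the true-epitope machinery.

    Chain A is an extended "antigen"; a shorter extended "antibody" chain B
    floats ``gap`` Angstrom above antigen residues ``contact_start`` to
    ``contact_end`` (1-based, inclusive), burying part of their accessible
    surface.  Returns the complex PDB text and the contacted antigen
    residue numbers.
    """
    if not (1 <= contact_start <= contact_end <= length):
        raise ValueError("contact span must lie within the chain")
    rng = np.random.default_rng(seed)
    spec_a = FixtureSpec(length=length, geometry="extended",
                         epitope_positions=tuple(range(contact_start, contact_end + 1)),
                         seed=seed)
    ca_a, _ = _ca_trace(spec_a)
    seq_a = _chain_sequence(spec_a, rng)
    n_b = contact_end - contact_start + 1
    ca_b = ca_a[contact_start - 1 : contact_end].copy()
    ca_b[:, 1] += gap
    seq_b = "".join("G" for _ in range(n_b))

    lines: list[str] = []
    serial = 1
    for chain, seq, ca in (("A", seq_a, ca_a), ("B", seq_b, ca_b)):
        atoms = _backbone(ca)
        for i in range(len(ca)):
            res3 = _AA3[seq[i]]
            for name in ("N", "CA", "C", "O"):
                x, y, z = atoms[name][i]
                lines.append(
                    f"ATOM  {serial:>5} {name.center(4)} {res3:>3} {chain}{i + 1:>4}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {name[0]:>2}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n", tuple(range(contact_start, contact_end + 1))


@dataclass(frozen=True)
class MimotopeTruth:
    """A generated mimotope with its ground-truth alignment.

    ``alignment[k]`` is the 0-based epitope-sequence position matched by
    mimotope position ``k``, or ``None`` for inserted gap residues.
    """

    mimotope: Mimotope
    window: tuple[int, int]  # 0-based [start, end) in the epitope sequence
    alignment: tuple[int | None, ...]
    n_substitutions: int


def make_mimotopes(
    epitope_sequence: str,
    n: int,
    substitution_rate: float = 0.0,
    pd_budget: float = 8.0,
    gap_spec: GapSpec | None = None,
    seed: int = 0,
    window_len: int | None = None,
) -> list[MimotopeTruth]:
    """Derive ``n`` mimotopes from an epitope sequence.

    Each mimotope is a window of the epitope sequence (window starts are
    laid out so that the windows jointly cover the whole epitope, with any
    remaining windows placed at random), in which each position is
    substituted with probability ``substitution_rate`` by a uniformly drawn
    amino acid whose PD to the original is positive but at most
    ``pd_budget`` (positions with no such partner are left unchanged), and
    into which ``gap_spec.count`` runs of ``gap_spec.length`` residues from
    ``gap_spec.alphabet`` are inserted at random internal points.
    Deterministic under ``seed``.
    """
    if not epitope_sequence:
        raise ValueError("epitope sequence must be non-empty")
    if not 0.0 <= substitution_rate <= 1.0:
        raise ValueError("substitution_rate must be in [0, 1]")
    gap_spec = gap_spec or GapSpec()
    rng = np.random.default_rng(seed)
    L = len(epitope_sequence)
    w = min(window_len or 8, L)
    if w < 2:
        raise ValueError("mimotope window must have length >= 2")

    # window starts guaranteeing joint coverage of the epitope sequence
    n_cover = max(1, math.ceil((L - w) / max(1, w - 1)) + 1)
    cover_starts = np.unique(
        np.linspace(0, L - w, num=min(n, n_cover)).round().astype(int)
    )
    starts = list(cover_starts) + [
        int(rng.integers(0, L - w + 1)) for _ in range(n - len(cover_starts))
    ]

    partner_cache = {
        aa: matching_partners(aa, pd_budget, include_self=False) for aa in set(epitope_sequence)
    }
    out: list[MimotopeTruth] = []
    for idx, start in enumerate(starts[:n]):
        window = list(epitope_sequence[start : start + w])
        align: list[int | None] = list(range(start, start + w))
        n_sub = 0
        for k in range(len(window)):
            if rng.random() < substitution_rate:
                partners = partner_cache[window[k]]
                if partners:
                    window[k] = partners[rng.integers(len(partners))]
                    n_sub += 1
        for _ in range(gap_spec.count):
            pos = int(rng.integers(1, len(window)))  # internal insertion point
            run = [gap_spec.alphabet[rng.integers(len(gap_spec.alphabet))]
                   for _ in range(gap_spec.length)]
            window[pos:pos] = run
            align[pos:pos] = [None] * gap_spec.length
        out.append(
            MimotopeTruth(
                mimotope=Mimotope(id=f"syn{idx + 1}", sequence="".join(window)),
                window=(start, start + w),
                alignment=tuple(align),
                n_substitutions=n_sub,
            )
        )
    return out
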