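"""Antigen structure handling: PDB parsing, per-residue SASA, surface map.

The algorithm operates on the *surface* of the antigen.  A residue is on
the surface when its solvent-accessible surface area (SASA, probe radius
1.4 Angstrom) exceeds 5% of its maximal SASA, where the maximal SASA is the
residue's area in an extended Gly-X-Gly tripeptide.  Surface residues are
then connected into an adjacency map (default: alpha-carbon pairs within
4 Angstrom) on which the seed search runs.

SASA is computed with the Shrake-Rupley algorithm (biotite implementation;
element van-der-Waals radii, Fibonacci sphere sampling with a fixed point
count, hydrogens ignored), which makes the values deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, NamedTuple, Sequence

import biotite.structure as struc
import numpy as np
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "MAX_SASA_GLY_X_GLY",
    "AntigenResidue",
    "AntigenStructure",
    "ResidueId",
    "SurfaceMap",
    "build_surface_map",
    "compute_sasa",
    "parse_structure",
    "select_surface_residues",
    "write_surface_report",
]

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine is treated as methionine
    "MSE": "M",
}

#: Maximal per-residue SASA (Angstrom^2) in an extended Gly-X-Gly tripeptide
#: (theoretical values; denominator of the 5% surface threshold).
MAX_SASA_GLY_X_GLY: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
    "MSE": 224.0,
}

#: Shrake-Rupley sphere points per atom; fixed for determinism.
DEFAULT_SASA_POINTS = 960


class PDBFormatError(ValueError):
    """The input text could not be interpreted as a PDB structure."""


class ChainNotFoundError(KeyError):
    """A requested chain is absent from the structure."""

    def __init__(self, missing: Sequence[str], available: Sequence[str]):
        super().__init__(tuple(missing))
        self.missing = list(missing)
        self.available = list(available)

    def __str__(self) -> str:  # noqa: D105
        return (
            f"chain(s) {','.join(self.missing)} not present; "
            f"available chains: {','.join(self.available)}"
        )


class ResidueId(NamedTuple):
    """Identity of a residue: chain id, author sequence number, insertion code."""

    chain: str
    seqnum: int
    icode: str = ""

    def __str__(self) -> str:  # noqa: D105
        return f"{self.chain}{self.seqnum}{self.icode}"


@dataclass
class AntigenResidue:
    """One polymer residue with coordinates and (once computed) SASA."""

    id: ResidueId
    name3: str
    aa1: str | None
    ca_xyz: np.ndarray | None
    n_xyz: np.ndarray | None
    sasa: float | None = None
    max_sasa: float | None = None
    is_surface: bool = False


@dataclass
class AntigenStructure:
    """Parsed antigen: ordered residues plus the underlying atom array."""

    residues: list[AntigenResidue]
    atoms: struc.AtomArray
    source: str = ""
    by_id: dict[ResidueId, AntigenResidue] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.by_id:
            self.by_id = {r.id: r for r in self.residues}
        if len(self.by_id) != len(self.residues):
            raise ValueError("duplicate residue identifiers in structure")

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.id.chain, None)
        return list(seen)

    def subset(self, chains: Iterable[str]) -> "AntigenStructure":
        """New structure restricted to ``chains`` (same coordinates)."""
        chains = list(chains)
        mask = np.isin(self.atoms.chain_id, chains)
        residues = [r for r in self.residues if r.id.chain in chains]
        return AntigenStructure(
            residues=[
                AntigenResidue(r.id, r.name3, r.aa1, r.ca_xyz, r.n_xyz) for r in residues
            ],
            atoms=self.atoms[mask],
            source=self.source,
        )


def parse_structure(
    pdb_text: str | IO[str], chains: Sequence[str] | None = None, source: str = ""
) -> AntigenStructure:
    """Parse PDB text into an :class:`AntigenStructure`.

    First model only; highest-occupancy alternate locations retained; waters
    and non-polymer HETATM records dropped.  Selenomethionine maps to Met;
    other modified polymer residues are kept as geometric obstacles but have
    no one-letter code (they never match a mimotope residue and never enter
    the surface map).
    """
    if hasattr(pdb_text, "read"):
        pdb_text = pdb_text.read()
    try:
        pdb = PDBFile.read(_as_lines(pdb_text))
        atoms = pdb.get_structure(
            model=1, altloc="occupancy", extra_fields=["occupancy"]
        )
    except Exception as exc:  # biotite raises various error types
        raise PDBFormatError(f"could not parse PDB input: {exc}") from exc
    if atoms.array_length() == 0:
        raise PDBFormatError("PDB input contains no atoms")

    # drop waters, hydrogens and non-amino-acid HETATM ligands
    keep = struc.filter_amino_acids(atoms)
    keep &= ~np.isin(atoms.element, ("H", "D"))
    atoms = atoms[keep]
    if atoms.array_length() == 0:
        raise PDBFormatError("PDB input contains no polymer (amino-acid) atoms")

    available = list(dict.fromkeys(atoms.chain_id))
    if chains is not None:
        chains = list(chains)
        missing = [c for c in chains if c not in available]
        if missing:
            raise ChainNotFoundError(missing, available)
        atoms = atoms[np.isin(atoms.chain_id, chains)]

    residues: list[AntigenResidue] = []
    for start in struc.get_residue_starts(atoms):
        chain = str(atoms.chain_id[start])
        seqnum = int(atoms.res_id[start])
        icode = str(atoms.ins_code[start]).strip()
        name3 = str(atoms.res_name[start])
        rid = ResidueId(chain, seqnum, icode)
        res_mask = (
            (atoms.chain_id == chain)
            & (atoms.res_id == seqnum)
            & (atoms.ins_code == atoms.ins_code[start])
        )
        res_atoms = atoms[res_mask]
        ca = _atom_coord(res_atoms, "CA")
        n = _atom_coord(res_atoms, "N")
        residues.append(
            AntigenResidue(
                id=rid,
                name3=name3,
                aa1=THREE_TO_ONE.get(name3),
                ca_xyz=ca,
                n_xyz=n,
            )
        )
    return AntigenStructure(residues=residues, atoms=atoms, source=source)


def _as_lines(text: str):
    import io

    return io.StringIO(text)


def _atom_coord(res_atoms: struc.AtomArray, name: str) -> np.ndarray | None:
    hit = res_atoms.atom_name == name
    if not hit.any():
        return None
    return np.asarray(res_atoms.coord[hit][0], dtype=float)


def compute_sasa(
    structure: AntigenStructure,
    probe_radius: float = 1.4,
    point_number: int = DEFAULT_SASA_POINTS,
) -> AntigenStructure:
    """Fill per-residue ``sasa`` and ``max_sasa`` in place and return the structure.

    Per-residue SASA is the sum over the residue's heavy atoms of their
    accessible areas in the context of the whole structure.
    """
    if not structure.residues:
        raise ValueError("cannot compute SASA of an empty structure")
    atoms = structure.atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        atom_sasa = struc.sasa(
            atoms,
            probe_radius=probe_radius,
            point_number=point_number,
            vdw_radii="Single",
        )
    atom_sasa = np.nan_to_num(atom_sasa, nan=0.0)
    for res in structure.residues:
        mask = (
            (atoms.chain_id == res.id.chain)
            & (atoms.res_id == res.id.seqnum)
            & (np.char.strip(atoms.ins_code.astype(str)) == res.id.icode)
        )
        res.sasa = float(atom_sasa[mask].sum())
        res.max_sasa = MAX_SASA_GLY_X_GLY.get(res.name3)
    return structure


def select_surface_residues(
    structure: AntigenStructure, fraction: float = 0.05
) -> set[ResidueId]:
    """Residues with ``sasa > fraction * max_sasa`` (strict inequality).

    Residues without a Gly-X-Gly reference (non-standard) are excluded with
    a warning.  Also refreshes each residue's ``is_surface`` flag.
    """
    surface: set[ResidueId] = set()
    for res in structure.residues:
        if res.sasa is None:
            raise ValueError("SASA not computed; call compute_sasa first")
        if res.max_sasa is None:
            logger.warning(
                "residue %s (%s) has no max-SASA reference; excluded from surface",
                res.id, res.name3,
            )
            res.is_surface = False
            continue
        res.is_surface = res.sasa > fraction * res.max_sasa
        if res.is_surface:
            surface.add(res.id)
    return surface


@dataclass
class SurfaceMap:
    """Adjacency of surface residues: residue id -> adjacent surface residue ids."""

    adjacency: dict[ResidueId, list[ResidueId]]

    def neighbors(self, rid: ResidueId) -> list[ResidueId]:
        return self.adjacency.get(rid, [])

    def __contains__(self, rid: ResidueId) -> bool:  # noqa: D105
        return rid in self.adjacency

    def __len__(self) -> int:  # noqa: D105
        return len(self.adjacency)


def build_surface_map(
    structure: AntigenStructure,
    surface_ids: set[ResidueId],
    cutoff: float = 4.0,
    metric: str = "ca",
) -> SurfaceMap:
    """Build the surface adjacency map.

    ``metric='ca'`` (default) treats two residues as adjacent when their
    alpha-carbons are within ``cutoff`` Angstrom (inclusive);
    ``metric='any-atom'`` uses the minimum heavy-atom distance instead.
    Only matchable residues (standard amino acids) with the required
    reference atom enter the map.
    """
    if metric not in ("ca", "any-atom"):
        raise ValueError(f"unknown adjacency metric {metric!r}; use 'ca' or 'any-atom'")
    members: list[AntigenResidue] = []
    for res in structure.residues:
        if res.id not in surface_ids or res.aa1 is None:
            continue
        if metric == "ca" and res.ca_xyz is None:
            logger.warning("surface residue %s lacks a CA atom; dropped from map", res.id)
            continue
        members.append(res)

    adjacency: dict[ResidueId, list[ResidueId]] = {r.id: [] for r in members}
    if metric == "ca":
        coords = np.stack([r.ca_xyz for r in members]) if members else np.empty((0, 3))
        if len(members):
            dm = cdist(coords, coords)
            close = (dm <= cutoff) & ~np.eye(len(members), dtype=bool)
            for i, j in zip(*np.nonzero(close)):
                adjacency[members[i].id].append(members[j].id)
    else:
        atoms = structure.atoms
        atom_groups = []
        for r in members:
            mask = (
                (atoms.chain_id == r.id.chain)
                & (atoms.res_id == r.id.seqnum)
                & (np.char.strip(atoms.ins_code.astype(str)) == r.id.icode)
            )
            atom_groups.append(atoms.coord[mask])
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if cdist(atom_groups[i], atom_groups[j]).min() <= cutoff:
                    adjacency[members[i].id].append(members[j].id)
                    adjacency[members[j].id].append(members[i].id)
    return SurfaceMap(adjacency=adjacency)


def write_surface_report(structure: AntigenStructure, path_or_buf) -> None:
    """Per-residue surface TSV: chain, seqnum, icode, name3, sasa, max_sasa, is_surface."""
    import pandas as pd

    rows = [
        {
            "chain": r.id.chain,
            "seqnum": r.id.seqnum,
            "icode": r.id.icode,
            "name3": r.name3,
            "sasa": None if r.sasa is None else round(r.sasa, 2),
            "max_sasa": r.max_sasa,
            "is_surface": r.is_surface,
        }
        for r in structure.residues
    ]
    pd.DataFrame(rows).to_csv(path_or_buf, sep="\t", index=False)
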