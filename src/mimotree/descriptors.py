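"""Amino-acid physicochemical property distance (PD).

Mimotope residues are rarely identical to the epitope residues they mimic,
so residue comparison is done in a five-dimensional physicochemical
descriptor space rather than by sequence identity.  Each standard amino
acid is represented by five eigen-descriptor components ``E1..E5``
(dimensionless, unit-norm eigenvector columns from a metric
multidimensional scaling of a large panel of physicochemical properties),
and each component carries an eigenvalue weight ``lambda_i``.  The
property distance between amino acids ``A`` and ``B`` is

    PD(A, B) = sqrt( sum_i lambda_i * (E_i^A - E_i^B)**2 )

Two residues whose PD does not exceed a cutoff (default 8.0) are treated
as identical during mimotope-to-surface mapping.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "DescriptorTable",
    "MatchPolicy",
    "UnknownResidueError",
    "default_table",
    "load_descriptor_table",
    "property_distance",
    "pd_matrix",
    "residues_match",
]

#: The 20 standard one-letter amino-acid codes, alphabetical.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

# Five-component eigen-descriptors per amino acid (E1..E5).  Columns are
# unit-norm over the 20 amino acids.  E1 tracks hydrophobicity, E2 size,
# E3 helix-forming propensity; E4/E5 mix rarer properties.
_E_COMPONENTS: dict[str, tuple[float, float, float, float, float]] = {
    "A": (0.008, 0.134, -0.475, -0.039, 0.181),
    "R": (0.171, -0.361, 0.107, -0.258, -0.364),
    "N": (0.255, 0.038, 0.117, 0.118, -0.055),
    "D": (0.303, -0.057, -0.014, 0.225, 0.156),
    "C": (-0.132, 0.174, 0.070, 0.565, -0.374),
    "Q": (0.149, -0.184, -0.030, 0.035, -0.112),
    "E": (0.221, -0.280, -0.315, 0.157, 0.303),
    "G": (0.218, 0.562, -0.024, 0.018, 0.106),
    "H": (0.023, -0.177, 0.041, 0.280, -0.021),
    "I": (-0.353, 0.071, -0.088, -0.195, -0.107),
    "L": (-0.267, 0.018, -0.265, -0.274, 0.206),
    "K": (0.243, -0.339, -0.044, -0.325, -0.027),
    "M": (-0.239, -0.141, -0.155, 0.321, 0.077),
    "F": (-0.329, -0.023, 0.072, -0.002, 0.208),
    "P": (0.173, 0.286, 0.407, -0.215, 0.384),
    "S": (0.199, 0.238, -0.015, -0.068, -0.196),
    "T": (0.068, 0.147, -0.015, -0.132, -0.274),
    "W": (-0.296, -0.186, 0.389, 0.083, 0.297),
    "Y": (-0.141, -0.057, 0.425, -0.096, -0.091),
    "V": (-0.274, 0.136, -0.187, -0.196, -0.299),
}

# Eigenvalue weights of the five components.  Scaled so that the finest
# amino-acid grouping under single linkage sits near PD 9.5 and cutoffs in
# the 8-10 range discriminate mid-scale (see docs/methods.md for the
# calibration); overridable via ``load_descriptor_table``.
_EIGENVALUES: tuple[float, float, float, float, float] = (524.3, 148.8, 85.7, 51.3, 35.9)


class UnknownResidueError(KeyError):
    """Raised when a one-letter code is not one of the 20 standard amino acids."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # noqa: D105
        return f"unknown amino-acid code {self.code!r}; expected one of {''.join(AMINO_ACIDS)}"


@dataclass(frozen=True)
class DescriptorTable:
    """Per-amino-acid eigen-descriptors and eigenvalue weights.

    Parameters
    ----------
    components
        Mapping from one-letter code to the five descriptor components.
    eigenvalues
        The five positive eigenvalue weights ``lambda_1..lambda_5``.
    """

    components: Mapping[str, tuple[float, ...]]
    eigenvalues: tuple[float, ...]

    def __post_init__(self) -> None:
        if set(self.components) != set(AMINO_ACIDS):
            missing = set(AMINO_ACIDS) - set(self.components)
            extra = set(self.components) - set(AMINO_ACIDS)
            raise ValueError(
                f"descriptor table must cover exactly the 20 standard amino acids "
                f"(missing: {sorted(missing)}, unexpected: {sorted(extra)})"
            )
        if len(self.eigenvalues) != 5 or any(lam <= 0 for lam in self.eigenvalues):
            raise ValueError("exactly five strictly positive eigenvalues required")
        for aa, comps in self.components.items():
            if len(comps) != 5:
                raise ValueError(f"amino acid {aa}: expected 5 components, got {len(comps)}")

    def vector(self, aa: str) -> np.ndarray:
        """Descriptor vector of ``aa``; raises :class:`UnknownResidueError`."""
        try:
            return np.asarray(self.components[aa], dtype=float)
        except KeyError:
            raise UnknownResidueError(aa) from None

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(self.eigenvalues, dtype=float)


def default_table() -> DescriptorTable:
    """The packaged descriptor table (see module docstring)."""
    return DescriptorTable(components=dict(_E_COMPONENTS), eigenvalues=_EIGENVALUES)


def load_descriptor_table(source: str | io.TextIOBase) -> DescriptorTable:
    """Load a user descriptor table from TSV.

    Format: a first line ``# lambda <l1> <l2> <l3> <l4> <l5>``, then a header
    ``aa\tE1\tE2\tE3\tE4\tE5`` and one row per amino acid.
    """
    if isinstance(source, str):
        with open(source) as fh:
            return load_descriptor_table(fh)
    lines = [ln.strip() for ln in source if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise ValueError("descriptor TSV must start with a '# lambda ...' line")
    lam_tokens = lines[0].lstrip("#").split()
    if lam_tokens and lam_tokens[0].lower() == "lambda":
        lam_tokens = lam_tokens[1:]
    eigenvalues = tuple(float(t) for t in lam_tokens)
    components: dict[str, tuple[float, ...]] = {}
    for ln in lines[1:]:
        fields = ln.split("\t") if "\t" in ln else ln.split()
        if fields[0].lower() == "aa":
            continue
        components[fields[0]] = tuple(float(x) for x in fields[1:6])
    return DescriptorTable(components=components, eigenvalues=eigenvalues)


@dataclass(frozen=True)
class MatchPolicy:
    """Decides when two amino acids count as identical.

    ``pd_cutoff`` is the inclusive PD bound: residues with
    ``PD <= pd_cutoff`` match ("a PD of 8 or less" is the working default).
    """

    pd_cutoff: float = 8.0
    table: DescriptorTable = field(default_factory=default_table)

    def __post_init__(self) -> None:
        if self.pd_cutoff < 0:
            raise ValueError(f"pd_cutoff must be non-negative, got {self.pd_cutoff}")


def property_distance(a: str, b: str, table: DescriptorTable | None = None) -> float:
    """Weighted Euclidean distance between two amino acids in descriptor space.

    Symmetric, non-negative, and zero exactly when the two descriptor
    vectors coincide (which for the packaged table means ``a == b``).
    """
    table = table or default_table()
    da = table.vector(a)
    db = table.vector(b)
    return float(math.sqrt(float(np.sum(table.weights * (da - db) ** 2))))


def pd_matrix(table: DescriptorTable | None = None) -> np.ndarray:
    """The full 20x20 PD matrix, ordered by :data:`AMINO_ACIDS`."""
    table = table or default_table()
    vecs = np.stack([table.vector(aa) for aa in AMINO_ACIDS])
    diff = vecs[:, None, :] - vecs[None, :, :]
    return np.sqrt(np.sum(table.weights * diff**2, axis=-1))


def residues_match(
    a: str, b: str, policy: MatchPolicy | None = None, table: DescriptorTable | None = None
) -> bool:
    """True iff ``PD(a, b) <= policy.pd_cutoff`` (inclusive at the bound)."""
    policy = policy or MatchPolicy()
    return property_distance(a, b, table or policy.table) <= policy.pd_cutoff


def matching_partners(
    aa: str, pd_budget: float, table: DescriptorTable | None = None, include_self: bool = True
) -> list[str]:
    """All standard amino acids within ``pd_budget`` of ``aa``.

    Used by the synthetic-mimotope generator to draw substitutions that are
    guaranteed to match the original residue at the given cutoff.
    """
    table = table or default_table()
    out = [
        b
        for b in AMINO_ACIDS
        if (include_self or b != aa) and property_distance(aa, b, table) <= pd_budget
    ]
    return out
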