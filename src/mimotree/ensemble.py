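"""Set-algebra combination of residue-level predictions from several methods.

Four combination rules: union, intersection, majority vote over exactly
three methods, and the "core" rule ``base ∪ (a ∩ b)`` (in practice the
union of a precise base method with the intersection of two complementary
ones).  All rules operate purely on residue-identifier sets; aligning the
residue numbering across methods is the caller's responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .core import Prediction
from .structure import ResidueId

logger = logging.getLogger(__name__)

__all__ = [
    "MethodPrediction",
    "combine_union",
    "combine_intersection",
    "combine_majority",
    "combine_core",
]


@dataclass(frozen=True)
class MethodPrediction:
    """A named method's predicted residue set."""

    method: str
    residue_ids: frozenset[ResidueId]

    @classmethod
    def from_tsv(cls, method: str, path_or_buf) -> "MethodPrediction":
        from .core import read_residue_tsv

        return cls(method=method, residue_ids=frozenset(read_residue_tsv(path_or_buf)))


def _warn_disjoint(preds: Sequence[MethodPrediction]) -> None:
    for i in range(len(preds)):
        for j in range(i + 1, len(preds)):
            if preds[i].residue_ids and preds[j].residue_ids and not (
                preds[i].residue_ids & preds[j].residue_ids
            ):
                logger.warning(
                    "predictions %s and %s share no residues; check that both "
                    "use the same structure and numbering",
                    preds[i].method, preds[j].method,
                )


def _as_prediction(residues: set[ResidueId], mode: str, preds: Sequence[MethodPrediction]) -> Prediction:
    return Prediction(
        residue_ids=set(residues),
        params={"mode": mode, "methods": [p.method for p in preds]},
    )


def combine_union(preds: Sequence[MethodPrediction]) -> Prediction:
    """Union of all member predictions (>= 2 required)."""
    if len(preds) < 2:
        raise ValueError("union requires at least 2 predictions")
    _warn_disjoint(preds)
    out: set[ResidueId] = set()
    for p in preds:
        out |= p.residue_ids
    return _as_prediction(out, "union", preds)


def combine_intersection(preds: Sequence[MethodPrediction]) -> Prediction:
    """Intersection of all member predictions (>= 2 required)."""
    if len(preds) < 2:
        raise ValueError("intersection requires at least 2 predictions")
    _warn_disjoint(preds)
    out = set(preds[0].residue_ids)
    for p in preds[1:]:
        out &= p.residue_ids
    return _as_prediction(out, "intersection", preds)


def combine_majority(preds: Sequence[MethodPrediction]) -> Prediction:
    """Residues present in at least two of exactly three predictions."""
    if len(preds) != 3:
        raise ValueError(f"majority vote requires exactly 3 predictions, got {len(preds)}")
    _warn_disjoint(preds)
    counts: dict[ResidueId, int] = {}
    for p in preds:
        for rid in p.residue_ids:
            counts[rid] = counts.get(rid, 0) + 1
    return _as_prediction({rid for rid, c in counts.items() if c >= 2}, "majority", preds)


def combine_core(
    base: MethodPrediction, a: MethodPrediction, b: MethodPrediction
) -> Prediction:
    """``base ∪ (a ∩ b)``: keep all of the base method, add the consensus
    of the other two."""
    preds = [base, a, b]
    _warn_disjoint(preds)
    out = set(base.residue_ids) | (set(a.residue_ids) & set(b.residue_ids))
    return _as_prediction(out, "core", preds)
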