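"""Evaluation statistics for residue-level epitope predictions.

Residue classification is binary over a universe of antigen residues:
sensitivity = TP/(TP+FN), precision = TP/(TP+FP), Matthews correlation
coefficient, and a hypergeometric enrichment p-value -- the probability
that a random residue subset of the prediction's size overlaps the true
epitope at least as well as the prediction does.  Paired method
comparisons use a one-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .structure import ResidueId

__all__ = [
    "EvaluationResult",
    "confusion",
    "sensitivity",
    "precision",
    "mcc",
    "hypergeom_pvalue",
    "wilcoxon_one_sided",
    "evaluate",
]


@dataclass(frozen=True)
class EvaluationResult:
    """Confusion counts and derived statistics for one prediction."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    precision: float
    mcc: float
    p_value: float
    size: int
    density: float

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
            "sensitivity": self.sensitivity, "precision": self.precision,
            "MCC": self.mcc, "p_value": self.p_value,
            "size": self.size, "density": self.density,
        }


def confusion(
    prediction: set[ResidueId], epitope: set[ResidueId], universe: set[ResidueId]
) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) over ``universe``; inputs must be subsets of it."""
    if not prediction <= universe:
        raise ValueError("prediction contains residues outside the universe")
    if not epitope <= universe:
        raise ValueError("epitope contains residues outside the universe")
    tp = len(prediction & epitope)
    fp = len(prediction - epitope)
    fn = len(epitope - prediction)
    tn = len(universe) - tp - fp - fn
    return tp, fp, fn, tn


def _check_counts(*counts: int) -> None:
    if any(c < 0 for c in counts):
        raise ValueError(f"counts must be non-negative, got {counts}")


def sensitivity(tp: int, fn: int) -> float:
    """TP/(TP+FN); 0 when the epitope is empty."""
    _check_counts(tp, fn)
    return tp / (tp + fn) if tp + fn else 0.0


def precision(tp: int, fp: int) -> float:
    """TP/(TP+FP); 0 when the prediction is empty."""
    _check_counts(tp, fp)
    return tp / (tp + fp) if tp + fp else 0.0


def mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is zero."""
    _check_counts(tp, fp, fn, tn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def hypergeom_pvalue(k: int, n: int, N: int, M: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Drawing ``n`` residues (the epitope size) without replacement from a
    universe of ``N`` residues of which ``M`` are in the prediction, the
    overlap ``X`` is hypergeometric; the p-value is the probability of an
    overlap at least as large as the observed ``k`` (inclusive).
    """
    if not (0 <= n <= N and 0 <= M <= N):
        raise ValueError(f"need 0 <= n, M <= N; got n={n}, M={M}, N={N}")
    if not (0 <= k <= min(n, M)):
        raise ValueError(f"need 0 <= k <= min(n, M); got k={k}, n={n}, M={M}")
    # sf(k-1) = P(X >= k); population N with M marked, n draws
    return float(stats.hypergeom.sf(k - 1, N, M, n))


def wilcoxon_one_sided(
    paired_a: Sequence[float], paired_b: Sequence[float], exact_max_n: int = 25
) -> float:
    """One-sided Wilcoxon signed-rank p-value for the hypothesis a > b.

    Zero differences are dropped; tied absolute differences receive
    mid-ranks.  For up to ``exact_max_n`` non-zero pairs the p-value comes
    from the exact distribution of the positive-rank sum (enumerated by
    dynamic programming over all sign assignments, valid under mid-ranking);
    larger samples use the normal approximation with tie correction.
    Degenerate input (no non-zero differences) returns 1.0.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired samples differ in length: {a.shape} vs {b.shape}")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        # doubled ranks are integers even with .5 mid-ranks
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        # dist[s] = number of sign assignments with doubled positive-rank sum s
        dist = np.zeros(total + 1, dtype=float)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: total + 1 - r]
            dist = dist + shifted
        w2 = int(round(2 * w_plus))
        return float(dist[w2:].sum() / 2**n)
    res = stats.wilcoxon(d, alternative="greater", method="approx", correction=True)
    return float(res.pvalue)


def evaluate(
    prediction: set[ResidueId],
    epitope: set[ResidueId],
    universe: set[ResidueId],
) -> EvaluationResult:
    """Full statistics table for one prediction against the true epitope.

    The universe defaults (at call sites) to all residues of the selected
    antigen chains; pass a surface-only set to restrict it.
    """
    tp, fp, fn, tn = confusion(prediction, epitope, universe)
    N = len(universe)
    M = len(prediction)
    return EvaluationResult(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=sensitivity(tp, fn),
        precision=precision(tp, fp),
        mcc=mcc(tp, fp, fn, tn),
        p_value=hypergeom_pvalue(tp, len(epitope), N, M) if N else 1.0,
        size=M,
        density=M / N if N else 0.0,
    )
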