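"""Weighted Levenshtein metric for CDR3 sequence comparison.

Cluster association and graph-edge construction both use a Levenshtein
distance with per-operation costs (deletion, insertion, substitution).
The default costs (1.1, 1.1, 1.9) together with the association threshold
lambda = 3 admit, relative to a cluster representative, at most two pure
indels (2 x 1.1 = 2.2) or one substitution plus one indel
(1.9 + 1.1 = 3.0), while two substitutions (3.8) are excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import edlib

#: Absolute tolerance for threshold comparisons.  The design point
#: "one substitution plus one indel" costs exactly 1.9 + 1.1 = 3.0 and must
#: compare <= lambda = 3 robustly under floating-point arithmetic.
TOL = 1e-9

#: Sentinel returned by :func:`distance_within` when the distance exceeds
#: the cutoff.
ABOVE_CUTOFF = math.inf


@dataclass(frozen=True)
class EditWeights:
    """Per-operation costs and the cluster-association threshold.

    Parameters
    ----------
    deletion, insertion, substitution
        Positive operation costs.  Metric symmetry requires
        ``deletion == insertion``; unequal indel costs are accepted but
        produce a warning since the resulting function is asymmetric.
    lambda_assoc
        Association threshold: a sequence joins a cluster when its distance
        to the representative is <= ``lambda_assoc``.
    """

    deletion: float = 1.1
    insertion: float = 1.1
    substitution: float = 1.9
    lambda_assoc: float = 3.0

    def __post_init__(self) -> None:
        for name in ("deletion", "insertion", "substitution"):
            if getattr(self, name) <= 0:
                raise ValueError(f"EditWeights.{name} must be positive")
        if self.lambda_assoc < 0:
            raise ValueError("EditWeights.lambda_assoc must be >= 0")
        if self.deletion != self.insertion:
            warnings.warn(
                "deletion != insertion breaks metric symmetry: "
                f"d={self.deletion}, i={self.insertion}",
                stacklevel=2,
            )

    @property
    def min_op(self) -> float:
        return min(self.deletion, self.insertion, self.substitution)


def weighted_levenshtein(a: str, b: str, w: EditWeights = EditWeights()) -> float:
    """Minimal total edit cost transforming ``a`` into ``b``.

    Standard Wagner-Fischer dynamic programme with weighted operations
    (no transpositions).  Deleting a character of ``a`` costs
    ``w.deletion``, inserting a character of ``b`` costs ``w.insertion``,
    and mismatched characters cost ``w.substitution``.
    """
    if a == b:
        return 0.0
    la, lb = len(a), len(b)
    if la == 0:
        return lb * w.insertion
    if lb == 0:
        return la * w.deletion
    dc, ic, sc = w.deletion, w.insertion, w.substitution
    prev = [j * ic for j in range(lb + 1)]
    cur = [0.0] * (lb + 1)
    for i in range(1, la + 1):
        cur[0] = i * dc
        ca = a[i - 1]
        for j in range(1, lb + 1):
            sub = prev[j - 1] + (0.0 if ca == b[j - 1] else sc)
            dele = prev[j] + dc
            ins = cur[j - 1] + ic
            m = sub if sub <= dele else dele
            cur[j] = m if m <= ins else ins
        prev, cur = cur, prev
    return prev[lb]


def distance_within(
    a: str, b: str, w: EditWeights = EditWeights(), cutoff: float = 3.0
) -> float:
    """Exact weighted distance if it is <= ``cutoff``, else :data:`ABOVE_CUTOFF`.

    Two exact lower bounds avoid most dynamic-programming work:
    the length difference costs at least ``|len(a)-len(b)|`` indels, and any
    edit script contains at least as many operations as the unit-cost
    Levenshtein distance, so the weighted cost is at least
    ``unit_distance * min(op costs)``.  The unit distance is obtained from
    the banded Myers bit-vector algorithm (edlib), which reports "above k"
    cheaply.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if a == b:
        return 0.0
    bound = cutoff + TOL
    indel_min = min(w.deletion, w.insertion)
    if abs(len(a) - len(b)) * indel_min > bound:
        return ABOVE_CUTOFF
    if a and b:
        k_units = int(bound // w.min_op)
        unit = edlib.align(a, b, task="distance", k=k_units)["editDistance"]
        if unit == -1 or unit * w.min_op > bound:
            return ABOVE_CUTOFF
    d = weighted_levenshtein(a, b, w)
    return d if d <= bound else ABOVE_CUTOFF
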