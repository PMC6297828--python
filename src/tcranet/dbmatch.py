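"""Match Clone-Attractors against a curated public TCR sequence table.

For every database CDR3 the minimum distance to any attractor
representative is computed and bucketed at 0 (identical to a
representative) and 1 (one edit away).  For distance-1 hits the database
sequence is additionally checked for identity with a *member* of the
matched attractor — a public sequence sitting inside the attractor's
basin rather than merely near its centre.

The distance-1 bucket counts edit *operations* by default (``unit_edit``:
one insertion, deletion or substitution of any kind); the weighted metric
used for clustering is available via ``metric="weighted"``, where the
"single operation" bucket admits any distance up to the largest
single-operation cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib
import pandas as pd

from tcranet.clustering import AttractorSet
from tcranet.distance import ABOVE_CUTOFF, TOL, EditWeights, distance_within
from tcranet.errors import ConfigurationError
from tcranet.io import validate_sequence

logger = logging.getLogger(__name__)


@dataclass
class MatchReport:
    """Distance-bucketed hits of database sequences against attractors."""

    hits: pd.DataFrame  # db_sequence, ca_id, distance, member_identity, annotations
    n_distance0: int
    n_distance1: int            # hits at distance exactly 1
    n_member_identical: int     # distance-1 hits identical to a member of the matched CA

    def __post_init__(self) -> None:
        assert self.n_distance0 <= self.n_distance0 + self.n_distance1
        assert self.n_member_identical <= self.n_distance1


def _unit_distance_le1(a: str, b: str) -> int | None:
    if a == b:
        return 0
    if abs(len(a) - len(b)) > 1:
        return None
    d = edlib.align(a, b, task="distance", k=1)["editDistance"]
    return None if d == -1 else d


def match_public(
    attractors: AttractorSet,
    db: pd.DataFrame,
    seq_col: str = "cdr3",
    metric: str = "unit_edit",
    weights: EditWeights = EditWeights(),
    ca_ids=None,
) -> MatchReport:
    """Match database sequences against attractor representatives.

    Parameters
    ----------
    attractors
        Attractor set (typically the graph-filtered or classifier-selected
        subset, restricted via ``ca_ids``).
    db
        Table with one CDR3 per row; all columns besides ``seq_col`` are
        passed through to the per-hit records as annotations.
    metric
        ``unit_edit`` buckets by operation count; ``weighted`` buckets by
        the clustering metric, the distance-1 bucket admitting up to one
        maximal single-operation cost.
    ca_ids
        Optional subset of attractor ids to match against.

    Equidistant representatives all produce hit records.
    """
    if seq_col not in db.columns:
        raise ConfigurationError(f"database is missing sequence column {seq_col!r}")
    if metric not in ("unit_edit", "weighted"):
        raise ConfigurationError(f"unknown metric {metric!r}")
    cas = [
        ca for ca in attractors.attractors if ca_ids is None or ca.ca_id in set(ca_ids)
    ]
    one_op = 1 if metric == "unit_edit" else max(
        weights.deletion, weights.insertion, weights.substitution
    )
    annot_cols = [c for c in db.columns if c != seq_col]
    rows = []
    d0_seqs: set[str] = set()
    d1_seqs: set[str] = set()
    d1_member_seqs: set[str] = set()
    for rec in db.itertuples(index=False):
        seq = validate_sequence(getattr(rec, seq_col))
        best = ABOVE_CUTOFF
        best_cas = []
        for ca in cas:
            if metric == "unit_edit":
                d = _unit_distance_le1(seq, ca.representative)
                if d is None:
                    continue
            else:
                d = distance_within(seq, ca.representative, weights, one_op)
                if d is ABOVE_CUTOFF:
                    continue
            if d < best - TOL:
                best, best_cas = d, [ca]
            elif abs(d - best) <= TOL:
                best_cas.append(ca)
        if best is ABOVE_CUTOFF:
            continue
        for ca in best_cas:
            member_identity = best > 0 and seq in ca.members
            rows.append(
                (seq, ca.ca_id, float(best), member_identity)
                + tuple(getattr(rec, c) for c in annot_cols)
            )
            if best == 0:
                d0_seqs.add(seq)
            else:
                d1_seqs.add(seq)
                if member_identity:
                    d1_member_seqs.add(seq)
    hits = pd.DataFrame(
        rows, columns=["db_sequence", "ca_id", "distance", "member_identity"] + annot_cols
    )
    logger.info(
        "matched %d db sequences: %d at distance 0, %d at distance 1 "
        "(%d identical to a member)",
        db.shape[0], len(d0_seqs), len(d1_seqs), len(d1_member_seqs),
    )
    return MatchReport(hits, len(d0_seqs), len(d1_seqs), len(d1_member_seqs))
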