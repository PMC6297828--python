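"""Greedy single-pass clustering of CDR3 sequences into Clone-Attractors.

Unique sequences are processed in order of ascending length (ties broken
lexicographically).  Each sequence either joins an existing cluster whose
medoid representative lies within the association threshold lambda, or
founds a new cluster with itself as representative.  Two association
strategies are provided:

``first_fit``
    winner-takes-all — the sequence joins the *oldest* cluster whose
    representative is within lambda (the greedy scan stops at the first
    hit);
``nearest_fit``
    the sequence joins the *closest* such cluster (ties go to the oldest).

After every association the cluster representative is refreshed to the
medoid — the member minimising the sum of weighted edit distances to all
other members (ties: shorter sequence, then lexicographically smaller).
The medoid is maintained incrementally from cached distance sums, so each
association costs one distance evaluation per existing member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, NamedTuple

import pandas as pd

from tcranet.distance import ABOVE_CUTOFF, TOL, EditWeights, distance_within, weighted_levenshtein

logger = logging.getLogger(__name__)

Strategy = Literal["first_fit", "nearest_fit"]


@dataclass
class CloneAttractor:
    """A cluster of similar CDR3 sequences with a medoid representative."""

    ca_id: int
    representative: str
    members: dict[str, int]  # sequence -> total count across samples/times

    @property
    def size(self) -> int:
        """Number of distinct member sequences (the basin size ||CA||)."""
        return len(self.members)

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError(
                f"representative {self.representative!r} not among members of CA {self.ca_id}"
            )


class AssociationRecord(NamedTuple):
    sequence: str
    ca_id: int
    distance: float  # distance to the representative at association time (0 for founders)


@dataclass
class AttractorSet:
    """Partition of the unique input sequences into Clone-Attractors."""

    attractors: list[CloneAttractor]
    weights: EditWeights
    association_log: list[AssociationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.attractors)

    def __iter__(self):
        return iter(self.attractors)

    @property
    def sizes(self) -> list[int]:
        return [ca.size for ca in self.attractors]

    @property
    def representatives(self) -> dict[int, str]:
        return {ca.ca_id: ca.representative for ca in self.attractors}

    def membership(self) -> dict[str, int]:
        """Mapping of every member sequence to its attractor id."""
        out: dict[str, int] = {}
        for ca in self.attractors:
            for seq in ca.members:
                out[seq] = ca.ca_id
        return out


@dataclass
class ActivityMatrix:
    """CA amplitude per (sample, time point).

    ``data`` has the attractor id as row index and a ``(sample_id,
    time_point)`` MultiIndex on the columns.  A zero encodes inactivity;
    there are no missing values.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise ValueError("ActivityMatrix columns must be a (sample_id, time_point) MultiIndex")
        self.data.index.name = "ca_id"
        self.data.columns.names = ["sample_id", "time_point"]

    @property
    def samples(self) -> list[str]:
        return sorted(self.data.columns.get_level_values("sample_id").unique())

    @property
    def time_points(self) -> list[int]:
        return sorted(self.data.columns.get_level_values("time_point").unique())

    def amplitude(self, ca_id: int, sample_id: str, time_point: int) -> float:
        return float(self.data.at[ca_id, (sample_id, time_point)])


class _Cluster:
    """Internal mutable cluster state with cached distance sums."""

    __slots__ = ("ca_id", "members", "dist_sums", "rep", "rep_len")

    def __init__(self, ca_id: int, seq: str, count: int) -> None:
        self.ca_id = ca_id
        self.members: dict[str, int] = {seq: count}
        self.dist_sums: dict[str, float] = {seq: 0.0}
        self.rep = seq
        self.rep_len = len(seq)

    def add(self, seq: str, count: int, w: EditWeights) -> None:
        total = 0.0
        for m in self.members:
            d = weighted_levenshtein(seq, m, w)
            self.dist_sums[m] += d
            total += d
        self.members[seq] = count
        self.dist_sums[seq] = total
        # medoid refresh; ties -> shorter, then lexicographically smaller
        self.rep = min(self.dist_sums, key=lambda s: (self.dist_sums[s], len(s), s))
        self.rep_len = len(self.rep)


def cluster_repertoire(
    sequences: Mapping[str, int] | Iterable[str],
    w: EditWeights = EditWeights(),
    strategy: Strategy = "first_fit",
) -> AttractorSet:
    """Cluster unique sequences (with total counts) into Clone-Attractors.

    Parameters
    ----------
    sequences
        Mapping of unique CDR3 amino-acid sequence to its total count, or a
        plain iterable of unique sequences (counts default to 1).
    w
        Edit weights including the association threshold ``lambda_assoc``.
    strategy
        ``first_fit`` (default, winner takes all) or ``nearest_fit``.

    Returns
    -------
    AttractorSet
        A partition of the input: every sequence belongs to exactly one
        attractor, and attractor sizes sum to the number of unique inputs.
    """
    if strategy not in ("first_fit", "nearest_fit"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if not isinstance(sequences, Mapping):
        seqs = list(sequences)
        if len(set(seqs)) != len(seqs):
            raise ValueError("input sequences must be unique (deduplicate with counts first)")
        sequences = {s: 1 for s in seqs}

    lam = w.lambda_assoc + TOL
    indel_min = min(w.deletion, w.insertion)
    max_len_diff = int(lam // indel_min)

    clusters: list[_Cluster] = []
    log: list[AssociationRecord] = []
    order = sorted(sequences, key=lambda s: (len(s), s))
    for seq in order:
        count = sequences[seq]
        lq = len(seq)
        best: _Cluster | None = None
        best_d = ABOVE_CUTOFF
        # lambda = 0 degenerates to one cluster per unique sequence
        candidates = clusters if w.lambda_assoc > 0 else ()
        for c in candidates:
            if abs(lq - c.rep_len) > max_len_diff:
                continue
            d = distance_within(seq, c.rep, w, w.lambda_assoc)
            if d <= lam:
                if strategy == "first_fit":
                    best, best_d = c, d
                    break
                if d < best_d:  # nearest_fit keeps the oldest on ties
                    best, best_d = c, d
        if best is None:
            c = _Cluster(len(clusters), seq, count)
            clusters.append(c)
            log.append(AssociationRecord(seq, c.ca_id, 0.0))
        else:
            best.add(seq, count, w)
            log.append(AssociationRecord(seq, best.ca_id, best_d))

    attractors = [CloneAttractor(c.ca_id, c.rep, dict(c.members)) for c in clusters]
    logger.info(
        "clustered %d unique sequences into %d attractors (strategy=%s, lambda=%g)",
        len(sequences), len(attractors), strategy, w.lambda_assoc,
    )
    return AttractorSet(attractors, w, log)


def update_representative(ca: CloneAttractor, w: EditWeights = EditWeights()) -> str:
    """Medoid of a cluster: the member minimising the summed distance to all
    other members.  Ties break by (shorter length, lexicographic order).

    This is the reference O(K^2) computation; :func:`cluster_repertoire`
    maintains the same quantity incrementally.
    """
    if not ca.members:
        raise ValueError("cannot compute a representative of an empty cluster")
    seqs = list(ca.members)
    sums = {s: 0.0 for s in seqs}
    for i, a in enumerate(seqs):
        for b in seqs[i + 1 :]:
            d = weighted_levenshtein(a, b, w)
            sums[a] += d
            sums[b] += d
    return min(sums, key=lambda s: (sums[s], len(s), s))


def attractor_activity(aset: AttractorSet, records) -> ActivityMatrix:
    """Amplitude of every attractor per (sample, time point).

    The amplitude is the sum of member-sequence counts observed in that
    sample and time point; combinations where no member was observed get 0.

    Parameters
    ----------
    aset
        Clustering of (at least) every sequence occurring in ``records``.
    records
        Iterable of :class:`tcranet.io.CloneRecord` (or any object with
        ``junction_aa``, ``count``, ``sample_id``, ``time_point``).
    """
    seq_to_ca = aset.membership()
    rows = []
    for r in records:
        ca = seq_to_ca.get(r.junction_aa)
        if ca is None:
            raise ValueError(
                f"sequence {r.junction_aa!r} is not a member of any attractor; "
                "clustering must cover all records"
            )
        rows.append((ca, r.sample_id, r.time_point, r.count))
    frame = pd.DataFrame(rows, columns=["ca_id", "sample_id", "time_point", "count"])
    table = frame.pivot_table(
        index="ca_id", columns=["sample_id", "time_point"], values="count",
        aggfunc="sum", fill_value=0.0,
    )
    # attractors with no observed member at all still get an all-zero row
    all_ids = [ca.ca_id for ca in aset.attractors]
    table = table.reindex(all_ids, fill_value=0.0).astype(float)
    return ActivityMatrix(table)
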