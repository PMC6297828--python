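"""Readers and writers for clone tables, metadata and derived artifacts.

Clone tables are tab-separated with AIRR-Rearrangement-style column names
(``junction_aa``, ``duplicate_count``) plus ``sample_id`` and
``time_point``; a :class:`ColumnMap` remaps other dialects.  All outputs
are TSV with ``#``-prefixed comment headers carrying the package version
and a configuration hash, and every writer/reader pair round-trips.

TCR alpha-chain sequences are accepted by the reader; the reference
workflow analyses the beta chain only, which is a property of the input
tables, not of this module.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from tcranet import __version__
from tcranet.clustering import ActivityMatrix, AttractorSet, CloneAttractor
from tcranet.distance import EditWeights
from tcranet.errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_RE = re.compile(rf"^[{AA_ALPHABET}]+$")

GROUPS = ("control", "transgenic")
PHENOTYPES = ("healthy", "pre_cancer", "cancer")
_PHENO_ORDER = {p: i for i, p in enumerate(PHENOTYPES)}


@dataclass(frozen=True)
class CloneRecord:
    """One observed CDR3 clone with its abundance in a (sample, time point)."""

    junction_aa: str
    count: int
    sample_id: str
    time_point: int


@dataclass(frozen=True)
class SampleMeta:
    """Group label and per-time-point phenotype of one sample (mouse)."""

    sample_id: str
    group: str  # control | transgenic
    phenotype_by_time: dict[int, str] = field(hash=False)


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from the expected fields to the table's column names."""

    junction_aa: str = "junction_aa"
    count: str = "duplicate_count"
    sample_id: str = "sample_id"
    time_point: str = "time_point"


def validate_sequence(seq: str, row: int | None = None) -> str:
    """Uppercase-AA validation; '*' and '_' (stops/frameshifts) are rejected."""
    if not isinstance(seq, str) or not _AA_RE.match(seq):
        where = f" at row {row}" if row is not None else ""
        raise ValidationError(f"invalid CDR3 amino-acid sequence {seq!r}{where}")
    return seq


def read_clone_table(path, dialect: ColumnMap = ColumnMap()) -> list[CloneRecord]:
    """Read and validate a tab-separated clone table.

    Rows with count 0 are dropped with a warning; duplicate
    (sequence, sample, time point) rows are summed into one record.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for f_name in ("junction_aa", "count", "sample_id", "time_point"):
        col = getattr(dialect, f_name)
        if col not in df.columns:
            raise ConfigurationError(
                f"clone table {path} is missing the {f_name!r} column {col!r}"
            )
    n_read = len(df)
    records: dict[tuple[str, str, int], int] = {}
    n_dropped = n_merged = 0
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        seq = validate_sequence(getattr(row, dialect.junction_aa), row_number)
        try:
            count = int(getattr(row, dialect.count))
            tp = int(getattr(row, dialect.time_point))
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-integer count/time_point at row {row_number}") from exc
        if count < 0:
            raise ValidationError(f"negative count at row {row_number}")
        if count == 0:
            logger.warning("dropping zero-count row %d (%s)", row_number, seq)
            n_dropped += 1
            continue
        key = (seq, getattr(row, dialect.sample_id), tp)
        if key in records:
            n_merged += 1
        records[key] = records.get(key, 0) + count
    logger.info(
        "clone table %s: %d rows read, %d dropped (zero count), %d merged, %d records",
        path, n_read, n_dropped, n_merged, len(records),
    )
    return [CloneRecord(s, c, sid, tp) for (s, sid, tp), c in records.items()]


def write_clone_table(records: Iterable[CloneRecord], path, dialect: ColumnMap = ColumnMap()) -> None:
    df = pd.DataFrame(
        [(r.junction_aa, r.count, r.sample_id, r.time_point) for r in records],
        columns=[dialect.junction_aa, dialect.count, dialect.sample_id, dialect.time_point],
    )
    with open(path, "w") as fh:
        fh.write(_comment_header())
        df.to_csv(fh, sep="\t", index=False)


def read_metadata(path) -> list[SampleMeta]:
    """Read sample metadata (one row per sample and time point).

    Control samples must be healthy at every time point; within a
    transgenic sample the phenotype must be monotone
    healthy* -> pre_cancer* -> cancer* (no reversal).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("sample_id", "time_point", "group", "phenotype"):
        if col not in df.columns:
            raise ConfigurationError(f"metadata {path} is missing column {col!r}")
    if df.duplicated(["sample_id", "time_point"]).any():
        raise ValidationError("metadata has duplicate (sample_id, time_point) rows")
    metas = []
    for sample_id, sub in df.groupby("sample_id", sort=True):
        groups = sub["group"].unique()
        if len(groups) != 1 or groups[0] not in GROUPS:
            raise ValidationError(f"sample {sample_id}: group must be one of {GROUPS}")
        group = groups[0]
        by_time: dict[int, str] = {}
        for _, row in sub.iterrows():
            pheno = row["phenotype"]
            if pheno not in PHENOTYPES:
                raise ValidationError(f"sample {sample_id}: unknown phenotype {pheno!r}")
            by_time[int(row["time_point"])] = pheno
        ordered = [by_time[t] for t in sorted(by_time)]
        if group == "control" and any(p != "healthy" for p in ordered):
            raise ValidationError(f"control sample {sample_id} has a non-healthy time point")
        ranks = [_PHENO_ORDER[p] for p in ordered]
        if any(b < a for a, b in zip(ranks, ranks[1:])):
            raise ValidationError(
                f"sample {sample_id}: phenotype reversal over time ({ordered})"
            )
        metas.append(SampleMeta(sample_id, group, by_time))
    return metas


def write_metadata(metas: Iterable[SampleMeta], path) -> None:
    rows = [
        (m.sample_id, t, m.group, p)
        for m in metas
        for t, p in sorted(m.phenotype_by_time.items())
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "time_point", "group", "phenotype"])
    with open(path, "w") as fh:
        fh.write(_comment_header())
        df.to_csv(fh, sep="\t", index=False)


def _comment_header(extra: dict | None = None) -> str:
    lines = [f"# tcranet {__version__}"]
    for k, v in (extra or {}).items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def _weights_hash(w: EditWeights) -> str:
    key = f"{w.deletion}:{w.insertion}:{w.substitution}:{w.lambda_assoc}"
    return hashlib.sha256(key.encode()).hexdigest()[:12]


def write_attractor_table(aset: AttractorSet, path, log_path=None) -> None:
    """One row per member: ca_id, representative, member, count.

    The edit weights travel in the comment header so the table
    round-trips; the association log (sequence, ca_id, distance at
    association) is written separately when ``log_path`` is given.
    """
    w = aset.weights
    extra = {
        "weights": f"{w.deletion},{w.insertion},{w.substitution}",
        "lambda": w.lambda_assoc,
        "config_hash": _weights_hash(w),
    }
    rows = [
        (ca.ca_id, ca.representative, member, count)
        for ca in aset.attractors
        for member, count in ca.members.items()
    ]
    df = pd.DataFrame(rows, columns=["ca_id", "representative", "member", "count"])
    with open(path, "w") as fh:
        fh.write(_comment_header(extra))
        df.to_csv(fh, sep="\t", index=False)
    if log_path is not None:
        log_df = pd.DataFrame(aset.association_log, columns=["sequence", "ca_id", "distance"])
        with open(log_path, "w") as fh:
            fh.write(_comment_header(extra))
            log_df.to_csv(fh, sep="\t", index=False)


def _parse_header_weights(path) -> EditWeights | None:
    weights = lam = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "weights=" in line:
                weights = [float(x) for x in line.split("=", 1)[1].split(",")]
            elif "lambda=" in line:
                lam = float(line.split("=", 1)[1])
    if weights is None or lam is None:
        return None
    return EditWeights(*weights, lambda_assoc=lam)


def read_attractor_table(path, log_path=None) -> AttractorSet:
    weights = _parse_header_weights(path) or EditWeights()
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"ca_id": int, "count": int})
    attractors = []
    for ca_id, sub in df.groupby("ca_id", sort=True):
        reps = sub["representative"].unique()
        if len(reps) != 1:
            raise ValidationError(f"attractor {ca_id} has conflicting representatives")
        members = dict(zip(sub["member"], sub["count"]))
        attractors.append(CloneAttractor(int(ca_id), reps[0], members))
    log = []
    if log_path is not None:
        from tcranet.clustering import AssociationRecord

        log_df = pd.read_csv(log_path, sep="\t", comment="#")
        log = [
            AssociationRecord(r.sequence, int(r.ca_id), float(r.distance))
            for r in log_df.itertuples(index=False)
        ]
    return AttractorSet(attractors, weights, log)


def write_activity_matrix(am: ActivityMatrix, path, extra: dict | None = None) -> None:
    """Wide TSV: ca_id rows, one ``sample:time`` column per data point.

    Absent (sample, time) combinations are written as 0 — a Clone-Attractor
    not observed at a data point is inactive, not missing.  ``extra``
    entries (e.g. a config hash) join the comment header.
    """
    df = am.data.copy()
    df.columns = [f"{s}:{t}" for s, t in df.columns]
    with open(path, "w") as fh:
        fh.write(_comment_header(extra))
        df.to_csv(fh, sep="\t", index=True)


def read_activity_matrix(path) -> ActivityMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    cols = []
    for c in df.columns:
        sample, _, tp = c.rpartition(":")
        cols.append((sample, int(tp)))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["sample_id", "time_point"])
    df.index = df.index.astype(int)
    return ActivityMatrix(df.astype(float))


def write_measure_table(measures, path, extra: dict | None = None) -> None:
    """Per-point MTI/sBWC rows followed by per-sample median/std rows."""
    with open(path, "w") as fh:
        fh.write(_comment_header(extra))
        per_point = measures.per_point.reset_index()
        per_point.insert(0, "record", "point")
        per_point.to_csv(fh, sep="\t", index=False)
        fh.write("\n")
        per_sample = measures.per_sample.reset_index()
        per_sample.insert(0, "record", "sample_summary")
        per_sample.to_csv(fh, sep="\t", index=False)


def records_to_frame(records: Sequence[CloneRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.junction_aa, r.count, r.sample_id, r.time_point) for r in records],
        columns=["junction_aa", "duplicate_count", "sample_id", "time_point"],
    )


def frame_to_records(df: pd.DataFrame) -> list[CloneRecord]:
    return [
        CloneRecord(r.junction_aa, int(r.duplicate_count), str(r.sample_id), int(r.time_point))
        for r in df.itertuples(index=False)
    ]
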