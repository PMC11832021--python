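"""I/O for eventalign-style segmentation tables and raw-signal stores.

The segmentation step (f5c/nanopolish ``eventalign``) maps each basecalled
k-mer of a read to a contiguous range of raw current samples.  This module
parses that TSV dialect into per-read event lists, loads the matching raw
pico-ampere vectors, and splits each read's signal into the basecalled
portion (covered by events) and the non-basecalled remainder (ligated
aptamers, adapter stretches, skipped samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column order of the f5c eventalign dialect (with --signal-index
#: --scale-events --print-read-names).
EVENTALIGN_COLUMNS = [
    "contig",
    "position",
    "reference_kmer",
    "read_name",
    "strand",
    "event_index",
    "event_level_mean",
    "event_stdv",
    "event_length",
    "model_kmer",
    "model_mean",
    "model_stdv",
    "standardized_level",
    "start_idx",
    "end_idx",
]

#: Columns this package actually consumes.
REQUIRED_COLUMNS = ["position", "read_name", "start_idx", "end_idx"]

_VALID_BASES = frozenset("ACGT")


class EventalignFormatError(ValueError):
    """Raised when a segmentation table does not match the expected dialect."""


class RawStoreError(ValueError):
    """Raised for malformed raw-signal stores or missing reads."""


@dataclass
class RawRead:
    """A read's raw current trace: pico-ampere samples at ~3 kHz."""

    read_id: str
    samples: np.ndarray
    sample_rate: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError(f"read {self.read_id!r}: empty sample vector")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"read {self.read_id!r}: non-finite samples")


@dataclass(frozen=True)
class KmerEvent:
    """One segmented k-mer occurrence.

    ``sample_start``/``sample_end`` are 0-based half-open raw-sample indices;
    ``dwell`` is the number of raw samples the k-mer spent in the pore.
    """

    position: int
    kmer: str
    sample_start: int
    sample_end: int

    def __post_init__(self) -> None:
        if self.sample_start >= self.sample_end:
            raise ValueError(
                f"event at position {self.position}: empty sample range "
                f"[{self.sample_start}, {self.sample_end})"
            )

    @property
    def dwell(self) -> int:
        return self.sample_end - self.sample_start


@dataclass
class SegmentedRead:
    """Ordered k-mer events of one read, optionally with a class label."""

    read_id: str
    events: list[KmerEvent] = field(default_factory=list)
    label: int | None = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.sample_start)

    @property
    def n_events(self) -> int:
        return len(self.events)


def parse_eventalign(
    source: str | IO[str],
    k: int,
    collapse: bool = True,
    kmer_column: str = "model_kmer",
) -> list[SegmentedRead]:
    """Parse an eventalign TSV into per-read event lists.

    Parameters
    ----------
    source:
        Path or open text stream of a header-bearing eventalign TSV.
    k:
        Expected k-mer length; rows with a different length raise.
    collapse:
        Merge consecutive rows of the same (read, position) into one event
        spanning the union of their sample ranges (mirrors f5c's
        ``--collapse-events`` when the upstream file was not collapsed).
    kmer_column:
        ``"model_kmer"`` (strand-aware, the sequence that occupied the pore;
        default) or ``"reference_kmer"``.
    """
    if kmer_column not in ("model_kmer", "reference_kmer"):
        raise ValueError(f"unsupported kmer column {kmer_column!r}")
    try:
        table = pd.read_csv(source, sep="\t", dtype={"read_name": str})
    except pd.errors.EmptyDataError:
        raise EventalignFormatError("eventalign table has no header") from None

    for col in REQUIRED_COLUMNS + [kmer_column]:
        if col not in table.columns:
            raise EventalignFormatError(f"missing required column {col!r}")
    if table.empty:
        return []

    n_dropped = 0
    reads: dict[str, list[KmerEvent]] = {}
    for read_name, group in table.groupby("read_name", sort=False):
        events: list[KmerEvent] = []
        for row in group.itertuples(index=False):
            kmer = str(getattr(row, kmer_column))
            if not _VALID_BASES.issuperset(kmer):
                n_dropped += 1
                continue
            if len(kmer) != k:
                raise EventalignFormatError(
                    f"k-mer {kmer!r} has length {len(kmer)}, expected k={k}"
                )
            start, end = int(row.start_idx), int(row.end_idx)
            pos = int(row.position)
            if collapse and events and events[-1].position == pos:
                prev = events[-1]
                events[-1] = KmerEvent(
                    position=pos,
                    kmer=prev.kmer,
                    sample_start=min(prev.sample_start, start),
                    sample_end=max(prev.sample_end, end),
                )
            else:
                events.append(
                    KmerEvent(position=pos, kmer=kmer, sample_start=start, sample_end=end)
                )
        reads[str(read_name)] = events
    if n_dropped:
        logger.info("dropped %d events with non-ACGT k-mers", n_dropped)
    return [SegmentedRead(read_id=rid, events=ev) for rid, ev in reads.items()]


def write_eventalign(reads: Iterable[SegmentedRead], path: str, contig: str = "ref") -> None:
    """Write segmented reads in the eventalign dialect.

    Only the consumed columns carry information; the remaining dialect
    columns are filled with neutral placeholders so the file round-trips
    through :func:`parse_eventalign` and external eventalign consumers.
    """
    rows = []
    for read in reads:
        for i, ev in enumerate(read.events):
            rows.append(
                {
                    "contig": contig,
                    "position": ev.position,
                    "reference_kmer": ev.kmer,
                    "read_name": read.read_id,
                    "strand": "t",
                    "event_index": i,
                    "event_level_mean": 0.0,
                    "event_stdv": 0.0,
                    "event_length": ev.dwell,
                    "model_kmer": ev.kmer,
                    "model_mean": 0.0,
                    "model_stdv": 0.0,
                    "standardized_level": 0.0,
                    "start_idx": ev.sample_start,
                    "end_idx": ev.sample_end,
                }
            )
    pd.DataFrame(rows, columns=EVENTALIGN_COLUMNS).to_csv(path, sep="\t", index=False)


def load_raw_store(path: str) -> dict[str, RawRead]:
    """Load the two-column text raw-signal store.

    Each line is ``read_id<TAB>s1 s2 s3 ...`` with whitespace-separated
    float samples.  Duplicate read ids are an error; lookups of absent ids
    raise ``KeyError`` naturally through the returned dict.
    """
    store: dict[str, RawRead] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise RawStoreError(f"line {lineno}: expected 2 tab-separated fields")
            read_id, payload = parts
            if read_id in store:
                raise RawStoreError(f"duplicate read id {read_id!r}")
            samples = np.array(payload.split(), dtype=float)
            if samples.size == 0:
                raise RawStoreError(f"line {lineno}: read {read_id!r} has no samples")
            store[read_id] = RawRead(read_id=read_id, samples=samples)
    return store


def save_raw_store(reads: Mapping[str, RawRead] | Iterable[RawRead], path: str) -> None:
    """Write raw reads to the two-column text store."""
    if isinstance(reads, Mapping):
        reads = reads.values()
    with open(path, "w") as fh:
        for read in reads:
            payload = " ".join(repr(float(v)) for v in read.samples)
            fh.write(f"{read.read_id}\t{payload}\n")


def load_pod5_store(path: str) -> dict[str, RawRead]:  # pragma: no cover - optional
    """Optional pod5 adapter exposing the same mapping contract."""
    try:
        import pod5
    except ImportError as exc:
        raise ImportError(
            "pod5 support requires the optional 'pod5' package "
            "(pip install poresip[pod5])"
        ) from exc
    store: dict[str, RawRead] = {}
    with pod5.Reader(path) as reader:
        for rec in reader.reads():
            rid = str(rec.read_id)
            if rid in store:
                raise RawStoreError(f"duplicate read id {rid!r}")
            store[rid] = RawRead(
                read_id=rid,
                samples=rec.signal_pa.astype(float),
                sample_rate=float(rec.run_info.sample_rate),
            )
    return store


def split_signal(raw: RawRead, seg: SegmentedRead) -> tuple[np.ndarray, np.ndarray]:
    """Partition a read's samples into basecalled and non-basecalled parts.

    Returns ``(R_r, X_r)`` where ``R_r`` concatenates all samples covered by
    any event range and ``X_r`` is every remaining sample in original order
    (aptamer prefix, inter-event skips, trailing signal).  Together they
    account for every sample exactly once.
    """
    n = raw.samples.size
    covered = np.zeros(n, dtype=bool)
    for ev in seg.events:
        if ev.sample_end > n:
            raise ValueError(
                f"read {seg.read_id!r}: event range [{ev.sample_start}, "
                f"{ev.sample_end}) exceeds signal length {n}"
            )
        covered[ev.sample_start : ev.sample_end] = True
    return raw.samples[covered], raw.samples[~covered]
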