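"""FASTQ ingestion: demultiplexing, UMI extraction, trimming, merging, filtering.

The stages mirror a standard targeted-amplicon preprocessing chain:
demultiplex by index with at most one mismatch, extract the unique molecular
identifier (UMI), trim 3' adapter read-through, merge the read pair on its
overlap, and apply the quality filter (keep iff mean Phred >= 30 and minimum
per-base Phred >= 24).
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

__all__ = [
    "SequencedRead",
    "MergedRead",
    "UmiScheme",
    "read_fastq",
    "write_fastq",
    "reverse_complement",
    "demultiplex",
    "extract_umi",
    "trim_adapter_3p",
    "merge_pair",
    "quality_filter",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MEAN_QUAL_MIN = 30.0
PER_BASE_QUAL_MIN = 24


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequencedRead:
    """A single sequencing read with Phred+33-decoded qualities."""

    read_id: str
    bases: str
    quals: np.ndarray  # int array, same length as bases
    mate: str = "R1"
    umi: Optional[str] = None
    sample: Optional[str] = None

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id}: bases ({len(self.bases)}) and quals "
                f"({len(self.quals)}) lengths differ"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class MergedRead(SequencedRead):
    """Consensus of an overlapping read pair."""

    overlap_len: int = 0
    r1_id: str = ""
    r2_id: str = ""


@dataclass(frozen=True)
class UmiScheme:
    """Where the UMI lives: the first ``length`` read bases, or a header field.

    ``header-field`` schemes take the text after the last ``:`` in the read id.
    """

    source: str = "read-prefix"  # read-prefix | header-field
    length: int = 8

    def __post_init__(self) -> None:
        if self.source not in ("read-prefix", "header-field"):
            raise ValueError(f"unknown UMI source {self.source!r}")
        if self.length < 1:
            raise ValueError("UMI length must be >= 1")


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fastq(path: str | Path, mate: str = "R1") -> Iterator[SequencedRead]:
    """Iterate Phred+33 FASTQ records; gzip is autodetected by magic bytes."""
    with _open_maybe_gzip(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
            yield SequencedRead(
                read_id=title.split()[0], bases=seq.upper(), quals=quals, mate=mate
            )


def write_fastq(path: str | Path, reads: Iterable[SequencedRead]) -> int:
    """Write reads as (optionally gzipped, by suffix) 4-line FASTQ records.

    Gzip output pins the header mtime to zero so identical content yields
    byte-identical files across runs.
    """
    path = Path(path)
    if path.suffix == ".gz":
        raw = open(path, "wb")
        out = io.TextIOWrapper(gzip.GzipFile(fileobj=raw, mode="wb", mtime=0))
    else:
        raw = None
        out = open(path, "wt")
    n = 0
    try:
        for read in reads:
            qual = "".join(chr(int(q) + 33) for q in read.quals)
            out.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")
            n += 1
    finally:
        out.close()
        if raw is not None:
            raw.close()
    return n


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _default_index(read: SequencedRead) -> str:
    return read.read_id.rsplit(":", 1)[-1]


def demultiplex(
    reads: Iterable[SequencedRead],
    barcode_table: dict[str, str],
    index_of: Callable[[SequencedRead], str] = _default_index,
) -> tuple[dict[str, list[SequencedRead]], list[SequencedRead], dict[str, int]]:
    """Assign reads to samples by index barcode, allowing one mismatch.

    A read is assigned iff exactly one barcode lies within Hamming distance 1
    of its index; ambiguous or distant indexes go to the unassigned stream.
    Returns ``(assigned, unassigned, counts)``.
    """
    if not barcode_table:
        raise ValueError("barcode table is empty")
    lengths = {len(b) for b in barcode_table.values()}
    if len(lengths) != 1:
        raise ValueError("barcodes must share one length within an index read")
    (bc_len,) = lengths
    items = sorted(barcode_table.items())
    for i, (s1, b1) in enumerate(items):
        for s2, b2 in items[i + 1 :]:
            if _hamming(b1, b2) < 3:
                logger.warning(
                    "barcodes for %s and %s are within Hamming distance 2; "
                    "one-mismatch demultiplexing may be ambiguous",
                    s1,
                    s2,
                )
    assigned: dict[str, list[SequencedRead]] = {s: [] for s in barcode_table}
    unassigned: list[SequencedRead] = []
    counts = {"input": 0, "assigned": 0, "unassigned": 0}
    for read in reads:
        counts["input"] += 1
        index = index_of(read)
        if len(index) != bc_len:
            raise ValueError(
                f"index {index!r} of read {read.read_id} does not match barcode "
                f"length {bc_len}"
            )
        hits = [s for s, b in items if _hamming(index, b) <= 1]
        if len(hits) == 1:
            read = replace(read, sample=hits[0])
            assigned[hits[0]].append(read)
            counts["assigned"] += 1
        else:
            unassigned.append(read)
            counts["unassigned"] += 1
    for sample in sorted(assigned):
        logger.info("demultiplex: %s -> %d reads", sample, len(assigned[sample]))
    logger.info("demultiplex: unassigned -> %d reads", counts["unassigned"])
    return assigned, unassigned, counts


# ---------------------------------------------------------------------------
# UMI extraction
# ---------------------------------------------------------------------------


def extract_umi(read: SequencedRead, scheme: UmiScheme) -> Optional[SequencedRead]:
    """Record the read's UMI, trimming it off for read-prefix schemes.

    Returns ``None`` for reads whose UMI contains ``N`` (routed to a discard
    stream by the caller).
    """
    if scheme.source == "read-prefix":
        if scheme.length > len(read):
            raise ValueError(
                f"UMI length {scheme.length} exceeds read length {len(read)}"
            )
        umi = read.bases[: scheme.length]
        if "N" in umi:
            return None
        return replace(
            read,
            bases=read.bases[scheme.length :],
            quals=read.quals[scheme.length :],
            umi=umi,
        )
    umi = read.read_id.rsplit(":", 1)[-1]
    if "N" in umi:
        return None
    return replace(read, umi=umi)


# ---------------------------------------------------------------------------
# Adapter trimming
# ---------------------------------------------------------------------------


def trim_adapter_3p(
    read: SequencedRead,
    adapter: str,
    min_overlap: int = 3,
    max_mismatch_frac: float = 0.1,
) -> SequencedRead:
    """Remove 3' adapter read-through.

    The longest read suffix matching a prefix of the adapter (>= min_overlap,
    <= 10% mismatches) is removed; reads without a hit are returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter sequence is empty")
    best = 0
    max_o = min(len(read), len(adapter))
    for o in range(max_o, min_overlap - 1, -1):
        mm = _hamming(read.bases[-o:], adapter[:o])
        if mm <= max_mismatch_frac * o:
            best = o
            break
    if best == 0:
        return read
    return replace(read, bases=read.bases[:-best], quals=read.quals[:-best])


# ---------------------------------------------------------------------------
# Paired-end merging
# ---------------------------------------------------------------------------

_BASE_CODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def merge_pair(
    r1: SequencedRead,
    r2: SequencedRead,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> Optional[MergedRead]:
    """Merge a read pair on their best overlap, or return ``None``.

    R2 is reverse-complemented, then the overlap maximizing the number of
    matched bases (subject to the mismatch ceiling) is chosen.  In
    disagreeing columns the higher-quality base wins and the column quality
    is the maximum of the two.
    """
    r2_bases = reverse_complement(r2.bases)
    r2_quals = r2.quals[::-1]
    a, b = _encode(r1.bases), _encode(r2_bases)
    l1, l2 = len(a), len(b)
    best_o, best_matched = 0, -1
    for o in range(min_overlap, min(l1, l2) + 1):
        mm = int(np.count_nonzero(a[l1 - o :] != b[:o]))
        if mm <= max_mismatch_frac * o and (o - mm) > best_matched:
            best_matched = o - mm
            best_o = o
    if best_o == 0:
        return None
    o = best_o
    left_b, left_q = a[: l1 - o], r1.quals[: l1 - o]
    right_b, right_q = b[o:], r2_quals[o:]
    ov1_b, ov1_q = a[l1 - o :], r1.quals[l1 - o :]
    ov2_b, ov2_q = b[:o], r2_quals[:o]
    take1 = ov1_q >= ov2_q
    cons_b = np.where(take1, ov1_b, ov2_b)
    cons_q = np.maximum(ov1_q, ov2_q)
    bases = (left_b.tobytes() + cons_b.tobytes() + right_b.tobytes()).decode("ascii")
    quals = np.concatenate([left_q, cons_q, right_q])
    return MergedRead(
        read_id=r1.read_id,
        bases=bases,
        quals=quals,
        mate="merged",
        umi=r1.umi if r1.umi is not None else r2.umi,
        sample=r1.sample,
        overlap_len=o,
        r1_id=r1.read_id,
        r2_id=r2.read_id,
    )


# ---------------------------------------------------------------------------
# Quality filter
# ---------------------------------------------------------------------------


def quality_filter(read: SequencedRead) -> bool:
    """Keep iff mean Phred >= 30 and minimum per-base Phred >= 24."""
    if len(read) == 0:
        logger.info("quality_filter: empty read %s discarded", read.read_id)
        return False
    quals = read.quals
    return bool(quals.mean() >= MEAN_QUAL_MIN and quals.min() >= PER_BASE_QUAL_MIN)
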