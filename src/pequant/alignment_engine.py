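"""Pairwise alignment primitives for amplicon read classification.

Short amplicon references make full dynamic programming affordable, so reads
are aligned with exact affine-gap alignment rather than a seeded mapper:

* :func:`align_global` — end-to-end alignment of a read against a reference
  amplicon.  With ``infix=True`` the reference flanks are free (a read that
  covers only part of the amplicon, as UDiTaS fragments do, aligns to the
  matching sub-interval without end-gap penalties).
* :func:`align_local` — Smith–Waterman local alignment, used to find AAV
  vector fragments in chimeric reads.
* :func:`normalize_events` — convert an alignment into left-normalized
  insertion/deletion/substitution events so that identical molecules yield
  identical event keys regardless of where the DP placed a gap.
* :func:`split_align_breakpoints` — split (prefix/suffix) alignment for reads
  spanning deletion junctions too large for a single affine gap to score
  well; reports the deleted reference interval with microhomology resolved to
  the leftmost equivalent placement.

Scoring
-------
Defaults are match +2, mismatch -4, and an affine gap cost of
``gap_open + length * gap_extend`` with gap_open=-8, gap_extend=-1, chosen so
one long contiguous indel is preferred over scattered gaps — matching how
contiguous prime-editing deletions present in the data.  ``N`` scores 0
against everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "Scoring",
    "DEFAULT_SCORING",
    "Alignment",
    "IndelEvent",
    "AlignmentInputError",
    "align_global",
    "align_local",
    "align_score",
    "canonicalize_events",
    "normalize_events",
    "apply_events",
    "event_placement_range",
    "split_align_breakpoints",
    "alignment_identity",
    "cigar_string",
    "sam_record",
]

_ALPHABET = "ACGTN"
_LEGAL = set(_ALPHABET)


class AlignmentInputError(ValueError):
    """Raised for sequences containing characters outside {A,C,G,T,N}."""


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -4
    gap_open: int = -8
    gap_extend: int = -1


DEFAULT_SCORING = Scoring()


@dataclass
class Alignment:
    """A pairwise alignment as an ordered list of operations.

    ``ops`` entries are ``(op, length, segment)`` with op in
    {"match", "mismatch", "insertion", "deletion"}; ``segment`` holds the
    query sequence for insertions and mismatches, else "".
    """

    query_id: str
    ref_name: str
    ref_start: int
    ops: list[tuple[str, int, str]]
    score: float
    mode: str
    query: str = field(default="", repr=False)
    query_start: int = 0  # offset of the first aligned query base (local/infix)

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(
            n for op, n, _ in self.ops if op in ("match", "mismatch", "deletion")
        )

    @property
    def query_consumed(self) -> int:
        return sum(n for op, n, _ in self.ops if op in ("match", "mismatch", "insertion"))


@dataclass(frozen=True)
class IndelEvent:
    """A left-normalized sequence event relative to the reference.

    ``ref_pos`` is 0-based; for insertions it is the between-base offset at
    which the allele is inserted.  ``allele`` holds the inserted or
    substituted query sequence, or the deleted reference sequence.
    """

    kind: str  # insertion | deletion | substitution
    ref_pos: int
    length: int
    allele: str

    @property
    def ref_span(self) -> tuple[int, int]:
        """Reference interval consumed by the event (empty for insertions)."""
        if self.kind == "insertion":
            return (self.ref_pos, self.ref_pos)
        return (self.ref_pos, self.ref_pos + self.length)


def _check_seq(seq: str, what: str) -> None:
    if not seq:
        raise AlignmentInputError(f"{what} sequence is empty")
    bad = set(seq) - _LEGAL
    if bad:
        raise AlignmentInputError(f"{what} contains illegal characters: {sorted(bad)}")


@lru_cache(maxsize=16)
def _matrix(match: int, mismatch: int):
    m = np.full((5, 5), float(mismatch))
    np.fill_diagonal(m, float(match))
    m[4, :] = 0.0
    m[:, 4] = 0.0
    return substitution_matrices.Array(_ALPHABET, dims=2, data=m)


@lru_cache(maxsize=16)
def _aligner(scoring: Scoring, mode: str, infix: bool) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = _matrix(scoring.match, scoring.mismatch)
    # Package convention: gap of length L costs gap_open + L*gap_extend.
    al.open_gap_score = scoring.gap_open + scoring.gap_extend
    al.extend_gap_score = scoring.gap_extend
    al.mode = mode
    if infix:
        al.end_deletion_score = 0.0  # reference flanks outside the read are free
    return al


def _ops_from_aligned(
    ref: str, query: str, aligned: np.ndarray, trim_flanks: bool
) -> tuple[int, int, list[tuple[str, int, str]]]:
    """Convert Biopython aligned blocks into ``(ref_start, query_start, ops)``.

    ``trim_flanks`` drops reference-only overhangs before the first and after
    the last aligned block (infix/local modes).
    """
    t_blocks, q_blocks = aligned
    if len(t_blocks) == 0:
        return 0, 0, []
    ops: list[tuple[str, int, str]] = []
    ref_start = int(t_blocks[0][0])
    query_start = int(q_blocks[0][0])
    if not trim_flanks:
        if ref_start > 0:
            ops.append(("deletion", ref_start, ""))
        if query_start > 0:
            ops.append(("insertion", query_start, query[:query_start]))
        ref_start = 0
        query_start = 0
    prev_t = int(t_blocks[0][0])
    prev_q = int(q_blocks[0][0])
    for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
        t0, t1, q0, q1 = int(t0), int(t1), int(q0), int(q1)
        if t0 > prev_t:
            ops.append(("deletion", t0 - prev_t, ""))
        if q0 > prev_q:
            ops.append(("insertion", q0 - prev_q, query[prev_q:q0]))
        # run-length encode match/mismatch columns inside the block
        run_kind = None
        run_start = 0
        for k in range(t1 - t0):
            kind = "match" if ref[t0 + k] == query[q0 + k] or "N" in (
                ref[t0 + k],
                query[q0 + k],
            ) else "mismatch"
            if kind != run_kind:
                if run_kind is not None:
                    seg = query[q0 + run_start : q0 + k] if run_kind == "mismatch" else ""
                    ops.append((run_kind, k - run_start, seg))
                run_kind, run_start = kind, k
        if run_kind is not None:
            seg = query[q0 + run_start : q1] if run_kind == "mismatch" else ""
            ops.append((run_kind, (t1 - t0) - run_start, seg))
        prev_t, prev_q = t1, q1
    if not trim_flanks and prev_t < len(ref):
        ops.append(("deletion", len(ref) - prev_t, ""))
    if not trim_flanks:
        # query overhangs should not occur in global mode, but guard anyway
        if prev_q < len(query):
            ops.append(("insertion", len(query) - prev_q, query[prev_q:]))
    merged: list[tuple[str, int, str]] = []
    for op in ops:
        if merged and merged[-1][0] == op[0]:
            prev = merged[-1]
            merged[-1] = (op[0], prev[1] + op[1], prev[2] + op[2])
        else:
            merged.append(op)
    return ref_start, query_start, merged


def _align(
    query: str,
    ref: str,
    scoring: Scoring,
    mode: str,
    infix: bool,
    query_id: str,
    ref_name: str,
) -> Alignment:
    _check_seq(query, "query")
    _check_seq(ref, "ref")
    al = _aligner(scoring, mode, infix)
    result = al.align(ref, query)
    best = result[0]
    trim = infix or mode == "local"
    ref_start, query_start, ops = _ops_from_aligned(ref, query, best.aligned, trim_flanks=trim)
    return Alignment(
        query_id=query_id,
        ref_name=ref_name,
        ref_start=ref_start,
        ops=ops,
        score=float(best.score),
        mode="local" if mode == "local" else ("glocal" if infix else "global"),
        query=query,
        query_start=query_start,
    )


def align_global(
    query: str,
    ref: str,
    scoring: Scoring = DEFAULT_SCORING,
    *,
    infix: bool = False,
    query_id: str = "query",
    ref_name: str = "ref",
) -> Alignment:
    """Optimal affine-gap global (or reference-infix) alignment.

    Ties between co-optimal alignments are broken deterministically by the
    DP traversal order; downstream event normalization makes the reported
    events canonical regardless of gap placement.
    """
    return _align(query, ref, scoring, "global", infix, query_id, ref_name)


def align_local(
    query: str,
    ref: str,
    scoring: Scoring = DEFAULT_SCORING,
    *,
    query_id: str = "query",
    ref_name: str = "ref",
) -> Alignment:
    """Best-scoring local alignment (score 0 when nothing aligns)."""
    return _align(query, ref, scoring, "local", False, query_id, ref_name)


def align_score(query: str, ref: str, scoring: Scoring = DEFAULT_SCORING) -> float:
    """Global alignment score only (no traceback) — used by bulk screens."""
    _check_seq(query, "query")
    _check_seq(ref, "ref")
    return float(_aligner(scoring, "global", False).score(ref, query))


def alignment_identity(aln: Alignment) -> float:
    """Matched fraction of the query (matches / query length)."""
    matches = sum(n for op, n, _ in aln.ops if op == "match")
    qlen = len(aln.query) if aln.query else aln.query_consumed
    return matches / qlen if qlen else 0.0


# ---------------------------------------------------------------------------
# Event extraction and normalization
# ---------------------------------------------------------------------------


def canonicalize_events(
    events: list[IndelEvent], ref: str, floor: int = 0
) -> list[IndelEvent]:
    """Left-normalize a sorted, non-overlapping event list (VCF convention).

    A deletion at ``p`` of length ``L`` moves to ``p-1`` iff
    ``ref[p-1] == ref[p+L-1]``; an insertion rotates its allele
    correspondingly.  Shifting never crosses a preceding event or ``floor``.
    Adjacent same-kind events that normalization brought together are merged.
    """
    shifted: list[IndelEvent] = []
    lo = floor
    for ev in sorted(events, key=lambda e: (e.ref_pos, e.kind)):
        if ev.kind == "substitution":
            shifted.append(ev)
            lo = ev.ref_pos + ev.length
            continue
        if ev.kind == "deletion":
            p, L = ev.ref_pos, ev.length
            while p > lo and ref[p - 1] == ref[p + L - 1]:
                p -= 1
            shifted.append(IndelEvent("deletion", p, L, ref[p : p + L]))
            lo = p + L
            continue
        p, allele = ev.ref_pos, ev.allele
        while p > lo and allele[-1] == ref[p - 1]:
            allele = ref[p - 1] + allele[:-1]
            p -= 1
        shifted.append(IndelEvent("insertion", p, ev.length, allele))
        lo = p
    merged: list[IndelEvent] = []
    for ev in shifted:
        if merged:
            prev = merged[-1]
            if (
                prev.kind == ev.kind == "deletion"
                and prev.ref_pos + prev.length == ev.ref_pos
            ):
                merged[-1] = IndelEvent(
                    "deletion", prev.ref_pos, prev.length + ev.length, prev.allele + ev.allele
                )
                continue
            if prev.kind == ev.kind == "insertion" and prev.ref_pos == ev.ref_pos:
                merged[-1] = IndelEvent(
                    "insertion", prev.ref_pos, prev.length + ev.length, prev.allele + ev.allele
                )
                continue
        merged.append(ev)
    return merged


def normalize_events(aln: Alignment, ref: str) -> list[IndelEvent]:
    """Extract events from an alignment with every indel left-normalized,
    so identical molecules yield identical event keys regardless of where
    the DP placed a gap."""
    events: list[IndelEvent] = []
    tpos = aln.ref_start
    for op, n, seg in aln.ops:
        if op == "match":
            tpos += n
        elif op == "mismatch":
            events.append(IndelEvent("substitution", tpos, n, seg))
            tpos += n
        elif op == "deletion":
            events.append(IndelEvent("deletion", tpos, n, ref[tpos : tpos + n]))
            tpos += n
        elif op == "insertion":
            events.append(IndelEvent("insertion", tpos, n, seg))
    return canonicalize_events(events, ref, floor=aln.ref_start)


def event_placement_range(event: IndelEvent, ref: str) -> tuple[int, int]:
    """Envelope of all equivalent placements of an indel.

    Returns ``(min_start, max_end)``: the reference span touched by any
    placement of the event that produces the same edited sequence.  Used for
    robust window-overlap tests (a nick-site indel inside a homopolymer may
    left-normalize out of a naive window).  Substitutions have a single
    placement.
    """
    if event.kind == "substitution":
        return event.ref_span
    p, L = event.ref_pos, event.length
    if event.kind == "deletion":
        right = p
        while right + L < len(ref) and ref[right] == ref[right + L]:
            right += 1
        return (p, right + L)
    allele = event.allele
    right = p
    while right < len(ref) and allele[0] == ref[right]:
        allele = allele[1:] + ref[right]
        right += 1
    return (p, right)


def apply_events(ref: str, events: list[IndelEvent], span: Optional[tuple[int, int]] = None) -> str:
    """Reconstruct the query sequence by applying events to the reference.

    ``span`` restricts reconstruction to a reference interval (defaults to
    the whole reference).  Events must be sorted and non-overlapping, as
    produced by :func:`normalize_events`.
    """
    lo, hi = span if span is not None else (0, len(ref))
    out: list[str] = []
    cursor = lo
    for ev in events:
        s, e = ev.ref_span
        if s < cursor:
            raise ValueError("events overlap or are unsorted")
        out.append(ref[cursor:s])
        if ev.kind == "deletion":
            cursor = e
        elif ev.kind == "insertion":
            out.append(ev.allele)
            cursor = s
        else:
            out.append(ev.allele)
            cursor = e
    out.append(ref[cursor:hi])
    return "".join(out)


# ---------------------------------------------------------------------------
# Split alignment for large-deletion breakpoints
# ---------------------------------------------------------------------------


def _local_identity(aln: Alignment) -> float:
    cols = sum(n for op, n, _ in aln.ops)
    matches = sum(n for op, n, _ in aln.ops if op == "match")
    return matches / cols if cols else 0.0


def split_align_breakpoints(
    query: str,
    ref: str,
    scoring: Scoring = DEFAULT_SCORING,
    *,
    min_segment: int = 25,
    min_identity: float = 0.95,
    max_junction_insert: int = 20,
) -> Optional[dict]:
    """Detect a large-deletion junction by prefix/suffix split alignment.

    If a prefix and a suffix of the query (each consuming >= ``min_segment``
    query bases at >= ``min_identity``) align collinearly to disjoint
    reference windows, the deleted interval ``[left_end, right_start)`` is
    returned with microhomology resolved to the leftmost placement.  Returns
    ``None`` when no such split exists.
    """
    _check_seq(query, "query")
    _check_seq(ref, "ref")
    arm1 = align_local(query, ref, scoring)
    if not arm1.ops:
        return None
    if arm1.query_consumed < min_segment or _local_identity(arm1) < min_identity:
        return None
    q1_start = arm1.query_start
    q1_end = q1_start + arm1.query_consumed

    if len(query) - q1_end >= min_segment:
        arm2 = align_local(query[q1_end:], ref, scoring)
        gap = arm2.query_start if arm2.ops else 0
        call = _pair_arms(ref, arm1, arm2, junction_gap=gap,
                          min_segment=min_segment, min_identity=min_identity,
                          max_junction_insert=max_junction_insert)
        if call is not None:
            return call
    if q1_start >= min_segment:
        arm2 = align_local(query[:q1_start], ref, scoring)
        gap = q1_start - (arm2.query_start + arm2.query_consumed) if arm2.ops else 0
        call = _pair_arms(ref, arm2, arm1, junction_gap=gap,
                          min_segment=min_segment, min_identity=min_identity,
                          max_junction_insert=max_junction_insert)
        if call is not None:
            return call
    return None


def _pair_arms(
    ref: str,
    left: Alignment,
    right: Alignment,
    *,
    junction_gap: int,
    min_segment: int,
    min_identity: float,
    max_junction_insert: int,
) -> Optional[dict]:
    if not right.ops or not left.ops:
        return None
    if junction_gap > max_junction_insert:
        return None
    if left.query_consumed < min_segment or right.query_consumed < min_segment:
        return None
    if _local_identity(left) < min_identity or _local_identity(right) < min_identity:
        return None
    left_end = left.ref_end
    right_start = right.ref_start
    if right_start <= left_end:
        return None
    # microhomology: shift the junction to its leftmost equivalent placement
    while left_end > 0 and ref[left_end - 1] == ref[right_start - 1]:
        left_end -= 1
        right_start -= 1
    if right_start <= left_end:
        return None
    return {
        "left_end": left_end,
        "right_start": right_start,
        "size": right_start - left_end,
    }


# ---------------------------------------------------------------------------
# SAM export
# ---------------------------------------------------------------------------

_CIGAR_CODE = {"match": "=", "mismatch": "X", "insertion": "I", "deletion": "D"}


def cigar_string(aln: Alignment, dialect: str = "MID") -> str:
    """CIGAR for an alignment; dialect "MID" folds =/X into M."""
    out = []
    for op, n, _ in aln.ops:
        code = _CIGAR_CODE[op]
        if dialect == "MID" and code in "=X":
            code = "M"
        if out and out[-1][1] == code:
            out[-1] = (out[-1][0] + n, code)
        else:
            out.append((n, code))
    return "".join(f"{n}{c}" for n, c in out)


def sam_record(aln: Alignment, quals: Optional[str] = None, dialect: str = "MID") -> str:
    """Render one SAM line for an aligned read (mapped, forward strand)."""
    qual = quals if quals is not None else "*"
    return "\t".join(
        [
            aln.query_id,
            "0",
            aln.ref_name,
            str(aln.ref_start + 1),
            "60",
            cigar_string(aln, dialect),
            "*",
            "0",
            "0",
            aln.query or "*",
            qual,
        ]
    )
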