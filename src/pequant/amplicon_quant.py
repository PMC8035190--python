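"""Amplicon-mode quantification of prime-editing outcomes.

A merged, quality-filtered read is aligned globally to the unedited amplicon
and called against the quantification window:

* ``precise_edit`` — the read's window sequence equals the edited allele's
  window exactly: the intended edit AND the synonymous PAM modification are
  present with no other event in the window.
* ``wild_type`` — the window sequence equals the unedited amplicon.
* ``indel`` — at least one insertion/deletion event touches the window.
* ``substitution_other`` — anything else (unintended substitutions, or the
  edit without the PAM modification, or sequencing errors in the window).
* ``ambiguous`` — the read does not cover the window (never silently dropped).

Per-event frequencies are cataloged in an :class:`IndelTable`, and the mean
frequency of each event key across negative-control replicates is subtracted
(floored at zero) to remove PCR/sequencing artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .alignment_engine import (
    Alignment,
    IndelEvent,
    canonicalize_events,
    event_placement_range,
    normalize_events,
)
from .core_model import AmpliconSpec, EditSpec, EditedAllele

__all__ = [
    "CALLS",
    "ReadOutcome",
    "IndelTable",
    "AmpliconSummary",
    "read_window_sequence",
    "edit_events",
    "window_haplotype",
    "call_read_outcome",
    "catalog_indels",
    "subtract_background",
    "summarize_amplicon",
]

CALLS = ("wild_type", "precise_edit", "indel", "substitution_other", "ambiguous")


@dataclass
class ReadOutcome:
    read_id: str
    call: str
    events: list[IndelEvent] = field(default_factory=list)
    window_events: list[IndelEvent] = field(default_factory=list)


@dataclass
class IndelTable:
    """Per-event frequency catalog.

    ``df`` columns: kind, ref_pos, length, allele, reads, freq and (after
    background subtraction) net_freq.  Frequencies use the total number of
    passing reads as denominator.
    """

    df: pd.DataFrame
    total_reads: int
    amplicon_name: str
    background_subtracted: bool = False

    KEY = ["kind", "ref_pos", "length", "allele"]


@dataclass
class AmpliconSummary:
    counts: dict[str, int]
    rates: dict[str, float]
    total_reads: int
    indel_table: Optional[IndelTable] = None
    net_indel_rate: Optional[float] = None

    @property
    def precise_rate(self) -> float:
        return self.rates["precise_edit"]

    @property
    def indel_rate(self) -> float:
        return self.rates["indel"]

    @property
    def wild_type_rate(self) -> float:
        return self.rates["wild_type"]


def read_window_sequence(
    aln: Alignment, window: tuple[int, int]
) -> Optional[str]:
    """The query bases presented across a reference window.

    Includes query bases aligned to reference positions in ``[w0, w1)`` and
    insertions anchored strictly inside the window.  Returns ``None`` when
    the alignment does not span the full window.
    """
    w0, w1 = window
    if aln.ref_start > w0 or aln.ref_end < w1:
        return None
    out: list[str] = []
    tpos = aln.ref_start
    qpos = aln.query_start
    query = aln.query
    for op, n, seg in aln.ops:
        if op in ("match", "mismatch"):
            lo = max(tpos, w0)
            hi = min(tpos + n, w1)
            if hi > lo:
                out.append(query[qpos + (lo - tpos) : qpos + (hi - tpos)])
            tpos += n
            qpos += n
        elif op == "deletion":
            tpos += n
        elif op == "insertion":
            if w0 < tpos < w1:
                out.append(query[qpos : qpos + n])
            qpos += n
        if tpos >= w1 and op != "insertion":
            # insertions exactly at w1 are outside the window; stop here
            break
    return "".join(out)


def edit_events(amplicon: AmpliconSpec, edit: EditSpec) -> list[IndelEvent]:
    """The edit spec expressed as left-normalized reference events.

    Substitution runs are emitted only where bases actually change, so an
    identity edit yields no events.
    """
    seq = amplicon.sequence
    r0, r1 = edit.ref_interval
    raw: list[IndelEvent] = []
    if edit.edit_type == "substitution" or (
        edit.edit_type == "replacement" and (r1 - r0) == len(edit.alt_segment)
    ):
        run_start = None
        for i, (a, b) in enumerate(zip(seq[r0:r1], edit.alt_segment)):
            if a != b and run_start is None:
                run_start = i
            elif a == b and run_start is not None:
                raw.append(
                    IndelEvent("substitution", r0 + run_start, i - run_start,
                               edit.alt_segment[run_start:i])
                )
                run_start = None
        if run_start is not None:
            raw.append(
                IndelEvent("substitution", r0 + run_start, (r1 - r0) - run_start,
                           edit.alt_segment[run_start:])
            )
    elif edit.edit_type == "deletion":
        raw.append(IndelEvent("deletion", r0, r1 - r0, seq[r0:r1]))
    elif edit.edit_type == "insertion":
        raw.append(IndelEvent("insertion", r0, len(edit.alt_segment), edit.alt_segment))
    else:  # replacement with length change: deletion plus insertion
        raw.append(IndelEvent("deletion", r0, r1 - r0, seq[r0:r1]))
        if edit.alt_segment:
            raw.append(IndelEvent("insertion", r0, len(edit.alt_segment), edit.alt_segment))
    if edit.pam_mod is not None:
        raw.append(
            IndelEvent("substitution", edit.pam_mod.position, 1, edit.pam_mod.alt)
        )
    return canonicalize_events(raw, seq)


def window_haplotype(
    ref: str, events: Sequence[IndelEvent], window: tuple[int, int]
) -> str:
    """Project events onto a reference window and return the resulting bases.

    Events must be left-normalized and sorted; insertions anchored exactly at
    a window boundary are treated as outside the window.  Because both the
    read's events and the edit spec's events pass through the same
    normalization, the comparison is invariant to where the aligner placed an
    equivalent gap — even when the placement range straddles the window edge.
    """
    w0, w1 = window
    pieces: list[str] = []
    cursor = w0
    # at equal positions an insertion applies before a deletion starting
    # there: a replacement reads prefix + inserted allele + suffix
    order = {"insertion": 0, "deletion": 1, "substitution": 1}
    for ev in sorted(events, key=lambda e: (e.ref_pos, order[e.kind])):
        if ev.kind == "insertion":
            if w0 < ev.ref_pos < w1 and ev.ref_pos >= cursor:
                pieces.append(ref[cursor : ev.ref_pos])
                pieces.append(ev.allele)
                cursor = ev.ref_pos
            continue
        s, e = ev.ref_span
        if e <= w0 or s >= w1 or e <= cursor:
            continue
        s_c, e_c = max(s, cursor), min(e, w1)
        pieces.append(ref[cursor:s_c])
        if ev.kind == "substitution":
            pieces.append(ev.allele[s_c - s : e_c - s])
        cursor = e_c
    pieces.append(ref[cursor:w1])
    return "".join(pieces)


def _indel_touches_window(
    event: IndelEvent, window: tuple[int, int], ref: str
) -> bool:
    """Overlap test robust to left-normalization.

    Uses the envelope of all equivalent placements, with closed-interval
    ("touching") semantics so a deletion ending exactly at the window start,
    or an insertion anchored at a window boundary, still counts.
    """
    if event.kind == "substitution":
        s, e = event.ref_span
        return s < window[1] and e > window[0]
    lo, hi = event_placement_range(event, ref)
    return lo <= window[1] and hi >= window[0]


def call_read_outcome(
    aln: Alignment,
    amplicon: AmpliconSpec,
    edit: EditSpec,
    edited: EditedAllele,
) -> ReadOutcome:
    """Classify one aligned read against the quantification window.

    The precise/wild-type decision compares the read's window sequence with
    the edited and unedited window strings derived from the edit spec — an
    exact-match rule with no error tolerance, so sequencing errors inside the
    window demote a read to ``substitution_other``.
    """
    window = edit.window(amplicon)
    w0, w1 = window
    ref = amplicon.sequence
    events = normalize_events(aln, ref)
    window_events = [ev for ev in events if _indel_touches_window(ev, window, ref)]
    if aln.ref_start > w0 or aln.ref_end < w1:
        return ReadOutcome(aln.query_id, "ambiguous", events, window_events)
    observed = window_haplotype(ref, events, window)
    if observed == window_haplotype(ref, edit_events(amplicon, edit), window):
        call = "precise_edit"
    elif any(ev.kind in ("insertion", "deletion") for ev in window_events):
        call = "indel"
    elif observed == ref[w0:w1]:
        call = "wild_type"
    else:
        call = "substitution_other"
    return ReadOutcome(aln.query_id, call, events, window_events)


def catalog_indels(
    outcomes: Iterable[ReadOutcome],
    amplicon: AmpliconSpec,
    *,
    in_window_only: bool = True,
) -> IndelTable:
    """One row per distinct (kind, ref_pos, length, allele) event.

    The denominator is the total number of passing reads, and each read
    supports an event key at most once.
    """
    rows: dict[tuple, int] = {}
    total = 0
    for outcome in outcomes:
        total += 1
        events = outcome.window_events if in_window_only else outcome.events
        for ev in set(events):
            key = (ev.kind, ev.ref_pos, ev.length, ev.allele)
            rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame(
        [(k[0], k[1], k[2], k[3], n) for k, n in sorted(rows.items())],
        columns=["kind", "ref_pos", "length", "allele", "reads"],
    )
    df["freq"] = df["reads"] / total if total else 0.0
    return IndelTable(df=df, total_reads=total, amplicon_name=amplicon.name)


def subtract_background(
    treatment: IndelTable, controls: Sequence[IndelTable]
) -> IndelTable:
    """Subtract the mean control frequency per event key, floored at zero.

    Keys are (kind, position, length, allele) — stricter than type+position
    alone, so a control artifact cannot cancel a different event at the same
    base.  Keys absent from every control pass through unchanged.
    """
    if not controls:
        raise ValueError("at least one control table is required")
    for c in controls:
        if c.amplicon_name != treatment.amplicon_name:
            raise ValueError(
                f"control table for amplicon {c.amplicon_name!r} does not match "
                f"treatment amplicon {treatment.amplicon_name!r}"
            )
    key = IndelTable.KEY
    ctrl_freqs = []
    for c in controls:
        if len(c.df):
            ctrl_freqs.append(c.df[key + ["freq"]])
    df = treatment.df.copy()
    if ctrl_freqs:
        pooled = pd.concat(ctrl_freqs, ignore_index=True)
        # a key absent from one control replicate contributes frequency 0
        mean_bg = (
            pooled.groupby(key, as_index=False)["freq"].sum().assign(
                bg=lambda d: d["freq"] / len(controls)
            )
        ).drop(columns="freq")
        df = df.merge(mean_bg, on=key, how="left")
        df["bg"] = df["bg"].fillna(0.0)
    else:
        df["bg"] = 0.0
    # rounding at 1e-12 removes binary round-off from the mean so that exact
    # treatment/control cancellation yields exactly zero (real frequencies
    # are never below 1/total_reads)
    df["net_freq"] = (df["freq"] - df["bg"]).round(12).clip(lower=0.0)
    df = df.drop(columns="bg")
    return IndelTable(
        df=df,
        total_reads=treatment.total_reads,
        amplicon_name=treatment.amplicon_name,
        background_subtracted=True,
    )


def summarize_amplicon(
    outcomes: Sequence[ReadOutcome],
    indel_table: Optional[IndelTable] = None,
) -> AmpliconSummary:
    """Category counts and rates over all passing reads.

    ``net_indel_rate`` (when a background-subtracted table is supplied) is
    the summed net frequency of insertion/deletion rows — the event-level
    indel burden remaining after control subtraction.
    """
    if not outcomes:
        raise ValueError("no passing reads to summarize")
    counts = {c: 0 for c in CALLS}
    for outcome in outcomes:
        counts[outcome.call] += 1
    total = len(outcomes)
    rates = {c: counts[c] / total for c in CALLS}
    net = None
    if indel_table is not None and indel_table.background_subtracted:
        mask = indel_table.df["kind"].isin(["insertion", "deletion"])
        net = float(indel_table.df.loc[mask, "net_freq"].sum())
    return AmpliconSummary(
        counts=counts,
        rates=rates,
        total_reads=total,
        indel_table=indel_table,
        net_indel_rate=net,
    )
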