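"""UDiTaS-mode quantification: UMI families, exemplar classification, and
large-deletion significance.

Unidirectional targeted sequencing (UDiTaS) anchors read 2 at a
locus-specific primer and lets Tn5 tagmentation set the other fragment end,
so one library captures small edits, kilobase-scale deletions and vector
(AAV) integrations without amplicon dropout bias.  Reads sharing a UMI are
collapsed to one exemplar, and each family is classified into exactly one
category:

``aav_integration`` > ``precise_edit`` > ``pegnick_deletion`` (a deletion
spanning both nick sites, < 100 bp) > ``small_indel_sub`` (< 50 bp) >
``large_deletion`` (>= 100 bp, via split alignment when needed) >
``wild_type``, else ``unclassified``.

Integration calls pass a false-priming filter: a read whose AAV hit starts
directly at the UDiTaS primer footprint and which carries no genuine locus
sequence beyond the primer was primed on the vector itself and is rejected.

Large-deletion families sharing identical normalized breakpoints form
clusters whose UMI support is tested against a background rate with a
one-sided binomial tail; Benjamini–Hochberg adjustment across clusters gates
significance at 0.05.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .alignment_engine import (
    Alignment,
    DEFAULT_SCORING,
    IndelEvent,
    Scoring,
    align_global,
    align_local,
    alignment_identity,
    event_placement_range,
    normalize_events,
    split_align_breakpoints,
)
from .amplicon_quant import call_read_outcome
from .core_model import AmpliconSpec, EditSpec, EditedAllele
from .read_processing import SequencedRead

logger = logging.getLogger(__name__)

__all__ = [
    "UDITAS_CATEGORIES",
    "ClassifyParams",
    "UmiFamily",
    "DeletionCluster",
    "UditasSummary",
    "build_umi_families",
    "select_exemplar",
    "classify_family",
    "detect_aav_integration",
    "cluster_deletions",
    "deletion_significance",
    "estimate_background_rate",
    "summarize_uditas",
]

UDITAS_CATEGORIES = (
    "wild_type",
    "precise_edit",
    "small_indel_sub",
    "pegnick_deletion",
    "large_deletion",
    "aav_integration",
    "unclassified",
)


@dataclass(frozen=True)
class ClassifyParams:
    """Size thresholds and alignment gates for family classification.

    Sizes follow the outcome taxonomy: small indels are < 50 bp, deletions
    between the pegRNA and nicking-sgRNA sites are < 100 bp, large deletions
    are >= 100 bp (the boundary value 100 is assigned to large).
    """

    small_indel_max: int = 49
    pegnick_deletion_max: int = 99
    large_deletion_min: int = 100
    min_local_score: float = 40.0
    locus_match_k: int = 15
    min_global_identity: float = 0.60
    split_retry_identity: float = 0.95
    min_split_segment: int = 25


@dataclass
class UmiFamily:
    umi: str
    members: list[SequencedRead]
    exemplar: Optional[SequencedRead] = None
    category: Optional[str] = None
    events: list[IndelEvent] = field(default_factory=list)
    deletion_call: Optional[tuple[int, int]] = None  # deleted [start, end)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"UMI family {self.umi} has no members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class DeletionCluster:
    start: int
    end: int
    umi_count: int
    p_value: Optional[float] = None
    p_adjusted: Optional[float] = None
    significant: Optional[bool] = None

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class UditasSummary:
    counts: dict[str, int]
    ratios: dict[str, float]
    total_umis: int
    aav_fraction: float
    clusters: list[DeletionCluster] = field(default_factory=list)
    family_size_histogram: dict[int, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Families and exemplars
# ---------------------------------------------------------------------------


def build_umi_families(
    reads: Iterable[SequencedRead],
) -> tuple[list[UmiFamily], int]:
    """Group reads by exact UMI string; UMIs are not error-corrected.

    Returns ``(families, n_without_umi)``; reads lacking a UMI are excluded
    and counted.
    """
    groups: dict[str, list[SequencedRead]] = defaultdict(list)
    n_missing = 0
    for read in reads:
        if read.umi is None:
            n_missing += 1
            continue
        groups[read.umi].append(read)
    families = [UmiFamily(umi=u, members=groups[u]) for u in sorted(groups)]
    hist = Counter(f.size for f in families)
    logger.info(
        "build_umi_families: %d families from %d reads (%d without UMI); sizes %s",
        len(families),
        sum(f.size for f in families),
        n_missing,
        dict(sorted(hist.items())),
    )
    return families, n_missing


def select_exemplar(family: UmiFamily) -> SequencedRead:
    """The family's most frequent member sequence.

    Ties break by highest summed base quality, then lexicographically by
    sequence — fully deterministic.
    """
    freq = Counter(read.bases for read in family.members)
    best_qual: dict[str, float] = defaultdict(float)
    rep: dict[str, SequencedRead] = {}
    for read in family.members:
        q = float(read.quals.sum())
        if read.bases not in rep or q > best_qual[read.bases]:
            rep[read.bases] = read
            best_qual[read.bases] = q
    ranked = sorted(
        freq, key=lambda s: (-freq[s], -best_qual[s], s)
    )
    exemplar = rep[ranked[0]]
    family.exemplar = exemplar
    return exemplar


# ---------------------------------------------------------------------------
# AAV integration
# ---------------------------------------------------------------------------


def _has_locus_match(
    bases: str, amplicon: AmpliconSpec, k: int
) -> bool:
    """Does the read share a >= k-base exact match with the locus outside the
    UDiTaS primer footprint?"""
    ref = amplicon.sequence
    if amplicon.uditas_primer_interval is not None:
        p0, p1 = amplicon.uditas_primer_interval
        ref = ref[:p0] + ("N" * (p1 - p0)) + ref[p1:]
    for i in range(0, len(bases) - k + 1):
        if bases[i : i + k] in ref:
            return True
    return False


def detect_aav_integration(
    read: SequencedRead,
    aav_ref: str,
    amplicon: AmpliconSpec,
    params: ClassifyParams = ClassifyParams(),
    scoring: Scoring = DEFAULT_SCORING,
) -> Optional[dict]:
    """Call an AAV/plasmid integration junction, filtering false priming.

    A call requires a local alignment to the vector scoring at least
    ``min_local_score``.  False priming — the vector hit beginning directly
    after the locus primer with no >= ``locus_match_k``-base locus sequence
    elsewhere in the read — is rejected.
    """
    aln = align_local(read.bases, aav_ref, scoring)
    if not aln.ops or aln.score < params.min_local_score:
        return None
    primer_len = 0
    if amplicon.uditas_primer_interval is not None:
        p0, p1 = amplicon.uditas_primer_interval
        primer_len = p1 - p0
        primer_seq = amplicon.sequence[p0:p1]
        adjacent = (
            read.bases.startswith(primer_seq)
            and aln.query_start <= primer_len + 2
        )
        if adjacent and not _has_locus_match(
            read.bases[primer_len:], amplicon, params.locus_match_k
        ):
            return None  # false priming on the vector
    if not _has_locus_match(read.bases, amplicon, params.locus_match_k):
        return None
    return {
        "aav_start": aln.ref_start,
        "aav_end": aln.ref_end,
        "read_start": aln.query_start,
        "read_end": aln.query_start + aln.query_consumed,
        "score": aln.score,
    }


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _deletion_spans_both_nicks(
    ev: IndelEvent, amplicon: AmpliconSpec, ref: str
) -> bool:
    lo_nick, hi_nick = amplicon.nick_window
    lo, hi = event_placement_range(ev, ref)
    return lo <= lo_nick and hi >= hi_nick


def _indel_in_nick_window(ev: IndelEvent, amplicon: AmpliconSpec, ref: str) -> bool:
    lo_nick, hi_nick = amplicon.nick_window
    lo, hi = event_placement_range(ev, ref)
    return lo <= hi_nick and hi >= lo_nick


def _classify_by_split(
    family: UmiFamily,
    exemplar: SequencedRead,
    amplicon: AmpliconSpec,
    params: ClassifyParams,
    scoring: Scoring,
) -> Optional[str]:
    """Category from split-alignment breakpoints, or None without a call."""
    call = split_align_breakpoints(
        exemplar.bases, amplicon.sequence, scoring,
        min_segment=params.min_split_segment,
    )
    if call is None:
        return None
    family.deletion_call = (call["left_end"], call["right_start"])
    if call["size"] >= params.large_deletion_min:
        return "large_deletion"
    if (
        call["left_end"] <= amplicon.nick_window[0]
        and call["right_start"] >= amplicon.nick_window[1]
    ):
        return "pegnick_deletion"
    return "unclassified"


def classify_family(
    family: UmiFamily,
    amplicon: AmpliconSpec,
    edit: EditSpec,
    edited: EditedAllele,
    aav_ref: Optional[str] = None,
    params: ClassifyParams = ClassifyParams(),
    scoring: Scoring = DEFAULT_SCORING,
) -> str:
    """Assign the family's exemplar to exactly one outcome category.

    The decision cascade runs AAV integration first (junction evidence wins),
    then requires the exemplar to cover the window between the two nick
    sites, then tests precise edit, nick-to-nick deletion, small
    indel/substitution, large deletion, and wild type in that order.
    Substitutions outside the quantification window are treated as
    sequencing noise and do not demote a family from wild type.
    """
    exemplar = family.exemplar or select_exemplar(family)
    ref = amplicon.sequence

    aln = align_global(
        exemplar.bases, ref, scoring, infix=True, query_id=exemplar.read_id,
        ref_name=amplicon.name,
    )
    identity = alignment_identity(aln)

    if identity < params.split_retry_identity:
        # an imperfect end-to-end alignment may hide a vector junction or a
        # deletion junction as scattered chance matches; junction-based
        # evidence (AAV local hit, then split breakpoints) takes precedence
        if aav_ref is not None:
            hit = detect_aav_integration(exemplar, aav_ref, amplicon, params, scoring)
            if hit is not None:
                family.category = "aav_integration"
                return family.category
        cat = _classify_by_split(family, exemplar, amplicon, params, scoring)
        if cat is not None:
            family.category = cat
            return family.category
        if identity < params.min_global_identity:
            # poorly mapped with no junction evidence
            family.category = "unclassified"
            return family.category

    events = normalize_events(aln, ref)
    family.events = events
    # a well-scoring alignment can still hide a vector junction as one long
    # terminal insertion; junction-based evidence takes precedence
    if aav_ref is not None and aln.ops:
        terminal_ins = [
            op for op in (aln.ops[0], aln.ops[-1]) if op[0] == "insertion" and op[1] >= 30
        ]
        if terminal_ins:
            hit = detect_aav_integration(exemplar, aav_ref, amplicon, params, scoring)
            if hit is not None:
                family.category = "aav_integration"
                return family.category
    lo_nick, hi_nick = amplicon.nick_window
    # the wild-type call asserts the absence of events between the nicks, so
    # it needs the exemplar to span that window; event-based calls only need
    # the evidence actually observed
    covers_nick_window = aln.ref_start <= lo_nick and aln.ref_end >= hi_nick

    outcome = call_read_outcome(aln, amplicon, edit, edited)
    if outcome.call == "ambiguous":
        family.category = "unclassified"
        return family.category
    if outcome.call == "precise_edit":
        family.category = "precise_edit"
        return family.category

    indels = [ev for ev in events if ev.kind in ("insertion", "deletion")]
    spanning = [
        ev
        for ev in indels
        if ev.kind == "deletion" and _deletion_spans_both_nicks(ev, amplicon, ref)
    ]
    for ev in spanning:
        if ev.length >= params.large_deletion_min:
            family.category = "large_deletion"
            family.deletion_call = (ev.ref_pos, ev.ref_pos + ev.length)
            return family.category
    for ev in spanning:
        if ev.length <= params.pegnick_deletion_max:
            family.category = "pegnick_deletion"
            family.deletion_call = (ev.ref_pos, ev.ref_pos + ev.length)
            return family.category

    window_indels = [ev for ev in indels if _indel_in_nick_window(ev, amplicon, ref)]
    if any(ev.length <= params.small_indel_max for ev in window_indels):
        family.category = "small_indel_sub"
        return family.category
    for ev in indels:
        if ev.kind == "deletion" and ev.length >= params.large_deletion_min:
            family.category = "large_deletion"
            family.deletion_call = (ev.ref_pos, ev.ref_pos + ev.length)
            return family.category
    if outcome.call == "substitution_other":
        # an unintended substitution inside the quantification window
        family.category = "small_indel_sub"
        return family.category
    if outcome.call == "wild_type" and not window_indels and covers_nick_window:
        family.category = "wild_type"
        return family.category
    family.category = "unclassified"
    return family.category


# ---------------------------------------------------------------------------
# Deletion clustering and significance
# ---------------------------------------------------------------------------


def cluster_deletions(families: Sequence[UmiFamily]) -> list[DeletionCluster]:
    """Group large-deletion families by identical normalized breakpoints."""
    groups: Counter[tuple[int, int]] = Counter()
    for family in families:
        if family.category == "large_deletion" and family.deletion_call is not None:
            groups[family.deletion_call] += 1
    return [
        DeletionCluster(start=s, end=e, umi_count=n)
        for (s, e), n in sorted(groups.items())
    ]


def estimate_background_rate(
    control_deletion_umis: int, control_total_umis: int, pseudocount: float = 0.5
) -> float:
    """Pooled control estimate of the per-UMI large-deletion probability."""
    if control_total_umis <= 0:
        raise ValueError("control_total_umis must be positive")
    return (control_deletion_umis + pseudocount) / control_total_umis


def deletion_significance(
    clusters: Sequence[DeletionCluster],
    total_umis: int,
    background_rate: float,
    alpha: float = 0.05,
) -> list[DeletionCluster]:
    """Binomial enrichment test per cluster with BH adjustment.

    Per cluster the one-sided tail ``P(X >= umi_count | n=total_umis,
    p=background_rate)`` is computed; Benjamini–Hochberg adjustment runs
    across all clusters and significance is called at adjusted p <= alpha.
    """
    if total_umis <= 0:
        raise ValueError("total_umis must be positive")
    if not clusters:
        return []
    pvals = np.array(
        [
            float(stats.binom.sf(c.umi_count - 1, total_umis, background_rate))
            if c.umi_count > 0
            else 1.0
            for c in clusters
        ]
    )
    _, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    for cluster, p, q in zip(clusters, pvals, p_adj):
        cluster.p_value = float(p)
        cluster.p_adjusted = float(max(p, q))
        cluster.significant = bool(cluster.p_adjusted <= alpha)
    return list(clusters)


def summarize_uditas(
    families: Sequence[UmiFamily],
    clusters: Optional[Sequence[DeletionCluster]] = None,
) -> UditasSummary:
    """Per-category UMI counts and ratios (denominator: all UMI families)."""
    if not families:
        raise ValueError("no UMI families to summarize")
    counts = {c: 0 for c in UDITAS_CATEGORIES}
    for family in families:
        if family.category is None:
            raise ValueError(f"family {family.umi} has not been classified")
        counts[family.category] += 1
    total = len(families)
    ratios = {c: counts[c] / total for c in UDITAS_CATEGORIES}
    assert sum(counts.values()) == total
    hist = dict(sorted(Counter(f.size for f in families).items()))
    return UditasSummary(
        counts=counts,
        ratios=ratios,
        total_umis=total,
        aav_fraction=counts["aav_integration"] / total,
        clusters=list(clusters or []),
        family_size_histogram=hist,
    )
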