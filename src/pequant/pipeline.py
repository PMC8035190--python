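"""Pipeline drivers tying the stages into the two quantification modes.

``run_amplicon`` executes merge -> quality filter -> global alignment ->
outcome calling -> indel catalog -> control background subtraction.
``run_uditas`` executes UMI extraction -> merge/anchor -> UMI families ->
exemplar classification -> deletion clustering -> BH significance.  Both
write TSV/JSON artifacts plus a manifest with per-stage read accounting.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .alignment_engine import DEFAULT_SCORING, Scoring, align_global
from .amplicon_quant import (
    AmpliconSummary,
    IndelTable,
    call_read_outcome,
    catalog_indels,
    subtract_background,
    summarize_amplicon,
)
from .core_model import AmpliconSpec, EditSpec, build_edited_allele
from .read_processing import (
    MergedRead,
    SequencedRead,
    UmiScheme,
    extract_umi,
    merge_pair,
    quality_filter,
    read_fastq,
)
from .uditas_quant import (
    ClassifyParams,
    UditasSummary,
    build_umi_families,
    classify_family,
    cluster_deletions,
    deletion_significance,
    estimate_background_rate,
    select_exemplar,
    summarize_uditas,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunManifest",
    "PipelineError",
    "run_amplicon",
    "run_uditas",
    "generate_report",
    "plot_deletion_spans",
]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunManifest:
    version: str = __version__
    mode: str = ""
    config_sha256: str = ""
    input_sha256: dict[str, str] = field(default_factory=dict)
    seed: Optional[int] = None
    stages: list[dict] = field(default_factory=list)
    started: float = 0.0
    finished: float = 0.0

    def add_stage(self, name: str, n_in: int, n_out: int, **routed: int) -> None:
        n_routed = sum(routed.values())
        if n_in != n_out + n_routed:
            raise PipelineError(
                f"stage {name}: accounting violated ({n_in} in != {n_out} out "
                f"+ {n_routed} routed)"
            )
        self.stages.append({"stage": name, "in": n_in, "out": n_out, **routed})
        logger.info("stage %s: %d in, %d out, routed %s", name, n_in, n_out, routed)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)


def _sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_pairs(
    r1, r2
) -> tuple[list[SequencedRead], list[SequencedRead]]:
    """Accept in-memory read lists or FASTQ paths."""
    if isinstance(r1, (str, Path)):
        r1 = list(read_fastq(r1, mate="R1"))
    if isinstance(r2, (str, Path)):
        r2 = list(read_fastq(r2, mate="R2"))
    if len(r1) != len(r2):
        raise PipelineError(f"R1/R2 pair count mismatch: {len(r1)} vs {len(r2)}")
    if not r1:
        raise PipelineError("empty input: no read pairs")
    return list(r1), list(r2)


# ---------------------------------------------------------------------------
# Amplicon mode
# ---------------------------------------------------------------------------


def _amplicon_outcomes(
    amplicon: AmpliconSpec,
    edit: EditSpec,
    r1,
    r2,
    scoring: Scoring,
    manifest: RunManifest,
    label: str = "sample",
):
    edited = build_edited_allele(amplicon, edit)
    r1, r2 = _load_pairs(r1, r2)
    n_pairs = len(r1)
    merged: list[MergedRead] = []
    for a, b in zip(r1, r2):
        m = merge_pair(a, b)
        if m is not None:
            merged.append(m)
    manifest.add_stage(f"{label}:merge", n_pairs, len(merged),
                       merge_failed=n_pairs - len(merged))
    passing = [m for m in merged if quality_filter(m)]
    manifest.add_stage(f"{label}:quality_filter", len(merged), len(passing),
                       low_quality=len(merged) - len(passing))
    outcomes = []
    for read in passing:
        aln = align_global(
            read.bases, amplicon.sequence, scoring,
            query_id=read.read_id, ref_name=amplicon.name,
        )
        outcomes.append(call_read_outcome(aln, amplicon, edit, edited))
    manifest.add_stage(f"{label}:align_call", len(passing), len(outcomes))
    return outcomes, edited


def run_amplicon(
    amplicon: AmpliconSpec,
    edit: EditSpec,
    r1,
    r2,
    controls: Sequence[tuple] = (),
    outdir: Optional[str | Path] = None,
    scoring: Scoring = DEFAULT_SCORING,
    seed: Optional[int] = None,
) -> tuple[AmpliconSummary, RunManifest]:
    """Amplicon-mode quantification of one sample.

    ``controls`` is a sequence of (r1, r2) read sets (paths or read lists)
    from negative-control replicates; their mean per-event indel frequencies
    are subtracted from the treatment catalog.
    """
    manifest = RunManifest(mode="amplicon", seed=seed, started=time.time())
    for path_like, name in ((r1, "r1"), (r2, "r2")):
        if isinstance(path_like, (str, Path)):
            manifest.input_sha256[name] = _sha256_file(path_like)
    outcomes, _ = _amplicon_outcomes(amplicon, edit, r1, r2, scoring, manifest)
    if not outcomes:
        raise PipelineError("no reads passed merging and quality filtering")
    table = catalog_indels(outcomes, amplicon)
    if controls:
        control_tables = []
        for i, (cr1, cr2) in enumerate(controls):
            ctrl_outcomes, _ = _amplicon_outcomes(
                amplicon, edit, cr1, cr2, scoring, manifest, label=f"control{i}"
            )
            control_tables.append(catalog_indels(ctrl_outcomes, amplicon))
        table = subtract_background(table, control_tables)
    summary = summarize_amplicon(outcomes, table)
    manifest.finished = time.time()
    if outdir is not None:
        _write_amplicon_artifacts(Path(outdir), summary, table, manifest)
    return summary, manifest


def _write_amplicon_artifacts(
    outdir: Path, summary: AmpliconSummary, table: IndelTable, manifest: RunManifest
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    df = table.df.copy()
    df.insert(2, "pos_1based", df["ref_pos"] + 1)
    df.to_csv(outdir / "indel_catalog.tsv", sep="\t", index=False)
    payload = {
        "total_reads": summary.total_reads,
        "counts": summary.counts,
        "rates": summary.rates,
        "net_indel_rate": summary.net_indel_rate,
    }
    (outdir / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    (outdir / "manifest.json").write_text(manifest.to_json())


# ---------------------------------------------------------------------------
# UDiTaS mode
# ---------------------------------------------------------------------------


def run_uditas(
    amplicon: AmpliconSpec,
    edit: EditSpec,
    r1,
    r2,
    aav_reference: Optional[str] = None,
    umi_scheme: UmiScheme = UmiScheme(source="read-prefix", length=12),
    params: ClassifyParams = ClassifyParams(),
    background_rate: Optional[float] = None,
    outdir: Optional[str | Path] = None,
    scoring: Scoring = DEFAULT_SCORING,
    seed: Optional[int] = None,
) -> tuple[UditasSummary, RunManifest]:
    """UDiTaS-mode quantification: UMI-collapsed outcome composition.

    Read 2 anchors the locus-specific primer (and carries the UMI for
    read-prefix schemes); read 1 carries the Tn5 end.  When the pair merges
    the consensus is classified, otherwise read 2 alone is.
    """
    manifest = RunManifest(mode="uditas", seed=seed, started=time.time())
    for path_like, name in ((r1, "r1"), (r2, "r2")):
        if isinstance(path_like, (str, Path)):
            manifest.input_sha256[name] = _sha256_file(path_like)
    r1, r2 = _load_pairs(r1, r2)
    n_pairs = len(r1)

    tagged: list[SequencedRead] = []
    n_bad_umi = 0
    for a, b in zip(r1, r2):
        extracted = extract_umi(b, umi_scheme)
        if extracted is None:
            n_bad_umi += 1
            continue
        merged = merge_pair(extracted, a)
        rep = merged if merged is not None else extracted
        rep.umi = extracted.umi
        tagged.append(rep)
    manifest.add_stage("umi_extract_anchor", n_pairs, len(tagged), umi_discarded=n_bad_umi)

    passing = [t for t in tagged if quality_filter(t)]
    manifest.add_stage("quality_filter", len(tagged), len(passing),
                       low_quality=len(tagged) - len(passing))
    families, n_missing = build_umi_families(passing)
    if not families:
        raise PipelineError("no UMI families (all reads lacked usable UMIs?)")
    edited = build_edited_allele(amplicon, edit)
    for family in families:
        select_exemplar(family)
        classify_family(family, amplicon, edit, edited, aav_reference, params, scoring)
    manifest.add_stage("classify_families", len(families), len(families))

    clusters = cluster_deletions(families)
    bg = background_rate
    if bg is None:
        bg = estimate_background_rate(0, len(families))
    clusters = deletion_significance(clusters, len(families), bg)
    summary = summarize_uditas(families, clusters)
    manifest.finished = time.time()
    if outdir is not None:
        _write_uditas_artifacts(Path(outdir), summary, families, clusters, manifest)
    return summary, manifest


def _write_uditas_artifacts(outdir, summary, families, clusters, manifest) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fam_df = pd.DataFrame(
        [(f.umi, f.size, f.category) for f in families],
        columns=["umi", "size", "category"],
    )
    fam_df.to_csv(outdir / "families.tsv", sep="\t", index=False)
    clu_df = pd.DataFrame(
        [
            (c.start + 1, c.end, c.size, c.umi_count, c.p_value, c.p_adjusted,
             c.significant)
            for c in clusters
        ],
        columns=["start_1based", "end_1based", "size", "umi_count", "p", "p_adj",
                 "significant"],
    )
    clu_df.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    payload = {
        "total_umis": summary.total_umis,
        "counts": summary.counts,
        "ratios": summary.ratios,
        "aav_fraction": summary.aav_fraction,
        "family_size_histogram": summary.family_size_histogram,
    }
    (outdir / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    (outdir / "manifest.json").write_text(manifest.to_json())


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def generate_report(summaries: dict[str, AmpliconSummary | UditasSummary]) -> str:
    """Render per-sample category fractions as a Markdown report."""
    if not summaries:
        raise ValueError("at least one summary is required")
    lines = ["# Prime-editing outcome report", ""]
    for name in sorted(summaries):
        summary = summaries[name]
        lines.append(f"## {name}")
        lines.append("")
        if isinstance(summary, UditasSummary):
            lines.append(f"Total UMIs: {summary.total_umis}")
            lines.append("")
            lines.append("| category | UMIs | fraction |")
            lines.append("|---|---|---|")
            for cat, n in summary.counts.items():
                lines.append(f"| {cat} | {n} | {summary.ratios[cat]:.4f} |")
            sig = [c for c in summary.clusters if c.significant]
            lines.append("")
            lines.append(
                f"Significant large-deletion clusters (BH-adjusted p <= 0.05): {len(sig)}"
            )
            for c in sig:
                lines.append(
                    f"- [{c.start + 1}, {c.end}] size {c.size} bp, "
                    f"{c.umi_count} UMIs, adj. p = {c.p_adjusted:.3g}"
                )
        else:
            lines.append(f"Total reads: {summary.total_reads}")
            lines.append("")
            lines.append("| call | reads | fraction |")
            lines.append("|---|---|---|")
            for cat, n in summary.counts.items():
                lines.append(f"| {cat} | {n} | {summary.rates[cat]:.4f} |")
            if summary.net_indel_rate is not None:
                lines.append("")
                lines.append(
                    f"Background-subtracted indel burden: {summary.net_indel_rate:.4f}"
                )
        lines.append("")
    return "\n".join(lines)


def plot_deletion_spans(
    clusters: Sequence, amplicon: AmpliconSpec, path: str | Path
) -> None:
    """Bar chart of deletion spans along the amplicon (SVG/PNG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, max(2, 0.3 * len(clusters) + 1)))
    ordered = sorted(clusters, key=lambda c: (c.start, c.end))
    for i, c in enumerate(ordered):
        color = "tab:red" if c.significant else "tab:gray"
        ax.barh(i, c.end - c.start, left=c.start, height=0.6, color=color)
        ax.text(c.end + 2, i, f"{c.size} bp / {c.umi_count} UMIs", va="center", fontsize=7)
    for nick, style in ((amplicon.peg_nick, "--"), (amplicon.nick_sgrna_nick, ":")):
        if nick is not None:
            ax.axvline(nick, linestyle=style, color="k", linewidth=0.8)
    ax.set_xlim(0, len(amplicon.sequence))
    ax.set_yticks([])
    ax.set_xlabel(f"{amplicon.name} position (bp)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
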