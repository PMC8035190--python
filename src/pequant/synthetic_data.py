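"""Ground-truth library simulator for amplicon and UDiTaS sequencing.

Every pipeline stage is testable without external data: the generator draws
molecules from a configurable outcome mixture (wild type, precise edit,
small indel, nick-to-nick deletion, large deletion, AAV integration), tags
each molecule with a unique molecular identifier, amplifies it into a
geometric-size read family, and sequences 150-bp paired-end reads with a
uniform per-base substitution error rate.

Two fragmenting modes are emulated:

* ``amplicon`` — fixed PCR ends; both reads come from the ends of the
  amplicon and overlap in the middle, as in targeted deep sequencing.
* ``uditas`` — read 2 starts at the locus-specific primer and read 1 starts
  at a uniformly placed Tn5 tagmentation end, drawn once per molecule (the
  fragment exists before amplification, so all family members share it).

Synthetic loci are generated random sequences with realistic edit geometry
(nick spacing, PAM placement, primer footprints) rather than real genomic
sequence.  Scenario sequences are derived from fixed per-scenario seeds so
the loci are stable across runs; the run seed controls molecule draws,
amplification, and errors.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core_model import (
    AmpliconSpec,
    EditSpec,
    EditedAllele,
    PamMod,
    SpecError,
    build_edited_allele,
    serialize_edit_config,
)
from .read_processing import SequencedRead, reverse_complement, write_fastq

__all__ = [
    "SimConfig",
    "Molecule",
    "SimulatedLibrary",
    "SCENARIOS",
    "simulate_molecules",
    "amplify_and_sequence",
    "simulate_library",
    "end_to_end_fixture",
    "write_library",
    "random_sequence",
]

MIXTURE_CATEGORIES = (
    "wild_type",
    "precise_edit",
    "small_indel_sub",
    "pegnick_deletion",
    "large_deletion",
    "aav_integration",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


@dataclass
class SimConfig:
    """Study conditions for one simulated library."""

    amplicon: AmpliconSpec
    edit: EditSpec
    mixture: dict[str, float]
    n_molecules: int = 10_000
    umi_length: int = 12
    family_size_mean: float = 4.0
    error_rate: float = 0.001
    read_length: int = 150
    mode: str = "amplicon"  # amplicon | uditas
    aav_reference: Optional[str] = None
    false_priming_fraction: float = 0.0
    low_qual_read_fraction: float = 0.02

    def __post_init__(self) -> None:
        unknown = set(self.mixture) - set(MIXTURE_CATEGORIES)
        if unknown:
            raise SpecError(f"unknown mixture categories: {sorted(unknown)}")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"mixture sums to {total}, expected 1")
        if self.n_molecules < 1:
            raise SpecError("n_molecules must be >= 1")
        if not (0.0 <= self.error_rate <= 0.05):
            raise SpecError("error_rate must lie in [0, 0.05]")
        if self.mode not in ("amplicon", "uditas"):
            raise SpecError(f"unknown mode {self.mode!r}")
        if self.mixture.get("aav_integration", 0.0) > 0 and self.aav_reference is None:
            raise SpecError("aav_integration in the mixture requires aav_reference")
        if self.mode == "uditas" and self.amplicon.uditas_primer_interval is None:
            raise SpecError("uditas mode requires uditas_primer_interval")


@dataclass
class Molecule:
    molecule_id: str
    category: str
    sequence: str
    event: Optional[dict] = None  # kind/start/end/size for event molecules
    umi: Optional[str] = None
    family_size: int = 1
    fragment_end: Optional[int] = None  # Tn5 end, molecule coordinates


@dataclass
class SimulatedLibrary:
    config: SimConfig
    molecules: list[Molecule]
    r1: list[SequencedRead]
    r2: list[SequencedRead]
    read_truth: pd.DataFrame  # read_id, molecule_id, category, n_errors_r1/r2
    molecule_truth: pd.DataFrame

    @property
    def realized_fractions(self) -> dict[str, float]:
        counts = self.molecule_truth["category"].value_counts()
        n = len(self.molecule_truth)
        return {c: counts.get(c, 0) / n for c in counts.index}


# ---------------------------------------------------------------------------
# Molecule construction
# ---------------------------------------------------------------------------


def _make_event_molecule(
    category: str,
    amplicon: AmpliconSpec,
    edited: EditedAllele,
    aav_ref: Optional[str],
    rng: np.random.Generator,
) -> tuple[str, Optional[dict]]:
    seq = amplicon.sequence
    nick = amplicon.peg_nick
    # deletions removing the capture primer would never be sequenced, so
    # event breakpoints stay clear of the primer footprint
    min_start = 1
    if amplicon.uditas_primer_interval is not None:
        min_start = amplicon.uditas_primer_interval[1] + 5
    if category == "wild_type":
        return seq, None
    if category == "precise_edit":
        return edited.sequence, None
    if category == "small_indel_sub":
        size = int(rng.integers(1, 50))
        if rng.random() < 0.5:
            insert = random_sequence(rng, size)
            return seq[:nick] + insert + seq[nick:], {
                "kind": "insertion",
                "start": nick,
                "end": nick,
                "size": size,
            }
        left = int(rng.integers(0, min(size, nick - min_start) + 1))
        a = max(min_start, nick - left)
        b = min(len(seq), a + size)
        return seq[:a] + seq[b:], {"kind": "deletion", "start": a, "end": b, "size": b - a}
    if category == "pegnick_deletion":
        lo, hi = amplicon.nick_window
        spacing = hi - lo
        size = int(rng.integers(spacing, 100))
        left = int(rng.integers(0, min(size - spacing, lo - min_start) + 1))
        a = lo - left
        b = a + size
        return seq[:a] + seq[b:], {"kind": "deletion", "start": a, "end": b, "size": size}
    if category == "large_deletion":
        lo, _ = amplicon.nick_window
        a = int(rng.integers(max(min_start, lo - 15), lo + 1))
        max_size = min(1000, len(seq) - a - 40)
        size = int(rng.integers(100, max(101, max_size + 1)))
        b = a + size
        return seq[:a] + seq[b:], {"kind": "deletion", "start": a, "end": b, "size": size}
    if category == "aav_integration":
        assert aav_ref is not None
        junction = int(rng.integers(nick - 5, nick + 6))
        frag_len = int(rng.integers(200, min(600, len(aav_ref)) + 1))
        start = int(rng.integers(0, len(aav_ref) - frag_len + 1))
        return seq[:junction] + aav_ref[start : start + frag_len], {
            "kind": "aav_integration",
            "start": junction,
            "end": junction,
            "size": frag_len,
        }
    raise SpecError(f"unknown category {category!r}")


def simulate_molecules(
    config: SimConfig, rng: np.random.Generator
) -> list[Molecule]:
    """Draw molecules i.i.d. from the configured outcome mixture."""
    edited = build_edited_allele(config.amplicon, config.edit)
    cats = list(MIXTURE_CATEGORIES)
    probs = np.array([config.mixture.get(c, 0.0) for c in cats])
    draws = rng.choice(len(cats), size=config.n_molecules, p=probs / probs.sum())
    molecules = []
    for i, d in enumerate(draws):
        category = cats[int(d)]
        seq, event = _make_event_molecule(
            category, config.amplicon, edited, config.aav_reference, rng
        )
        molecules.append(
            Molecule(molecule_id=f"mol{i:06d}", category=category, sequence=seq, event=event)
        )
    if config.mode == "uditas" and config.false_priming_fraction > 0:
        assert config.aav_reference is not None
        p0, p1 = config.amplicon.uditas_primer_interval
        primer = config.amplicon.sequence[p0:p1]
        n_fp = int(round(config.false_priming_fraction * config.n_molecules))
        for j in range(n_fp):
            frag_len = int(rng.integers(300, 800))
            start = int(rng.integers(0, len(config.aav_reference) - frag_len + 1))
            seq = primer + config.aav_reference[start : start + frag_len]
            molecules.append(
                Molecule(
                    molecule_id=f"fp{j:06d}",
                    category="false_priming",
                    sequence=seq,
                    event=None,
                )
            )
    return molecules


# ---------------------------------------------------------------------------
# Amplification and sequencing
# ---------------------------------------------------------------------------


def _sequence_errors(
    bases: str, rng: np.random.Generator, error_rate: float
) -> tuple[str, int]:
    if error_rate <= 0:
        return bases, 0
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii"), int(hit.size)


def _qual_array(
    n: int, q: int, rng: np.random.Generator, low_qual: bool
) -> np.ndarray:
    quals = np.full(n, q, dtype=np.int16)
    if low_qual and n > 0:
        quals[int(rng.integers(0, n))] = 20
    return quals


def amplify_and_sequence(
    molecules: list[Molecule],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[SequencedRead], list[SequencedRead], pd.DataFrame]:
    """UMI-tag each molecule, draw its family size, and emit read pairs.

    Linear pre-amplification followed by exponential PCR is modeled by its
    statistical consequence only: one UMI per molecule and geometrically
    dispersed family sizes.  Base quality is emitted as the Phred value
    matching the error rate; a small fraction of reads carry one Q20 base so
    the downstream quality filter sees work.
    """
    L = config.read_length
    base_q = int(np.clip(round(-10 * np.log10(max(config.error_rate, 1e-4))), 2, 40))
    r1_out: list[SequencedRead] = []
    r2_out: list[SequencedRead] = []
    truth_rows = []
    p_geom = 1.0 / max(config.family_size_mean, 1.0)
    for mol in molecules:
        mol.umi = random_sequence(rng, config.umi_length)
        mol.family_size = int(rng.geometric(p_geom)) if p_geom < 1.0 else 1
        if config.mode == "uditas":
            p0, _ = config.amplicon.uditas_primer_interval
            start = min(p0, len(mol.sequence) - 1)
            lo = min(start + 140, len(mol.sequence))
            mol.fragment_end = int(rng.integers(lo, len(mol.sequence) + 1))
            fragment = mol.sequence[start : mol.fragment_end]
        else:
            fragment = mol.sequence
        if len(fragment) < 30:
            continue  # fragment too short to sequence; counted via truth
        for copy in range(mol.family_size):
            read_id = f"{mol.molecule_id}.{copy}:{mol.umi}"
            if config.mode == "uditas":
                # the primer-embedded UMI is sequenced as the read-2 prefix
                fwd = mol.umi + fragment[: L - config.umi_length]
                rev = reverse_complement(fragment)[:L]
            else:
                fwd = fragment[:L]
                rev = reverse_complement(fragment)[:L]
            fwd_e, ne_f = _sequence_errors(fwd, rng, config.error_rate)
            rev_e, ne_r = _sequence_errors(rev, rng, config.error_rate)
            lowq1 = rng.random() < config.low_qual_read_fraction
            lowq2 = rng.random() < config.low_qual_read_fraction
            # UDiTaS: read 2 anchors the locus primer; read 1 carries the Tn5 end
            if config.mode == "uditas":
                r2 = SequencedRead(read_id, fwd_e, _qual_array(len(fwd_e), base_q, rng, lowq2), mate="R2")
                r1 = SequencedRead(read_id, rev_e, _qual_array(len(rev_e), base_q, rng, lowq1), mate="R1")
            else:
                r1 = SequencedRead(read_id, fwd_e, _qual_array(len(fwd_e), base_q, rng, lowq1), mate="R1")
                r2 = SequencedRead(read_id, rev_e, _qual_array(len(rev_e), base_q, rng, lowq2), mate="R2")
            r1_out.append(r1)
            r2_out.append(r2)
            truth_rows.append(
                (read_id, mol.molecule_id, mol.category, ne_f + ne_r)
            )
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "molecule_id", "category", "n_errors"]
    )
    return r1_out, r2_out, truth


def simulate_library(config: SimConfig, seed: int) -> SimulatedLibrary:
    """Deterministically simulate a full library under one seed."""
    rng = np.random.default_rng(seed)
    molecules = simulate_molecules(config, rng)
    r1, r2, read_truth = amplify_and_sequence(molecules, config, rng)
    mol_truth = pd.DataFrame(
        [
            (m.molecule_id, m.umi, m.category, m.family_size,
             None if m.event is None else m.event["kind"],
             None if m.event is None else m.event["start"],
             None if m.event is None else m.event["end"],
             None if m.event is None else m.event["size"])
            for m in molecules
        ],
        columns=["molecule_id", "umi", "category", "family_size",
                 "event_kind", "event_start", "event_end", "event_size"],
    )
    return SimulatedLibrary(
        config=config, molecules=molecules, r1=r1, r2=r2,
        read_truth=read_truth, molecule_truth=mol_truth,
    )


def write_library(library: SimulatedLibrary, outdir: str | Path) -> dict[str, Path]:
    """Write FASTQ.gz pairs, truth tables (TSV) and the config (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "r1": outdir / "reads_R1.fastq.gz",
        "r2": outdir / "reads_R2.fastq.gz",
        "read_truth": outdir / "read_truth.tsv",
        "molecule_truth": outdir / "molecule_truth.tsv",
        "config": outdir / "config.json",
    }
    write_fastq(paths["r1"], library.r1)
    write_fastq(paths["r2"], library.r2)
    library.read_truth.to_csv(paths["read_truth"], sep="\t", index=False)
    library.molecule_truth.to_csv(paths["molecule_truth"], sep="\t", index=False)
    cfg = json.loads(serialize_edit_config(library.config.amplicon, library.config.edit))
    cfg["run"] = {
        "mode": library.config.mode,
        "mixture": library.config.mixture,
        "n_molecules": library.config.n_molecules,
        "umi_length": library.config.umi_length,
        "family_size_mean": library.config.family_size_mean,
        "error_rate": library.config.error_rate,
        "read_length": library.config.read_length,
        "false_priming_fraction": library.config.false_priming_fraction,
        "aav_reference": library.config.aav_reference,
    }
    paths["config"].write_text(json.dumps(cfg, indent=2, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# Scenario registry
# ---------------------------------------------------------------------------


def _scenario_rng(name: str) -> np.random.Generator:
    digest = hashlib.sha256(f"pequant-scenario:{name}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "little"))


def _with_motifs(seq: str, motifs: dict[int, str]) -> str:
    arr = list(seq)
    for pos, bases in motifs.items():
        arr[pos : pos + len(bases)] = list(bases)
    return "".join(arr)


def _point_edit_scenario(
    name: str,
    *,
    ref_base: str,
    alt_base: str,
    mixture: dict[str, float],
) -> dict:
    """A 1-bp transition plus synonymous PAM change (AGG -> AAG geometry)."""
    rng = _scenario_rng(name)
    seq = random_sequence(rng, 240)
    # SpCas9 nicks 3 bp 5' of the PAM: PAM at [122,125), nick offset 119
    seq = _with_motifs(seq, {120: ref_base, 122: "AGG"})
    amplicon = AmpliconSpec(
        name=name, sequence=seq, peg_nick=119, nick_sgrna_nick=179,
        pam_interval=(122, 125),
    )
    edit = EditSpec(
        edit_type="substitution",
        ref_interval=(120, 121),
        alt_segment=alt_base,
        pam_mod=PamMod(position=123, ref="G", alt="A"),
        quant_window=(117, 126),
    )
    return {"amplicon": amplicon, "edit": edit, "mixture": mixture, "mode": "amplicon"}


def _deletion_scenario(
    name: str, *, del_len: int, forced: Optional[str], mixture: dict[str, float],
    length: int = 240,
) -> dict:
    rng = _scenario_rng(name)
    r0 = 120
    r1 = r0 + del_len
    seq = random_sequence(rng, length)
    if forced is not None:
        seq = _with_motifs(seq, {r0: forced})
    amplicon = AmpliconSpec(
        name=name, sequence=seq, peg_nick=r0, nick_sgrna_nick=min(r1 + 40, length - 20),
    )
    edit = EditSpec(
        edit_type="deletion", ref_interval=(r0, r1), alt_segment="",
        quant_window=(r0 - 2, r1 + 2),
    )
    return {"amplicon": amplicon, "edit": edit, "mixture": mixture, "mode": "amplicon"}


def _insertion_scenario(name: str, *, ins_len: int, mixture: dict[str, float]) -> dict:
    rng = _scenario_rng(name)
    seq = random_sequence(rng, 240)
    pos = 121
    alt = random_sequence(rng, ins_len)
    amplicon = AmpliconSpec(name=name, sequence=seq, peg_nick=119, nick_sgrna_nick=179)
    edit = EditSpec(
        edit_type="insertion", ref_interval=(pos, pos), alt_segment=alt,
        quant_window=(117, 126),
    )
    return {"amplicon": amplicon, "edit": edit, "mixture": mixture, "mode": "amplicon"}


def _replacement_scenario(
    name: str, *, ref_len: int, alt_len: int, mixture: dict[str, float]
) -> dict:
    rng = _scenario_rng(name)
    seq = random_sequence(rng, 240)
    r0, r1 = 110, 110 + ref_len
    alt = random_sequence(rng, alt_len)
    # the restoring element must not share long matches with what it replaces
    while any(alt[i : i + 8] in seq[r0:r1] for i in range(alt_len - 7)):
        alt = random_sequence(rng, alt_len)  # pragma: no cover - rare redraw
    amplicon = AmpliconSpec(
        name=name, sequence=seq, peg_nick=r0, nick_sgrna_nick=min(r1 + 40, 220),
    )
    edit = EditSpec(
        edit_type="replacement", ref_interval=(r0, r1), alt_segment=alt,
        quant_window=(r0 - 2, r1 + 2),
    )
    return {"amplicon": amplicon, "edit": edit, "mixture": mixture, "mode": "amplicon"}


def _uditas_scenario(name: str, mixture: dict[str, float]) -> dict:
    rng = _scenario_rng(name)
    seq = random_sequence(rng, 1500)
    seq = _with_motifs(seq, {151: "A", 153: "AGG"})
    amplicon = AmpliconSpec(
        name=name, sequence=seq, peg_nick=150, nick_sgrna_nick=210,
        pam_interval=(153, 156), uditas_primer_interval=(100, 120),
    )
    edit = EditSpec(
        edit_type="substitution", ref_interval=(151, 152), alt_segment="G",
        pam_mod=PamMod(position=154, ref="G", alt="A"),
        quant_window=(149, 157),
    )
    aav = random_sequence(_scenario_rng(name + ":aav"), 1200)
    return {
        "amplicon": amplicon, "edit": edit, "mixture": mixture,
        "mode": "uditas", "aav_reference": aav,
    }


def _amplicon_mixture(precise: float, indel: float) -> dict[str, float]:
    return {
        "wild_type": 1.0 - precise - indel,
        "precise_edit": precise,
        "small_indel_sub": indel,
    }


SCENARIOS = {
    # pathogenic-allele correction: A-to-G transition plus AGG->AAG PAM change;
    # truth fractions mirror the in vivo correction and indel rates
    "serpina1_correction": lambda: _point_edit_scenario(
        "serpina1_correction", ref_base="A", alt_base="G",
        mixture=_amplicon_mixture(0.067, 0.027),
    ),
    # oncogenic point mutation installation (C-to-T)
    "ctnnb1_s45f": lambda: _point_edit_scenario(
        "ctnnb1_s45f", ref_base="C", alt_base="T",
        mixture=_amplicon_mixture(0.060, 0.027),
    ),
    # 3-bp codon deletion (TCC); tumor-derived samples are near-clonal
    "ctnnb1_s45del": lambda: _deletion_scenario(
        "ctnnb1_s45del", del_len=3, forced="TCC",
        mixture=_amplicon_mixture(0.80, 0.03),
    ),
    # 32-bp HIV-resistance-allele deletion
    "ccr5_del": lambda: _deletion_scenario(
        "ccr5_del", del_len=32, forced=None,
        mixture=_amplicon_mixture(0.060, 0.020),
    ),
    # reporter: precise removal of a 47-bp disrupting insertion restores GFP
    "gfp_del47_reporter": lambda: _deletion_scenario(
        "gfp_del47_reporter", del_len=47, forced=None,
        mixture=_amplicon_mixture(0.08, 0.03),
    ),
    # reporter: a 39-bp disrupting segment replaced by an 18-bp element
    "tlr_replacement": lambda: _replacement_scenario(
        "tlr_replacement", ref_len=39, alt_len=18,
        mixture=_amplicon_mixture(0.08, 0.03),
    ),
    # targeted 3-bp deletion at an endogenous locus
    "emx1_del3": lambda: _deletion_scenario(
        "emx1_del3", del_len=3, forced=None,
        mixture=_amplicon_mixture(0.05, 0.02),
    ),
    # targeted 6-bp insertion at an endogenous locus
    "emx1_ins6": lambda: _insertion_scenario(
        "emx1_ins6", ins_len=6, mixture=_amplicon_mixture(0.03, 0.02),
    ),
    # UDiTaS library over an editing-rich condition exercising all categories
    "uditas_aav": lambda: _uditas_scenario(
        "uditas_aav",
        mixture={
            "wild_type": 0.80,
            "precise_edit": 0.10,
            "small_indel_sub": 0.05,
            "pegnick_deletion": 0.02,
            "large_deletion": 0.02,
            "aav_integration": 0.01,
        },
    ),
}


def end_to_end_fixture(
    scenario: str,
    seed: int,
    n_molecules: int = 2_000,
    **overrides,
) -> tuple[SimConfig, SimulatedLibrary]:
    """Build a named scenario and simulate its library.

    ``overrides`` update :class:`SimConfig` fields (mixture,
    false_priming_fraction, error_rate, ...).  Same (scenario, seed,
    overrides) twice gives byte-identical output.
    """
    if scenario not in SCENARIOS:
        raise SpecError(
            f"unknown scenario {scenario!r}; valid scenarios: {sorted(SCENARIOS)}"
        )
    parts = SCENARIOS[scenario]()
    config = SimConfig(
        amplicon=parts["amplicon"],
        edit=parts["edit"],
        mixture=parts["mixture"],
        mode=parts["mode"],
        aav_reference=parts.get("aav_reference"),
        n_molecules=n_molecules,
        family_size_mean=4.0 if parts["mode"] == "uditas" else 1.0,
    )
    if overrides:
        config = dc_replace(config, **overrides)
    return config, simulate_library(config, seed)
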