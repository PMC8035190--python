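"""Genomic coordinate model for prime-editing quantification.

An :class:`AmpliconSpec` describes the sequenced locus: the reference
sequence, the between-base nick offsets of the pegRNA and (for PE3) the
nicking sgRNA, the PAM interval, and — for UDiTaS libraries — the footprint
of the locus-specific primer.  An :class:`EditSpec` describes the intended
sequence change written by the pegRNA's RT template, the synonymous PAM
modification installed alongside it to prevent re-cutting, and the
quantification window within which a read must match the edited allele
exactly to be called a precise edit.

Conventions
-----------
* All coordinates are 0-based, half-open, on the top strand.  Human-readable
  reports convert to 1-based inclusive.
* Nick positions are between-base offsets: a nick at ``k`` separates bases
  ``k-1`` and ``k``.
* Reverse-strand guides carry top-strand coordinates plus an orientation
  flag; all downstream classification happens on the top strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "SpecError",
    "AmpliconSpec",
    "PamMod",
    "EditSpec",
    "EditedAllele",
    "build_edited_allele",
    "edited_window_sequence",
    "wild_window_sequence",
    "parse_edit_config",
    "serialize_edit_config",
]

_NUCS = set("ACGT")


class SpecError(ValueError):
    """Raised when an amplicon/edit specification violates its invariants."""


def _check_interval(iv: tuple[int, int], length: int, name: str) -> tuple[int, int]:
    start, end = int(iv[0]), int(iv[1])
    if not (0 <= start <= end <= length):
        raise SpecError(
            f"{name} [{start}, {end}) out of bounds for sequence of length {length}"
        )
    return (start, end)


@dataclass(frozen=True)
class AmpliconSpec:
    """Reference amplicon with guide geometry.

    Parameters
    ----------
    name : str
        Label used in reports and SAM output.
    sequence : str
        Uppercase nucleotide string over ``{A, C, G, T}``.
    peg_nick : int
        Between-base offset of the pegRNA-directed nick.
    nick_sgrna_nick : int, optional
        Between-base offset of the PE3 nicking-sgRNA nick.
    peg_strand, nick_strand : str
        Orientation flags (``"+"`` or ``"-"``); informational only.
    pam_interval : (int, int), optional
        Half-open interval of the protospacer-adjacent motif.
    uditas_primer_interval : (int, int), optional
        Half-open footprint of the UDiTaS locus-specific primer.
    """

    name: str
    sequence: str
    peg_nick: int
    nick_sgrna_nick: Optional[int] = None
    peg_strand: str = "+"
    nick_strand: str = "+"
    pam_interval: Optional[tuple[int, int]] = None
    uditas_primer_interval: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise SpecError("amplicon sequence must be non-empty")
        bad = set(self.sequence) - _NUCS
        if bad:
            raise SpecError(f"amplicon sequence contains illegal characters: {sorted(bad)}")
        n = len(self.sequence)
        if not (0 <= self.peg_nick <= n):
            raise SpecError(f"peg_nick {self.peg_nick} outside [0, {n}]")
        if self.nick_sgrna_nick is not None:
            if not (0 <= self.nick_sgrna_nick <= n):
                raise SpecError(f"nick_sgrna_nick {self.nick_sgrna_nick} outside [0, {n}]")
            if self.nick_sgrna_nick == self.peg_nick:
                raise SpecError("peg_nick and nick_sgrna_nick must differ")
        for iv, nm in (
            (self.pam_interval, "pam_interval"),
            (self.uditas_primer_interval, "uditas_primer_interval"),
        ):
            if iv is not None:
                object.__setattr__(self, nm, _check_interval(iv, n, nm))
        for flag, nm in ((self.peg_strand, "peg_strand"), (self.nick_strand, "nick_strand")):
            if flag not in ("+", "-"):
                raise SpecError(f"{nm} must be '+' or '-', got {flag!r}")

    @property
    def nick_window(self) -> tuple[int, int]:
        """Window between the pegRNA and nicking-sgRNA nick offsets.

        Raises :class:`SpecError` when no nicking sgRNA is specified.
        """
        if self.nick_sgrna_nick is None:
            raise SpecError("nick_window requires a nicking sgRNA position")
        lo, hi = sorted((self.peg_nick, self.nick_sgrna_nick))
        return (lo, hi)


@dataclass(frozen=True)
class PamMod:
    """Synonymous single-base PAM modification (position, ref base, alt base)."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in _NUCS or self.alt not in _NUCS:
            raise SpecError("pam_mod ref/alt must be single A/C/G/T bases")
        if self.ref == self.alt:
            raise SpecError("pam_mod ref and alt are identical")


EDIT_TYPES = ("substitution", "insertion", "deletion", "replacement")


@dataclass(frozen=True)
class EditSpec:
    """The intended pegRNA-templated edit plus the PAM modification."""

    edit_type: str
    ref_interval: tuple[int, int]
    alt_segment: str = ""
    pam_mod: Optional[PamMod] = None
    quant_window: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.edit_type not in EDIT_TYPES:
            raise SpecError(f"edit_type must be one of {EDIT_TYPES}, got {self.edit_type!r}")
        start, end = self.ref_interval
        if start > end:
            raise SpecError("ref_interval start > end")
        bad = set(self.alt_segment) - _NUCS
        if bad:
            raise SpecError(f"alt_segment contains illegal characters: {sorted(bad)}")
        ref_len = end - start
        alt_len = len(self.alt_segment)
        if self.edit_type == "substitution" and ref_len != alt_len:
            raise SpecError("substitution requires len(ref_interval) == len(alt_segment)")
        if self.edit_type == "deletion" and alt_len != 0:
            raise SpecError("deletion requires empty alt_segment")
        if self.edit_type == "insertion" and ref_len != 0:
            raise SpecError("insertion requires empty ref_interval")

    def validate_against(self, amplicon: AmpliconSpec) -> None:
        """Check all invariants that involve the amplicon sequence."""
        n = len(amplicon.sequence)
        r0, r1 = _check_interval(self.ref_interval, n, "ref_interval")
        if self.pam_mod is not None:
            p = self.pam_mod.position
            if not (0 <= p < n):
                raise SpecError(f"pam_mod position {p} outside amplicon")
            if r0 <= p < r1:
                raise SpecError("pam_mod position lies inside the edit ref_interval")
            if amplicon.sequence[p] != self.pam_mod.ref:
                raise SpecError(
                    f"pam_mod ref_base {self.pam_mod.ref!r} does not match amplicon "
                    f"base {amplicon.sequence[p]!r} at position {p}"
                )
        if self.quant_window is not None:
            w0, w1 = _check_interval(self.quant_window, n, "quant_window")
            if not (w0 <= r0 and r1 <= w1):
                raise SpecError("quant_window must cover the edit ref_interval")
            if r0 == r1 and not (w0 < r0 and r1 < w1):
                raise SpecError("quant_window must strictly contain an insertion point")
            if self.pam_mod is not None and not (w0 <= self.pam_mod.position < w1):
                raise SpecError("quant_window must cover the pam_mod position")

    def window(self, amplicon: AmpliconSpec) -> tuple[int, int]:
        """The quantification window, defaulting to the full amplicon."""
        if self.quant_window is not None:
            return self.quant_window
        return (0, len(amplicon.sequence))


@dataclass(frozen=True)
class EditedAllele:
    """Amplicon sequence with an :class:`EditSpec` applied.

    ``coordinate_map[i]`` is the original amplicon position of edited-allele
    base ``i``, or ``None`` for inserted bases.  Deleted amplicon positions
    are simply absent from the map.
    """

    sequence: str
    coordinate_map: tuple[Optional[int], ...] = field(repr=False)

    def __len__(self) -> int:
        return len(self.sequence)


def build_edited_allele(amplicon: AmpliconSpec, edit: EditSpec) -> EditedAllele:
    """Splice the edit (and PAM modification) into the amplicon sequence."""
    edit.validate_against(amplicon)
    seq = amplicon.sequence
    r0, r1 = edit.ref_interval
    out = seq[:r0] + edit.alt_segment + seq[r1:]
    cmap: list[Optional[int]] = list(range(r0)) + [None] * len(edit.alt_segment) + list(
        range(r1, len(seq))
    )
    if edit.pam_mod is not None:
        p = edit.pam_mod.position
        if p >= r1:
            p_edited = p - (r1 - r0) + len(edit.alt_segment)
        else:
            p_edited = p
        out = out[:p_edited] + edit.pam_mod.alt + out[p_edited + 1 :]
    return EditedAllele(sequence=out, coordinate_map=tuple(cmap))


def _apply_pam_to_window(seq: str, offset: int, edit: EditSpec) -> str:
    """Apply the PAM substitution to a window slice starting at ``offset``."""
    if edit.pam_mod is None:
        return seq
    i = edit.pam_mod.position - offset
    if 0 <= i < len(seq):
        seq = seq[:i] + edit.pam_mod.alt + seq[i + 1 :]
    return seq


def wild_window_sequence(amplicon: AmpliconSpec, edit: EditSpec) -> str:
    """Unedited amplicon sequence within the quantification window."""
    w0, w1 = edit.window(amplicon)
    return amplicon.sequence[w0:w1]


def edited_window_sequence(amplicon: AmpliconSpec, edit: EditSpec) -> str:
    """Edited-allele sequence within the quantification window.

    This is the exact string a read must present across the window (in
    amplicon coordinates) to be called a precise edit: the intended edit AND
    the synonymous PAM modification, with no other events.
    """
    w0, w1 = edit.window(amplicon)
    r0, r1 = edit.ref_interval
    seq = amplicon.sequence
    out = seq[w0:r0] + edit.alt_segment + seq[r1:w1]
    # PAM position is outside ref_interval; adjust for the indel if downstream.
    if edit.pam_mod is not None:
        p = edit.pam_mod.position
        if p >= r1:
            i = (p - r1) + (r0 - w0) + len(edit.alt_segment)
        else:
            i = p - w0
        if 0 <= i < len(out):
            if edit.pam_mod.ref != (
                seq[p]
            ):  # pragma: no cover - validate_against already enforces this
                raise SpecError("pam_mod ref mismatch")
            out = out[:i] + edit.pam_mod.alt + out[i + 1 :]
    return out


# ---------------------------------------------------------------------------
# Config (de)serialization
# ---------------------------------------------------------------------------

_REQUIRED_AMPLICON_KEYS = ("name", "peg_nick")
_REQUIRED_EDIT_KEYS = ("type", "ref_start", "ref_end")


def parse_edit_config(config_text: str) -> tuple[AmpliconSpec, EditSpec, dict]:
    """Parse a JSON edit-spec config into validated domain objects.

    Returns ``(amplicon, edit, run_params)`` where ``run_params`` carries any
    keys under ``"run"`` (pipeline thresholds, seeds, ...) untouched.
    """
    try:
        cfg = json.loads(config_text)
    except json.JSONDecodeError as exc:
        raise SpecError(f"config is not valid JSON: {exc}") from exc

    for section in ("amplicon", "edit"):
        if section not in cfg:
            raise SpecError(f"config missing required section {section!r}")
    amp_cfg, edit_cfg = cfg["amplicon"], cfg["edit"]

    for key in _REQUIRED_AMPLICON_KEYS:
        if key not in amp_cfg:
            raise SpecError(f"amplicon config missing required field {key!r}")
    if "sequence" in amp_cfg:
        sequence = str(amp_cfg["sequence"]).upper()
    elif "fasta_path" in amp_cfg:
        from Bio import SeqIO

        record = next(SeqIO.parse(amp_cfg["fasta_path"], "fasta"))
        sequence = str(record.seq).upper()
    else:
        raise SpecError("amplicon config requires 'sequence' or 'fasta_path'")

    def _iv(value):
        return None if value is None else (int(value[0]), int(value[1]))

    amplicon = AmpliconSpec(
        name=str(amp_cfg["name"]),
        sequence=sequence,
        peg_nick=int(amp_cfg["peg_nick"]),
        nick_sgrna_nick=(
            None if amp_cfg.get("nick_sgrna_nick") is None else int(amp_cfg["nick_sgrna_nick"])
        ),
        peg_strand=amp_cfg.get("peg_strand", "+"),
        nick_strand=amp_cfg.get("nick_strand", "+"),
        pam_interval=_iv(amp_cfg.get("pam_interval")),
        uditas_primer_interval=_iv(amp_cfg.get("uditas_primer_interval")),
    )

    for key in _REQUIRED_EDIT_KEYS:
        if key not in edit_cfg:
            raise SpecError(f"edit config missing required field {key!r}")
    pam_mod = None
    if edit_cfg.get("pam_mod") is not None:
        pm = edit_cfg["pam_mod"]
        for key in ("pos", "ref", "alt"):
            if key not in pm:
                raise SpecError(f"edit.pam_mod missing required field {key!r}")
        pam_mod = PamMod(position=int(pm["pos"]), ref=str(pm["ref"]), alt=str(pm["alt"]))
    edit = EditSpec(
        edit_type=str(edit_cfg["type"]),
        ref_interval=(int(edit_cfg["ref_start"]), int(edit_cfg["ref_end"])),
        alt_segment=str(edit_cfg.get("alt", "")).upper(),
        pam_mod=pam_mod,
        quant_window=_iv(edit_cfg.get("quant_window")),
    )
    edit.validate_against(amplicon)
    run_params = dict(cfg.get("run", {}))
    return amplicon, edit, run_params


def serialize_edit_config(
    amplicon: AmpliconSpec, edit: EditSpec, run_params: Optional[dict] = None
) -> str:
    """Inverse of :func:`parse_edit_config` (sequence inlined, not FASTA)."""
    cfg = {
        "amplicon": {
            "name": amplicon.name,
            "sequence": amplicon.sequence,
            "peg_nick": amplicon.peg_nick,
            "nick_sgrna_nick": amplicon.nick_sgrna_nick,
            "peg_strand": amplicon.peg_strand,
            "nick_strand": amplicon.nick_strand,
            "pam_interval": list(amplicon.pam_interval) if amplicon.pam_interval else None,
            "uditas_primer_interval": (
                list(amplicon.uditas_primer_interval)
                if amplicon.uditas_primer_interval
                else None
            ),
        },
        "edit": {
            "type": edit.edit_type,
            "ref_start": edit.ref_interval[0],
            "ref_end": edit.ref_interval[1],
            "alt": edit.alt_segment,
            "pam_mod": (
                None
                if edit.pam_mod is None
                else {
                    "pos": edit.pam_mod.position,
                    "ref": edit.pam_mod.ref,
                    "alt": edit.pam_mod.alt,
                }
            ),
            "quant_window": list(edit.quant_window) if edit.quant_window else None,
        },
        "run": dict(run_params or {}),
    }
    return json.dumps(cfg, indent=2, sort_keys=True)
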