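"""Assembly of designer PPR (dPPR) proteins for arbitrary ssRNA targets.

A dPPR construct is an N-terminal capping domain (NTD), a tandem array of
35-amino-acid code-programmed repeats — one repeat per target nucleotide,
N-to-C matching 5'-to-3' — and a C-terminal capping domain (CTD).  Only the
two code slots (repeat positions 5 and 35) differ between repeats; the other
33 residues come from a fixed scaffold template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .code import (
    AMINO_ACIDS,
    CodeTable,
    InvalidBaseError,
    PPRCode,
    base_to_code,
    default_code_table,
)

logger = logging.getLogger(__name__)

REPEAT_LENGTH = 35
ADVISORY_MIN_REPEATS = 2
ADVISORY_MAX_REPEATS = 30

#: Offset that maps construct numbering (NTD residue 1) onto the crystal
#: construct numbering (construct 123-572, repeats 174-523 for 10 repeats).
CRYSTAL_NUMBERING_OFFSET = 122


@dataclass(frozen=True)
class ScaffoldSpec:
    """The 35-aa repeat template with its two code slots, plus terminal caps.

    ``template`` carries default residues at the slot positions; they are
    substituted per repeat.  ``special_positions`` documents the conserved
    RNA-binding residues outside the code (hydrophobic clamp at 2,
    phosphate-binding lysine at 13).
    """

    template: str
    ntd: str
    ctd: str
    slot_positions: tuple[int, int] = (5, 35)
    special_positions: Mapping[int, str] = field(
        default_factory=lambda: {2: "V", 13: "K"}
    )

    def __post_init__(self) -> None:
        if len(self.template) != REPEAT_LENGTH:
            raise ValueError(
                f"scaffold template must be {REPEAT_LENGTH} aa, got {len(self.template)}"
            )
        for seq, name in ((self.template, "template"), (self.ntd, "ntd"), (self.ctd, "ctd")):
            bad = set(seq) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"non-amino-acid characters in {name}: {sorted(bad)}")
        if tuple(sorted(self.slot_positions)) != (5, 35):
            raise ValueError(f"slot positions must be (5, 35), got {self.slot_positions}")
        for pos in self.special_positions:
            if not 1 <= pos <= REPEAT_LENGTH:
                raise ValueError(f"special position {pos} outside 1..{REPEAT_LENGTH}")

    def repeat_sequence(self, code: PPRCode) -> str:
        """Template with the code residues substituted at positions 5 and 35."""
        chars = list(self.template)
        chars[self.slot_positions[0] - 1] = code.pos5
        chars[self.slot_positions[1] - 1] = code.pos35
        return "".join(chars)


@dataclass(frozen=True)
class RepeatAnnotation:
    """One designed repeat: which nucleotide it reads and where it sits."""

    index: int          # 1-based repeat number, N-to-C
    code: PPRCode
    target_base: str    # the 5'->3' nucleotide this repeat reads
    start: int          # 1-based inclusive span in the full construct
    end: int


@dataclass(frozen=True)
class DesignResult:
    """A complete designer PPR construct."""

    full_sequence: str
    ntd: str
    ctd: str
    repeats: tuple[RepeatAnnotation, ...]
    target_rna: str

    def __post_init__(self) -> None:
        if len(self.repeats) != len(self.target_rna):
            raise ValueError("repeat count must equal target length")
        expect = len(self.ntd) + REPEAT_LENGTH * len(self.repeats) + len(self.ctd)
        if len(self.full_sequence) != expect:
            raise ValueError("construct length inconsistent with NTD/repeats/CTD")
        for i, rep in enumerate(self.repeats):
            if rep.end - rep.start + 1 != REPEAT_LENGTH:
                raise ValueError(f"repeat {rep.index} span is not {REPEAT_LENGTH} residues")
            if i and rep.start - self.repeats[i - 1].start != REPEAT_LENGTH:
                raise ValueError("consecutive repeat starts must differ by 35")

    @property
    def repeat_region(self) -> str:
        return self.full_sequence[len(self.ntd): len(self.full_sequence) - len(self.ctd)]


def load_scaffold(path: str | Path | None = None) -> ScaffoldSpec:
    """Load a scaffold definition, or the packaged synthetic default.

    The packaged default is a constructed stand-in for a consensus designer
    repeat: correct architecture (35 aa, slots at 5/35, Val2, Lys13) and cap
    lengths matched to the crystal-construct numbering, but not a published
    sequence.
    """
    if path is None:
        text = resources.files("pprkit.data").joinpath("scaffold_synthetic.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return ScaffoldSpec(
        template=str(raw["template"]),
        ntd=str(raw["ntd"]),
        ctd=str(raw["ctd"]),
        slot_positions=tuple(raw.get("slot_positions", (5, 35))),
        special_positions={int(k): str(v) for k, v in (raw.get("special_positions") or {}).items()},
    )


_DEFAULT_SCAFFOLD: ScaffoldSpec | None = None


def default_scaffold() -> ScaffoldSpec:
    global _DEFAULT_SCAFFOLD
    if _DEFAULT_SCAFFOLD is None:
        _DEFAULT_SCAFFOLD = load_scaffold(None)
    return _DEFAULT_SCAFFOLD


def _normalize_target(target_rna: str, allow_ambiguity: bool) -> str:
    if not target_rna:
        raise InvalidBaseError("empty RNA target")
    out = []
    for i, ch in enumerate(target_rna.upper(), start=1):
        if ch == "T":
            logger.warning("T at target position %d treated as U", i)
            ch = "U"
        if ch == "Y" and allow_ambiguity:
            out.append(ch)
            continue
        if ch not in "ACGU":
            raise InvalidBaseError(
                f"invalid RNA base {ch!r} at position {i}: expected one of A, C, G, U (or T)"
            )
        out.append(ch)
    return "".join(out)


def design_dppr(
    target_rna: str,
    scaffold: ScaffoldSpec | None = None,
    table: CodeTable | None = None,
    code_overrides: Mapping[int, PPRCode | str] | None = None,
    allow_ambiguity: bool = False,
) -> DesignResult:
    """Design a dPPR protein that reads ``target_rna`` 5'->3'.

    One repeat is emitted per nucleotide; its code is the canonical design
    code for that base (U->ND, C->NS, A->SN, G->TD) unless overridden via
    ``code_overrides`` (1-based target position -> code).  With
    ``allow_ambiguity``, the pyrimidine ambiguity code Y is accepted and maps
    to the degenerate code NN; other IUPAC codes are rejected because no
    single supported code covers them.

    Target lengths outside the natural 2-30 repeat range only warn: the
    architecture still assembles, but such arrays are outside the envelope
    the scaffold was characterized in.
    """
    scaffold = scaffold or default_scaffold()
    if table is None:
        table = default_code_table()
    target = _normalize_target(target_rna, allow_ambiguity)
    n = len(target)
    if not ADVISORY_MIN_REPEATS <= n <= ADVISORY_MAX_REPEATS:
        logger.warning(
            "target length %d outside the natural tandem-array range %d-%d",
            n, ADVISORY_MIN_REPEATS, ADVISORY_MAX_REPEATS,
        )
    overrides = {}
    for pos, code in (code_overrides or {}).items():
        if not 1 <= int(pos) <= n:
            raise ValueError(f"code override position {pos} outside 1..{n}")
        code = PPRCode(code[0], code[1]).validate()
        overrides[int(pos)] = code

    repeats: list[RepeatAnnotation] = []
    parts: list[str] = [scaffold.ntd]
    offset = len(scaffold.ntd)
    for i, base in enumerate(target, start=1):
        if i in overrides:
            code = overrides[i]
        elif base == "Y":
            code = PPRCode("N", "N")
        else:
            code = base_to_code(base, position=i)
        start = offset + (i - 1) * REPEAT_LENGTH + 1
        repeats.append(
            RepeatAnnotation(index=i, code=code, target_base=base,
                             start=start, end=start + REPEAT_LENGTH - 1)
        )
        parts.append(scaffold.repeat_sequence(code))
    parts.append(scaffold.ctd)
    return DesignResult(
        full_sequence="".join(parts),
        ntd=scaffold.ntd,
        ctd=scaffold.ctd,
        repeats=tuple(repeats),
        target_rna=target,
    )


def write_design(
    result: DesignResult,
    fasta_path: str | Path,
    annot_path: str | Path,
    name: str | None = None,
    offset: int = 0,
) -> None:
    """Write the construct as FASTA (60-col wrap) plus a TSV annotation.

    ``offset`` shifts the annotated residue numbering, e.g. 122 reproduces
    the crystal-construct numbering (repeats at 174-523 for ten repeats).
    """
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    name = name or f"dPPR_{result.target_rna}"
    record = SeqRecord(
        Seq(result.full_sequence), id=name,
        description=f"target_rna={result.target_rna}",
    )
    seqio_write([record], str(fasta_path), "fasta")
    lines = ["repeat_index\tcode\ttarget_base\tstart\tend"]
    for rep in result.repeats:
        lines.append(
            f"{rep.index}\t{rep.code}\t{rep.target_base}"
            f"\t{rep.start + offset}\t{rep.end + offset}"
        )
    Path(annot_path).write_text("\n".join(lines) + "\n")


def read_annotation(annot_path: str | Path) -> list[RepeatAnnotation]:
    """Read back a TSV annotation written by :func:`write_design`."""
    rows = []
    lines = Path(annot_path).read_text().strip().splitlines()
    for line in lines[1:]:
        idx, code, base, start, end = line.split("\t")
        rows.append(RepeatAnnotation(int(idx), PPRCode(code[0], code[1]), base,
                                     int(start), int(end)))
    return rows
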