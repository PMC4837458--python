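"""Shared infrastructure: sequence I/O, run configuration, fixture generators.

Coordinate convention across the package: 1-based inclusive residue and
nucleotide numbering, matching crystallographic practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .structgeom import (
    Atom,
    Chain,
    RepeatSegmentation,
    Residue,
    StructureModel,
    segmentation_from_ranges,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FastaRecord:
    id: str
    sequence: str
    description: str = ""


def read_fasta(path: str | Path, normalize_rna: bool = False) -> list[FastaRecord]:
    """Read FASTA records (uppercased).  With ``normalize_rna``, T -> U.

    Empty files raise; duplicate ids only warn.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if normalize_rna and "T" in seq:
            logger.warning("record %s: T normalized to U", rec.id)
            seq = seq.replace("T", "U")
        if rec.id in seen:
            logger.warning("duplicate FASTA id %r in %s", rec.id, path)
        seen.add(rec.id)
        records.append(FastaRecord(rec.id, seq, rec.description))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[FastaRecord], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA; round-trips with read_fasta."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id,
                  description=r.description if r.description != r.id else "")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


@dataclass(frozen=True)
class RunConfig:
    """Run-wide knobs shared by the CLI subcommands."""

    code_table_path: str | None = None
    scaffold_path: str | None = None
    hbond_cutoff: float = 3.5
    salt_bridge_cutoff: float = 4.0
    val2_cutoff: float = 4.5
    scan_threshold_frac: float = 0.6
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        for name in ("hbond_cutoff", "salt_bridge_cutoff", "val2_cutoff",
                     "scan_threshold_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")


_CONFIG_FIELDS = {
    "code_table_path", "scaffold_path", "hbond_cutoff", "salt_bridge_cutoff",
    "val2_cutoff", "scan_threshold_frac", "seed", "verbosity",
}


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def make_ideal_helix(
    rise: float,
    twist_deg: float,
    radius: float,
    n_repeats: int,
    atoms_per_repeat: int = 5,
    seed: int = 0,
    jitter: float = 0.4,
) -> tuple[StructureModel, dict, list[tuple[int, int]]]:
    """Generate a Calpha-only model on an exact circular helix.

    Repeat centroids sit exactly on the helix (axis +z; positive twist is
    right-handed along the repeat progression): the ``atoms_per_repeat``
    pseudo-residues of each repeat are placed at the centroid plus seeded
    zero-sum offsets (paired +/-), so the per-repeat Calpha centroid equals
    the ideal point and the generator's parameters are exact ground truth.

    Returns (model, truth dict, per-repeat residue ranges).
    """
    if rise <= 0 or radius <= 0 or twist_deg == 0:
        raise ValueError("rise and radius must be positive and twist nonzero")
    if n_repeats < 4:
        raise ValueError("superhelix fitting needs at least 4 repeats")
    if atoms_per_repeat < 1:
        raise ValueError("atoms_per_repeat must be >= 1")
    rng = np.random.default_rng(seed)
    theta = np.radians(twist_deg)
    chain = Chain("A")
    seqid = 0
    ranges = []
    for j in range(n_repeats):
        centroid = np.array([
            radius * np.cos(j * theta),
            radius * np.sin(j * theta),
            j * rise,
        ])
        offsets = []
        for _ in range(atoms_per_repeat // 2):
            o = rng.normal(0.0, jitter, size=3)
            offsets.extend([o, -o])
        if atoms_per_repeat % 2:
            offsets.append(np.zeros(3))
        start = seqid + 1
        for o in offsets:
            seqid += 1
            res = Residue("ALA", seqid)
            res.add_atom(Atom("CA", "C", centroid + o))
            chain.residues.append(res)
        ranges.append((start, seqid))
    truth = {
        "rise": float(rise),
        "twist": float(twist_deg),
        "radius": float(radius),
        "period": float(rise * 360.0 / abs(twist_deg)),
        "diameter": float(2.0 * radius),
        "handedness": "right" if twist_deg > 0 else "left",
    }
    return StructureModel([chain], name="ideal_helix"), truth, ranges


def _residue(name: str, seqid: int, atoms: dict[str, tuple[str, tuple]]) -> Residue:
    res = Residue(name, seqid)
    for atom_name, (element, pos) in atoms.items():
        res.add_atom(Atom(atom_name, element, np.asarray(pos, float)))
    return res


def make_recognition_complex() -> tuple[StructureModel, RepeatSegmentation]:
    """Synthetic two-repeat dPPR-RNA complex with planted recognition geometry.

    A hand-placed fixture (synthetic coordinates, not derived from any
    deposited structure) exercising every recognition rule exactly once on
    repeat 1, which reads a uracil:

    * Asn at internal position 5: ND2 2.9 A from the base O2 — one direct
      position-5 hydrogen bond, and only that one.
    * Asp at position 35: OD1 2.8 A from a water that is itself 2.8 A from
      the base N3 — one water bridge, no direct position-35 contact.
    * Val at position 2: CG1 3.8-4.1 A above the base ring (sandwich face).
    * Lys at position 13: NZ exactly 3.0 A from the phosphate OP1.

    Repeat 2 (residues 36-70) pairs with a nucleotide 100 A away and its
    position-2/13 residues carry no side-chain atoms, so its rows come back
    empty and flagged incomplete.
    """
    protein = Chain("A")
    for seqid in range(1, 71):
        if seqid == 2:      # Val2 of repeat 1
            protein.residues.append(_residue("VAL", seqid, {
                "CA": ("C", (1.0, 1.2, 7.0)),
                "CB": ("C", (1.0, 1.2, 5.3)),
                "CG1": ("C", (1.0, 1.2, 3.8)),
            }))
        elif seqid == 5:    # Asn5 of repeat 1
            protein.residues.append(_residue("ASN", seqid, {
                "CA": ("C", (5.0, -5.0, 0.0)),
                "OD1": ("O", (4.0, -5.5, 0.0)),
                "ND2": ("N", (2.0, -4.0, 0.0)),
            }))
        elif seqid == 13:   # Lys13 of repeat 1
            protein.residues.append(_residue("LYS", seqid, {
                "CA": ("C", (-9.0, 0.0, 3.0)),
                "NZ": ("N", (-7.0, 0.0, 0.0)),
            }))
        elif seqid == 35:   # Asp35 of repeat 1
            protein.residues.append(_residue("ASP", seqid, {
                "CA": ("C", (4.0, 2.0, 7.0)),
                "OD1": ("O", (2.1, 1.2, 5.6)),
                "OD2": ("O", (2.1, 1.2, 7.0)),
            }))
        else:
            # keep the repeat-2 code readable at positions 5/35
            name = {40: "ASN", 70: "ASP"}.get(seqid, "ALA")
            protein.residues.append(_residue(name, seqid, {
                "CA": ("C", (100.0 + 4.0 * seqid, 80.0, 80.0)),
            }))

    rna = Chain("R")
    rna.residues.append(_residue("U", 1, {
        "P": ("P", (-4.5, 0.0, 1.0)),
        "OP1": ("O", (-4.0, 0.0, 0.0)),
        "OP2": ("O", (-5.0, 1.0, 1.5)),
        "N1": ("N", (0.0, 0.0, 0.0)),
        "C2": ("C", (1.4, 0.0, 0.0)),
        "O2": ("O", (2.0, -1.1, 0.0)),
        "N3": ("N", (2.1, 1.2, 0.0)),
        "C4": ("C", (1.5, 2.4, 0.0)),
        "O4": ("O", (2.2, 3.5, 0.0)),
        "C5": ("C", (0.1, 2.5, 0.0)),
        "C6": ("C", (-0.6, 1.3, 0.0)),
    }))
    rna.residues.append(_residue("U", 2, {
        "N1": ("N", (160.0, 160.0, 160.0)),
        "C2": ("C", (161.4, 160.0, 160.0)),
        "O2": ("O", (162.0, 158.9, 160.0)),
        "N3": ("N", (162.1, 161.2, 160.0)),
        "C4": ("C", (161.5, 162.4, 160.0)),
        "C5": ("C", (160.1, 162.5, 160.0)),
        "C6": ("C", (159.4, 161.3, 160.0)),
    }))

    water = Chain("W")
    water.residues.append(_residue("HOH", 101, {"O": ("O", (2.1, 1.2, 2.8))}))
    water.residues.append(_residue("HOH", 102, {"O": ("O", (50.0, 50.0, 50.0))}))

    model = StructureModel([protein, rna, water], name="synthetic_recognition")
    return model, segmentation_from_ranges([(1, 35), (36, 70)])
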