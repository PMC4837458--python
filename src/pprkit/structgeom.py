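"""Structural analysis of (d)PPR-RNA complexes.

Covers the geometric quantities that characterize an RNA-bound designer PPR
solenoid: iteratively pruned Calpha superposition (Kabsch), superhelix
axis / rise / twist / period / diameter / handedness from repeat centroids,
35-residue repeat segmentation, base-recognition hydrogen bonds on the
Watson-Crick face (direct and water-bridged), Val2 base-sandwich contacts
and Lys13-phosphate salt bridges.

Deposited crystal structures of this protein family resolve no hydrogens
(2.2-2.6 A), so the hydrogen-bond criterion here is heavy-atom donor /
acceptor distance only, without an angle term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .code import PPRCode

logger = logging.getLogger(__name__)

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
RNA_RESIDUES = {"A", "C", "G", "U"}
WATER_RESIDUES = {"HOH", "WAT", "H2O"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

#: Watson-Crick-face heavy atoms read by the code residues.
WC_FACE_ATOMS = {
    "U": ("O2", "N3", "O4"),
    "C": ("O2", "N3", "N4"),
    "A": ("N1", "N3", "N6"),
    "G": ("N1", "N2", "N3", "O6"),
}
BASE_RING_ATOMS = {
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "A": ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"),
    "G": ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"),
}
PHOSPHATE_OXYGENS = ("OP1", "OP2", "O5'", "O3'")
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class StructureError(ValueError):
    """Unparseable, empty or otherwise unusable structural input."""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # shape (3,), angstrom

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise StructureError(f"atom {self.name}: bad coordinates {self.pos}")


@dataclass
class Residue:
    name: str
    seqid: int
    atoms: dict[str, Atom] = field(default_factory=dict)

    def add_atom(self, atom: Atom) -> None:
        if atom.name in self.atoms:
            raise StructureError(f"duplicate atom {atom.name} in residue {self.name} {self.seqid}")
        self.atoms[atom.name] = atom

    @property
    def mol_class(self) -> str:
        if self.name in PROTEIN_RESIDUES:
            return "protein"
        if self.name in RNA_RESIDUES:
            return "rna"
        if self.name in WATER_RESIDUES:
            return "water"
        return "other"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def mol_class(self) -> str:
        """Majority molecule class of the chain's residues."""
        if not self.residues:
            return "other"
        counts: dict[str, int] = {}
        for res in self.residues:
            counts[res.mol_class] = counts.get(res.mol_class, 0) + 1
        return max(counts, key=counts.get)

    def residue_by_seqid(self, seqid: int) -> Residue | None:
        for res in self.residues:
            if res.seqid == seqid:
                return res
        return None

    def one_letter_sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues
                       if r.mol_class == "protein")

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atoms["CA"].pos for r in self.residues
                         if r.mol_class == "protein" and "CA" in r.atoms])


@dataclass
class StructureModel:
    chains: list[Chain]
    name: str = ""

    def chains_of_class(self, mol_class: str) -> list[Chain]:
        return [c for c in self.chains if c.mol_class == mol_class]

    @property
    def protein_chain(self) -> Chain:
        chains = self.chains_of_class("protein")
        if not chains:
            raise StructureError("no protein chain in model")
        return chains[0]

    @property
    def rna_chain(self) -> Chain:
        chains = self.chains_of_class("rna")
        if not chains:
            raise StructureError(
                "no RNA chain in model: recognition analysis needs the bound ssRNA"
            )
        return chains[0]

    def water_atoms(self) -> list[tuple[str, Residue, Atom]]:
        out = []
        for chain in self.chains:
            for res in chain.residues:
                if res.mol_class == "water":
                    for atom in res.atoms.values():
                        if atom.element == "O":
                            out.append((chain.chain_id, res, atom))
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Copy with every coordinate mapped through x -> R x + t."""
        chains = []
        for chain in self.chains:
            new_res = []
            for res in chain.residues:
                atoms = {
                    n: Atom(a.name, a.element, rotation @ a.pos + translation)
                    for n, a in res.atoms.items()
                }
                new_res.append(Residue(res.name, res.seqid, atoms))
            chains.append(Chain(chain.chain_id, new_res))
        return StructureModel(chains, name=self.name)


# ---------------------------------------------------------------------------
# Parsing (gemmi behind the module surface)

def read_structure(path: str | Path) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Altlocs are resolved to the highest-occupancy conformer (ties: first in
    file order); waters are retained and classified.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise StructureError(f"empty model in {path}")
    model = st[0]
    chains: list[Chain] = []
    for gchain in model:
        chain = Chain(gchain.name)
        for gres in gchain:
            res = Residue(gres.name.strip(), gres.seqid.num)
            best: dict[str, "gemmi.Atom"] = {}
            for atom in gres:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                res.add_atom(Atom(atom.name, atom.element.name.upper(),
                                  np.array([atom.pos.x, atom.pos.y, atom.pos.z])))
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            chains.append(chain)
    if not chains:
        raise StructureError(f"no usable chains in {path}")
    return StructureModel(chains, name=path.stem)


# ---------------------------------------------------------------------------
# Repeat segmentation

@dataclass(frozen=True)
class RepeatSegment:
    index: int                      # 1-based repeat number
    start: int                      # first residue seqid, inclusive
    end: int                        # last residue seqid, inclusive
    code: PPRCode | None = None     # residues at internal positions 5 and 35


@dataclass(frozen=True)
class RepeatSegmentation:
    """Ordered, non-overlapping repeat ranges of a fixed length.

    PPR repeats are 35 residues (the default); synthetic reduced models
    (e.g. the ideal-helix fixture, one pseudo-residue per Calpha) may use a
    different fixed repeat length.
    """

    segments: tuple[RepeatSegment, ...]
    repeat_length: int = 35

    def __post_init__(self) -> None:
        prev_end = None
        for seg in self.segments:
            if seg.end - seg.start + 1 != self.repeat_length:
                raise StructureError(
                    f"repeat {seg.index}: range {seg.start}-{seg.end} is not "
                    f"{self.repeat_length} residues"
                )
            if prev_end is not None and seg.start <= prev_end:
                raise StructureError(f"repeat {seg.index} overlaps the previous repeat")
            prev_end = seg.end

    def __len__(self) -> int:
        return len(self.segments)


def segmentation_from_ranges(
    ranges: Sequence[tuple[int, int]], repeat_length: int | None = None
) -> RepeatSegmentation:
    """Build a segmentation from explicit (start, end) seqid ranges."""
    if not ranges:
        raise StructureError("no ranges given")
    if repeat_length is None:
        repeat_length = ranges[0][1] - ranges[0][0] + 1
    segments = tuple(
        RepeatSegment(index=i, start=start, end=end)
        for i, (start, end) in enumerate(ranges, start=1)
    )
    return RepeatSegmentation(segments, repeat_length=repeat_length)


def segment_repeats(
    model: StructureModel,
    anchor: int = 174,
    n_repeats: int | None = None,
    ranges: Sequence[tuple[int, int]] | None = None,
) -> RepeatSegmentation:
    """Tile or validate 35-residue repeat ranges on the protein chain.

    With explicit ``ranges`` they are validated; otherwise 35-residue windows
    are tiled from ``anchor`` (default 174, the first repeat residue of the
    deposited ten-repeat constructs).  ``n_repeats`` defaults to as many full
    windows as the chain supports.  The code residues at internal positions
    5 and 35 are read off when present.
    """
    chain = model.protein_chain
    seqids = {r.seqid for r in chain.residues if r.mol_class == "protein"}
    if ranges is None:
        if anchor not in seqids:
            raise StructureError(f"anchor residue {anchor} absent from protein chain")
        if n_repeats is None:
            n_repeats = 0
            while {anchor + n_repeats * 35 + k for k in range(35)} <= seqids:
                n_repeats += 1
        if n_repeats < 1:
            raise StructureError(f"chain too short for one 35-residue repeat at anchor {anchor}")
        ranges = [(anchor + i * 35, anchor + i * 35 + 34) for i in range(n_repeats)]
    segments = []
    for i, (start, end) in enumerate(ranges, start=1):
        missing = {s for s in range(start, end + 1)} - seqids
        if missing:
            raise StructureError(
                f"repeat {i} ({start}-{end}): residues missing from chain: {sorted(missing)[:5]}"
            )
        code = None
        r5 = chain.residue_by_seqid(start + 4)
        r35 = chain.residue_by_seqid(start + 34)
        if r5 is not None and r35 is not None:
            a5, a35 = THREE_TO_ONE.get(r5.name), THREE_TO_ONE.get(r35.name)
            if a5 and a35:
                code = PPRCode(a5, a35)
        segments.append(RepeatSegment(index=i, start=start, end=end, code=code))
    return RepeatSegmentation(tuple(segments))


# ---------------------------------------------------------------------------
# Superposition

@dataclass(frozen=True)
class SuperposeResult:
    rmsd: float
    n_retained: int
    n_initial: int
    rotation: np.ndarray     # (3, 3), applied to model_b coordinates
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-6:
            raise StructureError(f"rotation determinant {det} != +1")


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of ``moving`` onto ``fixed`` (SVD Kabsch).

    Returns (rotation, translation, rmsd) with the proper-rotation sign
    correction, so x -> R x + t maps moving onto fixed.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[0] < 3:
        raise StructureError("superposition needs >= 3 paired atoms")
    mu_m, mu_f = moving.mean(axis=0), fixed.mean(axis=0)
    h = (moving - mu_m).T @ (fixed - mu_f)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = mu_f - rotation @ mu_m
    diff = (moving @ rotation.T + translation) - fixed
    rmsd = float(np.sqrt((diff ** 2).sum() / len(moving)))
    return rotation, translation, rmsd


def _pair_calpha(chain_a: Chain, chain_b: Chain, pair_by: str) -> tuple[np.ndarray, np.ndarray]:
    res_a = [r for r in chain_a.residues if r.mol_class == "protein" and "CA" in r.atoms]
    res_b = [r for r in chain_b.residues if r.mol_class == "protein" and "CA" in r.atoms]
    if pair_by == "numbering":
        ids_b = {r.seqid: r for r in res_b}
        pairs = [(r, ids_b[r.seqid]) for r in res_a if r.seqid in ids_b]
    elif pair_by == "alignment":
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = 0
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        seq_a = "".join(THREE_TO_ONE.get(r.name, "X") for r in res_a)
        seq_b = "".join(THREE_TO_ONE.get(r.name, "X") for r in res_b)
        alignment = aligner.align(seq_a, seq_b)[0]
        pairs = []
        for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
            for k in range(a_end - a_start):
                pairs.append((res_a[a_start + k], res_b[b_start + k]))
    else:
        raise ValueError(f"pair_by must be 'alignment' or 'numbering', got {pair_by!r}")
    if len(pairs) < 3:
        raise StructureError(f"only {len(pairs)} Calpha pairs: cannot superpose")
    xa = np.array([p[0].atoms["CA"].pos for p in pairs])
    xb = np.array([p[1].atoms["CA"].pos for p in pairs])
    return xa, xb


def superpose(
    model_a: StructureModel,
    model_b: StructureModel,
    prune_sigma: float = 2.0,
    max_cycles: int = 5,
    pair_by: str = "alignment",
) -> SuperposeResult:
    """Superpose model_b onto model_a on paired Calpha atoms.

    Pairing is by global sequence alignment (match 1 / mismatch 0 / gap -1)
    or by deposited residue numbering.  After the initial Kabsch fit, pairs
    deviating more than ``prune_sigma`` x the current RMSD are discarded and
    the fit repeated, up to ``max_cycles`` or convergence.
    """
    fixed, moving = _pair_calpha(model_a.protein_chain, model_b.protein_chain, pair_by)
    n_initial = len(fixed)
    keep = np.ones(n_initial, dtype=bool)
    rotation, translation, rmsd = kabsch(moving, fixed)
    for _ in range(max_cycles):
        if rmsd < 1e-6:  # already superposed to numerical precision
            break
        dev = np.linalg.norm(moving[keep] @ rotation.T + translation - fixed[keep], axis=1)
        bad = dev > prune_sigma * rmsd
        if not bad.any():
            break
        idx = np.flatnonzero(keep)
        keep[idx[bad]] = False
        if keep.sum() < 3:
            raise StructureError("fewer than 3 Calpha pairs survive pruning")
        rotation, translation, rmsd = kabsch(moving[keep], fixed[keep])
    return SuperposeResult(rmsd=rmsd, n_retained=int(keep.sum()), n_initial=n_initial,
                           rotation=rotation, translation=translation)


# ---------------------------------------------------------------------------
# Superhelix geometry

@dataclass(frozen=True)
class SuperhelixParams:
    axis: np.ndarray        # unit vector along repeat progression (N->C, 5'->3')
    rise: float             # angstrom per repeat
    twist: float            # signed degrees per repeat
    period: float           # angstrom per full turn: rise * 360 / |twist|
    diameter: float         # 2 x mean centroid radius, angstrom
    handedness: str         # 'right' or 'left'


def repeat_centroids(model: StructureModel, seg: RepeatSegmentation) -> np.ndarray:
    """Mean Calpha position per segmented repeat."""
    chain = model.protein_chain
    centroids = []
    for s in seg.segments:
        coords = [r.atoms["CA"].pos for r in chain.residues
                  if s.start <= r.seqid <= s.end and "CA" in r.atoms]
        if not coords:
            raise StructureError(f"repeat {s.index}: no Calpha atoms in range")
        centroids.append(np.mean(coords, axis=0))
    return np.array(centroids)


def _helix_axis(centroids: np.ndarray) -> np.ndarray:
    """Axis direction from centroid bisectors (exact for ideal helices).

    The second difference b_i = c_{i-1} + c_{i+1} - 2 c_i of points on a
    circular helix is purely radial, hence perpendicular to the axis; the
    axis is the direction most nearly orthogonal to all bisectors (smallest
    right singular vector).  Unlike the principal direction of the centroid
    cloud, this is unbiased for short or partial-turn solenoids.
    """
    bisectors = centroids[:-2] + centroids[2:] - 2.0 * centroids[1:-1]
    norms = np.linalg.norm(bisectors, axis=1)
    if np.all(norms < 1e-9):
        raise StructureError("repeat centroids are collinear: no defined superhelix")
    _, _, vt = np.linalg.svd(bisectors)
    axis = vt[-1]
    if (centroids[-1] - centroids[0]) @ axis < 0:
        axis = -axis
    return axis


def _circle_center(points_2d: np.ndarray) -> np.ndarray:
    """Least-squares (Kasa) circle-center fit in a plane."""
    a = np.column_stack([2.0 * points_2d, np.ones(len(points_2d))])
    b = (points_2d ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol[:2]


def superhelix(model: StructureModel, seg: RepeatSegmentation) -> SuperhelixParams:
    """Fit solenoid geometry to the repeat centroids.

    The axis comes from the centroid bisectors (see :func:`_helix_axis`),
    oriented along the repeat (N-to-C = 5'-to-3') progression, and its
    position from a least-squares circle fit of the centroids projected
    onto the normal plane.  Rise is the mean consecutive axial spacing;
    twist is the mean signed angle between consecutive radial vectors
    (right-hand rule about the axis), so positive twist = right-handed.
    """
    if len(seg) < 4:
        raise StructureError("superhelix fit needs at least 4 repeats")
    centroids = repeat_centroids(model, seg)
    axis = _helix_axis(centroids)
    # orthonormal frame spanning the plane normal to the axis
    e1 = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    proj = centroids @ np.column_stack([e1, e2])
    center_2d = _circle_center(proj)
    center = center_2d[0] * e1 + center_2d[1] * e2
    rel = centroids - center
    t = rel @ axis
    radial = rel - np.outer(t, axis)
    radii = np.linalg.norm(radial, axis=1)
    if np.mean(radii) < 1e-6 or np.any(radii < 1e-9):
        raise StructureError("repeat centroids are collinear with the axis: no defined twist")
    rise = float(np.mean(np.diff(t)))
    angles = []
    for i in range(len(centroids) - 1):
        u, v = radial[i], radial[i + 1]
        ang = np.arctan2(np.cross(u, v) @ axis, u @ v)
        angles.append(np.degrees(ang))
    twist = float(np.mean(angles))
    if abs(twist) < 1e-9:
        raise StructureError("zero twist: degenerate superhelix")
    period = rise * 360.0 / abs(twist)
    return SuperhelixParams(
        axis=axis,
        rise=rise,
        twist=twist,
        period=float(period),
        diameter=float(2.0 * np.mean(radii)),
        handedness="right" if twist > 0 else "left",
    )


# ---------------------------------------------------------------------------
# Hydrogen bonds and contacts

@dataclass(frozen=True)
class HBond:
    donor: str            # 'chain/resname seqid/atom'
    acceptor: str
    distance: float
    water_mediated: bool = False
    bridging_water: str | None = None


def _atom_id(chain_id: str, res: Residue, atom: Atom) -> str:
    return f"{chain_id}/{res.name}{res.seqid}/{atom.name}"


# Donor/acceptor polarity of the atoms this analysis touches. Watson-Crick
# N3 polarity distinguishes U (donor) from C (acceptor); G's N1/N2 donate
# while A's N1 accepts.
_DONOR_ATOMS = {
    ("U", "N3"), ("G", "N1"), ("G", "N2"), ("A", "N6"), ("C", "N4"),
    ("ASN", "ND2"), ("GLN", "NE2"), ("SER", "OG"), ("THR", "OG1"),
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"), ("TRP", "NE1"), ("CYS", "SG"),
}
_ACCEPTOR_ATOMS = {
    ("U", "O2"), ("U", "O4"), ("C", "O2"), ("C", "N3"), ("A", "N1"),
    ("A", "N3"), ("A", "N7"), ("G", "O6"), ("G", "N3"), ("G", "N7"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"),
}


def _orient_pair(res_p: Residue, atom_p: Atom, res_n: Residue, atom_n: Atom,
                 id_p: str, id_n: str) -> tuple[str, str]:
    """Order a protein/base atom pair as (donor, acceptor) by polarity."""
    p_donates = (res_p.name, atom_p.name) in _DONOR_ATOMS
    n_donates = (res_n.name, atom_n.name) in _DONOR_ATOMS
    n_accepts = (res_n.name, atom_n.name) in _ACCEPTOR_ATOMS
    if p_donates and n_accepts:
        return id_p, id_n
    if n_donates:
        return id_n, id_p
    return id_p, id_n


def _polar_sidechain_atoms(res: Residue) -> list[Atom]:
    return [a for a in res.atoms.values()
            if a.element in ("N", "O") and a.name not in BACKBONE_ATOMS]


@dataclass(frozen=True)
class RecognitionRow:
    repeat: int
    code: PPRCode | None
    base: str
    n_direct_pos5: int
    n_direct_pos35: int
    n_water_bridges: int


def find_hbonds(
    model: StructureModel,
    seg: RepeatSegmentation,
    d_cutoff: float = 3.5,
    include_water_bridges: bool = True,
) -> tuple[list[HBond], list[RecognitionRow]]:
    """Base-recognition polar contacts between code residues and RNA bases.

    For repeat i paired with the i-th RNA nucleotide (5'->3' chain order),
    reports heavy-atom N/O pairs within ``d_cutoff`` between the position-5 /
    position-35 side chains and the Watson-Crick-face atoms, and — when
    enabled — water bridges: a water oxygen within cutoff of both the base
    N3 and a polar position-35 side-chain atom.
    """
    protein = model.protein_chain
    rna = model.rna_chain
    nucleotides = [r for r in rna.residues if r.mol_class == "rna"]
    waters = model.water_atoms()
    hbonds: list[HBond] = []
    report: list[RecognitionRow] = []
    for s in seg.segments:
        if s.index > len(nucleotides):
            break
        nt = nucleotides[s.index - 1]
        wc_atoms = [nt.atoms[n] for n in WC_FACE_ATOMS.get(nt.name, ()) if n in nt.atoms]
        counts = {5: 0, 35: 0}
        n_bridges = 0
        for internal_pos in (5, 35):
            res = protein.residue_by_seqid(s.start + internal_pos - 1)
            if res is None:
                continue
            for atom in _polar_sidechain_atoms(res):
                for wc in wc_atoms:
                    dist = float(np.linalg.norm(atom.pos - wc.pos))
                    if dist <= d_cutoff:
                        donor, acceptor = _orient_pair(
                            res, atom, nt, wc,
                            _atom_id(protein.chain_id, res, atom),
                            _atom_id(rna.chain_id, nt, wc),
                        )
                        hbonds.append(HBond(donor, acceptor, dist))
                        counts[internal_pos] += 1
            if include_water_bridges and internal_pos == 35 and res is not None:
                n3 = nt.atoms.get("N3")
                if n3 is None:
                    continue
                for w_chain, w_res, w_atom in waters:
                    d_base = float(np.linalg.norm(w_atom.pos - n3.pos))
                    if d_base > d_cutoff:
                        continue
                    for atom in _polar_sidechain_atoms(res):
                        d_res = float(np.linalg.norm(w_atom.pos - atom.pos))
                        if d_res <= d_cutoff:
                            water_id = _atom_id(w_chain, w_res, w_atom)
                            hbonds.append(HBond(
                                donor=_atom_id(rna.chain_id, nt, n3),
                                acceptor=_atom_id(protein.chain_id, res, atom),
                                distance=max(d_base, d_res),
                                water_mediated=True,
                                bridging_water=water_id,
                            ))
                            n_bridges += 1
        report.append(RecognitionRow(
            repeat=s.index, code=s.code, base=nt.name,
            n_direct_pos5=counts[5], n_direct_pos35=counts[35],
            n_water_bridges=n_bridges,
        ))
    return hbonds, report


@dataclass(frozen=True)
class ContactRow:
    repeat: int
    val2_own_base: bool          # residue-2 side chain within cutoff of base i
    val2_prev_base: bool         # ... and of base i-1 (the sandwich partner)
    lys13_salt_bridge: bool
    lys13_distance: float | None
    incomplete: bool             # residue 2 or 13 side chain missing


def contact_report(
    model: StructureModel,
    seg: RepeatSegmentation,
    val2_cutoff: float = 4.5,
    salt_bridge_cutoff: float = 4.0,
) -> list[ContactRow]:
    """Val2 base-sandwich and Lys13-phosphate salt-bridge table.

    Val2 of repeat i packs against its own base i and against base i-1,
    completing the sandwich started by the previous repeat.  Lys13 NZ within
    ``salt_bridge_cutoff`` of any phosphate oxygen counts as a salt bridge.
    """
    protein = model.protein_chain
    try:
        nucleotides = [r for r in model.rna_chain.residues if r.mol_class == "rna"]
    except StructureError:
        nucleotides = []
    phosphate_atoms = [a for nt in nucleotides for n, a in nt.atoms.items()
                       if n in PHOSPHATE_OXYGENS]
    rows: list[ContactRow] = []
    for s in seg.segments:
        res2 = protein.residue_by_seqid(s.start + 1)
        res13 = protein.residue_by_seqid(s.start + 12)
        sc2 = [a for a in (res2.atoms.values() if res2 else [])
               if a.element not in ("H",) and a.name not in BACKBONE_ATOMS]
        nz = res13.atoms.get("NZ") if res13 else None
        incomplete = not sc2 or nz is None

        def touches(nt_index: int) -> bool:
            if not 1 <= nt_index <= len(nucleotides):
                return False
            nt = nucleotides[nt_index - 1]
            ring = [nt.atoms[n] for n in BASE_RING_ATOMS.get(nt.name, ()) if n in nt.atoms]
            return any(np.linalg.norm(a.pos - r.pos) <= val2_cutoff
                       for a in sc2 for r in ring)

        lys_dist = None
        if nz is not None and phosphate_atoms:
            dists = [float(np.linalg.norm(nz.pos - p.pos)) for p in phosphate_atoms]
            lys_dist = min(dists)
        rows.append(ContactRow(
            repeat=s.index,
            val2_own_base=touches(s.index),
            val2_prev_base=touches(s.index - 1),
            lys13_salt_bridge=lys_dist is not None and lys_dist <= salt_bridge_cutoff,
            lys13_distance=lys_dist,
            incomplete=incomplete,
        ))
    return rows
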