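"""Shared fixtures and helpers; all structural fixtures are generated in code."""

from __future__ import annotations

import numpy as np
import pytest

from pprkit.io import make_recognition_complex
from pprkit.structgeom import Atom, Chain, Residue, StructureModel

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def model_from_ca(sequence: str, coords, chain_id: str = "A",
                  first_seqid: int = 1) -> StructureModel:
    """Calpha-only protein model from a one-letter sequence and (n, 3) coords."""
    chain = Chain(chain_id)
    for i, (aa, xyz) in enumerate(zip(sequence, coords)):
        res = Residue(ONE_TO_THREE[aa], first_seqid + i)
        res.add_atom(Atom("CA", "C", np.asarray(xyz, float)))
        chain.residues.append(res)
    return StructureModel([chain])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def quaternion_rmsd(moving: np.ndarray, fixed: np.ndarray) -> float:
    """Independent superposition oracle: Horn's quaternion method.

    The optimal-superposition RMSD follows from the largest eigenvalue of
    the 4x4 quaternion key matrix, with no rotation matrix ever formed —
    a route disjoint from the SVD-based Kabsch implementation under test.
    """
    p = moving - moving.mean(axis=0)
    q = fixed - fixed.mean(axis=0)
    s = p.T @ q
    key = np.array([
        [s[0, 0] + s[1, 1] + s[2, 2], s[1, 2] - s[2, 1], s[2, 0] - s[0, 2], s[0, 1] - s[1, 0]],
        [s[1, 2] - s[2, 1], s[0, 0] - s[1, 1] - s[2, 2], s[0, 1] + s[1, 0], s[0, 2] + s[2, 0]],
        [s[2, 0] - s[0, 2], s[0, 1] + s[1, 0], s[1, 1] - s[0, 0] - s[2, 2], s[1, 2] + s[2, 1]],
        [s[0, 1] - s[1, 0], s[0, 2] + s[2, 0], s[1, 2] + s[2, 1], s[2, 2] - s[0, 0] - s[1, 1]],
    ])
    lam = float(np.linalg.eigvalsh(key)[-1])
    msd = ((p ** 2).sum() + (q ** 2).sum() - 2.0 * lam) / len(p)
    return float(np.sqrt(max(msd, 0.0)))


def write_model_pdb(model: StructureModel, path) -> None:
    """Serialize a StructureModel to PDB via gemmi (test I/O helper)."""
    import gemmi

    st = gemmi.Structure()
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seqid, " ")
            for atom in res.atoms.values():
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.pos)
                ga.occ = 1.0
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


@pytest.fixture
def recognition():
    """(model, segmentation) of the synthetic planted recognition complex."""
    return make_recognition_complex()
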