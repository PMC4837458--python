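"""Repeat detection and RNA target prediction for PPR arrays.

The inverse of design: given a protein sequence, find tandem 35-residue PPR
repeats with a scaffold-derived PSSM, read the code residues at positions 5
and 35 of each repeat, turn them into a position probability matrix (PPM)
over RNA bases, and scan transcripts for high-scoring candidate sites.

Scores are log-odds in bits against a uniform background.  The PSSM is
consensus-derived from the design scaffold, so detection is exact on
designed arrays and best-effort on natural P-type PPR proteins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .code import AMINO_ACIDS, RNA_BASES, BaseProfile, CodeTable, PPRCode, default_code_table
from .design import REPEAT_LENGTH, ScaffoldSpec, default_scaffold

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class RepeatHit:
    start: int      # 1-based residue index of the repeat's first residue
    score: float    # log-odds bits
    code: PPRCode

    @property
    def end(self) -> int:
        return self.start + REPEAT_LENGTH - 1


@dataclass(frozen=True)
class RepeatArray:
    """A chain of tandem repeat hits (>=2, spacing 35 +/- tolerance)."""

    hits: tuple[RepeatHit, ...]
    protein_id: str = ""

    def __post_init__(self) -> None:
        if len(self.hits) < 2:
            raise ValueError("a repeat array needs at least 2 hits")

    def __len__(self) -> int:
        return len(self.hits)


@dataclass(frozen=True)
class TargetPPM:
    """Per-repeat base probabilities; row i reads the i-th site nucleotide."""

    rows: tuple[BaseProfile, ...]
    background: BaseProfile = field(default_factory=BaseProfile.uniform)

    def __len__(self) -> int:
        return len(self.rows)

    def argmax_string(self) -> str:
        return "".join(row.argmax() for row in self.rows)

    def score_site(self, site: str) -> float:
        """Sum over positions of log2(p_row(base) / background(base))."""
        if len(site) != len(self.rows):
            raise ValueError(f"site length {len(site)} != PPM length {len(self.rows)}")
        total = 0.0
        for row, base in zip(self.rows, site):
            p = row[base]
            if p <= 0.0:
                return -math.inf
            total += math.log2(p / self.background[base])
        return total


@dataclass(frozen=True)
class SiteHit:
    transcript_id: str
    start: int          # 1-based nucleotide position
    score: float        # bits
    site: str
    pvalue: float | None = None


def build_repeat_pssm(scaffold: ScaffoldSpec | None = None, pseudocount: float = 0.1) -> np.ndarray:
    """35x20 log-odds matrix (bits, uniform background) from the scaffold.

    Each non-slot column is a pseudocount-smoothed one-hot on the template
    residue: p(aa) = (1[aa == template] + a/20) / (1 + a).  Columns 5 and 35
    are all-zero — the code slots carry no detection information.
    """
    scaffold = scaffold or default_scaffold()
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    pssm = np.zeros((REPEAT_LENGTH, 20))
    a = pseudocount
    for col, residue in enumerate(scaffold.template, start=1):
        if col in scaffold.slot_positions:
            continue
        probs = np.full(20, (a / 20) / (1 + a))
        probs[_AA_INDEX[residue]] = (1 + a / 20) / (1 + a)
        pssm[col - 1] = np.log2(probs / 0.05)
    return pssm


def max_pssm_score(pssm: np.ndarray) -> float:
    return float(pssm.max(axis=1).sum())


def score_window(seq: str, start: int, pssm: np.ndarray) -> float:
    """PSSM score of the 35-residue window beginning at 1-based ``start``."""
    window = seq[start - 1: start - 1 + REPEAT_LENGTH]
    if len(window) != REPEAT_LENGTH:
        raise ValueError("window extends past the sequence")
    return float(sum(pssm[i, _AA_INDEX[aa]] for i, aa in enumerate(window) if aa in _AA_INDEX))


def _extract_code(seq: str, start: int, scaffold: ScaffoldSpec) -> PPRCode:
    p5, p35 = scaffold.slot_positions
    return PPRCode(seq[start - 1 + p5 - 1], seq[start - 1 + p35 - 1])


def scan_protein(
    seq: str,
    pssm: np.ndarray | None = None,
    threshold_frac: float = 0.6,
    scaffold: ScaffoldSpec | None = None,
    spacing_tolerance: int = 1,
    protein_id: str = "",
) -> list[RepeatArray]:
    """Detect tandem PPR repeat arrays in a protein sequence.

    Every 35-residue window (stride 1) is scored against the PSSM; windows
    scoring above ``threshold_frac`` x the maximum attainable score become
    candidate hits, which are chained greedily N-to-C with an inter-start
    spacing of 35 +/- ``spacing_tolerance``.  Chains of fewer than two
    repeats are discarded.  Sequences shorter than 35 give an empty result.
    """
    scaffold = scaffold or default_scaffold()
    if pssm is None:
        pssm = build_repeat_pssm(scaffold)
    seq = seq.upper()
    if len(seq) < REPEAT_LENGTH:
        return []
    threshold = threshold_frac * max_pssm_score(pssm)
    candidates = [
        RepeatHit(start=s, score=score, code=_extract_code(seq, s, scaffold))
        for s in range(1, len(seq) - REPEAT_LENGTH + 2)
        if (score := score_window(seq, s, pssm)) >= threshold
    ]
    arrays: list[RepeatArray] = []
    used: set[int] = set()
    by_start = {h.start: h for h in candidates}
    # deltas in preference order: exact 35 spacing first, then nearest
    deltas = sorted(range(-spacing_tolerance, spacing_tolerance + 1), key=lambda d: (abs(d), d))
    for hit in candidates:
        if hit.start in used:
            continue
        chain = [hit]
        used.add(hit.start)
        while True:
            nxt = next(
                (cand for d in deltas
                 if (cand := by_start.get(chain[-1].start + REPEAT_LENGTH + d)) is not None
                 and cand.start not in used),
                None,
            )
            if nxt is None:
                break
            chain.append(nxt)
            used.add(nxt.start)
        if len(chain) >= 2:
            arrays.append(RepeatArray(hits=tuple(chain), protein_id=protein_id))
    return arrays


def predict_target(
    array: RepeatArray,
    seq: str,
    table: CodeTable | None = None,
    scaffold: ScaffoldSpec | None = None,
) -> TargetPPM:
    """Predicted RNA target PPM: row i = profile of repeat i's (5,35) code.

    Repeat order N-to-C equals site order 5'-to-3'.
    """
    if table is None:
        table = default_code_table()
    scaffold = scaffold or default_scaffold()
    seq = seq.upper()
    rows = []
    for hit in array.hits:
        if hit.end > len(seq):
            raise ValueError(f"repeat at {hit.start} extends past the sequence")
        rows.append(table.profile(_extract_code(seq, hit.start, scaffold)))
    return TargetPPM(rows=tuple(rows))


def _normalize_rna(seq: str) -> str:
    seq = seq.upper()
    if "T" in seq:
        logger.warning("T in transcript treated as U")
        seq = seq.replace("T", "U")
    return seq


_BASE_INDEX = {b: i for i, b in enumerate(RNA_BASES)}


def _ppm_logodds(ppm: TargetPPM) -> np.ndarray:
    """(width, 4) log2-odds array; zero-probability cells become -inf."""
    mat = np.empty((len(ppm), 4))
    for i, row in enumerate(ppm.rows):
        for b, j in _BASE_INDEX.items():
            p = row[b]
            mat[i, j] = np.log2(p / ppm.background[b]) if p > 0 else -np.inf
    return mat


def _score_all_windows(seq_idx: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Scores of every window, vectorized; windows with non-ACGU get NaN."""
    width = logodds.shape[0]
    valid = seq_idx >= 0
    safe = np.where(valid, seq_idx, 0)
    per_pos = logodds[np.arange(width)[None, :],
                      np.lib.stride_tricks.sliding_window_view(safe, width)]
    scores = per_pos.sum(axis=1)
    ok = np.lib.stride_tricks.sliding_window_view(valid, width).all(axis=1)
    return np.where(ok, scores, np.nan)


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, -1) for b in seq], dtype=np.int64)


def scan_transcripts(
    ppm: TargetPPM,
    transcripts: list[tuple[str, str]],
    top_k: int = 10,
    null_shuffles: int = 0,
    seed: int = 0,
) -> list[SiteHit]:
    """Rank candidate binding sites for a PPM across transcripts.

    Sense strand only (PPRs bind ssRNA).  Ties are broken by transcript
    order then position.  With ``null_shuffles`` > 0, each hit gets an
    empirical p-value against scores of seeded mononucleotide shuffles of
    its transcript: p = (1 + #null >= score) / (1 + #null).
    """
    if top_k <= 0:
        return []
    width = len(ppm)
    logodds = _ppm_logodds(ppm)
    hits: list[tuple[float, int, int, SiteHit]] = []
    encoded: dict[str, np.ndarray] = {}
    for t_idx, (tid, raw_seq) in enumerate(transcripts):
        seq = _normalize_rna(raw_seq)
        if len(seq) < width:
            logger.warning("transcript %s shorter than site width %d: skipped", tid, width)
            continue
        idx = _encode(seq)
        encoded[tid] = idx
        scores = _score_all_windows(idx, logodds)
        for pos0 in np.flatnonzero(~np.isnan(scores)):
            pos = int(pos0) + 1
            hits.append((float(scores[pos0]), t_idx, pos,
                         SiteHit(tid, pos, float(scores[pos0]), seq[pos0: pos0 + width])))
    hits.sort(key=lambda h: (-h[0], h[1], h[2]))
    top = [h[3] for h in hits[:top_k]]
    if null_shuffles > 0 and top:
        rng = np.random.default_rng(seed)
        null_by_tid: dict[str, np.ndarray] = {}
        for tid, idx in encoded.items():
            chunks = []
            for _ in range(null_shuffles):
                scores = _score_all_windows(rng.permutation(idx), logodds)
                chunks.append(scores[~np.isnan(scores)])
            null_by_tid[tid] = np.concatenate(chunks) if chunks else np.empty(0)
        top = [
            SiteHit(
                h.transcript_id, h.start, h.score, h.site,
                pvalue=float(
                    (1 + (null_by_tid[h.transcript_id] >= h.score).sum())
                    / (1 + null_by_tid[h.transcript_id].size)
                ),
            )
            for h in top
        ]
    return top
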