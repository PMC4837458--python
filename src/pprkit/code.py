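"""The PPR code: bi-residue base specificity of pentatricopeptide repeats.

Each 35-amino-acid PPR repeat reads one RNA base, and which base it prefers
is set almost entirely by the amino acids at repeat-internal positions 5 and
35 — the "PPR code".  The canonical design codes are ND -> U, NS -> C,
SN -> A and TD -> G; the degenerate codes NN (U or C), TN (A) and SD (G)
extend the set.  Position 5 is the chief determinant: asparagine there
favours pyrimidines, serine/threonine favour purines, and small residues
(Ala/Gly) leave room for purines but confer little specificity.

This module represents the code as a configurable probabilistic table
mapping a :class:`PPRCode` to a :class:`BaseProfile` over {A, C, G, U}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import yaml

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
RNA_BASES = ("A", "C", "G", "U")

#: Canonical design codes (base -> (pos5, pos35)).
CANONICAL_CODES = {"U": ("N", "D"), "C": ("N", "S"), "A": ("S", "N"), "G": ("T", "D")}

_PROB_TOL = 1e-9


class InvalidBaseError(ValueError):
    """A character outside the ACGU(T) RNA alphabet."""


class CodeTableError(ValueError):
    """A malformed code-table configuration."""


class PPRCode(NamedTuple):
    """Amino-acid pair at repeat positions 5 and 35."""

    pos5: str
    pos35: str

    def validate(self) -> "PPRCode":
        for aa in self:
            if aa not in AMINO_ACIDS:
                raise ValueError(f"not a one-letter amino acid: {aa!r}")
        return self

    def __str__(self) -> str:  # 'ND', 'SN', ...
        return self.pos5 + self.pos35


@dataclass(frozen=True)
class BaseProfile:
    """Probability distribution over the four RNA bases."""

    probabilities: Mapping[str, float]

    def __post_init__(self) -> None:
        probs = dict(self.probabilities)
        if set(probs) != set(RNA_BASES):
            raise ValueError(f"profile must cover exactly {RNA_BASES}, got {sorted(probs)}")
        if any(p < 0 for p in probs.values()):
            raise ValueError(f"negative probability in {probs}")
        total = sum(probs.values())
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"probabilities sum to {total}, not 1")
        object.__setattr__(self, "probabilities", probs)

    def __getitem__(self, base: str) -> float:
        return self.probabilities[base]

    def argmax(self) -> str:
        """Single most probable base (ties broken in ACGU order)."""
        return max(RNA_BASES, key=lambda b: self.probabilities[b])

    def argmax_set(self, tol: float = 1e-9) -> frozenset[str]:
        """All bases within ``tol`` of the maximum probability."""
        top = max(self.probabilities.values())
        return frozenset(b for b in RNA_BASES if self.probabilities[b] >= top - tol)

    @classmethod
    def from_base_set(cls, bases: Iterable[str], specificity_mass: float) -> "BaseProfile":
        """Put ``specificity_mass`` on ``bases`` (split equally), rest uniform."""
        bases = tuple(dict.fromkeys(bases))
        if not bases or not set(bases) <= set(RNA_BASES):
            raise ValueError(f"invalid base set {bases}")
        others = [b for b in RNA_BASES if b not in bases]
        probs = {b: specificity_mass / len(bases) for b in bases}
        rest = 1.0 - specificity_mass
        for b in others:
            probs[b] = rest / len(others) if others else 0.0
        return cls(probs)

    @classmethod
    def uniform(cls) -> "BaseProfile":
        return cls({b: 0.25 for b in RNA_BASES})


@dataclass
class CodeTable:
    """PPR code table: exact bi-residue entries plus position-5 fallbacks.

    ``entries`` maps exact codes to profiles; ``fallback_rules`` is an
    ordered list of (position-5 residue, profile) pairs consulted when no
    exact entry exists; anything else scores uniform.
    """

    entries: dict[PPRCode, BaseProfile]
    fallback_rules: list[tuple[str, BaseProfile]] = field(default_factory=list)
    specificity_mass: float = 0.90

    def __post_init__(self) -> None:
        required = {("N", "D"), ("N", "S"), ("S", "N"), ("T", "D"),
                    ("N", "N"), ("T", "N"), ("S", "D")}
        missing = required - {tuple(c) for c in self.entries}
        if missing:
            raise CodeTableError(
                "code table lacks literature codes: "
                + ", ".join("".join(c) for c in sorted(missing))
            )

    def profile(self, code: PPRCode) -> BaseProfile:
        return code_to_profile(code, self)


def base_to_code(base: str, position: int | None = None) -> PPRCode:
    """Canonical design code for an RNA base: U->ND, C->NS, A->SN, G->TD.

    ``T`` is accepted and treated as ``U`` (DNA-typed input) with a logged
    warning.  Anything else raises :class:`InvalidBaseError` naming the
    offending character and, when given, its 1-based position.
    """
    b = base.upper()
    if b == "T":
        logger.warning("T in RNA input treated as U")
        b = "U"
    if b not in CANONICAL_CODES:
        where = f" at position {position}" if position is not None else ""
        raise InvalidBaseError(f"invalid RNA base {base!r}{where}: expected one of A, C, G, U (or T)")
    return PPRCode(*CANONICAL_CODES[b])


def code_to_profile(code: PPRCode, table: CodeTable) -> BaseProfile:
    """Base-probability profile for a code under ``table``.

    Exact entries take precedence; otherwise the first matching position-5
    fallback applies; otherwise the profile is uniform.
    """
    code = PPRCode(*code).validate()
    entry = table.entries.get(code)
    if entry is not None:
        return entry
    for pos5, profile in table.fallback_rules:
        if code.pos5 == pos5:
            return profile
    return BaseProfile.uniform()


def _parse_table_dict(raw: dict, source: str) -> CodeTable:
    if not isinstance(raw, dict) or "codes" not in raw:
        raise CodeTableError(f"{source}: expected a mapping with a 'codes' section")
    mass = float(raw.get("specificity_mass", 0.90))
    if not 0.0 < mass <= 1.0:
        raise CodeTableError(f"{source}: specificity_mass must be in (0, 1], got {mass}")
    entries: dict[PPRCode, BaseProfile] = {}
    for key, value in raw["codes"].items():
        key = str(key).upper()
        if len(key) != 2:
            raise CodeTableError(f"{source}: code key {key!r} is not two letters")
        code = PPRCode(key[0], key[1])
        try:
            code.validate()
            if isinstance(value, dict):
                entries[code] = BaseProfile({str(k).upper(): float(v) for k, v in value.items()})
            else:
                entries[code] = BaseProfile.from_base_set(
                    [str(b).upper() for b in value], mass
                )
        except ValueError as exc:
            raise CodeTableError(f"{source}: entry {key!r}: {exc}") from exc
    fallbacks: list[tuple[str, BaseProfile]] = []
    for aa, value in (raw.get("fallbacks") or {}).items():
        aa = str(aa).upper()
        if aa not in AMINO_ACIDS:
            raise CodeTableError(f"{source}: fallback key {aa!r} is not an amino acid")
        try:
            fallbacks.append((aa, BaseProfile({str(k).upper(): float(v) for k, v in value.items()})))
        except ValueError as exc:
            raise CodeTableError(f"{source}: fallback {aa!r}: {exc}") from exc
    return CodeTable(entries=entries, fallback_rules=fallbacks, specificity_mass=mass)


def load_code_table(path: str | Path | None = None) -> CodeTable:
    """Load a code table from a YAML config, or the packaged default.

    The dialect is documented in the packaged ``data/code_table.yaml``:
    ``codes`` maps two-letter codes to base lists or explicit probability
    maps, ``fallbacks`` maps position-5 residues to explicit profiles.
    """
    if path is None:
        text = resources.files("pprkit.data").joinpath("code_table.yaml").read_text()
        source = "packaged default code table"
    else:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"code table not found: {path}")
        text = path.read_text()
        source = str(path)
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise CodeTableError(f"{source}: YAML parse error: {exc}") from exc
    return _parse_table_dict(raw, source)


_DEFAULT_TABLE: CodeTable | None = None


def default_code_table() -> CodeTable:
    """Packaged default table (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_code_table(None)
    return _DEFAULT_TABLE
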