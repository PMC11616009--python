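"""Polymer-SMILES parsing, tokenization, canonicalization and dataset IO.

A polymer repeat unit is written as an ordinary SMILES string in which the
wildcard atom ``[*]`` marks the two points where the unit bonds to its
neighbours along the chain (e.g. ``[*]CC(Cl)[*]`` for polyvinyl chloride).
All chemistry (validity, canonical form, atom-order enumeration) is delegated
to RDKit, which treats ``[*]`` as a dummy/wildcard atom natively.

The tokenizer is a regex SMILES tokenizer (bracket atoms, two-letter
halogens, ``%nn`` ring labels, single characters). It is lossless:
``detokenize(tokenize(s)) == s`` for every string it accepts. It is exposed
as an injectable interface so a different tokenizer can be substituted.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # rdkit's own stderr chatter; errors surface as None mols

logger = logging.getLogger("polycontrast")

#: A polymer repeat-unit SMILES string (``[*]`` marks connection points).
PolymerSmiles = str
#: An ordered list of SMILES tokens whose concatenation is the source string.
TokenSequence = list


class SmilesTokenizeError(ValueError):
    """Raised when a string cannot be split into SMILES tokens."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at position {position}")
        self.position = position


class ChemistryParseError(ValueError):
    """Raised when RDKit rejects a SMILES string."""


class ConfigurationError(ValueError):
    """Raised for bad dataset/column configuration."""


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------


class Tokenizer(Protocol):
    def tokenize(self, s: str) -> list[str]: ...

    def detokenize(self, tokens: Sequence[str]) -> str: ...


_TOKEN_RE = re.compile(
    r"\[[^\[\]]*\]"   # bracket atom, e.g. [*], [nH], [C@@H], [MASK]
    r"|Cl|Br"         # two-letter halogens
    r"|%\d{2}"        # two-digit ring-closure label
    r"|."             # any other single character
)


class RegexSmilesTokenizer:
    """Reference regex-based SMILES tokenizer (lossless, injectable)."""

    def tokenize(self, s: str) -> list[str]:
        if not s:
            raise SmilesTokenizeError("empty SMILES string", 0)
        tokens: list[str] = []
        pos = 0
        for m in _TOKEN_RE.finditer(s):
            tok = m.group(0)
            if tok in ("[", "]"):
                raise SmilesTokenizeError("unbalanced bracket", m.start())
            tokens.append(tok)
            pos = m.end()
        assert pos == len(s)
        return tokens

    def detokenize(self, tokens: Sequence[str]) -> str:
        return "".join(tokens)


DEFAULT_TOKENIZER = RegexSmilesTokenizer()


def tokenize(s: PolymerSmiles, tokenizer: Tokenizer = DEFAULT_TOKENIZER) -> list[str]:
    """Split a SMILES string into tokens; lossless w.r.t. :func:`detokenize`."""
    return tokenizer.tokenize(s)


def detokenize(tokens: Sequence[str], tokenizer: Tokenizer = DEFAULT_TOKENIZER) -> PolymerSmiles:
    """Concatenate tokens back into a string (inverse of :func:`tokenize`)."""
    return tokenizer.detokenize(tokens)


# ---------------------------------------------------------------------------
# Chemistry
# ---------------------------------------------------------------------------


def _parse_mol(s: PolymerSmiles) -> Chem.Mol:
    if not isinstance(s, str) or not s:
        raise ChemistryParseError(f"not a SMILES string: {s!r}")
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise ChemistryParseError(f"RDKit could not parse SMILES: {s!r}")
    return mol


def _restore_star_brackets(s: str) -> str:
    """RDKit writes plain wildcard atoms as bare ``*``; restore ``[*]``."""
    return "".join("[*]" if t == "*" else t for t in DEFAULT_TOKENIZER.tokenize(s))


def canonicalize(s: PolymerSmiles) -> PolymerSmiles:
    """Return the canonical SMILES for the molecular graph of ``s``.

    Deterministic and idempotent; any two renderings of the same graph map to
    the same string. Wildcard atoms are written ``[*]``.
    """
    return _restore_star_brackets(Chem.MolToSmiles(_parse_mol(s), canonical=True))


def enumerate_smiles(s: PolymerSmiles, rng: np.random.Generator) -> PolymerSmiles:
    """Generate a randomized (generally non-canonical) rendering of ``s``.

    The atom order is permuted with a draw from ``rng`` and the molecule is
    re-written without canonical ordering, so the output denotes the same
    molecular graph and is reproducible for a given generator state. For
    very small molecules the output may coincide with the input.
    """
    mol = _parse_mol(s)
    n = mol.GetNumAtoms()
    if n > 1:
        perm = [int(i) for i in rng.permutation(n)]
        mol = Chem.RenumberAtoms(mol, perm)
    return _restore_star_brackets(Chem.MolToSmiles(mol, canonical=False))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationProfile:
    """Constraints on the number of ``[*]`` connection tokens."""

    min_stars: int = 2
    max_stars: int | None = 2
    name: str = "homopolymer"


#: Homopolymer repeat unit: exactly two connection points.
HOMOPOLYMER_PROFILE = ValidationProfile(2, 2, "homopolymer")
#: Permissive: at least one connection point.
PERMISSIVE_PROFILE = ValidationProfile(1, None, "permissive")


@dataclass
class ValidationReport:
    smiles: str
    valid_smiles: bool
    star_count: int
    profile_ok: bool
    errors: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.valid_smiles and self.profile_ok

    def to_dict(self) -> dict:
        return {
            "smiles": self.smiles,
            "valid_smiles": self.valid_smiles,
            "star_count": self.star_count,
            "profile_ok": self.profile_ok,
            "errors": list(self.errors),
        }


def validate(s: PolymerSmiles,
             profile: ValidationProfile = HOMOPOLYMER_PROFILE) -> ValidationReport:
    """Check chemical validity and connection-token count; never raises."""
    errors: list[str] = []
    star_count = 0
    valid = True
    try:
        tokens = tokenize(s)
        star_count = sum(1 for t in tokens if t in ("[*]", "*"))
    except (SmilesTokenizeError, ChemistryParseError) as exc:
        errors.append(str(exc))
        valid = False
    if valid:
        try:
            _parse_mol(s)
        except ChemistryParseError as exc:
            errors.append(str(exc))
            valid = False
    profile_ok = valid and star_count >= profile.min_stars and (
        profile.max_stars is None or star_count <= profile.max_stars)
    if valid and not profile_ok:
        errors.append(
            f"star count {star_count} violates profile {profile.name!r} "
            f"(min {profile.min_stars}, max {profile.max_stars})")
    return ValidationReport(s, valid, star_count, profile_ok, errors)


# ---------------------------------------------------------------------------
# Dataset IO
# ---------------------------------------------------------------------------


def read_dataset(path: str | Path, format: str | None = None,
                 smiles_col: str = "smiles", label_col: str | None = None,
                 profile: ValidationProfile = HOMOPOLYMER_PROFILE,
                 ) -> tuple[list[PolymerSmiles], np.ndarray | None]:
    """Read a ``.smi`` (one SMILES per line) or CSV dataset.

    Rows failing :func:`validate` under ``profile`` are dropped and the count
    is logged. Order of surviving rows is preserved. Returns the SMILES list
    and, when ``label_col`` is given, the matching label vector.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "smi"
    if format not in ("smi", "csv"):
        raise ConfigurationError(f"unknown dataset format {format!r}")

    raw: list[tuple[str, float | None]] = []
    if format == "smi":
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    raw.append((line.split()[0], None))
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            cols = reader.fieldnames or []
            if smiles_col not in cols:
                raise ConfigurationError(f"missing column {smiles_col!r} in {path}")
            if label_col is not None and label_col not in cols:
                raise ConfigurationError(f"missing column {label_col!r} in {path}")
            for row in reader:
                y = float(row[label_col]) if label_col is not None else None
                raw.append((row[smiles_col], y))

    smiles: list[str] = []
    labels: list[float] = []
    dropped = 0
    for s, y in raw:
        if validate(s, profile).ok:
            smiles.append(s)
            if y is not None:
                labels.append(y)
        else:
            dropped += 1
    if dropped:
        logger.warning("read_dataset(%s): dropped %d invalid row(s)", path, dropped)
    if not smiles:
        logger.warning("read_dataset(%s): no valid records", path)
    y_arr = np.asarray(labels, dtype=float) if label_col is not None else None
    return smiles, y_arr
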