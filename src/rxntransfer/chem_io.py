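"""Reaction SMILES I/O: parsing, canonicalization, tokenization, vocabularies.

A reaction is written ``precursors>>products`` with fragments joined by
``.``; no distinction is made between reactants and reagents on the input
side.  Exact-match evaluation downstream relies on every molecule having a
unique canonical spelling, so canonicalization (via RDKit, stereo
descriptors preserved) and a deterministic fragment order are applied before
any comparison or serialization.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")  # silence per-molecule parse warnings

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionRecord",
    "TokenSequence",
    "Vocabulary",
    "ReactionParseError",
    "InvalidSmilesError",
    "TokenizationError",
    "parse_reaction_line",
    "read_reaction_file",
    "write_reaction_file",
    "reaction_smiles",
    "canonicalize_smiles",
    "canonicalize_reaction",
    "canonicalize_corpus",
    "tokenize",
    "detokenize",
    "format_src_tgt",
    "build_vocab",
]


class ReactionParseError(ValueError):
    """A reaction line does not conform to ``precursors>>products[\\tyear[\\tid]]``."""


class InvalidSmilesError(ValueError):
    """A SMILES string could not be parsed into a molecule."""


class TokenizationError(ValueError):
    """A SMILES string contains a span not covered by the token pattern."""


# Atom-wise SMILES tokenization: bracket atoms, two-letter halogens and
# %NN ring closures are single tokens; everything else is one character.
SMILES_TOKEN_PATTERN = re.compile(
    r"(\[[^\]]+]|Br?|Cl?|N|O|S|P|F|I|b|c|n|o|s|p|\(|\)|\.|=|#|-|\+|\\|\/|:|~|@|\?|>|\*|\$|%[0-9]{2}|[0-9])"
)


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: precursor and product fragment SMILES, optional metadata.

    Reactants and reagents are undifferentiated within ``precursors``.
    """

    precursors: tuple[str, ...]
    products: tuple[str, ...]
    year: int | None = None
    record_id: str | None = None

    def __post_init__(self) -> None:
        for side, name in ((self.precursors, "precursor"), (self.products, "product")):
            if not side:
                raise ValueError(f"reaction has no {name} fragments")
            for frag in side:
                if not frag:
                    raise ValueError(f"empty {name} fragment")
                if ">" in frag or any(c.isspace() for c in frag):
                    raise ValueError(f"illegal character in {name} fragment {frag!r}")

    @staticmethod
    def make(
        precursors: Sequence[str],
        products: Sequence[str],
        year: int | None = None,
        record_id: str | None = None,
    ) -> "ReactionRecord":
        return ReactionRecord(tuple(precursors), tuple(products), year, record_id)


@dataclass(frozen=True)
class TokenSequence:
    """Atom-wise tokens of a SMILES string; concatenation reproduces the source."""

    tokens: tuple[str, ...]
    source: str

    def __post_init__(self) -> None:
        if "".join(self.tokens) != self.source:
            raise ValueError("tokens do not concatenate to source")

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


class Vocabulary:
    """Token <-> index mapping with reserved specials at the lowest indices.

    Specials are, in order: padding, sequence start, sequence end, unknown.
    Ordinary tokens follow, sorted lexicographically, so the mapping is a
    pure function of the token set.
    """

    PAD = "<pad>"
    BOS = "<bos>"
    EOS = "<eos>"
    UNK = "<unk>"
    SPECIALS = (PAD, BOS, EOS, UNK)

    def __init__(self, tokens: Iterable[str]):
        ordinary = sorted(set(tokens) - set(self.SPECIALS))
        self._itos: list[str] = list(self.SPECIALS) + ordinary
        self._stoi: dict[str, int] = {t: i for i, t in enumerate(self._itos)}

    # -- mapping ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self._itos)

    def __contains__(self, token: str) -> bool:
        return token in self._stoi

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Vocabulary) and self._itos == other._itos

    @property
    def token_to_index(self) -> dict[str, int]:
        return dict(self._stoi)

    @property
    def tokens(self) -> tuple[str, ...]:
        """All tokens in index order, specials first."""
        return tuple(self._itos)

    @property
    def pad_index(self) -> int:
        return self._stoi[self.PAD]

    @property
    def bos_index(self) -> int:
        return self._stoi[self.BOS]

    @property
    def eos_index(self) -> int:
        return self._stoi[self.EOS]

    @property
    def unk_index(self) -> int:
        return self._stoi[self.UNK]

    def index(self, token: str) -> int:
        return self._stoi[token]

    def token(self, index: int) -> str:
        return self._itos[index]

    def encode(self, tokens: Iterable[str], strict: bool = True) -> list[int]:
        """Map tokens to indices.

        With ``strict`` (training), an out-of-vocabulary token raises;
        otherwise (inference) it maps to the unknown special and is logged.
        """
        out = []
        for t in tokens:
            idx = self._stoi.get(t)
            if idx is None:
                if strict:
                    raise KeyError(f"token {t!r} not in vocabulary")
                logger.info("mapping unknown token %r to %s", t, self.UNK)
                idx = self.unk_index
            out.append(idx)
        return out

    def decode(self, indices: Iterable[int]) -> list[str]:
        return [self._itos[i] for i in indices]

    # -- serialization ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        """One ordinary token per line; specials are implicit."""
        Path(path).write_text(
            "".join(t + "\n" for t in self._itos[len(self.SPECIALS):]), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls(t for t in lines if t)


# ---------------------------------------------------------------------------
# Parsing and serialization
# ---------------------------------------------------------------------------

def parse_reaction_line(line: str, lineno: int | None = None) -> ReactionRecord:
    """Parse ``precursors>>products[\\tyear[\\tid]]`` into a ReactionRecord.

    An agent field written before the ``>>`` separator (``A>B>>C``) is merged
    into the precursors with a warning; a line with no ``>>`` at all is
    rejected.
    """
    where = f" (line {lineno})" if lineno is not None else ""
    fields = line.rstrip("\n").split("\t")
    reaction = fields[0].strip()
    if ">>" not in reaction:
        raise ReactionParseError(f"no '>>' separator in {reaction!r}{where}")
    left, _, right = reaction.partition(">>")
    if ">" in right:
        raise ReactionParseError(f"multiple '>' separators in {reaction!r}{where}")
    if ">" in left:
        reactants, _, agents = left.partition(">")
        if ">" in agents:
            raise ReactionParseError(f"multiple '>' separators in {reaction!r}{where}")
        logger.warning("merging agent field into precursors%s: %r", where, reaction)
        left = ".".join(p for p in (reactants, agents) if p)
    precursors = [f for f in left.split(".") if f]
    products = [f for f in right.split(".") if f]
    if not precursors or not left or not all(left.split(".")):
        raise ReactionParseError(f"empty precursor side or fragment in {reaction!r}{where}")
    if not products or not right or not all(right.split(".")):
        raise ReactionParseError(f"empty product side or fragment in {reaction!r}{where}")

    year: int | None = None
    record_id: str | None = None
    if len(fields) > 1 and fields[1].strip():
        try:
            year = int(fields[1].strip())
        except ValueError as exc:
            raise ReactionParseError(f"non-integer year {fields[1]!r}{where}") from exc
    if len(fields) > 2 and fields[2].strip():
        record_id = fields[2].strip()
    if len(fields) > 3:
        raise ReactionParseError(f"too many tab-separated fields{where}")
    try:
        return ReactionRecord.make(precursors, products, year, record_id)
    except ValueError as exc:
        raise ReactionParseError(f"{exc}{where}") from exc


def read_reaction_file(path: str | Path) -> list[ReactionRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                records.append(parse_reaction_line(line, lineno=lineno))
    return records


def reaction_smiles(record: ReactionRecord) -> str:
    return ".".join(record.precursors) + ">>" + ".".join(record.products)


def write_reaction_file(records: Iterable[ReactionRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            line = reaction_smiles(rec)
            if rec.year is not None or rec.record_id is not None:
                line += f"\t{rec.year if rec.year is not None else ''}"
            if rec.record_id is not None:
                line += f"\t{rec.record_id}"
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# Canonicalization
# ---------------------------------------------------------------------------

def canonicalize_smiles(smiles: str) -> str:
    """Unique canonical SMILES (RDKit, isomeric: stereo descriptors kept)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparseable SMILES {smiles!r}")
    return Chem.MolToSmiles(mol, isomericSmiles=True)


def is_valid_smiles(smiles: str) -> bool:
    return Chem.MolFromSmiles(smiles) is not None


def canonicalize_reaction(record: ReactionRecord) -> ReactionRecord:
    """Canonicalize every fragment and sort each side lexicographically.

    Sorting makes exact-match comparison invariant to fragment order;
    duplicate fragments are kept (multiplicity is chemically meaningful:
    single vs. double substitution differ in it).
    """
    def canon_side(frags: tuple[str, ...], side: str) -> tuple[str, ...]:
        out = []
        for frag in frags:
            try:
                out.append(canonicalize_smiles(frag))
            except InvalidSmilesError as exc:
                raise InvalidSmilesError(f"invalid {side} fragment {frag!r}") from exc
        return tuple(sorted(out))

    return replace(
        record,
        precursors=canon_side(record.precursors, "precursor"),
        products=canon_side(record.products, "product"),
    )


def canonicalize_corpus(
    records: Iterable[ReactionRecord],
) -> tuple[list[ReactionRecord], int]:
    """Canonicalize a corpus, dropping records with uncanonicalizable products.

    A record whose product cannot be canonicalized is an unlearnable target;
    the number dropped is logged and returned.
    """
    kept, dropped = [], 0
    for rec in records:
        try:
            kept.append(canonicalize_reaction(rec))
        except InvalidSmilesError:
            dropped += 1
    if dropped:
        logger.warning("dropped %d records with uncanonicalizable fragments", dropped)
    return kept, dropped


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

def tokenize(smiles: str) -> TokenSequence:
    """Greedy left-to-right atom-wise tokenization of a SMILES string."""
    tokens = []
    pos = 0
    for match in SMILES_TOKEN_PATTERN.finditer(smiles):
        if match.start() != pos:
            raise TokenizationError(
                f"untokenizable span {smiles[pos:match.start()]!r} at position {pos} in {smiles!r}"
            )
        tokens.append(match.group())
        pos = match.end()
    if pos != len(smiles):
        raise TokenizationError(
            f"untokenizable span {smiles[pos:]!r} at position {pos} in {smiles!r}"
        )
    return TokenSequence(tuple(tokens), smiles)


def detokenize(tokens: TokenSequence | Iterable[str]) -> str:
    if isinstance(tokens, TokenSequence):
        return tokens.source
    return "".join(tokens)


def format_src_tgt(record: ReactionRecord) -> tuple[str, str]:
    """Space-separated token strings for the source (precursors) and target
    (products) sides; fragments joined by a literal ``.`` token."""
    src = " ".join(tokenize(".".join(record.precursors)).tokens)
    tgt = " ".join(tokenize(".".join(record.products)).tokens)
    return src, tgt


def build_vocab(records: Iterable[ReactionRecord]) -> Vocabulary:
    """Vocabulary of all tokens observed on either side of the corpus."""
    tokens: set[str] = set()
    for rec in records:
        tokens.update(tokenize(".".join(rec.precursors)).tokens)
        tokens.update(tokenize(".".join(rec.products)).tokens)
    return Vocabulary(tokens)
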