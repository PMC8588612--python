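"""SMILES tokenization, vocabulary construction, validity checks and corpus I/O.

The generator treats a molecule as a sentence over a small chemical alphabet:
multi-character organic-subset atoms (``Cl``, ``Br``), bracket expressions
(``[nH]``, ``[O-]``, ...) and two-digit ring closures (``%10``) are each one
token, everything else is a single character.  Two control tokens, ``GO`` and
``END``, delimit every sequence the language model sees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty about every unparseable SMILES; validity is a boolean here.
RDLogger.DisableLog("rdApp.error")

GO = "GO"
END = "END"

#: two-letter element symbols that may appear outside brackets
_TWO_LETTER = ("Cl", "Br")


class TokenizationError(ValueError):
    """Raised when a SMILES string cannot be split into known tokens."""

    def __init__(self, smiles: str, substring: str, position: int):
        self.smiles = smiles
        self.substring = substring
        self.position = position
        super().__init__(
            f"cannot tokenize {smiles!r}: unknown token {substring!r} at position {position}"
        )


def split_smiles(smiles: str) -> list[str]:
    """Lex a SMILES string into chemical tokens (no GO/END sentinels).

    Longest-match scan: bracket expressions are captured greedily up to the
    closing ``]``, ``%NN`` ring closures and two-letter halogens are single
    tokens, all remaining characters are one token each.
    """
    if not smiles:
        raise TokenizationError(smiles, "", 0)
    tokens: list[str] = []
    i = 0
    n = len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise TokenizationError(smiles, smiles[i:], i)
            tokens.append(smiles[i : j + 1])
            i = j + 1
        elif ch == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise TokenizationError(smiles, smiles[i : i + 3], i)
            tokens.append(smiles[i : i + 3])
            i += 3
        elif smiles[i : i + 2] in _TWO_LETTER:
            tokens.append(smiles[i : i + 2])
            i += 2
        else:
            tokens.append(ch)
            i += 1
    return tokens


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token alphabet with GO/END sentinels and index maps.

    Chemical tokens are stored sorted so that a vocabulary built from the same
    corpus is byte-identical across runs and corpus permutations.
    """

    tokens: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.tokens[0] != GO or self.tokens[1] != END:
            raise ValueError("vocabulary must start with GO, END")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(self.tokens)})

    @classmethod
    def from_tokens(cls, chemical_tokens: Iterable[str]) -> "Vocabulary":
        chem = sorted(set(chemical_tokens) - {GO, END})
        return cls(tokens=(GO, END, *chem))

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    @property
    def go_index(self) -> int:
        return 0

    @property
    def end_index(self) -> int:
        return 1

    def index(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise TokenizationError(token, token, 0) from None

    def encode(self, tokens: Sequence[str]) -> list[int]:
        return [self.index(t) for t in tokens]

    def decode(self, indices: Sequence[int]) -> list[str]:
        return [self.tokens[i] for i in indices]

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln]
        return cls(tokens=tuple(lines))


@dataclass
class TokenSequence:
    """A lexed SMILES: chemical tokens plus an optional trailing END sentinel."""

    tokens: list[str]
    source_smiles: str | None = None

    @property
    def chemical_tokens(self) -> list[str]:
        return [t for t in self.tokens if t not in (GO, END)]

    def detokenize(self) -> str:
        return "".join(self.chemical_tokens)


def tokenize(smiles: str, vocab: Vocabulary | None = None) -> TokenSequence:
    """Split ``smiles`` into tokens; with a vocabulary, validate membership.

    Raises :class:`TokenizationError` naming the offending substring when a
    lexed token is absent from ``vocab``.
    """
    parts = split_smiles(smiles)
    if vocab is not None:
        pos = 0
        for t in parts:
            if t not in vocab:
                raise TokenizationError(smiles, t, pos)
            pos += len(t)
    return TokenSequence(tokens=parts, source_smiles=smiles)


def detokenize(seq: TokenSequence | Sequence[str]) -> str:
    if isinstance(seq, TokenSequence):
        return seq.detokenize()
    return "".join(t for t in seq if t not in (GO, END))


def is_valid_smiles(smiles: str) -> tuple[bool, str | None]:
    """Return ``(valid, canonical_smiles)``.

    Validity means the chemistry parser yields a molecule; the canonical form
    is what uniqueness accounting is computed on (raw strings are trivially
    gamed by atom reordering).
    """
    if not smiles:
        return False, None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False, None
    return True, Chem.MolToSmiles(mol)


def canonicalize(smiles: str) -> str | None:
    return is_valid_smiles(smiles)[1]


def build_vocabulary(corpus: Iterable[str]) -> tuple[Vocabulary, int]:
    """Collect the token union over a corpus into a sorted vocabulary.

    Unparseable SMILES are skipped with a logged warning; the skip count is
    returned alongside the vocabulary.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    tokens: set[str] = set()
    skipped = 0
    for smi in corpus:
        valid, _ = is_valid_smiles(smi)
        if not valid:
            skipped += 1
            logger.warning("skipping unparseable SMILES %r", smi)
            continue
        tokens.update(split_smiles(smi))
    if not tokens:
        raise ValueError("no parseable SMILES in corpus")
    return Vocabulary.from_tokens(tokens), skipped


def read_smiles_file(path: str | Path) -> list[str]:
    """Read a corpus: one SMILES per line, or a TSV with a ``smiles`` column."""
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        return []
    header = lines[0].split("\t")
    if "smiles" in [h.lower() for h in header]:
        col = [h.lower() for h in header].index("smiles")
        return [ln.split("\t")[col] for ln in lines[1:]]
    return [ln.split("\t")[0] for ln in lines]


def write_smiles_file(path: str | Path, smiles: Iterable[str]) -> None:
    Path(path).write_text("\n".join(smiles) + "\n")
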