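"""Lexical scanning of SMILES / DeepSMILES strings.

The generator and the codec work at the string level, so they need a
common, minimal tokenizer.  It recognises bracket atoms, organic-subset
atoms, bonds, branch parentheses, dots and ring-closure numerals
(``%nn`` for two-digit labels).  It performs no chemistry: valence and
aromaticity checks are left to RDKit at parse time.
"""

from __future__ import annotations

import re
from typing import Iterator, NamedTuple

__all__ = [
    "FormatError",
    "Token",
    "TAG_ATOM_RE",
    "TAG_PAIR_RE",
    "tokenize",
    "count_atoms",
    "ring_value",
    "open_ring_labels",
    "ring_label_repr",
]


class FormatError(ValueError):
    """Raised when a string cannot be scanned as (Deep)SMILES."""


class Token(NamedTuple):
    kind: str  # 'atom' | 'bond' | 'open' | 'close' | 'ring' | 'dot'
    text: str
    pos: int   # character offset in the source string


# A cleaved-bond tag is a wildcard bracket atom carrying a positive
# isotope number; tags always travel as adjacent pairs.
TAG_ATOM_RE = re.compile(r"\[(\d+)\*\]")
TAG_PAIR_RE = re.compile(r"\[(\d+)\*\]\[(\d+)\*\]")

_TWO_LETTER = ("Cl", "Br")
_ONE_LETTER = set("BCNOPSFI*")
_AROMATIC = set("bcnops")
_BOND = set("-=#$:/\\~")


def tokenize(s: str) -> Iterator[Token]:
    """Yield tokens left to right; raise :class:`FormatError` on junk.

    Numerals outside brackets are emitted as ``ring`` tokens; in the
    DeepSMILES dialect the caller interprets them as ring sizes instead
    of paired labels — the lexical shape is identical.
    """
    i, n = 0, len(s)
    while i < n:
        c = s[i]
        if c == "[":
            j = s.find("]", i)
            if j < 0:
                raise FormatError(f"unterminated bracket atom at {i}: {s!r}")
            yield Token("atom", s[i : j + 1], i)
            i = j + 1
        elif c == "%":
            if i + 2 >= n or not s[i + 1 : i + 3].isdigit():
                raise FormatError(f"bad %nn ring numeral at {i}: {s!r}")
            yield Token("ring", s[i : i + 3], i)
            i += 3
        elif c.isdigit():
            yield Token("ring", c, i)
            i += 1
        elif s[i : i + 2] in _TWO_LETTER:
            yield Token("atom", s[i : i + 2], i)
            i += 2
        elif c in _ONE_LETTER or c in _AROMATIC:
            yield Token("atom", c, i)
            i += 1
        elif c in _BOND:
            yield Token("bond", c, i)
            i += 1
        elif c == "(":
            yield Token("open", c, i)
            i += 1
        elif c == ")":
            yield Token("close", c, i)
            i += 1
        elif c == ".":
            yield Token("dot", c, i)
            i += 1
        else:
            raise FormatError(f"unexpected character {c!r} at {i} in {s!r}")


def count_atoms(s: str, include_tags: bool = False) -> int:
    """Number of atom tokens in *s*; cleaved-bond tags excluded by default."""
    n = 0
    for tok in tokenize(s):
        if tok.kind == "atom":
            if not include_tags and TAG_ATOM_RE.fullmatch(tok.text):
                continue
            n += 1
    return n


def ring_value(text: str) -> int:
    """Numeric value of a ring token (``'7'`` -> 7, ``'%12'`` -> 12)."""
    return int(text[1:]) if text.startswith("%") else int(text)


def open_ring_labels(context: str) -> set[int]:
    """Ring labels open (seen an odd number of times) at the end of *context*.

    SMILES semantics: a label opens at first sight and closes at the
    second, after which it may be reused.
    """
    open_: set[int] = set()
    for tok in tokenize(context):
        if tok.kind == "ring":
            open_.symmetric_difference_update({ring_value(tok.text)})
    return open_


def ring_label_repr(label: int) -> str:
    """Write a ring label the way SMILES does: ``7`` or ``%12``."""
    if label < 1:
        raise ValueError("ring labels start at 1")
    if label < 10:
        return str(label)
    if label < 100:
        return f"%{label}"
    raise FormatError("more than 99 simultaneously open rings")
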