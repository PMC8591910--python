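"""Splitting tagged strings and building the fragment index.

A tagged string is one (Deep)SMILES line in which every cut bond is
written as an adjacent wildcard pair ``[x*][y*]``.  Splitting follows
the branch-nesting rule: the *seed* fragment is the prefix (it keeps
every tag pair in place, as future replacement sites); each *branch*
fragment begins immediately after a tag pair and extends as far as it
can without dropping below the nesting depth at which it started.  A
branch whose body itself contains tag pairs keeps them embedded and is
registered under the first pair that spawned it.

The index is simply an array of seed strings plus a mapping from the
literal tag-pair string to the array of branch bodies filed under it.
Duplicates are kept on purpose: a fragment seen twice in the training
set should be drawn twice as often.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .tokens import TAG_PAIR_RE, FormatError, ring_value, tokenize

__all__ = ["FragmentIndex", "split_tagged", "build_index"]

log = logging.getLogger(__name__)

_LONE_TAG_RE = re.compile(r"\[(\d*)\*\]")


class _Frame:
    __slots__ = ("start_depth", "key", "parts")

    def __init__(self, start_depth: int, key: str | None):
        self.start_depth = start_depth
        self.key = key
        self.parts: list[str] = []


def split_tagged(tagged: str) -> tuple[str, list[tuple[str, str]]]:
    """Split a tagged string into its seed and ``(key, body)`` branches.

    Branches are returned in order of appearance.  Raises
    :class:`~smifrag.tokens.FormatError` on unbalanced parentheses, a
    lone wildcard, a wildcard missing its isotope index, or an empty
    branch body.
    """
    frames: list[_Frame] = [_Frame(0, None)]
    opened: list[_Frame] = []
    depth = 0
    i, n = 0, len(tagged)
    while i < n:
        m = TAG_PAIR_RE.match(tagged, i)
        if m:
            frames[-1].parts.append(m.group(0))
            frame = _Frame(depth, m.group(0))
            frames.append(frame)
            opened.append(frame)
            i = m.end()
            continue
        c = tagged[i]
        if c == "[":
            j = tagged.find("]", i)
            if j < 0:
                raise FormatError(f"unterminated bracket atom in {tagged!r}")
            tok = tagged[i : j + 1]
            if _LONE_TAG_RE.fullmatch(tok):
                raise FormatError(
                    f"lone or index-less wildcard {tok!r} in {tagged!r}; "
                    "tags must be adjacent [x*][y*] pairs"
                )
            frames[-1].parts.append(tok)
            i = j + 1
        elif c == "(":
            depth += 1
            frames[-1].parts.append(c)
            i += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(f"unbalanced ')' in {tagged!r}")
            while len(frames) > 1 and frames[-1].start_depth > depth:
                frames.pop()
            frames[-1].parts.append(c)
            i += 1
        elif c == ".":
            # component separator: no branch may span it
            while len(frames) > 1:
                frames.pop()
            frames[-1].parts.append(c)
            i += 1
        else:
            frames[-1].parts.append(c)
            i += 1
    if depth != 0:
        raise FormatError(f"unbalanced '(' in {tagged!r}")
    branches: list[tuple[str, str]] = []
    for frame in opened:
        body = "".join(frame.parts)
        if not body:
            raise FormatError(f"empty branch body after {frame.key} in {tagged!r}")
        branches.append((frame.key, body))  # type: ignore[arg-type]
    return "".join(frames[0].parts), branches


@dataclass
class FragmentIndex:
    """Seed array plus keyed branch pools, as used by the generator."""

    seeds: list[str] = field(default_factory=list)
    branches: dict[str, list[str]] = field(default_factory=dict)
    dialect: str = "smiles"

    def add_line(self, tagged: str) -> None:
        seed, branch_list = split_tagged(tagged)
        self.seeds.append(seed)
        for key, body in branch_list:
            self.branches.setdefault(key, []).append(body)

    def missing_keys(self) -> set[str]:
        """Keys referenced inside stored strings but absent from the pools.

        A non-empty result means generation can dead-end on those keys
        (it then resamples); typical for tiny corpora.
        """
        referenced: set[str] = set()
        for s in self.seeds:
            referenced.update(m.group(0) for m in TAG_PAIR_RE.finditer(s))
        for bodies in self.branches.values():
            for b in bodies:
                referenced.update(m.group(0) for m in TAG_PAIR_RE.finditer(b))
        return {k for k in referenced if not self.branches.get(k)}

    # -- optional line-oriented cache ------------------------------------

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#smifrag-index dialect={self.dialect}\n#seeds\n")
            for s in self.seeds:
                fh.write(s + "\n")
            fh.write("#branches\n")
            for key, bodies in self.branches.items():
                for b in bodies:
                    fh.write(f"{key}\t{b}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "FragmentIndex":
        idx = cls()
        section = None
        with open(path) as fh:
            header = fh.readline().strip()
            if header.startswith("#smifrag-index"):
                for part in header.split():
                    if part.startswith("dialect="):
                        idx.dialect = part.split("=", 1)[1]
            for line in fh:
                line = line.rstrip("\n")
                if line in ("#seeds", "#branches"):
                    section = line
                    continue
                if not line:
                    continue
                if section == "#seeds":
                    idx.seeds.append(line)
                else:
                    key, _, body = line.partition("\t")
                    idx.branches.setdefault(key, []).append(body)
        return idx


def _check_dialect(tagged: str, dialect: str) -> None:
    if dialect != "deepsmiles":
        return
    for tok in tokenize(tagged):
        if tok.kind == "ring" and ring_value(tok.text) < 3:
            raise FormatError(
                f"ring numeral {tok.text!r} in a deepsmiles file looks like a "
                f"SMILES ring label (sizes below 3 are impossible): {tagged!r}"
            )


def build_index(
    source: str | Path | Iterable[str], dialect: str = "smiles"
) -> FragmentIndex:
    """Build a :class:`FragmentIndex` from a tagged-fragments file.

    *source* may be a path or an iterable of lines.  Lines hold a tagged
    string and an optional whitespace-separated name; ``#`` comment
    lines and blanks are skipped.  Closure violations are logged as
    warnings, not raised — the generator resamples around them.
    """
    idx = FragmentIndex(dialect=dialect)
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tagged = line.split()[0]
        _check_dialect(tagged, dialect)
        try:
            idx.add_line(tagged)
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    missing = idx.missing_keys()
    if missing:
        log.warning(
            "index_closure_violation n_keys=%d keys=%s",
            len(missing),
            ",".join(sorted(missing)[:5]),
        )
    return idx
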