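"""SMILES <-> DeepSMILES, in the flavor without ring-opening numbers.

In this flavor a ring bond is written as a single numeral at the ring
*closing* atom, equal to the ring size: the closure bonds that atom to
the atom ``size - 1`` positions earlier in the linear atom sequence of
the string (branch atoms included in the count).  Benzene ``c1ccccc1``
becomes ``cccccc6``; branch parentheses are kept exactly as in SMILES,
so tagged fragments split the same way in both dialects.  Sizes of 10
or more are written ``%nn``.

Bracket atoms — including ``[x*]`` cleaved-bond tags — are ordinary
atoms to the codec and pass through untouched.
"""

from __future__ import annotations

from .tokens import FormatError, Token, ring_label_repr, ring_value, tokenize

__all__ = ["encode", "decode", "FormatError"]


def _size_repr(size: int) -> str:
    if size < 10:
        return str(size)
    if size < 100:
        return f"%{size}"
    raise FormatError(f"ring size {size} not representable (max 99)")


def encode(smiles: str) -> str:
    """Rewrite each SMILES ring-digit pair as a ring-size numeral."""
    toks = list(tokenize(smiles))
    out: dict[int, str] = {}
    open_rings: dict[int, tuple[int, int, int | None]] = {}
    atom_ord = -1
    for ti, tok in enumerate(toks):
        if tok.kind == "atom":
            atom_ord += 1
        elif tok.kind == "ring":
            label = ring_value(tok.text)
            bond_ti = ti - 1 if ti > 0 and toks[ti - 1].kind == "bond" else None
            if label in open_rings:
                o_atom, o_ti, o_bond_ti = open_rings.pop(label)
                size = atom_ord - o_atom + 1
                out[o_ti] = ""
                prefix = ""
                if o_bond_ti is not None:
                    out[o_bond_ti] = ""
                    if bond_ti is None:
                        # closure carries no bond symbol: move the
                        # opening side's symbol onto the numeral
                        prefix = toks[o_bond_ti].text
                out[ti] = prefix + _size_repr(size)
            else:
                open_rings[label] = (atom_ord, ti, bond_ti)
    if open_rings:
        raise FormatError(f"unbalanced ring digits in {smiles!r}")
    return "".join(out.get(i, t.text) for i, t in enumerate(toks))


def decode(deep: str) -> str:
    """Rewrite each ring-size numeral back into a SMILES digit pair."""
    toks = list(tokenize(deep))
    atom_tis: list[int] = []
    inserts: dict[int, list[str]] = {}
    replace: dict[int, str] = {}
    last_close: dict[int, int] = {}  # label -> atom ordinal of its last closure
    for ti, tok in enumerate(toks):
        if tok.kind == "atom":
            atom_tis.append(ti)
        elif tok.kind == "ring":
            size = ring_value(tok.text)
            if not atom_tis:
                raise FormatError(f"ring numeral before any atom in {deep!r}")
            cur = len(atom_tis) - 1
            target = cur - (size - 1)
            if size < 3 or target < 0:
                raise FormatError(
                    f"ring size {size} exceeds the available atoms in {deep!r}"
                )
            # smallest SMILES label whose previous use closed strictly
            # before the opening atom (labels are reusable sequentially)
            label = 1
            while last_close.get(label, -1) >= target:
                label += 1
            rep = ring_label_repr(label)
            last_close[label] = cur
            inserts.setdefault(atom_tis[target], []).append(rep)
            replace[ti] = rep
    parts: list[str] = []
    for ti, tok in enumerate(toks):
        parts.append(replace.get(ti, tok.text))
        if ti in inserts:
            parts.extend(inserts[ti])
    return "".join(parts)
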