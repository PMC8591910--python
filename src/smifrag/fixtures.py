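"""Deterministic synthetic training corpora for tests and demos.

Six molecule families are available: branched alkanes, ethers, amines,
substituted arenes, fused ring systems (including molecules with zero
cleavable bonds, which exercise the copied-as-is seed-only path) and
stereo-bearing molecules (which exercise the cleavage exclusions around
stereocenters and cis/trans bonds).  Sizes are drawn so molecular
weights land mostly in the 150-350 Da range typical of drug-like
training sets — large enough that the default 150 Da fragment weight
actually cuts them.

Every emitted string is checked against RDKit at build time, so a
fixture corpus always has validity 1.0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem

__all__ = ["FixtureSpec", "FAMILY_NAMES", "make_fixture", "write_fixture"]

_SEED_MOD = 2**31


def _alkane(rng: np.random.Generator) -> str:
    n = int(rng.integers(11, 21))
    atoms = ["C"] * n
    for _ in range(int(rng.integers(0, 3))):
        i = int(rng.integers(1, n - 1))
        atoms[i] = "C(C)"
    return "".join(atoms)


def _ether(rng: np.random.Generator) -> str:
    n = int(rng.integers(10, 19))
    atoms = ["C"] * n
    # 1-2 interior oxygens, never adjacent
    positions = list(range(2, n - 2, 2))
    k = min(int(rng.integers(1, 3)), len(positions))
    for i in rng.choice(len(positions), size=k, replace=False):
        atoms[positions[int(i)]] = "O"
    if rng.integers(2):
        i = int(rng.integers(1, n - 1))
        if atoms[i] == "C":
            atoms[i] = "C(C)"
    return "".join(atoms)


def _amine(rng: np.random.Generator) -> str:
    n = int(rng.integers(10, 19))
    atoms = ["C"] * n
    i = int(rng.integers(2, n - 2))
    atoms[i] = "N" if rng.integers(2) else "N(C)"
    if rng.integers(2):
        j = int(rng.integers(1, n - 1))
        if atoms[j].startswith("C"):
            atoms[j] = "C(C)"
    return "".join(atoms)


_ARENE_SUBS = ("CCCC", "CCCCCC", "CC(C)C", "CCOCC", "CCN(C)C", "OCC", "CCO", "CCNCC")
_ARENE_CORES = (
    "{a}c1ccccc1{b}",
    "{a}c1ccc({b})cc1",
    "{a}c1cccc({b})c1",
    "{a}c1ccc({b})nc1",
)


def _arene(rng: np.random.Generator) -> str:
    core = _ARENE_CORES[int(rng.integers(len(_ARENE_CORES)))]
    a = _ARENE_SUBS[int(rng.integers(len(_ARENE_SUBS)))]
    b = _ARENE_SUBS[int(rng.integers(len(_ARENE_SUBS)))]
    return core.format(a=a, b=b)


# plain fused systems have no acyclic single bond: zero cleavable bonds
_FUSED_PLAIN = (
    "c1ccc2ccccc2c1",          # naphthalene
    "C1CCC2CCCCC2C1",          # decalin
    "c1ccc2ncccc2c1",          # quinoline
    "c1ccc2[nH]ccc2c1",        # indole
    "c1ccc2c(c1)ccc1ccccc12",  # phenanthrene
)
_FUSED_SUBSTITUTED = (
    "CCCCc1ccc2ccccc2c1",
    "CCOCCc1ccc2ncccc2c1",
    "CCCCCCC1CCC2CCCCC2C1",
)


def _fused(rng: np.random.Generator) -> str:
    pool = _FUSED_PLAIN + _FUSED_SUBSTITUTED
    return pool[int(rng.integers(len(pool)))]


_STEREO = (
    "C/C=C/CCCCCCCC",
    "CCCCC/C=C\\CCCC",
    "CC[C@H](O)CCCCCCC",
    "CC[C@@H](N)CCCCCCC",
    "C[C@H](CCCC)c1ccccc1",
    "CC/C=C/CC[C@@H](C)CCC",
)


def _stereo(rng: np.random.Generator) -> str:
    return _STEREO[int(rng.integers(len(_STEREO)))]


_FAMILY_BUILDERS: dict[str, Callable[[np.random.Generator], str]] = {
    "alkanes": _alkane,
    "ethers": _ether,
    "amines": _amine,
    "arenes": _arene,
    "fused_rings": _fused,
    "stereo_bearing": _stereo,
}
FAMILY_NAMES = tuple(_FAMILY_BUILDERS)


@dataclass
class FixtureSpec:
    n_molecules: int
    families: Sequence[str] = FAMILY_NAMES
    rng_seed: int = 7

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        unknown = set(self.families) - set(FAMILY_NAMES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")
        if not self.families:
            raise ValueError("at least one family is required")


def make_fixture(spec: FixtureSpec) -> list[tuple[str, str]]:
    """Deterministic list of ``(smiles, name)`` records.

    Families are cycled round-robin; when ``fused_rings`` is requested
    the first fused molecule is forced to the zero-cleavable-bond pool.
    """
    families = list(spec.families)
    records: list[tuple[str, str]] = []
    fused_done = False
    for i in range(spec.n_molecules):
        fam = families[i % len(families)]
        rng = np.random.default_rng([spec.rng_seed % _SEED_MOD, i])
        if fam == "fused_rings" and not fused_done:
            smi = _FUSED_PLAIN[int(rng.integers(len(_FUSED_PLAIN)))]
            fused_done = True
        else:
            smi = _FAMILY_BUILDERS[fam](rng)
        assert Chem.MolFromSmiles(smi) is not None, f"builder emitted junk: {smi}"
        records.append((smi, f"{fam[:-1] if fam.endswith('s') else fam}_{i:04d}"))
    return records


def write_fixture(spec: FixtureSpec, path: str | Path) -> list[tuple[str, str]]:
    """Write the fixture as a SMILES file and return its records."""
    records = make_fixture(spec)
    with open(path, "w") as fh:
        for smi, name in records:
            fh.write(f"{smi}\t{name}\n")
    return records
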