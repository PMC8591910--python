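"""Cutting molecules into tagged (Deep)SMILES fragments.

Each training molecule is written as a randomized SMILES in which every
cut bond appears as an adjacent wildcard pair ``[x*][y*]``; the isotope
numbers ``x`` and ``y`` index an atom-type dictionary, so the pair
encodes the directed extended bond type of the bond it replaced.  The
number of cuts is driven by the molecule's weight: by default one cut
per 150 Da of molecular weight beyond the first fragment, i.e.
``round(MW/150) - 1`` cuts (never negative).  Molecules that cannot or
need not be cut are emitted untagged and become pure seed fragments.

Randomized (rather than canonical) SMILES are used so that repeated
passes over the same file, with different seeds, yield different
fragmentations of the same molecule: which fragment ends up as the
seed, and the direction each fragment is written in, both vary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from . import deepsmiles as dsm
from .atomtypes import AtomType, find_cleavable_bonds, type_atom
from .index import split_tagged
from .tokens import TAG_ATOM_RE, TAG_PAIR_RE

__all__ = [
    "AtomTypeDictionary",
    "FragmentationConfig",
    "recommended_fragment_count",
    "randomize_smiles",
    "tag_cleaved_bonds",
    "tagged_to_mixture",
    "read_smiles_file",
    "fragment_file",
]

log = logging.getLogger(__name__)

_SEED_MOD = 2**31  # keep derived seeds in the int32 range


class AtomTypeDictionary:
    """Append-only bijection between positive integers and atom types.

    Indices start at 1 because isotope 0 is indistinguishable from "no
    isotope" in SMILES output.
    """

    def __init__(self) -> None:
        self.forward: dict[int, AtomType] = {}
        self.reverse: dict[AtomType, int] = {}

    def index_of(self, atype: AtomType) -> int:
        """Return the index of *atype*, registering it if new."""
        idx = self.reverse.get(atype)
        if idx is None:
            idx = len(self.forward) + 1
            self.forward[idx] = atype
            self.reverse[atype] = idx
        return idx

    def __len__(self) -> int:
        return len(self.forward)

    def to_tsv(self, path: str | Path, metadata: str | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("# index\tpi\telement\theavy_degree\tformal_charge\n")
            if metadata:
                fh.write(f"# {metadata}\n")
            for idx in sorted(self.forward):
                t = self.forward[idx]
                fh.write(
                    f"{idx}\t{t.pi_electrons}\t{t.element}\t"
                    f"{t.heavy_degree}\t{t.formal_charge}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AtomTypeDictionary":
        d = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                idx, pi, el, h, f = line.split("\t")
                t = AtomType(int(pi), el, int(h), int(f))
                d.forward[int(idx)] = t
                d.reverse[t] = int(idx)
        return d


@dataclass
class FragmentationConfig:
    mean_fragment_weight: float = 150.0  # Da, a hint not a hard bound
    rng_seed: int = 12345
    passes: int = 1
    untyped_mode: bool = False  # negative control: every tag index is 1
    dialect: str = "smiles"

    def __post_init__(self) -> None:
        if self.mean_fragment_weight <= 0:
            raise ValueError("mean_fragment_weight must be positive")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")
        if self.dialect not in ("smiles", "deepsmiles"):
            raise ValueError(f"unknown dialect {self.dialect!r}")


def recommended_fragment_count(
    mol: Chem.Mol, mean_fragment_weight: float = 150.0
) -> int:
    """``round(MW / mean_fragment_weight)`` with half-to-even rounding.

    Results of 0 or 1 mean "do not cut".
    """
    if mean_fragment_weight <= 0:
        raise ValueError("mean_fragment_weight must be positive")
    return round(Descriptors.MolWt(mol) / mean_fragment_weight)


def randomize_smiles(mol: Chem.Mol, rng: np.random.Generator) -> str:
    """A randomized (non-canonical) SMILES of *mol*, driven by *rng*.

    Atoms are renumbered with a random permutation and the writer roots
    at the new first atom, so root choice and branch order both vary.
    Dummy atoms are never placed first (a wildcard root would separate
    a tag pair in the output).
    """
    n = mol.GetNumAtoms()
    if n == 1:
        return Chem.MolToSmiles(mol, canonical=False)
    order = [int(i) for i in rng.permutation(n)]
    if mol.GetAtomWithIdx(order[0]).GetAtomicNum() == 0:
        for j in range(1, n):
            if mol.GetAtomWithIdx(order[j]).GetAtomicNum() != 0:
                order[0], order[j] = order[j], order[0]
                break
    return Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)


def tag_cleaved_bonds(
    mol: Chem.Mol,
    n_cuts: int,
    dictionary: AtomTypeDictionary,
    rng: np.random.Generator,
    untyped_mode: bool = False,
) -> str:
    """Cut up to *n_cuts* cleavable bonds and return the tagged string.

    Bonds are drawn randomly without replacement; if fewer cleavable
    bonds exist than requested, all of them are cut.  Each cut bond
    u-v is replaced by the chain u-[x*]-[y*]-v where the wildcard
    bonded to u carries the dictionary index of type(v) (the dummy
    stands for the neighbor it replaces) and vice versa.  In untyped
    mode every index is 1, so any fragment can join any other.
    """
    if n_cuts <= 0:
        return randomize_smiles(mol, rng)
    cleavable = find_cleavable_bonds(mol)
    if not cleavable:
        return randomize_smiles(mol, rng)
    k = min(n_cuts, len(cleavable))
    chosen = [cleavable[int(i)] for i in rng.choice(len(cleavable), size=k, replace=False)]
    rw = Chem.RWMol(mol)
    for cb in chosen:
        u, v = cb.atom_index_u, cb.atom_index_v
        if untyped_mode:
            iso_u_side = iso_v_side = 1
        else:
            iso_u_side = dictionary.index_of(type_atom(mol, v))
            iso_v_side = dictionary.index_of(type_atom(mol, u))
        rw.RemoveBond(u, v)
        du = Chem.Atom(0)
        du.SetIsotope(iso_u_side)
        dv = Chem.Atom(0)
        dv.SetIsotope(iso_v_side)
        i_du = rw.AddAtom(du)
        i_dv = rw.AddAtom(dv)
        rw.AddBond(u, i_du, Chem.BondType.SINGLE)
        rw.AddBond(i_du, i_dv, Chem.BondType.SINGLE)
        rw.AddBond(i_dv, v, Chem.BondType.SINGLE)
    cut = rw.GetMol()
    Chem.SanitizeMol(cut)
    # The non-canonical writer keeps each dummy pair adjacent as long as
    # no dummy roots a traversal; verify and redraw on the rare miss
    # (multi-component inputs can root a later component at a dummy).
    for _ in range(20):
        smi = randomize_smiles(cut, rng)
        if (
            len(TAG_PAIR_RE.findall(smi)) == k
            and len(TAG_ATOM_RE.findall(smi)) == 2 * k
        ):
            return smi
    raise RuntimeError(f"could not write adjacent tag pairs for {Chem.MolToSmiles(mol)}")


def tagged_to_mixture(tagged: str) -> str:
    """Dot-separated mixture form, for 2D depiction of the fragments.

    Every fragment carries the full ``[x*][y*]`` pair at each of its cut
    points, so the mixture parses as a multi-component molecule.
    """
    seed, branches = split_tagged(tagged)
    return ".".join([seed] + [key + body for key, body in branches])


def read_smiles_file(path: str | Path) -> Iterator[tuple[str, str | None]]:
    """Yield ``(smiles, name)`` records; '#' comments and blanks skipped."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            yield parts[0], (parts[1].strip() if len(parts) > 1 else None)


def fragment_file(
    input_path: str | Path,
    output_path: str | Path,
    config: FragmentationConfig,
) -> dict:
    """Fragment every molecule of a SMILES file, one tagged line per pass.

    Duplicate fragments are retained (their multiplicity encodes natural
    frequency).  Unparseable records are logged and skipped, never
    fatal.  Writes the tagged fragments file plus the atom-type
    dictionary sidecar ``<output>.dict.tsv``.  Returns run statistics.
    """
    dictionary = AtomTypeDictionary()
    records = list(read_smiles_file(input_path))
    n_written = n_skipped = n_tags = 0
    with open(output_path, "w") as out:
        for p in range(config.passes):
            for r, (smi, name) in enumerate(records):
                rng = np.random.default_rng(
                    [config.rng_seed % _SEED_MOD, p, r]
                )
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    log.warning("parse_failure record=%d smiles=%s", r, smi)
                    n_skipped += 1
                    continue
                n_frags = recommended_fragment_count(
                    mol, config.mean_fragment_weight
                )
                tagged = tag_cleaved_bonds(
                    mol, n_frags - 1, dictionary, rng, config.untyped_mode
                )
                if config.dialect == "deepsmiles":
                    tagged = dsm.encode(tagged)
                n_tags += len(TAG_PAIR_RE.findall(tagged))
                out.write(tagged + (f"\t{name}" if name else "") + "\n")
                n_written += 1
    sidecar = str(output_path) + ".dict.tsv"
    dictionary.to_tsv(
        sidecar,
        metadata=(
            f"aromaticity=rdkit-default dialect={config.dialect} "
            f"untyped={config.untyped_mode} seed={config.rng_seed} "
            f"passes={config.passes} frag_weight={config.mean_fragment_weight}"
        ),
    )
    stats = {
        "molecules_read": len(records),
        "passes": config.passes,
        "fragments_written": n_written,
        "skipped": n_skipped,
        "tag_pairs": n_tags,
        "atom_types": len(dictionary),
        "dictionary_file": sidecar,
    }
    log.info(
        "fragment_file %s",
        " ".join(f"{k}={v}" for k, v in stats.items()),
    )
    return stats
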