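"""Molecule generation by Markov assembly of tagged fragments.

Assembly is purely string-level: draw a seed uniformly from the seed
array, then, while the string under construction contains a tag pair,
delete the leftmost pair and splice in a body drawn uniformly from the
pool filed under that pair.  Uniform draws over pools that keep
duplicates is exactly what matches fragment frequencies to the
training set.  Because every splice re-forms a single bond that was
legal in some training molecule, every finished string parses as a
valid molecule.

In the SMILES dialect a spliced body's ring labels are first rewritten
to labels not currently open at the splice point; the DeepSMILES
dialect has no ring labels to collide, so splicing is plain string
concatenation (the fast path).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .index import FragmentIndex
from .tokens import (
    TAG_PAIR_RE,
    FormatError,
    count_atoms,
    open_ring_labels,
    ring_label_repr,
    ring_value,
    tokenize,
)

__all__ = [
    "GenerationConfig",
    "GenerationRecord",
    "GenerationError",
    "renumber_rings",
    "generate_one",
    "generate_many",
    "generate_file",
]

log = logging.getLogger(__name__)

_SEED_MOD = 2**31


class GenerationError(RuntimeError):
    """Generation could not produce a molecule within the retry budget."""


@dataclass
class GenerationConfig:
    count: int
    rng_seed: int = 12345
    dialect: str = "smiles"
    max_replacements: int = 200   # growth guard: discard and resample
    max_heavy_atoms: int = 500    # ditto, approximate atom-token count

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.max_replacements < 1 or self.max_heavy_atoms < 1:
            raise ValueError("guards must be positive")
        if self.dialect not in ("smiles", "deepsmiles"):
            raise ValueError(f"unknown dialect {self.dialect!r}")


class GenerationRecord(NamedTuple):
    text: str
    n_replacements: int
    seed_ordinal: int


def renumber_rings(context: str, body: str) -> str:
    """Rewrite *body*'s ring labels to avoid those open in *context*.

    Labels are remapped to the smallest labels free at the splice point
    (minimizing ``%nn`` notation); the body's internal pairing is
    preserved, and a label freed by its own closure may be reused.
    """
    in_use = open_ring_labels(context)
    out: list[str] = []
    open_map: dict[int, int] = {}
    for tok in tokenize(body):
        if tok.kind != "ring":
            out.append(tok.text)
            continue
        label = ring_value(tok.text)
        if label in open_map:
            target = open_map.pop(label)
        else:
            target = 1
            taken = in_use.union(open_map.values())
            while target in taken:
                target += 1
            open_map[label] = target
        out.append(ring_label_repr(target))
    if open_map:
        raise FormatError(f"unbalanced ring labels in fragment body {body!r}")
    return "".join(out)


def generate_one(
    index: FragmentIndex,
    rng: np.random.Generator,
    max_replacements: int = 200,
    max_heavy_atoms: int = 500,
    max_retries: int = 100,
    stats: dict | None = None,
) -> GenerationRecord:
    """Assemble one molecule string from *index*.

    A missing branch key or a tripped growth guard discards the attempt
    and resamples from scratch; after *max_retries* failed attempts a
    :class:`GenerationError` is raised.
    """
    if not index.seeds:
        raise GenerationError("empty fragment index: no seed fragments")
    renumber = index.dialect == "smiles"
    for _ in range(max_retries):
        seed_ord = int(rng.integers(len(index.seeds)))
        s = index.seeds[seed_ord]
        n_rep = 0
        ok = True
        while True:
            m = TAG_PAIR_RE.search(s)
            if m is None:
                break
            bodies = index.branches.get(m.group(0))
            if not bodies:
                ok = False  # dead-end key: resample
                break
            body = bodies[int(rng.integers(len(bodies)))]
            if renumber:
                body = renumber_rings(s[: m.start()], body)
            s = s[: m.start()] + body + s[m.end() :]
            n_rep += 1
            if n_rep > max_replacements or count_atoms(s) > max_heavy_atoms:
                ok = False
                break
        if ok:
            return GenerationRecord(s, n_rep, seed_ord)
        if stats is not None:
            stats["resamples"] = stats.get("resamples", 0) + 1
    raise GenerationError(
        f"no valid assembly within {max_retries} attempts "
        "(dead-end keys or growth guards)"
    )


def generate_many(
    index: FragmentIndex, config: GenerationConfig, stats: dict | None = None
) -> list[GenerationRecord]:
    """Generate ``config.count`` records, one rng substream per record."""
    if index.dialect != config.dialect:
        raise ValueError(
            f"index dialect {index.dialect!r} != config dialect {config.dialect!r}"
        )
    records = []
    base = config.rng_seed % _SEED_MOD
    for ordinal in range(config.count):
        rng = np.random.default_rng([base, ordinal])
        records.append(
            generate_one(
                index,
                rng,
                max_replacements=config.max_replacements,
                max_heavy_atoms=config.max_heavy_atoms,
                stats=stats,
            )
        )
    return records


def generate_file(
    index: FragmentIndex, config: GenerationConfig, output_path: str | Path
) -> dict:
    """Write ``config.count`` generated molecule strings, one per line.

    Output is bit-identical across runs for a fixed seed.
    """
    stats: dict = {"resamples": 0}
    records = generate_many(index, config, stats=stats)
    with open(output_path, "w") as fh:
        for rec in records:
            fh.write(rec.text + "\n")
    result = {
        "generated": len(records),
        "resamples": stats["resamples"],
        "mean_replacements": (
            float(np.mean([r.n_replacements for r in records])) if records else 0.0
        ),
        "dialect": config.dialect,
    }
    log.info(
        "generate_file %s", " ".join(f"{k}={v}" for k, v in result.items())
    )
    return result
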