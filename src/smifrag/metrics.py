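"""Distribution-learning metrics for a (training set, generated set) pair.

Covers the standard generator report card: validity (fraction of
strings RDKit parses), uniqueness (distinct canonical SMILES among
valid records), novelty (distinct valid canonicals absent from the
training set), Bemis-Murcko scaffold counts and intersections, the
per-descriptor histogram Jaccard index

    J(X, Y) = sum_i min(X_i, Y_i) / sum_i max(X_i, Y_i)

and a KL-divergence score: the mean over descriptors of
``exp(-KL(train || generated))`` on discretized descriptor
distributions, a fraction in (0, 1] where 1 means identical
distributions.  The descriptor space is eight-dimensional: molecular
weight, cLogP, aromatic ring count, TPSA, rotatable bond count,
synthetic accessibility score, H-bond acceptors and donors.

The Fréchet ChemNet Distance is not computed (it needs pretrained
ChemNet weights) and is reported as such.
"""

from __future__ import annotations

import logging
import math
import os
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, NamedTuple, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy.stats import entropy

# validity() deliberately feeds RDKit unparseable strings; silence the
# per-record parser noise.
RDLogger.DisableLog("rdApp.error")

__all__ = [
    "Histogram",
    "ScaffoldReport",
    "MetricsReport",
    "validity",
    "uniqueness",
    "novelty",
    "scaffold_report",
    "jaccard",
    "shared_edges",
    "descriptor_profile",
    "jaccard_profile",
    "kl_score",
    "write_histograms",
    "compute_report",
    "DESCRIPTOR_NAMES",
    "INTEGER_DESCRIPTORS",
]

log = logging.getLogger(__name__)

DESCRIPTOR_NAMES = (
    "mol_weight",
    "clogp",
    "aromatic_rings",
    "tpsa",
    "rotatable_bonds",
    "sa_score",
    "hba",
    "hbd",
)
# count-valued descriptors get unit-width integer bins
INTEGER_DESCRIPTORS = frozenset(
    {"aromatic_rings", "rotatable_bonds", "hba", "hbd"}
)

_sascorer = None


def _sa_score(mol: Chem.Mol) -> float:
    global _sascorer
    if _sascorer is None:
        from rdkit.Chem import RDConfig

        sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
        import sascorer  # noqa: PLC0415

        _sascorer = sascorer
    return _sascorer.calculateScore(mol)


_DESCRIPTOR_FUNCS: dict[str, Callable[[Chem.Mol], float]] = {
    "mol_weight": Descriptors.MolWt,
    "clogp": Crippen.MolLogP,
    "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "rotatable_bonds": rdMolDescriptors.CalcNumRotatableBonds,
    "sa_score": _sa_score,
    "hba": rdMolDescriptors.CalcNumHBA,
    "hbd": rdMolDescriptors.CalcNumHBD,
}


class Histogram(NamedTuple):
    bin_edges: np.ndarray
    counts: np.ndarray


@dataclass
class ScaffoldReport:
    unique_a: int
    unique_b: int
    intersection: int
    percent_new_b: float  # percent of B's scaffolds absent from A


@dataclass
class MetricsReport:
    validity: float
    uniqueness: float
    novelty: float
    scaffolds: ScaffoldReport
    jaccard_per_descriptor: dict[str, float]
    jaccard_mean: float
    kl_score: float
    kl_per_descriptor: dict[str, float]
    fcd: str = "not computed"
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "validity": self.validity,
            "uniqueness": self.uniqueness,
            "novelty": self.novelty,
            "scaffolds": vars(self.scaffolds),
            "jaccard_per_descriptor": self.jaccard_per_descriptor,
            "jaccard_mean": self.jaccard_mean,
            "kl_score": self.kl_score,
            "kl_per_descriptor": self.kl_per_descriptor,
            "fcd": self.fcd,
            "metadata": self.metadata,
        }


def _canonicalize(smiles_list: Sequence[str]) -> list[str]:
    """Canonical SMILES of the parseable records, in order."""
    out = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is not None:
            out.append(Chem.MolToSmiles(mol))
    return out


def validity(generated: Sequence[str]) -> float:
    """Fraction of strings that parse into valid molecules."""
    if not generated:
        raise ValueError("validity of an empty set is undefined")
    ok = sum(1 for s in generated if Chem.MolFromSmiles(s) is not None)
    return ok / len(generated)


def uniqueness(generated: Sequence[str]) -> float:
    """Distinct canonical forms among valid records / valid records."""
    if not generated:
        raise ValueError("uniqueness of an empty set is undefined")
    canon = _canonicalize(generated)
    if not canon:
        raise ValueError("no valid records: uniqueness undefined")
    return len(set(canon)) / len(canon)


def novelty(generated: Sequence[str], training: Sequence[str]) -> float:
    """Fraction of distinct valid generated molecules absent from training."""
    if not generated or not training:
        raise ValueError("novelty needs non-empty generated and training sets")
    gen = set(_canonicalize(generated))
    if not gen:
        raise ValueError("no valid records: novelty undefined")
    train = set(_canonicalize(training))
    return len(gen - train) / len(gen)


def _scaffold(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    # acyclic molecules share the empty-scaffold sentinel class
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def scaffold_report(set_a: Sequence[str], set_b: Sequence[str]) -> ScaffoldReport:
    """Unique Bemis-Murcko scaffold counts of two sets and their overlap."""
    sc_a = {s for s in (_scaffold(x) for x in set_a) if s is not None}
    sc_b = {s for s in (_scaffold(x) for x in set_b) if s is not None}
    inter = len(sc_a & sc_b)
    new_b = len(sc_b - sc_a)
    pct = 100.0 * new_b / len(sc_b) if sc_b else 0.0
    return ScaffoldReport(len(sc_a), len(sc_b), inter, pct)


def jaccard(x: Histogram, y: Histogram) -> float:
    """Histogram overlap: sum of bin minima over sum of bin maxima."""
    if not np.array_equal(x.bin_edges, y.bin_edges):
        raise ValueError("histograms must share bin edges")
    lo = np.minimum(x.counts, y.counts).sum()
    hi = np.maximum(x.counts, y.counts).sum()
    if hi == 0:
        return 1.0  # two empty histograms are identical
    return float(lo) / float(hi)


def shared_edges(
    a: np.ndarray, b: np.ndarray, bins: int = 20, integer_valued: bool = False
) -> np.ndarray:
    """Bin edges spanning the pooled min-max of two samples.

    Count-valued descriptors get unit-width bins centered on integers;
    a degenerate (single-valued) pooled sample gets one unit-wide bin.
    """
    lo = min(np.min(a), np.min(b))
    hi = max(np.max(a), np.max(b))
    if integer_valued:
        return np.arange(math.floor(lo) - 0.5, math.ceil(hi) + 1.5, 1.0)
    if lo == hi:
        return np.linspace(lo - 0.5, hi + 0.5, bins + 1)
    return np.linspace(lo, hi, bins + 1)


def descriptor_profile(smiles_list: Sequence[str]) -> dict[str, np.ndarray]:
    """The eight descriptor vectors, one entry per (computable) molecule."""
    if not smiles_list:
        raise ValueError("descriptor profile of an empty set is undefined")
    values: dict[str, list[float]] = {name: [] for name in DESCRIPTOR_NAMES}
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        try:
            row = {n: f(mol) for n, f in _DESCRIPTOR_FUNCS.items()}
        except Exception:  # descriptor failure: skip the record
            log.warning("descriptor_failure smiles=%s", s)
            continue
        for n, v in row.items():
            values[n].append(float(v))
    return {n: np.asarray(v, dtype=float) for n, v in values.items()}


def kl_score(
    train_profile: dict[str, np.ndarray],
    gen_profile: dict[str, np.ndarray],
    bins: int = 20,
    smoothing: float = 1e-10,
) -> tuple[float, dict[str, float]]:
    """Mean over descriptors of ``exp(-KL(train || generated))``.

    Both samples are discretized on shared bins; *smoothing* probability
    mass is added per bin after normalization (then renormalized) so a
    bin empty on one side never yields an infinite divergence.
    """
    per: dict[str, float] = {}
    for name in DESCRIPTOR_NAMES:
        t, g = train_profile[name], gen_profile[name]
        if t.size == 0 or g.size == 0:
            raise ValueError(f"empty sample for descriptor {name}")
        edges = shared_edges(t, g, bins, name in INTEGER_DESCRIPTORS)
        p = np.histogram(t, bins=edges)[0].astype(float)
        q = np.histogram(g, bins=edges)[0].astype(float)
        p = p / p.sum() + smoothing
        q = q / q.sum() + smoothing
        per[name] = float(np.exp(-entropy(p / p.sum(), q / q.sum())))
    return float(np.mean(list(per.values()))), per


def jaccard_profile(
    train_profile: dict[str, np.ndarray],
    gen_profile: dict[str, np.ndarray],
    bins: int = 20,
) -> dict[str, float]:
    """Per-descriptor histogram Jaccard on shared pooled-range bins.

    Histograms are normalized to frequencies first, so sets of unequal
    size are comparable; when both sets have the same size this equals
    the raw bin-count Jaccard.
    """
    out = {}
    for name in DESCRIPTOR_NAMES:
        t, g = train_profile[name], gen_profile[name]
        edges = shared_edges(t, g, bins, name in INTEGER_DESCRIPTORS)
        tc = np.histogram(t, bins=edges)[0].astype(float)
        gc = np.histogram(g, bins=edges)[0].astype(float)
        if tc.sum() > 0:
            tc /= tc.sum()
        if gc.sum() > 0:
            gc /= gc.sum()
        out[name] = jaccard(Histogram(edges, tc), Histogram(edges, gc))
    return out


def compute_report(
    training: Sequence[str],
    generated: Sequence[str],
    bins: int = 20,
    smoothing: float = 1e-10,
    metadata: dict | None = None,
) -> MetricsReport:
    """Full report for a (training, generated) pair of SMILES lists."""
    val = validity(generated)
    uniq = uniqueness(generated)
    nov = novelty(generated, training)
    scaf = scaffold_report(training, generated)
    t_prof = descriptor_profile(training)
    g_prof = descriptor_profile(generated)
    jac = jaccard_profile(t_prof, g_prof, bins)
    kl, kl_per = kl_score(t_prof, g_prof, bins, smoothing)
    meta = {"bins": bins, "kl_smoothing": smoothing}
    if metadata:
        meta.update(metadata)
    return MetricsReport(
        validity=val,
        uniqueness=uniq,
        novelty=nov,
        scaffolds=scaf,
        jaccard_per_descriptor=jac,
        jaccard_mean=float(np.mean(list(jac.values()))),
        kl_score=kl,
        kl_per_descriptor=kl_per,
        metadata=meta,
    )


def write_histograms(
    train_profile: dict[str, np.ndarray],
    gen_profile: dict[str, np.ndarray],
    out_dir: str | Path,
    bins: int = 20,
) -> None:
    """One TSV per descriptor (bin_lo, bin_hi, train, generated) for plotting."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in DESCRIPTOR_NAMES:
        t, g = train_profile[name], gen_profile[name]
        edges = shared_edges(t, g, bins, name in INTEGER_DESCRIPTORS)
        tc = np.histogram(t, bins=edges)[0]
        gc = np.histogram(g, bins=edges)[0]
        with open(out_dir / f"{name}.tsv", "w") as fh:
            fh.write("bin_lo\tbin_hi\ttrain\tgenerated\n")
            for i in range(len(tc)):
                fh.write(f"{edges[i]:g}\t{edges[i+1]:g}\t{tc[i]}\t{gc[i]}\n")
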