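"""String-level assembly: splicing, ring renumbering, guards, determinism."""

import itertools

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import Descriptors

from smifrag.fragment import (
    AtomTypeDictionary,
    recommended_fragment_count,
    tag_cleaved_bonds,
    tagged_to_mixture,
)
from smifrag.generate import (
    GenerationConfig,
    GenerationError,
    generate_file,
    generate_many,
    generate_one,
    renumber_rings,
)
from smifrag.index import FragmentIndex, build_index
from smifrag.tokens import FormatError


def test_single_path_reconstructs_ethanol(rng):
    idx = build_index(["O[2*][1*]CC"])
    for _ in range(5):
        rec = generate_one(idx, rng)
        assert Chem.CanonSmiles(rec.text) == "CCO"
        assert rec.n_replacements == 1


def test_untagged_seeds_are_echoed(rng):
    idx = build_index(["CCO", "c1ccccc1"])
    seen = {generate_one(idx, rng).text for _ in range(50)}
    assert seen == {"CCO", "c1ccccc1"}


def test_every_reachable_assembly_is_valid():
    """Brute force over all seed x body draws on a two-molecule toy index."""
    idx = build_index(["CCOC[1*][2*]CC(C)O", "CCC[1*][2*]c1ccc(CC)cc1"])
    for seed, body in itertools.product(
        idx.seeds, idx.branches["[1*][2*]"]
    ):
        assembled = seed.replace("[1*][2*]", body)
        assert Chem.MolFromSmiles(assembled) is not None


@pytest.mark.parametrize(
    "context,body,expected",
    [
        ("C1CC(", "C1CCCCC1", "C2CCCCC2"),   # label 1 open at splice point
        ("CCC(", "CCN", "CCN"),               # no ring digits: unchanged
        ("C1CC2CC3CC4CC5CC6CC7CC8CC9CC(", "C1CC1", "C%10CC%10"),  # overflow
        ("C1CC1C(", "C1CC1", "C1CC1"),        # label 1 closed again: reusable
        ("C1CC(", "C1CC1C1CC1", "C2CC2C2CC2"),  # sequential reuse in body
    ],
)
def test_renumber_rings(context, body, expected):
    assert renumber_rings(context, body) == expected


def test_renumber_rings_rejects_unbalanced_body():
    with pytest.raises(FormatError):
        renumber_rings("CC(", "C1CC")


def test_ring_collision_splices_reparse_with_both_ring_systems():
    cases = [
        ("C1CC(", ")CCC1", "C1CCCCC1", {6, 6}),
        ("C1CC2CC3CC4CC5CC6CC7CC8CC9CC(", ")CC9CC8CC7CC6CC5CC4CC3CC2CC1",
         "C1CC1", {3, 5, 6}),
    ]
    for ctx, tail, body, must_have in cases:
        spliced = ctx + renumber_rings(ctx, body) + tail
        mol = Chem.MolFromSmiles(spliced)
        assert mol is not None, spliced
        sizes = {len(r) for r in mol.GetRingInfo().AtomRings()}
        assert must_have <= sizes


def test_missing_key_resamples_then_errors(rng):
    # only seed references a key with an empty pool: generation dead-ends
    idx = FragmentIndex(seeds=["C[7*][8*]"], branches={})
    with pytest.raises(GenerationError):
        generate_one(idx, rng, max_retries=5)
    # with an untagged alternative seed, resampling succeeds
    idx2 = FragmentIndex(seeds=["C[7*][8*]", "CCO"], branches={})
    stats: dict = {}
    rec = generate_one(idx2, np.random.default_rng(0), stats=stats)
    assert rec.text == "CCO"


def test_growth_guard_discards_runaway_assemblies(rng):
    # self-referential body: every replacement spawns a new tag
    idx = FragmentIndex(
        seeds=["C[1*][2*]C"], branches={"[1*][2*]": ["C[1*][2*]C"]}
    )
    with pytest.raises(GenerationError):
        generate_one(idx, rng, max_replacements=10, max_retries=3)


def test_generate_file_bit_identical_runs(fragments_file, tmp_path):
    idx = build_index(fragments_file)
    cfg = GenerationConfig(count=500, rng_seed=2)
    a, b = tmp_path / "a.smi", tmp_path / "b.smi"
    generate_file(idx, cfg, a)
    generate_file(idx, cfg, b)
    assert a.read_text() == b.read_text()
    assert len(a.read_text().splitlines()) == 500


def test_generation_config_validation():
    with pytest.raises(ValueError):
        GenerationConfig(count=0)
    with pytest.raises(ValueError):
        GenerationConfig(count=1, max_replacements=0)
    with pytest.raises(ValueError):
        GenerationConfig(count=1, dialect="selfies")


def test_mass_consistency_with_mixture_oracle(fixture_corpus):
    """MW of a reassembled molecule equals the sum over its mixture fragments.

    Wildcard atoms are massless and suppress one implicit hydrogen on
    each attachment atom, so fragment weights add up exactly.
    """
    for i, (smiles, _) in enumerate(fixture_corpus[:30]):
        mol = Chem.MolFromSmiles(smiles)
        n = recommended_fragment_count(mol) - 1
        if n < 1:
            continue
        tagged = tag_cleaved_bonds(
            mol, n, AtomTypeDictionary(), np.random.default_rng(i)
        )
        total = sum(
            Descriptors.MolWt(Chem.MolFromSmiles(frag))
            for frag in tagged_to_mixture(tagged).split(".")
        )
        assert total == pytest.approx(Descriptors.MolWt(mol), abs=1e-6)


def test_seed_ordinal_provenance(fragments_file):
    idx = build_index(fragments_file)
    recs = generate_many(idx, GenerationConfig(count=50, rng_seed=4))
    for rec in recs:
        assert 0 <= rec.seed_ordinal < len(idx.seeds)
        assert "*" not in rec.text
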