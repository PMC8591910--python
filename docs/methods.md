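# Methods

## Model

The generator learns nothing parametric: its "model" is the fragment
library itself. Training molecules are cut at typed acyclic single
bonds; each cut is recorded in place, inside a randomized SMILES, as an
adjacent wildcard pair `[x*][y*]` whose isotope numbers index an
atom-type dictionary. Generation is a Markov chain over strings: draw a
seed fragment uniformly, then repeatedly replace the leftmost tag pair
with a uniformly drawn branch body filed under that exact literal key,
until no tags remain. Two design facts carry the statistical weight:

- **Typed keys restrict joins.** A branch body is only ever spliced
  where a bond of the same directed extended type was cut in the
  training set, so local chemistry around every formed bond is
  training-set chemistry, and every output parses (validity 1).
- **Duplicates are frequencies.** Fragment pools keep duplicates, and
  draws are uniform over pool entries, so common fragments are spliced
  proportionally often. Deduplicating the pools would destroy the
  distribution matching and must not be done.

### Atom and bond typing

`type(a) = (π, e, h, f)`: π-electron count, element, heavy-neighbor
count, formal charge. The π count is 1 for any aromatic atom, otherwise
the sum over the atom's bonds of (order − 1) (double +1, triple +2),
the classic atom-pair convention. Stereochemistry never enters a type.
Bond types are the directed triple `(type(u), order, type(v))`;
direction is kept — a key and its reverse index separate pools, and
both orientations arise naturally because randomized SMILES write each
bond in either direction across passes.

### Cleavable bonds

Single, acyclic, heavy–heavy, with neither endpoint carrying a
specified tetrahedral tag and no cis/trans direction mark on the bond.
Unspecified/implicit stereocenters do not block cleavage; the intent is
to preserve *specified* stereochemistry inside fragments. Bonds to
explicit hydrogens are never cleavable. Aromaticity is RDKit's default
perception at parse time (recorded in the dictionary sidecar); any
single perception model works as long as fragmentation and generation
share it, since key matching is literal.

### Cut-count heuristic

`num_frags = round(MW / w)` with half-to-even rounding and
`w = 150 Da` by default; `num_frags ≤ 1` means "do not cut" and the
molecule is emitted as an untagged seed (fused-ring-only molecules can
then be copied as-is into the output — an accepted property of the
method). If fewer cleavable bonds exist than requested, all are cut.
The weight is a hint only; actual fragment masses scatter around it.

## Tagging and splitting mechanics

A cut bond u–v is realized in the molecular graph as u–[x\*]–[y\*]–v
(the wildcard bonded to u carries the dictionary index of `type(v)`:
the dummy stands for the neighbor it replaces). Writing the edited
molecule as a randomized SMILES then yields the in-place tagged form;
because each dummy has degree 2, the pair is always written adjacently
unless a dummy roots the traversal, which the writer avoids (and
verifies, redrawing in the rare multi-component corner case).

Splitting respects branch-nesting depth: the seed is the prefix with
every tag pair left in place; a branch body starts after a pair and
ends where the nesting depth would drop below its starting depth (or at
end of string). Nested pairs spawn nested branches; a body containing
further pairs stays filed under its *first* pair only. This yields
exactly one branch body per tag pair, the invariant the index tests
assert.

Randomized SMILES are produced by renumbering atoms with a seeded
permutation and writing non-canonically (rooted at the new first atom).
This keeps all randomness in the package's own NumPy generators: every
stage derives per-record streams from `(seed, pass, record)` or
`(seed, ordinal)`, so outputs are bit-reproducible and independent of
parallelization or call order.

## Generation details

- **Replacement order** is leftmost-first. With independent uniform
  draws the order does not bias the sampled distribution; leftmost
  makes replay deterministic.
- **Ring renumbering** (SMILES dialect): labels open in the string
  before the splice point are computed by toggling; body labels are
  remapped to the smallest free labels, reusing labels freed by their
  own closure, which minimizes `%nn` notation. More than 99
  simultaneously open rings is a capacity error. The DeepSMILES dialect
  skips this step entirely.
- **Guards.** Branch bodies may carry further tags, so runaway growth
  is possible in principle (it is subcritical on realistic corpora
  because mean tags-per-body < 1). `max_replacements` (default 200) and
  `max_heavy_atoms` (default 500, counted as atom tokens) trip a
  discard-and-resample; a missing key (possible when an index is built
  from hand-edited or truncated files) likewise resamples. After 100
  failed attempts generation raises rather than loops.

## DeepSMILES codec

Only the flavor *without ring-opening numbers* is implemented; branch
parentheses are retained, so the nesting-depth splitter works unchanged
on either dialect. A ring is written as a single numeral at the closing
atom whose value is 1 + the distance (in atoms, counted along the
string, branch atoms included) back to the opening atom: benzene
`c1ccccc1` ↔ `cccccc6`. Values ≥ 10 use `%nn`. Decoding assigns SMILES
labels greedily, reusing a label only when its previous pair closed
strictly before the new opening atom. Bracket atoms — including tag
pairs — pass through untouched. Whole tagged strings are converted
before splitting; since rings never straddle fragments, per-fragment
and whole-string conversion agree.

## Metrics

Validity = fraction of generated strings RDKit parses. Uniqueness and
novelty are computed over canonical SMILES of the *valid* records only
(invalid strings are already penalized by validity). Scaffolds are
Bemis-Murcko; acyclic molecules share an empty-scaffold sentinel class.
The descriptor space is eight-dimensional: molecular weight, cLogP,
aromatic ring count, TPSA, rotatable bonds, synthetic accessibility
score, H-bond acceptors, H-bond donors.

Histograms for the Jaccard index `J = Σ min(Xᵢ,Yᵢ) / Σ max(Xᵢ,Yᵢ)` and
the KL score use shared edges spanning the pooled min–max of the two
samples: 20 bins by default for continuous descriptors, unit-width
integer bins for count descriptors. The per-descriptor Jaccard profile
normalizes each histogram to frequencies first so sets of unequal size
are comparable (for equal-size sets this equals the raw-count value).
The KL score is the mean over descriptors of `exp(−KL(train‖gen))`
after adding 1e-10 probability mass per bin (then renormalizing), so
empty bins never produce infinities; the score is stable under halving
the smoothing constant when the generated support covers the training
support. The Fréchet ChemNet Distance requires pretrained network
weights and is reported as "not computed".

## Synthetic corpora

The fixture generator emits six families — branched alkanes, ethers,
amines, substituted arenes, fused ring systems, stereo-bearing
molecules — cycled round-robin, each record built from its own
`(seed, index)` RNG stream and validated against RDKit at build time.
Sizes are drawn so molecular weights land mostly in 150–350 Da (the
drug-like range), which guarantees the default 150 Da fragment weight
actually cuts most molecules. The fused-ring family always includes at
least one molecule with zero cleavable bonds (exercising the seed-only
path); the stereo family exercises the cleavage exclusions.

What these corpora emulate — and what they do not: they cover the
syntactic and combinatorial space (branches, rings, fused systems,
heteroatoms, stereo marks; formal charges are absent) well enough to
exercise every code path, but they are far smaller and chemically far narrower
than real libraries. Passing tests therefore demonstrate correctness of
the machinery (validity, reconstruction, determinism, metric
definitions) and the *direction* of the typing effect, not the absolute
uniqueness/novelty/KL values reported on 100k-molecule drug libraries,
which depend on corpus size and diversity.

## Problem sizes

The test suite and the acceptance script run at deliberately small
scale as the package's own default study conditions: 100-molecule
training corpora, 10,000-molecule generation runs for the validity
check, 1,000-molecule round-trip corpora for the codec, 200/2,000
molecules for the typed-vs-untyped comparison. Validity is scale-free
(it holds per record); the comparative metrics at this scale are
directional, as discussed above.

## Known limitations

- The method never creates new ring systems; scaffold novelty on small
  corpora is near zero.
- Uniqueness degrades on tiny fragment pools (the sampler repeats
  itself); this is a property of the corpus, not a defect.
- Cleaving next to (but not at) stereo features can still leave a
  direction mark whose partner bond ends up in another fragment;
  cut-adjacent stereo is excluded, but exotic multi-center stereo is
  not specially handled beyond RDKit's own semantics.
- The dialect-mixing check on declared DeepSMILES files is heuristic
  (ring numerals 1 and 2 are impossible sizes); full validation happens
  at decode time.
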