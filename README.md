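# caenophylo

Comparative analyses on the phylogeny of the nematode genus *Caenorhabditis*:
parsimony mapping of phenotypic characters, ITS2 barcode-gap analysis with
explicit indel handling, and maximum-likelihood divergence estimation on a
fixed topology. The package is aimed at evolutionary biologists who work with
the 26 cultured *Caenorhabditis* species (and their growing strain
collections) and want the classic desk analyses — "how many steps does this
character need on the tree?", "is ITS2 a safe barcode for my isolates?",
"how divergent are these two species?" — as reproducible, scriptable code
rather than a chain of manual GUI operations.

## What it computes

**Character evolution (parsimony).** For a discrete character with states
observed at the tips of a rooted tree, the minimum number of state changes is
computed by the Fitch/Sankoff dynamic programme: for node *v* and state *s*,

    C_v(s) = Σ_{u ∈ children(v)} min_t [ c(s,t) + C_u(t) ]

with cost matrix `c` (unit costs by default; e.g. transversions may be
weighted twice transitions). Ambiguous most-parsimonious reconstructions are
resolved by ACCTRAN — changes are placed as close to the root as possible —
with a documented deterministic tie-break. On top of this the package counts
constrained hypotheses, e.g. "the derived state arose exactly once"
(one gain plus the minimal number of reversals below it) or "the root state
is fixed" (competence present in the stem species).

**ITS2 barcode gap.** Pairwise differences between aligned strain sequences
are tabulated as transitions (A↔G, C↔T), transversions, and indel *events* —
one event per gap run regardless of its length, with shared-gap columns
removed first. A strain tree constrained by the species topology carries
integer parsimony branch lengths (substitutions plus indel characters,
ACCTRAN-optimised), and the barcode-gap report compares each species'
largest intra-specific distance with its smallest distance to any other
species, flagging violations.

**Genetic divergence (GTR+Γ+I).** Log-likelihoods are computed by
Felsenstein pruning under the general time-reversible model with
discrete-gamma rate variation (equal-probability categories, category-mean
rates) and a proportion of invariant sites. Branch lengths on the fixed
topology are optimised by exact per-branch coordinate ascent; pairwise
divergences are patristic distances in expected substitutions/site.

**Simulators.** Seeded generators for characters on trees, GTR+Γ+I sequence
evolution with insertions/deletions, and multi-strain panels (Yule-shaped
strain subtrees grafted onto species tips) provide ground-truth event logs
for every pipeline stage.

The 26-species topology and a phenotypic character matrix (reproductive
mode, spicule and male-tail morphology, RNAi competence, …) ship with the
package as fixtures: `load_fixture_tree("caenorhabditis26")` (or
`"caenorhabditis26+outgroup"` with a *Protorhabditis*-like outgroup tip) and
`load_fixture_characters()`.

## Worked example

```sh
caenophylo map-characters --tree caenorhabditis26+outgroup \
    --chars fixture --out report.tsv
```

`report.tsv` (first columns):

```
character            steps  min_steps  homoplasy  n_gains  n_losses
reproductive_mode    3      1          True       3        0
spicule_tip          3      1          True       1        2
dorsal_ray_position  2      1          True       1        1
short_ray4           3      1          True       1        2
rnai_competence      4      1          True       4        0
```

Reproductive mode needs three steps — self-fertile hermaphroditism arose
independently on the terminal branches to *C. elegans*, *C. briggsae* and
*C.* sp. 11 — and is homoplasious (one step would suffice if the character
had a unique origin on the tree). The spicule tip shows one gain of the
simple state and two reversals to the complex state (*C. japonica*,
*C.* sp. 7).

```sh
caenophylo constrained-origin --tree caenorhabditis26+outgroup \
    --chars fixture --character reproductive_mode \
    --derived-state hermaphroditic --out origin.tsv
```

```
character          derived_state   unconstrained_steps  single_origin_steps
reproductive_mode  hermaphroditic  3                    6
```

A single origin of hermaphroditism would require six steps (one gain and
five reversals to gonochorism), twice the convergent scenario.

Other subcommands: `pairwise-diff`, `trim`, `barcode-gap`, `strain-lengths`,
`divergence`, and `simulate characters|alignment|strains`. All reports are
TSV with a `#` header recording version, configuration and seed; `--json`
writes a machine-readable twin.

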