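# Methods

This note documents the models, conventions and design choices behind the
package, in the order of the pipeline stages.

## Tree model and fixtures

Trees are rooted, with named tips, optional non-negative branch lengths and
arbitrary polytomies. Node identifiers are assigned in deterministic preorder
at parse time; every tie-breaking rule below is expressed in terms of these
identifiers, so results are reproducible across runs and platforms. Child
order in Newick is preserved on round-trip but carries no meaning: all
algorithms are invariant to it (tested).

The packaged 26-species *Caenorhabditis* topology encodes the genus
relationships used throughout: *C.* sp. 1 branches first, then *C. plicata*;
the remaining species form the Elegans super-group (Elegans group +
*C.* sp. 15 + Japonica group) and the Drosophilae super-group
(*C.* sp. 20, (*C.* sp. 6, *C.* sp. 13), Drosophilae group + Angaria group).
Where the published narrative under-determines internal structure, the
resolution was chosen as the unique arrangement consistent with every
published character step count; the trio *C.* sp. 17/18/19 is resolved as
(17,(18,19)) purely for determinism — all packaged characters have identical
lengths under either resolution. The `+outgroup` variant adds a single
*Protorhabditis*-like tip carrying the outgroup character states, which is
how reconstructions are rooted; unrooted analyses are expressed through it.

The character matrix re-encodes reproductive mode, spicule morphology
(overall shape, blade curvature, tip), male-tail fan characters (shape,
anterior closure, edge serration, terminal notch, ray-2/3 spacing, dorsal
ray position, short ray 4, precloacal lip), phasmid form, mating position
and RNAi competence. Missing or unreported states are `?` (notably RNAi
competence for *C.* sp. 1 and the outgroup). `?` is treated as the full
state set — the standard Fitch missing-data convention — and never enlarges
a character's alphabet.

## Parsimony machinery

All parsimony operations run on a single Sankoff dynamic programme. Unit
costs reproduce Fitch lengths (the unit-cost recursion is the polytomy-safe
generalisation of the Fitch set operations); arbitrary cost matrices support
weighted analyses such as transversions = 2 × transitions.

**ACCTRAN as an exact optimisation.** Rather than a second-pass heuristic,
the DP operates on lexicographic cost triples
`(total cost, Σ depth(change branch), Σ preorder id(change branch))`.
Because lexicographic order on ℝ³ is compatible with componentwise addition,
the usual Sankoff recursion remains valid, and the backtrack yields the
reconstruction that (1) is most parsimonious, (2) among those, minimises the
summed root-distance of its changes — the accelerated-transformation
preference for early changes and reversals over parallel late gains — and
(3) among those, has the smallest preorder-id sum. Property tests verify
against exhaustive enumeration that the result is always in the MP set and
optimal under this ordering. The ordering is this package's precise
definition of ACCTRAN tie-breaking; other implementations leave the
convention unspecified.

**Constrained counts.** The single-origin count places the unique gain of
the derived state on each branch of the root path of the derived tips' MRCA
in turn; below the gain, a loss-only cost matrix (gain cost ∞) counts
reversals; the minimum over placements plus one is reported. Root-state
constraints simply fix the root row of the DP. One consequence worth noting:
with the root fixed to a state observed in no tip of a uniform character,
the minimum is the number of root children (every root-adjacent branch must
change), not 1.

## ITS2 differences and indel coding

Pairwise difference classification follows hand-tabulation practice:

* columns where both sequences are gapped are removed first;
* remaining one-sided gap columns are grouped into maximal runs by which
  sequence is gapped — each run is one indel event, so a run interrupted
  only by the partner's overlapping gap stays a single event, while adjacent
  runs gapped in opposite sequences are two events (one insertion per
  lineage);
* base–base columns count as transition (A↔G, C↔T) or transversion;
  columns involving IUPAC ambiguity codes are never guessed — they are
  skipped and tallied separately.

The barcode-gap verdict uses the combined event count
(substitutions + indel events, one per gap run); both components are also
reported so substitution-only thresholds can be applied. A species with at
least two strains is flagged when its largest intra-specific distance
reaches its smallest inter-specific distance.

Marker trimming locates two conserved anchor motifs (defaults: the 3' end of
the 5.8S rRNA and the 5' start of the LSU rRNA flanking ITS2) in a reference
row, skipping that row's gaps, with a configurable mismatch tolerance
(default 2), and returns the columns strictly between the matches.

**Constrained strain tree.** Each species tip of the backbone topology is
expanded into a resolved subtree of its strains: exhaustive search over all
rooted resolutions per species (feasible to 7 strains, (2k−3)!! shapes),
greedy stepwise addition beyond, scored by total parsimony length over all
variable alignment columns plus all indel presence/absence characters
(simple indel coding: one binary character per distinct maximal gap-run
coordinate pair). Ties break by the deterministic enumeration order, which
follows lexicographic strain order — a documented rule in place of the
published analysis' unstated manual choice among equally parsimonious trees.
Branch lengths are ACCTRAN change counts summed over characters, so the
tree length equals the sum of per-character parsimony lengths.

## GTR+Γ+I likelihood and branch lengths

The rate matrix is built from exchangeabilities (AC, AG, AT, CG, CT relative
to GT = 1) and stationary frequencies, normalised to one expected
substitution per unit time at stationarity; gamma rate variation uses k
equal-probability categories with category-mean rates (k = 4 by default,
25 when mirroring the published setting), renormalised to mean 1; a site
contributes the invariant-mixture term only when some base is compatible
with every row. Gaps and ambiguity codes are missing data (partial
likelihood 1 for compatible bases). Likelihoods are computed by pruning over
compressed site patterns with the symmetric eigendecomposition of the
reversible rate matrix, so `P(t)` costs one matrix reconstruction per
branch/category.

Branch-length optimisation is exact coordinate ascent: a recursive traversal
keeps subtree ("below") and rest-of-tree ("above") partials current at every
branch — a subtree's partials are refreshed after its branches are updated,
and the above context is propagated through each branch's *current* length —
so each bounded scalar search (Brent, bounds [1e-8, 10], default parameter
estimates via Nelder–Mead in log/logit space with alternating branch-length
rounds) maximises the true likelihood in that coordinate and sweeps are
monotone. Convergence is declared when a sweep improves the log-likelihood
by less than `tol` (default 1e-6); exceeding `max_sweeps` raises an error
carrying the best tree so far. With a reversible model and a bifurcating
root, only the *sum* of the two root-adjacent branch lengths is identified;
recovery checks therefore compare those two branches as a sum.

Branch lengths and patristic distances are reported in expected
substitutions per site over the variable fraction, matching the
"substitutions/site" convention of likelihood phylograms.

## Simulators

* **Characters**: symmetric-rates Markov chain from a uniform root state;
  `rate` is events per unit branch length; every event is logged per branch.
  Parsimony length is a lower bound on logged events (tested over hundreds
  of seeds).
* **Sequences**: per-site rates drawn from the same discrete-gamma
  categories the likelihood uses (plus zero-rate invariant sites with
  probability p_inv); substitutions evolve by vectorised Gillespie
  simulation, which matches `exp(Qt)` marginals and yields true per-branch
  event counts. Indels occur as a Poisson process per branch (rate = events
  per unit branch length for the whole sequence), insertion:deletion 1:1,
  geometric lengths (default mean 3); insertions create fresh columns placed
  into a global column ordering, so the returned alignment is the true one.
* **Strain panels**: Yule-shaped subtrees (uniform random tip splits) with
  Exp(intra_scale) branch lengths grafted onto each species tip; one
  alignment is then simulated on the grafted tree. Only the intra/inter
  scale contrast matters for barcode-gap behaviour, which is why the subtree
  shape is deliberately generic.

Everything derives from one `numpy.random.default_rng(seed)`; identical
seeds give bit-identical outputs.

What the simulators do **not** emulate: rate heterotachy, selection,
coalescent population structure within species, alignment error, and the
ITS2 repeat polymorphisms seen in real strains (the *C.* sp. 8
imperfect-repeat region, within-animal ITS1 variation). Passing synthetic
tests therefore demonstrates algorithmic correctness under the stated
models, not robustness to those real-data complications.

## Problem sizes and numerical choices

Property tests compare against exhaustive oracles where enumeration is
feasible: parsimony on ≤ 8 tips/≤ 3 states (hundreds of random instances),
likelihood on ≤ 5 tips summed over all internal assignments and categories
(1e-8 agreement), two-tip Jukes–Cantor MLE against the closed-form distance
(1e-6). Branch-length recovery uses 50 kb simulated on the 26-species
topology with truth lengths drawn once from Exp(mean 0.05) clamped at 0.005
— a realistic scale for this clade's phylograms — and checks identifiable
branches ≥ 0.01 to 10% relative error. Barcode-gap closure uses twenty
seeded panels alternating clearly-clean (intra scale 0.002) and
deliberately-broken (0.07, at the species-separation scale) gaps; on broken
panels the species-level attribution of a borderline violation can
legitimately differ between the event-count ground truth and the observed
differences (superimposed changes), so clean panels require exact agreement
and all panels require verdict agreement.

The two checks against the published reference alignments (ITS2 strain
panel; RNAP2 partition) run only when those datasets are supplied under
`data/reference/`; the file names and formats are given in the test
docstrings.

## Known limitations

* Parsimony reconstructions report one optimal labeling; no DELTRAN, no
  enumeration of all MP reconstructions, no stochastic character mapping.
* Likelihood machinery estimates branch lengths and substitution parameters
  on a fixed topology only — no tree search, bootstrap or Bayesian sampling;
  base frequencies are empirical, not ML-estimated.
* The strain-tree search optimises species subtrees sequentially against the
  current resolution of the others; with many similarly-scored resolutions
  this is a heuristic, though exhaustive within each species clade.
* Partial likelihoods are unscaled; fine for trees of this size (tens of
  tips), not for hundreds of taxa.
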