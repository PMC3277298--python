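"""ITS2 barcode analysis: difference tabulation, indel coding, parsimony
branch lengths on a species-constrained strain tree, and the barcode-gap
report.

Distance convention
-------------------
A pairwise distance is the number of substitution differences plus the number
of indel *events* (one change per gap run, regardless of its length). Columns
where both sequences are gapped are removed before run detection, so a gap
run interrupted only by the partner's overlapping gap still counts as a
single event; adjacent runs gapped in opposite sequences count as two events
(one insertion in each lineage). Columns involving IUPAC ambiguity codes are
not guessed: they are skipped for the transition/transversion tally and
reported separately.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .charmap import (
    MISSING,
    CharacterMatrix,
    acctran,
    fitch_length,
)
from .trees import Node, PhyloTree

__all__ = [
    "Alignment",
    "DiffSummary",
    "BarcodeGapReport",
    "read_fasta_alignment",
    "trim_to_marker",
    "pairwise_differences",
    "all_pairwise",
    "indel_characters",
    "strain_tree_branch_lengths",
    "barcode_gap_report",
    "read_species_map",
]

GAP = "-"
BASES = set("ACGT")
AMBIG = set("RYSWKMBDHVN")
ALPHABET = BASES | AMBIG | {GAP}
PURINES = set("AG")

# default ITS2 anchors: conserved motifs at the 3' end of 5.8S and the 5' end
# of LSU rRNA in the C. elegans rRNA repeat annotation; configurable because
# primer/trim conventions differ between labs
DEFAULT_ANCHOR5 = "GCTGCGTTATTTACCACGAATTGCAGACGC"
DEFAULT_ANCHOR3 = "TTGACCTCAGATCAGACGTGG"


@dataclass
class Alignment:
    """Equal-length DNA rows (uppercase, gaps '-') with unique labels."""

    labels: list[str]
    rows: dict[str, str]

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")
        lengths = {len(self.rows[lab]) for lab in self.labels}
        if len(lengths) > 1:
            raise ValueError(f"rows of unequal length: {sorted(lengths)}")
        for lab in self.labels:
            seq = self.rows[lab].upper().replace("U", "T")
            bad = set(seq) - ALPHABET
            if bad:
                raise ValueError(f"illegal characters in {lab!r}: {sorted(bad)}")
            self.rows[lab] = seq

    @property
    def n_columns(self) -> int:
        return len(self.rows[self.labels[0]]) if self.labels else 0

    def __len__(self) -> int:
        return len(self.labels)

    def subset_columns(self, start: int, end: int) -> "Alignment":
        """Half-open column interval [start, end)."""
        return Alignment(
            labels=list(self.labels),
            rows={lab: self.rows[lab][start:end] for lab in self.labels},
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for lab in self.labels:
                fh.write(f">{lab}\n{self.rows[lab]}\n")


def read_fasta_alignment(path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    labels = [r.id for r in records]
    return Alignment(labels=labels, rows={r.id: str(r.seq) for r in records})


def read_species_map(path) -> dict[str, str]:
    """TSV with columns (strain, species); '#' comments ignored."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed species-map line: {line!r}")
            if parts[0] == "strain" and parts[1] == "species":
                continue  # header
            out[parts[0]] = parts[1]
    return out


# -- trimming -----------------------------------------------------------------


def _degap_with_columns(row: str) -> tuple[str, list[int]]:
    seq, cols = [], []
    for i, ch in enumerate(row):
        if ch != GAP:
            seq.append(ch)
            cols.append(i)
    return "".join(seq), cols


def _find_motif(seq: str, motif: str, max_mismatch: int, start: int = 0) -> int:
    """First index >= start where motif matches with <= max_mismatch mismatches."""
    m = len(motif)
    for i in range(start, len(seq) - m + 1):
        mism = 0
        for a, b in zip(seq[i : i + m], motif):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        if mism <= max_mismatch:
            return i
    return -1


def trim_to_marker(
    aln: Alignment,
    anchor5: str = DEFAULT_ANCHOR5,
    anchor3: str = DEFAULT_ANCHOR3,
    max_mismatch: int = 2,
    reference: Optional[str] = None,
) -> Alignment:
    """Cut the alignment down to the columns strictly between two conserved
    anchor motifs located in a reference row (gaps in that row are skipped
    while matching)."""
    if not anchor5 or not anchor3:
        raise ValueError("anchors must be non-empty")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    ref_label = reference if reference is not None else aln.labels[0]
    if ref_label not in aln.rows:
        raise KeyError(f"reference row {ref_label!r} not in alignment")
    anchor5, anchor3 = anchor5.upper(), anchor3.upper()
    seq, cols = _degap_with_columns(aln.rows[ref_label])

    i5 = _find_motif(seq, anchor5, max_mismatch)
    if i5 < 0:
        raise ValueError(f"5' anchor {anchor5!r} not found in {ref_label!r}")
    i3 = _find_motif(seq, anchor3, max_mismatch, start=i5 + len(anchor5))
    if i3 < 0:
        raise ValueError(
            f"3' anchor {anchor3!r} not found downstream of the 5' anchor"
        )
    start_col = cols[i5 + len(anchor5) - 1] + 1  # first column after anchor5
    end_col = cols[i3]  # first column of anchor3 (exclusive bound)
    return aln.subset_columns(start_col, end_col)


# -- pairwise differences -----------------------------------------------------


@dataclass(frozen=True)
class DiffSummary:
    transitions: int
    transversions: int
    indel_events: int
    both_gap_columns: int
    compared_columns: int
    ambiguous_columns: int

    @property
    def substitutions(self) -> int:
        return self.transitions + self.transversions

    @property
    def total(self) -> int:
        """Combined event count: substitutions + indel events."""
        return self.substitutions + self.indel_events


def pairwise_differences(a: str, b: str) -> DiffSummary:
    """Classify the differences between two aligned sequences.

    See the module docstring for the run/ambiguity conventions.
    """
    a, b = a.upper().replace("U", "T"), b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")

    ts = tv = ambig = both_gap = indels = 0
    prev_gap_side = None  # 'a', 'b' or None for the previous kept column
    compared = 0
    for ca, cb in zip(a, b):
        if ca == GAP and cb == GAP:
            both_gap += 1
            continue  # dropped before run detection
        compared += 1
        if ca == GAP or cb == GAP:
            side = "a" if ca == GAP else "b"
            if side != prev_gap_side:
                indels += 1
            prev_gap_side = side
            continue
        prev_gap_side = None
        if ca not in BASES or cb not in BASES:
            ambig += 1
            continue
        if ca != cb:
            if (ca in PURINES) == (cb in PURINES):
                ts += 1
            else:
                tv += 1
    return DiffSummary(
        transitions=ts,
        transversions=tv,
        indel_events=indels,
        both_gap_columns=both_gap,
        compared_columns=compared,
        ambiguous_columns=ambig,
    )


def all_pairwise(aln: Alignment) -> pd.DataFrame:
    """DiffSummary for every unordered pair of rows, as a tidy table."""
    if len(aln) < 2:
        raise ValueError("need at least two sequences")
    rows = []
    for la, lb in itertools.combinations(aln.labels, 2):
        d = pairwise_differences(aln.rows[la], aln.rows[lb])
        rows.append(
            {
                "strain_a": la,
                "strain_b": lb,
                "transitions": d.transitions,
                "transversions": d.transversions,
                "substitutions": d.substitutions,
                "indel_events": d.indel_events,
                "ambiguous": d.ambiguous_columns,
                "compared_columns": d.compared_columns,
            }
        )
    return pd.DataFrame(rows)


# -- indel coding -------------------------------------------------------------


def _gap_runs(row: str) -> list[tuple[int, int]]:
    """Maximal gap runs as half-open (start, end) column intervals."""
    runs = []
    start = None
    for i, ch in enumerate(row):
        if ch == GAP:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(row)))
    return runs


def indel_characters(aln: Alignment) -> CharacterMatrix:
    """Simple indel coding: one binary presence/absence character per distinct
    maximal gap-run coordinate pair; a row is 'present' iff it has a maximal
    gap run with exactly those coordinates."""
    run_sets = {lab: set(_gap_runs(aln.rows[lab])) for lab in aln.labels}
    all_runs = sorted(set().union(*run_sets.values())) if run_sets else []
    characters = [f"indel_{s}_{e}" for s, e in all_runs]
    cells = {}
    for lab in aln.labels:
        for (s, e), name in zip(all_runs, characters):
            cells[(lab, name)] = "present" if (s, e) in run_sets[lab] else "absent"
    return CharacterMatrix(taxa=list(aln.labels), characters=characters, cells=cells)


# -- constrained strain tree --------------------------------------------------


def _substitution_columns(aln: Alignment) -> list[dict[str, str]]:
    """Per-column character maps; gaps and ambiguity codes become missing."""
    cols = []
    for i in range(aln.n_columns):
        col = {}
        for lab in aln.labels:
            ch = aln.rows[lab][i]
            col[lab] = ch if ch in BASES else MISSING
        states = {v for v in col.values() if v != MISSING}
        if len(states) >= 2:  # only variable columns can contribute steps
            cols.append(col)
    return cols


def _parsimony_characters(aln: Alignment) -> list[dict[str, str]]:
    chars = _substitution_columns(aln)
    indels = indel_characters(aln)
    for name in indels.characters:
        chars.append(indels.column(name))
    return chars


def _rooted_topologies(leaves: Sequence[str]):
    """All rooted binary leaf-labelled shapes, as nested tuples; (2k-3)!! of
    them, generated deterministically by inserting leaves in the given order."""
    leaves = list(leaves)
    if len(leaves) == 1:
        yield leaves[0]
        return

    def insert_everywhere(tree, leaf):
        # replace any subtree s by (s, leaf)
        yield (tree, leaf)
        if isinstance(tree, tuple):
            left, right = tree
            for t in insert_everywhere(left, leaf):
                yield (t, right)
            for t in insert_everywhere(right, leaf):
                yield (left, t)

    def build(current, remaining):
        if not remaining:
            yield current
            return
        head, rest = remaining[0], remaining[1:]
        for t in insert_everywhere(current, head):
            yield from build(t, rest)

    yield from build(leaves[0], leaves[1:])


def _tuple_to_node(shape) -> Node:
    if isinstance(shape, str):
        return Node(id=-1, label=shape)
    node = Node(id=-1)
    for part in shape:
        child = _tuple_to_node(part)
        child.parent = node
        node.children.append(child)
    return node


def _clone_node(n: Node) -> Node:
    new = Node(id=-1, label=n.label, length=n.length)
    for c in n.children:
        cc = _clone_node(c)
        cc.parent = new
        new.children.append(cc)
    return new


def _stepwise_addition_shape(leaves: Sequence[str], score) -> tuple:
    """Greedy stepwise addition for species with many strains."""
    current = (leaves[0], leaves[1])
    for leaf in leaves[2:]:
        candidates = []

        def insert_everywhere(tree, leaf):
            yield (tree, leaf)
            if isinstance(tree, tuple):
                left, right = tree
                for t in insert_everywhere(left, leaf):
                    yield (t, right)
                for t in insert_everywhere(right, leaf):
                    yield (left, t)

        for cand in insert_everywhere(current, leaf):
            candidates.append((score(cand), cand))
        current = min(candidates, key=lambda x: x[0])[1]
    return current


def strain_tree_branch_lengths(
    species_tree: PhyloTree,
    species_map: Mapping[str, str],
    aln: Alignment,
    max_exhaustive: int = 7,
) -> PhyloTree:
    """Expand each species tip into its most-parsimonious strain subtree and
    assign integer parsimony branch lengths (substitutions + indel events,
    ACCTRAN-resolved ambiguity).

    The species topology acts as a backbone constraint. For species with at
    most ``max_exhaustive`` strains every rooted resolution is scored
    exhaustively; larger species use stepwise addition. Ties are broken by the
    deterministic enumeration order, which follows lexicographic strain order.
    """
    strains_by_species: dict[str, list[str]] = {}
    for strain in aln.labels:
        if strain not in species_map:
            raise KeyError(f"strain {strain!r} not in species map")
        strains_by_species.setdefault(species_map[strain], []).append(strain)
    for sp in strains_by_species:
        strains_by_species[sp].sort()

    species_tips = set(species_tree.tip_labels)
    unknown = set(strains_by_species) - species_tips
    if unknown:
        raise KeyError(f"species not in tree: {sorted(unknown)}")
    empty = species_tips - set(strains_by_species)
    if empty:
        raise ValueError(f"species without strains: {sorted(empty)}")

    characters = _parsimony_characters(aln)

    def build_tree(shapes: dict[str, object]) -> PhyloTree:
        root = _clone_node(species_tree.root)
        tree = PhyloTree(root)
        for tip in list(tree.tips):
            sp = tip.label
            shape = shapes[sp]
            sub = _tuple_to_node(shape)
            if tip.is_root:
                tree = PhyloTree(sub)
            else:
                parent = tip.parent
                idx = parent.children.index(tip)
                sub.parent = parent
                parent.children[idx] = sub
        return PhyloTree(tree.root)

    def total_length(tree: PhyloTree) -> int:
        total = 0
        for col in characters:
            states = {col.get(lab, MISSING) for lab in tree.tip_labels}
            states.discard(MISSING)
            if len(states) < 2:
                continue
            total += fitch_length(tree, {lab: col.get(lab, MISSING) for lab in tree.tip_labels})
        return total

    # initial shapes: sorted caterpillars
    def caterpillar(leaves):
        if len(leaves) == 1:
            return leaves[0]
        shape = (leaves[0], leaves[1])
        for leaf in leaves[2:]:
            shape = (shape, leaf)
        return shape

    shapes = {sp: caterpillar(strains_by_species[sp]) for sp in strains_by_species}

    # optimise each multi-strain species in species-tree tip order
    for sp in species_tree.tip_labels:
        strains = strains_by_species[sp]
        if len(strains) < 2:
            continue
        if len(strains) <= max_exhaustive:
            best_score, best_shape = None, None
            for cand in _rooted_topologies(strains):
                trial = dict(shapes)
                trial[sp] = cand
                score = total_length(build_tree(trial))
                if best_score is None or score < best_score:
                    best_score, best_shape = score, cand
            shapes[sp] = best_shape
        else:

            def score_fn(cand):
                trial = dict(shapes)
                trial[sp] = cand
                return total_length(build_tree(trial))

            shapes[sp] = _stepwise_addition_shape(strains, score_fn)

    final = build_tree(shapes)

    # ACCTRAN branch lengths: changes per branch summed over characters
    per_branch = {n.id: 0 for n in final.nodes}
    for col in characters:
        full_col = {lab: col.get(lab, MISSING) for lab in final.tip_labels}
        states = {v for v in full_col.values() if v != MISSING}
        if len(states) < 2:
            continue
        rec = acctran(final, full_col)
        for ev in rec.events:
            per_branch[ev.node_id] += 1
    for node in final.nodes:
        if not node.is_root:
            node.length = float(per_branch[node.id])
    final.length_unit = "steps"
    return final


# -- barcode gap --------------------------------------------------------------


@dataclass
class BarcodeGapReport:
    """Within- vs between-species ITS2 distance summary."""

    intra: pd.DataFrame  # species, n_strains, max_substitutions, max_indels, max_total
    inter: pd.DataFrame  # species_a, species_b, min_substitutions, min_indels, min_total
    violations: list[str] = field(default_factory=list)


def barcode_gap_report(
    diffs: pd.DataFrame, species_map: Mapping[str, str]
) -> BarcodeGapReport:
    """Summarise a pairwise difference table into the barcode-gap verdict.

    A species (with >= 2 strains) violates the barcode gap when its largest
    intra-specific combined distance (substitutions + indel events) is at
    least as large as its smallest combined distance to any other species.
    """
    diffs = diffs.copy()
    for col in ("strain_a", "strain_b"):
        missing = set(diffs[col]) - set(species_map)
        if missing:
            raise KeyError(f"strains not in species map: {sorted(missing)}")
    diffs["species_a"] = diffs["strain_a"].map(species_map)
    diffs["species_b"] = diffs["strain_b"].map(species_map)
    diffs["total"] = diffs["substitutions"] + diffs["indel_events"]

    intra_rows = []
    strains_per_species: dict[str, set] = {}
    for _, r in diffs.iterrows():
        strains_per_species.setdefault(r.species_a, set()).add(r.strain_a)
        strains_per_species.setdefault(r.species_b, set()).add(r.strain_b)

    intra_mask = diffs.species_a == diffs.species_b
    for sp, grp in diffs[intra_mask].groupby("species_a"):
        intra_rows.append(
            {
                "species": sp,
                "n_strains": len(strains_per_species[sp]),
                "max_substitutions": int(grp.substitutions.max()),
                "max_indels": int(grp.indel_events.max()),
                "max_total": int(grp.total.max()),
            }
        )
    intra = pd.DataFrame(
        intra_rows,
        columns=["species", "n_strains", "max_substitutions", "max_indels", "max_total"],
    )

    inter_rows = []
    inter_df = diffs[~intra_mask].copy()
    pair_key = inter_df.apply(
        lambda r: tuple(sorted((r.species_a, r.species_b))), axis=1
    )
    if len(inter_df):
        inter_df["pair"] = pair_key
        for (sa, sb), grp in inter_df.groupby("pair"):
            inter_rows.append(
                {
                    "species_a": sa,
                    "species_b": sb,
                    "min_substitutions": int(grp.substitutions.min()),
                    "min_indels": int(grp.indel_events.min()),
                    "min_total": int(grp.total.min()),
                }
            )
    inter = pd.DataFrame(
        inter_rows,
        columns=["species_a", "species_b", "min_substitutions", "min_indels", "min_total"],
    )

    violations = []
    for _, row in intra.iterrows():
        sp = row.species
        others = inter[(inter.species_a == sp) | (inter.species_b == sp)]
        if len(others) and row.max_total >= others.min_total.min():
            violations.append(sp)
    return BarcodeGapReport(intra=intra, inter=inter, violations=sorted(violations))
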