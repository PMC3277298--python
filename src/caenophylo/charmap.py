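"""Discrete-character parsimony mapping on a fixed phylogeny.

Implements the machinery used to trace phenotypic characters (reproductive
mode, male-tail and spicule morphology, RNAi competence, ...) over the
Caenorhabditis tree:

* minimum-step (Fitch) character length, via unit-cost dynamic programming
  that also handles polytomies and missing data,
* general cost-matrix (Sankoff) parsimony, e.g. transversions weighted twice
  transitions,
* ACCTRAN-resolved most-parsimonious reconstructions with explicit per-branch
  change events,
* single-origin constrained counting (one gain of a derived state plus the
  minimum number of reversals below it),
* root-state-constrained reconstructions (e.g. RNAi competence assumed present
  in the stem species).

ACCTRAN determinism
-------------------
Among all most-parsimonious reconstructions, the one returned minimises, in
lexicographic order, (total cost, sum of root-distances of change branches,
sum of preorder ids of change branches). Minimising the summed root-distance
pushes changes toward the root — the accelerated-transformation convention —
and the preorder-id term makes the remaining ties deterministic. The dynamic
program works directly on these lexicographic cost triples, so the chosen
reconstruction is exactly optimal under this ordering, not a heuristic.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import pandas as pd

from .trees import Node, PhyloTree

__all__ = [
    "MISSING",
    "CharacterMatrix",
    "Reconstruction",
    "ChangeEvent",
    "CostMatrix",
    "read_character_matrix",
    "load_fixture_characters",
    "fitch_length",
    "sankoff",
    "acctran",
    "count_events",
    "constrained_single_origin_steps",
    "root_constrained_reconstruction",
    "map_all_characters",
]

MISSING = "?"

Column = Mapping[str, str]


# -- data types ---------------------------------------------------------------


@dataclass
class CharacterMatrix:
    """Taxa x discrete characters; '?' denotes missing/inapplicable."""

    taxa: list[str]
    characters: list[str]
    cells: dict[tuple[str, str], str]

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in character matrix")
        if len(set(self.characters)) != len(self.characters):
            raise ValueError("duplicate character names")

    def column(self, character: str) -> dict[str, str]:
        if character not in self.characters:
            raise KeyError(f"unknown character {character!r}")
        return {t: self.cells[(t, character)] for t in self.taxa}

    def alphabet(self, character: str) -> list[str]:
        """Observed non-missing state tokens, sorted."""
        return sorted(
            {v for v in self.column(character).values() if v != MISSING}
        )


@dataclass(frozen=True)
class ChangeEvent:
    """A state change on the branch subtending ``node_id``."""

    node_id: int
    branch_label: Optional[str]  # tip label if the branch leads to a tip
    from_state: str
    to_state: str


@dataclass
class Reconstruction:
    """Per-node states of one most-parsimonious reconstruction."""

    states: dict[int, str]
    events: list[ChangeEvent]
    total_steps: float

    def count(self, from_state: str, to_state: str) -> int:
        return sum(
            1
            for e in self.events
            if e.from_state == from_state and e.to_state == to_state
        )


class CostMatrix:
    """Square non-negative change-cost table with zero diagonal."""

    def __init__(self, states: Sequence[str], costs: Mapping[tuple[str, str], float]):
        self.states = list(states)
        self._costs = dict(costs)
        for s in self.states:
            self._costs.setdefault((s, s), 0.0)
        for (a, b), c in self._costs.items():
            if c < 0:
                raise ValueError(f"negative cost for {a}->{b}")
            if a == b and c != 0:
                raise ValueError("diagonal costs must be zero")

    def cost(self, a: str, b: str) -> float:
        try:
            return self._costs[(a, b)]
        except KeyError:
            raise KeyError(f"state pair ({a!r}, {b!r}) not in cost matrix") from None

    @classmethod
    def unit(cls, states: Sequence[str]) -> "CostMatrix":
        return cls(
            states,
            {(a, b): 0.0 if a == b else 1.0 for a in states for b in states},
        )

    @classmethod
    def dna_ts_tv(cls, ts: float = 1.0, tv: float = 2.0) -> "CostMatrix":
        """Nucleotide costs with transversions weighted relative to transitions."""
        purines = {"A", "G"}
        bases = "ACGT"

        def c(a, b):
            if a == b:
                return 0.0
            same_class = (a in purines) == (b in purines)
            return ts if same_class else tv

        return cls(list(bases), {(a, b): c(a, b) for a in bases for b in bases})


# -- I/O ----------------------------------------------------------------------


def read_character_matrix(path) -> CharacterMatrix:
    """Read a TSV character matrix (taxon rows, character columns)."""
    with open(path, newline="") as fh:
        return _parse_matrix(fh)


def _parse_matrix(fh) -> CharacterMatrix:
    rows = [r for r in csv.reader(fh, delimiter="\t")
            if r and not r[0].startswith("#")]
    if not rows:
        raise ValueError("empty character matrix")
    header = rows[0]
    characters = header[1:]
    taxa, cells = [], {}
    for r in rows[1:]:
        if len(r) != len(header):
            raise ValueError(
                f"ragged row for taxon {r[0]!r}: {len(r)} fields, expected {len(header)}"
            )
        taxon = r[0]
        if taxon in taxa:
            raise ValueError(f"duplicate taxon {taxon!r}")
        taxa.append(taxon)
        for ch, tok in zip(characters, r[1:]):
            cells[(taxon, ch)] = tok
    return CharacterMatrix(taxa=taxa, characters=characters, cells=cells)


def load_fixture_characters() -> CharacterMatrix:
    """The packaged phenotypic character matrix for the 26 species + outgroup."""
    ref = resources.files("caenophylo") / "data" / "characters.tsv"
    import io

    return _parse_matrix(io.StringIO(ref.read_text()))


# -- Sankoff core -------------------------------------------------------------

# Costs inside the DP are lexicographic triples; see module docstring.
_INF = (math.inf, 0.0, 0.0)


def _t_add(a, b):
    return (a[0] + b[0], a[1] + b[1], a[2] + b[2])


def _depths(tree: PhyloTree) -> dict[int, int]:
    d = {tree.root.id: 0}
    for node in tree.preorder():
        for c in node.children:
            d[c.id] = d[node.id] + 1
    return d


def _check_column(tree: PhyloTree, column: Column) -> None:
    for lab in tree.tip_labels:
        if lab not in column:
            raise KeyError(f"tip {lab!r} absent from character matrix")


def _sankoff_engine(
    tree: PhyloTree,
    column: Column,
    costs: CostMatrix,
    root_state: Optional[str] = None,
) -> Reconstruction:
    """Exact DP over lexicographic cost triples; returns the ACCTRAN-resolved
    optimal reconstruction (optionally with the root state fixed)."""
    _check_column(tree, column)
    states = costs.states
    observed = {v for v in column.values() if v != MISSING}
    unknown = observed - set(states)
    if unknown:
        raise KeyError(f"states not in cost matrix: {sorted(unknown)}")
    depth = _depths(tree)

    table: dict[int, dict[str, tuple]] = {}
    for node in tree.postorder():
        if node.is_tip:
            tok = column[node.label]
            table[node.id] = {
                s: (0.0, 0.0, 0.0) if tok in (MISSING, s) else _INF
                for s in states
            }
            continue
        row = {}
        for s in states:
            total = (0.0, 0.0, 0.0)
            for child in node.children:
                best = _INF
                for t in states:
                    step = costs.cost(s, t)
                    penalty = (
                        (step, float(depth[child.id]), float(child.id))
                        if s != t
                        else (0.0, 0.0, 0.0)
                    )
                    cand = _t_add(penalty, table[child.id][t])
                    if cand < best:
                        best = cand
                total = _t_add(total, best)
            row[s] = total
        table[node.id] = row

    root_row = table[tree.root.id]
    if root_state is not None:
        if root_row[root_state][0] == math.inf:
            raise ValueError(f"root state {root_state!r} inconsistent with tips")
        chosen_root = root_state
    else:
        best = min(root_row.values())
        chosen_root = min(s for s in states if root_row[s] == best)

    # backtrack (preorder), re-deriving each child's optimal choice
    assignment: dict[int, str] = {tree.root.id: chosen_root}
    events: list[ChangeEvent] = []
    for node in tree.preorder():
        s = assignment[node.id]
        for child in node.children:
            scored = []
            for t in states:
                step = costs.cost(s, t)
                penalty = (
                    (step, float(depth[child.id]), float(child.id))
                    if s != t
                    else (0.0, 0.0, 0.0)
                )
                cand = _t_add(penalty, table[child.id][t])
                # residual ties: keep the parent state, then smallest token
                scored.append((cand, t != s, t))
            best, _, best_t = min(scored)
            assignment[child.id] = best_t
            if best_t != s:
                events.append(
                    ChangeEvent(
                        node_id=child.id,
                        branch_label=child.label if child.is_tip else None,
                        from_state=s,
                        to_state=best_t,
                    )
                )

    total = (
        root_row[chosen_root][0]
        if root_state is not None
        else min(r[0] for r in root_row.values())
    )
    return Reconstruction(states=assignment, events=events, total_steps=total)


# -- public operations --------------------------------------------------------


def fitch_length(tree: PhyloTree, column: Column) -> int:
    """Minimum number of unit-cost state changes explaining the tip states.

    Missing tips ('?') are free to take any state. Works on polytomies (the
    unit-cost Sankoff recursion is the polytomy-safe generalisation of the
    Fitch set algorithm).
    """
    _check_column(tree, column)
    observed = sorted({v for v in column.values() if v != MISSING})
    if not observed:
        raise ValueError("character has no observed states")
    if len(observed) == 1:
        return 0
    rec = _sankoff_engine(tree, column, CostMatrix.unit(observed))
    return int(round(rec.total_steps))


def sankoff(
    tree: PhyloTree, column: Column, costs: CostMatrix
) -> tuple[float, Reconstruction]:
    """Weighted parsimony: minimum total change cost and one reconstruction
    achieving it (ACCTRAN-resolved; see module docstring)."""
    rec = _sankoff_engine(tree, column, costs)
    return rec.total_steps, rec


def acctran(tree: PhyloTree, column: Column) -> Reconstruction:
    """ACCTRAN-resolved unit-cost most-parsimonious reconstruction."""
    _check_column(tree, column)
    observed = sorted({v for v in column.values() if v != MISSING})
    if not observed:
        raise ValueError("character has no observed states")
    rec = _sankoff_engine(tree, column, CostMatrix.unit(observed))
    rec.total_steps = int(round(rec.total_steps))
    return rec


def count_events(rec: Reconstruction, from_state: str, to_state: str) -> int:
    """Number of recorded change events matching (from_state -> to_state)."""
    return rec.count(from_state, to_state)


def root_constrained_reconstruction(
    tree: PhyloTree, column: Column, root_state: str
) -> Reconstruction:
    """Minimum-step reconstruction with the root state fixed (ACCTRAN ties)."""
    _check_column(tree, column)
    observed = {v for v in column.values() if v != MISSING}
    alphabet = sorted(observed | {root_state})
    rec = _sankoff_engine(
        tree, column, CostMatrix.unit(alphabet), root_state=root_state
    )
    rec.total_steps = int(round(rec.total_steps))
    return rec


def constrained_single_origin_steps(
    tree: PhyloTree, column: Column, derived_state: str
) -> int:
    """Minimum steps when the derived state is allowed to arise exactly once.

    The single gain is placed, in turn, on every branch of the root path of
    the MRCA of the derived tips (any branch ancestral to all of them); below
    the gain the derived state may only be lost (reversals), never regained.
    Returns the overall minimum of 1 gain + reversals.
    """
    _check_column(tree, column)
    observed = sorted({v for v in column.values() if v != MISSING})
    if derived_state not in observed:
        raise ValueError(f"no tips in derived state {derived_state!r}")
    if len(observed) > 2:
        raise ValueError("single-origin counting requires a binary character")
    ancestral = [s for s in observed if s != derived_state]
    if not ancestral:
        return 0  # all tips already derived: zero additional steps needed
    ancestral = ancestral[0]

    derived_tips = [t for t, v in column.items() if v == derived_state]
    mrca = tree.mrca(derived_tips)
    # candidate gain branches: every branch whose child is on root->MRCA path
    candidates = []
    node = mrca
    while node is not None and not node.is_root:
        candidates.append(node)
        node = node.parent

    loss_only = CostMatrix(
        [ancestral, derived_state],
        {
            (ancestral, derived_state): math.inf,
            (derived_state, ancestral): 1.0,
            (ancestral, ancestral): 0.0,
            (derived_state, derived_state): 0.0,
        },
    )

    def subtree_cost(gain_child: Optional[Node]) -> float:
        # cost below the gain point with the state fixed to derived there
        sub = _subtree_as_tree(tree, gain_child)
        sub_col = {t: column[t] for t in sub.tip_labels}
        rec = _sankoff_engine(sub, sub_col, loss_only, root_state=derived_state)
        return rec.total_steps

    best = math.inf
    for gain_child in candidates:
        cost = 1.0 + subtree_cost(gain_child)
        best = min(best, cost)
    if not candidates:  # derived tips span the root
        best = min(best, 1.0 + subtree_cost(None))
    return int(best) if math.isfinite(best) else math.inf


def _subtree_as_tree(tree: PhyloTree, node: Optional[Node]) -> PhyloTree:
    """Copy of the clade under *node* (whole tree if node is None)."""
    if node is None:
        return tree.copy()
    if node.is_tip:
        root = Node(id=0, label=node.label)
        return PhyloTree(root)

    def clone(n: Node) -> Node:
        new = Node(id=-1, label=n.label, length=n.length)
        for c in n.children:
            cc = clone(c)
            cc.parent = new
            new.children.append(cc)
        return new

    root = clone(node)
    root.length = None
    root.parent = None
    return PhyloTree(root)


def map_all_characters(tree: PhyloTree, matrix: CharacterMatrix) -> pd.DataFrame:
    """Per-character parsimony report.

    Columns: character, steps (Fitch length), min_steps (observed states - 1),
    homoplasy (steps > min_steps), n_gains / n_losses (binary characters only:
    a gain is a change away from the ACCTRAN root state), changes (compact
    event list "from->to@branch").
    """
    missing = set(matrix.taxa) - set(tree.tip_labels)
    extra = set(tree.tip_labels) - set(matrix.taxa)
    if extra:
        raise KeyError(f"tree tips absent from matrix: {sorted(extra)}")
    del missing  # matrix may cover extra taxa; only tree tips are mapped

    rows = []
    for ch in matrix.characters:
        column = {t: matrix.cells[(t, ch)] for t in tree.tip_labels}
        observed = sorted({v for v in column.values() if v != MISSING})
        if len(observed) <= 1:
            steps, rec = 0, None
            events = []
        else:
            rec = acctran(tree, column)
            steps = int(rec.total_steps)
            events = rec.events
        min_steps = max(len(observed) - 1, 0)
        if len(observed) == 2 and rec is not None:
            root_state = rec.states[tree.root.id]
            n_gains = sum(1 for e in events if e.from_state == root_state)
            n_losses = sum(1 for e in events if e.to_state == root_state)
        else:
            n_gains = n_losses = None
        change_str = ";".join(
            f"{e.from_state}->{e.to_state}@{e.branch_label or f'node{e.node_id}'}"
            for e in events
        )
        rows.append(
            {
                "character": ch,
                "steps": steps,
                "min_steps": min_steps,
                "homoplasy": steps > min_steps,
                "n_gains": n_gains,
                "n_losses": n_losses,
                "changes": change_str,
            }
        )
    return pd.DataFrame(rows).astype({"n_gains": "Int64", "n_losses": "Int64"})
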