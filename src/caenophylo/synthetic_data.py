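"""Seeded generators for test data with the statistical structure the
analyses assume.

Three layers:

* discrete characters evolving under a symmetric-rates Markov chain on a tree
  (test harness for the parsimony machinery),
* GTR+Γ+I sequence evolution with insertion/deletion events, yielding the
  true multiple alignment and a per-branch event log,
* multi-strain panels: a small Yule-shaped strain subtree is grafted onto
  each species tip, giving alignments with small intra-specific and larger
  inter-specific divergence — the structure a barcode-gap analysis relies on.

Every generator draws from a single ``numpy.random.default_rng(seed)``; the
same seed reproduces outputs bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .barcode import Alignment
from .divergence import GTRParams, gamma_category_rates, rate_matrix
from .trees import Node, PhyloTree, write_newick

__all__ = [
    "SimulationRecord",
    "simulate_character",
    "simulate_alignment",
    "simulate_strain_dataset",
]

_BASES = "ACGT"


@dataclass
class SimulationRecord:
    """Ground truth accompanying one simulated dataset."""

    seed: int
    parameters: dict
    tree: PhyloTree  # the tree actually simulated on, true branch lengths
    alignment: Optional[Alignment] = None
    tip_states: Optional[dict[str, str]] = None
    branch_events: dict[int, dict[str, int]] = field(default_factory=dict)

    def total_events(self) -> int:
        return sum(sum(ev.values()) for ev in self.branch_events.values())

    def true_event_distance(self, tip_a: str, tip_b: str) -> int:
        """Sum of realised events (substitutions + indels) on the tip path."""
        anc = self.tree.mrca([tip_a, tip_b])
        total = 0
        for lab in (tip_a, tip_b):
            node = self.tree.tip(lab)
            while node is not anc:
                total += sum(self.branch_events.get(node.id, {}).values())
                node = node.parent
        return total


def _branch_length(node: Node) -> float:
    return 1.0 if node.length is None else float(node.length)


# -- discrete characters ------------------------------------------------------


def simulate_character(
    tree: PhyloTree, rate: float, n_states: int, seed: int
) -> tuple[dict[str, str], SimulationRecord]:
    """Evolve one unordered character under a symmetric-rates Markov chain.

    ``rate`` is the expected number of change events per unit branch length;
    each event jumps to a uniformly chosen different state. The root state is
    uniform. Branches without lengths count as length 1.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if n_states < 2:
        raise ValueError("need at least 2 states")
    rng = np.random.default_rng(seed)
    states = [f"s{i}" for i in range(n_states)]

    assignment = {tree.root.id: int(rng.integers(n_states))}
    events: dict[int, dict[str, int]] = {}
    for node in tree.preorder():
        cur = assignment[node.id]
        for child in node.children:
            s = cur
            n_events = int(rng.poisson(rate * _branch_length(child)))
            for _ in range(n_events):
                jump = int(rng.integers(n_states - 1))
                s = jump if jump < s else jump + 1
            assignment[child.id] = s
            events[child.id] = {"substitutions": n_events}
    tip_states = {t.label: states[assignment[t.id]] for t in tree.tips}
    rec = SimulationRecord(
        seed=seed,
        parameters={"rate": rate, "n_states": n_states},
        tree=tree,
        tip_states=tip_states,
        branch_events=events,
    )
    return tip_states, rec


# -- sequence evolution with indels -------------------------------------------


class _Lineage:
    """A lineage's sequence: site ids, integer states and per-site rates."""

    __slots__ = ("ids", "states", "rates")

    def __init__(self, ids, states, rates):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.states = np.asarray(states, dtype=np.int64)
        self.rates = np.asarray(rates, dtype=float)

    def copy(self) -> "_Lineage":
        return _Lineage(self.ids.copy(), self.states.copy(), self.rates.copy())


def _sample_site_rates(rng, n, cat_rates, p_inv):
    rates = cat_rates[rng.integers(len(cat_rates), size=n)]
    if p_inv > 0:
        rates[rng.random(n) < p_inv] = 0.0
    return rates


def _evolve_substitutions(rng, lineage: _Lineage, q: np.ndarray, t: float) -> int:
    """Vectorised Gillespie simulation of substitutions; returns event count."""
    n_events = 0
    remaining = np.full(len(lineage.ids), t)
    exit_rate = -np.diag(q)
    jump_probs = q.copy()
    np.fill_diagonal(jump_probs, 0.0)
    jump_probs /= exit_rate[:, None]
    active = lineage.rates > 0
    while np.any(active):
        lam = exit_rate[lineage.states[active]] * lineage.rates[active]
        waits = rng.exponential(1.0 / lam)
        rem = remaining[active] - waits
        jumped = rem > 0
        remaining[np.flatnonzero(active)] = rem
        idx = np.flatnonzero(active)[jumped]
        if len(idx) == 0:
            break
        u = rng.random(len(idx))
        cum = np.cumsum(jump_probs[lineage.states[idx]], axis=1)
        lineage.states[idx] = (u[:, None] < cum).argmax(axis=1)
        n_events += len(idx)
        mask = np.zeros_like(active)
        mask[idx] = True
        active = mask & (remaining > 0)
    return n_events


def simulate_alignment(
    tree: PhyloTree,
    params: GTRParams,
    length: int,
    indel_rate: float = 0.0,
    mean_indel_len: float = 3.0,
    seed: int = 0,
) -> SimulationRecord:
    """Simulate GTR+Γ+I sequence evolution with indels along a tree.

    ``indel_rate`` is the expected number of indel events per unit branch
    length for the whole sequence; insertions and deletions are equally
    likely and lengths are geometric with the given mean. Insertions create
    new alignment columns (gaps in all lineages that never carried the site),
    deletions leave gaps. The returned record holds the true multiple
    alignment and per-branch event counts.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if indel_rate < 0:
        raise ValueError("indel_rate must be >= 0")
    rng = np.random.default_rng(seed)
    pi = np.asarray(params.freqs, float)
    pi = pi / pi.sum()  # exact normalisation for rng.choice
    q = rate_matrix(params)
    cat_rates = gamma_category_rates(params.alpha, params.n_categories)

    next_id = [length]
    master: list[int] = list(range(length))

    def fresh_sites(n):
        ids = np.arange(next_id[0], next_id[0] + n, dtype=np.int64)
        next_id[0] += n
        states = rng.choice(4, size=n, p=pi)
        rates = _sample_site_rates(rng, n, cat_rates, params.p_inv)
        return ids, states, rates

    root_ids = np.arange(length, dtype=np.int64)
    root_states = rng.choice(4, size=length, p=pi)
    root_rates = _sample_site_rates(rng, length, cat_rates, params.p_inv)
    lineages = {tree.root.id: _Lineage(root_ids, root_states, root_rates)}

    events: dict[int, dict[str, int]] = {}
    geom_p = 1.0 / max(mean_indel_len, 1.0)

    for node in tree.preorder():
        for child in node.children:
            lin = lineages[node.id].copy()
            t = _branch_length(child)
            n_sub = _evolve_substitutions(rng, lin, q, t)
            n_ins = n_del = 0
            if indel_rate > 0 and t > 0:
                for _ in range(int(rng.poisson(indel_rate * t))):
                    if rng.random() < 0.5 and len(lin.ids) > 0:  # deletion
                        ln = int(rng.geometric(geom_p))
                        start = int(rng.integers(len(lin.ids)))
                        stop = min(start + ln, len(lin.ids))
                        lin.ids = np.delete(lin.ids, slice(start, stop))
                        lin.states = np.delete(lin.states, slice(start, stop))
                        lin.rates = np.delete(lin.rates, slice(start, stop))
                        n_del += 1
                    else:  # insertion
                        ln = int(rng.geometric(geom_p))
                        pos = int(rng.integers(len(lin.ids) + 1))
                        ids, states, rates = fresh_sites(ln)
                        # place the new columns in the master ordering
                        if pos == 0:
                            anchor = (
                                master.index(int(lin.ids[0])) if len(lin.ids) else 0
                            )
                        else:
                            anchor = master.index(int(lin.ids[pos - 1])) + 1
                        master[anchor:anchor] = [int(i) for i in ids]
                        lin.ids = np.insert(lin.ids, pos, ids)
                        lin.states = np.insert(lin.states, pos, states)
                        lin.rates = np.insert(lin.rates, pos, rates)
                        n_ins += 1
            lineages[child.id] = lin
            events[child.id] = {
                "substitutions": n_sub,
                "insertions": n_ins,
                "deletions": n_del,
            }

    col_index = {sid: i for i, sid in enumerate(master)}
    rows = {}
    for tip in tree.tips:
        lin = lineages[tip.id]
        row = np.full(len(master), "-", dtype="<U1")
        cols = [col_index[int(i)] for i in lin.ids]
        row[cols] = np.array(list(_BASES))[lin.states]
        rows[tip.label] = "".join(row)
    aln = Alignment(labels=[t.label for t in tree.tips], rows=rows)

    return SimulationRecord(
        seed=seed,
        parameters={
            "model": "GTR+G+I",
            "freqs": list(params.freqs),
            "rates": list(params.rates),
            "alpha": params.alpha,
            "p_inv": params.p_inv,
            "n_categories": params.n_categories,
            "length": length,
            "indel_rate": indel_rate,
            "mean_indel_len": mean_indel_len,
        },
        tree=tree,
        alignment=aln,
        branch_events=events,
    )


# -- strain panels ------------------------------------------------------------


def _yule_subtree(rng, labels: list[str], intra_scale: float) -> Node:
    """Yule-shaped strain subtree; branch lengths ~ Exp(mean intra_scale)."""
    root = Node(id=-1, label=labels[0])
    tips = [root]
    for lab in labels[1:]:
        split = tips[int(rng.integers(len(tips)))]  # uniform tip splits: Yule
        left = Node(id=-1, label=split.label, parent=split)
        right = Node(id=-1, label=lab, parent=split)
        split.label = None
        split.children = [left, right]
        tips.remove(split)
        tips.extend([left, right])
    for n in _iter_nodes(root):
        if n is not root:
            n.length = float(rng.exponential(intra_scale))
    return root


def _iter_nodes(root: Node):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def simulate_strain_dataset(
    species_tree: PhyloTree,
    strains_per_species: Mapping[str, int],
    intra_scale: float,
    params: GTRParams,
    length: int = 600,
    indel_rate: float = 0.0,
    mean_indel_len: float = 3.0,
    seed: int = 0,
) -> tuple[Alignment, dict[str, str], SimulationRecord]:
    """Simulate a multi-strain panel on a species tree.

    Each species tip is replaced by a Yule-shaped subtree of its strains with
    expected branch lengths ``intra_scale`` (same units as the species tree),
    then one alignment is simulated on the grafted tree. Strains are named
    ``<species>_S<i>``. Returns (alignment, strain->species map, record).
    """
    if intra_scale <= 0:
        raise ValueError("intra_scale must be > 0")
    for sp in species_tree.tip_labels:
        if sp not in strains_per_species:
            raise ValueError(f"no strain count for species {sp!r}")
        if strains_per_species[sp] < 1:
            raise ValueError(f"species {sp!r} must have >= 1 strain")

    rng = np.random.default_rng(seed)
    species_map: dict[str, str] = {}

    def clone(n: Node) -> Node:
        new = Node(id=-1, label=n.label, length=n.length)
        for c in n.children:
            cc = clone(c)
            cc.parent = new
            new.children.append(cc)
        return new

    root = clone(species_tree.root)
    grafted = PhyloTree(root)
    for tip in list(grafted.tips):
        sp = tip.label
        k = strains_per_species[sp]
        labels = [f"{sp}_S{i + 1}" for i in range(k)]
        for lab in labels:
            species_map[lab] = sp
        if k == 1:
            tip.label = labels[0]
            continue
        sub = _yule_subtree(rng, labels, intra_scale)
        sub.length = tip.length
        sub.parent = tip.parent
        if tip.parent is None:
            grafted = PhyloTree(sub)
        else:
            idx = tip.parent.children.index(tip)
            tip.parent.children[idx] = sub
    strain_tree = PhyloTree(grafted.root)

    sim_seed = int(rng.integers(2**31 - 1))
    rec = simulate_alignment(
        strain_tree,
        params,
        length=length,
        indel_rate=indel_rate,
        mean_indel_len=mean_indel_len,
        seed=sim_seed,
    )
    rec.parameters.update(
        {
            "intra_scale": intra_scale,
            "strains_per_species": dict(strains_per_species),
            "panel_seed": seed,
        }
    )
    rec.seed = seed
    return rec.alignment, species_map, rec
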