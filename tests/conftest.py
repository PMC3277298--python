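"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's dynamic-programming code
paths: parsimony scores are obtained by exhaustive enumeration of ancestral
labelings, likelihoods by summing over all internal-node state assignments
and rate categories. They are only feasible on tiny instances, which is the
point — they provide ground truth the fast implementations must match.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from caenophylo.charmap import MISSING
from caenophylo.trees import Node, PhyloTree


# -- random instances ---------------------------------------------------------


def random_tree(rng: np.random.Generator, n_tips: int, with_lengths: bool = False,
                max_len: float = 1.0) -> PhyloTree:
    """Random binary topology by repeated joining; optional U(0, max_len] lengths."""
    nodes = [Node(id=-1, label=f"T{i}") for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = Node(id=-1, children=[left, right])
        left.parent = right.parent = parent
        nodes.append(parent)
    tree = PhyloTree(nodes[0])
    if with_lengths:
        for n in tree.nodes:
            if not n.is_root:
                n.length = float(rng.uniform(1e-3, max_len))
    return tree


def random_column(rng: np.random.Generator, tree: PhyloTree, n_states: int,
                  p_missing: float = 0.0) -> dict[str, str]:
    states = [f"s{i}" for i in range(n_states)]
    col = {}
    for lab in tree.tip_labels:
        if p_missing and rng.random() < p_missing:
            col[lab] = MISSING
        else:
            col[lab] = states[rng.integers(n_states)]
    if all(v == MISSING for v in col.values()):
        col[tree.tip_labels[0]] = states[0]
    return col


# -- parsimony enumeration oracle ---------------------------------------------


def brute_force_parsimony(
    tree: PhyloTree,
    column: dict[str, str],
    states: list[str],
    cost=lambda a, b: 0 if a == b else 1,
    root_state: str | None = None,
):
    """Minimum total change cost over every ancestral labeling (missing tips
    are also free). Returns (min_cost, list of optimal full assignments)."""
    free_nodes = [
        n for n in tree.nodes
        if (not n.is_tip) or column[n.label] == MISSING
    ]
    if root_state is not None and tree.root in free_nodes:
        free_nodes = [n for n in free_nodes if n is not tree.root]

    fixed = {
        n.id: column[n.label]
        for n in tree.nodes
        if n.is_tip and column[n.label] != MISSING
    }
    if root_state is not None:
        fixed[tree.root.id] = root_state

    best, argbest = math.inf, []
    for combo in itertools.product(states, repeat=len(free_nodes)):
        assignment = dict(fixed)
        assignment.update({n.id: s for n, s in zip(free_nodes, combo)})
        total = 0
        for node in tree.nodes:
            for child in node.children:
                total += cost(assignment[node.id], assignment[child.id])
        if total < best - 1e-12:
            best, argbest = total, [assignment]
        elif abs(total - best) <= 1e-12:
            argbest.append(assignment)
    return best, argbest


def reconstruction_depth_key(tree: PhyloTree, assignment: dict[int, str]):
    """(n_changes, sum of change-branch depths, sum of change-branch ids):
    the ordering under which the ACCTRAN resolution is optimal."""
    depth = {tree.root.id: 0}
    for node in tree.preorder():
        for c in node.children:
            depth[c.id] = depth[node.id] + 1
    n = sd = si = 0
    for node in tree.nodes:
        for child in node.children:
            if assignment[node.id] != assignment[child.id]:
                n += 1
                sd += depth[child.id]
                si += child.id
    return (n, sd, si)


# -- likelihood enumeration oracle --------------------------------------------


def enumeration_loglik(tree: PhyloTree, rows: dict[str, str], params) -> float:
    """Sum over all internal-node base assignments and rate categories."""
    from caenophylo.divergence import (
        IUPAC, STATES, gamma_category_rates, rate_matrix,
    )
    from scipy.linalg import expm

    pi = np.asarray(params.freqs, float)
    q = rate_matrix(params)
    cat_rates = gamma_category_rates(params.alpha, params.n_categories)
    internals = [n for n in tree.nodes if not n.is_tip]
    tips = tree.tips
    n_sites = len(next(iter(rows.values())))

    total = 0.0
    for site in range(n_sites):
        site_lik = 0.0
        for r in cat_rates:
            pmats = {
                n.id: expm(q * r * n.length) for n in tree.nodes if not n.is_root
            }
            lik = 0.0
            for combo in itertools.product(range(4), repeat=len(internals)):
                a = {n.id: s for n, s in zip(internals, combo)}
                term = pi[a[tree.root.id]]
                ok = True
                for node in tree.nodes:
                    for child in node.children:
                        if child.is_tip:
                            ch = rows[child.label][site].upper()
                            comp = [STATES.index(b) for b in IUPAC[ch]]
                            term *= sum(
                                pmats[child.id][a[node.id], j] for j in comp
                            )
                        else:
                            term *= pmats[child.id][a[node.id], a[child.id]]
                    if term == 0:
                        ok = False
                        break
                if ok:
                    lik += term
            site_lik += lik / len(cat_rates)
        # invariant component
        if params.p_inv > 0:
            mask = np.ones(4, bool)
            for t in tips:
                ch = rows[t.label][site].upper()
                m = np.zeros(4, bool)
                for b in IUPAC[ch]:
                    m[STATES.index(b)] = True
                mask &= m
            inv = pi[mask].sum()
            site_lik = params.p_inv * inv + (1 - params.p_inv) * site_lik
        total += math.log(site_lik)
    return total


# -- shared fixtures ----------------------------------------------------------


@pytest.fixture(scope="session")
def fixture_tree():
    from caenophylo import load_fixture_tree

    return load_fixture_tree("caenorhabditis26")


@pytest.fixture(scope="session")
def fixture_tree_outgroup():
    from caenophylo import load_fixture_tree

    return load_fixture_tree("caenorhabditis26+outgroup")


@pytest.fixture(scope="session")
def fixture_characters():
    from caenophylo import load_fixture_characters

    return load_fixture_characters()
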