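"""GTR+Γ+I likelihood on a fixed topology and ML branch-length estimation.

The model is the general time-reversible nucleotide substitution model with
discrete-gamma rate variation across sites (equal-probability categories,
category-mean rates) and a proportion of invariant sites. The rate matrix is
normalised to one expected substitution per unit time over the variable
fraction, so optimised branch lengths read directly as expected
substitutions/site, the unit used for pairwise divergence tables.

Likelihoods are computed by Felsenstein pruning over compressed site
patterns; gaps and IUPAC ambiguity codes enter as partial likelihood 1 for
every compatible base.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .trees import PhyloTree

__all__ = [
    "GTRParams",
    "JC_PARAMS",
    "rate_matrix",
    "gamma_category_rates",
    "gtr_gamma_inv_loglik",
    "optimize_branch_lengths",
    "divergence_table",
    "ConvergenceError",
]

STATES = "ACGT"
_STATE_INDEX = {b: i for i, b in enumerate(STATES)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT",
}


class ConvergenceError(RuntimeError):
    """Optimization failed to converge; carries the best tree found so far."""

    def __init__(self, message: str, best_tree: PhyloTree, best_loglik: float):
        super().__init__(message)
        self.best_tree = best_tree
        self.best_loglik = best_loglik


@dataclass(frozen=True)
class GTRParams:
    """GTR+Γ+I parameters.

    freqs: stationary base frequencies (A, C, G, T), positive, sum 1.
    rates: exchangeabilities (AC, AG, AT, CG, CT) relative to GT = 1.
    alpha: gamma shape for among-site rate variation (None or inf => no Γ).
    p_inv: proportion of invariant sites in [0, 1).
    n_categories: number of discrete gamma categories.
    """

    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    rates: tuple[float, float, float, float, float] = (1, 1, 1, 1, 1)
    alpha: Optional[float] = None
    p_inv: float = 0.0
    n_categories: int = 4

    def __post_init__(self):
        f = np.asarray(self.freqs, float)
        if f.shape != (4,) or np.any(f <= 0) or abs(f.sum() - 1) > 1e-6:
            raise ValueError("freqs must be 4 positive numbers summing to 1")
        if len(self.rates) != 5 or any(r <= 0 for r in self.rates):
            raise ValueError("rates must be 5 positive exchangeabilities")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must be in [0, 1)")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")


JC_PARAMS = GTRParams()  # equal frequencies, equal rates, no Gamma/I


def rate_matrix(params: GTRParams) -> np.ndarray:
    """GTR rate matrix, normalised to mean rate 1 at stationarity."""
    pi = np.asarray(params.freqs, float)
    ac, ag, at, cg, ct = params.rates
    s = np.array(
        [
            [0, ac, ag, at],
            [ac, 0, cg, ct],
            [ag, cg, 0, 1.0],
            [at, ct, 1.0, 0],
        ]
    )
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(pi * np.diag(q)).sum()
    return q / mu


def gamma_category_rates(alpha: Optional[float], k: int) -> np.ndarray:
    """Mean rates of k equal-probability discrete gamma categories (mean 1)."""
    if alpha is None or k == 1:
        return np.ones(max(k, 1))
    # boundaries of equal-probability bins for Gamma(alpha, mean 1)
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    # E[X | a<=X<b] * P = (1/alpha)*... via the shape alpha+1 incomplete gamma
    upper = gammainc(alpha + 1, alpha * edges[1:])
    lower = gammainc(alpha + 1, alpha * edges[:-1])
    means = k * (upper - lower)
    return means / means.mean()  # exact renormalisation against ppf round-off


def _eigen(params: GTRParams):
    """Symmetric eigendecomposition of the reversible rate matrix."""
    pi = np.asarray(params.freqs, float)
    q = rate_matrix(params)
    d = np.sqrt(pi)
    b = (q * d[:, None]) / d[None, :]
    w, u = np.linalg.eigh((b + b.T) / 2)
    left = u.T * d[None, :] / 1.0  # rows: u^T D^{1/2}
    right = (u / d[:, None])  # D^{-1/2} u  (columns)
    return w, right, left


def _prob_matrices(w, right, left, lengths: np.ndarray) -> np.ndarray:
    """P(t) for an array of t; shape (len(t), 4, 4)."""
    et = np.exp(np.outer(lengths, w))  # (n, 4)
    return np.einsum("ik,nk,kj->nij", right, et, left)


# -- alignment preprocessing --------------------------------------------------


def _pattern_table(tree: PhyloTree, rows: dict[str, str]):
    tips = tree.tip_labels
    for t in tips:
        if t not in rows:
            raise KeyError(f"tip {t!r} missing from alignment")
    seqs = [rows[t].upper().replace("U", "T") for t in tips]
    n = len(seqs[0])
    if n == 0:
        raise ValueError("empty alignment")
    if any(len(s) != n for s in seqs):
        raise ValueError("alignment rows differ in length")
    patterns: dict[tuple, int] = {}
    order = []
    for col in zip(*seqs):
        if col in patterns:
            patterns[col] += 1
        else:
            patterns[col] = 1
            order.append(col)
    counts = np.array([patterns[c] for c in order], float)
    # leaf partials per tip: (n_patterns, 4)
    leaf = {}
    for i, t in enumerate(tips):
        arr = np.zeros((len(order), 4))
        for p, col in enumerate(order):
            ch = col[i]
            try:
                comp = IUPAC[ch]
            except KeyError:
                raise ValueError(f"illegal character {ch!r} in row {t!r}") from None
            for b in comp:
                arr[p, _STATE_INDEX[b]] = 1.0
        leaf[t] = arr
    return counts, leaf, order


def _invariant_weights(order, pi: np.ndarray) -> np.ndarray:
    """P(pattern | invariant site) for each pattern: sum of pi over bases
    compatible with every row, 0 if no base fits all."""
    out = np.zeros(len(order))
    for p, col in enumerate(order):
        mask = np.ones(4, bool)
        for ch in col:
            comp = IUPAC[ch]
            m = np.zeros(4, bool)
            for b in comp:
                m[_STATE_INDEX[b]] = True
            mask &= m
        out[p] = pi[mask].sum()
    return out


# -- pruning ------------------------------------------------------------------


class _Pruner:
    """Caches pattern data and provides loglik / per-branch optimization."""

    def __init__(self, tree: PhyloTree, rows: dict[str, str], params: GTRParams):
        self.tree = tree
        self.params = params
        self.counts, self.leaf, self.order = _pattern_table(tree, rows)
        self.pi = np.asarray(params.freqs, float)
        self.cat_rates = gamma_category_rates(params.alpha, params.n_categories)
        self.w, self.right, self.left = _eigen(params)
        self.inv_w = _invariant_weights(self.order, self.pi)
        self.n_pat = len(self.counts)
        self.n_cat = len(self.cat_rates)

    def _pmats(self, t: float) -> np.ndarray:
        return _prob_matrices(self.w, self.right, self.left, t * self.cat_rates)

    def _below(self) -> dict[int, np.ndarray]:
        below: dict[int, np.ndarray] = {}
        for node in self.tree.postorder():
            if node.is_tip:
                below[node.id] = np.repeat(
                    self.leaf[node.label][:, None, :], self.n_cat, axis=1
                )
                continue
            part = np.ones((self.n_pat, self.n_cat, 4))
            for child in node.children:
                pm = self._pmats(child.length)
                part *= np.einsum("cij,pcj->pci", pm, below[child.id])
            below[node.id] = part
        return below

    def _site_likelihoods(self, below_root: np.ndarray) -> np.ndarray:
        var = np.einsum("pci,i->pc", below_root, self.pi).mean(axis=1)
        p_inv = self.params.p_inv
        return p_inv * self.inv_w + (1 - p_inv) * var

    def loglik(self) -> float:
        sl = self._site_likelihoods(self._below()[self.tree.root.id])
        if np.any(sl <= 0):
            return -np.inf
        return float((self.counts * np.log(sl)).sum())

    # branch-length optimization -------------------------------------------

    def optimize_lengths(
        self,
        tol: float = 1e-6,
        max_sweeps: int = 50,
        bounds: tuple[float, float] = (1e-8, 10.0),
    ) -> float:
        prev = self.loglik()
        for _ in range(max_sweeps):
            self._sweep(bounds)
            cur = self.loglik()
            if abs(cur - prev) < tol:
                return cur
            prev = cur
        raise ConvergenceError(
            f"branch-length optimization did not converge in {max_sweeps} sweeps",
            self.tree,
            prev,
        )

    def _sweep(self, bounds) -> None:
        """One exact coordinate-ascent pass over all branches.

        ``below[v]`` (subtree partials) and the flowing ``above`` context are
        kept current at every step: a subtree's partials are recomputed after
        its branches have been updated, so each scalar optimization maximises
        the true likelihood in that branch given all others — the sweep never
        decreases the log-likelihood.
        """
        below = self._below()
        p_inv = self.params.p_inv

        def optimize_branch(ab: np.ndarray, child) -> None:
            def neg_ll(t: float) -> float:
                pm = self._pmats(t)
                var = np.einsum(
                    "pci,cij,pcj->pc", ab, pm, below[child.id]
                ).mean(axis=1)
                sl = p_inv * self.inv_w + (1 - p_inv) * var
                if np.any(sl <= 0):
                    return np.inf
                return -float((self.counts * np.log(sl)).sum())

            current = neg_ll(child.length)
            res = optimize.minimize_scalar(
                neg_ll, bounds=bounds, method="bounded",
                options={"xatol": 1e-10},
            )
            if res.fun <= current:  # bounded search is a strict improvement
                child.length = float(res.x)

        def process(node, ab_node: np.ndarray) -> None:
            for child in node.children:
                ab = ab_node.copy()
                for sib in node.children:
                    if sib is child:
                        continue
                    pm = self._pmats(sib.length)
                    ab *= np.einsum("cij,pcj->pci", pm, below[sib.id])
                optimize_branch(ab, child)
                if not child.is_tip:
                    # context for the child's own children flows through the
                    # (just optimised) branch: above_j = sum_i ab_i P_ij(t)
                    prop = np.einsum(
                        "pci,cij->pcj", ab, self._pmats(child.length)
                    )
                    process(child, prop)
                    # child's subtree lengths changed: refresh its partials
                    part = np.ones((self.n_pat, self.n_cat, 4))
                    for c in child.children:
                        pm = self._pmats(c.length)
                        part *= np.einsum("cij,pcj->pci", pm, below[c.id])
                    below[child.id] = part

        root_ab = np.broadcast_to(self.pi, (self.n_pat, self.n_cat, 4)).copy()
        process(self.tree.root, root_ab)


# -- public API ---------------------------------------------------------------


def gtr_gamma_inv_loglik(
    tree: PhyloTree, rows: dict[str, str], params: GTRParams
) -> float:
    """Log-likelihood of an alignment on a tree with branch lengths, under
    GTR with discrete-gamma rate categories and invariant sites."""
    if not tree.has_lengths():
        raise ValueError("tree must have branch lengths")
    return _Pruner(tree, rows, params).loglik()


def empirical_frequencies(rows: dict[str, str]) -> tuple[float, ...]:
    """Base frequencies counted over unambiguous, non-gap cells."""
    counts = np.zeros(4)
    for seq in rows.values():
        for ch in seq.upper().replace("U", "T"):
            if ch in _STATE_INDEX:
                counts[_STATE_INDEX[ch]] += 1
    if counts.sum() == 0:
        raise ValueError("no unambiguous bases in alignment")
    return tuple(counts / counts.sum())


def optimize_branch_lengths(
    tree: PhyloTree,
    rows: dict[str, str],
    params: GTRParams,
    estimate_params: bool = False,
    tol: float = 1e-6,
    max_sweeps: int = 50,
) -> tuple[PhyloTree, GTRParams, float]:
    """ML branch lengths on a fixed topology by per-branch coordinate ascent.

    With ``estimate_params`` the exchangeabilities, gamma shape and invariant
    proportion are additionally optimised (base frequencies are set to the
    empirical frequencies of the alignment). Returns (tree copy with fitted
    lengths, parameters used, final log-likelihood).
    """
    work = tree.copy()
    for node in work.nodes:
        if not node.is_root and (node.length is None or node.length <= 0):
            node.length = 0.05  # neutral starting point
    if estimate_params:
        params = replace(params, freqs=empirical_frequencies(rows))

    pruner = _Pruner(work, rows, params)
    ll = pruner.optimize_lengths(tol=tol, max_sweeps=max_sweeps)

    if estimate_params:
        have_gamma = params.alpha is not None

        def unpack(x) -> GTRParams:
            rates = tuple(np.exp(x[:5]))
            alpha = float(np.exp(x[5])) if have_gamma else None
            p_inv = float(1 / (1 + np.exp(-x[6]))) if len(x) > 6 else params.p_inv
            return replace(params, rates=rates, alpha=alpha, p_inv=p_inv)

        x0 = list(np.log(params.rates))
        if have_gamma:
            x0.append(np.log(params.alpha))
            x0.append(np.log(params.p_inv / (1 - params.p_inv)) if params.p_inv > 0 else -3.0)

        def neg(x):
            try:
                p = unpack(np.asarray(x))
            except ValueError:
                return np.inf
            return -gtr_gamma_inv_loglik(work, rows, p)

        for _ in range(3):  # alternate parameter and branch-length rounds
            res = optimize.minimize(
                neg, x0, method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-4, "maxiter": 400},
            )
            x0 = res.x
            params = unpack(res.x)
            pruner = _Pruner(work, rows, params)
            new_ll = pruner.optimize_lengths(tol=tol, max_sweeps=max_sweeps)
            if abs(new_ll - ll) < max(tol, 1e-4):
                ll = new_ll
                break
            ll = new_ll

    work.length_unit = "substitutions/site"
    return work, params, ll


def divergence_table(tree: PhyloTree) -> pd.DataFrame:
    """All pairwise patristic distances, sorted ascending."""
    if not tree.has_lengths():
        raise ValueError("tree must have branch lengths")
    rows = []
    for a, b in itertools.combinations(tree.tip_labels, 2):
        rows.append(
            {"taxon_a": a, "taxon_b": b, "distance": tree.patristic_distance(a, b)}
        )
    return (
        pd.DataFrame(rows)
        .sort_values("distance", kind="mergesort")
        .reset_index(drop=True)
    )
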