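"""Independent oracles used to validate the package's computations.

These deliberately avoid the code paths they check: ancestral-state
reconstruction by exhaustive enumeration, the exact binomial two-tailed
P by summing over all outcomes, and the chi-square upper tail by direct
numerical integration of the density.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Mapping, Tuple

import numpy as np
from scipy.integrate import quad

from ssdfate.tree import SpeciesTree


def brute_force_wagner(
    tree: SpeciesTree,
    leaf_counts: Mapping[str, int],
    gain_penalty: float,
    loss_penalty: float,
    max_count: int,
) -> Tuple[float, List[Dict[str, int]]]:
    """Minimum cost and all co-optimal ancestral assignments by enumeration."""
    internal = [n for n in tree.nodes if not tree.is_leaf(n)]
    best = math.inf
    best_assignments: List[Dict[str, int]] = []
    for states in itertools.product(range(max_count + 1), repeat=len(internal)):
        assign = dict(zip(internal, states))
        assign.update({k: int(v) for k, v in leaf_counts.items()})
        cost = 0.0
        for node in tree.nodes:
            if node == tree.root:
                continue
            change = assign[node] - assign[tree.parent(node)]
            cost += gain_penalty * change if change > 0 else -loss_penalty * change
        if cost < best - 1e-12:
            best = cost
            best_assignments = [assign]
        elif abs(cost - best) <= 1e-12:
            best_assignments.append(assign)
    return best, best_assignments


def random_tree(rng: np.random.Generator, n_leaves: int) -> SpeciesTree:
    """A random rooted bifurcating topology over n_leaves labelled leaves."""
    labels = ["L%d" % i for i in range(n_leaves)]

    def build(items: List[str]) -> str:
        if len(items) == 1:
            return items[0]
        k = int(rng.integers(1, len(items)))
        return "(%s,%s)" % (build(items[:k]), build(items[k:]))

    perm = [labels[i] for i in rng.permutation(n_leaves)]
    return SpeciesTree.from_newick(build(perm) + ";", is_path=False)


def binom_two_tailed(k: int, n: int, p: float) -> float:
    """Exact two-tailed binomial P: sum of P(X=j) over outcomes no more
    likely than the observed one (small relative tolerance on the
    comparison, as is standard for this convention)."""
    logp, logq = math.log(p), math.log(1.0 - p)

    def log_pmf(j: int) -> float:
        return (
            math.lgamma(n + 1)
            - math.lgamma(j + 1)
            - math.lgamma(n - j + 1)
            + j * logp
            + (n - j) * logq
        )

    obs = math.exp(log_pmf(k))
    total = 0.0
    for j in range(n + 1):
        pj = math.exp(log_pmf(j))
        if pj <= obs * (1.0 + 1e-7):
            total += pj
    return min(1.0, total)


def chi2_sf_numeric(x: float, df: int) -> float:
    """Upper tail of the chi-square distribution by numerical integration."""

    def density(t: float) -> float:
        return t ** (df / 2.0 - 1.0) * math.exp(-t / 2.0) / (
            2.0 ** (df / 2.0) * math.gamma(df / 2.0)
        )

    val, _ = quad(density, x, np.inf, limit=200)
    return val
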