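"""Independent oracles used by the test suite.

Each oracle is written directly from first principles (brute force,
enumeration, closed form) and never shares code with the implementation it
checks.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

import numpy as np

from panpav.io_formats import TreeNode


# ---------------------------------------------------------------------------
# alignment identity (edit-distance DP via edlib)
# ---------------------------------------------------------------------------

def dp_identity(a: str, b: str) -> float:
    """Identity from a full dynamic-programming alignment (edlib NW).

    For the substitution-dominated pairs used in tests the optimal global
    alignment is gap-free, so identity = 1 - edit_distance / alignment
    columns with columns = max(len(a), len(b)).
    """
    import edlib

    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


# ---------------------------------------------------------------------------
# nucleotide diversity: exact all-pairs allele differences (rationals)
# ---------------------------------------------------------------------------

def window_pi_oracle(dosage: np.ndarray, positions: np.ndarray,
                     starts, ends) -> list[float]:
    """Exact per-window pi by enumerating all allele pairs per site.

    Each diploid sample contributes two alleles; a site with c alt among n
    alleles has c*(n-c) differing pairs out of n*(n-1)/2.  Sums are exact
    rationals divided by the window span.
    """
    out = []
    for s, e in zip(starts, ends):
        total = Fraction(0)
        for i in np.flatnonzero((positions - 1 >= s) & (positions - 1 < e)):
            alleles = []
            for d in dosage[i]:
                if d >= 0:
                    alleles.extend([1] * int(d) + [0] * (2 - int(d)))
            n = len(alleles)
            if n < 2:
                continue
            c = sum(alleles)
            diff = c * (n - c)
            pairs = n * (n - 1) // 2
            total += Fraction(diff, pairs)
        out.append(float(total / (e - s)))
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) a/b/c components, transcribed independently
# ---------------------------------------------------------------------------

def wc_fst_oracle(dosage: np.ndarray, group_indices: list[list[int]]) -> float:
    """theta = sum(a) / sum(a+b+c), per-site components in plain loops."""
    r = len(group_indices)
    sum_a = sum_abc = 0.0
    for site in range(dosage.shape[0]):
        n_i, p_i, h_i = [], [], []
        for idx in group_indices:
            vals = [int(dosage[site, j]) for j in idx if dosage[site, j] >= 0]
            n = len(vals)
            n_i.append(n)
            p_i.append(sum(vals) / (2 * n) if n else float("nan"))
            h_i.append(sum(1 for v in vals if v == 1) / n if n else float("nan"))
        if min(n_i) < 1 or sum(n_i) <= r:
            continue
        n_bar = sum(n_i) / r
        p_bar = sum(n * p for n, p in zip(n_i, p_i)) / (r * n_bar)
        s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * n_bar)
        h_bar = sum(n * h for n, h in zip(n_i, h_i)) / (r * n_bar)
        n_c = (sum(n_i) - sum(n * n for n in n_i) / sum(n_i)) / (r - 1)
        pq = p_bar * (1 - p_bar)
        a = (n_bar / n_c) * (s2 - (pq - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (
            pq - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        if not all(map(math.isfinite, (a, b, c))):
            continue
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc if sum_abc != 0 else float("nan")


# ---------------------------------------------------------------------------
# brute-force sweep filter
# ---------------------------------------------------------------------------

def brute_sweep_filter(chroms, starts, ends, scores, pi_wild, pi_dom,
                       top_score=0.05, top_rod=0.50):
    """Re-derivation of the composite filter with sorted lists.

    Ranking by raw score equals ranking by its z-score (monotone), so no
    normalization is needed here.  Returns (selected, survivors, merged).
    """
    W = len(scores)
    ranked = sorted(range(W), key=lambda i: (-scores[i], i))
    selected = sorted(ranked[:math.ceil(top_score * W)])
    selected = [i for i in selected if pi_wild[i] != 0]
    rod = {i: (math.inf if pi_dom[i] == 0 else pi_wild[i] / pi_dom[i])
           for i in selected}
    by_rod = sorted(selected, key=lambda i: (-rod[i], i))
    survivors = sorted(by_rod[:math.ceil(top_rod * len(selected))])
    merged = []
    for i in survivors:
        if merged and merged[-1][0] == chroms[i] and starts[i] <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], ends[i])
        else:
            merged.append([chroms[i], int(starts[i]), int(ends[i])])
    return selected, survivors, [tuple(m) for m in merged]


# ---------------------------------------------------------------------------
# hypergeometric upper tail (exact rationals)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _comb(n: int, k: int) -> int:
    return math.comb(n, k)


def fisher_one_sided_oracle(overlap: int, universe: int, term_size: int,
                            fg_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, term_size, fg_size)."""
    total = _comb(universe, fg_size)
    hi = min(term_size, fg_size)
    acc = Fraction(0)
    for k in range(max(overlap, max(0, fg_size + term_size - universe)), hi + 1):
        acc += Fraction(_comb(term_size, k) * _comb(universe - term_size, fg_size - k),
                        total)
    return float(acc)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def leaf_distances(tree: TreeNode) -> dict[tuple[str, str], float]:
    """All leaf-pair path lengths of a tree (branch-length sums)."""
    out: dict[tuple[str, str], float] = {}

    def walk(node: TreeNode) -> dict[str, float]:
        if node.is_leaf():
            return {node.name: 0.0}
        maps = []
        for child in node.children:
            m = {k: v + child.length for k, v in walk(child).items()}
            maps.append(m)
        for i in range(len(maps)):
            for j in range(i + 1, len(maps)):
                for la, da in maps[i].items():
                    for lb, db in maps[j].items():
                        out[tuple(sorted((la, lb)))] = da + db
        merged = {}
        for m in maps:
            merged.update(m)
        return merged

    walk(tree)
    return out


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """A random unrooted binary tree with positive branch lengths.

    Returns (tree, ids, distance matrix) where the matrix holds the exact
    path lengths — an additive metric that neighbor joining must recover.
    """
    nodes = [TreeNode(name=f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.1, 2.0))
        b.length = float(rng.uniform(0.1, 2.0))
        parent = TreeNode(children=[b, a])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    for nd in nodes:
        nd.length = float(rng.uniform(0.1, 2.0))
    tree = TreeNode(children=nodes)
    ids = sorted(leaf for pair in leaf_distances(tree) for leaf in pair)
    ids = [f"L{i}" for i in range(n_leaves)]
    dists = leaf_distances(tree)
    D = np.zeros((n_leaves, n_leaves))
    for x in range(n_leaves):
        for y in range(x + 1, n_leaves):
            D[x, y] = D[y, x] = dists[tuple(sorted((ids[x], ids[y])))]
    return tree, ids, D
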