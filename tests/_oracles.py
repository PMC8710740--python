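"""Independent brute-force oracles used to validate the fast implementations.

Each oracle takes a deliberately different route from the library code:
dynamic programming over all position pairs for inverted repeats, naive
per-column grouping for gap patterns, exhaustive state enumeration for
parsimony, and a generic numerical minimizer for squared-change
reconstruction.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def oracle_inverted_pairs(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal inverted-repeat pairs (a, b, L), a < b, via full DP.

    seq[a:a+L] == revcomp(seq[b:b+L]). O(n^2) memory and time.
    """
    n = len(seq)
    t = seq.translate(_COMP)[::-1]
    S = np.frombuffer(seq.encode(), np.uint8)
    T = np.frombuffer(t.encode(), np.uint8)
    L = np.zeros((n + 1, n + 1), np.int32)
    for i in range(1, n + 1):
        eq = S[i - 1] == T
        L[i, 1:] = np.where(eq, L[i - 1, :-1] + 1, 0)
    out = []
    for i in range(1, n + 1):
        for j in np.nonzero(L[i] >= min_len)[0]:
            l = int(L[i, j])
            # maximal: cannot extend right in both strings
            if i < n and j < n and S[i] == T[j]:
                continue
            a = i - l
            b = n - j
            if a < b:
                out.append((a, b, l))
    return out


def oracle_best_quadripartite(seq: str, min_len: int):
    """Best (L, lsc_len, ssc_len) among disjoint, non-adjacent pairs."""
    n = len(seq)
    best = None
    for a, b, l in oracle_inverted_pairs(seq, min_len):
        gap1 = b - (a + l)
        gap2 = n - 2 * l - gap1
        if gap1 <= 0 or gap2 <= 0:
            continue
        key = (l, -min(a, b))
        if best is None or key > best[0]:
            best = (key, (l, max(gap1, gap2), min(gap1, gap2)))
    return None if best is None else best[1]


def oracle_gap_events(taxa: list[str], rows: list[str]) -> list[tuple[int, int, frozenset]]:
    """Naive per-column gap grouping: [(start, end, gap_taxa), ...]."""
    n_cols = len(rows[0])
    pats = []
    for c in range(n_cols):
        pats.append(frozenset(t for t, r in zip(taxa, rows) if r[c] == "-"))
    events = []
    start = 0
    for c in range(1, n_cols + 1):
        if c == n_cols or pats[c] != pats[start]:
            p = pats[start]
            if p and len(p) < len(taxa):
                events.append((start, c, p))
            start = c
    return events


def oracle_fitch_min_changes(tree, tip_state: dict[str, int]):
    """Exhaustive minimum-change enumeration for a binary character.

    Returns (min change count, list of frozensets of change branches —
    one per equally-parsimonious internal assignment).
    """
    internal = tree.internal_nodes
    best = None
    best_sets = []
    for assign in itertools.product([0, 1], repeat=len(internal)):
        state = {n.id: s for n, s in zip(internal, assign)}
        state.update(tip_state)
        changes = frozenset(
            n.id
            for n in tree.preorder()
            if n.parent is not None and state[n.id] != state[n.parent.id]
        )
        k = len(changes)
        if best is None or k < best:
            best = k
            best_sets = [changes]
        elif k == best and changes not in best_sets:
            best_sets.append(changes)
    return best, best_sets


def oracle_scp_minimize(tree, tip_values: dict[str, float], weighted: bool = True):
    """Squared-change objective minimized by scipy's generic optimizer."""
    from scipy.optimize import minimize

    internal = tree.internal_nodes
    idx = {n.id: i for i, n in enumerate(internal)}
    edges = []
    for n in tree.preorder():
        if n.parent is None:
            continue
        w = 1.0 / n.edge_length if weighted else 1.0
        edges.append((n.id, n.parent.id, w))

    def value(x, nid):
        return x[idx[nid]] if nid in idx else tip_values[nid]

    def objective(x):
        return sum(w * (value(x, a) - value(x, b)) ** 2 for a, b, w in edges)

    def grad(x):
        g = np.zeros(len(internal))
        for a, b, w in edges:
            d = value(x, a) - value(x, b)
            if a in idx:
                g[idx[a]] += 2 * w * d
            if b in idx:
                g[idx[b]] -= 2 * w * d
        return g

    x0 = np.full(len(internal), np.mean(list(tip_values.values())))
    res = minimize(
        objective, x0, jac=grad, method="L-BFGS-B",
        options={"ftol": 1e-18, "gtol": 1e-14, "maxiter": 10000},
    )
    return {n.id: float(res.x[idx[n.id]]) for n in internal}, float(res.fun)


def oracle_spearman(x, y) -> float:
    """Tie-corrected Spearman rho evaluated from the rank formula directly."""
    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = np.mean(rx), np.mean(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = np.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def oracle_kruskal_h(groups) -> float:
    """Tie-corrected Kruskal-Wallis H evaluated from the definition."""
    allv = [v for g in groups for v in g]
    N = len(allv)
    order = sorted(range(N), key=lambda i: allv[i])
    ranks = [0.0] * N
    i = 0
    while i < N:
        j = i
        while j + 1 < N and allv[order[j + 1]] == allv[order[i]]:
            j += 1
        r = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    h = 0.0
    pos = 0
    for g in groups:
        rsum = sum(ranks[pos : pos + len(g)])
        h += rsum**2 / len(g)
        pos += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    # tie correction
    from collections import Counter

    ties = Counter(allv)
    correction = 1 - sum(t**3 - t for t in ties.values()) / (N**3 - N)
    return h / correction


def random_rooted_tree(labels, rng, max_bl: float = 2.0):
    """Random rooted binary topology with uniform random branch lengths."""
    from plastevo.trees import Node, PhyloTree

    nodes = [Node(id=l) for l in labels]
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        counter += 1
        parent = Node(id=f"I{counter}", children=[nodes[i], nodes[j]])
        nodes[i].parent = parent
        nodes[j].parent = parent
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]

    def assign(node):
        for c in node.children:
            c.edge_length = float(rng.uniform(0.1, max_bl))
            assign(c)

    assign(root)
    return PhyloTree(root)
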