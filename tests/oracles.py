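"""Independent reference implementations used only to check the package.

These deliberately use brute force (path enumeration, all-pairs scans)
and share no code with the implementations they verify.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from tailhmm.hmm_core import STATES, TailHmm


def brute_force_posteriors(model: TailHmm, observations: list[str]) -> np.ndarray:
    """P(state_i = TAIL | obs) by summing over all 2^n hidden paths."""
    n = len(observations)
    idx = {s: i for i, s in enumerate(STATES)}
    total = 0.0
    tail_mass = np.zeros(n)
    for path in product(STATES, repeat=n):
        p = model.pi[idx[path[0]]] * model.emission(path[0], observations[0])
        for t in range(1, n):
            p *= model.A[idx[path[t - 1]], idx[path[t]]]
            p *= model.emission(path[t], observations[t])
        total += p
        for t in range(n):
            if path[t] == STATES[0]:
                tail_mass[t] += p
    return tail_mass / total


def naive_dbscan(points: list[int], eps: float, minpts: int):
    """O(n^2) DBSCAN on the integer line.

    Returns (list of member-ordinal tuples ordered by leftmost member,
    sorted outliers).  Border points join the earliest-discovered
    cluster whose core reaches them; clusters are discovered by scanning
    cores left to right.
    """
    pts = sorted(points)
    nbrs = {p: [q for q in pts if abs(p - q) <= eps] for p in pts}
    cores = [p for p in pts if len(nbrs[p]) >= minpts]
    core_set = set(cores)

    # connected components of the core graph (cores within eps are linked)
    comp: dict[int, int] = {}
    n_comp = 0
    for c in cores:  # left-to-right discovery order
        if c in comp:
            continue
        stack = [c]
        comp[c] = n_comp
        while stack:
            u = stack.pop()
            for v in nbrs[u]:
                if v in core_set and v not in comp:
                    comp[v] = n_comp
                    stack.append(v)
        n_comp += 1

    members: dict[int, set[int]] = {i: set() for i in range(n_comp)}
    outliers = []
    for p in pts:
        if p in core_set:
            members[comp[p]].add(p)
            continue
        reaching = sorted(comp[c] for c in nbrs[p] if c in core_set)
        if reaching:
            members[reaching[0]].add(p)
        else:
            outliers.append(p)
    clusters = sorted((tuple(sorted(m)) for m in members.values() if m),
                      key=lambda t: t[0])
    return clusters, outliers


def concordance_pairs(scores, labels, positive="TAIL") -> float:
    """AUC as exhaustive pair counting, ties half-weighted."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))
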