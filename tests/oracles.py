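"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately written with different primitives than the
implementation it checks (dict-based walk enumeration instead of sparse
matrices, exact rational combinatorics instead of scipy, literal path
enumeration instead of set-intersection counting, recursive SCC search
instead of networkx).
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def signed_walk_scores(edges, nodes, seed_signs, c, tail=1e-9):
    """Signed RWR by direct per-length walk-distribution enumeration.

    The stationary signed scores equal c * sum_L (1-c)^L (signed walk
    distribution after L steps), where a step follows a uniform out-edge
    (flipping the walker sign on negative edges) and a step from a dangling
    node returns the walker to the seed distribution with its original
    sign.  Lengths are enumerated until the geometric tail (1-c)^(L+1)
    drops below ``tail``.
    """
    out = {v: [] for v in nodes}
    for u, v, s in edges:
        out[u].append((v, s))
    total_w = sum(1.0 for _ in seed_signs)
    q = {v: (0.0, 0.0) for v in nodes}
    for g, s in seed_signs.items():
        pos, neg = q[g]
        if s == 1:
            q[g] = (pos + 1.0 / total_w, neg)
        else:
            q[g] = (pos, neg + 1.0 / total_w)

    def step(dist):
        nxt = {v: [0.0, 0.0] for v in nodes}
        for v, (pos, neg) in dist.items():
            if out[v]:
                share = 1.0 / len(out[v])
                for w, sign in out[v]:
                    if sign == 1:
                        nxt[w][0] += pos * share
                        nxt[w][1] += neg * share
                    else:
                        nxt[w][0] += neg * share
                        nxt[w][1] += pos * share
            else:
                # dangling: walker jumps back to its seed, original sign
                mass = pos + neg
                for u, (qp, qn) in q.items():
                    nxt[u][0] += mass * qp
                    nxt[u][1] += mass * qn
        return {v: (a, b) for v, (a, b) in nxt.items()}

    acc = {v: [0.0, 0.0] for v in nodes}
    dist = dict(q)
    weight = c
    length = 0
    while True:
        for v, (pos, neg) in dist.items():
            acc[v][0] += weight * pos
            acc[v][1] += weight * neg
        if (1 - c) ** (length + 1) < tail:
            break
        dist = step(dist)
        weight *= 1 - c
        length += 1
    return {v: (a, b) for v, (a, b) in acc.items()}


def hypergeom_upper_exact(N, K, n, k):
    """P(X >= k) by exact rational summation over the support."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return float(total)


def pathsim_bruteforce(drug_targets, annotations, a, b):
    """PathSim by literal enumeration of compound-target-function-target-
    compound path instances."""
    def count(x, y):
        paths = 0
        for t in drug_targets[x]:
            for f in annotations.get(t, set()):
                for t2 in drug_targets[y]:
                    if f in annotations.get(t2, set()):
                        paths += 1
        return paths

    maa, mbb, mab = count(a, a), count(b, b), count(a, b)
    return 2.0 * mab / (maa + mbb)


def strongly_connected_components(nodes, edges):
    """Tarjan's SCC algorithm, iterative, independent of networkx."""
    adj = {v: [] for v in nodes}
    for u, v in edges:
        adj[u].append(v)
    index = {}
    lowlink = {}
    on_stack = set()
    stack = []
    counter = [0]
    sccs = []

    for root in nodes:
        if root in index:
            continue
        work = [(root, iter(adj[root]))]
        index[root] = lowlink[root] = counter[0]
        counter[0] += 1
        stack.append(root)
        on_stack.add(root)
        while work:
            v, it = work[-1]
            advanced = False
            for w in it:
                if w not in index:
                    index[w] = lowlink[w] = counter[0]
                    counter[0] += 1
                    stack.append(w)
                    on_stack.add(w)
                    work.append((w, iter(adj[w])))
                    advanced = True
                    break
                elif w in on_stack:
                    lowlink[v] = min(lowlink[v], index[w])
            if advanced:
                continue
            work.pop()
            if work:
                parent = work[-1][0]
                lowlink[parent] = min(lowlink[parent], lowlink[v])
            if lowlink[v] == index[v]:
                comp = set()
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    comp.add(w)
                    if w == v:
                        break
                sccs.append(comp)
    return sccs
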