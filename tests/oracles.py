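"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive every quantity from first principles
(exhaustive enumeration, full sorts, stdlib arithmetic) and never call
the code paths they verify.
"""

import numpy as np
import pandas as pd


def path_counts_bruteforce(net, mode="count"):
    """Compound x term matrix by exhaustive (compound, target, term) loop."""
    cids = net.compound_ids()
    pids = sorted(t.id for t in net.terms)
    ct = {(e.compound_id, e.target_id) for e in net.ct_edges}
    tp = set(net.tp_edges)
    tids = sorted(t.id for t in net.targets)
    M = np.zeros((len(cids), len(pids)), dtype=np.int64)
    for i, c in enumerate(cids):
        for k, p in enumerate(pids):
            count = 0
            for t in tids:
                if (c, t) in ct and (t, p) in tp:
                    count += 1
            M[i, k] = count if mode == "count" else int(count > 0)
    return pd.DataFrame(M, index=cids, columns=pids)


def pathsim_bruteforce(net, mode="count"):
    """PathSim by enumerating every compound->target->term->target->compound
    chain, integer arithmetic until the final division."""
    cids = net.compound_ids()
    ct = {}
    for e in net.ct_edges:
        ct.setdefault(e.compound_id, set()).add(e.target_id)
    tp = {}
    for t, p in net.tp_edges:
        tp.setdefault(t, set()).add(p)

    def chains(x, y):
        n = 0
        for tx in ct.get(x, ()):
            for p in tp.get(tx, ()):
                for ty in ct.get(y, ()):
                    if mode == "count":
                        if p in tp.get(ty, ()):
                            n += 1
        return n

    def binary_chains(x, y):
        px = {p for t in ct.get(x, ()) for p in tp.get(t, ())}
        py = {p for t in ct.get(y, ()) for p in tp.get(t, ())}
        return len(px & py), len(px), len(py)

    S = np.zeros((len(cids), len(cids)))
    for i, x in enumerate(cids):
        for j, y in enumerate(cids):
            if mode == "count":
                pxy, pxx, pyy = chains(x, y), chains(x, x), chains(y, y)
            else:
                pxy, pxx, pyy = binary_chains(x, y)
            denom = pxx + pyy
            S[i, j] = 2.0 * pxy / denom if denom > 0 else 0.0
    return pd.DataFrame(S, index=cids, columns=cids)


def partitions_agree(labels_a, labels_b):
    """True when two labelings over the same keys induce the same partition."""
    keys = sorted(labels_a)
    if sorted(labels_b) != keys:
        return False
    seen = {}
    for k in keys:
        pair = (labels_a[k], labels_b[k])
        if labels_a[k] in seen and seen[labels_a[k]] != labels_b[k]:
            return False
        seen[labels_a[k]] = labels_b[k]
    return len(set(labels_a.values())) == len(set(labels_b.values()))


def naive_complete_linkage(D):
    """O(n^3) agglomeration recomputing every cluster-pair maximum from
    the original matrix at each step; returns merge heights and the final
    two-cluster partition trail as a list of frozenset pairs."""
    ids = list(D.index)
    V = D.to_numpy(dtype=float)
    idx = {c: i for i, c in enumerate(ids)}
    clusters = [frozenset([c]) for c in ids]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(
                    V[idx[x], idx[y]] for x in clusters[a] for y in clusters[b]
                )
                key = (d, min(min(clusters[a]), min(clusters[b])),
                       max(min(clusters[a]), min(clusters[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _, _), a, b = best
        merges.append((clusters[a], clusters[b], d))
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges
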