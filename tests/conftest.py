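import numpy as np
import pytest

from cellfp.hetnet import (
    CompoundNode,
    CompoundTargetEdge,
    FunctionTerm,
    HeteroNetwork,
    Role,
    TargetGene,
    TermSource,
)


def make_network(ct, tp, roles=None, atc=None, threshold=20.0):
    """Assemble a HeteroNetwork from edge shorthand.

    ct: iterable of (compound, target) or (compound, target, score);
    tp: iterable of (target, term). Roles default to tcm_component unless
    listed in `roles` (mapping id -> Role); `atc` maps id -> code set.
    """
    roles = roles or {}
    atc = atc or {}
    ct = [e if len(e) == 3 else (*e, 30.0) for e in ct]
    cids = sorted({c for c, _, _ in ct})
    targets = sorted({t for _, t, _ in ct})
    terms = sorted({p for _, p in tp})
    compounds = [
        CompoundNode(
            id=c,
            name=c,
            role=roles.get(c, Role.TCM_COMPONENT),
            atc_codes=frozenset(atc.get(c, ())),
        )
        for c in cids
    ]
    net = HeteroNetwork(
        compounds=compounds,
        targets=[TargetGene(t) for t in targets],
        terms=[FunctionTerm(id=p, source=TermSource.GO_BP) for p in terms],
        ct_edges=[CompoundTargetEdge(c, t, s) for c, t, s in ct],
        tp_edges=sorted(set(tp)),
        score_threshold_applied=threshold,
    )
    net.validate()
    return net


def random_network(rng, max_compounds=8, max_targets=10, max_terms=6):
    """Small random tripartite network; every compound has >=1 target,
    targets may be annotation-less (empty fingerprint rows allowed)."""
    n_c = int(rng.integers(2, max_compounds + 1))
    n_t = int(rng.integers(1, max_targets + 1))
    n_p = int(rng.integers(1, max_terms + 1))
    ct = []
    for i in range(n_c):
        picks = rng.choice(n_t, size=int(rng.integers(1, n_t + 1)), replace=False)
        for j in picks:
            ct.append((f"c{i}", f"t{j}", float(rng.uniform(21, 40))))
    used_targets = sorted({t for _, t, _ in ct})
    tp = []
    for t in used_targets:
        n_ann = int(rng.integers(0, n_p + 1))
        if n_ann:
            for p in rng.choice(n_p, size=n_ann, replace=False):
                tp.append((t, f"p{p}"))
    # ensure at least one annotation so the term list is non-trivial
    if not tp:
        tp.append((used_targets[0], "p0"))
    roles = {f"c{i}": (Role.TCM_COMPONENT if i % 2 == 0 else Role.WESTERN_DRUG)
             for i in range(n_c)}
    return make_network(ct, tp, roles=roles)


@pytest.fixture
def toy_net():
    """c1 -> {t1, t2}; t1 -> {p1}; t2 -> {p1, p2}; c2 -> {t3}; t3 -> {p1, p2}.

    Path counts: c1 row = (p1: 2, p2: 1); c2 row = (p1: 1, p2: 1).
    """
    return make_network(
        ct=[("c1", "t1"), ("c1", "t2"), ("c2", "t3")],
        tp=[("t1", "p1"), ("t2", "p1"), ("t2", "p2"), ("t3", "p1"), ("t3", "p2")],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
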