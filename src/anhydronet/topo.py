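"""Signed three-node motif census and Erdős–Rényi randomization null.

Feed-forward loops (FFLs) are ordered triples (r, m, t) with edges r→m,
m→t, r→t; coherent when the direct sign equals the product of the indirect
signs. Feedback loops (FBLs) are directed 3-cycles counted once per
rotation class; positive when the number of negative edges is even.

The null model draws G(n, m) digraphs (exactly m directed edges, no
self-loops, 2-cycles allowed) with i.i.d. binomial edge signs, and the
per-class p-value is the fraction of draws whose motif count strictly
exceeds the observed one — so p = 0 is attainable when the observed count
is the maximum the parameters allow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grn import SignedNetwork

MOTIF_CLASSES = ("coherent_ffl", "incoherent_ffl", "positive_fbl", "negative_fbl")


@dataclass
class MotifCensus:
    counts: dict[str, int]
    instances: dict[str, list[tuple]] = field(default_factory=dict)


@dataclass
class NullTestResult:
    observed: dict[str, int]
    null_counts: dict[str, np.ndarray]
    p_values: dict[str, float]
    significant: dict[str, bool]
    n_nodes: int
    n_edges: int
    positive_ratio: float
    iterations: int
    seed: int


def _adjacency(edges: dict) -> tuple[dict, dict, dict]:
    succ: dict = {}
    pred: dict = {}
    sign: dict = {}
    for (u, v), s in edges.items():
        succ.setdefault(u, set()).add(v)
        pred.setdefault(v, set()).add(u)
        sign[(u, v)] = s
    return succ, pred, sign


def _census(edges: dict[tuple, int], keep_instances: bool) -> MotifCensus:
    succ, pred, sign = _adjacency(edges)
    counts = dict.fromkeys(MOTIF_CLASSES, 0)
    inst: dict[str, list] = {c: [] for c in MOTIF_CLASSES}

    for m in succ.keys() | pred.keys():
        for r in pred.get(m, ()):
            for t in succ.get(m, ()):
                if t == r or (r, t) not in sign:
                    continue
                coherent = sign[(r, t)] == sign[(r, m)] * sign[(m, t)]
                cls = "coherent_ffl" if coherent else "incoherent_ffl"
                counts[cls] += 1
                if keep_instances:
                    inst[cls].append(((r, m, t),
                                      (sign[(r, m)], sign[(m, t)], sign[(r, t)])))

    for (u, v) in sign:
        for w in succ.get(v, ()):
            if w == u or (w, u) not in sign:
                continue
            if not (u < v and u < w):  # one representative per rotation class
                continue
            n_neg = sum(s < 0 for s in (sign[(u, v)], sign[(v, w)], sign[(w, u)]))
            cls = "positive_fbl" if n_neg % 2 == 0 else "negative_fbl"
            counts[cls] += 1
            if keep_instances:
                inst[cls].append(((u, v, w),
                                  (sign[(u, v)], sign[(v, w)], sign[(w, u)])))
    return MotifCensus(counts, inst if keep_instances else {c: [] for c in MOTIF_CLASSES})


def census_motifs(net: SignedNetwork | dict) -> MotifCensus:
    """Count and list coherent/incoherent FFLs and positive/negative FBLs.

    Accepts a :class:`SignedNetwork` or a plain ``{(u, v): sign}`` mapping.
    A triple may be both an FFL and part of a 3-cycle; the classes are not
    mutually exclusive.
    """
    if isinstance(net, SignedNetwork):
        edges = {k: e.sign for k, e in net.edges.items()}
    else:
        edges = {k: int(v) for k, v in net.items()}
    return _census(edges, keep_instances=True)


def _sample_gnm_signed(n: int, m: int, positive_ratio: float,
                       rng: np.random.Generator) -> dict[tuple, int]:
    pairs = rng.choice(n * (n - 1), size=m, replace=False)
    signs = np.where(rng.random(m) < positive_ratio, 1, -1)
    edges = {}
    for k, s in zip(pairs, signs):
        i, r = divmod(int(k), n - 1)
        j = r if r < i else r + 1
        edges[(i, j)] = int(s)
    return edges


def erdos_renyi_null_test(observed: MotifCensus | dict, n_nodes: int, n_edges: int,
                          positive_ratio: float, iterations: int = 10_000,
                          seed: int = 0, greater_or_equal: bool = False) -> NullTestResult:
    """Randomization test of motif counts against signed G(n, m) digraphs.

    Each draw fixes the node and edge counts of the observed network, signs
    edges +1 with probability ``positive_ratio`` and recomputes the census.
    p = #(null > observed) / iterations per class (strictly greater; set
    ``greater_or_equal`` for the >= variant with +1 smoothing).
    """
    if n_edges > n_nodes * (n_nodes - 1):
        raise ValueError("more edges than ordered node pairs")
    if iterations < 1:
        raise ValueError("need at least one iteration")
    obs = observed.counts if isinstance(observed, MotifCensus) else dict(observed)
    rng = np.random.default_rng(seed)
    null = {c: np.zeros(iterations, dtype=np.int64) for c in MOTIF_CLASSES}
    for it in range(iterations):
        edges = _sample_gnm_signed(n_nodes, n_edges, positive_ratio, rng)
        counts = _census(edges, keep_instances=False).counts
        for c in MOTIF_CLASSES:
            null[c][it] = counts[c]
    p = {}
    for c in MOTIF_CLASSES:
        if greater_or_equal:
            p[c] = float((1 + (null[c] >= obs.get(c, 0)).sum()) / (1 + iterations))
        else:
            p[c] = float((null[c] > obs.get(c, 0)).mean())
    return NullTestResult(
        observed={c: int(obs.get(c, 0)) for c in MOTIF_CLASSES},
        null_counts=null, p_values=p,
        significant={c: p[c] < 0.05 for c in MOTIF_CLASSES},
        n_nodes=n_nodes, n_edges=n_edges, positive_ratio=positive_ratio,
        iterations=iterations, seed=seed)
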