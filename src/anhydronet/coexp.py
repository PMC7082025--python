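"""Coexpression module detection in the WGCNA tradition.

Adjacency is |Pearson correlation|^beta (unsigned convention), with the
soft power beta chosen as the smallest exponent whose connectivity
distribution fits a scale-free law with signed R^2 above 0.75 (connectivity
binned into equal-width bins; signed R^2 = -sign(slope) * R^2). Adjacency
is converted to the Ravasz-type unsigned topological overlap measure, genes
are clustered by average linkage on 1 - TOM, and the minimum module size is
chosen to maximize the Calinski–Harabasz pseudo-F over a candidate range.
GO enrichment per module is a one-sided Fisher exact test (hypergeometric
tail), uncorrected, at p < 0.05.

The dynamic tree cut of the original workflow is replaced by a documented
static procedure: cut heights are scanned over the dendrogram merge
heights; for a candidate minimum size, clusters below size are dissolved
(members join the profile-correlation-nearest retained module when that
correlation is positive, otherwise the designated "grey" unassigned
module), and the height maximizing pseudo-F on the assigned genes is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

UNASSIGNED = "grey"

# WGCNA-style module palette, assigned to modules by decreasing size.
_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white",
]


@dataclass
class SoftPowerSelection:
    table: pd.DataFrame       # per power: signed_r_squared, slope, mean_k
    selected_power: int
    r2_threshold: float


@dataclass
class TomMatrix:
    tom: np.ndarray
    dissimilarity: np.ndarray
    gene_ids: list[str]


@dataclass
class ModulePartition:
    assignments: dict[str, str]
    profiles: pd.DataFrame        # module x sample mean Z-score
    min_cluster_size: int
    pseudo_f: pd.Series           # best pseudo-F per candidate size
    cut_height: float
    sizes: dict[str, int] = field(default_factory=dict)

    def genes_in(self, module: str) -> list[str]:
        return [g for g, m in self.assignments.items() if m == module]

    @property
    def modules(self) -> list[str]:
        return [m for m in dict.fromkeys(self.assignments.values())
                if m != UNASSIGNED]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.assignments), "module": list(self.assignments.values())})


class SoftPowerError(RuntimeError):
    pass


def scale_free_r2_binned(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit index of a connectivity vector.

    Bins k into equal-width bins over its range, regresses log10 p(bin) on
    log10 mean(k) and returns (signed R^2, slope) with
    signed R^2 = -sign(slope) * R^2. Empty bins are dropped.
    """
    k = np.asarray(connectivity, float)
    k = k[k > 0]
    if k.size < 2:
        return np.nan, np.nan
    n_bins = min(n_bins, len(np.unique(k)))
    if n_bins < 2:
        return np.nan, np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] += 1e-12
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    dk, pk = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        dk.append(members.mean())
        pk.append(members.size / k.size)
    if len(dk) < 2:
        return np.nan, np.nan
    lx, ly = np.log10(dk), np.log10(pk)
    slope, _, r, _, _ = stats.linregress(lx, ly)
    return float(-np.sign(slope) * r**2), float(slope)


def select_soft_power(expression: pd.DataFrame, powers=range(1, 21),
                      r2_threshold: float = 0.75, n_bins: int = 10) -> SoftPowerSelection:
    """Smallest power whose |cor|^power connectivity is scale-free
    (signed R^2 > ``r2_threshold``)."""
    x = expression.to_numpy(float)
    if x.shape[0] < 3:
        raise ValueError("need at least three genes")
    corr = np.corrcoef(x)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    rows = []
    selected = None
    for beta in powers:
        adj = np.abs(corr) ** beta
        k = adj.sum(axis=1)
        signed_r2, slope = scale_free_r2_binned(k, n_bins)
        rows.append({"power": beta, "signed_r_squared": signed_r2,
                     "slope": slope, "mean_k": float(k.mean())})
        if selected is None and np.isfinite(signed_r2) and signed_r2 > r2_threshold:
            selected = int(beta)
    table = pd.DataFrame(rows).set_index("power")
    if selected is None:
        best = table["signed_r_squared"].idxmax()
        raise SoftPowerError(
            f"no power reaches signed R^2 > {r2_threshold} "
            f"(best: power {best} at {table.loc[best, 'signed_r_squared']:.3f})")
    return SoftPowerSelection(table, selected, r2_threshold)


def adjacency_matrix(expression: pd.DataFrame, power: int) -> np.ndarray:
    """Unsigned adjacency |cor|^power with zero diagonal."""
    corr = np.corrcoef(expression.to_numpy(float))
    corr = np.nan_to_num(corr, nan=0.0)
    adj = np.abs(corr) ** power
    np.fill_diagonal(adj, 0.0)
    return adj


def tom_dissimilarity(adjacency: np.ndarray, gene_ids=None) -> TomMatrix:
    """Unsigned topological overlap and its dissimilarity 1 - TOM.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) off the
    diagonal; TOM_ii = 1.
    """
    a = np.asarray(adjacency, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if (a < -1e-12).any() or (a > 1 + 1e-12).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = np.clip(a, 0.0, 1.0)
    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    ids = list(gene_ids) if gene_ids is not None else [str(i) for i in range(len(a))]
    return TomMatrix(tom, 1.0 - tom, ids)


def pseudo_f(profiles: np.ndarray, labels: np.ndarray) -> float:
    """Calinski–Harabasz index (BSS/(k-1)) / (WSS/(n-k)); undefined for k < 2."""
    from sklearn.metrics import calinski_harabasz_score

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("pseudo-F needs at least two clusters")
    x = np.asarray(profiles, float)
    if x.ndim == 1:
        x = x[:, None]
    return float(calinski_harabasz_score(x, labels))


def _dissolve_small(labels: np.ndarray, min_size: int, profiles: np.ndarray
                    ) -> tuple[np.ndarray, int]:
    """Dissolve clusters below min_size; members join the nearest retained
    cluster by profile correlation when positive, else -1 (unassigned).
    Returns (assignments with -1 for unassigned, number of retained clusters)."""
    ids, counts = np.unique(labels, return_counts=True)
    retained = ids[counts >= min_size]
    if len(retained) == 0:
        return np.full(len(labels), -1), 0
    out = np.where(np.isin(labels, retained), labels, -1)
    loose = np.flatnonzero(out == -1)
    if loose.size:
        n_col = profiles.shape[1]
        means = np.vstack([profiles[out == c].mean(axis=0) for c in retained])
        pc = profiles[loose] - profiles[loose].mean(axis=1, keepdims=True)
        ps = pc.std(axis=1)
        mc = means - means.mean(axis=1, keepdims=True)
        ms = mc.std(axis=1)
        denom = np.outer(ps, ms) * n_col
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.where(denom > 0, (pc @ mc.T) / denom, -np.inf)
        best = corr.argmax(axis=1)
        best_r = corr[np.arange(loose.size), best]
        out[loose] = np.where(best_r > 0, retained[best], -1)
    return out, len(retained)


def cluster_modules(dissimilarity: TomMatrix, profiles: pd.DataFrame,
                    size_range=range(1, 201)) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with pseudo-F-selected minimum
    module size.

    The dendrogram is built once; every merge height is a candidate cut.
    For each candidate minimum size, the height maximizing pseudo-F (on the
    Z-score profiles of assigned genes) subject to all retained clusters
    being at least that size is used; the selected size is the pseudo-F
    argmax (ties to the smallest size). Leftover genes form the "grey"
    unassigned module.
    """
    genes = dissimilarity.gene_ids
    n = len(genes)
    if n < 2:
        raise ValueError("need at least two genes")
    prof = profiles.loc[genes].to_numpy(float)
    condensed = squareform(dissimilarity.dissimilarity, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    heights = np.unique(link[:, 2])

    labels_by_height = [hierarchy.fcluster(link, t=h, criterion="distance")
                        for h in heights]

    cache: dict[tuple, tuple[float, np.ndarray]] = {}

    def evaluate(h_idx: int, min_size: int):
        labels = labels_by_height[h_idx]
        ids, counts = np.unique(labels, return_counts=True)
        retained = tuple(sorted(ids[counts >= min_size]))
        key = (h_idx, retained)
        if key in cache:
            return cache[key]
        assigned, k = _dissolve_small(labels, min_size, prof)
        k_eff = k + int((assigned == -1).any())
        if k < 2 or len(assigned) <= k_eff:
            cache[key] = (np.nan, assigned)
            return cache[key]
        try:
            # unassigned genes count as one (heterogeneous) cluster so that
            # dissolving a real module cannot inflate the index
            score = pseudo_f(prof, assigned)
        except ValueError:
            score = np.nan
        cache[key] = (score, assigned)
        return cache[key]

    best_per_size: dict[int, tuple[float, int]] = {}
    for s in size_range:
        if s > n:
            continue
        best = (np.nan, -1)
        for h_idx in range(len(heights)):
            score, _ = evaluate(h_idx, s)
            if np.isnan(score):
                continue
            if np.isnan(best[0]) or score > best[0]:
                best = (score, h_idx)
        best_per_size[s] = best

    valid = {s: b for s, b in best_per_size.items() if not np.isnan(b[0])}
    if not valid:
        raise RuntimeError("no candidate size yields a valid clustering")
    selected_size = min(valid, key=lambda s: (-valid[s][0], s))
    score, h_idx = valid[selected_size]
    _, assigned = evaluate(h_idx, selected_size)

    # name modules by decreasing size
    ids, counts = np.unique(assigned[assigned != -1], return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    palette = {c: (_COLORS[i] if i < len(_COLORS) else f"module{i+1}")
               for i, c in enumerate(order)}
    assignments = {g: (palette[c] if c != -1 else UNASSIGNED)
                   for g, c in zip(genes, assigned)}

    prof_rows = {}
    for module in list(palette.values()) + ([UNASSIGNED] if (assigned == -1).any() else []):
        members = [g for g, m in assignments.items() if m == module]
        prof_rows[module] = profiles.loc[members].mean(axis=0)
    module_profiles = pd.DataFrame(prof_rows).T
    module_profiles.columns = profiles.columns

    pf = pd.Series({s: b[0] for s, b in best_per_size.items()}, name="pseudo_f")
    sizes = {m: len([g for g, mm in assignments.items() if mm == m])
             for m in dict.fromkeys(assignments.values())}
    return ModulePartition(assignments, module_profiles, selected_size, pf,
                           float(heights[h_idx]), sizes)


@dataclass
class GoEnrichment:
    table: pd.DataFrame       # module, go_id, in_annotated, module_size, p, enriched
    representative: pd.DataFrame  # minimum-p GO per module


def go_enrichment(partition: ModulePartition, go_annotation: dict[str, set],
                  universe=None, alpha: float = 0.05) -> GoEnrichment:
    """One-sided Fisher exact (hypergeometric upper tail) per (module, GO).

    p = P(X >= observed in-module annotated count) with margins fixed by the
    module size and the universe-wide annotation count.
    """
    if universe is None:
        universe = set(partition.assignments)
    universe = set(universe)
    if not set(partition.assignments) <= universe:
        raise ValueError("universe must contain all module genes")
    n_universe = len(universe)
    go_members: dict[str, set] = {}
    for g in universe:
        for go in go_annotation.get(g, ()):
            go_members.setdefault(go, set()).add(g)

    rows = []
    for module in partition.modules:
        members = set(partition.genes_in(module))
        n_mod = len(members)
        for go, annotated in sorted(go_members.items()):
            a = len(members & annotated)
            # hypergeometric tail P(X >= a) == one-sided Fisher
            p = float(stats.hypergeom.sf(a - 1, n_universe, len(annotated), n_mod))
            rows.append({"module": module, "go_id": go, "in_annotated": a,
                         "module_size": n_mod, "go_size": len(annotated),
                         "p_value": p, "enriched": p < alpha})
    table = pd.DataFrame(rows)
    if table.empty:
        warnings.warn("no GO terms to test")
        return GoEnrichment(table, table)
    rep = table.loc[table.groupby("module")["p_value"].idxmin()]
    return GoEnrichment(table, rep.reset_index(drop=True))
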