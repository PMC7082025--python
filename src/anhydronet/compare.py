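"""Cross-species network comparison and contraction to the tolerance core.

The inferred network is compared to a reference species' transcriptional
regulatory network through a protein-similarity map (hits kept at
e-value < 1e-15). An inferred edge is conserved when some reference
homolog of its source reaches some homolog of its target by a directed
path (direct or indirect regulation). The network is then contracted to
the species-specific core: TFs without reference homologs that directly
regulate at least one coexpression module, retained when they are (1) most
upstream (zero in-degree), (2) FFL components, or (3) the designated HSF
plus shortest-path connectors between retained TFs; only species-specific
edges are kept, edge-sharing FFLs collapse into block nodes, and TFs
strictly between HSF and a block are elided in favor of a direct edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .grn import SignedNetwork
from .topo import census_motifs

BLAST6_COLUMNS = ["query", "subject", "pident", "length", "mismatch", "gapopen",
                  "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


@dataclass
class HomologyMap:
    pairs: dict[str, set[str]]
    e_values: dict[tuple[str, str], float]
    n_skipped: int = 0

    def homologs(self, query: str) -> set[str]:
        return self.pairs.get(query, set())

    def has_homolog(self, query: str) -> bool:
        return bool(self.pairs.get(query))


def load_homology(hit_table, e_threshold: float = 1e-15) -> HomologyMap:
    """Retain similarity hits with e-value strictly below ``e_threshold``.

    ``hit_table`` is a path or DataFrame in the standard 12-column tabular
    similarity-hit layout; malformed rows are skipped and counted.
    """
    if isinstance(hit_table, pd.DataFrame):
        rows = hit_table.itertuples(index=False)
    else:
        rows = pd.read_csv(hit_table, sep="\t", header=None,
                           comment="#").itertuples(index=False)
    pairs: dict[str, set[str]] = {}
    evalues: dict[tuple[str, str], float] = {}
    skipped = 0
    for row in rows:
        try:
            query, subject = str(row[0]), str(row[1])
            evalue = float(row[10])
        except (IndexError, ValueError, TypeError):
            skipped += 1
            continue
        if not np.isfinite(evalue) or evalue < 0:
            skipped += 1
            continue
        if evalue < e_threshold:
            pairs.setdefault(query, set()).add(subject)
            evalues[(query, subject)] = min(evalues.get((query, subject), np.inf),
                                            evalue)
    if skipped:
        warnings.warn(f"skipped {skipped} malformed similarity rows")
    return HomologyMap(pairs, evalues, skipped)


def load_reference_network(edges) -> nx.DiGraph:
    """Reference regulatory network from an edge list (TSV path, DataFrame,
    or iterable of (source, target))."""
    from pathlib import Path

    g = nx.DiGraph()
    if isinstance(edges, (str, bytes, Path)) or hasattr(edges, "read"):
        df = pd.read_csv(edges, sep="\t", header=None, comment="#")
        it = df.iloc[:, :2].itertuples(index=False)
    elif isinstance(edges, pd.DataFrame):
        it = edges.iloc[:, :2].itertuples(index=False)
    else:
        it = edges
    for u, v in it:
        if u != v:
            g.add_edge(str(u), str(v))
    return g


def flag_conserved_edges(net: SignedNetwork, ref: nx.DiGraph,
                         hom: HomologyMap, max_path_length: int | None = None
                         ) -> dict[tuple[str, str], bool]:
    """Edge (u, v) is conserved iff some homolog of u reaches some homolog of
    v along a directed reference path of length >= 1 (unbounded by default)."""
    reach_cache: dict[str, set[str]] = {}

    def reachable(a: str) -> set[str]:
        if a not in reach_cache:
            if a not in ref:
                reach_cache[a] = set()
            elif max_path_length is None:
                reach_cache[a] = set(nx.descendants(ref, a))
            else:
                lengths = nx.single_source_shortest_path_length(
                    ref, a, cutoff=max_path_length)
                reach_cache[a] = {n for n, d in lengths.items() if d >= 1}
        return reach_cache[a]

    flags = {}
    for (u, v) in net.edges:
        targets = hom.homologs(v)
        flags[(u, v)] = any(targets & reachable(a) for a in hom.homologs(u))
    return flags


@dataclass
class ContractedNetwork:
    nodes: set[str]                         # retained plain TFs
    blocks: dict[str, frozenset] = field(default_factory=dict)
    edges: set[tuple[str, str]] = field(default_factory=set)
    retention_reason: dict[str, str] = field(default_factory=dict)
    module_attachments: dict[str, set[str]] = field(default_factory=dict)

    @property
    def all_nodes(self) -> set[str]:
        return self.nodes | set(self.blocks)

    def in_degree_zero(self) -> set[str]:
        with_in = {v for _, v in self.edges}
        return {n for n in self.all_nodes if n not in with_in}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n, kind="tf", reason=self.retention_reason.get(n, ""))
        for b, members in self.blocks.items():
            g.add_node(b, kind="ffl_block", members=",".join(sorted(members)))
        g.add_edges_from(self.edges)
        return g


def _merge_overlapping_ffls(ffl_instances) -> list[set]:
    """Union FFLs that share at least one edge into blocks."""
    items = []
    for (triple, _signs) in ffl_instances:
        r, m, t = triple
        items.append((frozenset({(r, m), (m, t), (r, t)}), set(triple)))
    blocks: list[tuple[set, set]] = []   # (edge set, node set)
    for edges, nodes in items:
        hits = [b for b in blocks if b[0] & edges]
        for b in hits:
            blocks.remove(b)
        merged_edges = set(edges)
        merged_nodes = set(nodes)
        for be, bn in hits:
            merged_edges |= be
            merged_nodes |= bn
        blocks.append((merged_edges, merged_nodes))
    return [nodes for _, nodes in blocks]


def contract_network(net: SignedNetwork, conserved: dict[tuple[str, str], bool],
                     hom: HomologyMap, module_regulators: dict[str, set[str]],
                     hsf_id: str | None) -> ContractedNetwork:
    """Contract to the species-specific regulatory core.

    ``module_regulators`` maps TF id -> modules it was called to regulate
    directly. Candidates are TFs without reference homologs that regulate at
    least one module; retention follows criteria (1) most upstream — zero
    in-degree within the species-specific subnetwork induced by the
    candidate TFs (the network being contracted), (2) FFL membership among
    candidate species-specific edges, (3) HSF plus shortest-directed-path
    connectors between retained TFs. Edge-sharing FFLs become single block
    nodes and connectors strictly between HSF and a block are elided with a
    direct HSF→block edge.
    """
    species_edges = {k: e.sign for k, e in net.edges.items()
                     if not conserved.get(k, False)}
    g_spec = nx.DiGraph()
    g_spec.add_nodes_from(net.nodes)
    g_spec.add_edges_from(species_edges)

    candidates = {tf for tf in net.nodes
                  if not hom.has_homolog(tf) and module_regulators.get(tf)}
    if not candidates:
        warnings.warn("empty candidate set: contraction is empty")
        return ContractedNetwork(set())

    cand_edges = {(u, v): s for (u, v), s in species_edges.items()
                  if u in candidates and v in candidates}
    in_deg = {n: 0 for n in candidates}
    for (_u, v) in cand_edges:
        in_deg[v] += 1
    crit1 = {tf for tf in candidates if in_deg[tf] == 0}
    census = census_motifs(cand_edges)
    ffl_instances = census.instances["coherent_ffl"] + census.instances["incoherent_ffl"]
    crit2 = {n for (triple, _s) in ffl_instances for n in triple}

    core = crit1 | crit2
    retained = set(core)
    reasons = {n: "most_upstream" for n in crit1}
    for n in crit2:
        reasons[n] = (reasons[n] + "+ffl") if n in reasons else "ffl"

    if hsf_id is not None:
        if hsf_id in net.nodes:
            retained.add(hsf_id)
            reasons.setdefault(hsf_id, "hsf")
        else:
            warnings.warn(f"hsf id {hsf_id!r} absent from network")
            hsf_id = None

    # criterion 3: connectors join the criterion-1/2 nodes; HSF is added as a
    # node but is not itself a path anchor
    connectors: set[str] = set()
    anchor = sorted(core)
    for u in anchor:
        for v in anchor:
            if u == v:
                continue
            try:
                path = nx.shortest_path(g_spec, u, v)
            except nx.NetworkXNoPath:
                continue
            connectors |= set(path[1:-1]) - retained
    for n in connectors:
        reasons.setdefault(n, "connector")
    retained |= connectors

    kept_edges = {(u, v) for (u, v) in species_edges
                  if u in retained and v in retained}

    blocks_nodes = _merge_overlapping_ffls(
        [(t, s) for (t, s) in ffl_instances if set(t) <= retained])
    blocks: dict[str, frozenset] = {}
    node_to_block: dict[str, str] = {}
    for i, members in enumerate(sorted(blocks_nodes, key=lambda s: sorted(s)), 1):
        bid = f"FFL{i}"
        blocks[bid] = frozenset(members)
        for n in members:
            node_to_block[n] = bid

    def rename(n: str) -> str:
        return node_to_block.get(n, n)

    plain = {n for n in retained if n not in node_to_block}
    edges = {(rename(u), rename(v)) for (u, v) in kept_edges
             if rename(u) != rename(v)}

    # elide connectors strictly between HSF and a block
    if hsf_id is not None and blocks:
        contracted = nx.DiGraph()
        contracted.add_nodes_from(plain | set(blocks))
        contracted.add_edges_from(edges)
        hsf_node = rename(hsf_id)
        removable = set()
        for x in list(plain - {hsf_id} - crit1 - crit2):
            if x not in contracted:
                continue
            from_hsf = hsf_node in contracted and nx.has_path(contracted, hsf_node, x)
            to_block = any(nx.has_path(contracted, x, b) for b in blocks)
            if from_hsf and to_block:
                removable.add(x)
        if removable:
            reach_blocks = set()
            for x in removable:
                for b in blocks:
                    if nx.has_path(contracted, x, b):
                        reach_blocks.add(b)
            plain -= removable
            edges = {(u, v) for (u, v) in edges
                     if u not in removable and v not in removable}
            if hsf_node in plain | set(blocks):
                edges |= {(hsf_node, b) for b in reach_blocks if hsf_node != b}

    attachments: dict[str, set[str]] = {}
    for tf, mods in module_regulators.items():
        node = rename(tf)
        if node in plain or node in blocks:
            attachments.setdefault(node, set()).update(mods)

    return ContractedNetwork(plain, blocks, edges, reasons, attachments)
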