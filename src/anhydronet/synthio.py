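"""Synthetic data with planted structure for every pipeline stage.

The generator emulates the study design this pipeline targets: two
conditions (trehalose pretreatment, rehydration) sampled as replicated
time courses; a signed lag-1 linear regulatory system among transcription
factors with optional planted three-node motifs and a zero-in-degree
master regulator; TF-driven coexpressed target modules; background genes
with constant means (true negatives for differential expression);
negative-binomial count noise; and promoter sequences with binding sites
planted in module genes. Comparison-stage inputs (a reference network and
a similarity hit table) are derived from the planted truth.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grn import Edge, SignedNetwork
from .prep import CountMatrix, TimeSeriesDesign
from .regcall import Pwm, write_meme

MOTIF_CLASSES = ("coherent_ffl", "incoherent_ffl", "positive_fbl", "negative_fbl")
CONDITIONS = ("trehalose", "rehydration")
_COND_PREFIX = {"trehalose": "T", "rehydration": "R"}

TF_GO = "GO:0003700"


@dataclass
class PlantedNetwork:
    """Ground-truth signed regulatory network among TFs."""

    tf_ids: list[str]
    edges: list[tuple[str, str, int, float]]     # source, target, sign, weight
    planted_motifs: list[tuple[str, tuple[str, str, str]]] = field(default_factory=list)
    master_regulator: str | None = None

    def __post_init__(self) -> None:
        seen = set()
        for u, v, s, _w in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u}->{v}")
            if (u, v) in seen:
                raise ValueError(f"duplicate edge {u}->{v}")
            if s not in (1, -1):
                raise ValueError("edge signs must be +1 or -1")
            seen.add((u, v))
        sign_of = {(u, v): s for u, v, s, _ in self.edges}
        for cls, (a, b, c) in self.planted_motifs:
            if cls in ("coherent_ffl", "incoherent_ffl"):
                triple = [(a, b), (b, c), (a, c)]
            else:
                triple = [(a, b), (b, c), (c, a)]
            if any(e not in sign_of for e in triple):
                raise ValueError(f"motif {cls} {a, b, c}: edges missing")
            prod = np.prod([sign_of[e] for e in triple])
            want = 1 if cls in ("coherent_ffl", "positive_fbl") else -1
            if prod != want:
                raise ValueError(f"motif {cls} {a, b, c}: signs inconsistent")
        if self.master_regulator is not None:
            if any(v == self.master_regulator for _, v, _, _ in self.edges):
                raise ValueError("master regulator must have zero in-degree")

    def sign_of(self, u: str, v: str) -> int:
        for uu, vv, s, _ in self.edges:
            if (uu, vv) == (u, v):
                return s
        raise KeyError((u, v))

    def to_signed_network(self) -> SignedNetwork:
        net = SignedNetwork()
        for u, v, s, w in self.edges:
            net.edges[(u, v)] = Edge(s, w, ("truth",), float(s))
        return net

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges,
                            columns=["source", "target", "sign", "weight"])


def _draw_sign(rng: np.random.Generator, positive_ratio: float) -> int:
    return 1 if rng.random() < positive_ratio else -1


def generate_planted_network(n_tf: int, n_extra_edges: int, positive_ratio: float,
                             motif_requests, seed: int, master: bool = False,
                             connect: bool = False,
                             protect_motifs: bool = False) -> PlantedNetwork:
    """Random signed digraph with each requested motif planted on a disjoint
    node triple.

    Remaining edges are sampled uniformly without self-loops or duplicates;
    signs beyond motif constraints are +1 with probability
    ``positive_ratio``. With ``master``, the first TF gets zero in-degree
    and an outgoing edge into each planted triple. With ``connect``, every
    other TF receives at least one regulator (a cascade rooted at the
    network's sources, as in a regulatory hierarchy). Sampled edge weights
    are scaled by 1/sqrt(in-degree) and the whole system is rescaled if
    needed so the lag-1 dynamics stay stable. ``protect_motifs`` keeps
    extra edges out of the planted triples' nodes so every motif member's
    regulatory input is exactly its planted structure.
    """
    motif_requests = list(motif_requests)
    if not 0.0 <= positive_ratio <= 1.0:
        raise ValueError("positive_ratio must be a probability")
    reserved = 3 * len(motif_requests) + (1 if master else 0)
    if n_tf < max(reserved, 2):
        raise ValueError(f"n_tf={n_tf} too small for {len(motif_requests)} motifs")
    for cls in motif_requests:
        if cls not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {cls!r}")

    rng = np.random.default_rng(seed)
    tf_ids = [f"TF{i:03d}" for i in range(n_tf)]
    master_id = tf_ids[0] if master else None
    pool = tf_ids[1:] if master else tf_ids

    edges: dict[tuple[str, str], int] = {}
    motifs = []
    offset = 0
    for cls in motif_requests:
        a, b, c = pool[offset:offset + 3]
        offset += 3
        s1 = _draw_sign(rng, positive_ratio)
        s2 = _draw_sign(rng, positive_ratio)
        s3 = s1 * s2 if cls in ("coherent_ffl", "positive_fbl") else -s1 * s2
        if cls in ("coherent_ffl", "incoherent_ffl"):
            triple_edges = [((a, b), s1), ((b, c), s2), ((a, c), s3)]
        else:
            triple_edges = [((a, b), s1), ((b, c), s2), ((c, a), s3)]
        for e, s in triple_edges:
            edges[e] = s
        motifs.append((cls, (a, b, c)))

    if master:
        heads = [t[1][0] for t in motifs]
        if not heads:
            heads = list(rng.choice(pool, size=min(3, len(pool)), replace=False))
            for h in heads:
                edges.setdefault((master_id, h), 1)
        elif protect_motifs:
            # hierarchy: master feeds the first motif; each motif's head is
            # fed by the previous motif's tail, so signal flows loop to loop
            edges.setdefault((master_id, heads[0]), 1)
            for k in range(1, len(motifs)):
                prev_tail = motifs[k - 1][1][-1]
                edges.setdefault((prev_tail, heads[k]),
                                 _draw_sign(rng, positive_ratio))
        else:
            for h in heads:
                edges.setdefault((master_id, h), 1)

    capacity = n_tf * (n_tf - 1) - (n_tf - 1 if master else 0)
    if len(edges) + n_extra_edges > capacity:
        raise ValueError(
            f"infeasible edge count: {len(edges) + n_extra_edges} requested, "
            f"{capacity} ordered pairs available")

    motif_nodes = {n for _cls, triple in motifs for n in triple}
    protected = motif_nodes if protect_motifs else set()

    if connect:
        # cascade: every non-master TF gets a regulator from earlier in the
        # node order (acyclic fill-in; planted motif cycles are unaffected)
        indeg0 = [v for v in tf_ids
                  if v != master_id and v not in protected
                  and not any(e[1] == v for e in edges)]
        for v in indeg0:
            pos = tf_ids.index(v)
            sources = tf_ids[:pos] if pos > 0 else tf_ids[1:2]
            u = sources[int(rng.integers(len(sources)))] if sources else None
            if u is not None and u != v and (u, v) not in edges:
                edges[(u, v)] = _draw_sign(rng, positive_ratio)

    allowed = [(u, v) for u in tf_ids for v in tf_ids
               if u != v and v != master_id and v not in protected
               and (u, v) not in edges]
    if n_extra_edges:
        picks = rng.choice(len(allowed), size=n_extra_edges, replace=False)
        for k in sorted(picks):
            e = allowed[int(k)]
            edges[e] = _draw_sign(rng, positive_ratio)

    indeg: dict[str, int] = {}
    for (_u, v) in edges:
        indeg[v] = indeg.get(v, 0) + 1
    idx = {t: i for i, t in enumerate(tf_ids)}
    raw = {(u, v): float(rng.uniform(0.5, 0.9)) / np.sqrt(indeg[v])
           for (u, v) in edges}
    for (u, v) in raw:
        if u == master_id:
            raw[(u, v)] = 0.9 / np.sqrt(indeg[v])  # master drive dominates
    # guard the lag-1 system's stability: spectral radius of |W| below 0.95
    w_abs = np.zeros((n_tf, n_tf))
    for (u, v), w in raw.items():
        w_abs[idx[v], idx[u]] = w
    sr = float(np.max(np.abs(np.linalg.eigvals(w_abs))))
    scale = min(1.0, 0.95 / sr) if sr > 0 else 1.0
    edge_list = [(u, v, s, raw[(u, v)] * scale) for (u, v), s in edges.items()]
    return PlantedNetwork(tf_ids, edge_list, motifs, master_id)


@dataclass
class SimulationConfig:
    """Study-design parameters for the count simulator.

    Defaults mirror the emulated design: 5 time points per condition in
    biological triplicate; mild latent noise and moderate NB
    overdispersion. Root TFs (no regulators) follow an AR(1) with
    coefficient ``dynamics_coefficient`` and unit-scale innovations
    (``root_innovation_sd``): the weak persistence keeps an upstream driver
    time-varying while leaving it unpredictable from its descendants'
    lagged values, so a planted master stays most-upstream under inference.
    """

    n_timepoints: int = 5
    n_replicates: int = 3
    dynamics_coefficient: float = 0.3
    root_innovation_sd: float = 1.0
    noise_sd: float = 0.1
    nb_dispersion: float = 0.05
    library_size: int = 1_000_000
    gene_length_bp: int = 1000
    count_baseline: float = 2.0
    replicate_innovation_fraction: float = 0.5
    gene_noise_range: tuple = (0.4, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 3:
            raise ValueError("need at least three time points")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if not 0.0 <= self.replicate_innovation_fraction <= 1.0:
            raise ValueError("replicate_innovation_fraction must be in [0, 1]")


@dataclass
class ModuleTruth:
    """Planted gene→module labels with per-module driver TFs."""

    assignments: dict[str, str]                  # module gene -> module label
    drivers: dict[str, tuple[str, int]]          # module -> (driver TF, sign)
    background: list[str] = field(default_factory=list)

    @property
    def modules(self) -> list[str]:
        return list(self.drivers)

    def genes_in(self, module: str) -> list[str]:
        return [g for g, m in self.assignments.items() if m == module]

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, m) for g, m in self.assignments.items()]
        rows += [(g, "background") for g in self.background]
        return pd.DataFrame(rows, columns=["gene_id", "module"])


def make_module_truth(drivers: dict[str, tuple[str, int]],
                      module_size: int | dict[str, int],
                      n_background: int) -> ModuleTruth:
    assignments = {}
    for module in drivers:
        size = module_size[module] if isinstance(module_size, dict) else module_size
        for i in range(size):
            assignments[f"{module}_{i:04d}"] = module
    background = [f"BG_{i:04d}" for i in range(n_background)]
    return ModuleTruth(assignments, dict(drivers), background)


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    design: TimeSeriesDesign
    network: PlantedNetwork
    module_truth: ModuleTruth
    latent: dict[str, pd.DataFrame]              # condition -> gene x time
    go_annotation: dict[str, set] = field(default_factory=dict)
    promoters: dict[str, str] = field(default_factory=dict)
    pwms: list[Pwm] = field(default_factory=list)
    enrichment_plan: list[tuple] = field(default_factory=list)
    pwm_links: pd.DataFrame | None = None
    homology_hits: pd.DataFrame | None = None
    reference_edges: pd.DataFrame | None = None
    seed: int | None = None

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.gene_ids


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.clip(mu, 1e-8, None)
    if dispersion < 1e-12:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_latent_tfs(net: PlantedNetwork, cfg: SimulationConfig,
                        rng: np.random.Generator, n_timepoints: int | None = None,
                        x0: np.ndarray | None = None,
                        innovation_scale: float = 1.0) -> np.ndarray:
    """Latent TF abundances under signed lag-1 linear dynamics.

    x_i(t) = sum_j w_ji sign_ji x_j(t-1) + eps for regulated TFs; TFs with
    no regulators follow x(t) = dynamics_coefficient * x(t-1) + eta with
    eta ~ N(0, root_innovation_sd), so upstream signal is time-varying and
    propagates. eps ~ N(0, noise_sd).
    """
    n_tf = len(net.tf_ids)
    t_total = n_timepoints or cfg.n_timepoints
    idx = {tf: i for i, tf in enumerate(net.tf_ids)}
    w = np.zeros((n_tf, n_tf))
    for u, v, s, wt in net.edges:
        w[idx[v], idx[u]] = s * wt
    roots = ~(w != 0).any(axis=1)
    x = np.zeros((n_tf, t_total))
    x[:, 0] = rng.normal(0.0, 1.0, n_tf) if x0 is None else np.asarray(x0, float)
    for t in range(1, t_total):
        drive = w @ x[:, t - 1]
        drive[roots] = cfg.dynamics_coefficient * x[roots, t - 1]
        eps = rng.normal(0.0, cfg.noise_sd, n_tf) if cfg.noise_sd > 0 else np.zeros(n_tf)
        if cfg.root_innovation_sd > 0 and cfg.noise_sd > 0:
            eps[roots] = rng.normal(0.0, cfg.root_innovation_sd, int(roots.sum()))
        x[:, t] = drive + innovation_scale * eps
    return x


def simulate_expression(net: PlantedNetwork, module_truth: ModuleTruth,
                        cfg: SimulationConfig) -> SyntheticDataset:
    """Counts for TFs, module genes and background under the planted model.

    The two conditions are independent runs of the same network from
    different initial states. Module members track their driver TF's lagged
    abundance through a per-gene signed coefficient. Background genes have
    constant latent abundance.

    Biological replicates are hierarchical: each condition has a shared
    condition-response trajectory (the treatment effect, giving genes
    time-structured mean profiles), and every replicate adds its own
    independent innovations, with ``replicate_innovation_fraction`` of the
    innovation variance at the replicate level. Counts are then drawn NB
    per replicate with dispersion ``nb_dispersion``. With zero noise the
    replicates coincide and the system is exactly linear.
    """
    for module, (tf, sign) in module_truth.drivers.items():
        if tf not in net.tf_ids:
            raise ValueError(f"driver {tf!r} of module {module!r} is not a TF")
        if sign not in (1, -1):
            raise ValueError("driver signs must be +1 or -1")
    rng = np.random.default_rng(cfg.seed)

    module_genes = list(module_truth.assignments)
    gene_ids = list(net.tf_ids) + module_genes + list(module_truth.background)
    n_genes = len(gene_ids)
    t_total = cfg.n_timepoints

    gene_coef = {g: float(rng.uniform(0.7, 1.3)) for g in module_genes}
    # per-gene noise multiplier: spreads within-module correlation so module
    # connectivity is hub-like rather than uniform, as in real coexpression data
    lo, hi = cfg.gene_noise_range
    gene_noise = {g: float(rng.uniform(lo, hi)) for g in module_genes}
    background_level = {g: float(rng.normal(0.0, 1.0))
                        for g in module_truth.background}

    latent: dict[str, pd.DataFrame] = {}
    count_blocks = []
    sample_rows = []
    tf_index = {tf: i for i, tf in enumerate(net.tf_ids)}
    f_rep = cfg.replicate_innovation_fraction
    sh_scale, rep_scale = np.sqrt(1.0 - f_rep), np.sqrt(f_rep)

    def gene_latents(x_tf: np.ndarray, shared_gene_noise, extra_gene_noise) -> np.ndarray:
        lat = np.zeros((n_genes, t_total))
        lat[: len(net.tf_ids)] = x_tf
        for gi, g in enumerate(module_genes, start=len(net.tf_ids)):
            module = module_truth.assignments[g]
            tf, sign = module_truth.drivers[module]
            drv = x_tf[tf_index[tf]]
            lagged = np.concatenate([[drv[0]], drv[:-1]])
            lat[gi] = (sign * gene_coef[g] * lagged
                       + shared_gene_noise[g] + extra_gene_noise[g])
        for gi, g in enumerate(module_truth.background,
                               start=len(net.tf_ids) + len(module_genes)):
            lat[gi] = background_level[g]
        return lat

    zero_noise = {g: 0.0 for g in module_genes}
    for cond in CONDITIONS:
        x0 = rng.normal(0.0, 1.0, len(net.tf_ids))
        x_shared = simulate_latent_tfs(net, cfg, rng, x0=x0,
                                       innovation_scale=sh_scale)
        shared_gnoise = {
            g: (sh_scale * rng.normal(0.0, cfg.noise_sd * gene_noise[g], t_total)
                if cfg.noise_sd > 0 else 0.0)
            for g in module_genes}
        latent[cond] = pd.DataFrame(
            gene_latents(x_shared, shared_gnoise, zero_noise), index=gene_ids,
            columns=[f"t{t}" for t in range(t_total)])

        prefix = _COND_PREFIX[cond]
        for r in range(1, cfg.n_replicates + 1):
            x_idio = simulate_latent_tfs(net, cfg, rng,
                                         x0=np.zeros(len(net.tf_ids)),
                                         innovation_scale=rep_scale)
            rep_gnoise = {
                g: (rep_scale * rng.normal(0.0, cfg.noise_sd * gene_noise[g],
                                           t_total)
                    if cfg.noise_sd > 0 else 0.0)
                for g in module_genes}
            lat_rep = gene_latents(x_shared + x_idio, shared_gnoise, rep_gnoise)
            # baseline shift keeps typical latents in the near-linear softplus
            # regime so dynamics survive the latent -> count link; the scale
            # is fixed (not per-sample) so constant genes keep constant means
            mean_shape = _softplus(cfg.count_baseline + lat_rep)
            mu = (cfg.library_size * mean_shape
                  / (n_genes * _softplus(np.array(cfg.count_baseline))))
            for t in range(t_total):
                counts = _nb_draw(rng, mu[:, t], cfg.nb_dispersion)
                name = f"{prefix}{t}_{r}"
                count_blocks.append(pd.Series(counts, index=gene_ids, name=name))
                sample_rows.append({"sample": name, "condition": cond,
                                    "time_h": float(t), "replicate": r})

    counts = CountMatrix(
        pd.concat(count_blocks, axis=1),
        pd.Series(cfg.gene_length_bp, index=gene_ids, dtype=float))
    design = TimeSeriesDesign(pd.DataFrame(sample_rows).set_index("sample"))
    return SyntheticDataset(counts, design, net, module_truth, latent,
                            seed=cfg.seed)


def make_pwms(motif_ids, length: int = 8, seed: int = 0,
              dominant_p: float = 0.85) -> list[Pwm]:
    """Informative random PWMs: one dominant base per position."""
    rng = np.random.default_rng(seed)
    out = []
    for mid in motif_ids:
        mat = np.full((length, 4), (1.0 - dominant_p) / 3.0)
        for pos in range(length):
            mat[pos, rng.integers(4)] = dominant_p
        out.append(Pwm(mid, mat))
    return out


def generate_promoters(module_truth: ModuleTruth, pwm_set: list[Pwm],
                       enrichment_plan, upstream_length: int, gc_content: float,
                       seed: int) -> dict[str, str]:
    """Upstream sequences: i.i.d. background at the given GC content, with
    one PWM-sampled site inserted per planned module promoter with the
    stated probability, at a uniform position and random strand."""
    if not 0.0 < gc_content < 1.0:
        raise ValueError("gc_content must be in (0, 1)")
    pwm_by_id = {p.motif_id: p for p in pwm_set}
    for pwm_id, _module, prob in enrichment_plan:
        if pwm_id not in pwm_by_id:
            raise ValueError(f"unknown PWM {pwm_id!r} in enrichment plan")
        if not 0.0 <= prob <= 1.0:
            raise ValueError("insert probability must be in [0, 1]")
        if len(pwm_by_id[pwm_id]) > upstream_length:
            raise ValueError("PWM longer than upstream_length")

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc_content) / 2, gc_content / 2,
                      gc_content / 2, (1 - gc_content) / 2])
    comp = str.maketrans("ACGT", "TGCA")

    genes = list(module_truth.assignments) + list(module_truth.background)
    seqs = {g: rng.choice(4, size=upstream_length, p=probs) for g in genes}

    for pwm_id, module, prob in enrichment_plan:
        pwm = pwm_by_id[pwm_id]
        w = len(pwm)
        for g in module_truth.genes_in(module):
            if rng.random() >= prob:
                continue
            site = np.array([rng.choice(4, p=row) for row in pwm.matrix])
            if rng.random() < 0.5:
                site_str = "".join(bases[site])
                site = np.array([("ACGT".index(b)) for b in
                                 site_str.translate(comp)[::-1]])
            pos = int(rng.integers(0, upstream_length - w + 1))
            seqs[g][pos:pos + w] = site
    return {g: "".join(bases[v]) for g, v in seqs.items()}


def make_go_annotation(net: PlantedNetwork, module_truth: ModuleTruth) -> dict[str, set]:
    """TFs carry GO:0003700; each module carries its own GO term; every gene
    carries a shared uninformative term."""
    annotation: dict[str, set] = {}
    for tf in net.tf_ids:
        annotation[tf] = {TF_GO, "GO:0008150"}
    for i, module in enumerate(module_truth.modules, 1):
        go = f"GO:77{i:05d}"
        for g in module_truth.genes_in(module):
            annotation[g] = {go, "GO:0008150"}
    for g in module_truth.background:
        annotation[g] = {"GO:0008150"}
    return annotation


def _blast6_row(query: str, subject: str, evalue: float) -> list:
    return [query, subject, 98.0, 200, 2, 0, 1, 200, 1, 200, evalue, 350.0]


def make_comparison_inputs(net: PlantedNetwork, species_specific: set[str],
                           decoy_evalue: float = 1e-10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Similarity hit table and reference edge list derived from truth.

    TFs outside ``species_specific`` get a reference homolog at e = 1e-50;
    species-specific TFs get only a decoy hit above the retention threshold.
    The reference network mirrors planted edges between homologous TFs.
    """
    rows = []
    ref_of = {}
    for tf in net.tf_ids:
        if tf in species_specific:
            rows.append(_blast6_row(tf, f"REF_{tf}", decoy_evalue))
        else:
            ref_of[tf] = f"REF_{tf}"
            rows.append(_blast6_row(tf, f"REF_{tf}", 1e-50))
    hits = pd.DataFrame(rows)
    ref_edges = [(ref_of[u], ref_of[v]) for u, v, _s, _w in net.edges
                 if u in ref_of and v in ref_of]
    return hits, pd.DataFrame(ref_edges, columns=["source", "target"])


def make_pwm_links(drivers: dict[str, tuple[str, int]],
                   pwm_source: dict[str, str]) -> pd.DataFrame:
    """Similarity table linking each driver TF to its PWM source id at
    e = 1e-20, plus decoy rows above the 1e-5 bridge threshold."""
    rows = []
    for _module, (tf, _sign) in drivers.items():
        rows.append(_blast6_row(tf, pwm_source[tf], 1e-20))
        rows.append(_blast6_row(tf, "SRC_decoy", 1e-3))
    return pd.DataFrame(rows)


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write every artifact as plain text and return a path -> sha256 manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ds.counts.write_tsv(outdir / "counts.tsv")
    ds.design.write_tsv(outdir / "design.tsv")
    ds.network.to_frame().to_csv(outdir / "network_truth.tsv", sep="\t", index=False)
    ds.module_truth.to_frame().to_csv(outdir / "module_truth.tsv", sep="\t",
                                      index=False)
    rows = [(g, go) for g, gos in sorted(ds.go_annotation.items())
            for go in sorted(gos)]
    pd.DataFrame(rows).to_csv(outdir / "go_annotation.tsv", sep="\t",
                              header=False, index=False)
    if ds.promoters:
        with open(outdir / "promoters.fasta", "w") as fh:
            for g, seq in sorted(ds.promoters.items()):
                fh.write(f">{g}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
    if ds.pwms:
        write_meme(ds.pwms, outdir / "pwms.meme")
    for name, df in (("pwm_links.tsv", ds.pwm_links),
                     ("homology_hits.tsv", ds.homology_hits),
                     ("reference_network.tsv", ds.reference_edges)):
        if df is not None:
            df.to_csv(outdir / name, sep="\t", header=False, index=False)

    manifest = {}
    for path in sorted(outdir.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"seed": ds.seed, "files": manifest}, fh, indent=2, sort_keys=True)
    return manifest


def read_promoters(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
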