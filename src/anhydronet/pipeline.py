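"""One-call synthetic end-to-end run of every analysis stage.

``run_pipeline`` generates a synthetic dataset with a planted
zero-in-degree master regulator driving feed-forward loops that drive
coexpressed modules, then executes differential expression, per-condition
network inference, integration, the motif census with its randomization
null, module detection, motif+Granger regulation calls and cross-species
contraction — and scores every stage against the planted truth.

Stage parameters default to the emulated study's settings (100 boosting
trees, lag 1, 10,000 null iterations, signed R^2 > 0.75, FDR 0.05,
homology gates 1e-5 / 1e-15). The synthetic design uses 16 time points
per condition so the per-condition vector autoregression behind the
Granger test keeps usable residual degrees of freedom at lag 2; sample
sizes are otherwise desk-scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare, coexp, grn, prep, regcall, synthio, topo


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed."""

    # synthetic truth
    n_tf: int = 60
    n_extra_edges: int = 40
    positive_ratio: float = 0.75
    motif_requests: tuple = ("coherent_ffl", "coherent_ffl", "incoherent_ffl",
                             "positive_fbl", "negative_fbl")
    module_sizes: tuple = (45, 30, 25)
    n_background: int = 150
    n_timepoints: int = 16
    n_replicates: int = 3
    dynamics_coefficient: float = 0.3
    noise_sd: float = 0.45
    nb_dispersion: float = 0.01
    replicate_innovation_fraction: float = 0.4
    library_size: int = 2_000_000
    gene_length_bp: int = 1000
    upstream_length: int = 500
    gc_content: float = 0.5
    insert_probability: float = 0.9
    pwm_length: int = 8
    # stage parameters
    alpha: float = 0.05
    n_trees: int = 100
    lag: int = 1
    null_iterations: int = 10_000
    soft_power_r2: float = 0.75
    size_range_max: int = 200
    window_lengths: tuple = (100, 500)
    n_motif_draws: int = 300
    max_lag: int = 2
    e_value_pwm: float = 1e-5
    e_value_reference: float = 1e-15
    hsf_id: str | None = None            # default: first FFL root
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=str)


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: synthio.SyntheticDataset
    pca: prep.PcaResult
    deg: dict[str, prep.DegTable]
    venn: prep.VennCounts
    networks: dict[str, grn.SignedNetwork]
    scans: dict[str, grn.ThresholdScan]
    integrated: grn.SignedNetwork
    census: topo.MotifCensus
    null_test: topo.NullTestResult
    soft_power: coexp.SoftPowerSelection
    partition: coexp.ModulePartition
    enrichment: coexp.GoEnrichment
    motif_hits: list[regcall.MotifHitResult]
    granger: list[regcall.GrangerResult]
    calls: list[regcall.RegulationCall]
    conserved: dict
    contracted: compare.ContractedNetwork
    summary: dict
    manifest: dict = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def make_synthetic_dataset(cfg: PipelineConfig) -> synthio.SyntheticDataset:
    """Assemble the full planted-truth dataset for one pipeline run."""
    seeds = np.random.SeedSequence(cfg.seed).generate_state(8) % (2**31)
    net = synthio.generate_planted_network(
        cfg.n_tf, cfg.n_extra_edges, cfg.positive_ratio,
        cfg.motif_requests, seed=int(seeds[0]), master=True, connect=True,
        protect_motifs=True)
    master = net.master_regulator
    first_ffl = next(t for c, t in net.planted_motifs
                     if c in ("coherent_ffl", "incoherent_ffl"))
    # modules driven by the master and the first loop's head and middle TF —
    # each driver has a single strong regulator, so the contraction's
    # upstream criteria are decidable from reliably-inferred edges
    drivers = {"M1": (master, 1)}
    for i, tf in enumerate(first_ffl[:2], start=2):
        drivers[f"M{i}"] = (tf, 1 if i % 2 == 0 else -1)
    sizes = {m: cfg.module_sizes[i % len(cfg.module_sizes)]
             for i, m in enumerate(drivers)}
    truth = synthio.make_module_truth(drivers, sizes, cfg.n_background)

    sim_cfg = synthio.SimulationConfig(
        n_timepoints=cfg.n_timepoints, n_replicates=cfg.n_replicates,
        dynamics_coefficient=cfg.dynamics_coefficient, noise_sd=cfg.noise_sd,
        nb_dispersion=cfg.nb_dispersion, library_size=cfg.library_size,
        gene_length_bp=cfg.gene_length_bp,
        replicate_innovation_fraction=cfg.replicate_innovation_fraction,
        seed=int(seeds[1]))
    ds = synthio.simulate_expression(net, truth, sim_cfg)
    ds.seed = cfg.seed
    ds.go_annotation = synthio.make_go_annotation(net, truth)

    pwm_source = {tf: f"SRC_{tf}" for _m, (tf, _s) in drivers.items()}
    ds.pwms = synthio.make_pwms(sorted(set(pwm_source.values())),
                                length=cfg.pwm_length, seed=int(seeds[2]))
    ds.enrichment_plan = [(pwm_source[tf], module, cfg.insert_probability)
                          for module, (tf, _s) in drivers.items()]
    ds.promoters = synthio.generate_promoters(
        truth, ds.pwms, ds.enrichment_plan, cfg.upstream_length,
        cfg.gc_content, seed=int(seeds[3]))
    ds.pwm_links = synthio.make_pwm_links(drivers, pwm_source)

    species_specific = {master} | {n for _c, t in net.planted_motifs for n in t}
    ds.homology_hits, ds.reference_edges = synthio.make_comparison_inputs(
        net, species_specific)
    return ds


def condition_series(rpkm: pd.DataFrame, design: prep.TimeSeriesDesign,
                     condition: str, genes) -> np.ndarray:
    """(gene, time, replicate) array of RPKM for one condition."""
    genes = list(genes)
    times = design.timepoints(condition)
    reps = sorted(design.table.loc[design.samples_for(condition), "replicate"].unique())
    arr = np.zeros((len(genes), len(times), len(reps)))
    for ti, t in enumerate(times):
        for ri, r in enumerate(reps):
            mask = ((design.table["condition"] == condition)
                    & (design.table["time_h"] == t)
                    & (design.table["replicate"] == r))
            sample = design.table.index[mask][0]
            arr[:, ti, ri] = rpkm.loc[genes, sample].to_numpy()
    return arr


def run_pipeline(cfg: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute all stages in order on a synthetic dataset; deterministic
    given ``cfg`` (including its seed)."""
    seeds = np.random.SeedSequence((cfg.seed, 1)).generate_state(8) % (2**31)

    def stage(name, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc

    ds = stage("simulate", lambda: make_synthetic_dataset(cfg))
    rpkm = stage("rpkm", lambda: prep.rpkm_transform(ds.counts))
    pca = stage("pca", lambda: prep.principal_components(rpkm))

    deg = {}
    for cond in synthio.CONDITIONS:
        deg[cond] = stage(f"deg:{cond}",
                          lambda c=cond: prep.nb_lrt(ds.counts, ds.design, c,
                                                     alpha=cfg.alpha))
    venn = stage("venn", lambda: prep.partition_tf_targets(deg, ds.go_annotation))

    networks, scans = {}, {}
    for i, cond in enumerate(synthio.CONDITIONS):
        def infer(c=cond, k=i):
            tf_degs = [g for g in deg[c].deg_ids
                       if prep.TF_GO_TERM in ds.go_annotation.get(g, set())]
            if len(tf_degs) < 3:
                raise RuntimeError(f"too few TF DEGs in {c}")
            series = condition_series(rpkm, ds.design, c, tf_degs)
            return grn.infer_condition_network(
                series, tf_degs, c, n_trees=cfg.n_trees, lag=cfg.lag,
                seed=int(seeds[k]))
        networks[cond], scans[cond], _ = stage(f"infer:{cond}", infer)

    integrated = stage("integrate", lambda: grn.integrate_networks(
        networks["trehalose"], networks["rehydration"]))

    census = stage("motifs", lambda: topo.census_motifs(integrated))

    def null():
        signs = [e.sign for e in integrated.edges.values()]
        ratio = float(np.mean([s > 0 for s in signs])) if signs else 0.5
        return topo.erdos_renyi_null_test(
            census, n_nodes=len(integrated.nodes), n_edges=len(integrated.edges),
            positive_ratio=ratio, iterations=cfg.null_iterations,
            seed=int(seeds[2]))
    null_test = stage("motif_null", null)

    def modules():
        other_degs = sorted(
            (set(deg["trehalose"].deg_ids) | set(deg["rehydration"].deg_ids))
            - {g for g in ds.go_annotation
               if prep.TF_GO_TERM in ds.go_annotation[g]})
        z = prep.zscore_profiles(rpkm, ds.design, other_degs)
        power = coexp.select_soft_power(z, r2_threshold=cfg.soft_power_r2)
        adj = coexp.adjacency_matrix(z, power.selected_power)
        tom = coexp.tom_dissimilarity(adj, gene_ids=list(z.index))
        part = coexp.cluster_modules(tom, z,
                                     size_range=range(1, cfg.size_range_max + 1))
        enr = coexp.go_enrichment(part, ds.go_annotation)
        return z, power, part, enr
    z_other, soft_power, partition, enrichment = stage("modules", modules)

    def regulate():
        links = regcall.load_pwm_tf_links(ds.pwm_links, cfg.e_value_pwm)
        pwm_by_id = {p.motif_id: p for p in ds.pwms}
        tf_z = prep.zscore_profiles(rpkm, ds.design, ds.network.tf_ids)
        cond_cols = {c: [col for col in tf_z.columns if col.startswith(f"{c}:")]
                     for c in synthio.CONDITIONS}
        hits, granger = [], []
        k = 0
        for tf in sorted(links):
            pwms = [pwm_by_id[m] for m in sorted(links[tf]) if m in pwm_by_id]
            if not pwms or tf not in ds.network.tf_ids:
                continue
            for module in partition.modules:
                members = partition.genes_in(module)
                mod_seqs = {g: ds.promoters[g] for g in members
                            if g in ds.promoters}
                bg_seqs = {g: ds.promoters[g]
                           for g in ds.module_truth.background
                           if g not in set(members)}
                if not mod_seqs or len(bg_seqs) < len(mod_seqs):
                    continue
                best = None
                for pwm in pwms:
                    res = regcall.motif_enrichment(
                        pwm, mod_seqs, bg_seqs, cfg.window_lengths,
                        n_draws=cfg.n_motif_draws, seed=int(seeds[3]) + k,
                        tf_id=tf, module=module)
                    k += 1
                    if best is None or (np.isfinite(res.min_p)
                                        and res.min_p < best.min_p):
                        best = res
                hits.append(best)
                effect_all = z_other.loc[[g for g in members
                                          if g in z_other.index]].mean(axis=0)
                for cond in synthio.CONDITIONS:
                    cols = cond_cols[cond]
                    granger.append(regcall.granger_causality(
                        tf_z.loc[tf, cols].to_numpy(),
                        effect_all[cols].to_numpy(),
                        max_lag=cfg.max_lag, tf_id=tf, module=module,
                        condition=cond))
        regcall.adjust_granger(granger)
        calls = regcall.call_regulators(hits, granger, alpha=cfg.alpha)
        return hits, granger, calls
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        motif_hits, granger_results, calls = stage("regulate", regulate)

    def contract():
        hom = compare.load_homology(ds.homology_hits, cfg.e_value_reference)
        ref = compare.load_reference_network(ds.reference_edges)
        conserved = compare.flag_conserved_edges(integrated, ref, hom)
        module_regs: dict[str, set] = {}
        for call in calls:
            if call.called:
                module_regs.setdefault(call.tf_id, set()).add(call.module)
        hsf = cfg.hsf_id
        if hsf is None:
            first_ffl = next(t for c, t in ds.network.planted_motifs
                             if c in ("coherent_ffl", "incoherent_ffl"))
            hsf = first_ffl[0]
        contracted = compare.contract_network(integrated, conserved, hom,
                                              module_regs, hsf)
        return conserved, contracted
    conserved, contracted = stage("contract", contract)

    summary = _summarize(cfg, ds, deg, scans, integrated, census, null_test,
                         soft_power, partition, calls, contracted)

    result = PipelineResult(cfg, ds, pca, deg, venn, networks, scans, integrated,
                            census, null_test, soft_power, partition, enrichment,
                            motif_hits, granger_results, calls, conserved,
                            contracted, summary)
    if outdir is not None:
        result.manifest = write_outputs(result, outdir)
    return result


def _summarize(cfg, ds, deg, scans, integrated, census, null_test, soft_power,
               partition, calls, contracted) -> dict:
    from sklearn.metrics import adjusted_rand_score

    truth_edges = {(u, v): s for u, v, s, _w in ds.network.edges}
    est_edges = {k: e.sign for k, e in integrated.edges.items()}
    inter = set(truth_edges) & set(est_edges)
    precision = len(inter) / len(est_edges) if est_edges else 0.0
    recall = len(inter) / len(truth_edges) if truth_edges else 0.0
    sign_acc = (float(np.mean([truth_edges[e] == est_edges[e] for e in inter]))
                if inter else np.nan)

    truth_genes = sorted(ds.module_truth.assignments)
    truth_labels = [ds.module_truth.assignments[g] for g in truth_genes]
    est_labels = [partition.assignments.get(g, "missing") for g in truth_genes]
    ari = float(adjusted_rand_score(truth_labels, est_labels))

    called = {(c.tf_id, c.module) for c in calls if c.called}
    driver_of = {m: tf for m, (tf, _s) in ds.module_truth.drivers.items()}
    # map recovered modules to truth modules by majority overlap
    mapping = {}
    for module in partition.modules:
        members = partition.genes_in(module)
        overlaps = pd.Series([ds.module_truth.assignments.get(g, "bg")
                              for g in members]).value_counts()
        mapping[module] = overlaps.idxmax()
    true_calls = {(tf, m) for (tf, m) in called
                  if driver_of.get(mapping.get(m, "")) == tf}
    call_precision = len(true_calls) / len(called) if called else np.nan
    planted_pairs = len(driver_of)
    call_recall = (len({mapping.get(m, "") for _tf, m in true_calls})
                   / planted_pairs if planted_pairs else np.nan)

    zero_in = contracted.in_degree_zero()
    master = ds.network.master_regulator
    master_recovered = zero_in == {master}

    return {
        "n_genes": len(ds.counts.gene_ids),
        "n_deg_trehalose": int(deg["trehalose"].table["is_deg"].sum()),
        "n_deg_rehydration": int(deg["rehydration"].table["is_deg"].sum()),
        "threshold_trehalose": float(scans["trehalose"].selected_a),
        "threshold_rehydration": float(scans["rehydration"].selected_a),
        "n_nodes_integrated": len(integrated.nodes),
        "n_edges_integrated": len(integrated.edges),
        "edge_precision": precision,
        "edge_recall": recall,
        "sign_accuracy": sign_acc,
        "motif_counts": dict(census.counts),
        "motif_null_p": dict(null_test.p_values),
        "soft_power": int(soft_power.selected_power),
        "min_cluster_size": int(partition.min_cluster_size),
        "n_modules": len(partition.modules),
        "module_ari": ari,
        "n_calls": len(called),
        "call_precision": call_precision,
        "call_recall": call_recall,
        "contracted_nodes": sorted(contracted.all_nodes),
        "master_regulator": master,
        "master_recovered": bool(master_recovered),
    }


def write_outputs(result: PipelineResult, outdir) -> dict[str, str]:
    """Write stage artifacts (TSV/JSON/GraphML text) and a sha256 manifest."""
    import networkx as nx

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    synthio.write_dataset(result.dataset, outdir / "dataset")

    (outdir / "config.json").write_text(result.config.to_json())
    for cond, table in result.deg.items():
        table.table.to_csv(outdir / f"deg_{cond}.tsv", sep="\t",
                           index_label="gene_id")
    venn = {"tf": result.venn.tf, "other": result.venn.other}
    (outdir / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True))
    for cond, net in result.networks.items():
        net.write_tsv(outdir / f"network_{cond}.tsv")
        result.scans[cond].table.to_csv(outdir / f"threshold_scan_{cond}.tsv",
                                        sep="\t", index=False)
    result.integrated.write_tsv(outdir / "network_integrated.tsv")
    nx.write_graphml(result.integrated.to_networkx(),
                     outdir / "network_integrated.graphml")
    census = {"counts": result.census.counts,
              "p_values": result.null_test.p_values}
    (outdir / "motifs.json").write_text(json.dumps(census, indent=2, sort_keys=True))
    hist = pd.DataFrame(result.null_test.null_counts)
    hist.to_csv(outdir / "motif_null_histogram.tsv", sep="\t", index=False)
    result.partition.to_frame().to_csv(outdir / "modules.tsv", sep="\t", index=False)
    result.partition.profiles.to_csv(outdir / "module_profiles.tsv", sep="\t")
    result.enrichment.table.to_csv(outdir / "go_enrichment.tsv", sep="\t",
                                   index=False)
    calls = pd.DataFrame([dataclasses.asdict(c) for c in result.calls])
    calls.to_csv(outdir / "regulation_calls.tsv", sep="\t", index=False)
    nx.write_graphml(result.contracted.to_networkx(),
                     outdir / "network_contracted.graphml")
    (outdir / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True, default=str))

    manifest = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "pipeline_manifest.json":
            manifest[str(path.relative_to(outdir))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    (outdir / "pipeline_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
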