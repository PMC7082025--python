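"""Per-condition regulatory-network inference, thresholding and integration.

For each condition, boosted-tree ensembles (100 trees, lag 1) score every
regulator→target pair among the TF DEGs; the score threshold is the
minimum value at which the network's degree distribution fits a power law
(negative log-log slope, F-test p < 0.05); signs come from the lag-1
cross-correlation; the two networks are integrated by union.

Usage: python analysis/03_infer_network.py [--outdir results/synthetic] [--seed 1]
"""

import argparse
import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from anhydronet import grn, pipeline, prep  # noqa: E402

CONDITIONS = ("trehalose", "rehydration")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--trees", type=int, default=100)
    ap.add_argument("--lag", type=int, default=1)
    args = ap.parse_args()
    data = args.outdir / "dataset"

    design = prep.TimeSeriesDesign.read_tsv(data / "design.tsv")
    go = prep.read_go_annotation(data / "go_annotation.tsv")
    rpkm = pd.read_csv(args.outdir / "rpkm.tsv", sep="\t", index_col=0)
    truth = pd.read_csv(data / "network_truth.tsv", sep="\t")
    truth_edges = set(zip(truth["source"], truth["target"]))

    seeds = np.random.SeedSequence((args.seed, 1)).generate_state(8) % (2**31)
    nets = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, cond in enumerate(CONDITIONS):
            deg = pd.read_csv(args.outdir / f"deg_{cond}.tsv", sep="\t",
                              index_col=0)
            tf_degs = [g for g in deg.index[deg["is_deg"]]
                       if prep.TF_GO_TERM in go.get(g, set())]
            series = pipeline.condition_series(rpkm, design, cond, tf_degs)
            net, scan, _ = grn.infer_condition_network(
                series, tf_degs, cond, n_trees=args.trees, lag=args.lag,
                seed=int(seeds[k]))
            nets[cond] = net
            net.write_tsv(args.outdir / f"network_{cond}.tsv")
            scan.table.to_csv(args.outdir / f"threshold_scan_{cond}.tsv",
                              sep="\t", index=False)
            inter = set(net.edges) & truth_edges
            print(f"{cond}: threshold a = {scan.selected_a:.3f}, "
                  f"{len(net.edges)} signed edges over {len(net.nodes)} TFs "
                  f"(precision {len(inter) / max(len(net.edges), 1):.2f}, "
                  f"recall {len(inter) / len(truth_edges):.2f} vs planted truth)")

    integrated = grn.integrate_networks(nets["trehalose"], nets["rehydration"])
    integrated.write_tsv(args.outdir / "network_integrated.tsv")
    import networkx as nx
    nx.write_graphml(integrated.to_networkx(),
                     args.outdir / "network_integrated.graphml")
    inter = set(integrated.edges) & truth_edges
    print(f"integrated: {len(integrated.edges)} edges over "
          f"{len(integrated.nodes)} TFs; recall vs planted truth "
          f"{len(inter) / len(truth_edges):.2f}")


if __name__ == "__main__":
    main()
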