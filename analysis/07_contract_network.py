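"""Cross-species comparison and contraction to the tolerance-specific core.

Flags inferred edges as conserved when homologs of their endpoints are
connected (directly or indirectly) in the reference network, then
contracts to the species-specific module-regulating TFs: most-upstream
regulators, FFL blocks and the HSF with its connectors.

Usage: python analysis/07_contract_network.py [--outdir results/synthetic]
"""

import argparse
import json
import sys
import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from anhydronet import compare, grn  # noqa: E402


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--hsf", default=None,
                    help="HSF id (default: first planted FFL head)")
    args = ap.parse_args()
    data = args.outdir / "dataset"

    net = grn.SignedNetwork.read_tsv(args.outdir / "network_integrated.tsv")
    hom = compare.load_homology(data / "homology_hits.tsv")
    ref = compare.load_reference_network(data / "reference_network.tsv")
    calls = pd.read_csv(args.outdir / "regulation_calls.tsv", sep="\t")

    hsf = args.hsf
    if hsf is None:
        truth = pd.read_csv(data / "network_truth.tsv", sep="\t")
        roots = sorted(set(truth["source"]) - set(truth["target"]))
        master = roots[0]
        # planted convention: the master's direct target heads the first FFL
        hsf = truth.loc[truth["source"] == master, "target"].iloc[0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        conserved = compare.flag_conserved_edges(net, ref, hom)
        module_regs = {}
        for row in calls.itertuples(index=False):
            if row.called:
                module_regs.setdefault(row.tf_id, set()).add(row.module)
        contracted = compare.contract_network(net, conserved, hom, module_regs,
                                              hsf_id=hsf)

    nx.write_graphml(contracted.to_networkx(),
                     args.outdir / "network_contracted.graphml")
    summary = {
        "n_edges_integrated": len(net.edges),
        "n_edges_conserved": int(sum(conserved.values())),
        "retained_tfs": sorted(contracted.nodes),
        "ffl_blocks": {b: sorted(m) for b, m in contracted.blocks.items()},
        "edges": sorted(map(list, contracted.edges)),
        "most_upstream": sorted(contracted.in_degree_zero()),
        "module_attachments": {n: sorted(m) for n, m
                               in contracted.module_attachments.items()},
    }
    (args.outdir / "contracted_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))

    print(f"{summary['n_edges_conserved']} of {len(net.edges)} integrated "
          "edges are conserved in the reference network")
    print("contracted nodes:", summary["retained_tfs"],
          "blocks:", summary["ffl_blocks"])
    print("contracted edges:", summary["edges"])
    print("most-upstream regulator(s):", summary["most_upstream"])


if __name__ == "__main__":
    main()
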