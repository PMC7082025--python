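"""Coexpression-module detection among non-TF DEGs with GO enrichment.

Z-scored replicate-averaged profiles of the target DEGs are turned into an
unsigned |cor|^beta adjacency (beta = smallest power with signed scale-free
R^2 > 0.75), transformed to topological-overlap dissimilarity, clustered
by average linkage with the minimum module size selected by pseudo-F, and
each module is tested for GO enrichment (one-sided Fisher, p < 0.05).

Usage: python analysis/05_detect_modules.py [--outdir results/synthetic]
"""

import argparse
import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from anhydronet import coexp, prep  # noqa: E402

CONDITIONS = ("trehalose", "rehydration")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--r2", type=float, default=0.75)
    ap.add_argument("--size-max", type=int, default=200)
    args = ap.parse_args()
    data = args.outdir / "dataset"

    design = prep.TimeSeriesDesign.read_tsv(data / "design.tsv")
    go = prep.read_go_annotation(data / "go_annotation.tsv")
    rpkm = pd.read_csv(args.outdir / "rpkm.tsv", sep="\t", index_col=0)
    degs = set()
    for cond in CONDITIONS:
        table = pd.read_csv(args.outdir / f"deg_{cond}.tsv", sep="\t", index_col=0)
        degs |= set(table.index[table["is_deg"]])
    other = sorted(g for g in degs if prep.TF_GO_TERM not in go.get(g, set()))

    z = prep.zscore_profiles(rpkm, design, other)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        power = coexp.select_soft_power(z, r2_threshold=args.r2)
        adj = coexp.adjacency_matrix(z, power.selected_power)
        tom = coexp.tom_dissimilarity(adj, gene_ids=list(z.index))
        part = coexp.cluster_modules(tom, z,
                                     size_range=range(1, args.size_max + 1))
        enrich = coexp.go_enrichment(part, go)

    power.table.to_csv(args.outdir / "soft_power_scan.tsv", sep="\t")
    part.to_frame().to_csv(args.outdir / "modules.tsv", sep="\t", index=False)
    part.profiles.to_csv(args.outdir / "module_profiles.tsv", sep="\t")
    part.pseudo_f.to_csv(args.outdir / "pseudo_f_by_min_size.tsv", sep="\t",
                         header=["pseudo_f"])
    enrich.table.to_csv(args.outdir / "go_enrichment.tsv", sep="\t", index=False)

    print(f"clustered {len(z)} non-TF DEGs")
    print(f"soft power beta = {power.selected_power} "
          f"(signed R^2 = {power.table.loc[power.selected_power, 'signed_r_squared']:.2f})")
    print(f"minimum module size = {part.min_cluster_size} (pseudo-F argmax)")
    print(f"modules: {part.sizes}")
    rep = enrich.representative
    for row in rep.itertuples(index=False):
        print(f"  {row.module}: top GO {row.go_id} (p = {row.p_value:.2e})")


if __name__ == "__main__":
    main()
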