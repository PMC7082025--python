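"""RPKM, PCA and per-condition NB-LRT differential expression.

Reads the dataset written by 01_simulate_dataset.py, normalizes counts to
RPKM, summarizes samples by PCA, tests every gene for a time-point effect
within each condition (NB GLM likelihood ratio, BH FDR < 0.05) and splits
DEGs into transcription factors (GO:0003700) versus targets.

Usage: python analysis/02_differential_expression.py [--outdir results/synthetic]
"""

import argparse
import json
import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from anhydronet import prep  # noqa: E402

CONDITIONS = ("trehalose", "rehydration")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()
    data = args.outdir / "dataset"

    counts = prep.CountMatrix.read_tsv(data / "counts.tsv")
    design = prep.TimeSeriesDesign.read_tsv(data / "design.tsv")
    go = prep.read_go_annotation(data / "go_annotation.tsv")

    rpkm = prep.rpkm_transform(counts)
    rpkm.to_csv(args.outdir / "rpkm.tsv", sep="\t", index_label="gene_id")

    pca = prep.principal_components(rpkm, 3)
    pca.scores.to_csv(args.outdir / "pca_scores.tsv", sep="\t",
                      index_label="sample")
    ratios = [f"{100 * r:.1f}%" for r in pca.contribution_ratio]
    print("PCA contribution ratios (PC1-3):", ", ".join(ratios))

    deg = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cond in CONDITIONS:
            deg[cond] = prep.nb_lrt(counts, design, cond)
            deg[cond].table.to_csv(args.outdir / f"deg_{cond}.tsv", sep="\t",
                                   index_label="gene_id")
            n = int(deg[cond].table["is_deg"].sum())
            print(f"{cond}: {n} DEGs of {len(counts.gene_ids)} genes (FDR < 0.05)")

    venn = prep.partition_tf_targets(deg, go)
    payload = {"tf": venn.tf, "other": venn.other}
    (args.outdir / "venn.json").write_text(json.dumps(payload, indent=2,
                                                      sort_keys=True))
    print("TF DEGs (GO:0003700):", venn.tf)
    print("other DEGs:", venn.other)


if __name__ == "__main__":
    main()
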