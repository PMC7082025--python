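"""TF→module regulation calls: motif enrichment AND Granger causality.

For every PWM-linked TF and detected module, tests (a) enrichment of the
TF's binding motif in the module genes' upstream regions against random
background draws over multiple window lengths, and (b) Granger causality
from the TF's Z-score series to the module's mean Z-score per condition
(VAR, AIC lag, BH-adjusted F-test). A regulation is called when both
tests pass.

Usage: python analysis/06_call_regulators.py [--outdir results/synthetic]
"""

import argparse
import dataclasses
import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from anhydronet import coexp, prep, regcall, synthio  # noqa: E402

CONDITIONS = ("trehalose", "rehydration")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--windows", type=int, nargs="+", default=[100, 500])
    ap.add_argument("--draws", type=int, default=1000)
    ap.add_argument("--max-lag", type=int, default=2)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    data = args.outdir / "dataset"

    design = prep.TimeSeriesDesign.read_tsv(data / "design.tsv")
    rpkm = pd.read_csv(args.outdir / "rpkm.tsv", sep="\t", index_col=0)
    modules = pd.read_csv(args.outdir / "modules.tsv", sep="\t")
    promoters = synthio.read_promoters(data / "promoters.fasta")
    pwms = {p.motif_id: p for p in regcall.read_meme(data / "pwms.meme")}
    links = regcall.load_pwm_tf_links(data / "pwm_links.tsv")
    truth = pd.read_csv(data / "module_truth.tsv", sep="\t")
    background = set(truth.loc[truth["module"] == "background", "gene_id"])

    members = {m: list(sub["gene_id"])
               for m, sub in modules.groupby("module") if m != coexp.UNASSIGNED}
    z_all = prep.zscore_profiles(rpkm, design, rpkm.index)
    cond_cols = {c: [col for col in z_all.columns if col.startswith(f"{c}:")]
                 for c in CONDITIONS}

    hits, granger = [], []
    k = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tf in sorted(links):
            tf_pwms = [pwms[m] for m in sorted(links[tf]) if m in pwms]
            if not tf_pwms or tf not in z_all.index:
                continue
            for module, genes in sorted(members.items()):
                mod_seqs = {g: promoters[g] for g in genes if g in promoters}
                bg_seqs = {g: promoters[g] for g in background - set(genes)}
                if not mod_seqs or len(bg_seqs) < len(mod_seqs):
                    continue
                best = None
                for pwm in tf_pwms:
                    res = regcall.motif_enrichment(
                        pwm, mod_seqs, bg_seqs, tuple(args.windows),
                        n_draws=args.draws, seed=args.seed + k, tf_id=tf,
                        module=module)
                    k += 1
                    if best is None or (np.isfinite(res.min_p)
                                        and res.min_p < best.min_p):
                        best = res
                hits.append(best)
                effect = z_all.loc[[g for g in genes if g in z_all.index]].mean(axis=0)
                for cond in CONDITIONS:
                    cols = cond_cols[cond]
                    granger.append(regcall.granger_causality(
                        z_all.loc[tf, cols].to_numpy(), effect[cols].to_numpy(),
                        max_lag=args.max_lag, tf_id=tf, module=module,
                        condition=cond))
        regcall.adjust_granger(granger)
        calls = regcall.call_regulators(hits, granger)

    pd.DataFrame([{"tf": h.tf_id, "module": h.module, "min_p": h.min_p,
                   "significant": h.any_window_significant}
                  for h in hits]).to_csv(args.outdir / "motif_evidence.tsv",
                                         sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(g) for g in granger]).to_csv(
        args.outdir / "granger_evidence.tsv", sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
        args.outdir / "regulation_calls.tsv", sep="\t", index=False)

    called = [c for c in calls if c.called]
    print(f"tested {len(hits)} TF-module pairs; {len(called)} regulations called:")
    for c in called:
        print(f"  {c.tf_id} -> {c.module} (motif p {c.motif_min_p:.3g}, "
              f"Granger BH p {c.granger_bh_p:.3g})")


if __name__ == "__main__":
    main()
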