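"""Expression preprocessing and differential expression.

Covers RPKM transformation, sample-level PCA, the per-condition
negative-binomial likelihood-ratio test of "any time-point effect"
(H0: one mean across time points; H1: one mean per time point), BH FDR
control at 0.05, and the partition of DEGs into transcription factors
(GO:0003700) versus targets.

The LRT is a plain per-gene NB GLM with log link and library-total offsets:
no shrinkage, no size-factor estimation beyond totals. Gene-wise dispersion
is a method-of-moments estimate that matches the Pearson chi-square of the
full model to its residual degrees of freedom, floored at 1e-8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

TF_GO_TERM = "GO:0003700"

_DISPERSION_FLOOR = 1e-8
_DISPERSION_CEIL = 50.0


@dataclass
class TimeSeriesDesign:
    """Sample sheet for a two-condition time course with replicates.

    ``table`` is indexed by sample id with columns ``condition``, ``time_h``
    (numeric, sortable) and ``replicate``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"condition", "time_h", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))

    def samples_for(self, condition: str) -> list[str]:
        sub = self.table[self.table["condition"] == condition]
        sub = sub.sort_values(["time_h", "replicate"])
        return list(sub.index)

    def timepoints(self, condition: str) -> list[float]:
        sub = self.table[self.table["condition"] == condition]
        return sorted(sub["time_h"].unique())

    @classmethod
    def read_tsv(cls, path) -> "TimeSeriesDesign":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample")


@dataclass
class CountMatrix:
    """Gene x sample read counts with per-gene exon lengths in bp."""

    values: pd.DataFrame
    gene_length_bp: pd.Series

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.gene_length_bp = self.gene_length_bp.reindex(self.values.index)
        if self.gene_length_bp.isna().any() or (self.gene_length_bp <= 0).any():
            raise ValueError("every gene needs a positive length")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def read_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        lengths = df.pop("length_bp")
        return cls(df, lengths)

    def write_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "length_bp", self.gene_length_bp)
        out.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class PcaResult:
    scores: pd.DataFrame          # sample x component
    contribution_ratio: np.ndarray


@dataclass
class DegTable:
    """Per-gene LRT results for one condition."""

    table: pd.DataFrame           # lrt_statistic, df, p_value, fdr, is_deg, tested
    condition: str
    alpha: float = 0.05

    @property
    def deg_ids(self) -> list[str]:
        return list(self.table.index[self.table["is_deg"]])


def rpkm_transform(counts: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of exon per million mapped reads.

    rpkm = 1e9 * count / (gene_length_bp * per-sample mapped total).
    """
    totals = counts.values.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library size in samples: {bad}")
    denom = np.outer(counts.gene_length_bp.to_numpy(float), totals.to_numpy(float))
    return pd.DataFrame(
        1e9 * counts.values.to_numpy(float) / denom,
        index=counts.values.index,
        columns=counts.values.columns,
    )


def principal_components(rpkm: pd.DataFrame, n_components: int = 3) -> PcaResult:
    """PCA over samples (genes are features), eigendecomposition of the
    sample covariance of centered data; contribution ratio = lambda_i / sum."""
    from sklearn.decomposition import PCA

    x = rpkm.to_numpy(float).T  # samples x genes
    n_components = min(n_components, *x.shape)
    if np.allclose(x.var(axis=0), 0.0):
        warnings.warn("constant matrix: PCA undefined, returning zero scores")
        scores = np.zeros((x.shape[0], n_components))
        return PcaResult(
            pd.DataFrame(scores, index=rpkm.columns,
                         columns=[f"PC{i+1}" for i in range(n_components)]),
            np.zeros(n_components),
        )
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x)
    return PcaResult(
        pd.DataFrame(scores, index=rpkm.columns,
                     columns=[f"PC{i+1}" for i in range(n_components)]),
        pca.explained_variance_ratio_,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    adjusted_(i) = min_{j >= i} min(1, m * p_(j) / j) on the sorted vector.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB2 log-likelihood; y, mu are (genes, samples); alpha (genes,)."""
    a = alpha[:, None]
    n = 1.0 / a
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            special.gammaln(y + n) - special.gammaln(n) - special.gammaln(y + 1.0)
            + n * np.log(n / (n + mu))
            + y * np.log(mu / (n + mu))
        )
    return ll.sum(axis=1)


def _fit_group_means(y: np.ndarray, exposure: np.ndarray, alpha: np.ndarray,
                     n_iter: int = 50) -> np.ndarray:
    """MLE of a single NB rate per gene given exposures and fixed dispersion.

    Newton iterations on beta = log(rate); the score per sample is
    n (y - mu) / (mu + n) and the expected information is mu n / (mu + n).
    """
    rate = np.clip(y.sum(axis=1) / exposure.sum(), 1e-12, None)
    beta = np.log(rate)
    n = 1.0 / alpha
    for _ in range(n_iter):
        mu = np.exp(beta)[:, None] * exposure[None, :]
        score = (n[:, None] * (y - mu) / (mu + n[:, None])).sum(axis=1)
        info = (mu * n[:, None] / (mu + n[:, None])).sum(axis=1)
        step = score / np.clip(info, 1e-12, None)
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.exp(beta)


def _moment_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int) -> np.ndarray:
    """Dispersion alpha solving Pearson chi2(alpha) = residual df, per gene.

    chi2(alpha) = sum (y - mu)^2 / (mu + alpha mu^2) decreases in alpha, so a
    vectorized bisection suffices. Genes whose Poisson chi-square is already
    below the df get the floor.
    """
    df = max(y.shape[1] - n_params, 1)
    resid2 = (y - mu) ** 2

    def chi2(a):
        return (resid2 / (mu + a[:, None] * mu**2)).sum(axis=1)

    lo = np.full(y.shape[0], _DISPERSION_FLOOR)
    hi = np.full(y.shape[0], _DISPERSION_CEIL)
    under = chi2(lo) <= df
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_small = chi2(mid) > df
        lo = np.where(too_small, mid, lo)
        hi = np.where(too_small, hi, mid)
    alpha = 0.5 * (lo + hi)
    alpha[under] = _DISPERSION_FLOOR
    return np.clip(alpha, _DISPERSION_FLOOR, _DISPERSION_CEIL)


def nb_lrt(counts: CountMatrix, design: TimeSeriesDesign, condition: str,
           alpha: float = 0.05) -> DegTable:
    """NB likelihood-ratio test of time-point effect within one condition.

    Full model: one mean per time point; reduced: a single mean. Both use a
    log link with library-total offsets and a shared gene-wise dispersion
    (Pearson-matched method of moments on the full model, floored at 1e-8).
    The statistic is 2(l_full - l_reduced) with (#timepoints - 1) df.

    Because the dispersion is a plug-in estimate from few replicates, the
    chi-square reference is anticonservative; the statistic is instead
    referred to an F distribution, stat/df1 ~ F(df1, S - T), the
    quasi-likelihood-style small-sample reference (df2 is the dispersion
    estimate's residual df). FDR by BH; DEG iff fdr < alpha. All-zero genes
    get p = 1, are flagged untested and excluded from the BH denominator.
    """
    samples = design.samples_for(condition)
    if not samples:
        raise ValueError(f"no samples for condition {condition!r}")
    sub = design.table.loc[samples]
    times = sorted(sub["time_h"].unique())
    if len(times) < 2:
        raise ValueError("need at least two time points")

    y_all = counts.values[samples].to_numpy(float)
    totals = counts.values[samples].sum(axis=0).to_numpy(float)
    exposure = totals / totals.mean()
    groups = [np.flatnonzero((sub["time_h"] == t).to_numpy()) for t in times]
    if min(len(g) for g in groups) < 2:
        raise ValueError("need at least two replicates per time point")

    tested = y_all.sum(axis=1) > 0
    y = y_all[tested]
    n_genes = y.shape[0]

    # initial per-group Poisson rates -> dispersion -> NB refits
    mu_full = np.empty_like(y)
    for g in groups:
        rate = y[:, g].sum(axis=1) / exposure[g].sum()
        mu_full[:, g] = np.clip(rate, 1e-12, None)[:, None] * exposure[None, g]
    disp = _moment_dispersion(y, np.clip(mu_full, 1e-8, None), n_params=len(groups))

    ll_full = np.zeros(n_genes)
    mu_fit = np.empty_like(y)
    for g in groups:
        rate = _fit_group_means(y[:, g], exposure[g], disp)
        mu_fit[:, g] = rate[:, None] * exposure[None, g]
    ll_full = _nb_loglik(y, np.clip(mu_fit, 1e-12, None), disp)

    rate0 = _fit_group_means(y, exposure, disp)
    mu0 = rate0[:, None] * exposure[None, :]
    ll_red = _nb_loglik(y, np.clip(mu0, 1e-12, None), disp)

    df = len(times) - 1
    df_resid = len(samples) - len(times)
    stat = np.clip(2.0 * (ll_full - ll_red), 0.0, None)
    pvals = stats.f.sf(stat / df, df, df_resid)

    table = pd.DataFrame(
        index=counts.values.index,
        data={
            "lrt_statistic": 0.0,
            "df": df,
            "p_value": 1.0,
            "fdr": 1.0,
            "is_deg": False,
            "tested": tested,
            "dispersion": np.nan,
        },
    )
    table.loc[tested, "lrt_statistic"] = stat
    table.loc[tested, "p_value"] = pvals
    table.loc[tested, "dispersion"] = disp
    table.loc[tested, "fdr"] = bh_adjust(pvals)
    table["is_deg"] = table["fdr"] < alpha
    if (~tested).any():
        warnings.warn(f"{int((~tested).sum())} all-zero genes excluded from testing")
    return DegTable(table, condition, alpha)


@dataclass
class VennCounts:
    """Four-way DEG partition: TF vs other, per condition and shared."""

    condition_a: str
    condition_b: str
    tf: dict[str, int] = field(default_factory=dict)
    other: dict[str, int] = field(default_factory=dict)
    tf_genes: dict[str, set] = field(default_factory=dict)
    other_genes: dict[str, set] = field(default_factory=dict)


def partition_tf_targets(deg_by_condition: dict[str, DegTable],
                         go_annotation: dict[str, set]) -> VennCounts:
    """Split DEGs into transcription factors (GO:0003700) and targets and
    count condition-exclusive and shared members of each class.

    Genes missing from the annotation are non-TFs.
    """
    if len(deg_by_condition) != 2:
        raise ValueError("expected exactly two conditions")
    (cond_a, deg_a), (cond_b, deg_b) = deg_by_condition.items()
    degs_a, degs_b = set(deg_a.deg_ids), set(deg_b.deg_ids)

    def is_tf(g):
        return TF_GO_TERM in go_annotation.get(g, set())

    out = VennCounts(cond_a, cond_b)
    for label, gene_filter in (("tf", is_tf), ("other", lambda g: not is_tf(g))):
        a_only = {g for g in degs_a - degs_b if gene_filter(g)}
        b_only = {g for g in degs_b - degs_a if gene_filter(g)}
        both = {g for g in degs_a & degs_b if gene_filter(g)}
        counts = {f"{cond_a}_only": len(a_only), f"{cond_b}_only": len(b_only),
                  "both": len(both)}
        genes = {f"{cond_a}_only": a_only, f"{cond_b}_only": b_only, "both": both}
        if label == "tf":
            out.tf, out.tf_genes = counts, genes
        else:
            out.other, out.other_genes = counts, genes
    return out


def read_go_annotation(path) -> dict[str, set]:
    """Two-column TSV (gene_id, go_id) -> gene -> set of GO ids."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "go_id"])
    out: dict[str, set] = {}
    for g, go in zip(df["gene_id"], df["go_id"]):
        out.setdefault(str(g), set()).add(str(go))
    return out


def write_go_annotation(annotation: dict[str, set], path) -> None:
    rows = [(g, go) for g, gos in sorted(annotation.items()) for go in sorted(gos)]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def zscore_profiles(rpkm: pd.DataFrame, design: TimeSeriesDesign,
                    genes=None) -> pd.DataFrame:
    """Per-gene Z-scores of replicate-averaged time-point means, concatenated
    across conditions (columns ordered condition-by-condition, time-ascending).
    """
    if genes is not None:
        rpkm = rpkm.loc[list(genes)]
    cols = []
    labels = []
    for cond in design.conditions:
        for t in design.timepoints(cond):
            samp = [s for s in design.samples_for(cond)
                    if design.table.loc[s, "time_h"] == t]
            cols.append(rpkm[samp].mean(axis=1))
            labels.append(f"{cond}:{t:g}")
    mat = pd.concat(cols, axis=1)
    mat.columns = labels
    mu = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=0)
    sd = sd.replace(0.0, np.nan)
    z = mat.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
    return z
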