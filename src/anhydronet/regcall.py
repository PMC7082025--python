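"""TF→module regulation calls: promoter motif enrichment + Granger causality.

A TF is called a direct regulator of a module when (a) its binding motif is
enriched in the module genes' upstream regions (randomization test of the
mean best-hit log-odds score against equal-sized background draws, over
multiple upstream window lengths, significant at p < 0.05 in at least one
window) and (b) its time-series Z-score Granger-causes the module's mean
Z-score (bivariate VAR, lag chosen by AIC, upper-tail F-test, BH-adjusted
p < 0.05 over all tested pairs).

The enrichment statistic replaces the original black-box scorer with a
documented best-hit-mean randomization test; windows are measured from the
TSS-proximal (3') end of the supplied upstream sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prep import bh_adjust

DEFAULT_WINDOWS = (100, 500, 1000, 2000, 3000, 4000, 5000, 10000)

_BASES = "ACGT"
_PROB_FLOOR = 1e-3


@dataclass
class Pwm:
    """Position weight matrix: rows are positions, columns A, C, G, T."""

    motif_id: str
    matrix: np.ndarray
    tf_id: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be positions x 4")
        if len(self.matrix) < 4:
            raise ValueError("PWM must span at least 4 positions")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))


def write_meme(pwms: list[Pwm], path) -> None:
    """Minimal MEME motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                     f"nsites= 20 E= 0\n")
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[Pwm]:
    """Read a minimal MEME file via Biopython."""
    from Bio import motifs

    with open(path) as fh:
        records = motifs.parse(fh, "minimal")
    out = []
    for m in records:
        mat = np.array([[m.pwm[b][i] for b in _BASES] for i in range(m.length)])
        mat = mat / mat.sum(axis=1, keepdims=True)
        out.append(Pwm(m.name, mat))
    return out


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(_BASES):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _logodds(matrix: np.ndarray) -> np.ndarray:
    lo = np.log2(np.clip(matrix, _PROB_FLOOR, None) / 0.25)
    return np.hstack([lo, np.zeros((len(lo), 1))])  # column 4: ambiguity -> 0


def scan_pwm(pwm: Pwm, sequence: str) -> float:
    """Best-hit log-odds score (bits) over both strands and all offsets.

    Per-position score is log2(p_base / 0.25) with probabilities floored at
    1e-3; ambiguity codes score as background (0 bits).
    """
    w = len(pwm)
    if len(sequence) < w:
        raise ValueError("sequence shorter than PWM")
    enc = _encode(sequence)
    lo_fwd = _logodds(pwm.matrix)
    lo_rev = lo_fwd[::-1, [3, 2, 1, 0, 4]]  # reverse complement
    n_win = len(enc) - w + 1
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    pos = np.arange(w)
    fwd = lo_fwd[pos, windows].sum(axis=1)
    rev = lo_rev[pos, windows].sum(axis=1)
    assert len(fwd) == n_win
    return float(max(fwd.max(), rev.max()))


def _window_slice(seq: str, window: int) -> str:
    """Windows are anchored at the TSS-proximal (3') end."""
    return seq[-window:] if window < len(seq) else seq


def best_hit_scores(pwm: Pwm, sequences: dict[str, str], window: int) -> dict[str, float]:
    out = {}
    for name, seq in sequences.items():
        sub = _window_slice(seq, window)
        if len(sub) < len(pwm):
            warnings.warn(f"sequence {name} shorter than PWM at window {window}; "
                          "excluded")
            continue
        out[name] = scan_pwm(pwm, sub)
    return out


@dataclass
class MotifHitResult:
    tf_id: str
    module: str
    per_window: pd.DataFrame      # window, statistic, p_value
    any_window_significant: bool
    min_p: float


def motif_enrichment(pwm: Pwm, module_upstreams: dict[str, str],
                     background_upstreams: dict[str, str],
                     window_lengths=DEFAULT_WINDOWS, n_draws: int = 1000,
                     seed: int = 0, tf_id: str | None = None,
                     module: str = "") -> MotifHitResult:
    """Randomization test of mean best-hit score, per upstream window.

    Null statistics are means over ``n_draws`` random equal-sized subsets of
    the background; p = (1 + #null >= observed) / (1 + n_draws).
    """
    if not module_upstreams:
        raise ValueError("empty module sequence set")
    if len(background_upstreams) < len(module_upstreams):
        raise ValueError("background smaller than module set")
    rng = np.random.default_rng(seed)
    rows = []
    for window in window_lengths:
        mod_scores = best_hit_scores(pwm, module_upstreams, window)
        bg_scores = best_hit_scores(pwm, background_upstreams, window)
        if not mod_scores or len(bg_scores) < len(mod_scores):
            rows.append({"window": window, "statistic": np.nan, "p_value": np.nan})
            continue
        observed = float(np.mean(list(mod_scores.values())))
        bg = np.array(list(bg_scores.values()))
        k = len(mod_scores)
        draws = np.empty(n_draws)
        for d in range(n_draws):
            draws[d] = bg[rng.choice(len(bg), size=k, replace=False)].mean()
        p = float((1 + (draws >= observed - 1e-12).sum()) / (1 + n_draws))
        rows.append({"window": window, "statistic": observed, "p_value": p})
    per_window = pd.DataFrame(rows)
    finite = per_window["p_value"].dropna()
    min_p = float(finite.min()) if len(finite) else np.nan
    return MotifHitResult(tf_id or pwm.tf_id or pwm.motif_id, module, per_window,
                          bool(np.isfinite(min_p) and min_p < 0.05), min_p)


@dataclass
class GrangerResult:
    tf_id: str
    module: str
    condition: str
    selected_lag: int
    f_statistic: float
    p_value: float
    flagged: bool = False
    bh_adjusted_p: float = np.nan


def granger_causality(tf_zscore, module_mean_zscore, max_lag: int = 2,
                      tf_id: str = "", module: str = "",
                      condition: str = "") -> GrangerResult:
    """Bivariate VAR Granger test of TF (cause) → module mean (effect).

    The lag is selected by AIC over 1..max_lag (capped so the VAR stays
    estimable for short series) and the null that all cause lags have zero
    coefficients in the effect equation is tested with an upper-tail F-test.
    Constant series yield p = 1 with a flag.
    """
    from statsmodels.tsa.api import VAR

    cause = np.asarray(tf_zscore, float)
    effect = np.asarray(module_mean_zscore, float)
    if len(cause) != len(effect):
        raise ValueError("series length mismatch")
    if not (np.isfinite(cause).all() and np.isfinite(effect).all()):
        raise ValueError("series must be finite")
    t = len(cause)
    if np.std(cause) == 0 or np.std(effect) == 0:
        return GrangerResult(tf_id, module, condition, 1, np.nan, 1.0, flagged=True)
    # VAR(p) on 2 series spends 2p+1 params per equation; keep some residual df
    feasible = max(1, (t - 2) // 3)
    lag_cap = min(max_lag, feasible)
    data = np.column_stack([cause, effect])
    try:
        model = VAR(data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = model.select_order(maxlags=lag_cap)
            lag = int(sel.aic) if sel.aic and sel.aic >= 1 else 1
            lag = min(lag, lag_cap)
            res = model.fit(lag)
            test = res.test_causality(caused=1, causing=0, kind="f")
        return GrangerResult(tf_id, module, condition, lag,
                             float(test.test_statistic), float(test.pvalue))
    except Exception as exc:  # degenerate series
        warnings.warn(f"Granger test failed for ({tf_id}, {module}): {exc}")
        return GrangerResult(tf_id, module, condition, 1, np.nan, 1.0, flagged=True)


@dataclass
class RegulationCall:
    tf_id: str
    module: str
    called: bool
    motif_min_p: float
    granger_bh_p: float


def adjust_granger(results: list[GrangerResult]) -> list[GrangerResult]:
    """BH adjustment across all tested (tf, module, condition) triples."""
    if not results:
        return results
    p = np.array([r.p_value for r in results])
    adj = bh_adjust(p)
    for r, a in zip(results, adj):
        r.bh_adjusted_p = float(a)
    return results


def call_regulators(motif_results: list[MotifHitResult],
                    granger_results: list[GrangerResult],
                    alpha: float = 0.05) -> list[RegulationCall]:
    """Joint call: motif p < alpha in some window AND BH-adjusted Granger
    p < alpha (in any condition). Granger results must already carry their
    BH-adjusted p over the full tested set."""
    granger_best: dict[tuple[str, str], float] = {}
    for r in granger_results:
        if np.isnan(r.bh_adjusted_p):
            raise ValueError("run adjust_granger before calling regulators")
        key = (r.tf_id, r.module)
        granger_best[key] = min(granger_best.get(key, np.inf), r.bh_adjusted_p)

    motif_by_pair = {(m.tf_id, m.module): m for m in motif_results}
    calls = []
    for key in sorted(set(motif_by_pair) | set(granger_best)):
        motif = motif_by_pair.get(key)
        gr = granger_best.get(key, np.nan)
        if motif is None or key not in granger_best:
            warnings.warn(f"pair {key} present in only one evidence table; not called")
            calls.append(RegulationCall(key[0], key[1], False,
                                        motif.min_p if motif else np.nan, gr))
            continue
        called = bool(motif.any_window_significant and gr < alpha)
        calls.append(RegulationCall(key[0], key[1], called, motif.min_p, float(gr)))
    return calls


def load_pwm_tf_links(hit_table: pd.DataFrame | str, e_threshold: float = 1e-5
                      ) -> dict[str, set[str]]:
    """TF → motif-source ids linked by a similarity hit table (BLAST outfmt 6
    layout) at e-value < ``e_threshold``."""
    if not isinstance(hit_table, pd.DataFrame):
        hit_table = pd.read_csv(hit_table, sep="\t", header=None)
    links: dict[str, set[str]] = {}
    for row in hit_table.itertuples(index=False):
        query, subject, evalue = str(row[0]), str(row[1]), float(row[10])
        if evalue < e_threshold:
            links.setdefault(query, set()).add(subject)
    return links
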