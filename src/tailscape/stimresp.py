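"""Stimulation-response analysis of tail lengths and expression.

Replicate cohorts (default 4 control vs 4 stimulated samples) are compared
per gene on two axes: mean poly(A)-tail length (Welch t-test on the
per-replicate gene means) and poly(A)-tag counts (a negative-binomial test
with median-of-ratios size factors, method-of-moments dispersion shrunk to
a common trend, a Wald test on the cohort coefficient, and
Benjamini-Hochberg adjustment).  The two test outcomes classify the
mechanism behind a stimulus-induced tail-length increase:

* tail up + expression up -> ``burst`` (a wave of young, long-tailed
  nascent transcripts),
* tail up + expression down -> ``short-tail-decay`` (preferential loss of
  short-tailed isoforms),
* tail up + expression flat -> ``cytoplasmic-polyadenylation``,
* otherwise -> ``none``.

A Fisher's exact test asks whether a 3'-UTR motif (by default CPE-class
U-rich patterns) associates with tail-length increases, and a global
summary checks that stimulation leaves the overall tail-length distribution
unchanged (one-way ANOVA on per-sample means).
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "differential_tail",
    "differential_expression",
    "classify_mechanism",
    "motif_association",
    "global_tail_summary",
    "short_tail_depletion",
    "CPE_PATTERNS",
]

# Reconstructed CPE-class motifs (configurable; the canonical element is
# UUUUAU-like, with a UUUUAAU variant).
CPE_PATTERNS = ("TTTTAT", "TTTTAAT")


def differential_tail(
    control: pd.DataFrame, stimulated: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene tail-length change between replicate cohorts.

    Inputs are genes x replicates tables of per-replicate mean tail lengths
    (genes passing the 50-tag cutoff in every sample).  Returns delta_tail
    (stimulated - control, nt) and a two-sided Welch t-test p-value.  When
    both cohorts have zero within-cohort variance the test degenerates:
    p = 1 for equal means, p = 0 otherwise.
    """
    if control.shape[1] < 2 or stimulated.shape[1] < 2:
        raise ValueError("need >= 2 replicates per cohort")
    genes = control.index.intersection(stimulated.index)
    c = control.loc[genes].to_numpy(dtype=float)
    s = stimulated.loc[genes].to_numpy(dtype=float)
    delta = s.mean(axis=1) - c.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-identical replicates trip a precision warning; the degenerate
        # case is overridden explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(s, c, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    degenerate = (c.var(axis=1) == 0) & (s.var(axis=1) == 0)
    pvals[degenerate] = np.where(delta[degenerate] == 0, 1.0, 0.0)
    return pd.DataFrame({"delta_tail": delta, "p_tail": pvals}, index=genes)


def _size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors over genes with all-positive counts."""
    positive = counts[(counts > 0).all(axis=1)]
    log_geo = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geo, axis=0)
    return np.exp(ratios.median(axis=0).to_numpy())


def differential_expression(
    control: pd.DataFrame,
    stimulated: pd.DataFrame,
    alpha_floor: float = 1e-8,
) -> pd.DataFrame:
    """Negative-binomial expression test between replicate cohorts.

    Counts (genes x replicates per cohort) are normalized with
    median-of-ratios size factors.  Per-gene dispersion is estimated by
    method of moments and shrunk to a common mean-dispersion trend
    (alpha(mu) = a0 + a1/mu fit across genes); the Wald statistic for the
    cohort log-fold-change uses the delta-method standard error from the NB
    variance mu + alpha*mu^2.  P-values are Benjamini-Hochberg adjusted.
    All-zero genes are excluded.
    """
    if control.shape[1] < 2 or stimulated.shape[1] < 2:
        raise ValueError("need >= 2 replicates per cohort")
    genes = control.index.intersection(stimulated.index)
    counts = pd.concat([control.loc[genes], stimulated.loc[genes]], axis=1)
    nonzero = counts.sum(axis=1) > 0
    counts = counts[nonzero]
    genes = counts.index
    sf = _size_factors(counts)
    norm = counts.to_numpy(dtype=float) / sf[None, :]
    n_c = control.shape[1]
    norm_c, norm_s = norm[:, :n_c], norm[:, n_c:]
    mu_c = norm_c.mean(axis=1)
    mu_s = norm_s.mean(axis=1)
    # method-of-moments dispersion pooled across both cohorts
    mu_all = norm.mean(axis=1)
    within_var = (norm_c.var(axis=1, ddof=1) + norm_s.var(axis=1, ddof=1)) / 2.0
    raw_alpha = (within_var - mu_all) / np.maximum(mu_all, 1e-12) ** 2
    # common trend alpha(mu) = a0 + a1/mu, fit on genes with usable moments
    usable = (mu_all > 0) & np.isfinite(raw_alpha)
    x = np.column_stack([np.ones(usable.sum()), 1.0 / mu_all[usable]])
    coef, *_ = np.linalg.lstsq(x, raw_alpha[usable], rcond=None)
    alpha = np.maximum(coef[0] + coef[1] / np.maximum(mu_all, 1e-12), alpha_floor)
    pseudo = 0.5
    log2fc = np.log2((mu_s + pseudo) / (mu_c + pseudo))
    # delta-method variance of log2 of a cohort mean of NB counts
    var_log2_c = (mu_c + alpha * mu_c**2) / (
        control.shape[1] * np.maximum(mu_c + pseudo, 1e-12) ** 2 * np.log(2) ** 2
    )
    var_log2_s = (mu_s + alpha * mu_s**2) / (
        stimulated.shape[1] * np.maximum(mu_s + pseudo, 1e-12) ** 2 * np.log(2) ** 2
    )
    se = np.sqrt(var_log2_c + var_log2_s)
    wald = log2fc / np.maximum(se, 1e-12)
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_expression": pvals,
            "padj_expression": padj,
            "mean_control": mu_c,
            "mean_stimulated": mu_s,
            "dispersion": alpha,
        },
        index=genes,
    )


def classify_mechanism(
    results: pd.DataFrame,
    tail_alpha: float = 0.05,
    expression_alpha: float = 0.05,
) -> pd.Series:
    """Mechanism label per gene from the two test outcomes.

    ``results`` must carry delta_tail, p_tail, log2fc, padj_expression.  A
    significant tail increase (p < ``tail_alpha`` and delta > 0) combined
    with a significant expression increase, decrease, or no change maps to
    burst, short-tail-decay, or cytoplasmic-polyadenylation respectively;
    anything else is none.  The labeling is a pure function of the test
    outcomes.
    """
    tail_up = (results["p_tail"] < tail_alpha) & (results["delta_tail"] > 0)
    expr_sig = results["padj_expression"] < expression_alpha
    expr_up = expr_sig & (results["log2fc"] > 0)
    expr_down = expr_sig & (results["log2fc"] < 0)
    labels = np.full(len(results), "none", dtype=object)
    labels[tail_up & expr_up] = "burst"
    labels[tail_up & expr_down] = "short-tail-decay"
    labels[tail_up & ~expr_sig] = "cytoplasmic-polyadenylation"
    return pd.Series(labels, index=results.index, name="mechanism")


def motif_association(
    tail_increased: pd.Series, has_motif: pd.Series
) -> dict:
    """Fisher's exact test of motif presence vs tail-length increase.

    Both inputs are boolean Series over the same genes.  Returns the 2x2
    table, odds ratio, and two-sided p.  An empty margin makes the test
    uninformative: p = 1 with a warning.
    """
    genes = tail_increased.index.intersection(has_motif.index)
    a = int((tail_increased.loc[genes] & has_motif.loc[genes]).sum())
    b = int((tail_increased.loc[genes] & ~has_motif.loc[genes]).sum())
    c = int((~tail_increased.loc[genes] & has_motif.loc[genes]).sum())
    d = int((~tail_increased.loc[genes] & ~has_motif.loc[genes]).sum())
    table = np.array([[a, b], [c, d]])
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warnings.warn("empty margin in motif association table; p = 1")
        return {"table": table, "odds_ratio": np.nan, "p": 1.0}
    odds, p = stats.fisher_exact(table)
    return {"table": table, "odds_ratio": float(odds), "p": float(p)}


def find_cpe(utr3_sequence: str, patterns: tuple = CPE_PATTERNS) -> bool:
    """True when the 3'-UTR contains any configured CPE-class motif."""
    seq = utr3_sequence.upper().replace("U", "T")
    return any(re.search(p, seq) for p in patterns)


def global_tail_summary(
    tails_by_sample: dict,
    treatment: dict,
    bin_width: int = 2,
    max_tail: int | None = None,
) -> dict:
    """Distribution summaries and across-cohort ANOVA on sample mean tails.

    ``tails_by_sample`` maps sample id -> array of per-tag tail lengths;
    ``treatment`` maps sample id -> cohort label.  Histograms use
    ``bin_width``-nt bins.  The ANOVA compares per-sample mean tails grouped
    by treatment; identical cohorts give F = 0 (p reported as 1).
    """
    if len(set(treatment.values())) < 2:
        raise ValueError("need >= 2 cohorts")
    if max_tail is None:
        max_tail = int(max(np.max(v) for v in tails_by_sample.values())) + bin_width
    edges = np.arange(0, max_tail + bin_width, bin_width)
    histograms = {
        s: np.histogram(np.asarray(v), bins=edges)[0] for s, v in tails_by_sample.items()
    }
    sample_means = {s: float(np.mean(v)) for s, v in tails_by_sample.items()}
    groups = {}
    for s, grp in treatment.items():
        groups.setdefault(grp, []).append(sample_means[s])
    with warnings.catch_warnings():
        # identical cohorts trigger a constant-input warning; F = 0 there
        warnings.simplefilter("ignore")
        f_stat, p = stats.f_oneway(*groups.values())
    if not np.isfinite(p):
        p = 1.0
    return {
        "bin_edges": edges,
        "histograms": histograms,
        "sample_means": sample_means,
        "anova_F": float(f_stat) if np.isfinite(f_stat) else 0.0,
        "anova_p": float(p),
    }


def short_tail_depletion(
    control_tails: np.ndarray, stimulated_tails: np.ndarray, quantile: float = 0.25
) -> dict:
    """Change in the short-tail fraction between cohorts.

    The length cutoff is the given quantile of the pooled control
    distribution; returns each cohort's fraction of tags below the cutoff
    and their difference (negative = depletion of short-tailed molecules
    after stimulation).
    """
    cutoff = float(np.quantile(np.asarray(control_tails), quantile))
    f_c = float(np.mean(np.asarray(control_tails) < cutoff))
    f_s = float(np.mean(np.asarray(stimulated_tails) < cutoff))
    return {"cutoff": cutoff, "control_fraction": f_c, "stimulated_fraction": f_s,
            "difference": f_s - f_c}
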