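"""Translational-efficiency quantification and its sequence correlates.

TE for a gene is log2(RPF RPM / RNA RPM), computed from ribosome-protected
fragment and RNA-seq counts over the ORF (upstream counting excludes the
first 50 nt of each ORF; this module takes the counts as given).  Companion
statistics cover the spread of TE values (1-99 percentile fold range),
per-codon and per-amino-acid correlations with TE, ribosomal A-site codon
enrichment, RPF frame periodicity QC, and the tail-length/TE relationship
including a subset permutation test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SENSE_CODONS",
    "codon_frequencies",
    "compute_te",
    "percentile_range",
    "codon_te_correlation",
    "asite_occupancy",
    "occupancy_te_regression",
    "rpf_periodicity",
    "tail_te_correlation",
    "subset_correlation_test",
]

_BASES = "TCAG"
_STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES if a + b + c not in _STOPS
)

# standard genetic code, for pooling synonymous codons
_CODON_TO_AA = {}
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate(
    (a, b, c) for a in _BASES for b in _BASES for c in _BASES
):
    _CODON_TO_AA[_a + _b + _c] = _AA_ORDER[_i]


def codon_frequencies(cds_sequences: dict) -> pd.DataFrame:
    """Per-gene sense-codon frequencies (rows: genes, columns: 61 codons).

    Each CDS must have length divisible by 3; stop codons are excluded from
    both counts and the denominator.
    """
    from collections import Counter

    sense = set(SENSE_CODONS)
    rows = {}
    for gene, seq in cds_sequences.items():
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3:
            raise ValueError(f"CDS length of {gene} not divisible by 3")
        counts = Counter(seq[i : i + 3] for i in range(0, len(seq), 3))
        total = sum(v for c, v in counts.items() if c in sense)
        rows[gene] = {c: counts.get(c, 0) / total if total else 0.0 for c in SENSE_CODONS}
    return pd.DataFrame.from_dict(rows, orient="index")[list(SENSE_CODONS)]


def compute_te(
    rpf_counts: pd.Series,
    rna_counts: pd.Series,
    rpf_library_size: float | None = None,
    rna_library_size: float | None = None,
    rpm_cutoff: float = 10.0,
) -> pd.DataFrame:
    """Per-gene TE table from one RPF/RNA sample pair.

    RPM = count * 1e6 / library size (library sizes default to the column
    totals).  The RPM cutoff applies to the RNA-seq sample only; retained
    genes with zero RPF counts have no defined TE and are dropped with a
    warning.  TE is reported in log2.
    """
    rpf_lib = float(rpf_library_size if rpf_library_size is not None else rpf_counts.sum())
    rna_lib = float(rna_library_size if rna_library_size is not None else rna_counts.sum())
    if rpf_lib <= 0 or rna_lib <= 0:
        raise ValueError("library sizes must be positive")
    genes = rpf_counts.index.intersection(rna_counts.index)
    rna_rpm = rna_counts.loc[genes] * 1e6 / rna_lib
    rpf_rpm = rpf_counts.loc[genes] * 1e6 / rpf_lib
    passed = rna_rpm >= rpm_cutoff
    zero_rpf = passed & (rpf_rpm <= 0)
    if zero_rpf.any():
        warnings.warn(
            f"{int(zero_rpf.sum())} genes passed the RNA RPM cutoff but had no RPF "
            "reads; TE undefined, dropped"
        )
    keep = passed & (rpf_rpm > 0)
    out = pd.DataFrame(
        {
            "rna_rpm": rna_rpm[keep],
            "rpf_rpm": rpf_rpm[keep],
            "te": np.log2(rpf_rpm[keep] / rna_rpm[keep]),
        }
    )
    return out


def percentile_range(te: pd.Series | np.ndarray, lo: float = 1.0, hi: float = 99.0) -> float:
    """Fold range of TE between the ``lo`` and ``hi`` percentiles.

    log2 TE values are median-centered (the centering cancels in the range
    but mirrors how the distributions are displayed) and the fold range
    2**(P_hi - P_lo) is returned, with linear interpolation between order
    statistics.
    """
    values = np.asarray(te, dtype=float)
    if values.size < 100:
        raise ValueError("need >= 100 genes for a stable percentile range")
    centered = values - np.median(values)
    p_lo, p_hi = np.percentile(centered, [lo, hi])
    return float(2.0 ** (p_hi - p_lo))


def codon_te_correlation(
    codon_freqs: pd.DataFrame,
    te_by_sample: pd.DataFrame,
    by_amino_acid: bool = False,
) -> pd.DataFrame:
    """Mean +/- SD across samples of each codon's Pearson R with TE.

    ``codon_freqs`` is genes x codons (from :func:`codon_frequencies`);
    ``te_by_sample`` is genes x samples of log2 TE.  With ``by_amino_acid``
    frequencies are pooled over synonymous codons first.  Codons whose
    frequency has zero variance yield an undefined R, reported as NaN.
    Output is sorted by descending mean R.
    """
    if by_amino_acid:
        groups = pd.Series({c: _CODON_TO_AA[c] for c in codon_freqs.columns})
        codon_freqs = codon_freqs.T.groupby(groups).sum().T
    results = {}
    for feature in codon_freqs.columns:
        rs = []
        for sample in te_by_sample.columns:
            joined = pd.concat(
                [codon_freqs[feature], te_by_sample[sample]], axis=1, join="inner"
            ).dropna()
            x, y = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
            if x.std() == 0 or y.std() == 0 or len(x) < 3:
                rs.append(np.nan)
            else:
                rs.append(stats.pearsonr(x, y)[0])
        rs = np.asarray(rs, dtype=float)
        results[feature] = {
            "mean_r": np.nanmean(rs) if np.any(np.isfinite(rs)) else np.nan,
            "sd_r": np.nanstd(rs, ddof=1) if np.sum(np.isfinite(rs)) > 1 else np.nan,
        }
    out = pd.DataFrame.from_dict(results, orient="index")
    return out.sort_values("mean_r", ascending=False)


def asite_occupancy(
    rpf_positions: pd.DataFrame,
    cds_sequences: dict,
    offset: int = 15,
    lengths: tuple = (29, 30, 31),
    min_in_frame: int = 100,
) -> pd.Series:
    """Per-codon ribosomal A-site enrichment.

    ``rpf_positions`` columns: gene, five_prime (0-based offset of the RPF
    5' end within the CDS), read_length.  The A site is placed ``offset`` nt
    downstream of the 5' end for reads of the accepted ``lengths`` (the
    field-standard +15 for 29-31-nt footprints).  Enrichment is the observed
    A-site codon frequency over the pooled transcriptome codon frequency.
    """
    sub = rpf_positions[rpf_positions["read_length"].isin(lengths)]
    asite = sub["five_prime"].to_numpy() + offset
    in_frame = asite % 3 == 0
    counts = pd.Series(0.0, index=list(SENSE_CODONS))
    n_used = 0
    for gene, pos in zip(sub["gene"].to_numpy()[in_frame], asite[in_frame]):
        seq = cds_sequences.get(gene)
        if seq is None or pos + 3 > len(seq):
            continue
        codon = seq[pos : pos + 3].upper()
        if codon in counts.index:
            counts[codon] += 1
            n_used += 1
    if n_used < min_in_frame:
        raise ValueError(f"only {n_used} in-frame A-site reads (< {min_in_frame})")
    observed = counts / counts.sum()
    background = pd.Series(0.0, index=list(SENSE_CODONS))
    for seq in cds_sequences.values():
        seq = seq.upper()
        for i in range(0, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in background.index:
                background[codon] += 1
    background = background / background.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        return observed / background


def occupancy_te_regression(codon_te_r: pd.Series, enrichment: pd.Series) -> float:
    """R^2 of OLS of per-codon TE correlations on A-site enrichment."""
    joined = pd.concat([codon_te_r, enrichment], axis=1, join="inner").dropna()
    x = joined.iloc[:, 1].to_numpy()
    y = joined.iloc[:, 0].to_numpy()
    r, _ = stats.pearsonr(x, y)
    return float(r**2)


def rpf_periodicity(rpf_positions: pd.DataFrame, min_reads: int = 1000) -> np.ndarray:
    """Fraction of RPF 5' ends in each reading frame (sums to 1)."""
    frames = rpf_positions["five_prime"].to_numpy() % 3
    if frames.size < min_reads:
        raise ValueError(f"need >= {min_reads} CDS-mapped reads")
    return np.bincount(frames, minlength=3) / frames.size


def tail_te_correlation(mean_tail: pd.Series, te: pd.Series, exact_below: int = 30):
    """Spearman correlation between per-gene mean tail length and TE.

    Returns ``(r_s, p)``; two-sided p from the large-sample t approximation,
    or a seeded permutation p for small n (< ``exact_below``).
    """
    joined = pd.concat([mean_tail, te], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 10:
        raise ValueError("need >= 10 genes for a tail-TE correlation")
    x, y = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    r_s, p = stats.spearmanr(x, y)
    if n < exact_below:
        rng = np.random.default_rng(0)
        null = np.array(
            [stats.spearmanr(x, rng.permutation(y))[0] for _ in range(10_000)]
        )
        p = (1 + np.sum(np.abs(null) >= abs(r_s))) / (10_000 + 1)
    return float(r_s), float(p)


def subset_correlation_test(
    mean_tail: pd.Series,
    te: pd.Series,
    subset: pd.Index | list,
    n_perm: int = 1000,
    seed: int = 0,
):
    """Is a gene subset's tail-TE correlation larger than chance?

    The null distribution re-draws random subsets of identical size from all
    genes; the one-sided empirical p is the (add-one) fraction of null
    correlations at least as large as the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    joined = pd.concat([mean_tail, te], axis=1, join="inner").dropna()
    subset = pd.Index(subset).intersection(joined.index)
    if len(subset) < 50:
        raise ValueError("subset must contain >= 50 genes with both measurements")
    x = joined.iloc[:, 0]
    y = joined.iloc[:, 1]
    observed = stats.spearmanr(x.loc[subset], y.loc[subset])[0]
    rng = np.random.default_rng(seed)
    all_genes = joined.index.to_numpy()
    null = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(all_genes, size=len(subset), replace=False)
        null[i] = stats.spearmanr(x.loc[pick], y.loc[pick])[0]
    p = (1 + np.sum(null >= observed)) / (n_perm + 1)
    return float(observed), float(p), null
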