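"""miRNA-mediated repression statistics for site-defined mRNA cohorts.

Effects of an ectopically expressed miRNA on mRNA levels, RPF levels, and
mean poly(A)-tail length are measured as log2 fold-changes relative to
mRNAs lacking any 6-nt seed match to the miRNA anywhere in the transcript
(the no-site cohort).  Because secondary effects scale with 3'-UTR length,
fold-changes are first residualized on log 3'-UTR length: the slope is fit
on no-site mRNAs only and the fitted length component is subtracted from
every gene, so the post-normalization no-site slope is zero.  The cohort
effect is the mean normalized fold-change of the targets minus the median
normalized fold-change of the no-site cohort, tested one-tailed for
repression; an unpaired t-test compares the RNA and RPF effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "classify_sites",
    "normalize_fold_changes",
    "cohort_repression",
    "select_top_targets",
    "CohortEffect",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq))


def seed_match_sites(mirna_sequence: str) -> dict:
    """Target-site motifs (5'->3' mRNA sense) for a miRNA's seed.

    The seed match is the reverse complement of miRNA positions 2-7 (6mer)
    or 2-8 (7mer-m8); the A1 classes add an adenosine opposite miRNA
    position 1 regardless of the miRNA's first base.
    """
    mir = mirna_sequence.upper().replace("U", "T")
    if len(mir) < 8:
        raise ValueError("miRNA sequence must be >= 8 nt")
    six = _revcomp(mir[1:7])
    seven_m8 = _revcomp(mir[1:8])
    return {
        "6mer": six,
        "7mer-A1": six + "A",
        "7mer-m8": seven_m8,
        "8mer": seven_m8 + "A",
    }


def classify_sites(
    utr3_sequence: str, mirna_sequence: str, transcript_sequence: str | None = None
) -> str:
    """Strongest canonical seed-match site type in a 3'-UTR.

    Hierarchy: 8mer > 7mer-m8 > 7mer-A1 > 6mer.  A gene is ``none`` only
    when the 6mer match is absent from the entire transcript (``utr3`` is
    used when no transcript sequence is supplied).  Ambiguous bases never
    match.
    """
    sites = seed_match_sites(mirna_sequence)
    utr = utr3_sequence.upper().replace("U", "T")
    for site_type in ("8mer", "7mer-m8", "7mer-A1", "6mer"):
        if sites[site_type] in utr:
            return site_type
    scan = (transcript_sequence or utr3_sequence).upper().replace("U", "T")
    # a 6mer outside the 3'-UTR disqualifies the gene from the no-site
    # cohort without making it a canonical 3'-UTR target
    return "none" if sites["6mer"] not in scan else "excluded"


def normalize_fold_changes(
    fold_changes: pd.Series,
    utr3_lengths: pd.Series,
    no_site: pd.Index | list,
) -> pd.Series:
    """Remove the 3'-UTR-length confound from log2 fold-changes.

    The slope of no-site fold-changes on log10 3'-UTR length is estimated by
    OLS and the slope component ``slope * (log10 L - mean log10 L)`` is
    subtracted from every gene (intercept preserved), so that refitting on
    no-site genes gives slope 0.  Applying the normalization twice is a
    no-op.  All 3'-UTR lengths equal makes the fit degenerate and the data
    are returned unchanged.
    """
    no_site = pd.Index(no_site)
    if len(no_site) < 30:
        raise ValueError("need >= 30 no-site genes to fit the length confound")
    logl = np.log10(utr3_lengths.astype(float))
    x = logl.loc[no_site].to_numpy()
    y = fold_changes.loc[no_site].to_numpy()
    if np.ptp(x) == 0:
        return fold_changes.copy()
    slope = np.polyfit(x, y, 1)[0]
    center = x.mean()
    return fold_changes - slope * (logl.loc[fold_changes.index] - center)


@dataclass
class CohortEffect:
    """Repression summary for one cohort and one measure."""

    measure: str
    effect: float  # mean(cohort) - median(no-site), log2 units
    p_one_tailed: float | None
    n_cohort: int
    n_no_site: int


def cohort_repression(
    normalized_fc: dict | pd.DataFrame,
    cohort: pd.Index | list,
    no_site: pd.Index | list,
    min_cohort: int = 5,
) -> pd.DataFrame:
    """Cohort effects across measures, with significance tests.

    ``normalized_fc`` maps measure name (e.g. rna, rpf, tail) to a Series of
    normalized log2 fold-changes.  Per measure: effect = mean cohort FC -
    median no-site FC; one-tailed Welch t-test of cohort vs no-site with
    repression (cohort < no-site) as the alternative.  The returned frame
    also carries ``p_rna_vs_rpf`` (two-tailed unpaired t-test between the
    cohort's RNA and RPF fold-changes) when both measures are present.
    """
    cohort = pd.Index(cohort)
    no_site = pd.Index(no_site)
    if len(cohort.intersection(no_site)):
        raise ValueError("cohort and no-site sets must be disjoint")
    if isinstance(normalized_fc, pd.DataFrame):
        normalized_fc = {c: normalized_fc[c] for c in normalized_fc.columns}
    small = len(cohort) < min_cohort
    if small:
        warnings.warn(f"cohort of {len(cohort)} genes; effects reported without tests")
    rows = []
    for measure, fc in normalized_fc.items():
        c = fc.loc[cohort.intersection(fc.index)].dropna().to_numpy()
        ns = fc.loc[no_site.intersection(fc.index)].dropna().to_numpy()
        effect = float(c.mean() - np.median(ns))
        if small:
            p = None
        else:
            p = stats.ttest_ind(c, ns, equal_var=False, alternative="less").pvalue
        rows.append(
            CohortEffect(
                measure=measure,
                effect=effect,
                p_one_tailed=None if p is None else float(p),
                n_cohort=len(c),
                n_no_site=len(ns),
            )
        )
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("measure")
    if {"rna", "rpf"} <= set(out.index) and not small:
        rna = normalized_fc["rna"].loc[cohort.intersection(normalized_fc["rna"].index)].dropna()
        rpf = normalized_fc["rpf"].loc[cohort.intersection(normalized_fc["rpf"].index)].dropna()
        out.attrs["p_rna_vs_rpf"] = float(
            stats.ttest_ind(rna, rpf, equal_var=False).pvalue
        )
    return out


def select_top_targets(
    predicted_targets: pd.Index | list,
    reference_fraction: pd.Series,
    max_fraction: float = 0.75,
) -> pd.Index:
    """Top targets: predicted targets whose reference expression fell to
    <= ``max_fraction`` of its original level after miRNA induction.

    Genes missing from the reference table are excluded.
    """
    predicted = pd.Index(predicted_targets)
    known = predicted.intersection(reference_fraction.index)
    frac = reference_fraction.loc[known]
    return known[frac <= max_fraction]
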