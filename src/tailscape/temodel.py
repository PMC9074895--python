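"""Stepwise linear modeling of translational efficiency.

A per-gene feature table combines simple mRNA features (region lengths, GC
contents, expression, mean poly(A)-tail length, precomputed folding
energies) with complex features that are themselves linear sub-models over
many subfeatures (the 61 codon frequencies; 5'-UTR 6-mer counts).  The TE
model is built in two rounds of forward stepwise regression: round 1
selects features by AIC from the full menu; features whose inclusion adds
less than 0.003 adjusted R^2 are then dropped (poly(A)-tail length is
retained regardless, as the feature of primary interest); round 2 reruns
the stepwise selection on the reduced menu.  The final model is evaluated
by repeated random train/test splits, reporting the mean held-out R^2 and
95% percentile intervals of each feature's cumulative contribution.
Sub-models are refit inside each training split so that the held-out R^2
is leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, Ridge, RidgeCV

from .tequant import codon_frequencies

__all__ = [
    "ComplexFeature",
    "FeatureTable",
    "ModelFit",
    "build_feature_table",
    "fit_subfeature_model",
    "assemble_design",
    "stepwise_select",
    "filter_and_refit",
    "evaluate_model",
    "feature_correlation_matrix",
]


def _gc(seq: str) -> float:
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else np.nan


def _kmer_counts(sequences: dict, k: int = 6, max_kmers: int = 256) -> pd.DataFrame:
    """Per-gene k-mer counts, restricted to the ``max_kmers`` most abundant
    k-mers across all sequences (keeps the motif sub-model well conditioned
    and cheap to refit inside every bootstrap split)."""
    from collections import Counter

    per_gene = {}
    total: Counter = Counter()
    for gene, seq in sequences.items():
        seq = seq.upper().replace("U", "T")
        counts = Counter(seq[i : i + k] for i in range(len(seq) - k + 1))
        per_gene[gene] = counts
        total.update(counts)
    vocab = [kmer for kmer, _ in total.most_common(max_kmers)]
    rows = {g: [c.get(m, 0) for m in vocab] for g, c in per_gene.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=vocab).astype(float)


@dataclass
class ComplexFeature:
    """A group of subfeatures summarized by a linear sub-model.

    The sub-model is fit on training genes only; its predictions become a
    single column of the full design.  ``ridge_alpha`` switches to ridge
    regression (used for the high-dimensional 5'-UTR 6-mer counts, and as
    the automatic fallback for rank-deficient subfeature matrices).
    """

    name: str
    matrix: pd.DataFrame
    ridge_alpha: float | str | None = None


@dataclass
class FeatureTable:
    """Per-gene TE-model inputs: simple features plus complex-feature inputs."""

    simple: pd.DataFrame
    complexes: list = field(default_factory=list)

    @property
    def menu(self) -> list:
        return list(self.simple.columns) + [c.name for c in self.complexes]


def build_feature_table(
    sequences: pd.DataFrame,
    mean_tail: pd.Series,
    expression: pd.Series,
    folding: pd.DataFrame,
    isoform_utr3: pd.DataFrame | None = None,
    utr5_kmer_k: int = 6,
) -> FeatureTable:
    """Assemble the per-gene feature table.

    ``sequences`` has columns utr5, cds, utr3 (one representative mRNA per
    gene); ``folding`` carries the precomputed energies ``fe_utr3_per_nt``
    (minimum free energy normalized by 3'-UTR length, kcal/mol/nt) and
    ``fe_utr5_region`` (5' UTR plus first 35 nt of CDS).  ``isoform_utr3``
    (gene, utr3_length, fe_per_nt, expression), when given, replaces the
    single-isoform 3'-UTR length and folding energy with expression-weighted
    means over a gene's 3'-end isoforms.  Length and expression features are
    log10-transformed.
    """
    genes = sequences.index
    utr3_len = sequences["utr3"].str.len().astype(float)
    fe3 = folding["fe_utr3_per_nt"].reindex(genes)
    if isoform_utr3 is not None:
        grouped = isoform_utr3.groupby("gene")
        w_len = grouped.apply(
            lambda g: np.average(g["utr3_length"], weights=g["expression"]),
            include_groups=False,
        )
        utr3_len = w_len.reindex(genes).fillna(utr3_len)
        if "fe_per_nt" in isoform_utr3:
            w_fe = grouped.apply(
                lambda g: np.average(g["fe_per_nt"], weights=g["expression"]),
                include_groups=False,
            )
            fe3 = w_fe.reindex(genes).fillna(fe3)
    simple = pd.DataFrame(
        {
            "log_len_cds": np.log10(sequences["cds"].str.len()),
            "log_len_utr5": np.log10(sequences["utr5"].str.len().clip(lower=1)),
            "log_len_utr3": np.log10(utr3_len.clip(lower=1.0)),
            "gc_cds": sequences["cds"].map(_gc),
            "gc_utr5": sequences["utr5"].map(_gc),
            "gc_utr3": sequences["utr3"].map(_gc),
            "log_expression": np.log10(expression.reindex(genes).clip(lower=1e-3)),
            "tail_length": mean_tail.reindex(genes),
            "fe_utr3_per_nt": fe3,
            "fe_utr5_region": folding["fe_utr5_region"].reindex(genes),
        },
        index=genes,
    )
    codon = codon_frequencies(sequences["cds"].to_dict())
    kmers = _kmer_counts(sequences["utr5"].to_dict(), k=utr5_kmer_k)
    kmers = kmers.reindex(genes).fillna(0.0)
    return FeatureTable(
        simple=simple,
        complexes=[
            ComplexFeature("codon_composition", codon, ridge_alpha="cv"),
            ComplexFeature("utr5_motifs", kmers, ridge_alpha="cv"),
        ],
    )


def fit_subfeature_model(
    matrix: pd.DataFrame,
    te: pd.Series,
    train_idx: pd.Index,
    ridge_alpha: float | None = None,
) -> pd.Series:
    """Fit a linear sub-model on training genes; predict for all genes.

    Falls back to ridge with a small fixed penalty when the training matrix
    is rank-deficient for plain least squares.
    """
    x_train = matrix.loc[train_idx].to_numpy()
    y_train = te.loc[train_idx].to_numpy()
    if ridge_alpha == "cv":
        model = RidgeCV(alphas=np.logspace(-1, 5, 13))
    elif ridge_alpha is not None:
        model = Ridge(alpha=ridge_alpha)
    elif np.linalg.matrix_rank(x_train) < x_train.shape[1]:
        model = Ridge(alpha=1e-3)
    else:
        model = LinearRegression()
    model.fit(x_train, y_train)
    return pd.Series(model.predict(matrix.to_numpy()), index=matrix.index)


def assemble_design(
    table: FeatureTable,
    te: pd.Series,
    train_idx: pd.Index | None = None,
    cross_fit: int = 0,
) -> pd.DataFrame:
    """Full design matrix: simple features plus sub-model prediction columns.

    With ``cross_fit`` = k > 0 the sub-model predictions are computed
    out-of-fold (k-fold over genes), which keeps the stepwise selection from
    over-crediting complex features whose in-sample fit is optimistic.
    """
    if train_idx is None:
        train_idx = table.simple.index
    design = table.simple.copy()
    for cf in table.complexes:
        if cross_fit > 1:
            pred = pd.Series(np.nan, index=table.simple.index)
            folds = np.arange(len(pred)) % cross_fit
            for f in range(cross_fit):
                held = pred.index[folds == f]
                fitted = fit_subfeature_model(
                    cf.matrix, te, pred.index[folds != f], ridge_alpha=cf.ridge_alpha
                )
                pred.loc[held] = fitted.loc[held]
            design[cf.name] = pred
        else:
            design[cf.name] = fit_subfeature_model(
                cf.matrix, te, train_idx, ridge_alpha=cf.ridge_alpha
            )
    return design


def _ols_rss(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    design = np.column_stack([np.ones(len(y)), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float(resid @ resid)


def _aic(rss: float, n: int, n_features: int) -> float:
    # Gaussian log-likelihood profile; k = coefficients (incl. intercept) + 1
    k = n_features + 2
    return n * np.log(rss / n) + 2 * k


def _adj_r2(rss: float, tss: float, n: int, p: int) -> float:
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def stepwise_select(
    design: pd.DataFrame, te: pd.Series, menu: list | None = None
) -> list:
    """Forward stepwise selection by AIC.

    Starting from the intercept-only model, the feature whose addition
    minimizes the AIC joins the model; selection stops when no remaining
    feature decreases the AIC.  Returns feature names in selection order.
    """
    menu = list(menu if menu is not None else design.columns)
    if len(menu) < 2:
        raise ValueError("need >= 2 candidate features")
    y = te.loc[design.index].to_numpy()
    n = len(y)
    selected: list[str] = []
    current_aic = _aic(float(((y - y.mean()) ** 2).sum()), n, 0)
    while True:
        best = None
        for feat in menu:
            if feat in selected:
                continue
            x = design[selected + [feat]].to_numpy()
            _, rss = _ols_rss(x, y)
            aic = _aic(rss, n, len(selected) + 1)
            if best is None or aic < best[1]:
                best = (feat, aic)
        if best is None or best[1] >= current_aic:
            break
        selected.append(best[0])
        current_aic = best[1]
    return selected


def filter_and_refit(
    design: pd.DataFrame,
    te: pd.Series,
    round1: list,
    delta_r2: float = 0.003,
    forced: tuple = ("tail_length",),
) -> dict:
    """Round 2: drop weakly contributing features, force-keep, reselect.

    Features whose inclusion (in round-1 order) raised the adjusted R^2 by
    less than ``delta_r2`` leave the menu; ``forced`` features stay
    regardless.  Stepwise selection then reruns on the reduced menu, and
    forced features absent from the reselected list are appended so they
    appear in the final model.
    """
    for f in forced:
        if f not in design.columns:
            raise ValueError(f"forced feature {f!r} missing from the design")
    y = te.loc[design.index].to_numpy()
    n = len(y)
    tss = float(((y - y.mean()) ** 2).sum())
    contributions = {}
    prev = 0.0
    for i, feat in enumerate(round1):
        _, rss = _ols_rss(design[round1[: i + 1]].to_numpy(), y)
        adj = _adj_r2(rss, tss, n, i + 1)
        contributions[feat] = adj - prev
        prev = adj
    menu = [f for f in round1 if contributions[f] >= delta_r2]
    for f in forced:
        if f not in menu:
            menu.append(f)
    if len(menu) < 2:
        round2 = list(menu)
    else:
        round2 = stepwise_select(design, te, menu=menu)
    for f in forced:
        if f not in round2:
            round2.append(f)
    return {"round1_contributions": contributions, "menu": menu, "round2": round2}


@dataclass
class ModelFit:
    """Bootstrap evaluation of the final stepwise model."""

    features: list
    heldout_r2_mean: float
    heldout_r2_ci: tuple
    cumulative_r2_mean: np.ndarray
    cumulative_r2_ci: np.ndarray  # (n_features, 2)
    standalone_r2: pd.Series
    signs: pd.Series
    correlations: pd.DataFrame
    training_r2_mean: float


def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tss = float(((y_true - y_true.mean()) ** 2).sum())
    rss = float(((y_true - y_pred) ** 2).sum())
    return 1.0 - rss / tss


def evaluate_model(
    table: FeatureTable,
    te: pd.Series,
    features: list,
    n_boot: int = 100,
    split_fraction: float = 0.8,
    seed: int = 0,
) -> ModelFit:
    """Repeated random-split evaluation of an ordered feature list.

    For each of ``n_boot`` splits, complex sub-models and the cumulative
    OLS models are fit on the training genes and scored on the held-out
    genes.  Reported are the mean held-out R^2, the per-step cumulative
    held-out R^2 with 2.5/97.5 percentile intervals, each feature's
    standalone held-out R^2, its correlation sign with TE, and the pairwise
    Pearson matrix of the selected features.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    genes = table.simple.index
    n_train = int(round(split_fraction * len(genes)))
    if n_train < 1 or n_train >= len(genes):
        raise ValueError("degenerate train/test split")
    cumulative = np.empty((n_boot, len(features)))
    standalone = np.empty((n_boot, len(features)))
    train_r2 = np.empty(n_boot)
    for b in range(n_boot):
        perm = rng.permutation(len(genes))
        train_idx = genes[perm[:n_train]]
        test_idx = genes[perm[n_train:]]
        design = assemble_design(table, te, train_idx=train_idx)
        y_train = te.loc[train_idx].to_numpy()
        y_test = te.loc[test_idx].to_numpy()
        for i, feat in enumerate(features):
            cols = features[: i + 1]
            coef, _ = _ols_rss(design.loc[train_idx, cols].to_numpy(), y_train)
            pred = (
                np.column_stack(
                    [np.ones(len(test_idx)), design.loc[test_idx, cols].to_numpy()]
                )
                @ coef
            )
            cumulative[b, i] = _r2(y_test, pred)
            coef1, _ = _ols_rss(design.loc[train_idx, [feat]].to_numpy(), y_train)
            pred1 = (
                np.column_stack(
                    [np.ones(len(test_idx)), design.loc[test_idx, [feat]].to_numpy()]
                )
                @ coef1
            )
            standalone[b, i] = _r2(y_test, pred1)
        coef_full, rss_full = _ols_rss(design.loc[train_idx, features].to_numpy(), y_train)
        train_r2[b] = 1.0 - rss_full / float(((y_train - y_train.mean()) ** 2).sum())
    design_full = assemble_design(table, te)
    signs = pd.Series(
        {
            f: float(np.sign(np.corrcoef(design_full[f], te.loc[genes])[0, 1]))
            for f in features
        }
    )
    return ModelFit(
        features=list(features),
        heldout_r2_mean=float(cumulative[:, -1].mean()),
        heldout_r2_ci=tuple(np.percentile(cumulative[:, -1], [2.5, 97.5])),
        cumulative_r2_mean=cumulative.mean(axis=0),
        cumulative_r2_ci=np.percentile(cumulative, [2.5, 97.5], axis=0).T,
        standalone_r2=pd.Series(standalone.mean(axis=0), index=features),
        signs=signs,
        correlations=feature_correlation_matrix(design_full[features]),
        training_r2_mean=float(train_r2.mean()),
    )


def feature_correlation_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson matrix; constant features give NaN rows/columns."""
    if features.shape[1] < 2:
        raise ValueError("need >= 2 features")
    return features.corr(method="pearson")
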