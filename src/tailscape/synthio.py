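"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the data shapes the analysis consumes: gene models
with 5'-UTR / CDS / 3'-UTR structure and one or two 3'-end isoforms;
four-channel intensity traces whose log T-signal follows the GHMM's
emission/transition structure around a planted tail length; spike-in
tail-length standards; tag 3'-coordinate pileups at true mRNA ends;
negative-binomial RPF/RNA counts whose log2 TE is a planted linear function
of sequence features; miRNA fold-change tables with a planted
3'-UTR-length confound and site-type-dependent repression; and balanced
replicate stimulation cohorts carrying three planted tail-change
mechanisms.  Identical config + seed reproduces every output byte for
byte; truth tables are returned (and written) alongside the data so each
downstream stage can be scored without re-simulation.

Negative-binomial draws use the mean/dispersion parameterization
Var = mu + alpha * mu^2 (Gamma-Poisson mixture).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .ghmm import GHMMParams

__all__ = [
    "SynthConfig",
    "Transcriptome",
    "make_transcriptome",
    "make_feature_inputs",
    "planted_te",
    "simulate_intensity_tags",
    "simulate_tag_coordinates",
    "simulate_counts",
    "simulate_mirna_experiment",
    "simulate_stimulation",
    "load_config",
]

_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SynthConfig:
    """All knobs of the synthetic study, with the default scenario planted.

    Defaults encode the scenario the analyses are built around: gamma tails
    with a ~90-nt mean, a three-state intensity model, sequence features
    explaining 40% of log2-TE variance, miRNA repression acting on mRNA
    level only (tail truth = 0), and stimulated cohorts of four replicates
    carrying burst / short-tail-decay / cytoplasmic-polyadenylation genes.
    """

    seed: int = 0
    n_genes: int = 500
    # gene-model length laws (uniform over [lo, hi]); CDS in codons
    utr5_law: tuple = (50, 300)
    cds_codon_law: tuple = (100, 500)
    utr3_law: tuple = (100, 2000)
    second_isoform_fraction: float = 0.3  # genes with a second, shorter 3' end
    # tails and traces
    tail_law: dict = field(default_factory=lambda: {"kind": "gamma", "mean": 90.0, "shape": 4.0})
    tail_utr3_coupling: float = 15.0  # nt of gene mean tail per SD of log10 UTR3 length
    tail_gene_sd: float = 10.0
    trace_length: int = 250
    ghmm_truth: GHMMParams | None = None
    channel_norms: tuple = (1.0, 1.0, 1.0, 1.0)
    standards: tuple = ((10, 0.2), (50, 0.2), (100, 0.2), (160, 0.2), (210, 0.2))
    # TE / counts
    te_effects: dict = field(
        default_factory=lambda: {
            "codon_composition": 1.0,
            "fe_utr5_region": 0.6,
            "log_len_utr3": -0.5,
            "log_expression": 0.3,
        }
    )
    te_signal_fraction: float | None = 0.40
    noise_sd: float = 0.7746  # sqrt(0.6): total log2-TE variance ~ 1
    nb_dispersion: float = 0.01
    library_size: float = 20e6
    # miRNA experiment
    confound_slope: float = -0.1  # log2FC per log10 nt of 3'-UTR length
    repression_by_site: dict = field(
        default_factory=lambda: {
            "none": 0.0,
            "6mer": -0.1,
            "7mer-A1": -0.2,
            "7mer-m8": -0.3,
            "8mer": -0.4,
        }
    )
    te_effect_by_site: dict = field(default_factory=dict)  # default: no TE effect
    tail_effect_by_site: dict = field(default_factory=dict)  # default: no tail effect
    fc_noise_sd: float = 0.3
    tail_fc_noise_sd: float = 0.05
    # stimulation cohorts
    n_replicates: int = 4
    tail_delta: float = 20.0
    replicate_tail_sd: float = 4.5
    burst_fold: float = 8.0
    decay_fold: float = 0.25
    stim_dispersion: float = 0.05
    stim_count_mean: float = 300.0
    mechanism_fractions: dict = field(
        default_factory=lambda: {
            "burst": 0.06,
            "short-tail-decay": 0.06,
            "cytoplasmic-polyadenylation": 0.08,
        }
    )

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.trace_length < 1:
            raise ValueError("trace length must be >= 1")
        if self.nb_dispersion < 0 or self.stim_dispersion < 0:
            raise ValueError("negative dispersion")
        for lo, hi in (self.utr5_law, self.cds_codon_law, self.utr3_law):
            if lo < 1 or hi < lo:
                raise ValueError("invalid length law")
        if sum(f for _, f in self.standards) > 1 + 1e-9:
            raise ValueError("standard input fractions must sum to <= 1")
        if sum(self.mechanism_fractions.values()) > 1 + 1e-9:
            raise ValueError("mechanism fractions must sum to <= 1")
        if self.ghmm_truth is None:
            truth = GHMMParams.default_three_state().copy()
            # realistic read-level initiation dwell (~5 cycles)
            truth.transmat[0] = [0.8, 0.2, 0.0]
            self.ghmm_truth = truth

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def load_config(path) -> SynthConfig:
    """Load a SynthConfig from YAML (missing keys take the defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "ghmm_truth" in data:
        data["ghmm_truth"] = GHMMParams.from_dict(data["ghmm_truth"])
    for key in ("utr5_law", "cds_codon_law", "utr3_law", "channel_norms"):
        if key in data:
            data[key] = tuple(data[key])
    if "standards" in data:
        data["standards"] = tuple((int(l), float(f)) for l, f in data["standards"])
    return SynthConfig(**data)


@dataclass
class Transcriptome:
    """Gene models plus per-gene truth used by the other generators."""

    sequences: pd.DataFrame  # gene -> utr5, cds, utr3
    gene_table: pd.DataFrame  # expression_weight, tail_mean_true, utr3_length
    isoforms: pd.DataFrame  # gene, isoform, utr3_length, end_coordinate, fraction

    def write_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(row.utr5 + row.cds + row.utr3), id=gene, description="")
            for gene, row in self.sequences.iterrows()
        ]
        seqio_write(records, str(path), "fasta")

    def write_gtf(self, path) -> None:
        with open(path, "w") as fh:
            for gene, row in self.sequences.iterrows():
                l5, lc, l3 = len(row.utr5), len(row.cds), len(row.utr3)
                total = l5 + lc + l3
                attrs = f'gene_id "{gene}"; transcript_id "{gene}.1";'
                fh.write(
                    f"{gene}\tsynth\texon\t1\t{total}\t.\t+\t.\t{attrs}\n"
                    f"{gene}\tsynth\tfive_prime_utr\t1\t{l5}\t.\t+\t.\t{attrs}\n"
                    f"{gene}\tsynth\tCDS\t{l5 + 1}\t{l5 + lc}\t.\t+\t0\t{attrs}\n"
                    f"{gene}\tsynth\tthree_prime_utr\t{l5 + lc + 1}\t{total}\t.\t+\t.\t{attrs}\n"
                )


def _random_cds(rng: np.random.Generator, n_codons: int, gc_bias: float) -> str:
    """ATG + random non-stop codons with a per-gene GC bias + one stop."""
    p = np.array(
        [(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2]
    )  # A, C, G, T
    bases = np.array(list("ACGT"))
    body = []
    while len(body) < n_codons - 2:
        draw = rng.choice(bases, size=3 * (n_codons - 2 - len(body)), p=p)
        for i in range(0, len(draw), 3):
            codon = "".join(draw[i : i + 3])
            if codon not in _STOPS:
                body.append(codon)
            if len(body) == n_codons - 2:
                break
    stop = _STOPS[rng.integers(len(_STOPS))]
    return "ATG" + "".join(body) + stop


def _random_utr(rng: np.random.Generator, length: int, gc_bias: float) -> str:
    p = np.array([(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2])
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


def make_transcriptome(config: SynthConfig) -> Transcriptome:
    """Generate gene models, expression weights, and true gene mean tails.

    Each gene sits on its own contig.  Per-gene GC bias couples UTR/CDS GC
    contents and codon frequencies; gene mean tail length is coupled to
    3'-UTR length (``tail_utr3_coupling``) so the tail feature is partially
    redundant with UTR length, as in real transcriptomes.
    """
    rng = config.rng(1)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    gc_bias = rng.uniform(0.30, 0.70, size=config.n_genes)
    utr5_len = rng.integers(config.utr5_law[0], config.utr5_law[1] + 1, config.n_genes)
    cds_codons = rng.integers(
        config.cds_codon_law[0], config.cds_codon_law[1] + 1, config.n_genes
    )
    utr3_len = rng.integers(config.utr3_law[0], config.utr3_law[1] + 1, config.n_genes)
    seqs = {
        g: {
            "utr5": _random_utr(rng, int(utr5_len[i]), gc_bias[i]),
            "cds": _random_cds(rng, int(cds_codons[i]), gc_bias[i]),
            "utr3": _random_utr(rng, int(utr3_len[i]), gc_bias[i]),
        }
        for i, g in enumerate(genes)
    }
    sequences = pd.DataFrame.from_dict(seqs, orient="index")
    expression = np.exp(rng.normal(np.log(50.0), 1.0, config.n_genes))
    log_utr3 = np.log10(utr3_len.astype(float))
    spread = log_utr3.std()
    z = (log_utr3 - log_utr3.mean()) / spread if spread > 0 else np.zeros_like(log_utr3)
    base = config.tail_law.get("mean", 90.0)
    tail_mean = np.clip(
        base
        + config.tail_utr3_coupling * z
        + rng.normal(0.0, config.tail_gene_sd, config.n_genes),
        15.0,
        None,
    )
    gene_table = pd.DataFrame(
        {
            "expression_weight": expression,
            "tail_mean_true": tail_mean,
            "utr3_length": utr3_len.astype(int),
        },
        index=genes,
    )
    iso_rows = []
    second = rng.random(config.n_genes) < config.second_isoform_fraction
    for i, g in enumerate(genes):
        full_end = int(utr5_len[i] + 3 * cds_codons[i] + utr3_len[i])
        if second[i] and utr3_len[i] >= 200:
            short_utr3 = int(rng.integers(50, max(51, utr3_len[i] // 2)))
            frac_long = float(rng.uniform(0.3, 0.85))
            iso_rows.append((g, f"{g}.1", int(utr3_len[i]), full_end, frac_long))
            iso_rows.append(
                (
                    g,
                    f"{g}.2",
                    short_utr3,
                    full_end - int(utr3_len[i]) + short_utr3,
                    1.0 - frac_long,
                )
            )
        else:
            iso_rows.append((g, f"{g}.1", int(utr3_len[i]), full_end, 1.0))
    isoforms = pd.DataFrame(
        iso_rows, columns=["gene", "isoform", "utr3_length", "end_coordinate", "fraction"]
    )
    return Transcriptome(sequences=sequences, gene_table=gene_table, isoforms=isoforms)


def make_feature_inputs(config: SynthConfig, transcriptome: Transcriptome):
    """Per-gene planting features plus fabricated folding energies.

    Returns ``(features, folding)``.  ``features`` holds the columns the
    planted-TE machinery can reference: log lengths, GC contents, log
    expression, true mean tail, the fabricated folding energies, and the 61
    codon frequencies as ``codon_*`` columns.  Folding energies are
    fabricated as GC-driven with noise: more GC, more negative minimum free
    energy per nt (real energies come from RNA-folding software; these only
    reproduce the correlation structure the model cares about).
    """
    from .tequant import codon_frequencies

    rng = config.rng(8)
    seqs = transcriptome.sequences
    gt = transcriptome.gene_table
    gc3 = seqs["utr3"].map(_gc_content)
    gc5 = seqs["utr5"].map(_gc_content)
    folding = pd.DataFrame(
        {
            "fe_utr3_per_nt": -(0.1 + 0.5 * gc3) + rng.normal(0, 0.03, len(seqs)),
            "fe_utr5_region": -(5.0 + 60.0 * gc5) + rng.normal(0, 4.0, len(seqs)),
        },
        index=seqs.index,
    )
    features = pd.DataFrame(
        {
            "log_len_cds": np.log10(seqs["cds"].str.len()),
            "log_len_utr5": np.log10(seqs["utr5"].str.len()),
            "log_len_utr3": np.log10(gt["utr3_length"].astype(float)),
            "gc_cds": seqs["cds"].map(_gc_content),
            "gc_utr5": gc5,
            "gc_utr3": gc3,
            "log_expression": np.log10(gt["expression_weight"]),
            "tail_length": gt["tail_mean_true"],
            "expression_weight": gt["expression_weight"],
        },
        index=seqs.index,
    ).join(folding)
    codon = codon_frequencies(seqs["cds"].to_dict()).add_prefix("codon_")
    return features.join(codon), folding


def _gc_content(seq: str) -> float:
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def _draw_tails(rng: np.random.Generator, law: dict, n: int, mean_override=None) -> np.ndarray:
    mean = np.asarray(mean_override if mean_override is not None else law.get("mean", 90.0))
    kind = law.get("kind", "gamma")
    if kind == "gamma":
        shape = law.get("shape", 4.0)
        tails = rng.gamma(shape, mean / shape, size=n)
    elif kind == "geometric":
        tails = rng.geometric(1.0 / np.maximum(mean, 1.0), size=n).astype(float)
    elif kind == "fixed":
        tails = np.full(n, float(law["value"]))
    else:
        raise ValueError(f"unknown tail law {kind!r}")
    return np.maximum(np.rint(tails), 1).astype(int)


def simulate_intensity_tags(
    config: SynthConfig,
    transcriptome: Transcriptome | None = None,
    n_tags: int = 10_000,
    n_standard_tags: int = 0,
    standard_depletion: dict | None = None,
):
    """Simulate per-tag intensity traces with planted tail lengths.

    Each tag dwells in the initiation state for a geometric number of
    cycles (the GHMM's own generative law, rate from the truth transition
    a11), then exactly L cycles in the poly(A) state (truncated at the
    trace length), then the non-poly(A) state.  Per-cycle log T-signal is
    drawn from the state Gaussians, and raw channels are back-computed so
    T-signal computation round-trips: non-T channels are 1.0 and
    T = 3 * exp(log T-signal) (channel norms 1.0).

    Spike-in standards of known length are appended according to their
    input fractions; ``standard_depletion`` maps standard id -> recovery
    multiplier (e.g. 0.5 halves that standard's tag yield).

    Returns ``(raw, truth)``: a float (N, trace_length, 4) stack and a tag
    truth table (tag_id, gene, true_tail, read2_seq).
    """
    rng = config.rng(2)
    truth = config.ghmm_truth
    if transcriptome is None:
        genes = np.array(["g00000"])
        weights = np.array([1.0])
        gene_tail_means = np.array([config.tail_law.get("mean", 90.0)])
    else:
        genes = transcriptome.gene_table.index.to_numpy()
        weights = transcriptome.gene_table["expression_weight"].to_numpy()
        gene_tail_means = transcriptome.gene_table["tail_mean_true"].to_numpy()
    gidx = rng.choice(len(genes), size=n_tags, p=weights / weights.sum())
    tails = _draw_tails(rng, config.tail_law, n_tags, mean_override=gene_tail_means[gidx])
    tag_genes = genes[gidx]
    if n_standard_tags:
        std_ids, std_tails = [], []
        for length, frac in config.standards:
            n_std = int(round(n_standard_tags * frac))
            if standard_depletion:
                n_std = int(round(n_std * standard_depletion.get(f"std_{length}", 1.0)))
            std_ids += [f"std_{length}"] * n_std
            std_tails += [length] * n_std
        tag_genes = np.concatenate([tag_genes, np.array(std_ids, dtype=object)])
        tails = np.concatenate([tails, np.array(std_tails, dtype=int)])
    n_total = len(tails)
    t_len = config.trace_length
    a11 = truth.transmat[0, 0]
    dwell1 = (
        rng.geometric(1.0 - a11, size=n_total)
        if a11 < 1
        else np.full(n_total, t_len, dtype=int)
    )
    cycles = np.arange(t_len)[None, :]
    b1 = np.minimum(dwell1, t_len)[:, None]
    b2 = np.minimum(dwell1 + tails, t_len)[:, None]
    states = np.where(cycles < b1, 0, np.where(cycles < b2, 1, 2))
    logts = rng.normal(truth.means[states], np.sqrt(truth.variances[states]))
    raw = np.ones((n_total, t_len, 4))
    raw[:, :, 3] = 3.0 * np.exp(logts)
    raw *= np.asarray(config.channel_norms)[None, None, :]
    observed_tail = (states == 1).sum(axis=1)
    seqs = ["T" * min(int(t), t_len) + "ACGT" * 8 for t in tails]
    truth_table = pd.DataFrame(
        {
            "tag_id": [f"tag{i:07d}" for i in range(n_total)],
            "gene": tag_genes,
            "true_tail": tails,
            "observed_tail": observed_tail,  # after truncation at trace end
            "read2_seq": seqs,
        }
    )
    return raw, truth_table


def simulate_tag_coordinates(
    config: SynthConfig, transcriptome: Transcriptome, n_tags: int = 100_000
) -> pd.DataFrame:
    """Tag 3'-end coordinates piled at true isoform ends.

    Tags are allocated to genes by expression and to isoforms by the
    planted fractions; coordinates get a small symmetric jitter (+/- a few
    nt, as cleavage heterogeneity produces).  Tail lengths come from the
    gene tail law, so the >= 11-nt annotation filter has something to drop.
    """
    rng = config.rng(3)
    iso = transcriptome.isoforms
    weights = (
        transcriptome.gene_table.loc[iso["gene"], "expression_weight"].to_numpy()
        * iso["fraction"].to_numpy()
    )
    pick = rng.choice(len(iso), size=n_tags, p=weights / weights.sum())
    jitter = rng.integers(-2, 3, size=n_tags)
    gene_means = transcriptome.gene_table.loc[
        iso["gene"].to_numpy()[pick], "tail_mean_true"
    ].to_numpy()
    tails = _draw_tails(rng, config.tail_law, n_tags, mean_override=gene_means)
    return pd.DataFrame(
        {
            "gene": iso["gene"].to_numpy()[pick],
            "position": iso["end_coordinate"].to_numpy()[pick] + jitter,
            "strand": "+",
            "tail_length": tails,
        }
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if alpha < 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / alpha, alpha * mean)
    return rng.poisson(lam)


def planted_te(
    config: SynthConfig, features: pd.DataFrame, extra_noise_var: float = 0.0
) -> tuple[pd.Series, pd.Series]:
    """Planted log2 TE: scaled linear signal over features plus noise.

    ``features`` must contain every key of ``te_effects``; the special key
    ``codon_composition`` uses a fixed random weight vector over columns
    named ``codon_*``.  When ``te_signal_fraction`` is set, the summed
    signal is rescaled so that Var(signal) / (Var(signal) + noise_sd^2 +
    extra_noise_var) equals it exactly in-sample; ``extra_noise_var``
    lets the count simulator account for the measurement noise that
    counting adds downstream, so the planted fraction refers to the TE
    values as measured.  Returns ``(te_true, signal)``.
    """
    rng = config.rng(4)
    rescale = config.te_signal_fraction is not None
    signal = pd.Series(0.0, index=features.index)
    for feat, coef in config.te_effects.items():
        if feat == "codon_composition":
            codon_cols = [c for c in features.columns if c.startswith("codon_")]
            w = rng.normal(0.0, 1.0, len(codon_cols))
            comp = pd.Series(features[codon_cols].to_numpy() @ w, index=features.index)
            if comp.std() > 0:
                comp = (comp - comp.mean()) / comp.std()
            signal += coef * comp
        else:
            col = features[feat]
            # raw units when no rescaling is requested (coefficients then
            # mean log2-TE per feature unit); standardized otherwise so the
            # coefficients set the features' relative shares of the signal
            if rescale and col.std() > 0:
                col = (col - col.mean()) / col.std()
            signal += coef * col
    noise = rng.normal(0.0, config.noise_sd, len(signal))
    if config.te_signal_fraction is not None and signal.std() > 0:
        target_var = (
            config.te_signal_fraction
            / (1.0 - config.te_signal_fraction)
            * (config.noise_sd**2 + extra_noise_var)
        )
        signal = signal * np.sqrt(target_var) / signal.std(ddof=0)
        # plant the decomposition exactly in this realization: make the
        # biological-noise draw orthogonal to the signal with exactly the
        # nominal variance, so the planted variance share is a property of
        # the generated sample, not only of the generating law
        z = (signal - signal.mean()) / signal.std(ddof=0)
        noise = noise - noise.mean() - z * np.mean(noise * z)
        noise = noise * config.noise_sd / noise.std(ddof=0)
    te_true = signal + noise
    return te_true, signal


def simulate_counts(
    config: SynthConfig, features: pd.DataFrame, te_true: pd.Series | None = None
):
    """RPF and RNA count tables whose ratio encodes the planted TE.

    RNA means are proportional to expression weights; RPF means multiply in
    2**TE_true.  Both are negative binomial with ``nb_dispersion`` and sum
    approximately to ``library_size``.  Returns ``(rna, rpf, te_true)``.
    """
    missing = [k for k in config.te_effects if k != "codon_composition" and k not in features]
    if missing:
        raise ValueError(f"te_effects features missing from table: {missing}")
    rng = config.rng(5)
    expr = features["expression_weight"] if "expression_weight" in features else pd.Series(
        1.0, index=features.index
    )
    rna_mean = expr / expr.sum() * config.library_size
    if te_true is None:
        # expected log2-scale variance that counting adds to the measured TE
        # (delta method on two NB counts; RPF means approximated by RNA means)
        expressed = rna_mean[rna_mean >= 10e-6 * config.library_size]  # 10-RPM cohort
        count_noise = float(
            np.mean(2.0 / expressed + 2.0 * config.nb_dispersion) / np.log(2) ** 2
        )
        te_true, _ = planted_te(config, features, extra_noise_var=count_noise)
    rpf_raw = expr * 2.0**te_true
    rpf_mean = rpf_raw / rpf_raw.sum() * config.library_size
    rna = pd.Series(
        _nb_draw(rng, rna_mean.to_numpy(), config.nb_dispersion), index=features.index
    )
    rpf = pd.Series(
        _nb_draw(rng, rpf_mean.to_numpy(), config.nb_dispersion), index=features.index
    )
    return rna, rpf, te_true


def simulate_mirna_experiment(
    config: SynthConfig, site_labels: pd.Series, utr3_lengths: pd.Series
) -> pd.DataFrame:
    """Fold-change tables for a miRNA transduction experiment.

    Every gene receives the 3'-UTR-length confound (slope in log2FC per
    log10 nt) plus measure noise; genes with a site additionally receive
    the planted site-type repression on RNA and RPF (the default scenario
    plants no TE effect, i.e. RPF tracks RNA) and the planted tail effect
    (default 0 nt: steady-state tails unchanged).  Truth columns are
    included alongside the observed fold-changes.
    """
    unknown = set(site_labels.unique()) - set(config.repression_by_site)
    if unknown:
        raise ValueError(f"unknown site labels: {sorted(unknown)}")
    rng = config.rng(6)
    genes = site_labels.index
    logl = np.log10(utr3_lengths.loc[genes].astype(float))
    confound = config.confound_slope * logl
    rep = site_labels.map(config.repression_by_site).astype(float)
    te_eff = site_labels.map(lambda s: config.te_effect_by_site.get(s, 0.0)).astype(float)
    tail_eff = site_labels.map(lambda s: config.tail_effect_by_site.get(s, 0.0)).astype(float)
    n = len(genes)
    fc_rna = confound + rep + rng.normal(0, config.fc_noise_sd, n)
    fc_rpf = confound + rep + te_eff + rng.normal(0, config.fc_noise_sd, n)
    fc_tail = tail_eff + rng.normal(0, config.tail_fc_noise_sd, n)
    return pd.DataFrame(
        {
            "site_type": site_labels,
            "utr3_length": utr3_lengths.loc[genes],
            "fc_rna": fc_rna,
            "fc_rpf": fc_rpf,
            "fc_tail": fc_tail,
            "true_repression": rep,
            "true_te_effect": te_eff,
            "true_tail_effect": tail_eff,
        },
        index=genes,
    )


def simulate_stimulation(config: SynthConfig, n_genes: int | None = None) -> dict:
    """Balanced replicate cohorts with planted tail-change mechanisms.

    Returns a dict with per-replicate gene mean-tail tables and tag-count
    tables for the control and stimulated cohorts, and the per-gene
    mechanism truth.  Burst genes go up ``burst_fold`` in expression with a
    ``tail_delta`` nt tail increase; short-tail-decay genes gain tail but
    lose expression (``decay_fold``); cytoplasmic-polyadenylation genes
    gain tail at flat expression; the rest change in neither.
    """
    if config.n_replicates < 2:
        raise ValueError("need >= 2 replicates per cohort")
    rng = config.rng(7)
    n = n_genes if n_genes is not None else config.n_genes
    genes = [f"g{i:05d}" for i in range(n)]
    labels = np.full(n, "none", dtype=object)
    start = 0
    order = rng.permutation(n)
    for mech, frac in config.mechanism_fractions.items():
        k = int(round(frac * n))
        labels[order[start : start + k]] = mech
        start += k
    mechanisms = pd.Series(labels, index=genes, name="mechanism")
    base_tail = rng.normal(90.0, 15.0, n).clip(30.0)
    base_mean = np.exp(rng.normal(np.log(config.stim_count_mean), 0.8, n))
    tail_shift = np.where(labels == "none", 0.0, config.tail_delta)
    fold = np.select(
        [labels == "burst", labels == "short-tail-decay"],
        [config.burst_fold, config.decay_fold],
        default=1.0,
    )
    reps = config.n_replicates
    ctrl_tails = rng.normal(base_tail[:, None], config.replicate_tail_sd, (n, reps))
    stim_tails = rng.normal(
        (base_tail + tail_shift)[:, None], config.replicate_tail_sd, (n, reps)
    )
    ctrl_counts = _nb_draw(
        rng, np.repeat(base_mean[:, None], reps, axis=1), config.stim_dispersion
    )
    stim_counts = _nb_draw(
        rng, np.repeat((base_mean * fold)[:, None], reps, axis=1), config.stim_dispersion
    )
    cols_c = [f"ctrl_{i + 1}" for i in range(reps)]
    cols_s = [f"stim_{i + 1}" for i in range(reps)]
    return {
        "control_tails": pd.DataFrame(ctrl_tails, index=genes, columns=cols_c),
        "stimulated_tails": pd.DataFrame(stim_tails, index=genes, columns=cols_s),
        "control_counts": pd.DataFrame(ctrl_counts, index=genes, columns=cols_c),
        "stimulated_counts": pd.DataFrame(stim_counts, index=genes, columns=cols_s),
        "mechanisms": mechanisms,
        "true_tail_delta": pd.Series(tail_shift, index=genes),
        "true_fold": pd.Series(fold, index=genes),
    }
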