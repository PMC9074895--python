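# tailscape

Analysis toolkit for studying translational control in neurons: poly(A)-tail
length calling from raw sequencing intensities, 3′-end annotation,
translational-efficiency (TE) quantification, miRNA-repression statistics,
a stepwise linear model of TE, and classification of stimulation-induced
tail-length changes. A fully seeded synthetic-data module generates every
input the pipeline consumes, with the planted truth written alongside, so
each stage can be validated end to end.

## Who this is for

Computational biologists working with tail-length profiling (PAL-seq /
TAIL-seq style data, where per-cycle Illumina intensities rather than base
calls carry the tail signal), ribosome profiling, and matched RNA-seq — and
anyone who wants a tested, reusable implementation of this analysis chain
that can be exercised without access to the original sequencing data.

## The methods at the core

**Tail calling.** For each sequencing tag, the four intensity channels of
read 2 are normalized by their read-1 reference levels and collapsed into a
per-cycle *T signal*, T/(A+C+G), whose logarithm is high while the
poly(A) tail is being read and drops afterwards. A Gaussian hidden Markov
model with a left-to-right topology — initiation → poly(A) → non-poly(A)
(a five-state variant adds transition states) — is trained by Baum–Welch on
10,000 randomly chosen tags and decoded by Viterbi; the number of cycles in
the poly(A) state is the tail length. Reads that never show the tail's
T-stretch (≥10 T in an 11-nt window within the first 30 nt) but begin with
≥4 contiguous T get a direct short-tail call; per-gene means require ≥50
tags.

**3′-end annotation.** Tag 3′ coordinates (tails ≥11 nt) are assigned
greedily: the most-populated coordinate becomes an end, tags within ±10 nt
(a 21-nt window) are consumed, and ends keeping ≥10% of a gene's tags are
retained.

**TE and its correlates.** TE = log2(RPF RPM / RNA RPM) with a ≥10-RPM
RNA-seq cutoff; the spread of TE is summarized as the 1–99 percentile fold
range. Per-codon frequencies are correlated with TE across genes
(mean ± SD Pearson R over samples), A-site codon enrichment is computed
with the +15-nt offset convention, and the tail–TE relationship is a
Spearman correlation with a subset permutation test.

**miRNA repression.** Fold-changes are residualized on log10 3′-UTR length
(slope fit on mRNAs with no 6-nt seed match anywhere in the transcript),
and a cohort's effect is its mean normalized fold-change minus the no-site
median, tested one-tailed; an unpaired t-test compares RNA and RPF effects.

**TE model.** Two rounds of forward stepwise regression by AIC over simple
features (region lengths, GC contents, expression, folding energies, mean
tail length) plus complex features fit as linear sub-models (61 codon
frequencies; 5′-UTR 6-mers); features adding <0.003 adjusted R² are dropped
(tail length is kept as the feature of interest), and the final model is
evaluated over 100 random train/test splits with sub-models refit per
split.

**Stimulation responses.** Per gene, a Welch t-test on replicate mean tails
and a negative-binomial test on tag counts (median-of-ratios size factors,
trend dispersion, Wald test, BH adjustment) classify each tail-length
increase as a transcriptional burst (expression up), short-tail-isoform
decay (expression down), or cytoplasmic polyadenylation (expression flat).

## Worked example

```python
import numpy as np
from tailscape import synthio, tailcall

cfg = synthio.SynthConfig(seed=1, n_genes=100)
tx = synthio.make_transcriptome(cfg)
raw, truth = synthio.simulate_intensity_tags(cfg, tx, n_tags=10_000)

logts, keep = tailcall.compute_t_signal_batch(raw, np.ones(4))
params, history = tailcall.train_ghmm(logts, seed=1)
tails = tailcall.decode_tail_lengths(logts, params)

err = np.abs(tails - truth["observed_tail"].to_numpy())
print(f"mean planted tail {truth['true_tail'].mean():.1f} nt")
print(f"{np.mean(err <= 2) * 100:.1f}% of calls within 2 nt of truth")
```

This prints:

```
mean planted tail 87.3 nt
100.0% of calls within 2 nt of truth
```

i.e. the simulated tails average ~90 nt as configured, and after training
the model on the tags themselves, essentially every decoded tail length
lands within 2 nt of the planted value at the reference noise level.

The same chain runs from the shell, writing every intermediate file:

```bash
tailscape simulate --outdir out/ --n-tags 100000 --seed 1
```

which produces the transcriptome (FASTA/GTF), gzipped intensity traces,
tail calls and trained model parameters, per-gene mean tails, spike-in
standard recovery, 3′-end annotations, count tables, the TE table, and the
stepwise model report (`model_fit.json`, `model_steps.tsv`).

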