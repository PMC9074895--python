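# Methods

This note records the models implemented in `tailscape`, the defaults that
matter, what the synthetic-data generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Tail calling from intensities

### T signal

For each tag's read 2, every channel intensity is divided by that
channel's average read-1 intensity when reading the corresponding base
(`ChannelNorms`), and the T signal at a cycle is normalized T divided by
the sum of normalized A, C and G. The model works on the natural
logarithm of this ratio. Cycles where all four channels are zero, or
where the ratio is non-positive or non-finite, are imputed with the mean
of the five nearest valid log values on each side (fewer near the trace
edges); a trace with more than five such cycles is discarded.
Imputation operates on the log scale, the same scale the HMM sees.

### The Gaussian HMM

States emit one log-T-signal value per cycle from a state-specific
Gaussian. The three-state topology is strictly left-to-right
(initiation → poly(A) → non-poly(A)); the five-state variant inserts a
poly(A)-transition and a non-poly(A)-transition state to absorb the
boundary blur of the alternative sequencing mode, and tail length counts
only pure poly(A)-state cycles (the transition states are deliberately
excluded; counting them would systematically lengthen every call by the
transition dwell).

Defaults (packaged in `_defaults/ghmm_init.yaml`): emission means
(100, 1, −1) with variances (1, 0.25, 0.25), initial-state probabilities
(0.998, 0.001, 0.001). A state-1 emission mean of 100 in log units is
physically surprising but is treated as given; nothing in the machinery
depends on its scale. The numeric transition entries of the packaged
initialization (a11 = 0.99, a22 = 0.99) are configuration defaults for the
left-to-right topology, not measured values — training re-estimates them.

Training is standard Baum–Welch with three specifics:

* **Structural zeros.** Disallowed transitions start at exactly 0 and
  accrue zero expected counts, so they remain exactly 0; rows are
  renormalized each M-step. Row-stochasticity and the zero pattern are
  asserted in tests after every training run.
* **Convergence.** Iteration stops when the *mean per-trace*
  log-likelihood improvement falls below 1e-4 (an absolute threshold is
  meaningless when the total log-likelihood scales with 10,000 × 250
  emission terms), or at 100 iterations. Emission variances are floored
  at 1e-6 to prevent degenerate point-mass fits.
* **Training sample.** 10,000 tags drawn uniformly without replacement,
  seeded; fewer tags use all of them.

Decoding is Viterbi (posterior decoding is available behind a flag); the
tail length is the number of decoded poly(A)-state cycles. Forward,
backward and Viterbi run in log space, vectorized across traces of equal
length and chunked (2,000–5,000 traces) to bound memory.

### Routing screens

A read goes to the GHMM when any 11-nt window starting in its first 30 nt
contains ≥10 T. Reads failing that screen but starting with ≥4 contiguous
T are called directly from the leading-T run (such tails are <10 nt by
construction); everything else is discarded. Windows are half-open and
0-based internally; 1-based in documentation.

### Aggregation and spike-ins

Per-gene mean tails require ≥50 tail measurements. Spike-in standards of
known length are tracked separately; a standard's recovery ratio is its
share of recovered standard tags over its input fraction, so depletion of
long standards shows up as ratios below 1.

## 3′-end annotation

Per gene, tags with tails ≥11 nt are piled by the 3′-UTR coordinate
closest to the tail. Greedy assignment repeats: take the coordinate with
the most remaining tags (ties break to the 5′-most coordinate, transcript
orientation — a deterministic, strand-consistent rule), assign everything
within ±10 nt, remove, until empty; ends keeping ≥10% of the gene's total
3′-UTR tags are retained. The fraction's denominator is all of the gene's
tags, not the post-filter remainder, and the identical-output check
against a brute-force reference is part of the test suite. Note the
assigned *window* totals need not decrease across iterations (a later,
smaller peak can gather more neighbors); the monotone quantity is the
chosen peak's own height.

## TE quantification

TE = log2(RPF RPM / RNA RPM); the ≥10-RPM cutoff applies to the RNA-seq
sample only (RPF additionally needs ≥1 read, otherwise the gene is dropped
with a warning). The 1–99 percentile fold range uses linear interpolation
between order statistics (the percentile method must be pinned for
reproducibility) after median-centering. Codon–TE correlations are
Pearson R per sample, averaged with SD across samples; the amino-acid
variant pools synonymous codons first. A-site enrichment places the A site
15 nt downstream of the 5′ end for 29–31-nt footprints (configurable, the
field convention) against a background of pooled CDS codon counts.
Spearman p-values use the large-sample t approximation, switching to a
seeded permutation for n < 30. The subset permutation test draws random
same-size subsets and reports the add-one one-sided empirical p.

## miRNA repression

Site classes from a 3′-UTR scan: 8mer (seed match at miRNA positions 2–8
plus an A opposite position 1), 7mer-m8, 7mer-A1, 6mer, with the strongest
reported. "No-site" requires no 6-nt seed match in the entire transcript;
genes with a 6mer outside the 3′-UTR only are excluded from both cohorts.
The length confound is removed by OLS of no-site fold-changes on log10
UTR length (any log base gives the same residualization), subtracting the
slope component around the no-site mean so the intercept is preserved;
the operation is idempotent and exactly zeroes the refitted no-site slope.
The cohort effect is mean(cohort) − median(no-site) — the asymmetry is
kept deliberately — with a one-tailed Welch t-test for repression and a
two-tailed unpaired t-test comparing RNA and RPF fold-changes (the
tailedness of that comparison is not specified by the protocol being
reproduced; two-tailed is the conservative choice).

## The TE model

Simple features: log10 CDS/5′-UTR/3′-UTR lengths, GC contents of the three
regions, log10 expression, mean tail length, 3′-UTR minimum free energy
per nt, and the folding energy of the 5′ region (5′ UTR plus the first
35 nt of CDS). Multi-isoform 3′-UTR length and folding energy are
expression-weighted means over 3′-end isoforms. Complex features are
linear sub-models over the 61 codon frequencies and over 5′-UTR 6-mer
counts; both use ridge regression with a CV-chosen penalty, and the 6-mer
vocabulary is capped at the 256 most abundant 6-mers. The full default
menu has 12 entries; the exact menu of the original analysis is not
recoverable from its description, so this menu is a reconstruction
covering every named feature, and user columns are accepted.

Round 1 is forward selection by AIC (Gaussian profile likelihood,
k = coefficients + 1) until no addition lowers AIC. Features whose
inclusion, in selection order, raised the adjusted R² by less than 0.003
are dropped from the menu — except tail length, which is retained as the
feature of scientific interest — and round 2 reruns the selection on the
reduced menu.

Evaluation uses 100 random 80/20 train/test splits (the split fraction is
a package choice; configurable). Within each split the sub-models are
refit on the training genes only, so the held-out R² is leakage-free; for
the *selection* design the sub-model columns are computed out-of-fold
(5-fold cross-fitting), which stops the AIC from over-crediting complex
features whose in-sample fit is optimistic. Reported: mean held-out R²
(training R² is exposed too), per-step cumulative held-out R² with
2.5/97.5 percentile intervals, per-feature standalone R², correlation
signs, and the pairwise Pearson matrix.

## Stimulation responses

Tail changes: Welch t-test (unequal variances — the safer default when
only "t-test" is specified) on per-replicate gene means, two-sided, with
an exact shortcut when both cohorts have zero variance. Expression
changes use a negative-binomial test written as a defined, dependency-free
stand-in for DESeq-style testing: median-of-ratios size factors,
method-of-moments per-gene dispersions shrunk to a fitted common trend
α(μ) = a0 + a1/μ, a delta-method Wald test on the log2 fold-change of
normalized cohort means (variance μ + αμ² per count), and
Benjamini–Hochberg adjustment. A per-gene GLM would be the textbook Wald
route; the delta-method form is used because it is robust and exactly
vectorizable at n = 4 replicates, and its calibration on null data is
checked in the tests. Classification is a pure function of the two test
outcomes: a significant tail *increase* (p < 0.05 and Δ > 0) with
significantly increased, decreased, or unchanged expression (adjusted
p < 0.05) maps to burst, short-tail-decay, or cytoplasmic-polyadenylation;
anything else is "none". CPE motifs default to the U-rich patterns
UUUUAU / UUUUAAU — a configurable reconstruction, since the canonical
definitions live in external catalogs — and associate with tail increases
through Fisher's exact test. The global summary bins tails at 2 nt and
runs a one-way ANOVA on per-sample means across treatments; the
short-tailed-isoform check compares the fraction of tags below the
control cohort's 25th percentile (configurable), as the exact original
computation is not specified.

## The synthetic study

The generators produce exactly the structures the pipeline consumes, with
the truth saved alongside, and all randomness drawn from per-stream
`numpy` generators derived from one seed (identical config + seed gives
byte-identical outputs).

* **Transcriptome** — each gene on its own contig: 5′ UTR (uniform 50–300
  nt), CDS (uniform 100–500 codons, ATG start, no internal stops, one
  stop), 3′ UTR (uniform 100–2000 nt); a per-gene GC bias (0.30–0.70)
  couples GC contents and codon usage the way composition varies across
  real genes. ~30% of genes get a second, shorter 3′-end isoform.
  Gene-level mean tails are drawn around 90 nt with a planted coupling to
  3′-UTR length (+15 nt per SD of log length, gene scatter 10 nt), so the
  tail feature is partially redundant with UTR length, as observed in
  real data.
* **Intensity tags** — per tag, a geometric initiation dwell (the HMM's
  own generative law; rate from the truth a11, mean 5 cycles), exactly L
  poly(A) cycles (gamma-distributed L around the gene mean, shape 4,
  truncated at the 250-cycle trace), then non-poly(A); emissions from the
  state Gaussians. Raw channels are back-computed invertibly (non-T
  channels 1.0, T = 3·exp(logT), norms 1.0) so T-signal computation
  round-trips to 1e-9. Spike-in standards at 10/50/100/160/210 nt in
  equal input fractions, with optional per-standard depletion.
* **Counts** — RNA means proportional to lognormal expression weights at
  a 20M-read library; RPF means multiply in 2^TE; both negative binomial
  (Var = μ + αμ², α = 0.01). Planted log2 TE is a linear signal over
  named features (defaults: codon composition, 5′-region folding energy,
  3′-UTR length, expression) plus Gaussian noise. When a target signal
  fraction is set (default 0.40), the signal is scaled against the noise
  variance *plus the analytically expected count-measurement variance*
  (delta method, averaged over the ≥10-RPM cohort), and the noise draw is
  orthogonalized against the signal and variance-matched — so "features
  explain 40% of measured-TE variance" holds in the generated sample
  itself, not merely in expectation. Without a target fraction,
  coefficients act on raw feature units.
* **miRNA experiment** — every gene receives the UTR-length confound
  (−0.1 log2FC per log10 nt by default) plus noise (SD 0.3 log2 for
  RNA/RPF, 0.05 for tail); site genes add the site-type repression
  (−0.1/−0.2/−0.3/−0.4 for 6mer/7mer-A1/7mer-m8/8mer) to RNA and RPF
  equally — i.e. no TE effect — and the planted tail change defaults to
  zero. Both per-site TE and tail effects are overridable.
* **Stimulation** — 4 + 4 replicate cohorts; burst genes: 8-fold
  expression and +20 nt tail; short-tail-decay genes: 4-fold expression
  loss and +20 nt tail; cytoplasmic-polyadenylation genes: +20 nt tail at
  flat expression; the rest flat (fractions 6/6/8/80%). Replicate tail
  scatter 4.5 nt (matching the scatter reported for the strongest
  stimulus-responsive mRNA), counts NB with dispersion 0.05 around
  lognormal gene means (~300).

**What the generators do not emulate** — and hence what passing tests do
not show about real data: base-calling errors and sequence-dependent
intensity artifacts (the T signal is exactly Gaussian per state here);
cluster-density and optical effects; alignment ambiguity (tag coordinates
are taken as given); UTR isoform families beyond two 3′ ends; real codon
usage and motif grammars (composition is a one-dimensional GC gradient
plus multinomial noise); correlated biological replicates; and folding
energies, which are fabricated as GC-driven proxies rather than computed
by RNA-folding software. Conclusions about calibration and recovery
transfer to real data only to the extent these simplifications are benign.

## Problem sizes

The shipped tests and the acceptance script run the pipeline at the sizes
the analyses are designed around: 10,000 tags × 250 cycles for decoding
accuracy and Baum–Welch recovery, 1,000 random pileups for the annotation
equivalence check, 5,000 genes for the percentile-range recovery, 100
seeds of miR-1-sized cohorts (270 targets / 745 no-site) for the
repression bias, 4,000 genes × 100 bootstrap splits for the TE model, and
2,000 genes for the stimulation classifier and its calibration; the
end-to-end run uses 500 genes and 100,000 tags.

## Known limitations

* The NB stand-in's Wald test is asymptotic; at 4 replicates its per-gene
  p-values are approximate (BH-level FDR control is what the tests
  assert).
* The AIC stepwise explores single additions only; exchangeable
  collinear features enter in data-dependent order (the pairwise
  correlation matrix is reported for exactly this reason).
* Five-state decoding reuses the three-state machinery; its transition
  states are not separately validated against real alternative-mode data.
* The ≥10% end-annotation filter uses the all-tags denominator; with many
  minor ends this retains slightly fewer ends than a remaining-tags
  denominator would.
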