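# Methods

## The problem and the representation

`enhseq` classifies cell type-specific enhancers from DNA sequence alone.
Positives are fixed-length segments (default 200 bp, the scale of a
nucleosome plus spacer) cut from "strong enhancer" chromatin-state intervals
(ChromHMM Broad 15-state labels `4_Strong_Enhancer` and `5_Strong_Enhancer`),
taken from a genome in which exons and repeats have been masked to `N`.

The core representation is the **positional k-mer fold-change array**. For a
cell type, two sequence sets are compared: all positive segments and a
GC-matched *control* set sampled from masked, enhancer-excluded genome space.
For each odd k in the k set (default 5, 7, 9, 11), every k-mer seen in either
set is assigned

    fc(w) = ((c_pos(w) + α) / T_pos) / ((c_ctrl(w) + α) / T_ctrl)

where `c_pos`, `c_ctrl` are occurrence counts (stride-1 windows, forward
strand, windows containing non-ACGT skipped), `T_pos`, `T_ctrl` the total
window counts, and α a pseudocount (default 1). k-mers seen in neither set
take the default `T_ctrl / T_pos`, which is exactly 1 for balanced sets, so
unseen sequence is scored neutral. The pseudocount keeps every stored value
finite and positive and makes the mapping antisymmetric under swapping the
two sets when totals are equal.

A segment is then featurized position by position: for core position *i* and
each k, the window of length k **centered** on *i* is looked up in that k's
dictionary. Odd k is required precisely so windows of different k align on a
central nucleotide. The largest k determines the flank needed on each side,
`(max(k) − 1) / 2` — 5 bp for the default k set — and a 200 bp core yields a
200 × 4 array. Windows that are unstored or that contain `N` (e.g. a masked
flank) take the dictionary default, so the array shape never varies. Raw
fold changes are passed to the models; a log2 flag exists but defaults off.

## Background sampling

Control sequences (used only to build dictionaries) and negative sequences
(used only as the classifier's negative class) are disjoint at window
granularity, drawn in one seeded pass. Candidate windows are length-L,
ACGT-pure cores with room for flanks, outside the enhancer intervals of
*every* cell type in the run (conservative exclusion). Positives are binned
by GC (bin width 0.02; the last bin is closed above) and each background
set's per-bin quota is the largest-remainder apportionment of the requested
count over that histogram; windows are drawn uniformly and accepted until
quotas fill, controls first. This makes the GC match exact by construction
(assertable via quota arithmetic rather than statistically) and removes the
nucleotide-composition shortcut a classifier would otherwise exploit.
Rejection sampling is capped at 1000 draws per requested window, after which
the sampler fails loudly, naming the starved GC bins, rather than silently
distorting the distribution.

## Models

Three small architectures consume the same (L × |K|) arrays and emit one
probability (positions are the sequential axis; the |K| fold-change channels
are the feature axis):

* **MLP** — flatten; dense 256 and 64 with rectified activations, dropout 0.3;
  sigmoid output.
* **CNN** — two blocks of width-7 convolution (32 then 64 filters) with
  rectified activations and width-2 max pooling; global max pooling; dense
  64; sigmoid.
* **BiLSTM** — one bidirectional LSTM with 64 units per direction over
  positions; concatenated final states; dense 64; sigmoid.

Training minimizes binary cross-entropy with Adam (learning rate 1e-3, batch
64, at most 50 epochs) and early-stops on validation loss: the best weights
seen are always checkpointed and restored, and training halts after 5 epochs
without an improvement of at least `min_delta` (default 1e-3 in BCE units,
i.e. training stops once validation loss changes stop being meaningful at
the reported metric precision). Inputs are standardized per channel with
training-set statistics stored in the model; this rescales the heavy-tailed
raw fold changes for the optimizer without changing the representation.

The networks are implemented in a compact in-package numpy engine (dense,
1-D convolution via im2col, max pooling, dropout, bidirectional LSTM with
full backpropagation through time, Adam). Every layer's gradient is verified
against central finite differences in the test suite. All randomness — fold
assignment, weight initialization, batch shuffling, dropout — derives from
explicit seeds; one master seed per run fans out to per-fold seeds, so
results are bit-reproducible on a fixed platform.

## Cross-validation and tasks

Datasets are balanced (equal positives and negatives, enforced by seeded
down-sampling of the larger class). `make_folds` builds a stratified
partition into n test folds (default 5); within fold *f*, fold *f*+1 (mod n)
is the validation set and the remaining n−2 folds train — a rotating
train/validation/test scheme chosen because the representation's source
protocol specifies three roles but not their proportions. Reported accuracy
(threshold 0.5; a score exactly at threshold counts positive) and AUC
(rank-based, ties one half) are averaged over folds; ROC points are pooled
over test folds so one curve summarizes a run.

The **single-type task** distinguishes one cell type's segments from its
GC-matched negatives, featurized with that type's dictionaries. The
**pairwise task** distinguishes two cell types' enhancers: direction one
takes type A as positive and featurizes everything with A's dictionaries,
direction two swaps roles, and the reported metrics average the directions.
(Which dictionaries to use in the two-type setting is genuinely open; the
positive type's dictionaries are the default here, the two-direction average
makes the protocol symmetric, and `feature_channels="both"` offers the
alternative of carrying both types' dictionaries side by side as 2 |K|
channels, identical across directions up to the label swap.) `subsample_repeat` runs the
single-type task on repeated seeded subsamples (default 2000 per class, ten
repeats) to bound per-model training time on large corpora, reporting
mean ± sd across repeats.

## Dictionary scope and the membership leak

The standard protocol builds dictionaries from **all** positive segments
(long k-mers are too rare to split the corpus without destroying them — the
representation's stated rationale). This has a measurable consequence this
package documents rather than hides: a held-out positive's own 9- and
11-mers are near-unique, so they sit in the dictionary with fold change ≈ 2
(count 1 + pseudocount, vs 0 + pseudocount in controls), while a negative's
long k-mers sit near the neutral default. Cross-validated metrics under this
protocol therefore mix genuine motif signal with *dictionary membership*; a
motif-free null run scores far above chance (a test asserts this).

For analyses where that leak is the confound — null calibrations, unbiased
generalization estimates — both evaluation drivers accept
`dictionary_scope="train"`, which rebuilds dictionaries per fold from the
training positives only (the control set never enters test data and is
reused). The signal-recovery acceptance tests use the faithful default; the
null-calibration acceptance tests use the strict mode, since their purpose
is to show that *composition* (GC) shortcuts are absent, which the
membership leak would otherwise mask.

## Synthetic benchmark

The generator emulates the study design at desk scale: a 1 Mb genome over
two chromosomes with i.i.d. background at GC 0.5; two pseudo cell types with
500 non-overlapping 200 bp enhancers each; per-type vocabularies of three
7-mers and three 9-mers, disjoint between types and seed-deterministic, with
three instances planted per enhancer at non-overlapping offsets; exon and
repeat stand-in masks (5% of the genome, lengths 100–500 bp) placed outside
enhancers. A JSON truth record stores every planted instance, and outputs
are byte-identical under a fixed seed. These sizes are the package's default
study conditions: large enough that planted 7-/9-mers reach dictionary fold
changes ≫ 1 while unplanted k-mers stay in a neutral band, small enough for
laptop-scale CPU runs.

What the generator does *not* emulate — and therefore what passing tests do
not show about real data: genomic background is not i.i.d. (an order-1
Markov flag exists to stress GC matching but is off by default); real motifs
are degenerate (a per-position mutation-rate flag exists, default 0);
ChromHMM calls are noisy and enhancer grammar is richer than independent
exact motif instances. Results on the benchmark bound what the pipeline can
do under favorable conditions; they do not predict genome-scale accuracy.

## Numerical and edge-case choices

* Coordinates are BED 0-based half-open everywhere; masking replaces bases
  with `N` (never lowercasing), and all non-ACGT ambiguity codes are
  normalized to `N` at FASTA load.
* Interval tiling anchors at the interval start and discards the trailing
  remainder; a segment is dropped if its core contains any non-ACGT base or
  its flanks would run off the chromosome (flanks may contain `N`).
* GC content of an all-`N` sequence is an error, not a value.
* Accuracy's tie rule (score = threshold ⇒ predicted positive) is fixed and
  documented; AUC ties contribute one half.
* `fold_changes` refuses mismatched k and empty corpora; dictionary TSVs
  round-trip exactly (`repr` floats) and loading rejects duplicates and
  length-inconsistent k-mers.
* Early stopping checkpoints any strict improvement but counts patience only
  against improvements larger than `min_delta`, so the restored model is
  always the best seen.

## Known limitations

* Counting is forward-strand only by default, so positional lookups are
  strand-specific and a motif on the minus strand is a different k-mer.
  `build_dictionaries(..., revcomp=True)` augments both corpora with their
  reverse complements (making fc(w) = fc(revcomp(w))), but the flag defaults
  off because the flanking chromatin-state calls are unstranded and the
  benchmark plants forward-strand motifs.
* The architectures stand in for unavailable originals; they honor the
  stated model families and a CPU-hours budget, not exact layer tables.
* Fold-change dictionaries are dense Python dicts; at k = 11 on genome-scale
  corpora memory grows with the number of distinct observed k-mers.
* The sampler matches GC only; repeat content and higher-order composition
  are not matched (fixed L makes length matching automatic).
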