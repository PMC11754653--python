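# Methods

## The experimental design retrolib models

A pooled retron experiment has three layers, each with its own sequencing
readout:

1. **msDNA production screens** (bacterial host). A library of ncRNA
   variants is expressed with the retron RT; samples are taken of the
   plasmid pool before and after expression, and of the purified msDNA.
   Variants altering the reverse-transcribed *msd* region are identified by
   their altered sequence on the msDNA itself; variants altering the
   non-reverse-transcribed *msr* region are identified by a linked 10-nt
   barcode placed in the P4 loop (which rides along into the msDNA). A
   *pseudo-wild-type* control — wild-type ncRNA carrying only the P4
   barcode — normalizes barcoded sublibraries, cancelling the cost of the
   10-nt insert itself.

2. **Editron screens** (yeast-style time course). Each design fuses the
   ncRNA to a gRNA; its msDNA donor writes a unique 10-nt barcode into a
   genomic site and recodes the PAM NGG→NAT so the edited allele is not
   re-cut. Samples: plasmid pool at 0/24/48 h and the genomic edit site at
   48 h.

3. **Individual validation amplicons**: reads classified as precise edit /
   wild type / indel by exact window match.

## Quantification

*Relative abundance* is raw count over total counts per sample.

*msDNA production* divides a variant's msDNA relative abundance by the mean
of its pre- and post-expression plasmid abundances (integrating plasmid
abundance over the expression window), then scales so the wild type (or
pseudo-wild-type) is 100%. Variants with zero plasmid abundance are emitted
as missing, never infinite; there are no pseudocounts anywhere — the
pipeline filters rather than smooths.

*Barcode representation* divides a barcode's relative abundance in the
genome sample by its relative abundance in the time-integrated (t0+t24+t48)
plasmid pool. Barcodes are dropped unless the plasmid-pool sum is strictly
greater than `min_plasmid` (default 10) and the genome count is nonzero;
the genome-count>0 flag is also kept as the "working" indicator for
working-fraction summaries. Raising `min_plasmid` can only shrink the
surviving set (filter monotonicity; tested).

*Axis summaries* follow a three-level scheme: (i) within each group of
designs sharing every axis label except the axis of interest — within
replicate × site — divide by the reference level (groups whose reference is
missing or filtered are dropped and counted); (ii) take the median across
variants within each replicate × site; (iii) average the medians across
replicates and sites (± sd). The reference level therefore summarizes to
exactly 1.

*Statistics*: one-sample *t* against 1.0 (the natural null after
within-group normalization), paired *t*, and one-way ANOVA with either
Dunnett-vs-reference contrasts (via `scipy.stats.dunnett`) or
Bonferroni-corrected one-sample tests. Degenerate zero-variance groups are
handled explicitly (t = 0, p = 1 when the mean equals the null).

*Inverse normal transform*: z_i = Φ⁻¹((r_i − c)/(n + 1 − 2c)) with the Blom
offset c = 3/8 by default (configurable); ties get average ranks.

*Read handling*: barcode extraction requires an exact 5′ flank match (both
orientations tried, first occurrence wins), an exact 3′ flank at the
expected offset, and a unique best whitelist match within `max_mismatch`
(ties unassigned). The whitelist must have minimum pairwise Hamming
distance > 2·`max_mismatch`, which barcode generation guarantees by
construction (seeded, min distance 3). msDNA reads are matched exactly
after trimming the leading G/C homopolymer left by the poly-dC/TdT library
prep. Amplicon classification is exact-window: precise-edit window, else
wild-type window, else indel if both outer anchors are present, else
unclassified; both the literal edit/WT ratio and edit % of classified reads
are reported, since both conventions are in circulation.

## Library design choices

- Coordinates are 1-based closed intervals on the ncRNA 5′→3′; sequences
  are stored as DNA (RNA input converted U→T) because all counting operates
  on DNA reads.
- Stem-bubble "broken" variants replace the 5′-arm window so that every
  position is non-complementary to its wild-type partner, choosing for each
  base the first of A>C>G>T that is neither the original base nor the
  partner's complement — a deterministic rule guaranteeing zero pairing.
  "Restored" variants additionally mirror the reverse complement onto the
  3′ arm, recovering the pairing pattern with a non-wild-type sequence.
  Bubble lengths: 4 nt in P2/P3, 5 nt in P4.
- The P4 GC series redraws both arms (kept reverse-complementary) with the
  5′-arm GC fraction confined to each 10%-wide bin; the realized GC% is
  recorded per variant.
- Donor length counts the full synthesized donor including the 10-nt
  insert. The donor-center grid is config-driven; center 0 places the
  window midpoint at the middle of the insert (equivalently 5 nt 5′ of the
  insertion point on the unedited locus), and the default grid is
  symmetric: (−20, −10, 0, 10, 20).
- Cut positions use the canonical SpCas9 blunt cut between protospacer
  positions 17/18 (3 bp from the PAM). Each design's donor recodes the PAM
  of its own paired gRNA (NGG→NAT; in plus-strand coordinates both
  orientations recode the GG/CC dinucleotide to AT). With five gRNAs per
  donor geometry, the recoded PAM necessarily differs per pair, so the
  donor *sequence* is built per design while the "donor" count refers to
  the length × center × strand grid (50 per site; × 5 gRNAs = 250 pairs).
- Barcodes come from a seeded generator with minimum pairwise Hamming
  distance 3, giving unambiguous demultiplexing at 1 mismatch.

## The retDNN regressor

Input is a 4 × max_len one-hot tensor (channel order A,C,G,T; zero columns
past the sequence end). The network is two convolution+ReLU blocks
(default 32 channels, kernel 5, same padding), a residual dilated block
(one convolution per dilation rate, defaults 1/2/4, each added back to the
running representation), global pooling over positions, and a two-layer
perceptron head (hidden width 32). Targets are inverse-normal-transformed
activities, standardized internally during fitting and restored at
prediction; the loss is mean-squared error under Adam (step size 1e-3,
batch 64), with early stopping on validation loss (patience 8) and
restoration of the best-validation weights. Everything is seeded: two fits
with the same seed are bit-identical.

Design notes:

- **Pooling default is mean, not max.** The activity landscapes this model
  targets are dominated by additive per-position effects (in log space), a
  structure mean pooling represents exactly — a 1-wide convolution plus
  averaging *is* an additive model — while max pooling can only see the
  single strongest local feature. Max pooling remains available
  (`pool="max"`) for motif-presence-style targets.
- Position specificity comes from context, not coordinates: convolutions
  are translation-invariant, so per-position effects are learnable only
  because library variants are near mutants of one fixed wild-type backbone
  whose local sequence identifies each position. On random backbones the
  same landscape is provably not representable; the test suite encodes this
  distinction.
- The implementation is plain NumPy (im2col convolutions as batched
  matmuls with hand-written backward passes). This keeps the package free
  of a deep-learning framework dependency and makes determinism trivial.
- Hyperparameter search is a seeded exhaustive grid over estimator
  parameters with a fixed 3:1 train:validation split, ties breaking toward
  the earlier grid point.
- Padding is zero-column rather than a fifth channel; max_len defaults to
  the longest training sequence.

## The simulator and what it does (not) emulate

`simulate` draws all counts multinomially around true proportions:

- **Replicate structure**: each replicate's plasmid composition is the base
  composition jittered by lognormal noise (σ = 0.1 by default), shared by
  all of that replicate's samples — so plasmid-normalized statistics stay
  unbiased while replicates differ realistically.
- **msDNA samples** draw with probability ∝ plasmid proportion × planted
  production. The default tolerance landscape is flat at 1.0 with
  intolerant wells at the priming guanosine (0.05), the RT motif (0.02) and
  P3 (arms 0.3, loop 0.1), moderate costs in a1 (0.4), P2 arms (0.7) and
  the msd bases flanking a2 (0.2), class multipliers for deletions (0.6)
  and insertions (0.75), and a GC term exp(−0.015·(GC% − wt GC%)) on
  re-randomized P4 stems. P4-loop barcode insertions are cost-free, making
  the pseudo-wild-type's planted production exactly 1.
- **Editing samples**: three independent multinomials around the same
  plasmid proportions (plasmid composition is stable over the time course)
  and a genome sample with probability ∝ plasmid proportion × the product
  of per-axis factors. Default factors plant the directions a pooled
  editing screen shows: strand target 0.5 vs non-target 1.0; lengths
  54→0.1, 64→0.4, 78→0.7, 94→1.0, 112→1.3; cuts −16→0.40, −8→1.30, 0→1.0,
  +8→0.65, +16→0.45; centers falling off symmetrically; chassis neutral. A
  seeded 20% of designs are planted dead (factor 0). These are planted
  truths for recovery testing, configurable, and not asserted as facts
  about any real dataset.
- **Reads**: flank5 + barcode + flank3 with constant quality; substitution
  errors at a configurable rate applied to the variable insert (flanks are
  primer-derived and emitted as synthesized). At error rate 0 the emitted
  FASTQ re-counts to the source table exactly.

Not modelled: PCR amplification bias, chimeric reads, quality-score
structure, overdispersion beyond the optional lognormal jitter, indel
sequencing errors. Passing recovery tests therefore demonstrates the
*pipeline's* correctness — estimator consistency, filter behaviour,
normalization algebra — not robustness to every artefact of real
libraries.

The synthetic annotation (`synthetic_annotation`) is a self-consistent
~90-nt ncRNA with the full structural grammar (a1/priming G/P2/P3+motif/
P4/a2) so that every validation path and coordinate computation is
exercised; it is not the natural Eco1 sequence, whose coordinates a user
supplies as a YAML annotation from public sources.

## Problem sizes used in tests and the acceptance script

Recovery runs use depth 10⁶ with 3 replicates (editing: 1250-design
factorial over 5 chassis; production: a 50-variant library), where
multinomial sampling error per variant is well under the 5% recovery
tolerance. Model recovery trains on 3000 synthetic variants (σ = 0.2
lognormal noise, three seeds, 30-epoch cap) — the scale of a real ncRNA
variant library — and evaluates Pearson R on a 10% held-out split;
observed R ≈ 0.92–0.93 against the planted landscape, with the planted
negative GC effect reproduced as a negative prediction-vs-GC% slope.

## Numerical conventions

- Missing values propagate as NaN and are excluded with logged counts;
  division by a zero reference drops the group.
- The `>10` plasmid filter is strict (`>`, not `≥`).
- Whitelist ambiguity (two barcodes within 2·max_mismatch) is a
  configuration error, not a silent misassignment.
- All enumerators are deterministic given (annotation, parameters, seed);
  all simulations serialize their ground-truth model and seed alongside
  every output.

## Known limitations

- Exact/Hamming matching only: no alignment-based variant calling and no
  quantification of complex alleles.
- Interval remapping through multi-edit variants is first-order: each
  edit's coordinates refer to the sequence as left by the previous edit,
  which is exact for the enumerators shipped here but not a general
  liftover.
- Dunnett contrasts inherit `scipy.stats.dunnett`'s stochastic
  multivariate-t integration (agreement with published tables ≈ 1e-3).
- The CLI covers the common paths; combinatorial restriction of the
  editron factorial is exposed only through the library API (`restrict=`).
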