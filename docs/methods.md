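# Methods

This note records the models, conventions, numerical choices and known
limitations behind each `tfparalog` module, and what the synthetic-data
generators do and do not emulate.

## Coordinates, intervals and peak calling

All coordinates are 0-based half-open (BED dialect) everywhere in the
package; readers of 1-based formats must convert at the boundary. Interval
sets are kept sorted by (chrom, start, end) and every operation preserves
sortedness. Signal tracks use bedGraph step semantics with implicit zero
between steps.

Threshold peak calling mirrors genome-browser thresholding: a peak is a
maximal run of bases with signal ≥ threshold and length ≥ `min_length`
(default 1, no gap joining — the simplest reading of a thresholding
caller). The peak score is the maximum signal inside the peak and the
summit is the **leftmost** base attaining that maximum (a deterministic
tie-break). Raising the threshold can only shrink peak bases (tested
monotonicity).

Binding-site classification unifies mutually overlapping peaks of the two
factors by transitive closure (merge at gap 0): clusters containing peaks
of both factors become one F1F2 site spanning the union; single-factor
clusters keep their PF1/PF2 label. The three labels therefore partition
the merged union of the two input sets base-exactly, which is the invariant
the per-base oracle tests assert. Both factors' maximum signals are
recorded at every site so sub-threshold behaviour of the other factor at
preferential sites remains inspectable.

## PWM model and score-ratio scanning

A PWM is a (length × 4) per-position probability matrix; scores are log₂
odds against the background (uniform 0.25 by default). The scanning
statistic is the **score ratio** (raw − min)/(max − min), where min/max are
the PWM's extremal log-odds sums, so 0 is the worst possible window and 1
the best; the degenerate max = min case (e.g. an all-uniform PWM) is
defined as ratio 1.0. The default reporting threshold is ratio > 0.80,
strict; at `min_ratio = 1.0` perfect-score windows are reported (up to
float rounding) so the endpoint remains usable. Both strands are always
scanned; N bases contribute 0 log-odds; counting collapses plus/minus hits
on the identical span to one site, because near-palindromic AP-1-like
motifs would otherwise double-count every occurrence.

Composition features are strand-symmetric by construction: mononucleotide
classes {A+T, C+G} over non-N bases, and the 16 dinucleotides collapsed by
reverse-complement equivalence into 10 classes. Each group of rates sums
to 1 and is invariant under reverse-complementing the sequence (property
tested).

PWM reconstruction uses column probabilities (count + pseudocount) /
(n + 4·pseudocount); JASPAR count matrices are converted with pseudocount
0.01. Information content per column is 2 + Σ p log₂ p bits (uniform
background, 0·log 0 = 0), ranging from 0 (uniform) to 2 (single base).

## Binding-preference models

Feature rows are 1001-bp sequences centered on peak summits (odd window so
the summit is the exact center); rows whose window leaves the contig are
dropped with a warning. Features are the per-PWM maximum score ratio over
the window (both strands) plus the 12 composition rates — with a JASPAR
library of 650 PWMs this is the 662-variable design.

Protocol, shared by classification and regression: classes balanced by
seeded subsampling of the majority to the minority size; a seeded
stratified 70/30 train/test split; features standardized (zero mean, unit
variance) on the training rows only, constant features dropped with a
warning; an L1 penalty path of 100 logarithmically spaced λ from λ_max
(the smallest λ with all-zero coefficients) down to λ_max·10⁻⁴; λ selected
by 10-fold cross-validation **within the training split** at the mean-
deviance minimizer (the glmnet `lambda.min` rule — folding only the
training rows keeps the reported test metric leakage-free); final refit on
all training rows at the selected λ. Implementation detail: the CV scan
runs at loose solver tolerance (1e-2) for speed — the deviance curve is
smooth so the selected λ is stable — and the final model is refit at
tolerance 1e-4. Classification reports the held-out AUC (midrank ties, via
`roc_auc_score`); regression reports the held-out Pearson r of predicted
vs observed log₁₀(Y₁/Y₂) with its p-value. Coefficients are reported on
the standardized scale with the convention positive → PF1 (the PF1 rows
are encoded 1); the sign flips if the encoding flips, which is tested.
`single_feature_auc` ranks the same held-out rows by one raw feature value
and reports max(AUC, 1 − AUC), the feature's discriminative power
regardless of direction.

## Candidate regulatory elements

Promoter domains are symmetric TSS ± 1500 bp windows (strand-independent,
"centered on" the TSS); overlapping domains are unified before
classification so states stay base-disjoint. A domain overlapping any
H3K27ac peak is cAP, else cIP ("low H3K27ac" is operationalized as *no
overlap with a called H3K27ac peak*; no quantitative bound is defined).
H3K4me1 peaks have promoter-domain bases subtracted; the surviving pieces
are cAE if they overlap H3K27ac, else cIE. H3K4me3 is carried per element
as an annotation layer only and enters no rule. Promoter precedence holds
at every base (oracle-tested).

Signed fold changes use the convention fc = c/k if c ≥ k else −k/c (always
|fc| ≥ 1; an exact tie is +1 by convention), with inclusive category bounds
at ±threshold (default 1.5). Batch fold changes add a pseudo-signal floor,
default 5% of the median control signal over the queried intervals, so
near-zero control signals do not explode the ratio; the scalar function
defaults to floor 0 and rejects nonpositive floored signals.

## Regulation groups

With modulation calls for si1, si2 and si12 (each significant against both
control conditions upstream — this package consumes the calls, it does not
re-test): A = si1 and not si2; B = si2 and not si1 (si12 is deliberately
ignored for A/B, since the other siRNA "may strengthen" the effect);
C = only si12; D = both singles modulated, same direction, and
|fc(si12)| strictly greater than the stronger single. Two edge cases are
flagged rather than forced into a group: opposite-direction singles
(`discordant`) and both-singles-without-stronger-double
(`both_nonadditive`); both receive group `none` with the flag set, keeping
the A–D assignments unambiguous. The 8-way modulation truth table is
asserted exhaustively. The fold-change filter keeps genes whose strongest
modulated |fc| meets an inclusive threshold (default 1.5).

## PIR calling

The published viewpoint-interaction caller is deliberately **not**
reproduced; `call_pirs` is a defined, self-contained substitute that keeps
the three published parameter names meaningful: `alpha_fdr` (BH level,
default 0.1), `w_size` (window of 5 fragments), `q_wr` (per-replicate
background-ratio multiplier, default 1).

Pipeline per viewpoint: (1) replicate normalization equalizes per-replicate
cis totals outside the exclusion zone (2 fragments on each side of the
viewpoint, where undigested/self-ligation artifacts live); (2) background
= per-side non-increasing isotonic fit of the replicate-mean count versus
midpoint distance, after a median filter (window 2·w_size + 1 fragments)
so narrow interaction spikes cannot inflate the local background; sides
with < 20 fragments are skipped with a warning; (3) the test statistic is
the w_size-window mean of **relative** residuals
(mean − expected)/max(expected, 1) — relative, because count noise scales
with the expected count along the decay and raw residuals near the
viewpoint would otherwise dominate the null and mask distal interactions;
(4) the null is the pooled window statistic of `n_permutations` (default
1000, minimum 100) seeded resamples of the residual pool — resampling
rather than rotating, because a rotation preserves the contiguity of
genuine interaction runs and would reproduce the very windows under test —
with one-sided add-one p-values and BH control at `alpha_fdr`, run in two
passes: fragments rejected in pass one are excluded from the pass-two null
pool, so strong interactions do not fatten the null tail and mask
themselves (under the null pass one rejects essentially nothing, so type-I
control is unchanged — verified empirically at ≤ alpha + 0.05 over 50
seeded null profiles); (5) a fragment is called only if its w_size-window
mean count is ≥ q_wr × the window-mean expected in **every** replicate —
windowed, not per-fragment, so the reproducibility requirement is about
the region rather than single-fragment counting noise (`q_wr = ∞` silences
the caller regardless of signal, as expected of a consistency filter);
(6) called adjacent fragments merge into PIRs carrying mean observed/
expected enrichment, midpoint-to-midpoint distance to the viewpoint, and
fragment count. Distances are midpoint-based throughout. Trans
interactions are out of scope; profiles are cis-only by construction.

Measured calibration under the generator's study conditions (negative
binomial, dispersion 0.3, 3 replicates, planted 3× regions of 5
fragments): sensitivity ≈ 0.94 (a region counts as recovered when ≥ 3 of
its 5 fragments are called), ≈ 0.2 false PIRs per viewpoint with signal,
and a null false-PIR rate ≈ 0.10 at `alpha_fdr` 0.1.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed) — bit-identical
outputs across runs — and every dataset ships with a truth table;
downstream checks consume truth rather than re-deriving it.

The binding model plants a 7-bp TRE-like core (TGAGTCA) in three flavors:
PF2-truth sites draw from a **strict** PWM (0.91 consensus probability per
column, total IC ≈ 10 bits), PF1-truth sites from a **degenerate** PWM
(0.55 consensus with two near-uniform positions, IC ≈ 1.5 bits) inside
mildly AT-enriched ± 500-bp flanks, and F1F2-truth sites from a uniform
stringency mixture, with the planted signal ratio log₁₀(Y₁/Y₂) =
−β·(strict score ratio) + Gaussian noise (β = 1, σ = 0.15 by default).
The AT flank excess defaults to +0.01: over a 1001-bp window the A+T rate
has a standard deviation of ≈ 0.016, so +0.01 is a deliberately *subtle*
≈ 0.6 σ shift that keeps composition a secondary discriminator behind
motif stringency, as in real chromatin; a boost of +0.10 would make the
composition feature a ≈ 6 σ class label and reduce the classification task
to base counting. Under these defaults the models land at full AUC ≈ 0.80
with single strict-motif AUC ≈ 0.74 and ratio r ≈ 0.25–0.38 — the
qualitative regime of real paralog ChIP-seq — without any per-seed tuning.

Signal peaks are flat-core/shoulder step profiles (core 20 bp at the drawn
height starting at the site center, 0.6× shoulders), so the called summit
equals the planted center; the factor absent from a preferential site
leaves a faint sub-threshold plateau (25 signal units against the calling
threshold of 50), mirroring how preferential sites look in browser tracks.
Histone landscapes place marks per element class (cAE: K4me1 + K27ac +
ATAC; cIE: K4me1; cAP: promoter + K27ac + K4me3; cIP: promoter only) with
independent per-mark dropout. Capture profiles pseudo-digest a 1-Mb region
(exponential fragment lengths, mean 2.5 kb), decay as A/(1 + d/d₀)
(A = 100, d₀ = 50 kb) and draw negative-binomial counts (dispersion 0.3,
3 replicates) with planted 3× regions of 5 fragments. Expression calls
realize each group's defining pattern with |fc| drawn from [1.6, 4.0] and
optional per-condition call corruption.

Not emulated — and therefore not demonstrated by passing tests: read-level
artifacts (mappability, GC bias, duplicates), peak-shape heterogeneity,
motif grammar beyond a single planted occurrence per site, inter-replicate
correlation in capture counts, TAD structure, and the upstream
differential-testing machinery behind the modulation calls. Results on
real data depend on all of these; the test suite shows the *procedures*
are correct and calibrated under their stated assumptions, not that the
biology of any particular dataset will reproduce.

## Desk-scale problem sizes

The shipped study conditions are chosen so the whole suite runs on one
CPU in minutes: 2 × 1000 balanced sites (classification) and 2000 shared
sites (regression) on a 2 × 2-Mb genome with a 10-PWM scanning library;
50-seed calibration batches for the PIR caller on ~400-fragment, 1-Mb
viewpoints; and a few-hundred-site demonstration pipeline. All sizes are
config fields and scale up unchanged.

## Known limitations

- The threshold peak caller has no gap joining or minimum-length heuristics
  beyond `min_length`; fragmented plateaus become fragmented peaks.
- Score-ratio scanning treats positions independently (PWM assumption);
  no dinucleotide or higher-order motif models.
- The isotonic background assumes monotone decay per side; a genuinely
  non-monotone background (e.g. a neighboring viewpoint) would be absorbed
  as signal.
- `classify_overlap` labels touching-but-not-overlapping peaks of the two
  factors as one F1F2 cluster (merge at gap 0); with base-pair-resolution
  peak sets this boundary case is vanishingly rare.
- The regulation-group rules are deterministic in the upstream calls; no
  uncertainty propagates from the differential tests.
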