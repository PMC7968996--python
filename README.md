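# tfparalog

Analysis toolkit for dissecting how two **paralogous transcription factors**
divide a shared genome: which binding sites each factor prefers, what
sequence features drive the preference, which chromatin elements the sites
fall into, which genes the factors regulate redundantly or complementarily,
and which distal regions physically contact the regulated promoters.

The package grew out of the AP-1 biology of Fra-1 and Fra-2 — two Fos-family
proteins that bind near-identical TRE motifs (TGAG/CTCA) yet regulate
overlapping-but-distinct transcriptomes — but every stage is generic over
any factor pair with ChIP-seq peak sets, a PWM library, knockdown calls and
viewpoint interaction profiles.

## What it computes

1. **Binding-site classes.** Two called peak sets are partitioned into
   sites bound preferentially by factor A (**PF1**), preferentially by
   factor B (**PF2**), or efficiently by both (**F1F2**, the union span of
   mutually overlapping peaks). Peaks come from bedGraph signal tracks by
   thresholding (default threshold 50), or from any external caller.
2. **Binding-preference models.** Each site contributes a 1001-bp
   summit-centered sequence. Features are the per-PWM **maximum score
   ratio** — the log-odds score of the best window, min–max normalized to
   [0, 1] so a single threshold (0.80) is comparable across motifs — plus
   2 mononucleotide and 10 reverse-complement-collapsed dinucleotide rates.
   An L1-penalized (LASSO) logistic model separates PF1 from PF2 (70/30
   train/test split, 10-fold cross-validation on the training rows, λ at
   the CV-deviance minimum, held-out AUC); an L1 linear model regresses
   log₁₀(Y₁/Y₂), the two factors' signal ratio at F1F2 sites (held-out
   Pearson r).
3. **Candidate regulatory elements.** Promoter domains are 3-kb windows
   centered on TSSs: **cAP** with H3K27ac, **cIP** without. H3K4me1 regions
   outside promoter domains are enhancer candidates: **cAE** with H3K27ac,
   **cIE** without. States are base-disjoint with promoter precedence.
4. **Regulation groups.** From per-gene modulation calls under siRNA
   knockdown of factor 1, factor 2, and both: group **A**/**B**
   (preferential), **C** (redundant — only the double knockdown acts),
   **D** (complementary — both singles act, the double acts strictly more
   strongly), with an inclusive ±1.5 fold-change filter.
5. **Promoter-interacting regions (PIRs).** Per-viewpoint restriction-
   fragment interaction counts are normalized per replicate, fitted with a
   non-increasing isotonic distance-decay background per side, and tested
   with a windowed permutation statistic (defaults `alpha_fdr = 0.1`,
   `w_size = 5` fragments, `q_wr = 1`); called adjacent fragments merge
   into PIRs with enrichment, distance and layout statistics, nested
   ATAC/enhancer/TF-binding annotation, and condition delta-profiles.
6. **Synthetic data.** Seeded generators produce every input with planted
   truth: genomes with class-dependent motif stringency (strict vs
   degenerate TRE-like PWMs) and AT-shifted flanks, histone landscapes,
   negative-binomial viewpoint profiles with planted interactions, and
   knockdown call tables realizing the four regulation groups.

## Worked example

`examples/04_binding_preference_model.py` simulates 500 + 500 preferential
sites plus 600 shared sites, builds the feature matrix and fits both
models:

```
feature matrix: 1000 sites x 22 features
full-model test AUC = 0.83; strict-motif feature alone: AUC = 0.76
top selected features (positive -> PF1, negative -> PF2):
        strict_TRE  -1.145
               C+G  -0.357
                TA  +0.147
                AT  +0.070
             CC/GG  -0.056
signal-ratio regression at shared sites: r = 0.38 (p = 1.1e-07)
```

Read: the full LASSO model separates the two factors' preferred sites with
held-out AUC 0.83, and the single strict-motif feature alone is nearly as
accurate (0.76) — the intrinsic stringency of the AP-1-like motif, not
combinations with other factors, carries the discrimination. Its negative
sign points toward the PF2 class: closer-to-consensus motifs pull binding
toward factor B, and the same stringency measurably shifts the two factors'
signal ratio at shared sites (r = 0.38). The other
`examples/` scripts cover each capability: site classification, motif
scanning and PWM reconstruction, element annotation, regulation groups,
PIR calling, and the end-to-end pipeline (also available from a shell as
`tfparalog report --seed 11 --out pipeline_out`; `tfparalog --help` lists
the other subcommands).

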