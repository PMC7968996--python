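"""Discriminate the two factors' binding preferences from sequence features.

Builds the 1001-bp summit-centered feature matrix (per-PWM maximum score
ratios + 12 composition rates), balances the classes, fits an L1-penalized
logistic model (70/30 split, 10-fold CV, lambda at the CV minimum), and
compares the full model with the single strongest motif feature. Then fits
the companion L1 regression of log10(Y1/Y2) at shared sites.
"""

from tfparalog import discrimination as disc
from tfparalog.simulate import (
    SimulationConfig,
    default_pwm_library,
    plant_peaks,
    simulate_genome,
    truth_classified_peaks,
)

cfg = SimulationConfig(
    seed=0,
    n_chroms=2,
    chrom_length=1_200_000,
    n_tss_per_chrom=12,
    tss_min_spacing=15_000,
    n_peaks={"PF1": 500, "PF2": 500, "F1F2": 600},
)
genome, _ = simulate_genome(cfg)
genome, *_tracks, truth = plant_peaks(cfg, genome)
library = default_pwm_library()
sites = truth_classified_peaks(truth)

pf = [p for p in sites if p.label in ("PF1", "PF2")]
fm = disc.balance_classes(
    disc.build_feature_matrix(pf, genome, library), seed=0
)
spec = disc.ModelSpec(seed=0)
_, ev = disc.fit_classifier(fm, spec)
single = disc.single_feature_auc(fm, "strict_TRE", spec)

print(f"feature matrix: {fm.n_rows} sites x {fm.n_features} features")
print(f"full-model test AUC = {ev.auc:.2f}; "
      f"strict-motif feature alone: AUC = {single:.2f}")
print("top selected features (positive -> PF1, negative -> PF2):")
for name, coef in disc.top_coefficients(ev, 5).items():
    print(f"  {name:>16s}  {coef:+.3f}")

f12 = [p for p in sites if p.label == "F1F2"]
fm12 = disc.build_feature_matrix(f12, genome, library)
_, reg = disc.fit_ratio_regressor(fm12, disc.ModelSpec(seed=0))
print(f"signal-ratio regression at shared sites: "
      f"r = {reg.pearson_r:.2f} (p = {reg.pearson_p:.1e})")
print("(the strict-motif feature carries most of the discrimination and a "
      "negative coefficient: stricter motifs pull binding toward factor B)")
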