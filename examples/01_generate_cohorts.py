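"""Generate a two-cohort synthetic plasma-proteomics study with known truth.

Builds the discovery and replication cohorts (NPX matrices with per-assay
LODs, sample metadata, planted group effects), then prints what was planted.
"""

from npxtools import synth

config = synth.SynthConfig(
    n_plhiv_disc=120, n_hc_disc=80, n_plhiv_repl=200, n_hc_repl=80,
    n_proteins=400, n_true_dep=60, seed=11,
)

for cohort in ("discovery", "replication"):
    m, samples, truth = synth.generate_cohort(config, cohort)
    n_plhiv = (samples["group"] == "PLHIV").sum()
    print(f"{cohort}: {m.n_samples} samples ({n_plhiv} PLHIV), "
          f"{m.n_assays} assays across {m.assay_meta['panel'].nunique()} panels")
    print(f"  planted outlier samples: {truth.outlier_samples[cohort]}")

print(f"\nplanted truth: {len(truth.true_dep_effects)} true DEPs "
      f"(same signed effects in both cohorts), "
      f"{len(truth.low_detect_ids)} low-detection proteins, "
      f"planted tissue = {truth.planted_tissue!r}")
effects = list(truth.true_dep_effects.items())[:3]
print("example planted effects (log2-NPX shift in PLHIV):", effects)
# Interpretation: a planted effect of +0.6 means PLHIV plasma carries about
# 2**0.6 ~ 1.5x the protein concentration of healthy controls for that assay.
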