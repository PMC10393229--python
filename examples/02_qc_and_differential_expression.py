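"""QC an NPX matrix and call replicated differentially expressed proteins.

Deduplicates the technical-control assays, removes outlier samples by PCA,
filters poorly detected proteins, fits the covariate-adjusted moderated
model in both cohorts, and calls sDEPs (discovery FDR < 0.05, replication
P < 0.05, consistent direction).
"""

from npxtools import diffexp, qc, synth

config = synth.SynthConfig(
    n_plhiv_disc=120, n_hc_disc=80, n_plhiv_repl=200, n_hc_repl=80,
    n_proteins=400, n_true_dep=60, seed=11,
)

de_tables = {}
for cohort in ("discovery", "replication"):
    m, samples, truth = synth.generate_cohort(config, cohort)
    m, dedup = qc.dedup_control_assays(m, synth.CONTROL_PROTEINS, "inflammation")
    outliers, _ = qc.pca_outliers(m, k_sd=3.0)
    m = m.subset_samples([s for s in m.sample_ids if s not in set(outliers)])
    kept, dropped = qc.protein_qc_two_group(m, samples.loc[m.sample_ids, "group"])
    m = m.subset_assays(kept)
    print(f"{cohort}: removed {len(dedup)} duplicate control assays, "
          f"{len(outliers)} PCA outlier samples, {len(dropped)} below-LOD proteins; "
          f"{m.n_assays} proteins x {m.n_samples} samples into the model")
    de_tables[cohort] = diffexp.run_de(m, samples.loc[m.sample_ids])

sdeps = diffexp.call_sdeps(de_tables["discovery"], de_tables["replication"])
true = set(truth.true_dep_ids)
called = set(sdeps.index)
print(f"\nsDEPs called: {len(sdeps)} ({int(sdeps['up'].sum())} up, "
      f"{int((~sdeps['up']).sum())} down)")
print(f"recall of planted DEPs: {len(called & true) / len(true):.2f}; "
      f"false calls: {len(called - true)}")
big = diffexp.fold_change_subset(sdeps, threshold=1.5, scale="npx_diff")
print(f"sDEPs with |log2 fold-change| >= 1.5 in BOTH cohorts: {len(big)}")
# The effect column is the adjusted difference in mean log2 NPX between
# PLHIV and HC; a moderated t with shrunken residual variance gives the P.
print(sdeps.head(5).round(4))
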