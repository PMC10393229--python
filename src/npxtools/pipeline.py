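"""End-to-end orchestration: synth -> qc -> de -> enrich -> network -> assoc.

One seeded configuration drives cohort generation, QC, discovery/replication
differential expression, tissue/cell and pathway enrichment, the pathway
overlap network with MCL clustering, and the association analyses
(microbiome, baseline and prospective CVD, set enrichment, three-way
overlap). Every stage's record counts land in the run report, and all
intermediate tables can be persisted so each reported number is
re-derivable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, assoc, diffexp, enrich, pathnet, qc, synth
from .reporting import percent_round_half_up

logger = logging.getLogger("npxtools.pipeline")

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

_THRESHOLD_BOUNDS = {
    "fdr_thr": (0.0, 1.0),
    "p_thr": (0.0, 1.0),
    "alpha": (0.0, 1.0),
    "below_frac": (0.0, 1.0),
    "diff_frac": (0.0, 1.0),
    "min_prev": (0.0, 1.0),
    "ora_p_max": (0.0, 1.0),
    "overlap_threshold": (0.0, 1.0),
}


@dataclass
class RunConfig:
    """Validated run configuration; every threshold defaults to the study's."""

    seed: int = 0
    synth: dict = field(default_factory=dict)  # SynthConfig field overrides
    fdr_thr: float = 0.05
    p_thr: float = 0.05
    fc_threshold: float = 1.5
    fc_scale: str = "npx_diff"
    below_frac: float = 0.25
    diff_frac: float = 0.20
    k_sd: float = 3.0
    mean_count_min: float = 500.0
    ctrl_dev_max: float = 0.3
    min_category: int = 4
    ora_p_max: float = 0.05
    ora_min_count: int = 4
    overlap_threshold: float = 0.375
    inflation: float = 2.0
    alpha: float = 0.05
    min_prev: float = 0.20
    run_enrichment: bool = True
    run_network: bool = True
    run_microbiome: bool = True
    run_cvd: bool = True
    outdir: str | None = None

    def validate(self) -> "RunConfig":
        for name, (lo, hi) in _THRESHOLD_BOUNDS.items():
            v = getattr(self, name)
            if not (lo < v <= hi) and not (name == "overlap_threshold" and lo <= v < hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.fc_scale not in ("npx_diff", "linear_fc"):
            raise ValueError(f"fc_scale must be npx_diff or linear_fc, got {self.fc_scale!r}")
        if self.k_sd <= 0 or self.inflation <= 1:
            raise ValueError("k_sd must be > 0 and inflation > 1")
        known = {f.name for f in dataclasses.fields(synth.SynthConfig)}
        unknown = set(self.synth) - known
        if unknown:
            raise ValueError(f"unknown synth keys: {sorted(unknown)}")
        self.synth_config()  # runs SynthConfig.validate
        return self

    def synth_config(self) -> synth.SynthConfig:
        return synth.SynthConfig(**{**self.synth, "seed": self.seed})


def validate_config(path_or_dict) -> RunConfig:
    """Load and normalise a YAML run configuration.

    An empty file yields all defaults; unknown keys are rejected.
    """
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        text = Path(path_or_dict).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    return cfg.validate()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _qc_cohort(m, samples, cfg: RunConfig) -> dict:
    """Dedup + sample QC + PCA outliers + two-group protein QC for a cohort."""
    out: dict = {}
    n_assays_in = m.n_assays
    m, dedup_report = qc.dedup_control_assays(
        m, synth.CONTROL_PROTEINS, synth.CONTROL_HOME_PANEL
    )
    out["n_assays_raw"] = n_assays_in
    out["n_assays_dedup"] = m.n_assays
    out["dedup_spearman_min"] = (
        float(dedup_report["spearman_r"].min()) if len(dedup_report) else None
    )
    m, sample_report = qc.sample_qc_controls(m, cfg.mean_count_min, cfg.ctrl_dev_max)
    out["n_samples_after_vendor_qc"] = m.n_samples
    outliers, scores = qc.pca_outliers(m, k_sd=cfg.k_sd)
    kept = [s for s in m.sample_ids if s not in set(outliers)]
    m = m.subset_samples(kept)
    out["pca_outliers"] = outliers
    out["n_samples_final"] = m.n_samples
    samples = samples.loc[m.sample_ids]
    out["n_plhiv"] = int((samples["group"] == "PLHIV").sum())
    out["n_hc"] = int((samples["group"] == "HC").sum())
    kept_assays, dropped_assays = qc.protein_qc_two_group(
        m, samples["group"], cfg.below_frac, cfg.diff_frac
    )
    out["n_proteins_after_lod_qc"] = len(kept_assays)
    out["n_proteins_dropped_lod"] = len(dropped_assays)
    m_de = m.subset_assays(kept_assays)
    logger.info(
        "qc cohort=%s assays=%d->%d samples=%d->%d proteins=%d",
        samples["cohort"].iloc[0], n_assays_in, out["n_assays_dedup"],
        out["n_samples_after_vendor_qc"], out["n_samples_final"],
        out["n_proteins_after_lod_qc"],
    )
    return {"matrix_full": m, "matrix_de": m_de, "samples": samples, "summary": out}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all enabled stages; returns the run report dictionary.

    With ``cfg.outdir`` set, intermediate tables (DE tables, sDEP list,
    enrichment results, network exports, association tables) are persisted
    as TSV/JSON under that directory.
    """
    cfg.validate()
    scfg = cfg.synth_config()
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {"version": __version__, "seed": cfg.seed,
                    "config": dataclasses.asdict(cfg), "stages": {}}

    # --- synth + qc + de per cohort ------------------------------------
    truth = synth.make_truth(scfg)
    cohorts = {}
    for cohort in ("discovery", "replication"):
        m, samples, truth = synth.generate_cohort(scfg, cohort)
        samples = synth.generate_outcomes(scfg, m, samples, truth)
        stage = _qc_cohort(m, samples, cfg)
        de = diffexp.run_de(stage["matrix_de"], stage["samples"])
        stage["de"] = de
        stage["summary"]["n_dep_fdr"] = int((de["fdr"] < cfg.fdr_thr).sum())
        cohorts[cohort] = stage
        report["stages"][f"qc_{cohort}"] = stage["summary"]
        if outdir:
            de.to_csv(outdir / f"de_{cohort}.tsv", sep="\t")

    disc, repl = cohorts["discovery"], cohorts["replication"]
    sdeps = diffexp.call_sdeps(disc["de"], repl["de"], cfg.fdr_thr, cfg.p_thr)
    high_fc = diffexp.fold_change_subset(sdeps, cfg.fc_threshold, cfg.fc_scale)
    up_ids = sorted(sdeps.index[sdeps["up"]])
    true_set = set(truth.true_dep_ids)
    called = set(sdeps.index)
    recall = len(called & true_set) / len(true_set) if true_set else float("nan")
    emp_fdr = len(called - true_set) / len(called) if called else 0.0
    de_summary = {
        "n_proteins_disc": int(len(disc["de"])),
        "n_dep_disc": int((disc["de"]["fdr"] < cfg.fdr_thr).sum()),
        "n_sdep": int(len(sdeps)),
        "n_sdep_up": int(sdeps["up"].sum()),
        "n_sdep_down": int((~sdeps["up"]).sum()),
        "pct_sdep_up": percent_round_half_up(int(sdeps["up"].sum()), len(sdeps))
        if len(sdeps) else None,
        "n_high_fold_change": len(high_fc),
        "recall_vs_truth": recall,
        "empirical_fdr_vs_truth": emp_fdr,
    }
    report["stages"]["diffexp"] = de_summary
    logger.info("diffexp sdeps=%d recall=%.3f emp_fdr=%.3f",
                len(sdeps), recall, emp_fdr)
    if outdir:
        sdeps.to_csv(outdir / "sdeps.tsv", sep="\t")

    # measured-protein background: unique proteins after dedup
    background = sorted(set(disc["matrix_full"].proteins()))
    cmap, gene_sets = synth.generate_annotations(scfg, truth)

    # --- enrichment ------------------------------------------------------
    enr_tissue = None
    if cfg.run_enrichment:
        enr_tissue = enrich.tissue_cell_enrichment(
            up_ids, background, cmap, min_category=cfg.min_category, alpha=cfg.alpha
        )
        top = enr_tissue.iloc[0] if len(enr_tissue) else None
        report["stages"]["enrichment"] = {
            "n_categories_tested": int(len(enr_tissue)),
            "top_category": None if top is None else str(top["category"]),
            "top_category_p": None if top is None else float(top["p"]),
            "planted_tissue": truth.planted_tissue,
            "planted_is_top": bool(top is not None and top["category"] == truth.planted_tissue),
        }
        if outdir:
            enr_tissue.to_csv(outdir / "tissue_enrichment.tsv", sep="\t", index=False)

    # --- pathway ORA + network ------------------------------------------
    if cfg.run_network:
        ora = enrich.pathway_ora(
            up_ids, background, gene_sets, p_max=cfg.ora_p_max, min_count=cfg.ora_min_count
        )
        sig = ora[ora["significant"]]
        net_summary = {"n_pathways_tested": int(len(ora)),
                       "n_pathways_significant": int(len(sig))}
        if len(sig):
            g = pathnet.build_network(sig, threshold=cfg.overlap_threshold)
            clusters, converged = pathnet.mcl_cluster(g, inflation=cfg.inflation)
            labels = pathnet.annotate_clusters(g, clusters)
            net_summary.update(
                n_nodes=g.number_of_nodes(),
                n_edges=g.number_of_edges(),
                n_clusters=len(set(clusters.values())),
                mcl_converged=bool(converged),
                cluster_labels=labels,
            )
            if outdir:
                edges, nodes = pathnet.export_network(g, clusters)
                edges.to_csv(outdir / "pathway_edges.tsv", sep="\t", index=False)
                nodes.to_csv(outdir / "pathway_nodes.tsv", sep="\t", index=False)
        report["stages"]["pathnet"] = net_summary
        if outdir:
            ora.drop(columns="members").to_csv(outdir / "pathway_ora.tsv", sep="\t", index=False)

    # --- microbiome associations ----------------------------------------
    if cfg.run_microbiome:
        plhiv_ids = [s for s in disc["matrix_full"].sample_ids
                     if disc["samples"].loc[s, "group"] == "PLHIV"]
        m_plhiv = disc["matrix_full"].subset_samples(plhiv_ids)
        kept, _ = qc.protein_qc_single_group(m_plhiv, cfg.below_frac)
        m_plhiv = m_plhiv.subset_assays(kept)
        micro = synth.generate_microbiome(scfg, m_plhiv, truth)
        filtered = assoc.prevalence_filter(micro.abundance, cfg.min_prev)
        clr = assoc.clr_transform(filtered)
        covs = disc["samples"].loc[plhiv_ids, ["age", "sex", "smoking"]].copy()
        covs["read_count"] = np.log10(micro.read_counts.loc[plhiv_ids])
        npx_by_protein = m_plhiv.values.copy()
        npx_by_protein.columns = list(m_plhiv.proteins())
        micro_assoc = assoc.bulk_linear_assoc(clr, npx_by_protein, covs, family="microbiome")
        groups = assoc.protein_groups(npx_by_protein.columns, list(sdeps.index), cmap)
        props, pairwise = assoc.proportion_significant_comparison(
            micro_assoc, groups, alpha=cfg.alpha
        )
        prop_by_group = dict(zip(props["group"], props["proportion"]))
        report["stages"]["microbiome"] = {
            "n_species_raw": int(micro.abundance.shape[1]),
            "n_species_kept": int(filtered.shape[1]),
            "n_pairs_tested": int(len(micro_assoc)),
            "prop_significant_by_group": {k: float(v) for k, v in prop_by_group.items()},
            "max_prop_group": max(prop_by_group, key=prop_by_group.get),
            "n_pairwise_tests": int(len(pairwise)),
        }
        if outdir:
            micro_assoc.to_csv(outdir / "microbiome_assoc.tsv", sep="\t", index=False)
            pairwise.to_csv(outdir / "microbiome_group_chi2.tsv", sep="\t", index=False)

    # --- CVD associations -------------------------------------------------
    if cfg.run_cvd:
        base_tables = {}
        for cohort, stage in cohorts.items():
            sam = stage["samples"]
            plhiv = sam.index[sam["group"] == "PLHIV"]
            m_p = stage["matrix_full"].subset_samples(list(plhiv))
            kept, _ = qc.protein_qc_single_group(m_p, cfg.below_frac)
            m_p = m_p.subset_assays(kept)
            npx = m_p.values.copy()
            npx.columns = list(m_p.proteins())
            covs = sam.loc[m_p.sample_ids, ["age", "sex", "bmi", "smoking"]]
            cvd = sam.loc[m_p.sample_ids, ["cvd_baseline"]].astype(float)
            # group-difference framing: protein as response, CVD as predictor
            tbl = assoc.bulk_linear_assoc(npx, cvd, covs, family=f"cvd_baseline_{cohort}")
            tbl = tbl.rename(columns={"feature": "protein", "protein": "predictor"})
            base_tables[cohort] = tbl.set_index("protein")
        screen = assoc.two_stage_cvd_screen(
            base_tables["replication"], base_tables["discovery"], cfg.fdr_thr, cfg.p_thr
        )
        sam = disc["samples"]
        plhiv = sam.index[sam["group"] == "PLHIV"]
        m_p = disc["matrix_full"].subset_samples(list(plhiv))
        kept, _ = qc.protein_qc_single_group(m_p, cfg.below_frac)
        m_p = m_p.subset_assays(kept)
        covs = sam.loc[m_p.sample_ids,
                       ["age", "sex", "bmi", "smoking", "dyslipidemia", "hypertension", "t2d"]]
        event = sam.loc[m_p.sample_ids, "cvd_incident"]
        risk_rows = []
        prot_of = m_p.proteins()
        for aid in m_p.assay_ids:
            row = assoc.logistic_assoc(event, m_p.values[aid], covs)
            row["protein"] = prot_of[aid]
            risk_rows.append(row)
        risk = pd.DataFrame(risk_rows).set_index("protein")
        ok = risk["p"].notna()
        risk.loc[ok, "fdr"] = diffexp.bh_adjust(risk.loc[ok, "p"].to_numpy())
        risk_hits = sorted(risk.index[(risk["p"] < cfg.alpha) & ok])
        universe = sorted(set(risk.index))
        fisher = assoc.set_enrichment_fisher(
            set(sdeps.index) & set(universe), risk_hits, universe
        )
        venn = assoc.overlap_venn(
            set(sdeps.index) & set(universe), screen["replicated"], risk_hits
        )
        n_base = len(screen["stage1_hits"])
        n_base_up = len(set(screen["stage1_hits"]) & set(up_ids))
        drivers_found = sorted(set(truth.cvd_driver_ids) & set(risk_hits))
        report["stages"]["cvd"] = {
            "n_baseline_stage1": n_base,
            "n_baseline_replicated": len(screen["replicated"]),
            "pct_baseline_up_in_plhiv": percent_round_half_up(n_base_up, n_base)
            if n_base else None,
            "n_risk_hits": len(risk_hits),
            "sdep_risk_enrichment_p": fisher["p"],
            "sdep_risk_enrichment_or": fisher["odds_ratio"],
            "venn": {k: v for k, v in venn.items() if k != "abc_members"},
            "triple_overlap_members": venn["abc_members"],
            "driver_recall_risk": len(drivers_found) / len(truth.cvd_driver_ids)
            if truth.cvd_driver_ids else None,
        }
        if outdir:
            risk.to_csv(outdir / "cvd_risk_assoc.tsv", sep="\t")
            base_tables["replication"].to_csv(outdir / "cvd_baseline_repl.tsv", sep="\t")
            base_tables["discovery"].to_csv(outdir / "cvd_baseline_disc.tsv", sep="\t")

    if outdir:
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True,
                                                       default=str))
        (outdir / "report.md").write_text(render_report_md(report))
    return report


def render_report_md(report: dict) -> str:
    """Human-readable Markdown view of a run report."""
    lines = [f"# npxtools run report (seed {report['seed']})", ""]
    for stage, payload in report["stages"].items():
        lines.append(f"## {stage}")
        for k, v in payload.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    return "\n".join(lines)
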