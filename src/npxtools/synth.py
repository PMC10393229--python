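"""Synthetic discovery/replication plasma-proteomics cohorts with known truth.

Emulates the structure of a two-cohort Olink-style study of virally
suppressed people living with HIV (PLHIV) versus healthy controls (HC):

* an NPX matrix per cohort with planted, direction-consistent group effects
  on a subset of proteins, covariate (age/sex/smoking) effects, per-assay
  LODs, technical-control proteins duplicated onto every panel, and a few
  global-shift outlier samples;
* per-sample metadata (covariates, comorbidities, CVD outcomes, read counts);
* a tissue/cell specificity map with one planted enriched tissue and a GMT
  gene-set collection with planted pathway sets;
* a compositional microbiome species table with planted protein-species
  links; and
* binary baseline/incident CVD outcomes from a logistic model on designated
  driver proteins plus classical risk factors.

Everything is a deterministic function of ``SynthConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .qc import NPXMatrix

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "MicrobiomeTable",
    "generate_cohort",
    "generate_annotations",
    "generate_microbiome",
    "generate_outcomes",
    "write_synth_outputs",
]

PANELS = ("inflammation", "cardiometabolic", "neurology", "oncology")
CONTROL_PROTEINS = ("IL6", "CXCL8", "TNF")
CONTROL_HOME_PANEL = "inflammation"

TISSUES = (
    "intestine", "lymphoid_tissue", "liver", "brain", "kidney", "lung",
    "pancreas", "skin", "muscle", "heart", "adipose", "stomach", "spleen",
    "thyroid", "salivary_gland", "prostate", "ovary", "testis",
)
CELL_TYPES = (
    "enterocyte", "goblet_cell", "t_cell", "b_cell", "plasma_cell",
    "dendritic_cell", "nk_cell", "langerhans_cell", "endocrine_cell",
    "basal_respiratory_cell", "macrophage", "neutrophil",
)

# themed planted pathway names; overlapping membership among true DEPs makes
# the downstream enrichment map non-trivial
PLANTED_PATHWAY_NAMES = (
    "metabolism of lipids",
    "lipid metabolism pathway",
    "chemokine signaling pathway",
    "cytokine cytokine receptor interaction",
    "antigen processing and presentation",
    "mhc class ii antigen presentation",
)

# classical-risk-factor log-odds used by the CVD outcome model
CVD_RISK_COEFS = {
    "age_per_10y": 0.40,
    "sex_male": 0.30,
    "bmi_per_5": 0.30,
    "smoking": 0.50,
    "dyslipidemia": 0.40,
    "hypertension": 0.40,
    "t2d": 0.40,
}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohorts.

    Cohort sizes are pre-QC counts; outlier samples are planted on top and
    are meant to be removed by PCA sample QC. Effect sizes are on the
    log2-NPX scale.
    """

    n_plhiv_disc: int = 211
    n_hc_disc: int = 122
    n_plhiv_repl: int = 642
    n_hc_repl: int = 100
    n_proteins: int = 1463
    n_true_dep: int = 276
    frac_dep_up: float = 266 / 276
    effect_size_mean: float = 0.6
    effect_size_sd: float = 0.2
    frac_large_effect: float = 16 / 276
    large_effect_mean: float = 1.8
    covariate_effect_scale: float = 0.2
    noise_sd: float = 1.0
    lod_quantile: float = 0.05
    n_low_detect: int = 150
    low_detect_quantile: float = 0.32
    n_panels: int = 4
    n_outlier_plhiv_disc: int = 5
    n_outlier_hc_disc: int = 2
    n_outlier_plhiv_repl: int = 3
    n_outlier_hc_repl: int = 1
    outlier_shift_sd: float = 6.0
    n_fail_count_samples: int = 0
    n_fail_ctrl_samples: int = 0
    n_tissue_categories: int = 18
    n_cell_categories: int = 12
    tissue_enrichment_factor: float = 4.0
    n_planted_gene_sets: int = 6
    n_random_gene_sets: int = 25
    n_species: int = 150
    frac_rare_species: float = 0.15
    n_linked_pairs: int = 150
    link_strength: float = 1.0
    n_cvd_drivers: int = 10
    cvd_base_rate: float = 0.10
    cvd_protein_log_or: float = 1.0986122886681098  # ln 3 per SD of NPX
    seed: int = 0

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not np.isfinite(v):
                raise ValueError(f"non-finite config value: {f.name}={v}")
        if self.n_true_dep > self.n_proteins:
            raise ValueError("n_true_dep exceeds n_proteins")
        for name in ("frac_dep_up", "lod_quantile", "low_detect_quantile",
                     "cvd_base_rate", "frac_rare_species"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.lod_quantile >= 1.0:
            raise ValueError("lod_quantile must be < 1")
        if not 0.0 < self.cvd_base_rate < 1.0 and self.n_cvd_drivers:
            raise ValueError("cvd_base_rate must be strictly inside (0, 1)")
        if self.n_panels < 1 or self.n_panels > len(PANELS):
            raise ValueError(f"n_panels must be in [1, {len(PANELS)}]")
        if self.n_linked_pairs > self.n_species * self.n_proteins:
            raise ValueError("n_linked_pairs exceeds n_species * n_proteins")


@dataclass
class SynthTruth:
    """Planted ground truth shared by both cohorts."""

    true_dep_effects: dict[str, float]  # protein -> signed log2-NPX effect
    planted_tissue: str
    linked_pairs: list[tuple[str, str, int]]  # (protein, species, sign)
    cvd_driver_ids: list[str]
    low_detect_ids: list[str]
    outlier_samples: dict[str, list[str]] = field(default_factory=dict)

    @property
    def true_dep_ids(self) -> list[str]:
        return list(self.true_dep_effects)

    def to_dict(self) -> dict:
        return {
            "true_dep_effects": self.true_dep_effects,
            "planted_tissue": self.planted_tissue,
            "linked_pairs": [list(t) for t in self.linked_pairs],
            "cvd_driver_ids": self.cvd_driver_ids,
            "low_detect_ids": self.low_detect_ids,
            "outlier_samples": self.outlier_samples,
        }


@dataclass
class MicrobiomeTable:
    """Compositional species table: samples x species, rows sum to 1."""

    abundance: pd.DataFrame
    read_counts: pd.Series

    def prevalence(self) -> pd.Series:
        return (self.abundance > 0).mean(axis=0)


# ---------------------------------------------------------------------------
# deterministic RNG streams
# ---------------------------------------------------------------------------

_STREAMS = {"truth": 0, "discovery": 1, "replication": 2, "annotations": 3,
            "microbiome": 4, "outcomes": 5}


def _rng(config: SynthConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % (2**31), _STREAMS[stream]])
    )


def protein_ids(config: SynthConfig) -> list[str]:
    n_named = len(CONTROL_PROTEINS)
    ids = list(CONTROL_PROTEINS[: min(n_named, config.n_proteins)])
    ids += [f"PROT{i:04d}" for i in range(1, config.n_proteins - len(ids) + 1)]
    return ids


def species_ids(config: SynthConfig) -> list[str]:
    return [f"s__species_{i:03d}" for i in range(1, config.n_species + 1)]


# ---------------------------------------------------------------------------
# shared truth
# ---------------------------------------------------------------------------

def make_truth(config: SynthConfig) -> SynthTruth:
    """Draw the planted truth; identical for both cohorts under one seed."""
    config.validate()
    rng = _rng(config, "truth")
    prots = protein_ids(config)
    # controls never carry planted effects: they must stay boring duplicates
    eligible = [p for p in prots if p not in CONTROL_PROTEINS]
    dep_ids = sorted(str(x) for x in rng.choice(eligible, size=config.n_true_dep,
                                                replace=False))
    signs = np.where(rng.random(config.n_true_dep) < config.frac_dep_up, 1.0, -1.0)
    # bulk of effects around effect_size_mean, plus a heavy tail of
    # lipid-transport-like large shifts (a small fraction of DEPs)
    mags = rng.normal(config.effect_size_mean, config.effect_size_sd,
                      config.n_true_dep)
    large = rng.random(config.n_true_dep) < config.frac_large_effect
    mags[large] = rng.normal(config.large_effect_mean, config.effect_size_sd,
                             int(large.sum()))
    mags = np.abs(mags)
    mags = np.maximum(mags, 0.05 * abs(config.effect_size_mean)) if config.effect_size_mean else mags
    effects = {p: float(s * m) for p, s, m in zip(dep_ids, signs, mags)}

    non_dep = [p for p in eligible if p not in effects]
    n_low = min(config.n_low_detect, len(non_dep))
    low_detect = sorted(rng.choice(non_dep, size=n_low, replace=False)) if n_low else []

    spp = species_ids(config)
    n_links = min(config.n_linked_pairs, len(dep_ids) * max(len(spp), 1))
    linked: list[tuple[str, str, int]] = []
    if n_links and spp and dep_ids:
        # concentrate links on small pools of proteins and species so the
        # gut-specific protein group shows a clear excess of associations
        n_ppool = max(1, min(len(dep_ids), round(np.sqrt(n_links / 2.0)) or 1))
        n_spool = max(1, min(len(spp), -(-n_links // n_ppool)))
        while n_ppool * n_spool < n_links and n_ppool < len(dep_ids):
            n_ppool += 1
        prot_pool = sorted(rng.choice(dep_ids, size=n_ppool, replace=False))
        sp_pool = sorted(rng.choice(spp, size=n_spool, replace=False))
        # each species is globally enriched or depleted: one sign per species
        sp_sign = {s: int(g) for s, g in
                   zip(sp_pool, rng.choice([-1, 1], size=len(sp_pool), p=[0.3, 0.7]))}
        pairs = [(p, s) for p in prot_pool for s in sp_pool]
        take = rng.choice(len(pairs), size=n_links, replace=False)
        linked = [(pairs[i][0], pairs[i][1], sp_sign[pairs[i][1]])
                  for i in sorted(take)]

    n_drv = min(config.n_cvd_drivers, len(dep_ids))
    drivers = sorted(rng.choice(dep_ids, size=n_drv, replace=False)) if n_drv else []
    return SynthTruth(
        true_dep_effects=effects,
        planted_tissue="intestine",
        linked_pairs=linked,
        cvd_driver_ids=[str(d) for d in drivers],
        low_detect_ids=[str(x) for x in low_detect],
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _sample_covariates(rng, n_plhiv, n_hc, prefix):
    """Covariate marginals mirror the real cohorts so adjustment matters:
    PLHIV are older, more often male, and more often smokers than HCs."""
    ids = [f"{prefix}_P{i:04d}" for i in range(1, n_plhiv + 1)]
    ids += [f"{prefix}_H{i:04d}" for i in range(1, n_hc + 1)]
    group = np.array(["PLHIV"] * n_plhiv + ["HC"] * n_hc)
    age = np.where(
        group == "PLHIV", rng.uniform(35, 70, n_plhiv + n_hc), rng.uniform(25, 60, n_plhiv + n_hc)
    )
    sex_p = np.where(group == "PLHIV", 0.8, 0.65)
    sex = (rng.random(n_plhiv + n_hc) < sex_p).astype(int)
    smoke_p = np.where(group == "PLHIV", 0.30, 0.13)
    smoking = (rng.random(n_plhiv + n_hc) < smoke_p).astype(int)
    bmi = rng.normal(25.0, 4.0, n_plhiv + n_hc).clip(16, 45)
    tbl = pd.DataFrame(
        {
            "group": group,
            "age": np.round(age, 1),
            "sex": sex,
            "smoking": smoking,
            "bmi": np.round(bmi, 1),
            "dyslipidemia": (rng.random(n_plhiv + n_hc) < 0.25).astype(int),
            "hypertension": (rng.random(n_plhiv + n_hc) < 0.20).astype(int),
            "t2d": (rng.random(n_plhiv + n_hc) < 0.06).astype(int),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return tbl


def generate_cohort(
    config: SynthConfig, cohort: str = "discovery"
) -> tuple[NPXMatrix, pd.DataFrame, SynthTruth]:
    """Generate one cohort's NPX matrix, sample table, and the shared truth.

    NPX = per-protein baseline + group effect (true DEPs, PLHIV only)
    + age/sex/smoking effects + Gaussian noise. Outlier samples get a global
    additive shift of ``outlier_shift_sd * noise_sd`` on every assay.
    Per-assay LOD sits at ``lod_quantile`` of the HC distribution, except for
    the designated low-detection proteins whose LOD sits at
    ``low_detect_quantile`` of all samples (these exercise the below-LOD
    protein filter). Control proteins are duplicated onto every panel with
    tightly correlated copies.
    """
    if cohort not in ("discovery", "replication"):
        raise ValueError(f"unknown cohort {cohort!r}")
    config.validate()
    truth = make_truth(config)
    rng = _rng(config, cohort)
    if cohort == "discovery":
        n_plhiv, n_hc = config.n_plhiv_disc, config.n_hc_disc
        n_out_p, n_out_h = config.n_outlier_plhiv_disc, config.n_outlier_hc_disc
        prefix = "D"
    else:
        n_plhiv, n_hc = config.n_plhiv_repl, config.n_hc_repl
        n_out_p, n_out_h = config.n_outlier_plhiv_repl, config.n_outlier_hc_repl
        prefix = "R"

    samples = _sample_covariates(rng, n_plhiv, n_hc, prefix)
    samples["cohort"] = cohort
    n = len(samples)
    prots = protein_ids(config)
    p = len(prots)

    # protein-level parameters are drawn from the truth stream so baselines
    # and covariate coefficients agree across cohorts
    trng = _rng(config, "truth")
    trng.bit_generator.advance(10**6)  # past the draws consumed by make_truth
    baseline = trng.normal(3.0, 1.5, p)
    beta_age = trng.normal(0.0, config.covariate_effect_scale, p)   # per decade
    beta_sex = trng.normal(0.0, config.covariate_effect_scale, p)
    beta_smk = trng.normal(0.0, config.covariate_effect_scale, p)

    effect = np.array([truth.true_dep_effects.get(pr, 0.0) for pr in prots])
    is_plhiv = (samples["group"] == "PLHIV").to_numpy(dtype=float)
    age_c = ((samples["age"] - 45.0) / 10.0).to_numpy()
    X = (
        baseline[None, :]
        + np.outer(is_plhiv, effect)
        + np.outer(age_c, beta_age)
        + np.outer(samples["sex"].to_numpy(), beta_sex)
        + np.outer(samples["smoking"].to_numpy(), beta_smk)
        + rng.normal(0.0, config.noise_sd, (n, p))
    )

    # planted outlier samples: global additive shift on every assay
    plhiv_ids = list(samples.index[samples["group"] == "PLHIV"])
    hc_ids = list(samples.index[samples["group"] == "HC"])
    out_ids = []
    if n_out_p:
        out_ids += list(rng.choice(plhiv_ids, size=min(n_out_p, len(plhiv_ids)), replace=False))
    if n_out_h:
        out_ids += list(rng.choice(hc_ids, size=min(n_out_h, len(hc_ids)), replace=False))
    out_ids = [str(s) for s in out_ids]
    shift = config.outlier_shift_sd * config.noise_sd
    pos = samples.index.get_indexer(out_ids)
    X[pos, :] += shift
    truth.outlier_samples[cohort] = out_ids

    values = pd.DataFrame(X, index=samples.index, columns=prots)

    # per-assay LOD: quantile of the HC (null) distribution when HCs exist
    hc_mask = samples["group"] == "HC"
    ref = values.loc[hc_mask] if hc_mask.any() else values
    lod = ref.quantile(config.lod_quantile, axis=0)
    if truth.low_detect_ids:
        lod_low = values[truth.low_detect_ids].quantile(config.low_detect_quantile, axis=0)
        lod.loc[truth.low_detect_ids] = lod_low

    # assay table: every protein on its home panel; controls duplicated
    panels = [PANELS[i % config.n_panels] for i in range(p)]
    home_panel = dict(zip(prots, panels))
    for c in CONTROL_PROTEINS:
        if c in home_panel:
            home_panel[c] = CONTROL_HOME_PANEL
    assay_values = {}
    meta_rows = []
    for pr in prots:
        aid = f"{pr}@{home_panel[pr]}"
        assay_values[aid] = values[pr]
        meta_rows.append({"assay_id": aid, "protein": pr, "panel": home_panel[pr],
                          "lod": float(lod[pr])})
    for c in CONTROL_PROTEINS:
        if c not in values.columns:
            continue
        for panel in PANELS[: config.n_panels]:
            if panel == home_panel[c]:
                continue
            aid = f"{c}@{panel}"
            assay_values[aid] = values[c] + rng.normal(0.0, 0.15, n)
            meta_rows.append({"assay_id": aid, "protein": c, "panel": panel,
                              "lod": float(lod[c])})
    vdf = pd.DataFrame(assay_values, index=samples.index)
    meta = pd.DataFrame(meta_rows).set_index("assay_id").loc[vdf.columns]

    # vendor sample-QC columns; optionally plant failures
    mean_count = rng.normal(800.0, 80.0, n).clip(520, None)
    ctrl_dev = rng.normal(0.0, 0.08, n).clip(-0.29, 0.29)
    passing = [s for s in samples.index if s not in out_ids]
    if config.n_fail_count_samples:
        bad = rng.choice(passing, size=config.n_fail_count_samples, replace=False)
        mean_count[samples.index.get_indexer(bad)] = rng.uniform(100, 499, len(bad))
    if config.n_fail_ctrl_samples:
        bad = rng.choice(passing, size=config.n_fail_ctrl_samples, replace=False)
        ctrl_dev[samples.index.get_indexer(bad)] = rng.choice([-1, 1], len(bad)) * rng.uniform(
            0.35, 0.8, len(bad)
        )
    sample_qc = pd.DataFrame(
        {"mean_count": np.round(mean_count, 1), "ctrl_dev": np.round(ctrl_dev, 4)},
        index=samples.index,
    )

    m = NPXMatrix(vdf, meta, sample_qc)
    return m, samples, truth


# ---------------------------------------------------------------------------
# annotations: specificity map + gene sets
# ---------------------------------------------------------------------------

def generate_annotations(
    config: SynthConfig, truth: SynthTruth
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Tissue/cell specificity map and GMT-style gene-set collection.

    Every protein receives 0-2 categories. The planted tissue's draw weight
    is multiplied by ``tissue_enrichment_factor`` for true DEPs, and proteins
    carrying planted microbiome links always receive the planted tissue (so
    the intestine-specific protein group is well populated). Gene sets:
    several planted, overlapping sets concentrated in true DEPs plus random
    sets.

    Returns (category map DataFrame with columns gene_id/category_type/
    category, gene-set dict name -> {"description": str, "members": set}).
    """
    config.validate()
    prots = protein_ids(config)
    if not prots:
        raise ValueError("empty protein universe")
    rng = _rng(config, "annotations")
    tissues = list(TISSUES[: config.n_tissue_categories])
    cells = list(CELL_TYPES[: config.n_cell_categories])
    if truth.planted_tissue not in tissues:
        tissues = [truth.planted_tissue] + tissues[:-1]
    dep_set = set(truth.true_dep_ids)
    linked_prots = {p for p, _, _ in truth.linked_pairs}

    rows = []
    n_cat_choices = rng.choice([0, 1, 2], size=len(prots), p=[0.30, 0.50, 0.20])
    for prot, n_cat in zip(prots, n_cat_choices):
        cats: set[tuple[str, str]] = set()
        if prot in linked_prots:
            cats.add(("tissue", truth.planted_tissue))
        while len(cats) < n_cat:
            if rng.random() < 0.6:
                w = np.ones(len(tissues))
                if prot in dep_set and config.tissue_enrichment_factor != 1.0:
                    w[tissues.index(truth.planted_tissue)] *= config.tissue_enrichment_factor
                cat = ("tissue", str(rng.choice(tissues, p=w / w.sum())))
            else:
                cat = ("cell", str(rng.choice(cells)))
            cats.add(cat)
        for ctype, cname in sorted(cats):
            rows.append({"gene_id": prot, "category_type": ctype, "category": cname})
    cmap = pd.DataFrame(rows, columns=["gene_id", "category_type", "category"])

    gene_sets: dict[str, dict] = {}
    dep_list = sorted(dep_set)
    other = [p for p in prots if p not in dep_set]
    # planted sets come in themes (lipid / chemokine / antigen): sets within a
    # theme draw from one small DEP pool, so themed sets overlap strongly and
    # the enrichment map develops real cluster structure
    n_themes = max(1, min(3, len(dep_list) and config.n_planted_gene_sets))
    n_themes = min(3, n_themes)
    pool_size = min(36, max(4, len(dep_list) // max(n_themes, 1)))
    shuffled = list(rng.permutation(dep_list))
    theme_pools = [shuffled[t * pool_size : (t + 1) * pool_size] for t in range(n_themes)]
    for i in range(config.n_planted_gene_sets):
        name = PLANTED_PATHWAY_NAMES[i % len(PLANTED_PATHWAY_NAMES)]
        if name in gene_sets:
            name = f"{name} {i}"
        pool = theme_pools[(i // 2) % n_themes] or dep_list
        size = min(int(rng.integers(25, 41)), max(4, len(dep_list)))
        n_dep = min(int(round(size * 0.85)), len(pool))
        members = set(rng.choice(pool, size=n_dep, replace=False))
        if other and size > len(members):
            members |= set(rng.choice(other, size=size - len(members), replace=False))
        gene_sets[name] = {"description": "planted synthetic pathway", "members": members}
    for i in range(config.n_random_gene_sets):
        size = min(int(rng.integers(10, 80)), len(prots))
        members = set(rng.choice(prots, size=size, replace=False))
        gene_sets[f"random pathway {i+1:02d}"] = {
            "description": "random synthetic pathway",
            "members": members,
        }
    return cmap, gene_sets


# ---------------------------------------------------------------------------
# microbiome
# ---------------------------------------------------------------------------

def generate_microbiome(
    config: SynthConfig, npx: NPXMatrix, truth: SynthTruth
) -> MicrobiomeTable:
    """Compositional species abundances for the samples of ``npx``.

    Species log-abundances are Gaussian; planted (protein, species, sign)
    links add ``link_strength * sign * z(NPX)`` to the species' log
    abundance, inducing the planted correlation. Structural zeros are
    injected by Bernoulli thinning (a ``frac_rare_species`` subset of
    species gets presence probability ~ U(0.05, 0.15), falling below the 20%
    prevalence filter) before closure to row sums of 1.
    """
    config.validate()
    rng = _rng(config, "microbiome")
    spp = species_ids(config)
    sample_ids = npx.sample_ids
    n, s = len(sample_ids), len(spp)
    mu = rng.normal(-2.0, 1.0, s)
    logab = mu[None, :] + rng.normal(0.0, 1.0, (n, s))

    prot_by_assay = npx.proteins()
    assay_of = {pr: aid for aid, pr in prot_by_assay.items()}
    for prot, sp, sign in truth.linked_pairs:
        if sp not in spp or prot not in assay_of:
            continue
        x = npx.values[assay_of[prot]].to_numpy()
        z = (x - x.mean()) / (x.std(ddof=0) or 1.0)
        logab[:, spp.index(sp)] += config.link_strength * sign * z

    presence_p = rng.uniform(0.5, 1.0, s)
    n_rare = int(round(config.frac_rare_species * s))
    if n_rare:
        rare_idx = rng.choice(s, size=n_rare, replace=False)
        presence_p[rare_idx] = rng.uniform(0.05, 0.15, n_rare)
    # linked species are detectable by construction: they would not have
    # survived the prevalence filter otherwise
    linked_sp = {sp for _, sp, _ in truth.linked_pairs}
    for j, sp in enumerate(spp):
        if sp in linked_sp:
            presence_p[j] = max(presence_p[j], 0.9)
    present = rng.random((n, s)) < presence_p[None, :]
    raw = np.where(present, np.exp(logab), 0.0)
    rowsum = raw.sum(axis=1)
    # guard: a sample with nothing present gets the most common species
    empty = rowsum == 0
    if empty.any():
        raw[empty, int(np.argmax(presence_p))] = 1.0
        rowsum = raw.sum(axis=1)
    rel = raw / rowsum[:, None]
    abundance = pd.DataFrame(rel, index=pd.Index(sample_ids, name="sample_id"), columns=spp)
    read_counts = pd.Series(
        np.round(np.exp(rng.normal(np.log(2e7), 0.3, n))).astype(np.int64),
        index=abundance.index,
        name="read_count",
    )
    return MicrobiomeTable(abundance, read_counts)


# ---------------------------------------------------------------------------
# CVD outcomes
# ---------------------------------------------------------------------------

def _tuned_intercept(lp: np.ndarray, rate: float) -> float:
    """Intercept such that the mean event probability equals ``rate``."""
    f = lambda b0: expit(b0 + lp).mean() - rate
    lo, hi = -30.0, 30.0
    return float(brentq(f, lo, hi, xtol=1e-10))


def generate_outcomes(
    config: SynthConfig,
    npx: NPXMatrix,
    samples: pd.DataFrame,
    truth: SynthTruth,
) -> pd.DataFrame:
    """Attach baseline and incident CVD outcomes drawn from logistic models.

    The linear predictor combines classical risk factors (fixed coefficients
    in :data:`CVD_RISK_COEFS`) with ``cvd_protein_log_or`` per SD of NPX for
    each driver protein; the intercept is tuned so the expected event rate
    equals ``cvd_base_rate``. Baseline and incident outcomes are independent
    draws from the same mechanism. Returns a copy of ``samples`` with
    ``cvd_baseline`` and ``cvd_incident`` columns (incident only defined for
    PLHIV; NaN for HC, mirroring follow-up of the HIV group only).
    """
    config.validate()
    if not 0.0 < config.cvd_base_rate < 1.0:
        raise ValueError("cvd_base_rate must be strictly between 0 and 1")
    if list(npx.sample_ids) != list(samples.index):
        samples = samples.loc[npx.sample_ids]
    rng = _rng(config, "outcomes")
    out = samples.copy()

    lp = (
        CVD_RISK_COEFS["age_per_10y"] * (out["age"] - 50.0) / 10.0
        + CVD_RISK_COEFS["sex_male"] * out["sex"]
        + CVD_RISK_COEFS["bmi_per_5"] * (out["bmi"] - 25.0) / 5.0
        + CVD_RISK_COEFS["smoking"] * out["smoking"]
        + CVD_RISK_COEFS["dyslipidemia"] * out["dyslipidemia"]
        + CVD_RISK_COEFS["hypertension"] * out["hypertension"]
        + CVD_RISK_COEFS["t2d"] * out["t2d"]
    ).to_numpy(dtype=float)

    assay_of = {pr: aid for aid, pr in npx.proteins().items()}
    for prot in truth.cvd_driver_ids:
        if prot not in assay_of:
            continue
        x = npx.values[assay_of[prot]].to_numpy()
        z = (x - x.mean()) / (x.std(ddof=0) or 1.0)
        lp = lp + config.cvd_protein_log_or * z

    b0 = _tuned_intercept(lp, config.cvd_base_rate)
    prob = expit(b0 + lp)
    out["cvd_baseline"] = (rng.random(len(out)) < prob).astype(int)
    incident = (rng.random(len(out)) < prob).astype(float)
    incident[(out["group"] != "PLHIV").to_numpy()] = np.nan
    out["cvd_incident"] = incident
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_synth_outputs(outdir, config: SynthConfig) -> dict[str, str]:
    """Generate and write the full set of synthetic inputs to ``outdir``.

    Writes NPX long CSVs, sample metadata TSVs, the category map TSV, the
    gene-set GMT, the microbiome TSV with read counts, and the truth JSON.
    Returns a name -> path map.
    """
    from pathlib import Path

    from .enrich import write_gmt
    from .qc import write_npx_long

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    truth = make_truth(config)
    for cohort in ("discovery", "replication"):
        m, samples, truth = generate_cohort(config, cohort)
        samples = generate_outcomes(config, m, samples, truth)
        npx_path = outdir / f"npx_{cohort}.csv"
        write_npx_long(m, npx_path)
        meta_path = outdir / f"samples_{cohort}.tsv"
        samples.to_csv(meta_path, sep="\t")
        paths[f"npx_{cohort}"] = str(npx_path)
        paths[f"samples_{cohort}"] = str(meta_path)
        if cohort == "discovery":
            micro = generate_microbiome(config, m, truth)
            mpath = outdir / "microbiome_discovery.tsv"
            micro.abundance.T.to_csv(mpath, sep="\t")  # species x sample on disk
            rpath = outdir / "read_counts_discovery.tsv"
            micro.read_counts.to_csv(rpath, sep="\t")
            paths["microbiome_discovery"] = str(mpath)
            paths["read_counts_discovery"] = str(rpath)
    cmap, gene_sets = generate_annotations(config, truth)
    cpath = outdir / "category_map.tsv"
    cmap.to_csv(cpath, sep="\t", index=False)
    gpath = outdir / "gene_sets.gmt"
    write_gmt(gene_sets, gpath)
    tpath = outdir / "truth.json"
    tpath.write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))
    paths.update(category_map=str(cpath), gene_sets=str(gpath), truth=str(tpath))
    return paths
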