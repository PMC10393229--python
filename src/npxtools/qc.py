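"""Quality control of NPX-style proximity-extension-assay data.

Olink-style panels report relative protein abundance as NPX (Normalized
Protein eXpression), a log2-scale unit with a per-assay limit of detection
(LOD). Values below LOD are extrapolated and *reported*, never masked; QC
therefore operates on below-LOD fractions rather than on missingness.

The module covers assay deduplication (technical-control proteins measured
on every panel), vendor-style sample QC (mean assay counts and control
deviation), two flavours of below-LOD protein filtering, PCA-based sample
outlier detection, and intra/inter-plate coefficient-of-variation summaries.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NPXMatrix",
    "QCReport",
    "read_npx_long",
    "write_npx_long",
    "dedup_control_assays",
    "sample_qc_controls",
    "protein_qc_two_group",
    "protein_qc_single_group",
    "pca_outliers",
    "plate_cv",
]

REQUIRED_LONG_COLUMNS = ("sample_id", "assay_id", "protein", "panel", "npx", "lod")
OPTIONAL_SAMPLE_COLUMNS = ("mean_count", "ctrl_dev")


@dataclass
class NPXMatrix:
    """Samples x assays matrix of log2-scale NPX values.

    ``values``: DataFrame indexed by sample id, columns are assay ids.
    ``assay_meta``: DataFrame indexed by assay id with columns
    ``protein`` (gene symbol), ``panel``, ``lod`` (log2-NPX units).
    ``sample_qc``: optional per-sample vendor QC columns
    (``mean_count``, ``ctrl_dev``).
    """

    values: pd.DataFrame
    assay_meta: pd.DataFrame
    sample_qc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.assay_meta.index):
            self.assay_meta = self.assay_meta.loc[list(self.values.columns)]
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("NPX values must be finite")
        if self.assay_meta["lod"].isna().any():
            missing = self.assay_meta.index[self.assay_meta["lod"].isna()].tolist()
            raise ValueError(f"assays missing LOD: {missing[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_assays(self) -> int:
        return self.values.shape[1]

    def proteins(self) -> pd.Series:
        """Assay id -> protein symbol."""
        return self.assay_meta["protein"]

    def below_lod(self) -> pd.DataFrame:
        """Boolean samples x assays mask, strict ``npx < lod``."""
        lod = self.assay_meta["lod"].to_numpy()
        return pd.DataFrame(
            self.values.to_numpy() < lod[None, :],
            index=self.values.index,
            columns=self.values.columns,
        )

    def subset_samples(self, sample_ids) -> "NPXMatrix":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        sq = self.sample_qc.loc[keep] if self.sample_qc is not None else None
        return NPXMatrix(self.values.loc[keep], self.assay_meta.copy(), sq)

    def subset_assays(self, assay_ids) -> "NPXMatrix":
        keep = [a for a in self.assay_ids if a in set(assay_ids)]
        return NPXMatrix(
            self.values[keep], self.assay_meta.loc[keep], self.sample_qc
        )

    def to_long(self) -> pd.DataFrame:
        long = self.values.stack().rename("npx").reset_index()
        long.columns = ["sample_id", "assay_id", "npx"]
        meta = self.assay_meta.reset_index(names="assay_id")
        long = long.merge(meta, on="assay_id", how="left")
        if self.sample_qc is not None:
            long = long.merge(
                self.sample_qc.reset_index(names="sample_id"), on="sample_id", how="left"
            )
        cols = [c for c in REQUIRED_LONG_COLUMNS + OPTIONAL_SAMPLE_COLUMNS if c in long]
        return long[cols]


@dataclass
class QCReport:
    """Bookkeeping of every QC decision; kept + dropped = input at each step."""

    steps: list[dict] = field(default_factory=list)
    dropped_samples: list[dict] = field(default_factory=list)
    dropped_assays: list[dict] = field(default_factory=list)

    def record_step(self, name: str, n_in: int, n_out: int, unit: str) -> None:
        if n_out > n_in:
            raise ValueError(f"step {name}: output exceeds input")
        self.steps.append(
            {"step": name, "unit": unit, "n_in": n_in, "n_out": n_out, "n_dropped": n_in - n_out}
        )

    def drop_sample(self, sample_id: str, reason: str, **extra) -> None:
        self.dropped_samples.append({"sample_id": sample_id, "reason": reason, **extra})

    def drop_assay(self, assay_id: str, reason: str, **extra) -> None:
        self.dropped_assays.append({"assay_id": assay_id, "reason": reason, **extra})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_npx_long(path) -> NPXMatrix:
    """Read a long-format NPX CSV and pivot it to an :class:`NPXMatrix`.

    Required columns: sample_id, assay_id, protein, panel, npx, lod.
    Optional per-sample QC columns: mean_count, ctrl_dev.
    Duplicated (sample, assay) rows and missing cells are errors: panels are
    assumed complete (every sample measured on every assay).
    """
    long = pd.read_csv(path)
    missing = [c for c in REQUIRED_LONG_COLUMNS if c not in long.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    dup = long.duplicated(["sample_id", "assay_id"])
    if dup.any():
        first = long.loc[dup, ["sample_id", "assay_id"]].iloc[0]
        raise ValueError(
            f"duplicated (sample, assay) pair: ({first['sample_id']}, {first['assay_id']})"
        )
    if not pd.api.types.is_numeric_dtype(long["npx"]):
        raise ValueError("non-numeric NPX values")
    values = long.pivot(index="sample_id", columns="assay_id", values="npx")
    if values.isna().any().any():
        raise ValueError("missing (sample, assay) cells: panel completeness assumed")
    meta = long.drop_duplicates("assay_id").set_index("assay_id")[["protein", "panel", "lod"]]
    meta = meta.loc[values.columns]
    sample_qc = None
    present = [c for c in OPTIONAL_SAMPLE_COLUMNS if c in long.columns]
    if present:
        sample_qc = long.drop_duplicates("sample_id").set_index("sample_id")[present]
        sample_qc = sample_qc.loc[values.index]
    return NPXMatrix(values, meta, sample_qc)


def write_npx_long(m: NPXMatrix, path) -> None:
    m.to_long().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Assay deduplication
# ---------------------------------------------------------------------------

def dedup_control_assays(
    m: NPXMatrix, control_proteins, keep_panel: str
) -> tuple[NPXMatrix, pd.DataFrame]:
    """Collapse technical-control proteins measured on multiple panels.

    For each protein in ``control_proteins`` only the ``keep_panel`` assay is
    retained; all other assays are untouched. Returns the deduplicated matrix
    and a table of removed duplicates with the cross-panel Spearman
    correlation of each removed copy against the kept copy.
    """
    meta = m.assay_meta
    removed_rows = []
    drop_assays: list[str] = []
    for prot in control_proteins:
        assays = meta.index[meta["protein"] == prot]
        if len(assays) == 0:
            continue
        kept = [a for a in assays if meta.loc[a, "panel"] == keep_panel]
        if not kept:
            raise ValueError(f"control protein {prot!r} absent from panel {keep_panel!r}")
        kept_assay = kept[0]
        for a in assays:
            if a == kept_assay:
                continue
            rho = stats.spearmanr(m.values[kept_assay], m.values[a]).statistic
            removed_rows.append(
                {
                    "protein": prot,
                    "removed_assay": a,
                    "removed_panel": meta.loc[a, "panel"],
                    "kept_assay": kept_assay,
                    "spearman_r": float(rho),
                }
            )
            drop_assays.append(a)
    keep = [a for a in m.assay_ids if a not in set(drop_assays)]
    report = pd.DataFrame(
        removed_rows,
        columns=["protein", "removed_assay", "removed_panel", "kept_assay", "spearman_r"],
    )
    return m.subset_assays(keep), report


# ---------------------------------------------------------------------------
# Sample-level QC
# ---------------------------------------------------------------------------

def sample_qc_controls(
    m: NPXMatrix, mean_count_min: float = 500.0, control_dev_max: float = 0.3
) -> tuple[NPXMatrix, QCReport]:
    """Vendor-style sample QC on assay counts and control deviation.

    A sample passes with mean assay count >= ``mean_count_min`` (inclusive,
    "at least") and |control deviation| <= ``control_dev_max`` (inclusive,
    "within"). Requires the per-sample QC columns; their absence is an
    explicit error rather than a silent skip.
    """
    if m.sample_qc is None:
        raise ValueError("sample QC columns (mean_count, ctrl_dev) not available")
    report = QCReport()
    keep = []
    for sid, row in m.sample_qc.iterrows():
        if row["mean_count"] < mean_count_min:
            report.drop_sample(sid, "low_counts", mean_count=float(row["mean_count"]))
        elif abs(row["ctrl_dev"]) > control_dev_max:
            report.drop_sample(sid, "control_deviation", ctrl_dev=float(row["ctrl_dev"]))
        else:
            keep.append(sid)
    report.record_step("sample_qc_controls", m.n_samples, len(keep), "samples")
    return m.subset_samples(keep), report


# ---------------------------------------------------------------------------
# Protein-level QC
# ---------------------------------------------------------------------------

def _below_lod_fractions(m: NPXMatrix, sample_ids) -> pd.Series:
    sub = m.below_lod().loc[list(sample_ids)]
    return sub.mean(axis=0)


def protein_qc_two_group(
    m: NPXMatrix,
    groups: pd.Series,
    below_frac: float = 0.25,
    diff_frac: float = 0.20,
) -> tuple[list[str], list[str]]:
    """Two-group below-LOD filter used ahead of differential expression.

    An assay is dropped iff its below-LOD sample fraction exceeds
    ``below_frac`` in *both* groups AND the two fractions differ by less
    than ``diff_frac`` (a large between-group difference in detectability is
    itself a group signal and is retained). Below-LOD uses strict
    ``npx < lod``; "greater than 25%" is strict, "less than 20%" is strict.
    """
    groups = groups.loc[m.sample_ids]
    labels = groups.unique()
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(labels)}")
    ids_a = groups.index[groups == labels[0]]
    ids_b = groups.index[groups == labels[1]]
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError("both groups must be non-empty")
    frac_a = _below_lod_fractions(m, ids_a)
    frac_b = _below_lod_fractions(m, ids_b)
    drop_mask = (
        (frac_a > below_frac) & (frac_b > below_frac) & ((frac_a - frac_b).abs() < diff_frac)
    )
    dropped = list(m.values.columns[drop_mask])
    kept = list(m.values.columns[~drop_mask])
    return kept, dropped


def protein_qc_single_group(
    m: NPXMatrix, below_frac: float = 0.25
) -> tuple[list[str], list[str]]:
    """Single-group below-LOD filter (association analyses within one group).

    Drops an assay iff strictly more than ``below_frac`` of samples fall
    below its LOD.
    """
    if m.n_samples == 0:
        raise ValueError("empty matrix")
    frac = _below_lod_fractions(m, m.sample_ids)
    drop_mask = frac > below_frac
    return list(m.values.columns[~drop_mask]), list(m.values.columns[drop_mask])


# ---------------------------------------------------------------------------
# PCA outliers
# ---------------------------------------------------------------------------

def pca_scores(m: NPXMatrix, n_components: int = 2, scale: bool = True):
    """Per-protein centred (and optionally unit-scaled) PCA over samples.

    Returns (scores DataFrame with PC1..PCk, explained variance fractions,
    list of zero-variance assays dropped before the decomposition).
    """
    from sklearn.decomposition import PCA

    X = m.values.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    constant = sd == 0
    dropped = list(m.values.columns[constant])
    X = X[:, ~constant]
    if X.shape[1] < n_components or X.shape[0] < n_components:
        # degenerate: no usable variation
        scores = pd.DataFrame(
            np.zeros((m.n_samples, n_components)),
            index=m.values.index,
            columns=[f"PC{i+1}" for i in range(n_components)],
        )
        return scores, np.zeros(n_components), dropped
    X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0, ddof=1)
    pca = PCA(n_components=n_components, svd_solver="full")
    Z = pca.fit_transform(X)
    scores = pd.DataFrame(
        Z, index=m.values.index, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    return scores, pca.explained_variance_ratio_, dropped


def pca_outliers(
    m: NPXMatrix, k_sd: float = 3.0, scale: bool = True
) -> tuple[list[str], pd.DataFrame]:
    """Flag samples more than ``k_sd`` SDs from the mean of PC1 and/or PC2.

    Single pass (no re-fitting after exclusion). The flag decision is
    invariant to PC sign flips since it depends only on |score - mean|.
    """
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples for PCA outlier detection")
    if m.n_assays < 2:
        raise ValueError("need at least 2 assays for PCA outlier detection")
    scores, _, _ = pca_scores(m, n_components=2, scale=scale)
    flagged: set[str] = set()
    for pc in ("PC1", "PC2"):
        s = scores[pc]
        sd = s.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            continue
        dev = (s - s.mean()).abs()
        flagged.update(s.index[dev > k_sd * sd])
    ordered = [s for s in m.sample_ids if s in flagged]
    return ordered, scores


# ---------------------------------------------------------------------------
# Plate CVs
# ---------------------------------------------------------------------------

def plate_cv(
    control_values: pd.DataFrame,
    intra_max: float = 15.0,
    inter_max: float = 30.0,
    linearize: bool = True,
) -> dict:
    """Intra- and inter-plate coefficients of variation for control assays.

    ``control_values`` has columns ``plate`` and ``value`` (NPX). CVs are
    computed on the linear scale (2**NPX) unless ``linearize=False``:
    CV% = 100 * SD / mean. Intra-plate CV is the mean of within-plate CVs
    (plates with >= 2 replicates); inter-plate CV is the CV of plate means
    (requires >= 2 plates, otherwise reported missing).
    """
    df = control_values.copy()
    df["lin"] = np.power(2.0, df["value"]) if linearize else df["value"]

    def _cv(x: np.ndarray) -> float:
        return float(100.0 * np.std(x, ddof=1) / np.mean(x))

    within = [
        _cv(g["lin"].to_numpy()) for _, g in df.groupby("plate") if len(g) >= 2
    ]
    intra = float(np.mean(within)) if within else float("nan")
    plate_means = df.groupby("plate")["lin"].mean()
    inter = _cv(plate_means.to_numpy()) if len(plate_means) >= 2 else float("nan")
    return {
        "intra_cv_pct": intra,
        "inter_cv_pct": inter,
        "intra_pass": bool(intra <= intra_max) if np.isfinite(intra) else None,
        "inter_pass": bool(inter <= inter_max) if np.isfinite(inter) else None,
    }
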