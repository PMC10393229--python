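"""Per-protein association engines and derived analyses.

The generic building blocks are covariate-adjusted linear regression
(protein vs immune-cell proportions, inflammation markers, baseline CVD,
CLR-transformed microbial species), binomial logistic regression for
incident CVD (odds ratio per SD of NPX by default), and partial Spearman
correlation for HIV clinical parameters. On top sit the derived analyses:
the centered log-ratio transform and prevalence filter for compositional
microbiome data, the group-wise comparison of significant-association
proportions (pairwise chi-square), Fisher set-enrichment of protein sets,
the two-stage discovery->replication CVD screen, and three-set overlap
counts. FDR is always applied within one analysis family, never pooled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust

__all__ = [
    "linear_assoc",
    "bulk_linear_assoc",
    "logistic_assoc",
    "partial_spearman",
    "clr_transform",
    "prevalence_filter",
    "protein_groups",
    "proportion_significant_comparison",
    "set_enrichment_fisher",
    "two_stage_cvd_screen",
    "overlap_venn",
]


def _complete_cases(*arrays) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        a = np.asarray(a, dtype=float)
        mask &= np.isfinite(a) if a.ndim == 1 else np.isfinite(a).all(axis=1)
    return mask


def _covariate_matrix(covariates, index) -> np.ndarray:
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        return np.ones((len(index), 1))
    C = pd.DataFrame(covariates).loc[index].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(index)), C])


def linear_assoc(y, x, covariates=None) -> dict:
    """OLS of ``y`` on ``x`` plus covariates; Wald test for the x slope.

    Returns beta, se, 95% CI, t, p, n_used. Complete cases only.
    """
    y = pd.Series(y, dtype=float)
    x = pd.Series(x, dtype=float).loc[y.index]
    C = None if covariates is None else pd.DataFrame(covariates).loc[y.index]
    arrays = [y.to_numpy(), x.to_numpy()] + ([] if C is None else [C.to_numpy(dtype=float)])
    mask = _complete_cases(*arrays)
    idx = y.index[mask]
    k_cov = 0 if C is None else C.shape[1]
    if mask.sum() < k_cov + 3:
        raise ValueError("too few complete cases")
    Cm = _covariate_matrix(C, idx)
    X = np.column_stack([Cm, x.loc[idx].to_numpy()])
    yy = y.loc[idx].to_numpy()
    beta, res, rank, _ = np.linalg.lstsq(X, yy, rcond=None)
    resid = yy - X @ beta
    df = len(idx) - X.shape[1]
    s2 = float(resid @ resid) / df if df > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(s2 * xtx_inv[-1, -1]))
    b = float(beta[-1])
    t = b / se if se > 0 else np.sign(b) * np.inf
    p = float(2 * stats.t.sf(abs(t), df)) if df > 0 else np.nan
    half = stats.t.ppf(0.975, df) * se if df > 0 else np.nan
    return {
        "beta": b, "se": se, "ci_low": b - half, "ci_high": b + half,
        "t": float(t), "p": p, "n_used": int(mask.sum()), "model": "linear",
    }


def bulk_linear_assoc(
    responses: pd.DataFrame,
    predictors: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    family: str = "assoc",
) -> pd.DataFrame:
    """Vectorized (feature, protein) linear associations.

    For each response column y (a feature: immune-cell proportion, CLR
    species abundance, inflammation marker...) and each predictor column x
    (NPX), fits y ~ covariates + x and reports the x slope. Exact OLS via
    Frisch-Waugh-Lovell residualisation: per response, both y and all
    predictors are residualised on the covariates, giving every slope, SE
    and Wald P in one pass. FDR (BH) is computed across the whole family.
    """
    samples = responses.index
    predictors = predictors.loc[samples]
    C_all = None if covariates is None else pd.DataFrame(covariates).loc[samples]
    rows = []
    for feat in responses.columns:
        y = responses[feat].to_numpy(dtype=float)
        arrays = [y] + ([] if C_all is None else [C_all.to_numpy(dtype=float)])
        mask = _complete_cases(*arrays)
        idx = samples[mask]
        n = len(idx)
        Cm = _covariate_matrix(C_all, idx)
        kc = Cm.shape[1]
        if n < kc + 2:
            raise ValueError(f"too few complete cases for feature {feat!r}")
        yy = y[mask]
        Xp = predictors.loc[idx].to_numpy(dtype=float)
        # residualise on covariates (incl. intercept)
        Q, _ = np.linalg.qr(Cm)
        y_t = yy - Q @ (Q.T @ yy)
        X_t = Xp - Q @ (Q.T @ Xp)
        xtx = (X_t**2).sum(axis=0)
        xty = X_t.T @ y_t
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(xtx > 0, xty / np.where(xtx > 0, xtx, 1.0), np.nan)
        rss = float(y_t @ y_t) - beta**2 * xtx
        df = n - kc - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(np.maximum(rss, 0.0) / df / np.where(xtx > 0, xtx, np.nan))
            t = beta / se
        p = 2 * stats.t.sf(np.abs(t), df)
        for prot, b, s, tt, pp in zip(predictors.columns, beta, se, t, p):
            rows.append(
                {"feature": feat, "protein": prot, "beta": b, "se": s,
                 "t": tt, "p": pp, "n_used": n}
            )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(np.nan_to_num(out["p"].to_numpy(), nan=1.0))
    out["model"] = "linear"
    out["family"] = family
    return out


def logistic_assoc(
    event, x, covariates=None, standardize: bool = True, tol: float = 1e-8,
    max_iter: int = 50,
) -> dict:
    """Binomial logistic regression of a binary event on x plus covariates.

    Fit by Newton/IRLS (statsmodels) with convergence tolerance ``tol``.
    Reports OR = exp(beta_x) per SD of x (``standardize=True``, the default)
    or per unit, with Wald 95% CI and P. Degenerate predictors and perfect
    separation are flagged (``flag`` of "constant_x", "separation") instead
    of crashing.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    event = pd.Series(event, dtype=float)
    x = pd.Series(x, dtype=float).loc[event.index]
    C = None if covariates is None else pd.DataFrame(covariates).loc[event.index]
    arrays = [event.to_numpy(), x.to_numpy()] + (
        [] if C is None else [C.to_numpy(dtype=float)]
    )
    mask = _complete_cases(*arrays)
    idx = event.index[mask]
    ev = event.loc[idx].to_numpy()
    if len(np.unique(ev)) < 2:
        raise ValueError("both outcome classes must be present")
    xv = x.loc[idx].to_numpy()
    base = {"model": "logistic", "n_used": int(mask.sum()), "flag": ""}
    sd = xv.std(ddof=1)
    if sd == 0:
        return {**base, "or_": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "beta": np.nan, "flag": "constant_x"}
    if standardize:
        xv = (xv - xv.mean()) / sd
    Cm = _covariate_matrix(C, idx)
    X = np.column_stack([Cm, xv])
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is detected and flagged below; the warning is noise
            warnings.simplefilter("ignore")
            fit = sm.Logit(ev, X).fit(
                method="newton", tol=tol, maxiter=max_iter, disp=False, warn_convergence=False
            )
        beta = float(fit.params[-1])
        se = float(fit.bse[-1])
        if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 30 or se > 1e3:
            return {**base, "or_": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "p": np.nan, "beta": beta, "flag": "separation"}
        return {
            **base,
            "beta": beta,
            "or_": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
            "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
            "p": float(fit.pvalues[-1]),
        }
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return {**base, "or_": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "beta": np.nan, "flag": "separation"}


def partial_spearman(x, y, covariates=None) -> dict:
    """Partial Spearman correlation of x and y given covariates.

    Both variables are rank-transformed (average ranks for ties),
    residualised on the covariates by OLS, and the Pearson correlation of
    the residuals is referred to a t-distribution with
    df = n - 2 - n_covariates.
    """
    x = pd.Series(x, dtype=float)
    y = pd.Series(y, dtype=float).loc[x.index]
    C = None if covariates is None else pd.DataFrame(covariates).loc[x.index]
    arrays = [x.to_numpy(), y.to_numpy()] + ([] if C is None else [C.to_numpy(dtype=float)])
    mask = _complete_cases(*arrays)
    idx = x.index[mask]
    k_cov = 0 if C is None else C.shape[1]
    n = int(mask.sum())
    if n < k_cov + 3:
        raise ValueError("too few complete cases")
    rx = stats.rankdata(x.loc[idx])
    ry = stats.rankdata(y.loc[idx])
    Cm = _covariate_matrix(C, idx)
    Q, _ = np.linalg.qr(Cm)
    rx_res = rx - Q @ (Q.T @ rx)
    ry_res = ry - Q @ (Q.T @ ry)
    denom = np.sqrt((rx_res**2).sum() * (ry_res**2).sum())
    rho = float((rx_res * ry_res).sum() / denom) if denom > 0 else np.nan
    df = n - 2 - k_cov
    if np.isfinite(rho) and abs(rho) < 1 and df > 0:
        t = rho * np.sqrt(df / (1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df))
    else:
        p = 0.0 if np.isfinite(rho) and abs(rho) >= 1 else np.nan
    return {"rho": rho, "p": p, "n_used": n, "model": "partial_spearman"}


# ---------------------------------------------------------------------------
# microbiome
# ---------------------------------------------------------------------------

def clr_transform(abundance: pd.DataFrame, pseudocount: str | float = "half_min") -> pd.DataFrame:
    """Centered log-ratio transform of a samples x species table.

    Zeros are handled by adding a pseudocount delta to every entry:
    ``"half_min"`` (default) uses half the smallest nonzero abundance of the
    whole table; a float uses that value directly. Each output row sums to
    zero, and CLR is invariant to per-sample rescaling of the raw values.
    """
    A = abundance.to_numpy(dtype=float)
    if (A < 0).any():
        raise ValueError("abundances must be non-negative")
    if pseudocount == "half_min":
        nz = A[A > 0]
        if nz.size == 0:
            raise ValueError("all-zero abundance table")
        delta = 0.5 * nz.min()
    else:
        delta = float(pseudocount)
        if delta <= 0 and (A == 0).any():
            raise ValueError("pseudocount must be positive when zeros are present")
    L = np.log(A + delta)
    clr = L - L.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=abundance.index, columns=abundance.columns)


def prevalence_filter(abundance: pd.DataFrame, min_prev: float = 0.20) -> pd.DataFrame:
    """Keep species present (abundance > 0) in at least ``min_prev`` of samples.

    "Detected in less than 20% of samples" is a strict exclusion: a species
    present in exactly 20% of samples is kept.
    """
    prev = (abundance > 0).mean(axis=0)
    return abundance.loc[:, prev >= min_prev]


# ---------------------------------------------------------------------------
# protein groups and proportion comparison
# ---------------------------------------------------------------------------

def protein_groups(
    tested_proteins,
    sdep_ids,
    category_map: pd.DataFrame,
    intestine_category: str = "intestine",
    lymphoid_category: str = "lymphoid_tissue",
) -> pd.Series:
    """Partition tested proteins into the four comparison groups.

    intestine_sdep / lymphoid_sdep / other_sdep / non_dep, with the
    tissue-specific groups taking precedence (intestine first).
    """
    tcat = category_map[category_map["category_type"] == "tissue"]
    by_gene = tcat.groupby("gene_id")["category"].agg(set)
    sdep_ids = set(sdep_ids)
    labels = {}
    for prot in tested_proteins:
        cats = by_gene.get(prot, set())
        if prot in sdep_ids:
            if intestine_category in cats:
                labels[prot] = "intestine_sdep"
            elif lymphoid_category in cats:
                labels[prot] = "lymphoid_sdep"
            else:
                labels[prot] = "other_sdep"
        else:
            labels[prot] = "non_dep"
    return pd.Series(labels, name="protein_group")


def proportion_significant_comparison(
    assoc: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    yates: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare per-group proportions of significant (protein, feature) pairs.

    ``assoc`` must have columns ``protein`` and ``p``; ``groups`` maps
    protein -> group label. Per group, the proportion of association pairs
    with P < alpha is reported, then every pair of groups is compared with a
    2x2 chi-square test (significant vs not), uncorrected by default.
    """
    df = assoc[["protein", "p"]].copy()
    df["group"] = df["protein"].map(groups)
    df = df.dropna(subset=["group"])
    df["sig"] = df["p"] < alpha
    tab = df.groupby("group")["sig"].agg(["sum", "count"])
    tab["proportion"] = tab["sum"] / tab["count"]
    tab = tab.rename(columns={"sum": "n_significant", "count": "n_pairs"})
    if len(tab) < 2:
        raise ValueError("need >= 2 non-empty groups")
    rows = []
    import itertools

    for ga, gb in itertools.combinations(sorted(tab.index), 2):
        a_sig, a_tot = int(tab.loc[ga, "n_significant"]), int(tab.loc[ga, "n_pairs"])
        b_sig, b_tot = int(tab.loc[gb, "n_significant"]), int(tab.loc[gb, "n_pairs"])
        table = np.array([[a_sig, a_tot - a_sig], [b_sig, b_tot - b_sig]])
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            chi2, p = 0.0, 1.0
        elif (table[0] == table[1]).all():
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
        rows.append({"group_a": ga, "group_b": gb, "chi2": float(chi2), "p": float(p)})
    return tab.reset_index(), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# set enrichment, two-stage screen, venn
# ---------------------------------------------------------------------------

def set_enrichment_fisher(set_a, set_b, universe) -> dict:
    """One-sided (enrichment) Fisher exact test of overlap between two sets.

    2x2 table over the universe: membership in A x membership in B; the
    P value is the exact upper hypergeometric tail.
    """
    universe = set(universe)
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    odds, p = stats.fisher_exact(table, alternative="greater")
    return {"odds_ratio": float(odds), "p": float(p), "table": table.tolist(),
            "overlap": a}


def two_stage_cvd_screen(
    stage1: pd.DataFrame,
    stage2: pd.DataFrame,
    fdr_thr: float = 0.05,
    p_thr: float = 0.05,
) -> dict:
    """Two-stage protein screen: FDR in the larger cohort, then replication.

    ``stage1``/``stage2`` are association tables indexed by protein with
    columns ``beta`` (or ``effect``), ``p``, ``fdr``. Stage-1 hits have
    FDR < ``fdr_thr``; replicated hits additionally have stage-2
    P < ``p_thr`` with the same effect sign.
    """
    def eff(df):
        return df["beta"] if "beta" in df else df["effect"]

    shared = stage1.index.intersection(stage2.index)
    s1 = stage1.loc[shared]
    s2 = stage2.loc[shared]
    stage1_hits = list(s1.index[s1["fdr"] < fdr_thr])
    rep_mask = (
        (s1["fdr"] < fdr_thr)
        & (s2["p"] < p_thr)
        & (np.sign(eff(s1)) == np.sign(eff(s2)))
    )
    return {
        "stage1_hits": sorted(stage1_hits),
        "replicated": sorted(s1.index[rep_mask]),
    }


def overlap_venn(set_a, set_b, set_c) -> dict:
    """All 7 region counts of a three-set Venn plus the triple intersection."""
    A, B, C = set(set_a), set(set_b), set(set_c)
    regions = {
        "a_only": len(A - B - C),
        "b_only": len(B - A - C),
        "c_only": len(C - A - B),
        "ab_only": len((A & B) - C),
        "ac_only": len((A & C) - B),
        "bc_only": len((B & C) - A),
        "abc": len(A & B & C),
    }
    regions["union"] = len(A | B | C)
    regions["abc_members"] = sorted(A & B & C)
    return regions
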