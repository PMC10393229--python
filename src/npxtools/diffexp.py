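"""Covariate-adjusted differential protein expression with moderation.

Per protein, an ordinary least-squares fit of NPX on a design matrix
(intercept, group indicator, age, sex, smoking) gives the group coefficient
("fold-change" on the log2-NPX scale, i.e. the adjusted difference in mean
log2 NPX), its standard error, and the residual variance. Residual variances
are then shrunk toward a pooled prior by the empirical-Bayes moment-matching
scheme of Smyth (2004): with prior degrees of freedom d0 and prior variance
s0^2, the posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t-statistic t~ = beta_g / (c_g * s~_g) is referred to a
t-distribution on d0 + d_g degrees of freedom (capped at the pooled residual
df). P values are Benjamini-Hochberg adjusted, and the discovery->replication
call retains proteins with discovery FDR < 0.05, replication P < 0.05 and a
consistent effect sign in both cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .qc import NPXMatrix, pca_scores

__all__ = [
    "EBayesPrior",
    "make_design",
    "fit_linear_models",
    "estimate_prior",
    "ebayes_moderate",
    "bh_adjust",
    "run_de",
    "call_sdeps",
    "fold_change_subset",
    "pca_group_test",
]

DEFAULT_COVARIATES = ("age", "sex", "smoking")


@dataclass
class EBayesPrior:
    """Prior df (may be ``inf``) and prior variance for variance shrinkage."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0")
        if not (self.s0_sq > 0) and self.d0 > 0:
            raise ValueError("s0_sq must be > 0")


def make_design(
    samples: pd.DataFrame,
    group_col: str = "group",
    case_label: str = "PLHIV",
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Build the per-sample design matrix: intercept, group, covariates.

    Samples with any missing covariate are excluded (listwise deletion).
    """
    cols = [group_col, *covariates]
    sub = samples[cols].dropna()
    X = pd.DataFrame(index=sub.index)
    X["intercept"] = 1.0
    X["group"] = (sub[group_col] == case_label).astype(float)
    for c in covariates:
        X[c] = pd.to_numeric(sub[c])
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


def fit_linear_models(
    m: NPXMatrix | pd.DataFrame, X: pd.DataFrame, coef: str = "group"
) -> pd.DataFrame:
    """Vectorized per-protein OLS against a shared design matrix.

    Returns a DataFrame indexed by assay with columns ``effect`` (the
    ``coef`` coefficient), ``se`` (ordinary SE), ``df_resid``, ``s2``
    (residual variance), ``stdev_unscaled`` (SE / residual SD), ``n_used``.
    """
    values = m.values if isinstance(m, NPXMatrix) else m
    common = [s for s in X.index if s in set(values.index)]
    if len(common) <= X.shape[1]:
        raise ValueError("fewer samples than design parameters")
    Xm = X.loc[common].to_numpy(dtype=float)
    Y = values.loc[common].to_numpy(dtype=float)
    n, k = Xm.shape
    if np.linalg.matrix_rank(Xm) < k:
        raise ValueError("design matrix is rank deficient")
    j = list(X.columns).index(coef)
    Q, R = np.linalg.qr(Xm)
    beta = np.linalg.solve(R, Q.T @ Y)  # k x p
    resid = Y - Xm @ beta
    df_resid = n - k
    rss = (resid**2).sum(axis=0)
    s2 = rss / df_resid
    xtx_inv = np.linalg.inv(R.T @ R)
    c_j = math.sqrt(xtx_inv[j, j])
    return pd.DataFrame(
        {
            "effect": beta[j],
            "se": np.sqrt(s2) * c_j,
            "df_resid": float(df_resid),
            "s2": s2,
            "stdev_unscaled": c_j,
            "n_used": n,
        },
        index=values.columns,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 200) -> float:
    """Solve trigamma(x) = y for x > 0 by monotone bisection.

    trigamma is strictly decreasing on (0, inf) with range (0, inf), so the
    root exists and is unique for any y > 0.
    """
    if y <= 0:
        return math.inf
    lo, hi = 1e-8, 1e8
    # expand bounds if necessary (trigamma(1e-8) ~ 1e16, trigamma(1e8) ~ 1e-8)
    while special.polygamma(1, hi) > y:
        hi *= 10
    while special.polygamma(1, lo) < y:
        lo /= 10
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    return 0.5 * (lo + hi)


def estimate_prior(s2: np.ndarray, df_resid: np.ndarray) -> EBayesPrior:
    """Method-of-moments fit of the scaled-F prior on residual variances.

    Matches the mean and variance of log(s2) using digamma/trigamma
    identities (Smyth 2004). If the trigamma equation has no positive
    solution the prior df is infinite and every variance is shrunk to s0^2.
    Zero variances are excluded from estimation (they carry no information
    about the prior scale).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df_resid, dtype=float), s2.shape)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive residual variances to estimate the prior")
    z = np.log(s2[ok])
    dfo = df[ok]
    e = z - special.digamma(dfo / 2.0) + np.log(dfo / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    evar_adj = evar - np.mean(special.polygamma(1, dfo / 2.0))
    if evar_adj > 0:
        d0 = 2.0 * _trigamma_inverse(evar_adj)
        s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def ebayes_moderate(fits: pd.DataFrame, prior: EBayesPrior | None = None) -> pd.DataFrame:
    """Moderated t-statistics and two-sided P values for per-protein fits.

    ``prior=None`` estimates (d0, s0^2) from the residual variances; a
    supplied prior with ``d0=0`` reproduces the ordinary t-test exactly and
    ``d0=inf`` shrinks every variance fully to ``s0_sq``. Total df is
    ``d0 + df_resid`` capped at the pooled residual df (sum over proteins).
    """
    out = fits.copy()
    s2 = out["s2"].to_numpy(dtype=float)
    df = out["df_resid"].to_numpy(dtype=float)
    if prior is None:
        if not (s2 > 0).any():
            raise ValueError("all residual variances are zero; nothing to moderate")
        prior = estimate_prior(s2, df)
    d0 = prior.d0
    if d0 == 0:
        s2_post = s2.copy()
        df_total = df
    elif math.isinf(d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.full_like(df, df.sum())
    else:
        s2_post = (d0 * prior.s0_sq + df * s2) / (d0 + df)
        df_total = np.minimum(d0 + df, df.sum())
    c = out["stdev_unscaled"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = out["effect"].to_numpy() / (np.sqrt(s2_post) * c)
    t_mod = np.where(s2_post == 0, np.sign(out["effect"]) * np.inf, t_mod)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.where(np.isinf(t_mod), 0.0, p)
    out["s2_post"] = s2_post
    out["df_total"] = df_total
    out["t_mod"] = t_mod
    out["p"] = p
    out.attrs["prior"] = prior
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (monotone, in [0, 1])."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of P values")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("P values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def run_de(
    m: NPXMatrix,
    samples: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    prior: EBayesPrior | None = None,
    by_protein: bool = True,
) -> pd.DataFrame:
    """Full DE table: OLS + moderation + BH FDR, sorted by protein id.

    With ``by_protein=True`` (default) the index is the protein symbol
    rather than the assay id (requires unique proteins, i.e. deduplicated
    assays).
    """
    X = make_design(samples, covariates=covariates)
    fits = fit_linear_models(m, X)
    de = ebayes_moderate(fits, prior=prior)
    if by_protein:
        prot = m.proteins().loc[de.index]
        if prot.duplicated().any():
            raise ValueError("duplicate proteins; deduplicate assays before DE")
        de.index = pd.Index(prot, name="protein")
    de = de.sort_index(kind="stable")  # stable tie-break on protein id
    de["fdr"] = bh_adjust(de["p"].to_numpy())
    de["direction"] = np.sign(de["effect"]).astype(int)
    return de


# ---------------------------------------------------------------------------
# discovery -> replication calling
# ---------------------------------------------------------------------------

def call_sdeps(
    disc: pd.DataFrame,
    repl: pd.DataFrame,
    fdr_thr: float = 0.05,
    p_thr: float = 0.05,
) -> pd.DataFrame:
    """Shared DEPs: discovery FDR < thr, replication P < thr, same sign.

    ``disc``/``repl`` are DE tables indexed by protein with columns
    ``effect``, ``p``, ``fdr``. Proteins absent from either table are
    excluded. Returns a table indexed by protein with per-cohort effects and
    an ``up`` flag.
    """
    shared = disc.index.intersection(repl.index)
    if len(shared) == 0:
        raise ValueError("no shared proteins between cohorts")
    d = disc.loc[shared]
    r = repl.loc[shared]
    keep = (
        (d["fdr"] < fdr_thr)
        & (r["p"] < p_thr)
        & (np.sign(d["effect"]) == np.sign(r["effect"]))
        & (d["effect"] != 0)
    )
    out = pd.DataFrame(
        {
            "effect_disc": d["effect"],
            "effect_repl": r["effect"],
            "fdr_disc": d["fdr"],
            "p_repl": r["p"],
            "up": d["effect"] > 0,
        }
    ).loc[keep]
    return out.sort_index(kind="stable")


def fold_change_subset(
    sdeps: pd.DataFrame, threshold: float = 1.5, scale: str = "npx_diff"
) -> list[str]:
    """sDEPs with |fold-change| >= threshold in BOTH cohorts.

    ``scale="npx_diff"`` thresholds the log2-NPX difference itself;
    ``scale="linear_fc"`` thresholds 2**|effect|.
    """
    if scale not in ("npx_diff", "linear_fc"):
        raise ValueError(f"unknown scale {scale!r}")
    a = sdeps["effect_disc"].abs()
    b = sdeps["effect_repl"].abs()
    if scale == "linear_fc":
        a, b = np.power(2.0, a), np.power(2.0, b)
    keep = (a >= threshold) & (b >= threshold)
    return list(sdeps.index[keep])


def pca_group_test(m: NPXMatrix, groups: pd.Series, scale: bool = True) -> dict:
    """Group separation on PC1/PC2 assessed by the Mann-Whitney U test.

    Returns the PC scores, explained-variance fractions, and the two-sided
    U statistic and P value per component.
    """
    groups = groups.loc[m.sample_ids]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    if (groups == labels[0]).sum() < 2 or (groups == labels[1]).sum() < 2:
        raise ValueError("both groups need >= 2 samples")
    scores, evr, _ = pca_scores(m, n_components=2, scale=scale)
    result = {"scores": scores, "explained_variance_ratio": list(map(float, evr)), "tests": {}}
    for pc in ("PC1", "PC2"):
        a = scores.loc[groups == labels[0], pc]
        b = scores.loc[groups == labels[1], pc]
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        result["tests"][pc] = {"U": float(res.statistic), "p": float(res.pvalue)}
    return result
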