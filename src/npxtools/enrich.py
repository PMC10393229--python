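"""Hypergeometric enrichment against the measured-protein background.

Two flavours: tissue/cell specificity enrichment of a candidate protein
list (e.g. upregulated shared DEPs) against a gene -> category map, and
gene-set over-representation analysis (ORA) against a GMT collection. Both
use the one-sided upper-tail hypergeometric probability

    P = sum_{i=k}^{min(n, K_b)} C(K_b, i) C(N_b - K_b, n - i) / C(N_b, n)

where k = candidates in the category, n = candidate list size, K_b =
category size in the background and N_b = background size. The background
is always the measured panel, never the genome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .diffexp import bh_adjust

__all__ = [
    "hypergeom_upper",
    "tissue_cell_enrichment",
    "pathway_ora",
    "read_gmt",
    "write_gmt",
    "read_category_map",
    "write_category_map",
]


def hypergeom_upper(k: int, n: int, K_b: int, N_b: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), inclusive of k.

    Summed in log space for numerical stability. Bounds: 0 <= K_b <= N_b,
    0 <= n <= N_b, 0 <= k <= min(n, K_b).
    """
    k, n, K_b, N_b = int(k), int(n), int(K_b), int(N_b)
    if not (0 <= K_b <= N_b):
        raise ValueError(f"require 0 <= K_b <= N_b, got K_b={K_b}, N_b={N_b}")
    if not (0 <= n <= N_b):
        raise ValueError(f"require 0 <= n <= N_b, got n={n}, N_b={N_b}")
    if not (0 <= k <= min(n, K_b)):
        raise ValueError(f"require 0 <= k <= min(n, K_b), got k={k}")
    if k <= max(0, n - (N_b - K_b)):
        # tail covers the entire support (incl. k = 0 and the K_b = N_b urn)
        return 1.0
    upper = min(n, K_b)
    i = np.arange(k, upper + 1)
    logp = stats.hypergeom.logpmf(i, N_b, K_b, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def tissue_cell_enrichment(
    candidates,
    background,
    category_map: pd.DataFrame,
    min_category: int = 4,
    alpha: float = 0.05,
    fdr_within_type: bool = True,
) -> pd.DataFrame:
    """Per-category hypergeometric enrichment of ``candidates``.

    ``category_map`` has columns gene_id, category_type (tissue|cell),
    category. Only categories with at least ``min_category`` members in the
    background (i.e. strictly more than ``min_category - 1``) are eligible.
    N_b is the full background size. BH FDR is computed within each category
    type by default. Candidate ids must be a subset of the background.
    """
    candidates = set(candidates)
    background = set(background)
    stray = sorted(candidates - background)
    if stray:
        raise ValueError(f"candidate ids absent from background: {stray[:10]}")
    if not background:
        raise ValueError("empty background")
    cmap = category_map[category_map["gene_id"].isin(background)]
    rows = []
    for (ctype, cat), g in sorted(cmap.groupby(["category_type", "category"])):
        members = set(g["gene_id"])
        K_b = len(members)
        if K_b < min_category:
            continue
        k = len(candidates & members)
        p = hypergeom_upper(k, len(candidates), K_b, len(background))
        rows.append(
            {
                "category": cat,
                "category_type": ctype,
                "k": k,
                "n": len(candidates),
                "K_b": K_b,
                "N_b": len(background),
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["category", "category_type", "k", "n", "K_b", "N_b", "p"]
    )
    if len(out):
        if fdr_within_type:
            out["fdr"] = np.nan
            for ctype, idx in out.groupby("category_type").groups.items():
                out.loc[idx, "fdr"] = bh_adjust(out.loc[idx, "p"].to_numpy())
        else:
            out["fdr"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p"] < alpha
    else:
        out["fdr"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out.sort_values(["p", "category"], kind="stable").reset_index(drop=True)


def pathway_ora(
    candidates,
    background,
    gene_sets: dict[str, dict],
    p_max: float = 0.05,
    min_count: int = 4,
    mode: str = "standard",
) -> pd.DataFrame:
    """Over-representation analysis of ``candidates`` against GMT sets.

    Set members are intersected with the background before testing; N_b is
    the background size. A pathway is significant iff P < ``p_max`` AND the
    candidate overlap k >= ``min_count`` (i.e. strictly greater than
    ``min_count - 1`` proteins). ``mode="ease"`` computes the conservative
    k-1 variant of the upper tail for compatibility with DAVID-style EASE
    scores.
    """
    if mode not in ("standard", "ease"):
        raise ValueError(f"unknown mode {mode!r}")
    candidates = set(candidates)
    background = set(background)
    stray = sorted(candidates - background)
    if stray:
        raise ValueError(f"candidate ids absent from background: {stray[:10]}")
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]["members"]) & background
        if not members:
            continue
        overlap = sorted(candidates & members)
        k = len(overlap)
        k_test = max(k - 1, 0) if mode == "ease" else k
        p = hypergeom_upper(k_test, len(candidates), len(members), len(background))
        rows.append(
            {
                "pathway": name,
                "k": k,
                "n": len(candidates),
                "K_b": len(members),
                "N_b": len(background),
                "p": p,
                "significant": bool(p < p_max and k >= min_count),
                "members": overlap,
            }
        )
    out = pd.DataFrame(
        rows, columns=["pathway", "k", "n", "K_b", "N_b", "p", "significant", "members"]
    )
    return out.sort_values(["p", "pathway"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# GMT and category-map I/O
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, dict]:
    """Read a GMT file: tab-separated ``name  description  member...``.

    Empty sets are an error; duplicate members collapse.
    """
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {line_no}: expected >= 3 tab-separated fields")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise ValueError(f"GMT line {line_no}: empty set {name!r}")
            sets[name] = {"description": desc, "members": set(members)}
    return sets


def write_gmt(gene_sets: dict[str, dict], path) -> None:
    with open(path, "w") as fh:
        for name in gene_sets:
            desc = gene_sets[name].get("description", "")
            members = sorted(gene_sets[name]["members"])
            if not members:
                raise ValueError(f"refusing to write empty set {name!r}")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_category_map(path) -> pd.DataFrame:
    cmap = pd.read_csv(path, sep="\t")
    required = {"gene_id", "category_type", "category"}
    missing = required - set(cmap.columns)
    if missing:
        raise ValueError(f"category map missing columns: {sorted(missing)}")
    return cmap


def write_category_map(cmap: pd.DataFrame, path) -> None:
    cmap.to_csv(path, sep="\t", index=False)
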