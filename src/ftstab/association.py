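"""Pairwise correlations with FDR control, and the permutation Mantel test."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .efs import DistanceMatrix


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_matrix(X: pd.DataFrame, method: str = "pearson",
                       min_obs: int = 3) -> pd.DataFrame:
    """All-pairs correlation of rows of a variables x samples frame.

    Missing values are handled pairwise-complete.  Two-sided p-values come
    from the t-distribution on n-2 df (Spearman: on ranks).  Pairs touching
    a zero-variance variable, or with fewer than ``min_obs`` complete
    observations, are flagged with NaN r and p; NaN p-values are excluded
    from the BH family.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if X.index.has_duplicates:
        dup = X.index[X.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate variable names: {dup}")
    rows = []
    for a, b in combinations(X.index, 2):
        xa = X.loc[a].to_numpy(dtype=float)
        xb = X.loc[b].to_numpy(dtype=float)
        mask = np.isfinite(xa) & np.isfinite(xb)
        r = p = np.nan
        if mask.sum() >= min_obs:
            va, vb = xa[mask], xb[mask]
            if np.ptp(va) > 0 and np.ptp(vb) > 0:
                if method == "pearson":
                    r, p = stats.pearsonr(va, vb)
                else:
                    r, p = stats.spearmanr(va, vb)
        rows.append({"var_a": a, "var_b": b, "r": float(r), "p": float(p),
                     "n": int(mask.sum()), "method": method})
    report = pd.DataFrame(rows)
    report["p_adj"] = np.nan
    ok = report["p"].notna()
    if ok.any():
        report.loc[ok, "p_adj"] = bh_adjust(report.loc[ok, "p"].to_numpy())
    return report


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str
    tail: str
    n: int
    seed: int | None


def _triangle(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(D.shape[0], k=1)
    return D[iu]


def _rank_matrix(D: np.ndarray) -> np.ndarray:
    """Symmetric matrix of the ranks of the off-diagonal entries."""
    iu = np.triu_indices(D.shape[0], k=1)
    ranks = stats.rankdata(D[iu])
    R = np.zeros_like(D, dtype=float)
    R[iu] = ranks
    return R + R.T


def mantel(D1: DistanceMatrix, D2: DistanceMatrix, n_perm: int = 999,
           method: str = "pearson", seed: int | None = None,
           tail: str = "greater") -> MantelResult:
    """Permutation Mantel test between two distance matrices.

    The correlation of the strictly-lower triangles is recomputed under
    ``n_perm`` simultaneous row/column permutations of the second matrix;
    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1) for the one-tailed
    "greater" convention (ecology's default for distance association).
    """
    if list(D1.sample_ids) != list(D2.sample_ids):
        raise ValueError("distance matrices must share sample ids and order")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    n = D1.n
    # Spearman reduces to Pearson on ranked distances; ranking commutes with
    # simultaneous row/column permutation, so rank once up front.
    M1 = _rank_matrix(D1.D) if method == "spearman" else D1.D
    M2 = _rank_matrix(D2.D) if method == "spearman" else D2.D
    x = _triangle(M1)
    y = _triangle(M2)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant distance triangle: Mantel r undefined")

    xc = x - x.mean()
    xnorm = np.sqrt((xc ** 2).sum())

    def corr_with_x(vec: np.ndarray) -> float:
        vc = vec - vec.mean()
        denom = xnorm * np.sqrt((vc ** 2).sum())
        return float((xc * vc).sum() / denom) if denom > 0 else np.nan

    r_obs = corr_with_x(y)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    perm_r = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        perm_r[k] = corr_with_x(M2[np.ix_(perm, perm)][iu])
    if tail == "greater":
        exceed = (perm_r >= r_obs).sum()
    elif tail == "less":
        exceed = (perm_r <= r_obs).sum()
    else:
        exceed = (np.abs(perm_r) >= abs(r_obs)).sum()
    p = (1 + exceed) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, method=method,
                        tail=tail, n=n, seed=seed)


def env_distance(env: pd.DataFrame, variables: str | list[str],
                 standardize: bool = True) -> DistanceMatrix:
    """Euclidean distance between samples on (z-standardized) env variables.

    Standardization puts mixed units (degrees C, mg/L, umol/L) on one scale.
    Samples with missing values in the selected variables are dropped.
    """
    if isinstance(variables, str):
        variables = [variables]
    sub = env[variables].apply(pd.to_numeric, errors="coerce")
    complete = sub.dropna()
    dropped = [s for s in sub.index if s not in complete.index]
    values = complete.to_numpy(dtype=float)
    if standardize:
        sd = values.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        values = (values - values.mean(axis=0)) / sd
    from scipy.spatial.distance import pdist, squareform
    D = squareform(pdist(values, metric="euclidean"))
    dm = DistanceMatrix(sample_ids=list(complete.index), D=D, source="env")
    if dropped:
        dm.dropped = dropped  # type: ignore[attr-defined]
    return dm
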