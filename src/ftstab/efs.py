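"""The ecological functional stability (EFS) statistic.

The statistic compares how much community *function* varies between samples
with how much community *structure* varies.  Both are summarized by the
per-sample mean Euclidean distance to all other samples, computed on
relative-abundance tables: F on the functional table and T on taxonomic
tables (bacteria, archaea, and their concatenation "microbial").  The
dimensionless ratio F:T then reads:

* F:T < 1 — taxa turn over more than function: many taxa carry the same
  functions (functional redundancy), the function is buffered, the system
  is functionally *stable*;
* F:T = 1 — function and structure vary synchronously;
* F:T > 1 — function varies more than structure: functionally *unstable*.

The ratio is taken per sample from the mean distances (mean first, then
ratio), and is invariant to multiplying all tables by a common positive
constant but not to rescaling the functional table alone — hence both
spaces are put on the per-sample-relative scale before distances are taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy import stats

from .tables import AbundanceTable, TableValidationError

STABILITY_TOL = 0.05


@dataclass
class DistanceMatrix:
    """Symmetric Euclidean distance matrix over a fixed sample order."""

    sample_ids: list[str]
    D: np.ndarray
    source: str  # function | bacteria | archaea | microbial | env

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if D.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match matrix")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(D), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if (D < -1e-12).any():
            raise ValueError("negative distances")
        self.D = D

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def euclidean_distance_matrix(table: AbundanceTable, source: str | None = None) -> DistanceMatrix:
    """All-pairs Euclidean distances between sample rows."""
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    values = table.values
    if not np.isfinite(values).all():
        raise TableValidationError("missing values in abundance table")
    D = squareform(pdist(values, metric="euclidean"))
    return DistanceMatrix(sample_ids=table.sample_ids, D=D,
                          source=source or table.domain)


def concat_domains(bac: AbundanceTable, arc: AbundanceTable,
                   norm: str = "block") -> AbundanceTable:
    """Concatenate bacterial and archaeal relative tables into one microbial table.

    ``norm="block"`` keeps each domain block row-normalized to 1 (row sums 2),
    so both domains contribute equally regardless of feature counts;
    ``norm="joint"`` renormalizes the concatenated rows to sum 1.
    """
    if list(bac.sample_ids) != list(arc.sample_ids):
        raise TableValidationError("bacteria and archaea tables have different samples")
    if norm not in ("block", "joint"):
        raise ValueError("norm must be 'block' or 'joint'")
    bac_df = bac.data.add_prefix("bac|")
    arc_df = arc.data.add_prefix("arc|")
    data = pd.concat([bac_df, arc_df], axis=1)
    if norm == "joint":
        sums = data.sum(axis=1)
        data = data.div(sums.where(sums > 0, 1.0), axis=0)
    annot = {f"bac|{k}": v for k, v in bac.feature_annotation.items()}
    annot.update({f"arc|{k}": v for k, v in arc.feature_annotation.items()})
    return AbundanceTable(data=data, domain="microbial", scale=bac.scale,
                          feature_annotation=annot)


def mean_offdiag(D: DistanceMatrix) -> pd.Series:
    """Per-sample mean distance to every other sample."""
    n = D.n
    if n < 2:
        raise ValueError("mean off-diagonal distance undefined for n < 2")
    means = D.D.sum(axis=1) / (n - 1)
    return pd.Series(means, index=D.sample_ids, name=D.source)


def distance_summaries(
    func: AbundanceTable,
    bac: AbundanceTable,
    arc: AbundanceTable | None = None,
    tmic_norm: str = "block",
) -> pd.DataFrame:
    """Compute the F, T_bac, T_arc and T_mic mean-distance summaries.

    All inputs must be relative tables over the same samples.  With no
    archaeal table the microbial summary equals the bacterial one.
    """
    for name, t in (("function", func), ("bacteria", bac)):
        if t.scale != "relative":
            raise TableValidationError(f"{name} table must be relative (got {t.scale})")
    if list(func.sample_ids) != list(bac.sample_ids):
        raise TableValidationError("function and bacteria tables have different samples")
    out = pd.DataFrame(index=pd.Index(func.sample_ids, name="sample_id"))
    out["F"] = mean_offdiag(euclidean_distance_matrix(func, "function"))
    out["T_bac"] = mean_offdiag(euclidean_distance_matrix(bac, "bacteria"))
    if arc is not None and len(arc.feature_ids) > 0:
        if arc.scale != "relative":
            raise TableValidationError("archaea table must be relative")
        out["T_arc"] = mean_offdiag(euclidean_distance_matrix(arc, "archaea"))
        mic = concat_domains(bac, arc, norm=tmic_norm)
        out["T_mic"] = mean_offdiag(euclidean_distance_matrix(mic, "microbial"))
    else:
        out["T_arc"] = np.nan
        out["T_mic"] = out["T_bac"]
    return out


def classify_stability(ratio: float, tol: float = STABILITY_TOL) -> str:
    if np.isnan(ratio):
        return "undefined"
    if ratio < 1.0 - tol:
        return "stable"
    if ratio > 1.0 + tol:
        return "unstable"
    return "synchronous"


def ft_ratio(summaries: pd.DataFrame, tol: float = STABILITY_TOL) -> pd.DataFrame:
    """Per-sample F:T ratios and stability classes from distance summaries.

    Zero denominators are flagged NaN ("undefined") per sample rather than
    failing globally.
    """
    out = summaries.copy()

    def _safe_div(num: pd.Series, den: pd.Series) -> pd.Series:
        return num / den.where(den > 0, np.nan)

    out["ft_mic"] = _safe_div(out["F"], out["T_mic"])
    out["ft_bac"] = _safe_div(out["F"], out["T_bac"])
    out["ft_arc"] = _safe_div(out["F"], out["T_arc"])
    out["t_bac_to_t_arc"] = _safe_div(out["T_bac"], out["T_arc"])
    out["stability_class"] = [classify_stability(r, tol) for r in out["ft_mic"]]
    return out


def ft_identity_check(table: AbundanceTable) -> pd.Series:
    """F:T ratios when one table is supplied as both function and taxa.

    Both distance matrices then coincide, so every per-sample ratio is 1 —
    the synchronous-variation reference point of the statistic.
    """
    m = mean_offdiag(euclidean_distance_matrix(table))
    return m / m


# ---------------------------------------------------------------------------
# group contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    variant: str


def group_contrast(values: pd.Series, groups: pd.Series,
                   labels: tuple[str, str] | None = None,
                   variant: str = "welch") -> ContrastResult:
    """Two-sided two-sample t-test (Welch by default) between two groups."""
    groups = groups.loc[values.index]
    if labels is None:
        uniq = list(pd.unique(groups))
        if len(uniq) != 2:
            raise ValueError(f"need exactly two groups, got {uniq}")
        labels = (uniq[0], uniq[1])
    a = values[groups == labels[0]].dropna().to_numpy(dtype=float)
    b = values[groups == labels[1]].dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    equal_var = variant == "student"
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    df = float(res.df)
    if np.isnan(t):  # both groups constant: no evidence either way
        identical = np.allclose(a.mean(), b.mean())
        t, p = 0.0, 1.0
        if not identical:
            # zero within-group variance but different means: epsilon guard
            eps = 1e-12 * max(1.0, abs(a.mean()), abs(b.mean()))
            t = (a.mean() - b.mean()) / np.sqrt(eps / len(a) + eps / len(b))
            p = 0.0
    return ContrastResult(t=t, df=df, p=p,
                          mean_a=float(a.mean()), mean_b=float(b.mean()),
                          sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
                          n_a=len(a), n_b=len(b), variant=variant)


def paired_water_ratio(per_sample: pd.DataFrame, meta: pd.DataFrame,
                       metrics: tuple[str, ...] = ("F", "T_mic", "ft_mic")) -> pd.DataFrame:
    """Per-reservoir inflow:reservoir ratios of EFS metrics, tested against 1.

    For each reservoir the ratio is mean(metric | inflow) / mean(metric |
    reservoir water).  Across reservoirs a two-sided one-sample t-test
    against 1 is reported; if the ratios are (numerically) constant the
    t-test degenerates and a sign test is used instead.
    """
    meta = meta.loc[per_sample.index]
    rows = []
    for reservoir, sub_meta in meta.groupby("reservoir"):
        inflow_ids = sub_meta.index[sub_meta["water_type"] == "inflow"]
        res_ids = sub_meta.index[sub_meta["water_type"] == "reservoir"]
        if len(inflow_ids) == 0 or len(res_ids) == 0:
            continue  # reservoir lacks one water type: skipped
        row = {"reservoir": reservoir}
        for m in metrics:
            denom = per_sample.loc[res_ids, m].mean()
            row[m] = per_sample.loc[inflow_ids, m].mean() / denom if denom > 0 else np.nan
        rows.append(row)
    ratios = pd.DataFrame(rows).set_index("reservoir")
    summary_rows = []
    for m in metrics:
        vals = ratios[m].dropna().to_numpy(dtype=float)
        mean_ratio = float(vals.mean()) if len(vals) else np.nan
        if len(vals) < 2 or np.allclose(vals, vals[0]):
            # degenerate variance: sign test on (ratio - 1)
            n_pos = int((vals > 1).sum())
            n_neg = int((vals < 1).sum())
            n_eff = n_pos + n_neg
            p = float(stats.binomtest(n_pos, n_eff, 0.5).pvalue) if n_eff else 1.0
            t = np.nan
        else:
            res = stats.ttest_1samp(vals, 1.0)
            t, p = float(res.statistic), float(res.pvalue)
        summary_rows.append({"metric": m, "mean_ratio": mean_ratio,
                             "t": t, "p": p, "n_reservoirs": len(vals)})
    summary = pd.DataFrame(summary_rows).set_index("metric")
    summary.attrs["per_reservoir"] = ratios
    return summary
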