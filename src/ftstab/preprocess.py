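"""Rarefaction, relative abundance, dominant-group aggregation and pathway rollups."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import AbundanceTable, TableValidationError

PATHWAYS = ("C-fixation", "C-degradation", "CH4", "N", "P", "S")


@dataclass
class RarefactionReport:
    depth: int
    kept: list[str]
    dropped: list[str]


def rarefy(
    table: AbundanceTable,
    depth: int | str = "min",
    seed: int | None = None,
    reps: int = 1,
) -> tuple[AbundanceTable, RarefactionReport]:
    """Subsample every sample without replacement to a common depth.

    ``depth="min"`` uses the minimum sample total, mirroring the common
    rarefy-to-minimum-sequencing-depth workflow.  Samples whose total falls
    below ``depth`` are dropped and reported.  A single draw is taken by
    default; ``reps > 1`` averages repeated draws (the result is then no
    longer integer counts).
    """
    if table.scale != "counts":
        raise TableValidationError("rarefy requires a counts table")
    totals = table.data.sum(axis=1)
    if depth == "min":
        depth = int(totals.min())
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    keep_mask = totals >= depth
    if not keep_mask.any():
        raise ValueError(f"all samples fall below rarefaction depth {depth}")
    kept = table.data.index[keep_mask].tolist()
    dropped = table.data.index[~keep_mask].tolist()

    rng = np.random.default_rng(seed)
    counts = table.data.loc[kept].to_numpy(dtype=np.int64)
    out = np.zeros_like(counts, dtype=float)
    for _ in range(reps):
        for i, row in enumerate(counts):
            # exact without-replacement subsample of the count vector
            out[i] += rng.multivariate_hypergeometric(row, depth)
    out /= reps
    if reps == 1:
        out = out.astype(np.int64)
    data = pd.DataFrame(out, index=kept, columns=table.data.columns)
    return table.with_data(data), RarefactionReport(depth=depth, kept=kept, dropped=dropped)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample row by its total; idempotent on relative tables."""
    sums = table.data.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise TableValidationError(f"zero-sum samples cannot be normalized: {zero.index.tolist()}")
    data = table.data.div(sums, axis=0)
    return table.with_data(data, scale="relative")


def aggregate_dominant(table: AbundanceTable, threshold: float = 0.01,
                       others_label: str = "others") -> AbundanceTable:
    """Pool features with mean relative abundance below ``threshold``.

    The dominance criterion is the mean across all samples, so every sample
    keeps the same feature set — a requirement for a single Euclidean space.
    """
    if table.scale != "relative":
        raise TableValidationError("aggregate_dominant requires a relative table")
    means = table.data.mean(axis=0)
    minor = means.index[means < threshold]
    if len(minor) == 0:
        return table
    major = [f for f in table.data.columns if f not in set(minor)]
    data = table.data[major].copy()
    data[others_label] = table.data[minor].sum(axis=1)
    annot = {f: g for f, g in table.feature_annotation.items() if f in major}
    return AbundanceTable(data=data, domain=table.domain, scale=table.scale,
                          feature_annotation=annot)


def map_genes_to_pathways(genes: AbundanceTable) -> AbundanceTable:
    """Sum gene abundances into their annotated pathway groups.

    Every gene must be annotated to exactly one pathway; per-sample totals
    are conserved.
    """
    unannotated = [g for g in genes.feature_ids if g not in genes.feature_annotation]
    if unannotated:
        raise TableValidationError(f"genes without pathway annotation: {unannotated[:10]}")
    unknown = sorted({p for p in genes.feature_annotation.values() if p not in PATHWAYS})
    if unknown:
        raise TableValidationError(f"unknown pathway labels: {unknown}")
    groups = pd.Series(genes.feature_annotation)
    data = genes.data.T.groupby(groups).sum().T
    # keep canonical pathway order for the pathways present
    order = [p for p in PATHWAYS if p in data.columns]
    data = data[order]
    annot = {p: p for p in order}
    return AbundanceTable(data=data, domain="function", scale=genes.scale,
                          feature_annotation=annot)


def cf_cd_ratio(pathways: AbundanceTable) -> pd.Series:
    """Per-sample carbon-fixation : carbon-degradation ratio.

    Samples with zero C-degradation are flagged NaN rather than failing.
    """
    for col in ("C-fixation", "C-degradation"):
        if col not in pathways.data.columns:
            raise TableValidationError(f"pathway table lacks {col!r}")
    cf = pathways.data["C-fixation"]
    cd = pathways.data["C-degradation"]
    ratio = cf / cd.where(cd > 0, np.nan)
    ratio.name = "CF:CD"
    return ratio
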