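"""Reading, validation and alignment of abundance, metadata and environment tables.

The on-disk convention is a tab-separated matrix with samples as rows and
features as columns, plus an optional two-column annotation sidecar
(feature_id <tab> group).  Orientation is never guessed: readers take an
explicit ``orientation`` argument, because a silently transposed table is a
classic source of corrupted downstream distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DOMAINS = ("bacteria", "archaea", "function", "microbial")
SCALES = ("counts", "copies", "relative")

#: columns a sample-metadata table must provide
SAMPLEFRAME_REQUIRED = ("sample_id", "reservoir", "water_type", "depth_m", "season")
SAMPLEFRAME_OPTIONAL = ("hydraulic_load", "hrt", "longitude", "latitude", "elevation")
WATER_TYPES = ("inflow", "reservoir", "released")
SEASONS = ("August", "December")

ENV_COLUMNS = (
    "WT", "pH", "DO", "Chl_a", "yield", "ALK",
    "NO3_N", "NO2_N", "NH4_N", "PO4_P", "DSi",
    "Na", "K", "Mg", "Ca", "Cl", "SO4", "Sr",
)


class TableValidationError(ValueError):
    """Raised when a table violates its declared contract."""


@dataclass
class AbundanceTable:
    """A samples x features abundance matrix with annotations.

    Parameters
    ----------
    data:
        DataFrame with unique sample ids as index and unique feature ids as
        columns; all values finite and non-negative.
    domain:
        One of ``bacteria``, ``archaea``, ``function`` or ``microbial``
        (the concatenated bacteria+archaea table).
    scale:
        ``counts`` (sequencing reads), ``copies`` (qPCR copies per litre)
        or ``relative`` (per-sample fractions).
    feature_annotation:
        Optional map feature id -> group label (phylum or pathway name).
    """

    data: pd.DataFrame
    domain: str
    scale: str
    feature_annotation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if self.domain not in DOMAINS:
            raise TableValidationError(f"unknown domain {self.domain!r}; expected one of {DOMAINS}")
        if self.scale not in SCALES:
            raise TableValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample ids: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate feature ids: {dup}")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))
            cells = [(df.index[i], df.columns[j]) for i, j in bad[:5]]
            raise TableValidationError(f"non-finite or missing entries at {cells}")
        if (values < 0).any():
            bad = np.argwhere(values < 0)
            cells = [(df.index[i], df.columns[j]) for i, j in bad[:5]]
            raise TableValidationError(f"negative abundances at {cells}")
        if self.scale == "relative":
            sums = values.sum(axis=1)
            # a block-normalized microbial concatenation sums to one per block
            limit = 2.0 if self.domain == "microbial" else 1.0
            if not (np.isclose(sums, limit, atol=1e-9) | (sums <= limit + 1e-9)).all():
                bad = df.index[sums > limit + 1e-9].tolist()
                raise TableValidationError(f"relative rows exceeding {limit:g}: {bad}")
        if self.feature_annotation:
            missing = [f for f in self.feature_annotation if f not in df.columns]
            if missing:
                raise TableValidationError(f"annotation for unknown features: {missing[:5]}")

    # -- accessors --------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "AbundanceTable":
        annot = {f: g for f, g in self.feature_annotation.items() if f in data.columns}
        return AbundanceTable(data=data, domain=self.domain,
                              scale=scale or self.scale, feature_annotation=annot)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in table: {missing[:5]}")
        return self.with_data(self.data.loc[list(sample_ids)])


@dataclass
class AlignedBundle:
    """Tables, metadata and environment restricted to a common sample set."""

    tables: list[AbundanceTable]
    meta: pd.DataFrame | None
    env: pd.DataFrame | None
    dropped: dict[str, list[str]]

    @property
    def sample_ids(self) -> list[str]:
        return self.tables[0].sample_ids


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_matrix(path: str | Path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any() and not df[col].isna().any():
            row = df.index[converted.isna().argmax()]
            raise TableValidationError(
                f"non-numeric cell at sample {row!r}, feature {col!r} in {path}")
        df[col] = converted
    return df


def read_annotation(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Read a two-column (feature_id, group) sidecar file."""
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[1] < 2:
        raise TableValidationError(f"annotation file {path} needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_abundance_table(
    path: str | Path,
    domain: str,
    scale: str,
    orientation: str = "samples_as_rows",
    annotation_path: str | Path | None = None,
    sep: str = "\t",
) -> AbundanceTable:
    """Read a delimited abundance matrix.

    ``orientation`` must be ``samples_as_rows`` or ``features_as_rows``;
    there is deliberately no auto-detection.
    """
    if orientation not in ("samples_as_rows", "features_as_rows"):
        raise ValueError(f"orientation must be explicit, got {orientation!r}")
    df = _read_matrix(path, sep)
    if orientation == "features_as_rows":
        df = df.T
    annot = read_annotation(annotation_path, sep) if annotation_path else {}
    return AbundanceTable(data=df, domain=domain, scale=scale, feature_annotation=annot)


def write_abundance_table(table: AbundanceTable, path: str | Path,
                          annotation_path: str | Path | None = None) -> None:
    """Write the canonical TSV matrix (and optional annotation sidecar)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        table.data.to_csv(fh, sep="\t", index_label="sample_id", lineterminator="\n")
    if annotation_path and table.feature_annotation:
        with open(annotation_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("feature_id\tgroup\n")
            for feat, group in table.feature_annotation.items():
                fh.write(f"{feat}\t{group}\n")


def read_sample_frame(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    return validate_sample_frame(df)


def validate_sample_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLEFRAME_REQUIRED if c not in df.columns]
    if missing:
        raise TableValidationError(f"sample frame missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise TableValidationError(f"duplicate sample ids in metadata: {dup}")
    bad_wt = set(df["water_type"]) - set(WATER_TYPES)
    if bad_wt:
        raise TableValidationError(f"unknown water types: {sorted(bad_wt)}")
    bad_season = set(df["season"]) - set(SEASONS)
    if bad_season:
        raise TableValidationError(f"unknown seasons: {sorted(bad_season)}")
    if (df["depth_m"] < 0).any():
        raise TableValidationError("negative depth_m")
    if "hydraulic_load" in df.columns:
        h = df["hydraulic_load"].dropna()
        if (h <= 0).any():
            raise TableValidationError("hydraulic_load must be > 0 when present")
    return df.set_index("sample_id", drop=False)


def read_env_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    return validate_env_table(df)


def validate_env_table(df: pd.DataFrame) -> pd.DataFrame:
    if "sample_id" not in df.columns:
        raise TableValidationError("environment table missing sample_id column")
    if df["sample_id"].duplicated().any():
        raise TableValidationError("duplicate sample ids in environment table")
    if "pH" in df.columns:
        ph = df["pH"].dropna()
        if ((ph <= 0) | (ph >= 14)).any():
            raise TableValidationError("pH outside (0, 14)")
    if "yield" in df.columns:
        y = df["yield"].dropna()
        if ((y < 0) | (y > 1)).any():
            raise TableValidationError("yield outside [0, 1]")
    conc_cols = [c for c in df.columns if c not in ("sample_id", "pH", "WT")]
    for col in conc_cols:
        vals = pd.to_numeric(df[col], errors="coerce").dropna()
        if (vals < 0).any():
            raise TableValidationError(f"negative concentration in column {col!r}")
    return df.set_index("sample_id", drop=False)


def write_frame(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_samples(
    tables: Iterable[AbundanceTable],
    meta: pd.DataFrame | None = None,
    env: pd.DataFrame | None = None,
) -> AlignedBundle:
    """Restrict tables/metadata/environment to shared samples in one order.

    The canonical order is the first table's sample order filtered to the
    intersection; the operation is idempotent.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("align_samples requires at least one table")
    common = set(tables[0].sample_ids)
    for t in tables[1:]:
        common &= set(t.sample_ids)
    if meta is not None:
        common &= set(meta.index)
    if env is not None:
        common &= set(env.index)
    if not common:
        raise TableValidationError("empty sample intersection across inputs")
    order = [s for s in tables[0].sample_ids if s in common]
    dropped: dict[str, list[str]] = {}
    for i, t in enumerate(tables):
        lost = [s for s in t.sample_ids if s not in common]
        if lost:
            dropped[f"table_{i}_{t.domain}"] = lost
    aligned = [t.subset_samples(order) for t in tables]
    meta_out = meta.loc[order] if meta is not None else None
    env_out = env.loc[order] if env is not None else None
    return AlignedBundle(tables=aligned, meta=meta_out, env=env_out, dropped=dropped)
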