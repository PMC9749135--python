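"""Synthetic reservoir-microbiome generator.

Emulates the sampling design of a cascade-reservoir survey: four
reservoirs (CST, LT, YT, DH) sampled in August and December at an inflow
station, a depth profile inside the reservoir, and a released-water
station.  Taxonomic tables are phylum-level counts drawn from a multinomial
over Dirichlet-perturbed reservoir/season base compositions; functional
gene tables are coupled to the taxa through a sparse gene-content
(incidence) matrix whose column sparsity is the *functional redundancy* —
the number of taxa carrying each gene.  That coupling makes the F:T
statistic testable by parameter recovery: the more taxa share each gene,
the more taxonomic turnover averages out of the functional profile and the
lower F:T falls.

All randomness flows from a single integer seed through numpy's PCG64
generator; per-stage streams are derived as ``default_rng([seed, stage])``
so stages are independently reproducible.

What the generator does *not* emulate: phylogenetic structure, sequencing
error, OTU-level richness (tables are phylum-level), and any mechanistic
link between the environmental profiles and the community draws beyond the
shared design labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import AbundanceTable

# stage offsets for per-stage rng derivation
_STAGE = {"bacteria": 1, "archaea": 2, "gene_content": 3, "functions": 4, "env": 5}

#: paper-style depth profiles (m) per reservoir
DEFAULT_DEPTHS: dict[str, tuple[int, ...]] = {
    "CST": (0, 5, 10, 15, 30, 55),
    "LT": (0, 5, 10, 15, 30, 60, 80, 140),
    "YT": (0, 5, 10, 15, 30, 50),
    "DH": (0, 5, 10, 15, 25),
}

#: hydraulic load (m/yr-like) and retention time (days): CST/LT are yearly
#: regulated (low throughput, long HRT), YT/DH daily regulated.
DEFAULT_HYDRAULIC_LOAD = {"CST": 4.2, "LT": 7.5, "YT": 110.0, "DH": 180.0}
DEFAULT_HRT_DAYS = {"CST": 380.0, "LT": 310.0, "YT": 18.0, "DH": 8.0}

#: gene counts per pathway: C-cycling split CF/CD/CH4, plus N, P, S cycling
DEFAULT_PATHWAY_SIZES = {"C-fixation": 12, "C-degradation": 12, "CH4": 12,
                         "N": 22, "P": 8, "S": 5}


@dataclass
class GeneratorConfig:
    """Study-design and statistical parameters of the generator.

    ``dirichlet_concentration`` controls evenness of the bacterial base
    composition (small -> a few dominant phyla with a <1% tail);
    ``arc_concentration`` is the archaeal analogue and is lower, since
    archaeal communities in these systems are far less even than bacterial
    ones.  ``turnover`` scales the between-sample Dirichlet perturbation;
    inflow samples receive ``turnover * inflow_turnover_factor``,
    emulating riverine waters that are compositionally more volatile than
    the impounded water body.
    """

    reservoirs: tuple[str, ...] = ("CST", "LT", "YT", "DH")
    depths: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_DEPTHS))
    seasons: tuple[str, ...] = ("August", "December")
    n_bac_phyla: int = 57
    n_arc_phyla: int = 9
    n_genes: int = 71
    pathway_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PATHWAY_SIZES))
    dirichlet_concentration: float = 0.8
    arc_concentration: float = 0.25
    turnover: float = 0.3
    inflow_turnover_factor: float = 2.5
    redundancy: int = 5
    noise_sigma: float = 0.2
    library_size: int = 20000
    copies_scale: float = 3.0e5
    stratified_reservoirs: tuple[str, ...] = ("CST", "LT")
    stratified_season: Mapping[str, bool] = field(
        default_factory=lambda: {"August": True, "December": False})
    hydraulic_load: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HYDRAULIC_LOAD))
    hrt_days: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HRT_DAYS))
    seed: int = 0

    def __post_init__(self) -> None:
        n_taxa = self.n_bac_phyla + self.n_arc_phyla
        if not 1 <= self.redundancy <= n_taxa:
            raise ValueError(f"redundancy must be in [1, {n_taxa}]")
        for name in ("dirichlet_concentration", "arc_concentration",
                     "inflow_turnover_factor", "library_size", "copies_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.turnover < 0 or self.noise_sigma < 0:
            raise ValueError("turnover and noise_sigma must be >= 0")
        if sum(self.pathway_sizes.values()) != self.n_genes:
            raise ValueError("pathway sizes must sum to n_genes")
        for r in self.reservoirs:
            if r not in self.depths:
                raise ValueError(f"no depth profile for reservoir {r!r}")


def small_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A reduced design (2 reservoirs x 3 depths) for quick experiments."""
    defaults = dict(
        reservoirs=("CST", "YT"),
        depths={"CST": (0, 15, 55), "YT": (0, 15, 50)},
        n_bac_phyla=30, n_arc_phyla=8, n_genes=24,
        pathway_sizes={"C-fixation": 4, "C-degradation": 4, "CH4": 4,
                       "N": 6, "P": 3, "S": 3},
        library_size=5000,
        seed=seed,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

_COORDS = {"CST": (103.7, 25.6, 1640.0), "LT": (107.0, 25.0, 330.0),
           "YT": (107.5, 24.1, 220.0), "DH": (107.9, 23.9, 155.0)}


def sample_frame(config: GeneratorConfig) -> pd.DataFrame:
    """The deterministic sampling design shared by all generated tables."""
    rows = []
    for season in config.seasons:
        tag = season[:3]
        for res in config.reservoirs:
            lon, lat, elev = _COORDS.get(res, (106.0, 24.5, 300.0))
            common = dict(reservoir=res, season=season,
                          hydraulic_load=config.hydraulic_load[res],
                          hrt=config.hrt_days[res],
                          longitude=lon, latitude=lat, elevation=elev)
            rows.append(dict(sample_id=f"{res}-{tag}-IW", water_type="inflow",
                             depth_m=0.0, **common))
            for d in config.depths[res]:
                rows.append(dict(sample_id=f"{res}-{tag}-R{int(d):03d}",
                                 water_type="reservoir", depth_m=float(d), **common))
            rows.append(dict(sample_id=f"{res}-{tag}-RW", water_type="released",
                             depth_m=0.0, **common))
    df = pd.DataFrame(rows)
    return df.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# taxa
# ---------------------------------------------------------------------------

def _domain_counts(config: GeneratorConfig, meta: pd.DataFrame, n_taxa: int,
                   concentration: float, prefix: str, stage: int) -> pd.DataFrame:
    rng = np.random.default_rng([config.seed, stage])
    taxa = [f"{prefix}{i + 1:03d}" for i in range(n_taxa)]
    # domain-wide base: a few dominant phyla, long rare tail
    base = rng.dirichlet(np.full(n_taxa, concentration))
    base = np.maximum(base, 1e-12)
    counts = np.zeros((len(meta), n_taxa), dtype=np.int64)
    group_base: dict[tuple[str, str], np.ndarray] = {}
    for (res, season), _ in meta.groupby(["reservoir", "season"], sort=True):
        # moderate between-group compositional shift around the shared base
        group_base[(res, season)] = rng.dirichlet(base * 80.0 + 1e-9)
    for i, row in enumerate(meta.itertuples()):
        p = group_base[(row.reservoir, row.season)]
        turnover = config.turnover
        if row.water_type == "inflow":
            turnover *= config.inflow_turnover_factor
        if turnover > 0:
            alpha = np.maximum(p * 15.0 / turnover, 1e-9)
            p = rng.dirichlet(alpha)
        library = int(rng.integers(int(0.85 * config.library_size),
                                   int(1.15 * config.library_size) + 1))
        counts[i] = rng.multinomial(library, p / p.sum())
    return pd.DataFrame(counts, index=meta.index, columns=taxa)


def generate_taxa(config: GeneratorConfig,
                  meta: pd.DataFrame | None = None) -> tuple[AbundanceTable, AbundanceTable]:
    """Bacterial and archaeal phylum-level count tables over the design."""
    if meta is None:
        meta = sample_frame(config)
    bac_df = _domain_counts(config, meta, config.n_bac_phyla,
                            config.dirichlet_concentration, "BacPhylum",
                            _STAGE["bacteria"])
    arc_df = _domain_counts(config, meta, config.n_arc_phyla,
                            config.arc_concentration, "ArcPhylum",
                            _STAGE["archaea"])
    bac = AbundanceTable(data=bac_df, domain="bacteria", scale="counts",
                         feature_annotation={c: c for c in bac_df.columns})
    arc = AbundanceTable(data=arc_df, domain="archaea", scale="counts",
                         feature_annotation={c: c for c in arc_df.columns})
    return bac, arc


# ---------------------------------------------------------------------------
# gene content and functions
# ---------------------------------------------------------------------------

@dataclass
class GeneContentMatrix:
    """Taxa x genes incidence weights plus gene -> pathway labels.

    Each gene column has exactly ``redundancy`` nonzero entries with equal
    weight 1/redundancy: the simplest mechanism by which multiple taxa
    carry the same function.
    """

    incidence: pd.DataFrame
    pathway_of_gene: dict[str, str]

    def __post_init__(self) -> None:
        nz = (self.incidence.to_numpy() > 0).sum(axis=0)
        if len(set(nz)) > 1:
            raise ValueError("gene columns differ in redundancy")
        if (self.incidence.to_numpy() < 0).any():
            raise ValueError("negative incidence weights")

    @property
    def redundancy(self) -> int:
        return int((self.incidence.to_numpy() > 0).sum(axis=0)[0])


def gene_content_matrix(taxa_ids: list[str], config: GeneratorConfig) -> GeneContentMatrix:
    """Draw the sparse incidence matrix: ``redundancy`` carriers per gene."""
    rng = np.random.default_rng([config.seed, _STAGE["gene_content"]])
    n_taxa = len(taxa_ids)
    genes, pathway_of_gene = [], {}
    g = 0
    for pathway, size in config.pathway_sizes.items():
        for _ in range(size):
            g += 1
            gid = f"gene{g:03d}"
            genes.append(gid)
            pathway_of_gene[gid] = pathway
    W = np.zeros((n_taxa, len(genes)))
    for j in range(len(genes)):
        carriers = rng.choice(n_taxa, size=config.redundancy, replace=False)
        W[carriers, j] = 1.0 / config.redundancy
    incidence = pd.DataFrame(W, index=taxa_ids, columns=genes)
    return GeneContentMatrix(incidence=incidence, pathway_of_gene=pathway_of_gene)


def generate_functions(bac: AbundanceTable, arc: AbundanceTable,
                       G: GeneContentMatrix, noise_sigma: float,
                       config: GeneratorConfig) -> AbundanceTable:
    """Gene copy-number table coupled to the taxa through the incidence matrix.

    Per sample: gene abundance = (block-relative taxa vector . incidence)
    x multiplicative lognormal(0, sigma) noise x a copies-per-litre scale.
    Lognormal (not additive Gaussian) noise because qPCR copy numbers are
    positive and right-skewed.  With noise a small detection floor keeps
    the table strictly positive.
    """
    from .preprocess import to_relative
    from .efs import concat_domains

    taxa_rel = concat_domains(to_relative(bac), to_relative(arc), norm="block")
    # strip the block prefixes to match the incidence matrix's taxa ids
    X = taxa_rel.data.copy()
    X.columns = [c.split("|", 1)[1] for c in X.columns]
    missing = [t for t in X.columns if t not in G.incidence.index]
    if missing:
        raise ValueError(f"gene-content matrix does not cover taxa: {missing[:5]}")
    W = G.incidence.loc[list(X.columns)]
    genes = X.to_numpy() @ W.to_numpy()
    if noise_sigma > 0:
        rng = np.random.default_rng([config.seed, _STAGE["functions"]])
        genes = genes * rng.lognormal(0.0, noise_sigma, size=genes.shape)
        genes = np.maximum(genes, 1e-12)  # qPCR detection floor
    data = pd.DataFrame(genes * config.copies_scale, index=X.index,
                        columns=W.columns)
    return AbundanceTable(data=data, domain="function", scale="copies",
                          feature_annotation=dict(G.pathway_of_gene))


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def _thermocline(depth: float, max_depth: float, surface: float, bottom: float) -> float:
    """Logistic temperature profile with a thermocline near 12 m."""
    if max_depth <= 0:
        return surface
    z = (depth - 12.0) / 6.0
    frac = 1.0 / (1.0 + np.exp(-z))
    return surface - (surface - bottom) * frac


def generate_env(config: GeneratorConfig,
                 meta: pd.DataFrame | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Environmental table and sample metadata for the design.

    August profiles of the stratified (yearly regulated) reservoirs are
    monotone-decreasing in WT and DO with depth; December profiles are
    depth-homogeneous.  Values stay inside observed reservoir ranges
    (WT clipped to 13.3-29.5 C).
    """
    if meta is None:
        meta = sample_frame(config)
    rng = np.random.default_rng([config.seed, _STAGE["env"]])
    rows = []
    for row in meta.itertuples():
        res, season, depth = row.reservoir, row.season, row.depth_m
        max_depth = max(config.depths[res])
        stratified = (config.stratified_season.get(season, False)
                      and res in config.stratified_reservoirs)
        if season == "August":
            if stratified:
                surface = 27.5 + rng.normal(0, 0.4)
                bottom = 14.5 + rng.normal(0, 0.4)
                wt = _thermocline(depth, max_depth, surface, bottom)
                do = _thermocline(depth, max_depth, 9.0 + rng.normal(0, 0.3),
                                  1.0 + rng.normal(0, 0.2))
                ph = _thermocline(depth, max_depth, 8.4 + rng.normal(0, 0.05),
                                  7.3 + rng.normal(0, 0.05))
                chla = max(0.5, 22.0 * np.exp(-depth / 10.0) + rng.normal(0, 1.0))
            else:
                wt = 23.0 + rng.normal(0, 0.4)
                do = 7.5 + rng.normal(0, 0.4)
                ph = 7.8 + rng.normal(0, 0.08)
                chla = max(0.5, 4.0 + rng.normal(0, 1.0))
        else:  # December: homogenized water column
            wt = 17.0 + rng.normal(0, 0.25)
            do = 7.8 + rng.normal(0, 0.3)
            ph = 7.8 + rng.normal(0, 0.08)
            chla = max(0.5, 3.0 + rng.normal(0, 0.8))
        if row.water_type == "inflow":
            do += 2.0  # riverine inflow is better aerated
        wt = float(np.clip(wt, 13.3, 29.5))
        do = float(np.clip(do, 0.2, 15.5))
        ph = float(np.clip(ph, 7.1, 9.0))

        ca = rng.normal(1300.0, 120.0) if res == "CST" else rng.normal(900.0, 90.0)
        ca = max(ca, 300.0)
        ca_sr = rng.normal(1460.0, 150.0) if res == "CST" else rng.normal(480.0, 60.0)
        ca_sr = max(ca_sr, 280.0)
        sr_mg = ca / ca_sr * 87.62 / 1000.0
        no3 = max(5.0, rng.normal(330.0, 60.0) if res == "CST" else rng.normal(120.0, 25.0))
        rows.append(dict(
            sample_id=row.sample_id,
            WT=wt, pH=ph, DO=do, Chl_a=chla,
            **{"yield": float(np.clip(rng.normal(0.32, 0.06), 0.15, 0.46))},
            ALK=max(5e-4, rng.normal(2.5e-3, 3e-4)),
            NO3_N=no3, NO2_N=max(0.0, rng.normal(2.0, 0.6)),
            NH4_N=max(0.0, rng.normal(15.0, 4.0)),
            PO4_P=max(0.05, rng.normal(1.0, 0.5)),
            DSi=float(np.clip(rng.normal(160.0, 55.0), 30.0, 340.0)),
            Na=max(10.0, rng.normal(250.0, 40.0)),
            K=max(5.0, rng.normal(50.0, 10.0)),
            Mg=max(50.0, rng.normal(450.0, 60.0)),
            Ca=ca, Cl=max(10.0, rng.normal(220.0, 40.0)),
            SO4=float(np.clip(rng.normal(400.0, 120.0), 10.0, 800.0)),
            Sr=sr_mg,
        ))
    env = pd.DataFrame(rows).set_index("sample_id", drop=False)
    return env, meta


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    bacteria: AbundanceTable
    archaea: AbundanceTable
    genes: AbundanceTable
    gene_content: GeneContentMatrix
    env: pd.DataFrame
    meta: pd.DataFrame
    config: GeneratorConfig


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate the full coupled dataset (taxa, genes, environment, design)."""
    meta = sample_frame(config)
    bac, arc = generate_taxa(config, meta)
    G = gene_content_matrix(list(bac.feature_ids) + list(arc.feature_ids), config)
    genes = generate_functions(bac, arc, G, config.noise_sigma, config)
    env, meta = generate_env(config, meta)
    return SyntheticDataset(bacteria=bac, archaea=arc, genes=genes,
                            gene_content=G, env=env, meta=meta, config=config)
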