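"""Synthetic data with known truth for every analysis stage.

The generator emulates the structure of a regional ancient-DNA study:

* allele frequencies drifting along a small admixture graph
  (Balding-Nichols sampling per drift edge, calibrated so the realized f2
  between parent and child equals the nominal edge length);
* pseudo-haploid genotype sampling with heavy per-individual missingness
  (drawn from 50-95%, as typical for ancient capture data);
* admixed target cohorts built as Markov ancestry mosaics with a known
  admixture proportion and date in generations, for dating recovery;
* site metadata along a parametric coastline with five contiguous
  regions, language/diet labels assigned by region, calibrated date
  ranges spanning roughly 6600-100 calBP, and a coastal route network.

Everything is seed-deterministic: same configuration + seed, same output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from popkit.genotype_io import (
    GenotypeTable,
    IndividualRecord,
    MISSING,
    SnpPanel,
)
from popkit.mixture import AdmixtureGraph
from popkit.explanatory import RouteNetwork, Site, REGIONS

_TRANSVERSION_PAIRS = [("A", "C"), ("A", "T"), ("C", "G"), ("G", "T")]
_TRANSITION_PAIRS = [("A", "G"), ("C", "T")]


# ---------------------------------------------------------------------------
# Panel


def make_panel(
    n_snps: int,
    n_chromosomes: int = 20,
    chrom_length_morgans: float = 1.0,
    cm_per_mb: float = 1.0,
    rng: np.random.Generator | None = None,
    transversion_fraction: float = 0.5,
) -> SnpPanel:
    """Random SNP panel on a uniform genetic map.

    SNPs are spread evenly across chromosomes at uniform random genetic
    positions; physical positions follow the uniform ``cm_per_mb`` map
    (default 1 cM/Mb, so 5-Mb jackknife blocks and centimorgan distance
    bins interoperate without a map file).
    """
    rng = np.random.default_rng(rng)
    per = np.full(n_chromosomes, n_snps // n_chromosomes)
    per[: n_snps % n_chromosomes] += 1
    rows = []
    sid = 0
    for c in range(n_chromosomes):
        g = np.sort(rng.uniform(0, chrom_length_morgans, per[c]))
        bp = np.unique(np.round(g * 1e8 / cm_per_mb).astype(np.int64) + 1)
        while len(bp) < per[c]:  # collisions are vanishingly rare; pad
            extra = rng.integers(1, int(chrom_length_morgans * 1e8), per[c] - len(bp))
            bp = np.unique(np.concatenate([bp, extra]))
        bp = bp[: per[c]]
        g = (bp - 1) * cm_per_mb / 1e8
        is_tv = rng.random(per[c]) < transversion_fraction
        for k in range(per[c]):
            pool = _TRANSVERSION_PAIRS if is_tv[k] else _TRANSITION_PAIRS
            ref, alt = pool[rng.integers(len(pool))]
            if rng.random() < 0.5:
                ref, alt = alt, ref
            rows.append(
                (f"rs{sid}", str(c + 1), int(bp[k]), float(g[k]), ref, alt)
            )
            sid += 1
    df = pd.DataFrame(
        rows,
        columns=["snp_id", "chromosome", "physical_pos", "genetic_pos", "ref_allele", "alt_allele"],
    )
    return SnpPanel(df)


# ---------------------------------------------------------------------------
# Graph-drift frequencies


@dataclass
class DemographyModel:
    """A demography for frequency simulation.

    Drift edges of the admixture graph are in f2 units. Sample sizes are
    per leaf; individual missingness rates are drawn uniformly from
    ``missingness_range`` (ancient-DNA-like 50-95% by default).
    """

    graph: AdmixtureGraph
    sample_sizes: Mapping[str, int]
    n_snps: int = 50_000
    n_chromosomes: int = 20
    chrom_length_morgans: float = 1.0
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    missingness_range: tuple[float, float] = (0.5, 0.95)
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.missingness_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("missingness must lie in [0, 1)")


def _balding_nichols(
    p: np.ndarray, f2_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Drift child frequencies so that E[(child - p)^2 | p] = f2_length."""
    if f2_length == 0:
        return p.copy()
    interior = (p > 0) & (p < 1)  # fixed SNPs cannot drift further
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        f_prime = np.where(interior, f2_length / (p * (1 - p)), np.nan)
    # SNPs already near fixation cannot carry the full edge variance;
    # clip their F' (undershooting f2 there) but refuse edges so long
    # that clipping would distort the overall calibration
    clip_frac = float(np.mean(f_prime[interior] >= 1.0)) if interior.any() else 0.0
    if clip_frac > 0.2:
        raise ValueError(
            f"drift length {f2_length} too large for the current frequencies "
            f"({clip_frac:.0%} of SNPs would exceed the Balding-Nichols bound)"
        )
    f_prime = np.clip(f_prime, None, 0.98)
    out = p.copy()
    fp = f_prime[interior]
    pi = p[interior]
    a = np.maximum(pi * (1 - fp) / fp, 1e-8)
    b = np.maximum((1 - pi) * (1 - fp) / fp, 1e-8)
    out[interior] = rng.beta(a, b)
    return out


def simulate_frequencies(
    model: DemographyModel, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Per-leaf allele frequencies from graph drift.

    Ancestral frequencies are uniform on ``ancestral_range`` (bounded away
    from fixation so panels stay polymorphic); each drift edge applies
    Balding-Nichols resampling; an admixture node mixes its parents'
    frequencies linearly by the mixing proportion.
    """
    import networkx as nx

    rng = np.random.default_rng(model.seed if rng is None else rng)
    g = model.graph
    g.validate()
    lo, hi = model.ancestral_range
    freqs: dict[str, np.ndarray] = {}
    for node in nx.topological_sort(g.g):
        parents = list(g.g.in_edges(node, data=True))
        if not parents:
            freqs[node] = rng.uniform(lo, hi, model.n_snps)
        elif len(parents) == 1:
            (pa, _, data), = parents
            freqs[node] = _balding_nichols(freqs[pa], data["length"], rng)
        else:
            mixed = np.zeros(model.n_snps)
            for pa, _, data in parents:
                mixed += data["weight"] * freqs[pa]
            freqs[node] = mixed
    return {leaf: freqs[leaf] for leaf in g.leaves}


def sample_pseudohaploid(
    panel: SnpPanel,
    frequencies: Mapping[str, np.ndarray],
    sample_sizes: Mapping[str, int],
    missingness: float | tuple[float, float] | Mapping[str, float] = 0.0,
    rng: np.random.Generator | int | None = None,
    individuals: Sequence[IndividualRecord] | None = None,
) -> GenotypeTable:
    """Draw pseudo-haploid genotypes: one Bernoulli(freq) allele per site.

    ``missingness`` is a scalar rate, a (lo, hi) range sampled per
    individual, or a per-group mapping. Individual ids are
    ``<group>_<k>`` unless explicit records are supplied.
    """
    rng = np.random.default_rng(rng)
    S = len(panel)
    cols, inds = [], []
    for group, n in sample_sizes.items():
        f = np.asarray(frequencies[group])
        if len(f) != S:
            raise ValueError(f"frequencies for {group} do not match panel size")
        for k in range(n):
            if isinstance(missingness, Mapping):
                miss = float(missingness.get(group, 0.0))
            elif isinstance(missingness, tuple):
                miss = float(rng.uniform(*missingness))
            else:
                miss = float(missingness)
            calls = (rng.random(S) < f).astype(np.int8)
            if miss > 0:
                calls[rng.random(S) < miss] = MISSING
            cols.append(calls)
            inds.append(
                IndividualRecord(
                    individual_id=f"{group}_{k}",
                    group_label=group,
                    ploidy_mode="pseudo-haploid",
                )
            )
    if individuals is not None:
        if len(individuals) != len(inds):
            raise ValueError("individual records do not match sample sizes")
        inds = list(individuals)
    return GenotypeTable(panel, inds, np.column_stack(cols))


def simulate_demography(
    model: DemographyModel,
) -> tuple[GenotypeTable, dict[str, np.ndarray]]:
    """Panel + frequencies + pseudo-haploid sampling in one call."""
    rng = np.random.default_rng(model.seed)
    panel = make_panel(
        model.n_snps, model.n_chromosomes, model.chrom_length_morgans, rng=rng
    )
    freqs = simulate_frequencies(model, rng)
    table = sample_pseudohaploid(
        panel, freqs, model.sample_sizes, model.missingness_range, rng
    )
    return table, freqs


# ---------------------------------------------------------------------------
# Mosaic admixture


@dataclass
class MosaicConfig:
    """Configuration for a Markov ancestry-mosaic admixed cohort.

    ``alpha`` is the proportion of source-A ancestry, ``generations`` the
    age of the admixture pulse (segment lengths are Exponential with rate
    ``generations`` per Morgan), mirroring dates of the order 10-70
    generations typical for Holocene admixture events.
    """

    alpha: float
    generations: float
    n_samples: int
    n_source_haplotypes: int = 100
    missingness: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass
class MosaicResult:
    table: GenotypeTable
    realized_alpha: float
    mean_segment_length: float
    n_segments: int


def simulate_mosaic_admixture(
    config: MosaicConfig,
    panel: SnpPanel,
    freqA: np.ndarray,
    freqB: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> MosaicResult:
    """Admixed pseudo-haploid cohort with known admixture date.

    Source haplotype panels are drawn as Bernoulli(freq) per source. Each
    admixed chromosome is a Markov mosaic: crossover points form a Poisson
    process of rate ``generations`` per Morgan, each segment copies a
    random haplotype from the source chosen Bernoulli(alpha). Warns if the
    expected number of switch points per chromosome is below one.
    """
    import warnings

    rng = np.random.default_rng(config.seed if rng is None else rng)
    df = panel.df
    S = len(panel)
    H = config.n_source_haplotypes
    hapA = (rng.random((H, S)) < freqA).astype(np.int8)
    hapB = (rng.random((H, S)) < freqB).astype(np.int8)
    chrom_groups = [
        (chrom, sub.index.to_numpy(), sub["genetic_pos"].to_numpy())
        for chrom, sub in df.groupby("chromosome", sort=False)
    ]
    min_len = min(g[-1] - g[0] if len(g) > 1 else 0.0 for _, _, g in chrom_groups)
    if config.generations * min_len < 1:
        warnings.warn(
            "expected < 1 ancestry switch per chromosome; the decay curve "
            "will carry little date information",
            stacklevel=2,
        )
    calls = np.empty((S, config.n_samples), dtype=np.int8)
    n_a = 0
    n_tot = 0
    seg_lengths = []
    for i in range(config.n_samples):
        for _, idx, g in chrom_groups:
            L = g[-1] if len(g) else 0.0
            n_break = rng.poisson(config.generations * L)
            breaks = np.sort(rng.uniform(0, L, n_break))
            seg = np.searchsorted(breaks, g, side="right")
            n_seg = n_break + 1
            src_a = rng.random(n_seg) < config.alpha
            hap_choice = rng.integers(H, size=n_seg)
            edges = np.concatenate([[0.0], breaks, [L]])
            seg_lengths.extend(np.diff(edges))
            out = np.empty(len(idx), dtype=np.int8)
            for s_id in np.unique(seg):
                m = seg == s_id
                src = hapA if src_a[s_id] else hapB
                out[m] = src[hap_choice[s_id], idx[m]]
                if src_a[s_id]:
                    n_a += int(m.sum())
            n_tot += len(idx)
            calls[idx, i] = out
        if config.missingness > 0:
            miss = rng.random(S) < config.missingness
            calls[miss, i] = MISSING
    inds = [
        IndividualRecord(individual_id=f"admixed_{i}", group_label="Admixed")
        for i in range(config.n_samples)
    ]
    return MosaicResult(
        GenotypeTable(panel, inds, calls),
        realized_alpha=n_a / n_tot if n_tot else float("nan"),
        mean_segment_length=float(np.mean(seg_lengths)) if seg_lengths else float("nan"),
        n_segments=len(seg_lengths),
    )


# ---------------------------------------------------------------------------
# Five-region study structure


def five_region_cline_graph(
    endpoint_drift: float = 0.02, private_drift: float = 0.005
) -> AdmixtureGraph:
    """An admixture cline of five leaves mirroring the coastal region order.

    Two endpoint lineages P and Q each accumulate ``endpoint_drift`` f2
    units; region k along the coast derives k/4 of its ancestry from Q and
    the rest from P (mixture among neighbors producing a genetic cline
    correlated with coastal ordering), plus ``private_drift`` of its own.
    Leaf order along the cline follows the coastline: WesternArchipelago -
    BeagleChannel - MitrePeninsula - NorthTierraDelFuego - SouthContinent.
    """
    g = AdmixtureGraph()
    g.add_edge("Root", "Anc", 0.0)
    g.add_edge("Anc", "P", endpoint_drift)
    g.add_edge("Anc", "Q", endpoint_drift)
    for k, region in enumerate(REGIONS):
        alpha_q = k / (len(REGIONS) - 1)
        if alpha_q == 0.0:
            g.add_edge("P", region, private_drift)
        elif alpha_q == 1.0:
            g.add_edge("Q", region, private_drift)
        else:
            g.add_admixture(f"M{k}", "P", 1.0 - alpha_q, "Q")
            g.add_edge(f"M{k}", region, private_drift)
    return g


def outgroup_cline_graph(
    endpoint_drift: float = 0.02,
    private_drift: float = 0.005,
    outgroup_drift: float = 0.04,
) -> AdmixtureGraph:
    """Five-region admixture cline plus a deep outgroup for outgroup-f3."""
    g = five_region_cline_graph(endpoint_drift, private_drift)
    g.g.remove_edge("Root", "Anc")
    g.add_edge("Root", "Split", 0.0)
    g.add_edge("Split", "Outgroup", outgroup_drift)
    g.add_edge("Split", "Anc", 0.02)
    g.validate()
    return g


def admixture_study_graph(alpha: float = 0.5, target_drift: float = 0.005) -> AdmixtureGraph:
    """A nested tree with an admixed target, for proportion-recovery studies.

    Two source lineages S1 and S2 sit in sister clades that each also hold
    a right population (R3 with S1, R4 with S2), with further rights (R1,
    R2) and an outgroup O branching off at successively deeper splits.
    The nesting makes the rights differentially related to the two
    sources, which is what renders the mixture weights identifiable. The
    target T is an ``alpha`` : 1-alpha mix of the S1- and S2-side stems
    with ``target_drift`` of its own.
    """
    g = AdmixtureGraph()
    g.add_edge("Root", "O", 0.04)
    g.add_edge("Root", "X0", 0.01)
    g.add_edge("X0", "R1", 0.02)
    g.add_edge("X0", "X1", 0.01)
    g.add_edge("X1", "R2", 0.02)
    g.add_edge("X1", "X2", 0.01)
    g.add_edge("X2", "A0", 0.01)
    g.add_edge("X2", "B0", 0.01)
    g.add_edge("A0", "S1p", 0.005)
    g.add_edge("S1p", "S1", 0.005)
    g.add_edge("A0", "R3", 0.02)
    g.add_edge("B0", "S2p", 0.005)
    g.add_edge("S2p", "S2", 0.005)
    g.add_edge("B0", "R4", 0.02)
    g.add_admixture("Tpre", "S1p", alpha, "S2p")
    g.add_edge("Tpre", "T", target_drift)
    g.validate()
    return g


@dataclass
class StudyMetadata:
    individuals: list[IndividualRecord]
    sites: dict[str, Site]
    network: RouteNetwork
    coast_position: dict[str, float]  # site -> arc-length parameter in [0, 1]


_REGION_DATES = {  # (upper, lower) calBP sampling bounds per region
    "WesternArchipelago": (4700, 300),
    "BeagleChannel": (6600, 100),
    "MitrePeninsula": (1500, 300),
    "NorthTierraDelFuego": (2400, 200),
    "SouthContinent": (4700, 300),
}

_REGION_D15N = {  # means for maritime / mixed / terrestrial diets, permil
    "WesternArchipelago": 19.5,
    "BeagleChannel": 19.0,
    "MitrePeninsula": 16.0,
    "NorthTierraDelFuego": 13.0,
    "SouthContinent": 12.5,
}


def simulate_metadata(
    n_sites: int = 15,
    inds_per_site: int = 2,
    seed: int | None = None,
) -> StudyMetadata:
    """Sites along a parametric coastline, five contiguous regions, dates.

    Sites sit on a smooth coastal arc; the five regions partition the arc
    in coastline order, so geographic distance tracks arc position. The
    route network is the chain of site-adjacent waypoints along the coast
    (encoding the maritime/terrestrial crossings explicitly as network
    topology). Dates (95.4% ranges) and δ15N values are drawn per region.
    """
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 1, n_sites))
    # keep sites apart so same-site pairs only occur by construction
    region_of = lambda x: REGIONS[min(int(x * 5), 4)]
    lat = -55.5 + 3.0 * np.sin(np.pi * t)
    lon = -75.0 + 9.0 * t
    sites: dict[str, Site] = {}
    coast_position: dict[str, float] = {}
    individuals: list[IndividualRecord] = []
    waypoints: dict[str, tuple[float, float]] = {}
    edges: list[tuple[str, str]] = []
    prev_wp = None
    for k in range(n_sites):
        region = region_of(t[k])
        name = f"Site{k:02d}"
        sites[name] = Site(name, region, float(lat[k]), float(lon[k]))
        coast_position[name] = float(t[k])
        wp = f"W{k:02d}"
        waypoints[wp] = (float(lat[k]), float(lon[k]))
        if prev_wp is not None:
            edges.append((prev_wp, wp))
        prev_wp = wp
        hi, lo = _REGION_DATES[region]
        for j in range(inds_per_site):
            mid = rng.uniform(lo, hi)
            half = rng.uniform(50, 200)
            individuals.append(
                IndividualRecord(
                    individual_id=f"I{k:02d}{j}",
                    group_label=f"{region}_{name}_{int(round(mid, -2))}BP",
                    region=region,
                    site=name,
                    latitude=float(lat[k]),
                    longitude=float(lon[k]),
                    date_range_calbp=(mid + half, max(mid - half, 0.0)),
                    delta15N=float(rng.normal(_REGION_D15N[region], 0.8)),
                )
            )
    network = RouteNetwork(waypoints, edges)
    return StudyMetadata(individuals, sites, network, coast_position)


def default_study(
    seed: int | None = None,
    n_snps: int = 20_000,
    samples_per_region: int = 4,
) -> tuple[GenotypeTable, StudyMetadata, dict[str, np.ndarray]]:
    """A complete synthetic study: genotypes + metadata for the five regions.

    Builds the outgroup + five-region cline demography, samples
    pseudo-haploid genotypes with ancient-DNA missingness for the regional
    individuals (the outgroup is sampled at low missingness, as a
    high-quality reference panel would be), and attaches coastline
    metadata so genetic drift distance increases with coastal position.
    """
    rng = np.random.default_rng(seed)
    graph = outgroup_cline_graph()
    meta = simulate_metadata(
        n_sites=5 * samples_per_region, inds_per_site=1, seed=int(rng.integers(2**31))
    )
    by_region: dict[str, list[IndividualRecord]] = {r: [] for r in REGIONS}
    for ind in meta.individuals:
        by_region[ind.region].append(ind)
    sizes = {r: max(2, len(by_region[r])) for r in REGIONS}
    model = DemographyModel(
        graph,
        {**sizes, "Outgroup": 10},
        n_snps=n_snps,
        seed=int(rng.integers(2**31)),
    )
    panel = make_panel(model.n_snps, model.n_chromosomes, rng=rng)
    freqs = simulate_frequencies(model, rng)
    # pad metadata if a region drew fewer sites than requested samples
    records: list[IndividualRecord] = []
    for region in REGIONS:
        pool = by_region[region]
        while len(pool) < sizes[region]:
            clone = pool[len(pool) % max(len(pool), 1)] if pool else None
            k = len(pool)
            if clone is None:
                site = next(iter(meta.sites.values()))
                clone = IndividualRecord(
                    individual_id=f"{region}_extra{k}", region=region, site=site.name,
                    latitude=site.latitude, longitude=site.longitude,
                    date_range_calbp=(1000.0, 800.0), group_label=region,
                )
                pool.append(clone)
                continue
            pool.append(
                IndividualRecord(
                    individual_id=f"{clone.individual_id}_b{k}",
                    group_label=clone.group_label,
                    region=region,
                    site=clone.site,
                    latitude=clone.latitude,
                    longitude=clone.longitude,
                    date_range_calbp=clone.date_range_calbp,
                    delta15N=clone.delta15N,
                )
            )
        records.extend(pool[: sizes[region]])
    out_records = [
        IndividualRecord(individual_id=f"Outgroup_{k}", group_label="Outgroup")
        for k in range(10)
    ]
    table = sample_pseudohaploid(
        panel,
        freqs,
        {**{r: sizes[r] for r in REGIONS}, "Outgroup": 10},
        missingness={**{r: 0.6 for r in REGIONS}, "Outgroup": 0.05},
        rng=rng,
        individuals=[*records, *out_records],
    )
    meta.individuals = records
    return table, meta, freqs
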