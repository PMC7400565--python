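"""EIGENSTRAT genotype I/O, SNP/individual filters, jackknife blocks.

Genotypes are stored SNP-major as small integers: the count of the
alternate allele among the observed allele draws for that individual.
Pseudo-haploid individuals (one random sequence read per site, the standard
representation for low-coverage ancient DNA) take values {0, 1}; diploid
individuals take {0, 1, 2}. ``MISSING`` (9, the EIGENSTRAT convention)
marks no data.

Genetic positions are held in Morgans internally. EIGENSTRAT ``.snp``
files in the wild carry either Morgans or centimorgans in column 3; a
heuristic flags probable cM input (median per-chromosome span > 3) and
``read_eigenstrat(..., rescale_cm=True)`` divides by 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = 9

_TRANSITIONS = ({"A", "G"}, {"C", "T"})

REGION_NAMES = (
    "WesternArchipelago",
    "BeagleChannel",
    "MitrePeninsula",
    "NorthTierraDelFuego",
    "SouthContinent",
    "Other",
)


class EigenstratFormatError(ValueError):
    """Raised when a .geno/.snp/.ind trio is malformed or inconsistent."""


def is_transversion(ref: str, alt: str) -> bool:
    pair = {ref.upper(), alt.upper()}
    return pair not in _TRANSITIONS


@dataclass
class SnpPanel:
    """A SNP panel: ids, positions (physical bp 1-based, genetic Morgans), alleles.

    Backed by a pandas DataFrame with columns
    ``snp_id, chromosome, physical_pos, genetic_pos, ref_allele, alt_allele,
    is_transversion`` and optionally ``is_cpg_transition``.
    """

    df: pd.DataFrame

    REQUIRED = (
        "snp_id",
        "chromosome",
        "physical_pos",
        "genetic_pos",
        "ref_allele",
        "alt_allele",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"panel missing columns: {missing}")
        if "is_transversion" not in self.df.columns:
            self.df = self.df.assign(
                is_transversion=[
                    is_transversion(r, a)
                    for r, a in zip(self.df["ref_allele"], self.df["alt_allele"])
                ]
            )
        bad = self.df["ref_allele"].astype(str).str.upper() == self.df[
            "alt_allele"
        ].astype(str).str.upper()
        if bad.any():
            raise ValueError(
                f"ref and alt alleles identical at {int(bad.sum())} SNPs "
                f"(first: {self.df.loc[bad, 'snp_id'].iloc[0]})"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_cpg_annotation(self) -> bool:
        return "is_cpg_transition" in self.df.columns

    def validate_sorted(self) -> None:
        """Check physical positions strictly increasing within chromosomes."""
        for chrom, sub in self.df.groupby("chromosome", sort=False):
            pos = sub["physical_pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"panel not sorted: non-increasing physical_pos on chromosome {chrom}"
                )
            gen = sub["genetic_pos"].to_numpy()
            if np.any(np.diff(gen) < 0):
                raise ValueError(
                    f"decreasing genetic_pos on chromosome {chrom}"
                )


@dataclass
class IndividualRecord:
    """Metadata for one individual.

    ``group_label`` follows the Region_SiteName_AgeBP nomenclature common in
    aDNA studies. ``date_range_calbp`` is the (upper, lower) bound of the
    95.4% calibrated interval, or the string ``"modern"``.
    """

    individual_id: str
    group_label: str = ""
    region: str = "Other"
    site: str = ""
    latitude: float = float("nan")
    longitude: float = float("nan")
    date_range_calbp: tuple[float, float] | str | None = None
    delta15N: float | None = None
    ploidy_mode: str = "pseudo-haploid"
    sex: str = "U"

    def __post_init__(self) -> None:
        if self.ploidy_mode not in ("pseudo-haploid", "diploid"):
            raise ValueError(f"bad ploidy_mode {self.ploidy_mode!r}")
        if isinstance(self.date_range_calbp, tuple):
            hi, lo = self.date_range_calbp
            if hi < lo:
                raise ValueError(
                    f"{self.individual_id}: date range upper {hi} < lower {lo}"
                )
        if np.isfinite(self.latitude) and not -90 <= self.latitude <= 90:
            raise ValueError(f"latitude {self.latitude} out of range")
        if np.isfinite(self.longitude) and not -180 <= self.longitude <= 180:
            raise ValueError(f"longitude {self.longitude} out of range")

    @property
    def date_midpoint_calbp(self) -> float:
        """Midpoint of the 95.4% calibrated range; 0 for modern individuals."""
        if self.date_range_calbp == "modern":
            return 0.0
        if isinstance(self.date_range_calbp, tuple):
            return 0.5 * (self.date_range_calbp[0] + self.date_range_calbp[1])
        raise ValueError(f"{self.individual_id}: no date information")


@dataclass
class GenotypeTable:
    """SNP-major genotype matrix plus panel and individual metadata.

    ``calls`` has shape (n_snps, n_individuals); entries are alt-allele
    counts among observed draws, or ``MISSING``.
    """

    panel: SnpPanel
    individuals: list[IndividualRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.panel), len(self.individuals)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match panel x individuals "
                f"({len(self.panel)}, {len(self.individuals)})"
            )
        self._check_ploidy()

    def _check_ploidy(self) -> None:
        for j, ind in enumerate(self.individuals):
            col = self.calls[:, j]
            ok = (col == MISSING) | (col == 0) | (col == 1)
            if ind.ploidy_mode == "diploid":
                ok |= col == 2
            if not ok.all():
                bad = col[~ok][0]
                raise ValueError(
                    f"individual {ind.individual_id} ({ind.ploidy_mode}) has "
                    f"invalid call {bad}"
                )

    @property
    def individual_ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals]

    def n_snps_covered(self) -> np.ndarray:
        """Non-missing SNP count per individual."""
        return (self.calls != MISSING).sum(axis=0)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeTable(
            SnpPanel(self.panel.df.loc[mask].reset_index(drop=True)),
            list(self.individuals),
            self.calls[mask],
        )

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeTable":
        index = {iid: j for j, iid in enumerate(self.individual_ids)}
        cols = [index[i] for i in ids]
        return GenotypeTable(
            self.panel,
            [self.individuals[j] for j in cols],
            self.calls[:, cols],
        )


@dataclass
class BlockPartition:
    """Assignment of SNPs to contiguous jackknife blocks.

    Blocks never span chromosomes and cover at most ``span_bp`` of physical
    distance each. Weights (SNPs actually used per block) are statistic-
    specific and computed at estimation time from a usage mask.
    """

    block_index: np.ndarray
    n_blocks: int
    span_bp: int

    def __post_init__(self) -> None:
        self.block_index = np.asarray(self.block_index, dtype=np.int64)

    def weights(self, used: np.ndarray | None = None) -> np.ndarray:
        """SNPs used per block; ``used`` is a boolean per-SNP mask."""
        if used is None:
            used = np.ones(len(self.block_index), dtype=bool)
        return np.bincount(
            self.block_index[used], minlength=self.n_blocks
        ).astype(float)

    def block_sums(self, values: np.ndarray, used: np.ndarray) -> np.ndarray:
        """Sum per block of per-SNP ``values`` over ``used`` SNPs.

        ``values`` may be (S,) or (S, m); returns (B,) or (B, m).
        """
        idx = self.block_index[used]
        vals = np.asarray(values, dtype=float)[used]
        if vals.ndim == 1:
            return np.bincount(idx, weights=vals, minlength=self.n_blocks)
        out = np.empty((self.n_blocks, vals.shape[1]))
        for k in range(vals.shape[1]):
            out[:, k] = np.bincount(idx, weights=vals[:, k], minlength=self.n_blocks)
        return out


# ---------------------------------------------------------------------------
# EIGENSTRAT I/O


def _detect_cm(panel_df: pd.DataFrame) -> bool:
    spans = panel_df.groupby("chromosome")["genetic_pos"].agg(lambda g: g.max() - g.min())
    if len(spans) == 0:
        return False
    return float(np.median(spans)) > 3.0


def read_eigenstrat(
    geno_path,
    snp_path,
    ind_path,
    *,
    rescale_cm: bool = False,
) -> GenotypeTable:
    """Read an EIGENSTRAT .geno/.snp/.ind trio (digit-string dialect).

    ``.snp`` columns: id, chromosome, genetic_pos, physical_pos, ref, alt.
    ``.geno`` rows are SNP-major digit strings, 9 = missing. Individuals
    whose observed calls never exceed 1 are loaded as pseudo-haploid.

    If the genetic-position column looks like centimorgans (median
    per-chromosome span > 3) a warning is issued; pass ``rescale_cm=True``
    to divide by 100 on read.
    """
    snp = pd.read_csv(
        snp_path,
        sep=r"\s+",
        header=None,
        names=["snp_id", "chromosome", "genetic_pos", "physical_pos", "ref_allele", "alt_allele"],
        dtype={"snp_id": str, "chromosome": str, "ref_allele": str, "alt_allele": str},
    )
    if snp.shape[1] != 6:
        raise EigenstratFormatError(f"{snp_path}: expected 6 .snp columns")
    ind = pd.read_csv(
        ind_path,
        sep=r"\s+",
        header=None,
        names=["individual_id", "sex", "group_label"],
        dtype=str,
    )
    n_ind = len(ind)
    rows = []
    with open(geno_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if len(line) != n_ind:
                raise EigenstratFormatError(
                    f"{geno_path}:{lineno}: line has {len(line)} genotypes, "
                    f"{n_ind} individuals declared"
                )
            if not line.isdigit():
                raise EigenstratFormatError(
                    f"{geno_path}:{lineno}: non-digit genotype character"
                )
            rows.append(np.frombuffer(line.encode(), dtype=np.uint8) - ord("0"))
    if len(rows) != len(snp):
        raise EigenstratFormatError(
            f"{geno_path}: {len(rows)} genotype lines but {len(snp)} SNPs in {snp_path}"
        )
    calls = (
        np.asarray(rows, dtype=np.int8)
        if rows
        else np.empty((0, n_ind), dtype=np.int8)
    )
    if _detect_cm(snp):
        if rescale_cm:
            snp = snp.assign(genetic_pos=snp["genetic_pos"] / 100.0)
        else:
            warnings.warn(
                "genetic positions look like centimorgans (median per-chromosome "
                "span > 3 Morgans); pass rescale_cm=True to convert",
                stacklevel=2,
            )
    individuals = []
    for j in range(n_ind):
        col = calls[:, j] if len(calls) else np.empty(0, dtype=np.int8)
        observed = col[col != MISSING]
        mode = "diploid" if (observed == 2).any() else "pseudo-haploid"
        individuals.append(
            IndividualRecord(
                individual_id=ind["individual_id"][j],
                sex=ind["sex"][j],
                group_label=ind["group_label"][j],
                ploidy_mode=mode,
            )
        )
    return GenotypeTable(SnpPanel(snp), individuals, calls)


def write_eigenstrat(table: GenotypeTable, geno_path, snp_path, ind_path) -> None:
    """Write a GenotypeTable as an EIGENSTRAT trio (digit-string .geno)."""
    table._check_ploidy()  # refuse to serialize invariant-breaking tables
    df = table.panel.df
    with open(snp_path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.snp_id}\t{row.chromosome}\t{row.genetic_pos:.6f}\t"
                f"{int(row.physical_pos)}\t{row.ref_allele}\t{row.alt_allele}\n"
            )
    with open(ind_path, "w") as fh:
        for indiv in table.individuals:
            fh.write(f"{indiv.individual_id}\t{indiv.sex}\t{indiv.group_label}\n")
    digits = np.char.mod("%d", table.calls.astype(int))
    with open(geno_path, "w") as fh:
        for i in range(table.calls.shape[0]):
            fh.write("".join(digits[i]) + "\n")


# ---------------------------------------------------------------------------
# Filters and blocks


def filter_snps(
    table: GenotypeTable,
    *,
    transversions_only: bool = False,
    drop_cpg_transitions: bool = False,
    min_groups_covered: Mapping[str, Sequence[str]] | None = None,
) -> tuple[GenotypeTable, dict[str, int]]:
    """Apply SNP filters; returns the filtered table and counts removed per rule.

    ``min_groups_covered`` maps group name -> individual ids; a SNP is kept
    only if every listed group has at least one non-missing call.
    Requesting ``drop_cpg_transitions`` without a CpG annotation in the
    panel is an error (the status cannot be derived from alleles alone).
    """
    df = table.panel.df
    keep = np.ones(len(df), dtype=bool)
    removed: dict[str, int] = {}
    if transversions_only:
        rule = df["is_transversion"].to_numpy(dtype=bool)
        removed["transversions_only"] = int((keep & ~rule).sum())
        keep &= rule
    if drop_cpg_transitions:
        if not table.panel.has_cpg_annotation:
            raise ValueError(
                "drop_cpg_transitions requested but the panel has no "
                "is_cpg_transition annotation (supply a CpG annotation file)"
            )
        rule = ~df["is_cpg_transition"].to_numpy(dtype=bool)
        removed["drop_cpg_transitions"] = int((keep & ~rule).sum())
        keep &= rule
    if min_groups_covered:
        index = {iid: j for j, iid in enumerate(table.individual_ids)}
        rule = np.ones(len(df), dtype=bool)
        for group, ids in min_groups_covered.items():
            if not ids:
                raise ValueError(f"empty group {group!r}")
            cols = [index[i] for i in ids]
            rule &= (table.calls[:, cols] != MISSING).any(axis=1)
        removed["min_groups_covered"] = int((keep & ~rule).sum())
        keep &= rule
    return table.subset_snps(keep), removed


def assign_blocks(panel: SnpPanel, block_span_bp: int = 5_000_000) -> BlockPartition:
    """Partition SNPs into contiguous blocks of <= ``block_span_bp`` physical span.

    Blocks never cross a chromosome boundary. Windows are half-open
    [start, start + span) anchored at the first SNP position of each
    chromosome, so the partition is determined by the data alone.
    """
    panel.validate_sorted()
    df = panel.df
    block = np.empty(len(df), dtype=np.int64)
    next_block = 0
    for _, sub in df.groupby("chromosome", sort=False):
        pos = sub["physical_pos"].to_numpy()
        offsets = (pos - pos[0]) // block_span_bp
        # renumber consecutively so empty windows do not create empty blocks
        _, local = np.unique(offsets, return_inverse=True)
        block[sub.index.to_numpy()] = next_block + local
        next_block += local.max() + 1 if len(local) else 0
    return BlockPartition(block, next_block, block_span_bp)


@dataclass
class GroupCounts:
    """Per-SNP (alt count, total observed allele draws) for each group.

    Pseudo-haploid individuals contribute one observed allele per
    non-missing call; diploid individuals contribute two.
    """

    labels: list[str]
    alt: np.ndarray  # (G, S) float
    tot: np.ndarray  # (G, S) float

    def __post_init__(self) -> None:
        self._index = {g: k for k, g in enumerate(self.labels)}

    def freq(self, group: str) -> np.ndarray:
        """Alt-allele frequency estimate p-hat, NaN where unobserved."""
        k = self._index[group]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.tot[k] > 0, self.alt[k] / self.tot[k], np.nan)

    def n(self, group: str) -> np.ndarray:
        return self.tot[self._index[group]]

    def a(self, group: str) -> np.ndarray:
        return self.alt[self._index[group]]


def build_group_counts(
    table: GenotypeTable, grouping: Mapping[str, Sequence[str]]
) -> GroupCounts:
    """Aggregate calls into per-group per-SNP allele counts.

    ``grouping`` maps group name -> sequence of individual ids. Every id
    must exist in the table; an empty group is an error.
    """
    index = {iid: j for j, iid in enumerate(table.individual_ids)}
    labels = list(grouping)
    S = len(table.panel)
    alt = np.zeros((len(labels), S))
    tot = np.zeros((len(labels), S))
    for k, group in enumerate(labels):
        ids = list(grouping[group])
        if not ids:
            raise ValueError(f"empty group {group!r}")
        missing_ids = [i for i in ids if i not in index]
        if missing_ids:
            raise KeyError(f"group {group!r}: unknown individuals {missing_ids}")
        for iid in ids:
            j = index[iid]
            col = table.calls[:, j].astype(float)
            obs = col != MISSING
            draws = 2.0 if table.individuals[j].ploidy_mode == "diploid" else 1.0
            alt[k, obs] += col[obs]
            tot[k, obs] += draws
    return GroupCounts(labels, alt, tot)


def grouping_from_labels(table: GenotypeTable) -> dict[str, list[str]]:
    """Group individuals by their ``group_label`` metadata field."""
    grouping: dict[str, list[str]] = {}
    for ind in table.individuals:
        grouping.setdefault(ind.group_label, []).append(ind.individual_id)
    return grouping
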