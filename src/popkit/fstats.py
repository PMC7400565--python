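"""f-statistics with weighted block-jackknife standard errors.

Estimators follow the standard unbiased moment forms for allele-frequency
data with finite allele draws per group:

* ``f2(A, B)``: per SNP, (p - q)^2 - p(1-p)/(nA - 1) - q(1-q)/(nB - 1),
  where p, q are observed alt-allele frequencies and nA, nB the observed
  allele-draw counts (pseudo-haploid: one draw per individual).
* ``f3(C; A, B)``: per SNP, (c - p)(c - q) - c(1-c)/(nC - 1); the
  correction over observed draws implements the random-allele ("inbreed")
  semantics appropriate for pseudo-haploid data. A significantly negative
  f3 (Z < -3) is evidence that C is admixed between A- and B-related
  sources.
* ``f4(A, B; C, D)``: per SNP, (pA - pB)(pC - pD), no correction;
  f4 = 0 indicates a treelike (symmetric) relationship.

Estimates are plain means of per-SNP values over complete-case SNPs; the
block weight of a statistic is the number of SNPs it used in that block.
Standard errors use the weighted block jackknife over contiguous blocks
(default 5 Mb), which is robust to linkage disequilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from popkit.genotype_io import BlockPartition, GenotypeTable, GroupCounts, MISSING


@dataclass
class FStatResult:
    """One f-statistic estimate with jackknife uncertainty."""

    kind: str
    pops: tuple[str, ...]
    estimate: float
    jackknife_se: float
    z_score: float
    n_blocks_used: int
    n_snps_used: int

    def __repr__(self) -> str:  # compact, ADMIXTOOLS-style line
        args = ", ".join(self.pops)
        return (
            f"{self.kind}({args}) = {self.estimate:.6g} +/- {self.jackknife_se:.3g} "
            f"(Z = {self.z_score:.2f}, {self.n_snps_used} SNPs, "
            f"{self.n_blocks_used} blocks)"
        )


def weighted_block_jackknife(
    per_block_sums: np.ndarray,
    block_weights: np.ndarray,
    full_estimate: float | None = None,
) -> tuple[float, float]:
    """Weighted delete-one-block jackknife for a mean-type statistic.

    The statistic is the mean of per-SNP values; ``per_block_sums`` holds
    the sum of those values per block and ``block_weights`` the SNP count
    per block (blocks with zero weight are dropped). With B blocks of
    weight m_j, total M, full estimate theta and leave-one-out estimates
    theta_{-j}, h_j = M / m_j:

        tau_j = h_j * theta - (h_j - 1) * theta_{-j}
        theta_J = B * theta - sum_j (1 - m_j / M) * theta_{-j}
        var = (1 / B) * sum_j (tau_j - theta_J)^2 / (h_j - 1)

    Returns (full estimate, jackknife SE). Equal weights reduce this to the
    ordinary delete-one jackknife; rescaling all weights by a constant
    leaves both outputs unchanged.
    """
    sums = np.asarray(per_block_sums, dtype=float)
    w = np.asarray(block_weights, dtype=float)
    live = w > 0
    sums, w = sums[live], w[live]
    B = len(w)
    if B < 2:
        raise ValueError("jackknife needs >= 2 blocks with nonzero weight")
    M = w.sum()
    total = sums.sum()
    theta = total / M if full_estimate is None else float(full_estimate)
    loo = (total - sums) / (M - w)
    h = M / w
    tau = h * theta - (h - 1.0) * loo
    theta_j = B * theta - ((1.0 - w / M) * loo).sum()
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / B
    return theta, float(np.sqrt(var))


def jackknife_covariance(
    per_block_sums: np.ndarray, block_weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vector generalization of :func:`weighted_block_jackknife`.

    ``per_block_sums`` is (B, m): per-block sums of an m-vector of per-SNP
    values sharing one complete-case mask (so one weight per block).
    Returns (mean vector, m x m jackknife covariance).
    """
    sums = np.asarray(per_block_sums, dtype=float)
    w = np.asarray(block_weights, dtype=float)
    live = w > 0
    sums, w = sums[live], w[live]
    B = len(w)
    if B < 2:
        raise ValueError("jackknife needs >= 2 blocks with nonzero weight")
    M = w.sum()
    total = sums.sum(axis=0)
    theta = total / M
    loo = (total[None, :] - sums) / (M - w)[:, None]
    h = M / w
    tau = h[:, None] * theta[None, :] - (h - 1.0)[:, None] * loo
    theta_j = B * theta - ((1.0 - w / M)[:, None] * loo).sum(axis=0)
    dev = (tau - theta_j[None, :]) / np.sqrt(h - 1.0)[:, None]
    cov = dev.T @ dev / B
    return theta, cov


def _result(
    kind: str,
    pops: tuple[str, ...],
    values: np.ndarray,
    used: np.ndarray,
    blocks: BlockPartition,
) -> FStatResult:
    if not used.any():
        raise ValueError(f"{kind}{pops}: zero usable SNPs")
    sums = blocks.block_sums(values, used)
    weights = blocks.weights(used)
    est, se = weighted_block_jackknife(sums, weights)
    z = est / se if se > 0 else 0.0
    return FStatResult(
        kind,
        pops,
        float(est),
        float(se),
        float(z),
        int((weights > 0).sum()),
        int(used.sum()),
    )


def _f2_values(counts: GroupCounts, a: str, b: str):
    p, q = counts.freq(a), counts.freq(b)
    n, m = counts.n(a), counts.n(b)
    used = (n >= 2) & (m >= 2) & np.isfinite(p) & np.isfinite(q)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (p - q) ** 2 - p * (1 - p) / (n - 1) - q * (1 - q) / (m - 1)
    return np.where(used, vals, 0.0), used


def f2(a: str, b: str, counts: GroupCounts, blocks: BlockPartition) -> FStatResult:
    """Unbiased f2 (squared frequency difference) between groups a and b."""
    vals, used = _f2_values(counts, a, b)
    return _result("f2", (a, b), vals, used, blocks)


def _f3_values(counts: GroupCounts, c: str, a: str, b: str, inbreed_correction: bool):
    pc, pa, pb = counts.freq(c), counts.freq(a), counts.freq(b)
    nc = counts.n(c)
    used = np.isfinite(pc) & np.isfinite(pa) & np.isfinite(pb)
    if inbreed_correction:
        used &= nc >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (pc - pa) * (pc - pb)
        if inbreed_correction:
            vals = vals - pc * (1 - pc) / (nc - 1)
    return np.where(used, vals, 0.0), used


def f3(
    c: str,
    a: str,
    b: str,
    counts: GroupCounts,
    blocks: BlockPartition,
    inbreed_correction: bool = True,
) -> FStatResult:
    """f3(C; A, B) with the random-allele-draw heterozygosity correction.

    With the correction on (the default, correct for pseudo-haploid calls)
    the target C must have >= 2 observed allele draws at a SNP for it to be
    used.
    """
    vals, used = _f3_values(counts, c, a, b, inbreed_correction)
    if inbreed_correction and not used.any() and np.isfinite(counts.freq(c)).any():
        raise ValueError(
            f"f3 target {c!r} has < 2 observed allele draws at every SNP; "
            "the inbreed correction is undefined"
        )
    return _result("f3", (c, a, b), vals, used, blocks)


def _f4_values(counts: GroupCounts, a: str, b: str, c: str, d: str):
    pa, pb, pc, pd_ = (counts.freq(g) for g in (a, b, c, d))
    used = np.isfinite(pa) & np.isfinite(pb) & np.isfinite(pc) & np.isfinite(pd_)
    vals = (pa - pb) * (pc - pd_)
    return np.where(used, vals, 0.0), used


def f4(
    a: str, b: str, c: str, d: str, counts: GroupCounts, blocks: BlockPartition
) -> FStatResult:
    """f4(A, B; C, D): covariance of frequency differences, no correction."""
    vals, used = _f4_values(counts, a, b, c, d)
    return _result("f4", (a, b, c, d), vals, used, blocks)


@dataclass
class SharedDriftMatrix:
    """Symmetric matrix of outgroup-f3 shared-drift values.

    f3(Outgroup; i, j) measures shared genetic drift of i and j since
    their divergence from the outgroup: larger = more closely related.
    ``one_minus`` (1 - f3) and ``inverse`` (f3^-1) are the two distance
    transforms used for MDS and neighbor joining respectively.
    """

    labels: list[str]
    values: np.ndarray
    excluded: list[str] = field(default_factory=list)

    def one_minus(self) -> np.ndarray:
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d

    def inverse(self) -> np.ndarray:
        if np.any(self.values <= 0):
            raise ValueError(
                "nonpositive outgroup-f3 entries: the inverse distance "
                "transform is undefined (check the outgroup)"
            )
        d = 1.0 / self.values
        np.fill_diagonal(d, 0.0)
        return d


def outgroup_f3_matrix(
    counts: GroupCounts,
    outgroup: str,
    blocks: BlockPartition,
    *,
    targets: list[str] | None = None,
    min_snps: int = 100_000,
    threshold_mode: str = "per-individual",
) -> SharedDriftMatrix:
    """Matrix of f3(Outgroup; i, j) over all target pairs (incl. diagonal).

    Targets falling below ``min_snps`` are excluded and listed in the
    result. ``threshold_mode`` is ``"per-individual"`` (count of SNPs where
    the target and outgroup are jointly usable) or ``"pairwise"`` (minimum
    joint overlap with every partner).
    """
    if targets is None:
        targets = [g for g in counts.labels if g != outgroup]
    if outgroup in targets:
        raise ValueError("outgroup must be distinct from all targets")
    n_out = counts.n(outgroup)
    p_out = counts.freq(outgroup)
    base = (n_out >= 2) & np.isfinite(p_out)
    if not base.any():
        raise ValueError(f"outgroup {outgroup!r} unusable at every SNP")
    observed = {t: np.isfinite(counts.freq(t)) & base for t in targets}
    if threshold_mode == "per-individual":
        kept = [t for t in targets if observed[t].sum() >= min_snps]
    elif threshold_mode == "pairwise":
        kept = [
            t
            for t in targets
            if all(
                (observed[t] & observed[u]).sum() >= min_snps
                for u in targets
                if u != t
            )
        ]
    else:
        raise ValueError(f"bad threshold_mode {threshold_mode!r}")
    excluded = [t for t in targets if t not in kept]
    n = len(kept)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            res = f3(outgroup, kept[i], kept[j], counts, blocks, inbreed_correction=True)
            mat[i, j] = mat[j, i] = res.estimate
    return SharedDriftMatrix(kept, mat, excluded)


@dataclass
class HeterozygosityResult:
    group: str
    estimate: float
    jackknife_se: float
    n_snps_used: int


def conditional_heterozygosity(
    group: str, counts: GroupCounts, blocks: BlockPartition
) -> HeterozygosityResult:
    """Conditional heterozygosity of a group from pseudo-haploid draws.

    Expected mismatch probability of one allele drawn from each of two
    randomly chosen individuals: per SNP with n1 ref / n2 alt observed
    draws (n = n1 + n2 >= 2), h = 2 n1 n2 / (n (n - 1)). Estimate is the
    SNP mean with block-jackknife SE. Conventionally computed on
    transversion SNPs for ancient DNA (filter the counts upstream).
    """
    a = counts.a(group)
    n = counts.n(group)
    used = n >= 2
    if not used.any():
        raise ValueError(f"group {group!r} has < 2 observed draws at every SNP")
    with np.errstate(invalid="ignore", divide="ignore"):
        h = 2.0 * a * (n - a) / (n * (n - 1.0))
    vals = np.where(used, h, 0.0)
    sums = blocks.block_sums(vals, used)
    weights = blocks.weights(used)
    est, se = weighted_block_jackknife(sums, weights)
    return HeterozygosityResult(group, float(est), float(se), int(used.sum()))


@dataclass
class MismatchResult:
    pair: tuple[str, str]
    rate: float
    n_overlap: int
    call: str  # identical/twin-or-self | first-degree | unrelated-baseline | indeterminate


def pairwise_mismatch(
    ind1: str,
    ind2: str,
    table: GenotypeTable,
    *,
    min_overlap: int = 5_000,
    baseline_rate: float | None = None,
    non_cpg_only: bool = False,
) -> MismatchResult:
    """Average pseudo-haploid mismatch rate between two individuals.

    Relatedness is called from the ratio of the pair's rate to the
    cohort's unrelated baseline rate: <= 0.55x identical/twin (or same
    individual), 0.55-0.85x first-degree, >= 0.85x unrelated. Overlap
    below ``min_overlap`` (or no baseline) gives an indeterminate call.
    """
    idx = {iid: j for j, iid in enumerate(table.individual_ids)}
    c1 = table.calls[:, idx[ind1]]
    c2 = table.calls[:, idx[ind2]]
    keep = (c1 != MISSING) & (c2 != MISSING)
    if non_cpg_only:
        if not table.panel.has_cpg_annotation:
            raise ValueError("non_cpg_only requested but panel has no CpG annotation")
        keep &= ~table.panel.df["is_cpg_transition"].to_numpy(dtype=bool)
    n = int(keep.sum())
    if n < min_overlap:
        return MismatchResult((ind1, ind2), float("nan"), n, "indeterminate")
    rate = float((c1[keep] != c2[keep]).mean())
    if baseline_rate is None or baseline_rate <= 0:
        call = "indeterminate"
    else:
        ratio = rate / baseline_rate
        if ratio <= 0.55:
            call = "identical/twin-or-self"
        elif ratio < 0.85:
            call = "first-degree"
        else:
            call = "unrelated-baseline"
    return MismatchResult((ind1, ind2), rate, n, call)


def unrelated_baseline_rate(table: GenotypeTable, *, min_overlap: int = 5_000) -> float:
    """Median pairwise mismatch rate across the cohort (robust to a few kin)."""
    ids = table.individual_ids
    rates = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = pairwise_mismatch(ids[i], ids[j], table, min_overlap=min_overlap)
            if np.isfinite(r.rate):
                rates.append(r.rate)
    if not rates:
        raise ValueError("no pair reaches the minimum overlap")
    return float(np.median(rates))
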