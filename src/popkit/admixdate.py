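"""Admixture dating from the decay of weighted allele covariance.

After an admixture event g generations ago, ancestry blocks are broken up
by recombination, so the covariance (across admixed individuals) between
alleles at two loci — weighted by how ancestry-informative each locus is —
decays as exp(-g * d) with genetic distance d in Morgans. Fitting that
exponential to a binned covariance curve estimates the admixture date in
generations; a generation time (default 28.5 years) plus the mean sample
age converts to calendar years before present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from popkit.genotype_io import GenotypeTable, GroupCounts, MISSING

DEFAULT_BIN_WIDTH = 0.0005  # Morgans (0.05 cM)
DEFAULT_MAX_DIST = 0.1  # Morgans (10 cM)
DEFAULT_FIT_MIN = 0.0045  # Morgans (0.45 cM)
GENERATION_YEARS = 28.5


@dataclass
class DecayCurve:
    """Binned weighted ancestry covariance vs genetic distance.

    ``per_chrom_sums`` / ``per_chrom_counts`` keep per-chromosome
    contributions so the date SE can use a leave-one-chromosome-out
    jackknife. Dates are reported +/- 1 standard error.
    """

    bin_centers: np.ndarray  # Morgans
    covariance: np.ndarray
    pair_counts: np.ndarray
    chromosomes: list[str]
    per_chrom_sums: np.ndarray  # (n_chrom, n_bins)
    per_chrom_counts: np.ndarray
    bin_width: float
    # fit results
    amplitude: float = float("nan")
    rate_generations: float = float("nan")
    affine_constant: float = float("nan")
    fit_min: float = float("nan")
    fit_max: float = float("nan")
    converged: bool = False
    no_decay: bool = False
    date_generations: float = float("nan")
    date_generations_se: float = float("nan")
    leave_one_out_rates: np.ndarray | None = None
    date_years_bp: float = float("nan")
    date_years_bp_se: float = float("nan")


def ancestry_covariance_curve(
    target: GenotypeTable,
    refA_counts: GroupCounts,
    refB_counts_or_group,
    refB_group: str | None = None,
    *,
    refA_group: str | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_dist: float = DEFAULT_MAX_DIST,
) -> DecayCurve:
    """Binned weighted allele covariance across target individuals.

    Per SNP s the weight is w_s = pA(s) - pB(s), the reference allele
    frequency difference. For every intra-chromosome SNP pair (s, t) with
    genetic distance d in (0, max_dist], w_s * w_t * cov(g_s, g_t) is
    accumulated into the bin of d, where cov is the sample covariance of
    the calls across target individuals having data at both SNPs (>= 2
    required). Bin value = sum / pair count.

    ``refA_counts`` may carry both reference groups (then pass group names
    via ``refA_group`` / ``refB_group``), or pass two GroupCounts with a
    single group each.
    """
    if isinstance(refB_counts_or_group, GroupCounts):
        refB_counts = refB_counts_or_group
        ga = refA_group or refA_counts.labels[0]
        gb = refB_group or refB_counts.labels[0]
    else:
        refB_counts = refA_counts
        ga = refA_group or refA_counts.labels[0]
        gb = refB_counts_or_group
    pA = refA_counts.freq(ga)
    pB = refB_counts.freq(gb)
    if len(target.individuals) < 2:
        raise ValueError("need >= 2 target individuals")
    w_all = pA - pB

    df = target.panel.df
    n_bins = int(np.ceil(max_dist / bin_width))
    chroms = list(dict.fromkeys(df["chromosome"]))
    sums = np.zeros((len(chroms), n_bins))
    cnts = np.zeros((len(chroms), n_bins))
    any_pair = False
    for ci, chrom in enumerate(chroms):
        sel = (df["chromosome"] == chrom).to_numpy()
        sel &= np.isfinite(w_all)
        if sel.sum() < 2:
            continue
        g = df.loc[sel, "genetic_pos"].to_numpy()
        w = w_all[sel]
        X = target.calls[sel].astype(float)  # (S, N)
        Mk = (X != MISSING).astype(float)
        X = np.where(Mk > 0, X, 0.0)
        # pairwise-complete sample covariance via matmuls
        n_st = Mk @ Mk.T
        P = X @ X.T
        S1 = X @ Mk.T  # sum of x_s over inds covered at both s and t
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = (P - S1 * S1.T / n_st) / (n_st - 1.0)
        valid = n_st >= 2
        dmat = np.abs(g[:, None] - g[None, :])
        iu = np.triu_indices(len(g), k=1)
        d = dmat[iu]
        keep = (d > 0) & (d <= max_dist) & valid[iu] & np.isfinite(cov[iu])
        if not keep.any():
            continue
        any_pair = True
        vals = (w[:, None] * w[None, :])[iu][keep] * cov[iu][keep]
        bins = np.minimum((d[keep] / bin_width).astype(int), n_bins - 1)
        sums[ci] += np.bincount(bins, weights=vals, minlength=n_bins)
        cnts[ci] += np.bincount(bins, minlength=n_bins)
    if not any_pair:
        raise ValueError(
            "no SNP pair with >= 2 doubly-covered target individuals "
            "within max_dist"
        )
    total_s = sums.sum(axis=0)
    total_c = cnts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        covb = np.where(total_c > 0, total_s / total_c, np.nan)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return DecayCurve(
        centers, covb, total_c, chroms, sums, cnts, bin_width
    )


def _exp_model(d, a, n, c):
    return a * np.exp(-n * d) + c


def _fit_exp(d: np.ndarray, y: np.ndarray) -> tuple[float, float, float] | None:
    """Exponential fit with log-linear initialization; None if it fails."""
    c0 = float(np.mean(y[-max(3, len(y) // 5):]))
    resid = y - c0
    pos = resid > 0
    if pos.sum() >= 3:
        slope, intercept = np.polyfit(d[pos], np.log(resid[pos]), 1)
        n0 = max(-slope, 1.0)
        a0 = float(np.exp(intercept))
    else:
        n0, a0 = 50.0, max(float(y[0] - c0), 1e-6)
    try:
        popt, _ = curve_fit(
            _exp_model,
            d,
            y,
            p0=[a0, n0, c0],
            maxfev=20000,
            bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
        )
    except (RuntimeError, ValueError):
        return None
    return float(popt[0]), float(popt[1]), float(popt[2])


def fit_decay(
    curve: DecayCurve,
    fit_min: float = DEFAULT_FIT_MIN,
    fit_max: float | None = None,
) -> DecayCurve:
    """Fit y(d) = A exp(-n d) + c to the binned curve over [fit_min, fit_max].

    The rate n is the admixture date in generations. The SE comes from
    leave-one-chromosome-out refits combined with the weighted jackknife
    (chromosome weight = pair count in the fit range). A nonpositive
    amplitude, or a fit that does not converge, sets the ``no_decay`` /
    non-converged flags instead of reporting a date.
    """
    fit_max = curve.bin_centers[-1] + curve.bin_width if fit_max is None else fit_max
    in_range = (
        (curve.bin_centers >= fit_min)
        & (curve.bin_centers <= fit_max)
        & (curve.pair_counts > 0)
        & np.isfinite(curve.covariance)
    )
    if in_range.sum() < 5:
        raise ValueError("need >= 5 usable bins in the fit range")
    d = curve.bin_centers[in_range]
    y = curve.covariance[in_range]
    curve.fit_min, curve.fit_max = float(fit_min), float(fit_max)
    fit = _fit_exp(d, y)
    if fit is None:
        warnings.warn("decay fit did not converge", stacklevel=2)
        curve.converged = False
        return curve
    a, n, c = fit
    curve.converged = True
    curve.amplitude, curve.rate_generations, curve.affine_constant = a, n, c
    # an amplitude at (or numerically indistinguishable from) zero means no
    # detectable decay signal above the affine floor
    if a <= 1e-6 * float(np.max(np.abs(y))) or n <= 0:
        curve.no_decay = True
        return curve
    # leave-one-chromosome-out jackknife on the rate
    n_chrom = curve.per_chrom_sums.shape[0]
    loo = np.full(n_chrom, np.nan)
    weights = curve.per_chrom_counts[:, in_range].sum(axis=1)
    for ci in range(n_chrom):
        if weights[ci] == 0:
            continue
        s = curve.per_chrom_sums[:, in_range].sum(axis=0) - curve.per_chrom_sums[ci, in_range]
        k = curve.per_chrom_counts[:, in_range].sum(axis=0) - curve.per_chrom_counts[ci, in_range]
        ok = k > 0
        if ok.sum() < 5:
            continue
        f = _fit_exp(d[ok], s[ok] / k[ok])
        if f is not None and f[1] > 0:
            loo[ci] = f[1]
    good = np.isfinite(loo) & (weights > 0)
    curve.leave_one_out_rates = loo
    if good.sum() >= 2:
        w = weights[good]
        M = w.sum()
        B = good.sum()
        h = M / w
        theta = n
        tau = h * theta - (h - 1.0) * loo[good]
        theta_j = B * theta - ((1.0 - w / M) * loo[good]).sum()
        var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / B
        curve.date_generations_se = float(np.sqrt(var))
    curve.date_generations = n
    return curve


def generations_to_years(
    n_generations: float,
    n_generations_se: float = 0.0,
    generation_years: float = GENERATION_YEARS,
    mean_sample_age_bp: float = 0.0,
) -> tuple[float, float]:
    """Convert an admixture date in generations to years BP.

    years BP = mean sample age + n * generation_years, anchoring the date
    to when the sampled individuals lived; the SE scales linearly.
    """
    if n_generations < 0:
        raise ValueError("negative number of generations")
    years = mean_sample_age_bp + n_generations * generation_years
    return float(years), float(n_generations_se * generation_years)


def date_admixture(
    target: GenotypeTable,
    counts: GroupCounts,
    refA: str,
    refB: str,
    *,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_dist: float = DEFAULT_MAX_DIST,
    fit_min: float = DEFAULT_FIT_MIN,
    generation_years: float = GENERATION_YEARS,
    mean_sample_age_bp: float = 0.0,
) -> DecayCurve:
    """One-call pipeline: curve, exponential fit, calendar-year conversion."""
    curve = ancestry_covariance_curve(
        target, counts, refB, refA_group=refA,
        bin_width=bin_width, max_dist=max_dist,
    )
    curve = fit_decay(curve, fit_min=fit_min)
    if curve.converged and not curve.no_decay:
        years, yse = generations_to_years(
            curve.date_generations,
            curve.date_generations_se if np.isfinite(curve.date_generations_se) else 0.0,
            generation_years,
            mean_sample_age_bp,
        )
        curve.date_years_bp, curve.date_years_bp_se = years, yse
    return curve
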