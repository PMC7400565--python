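"""Association tests between distance matrices.

Simple Mantel, partial Mantel (via residualization), and multiple matrix
regression, all with permutation p-values obtained by jointly permuting
the rows and columns of the dependent (genetic) matrix only — the
convention matching R's multi.Mantel. Individuals are treated as
independent observations even though shared drift within groups makes
that only approximately true; this is documented behavior, not corrected
for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from popkit.explanatory import LabeledDistanceMatrix
from popkit.fstats import _f3_values
from popkit.genotype_io import BlockPartition, GroupCounts

EXHAUSTIVE_MAX_LABELS = 7


@dataclass
class MantelResult:
    """Coefficients and permutation p-values for a matrix association test."""

    method: str
    coefficients: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    r_squared: float | None = None
    seed: int | None = None
    exhaustive: bool = False


def _align(dy: LabeledDistanceMatrix, others: Sequence[LabeledDistanceMatrix]):
    labels = dy.labels
    mats = [dy.values]
    for o in others:
        if o.labels != labels:
            if set(o.labels) != set(labels):
                raise ValueError(
                    f"label mismatch between {dy.variable} and {o.variable}"
                )
            order = [o.labels.index(l) for l in labels]
            mats.append(o.values[np.ix_(order, order)])
        else:
            mats.append(o.values)
    return labels, mats


def _tri_indices(n: int):
    return np.tril_indices(n, k=-1)


def _spearman_vs(perm_rows: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Spearman r of each row of ``perm_rows`` against fixed ``x``."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(perm_rows, axis=1)
    return _pearson_vs(ry, rx)


def _pearson_vs(perm_rows: np.ndarray, x: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    xn = np.sqrt((xc ** 2).sum())
    yc = perm_rows - perm_rows.mean(axis=1, keepdims=True)
    yn = np.sqrt((yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (yc @ xc) / (yn * xn)


def _permuted_triangles(dy: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Lower triangles of Dy after simultaneous row/column permutation."""
    n = dy.shape[0]
    ii, jj = _tri_indices(n)
    return dy[perms[:, ii], perms[:, jj]]


def _perm_matrix(n: int, nperm: int, rng: np.random.Generator, exhaustive: bool):
    if exhaustive:
        return np.array(list(iter_permutations(range(n))), dtype=np.intp)
    return np.array([rng.permutation(n) for _ in range(nperm)], dtype=np.intp)


def mantel_simple(
    dy: LabeledDistanceMatrix,
    dx: LabeledDistanceMatrix,
    method: str = "spearman",
    nperm: int = 10_000,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> MantelResult:
    """Simple Mantel test of Dy against Dx.

    The coefficient (Spearman by default, Pearson available) is computed
    over the strictly-lower-triangle vectors; the null distribution comes
    from jointly permuting Dy's rows and columns. Two-sided p:
    (1 + #{|r_perm| >= |r_obs|}) / (nperm + 1), or the exact proportion
    under full enumeration (automatic for <= 7 labels).
    """
    labels, (my, mx) = _align(dy, [dx])
    n = len(labels)
    ii, jj = _tri_indices(n)
    x = mx[ii, jj]
    y = my[ii, jj]
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant distance matrix: Mantel coefficient undefined")
    corr = _spearman_vs if method == "spearman" else _pearson_vs
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    r_obs = float(corr(y[None, :], x)[0])
    if exhaustive is None:
        exhaustive = n <= EXHAUSTIVE_MAX_LABELS
    rng = np.random.default_rng(seed)
    perms = _perm_matrix(n, nperm, rng, exhaustive)
    r_perm = np.empty(len(perms))
    chunk = 2000
    for s in range(0, len(perms), chunk):
        tri = _permuted_triangles(my, perms[s : s + chunk])
        r_perm[s : s + chunk] = corr(tri, x)
    if exhaustive:
        p = float(np.mean(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    else:
        p = float((1 + np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12)) / (len(perms) + 1))
    return MantelResult(
        method=f"mantel-{method}",
        coefficients={dx.variable: r_obs},
        p_values={dx.variable: p},
        n_permutations=len(perms),
        seed=seed,
        exhaustive=exhaustive,
    )


def _ols(X: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return beta, rss, r2


def matrix_regression(
    dy: LabeledDistanceMatrix,
    dxs: Sequence[LabeledDistanceMatrix],
    nperm: int = 10_000,
    seed: int | None = None,
) -> MantelResult:
    """Multiple matrix regression of Dy on several explanatory matrices.

    OLS (with intercept) on the lower-triangle vectors; per-coefficient
    two-sided permutation p-values on |t|, permuting Dy's rows/columns and
    refitting. Reports the multiple R^2.
    """
    if len(dxs) < 2:
        raise ValueError("need >= 2 explanatory matrices (else use mantel_simple)")
    labels, mats = _align(dy, dxs)
    my, mxs = mats[0], mats[1:]
    n = len(labels)
    ii, jj = _tri_indices(n)
    y = my[ii, jj]
    X = np.column_stack([np.ones(len(y))] + [m[ii, jj] for m in mxs])
    cond = np.linalg.cond(X)
    if cond > 1e8:
        warnings.warn(
            f"explanatory triangles nearly collinear (cond {cond:.3g})",
            stacklevel=2,
        )
    p_params = X.shape[1]
    dof = len(y) - p_params
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta, rss, r2 = _ols(X, y)
    se = np.sqrt(np.diag(xtx_inv) * rss / dof)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_obs = beta / se

    rng = np.random.default_rng(seed)
    perms = _perm_matrix(n, nperm, rng, False)
    count_ge = np.zeros(p_params)
    proj = xtx_inv @ X.T  # (p, npairs)
    diag = np.diag(xtx_inv)
    chunk = 2000
    for s in range(0, len(perms), chunk):
        Y = _permuted_triangles(my, perms[s : s + chunk])  # (c, npairs)
        Bp = Y @ proj.T  # (c, p)
        rssp = (Y ** 2).sum(axis=1) - np.einsum("cp,cp->c", Bp, Bp @ (X.T @ X))
        rssp = np.maximum(rssp, 1e-300)
        sep = np.sqrt(diag[None, :] * (rssp / dof)[:, None])
        tp = Bp / sep
        count_ge += (np.abs(tp) >= np.abs(t_obs)[None, :] - 1e-12).sum(axis=0)
    pvals = (1 + count_ge) / (len(perms) + 1)
    names = [d.variable for d in dxs]
    return MantelResult(
        method="matrix-regression",
        coefficients={"intercept": float(beta[0]), **{nm: float(b) for nm, b in zip(names, beta[1:])}},
        p_values={nm: float(p) for nm, p in zip(names, pvals[1:])},
        n_permutations=len(perms),
        r_squared=float(r2),
        seed=seed,
    )


def partial_mantel(
    dy: LabeledDistanceMatrix,
    dx_focus: LabeledDistanceMatrix,
    covariates: Sequence[LabeledDistanceMatrix],
    method: str = "spearman",
    nperm: int = 10_000,
    seed: int | None = None,
) -> MantelResult:
    """Partial Mantel: association of Dy with Dx after removing covariates.

    Dy's lower triangle is residualized on the covariate triangles by
    multivariate linear regression; the residuals (restored to matrix
    form) are then Mantel-tested against the focus matrix, permuting the
    residual matrix's rows and columns. With no covariates this equals the
    simple Mantel test.
    """
    labels, mats = _align(dy, [dx_focus, *covariates])
    my, mx = mats[0], mats[1]
    covs = mats[2:]
    n = len(labels)
    ii, jj = _tri_indices(n)
    y = my[ii, jj]
    X = np.column_stack([np.ones(len(y))] + [c[ii, jj] for c in covs])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rmat = np.zeros_like(my)
    rmat[ii, jj] = resid
    rmat = rmat + rmat.T
    r_dy = LabeledDistanceMatrix.__new__(LabeledDistanceMatrix)
    r_dy.labels = labels
    r_dy.values = rmat  # residuals may be negative; bypass validation
    r_dy.variable = f"{dy.variable}|resid"
    fx = LabeledDistanceMatrix.__new__(LabeledDistanceMatrix)
    fx.labels = labels
    fx.values = mx
    fx.variable = dx_focus.variable
    return mantel_simple(r_dy, fx, method=method, nperm=nperm, seed=seed)


def jackknife_regression_ci(
    counts: GroupCounts,
    outgroup: str,
    targets: Sequence[str],
    explanatory: Sequence[LabeledDistanceMatrix],
    blocks: BlockPartition,
    transform: str = "one-minus",
    ci_z: float = 1.96,
) -> dict[str, tuple[float, float, tuple[float, float]]]:
    """Block-jackknife CIs for multiple-matrix-regression coefficients.

    The genetic distance matrix (1 - f3(Outgroup; i, j), or f3^-1) is
    recomputed with each 5-Mb block deleted, the regression refit, and the
    coefficient variability combined with the weighted block jackknife
    (block weights = outgroup-usable SNPs per block). Returns per
    variable: (estimate, SE, (lo, hi)) with the CI = estimate +/- 1.96 SE.
    """
    targets = list(targets)
    npairs_labels = [(a, b) for i, a in enumerate(targets) for b in targets[i + 1 :]]
    B = blocks.n_blocks
    sums = np.empty((len(npairs_labels), B))
    cnts = np.empty((len(npairs_labels), B))
    for k, (a, b) in enumerate(npairs_labels):
        vals, used = _f3_values(counts, outgroup, a, b, True)
        sums[k] = blocks.block_sums(vals, used)
        cnts[k] = blocks.weights(used)
    n_out = counts.n(outgroup)
    base_used = (n_out >= 2) & np.isfinite(counts.freq(outgroup))
    wts = blocks.weights(base_used)

    def genetic_matrix(f3_vec: np.ndarray) -> np.ndarray:
        n = len(targets)
        m = np.zeros((n, n))
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                v = f3_vec[k]
                if transform == "one-minus":
                    m[i, j] = m[j, i] = 1.0 - v
                elif transform == "inverse":
                    m[i, j] = m[j, i] = 1.0 / v
                else:
                    raise ValueError(f"unknown transform {transform!r}")
                k += 1
        return m

    _, mats = _align(
        LabeledDistanceMatrix(targets, np.zeros((len(targets),) * 2), "genetic"),
        explanatory,
    )
    ii, jj = _tri_indices(len(targets))
    X = np.column_stack([np.ones(len(ii))] + [m[ii, jj] for m in mats[1:]])

    def fit(f3_vec: np.ndarray) -> np.ndarray:
        y = genetic_matrix(f3_vec)[ii, jj]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta

    with np.errstate(invalid="ignore", divide="ignore"):
        full_f3 = sums.sum(axis=1) / cnts.sum(axis=1)
    beta_full = fit(full_f3)
    live = wts > 0
    if live.sum() < 2:
        raise ValueError("need >= 2 blocks with usable SNPs")
    loo = []
    for b in np.flatnonzero(live):
        with np.errstate(invalid="ignore", divide="ignore"):
            f3_b = (sums.sum(axis=1) - sums[:, b]) / (cnts.sum(axis=1) - cnts[:, b])
        loo.append(fit(f3_b))
    loo = np.asarray(loo)
    wl = wts[live]
    M = wl.sum()
    Bl = len(wl)
    h = M / wl
    tau = h[:, None] * beta_full[None, :] - (h - 1.0)[:, None] * loo
    theta_j = Bl * beta_full - ((1.0 - wl / M)[:, None] * loo).sum(axis=0)
    var = ((tau - theta_j[None, :]) ** 2 / (h - 1.0)[:, None]).sum(axis=0) / Bl
    se = np.sqrt(var)
    names = ["intercept"] + [d.variable for d in explanatory]
    return {
        nm: (float(b), float(s), (float(b - ci_z * s), float(b + ci_z * s)))
        for nm, b, s in zip(names, beta_full, se)
    }
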