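"""Admixture-proportion estimation (qpAdm-style) and admixture-graph
expected f-statistics.

``qpadm_fit`` models a target population as a mixture of k source
populations, testing fit against a set of "right" reference populations
through a system of f4-statistics. ``graph_expected_f`` computes the
f-statistics implied by a fixed admixture graph, for comparison with
observed values by Z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy import stats

from popkit.genotype_io import BlockPartition, GroupCounts
from popkit.fstats import FStatResult, jackknife_covariance, weighted_block_jackknife


@dataclass
class MixtureSolution:
    """qpAdm-style mixture model solution.

    Weights sum to 1 exactly but are not constrained to [0, 1];
    ``feasible`` reports whether they all fall in the unit interval.
    Convention for reporting: point estimate +/- 1 standard error.
    """

    target: str
    sources: list[str]
    rights: list[str]
    weights: np.ndarray
    weight_se: np.ndarray
    weight_cov: np.ndarray
    fit_statistic: float
    dof: int
    p_value: float
    feasible: bool
    n_snps_used: int
    n_blocks_used: int

    @property
    def fit_class(self) -> str:
        return classify_fit(self.p_value)


def classify_fit(p_value: float) -> str:
    """Map a model p-value to {pass, borderline, fail}.

    Fit classes: P > 0.02 passes, P < 0.005 fails, in between (inclusive
    of both boundaries) is borderline.
    """
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p-value {p_value} outside [0, 1]")
    if p_value > 0.02:
        return "pass"
    if p_value < 0.005:
        return "fail"
    return "borderline"


def _solve_constrained_gls(A: np.ndarray, y: np.ndarray, omega_inv: np.ndarray) -> np.ndarray:
    """Minimize (y - Aw)' Oi (y - Aw) subject to sum(w) = 1 (Lagrange)."""
    k = A.shape[1]
    G = A.T @ omega_inv @ A
    rhs = A.T @ omega_inv @ y
    Gi = np.linalg.solve(G, np.column_stack([rhs, np.ones(k)]))
    w0, g1 = Gi[:, 0], Gi[:, 1]
    lam = (1.0 - w0.sum()) / g1.sum()
    return w0 + lam * g1


def qpadm_fit(
    target: str,
    sources: list[str],
    rights: list[str],
    counts: GroupCounts,
    blocks: BlockPartition,
    *,
    max_iter: int = 30,
    tol: float = 1e-10,
) -> MixtureSolution:
    """Estimate admixture proportions of ``target`` from ``sources``.

    The first right population is the designated base r0. The model solves

        f4(T, r0; r_j, r0) = sum_i w_i f4(S_i, r0; r_j, r0),  j = 1..m

    by generalized least squares with the constraint sum(w) = 1. The
    residual covariance Omega comes from a weighted block jackknife of the
    per-block residual statistic vector (which depends on w, so the GLS is
    iterated to a fixed point). The fit statistic is the minimized
    quadratic form, referred to chi-square with dof = m - k + 1; the
    corresponding p-value implements the jackknife likelihood-ratio fit
    test. Weight SEs come from re-solving with each block deleted.
    """
    k, m1 = len(sources), len(rights)
    if k < 1:
        raise ValueError("need at least one source")
    m = m1 - 1
    if m < k:
        raise ValueError(f"need #rights - 1 >= #sources ({m} < {k})")
    groups = [target, *sources, *rights]
    if len(set(groups)) != len(groups):
        raise ValueError("target, sources and rights must be disjoint")
    r0, rest = rights[0], rights[1:]

    freqs = {g: counts.freq(g) for g in groups}
    used = np.ones(len(freqs[target]), dtype=bool)
    for g in groups:
        used &= np.isfinite(freqs[g])
    if not used.any():
        raise ValueError("zero SNPs observed in all groups")

    pT = freqs[target][used]
    pr0 = freqs[r0][used]
    pS = np.column_stack([freqs[s][used] for s in sources])  # (S, k)
    pR = np.column_stack([freqs[r][used] for r in rest])  # (S, m)

    right_diff = pR - pr0[:, None]  # (S, m)
    y_snp = (pT - pr0)[:, None] * right_diff  # (S, m)
    # A per SNP: (S, m, k) is large; we only need block sums of y and of
    # each A column, plus block sums of the residual vector at a given w.
    idx = blocks.block_index[used]
    B = blocks.n_blocks
    wts = np.bincount(idx, minlength=B).astype(float)
    M = wts.sum()

    def bsum(v):  # (S, m) -> (B, m)
        out = np.empty((B, v.shape[1]))
        for c in range(v.shape[1]):
            out[:, c] = np.bincount(idx, weights=v[:, c], minlength=B)
        return out

    y_blocks = bsum(y_snp)
    A_blocks = np.empty((B, m, k))
    for i in range(k):
        A_blocks[:, :, i] = bsum((pS[:, i] - pr0)[:, None] * right_diff)
    y_bar = y_blocks.sum(axis=0) / M
    A_bar = A_blocks.sum(axis=0) / M

    # iterate: Omega depends on w through the per-SNP residual vector
    w = np.full(k, 1.0 / k)
    omega_inv = None
    ridged = False
    for _ in range(max_iter):
        mix = pS @ w
        resid_snp = (pT - mix)[:, None] * right_diff
        _, omega = jackknife_covariance(bsum(resid_snp), wts)
        cond = np.linalg.cond(omega)
        if cond > 1e10:
            if not ridged:
                warnings.warn(
                    f"residual covariance ill-conditioned (cond {cond:.2g}); "
                    "adding ridge",
                    stacklevel=2,
                )
                ridged = True
            omega = omega + 1e-6 * (np.trace(omega) / m) * np.eye(m)
        omega_inv = np.linalg.inv(omega)
        w_new = _solve_constrained_gls(A_bar, y_bar, omega_inv)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new

    resid = y_bar - A_bar @ w
    fit_stat = float(resid @ omega_inv @ resid)
    dof = m - (k - 1)
    p = float(stats.chi2.sf(fit_stat, dof))

    # weight SEs: re-solve per deleted block (fixed Omega), weighted jackknife
    live = wts > 0
    Bl = int(live.sum())
    w_loo = np.empty((Bl, k))
    total_y = y_blocks.sum(axis=0)
    total_A = A_blocks.sum(axis=0)
    for bi, b in enumerate(np.flatnonzero(live)):
        Mb = M - wts[b]
        yb = (total_y - y_blocks[b]) / Mb
        Ab = (total_A - A_blocks[b]) / Mb
        w_loo[bi] = _solve_constrained_gls(Ab, yb, omega_inv)
    wl = wts[live]
    h = M / wl
    tau = h[:, None] * w[None, :] - (h - 1.0)[:, None] * w_loo
    theta_j = Bl * w - ((1.0 - wl / M)[:, None] * w_loo).sum(axis=0)
    dev = (tau - theta_j[None, :]) / np.sqrt(h - 1.0)[:, None]
    wcov = dev.T @ dev / Bl
    wse = np.sqrt(np.diag(wcov))

    return MixtureSolution(
        target=target,
        sources=list(sources),
        rights=list(rights),
        weights=w,
        weight_se=wse,
        weight_cov=wcov,
        fit_statistic=fit_stat,
        dof=dof,
        p_value=p,
        feasible=bool(np.all((w >= 0) & (w <= 1))),
        n_snps_used=int(used.sum()),
        n_blocks_used=Bl,
    )


# ---------------------------------------------------------------------------
# Admixture graphs


class AdmixtureGraph:
    """A directed acyclic admixture graph with drift-edge lengths.

    Drift edges carry lengths in f2 units (text files conventionally use
    the "FST x 1000" display scale; the parser converts). Admixture nodes
    have exactly two parents with mixing proportions summing to 1 and
    carry no drift on the incoming admixture edges.
    """

    def __init__(self) -> None:
        self.g = nx.DiGraph()

    def add_edge(self, parent: str, child: str, length: float) -> None:
        if length < 0:
            raise ValueError(f"negative drift length on {parent}->{child}")
        self.g.add_edge(parent, child, length=float(length), weight=1.0)

    def add_admixture(self, child: str, parent_a: str, alpha: float, parent_b: str) -> None:
        if not 0 < alpha < 1:
            raise ValueError(f"admixture proportion {alpha} outside (0, 1)")
        self.g.add_edge(parent_a, child, length=0.0, weight=float(alpha))
        self.g.add_edge(parent_b, child, length=0.0, weight=float(1.0 - alpha))

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.g):
            raise ValueError("admixture graph contains a cycle")
        roots = [n for n in self.g if self.g.in_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(f"graph must have exactly one root, found {roots}")
        for n in self.g:
            deg = self.g.in_degree(n)
            if deg > 2:
                raise ValueError(f"node {n} has {deg} parents")
            if deg == 2:
                tot = sum(d["weight"] for _, _, d in self.g.in_edges(n, data=True))
                if abs(tot - 1.0) > 1e-9:
                    raise ValueError(f"admixture weights into {n} sum to {tot}")

    @property
    def root(self) -> str:
        return next(n for n in self.g if self.g.in_degree(n) == 0)

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n in self.g if self.g.out_degree(n) == 0)

    @classmethod
    def from_text(cls, text: str, length_scale: float = 1e-3) -> "AdmixtureGraph":
        """Parse the edge-list format.

        Drift lines: ``parent child length`` (length on the FST x 1000
        display scale by default; ``length_scale`` converts to f2 units).
        Admixture lines: ``child <- parentA:alpha parentB:beta``.
        """
        graph = cls()
        for raw in text.splitlines():
            line = raw.split("#")[0].strip()
            if not line:
                continue
            if "<-" in line:
                child, rhs = (part.strip() for part in line.split("<-"))
                terms = rhs.split()
                if len(terms) != 2:
                    raise ValueError(f"bad admixture line: {raw!r}")
                (pa, aa), (pb, ab) = (t.rsplit(":", 1) for t in terms)
                alpha, beta = float(aa), float(ab)
                if abs(alpha + beta - 1.0) > 1e-9:
                    raise ValueError(f"admixture proportions do not sum to 1: {raw!r}")
                graph.add_admixture(child, pa, alpha, pb)
            else:
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(f"bad edge line: {raw!r}")
                graph.add_edge(parts[0], parts[1], float(parts[2]) * length_scale)
        graph.validate()
        return graph

    def path_probabilities(self) -> dict[str, dict[tuple[str, str], float]]:
        """P_leaf(edge): probability a lineage from the leaf traverses the edge.

        A lineage walks rootward from its leaf; at an admixture node it
        picks a parent with the mixing proportions. P multiplies along the
        way, sums over alternative paths.
        """
        order = list(nx.topological_sort(self.g))  # root first
        probs: dict[str, dict[tuple[str, str], float]] = {}
        for leaf in self.leaves:
            p_node = {n: 0.0 for n in self.g}
            p_node[leaf] = 1.0
            p_edge: dict[tuple[str, str], float] = {}
            for node in reversed(order):  # leaves first
                if p_node[node] == 0.0:
                    continue
                for parent, _, data in self.g.in_edges(node, data=True):
                    contrib = p_node[node] * data["weight"]
                    p_edge[(parent, node)] = p_edge.get((parent, node), 0.0) + contrib
                    p_node[parent] += contrib
            probs[leaf] = p_edge
        return probs


@dataclass
class ExpectedFStats:
    """Expected f-statistics implied by an admixture graph."""

    leaves: list[str]
    covariance: np.ndarray  # C(i, j) relative to the root

    def _idx(self, x: str) -> int:
        return self.leaves.index(x)

    def f2(self, a: str, b: str) -> float:
        c = self.covariance
        i, j = self._idx(a), self._idx(b)
        return c[i, i] + c[j, j] - 2 * c[i, j]

    def f3(self, c_: str, a: str, b: str) -> float:
        c = self.covariance
        i, j, k = self._idx(c_), self._idx(a), self._idx(b)
        return c[i, i] - c[i, j] - c[i, k] + c[j, k]

    def f4(self, a: str, b: str, c_: str, d: str) -> float:
        c = self.covariance
        i, j, k, l = (self._idx(x) for x in (a, b, c_, d))
        return c[i, k] - c[i, l] - c[j, k] + c[j, l]

    def all_f2(self):
        return {
            (a, b): self.f2(a, b) for a, b in combinations(self.leaves, 2)
        }

    def all_f4(self):
        out = {}
        for quad in combinations(self.leaves, 4):
            a, b, c_, d = quad
            out[(a, b, c_, d)] = self.f4(a, b, c_, d)
            out[(a, c_, b, d)] = self.f4(a, c_, b, d)
            out[(a, d, b, c_)] = self.f4(a, d, b, c_)
        return out


def graph_expected_f(graph: AdmixtureGraph) -> ExpectedFStats:
    """Expected f-statistics from a fixed admixture graph.

    The leaf covariance relative to the root is
    C(i, j) = sum_edges P_i(e) P_j(e) len(e), where P_i(e) is the
    probability a lineage from leaf i traverses edge e. f2/f3/f4 follow by
    the usual bilinear identities.
    """
    graph.validate()
    probs = graph.path_probabilities()
    leaves = graph.leaves
    n = len(leaves)
    cov = np.zeros((n, n))
    lengths = nx.get_edge_attributes(graph.g, "length")
    for i in range(n):
        for j in range(i, n):
            pi, pj = probs[leaves[i]], probs[leaves[j]]
            total = sum(
                p * pj[e] * lengths[e] for e, p in pi.items() if e in pj
            )
            cov[i, j] = cov[j, i] = total
    return ExpectedFStats(leaves, cov)


@dataclass
class GraphFitReport:
    rows: list[dict]
    max_abs_z: float
    worst: dict | None


def graph_fit_report(
    graph: AdmixtureGraph, observed_fstats: list[FStatResult]
) -> GraphFitReport:
    """Z-scores of observed minus graph-expected f-statistics (no refit)."""
    expected = graph_expected_f(graph)
    rows = []
    for obs in observed_fstats:
        if not np.isfinite(obs.jackknife_se) or obs.jackknife_se <= 0:
            raise ValueError(f"{obs.kind}{obs.pops}: missing jackknife SE")
        if obs.kind == "f2":
            exp = expected.f2(*obs.pops)
        elif obs.kind == "f3":
            exp = expected.f3(*obs.pops)
        elif obs.kind == "f4":
            exp = expected.f4(*obs.pops)
        else:
            raise ValueError(f"unknown statistic kind {obs.kind!r}")
        z = (obs.estimate - exp) / obs.jackknife_se
        rows.append(
            {
                "kind": obs.kind,
                "pops": obs.pops,
                "observed": obs.estimate,
                "expected": exp,
                "se": obs.jackknife_se,
                "z": z,
            }
        )
    if not rows:
        return GraphFitReport([], 0.0, None)
    worst = max(rows, key=lambda r: abs(r["z"]))
    return GraphFitReport(rows, abs(worst["z"]), worst)
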