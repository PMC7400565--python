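"""Mantel-family permutation tests: exactness, calibration, invariances."""

import itertools

import numpy as np
import pytest
from scipy import stats

from popkit.explanatory import LabeledDistanceMatrix
from popkit.matrixtests import (
    jackknife_regression_ci,
    mantel_simple,
    matrix_regression,
    partial_mantel,
)


def random_metric(rng, n, name="x"):
    pts = rng.normal(size=(n, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    np.fill_diagonal(d, 0)
    return LabeledDistanceMatrix([f"i{k}" for k in range(n)], d, name)


class TestMantelSimple:
    def test_self_correlation_minimal_p(self):
        rng = np.random.default_rng(1)
        dy = random_metric(rng, 12, "genetic")
        dx = LabeledDistanceMatrix(dy.labels, dy.values.copy(), "geography")
        r = mantel_simple(dy, dx, nperm=999, seed=0, exhaustive=False)
        assert r.coefficients["geography"] == pytest.approx(1.0)
        assert r.p_values["geography"] == pytest.approx(1 / 1000)

    def test_exhaustive_small_n_matches_montecarlo(self):
        rng = np.random.default_rng(2)
        dy, dx = random_metric(rng, 5, "genetic"), random_metric(rng, 5, "x")
        exact = mantel_simple(dy, dx, seed=0)  # auto-exhaustive at n=5
        assert exact.exhaustive and exact.n_permutations == 120
        mc = mantel_simple(dy, dx, nperm=20_000, seed=3, exhaustive=False)
        # binomial error of the Monte-Carlo estimate
        se = np.sqrt(exact.p_values["x"] * (1 - exact.p_values["x"]) / 20_000)
        assert abs(mc.p_values["x"] - exact.p_values["x"]) < 4 * se + 1e-4

    def test_exhaustive_p_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(4)
        dy, dx = random_metric(rng, 5, "genetic"), random_metric(rng, 5, "x")
        res = mantel_simple(dy, dx, seed=0)
        ii, jj = np.tril_indices(5, -1)
        x = stats.rankdata(dx.values[ii, jj])
        r_obs = None
        rs = []
        for perm in itertools.permutations(range(5)):
            p = np.array(perm)
            y = stats.rankdata(dy.values[p[ii], p[jj]])
            rs.append(stats.pearsonr(x, y).statistic)
            if perm == tuple(range(5)):
                r_obs = rs[-1]
        expected_p = np.mean(np.abs(rs) >= abs(r_obs) - 1e-12)
        assert res.p_values["x"] == pytest.approx(expected_p)

    def test_pearson_option(self):
        rng = np.random.default_rng(5)
        dy, dx = random_metric(rng, 10, "genetic"), random_metric(rng, 10, "x")
        r = mantel_simple(dy, dx, method="pearson", nperm=99, seed=0, exhaustive=False)
        ii, jj = np.tril_indices(10, -1)
        assert r.coefficients["x"] == pytest.approx(
            stats.pearsonr(dy.values[ii, jj], dx.values[ii, jj]).statistic
        )

    def test_constant_matrix_rejected(self):
        labels = ["a", "b", "c", "d"]
        const = LabeledDistanceMatrix(labels, np.ones((4, 4)) - np.eye(4), "x")
        rng = np.random.default_rng(6)
        dy = random_metric(rng, 4, "genetic")
        dy.labels = labels
        with pytest.raises(ValueError, match="constant"):
            mantel_simple(dy, const, seed=0)

    def test_seeded_runs_bit_reproducible(self):
        rng = np.random.default_rng(7)
        dy, dx = random_metric(rng, 15, "genetic"), random_metric(rng, 15, "x")
        r1 = mantel_simple(dy, dx, nperm=500, seed=42)
        r2 = mantel_simple(dy, dx, nperm=500, seed=42)
        assert r1.p_values == r2.p_values

    def test_invariant_to_common_relabeling(self):
        rng = np.random.default_rng(8)
        dy, dx = random_metric(rng, 9, "genetic"), random_metric(rng, 9, "x")
        perm = rng.permutation(9)
        dy2 = LabeledDistanceMatrix(
            [dy.labels[i] for i in perm], dy.values[np.ix_(perm, perm)], "genetic"
        )
        dx2 = LabeledDistanceMatrix(
            [dx.labels[i] for i in perm], dx.values[np.ix_(perm, perm)], "x"
        )
        r1 = mantel_simple(dy, dx, nperm=400, seed=9)
        r2 = mantel_simple(dy2, dx2, nperm=400, seed=9)
        assert r1.coefficients["x"] == pytest.approx(r2.coefficients["x"])


class TestMatrixRegression:
    def test_noiseless_construction_recovered(self):
        rng = np.random.default_rng(10)
        dx1 = random_metric(rng, 12, "geography")
        dx2 = random_metric(rng, 12, "time")
        dx2.labels = dx1.labels
        dy = LabeledDistanceMatrix(dx1.labels, 2.0 * dx1.values, "genetic")
        r = matrix_regression(dy, [dx1, dx2], nperm=200, seed=0)
        assert r.coefficients["geography"] == pytest.approx(2.0, abs=1e-9)
        assert r.coefficients["time"] == pytest.approx(0.0, abs=1e-9)
        assert r.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_driver_significant_proxy_attenuated(self):
        # geography drives genetics; language is a noisy copy of geography
        rng = np.random.default_rng(11)
        n = 25
        geo = random_metric(rng, n, "geography")
        lang_vals = geo.values + np.abs(rng.normal(0, 0.8, size=(n, n)))
        lang_vals = (lang_vals + lang_vals.T) / 2
        np.fill_diagonal(lang_vals, 0)
        lang = LabeledDistanceMatrix(geo.labels, lang_vals, "language")
        gen_vals = geo.values + np.abs(rng.normal(0, 0.2, size=(n, n)))
        gen_vals = (gen_vals + gen_vals.T) / 2
        np.fill_diagonal(gen_vals, 0)
        dy = LabeledDistanceMatrix(geo.labels, gen_vals, "genetic")
        simple_geo = mantel_simple(dy, geo, nperm=999, seed=1, exhaustive=False)
        simple_lang = mantel_simple(dy, lang, nperm=999, seed=2, exhaustive=False)
        assert simple_geo.p_values["geography"] < 0.01
        assert simple_lang.p_values["language"] < 0.05  # proxy shows up alone
        part_lang = partial_mantel(dy, lang, [geo], nperm=999, seed=3)
        assert part_lang.p_values["language"] > simple_lang.p_values["language"]

    def test_collinear_inputs_warn(self):
        rng = np.random.default_rng(12)
        dx1 = random_metric(rng, 10, "a")
        dx2 = LabeledDistanceMatrix(dx1.labels, dx1.values * 2.0, "b")
        dy = random_metric(rng, 10, "genetic")
        dy.labels = dx1.labels
        with pytest.warns(UserWarning, match="collinear"):
            matrix_regression(dy, [dx1, dx2], nperm=50, seed=0)


class TestPartialMantel:
    def test_no_covariates_equals_simple(self):
        rng = np.random.default_rng(13)
        dy, dx = random_metric(rng, 10, "genetic"), random_metric(rng, 10, "x")
        a = partial_mantel(dy, dx, [], nperm=500, seed=5)
        b = mantel_simple(dy, dx, nperm=500, seed=5, exhaustive=False)
        assert a.coefficients["x"] == pytest.approx(b.coefficients["x"])
        assert a.p_values["x"] == b.p_values["x"]

    def test_focus_equal_to_covariate_vanishes(self):
        rng = np.random.default_rng(14)
        dy = random_metric(rng, 12, "genetic")
        dx = random_metric(rng, 12, "x")
        dx.labels = dy.labels
        cov = LabeledDistanceMatrix(dy.labels, dx.values.copy(), "cov")
        r = partial_mantel(dy, dx, [cov], method="pearson", nperm=200, seed=6)
        assert abs(r.coefficients["x"]) < 1e-10

    def test_independent_variable_not_significant_at_nominal_rate(self):
        rng = np.random.default_rng(15)
        rejections = 0
        for rep in range(40):
            geo = random_metric(rng, 15, "geography")
            lang = random_metric(rng, 15, "language")
            noise = np.abs(rng.normal(0, 0.05, size=(15, 15)))
            gen = geo.values + (noise + noise.T) / 2
            np.fill_diagonal(gen, 0)
            dy = LabeledDistanceMatrix(geo.labels, gen, "genetic")
            lang.labels = geo.labels
            r = partial_mantel(dy, lang, [geo], nperm=199,
                               seed=int(rng.integers(2**31)))
            rejections += r.p_values["language"] <= 0.05
        assert rejections <= 7  # ~binomial(40, 0.05) upper tail


@pytest.fixture(scope="module")
def jk_setup():
    from popkit.genotype_io import (
        assign_blocks,
        build_group_counts,
        grouping_from_labels,
    )
    from popkit.simulate import (
        DemographyModel,
        make_panel,
        outgroup_cline_graph,
        sample_pseudohaploid,
        simulate_frequencies,
    )

    g = outgroup_cline_graph()
    rng = np.random.default_rng(16)
    panel = make_panel(10_000, 20, rng=rng)
    model = DemographyModel(g, {l: 4 for l in g.leaves}, n_snps=10_000)
    freqs = simulate_frequencies(model, rng)
    table = sample_pseudohaploid(
        panel, freqs, {l: 4 for l in g.leaves}, missingness=0.2, rng=rng
    )
    per_ind = {
        i: [i] for i in table.individual_ids if not i.startswith("Outgroup")
    }
    per_ind["OG"] = [i for i in table.individual_ids if i.startswith("Outgroup")]
    counts = build_group_counts(table, per_ind)
    blocks = assign_blocks(panel)
    targets = [i for i in per_ind if i != "OG"]
    rng2 = np.random.default_rng(17)
    n = len(targets)
    base = np.abs(rng2.normal(size=(n, n)))
    base = (base + base.T) / 2
    np.fill_diagonal(base, 0)
    expl = [LabeledDistanceMatrix(targets, base, "geography")]
    return counts, targets, expl, blocks


class TestJackknifeRegressionCI:
    def test_ci_brackets_estimate(self, jk_setup):
        counts, targets, expl, blocks = jk_setup
        out = jackknife_regression_ci(counts, "OG", targets, expl, blocks)
        beta, se, (lo, hi) = out["geography"]
        assert lo <= beta <= hi
        assert hi - lo == pytest.approx(2 * 1.96 * se, rel=1e-9)

    def test_empty_block_deletion_is_noop(self, jk_setup):
        counts, targets, expl, blocks = jk_setup
        # recomputing with an extra all-empty block leaves estimates unchanged
        import copy

        blocks2 = copy.deepcopy(blocks)
        blocks2.n_blocks += 1  # the phantom block holds no SNPs
        a = jackknife_regression_ci(counts, "OG", targets, expl, blocks)
        b = jackknife_regression_ci(counts, "OG", targets, expl, blocks2)
        assert a["geography"][0] == pytest.approx(b["geography"][0])
        assert a["geography"][1] == pytest.approx(b["geography"][1])
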