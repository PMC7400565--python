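"""f-statistics against independent per-SNP oracles and algebraic identities."""

import numpy as np
import pytest

from popkit.fstats import (
    conditional_heterozygosity,
    f2,
    f3,
    f4,
    jackknife_covariance,
    outgroup_f3_matrix,
    pairwise_mismatch,
    weighted_block_jackknife,
)
from popkit.genotype_io import (
    GenotypeTable,
    IndividualRecord,
    SnpPanel,
    assign_blocks,
    build_group_counts,
)
from popkit.simulate import (
    DemographyModel,
    make_panel,
    sample_pseudohaploid,
    simulate_frequencies,
)
from popkit.mixture import AdmixtureGraph
from popkit.genotype_io import grouping_from_labels
from conftest import make_panel_df, random_table


# --------------------------------------------------------------------------
# naive oracles: straightforward per-SNP loops, independent of the package


def naive_f2(counts, a, b):
    vals = []
    for s in range(counts.alt.shape[1]):
        na, nb = counts.n(a)[s], counts.n(b)[s]
        if na < 2 or nb < 2:
            continue
        p, q = counts.a(a)[s] / na, counts.a(b)[s] / nb
        vals.append((p - q) ** 2 - p * (1 - p) / (na - 1) - q * (1 - q) / (nb - 1))
    return np.mean(vals)


def naive_f3(counts, c, a, b):
    vals = []
    for s in range(counts.alt.shape[1]):
        nc, na, nb = counts.n(c)[s], counts.n(a)[s], counts.n(b)[s]
        if nc < 2 or na < 1 or nb < 1:
            continue
        pc = counts.a(c)[s] / nc
        pa = counts.a(a)[s] / na
        pb = counts.a(b)[s] / nb
        vals.append((pc - pa) * (pc - pb) - pc * (1 - pc) / (nc - 1))
    return np.mean(vals)


def naive_f4(counts, a, b, c, d):
    vals = []
    for s in range(counts.alt.shape[1]):
        ns = [counts.n(g)[s] for g in (a, b, c, d)]
        if min(ns) < 1:
            continue
        pa, pb, pc, pd = (counts.a(g)[s] / counts.n(g)[s] for g in (a, b, c, d))
        vals.append((pa - pb) * (pc - pd))
    return np.mean(vals)


class TestOracleEquivalence:
    def test_f2_hand_example(self):
        # A draws {1,1,0,0}, B draws {1,1,1,1} at one SNP
        df = make_panel_df(1)
        inds = [IndividualRecord(individual_id=f"i{k}") for k in range(8)]
        calls = np.array([[1, 1, 0, 0, 1, 1, 1, 1]], dtype=np.int8)
        t = GenotypeTable(SnpPanel(df), inds, calls)
        c = build_group_counts(
            t, {"A": ["i0", "i1", "i2", "i3"], "B": ["i4", "i5", "i6", "i7"]}
        )
        from popkit.fstats import _f2_values

        vals, used = _f2_values(c, "A", "B")
        assert used[0]
        assert vals[0] == pytest.approx(0.25 - 0.25 / 3, abs=1e-12)

    def test_fstats_match_naive_loops(self, small_setup):
        _, counts, blocks = small_setup
        assert f2("A", "B", counts, blocks).estimate == pytest.approx(
            naive_f2(counts, "A", "B"), abs=1e-12
        )
        assert f3("C", "A", "B", counts, blocks).estimate == pytest.approx(
            naive_f3(counts, "C", "A", "B"), abs=1e-12
        )
        # need 4 groups for f4
        rng = np.random.default_rng(7)
        t = random_table(rng, n_snps=50, n_ind=8)
        g = {"A": ["i0", "i1"], "B": ["i2", "i3"], "C": ["i4", "i5"], "D": ["i6", "i7"]}
        c = build_group_counts(t, g)
        b = assign_blocks(t.panel, block_span_bp=1_000_000)
        assert f4("A", "B", "C", "D", c, b).estimate == pytest.approx(
            naive_f4(c, "A", "B", "C", "D"), abs=1e-12
        )

    def test_monomorphic_panel_gives_zero(self):
        df = make_panel_df(5)
        inds = [IndividualRecord(individual_id=f"i{k}") for k in range(4)]
        t = GenotypeTable(SnpPanel(df), inds, np.ones((5, 4), dtype=np.int8))
        c = build_group_counts(t, {"A": ["i0", "i1"], "B": ["i2", "i3"]})
        b = assign_blocks(t.panel, block_span_bp=200_000)
        assert f2("A", "B", c, b).estimate == 0.0

    def test_f2_same_counts_equals_correction_term(self, rng):
        # identical draws: (p-q)^2 = 0, leaving -2 sum p(1-p)/(n-1) / S
        t = random_table(rng, n_snps=30, n_ind=4, missing_rate=0.0)
        g = {"A": ["i0", "i1", "i2", "i3"], "B": ["i0", "i1", "i2", "i3"]}
        c = build_group_counts(t, g)
        b = assign_blocks(t.panel, block_span_bp=1_000_000)
        p = c.a("A") / c.n("A")
        expected = np.mean(-2 * p * (1 - p) / (c.n("A") - 1))
        assert f2("A", "B", c, b).estimate == pytest.approx(expected, abs=1e-12)


class TestIdentities:
    def test_f3_against_f2_decomposition(self, small_setup):
        _, counts, blocks = small_setup
        from popkit.fstats import _f2_values, _f3_values

        v3, u3 = _f3_values(counts, "C", "A", "B", True)
        vac, uac = _f2_values(counts, "A", "C")
        vbc, ubc = _f2_values(counts, "B", "C")
        vab, uab = _f2_values(counts, "A", "B")
        common = u3 & uac & ubc & uab
        np.testing.assert_allclose(
            v3[common], 0.5 * (vac + vbc - vab)[common], atol=1e-12
        )

    def test_f3_target_duplicated_source_equals_f2(self, small_setup):
        _, counts, blocks = small_setup
        r3 = f3("C", "A", "A", counts, blocks)
        from popkit.fstats import _f2_values, _f3_values

        v3, u3 = _f3_values(counts, "C", "A", "A", True)
        v2, u2 = _f2_values(counts, "A", "C")
        common = u3 & u2
        # identical per SNP up to A's own correction term
        na = counts.n("A")
        pa = np.where(na > 0, counts.a("A") / np.maximum(na, 1), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = pa * (1 - pa) / (na - 1)
        np.testing.assert_allclose(v3[common], (v2 + corr)[common], atol=1e-12)

    def test_f4_degenerate_and_antisymmetry(self, rng):
        t = random_table(rng, n_snps=50, n_ind=8)
        g = {"A": ["i0", "i1"], "B": ["i2", "i3"], "C": ["i4", "i5"], "D": ["i6", "i7"]}
        c = build_group_counts(t, g)
        b = assign_blocks(t.panel, block_span_bp=1_000_000)
        assert f4("A", "B", "C", "C", c, b).estimate == 0.0
        r = f4("A", "B", "C", "D", c, b)
        assert f4("B", "A", "C", "D", c, b).estimate == pytest.approx(-r.estimate, abs=1e-15)
        assert f4("C", "D", "A", "B", c, b).estimate == pytest.approx(r.estimate, abs=1e-15)

    def test_f4_three_term_sum_is_zero(self, rng):
        t = random_table(rng, n_snps=50, n_ind=8, missing_rate=0.0)
        g = {"A": ["i0", "i1"], "B": ["i2", "i3"], "C": ["i4", "i5"], "D": ["i6", "i7"]}
        c = build_group_counts(t, g)
        b = assign_blocks(t.panel, block_span_bp=1_000_000)
        total = (
            f4("A", "B", "C", "D", c, b).estimate
            + f4("B", "C", "A", "D", c, b).estimate
            + f4("C", "A", "B", "D", c, b).estimate
        )
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_f4_linearity_in_fourth_slot(self, rng):
        t = random_table(rng, n_snps=60, n_ind=10, missing_rate=0.0)
        g = {k: [f"i{2*j}", f"i{2*j+1}"] for j, k in enumerate("ABCDE")}
        c = build_group_counts(t, g)
        b = assign_blocks(t.panel, block_span_bp=1_000_000)
        lhs = f4("A", "B", "C", "D", c, b).estimate
        rhs = f4("A", "B", "C", "E", c, b).estimate + f4("A", "B", "E", "D", c, b).estimate
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestJackknife:
    def test_equal_weights_reduce_to_ordinary_jackknife(self, rng):
        vals = rng.normal(size=40)
        sums = vals.reshape(8, 5).sum(axis=1)
        w = np.full(8, 5.0)
        est, se = weighted_block_jackknife(sums, w)
        # ordinary delete-one jackknife over block means
        theta = vals.mean()
        loo = np.array([(vals.sum() - s) / 35 for s in sums])
        var = (8 - 1) / 8 * np.sum((loo - loo.mean()) ** 2)
        assert est == pytest.approx(theta)
        assert se == pytest.approx(np.sqrt(var), rel=1e-10)

    def test_matches_closed_form_se_of_mean(self, rng):
        n = 10_000
        vals = rng.normal(size=n)
        sums = vals.reshape(100, 100).sum(axis=1)
        _, se = weighted_block_jackknife(sums, np.full(100, 100.0))
        assert se == pytest.approx(vals.std(ddof=1) / np.sqrt(n), rel=0.05)

    def test_weight_rescaling_invariance(self, rng):
        sums = rng.normal(size=12)
        w = rng.integers(5, 50, size=12).astype(float)
        est1, se1 = weighted_block_jackknife(sums, w)
        est2, se2 = weighted_block_jackknife(sums * 1.0, w * 2)  # doubling weights
        # doubling weights rescales the estimate of the mean; statistic scale
        # invariance applies when sums scale with weights
        est3, se3 = weighted_block_jackknife(sums * 2, w * 2)
        assert est3 == pytest.approx(est1)
        assert se3 == pytest.approx(se1)

    def test_block_relabeling_invariance(self, rng):
        sums = rng.normal(size=15)
        w = rng.integers(10, 30, size=15).astype(float)
        perm = rng.permutation(15)
        est1, se1 = weighted_block_jackknife(sums, w)
        est2, se2 = weighted_block_jackknife(sums[perm], w[perm])
        assert (est1, se1) == pytest.approx((est2, se2))

    def test_single_block_rejected(self):
        with pytest.raises(ValueError, match=">= 2 blocks"):
            weighted_block_jackknife(np.array([1.0]), np.array([10.0]))

    def test_covariance_diagonal_matches_scalar(self, rng):
        sums = rng.normal(size=(20, 3))
        w = rng.integers(5, 40, size=20).astype(float)
        mean, cov = jackknife_covariance(sums, w)
        for k in range(3):
            est, se = weighted_block_jackknife(sums[:, k], w)
            assert mean[k] == pytest.approx(est)
            assert np.sqrt(cov[k, k]) == pytest.approx(se, rel=1e-10)


class TestHeterozygosity:
    def test_single_polymorphic_draw_pair(self):
        df = make_panel_df(1)
        inds = [IndividualRecord(individual_id=f"i{k}") for k in range(2)]
        t = GenotypeTable(SnpPanel(df), inds, np.array([[0, 1]], dtype=np.int8))
        c = build_group_counts(t, {"g": ["i0", "i1"]})
        b = assign_blocks(t.panel, block_span_bp=1)
        with pytest.raises(ValueError):
            conditional_heterozygosity("g", c, b)  # single block: SE undefined

    def test_identical_individuals_give_zero(self):
        df = make_panel_df(6)
        inds = [IndividualRecord(individual_id=f"i{k}") for k in range(3)]
        t = GenotypeTable(SnpPanel(df), inds, np.ones((6, 3), dtype=np.int8))
        c = build_group_counts(t, {"g": ["i0", "i1", "i2"]})
        b = assign_blocks(t.panel, block_span_bp=200_000)
        assert conditional_heterozygosity("g", c, b).estimate == 0.0

    def test_bernoulli_half_draws(self, rng):
        n = 10_000
        df = make_panel_df(n, spacing=600_000)
        inds = [IndividualRecord(individual_id=f"i{k}") for k in range(4)]
        calls = (rng.random((n, 4)) < 0.5).astype(np.int8)
        t = GenotypeTable(SnpPanel(df), inds, calls)
        c = build_group_counts(t, {"g": t.individual_ids})
        b = assign_blocks(t.panel)
        r = conditional_heterozygosity("g", c, b)
        assert abs(r.estimate - 0.5) < 3 * r.jackknife_se
        assert 0.0 <= r.estimate <= 1.0


class TestMismatch:
    def _table(self, calls):
        calls = np.asarray(calls, dtype=np.int8)
        df = make_panel_df(calls.shape[0], spacing=400_000)
        inds = [IndividualRecord(individual_id=f"i{k}") for k in range(calls.shape[1])]
        return GenotypeTable(SnpPanel(df), inds, calls)

    def test_identical_vectors(self, rng):
        v = (rng.random(100) < 0.4).astype(np.int8)
        t = self._table(np.column_stack([v, v]))
        r = pairwise_mismatch("i0", "i1", t, min_overlap=50, baseline_rate=0.3)
        assert r.rate == 0.0
        assert r.call == "identical/twin-or-self"

    def test_complementary_vectors(self, rng):
        v = (rng.random(100) < 0.4).astype(np.int8)
        t = self._table(np.column_stack([v, 1 - v]))
        r = pairwise_mismatch("i0", "i1", t, min_overlap=50)
        assert r.rate == 1.0

    def test_low_overlap_indeterminate(self, rng):
        t = self._table(np.zeros((10, 2)))
        r = pairwise_mismatch("i0", "i1", t, min_overlap=5000)
        assert r.call == "indeterminate"

    def test_parent_offspring_rate_ratio(self, rng):
        # one shared haplotype: child allele = parent's with prob 1/2, else
        # population draw; mismatch ~ 0.75x the unrelated baseline
        n = 40_000
        p = rng.uniform(0.2, 0.8, n)
        m1, m2 = ((rng.random(n) < p).astype(np.int8) for _ in range(2))
        mother = np.where(rng.random(n) < 0.5, m1, m2)  # her random-allele call
        transmitted = np.where(rng.random(n) < 0.5, m1, m2)  # independent draw
        paternal = (rng.random(n) < p).astype(np.int8)
        child = np.where(rng.random(n) < 0.5, transmitted, paternal)
        unrel = (rng.random(n) < p).astype(np.int8)
        df = make_panel_df(n, spacing=50_000)
        t = GenotypeTable(
            SnpPanel(df),
            [IndividualRecord(individual_id=i) for i in ("m", "c", "u")],
            np.column_stack([mother, child, unrel]),
        )
        base = pairwise_mismatch("m", "u", t, min_overlap=100).rate
        po = pairwise_mismatch("m", "c", t, min_overlap=100, baseline_rate=base)
        assert po.rate / base == pytest.approx(0.75, abs=0.05)
        assert po.call == "first-degree"


@pytest.fixture(scope="module")
def tree_data():
    g = AdmixtureGraph()
    g.add_edge("R", "X", 0.01)
    g.add_edge("R", "O", 0.03)
    g.add_edge("X", "A", 0.01)
    g.add_edge("X", "Y", 0.01)
    g.add_edge("Y", "B", 0.01)
    g.add_edge("Y", "C", 0.01)
    rng = np.random.default_rng(42)
    panel = make_panel(20_000, 20, rng=rng)
    model = DemographyModel(g, {l: 10 for l in g.leaves}, n_snps=20_000)
    freqs = simulate_frequencies(model, rng)
    table = sample_pseudohaploid(
        panel, freqs, {l: 10 for l in g.leaves}, missingness=0.3, rng=rng
    )
    counts = build_group_counts(table, grouping_from_labels(table))
    blocks = assign_blocks(panel)
    return counts, blocks


class TestSimulatedTreeBehavior:
    """Distributional sanity on tree / admixture simulations."""

    def test_unadmixed_f3_not_significantly_negative(self, tree_data):
        counts, blocks = tree_data
        for target, s1, s2 in [("B", "A", "C"), ("C", "A", "B"), ("A", "B", "O")]:
            r = f3(target, s1, s2, counts, blocks)
            assert r.z_score > -3

    def test_treelike_f4_consistent_with_zero(self, tree_data):
        counts, blocks = tree_data
        r = f4("B", "C", "A", "O", counts, blocks)
        assert abs(r.z_score) < 4

    def test_admixed_target_f3_strongly_negative(self):
        rng = np.random.default_rng(11)
        n = 100_000
        pa = rng.uniform(0.05, 0.95, n)
        pb = np.clip(pa + rng.normal(0, 0.25, n), 0.01, 0.99)
        pt = 0.5 * pa + 0.5 * pb
        df = make_panel_df(n, spacing=60_000)
        panel = SnpPanel(df)
        freqs = {"A": pa, "B": pb, "T": pt}
        t = sample_pseudohaploid(panel, freqs, {"A": 10, "B": 10, "T": 10}, rng=rng)
        c = build_group_counts(t, grouping_from_labels(t))
        b = assign_blocks(panel)
        r = f3("T", "A", "B", c, b)
        assert r.estimate < 0
        assert r.z_score < -3


@pytest.fixture(scope="module")
def drift_matrix():
    from popkit.simulate import outgroup_cline_graph

    g = outgroup_cline_graph()
    rng = np.random.default_rng(5)
    panel = make_panel(15_000, 20, rng=rng)
    model = DemographyModel(g, {l: 6 for l in g.leaves}, n_snps=15_000)
    freqs = simulate_frequencies(model, rng)
    table = sample_pseudohaploid(
        panel, freqs, {l: 6 for l in g.leaves}, missingness=0.2, rng=rng
    )
    counts = build_group_counts(table, grouping_from_labels(table))
    blocks = assign_blocks(panel)
    return outgroup_f3_matrix(counts, "Outgroup", blocks, min_snps=1000)


class TestOutgroupF3Matrix:

    def test_symmetry_and_diagonal_dominance(self, drift_matrix):
        sd = drift_matrix
        np.testing.assert_allclose(sd.values, sd.values.T)
        for i in range(len(sd.labels)):
            assert sd.values[i, i] >= sd.values[i].min()

    def test_sisters_share_more_drift(self, drift_matrix):
        sd = drift_matrix
        i = sd.labels.index("WesternArchipelago")
        j = sd.labels.index("BeagleChannel")
        k = sd.labels.index("SouthContinent")
        assert sd.values[i, j] > sd.values[i, k]

    def test_one_minus_transform(self, drift_matrix):
        sd = drift_matrix
        om = sd.one_minus()
        off = ~np.eye(len(sd.labels), dtype=bool)
        np.testing.assert_allclose(om[off], 1 - sd.values[off])
        assert np.all(np.diag(om) == 0)

    def test_min_snps_exclusion_listed(self, drift_matrix):
        from popkit.simulate import outgroup_cline_graph
        assert drift_matrix.excluded == []
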