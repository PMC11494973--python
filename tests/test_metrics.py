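"""Efficiency, purity gates, concordance statistics and diversity measures."""

import numpy as np
import pandas as pd
import pytest

import nano16s as n16
from conftest import make_profile


class TestPoolEfficiency:
    def test_fraction(self):
        table = pd.DataFrame(
            {"read_id": [f"r{i}" for i in range(100)],
             "status": ["assigned"] * 50 + ["no_primer"] * 50}
        )
        stats = n16.pool_efficiency(table, "p")
        assert stats.efficiency == 0.5
        assert (stats.n_pcr_demuxed, stats.n_total) == (50, 100)

    def test_zero_assigned(self):
        table = pd.DataFrame({"read_id": ["r"], "status": ["no_barcode"]})
        assert n16.pool_efficiency(table, "p").efficiency == 0.0

    def test_unknown_pool_errors(self):
        table = pd.DataFrame({"read_id": ["r"], "status": ["assigned"], "native_pool": ["a"]})
        with pytest.raises(KeyError):
            n16.pool_efficiency(table, "b")


class TestCallSample:
    def test_passing_call(self):
        call = n16.call_sample(make_profile({"A": 0.95, "B": 0.05}, 200))
        assert call.top_species == "A"
        assert call.purity == pytest.approx(0.95)
        assert call.passes_purity and call.passes_depth

    def test_purity_boundary(self):
        assert not n16.call_sample(make_profile({"A": 0.89, "B": 0.11})).passes_purity
        assert n16.call_sample(make_profile({"A": 0.90, "B": 0.10})).passes_purity

    def test_depth_boundary(self):
        assert not n16.call_sample(make_profile({"A": 1.0}, 9)).passes_depth
        assert n16.call_sample(make_profile({"A": 1.0}, 10)).passes_depth

    def test_empty_profile(self):
        call = n16.call_sample(n16.AbundanceProfile("s", {}, 0))
        assert call.top_species is None
        assert not call.passes_depth and not call.passes_purity

    def test_tie_breaks_lexicographically(self):
        call = n16.call_sample(make_profile({"B": 0.5, "A": 0.5}))
        assert call.top_species == "A"


class TestPpv:
    def test_worked_example(self):
        assert n16.ppv(36, 4) == pytest.approx(0.90)

    @pytest.mark.parametrize("tp,fp,expected", [(10, 0, 1.0), (0, 5, 0.0)])
    def test_edges(self, tp, fp, expected):
        assert n16.ppv(tp, fp) == expected

    def test_undefined(self):
        with pytest.raises(ValueError):
            n16.ppv(0, 0)


def brute_chi2(counts):
    counts = np.asarray(counts, float)
    n = counts.sum()
    chi2 = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            e = counts[i].sum() * counts[:, j].sum() / n
            chi2 += (counts[i, j] - e) ** 2 / e
    return chi2


def brute_theils_u(counts):
    counts = np.asarray(counts, float)
    n = counts.sum()

    def H(p):
        p = p[p > 0]
        return -(p * np.log(p)).sum()

    h_row = H(counts.sum(axis=1) / n)
    h_cond = sum(
        (counts[:, j].sum() / n) * H(counts[:, j] / counts[:, j].sum())
        for j in range(counts.shape[1])
        if counts[:, j].sum() > 0
    )
    return (h_row - h_cond) / h_row


class TestConcordanceStats:
    def test_diagonal_table_perfect_association(self):
        t = n16.ContingencyTable(["a", "b"], ["x", "y"], [[10, 0], [0, 10]])
        assert n16.cramers_v(t) == pytest.approx(1.0)
        assert n16.theils_u(t) == pytest.approx(1.0)

    def test_independent_table_zero(self):
        t = n16.ContingencyTable(["a", "b"], ["x", "y"], [[5, 5], [5, 5]])
        assert n16.cramers_v(t) == pytest.approx(0.0, abs=1e-12)
        assert n16.theils_u(t) == pytest.approx(0.0, abs=1e-12)

    def test_fixture_matches_brute_force(self):
        counts = [[8, 2], [3, 7]]
        t = n16.ContingencyTable(["a", "b"], ["x", "y"], counts)
        chi2 = brute_chi2(counts)
        assert chi2 == pytest.approx(5.05, abs=0.01)
        assert n16.cramers_v(t) == pytest.approx(np.sqrt(chi2 / 20), abs=1e-12)
        assert n16.cramers_v(t) == pytest.approx(0.503, abs=0.001)
        assert n16.theils_u(t, "row|col") == pytest.approx(brute_theils_u(counts), abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 20, size=(3, 4))
        t = n16.ContingencyTable(list("abc"), list("wxyz"), counts)
        perm_r = rng.permutation(3)
        perm_c = rng.permutation(4)
        t2 = n16.ContingencyTable(
            [t.row_labels[i] for i in perm_r],
            [t.col_labels[j] for j in perm_c],
            counts[np.ix_(perm_r, perm_c)],
        )
        assert n16.cramers_v(t) == pytest.approx(n16.cramers_v(t2))
        assert n16.theils_u(t) == pytest.approx(n16.theils_u(t2))

    def test_zero_marginals_dropped(self):
        t = n16.ContingencyTable(
            ["a", "b", "c"], ["x", "y", "z"], [[10, 0, 0], [0, 10, 0], [0, 0, 0]]
        )
        assert n16.cramers_v(t) == pytest.approx(1.0)

    def test_direction_argument(self):
        counts = [[8, 2, 0], [3, 7, 5]]
        t = n16.ContingencyTable(["a", "b"], ["x", "y", "z"], counts)
        u_rc = n16.theils_u(t, "row|col")
        u_cr = n16.theils_u(t, "col|row")
        assert u_rc != pytest.approx(u_cr)
        assert brute_theils_u(np.array(counts).T) == pytest.approx(u_cr)


class TestAlphaDiversity:
    def test_uniform_four_taxa(self):
        r, s, bp = n16.alpha_diversity(make_profile({c: 0.25 for c in "abcd"}))
        assert (r, bp) == (4, 0.25)
        assert s == pytest.approx(np.log(4))

    def test_single_taxon(self):
        assert n16.alpha_diversity(make_profile({"a": 1.0})) == (1, 0.0, 1.0)

    def test_skewed_profile(self):
        r, s, bp = n16.alpha_diversity(make_profile({"a": 0.5, "b": 0.25, "c": 0.25}))
        assert r == 3
        assert s == pytest.approx(1.0397, abs=1e-4)
        assert bp == 0.5

    def test_empty_profile_convention(self):
        assert n16.alpha_diversity(n16.AbundanceProfile("s", {}, 0)) == (0, 0.0, 0.0)


class TestBrayCurtis:
    def test_identical_zero(self):
        p = make_profile({"a": 0.6, "b": 0.4})
        assert n16.bray_curtis(p, p) == pytest.approx(0.0)

    def test_disjoint_one(self):
        assert n16.bray_curtis({"a": 1.0}, {"b": 1.0}) == pytest.approx(1.0)

    def test_hand_example(self):
        assert n16.bray_curtis({"A": 0.6, "B": 0.4}, {"A": 0.2, "B": 0.8}) == pytest.approx(0.4)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pa = rng.dirichlet(np.ones(5))
            qa = rng.dirichlet(np.ones(5))
            p = {f"t{i}": v for i, v in enumerate(pa)}
            q = {f"t{i}": v for i, v in enumerate(qa)}
            assert n16.bray_curtis(p, q) == pytest.approx(n16.bray_curtis(q, p))
            assert 0.0 <= n16.bray_curtis(p, q) <= 1.0


class TestPermanova:
    def _clustered(self, gap, seed=0, n=6):
        rng = np.random.default_rng(seed)
        pts = np.vstack(
            [rng.normal(0, 1, size=(n, 3)), rng.normal(gap, 1, size=(n, 3))]
        )
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        return d, ["a"] * n + ["b"] * n

    def test_complete_separation(self):
        # two groups of identical points far apart; groups large enough
        # that permutations essentially never reproduce the exact split
        n = 16
        d = np.ones((n, n)) - np.eye(n)
        d[: n // 2, : n // 2] = 0
        d[n // 2 :, n // 2 :] = 0
        res = n16.permanova(d, ["a"] * (n // 2) + ["b"] * (n // 2), n_perm=99, seed=1)
        assert res.p_value == pytest.approx(1 / 100)
        assert res.r2 > 0.9

    def test_relabelling_invariance(self):
        d, groups = self._clustered(3.0, seed=5)
        perm = np.random.default_rng(2).permutation(len(groups))
        d2 = d[np.ix_(perm, perm)]
        g2 = [groups[i] for i in perm]
        r1 = n16.permanova(d, groups, n_perm=199, seed=7)
        r2 = n16.permanova(d2, g2, n_perm=199, seed=7)
        assert r1.f_stat == pytest.approx(r2.f_stat)
        assert r1.r2 == pytest.approx(r2.r2)

    def test_matches_skbio(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        d, groups = self._clustered(2.0, seed=9)
        dm = DistanceMatrix(d, [f"s{i}" for i in range(len(groups))])
        ours = n16.permanova(dm, groups, n_perm=9, seed=1)
        theirs = skbio_permanova(dm, grouping=list(groups), permutations=9)
        assert ours.f_stat == pytest.approx(float(theirs["test statistic"]), rel=1e-9)

    def test_degenerate_grouping_errors(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            n16.permanova(d, ["a", "a", "b"], n_perm=9)

    def test_null_p_values_roughly_uniform(self):
        # smaller companion to the full calibration in the acceptance suite
        from scipy.stats import kstest

        rng = np.random.default_rng(11)
        ps = []
        for _ in range(60):
            pts = rng.normal(size=(10, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            res = n16.permanova(d, ["a"] * 5 + ["b"] * 5, n_perm=99, seed=int(rng.integers(2**31)))
            ps.append(res.p_value)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestPairedDissimilarity:
    def test_identical_sets_all_zero(self):
        profs = {f"s{i}": make_profile({"a": 0.5, "b": 0.5}) for i in range(3)}
        report = n16.paired_dissimilarity_report(profs, profs, {k: k for k in profs})
        paired = report[report["kind"] == "paired"]["bray_curtis"]
        assert (paired == 0).all()

    def test_paired_lower_than_unpaired(self):
        rng = np.random.default_rng(13)
        profs_a, profs_b, pairing = {}, {}, {}
        for i in range(6):
            base = rng.dirichlet(np.ones(6) * 0.5)
            noise = rng.dirichlet(base * 200 + 1e-3)
            profs_a[f"a{i}"] = make_profile({f"t{j}": v for j, v in enumerate(base) if v > 0})
            profs_b[f"b{i}"] = make_profile({f"t{j}": v for j, v in enumerate(noise) if v > 0})
            pairing[f"a{i}"] = f"b{i}"
        report = n16.paired_dissimilarity_report(profs_a, profs_b, pairing)
        paired = report[report["kind"] == "paired"]["bray_curtis"].mean()
        unpaired = report[report["kind"] == "unpaired"]["bray_curtis"].mean()
        assert paired < unpaired

    def test_single_pair_has_empty_unpaired_set(self):
        p = {"a0": make_profile({"a": 1.0})}
        q = {"b0": make_profile({"a": 1.0})}
        report = n16.paired_dissimilarity_report(p, q, {"a0": "b0"})
        assert (report["kind"] == "unpaired").sum() == 0

    def test_unknown_ids_listed(self):
        p = {"a0": make_profile({"a": 1.0})}
        with pytest.raises(KeyError, match="zz"):
            n16.paired_dissimilarity_report(p, p, {"zz": "a0"})


class TestRarefy:
    def test_full_depth_identity(self):
        counts = {"a": 5, "b": 7}
        assert n16.rarefy(counts, 12, seed=1) == counts

    def test_zero_depth(self):
        assert n16.rarefy({"a": 5}, 0, seed=1) == {"a": 0}

    def test_depth_exceeds_total_errors(self):
        with pytest.raises(ValueError):
            n16.rarefy({"a": 5}, 6)

    def test_hypergeometric_expectation(self):
        counts = {"A": 900, "B": 100}
        draws = [n16.rarefy(counts, 100, seed=s)["A"] for s in range(200)]
        # E[A] = 90, Var = n*p*(1-p)*(N-n)/(N-1)
        var = 100 * 0.9 * 0.1 * (1000 - 100) / 999
        se = np.sqrt(var / 200)
        assert abs(np.mean(draws) - 90) < 3 * np.sqrt(var)
        assert abs(np.mean(draws) - 90) < 5 * se + 1  # tight sanity on the mean
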