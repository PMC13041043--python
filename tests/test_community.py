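import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes

from fjordflux import community as comm


def small_table(counts=None, meta=None):
    taxonomy = pd.DataFrame(
        {
            "domain": ["Bacteria", "Bacteria", "Bacteria", "Archaea",
                       "Bacteria", "Bacteria"],
            "phylum": ["Proteobacteria", "Proteobacteria", "Bacteroidota",
                       "Thermoproteota", "Nitrospinota", None],
            "class": ["Gammaproteobacteria", "Alphaproteobacteria",
                      "Bacteroidia", "Nitrososphaeria", "Nitrospinia", None],
            "order": [None] * 6,
            "family": ["Nitrosomonadaceae", None, None, None, None, None],
            "genus": [None, "Nitrosococcus", None, None, None, None],
        },
        index=pd.Index([f"asv{i}" for i in range(1, 7)], name="asv_id"),
    )
    if counts is None:
        counts = pd.DataFrame(
            [[2, 3, 5, 0, 0, 0], [1, 1, 1, 1, 1, 5]],
            index=pd.Index(["s1", "s2"], name="sample_id"),
            columns=taxonomy.index,
        )
    return comm.TaxaTable(counts, taxonomy, meta)


class TestRelativeAbundance:
    def test_asv_level_proportions(self):
        props, excluded = comm.relative_abundance(small_table())
        assert excluded == []
        assert np.allclose(props.loc["s1"], [0.2, 0.3, 0.5, 0, 0, 0])

    def test_rank_aggregation_pools(self):
        props, _ = comm.relative_abundance(small_table(), rank="phylum")
        assert props.loc["s1", "Proteobacteria"] == pytest.approx(0.5)

    def test_unassigned_pooled_with_parent(self):
        props, _ = comm.relative_abundance(small_table(), rank="phylum")
        assert "Unclassified_Bacteria" in props.columns
        assert props.loc["s2", "Unclassified_Bacteria"] == pytest.approx(0.5)

    def test_rows_sum_to_one(self):
        for rank in (None, "phylum", "genus"):
            props, _ = comm.relative_abundance(small_table(), rank=rank)
            assert np.allclose(props.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_sample_excluded(self):
        counts = pd.DataFrame(
            [[1, 1, 1, 0, 0, 0], [0] * 6],
            index=pd.Index(["ok", "empty"], name="sample_id"),
            columns=[f"asv{i}" for i in range(1, 7)])
        props, excluded = comm.relative_abundance(small_table(counts))
        assert excluded == ["empty"]
        assert list(props.index) == ["ok"]


class TestGuilds:
    def test_default_rules(self):
        table = small_table()
        assignment, overlaps = comm.assign_guilds(table.taxonomy)
        assert assignment["asv1"] == "AOB"    # family Nitrosomonadaceae
        assert assignment["asv2"] == "AOB"    # genus Nitrosococcus
        assert assignment["asv4"] == "AOA"    # class Nitrososphaeria
        assert assignment["asv5"] == "NOB"    # phylum Nitrospinota
        assert assignment["asv6"] is None
        assert overlaps == {}

    def test_overlap_reported_and_precedence(self):
        taxonomy = pd.DataFrame(
            {"domain": ["Bacteria"], "phylum": ["Nitrospinota"],
             "class": ["Nitrososphaeria"], "order": [None], "family": [None],
             "genus": [None]},
            index=pd.Index(["weird"], name="asv_id"))
        assignment, overlaps = comm.assign_guilds(taxonomy)
        assert assignment["weird"] == "AOA"   # AOA > AOB > NOB precedence
        assert overlaps == {"weird": ["AOA", "NOB"]}

    def test_subset_against_total_community(self):
        out = comm.subset_nitrifiers(small_table())
        # s1: 10 reads, no nitrifiers except asv1/asv2 (AOB: 2+3=5)
        assert out.loc["s1", "AOB"] == pytest.approx(0.5)
        assert out.loc["s1", "AOA"] == 0.0
        # partition: guild + remainder sums to 1
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_remainder_split_by_domain(self):
        out = comm.subset_nitrifiers(small_table())
        assert "Other_Bacteria" in out.columns
        # s2 archaeal ASV is AOA, bacterial remainder = asv3 + asv6
        assert out.loc["s2", "Other_Bacteria"] == pytest.approx(6 / 10)


class TestRichness:
    def test_counts(self):
        counts = pd.DataFrame(
            [[5, 0, 2, 0, 1, 0], [0] * 6],
            index=pd.Index(["a", "b"], name="sample_id"),
            columns=[f"asv{i}" for i in range(1, 7)])
        r = comm.richness(small_table(counts))
        assert r["a"] == 3 and r["b"] == 0

    def test_scale_invariance(self):
        t1 = small_table()
        t2 = small_table(t1.counts * 2)
        assert (comm.richness(t1) == comm.richness(t2)).all()


def bc_oracle(x, y):
    return np.sum(np.abs(x - y)) / np.sum(x + y)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = comm.bray_curtis(np.array([[0.2, 0.8], [0.2, 0.8]]))
        assert d[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = comm.bray_curtis(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert d[0, 1] == 1.0

    def test_hand_value(self):
        d = comm.bray_curtis(np.array([[0.5, 0.5, 0.0],
                                       [0.25, 0.25, 0.5]]))
        assert d[0, 1] == pytest.approx(0.5, abs=1e-15)

    def test_matches_bruteforce_oracle(self, rng):
        x = rng.uniform(size=(5, 8))
        d = comm.bray_curtis(x)
        for i in range(5):
            for j in range(5):
                assert d[i, j] == pytest.approx(bc_oracle(x[i], x[j]),
                                                abs=1e-12)
        assert np.allclose(d, d.T)
        assert (d <= 1.0 + 1e-15).all() and (d >= 0).all()

    def test_two_zero_rows_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            comm.bray_curtis(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            comm.bray_curtis(np.array([[-1.0, 1.0], [1.0, 0.0]]))


class TestNMDS:
    def test_three_points_exact(self):
        d = np.array([[0, 1.0, 1.2], [1.0, 0, 0.8], [1.2, 0.8, 0]])
        res = comm.nmds(d, k=2, seed=0)
        assert res.stress < 1e-6

    def test_stress_history_monotone(self, rng):
        x = rng.normal(size=(12, 4))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        res = comm.nmds(d, seed=1)
        hist = res.stress_history
        assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))

    def test_geometry_recovery(self, rng):
        pts = rng.normal(size=(10, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = comm.nmds(d, k=2, seed=0)
        m1, m2, _ = procrustes(pts, res.coordinates)
        assert np.corrcoef(m1.ravel(), m2.ravel())[0, 1] > 0.99

    def test_seed_reproducible(self, rng):
        x = rng.uniform(size=(8, 5))
        d = comm.bray_curtis(x)
        a = comm.nmds(d, seed=7)
        b = comm.nmds(d, seed=7)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            comm.nmds(d)

    def test_centered_output(self, rng):
        x = rng.uniform(size=(9, 4))
        res = comm.nmds(comm.bray_curtis(x), seed=0)
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)


def block_distance(n_within=0.1, n_between=1.0):
    d = np.full((4, 4), n_between)
    d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = n_within
    np.fill_diagonal(d, 0.0)
    return d


class TestPermanova:
    def test_worked_example(self):
        res = comm.permanova(block_distance(), ["a", "a", "b", "b"],
                             n_perm=999, seed=0)
        assert res.pseudo_f == pytest.approx(199.0, abs=1e-9)
        assert res.p == pytest.approx(1.0 / 3.0)
        assert res.exhaustive
        assert res.n_permutations == 6

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            comm.permanova(block_distance(), ["a"] * 4)

    def test_p_lower_bound(self, rng):
        x = rng.normal(size=(14, 3))
        x[7:] += 5.0
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        res = comm.permanova(d, ["a"] * 7 + ["b"] * 7, n_perm=199, seed=0)
        assert res.p >= 1.0 / 200
        assert res.p <= 0.05

    def test_exhaustive_matches_montecarlo(self, rng):
        x = rng.normal(size=(7, 2))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        groups = ["a", "a", "a", "b", "b", "b", "b"]
        ex = comm.permanova(d, groups, n_perm=99999, seed=0)
        assert ex.exhaustive
        # Monte-Carlo estimate with enough permutations agrees within
        # binomial error
        mc_hits = 0
        b = 2000
        rng2 = np.random.default_rng(1)
        codes = np.array([0, 0, 0, 1, 1, 1, 1])
        f_obs, _ = comm._permanova_f(d ** 2, codes, 2)
        for _ in range(b):
            f_p, _ = comm._permanova_f(d ** 2, rng2.permutation(codes), 2)
            mc_hits += f_p >= f_obs - 1e-12
        se = np.sqrt(ex.p * (1 - ex.p) / b)
        assert abs(mc_hits / b - ex.p) < 4 * se + 1e-3

    def test_null_rejection_rate_small(self, rng):
        rej = 0
        n_sim = 300
        for _ in range(n_sim):
            x = rng.normal(size=(12, 3))
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            res = comm.permanova(d, ["a"] * 6 + ["b"] * 6, n_perm=199,
                                 seed=int(rng.integers(1e9)))
            rej += res.p <= 0.05
        assert 0.02 <= rej / n_sim <= 0.09

    def test_r_squared_fraction(self):
        res = comm.permanova(block_distance(), ["a", "a", "b", "b"],
                             n_perm=999)
        assert 0.0 < res.r_squared < 1.0
        assert res.r_squared == pytest.approx(0.995 / 1.005)


class TestDispersion:
    def test_identical_geometry_high_p(self):
        res = comm.dispersion_homogeneity(block_distance(),
                                          ["a", "a", "b", "b"],
                                          n_perm=999, seed=0)
        assert res.pseudo_f == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.5

    def test_unequal_dispersion_detected(self, rng):
        tight = rng.normal(scale=0.01, size=(10, 3))
        loose = rng.normal(scale=0.9, size=(10, 3))
        x = np.vstack([tight, loose])
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        res = comm.dispersion_homogeneity(d, ["a"] * 10 + ["b"] * 10,
                                          n_perm=999, seed=0)
        assert res.p <= 0.05

    def test_all_equal_distances(self):
        d = np.full((6, 6), 0.7)
        np.fill_diagonal(d, 0.0)
        res = comm.dispersion_homogeneity(d, ["a"] * 3 + ["b"] * 3,
                                          n_perm=999, seed=0)
        assert res.pseudo_f == pytest.approx(0.0, abs=1e-9)


class TestTopTaxa:
    def test_other_pooling(self, rng):
        props = pd.DataFrame(rng.dirichlet(np.ones(15), size=4),
                             columns=[f"p{i}" for i in range(15)])
        out = comm.top_taxa_display(props, n_top=9)
        assert out.shape[1] == 10
        assert "Other" in out.columns
        assert np.allclose(out.sum(axis=1), 1.0)
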