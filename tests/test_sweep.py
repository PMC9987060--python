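import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan import (
    MISSING,
    PopulationMap,
    PopulationSpec,
    SimConfig,
    enumerate_windows,
    genes_in_regions,
    genomewide_fst,
    merge_regions,
    pairwise_fst_matrix,
    pi_lnratio,
    select_sweep_windows,
    shared_genes,
    simulate,
    site_fst_components,
    site_frequencies,
    sweep_scan,
    windowed_fst,
    windowed_pi,
)

from conftest import make_matrix, split_popmap

M = MISSING


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def wc_components_oracle(dosA, dosB):
    """Scalar transcription of the Weir-Cockerham (1984) two-population
    diploid variance components, computed directly from genotype lists."""
    dosA = [d for d in dosA if d != M]
    dosB = [d for d in dosB if d != M]
    n1, n2 = len(dosA), len(dosB)
    if n1 < 2 or n2 < 2:
        return None
    p1 = sum(dosA) / (2 * n1)
    p2 = sum(dosB) / (2 * n2)
    h1 = sum(1 for d in dosA if d == 1) / n1
    h2 = sum(1 for d in dosB if d == 1) / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def pi_bruteforce(dosages):
    """Mean pairwise difference over all haplotype pairs at one site."""
    haplos = []
    for d in dosages:
        if d == M:
            continue
        haplos.extend({0: (0, 0), 1: (0, 1), 2: (1, 1)}[d])
    n = len(haplos)
    if n < 2:
        return None
    diff = sum(
        1 for i in range(n) for j in range(i + 1, n) if haplos[i] != haplos[j]
    )
    return diff / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


class TestEnumerateWindows:
    def test_one_megabase_layout(self):
        wins = enumerate_windows({"chr1": 1_000_000}, size=100_000, step=10_000)
        assert len(wins) == 100
        full = wins[wins["end"] - wins["start"] + 1 == 100_000]
        assert len(full) == 91
        assert full["start"].max() == 900_001
        assert wins["end"].max() == 1_000_000

    def test_contig_shorter_than_window(self):
        wins = enumerate_windows({"tiny": 5_000}, size=100_000, step=10_000)
        assert len(wins) == 1
        assert (wins.iloc[0]["start"], wins.iloc[0]["end"]) == (1, 5_000)
        assert enumerate_windows(
            {"tiny": 5_000}, size=100_000, step=10_000, drop_tails=True
        ).empty

    def test_tiling_partition(self):
        wins = enumerate_windows({"c": 95_000}, size=10_000, step=10_000)
        lengths = wins["end"] - wins["start"] + 1
        assert lengths.sum() == 95_000

    def test_empty_contig_set_errors(self):
        with pytest.raises(ValueError):
            enumerate_windows({})


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


class TestFstComponents:
    def test_fixed_difference_gives_one(self):
        calls = np.array([[0] * 10 + [2] * 10]).T.reshape(20, 1)
        G = make_matrix(calls)
        pm = split_popmap(G, 10)
        fA = site_frequencies(G, "A", pm)
        fB = site_frequencies(G, "B", pm)
        a, b, c = site_fst_components(fA, fB)
        assert a[0] / (a[0] + b[0] + c[0]) == pytest.approx(1.0, abs=1e-12)

    def test_identical_all_het_profile_nonpositive_a(self):
        calls = np.ones((20, 1), dtype=np.int8)
        G = make_matrix(calls)
        pm = split_popmap(G, 10)
        fA = site_frequencies(G, "A", pm)
        fB = site_frequencies(G, "B", pm)
        a, b, c = site_fst_components(fA, fB)
        oracle = wc_components_oracle([1] * 10, [1] * 10)
        assert a[0] <= 0
        assert a[0] == pytest.approx(oracle[0], abs=1e-12)

    def test_duplicated_population_null_near_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, size=1000)
        calls = rng.binomial(2, p, size=(40, 1000)).astype(np.int8)
        G = make_matrix(calls, positions=np.arange(1, 1001) * 10)
        pm = split_popmap(G, 20)
        assert abs(genomewide_fst(G, "A", "B", pm)) <= 0.01

    def test_single_site_window_equals_site_ratio(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(12, 1)).astype(np.int8)
        G = make_matrix(calls, positions=[50])
        pm = split_popmap(G, 6)
        wins = enumerate_windows(G.contig_lengths, size=150, step=150)
        fst = windowed_fst(G, "A", "B", wins, pm, min_snps=1)
        fA = site_frequencies(G, "A", pm)
        fB = site_frequencies(G, "B", pm)
        a, b, c = site_fst_components(fA, fB)
        assert fst[0] == pytest.approx(a[0] / (a[0] + b[0] + c[0]), abs=1e-15)

    def test_matches_literal_oracle_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            nA, nB = rng.integers(2, 7), rng.integers(2, 7)
            n_sites = rng.integers(1, 6)
            calls = rng.choice(
                [0, 1, 2, M], p=[0.3, 0.3, 0.3, 0.1], size=(nA + nB, n_sites)
            ).astype(np.int8)
            G = make_matrix(calls, positions=(np.arange(n_sites) + 1) * 10)
            pm = split_popmap(G, int(nA))
            fA = site_frequencies(G, "A", pm)
            fB = site_frequencies(G, "B", pm)
            a, b, c = site_fst_components(fA, fB)
            num = den = 0.0
            any_usable = False
            for j in range(n_sites):
                res = wc_components_oracle(calls[:nA, j], calls[nA:, j])
                if res is None:
                    assert np.isnan(a[j])
                    continue
                any_usable = True
                oa, ob, oc = res
                assert a[j] == pytest.approx(oa, abs=1e-12)
                assert b[j] == pytest.approx(ob, abs=1e-12)
                assert c[j] == pytest.approx(oc, abs=1e-12)
                num += oa
                den += oa + ob + oc
            if any_usable and den != 0:
                wins = enumerate_windows(G.contig_lengths, size=10_000, step=10_000)
                fst = windowed_fst(G, "A", "B", wins, pm, min_snps=1)
                assert fst[0] == pytest.approx(num / den, abs=1e-12)

    def test_all_windows_masked_when_min_snps_too_high(self):
        calls = np.array([[0, 1, 2, 1]]).T.reshape(4, 1)
        G = make_matrix(calls)
        pm = split_popmap(G, 2)
        wins = enumerate_windows(G.contig_lengths, size=1000, step=1000)
        fst = windowed_fst(G, "A", "B", wins, pm, min_snps=10)
        assert np.isnan(fst).all()


@pytest.fixture(scope="module")
def bn():
    cfg = SimConfig(
        seed=20,
        contigs=[("chr1", 2_000_000)],
        n_sites=20_000,
        populations=[PopulationSpec("A", 20, 0.2), PopulationSpec("B", 20, 0.2)],
        missing_rate=0.0,
        sweeps=[],
    )
    G, pm, _, _ = simulate(cfg)
    return G, pm


class TestBaldingNicholsRecovery:
    def test_genomewide_fst_near_truth(self, bn):
        G, pm = bn
        assert 0.17 <= genomewide_fst(G, "A", "B", pm) <= 0.23
        assert 0.17 <= genomewide_fst(G, "A", "B", pm, estimator="hudson") <= 0.23

    def test_wc_hudson_window_agreement(self, bn):
        G, pm = bn
        wins = enumerate_windows(G.contig_lengths)
        fw = windowed_fst(G, "A", "B", wins, pm)
        fh = windowed_fst(G, "A", "B", wins, pm, estimator="hudson")
        ok = ~np.isnan(fw) & ~np.isnan(fh)
        r = np.corrcoef(fw[ok], fh[ok])[0, 1]
        assert r >= 0.95
        assert abs(np.mean(fw[ok]) - np.mean(fh[ok])) <= 0.02


# ---------------------------------------------------------------------------
# pi and ln-ratio
# ---------------------------------------------------------------------------


class TestWindowedPi:
    def test_two_diploid_het_het_case(self):
        G = make_matrix(np.array([[1, 1]]).T, positions=[1], contig_length=1)
        pm = PopulationMap({s: "P" for s in G.sample_ids})
        wins = enumerate_windows({"chr1": 1}, size=1, step=1)
        pi = windowed_pi(G, "P", wins, pm)
        assert pi[0] == pytest.approx(2 / 3, abs=1e-15)
        assert pi[0] == pi_bruteforce([1, 1])

    def test_matches_bruteforce_exactly_on_random_tables(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = rng.integers(2, 7)
            n_sites = rng.integers(1, 6)
            calls = rng.choice(
                [0, 1, 2, M], p=[0.3, 0.3, 0.3, 0.1], size=(n, n_sites)
            ).astype(np.int8)
            length = int(n_sites) * 10 + 5
            G = make_matrix(
                calls, positions=(np.arange(n_sites) + 1) * 10, contig_length=length
            )
            pm = PopulationMap({s: "P" for s in G.sample_ids})
            wins = enumerate_windows({"chr1": length}, size=length, step=length)
            pi = windowed_pi(G, "P", wins, pm)
            expected = (
                sum(
                    v
                    for v in (pi_bruteforce(calls[:, j]) for j in range(n_sites))
                    if v is not None
                )
                / length
            )
            assert pi[0] == expected  # bit-identical arithmetic path

    def test_monomorphic_window_is_zero(self):
        G = make_matrix(np.zeros((4, 3), dtype=np.int8))
        pm = PopulationMap({s: "P" for s in G.sample_ids})
        wins = enumerate_windows(G.contig_lengths, size=400, step=400)
        assert windowed_pi(G, "P", wins, pm)[0] == 0.0

    def test_per_bp_normalization_halves_with_double_length(self):
        calls = np.array([[0, 1, 2, 1]]).T.reshape(4, 1)
        G = make_matrix(calls, positions=[10], contig_length=100)
        pm = PopulationMap({s: "P" for s in G.sample_ids})
        w1 = enumerate_windows({"chr1": 100}, size=100, step=100)
        w2 = enumerate_windows({"chr1": 200}, size=200, step=200)
        G2 = make_matrix(calls, positions=[10], contig_length=200)
        pi1 = windowed_pi(G, "P", w1, pm)[0]
        pi2 = windowed_pi(G2, "P", w2, pm)[0]
        assert pi2 == pytest.approx(pi1 / 2, rel=1e-12)


class TestPiLnRatio:
    def test_closed_form_and_masking(self):
        out = pi_lnratio([0.010, 0.002, 0.0, 0.01], [0.001, 0.002, 0.01, 0.0])
        assert out[0] == pytest.approx(np.log(10), abs=1e-12)
        assert out[1] == 0.0
        assert np.isnan(out[2]) and np.isnan(out[3])

    def test_focal_excess_diversity_is_negative(self):
        assert pi_lnratio([0.001], [0.01])[0] < 0


# ---------------------------------------------------------------------------
# Selection, merging, genes
# ---------------------------------------------------------------------------


class TestSelection:
    def test_five_percent_of_1000(self):
        rng = np.random.default_rng(0)
        fst = rng.random(1000)
        lnr = fst.copy()  # perfectly rank-correlated
        sel, t_f, t_l = select_sweep_windows(fst, lnr)
        assert (fst >= t_f).sum() == 50
        assert sel.sum() == 50  # upper bound attained

    def test_independent_uniform_intersection_mean(self):
        rng = np.random.default_rng(8)
        sizes = [
            select_sweep_windows(rng.random(1000), rng.random(1000))[0].sum()
            for _ in range(500)
        ]
        assert np.mean(sizes) == pytest.approx(2.5, abs=0.5)

    def test_too_few_windows_errors(self):
        with pytest.raises(ValueError, match="unstable"):
            select_sweep_windows(np.arange(10.0), np.arange(10.0))

    def test_masked_windows_excluded(self):
        fst = np.concatenate([np.arange(100.0), [np.nan] * 50])
        lnr = np.concatenate([np.arange(100.0), np.arange(50.0)])
        sel, t_f, _ = select_sweep_windows(fst, lnr)
        assert not sel[100:].any()
        assert t_f == pytest.approx(np.quantile(np.arange(100.0), 0.95))


class TestMergeRegions:
    def test_overlap_union(self):
        wins = pd.DataFrame(
            {"contig": ["c", "c"], "start": [1, 10_001], "end": [100_000, 110_000]}
        )
        regions = merge_regions(wins)
        assert len(regions) == 1
        assert (regions.iloc[0]["start"], regions.iloc[0]["end"]) == (1, 110_000)
        assert regions.iloc[0]["n_windows"] == 2

    def test_bookended_merge_but_gap_kept(self):
        wins = pd.DataFrame(
            {"contig": ["c"] * 3, "start": [1, 101, 300], "end": [100, 200, 400]}
        )
        regions = merge_regions(wins)
        assert len(regions) == 2

    def test_different_contigs_never_merge(self):
        wins = pd.DataFrame(
            {"contig": ["c1", "c2"], "start": [1, 1], "end": [100, 100]}
        )
        assert len(merge_regions(wins)) == 2

    def test_disjoint_preserve_total_bp(self):
        wins = pd.DataFrame(
            {"contig": ["c"] * 3, "start": [1, 500, 900], "end": [100, 600, 1000]}
        )
        regions = merge_regions(wins)
        assert len(regions) == 3
        assert (regions["end"] - regions["start"] + 1).sum() == (
            wins["end"] - wins["start"] + 1
        ).sum()

    @given(
        st.lists(
            st.tuples(st.integers(1, 500), st.integers(1, 200)),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_idempotent(self, intervals):
        wins = pd.DataFrame(
            [("c", s, s + ln - 1) for s, ln in intervals],
            columns=["contig", "start", "end"],
        )
        once = merge_regions(wins)
        twice = merge_regions(once[["contig", "start", "end"]])
        pd.testing.assert_frame_equal(
            once[["contig", "start", "end"]].reset_index(drop=True),
            twice[["contig", "start", "end"]].reset_index(drop=True),
        )


class TestGenes:
    def make_genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end", "strand"])

    def test_overlap_boundaries(self):
        regions = pd.DataFrame(
            [("c", 1, 110_000)], columns=["contig", "start", "end"]
        )
        genes = self.make_genes(
            [
                ("inside", "c", 50_000, 60_000, "+"),
                ("bookended", "c", 110_001, 120_000, "+"),
                ("one_bp", "c", 110_000, 120_000, "+"),
                ("other_contig", "d", 50_000, 60_000, "+"),
            ]
        )
        per_region, union = genes_in_regions(regions, genes)
        assert union == {"inside", "one_bp"}
        assert per_region[0] == union

    def test_constructed_truth_union(self):
        regions = pd.DataFrame(
            [("c", 100, 200), ("c", 1000, 2000)], columns=["contig", "start", "end"]
        )
        genes = self.make_genes(
            [(f"g{i}", "c", 300 * i + 1, 300 * i + 50, "+") for i in range(10)]
        )
        per_region, union = genes_in_regions(regions, genes)
        expected = {
            g.gene_id
            for g in genes.itertuples(index=False)
            if (g.start <= 200 and g.end >= 100) or (g.start <= 2000 and g.end >= 1000)
        }
        assert union == expected
        assert per_region[0] | per_region[1] == union


class TestSharedGenes:
    def test_three_way_example(self):
        inter, venn = shared_genes(
            {"X": {"a", "b", "c"}, "Y": {"b", "c", "d"}, "Z": {"c", "e"}}
        )
        assert inter == {"c"}
        assert venn["X&Y&Z"] == 1
        assert venn["X"] == 1  # only "a"
        assert venn["X&Y"] == 1  # only "b"
        assert venn["Z"] == 1  # only "e"

    def test_identical_and_disjoint(self):
        inter, venn = shared_genes({"X": {"a", "b"}, "Y": {"a", "b"}})
        assert inter == {"a", "b"} and venn["X&Y"] == 2
        inter, venn = shared_genes({"X": {"a"}, "Y": {"b"}})
        assert inter == set() and venn["X&Y"] == 0

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            shared_genes({"X": {"a"}})


# ---------------------------------------------------------------------------
# Pairwise matrix
# ---------------------------------------------------------------------------


class TestPairwiseFstMatrix:
    def test_three_population_rank(self):
        cfg = SimConfig(
            seed=9,
            contigs=[("chr1", 1_000_000)],
            n_sites=8_000,
            populations=[
                PopulationSpec("P1", 15, 0.05),
                PopulationSpec("P2", 15, 0.05),
                PopulationSpec("P3", 15, 0.3),
            ],
            missing_rate=0.0,
            sweeps=[],
        )
        G, pm, _, _ = simulate(cfg)
        mat = pairwise_fst_matrix(G, pm)
        means = mat.mean_per_population
        assert means.idxmax() == "P3"
        v = mat.values
        assert np.allclose(v, v.T) and np.all(np.diag(v) == 0)
        assert mat.differentiation_class["P3"] == "high"
        assert mat.differentiation_class["P1"] == "low"

    def test_fixed_difference_pair_is_one(self):
        calls = np.vstack([np.zeros((5, 20)), np.full((5, 20), 2)]).astype(np.int8)
        G = make_matrix(calls, positions=(np.arange(20) + 1) * 10)
        pm = split_popmap(G, 5)
        mat = pairwise_fst_matrix(G, pm)
        assert mat.values.loc["A", "B"] == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# End-to-end scan
# ---------------------------------------------------------------------------


class TestSweepScan:
    def test_null_scan_selects_at_most_five_percent(self):
        cfg = SimConfig(
            seed=4,
            contigs=[("chr1", 1_000_000)],
            n_sites=10_000,
            populations=[PopulationSpec("R", 20, 0.05), PopulationSpec("F", 20, 0.05)],
            missing_rate=0.0,
            sweeps=[],
        )
        G, pm, _, _ = simulate(cfg)
        res = sweep_scan(G, pm, "R", "F")
        unmasked = res.windows.dropna(subset=["fst", "pi_lnratio"])
        assert res.windows["selected"].sum() <= np.ceil(0.05 * len(unmasked))

    def test_planted_sweeps_recovered(self, default_fixture):
        from sweepscan import evaluate_recovery

        res = sweep_scan(
            default_fixture["filtered"],
            default_fixture["popmap"],
            "SZ",
            "JL",
            genes=default_fixture["genes"],
            contig_lengths=default_fixture["contig_lengths"],
        )
        truth = default_fixture["truth"]
        recall, precision = evaluate_recovery(res.regions, truth)
        assert recall >= 0.8
        assert precision >= 0.5
        # the reported gene list captures most of the planted truth genes
        found = len(res.gene_ids & truth.gene_ids)
        assert found >= 0.8 * len(truth.gene_ids)
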