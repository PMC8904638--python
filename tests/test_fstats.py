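"""Patterson f-statistics and the weighted block jackknife."""

import numpy as np
import pandas as pd
import pytest

from finepop import fstats, simdata
from finepop.fstats import AlleleFreqTable

from conftest import make_genotypes


def freq_table(freq_dict, n_chrom=None, snp_meta=None):
    """Population-frequency table for closed-form examples."""
    some = next(iter(freq_dict.values()))
    m = len(some)
    if snp_meta is None:
        snp_meta = simdata.default_snp_meta(m)
    if n_chrom is None:
        n_chrom = {p: np.full(m, 10**9) for p in freq_dict}  # infinite-n mode
    return AlleleFreqTable(
        freqs={p: np.asarray(f, float) for p, f in freq_dict.items()},
        n_chrom={p: np.asarray(n) for p, n in n_chrom.items()},
        snp_meta=snp_meta,
    )


def two_blocks(m):
    return np.repeat([0, 1], [m // 2, m - m // 2])


class TestAlleleFreqs:
    def test_counting(self):
        G = make_genotypes([[0], [1], [2]])
        ft = fstats.allele_freqs(G)
        assert ft.freqs["POP"][0] == pytest.approx(0.5)
        assert ft.n_chrom["POP"][0] == 6

    def test_all_missing_snp_flagged(self):
        G = make_genotypes([[-1, 1], [-1, 0]])
        ft = fstats.allele_freqs(G)
        assert ft.n_chrom["POP"][0] == 0
        assert not ft.require(["POP"])[0]

    def test_matches_bruteforce_count(self, rng):
        calls = rng.integers(-1, 3, size=(15, 20)).astype(np.int8)
        G = make_genotypes(calls, pops=["A"] * 7 + ["B"] * 8)
        ft = fstats.allele_freqs(G)
        for j in range(20):
            g = calls[:7, j]
            g = g[g >= 0]
            if len(g):
                assert ft.freqs["A"][j] == pytest.approx(g.sum() / (2 * len(g)))


class TestF3:
    def test_population_frequency_example(self):
        ft = freq_table({"A": [0.1, 0.9], "B": [0.9, 0.1], "C": [0.5, 0.5]})
        res = fstats.f3("A", "B", "C", ft, blocks=two_blocks(2), correction=False)
        assert res.estimate == pytest.approx(-0.16)

    def test_identical_populations_zero(self):
        f = np.linspace(0.1, 0.9, 10)
        ft = freq_table({"A": f, "B": f, "C": f})
        res = fstats.f3("A", "B", "C", ft, blocks=two_blocks(10), correction=False)
        assert res.estimate == pytest.approx(0.0, abs=1e-15)

    def test_admixed_target_strongly_negative(self):
        # 50/50 mixture with shallow target drift -> Z < -3
        rng = np.random.default_rng(77)
        m = 5000
        anc = rng.uniform(0.1, 0.9, m)
        a_pop = simdata.simulate_source_freqs(anc, 0.1, rng)
        b_pop = simdata.simulate_source_freqs(anc, 0.1, rng)
        c_pop = simdata.simulate_source_freqs(0.5 * (a_pop + b_pop), 0.005, rng)
        nc = 100
        sample = lambda f: rng.binomial(nc, f) / nc
        ft = freq_table(
            {"A": sample(a_pop), "B": sample(b_pop), "C": sample(c_pop)},
            n_chrom={p: np.full(m, nc) for p in "ABC"},
        )
        res = fstats.f3("A", "B", "C", ft)
        assert res.z < -3

    def test_normalized_mode_same_sign(self):
        rng = np.random.default_rng(78)
        m = 2000
        anc = rng.uniform(0.1, 0.9, m)
        a_pop = simdata.simulate_source_freqs(anc, 0.1, rng)
        b_pop = simdata.simulate_source_freqs(anc, 0.1, rng)
        c_pop = 0.5 * (a_pop + b_pop)
        nc = 60
        sample = lambda f: rng.binomial(nc, f) / nc
        ft = freq_table(
            {"A": sample(a_pop), "B": sample(b_pop), "C": sample(c_pop)},
            n_chrom={p: np.full(m, nc) for p in "ABC"},
        )
        raw = fstats.f3("A", "B", "C", ft)
        norm = fstats.f3("A", "B", "C", ft, normalize=True)
        assert np.sign(raw.estimate) == np.sign(norm.estimate)
        assert abs(norm.estimate) != abs(raw.estimate)


class TestOutgroupF3:
    @pytest.fixture
    def tree_freqs(self):
        # ((P1,P2),P3) with outgroup O: sisters share drift relative to O
        rng = np.random.default_rng(55)
        m = 4000
        anc = rng.uniform(0.1, 0.9, m)
        internal = simdata.simulate_source_freqs(anc, 0.08, rng)  # P1/P2 ancestor
        p1 = simdata.simulate_source_freqs(internal, 0.03, rng)
        p2 = simdata.simulate_source_freqs(internal, 0.03, rng)
        p3 = simdata.simulate_source_freqs(anc, 0.11, rng)
        nc = 80
        sample = lambda f: rng.binomial(nc, np.clip(f, 1e-6, 1 - 1e-6)) / nc
        return freq_table(
            {"O": sample(anc), "P1": sample(p1), "P2": sample(p2), "P3": sample(p3)},
            n_chrom={p: np.full(m, nc) for p in ("O", "P1", "P2", "P3")},
        )

    def test_sisters_share_more_drift(self, tree_freqs):
        sisters = fstats.f3_outgroup("O", "P1", "P2", tree_freqs)
        distant = fstats.f3_outgroup("O", "P1", "P3", tree_freqs)
        assert sisters.estimate > distant.estimate

    def test_self_comparison_is_maximal(self, tree_freqs):
        self_cmp = fstats.f3_outgroup("O", "P1", "P1", tree_freqs)
        for other in ("P2", "P3"):
            assert self_cmp.estimate >= fstats.f3_outgroup("O", "P1", other, tree_freqs).estimate

    def test_symmetric_in_pop_order(self, tree_freqs):
        ab = fstats.f3_outgroup("O", "P1", "P2", tree_freqs)
        ba = fstats.f3_outgroup("O", "P2", "P1", tree_freqs)
        assert ab.estimate == pytest.approx(ba.estimate, abs=1e-15)


class TestF4:
    def test_two_snp_example(self):
        ft = freq_table(
            {"A": [0.1, 0.5], "B": [0.2, 0.4], "C": [0.3, 0.9], "D": [0.6, 0.1]}
        )
        res = fstats.f4("A", "B", "C", "D", ft, blocks=two_blocks(2))
        assert res.estimate == pytest.approx(0.055)

    def test_equal_cd_gives_zero(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(0.1, 0.9, 20)
        ft = freq_table({"A": rng.uniform(0.1, 0.9, 20), "B": rng.uniform(0.1, 0.9, 20), "C": f, "D": f})
        res = fstats.f4("A", "B", "C", "D", ft, blocks=two_blocks(20))
        assert res.estimate == 0.0

    def test_antisymmetry(self, rng):
        fr = {p: rng.uniform(0.1, 0.9, 30) for p in "ABCD"}
        ft = freq_table(fr)
        blk = two_blocks(30)
        base = fstats.f4("A", "B", "C", "D", ft, blocks=blk).estimate
        assert fstats.f4("B", "A", "C", "D", ft, blocks=blk).estimate == pytest.approx(-base, abs=1e-15)
        assert fstats.f4("A", "B", "D", "C", ft, blocks=blk).estimate == pytest.approx(-base, abs=1e-15)

    def test_additivity(self, rng):
        fr = {p: rng.uniform(0.1, 0.9, 40) for p in "ABCDE"}
        ft = freq_table(fr)
        blk = two_blocks(40)
        lhs = (
            fstats.f4("A", "B", "C", "D", ft, blocks=blk).estimate
            + fstats.f4("A", "B", "D", "E", ft, blocks=blk).estimate
        )
        rhs = fstats.f4("A", "B", "C", "E", ft, blocks=blk).estimate
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestF4Ratio:
    def test_exact_linear_mixture(self, rng):
        alpha = 0.25
        m = 50
        b = rng.uniform(0.1, 0.9, m)
        c = rng.uniform(0.1, 0.9, m)
        x = alpha * b + (1 - alpha) * c
        ft = freq_table(
            {"A": rng.uniform(0.1, 0.9, m), "O": rng.uniform(0.1, 0.9, m),
             "X": x, "B": b, "C": c}
        )
        res = fstats.f4_ratio("A", "O", "X", "B", "C", ft, blocks=two_blocks(m))
        assert res.estimate == pytest.approx(alpha, abs=1e-10)

    def test_x_equals_b_gives_one(self, rng):
        m = 30
        b = rng.uniform(0.1, 0.9, m)
        ft = freq_table(
            {"A": rng.uniform(0.1, 0.9, m), "O": rng.uniform(0.1, 0.9, m),
             "X": b, "B": b, "C": rng.uniform(0.1, 0.9, m)}
        )
        res = fstats.f4_ratio("A", "O", "X", "B", "C", ft, blocks=two_blocks(m))
        assert res.estimate == pytest.approx(1.0, abs=1e-12)

    def test_introgression_recovery(self):
        # 3% introgression of B into X against background C
        rng = np.random.default_rng(31)
        alphas = []
        for rep in range(20):
            m = 4000
            anc = rng.uniform(0.1, 0.9, m)
            deep = simdata.simulate_source_freqs(anc, 0.3, rng)  # archaic-like B
            c = simdata.simulate_source_freqs(anc, 0.02, rng)
            x = 0.03 * deep + 0.97 * c
            a = simdata.simulate_source_freqs(deep, 0.05, rng)  # sister of B
            o = simdata.simulate_source_freqs(anc, 0.02, rng)
            nc = 100
            sample = lambda f: rng.binomial(nc, np.clip(f, 1e-9, 1 - 1e-9)) / nc
            ft = freq_table(
                {"A": sample(a), "O": sample(o), "X": sample(x), "B": sample(deep), "C": sample(c)},
                n_chrom={p: np.full(m, nc) for p in ("A", "O", "X", "B", "C")},
            )
            alphas.append(fstats.f4_ratio("A", "O", "X", "B", "C", ft).estimate)
        assert abs(np.mean(alphas) - 0.03) < 0.01

    def test_unstable_denominator_flagged(self, rng):
        m = 30
        f = rng.uniform(0.1, 0.9, m)
        ft = freq_table(
            {"A": f + rng.normal(0, 1e-4, m), "O": f, "X": rng.uniform(0.1, 0.9, m),
             "B": rng.uniform(0.1, 0.9, m), "C": rng.uniform(0.1, 0.9, m)}
        )
        res = fstats.f4_ratio("A", "O", "X", "B", "C", ft, blocks=two_blocks(m))
        assert "unstable-denominator" in res.flags


class TestBlockJackknife:
    def test_identical_blocks_zero_se(self):
        v = np.tile([1.0, 2.0, 3.0], 4)
        blocks = np.repeat(np.arange(4), 3)
        est, se = fstats.block_jackknife(v, None, blocks)
        assert est == pytest.approx(2.0)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_equal_blocks_match_textbook_delete1(self):
        # 5 equal blocks of 1 value: weighted jackknife reduces to the
        # classic delete-1 formula on the block means
        vals = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        blocks = np.arange(5)
        est, se = fstats.block_jackknife(vals, None, blocks)
        theta = vals.mean()
        loo = np.array([np.delete(vals, i).mean() for i in range(5)])
        se_classic = np.sqrt((5 - 1) / 5 * np.sum((loo - loo.mean()) ** 2))
        assert est == pytest.approx(theta)
        assert se == pytest.approx(se_classic, rel=1e-10)

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            fstats.block_jackknife(np.ones(10), None, np.zeros(10))

    def test_blocks_by_genetic_distance(self):
        meta = simdata.default_snp_meta(1000, n_chrom=2, chrom_length_morgans=0.5)
        blocks = fstats.assign_blocks(meta, size_cm=5.0)
        # contiguity: block ids are non-decreasing along the map
        assert (np.diff(blocks) >= 0).all()
        # chromosome boundaries start new blocks
        chrom = meta["chrom"].to_numpy()
        edge = np.flatnonzero(chrom[1:] != chrom[:-1])[0]
        assert blocks[edge + 1] != blocks[edge]

    def test_null_f4_calibration_small(self):
        # reduced version of the |Z|>3 <= 1% calibration (full run in the
        # acceptance suite)
        rate = null_f4_exceedance(n_rep=100, seed=9)
        assert rate <= 0.03


def null_f4_exceedance(n_rep, seed, m=4000, nc=60):
    rng = np.random.default_rng(seed)
    meta = simdata.default_snp_meta(m)
    blocks = fstats.assign_blocks(meta, size_cm=5.0)
    n_exceed = 0
    for _ in range(n_rep):
        anc = rng.uniform(0.1, 0.9, m)
        ab = simdata.simulate_source_freqs(anc, 0.05, rng)
        cd = simdata.simulate_source_freqs(anc, 0.05, rng)
        pops = {
            "A": simdata.simulate_source_freqs(ab, 0.03, rng),
            "B": simdata.simulate_source_freqs(ab, 0.03, rng),
            "C": simdata.simulate_source_freqs(cd, 0.03, rng),
            "D": simdata.simulate_source_freqs(cd, 0.03, rng),
        }
        sample = {p: rng.binomial(nc, f) / nc for p, f in pops.items()}
        ft = AlleleFreqTable(
            freqs=sample,
            n_chrom={p: np.full(m, nc) for p in pops},
            snp_meta=meta,
        )
        res = fstats.f4("A", "B", "C", "D", ft, blocks=blocks)
        if abs(res.z) > 3:
            n_exceed += 1
    return n_exceed / n_rep


def test_null_f4_z_scores_standard_normal_like():
    rng = np.random.default_rng(17)
    m, nc = 3000, 60
    meta = simdata.default_snp_meta(m)
    blocks = fstats.assign_blocks(meta, size_cm=5.0)
    zs = []
    for _ in range(200):
        anc = rng.uniform(0.1, 0.9, m)
        ab = simdata.simulate_source_freqs(anc, 0.05, rng)
        cd = simdata.simulate_source_freqs(anc, 0.05, rng)
        sample = {}
        for p, base in (("A", ab), ("B", ab), ("C", cd), ("D", cd)):
            f = simdata.simulate_source_freqs(base, 0.03, rng)
            sample[p] = rng.binomial(nc, f) / nc
        ft = AlleleFreqTable(sample, {p: np.full(m, nc) for p in sample}, meta)
        zs.append(fstats.f4("A", "B", "C", "D", ft, blocks=blocks).z)
    from scipy import stats as sps

    assert sps.kstest(zs, "norm").pvalue > 0.01
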