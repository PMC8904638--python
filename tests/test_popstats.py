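"""Weir-Cockerham FST, RoH scanning, PCA."""

import numpy as np
import pandas as pd
import pytest

from finepop import popstats, simdata
from finepop.genio import MISSING, GenotypeMatrix

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# independent line-by-line oracle for the 1984 variance components


def wc_fst_oracle(callsA, callsB):
    """Direct transcription of the r=2 Weir-Cockerham component formulas,
    computed SNP by SNP with explicit loops."""
    sum_a = sum_abc = 0.0
    m = callsA.shape[1]
    for j in range(m):
        gA = callsA[:, j][callsA[:, j] != MISSING]
        gB = callsB[:, j][callsB[:, j] != MISSING]
        if len(gA) == 0 or len(gB) == 0:
            continue
        nA, nB = len(gA), len(gB)
        pA = gA.sum() / (2 * nA)
        pB = gB.sum() / (2 * nB)
        hA = np.mean(gA == 1)
        hB = np.mean(gB == 1)
        r = 2
        n_bar = (nA + nB) / r
        if n_bar <= 1:
            continue
        n_c = (r * n_bar - (nA**2 + nB**2) / (r * n_bar)) / (r - 1)
        p_bar = (nA * pA + nB * pB) / (r * n_bar)
        if p_bar <= 0 or p_bar >= 1:
            continue
        s2 = (nA * (pA - p_bar) ** 2 + nB * (pB - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (nA * hA + nB * hB) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - 1.0 / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        if a + b + c == 0:
            continue
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc


class TestWcFst:
    def test_complete_fixation_gives_one(self):
        calls = np.vstack([np.full((5, 4), 2), np.full((5, 4), 0)]).astype(np.int8)
        G = make_genotypes(calls, pops=["A"] * 5 + ["B"] * 5)
        assert popstats.wc_fst(G, "A", "B").fst == pytest.approx(1.0)

    def test_shared_fixed_snp_excluded(self):
        calls = np.column_stack([np.full(10, 2), [2, 0, 1, 2, 0, 1, 2, 0, 1, 2]]).astype(np.int8)
        G = make_genotypes(calls, pops=["A"] * 5 + ["B"] * 5)
        res = popstats.wc_fst(G, "A", "B")
        assert res.n_snps_used == 1

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(20):
            calls = rng.integers(0, 3, size=(20, 20)).astype(np.int8)
            calls[rng.random(calls.shape) < 0.05] = MISSING
            G = make_genotypes(calls, pops=["A"] * 10 + ["B"] * 10)
            try:
                est = popstats.wc_fst(G, "A", "B").fst
            except ValueError:
                continue
            oracle = wc_fst_oracle(calls[:10], calls[10:])
            assert est == pytest.approx(oracle, abs=1e-12)

    def test_empty_population_rejected(self, rng):
        calls = rng.integers(0, 3, size=(4, 5)).astype(np.int8)
        G = make_genotypes(calls, pops=["A"] * 4)
        with pytest.raises(ValueError):
            popstats.wc_fst(G, "A", "B")

    def test_panmictic_null_centred_on_zero(self):
        rng = np.random.default_rng(123)
        vals = []
        for _ in range(100):
            freqs = rng.uniform(0.2, 0.8, 800)
            calls = ((rng.random((40, 800)) < freqs).astype(np.int8)
                     + (rng.random((40, 800)) < freqs).astype(np.int8))
            G = make_genotypes(calls, pops=["A"] * 20 + ["B"] * 20,
                               cm=np.arange(800) * 0.1, bp=np.arange(1, 801) * 100)
            vals.append(popstats.wc_fst(G, "A", "B").fst)
        assert abs(np.mean(vals)) < 0.002


class TestPairwiseMatrix:
    def test_three_groups_symmetric(self, rng):
        calls = rng.integers(0, 3, size=(12, 50)).astype(np.int8)
        G = make_genotypes(calls, pops=["A"] * 4 + ["B"] * 4 + ["C"] * 4)
        mat, flagged = popstats.pairwise_fst_matrix(G)
        assert mat.shape == (3, 3)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
        assert np.allclose(np.diag(mat), 0.0)
        assert not flagged

    def test_identical_groups_near_zero(self):
        rng = np.random.default_rng(3)
        freqs = rng.uniform(0.2, 0.8, 10_000)
        half = ((rng.random((10, 10_000)) < freqs).astype(np.int8)
                + (rng.random((10, 10_000)) < freqs).astype(np.int8))
        calls = np.vstack([half, half])
        G = make_genotypes(calls, pops=["A"] * 10 + ["B"] * 10,
                           cm=np.arange(10_000) * 0.01, bp=np.arange(1, 10_001) * 100)
        mat, _ = popstats.pairwise_fst_matrix(G)
        # duplicated individuals leave zero among-group variance, so the
        # unbiased estimator is at or below zero (negative, not clipped)
        assert mat.loc["A", "B"] <= 0.005

    def test_divergence_ordering(self):
        rng = np.random.default_rng(8)
        anc = rng.uniform(0.2, 0.8, 3000)
        meta = simdata.default_snp_meta(3000)
        drifted = simdata.simulate_source_freqs(anc, np.array([0.05, 0.05]), rng)
        pan = [
            simdata.simulate_panel(anc, 30, rng, meta, "A")[1],
            simdata.simulate_panel(anc, 30, rng, meta, "B")[1],
            simdata.simulate_panel(drifted[0], 30, rng, meta, "C")[1],
            simdata.simulate_panel(drifted[1], 30, rng, meta, "D")[1],
        ]
        G = GenotypeMatrix(
            np.vstack([p.calls for p in pan]),
            meta,
            pd.concat([p.sample_meta for p in pan], ignore_index=True),
        )
        mat, _ = popstats.pairwise_fst_matrix(G)
        assert mat.loc["C", "D"] > mat.loc["A", "B"]

    def test_small_group_flagged(self, rng):
        calls = rng.integers(0, 3, size=(5, 30)).astype(np.int8)
        G = make_genotypes(calls, pops=["A"] * 4 + ["B"])
        mat, flagged = popstats.pairwise_fst_matrix(G)
        assert flagged == ["B"]
        assert np.isnan(mat.loc["A", "B"])


# ---------------------------------------------------------------------------
# RoH


def roh_oracle(calls, bp, window, max_het, max_miss, min_kb, hit_frac, min_snps):
    """Brute-force window re-scan for a single individual, single chrom."""
    m = len(calls)
    n_win = m - window + 1
    if n_win < 1:
        return []
    hits = []
    for s in range(n_win):
        w = calls[s : s + window]
        hits.append(
            int(np.sum(w == 1) <= max_het and np.sum(w == MISSING) <= max_miss)
        )
    segs = []
    state = []
    for t in range(m):
        covering = [hits[s] for s in range(max(0, t - window + 1), min(t, n_win - 1) + 1)]
        state.append(np.mean(covering) >= hit_frac)
    t = 0
    while t < m:
        if state[t]:
            u = t
            while u + 1 < m and state[u + 1]:
                u += 1
            kb = (bp[u] - bp[t] + 1) / 1000
            if kb >= min_kb and (u - t + 1) >= min_snps:
                segs.append((int(bp[t]), int(bp[u])))
            t = u + 1
        else:
            t += 1
    return segs


class TestRoH:
    def test_all_het_individual_has_no_segments(self):
        calls = np.ones((1, 200), dtype=np.int8)
        G = make_genotypes(calls, bp=np.arange(1, 201) * 10_000)
        segs = popstats.detect_roh(G, window_snps=50, min_kb=100, min_seg_snps=10)
        assert segs == []

    def test_constructed_hom_run_detected(self):
        het_flank = np.tile([1, 1], 100)
        hom = np.zeros(300, dtype=np.int8)
        calls = np.concatenate([het_flank, hom, het_flank])[None, :].astype(np.int8)
        bp = np.arange(1, calls.shape[1] + 1) * 10_000  # 10 kb spacing
        G = make_genotypes(calls, bp=bp)
        segs = popstats.detect_roh(
            G, window_snps=50, max_het=1, max_missing=5,
            min_kb=1000, hit_fraction=0.05, min_seg_snps=100,
        )
        assert len(segs) == 1
        seg = segs[0]
        # the detected run contains the interior of the homozygous block
        # (its first/last few SNPs sit under window edge effects)
        assert seg.start_bp <= bp[210] and seg.end_bp >= bp[490]

    def test_short_run_below_length_floor_rejected(self):
        # 300 hom SNPs spanning only 800 kb -> below the 1000 kb floor
        het_flank = np.tile([1, 1], 150)
        hom = np.zeros(300, dtype=np.int8)
        calls = np.concatenate([het_flank, hom, het_flank])[None, :].astype(np.int8)
        m = calls.shape[1]
        bp = np.cumsum(np.full(m, 800_000 // 299))  # hom stretch ~800 kb
        G = make_genotypes(calls, bp=bp)
        segs = popstats.detect_roh(
            G, window_snps=50, min_kb=1000, hit_fraction=0.05, min_seg_snps=100
        )
        assert segs == []

    def test_matches_bruteforce_rescan(self):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            m = 500
            calls = rng.choice([0, 1, 2, MISSING], size=(1, m), p=[0.55, 0.25, 0.15, 0.05]).astype(np.int8)
            bp = np.cumsum(rng.integers(500, 20_000, size=m))
            G = make_genotypes(calls, bp=bp)
            segs = popstats.detect_roh(
                G, window_snps=25, max_het=1, max_missing=2,
                min_kb=50, hit_fraction=0.05, min_seg_snps=20,
            )
            got = [(s.start_bp, s.end_bp) for s in segs]
            want = roh_oracle(calls[0], bp, 25, 1, 2, 50, 0.05, 20)
            assert got == want

    def test_window_larger_than_chrom_warns(self):
        G = make_genotypes(np.zeros((1, 10), dtype=np.int8))
        with pytest.warns(UserWarning):
            segs = popstats.detect_roh(G, window_snps=100)
        assert segs == []


class TestRoHSummary:
    def test_empty(self):
        meta = pd.DataFrame({"id": ["a", "b"], "population": ["X", "X"]})
        per_ind, per_group = popstats.roh_summary([], meta)
        assert (per_ind["n_segments"] == 0).all()
        assert per_group.iloc[0]["mean_total_kb"] == 0.0

    def test_addition_and_group_mean(self):
        meta = pd.DataFrame({"id": ["a", "b"], "population": ["X", "X"]})
        segs = [
            popstats.RoHSegment("a", "1", 1, 1_200_000, 150),
            popstats.RoHSegment("a", "1", 2_000_000, 3_499_999, 150),
        ]
        per_ind, per_group = popstats.roh_summary(segs, meta)
        row = per_ind.set_index("id").loc["a"]
        assert row["n_segments"] == 2
        assert row["total_kb"] == pytest.approx(2700.0)
        assert per_group.iloc[0]["mean_n_segments"] == pytest.approx(1.0)
        assert per_group.iloc[0]["mean_total_kb"] == pytest.approx(1350.0)


# ---------------------------------------------------------------------------
# PCA


class TestPCA:
    def test_separates_two_populations(self):
        rng = np.random.default_rng(42)
        anc = rng.uniform(0.2, 0.8, 2000)
        f = simdata.simulate_source_freqs(anc, np.array([0.1, 0.1]), rng)
        meta = simdata.default_snp_meta(2000)
        gA = simdata.simulate_panel(f[0], 25, rng, meta, "A")[1]
        gB = simdata.simulate_panel(f[1], 25, rng, meta, "B")[1]
        G = GenotypeMatrix(
            np.vstack([gA.calls, gB.calls]), meta,
            pd.concat([gA.sample_meta, gB.sample_meta], ignore_index=True),
        )
        scores, frac = popstats.pca_genotypes(G, n_components=2)
        from sklearn.metrics import silhouette_score

        sil = silhouette_score(scores[:, :1], [0] * 25 + [1] * 25)
        assert sil > 0.8

    def test_duplicated_individual_same_scores(self, rng):
        calls = rng.integers(0, 3, size=(8, 60)).astype(np.int8)
        calls[0] = calls[1]
        G = make_genotypes(calls)
        scores, _ = popstats.pca_genotypes(G, n_components=3)
        assert np.allclose(scores[0], scores[1], atol=1e-8)

    def test_variance_fractions_valid(self, rng):
        calls = rng.integers(0, 3, size=(10, 80)).astype(np.int8)
        G = make_genotypes(calls)
        _, frac = popstats.pca_genotypes(G, n_components=5)
        assert frac.sum() <= 1.0 + 1e-9
        assert (np.diff(frac) <= 1e-12).all()

    def test_reordering_invariance(self, rng):
        calls = rng.integers(0, 3, size=(12, 100)).astype(np.int8)
        G = make_genotypes(calls)
        perm = rng.permutation(12)
        scores1, _ = popstats.pca_genotypes(G, n_components=3)
        scores2, _ = popstats.pca_genotypes(G.take_inds(perm), n_components=3)
        assert np.allclose(scores1[perm], scores2, atol=1e-8)


class TestPCACoancestry:
    def test_block_structure_recovered(self, rng):
        blocks = []
        for k in range(3):
            base = np.zeros(9)
            base[3 * k : 3 * k + 3] = 10.0
            blocks += [base + rng.normal(0, 0.1, 9) for _ in range(3)]
        M = np.array(blocks)
        scores, _ = popstats.pca_coancestry(M, n_components=2)
        from sklearn.metrics import silhouette_score

        sil = silhouette_score(scores, [0, 0, 0, 1, 1, 1, 2, 2, 2])
        assert sil > 0.8

    def test_identical_rows_zero_variance(self):
        M = np.tile(np.arange(4.0), (4, 1))
        with pytest.warns(UserWarning, match="rank"):
            scores, frac = popstats.pca_coancestry(M, n_components=2)
        assert scores.shape[1] == 0 or np.allclose(scores, 0)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            popstats.pca_coancestry(np.zeros((3, 4)))

    def test_sign_convention_deterministic(self, rng):
        M = rng.normal(size=(6, 6))
        s1, _ = popstats.pca_coancestry(M, 3)
        s2, _ = popstats.pca_coancestry(M.copy(), 3)
        assert np.array_equal(s1, s2)
        for k in range(s1.shape[1]):
            assert s1[np.argmax(np.abs(s1[:, k])), k] >= 0
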