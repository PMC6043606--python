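"""Negative-binomial SNP-desert scan, checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from clonescan.deserts import (
    DesertModel,
    desert_density,
    desert_age_profile,
    desert_threshold,
    estimate_p,
    find_deserts,
    fold_depletion,
    merge_intervals,
    shared_boundaries,
)

# ---------------------------------------------------------------------------
# independent oracles


def brute_threshold(p: float, k: int, alpha: float) -> int:
    """Smallest L with P[Bin(L, p) <= k-1] <= alpha by stepwise pmf summation."""
    L = k
    while sum(stats.binom.pmf(i, L, p) for i in range(k)) > alpha:
        L += 1
    return L


def brute_deserts(pos, chrom_len, model):
    """Exhaustive window scan: every boundary-delimited window with < k SNPs
    and interior length > L_k, plus tail windows ending at the last SNP with
    j < k SNPs remaining after the anchor, merged naively to a fixpoint."""
    pos = sorted(int(x) for x in pos)
    m = len(pos)
    k = model.k
    th = {j: brute_threshold(model.p, j, model.alpha) for j in range(1, k + 1)}
    bounds = [0] + pos
    cands = []
    for i in range(len(bounds)):
        for j in range(i + 1, len(bounds)):
            inside = j - i - 1
            if inside >= k:
                continue
            a, b = bounds[i] + 1, bounds[j] - 1
            if b >= a and (b - a + 1) > th[k]:
                cands.append((a, b))
    for i in range(len(bounds)):
        j_rem = m - i
        if not 1 <= j_rem <= k - 1:
            continue
        a, b = bounds[i] + 1, pos[-1] - 1
        if b >= a and (b - a + 1) > th[j_rem]:
            cands.append((a, b))
    cands = sorted(set(cands))
    changed = True
    while changed:
        changed = False
        for x in range(len(cands)):
            for y in range(len(cands)):
                if x == y:
                    continue
                (a1, b1), (a2, b2) = cands[x], cands[y]
                if a2 <= b1 + model.merge_gap + 1 and a1 <= b2 + model.merge_gap + 1:
                    cands[x] = (min(a1, a2), max(b1, b2))
                    cands.pop(y)
                    changed = True
                    break
            if changed:
                break
    return sorted(cands)


# ---------------------------------------------------------------------------
# threshold


class TestThreshold:
    def test_certain_snps_make_L_equal_k(self):
        # p=1: every bp is a SNP, so 5 bp can never hold fewer than 5
        model = DesertModel(p=1 - 1e-12, k=5, alpha=1e-4)
        assert desert_threshold(model) == 5

    def test_alpha_one_gives_L_equal_k(self):
        model = DesertModel(p=0.01, k=5, alpha=1.0)
        assert desert_threshold(model) == 5

    def test_genome_scale_density_matches_brute_force(self):
        # 180,000 SNPs over 32 Mb -> p = 0.005625
        p = 180_000 / 32e6
        model = DesertModel(p=p, k=5, alpha=1e-4)
        L = desert_threshold(model)
        assert L == brute_threshold(p, 5, 1e-4)
        # exact CDF brackets the crossing
        assert stats.binom.cdf(4, L, p) <= 1e-4 < stats.binom.cdf(4, L - 1, p)
        # Poisson cross-check: lambda = pL near the 1e-4 quantile crossing
        assert stats.poisson.cdf(4, p * L) == pytest.approx(1e-4, rel=0.25)

    @pytest.mark.parametrize("p,k", [(0.02, 3), (0.005, 5), (0.1, 1)])
    def test_matches_brute_force_across_parameters(self, p, k):
        model = DesertModel(p=p, k=k, alpha=1e-4)
        assert desert_threshold(model) == brute_threshold(p, k, 1e-4)


# ---------------------------------------------------------------------------
# scan


class TestFindDeserts:
    def test_planted_gap_found(self):
        # SNP every 100 bp except a 5 Kb hole; scan must return exactly the hole
        pos = np.array([p for p in range(100, 10_001, 100) if not 3000 < p < 8000])
        model = DesertModel(p=len(pos) / 10_000, k=5, alpha=1e-4)
        assert desert_threshold(model) < 5000
        table = find_deserts({"c": pos}, {"c": 10_000}, model)
        assert len(table) == 1
        row = table.iloc[0]
        # the desert contains the hole; its boundaries extend to the k-th
        # flanking SNP on each side, so up to k-1 SNPs sit inside
        assert row["start"] <= 3001 and row["end"] >= 7999
        assert row["n_snps"] < 2 * model.k

    def test_two_subthreshold_gaps_merge_across_small_gap(self):
        # two gaps separated by 50 bp of SNP-dense sequence merge into one desert
        model = DesertModel(p=0.05, k=5, alpha=1e-4, merge_gap=100)
        L = desert_threshold(model)
        dense = list(range(5000, 5051, 10))  # 6 SNPs in 50 bp between the gaps
        pos = np.array([1000, 2000, 3000, 4000] + dense + [6000, 7000, 8000, 9000, 9990])
        table = find_deserts({"c": np.sort(pos)}, {"c": 10_000}, model)
        merged = table[(table["start"] < 5000) & (table["end"] > 5100)]
        assert len(merged) == 1

    def test_empty_chromosome_shorter_than_threshold_has_no_desert(self):
        model = DesertModel(p=0.01, k=5, alpha=1e-4)
        with pytest.warns(UserWarning, match="threshold"):
            table = find_deserts({"c": np.array([], dtype=int)}, {"c": 500}, model)
        assert len(table) == 0

    def test_unsorted_input_sorted_with_warning(self):
        model = DesertModel(p=0.01, k=5, alpha=1e-4)
        pos = np.array([9000, 100, 5000])
        with pytest.warns(UserWarning, match="unsorted"):
            a = find_deserts({"c": pos}, {"c": 50_000}, model)
        b = find_deserts({"c": np.sort(pos)}, {"c": 50_000}, model)
        pd.testing.assert_frame_equal(a, b)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        chrom_len = 30_000
        density = rng.uniform(0.002, 0.02)
        pos = np.sort(rng.choice(chrom_len, rng.binomial(chrom_len, density), replace=False) + 1)
        if seed % 2 and len(pos) > 10:
            a = rng.integers(1, chrom_len - 10_000)
            pos = pos[(pos < a) | (pos > a + rng.integers(2_000, 9_000))]
        if len(pos) == 0:
            return
        model = DesertModel(p=len(pos) / chrom_len, k=5, alpha=1e-4)
        got = find_deserts({"c": pos}, {"c": chrom_len}, model)
        assert sorted(zip(got["start"], got["end"])) == brute_deserts(pos, chrom_len, model)

    def test_deserts_never_overlap_and_are_order_invariant(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(40_000, 300, replace=False) + 1)
        pos = pos[(pos < 10_000) | (pos > 22_000)]
        model = DesertModel(p=len(pos) / 40_000, k=5, alpha=1e-4)
        table = find_deserts({"c": pos}, {"c": 40_000}, model)
        ivs = sorted(zip(table["start"], table["end"]))
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert s2 > e1
        shuffled = pos.copy()
        rng.shuffle(shuffled)
        with pytest.warns(UserWarning):
            table2 = find_deserts({"c": shuffled}, {"c": 40_000}, model)
        assert sorted(zip(table2["start"], table2["end"])) == ivs

    def test_false_discovery_shrinks_with_alpha(self):
        # on homogeneous tracks the number of called deserts is monotone
        # non-increasing as alpha tightens
        rng = np.random.default_rng(9)
        counts = {1e-2: 0, 1e-4: 0, 1e-6: 0}
        for rep in range(20):
            pos = np.sort(rng.choice(100_000, 800, replace=False) + 1)
            for alpha in counts:
                model = DesertModel(p=len(pos) / 100_000, k=5, alpha=alpha)
                counts[alpha] += len(find_deserts({"c": pos}, {"c": 100_000}, model))
        assert counts[1e-2] >= counts[1e-4] >= counts[1e-6]


# ---------------------------------------------------------------------------
# density and comparisons


class TestDensity:
    def test_large_desert_density_and_sigma(self):
        # 75 SNPs in 320 Kb: p = 2.34e-4, sigma = 2.71e-5
        p, lo, hi = desert_density(75, 320_000)
        assert p == pytest.approx(2.34e-4, rel=0.01)
        sigma = (hi - p) / 2
        assert sigma == pytest.approx(2.71e-5, rel=0.01)

    @pytest.mark.parametrize("n,L,expected", [(0, 1000, 0.0), (1000, 1000, 1.0)])
    def test_degenerate_densities_have_zero_sigma(self, n, L, expected):
        p, lo, hi = desert_density(n, L)
        assert p == expected and lo == p and hi == p

    def test_more_snps_than_bases_rejected(self):
        with pytest.raises(ValueError):
            desert_density(11, 10)

    def test_fold_depletion_twenty_four(self):
        # genome 180,000 SNPs / 32 Mb; desert 75 SNPs in 320 Kb -> 24x
        assert fold_depletion(180_000, 32_000_000, 75, 320_000) == pytest.approx(24.0)

    def test_equal_densities_give_fold_one(self):
        assert fold_depletion(1000, 1_000_000, 10, 10_000) == pytest.approx(1.0)


class TestSharedBoundaries:
    def _table(self, ivs):
        return pd.DataFrame(
            [(c, s, e, e - s + 1, 0, 0.0, 0.0, 0.0) for c, s, e in ivs],
            columns=["chrom", "start", "end", "length", "n_snps", "density", "lo2sig", "hi2sig"],
        )

    def test_identical_lists_fully_clustered(self):
        ivs = [("c1", 100, 900), ("c2", 5000, 9000)]
        tables = {f"iso{i}": self._table(ivs) for i in range(4)}
        out = shared_boundaries(tables, tol_bp=0)
        assert (out["n_isolates"] == 4).all()
        assert len(out) == 4  # 2 deserts x {left, right}

    def test_offset_boundaries_not_clustered_at_zero_tolerance(self):
        tables = {
            "a": self._table([("c1", 100, 900)]),
            "b": self._table([("c1", 101, 901)]),
        }
        out = shared_boundaries(tables, tol_bp=0)
        assert (out["n_isolates"] == 1).all()
        out2 = shared_boundaries(tables, tol_bp=1)
        assert (out2["n_isolates"] == 2).all()

    def test_recovers_generator_loh_blocks(self, desk_ref, population, clonal_family):
        clones, _, model = clonal_family
        tables = {}
        for c in clones:
            het = sorted(c.het_sites)
            positions = {
                name: np.array([p for cc, p in het if cc == name], dtype=np.int64)
                for name in desk_ref.names
            }
            dm = DesertModel(p=estimate_p(len(het), desk_ref.total_length))
            tables[c.name] = find_deserts(positions, desk_ref.lengths, dm)
        out = shared_boundaries(tables, tol_bp=2_000)
        # every planted LoH block should surface as a boundary cluster shared
        # by most clones; boundaries sit up to ~k mean inter-SNP spacings
        # outside the block (they extend to the k-th flanking SNP), and
        # private mutations may nudge individual isolates
        for chrom, start, end in model.loh_blocks:
            near_left = out[(out["chrom"] == chrom) & (out["side"] == "left")
                            & ((out["coord"] - start).abs() < 8_000)]
            assert near_left["n_isolates"].max() >= 4
            near_right = out[(out["chrom"] == chrom) & (out["side"] == "right")
                             & ((out["coord"] - end).abs() < 8_000)]
            assert near_right["n_isolates"].max() >= 4

    def test_single_isolate_rejected(self):
        with pytest.raises(ValueError):
            shared_boundaries({"a": self._table([])})


class TestAgeProfile:
    def test_homogeneous_deserts_not_rejected_and_depletion_measured(self):
        # deserts drawn from one shared (low) Poisson rate: the homogeneity
        # test should usually accept, and fold-depletion reflects the planted
        # 20x density contrast
        rng = np.random.default_rng(13)
        chrom_len = 1_000_000
        blocks = [(i * 200_000 + 50_000, i * 200_000 + 150_000) for i in range(5)]
        base, desert_rate = 0.004, 0.0002
        pos = []
        for x in range(0, chrom_len, 1000):
            in_desert = any(s <= x < e for s, e in blocks)
            rate = desert_rate if in_desert else base
            n = rng.poisson(rate * 1000)
            pos.extend(rng.integers(x + 1, x + 1001, n).tolist())
        pos = {"c": np.sort(np.unique(pos))}
        deserts = pd.DataFrame(
            [("c", s + 1, e, e - s, int(((pos["c"] > s) & (pos["c"] <= e)).sum()),
              0.0, 0.0, 0.0) for s, e in blocks],
            columns=["chrom", "start", "end", "length", "n_snps", "density", "lo2sig", "hi2sig"],
        )
        table, p_hom, fold = desert_age_profile(deserts, pos, {"c": chrom_len}, min_length=50_000)
        assert len(table) == 5
        assert p_hom > 0.01
        assert fold == pytest.approx(base / desert_rate, rel=0.35)

    def test_heterogeneous_desert_ages_rejected(self):
        pos = {"c": np.sort(np.random.default_rng(3).choice(1_000_000, 2000, replace=False) + 1)}
        deserts = pd.DataFrame(
            [("c", 1, 100_000, 100_000, 5, 0.0, 0.0, 0.0),
             ("c", 500_001, 600_000, 100_000, 300, 0.0, 0.0, 0.0)],
            columns=["chrom", "start", "end", "length", "n_snps", "density", "lo2sig", "hi2sig"],
        )
        _, p_hom, _ = desert_age_profile(deserts, pos, {"c": 1_000_000})
        assert p_hom < 1e-6


class TestMergeIntervals:
    def test_merge_reaches_fixpoint(self):
        ivs = [(1, 100), (150, 250), (300, 400)]
        assert merge_intervals(ivs, 50) == [(1, 400)]
        assert merge_intervals(ivs, 10) == ivs

    def test_estimate_p(self):
        assert estimate_p(180_000, 32_000_000) == pytest.approx(0.005625)
        with pytest.raises(ValueError):
            estimate_p(10, 0)
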