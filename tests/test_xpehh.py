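"""EHH/iHH/XP-EHH against hand combinatorics and the pairwise-identity oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bovidemog.xpehh import (
    EhhCurve,
    _ihh_all,
    ehh,
    ehh_partitioned,
    flag_outliers,
    ihh,
    standardize_by_chrom,
    xpehh,
)

from conftest import make_hapset


def brute_force_ehh(H, core, x):
    """Pairwise-identity oracle: fraction of haplotype pairs identical over
    the allele string core..x inclusive."""
    lo, hi = min(core, x), max(core, x)
    n = H.shape[0]
    hits = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.array_equal(H[i, lo : hi + 1], H[j, lo : hi + 1]):
                hits += 1
    return hits / (n * (n - 1) / 2)


class TestEhh:
    def test_identical_haplotypes_stay_one(self):
        H = np.tile(np.array([0, 1, 1, 0, 1], dtype=np.uint8), (6, 1))
        hs = make_hapset(H, [100, 200, 300, 400, 500])
        curve = ehh(hs, 2, "right")
        assert [v for _, v in curve.points] == [1.0, 1.0, 1.0]

    def test_two_equal_groups(self):
        # 4 haplotypes split 2/2 at the flank: (1+1)/C(4,2) = 1/3
        H = np.array([[0, 0], [0, 0], [0, 1], [0, 1]], dtype=np.uint8)
        hs = make_hapset(H, [100, 200])
        curve = ehh(hs, 0, "right", cutoff=0.0)
        assert curve.points == [(100, 1.0), (200, pytest.approx(1 / 3))]

    def test_all_distinct_gives_zero(self):
        H = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
        hs = make_hapset(H, [100, 200])
        curve = ehh(hs, 0, "right", cutoff=0.0)
        # strings 00,00.. wait: distinct over both columns
        assert curve.points[-1][1] < 1.0

    def test_monotone_decay(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            H = rng.integers(0, 2, (8, 10)).astype(np.uint8)
            hs = make_hapset(H, np.arange(10) * 1000 + 1)
            for direction in ("left", "right"):
                vals = [v for _, v in ehh(hs, 5, direction, cutoff=0.0).points]
                assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_matches_pairwise_identity_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = 2 * rng.integers(2, 6)
            m = rng.integers(3, 12)
            H = rng.integers(0, 2, (n, m)).astype(np.uint8)
            pos = np.sort(rng.choice(np.arange(1, 10**6), m, replace=False))
            hs = make_hapset(H, pos)
            core = int(rng.integers(0, m))
            curve = ehh(hs, core, "right", cutoff=0.0)
            for pos_x, val in curve.points[1:]:
                x = int(np.flatnonzero(pos == pos_x)[0])
                assert val == pytest.approx(brute_force_ehh(H, core, x))

    def test_gap_truncation(self):
        H = np.tile(np.array([1, 1, 1, 1], dtype=np.uint8), (4, 1))
        hs = make_hapset(H, [1000, 2000, 500_000, 501_000])
        curve = ehh(hs, 0, "right")
        # the 2000 -> 500000 step exceeds the 400 kb gap limit
        assert [p for p, _ in curve.points] == [1000, 2000]

    def test_cutoff_truncation(self):
        rng = np.random.default_rng(2)
        H = rng.integers(0, 2, (10, 6)).astype(np.uint8)
        hs = make_hapset(H, np.arange(6) * 1000 + 1)
        curve = ehh(hs, 0, "right", cutoff=0.3)
        assert all(v >= 0.3 for _, v in curve.points)

    def test_partitioned_restricts_to_carriers(self):
        H = np.array(
            [[1, 0, 0], [1, 0, 0], [0, 1, 1], [0, 1, 0]], dtype=np.uint8
        )
        hs = make_hapset(H, [100, 200, 300])
        c = ehh_partitioned(hs, 0, 1, "right")
        # both carriers of allele 1 are identical throughout
        assert [v for _, v in c.points] == [1.0, 1.0, 1.0]


class TestIhh:
    def test_rectangular_geometry(self):
        H = np.tile(np.array([1, 1], dtype=np.uint8), (4, 1))
        hs = make_hapset(H, [1000, 11000])
        left = ehh(hs, 0, "left")
        right = ehh(hs, 0, "right")
        assert ihh(left, right) == pytest.approx(10_000.0)

    def test_doubling_distances_doubles_ihh(self):
        rng = np.random.default_rng(3)
        H = rng.integers(0, 2, (10, 8)).astype(np.uint8)
        pos = np.arange(8) * 5000 + 1
        v1 = ihh(
            ehh(make_hapset(H, pos), 4, "left"),
            ehh(make_hapset(H, pos), 4, "right"),
        )
        pos2 = np.arange(8) * 10000 + 1
        v2 = ihh(
            ehh(make_hapset(H, pos2), 4, "left"),
            ehh(make_hapset(H, pos2), 4, "right"),
        )
        assert v2 == pytest.approx(2 * v1)

    def test_core_mismatch_rejected(self):
        a = EhhCurve(0, "left", [(100, 1.0)])
        b = EhhCurve(1, "right", [(200, 1.0)])
        with pytest.raises(ValueError):
            ihh(a, b)


class TestFastPath:
    def test_fast_ihh_equals_reference(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            n = 2 * rng.integers(2, 8)
            m = rng.integers(5, 20)
            H = rng.integers(0, 2, (n, m)).astype(np.uint8)
            pos = np.sort(rng.choice(np.arange(1, 3_000_000), m, replace=False))
            hs = make_hapset(H, pos)
            cores = np.arange(m)
            fast = _ihh_all(hs, cores, 0.05, 400_000)
            ref = np.array(
                [
                    ihh(ehh(hs, c, "left"), ehh(hs, c, "right"))
                    for c in range(m)
                ]
            )
            np.testing.assert_allclose(fast, ref)


class TestXpehh:
    def test_identical_populations_raw_zero(self, two_pop_sim):
        _, hapsets, _ = two_pop_sim
        hs = hapsets["A"][0]
        rec = xpehh(hs, hs)
        assert rec.tested.any()
        assert np.allclose(rec.loc[rec.tested, "raw"], 0.0)

    def test_swap_negates_raw(self, two_pop_sim):
        _, hapsets, _ = two_pop_sim
        a, b = hapsets["A"][0], hapsets["B"][0]
        r_ab = xpehh(a, b)
        r_ba = xpehh(b, a)
        np.testing.assert_allclose(
            r_ab.loc[r_ab.tested, "raw"],
            -r_ba.loc[r_ba.tested, "raw"],
            atol=1e-12,
        )

    def test_mismatched_maps_rejected(self, two_pop_sim):
        _, hapsets, _ = two_pop_sim
        a = hapsets["A"][0]
        b = hapsets["B"][0]
        shifted = make_hapset(
            b.haplotypes, b.variants["pos_bp"].to_numpy() + 7
        )
        with pytest.raises(ValueError, match="variant map"):
            xpehh(a, shifted)


class TestStandardize:
    def _rec(self, raws, chroms=None, tested=None):
        n = len(raws)
        return pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(n)],
                "chrom": chroms or ["1"] * n,
                "pos_bp": np.arange(n) * 1000 + 1,
                "ihh_a": 1.0,
                "ihh_b": 1.0,
                "raw": raws,
                "tested": tested if tested is not None else [True] * n,
            }
        )

    def test_two_values_hand_evaluation(self):
        out = standardize_by_chrom(self._rec([0.1, 0.3]))
        np.testing.assert_allclose(
            out["z"], [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12
        )

    def test_mean_zero_sd_one_per_chrom(self):
        rng = np.random.default_rng(5)
        raws = rng.normal(size=40)
        chroms = ["1"] * 25 + ["2"] * 15
        out = standardize_by_chrom(self._rec(list(raws), chroms=chroms))
        for _, sub in out.groupby("chrom"):
            assert sub["z"].mean() == pytest.approx(0.0, abs=1e-12)
            assert sub["z"].std(ddof=1) == pytest.approx(1.0)

    def test_location_invariance(self):
        rng = np.random.default_rng(6)
        raws = rng.normal(size=10)
        z1 = standardize_by_chrom(self._rec(list(raws)))["z"]
        z2 = standardize_by_chrom(self._rec(list(raws + 5.0)))["z"]
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_zero_variance_names_chromosome(self):
        with pytest.raises(ValueError, match="chromosome 1"):
            standardize_by_chrom(self._rec([0.2, 0.2, 0.2]))

    def test_flags_100_distinct(self):
        rng = np.random.default_rng(7)
        raws = rng.permutation(np.linspace(-2, 2, 100))
        out = flag_outliers(standardize_by_chrom(self._rec(list(raws))))
        # sort-based oracle: 5 smallest low, 5 largest high
        z = out["z"].to_numpy()
        order = np.argsort(z)
        assert set(out.index[out.outlier == "low"]) == set(order[:5])
        assert set(out.index[out.outlier == "high"]) == set(order[-5:])

    def test_all_equal_z_not_flagged(self):
        rec = self._rec([0.1, 0.5, 0.5, 0.9])
        out = standardize_by_chrom(rec)
        out["z"] = 0.0  # force the degenerate case
        flagged = flag_outliers(out)
        assert (flagged["outlier"] == "none").all()

    def test_flags_spread_over_chromosomes_on_neutral_data(self):
        """Genome-wide quantile flags on sweep-free data fall on each
        chromosome roughly in proportion to its tested SNPs."""
        from scipy import stats

        from bovidemog.simulate import PopulationSpec, SimConfig, simulate

        cfg = SimConfig(
            chrom_length_bp=15_000_000,
            n_variants=500,
            n_chromosomes=4,
            populations=[
                PopulationSpec("anc", [(100, 150)]),
                PopulationSpec("A", [(60, 120)], parents=["anc"], split_generation=60),
                PopulationSpec("B", [(60, 120)], parents=["anc"], split_generation=60),
            ],
            sample_sizes={"A": 30, "B": 30},
            seed=404,
        )
        _, haps, _ = simulate(cfg)
        rec = pd.concat(
            [xpehh(a, b) for a, b in zip(haps["A"], haps["B"])],
            ignore_index=True,
        )
        out = flag_outliers(standardize_by_chrom(rec))
        tested = out[out["tested"]]
        flagged = tested.groupby("chrom", sort=False).apply(
            lambda s: (s["outlier"] != "none").sum(), include_groups=False
        )
        expected = tested.groupby("chrom", sort=False).size() * (
            (tested["outlier"] != "none").mean()
        )
        chi2 = (((flagged - expected) ** 2) / expected).sum()
        p = stats.chi2.sf(chi2, df=len(flagged) - 1)
        assert p > 0.001

    @settings(max_examples=25, derandomize=True)
    @given(st.permutations(list(range(40))))
    def test_flags_permutation_invariant(self, perm):
        rng = np.random.default_rng(8)
        raws = list(rng.normal(size=40))
        base = flag_outliers(standardize_by_chrom(self._rec(raws)))
        rec_p = self._rec(raws).iloc[perm].reset_index(drop=True)
        out_p = flag_outliers(standardize_by_chrom(rec_p))
        merged = base.merge(out_p, on="variant_id", suffixes=("_a", "_b"))
        assert (merged["outlier_a"] == merged["outlier_b"]).all()
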