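"""Window statistics against brute-force and coalescent oracles."""

import itertools

import msprime
import numpy as np
import pytest

from islandsweep import winstats
from islandsweep.winstats import (
    WindowSpec,
    dxy,
    fst_hudson,
    fst_weir_cockerham,
    ld_prune,
    ld_r2,
    net_divergence,
    pi,
    pi_log_ratio,
    tajimas_d,
    watterson_theta,
    window_iter,
)


def counts(H):
    """(n_alt, n_called) per site for a haplotype matrix with -1 missing."""
    H = np.asarray(H)
    return (H == 1).sum(axis=1), (H >= 0).sum(axis=1)


def brute_pi(H, length):
    """Mean pairwise Hamming distance per bp (pairwise deletion)."""
    H = np.asarray(H)
    n = H.shape[1]
    tot = 0.0
    for a, b in itertools.combinations(range(n), 2):
        ok = (H[:, a] >= 0) & (H[:, b] >= 0)
        tot += np.sum(H[ok, a] != H[ok, b])
    return tot / (n * (n - 1) / 2) / length


def brute_dxy(HA, HB, length):
    HA, HB = np.asarray(HA), np.asarray(HB)
    tot = pairs = 0.0
    per_site = np.zeros(HA.shape[0])
    for a in range(HA.shape[1]):
        for b in range(HB.shape[1]):
            ok = (HA[:, a] >= 0) & (HB[:, b] >= 0)
            per_site[ok] += (HA[ok, a] != HB[ok, b]).astype(float)
    # mean over pairs per site, then summed / length
    npairs = np.zeros(HA.shape[0])
    for a in range(HA.shape[1]):
        for b in range(HB.shape[1]):
            ok = (HA[:, a] >= 0) & (HB[:, b] >= 0)
            npairs[ok] += 1
    with np.errstate(invalid="ignore"):
        ms = np.where(npairs > 0, per_site / np.maximum(npairs, 1), 0.0)
    return ms.sum() / length


class TestWindows:
    def test_enumeration(self):
        spec = WindowSpec(10_000, 2_500, {"s": 15_000})
        assert list(window_iter(spec)) == [
            ("s", 1, 10_000), ("s", 2_501, 12_500), ("s", 5_001, 15_000)
        ]

    @pytest.mark.parametrize("length,n", [(9_999, 0), (10_000, 1)])
    def test_boundary_lengths(self, length, n):
        assert len(list(window_iter(WindowSpec(10_000, 2_500, {"s": length})))) == n

    def test_bad_steps_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(10_000, 0, {})
        with pytest.raises(ValueError):
            WindowSpec(10_000, 20_000, {})


class TestPi:
    def test_single_difference_two_haplotypes(self):
        H = np.zeros((10, 2), dtype=int)
        H[0, 1] = 1
        n_alt, n_called = counts(H)
        assert pi(n_alt, n_called, 10_000) == pytest.approx(1e-4)

    def test_identical_haplotypes_zero(self):
        n_alt, n_called = counts(np.zeros((5, 4), dtype=int))
        assert pi(n_alt, n_called, 100) == 0.0

    def test_two_two_split_window_of_10(self):
        H = np.zeros((1, 4), dtype=int)
        H[0, :2] = 1
        n_alt, n_called = counts(H)
        assert pi(n_alt, n_called, 10) == pytest.approx((2 * 2 * 2 / 12) / 10)

    def test_undefined_without_two_alleles(self):
        assert np.isnan(pi(np.array([0]), np.array([1]), 100))

    def test_matches_pairwise_hamming_on_complete_panels(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_h = rng.integers(2, 9)
            n_s = rng.integers(1, 51)
            H = rng.integers(0, 2, size=(n_s, n_h))
            got = pi(*counts(H), 1000)
            assert got == pytest.approx(brute_pi(H, 1000), abs=1e-12)

    def test_missing_data_pairwise_deletion_per_site(self):
        # with unknowns, each site averages over its co-called pairs
        rng = np.random.default_rng(43)
        H = rng.integers(0, 2, size=(30, 6))
        H[rng.random(H.shape) < 0.2] = -1
        expect = 0.0
        for row in H:
            called = row[row >= 0]
            n = len(called)
            if n >= 2:
                expect += 2 * (called == 1).sum() * (called == 0).sum() / (n * (n - 1))
        assert pi(*counts(H), 500) == pytest.approx(expect / 500, abs=1e-12)


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        assert np.isnan(tajimas_d(np.array([0, 0]), np.array([4, 4])))

    def test_two_singletons_n4(self):
        # hand-evaluated: k = 1.0, thetaW = 2/a1 = 1.0909, D ~ -0.71
        n_alt = np.array([1, 1])
        n_called = np.array([4, 4])
        assert tajimas_d(n_alt, n_called) == pytest.approx(-0.71, abs=0.01)

    def test_neutral_coalescent_mean_near_zero(self):
        # oracle: independent neutral loci; D has mean ~ 0
        ds = []
        reps = msprime.sim_ancestry(
            samples=10, population_size=1000, num_replicates=80,
            sequence_length=5_000, random_seed=7,
        )
        for i, ts in enumerate(reps):
            mts = msprime.sim_mutations(
                ts, rate=2e-6, random_seed=100 + i,
                model=msprime.BinaryMutationModel(),
            )
            H = mts.genotype_matrix()
            if H.shape[0] < 2:
                continue
            d = tajimas_d(*counts(H))
            if not np.isnan(d):
                ds.append(d)
        se = np.std(ds, ddof=1) / np.sqrt(len(ds))
        assert abs(np.mean(ds)) < 3 * se


class TestFst:
    def test_fixed_difference_near_one(self):
        HA = np.zeros((50, 20), dtype=int)
        HB = np.ones((50, 20), dtype=int)
        f = fst_weir_cockerham(*counts(HA), *counts(HB))
        assert f > 0.95

    def test_panmictic_near_zero(self):
        rng = np.random.default_rng(1)
        H = rng.integers(0, 2, size=(400, 40))
        f = fst_weir_cockerham(*counts(H[:, :20]), *counts(H[:, 20:]))
        assert abs(f) < 0.05

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(2)
        HA = rng.integers(0, 2, size=(60, 10))
        HB = rng.integers(0, 2, size=(60, 12))
        a = fst_weir_cockerham(*counts(HA), *counts(HB))
        b = fst_weir_cockerham(*counts(1 - HA), *counts(1 - HB))
        assert a == pytest.approx(b, abs=1e-12)

    def test_island_model_matches_coalescent_expectation(self):
        # two-deme symmetric island model of haploids at equilibrium:
        # E[T_same] = 2N, E[T_diff] = 2N + 1/(2m), so Hudson Fst has
        # expectation 1 / (1 + 4 N m); Monte-Carlo check within 3 SE
        N, m = 1000, 2.5e-4
        dem = msprime.Demography()
        dem.add_population(name="a", initial_size=N)
        dem.add_population(name="b", initial_size=N)
        dem.set_symmetric_migration_rate(["a", "b"], m)
        per_rep = []  # (hw_sum, hb_sum) per locus, for ratio-of-sums
        vals_wc, vals_h = [], []
        reps = msprime.sim_ancestry(
            samples={"a": 15, "b": 15}, demography=dem, ploidy=1,
            sequence_length=5_000, num_replicates=60, random_seed=5,
        )
        for i, ts in enumerate(reps):
            mts = msprime.sim_mutations(
                ts, rate=1e-6, random_seed=999 + i,
                model=msprime.BinaryMutationModel(),
            )
            H = mts.genotype_matrix()
            if H.shape[0] < 1:
                continue
            (a1, n1), (a2, n2) = counts(H[:, :15]), counts(H[:, 15:])
            p1, p2 = a1 / n1, a2 / n2
            hw = (2 * p1 * (1 - p1) * n1 / (n1 - 1)
                  + 2 * p2 * (1 - p2) * n2 / (n2 - 1)) / 2.0
            hb = p1 * (1 - p2) + p2 * (1 - p1)
            per_rep.append((hw.sum(), hb.sum()))
            h = fst_hudson(a1, n1, a2, n2)
            w = fst_weir_cockerham(a1, n1, a2, n2)
            if np.isfinite(h) and np.isfinite(w):
                vals_h.append(h)
                vals_wc.append(w)
        hw_tot = sum(x for x, _ in per_rep)
        hb_tot = sum(y for _, y in per_rep)
        fst_all = 1.0 - hw_tot / hb_tot
        # delete-one-locus jackknife SE of the ratio-of-sums estimate
        g = len(per_rep)
        pseudo = [
            1.0 - (hw_tot - x) / (hb_tot - y) for x, y in per_rep
        ]
        se = np.sqrt((g - 1) / g * np.sum((np.array(pseudo) - np.mean(pseudo)) ** 2))
        expect = 1.0 / (1.0 + 4 * N * m)
        assert abs(fst_all - expect) < 3 * se
        # the two estimators agree closely on the same data
        assert np.mean(vals_wc) == pytest.approx(np.mean(vals_h), abs=0.03)


class TestDivergence:
    def test_net_divergence_formula(self):
        assert net_divergence(0.02, 0.01, 0.01) == pytest.approx(0.01)

    def test_same_population_d_zero(self):
        rng = np.random.default_rng(3)
        H = rng.integers(0, 2, size=(40, 8))
        n_alt, n_called = counts(H)
        dxy_v = dxy(n_alt, n_called, n_alt, n_called, 1000)
        p = pi(n_alt, n_called, 1000)
        d = net_divergence(dxy_v, p, p)
        # dxy over a sample against itself averages over n^2 pairs while pi
        # averages over n(n-1), so d sits within -pi/(n-1) of zero exactly
        n = 8
        assert -p / (n - 1) - 1e-12 <= d <= 1e-12
        assert d <= dxy_v

    def test_one_fixed_difference(self):
        HA = np.zeros((1, 6), dtype=int)
        HB = np.ones((1, 6), dtype=int)
        v = dxy(*counts(HA), *counts(HB), 10_000)
        assert v == pytest.approx(1e-4)
        assert net_divergence(v, 0.0, 0.0) == pytest.approx(1e-4)

    def test_dxy_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            HA = rng.integers(0, 2, size=(30, rng.integers(2, 8)))
            HB = rng.integers(0, 2, size=(30, rng.integers(2, 8)))
            got = dxy(*counts(HA), *counts(HB), 500)
            assert got == pytest.approx(brute_dxy(HA, HB, 500), abs=1e-12)

    def test_d_never_exceeds_dxy(self):
        rng = np.random.default_rng(5)
        HA = rng.integers(0, 2, size=(50, 6))
        HB = rng.integers(0, 2, size=(50, 6))
        ca, cb = counts(HA), counts(HB)
        v = dxy(*ca, *cb, 500)
        d = net_divergence(v, pi(*ca, 500), pi(*cb, 500))
        assert d <= v + 1e-15


class TestPiLogRatio:
    @pytest.mark.parametrize(
        "u,s,expect",
        [(1e-3, 1e-3, 0.0), (1e-2, 1e-3, 1.0)],
    )
    def test_finite_cases(self, u, s, expect):
        assert pi_log_ratio(u, s) == pytest.approx(expect)

    def test_swept_window_flagged_infinite(self):
        assert pi_log_ratio(1e-3, 0.0) == np.inf

    def test_uninformative_window_dropped(self):
        assert np.isnan(pi_log_ratio(0.0, 1e-3))


class TestLD:
    def test_perfect_coupling(self):
        h = np.array([0, 0, 1, 1])
        assert ld_r2(h, h) == pytest.approx(1.0)

    def test_hand_enumerated_case(self):
        # haplotypes AB, AB, ab, aB with A=1, B=1
        hi = np.array([1, 1, 0, 0])
        hj = np.array([1, 1, 0, 1])
        assert ld_r2(hi, hj) == pytest.approx(1 / 3)

    def test_monomorphic_undefined(self):
        assert np.isnan(ld_r2(np.array([1, 1, 1]), np.array([0, 1, 0])))

    def test_prune_removes_later_of_coupled_pair(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 2, size=60)
        b = rng.integers(0, 2, size=60)
        H = np.stack([a, a, b])  # sites 0,1 perfectly coupled
        kept = ld_prune(H, threshold=0.5)
        assert 0 in kept and 1 not in kept

    def test_prune_keeps_independent_sites(self):
        rng = np.random.default_rng(7)
        H = rng.integers(0, 2, size=(10, 500))
        kept = ld_prune(H, threshold=0.9)
        assert len(kept) == 10


class TestWindowTable:
    def test_columns_and_exact_net_divergence_identity(self, datasets):
        ds = datasets("parallel")
        m = [ds.matrix("scaffold_X1")]
        pops = {
            "kfw": ds.samples_where(deme="kauai", morph="flatwing"),
            "aus": ds.samples_where(deme="australia"),
        }
        tbl = winstats.window_stats(m, pops, ratio_pair=("aus", "kfw"))
        assert {"pi_kfw", "fst_kfw_aus", "dxy_kfw_aus", "d_kfw_aus",
                "pi_log_ratio"} <= set(tbl.columns)
        ok = tbl.dropna(subset=["d_kfw_aus"])
        np.testing.assert_allclose(
            ok["d_kfw_aus"],
            ok["dxy_kfw_aus"] - (ok["pi_kfw"] + ok["pi_aus"]) / 2,
            atol=1e-12,
        )
        assert (ok["pi_kfw"] >= 0).all() and (ok["dxy_kfw_aus"] >= 0).all()
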