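"""Diversity / divergence estimators against brute-force oracles."""

import itertools

import numpy as np
import pytest

import androscan as asn
from androscan import popgen

from conftest import make_manifest, make_variants


# ---------------------------------------------------------------------------
# independent oracles (pair counting / literal transcription; no shared code)
# ---------------------------------------------------------------------------

def pi_by_pair_enumeration(n_alt, n_called):
    """Mean pairwise difference by enumerating every haplotype pair."""
    haps = [1] * n_alt + [0] * (n_called - n_alt)
    pairs = list(itertools.combinations(haps, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def hudson_window_by_pair_counting(dosages, group1, group2):
    """Windowed Hudson F_ST as 1 - Hw/Hb from explicit pair counts.

    Hw is the average of the two within-group mean pairwise differences,
    Hb the between-group mean difference; sums run over sites.
    """
    num_sum = den_sum = 0.0
    for site in dosages:
        hap = {}
        for g, cols in (("g1", group1), ("g2", group2)):
            h = []
            for c in cols:
                if site[c] != -1:
                    h.extend([1] * site[c] + [0] * (2 - site[c]))
            hap[g] = h
        h1, h2 = hap["g1"], hap["g2"]
        if len(h1) < 2 or len(h2) < 2:
            continue
        hw1 = pi_by_pair_enumeration(sum(h1), len(h1))
        hw2 = pi_by_pair_enumeration(sum(h2), len(h2))
        hb = sum(a != b for a in h1 for b in h2) / (len(h1) * len(h2))
        num_sum += hb - (hw1 + hw2) / 2.0
        den_sum += hb
    return num_sum / den_sum if den_sum else float("nan")


def wc_window_by_1984_equations(dosages, group1, group2):
    """Weir & Cockerham (1984) window F_ST, literal scalar transcription."""
    a_sum = abc_sum = 0.0
    for site in dosages:
        pops = []
        for cols in (group1, group2):
            d = [site[c] for c in cols if site[c] != -1]
            if len(d) < 2:
                pops = []
                break
            pops.append(d)
        if not pops:
            continue
        r = len(pops)
        n = [len(d) for d in pops]
        p = [sum(d) / (2.0 * len(d)) for d in pops]
        h = [sum(1 for x in d if x == 1) / len(d) for d in pops]
        if all(pi in (0.0, 1.0) for pi in p) and len(set(p)) == 1:
            continue
        nbar = sum(n) / r
        nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = nbar / nc * (
            s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        abc_sum += a + b + c
    return a_sum / abc_sum if abc_sum else float("nan")


# ---------------------------------------------------------------------------
# per-site estimators
# ---------------------------------------------------------------------------

class TestSitePi:
    def test_matches_pair_enumeration_exhaustively(self):
        for n in range(2, 9):
            for j in range(n + 1):
                assert asn.site_pi(j, n) == pytest.approx(
                    pi_by_pair_enumeration(j, n), abs=1e-12
                )

    @pytest.mark.parametrize(
        "n_alt,n_called,expected",
        [(2, 4, 2 / 3), (0, 10, 0.0), (1, 2, 1.0)],
    )
    def test_examples(self, n_alt, n_called, expected):
        assert asn.site_pi(n_alt, n_called) == pytest.approx(expected)

    def test_undefined_below_two_haplotypes(self):
        assert np.isnan(asn.site_pi(0, 1))


class TestHudsonSite:
    def test_fixed_difference_is_one(self):
        num, den = asn.hudson_fst_site(1.0, 10, 0.0, 10)
        assert (num, den) == (1.0, 1.0)

    def test_equal_intermediate_frequencies(self):
        num, den = asn.hudson_fst_site(0.5, 11, 0.5, 11)
        assert num == pytest.approx(-0.05)
        assert den == pytest.approx(0.5)

    def test_monomorphic_uninformative(self):
        assert asn.hudson_fst_site(0.0, 10, 0.0, 10) == (0.0, 0.0)

    def test_small_group_undefined(self):
        num, den = asn.hudson_fst_site(0.5, 1, 0.5, 10)
        assert np.isnan(num) and np.isnan(den)


class TestWeirCockerhamSite:
    def test_fixed_difference_window_is_one(self):
        a, abc = asn.wc_fst_site([0] * 5, [2] * 5)
        assert a / abc == pytest.approx(1.0)

    def test_identical_groups_not_positive(self):
        a, abc = asn.wc_fst_site([0, 1, 2, 1], [0, 1, 2, 1])
        assert a / abc <= 0

    def test_three_v_three_matches_oracle(self):
        site = np.array([[0, 1, 2, 2, 2, 1]])
        ours = asn.wc_fst_site(site[0, :3], site[0, 3:])
        oracle = wc_window_by_1984_equations(site, [0, 1, 2], [3, 4, 5])
        assert ours[0] / ours[1] == pytest.approx(oracle, abs=1e-12)

    def test_monomorphic_across_groups(self):
        assert asn.wc_fst_site([0, 0, 0], [0, 0, 0]) == (0.0, 0.0)


class TestRod:
    @pytest.mark.parametrize(
        "pi_m,pi_h,expected",
        [(1e-3, 1e-3, 0.0), (0.0, 2e-3, 1.0), (1e-3, 2e-3, 0.5)],
    )
    def test_examples(self, pi_m, pi_h, expected):
        assert asn.rod(pi_m, pi_h) == pytest.approx(expected)

    def test_undefined_at_zero_herm_diversity(self):
        assert np.isnan(asn.rod(1e-3, 0.0))


# ---------------------------------------------------------------------------
# windowed estimators
# ---------------------------------------------------------------------------

class TestWindowPi:
    def test_single_site(self):
        # one called diploid heterozygote: two haplotypes that differ, pi = 1
        v = make_variants([[1, -1]], positions=[500])
        assert asn.window_pi(v, ["s0", "s1"], (0, 10_000)) == pytest.approx(1e-4)

    def test_no_variant_sites(self):
        v = make_variants([[1, 1]], positions=[50_000])
        assert asn.window_pi(v, ["s0", "s1"], (0, 10_000)) == 0.0

    def test_hand_summed_three_sites(self):
        # site_pi values 0.5, 2/3 and 1 (missing call shrinks n) over 10 kb
        v = make_variants(
            [[1, 0], [2, 0], [1, -1]], positions=[100, 200, 300]
        )
        pi = asn.window_pi(v, ["s0", "s1"], (0, 10_000))
        assert pi == pytest.approx((0.5 + 2 / 3 + 1.0) / 10_000)

    def test_zero_length_window_rejected(self):
        v = make_variants([[1, 1]])
        with pytest.raises(asn.ValidationError):
            asn.window_pi(v, ["s0", "s1"], (100, 100))


class TestWindowFst:
    def test_fixed_difference_window(self):
        rows = [[2, 2, 2, 0, 0, 0]] * 5
        v = make_variants(rows)
        m = make_manifest(["male"] * 3 + ["hermaphrodite"] * 3)
        assert asn.window_fst(v, m, (0, 1_000)) == pytest.approx(1.0)

    def test_uninformative_window_flagged(self):
        rows = [[0, 0, 0, 0, 0, 0]] * 5  # monomorphic -> zero denominators
        v = make_variants(rows)
        m = make_manifest(["male"] * 3 + ["hermaphrodite"] * 3)
        assert np.isnan(asn.window_fst(v, m, (0, 1_000)))

    @pytest.mark.parametrize("estimator", popgen.ESTIMATORS)
    def test_random_tables_match_oracles(self, estimator):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n_samples = int(rng.integers(4, 11))
            n_sites = int(rng.integers(5, 51))
            dosages = rng.integers(0, 3, size=(n_sites, n_samples))
            dosages[rng.random(dosages.shape) < 0.05] = -1
            n_m = int(rng.integers(2, n_samples - 1))
            v = make_variants(dosages, positions=np.arange(n_sites) + 1)
            m = make_manifest(
                ["male"] * n_m + ["hermaphrodite"] * (n_samples - n_m)
            )
            ours = asn.window_fst(v, m, (0, n_sites + 10), estimator, min_sites=1)
            g1 = list(range(n_m))
            g2 = list(range(n_m, n_samples))
            if estimator == "hudson":
                expected = hudson_window_by_pair_counting(dosages, g1, g2)
            else:
                expected = wc_window_by_1984_equations(dosages, g1, g2)
            if np.isnan(expected):
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(expected, abs=1e-10)

    def test_label_permutation_symmetry(self):
        """Swapping the sex labels leaves F_ST unchanged and maps
        ROD(m,h) -> 1 - 1/(1 - ROD)."""
        rng = np.random.default_rng(7)
        dosages = rng.integers(0, 3, size=(30, 8))
        v = make_variants(dosages, positions=np.arange(30) + 1)
        m1 = make_manifest(["male"] * 4 + ["hermaphrodite"] * 4)
        m2 = make_manifest(["hermaphrodite"] * 4 + ["male"] * 4)
        for est in popgen.ESTIMATORS:
            f1 = asn.window_fst(v, m1, (0, 100), est, min_sites=1)
            f2 = asn.window_fst(v, m2, (0, 100), est, min_sites=1)
            assert f1 == pytest.approx(f2, abs=1e-12)
        pi_a = asn.window_pi(v, m1.males, (0, 100))
        pi_b = asn.window_pi(v, m1.hermaphrodites, (0, 100))
        rod_fwd = asn.rod(pi_a, pi_b)
        rod_swapped = asn.rod(pi_b, pi_a)
        assert rod_swapped == pytest.approx(1 - 1 / (1 - rod_fwd))

    def test_balding_nichols_window_target_recovery(self):
        """Mean windowed Hudson F_ST recovers a 0.2 simulation target."""
        from androscan.simulate import balding_nichols_freqs

        rng = np.random.default_rng(11)
        n_sites = 20_000
        _, deme_p = balding_nichols_freqs(rng, n_sites, 2, 0.2)
        probs = np.repeat(deme_p, 25, axis=1)  # 25 diploids per deme
        dosages = rng.binomial(2, probs).astype(np.int8)
        cols1 = np.arange(25)
        cols2 = np.arange(25, 50)
        num, den = popgen.fst_site_components(dosages, cols1, cols2)
        per_window = [
            popgen.combine_fst(num[i:i + 200], den[i:i + 200])
            for i in range(0, n_sites, 200)
        ]
        assert np.nanmean(per_window) == pytest.approx(0.2, abs=0.02)
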