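"""Sequence features: seed sites, folding windows, CAI, group statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from asdecay.features import (AlleleSequencePair, MirnaSeed, cai,
                              compare_groups, count_mirna_sites,
                              max_abs_delta_mfe, mfe_windows, nussinov_fold,
                              select_matched_controls, site_difference_test,
                              snp_density)
from asdecay.simulate import derive_rng, simulate_allele_sequences

# miRNA with seed positions 2-8 = GGAAUGU: core 6mer target match CAUUCC,
# the m8-pairing target base is A, so 8mer site = ACAUUCCA.
MIR = MirnaSeed("mir-test", "UGGAAUGUAAAGAAGUAUGUAU")

rna_st = st.text(alphabet="ACGU", min_size=0, max_size=40)


def naive_site_scan(target: str, seed: MirnaSeed) -> int:
    """Independent oracle: test every position against the three literal
    patterns, best (longest) type per 6mer-core occurrence."""
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
    rc = lambda s: "".join(comp[c] for c in reversed(s))
    pat_8 = rc(seed.sequence[1:8]) + "A"
    pat_7m8 = rc(seed.sequence[1:8])
    pat_71a = rc(seed.sequence[1:7]) + "A"
    n = 0
    for j in range(len(target) - 5):
        if target[j:j + 6] != rc(seed.sequence[1:7]):
            continue
        if target[j - 1:j + 7] == pat_8 and j >= 1:
            n += 1
        elif target[j - 1:j + 6] == pat_7m8 and j >= 1:
            n += 1
        elif target[j:j + 7] == pat_71a:
            n += 1
    return n


class TestSnpDensity:
    def test_whole_transcript(self):
        assert snp_density(range(10), 2000) == 5.0
        assert snp_density([], 500) == 0.0

    def test_region_restricted(self):
        # 3 of 5 variants inside a 600-nt CDS span
        assert snp_density([10, 250, 300, 700, 1900], 2000,
                           region_span=(201, 800)) == 5.0

    def test_zero_length_region_rejected(self):
        with pytest.raises(ValueError):
            snp_density([1], 0)


class TestMirnaSites:
    def test_site_type_examples(self):
        assert count_mirna_sites("UUUACAUUCCAUUU", [MIR]) == 1        # 8mer
        assert count_mirna_sites("UUUACAUUCCGUUU", [MIR]) == 1        # 7mer-m8
        assert count_mirna_sites("UUGCAUUCCAUUU", [MIR]) == 1         # 7mer-1A
        assert count_mirna_sites("UUGCAUUCCGUUU", [MIR]) == 0         # bare 6mer
        assert count_mirna_sites("GGGGGGGGGGGG", [MIR]) == 0

    def test_rejects_short_seed(self):
        with pytest.raises(ValueError):
            MirnaSeed("short", "ACGUACG")

    def test_top_k_restricts_seed_list(self):
        other = MirnaSeed("mir-b", "UAAAAAAAAGGG")
        target = "UUUACAUUCCAUUU"
        assert count_mirna_sites(target, [other, MIR], top_k=1) == 0
        assert count_mirna_sites(target, [other, MIR], top_k=2) == 1

    def test_matches_naive_scan_on_random_sequences(self, rng):
        seeds = [MIR, MirnaSeed("mir-2", "UCCCUGAGACCCUUUAACCUGUGA")]
        for _ in range(60):
            target = "".join(rng.choice(list("ACGU"), size=120))
            for seed in seeds:
                assert count_mirna_sites(target, [seed]) == naive_site_scan(target, seed)


def brute_force_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Enumerate every nested structure explicitly (oracle for short strings)."""
    pairable = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
                ("G", "U"), ("U", "G")}

    def best(positions):
        if len(positions) < 2:
            return 0
        i = positions[0]
        score = best(positions[1:])  # i unpaired
        for idx in range(1, len(positions)):
            j = positions[idx]
            if j - i > min_loop and (seq[i], seq[j]) in pairable:
                inside = best(positions[1:idx])
                outside = best(positions[idx + 1:])
                score = max(score, 1 + inside + outside)
        return score

    return best(tuple(range(len(seq))))


class TestNussinov:
    def test_examples(self):
        assert nussinov_fold("AAAA") == 0.0
        assert nussinov_fold("GGGAAACCC") == -3.0

    def test_rejects_invalid_characters(self):
        with pytest.raises(ValueError):
            nussinov_fold("ACGX")

    def test_exhaustive_equivalence_short(self):
        for L in range(1, 7):
            for tup in itertools.product("ACGU", repeat=L):
                s = "".join(tup)
                assert nussinov_fold(s) == -brute_force_max_pairs(s), s

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(rna_st.filter(lambda s: 7 <= len(s) <= 12))
    def test_enumeration_equivalence_random(self, s):
        assert nussinov_fold(s) == -brute_force_max_pairs(s)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(rna_st, st.sampled_from("ACGU"))
    def test_extension_never_loses_pairs(self, s, base):
        assert nussinov_fold(s + base) <= nussinov_fold(s)


class TestMfeWindows:
    def _pair(self, length=600, positions=(5, 300), seed=4):
        pair, _, _ = simulate_allele_sequences(length, list(positions), seed=seed)
        return pair

    def test_interior_window_is_centered(self):
        df = mfe_windows(self._pair(), window=41)
        row = df[df["pos"] == 300].iloc[0]
        assert (row["start"], row["end"]) == (280, 320)
        assert row["end"] - row["start"] + 1 == 41

    def test_boundary_shift_rule(self):
        df = mfe_windows(self._pair(), window=41)
        row = df[df["pos"] == 5].iloc[0]
        assert (row["start"], row["end"]) == (1, 41)
        tail = mfe_windows(self._pair(positions=(598,)), window=41)
        assert (tail.loc[0, "start"], tail.loc[0, "end"]) == (560, 600)

    def test_identical_windows_give_zero(self):
        # variants far apart: the window around a non-variant position is
        # identical between alleles
        pair = self._pair(positions=(500,))
        df = mfe_windows(pair, window=41, positions=[100])
        assert df.loc[0, "delta_mfe"] == 0.0

    def test_short_transcript_flagged(self):
        pair, _, _ = simulate_allele_sequences(30, [15], seed=1)
        df = mfe_windows(pair, window=41)
        assert df.loc[0, "truncated"]
        assert (df.loc[0, "start"], df.loc[0, "end"]) == (1, 30)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            mfe_windows(self._pair(), window=40)

    def test_allele_swap_invariance_of_summary(self):
        pair = self._pair(positions=(100, 300, 450), seed=9)
        swapped = AlleleSequencePair(pair.gene_id, pair.seq_allele2,
                                     pair.seq_allele1, pair.variant_positions,
                                     pair.regions)
        a = max_abs_delta_mfe(mfe_windows(pair, window=21))
        b = max_abs_delta_mfe(mfe_windows(swapped, window=21))
        assert a == b


class TestCai:
    def test_boundary_cases(self):
        assert cai("GCUGCU", {"GCU": 1.0}) == pytest.approx(1.0)
        weights = {"GCU": 1.0, "CCU": 1.0, "GGU": 1.0}
        assert cai("GCUCCUGGU", weights) == pytest.approx(1.0)

    def test_geometric_mean_by_hand(self):
        assert cai("GCUGCG", {"GCU": 0.5, "GCG": 1.0}) == pytest.approx(
            np.sqrt(0.5))

    def test_synonymous_order_invariance(self):
        w = {"GCU": 0.3, "GCG": 0.9, "CCU": 0.6}
        assert cai("GCUGCGCCU", w) == pytest.approx(cai("CCUGCGGCU", w))

    def test_met_trp_and_stops_excluded(self):
        w = {"GCU": 0.5}
        assert cai("AUGGCUUGGUAA", w) == pytest.approx(0.5)

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            cai("GCUG", {"GCU": 1.0})


class TestCompareGroups:
    def test_identical_samples_ks(self):
        d, p = compare_groups([1, 2, 3, 4], [1, 2, 3, 4], test="KS_two_sided")
        assert d == 0.0 and p == 1.0

    def test_mwu_exact_enumeration(self):
        u, p = compare_groups([1, 2], [3, 4], test="MWU_two_sided")
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_location_shift_detected(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        for test in ("KS_two_sided", "MWU_two_sided"):
            assert compare_groups(a, b, test=test)[1] < 1e-3

    def test_rejects_tiny_samples(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])


class TestSiteDifference:
    def test_zero_differences_give_zero_median(self):
        df = pd.DataFrame({"gene_id": [f"g{i}" for i in range(10)],
                           "group": ["ASD"] * 5 + ["control"] * 5,
                           "stable_sites": 6, "unstable_sites": 6})
        out = site_difference_test(df, min_diff=0)
        assert out["median_asd"] == 0.0 and out["median_control"] == 0.0

    def test_planted_destabilising_sites_detected(self, rng):
        """Extra sites planted on the unstable allele drive the ASD group's
        stable-minus-unstable difference negative."""
        n = 100
        base = rng.poisson(8, size=2 * n) + 5
        rows = []
        for i in range(n):
            rows.append(("a%d" % i, "ASD", base[i], base[i] + rng.poisson(2) + 1))
            d = rng.choice([-1, 1]) * (rng.poisson(1) + 1)
            rows.append(("c%d" % i, "control", base[n + i] + max(d, 0),
                         base[n + i] + max(-d, 0)))
        df = pd.DataFrame(rows, columns=["gene_id", "group",
                                         "stable_sites", "unstable_sites"])
        out = site_difference_test(df)
        assert out["median_asd"] < 0
        assert out["p_mwu"] < 0.05

    def test_random_labels_are_symmetric(self, rng):
        n = 500
        diffs = rng.choice([-2, -1, 1, 2], size=n)
        df = pd.DataFrame({"gene_id": [f"c{i}" for i in range(n)],
                           "group": "control",
                           "stable_sites": 8 + np.maximum(diffs, 0),
                           "unstable_sites": 8 + np.maximum(-diffs, 0)})
        out = site_difference_test(df)
        assert out["sign_p_control"] > 0.01

    def test_small_groups_report_na(self, caplog):
        df = pd.DataFrame({"gene_id": ["g1", "g2"], "group": ["ASD", "control"],
                           "stable_sites": [10, 10], "unstable_sites": [5, 15]})
        out = site_difference_test(df)
        assert np.isnan(out["p_mwu"])


class TestMatchedControls:
    def test_pool_equal_to_targets_returns_permutation(self, rng):
        dens = pd.Series(rng.uniform(1, 10, size=50),
                         index=[f"g{i}" for i in range(50)])
        chosen = select_matched_controls(dens, dens.to_numpy(), seed=3)
        assert sorted(chosen) == sorted(dens.index)

    def test_seed_determinism(self, rng):
        pool = pd.Series(rng.uniform(0, 5, 300),
                         index=[f"c{i}" for i in range(300)])
        asd = rng.uniform(0, 5, 40)
        a = select_matched_controls(pool, asd, seed=7)
        b = select_matched_controls(pool, asd, seed=7)
        assert a == b

    def test_matched_distribution_passes_ks(self, rng):
        """On pools 10x the target size, the matched subset is statistically
        indistinguishable in density from the target in almost all runs."""
        ok = 0
        for seed in range(20):
            r = derive_rng(seed, "pool")
            asd = r.lognormal(1.0, 0.5, size=60)
            pool = pd.Series(r.lognormal(1.3, 0.7, size=600),
                             index=[f"c{i}" for i in range(600)])
            chosen = select_matched_controls(pool, asd, seed=seed)
            p = sps.ks_2samp(asd, pool.loc[chosen]).pvalue
            ok += p > 0.05
        assert ok >= 18  # >= 95% of runs, allowing one MC miss

    def test_strict_mode_raises_on_underfill(self, rng):
        pool = pd.Series([0.1, 0.2], index=["c1", "c2"])
        with pytest.raises(ValueError):
            select_matched_controls(pool, rng.uniform(5, 9, 30), seed=0,
                                    strict=True)
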