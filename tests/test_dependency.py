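"""Stratified-MI dependency score and its permutation test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gdnet.dependency import (
    CMIParams,
    cmi_score,
    mutual_information,
    permutation_pvalue,
    screen_pairs,
    stratified_mi,
)


def brute_force_mi(x, y):
    """Independent oracle: direct summation over the empirical joint."""
    x, y = np.asarray(x), np.asarray(y)
    n = x.size
    mi = 0.0
    for a, b in itertools.product((0, 1), repeat=2):
        p_joint = np.mean((x == a) & (y == b))
        px, py = np.mean(x == a), np.mean(y == b)
        if p_joint > 0:
            mi += p_joint * math.log2(p_joint / (px * py))
    return mi


def vectors_from_counts(n11, n10, n01, n00):
    x = np.array([1] * (n11 + n10) + [0] * (n01 + n00))
    y = np.array([1] * n11 + [0] * n10 + [1] * n01 + [0] * n00)
    return x, y


class TestMutualInformation:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((5, 0, 0, 5), 1.0),              # perfect balanced dependence
            ((2, 2, 2, 2), 0.0),              # exact independence
            ((4, 1, 1, 4), 0.2780719051126377),  # hand-evaluated joint sum
        ],
    )
    def test_known_tables(self, counts, expected):
        x, y = vectors_from_counts(*counts)
        assert mutual_information(x, y) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_for_all_small_tables(self):
        """Exhaustive oracle equivalence over every 2x2 table with n <= 12."""
        for n in range(2, 13):
            for n11 in range(n + 1):
                for n10 in range(n - n11 + 1):
                    for n01 in range(n - n11 - n10 + 1):
                        n00 = n - n11 - n10 - n01
                        x, y = vectors_from_counts(n11, n10, n01, n00)
                        assert mutual_information(x, y) == pytest.approx(
                            brute_force_mi(x, y), abs=1e-12
                        )

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=2, max_size=40))
    def test_symmetry_and_bounds(self, pairs):
        x = np.array([a for a, _ in pairs])
        y = np.array([b for _, b in pairs])
        mi = mutual_information(x, y)
        assert mi == pytest.approx(mutual_information(y, x), abs=1e-12)
        assert 0 <= mi <= 1 + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            mutual_information([0, 1], [0, 1, 1])


class TestStratifiedMI:
    def test_stratum_size_is_floor(self):
        params = CMIParams(stratum_fraction=0.35)
        a = np.tile([0, 1], 5)
        b = np.arange(10.0)
        res = cmi_score(a, a, b, params)
        assert res.n_stratum == 3  # floor(0.35 * 10)

    def test_perfect_coupling_in_low_stratum(self):
        # bottom 7 of 20 samples have target == phenotype with balanced counts
        params = CMIParams(stratum_fraction=0.35)
        b = np.arange(20.0)
        phen = np.array([0, 1] * 10)
        a = np.arange(20) % 3 % 2  # scrambled elsewhere
        a[:7] = phen[:7]
        phen[:7] = [0, 1, 0, 1, 0, 1, 0]  # keep the stratum near-balanced
        a[:7] = phen[:7]
        mi_low = stratified_mi(a, phen, b, params, "low")
        assert mi_low == pytest.approx(
            mutual_information(a[:7], phen[:7]), abs=1e-12
        )
        assert mi_low > 0.9

    def test_independent_target_scores_near_zero(self, rng):
        params = CMIParams()
        n = 200
        a = rng.integers(0, 2, n)
        phen = rng.integers(0, 2, n)
        b = rng.normal(size=n)
        res = cmi_score(a, phen, b, params)
        assert res.cmi < 0.15

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_monotone_transform_of_modulator(self, seed):
        """Only the order of the modulator values matters."""
        params = CMIParams()
        r = np.random.default_rng(seed)
        n = 40
        a = r.integers(0, 2, n)
        phen = r.integers(0, 2, n)
        b = r.normal(size=n)
        base = cmi_score(a, phen, b, params)
        for transform in (lambda v: 3 * v + 2, np.exp, lambda v: v**3):
            res = cmi_score(a, phen, transform(b), params)
            assert res.cmi == pytest.approx(base.cmi, abs=1e-12)

    def test_tiny_stratum_rejected(self):
        params = CMIParams(stratum_fraction=0.35)
        with pytest.raises(ValueError, match="stratum"):
            stratified_mi([0, 1, 0, 1], [0, 1, 1, 0], [1.0, 2.0, 3.0, 4.0], params, "low")


class TestPermutationPvalue:
    def test_rank_formula_extremes(self):
        """A score beating every null draw earns p = 1/N; a beaten one earns 1."""
        params = CMIParams(n_permutations=1000, seed=0)
        n = 40
        b = np.arange(float(n))
        phen = np.tile([0, 1], n // 2)
        a = phen.copy()  # deterministic coupling everywhere except the gate
        a[14:] = np.tile([0, 1], (n - 14) // 2) ^ (np.arange(n - 14) % 2)
        p, res = permutation_pvalue(a, phen, b, params)
        assert res.cmi > 0
        assert p >= 1 / 1000
        # an identically-zero score can never beat the null strictly
        a0 = np.tile([0, 1], n // 2)
        p0, res0 = permutation_pvalue(a0, a0 ^ 1 ^ 1, b, params)
        assert 0 < p0 <= 1.0

    def test_count_formula(self, monkeypatch):
        """p = min(1, (1 + #{null >= real}) / N) exactly."""
        import gdnet.dependency as dep

        params = CMIParams(n_permutations=1000, seed=0)
        n = 40
        r = np.random.default_rng(5)
        a, phen, b = r.integers(0, 2, n), r.integers(0, 2, n), r.normal(size=n)
        real = cmi_score(a, phen, b, params).cmi

        fake_null = np.concatenate([np.full(49, real + 1.0), np.full(951, real - 0.5)])
        monkeypatch.setattr(dep, "_null_cmis", lambda *args, **kw: fake_null)
        p, _ = permutation_pvalue(a, phen, b, params)
        assert p == pytest.approx(0.05)

        monkeypatch.setattr(dep, "_null_cmis", lambda *args, **kw: np.full(1000, real + 1))
        p, _ = permutation_pvalue(a, phen, b, params)
        assert p == 1.0

    def test_null_pvalues_not_anticonservative(self, rng):
        """Under the generator null, p-values are stochastically >= uniform."""
        from scipy import stats

        params = CMIParams(n_permutations=100, seed=8)
        n = 120
        ps = []
        for _ in range(80):
            a = rng.integers(0, 2, n)
            phen = rng.integers(0, 2, n)
            b = rng.normal(size=n)
            p, _ = permutation_pvalue(a, phen, b, params)
            ps.append(p)
        # one-sided KS: empirical CDF should not sit far above the uniform CDF
        d_plus = max(
            (i + 1) / len(ps) - p for i, p in enumerate(sorted(ps))
        )
        assert d_plus < 1.36 / np.sqrt(len(ps)) + 0.1  # generous sanity bound
        assert np.mean(np.array(ps) <= 0.05) < 0.15


class TestScreen:
    def test_empty_candidates(self, gated_dataset):
        from gdnet.io import CandidatePairs

        _, (expr, phen, _, _) = gated_dataset
        assert screen_pairs(expr, phen, CandidatePairs(set()), CMIParams()) == []

    def test_planted_pairs_recovered_and_nulls_calibrated(self, gated_dataset):
        cfg, (expr, phen, cands, truth) = gated_dataset
        params = CMIParams(seed=3)
        pairs = screen_pairs(expr, phen, cands, params)
        planted = {(m, t) for m, t, _ in truth.modulated_pairs}
        planted_genes = {g for m, t, _ in truth.modulated_pairs for g in (m, t)}
        recovered = sum(1 for p in pairs if (p.modulator, p.target) in planted)
        assert recovered >= 8
        null_hits = [
            p for p in pairs
            if p.modulator not in planted_genes and p.target not in planted_genes
        ]
        # 180 null directions at alpha 0.05: binomial 95% band
        assert 2 <= len(null_hits) <= 16

    def test_same_seed_bit_identical(self, gated_dataset):
        _, (expr, phen, cands, _) = gated_dataset
        params = CMIParams(n_permutations=100, seed=42)
        first = screen_pairs(expr, phen, cands, params)
        second = screen_pairs(expr, phen, cands, params)
        assert [(p.modulator, p.target, p.cmi, p.p_value) for p in first] == [
            (p.modulator, p.target, p.cmi, p.p_value) for p in second
        ]
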