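"""Unit and property tests for the allele-level drive machinery."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdclvr import (
    Architecture,
    ClvrTargetAllele,
    DriveParams,
    Genotype,
    HomingAllele,
    ViabilityMode,
    cleave_rescue_transition_prob,
    daisy_inheritance,
    drive_active,
    female_is_fertile,
    germline_clvr_cleavage,
    germline_homing,
    make_gametes,
    offspring_sex,
    offspring_viability,
)
from hdclvr.genetics import transmit_clvr_batch, transmit_homing_batch


def enumerate_cleavage_outcome(i, P_c, P_f, P_b):
    """Independent oracle: enumerate per-site cut patterns of an i-site
    target gene; a gene with k cuts stays functional iff every repair is in
    frame and every one of the k-1 intervening blocks is retained.

    Returns (dict j -> P(functional with j intact sites), P(non-functional)).
    """
    probs = {}
    for pattern in itertools.product([0, 1], repeat=i):
        k = sum(pattern)
        p_pattern = (P_c**k) * ((1 - P_c) ** (i - k))
        p_keep = ((1 - P_f) ** k) * (P_b ** max(k - 1, 0))
        probs[i - k] = probs.get(i - k, 0.0) + p_pattern * p_keep
    return probs, 1.0 - sum(probs.values())


class TestCleaveRescueTransition:
    @pytest.mark.parametrize(
        "i,j,expected",
        [
            (1, 1, 0.05),  # single uncut site
            (0, 0, 1.0),  # no sites, nothing can change
            (2, 0, 0.0200155),  # both cut in frame, one block retained
        ],
    )
    def test_default_values(self, i, j, expected):
        params = DriveParams(architecture=Architecture.HOMING_CLVR)
        assert cleave_rescue_transition_prob(i, j, params) == pytest.approx(
            expected, rel=1e-4
        )

    def test_no_cutting_is_identity(self):
        params = DriveParams(architecture=Architecture.HOMING_CLVR, P_c=0.0)
        for i in range(5):
            assert cleave_rescue_transition_prob(i, i, params) == 1.0
            for j in range(i):
                assert cleave_rescue_transition_prob(i, j, params) == 0.0

    @pytest.mark.parametrize("i,j", [(1, 2), (-1, 0), (2, -1), (5, 3)])
    def test_invalid_arguments(self, i, j):
        params = DriveParams(architecture=Architecture.HOMING_CLVR, n_grnas_clvr=4)
        with pytest.raises(ValueError):
            cleave_rescue_transition_prob(i, j, params)

    def test_matches_enumeration_oracle(self):
        params = DriveParams(architecture=Architecture.HOMING_CLVR, n_grnas_clvr=8)
        for i in range(9):
            oracle, residual = enumerate_cleavage_outcome(
                i, params.P_c, params.P_f, params.P_b
            )
            for j in range(i + 1):
                assert cleave_rescue_transition_prob(i, j, params) == pytest.approx(
                    oracle[j], abs=1e-12
                )
            total = sum(
                cleave_rescue_transition_prob(i, j, params) for j in range(i + 1)
            )
            assert 1.0 - total == pytest.approx(residual, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        i=st.integers(0, 8),
        P_c=st.floats(0, 1),
        P_f=st.floats(0, 1),
        P_b=st.floats(0, 1),
    )
    def test_normalization(self, i, P_c, P_f, P_b):
        params = DriveParams(
            architecture=Architecture.HOMING_CLVR,
            n_grnas_clvr=8,
            P_c=P_c,
            P_f=P_f,
            P_b=P_b,
        )
        total = sum(cleave_rescue_transition_prob(i, j, params) for j in range(i + 1))
        assert total <= 1.0 + 1e-12
        assert 0.0 <= 1.0 - total + 1e-12

    def test_matches_monte_carlo_per_site_oracle(self, rng):
        """Direct per-site simulation of cut/repair/block outcomes agrees
        with every P_4j (and the residual) within 3 s.e. at 10^6 draws."""
        params = DriveParams(architecture=Architecture.HOMING_CLVR, n_grnas_clvr=4)
        n = 1_000_000
        cut = rng.random((n, 4)) < params.P_c
        k = cut.sum(axis=1)
        inframe_all = rng.random((n, 4)) < (1 - params.P_f)
        inframe = (inframe_all | ~cut).all(axis=1)
        blocks_kept = rng.random(n) < params.P_b ** np.maximum(k - 1, 0)
        functional = inframe & blocks_kept
        for j in range(5):
            p_hat = np.mean(functional & (k == 4 - j))
            p = cleave_rescue_transition_prob(4, j, params)
            se = math.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(p_hat - p) < 3 * se + 1e-9
        residual = 1 - sum(
            cleave_rescue_transition_prob(4, j, params) for j in range(5)
        )
        assert residual == pytest.approx(0.9992019, abs=1e-6)
        se = math.sqrt(residual * (1 - residual) / n)
        assert abs(np.mean(~functional) - residual) < 3 * se + 1e-9


class TestClvrCleavage:
    def test_inactive_identity(self, hdclvr_params, rng):
        allele = ClvrTargetAllele.wild(4)
        assert germline_clvr_cleavage(allele, False, hdclvr_params, rng) == allele

    def test_nonfunctional_is_absorbing(self, hdclvr_params, rng):
        broken = ClvrTargetAllele.broken()
        for _ in range(50):
            broken = germline_clvr_cleavage(broken, True, hdclvr_params, rng)
            assert not broken.gene_functional

    def test_active_destruction_rate(self, hdclvr_params, rng):
        """With 4 multiplexed gRNAs nearly every cleaved target gene loses
        function (enumeration oracle gives 0.9992 at default parameters)."""
        allele = ClvrTargetAllele.wild(4)
        n = 20_000
        dead = sum(
            not germline_clvr_cleavage(allele, True, hdclvr_params, rng).gene_functional
            for _ in range(n)
        )
        p = 0.9992019
        assert abs(dead / n - p) < 3 * math.sqrt(p * (1 - p) / n) + 1e-4


class TestGermlineHoming:
    def _het(self, params, daisies=0):
        return Genotype(
            homing=(HomingAllele.drive(params.n_grnas_homing),
                    HomingAllele.wild(params.n_grnas_homing)),
            clvr=(ClvrTargetAllele.broken(), ClvrTargetAllele.wild(params.n_grnas_clvr)),
            daisies=daisies,
            sex="female",
        )

    def test_conversion_rate_without_nhej(self, rng):
        params = DriveParams(architecture=Architecture.HOMING, P_n=0.0, n_grnas_homing=1)
        het = self._het(params)
        n = 20_000
        converted = 0
        for _ in range(n):
            a, b = germline_homing(het, params, rng)
            converted += a.is_drive and b.is_drive
        # conversion probability is P_c = 0.95; drive-gamete share 0.975
        assert abs(converted / n - 0.95) < 3 * math.sqrt(0.95 * 0.05 / n)

    def test_nhej_functional_resistance_rate(self, rng):
        """With NHEJ certain, one in three resistance alleles stays in frame."""
        params = DriveParams(architecture=Architecture.HOMING, P_n=1.0, n_grnas_homing=1)
        het = self._het(params)
        n = 20_000
        functional = 0
        cut = 0
        for _ in range(n):
            a, b = germline_homing(het, params, rng)
            assert not b.is_drive  # never converts
            if b.n_intact == 0:
                cut += 1
                functional += b.gene_functional
        frac = functional / cut
        assert abs(frac - (1 - 0.667)) < 3 * math.sqrt(0.333 * 0.667 / cut)

    def test_no_daisy_no_drive(self, hdclvr_params, rng):
        het = self._het(hdclvr_params, daisies=0)
        assert not drive_active(het, hdclvr_params)
        assert germline_homing(het, hdclvr_params, rng) == het.homing

    def test_drive_alleles_never_revert(self, homing_clvr_params, rng):
        het = self._het(homing_clvr_params)
        for _ in range(200):
            a, b = germline_homing(het, homing_clvr_params, rng)
            assert a.is_drive or b.is_drive


class TestDaisyInheritance:
    def test_no_daisies(self, rng):
        assert daisy_inheritance(0, 0, rng) == 0

    def test_halving_from_single_parent(self, rng):
        draws = [daisy_inheritance(60, 0, rng) for _ in range(20_000)]
        se = math.sqrt(60 * 0.25 / len(draws))
        assert abs(np.mean(draws) - 30.0) < 3 * se

    def test_two_parent_moments_and_support(self, rng):
        draws = np.array([daisy_inheritance(4, 6, rng) for _ in range(20_000)])
        assert draws.min() >= 0 and draws.max() <= 10
        se = math.sqrt(10 * 0.25 / draws.size)
        assert abs(draws.mean() - 5.0) < 3 * se

    def test_repeated_outcross_halves_mean(self, hdclvr_params, rng):
        """E[daisies] after t outcross generations is H / 2^t."""
        H, t, n = 60, 3, 4000
        counts = np.full(n, H)
        for _ in range(t):
            counts = rng.binomial(counts, 0.5)  # wildtype mate contributes none
        expected = H / 2**t
        assert abs(counts.mean() - expected) < 4 * math.sqrt(expected / n) + 0.2

    def test_negative_counts_rejected(self, rng):
        with pytest.raises(ValueError):
            daisy_inheritance(-1, 0, rng)


class TestSexAndViability:
    def test_sex_ratio_unskewed(self, hdclvr_params, rng):
        father = Genotype.wildtype(hdclvr_params, sex="male")
        males = sum(
            offspring_sex(father, hdclvr_params, rng) == "male" for _ in range(10_000)
        )
        assert abs(males / 10_000 - 0.5) < 3 * math.sqrt(0.25 / 10_000)

    def test_driving_y_full_skew(self, rng):
        params = DriveParams(
            architecture=Architecture.DRIVING_Y, driving_y_skew=1.0, daisyfield_size=0
        )
        father = Genotype(
            homing=(HomingAllele.wild(1), HomingAllele.wild(1)),
            clvr=(ClvrTargetAllele.wild(4), ClvrTargetAllele.wild(4)),
            driving_y=True,
            sex="male",
        )
        assert all(
            offspring_sex(father, params, rng) == "male" for _ in range(200)
        )

    def test_driving_y_partial_skew(self, rng):
        params = DriveParams(
            architecture=Architecture.DRIVING_Y, driving_y_skew=0.9, daisyfield_size=0
        )
        father = Genotype(
            homing=(HomingAllele.wild(1), HomingAllele.wild(1)),
            clvr=(ClvrTargetAllele.wild(4), ClvrTargetAllele.wild(4)),
            driving_y=True,
            sex="male",
        )
        n = 20_000
        males = sum(offspring_sex(father, params, rng) == "male" for _ in range(n))
        assert abs(males / n - 0.9) < 3 * math.sqrt(0.09 / n)

    def test_wildtype_viable(self, homing_clvr_params):
        g = Genotype.wildtype(homing_clvr_params)
        assert offspring_viability(g, homing_clvr_params)

    def test_resistance_without_rescue_is_lethal(self, homing_clvr_params):
        g = Genotype(
            homing=(HomingAllele("wild", (False,), False), HomingAllele.wild(1)),
            clvr=(ClvrTargetAllele.broken(), ClvrTargetAllele.broken()),
        )
        assert not offspring_viability(g, homing_clvr_params)

    def test_overexpression_mode(self, homing_clvr_params):
        three_copies = Genotype(
            homing=(HomingAllele.drive(1), HomingAllele.wild(1)),
            clvr=(ClvrTargetAllele.wild(4), ClvrTargetAllele.wild(4)),
        )
        assert not offspring_viability(three_copies, homing_clvr_params)
        tolerant = DriveParams(
            architecture=Architecture.HOMING_CLVR,
            viability_mode=ViabilityMode.AT_LEAST_TWO_COPIES,
        )
        assert offspring_viability(three_copies, tolerant)

    def test_female_fertility_haplosufficiency(self):
        wild, drive = HomingAllele.wild(1), HomingAllele.drive(1)
        broken = HomingAllele("wild", (False,), False)
        clvr = (ClvrTargetAllele.wild(4), ClvrTargetAllele.wild(4))
        assert female_is_fertile(Genotype(homing=(drive, wild), clvr=clvr))
        assert not female_is_fertile(Genotype(homing=(drive, drive), clvr=clvr))
        assert not female_is_fertile(Genotype(homing=(drive, broken), clvr=clvr))


class TestMakeGametes:
    def test_wildtype_cross_is_trivial(self, homing_clvr_params, rng):
        mother = Genotype.wildtype(homing_clvr_params, "female")
        father = Genotype.wildtype(homing_clvr_params, "male")
        child = make_gametes(mother, father, homing_clvr_params, rng)
        assert child.daisies == 0
        assert all(not a.is_drive and a.gene_functional for a in child.homing)
        assert all(a.gene_functional for a in child.clvr)

    def test_daisyless_parent_is_mendelian(self, hdclvr_params):
        """With zero daisy elements the gamete draw is identical (same seed)
        to a plain Mendelian-inheritance oracle."""
        mother = Genotype(
            homing=(HomingAllele.drive(1), HomingAllele.wild(1)),
            clvr=(ClvrTargetAllele.broken(), ClvrTargetAllele.wild(4)),
            daisies=0,
            sex="female",
        )
        father = Genotype.wildtype(hdclvr_params, "male")
        seed = 777
        child = make_gametes(
            mother, father, hdclvr_params, np.random.default_rng(seed)
        )
        oracle = np.random.default_rng(seed)
        h = (mother.homing[oracle.integers(2)], father.homing[oracle.integers(2)])
        c = (mother.clvr[oracle.integers(2)], father.clvr[oracle.integers(2)])
        d = oracle.binomial(0, 0.5) + oracle.binomial(0, 0.5)
        sex = "male" if oracle.random() < 0.5 else "female"
        assert child.homing == h
        assert child.clvr == c
        assert child.daisies == d
        assert child.sex == sex

    def test_scalar_and_batch_paths_agree_in_distribution(self, hdclvr_params):
        """The scalar reference and the vectorised engine give the same
        gamete distributions for an active drive heterozygote."""
        params = hdclvr_params
        mother = Genotype(
            homing=(HomingAllele.drive(1), HomingAllele.wild(1)),
            clvr=(ClvrTargetAllele.broken(), ClvrTargetAllele.wild(4)),
            daisies=30,
            sex="female",
        )
        rng = np.random.default_rng(3)
        n_scalar = 6000
        scalar = [germline_homing(mother, params, rng) for _ in range(n_scalar)]
        picks = rng.integers(0, 2, n_scalar)
        scalar_drive = np.mean([pair[p].is_drive for pair, p in zip(scalar, picks)])

        n_batch = 60_000
        kind2 = np.tile(np.array([[1, 0]], dtype=np.int16), (n_batch, 1))
        intact2 = np.tile(np.array([[0, 1]], dtype=np.int16), (n_batch, 1))
        func2 = np.tile(np.array([[False, True]]), (n_batch, 1))
        active = np.ones(n_batch, dtype=bool)
        bk, _, _ = transmit_homing_batch(
            kind2, intact2, func2, active, params, np.random.default_rng(4)
        )
        batch_drive = np.mean(bk == 1)
        se = math.sqrt(0.97 * 0.03 / n_scalar)
        assert abs(scalar_drive - batch_drive) < 4 * se

        # cleave-and-rescue gamete: fraction still functional
        scalar_func = np.mean(
            [
                germline_clvr_cleavage(
                    ClvrTargetAllele.wild(4), True, params, rng
                ).gene_functional
                for _ in range(n_scalar)
            ]
        )
        ci = np.tile(np.array([[4, 4]], dtype=np.int16), (n_batch, 1))
        cf = np.ones((n_batch, 2), dtype=bool)
        _, bf = transmit_clvr_batch(ci, cf, active, params, np.random.default_rng(5))
        se = math.sqrt(0.01 / n_scalar)
        assert abs(scalar_func - np.mean(bf)) < 4 * se + 1e-4
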