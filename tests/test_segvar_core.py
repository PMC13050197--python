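import numpy as np
import pytest

from tetrasegvar import (
    DosageGenotype,
    GeneticMap,
    MarkerEffects,
    PhasedParent,
    build_cov_blocks,
    cov_brute_force,
    cov_double_reduction,
    cov_phased,
    haldane,
    haldane_inverse,
    predict_cross,
    segregation_variance,
    var_locus,
)

from conftest import all_two_locus_phasings, random_parent


class TestHaldane:
    def test_zero_distance(self):
        assert haldane(0.0) == 0.0

    def test_asymptote(self):
        assert haldane(50.0) == pytest.approx(0.5, abs=1e-12)

    def test_closed_form_value(self):
        assert haldane(0.5) == pytest.approx(0.5 * (1 - np.exp(-1.0)))

    def test_monotone(self):
        d = np.linspace(0, 5, 100)
        assert np.all(np.diff(haldane(d)) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            haldane(-0.1)

    def test_inverse_roundtrip(self):
        d = np.array([0.0, 0.05, 0.3, 2.0])
        assert np.allclose(haldane_inverse(haldane(d)), d)


class TestCovPhased:
    def test_zero_at_c_half(self, rng):
        for _ in range(50):
            p1, p2 = random_parent(rng, "a"), random_parent(rng, "b")
            assert cov_phased(p1, p2, 0, 1, 0.5) == 0.0

    def test_coupling_duplex_value(self, duplex_coupling, nulliplex):
        assert cov_phased(
            duplex_coupling, nulliplex, 0, 1, 0.0
        ) == pytest.approx(1 / 3)

    def test_balanced_phase_zero_for_all_c(self, balanced_duplex):
        for c in (0.0, 0.1, 0.3, 0.5):
            assert cov_phased(
                balanced_duplex, balanced_duplex, 0, 1, c
            ) == pytest.approx(0.0, abs=1e-15)

    def test_magnitude_non_increasing_in_c(self, rng):
        p1, p2 = random_parent(rng, "a"), random_parent(rng, "b")
        vals = [abs(cov_phased(p1, p2, 0, 1, c)) for c in np.linspace(0, 0.5, 11)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_matches_brute_force_exhaustively(self):
        """Oracle equivalence over all 2^8 x 2^8 phasings and a c grid.

        Gametes of the two parents are independent, so the brute-force
        covariance decomposes as covg(P1) + covg(P2); verifying the literal
        1,296-row enumeration on a subsample and the decomposition on all
        pairs covers the full cross product.
        """
        from tetrasegvar.gamete_engine import enumerate_gametes

        phasings = all_two_locus_phasings()
        cs = np.arange(0.0, 0.501, 0.05)
        covg = np.empty((256, len(cs)))
        f = np.empty(256)
        for i, hap in enumerate(phasings):
            par = PhasedParent("p", hap)
            a, b = hap[:, 0].astype(float), hap[:, 1].astype(float)
            f[i] = (a * b).sum() / 3 - a.sum() * b.sum() / 12
            for k, c in enumerate(cs):
                g = enumerate_gametes(par, 0, 1, float(c))
                covg[i, k] = g.probabilities @ (
                    g.allele_a * g.allele_b
                ) - (g.probabilities @ g.allele_a) * (
                    g.probabilities @ g.allele_b
                )
        # all 256 x 256 pairs at once per c
        for k, c in enumerate(cs):
            brute = covg[:, k][:, None] + covg[:, k][None, :]
            closed = (f[:, None] + f[None, :]) * (1 - 2 * c)
            assert np.max(np.abs(brute - closed)) <= 1e-12
        # literal 1,296-row brute force equals the decomposition
        rng = np.random.default_rng(3)
        for _ in range(40):
            i, j = rng.integers(0, 256, 2)
            c = float(rng.choice(cs))
            k = int(np.argmin(np.abs(cs - c)))
            p1 = PhasedParent("a", phasings[i])
            p2 = PhasedParent("b", phasings[j])
            assert cov_brute_force(p1, p2, 0, 1, c) == pytest.approx(
                covg[i, k] + covg[j, k], abs=1e-12
            )


class TestVarLocus:
    @pytest.mark.parametrize(
        "x1, x2, expected",
        [(0, 0, 0.0), (4, 4, 0.0), (2, 2, 2 / 3), (1, 0, 1 / 4)],
    )
    def test_values(self, x1, x2, expected):
        assert var_locus(x1, x2) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            var_locus(5, 0)

    def test_equals_cov_phased_same_locus_all_phasings(self):
        """Diagonal formula == bracket formula at B=A, c=0 for every
        phasing consistent with each dosage pair."""
        singles = [
            np.array([(code >> h) & 1 for h in range(4)]).reshape(4, 1)
            for code in range(16)
        ]
        for h1 in singles:
            for h2 in singles:
                p1 = PhasedParent("a", h1)
                p2 = PhasedParent("b", h2)
                expected = var_locus(int(h1.sum()), int(h2.sum()))
                assert cov_phased(p1, p2, 0, 0, 0.0) == pytest.approx(
                    expected, abs=1e-14
                )


class TestDoubleReduction:
    def test_alpha_zero_c_zero_equals_phased(self, duplex_coupling, nulliplex):
        assert cov_double_reduction(
            duplex_coupling, nulliplex, 0, 1, 0.0, 0.0
        ) == pytest.approx(cov_phased(duplex_coupling, nulliplex, 0, 1, 0.0))

    def test_increasing_in_alpha_for_positive_bracket(
        self, duplex_coupling, nulliplex
    ):
        vals = [
            cov_double_reduction(duplex_coupling, nulliplex, 0, 1, 0.1, a)
            for a in (0.0, 0.05, 0.1, 1 / 6)
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_attenuation_differs_from_bivalent_model(
        self, duplex_coupling, nulliplex
    ):
        # at alpha=0, c=0.25 the quadrivalent factor is 2/3 vs 1/2
        bracket = cov_phased(duplex_coupling, nulliplex, 0, 1, 0.0)
        dr = cov_double_reduction(duplex_coupling, nulliplex, 0, 1, 0.25, 0.0)
        assert dr == pytest.approx(bracket * (1 - 1 / 3))
        assert cov_phased(
            duplex_coupling, nulliplex, 0, 1, 0.25
        ) == pytest.approx(bracket * 0.5)

    def test_alpha_out_of_range(self, duplex_coupling, nulliplex):
        with pytest.raises(ValueError):
            cov_double_reduction(duplex_coupling, nulliplex, 0, 1, 0.1, 0.2)


class TestCovBlocks:
    def _parents(self, rng, p=5):
        return random_parent(rng, "a", p), random_parent(rng, "b", p)

    def test_unphased_blocks_diagonal(self, rng, two_chrom_map):
        p1, p2 = self._parents(rng)
        blocks = build_cov_blocks(p1, p2, two_chrom_map, mode="unphased")
        assert len(blocks) == 2
        for blk in blocks:
            off = blk.matrix - np.diag(np.diag(blk.matrix))
            assert np.all(off == 0)

    def test_single_marker_chromosome_is_var_locus(self, rng):
        gm = GeneticMap(["m"], ["1"], [0.0])
        p1, p2 = self._parents(rng, 1)
        blk = build_cov_blocks(p1, p2, gm, mode="phased")[0]
        x1, x2 = int(p1.dosages()[0]), int(p2.dosages()[0])
        assert blk.matrix[0, 0] == pytest.approx(var_locus(x1, x2))

    def test_colocated_markers_get_bare_bracket(self, rng):
        gm = GeneticMap(["a", "b"], ["1", "1"], [0.3, 0.3])
        p1, p2 = self._parents(rng, 2)
        blk = build_cov_blocks(p1, p2, gm, mode="phased")[0]
        assert blk.matrix[0, 1] == pytest.approx(
            cov_phased(p1, p2, 0, 1, 0.0)
        )

    def test_phased_block_matches_pairwise_closed_form(self, rng, two_chrom_map):
        p1, p2 = self._parents(rng)
        blocks = build_cov_blocks(p1, p2, two_chrom_map, mode="phased")
        pos = two_chrom_map.positions
        for blk in blocks:
            for ii, gi in enumerate(blk.marker_index):
                for jj, gj in enumerate(blk.marker_index):
                    c = haldane(abs(pos[gi] - pos[gj]))
                    assert blk.matrix[ii, jj] == pytest.approx(
                        cov_phased(p1, p2, gi, gj, c), abs=1e-12
                    )

    def test_diagonal_equals_var_locus_in_all_modes(self, rng, two_chrom_map):
        p1, p2 = self._parents(rng)
        x1, x2 = p1.dosages(), p2.dosages()
        for mode, alpha in (("phased", None), ("unphased", None),
                            ("double_reduction", 0.1)):
            blocks = build_cov_blocks(p1, p2, two_chrom_map, mode=mode,
                                      alpha=alpha)
            for blk in blocks:
                for ii, gi in enumerate(blk.marker_index):
                    assert blk.matrix[ii, ii] == pytest.approx(
                        var_locus(int(x1[gi]), int(x2[gi]))
                    )

    def test_phased_mode_rejects_dosage_input(self, rng, two_chrom_map):
        p1 = DosageGenotype("a", rng.integers(0, 5, 5))
        p2 = DosageGenotype("b", rng.integers(0, 5, 5))
        with pytest.raises(TypeError):
            build_cov_blocks(p1, p2, two_chrom_map, mode="phased")


class TestSegregationVariance:
    def test_zero_effects_zero_variance(self, rng, two_chrom_map):
        p1, p2 = random_parent(rng, "a", 5), random_parent(rng, "b", 5)
        blocks = build_cov_blocks(p1, p2, two_chrom_map)
        assert segregation_variance(blocks, MarkerEffects(np.zeros(5))) == 0.0

    def test_single_qtl_duplex(self, duplex_coupling):
        gm = GeneticMap(["m"], ["1"], [0.0])
        p = duplex_coupling.subset(np.array([0]))
        blocks = build_cov_blocks(p, p, gm)
        beta = 1.7
        assert segregation_variance(
            blocks, MarkerEffects(np.array([beta]))
        ) == pytest.approx(beta**2 * 2 / 3)

    def test_unphased_equals_effect_weighted_var_sum(self, rng, two_chrom_map):
        p1, p2 = random_parent(rng, "a", 5), random_parent(rng, "b", 5)
        beta = rng.normal(size=5)
        blocks = build_cov_blocks(p1, p2, two_chrom_map, mode="unphased")
        expected = sum(
            beta[i] ** 2 * var_locus(int(p1.dosages()[i]), int(p2.dosages()[i]))
            for i in range(5)
        )
        assert segregation_variance(
            blocks, MarkerEffects(beta)
        ) == pytest.approx(expected)

    def test_nonnegative_on_random_inputs(self, rng, two_chrom_map):
        for _ in range(50):
            p1, p2 = random_parent(rng, "a", 5), random_parent(rng, "b", 5)
            beta = rng.normal(size=5)
            blocks = build_cov_blocks(p1, p2, two_chrom_map)
            assert segregation_variance(blocks, MarkerEffects(beta)) >= 0.0


class TestPredictCross:
    def test_monomorphic_genome_all_zero(self, two_chrom_map):
        p = PhasedParent("p", np.zeros((4, 5), dtype=int))
        pred = predict_cross(p, p, two_chrom_map, MarkerEffects(np.ones(5)))
        assert pred.sigma2_phased == 0.0
        assert pred.sigma2_unphased == 0.0

    def test_balanced_phase_phased_equals_unphased(self, rng):
        # both parents AB/Ab/aB/ab at every adjacent pair: brackets vanish
        hap = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        gm = GeneticMap(["a", "b"], ["1", "1"], [0.0, 0.1])
        p = PhasedParent("p", hap)
        pred = predict_cross(p, p, gm, MarkerEffects(np.ones(2)))
        assert pred.sigma2_phased == pytest.approx(pred.sigma2_unphased)

    def test_coupling_ld_inflates_phased_variance(self, duplex_coupling):
        gm = GeneticMap(["a", "b"], ["1", "1"], [0.0, 0.05])
        pred = predict_cross(
            duplex_coupling, duplex_coupling, gm, MarkerEffects(np.ones(2))
        )
        assert pred.sigma2_phased > pred.sigma2_unphased
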