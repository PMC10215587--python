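"""Generator contracts: transmission, determinism, moment structure."""

import numpy as np
import pytest

from gamcross.grm import build_centered_matrix, build_gametic_matrix, origin_gametes
from gamcross.simulate import (
    MISSING,
    CrossDesign,
    corrupt_genotypes,
    make_phasing_scenarios,
    simulate_cross,
    simulate_founders,
    simulate_gametic_effects,
    simulate_phenotypes,
)


class TestFounders:
    def test_degenerate_maf_range_pins_frequencies(self):
        fE, fR = simulate_founders(2, 2, 4, 0.5, 0.5, seed=0)
        assert np.all(fE.q == 0.5) and np.all(fR.q == 0.5)

    def test_sample_frequencies_within_binomial_error(self):
        fE, fR = simulate_founders(100, 100, 1000, 0.05, 0.5, seed=1)
        for pop in (fE, fR):
            emp = pop.genotypes.mean(axis=0) / 2
            se = np.sqrt(pop.q * (1 - pop.q) / (2 * pop.n_individuals))
            # 4-sigma bound per locus, allow a tiny tail across 1000 loci
            assert np.mean(np.abs(emp - pop.q) > 4 * se) < 0.005

    def test_determinism(self):
        a = simulate_founders(5, 5, 50, 0.1, 0.4, seed=9)
        b = simulate_founders(5, 5, 50, 0.1, 0.4, seed=9)
        assert np.array_equal(a[0].haplotypes, b[0].haplotypes)
        assert np.array_equal(a[1].q, b[1].q)

    @pytest.mark.parametrize("bounds", [(0.0, 0.3), (0.4, 0.3), (0.1, 0.6)])
    def test_invalid_maf_bounds(self, bounds):
        with pytest.raises(ValueError):
            simulate_founders(2, 2, 10, *bounds, seed=0)

    def test_genotype_is_haplotype_sum(self):
        fE, _ = simulate_founders(10, 2, 60, seed=3)
        assert np.array_equal(fE.genotypes, fE.haplotypes.sum(axis=1))


class TestCross:
    def test_allele_conservation(self, small_dataset):
        """Every transmitted allele exists in the parent at that locus."""
        gametes = small_dataset["gametes"]
        ped = small_dataset["pedigree"]
        fE, fR = small_dataset["founders"]
        hap_of = {i: h for pop in (fE, fR) for i, h in zip(pop.ids, pop.haplotypes)}
        for i in range(0, gametes.n_sows, 7):
            sire_h = hap_of[ped.iloc[i]["sire"]]
            ok = (gametes.paternal[i] == sire_h[0]) | (gametes.paternal[i] == sire_h[1])
            assert ok.all()

    def test_homozygous_sire_transmits_exact_haplotype(self):
        fE, fR = simulate_founders(3, 3, 40, seed=5)
        fE.haplotypes[:] = fE.haplotypes[:, :1, :]  # force homozygosity
        design = CrossDesign(
            n_sires_E=3, n_dams_E=3, n_sires_R=3, n_dams_R=3, n_er_sows=6, n_re_sows=0
        )
        gametes, ped = simulate_cross(fE, fR, design, seed=6)
        sire_hap = {i: h[0] for i, h in zip(fE.ids, fE.haplotypes)}
        for k in range(6):
            assert np.array_equal(gametes.paternal[k], sire_hap[ped.iloc[k]["sire"]])

    def test_cross_origin_labels(self, small_dataset):
        g = small_dataset["gametes"]
        er = g.cross == "ER"
        assert set(g.origin_of("paternal")[er]) == {"E"}
        assert set(g.origin_of("maternal")[er]) == {"R"}
        assert set(g.origin_of("paternal")[~er]) == {"R"}

    def test_infeasible_design_raises(self):
        fE, fR = simulate_founders(3, 3, 10, seed=0)
        design = CrossDesign(
            n_sires_E=10, n_dams_E=3, n_sires_R=3, n_dams_R=3, n_er_sows=5, n_re_sows=5
        )
        with pytest.raises(ValueError, match="founders"):
            simulate_cross(fE, fR, design, seed=0)


class TestGameticEffects:
    def test_independent_case_uncorrelated(self, rng):
        V = np.diag([0.3, 0.3])
        eff = simulate_gametic_effects(np.eye(2000), np.eye(10), V, V, seed=rng)
        r = np.corrcoef(eff.U_E[:, 0], eff.U_E[:, 1])[0, 1]
        assert abs(r) < 0.08

    def test_correlation_one_makes_roles_identical(self):
        V = np.array([[0.2, 0.2], [0.2, 0.2]])
        eff = simulate_gametic_effects(np.eye(50), np.eye(5), V, V, seed=0)
        assert np.allclose(eff.U_E[:, 0], eff.U_E[:, 1], atol=1e-8)

    def test_empirical_covariance_matches_kron_blocks(self, small_dataset):
        """Sample covariance over replicates converges to V (x) G."""
        G = small_dataset["grm"]["E"].values[:20, :20]
        V = np.array([[0.4, 0.1], [0.1, 0.25]])
        rng = np.random.default_rng(11)
        n_rep = 600
        draws = np.empty((n_rep, 20, 2))
        for k in range(n_rep):
            draws[k] = simulate_gametic_effects(G, np.eye(2), V, V, seed=rng).U_E
        for a, b, v in ((0, 0, V[0, 0]), (1, 1, V[1, 1]), (0, 1, V[0, 1])):
            emp = np.einsum("ki,kj->ij", draws[:, :, a], draws[:, :, b]) / n_rep
            target = v * G
            se = np.sqrt((V[a, a] * V[b, b] * np.outer(np.diag(G), np.diag(G))
                          + (v * G) ** 2) / n_rep)
            assert np.mean(np.abs(emp - target) > 3 * se) < 0.02

    def test_non_psd_covariance_rejected(self):
        V_bad = np.array([[0.1, 0.5], [0.5, 0.1]])
        with pytest.raises(ValueError, match="semi-definite"):
            simulate_gametic_effects(np.eye(4), np.eye(4), V_bad, np.eye(2), seed=0)


class TestPhenotypes:
    def test_null_model_gives_zero_phenotypes(self, small_dataset):
        from conftest import table4_params

        params = table4_params()
        for tp in (params.tnb, params.nba):
            tp.V_E = np.zeros((2, 2))
            tp.V_R = np.zeros((2, 2))
            tp.sigma2_s_er = tp.sigma2_s_re = tp.sigma2_e_er = tp.sigma2_e_re = 0.0
            tp.mean_er = tp.mean_re = 0.0
            tp.parity_sd = tp.hys_sd = 0.0
        g = small_dataset["gametes"]
        effects = {
            t: type(small_dataset["effects"]["tnb"])(
                U_E=np.zeros_like(small_dataset["effects"]["tnb"].U_E),
                U_R=np.zeros_like(small_dataset["effects"]["tnb"].U_R),
            )
            for t in ("tnb", "nba")
        }
        ph, _ = simulate_phenotypes(g, effects, params, CrossDesign(), seed=1)
        assert np.allclose(ph["tnb"], 0) and np.allclose(ph["nba"], 0)

    def test_variance_decomposition(self):
        """Empirical phenotypic variance ~ s2_s + s2_p + s2_m + s2_e per cross."""
        from conftest import table4_params

        from gamcross.simulate import simulate_dataset

        design = CrossDesign(
            n_sires_E=60, n_dams_E=60, n_sires_R=60, n_dams_R=60,
            n_er_sows=220, n_re_sows=220, n_hys=1,
        )
        params = table4_params()
        for tp in (params.tnb, params.nba):
            tp.parity_sd = tp.hys_sd = 0.0
        data = simulate_dataset(
            n_founders_E=60, n_founders_R=60, n_snp=400,
            design=design, params=params, seed=21,
        )
        ph = data["phenotypes"]
        expected = {
            "ER": 0.144 + 0.206 + 0.163 + 4.296,
            "RE": 0.357 + 0.224 + 0.197 + 4.795,
        }
        for cross, sub in ph.groupby("cross"):
            v = sub["tnb"].var()
            assert v == pytest.approx(expected[cross], rel=0.15)

    def test_single_sow_residual_variance(self):
        """With only residual variance, record variance matches sigma2_e."""
        from conftest import table4_params

        fE, fR = simulate_founders(2, 2, 20, seed=1)
        design = CrossDesign(
            n_sires_E=1, n_dams_E=1, n_sires_R=1, n_dams_R=1,
            n_er_sows=1, n_re_sows=0, records_min=1000, records_max=1000, n_hys=1,
        )
        gametes, _ = simulate_cross(fE, fR, design, seed=2)
        params = table4_params()
        for tp in (params.tnb, params.nba):
            tp.V_E = np.zeros((2, 2))
            tp.V_R = np.zeros((2, 2))
            tp.sigma2_s_er = tp.sigma2_s_re = 0.0
            tp.sigma2_e_er = 4.296
            tp.parity_sd = tp.hys_sd = 0.0
        from gamcross.simulate import GameticEffects

        z = {
            t: GameticEffects(U_E=np.zeros((1, 2)), U_R=np.zeros((1, 2)))
            for t in ("tnb", "nba")
        }
        ph, _ = simulate_phenotypes(gametes, z, params, design, seed=3)
        assert ph["tnb"].var() == pytest.approx(4.296, rel=0.15)


class TestCorruption:
    def test_zero_rates_leave_genotypes_untouched(self, rng):
        g = rng.integers(0, 3, size=(30, 50)).astype(np.int8)
        out, fate = corrupt_genotypes(g, seed=1)
        assert np.array_equal(out, g)
        assert set(fate) == {"ok"}

    def test_planted_monomorphic_snps_have_single_allele(self, rng):
        g = rng.integers(0, 3, size=(40, 100)).astype(np.int8)
        out, fate = corrupt_genotypes(g, monomorph_fraction=0.10, seed=2)
        planted = np.flatnonzero(fate == "monomorphic")
        assert len(planted) == 10
        assert np.all(out[:, planted] == 0)

    def test_overlapping_subsets_rejected(self, rng):
        g = rng.integers(0, 3, size=(10, 20)).astype(np.int8)
        with pytest.raises(ValueError, match="overlap"):
            corrupt_genotypes(g, monomorph_fraction=0.6, rare_fraction=0.6, seed=0)


class TestPhasingScenarios:
    def test_zero_flip_rates_identical(self, small_dataset):
        from gamcross.consensus import similitude_matrix

        scen = make_phasing_scenarios(small_dataset["gametes"], 3, [0, 0, 0], seed=1)
        M, mean = similitude_matrix(scen)
        assert np.allclose(M, 1.0) and mean == 1.0

    def test_flip_rate_length_mismatch(self, small_dataset):
        with pytest.raises(ValueError, match="flip rates"):
            make_phasing_scenarios(small_dataset["gametes"], 9, [0.1] * 5, seed=0)

    def test_flips_preserve_allele_multiset(self, small_dataset):
        g = small_dataset["gametes"]
        scen = make_phasing_scenarios(g, 2, [0.5, 0.2], seed=3)
        for s in range(2):
            assert np.array_equal(
                np.sort(np.stack([scen.paternal[s], scen.maternal[s]]), axis=0),
                np.sort(np.stack([g.paternal, g.maternal]), axis=0),
            )
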