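"""PRS construction, cis/trans classification and pQTS scan checks."""

import numpy as np
import pytest

from prsprot import normalize, pqts, simgen
from prsprot.containers import (AdjustedProteinPanel, GenotypePanel, PrsModel)


def _geno(dosages, chrom=None, pos=None, ea=None):
    dosages = np.asarray(dosages, dtype=float)
    n, s = dosages.shape
    return GenotypePanel(
        dosages=dosages, snp_id=[f"rs{j}" for j in range(s)],
        chrom=chrom or ["1"] * s,
        pos=pos if pos is not None else np.arange(1, s + 1) * 1000,
        effect_allele=ea or ["A"] * s,
        sample_id=[f"s{i}" for i in range(n)])


def _adjusted(values, geno, tss_chrom=None, tss_pos=None):
    values = np.asarray(values, dtype=float)
    p = values.shape[1]
    return AdjustedProteinPanel(
        values=values, analyte_id=[f"a{k}" for k in range(p)],
        gene_symbol=[f"G{k}" for k in range(p)],
        tss_chrom=tss_chrom or ["9"] * p,
        tss_pos=np.asarray(tss_pos if tss_pos is not None
                           else np.arange(1, p + 1) * 1000),
        sample_id=list(geno.sample_id))


def _model(geno, weights, ea=None):
    return PrsModel(snp_id=list(geno.snp_id), chrom=list(geno.chrom),
                    pos=geno.pos.copy(),
                    effect_allele=ea or list(geno.effect_allele),
                    weight=np.asarray(weights, dtype=float))


class TestBuildPrs:
    def test_hand_dot_product(self):
        geno = _geno([[2.0, 1.0, 0.0]])
        res = pqts.build_prs(geno, _model(geno, [0.2, -0.1, 0.5]))
        assert np.allclose(res.score, [0.3])

    def test_zero_weights(self):
        geno = _geno(np.random.default_rng(0).integers(0, 3, (5, 4)))
        res = pqts.build_prs(geno, _model(geno, np.zeros(4)))
        assert np.allclose(res.score, 0.0)

    def test_single_snp_identity(self):
        geno = _geno([[0.0], [1.0], [2.0]])
        res = pqts.build_prs(geno, _model(geno, [1.0]))
        assert np.allclose(res.score, geno.dosages[:, 0])

    def test_effect_allele_flip(self):
        geno = _geno([[2.0], [0.0]], ea=["A"])
        model = _model(geno, [1.0], ea=["G"])
        res = pqts.build_prs(geno, model)
        assert res.n_flipped == 1
        assert np.allclose(res.score, [0.0, 2.0])

    def test_missing_and_ambiguous_reported(self):
        geno = _geno([[1.0, 1.0]], ea=["A", "C"])
        model = PrsModel(snp_id=["rs0", "rs1", "rsX"],
                         chrom=["1", "1", "2"], pos=[1000, 2000, 5],
                         effect_allele=["T", "C", "A"],
                         weight=[1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="ambiguous"):
            res = pqts.build_prs(geno, model)
        assert res.missing == ["rsX"]
        assert res.ambiguous == ["rs0"]
        assert res.n_matched == 2

    def test_no_match_is_error(self):
        geno = _geno([[1.0]])
        model = PrsModel(snp_id=["rsX"], chrom=["5"], pos=[1],
                         effect_allele=["A"], weight=[1.0])
        with pytest.raises(ValueError):
            pqts.build_prs(geno, model)


class TestIsCis:
    @pytest.mark.parametrize("snp,tss,expected", [
        ((("1"), 5_000_000), (("1"), 2_500_000), True),    # exactly 2.5 Mb
        ((("1"), 5_000_001), (("1"), 2_500_000), False),   # one bp outside
        ((("1"), 100), (("2"), 100), False),               # other chromosome
        ((("1"), 100), (("1"), 200), True),
    ])
    def test_boundaries(self, snp, tss, expected):
        assert pqts.is_cis(snp[0], snp[1], tss[0], tss[1]) is expected

    def test_every_pair_classified_exactly_once(self, small_panels):
        cfg, geno, proteins, *_ = small_panels
        cis = pqts.cis_matrix(geno.chrom, geno.pos, proteins.tss_chrom,
                              proteins.tss_pos)
        for j in range(cfg.n_snps):
            for k in range(cfg.n_proteins):
                assert cis[j, k] == pqts.is_cis(
                    geno.chrom[j], geno.pos[j],
                    proteins.tss_chrom[k], proteins.tss_pos[k])


class TestPqtsScan:
    def test_perfect_fit(self, rng):
        geno = _geno(rng.integers(0, 3, (30, 2)))
        res = pqts.build_prs(geno, _model(geno, [0.5, 0.25]))
        adj = _adjusted(res.score[:, None], geno)
        rec = pqts.pqts_scan(adj, geno, _model(geno, [0.5, 0.25]))[0]
        assert abs(rec.alpha1 - 1.0) < 1e-8
        assert rec.p_value < 1e-100

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        geno = _geno(rng.integers(0, 3, (25, 3)).astype(float))
        model = _model(geno, [0.4, -0.2, 0.1])
        y = rng.normal(size=(25, 4))
        adj = _adjusted(y, geno)
        recs = pqts.pqts_scan(adj, geno, model)
        x = sm.add_constant(pqts.build_prs(geno, model).score)
        for k, rec in enumerate(recs):
            fit = sm.OLS(y[:, k], x).fit()
            assert abs(rec.alpha1 - fit.params[1]) < 1e-10
            assert abs(rec.se - fit.bse[1]) < 1e-10
            assert abs(rec.p_value - fit.pvalues[1]) < 1e-10

    def test_scale_equivariance(self, rng):
        geno = _geno(rng.integers(0, 3, (40, 2)).astype(float))
        y = rng.normal(size=(40, 3))
        adj = _adjusted(y, geno)
        r1 = pqts.pqts_scan(adj, geno, _model(geno, [0.3, 0.7]))
        r2 = pqts.pqts_scan(adj, geno, _model(geno, [1.5, 3.5]))  # x5
        for a, b in zip(r1, r2):
            assert abs(a.alpha1 - 5 * b.alpha1) < 1e-10
            assert abs(a.t_stat - b.t_stat) < 1e-10
            assert abs(a.p_value - b.p_value) < 1e-10

    def test_restricted_equals_full_without_cis_snps(self, rng):
        geno = _geno(rng.integers(0, 3, (50, 3)).astype(float))
        model = _model(geno, [0.2, 0.3, -0.4])
        adj = _adjusted(rng.normal(size=(50, 2)), geno)  # TSS on chrom 9
        full = pqts.pqts_scan(adj, geno, model, mode="full")
        trans = pqts.pqts_scan(adj, geno, model, mode="trans_restricted")
        for a, b in zip(full, trans):
            assert a.alpha1 == pytest.approx(b.alpha1, abs=1e-12)
            assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
            assert b.n_snps_used == 3

    def test_trans_restriction_drops_cis_contribution(self, rng):
        geno = _geno(rng.integers(0, 3, (60, 2)).astype(float),
                     chrom=["1", "2"], pos=[1_000_000, 1_000_000])
        model = _model(geno, [1.0, 1.0])
        # analyte 0 cis to SNP 0, analyte 1 cis to nothing
        adj = _adjusted(rng.normal(size=(60, 2)), geno,
                        tss_chrom=["1", "7"], tss_pos=[2_000_000, 5])
        trans = pqts.pqts_scan(adj, geno, model, mode="trans_restricted")
        assert trans[0].n_snps_used == 1
        assert trans[1].n_snps_used == 2
        # restricted score for analyte 0 is just SNP 1's dosage
        only = pqts.pqts_scan(adj, geno, _model(geno, [0.0, 1.0]))
        assert trans[0].p_value == pytest.approx(only[0].p_value, abs=1e-10)

    def test_null_type_one_error_rate(self):
        cfg = simgen.SimConfig(n_samples=300, n_snps=10, n_proteins=1000,
                               ld_block_size=5, n_confounders=0, seed=21)
        geno = simgen.simulate_genotypes(cfg)
        panel, _, _ = simgen.simulate_proteins(cfg, geno)
        adj = normalize.adjust_protein_panel(panel)
        model = simgen.prs_model_from_weights(geno, np.full(10, 0.1))
        recs = pqts.pqts_scan(adj, geno, model)
        assert sum(r.significant for r in recs) == 0
        rate = np.mean([r.p_value < 0.05 for r in recs])
        ci = 2.576 * np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rate - 0.05) < ci

    def test_constant_prs_rejected(self):
        geno = _geno(np.ones((10, 1)))
        adj = _adjusted(np.random.default_rng(0).normal(size=(10, 1)), geno)
        with pytest.raises(ValueError, match="constant"):
            pqts.pqts_scan(adj, geno, _model(geno, [1.0]))


class TestStrongTransScan:
    def test_planted_effect_detected(self):
        cfg = simgen.SimConfig(n_samples=5000, n_snps=8, n_proteins=4,
                               ld_block_size=4, ld_rho=0.0, n_confounders=0,
                               network_spec=[([2], [0], 0.5)], seed=9)
        geno = simgen.simulate_genotypes(cfg)
        panel, _, _ = simgen.simulate_proteins(cfg, geno)
        adj = normalize.adjust_protein_panel(panel)
        model = simgen.prs_model_from_weights(geno, np.full(8, 0.1))
        hits = pqts.strong_trans_pqtl_scan(adj, geno, model, "prot0001")
        assert hits == [geno.snp_id[2]]

    def test_null_protein_empty(self):
        cfg = simgen.SimConfig(n_samples=2000, n_snps=8, n_proteins=4,
                               ld_block_size=4, n_confounders=0, seed=10)
        geno = simgen.simulate_genotypes(cfg)
        panel, _, _ = simgen.simulate_proteins(cfg, geno)
        adj = normalize.adjust_protein_panel(panel)
        model = simgen.prs_model_from_weights(geno, np.full(8, 0.1))
        assert pqts.strong_trans_pqtl_scan(adj, geno, model, "prot0002") == []

    def test_unknown_analyte(self, rng):
        geno = _geno(rng.integers(0, 3, (10, 2)).astype(float))
        adj = _adjusted(rng.normal(size=(10, 1)), geno)
        model = _model(geno, [1.0, 1.0])
        with pytest.raises(KeyError):
            pqts.strong_trans_pqtl_scan(adj, geno, model, "nope")
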