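"""Kinship, pruning, PCA, x2y and the association scan."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import pointbiserialr

from mitopop import mitonuclear as mn
from mitopop.simulate import CohortSimConfig, simulate_nuclear_cohort


@pytest.fixture(scope="module")
def pedigree_cohort():
    cfg = CohortSimConfig(
        n_snps=20_000, n_per_deme=(120, 120), subpop_fst=0.05,
        pedigree_spec={"duplicate": 2, "parent_offspring": 6, "second_degree": 4},
        seed=31,
    )
    return simulate_nuclear_cohort(cfg)


class TestKinship:
    def test_duplicate_phi_exactly_half(self, pedigree_cohort):
        g, _, _, ped = pedigree_cohort
        dups = ped[ped.relation == "duplicate"]
        est = mn.king_robust_kinship(g, pairs=list(zip(dups.id1, dups.id2)))
        assert (est.phi == 0.5).all()
        assert (est.degree == "duplicate/MZ").all()

    def test_parent_offspring_expectation(self, pedigree_cohort):
        g, _, _, ped = pedigree_cohort
        po = ped[ped.relation == "parent_offspring"]
        est = mn.king_robust_kinship(g, pairs=list(zip(po.id1, po.id2)))
        assert 0.22 < est.phi.mean() < 0.28
        assert set(est.degree) == {"1st"}

    def test_second_degree_expectation(self, pedigree_cohort):
        g, _, _, ped = pedigree_cohort
        sd = ped[ped.relation == "second_degree"]
        est = mn.king_robust_kinship(g, pairs=list(zip(sd.id1, sd.id2)))
        assert 0.09 < est.phi.mean() < 0.16

    def test_unrelated_near_zero(self, pedigree_cohort):
        g, _, _, _ = pedigree_cohort
        pairs = [(f"S{i:05d}", f"S{i+40:05d}") for i in range(10)]
        est = mn.king_robust_kinship(g, pairs=pairs)
        assert -0.05 < est.phi.mean() < 0.05

    def test_symmetry(self, pedigree_cohort):
        g, _, _, ped = pedigree_cohort
        a, b = ped.iloc[0].id1, ped.iloc[0].id2
        phi_ab = mn.king_robust_kinship(g, pairs=[(a, b)]).phi.iloc[0]
        phi_ba = mn.king_robust_kinship(g, pairs=[(b, a)]).phi.iloc[0]
        assert phi_ab == pytest.approx(phi_ba, abs=1e-12)

    def test_min_shared_skip(self, pedigree_cohort):
        g, _, _, _ = pedigree_cohort
        est = mn.king_robust_kinship(
            g, pairs=[("S00000", "S00001")], min_shared=10**9
        )
        assert est.degree.iloc[0] == "skipped"
        assert math.isnan(est.phi.iloc[0])


class TestPruneRelated:
    def test_triangle_hub_removed(self):
        df = pd.DataFrame(
            [
                {"id1": "A", "id2": "B", "degree": "1st"},
                {"id1": "A", "id2": "C", "degree": "1st"},
                {"id1": "B", "id2": "C", "degree": "unrelated"},
            ]
        )
        kept, removed = mn.prune_related(df)
        assert removed == ["A"] and kept == ["B", "C"]

    def test_alpha_numeric_tie_break(self):
        df = pd.DataFrame([{"id1": "S2", "id2": "S1", "degree": "duplicate/MZ"}])
        kept, removed = mn.prune_related(df)
        assert removed == ["S1"] and kept == ["S2"]

    def test_no_offending_pairs(self):
        df = pd.DataFrame([{"id1": "A", "id2": "B", "degree": "3rd"}])
        kept, removed = mn.prune_related(df)
        assert removed == [] and set(kept) == {"A", "B"}

    def test_row_order_independence(self):
        rows = [
            {"id1": "A", "id2": "B", "degree": "1st"},
            {"id1": "A", "id2": "C", "degree": "2nd"},
            {"id1": "B", "id2": "D", "degree": "duplicate/MZ"},
            {"id1": "C", "id2": "D", "degree": "unrelated"},
        ]
        base = mn.prune_related(pd.DataFrame(rows))
        flipped = mn.prune_related(pd.DataFrame(rows[::-1]))
        assert base == flipped


class TestLdPrune:
    def _matrix(self, geno, pos):
        m = geno.shape[1]
        return mn.GenotypeMatrix(
            [f"S{i}" for i in range(geno.shape[0])],
            np.full(m, "3L", dtype=object), np.asarray(pos),
            np.full(m, "A", dtype=object), np.full(m, "T", dtype=object),
            geno,
        )

    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(1)
        a = rng.binomial(2, 0.4, 100).astype(np.int8)
        g = self._matrix(np.column_stack([a, a]), [100, 200])
        assert mn.ld_prune(g).tolist() == [True, False]

    def test_independent_variants_retained(self):
        rng = np.random.default_rng(2)
        geno = rng.binomial(2, 0.5, size=(300, 20)).astype(np.int8)
        g = self._matrix(geno, np.arange(20) * 60)
        assert mn.ld_prune(g).all()

    def test_planted_blocks_one_survivor_each(self):
        rng = np.random.default_rng(3)
        base = rng.binomial(2, 0.4, size=(150, 8)).astype(np.int8)
        geno = np.repeat(base, 5, axis=1)
        pos = np.arange(40) * 80
        g = self._matrix(geno, pos)
        retained = mn.ld_prune(g)
        assert retained.reshape(8, 5).sum(axis=1).tolist() == [1] * 8


class TestPca:
    def test_structure_recovery(self):
        cfg = CohortSimConfig(
            n_snps=3000, n_per_deme=(80, 80), subpop_fst=0.1, seed=8
        )
        g, _, samples, _ = simulate_nuclear_cohort(cfg)
        scores = mn.pca_covariates(g, n_snps=3000, n_components=4, seed=2)
        deme = (samples["population"] == "POP1").astype(int)
        r = abs(pointbiserialr(deme, scores["PC1"])[0])
        assert r > 0.9

    def test_duplicate_rows_identical_scores(self):
        cfg = CohortSimConfig(n_snps=1000, n_per_deme=(50, 50), seed=9)
        g, _, _, _ = simulate_nuclear_cohort(cfg)
        geno = np.vstack([g.genotypes, g.genotypes[:1]])
        g2 = mn.GenotypeMatrix(
            g.sample_ids + ["DUP"], g.chrom, g.pos, g.ref, g.alt, geno
        )
        scores = mn.pca_covariates(g2, n_snps=1000, n_components=3, seed=3, prune=False)
        assert np.allclose(scores.loc["DUP"], scores.loc[g.sample_ids[0]], atol=1e-8)

    def test_null_deme_no_axis(self):
        cfg = CohortSimConfig(n_snps=2000, n_per_deme=(120,), subpop_fst=0.05,
                              deme_prevalence=(0.5,), seed=10)
        g, _, _, _ = simulate_nuclear_cohort(cfg)
        scores = mn.pca_covariates(g, n_snps=2000, n_components=4, seed=4)
        rng = np.random.default_rng(5)
        fake = rng.integers(0, 2, g.n_samples)
        rs = [abs(pointbiserialr(fake, scores[c])[0]) for c in scores.columns]
        assert max(rs) < 0.25


class TestX2y:
    def test_perfect_categorical_prediction(self):
        rng = np.random.default_rng(1)
        x = pd.Series(rng.normal(size=300), name="x")
        y = pd.Series(np.where(x > 0, "a", "b"), name="y")
        assert mn.x2y_metric(x, y, resamples=50, seed=1).x2y > 95

    def test_null_point_zero_and_ci_covers(self):
        covered = 0
        points = []
        for s in range(25):
            rng = np.random.default_rng(1000 + s)
            x = pd.Series(rng.normal(size=120), name="x")
            y = pd.Series(rng.choice(["a", "b"], 120), name="y")
            res = mn.x2y_metric(x, y, resamples=100, seed=s)
            points.append(res.x2y)
            covered += res.ci_low <= 0 <= res.ci_high
        assert covered >= 23
        assert np.median(points) == pytest.approx(0.0, abs=2.0)

    def test_constant_response_sentinel(self):
        x = pd.Series(np.arange(30.0), name="x")
        y = pd.Series(["a"] * 30, name="y")
        assert math.isnan(mn.x2y_metric(x, y, resamples=10, seed=1).x2y)

    def test_minimum_observations(self):
        with pytest.raises(ValueError):
            mn.x2y_metric(pd.Series(range(5)), pd.Series(range(5)))

    def test_continuous_response_regression(self):
        rng = np.random.default_rng(7)
        x = pd.Series(rng.normal(size=200), name="x")
        y = pd.Series(3 * x + rng.normal(0, 0.1, 200), name="y")
        res = mn.x2y_metric(x, y, resamples=50, seed=2)
        assert res.x2y > 90
        assert res.ci_low <= res.x2y <= res.ci_high


@pytest.fixture(scope="module")
def small_cohort():
    cfg = CohortSimConfig(
        n_snps=400, n_per_deme=(150, 150), subpop_fst=0.05,
        deme_prevalence=(0.65, 0.35), seed=77,
    )
    g, pheno, samples, _ = simulate_nuclear_cohort(cfg)
    pcs = mn.pca_covariates(g, n_snps=400, n_components=3, seed=1, prune=False)
    return g, pheno, pcs


class TestGwas:
    def test_matches_statsmodels_lrt(self, small_cohort):
        """Independent oracle: per-SNP logistic LRT via statsmodels."""
        g, pheno, pcs = small_cohort
        scan = mn.gwas_scan(g, pheno, pcs, maf_min=0.05)
        y = pheno.to_numpy(float)
        C = np.column_stack([np.ones(g.n_samples), pcs.to_numpy(float)])
        m0 = sm.Logit(y, C).fit(disp=0)
        tested = np.flatnonzero(g.maf() >= 0.05)
        for row_i, snp in enumerate(tested[:25]):
            X = np.column_stack([C, g.genotypes[:, snp].astype(float)])
            m1 = sm.Logit(y, X).fit(disp=0)
            lrt = 2 * (m1.llf - m0.llf)
            assert scan.results.stat.iloc[row_i] == pytest.approx(lrt, abs=1e-6)
            assert scan.results.beta.iloc[row_i] == pytest.approx(
                m1.params[-1], abs=1e-6
            )

    def test_permuted_phenotype_p_uniform(self, small_cohort):
        from scipy.stats import kstest

        g, pheno, pcs = small_cohort
        rng = np.random.default_rng(5)
        perm = pd.Series(
            rng.permutation(pheno.to_numpy()), index=pheno.index, name="lineage"
        )
        scan = mn.gwas_scan(g, perm, pcs, maf_min=0.01)
        assert kstest(scan.results.p, "uniform").pvalue > 0.01

    def test_separation_fallback(self):
        rng = np.random.default_rng(6)
        n = 120
        y = pd.Series(
            np.r_[np.ones(60), np.zeros(60)].astype(int),
            index=[f"S{i:05d}" for i in range(n)], name="lineage",
        )
        sep = np.r_[np.full(60, 2), np.zeros(60)].astype(np.int8)  # perfect separator
        other = rng.binomial(2, 0.4, n).astype(np.int8)
        g = mn.GenotypeMatrix(
            list(y.index), np.array(["3L", "3L"], dtype=object),
            np.array([100, 300]), np.array(["A", "A"], dtype=object),
            np.array(["T", "T"], dtype=object), np.column_stack([sep, other]),
        )
        scan = mn.gwas_scan(g, y, covariates=None, maf_min=0.0)
        assert not scan.results.converged.iloc[0]
        assert np.isfinite(scan.results.stat.iloc[0])
        assert 0 < scan.results.p.iloc[0] < 1e-6

    def test_phenotype_must_have_both_classes(self, small_cohort):
        g, pheno, pcs = small_cohort
        ones = pd.Series(1, index=pheno.index, name="lineage")
        with pytest.raises(ValueError):
            mn.gwas_scan(g, ones, pcs)

    def test_bonferroni_threshold_arithmetic(self):
        assert mn.bonferroni_threshold(0.05, 1_139_052) == pytest.approx(
            4.39e-8, rel=1e-3
        )


class TestAnnotate:
    GFF = """##gff-version 3
3L\tsrc\tgene\t1000\t5000\t.\t+\t.\tID=GENE1
3L\tsrc\tCDS\t1000\t2000\t.\t+\t0\tID=cds-GENE1;Parent=GENE1
3L\tsrc\tCDS\t4000\t5000\t.\t+\t0\tID=cds-GENE2;Parent=GENE2
malformed line without tabs
3L\tsrc\tCDS\tnotanumber\t10\t.\t+\t0\tID=cds-BAD
"""

    def _scan(self, positions, ps):
        return pd.DataFrame(
            {"chrom": "3L", "pos": positions, "p": ps}
        )

    def test_cds_hit_and_flank_boundary(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(self.GFF)
        scan = self._scan([1500, 2999, 3001, 999 + 1, 4000 - 1001], [1e-9] * 5)
        out = mn.annotate_hits(scan, gff, flank=1000, threshold=1e-8)
        assert out.iloc[0].genes == "GENE1"            # inside CDS
        assert out.iloc[1].genes == "GENE1"            # 999 bp downstream
        assert "GENE2" in out.iloc[2].genes            # 999 bp upstream of GENE2
        assert out.iloc[3].genes == "GENE1"            # 1000 bp boundary inclusive
        assert out.iloc[4].intergenic or out.iloc[4].genes != ""

    def test_overlapping_flanks_list_both_genes(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(self.GFF)
        out = mn.annotate_hits(self._scan([3000], [1e-9]), gff, flank=1000,
                               threshold=1e-8)
        assert out.iloc[0].genes == "GENE1,GENE2"

    def test_intergenic_with_distance(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(self.GFF)
        out = mn.annotate_hits(self._scan([20_000], [1e-9]), gff, flank=1000,
                               threshold=1e-8)
        assert out.iloc[0].intergenic
        assert out.iloc[0].nearest_bp == 15_000


def test_vcf_round_trip(tmp_path):
    cfg = CohortSimConfig(n_snps=200, n_per_deme=(20, 20), seed=12)
    g, _, _, _ = simulate_nuclear_cohort(cfg)
    g.genotypes[0, 0] = mn.MISSING
    path = tmp_path / "cohort.vcf"
    g.to_vcf(path)
    back = mn.GenotypeMatrix.from_vcf(path)
    assert back.sample_ids == g.sample_ids
    assert np.array_equal(back.genotypes, g.genotypes)
    assert np.array_equal(back.pos, g.pos)
    assert list(back.ref) == list(g.ref)


def test_end_to_end_planted_loci_recovered():
    """Full nuclear pipeline on one synthetic study: the significant set
    contains the planted loci with at most one false positive."""
    cfg = CohortSimConfig(
        n_snps=4000, n_per_deme=(400, 400), subpop_fst=0.05,
        deme_prevalence=(0.6, 0.4),
        planted_loci=[(500, 3.0), (2000, 3.0), (3500, 3.0)], planted_maf=0.3,
        pedigree_spec={"duplicate": 2, "parent_offspring": 2},
        seed=202,
    )
    g, pheno, samples, ped = simulate_nuclear_cohort(cfg)
    est = mn.king_robust_kinship(g, pairs=list(zip(ped.id1, ped.id2)), min_shared=1000)
    kept_ids = [s for s in g.sample_ids if s not in set(mn.prune_related(est)[1])]
    g2 = g.subset_samples(kept_ids)
    pcs = mn.pca_covariates(g2, n_snps=2000, n_components=6, seed=3)
    retained = mn.ld_prune(g2)
    scan = mn.gwas_scan(
        g2, pheno.loc[kept_ids], pcs, maf_min=0.01,
        n_independent=int(retained.sum()),
    )
    sig_pos = set(
        scan.results.loc[scan.results.p <= scan.bonferroni_threshold, "pos"]
    )
    planted_pos = {g.pos[i] for i, _ in cfg.planted_loci}
    assert planted_pos <= sig_pos
    assert len(sig_pos - planted_pos) <= 1
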