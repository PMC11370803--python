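"""Distances, AMOVA, pairwise FST and Mantel IBD."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from mitopop import structure as st
from mitopop.alignment import HaplotypeAlignment, write_alignment
from mitopop.simulate import DemographicModel, MutationModel, simulate_mtdna_alignment


@pytest.fixture(scope="module")
def structured_alignment():
    model = DemographicModel(
        ["A", "B", "C", "D"], [5000] * 4, split_time=30_000, ancestral_size=5000
    )
    return simulate_mtdna_alignment(
        model, MutationModel(1e-7, sequence_length=1000), [8, 8, 8, 8], seed=5
    )


class TestDistances:
    def test_identical_pair_zero_under_every_model(self):
        aln = HaplotypeAlignment.from_sequences(["a", "b"], ["ACGTACGTAC"] * 2)
        for model in st.DISTANCE_MODELS:
            dm = st.genetic_distance_matrix(aln, model, gamma_alpha=1.0)
            assert dm.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_p_distance_arithmetic(self):
        aln = HaplotypeAlignment.from_sequences(["a", "b"], ["AAAAAAAAAA", "TTAAAAAAAA"])
        dm = st.genetic_distance_matrix(aln, "p")
        assert dm.d[0, 1] == pytest.approx(0.2)

    def test_jc69_closed_form(self):
        aln = HaplotypeAlignment.from_sequences(["a", "b"], ["AAAAAAAAAA", "TTAAAAAAAA"])
        dm = st.genetic_distance_matrix(aln, "JC69")
        assert dm.d[0, 1] == pytest.approx(-0.75 * math.log(1 - 4 * 0.2 / 3), abs=1e-10)

    def test_pairwise_deletion(self):
        aln = HaplotypeAlignment.from_sequences(["a", "b"], ["AAAAN", "TAAAA"])
        dm = st.genetic_distance_matrix(aln, "p")
        assert dm.d[0, 1] == pytest.approx(0.25)  # 1 mismatch / 4 compared

    def test_saturated_distance_is_nan(self):
        aln = HaplotypeAlignment.from_sequences(["a", "b"], ["AAAA", "TTTT"])
        dm = st.genetic_distance_matrix(aln, "JC69")
        assert math.isnan(dm.d[0, 1])

    def test_tn93_matches_r_ape(self, tmp_path, structured_alignment):
        """Independent oracle: ape::dist.dna TN93 (+gamma) on the same FASTA."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        sub = structured_alignment.subset(structured_alignment.sample_ids[:8])
        fa = tmp_path / "a.fasta"
        write_alignment(sub, fa)
        script = (
            f'library(ape); x <- read.dna("{fa}", format="fasta");'
            'd <- dist.dna(x, model="TN93", pairwise.deletion=TRUE);'
            'g <- dist.dna(x, model="TN93", gamma=1.0, pairwise.deletion=TRUE);'
            'cat(c(d, g), sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        vals = np.array([float(v) for v in out.stdout.split()])
        n_pairs = len(vals) // 2
        ours = st.genetic_distance_matrix(sub, "TN93")
        ours_g = st.genetic_distance_matrix(sub, "TN93_gamma", gamma_alpha=1.0)
        iu = np.triu_indices(8, 1)
        # R's dist object is column-major lower triangle == our upper triangle
        assert np.allclose(np.sort(ours.d[iu]), np.sort(vals[:n_pairs]), atol=1e-8)
        assert np.allclose(np.sort(ours_g.d[iu]), np.sort(vals[n_pairs:]), atol=1e-8)


class TestAmova:
    def test_ssd_additivity(self, structured_alignment):
        dm = st.genetic_distance_matrix(structured_alignment, "p")
        pops = dict(
            zip(structured_alignment.sample_ids, structured_alignment.metadata["population"])
        )
        groups = {"A": "g1", "B": "g1", "C": "g2", "D": "g2"}
        res = st.amova(dm, pops, groups, permutations=20, seed=1)
        d2 = dm.d**2
        total = d2.sum() / (2 * len(dm.sample_ids))
        assert sum(res.ssd.values()) == pytest.approx(total, abs=1e-9)
        assert sum(res.percent.values()) == pytest.approx(100.0, abs=0.1)
        # df check: (G-1, P-G, N-P)
        assert res.df == {
            "among_groups": 1, "among_populations": 2, "within_populations": 28
        }

    def test_phi_definitions_hold(self, structured_alignment):
        dm = st.genetic_distance_matrix(structured_alignment, "p")
        pops = dict(
            zip(structured_alignment.sample_ids, structured_alignment.metadata["population"])
        )
        res = st.amova(dm, pops, {"A": "g1", "B": "g1", "C": "g2", "D": "g2"},
                       permutations=0, seed=1)
        a, b, c = (res.sigma["among_groups"], res.sigma["among_populations"],
                   res.sigma["within_populations"])
        assert res.phi_ct == pytest.approx(a / (a + b + c))
        assert res.phi_sc == pytest.approx(b / (b + c))
        assert res.phi_st == pytest.approx((a + b) / (a + b + c))

    def test_identical_populations_phi_near_zero(self):
        rng = np.random.default_rng(2)
        haps = ["".join("ACGT"[c] for c in rng.integers(0, 4, 60)) for _ in range(6)]
        seqs = haps * 4  # same multiset in two populations of 12
        ids = [f"s{i}" for i in range(24)]
        aln = HaplotypeAlignment.from_sequences(ids, seqs)
        dm = st.genetic_distance_matrix(aln, "p")
        pops = {s: ("P1" if i < 12 else "P2") for i, s in enumerate(ids)}
        res = st.amova(dm, pops, None, permutations=99, seed=3)
        # the unbiased estimator sits slightly below zero in the absence of
        # structure (expectation about -1/(n_p - 1)); no positive signal
        assert res.phi_st < 0.05
        assert abs(res.phi_st) < 0.15
        assert res.p_values["within_populations"] > 0.05

    def test_fixed_haplotypes_phi_one(self):
        seqs = ["AAAAAA"] * 5 + ["TTTTTT"] * 5
        ids = [f"s{i}" for i in range(10)]
        aln = HaplotypeAlignment.from_sequences(ids, seqs)
        dm = st.genetic_distance_matrix(aln, "p")
        pops = {s: ("P1" if i < 5 else "P2") for i, s in enumerate(ids)}
        res = st.amova(dm, pops, None, permutations=10, seed=1)
        assert res.phi_st == pytest.approx(1.0)

    def test_singleton_population_design_error(self, structured_alignment):
        dm = st.genetic_distance_matrix(structured_alignment, "p")
        pops = dict(
            zip(structured_alignment.sample_ids, structured_alignment.metadata["population"])
        )
        lone = structured_alignment.sample_ids[0]
        pops[lone] = "LONE"
        with pytest.raises(ValueError, match="singleton"):
            st.amova(dm, pops, {"A": "g", "B": "g", "C": "g", "D": "g", "LONE": "g2"},
                     permutations=0, seed=1)

    def test_two_population_amova_equals_pairwise_fst(self, structured_alignment):
        keep = [
            s for s, p in zip(
                structured_alignment.sample_ids,
                structured_alignment.metadata["population"],
            )
            if p in ("A", "B")
        ]
        sub = structured_alignment.subset(keep)
        dm = st.genetic_distance_matrix(sub, "p")
        pops = dict(zip(sub.sample_ids, sub.metadata["population"]))
        one = st.amova(dm, pops, None, permutations=0, seed=1)
        fst = st.pairwise_fst(dm, pops, permutations=0, seed=1)
        assert one.phi_st == fst.long.fst.iloc[0]


class TestPairwiseFst:
    def test_duplicate_populations_near_zero(self):
        rng = np.random.default_rng(4)
        haps = ["".join("ACGT"[c] for c in rng.integers(0, 4, 50)) for _ in range(8)]
        ids = [f"s{i}" for i in range(16)]
        aln = HaplotypeAlignment.from_sequences(ids, haps * 2)
        dm = st.genetic_distance_matrix(aln, "p")
        pops = {s: ("P1" if i < 8 else "P2") for i, s in enumerate(ids)}
        res = st.pairwise_fst(dm, pops, permutations=99, seed=5)
        # no positive differentiation; the estimator's null expectation is
        # mildly negative (about -1/(n_p - 1))
        assert -0.2 < res.long.fst.iloc[0] < 0.05
        assert res.long.p.iloc[0] > 0.05

    def test_fixed_haplotypes_fst_one_with_sentinel(self):
        ids = [f"s{i}" for i in range(8)]
        aln = HaplotypeAlignment.from_sequences(ids, ["AAAA"] * 4 + ["TTTT"] * 4)
        dm = st.genetic_distance_matrix(aln, "p")
        pops = {s: ("P1" if i < 4 else "P2") for i, s in enumerate(ids)}
        res = st.pairwise_fst(dm, pops, permutations=10, seed=1)
        assert res.long.fst.iloc[0] == 1.0
        assert math.isnan(res.long.linearized.iloc[0])
        assert res.long.p.iloc[0] < 0.2

    def test_haplotype_fst_bounds(self):
        ids = [f"s{i}" for i in range(8)]
        fixed = HaplotypeAlignment.from_sequences(ids, ["AAAA"] * 4 + ["TTTT"] * 4)
        pops = {s: ("P1" if i < 4 else "P2") for i, s in enumerate(ids)}
        assert st.haplotype_fst(fixed, pops).fst.iloc[0] == pytest.approx(1.0)
        same = HaplotypeAlignment.from_sequences(
            ids, ["AAAA", "AATT", "AAAA", "AATT"] * 2
        )
        assert st.haplotype_fst(same, pops).fst.iloc[0] == pytest.approx(0.0)

    def test_min_population_size(self):
        ids = ["a", "b", "c"]
        aln = HaplotypeAlignment.from_sequences(ids, ["AAAA", "AATT", "TTTT"])
        dm = st.genetic_distance_matrix(aln, "p")
        with pytest.raises(ValueError):
            st.pairwise_fst(dm, {"a": "P1", "b": "P1", "c": "P2"})


class TestMantelIbd:
    @pytest.fixture
    def coords(self):
        rng = np.random.default_rng(0)
        ids = [f"p{i}" for i in range(6)]
        return ids, pd.DataFrame(
            {
                "population": ids,
                "latitude": rng.uniform(0, 15, 6),
                "longitude": rng.uniform(-15, 15, 6),
            }
        )

    def _geo_matrix(self, coords):
        ids, df = coords
        geo = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                if i != j:
                    geo[i, j] = st.haversine_km(
                        df.latitude[i], df.longitude[i],
                        df.latitude[j], df.longitude[j],
                    )
        return ids, df, geo

    def test_identical_matrices_r_one(self, coords):
        ids, df, geo = self._geo_matrix(coords)
        gen = np.log10(geo + np.eye(6))
        np.fill_diagonal(gen, 0)
        res = st.mantel_ibd(
            pd.DataFrame(gen, index=ids, columns=ids), df,
            permutations=99, seed=1, linearize=False,
        )
        assert res.mantel_r == pytest.approx(1.0)
        assert res.p_value <= 0.05
        assert res.r_squared == pytest.approx(1.0)

    def test_haversine_equator_degree(self):
        # one degree of longitude on the equator: 2 pi R / 360
        assert st.haversine_km(0, 0, 0, 1) == pytest.approx(111.195, abs=0.01)

    def test_rescaling_invariance(self, coords):
        ids, df, geo = self._geo_matrix(coords)
        rng = np.random.default_rng(3)
        gen = np.log10(geo + np.eye(6)) * 0.1 + rng.normal(0, 0.05, (6, 6))
        gen = (gen + gen.T) / 2
        np.fill_diagonal(gen, 0)
        gen = np.abs(gen)
        r1 = st.mantel_ibd(pd.DataFrame(gen, index=ids, columns=ids), df,
                           permutations=49, seed=9, linearize=False)
        df2 = df.copy()  # same coordinates: geographic matrix rescaled by log10 offset
        r2 = st.mantel_ibd(pd.DataFrame(gen * 3.0, index=ids, columns=ids), df2,
                           permutations=49, seed=9, linearize=False)
        assert r1.mantel_r == pytest.approx(r2.mantel_r, abs=1e-12)

    def test_zero_distance_guard(self):
        ids = ["a", "b", "c", "d"]
        df = pd.DataFrame(
            {"population": ids, "latitude": [0, 0, 1, 2], "longitude": [0, 0, 1, 2]}
        )
        gen = pd.DataFrame(np.ones((4, 4)) - np.eye(4), index=ids, columns=ids) * 0.1
        with pytest.raises(ValueError, match="zero great-circle"):
            st.mantel_ibd(gen, df, permutations=9, seed=1, linearize=False)

    def test_minimum_population_count(self, coords):
        ids, df, geo = self._geo_matrix(coords)
        gen = pd.DataFrame(np.log10(geo + np.eye(6)), index=ids, columns=ids)
        with pytest.raises(ValueError, match="at least 4"):
            st.mantel_ibd(gen, df, exclusions=ids[:3], permutations=9, seed=1,
                          linearize=False)
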