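"""Synthetic data generators for every pipeline stage.

Four generators emulate the statistical structure the analyses assume:

* a haploid structured-coalescent mtDNA gene pool (msprime), including a
  two-lineage "cryptic" scenario where a divergent maternal lineage is
  admixed along a west-to-east geographic gradient;
* a structured nuclear SNP cohort (Balding-Nichols allele frequencies,
  Hardy-Weinberg genotypes within demes) with planted mito-associated loci
  and planted pedigree relatives;
* marker-derived short-read sets with per-base sequencing error plus random
  background reads, for the endosymbiont screen;
* fixed-S neutral coalescent replicates (mutations placed uniformly on the
  genealogy conditional on the observed number of segregating sites), the
  null distribution behind the neutrality-test p-values.

All functions take an explicit integer seed and are bit-reproducible.
mtDNA is simulated without recombination throughout, reflecting maternal
inheritance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd
import tskit

from .alignment import ALPHABET, HaplotypeAlignment
from .diversity import SiteFrequencySpectrum

_BASE_CODE = {b: i for i, b in enumerate("ACGT")}


# ---------------------------------------------------------------------------
# model containers


@dataclass
class DemographicModel:
    """Haploid island/split demography for the mtDNA simulator.

    ``deme_sizes`` are haploid effective sizes; ``migration`` is a per-
    generation backwards migration-probability matrix (row = deme of the
    lineage, entries in [0, 1], rows summing to at most 1).  If
    ``split_time`` is set, all demes merge into a single ancestral deme of
    size ``ancestral_size`` that many generations ago.
    """

    deme_labels: list[str]
    deme_sizes: list[float]
    migration: np.ndarray | None = None
    split_time: float | None = None
    ancestral_size: float | None = None
    generations_per_year: float = 10.0

    def __post_init__(self) -> None:
        if len(self.deme_labels) != len(self.deme_sizes):
            raise ValueError("deme_labels and deme_sizes disagree")
        if any(s < 1 for s in self.deme_sizes):
            raise ValueError("deme sizes must be >= 1")
        if self.migration is not None:
            m = np.asarray(self.migration, dtype=float)
            if m.shape != (len(self.deme_labels),) * 2:
                raise ValueError("migration matrix shape mismatch")
            off = m - np.diag(np.diag(m))
            if (off < 0).any() or (off > 1).any() or (off.sum(axis=1) > 1).any():
                raise ValueError("migration rows must have entries in [0,1] summing <= 1")
            self.migration = m
        if self.split_time is not None and self.split_time < 0:
            raise ValueError("split_time must be >= 0")


@dataclass
class MutationModel:
    mu: float
    mode: str = "jukes_cantor_finite"  # or "infinite_sites"
    sequence_length: int = 15_000

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.sequence_length <= 0:
            raise ValueError("sequence_length must be > 0")
        if self.mode not in ("jukes_cantor_finite", "infinite_sites"):
            raise ValueError(f"unknown mutation mode {self.mode!r}")


@dataclass
class CohortSimConfig:
    """Nuclear SNP cohort with planted mito-lineage effects and relatives."""

    n_snps: int = 10_000
    n_per_deme: tuple[int, ...] = (500, 500)
    subpop_fst: float = 0.05
    planted_loci: list[tuple[int, float]] = field(default_factory=list)
    planted_maf: float | None = None  # fix the ancestral frequency of planted loci
    deme_prevalence: tuple[float, ...] = (0.5, 0.5)
    pedigree_spec: dict[str, int] = field(default_factory=dict)
    maf_floor: float = 0.05
    chrom: str = "3L"
    start_bp: int = 15_000_000
    spacing_bp: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.subpop_fst < 1):
            raise ValueError("subpop_fst must be in (0, 1)")
        if not (0 <= self.maf_floor < 0.5):
            raise ValueError("maf_floor must be in [0, 0.5)")
        if any(orr <= 0 for _, orr in self.planted_loci):
            raise ValueError("odds ratios must be > 0")
        if any(i >= self.n_snps for i, _ in self.planted_loci):
            raise ValueError("planted locus index out of range")


# ---------------------------------------------------------------------------
# helpers


def _msprime_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def _demography(model: DemographicModel) -> msprime.Demography:
    dem = msprime.Demography()
    for label, size in zip(model.deme_labels, model.deme_sizes):
        dem.add_population(name=label, initial_size=size)
    if model.migration is not None:
        for i, a in enumerate(model.deme_labels):
            for j, b in enumerate(model.deme_labels):
                if i != j and model.migration[i, j] > 0:
                    dem.set_migration_rate(source=a, dest=b, rate=model.migration[i, j])
    if model.split_time is not None:
        anc = model.ancestral_size or model.deme_sizes[0]
        dem.add_population(name="ancestral", initial_size=anc)
        dem.add_population_split(
            time=model.split_time, derived=list(model.deme_labels), ancestral="ancestral"
        )
    dem.sort_events()
    return dem


def _alignment_from_ts(
    mts: tskit.TreeSequence, L: int, infinite_sites: bool, rng: np.random.Generator
) -> np.ndarray:
    """Sample-by-site base-code matrix from a mutated tree sequence."""
    n = mts.num_samples
    anc = rng.integers(0, 4, size=L, dtype=np.uint8)
    mat = np.tile(anc, (n, 1))
    used: set[int] = set()
    for var in mts.variants():
        if infinite_sites:
            col = int(var.site.position)
            while col in used and col < L - 1:
                col += 1
            if col in used:  # wrapped past the end; reuse any free column
                col = next(c for c in range(L) if c not in used)
        else:
            col = int(var.site.position)
        used.add(col)
        codes = np.array([_BASE_CODE[a] for a in var.alleles if a is not None], dtype=np.uint8)
        mat[:, col] = codes[var.genotypes]
    return mat


def _synthetic_coords(
    deme_index: np.ndarray, n_demes: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """West-to-east longitudes (5 degrees between demes, jittered) and
    jittered equatorial latitudes, so distance gradients are meaningful."""
    lon = -15.0 + 5.0 * deme_index + rng.normal(0, 0.3, size=len(deme_index))
    lat = 10.0 + rng.normal(0, 0.3, size=len(deme_index))
    return lat, lon


# ---------------------------------------------------------------------------
# mtDNA alignments


def simulate_mtdna_alignment(
    model: DemographicModel,
    mut: MutationModel,
    n_per_deme: dict[str, int] | list[int],
    seed: int,
) -> HaplotypeAlignment:
    """Haploid structured-coalescent mtDNA alignment with sample metadata.

    Genealogies come from msprime under the given demography (ploidy 1, no
    recombination); mutations are Poisson on branches with rate ``mut.mu``
    per site per generation, finite-site Jukes-Cantor by default.
    """
    if isinstance(n_per_deme, dict):
        counts = [int(n_per_deme.get(lbl, 0)) for lbl in model.deme_labels]
    else:
        counts = [int(c) for c in n_per_deme]
    if sum(counts) == 0:
        raise ValueError("zero samples requested")
    rng = np.random.default_rng(seed)
    samples = [
        msprime.SampleSet(c, population=lbl, ploidy=1)
        for lbl, c in zip(model.deme_labels, counts)
        if c > 0
    ]
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=_demography(model),
        sequence_length=mut.sequence_length,
        ploidy=1,
        recombination_rate=0,
        random_seed=_msprime_seed(rng),
    )
    infinite = mut.mode == "infinite_sites"
    mts = msprime.sim_mutations(
        ts,
        rate=mut.mu,
        model=msprime.JC69(),
        discrete_genome=not infinite,
        random_seed=_msprime_seed(rng),
    )
    mat = _alignment_from_ts(mts, mut.sequence_length, infinite, rng)
    deme_index = np.repeat(
        np.arange(len(model.deme_labels)), counts
    )
    ids = [
        f"{model.deme_labels[d]}_{i:04d}" for i, d in enumerate(deme_index)
    ]
    lat, lon = _synthetic_coords(deme_index, len(model.deme_labels), rng)
    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "population": [model.deme_labels[d] for d in deme_index],
            "species": "gambiae",
            "latitude": lat,
            "longitude": lon,
            "sex": rng.choice(["F", "M"], size=len(ids)),
        }
    )
    return HaplotypeAlignment(ids, mat, meta)


def two_deme_island_model(
    nm: float, deme_size: float = 10_000.0, labels: tuple[str, str] = ("W", "E")
) -> DemographicModel:
    """Symmetric two-deme haploid island model parameterised by the scaled
    migration rate Nm, configured so the equilibrium differentiation equals
    the classical haploid island-model value FST = 1 / (1 + 2 Nm)."""
    m = nm / (2.0 * deme_size)
    mig = np.array([[0.0, m], [m, 0.0]])
    return DemographicModel(list(labels), [deme_size, deme_size], migration=mig)


def simulate_cryptic_scenario(
    seed: int,
    n_per_deme: tuple[int, ...] = (30, 30, 30),
    gradient: tuple[float, ...] = (0.49, 0.31, 0.10),
    split_time: float = 500_000.0,
    deme_size: float = 50_000.0,
    mu: float = 1e-8,
    sequence_length: int = 15_000,
) -> tuple[HaplotypeAlignment, pd.Series]:
    """mtDNA cohort with a divergent lineage admixed along a gradient.

    Two maternal lineages ("common" and "cryptic") split ``split_time``
    generations ago; each sample in geographic deme d carries a cryptic
    haplotype with probability ``gradient[d]``, decreasing west to east
    (defaults echo the observed prevalences in hybrid / coluzzii / gambiae
    groups, cryptic overall a clear minority).
    Defaults put the split at 50 kyr before present (10 generations/year)
    with a mutation rate of 1e-8 per site per generation, so between-lineage
    divergence is roughly ten times within-lineage diversity.

    Returns the annotated alignment and the true per-sample lineage labels.
    """
    if any(not (0 <= g <= 1) for g in gradient):
        raise ValueError("gradient entries must be in [0, 1]")
    if len(gradient) != len(n_per_deme):
        raise ValueError("gradient and n_per_deme disagree")
    rng = np.random.default_rng(seed)
    deme_index = np.repeat(np.arange(len(n_per_deme)), n_per_deme)
    is_cryptic = rng.random(len(deme_index)) < np.asarray(gradient)[deme_index]
    model = DemographicModel(
        ["common", "cryptic"],
        [deme_size, deme_size],
        split_time=split_time,
        ancestral_size=deme_size,
    )
    mut = MutationModel(mu=mu, sequence_length=sequence_length)
    counts = [int((~is_cryptic).sum()), int(is_cryptic.sum())]
    raw = simulate_mtdna_alignment(model, mut, counts, seed=_msprime_seed(rng))
    # rows 0..counts[0]-1 are common haplotypes, the rest cryptic; deal them
    # out to the geographic samples
    order = np.concatenate([np.flatnonzero(~is_cryptic), np.flatnonzero(is_cryptic)])
    mat = np.empty_like(raw.matrix)
    mat[order] = raw.matrix
    ids = [f"D{d}_{i:04d}" for i, d in enumerate(deme_index)]
    lat, lon = _synthetic_coords(deme_index, len(n_per_deme), rng)
    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "population": [f"POP{d}" for d in deme_index],
            "species": np.where(is_cryptic, "coluzzii", "gambiae"),
            "latitude": lat,
            "longitude": lon,
            "sex": rng.choice(["F", "M"], size=len(ids)),
        }
    )
    labels = pd.Series(
        np.where(is_cryptic, "cryptic", "common"), index=ids, name="lineage"
    )
    return HaplotypeAlignment(ids, mat, meta), labels


# ---------------------------------------------------------------------------
# fixed-S neutral null replicates


def neutral_null_replicates(
    n: int, S_obs: int, reps: int, seed: int | None = None
) -> list[SiteFrequencySpectrum]:
    """Folded spectra from the standard neutral coalescent conditioned on S.

    Each replicate draws a neutral genealogy for n haploid lineages and
    places exactly ``S_obs`` mutations on branches with probability
    proportional to branch length (the fixed-S algorithm), avoiding any
    assumption about theta.
    """
    if n < 2 or S_obs < 1:
        raise ValueError("need n >= 2 and S_obs >= 1")
    rng = np.random.default_rng(seed)
    out: list[SiteFrequencySpectrum] = []
    for _ in range(reps):
        ts = msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=1.0, random_seed=_msprime_seed(rng)
        )
        tree = ts.first()
        nodes = [u for u in tree.nodes() if tree.parent(u) != tskit.NULL]
        lengths = np.array([tree.branch_length(u) for u in nodes])
        sizes = np.array([tree.num_samples(u) for u in nodes])
        picks = rng.multinomial(S_obs, lengths / lengths.sum())
        minor = np.minimum(sizes, n - sizes)
        xi = np.zeros(n // 2, dtype=int)
        np.add.at(xi, minor - 1, picks)
        out.append(SiteFrequencySpectrum(n=n, counts=xi, L_effective=S_obs))
    return out


# ---------------------------------------------------------------------------
# nuclear cohort


def simulate_nuclear_cohort(cfg: CohortSimConfig):
    """Structured diploid SNP cohort with planted effects and relatives.

    Allele frequencies differentiate across demes by the Balding-Nichols
    beta model at the configured FST; genotypes are Hardy-Weinberg within
    demes.  The binary mito-lineage phenotype follows a logistic model with
    per-deme intercepts (``deme_prevalence``) plus ``log(OR)`` per alt
    allele at each planted locus.  Pedigree pairs (duplicate,
    parent_offspring, full_sib, second_degree) are appended by gene
    dropping from founders of deme 0.

    Returns ``(genotypes, phenotype, samples, pedigree)`` where ``samples``
    carries deme, sex and infection covariate columns and ``pedigree``
    lists the planted related pairs.
    """
    from .mitonuclear import GenotypeMatrix

    rng = np.random.default_rng(cfg.seed)
    n_demes = len(cfg.n_per_deme)
    if len(cfg.deme_prevalence) != n_demes:
        raise ValueError("deme_prevalence and n_per_deme disagree")
    F = cfg.subpop_fst
    p_anc = rng.uniform(max(cfg.maf_floor, 0.01), 1 - max(cfg.maf_floor, 0.01), cfg.n_snps)
    if cfg.planted_maf is not None:
        for idx, _ in cfg.planted_loci:
            p_anc[idx] = cfg.planted_maf
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    p_deme = rng.beta(a, b, size=(n_demes, cfg.n_snps))
    p_deme = np.clip(p_deme, 1e-4, 1 - 1e-4)

    deme_index = np.repeat(np.arange(n_demes), cfg.n_per_deme)
    n_founders = len(deme_index)
    geno = rng.binomial(2, p_deme[deme_index]).astype(np.int8)

    ids = [f"S{i:05d}" for i in range(n_founders)]
    demes = [f"POP{d}" for d in deme_index]

    # pedigree relatives, gene-dropped from deme-0 founders
    ped_rows = []
    extra_geno = []
    extra_demes = []
    counter = n_founders

    def _child_of(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
        a1 = rng.random(cfg.n_snps) < g1 / 2.0
        a2 = rng.random(cfg.n_snps) < g2 / 2.0
        return (a1.astype(np.int8) + a2.astype(np.int8))

    def _founder() -> np.ndarray:
        return rng.binomial(2, p_deme[0]).astype(np.int8)

    for kind, count in cfg.pedigree_spec.items():
        for _ in range(count):
            if kind == "duplicate":
                src = int(rng.integers(0, min(cfg.n_per_deme[0], n_founders)))
                new = geno[src].copy()
                pair = (ids[src], f"S{counter:05d}")
            elif kind == "parent_offspring":
                src = int(rng.integers(0, min(cfg.n_per_deme[0], n_founders)))
                new = _child_of(geno[src], _founder())
                pair = (ids[src], f"S{counter:05d}")
            elif kind == "full_sib":
                pa, pb = _founder(), _founder()
                s1, s2 = _child_of(pa, pb), _child_of(pa, pb)
                extra_geno.append(s1)
                extra_demes.append("POP0")
                first = f"S{counter:05d}"
                counter += 1
                new = s2
                pair = (first, f"S{counter:05d}")
            elif kind == "second_degree":
                shared = _founder()
                s1 = _child_of(shared, _founder())
                s2 = _child_of(shared, _founder())
                extra_geno.append(s1)
                extra_demes.append("POP0")
                first = f"S{counter:05d}"
                counter += 1
                new = s2
                pair = (first, f"S{counter:05d}")
            else:
                raise ValueError(f"unknown pedigree pair kind {kind!r}")
            extra_geno.append(new)
            extra_demes.append("POP0")
            ped_rows.append({"id1": pair[0], "id2": pair[1], "relation": kind})
            counter += 1

    if extra_geno:
        geno = np.vstack([geno, np.array(extra_geno, dtype=np.int8)])
        ids = ids + [f"S{i:05d}" for i in range(n_founders, counter)]
        demes = demes + extra_demes
        deme_index = np.concatenate(
            [deme_index, np.zeros(len(extra_demes), dtype=int)]
        )

    # binary phenotype from deme intercepts + planted loci
    prev = np.asarray(cfg.deme_prevalence, dtype=float)
    logit = np.log(prev / (1 - prev))[deme_index]
    for idx, orr in cfg.planted_loci:
        logit = logit + math.log(orr) * geno[:, idx]
    phenotype = (rng.random(len(ids)) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    pos = cfg.start_bp + cfg.spacing_bp * np.arange(cfg.n_snps, dtype=np.int64)
    pos = pos + rng.integers(0, max(cfg.spacing_bp // 3, 1), cfg.n_snps)
    pos = np.sort(pos)
    refalt = rng.integers(0, 4, size=(cfg.n_snps, 2))
    refalt[:, 1] = (refalt[:, 0] + 1 + rng.integers(0, 3, cfg.n_snps)) % 4
    bases = np.array(list("ACGT"))
    gm = GenotypeMatrix(
        sample_ids=ids,
        chrom=np.full(cfg.n_snps, cfg.chrom, dtype=object),
        pos=pos,
        ref=bases[refalt[:, 0]],
        alt=bases[refalt[:, 1]],
        genotypes=geno,
    )
    samples = pd.DataFrame(
        {
            "sample_id": ids,
            "population": demes,
            "sex": rng.choice(["F", "M"], size=len(ids)),
            "wolbachia": rng.random(len(ids)) < 0.1,
        }
    )
    pedigree = pd.DataFrame(ped_rows, columns=["id1", "id2", "relation"])
    return gm, pd.Series(phenotype, index=ids, name="lineage"), samples, pedigree


# ---------------------------------------------------------------------------
# marker read sets


def simulate_wolbachia_readset(
    panel: dict[str, str],
    infected: bool,
    n_marker_reads: int = 5,
    read_len: int = 100,
    error_rate: float = 0.0,
    n_background_reads: int = 20,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Reads for one sample: marker substrings (if infected) plus random
    background sequence.  Returns (read_id, sequence) pairs; base qualities
    are constant and left to the FASTQ writer."""
    rng = np.random.default_rng(seed)
    if min(len(s) for s in panel.values()) < read_len:
        raise ValueError("read_len exceeds shortest panel sequence")
    reads: list[tuple[str, str]] = []
    if infected:
        marker_id = sorted(panel)[int(rng.integers(0, len(panel)))]
        marker = panel[marker_id]
        for i in range(n_marker_reads):
            start = int(rng.integers(0, len(marker) - read_len + 1))
            seq = np.frombuffer(marker[start : start + read_len].encode(), dtype=np.uint8).copy()
            if error_rate > 0:
                hit = rng.random(read_len) < error_rate
                shift = rng.integers(1, 4, size=read_len)
                codes = np.array([_BASE_CODE.get(chr(c), 0) for c in seq])
                codes[hit] = (codes[hit] + shift[hit]) % 4
                seq = np.frombuffer("".join("ACGT"[c] for c in codes).encode(), np.uint8)
            if rng.random() < 0.5:
                seq = _revcomp_bytes(seq)
            reads.append((f"marker_{i}", bytes(seq).decode()))
    for i in range(n_background_reads):
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, read_len))
        reads.append((f"bg_{i}", seq))
    return reads


_COMP = dict(zip(b"ACGTN", b"TGCAN"))


def _revcomp_bytes(seq: np.ndarray) -> np.ndarray:
    return np.array([_COMP.get(c, ord("N")) for c in seq[::-1]], dtype=np.uint8)


def write_fastq(reads: list[tuple[str, str]], path, quality: int = 35) -> None:
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qchar * len(seq)}\n")
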