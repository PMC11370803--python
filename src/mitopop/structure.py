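"""Population structure: sequence distances, AMOVA, pairwise FST, and
isolation-by-distance Mantel tests.

The variance decomposition follows the analysis of molecular variance of
Excoffier, Smouse & Quattro (1992): squared inter-haplotype distances are
partitioned across nested levels (between species/groups, among populations
within groups, within populations), variance components are extracted from
the expected mean squares with unequal-sample-size coefficients, and the
Phi-statistics are tested by the three standard permutation schemes.
Pairwise FST is the two-population Phi_ST from the same decomposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel

from .alignment import HaplotypeAlignment

EARTH_RADIUS_KM = 6371.0

DISTANCE_MODELS = ("p", "JC69", "K80", "HKY85", "TN93", "TN93_gamma")


@dataclass
class SequenceDistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray
    model: str = "p"
    gamma_alpha: float | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.sample_ids),) * 2:
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")


@dataclass
class AmovaResult:
    df: dict[str, int]
    ssd: dict[str, float]
    msd: dict[str, float]
    sigma: dict[str, float]
    percent: dict[str, float]
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_values: dict[str, float]
    permutations: int

    def table(self) -> pd.DataFrame:
        levels = ["among_groups", "among_populations", "within_populations"]
        total = sum(self.sigma.values())
        rows = [
            {
                "level": lv,
                "df": self.df[lv],
                "SSD": self.ssd[lv],
                "MSD": self.msd[lv],
                "sigma": self.sigma[lv],
                "percent": self.percent[lv],
                "phi": {"among_groups": self.phi_ct,
                        "among_populations": self.phi_sc,
                        "within_populations": self.phi_st}[lv],
                "p": self.p_values.get(lv, math.nan),
            }
            for lv in levels
        ]
        rows.append(
            {"level": "total", "df": sum(self.df.values()),
             "SSD": sum(self.ssd.values()), "MSD": math.nan,
             "sigma": total, "percent": 100.0, "phi": math.nan, "p": math.nan}
        )
        return pd.DataFrame(rows)


@dataclass
class FstMatrix:
    populations: list[str]
    fst: pd.DataFrame            # square
    long: pd.DataFrame           # pop1, pop2, fst, linearized, p
    permutations: int


@dataclass
class IbdResult:
    mantel_r: float
    p_value: float
    permutations: int
    r_squared: float
    populations: list[str]
    distance_transform: str = "log10 great-circle km"


# ---------------------------------------------------------------------------
# sequence distances


def _pair_counts(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise compared-site, mismatch, AG-transition and CT-transition
    counts under pairwise deletion (vectorised over all pairs)."""
    n, L = mat.shape
    valid = mat < 4
    compared = np.zeros((n, n))
    mism = np.zeros((n, n))
    ts_ag = np.zeros((n, n))
    ts_ct = np.zeros((n, n))
    for i in range(n):
        vi = valid[i]
        both = valid & vi  # (n, L)
        compared[i] = both.sum(axis=1)
        diff = (mat != mat[i]) & both
        mism[i] = diff.sum(axis=1)
        a, b = mat[i], mat
        ag = diff & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0)))
        ct = diff & (((a == 1) & (b == 3)) | ((a == 3) & (b == 1)))
        ts_ag[i] = ag.sum(axis=1)
        ts_ct[i] = ct.sum(axis=1)
    return compared, mism, ts_ag, ts_ct


def _safe_log(x: np.ndarray) -> np.ndarray:
    out = np.full_like(x, np.nan, dtype=float)
    ok = x > 0
    out[ok] = np.log(x[ok])
    return out


def _gamma_log(x: np.ndarray, alpha: float | None) -> np.ndarray:
    """-log(x), or its gamma rate-heterogeneity transform alpha*(x^(-1/alpha)-1)."""
    if alpha is None:
        return -_safe_log(x)
    out = np.full_like(x, np.nan, dtype=float)
    ok = x > 0
    out[ok] = alpha * (np.power(x[ok], -1.0 / alpha) - 1.0)
    return out


def genetic_distance_matrix(
    aln: HaplotypeAlignment,
    model: str = "p",
    gamma_alpha: float | None = None,
) -> SequenceDistanceMatrix:
    """Pairwise sequence distances under a standard substitution model.

    p-distance is mismatches over compared sites (pairwise deletion);
    JC69/K80/TN93 use their closed-form corrections, HKY85 is evaluated
    with the TN93 closed form (of which it is a special case).  TN93_gamma
    applies the gamma rate-heterogeneity transform with shape
    ``gamma_alpha``.  Saturated pairs (non-positive log argument) yield NaN
    with a warning left to the caller via the NaN sentinel.
    """
    if model not in DISTANCE_MODELS:
        raise ValueError(f"unknown model {model!r}")
    mat = aln.matrix
    compared, mism, ts_ag, ts_ct = _pair_counts(mat)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(compared > 0, mism / compared, np.nan)
    alpha = gamma_alpha if model == "TN93_gamma" else None
    if model == "p":
        d = p
    elif model == "JC69":
        d = 0.75 * _gamma_log(1.0 - 4.0 * p / 3.0, None)
    elif model == "K80":
        with np.errstate(divide="ignore", invalid="ignore"):
            P = (ts_ag + ts_ct) / compared
            Q = p - P
        d = 0.5 * (-_safe_log(1 - 2 * P - Q)) + 0.25 * (-_safe_log(1 - 2 * Q))
    else:  # TN93 family (HKY85 evaluated with the same closed form)
        freqs = np.array([(mat == b).sum() for b in range(4)], dtype=float)
        freqs /= freqs.sum()
        pa, pc, pg, pt = freqs
        pr, py = pa + pg, pc + pt
        with np.errstate(divide="ignore", invalid="ignore"):
            P1 = ts_ag / compared
            P2 = ts_ct / compared
            Q = p - P1 - P2
        k1 = 2 * pa * pg / pr
        k2 = 2 * pc * pt / py
        k3 = 2 * (pr * py - pa * pg * py / pr - pc * pt * pr / py)
        w1 = 1 - P1 / k1 - Q / (2 * pr)
        w2 = 1 - P2 / k2 - Q / (2 * py)
        w3 = 1 - Q / (2 * pr * py)
        d = k1 * _gamma_log(w1, alpha) + k2 * _gamma_log(w2, alpha) + k3 * _gamma_log(w3, alpha)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise
    return SequenceDistanceMatrix(list(aln.sample_ids), d, model=model, gamma_alpha=alpha)


# ---------------------------------------------------------------------------
# AMOVA


def _ssd_within(d2: np.ndarray, labels: np.ndarray) -> float:
    """Sum over groups of (sum of squared distances within) / group size."""
    total = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        total += sub.sum() / (2.0 * len(idx))
    return total


def _three_level_components(
    d2: np.ndarray, pop: np.ndarray, grp_of_pop: dict
) -> tuple[dict, dict, dict, dict]:
    N = len(pop)
    pops, pop_sizes = np.unique(pop, return_counts=True)
    grp = np.array([grp_of_pop[p] for p in pop])
    groups = np.unique(grp)
    P, G = len(pops), len(groups)
    size_of = dict(zip(pops, pop_sizes))

    ssd_total = d2.sum() / (2.0 * N)
    ssd_wp = _ssd_within(d2, pop)
    ssd_wg = _ssd_within(d2, grp)
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    df = {"among_groups": G - 1, "among_populations": P - G, "within_populations": N - P}
    ssd = {"among_groups": ssd_ag, "among_populations": ssd_ap, "within_populations": ssd_wp}
    msd = {k: (ssd[k] / df[k] if df[k] > 0 else math.nan) for k in ssd}

    # unequal-size coefficients of the expected mean squares
    sum_n2_over_ng = 0.0
    sum_ng2 = 0.0
    for g in groups:
        members = [p for p in pops if grp_of_pop[p] == g]
        ng = sum(size_of[p] for p in members)
        sum_n2_over_ng += sum(size_of[p] ** 2 for p in members) / ng
        sum_ng2 += ng**2
    n_coef = (N - sum_n2_over_ng) / (P - G)
    n_prime = (sum_n2_over_ng - sum(v**2 for v in size_of.values()) / N) / (G - 1)
    n_dprime = (N - sum_ng2 / N) / (G - 1)

    sig_c = msd["within_populations"]
    sig_b = (msd["among_populations"] - sig_c) / n_coef
    sig_a = (msd["among_groups"] - sig_c - n_prime * sig_b) / n_dprime
    sigma = {"among_groups": sig_a, "among_populations": sig_b, "within_populations": sig_c}
    return df, ssd, msd, sigma


def phi_statistics(sigma: dict[str, float]) -> tuple[float, float, float]:
    """(phi_ct, phi_sc, phi_st) from the three variance components."""
    a, b, c = (sigma["among_groups"], sigma["among_populations"], sigma["within_populations"])
    total = a + b + c
    return a / total, b / (b + c), (a + b) / total


def amova(
    dm: SequenceDistanceMatrix,
    populations: dict[str, str] | pd.Series,
    groups: dict[str, str] | None,
    permutations: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA on squared sequence distances.

    With ``groups`` (population -> group), the full three-level design
    (groups / populations within groups / within populations); with
    ``groups=None``, the single-level among/within-population
    decomposition whose Phi_ST is the quantity behind pairwise FST.
    Permutation p-values use the scheme appropriate
    to each Phi: samples among populations within groups (Phi_SC), whole
    populations among groups (Phi_CT), samples among all populations
    (Phi_ST); all with the add-one correction.
    """
    if isinstance(populations, pd.Series):
        populations = populations.to_dict()
    pop = np.array([populations[s] for s in dm.sample_ids])
    pops, pop_sizes = np.unique(pop, return_counts=True)
    if (pop_sizes < 2).any():
        bad = pops[pop_sizes < 2].tolist()
        raise ValueError(f"singleton populations break the design: {bad}")
    if groups is None:
        return _one_level_amova(dm, pop, permutations, seed)
    grp_labels = {g for g in groups.values()}
    if len(grp_labels) < 2:
        raise ValueError("need at least 2 groups")
    if all(v == 1 for v in pd.Series([groups[p] for p in pops]).value_counts()):
        raise ValueError(
            "every group holds a single population; use groups=None for a "
            "one-level decomposition"
        )
    d2 = dm.d**2
    df, ssd, msd, sigma = _three_level_components(d2, pop, groups)
    phi_ct, phi_sc, phi_st = phi_statistics(sigma)
    total = sum(sigma.values())
    percent = {k: 100.0 * max(v, 0.0) / total for k, v in sigma.items()}

    rng = np.random.default_rng(seed)
    grp = np.array([groups[p] for p in pop])
    hits = {"among_groups": 0, "among_populations": 0, "within_populations": 0}
    for _ in range(permutations):
        # Phi_ST: samples among all populations
        perm_pop = rng.permutation(pop)
        st = phi_statistics(_three_level_components(d2, perm_pop, groups)[3])[2]
        if st >= phi_st:
            hits["within_populations"] += 1
        # Phi_SC: samples among populations within their group
        perm = pop.copy()
        for g in np.unique(grp):
            idx = np.flatnonzero(grp == g)
            perm[idx] = perm[idx][rng.permutation(len(idx))]
        sc = phi_statistics(_three_level_components(d2, perm, groups)[3])[1]
        if sc >= phi_sc:
            hits["among_populations"] += 1
        # Phi_CT: whole populations among groups
        shuffled = rng.permutation([groups[p] for p in pops])
        gmap = dict(zip(pops, shuffled))
        ct = phi_statistics(_three_level_components(d2, pop, gmap)[3])[0]
        if ct >= phi_ct:
            hits["among_groups"] += 1
    p_values = {k: (1 + v) / (1 + permutations) for k, v in hits.items()}
    return AmovaResult(
        df=df, ssd=ssd, msd=msd, sigma=sigma, percent=percent,
        phi_ct=phi_ct, phi_sc=phi_sc, phi_st=phi_st,
        p_values=p_values, permutations=permutations,
    )


def _one_level_amova(
    dm: SequenceDistanceMatrix, pop: np.ndarray, permutations: int, seed
) -> AmovaResult:
    """Single-level decomposition (among / within populations)."""
    d2 = dm.d**2
    N = len(pop)
    pops, sizes = np.unique(pop, return_counts=True)
    K = len(pops)
    ssd_total = d2.sum() / (2.0 * N)
    ssd_wp = _ssd_within(d2, pop)
    ssd_ap = ssd_total - ssd_wp
    df = {"among_groups": 0, "among_populations": K - 1, "within_populations": N - K}
    ssd = {"among_groups": 0.0, "among_populations": ssd_ap, "within_populations": ssd_wp}
    msd = {
        "among_groups": math.nan,
        "among_populations": ssd_ap / (K - 1),
        "within_populations": ssd_wp / (N - K),
    }
    n0 = (N - (sizes**2).sum() / N) / (K - 1)
    sig_w = msd["within_populations"]
    sig_a = (msd["among_populations"] - sig_w) / n0
    sigma = {"among_groups": 0.0, "among_populations": sig_a, "within_populations": sig_w}
    total = sig_a + sig_w
    phi_st = sig_a / total if total else math.nan
    percent = {
        k: (100.0 * max(v, 0.0) / total if total else math.nan)
        for k, v in sigma.items()
    }
    rng = np.random.default_rng(seed)
    if math.isnan(phi_st):
        p = math.nan
    else:
        hits = 0
        for _ in range(permutations):
            if _two_pop_phist(d2, rng.permutation(pop)) >= phi_st:
                hits += 1
        p = (1 + hits) / (1 + permutations)
    return AmovaResult(
        df=df, ssd=ssd, msd=msd, sigma=sigma, percent=percent,
        phi_ct=math.nan, phi_sc=math.nan, phi_st=phi_st,
        p_values={"within_populations": p}, permutations=permutations,
    )


def _two_pop_phist(d2: np.ndarray, labels: np.ndarray) -> float:
    """Phi_ST of a one-level (two or more population) AMOVA."""
    N = len(labels)
    pops, sizes = np.unique(labels, return_counts=True)
    K = len(pops)
    ssd_total = d2.sum() / (2.0 * N)
    ssd_wp = _ssd_within(d2, labels)
    ssd_ap = ssd_total - ssd_wp
    df_a, df_w = K - 1, N - K
    msd_w = ssd_wp / df_w
    msd_a = ssd_ap / df_a
    n0 = (N - (sizes**2).sum() / N) / (K - 1)
    sig_w = msd_w
    sig_a = (msd_a - msd_w) / n0
    denom = sig_a + sig_w
    if denom == 0:
        return math.nan  # monomorphic data carry no differentiation signal
    return sig_a / denom


def pairwise_fst(
    dm: SequenceDistanceMatrix,
    populations: dict[str, str] | pd.Series,
    permutations: int = 1000,
    seed: int | None = None,
) -> FstMatrix:
    """Distance-based pairwise Phi_ST between all population pairs, with
    label-permutation p-values and the linearized value fst/(1-fst)
    (NaN sentinel at fst = 1)."""
    if isinstance(populations, pd.Series):
        populations = populations.to_dict()
    pop = np.array([populations[s] for s in dm.sample_ids])
    pops, sizes = np.unique(pop, return_counts=True)
    if (sizes < 2).any():
        raise ValueError("each population needs >= 2 samples")
    rng = np.random.default_rng(seed)
    d2 = dm.d**2
    square = pd.DataFrame(0.0, index=pops, columns=pops)
    rows = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            idx = np.flatnonzero((pop == pops[i]) | (pop == pops[j]))
            sub = d2[np.ix_(idx, idx)]
            labels = pop[idx]
            fst = _two_pop_phist(sub, labels)
            if math.isnan(fst):
                pval = math.nan
            else:
                hits = 0
                for _ in range(permutations):
                    if _two_pop_phist(sub, rng.permutation(labels)) >= fst:
                        hits += 1
                pval = (1 + hits) / (1 + permutations)
            lin = fst / (1 - fst) if fst < 1 else math.nan
            square.loc[pops[i], pops[j]] = square.loc[pops[j], pops[i]] = fst
            rows.append(
                {"pop1": pops[i], "pop2": pops[j], "fst": fst,
                 "linearized": lin, "p": pval}
            )
    return FstMatrix(list(pops), square, pd.DataFrame(rows), permutations)


def haplotype_fst(
    aln: HaplotypeAlignment, populations: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Frequency-only haplotype FST (Nei's GST) between population pairs.

    Treats each distinct cleaned sequence as an allele and computes
    (H_T - H_S)/H_T from haplotype frequencies, ignoring sequence
    divergence; a sensitivity alternative to the distance-based Phi_ST.
    """
    if isinstance(populations, pd.Series):
        populations = populations.to_dict()
    _, inv = np.unique(aln.matrix, axis=0, return_inverse=True)
    pop = np.array([populations[s] for s in aln.sample_ids])
    pops = np.unique(pop)
    rows = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            freqs = []
            for p in (pops[i], pops[j]):
                hap = inv[pop == p]
                freqs.append(np.bincount(hap, minlength=inv.max() + 1) / len(hap))
            hs = float(np.mean([1 - (f**2).sum() for f in freqs]))
            fbar = (freqs[0] + freqs[1]) / 2
            ht = float(1 - (fbar**2).sum())
            rows.append(
                {"pop1": pops[i], "pop2": pops[j],
                 "fst": (ht - hs) / ht if ht > 0 else math.nan}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# isolation by distance


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (Earth radius 6,371 km)."""
    la1, lo1, la2, lo2 = map(math.radians, (lat1, lon1, lat2, lon2))
    h = (
        math.sin((la2 - la1) / 2) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


def mantel_ibd(
    fst: FstMatrix | pd.DataFrame,
    coords: pd.DataFrame,
    permutations: int = 1000,
    seed: int | None = None,
    exclusions: list[str] | None = None,
    alternative: str = "greater",
    linearize: bool = True,
) -> IbdResult:
    """Mantel correlation of linearized FST with log10 great-circle
    distance between population centroids.

    ``coords`` needs columns population/latitude/longitude (one row per
    population).  The permutation test shuffles rows and columns of the
    geographic matrix jointly; default is one-sided for positive
    association.
    """
    square = fst.fst if isinstance(fst, FstMatrix) else fst
    coords = coords.set_index("population") if "population" in coords.columns else coords
    keep = [p for p in square.index if not (exclusions and p in exclusions)]
    if len(keep) < 4:
        raise ValueError("need at least 4 populations after exclusions")
    gmat = square.loc[keep, keep].to_numpy(dtype=float)
    if linearize:
        if np.any(gmat >= 1.0):
            raise ValueError("fst = 1 cannot be linearized; exclude the pair")
        gmat = gmat / (1.0 - gmat)
        np.fill_diagonal(gmat, 0.0)
    geo = np.zeros_like(gmat)
    for i, a in enumerate(keep):
        for j, b in enumerate(keep):
            if i < j:
                km = haversine_km(
                    coords.loc[a, "latitude"], coords.loc[a, "longitude"],
                    coords.loc[b, "latitude"], coords.loc[b, "longitude"],
                )
                if km <= 0:
                    raise ValueError(
                        f"zero great-circle distance between {a} and {b}; "
                        "jitter coordinates or exclude one population"
                    )
                geo[i, j] = geo[j, i] = math.log10(km)
    r, p, n_used = _skbio_mantel(
        DistanceMatrix(gmat, ids=keep),
        DistanceMatrix(geo, ids=keep),
        method="pearson",
        permutations=permutations,
        alternative=alternative,
        seed=seed,
    )
    return IbdResult(
        mantel_r=float(r), p_value=float(p), permutations=permutations,
        r_squared=float(r) ** 2, populations=keep,
    )
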