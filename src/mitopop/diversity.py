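"""Per-group diversity and neutrality statistics for haploid alignments.

Implements the classical summary statistics for a sample of n haploid
sequences: segregating sites S, singletons, mean pairwise differences K,
haplotype count/diversity, nucleotide diversity pi, Watterson's theta,
Tajima's D with a conditional-on-S simulation p-value, and Achaz's Y — a
Tajima-like statistic whose estimators ignore singletons and is therefore
robust to sequencing error.  Between-group divergence (Dxy, net divergence
Da) and a molecular-clock split-time converter are included.

Missing data are handled by *complete deletion* by default: any column
containing N or '-' in the analysed group is excluded, and ``L_effective``
records what remains.  Statistics that are undefined on a degenerate group
(S = 0) are reported as NaN sentinels, never silently as zero.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass

import numpy as np

from .alignment import HaplotypeAlignment, N as N_CODE

__all__ = [
    "SiteFrequencySpectrum",
    "DiversityRecord",
    "GroupDivergence",
    "folded_sfs",
    "diversity_summary",
    "tajimas_d",
    "tajima_significance",
    "achaz_y",
    "achaz_y_from_sfs",
    "achaz_y_numerator",
    "achaz_y_analytic_sd",
    "achaz_y_null_sd",
    "achaz_y_montecarlo",
    "between_group_divergence",
    "split_time_estimate",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class SiteFrequencySpectrum:
    """Folded site-frequency spectrum of a group of n haploid sequences.

    ``counts[j-1]`` is the number of polymorphic sites whose minor allele
    occurs in exactly j sequences, j = 1 .. floor(n/2).  Sites with more
    than two alleles contribute through their minor count n - (major count).
    """

    n: int
    counts: np.ndarray
    L_effective: int

    @property
    def S(self) -> int:
        return int(self.counts.sum())

    @property
    def singletons(self) -> int:
        return int(self.counts[0]) if len(self.counts) else 0


@dataclass
class DiversityRecord:
    group: str
    n: int
    L_effective: int
    S: int
    singletons: int
    shared_polymorphisms: int
    K: float
    H: int
    HD: float
    pi: float
    theta_w: float
    tajimas_d: float
    tajimas_d_p: float
    achaz_y: float


@dataclass
class GroupDivergence:
    dxy_total: float
    dxy_per_site: float
    pi_within_a: float
    pi_within_b: float
    da: float
    L_effective: int


# ---------------------------------------------------------------------------
# column machinery


def _rows_for(aln: HaplotypeAlignment, group) -> np.ndarray:
    if group is None:
        return np.arange(aln.n)
    pos = {s: i for i, s in enumerate(aln.sample_ids)}
    return np.asarray([pos[s] for s in group], dtype=int)


def _complete_columns(mat: np.ndarray) -> np.ndarray:
    """Mask of columns with no N/gap in any row (complete deletion)."""
    return (mat < N_CODE).all(axis=0)


def _base_counts(mat: np.ndarray) -> np.ndarray:
    """(4, L) counts of A/C/G/T per column; rows must be gap/N free."""
    return np.stack([(mat == b).sum(axis=0) for b in range(4)])


def _pairdiff_stats(counts: np.ndarray, n: int) -> tuple[np.ndarray, float]:
    """Per-column count of differing pairs and the total over columns."""
    npairs = n * (n - 1) / 2.0
    same = (counts * (counts - 1) / 2.0).sum(axis=0)
    diff = npairs - same
    return diff, float(diff.sum())


def folded_sfs(aln: HaplotypeAlignment, group=None, deletion: str = "complete") -> SiteFrequencySpectrum:
    """Folded SFS of a sample subset under the chosen deletion rule."""
    rows = _rows_for(aln, group)
    if len(rows) < 2:
        raise ValueError("need at least 2 sequences for an SFS")
    mat = aln.matrix[rows]
    n = len(rows)
    if deletion != "complete":
        raise ValueError("folded_sfs supports complete deletion only")
    keep = _complete_columns(mat)
    counts = _base_counts(mat[:, keep])
    minor = n - counts.max(axis=0)
    poly = minor > 0
    xi = np.bincount(minor[poly], minlength=n // 2 + 1)[1 : n // 2 + 1]
    return SiteFrequencySpectrum(n=n, counts=xi.astype(int), L_effective=int(keep.sum()))


# ---------------------------------------------------------------------------
# Tajima's D


def _harmonic(n: int) -> float:
    return float(sum(1.0 / i for i in range(1, n)))


def tajimas_d(n: int, S: int, K: float) -> float:
    """Tajima's (1989) D from sample size, segregating sites and mean
    pairwise differences (all per locus).  NaN when S = 0."""
    if S == 0 or n < 4:
        return math.nan
    a1 = _harmonic(n)
    a2 = float(sum(1.0 / i**2 for i in range(1, n)))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (K - S / a1) / math.sqrt(var)


def _k_from_sfs(sfs: SiteFrequencySpectrum) -> float:
    n = sfs.n
    j = np.arange(1, len(sfs.counts) + 1)
    return float((sfs.counts * j * (n - j)).sum() / (n * (n - 1) / 2.0))


def tajima_significance(
    d_obs: float, n: int, S: int, reps: int = 1000, seed: int | None = None
) -> float:
    """Two-sided empirical p-value for Tajima's D under the standard neutral
    coalescent conditioned on the observed number of segregating sites.

    Uses the add-one correction (1 + hits) / (1 + reps) so p is never zero.
    """
    if not math.isfinite(d_obs) or S < 1:
        return math.nan
    from . import simulate  # deferred: simulate does not depend on this module

    hits = 0
    for sfs in simulate.neutral_null_replicates(n, S, reps, seed=seed):
        d_null = tajimas_d(n, sfs.S, _k_from_sfs(sfs))
        if abs(d_null) >= abs(d_obs):
            hits += 1
    return (1 + hits) / (1 + reps)


# ---------------------------------------------------------------------------
# Achaz's Y (folded, singleton-free)


@functools.lru_cache(maxsize=64)
def _fu_sigma(n: int) -> np.ndarray:
    """Second-moment coefficients sigma_ij of the unfolded SFS under the
    standard neutral model (Fu 1995), for 1 <= i, j <= n-1."""
    an = np.zeros(n + 2)
    for k in range(2, n + 2):
        an[k] = an[k - 1] + 1.0 / (k - 1)  # an[k] = sum_{i<k} 1/i

    def beta(i: int) -> float:
        return 2.0 * n / ((n - i + 1.0) * (n - i)) * (an[n + 1] - an[i]) - 2.0 / (n - i)

    sig = np.zeros((n, n))  # index by 1-based i, j
    for i in range(1, n):
        if 2 * i < n:
            sig[i, i] = beta(i + 1)
        elif 2 * i == n:
            sig[i, i] = 2.0 * (an[n] - an[i]) / (n - i) - 1.0 / i**2
        else:
            sig[i, i] = beta(i) - 1.0 / i**2
    for i in range(2, n):
        for j in range(1, i):
            if i + j < n:
                sig[i, j] = (beta(i + 1) - beta(i)) / 2.0
            elif i + j == n:
                sig[i, j] = (
                    (an[n] - an[i]) / (n - i)
                    + (an[n] - an[j]) / (n - j)
                    - (beta(i) + beta(j + 1)) / 2.0
                    - 1.0 / (i * j)
                )
            else:
                sig[i, j] = (beta(j) - beta(j + 1)) / 2.0 - 1.0 / (i * j)
            sig[j, i] = sig[i, j]
    return sig[1:, 1:]  # (n-1, n-1), 0-based for i-1, j-1


def _achaz_weights(n: int) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Unfolded-class weights of the two singleton-free estimators.

    Both exclude classes 1 and n-1 (folded data cannot separate them), so
    the resulting statistic is computable from a folded spectrum: pairwise
    estimator weight i(n-i), Watterson-type weight constant 1.
    """
    i = np.arange(1, n)
    keep = (i >= 2) & (i <= n - 2)
    w_pi = np.where(keep, n - i, 0.0)  # omega_i; theta_hat = sum(omega*i*xi)/sum(omega)
    w_w = np.where(keep, 1.0 / i, 0.0)
    return w_pi, w_w, float(w_pi.sum()), float(w_w.sum())


def achaz_y_from_sfs(sfs: SiteFrequencySpectrum) -> float:
    """Achaz's Y from a folded SFS (analytic standardization).

    Numerator: singleton-free pairwise estimator minus singleton-free
    Watterson estimator (per locus).  Denominator: its standard deviation
    under the standard neutral model from the Fu (1995) xi covariances,
    with theta and theta^2 plugged in from the singleton-free S.
    """
    sd = achaz_y_analytic_sd(sfs)
    if not math.isfinite(sd) or sd <= 0:
        return math.nan
    return achaz_y_numerator(sfs) / sd


def achaz_y_analytic_sd(sfs: SiteFrequencySpectrum) -> float:
    """Neutral-model SD of Y's numerator from the Fu (1995) covariances,
    with theta and theta^2 plugged in from the singleton-free S."""
    n = sfs.n
    if n < 5:
        return math.nan
    w_pi, w_w, W_pi, W_w = _achaz_weights(n)
    s_star = int(sfs.counts[1:].sum())
    if s_star == 0:
        return math.nan
    i = np.arange(1, n)
    omega = w_pi / W_pi - w_w / W_w
    sig = _fu_sigma(n)
    alpha = float((i * omega**2).sum())
    beta = float(((i * omega)[:, None] * (i * omega)[None, :] * sig).sum())
    # unbiased theta / theta^2 plug-ins from the singleton-free class total
    mask = (i >= 2) & (i <= n - 2)
    B = float(sig[np.ix_(mask, mask)].sum())
    theta = s_star / W_w
    theta2 = s_star * max(s_star - 1, 0) / (W_w**2 + B)
    var = alpha * theta + beta * theta2
    if var <= 0:
        return math.nan
    return math.sqrt(var)


def achaz_y_numerator(sfs: SiteFrequencySpectrum) -> float:
    """theta_pi* - theta_W*, both excluding singleton classes (per locus)."""
    n = sfs.n
    j = np.arange(1, len(sfs.counts) + 1)
    _, _, W_pi, W_w = _achaz_weights(n)
    nonsing = (j >= 2) & (j <= n - 2)  # minor-count classes kept
    theta_pi = float((sfs.counts * j * (n - j) * nonsing).sum() / W_pi)
    s_star = int((sfs.counts * nonsing).sum())
    if n % 2 == 0 and len(sfs.counts) == n // 2:
        pass  # the n/2 class is its own fold; weights already correct
    theta_w = s_star / W_w
    return theta_pi - theta_w


def achaz_y(
    aln: HaplotypeAlignment, group=None, standardization: str = "analytic",
    reps: int = 1000, seed: int | None = None,
) -> float:
    """Achaz's Y for a group; ``standardization`` is "analytic" (Fu-1995
    covariances) or "montecarlo" (SD of the numerator over fixed-S neutral
    replicates)."""
    sfs = folded_sfs(aln, group)
    if standardization == "analytic":
        return achaz_y_from_sfs(sfs)
    if standardization == "montecarlo":
        return achaz_y_montecarlo(sfs, reps=reps, seed=seed)
    raise ValueError(f"unknown standardization {standardization!r}")


def achaz_y_montecarlo(
    sfs: SiteFrequencySpectrum, reps: int = 1000, seed: int | None = None
) -> float:
    """Y standardized by the Monte-Carlo SD of its numerator under the
    fixed-S neutral null (cross-check for the analytic form)."""
    from . import simulate

    num = achaz_y_numerator(sfs)
    if not math.isfinite(num) or sfs.S < 1:
        return math.nan
    sd = achaz_y_null_sd(sfs.n, sfs.S, reps=reps, seed=seed)
    if not sd:
        return math.nan
    return num / sd


def achaz_y_null_sd(n: int, S: int, reps: int = 1000, seed: int | None = None) -> float:
    """Monte-Carlo SD of Y's numerator over fixed-S neutral replicates."""
    from . import simulate

    nulls = [
        achaz_y_numerator(rep)
        for rep in simulate.neutral_null_replicates(n, S, reps, seed=seed)
    ]
    return float(np.std(nulls, ddof=1))


# ---------------------------------------------------------------------------
# per-group summary


def diversity_summary(
    aln: HaplotypeAlignment,
    group=None,
    group_label: str = "all",
    tajima_p_reps: int = 0,
    seed: int | None = None,
) -> DiversityRecord:
    """Tabular diversity summary of a sample subset (complete deletion).

    ``tajima_p_reps`` > 0 adds the conditional-on-S simulation p-value for
    Tajima's D (NaN otherwise).
    """
    rows = _rows_for(aln, group)
    n = len(rows)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    mat = aln.matrix[rows]
    keep = _complete_columns(mat)
    sub = mat[:, keep]
    L_eff = int(keep.sum())
    if L_eff == 0:
        raise ValueError("no complete columns in group")
    counts = _base_counts(sub)
    minor = n - counts.max(axis=0)
    S = int((minor > 0).sum())
    sing = int((minor == 1).sum())
    _, total_diff = _pairdiff_stats(counts, n)
    K = total_diff / (n * (n - 1) / 2.0)
    # haplotypes over the cleaned columns
    uniq, inv = np.unique(sub, axis=0, return_inverse=True)
    H = uniq.shape[0]
    freqs = np.bincount(inv) / n
    HD = n / (n - 1.0) * (1.0 - float((freqs**2).sum()))
    pi = K / L_eff
    theta_w = S / (_harmonic(n) * L_eff)
    d = tajimas_d(n, S, K)
    d_p = math.nan
    if tajima_p_reps and math.isfinite(d):
        d_p = tajima_significance(d, n, S, reps=tajima_p_reps, seed=seed)
    y = achaz_y_from_sfs(SiteFrequencySpectrum(n, np.bincount(minor[minor > 0], minlength=n // 2 + 1)[1 : n // 2 + 1], L_eff)) if S else math.nan
    return DiversityRecord(
        group=group_label, n=n, L_effective=L_eff, S=S, singletons=sing,
        shared_polymorphisms=S - sing, K=K, H=H, HD=HD, pi=pi,
        theta_w=theta_w, tajimas_d=d, tajimas_d_p=d_p, achaz_y=y,
    )


# ---------------------------------------------------------------------------
# between-group divergence and split time


def between_group_divergence(
    aln: HaplotypeAlignment, group_a, group_b
) -> GroupDivergence:
    """Mean pairwise divergence between two disjoint groups (Dxy) together
    with within-group diversities and net divergence Da = Dxy - (piA+piB)/2.

    Complete deletion is applied over the union of the two groups so all
    three quantities share one effective length.
    """
    rows_a = _rows_for(aln, group_a)
    rows_b = _rows_for(aln, group_b)
    if set(rows_a) & set(rows_b):
        raise ValueError("groups overlap")
    mat = aln.matrix[np.concatenate([rows_a, rows_b])]
    keep = _complete_columns(mat)
    L_eff = int(keep.sum())
    sub = mat[:, keep]
    na, nb = len(rows_a), len(rows_b)
    ca = _base_counts(sub[:na])
    cb = _base_counts(sub[na:])
    # cross-group differing pairs per column: na*nb - sum_b ca_b*cb_b
    cross_same = (ca * cb).sum(axis=0)
    dxy_total = float((na * nb - cross_same).sum()) / (na * nb)
    pi_a = _pairdiff_stats(ca, na)[1] / (na * (na - 1) / 2.0) / L_eff if na > 1 else math.nan
    pi_b = _pairdiff_stats(cb, nb)[1] / (nb * (nb - 1) / 2.0) / L_eff if nb > 1 else math.nan
    dxy_site = dxy_total / L_eff
    da = dxy_site - np.nanmean([pi_a, pi_b])
    return GroupDivergence(
        dxy_total=dxy_total, dxy_per_site=dxy_site,
        pi_within_a=pi_a, pi_within_b=pi_b, da=float(da), L_effective=L_eff,
    )


def split_time_estimate(
    d_per_site: float, mu: float, generations_per_year: float = 10.0
) -> float:
    """Molecular-clock split time in years from a per-site divergence.

    Divergence accumulates at 2*mu per site per generation between two
    isolated lineages, so t = d / (2 mu) generations.  Pass net divergence
    (Da) to correct for ancestral polymorphism, or raw Dxy for the
    uncorrected clock.
    """
    if mu <= 0 or generations_per_year <= 0:
        raise ValueError("mu and generations_per_year must be positive")
    return d_per_site / (2.0 * mu) / generations_per_year
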