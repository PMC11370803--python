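"""Mitonuclear association: kinship pruning, LD pruning, PCA covariates,
the x2y cross-feature metric, and a covariate-adjusted GWAS of mtDNA
lineage membership.

The association model is a per-variant logistic regression of the binary
lineage label on additive allele dosage plus covariates (principal
components, sex, endosymbiont infection status), tested by the likelihood
ratio against the covariate-only model.  Genomic control is diagnosed with
the inflation factor lambda (median 1-df chi-square over 0.4549) and the
multiple-testing threshold is Bonferroni over the number of independent
(LD-pruned) variants.  Kinship uses the allele-frequency-free KING-robust
estimator; related samples are removed by the documented greedy rule
(most relationships first, ties broken by ascending sample id).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

# KING kinship ranges: powers-of-two cutoffs between relationship degrees
KING_DEGREE_CUTOFFS = [
    (0.354, "duplicate/MZ"),
    (0.177, "1st"),
    (0.0884, "2nd"),
    (0.0442, "3rd"),
]
DEGREE_ORDER = ["duplicate/MZ", "1st", "2nd", "3rd", "unrelated"]

MISSING = -1
CHI2_MEDIAN_1DF = 0.4549364231195724  # chi2.ppf(0.5, 1)


@dataclass
class GenotypeMatrix:
    """Biallelic nuclear SNP genotypes coded 0/1/2 alt-allele dosage.

    ``genotypes`` is (n_samples, n_variants) int8 with -1 for missing;
    positions are 1-based and sorted within chromosome.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.genotypes.shape != (len(self.sample_ids), len(self.pos)):
            raise ValueError("genotype matrix shape mismatch")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if not (np.diff(p) >= 0).all():
                raise ValueError(f"positions not sorted on {c}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def maf(self) -> np.ndarray:
        g = np.ma.masked_equal(self.genotypes, MISSING)
        p = g.mean(axis=0).filled(np.nan) / 2.0
        return np.minimum(p, 1 - p)

    def subset_samples(self, ids) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [pos[s] for s in ids]
        return GenotypeMatrix(
            list(ids), self.chrom, self.pos, self.ref, self.alt, self.genotypes[rows]
        )

    def subset_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            list(self.sample_ids), self.chrom[index], self.pos[index],
            self.ref[index], self.alt[index], self.genotypes[:, index],
        )

    # -- VCF round trip --------------------------------------------------
    def to_vcf(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in pd.unique(pd.Series(self.chrom)):
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.sample_ids) + "\n"
            )
            gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            for v in range(self.n_variants):
                calls = "\t".join(gt_code[int(g)] for g in self.genotypes[:, v])
                fh.write(
                    f"{self.chrom[v]}\t{self.pos[v]}\t.\t{self.ref[v]}\t"
                    f"{self.alt[v]}\t.\tPASS\t.\tGT\t{calls}\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        ids = list(vcf.samples)
        chrom, pos, ref, alt, rows = [], [], [], [], []
        skipped = 0
        for var in vcf:
            if len(var.ALT) != 1:
                skipped += 1
                continue
            chrom.append(var.CHROM)
            pos.append(var.POS)
            ref.append(var.REF)
            alt.append(var.ALT[0])
            g = var.gt_types.astype(np.int8)  # 0/1/2, 3=missing with gts012
            g[g == 3] = MISSING
            rows.append(g)
        if skipped:
            logger.warning("skipped %d non-biallelic records", skipped)
        return cls(
            ids, np.array(chrom, dtype=object), np.array(pos), np.array(ref, dtype=object),
            np.array(alt, dtype=object), np.array(rows, dtype=np.int8).T,
        )


# ---------------------------------------------------------------------------
# KING-robust kinship


def king_robust_kinship(
    g: GenotypeMatrix,
    pairs: list[tuple[str, str]] | None = None,
    populations: dict[str, str] | pd.Series | None = None,
    min_shared: int = 1000,
) -> pd.DataFrame:
    """KING-robust kinship coefficients (Manichaikul et al. 2010).

    phi = (N_het,het - 2 N_opp,hom) / (N_het_i + N_het_j), an allele-
    frequency-free estimator robust to population structure.  Pairs are
    either given explicitly or formed within populations.  Pairs sharing
    fewer than ``min_shared`` non-missing variants are skipped.
    """
    idx = {s: i for i, s in enumerate(g.sample_ids)}
    if pairs is None:
        if populations is not None:
            if isinstance(populations, pd.Series):
                populations = populations.to_dict()
            pairs = [
                (a, b)
                for i, a in enumerate(g.sample_ids)
                for b in g.sample_ids[i + 1 :]
                if populations[a] == populations[b]
            ]
        else:
            pairs = [
                (a, b)
                for i, a in enumerate(g.sample_ids)
                for b in g.sample_ids[i + 1 :]
            ]
    geno = g.genotypes
    rows = []
    for a, b in pairs:
        ga, gb = geno[idx[a]], geno[idx[b]]
        ok = (ga != MISSING) & (gb != MISSING)
        n_ok = int(ok.sum())
        if n_ok < min_shared:
            rows.append({"id1": a, "id2": b, "n_shared": n_ok, "phi": math.nan,
                         "degree": "skipped"})
            continue
        ha, hb = (ga == 1) & ok, (gb == 1) & ok
        n_hh = int((ha & hb).sum())
        n_opp = int((((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0))).sum())
        nha, nhb = int(ha.sum()), int(hb.sum())
        phi = (n_hh - 2.0 * n_opp) / (nha + nhb) if (nha + nhb) else math.nan
        rows.append(
            {"id1": a, "id2": b, "n_shared": n_ok, "n_het_het": n_hh,
             "n_opp_hom": n_opp, "n_het_1": nha, "n_het_2": nhb,
             "phi": phi, "degree": _degree(phi)}
        )
    return pd.DataFrame(rows)


def _degree(phi: float) -> str:
    if not math.isfinite(phi):
        return "skipped"
    for cut, name in KING_DEGREE_CUTOFFS:
        if phi > cut:
            return name
    return "unrelated"


def prune_related(
    estimates: pd.DataFrame, degree_threshold: str = "2nd"
) -> tuple[list[str], list[str]]:
    """Greedy removal of related samples.

    While any pair at or closer than ``degree_threshold`` remains, remove
    the sample with the most offending relationships, breaking ties by
    ascending alpha-numeric id.  Returns (kept, removed); deterministic and
    independent of input row order.
    """
    cutoff = DEGREE_ORDER.index(degree_threshold)
    offending = {
        d for d in DEGREE_ORDER[: cutoff + 1]
    }
    edges = {
        frozenset((r.id1, r.id2))
        for r in estimates.itertuples()
        if r.degree in offending
    }
    samples = sorted(set(estimates["id1"]) | set(estimates["id2"]))
    removed: list[str] = []
    edges = {tuple(sorted(e)) for e in edges}
    while edges:
        counts: dict[str, int] = {}
        for a, b in edges:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        worst = max(counts.values())
        victim = min(s for s, c in counts.items() if c == worst)
        removed.append(victim)
        edges = {e for e in edges if victim not in e}
    kept = [s for s in samples if s not in set(removed)]
    return kept, removed


# ---------------------------------------------------------------------------
# LD pruning


def _window_r2_prune(
    geno: np.ndarray, pos: np.ndarray, retained: np.ndarray,
    window_bp: int, step_bp: int, r2_max: float,
) -> int:
    """One sliding-window scan; drops later variants of correlated pairs
    in-place in `retained`; returns the number removed."""
    removed = 0
    if len(pos) == 0:
        return 0
    start = int(pos.min())
    stop = int(pos.max())
    w = start
    while w <= stop:
        in_win = np.flatnonzero(retained & (pos >= w) & (pos < w + window_bp))
        if len(in_win) > 1:
            sub = geno[:, in_win].astype(float)
            sub[sub == MISSING] = np.nan
            mu = np.nanmean(sub, axis=0)
            subc = np.nan_to_num(sub - mu)
            sd = subc.std(axis=0)
            for aa in range(len(in_win)):
                if not retained[in_win[aa]]:
                    continue
                for bb in range(aa + 1, len(in_win)):
                    if not retained[in_win[bb]]:
                        continue
                    if sd[aa] == 0 or sd[bb] == 0:
                        continue
                    r = (subc[:, aa] @ subc[:, bb]) / (len(subc) * sd[aa] * sd[bb])
                    if r * r >= r2_max:
                        retained[in_win[bb]] = False
                        removed += 1
        w += step_bp
    return removed


def ld_prune(
    g: GenotypeMatrix,
    window_bp: int = 500,
    step_bp: int = 200,
    r2_max: float = 0.1,
    passes: int = 5,
) -> np.ndarray:
    """Sliding-window LD pruning on dosage r-squared.

    Within each base-pair window the later variant of any pair with
    r^2 >= ``r2_max`` is dropped; the scan is repeated ``passes`` times or
    until no further removals.  Returns the boolean retained mask.
    """
    retained = np.ones(g.n_variants, dtype=bool)
    for _ in range(passes):
        removed = 0
        for c in pd.unique(pd.Series(g.chrom)):
            sel = np.flatnonzero(g.chrom == c)
            sub_ret = retained[sel].copy()
            removed += _window_r2_prune(
                g.genotypes[:, sel], g.pos[sel], sub_ret, window_bp, step_bp, r2_max
            )
            retained[sel] = sub_ret
        if removed == 0:
            break
    return retained


# ---------------------------------------------------------------------------
# PCA covariates


def pca_covariates(
    g: GenotypeMatrix,
    n_snps: int = 100_000,
    region: tuple[str, int, int] | None = None,
    n_components: int = 6,
    seed: int | None = None,
    prune: bool = True,
) -> pd.DataFrame:
    """Principal-component covariates from a random LD-pruned SNP subset.

    Dosages are centred per variant and scaled by sqrt(p(1-p)) (Patterson
    scaling); scores are the top components of the singular decomposition,
    z-normalised for covariate use.
    """
    rng = np.random.default_rng(seed)
    sel = np.arange(g.n_variants)
    if region is not None:
        c, lo, hi = region
        sel = np.flatnonzero((g.chrom == c) & (g.pos >= lo) & (g.pos <= hi))
    if len(sel) > n_snps:
        sel = np.sort(rng.choice(sel, size=n_snps, replace=False))
    else:
        logger.warning("only %d SNPs available (requested %d)", len(sel), n_snps)
    sub = g.subset_variants(sel)
    if prune:
        sub = sub.subset_variants(ld_prune(sub))
    x = sub.genotypes.astype(float)
    x[x == MISSING] = np.nan
    p = np.nanmean(x, axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    x, p = x[:, keep], p[keep]
    x = np.nan_to_num((x - 2 * p) / np.sqrt(p * (1 - p)))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0)
    return pd.DataFrame(
        scores, index=g.sample_ids, columns=[f"PC{i+1}" for i in range(k)]
    )


# ---------------------------------------------------------------------------
# x2y metric


@dataclass
class X2yResult:
    predictor: str
    response: str
    x2y: float
    ci_low: float
    ci_high: float
    resamples: int


def _is_categorical(v: pd.Series) -> bool:
    return (
        v.dtype == object
        or v.dtype == bool
        or isinstance(v.dtype, pd.CategoricalDtype)
    )


def _best_split(xv: np.ndarray, yv: np.ndarray) -> tuple[float, object, object]:
    """Threshold and side labels of the misclassification-minimising
    single split, via prefix class counts on sorted x."""
    order = np.argsort(xv, kind="stable")
    xs, ys = xv[order], yv[order]
    classes, codes = np.unique(ys, return_inverse=True)
    n, k = len(ys), len(classes)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), codes] = 1.0
    prefix = onehot.cumsum(axis=0)
    total = prefix[-1]
    # split after position i (0..n-2), only where x strictly increases
    valid = np.flatnonzero(np.diff(xs) > 0)
    if len(valid) == 0:
        maj = classes[int(np.argmax(total))]
        return math.inf, maj, maj
    left = prefix[valid]
    right = total - left
    err = (valid + 1 - left.max(axis=1)) + (n - valid - 1 - right.max(axis=1))
    j = int(np.argmin(err))
    cut = valid[j]
    thr = (xs[cut] + xs[cut + 1]) / 2.0
    return thr, classes[int(np.argmax(left[j]))], classes[int(np.argmax(right[j]))]


def _x2y_point(x: pd.Series, y: pd.Series, n_folds: int = 5) -> float:
    """Percent error reduction of the single-feature model over the
    baseline (mean prediction / majority class), estimated out of sample
    by K-fold cross-validation and floored at zero."""
    n = len(x)
    folds = np.arange(n) % n_folds
    base_err = 0.0
    model_err = 0.0
    y_cat = _is_categorical(y)
    x_cat = _is_categorical(x)
    xv_all = x.to_numpy()
    yv_all = y.to_numpy()
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        ytr, yte = yv_all[tr], yv_all[te]
        xtr, xte = xv_all[tr], xv_all[te]
        if y_cat:
            vals, counts = np.unique(ytr, return_counts=True)
            majority = vals[int(np.argmax(counts))]
            base_err += float((yte != majority).sum())
            if x_cat:
                rule = pd.Series(ytr).groupby(pd.Series(xtr)).agg(
                    lambda s: s.mode().iloc[0]
                )
                pred = pd.Series(xte).map(rule).fillna(majority).to_numpy()
            else:
                thr, cl, cr = _best_split(xtr.astype(float), ytr)
                pred = np.where(xte.astype(float) <= thr, cl, cr)
            model_err += float((yte != pred).sum())
        else:
            mu = float(ytr.mean())
            base_err += float(np.abs(yte.astype(float) - mu).sum())
            if x_cat:
                means = pd.Series(ytr.astype(float)).groupby(pd.Series(xtr)).mean()
                pred = pd.Series(xte).map(means).fillna(mu).to_numpy(float)
            else:
                res = stats.linregress(xtr.astype(float), ytr.astype(float))
                pred = res.intercept + res.slope * xte.astype(float)
            model_err += float(np.abs(yte.astype(float) - pred).sum())
    if base_err == 0:
        return math.nan
    return max(100.0 * (base_err - model_err) / base_err, 0.0)


def x2y_metric(
    x: pd.Series, y: pd.Series, resamples: int = 1000, seed: int | None = None
) -> X2yResult:
    """Association of x with y as percent reduction of prediction error.

    Continuous responses use a single-feature linear regression against a
    mean-prediction baseline (MAE); categorical responses use a one-split
    decision rule against the majority class.  Errors are estimated out of
    sample by 5-fold cross-validation and the reduction floored at 0, so
    independent features score 0 rather than picking up in-sample
    overfitting.  The 95% CI is a percentile bootstrap over paired
    observations.
    """
    x, y = pd.Series(x).reset_index(drop=True), pd.Series(y).reset_index(drop=True)
    if len(x) < 20:
        raise ValueError("need at least 20 paired observations")
    point = _x2y_point(x, y)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(resamples):
        idx = rng.integers(0, len(x), len(x))
        b = _x2y_point(x.iloc[idx].reset_index(drop=True), y.iloc[idx].reset_index(drop=True))
        if math.isfinite(b):
            boots.append(b)
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (math.nan, math.nan))
    return X2yResult(
        predictor=str(x.name), response=str(y.name), x2y=point,
        ci_low=float(lo), ci_high=float(hi), resamples=resamples,
    )


# ---------------------------------------------------------------------------
# GWAS


@dataclass
class AssocScan:
    results: pd.DataFrame  # chrom, pos, maf, beta, se, stat, p, converged
    lam: float
    bonferroni_threshold: float
    n_independent: int
    covariates: list[str] = field(default_factory=list)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _logistic_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10):
    """Plain Newton logistic fit; returns (beta, loglik, converged)."""
    beta = np.zeros(X.shape[1])
    ll_old = -math.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = _sigmoid(eta)
        w = mu * (1 - mu)
        ll = float(y @ eta - np.logaddexp(0, eta).sum())
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, ll, False
        beta = beta + step
        if abs(ll - ll_old) < tol:
            return beta, ll, True
        ll_old = ll
    return beta, ll, False


def _batched_snp_logistic(
    C: np.ndarray, G: np.ndarray, y: np.ndarray, beta0: np.ndarray,
    max_iter: int = 30, tol: float = 1e-8,
):
    """Per-SNP logistic fits of y ~ C + g, Newton iterations batched over
    SNPs with the covariate block shared.  Returns (beta_g, se_g, loglik,
    converged) arrays of length n_snps."""
    n, p = C.shape
    S = G.shape[1]
    # parameter matrix: (S, p+1); last column is the dosage effect
    B = np.tile(np.append(beta0, 0.0), (S, 1))
    O = (C[:, :, None] * C[:, None, :]).reshape(n, p * p)  # outer products
    ll = np.full(S, -np.inf)
    active = np.ones(S, dtype=bool)
    converged = np.zeros(S, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        Ba = B[idx]
        Ga = G[:, idx]
        eta = np.clip(C @ Ba[:, :p].T + Ga * Ba[:, p], -30, 30)  # (n, s)
        mu = _sigmoid(eta)
        w = mu * (1 - mu) + 1e-12
        r = y[:, None] - mu
        grad_c = C.T @ r                         # (p, s)
        grad_g = (Ga * r).sum(axis=0)            # (s,)
        A = (O.T @ w).reshape(p, p, -1)          # (p, p, s)
        bvec = C.T @ (w * Ga)                    # (p, s)
        csc = (w * Ga * Ga).sum(axis=0)          # (s,)
        s_n = len(idx)
        H = np.empty((s_n, p + 1, p + 1))
        H[:, :p, :p] = np.moveaxis(A, 2, 0)
        H[:, :p, p] = bvec.T
        H[:, p, :p] = bvec.T
        H[:, p, p] = csc
        gfull = np.empty((s_n, p + 1))
        gfull[:, :p] = grad_c.T
        gfull[:, p] = grad_g
        try:
            step = np.linalg.solve(H, gfull[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.array([np.linalg.lstsq(h, gv, rcond=None)[0] for h, gv in zip(H, gfull)])
        B[idx] = Ba + step
        ll_new = (y[:, None] * eta - np.logaddexp(0, eta)).sum(axis=0)
        done = np.abs(ll_new - ll[idx]) < tol
        ll[idx] = ll_new
        converged[idx[done]] = True
        bad = ~np.isfinite(B[idx]).all(axis=1)
        if bad.any():
            converged[idx[bad]] = False
            active_idx = idx[bad]
            B[active_idx] = 0.0
        still = ~done & ~bad
        active[:] = False
        active[idx[still]] = True
    # final loglik and dosage SE at the converged parameters
    eta = np.clip(C @ B[:, :p].T + G * B[:, p], -30, 30)
    mu = _sigmoid(eta)
    w = mu * (1 - mu) + 1e-12
    ll = (y[:, None] * eta - np.logaddexp(0, eta)).sum(axis=0)
    A = (O.T @ w).reshape(p, p, -1)
    bvec = C.T @ (w * G)
    csc = (w * G * G).sum(axis=0)
    se = np.full(S, np.nan)
    Amat = np.moveaxis(A, 2, 0)
    try:
        Ainv_b = np.linalg.solve(Amat, np.moveaxis(bvec, 1, 0)[:, :, None])[:, :, 0]
        schur = csc - (np.moveaxis(bvec, 1, 0) * Ainv_b).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(1.0 / schur)
    except np.linalg.LinAlgError:
        pass
    return B[:, p], se, ll, converged


def _score_test(C: np.ndarray, G: np.ndarray, y: np.ndarray, beta0: np.ndarray):
    """1-df score statistics of each SNP at the covariate-only fit."""
    eta0 = np.clip(C @ beta0, -30, 30)
    mu0 = _sigmoid(eta0)
    w0 = mu0 * (1 - mu0) + 1e-12
    r0 = y - mu0
    U = G.T @ r0
    CtWC = (C * w0[:, None]).T @ C
    CtWG = C.T @ (w0[:, None] * G)
    sol = np.linalg.solve(CtWC, CtWG)
    V = (w0[:, None] * G * G).sum(axis=0) - (CtWG * sol).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return U * U / V


def gwas_scan(
    g: GenotypeMatrix,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    maf_min: float = 0.01,
    n_independent: int | None = None,
    alpha: float = 0.05,
) -> AssocScan:
    """Covariate-adjusted logistic GWAS of a binary lineage label.

    Per variant with MAF >= ``maf_min``: logistic regression of phenotype
    on additive dosage plus covariates, p-value from the likelihood-ratio
    test against the covariate-only model (score-test fallback where the
    alternative fit fails to converge).  ``n_independent`` (post-LD-prune
    variant count) sets the Bonferroni threshold alpha/n_independent; by
    default the number of tested variants is used.
    """
    y = phenotype.loc[g.sample_ids].to_numpy(dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("phenotype must have both classes")
    if covariates is not None:
        Cov = covariates.loc[g.sample_ids]
        cov_names = list(Cov.columns)
        C = np.column_stack([np.ones(g.n_samples), Cov.to_numpy(dtype=float)])
    else:
        cov_names = []
        C = np.ones((g.n_samples, 1))
    maf = g.maf()
    test = np.flatnonzero(maf >= maf_min)
    G = g.genotypes[:, test].astype(float)
    G[G == MISSING] = np.nan
    col_mean = np.nanmean(G, axis=0)
    nan_mask = np.isnan(G)
    if nan_mask.any():
        G[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])

    beta0, ll0, ok0 = _logistic_fit(C, y)
    if not ok0:
        raise RuntimeError("covariate-only model failed to converge")
    beta_g, se, ll1, conv = _batched_snp_logistic(C, G, y, beta0)
    # runaway dosage effects signal (quasi-)complete separation: the clipped
    # likelihood plateaus, so treat these fits as non-converged
    conv = conv & (np.abs(beta_g) <= 10.0)
    lrt = 2.0 * (ll1 - ll0)
    lrt = np.where(np.isfinite(lrt) & (lrt >= 0), lrt, np.nan)
    stat = lrt.copy()
    need_fallback = ~conv | ~np.isfinite(stat)
    if need_fallback.any():
        score = _score_test(C, G[:, need_fallback], y, beta0)
        stat[need_fallback] = score
    p = stats.chi2.sf(stat, df=1)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    lam = float(np.nanmedian(stat) / CHI2_MEDIAN_1DF)
    n_ind = n_independent if n_independent is not None else len(test)
    results = pd.DataFrame(
        {
            "chrom": g.chrom[test],
            "pos": g.pos[test],
            "maf": maf[test],
            "beta": beta_g,
            "se": se,
            "stat": stat,
            "p": p,
            "converged": conv,
        }
    )
    return AssocScan(
        results=results, lam=lam,
        bonferroni_threshold=alpha / n_ind, n_independent=n_ind,
        covariates=cov_names,
    )


def bonferroni_threshold(alpha: float, n_independent: int) -> float:
    """Significance threshold alpha / number of independent variants."""
    return alpha / n_independent


# ---------------------------------------------------------------------------
# gene annotation


_ATTR_RE = re.compile(r"(?:^|;)\s*(?:ID|Parent|gene_id|locus_tag)=([^;]+)")


def _read_cds(gff_path) -> tuple[pd.DataFrame, int]:
    rows = []
    skipped = 0
    with open(gff_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                skipped += 1
                continue
            if parts[2] != "CDS":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                skipped += 1
                continue
            m = _ATTR_RE.search(parts[8])
            gene = m.group(1) if m else f"{parts[0]}:{start}-{end}"
            gene = gene.split(".")[0].replace("cds-", "")
            rows.append({"chrom": parts[0], "start": start, "end": end, "gene": gene})
    return pd.DataFrame(rows), skipped


def annotate_hits(
    scan: AssocScan | pd.DataFrame,
    gff_path,
    flank: int = 1000,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Map significant variants to genes whose CDS +/- ``flank`` bp contains
    them (1-based inclusive); intergenic hits get the nearest-gene distance.
    """
    if isinstance(scan, AssocScan):
        thr = threshold if threshold is not None else scan.bonferroni_threshold
        hits = scan.results[scan.results["p"] <= thr]
    else:
        if threshold is None:
            raise ValueError("threshold required with a raw results frame")
        hits = scan[scan["p"] <= threshold]
    cds, skipped = _read_cds(gff_path)
    if skipped:
        logger.warning("skipped %d malformed GFF lines", skipped)
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in cds.groupby("chrom"):
        t = IntervalTree()
        for r in sub.itertuples():
            # half-open tree interval covering [start-flank, end+flank] inclusive
            t[r.start - flank : r.end + flank + 1] = r.gene
        trees[chrom] = t
    rows = []
    for r in hits.itertuples():
        overl = sorted({iv.data for iv in trees.get(r.chrom, IntervalTree())[r.pos]})
        if overl:
            rows.append(
                {"chrom": r.chrom, "pos": r.pos, "p": r.p,
                 "genes": ",".join(overl), "intergenic": False, "nearest_bp": 0}
            )
        else:
            sub = cds[cds["chrom"] == r.chrom]
            if len(sub):
                dist = np.minimum(
                    np.abs(sub["start"] - r.pos), np.abs(sub["end"] - r.pos)
                )
                j = int(dist.idxmin())
                rows.append(
                    {"chrom": r.chrom, "pos": r.pos, "p": r.p, "genes": "",
                     "intergenic": True, "nearest_bp": int(dist.loc[j])}
                )
            else:
                rows.append(
                    {"chrom": r.chrom, "pos": r.pos, "p": r.p, "genes": "",
                     "intergenic": True, "nearest_bp": -1}
                )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "p", "genes", "intergenic", "nearest_bp"]
    )
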