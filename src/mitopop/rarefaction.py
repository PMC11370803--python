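"""Rarefaction of diversity statistics across sample sizes.

Population sample sizes differ, and several statistics (S, H, and the
variance of most others) depend on n.  The standardisation here resamples
sequences at each size from 3 up to min(50, group size), recomputes the
statistics on every cleaned subsample, and reports the replicate mean with
two spread columns: the SD of the replicate distribution and the Monte
Carlo standard error SD/sqrt(reps).  Resampling is *with replacement* by
default (the procedure standardised here), with a classical
without-replacement mode as an option; under replacement, duplicate draws
of the same sequence lower H and HD of the subsample, a direct consequence
of the resampling scheme.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .alignment import HaplotypeAlignment, N as N_CODE
from . import diversity as dv

logger = logging.getLogger(__name__)

STATISTICS = ("S", "H", "pi", "tajD", "achazY")


def _subsample_stats(mat: np.ndarray, wanted: tuple[str, ...]) -> dict[str, float]:
    """Diversity statistics of a row subset, complete deletion applied."""
    n = mat.shape[0]
    keep = (mat < N_CODE).all(axis=0)
    sub = mat[:, keep]
    L_eff = int(keep.sum())
    out: dict[str, float] = {}
    counts = np.stack([(sub == b).sum(axis=0) for b in range(4)])
    minor = n - counts.max(axis=0)
    S = int((minor > 0).sum())
    if "S" in wanted:
        out["S"] = S
    if "H" in wanted:
        out["H"] = np.unique(sub, axis=0).shape[0]
    if "pi" in wanted or "tajD" in wanted:
        npairs = n * (n - 1) / 2.0
        K = float((npairs - (counts * (counts - 1) / 2.0).sum(axis=0)).sum()) / npairs
        if "pi" in wanted:
            out["pi"] = K / L_eff if L_eff else math.nan
        if "tajD" in wanted:
            out["tajD"] = dv.tajimas_d(n, S, K)
    if "achazY" in wanted:
        if S:
            xi = np.bincount(minor[minor > 0], minlength=n // 2 + 1)[1 : n // 2 + 1]
            out["achazY"] = dv.achaz_y_from_sfs(dv.SiteFrequencySpectrum(n, xi, L_eff))
        else:
            out["achazY"] = math.nan
    return out


def rarefy(
    aln: HaplotypeAlignment,
    group=None,
    statistics: tuple[str, ...] = STATISTICS,
    sizes: range | list[int] = range(3, 51),
    reps: int = 5000,
    replacement: bool = True,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rarefaction curves for a group of sequences.

    Returns a long-format frame (statistic, size, mean, sd, se, reps_used,
    replacement) where ``se = sd / sqrt(reps_used)``.  Replicates on which a
    statistic is undefined (for example Tajima's D at S = 0) are excluded
    from that statistic's summary, with the count logged.
    """
    unknown = set(statistics) - set(STATISTICS)
    if unknown:
        raise ValueError(f"unknown statistics: {sorted(unknown)}")
    rows_idx = dv._rows_for(aln, group)
    n_total = len(rows_idx)
    if n_total < 3:
        raise ValueError("need at least 3 sequences to rarefy")
    mat = aln.matrix[rows_idx]
    rng = np.random.default_rng(seed)
    out_rows = []
    n_dropped = 0
    for size in sizes:
        if size > n_total:
            break
        values: dict[str, list[float]] = {s: [] for s in statistics}
        for _ in range(reps):
            pick = (
                rng.integers(0, n_total, size)
                if replacement
                else rng.choice(n_total, size=size, replace=False)
            )
            stats = _subsample_stats(mat[pick], tuple(statistics))
            for s in statistics:
                values[s].append(stats[s])
        for s in statistics:
            arr = np.asarray(values[s], dtype=float)
            ok = np.isfinite(arr)
            n_dropped += int((~ok).sum())
            arr = arr[ok]
            reps_used = len(arr)
            mean = float(arr.mean()) if reps_used else math.nan
            sd = float(arr.std(ddof=1)) if reps_used > 1 else 0.0
            out_rows.append(
                {
                    "statistic": s,
                    "size": size,
                    "mean": mean,
                    "sd": sd,
                    "se": sd / math.sqrt(reps_used) if reps_used else math.nan,
                    "reps_used": reps_used,
                    "replacement": replacement,
                }
            )
    if n_dropped:
        logger.info("excluded %d undefined replicate values", n_dropped)
    return pd.DataFrame(out_rows)
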