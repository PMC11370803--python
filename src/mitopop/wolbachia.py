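"""Endosymbiont (Wolbachia) infection screening from unmapped reads.

Each read is compared against a marker panel (wsp / ftsZ / groE-type
sequences) on both strands using exact 15-mer seeds extended by a local
Smith-Waterman alignment (match +1, mismatch -1, gap open -2, gap extend
-1).  A sample is called infected when at least ``min_reads`` matches that
pass the length and identity thresholds hit the *same* panel record.  Two
threshold presets are evaluated in one pass: strict (>= 98 aligned bases,
>= 95% identity) and lenient (>= 90 bases, >= 90% identity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

SEED_K = 15

_CODE = {c: i for i, c in enumerate("ACGT")}
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ScreenCriteria:
    name: str
    min_reads: int = 3
    min_len: int = 90
    min_identity: float = 90.0

    def __post_init__(self) -> None:
        if self.min_reads < 1 or self.min_len <= 0 or not (0 < self.min_identity <= 100):
            raise ValueError("invalid screen criteria")


STRICT = ScreenCriteria("strict", min_reads=3, min_len=98, min_identity=95.0)
LENIENT = ScreenCriteria("lenient", min_reads=3, min_len=90, min_identity=90.0)


@dataclass
class ReadMatch:
    read_id: str
    panel_id: str
    aligned_length: int
    identity: float
    strand: str


@njit(cache=True)
def _sw_kernel(q, r):
    """Local alignment with affine gaps (open 2, extend 1, match +1,
    mismatch -1).  Returns (score, matches, query_bases_aligned)."""
    nq, nr = len(q), len(r)
    NEG = -10**6
    M = np.full((nq + 1, nr + 1), 0, dtype=np.int32)
    Ix = np.full((nq + 1, nr + 1), NEG, dtype=np.int32)  # gap in query (consume r)
    Iy = np.full((nq + 1, nr + 1), NEG, dtype=np.int32)  # gap in ref (consume q)
    best, bi, bj = 0, 0, 0
    for i in range(1, nq + 1):
        for j in range(1, nr + 1):
            s = 1 if q[i - 1] == r[j - 1] else -1
            diag = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            m = diag + s
            if m < 0:
                m = 0
            M[i, j] = m
            ix = max(M[i, j - 1] - 2, Ix[i, j - 1] - 1)
            Ix[i, j] = ix
            iy = max(M[i - 1, j] - 2, Iy[i - 1, j] - 1)
            Iy[i, j] = iy
            if m > best:
                best, bi, bj = m, i, j
    # traceback from (bi, bj) in state M
    matches = 0
    qbases = 0
    i, j = bi, bj
    state = 0  # 0=M, 1=Ix, 2=Iy
    while i > 0 and j > 0:
        if state == 0:
            if M[i, j] == 0:
                break
            if q[i - 1] == r[j - 1]:
                matches += 1
            qbases += 1
            prev = M[i, j] - (1 if q[i - 1] == r[j - 1] else -1)
            i -= 1
            j -= 1
            if M[i, j] == prev:
                state = 0
            elif Ix[i, j] == prev:
                state = 1
            else:
                state = 2
        elif state == 1:
            prev = Ix[i, j]
            j -= 1
            if Ix[i, j] - 1 == prev:
                state = 1
            else:
                state = 0
        else:
            prev = Iy[i, j]
            qbases += 1
            i -= 1
            if Iy[i, j] - 1 == prev:
                state = 2
            else:
                state = 0
    return best, matches, qbases


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.int8)


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


class PanelIndex:
    """Seed index over a marker panel: exact k-mer -> (record, offset)."""

    def __init__(self, panel: dict[str, str], k: int = SEED_K):
        self.k = k
        self.panel = {pid: s.upper() for pid, s in panel.items()}
        self.encoded = {pid: _encode(s) for pid, s in self.panel.items()}
        self.index: dict[str, list[tuple[str, int]]] = {}
        for pid, s in self.panel.items():
            for off in range(len(s) - k + 1):
                self.index.setdefault(s[off : off + k], []).append((pid, off))

    def candidates(self, read: str) -> dict[str, int]:
        """Panel records seeded by the read, with one anchor ref offset."""
        hits: dict[str, int] = {}
        for pos in range(len(read) - self.k + 1):
            for pid, off in self.index.get(read[pos : pos + self.k], ()):
                hits.setdefault(pid, off - pos)
        return hits


def best_match(
    read_id: str, read: str, index: PanelIndex, pad: int = 20
) -> ReadMatch | None:
    """Best seeded local alignment of a read against the panel (both
    strands), or None when no seed hits."""
    best: ReadMatch | None = None
    for strand, seq in (("+", read.upper()), ("-", revcomp(read))):
        q = _encode(seq)
        for pid, diag in index.candidates(seq).items():
            ref = index.encoded[pid]
            lo = max(diag - pad, 0)
            hi = min(diag + len(seq) + pad, len(ref))
            score, matches, qbases = _sw_kernel(q, ref[lo:hi])
            if qbases == 0:
                continue
            ident = 100.0 * matches / qbases
            if best is None or (qbases, ident) > (best.aligned_length, best.identity):
                best = ReadMatch(read_id, pid, qbases, ident, strand)
    return best


def read_fastq(path) -> list[tuple[str, str]]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            reads.append((header[1:].split()[0], seq))
    return reads


def read_panel_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def screen_reads(
    reads: list[tuple[str, str]],
    panel: dict[str, str] | PanelIndex,
    criteria: list[ScreenCriteria] = (STRICT, LENIENT),
) -> tuple[dict[str, bool], list[ReadMatch]]:
    """Classify one sample's read set under each criteria preset.

    Returns ({preset name: infected}, surviving-filterless match list).  A
    sample is infected under a preset when >= ``min_reads`` passing matches
    share a single panel record id.  An empty read set is uninfected.
    """
    index = panel if isinstance(panel, PanelIndex) else PanelIndex(panel)
    matches: list[ReadMatch] = []
    for rid, seq in reads:
        if len(seq) < index.k:
            continue
        m = best_match(rid, seq, index)
        if m is not None:
            matches.append(m)
    calls: dict[str, bool] = {}
    for crit in criteria:
        per_panel: dict[str, int] = {}
        for m in matches:
            if m.aligned_length >= crit.min_len and m.identity >= crit.min_identity:
                per_panel[m.panel_id] = per_panel.get(m.panel_id, 0) + 1
        calls[crit.name] = any(v >= crit.min_reads for v in per_panel.values())
    return calls, matches
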