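"""Haplotype alignments: FASTA I/O, metadata joining, and column cleanup.

An alignment is a rectangular block of haploid mtDNA sequences over the
alphabet {A, C, G, T, N, -}.  All column coordinates exposed by this module
(region masks, removal reports) are 1-based inclusive, following the usual
convention for sequence alignments; internally columns are stored 0-based in
a numpy byte matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = b"ACGTN-"
# integer codes for the byte matrix
_CODE = {c: i for i, c in enumerate(ALPHABET)}
A, C, G, T, N, GAP = range(6)
VALID_BASES = frozenset(b"ACGTN-")

METADATA_COLUMNS = ["sample_id", "population", "species", "latitude", "longitude", "sex"]


class AlignmentShapeError(ValueError):
    """Sequences in a FASTA alignment do not share a common length."""


class AlignmentInputError(ValueError):
    """Empty or otherwise unusable alignment input."""


@dataclass
class RegionMask:
    """Set of 1-based inclusive column intervals to remove (e.g. control region)."""

    intervals: list[tuple[int, int]]
    label: str = ""

    def __post_init__(self) -> None:
        norm = sorted((int(s), int(e)) for s, e in self.intervals)
        for s, e in norm:
            if s < 1 or e < s:
                raise ValueError(f"invalid interval ({s}, {e}); need 1 <= start <= end")
        merged: list[tuple[int, int]] = []
        for s, e in norm:
            if merged and s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        self.intervals = merged

    def column_index(self, length: int) -> np.ndarray:
        """0-based indices of masked columns within an alignment of `length`."""
        idx: list[np.ndarray] = []
        for s, e in self.intervals:
            if e > length:
                raise ValueError(f"mask interval ({s}, {e}) exceeds alignment length {length}")
            idx.append(np.arange(s - 1, e))
        if not idx:
            return np.empty(0, dtype=int)
        return np.concatenate(idx)


@dataclass
class HaplotypeAlignment:
    """Aligned haploid sequences with optional per-sample metadata.

    `matrix` holds one row per sample with integer base codes
    (A=0, C=1, G=2, T=3, N=4, gap=5).
    """

    sample_ids: list[str]
    matrix: np.ndarray
    metadata: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise AlignmentInputError("duplicate sample ids in alignment")
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.sample_ids):
            raise AlignmentShapeError("matrix shape inconsistent with sample ids")
        if self.matrix.shape[1] == 0:
            raise AlignmentInputError("alignment has zero columns")

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, i: int | str) -> str:
        if isinstance(i, str):
            i = self.sample_ids.index(i)
        return bytes(ALPHABET[c] for c in self.matrix[i]).decode()

    def sequences(self) -> list[str]:
        return [self.sequence(i) for i in range(self.n)]

    def subset(self, ids: Sequence[str]) -> "HaplotypeAlignment":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [pos[s] for s in ids]
        meta = None
        if self.metadata is not None:
            meta = self.metadata.set_index("sample_id").loc[list(ids)].reset_index()
        return HaplotypeAlignment(list(ids), self.matrix[rows], meta)

    # -- construction ----------------------------------------------------
    @classmethod
    def from_sequences(
        cls,
        sample_ids: Iterable[str],
        sequences: Iterable[str],
        metadata: pd.DataFrame | None = None,
    ) -> "HaplotypeAlignment":
        ids = list(sample_ids)
        seqs = [s.upper().encode() for s in sequences]
        if not seqs:
            raise AlignmentInputError("no sequences supplied")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlignmentShapeError(f"unequal sequence lengths: {sorted(lengths)}")
        raw = np.frombuffer(b"".join(seqs), dtype=np.uint8).reshape(len(seqs), -1).copy()
        mat = np.full_like(raw, N)
        for byte, code in _CODE.items():
            mat[raw == byte] = code
        n_invalid = int((~np.isin(raw, np.frombuffer(ALPHABET, dtype=np.uint8))).sum())
        if n_invalid:
            logger.warning("mapped %d non-ACGTN- characters to N", n_invalid)
        return cls(ids, mat, metadata)


def read_alignment(path) -> HaplotypeAlignment:
    """Read an aligned FASTA file.

    Lowercase is normalised to uppercase and IUPAC ambiguity codes are
    collapsed to N (with a logged count); unequal record lengths raise
    :class:`AlignmentShapeError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentInputError(f"no FASTA records in {path}")
    return HaplotypeAlignment.from_sequences(
        [r.id for r in records], [str(r.seq) for r in records]
    )


def write_alignment(aln: HaplotypeAlignment, path) -> None:
    records = [
        SeqRecord(Seq(aln.sequence(i)), id=aln.sample_ids[i], description="")
        for i in range(aln.n)
    ]
    SeqIO.write(records, str(path), "fasta")


def crop_and_clean(
    aln: HaplotypeAlignment,
    mask: RegionMask | None = None,
    drop_gap_ambiguous_columns: bool = True,
) -> tuple[HaplotypeAlignment, dict[str, int]]:
    """Remove masked columns and, optionally, every column containing '-' or N.

    Returns the cleaned alignment and a removal report with counts per
    reason.  Applying the same call twice is a no-op the second time.
    """
    drop = np.zeros(aln.length, dtype=bool)
    n_masked = 0
    if mask is not None:
        idx = mask.column_index(aln.length)
        drop[idx] = True
        n_masked = int(drop.sum())
    n_gappy = 0
    if drop_gap_ambiguous_columns:
        gappy = (aln.matrix >= N).any(axis=0)
        n_gappy = int((gappy & ~drop).sum())
        drop |= gappy
    keep = ~drop
    report = {
        "columns_in": aln.length,
        "masked": n_masked,
        "gap_or_ambiguous": n_gappy,
        "columns_out": int(keep.sum()),
    }
    if report["columns_out"] == 0:
        raise AlignmentInputError("all columns removed by cleanup")
    out = HaplotypeAlignment(list(aln.sample_ids), aln.matrix[:, keep], aln.metadata)
    return out, report


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV (header required, columns as METADATA_COLUMNS)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise AlignmentInputError(f"metadata missing columns: {sorted(missing)}")
    bad_lat = ~meta["latitude"].between(-90, 90)
    bad_lon = ~meta["longitude"].between(-180, 180)
    if bad_lat.any() or bad_lon.any():
        raise AlignmentInputError("latitude/longitude outside valid ranges")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def join_metadata(
    aln: HaplotypeAlignment, meta: pd.DataFrame, strict: bool = True
) -> HaplotypeAlignment:
    """Attach one metadata row per aligned sample.

    In strict mode a sample without a metadata row is an error; otherwise
    unmatched samples are dropped with a warning.  Metadata rows without a
    sequence are ignored (warned).
    """
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise AlignmentInputError(f"duplicate metadata sample ids: {dups}")
    have = set(meta["sample_id"])
    matched = [s for s in aln.sample_ids if s in have]
    unmatched = [s for s in aln.sample_ids if s not in have]
    if unmatched:
        if strict:
            raise AlignmentInputError(f"samples without metadata: {unmatched}")
        logger.warning("dropping %d samples without metadata", len(unmatched))
    extra = have - set(aln.sample_ids)
    if extra:
        logger.warning("ignoring %d metadata rows without sequences", len(extra))
    sub = aln.subset(matched) if unmatched else aln
    joined = meta.set_index("sample_id").loc[sub.sample_ids].reset_index()
    return HaplotypeAlignment(list(sub.sample_ids), sub.matrix, joined)
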