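"""Barcode read counting: FASTQ -> tag-level count matrix with QC.

A read carries a 20-nt strain barcode downstream of a known 5' flank.  The
flank is located allowing up to ``max_flank_mm`` substitutions, the candidate
20-mer is matched against the combined uptag/downtag index allowing up to
``max_mm`` mismatches (exact match wins; an equally-near pair of catalog tags
is ambiguous), and per-sample QC enforces the conservation invariant
assigned + unmatched + ambiguous = total_reads.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .synthetic import (
    DOWNTAG_FLANK5,
    TAG_LENGTH,
    UPTAG_FLANK5,
    StrainCatalog,
    _encode,
)

__all__ = [
    "TagCountMatrix",
    "TagIndex",
    "extract_tag",
    "match_tag",
    "classify_reads",
    "count_fastq",
]

AMBIGUOUS = "ambiguous"

_QC_COLUMNS = ["total_reads", "assigned", "unmatched", "ambiguous"]


@dataclass
class TagCountMatrix:
    """Tag x sample count matrix plus per-sample QC tallies."""

    counts: pd.DataFrame  # tags x samples, int
    qc: pd.DataFrame  # samples x (total_reads, assigned, unmatched, ambiguous)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        for sample in self.counts.columns:
            row = self.qc.loc[sample]
            if row["assigned"] + row["unmatched"] + row["ambiguous"] != row["total_reads"]:
                raise ValueError(f"QC conservation violated for sample {sample!r}")
            if int(self.counts[sample].sum()) != int(row["assigned"]):
                raise ValueError(f"counts do not sum to assigned for {sample!r}")

    def to_tsv(self, counts_path: str | Path, qc_path: str | Path | None = None) -> Path:
        counts_path = Path(counts_path)
        self.counts.rename_axis("tag").to_csv(counts_path, sep="\t")
        if qc_path is not None:
            self.qc.rename_axis("sample_id").to_csv(qc_path, sep="\t")
        return counts_path

    @classmethod
    def from_tsv(cls, counts_path: str | Path, qc_path: str | Path | None = None) -> "TagCountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts = counts.astype(np.int64)
        if qc_path is not None:
            qc = pd.read_csv(qc_path, sep="\t", index_col=0)
        else:
            qc = pd.DataFrame(
                {
                    "total_reads": counts.sum(axis=0),
                    "assigned": counts.sum(axis=0),
                    "unmatched": 0,
                    "ambiguous": 0,
                }
            )
        return cls(counts=counts, qc=qc[_QC_COLUMNS])


# ---------------------------------------------------------------------------
# Flank location / tag extraction
# ---------------------------------------------------------------------------

def _best_flank_offsets(reads: np.ndarray, flank: np.ndarray, tag_len: int):
    """Best (fewest-mismatch, leftmost) flank placement per read.

    ``reads`` is (n, L) uint8; only offsets leaving ``tag_len`` nt after the
    flank are considered.  Returns (offsets, mismatches); offset -1 where no
    placement fits.
    """
    n, read_len = reads.shape
    flen = flank.size
    n_offsets = read_len - flen - tag_len + 1
    if n_offsets <= 0:
        return np.full(n, -1), np.full(n, np.iinfo(np.int64).max)
    mm = np.empty((n, n_offsets), dtype=np.int64)
    for off in range(n_offsets):
        mm[:, off] = (reads[:, off : off + flen] != flank).sum(axis=1)
    best = mm.argmin(axis=1)  # leftmost on ties
    return best, mm[np.arange(n), best]


def extract_tag(
    read: str,
    flank5: str = UPTAG_FLANK5,
    flank3: str = "",
    max_flank_mm: int = 2,
    tag_len: int = TAG_LENGTH,
) -> str | None:
    """Extract the candidate tag between the best 5' flank match and +tag_len.

    Returns None when no flank placement within ``max_flank_mm`` mismatches
    leaves ``tag_len`` nt of read.  ``flank3`` is accepted for interface
    symmetry; placement is anchored on the 5' flank alone.
    """
    if len(read) < tag_len:
        raise ValueError("read shorter than the tag length")
    try:
        mat = _encode([read])
    except ValueError:
        return None  # e.g. N bases: no acceptable placement
    offs, mms = _best_flank_offsets(mat, _encode([flank5])[0], tag_len)
    if offs[0] < 0 or mms[0] > max_flank_mm:
        return None
    start = int(offs[0]) + len(flank5)
    return read[start : start + tag_len]


# ---------------------------------------------------------------------------
# Tag matching
# ---------------------------------------------------------------------------

def _neighbors1(tag: str) -> Iterable[str]:
    for i, base in enumerate(tag):
        for b in "ACGT":
            if b != base:
                yield tag[:i] + b + tag[i + 1 :]


class TagIndex:
    """Combined uptag+downtag index supporting <=1-mismatch lookup.

    With the catalog's minimum pairwise Hamming distance >= 2*max_mm + 1,
    a read with at most max_mm errors can never be misassigned.
    """

    def __init__(self, catalog: StrainCatalog, max_mm: int = 1) -> None:
        if max_mm < 0:
            raise ValueError("max_mm must be >= 0")
        self.catalog = catalog
        self.max_mm = max_mm
        self.tag_map = catalog.tag_to_strain()
        self._near: dict[str, str | None] = {}
        if max_mm >= 1:
            for tag in self.tag_map:
                for nb in _neighbors1(tag):
                    if nb in self._near and self._near[nb] != tag:
                        self._near[nb] = None  # two equally-near tags
                    else:
                        self._near[nb] = tag
        self._tag_list = list(self.tag_map)
        self._tag_mat = _encode(self._tag_list) if self._tag_list else None

    def lookup(self, candidate: str):
        """-> (strain_id, kind), AMBIGUOUS, or None (unmatched)."""
        hit = self.tag_map.get(candidate)
        if hit is not None:
            return hit
        if self.max_mm == 0:
            return None
        if self.max_mm == 1:
            near = self._near.get(candidate, "missing")
            if near == "missing":
                return None
            if near is None:
                return AMBIGUOUS
            return self.tag_map[near]
        # general (slow) path for max_mm > 1
        cand = _encode([candidate])[0]
        dist = (self._tag_mat != cand).sum(axis=1)
        best = int(dist.min())
        if best > self.max_mm:
            return None
        hits = np.nonzero(dist == best)[0]
        if hits.size > 1:
            return AMBIGUOUS
        return self.tag_map[self._tag_list[int(hits[0])]]


def match_tag(candidate: str, catalog: StrainCatalog, max_mm: int = 1):
    """Match a 20-nt candidate against the catalog.

    Exact match wins; otherwise the unique catalog tag within Hamming
    <= max_mm; two or more equally-near tags give ``AMBIGUOUS``; no tag in
    range gives None.
    """
    if len(candidate) != len(next(iter(catalog.tag_to_strain()))):
        raise ValueError("candidate length does not match catalog tag length")
    tag_map = catalog.tag_to_strain()
    hit = tag_map.get(candidate)
    if hit is not None:
        return hit
    if max_mm == 0:
        return None
    cand = _encode([candidate])[0]
    tags = list(tag_map)
    dist = (_encode(tags) != cand).sum(axis=1)
    best = int(dist.min())
    if best > max_mm:
        return None
    hits = np.nonzero(dist == best)[0]
    if hits.size > 1:
        return AMBIGUOUS
    return tag_map[tags[int(hits[0])]]


# ---------------------------------------------------------------------------
# FASTQ counting
# ---------------------------------------------------------------------------

def _read_fastq(path: str | Path) -> list[str]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    seqs = []
    with opener(path, "rt") as fh:
        try:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                seqs.append(seq.upper())
        except ValueError as exc:
            raise ValueError(
                f"unreadable FASTQ record in {path} at record index {len(seqs)}: {exc}"
            ) from exc
    return seqs


def classify_reads(
    seqs: list[str],
    index: TagIndex,
    max_flank_mm: int = 2,
    tag_len: int = TAG_LENGTH,
) -> list:
    """Per-read outcome, in read order.

    Each element is ``(strain_id, kind)``, ``AMBIGUOUS`` or None (unmatched).
    Each read is tried against the uptag 5' flank first, then the downtag 5'
    flank; the first candidate that matches the catalog assigns the read.
    This is the code path ``count_fastq`` tallies.
    """
    flanks = [
        (_encode([UPTAG_FLANK5])[0], len(UPTAG_FLANK5)),
        (_encode([DOWNTAG_FLANK5])[0], len(DOWNTAG_FLANK5)),
    ]
    outcomes: list = [None] * len(seqs)
    clean_idx = [i for i, s in enumerate(seqs) if set(s) <= set("ACGT")]
    groups: dict[int, list[int]] = {}
    for i in clean_idx:
        groups.setdefault(len(seqs[i]), []).append(i)
    for _length, idx in sorted(groups.items()):
        mat = _encode([seqs[i] for i in idx])
        for i, cands in zip(idx, _candidates(mat, flanks, max_flank_mm, tag_len)):
            for cand in cands:
                hit = index.lookup(cand)
                if hit is not None:
                    outcomes[i] = hit
                    break
    return outcomes


def count_fastq(
    fastq_by_sample: Mapping[str, str | Path],
    catalog: StrainCatalog,
    max_flank_mm: int = 2,
    max_mm: int = 1,
    tag_len: int = TAG_LENGTH,
) -> TagCountMatrix:
    """Count tags in one FASTQ per sample into a TagCountMatrix.

    The result is independent of read order and satisfies the conservation
    invariant assigned + unmatched + ambiguous = total_reads.
    """
    samples = list(fastq_by_sample)
    if len(set(samples)) != len(samples):
        raise ValueError("sample ids must be unique")
    index = TagIndex(catalog, max_mm=max_mm)
    tags = catalog.tags
    tag_row = {t: i for i, t in enumerate(tags)}
    strain_kind_row = {
        (strain, kind): tag_row[tag] for tag, (strain, kind) in index.tag_map.items()
    }
    counts = np.zeros((len(tags), len(samples)), dtype=np.int64)
    qc_rows = []
    for j, sample in enumerate(samples):
        seqs = _read_fastq(fastq_by_sample[sample])
        assigned = unmatched = ambiguous = 0
        for outcome in classify_reads(seqs, index, max_flank_mm, tag_len):
            if outcome is None:
                unmatched += 1
            elif outcome == AMBIGUOUS:
                ambiguous += 1
            else:
                counts[strain_kind_row[outcome], j] += 1
                assigned += 1
        qc_rows.append(
            {
                "sample_id": sample,
                "total_reads": len(seqs),
                "assigned": assigned,
                "unmatched": unmatched,
                "ambiguous": ambiguous,
            }
        )
    qc = pd.DataFrame(qc_rows).set_index("sample_id")[_QC_COLUMNS]
    frame = pd.DataFrame(counts, index=pd.Index(tags, name="tag"), columns=samples)
    return TagCountMatrix(counts=frame, qc=qc)


def _candidates(mat, flanks, max_flank_mm: int, tag_len: int) -> list[list[str]]:
    """Per read, candidate tags from each flank family (uptag first)."""
    n = mat.shape[0]
    out: list[list[str]] = [[] for _ in range(n)]
    if n == 0:
        return out
    from .synthetic import _decode

    for flank, flen in flanks:
        offs, mms = _best_flank_offsets(mat, flank, tag_len)
        ok = (offs >= 0) & (mms <= max_flank_mm)
        idx = np.nonzero(ok)[0]
        if idx.size == 0:
            continue
        starts = offs[idx] + flen
        tag_mat = np.empty((idx.size, tag_len), dtype=np.uint8)
        for row, (i, st) in enumerate(zip(idx, starts)):
            tag_mat[row] = mat[i, st : st + tag_len]
        for i, tag in zip(idx, _decode(tag_mat)):
            out[int(i)].append(tag)
    return out
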