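"""Capture-kit target-region harmonisation and per-gene targeted lengths.

Exome cohorts sequenced with different capture-kit versions target slightly
different regions.  To make per-gene scores comparable across kits, analyses
are restricted to the base-pair intersection of all kit BED files, and the
gene-length correction divides by the number of targeted bases overlapping
each gene.

Intervals are handled in the standard BED convention (0-based, half-open)
and stored merged and sorted per contig.  Variant positions, which arrive
1-based from VCF, are converted at the lookup boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TargetRegions",
    "BedFormatError",
    "read_bed",
    "read_gene_model",
    "merge_intervals",
    "intersect_intervals",
    "intersect_beds",
    "gene_targeted_length",
]

log = logging.getLogger(__name__)

# per-contig interval arrays of shape (n, 2), dtype int64, merged + sorted
IntervalMap = dict[str, np.ndarray]


class BedFormatError(ValueError):
    """A malformed BED line (reported with its line number)."""


def _normalize_contig(contig: str, strip_chr: bool) -> str:
    if strip_chr and contig.lower().startswith("chr"):
        return contig[3:]
    return contig


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    """Merge possibly-overlapping half-open intervals into a sorted disjoint set."""
    arr = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    for s, e in arr:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64).reshape(-1, 2)


def intersect_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Base-pair intersection of two merged, sorted interval arrays."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        start = max(a[i, 0], b[j, 0])
        end = min(a[i, 1], b[j, 1])
        if start < end:
            out.append((start, end))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


@dataclass
class TargetRegions:
    """A merged set of targeted genomic intervals plus per-gene targeted lengths.

    ``intervals`` maps contig name to an ``(n, 2)`` array of 0-based half-open
    intervals, merged and sorted.  ``gene_lengths`` (filled by
    :func:`gene_targeted_length`) maps gene symbol to total targeted bp.
    """

    intervals: IntervalMap
    gene_lengths: dict[str, int] = field(default_factory=dict)
    strip_chr: bool = False

    def contains(self, contig: str, pos: int) -> bool:
        """Whether a 1-based position falls inside the targeted regions."""
        ivs = self.intervals.get(_normalize_contig(contig, self.strip_chr))
        if ivs is None or len(ivs) == 0:
            return False
        p = pos - 1  # to 0-based
        k = int(np.searchsorted(ivs[:, 0], p, side="right")) - 1
        return k >= 0 and p < ivs[k, 1]

    @property
    def total_bp(self) -> int:
        return int(sum((ivs[:, 1] - ivs[:, 0]).sum() for ivs in self.intervals.values()))

    def targeted_length(self, gene: str) -> int:
        """Targeted bp for ``gene``; raises ``KeyError`` when the gene has no overlap."""
        return self.gene_lengths[gene]


def read_bed(path: str, strip_chr: bool = False) -> IntervalMap:
    """Read a BED3+ file into merged per-contig interval arrays."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start or start < 0:
                raise BedFormatError(f"{path}:{lineno}: invalid interval {start}-{end}")
            contig = _normalize_contig(fields[0], strip_chr)
            by_contig.setdefault(contig, []).append((start, end))
    return {c: merge_intervals(ivs) for c, ivs in by_contig.items()}


def intersect_beds(bed_files: Sequence[str], strip_chr: bool = False) -> TargetRegions:
    """Base-pair intersection across capture-kit BED files.

    With a single file this returns its merged intervals; with several it
    returns the regions targeted by every kit.  The operation is commutative
    and associative over file order.
    """
    if not bed_files:
        raise ValueError("at least one BED file is required")
    maps = [read_bed(p, strip_chr=strip_chr) for p in bed_files]
    result = maps[0]
    for other in maps[1:]:
        shared = set(result) & set(other)
        result = {c: intersect_intervals(result[c], other[c]) for c in shared}
        result = {c: ivs for c, ivs in result.items() if len(ivs)}
    if not result:
        log.warning("intersection of %d BED files is empty", len(bed_files))
    return TargetRegions(intervals=result, strip_chr=strip_chr)


def read_gene_model(path: str, strip_chr: bool = False) -> dict[str, list[tuple[str, int, int]]]:
    """Read a gene model as BED4+ (chrom, start, end, gene symbol), one row per exon."""
    model: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedFormatError(f"{path}:{lineno}: gene model needs 4 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            contig = _normalize_contig(fields[0], strip_chr)
            model.setdefault(fields[3], []).append((contig, start, end))
    return model


def gene_targeted_length(
    regions: TargetRegions,
    gene_model: Mapping[str, Sequence[tuple[str, int, int]]],
) -> dict[str, int]:
    """Per-gene total targeted bp: sum of each exon's overlap with the regions.

    Genes with zero overlap are omitted (and logged); the result is also
    stored on ``regions.gene_lengths`` for use by the length correction.
    """
    lengths: dict[str, int] = {}
    for gene, exons in gene_model.items():
        merged_by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in exons:
            merged_by_contig.setdefault(
                _normalize_contig(contig, regions.strip_chr), []
            ).append((start, end))
        total = 0
        for contig, ivs in merged_by_contig.items():
            target = regions.intervals.get(contig)
            if target is None:
                continue
            overlap = intersect_intervals(merge_intervals(ivs), target)
            if len(overlap):
                total += int((overlap[:, 1] - overlap[:, 0]).sum())
        if total > 0:
            lengths[gene] = total
        else:
            log.info("gene %s has no overlap with target regions; omitted", gene)
    regions.gene_lengths = lengths
    return lengths
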