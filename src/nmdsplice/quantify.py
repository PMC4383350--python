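"""Read filtering, junction-crossing read counting and isoform-ratio (PSI)
estimation.

A read is *identifying* for a binary splicing event when it is consistent
with one isoform but not the other: a spliced read whose gap matches exactly
one cataloged junction of the event, or an unspliced read crossing a retained
intron's boundary contiguously. Reads compatible with both isoforms are never
counted.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import pysam
from scipy.stats import beta as beta_dist

from .models import PsiEstimate, SplicingEvent

DEFAULT_MIN_OVERHANG = 6

# CIGAR operation codes that consume the reference
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X


@dataclass(frozen=True)
class AlignedRead:
    """Minimal view of one alignment: enough to filter and to count.

    ``blocks`` are the contiguously aligned reference segments; deletions do
    not split a block, reference skips (introns, CIGAR N) do.
    """

    read_id: str
    chrom: str
    mapq: int
    blocks: tuple[tuple[int, int], ...]

    @classmethod
    def from_alignment(cls, aln: "pysam.AlignedSegment") -> "AlignedRead":
        blocks: list[tuple[int, int]] = []
        pos = aln.reference_start
        seg_start = pos
        for op, length in aln.cigartuples or ():
            if op == 3:  # N: splice
                if pos > seg_start:
                    blocks.append((seg_start, pos))
                pos += length
                seg_start = pos
            elif op in _REF_CONSUMING:
                pos += length
        if pos > seg_start:
            blocks.append((seg_start, pos))
        return cls(aln.query_name, aln.reference_name, aln.mapping_quality, tuple(blocks))

    @property
    def gaps(self) -> tuple[tuple[int, int], ...]:
        """Reference intervals skipped between blocks (putative introns)."""
        return tuple(
            (a[1], b[0]) for a, b in zip(self.blocks, self.blocks[1:])
        )

    @property
    def min_overhang(self) -> Optional[int]:
        """Shortest aligned block flanking any spanned junction, or None for
        unspliced alignments."""
        if len(self.blocks) < 2:
            return None
        flanks = []
        for i in range(len(self.blocks) - 1):
            left = self.blocks[i][1] - self.blocks[i][0]
            right = self.blocks[i + 1][1] - self.blocks[i + 1][0]
            flanks.append(min(left, right))
        return min(flanks)


@dataclass
class FilterStats:
    n_in: int = 0
    n_unmapped: int = 0
    n_mapq: int = 0
    n_overhang: int = 0
    n_kept: int = 0


def iter_sam(path: str) -> Iterator[AlignedRead]:
    """Stream mapped alignments from a SAM/BAM file as AlignedRead objects."""
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            for aln in fh.fetch(until_eof=True):
                if aln.is_unmapped:
                    yield AlignedRead(aln.query_name, "*", aln.mapping_quality, ())
                else:
                    yield AlignedRead.from_alignment(aln)
    finally:
        pysam.set_verbosity(save)


def filter_alignments(
    reads: Iterable[AlignedRead],
    min_mapq_exclusive: int = 0,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    stats: Optional[FilterStats] = None,
) -> list[AlignedRead]:
    """Post-alignment filters: drop mapq <= ``min_mapq_exclusive`` and spliced
    reads whose junction overhang is below ``min_overhang`` nt.

    A read is retained iff mapq exceeds the threshold AND (it spans no
    junction OR its minimum overhang is at least ``min_overhang``). Unmapped
    records are skipped and counted.
    """
    stats = stats if stats is not None else FilterStats()
    kept = []
    for r in reads:
        stats.n_in += 1
        if not r.blocks:
            stats.n_unmapped += 1
            continue
        if r.mapq <= min_mapq_exclusive:
            stats.n_mapq += 1
            continue
        oh = r.min_overhang
        if oh is not None and oh < min_overhang:
            stats.n_overhang += 1
            continue
        stats.n_kept += 1
        kept.append(r)
    return kept


@dataclass
class JunctionCounts:
    """Per-sample identifying-read counts over an event catalog.

    ``counts`` holds event-level tallies keyed by (event_id, isoform label);
    ``junction_counts`` the finer per-junction/per-boundary tallies (one read
    may contribute to several keys of the same isoform but to the event-level
    tally at most once). ``unassigned`` counts junction reads whose gap
    matches no cataloged junction.
    """

    sample_id: str
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    junction_counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    unassigned: int = 0
    ambiguous: int = 0

    def k_n(self, event_id: str) -> tuple[int, int]:
        k = self.counts.get((event_id, "A"), 0)
        n = k + self.counts.get((event_id, "B"), 0)
        return k, n


class _RetentionIndex:
    """Sorted per-chromosome index of retention boundary positions."""

    def __init__(self) -> None:
        self._pos: dict[str, list[int]] = {}
        self._entries: dict[tuple[str, int], list[tuple[str, str, str]]] = {}

    def add(self, chrom: str, pos: int, entry: tuple[str, str, str]) -> None:
        self._entries.setdefault((chrom, pos), []).append(entry)

    def freeze(self) -> None:
        by_chrom: dict[str, set[int]] = {}
        for chrom, pos in self._entries:
            by_chrom.setdefault(chrom, set()).add(pos)
        self._pos = {c: sorted(ps) for c, ps in by_chrom.items()}

    def lookup(self, chrom: str, lo: int, hi: int) -> Iterator[tuple[int, tuple[str, str, str]]]:
        """Yield indexed boundary positions p with lo <= p <= hi."""
        positions = self._pos.get(chrom)
        if not positions:
            return
        i = bisect_left(positions, lo)
        while i < len(positions) and positions[i] <= hi:
            p = positions[i]
            for entry in self._entries[(chrom, p)]:
                yield p, entry
            i += 1


def _build_indices(catalog: Sequence[SplicingEvent]):
    junction_index: dict[tuple[str, int, int], list[tuple[str, str, str]]] = {}
    retention_index = _RetentionIndex()
    for ev in catalog:
        for label, junctions, retained in (
            ("A", ev.isoform_a_junctions, ev.a_retained),
            ("B", ev.isoform_b_junctions, ev.b_retained),
        ):
            for j in junctions:
                junction_index.setdefault(j.key(), []).append((ev.event_id, label, j.label()))
            if retained is not None:
                for boundary in (retained.start, retained.end):
                    retention_index.add(
                        retained.chrom, boundary,
                        (ev.event_id, label, f"{retained.chrom}:{boundary}^"),
                    )
    retention_index.freeze()
    return junction_index, retention_index


def count_event_reads(
    filtered_reads: Iterable[AlignedRead],
    event_catalog: Sequence[SplicingEvent],
    sample_id: str = "sample",
    retention_flank: int = DEFAULT_MIN_OVERHANG,
) -> JunctionCounts:
    """Count identifying reads per event isoform.

    A spliced read supports a junction isoform when one of its gaps matches a
    cataloged junction exactly (block boundaries coincide with donor and
    acceptor). An unspliced block supports a retention isoform when it covers
    a retained intron's boundary with at least ``retention_flank`` aligned nt
    on both sides. A fragment (all records sharing a read id) increments each
    event at most once, and never both isoforms of one event: conflicting
    support is discarded and counted as ambiguous.
    """
    junction_index, retention_index = _build_indices(event_catalog)
    counts = JunctionCounts(sample_id)
    support: dict[str, dict[str, set[tuple[str, str]]]] = {}

    for read in filtered_reads:
        rs = support.setdefault(read.read_id, {})
        for lo, hi in read.gaps:
            entries = junction_index.get((read.chrom, lo, hi))
            if not entries:
                counts.unassigned += 1
                continue
            for event_id, label, key in entries:
                rs.setdefault(event_id, set()).add((label, key))
        for bs, be in read.blocks:
            for pos, (event_id, label, key) in retention_index.lookup(
                read.chrom, bs + retention_flank, be - retention_flank
            ):
                if bs + retention_flank <= pos <= be - retention_flank:
                    rs.setdefault(event_id, set()).add((label, key))

    for rs in support.values():
        for event_id, labelled in rs.items():
            labels = {lab for lab, _ in labelled}
            if len(labels) != 1:
                counts.ambiguous += 1
                continue
            label = labels.pop()
            counts.counts[(event_id, label)] = counts.counts.get((event_id, label), 0) + 1
            for _, key in labelled:
                counts.junction_counts[(event_id, label, key)] = (
                    counts.junction_counts.get((event_id, label, key), 0) + 1
                )
    return counts


def identifying_reads(counts: JunctionCounts, event: SplicingEvent | str) -> int:
    """Total identifying reads for one event: isoform-A plus isoform-B reads."""
    event_id = event if isinstance(event, str) else event.event_id
    return counts.counts.get((event_id, "A"), 0) + counts.counts.get((event_id, "B"), 0)


def estimate_psi(
    k: int,
    n: int,
    event_id: str = "",
    sample_id: str = "",
    ci: float = 0.95,
) -> PsiEstimate:
    """Isoform-ratio estimate with a uniform-prior Beta posterior interval.

    psi_hat = k/n; the credible bounds are the (1-ci)/2 and 1-(1-ci)/2
    quantiles of Beta(k+1, n-k+1). With n = 0 all values are NaN markers so
    the event is carried forward explicitly rather than dropped.
    """
    if k < 0 or n < 0 or k > n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    if n == 0:
        return PsiEstimate(event_id, sample_id, 0, 0, math.nan, math.nan, math.nan)
    alpha = (1.0 - ci) / 2.0
    lo, hi = beta_dist.ppf([alpha, 1.0 - alpha], k + 1, n - k + 1)
    psi = k / n
    # the interval always contains the point estimate (clamped at k=0, k=n)
    return PsiEstimate(event_id, sample_id, k, n, psi, min(float(lo), psi), max(float(hi), psi))


def psi_table(
    counts: JunctionCounts, catalog: Sequence[SplicingEvent], ci: float = 0.95
) -> list[PsiEstimate]:
    """PSI estimates for every cataloged event in one sample, in catalog order."""
    out = []
    for ev in catalog:
        k, n = counts.k_n(ev.event_id)
        out.append(estimate_psi(k, n, ev.event_id, counts.sample_id, ci))
    return out
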