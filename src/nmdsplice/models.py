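"""Core domain types shared across the annotation, quantification and testing layers.

Coordinates are 0-based half-open throughout; GTF/BED conversions happen only
in the readers and writers. Splice junctions are identified by the genomic
positions of their intron boundaries: ``donor_pos`` abuts the upstream exon and
``acceptor_pos`` the downstream exon, so on the plus strand
``donor_pos < acceptor_pos`` and on the minus strand the order is reversed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional


class NMDStatus(str, enum.Enum):
    """Predicted fate of an isoform under the 50-nt rule."""

    SUBSTRATE = "nmd_substrate"
    NOT_SUBSTRATE = "not_substrate"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class EventClass(str, enum.Enum):
    CASSETTE_EXON = "cassette_exon"
    ALT_5SS = "alt_5ss"
    ALT_3SS = "alt_3ss"
    RETAINED_INTRON = "retained_intron"
    MUTUALLY_EXCLUSIVE = "mutually_exclusive"
    NOVEL_JUNCTION = "novel_junction"
    CONSTITUTIVE_INTRON_RETENTION = "constitutive_intron_retention"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval on a stranded chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"illegal strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SpliceJunction:
    """An intron, identified by the genomic positions of its boundaries.

    ``constitutive`` and ``annotated`` are classification flags and do not take
    part in identity: the same physical junction compares and hashes equal
    whatever it has been labelled.
    """

    chrom: str
    donor_pos: int
    acceptor_pos: int
    strand: str
    constitutive: bool = field(default=False, compare=False)
    annotated: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if self.strand == "+":
            if self.donor_pos >= self.acceptor_pos:
                raise ValueError("plus-strand junction requires donor < acceptor")
        elif self.strand == "-":
            if self.donor_pos <= self.acceptor_pos:
                raise ValueError("minus-strand junction requires donor > acceptor")
        else:
            raise ValueError(f"illegal strand {self.strand!r}")

    @property
    def intron(self) -> GenomicInterval:
        lo, hi = sorted((self.donor_pos, self.acceptor_pos))
        return GenomicInterval(self.chrom, lo, hi, self.strand)

    @property
    def intron_length(self) -> int:
        return abs(self.acceptor_pos - self.donor_pos)

    def key(self) -> tuple[str, int, int]:
        """Strand-agnostic lookup key (chrom, intron lo, intron hi)."""
        lo, hi = sorted((self.donor_pos, self.acceptor_pos))
        return (self.chrom, lo, hi)

    def label(self) -> str:
        return f"{self.chrom}:{self.donor_pos}-{self.acceptor_pos}"


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure (and optionally the ORF) of a single isoform.

    Exons are ordered 5'->3' in transcript orientation: ascending genomic
    coordinates on the plus strand, descending on the minus strand. ``cds`` is
    a half-open interval in spliced-transcript coordinates and, by this
    package's convention, includes the stop codon.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    source: str = "annotationA"
    cds: Optional[tuple[int, int]] = None
    also_known_as: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        strand = self.exons[0].strand
        chrom = self.exons[0].chrom
        for e in self.exons:
            if e.strand != strand or e.chrom != chrom:
                raise ValueError(f"transcript {self.transcript_id} mixes chrom/strand")
        for a, b in zip(self.exons, self.exons[1:]):
            if strand == "+" and a.end > b.start:
                raise ValueError(f"transcript {self.transcript_id}: exons unordered/overlapping")
            if strand == "-" and b.end > a.start:
                raise ValueError(f"transcript {self.transcript_id}: exons unordered/overlapping")
        if self.cds is not None:
            s, e = self.cds
            if not (0 <= s < e <= self.length):
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS ({s},{e}) outside transcript of length {self.length}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        starts = [e.start for e in self.exons]
        ends = [e.end for e in self.exons]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)

    def junctions(self) -> tuple[SpliceJunction, ...]:
        """Splice junctions between consecutive exons, 5'->3'."""
        out = []
        for up, down in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(SpliceJunction(self.chrom, up.end, down.start, "+"))
            else:
                out.append(SpliceJunction(self.chrom, up.start, down.end, "-"))
        return tuple(out)

    def junction_positions(self) -> tuple[int, ...]:
        """Transcript-coordinate positions of exon-exon junctions.

        Position ``j`` means the junction sits between spliced bases ``j-1``
        and ``j``.
        """
        pos, acc = [], 0
        for e in self.exons[:-1]:
            acc += len(e)
            pos.append(acc)
        return tuple(pos)

    def exon_chain_key(self) -> tuple:
        """Identity of the exon chain: chrom, strand and all exon boundaries."""
        return (self.chrom, self.strand, tuple((e.start, e.end) for e in self.exons))

    def to_genomic(self, tx_pos: int) -> int:
        """Map a transcript coordinate to the genomic coordinate of that base."""
        if not 0 <= tx_pos < self.length:
            raise ValueError(f"transcript position {tx_pos} outside [0,{self.length})")
        off = tx_pos
        for e in self.exons:
            if off < len(e):
                return e.start + off if self.strand == "+" else e.end - 1 - off
            off -= len(e)
        raise AssertionError("unreachable")

    def genomic_to_tx(self, gpos: int) -> Optional[int]:
        """Map a genomic base to its transcript coordinate, or None if intronic."""
        acc = 0
        for e in self.exons:
            if e.start <= gpos < e.end:
                return acc + (gpos - e.start if self.strand == "+" else e.end - 1 - gpos)
            acc += len(e)
        return None


@dataclass(frozen=True)
class OrfAssignment:
    """Resolved ORF of one transcript, with the provenance of the call."""

    transcript_id: str
    cds: Optional[tuple[int, int]]
    source: str  # curated_db | annotation_predicted | longest_orf_fallback | none

    def __post_init__(self) -> None:
        if (self.source == "none") != (self.cds is None):
            raise ValueError("source=none iff cds absent")


@dataclass(frozen=True)
class NMDCall:
    transcript_id: str
    status: NMDStatus
    max_downstream_junction_distance: Optional[int] = None


@dataclass(frozen=True)
class SplicingEvent:
    """A binary isoform contrast — the unit of quantification and testing.

    By convention isoform A is the designated isoform: the predicted NMD
    substrate when exactly one of the two isoforms is a substrate. A retention
    isoform is represented by its retained genomic interval instead of (or in
    addition to) junctions.
    """

    event_id: str
    event_class: EventClass
    gene_id: str
    isoform_a_junctions: frozenset[SpliceJunction]
    isoform_b_junctions: frozenset[SpliceJunction]
    nmd_flag_a: NMDStatus = NMDStatus.UNKNOWN
    nmd_flag_b: NMDStatus = NMDStatus.UNKNOWN
    a_retained: Optional[GenomicInterval] = None
    b_retained: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        same_junctions = self.isoform_a_junctions == self.isoform_b_junctions
        same_retention = self.a_retained == self.b_retained
        if same_junctions and same_retention:
            raise ValueError(f"event {self.event_id}: isoforms are identical")

    @property
    def eligible(self) -> bool:
        """True when exactly one isoform is a predicted NMD substrate."""
        return (self.nmd_flag_a == NMDStatus.SUBSTRATE) != (
            self.nmd_flag_b == NMDStatus.SUBSTRATE
        )


@dataclass
class PsiEstimate:
    """Isoform-ratio estimate for one event in one sample.

    ``psi_hat`` is k/n for the designated isoform with a uniform-prior Beta
    posterior credible interval; with no identifying reads all three values
    are NaN markers.
    """

    event_id: str
    sample_id: str
    k: int
    n: int
    psi_hat: float
    ci_low: float
    ci_high: float

    @property
    def defined(self) -> bool:
        return self.n > 0 and not math.isnan(self.psi_hat)


@dataclass
class DiffSpliceCall:
    """Differential-splicing test outcome for one event."""

    event_id: str
    k1: int
    n1: int
    k2: int
    n2: int
    psi1: float
    psi2: float
    delta_psi: float
    bf10: float
    passes_reads: bool
    passes_delta: bool
    passes_bf: bool
    nmd_direction: str = "ineligible"  # nmd_up | nmd_down | unchanged | ineligible

    @property
    def called(self) -> bool:
        return self.passes_reads and self.passes_delta and self.passes_bf


@dataclass
class ClassSummary:
    """Per-event-class tally of NMD-substrate direction changes."""

    event_class: str
    n_eligible: int
    n_up: int
    n_down: int

    @property
    def frac_nmd_up(self) -> float:
        return self.n_up / self.n_eligible if self.n_eligible else 0.0

    @property
    def frac_nmd_down(self) -> float:
        return self.n_down / self.n_eligible if self.n_eligible else 0.0

    @property
    def enrichment(self) -> float:
        """Ratio of up- to down-fractions; NaN marker when nothing decreased."""
        if self.n_eligible == 0 or self.n_down == 0:
            return math.nan
        return self.n_up / self.n_down


@dataclass
class GlobalSummary:
    """The global up/down pattern of predicted NMD substrates, per event class."""

    classes: dict[str, ClassSummary]

    def overall(self) -> ClassSummary:
        return ClassSummary(
            "all",
            sum(c.n_eligible for c in self.classes.values()),
            sum(c.n_up for c in self.classes.values()),
            sum(c.n_down for c in self.classes.values()),
        )
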