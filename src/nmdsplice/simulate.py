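"""Synthetic data generator with known ground truth.

Emulates the statistical structure of a two-condition NMD-inhibition
experiment: a catalog of binary splicing events, each with one predicted
NMD-substrate isoform, whose relative abundance is multiplied (on the odds
scale) by a stabilization factor in the "NMD-inhibited" condition for a
configurable fraction of events. Outputs are a GTF annotation, a curated-ORF
table, per-condition junction-count tables, optional SAM alignments, and the
implanted truth for every transcript and event.

Gene structures are fixed templates per event class, laid out on one
synthetic chromosome with disjoint loci; ORFs are placed so the designated
isoform violates or satisfies the 50-nt rule as implanted. Everything is
deterministic under the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml

from .annotation import aberrant_isoform_id
from .models import EventClass, GenomicInterval, SpliceJunction, TranscriptModel
from .quantify import JunctionCounts

CHROM = "chrS"
_GENE_SPACING = 5_000
_GENE_OFFSET0 = 10_000

DEFAULT_CLASS_MIX = {
    "cassette_exon": 0.30,
    "alt_5ss": 0.10,
    "alt_3ss": 0.10,
    "retained_intron": 0.10,
    "mutually_exclusive": 0.05,
    "novel_junction": 0.20,
    "constitutive_intron_retention": 0.15,
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    depth is the mean identifying-read count per event and condition
    (Poisson); psi_baseline the Beta(a, b) prior for the condition-1 isoform
    ratio; stabilization the multiplicative odds factor applied to the
    substrate isoform in condition 2 for the affected fraction of
    NMD-eligible events; dispersion, when set, is a beta-binomial
    concentration (smaller = noisier counts).
    """

    n_genes: int = 1000
    event_class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    depth: float = 100.0
    psi_baseline: tuple[float, float] = (2.0, 2.0)
    affected_fraction: float = 0.15
    stabilization: float = 3.5
    dispersion: Optional[float] = None
    nmd_eligible_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.stabilization < 1:
            raise ValueError("stabilization must be >= 1")
        bad = set(self.event_class_mix) - {c.value for c in EventClass}
        if bad:
            raise ValueError(f"unknown event classes in mix: {sorted(bad)}")
        total = sum(self.event_class_mix.values())
        if total <= 0:
            raise ValueError("event_class_mix proportions must sum to a positive value")
        if abs(total - 1.0) > 1e-9:
            self.event_class_mix = {k: v / total for k, v in self.event_class_mix.items()}
        for name in ("affected_fraction", "nmd_eligible_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "psi_baseline" in d:
            d["psi_baseline"] = tuple(d["psi_baseline"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["psi_baseline"] = list(self.psi_baseline)
        return d


@dataclass
class TruthEvent:
    """Implanted truth for one simulated splicing event."""

    event_id: str
    gene_id: str
    event_class: str
    eligible: bool
    affected: bool
    a_junctions: tuple[SpliceJunction, ...] = ()
    b_junctions: tuple[SpliceJunction, ...] = ()
    a_retained: Optional[GenomicInterval] = None
    b_retained: Optional[GenomicInterval] = None
    psi1: float = math.nan
    psi2: float = math.nan
    n1: int = -1
    k1: int = -1
    n2: int = -1
    k2: int = -1


@dataclass
class GroundTruth:
    events: list[TruthEvent]
    transcript_status: dict[str, str]

    def by_id(self) -> dict[str, TruthEvent]:
        return {e.event_id: e for e in self.events}


@dataclass
class SimulatedAnnotation:
    """generate_annotation output bundle: GTF text, curated-ORF table and
    the in-memory models it serializes, plus the implanted truth."""

    transcripts: list[TranscriptModel]
    orf_table: dict[str, tuple[int, int]]
    gtf_text: str
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Gene templates, one per event class
# ---------------------------------------------------------------------------

def _iv(o: int, s: int, e: int, strand: str = "+") -> GenomicInterval:
    return GenomicInterval(CHROM, o + s, o + e, strand)


def _jct(o: int, d: int, a: int, strand: str = "+") -> SpliceJunction:
    return SpliceJunction(CHROM, o + d, o + a, strand)


def _make_gene(cls_name: str, gid: str, o: int, eligible: bool):
    """Build one gene: transcript models, curated-ORF entries and the truth
    skeleton of its single implanted event. Substrate status is controlled
    entirely by the implanted ORFs under the 50-nt rule."""
    transcripts: list[TranscriptModel] = []
    orfs: dict[str, tuple[int, int]] = {}
    status: dict[str, str] = {}

    if cls_name == "cassette_exon":
        e1, e2, e3 = _iv(o, 0, 300), _iv(o, 400, 550), _iv(o, 650, 1000)
        inc = TranscriptModel(f"{gid}.inc", gid, (e1, e2, e3))
        exc = TranscriptModel(f"{gid}.exc", gid, (e1, e3))
        # inclusion stop 102 nt upstream of the exon2/exon3 junction when eligible
        orfs[inc.transcript_id] = (0, 348) if eligible else (0, 480)
        orfs[exc.transcript_id] = (0, 450)
        transcripts += [inc, exc]
        status[inc.transcript_id] = "nmd_substrate" if eligible else "not_substrate"
        status[exc.transcript_id] = "not_substrate"
        ev = TruthEvent(
            f"{gid}:CE:{CHROM}:{o + 400}-{o + 550}", gid, cls_name, eligible, False,
            a_junctions=(_jct(o, 300, 400), _jct(o, 550, 650)),
            b_junctions=(_jct(o, 300, 650),),
        )
    elif cls_name == "alt_5ss":
        e3, e2 = _iv(o, 0, 350, "-"), _iv(o, 450, 600, "-")
        e1l, e1s = _iv(o, 700, 1000, "-"), _iv(o, 760, 1000, "-")
        ta = TranscriptModel(f"{gid}.a", gid, (e1l, e2, e3))
        tb = TranscriptModel(f"{gid}.b", gid, (e1s, e2, e3))
        orfs[ta.transcript_id] = (0, 300) if eligible else (0, 600)
        orfs[tb.transcript_id] = (0, 600)
        transcripts += [ta, tb]
        status[ta.transcript_id] = "nmd_substrate" if eligible else "not_substrate"
        status[tb.transcript_id] = "not_substrate"
        ev = TruthEvent(
            f"{gid}:A5:{CHROM}:{o + 700}-{o + 760}:{o + 600}", gid, cls_name, eligible, False,
            a_junctions=(_jct(o, 700, 600, "-"),),
            b_junctions=(_jct(o, 760, 600, "-"),),
        )
    elif cls_name == "alt_3ss":
        e1, e2a, e2b, e3 = _iv(o, 0, 300), _iv(o, 400, 600), _iv(o, 460, 600), _iv(o, 700, 1000)
        ta = TranscriptModel(f"{gid}.a", gid, (e1, e2a, e3))
        tb = TranscriptModel(f"{gid}.b", gid, (e1, e2b, e3))
        orfs[ta.transcript_id] = (0, 348) if eligible else (0, 600)
        orfs[tb.transcript_id] = (0, 540)
        transcripts += [ta, tb]
        status[ta.transcript_id] = "nmd_substrate" if eligible else "not_substrate"
        status[tb.transcript_id] = "not_substrate"
        ev = TruthEvent(
            f"{gid}:A3:{CHROM}:{o + 400}-{o + 460}:{o + 300}", gid, cls_name, eligible, False,
            a_junctions=(_jct(o, 300, 400),),
            b_junctions=(_jct(o, 300, 460),),
        )
    elif cls_name == "retained_intron":
        e1, e2 = _iv(o, 0, 600), _iv(o, 700, 1000)
        spl = TranscriptModel(f"{gid}.spl", gid, (e1, e2))
        ret = TranscriptModel(f"{gid}.ret", gid, (_iv(o, 0, 1000),))
        cds = (0, 498) if eligible else (0, 570)
        orfs[spl.transcript_id] = cds
        orfs[ret.transcript_id] = cds
        transcripts += [spl, ret]
        status[spl.transcript_id] = "nmd_substrate" if eligible else "not_substrate"
        status[ret.transcript_id] = "not_substrate"
        ev = TruthEvent(
            f"{gid}:RI:{CHROM}:{o + 600}-{o + 700}", gid, cls_name, eligible, False,
            a_junctions=(_jct(o, 600, 700),),
            b_retained=_iv(o, 600, 700),
        )
    elif cls_name == "mutually_exclusive":
        e1, e2a, e2b, e3 = _iv(o, 0, 300), _iv(o, 400, 550), _iv(o, 600, 750), _iv(o, 850, 1100)
        ta = TranscriptModel(f"{gid}.a", gid, (e1, e2a, e3))
        tb = TranscriptModel(f"{gid}.b", gid, (e1, e2b, e3))
        orfs[ta.transcript_id] = (0, 348) if eligible else (0, 600)
        orfs[tb.transcript_id] = (0, 600)
        transcripts += [ta, tb]
        status[ta.transcript_id] = "nmd_substrate" if eligible else "not_substrate"
        status[tb.transcript_id] = "not_substrate"
        ev = TruthEvent(
            f"{gid}:MX:{CHROM}:{o + 400}-{o + 550}:{o + 600}-{o + 750}",
            gid, cls_name, eligible, False,
            a_junctions=(_jct(o, 300, 400), _jct(o, 550, 850)),
            b_junctions=(_jct(o, 300, 600), _jct(o, 750, 850)),
        )
    elif cls_name == "novel_junction":
        e1, e2, e3 = _iv(o, 0, 300), _iv(o, 380, 460), _iv(o, 540, 840)
        t = TranscriptModel(f"{gid}.t", gid, (e1, e2, e3))
        orfs[t.transcript_id] = (0, 375)
        transcripts.append(t)
        status[t.transcript_id] = "not_substrate"
        event_id = f"{gid}:NJ:{CHROM}:{o + 300}-{o + 540}"
        # aberrant isoform skips exon 2; its curated ORF implants the PTC
        orfs[aberrant_isoform_id(event_id)] = (0, 150) if eligible else (0, 420)
        ev = TruthEvent(
            event_id, gid, cls_name, eligible, False,
            a_junctions=(_jct(o, 300, 540),),
            b_junctions=(_jct(o, 300, 380),),
        )
    elif cls_name == "constitutive_intron_retention":
        e1, e2 = _iv(o, 0, 600), _iv(o, 700, 1000)
        t = TranscriptModel(f"{gid}.t", gid, (e1, e2))
        cds = (0, 498) if eligible else (0, 570)
        orfs[t.transcript_id] = cds
        transcripts.append(t)
        status[t.transcript_id] = "nmd_substrate" if eligible else "not_substrate"
        event_id = f"{gid}:CIR:{CHROM}:{o + 600}-{o + 700}"
        orfs[aberrant_isoform_id(event_id)] = cds
        if eligible:
            # designated isoform: the (substrate) spliced form
            ev = TruthEvent(
                event_id, gid, cls_name, eligible, False,
                a_junctions=(_jct(o, 600, 700),),
                b_retained=_iv(o, 600, 700),
            )
        else:
            ev = TruthEvent(
                event_id, gid, cls_name, eligible, False,
                a_retained=_iv(o, 600, 700),
                b_junctions=(_jct(o, 600, 700),),
            )
    else:  # pragma: no cover - guarded by SimulationConfig validation
        raise ValueError(f"unknown event class {cls_name!r}")
    return transcripts, orfs, status, ev


def _class_allocation(config: SimulationConfig) -> list[str]:
    """Deterministic largest-remainder allocation of genes to event classes."""
    items = sorted(config.event_class_mix.items())
    raw = [(name, config.n_genes * prop) for name, prop in items]
    counts = {name: int(x) for name, x in raw}
    short = config.n_genes - sum(counts.values())
    for name, _ in sorted(raw, key=lambda t: (-(t[1] - int(t[1])), t[0]))[:short]:
        counts[name] += 1
    out = []
    for name, _ in items:
        out.extend([name] * counts[name])
    return out


def _tx_range_to_genomic(t: TranscriptModel, s: int, e: int) -> list[GenomicInterval]:
    """Genomic intervals covered by transcript-coordinate range [s, e)."""
    out = []
    acc = 0
    for exon in t.exons:
        lo, hi = max(s, acc), min(e, acc + len(exon))
        if lo < hi:
            if t.strand == "+":
                out.append(GenomicInterval(exon.chrom, exon.start + (lo - acc), exon.start + (hi - acc), "+"))
            else:
                out.append(GenomicInterval(exon.chrom, exon.end - (hi - acc), exon.end - (lo - acc), "-"))
        acc += len(exon)
    return out


def _gtf_text(transcripts: Sequence[TranscriptModel], orf_table: dict) -> str:
    """Serialize models to GTF (1-based inclusive). CDS features include the
    stop codon, matching this package's transcript-coordinate convention."""
    lines = []
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    for gid in sorted(by_gene):
        members = sorted(by_gene[gid], key=lambda t: t.transcript_id)
        span_lo = min(t.span.start for t in members)
        span_hi = max(t.span.end for t in members)
        chrom, strand = members[0].chrom, members[0].strand
        attrs = f'gene_id "{gid}";'
        lines.append(
            f"{chrom}\tnmdsplice_sim\tgene\t{span_lo + 1}\t{span_hi}\t.\t{strand}\t.\t{attrs}"
        )
        for t in members:
            tattrs = f'gene_id "{gid}"; transcript_id "{t.transcript_id}";'
            lines.append(
                f"{chrom}\tnmdsplice_sim\ttranscript\t{t.span.start + 1}\t{t.span.end}\t.\t{strand}\t.\t{tattrs}"
            )
            for e in sorted(t.exons, key=lambda e: e.start):
                lines.append(
                    f"{chrom}\tnmdsplice_sim\texon\t{e.start + 1}\t{e.end}\t.\t{strand}\t.\t{tattrs}"
                )
            cds = orf_table.get(t.transcript_id)
            if cds:
                for iv in sorted(_tx_range_to_genomic(t, *cds), key=lambda i: i.start):
                    lines.append(
                        f"{chrom}\tnmdsplice_sim\tCDS\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t0\t{tattrs}"
                    )
    return "\n".join(lines) + "\n"


def generate_annotation(config: SimulationConfig) -> SimulatedAnnotation:
    """Generate the synthetic annotation and implanted truth.

    One gene per event class slot; NMD eligibility (exactly one substrate
    isoform) and the affected flag are drawn per event from the configured
    fractions, deterministically under the seed.
    """
    rng = np.random.default_rng(config.seed)
    transcripts: list[TranscriptModel] = []
    orf_table: dict[str, tuple[int, int]] = {}
    status: dict[str, str] = {}
    events: list[TruthEvent] = []
    for i, cls_name in enumerate(_class_allocation(config)):
        gid = f"g{i:05d}"
        o = _GENE_OFFSET0 + i * _GENE_SPACING
        eligible = bool(rng.random() < config.nmd_eligible_fraction)
        ts, orfs, st, ev = _make_gene(cls_name, gid, o, eligible)
        ev.affected = eligible and bool(rng.random() < config.affected_fraction)
        transcripts.extend(ts)
        orf_table.update(orfs)
        status.update(st)
        events.append(ev)
    truth = GroundTruth(events, status)
    return SimulatedAnnotation(transcripts, orf_table, _gtf_text(transcripts, orf_table), truth)


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def shifted_psi(psi1: float, stabilization: float) -> float:
    """Condition-2 ratio after multiplying the substrate isoform's odds."""
    if stabilization == 1.0 or psi1 <= 0.0:
        return psi1 if 0.0 <= psi1 else 0.0
    if psi1 >= 1.0:
        return 1.0
    return _logistic(math.log(psi1 / (1 - psi1)) + math.log(stabilization))


def simulate_counts(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: Optional[np.random.Generator] = None,
) -> tuple[JunctionCounts, JunctionCounts]:
    """Draw two-condition identifying-read counts for every truth event.

    Per event and condition: n ~ Poisson(depth), k ~ Binomial(n, psi) (or
    beta-binomial when dispersion is set); affected events have their
    condition-2 psi shifted by the stabilization factor on the odds scale.
    Realized tallies are written back into the truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    a, b = config.psi_baseline
    c1 = JunctionCounts("cond1")
    c2 = JunctionCounts("cond2")
    for ev in truth.events:
        psi1 = float(np.clip(rng.beta(a, b), 1e-9, 1 - 1e-9))
        psi2 = shifted_psi(psi1, config.stabilization) if ev.affected else psi1
        ks, ns = [], []
        for psi in (psi1, psi2):
            n = int(rng.poisson(config.depth))
            p = psi
            if config.dispersion is not None:
                p = float(rng.beta(psi * config.dispersion, (1 - psi) * config.dispersion))
            k = int(rng.binomial(n, p)) if n > 0 else 0
            ks.append(k)
            ns.append(n)
        ev.psi1, ev.psi2 = psi1, psi2
        ev.k1, ev.n1, ev.k2, ev.n2 = ks[0], ns[0], ks[1], ns[1]
        for counts, k, n in ((c1, ks[0], ns[0]), (c2, ks[1], ns[1])):
            counts.counts[(ev.event_id, "A")] = k
            counts.counts[(ev.event_id, "B")] = n - k
            # shared-junction coupling: reads supporting the reference
            # junction of a novel-junction contrast also support the spliced
            # isoform of the retention contrast on that same constitutive
            # junction, so the tables mirror what the emitted alignments imply
            if ev.event_class == "novel_junction" and n - k > 0:
                (ref,) = ev.b_junctions
                lo, hi = sorted((ref.donor_pos, ref.acceptor_pos))
                sibling = f"{ev.gene_id}:CIR:{ref.chrom}:{lo}-{hi}"
                counts.counts[(sibling, "B")] = n - k
    return c1, c2


# ---------------------------------------------------------------------------
# SAM emission
# ---------------------------------------------------------------------------

def _isoform_read(junctions, retained, idx: int, flank: int, short: bool):
    """(pos0, cigar) for the idx-th read of one isoform (round-robin over its
    junctions / retention boundaries)."""
    if junctions:
        j = junctions[idx % len(junctions)]
        lo, hi = sorted((j.donor_pos, j.acceptor_pos))
        left = 5 if short else flank
        return lo - left, f"{left}M{hi - lo}N{flank}M"
    boundary = (retained.start, retained.end)[idx % 2]
    return boundary - flank, f"{2 * flank}M"


def emit_sam(
    sim: SimulatedAnnotation,
    counts: JunctionCounts,
    rng: Optional[np.random.Generator] = None,
    mapq_zero_fraction: float = 0.0,
    short_overhang_fraction: float = 0.0,
    flank: int = 10,
    mapq: int = 50,
) -> str:
    """Render one condition's counts as junction-spanning SAM alignments.

    With the decoy fractions at zero (the default), re-running the alignment
    path (filter, count) on this text reproduces ``counts`` exactly. Nonzero
    fractions re-emit that share of reads with mapq 0 or a 5-nt overhang so
    the post-alignment filters can be exercised end to end.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    chrom_len: dict[str, int] = {}
    for t in sim.transcripts:
        chrom_len[t.chrom] = max(chrom_len.get(t.chrom, 0), t.span.end + 1000)
    records = []
    ridx = 0
    for ev in sorted(sim.truth.events, key=lambda e: e.event_id):
        for label, junctions, retained in (
            ("A", ev.a_junctions, ev.a_retained),
            ("B", ev.b_junctions, ev.b_retained),
        ):
            n_reads = counts.counts.get((ev.event_id, label), 0)
            if n_reads <= 0:
                continue
            chrom = junctions[0].chrom if junctions else retained.chrom
            for i in range(n_reads):
                short = bool(short_overhang_fraction and rng.random() < short_overhang_fraction)
                pos0, cigar = _isoform_read(junctions, retained, i, flank, short)
                q = 0 if mapq_zero_fraction and rng.random() < mapq_zero_fraction else mapq
                records.append(
                    (chrom, pos0,
                     f"r{counts.sample_id}.{ridx:08d}\t0\t{chrom}\t{pos0 + 1}\t{q}\t{cigar}\t*\t0\t0\t*\t*")
                )
                ridx += 1
    records.sort(key=lambda r: (r[0], r[1]))
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for chrom in sorted(chrom_len):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{chrom_len[chrom]}")
    for _, _, rec in records:
        lines.append(rec)
    return "\n".join(lines) + "\n"
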