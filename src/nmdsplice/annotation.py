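"""Annotation processing: merged transcript models, constitutive junctions,
candidate (novel) junctions, ORF assignment, NMD-substrate classification and
the binary splicing-event catalog.

The central prediction is the 50-nt rule: an isoform is a predicted substrate
of nonsense-mediated decay (NMD) when its stop codon lies more than 50 nt
upstream of at least one downstream exon-exon junction, measured in
spliced-transcript coordinates from the last base of the stop codon.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import gffutils

from .models import (
    EventClass,
    GenomicInterval,
    NMDCall,
    NMDStatus,
    OrfAssignment,
    SpliceJunction,
    SplicingEvent,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
DEFAULT_PTC_DISTANCE = 50


class GtfParseError(ValueError):
    """Raised for malformed GTF input, naming the offending line."""


# ---------------------------------------------------------------------------
# GTF reading
# ---------------------------------------------------------------------------

def _validate_gtf_lines(path: str) -> None:
    """Cheap structural pre-scan so parse errors can name the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GtfParseError(f"{path}:{lineno}: non-numeric coordinates") from None
            if start < 1 or end < start:
                raise GtfParseError(f"{path}:{lineno}: invalid coordinate range {start}..{end}")
            if fields[6] not in ("+", "-", "."):
                raise GtfParseError(f"{path}:{lineno}: invalid strand {fields[6]!r}")


def read_gtf(path: str, source: str = "annotationA") -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Exons are ordered 5'->3' in transcript orientation. CDS features (plus any
    stop_codon features) are mapped into transcript coordinates; the stored
    CDS interval therefore includes the stop codon.
    """
    _validate_gtf_lines(path)
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils internal failures
        raise GtfParseError(f"{path}: {exc}") from exc

    exons: dict[str, list] = defaultdict(list)
    cds_parts: dict[str, list] = defaultdict(list)
    gene_of: dict[str, str] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        tids = feat.attributes.get("transcript_id")
        if not tids:
            raise GtfParseError(
                f"{path}: {feat.featuretype} feature at {feat.seqid}:{feat.start} lacks transcript_id"
            )
        tid = tids[0]
        gene_of.setdefault(tid, feat.attributes.get("gene_id", [tid])[0])
        iv = (feat.seqid, feat.start - 1, feat.end, feat.strand)
        if feat.featuretype == "exon":
            exons[tid].append(iv)
        else:
            cds_parts[tid].append(iv)

    for tid in cds_parts:
        if tid not in exons:
            raise GtfParseError(f"{path}: transcript {tid} has CDS features but zero exons")

    models = []
    for tid, ivs in exons.items():
        strand = ivs[0][3]
        ivs.sort(key=lambda x: x[1], reverse=(strand == "-"))
        exon_tuple = tuple(
            GenomicInterval(chrom, s, e, strand) for chrom, s, e, strand in ivs
        )
        model = TranscriptModel(tid, gene_of[tid], exon_tuple, source=source)
        cds = None
        if tid in cds_parts:
            tx_coords = []
            ok = True
            for chrom, s, e, _ in cds_parts[tid]:
                lo = model.genomic_to_tx(s)
                hi = model.genomic_to_tx(e - 1)
                if lo is None or hi is None:
                    logger.warning("transcript %s: CDS outside exons; CDS dropped", tid)
                    ok = False
                    break
                tx_coords.extend((lo, hi))
            if ok and tx_coords:
                cds = (min(tx_coords), max(tx_coords) + 1)
        if cds is not None:
            model = TranscriptModel(tid, gene_of[tid], exon_tuple, source=source, cds=cds)
        models.append(model)
    models.sort(key=lambda m: m.transcript_id)
    return models


# ---------------------------------------------------------------------------
# Annotation merging and gene grouping
# ---------------------------------------------------------------------------

def merge_annotations(
    set_a: Sequence[TranscriptModel], set_b: Sequence[TranscriptModel]
) -> list[TranscriptModel]:
    """Union of two annotation sets with identical exon chains collapsed.

    Two transcripts are the same record iff their exon chains (chromosome,
    strand, every exon boundary) are identical; a collapsed record keeps the
    lexicographically first transcript id and carries the others in
    ``also_known_as``. UTR-length variants therefore remain distinct records.
    """
    strand_of: dict[str, str] = {}
    for t in itertools.chain(set_a, set_b):
        prev = strand_of.setdefault(t.transcript_id, t.strand)
        if prev != t.strand:
            raise ValueError(
                f"transcript {t.transcript_id} has contradictory strands {prev!r}/{t.strand!r}"
            )

    by_chain: dict[tuple, list[TranscriptModel]] = {}
    for t in itertools.chain(set_a, set_b):
        by_chain.setdefault(t.exon_chain_key(), []).append(t)

    merged = []
    for members in by_chain.values():
        ids = sorted({m.transcript_id for m in members})
        rep = min(members, key=lambda m: m.transcript_id)
        if len(ids) == 1 and len(members) == 1:
            merged.append(rep)
            continue
        cds = next((m.cds for m in sorted(members, key=lambda m: m.transcript_id) if m.cds), None)
        merged.append(
            TranscriptModel(
                ids[0],
                rep.gene_id,
                rep.exons,
                source="merged",
                cds=cds,
                also_known_as=tuple(i for i in ids if i != ids[0]),
            )
        )
    merged.sort(key=lambda m: m.transcript_id)
    return merged


@dataclass(frozen=True)
class Gene:
    """A group of transcripts sharing exonic overlap on one strand."""

    gene_id: str
    transcripts: tuple[TranscriptModel, ...]

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    def junctions(self) -> set[SpliceJunction]:
        out: set[SpliceJunction] = set()
        for t in self.transcripts:
            out.update(t.junctions())
        return out


def _exons_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    return any(ea.overlaps(eb) for ea in a.exons for eb in b.exons)


def group_genes(transcripts: Sequence[TranscriptModel]) -> list[Gene]:
    """Group transcripts into genes: connected components of exon-overlapping,
    same-strand transcripts. The gene id is the sorted '|' join of member
    gene ids."""
    genes: list[Gene] = []
    by_cs: dict[tuple[str, str], list[TranscriptModel]] = defaultdict(list)
    for t in transcripts:
        by_cs[(t.chrom, t.strand)].append(t)
    for members in by_cs.values():
        members = sorted(members, key=lambda t: (t.span.start, t.transcript_id))
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(members)), 2):
            if members[j].span.start >= members[i].span.end:
                continue
            if _exons_overlap(members[i], members[j]):
                parent[find(i)] = find(j)
        comps: dict[int, list[TranscriptModel]] = defaultdict(list)
        for i, t in enumerate(members):
            comps[find(i)].append(t)
        for comp in comps.values():
            gid = "|".join(sorted({t.gene_id for t in comp}))
            genes.append(Gene(gid, tuple(sorted(comp, key=lambda t: t.transcript_id))))
    genes.sort(key=lambda g: (g.chrom, g.transcripts[0].span.start, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# Junction classification
# ---------------------------------------------------------------------------

def identify_constitutive_junctions(genes: Iterable[Gene]) -> set[SpliceJunction]:
    """Flag each annotated junction as constitutive or not.

    A junction is constitutive iff (i) every transcript of its gene whose span
    overlaps the intron splices exactly that junction, and (ii) its donor is
    paired with no other acceptor, and its acceptor with no other donor,
    anywhere in the gene.
    """
    out: set[SpliceJunction] = set()
    for gene in genes:
        juncs = gene.junctions()
        donor_to_acc: dict[int, set[int]] = defaultdict(set)
        acc_to_donor: dict[int, set[int]] = defaultdict(set)
        for j in juncs:
            donor_to_acc[j.donor_pos].add(j.acceptor_pos)
            acc_to_donor[j.acceptor_pos].add(j.donor_pos)
        for j in juncs:
            const = (
                len(donor_to_acc[j.donor_pos]) == 1
                and len(acc_to_donor[j.acceptor_pos]) == 1
            )
            if const:
                intron = j.intron
                for t in gene.transcripts:
                    if t.span.overlaps(intron) and j not in t.junctions():
                        const = False
                        break
            out.add(
                SpliceJunction(
                    j.chrom, j.donor_pos, j.acceptor_pos, j.strand,
                    constitutive=const, annotated=True,
                )
            )
    return out


def enumerate_candidate_junctions(gene: Gene) -> set[SpliceJunction]:
    """All donor x acceptor pairings of the gene's annotated splice sites.

    Pairs with the donor upstream of the acceptor in transcript orientation
    are returned; annotated pairings carry ``annotated=True``, the rest are
    the novel candidates used to detect aberrant splicing.
    """
    annotated = gene.junctions()
    donors = {j.donor_pos for j in annotated}
    acceptors = {j.acceptor_pos for j in annotated}
    out: set[SpliceJunction] = set()
    for d in donors:
        for a in acceptors:
            if gene.strand == "+" and not d < a:
                continue
            if gene.strand == "-" and not d > a:
                continue
            is_annot = any(j.donor_pos == d and j.acceptor_pos == a for j in annotated)
            out.add(
                SpliceJunction(gene.chrom, d, a, gene.strand, annotated=is_annot)
            )
    return out


# ---------------------------------------------------------------------------
# ORF assignment and NMD classification
# ---------------------------------------------------------------------------

def _valid_cds(cds: tuple[int, int], tx_length: int) -> bool:
    s, e = cds
    return 0 <= s < e <= tx_length and (e - s) % 3 == 0


def find_longest_orf(sequence: str, min_length: int = 60) -> Optional[tuple[int, int]]:
    """Longest AUG-initiated, stop-terminated ORF of at least ``min_length`` nt.

    Returns half-open coordinates including the stop codon, or None. Ties go
    to the 5'-most start.
    """
    seq = sequence.upper().replace("U", "T")
    best: Optional[tuple[int, int]] = None
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for pos in range(start + 3, len(seq) - 2, 3):
            if seq[pos : pos + 3] in STOP_CODONS:
                length = pos + 3 - start
                if length >= min_length and (best is None or length > best[1] - best[0]):
                    best = (start, pos + 3)
                break
    return best


def assign_orf(
    transcript: TranscriptModel,
    curated_orf_table: Optional[Mapping[str, tuple[int, int]]] = None,
    sequence: Optional[str] = None,
    min_orf_length: int = 60,
) -> OrfAssignment:
    """Resolve the transcript's ORF with precedence
    curated table > annotation CDS > longest-ORF fallback.

    The annotation CDS is rejected (with a warning) when its length is not a
    multiple of three or, when a spliced sequence is supplied, when it
    contains an internal stop codon.
    """
    tid = transcript.transcript_id
    if curated_orf_table:
        for name in (tid, *transcript.also_known_as):
            if name in curated_orf_table:
                cds = tuple(curated_orf_table[name])
                if _valid_cds(cds, transcript.length):
                    return OrfAssignment(tid, cds, "curated_db")
                logger.warning("transcript %s: invalid curated CDS %s ignored", tid, cds)
    if transcript.cds is not None:
        cds = transcript.cds
        ok = _valid_cds(cds, transcript.length)
        if ok and sequence is not None:
            coding = sequence.upper().replace("U", "T")[cds[0] : cds[1] - 3]
            ok = not any(
                coding[i : i + 3] in STOP_CODONS for i in range(0, len(coding) - 2, 3)
            )
        if ok:
            return OrfAssignment(tid, cds, "annotation_predicted")
        logger.warning("transcript %s: annotated CDS rejected, trying fallback", tid)
    if sequence is not None:
        orf = find_longest_orf(sequence, min_orf_length)
        if orf is not None:
            return OrfAssignment(tid, orf, "longest_orf_fallback")
    return OrfAssignment(tid, None, "none")


def classify_nmd(
    transcript: TranscriptModel,
    orf: OrfAssignment,
    ptc_distance: int = DEFAULT_PTC_DISTANCE,
) -> NMDCall:
    """Apply the 50-nt rule to one isoform.

    The distance from the last base of the stop codon to each downstream
    exon-exon junction is computed in spliced-transcript coordinates; the
    isoform is a predicted NMD substrate iff any such distance strictly
    exceeds ``ptc_distance``. Without an ORF the status is unknown.
    """
    if orf.cds is None:
        return NMDCall(transcript.transcript_id, NMDStatus.UNKNOWN)
    cds_end = orf.cds[1]
    if cds_end > transcript.length:
        raise ValueError(
            f"transcript {transcript.transcript_id}: stop codon past transcript end"
        )
    distances = [j - cds_end for j in transcript.junction_positions() if j >= cds_end]
    if not distances:
        return NMDCall(transcript.transcript_id, NMDStatus.NOT_SUBSTRATE)
    far = max(distances)
    status = NMDStatus.SUBSTRATE if far > ptc_distance else NMDStatus.NOT_SUBSTRATE
    return NMDCall(transcript.transcript_id, status, far)


# ---------------------------------------------------------------------------
# Event catalog
# ---------------------------------------------------------------------------

def aberrant_isoform_id(event_id: str) -> str:
    """Identifier under which a curated-ORF table may describe the
    unannotated (aberrant) isoform of a novel-junction or retention event."""
    return f"{event_id}:aberrant"


def _modify_for_retention(t: TranscriptModel, junction: SpliceJunction, tid: str) -> TranscriptModel:
    """Transcript model with ``junction``'s intron retained (flanking exons fused)."""
    intron = junction.intron
    exons: list[GenomicInterval] = []
    i = 0
    tx_exons = list(t.exons)
    while i < len(tx_exons):
        e = tx_exons[i]
        fuse_next = False
        if i + 1 < len(tx_exons):
            nxt = tx_exons[i + 1]
            lo, hi = (e, nxt) if e.start < nxt.start else (nxt, e)
            if lo.end == intron.start and hi.start == intron.end:
                fuse_next = True
        if fuse_next:
            nxt = tx_exons[i + 1]
            exons.append(
                GenomicInterval(e.chrom, min(e.start, nxt.start), max(e.end, nxt.end), e.strand)
            )
            i += 2
        else:
            exons.append(e)
            i += 1
    return TranscriptModel(tid, t.gene_id, tuple(exons), source="derived")


def _modify_for_junction(t: TranscriptModel, junction: SpliceJunction, tid: str) -> TranscriptModel:
    """Transcript model re-spliced to use ``junction``: all exonic sequence of
    ``t`` inside the new intron is removed."""
    intron = junction.intron
    exons: list[GenomicInterval] = []
    for e in t.exons:
        if e.end <= intron.start or e.start >= intron.end:
            exons.append(e)
            continue
        if e.start < intron.start:
            exons.append(GenomicInterval(e.chrom, e.start, intron.start, e.strand))
        if e.end > intron.end:
            exons.append(GenomicInterval(e.chrom, intron.end, e.end, e.strand))
    if not exons:
        raise ValueError(f"junction {junction.label()} removes all exons of {t.transcript_id}")
    return TranscriptModel(tid, t.gene_id, tuple(exons), source="derived")


def _transcript_retains(t: TranscriptModel, intron: GenomicInterval) -> bool:
    return any(e.start < intron.start and e.end > intron.end for e in t.exons)


def _isoform_status(
    gene: Gene,
    calls: Mapping[str, NMDCall],
    junctions: frozenset[SpliceJunction],
    retained: Optional[GenomicInterval],
) -> NMDStatus:
    """Status of an event isoform, read off the annotated transcripts that
    realize it; disagreement between carriers yields unknown."""
    statuses = set()
    for t in gene.transcripts:
        tj = set(t.junctions())
        if junctions and not junctions <= tj:
            continue
        if retained is not None and not _transcript_retains(t, retained):
            continue
        statuses.add(calls[t.transcript_id].status)
    if len(statuses) == 1:
        return statuses.pop()
    return NMDStatus.UNKNOWN


def _aberrant_status(
    gene: Gene,
    event_id: str,
    template: TranscriptModel,
    template_orf: OrfAssignment,
    aberrant: TranscriptModel,
    orf_table: Optional[Mapping[str, tuple[int, int]]],
    ptc_distance: int,
) -> NMDStatus:
    """NMD status of a constructed (unannotated) isoform.

    Precedence: a curated-ORF entry under the aberrant isoform id; otherwise
    projection of the template's stop codon onto the modified model, valid
    only when the modification lies entirely 3' of the stop; otherwise
    unknown. Frameshift-induced stop relocation is not predictable without
    genome sequence.
    """
    ab_id = aberrant_isoform_id(event_id)
    if orf_table and ab_id in orf_table:
        cds = tuple(orf_table[ab_id])
        if _valid_cds(cds, aberrant.length):
            return classify_nmd(aberrant, OrfAssignment(ab_id, cds, "curated_db"), ptc_distance).status
        logger.warning("event %s: invalid curated CDS for aberrant isoform", event_id)
    if template_orf.cds is not None:
        cds_start, cds_end = template_orf.cds
        stop_g = template.to_genomic(cds_end - 1)
        ab_tx = aberrant.genomic_to_tx(stop_g)
        if ab_tx == cds_end - 1:  # everything 5' of the stop is untouched
            call = classify_nmd(
                aberrant, OrfAssignment(ab_id, (cds_start, cds_end), "curated_db"), ptc_distance
            )
            return call.status
    return NMDStatus.UNKNOWN


def _skipped_exon(gene: Gene, j_up: SpliceJunction, j_down: SpliceJunction) -> Optional[GenomicInterval]:
    """The exon lying between two junctions used consecutively in a transcript."""
    if gene.strand == "+":
        lo, hi = j_up.acceptor_pos, j_down.donor_pos
    else:
        lo, hi = j_down.donor_pos, j_up.acceptor_pos
    if lo < hi:
        return GenomicInterval(gene.chrom, lo, hi, gene.strand)
    return None


def build_event_catalog(
    genes: Sequence[Gene],
    constitutive_junctions: Optional[set[SpliceJunction]] = None,
    candidate_junctions: Optional[Mapping[str, set[SpliceJunction]]] = None,
    orf_table: Optional[Mapping[str, tuple[int, int]]] = None,
    sequences: Optional[Mapping[str, str]] = None,
    ptc_distance: int = DEFAULT_PTC_DISTANCE,
    classes: Optional[set[EventClass]] = None,
) -> list[SplicingEvent]:
    """Catalog binary splicing events across the annotation.

    Annotated contrasts (cassette exons, alternative 5'/3' splice sites,
    annotated intron retention, mutually exclusive exons) are detected from
    transcript structure; aberrant contrasts (novel junctions between
    annotated splice sites, retention of constitutive introns) are derived
    from the candidate-junction enumeration and the constitutive set. Each
    isoform's NMD flag is obtained by classifying the corresponding
    full-length isoform; isoform A is the predicted NMD substrate whenever
    exactly one isoform is a substrate. Events where both or neither isoform
    is a substrate stay in the catalog but are ineligible for the
    NMD-direction analysis.
    """
    if constitutive_junctions is None:
        constitutive_junctions = identify_constitutive_junctions(genes)
    const_keys = {j.key() for j in constitutive_junctions if j.constitutive}
    events: list[SplicingEvent] = []

    for gene in genes:
        chrom, strand = gene.chrom, gene.strand
        orfs = {
            t.transcript_id: assign_orf(
                t, orf_table, sequences.get(t.transcript_id) if sequences else None
            )
            for t in gene.transcripts
        }
        calls = {
            tid: classify_nmd(t, orfs[tid], ptc_distance)
            for tid, t in ((t.transcript_id, t) for t in gene.transcripts)
        }
        ann_junctions = gene.junctions()
        ann_keys = {j.key() for j in ann_junctions}
        adjacent_pairs: set[tuple[SpliceJunction, SpliceJunction]] = set()
        for t in gene.transcripts:
            tj = t.junctions()
            adjacent_pairs.update(zip(tj, tj[1:]))

        def emit(event_id, eclass, ja, jb, fa, fb, ra=None, rb=None):
            if classes is not None and eclass not in classes:
                return
            if fb == NMDStatus.SUBSTRATE and fa != NMDStatus.SUBSTRATE:
                ja, jb, fa, fb, ra, rb = jb, ja, fb, fa, rb, ra
            events.append(
                SplicingEvent(
                    event_id, eclass, gene.gene_id,
                    frozenset(ja), frozenset(jb), fa, fb, ra, rb,
                )
            )

        # --- cassette exons & mutually exclusive exons -------------------
        skip_like: dict[tuple[int, int], list[tuple[SpliceJunction, SpliceJunction, GenomicInterval]]] = defaultdict(list)
        for j1, j2 in adjacent_pairs:
            ex = _skipped_exon(gene, j1, j2)
            if ex is not None:
                skip_like[(j1.donor_pos, j2.acceptor_pos)].append((j1, j2, ex))
        consumed_donor_pairs: set[tuple[int, frozenset[int]]] = set()
        consumed_acceptor_pairs: set[tuple[int, frozenset[int]]] = set()
        for (d, a), paths in sorted(skip_like.items()):
            try:
                skip_j = SpliceJunction(chrom, d, a, strand)
            except ValueError:
                continue
            paths = sorted(paths, key=lambda p: (p[2].start, p[2].end))
            if skip_j in ann_junctions:
                for j1, j2, ex in paths:
                    fa = _isoform_status(gene, calls, frozenset({j1, j2}), None)
                    fb = _isoform_status(gene, calls, frozenset({skip_j}), None)
                    emit(
                        f"{gene.gene_id}:CE:{chrom}:{ex.start}-{ex.end}",
                        EventClass.CASSETTE_EXON,
                        {j1, j2}, {skip_j}, fa, fb,
                    )
                    consumed_donor_pairs.add((d, frozenset({j1.acceptor_pos, a})))
                    consumed_acceptor_pairs.add((a, frozenset({j2.donor_pos, d})))
            elif len(paths) >= 2:
                for (j1, j2, e1), (j3, j4, e2) in itertools.combinations(paths, 2):
                    if e1.overlaps(e2):
                        continue
                    fa = _isoform_status(gene, calls, frozenset({j1, j2}), None)
                    fb = _isoform_status(gene, calls, frozenset({j3, j4}), None)
                    emit(
                        f"{gene.gene_id}:MX:{chrom}:{e1.start}-{e1.end}:{e2.start}-{e2.end}",
                        EventClass.MUTUALLY_EXCLUSIVE,
                        {j1, j2}, {j3, j4}, fa, fb,
                    )
                    consumed_donor_pairs.add((d, frozenset({j1.acceptor_pos, j3.acceptor_pos})))
                    consumed_acceptor_pairs.add((a, frozenset({j2.donor_pos, j4.donor_pos})))

        # --- alternative 5'/3' splice sites ------------------------------
        by_acceptor: dict[int, list[SpliceJunction]] = defaultdict(list)
        by_donor: dict[int, list[SpliceJunction]] = defaultdict(list)
        for j in ann_junctions:
            by_acceptor[j.acceptor_pos].append(j)
            by_donor[j.donor_pos].append(j)
        for a, js in sorted(by_acceptor.items()):
            for j1, j2 in itertools.combinations(sorted(js, key=lambda j: j.donor_pos), 2):
                if (a, frozenset({j1.donor_pos, j2.donor_pos})) in consumed_acceptor_pairs:
                    continue
                fa = _isoform_status(gene, calls, frozenset({j1}), None)
                fb = _isoform_status(gene, calls, frozenset({j2}), None)
                emit(
                    f"{gene.gene_id}:A5:{chrom}:{j1.donor_pos}-{j2.donor_pos}:{a}",
                    EventClass.ALT_5SS, {j1}, {j2}, fa, fb,
                )
        for d, js in sorted(by_donor.items()):
            for j1, j2 in itertools.combinations(sorted(js, key=lambda j: j.acceptor_pos), 2):
                if (d, frozenset({j1.acceptor_pos, j2.acceptor_pos})) in consumed_donor_pairs:
                    continue
                fa = _isoform_status(gene, calls, frozenset({j1}), None)
                fb = _isoform_status(gene, calls, frozenset({j2}), None)
                emit(
                    f"{gene.gene_id}:A3:{chrom}:{j1.acceptor_pos}-{j2.acceptor_pos}:{d}",
                    EventClass.ALT_3SS, {j1}, {j2}, fa, fb,
                )

        # --- annotated intron retention ----------------------------------
        for j in sorted(ann_junctions, key=lambda j: j.key()):
            intron = j.intron
            if any(_transcript_retains(t, intron) for t in gene.transcripts):
                fa = _isoform_status(gene, calls, frozenset({j}), None)
                fb = _isoform_status(gene, calls, frozenset(), intron)
                emit(
                    f"{gene.gene_id}:RI:{chrom}:{intron.start}-{intron.end}",
                    EventClass.RETAINED_INTRON,
                    {j}, set(), fa, fb, None, intron,
                )

        # --- aberrant contrasts ------------------------------------------
        gene_const = sorted(
            (j for j in ann_junctions if j.key() in const_keys), key=lambda j: j.key()
        )
        candidates = (
            candidate_junctions.get(gene.gene_id, set())
            if candidate_junctions is not None
            else enumerate_candidate_junctions(gene)
        )
        novel = sorted(
            (c for c in candidates if c.key() not in ann_keys), key=lambda c: c.key()
        )
        for c in novel:
            ref = next((j for j in gene_const if j.donor_pos == c.donor_pos), None)
            if ref is None:
                ref = next((j for j in gene_const if j.acceptor_pos == c.acceptor_pos), None)
            if ref is None:
                continue
            event_id = f"{gene.gene_id}:NJ:{chrom}:{c.donor_pos}-{c.acceptor_pos}"
            template = min(
                (t for t in gene.transcripts if ref in t.junctions()),
                key=lambda t: t.transcript_id,
            )
            try:
                aberrant = _modify_for_junction(template, c, aberrant_isoform_id(event_id))
            except ValueError:
                continue
            fa = _aberrant_status(
                gene, event_id, template, orfs[template.transcript_id],
                aberrant, orf_table, ptc_distance,
            )
            fb = _isoform_status(gene, calls, frozenset({ref}), None)
            emit(event_id, EventClass.NOVEL_JUNCTION, {c}, {ref}, fa, fb)

        for j in gene_const:
            intron = j.intron
            event_id = f"{gene.gene_id}:CIR:{chrom}:{intron.start}-{intron.end}"
            template = min(
                (t for t in gene.transcripts if j in t.junctions()),
                key=lambda t: t.transcript_id,
            )
            aberrant = _modify_for_retention(template, j, aberrant_isoform_id(event_id))
            fa = _aberrant_status(
                gene, event_id, template, orfs[template.transcript_id],
                aberrant, orf_table, ptc_distance,
            )
            fb = _isoform_status(gene, calls, frozenset({j}), None)
            emit(
                event_id, EventClass.CONSTITUTIVE_INTRON_RETENTION,
                set(), {j}, fa, fb, intron, None,
            )

    events.sort(key=lambda e: e.event_id)
    return events
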