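"""Annotation layer: GTF reading, merging, junction classes, ORFs, the
50-nt NMD rule and the event catalog."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nmdsplice as ns
from nmdsplice.annotation import GtfParseError, find_longest_orf

from conftest import make_transcript


# ---------------------------------------------------------------------------
# read_gtf
# ---------------------------------------------------------------------------

def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


def test_gtf_coordinates_become_zero_based_half_open(tmp_path):
    gtf = 'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
    models = ns.read_gtf(_write(tmp_path, "a.gtf", gtf))
    assert len(models) == 1
    (exon,) = models[0].exons
    assert (exon.start, exon.end) == (100, 200)


def test_minus_strand_exons_ordered_three_prime_first(tmp_path):
    gtf = (
        'chr1\tsrc\texon\t101\t200\t.\t-\t.\tgene_id "g"; transcript_id "t";\n'
        'chr1\tsrc\texon\t301\t400\t.\t-\t.\tgene_id "g"; transcript_id "t";\n'
    )
    models = ns.read_gtf(_write(tmp_path, "m.gtf", gtf))
    exons = models[0].exons
    # exon 1 (5' in transcript orientation) is the genomically rightmost
    assert exons[0].start == 300 and exons[1].start == 100
    (j,) = models[0].junctions()
    assert (j.donor_pos, j.acceptor_pos) == (300, 200)


def test_malformed_gtf_names_the_line(tmp_path):
    gtf = 'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\nbroken line\n'
    with pytest.raises(GtfParseError, match=":2"):
        ns.read_gtf(_write(tmp_path, "bad.gtf", gtf))


def test_cds_without_exons_rejected(tmp_path):
    gtf = 'chr1\tsrc\tCDS\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
    with pytest.raises(GtfParseError, match="zero exons"):
        ns.read_gtf(_write(tmp_path, "c.gtf", gtf))


def test_simulator_gtf_round_trip(tmp_path, mixed_sim):
    """Re-reading the generator's GTF reproduces its in-memory models."""
    _, sim = mixed_sim
    models = ns.read_gtf(_write(tmp_path, "sim.gtf", sim.gtf_text))
    by_id = {m.transcript_id: m for m in models}
    assert set(by_id) == {t.transcript_id for t in sim.transcripts}
    for t in sim.transcripts:
        assert by_id[t.transcript_id].exon_chain_key() == t.exon_chain_key()
        # GTF CDS features mirror the curated table (stop codon included)
        assert by_id[t.transcript_id].cds == sim.orf_table[t.transcript_id]


# ---------------------------------------------------------------------------
# merge_annotations
# ---------------------------------------------------------------------------

def _two_exon(tid, gene="g", start=100):
    return make_transcript(tid, [(start, start + 100), (start + 200, start + 300)], gene=gene)


def test_merge_idempotent_and_commutative():
    a = [_two_exon("t1"), make_transcript("t2", [(500, 600)])]
    assert {m.exon_chain_key() for m in ns.merge_annotations(a, a)} == {
        m.exon_chain_key() for m in a
    }
    ab = ns.merge_annotations(a, [])
    ba = ns.merge_annotations([], a)
    assert {m.exon_chain_key() for m in ab} == {m.exon_chain_key() for m in ba}


def test_merge_disjoint_is_union():
    a = [_two_exon("t1", start=100)]
    b = [_two_exon("t2", start=5000)]
    assert len(ns.merge_annotations(a, b)) == 2


def test_merge_collapses_identical_chain_keeping_both_ids():
    a = [_two_exon("ucsc.1")]
    b = [_two_exon("enst.1")]
    (m,) = ns.merge_annotations(a, b)
    assert m.source == "merged"
    assert {m.transcript_id, *m.also_known_as} == {"ucsc.1", "enst.1"}


def test_merge_rejects_contradictory_strand():
    a = [make_transcript("t1", [(100, 200)], strand="+")]
    b = [make_transcript("t1", [(100, 200)], strand="-")]
    with pytest.raises(ValueError, match="contradictory strands"):
        ns.merge_annotations(a, b)


# ---------------------------------------------------------------------------
# constitutive and candidate junctions
# ---------------------------------------------------------------------------

def test_single_isoform_junction_is_constitutive():
    genes = ns.group_genes([_two_exon("t1")])
    juncs = ns.identify_constitutive_junctions(genes)
    assert [j.constitutive for j in juncs] == [True]


def test_cassette_flanking_junctions_not_constitutive():
    inc = make_transcript("t.inc", [(0, 100), (200, 250), (400, 500)])
    exc = make_transcript("t.exc", [(0, 100), (400, 500)], gene="t")
    juncs = ns.identify_constitutive_junctions(ns.group_genes([inc, exc]))
    assert juncs and all(not j.constitutive for j in juncs)


def test_retaining_transcript_breaks_constitutivity():
    spl = make_transcript("t.spl", [(0, 100), (200, 300)])
    ret = make_transcript("t.ret", [(0, 300)], gene="t")
    juncs = ns.identify_constitutive_junctions(ns.group_genes([spl, ret]))
    assert all(not j.constitutive for j in juncs)


def test_simulated_constitutive_set_recovered(mixed_sim):
    """Generator templates fix which junctions are constitutive; single-
    transcript genes have only constitutive junctions, multi-isoform genes
    only where both sites are uniquely paired and no isoform retains."""
    _, sim = mixed_sim
    genes = ns.group_genes(sim.transcripts)
    flagged = {j.key(): j.constitutive for j in ns.identify_constitutive_junctions(genes)}
    for gene in genes:
        single = len(gene.transcripts) == 1
        for j in gene.junctions():
            donors = {x.donor_pos for x in gene.junctions() if x.acceptor_pos == j.acceptor_pos}
            acceptors = {x.acceptor_pos for x in gene.junctions() if x.donor_pos == j.donor_pos}
            retained = any(
                any(e.start < j.intron.start and e.end > j.intron.end for e in t.exons)
                for t in gene.transcripts
            )
            expect = len(donors) == 1 and len(acceptors) == 1 and not retained
            assert flagged[j.key()] == expect, (gene.gene_id, j.label(), single)


def test_enumerate_two_by_two():
    t1 = make_transcript("t1", [(0, 100), (200, 300), (400, 500)])
    t2 = make_transcript("t2", [(0, 150), (200, 300), (400, 500)], gene="t1")
    (gene,) = ns.group_genes([t1, t2])
    cands = ns.enumerate_candidate_junctions(gene)
    # donors {100,150,300}, acceptors {200,400}: pairs with d < a
    assert len(cands) == 5
    novel = {c.label() for c in cands if not c.annotated}
    assert novel == {"chr1:100-400", "chr1:150-400"}


def test_enumerate_intronless_gene_empty():
    (gene,) = ns.group_genes([make_transcript("t", [(0, 500)])])
    assert ns.enumerate_candidate_junctions(gene) == set()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=6), st.integers(min_value=0, max_value=10**6),
       st.booleans())
def test_enumerate_matches_brute_force(n_exons, seed, minus):
    """Candidate count equals brute-force enumeration over all site pairs."""
    rnd = random.Random(seed)
    pos, coords = 0, []
    for _ in range(n_exons):
        start = pos + rnd.randint(50, 200)
        end = start + rnd.randint(50, 200)
        coords.append((start, end))
        pos = end
    strand = "-" if minus else "+"
    (gene,) = ns.group_genes([make_transcript("t", coords, strand=strand)])
    cands = ns.enumerate_candidate_junctions(gene)
    donors = {j.donor_pos for j in gene.junctions()}
    acceptors = {j.acceptor_pos for j in gene.junctions()}
    brute = {
        (d, a)
        for d in donors
        for a in acceptors
        if (d < a if strand == "+" else d > a)
    }
    assert {(c.donor_pos, c.acceptor_pos) for c in cands} == brute
    assert {j.key() for j in gene.junctions()} <= {c.key() for c in cands}


# ---------------------------------------------------------------------------
# ORF assignment
# ---------------------------------------------------------------------------

def test_orf_precedence_curated_over_annotation():
    t = make_transcript("t", [(0, 300)], cds=(0, 150))
    orf = ns.assign_orf(t, curated_orf_table={"t": (0, 99)})
    assert orf.cds == (0, 99) and orf.source == "curated_db"


def test_orf_annotation_cds_when_no_curated_entry():
    t = make_transcript("t", [(0, 300)], cds=(0, 150))
    orf = ns.assign_orf(t, curated_orf_table={})
    assert orf.cds == (0, 150) and orf.source == "annotation_predicted"


def test_orf_invalid_annotation_cds_falls_back():
    # CDS length not a multiple of 3 -> rejected; fallback scans the sequence
    seq = "GG" + "ATG" + "GCA" * 30 + "TAA" + "CCCC"
    t = make_transcript("t", [(0, len(seq))], cds=(0, 100))
    orf = ns.assign_orf(t, sequence=seq)
    assert orf.source == "longest_orf_fallback"
    assert orf.cds == (2, 2 + 3 + 90 + 3)


def test_orf_none_without_any_source():
    t = make_transcript("t", [(0, 300)])
    orf = ns.assign_orf(t)
    assert orf.source == "none" and orf.cds is None


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_longest_orf_matches_exhaustive_scan(seed):
    """find_longest_orf agrees with an independent exhaustive scan."""
    rnd = random.Random(seed)
    seq = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(30, 400)))
    best = None
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(seq):
            if seq[j : j + 3] in ("TAA", "TAG", "TGA"):
                if j + 3 - i >= 60 and (best is None or j + 3 - i > best[1] - best[0]):
                    best = (i, j + 3)
                break
            j += 3
    assert find_longest_orf(seq) == best


# ---------------------------------------------------------------------------
# classify_nmd (50-nt rule)
# ---------------------------------------------------------------------------

def _nmd(t, cds):
    return ns.classify_nmd(t, ns.OrfAssignment(t.transcript_id, cds, "curated_db"))


def test_junction_100nt_downstream_of_stop_triggers():
    # stop 100 nt upstream of a spliced junction in the 3' UTR
    t = make_transcript("t", [(0, 400), (500, 700)])
    call = _nmd(t, (0, 300))
    assert call.status == ns.NMDStatus.SUBSTRATE
    assert call.max_downstream_junction_distance == 100


def test_single_exon_transcript_never_substrate():
    t = make_transcript("t", [(0, 400)])
    assert _nmd(t, (0, 300)).status == ns.NMDStatus.NOT_SUBSTRATE


@pytest.mark.parametrize(
    "cds_end,expected",
    [(350, ns.NMDStatus.NOT_SUBSTRATE),   # distance exactly 50
     (349, ns.NMDStatus.SUBSTRATE)],      # distance 51
)
def test_fifty_nt_boundary_is_strict(cds_end, expected):
    t = make_transcript("t", [(0, 400), (500, 700)])  # junction at tx 400
    assert _nmd(t, (0, cds_end)).status == expected


def test_no_orf_means_unknown():
    t = make_transcript("t", [(0, 400), (500, 700)])
    call = ns.classify_nmd(t, ns.OrfAssignment("t", None, "none"))
    assert call.status == ns.NMDStatus.UNKNOWN


def test_corrupt_orf_rejected():
    t = make_transcript("t", [(0, 100), (200, 260)])
    with pytest.raises(ValueError, match="past transcript end"):
        ns.classify_nmd(t, ns.OrfAssignment("t", (0, 300), "curated_db"))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_nmd_rule_invariant_under_strand_flip(seed):
    """The 50-nt rule is computed in transcript coordinates, so mirroring a
    gene onto the minus strand never changes the call."""
    rnd = random.Random(seed)
    pos, coords = 0, []
    for _ in range(rnd.randint(1, 5)):
        start = pos + rnd.randint(10, 100)
        end = start + rnd.randint(30, 300)
        coords.append((start, end))
        pos = end
    t_plus = make_transcript("t", coords, strand="+")
    span = 10_000
    flipped = [(span - e, span - s) for s, e in coords]
    t_minus = make_transcript("t", flipped, strand="-")
    length = t_plus.length
    cds_len = 3 * rnd.randint(1, length // 3)
    assert _nmd(t_plus, (0, cds_len)).status == _nmd(t_minus, (0, cds_len)).status


# ---------------------------------------------------------------------------
# event catalog
# ---------------------------------------------------------------------------

def test_ptc_introducing_cassette_exon_event():
    """SRSF3-like gene: including the poison exon creates a PTC far upstream
    of the downstream junction; skipping keeps the normal ORF."""
    inc = make_transcript("srsf3.inc", [(0, 300), (400, 550), (650, 1000)], gene="srsf3")
    exc = make_transcript("srsf3.exc", [(0, 300), (650, 1000)], gene="srsf3")
    orfs = {"srsf3.inc": (0, 348), "srsf3.exc": (0, 450)}
    catalog = ns.build_event_catalog(ns.group_genes([inc, exc]), orf_table=orfs)
    (ce,) = [e for e in catalog if e.event_class == ns.EventClass.CASSETTE_EXON]
    assert ce.eligible
    assert ce.nmd_flag_a == ns.NMDStatus.SUBSTRATE  # A designates the substrate
    assert len(ce.isoform_a_junctions) == 2 and len(ce.isoform_b_junctions) == 1


def test_novel_junction_event_from_constitutive_reference():
    t = make_transcript("t", [(0, 300), (380, 460), (540, 840)], cds=(0, 375))
    catalog = ns.build_event_catalog(ns.group_genes([t]))
    nj = [e for e in catalog if e.event_class == ns.EventClass.NOVEL_JUNCTION]
    assert len(nj) == 1
    (ref,) = nj[0].isoform_b_junctions
    assert ref.annotated and (ref.donor_pos, ref.acceptor_pos) == (300, 380)
    (novelj,) = nj[0].isoform_a_junctions
    assert (novelj.donor_pos, novelj.acceptor_pos) == (300, 540)


def test_simulated_catalog_recovers_implanted_events(mixed_sim, mixed_catalog):
    """Every implanted event is recovered with its class, designated-isoform
    structure and NMD flags."""
    _, sim = mixed_sim
    by_id = {e.event_id: e for e in mixed_catalog}
    for truth in sim.truth.events:
        ev = by_id[truth.event_id]
        assert str(ev.event_class) == truth.event_class
        assert ev.eligible == truth.eligible
        assert ev.isoform_a_junctions == frozenset(truth.a_junctions)
        assert ev.isoform_b_junctions == frozenset(truth.b_junctions)
        assert ev.a_retained == truth.a_retained
        assert ev.b_retained == truth.b_retained
        if truth.eligible:
            assert ev.nmd_flag_a == ns.NMDStatus.SUBSTRATE
            assert ev.nmd_flag_b != ns.NMDStatus.SUBSTRATE


def test_nmd_flags_match_generator_truth_for_all_isoforms(mixed_sim):
    """classify_nmd on the emitted annotation reproduces the implanted NMD
    status of every transcript."""
    _, sim = mixed_sim
    for t in sim.transcripts:
        orf = ns.assign_orf(t, sim.orf_table)
        call = ns.classify_nmd(t, orf)
        assert str(call.status) == sim.truth.transcript_status[t.transcript_id], t.transcript_id


def test_constitutive_subset_of_candidates(mixed_sim):
    """Constitutive junctions are annotated candidates; no novel candidate is
    ever flagged constitutive."""
    _, sim = mixed_sim
    genes = ns.group_genes(sim.transcripts)
    const = {j.key() for j in ns.identify_constitutive_junctions(genes) if j.constitutive}
    annotated_cands, novel_cands = set(), set()
    for g in genes:
        for c in ns.enumerate_candidate_junctions(g):
            (annotated_cands if c.annotated else novel_cands).add(c.key())
    assert const <= annotated_cands
    assert not (const & novel_cands)
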