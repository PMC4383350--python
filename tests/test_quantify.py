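"""Alignment filtering, identifying-read counting and PSI estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta as beta_dist

import nmdsplice as ns
from nmdsplice.quantify import AlignedRead

from conftest import make_transcript


def read(read_id="r1", chrom="chr1", mapq=30, blocks=((100, 150),)):
    return AlignedRead(read_id, chrom, mapq, tuple(blocks))


# ---------------------------------------------------------------------------
# filter_alignments
# ---------------------------------------------------------------------------

def test_mapq_zero_read_removed():
    assert ns.filter_alignments([read(mapq=0)]) == []


@pytest.mark.parametrize("overhang,kept", [(5, 0), (6, 1)])
def test_overhang_boundary_less_than_six_removed(overhang, kept):
    r = read(blocks=((100, 100 + overhang), (500, 560)))
    assert len(ns.filter_alignments([r])) == kept


def test_exonic_read_untouched_by_overhang_filter():
    r = read(mapq=30, blocks=((100, 103),))  # 3 nt, but spans no junction
    assert ns.filter_alignments([r]) == [r]


def test_unmapped_records_skipped_with_counter():
    stats = ns.FilterStats()
    ns.filter_alignments([AlignedRead("u", "*", 0, ())], stats=stats)
    assert stats.n_unmapped == 1 and stats.n_kept == 0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_filtering_monotone_in_overhang_threshold(seed):
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(50):
        left = int(rng.integers(1, 20))
        right = int(rng.integers(1, 20))
        start = int(rng.integers(0, 1000))
        reads.append(
            read(f"r{i}", mapq=int(rng.integers(0, 60)),
                 blocks=((start, start + left), (start + 200, start + 200 + right)))
        )
    kept = [len(ns.filter_alignments(reads, min_overhang=th)) for th in range(1, 15)]
    assert kept == sorted(kept, reverse=True)


# ---------------------------------------------------------------------------
# AlignedRead from SAM
# ---------------------------------------------------------------------------

def test_cigar_blocks_split_at_splices_not_deletions(tmp_path):
    sam = (
        "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n"
        "r1\t0\tchr1\t101\t50\t10M5D10M100N10M\t*\t0\t0\t*\t*\n"
    )
    p = tmp_path / "a.sam"
    p.write_text(sam)
    (r,) = list(ns.iter_sam(str(p)))
    # deletion keeps one contiguous block of 10+5+10=25 ref bases
    assert r.blocks == ((100, 125), (225, 235))
    assert r.gaps == ((125, 225),)
    assert r.min_overhang == 10


# ---------------------------------------------------------------------------
# count_event_reads / identifying_reads
# ---------------------------------------------------------------------------

@pytest.fixture()
def ri_event():
    spl = make_transcript("t.spl", [(0, 600), (700, 1000)])
    ret = make_transcript("t.ret", [(0, 1000)], gene="t")
    orfs = {"t.spl": (0, 498), "t.ret": (0, 498)}
    (ev,) = ns.build_event_catalog(ns.group_genes([spl, ret]), orf_table=orfs)
    assert ev.event_class == ns.EventClass.RETAINED_INTRON
    return ev


def test_junction_read_counts_for_spliced_isoform(ri_event):
    r = read(blocks=((580, 600), (700, 720)))
    counts = ns.count_event_reads([r], [ri_event])
    assert counts.counts == {(ri_event.event_id, "A"): 1}
    assert ns.identifying_reads(counts, ri_event) == 1


def test_contiguous_boundary_crossing_counts_retention(ri_event):
    r = read(blocks=((590, 610),))  # 10 nt each side of the donor boundary
    counts = ns.count_event_reads([r], [ri_event])
    assert counts.counts == {(ri_event.event_id, "B"): 1}


def test_short_boundary_crossing_not_counted(ri_event):
    r = read(blocks=((595, 610),))  # only 5 nt on the upstream side
    counts = ns.count_event_reads([r], [ri_event])
    assert counts.counts == {}


def test_exonic_read_identifies_neither_isoform(ri_event):
    counts = ns.count_event_reads([read(blocks=((100, 140),))], [ri_event])
    assert counts.counts == {} and counts.unassigned == 0


def test_uncataloged_junction_goes_to_unassigned(ri_event):
    r = read(blocks=((100, 150), (300, 350)))
    counts = ns.count_event_reads([r], [ri_event])
    assert counts.unassigned == 1 and counts.counts == {}


def test_fragment_counted_once_per_event(ri_event):
    mates = [
        read("frag1", blocks=((580, 600), (700, 720))),
        read("frag1", blocks=((570, 600), (700, 740))),
    ]
    counts = ns.count_event_reads(mates, [ri_event])
    assert counts.counts == {(ri_event.event_id, "A"): 1}


def test_conflicting_fragment_support_discarded(ri_event):
    mates = [
        read("frag1", blocks=((580, 600), (700, 720))),  # spliced
        read("frag1", blocks=((590, 610),)),             # retention
    ]
    counts = ns.count_event_reads(mates, [ri_event])
    assert counts.counts == {} and counts.ambiguous == 1


def test_identifying_reads_sums_both_isoforms(ri_event):
    counts = ns.JunctionCounts("s")
    counts.counts = {(ri_event.event_id, "A"): 12, (ri_event.event_id, "B"): 9}
    assert ns.identifying_reads(counts, ri_event) == 21
    assert ns.identifying_reads(ns.JunctionCounts("s"), ri_event) == 0


def test_simulated_counts_recovered_from_emitted_sam(tmp_path, mixed_sim, mixed_catalog):
    """Filtering and counting the simulator's SAM reproduces its count
    tables exactly, and counts are conserved (no unassigned/ambiguous)."""
    cfg, sim = mixed_sim
    rng = np.random.default_rng(123)
    c1, _ = ns.simulate_counts(cfg, sim.truth, rng)
    p = tmp_path / "r.sam"
    p.write_text(ns.emit_sam(sim, c1))
    reads = ns.filter_alignments(ns.iter_sam(str(p)))
    recount = ns.count_event_reads(reads, mixed_catalog, sample_id="cond1")
    expected = {k: v for k, v in c1.counts.items() if v > 0}
    assert recount.counts == expected
    assert recount.unassigned == 0 and recount.ambiguous == 0


# ---------------------------------------------------------------------------
# estimate_psi
# ---------------------------------------------------------------------------

def test_psi_extremes():
    lo = ns.estimate_psi(0, 10)
    hi = ns.estimate_psi(10, 10)
    assert lo.psi_hat == 0.0 and lo.ci_low == 0.0
    assert hi.psi_hat == 1.0 and hi.ci_high == 1.0


def test_psi_zero_reads_gives_nan_marker():
    p = ns.estimate_psi(0, 0)
    assert not p.defined and math.isnan(p.psi_hat)


def test_psi_invalid_counts_error():
    with pytest.raises(ValueError):
        ns.estimate_psi(5, 3)


def test_psi_interval_matches_quadrature_oracle():
    """95% bounds for k=10, n=20 equal quantiles of the posterior computed by
    numerical integration on a fine grid."""
    k, n = 10, 20
    grid = np.linspace(0.0, 1.0, 200_001)
    log_post = k * np.log(np.clip(grid, 1e-300, None)) + (n - k) * np.log(
        np.clip(1 - grid, 1e-300, None)
    )
    dens = np.exp(log_post - log_post.max())
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    lo = grid[np.searchsorted(cdf, 0.025)]
    hi = grid[np.searchsorted(cdf, 0.975)]
    est = ns.estimate_psi(k, n)
    assert est.ci_low == pytest.approx(lo, abs=2e-4)
    assert est.ci_high == pytest.approx(hi, abs=2e-4)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=1, max_value=300), st.data())
def test_psi_label_swap_equivariance(n, data):
    k = data.draw(st.integers(min_value=0, max_value=n))
    a = ns.estimate_psi(k, n)
    b = ns.estimate_psi(n - k, n)
    assert b.psi_hat == pytest.approx(1 - a.psi_hat, abs=1e-12)
    assert b.ci_low == pytest.approx(1 - a.ci_high, abs=1e-9)
    assert b.ci_high == pytest.approx(1 - a.ci_low, abs=1e-9)


def test_counts_conservation_on_simulated_sam(tmp_path, mixed_sim, mixed_catalog):
    """k <= n and A + B identifying reads equal the junction reads emitted
    for each event."""
    cfg, sim = mixed_sim
    rng = np.random.default_rng(5)
    c1, _ = ns.simulate_counts(cfg, sim.truth, rng)
    for ev in sim.truth.events:
        k, n = c1.k_n(ev.event_id)
        assert 0 <= k <= n
        assert n == c1.counts[(ev.event_id, "A")] + c1.counts[(ev.event_id, "B")]
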