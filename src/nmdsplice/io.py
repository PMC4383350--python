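"""Tabular readers and writers.

Every artifact of a run (event catalog, junction BED, count tables, PSI
tables, differential calls, global summary, curated-ORF tables, simulation
truth) round-trips through plain TSV so stages can be run and audited
independently. All genomic coordinates in these files are 0-based half-open
except the BED name field conventions noted below.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .models import (
    ClassSummary,
    DiffSpliceCall,
    EventClass,
    GenomicInterval,
    GlobalSummary,
    NMDStatus,
    PsiEstimate,
    SpliceJunction,
    SplicingEvent,
)
from .quantify import JunctionCounts


def _junctions_str(junctions: Iterable[SpliceJunction]) -> str:
    return ";".join(
        f"{j.donor_pos}-{j.acceptor_pos}"
        for j in sorted(junctions, key=lambda j: (j.donor_pos, j.acceptor_pos))
    )


def _interval_str(iv: Optional[GenomicInterval]) -> str:
    return f"{iv.start}-{iv.end}" if iv is not None else ""


def catalog_to_frame(catalog: Sequence[SplicingEvent]) -> pd.DataFrame:
    rows = []
    for ev in catalog:
        anyj = next(iter(ev.isoform_a_junctions or ev.isoform_b_junctions), None)
        chrom = anyj.chrom if anyj else (ev.a_retained or ev.b_retained).chrom
        strand = anyj.strand if anyj else (ev.a_retained or ev.b_retained).strand
        rows.append(
            {
                "event_id": ev.event_id,
                "event_class": str(ev.event_class),
                "gene_id": ev.gene_id,
                "chrom": chrom,
                "strand": strand,
                "a_junctions": _junctions_str(ev.isoform_a_junctions),
                "a_retained": _interval_str(ev.a_retained),
                "b_junctions": _junctions_str(ev.isoform_b_junctions),
                "b_retained": _interval_str(ev.b_retained),
                "nmd_flag_a": str(ev.nmd_flag_a),
                "nmd_flag_b": str(ev.nmd_flag_b),
                "eligible": ev.eligible,
            }
        )
    return pd.DataFrame(rows)


def write_catalog(catalog: Sequence[SplicingEvent], path: str) -> None:
    catalog_to_frame(catalog).to_csv(path, sep="\t", index=False)


def _parse_junctions(text: str, chrom: str, strand: str) -> frozenset[SpliceJunction]:
    if not text or (isinstance(text, float) and math.isnan(text)):
        return frozenset()
    out = set()
    for part in str(text).split(";"):
        d, a = part.split("-")
        out.add(SpliceJunction(chrom, int(d), int(a), strand))
    return frozenset(out)


def _parse_interval(text, chrom: str, strand: str) -> Optional[GenomicInterval]:
    if not text or (isinstance(text, float) and math.isnan(text)):
        return None
    lo, hi = str(text).split("-")
    return GenomicInterval(chrom, int(lo), int(hi), strand)


def read_catalog(path: str) -> list[SplicingEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"a_junctions": str, "b_junctions": str,
                                            "a_retained": str, "b_retained": str})
    events = []
    for row in df.itertuples(index=False):
        events.append(
            SplicingEvent(
                row.event_id,
                EventClass(row.event_class),
                row.gene_id,
                _parse_junctions(row.a_junctions, row.chrom, row.strand),
                _parse_junctions(row.b_junctions, row.chrom, row.strand),
                NMDStatus(row.nmd_flag_a),
                NMDStatus(row.nmd_flag_b),
                _parse_interval(row.a_retained, row.chrom, row.strand),
                _parse_interval(row.b_retained, row.chrom, row.strand),
            )
        )
    return events


def write_junction_bed(junctions: Iterable[SpliceJunction], path: str) -> None:
    """BED6 of introns; the name field carries the constitutive/annotated/
    novel label."""
    rows = []
    for j in sorted(junctions, key=lambda j: j.key()):
        label = "constitutive" if j.constitutive else ("annotated" if j.annotated else "novel")
        lo, hi = sorted((j.donor_pos, j.acceptor_pos))
        rows.append(f"{j.chrom}\t{lo}\t{hi}\t{label}\t0\t{j.strand}")
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + ("\n" if rows else ""))


def write_counts(counts: JunctionCounts, path: str) -> None:
    rows = [
        {"sample_id": counts.sample_id, "event_id": eid, "isoform": label, "count": c}
        for (eid, label), c in sorted(counts.counts.items())
    ]
    pd.DataFrame(rows, columns=["sample_id", "event_id", "isoform", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_counts(path: str, sample_id: Optional[str] = None) -> JunctionCounts:
    df = pd.read_csv(path, sep="\t")
    if sample_id is None:
        samples = df["sample_id"].unique()
        if len(samples) > 1:
            raise ValueError(f"{path}: multiple samples {list(samples)}; pass sample_id")
        sample_id = str(samples[0]) if len(samples) else "sample"
    counts = JunctionCounts(sample_id)
    for row in df[df["sample_id"].astype(str) == sample_id].itertuples(index=False):
        counts.counts[(row.event_id, row.isoform)] = int(row.count)
    return counts


def psi_to_frame(estimates: Sequence[PsiEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": p.event_id,
                "sample_id": p.sample_id,
                "k": p.k,
                "n": p.n,
                "psi_hat": p.psi_hat,
                "ci_low": p.ci_low,
                "ci_high": p.ci_high,
            }
            for p in estimates
        ]
    )


def write_psi(estimates: Sequence[PsiEstimate], path: str) -> None:
    psi_to_frame(estimates).to_csv(path, sep="\t", index=False, float_format="%.6g")


def calls_to_frame(
    calls: Sequence[DiffSpliceCall], catalog: Optional[Sequence[SplicingEvent]] = None
) -> pd.DataFrame:
    cls = {e.event_id: str(e.event_class) for e in catalog} if catalog else {}
    rows = []
    for c in calls:
        rows.append(
            {
                "event_id": c.event_id,
                "event_class": cls.get(c.event_id, ""),
                "k1": c.k1, "n1": c.n1, "k2": c.k2, "n2": c.n2,
                "psi1": c.psi1, "psi2": c.psi2, "delta_psi": c.delta_psi,
                "log10_bf10": math.log10(c.bf10) if c.bf10 > 0 else math.nan,
                "passes_reads": c.passes_reads,
                "passes_delta": c.passes_delta,
                "passes_bf": c.passes_bf,
                "called": c.called,
                "nmd_direction": c.nmd_direction,
            }
        )
    return pd.DataFrame(rows)


def write_calls(
    calls: Sequence[DiffSpliceCall],
    path: str,
    catalog: Optional[Sequence[SplicingEvent]] = None,
) -> None:
    calls_to_frame(calls, catalog).to_csv(path, sep="\t", index=False, float_format="%.6g")


def summary_to_frame(summary: GlobalSummary) -> pd.DataFrame:
    def row(c: ClassSummary) -> dict:
        return {
            "event_class": c.event_class,
            "n_eligible": c.n_eligible,
            "n_up": c.n_up,
            "n_down": c.n_down,
            "frac_nmd_up": c.frac_nmd_up,
            "frac_nmd_down": c.frac_nmd_down,
            "enrichment": c.enrichment,
        }

    rows = [row(c) for c in summary.classes.values()]
    rows.append(row(summary.overall()))
    return pd.DataFrame(rows)


def write_summary(summary: GlobalSummary, path: str) -> None:
    summary_to_frame(summary).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_orf_table(orf_table: Mapping[str, tuple[int, int]], path: str) -> None:
    rows = [
        {"transcript_id": tid, "cds_start": s, "cds_end": e}
        for tid, (s, e) in sorted(orf_table.items())
    ]
    pd.DataFrame(rows, columns=["transcript_id", "cds_start", "cds_end"]).to_csv(
        path, sep="\t", index=False
    )


def read_orf_table(path: str) -> dict[str, tuple[int, int]]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.transcript_id): (int(r.cds_start), int(r.cds_end))
        for r in df.itertuples(index=False)
    }


def truth_to_frame(truth) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": e.event_id,
                "gene_id": e.gene_id,
                "event_class": e.event_class,
                "eligible": e.eligible,
                "affected": e.affected,
                "psi1": e.psi1,
                "psi2": e.psi2,
                "k1": e.k1, "n1": e.n1, "k2": e.k2, "n2": e.n2,
            }
            for e in truth.events
        ]
    )


def write_truth(truth, path: str) -> None:
    truth_to_frame(truth).to_csv(path, sep="\t", index=False, float_format="%.6g")
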