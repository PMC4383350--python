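import pytest

import nmdsplice as ns


@pytest.fixture(scope="session")
def mixed_sim():
    """Small simulated experiment covering every event class."""
    cfg = ns.SimulationConfig(n_genes=21, seed=7)
    sim = ns.generate_annotation(cfg)
    return cfg, sim


@pytest.fixture(scope="session")
def mixed_catalog(mixed_sim):
    """Event catalog rebuilt from the simulator's transcript models."""
    _, sim = mixed_sim
    genes = ns.group_genes(sim.transcripts)
    return ns.build_event_catalog(genes, orf_table=sim.orf_table)


def make_transcript(tid, exon_coords, strand="+", chrom="chr1", cds=None, gene=None):
    """Helper: build a TranscriptModel from (start, end) exon tuples given in
    genomic order; minus-strand chains are re-ordered to transcript order."""
    exons = [ns.GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
    exons.sort(key=lambda e: e.start, reverse=(strand == "-"))
    return ns.TranscriptModel(tid, gene or tid.split(".")[0], tuple(exons), cds=cds)
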