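"""Classify isoforms as predicted NMD substrates with the 50-nt rule.

Builds a two-exon transcript whose stop codon sits 100 nt upstream of a
spliced 3' UTR junction (the architecture that makes an mRNA such as DUX4 an
endogenous NMD substrate), plus the unspliced form of the same locus, and
prints the rule's verdict for each.
"""

import nmdsplice as ns

spliced = ns.TranscriptModel(
    "demo.spliced", "demo",
    (
        ns.GenomicInterval("chr4", 0, 400, "+"),
        ns.GenomicInterval("chr4", 500, 700, "+"),
    ),
)
retained = ns.TranscriptModel(
    "demo.retained", "demo",
    (ns.GenomicInterval("chr4", 0, 700, "+"),),
)
orf_table = {"demo.spliced": (0, 300), "demo.retained": (0, 300)}

for t in (spliced, retained):
    orf = ns.assign_orf(t, orf_table)
    call = ns.classify_nmd(t, orf)
    dist = call.max_downstream_junction_distance
    dist_txt = f"{dist} nt" if dist is not None else "no downstream junction"
    print(f"{t.transcript_id:16s} status={call.status.value:14s} "
          f"max stop-to-junction distance: {dist_txt}")

# The spliced isoform has an exon-exon junction 100 nt downstream of its stop
# codon (> 50 nt), so it is a predicted NMD substrate; retaining the intron
# removes the junction and with it the NMD signal.
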