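# Methods

## The statistic

The package's target quantity is the global asymmetry in how predicted NMD
substrates change between two conditions. For every binary splicing event
with exactly one NMD-substrate isoform, Ψ denotes the substrate isoform's
share of identifying reads. After filtering (below), events are labeled
`nmd_up` (Ψ rose by ≥ 10 percentage points), `nmd_down` (fell by ≥ 10), or
`unchanged`; the per-class fractions up and down and their ratio
(enrichment) summarize the experiment. Under intact NMD the two fractions
are comparable; global NMD inhibition produces a large excess of `nmd_up`.

## NMD-substrate prediction (50-nt rule)

An isoform is a predicted NMD substrate iff the distance from the **last
base of its stop codon** to some downstream exon–exon junction, measured in
spliced-transcript coordinates, **strictly exceeds 50 nt**. Isoforms
without a resolvable ORF are `unknown` and never enter the direction
analysis. Anchoring at the stop codon's last base follows the standard
50-nt-rule literature; the rule checks *any* downstream junction, which is
equivalent to checking the farthest one.

ORFs resolve with precedence **curated table → annotation CDS → longest
AUG-initiated ORF ≥ 60 nt** (the fallback requires a spliced sequence and
is otherwise skipped). An annotation CDS whose length is not a multiple of
three, or which contains an internal stop codon when sequence is available,
is rejected with a warning and the fallback attempted. By package
convention the CDS interval *includes* the stop codon; the GTF writer and
reader share this convention (stop_codon features, when present, are folded
into the CDS).

Aberrant isoforms (novel junctions, retention of constitutive introns) have
no annotated transcript. Their models are constructed from the annotated
template transcript and classified through the same precedence chain: a
curated-ORF entry keyed by `<event_id>:aberrant` wins; otherwise the
template's stop codon is projected onto the modified model, valid only when
the modification lies entirely 3′ of the stop (everything upstream
unchanged); otherwise the flag is `unknown`, because frameshift-induced
stop relocation cannot be predicted without genome sequence. This is a
deliberate precision-over-recall choice: an `unknown` flag removes the
event from the direction analysis rather than guessing.

## Junction classes and the event catalog

A junction is **constitutive** iff its donor pairs with no other acceptor
and its acceptor with no other donor anywhere in the gene, and every
transcript overlapping its intron splices exactly that junction (a
retaining transcript therefore breaks constitutivity). Genes are connected
components of exon-overlapping, same-strand transcripts; two transcripts
are the same record iff their exon chains are identical, so UTR-length
variants stay distinct (junction-level analyses are insensitive to
collapsing them).

Candidate junctions are all donor×acceptor pairings of annotated sites with
the donor upstream in transcript orientation; unannotated pairings are the
novel candidates. Each novel candidate sharing a site with a constitutive
junction becomes a `novel_junction` event against that reference (donor
match preferred over acceptor match, one event per novel junction); every
constitutive junction also yields a `constitutive_intron_retention`
contrast. Annotated contrasts (cassette exon, alt 5′/3′ splice site,
annotated retained intron, mutually exclusive exons) are detected from
transcript structure; cassette and mutually-exclusive patterns consume
their site pairs so they are not double-reported as alternative-splice-site
events. Mutually exclusive exons use the same binary machinery as all other
classes; no three-way isoform model is attempted. Isoform A of each event
designates the NMD substrate whenever exactly one isoform is a substrate;
events with both or neither stay in the catalog but are ineligible for the
direction analysis.

## Quantification

Alignments are kept iff mapq > 0 **and** (the read spans no junction **or**
its minimum junction overhang is ≥ 6 nt). A spliced read supports a
junction isoform when a gap matches a cataloged junction exactly (block
boundaries equal to donor and acceptor); an unspliced block supports a
retention isoform when it covers a retained intron boundary with ≥ 6 nt on
both sides (the same overhang parameter, applied symmetrically). Reads
consistent with both isoforms are never counted; a fragment (all records
sharing a read name, hence both mates) increments an event at most once,
and conflicting within-fragment support is discarded and counted as
ambiguous. A read spanning junctions of several events increments each
event independently — one physical junction can legitimately be evidence in
two contrasts (e.g. the spliced isoform of a retention event and the
reference of a novel-junction event).

Ψ is estimated as k/n with a Beta(k+1, n−k+1) posterior (uniform prior);
the 95% interval is the 2.5%/97.5% posterior quantiles, clamped to contain
the point estimate so k = 0 gives [0, ·] and k = n gives [·, 1]. Events
with n = 0 carry NaN markers rather than being dropped; downstream filters
remove them. The binomial junction-read estimator is used for **all** event
classes — one testable code path, exact under the simulator's generative
model and matching the interval semantics of full generative-model
estimators at the junction level.

## The Bayes-factor test

Two conditions are modeled as independent binomials. H₀: a common ratio p
with uniform prior; H₁: independent p₁, p₂, each uniform. Both marginal
likelihoods are Beta integrals and shared binomial coefficients cancel:

    BF₁₀ = B(k₁+1, n₁−k₁+1) B(k₂+1, n₂−k₂+1) / B(k₁+k₂+1, n₁+n₂−k₁−k₂+1)

computed in log space (`betaln`). The same quantity is the reciprocal
Savage–Dickey density ratio of δ = p₁ − p₂ at zero (the prior density of δ
at 0 is exactly 1), and `savage_dickey_bf10` evaluates that overlap
integral numerically as an internal cross-check (agreement to 1e-6 relative
is asserted in the tests). Uniform Beta(1,1) priors are the design choice:
they give the canonical Savage–Dickey worked example and a closed form.

Filters: `n > 20` in **both** conditions (strict, following the wording
"at >20 identifying reads"), `|ΔΨ| ≥ 0.10` and `BF₁₀ ≥ 5` (both
inclusive). The ΔΨ comparison carries a 1e-12 tolerance so exact-boundary
ratios are not lost to binary rounding. If several libraries per condition
are supplied, counts are summed before testing (single-library-per-condition
design). No multiple-testing correction is applied — the criterion *is* the
Bayes-factor threshold — but the number of tested events is reported so
users can post-correct. Summary denominators are the NMD-eligible events
passing the read filter (n = 0 events never enter a denominator); the
enrichment ratio is reported as an undefined marker when nothing decreased.

## Simulator

The generator emulates the statistical structure of a two-condition
NMD-inhibition experiment, not its sequence content:

- One gene per event, from fixed structural templates per event class
  (~1 kb loci on one synthetic chromosome; alternative-5′SS genes are
  placed on the minus strand so strand handling is exercised throughout).
  Implanted curated ORFs make exactly one isoform a substrate
  (`nmd_eligible_fraction`, default 1.0, can dilute this).
- Condition-1 Ψ ~ Beta(a, b) (default (2, 2): events spread over the whole
  ratio range); per condition n ~ Poisson(depth) identifying reads and
  k ~ Binomial(n, Ψ), or beta-binomial with concentration `dispersion` for
  overdispersed libraries.
- For an `affected_fraction` of NMD-eligible events (default 0.15, the
  order of magnitude a strongly NMD-inhibited transcriptome shows), the
  substrate isoform's **odds** are multiplied by `stabilization` (default
  3.5, mapping Ψ 0.30 → 0.60) in condition 2. The odds-scale effect is
  symmetric in isoform labeling and keeps Ψ in [0, 1]. Default depth 100
  reflects well-covered junctions in a deeply sequenced library.
- Counts are event-local, except that reads emitted for the reference
  junction of a novel-junction contrast also appear, deterministically, in
  the spliced isoform of the retention contrast on that same constitutive
  junction — the count tables mirror exactly what the emitted alignments
  imply, which is what makes the SAM path and the count-table path
  byte-identical.
- SAM emission writes junction-spanning records (10 nt flanks, mapq 50) and
  boundary-crossing records for retention isoforms; opt-in decoy fractions
  re-emit reads with mapq 0 or 5-nt overhangs to exercise the filters. All
  outputs are byte-deterministic under the seed.

What the simulator does **not** model: sequence content (no bases,
mismatches or quality scores), shared reads between genes, positional
coverage bias, or expression-level differences between genes. Passing tests
therefore demonstrate correctness of the counting, testing and
summarization machinery under the stated generative model — not robustness
to alignment artifacts or annotation errors in real data.

## Numerical and scale choices

- Coordinates are 0-based half-open internally; GTF (1-based inclusive) and
  BED conversions live only in readers/writers.
- Test problem sizes: null calibration uses 10,000 events at depth 100
  (call rate < 1% asserted), power uses 2,000 events with 15% affected
  (tight Beta(900, 2100) baseline so the implanted shift is ΔΨ = +0.30),
  interval calibration 1,000 events; the Bayes-factor grid runs to n = 500
  against a Gauss–Legendre double-quadrature oracle, which is exact for
  these polynomial integrands.
- Degenerate inputs: zero-read events produce NaN-marked Ψ rows; a
  condition with zero reads fails the read filter but the Bayes factor is
  still computed from the informative condition when n₁+n₂ > 0; corrupt
  ORFs (stop beyond transcript end) raise.

## Known limitations

- Without genome sequence, NMD flags of aberrant isoforms whose
  modification touches the CDS are `unknown` rather than predicted.
- The one-event-per-novel-junction pairing (donor-preferred) is a
  convention; a novel junction sharing both sites with two different
  constitutive junctions is only contrasted against one of them.
- Isoform ratios are binary; genes with more than two locally competing
  isoforms are represented as multiple overlapping binary events.
- The read counter assumes exact junction matches; small alignment slippage
  around junctions would be dropped rather than rescued.
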