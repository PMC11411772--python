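# Methods

## Model and procedure

`svmeld` is a consensus structural-variant (SV) caller operating purely at
the call level: its inputs are VCFs from upstream callers, never reads. The
procedure has two stages.

**Pre-training.** Given call sets from *k* callers and a gold-standard
truth set sharing one SV type, every caller is benchmarked within each
length bin: truth and calls are stratified by their own event length,
matching is re-run independently per stratum, and a
sensitivity/precision/F-score row is computed per (caller, bin) cell. The
callers are ranked per bin — by F-score by default — and the full ranked
table is frozen into a YAML profile keyed by organism tag, coverage tier
and SV type. Deletions and insertions are trained separately; their winning
combinations differ in practice.

**Discovery.** For a new sample, the nearest profile is resolved (exact
organism and the tier containing the sample's depth; otherwise the nearest
tier of the same organism by depth midpoint; otherwise a designated default
organism, with a warning). Each bin's rank-0 caller contributes exactly its
records whose own length falls in that bin; the concatenation is
deduplicated and written as one VCF with per-record provenance
(`INFO/SRC`).

**Matching rule.** A call matches a truth event iff they share chromosome
and SV type and both breakpoints agree within τ bp (inclusive). Insertions
are point events (`end == pos`), so the rule degenerates to one position
comparison; an optional length-similarity gate exists but is off by
default, since a right coordinate for an insertion is not well defined.
Pairing is greedy and one-to-one: truth records are visited in the total
sort order `(chrom, pos, end, svtype, …)` and each takes the first unpaired
matching call in that same order. Greedy pairing can fall below the maximum
bipartite matching on pathological clusters, but is deterministic,
O(n log n), and equals the optimum whenever each record has at most one
candidate — which the region's spacing makes the norm in real data. Fixing
"first" to the sort order makes every result bit-reproducible.

**Metrics.** sensitivity = TP/(TP+FN), precision = TP/(TP+FP), F-score =
their harmonic mean; zero-denominator cells report 0 rather than NaN so
empty call sets still produce comparable rows. The τ sweep is
{0, 10, 100, 1000, 10000} bp with 100 bp as the headline threshold — at
τ = 0 most real callers match nothing, and beyond 10 kb the notion of "the
same event" dissolves.

## Consensus details

* **Deduplication** reuses the matching predicate (default τ = 100 bp, the
  same threshold used for scoring, so "one event" means the same thing when
  building and when judging). Records are visited in (caller-rank, sort
  key) order and kept unless an already-kept record of the same chromosome
  and type lies within τ on both breakpoints. This single pass guarantees
  all three desired properties at once: the higher-ranked caller's record
  represents a duplicate cluster, no two kept records are within τ of each
  other, and the operation is idempotent.
* **Recall mode** is the deduplicated union of all callers; on any truth
  set its sensitivity dominates each input's by containment.
* **Precision mode** keeps a record iff ≥ `min_support` *distinct* callers
  have a τ-equivalent record (a caller's own duplicates count once, so a
  noisy caller cannot corroborate itself). `min_support` defaults to 2 —
  the weakest corroboration able to remove caller-private false positives;
  `min_support=1` degenerates to recall mode. Survivors carry their
  support count (`INFO/SUPP`).
* No breakpoint averaging or coordinate refinement is performed; the
  representative record's attributes pass through unmodified.

## Pre-filters and conventions

Events shorter than 50 bp are removed ("smaller than" is strict — 50 bp is
kept), since they fall below the definitional SV size. High-confidence BED
filtering defaults to full containment of the record's 0-based half-open
footprint, the usual convention for benchmark regions; any-overlap is
available by option. Internally coordinates mirror VCF (1-based,
inclusive); BED conversion happens only at the filter boundary. For
deletions the stored length always equals `end − pos`; VCF SVLEN sign is
reconstructed on write. Multi-allelic records are split per ALT (with
per-ALT SVLEN taking precedence over the single `stop` htslib derives,
which cannot describe several ALTs). Genotypes are ignored throughout —
this is a site-level tool.

## Downsampler

Generic per-read subsampling orphans mates; the resulting singletons
corrupt insert-size and discordant-pair signals. Here the keep decision is
`blake2b(read_name, salt=seed) / 2^64 < p`, made once per template: mates,
secondary and supplementary alignments inherit it wherever they occur in
the file, with no buffering. Consequences verified by tests: zero
singletons at any fraction, byte-identical output across reruns,
independence of selections across seeds, and kept-template counts matching
Binomial(n, p).

## Synthetic data generator

The generator emulates what is actually measured about real callers:
per-length-bin sensitivity, a genome-wide false-positive rate, and
breakpoint uncertainty.

* Truth sets place a chosen number of events per bin; positions are
  uniform with a random inter-event gap of at least twice the maximum
  simulated length, lengths are log-uniform within each bin (SV length
  distributions are heavy-tailed; log-uniform spreads mass across each
  decade instead of piling onto the bin's upper edge). The open-ended top
  bin is capped at 10× its lower edge (10 kb by default) so spacing is
  well defined.
* Corruption emits each truth event with its bin's sensitivity, adds
  rounded zero-mean Gaussian jitter independently to both deletion
  breakpoints (insertions jitter position only, with separate length
  noise), and adds Poisson(fp_rate × genome Mb) false events whose lengths
  are resampled from the truth distribution so every bin sees false calls.
  Emitted records are clamped to the 50 bp minimum.

Default experiment conditions used by the tests and the acceptance script:
500 truth events per bin, two callers with complementary per-bin
sensitivities (0.9 vs 0.3, a 0.6 gap), false-positive rate 1/Mb, jitter
SD 10 bp, scored at τ = 100 bp on a 240 Mb two-chromosome toy genome.
Calibration holds by construction: measured recall sits in the binomial
interval whenever τ ≥ 3× jitter SD, and measured false positives in the
Poisson interval.

**What passing on fixtures does and does not show.** The generator's
events are widely spaced, independent, and free of the things that make
real genomes hard: repeat- and segmental-duplication-driven clustered
events, systematic (correlated-across-callers) false positives, breakpoint
biases that are not zero-mean, imprecise `END` annotation, and genotype
errors. Passing therefore demonstrates the machinery — binning, ranking,
routing, deduplication, accounting — is correct, not that any particular
accuracy level will transfer to a given real dataset. One known
consequence: per-bin *stratified* recovery is only binomial when jitter is
small against the bin width, because jitter perturbs event lengths and
migrates edge events into neighbouring bins.

## Numerical and design choices

* Bin edges (50, 100, 500, 1000) are configuration, not inference; bins
  are half-open `[lo, hi)` so a boundary length belongs to the upper bin
  and the partition is exact.
* Coverage tier edges (0.5, 8, 20×) separate the ultra-low / low / mid /
  full-depth regimes; also pure configuration.
* Ranking ties break by higher precision (false positives being the
  field's chronic failure mode), then lexicographic caller id — so training
  is invariant to the order call sets are supplied.
* A bin with no truth events cannot be ranked on its own evidence; its
  winner falls back to unstratified metrics and the profile flags it
  `untrained_bins`.
* Training τ defaults to 100 bp, matching the headline reporting
  threshold.
* Empty inputs are legal everywhere and produce empty outputs or
  zero-metric rows, never exceptions; contract violations (overlapping
  train/test chromosome sets, min_support exceeding the caller count,
  missing winner call sets, malformed profiles) fail fast with the
  offending name in the message.

## Known limitations

* Insertion evaluation compares positions and (optionally) lengths, never
  inserted sequence; two different insertions at one locus are
  indistinguishable.
* Greedy matching is order-defined; a different total order could pair
  differently in dense clusters (counts are nearly always identical).
* The organism key is an exact tag — no notion of relatedness between
  organisms.
* The downsampler assumes read names identify templates; files with
  duplicated names across lanes inherit those collisions.
* Profiles do not transfer across bin-edge configurations; retrain after
  changing edges.
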