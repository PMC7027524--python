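# Methods

## Model

All statistics operate in *model coordinates*: 1-based inclusive
positions on an rRNA gene model (for 16S, *E. coli* numbering over
L = 1542 positions). Given N rRNA-matching reads, the null hypothesis
of random fragmentation says each read's start position is uniform over
the positions that admit its fragment length; marginally, each position
p receives a count

    c_p ~ Binomial(N, 1/L).

Amplicon carryover concentrates mass instead at the primer anchors: for
the V3–V4 16S design, starts at the forward-primer position 341 and
(for fully merged amplicons) ends at the reverse-primer position 805.
The same reasoning applies independently to the end-coordinate
histogram; in real contaminated libraries the end peak need not
coincide with the reverse primer footprint (partially merged or
truncated amplicons end earlier), which is why start and end windows
are detected separately and never paired.

## Peak calling

"Peaks" are formalized rather than eyeballed. For each of the start and
end histograms:

1. per-position one-sided p-value `P(X ≥ c_p)` under Binomial(N, 1/L)
   (`scipy.stats.binom.sf`);
2. Benjamini–Hochberg adjustment across the L positions
   (`statsmodels.stats.multitest`);
3. a position is flagged iff `p_adj ≤ alpha` **and** `c_p ≥
   min_fold·N/L` **and** `c_p ≥ min_count`;
4. flagged positions within `merge_gap` of each other merge into one
   window.

Defaults: `alpha = 0.01`, `min_fold = 5`, `min_count = 10`,
`merge_gap = 3`. The two floors make the caller conservative: at
realistic depths a position must carry several-fold the uniform
expectation, not merely achieve statistical significance, so pure-null
data essentially never produces windows (the BH step alone would
already control false windows near alpha; the floors push the realized
type-I rate to ~0, which the acceptance suite verifies over 20 null
runs of 50,000 reads). `merge_gap = 3` keeps a true multi-position peak
with one or two interior dropouts in a single window. The null uses
1/L over the full model length; edge effects from finite fragment
length (positions within one fragment length of the 3' edge receive
slightly more starts under the exact null) are second-order at
L ≈ 1542 with ~150 bp fragments and are deliberately ignored — they
make the test marginally conservative at interior positions, never
anticonservative at a true peak.

Removal is by window membership: a read is dropped iff its start lies
in any start-window **or** its end lies in any end-window. This is
deliberately coordinate-only — no primer-sequence matching — so it also
removes contaminants whose primer bases were trimmed upstream.

## SSU:LSU screen

Both rRNA subunits occur once per operon, so SSU and LSU fragment
counts from the same library should be of the same order. The screen
flags a sample when `n_ssu / n_lsu` exceeds a threshold, default 10 —
chosen an order of magnitude below the ~42 ratio a genuinely
contaminated sample can reach while staying well above the ~1–2 range
of clean libraries. `n_lsu = 0` with `n_ssu > 0` flags with an
undefined ratio; a sample with no rRNA reads at all is reported
unflagged with a warning rather than an error.

## Profile comparison

Decontamination success is quantified as the total-variation distance
between coordinate profiles: the start and end histograms are
concatenated, normalized jointly to sum 1, and TV = ½·L1. This single
number is 0 for identical profile shapes and 1 for disjoint support,
and satisfies the metric axioms. Computing TV on the concatenation
(rather than on starts alone) makes the comparison sensitive to
contamination visible in either histogram. The contract checked in
tests: after removing windows that captured a true spike, the cleaned
profile's TV distance to the uncontaminated reference is below the
contaminated profile's.

SSU-vs-LSU *taxonomic* concordance uses the same statistic on domain
percentage compositions (½·Σ|p1−p2|/100), with "agreement" reported at
TV ≤ 0.05 by default.

## Community arithmetic

Domain percentages are `100·count/total` with all four categories
(Bacteria, Fungi, Other, Unassigned) in the normalization — reported
per-sample rows do not sum to 100, confirming a remainder category.
The bacteria/fungi ratio is computed from the percentages as reported
(half-up rounded to 2 decimals), not from raw counts, so any published
row is reproducible from its printed percentages alone; rounding is
half-up because that convention reproduces every checked printed
ratio. The plasmid hit filter keeps BLAST-tabular hits with
`pct_identity ≥ 95` and `align_len ≥ 90` (both inclusive), and the
match fraction is half-up rounded to 1 decimal.

## Synthetic data

The generator emulates the two read populations the procedure
distinguishes:

- **Shotgun null** — fragment lengths from a truncated normal (defaults
  mean 150, sd 30, min 50, max 300 bp, matching merged 2×150 reads;
  all four free parameters), starts uniform over `1..L−len+1`.
- **Amplicon contamination** — starts at `fwd_start`, ends at
  `rev_end`, each offset by independent N(0, jitter_sd) noise rounded
  to integer positions and truncated to model bounds. `jitter_sd = 0`
  (the default) gives exact anchoring for sharp tests; small positive
  values reproduce multi-position peaks like the 338–344-style windows
  seen in real contaminated data. The published data do not constrain
  the contaminating insert-length distribution after read merging, so
  amplicon reads here span the full primer-to-primer footprint and the
  jitter knob stands in for ragged ends.
- **Errors** — independent per-base substitutions only. No indels, by
  design: it keeps the built-in matcher's coordinates exact and the
  truth table unambiguous. Real reads have indels and quality-dependent
  error profiles; coordinate-level conclusions from these simulations
  transfer, but matcher accuracy on real data should come from Infernal
  output instead.

Reference sequences for sequence-level simulation are i.i.d. random
nucleotides (`random_reference`, labelled synthetic): positional
statistics do not depend on base composition, and a random 1542-mer
lacks the repeats and conserved domains of a real 16S gene — which only
makes the matcher tests *harder* to pass by luck and means nothing here
validates taxonomy-dependent behaviour.

Not emulated: chimeras, unmerged read pairs, quality-score error
models, multi-template (per-taxon) coordinate systems, LSU amplicon
designs. Passing tests therefore demonstrate the statistical procedure
and its bookkeeping, not robustness to every real-library artifact.

## Built-in matcher

`align_reads` is a seed-and-extend, substitution-only matcher: exact
k-mer seeds (default k = 15) sampled every k bases along the read
(plus the terminal window, so one substitution cannot eliminate every
seed of a ≥ 2k read), candidate diagonals scored by full ungapped
comparison, best identity wins; both strands are tried and
minus-strand matches keep forward-model coordinates. Defaults
`min_identity = 0.90`, `min_len = 50`. It exists so synthetic tests
need no external binary; for real data the supported route is Infernal
`cmsearch --tblout`, whose model-coordinate columns are authoritative
(tests check the matcher's coordinates against a Smith–Waterman oracle
on error-free reads). Hits are resolved per read by minimum E-value,
ties by maximum score, then lexicographic marker name.

One caveat carried as a documented limitation: Rfam model coordinates
and *E. coli* 16S numbering may differ by small offsets; the package
treats the model's own coordinate system as the single frame and makes
no cross-numbering correction.

## Problem sizes and determinism

Test and acceptance runs use 20,000 uniform + 5,000 amplicon reads for
spike experiments, 20 × 50,000 reads for the null sweep, 1,000 reads
for the matcher-vs-oracle comparison and 10 seeds for the TV-direction
check — sizes at which every binomial expectation involved is large
enough for the statistics to be stable while a full run stays in
seconds. All generators take explicit integer seeds
(`numpy.random.default_rng`); identical configurations produce
byte-identical truth tables, and the CLI writes a manifest (parameters,
version, seed) next to every output.

## Known limitations

- The binomial null ignores fragment-length edge effects (above) and
  models positions independently; both choices are conservative.
- Windows are not cross-matched into start/end "amplicon pairs";
  removal on either membership can over-remove if two unrelated
  contamination events overlap, which the TV comparison would reveal.
- The flag threshold of the SSU:LSU screen is a design choice informed
  by one well-characterized contaminated example, not a fitted value.
- `parse_tblout` assumes `cmsearch` column orientation (target = read,
  query = model); `cmscan` output must be converted first.
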