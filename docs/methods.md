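# Methods

## Model and procedure

The package detects composite elements (CEs): pairs of transcription
factor binding motifs that co-occur within single ChIP-seq peaks more
often than expected under a composition-preserving permutation of those
same peaks. The first motif of every pair (Anchor) is fixed — it
represents the ChIP-ed factor — while the second (Partner) is either a
single user motif, a library of motifs, or the Anchor itself (homotypic
CEs, reported under the name "Anchor").

### Motif model and conservation levels

Motifs are positional nucleotide count (or probability) matrices over
(A, C, G, T). Scanning uses a log-odds position weight matrix

    w_i(b) = log2( (n_i(b) + p·q(b)) / (N_i + p) ) − log2 q(b)

with per-column counts `n_i(b)`, column depth `N_i`, background
frequencies `q` (taken from the calibration set by default) and a
pseudocount `p` (default 1.0) distributed across letters by `q`.
Probability matrices are first scaled to pseudo-counts at an effective
depth of 100. A window's score is the sum of its per-position weights;
the reverse strand scores the reverse complement. Windows containing N
are skipped.

Scores are mapped to conservation levels empirically: on a calibration
sequence set (both strands pooled) the survival function
FPR(s) = #{windows scoring ≥ s} / #windows is tabulated over the
distinct achieved scores, and every reported hit carries
CL = −log10 FPR(score). Ties share the largest FPR among equal scores,
so conservation is never overstated; a hit scoring above every
calibration window receives the smallest resolvable rate, 1/#windows.
Five thresholds `t_k` — the smallest scores with FPR ≤ 10^(−e_k) for
edges e = (3.5, 4.0, 4.5, 5.0, 5.5) — delimit the five CL ranges used in
reporting; hits are kept from `cl_min` = 3.0 upward so that the heatmap's
"CL < 3.5" bin is populated. The five range boundaries are a documented
default of this implementation, not a published constant; they are
consistent with the 3.5–5.5 span of the heatmap bins and are fully
configurable. Calibration requires at least 10^5.5 ≈ 316k scannable
windows so the deepest range is resolvable; the packaged synthetic
calibration generator (Markov-0 chunks, 1 Mb by default) satisfies this
without any external download, at the cost of ignoring promoter-specific
composition (see Limitations).

### Background by permutation

For each foreground peak, `bg_reps` (default 10) shuffled copies form
the background. The default shuffle preserves all 16 dinucleotide counts
exactly via a random Eulerian walk on the letter-transition multigraph
(random last-exit edges resampled until they form a tree into the final
letter, remaining out-edges permuted); a plain mononucleotide permutation
is available as `mode="mono"`. Dinucleotide preservation is the standard
guard against CpG/stacking artefacts inflating motif scores in shuffled
sequences. Sub-seeds derive deterministically from (seed, peak index,
replicate), so backgrounds are reproducible byte-for-byte.

### Pair taxonomy

Within each peak, every ordered (anchor hit, partner hit) pair is
classified; homotypic pairs are unordered, exclude identical coordinates,
and put the higher-scoring hit in the anchor role.

* **Location.** Full overlap: one interval contains the other (overlap
  length = shorter motif; border distance = min of start- and
  end-offsets). Partial overlap: intersection without containment.
  Spacer: disjoint with gap within [spacer_min, spacer_max]
  (default 0–29, user-adjustable); gaps outside the limits are
  discarded. Five flows are tested independently: Full, Partial,
  Overlap = Full ∪ Partial, Spacer, Any = Overlap ∪ Spacer.
* **Orientation.** Same strand: DirectAP when the anchor precedes the
  partner in the reading order of that strand, DirectPA otherwise.
  Opposite strands: Inverted when the heads face each other (the '+'
  hit upstream of the '−' hit), Everted when they point apart.
  Precedence is decided by interval centres (`start + end`, exact in
  integers). Centre comparison equals left/right order whenever neither
  motif contains the other, and — unlike a start-coordinate rule — it is
  exactly invariant under reverse complement of the peak for containment
  pairs too, which is what the taxonomy requires (a contained motif has
  no meaningful left/right position). Ties break toward the anchor in
  its own reading direction, which keeps even degenerate
  identical-interval pairs mirror-stable.
* **Conservation relation.** anchor_more / partner_more by comparing the
  continuous CLs; exact ties are excluded from asymmetry counts so that
  a measure-zero technicality cannot bias either class.

### Statistics

* **Enrichment** (per flow × conservation class: any / anchor-more /
  partner-more, 15 tests per motif pair) counts *sequences* with vs
  without a CE in foreground and background and applies a one-sided
  (greater) Fisher's exact test — overrepresentation in the foreground
  is the hypothesis of interest. The test is the exact hypergeometric
  tail (scipy's hypergeometric distribution; no asymptotic
  approximation); degenerate margins give p = 1.
* **Asymmetry** (per flow) counts *CEs* with anchor-more vs partner-more
  conservation in foreground and background and applies a two-sided
  Fisher test; the reported −log10 p carries sign '+' when the
  foreground's anchor-more proportion exceeds the background's, '−'
  otherwise, and ±0 at equality. The null has no direction, hence
  two-sided with a sign, in contrast to the directional enrichment test.
  Flows with fewer than 5 conservation-informative CEs in either dataset
  are reported as not assessed rather than returning an unstable sign.
* **Heatmaps** bin CEs by (anchor CL, partner CL) into 12×12 cells with
  boundaries (3.5, 3.7, …, 5.5) — open bins below 3.5 and above 5.5 —
  and show the per-mille contrast `1000·Obs_ij/Obs − 1000·Exp_ij/Exp`
  (rows = anchor, columns = partner). The matrix sums to zero by
  construction; an empty side yields a flagged all-zero matrix.
* **Similarity** guards against pairs where the "partner" is effectively
  the anchor itself. Both matrices are column-normalised; over all
  relative offsets with ≥ 4 overlapping columns and both orientations
  (partner as-is and reverse-complemented) the Pearson correlation of
  the flattened overlapping cells is maximised; the p-value is
  `(1 + #{shuffled ≥ observed}) / (1 + n_shuffles)` over partners with
  independently permuted column order (default 1000 shuffles). p < 0.05
  annotates the output row as potentially self-matching but never
  removes it. This is a concrete, self-contained definition chosen for
  reproducibility; statistics computed on matrices (rather than on
  overlapping predicted-site sets) keep the check independent of the
  scanning thresholds. Note that motifs with near-exchangeable columns
  (e.g. one-hot consensus matrices) can reach the observed maximum under
  the null, so even self-comparison need not be flagged — the null is
  "no more similar than a column-shuffled version", by design.
* **Library runs** share the anchor calibration and the permuted
  background across partners, append Bonferroni-adjusted −log10 p per
  flow (raw values always retained), and support stable sorting of the
  result table by any column.
* p-values are floored at 1e-320 before taking −log10.

### CE logo

Among overlap-class foreground CEs the modal structural variant —
(orientation, location, overlap length, signed partner offset in the
anchor-normalised frame) — is selected (ties: more CE instances, then
more distinct peaks, then lexicographically smallest label). Each
instance contributes the peak subsequence spanning the union of the two
intervals, reverse-complemented when the anchor lies on '−' so all
anchors share one frame; stacked positional counts plus anchor/partner
interval-and-strand annotations form the logo. Rendering is left to the
caller (the counts table is logo-software-agnostic); the package's
contract is the exact counts matrix.

## Synthetic data generator

`random_peaks` / `make_calibration` emit i.i.d. Markov-0 sequences;
`plant` writes an Anchor site and a Partner site realising an exact
orientation/location/geometry at a uniformly random admissible position
into a seeded subset of peaks, emitting a BED-like truth table. Site
emission is per-column: the consensus letter with probability equal to
the site *strength*, otherwise a background letter — the simplest model
in which strength controls hit CL monotonically. For overlapping plants
the anchor's letters win the shared columns (the inner motif wins for
Full overlaps), so overlap geometries whose consensus strings agree on
the shared columns should be used when both motifs must stay detectable.
Layouts that cannot reproduce the requested orientation under the centre
rule (e.g. a DirectAP Full overlap with a longer partner, or an Inverted
Full overlap with the partner centred left of the anchor) are rejected
with an explicit error; Full plants require unequal motif lengths, with
the geometry parameter giving the shorter motif's offset inside the
longer.

What the generator does **not** emulate: read-density peak shape, GC or
mappability covariates, positional bias of sites within peaks, motif
clustering beyond the planted pair, and promoter-like composition of the
calibration set. Passing tests on this generator demonstrate the
correctness of the counting and testing machinery and end-to-end
recovery of known signal — not performance on real peaks, where
composition confounds are harsher.

## Default problem sizes

Tests and the acceptance script use 100–500 peaks of 300 bp, 10
background replicates, and 0.4–1 Mb calibration sets — sizes at which
every empirical quantity in the contract (FPR ≤ 10^−5.5 resolution, CE
counts per flow, permutation nulls) is well-defined while a full run
completes in seconds on one core. The vectorised scanner processes all
peaks of a dataset as one padded code matrix per strand.

## Numerical choices and degenerate inputs

* Fisher two-sided sums outcome probabilities ≤ the observed one with a
  1e-12 relative guard for tied masses; a mask covering the whole
  support returns exactly 1.
* FPR lookup is exact (no interpolation); the threshold score for a CL
  target is the smallest achieved score meeting it, +inf when the
  calibration set cannot resolve the target (such a profile simply
  reports no hits).
* Matrices shorter than 4 columns, all-zero columns, negative entries,
  and probability columns not summing to 1 (±1e-6) are rejected on
  ingest; probability round-trips are exact to 1e-9, count round-trips
  exact.
* Peaks shorter than a motif yield empty hit lists; empty CE sets yield
  header-only tables, p = 1 everywhere, and no logo.
* Duplicate motif ids in a library are suffixed `.2`, `.3`, …;
  malformed library blocks are skipped with a warning (an all-malformed
  library is an error).

## Design decisions

* The CLI is a thin veneer; the library API (and `examples/`) is the
  primary surface. The original service architecture around this kernel
  (web frontend, task queue) is out of scope; a synchronous run with a
  progress callback replaces it.
* Alphabet order is fixed to (A, C, G, T) internally; every dialect
  parser permutes into it on ingest.
* All anchor hits above `cl_min` participate in pairing by default;
  `anchor_best_only` restricts each peak to its best anchor hit for
  users who prefer one-site-per-peak semantics.
* Homotypic enrichment counts each unordered hit pair once; using the
  higher-scoring hit as "anchor" makes the conservation relation
  well-defined without doubling pairs.

## Known limitations

* CL resolution saturates at 1/#calibration-windows; two motifs that
  both score above every calibration window tie at the cap and drop out
  of asymmetry counts.
* The similarity permutation null preserves column multisets only;
  motifs with strong inter-column structure (dinucleotide constraints)
  are not modelled.
* Background permutation preserves composition, not chromatin context;
  enrichment against it answers "more often than by sequence
  composition", nothing stronger.
* Mononucleotide mode shuffles uniformly; the dinucleotide Eulerian
  shuffle samples via rejection of random last-exit assignments, which
  is exact on the dinucleotide counts but only approximately uniform
  over Eulerian walks for highly repetitive sequences.
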