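# Methods

`pequant` quantifies prime-editing outcomes from two kinds of targeted
sequencing libraries: plain PCR amplicons (precise-edit and indel rates per
read) and UDiTaS-style unidirectional libraries (outcome composition per
unique molecular identifier, including large deletions and vector
integrations).  This note records the models, the parameters that matter,
the numerical choices, and what the synthetic benchmark does and does not
establish.

## Coordinate model

All internal coordinates are 0-based, half-open, on the top strand; reports
convert to 1-based inclusive.  Nick positions are between-base offsets: a
nick at `k` separates bases `k-1` and `k`, which makes the span of a
deletion lying between the pegRNA nick and the nicking-sgRNA nick an
ordinary half-open interval.  Reverse-strand guides carry top-strand
coordinates plus an orientation flag; classification always happens on the
top-strand sequence.

An edit specification is the intended sequence change (substitution,
insertion, deletion, or replacement over a reference interval), an optional
synonymous PAM modification given as a single-base (position, ref, alt)
triple, and a quantification window.  The window has no natural default —
published analyses differ on whether the full amplicon or a sub-window is
scored — so it is an explicit config field.  The bundled scenarios use the
minimal window covering the edit, the PAM position and the pegRNA nick,
with one to two bases of margin; a window should extend past any repeat
context of the edit so that left-normalization cannot carry an event across
its boundary.

## Read processing

Demultiplexing assigns a read when exactly one barcode lies within Hamming
distance 1 of its index; anything else is routed to an unassigned stream.
Barcode sets with pairwise distance below 3 trigger a warning because
one-mismatch assignment can then be ambiguous by construction.

Pair merging reverse-complements read 2 and picks the overlap maximizing
matched bases, requiring at least 10 overlapping bases and at most 10%
mismatches (exposed in config; the upstream merger the protocol names does
not publish its acceptance thresholds, so these are this package's
defaults).  In disagreeing overlap columns the higher-quality base wins and
the column quality is the maximum of the two.

The quality filter keeps a read iff its mean Phred score is at least 30 and
its minimum per-base score at least 24 — the boundary values themselves are
kept, reading the removal condition ("under 30", "under 24") literally.

UMI schemes are configurable: a read prefix of configurable length (default
8; the UDiTaS scenario uses 12) or a header field.  UMIs are compared
exactly; no error correction or clustering is applied by default, so UMIs at
Hamming distance 1 found distinct families.  The consequence — sequencing
errors inside the UMI spawn spurious singleton families at a per-read rate
of roughly `umi_length x e` — is visible in the benchmark (about 4% extra
families at e = 0.001) and distributes across categories in proportion to
the mixture, leaving composition ratios nearly unbiased.

## Alignment

Amplicon references are short enough for exact affine-gap dynamic
programming, so there is no seed-and-extend mapper.  Scoring defaults are
match +2, mismatch −4, and gap cost `gap_open + L·gap_extend` with
gap_open = −8, gap_extend = −1; the heavy opening penalty makes one long
contiguous indel preferable to scattered gaps, matching how prime-editing
deletions present.  `N` scores 0 against everything.  UDiTaS fragments
align in a reference-infix mode (free reference flanks); amplicon reads
end-to-end.

Ties between co-optimal alignments are broken by the DP traversal order and
then erased by event normalization: every indel is shifted to its leftmost
equivalent placement (VCF convention), so identical molecules yield
identical `(kind, position, length, allele)` keys regardless of gap
placement.  This is what makes position-keyed background subtraction and
breakpoint clustering well defined.

Window comparisons use canonical haplotypes rather than raw alignment
columns: both the read's normalized events and the edit spec's own event
decomposition are projected onto the quantification window with the same
left-normalization, making the precise/wild-type decision invariant to
equivalent gap placements even when an event's placement range straddles
the window boundary.  Insertions anchored exactly on a window boundary
count as outside the window on both sides of the comparison.

Reads whose end-to-end identity (matches / read length) falls below 0.95
are re-examined by split alignment before event-based classification: a
fragment spanning a deletion junction can otherwise produce a spurious
mid-reference alignment whose identity is inflated by chance matches.  The
split caller requires a prefix and a suffix (each consuming ≥ 25 read bases
at ≥ 95% identity) aligning collinearly to disjoint reference windows, with
at most 20 untemplated bases at the junction, and reports the deleted
interval with microhomology resolved leftmost — the same canonical frame as
event normalization, so split-derived and gap-derived breakpoints cluster
together.  Below 0.60 identity with no junction evidence a read is
unclassified.  These two thresholds are package choices, exposed in
`ClassifyParams`.

## Amplicon quantification

A read is `precise_edit` iff its window haplotype equals the edited
allele's window exactly — the intended edit **and** the synonymous PAM
modification, with no other event in the window.  There is no error
tolerance: a sequencing error inside the window demotes the read to
`substitution_other`.  Tolerating errors would require a quality model the
data do not supply, and the exact rule keeps the precise fraction an honest
read-level count.  `indel` means at least one insertion or deletion touches
the window (overlap is tested against the event's full equivalent-placement
envelope, with touching intervals counting); `wild_type` requires an exact
window match to the reference; reads not covering the window are
`ambiguous` and never silently dropped.

The indel catalog keys events by (kind, position, length, allele) —
stricter than type and position alone, so a control artifact at a position
cannot cancel a different event there.  Background subtraction computes,
per key, `net = max(0, treatment − mean(controls))`, with keys absent from
every control passing through unchanged.  The subtraction is rounded at
1e−12 before flooring so that exact treatment/control cancellation yields
exactly zero despite binary round-off in the mean; real frequencies are
never below `1/total_reads`.  Subtraction applies to the event catalog
only — precise-edit counts are never adjusted.

The per-read indel rate counts reads with any window indel; the
background-subtracted quantity is event-level (the summed net frequency of
indel rows), and the two are reported side by side rather than conflated.
Out-of-window events are recorded separately and do not change calls.

## UDiTaS quantification

Reads sharing a UMI form a family; the exemplar is the most frequent member
sequence, ties broken by highest summed base quality and then
lexicographically.  Classification runs a fixed cascade: AAV integration
(junction evidence wins over everything), then precise edit, then a
deletion spanning both nick sites with size < 100 bp (`pegnick_deletion`,
sizes 1–99), then any indel below 50 bp or a substitution
(`small_indel_sub`), then deletions of 100 bp or more (`large_deletion`;
the boundary value 100 is assigned to large), then wild type.  Deletions of
50–99 bp that do not span both nicks fit none of the documented bands and
are left `unclassified` rather than forced into one.

Evidence requirements differ by call: the wild-type call asserts the
*absence* of events between the nicks and therefore requires the exemplar
to span that window, while event-based calls need only the event actually
observed.  Substitution evidence is scoped to the quantification window;
substitutions elsewhere are treated as sequencing noise and do not demote a
family from wild type — without this scoping, raw error at e = 0.001 over a
60-bp nick window would flood the small-indel/substitution category with
several percent of wild-type families.

AAV integration requires a local alignment to the vector reference scoring
at least 40 (20 exact bases at default scoring) plus the false-priming
filter: a read whose vector hit starts directly at the locus-primer
footprint and which contains no exact locus match of at least 15 bases
beyond the primer was primed on the vector itself and is rejected.  Both
thresholds are package choices (the protocol describes the filter but not
numbers) and sit in `ClassifyParams`.

Large-deletion families with identical normalized breakpoints form
clusters.  Cluster support is tested against a per-UMI background
probability with a one-sided binomial tail `P(X ≥ k | n = total UMIs,
p = background)`; the background defaults to a pooled control estimate with
a pseudo-count of 0.5 (or `0.5/total` when no controls exist).
Benjamini–Hochberg adjustment runs across all clusters of a sample and
significance is called at adjusted p ≤ 0.05.  The binomial null is this
package's construction — the source analyses name only the adjustment and
the cut-off — and its calibration is checked empirically: in 200
background-only simulations the proportion of runs with any significant
cluster stays below 0.05 plus three standard errors
(`analysis/04_deletion_null_calibration.py`).

Composition ratios use all UMI families (including `unclassified`) as the
denominator; the AAV fraction is integration UMIs over total UMIs.

## Synthetic libraries

The generator draws molecules i.i.d. from a configurable outcome mixture
and emits 150-bp paired-end reads.  What it emulates: per-base substitution
errors at a uniform rate `e` (default 0.001) with Phred emission
`Q = round(−10·log10 e)`; one UMI per molecule (default length 12) with
geometric family sizes (default mean 4) standing in for linear
pre-amplification followed by exponential PCR; fixed fragment ends for
amplicon libraries; and for UDiTaS a read 2 anchored at the locus primer
(carrying the UMI as its prefix) with a Tn5 end drawn uniformly once per
molecule — the fragment exists before amplification, so a family shares
it.  Event molecules are constructed by splicing: small indels of 1–49 bp
at the pegRNA nick, deletions spanning both nicks below 100 bp, large
deletions of 100–1,000 bp, locus–vector junction chimeras near the nick,
and optional false-priming molecules (primer followed directly by vector
sequence).  Deletion breakpoints stay clear of the capture-primer footprint,
since a molecule that loses its primer site is never sequenced.

Two percent of reads carry a single Q20 base so the quality filter has work
to do; the incidence is per read rather than per base because a 2% per-base
Q20 rate would put at least one sub-threshold base in essentially every
150-bp read and the minimum-quality rule would then discard the whole
library.  Low-quality incidence is independent of outcome category, so the
filter does not bias composition.

Scenario loci are generated random sequences carrying the designed edit
geometry (a 1-bp A→G correction with an AGG→AAG PAM change, an oncogenic
C→T, a 3-bp TCC codon deletion, the 32-bp resistance-allele deletion, a
47-bp reporter-restoring deletion, a 39-bp→18-bp replacement, 3-bp/6-bp
targeted edits, and a UDiTaS locus with 60-bp nick spacing and a 20-bp
primer footprint) — not real genomic sequence.  Scenario sequences derive
from fixed per-scenario seeds so loci are stable across runs; the run seed
drives molecule draws, amplification and errors, and identical (config,
seed) gives byte-identical FASTQ output (gzip mtime pinned to zero).

What the generator does **not** model: indel-type sequencing errors,
quality-correlated errors, PCR chimeras and index hopping, UMI errors
arising during amplification (UMI errors appear only via sequencing error
on the prefix), tagmentation sequence bias, and real-locus homology.
Passing the recovery benchmark therefore shows the pipeline's logic is
correct under calibrated noise, not that real libraries are free of the
artifacts the generator omits.

## Benchmark conditions and expectations

The headline check simulates each scenario at n = 10,000 molecules (chosen
from the 10,000–20,000 range as the point of maximal statistical honesty
for the category sizes involved) and requires every recovered category
fraction to sit within three binomial standard errors of the library's
realized truth-table fraction.  Amplicon truth mixtures mirror the
measured conditions they are named for (e.g. 6.7% precise / 2.7% indel for
the correction scenario; near-clonal 80% precise for tumor-derived
samples; 6% for the 32-bp deletion).  The UDiTaS mixture is an
editing-rich condition (80% wild type, 10% precise, 5% small indel, 2%
nick-to-nick, 2% large deletion, 1% AAV integration) that preserves the
qualitative ordering of the in vivo composition — precise edits dominate
among modified alleles, vector capture is rarest — while giving every
category enough counts to be recoverable at desk scale.

Two systematic effects are part of the design and accounted for in the
tests: exact-match calling demotes error-carrying wild-type reads to
`substitution_other` (amplicon mode; the two bins are compared jointly
against wild-type truth), and in UDiTaS mode quantification-window errors
on exemplars move roughly 0.3% of wild-type families into
`small_indel_sub` — visible, bounded, and documented rather than hidden by
error-tolerant matching.

## Known limitations

* No UMI error correction; family counts are slightly inflated at high
  error rates (documented above).
* The AAV caller reports presence of a junction per family, not the
  integrated fragment's structure or orientation.
* No inversion or translocation detection; the split caller only pairs
  collinear arms on one reference.
* Replacement edits are represented canonically as deletion-plus-insertion;
  the optimal alignment of a replacement read may legitimately scatter into
  smaller events, which is why precise calling compares haplotypes, not
  event lists, and why the installed-segment size of a replacement is
  reported from the canonical decomposition.
* Phred+33 only; no color-space or Phred+64 support.
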