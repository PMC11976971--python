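# Methods

## The measurement problem

A promoter cassette built from the human U1 snRNA promoter, a crRNA body
(direct repeat + spacer), the U1 3′ downstream region and the 3′ box
produces transcripts whose exact boundaries are not dictated by the
annotation alone: Integrator cleavage leaves templated downstream bases,
cytosolic TUT4/7 add non-templated uridines, transcription can initiate a
base or two away from the +1 site, and a fraction of molecules carry an m7G
cap. RACE libraries encode these features as read structure, and `racemap`
decodes them:

* a 3′ RACE read is `construct[anchor .. end] + tail + NNNN + adapter`,
  where the anchor is the gene-specific primer's 3′ end, `tail` is the
  non-templated suffix and the four N are the adapter's random 5′ bases;
* a 5′ RACE read is `TSO + G^k + construct[start ..]`, where k = 3 for
  uncapped and k = 4 for capped molecules (template switching copies the
  cap as an extra C in the cDNA, read out as G).

## Preprocessing

The chain is 3′ adapter removal → quality filter → random-nt removal → 5′
adapter removal, with adapter steps active only when the corresponding
adapter exists in the library architecture (a 3′ RACE read has no TSO
handle; a 5′ RACE insert has no ligated 3′ adapter — keeping "trimmed-only"
semantics for an absent adapter would discard the entire library).

Adapter matching is a semi-global scan with unit mismatch cost and no
indels: for the 3′ adapter, the rightmost full or 3′-partial occurrence
with mismatch rate ≤ `max_err` (default 0.1) over the matched span; for the
5′ adapter, the leftmost full occurrence, else the longest adapter suffix
at the read start. Partial matches are accepted down to 3 bases of overlap;
N counts as a mismatch. Reads without a hit are discarded, as are inserts
shorter than `min_len` (default 20 nt) after any trimming step. The quality
filter passes a read iff ≥ `p`% (default 95, boundary inclusive) of bases
have Phred ≥ `q` (default 30). The four random adapter nucleotides end up
at the insert's 3′ end after 3′-adapter removal and are cut last-4.

Indel-free matching is a deliberate simplification: the caller consumes
only the top-N abundant insert sequences, and indel-bearing reads are rare
enough to fall below that cut rather than distort it.

## End calling

Unique inserts are ranked by count (ties broken lexicographically, so
output order is deterministic) and the top N = 20 are analysed, each
weighted by its read count. Weighted and per-read computation give
identical summaries for the retained sequences, which a test asserts.

**3′.** The maximal templated prefix of the insert against the construct
from the anchor determines the end: `end_offset = anchor + prefix_len −
crrna_end` (offset 0 = last annotated crRNA base), the unmatched suffix is
the tail. Template wins ties: a tail base equal to the next template base
is counted as templated, which (i) makes the "ACT" downstream extension a
templated +3 end rather than an "other" tail, and (ii) places Pol III ends
after a templated poly-T terminator instead of mis-reading it as
uridylation. Tail classes: `none` (empty), `monoU`/`diU`/`oligoU` (all-T,
length 1/2/≥3), `other` (any non-T character). Templated matching is exact
(0 mismatches) by default — top-N collapsing suppresses error variants — and
a mismatch budget exists only for robustness studies; when enabled, a
templated prefix still never ends on a mismatch, so mismatched trailing
bases always fall into the tail.

**5′.** With r observed leading guanosines, the caller tries k = 0..r
non-templated leader Gs and accepts the smallest k whose remainder occurs
verbatim in the construct (maximal templated span; the remainder must be ≥
`min_anchor` = 15 nt, long enough to be unique in a construct-sized
reference). Hence on a +1 G construct a read showing four Gs is called
leader 3 + templated G, start offset 0. Cap class is a pure function of the
leader count — 3 → uncapped, 4 → capped, anything else → `other` — and the
capped fraction is `w(capped) / (w(capped) + w(uncapped))` with an exact
(Clopper–Pearson, via the beta quantile) 95% interval on the rounded
weights. `other` leaders are excluded from the fraction rather than
guessed.

Distributions are reported inside display windows (−5..+10 at the 3′ end,
−3..+3 at the 5′ end, matching the ranges worth plotting); out-of-window
and unassigned mass is pooled into `other`, so every table sums to 1.

## SNV screen

Rows of a ClinVar `variant_summary.txt`-dialect table are parsed, keeping
`Type == "single nucleotide variant"`, a pathogenic significance, and a
non-synonymous protein annotation. The pathogenic criterion defaults to the
string `Pathogenic` exactly; `wide` mode adds `Likely pathogenic` and the
combined class, so counts can be bracketed — the two modes bound the
defensible definitions. mRNA-sense G>A marks a REPAIR (A-to-I) candidate,
T>C a RESCUE (C-to-U) candidate; the classes are disjoint by construction.
For each candidate the transcript named in the HGVS expression provides the
flank: `mrna_pos = cds_start + c_pos − 1`, window ±`half_window` (30 nt)
clipped at transcript ends. A variant is AAAA-adjacent iff a run of ≥4 A
on the mRNA has at least one base within `adjacency_nt` of the variant: the
spacer covering such a region is the reverse complement and so carries ≥4
consecutive U — a Pol III terminator that truncates U6-driven guides.

No canonical adjacency window exists; 30 nt (one spacer length) is the
default and `screen_summary` sweeps 10/20/30/50 in one run so the choice is
visible rather than baked in. Only simple coding positions are mapped
(intronic `+/-` and UTR `*` HGVS are skipped and counted in the skip
report) — the amino-acid-changing filter already excludes non-coding
records. Duplicate (accession, c. change) pairs are deduplicated before
counting. Reported percentage = 100 × adjacent / targetable, one decimal.

## Synthetic data

The generator emits the two read architectures above plus variant cohorts,
with a TSV truth sidecar per output (one row per read/row). Defaults are
the study conditions: 3′ ends at {0: 0.10, +1: 0.05, +3: 0.70, +4: 0.10,
+5: 0.05} — modal +3, the "ACT" position, which on the demo construct lies
7 nt upstream of the 3′ box; tails {none 0.5, monoU 0.3, diU 0.2}; capped
fraction 0.5 with leader distributions a point mass at 3 (uncapped) and 4
(capped); variant cohorts with 50% pathogenic, 70% amino-acid-changing,
G>A 25% / T>C 15% (G>A being the most common pathogenic transition class),
and an AAAA run planted near 17% of targetable variants.

Reads are single-end, RNA-sense, fixed length 150 nt (truncating): end
calling only needs the end-proximal sequence, so paired-end merging adds
nothing at these insert sizes. Qualities are flat Q37, Phred+33,
configurable but unmodelled. Errors are uniform per-base substitutions
only — no indels, no quality correlation, no PCR duplicates, no
ligation/RT sequence bias. Identical config + seed reproduces byte-identical
FASTQ, GenBank and truth files (categorical draws iterate keys in sorted
order; the GenBank date field is pinned).

Two generator-design constraints keep truth labels exact rather than
merely probable. First, the default 3′ offset set omits +2 because the demo
construct's base at +2 is T: a drawn U tail there would be re-templated by
the longest-match rule and the truth sidecar would disagree with the only
defensible call. Second, variant transcripts are scrubbed of all A-runs ≥4
before an AAAA is explicitly planted (flanked by non-A so it cannot
extend), making `aaaa_adjacent` a planted label, not a statistical one.
These constraints are what "exact oracle equivalence at zero error" means:
the simulation avoids the genuinely ambiguous configurations, so passing
tests certify the calling rules, not the resolution of ambiguity. Real
libraries do contain ambiguous reads (a uridine added right before a
templated T is physically indistinguishable from a longer templated end);
the caller resolves them by the longest-match convention, and no test can
certify that biology.

What passing tests show, therefore: the trimming dialect is internally
consistent, the caller inverts the generator exactly at zero error, drawn
proportions are recovered within binomial error, and the screen's counting
logic is exact. What they do not show: robustness to indels, adapter
chimeras, paired-end disagreement, isoform ambiguity in transcript lookup,
or HGVS dialects beyond simple coding SNVs.

## Problem sizes and numerics

Test and demonstration runs use 2,000 reads per library for exact-recovery
checks, 5,000 for proportion recovery (3σ binomial bounds; total-variation
distance vs the configured distribution < 0.05), and 1,000-record variant
cohorts — sizes at which binomial noise is far below the effects measured.
Probability maps must sum to 1 within 1e-9; emitted distributions sum to 1
by construction. Clopper–Pearson bounds use the beta-quantile form with the
conventional endpoint conventions at k = 0 and k = n.

## Limitations

* Trimming is a defined dialect, not a re-implementation of any published
  trimmer's full option surface; adapters are configuration, never
  hard-coded.
* One transcript per variant (the accession in the HGVS name); no
  cross-isoform expansion, no genome-coordinate input, no liftover.
* Cap inference is indirect (leader G count); chemically validating the cap
  requires an orthogonal assay and is out of scope.
* The screen counts candidates; it does not design guides or score editing
  efficiency.
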