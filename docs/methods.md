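# Methods

## Scope and model

`seedshift` annotates the effect of somatic 3′UTR substitutions on putative
miRNA target sites defined by perfect Watson–Crick complementarity to the
miRNA seed region. Six seed classes are used (miRNA bases 1–8, 1–7, 2–8,
1–6, 2–7, 3–8, named m8/m7a/m7b/m6a/m6b/m6c), reflecting the observation
from CLIP-style experiments that many functional sites carry only 6-nt
matches even though 7/8-nt matches are more specific. The model is
deliberately minimal: no G:U wobble pairs, no 3′-compensatory pairing, no
site accessibility or thermodynamics, and no quantitative repression
prediction. TargetScan context+ scores enter only as an externally computed
input table; this package never computes them.

## Coordinate and strand conventions

External coordinates are 1-based inclusive on the plus strand (HGVS `g.`
notation, e.g. `chr4:g.96075969G>T`); chromosome names are normalised to
lower-case with a `chr` prefix. Internally, UTR offsets are 0-based
half-open on the **transcript strand**: readers never reverse-complement
silently, and the minus-strand mapping (offset reflection plus allele
reverse-complementation) happens in exactly one place
(`mutate.map_to_utr`). A mutation belongs to a UTR only if *every* mutated
base is contained in the UTR interval — containment, not overlap, which is
the unambiguous reading for multi-nucleotide substitutions. Length-changing
variants are parsed and flagged but excluded from all substitution
analyses; every analysis in scope concerns substitutions.

## Scanner semantics

At one anchor offset, the maximal match is the longest class whose motif
occurs there; among equal lengths the classes anchored on miRNA bases 2–8
take priority (m8 > m7b > m7a > m6b > m6a > m6c) — the seed proper
(bases 2–8) carries most of the pairing specificity, and no published
tie-break exists for this labelling, so the package fixes one. A reported
match additionally must not be interval-contained in another reported match
of the same miRNA: an m8 site necessarily contains nested m7a/m6a/…
occurrences at shifted anchors, and reporting them separately would
triple-count a single site. Overlapping but non-nested matches at different
offsets are all reported. `N` and lower-case (masked) bases never match.

A second, deliberately naive scanner (`bruteforce.py`) enumerates all six
motifs at all offsets by character comparison and applies the same
per-anchor maximality and containment rules. It is the validation oracle:
the test suite asserts exact agreement with the production scanner over
seeded random sequence/miRNA-set trials, and the synthetic-data generator
verifies every planted label against it.

## Classification semantics

For each mutation × miRNA, matches overlapping the mutated span are
collected from the reference and mutant sequences. Because a substitution
can extend or truncate a site by one end, the partner site need not itself
contain the mutated base (mutating the last base of an m8 site leaves an
intact m7b one base shorter; extending a 6-mer into a 7-mer mutates a base
*adjacent* to the reference site). Candidates therefore also include
matches from the other sequence that overlap a span-overlapping match.
Reference and mutant candidates are paired one-to-one by maximal site
interval overlap (ties: leftmost, with a role-symmetric sort key);
unpaired reference matches in the span are disrupted, unpaired mutant
matches created, and pairs with different maximal classes modified. A pair
with the same class (possibly at a shifted anchor) is a surviving site and
emits no event. The rule is symmetric under swapping the alleles, which
exchanges created↔disrupted and reverses every modified transition — an
invariant asserted exactly in the tests.

miRNAs with identical seeds are **not** collapsed into families: hits are
reported per mature miRNA, matching how selected events are presented in
this literature. When a mutation is contained in several transcripts, it is
processed once per distinct (gene, UTR sequence), avoiding double-counting
identical isoforms while still reporting genuinely different UTRs.

## Pattern statistics

Substitutions are collapsed into six reverse-complement-equivalent classes
(`G>A/C>T` etc.); class assignment is invariant under simultaneous
complementation of both alleles. Relative position along the UTR is the
transcript-strand offset of the first changed base divided by UTR length,
so position 0 is the base after the final coding exon on either strand. The
positional distribution uses rolling windows of width 5% of UTR length;
the step is 1% (centers 2.5%–97.5%), a disclosed choice — only the width is
fixed by the study design — and `step == width` degenerates to a plain
histogram. Mutations contained in UTRs of two or more genes with
non-identical UTR sequences are removed from the positional analysis only.
Recurrence is site-level: an exact (chrom, pos, ref, alt) tuple seen in ≥ 2
distinct samples; percentages are rounded half-up to two decimals, which
reproduces the printed 0.66% (1/152) and 0.41% (116/28,626).

## Prioritization

The cascade keeps an event iff |Δcontext+| > 0.2 (strict: a change of
exactly 0.2 is dropped), miRNA total reads ≥ 100 (strict complement of
"fewer than 100"), and the configured annotation requirements hold. Events
without a score row, and miRNAs absent from the expression table, are
dropped with logged counts. The filters are pure intersections, so their
order cannot change the final set. Concordance marks the biologically
interpretable direction: an overexpressed gene losing a site (weakened
repression) or an underexpressed gene gaining one. For modified events the
direction is ranked by site length (8 > 7 > 6); equal-length class changes
are neutral. The disrupted:created ratio excludes modified events and is
undefined (flagged, not divided) when nothing was created.

## LD integration

A hit requires three independently checkable predicates on one altered
site: a germline SNP inside the site span (inclusive), a marker within
100 kb of the span on the same chromosome (distance 0 inside the span),
and an LD block containing both the full span and the marker. For modified
events the site span is the union of the reference and mutant spans; for
created/disrupted events it is the span of whichever sequence contains the
site. Blocks and marker–SNP R² values are inputs from external haplotype
tools; block rows with end < start are rejected with a warning rather than
reinterpreted, and hits whose SNP has no R² entry carry a missing flag.
One germline SNP can legitimately produce several hits when overlapping
sites of different miRNAs share it — single sites targeted by multiple
miRNAs occur in the real data.

## Synthetic data

The generator defines the standard study conditions used by the test suite
and the acceptance script:

* **150 planted events** (50 created, 50 disrupted, 50 modified with
  transitions cycling through m6b→m7b, m7b→m6b, m6c→m7b, m8→m7b, m7b→m8,
  m7a→m6a), one mutation per UTR so labels are isolated;
* **UTR lengths 150–1500 nt, GC 0.40** — human 3′UTRs are AT-rich and
  median lengths are high hundreds of nt;
* **20 miRNAs** with pairwise-distinct 8-base seeds;
* per-cancer substitution mixtures qualitatively matching the known
  etiologies (UV-dominated melanoma → G>A/C>T-heavy; tobacco-associated
  lung/SCLC → G>T/C>A-heavy; prostate flatter);
* an LD scenario with 3 positives (SNP in site, marker < 100 kb, block
  containing both) and 3 negatives that each violate exactly one predicate;
* sidecar score/expression/annotation tables that exercise both sides of
  every filter boundary, including the exact boundary values (|Δ| = 0.2,
  reads = 99/100).

Planting embeds the target motif, then searches single-base substitutions
in a small window until the classification semantics — driven by the
brute-force scanner — yield exactly the intended event; accidental extra
matches trigger a redraw of the background. Created events are planted as
the allele swap of a disruption. Background sequence is i.i.d.; the
generator does **not** emulate conservation, trinucleotide mutational
signatures, UTR secondary structure, isoform complexity, or realistic LD
structure, so passing tests demonstrate the correctness of the pipeline's
logic under known truth, not the biological accuracy of seed-match
prediction on real genomes. All outputs are byte-identical for a fixed
seed.

## Numerical choices and degenerate inputs

Percentages and ratios round half-up to two decimals (Decimal arithmetic on
exact rationals, so 1/152 → 0.66, not 0.65). Empty mutation sets yield a
flagged empty spectrum and an undefined recurrence percentage rather than
NaNs. Reference-allele mismatches against the stored UTR sequence are hard
errors per site but skip-and-continue at pipeline scale, with every skip
recorded. Overlapping LD blocks resolve to the smallest containing block,
logged. The pipeline validates all input paths before writing anything, and
stage failures abort with a stage-named error.

## Problem sizes

The default test-suite and acceptance workloads — 150 planted events over
~120 kb of simulated UTR sequence, 20 miRNAs, 1,000 scanner-oracle trials,
200 strand round-trip cases — run in well under a minute and were chosen as
the smallest sizes at which every claimed property (exact truth recovery,
exact symmetry, exact oracle agreement) is exercised across all six seed
classes, both strands, and all filter boundaries.

## Known limitations

Perfect seed complementarity over-calls functional sites and misses
non-canonical ones; the package inherits both biases by design. Context+
deltas are consumed, so the "top 15%" calibration of the 0.2 threshold
cannot be revisited here. Indel effects on sites are out of scope.
Annotation lists (cancer genes/miRNAs) are flat inputs with no curation
logic. Liftover between assemblies is out of scope: all inputs must share
one assembly.
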