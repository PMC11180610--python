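# Methods

This note documents the models and procedures implemented in `crisprtox`,
the defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that affect results.

## Amplicon outcome classification

### Alignment

Reads are aligned to the amplicon reference with `Bio.Align.PairwiseAligner`
in global mode: match +5, mismatch −4, gap open −20, gap extend −1, and free
end-gaps on the reference so that pre-trimmed reads shorter than the
amplicon align without penalty. The long gap-open penalty with a cheap
extension tolerates the long deletions that nuclease editing produces, in
the style of amplicon-editing aligners. Read orientation is auto-detected by
aligning both strands and keeping the higher score. Reads under 100 nt are
dropped up front (inputs are assumed adapter- and quality-trimmed); reads
whose best alignment identity falls below 60 % are counted as unalignable
and excluded from the denominator of all class fractions.

Alignments are reduced to an event list (substitutions, deletions,
insertions) and indels are left-normalized. Because an indel inside a repeat
has several placements that produce the same read, all window-overlap
decisions use the *union* of equivalent placements
(`deletion_placement_range`, `insertion_position_range`). This makes
classification independent of the reported placement and exactly symmetric
under reverse-complementing the reference and flipping the protospacer
strand — a property the test suite checks.

### Coordinates and spec defaults

Internally coordinates are 0-based half-open; protospacer positions are
reported 1-based from the PAM-distal end, the editing-literature convention.
Defaults on `AmpliconSpec`:

| parameter | default | rationale |
| --- | --- | --- |
| `cut_offset` | 17 | blunt SpCas9 cut / nCas9 nick between protospacer positions 17 and 18, 3 nt 5′ of the PAM |
| `editing_window` | (4, 8) | the canonical CBE/ABE activity window; exposed because deaminase variants differ |
| `indel_window_halfwidth` | 1 nt | a 1-bp quantification window around the cut; configurable because CBE-induced deletions extend between the deaminase target sites and the nick, and a wider window is appropriate when quantifying them |
| `substitution_region_flank` | 10 nt | substitutions farther than protospacer ± 10 nt are overwhelmingly sequencing noise and are reverted during allele normalization; indels are never reverted |

Normalization (reverting out-of-region mismatches and re-merging identical
alleles) is idempotent.

### Class taxonomies

BE/nuclease mode classifies each normalized allele with precedence

1. `indel` — any indel overlapping the quantification window;
2. `other_SNV` — any retained substitution that is not the programmed
   conversion at an editing-window position;
3. `expected_edit` — at least one programmed conversion;
4. `WT`.

The precedence makes the stacked fractions exclusive and counts an allele
carrying both an indel and a transition as a double-strand-break repair
product — the conservative choice for a genotoxicity readout. Prime-editing
mode: `precise_PE` iff the allele equals the reference with exactly the
intended edit; `imprecise_PE` iff the intended edit is present together with
scaffold incorporation at the pegRNA nick or another indel at either nick;
`other` for all remaining non-reference alleles. Scaffold incorporation
requires a ≥3-nt match to the scaffold prefix: "the first bases" of the
scaffold is not a fixed length, and 3 nt avoids spurious 1-nt matches.

Deletion profiles report each deletion's center (midpoint of the deleted
interval) binned per nucleotide, and per-reference-position deletion
coverage as a fraction of indel-bearing reads.

## Clonal tracking

Barcodes are the fixed-length segment between two 12-nt anchors, each
matched with at most one mismatch; reads shorter than 50 nt or missing an
anchor are discarded and counted. Error correction builds a graph with edges
between barcodes at Levenshtein distance ≤ 2 (edlib; Hamming available) and
collapses each connected component onto its highest-count member, ties going
to the lexicographically smallest for determinism; a count-ratio directional
merge (a neighbor is absorbed only by a barcode with ≥ 2× its count) is
available behind `method="directional"` for libraries whose true barcodes
may sit within the edit-distance radius. The minimum-count filter
(default 2) is applied **after** correction so satellite reads can rescue a
parent barcode observed once — the ordering is an assumption, made because
correction-then-filter conserves more true clones. Correction never
increases the number of unique barcodes, conserves read counts up to the
final filter, and is idempotent.

Clone counts divide unique barcodes by the sample's vector copy number
(a clone carrying v integrations contributes v barcodes). Repopulating-cell
frequency divides the transplanted culture-initiating (d₀-equivalent) cell
number by the unique barcodes engrafted long-term in bone marrow. Lineage
sharing uses the Jaccard index and the fraction of stem/progenitor barcodes
found in 0–k mature lineages.

## Variant landscape

Hard filters remove records with QD < 2.0, site depth < 500, GQ < 80 or
per-sample depth below a tier threshold — 50 for bulk in-vitro samples, 10
for sorted in-vivo fractions, which are sequenced much shallower. Removals
are strict inequalities, so a value exactly at a threshold is retained.
Records missing a required field fail closed (removed, with a logged count).
Variant identity is (chrom, pos, ref, alt); genotype/phase is ignored.

Germline subtraction removes every variant present in the
mock-electroporated reference sample; it is idempotent and its output is
disjoint from the reference by construction. `treatment_associated_set`
supports two semantics: `reference` (default) subtracts the union of mock
variants from each condition's union; `shared` additionally subtracts
variants recurring in ≥1 sample of *every* condition, treating
cross-condition recurrence as missed germline. Both are provided because
the set semantics of recurrence-based subtraction are genuinely ambiguous;
neither is asserted as the only correct reading.

Multiallelic sites (more than one alt at a position, or >2 distinct alts
across companion samples) are removed before spectra are computed. SNVs are
collapsed by strand into six classes (pyrimidine-reference convention);
class assignment is invariant under complementing both alleles, a property
tested over all 12 ordered SNVs. Spectrum proportions are over SNVs only and
are reported empty when there are none.

The colony-pool filter first removes records with coverage < 10, then keeps
VAF within [0.05, 0.2] inclusive, and reports the expected VAF of a variant
private to one of n equally represented diploid colonies, 1/(2n) — 1/12 ≈
0.083 for the six-colony pools the assay is designed around. The RNA
consensus filter keeps variants called by **all** callers after removing
anything called in the untreated control, and requires quality-filtered
coverage ≥ 20 in both samples with an untreated reference-base fraction
≥ 0.99; pileups are assumed restricted to bases with quality ≥ 30.

## Structural lesions

ddPCR copy number is the plain droplet ratio
`(target⁺ / normalizer⁺) × 2`, exactly as the assay reports it; a
Poisson-corrected variant (−ln(1 − k/n) occupancy transform) exists behind a
flag but is never the default, so the implemented statistic matches the
printed formula. The normalizer is a two-copy reference gene.

Allele-loss calling derives a mean ± k·s.d. interval (sample s.d., n−1) from
mock colonies; k = 3 guarantees coverage of at least 1 − 1/k² = 8/9 ≈ 89 %
of mock observations for any distribution shape (Chebyshev). Colonies below
the lower limit are called `monoallelic`, and below 0.5 copies `biallelic` —
0.5 is midway between one retained copy and zero and is exposed as a
parameter since the underlying assay distinguishes the two regimes without
a published cutoff. Calls are monotone in the copy number. Group enrichment
of below-limit colonies uses the two-tailed minimum-likelihood Fisher's
exact test (the sum of probabilities of all fixed-margin tables no more
likely than the observed one — stated explicitly because two-tailed Fisher
has competing definitions) with Benjamini–Hochberg adjustment across
pairwise comparisons.

Junction enumeration covers the four reciprocal fusions between two loci cut
on different chromosomes: two balanced junctions (A-left+B-right,
B-left+A-right) and two inverted ones (A-left+B-left, A-right+B-right),
each assigned the amplifying pair from the 2×2 primer matrix and a predicted
breakpoint window — a point at the cut for nucleases, the span from the
deaminase target sites to the nick for CBEs, whose translocations are more
heterogeneous. Intra-chromosomal pairs are rejected (deletion junctions are
a different assay). A string-search in-silico PCR helper validates that a
synthetic fusion is amplified by its expected primer pair only.

## Response scores

Fold change = (target/HPRT) in the sample divided by (target/HPRT) in the
untreated baseline; multiple baseline replicates are combined by geometric
mean, the natural average for ratio data. The formula is abundance-agnostic
(ddPCR copies/µl or normalized counts both work). The IFN score is the sum
of the IRF7, OAS1 and DDX58 fold changes, so the untreated reference scores
3.

## Synthetic data: what it emulates, and what it does not

All generators draw from `numpy.random.default_rng((seed, stream))`; a fixed
seed gives byte-identical outputs, and every emitted read/variant/droplet is
attributable to exactly one truth record.

* **Amplicon reads** apply one sampled outcome per read: programmed
  conversions at a random non-empty subset of editable window positions;
  bystander substitutions at non-window protospacer positions; deletions
  with geometric lengths (mean 4 nt, truncated at 30 — positions are
  modeled on the observed profiles, lengths are a modeling choice) centered
  Normal(cut, 2 nt) for nuclease targets and Uniform(deaminase sites, nick)
  for CBE targets; scaffold-prefix insertions (≥3 nt) at the pegRNA nick or
  deletions at either nick for imprecise prime editing. I.i.d. per-base
  substitution errors (default 0.1 %) are added on top. Not emulated:
  quality-dependent or indel sequencing errors, PCR chimeras, paired-end
  structure.
* **Barcode reads** embed an anchor–barcode–anchor cassette in 15-nt vector
  context; truth barcodes (18 nt, defaults chosen for unambiguous
  extraction at ≤1 %/base error) are sampled pairwise >2 edits apart so
  truth clones are unambiguous; abundances are log-normal (σ = 1) split
  across lineages.
* **Variant tables** share one germline set across all samples and add
  treatment-private SNVs from the configured spectrum; colony-pool mode
  plants one heterozygous variant per colony with VAF ~
  Binomial(depth, 1/(2n))/depth. Quality fields of passing variants are
  drawn inside all thresholds (QD ∈ [5, 35], GQ ∈ [90, 99], per-sample DP ∈
  [400, 800], site DP ∈ [600, 1200] — site depth must clear the 500 cutoff,
  so it is drawn above it); a configurable fraction of failing variants is
  drawn just below one threshold each, cycling through the four filters so
  tests exercise both sides of every boundary.
* **Droplet counts** are binomial: the normalizer occupies a droplet with
  probability 0.05 (a typical partitioning for 5–50 ng input) and the
  target with that probability scaled by copies/2; the plain ratio formula
  is unbiased in expectation in this regime, and a saturation warning fires
  when copies exceed 2/p.

Because sequencing errors inside the quantification window are
indistinguishable from real edits by design, the mixture-recovery
property (configured class proportions recovered within 3 binomial standard
errors at n = 10,000 reads) is checked on error-free reads and with the
indel window widened to span the simulated deletion spread; with errors
enabled the recovered `other_SNV` fraction is biased upward by roughly the
per-read error probability inside the substitution region, exactly as in
the real assay. Passing these tests shows the decision logic and set
algebra are correct on data matching the stated models; it does not certify
performance on real sequencing artifacts (context-dependent errors, PCR
jackpots, mapping ambiguity), which are out of scope.

## Problem sizes used in tests and the acceptance script

Mixture recovery uses 10,000 reads on a 200-nt amplicon; barcode recovery
40 clones / 4,000 reads (≤500 raw barcodes, within reach of the exhaustive
pairwise oracle); variant recovery 1,000 planted private variants; loss
calling 30 mock + 300 test colonies at 20,000 droplets; Fisher agreement is
enumerated exactly for table totals ≤ 40. These sizes give the property
tests 3-s.e. resolution of about 1–1.5 percentage points while keeping the
whole suite in seconds.
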