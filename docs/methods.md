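# Methods

## K-mer feature databases

The database is an exact map from canonical k-mers to features. k is odd
and at most 31, so a k-mer packs into one 64-bit code (2 bits per base,
first base most significant, which makes integer order equal lexicographic
order); odd k rules out reverse-complement palindromes, so the canonical
form (minimum of the k-mer and its reverse complement) is unique.
Membership is a binary search over a sorted key array with parallel payload
and strand arrays; the file format is a magic string, a format version, a
JSON feature-table header, and the three arrays, so serialization is
deterministic and round-trips byte-identically.

Feature attribution works per window: a k-mer window that overlaps an
annotated interval belongs to that interval's feature. Windows that overlap
intervals of more than one class at a locus (e.g. straddling a
telomere/arm boundary) resolve by the precedence telomere > centromere >
arm; the residual tie — one window overlapping two adjacent *arm*
intervals — resolves to the lower feature id. This situation cannot arise
in the bundled simulator (arms are always separated by a centromere or
telomere) but the rule keeps attribution total and deterministic for
arbitrary BED input. A k-mer *sequence* resolved to two or more distinct
features anywhere in the genome is stored as ambiguous. K-mers from
unannotated regions are excluded (they will read back as novel), with a
logged warning giving the uncovered fraction. Strand tags are FWD/REV when
all reference occurrences of a canonical key share one orientation and
MIXED otherwise; telomere keys are typically MIXED because the 5' telomere
is the reverse complement of the 3' array.

## Karyogram construction

Annotation emits one call per window: a feature id, ambiguous, novel, or
gap (any window containing a non-ACGT base). Pixels of `pixel_bp` bases
(default 250 000) take the modal call of the windows starting inside them;
exact count ties resolve by telomere > centromere > arm (lowest id) >
ambiguous > novel > gap, preferring informative labels. Chromosome
assignment counts only arm calls — telomere and centromere calls are
global and carry no chromosome identity — and the contig is unplaced when
the winning chromosome holds less than `min_fraction` (default 0.5) of its
arm calls. Orientation uses strand votes (accumulated only from
unambiguous feature calls with non-MIXED stored strand) and falls back to
the positional concordance of p → centromere → q calls, then to "+".
Ordering sorts by (chromosome index, mean expected rank with p = 1,
cen = 2, q = 3, descending length); telomere calls are excluded from the
rank mean because a telomere call cannot be attributed to the p or q end.
Unplaced contigs sort last by descending length.

Rendering is a pure function of the tracks, placements, and options:
sequences shorter than `min_draw_bp` (default 1 Mbp) are placed and
classified but not drawn, runs of same-colored pixels merge into single
SVG rectangles, and reverse-oriented contigs are drawn flipped.

## Completeness classification

A terminal window of `min(10 kbp, 5% of contig length)` calls defines the
flanks: a terminus is telomeric (centromeric) when at least `tel_frac`
(`cen_frac`, both default 0.5) of its non-gap calls are telomere
(centromere) calls. The cascade, first match wins:

1. **complete chromosome** — both termini telomeric;
2. **complete arm** — exactly one terminus telomeric, and either the
   opposite flank centromeric or the contig spans p–cen–q (arm calls from
   both arms plus at least `cen_min_bp` = 50 kbp of centromere calls);
3. **centromere** — centromere fraction ≥ `cen_pure_frac` = 0.9;
4. **partial arm** — arm-specific (assignment fraction ≥ 0.5) with exactly
   one telomeric-or-centromeric flank;
5. **marker** — everything else, in particular arm-specific sequence with
   no flanks.

All thresholds are configurable (`ClassifyParams`); the defaults were
chosen once to match the scale of the bundled simulator (12 kbp telomere
arrays, ~68 kbp centromere arrays, 45–55 kbp arms) and human-like real
data alike. Gap calls are neutral: excluded from every denominator, so
scaffold N-runs do not break classification. A contig matching no rule
(e.g. entirely novel sequence) falls through to marker rather than
erroring; only an empty track raises. The boundary between "centromere"
and "partial arm" for fragments mixing centromeric and arm sequence is
governed by `cen_pure_frac`, a deliberate design choice where no crisper
definition exists.

## Contiguity statistics

Lengths are sorted descending and cumulatively summed; `NG(x)` is the
length at the first index where the cumulative sum reaches `x%` of the
expected genome size G, and `LG(x)` is that index + 1. When the total
assembly length falls short of `x%` of G the value is undefined and
reported as (0, 0, defined=False) rather than extrapolated.
`auN = Σ L_i² / Σ L_i` is the closed form of the area under the Nx step
curve (each sequence contributes a step of width `100·L_i/ΣL` and height
`L_i`) and never depends on G. Tests verify the closed-form scan against a
direct-definition oracle that tries every candidate length, and auN
against explicit step integration.

## Read-pair phasing

Only primary alignments contribute; secondary and supplementary records
are skipped to avoid double counting. An aligned record lacking an AS tag
is treated as unaligned (logged), which conservatively pushes the pair
toward the not-properly-mapped group. The five-group cascade is evaluated
in order: (1) not proper on both haplotypes; (2) any mate reference in the
sex-chromosome set, checked on all available alignments of both
haplotypes; (3) proper on exactly one haplotype → that haplotype;
(4) equal summed AS → homozygous; (5) higher summed AS wins. The groups
are therefore mutually exclusive and exhaustive by construction, and
swapping the two haplotype streams exchanges the hap1/hap2 counts while
fixing the other three groups.

MAPQ phasing requires both mates on the same haplotype with MAPQ ≥ 10
(default); ties, low MAPQ, unmapped mates, and haplotype-split pairs are
unphased. Reference names attribute to haplotypes through a configurable
prefix convention (default `hap1_`/`hap2_`).

The distribution diagnostic restricts to pairs assigned hap1/hap2 with a
summed AS on both haplotypes — pairs proper on only one haplotype have no
discordant score — so the concordant and discordant samples are
equal-sized and paired. The exponential fit is the two-parameter MLE
(location = sample minimum, scale = mean − minimum). The KS statistic is
the exact supremum ECDF gap over the merged sample points; the p-value
uses the asymptotic Kolmogorov survival function at `√(n₁n₂/(n₁+n₂))·D`.
Exact small-sample p-values are not computed; at the sample sizes where
the diagnostic is meaningful the asymptotic form is adequate.

## The simulator, and what passing tests do not show

The toy genome is telomere – p arm – centromere – q arm – telomere per
chromosome: telomere arrays of 2 000 × TTAGGG (12 kbp, reverse-complemented
at the 5' end as on a real forward strand), a 171 bp centromere monomer
shared across chromosomes and tiled 400 times with 2% per-copy mutation
(~68 kbp arrays that differ between chromosomes yet share the single
global centromere feature), and uniform-random arms of 45–55 kbp that are
verified k-mer-disjoint across chromosomes at build time. Optional
segmental duplications copy an arm segment into another arm to exercise
ambiguity; optional acrocentric chromosomes shrink the p arm. All
generation is a pure function of the spec and seed.

Derived assemblies are defined by an event log (splits, telomere drops,
extractions, reverse complements, fusions), and each single-source
contig's completeness category is recomputed from its source coordinates
with a 500 bp margin — truth by construction, independent of the k-mer
classifier it tests. Fusion contigs have no defined category (truth None)
and serve the assignment tests instead. Diploids add substitution-only
heterozygous SNVs uniformly on the arms (indels would shift coordinates
and change the alignment-score arithmetic); read pairs sample a uniform
haplotype and position, and the scorer assigns each mate
`AS = matches − 4·mismatches` at its true locus, with a pair "proper" on a
haplotype when both mates score at least half the maximum.

This emulates what the methods need and nothing more. Real data differ in
ways the simulator does not model: repeat families beyond a single
satellite, sequence-composition bias, indels and structural variants,
mapping ambiguity resolved by a real aligner (the scorer evaluates reads
at their true locus, so mismapping never occurs), base-quality-dependent
error profiles, and chromosome-scale heterogeneity of heterozygosity.
Passing the truth-recovery suites therefore demonstrates that the decision
rules are implemented exactly, not that their thresholds are optimal for
any particular organism or dataset.

## Problem sizes and numerical choices

The bundled suites use 2–5 chromosomes (~0.2 Mbp each) for unit tests,
24 chromosomes (~4.2 Mbp) for the feature-count check, 10 000 read pairs
for the phasing run, 300–1 000 random length multisets for the contiguity
oracles, and samples up to ~800 for the KS oracle — sizes chosen so the
whole suite runs in well under a minute per module while every category
and group is instantiated many times. Oracle agreement is required exactly
for the integer statistics, to 10⁻⁹ relative for auN, and to 10⁻¹² for
the KS statistic. All randomness flows from explicit integer seeds;
reruns are byte-identical.
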