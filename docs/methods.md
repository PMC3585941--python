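# Methods

This note documents the models, parameter choices and known limitations
of each pipeline stage, and what the synthetic study does and does not
establish about real data.

## Read cleaning and tag collapsing

Reads are Phred+33 FASTQ.  A read is discarded whole if any base has
Q < 20 (the "low quality" filter; the threshold is a declared default —
sequencing-era pipelines rarely published theirs).  The 3' adapter is
located by an exact search for its first 8 nt anywhere in the read;
adapter-free reads are kept only when already inside the 18–30 nt
window.  Exact-match trimming is adequate for error-free synthetic reads
and deterministic; it would under-trim real reads with adapter
sequencing errors.  Inserts containing N are discarded as ambiguous.
Surviving inserts are normalized to the RNA alphabet (T→U) — the
internal alphabet everywhere — and collapsed into a `TagTable` of unique
sequences with one count per library.  By construction a tag's counts
expand back to the clean-read multiset, and column sums equal clean
totals.

## Genome mapping and the annotation cascade

Mapping is exact (the category cascade and known-miRNA identification
are defined by perfect matching) via a hash index over 18-nt seeds with
full-length verification on both strands.  Tags with more than 20 loci
keep their hit count but only the first 20 hits.  Each multi-hit tag is
judged once, at its representative hit — the lexicographically first
(chromosome, start, strand) — a deterministic tie-break that avoids
double counting.

The cascade assigns exactly one category per tag, in priority order
rRNA > scRNA > snoRNA > snRNA > tRNA > repeat > exon > intron >
known-miRNA > siRNA, with `no_annotation` for everything left, including
unmapped tags (this is what lets the category rows sum to 100% while the
genome-match roll-up sits near 90%).  The order is configurable because
published pipelines state the removal order only in prose.  Exon and
intron split into sense/antisense by strand agreement between the hit
and the feature.  The siRNA category is operational: a mapped,
otherwise-unannotated 21–24 nt tag whose representative locus overlaps
an opposite-strand tag locus (a double-stranded arrangement).
Percentages are computed half-up to two decimals; against the published
per-category counts this arithmetic reproduces every printed percentage
exactly, and the printed leaf categories partition the printed clean
totals exactly.

## Known-miRNA profiling

A miRNA is detected in a library iff its mature sequence was sequenced
there (exact match only).  Mature entries with identical sequences are
collapsed to one family identifier, so a read is never credited twice;
whether the original study family-collapsed its deep-sequencing counts
is unstated, and collapsing identical sequences is the conservative
reading.  Reads placing anywhere on a precursor (exact substring) build
its stack; isomiRs are stack entries whose 5'/3' ends lie within ±2 nt
of the annotated mature ends.  The star arm is inferred from the folded
precursor assuming the canonical Dicer geometry (2-nt 3' overhangs):
star span = partner(mature 3' end − 2) … partner(mature 5' end) + 2,
scanning to the nearest paired position when an end is unpaired.

## Folding engine

The bundled engine minimizes a simple additive pair-energy model —
GC −3.0, AU −2.0, GU −1.0 kcal/mol, minimum hairpin loop 3 nt, no
pseudoknots — by Nussinov-style dynamic programming with deterministic
tie-breaks, returning a dot-bracket structure and its energy.  The model
is intentionally minimal and fully specified: every MFE the predictor
uses is reproducible to the digit, and the test suite pins the DP
against exhaustive enumeration of all nested structures for n ≤ 14.
The −18 kcal/mol precursor threshold applies to whichever engine is
active (the fold function is pluggable; a nearest-neighbor engine such
as RNAfold can be substituted), but all shipped results use the bundled
model.  Note that under this model the MFE is *not* invariant under
reverse complementation: GU wobble pairs map to non-pairing A–C under
revcomp, so no such symmetry is asserted anywhere.

## Novel-miRNA prediction

Unannotated (and siRNA-class) mapped tags are clustered into same-strand
loci with a 300 nt merge distance; the most abundant tag is the mature
candidate (ties to the 5'-most).  Cheap predicates run before any
folding — total reads ≥ 5, exactly one genomic locus, no opposite-strand
stack over the locus ± flank, and a Dicer-consistency check requiring
≥ 50% of locus reads to share the mature 5' end (the declared stand-in
for "Dicer cleavage sites").  These filters commute with the duplex
criteria (the call condition is their conjunction), so evaluating them
first changes nothing but runtime.

Surviving loci are excised in six windows — spans 60/150/300 nt on
either side of the mature, plus 20 nt flanks — folded, and evaluated:
mature length 18–25 nt, MFE ≤ −18 kcal/mol, ≥ 16 mature/star base pairs,
bulge (longest unpaired run on either duplex strand) ≤ 4 nt, asymmetry
(|unpaired on mature − unpaired on star| within the duplex) ≤ 4 nt,
mature–star spacing ≤ 300 nt.  Bulge and asymmetry are declared
operationalizations of the MIREAP terms.  Among passing windows the one
with the *most duplex pairs* wins (ties to lower MFE): a random flanking
window can, with appreciable probability, present an incidental
16–17-pair duplex for a given 21-mer, whereas the genuine hairpin
presents 18–20, so the max-pairs rule selects the true arm.  Passing
candidates overlapping a repeat annotation are rejected.  Star support
is flagged when a read maps inside the structural star span padded by
6 nt — the MFE structure leaves mismatch-adjacent duplex ends unpaired,
so a genuine star read may begin a few nt outside the strictly paired
span.

Exact reproduction of the original 60 novel calls is not attempted: the
original folding engine and its energy parameters are not recoverable,
and the raw libraries are unavailable.  The predictor is instead
validated by planted-truth recovery (precision and recall ≥ 0.9 against
10 planted hairpins and 10 single-flaw decoys).

## Differential expression

TPM = count / clean total × 10⁶, exact, with no pseudocounts at the
normalization step; over a full tag table each library's TPM sums to
10⁶.  The published analysis names no test statistic; the
Audic–Claverie exact Poisson test — the de facto standard for
two-library tag counts in that era — is the declared choice and is
oracle-tested against direct summation of its posterior predictive.
The posterior-predictive tail test is directional when depths differ;
the reported p is the average of the two conditioning directions, which
restores exact symmetry under swapping the libraries and reduces to the
plain test at equal depths.  Pair preparation follows the published
conventions: TPM 0 → 0.01 when the partner stage is expressed; both
< 1 TPM → untested.  A call requires p < 0.01 (raw, no multiple-testing
correction, matching the published raw-P threshold; BH-FDR could be
layered on but is off) and fold change > 2, read as |log2 ratio| ≥ 1
(the stricter |log2 ratio| ≥ 2 reading is selectable).  Fold changes are
computed on TPM.

Stage preference compares each stage against the mean of the other
three (zeros → 0.01), calling when ratio > 2 and
Z = (x − mean)/sd(others, sample) > 2; a zero spread with a qualifying
ratio still calls.  The others-only construction is declared: with only
four stages, a whole-profile sample Z-score can never exceed 2, so the
original rule must have excluded the candidate stage from the spread.
Clustering is k-means (Euclidean, 100 restarts, fixed seed) on per-row
standardized log2(TPM + 0.01) profiles.

## Editing detection

An editing event is a set of unannotated tags identical in length to a
mature reference and differing at exactly one position (Hamming
distance 1; indels are out of scope — "one mismatch" implies
substitution).  Distance-0 reads feed the reference count; distance ≥ 2
reads are ignored.  Events need ≥ 5 edited reads summed over libraries,
reusing the novel-miRNA noise floor since no editing-specific threshold
was published.  Position 1 is detectable — the real data's empty 5'
terminus is an observation, not a rule — and a planted position-1 site
verifies this.  Rate consistency across libraries is tested by one-way
ANOVA on per-read 0/1 outcomes grouped by library, which is the
rate-comparison made well-defined at finite depth.  Events whose edited
sequence maps perfectly somewhere in the genome are flagged (possible
paralog or SNP — the in-silico analogue of the genomic-DNA control) but
not removed; whether the original scan filtered such tags is unstated.

## Synthetic study design

The generator emulates the study's data structure, not its biology:

- **Genome and loci.**  A 200 kb single-chromosome genome assembled
  block by block with ≥ 350 nt random spacers: 30 known miRNA hairpins,
  10 novel hairpins, 10 decoys, rRNA/tRNA/snRNA/snoRNA/repeat loci,
  3 exon–intron genes, 8 double-stranded siRNA regions, 120 diffuse
  background regions, and one paralog locus carrying an edited miRNA
  sequence.  Hairpins are mature + A/C loop + imperfect star: the star
  is the reverse complement with two non-pairing substitutions, because
  a perfect stem would make mature and star reads map to both arms on
  both strands and falsely trip the multi-locus/both-strand filters —
  real stems are imperfect for the same functional reason.  Planted
  novel hairpins are re-validated against the *actual predictor* in
  their final genome context, requiring recovery with the planted star
  arm, and redrawn on failure; unstructured decoys are symmetrically
  verified to fail the duplex stage.  Planted matures avoid the adapter
  seed and its reverse complement so trimming is never ambiguous.
- **Decoys.**  Two each of: read count < 5 (expected 1 read), two
  genomic loci, antisense stack over the precursor, repeat annotation
  over the star arm (the hairpin itself is valid, so the repeat filter
  is the sole rejection), and unstructured loci (no hairpin; these fail
  the duplex stage, necessarily on one or more duplex sub-criteria).
- **Emission.**  Every read source carries an expected TPM per stage;
  per-stage TPMs sum to exactly 10⁶ (background absorbs the remainder),
  and a library is one multinomial draw of the configured depth
  (10⁵/stage), so emitted reads per stage equal depth exactly.  Editing
  sites split their parent's draw binomially at the planted rate.
  Reads carry the full TruSeq-style 3' adapter at constant Q40.
  Sequencing error is off by default (the pipeline's perfect-match
  logic would only shift mass into `no_annotation`); a substitution
  rate is available for robustness experiments.
- **Abundances.**  Known miRNAs sit on a 100–12000 TPM geometric grid;
  planted fold changes (|log2FC| 2–3 across specific transitions, low
  side ≥ 100 expected reads) and two single-stage spikes are encoded in
  the per-stage profiles; the resulting miRNA share of total reads runs
  ~9–18% across stages, in the range of the published category table.
  Class length distributions are calibrated so 24 nt is modal, 21 nt
  second, and ≥ 85% of reads fall in 20–24 nt; ~9% of reads are
  unmappable (unassembled-genome stand-ins).  Editing parents are
  flat-profile miRNAs, with one high-rate A→U at position 14 planted to
  dominate the substitution tally.
- **Determinism.**  All randomness flows from one seed through two
  derived streams (reference construction, emission); identical config
  and seed give byte-identical FASTA/FASTQ and reports.

What passing tests show — and don't.  Recovery at precision/recall 1.0
on error-free, perfectly matched synthetic reads demonstrates the
pipeline's logic, thresholds and bookkeeping, not robustness to
sequencing error, ligation bias, PCR duplication, isomiR-rich loci or
genome mis-assembly, none of which are simulated.  Occasionally (roughly
a third of seeds) one diffuse background locus folds into a genuinely
qualifying hairpin and is called — an honest false positive of the
criteria themselves, the same reason real predictors post-filter
manually; precision stays ≥ 0.9.  Exact binomial (Clopper–Pearson) 95%
intervals on pooled editing rates cover the planted truth per site at
~95%, so all six sites are simultaneously covered in only ~¾ of seeds;
the shipped test seed is checked, and the acceptance script reports the
coverage fraction.

## Numerical choices and degenerate inputs

Folding uses integer deci-kcal scores, so DP comparisons are exact; ties
prefer pairing (i, j), then the smallest bifurcation point.  Percentages
round half-up via `decimal`.  Empty sequences fold to the empty
structure at 0.0; an all-unpaired mature yields a `no_star_arm` failure
rather than an exception; ANOVA with zero within-group variance and
equal means reports p = 1; k-means refuses fewer profiles than clusters;
zero library depth, negative counts, out-of-bounds annotations and
non-RNA characters raise immediately with the offending name.

## Known limitations

- Exact-match mapping only (no mismatched genome alignment); the
  `max_mismatches` knob is reserved.
- The annotation cascade judges multi-hit tags at one representative
  locus; a tag overlapping different feature classes at different loci
  is classified by the representative only.
- The AC test assumes fixed library depths (Poisson sampling); no
  overdispersion model, matching the single-replicate design.
- The Z-score stage-preference construction is a declared stand-in for
  an under-specified published rule; its absolute calls (e.g. "81
  miRNAs") are therefore not comparable.
- MIREAP's internal scoring is not reproduced; criteria are applied to
  the bundled fold.
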