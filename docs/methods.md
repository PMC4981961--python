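# Methods

This note documents the models, rules and numerical choices behind
`miralga`, what the synthetic-data generator does and does not emulate,
and where the design was genuinely open.

## Read cleaning and accounting

Raw reads are `5'adapter + insert + 3'adapter` (Illumina TruSeq
small-RNA adapter sequences by default; configurable). Each read gets
exactly one label from a fixed cascade, in the order the summary table
reports them: low quality (mean Phred < 20) → 3' adapter absent → empty
insert → 5'-adapter sequence inside the insert → insert < 18 nt →
poly(A) (≥ 90 % adenine) → clean. The order matters for
multiply-contaminated reads and is asserted in tests (a short poly(A)
insert counts as short). Percentages are shares of the high-quality
pool, rounded to two decimals for report output. An optional oversize
filter (> 43 nt, the upper bound of the observed insert-length range)
exists but fires rarely at default settings; it is reported as its own
row when it does. The mean-Phred ≥ 20 definition of "high quality" is a
package choice — summary tables of this kind print the row without
defining the filter.

## Mapping

A read is mapped iff it has a perfect full-length match on either strand
of a contig. Contigs are indexed by 12-mers; since inserts are ≥ 18 nt a
seed hit is guaranteed, so the seeded search is exact. Multi-mapping
reads count once toward the mapped fractions (any-hit counting); hits
are reported up to 50 per read. Coordinates are 0-based half-open
internally, 1-based only in human-readable reports.

## Annotation cascade

Categories are assigned in the priority order rRNA > tRNA > snRNA >
snoRNA > known miRNA > unannotated; the first class whose search
succeeds wins, so the category counts partition the input. The aligner
places the full read inside a reference with unit costs and *separate*
budgets — mismatches ≤ 2 and gaps ≤ 3 — via a gap-layered dynamic
program (edit distance alone cannot enforce the two budgets
independently; edlib is used only as a fast prescreen). Candidate
references must additionally share an exact 11-mer with the read, the
classic BLASTn word size. Without that seeding requirement, a (2 mm,
3 gap) budget on an 18–25-nt read matches ~30 % of *random* reads to
random ncRNA references — alignments no word-seeded search would ever
report and that would poison every downstream stage. Reads that
genuinely derive from a reference always share such a word.

## Hairpin folding

The built-in model folds **single stems only**: a chain of nested pairs
(Watson–Crick + G:U) closed by one terminal loop (≥ 3 nt), interrupted
by bulges and interior loops of up to 10 nt per side; no multiloops.
Energies are a simplified Turner-style parameterisation: a 6 × 6
pair-on-pair stacking table (kcal/mol), logarithmic hairpin and
bulge/interior penalties, no stacking bonus across interrupted helices.
All arithmetic is integer deci-kcal/mol, so the dynamic program and the
exhaustive test oracle compare exactly and ties are impossible to
mis-order; ties in energy prefer more pairs, then the 5'-most outer
pair. The DP is O(n² · L²) with L the 10-nt loop cap; a 190-nt window
folds in ~0.2–0.4 s.

Absolute energies of a simplified table differ from any specific
published folder, so the −18 kcal/mol acceptance threshold is
interpreted against whichever engine is configured; under the built-in
table a canonical ~50–190-nt window holding an 18–21-bp stem scores
−25 to −45 kcal/mol and a random window of the same length typically
scores above −18 once the hairpin-shape filters are applied. Any
external engine returning `(dot-bracket, mfe)` can be plugged in; all
downstream filters consume only that pair plus metrics recomputed from
the dot-bracket (which also handles multiloop structures an external
engine may emit).

When a precursor is excised around a mature read, the fold is
constrained so the outer pair encloses the read (`enclose=`): the
reported structure is the best hairpin *harbouring* the mature, not the
globally best stem of the window. In long excision windows, spurious
flank-against-flank stems otherwise bury genuine but AU-rich hairpins.

"Perfect stem-loop hairpin" is operationalised as: exactly one hairpin
loop and ≥ 75 % of the mature's bases paired.

## Discovery

*Known from reads.* Reads annotated as known-miRNA are grouped by best
database hit; the most abundant read of a group anchors a genomic
excision, and the candidate survives if a window folds into a valid
hairpin.

*Conserved from ESTs.* Every database mature (18–25 nt) is searched in
the ESTs with a combined budget of mismatches + gaps ≤ 3 (the homology
criterion for cross-species conservation). Hits are discarded if any
ncRNA class also matches the window, or if no flanking window folds into
a valid hairpin; duplicates across ESTs and across species variants of
one family merge by mature sequence and by overlapping locus.

*Novel from loci.* Unannotated mapped reads are clustered into loci
(gap ≤ 200 nt on the same contig and strand). At realistic read
densities background reads chain entire contigs into single loci, so
candidates are seeded per read, not per locus: every read with ≥ 5
copies that locally dominates its neighbourhood (no better-supported
read within 60 nt) anchors an excision. Windows are tried over a ladder
of flank extents (150/100/60/30 nt on the long side, 20 nt on the
short side, both orientations — the mature may sit on either arm), and
the first window passing the full battery is kept: one hairpin loop,
MFE ≤ −18 kcal/mol, mature ≥ 75 % paired, duplex overhangs ≤ 2 nt,
per-strand bulges/loops ≤ 4 nt. A hairpin whose star arm equals the
mature's reverse complement also maps on the opposite strand; mirror
calls are merged by mature sequence. Star-read support is *not*
required. The ≥ 5-copy support threshold and the 60-nt dominance radius
are depth defaults in the spirit of Mireap-style callers; at the default
study scale they admit every planted locus and no background locus.

## Families

Two matures link when their global (Needleman–Wunsch) alignment has
≥ 98 % identity — gaps count against identity — and ≤ 1 substitution
("fewer than two mismatches"). Families are connected components under
that relation (single linkage), which makes the partition
order-invariant; note that for 18–25-nt matures the 98 % identity
condition effectively requires identical sequences, which is why family
tables of this kind are dominated by singletons. A family is `conserved`
if any member carries a known-family hit and takes that family's name
(species prefix and allele suffix stripped); otherwise it is
species-specific. The conservation matrix counts database members per
(species, family) pair; an explicit species list keeps all-zero columns
visible.

## Target prediction

Sites are gapless antiparallel duplexes: miRNA position 1 (5' end)
pairs the 3' end of the site; insertions and deletions are excluded by
construction. Acceptance requires: mismatch score < 3, counting G:U
wobbles 0.5 and full mismatches 1.0; score within the preset cap
(strict 2.0, relaxed 2.5 — two stringency presets standing in for the
two external predictors such surveys typically union, with the cap as
their only declared difference); positions 8–12 all paired (wobbles
allowed — a literal "zero mismatches at 10–11 plus perfect 8–12 duplex"
reading would make a nonzero translational-inhibition fraction
impossible); ≤ 1 full mismatch in positions 1–7; duplex energy ≤ −18
kcal/mol. Duplex energy sums the stacking table over adjacent paired
positions plus a +1.0 kcal/mol penalty per internal mismatch. A site
with any non-Watson–Crick state at positions 9–11 is classified as
translational inhibition, else cleavage. The union over presets is
deduplicated by (miRNA, gene); summary tables report per-class miRNA,
gene, cleavage and TI locus counts with TI share = TI/(TI+cleavage).
The scanner is vectorized over all windows of all transcripts at once
(scores in half-units, energies in deci-kcal, so comparisons are exact);
a brute-force per-window evaluator over every possible 12-mer site
confirms set equality in the test suite.

## Enrichment

Per term: upper-tail hypergeometric p = P(X ≥ k) for k annotated genes
in a selection of n from a background of N with K term carriers.
Benjamini–Hochberg across all tested terms gives the adjusted p; the
reported q-value *is* the BH FDR (no separate estimator). GO terms are
called significant at adjusted p < 0.05, KEGG at p < 0.05 and q < 0.05.
The background is the full transcript set of the run, declared in
config, and annotations are used as given (no GO-DAG ancestor
propagation). The test suite checks the tail sum against direct
summation, BH against the step-up closed form, and the type-I rate on a
1000-term null simulation (0.05 ± 0.02).

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the pipeline assumes,
at desk scale: 30 contigs × 5 kb; 50 novel + 20 known planted precursors
(mature + 4–8-nt loop + star with G:U wobbles at rate 0.1, ≥ 500 nt
apart); 20,000 reads whose clean mass mixes planted matures (24 %),
ncRNA fragments (10 %), genome background (26 %) and unmappable random
sequence (40 %), so that about half of the read mass maps — the
hallmark of a contig-level assembly; per-category contamination at the
small fractions such libraries actually show (e.g. 1.58 % 5'-adapter
contaminants, 2.62 % short inserts); a multi-species mature/precursor
database carrying every planted known family under 3–7 plant species
prefixes with occasional one-base variants; 120 ESTs with 9 compliant
planted homologs (≤ 3 edits) plus 2 decoys verified to sit ≥ 4 edits
from every database mature; 300 transcripts with 60 planted target
sites (perfect, central-wobble or single-edge-mismatch patterns with
recorded intended modes); and GO/KEGG maps with one deliberately
enriched term among targeted genes. All randomness flows from one root
seed through named child streams, so the three generator entry points
agree on the planted material and identical configs give byte-identical
files.

Deliberately *not* emulated: sequencing error and quality-score
structure beyond a two-level high/low scheme, expression dynamics
(every planted mature is uniformly expressed), repeat structure and
gene models in the genome, and real ncRNA sequence families (reference
sets are random sequences; covariance-model search is not replicated).
Passing tests therefore demonstrate that the *rules* are implemented
correctly and recover what they are defined to recover — not that the
pipeline is robust to the full messiness of a real library.

## Scale and runtime

Default study sizes were chosen so a full pipeline run takes ~45–90 s
on one CPU (folding dominates), the whole test suite ~3–4 min, and the
acceptance script ~2 min including a second full run for the
determinism check.

## Known limitations

* The gene-model partition (exon-antisense/intron/intergenic) used by
  some pipelines to pre-filter novel-miRNA input requires annotations a
  contig-level assembly lacks; all unannotated mapped reads are used
  instead.
* The energy model is single-stem by construction, so it can never
  report a multi-hairpin structure; the one-hairpin filter only becomes
  a genuine discriminator with a plugged-in general-purpose folder.
* Family linkage uses matures only; precursor identity is carried as
  metadata, not as a gating criterion.
* Mapping is exact-match only; a mismatch-tolerant genomic mode is out
  of scope (homology searches live in the annotation aligner).
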