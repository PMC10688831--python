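# Methods

This note documents the models and procedures implemented in `lysogenkit`,
the assumptions behind them, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that make results reproducible.

## The att direct-repeat model

Temperate phages integrate by site-specific recombination between a short
host attachment site (attB) and its phage counterpart (attP).  The
crossover duplicates the shared core sequence, so an integrated prophage
is flanked by two near-identical direct repeats: attL at the integrase end
and attR at the lysin end.  The core is short — 10 to 25 bp — and the two
copies are identical or differ by a couple of substitutions.

The scanner models exactly this: two windows of `flank_window` bp (default
4000), each centred on a rough candidate boundary so the search reaches
2 kb outside and 2 kb inside the predicted bounds, are compared
exhaustively for substring pairs with core length `L ∈ [att_min_len,
att_max_len]` and Hamming distance `m ≤ att_max_mismatch`.  Indels are not
modelled — the biological repeats are substitution-near-identical, and a
Hamming-only model keeps the search exactly checkable against a
brute-force oracle.  Pairs score `s = L − penalty·m` with `penalty = 2`,
so one extra mismatch must be bought back by two extra base pairs of core.

Reported pairs are *canonical*:

* both ends lie on matching positions (a mismatched end is always trimmed:
  it costs more than it contributes);
* the pair is not left-slideable — if shifting both copies one position
  left still yields a qualifying pair, only the leftmost placement of that
  sliding family is reported;
* a pair contained (same diagonal) in a reported pair of equal or higher
  score is suppressed.

Ranking is by score, then longer core, fewer mismatches, outermost
placement, smallest left coordinate.  The full ranked list is returned
rather than a single call, because competing pairs can be genuinely
ambiguous (a prophage can present two plausible att pairs); downstream
code uses rank 1 but reports the list.

The implementation seeds candidate diagonals from vectorised
`att_min_len`-window match counts (any qualifying pair necessarily
contains such a window, so the seed set is complete) and enumerates
match-run blocks only around the seeds.  An independent exhaustive oracle
(`tests/att_oracle.py`, pure triple loop and a dense prefix-sum variant)
reproduces the scanner's output exactly on windows up to 2 kb; this
equivalence is asserted in the test suite and re-measured by the
acceptance script.

### The detectability ceiling

Two random windows of *w* bp share chance repeats whose best score grows
like `log4(w²)` plus the allowance bought by the mismatch budget: measured
on i.i.d. sequence, the best chance score is ≈ 10–13 for w = 1–2 kb and
13–15 for w = 8 kb.  A true att core is therefore statistically
identifiable only when its own score clears that ceiling.  A 10 bp core
with two mismatches (score 6) can never be distinguished from background
in kilobase windows — by any method, not just this one — whereas a 17 bp
exact core (score 17) almost always wins.  Consequences:

* boundary-recovery rates over synthetic lysogens must be read stratified
  by planted score: the acceptance script reports overall rank-1 recovery
  across cores of 10–25 bp with 0–2 mutations *and* the recovery for
  cores scoring ≥ 16, which sits at the ceiling's edge;
* on real genomes the ranked list, not rank 1 alone, is the curation
  surface for weak cores, mirroring manual practice;
* "recovered the planted pair" is judged by overlap of both cores with the
  planted copies, because canonical trimming/extension legitimately moves
  pair ends by a few bases (a mutated end is trimmed; coincidentally
  matching flanks are absorbed).

A related consequence: a background with *no* repeats outside the att
pair, at these window sizes, does not exist — i.i.d. sequence of a few kb
always contains qualifying chance pairs (expected ≈ 4·10⁻⁴ per position
pair).  The generator therefore makes no attempt to emit repeat-free
background; the optional decoy mode adds *extra* planted repeat pairs for
stress testing instead.

## Orientation and locus assignment

Prophages are displayed attL→attR.  If the lysogeny-module genes sit
nearer the genomic right repeat, the prophage is recorded as
reverse-complement and the att labels swap; with only one marker module
present its proximity decides; with neither, orientation defaults to
forward with a warning.  This operation is an involution under
reverse-complementing the input (asserted as a property test).

The integration locus is the annotated feature the att cores intersect.
Integration into a gene leaves the split pattern — a partial copy at one
junction, the restored full-length gene at the other, both overlapping an
att core — which is collapsed to a single unambiguous label naming the
restored copy as the disrupted feature.  Ties between distinct features
are reported as ambiguous with both names.  No overlap means a non-coding
locus.

## Gene categories and completeness

Products are mapped to functional categories by an ordered, case-
insensitive keyword table (shipped as editable JSON in
`lysogenkit/data/category_keywords.json`): transposase ≻ lysogeny ≻
methyltransferase ≻ endonuclease ≻ packaging ≻ head ≻ tail ≻ fiber ≻
lysis ≻ replication ≻ tRNA ≻ hypothetical ≻ unknown.  First match wins, so
an "IS30 family transposase" among tail genes is a transposase and a
"tail fiber protein" follows the tail module by the stated priority.  The
table is a reconstruction of standard phage annotation vocabulary; no
published keyword list exists for this curation style, which is why it is
data, not code.

The completeness rule codifies manual practice:

* **intact** — all six essential modules (lysogeny, replication,
  packaging, head, tail, lysis) present *and* both att sites found;
* **questionable** — exactly one essential module missing (att complete),
  or all modules present with one att side unresolved;
* **incomplete** — anything else.  Every failed criterion is listed.

Fiber/receptor genes are optional.  The rule is total and monotone:
deleting genes can never upgrade a verdict (property-tested over random
deletion sequences).  Note one deliberate strictness: a prophage missing
only its lysis genes is called questionable here even though a curator
may choose to keep such a phage in an intact set when all other modules
and sequence context support it; the essential-module set is an argument
for that reason.

Transposases are attributed to the module whose genes surround them (the
downstream module when they sit between two).  When the prophage sequence
and att pair are available, a copy of the att core between a transposase
and the lysis module raises `internal_att_before_lysis` — such an element
can excise with the lysis genes and truncate the phage.  A
methyltransferase with an endonuclease-category gene within
`rm_proximity` genes downstream (default 2, strand-aware) is a
restriction–modification candidate; otherwise it is an orphan MTase, with
adenine/cytosine specificity parsed from the product text.

Split prophages (fragments on different contigs with disjoint module
sets) are joined in canonical module order on a virtual contig, att
status recomputed from the outer fragments; duplicated essential modules
refuse with a diagnostic.

## Marker-gene phylogenetics

Global alignment is Needleman–Wunsch with match +1, mismatch −1 and
affine gaps costing 5 + (k−1) for length k (Biopython's `PairwiseAligner`
under the hood; scores validated against an exhaustive state-DP oracle on
short strings).  Identity is matching columns over all alignment columns.

Distances are p-distance or the Jukes–Cantor correction
`d = −(3/4)·ln(1 − 4p/3)`, the one-parameter model that treats all
substitutions as equally likely; it is undefined at p ≥ 3/4, where the
caller may fall back to a fixed capped distance (flagged).  JC69 was
chosen as the production distance because it is also the model driving
the bootstrap; composite-likelihood distances add little at single-gene
scale and are deliberately not implemented.

Neighbor joining is the Saitou–Nei algorithm with a deterministic
tie-break (lowest index pair in the current matrix order), negative
branch lengths clamped to zero and counted, and the final three lineages
joined at an unrooted trifurcation by the three-point formulas — which
makes NJ exact on additive matrices, a property the tests assert against
random trees and against dendropy's independent NJ implementation.

Bootstrap supports resample alignment columns with replacement from one
seeded generator; each replicate's distance matrix feeds the same
deterministic NJ, and an internal edge's support is the percentage of
replicates containing its bipartition.  1000 replicates is the
production default; simulations in the tests use 100, which is ample for
the two-clade sanity check.

Insertion groups are single-linkage clusters at pairwise identity
≥ `group_link_identity` (default 80%, sitting between observed
within-group identities of ≳ 88% and between-group identities of ≲ 48%;
no published threshold exists, so this is a calibrated reconstruction and
configurable).  Clusters containing seed taxa inherit the seed group
label; unseeded clusters get fresh labels ordered by their smallest
member, making the assignment invariant to taxon order.  Each group's
reference locus is the modal locus of its seeds (of all members when
unseeded); a member whose own locus differs is flagged an outlier — the
signature of an integrase that clusters with one group while its phage
integrates elsewhere.

## Codon usage and tRNA inventories

Codon counts use the standard genetic code; stop codons never enter
amino-acid fractions; CDS not divisible by three are trimmed with a
warning and N-containing codons are counted separately.  Synonymous
fractions are percentages summing to 100 per amino acid (undefined, and
reported as missing, at zero counts).  Cohort comparisons compute
fractions per entity and then average (mean ± sd, n−1 denominator by
default) rather than pooling counts — with per-phage fractions the mean
is not dominated by the largest genome.  The host table conventionally
includes the prophage CDS, since the prophage is part of the host genome;
an exclude-prophage composition is available by simply building the table
from host-only CDS, and the acceptance script reports both (at the
synthetic 50 + 50 gene scale the prophage is half the host pool, so the
two differ far more than they would on a real chromosome with ~40× more
host genes).

tRNA isotypes and anticodons are taken from annotation text, not
predicted from sequence.  A tRNA overlapping an att core (or annotated
partial) is the integration target's copy: marked partial and excluded
from the prophage's tRNA count.  Anticodon decoding is reverse-complement
with two standard notes: a G at the wobble position also reads the
U-ending synonymous codon, and the isoleucine CAU anticodon is the Ile2
case — lysidine modification by the host enzyme TilS redirects it from
AUG to the minor AUA codon, which is why the host's TilS status is
attached to Ile2 records when host features are supplied.

## Cohort dereplication and summaries

Dereplication consumes a precomputed pairwise identity table (ANI %,
aligned fraction %); computing ANIb itself is a BLAST-fragment pipeline
and out of scope.  A pair at or above both thresholds (defaults 99.00%
and 95%, inclusive) is a duplicate; pairs are visited in lexicographic
order and the later id is dropped unless a keep-list protects it.  The
procedure never drops both members of a pair and is idempotent.  A toy
collinear estimator (1020 bp fragments, global alignment, 30% identity
floor) exists purely so synthetic tests can exercise the rule end-to-end;
it is not ANIb.

Cohort summaries fix their rounding so reports are bit-stable: incidence
(strains with ≥ 1 intact prophage) as an integer percent, means and kb
statistics to one decimal, quartiles by linear interpolation.  The
bundled `datasets` module carries a 45-strain survey table whose
per-strain allocation is a deterministic reconstruction of published
marginals; every statistic the report computes depends only on those
marginals (synthetic strain ids are prefixed `LCV-`).

## The synthetic lysogen forge

The generator emulates the one genomic situation the pipeline curates: a
host chromosome with an integrated phage.  Defaults are chosen to match
the organism context — host background at GC 0.42 with generic
housekeeping CDS; a module plan of 43 CDS (6 lysogeny, 10 replication, 3
packaging, 7 head, 10 tail, 3 fiber, 4 lysis) giving cassettes of ≈ 40 kb,
inside the observed 29–51 kb intact-prophage range; gene lengths uniform
300–1500 bp in codon multiples with ATG/TAA ends; att core default 17 bp
(the length of the canonical printed example pair); interior codons drawn
from per-amino-acid bias vectors so codon-usage ground truth is exact.
Integration inserts `core + cassette` immediately upstream of the target
gene: the upstream copy is the partial remnant (mutations, if any, are
applied to it), the downstream full-length gene ends in the attR copy.
Which junction retains the functional gene is not observable from repeat
structure alone; placing the restored copy downstream is a convention and
the orientation option covers the mirrored case.

What the forge does **not** emulate — and therefore what passing tests do
not show about real data: operons, promoters and realistic intergenic
structure; annotation errors (products are always parseable);
repeat-free background (see the detectability ceiling above — chance
repeats are present exactly as in real DNA, which is a feature);
rearranged or degraded prophages beyond module deletion; and real ANIb
(the toy estimator assumes collinearity).  Tests on forged data certify
the algorithms' correctness and calibration under known truth, not the
annotation quality of any particular genome.

Marker families for phylogenetics are evolved along arbitrary rooted
trees under the exact JC69 transition kernel (per branch of length *b*,
each site changes with probability `(3/4)(1 − e^{−4b/3})` to a uniform
other base), so additive-matrix and bootstrap behaviour can be tested
against the generating tree.

Everything is deterministic for a fixed seed; identical seeds give
byte-identical FASTA/GFF output.

## Problem sizes and runtime

The test suite and acceptance script size their simulations to run in a
few minutes on one CPU: 200 forged lysogens (≈ 90 kb each) for att
recovery plus 100 exact-repeat replicates; oracle equivalence on windows
up to 2 kb; 50 replicates for locus assignment; 100 random additive trees
(n ≤ 8) for NJ; 100 bootstrap replicates on 500 bp two-clade alignments;
an 8-phage codon cohort at 50 genes per entity; 1000 random deletion
sequences for verdict monotonicity.  The production defaults
(`bootstrap_reps = 1000`, full-genome scans) scale linearly from these.

## Known limitations

* Substitution-only att matching: an att pair interrupted by an indel is
  found only as two shorter pairs, if at all.
* Rank-1 recovery of low-scoring att cores is bounded by the chance-repeat
  ceiling, not by implementation quality; use the ranked list.
* Category assignment is keyword-based; profile-HMM classification would
  be more robust to product wording and is out of scope.
* Insertion-group thresholds are calibrated reconstructions; with marker
  sets whose identities fall between the calibration bands, single-linkage
  clusters can chain.
* The joined-prophage object has no att coordinates (its contig is
  virtual); only module-level statistics are meaningful on it.
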