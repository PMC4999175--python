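# Methods

This note documents the models and procedures `chemomine` implements, the
parameters that matter, the synthetic data the tests run on, and the design
choices made where the design was genuinely open.

## Motif model and scanner

A motif is an ordered list of required anchor residues separated by
inclusive gap ranges: `C-x(15,39)-C` means "a cysteine, then between 15 and
39 unrestricted residues, then another cysteine".  Gap residues are truly
unrestricted — they may themselves be cysteines — which is why membership is
defined by *any-assignment* semantics: a protein carries the motif iff at
least one strictly increasing assignment of anchor positions satisfies every
gap range.  A greedy left-to-right regular expression can miss valid
alternative cysteine assignments, so the scanner is a backtracking search
over candidate anchor positions with two prunings (gap-range filtering and a
remaining-minimum-span bound).  Enumeration is capped at 10,000 assignments
per protein with a warning; only adversarial cysteine-rich sequences
approach the cap.  The test suite checks the scanner exactly against an
independent exhaustive-enumeration oracle on random and planted proteins.

Five patterns ship built in: the general insect OBP six-cysteine pattern,
the narrower classic hemipteran variant, a Plus-C OBP pattern, and two CSP
four-cysteine variants (a broad `C-x(6,8)-C-x(16,21)-C-x(2)-C` and a tight
`C-x(5,6)-C-x(18,19)-C-x(2)-C`).  The two CSP variants circulate side by
side in the hemipteran literature and do not nest; both are provided and the
tight variant is the default because it is the one the full deposited CSP
set satisfies.  Classic and general OBP ranges overlap without either
containing the other, so the classifier tests each flag independently and
resolves the primary family by the fixed precedence
Plus-C > classic > general > CSP.  The Plus-C pattern ends `…-C6-P-x(9,10)-C6a`
with a trailing spacer whose right edge the notation leaves open; it is
compiled with the proline immediately following C6 (gap 0) and the trailing
spacer as a requirement that at least 9 residues follow the final anchor.
Scanning operates on the full precursor protein, signal peptide included;
precursor lengths are what the source records tabulate.

## ORF model

ORFs are enumerated on both strands in all three frames.  Every ATG opens an
ORF that runs to the next in-frame stop (complete) or to the sequence end
(3'-truncated); the frame-initial segment that reaches a stop without an
ATG is reported as 5'-truncated.  "Complete" means start *and* stop — the
sense in which an assembly-truncated unigene lacks a complete ORF.
Coordinates are 0-based half-open on the forward strand; conversion to
1-based happens only in reports.  The representative protein of a transcript
is its longest qualifying ORF, with ties broken complete-first, then
'+'-strand, then smallest start — a deterministic rule so repeated runs
agree.  The default minimum ORF length is 80 aa: the smallest deposited
OBP/CSP precursor is 112 aa, so 80 leaves margin while suppressing spurious
short ORFs.  Translation uses the standard genetic code (insect mRNAs); any
codon containing N translates to X.

## Comparative analysis

Pairwise identity uses a global end-to-end Gotoh alignment with affine gaps;
a gap of length k costs `gap_open + k·gap_extend`.  Defaults: match +1,
mismatch 0, gap open 10, gap extend 0.2 — the common progressive-alignment
penalty scale for proteins — all configurable.  Identity is identical
aligned pairs over the full alignment length including gap columns, a
conservative denominator.  Published identity ranges computed with other
tools' (undocumented) denominators are therefore not asserted as test
values.

Tree distances are p-distances (differing over both-ungapped columns); the
distance model behind the original MEGA trees is unstated, and p-distance is
the simplest defensible default.  Neighbour joining follows Saitou–Nei with
`Q(i,j) = (r−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`, standard branch-length
formulas, negative lengths clamped to zero, and Q-ties broken by the
lexicographically smallest label pair, making output bit-reproducible.  On
additive matrices NJ recovers the generating tree exactly; the suite checks
topology and path lengths (≤1e−9) on random 4–8-taxon additive matrices and
cross-checks topologies against scikit-bio's NJ.  Bootstrap resamples
alignment columns with replacement (single integer seed); each replicate's
tree votes for the original tree's internal-edge bipartitions.  Replicates
in which some pair has no comparable columns are skipped with a warning, and
supports are percentages of the *successful* replicates — the skip count is
returned so a caller can judge coverage.  When no externally aligned input
is supplied, a center-star multiple alignment built from the pairwise
aligner serves as the guide; it is adequate at candidate-set scale and a
full progressive aligner is deliberately out of scope.

## Expression

RPKM is computed exactly as `(1,000,000 × C × 1,000)/(N × L)` with no
pseudo-counts; C = 0 gives 0, and cross-condition ratios with zero
denominators are reported as explicit inf/nan markers.  The library size N
is supplied separately from the count table because N counts reads aligned
to *all* unigenes, a superset of the genes tabulated.

qPCR efficiencies come from an OLS fit of Ct on log10 input amount;
`E% = 100·(10^(−1/slope) − 1)`, accepted in the 90–110% window.  Relative
quantification averages technical replicates per (gene, sample), computes
per-gene relative quantities `Q = E^(Ct_min − Ct)` (E is the amplification
factor, default 2 when no curve is supplied, since assays are validated into
the window rather than published per gene), and divides by the sample's
normalization factor — the geometric mean of the reference genes'
quantities.  This cancels loading shifts shared by all genes of a sample
exactly; fold changes are reported relative to a configurable calibrator
sample.  ANOVA is run on the raw (untransformed) normalized quantities with
biological replicates as units; a log-transform option exists but is off by
default, as the original analysis does not state a transform.  The one-way
ANOVA is classical (F = MS_between/MS_within); Fisher's LSD declares
`|mean_i − mean_j| > t(1−α/2, df_error)·√(MSE(1/n_i + 1/n_j))` significant
and the compact letter display uses insert-and-absorb over groups sorted by
descending mean.  With zero within-group variance and unequal means, F is
reported as +inf and letters follow the exact ordering of means.

## Synthetic data

Generators are pure functions of (plan, seed); one global seed expands into
per-component streams by fixed offsets so adding a generator never perturbs
existing fixtures.  Planted-motif proteins draw non-anchor residues from the
alphabet *excluding* the anchor letters, making the planted assignment
provably the unique match (a `realistic` mode lifts this for stress tests).
Read counts are Poisson with mean `rpkm·N·L/10⁹`; Ct values follow
`base − log_E(fold) + shift_sample + N(0, sd)` with reference genes at fold
1; alignments evolve a root sequence along a newick tree with per-site
substitution probability `1 − exp(−rate·length)` and no indels.

What the generators deliberately do not model: codon-usage bias, indel
evolution, read-level sequencing error, assembly artifacts, amplification
inhibitors, or between-gene efficiency correlations.  Passing tests
demonstrate algorithmic correctness under the stated models, not robustness
to every artifact of real sequencing data.

The `synthetic_accessions` module builds stand-in transcripts reproducing
the documented structure of the 18 deposited *S. avenae* OBP/CSP records —
precursor lengths, ORF completeness (one OBP and one CSP are 5'-truncated),
and cysteine-spacing class (nine classic OBPs; one OBP with 47 residues
between C3 and C4; one with 49 between C1 and C2 and 21 between C4 and C5;
two Plus-C OBPs; five CSPs on the tight pattern).  Membership is re-measured
with the scanner at construction time, never assumed.  These stand-ins let
the end-to-end checks run without network access;
`scripts/fetch_accessions.py` retrieves the real records where a connection
exists.

## Problem sizes and numerics

The test suite and acceptance script use desk-scale problems chosen to make
each property sharply testable: 500 random + 200 planted proteins for the
scanner/oracle equivalence, 100 random additive matrices (4–8 taxa) for NJ,
1000 Poisson genes for RPKM recovery (≥99% within 3 standard errors), 3-
sample fold designs at noise sd 0.05 for qPCR recovery (≤10% error), and
200 bootstrap replicates for the deep-split support check.  Floating-point
tie comparisons in the aligner's traceback use a 1e−9 tolerance; distance-
matrix symmetry is validated to 1e−12; branch-length recovery is asserted to
1e−9.

## Known limitations

* Center-star alignment is a guide-tree-free approximation; deep multiple
  alignments should be produced externally and passed in aligned.
* p-distance ignores multiple substitutions; long-branch trees may need an
  external corrected distance matrix.
* The motif dialect supports single-residue anchors only (no residue
  classes or exclusions).
* Signal-peptide prediction, BLAST confirmation and primer design are out of
  scope; the pipeline consumes their outputs as metadata where relevant.
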