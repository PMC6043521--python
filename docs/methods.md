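# Methods

This note documents the models and procedures implemented in `phytkit`,
the parameter choices that matter, what the synthetic data does and does
not emulate, and the package's known limitations.

## Family screening

**Domain annotation.** Candidate subtilases are annotated by optimal local
alignment (Smith–Waterman) of an S8 (peptidase-domain) reference and an I9
(prodomain) reference against each protein.  Scoring uses BLOSUM62 with
BLAST's canonical protein gap parameters — a gap of length *k* costs
`11 + k·1`.  Unknown residues (`X`) score as the worst value in the
partner residue's matrix column, a deliberately conservative choice so
that runs of `X` can never fabricate a domain hit.  A domain counts as
present when the alignment reaches 50% of the reference's ungapped
self-score **and** covers at least 60% of the reference.  Both thresholds
are exposed in `ScreenConfig`; the defaults were chosen once as values
that cleanly separate genuine anchor hits (near self-score) from the best
chance alignments of unrelated sequence (a small fraction of self-score)
and are not tuned per dataset.

**Catalytic machinery.** The four catalytic residues of the S8 domain
(Asp/His/Asn/Ser) are located by mapping the reference's designated
positions through the alignment; a position is accepted only when the
protein carries the identical residue there, so a single catalytic
mutation is reported as a missing residue.

**Completeness filter.** A protein is retained iff its length lies in
[650, 800] inclusive, all four catalytic residues were found, and the I9
prodomain is present.  The bounds are read as inclusive (the conventional
reading of "between"); the boundary behavior is unit-tested at 649/650 and
800/801.  The exclusion report names the first failing criterion in the
order length → catalytic → I9.

**Tandem arrays.** Family genes are clustered per chromosome into maximal
runs in which consecutive gene starts differ by ≤ 100 kb (`max_gap_kb`,
exposed as a flag — "tandemly arranged" has no universal definition, so
the radius is a declared parameter rather than a hidden constant).

## Junction calling and classification

Junctions are called by anchoring to annotated references: each reference
(sequence + known junction index + optional residue-331 index) is locally
aligned to the query; among references whose junction column lies inside
the aligned footprint, the highest-scoring alignment (ties broken by
reference id) maps the junction — and, through the same alignment, the
residue-331 position.  When the junction column falls in an alignment gap
the nearest aligned reference position on the mature side anchors the call
and the result is flagged `junction_in_gap`; when residue-331 falls in a
gap it is reported absent and the candidate subtype becomes `other`.
A motif-independent alternative (maximum-PWM-score scan) was considered
and rejected as the default because junction context varies more than the
anchors do; reference anchoring is also how characterized relatives are
used in practice.

The called window's P1'/P2' residues are checked against the invariant
Thr-Thr that marks the mature amino terminus of plant subtilases; a
mismatch raises a warning, never a rejection — the Thr-Thr pattern is an
empirical observation, not a definition of the junction.

Classification is a pure function of the window and the mapped
residue-331: candidate iff P1 = Asp; subtype His-/Lys-/Gly-type by the
331 residue, `other` otherwise.

## Enrichment statistics (logos)

For each window position (P6..P6') and amino acid, the count among
non-pad windows at that position is tested against the amino acid's
background frequency with a **two-sided exact binomial test**, using the
doubled-smaller-tail convention `min(1, 2·min(P(X≤k), P(X≥k)))`.  The
effect size is the percent difference `100·(f_sample − f_bg)`; letter
heights in a rendered logo are the percent difference where significant
(α = 0.05 by default) and zero elsewhere.  No multiple-testing correction
is applied, matching the convention of iceLogo-style displays; α is a
parameter.  The exact test replaces resampling-based reference-set
z-scores: it is deterministic, oracle-testable to 1e-12, and conservative
— under the null the realized per-cell significant rate stays at or below
α (verified over 100 seeded trials), so a logo never overstates
significance.  Pad symbols at boundary positions reduce that position's
sample size rather than acting as a 21st letter.

## Phylogeny

Distances come from an existing alignment (pairwise deletion: sites where
either row is gapped are skipped for that pair).  The default distance is
the raw mismatch fraction *p*; the Kimura protein correction
`d = −ln(1 − p − 0.2p²)` is provided because alignment tools commonly
apply it, and fails loudly (with advice to use `correction="none"`) when
`p ≥ 0.8541` makes the log argument non-positive.

Neighbor joining follows Saitou–Nei: join the pair minimizing
`Q(i,j) = (n−2)·d(i,j) − r_i − r_j`, with the standard two-point branch
lengths and a closing three-way join; the root is the conventional
trifurcation representing an unrooted binary tree.  Ties in Q break by the
smallest index pair, for cross-platform determinism.  Negative branch
lengths are clamped to zero with the deficit moved to the sister edge
(total conserved), toggleable.  On additive matrices the output's
leaf-to-leaf path lengths reproduce the input to 1e-9 — the canonical NJ
consistency guarantee, asserted over seeded random trees and cross-checked
against an independent NJ implementation.  A two-taxon input returns the
single edge split at its midpoint.

Clade assignment gives each unlabeled leaf the subfamily of its nearest
labeled leaf by patristic distance (ties: lexicographic label).  This is
an operationalization of subfamily membership — real subfamily boundaries
involve curatorial judgment — and is validated against exhaustive
path-length computation.

## In-silico PICS

**Digestion** cuts after every residue of the enzyme's rule set
(trypsin {K, R}; chymotrypsin {F, Y, W, L}), blocked before proline, with
zero missed cleavages.  Peptides outside [8, 30] residues are dropped
(the MS-observable range; both bounds configurable).  The Results/Methods
disagreement over which enzyme generated the original libraries is left
open deliberately: both rule sets ship, and the CLI requires `--enzyme`
explicitly rather than defaulting.

**Cleavage simulation.** A specificity model is a 12×20 additive score
matrix over the window plus a cutoff τ: a bond's score is the sum of
weights over its window (pads contribute 0, so boundary bonds are neither
favored nor penalized).  Threshold mode cleaves deterministically at
`score ≥ τ`; Bernoulli mode cleaves with probability
`logistic(steepness·(score − τ))` from a seeded generator.  At most one
cut per peptide is retained (highest score, leftmost on ties), mirroring
single-event detection per library peptide; prime fragments shorter than
4 residues are discarded as unidentifiable.

**Reconstruction** locates each prime fragment as a proper suffix of
library peptides via a precomputed suffix index.  A unique hit rebuilds
the window from the source peptide around the inferred bond; zero or
multiple hits discard the fragment into a tracked ambiguity report.
Because simulation records every event's true window, the round trip is
testable exactly: on unambiguous fragments reconstruction recovers 100% of
true windows, and with a strict Asp-P1 model every retained window carries
Asp at P1.

## Assay quantification

**Initial rates** are OLS slopes (RFU/min; per-hour by unit flag, carried
on every estimate — no implicit conversions).  The default window policy
fits every contiguous prefix covering ≥ 30% of the points and keeps the
best-r² one (ties: more points): plate-reader traces go sub-linear as
substrate depletes, so the prefix family targets the initial linear phase
while remaining exact on fully linear traces under any policy.  Fixed
windows and full-trace fits are available.  A perfectly constant trace is
assigned r² = 1 (zero residuals).  No Michaelis–Menten model is fit; only
relative rates are reported.

**pH profiles** report percent of the maximum slope with the optimum at
the measured argmax (no interpolation; ties to the lower pH).
**Substrate panels** are normalized per enzyme with a lexicographic
tie-break for the top substrate and an explicit flag when all rates are
zero.  **Peptide scoring** treats the C-terminal residue of an
AFC-conjugate peptide as P1 (the fluorophore occupies the prime side), so
a 4-mer fills P4..P1 and missing positions contribute 0.

## Necrosis quantification and group comparison

Scans are averaged to grayscale; the leaf mask is every pixel strictly
below the white threshold (default 250/255); dark (necrotic) pixels are
leaf pixels at or below the dark threshold — Otsu's method computed
within the mask by default, or a fixed value for exact reproducibility on
tri-modal synthetic images.  Per-image thresholding was chosen over a
global cutoff so scans of different exposure remain comparable; both
thresholds are flags.  The statistic is `100·dark/leaf`.

Group comparison is the classic pooled-variance unpaired t-test ("unpaired
t-test" without a Welch qualifier means the equal-variance form); Welch is
available.  Zero pooled variance with equal means returns p = 1 by
convention; with unequal means it is an error rather than a silent
infinity.  The implementation is closed-form and cross-checked against
`scipy.stats.ttest_ind` to 1e-12, with Monte-Carlo type-I calibration at
α = 0.05.

## Synthetic data: what it emulates, what it does not

Generators are bit-reproducible under a fixed seed and emit only the 20
canonical amino acids (downstream statistics assume a 20-letter
background; `X` is tolerated on *input* and flagged).  Default background
composition is uniform 0.05; an Arabidopsis-like plant composition table
is shipped as an alternative.

Planted subtilases are assembled on a fixed layout relative to the
junction index *j*: I9 anchor at [j−70, j−10), the 12-mer junction window
at [j−6, j+6), S8 anchor at [j+30, j+180), residue-331 analog at j+95
(offset 65 inside the S8 anchor, between the His and Asn catalytic
positions).  The anchors are fixed **synthetic** segments shipped with the
package — stand-ins for conserved domain cores that make the pipeline
testable offline; real reference sequences are pluggable everywhere an
anchor is accepted.  Because the inter-anchor spacing is constant, planted
family members align diagonally through the junction region, which is what
lets reference-anchored junction calling recover planted junctions
exactly.  Real subtilases vary in spacer lengths and domain divergence, so
exact-recovery results on synthetic families demonstrate correctness of
the machinery, not expected accuracy on real proteomes.  Likewise the
synthetic leaf images (white background / mid-gray leaf / dark lesions in
disjoint intensity bands) validate the counting machinery exactly but say
nothing about segmentation of real stained leaves with veins and
shadows, and the trace generator (line + i.i.d. Gaussian noise) omits
lag phases, depletion curvature and photobleaching.

The `family` module's planted family reproduces the *composition* of the
curated tomato subtilase set (82 complete members; 12 Asp-P1 candidates;
5 His-, 1 Lys-, 6 Gly-type at residue 331) as its study condition, so the
full chain can be exercised end to end at realistic scale; screening a
real proteome release additionally requires the download-and-curate steps
that are out of scope here (manual intron repair and supplementation with
individually published sequences are not automated).

## Numerical conventions

- Alignment tie-breaking follows the engine's deterministic first
  traceback; scores are exact optima (verified against independent
  recursion and, at tiny sizes, full path enumeration).
- Exact binomial p-values use `scipy.stats.binom` tails; agreement with
  independent pmf summation is asserted to 1e-12.
- All seeds are integers < 2³¹; sub-seeds are drawn once from a parent
  generator, never reused across stages.
- Problem sizes used by the acceptance script (600-protein PICS proteome,
  ~5,800-peptide library, 82+120-protein screen, 20 NJ trees, 10⁴
  t-test simulations) were fixed as comfortable desk-scale analogs of the
  original experiments.

## Known limitations

- BLAST bit-scores/E-values are not reproduced; domain presence is defined
  by the self-score fraction + coverage rule above.
- No HMM-based domain detection and no signal-peptide prediction.
- Progressive multiple alignment is consumed, not produced.
- The PICS simulation does not model protection chemistry, capture
  efficiency, missed identifications or PTMs.
- Junction calling assumes at least one homologous annotated reference;
  proteins sharing no similarity with any reference are reported
  uncallable rather than guessed.
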