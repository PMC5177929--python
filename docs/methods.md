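# Methods

This note documents the models, algorithms and design choices behind
`stressmir`, in the order data flows through the pipeline.

## Preprocessing

Reads are Phred+33 FASTQ.  A read passes the quality gate when its mean
base quality is ≥ 20 (configurable; this stands in for the diagnostic
quality check of a typical sRNA-seq run).  Adapter trimming cuts at the
leftmost position where the 3′ adapter's prefix matches exactly for at
least `min_overlap` (default 5) bases *and* the match continues as adapter
to the end of the read (or spans the full adapter) — so a short spurious
adapter-prefix inside the insert does not truncate it.  Reads without an
adapter match are kept whole and flagged untrimmed; untrimmed reads are
not counted as inserts.

Inserts of 18–24 nt are collapsed across **all** libraries into distinct
tags; tag ids are assigned by sorting the unique sequences and numbering
serially, so naming depends only on the sequence set, never on input or
library order.  RPM uses the library's retained 18–24 nt read count as
denominator, computed **before** decoy removal (normalisation at collapse
time precedes contaminant screening in this design).  Decoy screening
removes a tag iff its sequence or reverse complement is an exact substring
of any ncRNA/chloroplast reference (U→T canonicalised, zero mismatches —
the strictest reproducible rule; whether mismatched decoy matching should
be allowed is unknowable and deliberately not guessed).  The expression
gate keeps tags with ≥ 10 RPM in at least one library (inclusive ≥).

## Secondary structure

The built-in folder is a Zuker-style dynamic program over a deliberately
simplified nearest-neighbour model:

* allowed pairs AU, UA, GC, CG, GU, UG; minimum hairpin loop 3; no
  pseudoknots; interior loops capped at 30 unpaired bases;
* stacking energy per adjacent pair of pairs from a 36-entry YAML table
  (GC-rich stacks ≈ −3.15 kcal/mol down to GU/GU ≈ −1.05);
* hairpin loop `5.0 + 1.75·ln(u/3)`, interior/bulge `3.0 + 1.1·ln(u)`,
  multibranch `4.6 + 0.4·(helices incl. closing) + 0.1·unpaired`,
  exterior loop free.

This is not the full Turner model: the downstream criterion consumes only
MFE per nucleotide, and interoperability with a full-featured external
folder is preserved through the `sequence / dot-bracket (energy)` parser,
so either provider can feed the gate (MFE/len < −0.2 kcal/mol/nt,
strictly).  On sequences ≤ 14 nt the DP is verified exactly against
exhaustive enumeration of all nested structures under the same parameter
table.  Co-optimal structures are resolved by a fixed traceback preference
(stack, then interior loops by increasing 5′ helix offset, then
multibranch, then hairpin), which yields a deterministic — typically
lexicographically early — structure; optimal energy is unaffected by the
tie-break.

## Hairpin generator and star geometry

`build_hairpin` places the mature on the 5′ arm and constructs the star
arm as the reverse complement of the mature minus its terminal 2 nt, plus
a 2-nt tail, so that the excised duplex carries 2-nt 3′ overhangs on both
strands: the mature's last two bases sit unpaired at the loop side, the
star's last two at the precursor 3′ end.  The loop is a homopolymer of A
or C — the letter chosen so at most one mature-overhang base could pair
into it; a single isolated pair is never favourable under the energy
model, so the fold preserves the planted register.  An option plants ≤ 2
single-nucleotide bulges in the star arm to emulate the asymmetric bulges
of real precursors.

`predict_star` reads the duplex off the fold's pair table: with `p` the
partner table and the mature at `[s, e)`, the star is
`[p[i1], p[i0] + 1 + 2)` where `i0` is the first paired mature base and
`i1` the last paired base at or before `e − 1 − 2`; bulges are absorbed by
the nearest-paired rule and flagged `exact=False`.  Failure modes return
reason codes (mature spans the loop, insufficient pairing — default
tolerance ≥ 60% of mature bases paired, star out of bounds or crossing
the loop).  On generator-built perfect hairpins the prediction equals the
planted interval exactly; with one bulge it is within ±1 nt.

## Classification

A tag becomes a miRNA iff it has ≥ 1 perfect precursor hit whose fold
passes the MFE gate and whose duplex geometry yields a valid star;
`star_supported` additionally requires the star sequence (exact match,
any read count ≥ 1 in any library) among the distinct tags — both the
lenient (geometry-only) and strict (expression-backed) verdicts are kept,
since typical studies annotate more miRNAs than have sequenced stars.
Multi-locus tags are counted once (expression is tag-level) with all loci
listed as evidence.  When two accepted tags form a mature/star duplex on
a shared locus, the lower-expressed one is reported as the star of the
other (reason `star_of_mirna`) rather than as a distinct miRNA — star
reads are evidence, not annotations.  Families come from a known-mature
catalogue: exact identity, containment (isomiR length variants) or an
equal-length match with ≤ 2 substitutions and an identical position 2–8
seed; matches spanning several families yield `AMBIGUOUS`.

## Differential expression

TMM follows the published trimmed-mean-of-M-values recipe: reference =
library whose 75th percentile of count proportions is closest to the mean;
M/A over tags positive in both libraries; 30%/5% two-sided trims on M/A by
rank; factor = 2^(inverse-variance-weighted mean of trimmed M) with
binomial-approximation variances; factors rescaled to geometric mean 1.
It matches both an independent step-by-step reimplementation (≤ 1e−8) and
Bioconductor edgeR (≤ 1e−6) in the test suite.  Library sizes default to
column sums and can be stated explicitly.

GLMs are NB with log link, fitted by iteratively reweighted least squares,
vectorised across all tags at once (batched normal equations); offsets are
log effective sizes.  The common dispersion maximises the summed Cox–Reid
adjusted profile likelihood (per-tag NB log-likelihood minus ½ log det of
the Fisher information) by bounded 1-D search on log φ ∈ [10⁻⁶, 10].
Tagwise dispersions solve the Pearson moment equation
Σ (y−μ)²/(μ(1+φμ)) = n − p — the residual-degrees-of-freedom correction
matters: the naive moment estimator is biased low by ≈ (n−p)/n and
anticonservative — then shrink toward the common value with 10 prior
degrees of freedom (`prior_df → ∞` recovers the common value).

The treatment-level DE call is a likelihood-ratio test dropping the
treatment main effect and its five interactions (χ²₆), chosen as the
definition of "differentially expressed upon a stress" because it matches
per-treatment DE-set accounting; per-(treatment, day) Wald contrasts
(βT + βT:t) supply direction.  BH-FDR is applied within each contrast
family at α = 0.05.  The direction-by-day table counts the sign of the
per-day log₂FC among treatment-level DE tags by default (the
"N of M down at day t" accounting), with an option to require per-day
significance instead.  Because the headline per-treatment counts could be
defined within-day or pooled, both scopes are emitted.  The heat-map
matrix is log₂(count/effective size × 10⁶ + 1) (pseudocount 1, unstated in
typical reports) with average-linkage Euclidean ordering of rows and
columns.

## Target scoring

The expectation score is a banded global alignment of the miRNA (5′→3′)
against the site read 3′→5′: match 0, G:U wobble 0.5, mismatch 1.0, gap
2.0, all doubled at miRNA positions 2–13 (1-based); at most 2 positions of
strand offset.  Transcripts are scanned over every window within the gap
band of the miRNA length; windows with expectation ≤ 3.0 are reported in
(expectation, transcript, position) order, so each transcript's best site
comes first.  The penalty table, seed bounds, gap band and cutoff are
arguments, since they are predictor conventions rather than fitted values.
A central (positions 9–11) mismatch is annotated as translational
inhibition but never used for filtering.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline must
survive: the 72-library factorial design; hairpin-borne matures with
expressed low-abundance stars; isomiR length variants; exact-substring
ncRNA/chloroplast contaminants; precursor-less 24-nt siRNA background; NB
counts (default dispersion 0.1, per-library size factors lognormal(0,
0.15)) with planted treatment × time log₂ fold changes — by default heat
downregulation (−2) at days 0–1 for half the miRNAs, echoing the
early-day, heat-dominated response such studies report; adapter-flanked
reads padded to 50 cycles.  Default per-tag baselines (mature ≈ 30–80,
star ≈ 2, background ≈ 8 expected counts per library) keep desk-scale runs
fast; per-library depth is a free parameter since real studies rarely
state a target.  It does **not** model sequencing error by default
(optional uniform substitution rate), quality heterogeneity, 5′-adapter
chemistry, ligation bias, PCR duplicates, multi-mapping across paralogous
loci, or genuine expression correlation structure — so passing tests
demonstrate algorithmic correctness on clean data, not robustness to
platform artefacts.

## Numerical choices and degenerate inputs

IRLS runs at most 50 iterations with a relative deviance tolerance of
1e−8, linear predictors clipped to ±30, and a 1e−10 ridge on the normal
equations; non-converged tags are flagged and excluded from testing.
All-zero tags are excluded from dispersion estimation.  RPM with a zero
denominator and a nonzero count is a hard error; zero-count libraries
otherwise give zero RPM.  Empty decoy sets, empty precursor sets and empty
transcript sets degrade to warnings and empty results.  Tag ids, FASTQ
emission order, and all simulations are deterministic given the seed.

## Problem sizes

The shipped verification runs use 50–2000 tags, 72 libraries, sequences
≤ 14 nt for exhaustive fold enumeration, 100 hairpins for star geometry,
and 10-seed null simulations — sizes chosen so the full chain, including
its brute-force oracles, completes on a laptop-class single core in
minutes while leaving the estimators in their asymptotically sensible
regimes (n = 72 with 24 design parameters).

## Known limitations

The energy model is coarse (no dangles, no terminal-AU penalties, no
temperature dependence, no partition function); the MFE gate, not absolute
energies, is the supported use.  The duplex-collapse rule assumes the
mature arm out-expresses its star, which is the overwhelmingly common but
not universal case.  Family assignment depends on the catalogue's naming
convention (`miR<number>` extractable from the record id).  The DE module
fits fixed-factor time (no smooth trends), no batch covariates and no
quasi-likelihood moderation.
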