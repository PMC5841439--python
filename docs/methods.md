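# Methods

This note documents the models, numerical choices and limitations of the
package; it is the design record a maintainer should read before changing
defaults.

## Event model

Events are derived from annotation only, by pairwise comparison of the
transcripts of a gene. Each event is minimal: a local difference flanked by
exons with identical boundaries in both transcripts. Detection patterns:

- **ES** — consecutive exons (U, D) in one transcript; the other has exactly
  one exon V between them with junctions U→V→D.
- **ME** — U, V1, D against U, V2, D with V1, V2 distinct and
  non-overlapping.
- **IR** — consecutive (U, D) in one transcript; a single exon spanning
  exactly [U.start, D.end) in the other.
- **A5SS/A3SS** — two exons sharing one boundary and differing at the
  junction-side boundary, both spliced to an identical neighbouring exon.
  Which type it is depends on strand, since donor/acceptor are defined in
  transcript orientation.
- **AFE/ALE** — distinct, non-overlapping terminal (in transcript
  orientation) exons spliced to a shared constitutive exon.

The inclusion chain is the longer isoform for ES/A5SS/A3SS/IR, the chain
with the longer variable exon for ME (ties broken toward the smaller
genomic start, for determinism), and the proximal isoform for AFE/ALE (the
variable exon closer to the shared constitutive exon). Events with
different flanking contexts are deliberately kept distinct, because
counting is junction-anchored. Coordinates are 0-based half-open
everywhere; GTF I/O converts. Event ids are built from type, chromosome,
strand and both chains, so identical coordinates always produce identical
ids, and the catalog is sorted (chromosome, start, type, id).

Known limitation: only two-isoform events are modelled; complex regions
with three or more locally distinct isoforms yield several overlapping
pairwise events rather than one multi-way event.

## Counting

A read supports junction (a, b) iff two consecutive aligned blocks end at a
and start at b exactly — no tolerance window, so results do not depend on
aligner-specific fuzz. A read supports a body interval iff at least one
block lies entirely within it. Per-type assignment:

| type | n_inc | n_exc |
|------|-------|-------|
| ES | J(U→V) + J(V→D) + body(V) | J(U→D) |
| ME | junctions + body of V1 chain | junctions + body of V2 chain |
| A5SS/A3SS | long-site junction + body(extension) | short-site junction |
| IR | body(intron) + boundary-spanning single-block reads | J(U→D) |
| AFE/ALE | body(variable exon) + its junction to the constitutive exon | same for the distal exon |

Reads compatible with both isoforms (e.g. blocks inside shared flanks)
contribute to neither count. A single read may legitimately contribute more
than one unit to a chain — a junction-spanning read whose second block lies
entirely inside the variable exon hits both the junction feature and the
body feature; the counting tests model this explicitly. No effective-length
normalisation is applied: PSI is a count fraction, and the two chains have
different informative lengths, so PSI is an isoform-usage index rather than
an unbiased molar fraction. This matches the count-based definition the
analysis chain is built on and is invisible to ΔΨ-based testing when read
length and depth are comparable between groups.

## Differential test

Counts are beta-binomial: `n_inc | n ~ BetaBin(n, p·θ, (1−p)·θ)` with
group-level proportion p and precision θ = α + β shared across samples
(two isoforms, so the Dirichlet-Multinomial reduces to beta-binomial).
Proportions are optimised on the logit scale in [−12, 12] and θ on the log
scale in [−5, 10] (L-BFGS-B, three moment-informed starts; the alternative
fit is additionally seeded from the null optimum so its log-likelihood can
never fall below the null's). A dense, iteratively refined grid search over
the same domain serves as an independent oracle in the tests; agreement is
required to 1e-3.

**Dispersion is pooled across events.** With three samples per group a
per-event θ is hopeless: estimated freely under both models the LRT's
type-I error at α = 0.05 measures ≈ 0.11; estimated under the null only,
a true group shift is absorbed into overdispersion and power collapses.
The package therefore estimates a single θ across all tested events with a
Williams-type moment estimator on within-group residuals,

    X² = Σᵢ (kᵢ − nᵢ·p̂_g)² / (nᵢ·p̂_g·(1−p̂_g)),
    E[X²] = Σᵢ (1 + (nᵢ−1)·ρ)(1 − nᵢ/N_g),   ρ = 1/(θ+1),

summed over events and groups and solved for ρ. Group-mean shifts never
enter (only within-group residuals do), so the estimate is unbiased under
differential splicing; pooling makes it precise. Each event's LRT then
holds θ fixed under both null and alternative. Measured operating
characteristics at the package's reference conditions (3 vs 3, mean depth
100, θ = 10): type-I error 0.04–0.05 at α = 0.05; at depth 200, θ = 50 with
a 0.3 PSI shift: recall ≈ 1.0 and empirical FDR ≈ 0.05 at the
|ΔΨ| > 0.05 ∧ q < 0.05 calling thresholds. The cost is the assumption of a
common dispersion scale across events; strongly event-specific dispersion
would make individual tests mis-calibrated in both directions.
`lrt_event(..., theta=None)` still exposes the textbook per-event LRT.

Events are tested only when every group has total coverage ≥ 10
(configurable); untested events are reported with NA and excluded from the
BH multiplicity count. PSI is pooled within group (depth-weighted), not a
mean of per-sample fractions. BH adjustment follows the step-up formula
directly and is cross-checked against statsmodels in the tests.

## Conservation

Gene-level overlap uses a one-sided (greater) Fisher exact test on
[[both, a_only], [b_only, neither]] against the homologous-expressed
background. On the published Venn counts (89/578/518 over 12,233) this
implementation computes p ≈ 3.2e-18, agreeing with direct hypergeometric
summation to 1e-6 relative; the figure caption of the motivating study
prints p = 1.7e-32 for the same table, which does not follow from these
counts under a standard one-sided Fisher test. The package reports its
oracle-verified value.

Sequence-level conservation is defined for ES events only. Isoform
sequences are U+V+D and U+D concatenations (reverse-complemented on the
minus strand), translated in the annotated reading frame when the event
span lies inside the CDS of host transcripts of both chains; an internal
stop triggers a warning and nucleotide fallback. Alignment is global with
affine gaps (BLOSUM62 for protein; +2/−1 with gap open 10, extend 0.5 for
nucleotide) and free end gaps, since identity is scored as
matches / aligned columns excluding terminal gaps. Argument order is
canonicalised before aligning because tied optimal alignments could
otherwise make identity depend on species order. The pairing assignment
(straight vs crossed) with higher summed identity wins; both members of the
winning pairing must reach the identity threshold (default 0.5,
deliberately permissive) for `both`/`cross_matched`, one for `partial`.
PSI consistency is strict: ΔΨ = 0 in either species is sign-indeterminate
and yields N.

The packaged 24-row reference table stores inputs only (gene pair, the two
ΔΨ values, the conservation label); the Y/N column is always recomputed.

## Signature screen

Disease signatures are oriented by the SF's expression direction computed
from a median-of-ratios normalised count table (genes with a zero count in
any sample are excluded from the size-factor median, the standard
contract); any fold change away from 1 counts as a direction, since the
screen's sign logic needs only the direction. SFs with undetermined
direction are skipped and logged. The candidate rule defaults to requiring
both the ++ and the −− one-sided Fisher tests at α = 0.05 (the AND reading)
and can be relaxed to either; no multiplicity correction is applied across
SFs by default, though the comparison table carries enough to add one.
The common-event universe is all events tested in both datasets, including
0/0 cells.

## Enrichment

The null "log odds ratio < 1" is read in natural log, i.e. odds ratio
below e ≈ 2.718 (configurable; 1 gives the central test). The p-value is
the upper tail of Fisher's noncentral hypergeometric distribution at the
threshold odds ratio, computed by summing the pmf over the upper support —
the distribution's `sf` loses precision in deep tails, the pmf does not.
The reported effect size is the sample log odds ratio with a
Haldane-Anscombe 0.5 correction only when a cell is zero. Term hierarchies
are out of scope; annotations are flat sets.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
ground truth recorded for every planted feature:

- **Annotation**: one event per gene, seven fixed plus-strand geometry
  templates mirrored onto the minus strand for alternating genes; random
  uniform nucleotide sequence. Defaults: 2 genes per event type, read
  length 50.
- **Counts**: totals are negative-binomial (default mean 200, dispersion
  0.05 — a realistic bulk coverage spread), inclusion counts beta-binomial
  (default θ = 50). Planted differential events get a ΔΨ of 0.3 (default)
  in a random direction with room inside [0.02, 0.98]; clipping PSIs away
  from the boundary avoids degenerate maximum-likelihood corner cases by
  construction. Reference conditions used for the operating-characteristic
  checks: null calibration at p = 0.5, θ = 10, 3 vs 3, depth 100, 2000
  events; recovery at 10% planted, ΔΨ = 0.3, θ = 50, depth 200, 1000
  events.
- **Second species**: genes cloned with i.i.d. substitutions (default rate
  0.1). Cross-matched conservation cannot be realised by a plain clone —
  with consistent geometry the straight pairing always wins, because the
  extra variable exon only adds gap columns — so it is planted by shifting
  the exon boundary in species B: B's upstream exon absorbs A's
  variable-exon sequence and B gains a novel variable exon, making B's
  exclusion isoform match A's inclusion isoform. This emulates a real
  annotation-level exon-boundary shift rather than a sequence hack.
- **SF perturbations**: disjoint regulons with signed effects; KO/KD
  reverses the OE response; the disease cohort mirrors a configurable
  fraction of each regulon consistently with the SF's planted expression
  direction (default fold change 3). The signature-level generator
  (`simulate_signature_pair`) uses a spurious non-zero symbol rate of 0.02,
  matching what the count-level path emits after BH control — not an
  arbitrary noise knob.
- **Terms**: flat annotations with a few terms drawing ~70% of their genes
  from the foreground.

What the generator does **not** model: sequencing error, positional or GC
bias, fragment-length effects, multi-mapping, correlated events within a
gene, event-specific dispersion, and annotation errors. Passing tests
therefore demonstrate the correctness and calibration of the algorithms
under the stated model, not robustness to the full messiness of real
RNA-Seq data.

## Determinism

All randomness flows through numpy Generators seeded from configuration;
the pipeline writes a manifest with SHA-256 hashes of every output, and
identical seeds reproduce identical bytes. Desk-scale problem sizes (a few
thousand events, hundreds of replicates) keep the full test suite and the
reproduction script in the tens of seconds on one CPU.
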