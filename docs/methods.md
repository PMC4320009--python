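# Methods

This note documents the models, conventions and numerical choices behind
`barcodegap`, and what the synthetic-data generator does and does not
emulate.

## Distance model

Distances are Kimura-2-parameter:
`d = -½ ln(1-2P-Q) - ¼ ln(1-2Q)`, with `P`/`Q` the transition and
transversion difference proportions over the compared sites.  The model
assumes equal base frequencies and homogeneous rates across sites; it is
the standard currency of barcode surveys, not a claim of best fit.
When a log argument is non-positive (`1-2P-Q ≤ 0` or `1-2Q ≤ 0`) the pair
is *saturated* and the package raises rather than returning a clamped
value — a saturated COI pair inside one genus indicates a data problem.

**Site scope.** Gaps and IUPAC ambiguity codes are treated as missing at
that site, never expanded into compatible bases.  Under `complete`
deletion (the default, matching how published between-species tables are
computed) every column containing a missing state anywhere in the study
is dropped before any pair is compared, so all pairs share one site
scope; `pairwise` deletion decides per pair.

**Standard errors.** The upstream tools print SEs without defining their
estimator, so the package standardises on a nonparametric *site
bootstrap*: resample the retained columns with replacement, recompute,
take the standard deviation across replicates (default 1000, seeded).
Under complete deletion all pairs are resampled jointly per replicate, as
a column bootstrap of a shared alignment should be.  One deliberate
exception: the barcode-gap summary's `se` field is the standard deviation
of the block's pairwise distances (a dispersion, not an SE of the mean),
because that is the quantity a reader compares specimens against.

**Averaging convention.** The conspecific/congeneric summary aggregates
over *pairs*, not species: a species sampled 17 times contributes more
pairs than one sampled twice.  Group-mean matrices put within-group means
on the diagonal, with 0 for groups sampled once.

## Tree

Saitou–Nei neighbor joining on the Q-criterion.  Ties in Q resolve to the
lowest (i, j) index pair in current matrix order, making runs
deterministic; note that with exact ties the *topology among the tied
alternatives* therefore follows input order, and bootstrap replicates of
low-signal clades hit such ties routinely.  High-signal edges are stable
under input order; shallow-edge supports can shift by a few replicates.
Negative branch-length estimates (an NJ artefact on non-additive
matrices) are clamped to 0 by default (`clamp=False` to disable).  On
additive matrices NJ recovers the generating topology exactly and path
lengths to numerical precision — this is tested on random trees.

Bootstrap supports are classic Felsenstein bipartition supports:
replicate columns are drawn from the complete-deletion-filtered
alignment so every replicate shares the point estimate's site scope;
support = % of non-dropped replicates containing the bipartition.
Replicates in which any pair saturates are dropped and counted, with a
warning above 5%.  Randomness attaches to column draws only.

Monophyly is evaluated on the unrooted tree: a species is monophyletic
iff some edge separates exactly its leaf set; single-specimen species are
monophyletic by convention.

## Haplotypes and network

Haplotype identity is exact string match after uppercasing (gaps and
ambiguity codes significant) — the convention of the classic tools.  A
greedy IUPAC-compatibility mode exists for studies with scattered
ambiguous calls; compatibility is not transitive, so that mode is an
assignment, not an equivalence relation, and is documented as such.

Site statistics: variable = ≥ 2 distinct unambiguous bases at a column;
parsimony-informative = ≥ 2 such bases each carried by ≥ 2 sequences.
The two are reported separately even though survey papers often conflate
them.  Composition is computed per sequence over unambiguous calls, then
averaged over sequences.

The network is a minimum-spanning network: Kruskal rounds over ascending
step counts, keeping *all* equal-weight edges that join components
separate at the start of the round, so alternative equally-short
connections survive.  Edges above the connection limit j* are discarded;
MSN pruning never changes connectivity, so components equal those of the
thresholded complete graph (tested against an independent graph oracle).

**Connection limit.** The classic 95% statistical-parsimony criterion
asks for the largest number of steps still likely to be homoplasy-free.
The package computes this from a finite-sites site-collision model:
j mutations thrown uniformly on L sites are homoplasy-free exactly when
they occupy j distinct sites, so

    P_par(j) = Π_{i=0}^{j-1} (1 - i/L),

and j* is the largest j with P_par(j) ≥ 0.95 (minimum 1).  This is a
transparent, reproducible stand-in for the historical recursion, lands in
the same range (j* = 8 at L = 573; the folklore value for ~600 bp mtDNA
is 9–10), and is cross-checked in the tests against a Monte-Carlo
placement simulation.  Studies wanting a published limit can pass a fixed
override; the delimitation verdicts in the bundled scenarios are
insensitive to j* anywhere in 5–15 because hidden lineages sit ≥ 20 steps
apart.

## Delimitation rules

Lineages are single-linkage clusters cut at the 2% cutoff: two specimens
share a lineage iff chained by pairs each *strictly below* t.  Single
linkage is the transitive closure of the pairwise rule as usually
phrased; complete linkage is available for users who want compact
clusters.  Raising t can only merge clusters (tested as a monotonicity
sweep).  Lineage labels are the species initial plus size rank (ties by
first specimen id); single-individual lineages are annotated, since a
lineage known from one specimen is a weak hypothesis.

Flags are independent booleans with recorded evidence:

* `cutoff_2pct` — more than one threshold cluster;
* `network_split` — haplotypes in more than one subnetwork;
* `ten_x` — maximum conspecific divergence ≥ 10× a reference mean
  intraspecific variability.  Default reference is the whole-study
  conspecific mean ("of the group"); a per-species mode exists.  Note a
  self-damping property: deep splits inflate the whole-study reference,
  so in studies where several species are deeply split the 10X flag is
  conservative — the cutoff and network flags carry the decision;
* `supported_subclades` — some internal edge with bootstrap support ≥
  `support_min` (default 80) isolates a proper subset of the species.

The headline `deep_divergence` verdict is `cutoff_2pct OR network_split`,
the two lines of evidence barcode surveys treat as decisive.  Species
pairs whose *between*-species mean falls below t are reported as shallow
interspecific pairs (recent speciation or over-split taxonomy).

## Synthetic studies

The generator emulates the shape of a single-genus COI survey:
14 species, 110 specimens (1–17 per species, mean 7.9), 573 bp, C/T-
biased composition, species-private haplotypes, hidden lineages in four
species spanning ~3.4–16.2% between-lineage divergence.

Genealogy is a three-level star: study root → species ancestors (radius
0.07 substitutions/site, ≈ 19% congeneric divergence; one outlying
species at 0.10) → lineage ancestors (per-lineage radii chosen so
lineage-pair divergences bracket the published spans: two lineages at
16.2%; three at 4.6–12.5%; five at 3.4–7.7%; five at 5.0–16.2%) →
specimens at half the within-lineage diversity.  Stars make every
expected pairwise distance an analytic sum of branch lengths, which is
what makes parameter-recovery tests sharp.  The expected distance between
specimens of different lineages is `r_a + r_b + (w_a + w_b)/2`.

Sequences evolve by the exact K2P jump process (transition/transversion
rate ratio κ = 4, rates scaled to one substitution per site per unit
branch length).  By default *nonsense mutations are suppressed*: an event
whose target would create a frame-0 vertebrate-mitochondrial stop codon
is redirected to a legal target with rates renormalised, and the root is
drawn stop-free.  This emulates the purifying selection that keeps real
barcodes stop-free — so clean simulated studies pass the QC screen —
while leaving the per-site substitution rate, and hence the distance
calibration, untouched.  The root is drawn from base frequencies
A .26, C .24, G .17, T .33.

Within-lineage diversity defaults sit at 0.1–0.6% for clean species and
for the hidden species' lineages (one lineage at 1.5%, mirroring a
genuinely diverse published lineage).  These are deliberate: at L = 573
and n ≤ 17, a "clean" species with ~1%+ internal diversity has an
appreciable chance of realising a > 2% pair or a > j*-step haplotype gap,
i.e. the one-lineage truth would not be what the data show.  Real surveys
report clean species up to ~1.3% mean diversity — such species genuinely
sit in the flag-ambiguous zone, and the generator does not pretend
otherwise.  Similarly, a published five-lineage species includes one
lineage whose internal diversity (2.3%) exceeds the 2% cutoff itself;
the corresponding preset uses homogeneous low diversity because a
five-lineage truth is otherwise ill-defined under the cutoff.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: among-site rate heterogeneity (real COI
variation concentrates at third positions, so the generator's variable-
site count, ≈ 490/573 at study-scale divergence, is far above the ~230
typical of real matrices at the same K2P depth); indels and sequencing
error; coalescent genealogy within lineages (stars have no internal
structure); base-composition bias in the *process* (K2P's stationary
composition is uniform — the C/T bias enters through the root and decays
on the order of the branch length, which at study depths leaves the bias
clearly visible but slightly flattened); geographically structured
sampling.

## Problem sizes and determinism

Defaults follow the emulated study: B = 1000 bootstrap pseudo-replicates
and 1000 site-bootstrap SE replicates; the full 110 × 573 pipeline at
those settings runs in well under a minute on one CPU.  The test suite
exercises end-to-end runs at B = 50–200 and recovery experiments at
20–50 replicate seeds — sizes chosen to keep the suite fast while leaving
Monte-Carlo margins comfortably inside the asserted tolerances; the
acceptance script runs the full-size configuration once.  All randomness
descends from a single seed per run (simulation, SEs and bootstrap get
independent child streams), and a rerun with the same config is
byte-identical, floats rounded to six decimals in reports.

## Known limitations

* K2P only; no model selection, no JC/TN93/GTR (out of scope).
* The connection limit is a site-collision bound, not the historical
  recursion's exact constants; use the override to reproduce a published
  limit.
* Supports on edges affected by exact NJ Q-ties depend on taxon input
  order (see above); decision-relevant, well-supported edges do not.
* The 10X rule's whole-study reference is self-damping in heavily split
  studies (see above).
* The compatibility haplotype-matching mode is greedy, not transitive.
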