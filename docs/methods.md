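# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `genedecay`, in the order the pipeline applies them.

## Data model and conventions

A **codon alignment** is a gapped FASTA with one sequence designated the
*reference*; the reference with gaps removed must have length divisible by 3
and defines both the reading frame and the coordinate system. Internally all
coordinates are 0-based half-open; every user-facing table is 1-based
inclusive, matching the convention of quoting mutation positions "following
the reference sequence". IUPAC ambiguity codes other than `N` are collapsed
to `N` on input and treated as missing everywhere downstream.

The **species tree** is rooted Newick; branch classes ride on node labels
with a `#class` suffix (written before or after the branch length — both are
accepted). Unlabeled branches belong to class `background`. When a species
manifest with clades (`toothed`, `baleen`, `outgroup`) is supplied, the
helper `label_whale_branches` derives the standard classes automatically:
`stem` for the branch above the whale crown node, `toothed`/`baleen` for
branches inside those subtrees.

The **manifest** is a TSV (`species`, `clade`, one column per gene) with
cell vocabulary `+` (sequenced, intact claim), `P` (sequenced pseudogene
candidate), `-` (absent from the genome), `.` (not amplified).

## ORF-disruption scanning

Disruptions are read per species against the reference:

* a **deletion** is a maximal run of reference positions the species lacks;
  runs are broken only by positions where the species has a base, so columns
  where both sequences are gapped (another species' insertion) do not split
  an event;
* an **insertion** is a maximal run of species bases opposite reference
  gaps, broken only by reference bases;
* indels with length ≡ 0 (mod 3) preserve the frame and are recorded as
  annotations, not disruptions;
* a **premature stop** is a species codon at reference-frame codon columns,
  upstream of the reference's terminal stop, that translates to TAA/TAG/TGA.
  Codons containing `N` are skipped. Stops that exist only in a shifted
  frame downstream of an indel are not called (the frame of record is the
  reference's).

Two species share an event iff kind, reference start, and length (indels) or
codon columns (stops) are exactly equal. Near-matches (same kind and length,
start within one position) are surfaced as warnings and never auto-merged:
alignment ambiguity should be visible, not silently resolved. Sharing
classes: `S` (carriers span toothed and baleen), `S*` (≥2, toothed only),
`S#` (≥2, baleen only), `U` (single carrier). Loss dating is Dollo
parsimony: the branch subtending the MRCA of all carriers, which for a
cross-clade event is the stem whale branch. The no-reversal assumption is
appropriate for frame-shifts and stops, where back-mutation at the same
coordinates is vanishingly unlikely.

## Pairwise dN/dS (modified Nei–Gojobori)

Site counting weights each possible point mutation by the
transition/transversion ratio **R** (transitions R, transversions 1); a
position's synonymous site fraction is the weighted fraction of synonymous
changes, with mutations into stop codons excluded from the numerator but
retained in the denominator, so synonymous + nonsynonymous sites = 3 exactly
per codon. R defaults to 2.0 — a standard mammalian transition bias — and is
configurable; the choice affects only the N/S split, not the difference
counts. Differences are averaged over all k! mutational pathways between
two codons, skipping pathways through stops; pairs with every pathway
blocked are dropped and tallied. Codons with gaps, `N`, or stops in either
sequence are removed pairwise before counting.

Distances use the Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3) with
analytic variance Var(d) = 9p(1−p)/((3−4p)²·m); a bootstrap over codons is
available as an alternative variance. The Z-test reports both the two-sided
p and the one-sided p for purifying selection (dN < dS), since claims of
"significantly below 1" can be read either way. Group comparisons are
one-sample two-tailed t-tests with the n−1 sample SD; pairs with dS = 0 have
undefined ω and are excluded from group means with an exclusion count.

## Branch-class ω models (GY94)

Codon columns containing a gap, `N`, or a stop in any retained sequence are
removed before fitting (premature stops must not contribute apparent
nonsynonymous signal); the removal log is kept. Codon frequencies default to
F3x4 (position-specific nucleotide frequencies with pseudocount 0.5,
renormalized over sense codons); F1x4 and uniform are available. The GY94
generator is scaled to unit expected rate, so branch lengths are expected
substitutions per codon. Transition probabilities use the symmetric
similarity transform that reversibility affords (one eigendecomposition per
ω class per evaluation); P(t) entries are clipped at zero only within 1e-10
and renormalized, anything worse is an error.

The scheme ladder mirrors the usual relaxed-selection test sequence:
`one_ratio` → `stem_two_ratio` (frees the stem whale branch) →
`crown_two_ratio` (stem + crown share a second ω) →
`stem_plus_crown_three_ratio` (stem and crown each free) →
`toothed_vs_baleen` (crown split by clade). Each step frees exactly one ω,
so every conventional LRT has df = 1; the statistic is clamped at 0.

Optimization is bounded L-BFGS-B on log-transformed parameters
(ω ∈ [1e-4, 10], κ ∈ [0.1, 20], lengths ∈ [1e-8, 20]), convergence at
|ΔlnL| below 1e-6, with 2 seeded random restarts by default. Branch lengths
are jointly estimated by default; they can be held fixed at the input tree's
values, which is what the simulation studies below do — there the generating
lengths are known, and fixing them keeps 400 model fits per study within a
few minutes without changing what the studies test (the ω estimators and
the LRT's null distribution given known lengths).

Site patterns are compressed before pruning; missing taxa contribute
all-ones partials; per-node scaling guards against underflow.

## Ancestral reconstruction

Marginal empirical-Bayes reconstruction at an internal node under
nucleotide HKY (κ fitted by ML with empirical base frequencies if not
given): per site, posterior ∝ downstream conditional likelihood × upstream
partial × stationary prior, computed by a two-pass (down/up) algorithm. The
maximum-posterior base is reported per site; ties are broken alphabetically
and flagged. HKY is the default because classical reconstruction tooling
for this task is nucleotide-based; the reconstructed sequence is checked
for frame sanity when appended to a codon dataset as an observed tip
(`ancestor_as_tip`), where downstream fits treat it as data and give it its
own branch class.

## The simulator

The simulator exists to make every stage testable without downloads; it
emulates the evolutionary scenario the inference chain assumes:

* the root codon sequence is drawn from the configured codon frequencies
  (uniform over the 61 sense codons by default);
* functional lineages evolve by a continuous-time jump process under the
  branch's GY94 generator — the state space excludes stops, so functional
  sequences never contain one, and realized substitution counts per branch
  are logged;
* at a **loss event** (branch, fraction along it) the lineage and all its
  descendants switch to neutral nucleotide HKY with the same κ (stops now
  permitted) at 1/3 of the codon clock's per-site rate — the neutral-limit
  continuation of "expected substitutions per codon" — plus a Poisson indel
  process (default 0.02 events per nucleotide site per unit branch length,
  post-loss only) with lengths drawn from {1: .35, 2: .25, 3: .10, 4: .15,
  5: .10, 6: .05}, i.e. 85% frame-shifting;
* every position carries a persistent site identity; the alignment is
  assembled from this master coordinate map, never re-aligned, so truth
  coordinates are exact. The truth log's per-species disruption lists are
  derived from the site-identity bookkeeping — an independent route from the
  alignment-column scanner, which is what makes recovery tests meaningful.

Indels occur only after loss because functional CDS alignments are treated
as indel-free after sanitization and indels are precisely the pseudogene
signature under test. What the simulator does **not** model: alignment
error (it emits true alignments), sequencing error, rate variation across
sites, CpG effects, selection on the nucleotide level post-loss, and
recombination. Passing tests therefore demonstrate correctness of the
inference chain under its own assumptions, not robustness to real-data
alignment artifacts.

The canned fixture suite (seed 20140506, fixed once) contains: (a) a
12-taxon whale-shaped tree (one outgroup, six toothed, five baleen; stem
branch length 0.25) with a stem-branch loss at fraction 0.3 of the branch,
ω = 0.06 background, 300 codons; (b) the same tree, no loss, ω = 0.06;
(c) neutral ω = 1; (d) a 3-taxon, 3-codon micro case small enough for
exhaustive-enumeration oracles.

## Validation studies and problem sizes

The validation module regenerates data under known conditions:

* **LRT null calibration**: 300 replicates of one-ω (0.2, κ = 2) evolution
  on the 12-taxon tree at 300 codons; the stem-two-ratio vs one-ratio
  rejection rate at α = 0.05 must sit inside the 95% binomial interval
  around 0.05.
* **Stem-ω recovery**: 100 replicates with stem ω = 0.6 against background
  0.06 (the direction and roughly the magnitude of a crown-vs-background
  relaxation contrast), 300 codons; median stem estimate and LRT power are
  reported.
* **Loss dating**: the stem-loss fixture must yield exact-coordinate
  recovery of every truth-logged frame-shifting indel and premature stop,
  class `S` for all cross-clade disruptions, and stem-branch Dollo
  assignment.
* Brute-force oracles: counting (1000 random codon pairs vs full
  enumeration, exact), pruning (every ≤3-taxon, ≤3-codon instance vs
  exhaustive internal-state summation, to 1e-8 using an independent
  scipy-expm route).

These runs use single-start fits with branch lengths fixed at the
generating tree's values; with 2–3 free parameters the likelihood surface
is well-behaved and restarts do not change the optima, which the
refit-from-optimum test confirms.

## Known limitations

* No site-model or branch-site selection tests, and no gamma rate
  heterogeneity — branch models only.
* Pairwise distances are Jukes–Cantor-corrected counts, not ML distances;
  saturation (p ≥ 3/4) is an error, not an extrapolation.
* The Dollo assignment reports the MRCA branch of observed carriers; if a
  shared disruption was subsequently obscured in one clade (e.g. a stop
  mutated away), the assignment moves tipward of the true origin.
* Reading frames are the caller's responsibility: partial amplicons must be
  supplied pre-aligned against an in-frame reference; exon structure is
  never inferred.
* ω for branch classes with very few expected substitutions is weakly
  identified and may sit at the box bounds; the convergence metadata and
  warnings surface this.
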