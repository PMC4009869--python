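# Methods

## The problem

Insertions and deletions (indels) leave gaps in multiple sequence
alignments. Most phylogenetic analyses discard them; this package treats
them as characters in their own right, asks how much tree signal they
carry relative to the nucleotides they are embedded in, and provides the
machinery to combine both signals in one partitioned likelihood. The
package is organised as a library (`src/gaptree`) with numbered analysis
drivers (`analysis/01...06`) that run the full workflow on simulated data
with known truth.

## Gap coding

Simple indel coding scores each distinct gap span — a maximal run of `-`
with a particular (start, end) — as one binary presence/absence
character. A taxon is `1` if it shows exactly that span and `0` if it has
sequence in any of the span's columns. It is *missing* (`?`) when it has
no nucleotide over those columns for any other reason: a strictly longer
enclosing gap (a taxon whose larger deletion covers the span carries no
evidence about whether the smaller event occurred on its lineage), an
unsequenced terminal region, or explicit `?` cells. These three cases
collapse into a single operational rule — missing iff no
nucleotide-present symbol in the span's columns — which reproduces the
enclosing-gap convention exactly and makes malformed inputs
deterministic.

Choices that the coding scheme leaves open:

* **Terminal gaps** default to missing data (`terminal_policy="missing"`)
  because leading/trailing gaps usually record incomplete sequencing, not
  deletion. `terminal_policy="code"` scores them like internal gaps.
* **Ambiguity codes** (`N`, `R`, `Y`, ...) count as nucleotide present:
  ambiguity is uncertainty about a residue that exists; a gap is the
  absence of one.
* A span **partially overlapping** (neither identical to nor enclosing)
  a character's span scores `0`, following the original description of
  the method; the alternative (missing) would discard real
  presence-of-sequence evidence.
* Characters are assigned to the **locus containing their start column**.
  Loci aligned separately can never produce cross-boundary spans, so the
  rule only disambiguates malformed input.
* Indel length = span width in alignment columns. Length filtering
  (`filter_by_indel_length`) drops characters below a threshold; it is
  idempotent and monotone.

Coordinates are 0-based half-open everywhere; partition files use the
1-based inclusive convention usual in phylogenetics configuration files
and are converted on read.

## Parsimony

Characters are scored with Fitch's algorithm, vectorised over characters
using bitmask state sets; missing data contributes the full state set.
Multifurcations are folded pairwise, which equals scoring the binarised
tree. The engine is checked against exhaustive enumeration of internal
labellings on every run of the test suite.

Tree search is hill climbing over nearest-neighbour-interchange (NNI)
moves, optionally augmented with subtree-prune-regraft (SPR). The
parsimony **ratchet** alternates hill climbs under perturbed weights — a
random 20 % of the informative characters doubled — with climbs under
equal weights, keeping every distinct topology at the best equal-weight
length. NNI-only search stalls in local optima on random matrices; with
SPR the ratchet attains the exhaustive-search optimum on all 20 random
7-taxon test matrices. Defaults: 100 iterations, 20 % perturbation,
doubling (not deleting) sampled characters, NNI swap; analysis scripts
pass `swap="spr"`.

The bootstrap resamples all coded characters (not only informative ones)
with equal probability, runs a ratchet per replicate, and takes each
replicate's majority-rule consensus of best trees; supports are
bipartition frequencies across replicates.

Homoplasy is summarised by per-character and ensemble consistency and
retention indices. For a binary character with *a* ones and *b* zeros
(missing excluded), the minimum conceivable steps is 1 and the maximum is
min(*a*, *b*); for nucleotides the analogues are (#observed states − 1)
and n − (largest state count). Characters whose minimum equals their
maximum carry no homoplasy information and are excluded from the
ensemble sums. The bounds are validated against brute-force extremes over
every 6-taxon topology.

## Likelihood

Binary gap characters evolve under the two-state symmetric Markov model
(Cavender–Farris–Neyman, CFN) with equal state frequencies; nucleotides
under GTR. Rate heterogeneity uses the discrete-Γ approximation with
four equal-weight categories whose rates are the mean of each quartile;
an invariant-sites proportion is available for nucleotides. GTR base
frequencies default to the empirical counts; exchangeabilities are
optimised with the G–T rate fixed at 1. All likelihoods are computed by
Felsenstein pruning, vectorised over characters with per-character
rescaling; the engine matches brute-force summation over ancestral
states to better than 1e-9 on hundreds of random instances, and GTR with
equal rates and frequencies reproduces the Jukes–Cantor pairwise closed
form to 1e-12.

**Acquisition bias.** Every observable gap character is variable, so the
plain CFN likelihood is biased — uncorrected fits on variable-only data
overestimate tree length substantially (about 1.6× in the packaged
8-taxon experiments). Two corrections are provided:

* `correction="conditional"` (the reference): each character's
  likelihood is divided by the probability of a variable character, the
  binary case of the Mkv correction. This restores total-treelength
  recovery to within a few percent at 5,000 characters.
* `correction="augmentation"` (the historical approximation): append
  `m` constant columns (half all-0, half all-1), fit the plain model,
  and score the augmentation by the conditional likelihood of the
  observed characters at the fitted parameters.
  `estimate_invariant_augmentation` scans a geometric grid
  (default 0, 2, 20, 200, 2,000, 20,000 — the procedure itself is only
  specified as "systematic") and refines around the best bracket by
  interval subdivision on even integers. The scan is unimodal on the
  packaged fixtures and its branch-length estimates land between the
  uncorrected and exact-conditional fits, closer to the latter.

An invariant-sites proportion is disallowed together with either
correction (unidentifiable). Equal CFN state frequencies are fixed.

**Optimisation** is coordinate-wise: bounded Brent line searches per
branch, then model parameters, iterated to a relative log-likelihood
tolerance of 1e-6 (30-round cap, flagged if hit). The log-likelihood
never decreases across rounds. Branch lengths are bounded in
[1e-9, 40]; zero-length inputs are nudged to 0.05 to leave the boundary.

**Partitioned (combined) model.** Partitions share one topology and one
branch-length vector; each partition scales the lengths by its own rate
multiplier, with the first multiplier fixed at 1 for identifiability
(the per-partition linking used by the original partitioned programs is
not documented; the multiplier parameterisation is the standard
identifiable choice). The combined log-likelihood is the sum over
partitions and is tested for additivity.

**Tree search** (`ml_search`) hill-climbs over NNI moves from a
neighbour-joining start (mismatch distances) plus optional random
restarts. Neighbours are ranked by a cheap two-round partial refit;
every neighbour whose partial score is within 3 log-units of the current
optimum is fully re-optimised (partial fits understate the optimum, so a
fixed top-k ranking misses improving moves). The search equals the
exhaustive 105-topology optimum on the packaged 6-taxon instance and is
deterministic under seed. The ML bootstrap resamples characters within
each partition independently.

## Tree comparison

Bipartitions are stored canonically (the tip block not containing the
alphabetically first taxon). Robinson–Foulds distance is the symmetric
difference of internal-edge bipartition sets and is property-tested as a
metric. Support comparisons classify each bipartition by the
well-supported (≥ 70 %) / poorly-supported (< 50 %) thresholds, treating
absent bipartitions as support 0 — the convention a support-vs-support
scatterplot needs for non-shared clades.

`jackknife_equalized_support` compares datasets of unequal size fairly:
each of (default) 100 pseudomatrices subsamples the larger matrix's
informative characters without replacement down to the smaller's
informative count — uninformative characters are all retained, since the
equalisation is defined on informative sites — then each pseudomatrix is
bootstrapped and supports averaged. The bootstrap count per pseudomatrix
is the caller's (default 100 in the CLI); it is not fixed by the
procedure's definition.

`gap_rate_convert` rescales gap-tree branch lengths by (gap characters
including augmented invariants) / (nucleotide sites), expressing indel
rates as gap changes per nucleotide site, directly comparable to
substitution rates. `branch_length_compare` pairs edges by bipartition
(tip edges by label) and reports a Spearman rank correlation; edges
present in only one tree are counted, not paired.

## Synthetic data

`simulate_evolution` runs substitutions and indels as competing
exponential processes along each edge (Gillespie), with per-edge
lognormal rate multipliers applied *jointly* to both processes so that
fast lineages are fast for both — reproducing the observed correlation
between substitution and gap branch lengths. Defaults emulate large
non-coding nuclear datasets: indel events at one tenth the substitution
rate, deletions twice as common as insertions, geometric indel lengths
with p = 0.6 (mean ≈ 1.7 columns, 1-bp events the most common class),
insertion position uniform over the sequence including ends, deletion
start uniform with truncation at the end. At these defaults the
parsimony treelength from coded gaps is roughly 10 % of the nucleotide
treelength, the regime large empirical gap matrices occupy.

Homology is tracked exactly: every inserted column gets a globally
unique identifier, so the emitted alignment is the true alignment —
independent insertions never share a column and every gap span descends
from logged deletions or absence of an insertion. The event log records
edge, type, length and the column identifiers of every indel.

What the simulator does *not* emulate: selection, context-dependent
indel hotspots, alignment error (the true alignment is emitted, so
coding noise from misalignment is absent), rate variation along the
sequence, and base-compositional drift. Passing recovery tests therefore
demonstrate correctness of the estimators under the model, not
robustness to real-data alignment artefacts.

`simulate_binary_characters` draws binary characters directly under CFN
on a fixed tree, optionally conditioned on being variable (the
acquisition regime of gap data) or parsimony-informative, or until a
target count of informative characters is reached. The recovery and
bias experiments condition on *variable* and count *informative*
characters: conditioning the data on informativeness while the model
conditions on variability is internally inconsistent and drives branch
estimates to the boundary.

## Experiment design in the packaged analyses

Recovery and bias experiments use a fixed balanced 8-taxon tree (tip
edges 0.2, internal edges 0.1 expected changes per character). A fixed
tree with resolvable internal edges makes the experiments measure the
estimators; random trees occasionally contain internal edges too short
to resolve at 2,000 characters, which measures the data instead.
Problem sizes throughout (2,000–5,000 characters, 20 replicates, tens of
bootstrap replicates in the drivers) are chosen so the whole analysis
reruns from scratch in minutes on one core while keeping Monte-Carlo
error well inside the tested tolerances.

## Known limitations

* Tree search is NNI/SPR hill climbing with restarts, not TBR or a
  genetic algorithm; on large matrices it finds good, not certified,
  optima (the exhaustive guarantees in the tests are for ≤ 7 taxa).
* The conditional correction assumes characters were acquired iff
  variable; gap matrices additionally under-sample autapomorphies of
  unsampled taxa, which no available correction addresses.
* The partitioned model links branch lengths up to one multiplier per
  partition; fully unlinked lengths are not offered.
* `jackknife_equalized_support` requires the larger dataset to be a
  binary character matrix (nucleotide jackknifing of the larger set is
  not implemented; the smaller dataset only contributes its informative
  count).
* The simulator's indel length distribution is geometric; power-law
  alternatives are not built in.
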