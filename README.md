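# gaptree

Phylogenetic analysis of alignment gap characters: indels coded as binary
presence/absence data, trees estimated from them under parsimony and a
corrected two-state likelihood model, and the gap signal compared and
combined with the nucleotide signal it is embedded in.

The package is for molecular systematists who have a multiple sequence
alignment with gaps — typically non-coding nuclear data — and want to
know what the indels themselves say about the tree.

## What it computes

**Gap coding.** Simple indel coding: every distinct gap span (start, end)
becomes one binary character; a taxon scores 1 for exactly that span, 0
when it has sequence in the span's columns, and `?` when a strictly
longer gap encloses the span (no evidence either way), the region is an
unsequenced terminus, or the cells are missing. Matrices can be filtered
by indel length (all, >1 bp, >2 bp).

**Parsimony.** Fitch scoring vectorised over characters, parsimony
ratchet search (NNI/SPR hill climbing with 20 % character reweighting),
nonparametric bootstrap, and consistency/retention indices
(per-character: ci = m/s, ri = (g − s)/(g − m), where s is the observed
steps, m the minimum over all trees and g the maximum).

**Likelihood.** The Cavender–Farris–Neyman (CFN) two-state model with
equal state frequencies and discrete-Γ rates for gap characters, and
GTR+I+Γ for nucleotides, both via Felsenstein pruning. Because a gap
character is only observable when variable, the CFN likelihood is
corrected for acquisition bias: either exactly, by conditioning each
character on variability (CFNv, with
P(variable) = 1 − Σ_s P(all tips in state s)), or by the
invariant-character augmentation procedure — append m/2 all-0 and m/2
all-1 columns and pick the m that maximises the conditional likelihood
of the observed characters. Combined analyses sum per-partition
log-likelihoods on a shared topology, with branch lengths scaled by a
free rate multiplier per partition.

**Comparison.** Robinson–Foulds distances, bootstrap-support scatter
classes (well-supported ≥ 70 % vs poorly supported < 50 %), jackknife
equalisation of informative-character counts before comparing supports,
conversion of gap branch lengths to gap changes per nucleotide site, and
branch-length correlations between data types.

**Simulation.** A sequence simulator with exact homology tracking
(substitutions and indels as competing processes, deletion bias,
geometric indel lengths, lineage rate multipliers shared between both
processes) that emits the true alignment, true tree and indel event log,
plus a direct CFN character simulator with variable-only or
informative-count conditioning.

## Worked example

The numbered scripts under `analysis/` run the whole workflow on
simulated data with known truth (12 taxa, ~4.4 kb, indels at one tenth
the substitution rate):

```
python analysis/01_simulate_dataset.py
python analysis/02_code_gaps.py
python analysis/03_parsimony_trees.py
python analysis/04_likelihood_trees.py
python analysis/05_combined_analysis.py
python analysis/06_compare_signals.py
```

Output of the first three steps:

```
alignment: 12 taxa x 4448 columns
indel events: 838 (570 deletions, 268 insertions)
1-bp indels: 56% of events
true tree length: 2.326 substitutions/site

   all:   814 characters, 814 variable, 194 parsimony-informative
 gt1bp:   401 characters, 401 variable, 111 parsimony-informative
 gt2bp:   194 characters, 194 variable, 51 parsimony-informative
removing 1-bp gaps shrinks the matrix by 51%

   all: MP length 839, RI 0.944, CI 0.886
 gt1bp: MP length 418, RI 0.935, CI 0.867
 gt2bp: MP length 198, RI 0.968, CI 0.927
```

Every coded character is variable (gaps are only observable where taxa
differ), about a quarter are parsimony-informative, and the matrix
shrinks by half when 1-bp indels are dropped — short indels dominate.
The retention indices near 0.94 show the low homoplasy typical of gap
characters relative to nucleotides.

Steps 04–06 fit the corrected likelihood model and compare signals:

```
gap ML tree: lnL -2642.71, length 0.105
augmentation optimum m* = 8258 invariant characters
nucleotide ML tree: lnL -33153.25, length 2.254
combined lnL -35806.20
gap partition rate multiplier: 0.043 (gap changes per substitution)
...
nuc__true: 0
gap change rate = 0.095 of the nucleotide substitution rate
branch-length rank correlation (nuc vs gaps): 0.9649350649350649 over 21 shared edges
```

The nucleotide tree matches the generating topology (Robinson–Foulds
distance 0), and the gap trees match it too except at the strictest
length filter, where only 51 informative characters remain. The
augmentation scan infers that thousands of invariant gap characters went
unobserved — the corrected branch lengths count them — so rescaling the
gap tree by matrix sizes puts the gap-change rate at 0.095 of the
substitution rate, recovering the simulator's true ratio of 0.1. Branch
lengths from the two data types are strongly rank-correlated (Spearman
0.96), as expected when lineage rates act jointly on substitutions and
indels. Tables and trees land under `results/`.

A `gaptree` command-line interface wraps the same functionality
(`gaptree code-gaps`, `mp`, `ml`, `compare`, `simulate`, `run`).

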