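# Methods

This note records the models, conventions and numerical choices behind
`phyloconflict`, and what the synthetic-data validations do and do not
demonstrate.

## Conflict classification

The unit of comparison is the **bipartition**: the two leaf sets
separated by an internal edge, stored canonically (the side *not*
containing the lexicographically smallest taxon first) so equal splits
hash equal. Two splits conflict iff, on their shared taxon set, all four
pairwise side intersections are non-empty; a split whose restriction to
a subset leaves fewer than two taxa on a side collapses and carries no
information there.

Classifying one gene tree against one reference node:

- restrict the reference split to the gene's leaf set; if it collapses,
  the node is **uninformative (missing taxa)** — this reproduces the
  standard worked case: for reference `((A,B),C)`, a gene missing B but
  containing `(A,C)` is concordant with the node uniting {A,B,C} yet
  uninformative for (A,B);
- otherwise, if a qualifying gene edge induces exactly the restricted
  split → **concordant**; a qualifying edge inducing an incompatible
  split → **conflict**, recording that split; otherwise **uninformative
  (low support)**. With a support cutoff (default 70, "moderate"
  bootstrap support), edges whose support is missing or below the cutoff
  never qualify. Conflict therefore requires an *explicitly supported
  incompatible* split; mere absence of the reference split is not
  conflict. When several supported splits contradict the reference node,
  the first in postorder is recorded — the choice is arbitrary but
  deterministic, and only affects which alternative a multiply-conflicted
  gene reports, not the conflict count.

Restriction happens per original edge, so in a gene tree pruned of taxa
a merged edge path is "supported" if any edge on it qualifies.

**Dominant alternative.** Among the conflicting splits recorded at a
node, the most frequent identical split is the dominant alternative;
ties break to the canonically smallest split. The four counts
(concordant / dominant alternative / other conflict / uninformative)
always sum to the number of gene trees.

**Rooting.** Gene trees are rooted on a ranked outgroup list: the first
listed taxon present is used, later ones only when earlier ones are
missing from that gene. Support values are treated as a property of the
edge below their node, and re-rooting preserves the edge–support
association (verified by test).

**Time slices.** Node ages (Ma) bin into five 30-Ma intervals labelled
150–121, 120–91, 90–61, 60–31, 30–0. The printed labels abut at
121/120 etc., so a contiguous rule is needed: a node joins the bin with
the largest lower printed edge ≤ its age (edges 121, 91, 61, 31, 0; the
oldest bin is closed at the crown age). Hence 95 → 120–91, 121 →
150–121, 30 → 30–0. Per gene and bin, the concordance proportion is
concordant / evaluable, where the denominator excludes only nodes voided
by missing taxa (not low-support nodes), and is undefined (NaN) for
empty bins.

**Per-gene scores and regions.** A gene's score is its concordant-node
count, tabulated both with and without the support cutoff, over the
nodes available to it (not voided by missing taxa); rank ties break
alphabetically. Region summaries (LSC/SSC/IR) sum per-gene concordant
counts, alignment lengths and gene tree lengths per region. The summed
gene tree length is this package's region rate proxy; re-inferring a
maximum-likelihood tree on each region supermatrix (which is how a
region "tree length" could also be defined) is deliberately out of
scope, and planted rate contrasts survive the proxy.

## Alignments

Supermatrices concatenate genes in the given order; taxa absent from a
gene are filled with `?` (not `-`) across its span, distinguishing gene
absence from indels. Occupancy cleaning keeps columns whose fraction of
non-missing characters (`-`, `?`, `N` all count as missing) meets the
threshold (the standard screen is 30%); cleaning is idempotent. Codon
alignments expand each amino-acid column into three nucleotide columns
(gap → `---`) after verifying that every taxon's ungapped nucleotide
sequence translates (NCBI table 11, the plastid/bacterial code; one
trailing stop codon tolerated) to its amino-acid row; mismatching taxa
either abort (`strict`) or are dropped and reported (`drop`) — both
behaviors exist because upstream databases do contain nucleotide/protein
records that disagree.

## Likelihood engine

Nucleotide GTR+Γ only. The rate matrix is built from exchangeabilities
(order AC, AG, AT, CG, CT, GT; GT fixed at 1) and stationary
frequencies, normalized to one expected substitution per unit branch
length; among-site variation uses the discrete-Gamma approximation
(equal-probability categories, conditional-mean rates, mean normalized
to 1; default 4 categories). Site likelihoods are computed by
Felsenstein pruning with per-node scaling; gaps and IUPAC ambiguity
codes are (partially) ambiguous tip states. The pruning value is checked
against exhaustive internal-state enumeration on small trees (agreement
≈1e-14) and is invariant to root placement, as a reversible model
requires.

**Branch lengths** are optimized coordinate-wise: for each branch the
tree likelihood is an explicit function of that length alone once the
conditional likelihoods on both sides are fixed, and projecting the
two-sided kernel onto the rate-matrix eigenbasis makes each trial length
a single exponential plus contraction. Each univariate problem is solved
by bounded scalar search on [1e-8, 10]; sweeps repeat until the
log-likelihood gains < 1e-6 (max 20 sweeps, warning on hitting the
cap). Because every step is an exact coordinate maximization, the
likelihood never decreases. Identifiability caveat: on a rooted binary
tree only the *sum* of the two root-child branches is identifiable, so
recovery checks compare on the unrooted tree.

**Constrained search.** A constraint (possibly multifurcating tree)
contributes its resolved splits, restricted to the gene's taxa; a
topology satisfies it iff it displays every such split. The search is
deterministic: stepwise addition in sorted-taxon order scored by Fitch
parsimony, rejecting placements that violate the constraint, then NNI
hill-climbing in which constraint-breaking moves are skipped, candidate
moves are scored by re-optimizing only the branches around the
rearranged edge, and the surviving topology is fully re-optimized
(coarse 1e-3 tolerance while searching, final polish at 1e-6).
Self-contradictory constraint sets are rejected up front.

**Edge test.** For ≥2 hypotheses about a focal relationship, each gene
is scored under each constraint; totals are exact column sums and the
best hypothesis attains the maximum (ties break alphabetically,
reported deterministically). Model parameters are *fixed per gene* —
supplied, or estimated once (empirical frequencies; exchangeabilities
and Γ shape by L-BFGS-B on a starting topology) — not re-fitted per
constraint, so hypothesis score differences reflect topology alone. A
gene whose sampled taxa leave all hypotheses' restricted constraints
identical cannot distinguish them: it is searched unconstrained once,
contributes that score to every column (neutral), and is flagged.
Totals are stored at full precision; a rounded display form is provided
for summary tables.

## Regression and saturation

The concordance regression is an aggregate binomial GLM (logit link)
fitted by IRLS via statsmodels: endog is (successes, failures) per gene,
so the aggregate fit equals the expanded Bernoulli fit (tested). The
quasibinomial family keeps the binomial point estimates and multiplies
standard errors by √φ with φ = Pearson χ²/(N−p−1) — computed directly
from the Pearson statistic because statsmodels' built-in `scale="X2"`
drops the aggregate weights for two-column endog (verified against R's
`glm(..., family=quasibinomial)`). Separation is reported as an error
when coefficients diverge or fitted probabilities pin to 0/1; saturated
fits to interior proportions are fine. Influence diagnostics (hat
values, studentized deviance residuals, Cook's distance) come from the
GLM influence machinery, flagged at the conventional |r| > 2, h > 2p/N,
D > 4/N.

The F84 distance uses the standard closed form
d = −2A·ln(1 − P/2A − (A−B)Q/2AC) + 2(A−B−C)·ln(1 − Q/2C) with
A = π_Aπ_G/π_R + π_Cπ_T/π_Y, B = π_Aπ_G + π_Cπ_T, C = π_Rπ_Y, P and Q
the transition and transversion proportions, base frequencies averaged
over the two sequences, and sites with gaps or ambiguity in either row
excluded.
It is the exact ML estimator for the pairwise model (verified against
numerical optimization to 1e-6 and against R ape's `dist.dna` to
1e-9), reduces to Jukes–Cantor under uniform composition with
transversions at twice the transition count, and returns a flagged
infinity when a logarithm's argument is non-positive (divergence beyond
what the correction can recover). Saturation reports, per codon
position and for all sites, every pair's observed and corrected
distance plus the origin slope Σxy/Σx² over finite pairs; flagged pairs
stay in the table. No significance threshold is imposed — the slope and
flags are reported and judgment is left to the user, since "saturated"
is a matter of degree.

## Synthetic data

The generator emulates a plastome-scale study design: ~53 taxa spanning
150 Ma, ~79 genes of heterogeneous length (300–4500 bp, log-uniform)
and rate (lognormal multipliers, σ=0.5, base rate 5e-4
substitutions/site/Ma so typical gene tree lengths land near 1), most
gene-tree edges weakly supported (P(high support) = 0.4; high ∈
[85,100], low ∈ [0,60] — so most genes are uninformative under the
70-cutoff, as in real plastome data), 5% random taxon dropout, and an
AT-rich GTR+Γ model (α = 0.4). The reference is a Yule tree rescaled so
the root sits exactly at the crown age; draws are retried (still
seed-deterministically) until every 30-Ma bin holds a node, with a
warning when the taxon count makes that impossible.

Conflict is planted by NNI at focal nodes: an exact round(fraction ×
n_genes) subset of genes is rearranged — exact, not Bernoulli, so
planted pies are recovered exactly rather than approximately — with one
deterministic move per node so all conflicting genes share a single
alternative split (the dominant alternative downstream). Focal
candidates exclude children of the root, where the "edge" is the root
edge and an NNI does not produce an incompatible split. NNI planting is
a deliberate choice: the pipeline characterizes topological conflict
agnostic to its cause, so no coalescent machinery is simulated, and
supports are assigned rather than bootstrapped to keep fixtures fast.

What the validations show — and don't. Planted-conflict recovery shows
the mapping machinery is exact on trees with known supports; it says
nothing about bootstrap behavior on real alignments. The edge-test
study (20 genes × 500 sites on 6-taxon trees, 20 replicates, the
constraint pair being the true focal split and its NNI neighbor,
generating model supplied) shows the constrained search discriminates a
true resolution under the model; real plastome edge tests confront model
misspecification this design excludes. The regression study (200 genes,
49 trials each, concordance probability logistic in log alignment
length with slope 1.5) checks sign recovery and ~95% Wald coverage, not
robustness to confounded predictors. The saturation scenario simulates
rate-homogeneous data (the F84 correction assumes equal rates across
sites) on 16-taxon trees at total tree lengths 0.5 vs 20 — the
unsaturated slope is then near 1 and the saturated slope collapses;
under strong Γ heterogeneity the slope is depressed even without
saturation, which is a property of the diagnostic itself. Branch-length
recovery uses 6 taxa × 10 kb under plain GTR with lengths in
[0.1, 0.3], where all lengths are well identified; with strong rate
heterogeneity or very short branches, 10 kb is not enough data for 10%
relative error on every branch — that is sampling noise, not an
optimizer defect.

Problem sizes throughout (taxon counts, replicate counts, site counts)
are chosen as the smallest that make each check sharp; they are stated
alongside each result the acceptance script writes.

## Determinism and reports

All generators draw from `numpy` Generators seeded via `SeedSequence`
from the user seed plus fixed stream ids; the search is deterministic
given inputs; reports carry the package version, the configuration echo
and the seed, contain no timestamps, and rerun byte-identically. RF
network exports give zero-RF pairs twice the largest finite inverse
weight (flagged) since 1/RF is undefined there; graph layout is left to
downstream tools.

## Known limitations

- Amino-acid models, codon models, bootstrap replication and Bayesian
  machinery are out of scope; amino-acid *trees* are fine for conflict
  mapping, but the likelihood engine is nucleotide-only.
- The NNI-based constrained search is adequate at desk scale (≤ ~20
  taxa); large empirical edge tests would want SPR moves and smarter
  starting trees.
- RF on unequal leaf sets prunes to the shared taxa; analyses that
  require identical leaf sets should filter genes first, and published
  pairwise RF values computed under a different missing-taxon rule may
  differ.
- The quasibinomial dispersion corrects standard errors, not point
  estimates; strongly overdispersed data may still warrant a different
  mean model.
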