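# Methods

`panevo` implements the comparative pan-genomics workflow used to study
bacterial genera such as *Bifidobacterium*: build gene families across a
set of genomes, characterize the pan/core structure and its openness,
quantify the selection pressure acting on the core genes, relate
functional-category abundances to genome size, and transfer host–microbe
protein–protein interactions from template interactomes. Every stage is
validated against a synthetic-data generator with known ground truth; this
note records the models, the conventions the package fixes where the
field's tooling leaves them implicit, and what the synthetic validation
does and does not establish.

## Gene-family clustering

Families are built by single-pass greedy centroid clustering, the
convention of USEARCH-style tools: sequences are processed longest-first
(ties broken lexicographically by gene id); each sequence joins the first
existing centroid whose pairwise identity reaches the threshold (default
0.50), otherwise it founds a new family with itself as centroid. There is
no reclustering or centroid updating; given the same input set the result
is deterministic.

**Identity convention.** Pairwise identity is computed on the optimal
global BLOSUM62 alignment (BLAST protein gap costs: open 11, extend 1, end
gaps penalized) as identical aligned residue pairs divided by alignment
columns, excluding terminal-gap columns; `X` residues never count as
identical. Arguments are canonically ordered before alignment so identity
is exactly symmetric. Tools delegate this definition to their internals in
practice, so it is pinned here explicitly: results are reproducible
bit-for-bit.

**Prescreen.** A full BLOSUM62 alignment per candidate pair is too slow
for genome-scale runs, so `greedy_cluster` skips clearly-unrelated
centroids in two cheap stages before computing the real identity:

1. *Edit-distance envelope.* A banded unit-cost global alignment
   (edlib) aborts when the edit distance exceeds
   `|la-lb| + (1-t+0.05)*min(la,lb) + 2`. Over a 3000-pair adversarial
   panel (random pairs, substitution-mutated pairs, indel-mutated pairs,
   lengths 30–150) the observed maximum of `(d - |la-lb|)/min(la,lb)` for
   pairs at BLOSUM identity >= t was exactly `1-t`; the cutoff adds a 5%
   plus 2-residue margin on top.
2. *Unit-cost path identity.* For survivors, identity computed on the
   unit-cost optimal path (same column-counting rules) is compared against
   `t - 0.10`; on the same panel BLOSUM identity never exceeded the
   unit-cost path identity by more than 0.056, so the 0.10 margin doubles
   the observed envelope.

Both stages are conservative by construction on the measured envelope, and
`prescreen=False` disables them entirely for auditing; the test suite
checks equivalence with a naive straight-line reimplementation of the
greedy rule on random and on family-structured inputs.

## Pan/core rarefaction and openness

From the family-by-genome presence matrix, pan(n) and core(n) curves are
accumulated over random genome orderings (default 30 iterations, the
conventional sampling depth for these plots). The median curve across
iterations feeds the fits (medians damp permutation outliers; means are
also reported). The median pan curve is fitted to Heaps' law
`pan(n) = kappa * n^gamma` by least squares in log–log space; the median
core curve to an exponential decay `core(n) = c + a * exp(-n/tau)`.

**Openness verdict.** The pan-genome is called *open* when (i) the fitted
exponent gamma is positive, (ii) its 95% t-interval excludes zero, and
(iii) the power law is preferred by AIC over a saturating exponential
`c - a * exp(-n/tau)` fitted to the same median pan curve (both SSEs
evaluated on the log scale; 2 vs 3 parameters). The first two conditions
alone cannot reject a finite pan-genome: any saturating curve fitted in
log–log space shows a small positive slope with a tight interval, so a
CI-only rule would call every non-degenerate closed pan-genome open. The
model-comparison term is what distinguishes unbounded power-law growth
from saturation. All fitted parameters, the interval, and both AIC values
are reported so the call is auditable; a constant pan curve short-circuits
to gamma = 0, verdict closed.

## Selection pressure

### Codon-usage relative entropy

For a designated gene set the 61 sense codons are tallied (stop codons and
codons containing ambiguous bases are skipped) and compared against a null
expectation by the Kullback–Leibler divergence in bits,
`D = sum p_obs * log2(p_obs / p_exp)`. Two null models are provided:

* `positional_nucleotide` (default): the expectation for codon *xyz* is
  `f1(x) f2(y) f3(z)` from position-specific nucleotide frequencies of the
  same gene set, renormalized over sense codons — the usage expected if
  codon positions were independent. It needs no external input, which is
  why it is the default.
* `uniform_synonymous`: each codon's expectation is its amino acid's
  observed frequency split equally across the synonymous family, isolating
  within-family codon preference.

The log base only scales D; group comparisons are unaffected.

**Finite-sample bias.** The plug-in estimate of D carries a positive bias
of roughly `(k - 1 - d) / (2 N ln 2)` bits (k = 61 categories, d = null
model parameters — 9 positional frequencies or 19 amino-acid frequencies —
N = codons counted). A core gene set is much smaller than its chromosome,
so uncorrected estimates make the core look more divergent through sample
size alone: in a simulation with *equal* codon bias in both sets, Welch's
test on uncorrected estimates rejected at 54% instead of 5%.
`estimate_relative_entropy` therefore subtracts this Miller–Madow-type
term (it may push near-null estimates slightly below zero); with the
correction the equal-bias rejection rate on disjoint sets measured 0.04.
The plain `relative_entropy` keeps the textbook formula for closed-form
uses. One caveat is intrinsic to the core-vs-chromosome design: the core
codons are a subset of the chromosome codons, which correlates the two
groups and makes Welch's test conservative (rejection below nominal) — the
safe direction for a significance claim.

Per-genome core and chromosome divergences are compared across genomes by
Welch's unequal-variance t-test (Welch–Satterthwaite degrees of freedom),
reporting the two-sided p and the one-sided p for core > chromosome.

### Nei–Gojobori Ka/Ks

The counting method of Nei and Gojobori (1986) with Jukes–Cantor
correction:

* **Sites.** For each sense codon, each of the 9 single-nucleotide changes
  is classified under the standard code; the synonymous site count s is
  the per-position synonymous fraction summed over positions, n = 3 - s.
  Changes to stop codons count as nonsynonymous, preserving the identity
  s + n = 3 per codon (and S + N = 3L per sequence), which the tests
  assert.
* **Differences.** For a codon pair differing at k positions, all k!
  orderings of the changes are enumerated; pathways whose intermediate
  codons are stops are excluded, falling back to all pathways when every
  one is blocked (a logged, rare case). Synonymous/nonsynonymous step
  counts are averaged over the used pathways, so s_d + n_d equals the
  Hamming distance of the pair.
* **Rates.** S and N are averaged over the two sequences; p_s = s_d/S and
  p_n = n_d/N are corrected by `d = -(3/4) ln(1 - (4/3) p)`. A proportion
  at or above 3/4 flags the pair *saturated* (correction undefined). omega
  = Ka/Ks is flagged *undefined* — neither 0 nor infinity — when Ks = 0;
  undefined and saturated pairs are excluded from family aggregates and
  counted.
* **Families.** Core-family CDS are aligned at the protein level
  (center-star progressive alignment anchored on the longest sequence,
  BLOSUM62 global pairwise alignments merged over the anchor's
  coordinates), back-translated to codons, and every column containing a
  gap is removed globally before pairwise NG counting. Family Ka and Ks
  are means over valid pairs; family omega is their ratio. Averaging Ka
  and Ks before taking the ratio (rather than averaging per-pair ratios)
  keeps the aggregate defined when individual pairs have tiny Ks.

The entire difference-counting table (61 x 61) is checked against an
independent exhaustive pathway enumeration that carries its own copy of
the genetic code.

## Feature statistics

COG-class abundance tables count each gene once: genes assigned to more
than one class are tallied under a separate `MC` (multiple classes)
column, and the `R` (general function prediction only), `S` (function
unknown) and `MC` columns are produced but excluded from correlations, as
is conventional when the classes carry no specific functional signal.
Feature-vs-genome-size association uses Spearman's rank correlation
(average ranks for ties; the tie-free closed form is used exactly when
possible) with a two-sided p from the t-approximation with n-2 df for
n >= 10 and exact full permutation below that (the permutation null is
evaluated via centered rank dot products, which are monotone in |rho| for
a fixed rank multiset). Significance defaults to alpha = 0.001. Group
differences use the tie-corrected Kruskal–Wallis H with a chi-square p on
k-1 df. The conserved-peptide scanner slides the query over each protein
and reports exact hits and variant hits (1..max_mismatch differences) with
positions and mismatch residues; its default query is the SecA-encrypted
immunomodulatory peptide `FAIVDEVDSILIDEAR`, whose F1Y variant is the
common form in gut bifidobacteria.

## Interolog transfer

A microbe protein and a host protein are predicted to interact when they
map, by filtered homology, onto the two ends of a template interaction.
Hits must satisfy e-value <= 1e-10, identity >= 30%, query coverage >=
60%, template coverage >= 90% (the thresholds interolog servers document);
template edges whose detection method matches a co-complex method
(case-insensitive substring, default "tandem affinity purification") are
discarded, because co-complex evidence does not establish binary contact.
Both orientations of each undirected template edge are considered. *Joint*
scores are defined worst-of-pair — joint e-value = max of the two hit
e-values, joint identity = min of the two identities — and candidates
failing the joint thresholds are dropped. This worst-of-pair definition is
the conservative reading of "joint" filtering and it changes edge counts,
so it is fixed here explicitly. Edges are deduplicated by (microbe, host)
with supporting template pairs accumulated, keeping provenance
recoverable; predictions are checked against exhaustive cross-join
enumeration on fixtures, and loosening any single threshold can only grow
the edge set.

## Synthetic data

The generator produces datasets whose ground truth matches what each
stage estimates.

**Family content.** Core families appear in every genome. In *open* mode,
each accessory family receives an occurrence probability p drawn from a
Poisson process with intensity `A p^(-1-gamma) dp` on `(p_min, 1]`,
`A = kappa / Gamma(1-gamma)`, `p_min = 1/(4 n_genomes)`, and every genome
carries it independently with probability p. Integrating the intensity
gives the expected number of families first seen in the i-th genome as
`~ kappa * i^(gamma-1)` — Heaps-law accumulation with exponent gamma and
Poisson jitter — and because genomes are exchangeable the same exponent
governs the curve under *any* genome ordering, so rarefaction recovers it.
The expected pan curve is
`core - A/gamma + (kappa/gamma) * Gamma(1-gamma) * Gamma(n+1)/Gamma(n+1-gamma)`;
the defaults (core = 400, kappa = 150, gamma = 0.3) sit near the regime
`core ~= A/gamma` in which the additive constants cancel and the curve is
an almost pure power law, so the offset-free log–log fit is unbiased for
gamma (realized exponent ~0.25 at n = 60; the shortfall from 0.3 comes
from the p_min truncation of the rare-family tail). In *closed* mode a
finite pool (default 600 families, 400 of them core) is sampled with
per-family occupancy probabilities drawn once from U(0.2, 0.8), so the pan
curve saturates by roughly 20 genomes.

**Sequences.** Each family's ancestral CDS is drawn codon-by-codon from a
usage distribution with uniform amino-acid weights and within-family codon
weights `exp(bias * z_c)` for a fixed preference vector z_c (a model
constant chosen non-positional, so planted bias is visible to the
positional null). Core families use `core_codon_bias` (default 2.0),
others `noncore_codon_bias` (default 0.5). Genome copies evolve
independently from the ancestor (a star tree, ks_target/2 per branch)
under a per-codon proposal process: proposals pick one of the nine
single-nucleotide changes uniformly at rate `3 * ks_branch` per codon;
synonymous proposals are always accepted and nonsynonymous ones with
probability omega_target. A proposal that would create a stop codon is —
if accepted — redirected to a uniformly chosen viable nonsynonymous
neighbour of the current codon rather than discarded: NG site counting
treats stop-adjacent changes as nonsynonymous sites, so outright
rejection would depress the realized nonsynonymous rate by the
stop-adjacent fraction (~4-7%) and bias omega-hat low (measured 0.92-0.94
at omega = 1.0 under rejection); with redirection the accepted synonymous
events per NG synonymous site equal ks_branch and the accepted
nonsynonymous events per NG nonsynonymous site equal
`omega_target * ks_branch` for every codon, so pairwise Ks is calibrated
to ks_target and NG recovery of omega is unbiased (measured means 0.103,
0.206, 1.00 at planted 0.1, 0.2, 1.0). ks_target > 1 is refused because it approaches Jukes–Cantor
saturation at the default lengths. Default gene length is gamma-
distributed with mean 150 codons (minimum 60) — realistic order for
bacterial genes and small enough that full-pipeline validation runs in
minutes on one CPU; the Ka/Ks recovery checks use 300-codon pairs.

**Feature tables.** Genome sizes are uniform on 1.7–3.3 Mb (the observed
bifidobacterial range). A feature planted at Spearman rho_s uses a
Gaussian copula on the size ranks with Pearson parameter
`2 sin(pi rho_s / 6)`, whose Spearman correlation is exactly rho_s;
targets of 1 are pure monotone transforms (realized rho exactly +/-1) and
targets of 0 independent noise.

**What the synthetic validation does not show.** Generated families are
gapless (substitutions only), so clustering and codon alignment are not
stressed by indels or domain shuffling; there are no paralogs, no
horizontal transfer of sequence (mobilome quantities exist only as
feature-table counts), no GC/strand composition structure, and genomes are
conditionally independent given the family model, unlike phylogenetically
structured real strain collections. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated models, not
robustness to every property of real assemblies.

## Validation problem sizes

The package-level validation (tests and `scripts/acceptance.py`) uses: the
full 61-codon and 61x61-pair NG tables; 200 pairs x 300 codons per omega
recovery setting (omega in {0.2, 1.0}, Ks 0.5); 10 seeds x 60 genomes per
openness mode (matrix level); one 20-genome dataset with 400 core + ~200
accessory families for exact clustering recovery; 56-genome entropy runs
with 500 equal-bias replicates at the codon-count level; 1000 random
profiles for DKL nonnegativity; 100 random matrices for rarefaction
invariants; toy interolog fixtures small enough for exhaustive
enumeration. These sizes were chosen so each conclusion is measured at the
scale it needs while a complete run stays within a few minutes on one CPU.

## Reproducibility

Every stochastic component takes an explicit seed; the pipeline derives
per-stage seeds from the global seed by hashing the stage name, so stages
can be rerun in isolation. Reruns with the same config and seed produce
byte-identical outputs, which the manifest's SHA-256 checksums make easy
to verify.
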