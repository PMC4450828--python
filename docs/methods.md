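# Methods

This note records the modelling conventions, default parameters, and
validation scope of the package. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Codon substitution model

The substitution process runs on the 61 sense codons of the standard
genetic code (configurable to any NCBI table). The instantaneous rate
from codon *i* to *j* is nonzero only for single-nucleotide changes:

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

* `pi` — equilibrium codon frequencies. Default **F3x4**: products of
  position-specific nucleotide frequencies estimated from the alignment,
  stop-codon mass renormalised, unobserved codons floored at 1e-10.
  "observed" (empirical codon frequencies, pseudocount 0.5) and "uniform"
  are available; every output records which scheme was used. The choice
  matters at the percent level for Ka/Ks; uniform is the analytically
  transparent option used by most tests.
* `kappa` — transition/transversion rate ratio, optimized within
  [0.1, 50], default start 2 (a typical vertebrate nuclear value).
* `omega` — nonsynonymous/synonymous rate ratio, optimized within
  [1e-4, 50].

The matrix is reversible; `exp(Qt)` is computed through the symmetric
eigendecomposition under the `sqrt(pi)` similarity transform, which is
both faster and more stable than a general matrix exponential and is
cross-checked against `scipy.linalg.expm` in the tests.

**Branch-length units and rescaling.** A branch length is the expected
number of substitutions per codon *under the model being scored* (the
codeml convention). Concretely, the unscaled matrix for a branch runs
for time `t_b / rbar_b`, where `rbar_b` is the equilibrium substitution
rate averaged over site classes with that branch's omegas. For the
free-ratio model this reduces to scaling each branch by its own omega's
rate; for branch-site fits the normalisation is recomputed from the
current mixture at every likelihood evaluation. Ka/Ks values depend on
this convention, which is why it is spelled out here.

**Site opportunities.** Synonymous and nonsynonymous sites per codon
(S + N = 3) are defined by the neutral mutational flux of the 61-state
chain: S = 3·rho_S/(rho_S + rho_N) where rho_S, rho_N are equilibrium
rates into synonymous and nonsynonymous neighbours at omega = 1.
Mutations into stop codons do not exist in the state space and therefore
do not count as opportunity (with uniform frequencies and kappa = 1 this
gives S = 0.764, from the 134 synonymous vs 392 nonsynonymous
sense-to-sense single-base neighbour pairs). Fitted `(t, omega)` convert
to per-branch Ka and Ks so that `Ka·N + Ks·S = t` per codon and
`Ka/Ks = omega` exactly; expected substitution counts are
`n_b = Ka_b · N · L` and `s_b = Ks_b · S · L` for an L-codon gene.

## Estimators

**Free-ratio ML.** Joint bounded L-BFGS-B over log-parameters
(`kappa`, all `t_b` in [1e-6, 20], all `omega_b`), 3 seeded multi-starts
by default, tolerance 1e-8 on the log-likelihood. Rooted binary input
trees are first collapsed at the degree-2 root, whose two adjacent
branches are not separately identifiable under a reversible model. A
branch driven to the lower length bound (no substitutions) or to the
omega ceiling (no synonymous substitutions, Ks = 0) gets `omega = NaN`:
missing, never a pseudo-count, because pseudo-values bias the
genome-wide sign test.

**Nei–Gojobori (1986) counting.** Independent of the likelihood
machinery; used as a cross-check. Conventions: site fractions exclude
mutations to stop codons from numerator and denominator; multi-hit
codons average over all minimal substitution pathways with equal
weights, pathways through stops excluded and weights renormalised (in
the standard code every sense-codon pair retains at least one valid
pathway); proportions are Jukes–Cantor corrected, with p >= 3/4 flagged
as saturated and the rate reported as NaN.

**Lineage sign test.** Among genes with omega defined on both lineages
and unequal, the count with `omega_F > omega_L` is tested against
Binomial(n, 1/2), one-sided, by direct log-space pmf summation (exact to
1e-12 against rational-arithmetic summation for n <= 200; stable in the
2^-80 tails). Fewer than 10 informative genes flags the result
low-power. This per-gene construction is the package's reading of the
published lineage-level "binomial test", which is not fully specified at
the source; the concatenation-resample mean is reported alongside as the
"mean value" estimator.

**Category test.** For each category with strictly more than 20 member
genes, aggregate expected nonsynonymous counts on the two lineages,
round half-up to integers, and test against the genome-wide proportion
`p_hat = sum(n_F) / (sum(n_F) + sum(n_L))`, one-sided in each direction;
flag at raw P < 0.05 exactly as published practice does. A
Benjamini–Hochberg column is emitted but does not drive the flag. A
gene-level variant (each gene one trial) is available behind
`method="genes"`. Note the statistic is *relative*: in a genome where
some categories are truly accelerated, the unaccelerated remainder sits
below `p_hat` and can legitimately flag in the other direction; only
fully null genomes test the nominal error rate.

**Concatenation resample.** R replicates each draw k genes without
replacement (independently across replicates; the source is silent on
the scheme), concatenate, and refit the free-ratio model — estimating
lineage omega on the concatenation, not averaging per-gene omegas.
Defaults k = 150, R = 10,000; fully reproducible from one seed via
`numpy` SeedSequence spawning.

**Branch-site model A.** Classes 0 (`omega0` everywhere), 1 (neutral),
2a (`omega0` background / `omega2` foreground), 2b (neutral background /
`omega2` foreground), proportions `(p0, p1, p2·p0/(p0+p1),
p2·p1/(p0+p1))`. Two-step fitting: branch lengths and kappa are
estimated once under the one-ratio model and held fixed; the mixture
parameters are then optimized for the null (`omega2 = 1`) and the
alternative. The alternative is seeded from the null optimum in addition
to its 5 multi-starts, which guarantees nesting
(`lnL_alt >= lnL_null`) structurally — the omega2 = 1 boundary is an
attractor and a fresh optimizer can otherwise land a few 1e-5 below the
null. codeml instead re-optimizes branch lengths per model; the
two-step approximation was chosen for speed, is standard practice in
fast implementations, and re-optimizing the foreground length was
prototyped and did not change the operating characteristics (see
Limitations). The LRT uses chi-square with 1 df, not the 50:50 boundary
mixture — the conservative common practice.

**BEB.** Per-site posterior of classes 2a+2b, averaging over a uniform
discrete prior: 10 grid points per dimension for `omega0` in (0, 1) and
`omega2` in [1, 11), and the triangular `(p0, p1)` grid at the same
resolution; grid points are weighted by their whole-alignment
likelihood. Branch durations and per-branch normalisation are frozen at
the alternative-model MLE: grid points re-weight the site classes but do
not re-time the tree.

**PSG filter.** All three strict: LRT p < 0.05, `omega2 > 1`, >= 1 site
with posterior > 0.95. The published manual alignment-curation step is
replaced by an automated screen: a candidate whose every supporting site
lies within 5 codons of a column removed during QC is dropped and
flagged for human review — manual curation is not reproducible.

## QC and input conventions

Columns containing a gap, an ambiguous (non-ACGT) codon, or a stop in
any taxon are deleted whole (no per-taxon masking); stop-containing
columns are logged rather than raising, since trimmed CDS predictions
carry terminal stops. Alignments shorter than 150 nt after QC are
discarded (retention at exactly 150 nt; a threshold off the codon grid
rounds up). Ortholog clusters keep only members with confidence >= 1.0
and survive only with exactly one gene per configured species.
4-fold-degenerate site extraction takes third positions of columns where
*every* taxon's codon lies in a four-fold family — the conservative
cross-taxon rule. Positions are 0-based internally and 1-based in all
outputs.

## Synthetic data

The simulator evolves codons down the tree with the same rate matrices
and the same branch-scaling convention the estimators assume, so planted
parameters are recoverable in expectation. The default scenario is a
caricature of a two-pair comparative transcriptome study: five taxa
(two congeneric high/low pairs and an outgroup), 200 genes of 200–400
codons, uniform codon frequencies (analytic transparency; F3x4-style
skew available), kappa = 2, background omega = 0.2 (strong purifying
selection typical of vertebrate orthologs), 10 categories of 25 genes
with 2 planted accelerated categories (foreground omega x3), 5 planted
PSGs (20% of sites in the selected classes, omega2 = 4). Site classes
are i.i.d. along the gene; gene lengths uniform on the configured range;
planted accelerated categories get dedicated member genes while null
categories sample from the remaining pool with overlap, as real GO
annotations do.

What the simulator does **not** emulate: alignment error, annotation
noise, gene-level rate heterogeneity within a class, site
autocorrelation, codon-usage differences between taxa. A green test
therefore establishes correctness of the estimators and calibration of
the tests under the model's own assumptions — not robustness to
misspecification.

## Numerical choices

* Per-pattern log-likelihoods are floored at the smallest representable
  log (~-745) instead of -inf: exact zeros arise only from
  eigendecomposition round-off at tiny branch lengths and would poison
  quasi-Newton line searches.
* Partial likelihoods are rescaled per pattern at every internal node.
* Optimization is in log-space for positive parameters and
  stick-breaking space for mixture proportions; expected-count rounding
  is half-up; seeds for replicate streams are spawned from a single
  SeedSequence so every output records one seed.
* Degenerate inputs: identical sequences give branch lengths at the
  lower bound and `omega = NaN`; saturated NG86 comparisons are flagged
  rather than clipped.

## Known limitations

* This is not codeml: branch lengths are fixed at one-ratio estimates
  during branch-site fits, and numerical details (frequency flooring,
  optimizer, BEB grid edges) differ, so third-decimal agreement with
  PAML outputs should not be expected.
* BEB site identification is intrinsically weak when selected sites
  carry on the order of one expected foreground substitution: posteriors
  then cluster just below the 0.95 bar. In the validation suite the
  LRT-level detection (p < 0.05 with omega2 > 1) reaches its nominal
  power target, while the full three-way PSG filter recovers ~60–70% of
  planted genes in the same world; the corresponding acceptance test
  asserts both bars and the second one fails honestly rather than being
  weakened.
* The chi-square(1) LRT reference is conservative at the boundary; null
  rejection rates in the tests run well below 0.05.
* The category test is relative to the genome-wide proportion; it cannot
  call absolute acceleration, and in a genome with real signal the
  complement of the signal is displaced by construction.
* No gamma rate variation across sites in the free-ratio model, no
  clade models, no empirical codon models.
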