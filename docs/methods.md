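# Methods

## The model

The package infers the demographic history of two diverging populations —
brown bears (*Ursus arctos*, "uar") and polar bears (*U. maritimus*, "uma")
— under an isolation model with three parameters: the effective population
sizes `N_uar` and `N_uma` (diploid individuals, constant through time) and
the split time `T` (generations).  Backward in time, sampled lineages
coalesce within their population at pairwise rate `1/K` per generation,
where `K` is the effective chromosome count (`2N` for autosomal loci, `N`
for mtDNA), and both populations merge into an ancestral population at time
`T`.  There is no migration, growth, or bottleneck.  The ancestral
population takes the brown-bear size by default — the polar lineage is
treated as arising from within brown-bear diversity — with a configuration
override (`k_anc`), since the choice is not identifiable from the data the
summaries retain and has to be fixed by convention.

Mutation follows the infinite-sites model at a per-site, per-generation
rate; autosomal loci additionally recombine internally with a crossover rate
equal to the mutation rate (per locus, so the scaled crossover rate equals
the scaled mutation rate), while mtDNA does not recombine.  The calibrated
rates shipped as constants are 1.314e-8 substitutions/site/generation for
the autosomal loci and 7.036e-8 (Set-I edit) or 7.838e-8 (Set-II edit) for
mtDNA, derived from an average outgroup distance assuming a 12-MYA panda
split and 10-year generations; both Set rates are configurable because it is
not recorded which one drove the Set-II simulations.  All year conversions
use the 10-year generation time.

## Simulation engine

The coalescent simulator is written in-house and parametrized directly by
chromosome count and generations, avoiding the `4N0` rescaling of the
classic simulators; conversion helpers to and from that convention are
provided and unit-tested.  Without recombination it builds one explicit
genealogy (exposed with branch times, subset TMRCAs, and a Newick dump).
With recombination it runs a Hudson-style ancestral recombination graph:
each lineage carries its intervals of ancestral material with the bitmask of
descendant samples, crossovers split lineages at a per-lineage rate
proportional to the span of carried material, and segments that reach their
marginal MRCA are retired.  Mutations are Poisson on branch length x rate,
assigned to branches (or interval-pieces) proportionally and placed at
continuous positions, then discretized to unique 1-based coordinates.  In
the (extreme-parameter) case where more mutations fall than the locus has
base pairs, spectra remain valid and only FASTA rendering becomes
impossible; the simulator does not abort inside an ABC loop.

The engine is cross-checked in the test suite against closed forms
(`E[TMRCA] = 2K(1 - 1/n)`, Watterson's `E[S] = theta * sum 1/i`) and against
msprime run with the equivalent scaled parameters.

## Summaries

Sequence data are reduced to frequency spectra.  For the autosomal data:
the derived-allele site frequency spectrum per population (`SFS_uar`,
`SFS_uma`) and a two-dimensional haplotype frequency spectrum (2D-HFS) in
which each distinct haplotype at a locus tallies at (copies among brown
bears, copies among polar bears); spectra are pooled across loci.  For
mtDNA: a joint 2D-SFS over (derived copies in brown, derived copies in
polar).  Bin counts follow Sturges' rule `round(1 + log2 x)`; the frozen
default autosomal layout is 8 derived-allele bins (1-4 ... 29-36, the last
bin wider) per population plus a 7x7 haplotype grid (bins 0, 1-6, ...,
31-36) minus the structurally empty (0,0) cell — 64 dimensions in the fixed
block order `SFS_uar | SFS_uma | 2D-HFS` (row-major).  mtDNA layouts use the
full spectrum per axis (or coarser configured intervals on the polar axis),
always excluding (0,0); the fixed-derived cell and any further exclusions
are configuration-driven because the printed bin totals of the original
figures cannot be reconstructed from their captions, and the realized
dimension is reported at run time rather than asserted.

## Kernel-ABC

For `i = 1..n`: draw `theta_i = (N_uar, N_uma, T)` from independent
log-normal priors with natural-scale mean `mu` and variance `mu^2`
(equivalently `sigma2_log = ln 2`, `mu_log = ln mu - ln2/2`); simulate a
dataset; summarize to `s_i`.  The posterior mean at the observed summary
`s_obs` is the kernel ridge regression prediction

    E[theta | s_obs] ~= mean(theta) + k_obs^T (G + n lambda I)^(-1) (theta - mean(theta))

with Gaussian kernel `k(u, v) = exp(-||u - v||^2 / (2 sigma^2))`.  Summary
coordinates are z-standardized with training-set moments before kernel
evaluation (site counts and haplotype tallies live on different scales);
targets are regressed on the natural parameter scale.  The default prior
sets are LN(30000), LN(10000), LN(100000) for the autosomal fit and
LN(200000), LN(10000), LN(30000) for mtDNA.

`(sigma^2, lambda)` are selected by seeded 10-fold cross-validation
(contiguous folds after a shuffle; prediction error averaged over
standardized parameter coordinates) over a grid: `sigma^2` centered on the
median pairwise squared distance (x1/4, x1, x4) and `lambda` geometric in
1e-6..1e-1.  Inside `run_abc` the CV runs on a seeded subsample of at most
1,000 rows before the final fit on the full table; at the table sizes used
the selected grid point is insensitive to the subsampling while the cost of
full-table CV is not.  The whole algorithm is repeated `R` times with
independent seeds; the mean and SD of the posterior means over replications
are reported.  Full-scale settings are `n = 20,000`, `R = 100`; the analysis
drivers and tests run scaled-down versions (noted inline) chosen so each
driver finishes in minutes on one core.

TMRCA estimation reuses the same regression machinery with the demographic
parameter replaced by the TMRCA of a chosen lineage subset (for example one
brown chromosome plus the whole polar clade, matching the geographic-lineage
geometry), simulated under the fitted model; since mtDNA does not recombine
each replicate contributes one genealogy and its exact subset TMRCA.

## Data editing and polarization

Ancestral states are assigned per segregating site by outgroup comparison:
if the two black-bear sequences agree and their allele occurs in the
ingroup, it is ancestral; otherwise the panda allele is ancestral if it
occurs in the ingroup; otherwise the site is dropped and logged.  Sites with
more than two ingroup alleles (infinite-sites violations) and sites with
gaps or ambiguity codes in any retained sequence are excluded.  For
monomorphic ingroup columns the outgroup state stands alone; columns whose
outgroup-defined ancestral allele is absent from the ingroup are
fixed-derived and kept only where a 2D-SFS layout includes the fixed cell.

Recurrent mutation in mtDNA is detected with the four-gamete test (all of
00/01/10/11 across a site pair).  Two editings make an alignment
infinite-sites compatible: drop implicated *sequences* — iteratively remove
the ingroup sequence carrying a rarest gamete in the most incompatible
pairs, ties broken by lexicographically smallest id, then truncate to the
longest incompatibility-free prefix window if a removal budget stopped the
loop early — or drop implicated *sites* (every column in at least one
incompatible pair).  The sequence-removal degree and tie-break are this
package's determinization of a procedure whose original criteria were not
recorded; the prefix-window rule generalizes the original coordinate-range
truncation.

## Synthetic data

The generator emulates the study's data shapes: 14 autosomal loci of 500 bp
(locus lengths were never published; 500 bp is the configurable default)
with 36 + 36 sampled chromosomes, and a single mtDNA locus with 9 + 26
haploid sequences.  Renders each locus to FASTA by mapping
ancestral/derived states to random distinct bases over a random background,
and writes ground truth (generating parameters, per-locus TMRCA, ancestral
base per site).  Outgroups extend the same genealogy: a panda-like outgroup
at the configured divergence (default 2.4M generations = 12 MYA) and two
black-bear-like outgroups at one third of it, their pair splitting at 1/30
of it so they occasionally disagree.  Outgroup-path substitutions land on
the outgroup branches at non-segregating positions, so the recorded truth
is exact and polarization can be validated against it; real data differ in
exactly this respect (outgroup back-mutations and alignment error exist),
so passing polarization tests bounds algorithmic, not biological, error.
Recurrent mutations are injected by striking an existing segregating site a
second time on a lineage chosen to create at least one four-gamete
incompatibility whenever a compatible partner site exists.

What the synthetic data do not emulate: real locus names and lengths,
base-compositional heterogeneity, rate variation along the genome,
alignment gaps, and any post-split migration.

## Neutrality tests

Tajima's D, Fu & Li's D and F (outgroup versions, with the derived-singleton
count as the external-mutation class), and Fay & Wu's H
(`H = pi - theta_H`, `theta_H = sum 2 xi_i i^2 / (n(n-1))`), all computed
from the binary matrix.  Significance comes from the null distribution of
each statistic over coalescent simulations of a constant-size population
conditioned on the observed number of segregating sites (mutations placed
multinomially on branch lengths), with two-tailed p-values via the doubled
smaller tail and the +1 correction.  Conditioning on S and the two-tailed
convention follow the behavior of the standard desktop implementation the
field uses; the tails are a documented choice.

## Derived quantities

Autosomal effective sizes are doubled (`N_aDNA = 2 N_e`) and mtDNA sizes
halved (`N_mtDNA = N/2`, the haploid-size convention of the original
analysis, applied verbatim); the ratio `N_mtDNA / 2N_e` is compared against
the 0.25 equilibrium expectation for random mating, equal sex ratio, and
Poisson offspring.  Times convert to MYA at 10 years/generation, rounded to
two decimals.

## Numerical choices and scaling

- Cholesky solves with `G + n lambda I`; `lambda = 0` is rejected with a
  pointer to positive regularization.
- Seeds: one root `SeedSequence` spawns independent child streams per locus,
  per replication, and per grid point, so any component is reproducible in
  isolation.
- The acceptance-style recovery experiment builds the `R = 5` training
  tables once and evaluates all 10 observation trials against them: the
  trial average then integrates over observation noise (the quantity the
  recovery tolerance is about) at a fifth of the cost of fully independent
  tables.
- Problem sizes in tests and drivers: recovery uses `n = 3,000`, `R = 5`,
  10 trials; the drivers use `n = 1,500-2,000`, `R = 2-3`; Monte-Carlo
  oracles use 2,000-20,000 replicates, with tolerances stated as multiples
  of the measured standard error.

## Known limitations

- Posterior uncertainty is summarized only by the replication SD of the
  posterior-mean predictor, not by a posterior distribution.
- The ARG path reports marginal-tree TMRCAs (length-weighted mean per
  locus) but no explicit marginal trees; subset-TMRCA regression therefore
  requires a non-recombining model, which is the only place it is needed.
- The mtDNA excluded-cell sets are conventions, not recoveries of the
  original binning; comparisons across tools should match layouts first.
- With 36 + 36 chromosomes and ~100 segregating sites, `N_uma` and `T` are
  weakly identified; recovery tolerances reflect that, and nothing in the
  package sharpens identifiability beyond what the summaries carry.
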