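# ursabc

Kernel-ABC demographic inference for the brown-bear / polar-bear divergence
problem, exercised end-to-end on synthetic data.

Brown bears (*Ursus arctos*, `uar`) and polar bears (*U. maritimus*, `uma`)
show notoriously discordant gene trees between autosomal loci and
mitochondrial DNA.  A population-genetic way through the discordance is to
fit an explicit divergence model to both kinds of data and compare the
fitted effective sizes and split times.  This package implements that
analysis as a reusable pipeline for anyone studying two-population
divergence with high-dimensional frequency-spectrum summaries:

- **Model.** Two populations of constant effective sizes `N_uar`, `N_uma`
  (diploid individuals) split `T` generations ago from an ancestral
  population; no migration.  Autosomal loci mutate and recombine internally
  at equal per-site rates under infinite sites; mtDNA is haploid and
  non-recombining.
- **Summaries.** Per-population site frequency spectra `xi_i` (sites whose
  derived allele occurs on `i` chromosomes) and a 2D haplotype frequency
  spectrum over (copies in `uar`, copies in `uma`) pooled over loci, binned
  by Sturges' rule into a fixed 64-dimensional vector; for mtDNA a joint 2D
  site frequency spectrum.
- **Inference.** Kernel approximate Bayesian computation: draw
  `theta_i = (N_uar, N_uma, T)` from log-normal priors `LN(mu, mu^2)`,
  simulate with an in-house coalescent (with an ancestral-recombination-graph
  path for recombining loci), summarize to `s_i`, and predict the posterior
  mean at the observed summary by Gaussian-kernel ridge regression,

      E[theta | s_obs] ~= mean(theta) + k_obs^T (G + n*lambda*I)^(-1) (theta - mean(theta)),

  with `(sigma^2, lambda)` chosen by seeded 10-fold cross-validation and
  the whole algorithm replicated for a Monte-Carlo SD.
- **Downstream.** Outgroup polarization (black-bear consensus, panda
  fallback), four-gamete detection of recurrent mtDNA mutation and two
  editing strategies (drop sequences / drop sites), TMRCA estimation by
  regressing simulated coalescence times on summaries, Tajima's D, Fu & Li's
  D and F, Fay & Wu's H with fixed-S coalescent p-values, and the
  `N_mtDNA / N_aDNA` ratio bookkeeping against the 0.25 equilibrium
  expectation.

See `docs/methods.md` for the model, conventions, and numerical choices.

## Worked example

The analysis scripts run the whole pipeline on synthetic data generated at
a known truth (autosomal truth `N_uar = 40,000`, `N_uma = 8,000`,
`T = 120,000`; mtDNA truth `120,000 / 5,000 / 30,000`):

```bash
python analysis/01_generate_data.py    # simulate FASTA + truth records
python analysis/02_summarize.py        # polarize, edit mtDNA, summarize
python analysis/03_infer_adna.py       # kernel-ABC on the autosomal summaries
python analysis/04_infer_mtdna.py      # kernel-ABC on both edited mtDNA sets
python analysis/05_tmrca.py            # TMRCA of polar clade / brown+polar
python analysis/06_neutrality.py       # neutrality statistics + p-values
python analysis/07_prior_sensitivity.py
python analysis/08_report.py           # derived quantities and ratios
```

`03_infer_adna.py` (n = 3,000 simulations, R = 3 replications, seed 42)
prints:

```
parameter  posterior_mean  replication_sd    truth  rel_error
    n_uar         44755.7          1478.8  40000.0      0.119
    n_uma         12288.8           612.9   8000.0      0.536
    t_div        118974.9          3292.7 120000.0      0.009
```

`N_uar` and `T` are recovered tightly; `N_uma` scatters more on any single
dataset (the polar-bear spectrum carries the least information at these
sample sizes) — the test suite's recovery experiment shows the error
averaged over ten observed datasets stays under 35% per coordinate.
`04_infer_mtdna.py` recovers the mtDNA truth well from the
sequence-exclusion edit (raw `130,986 / 4,753 / 38,714`) and, instructively,
underestimates `N_uar` and `T` from the site-exclusion edit, which had
stripped 229 genuine sites implicated by three injected recurrent
mutations.  The same artifact shows up in `06_neutrality.py`: the
site-stripped set turns Fu & Li's D significant (p = 0.0066) on perfectly
neutral data, while the sequence-exclusion set shows no signal.

`08_report.py` also applies the derived-quantity bookkeeping to the
published posterior means as an arithmetic cross-check and prints the
mtDNA-to-autosomal effective-size ratios `0.723 / 0.622` (brown) and
`0.149 / 0.269` (polar), the `2 N_e` doubling `15,734`, and the
`136,597 generations -> 1.37 MYA` conversion.

## Layout

```
src/ursabc/        library: synthdata, seqio, coalsim, sumstats, kabc,
                   demography, neutrality, cli
analysis/          numbered narrative drivers (write tables to results/)
tests/             pytest suite incl. acceptance criteria
scripts/           acceptance.py
docs/methods.md    model, conventions, numerical choices, limitations
```

A thin `ursabc` command-line wrapper exposes the drivers' operations
(`synth`, `simulate`, `summarize`, `infer`, `tmrca`, `sensitivity`,
`report`, `neutrality-test`) for shell use; the library functions are the
primary interface.
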