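# omegascan

Comparative molecular-evolution scans on protein-coding genes: per-branch
Ka/Ks estimation under a Goldman–Yang codon model, lineage-level
acceleration tests with concatenation resampling, GO-category
accelerated-evolution binomial tests, and a branch-site positive-selection
scan with strict candidate-gene filters. A codon-evolution simulator with
planted effects makes every stage testable from a single seed, without any
external data.

The package is aimed at comparative transcriptomics studies of the kind
used to ask whether a focal lineage (say, a high-altitude species) evolves
faster than its lowland sister, which functional categories drive the
acceleration, and which individual genes show branch-specific positive
selection.

## The models

**Codon substitution model.** Substitution rates between sense codons
*i → j* that differ at one position:

```
q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]
```

with equilibrium codon frequencies `pi` (F3x4 by default), transition /
transversion ratio `kappa`, and nonsynonymous/synonymous rate ratio
`omega` = Ka/Ks. Branch lengths are expected substitutions per codon.
Likelihoods are computed by Felsenstein pruning over unique site patterns;
`exp(Qt)` comes from the symmetric eigendecomposition of the reversible
rate matrix.

**Free-ratio model.** Each branch of the unrooted tree gets its own
`omega_b`; joint ML over `kappa`, all branch lengths and all omegas.
Fitted `(t_b, omega_b)` convert to per-branch Ka and Ks through the
mutational-opportunity site counts (S + N = 3 per codon), so that
`Ka*N + Ks*S = t` and `Ka/Ks = omega` exactly. A Nei–Gojobori (1986)
counting estimator with Jukes–Cantor correction is included as an
independent cross-check.

**Lineage and category tests.** Per-gene sign test between two lineages'
omegas (one-sided binomial against 1/2); per-GO-category binomial test of
aggregated nonsynonymous substitution counts against the genome-wide
proportion, for categories with more than 20 genes, flagged at raw
P < 0.05; and a resampling estimator that concatenates k randomly chosen
orthologs R times and refits the free-ratio model (defaults k = 150,
R = 10,000).

**Branch-site model A.** Four site classes — purifying `omega0` on all
branches, neutral, and two classes with `omega2 >= 1` restricted to a
designated foreground branch — against a null with `omega2 = 1`, compared
by a chi-square(1) LRT. Per-site posteriors of positive selection come
from Bayes empirical Bayes averaging over a 10-point prior grid per
parameter. A positively selected gene (PSG) must pass all of: LRT
p < 0.05, `omega2` > 1, and at least one site with BEB posterior > 0.95.

## Worked example

Simulate a small two-pair study (high/low-altitude *Phrynocephalus*-like
pair, high/low *Rana*-like pair, outgroup) in which one GO category has a
3x elevated foreground omega, then ask whether the high-altitude branch
runs faster:

```python
from omegascan import (SimulationScenario, simulate_study, fit_free_ratio,
                       lineage_rates_table, lineage_sign_test, ng86_pairwise)

scenario = SimulationScenario(n_genes=12, codons_range=(150, 250),
                              n_categories=2, category_size=4,
                              n_accel_categories=1, accel_multiplier=3.0,
                              n_psg=0)
study = simulate_study(scenario, seed=11)
fits = [fit_free_ratio(aln, study.tree, seed=1) for aln in study.alignments]
rates = lineage_rates_table(fits, ["highPhryno", "lowPhryno"])
print(rates.pivot(index="gene", columns="lineage", values="omega").head(6).round(3))
sign = lineage_sign_test(rates, "highPhryno", "lowPhryno")
print(f"genes with higher omega on the high-altitude branch: "
      f"{sign.n_a_greater}/{sign.n_informative} (one-sided p = {sign.p_value:.4f})")
```

prints

```
lineage    highPhryno  lowPhryno
gene
gene_0000       0.784      0.000
gene_0001         NaN      0.543
gene_0002       0.387      0.366
gene_0003       0.157        NaN
gene_0004       0.306      0.159
gene_0005       0.439      0.341

genes with higher omega on the high-altitude branch: 7/9 (one-sided p = 0.0898)
```

Each cell is that gene's fitted omega on one terminal branch. `NaN` marks
branches whose ratio is undefined (no substitutions, or no synonymous
substitutions — Ks = 0); such genes drop out of the sign test rather than
entering with a pseudo-value. At 12 genes, 8 of them with a genuinely
elevated foreground omega, the sign test leans the right way (7/9) but is
not yet significant — the genome-scale version of this comparison is what
drives the headline p-value in a real study.

## Command line

```bash
omegascan simulate --seed 7 --out study/          # synthetic study + truth
omegascan qc study/alignments --out qc/           # column QC + 150 nt filter
omegascan rates qc/ --tree study/tree.nwk --lineages highPhryno,lowPhryno \
    --seed 1 --out rates.tsv
omegascan accel rates.tsv --go-map study/go_map.tsv \
    --focal highPhryno --sister lowPhryno --out categories.tsv
omegascan possel qc/ --tree study/tree.nwk --foreground highPhryno \
    --seed 1 --out psg.tsv
omegascan run-all pipeline.cfg                    # everything, from a config
```

`pipeline.cfg` is a flat `key = value` file (see `PipelineConfig` for the
knobs); every run writes a JSON manifest with the seed, the configuration
hash and per-stage gene counts, and reruns with the same seed and config
are byte-identical.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

simulates a seeded synthetic study (one planted accelerated category, two
planted PSGs), runs the complete pipeline — QC, free-ratio rates, lineage
sign test, concatenation resample, category scan, branch-site scan — and
writes the stage summary under `results/pipeline/`. The JSON written to
`--out` is an empty object; this build defines no numeric reproduction
targets, and the script's job is to demonstrate the end-to-end
computation from a seed.

See `docs/methods.md` for the modelling conventions, default parameters,
and the validation suite's scope and known limitations.
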