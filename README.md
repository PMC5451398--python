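# isvs-sim

Simulation and statistical assessment of **iterative sequencing and
variant screening (ISVS)** — a search strategy for the rare pathogenic
variants of an autosomal recessive disease gene, and a way to test the
disease association of the variants it finds *without a control group*.

## The problem and the method

Autosomal recessive diseases are typically caused by a limited set of
ultra-rare variants. Sequencing a whole patient cohort to find them is
expensive, and proving disease association for a variant seen in a
handful of patients is statistically hopeless with case/control counts.

ISVS exploits the structure of recessive inheritance. Starting from one
sequenced proband with a bi-allelic genotype, it alternates two cheap
steps until nothing new appears:

1. **screen** the whole cohort (a focused assay per variant) for every
   newly revealed variant, finding all carriers;
2. **sequence** the gene in every newly found carrier, revealing all of
   their variants.

Because a carrier of one pathogenic allele who is affected should carry
a second pathogenic allele *in trans* (on the other haplotype), the
cascade rapidly reaches the pathogenic variant set — formally, the
connected component of the seed patient in the bipartite patient–variant
carrier graph.

The same logic yields a pathogenicity statistic. For each variant found,
let **x** be its total number of carriers in the cohort and **y** the
number of those carriers that are homozygous for it or carry another
detected variant in trans. Pathogenic variants of a recessive gene pile
up in-trans partners (y ≈ x); rare benign variants do not (y ≈ 0).
Simulating many cohorts under a population model — disease prevalence
f1, fraction f2 of cases caused by the gene, bi-allelic population
frequency f3 = f1·f2, cumulative pathogenic allele frequency
q = √f3, per-variant allele frequencies drawn from Beta(0.5, 10) and
rescaled — calibrates, for every (x, y) cell, how often pathogenic vs
non-pathogenic variants land there. Two classifiers are built on this:

* an **empirical cell table** with a conservative cumulative count
  aggregation over pure-pathogenic cells, giving
  P(pathogenic | x, y) = cum_pat / (cum_pat + cum_nonpat);
* a two-feature **RBF-kernel SVM** with Platt-calibrated probabilities,
  reported as a likelihood ratio LR = p/(1−p), capped at 10⁷.

An observed variant table from a real cohort (carrier counts, partner
variants, control counts) can then be scored: allele frequencies,
patient-vs-control Fisher exact tests, and the simulation-calibrated
(x, y) evidence.

## Worked example

```python
from isvs import SimParams, run_experiment, likelihood_ratio

result = run_experiment(SimParams(n_sims=2000, master_seed=1))
s = result.summary
print(f"success_rate={s.success_rate:.4f} avg_steps={s.avg_steps:.3f}")
print(s.accuracy)
for cell in [(5, 4), (2, 2), (1, 1)]:
    print(cell, round(likelihood_ratio(result.model, *cell), 1))
```

prints (exact output of this snippet):

```
success_rate=0.9845 avg_steps=4.163
  classifier  confidence  accuracy  accuracy_se
0  empirical        0.50  0.970522     0.000655
1  empirical        0.95  0.918018     0.003498
2        svm        0.50  0.974648     0.000626
3        svm        0.95  0.902651     0.002451
(5, 4) 1112.6
(2, 2) 87.2
(1, 1) 9.6
```

Read: across 2000 simulated screens of a 2000-patient cohort, 98.45% of
runs found *every* bi-allelic patient, in ~4.2 screen-and-sequence
cycles on average; held-out variants are classified pathogenic vs benign
with 97% accuracy at the 0.5 probability threshold; and a variant seen
in 5 patients, 4 of them with an in-trans partner, has ~1100:1 odds of
being pathogenic under the calibrated model.

The same pipeline from the shell:

```bash
isvs simulate --out out/ --seed 1 --n-sims 2000
isvs assess --variants tmprss3 --calibration out/cells.tsv --out assessed.tsv
```

`isvs assess` scores the packaged observed variant table of a
2247-patient sensorineural-hearing-loss cohort screened for *TMPRSS3*
(13 rare variants with partner lists and control counts); `isvs sweep`
and `isvs mix` run parameter grids and two-population mixtures.

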