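# genoerode

Genomic-erosion analysis for small, fragmented populations of endangered
species. Given a multi-sample variant callset plus the usual annotation
sidecars (conservation scores, gene models, repeat and sex-scaffold masks),
the package quantifies how much genetic diversity a population has lost, how
inbred its individuals are, how large a burden of putatively deleterious
variation they carry, and what moving an individual between populations
(assisted gene flow) would risk introducing. It is aimed at conservation
geneticists working with handfuls of genomes per population — the regime
where every estimator choice has to be robust to n = 3–8 diploids.

A fully synthetic data generator with exact ground truth (planted
identity-by-descent tracts, known allele frequencies, labelled deleterious
sites) makes the entire pipeline testable end to end without any external
data.

## What it computes

- **Site filtering** — per-genotype depth (< ⅓ of the sample's mean
  coverage) and quality (GQ < 30) to missing; removal of indels and SNPs
  within ±5 bp of an indel; CpG-site, repeat and sex-linked-scaffold masks.
- **Heterozygosity** — per-individual θ, heterozygous sites per 1000 bp of
  callable genome.
- **Runs of homozygosity** — a windowed heterozygote-density scan; the
  genomic inbreeding coefficient F_ROH = (bp in ROH ≥ L) / genome length,
  reported at L = 100 kb (all ROH) and L = 2 Mb (recent inbreeding).
- **Relative mutational load** — the GERP-score-weighted mean over an
  individual's derived alleles at constrained sites:
  Σᵢ dᵢ·sᵢ / Σᵢ dᵢ over sites with score sᵢ > 4 (dᵢ = derived dosage), plus
  fixed-depth (six alleles per population) subsampling of deleterious
  derived alleles into private / pairwise-shared / shared-by-all classes.
- **Coding burden** — per-individual counts of loss-of-function, missense
  and synonymous variant sites carried, split by zygosity; per-population
  fixed and private LoF sites; per-donor **translocation risk** = number of
  the donor's LoF variants absent from the recipient population.
- **Selection scan** — per-gene Hudson F_ST (ratio of averages) for each
  population pair, branch lengths T = −ln(1 − F_ST), and the population
  branch statistic PBS_A = (T_AB + T_AC − T_BC)/2; infinite values are
  capped at the population's finite maximum and outliers called at PBS > 3.
- **Group comparisons** — unadjusted two-sided pairwise Welch t-tests,
  percent differences and temporal fold changes.

## Worked example

Simulate a three-population study (two populations also sampled a century
ago) with inbreeding planted in the Malay Peninsula population, then
estimate diversity, inbreeding, load and translocation risk:

```python
from genoerode import (
    default_config, simulate_dataset, detect_roh, froh,
    genome_heterozygosity, relative_load, burden, translocation_risk,
    pairwise_t_tests,
)
import pandas as pd

cfg = default_config(
    seed=1,
    inbreeding_f={"MalayPeninsula": 0.3, "MalayPeninsula:historical": 0.08,
                  "Borneo": 0.05},
)
data, truth, _ = simulate_dataset(cfg)

rows = []
for _, s in data.samples.iterrows():
    theta = genome_heterozygosity(data, s["id"], cfg.genome_length).theta
    segs = detect_roh(data, s["id"])
    rows.append((s["id"], s["population"], s["era"], theta,
                 froh(segs, cfg.genome_length, 100_000),
                 relative_load(data, s["id"]).relative_load,
                 burden(data, s["id"]).n_lof_total))
tab = pd.DataFrame(rows, columns=["sample", "population", "era", "theta",
                                  "froh_100kb", "rel_load", "n_lof"])
print(tab.groupby(["population", "era"])[
    ["theta", "froh_100kb", "rel_load", "n_lof"]].mean().round(3))

modern = tab[tab["era"] == "modern"]
for c in pairwise_t_tests(modern["froh_100kb"], modern["population"], "froh_100kb"):
    print(f"{c.group_a} vs {c.group_b}: mean {c.mean_a:.3f} vs {c.mean_b:.3f}, "
          f"t = {c.t:.2f}, p = {c.p_value:.2e}")

n, _ = translocation_risk(data, "Sumatra_mod1", "MalayPeninsula")
print(f"translocation risk Sumatra_mod1 -> MalayPeninsula: {n} novel LoF variants")
```

Output:

```
                           theta  froh_100kb  rel_load    n_lof
population     era
Borneo         historical  0.214       0.052     5.509  284.000
               modern      0.215       0.052     5.510  284.600
MalayPeninsula historical  0.205       0.081     5.512  284.333
               modern      0.157       0.303     5.509  274.667
Sumatra        modern      0.224       0.000     5.505  283.750
Sumatra vs Borneo: mean 0.000 vs 0.052, t = -160.01, p = 9.15e-09
Sumatra vs MalayPeninsula: mean 0.000 vs 0.303, t = -322.96, p = 9.59e-06
Borneo vs MalayPeninsula: mean 0.052 vs 0.303, t = -252.73, p = 1.47e-06
translocation risk Sumatra_mod1 -> MalayPeninsula: 14 novel LoF variants
```

Reading it: the recovered F_ROH ≥ 100 kb means (0.303, 0.052, ~0) match the
planted inbreeding targets (0.3, 0.05, 0) to within a tract length; the
inbred Malay Peninsula population shows depressed heterozygosity
(θ = 0.157 vs ~0.22 elsewhere), and the Welch tests separate the three
populations sharply. The translocation-risk count is the number of LoF
variants this particular Sumatran donor would introduce into the Malay
Peninsula gene pool.

The same stages are exposed as a CLI (`genoerode simulate | filter |
diversity | load-gerp | load-coding | pbs | run-all`); see
`genoerode --help`.

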