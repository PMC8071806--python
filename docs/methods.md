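# Methods

This note documents the models and procedures implemented in `genoerode`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions used where a published
description would be ambiguous.

## Data model

The central container is a sites × samples matrix of alternate-allele
dosages (0/1/2, with a missing sentinel), carried with per-site annotations
(ancestral allele, GERP conservation score, effect category, gene id) and
per-sample metadata (population, era, mean coverage). Coordinates are
1-based inclusive internally (VCF convention); BED inputs and outputs are
converted at the boundary.

Derived-allele dosage is obtained by polarizing against the recorded
ancestral allele (VCF `AA`): equal to the alternate dosage when the
ancestral allele is REF, flipped (2 − dosage) when it is ALT, and undefined
when the ancestral state is unknown or matches neither allele. Sites with
undefined polarization remain usable for heterozygosity and ROH (which
need only het/hom state) but are excluded from every derived-allele
computation (load, burden, sharing, translocation risk). Missing genotypes
are excluded from whatever count they would otherwise enter; they never
break an ROH run and never enter allele-frequency denominators.

## Site filtering

Per genotype (when depth/quality matrices are available): calls with depth
below `depth_fraction` (default ⅓) of that sample's mean coverage, or
genotype quality below 30, become missing. The depth rule is applied per
sample per genotype, mirroring per-individual VCF filtering; the quality
rule is mapped to the per-genotype GQ field because base-level qualities
are unavailable after calling — a documented substitution. Per site: indel
records are dropped from the SNP table; SNPs within ±5 bp (inclusive, i.e.
distance ≤ 5) of an indel position are removed; CpG positions (every C
immediately followed by G in the reference, both positions, case-
insensitive, ambiguous bases never matching), repeat intervals and
sex-linked scaffolds (supplied as a name list) are excluded. Filtering
only removes sites or sets genotypes missing — it never edits a retained
value — so it is idempotent and order-preserving.

## Heterozygosity

θ = 1000 × (heterozygous sites) / (callable length in bp). The callable
length counts all filtered-callable positions, not just variant sites, and
must be supplied by the caller (for synthetic data, the genome length).
This is direct genotype counting; it replaces read-level maximum-likelihood
estimation, which requires read data that is out of scope here. With
accurate genotypes the two coincide in expectation.

## Runs of homozygosity and F_ROH

The detector is a single documented sliding-window heterozygote-density
scan (published analyses typically cite external tools without parameters,
so the algorithm itself must be pinned down somewhere; here it is pinned
in code and prose). Per scaffold, over the sample's called sites in order:

1. A run starts at a homozygous site.
2. It extends one site at a time while (a) every window of `window_snps`
   consecutive sites within the run — the whole run while shorter than a
   window — contains at most `max_het_per_window` heterozygous calls, and
   (b) consecutive sites are at most `max_gap` bp apart.
3. When extension stops, the run is trimmed to its outermost homozygous
   sites and reported if it spans ≥ `min_length` bp and ≥ `min_snps`
   sites; scanning resumes after the run.

Because both run conditions are hereditary (any sub-run of a valid run is
valid), checking the trailing window at each extension step is equivalent
to checking every window, which is what the brute-force oracle in the test
suite does; the two must agree exactly, and do, on randomized instances.
The greedy left-to-right scan makes per-sample segments deterministic and
non-overlapping by construction.

Defaults — window 50 SNPs, ≤ 1 het per window, min length 100 kb, min 25
SNPs, max gap 500 kb — are tuned for ~1 SNP/kb callsets; all are exposed in
`ROHParams`. F_ROH(≥ L) is the summed length of segments at least L,
divided by the total length of retained scaffolds (not callable length:
"proportion of the genome"). It is reported at L = 100 kb (all ROH,
long-term small-N signal) and 2 Mb (recent inbreeding).

## GERP-weighted relative load

relative_load = Σᵢ dᵢsᵢ / Σᵢ dᵢ over sites with score sᵢ strictly above
the threshold, where dᵢ ∈ {1, 2} is the derived dosage (heterozygous
alleles weighted 1, homozygous 2). The default threshold is 4 ("highly
constrained"); 1 ("non-neutral") is a common alternative and is available
as a parameter, with every result labelled by the threshold used. The
denominator is restricted to above-threshold alleles, making the statistic
a per-allele mean deleteriousness bounded by the included scores; an
`all_derived_denominator` variant (denominator over all scored derived
alleles) is provided for sensitivity analysis. A zero denominator returns
a flagged undefined result, never a division by zero.

Allele sharing: at each site with score above threshold where every
population has ≥ 6 called alleles, 6 alleles are drawn per population
without replacement (a hypergeometric draw on the derived count); a
population carries the allele iff ≥ 1 draw is derived. Sites carried by no
population are dropped; the rest are classified unique / pairwise-shared /
shared-by-all, and percentages over classified sites sum to 100. The fixed
draw depth removes sample-size bias between populations; sites failing the
6-allele floor in any population are skipped, not imputed. The draw is
seeded and deterministic.

## Coding burden and translocation risk

Effect categories (synonymous / missense / LoF) are consumed as
annotations — from `EFF`-style fields on real data, from generator truth
labels on synthetic data — never predicted. Burden counts variant *sites*
carried (derived dosage ≥ 1), split by zygosity; an allele-counting variant
(hom = 2) is available by flag since published per-individual counts can be
either. "Fixed" in a population requires every non-missing genotype
homozygous derived, with an optional call-rate floor (default none,
matching n = 3–8 samples). "Private" requires derived frequency > 0 in the
focal population and 0 in every other population with calls. Translocation
risk for a donor and recipient population is the number of LoF sites where
the donor carries ≥ 1 derived allele and the recipient's derived frequency
is 0 — the donor's potential novel contribution to the recipient gene pool.

## PBS selection scan

Per gene (SNP sets by interval overlap; SNPs in overlapping genes count
for each), pairwise F_ST uses the Hudson estimator,

  num = (p₁ − p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1),
  den = p₁(1−p₂) + p₂(1−p₁),

with n the called allele counts, combined across the gene's SNPs as a
ratio of averages and clamped to [0, 1]. Hudson is the small-sample-robust
choice at a few diploids per population and has no free weights; negative
per-SNP components are retained (truncating them biases the gene-level
ratio upward). Monomorphic genes are flagged no-data and excluded from
percentile computations.

Branch lengths are T = −ln(1 − F_ST) (natural log), and
PBS_A = (T_AB + T_AC − T_BC)/2 with cyclic permutations. F_ST = 1 makes a
branch infinite; +∞ PBS values are replaced by the population's maximum
finite PBS before outlier calling, and the mirror case (−∞, arising in
the third population when one pair is fully diverged) by the finite
minimum. Capping never reorders finite values. Outliers are genes with
capped PBS strictly above a hard threshold (default 3); the 99.8th
percentile (linear interpolation) is reported alongside for context, the
threshold being the operative rule. Genes with F_ST = 1 in all three
pairwise comparisons are reported separately, as are genes outlying in
exactly one population.

Missense summaries count genes with ≥ 1 missense variant present
(derived frequency > 0), exclusive to a population, or fixed (frequency
1); variants fixed in all populations carry no comparative signal and are
excluded by default.

## Group comparisons

Two-sided pairwise t-tests use the Welch (unequal-variance) form by
default — with unequal n and variance it is the safer default, and it is
also what R's `t.test` does out of the box; the pooled-variance form is
available by flag. No multiple-testing adjustment is applied by default
(the convention for these descriptive panels); pairs with < 2 samples on
a side are skipped with a warning. Effect measures: signed percent
difference 100·(a − b)/b and fold change modern/historical, which satisfy
fold = 1 + pct/100 on the same pair. Identical constant groups return
t = 0, p = 1 by convention rather than NaN.

## Synthetic data generator

The generator emulates the *statistical structure* the pipeline assumes,
at desk scale: three populations diverged under a Balding–Nichols model
(per-population site frequency ~ Beta with mean equal to the shared
ancestral frequency and variance scaled by a per-population drift
parameter F, which doubles as the expected pairwise Hudson F_ST between
populations of equal drift), two sampling eras for two populations,
per-site GERP scores from a three-component mixture (constrained
U(4.5, 6.5), intermediate U(1, 4), neutral U(−3, 0.5)), genes as
non-overlapping intervals holding a configurable fraction of sites with
synonymous/missense/LoF labels, indel records to exercise the proximity
filter, a fraction of sites emitted with the derived allele as REF to
exercise polarization, and per-genotype Poisson depths.

Inbreeding is realized literally as planted IBD tracts: per sample, tract
lengths are drawn from a configurable mixture over [100 kb, 10 Mb] until
the per-scaffold target F·L is met (the last tract truncated to hit the
target), placed uniformly without overlap; inside a tract the genotype is
homozygous derived with probability equal to the site's population
frequency. This gives an exact per-sample truth F (realized tract length /
genome length) for ROH-recovery tests — the reason tracts are planted
rather than simulated through a pedigree. A locus-specific drift override
(`sweeps`) lets a single gene diverge in one population to plant a
selection-scan signal.

Default study conditions: 16 modern + 5 historical diploids across three
populations (8/0 Sumatra, 5/2 Borneo, 3/3 Malay Peninsula), a 30 Mb genome
in three 10 Mb scaffolds with 30,000 polymorphic sites (1 SNP/kb), drift
0.1 per population, ancestral frequencies Beta(0.5, 0.5), 200 genes of
20 kb, 30% coding sites at (0.55, 0.40, 0.05) effect probabilities, 2%
indels, coverage U(9, 25)×. These are scaled-down stand-ins chosen once as
realistic for this data regime; analyses in the test and acceptance suites
state their own problem sizes where they differ.

What the generator does **not** emulate — hence what passing tests do not
show about real data: coalescent linkage structure and recombination maps
(sites are independent given population frequencies), read-level error and
mapping artefacts, reference bias in historical samples, site-frequency-
spectrum distortions from selection, and correlated missingness. Tests
against it validate the estimators' correctness and calibration under the
assumed model, not robustness to those real-data pathologies.

## Numerical conventions and degenerate inputs

- Seeds: one `numpy` generator per simulation, all draws in fixed order →
  byte-identical file bundles for a fixed config and seed.
- F_ST is clamped to [0, 1] at the gene level only; PBS may be negative
  (flooring at 0 is optional and off by default).
- Zero denominators are flagged (undefined load, no-data genes, skipped
  comparisons), never raised through division.
- Overlapping ROH segments or planted tracts, out-of-bounds tracts,
  unknown samples, empty populations and a donor inside the recipient
  population all raise immediately with the offending name.
- Report tables round only at serialization (θ to 2 decimals in summaries;
  full precision internally).

## Known limitations

- The ROH scan is one documented instantiation; published studies often
  combine two external callers whose parameters are not stated, so
  absolute F_ROH levels are comparable only under matched thresholds.
- Heterozygosity by genotype counting inherits any genotyping bias;
  historical (low-coverage, damaged) samples in real data would need the
  read-level estimator this package deliberately does not include.
- Only the Hudson F_ST estimator is provided.
- Allele frequencies treat samples as unrelated; close relatives would
  bias sharing, fixation and PBS estimates.
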