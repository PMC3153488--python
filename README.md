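# admixqtl

Association testing for quantitative traits — including gene-expression
traits (eQTL) — in samples drawn from **structured (admixed) populations**,
using a single **control marker** to remove the spurious association that
population stratification creates.

## Who this is for

Genome-wide association and eQTL studies regress a trait on marker allele
counts (0/1/2) to detect linkage disequilibrium (LD) with a causal locus.
When the cohort mixes two genetically diverged subpopulations, any marker
whose allele frequency differs between them becomes associated with any
trait whose mean differs between them — no physical linkage required.
`admixqtl` is for analysts who have such a cohort and want a correction
that needs **no ancestry prediction**: one well-chosen marker per test is
enough.

## The statistic

In a two-way admixture (proportions m : 1−m) the marker–trait covariance
decomposes exactly:

```
Cov(X,Y) = [ m·Cov₁ + (1−m)·Cov₂ ]  +  2m(1−m)(p₁−p₂)(μ₁−μ₂)
              genuine (within-pop LD)      spurious (structure)
```

with Covᵢ = 2Dᵢ(d + (1−2qᵢ)h).  A control marker Z — autosomal, on another
chromosome, unassociated with trait and test marker within subpopulations —
shows an excess genotype variance δ = Var_obs(Z) − 2c̄(1−c̄) = 2m(1−m)(c₁−c₂)²
(the Wahlund effect).  The corrected slope

```
b* = [ Cov(X,Y) − Cov(X,Z)·Cov(Z,Y) / (2δ) ] / Var(X)
```

subtracts the spurious term **exactly** at the population level and is
tested by Student's t on n−3 df (delete-one jackknife standard error).
The package also implements the two standard comparators — plain
regression (no correction) and multiple regression on a membership
probability — plus noncentral-t power prediction, an exact admixture
simulator, Hardy–Weinberg structure diagnostics, and an eQTL scan layer
(Sidak thresholds, 5 Mb peak merging, ±500 kb cis windows).

## Worked example

```python
from admixqtl import (default_null_scenario, simulate_admixed_sample,
                      fit_simple, fit_corrected, fit_structured)

spec = default_null_scenario()          # strong structure, zero within-pop LD
sample = simulate_admixed_sample(spec, n=200, seed=42)
for fit in (fit_simple(sample.X, sample.Y),
            fit_corrected(sample.X, sample.Z, sample.Y),
            fit_structured(sample.X, sample.membership_prob, sample.Y)):
    print(f"{fit.method:<11} b = {fit.b:6.3f}  se = {fit.se:.3f}  p = {fit.p:.2e}")
```

```
simple      b =  0.588  se = 0.102  p = 3.07e-08
corrected   b = -0.020  se = 0.128  p = 8.75e-01
structured  b = -0.050  se = 0.143  p = 7.28e-01
```

The test marker has **no** LD with the QTL inside either subpopulation, so
every association here is a stratification artefact.  The uncorrected
regression reports a wildly significant slope (population value 0.529);
the control-marker correction — using only one marker from another
chromosome — brings it to zero, as does the membership-covariate
regression that, unlike the correction, requires knowing each individual's
origin.  See `examples/` for replicate studies, power curves, a miniature
eQTL scan and the HWE diagnostics, each printing and explaining its
numbers.

## Command line

A thin CLI wraps the library for file-based runs:

```bash
admixqtl simulate --preset null-strong --n 200 --seed 1 --out-prefix demo
admixqtl assoc --genotypes demo.genotypes.tsv --phenotypes demo.phenotypes.tsv \
               --trait trait --marker test --method corrected --control auto
admixqtl study --preset ld-strong --n-reps 100 --seed 1 --out study.tsv
admixqtl scan  --genotypes g.tsv --phenotypes expr.tsv --annotation genes.tsv \
               --method corrected --control auto --out-prefix scan
admixqtl power --preset ld-strong
```

Formats: VCF v4.x (biallelic SNPs, ALT-allele counts, `./.` missing) or a
genotype TSV with header `marker  chrom  pos  <sample ids…>` and 0/1/2/NA
entries; phenotype TSV keyed by sample id with one column per trait;
transcript annotation as BED or a 1-based TSV (`gene chrom start end
strand`).  Every run writes a JSON manifest (config, seed, input hashes)
sufficient to reproduce it.

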