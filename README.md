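# mtspectrum

Analysis of heteroplasmic mitochondrial DNA mutations from paired-tissue
sequencing of mutator mice (proofreading-deficient polymerase gamma, "PolG"
mice). Such animals accumulate hundreds of mtDNA variants per tissue, each
present in only a fraction of the mtDNA copies, which makes it possible to
study mutation spectra and selection within single individuals. `mtspectrum`
is for researchers who have per-sample variant calls (Mutect2-style VCFs) and
per-base depth tables from brain and liver of the same animals and want the
standard downstream analysis: inheritance classification, mutation-load
metrics, spectrum and codon-effect breakdowns, strand-asymmetry correction,
and the associated statistics.

## The metrics and the model

A variant is **germline** when the identical change (same base, same
nucleotide substitution) is detected in both tissues of one animal, and
**somatic** when it is private to one tissue. Two load metrics are computed
per sample over any applicable length *L* (whole genome or one region):

```
mutation count     = (number of bases with a detected mutation) / L
mutation frequency = (sum of per-base mutated read fractions)   / L
```

Count measures how many distinct sites are hit; frequency measures how far
those mutations have spread through the heteroplasmic pool. Substitutions
collapse into six classes (a change and its reverse complement are one
molecular event: C:T/G:A, T:C/A:G, C:A/G:T, T:A/A:T, C:G/G:C, T:G/A:C), while
the stranded direction is kept for asymmetry analysis, where raw counts from
source base *N* are rescaled by `depth(C)/depth(N)` to remove the reference
strand's nucleotide composition bias. Coding changes are annotated under the
vertebrate mitochondrial genetic code (translation table 2) as
silent/missense/nonsense with amino-acid property changes (hydrophobic,
hydrophilic, acidic, basic, stop); indels are frameshift when their length is
not a multiple of three. Statistics follow the field's practice: paired
t-tests for tissue totals, linear mixed models on cube-root-transformed
metrics with animal as a random intercept, one-way ANOVA with Tukey HSD, and
Shapiro-Wilk normality logging.

A fully seeded synthetic-cohort generator (`mtspectrum.synthetic_data`)
produces paired-tissue VCFs, depth tables and a truth table with the
structure this analysis assumes, so the entire pipeline is testable without
any sequencing data.

## Worked example

```python
import numpy as np
import mtspectrum as m

ref = m.mouse_like_reference()           # synthetic mouse-like mtDNA layout
config = m.SimConfig(seed=11)            # 14 animals, study-scale load
cohort = m.simulate_cohort(config)

per_animal = {}
for animal in sorted({a for a, _ in cohort.calls}):
    per_animal[animal] = m.classify_variants(
        cohort.calls[(animal, "brain")], cohort.calls[(animal, "liver")], ref)

liver = [m.mutation_count([v for v in cl if v.tissue == "liver"], ref.length)
         for cl in per_animal.values()]
brain = [m.mutation_count([v for v in cl if v.tissue == "brain"], ref.length)
         for cl in per_animal.values()]
res = m.paired_tissue_test(liver, brain)
print(f"mean mutation count: liver {np.mean(liver):.5f}, brain {np.mean(brain):.5f}")
print(f"paired t-test: t = {res.statistic:.2f}, p = {res.p_value:.3g}")

g = [v.allele_fraction for cl in per_animal.values() for v in cl
     if v.tissue == "liver" and v.inheritance == "germline"]
s = [v.allele_fraction for cl in per_animal.values() for v in cl
     if v.tissue == "liver" and v.inheritance == "somatic"]
print(f"mean allele fraction: germline {np.mean(g):.3f}, somatic {np.mean(s):.3f}")

pooled = [v for cl in per_animal.values() for v in cl]
unique = list({(v.animal_id, v.pos, v.alt_allele): v for v in pooled}.values())
spec = {r.group: r.n_variants for r in m.substitution_spectrum(unique, ref.length)
        if r.grouping == "collapsed_class"}
snv = sum(spec.values())
for cls, n in sorted(spec.items(), key=lambda kv: -kv[1]):
    print(f"  {cls:10s} {n:5d}  ({100*n/snv:.1f}%)")
```

Output:

```
mean mutation count: liver 0.02409, brain 0.01244
paired t-test: t = 32.02, p = 9.41e-14
mean allele fraction: germline 0.197, somatic 0.077
  C:T/G:A     3121  (60.5%)
  T:C/A:G     1080  (20.9%)
  C:A/G:T      377  (7.3%)
  T:A/A:T      352  (6.8%)
  C:G/G:C      121  (2.3%)
  T:G/A:C      109  (2.1%)
```

Liver carries about twice the mutation count of brain; germline variants sit
at roughly 2.6x the allele fraction of somatic ones; and the spectrum is
dominated by the C:T/G:A transitions characteristic of polymerase
proofreading failure — each of these is the generator's injected structure
read back through the full pipeline.

A thin CLI wraps the same library:

```sh
mtspectrum simulate --seed 11 --out run/        # VCFs, depth tables, truth
mtspectrum analyze run/ --out results/          # mutation table + summaries
```

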