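# Methods

## Scope and data model

`mtspectrum` analyses heteroplasmic variant calls on a single circular
mitochondrial contig. The reference sequence is the light (L) strand — the
strand the variant caller reports against — and every public interface uses
1-based inclusive coordinates (VCF convention). Position arithmetic wraps
modulo the genome length; a feature with `start > end` spans the replication
origin. Four region classes are recognised (CDS, tRNA, rRNA, D-loop) and any
uncovered position is `intergenic`. Mouse mtDNA features are essentially
non-overlapping; if a degenerate annotation does overlap, a position is
assigned by the precedence CDS > tRNA > rRNA > D-loop and a warning is
logged, because each mutation must carry exactly one region label.

## Inheritance classification

Within one animal, a variant is germline when an identical (position,
reference allele, alternate allele) tuple is called in both brain and liver,
and somatic otherwise. Matching is exact: no allele-fraction similarity is
required (detection thresholds belong to the upstream caller), and the same
change arising independently in both tissues is knowingly counted as
germline — no correction is attempted. Germline variants are reported once
per tissue so tissue-level frequency metrics stay computable; the count
metric cannot separate tissues for germline mutations by construction.
Indels take the region of their anchored (left-aligned) position.

## Metrics

For a variant set and an applicable length `L`:

* count = |{mutated positions}| / L — two alternate alleles at one base
  count one mutated base (a switch to unique-(pos,alt) counting exists, and
  a divergence between the two is logged);
* frequency = sum of allele fractions / L.

Per-region metrics use the summed feature length of that region as `L`;
genome-wide metrics use the full genome length, D-loop included. Codon
position metrics use one third of the complete-codon CDS length, since every
complete codon contributes exactly one first, second and third position;
genes whose terminal codon is incomplete (completed by polyadenylation in
vivo) have that partial codon excluded from numerator and denominator, and
SNVs falling in it are flagged `incomplete_terminal_codon` rather than
annotated.

Genome scans assign each base the mean allele fraction of its variants
(multiple alternate alleles at one base are averaged), smooth with a centred
250-bp rolling mean that wraps the circular genome, and normalise the track
by its own maximum (`x/max(x)`), so the peak is 1 whenever any signal is
present.

## Codon effects and properties

Translation uses NCBI table 2 (vertebrate mitochondrial: TGA=Trp, ATA=Met,
AGA/AGG=stop), built from Biopython's table rather than re-typed. For a CDS
SNV the reference codon is read on the coding strand (reverse complement for
minus-strand genes), the variant base is substituted at its codon offset,
and both codons are translated: silent (same residue), nonsense (variant
residue is a stop, reference is not), else missense. A reference codon that
is itself a stop and mutates away from stop is classified missense. The
five-class property scheme (hydrophobic = A V L I P F M W G; hydrophilic =
S T C Y N Q; acidic = D E; basic = K R H; stop = \*) is packaged as data and
overridable, since reasonable schemes differ at the margins (G, C, Y).

## Strand-asymmetry correction

Comparing C→T with G→A counts on the reference strand is confounded by base
composition: the L-strand carries roughly twice as many cytosines as
guanines, so equal per-site mutation probabilities produce a spurious 2:1
raw asymmetry. Counts from source base *N* are therefore rescaled by
`total_depth(C) / total_depth(N)`, where the totals sum per-base sequencing
depth over reference positions of each base — i.e. all bases are normalised
to cytosine, whose factor is exactly 1. When no depth profile is available
the documented fallback uses reference base counts (depth-unweighted), which
coincides with the depth version under uniform coverage.

## Statistics

Count and frequency metrics are strongly right-skewed across animals, so
responses are cube-root transformed before linear modelling (cube root of 0
is 0; no offset). The transform is always applied regardless of the
Shapiro-Wilk log entry — the normality check is recorded, not used as a
gate. Models:

* paired t-test for liver-vs-brain per-animal totals (df = n−1, two-sided);
  identical vectors return t = 0, p = 1, and a constant non-zero difference
  is flagged as degenerate instead of reported as infinite;
* linear mixed models with a random intercept per animal (statsmodels
  MixedLM, REML). Fixed factors are categorical, full-factorial by default
  (e.g. inheritance × effect, matching the reported interaction analyses).
  p-values use the Wald normal approximation, recorded in
  `ModelResult.method`; statsmodels does not provide Satterthwaite degrees
  of freedom, and with ≥ 14 groups the approximation is adequate. Rows for
  animals with no observations in a category are simply absent (the
  documented row filter). Singular or non-converged fits attach warnings to
  the result rather than raising;
* one-way ANOVA (OLS + type-I anova_lm) with Tukey HSD pairwise tests for
  substitution classes, codon positions and strand comparisons. All-equal
  groups short-circuit to F = 0, p = 1 instead of 0/0.

## The synthetic cohort generator

`simulate_cohort` emulates the data structure the analysis assumes, at the
variant-call level — no reads, alignment or calling are simulated, so caller
artefacts (alignment error, filter behaviour, detection limits near 0.1%
heteroplasmy) are outside what any passing test can demonstrate.

Defaults are the study conditions the package targets: 14 animals; 160
germline variants per animal; somatic loads of 240 (liver) and 40 (brain)
per tissue, reproducing the roughly twofold total-count excess of liver;
per-animal counts drawn Poisson around those means (`count_model="fixed"`
injects exact numbers). Substitution classes are multinomial with weights
0.60 / 0.20 / 0.075 / 0.075 / 0.025 / 0.025 over C:T/G:A, T:C/A:G, C:A/G:T,
T:A/A:T, C:G/G:C, T:G/A:C — the replication-error transition three times the
second class, the two rare transversion classes nearly absent. The stranded
direction at a chosen site follows the reference base, so composition alone
generates the raw strand asymmetry the correction must remove. Allele
fractions default to Beta(1.5, 6) for germline (mean 0.20) and Beta(1, 12)
for somatic (mean 0.077), a ≈2.6× separation; AFs are quantised to 4
decimals so VCF float storage round-trips. Site choice applies a 0.2
multiplier inside the D-loop (five-fold depletion), positions are never
reused within an animal (no accidental germline), and germline missense
draws are rejected with probability 0.5 (`missense_germline_penalty`),
creating the somatic-excess-of-missense interaction the mixed model should
detect. Indels are 15% of variants, geometric(0.68) lengths (mean ≈1.5 bp,
≈7% in-frame), 85% deletions. Depth is i.i.d. Poisson around 8200× per
position.

The bundled `mouse_like_reference()` is a synthetic stand-in for a real
mouse mitochondrial genome: real gene order, kinds, strands and approximate
lengths (16.4 kb, 880-bp D-loop, ND6 and eight tRNAs on the minus strand),
L-strand-like composition with C ≈ 2×G, stop-free reading frames — but
random sequence. The packaged 600-bp `toy_reference()` (FASTA + GFF + BED,
all synthetic) adds the awkward cases: a minus-strand gene and a gene with
an incomplete terminal codon; origin-wrapping features are exercised with
in-test constructions.

What the generator deliberately does not model: shared germline mutations
between related animals, biological overdispersion beyond Poisson in
per-animal counts (real cohorts vary more; the worked example's t statistic
is correspondingly larger than field data would give), linkage between
variants on one molecule, region-specific spectra, and large structural
variants or multimers (unresolvable by short reads in any case).

## Verification strategy and problem sizes

Every numerical path is checked against an independent oracle: load metrics
against a literal per-base accumulation (≤1e-12 on 100 random fixtures);
codon effects against whole-gene retranslation via Biopython over every
possible SNV of the toy gene set (100% agreement required); the rolling mean
against a naive circular window average; tissue pairing against exhaustive
tuple intersection; the strand correction against its analytic null (equal
per-site rates on a 2:1 C:G genome, corrected counts within 3 binomial SDs).
Parameter recovery runs 14-animal cohorts of ~2100 variants — large enough
that 3-SD bands are a few percent wide, small enough that the whole recovery
block (including 50 mixed-model replicates for interaction detection) runs
in well under a minute on one CPU. The frameshift null is enumerated exactly
over lengths 1–30 (10/30 in-frame). Random draws everywhere go through
`numpy.random.default_rng` seeded from a single configuration or CLI seed.

## Known limitations

* Single contig only; nuclear genomes, NUMT filtering and multi-contig
  references are out of scope.
* Mixed-model inference is asymptotic (Wald); exact small-sample df are not
  available in the underlying fitter.
* The germline definition is operational (presence in both tissues) and
  inherits its false-positive mode: independent recurrence is
  indistinguishable from inheritance.
* Indel region assignment uses the anchor base; an indel spanning a region
  boundary is attributed entirely to the anchor's region.
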