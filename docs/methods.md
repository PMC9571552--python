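# Methods

This note documents the models behind `urivar`, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the design choices made where several reasonable options existed.

## 1. Problem setting

Tumor-only (matched-normal-free) somatic SNV calling from urine-derived
DNA on a deep targeted panel. Two facts dominate the design:

* at ~1000× depth and a 0.15% VAF floor, raw sequencing error is not a
  single number — each site × substitution has its own error rate, and
  sites in the upper tail of that distribution will repeatedly imitate
  low-VAF variants;
* without a matched normal, germline variants must be recognized from
  allele fractions and population-SNP annotations alone.

## 2. Panel-of-normals noise model

For normal samples *j* = 1..n (default n = 16, ≥ 2 required) the error
VAF v⁽ʲ⁾ = alt/depth is collected per site × alt (depth 0 ⇒ missing) and
summarized as mean μ̂, sample sd σ̂ (ddof = 1), and max m̂. A Beta(a, b)
method-of-moments fit is kept for diagnostics and simulation round-trips;
it is not part of the default threshold rule. Site/alt pairs observed in
fewer than two normals fall back to panel-global pooled statistics
(common-SNP sites are excluded from that pool so germline allele
fractions cannot inflate it), ensuring coverage dropout never creates a
site where calling is impossible.

The calling threshold is

    thr(i, alt) = max( floor, μ̂ + k σ̂, (1+δ) m̂ ),
    floor = 0.0015, k = 4, δ = 0.1.

The three terms have distinct jobs: the floor is the assay's analytic
limit; μ̂ + kσ̂ scales with site noise; (1+δ)m̂ guarantees that no member
of the normal cohort would be called at its own site (the in-sample
false-positive count is structurally zero, which is the sense in which
the threshold rule "contains" the null). A *fresh* null sample at these
noise levels still exceeds the thresholds at a few hundred of 150 000
site×alt tests — Poisson tails at single-digit expected counts are far
heavier than a Gaussian k·σ rule suggests — and that residue is exactly
what the anomaly component exists to remove. k, δ, and the floor are
config-exposed.

## 3. Ensemble SNV calling

**Hard filters:** mean alt base quality ≥ 30, VAF ≥ 0.15%, depth ≥ 100,
alt reads ≥ 3. The depth/alt-read minima make the 0.15% floor meaningful;
all are config-exposed.

**Isolation forest.** Standard construction: 100 trees, subsample
ψ = 256 drawn without replacement, uniform random feature and split
point, depth cap ⌈log₂ψ⌉, unresolved leaves contribute c(size); anomaly
score s(x) = 2^(−E[h(x)]/c(ψ)) ∈ (0, 1]. Deterministic per seed; scores
on n ≤ 8 instances are verified against a brute-force enumeration of the
same trees to 1e-12.

**Features.** Eight per candidate: log₁₀ VAF, log₁₀ depth, asinh of the
PON z-score (v − μ̂)/max(σ̂, 1e-6), log₁₀ PON mean error, mean alt
quality, strand balance min(f, r)/alt, log₂(1 + alt reads), and
log₂(VAF/threshold) — the margin over the site's own calling bar. Each
feature tracks a distinct noise mechanism (site error level, sampling
depth, base-calling quality, strand asymmetry). The compressive
transforms matter, not cosmetically: isolation trees split uniformly
within a feature's observed range, so on a linear VAF axis spanning
[0.0015, 1] essentially no splits land between background noise (~0.3%)
and a 1% variant, and the forest cannot separate them. On log scale that
region receives split mass proportional to its log-width and separation
is restored (measured: validation PPV 0.61 → 0.90 from this change
alone).

**Training corpus.** The forest is fit on presumed negatives only: every
above-floor (VAF ≥ 0.15%) site×alt observation in the PON samples plus
the non-truth observations of the 1:100 training dilutions. Truth sites
are excluded so the model represents background, making genuine signal
anomalous by construction.

**Calibration.** The cutoff is grid-searched over observed scores on the
1:100 training dilutions: among cutoffs whose ensemble training
sensitivity is ≥ 0.91, the PPV-maximizing (largest on ties) cutoff wins;
if the target is unreachable the calibration fails loudly with the best
achievable operating point. The training mixture is triplicate 1:100
dilutions with a 1:2 het:hom genotype mix (120 het + 240 hom per
replicate, i.e. truth at 0.5% and 1% expected VAF). The hom-skew is
deliberate: the calibration anchor is the training operating point of
roughly 91% sensitivity at ~94% PPV, and with an even genotype mix the
0.5%-VAF hets pin the pooled empirical sensitivity so close to 0.91 that
the cutoff degenerates to ~0 forest rejection and training PPV collapses
to ~0.6. A 1:2 mix reproduces the intended anchor (achieved ≈ 0.91 /
0.92 at the default seed) and leaves the forest enough room to reject
noise. Composition and target are config-exposed.

**Germline classification.** At a common-SNP site, a call is germline if
an exact two-sided binomial test of the alt count is consistent with
p = 0.5 (het) or p = 0.995 (hom) at α = 0.01. Otherwise calls below VAF
0.35 are somatic and the remainder ambiguous — a tumor-only caller
cannot distinguish a 40% somatic clone from a private germline variant
by allele fraction, so high-VAF non-SNP calls are deliberately not
labeled somatic. Concordance and longitudinal tracking therefore operate
on the non-germline (somatic + ambiguous) call set; benchmark
sensitivity/PPV use the somatic set only, which is conservative for the
spiked (low-VAF) truth.

## 4. CNV and copy-neutral LOH

Relative coverage per target = target mean depth / median target depth
(median-normalization removes library size). Against the PON's n
per-target relative coverages, a single new observation is tested with
the prediction-interval form t = (x − x̄)/(s√(1 + 1/n)), df = n − 1,
two-sided, BH-corrected across targets at q < 0.05, plus an effect floor
|log₂FC| > 0.3 so statistically-significant-but-tiny coverage wobble is
not reported. Targets with zero PON spread are skipped with a warning.

LOH: heterozygous-SNP window [0.10, 0.90]; per-gene mean |VAF − 0.5|
standardized against the PON per-gene baseline (mean/sd across normals,
sd floored at 0.002; computed only for genes with ≥ 3 het sites in ≥ 2
normals); called at z ≥ 3 and ≥ 5 het sites. Homozygous sites match
their expected 100%/0% state and contribute nothing. The region unit is
the panel gene. The sample's LOH burden = number of called regions; for
cohort contrasts (e.g. grade groups) burdens are compared with
Mann–Whitney U.

## 5. Synthetic-data generator

Fixed, seed-derived assay state shared by all samples: a 50 kb panel (50
one-kb targets over 5 chromosomes), per-site reference base, per-site
error rate eᵢ ~ Beta(1, 999) (mean 1e-3 — deliberately unflattering;
real deduplicated panels are often cleaner, which makes passing
benchmarks here conservative), per-target capture factor
LogNormal(0, 0.15), and 16 common SNPs per target with MAF ~ U(0.2, 0.5)
and a fixed alt base.

Per sample: depth ~ NegBin(mean 1000 × capture × per-sample target
jitter LogNormal(0, 0.05), dispersion 20); error reads
Binomial(depth, w·eᵢ) spread over the three non-ref bases with weights
0.5/0.3/0.2 (transition favored); germline genotypes drawn per
individual under Hardy–Weinberg; spiked variants at probability
expected_VAF + eᵢ (clipped) — additive error, slightly conservative for
precision testing and the reference the unbiasedness checks compare
against. Mean per-allele phred qualities: ~N(37, 1.5) for genuine
alleles, ~N(33, 3) for error alleles (per-read sd scaled by √reads) — a
mild, realistic quality signal that the Q30 filter and the forest can
use but that does not carry the benchmark. The capture factor is treated
as a probe property (shared across samples) with only the smaller
0.05-sigma jitter per sample; if the full 0.15-sigma factor were
per-sample, normalization against the PON could not remove it and
log₂FC recovery within 0.1 would be impossible.

Dilutions: "1:d" means spike fraction 1/d (forced by the printed
expectations: a het at 1:10 must appear at 5%), replicates share one
spiked genotype set (one physical mixture, sequenced repeatedly). CNV
injection re-draws a target's depths with the mean scaled by the copy
ratio; LOH injection re-draws het-SNP alt counts at p = 0.5 + t/2.
Tumor/urine pairs place clonal mutations at the tumor VAF and at
shedding × tumor VAF in urine, plus urine-exclusive events at
U(0.2%, 1%).

What the generator does *not* emulate: UMI/duplex structure, strand-
biased artifact classes (errors here are strand-symmetric, so the
strand-balance feature is honest but weak), trinucleotide-context error
structure, FFPE damage, contamination between individuals, and InDels.
Passing benchmarks therefore demonstrates the statistical machinery
under a realistic error-magnitude regime, not robustness to every
artifact class of real urine sequencing.

## 6. Benchmarks, sizes, determinism

The default benchmark uses a 50 kb panel so the full pipeline (16
normals, 3 training + 6 validation dilutions, CNV/LOH injections,
concordance and serial scenarios) completes in well under a minute;
truth counts are 540 per expected-VAF level (≥ 500, so a 97.4%
sensitivity bound is resolvable at ±2%). Per-level PPV pools each
sample's full call set over the samples containing that level (a 1:50
replicate contains both 1% het and 2% hom truth; both count toward its
precision). TN accounting is per possible substitution (3 × panel
bases). CNV recovery uses 9 replicates with the injected target rotating
across replicates, so no single target's PON estimate biases the median;
LOH recovery picks, per replicate, the first gene with ≥ 5 het sites in
that individual.

All randomness flows from one root seed through named integer
substreams (`default_rng([seed, stream, index])`); identical configs
give byte-identical counts tables, VCFs, and pipeline reports. Ties in
candidate ordering are broken by (chrom, pos, alt).

## 7. Known limitations

* The germline/somatic boundary (0.35) and the α = 0.01 balance test are
  pragmatic defaults, not estimated from data; cohort-level concordance
  values consequently depend on them.
* The forest's score distribution shifts slightly with the training-set
  composition; the calibration re-anchors the cutoff each run, but
  cross-run cutoffs are not comparable.
* Sensitivity at 1% expected VAF sits near its binomial noise floor
  (540 truths ⇒ sd ≈ 0.6%); seed-to-seed excursions of ±1% around ~98%
  are expected.
* No segmentation across targets, allele-specific copy number, purity
  estimation, or InDel support.
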