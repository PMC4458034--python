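# Methods

This note documents the models, algorithms and numerical choices behind
`recurcna`: a reimplementation, with a fully synthetic data generator, of a
genome-wide copy-number (CN) and allelic-ratio analysis of rectal-cancer
recurrence in a matched tumor/normal SNP-array cohort.

## The scientific question

Rectal-cancer patients treated by surgery alone have a ~10% risk of local
recurrence, yet preoperative radiotherapy is offered broadly.  A somatic
marker that identifies the high-risk minority would let treatment be
restricted to them.  The analysis implemented here asks whether genome-wide
CN alterations or allelic-ratio patterns in the primary tumor — measured on
SNP arrays against the patient's matched normal tissue — distinguish
patients who later developed a local recurrence (L), a distant recurrence
(D), both (LD), or neither (C).  The headline signal is *retention of
heterozygosity on chromosome 7*: locally recurring tumors keep balanced
parental alleles where control tumors mostly show allelic imbalance.

## Data model and simulator

### Latent tumor state

A tumor genome is a tiling of segments, each carrying a total copy number
`c` and a B-allele copy number `b` (0 ≤ b ≤ c).  The allelic-ratio class of
a segment is

* **1 — retention**: `b/c = 1/2` (balanced, e.g. 2:1),
* **2 — imbalance**: unequal but both alleles present (e.g. 3:1 gain),
* **3 — LOH**: one parental allele absent (`b = 0` or `b = c`).

The generator draws, per patient:

* **Chromosomes 7 and 13**: one chromosome-wide state from group-specific
  priors.  L-group tumors retain chromosome 7 with probability 1 (prior
  configurable); control/distant-group tumors draw imbalanced gain (3:1)
  with probability 0.60 and copy-neutral LOH (2:0) with probability 0.02,
  retention otherwise.  Chromosome 13: L retains with probability 0.78;
  controls draw imbalance 0.60 / LOH 0.13.
* **All other arms**: independent arm-level events — imbalanced gain (3:1)
  or mono-allelic deletion (1:0) — at background rates of 0.25/0.20 per arm
  for C, D and LD and 0.08/0.08 for L.  The lower L rates reproduce the
  observed genome-wide deficit of allelic aberrations in locally recurring
  tumors; because D and LD share the control priors exactly, the D-vs-C
  comparison is effect-free by construction and serves as the built-in null.

### Observable signals

With tumor purity ρ (default 0.75 — microdissected tumor tissue is fairly
pure, but the exact value is a modeling choice) the expected signals are the
standard two-population mixture

```
CN ratio          = (ρ·c + (1−ρ)·2) / 2
BAF (het probe)   = (ρ·b' + (1−ρ)·1) / (ρ·c + (1−ρ)·2)
```

where `b'` is `b` or `c−b` depending on which parental haplotype carries the
B allele (randomized per probe — SNPs are unphased).  Germline genotypes are
drawn per probe from its population heterozygosity (uniform on [0.2, 0.55]);
normals are diploid.  Gaussian noise is added (CN SD 0.08, BAF SD 0.03) plus
a sinusoidal "wave" artifact on the tumor CN ratio (amplitude 0.05, period
30 Mb, random phase) emulating the long-range intensity waves of real
arrays.  Raw intensities are the CN ratio scaled by 2^s with s ~ N(5, 0.3),
giving samples that pass the mean-log2 ≥ 4 QC by default.

### Genome scale

Desk scale by default: 22 autosomes × 2 arms × 120 probes per arm, 60 Mb per
arm, with chromosome 13 acrocentric (no p-arm probes) — 5,160 probes.  Real
array density (~300k probes) is a configuration choice, not a default; all
rates are per-arm so conclusions do not depend on probe count, only
precision does.

### Matched cohort

Group sizes default to the discovery cohort: C 46, L 10, D 41, LD 15.
Covariates are drawn from cohort-like marginals (TNM I/II/III =
10/21/69%, CRM involvement 27%, male 65%, age ~ N(64, 9²)).  Every
recurrent patient receives a matched control with identical TNM stage, CRM
status and sex and an age gap ≤ 7 years; a control may serve one patient in
each recurrence group but is unique within a group (this is how 66 recurrent
patients can share 46 controls).  The generator first clones controls to
cover the per-stratum demand (with ±2-year age jitter), then runs greedy
nearest-age matching per group with random patient order, retrying the order
and finally resampling covariates if a stratum cannot be served; exhaustion
raises an explicit matching error naming the stratum.

### Survival

Event histories are exponential: death at a group-specific rate (C 0.045/y,
L 0.09, D 0.16, LD 0.20), cancer as cause with group-specific probability,
independent exponential censoring (0.04/y) and administrative censoring at
the 12-year horizon.  Recurrence times for the defining groups are truncated
exponentials conditioned to precede the observation end, since the groups
are defined by an observed recurrence.  Nothing in the endpoint definitions
prescribes a generative model; exponential hazards are the simplest family
supporting Cox-recovery tests.

### qPCR plates

For a SNP panel, per sample × SNP × duplicate well × allele channel, the
template count is `input_molecules × (per-cell allele copies)/2` under the
same purity mixture, and `Ct = 26 − log2(molecules) + noise` (SD 0.15).
Wells past the detection limit (Ct > 40, including the absent allele of a
homozygous genotype) drop out to missing with probability 0.9.

## Analysis pipeline

### QC

Samples with mean log2 raw intensity < 4 are flagged; tumor/normal identity
is checked by genotype concordance at germline-homozygous probes (those are
robust to somatic allelic imbalance), failing below 0.90.  Flagged samples
are marked excluded but never silently dropped.

### Genotypes, normalization, mirrored BAF

Genotypes from normal BAF: AA < 0.15, AB in [0.35, 0.65], BB > 0.85, NoCall
in the gaps.  Tumor CN ratios are divided by the sample mean (the thresholds
below are defined relative to it).  Mirrored BAF, `|BAF − 0.5| + 0.5`, is
computed at germline-heterozygous probes only; it is label-free and lives in
[0.5, 1].

### De-waving

The wave is separated from true CN steps in two stages.  (1) A running
median over one wave period's worth of probes (window in probe counts, not
bp — with irregular probe spacing a bp-window median can flip several probes
before a true breakpoint) captures the segment-scale baseline: the median of
a sinusoid over a full period is ≈ 0 while step edges survive.  The baseline
is snapped to plateaus by cutting at jumps of a lagged difference (threshold
`max(6·σ_base, 0.08)` where σ_base is the baseline's own noise scale,
estimated from robust first differences of the signal).  (2) The wave is the
local-linear regression (lowess, window ≈ a quarter period — wide enough to
average noise, narrow enough not to attenuate the sinusoid) of the residual
(signal minus plateau medians), constrained to zero mean within each plateau
— which preserves segment means *by construction* — and divided out.
Measured fidelity at amplitude 0.1: residual wave amplitude ≤ 0.02 and a
0.5 step recovered within a few percent; a wave-free profile changes by
< 0.01.  Chromosomes with fewer than 10 probes are skipped with a warning.

### Segmentation

Recursive binary segmentation, applied independently to the CN signal and
the mirrored-BAF signal (het probes only), breakpoint union taken.  At each
recursion the split maximizing the two-sample t statistic is kept iff a
within-segment permutation test (default 200 permutations, seeded) gives
p < 0.01 and both children have ≥ 5 probes.  Measured behavior: < 5% false
splits on constant noise; a 4-SD step is found within ±2 probes in > 95% of
runs.

### State calling

Per segment: CN state is **loss** below 0.92 and **gain** above 1.08
(strict inequalities; values exactly at a threshold are neutral —
symmetric and conservative), relative to the normalized sample mean.
Allelic class from mean mirrored BAF over het probes: class 1 below 0.60,
class 3 at or above 0.78, class 2 between; missing when a segment has fewer
than 10 informative probes.  The LOH cut of 0.78 is placed so that at the
default purity 0.75 a mono-allelic deletion (mBAF = 0.80) calls LOH, a 3:1
gain (mBAF ≈ 0.64) calls imbalance, and copy-neutral LOH (mBAF ≈ 0.875)
calls LOH.  All cutpoints are config fields.

A caveat worth stating: thresholds relative to the *sample mean* assume a
mostly diploid genome.  A tumor whose gains outweigh losses strongly enough
shifts its mean so that neutral probes drop below the loss threshold; at the
default background rates this affects a small minority of simulated samples
and is a property of the method, not of the implementation.

### Frequency profiles

Per group and probe, the fraction of patients with a gain (any segment) or
loss — losses restricted to segments of ≥ 15 probes, mirroring how published
frequency plots suppress small deletions; the arm summary is the maximum
probe frequency on the arm.

### Hierarchical association testing

The global test of a feature set against a binary group label uses the
score-form statistic

```
Q = (1/m) · Σ_j (z_jᵀ ỹ)²
```

with rows z_j standardized to mean 0/SD 1 (zero-variance rows dropped) and
ỹ the centered label vector; p-values come from seeded label permutations
(`(1 + #{Q_perm ≥ Q}) / (1 + B)`), which is asymptotics-free and valid at
any sample size — measured type-I error ≈ 0.05 at nominal 0.05.  The
CN test uses per-probe normalized ratios; the allelic test uses per-probe
class codes 1/2/3 expanded from segments (probes in class-missing segments
code as 1, i.e. no evidence of aberration).

The hierarchy gates: genome-wide test per datatype; if p < 0.05, per-arm
tests BH-adjusted across all arms (one family per comparison × datatype);
for arms passing adjusted 0.05, region tests on contiguous ~30-probe windows
within the arm, BH-adjusted within that arm's family.  Permutation counts:
10,000 (genome, arm) and 1,000–2,000 (region) by default.

A design note: with only 10 L-group patients, a permutation p-value cannot
fall below the hypergeometric bound ~C(k,10)/C(56,10), where k is the number
of chromosome-7-balanced patients in the pooled comparison — the permutation
test is intrinsically coarser than an asymptotic score test at this sample
size, and the arm-level power of the hierarchy depends directly on the
control group's aberration prevalence.

### Chromosome status and exact tests

A patient's overall chromosome status is the most abundant allelic class on
the chromosome, weighted by heterozygous-probe counts (configurable to raw
probe counts); ties resolve to the higher (more aberrant) class.  Status of
a chromosome combination is the maximum of the members.  Status-by-group
tables (2 rows × 3 classes) are tested with an exact Fisher test computed by
full enumeration of tables with the observed margins; the p-value sums the
multivariate-hypergeometric probabilities of tables no more probable than
the observed one (relative tolerance 1e-7 against floating-point ties).  The
implementation matches an independent brute-force oracle exactly on all
small 2×2 and random 2×3 tables and reproduces R's `fisher.test` to seven
digits on the status tables.

### Survival models

OS = death by any cause; DSS = death by rectal cancer (other deaths censor
at the death time); LRFP/DRFP = first local/distant recurrence (death
without that recurrence censors); all censored at the 12-year horizon.
Marker effects are fitted with the Cox proportional-hazards model (lifelines,
Efron ties), univariate or with the fixed covariate set — TNM stage as
II-vs-I and III-vs-I indicators, age continuous, sex and CRM binary —
included irrespective of significance.  Death before recurrence is treated
as plain censoring (the endpoint definitions imply it), not as a competing
risk.  Measured: with a true hazard ratio of 3 at n = 112 and ~25 events the
mean estimated log-HR is within a few percent of log 3 (small upward
finite-sample bias expected), and the null 95% CI covers 1 at ≈ 95%.

### qPCR validation arithmetic

Panel selection: per region (7p, 7q, chromosome 13), SNPs with observed
normal-tissue heterozygosity ≥ 40% ranked descending, top 16 kept,
deterministic tie-break by SNP id.  Ct preprocessing sets missing wells and
Ct > 30 to exactly 30; molecules = 2^(26 − Ct) (Ct 26 ↔ one molecule).
Replicate wells are averaged on the molecule scale; each channel is divided
by the sample's total molecule amount on that channel (cancelling global
channel-efficiency differences) and the per-SNP allelic ratio is normalized
A over normalized B, with an empty B channel emitting a flagged sentinel
ratio of 2^8.  The per-patient region summary is the mean of the *folded*
ratio max(r, 1/r) over SNPs heterozygous in that sample — raw A/B means are
allele-label-dependent, the folded mean is not (documented choice; the raw
mean is recoverable from the ratio table).  Group differences per region use
Welch's two-sample t-test with the Welch–Satterthwaite degrees of freedom.

### Meta-analysis counting rule

Per study and arm, an alteration is *frequent* when its case fraction is
≥ 0.25 (inclusive); an alteration is *common* when ≥ 0.40 (inclusive) of the
site-filtered studies flag it, with per-arm missing fractions excluded from
that arm's denominator (not the whole study).  The rectum-vs-colon contrast
reports arms whose study fractions differ by strictly more than 0.20.  Both
monotonicity properties (raising either threshold never enlarges a flag set)
are tested.

## Problem sizes used in validation

Validation experiments run at the desk scale above: 20 end-to-end
replicates of the L/C/D portion of the cohort (97 patients × 5,160 probes)
for state recovery and hierarchy power; 1,000 replicates × 1,000
permutations (20 features × 40 samples) for global-test calibration; 5
replicates for de-waving fidelity; 200 + 200 replicates for Cox recovery
and null coverage.

## What the simulation does and does not establish

The generator reproduces the statistical *structure* the analysis assumes —
purity-attenuated mixture signals, genotype-conditional BAF, wave artifacts,
matched covariates, group-specific aberration priors — so passing tests
show the pipeline recovers known truth under that structure and that its
tests are calibrated.  It does not model FFPE degradation, intratumoral
heterogeneity or subclonality, probe-specific response, GC-content coupling
of the wave, linkage between SNPs, or germline CNVs; conclusions about real
arrays therefore rest on the method, not on these simulations.  Arm-level
events are whole-arm by construction, so segmentation is only exercised at
arm-scale breakpoints in cohort runs (sub-arm steps are exercised in the
dedicated segmentation tests).

## Known limitations

* Sample-mean normalization is fragile under extreme aberration load (see
  above); a mode-based normalization would be more robust but is not what
  the method specifies.
* Deletion-LOH at purity below ~0.7 falls under the 0.78 mBAF cut and is
  classed as imbalance — an attenuation inherent to mixture signals, not
  recoverable without purity estimation (out of scope).
* The exact Fisher enumeration is practical for the small status tables
  (2×3, n ≈ 100); large sparse tables would need a network algorithm.
* Permutation p-values have a resolution floor of 1/(B+1); gated hierarchies
  inherit it at every level.
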