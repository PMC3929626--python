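# Methods

## Scope and model

`exonscreen` screens two-group exon-array experiments for cassette-exon
inclusion changes. The statistical object is the splicing index: for
exon probeset e of transcript g in sample i,

    SI_ei = 2^(x_ei − x_gi)

where x are summarized log2 intensities. The group mean of SI is the
inclusion index PSI, and the screened statistic is the ratio
PSI_KO / PSI_CTRL. The splicing index cancels transcript-level
abundance only in expectation; residual transcription artifacts are
handled explicitly by excluding exons on differentially expressed
transcripts. PSI here is a linear, unbounded inclusion proxy, not a
probability — exon arrays measure probe intensity, not isoform counts.

The exon-level test is a two-sided pooled-variance Student's t on
per-sample log2 SI values (a moderated variant is available via
`exon_test="moderated"`). A t-test on the log index is exact under the
generative model used by the simulator (Gaussian log-scale noise), and
its calibration on real-shaped data is checked empirically by the null
simulations in the acceptance tests. Whether the exon p should come
from a t on splicing indices or from an interaction ANOVA is a genuine
design fork; the t was chosen because it matches the per-exon
group-comparison framing of the candidate tables this package emits,
and the choice is a config parameter.

## Preprocessing

* **Background**: RMA convolution, observed = Exponential signal +
  Normal background; corrected value is the posterior mean E[s|o].
  Per-array parameters default to mode-based estimates (mode of the
  intensity histogram = background mean; spread of sub-mode values =
  background sd; mean excess of supra-mode values = signal scale).
  These estimates need a background population to lock onto, which the
  simulator provides through decoy probesets (below).
* **GC adjustment**: per-array median-centering of GC-fraction bins
  (25 by default), applied only when per-probe GC fractions are
  available, and off by default so results do not depend on optional
  annotation. The adjustment method on the original platform is not
  public; median-centering is the minimal location correction.
* **Quantile normalization**: rank-mean algorithm; tied values within
  an array receive the mean of the target quantiles their rank block
  occupies. Idempotent, and exactly distribution-equalizing on
  tie-free data.
* **Summarization**: arithmetic mean of log2 probe values per
  probeset (the platform convention this package mirrors; no
  median-polish).
* **Expression floors**: gene-level features with linear signal
  below 25 and exon probesets with log2 signal below 3 are removed.
  "Across arrays" is read as the mean across arrays; the aggregation
  (mean/min/max) is a parameter because the original description does
  not pin it down.

## Transcript-level statistics

Moderated t as in the standard empirical-Bayes variance-shrinkage
model: d_g = n − 2 residual df per feature, prior (d₀, s²₀) by moment
matching of log variances with trigamma inversion, posterior variance
s̃² = (d₀s²₀ + d_g s²_g)/(d₀ + d_g), reference distribution
t(d₀ + d_g). When the log-variance dispersion does not exceed its
theoretical sampling value, d₀ = ∞ and the prior scale is the mean
observed variance (all features fully shrunk; the statistic becomes
z-like). The implementation is cross-checked in the test suite against
limma's eBayes on the same matrix.

Calls require |linear fold| ≥ 1.5 and p ≤ 0.05 (both inclusive, both
parameters). No multiple-testing correction enters the calls; a
Benjamini–Hochberg column is emitted for information because the
screen's downstream use of the DE list is exclusion, not discovery.
Signed folds follow the convention +r for up, −1/r for down, so the
magnitude is always ≥ 1.

## Candidate cascade

1. keep exons with PSI ratio ≤ 2/3 or ≥ 1.5 **and** p ≤ 0.05
   (the low cut is exactly 2/3, the reciprocal of 1.5, so the window
   is symmetric in log space);
2. drop exons whose transcript is on the DE list (`de_overlap` flag);
   exclusion keys on transcript identity, not genomic overlap;
3. require ≥ 1 AGAA site and binding-site frequency F ≥ 1.5.

F = 256·count/length, calibrated so one site per 256 nt — the chance
expectation for a 4-mer — equals 1. The alternative literal reading
count·length/256 (which agrees only at length 256) is available as
`freq_convention="literal"` for comparison experiments. Overlapping
motif occurrences are counted, because GAA-rich clusters are the
biological signal and overlap exclusion would undercount them; the
search is sense-strand only, on mRNA sequence.

## PTC / NMD prediction

For a skipped exon, the shortened mRNA is rebuilt and translated from
the original start codon (skipping the start-codon exon is an error).
Stops strictly upstream of the original stop — mapped into the new
coordinate system, or end-of-sequence when the stop itself was skipped
— count as PTCs. NMD is predicted by the classical junction rule: the
first PTC must lie more than 50 nt (parameter) upstream of the last
exon–exon junction. Skipping the last exon of a transcript whose ORF
ends there therefore never yields an NMD call: the retained sequence
is the original clean ORF prefix.

## Synthetic data

The generator emulates the study design rather than the platform:

* **Design**: 4 CTRL vs 4 KO arrays (defaults), 4 probes per probeset,
  per-probe affinities ~ N(0, 0.3) drawn once and shared across
  samples (they cancel in group contrasts), log2 noise sd 0.25,
  additive background truncated-Normal(30, 10). The noise and
  background levels are package conventions chosen to resemble a
  well-behaved array experiment; the original arrays' noise parameters
  are unknown.
* **Background model**: truncated-Normal rather than Exponential, so
  the generative background matches the corrector's Normal-background
  assumption and both background parameters are meaningful.
* **Sequences**: random exon sequences are scrubbed of chance AGAA
  occurrences, then a Poisson(rate·len/256) number of sites is
  planted, giving exact control of motif content (rate 0 ⇒ exactly
  zero sites) at the cost of slightly non-uniform local base
  composition around planted sites. Every transcript carries a clean
  ORF (ATG…stop, no internal in-frame stops) spanning ≥ 2 exons.
* **Effects**: round(frac_de·n) transcripts get a linear fold from
  `de_fold_range` (direction random); round(frac_as·n_exons) exons on
  the *remaining* transcripts get a PSI ratio from `as_ratio_range`
  restricted outside (2/3, 1.5) — planted truth is detectable by
  design and disjoint from the DE-exclusion rule, so cascade
  sensitivity is measurable without collision artifacts.
  `as_ratio_values` optionally fixes a discrete ratio set, and
  `as_min_motif_freq` enriches planted exons with AGAA sites to a
  target F, for benchmarks that must not be limited by motif content.
* **Mosaicism**: the KO expectation is the linear mixture
  (1−m)·KO_state + m·CTRL_state, modeling two cell populations
  contributing RNA, applied to expectations rather than to sampled
  replicates. The observed exon ratio then contracts to (1−m)r + m
  when transcript levels are flat — at m = 0.5 a planted ratio of 2.0
  sits exactly on the screening window boundary, which is why
  sensitivity collapses in the mosaic benchmark.
* **Decoys**: unexpressed probesets (pure background, one "gene" plus
  three "exon" probesets each, count = `decoy_fraction` × real
  transcripts) emulate the absent features that dominate real arrays.
  They anchor the per-array background-parameter estimate and give the
  expression floors real work; without them, mode-based background
  estimation has no background population and misbehaves.

All randomness descends from one integer seed through
`numpy.random.SeedSequence` spawning; regeneration with the same seed
is byte-identical.

## Problem sizes and tolerances

The acceptance benchmarks use 10 × 50 transcripts (≈ 3,000 exons
pooled) for null calibration — the type-I band [0.03, 0.07] is the
three-ish-sigma binomial interval around 0.05 at n ≥ 2,000 — and 150
transcripts (≈ 90 planted exons) for cascade recovery. Oracle
equivalences are exact (quantile normalization), < 1e-10 (moderated t
at d₀ = 0), or integer-equal (motif counting). Numerical guards: a
strictly-positive floor of 2⁻²⁰ on corrected intensities, background
sd below 1e-8 treated as the deterministic-background limit o − μ, and
deep-left-tail posterior means clamped to the floor where the
convolution denominator underflows.

## Limitations

* Probe affinities are sequence-independent; there is no GC-dependent
  bias, cross-hybridization, or CEL-level structure in the simulator,
  so passing benchmarks demonstrate the statistics, not platform
  robustness.
* The simulator plants inclusion effects as intensity scalings with a
  flat baseline inclusion of 1; it does not model partial constitutive
  inclusion, multiple competing isoforms, or position-dependent
  enhancer action.
* PSI ratios from splicing indices are relative quantities; they are
  not percent-spliced-in probabilities and are not comparable across
  exons with different probe behavior.
* The NMD rule is the 50-nt junction heuristic; uORFs, long 3'UTR
  triggers and EJC-independent decay are out of scope.
* Published headline counts from the original full-scale array
  analysis depend on proprietary preprocessing internals and the
  deposited raw data, and are therefore documented rather than
  reproduced; the package's guarantees are stated on synthetic data
  with known truth.
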