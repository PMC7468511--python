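# Methods

## MEP polyphasia scoring

**Definition.** An MEP is scored by the number of times the
baseline-corrected signal crosses zero inside an analysis window anchored
at the first MEP peak, from 9 ms before to 36 ms after it. An MEP with more
than `polyphasia_threshold` crossings (default 2) is polyphasic; an MEP
with exactly the threshold count is *not* (the boundary case is assigned to
the non-polyphasic side). Per subject we report the arithmetic mean of the
crossing counts over all analysable pulses, the polyphasia ratio
(polyphasic MEPs / total MEPs), a binary subject label, and where the
polyphasia occurred (stimulation level: cortex / spinal / both; muscle:
ADM / TA / both).

**Baseline.** Mean of the pre-stimulus segment (≥ 5 ms required); the
pre-stimulus SD is the noise estimate.

**First peak.** Response onset is the first post-stimulus sample whose
absolute deviation from baseline exceeds `onset_k` × noise SD
(`onset_k = 3`; floor `onset_floor_mv = 0.1` mV for noiseless traces); the
peak is the first local extremum at or after onset — deliberately the
*first*, not the global, extremum, so a large late lobe cannot shift the
window. On noisy recordings the detected extremum can sit 1–2 ms before the
true lobe peak; the window is wide enough that this jitter is harmless.

**Hysteresis (Schmitt-trigger) counting.** Within the window, samples are
classified +1 / −1 only beyond ±`hysteresis_frac` × (window max absolute
amplitude), with `hysteresis_frac = 0.05`; the crossing count is the number
of state changes in the thresholded sequence. A sign change therefore only
counts when the signal attains 5% of the peak on both sides, which makes
the count invariant under amplitude scaling, sign flip, and constant
offset (baseline is re-estimated). If the window overruns the trace it is
clipped with a logged warning — window length legitimately varies between
recordings.

**Subject rule.** A subject is polyphasic when at least one MEP is
(`min_polyphasic_fraction = 0`); a stricter minimum fraction is a config
key. The rule is exposed because per-subject classification conventions
differ between laboratories.

## Synthetic MEPs

A synthetic MEP is a train of `k + 1` alternating-sign Gaussian lobes
(σ = phase width / 4) spaced `phase_width_ms = 3` apart, first lobe peaking
at `peak_latency_ms` (default 20 ms, a typical cortical ADM latency) with
amplitudes decaying by 0.8 per lobe; such a waveform changes sign exactly
`k` times, so the generator's target crossing count is exact ground truth.
White Gaussian noise rides on top; the pre-stimulus segment is noise only.
Defaults: 20 kHz sampling (Nyquist-safe for a 20 Hz–10 kHz recording
bandwidth), 2 mV peak amplitude, 10 ms pre- / 60 ms post-stimulus sweep.

**Noise level.** The default noise SD is 1% of the drawn amplitude. This is
a deliberate, load-bearing choice: the 5% hysteresis band equals 5 noise
SDs at this level, so a spurious band excursion by broadband noise has
per-sample probability ≈ 2.9·10⁻⁷ and the counter reproduces the planted
count essentially always (0 miscounts in 3000 instrumented traces; a
300-seed Monte-Carlo check is in the suite). At 2% noise the band is only
2.5 SDs and, with ~900 samples per window at 20 kHz, broadband noise
generates several spurious crossings per trace (measured inflation from
~1.5 to ~7 mean crossings), which no windowed sign-change counter with a
5% relative band can reject. Real surface-EMG baseline noise is strongly
band-limited, so the 1% broadband equivalent is also the more realistic
stand-in.

**Cohort presets.** Group crossing-count distributions are categorical pmfs
on {1, 2, 3}. The shipped presets set the pmf expectation to each group's
reported mean crossing count — patients {1: .62, 2: .27, 3: .11} (mean
1.49), relatives {1: .65, 2: .24, 3: .11} (1.46), controls
{1: .82, 2: .14, 3: .04} (1.22) — with support chosen so that some MEPs are
genuinely polyphasic (> 2 crossings), as patient recordings are. A separate
`patient-ratio` preset sets P(crossings > 2) = 0.77, the patients' mean
polyphasia ratio. Two presets exist because the published patient summary
statistics (mean 1.49, ratio 0.77, 85% of subjects polyphasic) are not
jointly satisfiable under any single "polyphasic ⇔ crossings > 2"
convention; each preset targets one statistic and no joint fit is
attempted. Amplitude jitter SD 0.3 mV, latency jitter SD 1.5 ms, 10–15
pulses per subject, default group sizes 20/23/30.

**What a green round-trip establishes.** That the scorer recovers the
generator's planted counts through noise, peak detection and windowing —
not that real EMG behaves like Gaussian lobes. The generator has no
stimulus artifact, no line noise, no motor-unit interference pattern, no
inter-pulse amplitude correlation; miscount robustness against those
artefacts is untested by construction. Note also that a group mean over
20 × 12 draws carries a sampling SE of ≈ 0.044 crossings, so point
recoveries tighter than ±0.1 are partly luck of the seed.

## Group statistics

Implemented from first principles (SciPy is used only for χ² / normal tail
probabilities, and as an independent oracle in the tests):

* **Fisher's exact test** on r×2 tables by full enumeration of tables with
  the observed margins under the (multivariate) hypergeometric likelihood;
  two-sided p sums probabilities ≤ the observed table's (tolerance 10⁻⁹
  guards float round-off). Enumeration is bounded at N ≤ 200; beyond that
  the error message points to the chi-square test.
* **Pearson chi-square**, df = (r−1)(c−1), optional Yates correction for
  2×2; zero margins are an error.
* **Wilcoxon rank-sum**, two-sided; exact by full rank-assignment
  enumeration when both n ≤ 10 and no ties, otherwise normal approximation
  with tie-corrected variance and 0.5 continuity correction. Identical
  pooled samples return p = 1 with a warning.
* **Kruskal–Wallis** H with tie correction, χ² tail with df = k−1.
* **percentage()** rounds half-up (the convention that reproduces printed
  table percentages like 85 from 17/20).

All tests are two-sided and uncorrected for multiplicity, matching the
reporting conventions of the comparisons they reproduce. The pipeline runs
Kruskal–Wallis as the omnibus test and pairwise Wilcoxon as post-hoc.

## Trio filtering

"Affected" in segregation means *polyphasic*, not epileptic — the phenotype
segregates through parents who are polyphasic without epilepsy. Scenario
rules on alternate-allele counts (child c, father f, mother m):

| scenario | rule |
| --- | --- |
| autosomal_dominant | c ≥ 1; ≥ 1 parent affected; every affected parent ≥ 1; every unaffected parent = 0 |
| autosomal_recessive | c = 2, f = 1, m = 1 |
| de_novo | c ≥ 1, f = 0, m = 0 |
| compound_het | ≥ 2 child-het variants in one gene, ≥ 1 paternal-only and ≥ 1 maternal-only origin |
| x_linked | X chromosome; male child: c ≥ 1 with carrier mother; female: c = 2, both parents carry |

The dominant rule explicitly requires an affected transmitting parent;
without that clause every de novo variant would double as "dominant" when
both parents are unaffected, and the two scenario outputs could not be
disjoint. Hemizygous male X genotypes coded 1 or 2 both count as carrying.
Compound-het phase is inferred from parental origin only (no read-backed
phasing), so a variant carried by both parents has ambiguous origin and is
dropped from pairing. Variants with a missing genotype in any member are
skipped per scenario, with a log note.

Annotation filter: all *present* reference MAFs (1000 Genomes, ESP, ExAC)
must be ≤ `maf_max` (default 0.01); variants with no MAF anywhere are
treated as novel and pass; impact must be HIGH or MEDIUM (VEP's MODERATE is
accepted as a synonym) and region `coding_exonic`. The filter is
idempotent. The control-cohort exclusion removes any candidate with an
alternate allele in any control sample. The 1% MAF default is kept even
though published candidate lists occasionally include far more common
variants; the threshold is a config key.

## Case/control simulation and the risk model

**Simulator.** Genotypes are binomial(2, f) per variant under
Hardy–Weinberg and linkage equilibrium, allele frequencies uniform on a
configurable range (default 0.05–0.5). Phenotypes follow a logistic model
over planted per-allele log-odds effects; the intercept is calibrated by
bisection so the expected case count matches the design, and cohorts are
resampled until the realised split is exactly 16/14 (mirroring fixed group
sizes). The truth record stores effects, intercept and frequencies. No LD
and no population structure are modelled — the risk-model machinery being
exercised ignores both.

**Odds ratios.** Per variant, case/control alternate vs reference allele
counts form a 2×2 table (missing genotypes drop that sample for that
variant only); OR = ad/bc with +0.5 on all cells when any cell is zero
(Haldane–Anscombe). OR > 1 ⇒ high-risk, < 1 ⇒ low-risk, = 1 ⇒ neutral.

**Selection.** Top k = 16 by |log OR|; ties break by larger total
alternate-allele count, then genomic order — fully deterministic. |log OR|
is used because the high/low-risk labelling is symmetric in direction;
the ranking statistic is a config choice.

**Logistic fit.** Newton/IRLS on the penalised log-likelihood with a fixed
ridge λ = 10⁻³ on slopes only (intercept unpenalised), convergence when the
max Newton step < 10⁻⁸ (cap 200 iterations). The ridge guarantees a finite
optimum under the quasi-separation that is routine with 16 predictors and
29 training samples; at this λ the fit matches an unpenalised-intercept
scikit-learn ridge logistic to ~10⁻⁴. Constant columns are dropped
(coefficient 0). Missing allele counts impute to 0 in both fitting and
scoring, keeping every sample's score defined.

**Scores.** Unweighted = count of alternate alleles at high-risk variants;
weighted = Σ coefficient × allele count; predicted risk =
logistic(intercept + weighted); positive call ⇔ risk > 0.5.

**LOOCV.** For each held-out sample, ORs, top-k selection and the fit are
recomputed on the other n−1 samples — no information from the held-out
sample reaches its own predictors (asserted by a corruption test). Folds
that lose a whole class are skipped with a warning. The pooled variant list
is the union of per-fold selections. Metrics (accuracy, sensitivity,
specificity as percentages; MCC with the 0-when-degenerate convention; AUC
in Mann–Whitney rank form with midranks) are computed on the pooled
out-of-fold risks.

On null data the LOOCV accuracy is near — but not an unbiased estimate of —
50%: holding out a sample shifts the training class balance away from the
held-out class, and with a 16/14 design the intercept-only predictor calls
everything "case" (16/30 correct). The calibration test therefore asserts
the empirical mean over 200 datasets within 3 empirical SEs of 50%, which
the shipped generator satisfies.

**Clustering.** UPGMA (average linkage, Euclidean) over per-sample
(risk, weighted score) vectors via `scipy.cluster.hierarchy.linkage`;
output is the merge table plus dendrogram leaf order. Merge heights are
non-decreasing by construction of average linkage.

## Numerical and degenerate-input conventions

* p-values are clamped into (0, 1]; exact-test tolerances are 10⁻⁹ on
  log-probability comparisons.
* The MEP TSV round trip is bit-exact: amplitudes are written with `repr`
  precision and parsed with correctly-rounded `float()` (pandas' fast
  parser is off by 1 ulp on ~30% of values).
* VCF counts: `0/1` → 1, `1/1` → 2, `./.` → missing; multi-allelic sites
  split into bi-allelic records per alternate allele; 1-based positions
  untouched.
* Flat traces raise a no-response error and are logged as unanalysable;
  subjects with zero analysable MEPs are excluded from group tables with a
  note.
* All generators take explicit integer seeds; equal seeds give
  byte-identical outputs.

## Known limitations

* The waveform model is phenomenological; it cannot probe scorer behaviour
  against stimulus artifacts, line noise or motor-unit interference.
* Trio background variants are simulated free of LD and, for exact
  planted-truth recovery, rejection-sampled so no background variant
  satisfies the target scenario; real trios contain chance-segregating
  variants, and on real data the scenario filters return candidate *lists*,
  not unique hits.
* The two-case pipeline's published headline metrics depend on the original
  exomes, which are access-controlled; here they are reproduced only from
  the printed confusion counts, while the pipeline's statistical behaviour
  (null calibration, planted-effect recovery, determinism, no leakage) is
  validated on synthetic data.
* Fisher enumeration is exponential in rows; it is bounded at N ≤ 200 and
  intended for study-scale tables (N = 73).
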