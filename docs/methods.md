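# Methods

`dictytox` implements a developmental-toxicity (DART) evaluation pipeline
for the social amoeba *Dictyostelium discoideum*: growth toxicity from
time-lapse cell counts, developmental toxicity from stage-reporter
fluorescence courses, teratogen classification from the ratio of the two,
and a pooled insertional-mutagenesis (REMI-Seq) selection analysis for the
genetic mode of action. This note records the models, the defaults and
their rationale, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Growth toxicity

Cell counts per frame follow lag + exponential growth capped at a carrying
capacity. The doubling time is `ln 2 / slope` from a log-linear least-squares
fit of `ln(count)` against time. The exponential phase is found
automatically: every contiguous sub-window inside 8–48 h spanning ≥ 8 h
with ≥ 5 points is fit, and among windows whose r² lies within 0.02 of the
maximum the longest is kept. Pure max-r² selection is unstable — with
multiplicative count noise a short window occasionally fits near-perfectly
by chance and returns a badly biased slope — while lag and saturation
phases depress r² by far more than 0.02, so the parsimony rule excludes
them just as the raw rule would. One special case: when some window fits
perfectly to numerical precision (noise-free data), only perfect windows
qualify, so a noiseless series is never extended into a saturated tail. A
non-positive best slope yields a "no growth" flag rather than a doubling
time; fewer than 4 usable points is an error.

Dose ranges are anchored by converting the rat LD50 to molarity
(mg/kg ÷ g/mol = mmol/l, taking 1 kg of body weight as 1 l). The
development ladder uses the fixed fold factors anchor/125, /25, /5,
anchor, ×5, ×25; the initial growth ladder is geometric, by default 6
doses spanning 100-fold centered on the anchor.

NOAEL/LOAEL calling: a dose is adverse when a two-sided Welch t-test of
its replicate doubling times against control wells is significant at
α = 0.05 *and* the effect is a doubling-time increase — slowed growth is
the toxicity readout; acceleration is never scored adverse. The test
choice (Welch, two-sided, no multiplicity correction) mirrors the
3-replicate-well design; it is a documented substitute since no specific
test is canonical for this assay. LOAEL is the lowest adverse dose, NOAEL
the highest non-adverse dose below it; with no adverse dose the NOAEL is
the maximum tested dose and the result carries a censoring flag. A
non-monotone pattern (adverse at one dose but not a higher one) keeps the
LOAEL at the lowest adverse dose and logs a warning. An optional
`min_effect` fold gate (off by default) additionally requires the
dose/control mean ratio to reach a given fold; see "Cohort round trip".

## Developmental reporters

Six reporter strains mark initiation, streaming, mound, slug, culminant
and fruiting-body stages of the 24 h developmental cycle, read every 2 h
(13 points including t = 0). Each replicate course is normalized to its
total signal, so the mean normalized value is exactly 1/T and the raw-scale
rule "a time point exceeding threshold-fold the course mean" becomes
`normalized value ≥ threshold/T` — the two scales agree by construction.
A course has a developmental profile when the across-replicate mean at any
point reaches that cutoff; the peak is the argmax of the mean course.
Rising reporters without an interior maximum are treated identically
(argmax of the course). The per-reporter threshold is calibrated on
control developments as the highest value on the 1.1–1.6 grid (step 0.1 —
the endpoints are given, the step is our choice) at which every control
shows a peak; a flat control fails calibration, and a control without a
profile at comparison time invalidates the assay run.

Treated-vs-control calls use two-sided Welch t-tests on per-replicate peak
times and peak values at α = 0.05: absent (control peaks, treated does
not), delayed/advanced (timing), attenuated/elevated (strength), else
normal. Timing takes precedence when both tests are significant; the
six-way vocabulary is a superset of qualitative "heterogeneity" scoring,
which does not map one-to-one onto timing vs strength. Peak times snap to
the 2 h grid, so zero-variance groups are routine; the Welch p-value is
defined as 1 (equal means) or 0 (different means) in that degenerate case.

Cell-type proportioning compares prespore/prestalk marker ratios at 24 h
against wild type, and is only computed when the fruiting-body call is
normal — a delayed development would inflate the ratio artifactually.

Qualitative-vs-quantitative agreement tallies are reported under three
pooling rules: strict identity; timing defects pooled with absence; and
timing plus strength defects pooled.

## Teratogen classification

The teratogenic potential ratio is growth LOAEL ÷ development NOAEL, with
the growth NOAEL substituted (and recorded) when solubility prevented a
growth LOAEL. Ratio ≥ 10 classifies teratogenic; the boundary is
inclusive. Censored NOAEL values are used as-is, with the censoring flag
propagated, since they bound the true threshold.

Predictivity metrics from the confusion matrix: sensitivity
100·tp/(tp+fn), specificity 100·tn/(tn+fp), PPV 100·tp/(tp+fp), NPV
100·tn/(tn+fn), concordance 100·(tp+tn)/N. The *overall predictive value*
is defined here as the arithmetic mean of PPV and NPV; no formula is
canonical for it, and this one reproduces the published summary rows from
their counts. Metrics are stored at full precision and printed to the
nearest integer (half-up); an empty denominator leaves a metric undefined
rather than 0. `compare_to_reported` flags published values whose
nearest-integer recomputation disagrees — used for the one tabulated PPV
that is inconsistent with its own row's implied counts.

Cross-model dose sets are converted to molarity with the same 1 kg ≈ 1 l
convention, taking the lowest value when sources conflict. Pairwise
Pearson correlations use log10 molar doses (doses span > 5 orders of
magnitude; a linear-scale variant sits behind a flag) on pairwise-complete
compounds, and pairs with n ≤ 3 are reported but flagged untested.
Phenotype-vs-dose independence uses one-way ANOVA on log10 NOAEL across
stage groups, or a Welch t-test for two groups.

## REMI-Seq selection analysis

Counts are normalized per sample: sequence tags of one insertion point are
summed, non-uniquely mapped rows dropped, then scaled to reads per million.
Mutants are binned by mean normalized DMSO counts (<100; 100–1000
inclusive, with both boundaries in the middle bin since the upper bin is
defined as >1000; >1000) so mutants of similar depth are compared and the
high-dropout low-count bin is isolated. Log2 fold changes against the DMSO
replicate mean use pseudocount 1 (base and zero-handling are our choices);
Z-scores are standardized within each (bin × replicate) — the only
standardization population under which the binning has any effect. Bins
with fewer than 3 members have undefined Z and their mutants stay neutral.

Advantaged: Z > 1.5 in both replicates at round 5 (when resistant mutants
have taken over). Disadvantaged: Z < −1 in both replicates at round 2
(before dropouts dominate), excluding the <100-read bin. Insertions map to
genes if intragenic or within 500 bp upstream of a transcription start,
strand-aware with 1-based inclusive coordinates; an insertion upstream of
two divergent genes goes to the nearer start (logged). tRNA, pseudogene
and transposable-element insertions, and genes on an axenic-growth
blacklist (applied to both lists symmetrically), are removed; remaining
intergenic insertions leave the gene lists but stay in the mutant-level
output.

List comparisons: upper-tail hypergeometric overlap probability;
rank-quartile placement (all scored mutants ranked by mean Z, quartile
sizes differing by ≤ 1, ties broken by stable mutant-id order, chi-squared
goodness of fit against uniform, 3 df); and GO-term over-representation by
per-term upper-tail hypergeometric tests against the screened-library
universe (same exclusions as the gene lists), gene-level, at p < 0.05
with no multiplicity correction by default and Benjamini–Hochberg behind a
flag. Ontology graph traversal and semantic redundancy reduction are out
of scope; the term→gene table is a precomputed input.

## Validation scores

Competition fitness: trajectories of the mutant fraction in 50:50 mixed
culture are renormalized by rescaling odds so the adjusted round-0
fraction is exactly 0.5 (odds rescaling rather than subtraction keeps the
[0,1] range); the score is the mean of log2(drug/vehicle) normalized
fractions at round 3 and the final round (6, or the fixation round), with
fractions floored at ε = 5×10⁻⁵ ≈ 1/(2 × 10⁴ cells measured) so fixation
keeps the score finite. Log base 2 throughout (the base is unstated in the
assay definitions; 2 is the package convention). Fluid uptake: per strain,
fold reduction = MFI_untreated / MFI_treated; the score is
log2(reduction_mutant / reduction_control), zero when the mutant responds
like the control mutant.

## Synthetic data

The generators produce every input the pipeline consumes, with the
statistical structure the analyses assume. All randomness flows from one
integer seed through spawned sub-streams, so identical seeds give
byte-identical tables.

- **Growth counts**: lag + exponential capped at capacity; defaults of 3
  wells, 1 h framerate, 48 h horizon and a ~10 h doubling time match the
  study design. Noise is Poisson-lognormal (a Poisson draw around a
  lognormally jittered mean — overdispersed counts are the norm for
  microscopy segmentation), with cv = 0 giving the deterministic curve
  exactly. The default cv of 0.05 is a free parameter: no quantitative
  noise magnitude is published for this assay.
- **Reporter courses**: Gaussian bumps on a baseline with stage-specific
  centers and widths placed by the reported timings (initiation maximal at
  the start and decaying; streaming detectable from ~6 h; mound rising
  from ~12 h; slug spiking at 12–16 h on an elevated baseline; culminant
  after ~20 h; fruiting body only at 22–24 h). Rising reporters are
  simulated with late, wide bumps rather than pure sigmoids: a sigmoid's
  argmax is pinned to the final time point, which would make planted
  delays invisible to the argmax-based peak caller. Treatments compose:
  block (zeroes the peak of all reporters downstream of a stage), delay
  (shifts the peak), attenuation/elevation (scales the peak), baseline
  scaling. Multiplicative lognormal noise, default cv 0.05.
- **Screens**: one lognormal starting pool (dispersion σ = 1) shared by
  drug and vehicle screens — as in a real split pool, which is what makes
  fold changes against DMSO cancel the abundance draw; frequencies update
  deterministically by f ∝ f·(1+s)^g with g = 3.5 generations/round over
  5 rounds; multinomial read sampling per (screen, replicate, round) at
  the configured depth, 2 replicates, sampled at rounds 2 and 5.
- **Competition**: odds multiply by the fitness ratio each round
  (generations folded into the per-round ratio), with beta measurement
  noise of configurable concentration.

What the generators do *not* emulate: images or read-level sequencing
data; per-round genetic drift and bottlenecks in screen populations
(replicates differ only by read sampling, which understates
between-replicate variance for low-abundance mutants); PCR/jackpot
artifacts; plate-position effects (none were found in the assay);
compound-specific dose-response shapes beyond a step effect. Passing
recovery tests therefore demonstrate correctness of the analysis chain
under the assumed noise model, not robustness to every artifact of real
plate-reader or sequencing data.

## Cohort round trip

The deterministic end-to-end check plants a 12-compound cohort: each
compound has a growth-ladder position at which the doubling time doubles
and (optionally) a development-ladder position from which the
fruiting-body reporter is blocked, giving known NOAEL/LOAEL positions,
known ratios, and — with truth labels planted accordingly — a known
confusion matrix (tp=5, fp=2, tn=4, fn=1). Two analysis settings keep the
round trip exact at the study noise levels:

- growth adversity adds a `min_effect` = 1.2-fold doubling-time gate on
  top of Welch significance. A pure α = 0.05 test falsely flags ~5% of
  null doses; a single false call at a low dose collapses the NOAEL and
  with it the ratio. The planted effect (2-fold) passes the gate with a
  wide margin, so power is unaffected.
- a development dose counts adverse when the fruiting-body profile is
  absent at the calibrated threshold. The planted developmental defect is
  a block, and profile presence is essentially noise-free at these
  settings, whereas the timing/strength t-tests would contribute pure
  type-I calls. The t-test machinery is exercised separately by the
  reporter-level tests.

Problem sizes throughout the test suite (12 compounds, 2000-mutant
screens at 5×10⁶ reads, 20–200 seed replications) are chosen so the full
statistical behavior is visible while the whole suite runs in well under a
minute of compute per module.

## Known limitations

- Per-reporter thresholds for the real study strains are not shipped —
  only the calibration rule is published, so users calibrate on their own
  controls.
- The NOAEL/LOAEL caller assumes a monotone adverse direction per assay;
  U-shaped responses are called at the lowest adverse dose with a warning.
- The screen normalization reading "tags summed per insertion point, then
  per-sample scaling" is one interpretation of an ambiguous description;
  it is the only one consistent with the downstream per-mutant fold
  changes.
- GO enrichment assumes a gene-level universe; a mutant-level universe
  would weight multi-insertion genes differently.
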