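# Methods notes

This note documents the models and procedures implemented in `hierkit`, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the numerical decisions taken where the underlying
procedures left room for interpretation.

## Tournament analytics

**Elo engine.** Ratings update after every contest by `Δ = k·(1 − E_winner)`
with `E_winner = 1/(1 + 10^((R_loser − R_winner)/400))`; the update is
exactly zero-sum, so the group total is conserved at `N × start` after every
contest (asserted in tests to 1e-8 points). Defaults `k = 100` points and
`start = 1000` points follow the conventions of the widely used animal-
dominance Elo tooling; both are configurable, and none of the derived
statistics (ranks, stability, consistency) depend on the absolute scale.

**Ordinal ranks.** Rank 1 is the highest rating at the end of a round robin.
Ties are broken by the rating at the end of the previous round robin, then
by animal identifier — an arbitrary but documented convention; ties are
measure-zero for real-valued ratings and arise mainly at the start.

**Stability** is the fraction of animals whose ordinal rank is unchanged
between consecutive round robins (1 = no changes, 0 = all changed), reported
as a trailing moving average. The averaging window defaults to 2
transitions; the source procedure specifies a moving average without a
width, and the window only smooths presentation — endpoints (all-stable = 1,
all-change = 0) are window-invariant. Partial rank swaps are counted by the
unweighted fraction of unchanged animals; a swap-distance-weighted variant
was considered and rejected to keep the stated endpoint semantics exact.

**Pairwise consistency** is a per-pair counter over that pair's contests in
order: 0 at the pair's first contest, incremented when the winner repeats
(capped), reset to 0 on a reversal. The cap is 4 for quartets and 3 for
trios, and values are reported as counter/cap so both group sizes share a
[0, 1] scale. The counter value at each contest (not a within-window
average) is the reported series; the group value is the mean over pairs.
Under fair-coin outcomes the counter is a Markov chain whose exact
per-contest expectation is computed by dynamic programming in the tests and
matched by the Monte-Carlo null ensemble within sampling error.

**Random-outcome null.** `null_ensemble` keeps the observed schedule and
redraws every winner as a fair coin flip, recomputing mean stability and
consistency per replicate. Only the empirical distribution and its
quantiles are returned; model-based significance testing (mixed models etc.)
is deliberately out of scope and left to standard statistical software.

**Defensive index** is A/(A+B) of the two animals' defensive durations;
both-zero is undefined (NaN, flagged), not zero, because "no defensive
behavior at all" carries no share information.

**Draws** are rejected as invalid records: a tube test always produces a
loser (the first mouse to exit), so a draw indicates a data error rather
than a tie to be scored.

## Calcium imaging

**Photometry preprocessing.** Traces are block-average downsampled to 20 Hz
(the block average conserves the mean exactly) and smoothed with a Gaussian
kernel of standard deviation 0.25 s (5 samples at 20 Hz); the kernel width
is configurable and logged. Baseline statistics come from the 30 s
preceding tube entry. The baseline SD is measured on the *downsampled,
unsmoothed* signal: smoothing shrinks noise and threshold together, and with
a smoothed-baseline SD the downstream 3-SD criterion fires on roughly 10% of
pure-noise trials; with the pre-smoothing SD the empirical false-onset rate
is far below the 5% design bound while 10-SD planted steps remain reliably
detected (both recorded by the test suite at 1,000 and 400 noise trials
respectively).

**Onset detection.** After baseline-mean subtraction, the onset is the
first sample (at or after tube entry) starting a run of at least five
successive points whose first differences share a sign while the
baseline-subtracted signal exceeds 3 baseline SDs in that direction. The
3-SD magnitude criterion is applied to the signal values by default; the
alternative reading (thresholding the differentiated values) is available
via `criterion_on="derivative"` but is insensitive to slow-rising sustained
steps after smoothing. Onsets are reported relative to the middle-meeting
event and may be averaged over blocks of four successive trials
(`average_onsets` averages onset times, not traces; trials without a
detection are dropped from their block). Smoothing introduces a systematic
early bias of a fraction of the kernel width (the step's smoothed flank
crosses threshold before the true onset); localization accuracy is therefore
stated as within half the truncated kernel support (4σ = 1 s at defaults),
and the bias cancels in onset *differences*.

**Epoch partition.** The tube is divided into thirds; epoch intervals are
half-open `[start, end)`, with positions exactly at a boundary belonging to
the later epoch. Trials whose first interaction falls outside the middle
third (or lacks the annotation) are excluded, not analyzed.

**ROI classification.** The post-minus-pre mean difference per ROI is
compared with ±2 SD of the session's difference distribution. The SD is
estimated robustly (1.4826 × MAD) by default: the plain across-ROI SD is
self-defeating on responsive sessions, since at most 25% of any
distribution can lie beyond two of its own global SDs (Chebyshev), while
sessions can have well over half their cells responding. The robust
estimate equals the plain SD on null sessions but itself breaks down at 50%
contamination; for such sessions a baseline-derived `null_sd` can be passed
explicitly and takes precedence. Fractions always partition (each ROI gets
exactly one label) and sum to one.

## Slice electrophysiology

**Spikes and FI curves.** Spikes are upward 0 mV crossings with a 2 ms
refractory guard (both configurable; the threshold and guard are
conventions, not fitted). Rates are counts divided by step duration, so
equal spike densities give equal rates regardless of step length.

**Input resistance** is ΔV/ΔI from the plateau of a −10 mV, 20 ms
voltage-clamp pulse; the plateau is the trailing half of the step window to
skip the capacitive transient, and an RC-simulated cell is recovered within
2% in tests.

**Excitability clustering.** K-means with k = 2 on z-scored (peak rate,
input resistance) features, 10 seeded restarts. Cluster identity is defined
by centroid order — cluster 1 is the lower-input-resistance centroid — never
by initialization, and descriptive thresholds (e.g. "< 65 Hz") are not used
as the classifier since printed cluster descriptors can overlap.

**Hartigan's dip.** The dip statistic (smallest sup-norm distance between
the empirical CDF and any unimodal CDF — convex to the mode, concave after,
with an atom permitted at the mode) is computed exactly: candidate mode
positions are scanned over the sample's support points; for each, a small
linear program minimizes the fit error of the convex/concave pieces with the
mode atom absorbing the ecdf jump; a convex-hull feasibility bound prunes
all but the competitive candidates. Anchors: an equally spaced sample gives
exactly `1/(2n)`, two equal point masses approach 1/4, and a constant sample
is exactly unimodal (dip 0). An independently re-derived LP oracle in the
test suite confirms the values on small samples. The statistic is
affine-invariant but, contrary to a common shorthand, *not* invariant under
nonlinear monotone transforms (it depends on spacings). The p-value is
calibrated against uniform reference samples of the same size (seeded
bootstrap, default 1,000 draws).

**PSC detection.** The trace is low-pass filtered at 2 kHz and notch
filtered at 60/120/180 Hz, rectified by polarity (excitatory events
negative-going at −70 mV, inhibitory positive-going at 0 mV), and scanned
with a sliding scaled-template least-squares fit (amplitude + offset per
position). The template is a difference of exponentials with the standard
kinetics per polarity (excitatory: 0.5 ms rise, 2 ms decay, 3 ms baseline,
7 ms template; inhibitory: 1/3/5/10 ms), and detections require the fitted
amplitude to exceed 3 × the baseline noise SD (MAD-estimated, robust to the
events themselves). Qualifying positions are reduced to local maxima and
merged within a rise+decay refractory. Event charge is the fitted amplitude
times the *full* transient's time integral (pA·s = pC), not the truncated
fitting template's; the summed event charges match the noiseless trace
integral within the truncation tolerance in tests.

**Paired pulse.** Five evoked amplitudes are normalized to the first
(ratios[0] ≡ 1 exactly); facilitation/depression is the mean of ratios 2–5
above/below 1, with the exact boundary flagged as "mixed". Amplitudes are
measured pre-pulse-to-peak by the caller's convention.

**TRPM3 fraction** is (peak control − peak antagonist)/peak control on
rectified peaks; it is 0 at identical peaks, 1 at complete block, and
negative if the antagonist potentiates. IV protocols step from −110 to
+30 mV in 5 mV increments from a −70 mV hold; the first 1 ms after step
onset is blanked before taking the maximum-magnitude (signed) current.

**White noise stimuli.** Gaussian current patterns (default 400 patterns,
SD 50 pA) convolved with a peak-normalized alpha kernel `(t/α)·e^{1−t/α}`
(α = 2 ms), of which 200 are selected uniformly at random (seeded). The
kernel imposes an autocorrelation time of order α, verified spectrally in
tests.

## Gene-set enrichment

**QC.** Nuclei are dropped when mitochondrial fraction > 10%, total UMIs >
20,000 (doublet proxy), hemoglobin fraction > 1%, or immediate-early-gene
fraction > 1% (dissection stress). Gene classes default to the "mt-"
prefix, "Hba"/"Hbb" prefixes, and {Fos, Fosb, Jun, Junb, Egr1, Arc}; all
thresholds and lists are configurable. The filter is idempotent, and the
removal report lists a nucleus under every rule it violates.

**Normalization** is `log(1 + count/total × 10⁴)` (natural log); the
downstream ranking is exactly invariant to per-nucleus depth rescaling.

**Ranking.** Genes are ordered by signal-to-noise `(μ_A − μ_B)/(σ_A′ +
σ_B′)` with each σ floored at `max(σ, 0.2·|μ|)` (and 0.2 when both vanish):
the floor prevents near-constant, low-expression genes from dominating the
extremes of the ranking.

**Enrichment score.** The weighted KS running sum increments by
`|metric|^p / Σ_set |metric|^p` at set members (p = 1) and decrements by
`1/(N − n_set)` otherwise; the ES is the running-sum value of maximum
absolute deviation, bounded in [−1, 1]. Leading-edge genes are the set
members at or before the maximum (at or after the minimum for negative ES).
Sets are restricted to the expressed-gene universe and must have 15–500
members after restriction. The implementation matches a literal brute-force
enumeration on short lists and the reference gseapy implementation on a
200-gene ranking.

**Permutations and significance.** Condition labels are permuted within the
cluster being tested (cluster sizes are preserved by construction), 1,000
times by default. ES values are normalized per set by the mean |null ES| of
matching sign (NES). The nominal p-value is the sign-matched tail fraction
of the *pooled* null NES across sets (with a +1 pseudo-count): per-set
nulls floor the p-value near 2/n_perm, which would make the
Benjamini–Hochberg-adjusted p < 0.01 criterion unattainable at 1,000
permutations for any realistically sized collection, whereas the pooled
null (a standard GSEA convention) resolves to ~1/(n_perm × n_sets). FDR
follows the GSEA convention (ratio of null to observed NES tail fractions,
clipped at 1), adjusted p-values are BH within a comparison, and a set is
significant when FDR < 0.25 *and* adjusted p < 0.01.

**DEG intersection.** Leading-edge genes of significant sets are combined
with an externally supplied differential-expression table at |log FC| ≥ 0.1
per cluster and comparison. Both combination conventions appear in
descriptions of this procedure; the default is the intersection (a gene must
pass both criteria), with `mode="union"` available. DEG fitting itself
(e.g. MAST) is not reimplemented — the table is an input.

## Tracing

The convergence index is inputs/starters, multiplied by the fraction of
starter cells located in the target nucleus ("normalized by the percentage"
is implemented as multiplication, per the explicit figure-legend wording).
Relative synaptic density divides each ROI's per-pixel fluorescence by the
same slice's dark-region reference and normalizes to the ROI sum, so values
sum to exactly 1 per animal; replicates are aggregated as per-ROI means.
The dark reference is taken per slice; both metrics are invariant to global
intensity or count rescaling.

## Synthetic data: what it does and does not emulate

Generators are seeded and bit-reproducible. The dominance world draws
winners from a Bradley–Terry-style logistic in the latent-score difference
(any monotone link would do; the logistic is chosen for consistency with
Elo's own model), with an optional outcome-inversion rate for upsets, and
schedules every unordered pair once per round robin with roles swapped on
alternate round robins — 12 contests per quartet tournament, 6 per trio
(the ordered-pair rule; a 9-interaction trio convention exists but is not
emulated, and the generator logs a note for trios). Defensive durations are
gamma-distributed with the loser accruing extra time, so the defensive
index correlates with losing as observed in behaving animals.

Photometry trials are Gaussian noise with an optional sustained step;
miniscope sessions are per-ROI pre/post means with planted response
classes; PSC traces are Poisson-timed difference-of-exponential transients
in Gaussian noise; count matrices are gamma–Poisson with planted
per-condition log-scale mean shifts on chosen sets, low-expressed QC
sentinel genes, and injectable QC violations.

None of the generators emulate slow drifts, bleaching, motion artifacts,
hemodynamic contamination, bursty (non-Poisson) synaptic release,
overlapping-event pileup beyond what the Poisson process produces, ambient
RNA, or batch effects. Passing tests therefore demonstrate correctness of
the procedures under their stated noise models — not robustness to every
artifact of real recordings, which is the role of the excluded upstream
preprocessing (motion correction, ΔF/F isosbestic correction, source
extraction, read alignment).

## Problem sizes

Simulation sizes used by the test suite and the acceptance script are
chosen to give tight Monte-Carlo error at interactive runtimes on one CPU:
10⁴ random logs for zero-sum conservation, 400 replicates for null
ensembles, 1,000 noise trials for the false-onset bound, 10,000 ROIs for
Gaussian tails, 60 s at 20 kHz for detector recall, 160 nuclei × 250 genes
× 200 permutations × 20 seeds for planted-set detection. Dip-test p-values
in tests use 200 bootstrap draws (the exact-LP statistic is the costly
part); the default elsewhere is 1,000.

## Known limitations

- The dip computation is exact but LP-based; for samples much larger than a
  few hundred points, bootstrap p-values become the dominant cost.
- The deviation-onset detector inherits a systematic early bias from
  smoothing (documented above); compare onsets, not absolute values,
  across conditions.
- `classify_rois` cannot infer the null scale when ≥50% of ROIs respond;
  supply `null_sd` from a baseline recording in that regime.
- The GSEA engine stores counts densely; it targets the post-QC scale of a
  focused study (10³–10⁴ nuclei, 10³–10⁴ genes), not atlas-scale matrices.
- Multiple-group tournament logs are analyzed one group at a time;
  cross-group mixed-effects modeling is intentionally out of scope.
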