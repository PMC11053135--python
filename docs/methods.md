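# Methods

## What the package models

`eesmap` analyzes acute epidural electrical stimulation (EES) mapping
experiments of the lower urinary tract: a ball electrode on the dorsal
surface of the spinal cord delivers current pulses at a series of
rostro-caudal sites while detrusor EMG (Detr), external-urethral-sphincter
EMG (EUS), hindlimb tibialis-anterior EMG (TA) and intravesical pressure
(CYST) are recorded.  The analysis has four stages, each usable on its own:

1. **Evoked-potential extraction** — stimulus-locked epoching and
   averaging at 1 Hz, first-peak latency and peak-to-peak amplitude per
   (site, channel, current).
2. **Recruitment mapping** — amplitude-vs-current curves per (site,
   channel), rising-limb regression slopes, per-animal normalization and
   the cross-animal sites x channels "segment map".
3. **Burst analysis** — sustained 5 Hz trains quantified as a percentage
   of the pre-stimulation background (%BG).
4. **Exact nonparametric statistics** — enumerated Wilcoxon signed-rank
   and Mann-Whitney tests, Kruskal-Wallis with Dunn's post hoc, for the
   five-animal sample sizes where asymptotics are unreliable.

Because raw recordings from such experiments are rarely shareable, the
package ships a synthetic-data generator whose defaults encode the study
conditions (protocol, latencies, rostro-caudal gain structure), with full
ground truth for closed-loop validation of every downstream stage.

## Synthetic recordings

**Protocol.** Default 1 Hz pulses over a stepped ladder of 10–800 µA in
10 µA increments, 10 pulses per rung, 0.3 ms pulse width, digitized at
20 kHz.  Burst mode: a 5 Hz train at the top ladder current, preceded by a
quiet background segment (default 5 s).

**Templates.** Evoked waveforms are fixed shapes scaled per pulse:

* *fast* (EUS, TA): three alternating Gaussian lobes (+1, −1.3, +0.3 of a
  common width), 20 ms default duration — multiphasic and integrating to
  ~0, as AC-coupled EMG does;
* *slow* (Detr): a positive raised-cosine lobe over the first 30% of the
  waveform followed by a longer, shallower negative lobe with matching
  area, 225 ms default duration;
* *pressure* (CYST): a single positive lobe with a fast (15%) half-cosine
  rise and slow decay; unipolar, no zero-integral constraint.

Rise times are deliberately short relative to the waveform so that the
first peak sits early in the template and the response onset stays after
the stimulus at the configured latencies.  A template's max-minus-min
equals the commanded amplitude exactly.

**Recruitment law.** Response amplitude is piecewise linear in current:
zero below threshold, `gain x (current − threshold)` up to saturation,
constant beyond.  Site specificity enters as a per-(site, channel) gain
multiplier; the shipped `study_defaults()` preset makes Detr/CYST
rostral-dominant (T13/L1 multipliers ≈ 4–6x the caudal ones) and EUS
caudal-dominant, with channel latencies at the reported group means
(Detr 38.0 ms at both levels, EUS 13.7 ms rostral / 7.4 ms caudal,
TA 14.6 / 9.0 ms).  Recruitment thresholds default to 0 µA so the fitted
rising-limb slope equals the effective gain identically on noise-free
data; thresholds are per-channel parameters for users who want them.

**Stochastic elements.** Latency jitter is normal, truncated at ±3 SD
(default SDs 0.3–1 ms).  Measurement noise is white Gaussian per channel
(defaults 0.02–0.05 units; no noise levels are reported for the original
recordings, so these are phenomenological and fully configurable).
Optional tonic background activity (5 ms-correlated Gaussian noise scaled
to a requested RMS) supplies the %BG denominator in burst mode.  A
one-sample full-scale deflection at each pulse marks the stimulus
artifact.  All randomness derives from one master seed through a fixed
counter scheme (site *i* → substream *i*; session-level streams and
per-animal cohort draws use reserved keys), so sessions are
bit-reproducible and adding a site never perturbs the others.  Cohorts
add per-animal lognormal gain variability (default σ = 0.2).

**What the generator does not emulate:** movement artifacts, electrode
drift, mains interference, bladder filling dynamics, inter-pulse
facilitation/depression, or any biophysical model of current spread
(gains are phenomenological).  Passing tests therefore demonstrate that
the *analysis* recovers known parameters under idealized noise, not that
it is robust to every artifact of real recordings.

## Evoked-potential measurement

Per (site, channel, current): sweeps in `[-pre, +post]` (defaults 50 /
400 ms) are averaged pointwise; baseline mean and SD come from
`[-baseline_window, 0)` (default 50 ms).  The first `blanking` ms
(default 2 ms) after the pulse are excluded from measurement and linearly
interpolated — anchored on ~1 ms local means — *before* any smoothing, so
the stimulus artifact cannot leak into the baseline or response window.
Optional moving-average smoothing follows (recommended ~10 ms for the
slow Detr/CYST waves, none or ≤1 ms for fast EMG; the pipeline applies
this per channel kind).  Samples within half a smoothing window of the
blanked interval are also excluded from measurement, because they mix
with the interpolated segment.

**Presence and first peak.** A response is present when some deflection
exceeds `k x baseline SD` (default k = 3) *and stays beyond the threshold
for at least 0.5 ms*.  The sustained-exceedance requirement is essential:
a bare k-sigma rule is crossed somewhere in a several-hundred-sample
window almost surely, while white noise essentially never stays beyond
3 SD for half a millisecond at 20 kHz — measured false-presence rate on
pure noise is ≤ 5% over 100 seeded epochs.  The *first peak* is the
largest deviation inside the first qualifying excursion (excursions are
same-sign by construction); taking the excursion extremum rather than the
first raw inflection keeps latency robust to noise wiggles riding on the
rising limb of slow waves.  Latency is the time of that peak; when
baseline SD is exactly zero any nonzero excursion qualifies.

**Peak-to-peak amplitude** is the first peak minus the extremum of the
immediately following opposite-polarity qualifying excursion; for
monophasic responses (no such excursion) it is |first peak − baseline
mean|; absent responses score 0.  A `minmax` mode (max − min of the
post-blanking window) is selectable.  Rectification before averaging is
available but off by default for latency work, since it destroys the
polarity of the first peak.

With the defaults, latency on broad slow waves carries an intrinsic
peak-location uncertainty of a few ms at realistic SNR (the wave's top is
flat relative to the noise), consistent with the large latency SDs
typical of detrusor responses; fast-channel latencies resolve to well
under 1 ms.

## Recruitment mapping

Recruitment points are the measured peak-to-peak amplitudes versus
current (absent → 0; repeats averaged; sorted).  The slope is ordinary
least squares of amplitude on current over the *rising limb only*: from
the lowest current through the first attainment of the maximum amplitude.
Points after the maximum (plateau or decline) are excluded, so the
estimate is invariant to how far past saturation the ladder ran.  A
constant curve gets slope 0 over the full range; a range with fewer than
two points leaves the slope undefined and excluded from normalization.
The intercept is free (the fit is a generic linear regression, not forced
through zero).

Normalization is per animal and per channel across sites: slopes are
clamped at 0, divided by the per-channel maximum and expressed in %, so
each channel's map spans [0, 100] per animal (an all-zero channel is
flagged degenerate).  The segment map is the cross-animal mean ± SE per
(site, channel), with site labels aligned across animals (missing sites
simply absent).  For the rostral/caudal contrast each animal contributes
its group score — by default the *maximum* over its sites in the group
(the region's best recruitment; `mean` is selectable) — and groups are
compared with the paired exact Wilcoxon test.

## Burst analysis

%BG = 100 x stim metric / background metric, computed identically on both
intervals: full-wave rectification, 50 ms moving-average smoothing, then
RMS (a mean-rectified metric is selectable; the choice is recorded in the
result).  Smoothing is applied per interval so the background never
bleeds into the stimulation segment through the filter.
Stimulus-artifact samples (2 ms per pulse) are interpolated away first.
The background interval defaults to the whole pre-train block; the
stimulation interval runs from the first pulse to one period past the
last.  A zero background metric raises a degenerate-background error
rather than returning infinity.  The generator's burst ground truth
stores the %BG expected from the pre-noise signal under the default
metric, enabling closed-loop tests (measured within ~5% when measurement
noise is small relative to tonic activity).

## Exact statistics

All tests operate on midranks; sidedness is always explicit, never
inferred from the data.

* **Wilcoxon signed-rank**: zero differences dropped; W = sum of
  positive-difference ranks; the exact null distribution of W over all
  2^m sign assignments is built by an integer dynamic program over
  doubled midranks (ties exact by construction).  Enumeration is used up
  to m = 25 nonzero pairs; beyond that a tie-corrected normal
  approximation with continuity correction applies (or on request).
* **Mann-Whitney**: U for the first sample; exact p from the distribution
  of the first-sample rank sum over all C(n1+n2, n1) labelings, same
  doubled-midrank dynamic program.
* **Two-sided convention**: `min(1, 2 x min(lower tail, upper tail))`.
  Under complete separation this gives 2/C(9,4) ≈ 0.0159 for sizes (4, 5)
  and 2/C(8,3) ≈ 0.0357 for (3, 5).
* **Kruskal-Wallis**: H with the standard tie correction; p from the
  chi-square approximation with k−1 df (the conventional choice); an
  exact permutation p is available behind a flag for pooled n ≤ 12.
* **Dunn's post hoc**: z from mean-rank differences with tie-corrected
  pooled variance; two-sided normal p; adjustment default `none`
  (reported post-hoc p-values in this literature rarely state their
  correction), with Bonferroni and Holm selectable.
* **Summaries** are mean ± SE (sample SD/√n; SE = 0 flagged at n = 1).
* p-values are printed with half-up rounding (`round_half_up`), matching
  the convention that renders 1/32 as 0.0313 rather than banker's 0.0312.

Correctness is established against literal enumeration oracles (all sign
vectors / all labelings) over hundreds of random small instances
including ties, and against scipy's exact methods where ties are absent.

## Pipeline and reproducibility

`run_pipeline` composes simulate → extract → map → burst → stats for a
cohort and writes delimited-text tables (`evoked.csv`, `curves.csv`,
`slopes.csv`, `segment_map.csv`, `group_summary.csv`, `burst.csv`,
`stats.csv`), each opening with a `# config_hash=` comment (SHA-256 of
the JSON-serialized configuration) and printing floats with 6 significant
digits.  Runs are deterministic given (config, seed): two runs produce
byte-identical files.  Times are absolute seconds in session containers
and stimulus-relative milliseconds in evoked outputs.

**Problem sizes.** The validation suite runs the analysis at reduced
scale, which the generator supports without loss of structure: 2–4 kHz
digitization (20 kHz where single-sample criteria matter), 6–12 rung
ladders ending at 60–120 µA, 3–5 pulses per rung, five sites, and cohorts
of 3–5 animals; cohort-recovery checks use 50 seeded cohorts and
Monte-Carlo properties 100 replicates.  These sizes preserve every
qualitative feature of the full protocol (sub- to supra-threshold ladder
coverage, multi-sweep averaging, rostral/caudal contrast) while keeping
the whole suite fast.

## Known limitations

* The presence criterion assumes approximately white, stationary baseline
  noise; strongly colored noise would require retuning the
  sustained-exceedance duration.
* Latency of broad slow waves is intrinsically imprecise at low SNR
  (flat-top argmax); group means remain unbiased for symmetric peaks, but
  the asymmetric pressure waveform acquires a small rightward bias at
  high noise, one reason CYST is conventionally excluded from latency
  statistics.
* Near recruitment threshold the first response component may fall below
  the detection criterion while a later, larger component qualifies; the
  pipeline therefore summarizes latency over the upper half of the
  current ladder only.
* The Kruskal-Wallis chi-square p is approximate at n = 5 per group; the
  exact permutation option exists precisely because of this, but the
  chi-square value is what this literature reports.
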