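# Methods

This note records the model behind `forktrace`, the numerical choices the
published procedure leaves open, what the simulator does and does not
emulate, and the known limitations. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model

A resquiggled read is a sequence of reference-aligned bases with one mean
normalized current per base, (Nᵢ, mᵢ). All analysis operates on the
current shifts δᵢ = mᵢ − mᵢ₊₁. The shift at transition i is attributed
to the hexamer bases i…i+5 (the pentamer-to-pentamer transition), and
"a T in the middle of the pentamer" means position i+2 — the site at
which B/T calling takes place. Bases are always given on the reference
forward strand (the upstream signal-to-reference alignment maps them
there), so hexamer contexts are strand-free inside this package; this is
an explicit assumption, documented because the handling of reverse-strand
reads upstream is outside our control.

The expected shift per hexamer is estimated as the per-hexamer arithmetic
mean over a read cohort, once for a thymidine-only cohort (TM_T) and once
for a fully BrdU-substituted cohort (TM_B). BrdU displaces the expected
shift positively, essentially only at central-T hexamers, and
|δᵀ − δᴮ| > 0.4 defines the informative subset (about 512 of the 4096
transitions, i.e. one transition per ~8 nt of random sequence).

### Drift normalization

Each read may drift linearly in scale and offset. The correction is the
ordinary least squares map (α₀, β₀) = argmin Σ (α δᵢ + β − δᵢ⁽ᵉ⁾)²,
fitted only on transitions with no T in the centre of either pentamer
(positions i+2 and i+3), because those are the transitions BrdU can
perturb. Choices the published rule leaves open, fixed here:

* the 0.25 rejection cutoff applies to the *mean* squared distance (the
  summed distance would depend on read length); the inequality is strict,
  a read exactly at the cutoff is retained;
* a read needs at least 50 eligible transitions, below which the
  two-parameter fit is unstable;
* hexamers with fewer than `min_occurrences` observations are imputed
  with the global mean shift and flagged, so expected-shift lookups have
  no holes.

Because the fit regresses the expected signal on the *noisy* observed
shifts, the recovered α is attenuated by the classical
regression-dilution factor var(signal)/(var(signal)+σ²). The two-step
procedure (bootstrap matrix → per-read fit → re-estimate) is therefore
self-consistent rather than unbiased: estimated matrices are globally
shrunk by the same factor the normalized reads are. The recovery test
asserts correlation with the generating matrices plus a bounded global
scale rather than elementwise identity, which is what the estimator can
actually deliver.

## BrdU content estimation

**TM caller.** At every central-T site: X if the two contexts are less
than 0.4 apart, otherwise the context nearest to the observed shift.
Exact ties stay X — deterministic and conservative. The fractional
profile is a sliding B/(B+T) over 30 consecutive non-X calls, X excluded
from numerator and denominator, anchored at the central retained site.

**Convolutional estimator.** Input windows are 96 consecutive
transitions, each encoded as one-hot base (A,T,C,G order) plus the
normalized shift, shape (96, 5). Three 1-D convolutions (32 filters,
kernel 5, same padding, ReLU) with 4× max-pooling after the first two
(hence the window must be a multiple of 16) give a (6, 32) map; a shared
dense+sigmoid head scores each of the 6 positions and the mean is the
window's content. Training uses plain SGD (learning rate 0.1, decay
10⁻⁶ per step, momentum 0.9), a 90/10 train/validation split, and early
stopping after 5 epochs without validation improvement. Labels are
per-window copies of the cohort-level content. An optional second pass
predicts each high-content read's mean content and drops reads predicting
below half their label (parental molecules contaminating a substituted
cohort), then retrains from scratch. Unstated details fixed here: mean
squared error loss, batch size 32, Glorot-uniform initialization, best
validation weights restored. The network is implemented directly in
numpy (explicit forward/backward passes); a gradient test checks backprop
against finite differences. Inference slides the window by 10
transitions (plus one flush-right window), and each 10-nt segment
averages the predictions of every window fully containing it.

## Track detection, orientation, scores

The smoothed profile is rescaled per read to [0, 1] *only for
segmentation*, so that the Ramer–Douglas–Peucker tolerance (default
ε = 0.05, rescaled units) is comparable across reads. Amplitudes,
flanking minima, plateau checks and slopes are all measured on the
BrdU-content scale itself: the plateau ceilings (0.12 TM / 0.14 CNN) and
the 0.075 level gap are unambiguous content fractions, and keeping
amplitudes on the same scale avoids inflating noise wiggles on
low-amplitude reads.

The polyline vertices are reduced to turning points with a hysteresis
equal to the down amplitude (0.26): a running extreme becomes a turning
point only once the signal has reversed by more than that amount, so no
number of sub-threshold noise wiggles can fragment a long rise or a long
chase decay. Run endpoints are then trimmed to the 10–90% span of the
run amplitude, which keeps noise excursions merged into a run from
dragging the track start into the flanking plateau — track-start
precision depends on this. A track is an upward run with total rise
> 0.44 followed, possibly across sub-threshold plateau wiggles, by a
downward run with total fall > 0.26. An upward run reaching the end of
the read can optionally be kept as an open-ended (unorientable) track;
the chimeric-read precision experiment uses this.

**Orientation.** The steep side of a pulse-chase track is the fork
start. Rise/fall slope-magnitude ratio above 1.5 orients the track; with
symmetric slopes, the flanking-minima rule applies (the chase side
retains ~10% BrdU, above the pre-pulse level). Two abstention guards are
this package's own additions: (i) if the slope rule and the level rule
are both decisive but contradict each other the track stays unoriented —
a genuine fork satisfies both; (ii) any orientation requires the putative
pre-pulse flank to be near parental content (≤ 0.15 TM / 0.175 CNN).
That flank is DNA replicated before the pulse, so elevated content there
marks a noise structure riding on a real track's tail. Both guards only
ever withhold an orientation, never flip one.

**Scores.** The published procedure names but never defines its two
per-track confidence scores; the reconstructions used here are:
Ascore = signed steep/shallow slope-magnitude ratio (sign encodes
direction, + = rightward), so the |Ascore| > 2 event gate is a stricter
version of the 1.5 orientation ratio; Jscore = starting-jump amplitude
(the steep-side shift, content units) divided by the read's off-track
residual standard deviation around the piecewise-linear fit — a Jscore
above 1 means the jump exceeds the read's noise floor.

**Read filters.** Reads shorter than 5 kb are dropped; a read must also
show a whole-read BrdU-proportion standard deviation of at least 0.3 (TM)
or 0.115 (CNN) and a smoothed amplitude of at least 0.5 / 0.4. For the
TM path the sd is computed on the unsmoothed binary B/T call series: a
binary series has sd √(p(1−p)) ≤ 0.5 and the 0.3 threshold is attainable
and meaningful there (it keeps reads whose overall B fraction lies
between ~10% and ~90%), whereas the smoothed fraction profile of any
realistic track shape has whole-read sd below ~0.25, which would make a
0.3 threshold reject everything. The CNN threshold 0.115 applies to the
continuous content profile, which is consistent on that scale.

**Events.** Only pairs adjacent along the read qualify; an intervening
unoriented or low-score track voids the pair (conservative reading of
"consecutive"). Initiation: diverging pair, fork-start gap ≥ 1 kb
(inclusive), mean content between the fork starts at or below the plateau
ceiling (full interval, untrimmed). Termination: converging pair, content
at both fork starts at or below the same ceiling; no gap requirement.
Midpoints are the means of the two fork starts. CNN/TM event sets are
pooled by greedy nearest-pair matching within 2 kb per read and event
type (ties to the smaller distance, then leftmost); matched pairs count
once.

## Genome profiles

Coverage is accumulated on a 100-nt internal grid (a documented
memory/accuracy compromise; the ±50 nt quantization is far below the
method's ~100–200 nt start precision). RFD = (R − L)/(R + L), missing
where no oriented track covers a bin — missing is NaN, never 0, because
RFD = 0 (balanced forks) is meaningful. Smoothing is a centred 1-kb
running mean that shrinks at chromosome ends, ignores missing bins and
leaves a bin missing when less than half its window is defined.

OEM(x) = rightward-fork fraction of (x, x+10 kb] minus that of
(x−10 kb, x], which makes initiation zones positive (+1 at an isolated
fully efficient origin) and termination zones negative; with the opposite
window order an origin would score −1, so the sign convention is fixed to
match how ascending/descending RFD segments are discussed. OEM windows
whose mean per-bin coverage falls below 5 tracks are masked: a
fork-direction fraction estimated from a handful of molecules is noise.

I−T density bins initiation minus termination counts in non-overlapping
5-kb windows, smoothed with the centred odd-bin approximation of a 10-kb
running mean (3 bins). Profile comparisons use Spearman rank correlation
over bins defined in both signals (≥ 10 required).

## Event analysis

Clustering is single linkage: consecutive events with gap strictly less
than the mIED (default 1.5 kb) share a cluster; dimension d = member
count, width = outmost-member span, median point = interpolated median of
member midpoints (the lower/interpolated choice for even d is unstated
upstream; interpolated is used). Dimension classes are d = 1, 2–4, 5–12,
> 12. Shuffled controls redistribute events uniformly and independently
per chromosome, preserving per-chromosome counts, without collision or
annotation avoidance. Distances are midpoint-to-centre. Overlaps resize
every interval to 2 kb around its midpoint and require strictly positive
intersection. The PWM scan expects a non-negative weight matrix (columns
A, C, G, T), scores both strands and reports matches at ≥ threshold ×
maximal attainable score at forward coordinates; the motif-fraction null
band shuffles window centres (default 1000 times) and reports the median,
the [0.01, 0.99] percentile interval, and the observed value's empirical
percentile.

## The simulator: what it emulates and what it does not

The simulator generates data at the level the analysis consumes —
per-base mean currents and shifts — not raw picoampere events. Defaults
are the study conditions:

* 512/4096 informative hexamers (12.5%), all with a central T, displaced
  positively by ~0.8 normalized units (never below 0.45, so every
  informative site clears the 0.4 calling threshold);
* thymidine-context shifts drawn N(0, 0.7); per-transition Gaussian noise
  σ = 0.25 — chosen so that the native-DNA false-B rate (~6–8%) and the
  resulting whole-read call-sd distribution reproduce the selectivity the
  published read filters assume. The noise distribution is not stated
  upstream; i.i.d. Gaussian is an assumption, with variance a config
  knob;
* pulse-chase tracks: logistic rise over 300 nt from ~0 to a peak drawn
  uniformly in [0.6, 0.8], then exponential decay over 15 kb to a 0.10
  chase floor that persists until harvest. Rise and decay shapes are
  selectable (a logistic decay with equal rise/decay lengths gives an
  exactly symmetric track, on which orientation must — and does —
  refuse to call);
* read lengths uniform in 10–140 kb; per-read drift α ∈ [0.8, 1.2],
  β ∈ [−0.2, 0.2] applied inversely so normalization must undo it;
* genome runs: each read comes from its own cell; origins fire with
  their efficiency at a time uniform in a 30-min window before the pulse
  (standing in for the spread of S-phase progression across an
  asynchronous culture), forks move at 1500 nt/min, a position's
  replication time is the earliest fork arrival — so late-firing origins
  inside replicated regions are passively replicated and contribute
  nothing — and replication stops at harvest. Chimeric reads hold the
  chase floor strictly left of the transition point and rise over
  `rise_length` from the point on, so the returned truth coordinate is
  the foot of the rise, the quantity track-start detection estimates.

Not emulated: pore-level event segmentation and basecalling errors,
sequence-composition bias of the informative set (real informative
transitions are unevenly distributed, giving ~18-nt call spacing against
~8 nt here), per-flowcell batch effects beyond the linear per-read drift,
repeats/rDNA, and fork stalling or speed variation. Passing tests
therefore demonstrate correctness of the analysis pipeline under the
stated signal model, not robustness to every artefact of real nanopore
data.

## Validation scale

The validation suite runs at desk scale, sized to exercise every stage
in minutes: 500 native reads for the false-positive null, 300 chimeric
reads for start precision, 500 reads per condition for matrix recovery,
five cohorts of 60 reads (2 kb) for estimator ranking with the CNN
trained on 40 reads per cohort, and one genome run of 2000 reads over
2 × 300 kb with five origins whose efficiencies (1.0, 1.0, 0.25, 0.07,
0.02) ladder the cluster-dimension classes; the weak origins sit 40 kb
from strong ones so through-moving forks provide the passive coverage
against which their RFD shift is measured. Dimension classes holding
only 1–3 events make the per-class mean RFD shift noisy, so the
monotonicity check allows a 0.3 slack between consecutive classes while
requiring a large overall increase.

## Known limitations

* Ascore/Jscore are reconstructions (the published pipeline names but
  does not define them); absolute score values are not comparable to
  other implementations, only their gating behaviour is.
* The TM read filter interpretation (binary-call sd) and the
  content-scale amplitude reading are this package's resolutions of
  ambiguous published thresholds; both are config-exposed.
* The RDP tolerance, turning-point hysteresis, foot-trimming fraction,
  orientation guards and OEM coverage floor are implementation choices
  calibrated against the simulator; on real data they may warrant
  re-tuning through `DetectionParams`.
* Orientation accuracy and event recall degrade for tracks truncated at
  read boundaries; open-ended tracks are never oriented.
* The CNN estimator compresses the content scale toward the cohort mean
  (regression toward the middle); cohort ranking is reliable, absolute
  content less so — consistent with the underestimation the TM/CNN
  comparison to mass spectrometry shows on real data.
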