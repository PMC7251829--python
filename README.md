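# forktrace

Single-molecule replication fork mapping from nanopore current-shift
signals after a BrdU pulse-chase.

When *S. cerevisiae* cells carrying a reconstituted thymidine salvage
pathway receive a brief BrdU pulse followed by a thymidine chase, newly
replicated DNA carries an asymmetric incorporation track: BrdU content
rises steeply (from ~0 to 60–80%) at the position each fork occupied at
pulse onset and decays shallowly (to ~10%) along the direction of fork
movement. Because BrdU positively shifts the nanopore current at
pentamer-to-pentamer transitions with a central T, these tracks can be
read directly off single sequenced molecules. `forktrace` implements the
full computational path from reference-aligned per-base currents to
genome-wide replication profiles:

* **Signal normalization** — per-hexamer expected current shifts
  (4096-entry transition matrices for the thymidine and BrdU contexts),
  two-step per-read linear drift correction
  (α̂, β̂) = argmin Σᵢ (α δᵢ + β − δᵢ⁽ᵉ⁾)², and a residual filter
  (mean squared distance > 0.25 discards the read).
* **BrdU content estimation** — a transition-matrix caller that assigns
  B/T/X at every T site (X wherever |δᵀ − δᴮ| ≤ 0.4), smoothed as a
  sliding B/(B+T) fraction over 30 consecutive calls; and an independent
  convolutional estimator (three 32-filter kernel-5 convolutions with two
  4× max-poolings and a sigmoid head) mapping 96-transition windows to
  fractional content on a 10-nt grid.
* **Track detection and orientation** — Ramer–Douglas–Peucker
  piecewise-linear segmentation, upward/downward shift detection
  (amplitudes > 0.44 / > 0.26), orientation by slope asymmetry
  (−slope₁/slope₂ > 1.5) or flanking-minima levels (min_f − min_p >
  0.075), and two confidence scores: Ascore (signed steep/shallow slope
  ratio) and Jscore (starting-jump amplitude over the read's residual
  noise).
* **Event calling** — initiation = consecutive diverging high-confidence
  tracks (|Ascore| > 2, Jscore > 1) with fork starts ≥ 1 kb apart and a
  low inter-fork plateau; termination = converging tracks with low
  content at both fork starts; event midpoint = mean of the fork starts.
* **Genome profiles** — RFD = (R − L)/(R + L) with a 1-kb running mean,
  the origin efficiency metric (OEM) on 10-kb flanking windows,
  initiation-minus-termination density in 5-kb bins, Spearman profile
  correlations, event clustering at a maximal inter-event distance
  (mIED), distance/overlap comparisons against annotation BED tracks,
  replication-timing assignment and PWM motif scans with shuffled
  controls.
* **A pulse-chase simulator** — generates transition matrices, drifting
  noisy reads, in-silico chimeric reads with known transition points, and
  whole-genome read populations driven by an origin-firing model with
  passive replication, together with per-read ground truth. Every stage
  of the pipeline is testable with no sequencing data.

## Worked example

```python
import forktrace as ft

# simulate a 2 x 300 kb genome with five origins of graded efficiency
cfg = ft.SimulationConfig(seed=1)
lengths = {"chrS1": 300_000, "chrS2": 300_000}
genome = ft.random_genome(lengths, seed=2)
origins = ft.OriginModel(
    positions={"chrS1": [70_000, 110_000], "chrS2": [60_000, 100_000, 140_000]},
    efficiencies={"chrS1": [1.0, 0.25], "chrS2": [0.02, 1.0, 0.07]},
)
reads, truth = ft.simulate_genome_run(genome, origins, 2_000, cfg)

# TM path: normalize, call B/T/X, smooth, detect and orient tracks
tm_t, tm_b = ft.make_transition_matrices(cfg)
profiles = ft.tm_profiles(reads, tm_t, tm_b)
tracks, events = ft.detect_all(profiles, ft.DetectionParams.for_tm())

oriented = ft.oriented(tracks)
n_init = sum(e.type == "initiation" for e in events)
print(len(oriented), n_init, len(events) - n_init)

rfd = ft.compute_rfd(oriented, lengths)
print(round(rfd.values["chrS1"][650], 2), round(rfd.values["chrS1"][750], 2))
```

Output:

```
862 82 7
-1.0 1.0
```

862 tracks were oriented, giving 82 initiation and 7 termination events;
the RFD 5 kb left of the fully efficient origin at chrS1:70 kb is −1.0
(purely leftward forks) and 5 kb right of it +1.0 (purely rightward),
i.e. the profile crosses zero at the origin, as population RFD around an
efficient origin must.

## Command line

```bash
forktrace simulate --out run/ --seed 1 --n-reads 500
forktrace train-tm --thymidine thy.tsv --brdu brdu.tsv --out tm.tsv
forktrace call   --reads run/reads.tsv --matrices tm.tsv --out profiles.tsv
forktrace tracks --reads run/reads.tsv --matrices tm.tsv --out tracks.bed
forktrace events --reads run/reads.tsv --matrices tm.tsv --out events.bed
forktrace profiles --reads run/reads.tsv --matrices tm.tsv \
    --genome-sizes sizes.txt --out profiles/
forktrace cluster --events events.bed --mied 1500 --out clusters.bed
```

## Resquiggled-read table format

Reads enter the pipeline as a tab-separated text table, one read per row
(see `tests/data/example_reads.tsv` for a 5-read example):

```
#read_id  chrom  ref_start  strand  bases      currents            meta
r0        chrI   1000       +       ACGTTG...  0.12,-0.43,1.05,...  {}
```

`bases` is the reference-aligned base string on the forward strand,
`currents` the comma-separated per-base mean normalized currents, and
`meta` an optional JSON object (the simulator stores its ground truth
there). Current shifts δᵢ = mᵢ − mᵢ₊₁ are derived on load. All
coordinates are 0-based, half-open. Annotations are plain BED6; genome
signals are read/written as wiggle or bedGraph.

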