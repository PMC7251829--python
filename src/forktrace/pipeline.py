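"""End-to-end orchestration of the per-read analysis.

Thin glue used by the command-line interface, the test-suite and the
reproduction script: normalize reads against the thymidine reference,
estimate BrdU content (TM or CNN), filter, detect/orient/score tracks and
call events.
"""

from __future__ import annotations

import numpy as np

from .calling import CnnEstimator, call_cnn, call_tm, profile_to_fraction
from .io import BrdUProfile, ReplicationEvent, ReplicationTrack, ResquiggledRead, TransitionMatrix
from .normalize import normalize_reads
from .tracks import DetectionParams, analyze_profile, filter_reads


def tm_profiles(
    reads: list[ResquiggledRead],
    tm_t: TransitionMatrix,
    tm_b: TransitionMatrix,
    smoothing_window: int = 30,
    normalize: bool = True,
) -> list[BrdUProfile]:
    """Smoothed TM content profiles for a read cohort."""
    if normalize:
        reads, _ = normalize_reads(reads, tm_t)
    return [profile_to_fraction(call_tm(r, tm_t, tm_b), smoothing_window)
            for r in reads]


def cnn_profiles(reads: list[ResquiggledRead], estimator: CnnEstimator,
                 tm_t: TransitionMatrix, normalize: bool = True) -> list[BrdUProfile]:
    """CNN content profiles for a read cohort."""
    if normalize:
        reads, _ = normalize_reads(reads, tm_t)
    return [call_cnn(r, estimator) for r in reads]


def detect_all(
    profiles: list[BrdUProfile],
    params: DetectionParams,
    qc: list | None = None,
) -> tuple[list[ReplicationTrack], list[ReplicationEvent]]:
    """Filter profiles, then detect, orient, score and call events."""
    tracks: list[ReplicationTrack] = []
    events: list[ReplicationEvent] = []
    for profile in filter_reads(profiles, params, qc=qc):
        t, e = analyze_profile(profile, params)
        tracks.extend(t)
        events.extend(e)
    return tracks, events


def oriented(tracks: list[ReplicationTrack]) -> list[ReplicationTrack]:
    return [t for t in tracks if t.orientation in ("right", "left")]


def chimeric_precision(
    n_reads: int = 300,
    seed: int = 1,
    config=None,
    params: DetectionParams | None = None,
    read_length: int = 30_000,
) -> np.ndarray:
    """Track-start errors on in-silico chimeric reads.

    Generates reads whose BrdU probability steps from the chase floor to a
    pulse-level peak at a known interior coordinate, runs the TM path
    (calling, 30-site smoothing, segmentation, detection) and returns
    |detected track start - true transition| per read (NaN when nothing was
    detected).  The median of the result is the method's track-start
    precision.
    """
    from .simulate import (SimulationConfig, make_transition_matrices,
                           random_genome, simulate_chimeric_read)

    config = config or SimulationConfig(seed=seed)
    params = params or DetectionParams.for_tm()
    matrices = make_transition_matrices(config)
    rng = np.random.default_rng(seed)
    errors = np.full(n_reads, np.nan)
    for k in range(n_reads):
        ref = random_genome({"c": read_length},
                            seed=int(rng.integers(2 ** 31 - 1)))["c"]
        peak = float(rng.uniform(*config.pulse_peak_range))
        read, truth = simulate_chimeric_read(ref, read_length // 2, matrices,
                                             config=config, rng=rng, peak=peak)
        profile = profile_to_fraction(call_tm(read, *matrices))
        from .tracks import track_start_error

        errors[k] = track_start_error(profile, truth, params)
    return errors


def orientation_accuracy(tracks, truth_by_read: dict) -> float:
    """Fraction of oriented tracks matching the simulator's fork direction.

    Each detected oriented track is matched to the ground-truth track with
    the largest overlap on its read; tracks with no overlapping truth are
    ignored.
    """
    n = hits = 0
    for t in tracks:
        if t.orientation not in ("right", "left"):
            continue
        best, best_ov = None, 0.0
        for tt in truth_by_read.get(t.read_id, []):
            ov = min(t.end, tt["end"]) - max(t.start, tt["start"])
            if ov > best_ov:
                best, best_ov = tt, ov
        if best is None:
            continue
        n += 1
        hits += int(best["orientation"] == t.orientation)
    return hits / n if n else float("nan")
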