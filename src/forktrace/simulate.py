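"""Pulse-chase replication signal simulator.

The simulator generates everything the pipeline consumes, starting at the
per-base mean-current/shift level where the signal analysis operates (no
raw picoampere event emulation): a pair of thymidine/BrdU transition
matrices, per-read BrdU incorporation probability fields shaped like a
pulse-chase experiment (steep rise to a 60-80% peak, shallow decay to a
~10% chase floor), resquiggled reads with per-read linear drift and
Gaussian per-transition noise, in-silico chimeric reads with a known
low-to-high transition for precision scoring, and whole-genome read
populations driven by an explicit origin-firing model.

Ground truth (per-site BrdU incorporation, track extents and orientations,
initiation/termination midpoints) is recorded in each read's ``meta`` so
downstream checks never have to re-derive it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import (
    N_HEXAMERS,
    BASES,
    ResquiggledRead,
    TransitionMatrix,
    central_t_mask,
    encode_bases,
    hexamer_indices,
)

#: hexamers with a T in the middle of their first pentamer (position 2 of 6)
_CENTRAL_T_COUNT = N_HEXAMERS // 4


@dataclass
class SimulationConfig:
    """Knobs of the synthetic signal model.

    informative_fraction
        Fraction of the 4096 hexamers whose T/B expected shifts differ by
        more than the calling threshold; 0.125 reproduces the ~512
        informative pentamer-to-pentamer transitions of the real pore model.
    shift_gap
        Mean |delta_T - delta_B| at informative hexamers, in normalized
        current units (comfortably above the 0.4 calling threshold).
    noise_sd
        Per-transition Gaussian noise, normalized current units.
    read_length_range, pulse_peak_range, chase_floor, rise_length,
    decay_length
        Geometry of reads and of the pulse-chase incorporation profile, in
        nucleotides / fractions.  The rise must be shorter than the decay:
        the asymmetry is the orientation signal.
    decay_shape
        'exponential' (default) or 'logistic'; with 'logistic' and equal
        rise/decay lengths the track profile is exactly mirror-symmetric,
        which is useful for testing that orientation then refuses to call.
    """

    seed: int = 0
    informative_fraction: float = 0.125
    shift_gap: float = 0.8
    noise_sd: float = 0.25
    read_length_range: tuple[int, int] = (10_000, 140_000)
    pulse_peak_range: tuple[float, float] = (0.6, 0.8)
    chase_floor: float = 0.10
    rise_length: int = 300
    decay_length: int = 15_000
    rise_shape: str = "logistic"
    decay_shape: str = "exponential"
    gap_threshold: float = 0.4  # |delta_T - delta_B| above which a site is callable
    base_shift_sd: float = 0.7  # spread of the thymidine-context matrix entries

    def __post_init__(self) -> None:
        if not 0 <= self.informative_fraction <= _CENTRAL_T_COUNT / N_HEXAMERS:
            raise ValueError(
                "informative_fraction must lie in [0, 0.25]: only hexamers with "
                "a central T can be informative"
            )
        lo, hi = self.pulse_peak_range
        if not (self.chase_floor < lo <= hi <= 1.0):
            raise ValueError("pulse_peak_range must lie within (chase_floor, 1]")
        if self.rise_length > self.decay_length:
            raise ValueError("rise_length must not exceed decay_length "
                             "(profile asymmetry encodes fork direction)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class OriginModel:
    """Replication origins of a simulated genome.

    ``positions`` maps chromosome name to strictly increasing 0-based
    coordinates; ``efficiencies`` holds the matching per-cell-cycle firing
    probabilities.  Times are minutes; in each simulated cell an origin
    fires with its efficiency at a time uniform in [0, pulse_start), which
    stands in for the spread of S-phase progression across an
    asynchronously growing culture at the moment of the pulse.  Forks move
    bidirectionally at ``fork_speed`` nt/min; a position's replication time
    is the earliest fork arrival (so late-firing origins inside an
    already-replicated region are passively replicated and contribute
    nothing), and replication stops at ``chase_end`` (harvest).
    """

    positions: dict  # chrom -> sequence of int
    efficiencies: dict  # chrom -> sequence of float in [0, 1]
    fork_speed: float = 1500.0  # nt per minute
    pulse_start: float = 30.0
    pulse_end: float = 34.0
    chase_end: float = 75.0

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: origin positions must be strictly increasing")
            eff = np.asarray(self.efficiencies[chrom], dtype=float)
            if eff.shape != pos.shape or np.any((eff < 0) | (eff > 1)):
                raise ValueError(f"{chrom}: efficiencies must match positions, in [0,1]")


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------


def make_transition_matrices(
    config: SimulationConfig,
) -> tuple[TransitionMatrix, TransitionMatrix]:
    """Draw a thymidine-context matrix and its BrdU-context counterpart.

    Both matrices cover all 4096 hexamers.  A random subset of the
    central-T hexamers, of size ``informative_fraction * 4096``, receives a
    positive BrdU displacement strictly above the calling threshold; every
    other hexamer has identical entries in the two contexts (in particular
    all hexamers without a central T, as in the real pore, where BrdU only
    perturbs the current when it occupies the centre of the pentamer).
    """
    rng = config.rng()
    values_t = rng.normal(0.0, config.base_shift_sd, N_HEXAMERS)
    values_b = values_t.copy()

    central_t = np.flatnonzero(_central_t_hexamers())
    n_informative = int(round(config.informative_fraction * N_HEXAMERS))
    if n_informative > 0:
        informative = rng.choice(central_t, size=n_informative, replace=False)
        # displacement ~ shift_gap on average, never below threshold + margin
        disp = config.shift_gap * (0.75 + 0.5 * rng.random(n_informative))
        disp = np.maximum(disp, config.gap_threshold + 0.05)
        values_b[informative] += disp

    return (
        TransitionMatrix(values_t, "T"),
        TransitionMatrix(values_b, "B"),
    )


def _central_t_hexamers() -> np.ndarray:
    idx = np.arange(N_HEXAMERS)
    return (idx // 4 ** 3) % 4 == 3  # base at offset 2 is T (code 3)


# ---------------------------------------------------------------------------
# pulse-chase incorporation profile
# ---------------------------------------------------------------------------


def _rise_curve(u: np.ndarray, shape: str) -> np.ndarray:
    """Monotone 0 -> 1 over u in [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    if shape == "logistic":
        k = 10.0
        lo, hi = 1 / (1 + math.exp(k / 2)), 1 / (1 + math.exp(-k / 2))
        return (1 / (1 + np.exp(-k * (u - 0.5))) - lo) / (hi - lo)
    if shape == "linear":
        return u
    raise ValueError(f"unknown rise shape {shape!r}")


def _decay_curve(u: np.ndarray, shape: str) -> np.ndarray:
    """Monotone 1 -> 0 over u in [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    if shape == "exponential":
        k = 4.0
        return (np.exp(-k * u) - math.exp(-k)) / (1 - math.exp(-k))
    if shape == "logistic":
        return 1.0 - _rise_curve(u, "logistic")
    if shape == "linear":
        return 1.0 - u
    raise ValueError(f"unknown decay shape {shape!r}")


def pulse_chase_profile(
    track_start: int,
    orientation: str,
    config: SimulationConfig,
    peak: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-base BrdU probability over one fork's track.

    For a rightward fork the probability rises from ~0 to ``peak`` over
    ``rise_length`` starting exactly at ``track_start`` (the fork position
    at pulse onset), then decays to ``chase_floor`` over ``decay_length``.
    A leftward fork is the mirror image about the track midpoint, with
    ``track_start`` at its right end.  Returns (positions, probabilities).
    """
    if orientation not in ("left", "right"):
        raise ValueError("orientation must be 'left' or 'right'")
    if peak is None:
        peak = float(np.mean(config.pulse_peak_range))
    extent = config.rise_length + config.decay_length
    d = np.arange(extent, dtype=float)
    prob = np.empty(extent)
    rising = d < config.rise_length
    prob[rising] = peak * _rise_curve(d[rising] / config.rise_length, config.rise_shape)
    u = (d[~rising] - config.rise_length) / config.decay_length
    prob[~rising] = config.chase_floor + (peak - config.chase_floor) * _decay_curve(
        u, config.decay_shape
    )
    if orientation == "right":
        positions = track_start + np.arange(extent)
    else:
        prob = prob[::-1].copy()
        positions = track_start - extent + 1 + np.arange(extent)
    return positions, prob


# ---------------------------------------------------------------------------
# read-level simulation
# ---------------------------------------------------------------------------


def simulate_read(
    reference_window: str,
    brdu_probability: np.ndarray | float,
    matrices: tuple[TransitionMatrix, TransitionMatrix],
    drift: tuple[float, float] = (1.0, 0.0),
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    read_id: str = "sim",
    chrom: str = "chrSim",
    ref_start: int = 0,
) -> ResquiggledRead:
    """Emit a resquiggled read from the forward signal model.

    Per transition with a full hexamer context the expected shift comes
    from the BrdU matrix when the central T site incorporated BrdU
    (Bernoulli draw at the local probability) and from the thymidine
    matrix otherwise; Gaussian noise is added, then the inverse of the
    drift correction is applied so that the drift fit recovers
    ``drift = (alpha, beta)`` exactly on noiseless input.  Trailing
    transitions without a full context carry pure noise.  Ground-truth
    incorporation per T site is recorded in ``meta``.
    """
    if config is None:
        config = SimulationConfig()
    if rng is None:
        rng = config.rng()
    n = len(reference_window)
    if n < 6:
        raise ValueError("reference window must be at least 6 bases long")
    tm_t, tm_b = matrices
    codes = encode_bases(reference_window)
    hexamers = hexamer_indices(codes)
    t_sites = central_t_mask(codes)

    prob = np.broadcast_to(np.asarray(brdu_probability, dtype=float), (n,))
    # one Bernoulli draw per T site; site for transition i is base i+2
    site_prob = prob[2:n - 3]
    incorporated = np.zeros(hexamers.size, dtype=bool)
    incorporated[t_sites] = rng.random(int(t_sites.sum())) < site_prob[t_sites]

    expected = tm_t.values[hexamers].copy()
    expected[incorporated] = tm_b.values[hexamers[incorporated]]

    shifts = np.empty(n - 1)
    shifts[: n - 5] = expected
    shifts[n - 5:] = 0.0
    if config.noise_sd > 0:
        shifts += rng.normal(0.0, config.noise_sd, n - 1)

    alpha, beta = drift
    if alpha == 0:
        raise ValueError("drift scale alpha must be non-zero")
    observed = (shifts - beta) / alpha  # normalization will undo this

    currents = np.concatenate([[0.0], -np.cumsum(observed)]).astype(np.float32)
    meta = {
        "seed": int(config.seed),
        "drift": [float(alpha), float(beta)],
        "t_site_positions": (ref_start + 2 + np.flatnonzero(t_sites)).astype(np.int64),
        "t_site_brdu": incorporated[t_sites].astype(np.int8),
    }
    return ResquiggledRead(read_id, chrom, ref_start, "+", reference_window,
                           currents, meta=meta)


def simulate_chimeric_read(
    reference: str,
    transition_point: int,
    matrices: tuple[TransitionMatrix, TransitionMatrix],
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    read_id: str = "chimera",
    peak: float | None = None,
) -> tuple[ResquiggledRead, int]:
    """A read whose BrdU probability steps from chase floor to pulse peak.

    The probability is exactly ``chase_floor`` left of ``transition_point``
    and rises to ``peak`` over ``rise_length`` from the point on (the step
    is blurred on its high side only, so the returned true coordinate is
    the foot of the rise, which is what track-start detection estimates).
    """
    if config is None:
        config = SimulationConfig()
    if rng is None:
        rng = config.rng()
    n = len(reference)
    if not 0 < transition_point < n:
        raise ValueError("transition point must be interior to the read")
    if peak is None:
        peak = float(np.mean(config.pulse_peak_range))
    x = np.arange(n, dtype=float)
    prob = np.full(n, config.chase_floor)
    after = x >= transition_point
    u = (x[after] - transition_point) / config.rise_length
    prob[after] = config.chase_floor + (peak - config.chase_floor) * _rise_curve(
        u, config.rise_shape
    )
    read = simulate_read(reference, prob, matrices, config=config, rng=rng,
                         read_id=read_id)
    read.meta["transition_point"] = int(transition_point)
    return read, transition_point


# ---------------------------------------------------------------------------
# genome-scale simulation
# ---------------------------------------------------------------------------


def random_genome(lengths: dict, seed: int = 0) -> dict[str, str]:
    """Uniform-random A/C/G/T reference sequences, one per chromosome."""
    rng = np.random.default_rng(seed)
    return {
        chrom: "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
        for chrom, length in lengths.items()
    }


def _pulse_time_profile(t: np.ndarray, origin_model: OriginModel,
                        config: SimulationConfig, peak: float) -> np.ndarray:
    """BrdU incorporation probability as a function of replication time.

    Zero before the pulse starts; rises to ``peak`` over the time a fork
    needs to cover ``rise_length``; decays to the chase floor over the time
    to cover ``decay_length``.  This makes the temporal model consistent
    with the spatial profile of :func:`pulse_chase_profile`.
    """
    v = origin_model.fork_speed
    rise_tau = config.rise_length / v
    decay_tau = config.decay_length / v
    out = np.zeros_like(t, dtype=float)
    dt = t - origin_model.pulse_start
    rising = (dt >= 0) & (dt < rise_tau)
    out[rising] = peak * _rise_curve(dt[rising] / rise_tau, config.rise_shape)
    decaying = dt >= rise_tau
    u = (dt[decaying] - rise_tau) / decay_tau
    out[decaying] = config.chase_floor + (peak - config.chase_floor) * _decay_curve(
        u, config.decay_shape
    )
    return out


def simulate_genome_run(
    reference: dict[str, str],
    origin_model: OriginModel,
    n_reads: int,
    config: SimulationConfig,
    drift_range: tuple[float, float] = (0.8, 1.2),
    offset_range: tuple[float, float] = (-0.2, 0.2),
) -> tuple[list[ResquiggledRead], list[dict]]:
    """Sample reads from independently replicating cells.

    Each read comes from its own simulated cell: every origin on the read's
    chromosome fires independently with its efficiency at a time uniform in
    [0, pulse_start); forks progress bidirectionally at ``fork_speed`` and
    stop where converging forks meet or at ``chase_end``.  The replication
    time field determines the local BrdU probability through the pulse-chase
    time course.  Reads are placed uniformly with lengths drawn from
    ``read_length_range``.  Returns the reads plus one ground-truth record
    per read (track extents/orientations and any initiation or termination
    midpoint the read spans).
    """
    matrices = make_transition_matrices(config)
    rng = config.rng()
    chroms = list(reference)
    lengths = np.array([len(reference[c]) for c in chroms], dtype=float)
    if any(len(origin_model.positions.get(c, ())) == 0 for c in chroms):
        raise ValueError("every chromosome needs at least one origin")

    reads: list[ResquiggledRead] = []
    truth: list[dict] = []
    v = origin_model.fork_speed
    for k in range(n_reads):
        ci = rng.choice(len(chroms), p=lengths / lengths.sum())
        chrom = chroms[ci]
        chrom_len = int(lengths[ci])
        read_len = int(rng.integers(config.read_length_range[0],
                                    config.read_length_range[1] + 1))
        read_len = min(read_len, chrom_len)
        start = int(rng.integers(0, chrom_len - read_len + 1))

        pos = np.asarray(origin_model.positions[chrom], dtype=float)
        eff = np.asarray(origin_model.efficiencies[chrom], dtype=float)
        fired = rng.random(pos.size) < eff
        peak = float(rng.uniform(*config.pulse_peak_range))
        origins = pos[fired]
        fire_times = rng.uniform(0.0, origin_model.pulse_start, int(fired.sum()))

        x = np.arange(start, start + read_len, dtype=float)
        if origins.size:
            # replication time field: earliest fork to reach each position;
            # origins overrun by an earlier fork are passively replicated
            tt = fire_times[:, None] + np.abs(x[None, :] - origins[:, None]) / v
            owner = np.argmin(tt, axis=0)
            t_rep = tt[owner, np.arange(x.size)]
            replicated = t_rep <= origin_model.chase_end
            prob = np.zeros(read_len)
            prob[replicated] = _pulse_time_profile(t_rep[replicated], origin_model,
                                                   config, peak)
            direction = np.where(x >= origins[owner], 1, -1)
            direction[~replicated] = 0
        else:
            t_rep = np.full(read_len, np.inf)
            owner = np.zeros(read_len, dtype=int)
            prob = np.zeros(read_len)
            direction = np.zeros(read_len, dtype=int)

        alpha = float(rng.uniform(*drift_range))
        beta = float(rng.uniform(*offset_range))
        read = simulate_read(reference[chrom][start:start + read_len], prob,
                             matrices, drift=(alpha, beta), config=config,
                             rng=rng, read_id=f"read_{k:05d}", chrom=chrom,
                             ref_start=start)
        record = _ground_truth_record(x, t_rep, owner, direction, origins,
                                      origin_model, config)
        read.meta.update(record)
        reads.append(read)
        truth.append({"read_id": read.read_id, "chrom": chrom,
                      "start": start, "end": start + read_len, **record})
    return reads, truth


def _ground_truth_record(x, t_rep, owner, direction, origins, origin_model,
                         config) -> dict:
    """Tracks and event midpoints for one read, from its replication field.

    A track is a maximal run of positions replicated by the same fork
    (constant owner and direction) within the visible pulse-chase time
    window; its fork start is the position replicated at pulse onset (the
    steep side).  Initiation midpoints are direction flips from left to
    right at a fired origin; termination midpoints are flips from right to
    left (fork meeting points).  Events are recorded when both flanking
    fork starts lie inside the read.
    """
    v = origin_model.fork_speed
    t0 = origin_model.pulse_start
    track_tau = (config.rise_length + config.decay_length) / v
    visible = (t_rep >= t0) & (t_rep <= min(t0 + track_tau, origin_model.chase_end))

    tracks = []
    n = x.size
    i = 0
    while i < n:
        if not visible[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and visible[j + 1] and owner[j + 1] == owner[i]
               and direction[j + 1] == direction[i]):
            j += 1
        seg_t = t_rep[i:j + 1]
        fs = int(x[i + int(np.argmin(seg_t))])  # closest to pulse onset
        tracks.append({
            "start": float(x[i]),
            "end": float(x[j]) + 1,
            "orientation": "right" if direction[i] > 0 else "left",
            "fork_start": fs,
            "owner": int(owner[i]),
        })
        i = j + 1

    initiations = []
    terminations = []
    flips = np.flatnonzero((direction[:-1] != 0) & (direction[1:] != 0)
                           & (direction[:-1] != direction[1:]))
    def _fork_track(owner_idx, orientation):
        for t in tracks:
            if t["owner"] == owner_idx and t["orientation"] == orientation:
                return t
        return None

    for f in flips:
        if direction[f] < 0 < direction[f + 1]:  # diverging forks: initiation
            o = origins[owner[f]] if origins.size else x[f]
            left_tr = _fork_track(owner[f], "left")
            right_tr = _fork_track(owner[f + 1], "right")
            if left_tr and right_tr:
                initiations.append({
                    "midpoint": float(o),
                    "fork_start_left": left_tr["fork_start"],
                    "fork_start_right": right_tr["fork_start"],
                })
        else:  # converging forks: termination
            left_tr = _fork_track(owner[f], "right")
            right_tr = _fork_track(owner[f + 1], "left")
            if left_tr and right_tr:
                terminations.append({
                    "midpoint": float((x[f] + x[f + 1]) / 2),
                    "fork_start_left": left_tr["fork_start"],
                    "fork_start_right": right_tr["fork_start"],
                })
    return {
        "true_tracks": tracks,
        "true_initiations": initiations,
        "true_terminations": terminations,
    }


def truth_events_to_bed_rows(truth: Sequence[dict]) -> list[tuple]:
    """Flatten ground-truth event midpoints to BED-able tuples."""
    rows = []
    for rec in truth:
        for ev in rec.get("true_initiations", []):
            m = int(ev["midpoint"])
            rows.append((rec["chrom"], m - 1, m + 1, "init", 1, "."))
        for ev in rec.get("true_terminations", []):
            m = int(ev["midpoint"])
            rows.append((rec["chrom"], m - 1, m + 1, "term", 1, "."))
    return rows
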