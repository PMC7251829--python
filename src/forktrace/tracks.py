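"""BrdU track detection, orientation, scoring and event calling.

The smoothed per-read content signal is rescaled to [0, 1], simplified to a
piecewise-linear polyline with the Ramer-Douglas-Peucker algorithm, and
scanned for tracks: a maximal upward run of segments with total rise above
``up_amplitude`` followed, possibly after a plateau, by a downward run with
total fall above ``down_amplitude``.  A track is oriented by slope
asymmetry (the pulse side of a fork is much steeper than the chase side)
or, failing that, by the flanking minima (the chase side retains more BrdU
than the pre-pulse side).  Two per-track confidence scores gate event
calling:

* ``Ascore``: signed ratio of the steep to the shallow slope magnitude
  (positive = rightward), so the |Ascore| > 2 event filter is a stricter
  version of the 1.5 orientation ratio;
* ``Jscore``: the starting-jump amplitude in content units
  divided by the read's off-track residual standard deviation, i.e. a
  signal-to-noise ratio — a Jscore above 1 means the jump exceeds the
  read's noise floor.

Both formulas are reconstructions: the scores are named, used and
thresholded by the published procedure but never written out, so the
definitions here are the package's own and are kept in one place.

Initiation events are consecutive diverging (leftward then rightward)
high-confidence tracks with fork starts at least 1 kb apart and a low mean
signal between them; terminations are converging pairs with low signal at
both fork starts; event midpoints are the means of the two fork starts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import BrdUProfile, ReplicationEvent, ReplicationTrack

logger = logging.getLogger("forktrace")


@dataclass
class DetectionParams:
    """Thresholds of the track/event caller.

    The read filters and amplitudes are method-specific (the CNN signal is
    less dispersed than the TM fraction); use :meth:`for_cnn` /
    :meth:`for_tm` for the published defaults.
    """

    min_read_length: int = 5_000
    min_profile_sd: float = 0.3
    min_amplitude: float = 0.5
    up_amplitude: float = 0.44  # content units (fraction BrdU)
    down_amplitude: float = 0.26
    slope_ratio: float = 1.5
    level_gap: float = 0.075
    ascore_min: float = 2.0
    jscore_min: float = 1.0
    fork_gap_min: int = 1_000
    plateau_max: float = 0.12
    share_distance: int = 2_000
    rdp_epsilon: float = 0.05  # rescaled units
    min_run_amplitude: float = 0.26  # turning-point hysteresis, content units
    #: orientation guard: the fork-start flank of a genuine pulse-chase track
    #: is DNA replicated before the pulse, so its content must stay near the
    #: parental level; tracks whose putative pre-pulse flank exceeds this are
    #: left unoriented (same physics as the fork-start ceiling for events)
    orient_floor_max: float = 0.15

    @classmethod
    def for_tm(cls) -> "DetectionParams":
        return cls(min_profile_sd=0.3, min_amplitude=0.5, plateau_max=0.12,
                   orient_floor_max=0.15)

    @classmethod
    def for_cnn(cls) -> "DetectionParams":
        return cls(min_profile_sd=0.115, min_amplitude=0.4, plateau_max=0.14,
                   orient_floor_max=0.175)


# ---------------------------------------------------------------------------
# read filtering
# ---------------------------------------------------------------------------


def filter_reads(profiles: list[BrdUProfile], params: DetectionParams,
                 qc: list | None = None) -> list[BrdUProfile]:
    """Keep profiles long enough and dispersed enough to contain a track.

    A profile passes when its reference span is at least ``min_read_length``,
    its whole-read BrdU-proportion sd is >= ``min_profile_sd`` and its
    smoothed amplitude (max - min) is >= ``min_amplitude``.  For the TM path
    the sd is that of the unsmoothed per-call B indicator (carried on the
    profile as ``raw_sd``): only a binary call series can reach the 0.3
    threshold, the smoothed fraction's sd cannot.  When ``qc`` is given,
    one record per profile (kept or not) is appended to it.
    """
    kept = []
    for p in profiles:
        if p.content is None or p.content.size == 0:
            reason = "empty profile"
            length = sd = amp = 0.0
        else:
            length = int(p.positions[-1] - p.positions[0])
            sd = float(p.raw_sd) if p.raw_sd is not None else float(np.std(p.content))
            amp = float(p.content.max() - p.content.min())
            if length < params.min_read_length:
                reason = "short read"
            elif sd < params.min_profile_sd:
                reason = "low signal sd"
            elif amp < params.min_amplitude:
                reason = "low signal amplitude"
            else:
                reason = ""
                kept.append(p)
        if qc is not None:
            qc.append({"read_id": p.read_id, "length": length, "sd": sd,
                       "amplitude": amp, "rejected": reason})
    return kept


# ---------------------------------------------------------------------------
# piecewise-linear segmentation (Ramer-Douglas-Peucker)
# ---------------------------------------------------------------------------


def segment_profile(values: np.ndarray, rdp_epsilon: float) -> np.ndarray:
    """Breakpoint indices of the RDP simplification of (index, value) points.

    Endpoints are always retained; every dropped point lies within
    ``rdp_epsilon`` perpendicular distance of the chord that removed it.
    Implemented iteratively with an explicit stack.
    """
    n = values.size
    if n < 3:
        return np.arange(n)
    x = np.arange(n, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        dx, dy = x[j] - x[i], y[j] - y[i]
        norm = np.hypot(dx, dy)
        # perpendicular distance of interior points to the chord i->j
        d = np.abs(dy * (x[i + 1:j] - x[i]) - dx * (y[i + 1:j] - y[i])) / norm
        kmax = int(np.argmax(d))
        if d[kmax] > rdp_epsilon:
            mid = i + 1 + kmax
            keep[mid] = True
            stack.append((i, mid))
            stack.append((mid, j))
    return np.flatnonzero(keep)


def rescale(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Per-read min->0, max->1 rescaling; returns (rescaled, lo, hi)."""
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.zeros_like(values), lo, hi
    return (values - lo) / (hi - lo), lo, hi


# ---------------------------------------------------------------------------
# track detection
# ---------------------------------------------------------------------------


def _runs_from_breakpoints(breakpoints: np.ndarray, y: np.ndarray,
                           min_run_amplitude: float) -> list[dict]:
    """Alternating monotone runs between significant turning points.

    The polyline vertices are reduced to turning points with a hysteresis
    of ``min_run_amplitude``: a running extreme only becomes a turning
    point once the signal has reversed by more than that amount, so noise
    wiggles of any number — as long as each stays below the hysteresis —
    cannot fragment a long rise or decay.  Returns runs (i, j, dy, class)
    with class 'rise' or 'fall' and |dy| >= the hysteresis except possibly
    for the terminal runs.
    """
    v = breakpoints
    if v.size < 2:
        return []
    turning = [0]  # indices into v
    direction = 0  # +1 while tracking a max, -1 while tracking a min
    ext = 0  # index into v of the running extreme
    for k in range(1, v.size):
        yk = y[v[k]]
        if direction >= 0 and yk > y[v[ext]]:
            ext = k
        elif direction <= 0 and yk < y[v[ext]]:
            ext = k
        if direction == 0:
            if abs(yk - y[v[0]]) > min_run_amplitude:
                direction = 1 if yk > y[v[0]] else -1
                ext = k
        elif direction > 0 and y[v[ext]] - yk > min_run_amplitude:
            turning.append(ext)
            direction, ext = -1, k
        elif direction < 0 and yk - y[v[ext]] > min_run_amplitude:
            turning.append(ext)
            direction, ext = 1, k
    if turning[-1] != v.size - 1:
        if ext != turning[-1]:
            turning.append(ext)
        if turning[-1] != v.size - 1:
            turning.append(v.size - 1)
    runs = []
    for a, b in zip(turning[:-1], turning[1:]):
        dy = float(y[v[b]] - y[v[a]])
        runs.append({"i": int(v[a]), "j": int(v[b]), "dy": dy,
                     "class": "rise" if dy > 0 else "fall"})
    return runs


def detect_tracks(
    profile: BrdUProfile,
    params: DetectionParams,
    breakpoints: np.ndarray | None = None,
    allow_open_end: bool = False,
) -> list[ReplicationTrack]:
    """Unoriented tracks on one smoothed profile.

    The signal is rescaled per read only for segmentation (so that
    ``rdp_epsilon`` is comparable across reads); amplitudes, flanking
    minima and slopes are all measured on the BrdU-content scale itself,
    where the published thresholds (0.44 up, 0.26 down, like the plateau
    ceiling and the 0.075 level gap) live.  A track is an upward run with
    total rise > ``up_amplitude`` followed — possibly after a plateau —
    by a downward run with total fall > ``down_amplitude``.  With
    ``allow_open_end`` an upward run that reaches the end of the read
    without a closing fall still yields an (open-ended, unorientable)
    track, which is what the chimeric-read precision measurement uses.
    """
    if profile.content is None or profile.content.size < 3:
        return []
    rescaled, lo, hi = rescale(profile.content)
    if hi == lo:
        return []
    if breakpoints is None:
        breakpoints = segment_profile(rescaled, params.rdp_epsilon)
    y = profile.content
    pos = profile.positions
    runs = _runs_from_breakpoints(breakpoints, y, params.min_run_amplitude)

    # residual noise around the piecewise-linear fit, content units
    fit = np.interp(np.arange(y.size), breakpoints, y[breakpoints])
    residuals = y - fit

    tracks = []
    k = 0
    while k < len(runs):
        run = runs[k]
        if run["class"] == "rise" and run["dy"] > params.up_amplitude:
            # walk across the plateau: wiggles smaller than the closing
            # amplitude are tolerated as long as they do not add up to a
            # second upward shift
            nxt = k + 1
            plateau_net = 0.0
            closed = None
            while nxt < len(runs):
                r = runs[nxt]
                if r["class"] == "fall" and -r["dy"] > params.down_amplitude:
                    closed = r
                    break
                if abs(r["dy"]) >= params.up_amplitude or \
                        plateau_net + r["dy"] > params.up_amplitude:
                    break  # a new structure starts; abandon this candidate
                plateau_net += r["dy"]
                nxt += 1
            if closed is not None:
                tracks.append(_make_track(profile, params, pos, y, run, closed))
                k = nxt + 1
                continue
            if nxt >= len(runs) and allow_open_end:
                tracks.append(_make_track(profile, params, pos, y, run, None))
        k += 1

    if tracks:
        off = np.ones(y.size, dtype=bool)
        for t in tracks:
            off[np.searchsorted(pos, t.start):np.searchsorted(pos, t.end,
                                                              "right")] = False
        resid_sd = float(np.std(residuals[off])) if off.sum() >= 10 \
            else float(np.std(residuals))
        for t in tracks:
            t.resid_sd = resid_sd
    return tracks


def _trim_foot(y: np.ndarray, i: int, j: int, frac: float = 0.1) -> tuple[int, int]:
    """Trim a monotone run to its substantive part.

    Noise wiggles merged into a run drag its endpoints into the flanking
    plateaus; the returned (start, end) are the last point still within
    ``frac`` of the run amplitude of the low end and the first point within
    ``frac`` of the high end, so the run spans the actual shift.
    """
    lo, hi = (y[i], y[j]) if y[j] >= y[i] else (y[j], y[i])
    amp = hi - lo
    if amp <= 0 or j - i < 2:
        return i, j
    seg = y[i:j + 1]
    near_lo = seg <= lo + frac * amp
    near_hi = seg >= hi - frac * amp
    if y[j] >= y[i]:  # rising: last point near the bottom, first near the top
        i2 = i + int(np.flatnonzero(near_lo)[-1]) if near_lo.any() else i
        j2 = i + int(np.flatnonzero(near_hi)[0]) if near_hi.any() else j
    else:  # falling
        i2 = i + int(np.flatnonzero(near_hi)[-1]) if near_hi.any() else i
        j2 = i + int(np.flatnonzero(near_lo)[0]) if near_lo.any() else j
    if j2 <= i2:
        return i, j
    return i2, j2


def _make_track(profile, params, pos, y, rise, fall) -> ReplicationTrack:
    kb = 1000.0
    i0, i1 = _trim_foot(y, rise["i"], rise["j"])
    if fall is not None:
        f0, j1 = _trim_foot(y, fall["i"], fall["j"])
        span_down = (pos[j1] - pos[f0]) / kb
        slope_down = float(y[j1] - y[f0]) / span_down if span_down > 0 else -np.inf
        min_f = float(y[j1])
        fall_amp = float(y[f0] - y[j1])
        open_ended = False
    else:
        j1 = y.size - 1
        slope_down = np.nan
        min_f = np.nan
        fall_amp = np.nan
        open_ended = True
    span_up = (pos[i1] - pos[i0]) / kb
    rise_dy = float(y[i1] - y[i0])
    slope_up = rise_dy / span_up if span_up > 0 else np.inf
    return ReplicationTrack(
        chrom=profile.chrom,
        start=int(pos[i0]),
        end=int(pos[j1]) + 1,
        orientation=None,
        slope_up=float(slope_up),
        slope_down=float(slope_down),
        min_p=float(y[i0]),
        min_f=min_f,
        rise_amp=float(rise_dy),
        fall_amp=float(fall_amp),
        read_id=profile.read_id,
        method=profile.method,
        open_ended=open_ended,
    )


# ---------------------------------------------------------------------------
# orientation and scoring
# ---------------------------------------------------------------------------


def orient_track(track: ReplicationTrack, params: DetectionParams) -> ReplicationTrack:
    """Assign fork direction, or leave the track unoriented.

    The steep side of a pulse-chase track is the fork start, so a rise much
    steeper than the fall (ratio > ``slope_ratio``) means a rightward fork
    and the mirrored ratio a leftward one.  With symmetric slopes the
    flanking minima decide: BrdU decays during the chase but stays above
    the pre-pulse level, so the higher flank is the trailing (chase) side.

    Two coherence guards keep noise structures unoriented: when the slope
    rule and the level rule are both decisive but contradict each other the
    track is left unoriented (a genuine fork satisfies both — its steep
    side adjoins the lower, pre-pulse flank), and a level-rule orientation
    is only accepted when the putative pre-pulse flank is itself near the
    parental level (twice the plateau ceiling at most).
    """
    if track.open_ended:
        return track
    up = abs(track.slope_up) if np.isfinite(track.slope_up) else np.inf
    down = abs(track.slope_down) if np.isfinite(track.slope_down) else np.inf
    ratio_right = up / down if down > 0 else np.inf
    ratio_left = down / up if up > 0 else np.inf
    by_level = None
    if track.min_f - track.min_p > params.level_gap:
        by_level = "right"
    elif track.min_p - track.min_f > params.level_gap:
        by_level = "left"
    if ratio_right > params.slope_ratio and not ratio_left > params.slope_ratio:
        by_slope = "right"
    elif ratio_left > params.slope_ratio and not ratio_right > params.slope_ratio:
        by_slope = "left"
    else:
        by_slope = None
    candidate = None
    if by_slope is not None:
        if by_level is not None and by_level != by_slope:
            return track  # contradictory evidence: abstain
        candidate = by_slope
    elif by_level is not None:
        candidate = by_level
    if candidate is not None:
        pre_pulse = track.min_p if candidate == "right" else track.min_f
        if pre_pulse <= params.orient_floor_max:
            track.orientation = candidate
    return track


def score_track(track: ReplicationTrack) -> tuple[float, float]:
    """(Ascore, Jscore) of an oriented track; also stored on the track.

    Ascore is the signed steep/shallow slope-magnitude ratio (sign encodes
    orientation, + = rightward); Jscore is the starting-jump amplitude (the
    steep-side shift, pre-rescale units) divided by the read's off-track
    residual sd.  Mirroring a track negates Ascore and leaves Jscore
    unchanged.
    """
    if track.orientation is None:
        raise ValueError("score_track requires an oriented track")
    up = abs(track.slope_up)
    down = abs(track.slope_down)
    if track.orientation == "right":
        ascore = up / down if down > 0 else np.inf
        jump = track.rise_amp
    else:
        ascore = -(down / up) if up > 0 else -np.inf
        jump = track.fall_amp
    noise = max(track.resid_sd, 1e-9)
    track.ascore = float(ascore)
    track.jscore = float(jump / noise)
    return track.ascore, track.jscore


# ---------------------------------------------------------------------------
# event calling
# ---------------------------------------------------------------------------


def _passes(track: ReplicationTrack, params: DetectionParams) -> bool:
    return (track.orientation is not None
            and np.isfinite(track.jscore)
            and abs(track.ascore) > params.ascore_min
            and track.jscore > params.jscore_min)


def _profile_value_at(profile: BrdUProfile, coord: int) -> float:
    idx = np.clip(np.searchsorted(profile.positions, coord),
                  0, profile.positions.size - 1)
    return float(profile.content[idx])


def call_events(
    tracks: list[ReplicationTrack],
    params: DetectionParams,
    profile: BrdUProfile,
) -> list[ReplicationEvent]:
    """Initiation/termination events from one read's ordered tracks.

    Only pairs adjacent along the read qualify; an intervening unoriented
    or low-score track voids the pair (conservative reading of
    "consecutive").  Initiations need diverging high-confidence tracks,
    fork starts >= 1 kb apart and a mean signal between the fork starts at
    or below ``plateau_max``; terminations need converging tracks with the
    signal at both fork starts at or below the same ceiling.
    """
    tracks = sorted(tracks, key=lambda t: t.start)
    events = []
    for a, b in zip(tracks[:-1], tracks[1:]):
        if not (_passes(a, params) and _passes(b, params)):
            continue
        if a.orientation == "left" and b.orientation == "right":
            fs_l, fs_r = a.fork_start, b.fork_start
            if fs_r - fs_l < params.fork_gap_min:
                continue
            sel = (profile.positions >= fs_l) & (profile.positions <= fs_r)
            if sel.any() and float(profile.content[sel].mean()) > params.plateau_max:
                continue
            events.append(ReplicationEvent(
                "initiation", a.chrom, int(round((fs_l + fs_r) / 2)),
                fs_l, fs_r, read_id=a.read_id, method=a.method))
        elif a.orientation == "right" and b.orientation == "left":
            fs_l, fs_r = a.fork_start, b.fork_start
            if fs_r <= fs_l:
                continue
            if (_profile_value_at(profile, fs_l) > params.plateau_max
                    or _profile_value_at(profile, fs_r) > params.plateau_max):
                continue
            events.append(ReplicationEvent(
                "termination", a.chrom, int(round((fs_l + fs_r) / 2)),
                fs_l, fs_r, read_id=a.read_id, method=a.method))
    return events


def merge_method_events(
    cnn_events: list[ReplicationEvent],
    tm_events: list[ReplicationEvent],
    share_distance: int = 2_000,
) -> tuple[list[ReplicationEvent], int]:
    """Pool the two methods' event lists, counting shared events once.

    Events of the same type on the same read whose midpoints are within
    ``share_distance`` are matched greedily (smallest distance first, ties
    to the leftmost pair); each matched pair contributes one pooled event
    flagged ``shared``.  Unmatched events from both lists are retained.
    """
    pooled: list[ReplicationEvent] = []
    n_shared = 0
    keys = {(e.read_id, e.type) for e in cnn_events + tm_events}
    for key in sorted(keys):
        a_list = [e for e in cnn_events if (e.read_id, e.type) == key]
        b_list = [e for e in tm_events if (e.read_id, e.type) == key]
        pairs = sorted(
            ((abs(a.midpoint - b.midpoint), a.midpoint, i, j)
             for i, a in enumerate(a_list) for j, b in enumerate(b_list)
             if abs(a.midpoint - b.midpoint) <= share_distance),
        )
        used_a: set[int] = set()
        used_b: set[int] = set()
        for dist, _, i, j in pairs:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            ev = a_list[i]
            ev.shared = True
            pooled.append(ev)
            n_shared += 1
        pooled.extend(a for i, a in enumerate(a_list) if i not in used_a)
        pooled.extend(b for j, b in enumerate(b_list) if j not in used_b)
    return pooled, n_shared


# ---------------------------------------------------------------------------
# per-read pipeline helpers
# ---------------------------------------------------------------------------


def analyze_profile(
    profile: BrdUProfile,
    params: DetectionParams,
    allow_open_end: bool = False,
) -> tuple[list[ReplicationTrack], list[ReplicationEvent]]:
    """Segment, detect, orient and score one profile; call its events."""
    tracks = detect_tracks(profile, params, allow_open_end=allow_open_end)
    for t in tracks:
        orient_track(t, params)
        if t.orientation is not None:
            score_track(t)
    events = call_events([t for t in tracks if not t.open_ended], params, profile)
    return tracks, events


def track_start_error(profile: BrdUProfile, true_start: int,
                      params: DetectionParams) -> float:
    """|detected track start - true transition| for a chimeric read.

    Chimeric reads end at high content, so detection runs with
    ``allow_open_end``; the track with the largest upward shift provides
    the detected start.  Returns NaN when nothing is detected (the read
    filters are not applied here: this measures detection geometry, not
    read selection).
    """
    tracks = detect_tracks(profile, params, allow_open_end=True)
    if not tracks:
        return float("nan")
    best = max(tracks, key=lambda t: t.rise_amp)
    return float(abs(best.start - true_start))
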