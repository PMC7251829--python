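"""Clustering, annotation comparisons and randomization controls for
initiation/termination events.

Events are chained into clusters by single linkage on inter-event distance
(neighbours strictly closer than the clustering limit mIED share a
cluster); a cluster's dimension d is its event count and its width the
span of its outmost members.  Controls shuffle events uniformly per
chromosome, preserving per-chromosome counts.  Annotation comparisons use
midpoint-to-centre distances and 2-kb resized overlaps, and origin-motif
content is assessed with a position-weight-matrix scan at a fraction of
the maximal attainable score, against a shuffled-window null band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EventCluster, GenomeSignal, ReplicationEvent, encode_bases
from .profiles import GRID

#: cluster-dimension grouping used throughout the event analyses
DIMENSION_CLASSES = ((1, 1), (2, 4), (5, 12), (13, None))


def dimension_class(d: int) -> str:
    for lo, hi in DIMENSION_CLASSES:
        if d >= lo and (hi is None or d <= hi):
            return f"d={lo}-{hi}" if hi not in (None, lo) else (
                f"d>{lo - 1}" if hi is None else "d=1")
    raise ValueError(d)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def cluster_events(events: list[ReplicationEvent], mied: float = 1_500) -> list[EventCluster]:
    """Single-linkage chaining: neighbours with gap < mIED share a cluster.

    The gap comparison is strict (a gap exactly equal to mIED starts a new
    cluster).  Events are grouped per chromosome and sorted by midpoint.
    """
    clusters: list[EventCluster] = []
    for chrom in sorted({e.chrom for e in events}):
        evs = sorted((e for e in events if e.chrom == chrom),
                     key=lambda e: e.midpoint)
        current = [evs[0]]
        for prev, ev in zip(evs[:-1], evs[1:]):
            if ev.midpoint - prev.midpoint < mied:
                current.append(ev)
            else:
                clusters.append(EventCluster(chrom, current, mied))
                current = [ev]
        clusters.append(EventCluster(chrom, current, mied))
    return clusters


def cluster_sweep(events: list[ReplicationEvent], mied_grid) -> pd.DataFrame:
    """Cluster counts by dimension class and width quantiles per mIED."""
    rows = []
    for mied in mied_grid:
        clusters = cluster_events(events, mied)
        dims = np.array([c.dimension for c in clusters])
        widths = np.array([c.width for c in clusters if c.dimension > 1])
        rows.append({
            "mied": mied,
            "n_clusters": len(clusters),
            "n_singleton": int((dims == 1).sum()),
            "n_multi": int((dims > 1).sum()),
            "total_events": int(dims.sum()),
            "width_median": float(np.median(widths)) if widths.size else np.nan,
            "width_q25": float(np.quantile(widths, 0.25)) if widths.size else np.nan,
            "width_q75": float(np.quantile(widths, 0.75)) if widths.size else np.nan,
        })
    return pd.DataFrame(rows)


def shuffle_events(events: list[ReplicationEvent], chrom_lengths: dict,
                   seed: int = 0) -> list[ReplicationEvent]:
    """Uniform random repositioning preserving per-chromosome counts."""
    rng = np.random.default_rng(seed)
    out = []
    for chrom in sorted({e.chrom for e in events}):
        evs = [e for e in events if e.chrom == chrom]
        positions = np.sort(rng.integers(1, chrom_lengths[chrom] - 1, len(evs)))
        for e, p in zip(evs, positions):
            out.append(ReplicationEvent(e.type, chrom, int(p), int(p) - 1,
                                        int(p) + 1, read_id=e.read_id,
                                        method=e.method))
    return out


# ---------------------------------------------------------------------------
# distances, overlaps, aligned profiles
# ---------------------------------------------------------------------------


def distance_to_nearest(query_points: list[tuple[str, float]],
                        annotations: list[tuple[str, int, int]]) -> np.ndarray:
    """|query midpoint - nearest annotation centre| per query.

    Annotations are (chrom, start, end[, ...]) intervals; distance is
    midpoint-to-centre.  Queries on chromosomes without any annotation get
    +inf.  An empty annotation set is an error.
    """
    if not annotations:
        raise ValueError("empty annotation set")
    centers: dict[str, np.ndarray] = {}
    for ann in annotations:
        chrom, start, end = ann[0], ann[1], ann[2]
        centers.setdefault(chrom, [])
        centers[chrom].append((start + end) / 2)
    centers = {c: np.sort(v) for c, v in centers.items()}
    out = np.empty(len(query_points))
    for i, (chrom, point) in enumerate(query_points):
        if chrom not in centers:
            out[i] = np.inf
            continue
        cs = centers[chrom]
        j = np.searchsorted(cs, point)
        cands = cs[max(0, j - 1): j + 1]
        out[i] = np.abs(cands - point).min()
    return out


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF support points and heights (right-continuous)."""
    x = np.sort(np.asarray(values, dtype=float))
    y = np.arange(1, x.size + 1) / x.size
    return x, y


def overlap_fraction(set_a, set_b, resize: int = 2_000) -> tuple[float, float]:
    """Fractions of A overlapping B and of B overlapping A after resizing.

    Every interval is replaced by a ``resize``-wide window centred on its
    midpoint; overlap means a strictly positive intersection.
    """
    def _resized(items):
        out = {}
        for it in items:
            chrom, start, end = it[0], it[1], it[2]
            mid = (start + end) / 2
            out.setdefault(chrom, []).append((mid - resize / 2, mid + resize / 2))
        return {c: sorted(v) for c, v in out.items()}

    ra, rb = _resized(set_a), _resized(set_b)

    def _frac(query, subject):
        n = hits = 0
        for chrom, ivs in query.items():
            subj = subject.get(chrom, [])
            starts = np.array([s for s, _ in subj])
            ends = np.array([e for _, e in subj])
            for s, e in ivs:
                n += 1
                if subj and bool(np.any((starts < e) & (ends > s))):
                    hits += 1
        return hits / n if n else float("nan")

    return _frac(ra, rb), _frac(rb, ra)


def mean_profile_around(points: list[tuple[str, float]], signal: GenomeSignal,
                        flank: int = 10_000) -> tuple[np.ndarray, np.ndarray]:
    """Position-wise mean of ``signal`` in windows centred on ``points``.

    Returns (offsets in nt, mean values); missing bins are excluded
    position-wise.  An error if no point has any defined flanking value.
    """
    w = flank // signal.bin_size
    offsets = (np.arange(-w, w + 1)) * signal.bin_size
    acc = np.zeros(2 * w + 1)
    cnt = np.zeros(2 * w + 1)
    for chrom, point in points:
        if chrom not in signal.values:
            continue
        arr = signal.values[chrom]
        c = int(point // signal.bin_size)
        lo, hi = c - w, c + w + 1
        src_lo, src_hi = max(0, lo), min(arr.size, hi)
        if src_hi <= src_lo:
            continue
        seg = arr[src_lo:src_hi]
        dst = slice(src_lo - lo, src_lo - lo + seg.size)
        ok = np.isfinite(seg)
        acc[dst][ok] += seg[ok]
        cnt[dst][ok] += 1
    if not cnt.any():
        raise ValueError("no point has a defined flanking signal")
    out = np.full(offsets.size, np.nan)
    out[cnt > 0] = acc[cnt > 0] / cnt[cnt > 0]
    return offsets, out


def rfd_shift_amplitude(points: list[tuple[str, float]], rfd: GenomeSignal,
                        flank: int = 10_000) -> float:
    """Mean RFD downstream minus upstream of the aligned points.

    The canonical summary of the averaged RFD profile around initiation
    clusters: efficient origins produce a large positive shift.
    """
    offsets, prof = mean_profile_around(points, rfd, flank)
    left = prof[offsets < 0]
    right = prof[offsets > 0]
    return float(np.nanmean(right) - np.nanmean(left))


def assign_timing(events: list[ReplicationEvent], timing: GenomeSignal
                  ) -> tuple[np.ndarray, list[str]]:
    """Normalized replication timing of each event's bin.

    Returns (timing values for scorable events, ids of events excluded
    because their bin has no defined timing).
    """
    values, excluded = [], []
    for e in events:
        v = timing.value_at(e.chrom, e.midpoint) if e.chrom in timing.values \
            else float("nan")
        if np.isfinite(v):
            values.append(v)
        else:
            excluded.append(e.read_id)
    return np.asarray(values), excluded


# ---------------------------------------------------------------------------
# motif scan
# ---------------------------------------------------------------------------


@dataclass
class Pwm:
    """Position weight matrix over A/C/G/T (non-negative weights).

    ``matrix`` has one row per motif position, columns in A, C, G, T
    order; a site matches when its weight sum reaches ``threshold`` times
    the maximum attainable score.
    """

    matrix: np.ndarray
    threshold: float = 0.8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (motif length, 4)")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G on the 0..3 codes


def pwm_scan(genome: dict[str, str], pwm: Pwm) -> list[tuple[str, int, str, float]]:
    """All motif matches on both strands, 0-based forward coordinates.

    Returns (chrom, position, strand, score) for every window whose score
    reaches ``threshold * max_score``; a reverse-strand match is reported
    at the forward coordinate of the window it occupies.  Sequences
    shorter than the motif yield nothing.
    """
    cutoff = pwm.threshold * pwm.max_score
    length = pwm.length
    rows = np.arange(length)
    matches = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        if len(seq) < length:
            continue
        codes = encode_bases(seq)
        for strand in "+-":
            strand_codes = codes if strand == "+" else _COMPLEMENT[codes][::-1]
            wins = np.lib.stride_tricks.sliding_window_view(strand_codes, length)
            scores = pwm.matrix[rows[None, :], wins].sum(axis=1)
            for i in np.flatnonzero(scores >= cutoff):
                pos = int(i) if strand == "+" else len(seq) - length - int(i)
                matches.append((chrom, pos, strand, float(scores[i])))
    return sorted(matches)


def motif_fraction(
    windows: list[tuple[str, int, int]],
    matches: list[tuple[str, int, str, float]],
    chrom_lengths: dict,
    n_shuffles: int = 1_000,
    seed: int = 0,
) -> dict:
    """Fraction of windows containing a motif match, with a shuffled null.

    Window centres are shuffled uniformly per chromosome ``n_shuffles``
    times (counts preserved); the null's median and [0.01, 0.99] percentile
    band are reported with the empirical percentile of the observed value.
    """
    match_pos = {}
    for chrom, pos, _, _ in matches:
        match_pos.setdefault(chrom, []).append(pos)
    match_pos = {c: np.sort(v) for c, v in match_pos.items()}

    def _fraction(wins):
        hits = 0
        for chrom, start, end in wins:
            mp = match_pos.get(chrom)
            if mp is not None and np.searchsorted(mp, end) > np.searchsorted(mp, start):
                hits += 1
        return hits / len(wins) if wins else float("nan")

    observed = _fraction(windows)
    rng = np.random.default_rng(seed)
    widths = {}
    for chrom, start, end in windows:
        widths.setdefault(chrom, []).append(end - start)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuffled = []
        for chrom, ws in widths.items():
            centers = rng.integers(0, chrom_lengths[chrom], len(ws))
            for c, w in zip(centers, ws):
                shuffled.append((chrom, int(c - w // 2), int(c + w // 2)))
        null[k] = _fraction(shuffled)
    return {
        "observed": observed,
        "null_median": float(np.median(null)),
        "null_band": (float(np.quantile(null, 0.01)), float(np.quantile(null, 0.99))),
        "percentile": float(np.mean(null < observed)),
    }
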