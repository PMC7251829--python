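"""Genome-wide signals assembled from oriented tracks and events.

RFD (replication fork directionality) at a position is the difference
between rightward- and leftward-fork coverage over the total coverage,
(R - L)/(R + L): +1 means purely rightward replication, -1 purely
leftward, and positions with no covering track are missing (NaN), which
is distinct from RFD = 0 (balanced coverage).  The OEM (origin efficiency
metric) compares the rightward-fork fraction of the two 10-kb windows
flanking a position, signed so initiation zones are positive and
termination zones negative.  The initiation-minus-termination density
bins pooled events in 5-kb windows.

Signals are accumulated on a 100-nt internal grid (a documented
memory/accuracy compromise vs strictly per-nucleotide coverage) and
smoothed with centred running means that shrink at chromosome ends,
ignore missing bins, and leave a bin missing when fewer than half of its
window is defined.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .io import GenomeSignal, ReplicationEvent, ReplicationTrack

GRID = 100  # internal accumulation grid, nt


def _running_mean_nan(values: np.ndarray, window_bins: int,
                      min_defined: float = 0.5) -> np.ndarray:
    """Centred running mean ignoring NaN; shrinks at the edges.

    A bin stays NaN when fewer than ``min_defined`` of its available
    window is defined.
    """
    if window_bins <= 1:
        return values.copy()
    half = window_bins // 2
    n = values.size
    finite = np.isfinite(values)
    vals = np.where(finite, values, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(finite)])
    i = np.arange(n)
    lo = np.maximum(0, i - half)
    hi = np.minimum(n, i + half + 1)
    total = csum[hi] - csum[lo]
    count = ccnt[hi] - ccnt[lo]
    width = hi - lo
    out = np.full(n, np.nan)
    ok = count >= np.maximum(1, min_defined * width)
    out[ok] = total[ok] / count[ok]
    return out


def _coverage(tracks: list[ReplicationTrack], chrom_lengths: dict,
              grid: int = GRID) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """(rightward, leftward) per-bin coverage counts per chromosome."""
    cov = {c: (np.zeros(int(np.ceil(l / grid))), np.zeros(int(np.ceil(l / grid))))
           for c, l in chrom_lengths.items()}
    for t in tracks:
        if t.orientation not in ("right", "left") or t.chrom not in cov:
            continue
        r, l = cov[t.chrom]
        arr = r if t.orientation == "right" else l
        b0 = max(0, t.start // grid)
        b1 = min(arr.size, (t.end - 1) // grid + 1)
        arr[b0:b1] += 1
    return cov


def compute_rfd(
    tracks: list[ReplicationTrack],
    chrom_lengths: dict,
    grid: int = GRID,
    smooth: int = 1_000,
) -> GenomeSignal:
    """RFD = (R - L)/(R + L) per bin, then a centred 1-kb running mean."""
    cov = _coverage(tracks, chrom_lengths, grid)
    window_bins = max(1, int(round(smooth / grid)) | 1)  # odd, centred
    values = {}
    for chrom, (r, l) in cov.items():
        total = r + l
        rfd = np.full(total.size, np.nan)
        covered = total > 0
        rfd[covered] = (r[covered] - l[covered]) / total[covered]
        values[chrom] = _running_mean_nan(rfd, window_bins)
    return GenomeSignal("RFD", grid, values)


def compute_oem(
    tracks: list[ReplicationTrack],
    chrom_lengths: dict,
    window: int = 10_000,
    grid: int = GRID,
    min_coverage: float = 5.0,
) -> GenomeSignal:
    """Origin efficiency metric on sliding flanking windows.

    OEM(x) = R/(R+L) over (x, x+window] minus R/(R+L) over (x-window, x],
    which makes initiation zones positive (+1 at an isolated fully
    efficient origin) and termination zones negative.  Missing wherever
    either flanking window's mean per-bin track coverage falls below
    ``min_coverage``: a fork-direction fraction estimated from a handful
    of molecules is noise, not signal.
    """
    cov = _coverage(tracks, chrom_lengths, grid)
    w = max(1, window // grid)
    values = {}
    for chrom, (r, l) in cov.items():
        n = r.size
        cr = np.concatenate([[0.0], np.cumsum(r)])
        cl = np.concatenate([[0.0], np.cumsum(l)])
        i = np.arange(n)
        lo = np.maximum(0, i - w)
        hi = np.minimum(n, i + w)
        r_left = cr[i] - cr[lo]
        l_left = cl[i] - cl[lo]
        r_right = cr[hi] - cr[i]
        l_right = cl[hi] - cl[i]
        left_tot = r_left + l_left
        right_tot = r_right + l_right
        oem = np.full(n, np.nan)
        ok = ((left_tot / np.maximum(i - lo, 1) >= max(min_coverage, 1e-12))
              & (right_tot / np.maximum(hi - i, 1) >= max(min_coverage, 1e-12)))
        frac_left = np.divide(r_left, left_tot, out=np.zeros(n), where=left_tot > 0)
        frac_right = np.divide(r_right, right_tot, out=np.zeros(n), where=right_tot > 0)
        oem[ok] = frac_right[ok] - frac_left[ok]
        values[chrom] = oem
    return GenomeSignal("OEM", grid, values)


def it_density(
    events: list[ReplicationEvent],
    chrom_lengths: dict,
    bin_size: int = 5_000,
    smooth: int = 10_000,
) -> GenomeSignal:
    """Initiation minus termination counts per bin, 10-kb running mean.

    The smoothing window is the centred odd-bin approximation of
    ``smooth`` (3 bins of 5 kb for the defaults).
    """
    values = {}
    for chrom, length in chrom_lengths.items():
        n = int(np.ceil(length / bin_size))
        counts = np.zeros(n)
        for e in events:
            if e.chrom != chrom:
                continue
            b = min(n - 1, e.midpoint // bin_size)
            counts[b] += 1 if e.type == "initiation" else -1
        window_bins = max(1, int(round(smooth / bin_size)) | 1)
        values[chrom] = _running_mean_nan(counts, window_bins, min_defined=0.0)
    return GenomeSignal("IT_density", bin_size, values)


def rfd_correlation(signal_a: GenomeSignal, signal_b: GenomeSignal) -> float:
    """Spearman rank correlation over bins defined in both signals.

    The two signals must share a grid; chromosomes present in both are
    concatenated, NaN bins are excluded pairwise, and fewer than 10 shared
    defined bins is an error.
    """
    if signal_a.bin_size != signal_b.bin_size:
        raise ValueError("signals must share a common grid")
    xs, ys = [], []
    for chrom in sorted(set(signal_a.values) & set(signal_b.values)):
        a = signal_a.values[chrom]
        b = signal_b.values[chrom]
        n = min(a.size, b.size)
        ok = np.isfinite(a[:n]) & np.isfinite(b[:n])
        xs.append(a[:n][ok])
        ys.append(b[:n][ok])
    x = np.concatenate(xs) if xs else np.zeros(0)
    y = np.concatenate(ys) if ys else np.zeros(0)
    if x.size < 10:
        raise ValueError(f"only {x.size} shared defined bins (< 10)")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def resample_signal(signal: GenomeSignal, bin_size: int) -> GenomeSignal:
    """Block-average a signal onto a coarser grid (NaN-aware)."""
    if bin_size % signal.bin_size != 0:
        raise ValueError("target bin size must be a multiple of the source's")
    k = bin_size // signal.bin_size
    values = {}
    for chrom, arr in signal.values.items():
        n = int(np.ceil(arr.size / k))
        padded = np.full(n * k, np.nan)
        padded[: arr.size] = arr
        blocks = padded.reshape(n, k)
        ok = np.isfinite(blocks)
        sums = np.where(ok, blocks, 0.0).sum(axis=1)
        cnt = ok.sum(axis=1)
        out = np.full(n, np.nan)
        out[cnt > 0] = sums[cnt > 0] / cnt[cnt > 0]
        values[chrom] = out
    return GenomeSignal(signal.kind, bin_size, values)
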