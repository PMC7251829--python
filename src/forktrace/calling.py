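"""Per-read BrdU content estimation.

Two independent estimators operate on drift-normalized reads:

* the transition-matrix (TM) caller assigns B, T or X at every T site
  (hexamers with a T in the middle of their first pentamer) by comparing
  the observed current shift with the expected thymidine- and BrdU-context
  shifts, calling X wherever the two contexts are less than the gap
  threshold apart; the calls are then smoothed into a fractional content
  by a sliding window over 30 consecutive B/T calls;

* a small 1D convolutional network maps a window of 96 transitions (one-hot
  base plus normalized shift, shape (96, 5)) to the window's mean BrdU
  content through three 32-filter convolutions of kernel 5, two 4x
  max-poolings and a per-position sigmoid dense head averaged over the
  remaining 6 positions.  Inference slides the window by 10 transitions and
  averages, per 10-nt segment, the predictions of every window containing
  the segment.

The network is trained with plain stochastic gradient descent (learning
rate 0.1, decay 1e-6, momentum 0.9), a 90/10 train/validation split and
early stopping after 5 epochs without validation improvement; an optional
second pass re-labels high-content cohorts by predicted content to expel
unsubstituted parental reads, then retrains from scratch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import (
    BrdUProfile,
    ResquiggledRead,
    TransitionMatrix,
    central_t_mask,
    hexamer_indices,
)

logger = logging.getLogger("forktrace")

CALL_B, CALL_T, CALL_X = (np.uint8(ord(c)) for c in "BTX")


# ---------------------------------------------------------------------------
# transition-matrix caller
# ---------------------------------------------------------------------------


def call_tm(
    read: ResquiggledRead,
    tm_t: TransitionMatrix,
    tm_b: TransitionMatrix,
    gap_threshold: float = 0.4,
) -> BrdUProfile:
    """B/T/X call at every T site of a normalized read.

    A site is callable only when the thymidine- and BrdU-context expected
    shifts differ by more than ``gap_threshold``; the call is then the
    context nearest to the observed shift (exact ties stay X, which keeps
    the caller deterministic).
    """
    codes = read.codes
    hexamers = hexamer_indices(codes)
    sites = central_t_mask(codes)
    hex_at = hexamers[sites]
    delta_obs = read.shifts[: hexamers.size][sites]
    d_t = tm_t.values[hex_at]
    d_b = tm_b.values[hex_at]

    calls = np.full(hex_at.size, CALL_X)
    informative = np.abs(d_t - d_b) > gap_threshold
    dist_t = np.abs(delta_obs - d_t)
    dist_b = np.abs(delta_obs - d_b)
    calls[informative & (dist_b < dist_t)] = CALL_B
    calls[informative & (dist_t < dist_b)] = CALL_T
    positions = read.ref_start + 2 + np.flatnonzero(sites)
    return BrdUProfile(read.read_id, read.chrom, positions, calls=calls, method="TM")


def profile_to_fraction(profile: BrdUProfile, window: int = 30) -> BrdUProfile:
    """Sliding B/(B+T) fraction over ``window`` consecutive non-X calls.

    X sites are dropped entirely (they enter neither numerator nor
    denominator); each fraction is anchored at the reference coordinate of
    the window's central retained site.  Fewer than ``window`` non-X sites
    yield an empty profile.
    """
    if profile.calls is None:
        raise ValueError("profile_to_fraction needs a B/T/X call profile")
    keep = profile.calls != CALL_X
    b = (profile.calls[keep] == CALL_B).astype(float)
    pos = profile.positions[keep]
    raw_sd = float(b.std()) if b.size else 0.0
    if b.size < window:
        return BrdUProfile(profile.read_id, profile.chrom,
                           np.zeros(0, dtype=np.int64),
                           content=np.zeros(0), method=profile.method,
                           raw_sd=raw_sd)
    kernel = np.ones(window) / window
    frac = np.convolve(b, kernel, mode="valid")
    centers = pos[window // 2: window // 2 + frac.size]
    return BrdUProfile(profile.read_id, profile.chrom, centers,
                       content=frac, method=profile.method, raw_sd=raw_sd)


# ---------------------------------------------------------------------------
# convolutional estimator
# ---------------------------------------------------------------------------


@dataclass
class CnnSpec:
    """Architecture of the window-content estimator."""

    window: int = 96
    input_channels: int = 5  # one-hot A,T,C,G + normalized shift
    filters: int = 32
    kernel: int = 5
    pool: int = 4  # after conv layers 1 and 2; combined 16x reduction
    stride: int = 10  # inference window shift

    def __post_init__(self) -> None:
        if self.window % (self.pool ** 2) != 0:
            raise ValueError("window must be a multiple of the combined pooling (16)")


@dataclass
class TrainSpec:
    """SGD schedule of the estimator."""

    learning_rate: float = 0.1
    decay: float = 1e-6
    momentum: float = 0.9
    batch_size: int = 32
    val_fraction: float = 0.1
    patience: int = 5  # epochs without validation improvement
    max_epochs: int = 50
    second_pass: bool = True  # relabel BrdU-rich reads by predicted content
    relabel_threshold: float = 0.5  # labels >= this are screened in pass 2

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("early-stop patience must be >= 1")
        if not 0 < self.val_fraction < 1:
            raise ValueError("validation fraction must be in (0, 1)")


def _one_hot_features(read: ResquiggledRead) -> np.ndarray:
    """(n-1, 5) features: one-hot base of N_i plus the shift at transition i."""
    codes = read.codes[:-1]
    shifts = read.shifts
    feats = np.zeros((shifts.size, 5), dtype=np.float32)
    # one-hot column order is A, T, C, G; base codes are A=0, C=1, G=2, T=3
    onehot_col = np.array([0, 2, 3, 1])
    feats[np.arange(shifts.size), onehot_col[codes]] = 1.0
    feats[:, 4] = shifts
    return feats


class CnnEstimator:
    """Numpy implementation of the (96, 5) -> content network.

    Three same-padded 1D convolutions (32 filters, kernel 5, ReLU) with 4x
    max-pooling after the first two, a shared dense+sigmoid head applied to
    each of the 6 remaining positions, averaged to a single fraction.
    Forward and backward passes are explicit; the optimizer is SGD with
    momentum and the Keras-style 1/(1+decay*t) learning-rate decay.
    """

    def __init__(self, spec: CnnSpec | None = None, seed: int = 0):
        self.spec = spec or CnnSpec()
        rng = np.random.default_rng(seed)
        k, f, c = self.spec.kernel, self.spec.filters, self.spec.input_channels
        self.params = {
            "W1": _glorot(rng, k * c, f),
            "b1": np.zeros(f),
            "W2": _glorot(rng, k * f, f),
            "b2": np.zeros(f),
            "W3": _glorot(rng, k * f, f),
            "b3": np.zeros(f),
            "Wd": _glorot(rng, f, 1),
            "bd": np.zeros(1),
        }
        self._velocity = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._iterations = 0
        self.history: list[dict] = []

    # -- forward / backward ------------------------------------------------

    def _forward(self, x: np.ndarray, cache: bool = False):
        p = self.spec.pool
        w1, z1 = _conv1d(x, self.params["W1"], self.params["b1"], self.spec.kernel)
        r1 = np.maximum(z1, 0.0)
        p1, i1 = _maxpool(r1, p)
        w2, z2 = _conv1d(p1, self.params["W2"], self.params["b2"], self.spec.kernel)
        r2 = np.maximum(z2, 0.0)
        p2, i2 = _maxpool(r2, p)
        w3, z3 = _conv1d(p2, self.params["W3"], self.params["b3"], self.spec.kernel)
        h = np.maximum(z3, 0.0)
        logits = h @ self.params["Wd"] + self.params["bd"]  # (N, 6, 1)
        s = 1.0 / (1.0 + np.exp(-logits[..., 0]))  # (N, 6)
        y = s.mean(axis=1)
        if not cache:
            return y
        return y, (x, w1, z1, i1, p1, w2, z2, i2, p2, w3, z3, h, s)

    def predict(self, windows: np.ndarray) -> np.ndarray:
        """Content fraction for a batch of (window, 5) inputs."""
        out = []
        for i in range(0, len(windows), 512):
            out.append(self._forward(windows[i:i + 512]))
        return np.concatenate(out) if out else np.zeros(0)

    def _backward(self, cache, dy: np.ndarray) -> dict:
        x, w1, z1, i1, p1, w2, z2, i2, p2, w3, z3, h, s = cache
        k = self.spec.kernel
        grads = {}
        ds = dy[:, None] / s.shape[1] * s * (1.0 - s)  # (N, 6)
        grads["Wd"] = np.einsum("nlc,nl->c", h, ds)[:, None]
        grads["bd"] = np.array([ds.sum()])
        dh = ds[..., None] * self.params["Wd"][None, None, :, 0]
        dz3 = dh * (z3 > 0)
        grads["W3"], grads["b3"], dp2 = _conv1d_back(w3, dz3, self.params["W3"], k)
        dr2 = _maxpool_back(dp2, i2, z2.shape, self.spec.pool)
        dz2 = dr2 * (z2 > 0)
        grads["W2"], grads["b2"], dp1 = _conv1d_back(w2, dz2, self.params["W2"], k)
        dr1 = _maxpool_back(dp1, i1, z1.shape, self.spec.pool)
        dz1 = dr1 * (z1 > 0)
        grads["W1"], grads["b1"], _ = _conv1d_back(w1, dz1, self.params["W1"], k)
        return grads

    def _sgd_step(self, grads: dict, train: TrainSpec) -> None:
        lr = train.learning_rate / (1.0 + train.decay * self._iterations)
        self._iterations += 1
        for name, g in grads.items():
            v = self._velocity[name]
            v *= train.momentum
            v -= lr * g
            self.params[name] += v

    # -- training ----------------------------------------------------------

    def fit(self, windows: np.ndarray, labels: np.ndarray, train: TrainSpec,
            rng: np.random.Generator) -> None:
        n = len(windows)
        order = rng.permutation(n)
        n_val = max(1, int(round(train.val_fraction * n)))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        xv, yv = windows[val_idx], labels[val_idx]
        xt, yt = windows[tr_idx], labels[tr_idx]

        best_loss = np.inf
        best_params = None
        stale = 0
        for epoch in range(train.max_epochs):
            perm = rng.permutation(len(xt))
            for i in range(0, len(perm), train.batch_size):
                idx = perm[i:i + train.batch_size]
                y, cache = self._forward(xt[idx], cache=True)
                err = y - yt[idx]
                grads = self._backward(cache, 2.0 * err / err.size)
                self._sgd_step(grads, train)
            val_loss = float(np.mean((self.predict(xv) - yv) ** 2))
            self.history.append({"epoch": epoch, "val_loss": val_loss})
            logger.debug("cnn epoch %d val_loss %.5f", epoch, val_loss)
            if val_loss < best_loss - 1e-6:
                best_loss, stale = val_loss, 0
                best_params = {k_: v.copy() for k_, v in self.params.items()}
            else:
                stale += 1
                if stale >= train.patience:
                    break
        if best_params is not None:
            self.params = best_params

    def predict_read(self, read: ResquiggledRead) -> float:
        """Mean predicted content over non-overlapping windows of one read."""
        feats = _one_hot_features(read)
        w = self.spec.window
        n = feats.shape[0] // w
        if n == 0:
            return float("nan")
        windows = feats[: n * w].reshape(n, w, 5)
        return float(self.predict(windows).mean())


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, (fan_in, fan_out))


def _conv1d(x: np.ndarray, w: np.ndarray, b: np.ndarray, kernel: int):
    """Same-padded 1D convolution via an im2col matmul.

    x: (N, L, C); w: (kernel*C, F).  Returns (windows, output) where
    windows (N, L, kernel*C) is kept for the backward pass.
    """
    pad = kernel // 2
    xp = np.pad(x, ((0, 0), (pad, kernel - 1 - pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=1)
    # (N, L, C, k) -> (N, L, k, C) -> (N, L, k*C)
    win = np.ascontiguousarray(win.transpose(0, 1, 3, 2))
    win = win.reshape(x.shape[0], x.shape[1], -1)
    return win, win @ w + b


def _conv1d_back(windows, dz, w, kernel):
    n, length, _ = dz.shape
    dw = np.einsum("nlk,nlf->kf", windows, dz)
    db = dz.sum(axis=(0, 1))
    dwin = dz @ w.T  # (N, L, k*C)
    c = w.shape[0] // kernel
    dwin = dwin.reshape(n, length, kernel, c)
    pad = kernel // 2
    dxp = np.zeros((n, length + kernel - 1, c))
    for j in range(kernel):
        dxp[:, j:j + length] += dwin[:, :, j]
    return dw, db, dxp[:, pad:pad + length]


def _maxpool(x: np.ndarray, pool: int):
    n, length, c = x.shape
    blocks = x.reshape(n, length // pool, pool, c)
    idx = blocks.argmax(axis=2)
    return np.take_along_axis(blocks, idx[:, :, None, :], axis=2)[:, :, 0, :], idx


def _maxpool_back(dp, idx, shape, pool):
    n, length, c = shape
    dblocks = np.zeros((n, length // pool, pool, c))
    np.put_along_axis(dblocks, idx[:, :, None, :], dp[:, :, None, :], axis=2)
    return dblocks.reshape(n, length, c)


# ---------------------------------------------------------------------------
# training / inference entry points
# ---------------------------------------------------------------------------


def reads_to_windows(reads, labels, spec: CnnSpec):
    """Non-overlapping (window, 5) segments with per-window copies of each
    read's cohort-level content label."""
    xs, ys, owners = [], [], []
    w = spec.window
    for ridx, (read, label) in enumerate(zip(reads, labels)):
        feats = _one_hot_features(read)
        n = feats.shape[0] // w
        if n == 0:
            continue
        xs.append(feats[: n * w].reshape(n, w, 5))
        ys.append(np.full(n, label, dtype=np.float32))
        owners.append(np.full(n, ridx))
    if not xs:
        raise ValueError("no read long enough to yield a training window")
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(owners)


def train_cnn(
    labeled_reads: list[tuple[ResquiggledRead, float]],
    cnn_spec: CnnSpec | None = None,
    train_spec: TrainSpec | None = None,
    seed: int = 0,
) -> CnnEstimator:
    """Train the window-content estimator on cohort-labelled reads.

    ``labeled_reads`` pairs each read with its cohort's mean BrdU content.
    At least two distinct content levels are required (a single level makes
    the regression unidentifiable).  With ``second_pass`` enabled, reads in
    high-content cohorts whose first-pass predicted content falls below
    half their label (parental, unsubstituted molecules) are removed and
    the estimator is retrained from scratch on the cleaned set.
    """
    cnn_spec = cnn_spec or CnnSpec()
    train_spec = train_spec or TrainSpec()
    labels = np.array([lab for _, lab in labeled_reads], dtype=float)
    if np.unique(np.round(labels, 6)).size < 2:
        raise ValueError("need at least 2 distinct content levels to train")

    rng = np.random.default_rng(seed)
    reads = [r for r, _ in labeled_reads]
    est = CnnEstimator(cnn_spec, seed=seed)
    x, y, _ = reads_to_windows(reads, labels, cnn_spec)
    est.fit(x, y, train_spec, rng)

    if train_spec.second_pass:
        keep = np.ones(len(reads), dtype=bool)
        for i, (read, label) in enumerate(labeled_reads):
            if label >= train_spec.relabel_threshold:
                pred = est.predict_read(read)
                if np.isfinite(pred) and pred < label / 2:
                    keep[i] = False
        if not keep.all() and np.unique(np.round(labels[keep], 6)).size >= 2:
            logger.info("cnn second pass: dropped %d/%d reads from high-content "
                        "cohorts", int((~keep).sum()), len(reads))
            est = CnnEstimator(cnn_spec, seed=seed + 1)
            x, y, _ = reads_to_windows(
                [r for r, k in zip(reads, keep) if k], labels[keep], cnn_spec)
            est.fit(x, y, train_spec, np.random.default_rng(seed + 1))
    return est


def call_cnn(read: ResquiggledRead, estimator: CnnEstimator) -> BrdUProfile:
    """Fractional BrdU content on a 10-nt grid.

    Windows start every ``stride`` transitions, plus one flush-right window
    so the read end is covered; each 10-nt segment's value is the mean
    prediction over every window that fully contains the segment.  Reads
    shorter than one window yield an empty profile.
    """
    spec = estimator.spec
    feats = _one_hot_features(read)
    n_trans = feats.shape[0]
    w, stride = spec.window, spec.stride
    if n_trans < w:
        logger.info("read %s shorter than one window (%d transitions); empty "
                    "profile", read.read_id, n_trans)
        return BrdUProfile(read.read_id, read.chrom, np.zeros(0, dtype=np.int64),
                           content=np.zeros(0), method="CNN")
    starts = list(range(0, n_trans - w + 1, stride))
    if starts[-1] != n_trans - w:
        starts.append(n_trans - w)
    starts = np.array(starts)
    windows = np.stack([feats[s:s + w] for s in starts])
    preds = estimator.predict(windows)

    n_seg = n_trans // stride
    sums = np.zeros(n_seg)
    counts = np.zeros(n_seg)
    for s, p in zip(starts, preds):
        j0 = int(np.ceil(s / stride))
        j1 = (s + w) // stride - 1  # last segment fully inside the window
        j1 = min(j1, n_seg - 1)
        if j1 >= j0:
            sums[j0:j1 + 1] += p
            counts[j0:j1 + 1] += 1
    covered = counts > 0
    content = np.clip(sums[covered] / counts[covered], 0.0, 1.0)
    positions = read.ref_start + stride * np.flatnonzero(covered) + stride // 2
    return BrdUProfile(read.read_id, read.chrom, positions.astype(np.int64),
                       content=content, method="CNN")
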