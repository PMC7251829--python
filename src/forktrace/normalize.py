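"""Transition-matrix estimation and per-read drift normalization.

The expected current shift for each of the 4096 pentamer-to-pentamer
transitions (hexamers) is the arithmetic mean of the observed shifts at
that hexamer across a read cohort.  Individual reads drift linearly in
scale and offset relative to the cohort; the drift is removed by the
least-squares linear map ``alpha*delta + beta`` that best matches the
expected shifts, fitted only on transitions without a T in the centre of
either pentamer (those are the transitions BrdU can perturb, so they are
excluded from the fit).  Reads whose minimized mean squared distance
exceeds a cutoff (default 0.25) are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import (
    N_HEXAMERS,
    DriftFit,
    ResquiggledRead,
    TransitionMatrix,
    either_pentamer_t_mask,
    hexamer_indices,
)

logger = logging.getLogger("forktrace")

#: minimum usable non-T-centred transitions for a stable 2-parameter fit
MIN_FIT_TRANSITIONS = 50
RESIDUAL_CUTOFF = 0.25
READ_CAP = 4000  # reads used per matrix estimate


def compute_shifts(read: ResquiggledRead) -> np.ndarray:
    """Current shifts delta_i = m_i - m_{i+1}; length n-1."""
    if len(read) < 2:
        raise ValueError("need at least 2 currents to form a shift")
    return read.shifts


def estimate_transition_matrix(
    reads: Sequence[ResquiggledRead],
    min_occurrences: int = 10,
    context: str = "T",
    read_cap: int = READ_CAP,
) -> TransitionMatrix:
    """Per-hexamer mean of observed shifts over a read cohort.

    Hexamers seen fewer than ``min_occurrences`` times are imputed with the
    global mean shift and flagged in ``imputed`` so that expected-shift
    lookups have no holes.
    """
    reads = list(reads)[:read_cap]
    if not reads:
        raise ValueError("cannot estimate a transition matrix from zero reads")
    sums = np.zeros(N_HEXAMERS)
    counts = np.zeros(N_HEXAMERS, dtype=np.int64)
    for read in reads:
        hexamers = hexamer_indices(read.codes)
        shifts = read.shifts[: hexamers.size]
        np.add.at(sums, hexamers, shifts)
        np.add.at(counts, hexamers, 1)
    imputed = counts < min_occurrences
    values = np.empty(N_HEXAMERS)
    observed = ~imputed
    values[observed] = sums[observed] / counts[observed]
    global_mean = sums.sum() / max(counts.sum(), 1)
    values[imputed] = global_mean
    if imputed.any():
        logger.info("transition matrix: %d/%d hexamers imputed with the global mean",
                    int(imputed.sum()), N_HEXAMERS)
    return TransitionMatrix(values, context, counts=counts, imputed=imputed)


def fit_drift(read: ResquiggledRead, reference_matrix: TransitionMatrix) -> DriftFit:
    """Closed-form least-squares drift of one read against expected shifts.

    Minimizes sum_i (alpha*delta_i + beta - expected_i)^2 over transitions
    with a full hexamer context and no T in the centre of either pentamer.
    The reported residual is the minimized *mean* squared distance.
    """
    codes = read.codes
    hexamers = hexamer_indices(codes)
    eligible = ~either_pentamer_t_mask(codes)
    if int(eligible.sum()) < MIN_FIT_TRANSITIONS:
        raise ValueError(
            f"read {read.read_id}: only {int(eligible.sum())} usable transitions "
            f"(< {MIN_FIT_TRANSITIONS}); drift fit rejected"
        )
    delta = read.shifts[: hexamers.size][eligible].astype(np.float64)
    expected = reference_matrix.values[hexamers[eligible]]
    var = np.var(delta)
    if var == 0:
        raise ValueError(f"read {read.read_id}: constant shifts, drift unidentifiable")
    alpha = float(np.cov(delta, expected, bias=True)[0, 1] / var)
    beta = float(expected.mean() - alpha * delta.mean())
    residual = float(np.mean((alpha * delta + beta - expected) ** 2))
    return DriftFit(alpha=alpha, beta=beta, residual=residual,
                    n_transitions=int(eligible.sum()))


def normalize_reads(
    reads: Iterable[ResquiggledRead],
    reference_matrix: TransitionMatrix,
    residual_cutoff: float = RESIDUAL_CUTOFF,
) -> tuple[list[ResquiggledRead], list[tuple[str, str, float]]]:
    """Apply the fitted drift to each read; discard poor fits.

    Returns (normalized reads, rejection log).  A read is discarded when its
    minimized mean squared distance is strictly greater than the cutoff
    (a read at exactly the cutoff is retained), or when the drift fit
    itself is impossible.  Surviving reads carry drift-corrected currents,
    so their derived shifts equal ``alpha*delta + beta``.
    """
    kept: list[ResquiggledRead] = []
    rejected: list[tuple[str, str, float]] = []
    for read in reads:
        try:
            fit = fit_drift(read, reference_matrix)
        except ValueError as exc:
            rejected.append((read.read_id, str(exc), float("nan")))
            logger.info("read %s rejected: %s", read.read_id, exc)
            continue
        if fit.residual > residual_cutoff:
            rejected.append((read.read_id, "residual above cutoff", fit.residual))
            logger.info("read %s rejected: residual %.3f > %.3f",
                        read.read_id, fit.residual, residual_cutoff)
            continue
        kept.append(_apply_drift(read, fit))
    return kept, rejected


def _apply_drift(read: ResquiggledRead, fit: DriftFit) -> ResquiggledRead:
    # shifts transform as alpha*delta + beta; currents are rebuilt so that
    # the derived shifts of the returned read are the normalized ones
    new_shifts = fit.alpha * read.shifts + fit.beta
    currents = np.concatenate([[read.currents[0]], read.currents[0] - np.cumsum(new_shifts)])
    out = ResquiggledRead(read.read_id, read.chrom, read.ref_start, read.strand,
                          read.bases, currents, meta=dict(read.meta))
    out.meta["drift_fit"] = {"alpha": fit.alpha, "beta": fit.beta,
                             "residual": fit.residual}
    return out


def build_reference_matrices(
    thymidine_reads: Sequence[Sequence[ResquiggledRead]] | Sequence[ResquiggledRead],
    brdu_reads: Sequence[Sequence[ResquiggledRead]] | Sequence[ResquiggledRead],
    residual_cutoff: float = RESIDUAL_CUTOFF,
    min_occurrences: int = 10,
    read_cap: int = READ_CAP,
) -> tuple[TransitionMatrix, TransitionMatrix, dict]:
    """Two-step estimation of the thymidine/BrdU reference matrix pair.

    Per condition and replicate: a bootstrap matrix is estimated from raw
    reads (step 1); each read's drift is then fitted against it, poor fits
    are discarded, and the matrix is re-estimated from the normalized
    survivors (step 2).  Replicate matrices are averaged.  Each argument is
    either a list of replicate read sets or a single read set (accepted
    with a warning, since averaging needs two replicates to do anything).

    Returns (TM_T, TM_B, report); the report carries per-condition
    rejection fractions and the reads re-normalized against TM_T.
    """
    report: dict = {"rejection_fraction": {}, "normalized_reads": {}}
    matrices = {}
    for name, cohort in (("T", thymidine_reads), ("B", brdu_reads)):
        replicates = _as_replicates(cohort)
        if not replicates or not any(replicates):
            raise ValueError(f"{name} condition: no reads supplied")
        if len(replicates) == 1:
            logger.warning("%s condition: single replicate, averaging is a no-op", name)
        rep_matrices = []
        n_total = n_rejected = 0
        for rep in replicates:
            step1 = estimate_transition_matrix(rep, min_occurrences, context=name,
                                               read_cap=read_cap)
            normalized, rejected = normalize_reads(rep, step1, residual_cutoff)
            n_total += len(rep)
            n_rejected += len(rejected)
            if not normalized:
                raise ValueError(f"{name} condition: zero reads survived normalization")
            rep_matrices.append(
                estimate_transition_matrix(normalized, min_occurrences,
                                           context=name, read_cap=read_cap)
            )
        values = np.mean([m.values for m in rep_matrices], axis=0)
        counts = np.sum([m.counts for m in rep_matrices], axis=0)
        imputed = np.all([m.imputed for m in rep_matrices], axis=0)
        matrices[name] = TransitionMatrix(values, name, counts=counts, imputed=imputed)
        report["rejection_fraction"][name] = n_rejected / max(n_total, 1)

    tm_t, tm_b = matrices["T"], matrices["B"]
    # final pass: re-normalize every read against the thymidine reference
    for name, cohort in (("T", thymidine_reads), ("B", brdu_reads)):
        flat = [r for rep in _as_replicates(cohort) for r in rep]
        normalized, _ = normalize_reads(flat, tm_t, residual_cutoff)
        report["normalized_reads"][name] = normalized
    return tm_t, tm_b, report


def _as_replicates(cohort) -> list[list[ResquiggledRead]]:
    cohort = list(cohort)
    if cohort and isinstance(cohort[0], ResquiggledRead):
        return [cohort]
    return [list(rep) for rep in cohort]
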