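"""Core data model and file IO for the fork-mapping pipeline.

Coordinate conventions
----------------------
Every coordinate handled internally is 0-based, half-open ``[start, end)``.
BED input is already 0-based half-open and is taken as-is; wiggle input is
1-based and converted on load.  Resquiggled read bases are given on the
reference forward strand (the upstream signal-to-reference alignment maps
them there), so hexamer contexts are strand-free throughout the package.

Signal containers use ``NaN`` as the explicit missing marker: an undefined
RFD bin is *not* the same thing as RFD = 0 (which means balanced fork
coverage), so missing values are never encoded as zeros.

Resquiggled-read table format
-----------------------------
A tab-separated text file with one read per row and a ``#``-prefixed header:

    read_id  chrom  ref_start  strand  bases  currents  [meta]

``bases`` is the reference-aligned base string (A/C/G/T), ``currents`` the
comma-separated per-base mean normalized currents, and the optional ``meta``
column a JSON object (the simulator stores its ground truth there).  Current
shifts ``delta_i = m_i - m_{i+1}`` are derived on load, never stored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("forktrace")

BASES = "ACGT"
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i

#: number of distinct pentamer-to-pentamer transitions (hexamers)
N_HEXAMERS = 4 ** 6

# powers of 4 used to index a hexamer: base at offset k contributes code*4^(5-k)
_HEX_POWERS = 4 ** np.arange(5, -1, -1)


def encode_bases(bases: str) -> np.ndarray:
    """Map an A/C/G/T string to uint8 codes 0..3; raises on other characters."""
    codes = _BASE_CODE[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        bad = bases[int(np.argmax(codes > 3))]
        raise ValueError(f"non-ACGT base {bad!r} in sequence")
    return codes


def decode_hexamer(index: int) -> str:
    return "".join(BASES[(index // p) % 4] for p in _HEX_POWERS)


def hexamer_indices(codes: np.ndarray) -> np.ndarray:
    """Hexamer index for every transition i with a full 6-base context.

    The hexamer attached to the current shift at transition ``i`` is
    ``bases[i:i+6]``; a read of n bases therefore yields n-5 indexed
    transitions (the trailing shifts have no full context).
    """
    if codes.size < 6:
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), 6)
    return windows @ _HEX_POWERS


def central_t_mask(codes: np.ndarray) -> np.ndarray:
    """True where transition i has a T in the middle of its first pentamer.

    "T in the middle position of a pentamer" is position 3 (1-based) of the
    first pentamer, i.e. ``bases[i+2]``; these are the sites at which B/T
    calling takes place.
    """
    if codes.size < 6:
        return np.zeros(0, dtype=bool)
    return codes[2:-3] == 3  # code 3 == 'T'


def either_pentamer_t_mask(codes: np.ndarray) -> np.ndarray:
    """True where transition i has a T in the centre of either pentamer.

    The drift fit disregards these transitions: the first pentamer's centre
    is ``bases[i+2]`` and the second's is ``bases[i+3]``.
    """
    if codes.size < 6:
        return np.zeros(0, dtype=bool)
    return (codes[2:-3] == 3) | (codes[3:-2] == 3)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ResquiggledRead:
    """A reference-aligned read: per-base mean currents plus derived shifts."""

    read_id: str
    chrom: str
    ref_start: int
    strand: str
    bases: str
    currents: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents)
        if self.currents.dtype.kind != "f":
            self.currents = self.currents.astype(float)
        if len(self.bases) != self.currents.size:
            raise ValueError(
                f"read {self.read_id}: {len(self.bases)} bases vs "
                f"{self.currents.size} currents"
            )
        self._codes: np.ndarray | None = None

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = encode_bases(self.bases)
        return self._codes

    @property
    def shifts(self) -> np.ndarray:
        """Current shifts delta_i = m_i - m_{i+1} (length n-1)."""
        return self.currents[:-1] - self.currents[1:]

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def ref_end(self) -> int:
        return self.ref_start + len(self.bases)


@dataclass
class TransitionMatrix:
    """Expected normalized current shift per hexamer (4096 entries)."""

    values: np.ndarray
    context: str  # 'T' or 'B'
    counts: np.ndarray | None = None
    imputed: np.ndarray | None = None  # hexamers never observed / low coverage

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_HEXAMERS,):
            raise ValueError(f"transition matrix must have {N_HEXAMERS} entries")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("transition matrix contains non-finite values")

    def lookup(self, hexamers: np.ndarray) -> np.ndarray:
        return self.values[hexamers]


@dataclass
class DriftFit:
    """Per-read linear drift: normalized shift = alpha*delta + beta."""

    alpha: float
    beta: float
    residual: float  # mean squared distance after the fit
    n_transitions: int = 0


@dataclass
class BrdUProfile:
    """Per-read BrdU signal: B/T/X calls (TM) or fractional content (CNN/TM).

    ``positions`` are reference coordinates; ``calls`` uses the byte codes
    b'B', b'T', b'X'.  ``content`` values are fractions in [0, 1].
    """

    read_id: str
    chrom: str
    positions: np.ndarray
    calls: np.ndarray | None = None
    content: np.ndarray | None = None
    method: str = "TM"
    #: sd of the unsmoothed per-call B indicator (TM path); the read filter
    #: uses it where available because the binary-call dispersion, not the
    #: smoothed profile's, is what separates substituted from native reads
    raw_sd: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.content is not None:
            self.content = np.asarray(self.content, dtype=float)


@dataclass
class ReplicationTrack:
    chrom: str
    start: int
    end: int
    orientation: str | None  # 'left', 'right' or None
    slope_up: float  # rescaled units per kb, > 0
    slope_down: float  # rescaled units per kb, < 0
    min_p: float  # rescaled signal at the preceding minimum
    min_f: float  # rescaled signal at the following minimum
    rise_amp: float = float("nan")  # pre-rescale amplitude of the upward shift
    fall_amp: float = float("nan")  # pre-rescale amplitude of the downward shift
    resid_sd: float = float("nan")  # off-track residual sd, pre-rescale units
    read_id: str = ""
    method: str = "TM"
    ascore: float = float("nan")
    jscore: float = float("nan")
    open_ended: bool = False

    @property
    def fork_start(self) -> int:
        """Fork position at pulse onset: the steep side of the track."""
        if self.orientation == "right":
            return self.start
        if self.orientation == "left":
            return self.end
        raise ValueError("unoriented track has no fork start")


@dataclass
class ReplicationEvent:
    type: str  # 'initiation' or 'termination'
    chrom: str
    midpoint: int
    fork_start_left: int
    fork_start_right: int
    read_id: str = ""
    method: str = "TM"
    shared: bool = False

    def __post_init__(self) -> None:
        if not self.fork_start_left < self.midpoint < self.fork_start_right:
            raise ValueError("event midpoint must lie between fork starts")


@dataclass
class EventCluster:
    chrom: str
    events: list
    mied: float

    @property
    def dimension(self) -> int:
        return len(self.events)

    @property
    def width(self) -> int:
        pts = [e.midpoint for e in self.events]
        return max(pts) - min(pts)

    @property
    def median_point(self) -> float:
        return float(np.median([e.midpoint for e in self.events]))

    @property
    def start(self) -> int:
        return min(e.midpoint for e in self.events)

    @property
    def end(self) -> int:
        return max(e.midpoint for e in self.events)


@dataclass
class GenomeSignal:
    """A binned genome-wide track; NaN marks bins where the signal is undefined."""

    kind: str  # 'RFD', 'OEM', 'IT_density', 'timing', ...
    bin_size: int
    values: dict  # chrom -> np.ndarray of per-bin values

    def bin_of(self, pos: int) -> int:
        return int(pos // self.bin_size)

    def value_at(self, chrom: str, pos: int) -> float:
        arr = self.values[chrom]
        b = self.bin_of(pos)
        if b < 0 or b >= arr.size:
            return float("nan")
        return float(arr[b])


# ---------------------------------------------------------------------------
# resquiggled-read table
# ---------------------------------------------------------------------------

_TABLE_HEADER = "#read_id\tchrom\tref_start\tstrand\tbases\tcurrents\tmeta"


def write_resquiggled_table(reads: Iterable[ResquiggledRead], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_TABLE_HEADER + "\n")
        for read in reads:
            currents = ",".join(f"{c:.5f}" for c in read.currents)
            meta = json.dumps(read.meta, default=_json_default) if read.meta else "{}"
            fh.write(
                f"{read.read_id}\t{read.chrom}\t{read.ref_start}\t{read.strand}\t"
                f"{read.bases}\t{currents}\t{meta}\n"
            )


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_resquiggled_table(path: str | Path, strict: bool = False) -> Iterator[ResquiggledRead]:
    """Stream reads from a table; malformed rows are logged and skipped.

    With ``strict=True`` a malformed row raises instead, naming the row.
    Rows with non-ACGT bases are rejected with a logged reason either way.
    """
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                parts = line.split("\t")
                if len(parts) == 6:
                    read_id, chrom, ref_start, strand, bases, currents = parts
                    meta = {}
                elif len(parts) == 7:
                    read_id, chrom, ref_start, strand, bases, currents, meta_s = parts
                    meta = json.loads(meta_s) if meta_s else {}
                else:
                    raise ValueError(f"expected 6 or 7 columns, found {len(parts)}")
                read = ResquiggledRead(
                    read_id=read_id,
                    chrom=chrom,
                    ref_start=int(ref_start),
                    strand=strand,
                    bases=bases,
                    currents=np.fromstring(currents, sep=",") if currents else np.zeros(0),
                    meta=meta,
                )
                encode_bases(bases)  # reject non-ACGT early, with a clear reason
            except (ValueError, json.JSONDecodeError) as exc:
                if strict:
                    raise ValueError(f"{path}, row {lineno}: {exc}") from exc
                logger.warning("%s row %d rejected: %s", path, lineno, exc)
                continue
            yield read


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def _bed_fields(item, event_halfwidth: int):
    if isinstance(item, ReplicationTrack):
        strand = {"right": "+", "left": "-", None: "."}[item.orientation]
        score = 0 if np.isnan(item.jscore) else min(1000, int(round(item.jscore * 100)))
        return (item.chrom, item.start, item.end, item.read_id or "track", score, strand)
    if isinstance(item, ReplicationEvent):
        name = "init" if item.type == "initiation" else "term"
        return (
            item.chrom,
            max(0, item.midpoint - event_halfwidth),
            item.midpoint + event_halfwidth,
            name,
            1,
            ".",
        )
    if isinstance(item, EventCluster):
        return (item.chrom, item.start, item.end + 1, f"cluster_d{item.dimension}",
                item.dimension, ".")
    chrom, start, end = item[:3]
    rest = list(item[3:]) + ["region", 0, "."][len(item) - 3:]
    return (chrom, start, end, rest[0], rest[1], rest[2])


def write_bed(items: Sequence, path: str | Path, event_halfwidth: int = 1) -> None:
    """Write tracks, events, clusters or (chrom,start,end[,...]) tuples as BED6.

    Track orientation is encoded in the strand column (+ = rightward); events
    are expanded to ``midpoint +/- event_halfwidth``.  Output is sorted by
    (chrom, start).
    """
    rows = sorted((_bed_fields(it, event_halfwidth) for it in items),
                  key=lambda r: (r[0], r[1]))
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_annotation_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED intervals as (chrom, start, end, name); 0-based half-open.

    Mixed chromosome naming conventions (some records with and some without
    a ``chr`` prefix) are rejected with the offenders listed.
    """
    intervals = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}, row {lineno}: fewer than 3 BED columns")
            name = parts[3] if len(parts) > 3 else ""
            intervals.append((parts[0], int(parts[1]), int(parts[2]), name))
    prefixes = {iv[0].startswith("chr") for iv in intervals}
    if len(prefixes) > 1:
        offenders = sorted({iv[0] for iv in intervals if not iv[0].startswith("chr")})
        raise ValueError(f"mixed chromosome naming conventions; offenders: {offenders}")
    return intervals


# ---------------------------------------------------------------------------
# wiggle / bedGraph
# ---------------------------------------------------------------------------


def read_wig(path: str | Path, bin_size: int = 1000, kind: str = "signal") -> GenomeSignal:
    """Read fixedStep/variableStep wiggle or bedGraph into a binned signal.

    Wiggle positions are 1-based and converted to the internal 0-based
    convention (``fixedStep start=1`` lands at internal coordinate 0).  Values
    are averaged within ``bin_size`` bins; untouched bins are NaN.  When
    ``kind='timing'`` the defined values are normalized so that min -> 0 and
    max -> 1 (start and end of S phase).
    """
    per_chrom: dict[str, dict[int, list[float]]] = {}
    mode = None
    chrom = ""
    step = span = 1
    pos = 0
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                attrs = dict(kv.split("=") for kv in line.split()[1:])
                mode, chrom = "fixed", attrs["chrom"]
                pos = int(attrs["start"]) - 1
                step = int(attrs.get("step", 1))
                span = int(attrs.get("span", 1))
                continue
            if line.startswith("variableStep"):
                attrs = dict(kv.split("=") for kv in line.split()[1:])
                mode, chrom = "variable", attrs["chrom"]
                span = int(attrs.get("span", 1))
                continue
            parts = line.split()
            if mode is None or len(parts) == 4:  # bedGraph row
                c, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                _bin_add(per_chrom, c, s, e, v, bin_size)
            elif mode == "fixed":
                _bin_add(per_chrom, chrom, pos, pos + span, float(parts[0]), bin_size)
                pos += step
            else:
                p = int(parts[0]) - 1
                _bin_add(per_chrom, chrom, p, p + span, float(parts[1]), bin_size)

    values: dict[str, np.ndarray] = {}
    for c, bins in per_chrom.items():
        n = max(bins) + 1
        arr = np.full(n, np.nan)
        for b, vals in bins.items():
            arr[b] = float(np.mean(vals))
        values[c] = arr
    signal = GenomeSignal(kind=kind, bin_size=bin_size, values=values)
    if kind == "timing":
        normalize_timing(signal)
    return signal


def _bin_add(per_chrom, chrom, start, end, value, bin_size):
    bins = per_chrom.setdefault(chrom, {})
    for b in range(start // bin_size, (max(end - 1, start)) // bin_size + 1):
        bins.setdefault(b, []).append(value)


def normalize_timing(signal: GenomeSignal) -> None:
    """Rescale defined values in place so min -> 0 and max -> 1 genome-wide."""
    allv = np.concatenate([v[np.isfinite(v)] for v in signal.values.values()])
    lo, hi = allv.min(), allv.max()
    if hi == lo:
        raise ValueError("timing track is constant; cannot normalize")
    for c in signal.values:
        signal.values[c] = (signal.values[c] - lo) / (hi - lo)


def write_bedgraph(signal: GenomeSignal, path: str | Path) -> None:
    """Write a binned signal as bedGraph, skipping undefined (NaN) bins."""
    with Path(path).open("w") as fh:
        fh.write(f"track type=bedGraph name={signal.kind}\n")
        for chrom in sorted(signal.values):
            arr = signal.values[chrom]
            for b in np.flatnonzero(np.isfinite(arr)):
                s = int(b) * signal.bin_size
                fh.write(f"{chrom}\t{s}\t{s + signal.bin_size}\t{arr[b]:.6g}\n")


# ---------------------------------------------------------------------------
# FASTA and transition-matrix tables
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with Path(path).open("w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_transition_matrices(tm_t: TransitionMatrix, tm_b: TransitionMatrix,
                              path: str | Path) -> None:
    """Serialize the T/B matrix pair as a 4096-row table."""
    with Path(path).open("w") as fh:
        fh.write("#hexamer\tdelta_T\tdelta_B\tcount_T\tcount_B\n")
        ct = tm_t.counts if tm_t.counts is not None else np.zeros(N_HEXAMERS, int)
        cb = tm_b.counts if tm_b.counts is not None else np.zeros(N_HEXAMERS, int)
        for h in range(N_HEXAMERS):
            fh.write(f"{decode_hexamer(h)}\t{tm_t.values[h]:.6f}\t"
                     f"{tm_b.values[h]:.6f}\t{int(ct[h])}\t{int(cb[h])}\n")


def read_transition_matrices(path: str | Path) -> tuple[TransitionMatrix, TransitionMatrix]:
    vt = np.zeros(N_HEXAMERS)
    vb = np.zeros(N_HEXAMERS)
    ct = np.zeros(N_HEXAMERS, dtype=np.int64)
    cb = np.zeros(N_HEXAMERS, dtype=np.int64)
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            hexamer, dt, db, c1, c2 = line.split("\t")
            h = int(encode_bases(hexamer) @ _HEX_POWERS)
            vt[h], vb[h], ct[h], cb[h] = float(dt), float(db), int(c1), int(c2)
    return (TransitionMatrix(vt, "T", counts=ct), TransitionMatrix(vb, "B", counts=cb))
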