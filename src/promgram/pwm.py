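"""Position weight matrices, window scoring and anchored genome scanning.

A PWM is a per-position base-frequency matrix describing a transcription
factor binding motif.  Windows are scored by min-max-normalized additive
log-odds against a uniform background, so every PWM's scores live on the
same [0, 1] scale and its cutoff ``threshold`` is portable between motifs.

The anchored scan mirrors the proximal-promoter geometry used throughout
the package: an anchor motif (the CAAT-box role, typically ~75 nt upstream
of the TSS) is located genome-wide, and a fixed 601-nt window
[-425, +175] around each anchor occurrence is extracted when its GC
content exceeds a floor.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: anchored-segment geometry: bases upstream/downstream of the anchor start
DEFAULT_UPSTREAM = 425
DEFAULT_DOWNSTREAM = 175
#: GC floor for anchored segments (strict: a segment must exceed it)
DEFAULT_GC_MIN = 0.37


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParameterError(ValueError):
    """Raised when an operation receives out-of-contract parameters."""


@dataclass
class PWM:
    """A position weight matrix with a normalized score cutoff.

    Parameters
    ----------
    motif_id : str
        Name of the motif.
    matrix : ndarray, shape (W, 4)
        Per-position base frequencies in A, C, G, T order.  The matrix is
        pseudocount-regularized on construction so every row sums to 1.
    pseudocount : float
        Additive regularizer applied to the raw frequencies.
    threshold : float
        Normalized-score cutoff in [0, 1]; windows scoring >= threshold
        count as hits.
    is_anchor : bool
        Whether this motif plays the anchor (CAAT-box) role in genome scans.
    """

    motif_id: str
    matrix: np.ndarray
    pseudocount: float = 0.01
    threshold: float = 0.8
    is_anchor: bool = False
    _logodds: np.ndarray = field(init=False, repr=False)
    _score_min: float = field(init=False, repr=False)
    _score_max: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ParameterError("PWM matrix must have shape (W, 4) with W >= 1")
        if np.any(m < 0):
            raise ParameterError("PWM frequencies must be non-negative")
        if not 0.0 <= self.threshold <= 1.0:
            raise ParameterError("PWM threshold must lie in [0, 1]")
        if self.pseudocount <= 0:
            raise ParameterError("pseudocount must be positive")
        # normalize raw rows, then regularize: p' = (p + c) / (1 + 4c)
        row_sums = m.sum(axis=1, keepdims=True)
        if np.any(row_sums <= 0):
            raise ParameterError("each PWM position needs positive total mass")
        m = m / row_sums
        m = (m + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        self.matrix = m
        lo = np.log(m / 0.25)
        # N (index 4) contributes the position's minimum
        self._logodds = np.column_stack([lo, lo.min(axis=1)])
        self._score_min = float(lo.min(axis=1).sum())
        self._score_max = float(lo.max(axis=1).sum())

    def __len__(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def width(self) -> int:
        return len(self)

    @property
    def consensus(self) -> str:
        """Highest-frequency base at each position (ties: A<C<G<T order)."""
        return "".join(BASES[i] for i in np.argmax(self.matrix, axis=1))

    def reverse_complement(self) -> "PWM":
        """The PWM describing the motif on the opposite strand."""
        rc = PWM.__new__(PWM)
        # undo regularization so re-construction does not double-apply it
        raw = self.matrix * (1.0 + 4.0 * self.pseudocount) - self.pseudocount
        raw = np.clip(raw, 0.0, None)[::-1, ::-1]
        rc.__init__(
            motif_id=self.motif_id,
            matrix=raw,
            pseudocount=self.pseudocount,
            threshold=self.threshold,
            is_anchor=self.is_anchor,
        )
        return rc


@dataclass(frozen=True)
class MotifHit:
    """One detected binding-site instance, in forward coordinates."""

    motif_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    score: float


@dataclass(frozen=True)
class GenomicSegment:
    """A fixed-length anchored genome segment, oriented along its strand."""

    chrom: str
    start: int
    end: int
    strand: str
    anchor_pos: int
    sequence: str
    gc: float


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as integer indices (A0 C1 G2 T3 N4)."""
    try:
        return np.fromiter(
            (_BASE_INDEX[b] for b in seq.upper()), dtype=np.int8, count=len(seq)
        )
    except KeyError as exc:  # pragma: no cover - message only
        raise ParameterError(f"unexpected base {exc} in sequence") from exc


def score_window(pwm: PWM, window: str) -> float:
    """Normalized log-odds score of one window of length W.

    Returns (S - S_min) / (S_max - S_min) where S sums per-position
    log(freq/0.25); N positions contribute the position minimum.  The
    consensus scores 1.0 and the per-position-worst window scores 0.0.
    """
    if len(window) != len(pwm):
        raise ParameterError(
            f"window length {len(window)} != PWM width {len(pwm)}"
        )
    idx = encode(window)
    s = float(pwm._logodds[np.arange(len(pwm)), idx].sum())
    rng = pwm._score_max - pwm._score_min
    if rng == 0:
        return 1.0
    return (s - pwm._score_min) / rng


def _window_scores(pwm: PWM, encoded: np.ndarray) -> np.ndarray:
    """Normalized scores of every window of an encoded sequence."""
    w = len(pwm)
    n = len(encoded) - w + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, w)
    raw = pwm._logodds[np.arange(w)[None, :], windows].sum(axis=1)
    rng = pwm._score_max - pwm._score_min
    if rng == 0:
        return np.ones(n)
    return (raw - pwm._score_min) / rng


def scan_sequence(
    pwm: PWM,
    seq: str,
    seq_id: str = "seq",
    both_strands: bool = True,
    threshold: float | None = None,
) -> list[MotifHit]:
    """All windows scoring at or above the PWM threshold.

    Minus-strand windows are scored on the reverse complement of the
    window; hits are reported in forward coordinates, sorted by start then
    strand ('+' before '-').  Overlapping hits are all kept.
    """
    if not seq:
        raise ParameterError("sequence must be non-empty")
    t = pwm.threshold if threshold is None else threshold
    encoded = encode(seq)
    hits: list[MotifHit] = []
    w = len(pwm)
    scores = _window_scores(pwm, encoded)
    for start in np.flatnonzero(scores >= t):
        hits.append(
            MotifHit(pwm.motif_id, seq_id, int(start), int(start) + w, "+",
                     float(scores[start]))
        )
    if both_strands:
        rc_scores = _window_scores(pwm.reverse_complement(), encoded)
        for start in np.flatnonzero(rc_scores >= t):
            hits.append(
                MotifHit(pwm.motif_id, seq_id, int(start), int(start) + w,
                         "-", float(rc_scores[start]))
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def compute_gc(seq: str) -> float:
    """GC fraction over A/C/G/T bases; N excluded; empty or all-N -> 0."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    return gc / acgt if acgt else 0.0


def extract_anchor_segments(
    chrom_seq: str,
    anchor_hits: Iterable[MotifHit],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    gc_min: float = DEFAULT_GC_MIN,
    chrom: str = "chrom",
) -> list[GenomicSegment]:
    """Fixed-length windows around anchor motif occurrences.

    For a plus-strand anchor starting at p the segment covers the
    inclusive window [p - upstream, p + downstream], i.e. half-open
    [p - upstream, p + downstream + 1); for a minus-strand anchor the
    window is mirrored around the hit start ([p - downstream,
    p + upstream]) and the stored sequence is reverse-complemented so the
    anchor geometry reads identically on both strands.  Windows running
    past a chromosome end are dropped, as are segments whose GC content
    does not exceed ``gc_min`` (strict).
    """
    length = upstream + downstream + 1
    out: list[GenomicSegment] = []
    n = len(chrom_seq)
    for hit in anchor_hits:
        p = hit.start
        if hit.strand == "+":
            start, end = p - upstream, p + downstream + 1
        else:
            start, end = p - downstream, p + upstream + 1
        if start < 0 or end > n:
            continue
        seq = chrom_seq[start:end]
        gc = compute_gc(seq)
        if gc <= gc_min:
            continue
        if hit.strand == "-":
            seq = reverse_complement(seq)
        out.append(
            GenomicSegment(chrom, start, end, hit.strand, p, seq, gc)
        )
        assert end - start == length
    return out


# ---------------------------------------------------------------------------
# PWM file format: header ">motif_id threshold=<t> anchor=<0|1>" followed by
# one row per position of four tab-separated A C G T frequencies.
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(
    r">\s*(?P<id>\S+)\s+threshold=(?P<t>[\d.eE+-]+)\s+anchor=(?P<a>[01])"
)


def write_pwms(pwms: Sequence[PWM], path: str | Path) -> None:
    """Write PWMs in the package's TSV dialect."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(
                f">{pwm.motif_id} threshold={pwm.threshold:.6g} "
                f"anchor={int(pwm.is_anchor)}\n"
            )
            for row in pwm.matrix:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def read_pwms(path: str | Path, pseudocount: float = 0.01) -> list[PWM]:
    """Read PWMs written by :func:`write_pwms`.

    Stored frequencies are already regularized; they are renormalized but
    a fresh pseudocount is still applied, so a write/read round trip is
    idempotent only up to the (small) pseudocount; thresholds and flags
    round-trip exactly.
    """
    pwms: list[PWM] = []
    header: re.Match | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        if header is None:
            return
        pwms.append(
            PWM(
                motif_id=header["id"],
                matrix=np.array(rows),
                pseudocount=pseudocount,
                threshold=float(header["t"]),
                is_anchor=header["a"] == "1",
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                m = _HEADER_RE.match(line)
                if m is None:
                    raise ParameterError(f"malformed PWM header: {line!r}")
                header, rows = m, []
            else:
                rows.append([float(v) for v in line.split("\t")])
    flush()
    return pwms


def write_hits_bed(hits: Sequence[MotifHit], path: str | Path) -> None:
    """Write motif hits as BED6; scores scaled x1000 and rounded."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{h.motif_id}\t"
                f"{int(round(h.score * 1000))}\t{h.strand}\n"
            )
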