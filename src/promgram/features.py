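"""Grammar feature extraction: motif chains and (M_i, S_i, L_(i+1)_i) vectors.

A promoter window is summarized by the ordered chain of motif occurrences
counted from the window's downstream (right) end — the end nearest the
TSS.  Position 1 is the motif whose end lies closest to the right end;
position indices increase moving upstream.  Each chain slot i contributes
a motif identity M_i and strand S_i, and each adjacent pair contributes a
discretized spacer length L_(i+1)_i (the nt gap between the two motifs).
Slots beyond the chain length are MISSING.  Only sequences whose chain
contains at least three motifs are admitted to training/classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import math

import numpy as np
import pandas as pd

from .pwm import PWM, MotifHit, ParameterError, scan_sequence

logger = logging.getLogger(__name__)

MISSING = "NA"
#: default spacer discretization (nt, right-open bins; last bin unbounded)
DEFAULT_BINS: tuple[float, ...] = (0, 20, 50, 100, 200, math.inf)
DEFAULT_MAX_POSITIONS = 8
#: minimum number of chain motifs for a sequence to be admitted
MIN_MOTIFS = 3

CLASS_HISTONE = "histone"
CLASS_BACKGROUND = "background"


def bin_labels(bins: Sequence[float]) -> list[str]:
    """Human-readable labels for the spacer bins, e.g. '20-50'."""
    labels = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        hi_s = "inf" if math.isinf(hi) else f"{int(hi)}"
        labels.append(f"{int(lo)}-{hi_s}")
    return labels


def bin_spacer(spacer: int, bins: Sequence[float]) -> str:
    """Bin a raw spacer (nt); negative spacers are clamped to the first bin."""
    spacer = max(0, spacer)
    k = int(np.searchsorted(np.asarray(bins[1:-1]), spacer, side="right"))
    return bin_labels(bins)[k]


@dataclass
class FeatureVector:
    """One sequence's grammar encoding with MISSING slots.

    ``M`` holds motif ids, ``S`` strands ('+'/'-'), ``L`` spacer-bin
    labels; unused slots hold the token ``NA``.  Non-missing slots are
    contiguous from slot 1.
    """

    seq_id: str
    class_label: str
    M: list[str]
    S: list[str]
    L: list[str]

    @property
    def n_motifs(self) -> int:
        return sum(m != MISSING for m in self.M)

    def __post_init__(self) -> None:
        if len(self.L) != len(self.M) - 1 or len(self.S) != len(self.M):
            raise ParameterError("slot arity mismatch in FeatureVector")


@dataclass
class FeatureTable:
    """A set of feature vectors sharing a motif alphabet and spacer bins."""

    rows: list[FeatureVector]
    motif_alphabet: list[str]
    n_positions: int = DEFAULT_MAX_POSITIONS
    spacer_bins: tuple[float, ...] = DEFAULT_BINS

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.rows:
            counts[r.class_label] = counts.get(r.class_label, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        p = self.n_positions
        cols = {"seq_id": [r.seq_id for r in self.rows],
                "class": [r.class_label for r in self.rows]}
        for i in range(p):
            cols[f"M{i + 1}"] = [r.M[i] for r in self.rows]
        for i in range(p):
            cols[f"S{i + 1}"] = [r.S[i] for r in self.rows]
        for i in range(p - 1):
            cols[f"L{i + 2}_{i + 1}"] = [r.L[i] for r in self.rows]
        return pd.DataFrame(cols)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#bins=" + ",".join(
                "inf" if math.isinf(b) else f"{b:g}" for b in self.spacer_bins
            ) + "\n")
            fh.write("#alphabet=" + ",".join(self.motif_alphabet) + "\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureTable":
        bins: tuple[float, ...] = DEFAULT_BINS
        alphabet: list[str] | None = None
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#bins="):
                    bins = tuple(
                        math.inf if tok == "inf" else float(tok)
                        for tok in line.strip()[len("#bins="):].split(",")
                    )
                elif line.startswith("#alphabet="):
                    alphabet = line.strip()[len("#alphabet="):].split(",")
                else:
                    fh.seek(pos)
                    break
                pos = fh.tell()
            df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
        p = sum(c.startswith("M") for c in df.columns)
        rows = []
        for _, rec in df.iterrows():
            rows.append(FeatureVector(
                seq_id=rec["seq_id"],
                class_label=rec["class"],
                M=[rec[f"M{i + 1}"] for i in range(p)],
                S=[rec[f"S{i + 1}"] for i in range(p)],
                L=[rec[f"L{i + 2}_{i + 1}"] for i in range(p - 1)],
            ))
        if alphabet is None:
            alphabet = sorted(
                {m for r in rows for m in r.M if m != MISSING}
            )
        return cls(rows, alphabet, p, bins)


def select_chain(
    hits: Iterable[MotifHit],
    seq_len: int,
    max_positions: int = DEFAULT_MAX_POSITIONS,
) -> list[MotifHit]:
    """Order hits into the grammar chain, rightmost end first.

    Hits are ranked by the distance of their END coordinate from the
    sequence's right end (nearest first).  Overlapping hits are resolved
    to one hit per locus by score (ties: earlier start, then lexicographic
    motif id).  The first ``max_positions`` surviving hits form the chain;
    position i increases away from the right end.
    """
    # overlap resolution first: one hit per locus, best score wins
    # (ties: earlier start, then lexicographic motif id)
    kept: list[MotifHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.start, h.motif_id)):
        if all(h.end <= k.start or h.start >= k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: seq_len - h.end)
    return kept[:max_positions]


def vectorize(
    chain: Sequence[MotifHit],
    bins: Sequence[float] = DEFAULT_BINS,
    n_positions: int = DEFAULT_MAX_POSITIONS,
    seq_id: str = "seq",
    class_label: str = "unknown",
) -> FeatureVector:
    """Encode an ordered chain as an (M, S, L) feature vector.

    L_(i+1)_i is the binned nt gap between the motif at position i+1
    (upstream) and the motif at position i (downstream): start of the
    downstream motif minus end of the upstream motif, clamped at 0 when
    overlap resolution leaves touching or crossing hits.
    """
    M = [MISSING] * n_positions
    S = [MISSING] * n_positions
    L = [MISSING] * (n_positions - 1)
    for i, hit in enumerate(chain[:n_positions]):
        M[i] = hit.motif_id
        S[i] = hit.strand
        if i > 0:
            gap = chain[i - 1].start - hit.end
            L[i - 1] = bin_spacer(gap, bins)
    return FeatureVector(seq_id, class_label, M, S, L)


def build_feature_table(
    sequences: Iterable[tuple[str, str, str]],
    pwms: Sequence[PWM],
    bins: Sequence[float] = DEFAULT_BINS,
    n_positions: int = DEFAULT_MAX_POSITIONS,
    min_motifs: int = MIN_MOTIFS,
    both_strands: bool = True,
) -> FeatureTable:
    """Scan labelled sequences and assemble the admitted feature vectors.

    ``sequences`` yields (seq_id, class_label, sequence).  Only sequences
    whose resolved chain holds at least ``min_motifs`` motifs are admitted.
    Raises if no sequence is admissible.
    """
    rows: list[FeatureVector] = []
    n_rejected = 0
    for seq_id, label, seq in sequences:
        hits: list[MotifHit] = []
        for pwm in pwms:
            hits.extend(scan_sequence(pwm, seq, seq_id, both_strands))
        chain = select_chain(hits, len(seq), n_positions)
        if len(chain) < min_motifs:
            n_rejected += 1
            continue
        rows.append(vectorize(chain, bins, n_positions, seq_id, label))
    logger.info("feature table: %d admitted, %d rejected (<%d motifs)",
                len(rows), n_rejected, min_motifs)
    if not rows:
        raise ParameterError(
            "no sequence passed the >=%d-motif admission filter" % min_motifs
        )
    return FeatureTable(rows, [p.motif_id for p in pwms], n_positions,
                        tuple(bins))


def calibrate_threshold(
    pwm: PWM,
    known_sites: Sequence[str],
    target_recall: float = 0.9,
) -> float:
    """Largest threshold at which >= target_recall of known sites still hit.

    Equivalently the ceil(target_recall * n)-th largest site score.
    """
    if not known_sites:
        raise ParameterError("need at least one known site")
    if not 0 < target_recall <= 1:
        raise ParameterError("target_recall must lie in (0, 1]")
    from .pwm import score_window

    scores = sorted((score_window(pwm, s) for s in known_sites), reverse=True)
    k = math.ceil(target_recall * len(scores))
    return scores[k - 1]
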