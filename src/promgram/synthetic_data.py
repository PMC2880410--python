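"""Synthetic inputs with known ground truth for the whole pipeline.

Every generator is a pure function of its parameters and a seed: classed
training sequences carrying a planted motif grammar, toy PWMs, a toy
multi-chromosome genome with planted promoter segments plus annotation,
and latent-factor expression matrices with a tightly coexpressed
"histone" probe block.

The planted grammar mirrors the proximal-promoter geometry the package
models: a chain of at least three motifs with a conserved order, strand
bias and spacer distribution, anchored near the downstream (TSS-proximal)
end of a 601-nt window — the [-500, +100] promoter window with the anchor
motif at -75 relative to the TSS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GeneAnnotation
from .pwm import (BASES, PWM, MotifHit, ParameterError, reverse_complement)

#: anchor start sits at seq_len - 1 - anchor_offset; 175 puts it 425 nt
#: into a 601-nt window, i.e. at -75 of a [-500, +100] promoter window
DEFAULT_ANCHOR_OFFSET = 175
DEFAULT_SEQ_LEN = 601
#: index of the TSS-equivalent base inside a 601-nt window ([-500, +100])
TSS_INDEX = 500


@dataclass
class GrammarSpec:
    """A planted promoter grammar.

    ``motif_chain`` lists motif ids in chain order, position 1 (the most
    downstream motif) first.  ``strand_probs[i]`` is the probability that
    chain slot i sits on the plus strand; ``spacer_dists[i]`` is a
    discrete distribution over the nt gap between chain slots i+1 and i+2.
    ``insertion_noise`` is the per-slot dropout probability and
    ``motif_fidelity`` the probability a planted base is the consensus
    base (1.0 plants exact consensus strings).
    """

    motif_chain: list[str]
    strand_probs: list[float]
    spacer_dists: list[dict[int, float]]
    anchor_offset: int = DEFAULT_ANCHOR_OFFSET
    insertion_noise: float = 0.0
    background_gc: float = 0.45
    motif_fidelity: float = 1.0

    def __post_init__(self) -> None:
        k = len(self.motif_chain)
        if k < 3:
            raise ParameterError("grammar chain must hold >= 3 motifs")
        if len(self.strand_probs) != k or len(self.spacer_dists) != k - 1:
            raise ParameterError("strand_probs/spacer_dists arity mismatch")
        for p in (*self.strand_probs, self.insertion_noise,
                  self.background_gc, self.motif_fidelity):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("probabilities must lie in [0, 1]")
        for dist in self.spacer_dists:
            if not math.isclose(sum(dist.values()), 1.0, abs_tol=1e-9):
                raise ParameterError("spacer distributions must sum to 1")
            if any(g < 0 for g in dist):
                raise ParameterError("spacer lengths must be >= 0")


@dataclass
class ExpressionSpec:
    """Shape and correlation structure of a synthetic expression matrix.

    Defaults follow the GNF-Atlas-like layout the pipeline analyzes:
    79 tissues, 2 technical replicates each, 93 histone probes.
    ``rho_histone`` is the target pairwise correlation inside the histone
    block, ``rho_predicted`` the correlation of predicted-block probes
    with the shared latent tissue profile.
    """

    n_tissues: int = 79
    n_replicates: int = 2
    n_histone_probes: int = 93
    n_predicted_probes: int = 200
    n_background_probes: int = 2000
    rho_histone: float = 0.8
    rho_predicted: float = 0.5
    noise_sd: float = 0.1
    baseline_log2: float = 6.0

    def __post_init__(self) -> None:
        for n in (self.n_tissues, self.n_replicates, self.n_histone_probes,
                  self.n_predicted_probes, self.n_background_probes):
            if n < 2:
                raise ParameterError("all counts must be >= 2")
        if not 0.0 <= self.rho_histone <= 1.0:
            raise ParameterError(
                "rho_histone outside [0, 1]: the equicorrelated histone "
                "block has no positive semi-definite Gram matrix")
        if not -1.0 <= self.rho_predicted <= 1.0:
            raise ParameterError("rho_predicted outside [-1, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# toy PWMs
# ---------------------------------------------------------------------------


def generate_toy_pwms(
    n_motifs: int,
    length_range: tuple[int, int] = (5, 12),
    seed: int | None = None,
    dominant: float = 0.85,
    threshold: float = 0.85,
) -> list[PWM]:
    """Random sharp PWMs; motif 0 is flagged as the anchor (CAAT-box role).

    Each position puts mass ``dominant`` on one consensus base and spreads
    the rest uniformly.  When the length range allows, the anchor motif's
    consensus is the canonical CCAAT pentamer.
    """
    lo, hi = length_range
    if n_motifs < 1:
        raise ParameterError("n_motifs must be >= 1")
    if lo < 4 or hi < lo:
        raise ParameterError("motif lengths must be >= 4 and range ordered")
    if not 0.25 < dominant <= 1.0:
        raise ParameterError("dominant base frequency must exceed 0.25")
    rng = np.random.default_rng(seed)
    pwms: list[PWM] = []
    for j in range(n_motifs):
        if j == 0 and lo <= 5 <= hi:
            consensus = "CCAAT"
        else:
            w = int(rng.integers(lo, hi + 1))
            consensus = "".join(rng.choice(list(BASES), size=w))
        matrix = np.full((len(consensus), 4), (1.0 - dominant) / 3.0)
        for i, b in enumerate(consensus):
            matrix[i, BASES.index(b)] = dominant
        pwms.append(PWM(motif_id=f"motif{j:02d}", matrix=matrix,
                        threshold=threshold, is_anchor=(j == 0)))
    return pwms


def default_grammar(
    pwms: Sequence[PWM],
    n_chain: int = 5,
    seed: int | None = None,
    **overrides,
) -> GrammarSpec:
    """A strongly conserved grammar over the first ``n_chain`` PWMs.

    The anchor motif takes chain position 1 (most downstream); strands are
    heavily plus-biased and each adjacent pair gets a narrow two-point
    spacer distribution, so order/strand/spacing carry real signal.
    """
    if n_chain < 3 or n_chain > len(pwms):
        raise ParameterError("n_chain must be in [3, n_pwms]")
    rng = np.random.default_rng(seed)
    chain = [p.motif_id for p in pwms[:n_chain]]
    spacers = []
    for _ in range(n_chain - 1):
        base = int(rng.integers(10, 60))
        spacers.append({base: 0.7, base + 15: 0.3})
    kwargs = dict(
        motif_chain=chain,
        strand_probs=[0.9] * n_chain,
        spacer_dists=spacers,
    )
    kwargs.update(overrides)
    return GrammarSpec(**kwargs)


# ---------------------------------------------------------------------------
# sequence planting
# ---------------------------------------------------------------------------


def _random_background(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=n, p=probs))


def _chain_fits(grammar: GrammarSpec, widths: dict[str, int],
                seq_len: int) -> bool:
    """Whether the chain fits at its worst-case spacer draws."""
    left_need = sum(max(dist) + widths[m] for dist, m in
                    zip(grammar.spacer_dists, grammar.motif_chain[1:]))
    start1 = seq_len - 1 - grammar.anchor_offset
    return (start1 - left_need >= 0
            and start1 + widths[grammar.motif_chain[0]] <= seq_len)


def _sample_instance(rng: np.random.Generator, pwm: PWM,
                     fidelity: float) -> str:
    if fidelity >= 1.0:
        return pwm.consensus
    bases = []
    for i, cons in enumerate(pwm.consensus):
        if rng.random() < fidelity:
            bases.append(cons)
        else:
            bases.append(BASES[int(rng.choice(4, p=pwm.matrix[i]))])
    return "".join(bases)


def _plant(
    rng: np.random.Generator,
    grammar: GrammarSpec,
    pwms_by_id: dict[str, PWM],
    seq_len: int,
    seq_id: str,
) -> tuple[str, list[MotifHit]]:
    """One positive sequence: background with the grammar chain written in."""
    seq = list(_random_background(rng, seq_len, grammar.background_gc))
    hits: list[MotifHit] = []
    w1 = len(pwms_by_id[grammar.motif_chain[0]])
    start = seq_len - 1 - grammar.anchor_offset
    for slot, motif_id in enumerate(grammar.motif_chain):
        pwm = pwms_by_id[motif_id]
        w = len(pwm)
        if slot > 0:
            gaps, probs = zip(*sorted(grammar.spacer_dists[slot - 1].items()))
            gap = int(rng.choice(gaps, p=np.array(probs)))
            start = prev_start - gap - w
        if start < 0:
            raise ParameterError(
                f"grammar chain does not fit in seq_len={seq_len}")
        prev_start = start
        dropped = rng.random() < grammar.insertion_noise
        strand = "+" if rng.random() < grammar.strand_probs[slot] else "-"
        if not dropped:
            inst = _sample_instance(rng, pwm, grammar.motif_fidelity)
            if strand == "-":
                inst = reverse_complement(inst)
            seq[start:start + w] = inst
            hits.append(MotifHit(motif_id, seq_id, start, start + w,
                                 strand, 1.0))
    hits.sort(key=lambda h: h.start)
    return "".join(seq), hits


def generate_training_set(
    grammar: GrammarSpec,
    pwms: Sequence[PWM],
    n_pos: int,
    n_neg: int,
    seq_len: int = DEFAULT_SEQ_LEN,
    seed: int | None = None,
) -> tuple[list[tuple[str, str, str]], list[MotifHit]]:
    """Labelled training sequences plus the planted ground-truth hits.

    Returns (records, truth): records are (seq_id, class_label, sequence)
    with exactly ``n_pos`` histone-class and ``n_neg`` background-class
    entries of length ``seq_len``; truth lists every planted motif
    instance for oracle tests.
    """
    pwms_by_id = {p.motif_id: p for p in pwms}
    missing = set(grammar.motif_chain) - set(pwms_by_id)
    if missing:
        raise ParameterError(f"grammar motifs missing from PWM set: {missing}")
    if not _chain_fits(grammar, {k: len(v) for k, v in pwms_by_id.items()},
                       seq_len):
        raise ParameterError("grammar chain cannot fit in seq_len")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str, str]] = []
    truth: list[MotifHit] = []
    for i in range(n_pos):
        seq_id = f"pos{i:04d}"
        seq, hits = _plant(rng, grammar, pwms_by_id, seq_len, seq_id)
        records.append((seq_id, "histone", seq))
        truth.extend(hits)
    for i in range(n_neg):
        seq_id = f"neg{i:04d}"
        records.append(
            (seq_id, "background",
             _random_background(rng, seq_len, grammar.background_gc)))
    return records, truth


def generate_rotating_grammar_set(
    pwms: Sequence[PWM],
    n_pos: int,
    n_neg: int,
    seq_len: int = DEFAULT_SEQ_LEN,
    seed: int | None = None,
    n_chain: int = 5,
    spacer_menu: Sequence[int] = (5, 25, 60, 110),
    anchor_offset: int = 30,
    strand_prob: float = 0.5,
    background_gc: float = 0.45,
) -> list[tuple[str, str, str]]:
    """Positives with first-order-only grammar signal.

    Each positive's chain starts at a random point of the fixed motif
    cycle (pwms[0], pwms[1], ...), so every chain slot's marginal motif
    distribution is uniform; the spacer preceding each motif is a
    deterministic function of that motif (cycling through
    ``spacer_menu``).  The class signal therefore lives entirely in
    adjacent-pair dependencies — which motif follows which, and at what
    distance — and is invisible to per-slot marginals.  Negatives are
    i.i.d. background.
    """
    rng = np.random.default_rng(seed)
    ids = [p.motif_id for p in pwms]
    spacing = {ids[k]: int(spacer_menu[k % len(spacer_menu)])
               for k in range(len(ids))}
    records: list[tuple[str, str, str]] = []
    pwms_by_id = {p.motif_id: p for p in pwms}
    for i in range(n_pos):
        s = int(rng.integers(len(ids)))
        chain = [ids[(s + j) % len(ids)] for j in range(n_chain)]
        grammar = GrammarSpec(
            motif_chain=chain,
            strand_probs=[strand_prob] * n_chain,
            spacer_dists=[{spacing[chain[j + 1]]: 1.0}
                          for j in range(n_chain - 1)],
            anchor_offset=anchor_offset,
            background_gc=background_gc,
        )
        seq, _ = _plant(rng, grammar, pwms_by_id, seq_len, f"pos{i:04d}")
        records.append((f"pos{i:04d}", "histone", seq))
    for i in range(n_neg):
        records.append((f"neg{i:04d}", "background",
                        _random_background(rng, seq_len, background_gc)))
    return records


# ---------------------------------------------------------------------------
# toy genome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSegment:
    """Ground-truth record of one planted promoter segment (BED-like)."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str


def generate_toy_genome(
    grammar: GrammarSpec,
    pwms: Sequence[PWM],
    n_chrom: int = 3,
    chrom_len: int = 100_000,
    n_planted: int = 20,
    seed: int | None = None,
    seg_len: int = DEFAULT_SEQ_LEN,
    intergenic_fraction: float = 0.3,
    minus_fraction: float = 0.5,
) -> tuple[dict[str, str], list[PlantedSegment], list[GeneAnnotation]]:
    """A toy genome with planted promoter segments and a gene annotation.

    Each planted segment is a full positive promoter window written into a
    random background chromosome (reverse-complemented for minus-strand
    plants).  A fraction of segments get a downstream "gene" whose TSS
    sits at the window's TSS-equivalent position; the rest stay
    intergenic.  Returns (genome, truth records, annotations).
    """
    rng = np.random.default_rng(seed)
    pwms_by_id = {p.motif_id: p for p in pwms}
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    capacity = n_chrom * max(chrom_len // (2 * seg_len), 0)
    if n_planted > capacity:
        raise ParameterError(
            f"{n_planted} segments cannot fit without overlap "
            f"({n_chrom} x {chrom_len} nt)")
    genome = {c: list(_random_background(rng, chrom_len,
                                         grammar.background_gc))
              for c in chrom_names}
    # non-overlapping placements, margin 1 segment from chromosome ends
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    truth: list[PlantedSegment] = []
    annotations: list[GeneAnnotation] = []
    for i in range(n_planted):
        for _ in range(1000):
            chrom = chrom_names[int(rng.integers(n_chrom))]
            a = int(rng.integers(seg_len, chrom_len - 2 * seg_len))
            if all(a + seg_len <= s or a >= e
                   for s, e in placed[chrom]):
                break
        else:
            raise ParameterError("could not place segments without overlap")
        placed[chrom].append((a, a + seg_len))
        strand = "-" if rng.random() < minus_fraction else "+"
        name = f"prom{i:03d}"
        seg, _ = _plant(rng, grammar, pwms_by_id, seg_len, name)
        if strand == "-":
            seg = reverse_complement(seg)
        genome[chrom][a:a + seg_len] = seg
        truth.append(PlantedSegment(chrom, a, a + seg_len, name, strand))
        if rng.random() >= intergenic_fraction:
            gene_len = int(rng.integers(2000, 10_000))
            gid = f"gene{i:03d}"
            if strand == "+":
                tss = a + TSS_INDEX
                tx_start = tss
                tx_end = min(chrom_len, tss + gene_len)
            else:
                tss = a + (seg_len - 1 - TSS_INDEX)
                tx_end = tss + 1
                tx_start = max(0, tx_end - gene_len)
            annotations.append(GeneAnnotation(
                gene_id=gid, transcript_id=f"{gid}.t1", chrom=chrom,
                tx_start=tx_start, tx_end=tx_end, tss=tss, strand=strand))
    return ({c: "".join(s) for c, s in genome.items()}, truth, annotations)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def generate_expression(
    spec: ExpressionSpec,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """Raw probe x array expression with a planted correlation structure.

    A shared latent tissue profile z drives the histone block
    (x_i = sqrt(rho_h) z + sqrt(1 - rho_h) e_i, so pairwise correlation is
    rho_h) and the predicted block (x = rho_p z + sqrt(1 - rho_p^2) e);
    background probes are independent noise.  Values are emitted on the
    raw (2^log2) scale with per-probe baseline offsets and technical
    replicate noise both scaled by ``noise_sd``, so the noiseless limit
    leaves block members identical.  Returns (raw values, probe group
    labels, array -> tissue replicate map).
    """
    rng = np.random.default_rng(seed)
    T, R = spec.n_tissues, spec.n_replicates
    tissues = [f"tissue{t:02d}" for t in range(T)]
    arrays = [f"{t}_r{r + 1}" for t in tissues for r in range(R)]
    replicate_map = {f"{t}_r{r + 1}": t for t in tissues for r in range(R)}
    z = rng.standard_normal(T)

    def block(n: int, load: float) -> np.ndarray:
        eps = rng.standard_normal((n, T))
        return load * z[None, :] + math.sqrt(max(0.0, 1 - load * load)) * eps

    profiles = np.vstack([
        block(spec.n_histone_probes, math.sqrt(spec.rho_histone)),
        block(spec.n_predicted_probes, spec.rho_predicted),
        block(spec.n_background_probes, 0.0),
    ])
    n_probes = profiles.shape[0]
    probe_ids = (
        [f"hist{i:04d}" for i in range(spec.n_histone_probes)]
        + [f"pred{i:04d}" for i in range(spec.n_predicted_probes)]
        + [f"bg{i:05d}" for i in range(spec.n_background_probes)]
    )
    groups = pd.Series(
        ["histone"] * spec.n_histone_probes
        + ["predicted"] * spec.n_predicted_probes
        + ["background"] * spec.n_background_probes,
        index=probe_ids, name="group",
    )
    offsets = spec.noise_sd * rng.standard_normal(n_probes)
    log2 = np.empty((n_probes, T * R))
    for t in range(T):
        for r in range(R):
            rep_noise = spec.noise_sd * rng.standard_normal(n_probes)
            log2[:, t * R + r] = (spec.baseline_log2 + offsets
                                  + profiles[:, t] + rep_noise)
    values = pd.DataFrame(np.exp2(log2), index=probe_ids, columns=arrays)
    return values, groups, replicate_map


# ---------------------------------------------------------------------------
# writers (plain-text interchange)
# ---------------------------------------------------------------------------


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    """Write (id, sequence) pairs as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in records]
    seqio_write(recs, str(path), "fasta")


def write_truth_bed(truth: Sequence[PlantedSegment] | Sequence[MotifHit],
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in truth:
            if isinstance(rec, PlantedSegment):
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}"
                         f"\t0\t{rec.strand}\n")
            else:
                fh.write(f"{rec.seq_id}\t{rec.start}\t{rec.end}"
                         f"\t{rec.motif_id}\t{int(round(rec.score * 1000))}"
                         f"\t{rec.strand}\n")


def write_annotations(annotations: Sequence[GeneAnnotation],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttranscript_id\tchrom\ttx_start\ttx_end\ttss"
                 "\tstrand\n")
        for a in annotations:
            fh.write(f"{a.gene_id}\t{a.transcript_id}\t{a.chrom}"
                     f"\t{a.tx_start}\t{a.tx_end}\t{a.tss}\t{a.strand}\n")


def write_expression(values: pd.DataFrame, replicate_map: dict[str, str],
                     prefix: str | Path) -> tuple[Path, Path]:
    """Write the expression TSV and its replicate-map sidecar."""
    prefix = Path(prefix)
    expr_path = prefix.with_suffix(".expression.tsv")
    map_path = prefix.with_suffix(".replicates.tsv")
    values.to_csv(expr_path, sep="\t", index_label="probe_id")
    pd.Series(replicate_map, name="tissue").rename_axis("array_id") \
        .to_csv(map_path, sep="\t")
    return expr_path, map_path
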