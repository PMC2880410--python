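"""Genome-scale pipeline: anchor scan, classification, clustering, mapping.

The scan reproduces the anchored-funnel design: locate every anchor-motif
(CAAT-box) occurrence on a chromosome, extract the fixed [-425, +175]
window around each occurrence whose GC content clears the floor, scan
each window with the full PWM set, admit windows with at least three
resolved motifs, and classify the admitted grammar vectors with the
fitted network.  Chromosomes are processed one at a time so memory stays
bounded by a single chromosome plus its hit buffer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .bayesnet import CLASS_STATES, BNModel, predict_proba
from .features import (DEFAULT_BINS, DEFAULT_MAX_POSITIONS, MIN_MOTIFS,
                       FeatureVector, select_chain, vectorize)
from .pwm import (DEFAULT_DOWNSTREAM, DEFAULT_GC_MIN, DEFAULT_UPSTREAM, PWM,
                  GenomicSegment, MotifHit, ParameterError,
                  extract_anchor_segments, scan_sequence)

logger = logging.getLogger(__name__)

CATEGORY_TSS = "overlap_TSS"
CATEGORY_TRANSCRIPT = "within_transcript"
CATEGORY_INTERGENIC = "intergenic"


@dataclass(frozen=True)
class GeneAnnotation:
    """A transcript record: span, TSS and strand (0-based half-open)."""

    gene_id: str
    transcript_id: str
    chrom: str
    tx_start: int
    tx_end: int
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if not self.tx_start < self.tx_end:
            raise ParameterError("tx_start must be < tx_end")
        if not self.tx_start <= self.tss < self.tx_end:
            raise ParameterError("tss must lie inside the transcript span")


@dataclass
class GenomicPrediction:
    """A classified genome segment with its annotation category."""

    segment: GenomicSegment
    posterior: float
    call: str
    category: str | None = None
    mapped_gene: str | None = None
    distance_to_nearest_gene: int | None = None


@dataclass
class ScanConfig:
    """Tunable parameters of the genome scan."""

    upstream: int = DEFAULT_UPSTREAM
    downstream: int = DEFAULT_DOWNSTREAM
    gc_min: float = DEFAULT_GC_MIN
    min_motifs: int = MIN_MOTIFS
    n_positions: int = DEFAULT_MAX_POSITIONS
    spacer_bins: tuple[float, ...] = DEFAULT_BINS
    cut: float = 0.5
    anchor_both_strands: bool = True
    segment_both_strands: bool = True


def run_scan(
    genome: dict[str, str],
    pwms: Sequence[PWM],
    model: BNModel,
    config: ScanConfig | None = None,
) -> tuple[list[GenomicPrediction], dict[str, int]]:
    """Scan a genome and classify anchored segments.

    Returns the predictions for every admitted segment plus the stage
    counts of the funnel: anchor hits, GC-passing anchored segments,
    admitted (>= min_motifs) segments, and histone calls.
    """
    config = config or ScanConfig()
    anchors = [p for p in pwms if p.is_anchor]
    if len(anchors) != 1:
        raise ParameterError(
            f"exactly one PWM must be flagged anchor, found {len(anchors)}")
    anchor = anchors[0]
    unknown = set(p.motif_id for p in pwms) - set(model.motif_states)
    if unknown:
        raise ParameterError(
            f"PWM ids absent from the model's motif alphabet: {unknown}")
    counts = {"anchor_hits": 0, "anchored_segments": 0, "admitted": 0,
              "histone_calls": 0}
    predictions: list[GenomicPrediction] = []
    for chrom, seq in genome.items():
        anchor_hits = scan_sequence(anchor, seq, chrom,
                                    both_strands=config.anchor_both_strands)
        counts["anchor_hits"] += len(anchor_hits)
        segments = extract_anchor_segments(
            seq, anchor_hits, config.upstream, config.downstream,
            config.gc_min, chrom)
        counts["anchored_segments"] += len(segments)
        vectors: list[FeatureVector] = []
        admitted: list[GenomicSegment] = []
        for seg in segments:
            hits: list[MotifHit] = []
            for pwm in pwms:
                hits.extend(scan_sequence(
                    pwm, seg.sequence, chrom,
                    both_strands=config.segment_both_strands))
            chain = select_chain(hits, len(seg.sequence), config.n_positions)
            if len(chain) < config.min_motifs:
                continue
            vectors.append(vectorize(chain, config.spacer_bins,
                                     config.n_positions,
                                     seq_id=f"{chrom}:{seg.start}"))
            admitted.append(seg)
        counts["admitted"] += len(admitted)
        if admitted:
            post = predict_proba(model, vectors)
            for seg, p in zip(admitted, post):
                call = CLASS_STATES[0] if p > config.cut else CLASS_STATES[1]
                predictions.append(GenomicPrediction(seg, float(p), call))
            counts["histone_calls"] += int(
                sum(pr.call == CLASS_STATES[0]
                    for pr in predictions[-len(admitted):]))
        logger.info("%s: %d anchor hits -> %d segments -> %d admitted",
                    chrom, len(anchor_hits), len(segments), len(admitted))
    return predictions, counts


@dataclass(frozen=True)
class Cluster:
    """A maximal run of mutually overlapping histone-called segments."""

    chrom: str
    start: int
    end: int
    n_members: int


def cluster_predictions(
    preds: Sequence[GenomicPrediction],
    genome_size: int | None = None,
) -> tuple[list[Cluster], dict]:
    """Single-linkage merge of overlapping histone calls (strand-agnostic).

    Segments on the same chromosome overlapping by >= 1 nt join one
    cluster; the cluster span is the union.  Returns the clusters and a
    summary (cluster count, and bases-per-cluster when ``genome_size`` is
    given).
    """
    hist = sorted(
        (p for p in preds if p.call == CLASS_STATES[0]),
        key=lambda p: (p.segment.chrom, p.segment.start),
    )
    clusters: list[Cluster] = []
    cur = None
    for p in hist:
        s = p.segment
        if cur is not None and s.chrom == cur[0] and s.start < cur[2]:
            cur = (cur[0], cur[1], max(cur[2], s.end), cur[3] + 1)
        else:
            if cur is not None:
                clusters.append(Cluster(*cur))
            cur = (s.chrom, s.start, s.end, 1)
    if cur is not None:
        clusters.append(Cluster(*cur))
    summary = {"n_histone": len(hist), "n_clusters": len(clusters)}
    if genome_size and clusters:
        summary["bases_per_cluster"] = genome_size / len(clusters)
    return clusters, summary


def map_predictions(
    preds: Sequence[GenomicPrediction],
    annotations: Sequence[GeneAnnotation],
) -> tuple[list[GenomicPrediction], dict[str, dict[str, int]]]:
    """Assign an annotation category to each histone-called prediction.

    Precedence: overlap_TSS (segment contains a TSS on the same strand)
    over within_transcript (segment intersects a transcript span, any
    strand) over intergenic.  Intergenic predictions carry the distance
    to the nearest transcript edge on their chromosome (0 if touching,
    None if the chromosome is gene-free).  Also returns per-gene
    prediction counts for each category and for all categories together.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for a in annotations:
        by_chrom.setdefault(a.chrom, []).append(a)
    known_chroms = {p.segment.chrom for p in preds}
    for chrom in set(by_chrom) - known_chroms:
        logger.warning("annotation chromosome %s not in predictions; "
                       "kept for distance lookups", chrom)
    gene_counts: dict[str, dict[str, int]] = {
        CATEGORY_TSS: {}, CATEGORY_TRANSCRIPT: {}, CATEGORY_INTERGENIC: {},
        "all": {},
    }
    out: list[GenomicPrediction] = []
    for p in preds:
        if p.call != CLASS_STATES[0]:
            out.append(p)
            continue
        seg = p.segment
        genes = by_chrom.get(seg.chrom, [])
        tss_gene = next(
            (a for a in genes
             if seg.start <= a.tss < seg.end and a.strand == seg.strand),
            None)
        if tss_gene is not None:
            p.category, p.mapped_gene = CATEGORY_TSS, tss_gene.gene_id
            p.distance_to_nearest_gene = 0
        else:
            tx_gene = next(
                (a for a in genes
                 if seg.start < a.tx_end and a.tx_start < seg.end), None)
            if tx_gene is not None:
                p.category, p.mapped_gene = (CATEGORY_TRANSCRIPT,
                                             tx_gene.gene_id)
                p.distance_to_nearest_gene = 0
            else:
                p.category = CATEGORY_INTERGENIC
                if genes:
                    dists = [
                        (max(a.tx_start - seg.end,
                             seg.start - a.tx_end, 0), a.gene_id)
                        for a in genes
                    ]
                    d, gid = min(dists)
                    p.mapped_gene = gid
                    p.distance_to_nearest_gene = int(d)
                else:
                    p.mapped_gene = None
                    p.distance_to_nearest_gene = None
        if p.mapped_gene is not None:
            gene_counts[p.category][p.mapped_gene] = \
                gene_counts[p.category].get(p.mapped_gene, 0) + 1
            gene_counts["all"][p.mapped_gene] = \
                gene_counts["all"].get(p.mapped_gene, 0) + 1
        out.append(p)
    return out, gene_counts


# ---------------------------------------------------------------------------
# io
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA file into a chrom -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read the TSV annotation dialect (gene_id .. strand header)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        GeneAnnotation(r.gene_id, r.transcript_id, r.chrom,
                       int(r.tx_start), int(r.tx_end), int(r.tss), r.strand)
        for r in df.itertuples()
    ]


def write_predictions(preds: Sequence[GenomicPrediction],
                      prefix: str | Path) -> tuple[Path, Path]:
    """Write predictions as BED6 plus a detail TSV."""
    prefix = Path(prefix)
    bed = prefix.with_suffix(".bed")
    tsv = prefix.with_suffix(".tsv")
    with open(bed, "w") as fh:
        for p in preds:
            s = p.segment
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{p.call}\t"
                     f"{int(round(p.posterior * 1000))}\t{s.strand}\n")
    with open(tsv, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tposterior\tcall\tcategory"
                 "\tmapped_gene\tdistance\n")
        for p in preds:
            s = p.segment
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.strand}"
                f"\t{p.posterior:.6f}\t{p.call}"
                f"\t{p.category or 'NA'}\t{p.mapped_gene or 'NA'}"
                f"\t{'NA' if p.distance_to_nearest_gene is None else p.distance_to_nearest_gene}\n")
    return bed, tsv


def write_run_report(counts: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(counts, indent=2))
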