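"""Flatten a gene's reference transcripts into one numbered exon model.

The flattened model merges every overlapping reference exon into a single
numbered "known exon" (transcription order, exon 1 = 5'-most) while keeping
each distinct annotated (start, end) pair as a *variant* of that exon, and
catalogs the gene's known donors, acceptors, junctions, transcription starts
and ends. It is the coordinate frame every event call is made against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotation_io import (
    AnnotationError,
    GenomicInterval,
    TranscriptModel,
    write_gtf,
)

log = logging.getLogger(__name__)


@dataclass
class FlatExon:
    """One merged reference exon.

    ``index`` counts in transcription order starting at 1. ``variants`` are
    the distinct annotated (start, end) pairs merged into this exon; the
    interval is their union. ``is_ever_first``/``is_ever_last`` record
    whether any reference transcript starts/ends (in transcription order)
    with an exon merged here.
    """

    index: int
    interval: GenomicInterval
    variants: list[tuple[int, int]]
    is_ever_first: bool
    is_ever_last: bool

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("FlatExon needs at least one variant")
        lo = min(s for s, _ in self.variants)
        hi = max(e for _, e in self.variants)
        if (lo, hi) != (self.interval.start, self.interval.end):
            raise ValueError("FlatExon interval must span its variants")


@dataclass
class FlattenedGeneModel:
    gene_id: str
    chrom: str
    strand: str
    flat_exons: list[FlatExon]
    known_donors: set[int] = field(default_factory=set)
    known_acceptors: set[int] = field(default_factory=set)
    known_junctions: set[tuple[int, int]] = field(default_factory=set)
    known_tss: set[int] = field(default_factory=set)
    known_tts: set[int] = field(default_factory=set)

    @property
    def span(self) -> tuple[int, int]:
        ivs = [fe.interval for fe in self.flat_exons]
        return min(i.start for i in ivs), max(i.end for i in ivs)

    def exons_genomic_order(self) -> list[FlatExon]:
        return sorted(self.flat_exons, key=lambda fe: fe.interval.start)

    def by_index(self, index: int) -> FlatExon:
        return self.flat_exons[index - 1]

    def classify_position(self, pos: int) -> tuple[str, int | None]:
        """Locate a genomic position relative to the flattened model.

        Returns one of ``("exon", k)``, ``("intron", k)`` for the intron
        between exon k and k+1 (transcription order), ``("upstream", None)``
        or ``("downstream", None)`` — up/downstream in transcription
        orientation.
        """
        lo, hi = self.span
        if pos < lo:
            return ("upstream" if self.strand == "+" else "downstream", None)
        if pos >= hi:
            return ("downstream" if self.strand == "+" else "upstream", None)
        genomic = self.exons_genomic_order()
        for fe in genomic:
            if fe.interval.start <= pos < fe.interval.end:
                return ("exon", fe.index)
        # between two flat exons: name the intron by its transcription-5' exon
        for a, b in zip(genomic, genomic[1:]):
            if a.interval.end <= pos < b.interval.start:
                k = a.index if self.strand == "+" else b.index
                return ("intron", k)
        raise AssertionError("unreachable: position inside span but unplaced")


def merge_intervals(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping (start, end) half-open pairs (touching ones stay apart)."""
    ordered = sorted(set(pairs))
    merged: list[list[int]] = []
    for s, e in ordered:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def flatten_gene(transcripts: Sequence[TranscriptModel]) -> FlattenedGeneModel:
    """Build the flattened model for one gene's reference transcripts."""
    if not transcripts:
        raise AnnotationError("cannot flatten a gene with no transcripts")
    gene_id = transcripts[0].gene_id
    strands = {t.strand for t in transcripts}
    chroms = {t.chrom for t in transcripts}
    if len(strands) > 1 or len(chroms) > 1:
        raise AnnotationError(f"gene {gene_id}: transcripts on mixed strands/chroms")
    strand, chrom = strands.pop(), chroms.pop()

    all_pairs = [(e.start, e.end) for t in transcripts for e in t.exons]
    merged = merge_intervals(all_pairs)

    # disjoint loci under one gene_id are flattened jointly but flagged
    if len(transcripts) > 1:
        spans = sorted((t.span.start, t.span.end) for t in transcripts)
        if any(b[0] >= a[1] for a, b in zip(spans, spans[1:])):
            log.warning("gene %s: transcripts occupy disjoint loci; flattening jointly", gene_id)

    firsts = {(t.exons_tx_order()[0].start, t.exons_tx_order()[0].end) for t in transcripts}
    lasts = {(t.exons_tx_order()[-1].start, t.exons_tx_order()[-1].end) for t in transcripts}

    n = len(merged)
    flat: list[FlatExon] = []
    for gi, (s, e) in enumerate(merged):
        variants = sorted({p for p in set(all_pairs) if p[0] < e and s < p[1]})
        index = gi + 1 if strand == "+" else n - gi
        flat.append(
            FlatExon(
                index=index,
                interval=GenomicInterval(chrom, s, e, strand),
                variants=variants,
                is_ever_first=any(v in firsts for v in variants),
                is_ever_last=any(v in lasts for v in variants),
            )
        )
    flat.sort(key=lambda fe: fe.index)

    model = FlattenedGeneModel(gene_id=gene_id, chrom=chrom, strand=strand, flat_exons=flat)
    for t in transcripts:
        model.known_tss.add(t.tss)
        model.known_tts.add(t.tts)
        for up, down in zip(t.exons, t.exons[1:]):
            if strand == "+":
                donor, acceptor = up.end, down.start
            else:
                donor, acceptor = down.start, up.end
            model.known_donors.add(donor)
            model.known_acceptors.add(acceptor)
            model.known_junctions.add((donor, acceptor))
    return model


def flattened_to_transcript(model: FlattenedGeneModel) -> TranscriptModel:
    """One synthetic transcript holding all flat exons (for GTF export)."""
    return TranscriptModel(
        transcript_id=f"{model.gene_id}.flattened",
        gene_id=model.gene_id,
        exons=[fe.interval for fe in model.flat_exons],
        source="reference",
    )


def write_flattened_gtf(models: Iterable[FlattenedGeneModel], path: str | Path) -> None:
    write_gtf([flattened_to_transcript(m) for m in models], path)


def flattened_table(models: Iterable[FlattenedGeneModel]) -> pd.DataFrame:
    rows = []
    for m in models:
        for fe in m.flat_exons:
            rows.append(
                {
                    "gene": m.gene_id,
                    "exon_index": fe.index,
                    "chrom": fe.interval.chrom,
                    "start": fe.interval.start,
                    "end": fe.interval.end,
                    "n_variants": len(fe.variants),
                    "ever_first": fe.is_ever_first,
                    "ever_last": fe.is_ever_last,
                }
            )
    return pd.DataFrame(rows)
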