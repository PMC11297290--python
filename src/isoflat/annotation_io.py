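"""Readers and writers for the formats the tool touches, plus shared configuration.

All coordinates are held internally as 0-based half-open intervals; GTF is
read and written in its native 1-based inclusive convention and BED in its
native 0-based half-open convention, so interval arithmetic inside the
package never carries an off-by-one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TranscriptModel:
    """One transcript: ordered exon intervals plus its gene assignment.

    Exons are stored in genomic order (ascending start) regardless of strand;
    transcription order is derived from the strand when needed.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    source: str = "reference"  # {"reference", "long_read"}

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"transcript {self.transcript_id} mixes chromosomes/strands: "
                f"{sorted(chroms)} {sorted(strands)}"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id} has overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def exons_tx_order(self) -> list[GenomicInterval]:
        """Exons in transcription order (5' -> 3')."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    @property
    def tss(self) -> int:
        """Transcription start coordinate (0-based)."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end - 1

    @property
    def tts(self) -> int:
        """Transcription termination coordinate (0-based)."""
        return self.exons[-1].end - 1 if self.strand == "+" else self.exons[0].start

    def junctions(self) -> list[tuple[int, int]]:
        """Ordered (donor, acceptor) pairs in transcription order.

        On '+' the donor of an intron is the end coordinate of the upstream
        exon (half-open, i.e. the first intronic base) and the acceptor is the
        start of the downstream exon. On '-' the roles mirror.
        """
        pairs = []
        for up, down in zip(self.exons, self.exons[1:]):
            pairs.append((up.end, down.start))
        if self.strand == "+":
            return pairs
        return [(a, d) for (d, a) in reversed(pairs)]


@dataclass
class ReferenceAnnotation:
    """Reference transcripts grouped by gene."""

    genes: dict[str, list[TranscriptModel]]
    gene_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid, txs in self.genes.items():
            strands = {t.strand for t in txs}
            chroms = {t.chrom for t in txs}
            if len(strands) > 1 or len(chroms) > 1:
                raise AnnotationError(
                    f"gene {gid} has transcripts on mixed strands/chromosomes"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def transcripts(self) -> Iterable[TranscriptModel]:
        for txs in self.genes.values():
            yield from txs


@dataclass
class Config:
    """Tunable thresholds, defaulting to the published values where they exist.

    splice_tolerance_bp : offsets up to this many bp from a known splice site
        are treated as matching it; strictly larger offsets are called as
        alternative 5'/3' splice sites.
    tss_tts_window_bp : distance window for calling a transcription start/end
        "known" (also the proximity window for TSS-evidence peaks).
    rare_min_reads / rare_n_samples : a transcript is retained when its
        rare_n_samples highest per-sample full-length read counts sum to at
        least rare_min_reads (see quantify.filter_rare for the alternative
        per-sample semantics).
    major_fraction : an isoform is "major" when its usage relative to the
        dominant isoform exceeds this fraction (strict).
    minor_filter_fc : pre-DTU minor-isoform filter threshold (strict).
    nmd_distance_nt : a stop codon more than this many nt upstream of the
        last exon-exon junction marks a decay (NMD) candidate.
    coding_score_threshold : external coding-potential scores above this are
        taken as coding when such a score table is supplied.
    """

    splice_tolerance_bp: int = 10
    tss_tts_window_bp: int = 50
    rare_min_reads: int = 10
    rare_n_samples: int = 5
    major_fraction: float = 0.5
    minor_filter_fc: float = 0.5
    nmd_distance_nt: int = 50
    coding_score_threshold: float = 0.44
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "splice_tolerance_bp",
            "tss_tts_window_bp",
            "rare_min_reads",
            "rare_n_samples",
            "minor_filter_fc",
            "nmd_distance_nt",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.major_fraction <= 1):
            raise ValueError("major_fraction must be in (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Load a flat key=value config file; unknown keys are rejected."""
        cfg = cls()
        valid = set(cfg.__dataclass_fields__)
        overrides: dict[str, object] = {}
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected key=value, got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in valid:
                raise ValueError(f"{path}:{ln}: unknown config key {key!r}")
            typ = type(getattr(cfg, key))
            overrides[key] = typ(val)
        return replace(cfg, **overrides)


# GTF2 `key "value";` or GFF3 `key=value` attributes
_ATTR_RE = re.compile(r'(\w+)[ =]+"?([^";]+)"?;?')

_STRAND_ALIASES = {"+": "+", "-": "-", "−": "-"}


def _parse_attributes(field9: str) -> dict[str, str]:
    return {m.group(1): m.group(2).strip() for m in _ATTR_RE.finditer(field9)}


def read_gtf(
    path: str | Path, source: str = "reference"
) -> ReferenceAnnotation | list[TranscriptModel]:
    """Read exon features from a GTF/GFF file.

    Returns a :class:`ReferenceAnnotation` when ``source == "reference"``,
    otherwise a flat list of long-read :class:`TranscriptModel` (gene
    assignment taken from the ``gene_id`` attribute as written by the
    upstream collapse/annotation step, never re-derived by overlap).
    """
    if source not in ("reference", "long_read"):
        raise ValueError(f"source must be 'reference' or 'long_read', got {source!r}")
    by_tx: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    gene_names: dict[str, str] = {}
    tx_order: list[str] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(
                    f"{path}:{ln}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start), int(end)
            except ValueError:
                raise AnnotationError(
                    f"{path}:{ln}: non-integer coordinates {start!r}/{end!r}"
                ) from None
            if strand not in _STRAND_ALIASES:
                raise AnnotationError(f"{path}:{ln}: bad strand {strand!r}")
            attr = _parse_attributes(attrs)
            if "transcript_id" not in attr or "gene_id" not in attr:
                raise AnnotationError(
                    f"{path}:{ln}: exon lacks transcript_id/gene_id attributes"
                )
            tid, gid = attr["transcript_id"], attr["gene_id"]
            if tid not in by_tx:
                by_tx[tid] = []
                tx_order.append(tid)
                tx_gene[tid] = gid
            elif tx_gene[tid] != gid:
                raise AnnotationError(
                    f"{path}:{ln}: transcript {tid} assigned to both "
                    f"{tx_gene[tid]} and {gid}"
                )
            by_tx[tid].append(
                GenomicInterval(chrom, start1 - 1, end1, _STRAND_ALIASES[strand])
            )
            if "gene_name" in attr:
                gene_names.setdefault(gid, attr["gene_name"])
    transcripts = [
        TranscriptModel(tid, tx_gene[tid], by_tx[tid], source=source)
        for tid in tx_order
    ]
    if source == "long_read":
        return transcripts
    genes: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        genes.setdefault(tx.gene_id, []).append(tx)
    return ReferenceAnnotation(genes=genes, gene_names=gene_names)


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GTF exon features (1-based inclusive on disk)."""
    with open(path, "w") as out:
        for tx in transcripts:
            for ex in tx.exons:
                attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                out.write(
                    f"{ex.chrom}\tisoflat\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\t{attrs}\n"
                )


def write_bed12(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write one BED12 line per transcript (genome-browser track)."""
    with open(path, "w") as out:
        for tx in transcripts:
            chrom_start = tx.exons[0].start
            chrom_end = tx.exons[-1].end
            sizes = ",".join(str(len(e)) for e in tx.exons)
            starts = ",".join(str(e.start - chrom_start) for e in tx.exons)
            out.write(
                f"{tx.chrom}\t{chrom_start}\t{chrom_end}\t{tx.transcript_id}\t0\t"
                f"{tx.strand}\t{chrom_start}\t{chrom_end}\t0\t{len(tx.exons)}\t"
                f"{sizes},\t{starts},\n"
            )


def read_bed12(path: str | Path, gene_ids: Mapping[str, str] | None = None) -> list[TranscriptModel]:
    """Read BED12 transcript models (inverse of :func:`write_bed12`)."""
    out = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) < 12:
                raise AnnotationError(f"{path}:{ln}: expected 12 BED fields")
            chrom, cstart, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                GenomicInterval(chrom, cstart + s, cstart + s + size, strand)
                for s, size in zip(starts, sizes)
            ]
            gid = gene_ids.get(name, name) if gene_ids else name
            out.append(TranscriptModel(name, gid, exons, source="long_read"))
    return out


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read an isoform x sample full-length read-count table.

    Delimiter is auto-detected from the extension (.csv -> comma, else tab).
    Counts must be non-negative integers and isoform ids unique.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise AnnotationError(f"duplicate isoform ids in {path}: {dups}")
    if df.isna().any().any():
        r, c = next(zip(*df.isna().to_numpy().nonzero()))
        raise AnnotationError(
            f"missing count at ({df.index[r]}, {df.columns[c]}) in {path}"
        )
    for col in df.columns:
        bad = ~df[col].apply(lambda v: float(v) == int(v) and v >= 0)
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise AnnotationError(
                f"negative or non-integer count at ({row}, {col}) in {path}"
            )
    return df.astype(int)


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, index_label="isoform")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sample metadata table (columns: sample, group[, age])."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns or "group" not in df.columns:
        raise AnnotationError(f"{path}: needs 'sample' and 'group' columns")
    return df.set_index("sample")


def read_junction_table(path: str | Path) -> pd.DataFrame:
    """Read a splice-junction support table (STAR SJ.out.tab layout).

    Columns used: chrom, intron start (1-based), intron end (inclusive),
    strand code (0 undefined, 1 '+', 2 '-') and uniquely-mapped read count.
    Returned with 0-based half-open intron coordinates.
    """
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] < 7:
        raise AnnotationError(f"{path}: expected >= 7 columns (SJ.out.tab layout)")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": df[1].astype(int) - 1,
            "end": df[2].astype(int),
            "strand": df[3].map({0: ".", 1: "+", 2: "-"}),
            "unique_reads": df[6].astype(int),
        }
    )
    return out


def read_tss_peaks(path: str | Path) -> pd.DataFrame:
    """Read TSS-evidence peaks (BED, first 3-6 columns used)."""
    rows = []
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            f = raw.rstrip("\n").split("\t")
            rows.append(
                {
                    "chrom": f[0],
                    "start": int(f[1]),
                    "end": int(f[2]),
                    "strand": f[5] if len(f) > 5 else ".",
                }
            )
    return pd.DataFrame(rows)


def read_coding_scores(path: str | Path) -> pd.Series:
    """Read an external coding-potential score table (transcript_id, score)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise AnnotationError(f"{path}: expected transcript_id and score columns")
    return df.set_index(df.columns[0])[df.columns[1]].astype(float)
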