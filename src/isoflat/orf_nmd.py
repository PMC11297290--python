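"""ORF prediction, NMD flagging, cryptic-exon frame effects, protein collapsing.

The open reading frame is the longest ATG-initiated frame ending at an
in-frame stop (5'-most on ties); a transcript whose stop codon lies more
than 50 nt (configurable) upstream of its last exon-exon junction is
flagged as a nonsense-mediated decay (NMD) candidate, following the
canonical 50-nt rule. Transcripts predicted to produce an identical
protein are collapsed into one group represented by the most abundant
member. When an external coding-potential score table is available,
coding status follows the score threshold instead of ORF presence.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import pandas as pd

from .annotation_io import Config, TranscriptModel

_CODON = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _a in enumerate(_AA):
    _CODON["".join((_BASES[_i // 16], _BASES[_i // 4 % 4], _BASES[_i % 4]))] = _a

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate(seq: str) -> str:
    """Translate nucleotides to amino acids ('*' = stop, 'X' = ambiguous)."""
    return "".join(
        _CODON.get(seq[i : i + 3].upper(), "X") for i in range(0, len(seq) - 2, 3)
    )


def spliced_sequence(isoform: TranscriptModel, genome) -> str:
    """mRNA sequence: exon sequences joined in transcription order.

    ``genome`` is any mapping of chromosome name to an indexable sequence
    (a dict of strings or a pyfaidx.Fasta). '-'-strand transcripts are
    reverse-complemented.
    """
    if isoform.chrom not in genome:
        raise KeyError(f"chromosome {isoform.chrom} absent from genome")
    chrom_seq = genome[isoform.chrom]
    parts = []
    for ex in isoform.exons:
        if ex.end > len(chrom_seq):
            raise ValueError(
                f"exon {ex.start}-{ex.end} out of bounds on {isoform.chrom}"
            )
        parts.append(str(chrom_seq[ex.start : ex.end]))
    seq = "".join(parts)
    return reverse_complement(seq) if isoform.strand == "-" else seq.upper()


@dataclass
class ORFRecord:
    transcript_id: str
    orf_start: int  # transcript coordinate, 0-based
    orf_end: int  # exclusive; includes the stop codon when has_stop
    protein: str
    has_stop: bool
    ptc_to_last_junction_nt: int | None = None  # junction - stop end (signed)
    nmd_candidate: bool = False
    mono_exonic: bool = False
    coding_call: str = "noncoding"  # coding | noncoding | external_score

    @property
    def length_nt(self) -> int:
        return self.orf_end - self.orf_start


def find_orf(mrna: str, transcript_id: str = "") -> ORFRecord | None:
    """Longest ATG-initiated ORF; ties resolve to the 5'-most start.

    An ORF runs from ATG to the first in-frame stop (stop included in its
    length); with no in-frame stop it runs to the sequence end and is
    marked ``has_stop=False``. Returns None when the sequence holds no ATG.
    """
    seq = mrna.upper()
    n = len(seq)
    stops_by_frame: dict[int, list[int]] = {0: [], 1: [], 2: []}
    starts = []
    for i in range(n - 2):
        codon = seq[i : i + 3]
        if codon == "ATG":
            starts.append(i)
        elif codon in ("TAA", "TAG", "TGA"):
            stops_by_frame[i % 3].append(i)
    if not starts:
        return None
    best: tuple[int, int, int, bool] | None = None  # (-length, start, end, has_stop)
    for s in starts:
        frame_stops = stops_by_frame[s % 3]
        j = bisect_left(frame_stops, s)
        if j < len(frame_stops):
            end, has_stop = frame_stops[j] + 3, True
        else:
            end, has_stop = s + ((n - s) // 3) * 3, False
        cand = (-(end - s), s, end, has_stop)
        if best is None or cand < best:
            best = cand
    _, s, end, has_stop = best
    protein = translate(seq[s : end - 3] if has_stop else seq[s:end])
    return ORFRecord(
        transcript_id=transcript_id,
        orf_start=s,
        orf_end=end,
        protein=protein,
        has_stop=has_stop,
        coding_call="coding" if has_stop else "noncoding",
    )


def last_junction_position(exon_lengths: list[int]) -> int | None:
    """Transcript coordinate of the last exon-exon junction (None if
    mono-exonic). Lengths must be given in transcription order."""
    if len(exon_lengths) < 2:
        return None
    return sum(exon_lengths[:-1])


def predict_nmd(
    orf: ORFRecord, exon_lengths: list[int], cfg: Config | None = None
) -> ORFRecord:
    """Flag an NMD candidate: stop codon > ``nmd_distance_nt`` upstream of
    the last exon-exon junction. Mono-exonic transcripts are never NMD."""
    cfg = cfg or Config()
    junction = last_junction_position(exon_lengths)
    if junction is None:
        orf.mono_exonic = True
        orf.nmd_candidate = False
        return orf
    if not orf.has_stop:
        orf.nmd_candidate = False
        return orf
    orf.ptc_to_last_junction_nt = junction - orf.orf_end
    orf.nmd_candidate = orf.ptc_to_last_junction_nt > cfg.nmd_distance_nt
    return orf


def genomic_to_transcript(
    isoform: TranscriptModel, interval: tuple[int, int]
) -> tuple[int, int]:
    """Map a genomic interval lying inside the exon chain to transcript
    coordinates (transcription orientation)."""
    s, e = interval
    offset = 0
    for ex in isoform.exons_tx_order():
        if ex.start <= s and e <= ex.end:
            if isoform.strand == "+":
                return offset + (s - ex.start), offset + (e - ex.start)
            return offset + (ex.end - e), offset + (ex.end - s)
        offset += len(ex)
    raise ValueError(f"interval {interval} not contained in one exon")


def cryptic_exon_frame(
    mrna: str, orf: ORFRecord, ce_tx: tuple[int, int]
) -> str:
    """Frame effect of a cryptic exon given in transcript coordinates.

    Returns ``in_frame_no_stop``, ``in_frame_with_stop``, ``frameshift`` or
    ``UTR`` (cryptic exon entirely outside the translated region).
    """
    s, e = ce_tx
    if orf is None or e <= orf.orf_start or s >= orf.orf_end:
        return "UTR"
    if (e - s) % 3 != 0:
        return "frameshift"
    # translate in ORF frame across the cryptic exon and look for a stop
    first_codon = (max(s, orf.orf_start) - orf.orf_start) // 3
    last_codon = (min(e, len(mrna)) - 1 - orf.orf_start) // 3
    region = mrna[orf.orf_start + first_codon * 3 : orf.orf_start + (last_codon + 1) * 3]
    if "*" in translate(region):
        return "in_frame_with_stop"
    return "in_frame_no_stop"


@dataclass
class ProteinGroup:
    protein: str
    members: list[str]
    representative: str
    total_reads: float = 0.0


@dataclass
class CollapseResult:
    groups: list[ProteinGroup]
    n_coding: int
    n_unique_proteins: int
    n_no_stop: int
    redundant_by_category: dict[str, int] = field(default_factory=dict)

    @property
    def n_redundant(self) -> int:
        return self.n_coding - self.n_unique_proteins

    def pct_redundant_in(self, category: str) -> float:
        n = self.redundant_by_category.get(category, 0)
        return round(100.0 * n / self.n_redundant, 1) if self.n_redundant else 0.0


def collapse_proteins(
    orfs: list[ORFRecord],
    abundance: pd.Series | dict | None = None,
    categories: dict[str, str] | None = None,
) -> CollapseResult:
    """Collapse coding transcripts with identical proteins into groups.

    The representative is the most abundant member (ties -> id order).
    Transcripts without a stop codon are excluded from collapsing and
    reported separately. ``categories`` (transcript -> structural category)
    feeds the redundant-by-category accounting: a redundant transcript is a
    non-representative member of a multi-transcript group.
    """
    abundance = {} if abundance is None else dict(abundance)
    coding = [o for o in orfs if o.coding_call in ("coding", "external_score") and o.has_stop]
    n_no_stop = sum(1 for o in orfs if not o.has_stop)
    by_protein: dict[str, list[ORFRecord]] = {}
    for o in coding:
        by_protein.setdefault(o.protein, []).append(o)
    groups = []
    redundant_ids: list[str] = []
    for protein in sorted(by_protein):
        members = sorted(by_protein[protein], key=lambda o: o.transcript_id)
        # most abundant member; ties -> id order
        rep = sorted(
            members,
            key=lambda o: (-float(abundance.get(o.transcript_id, 0.0)), o.transcript_id),
        )[0]
        member_ids = [o.transcript_id for o in members]
        redundant_ids.extend(i for i in member_ids if i != rep.transcript_id)
        groups.append(
            ProteinGroup(
                protein=protein,
                members=member_ids,
                representative=rep.transcript_id,
                total_reads=float(sum(abundance.get(i, 0.0) for i in member_ids)),
            )
        )
    by_cat: dict[str, int] = {}
    if categories:
        for tid in redundant_ids:
            cat = categories.get(tid, "unknown")
            by_cat[cat] = by_cat.get(cat, 0) + 1
    return CollapseResult(
        groups=groups,
        n_coding=len(coding),
        n_unique_proteins=len(groups),
        n_no_stop=n_no_stop,
        redundant_by_category=by_cat,
    )


def apply_external_scores(
    orfs: list[ORFRecord], scores: pd.Series, cfg: Config | None = None
) -> list[ORFRecord]:
    """Override coding calls with an external coding-potential score table:
    coding iff score > threshold (default 0.44)."""
    cfg = cfg or Config()
    for o in orfs:
        if o.transcript_id in scores.index:
            coding = scores[o.transcript_id] > cfg.coding_score_threshold
            o.coding_call = "external_score" if coding else "noncoding"
    return orfs


def write_protein_fasta(result: CollapseResult, path, width: int = 60) -> None:
    """Representative protein sequences; headers carry the member count."""
    with open(path, "w") as out:
        for g in result.groups:
            out.write(f">{g.representative} members={len(g.members)}\n")
            for i in range(0, len(g.protein), width):
                out.write(g.protein[i : i + width] + "\n")


def collapse_table(result: CollapseResult) -> pd.DataFrame:
    rows = [
        {
            "representative": g.representative,
            "n_members": len(g.members),
            "members": ";".join(g.members),
            "total_reads": g.total_reads,
            "protein_length": len(g.protein),
        }
        for g in result.groups
    ]
    return pd.DataFrame(rows)
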