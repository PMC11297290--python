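"""Alternative-splicing event calling against the flattened gene model.

Each long-read isoform is matched exon-by-exon to its gene's flattened
reference model; from the matches we call alternative first/last exon use
(AF/AL), alternative promoter/terminator (AP/AT), alternative 5'/3' splice
sites (A5/A3, ">10 bp" tolerance rule), exon skipping (ES), intron
retention (IR, an isoform exon spanning >=2 known exons), cryptic exons
(CE, wholly intronic) and novel exons outside the gene span (NE). Isoforms
are independently assigned the standard structural categories (FSM/ISM/
NIC/NNC) by exact junction-chain comparison. Events are always computed
against the flattened model, independent of category, so known isoforms can
still carry ES/IR annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .annotation_io import AnnotationError, Config, TranscriptModel
from .gene_model import FlatExon, FlattenedGeneModel

# exon-presence matrix codes
ABSENT, PRESENT, SKIPPED, IR_SPANNED = 0, 1, 2, 3


@dataclass
class ExonMatch:
    """How one isoform exon relates to the flattened model.

    ``isoform_exon_index`` is 1-based in transcription order.
    ``matched_flat_exons`` holds the transcription-order indices of every
    flat exon the isoform exon overlaps (empty for cryptic/novel exons).
    ``boundary_offsets`` is (5'-edge, 3'-edge) distance in nt to the nearest
    same-side variant boundary of the principal matched exon (None when no
    flat exon is matched).
    """

    isoform_exon_index: int
    matched_flat_exons: list[int]
    match_class: str  # exact | tolerant | alt_boundary | spanning | cryptic | novel_upstream | novel_downstream
    boundary_offsets: tuple[int, int] | None = None
    principal: int | None = None


@dataclass
class ASEventSet:
    isoform_id: str
    af: bool = False
    af_first_exon: int | None = None
    al: bool = False
    al_last_exon: int | None = None
    ap: bool = False
    at: bool = False
    a5: list[tuple[int, int]] = field(default_factory=list)  # (flat exon, offset nt)
    a3: list[tuple[int, int]] = field(default_factory=list)
    es: list[int] = field(default_factory=list)  # skipped flat exon indices
    ir: list[tuple[int, int, int]] = field(default_factory=list)  # (first, last, n spanned)
    ce: list[tuple[int, tuple[int, int]]] = field(default_factory=list)  # (intron idx, interval)
    ne: list[tuple[str, tuple[int, int]]] = field(default_factory=list)  # (side, interval)

    def event_counts(self) -> dict[str, int]:
        return {
            "A5": len(self.a5),
            "A3": len(self.a3),
            "A5A3": len(self.a5) + len(self.a3),
            "ES": len(self.es),
            "IR": len(self.ir),
            "CE": len(self.ce),
            "NE": len(self.ne),
        }


@dataclass
class StructuralCategory:
    category: str  # FSM | ISM | NIC | NNC
    matched_reference_transcript: str | None = None
    mono_exon: bool = False


def match_exons(
    isoform: TranscriptModel, model: FlattenedGeneModel, cfg: Config | None = None
) -> list[ExonMatch]:
    """Match each isoform exon to the flattened model (transcription order)."""
    cfg = cfg or Config()
    if isoform.chrom != model.chrom or isoform.strand != model.strand:
        raise AnnotationError(
            f"isoform {isoform.transcript_id} is on {isoform.chrom}{isoform.strand}, "
            f"gene {model.gene_id} on {model.chrom}{model.strand}"
        )
    tau = cfg.splice_tolerance_bp
    matches: list[ExonMatch] = []
    for i, ex in enumerate(isoform.exons_tx_order(), start=1):
        hits = [
            fe
            for fe in model.flat_exons
            if ex.start < fe.interval.end and fe.interval.start < ex.end
        ]
        if not hits:
            region, _k = model.classify_position(ex.start)
            cls = {
                "intron": "cryptic",
                "upstream": "novel_upstream",
                "downstream": "novel_downstream",
            }[region]
            matches.append(ExonMatch(i, [], cls))
            continue
        idxs = sorted(fe.index for fe in hits)
        if len(hits) > 1:
            # principal = largest overlap, ties toward the lower exon index
            principal = sorted(
                hits, key=lambda fe: (-ex.overlap_len(fe.interval), fe.index)
            )[0]
            matches.append(
                ExonMatch(i, idxs, "spanning", principal=principal.index)
            )
            continue
        fe = hits[0]
        start_off = min(abs(ex.start - s) for s, _ in fe.variants)
        end_off = min(abs(ex.end - e) for _, e in fe.variants)
        if model.strand == "+":
            offsets = (start_off, end_off)
        else:
            offsets = (end_off, start_off)
        if (ex.start, ex.end) in fe.variants:
            cls = "exact"
        elif start_off <= tau and end_off <= tau:
            cls = "tolerant"
        else:
            cls = "alt_boundary"
        matches.append(ExonMatch(i, idxs, cls, boundary_offsets=offsets, principal=fe.index))
    return matches


def _edge_coords(ex, strand: str) -> tuple[int, int]:
    """(acceptor-side coordinate, donor-side coordinate) of an exon."""
    return (ex.start, ex.end) if strand == "+" else (ex.end, ex.start)


def _variant_edges(fe: FlatExon, strand: str) -> tuple[list[int], list[int]]:
    """(acceptor-side, donor-side) variant boundary coordinates."""
    starts = [s for s, _ in fe.variants]
    ends = [e for _, e in fe.variants]
    return (starts, ends) if strand == "+" else (ends, starts)


def call_alt_splice_sites(
    isoform: TranscriptModel,
    matches: Sequence[ExonMatch],
    model: FlattenedGeneModel,
    cfg: Config | None = None,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Call A5 (alternative donor) and A3 (alternative acceptor) events.

    Only internal splice edges are eligible: an isoform's transcription-start
    edge belongs to AP and its end edge to AT. An edge is an event iff its
    distance to every same-side variant boundary of the principal matched
    exon *and* to every known donor/acceptor of the gene strictly exceeds
    the tolerance; the recorded offset is the distance to the nearest
    variant boundary.
    """
    cfg = cfg or Config()
    tau = cfg.splice_tolerance_bp
    exons = isoform.exons_tx_order()
    n = len(exons)
    a5: list[tuple[int, int]] = []
    a3: list[tuple[int, int]] = []
    for m, ex in zip(matches, exons):
        if len(m.matched_flat_exons) != 1:
            continue
        fe = model.by_index(m.matched_flat_exons[0])
        acc_coord, don_coord = _edge_coords(ex, model.strand)
        acc_vars, don_vars = _variant_edges(fe, model.strand)
        i = m.isoform_exon_index
        if i > 1:  # acceptor edge internal
            off = min(abs(acc_coord - v) for v in acc_vars)
            near_known = min(
                (abs(acc_coord - a) for a in model.known_acceptors), default=tau + 1
            )
            if off > tau and near_known > tau:
                a3.append((fe.index, off))
        if i < n:  # donor edge internal
            off = min(abs(don_coord - v) for v in don_vars)
            near_known = min(
                (abs(don_coord - d) for d in model.known_donors), default=tau + 1
            )
            if off > tau and near_known > tau:
                a5.append((fe.index, off))
    return a5, a3


def call_exon_skipping(
    matches: Sequence[ExonMatch], model: FlattenedGeneModel
) -> list[int]:
    """Flat exons strictly inside the isoform's matched span with no overlap.

    IR-spanned exons count as matched, so a retained intron never produces
    a skip call; exons outside the span belong to AF/AL, never ES.
    """
    matched: set[int] = set()
    for m in matches:
        matched.update(m.matched_flat_exons)
    if not matched:
        return []
    lo, hi = min(matched), max(matched)
    return [k for k in range(lo + 1, hi) if k not in matched]


def call_intron_retention(
    matches: Sequence[ExonMatch], model: FlattenedGeneModel
) -> list[tuple[int, int, int]]:
    """One IR event per isoform exon that spans >=2 flat exons."""
    out = []
    for m in matches:
        if m.match_class == "spanning":
            idxs = m.matched_flat_exons
            out.append((min(idxs), max(idxs), len(idxs)))
    return out


def call_novel_exons(
    isoform: TranscriptModel,
    matches: Sequence[ExonMatch],
    model: FlattenedGeneModel,
) -> tuple[list[tuple[int, tuple[int, int]]], list[tuple[str, tuple[int, int]]]]:
    """Cryptic (intronic) and novel (outside-span) exon calls."""
    exons = isoform.exons_tx_order()
    ce: list[tuple[int, tuple[int, int]]] = []
    ne: list[tuple[str, tuple[int, int]]] = []
    for m, ex in zip(matches, exons):
        if m.match_class == "cryptic":
            _, k = model.classify_position(ex.start)
            ce.append((k, (ex.start, ex.end)))
        elif m.match_class == "novel_upstream":
            ne.append(("upstream", (ex.start, ex.end)))
        elif m.match_class == "novel_downstream":
            ne.append(("downstream", (ex.start, ex.end)))
    return ce, ne


def call_first_last(
    isoform: TranscriptModel,
    matches: Sequence[ExonMatch],
    model: FlattenedGeneModel,
    cfg: Config | None = None,
) -> dict:
    """AF/AL (alternative first/last exon) and AP/AT (promoter/terminator)."""
    cfg = cfg or Config()
    w = cfg.tss_tts_window_bp
    first, last = matches[0], matches[-1]
    if first.matched_flat_exons:
        k = min(first.matched_flat_exons)  # transcription-5'-most
        af = not model.by_index(k).is_ever_first
        af_exon = k
    else:
        af, af_exon = True, None
    if last.matched_flat_exons:
        k = max(last.matched_flat_exons)
        al = not model.by_index(k).is_ever_last
        al_exon = k
    else:
        al, al_exon = True, None
    ap = all(abs(isoform.tss - t) > w for t in model.known_tss)
    at = all(abs(isoform.tts - t) > w for t in model.known_tts)
    return {
        "af": af,
        "af_first_exon": af_exon,
        "al": al,
        "al_last_exon": al_exon,
        "ap": ap,
        "at": at,
    }


def call_events(
    isoform: TranscriptModel, model: FlattenedGeneModel, cfg: Config | None = None
) -> ASEventSet:
    """Run every event caller on one isoform and bundle the results."""
    cfg = cfg or Config()
    matches = match_exons(isoform, model, cfg)
    a5, a3 = call_alt_splice_sites(isoform, matches, model, cfg)
    es = call_exon_skipping(matches, model)
    ir = call_intron_retention(matches, model)
    ce, ne = call_novel_exons(isoform, matches, model)
    fl = call_first_last(isoform, matches, model, cfg)
    return ASEventSet(
        isoform_id=isoform.transcript_id,
        af=fl["af"],
        af_first_exon=fl["af_first_exon"],
        al=fl["al"],
        al_last_exon=fl["al_last_exon"],
        ap=fl["ap"],
        at=fl["at"],
        a5=sorted(a5),
        a3=sorted(a3),
        es=sorted(es),
        ir=sorted(ir),
        ce=sorted(ce),
        ne=sorted(ne),
    )


def _contains_subchain(chain: tuple, sub: tuple) -> bool:
    if not sub or len(sub) > len(chain):
        return False
    return any(chain[i : i + len(sub)] == sub for i in range(len(chain) - len(sub) + 1))


def classify_structural_category(
    isoform: TranscriptModel,
    reference: Sequence[TranscriptModel],
    model: FlattenedGeneModel,
) -> StructuralCategory:
    """FSM / ISM / NIC / NNC by exact junction-chain comparison.

    FSM: junction chain equals a reference transcript's chain. ISM: a
    contiguous sub-chain of one. NIC: every splice site known but the
    combination novel. NNC: at least one novel splice site. Coordinates are
    compared exactly; the splice tolerance applies only to event labels.
    Mono-exonic isoforms are matched by containment and flagged.
    """
    chain = tuple(isoform.junctions())
    refs = sorted(reference, key=lambda t: t.transcript_id)
    if not chain:  # mono-exonic isoform
        ex = isoform.exons[0]
        for ref in refs:
            if len(ref.exons) == 1:
                r = ref.exons[0]
                if r.start <= ex.start and ex.end <= r.end:
                    return StructuralCategory("FSM", ref.transcript_id, mono_exon=True)
        for ref in refs:
            for r in ref.exons:
                if r.start <= ex.start and ex.end <= r.end:
                    return StructuralCategory("ISM", ref.transcript_id, mono_exon=True)
        return StructuralCategory("NIC", None, mono_exon=True)
    for ref in refs:
        if chain == tuple(ref.junctions()):
            return StructuralCategory("FSM", ref.transcript_id)
    for ref in refs:
        if _contains_subchain(tuple(ref.junctions()), chain):
            return StructuralCategory("ISM", ref.transcript_id)
    donors = {d for d, _ in chain}
    acceptors = {a for _, a in chain}
    if donors <= model.known_donors and acceptors <= model.known_acceptors:
        return StructuralCategory("NIC")
    return StructuralCategory("NNC")


@dataclass
class GeneSummary:
    gene_id: str
    n_isoforms: int
    n_known: int
    n_novel: int
    n_coding: int | None
    n_noncoding: int | None
    events: dict[str, tuple[int, int]]  # type -> (n isoforms with event, n events)
    skip_counts: dict[int, int]  # flat exon index -> n isoforms skipping it

    def pct_isoforms_with(self, event_type: str, decimals: int = 1) -> float:
        n_iso = self.events[event_type][0]
        return round(100.0 * n_iso / self.n_isoforms, decimals) if self.n_isoforms else 0.0


def summarize_gene(
    gene_id: str,
    events: Sequence[ASEventSet],
    categories: Sequence[StructuralCategory],
    model: FlattenedGeneModel,
    coding_flags: Sequence[bool] | None = None,
    known_categories: frozenset[str] = frozenset({"FSM"}),
) -> GeneSummary:
    """Per-gene accounting of isoforms, categories and event burdens.

    "Known" defaults to FSM only (the conservative reading); pass
    ``known_categories={"FSM", "ISM"}`` for the inclusive convention.
    A5 and A3 are pooled into one A5A3 column.
    """
    n = len(events)
    n_known = sum(1 for c in categories if c.category in known_categories)
    ev: dict[str, tuple[int, int]] = {}
    for etype in ("A5A3", "ES", "IR", "CE", "NE"):
        counts = [e.event_counts()[etype] for e in events]
        ev[etype] = (sum(1 for c in counts if c > 0), sum(counts))
    skip_counts = {fe.index: 0 for fe in model.flat_exons}
    for e in events:
        for k in e.es:
            skip_counts[k] += 1
    n_coding = n_noncoding = None
    if coding_flags is not None:
        n_coding = sum(bool(f) for f in coding_flags)
        n_noncoding = n - n_coding
    return GeneSummary(
        gene_id=gene_id,
        n_isoforms=n,
        n_known=n_known,
        n_novel=n - n_known,
        n_coding=n_coding,
        n_noncoding=n_noncoding,
        events=ev,
        skip_counts=skip_counts,
    )


def exon_state_row(events: ASEventSet, matches: Sequence[ExonMatch], model: FlattenedGeneModel) -> np.ndarray:
    """State vector over flat exons: present / skipped / IR-spanned / absent."""
    n = len(model.flat_exons)
    row = np.full(n, ABSENT, dtype=np.int8)
    for m in matches:
        for k in m.matched_flat_exons:
            row[k - 1] = IR_SPANNED if m.match_class == "spanning" else PRESENT
    for k in events.es:
        row[k - 1] = SKIPPED
    return row


def _state_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Jaccard-style distance over non-absent exon states."""
    active = (u != ABSENT) | (v != ABSENT)
    if not active.any():
        return 0.0
    return float(np.sum(u[active] != v[active]) / np.sum(active))


def build_exon_matrix(
    isoforms: Sequence[TranscriptModel],
    model: FlattenedGeneModel,
    cfg: Config | None = None,
) -> pd.DataFrame:
    """Isoform x known-exon state matrix, rows in dendrogram leaf order.

    Rows are ordered by deterministic average-linkage hierarchical
    clustering on a Jaccard distance over the exon states (skipped and
    IR-spanned are distinct states); ties resolve through a prior sort on
    isoform id.
    """
    cfg = cfg or Config()
    ordered = sorted(isoforms, key=lambda t: t.transcript_id)
    rows, ids = [], []
    for iso in ordered:
        matches = match_exons(iso, model, cfg)
        ev = call_events(iso, model, cfg)
        rows.append(exon_state_row(ev, matches, model))
        ids.append(iso.transcript_id)
    X = np.array(rows)
    if len(ordered) > 2:
        dist = pdist(X, metric=_state_distance)
        order = leaves_list(linkage(dist, method="average"))
    else:
        order = np.arange(len(ordered))
    cols = [f"exon_{fe.index}" for fe in model.flat_exons]
    return pd.DataFrame(X[order], index=[ids[i] for i in order], columns=cols)


def events_table(
    results: Iterable[tuple[TranscriptModel, ASEventSet, StructuralCategory]]
) -> pd.DataFrame:
    """Per-isoform event table (TSV-ready)."""
    rows = []
    for iso, ev, cat in results:
        rows.append(
            {
                "isoform": iso.transcript_id,
                "gene": iso.gene_id,
                "category": cat.category,
                "matched_reference": cat.matched_reference_transcript or "",
                "mono_exon": cat.mono_exon,
                "AF": ev.af,
                "AL": ev.al,
                "AP": ev.ap,
                "AT": ev.at,
                "nA5": len(ev.a5),
                "nA3": len(ev.a3),
                "ES": ";".join(map(str, ev.es)),
                "IR": ";".join(f"{a}-{b}:{n}" for a, b, n in ev.ir),
                "CE": ";".join(f"intron{k}:{s}-{e}" for k, (s, e) in ev.ce),
                "NE": ";".join(f"{side}:{s}-{e}" for side, (s, e) in ev.ne),
            }
        )
    return pd.DataFrame(rows)


def summary_table(summaries: Iterable[GeneSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "gene": s.gene_id,
            "n_isoforms": s.n_isoforms,
            "n_known": s.n_known,
            "n_novel": s.n_novel,
            "n_coding": s.n_coding,
            "n_noncoding": s.n_noncoding,
        }
        for etype in ("A5A3", "ES", "IR"):
            n_iso, n_ev = s.events[etype]
            row[f"{etype}_isoforms"] = n_iso
            row[f"{etype}_events"] = n_ev
            row[f"{etype}_pct"] = s.pct_isoforms_with(etype)
        rows.append(row)
    return pd.DataFrame(rows)


def annotate_junction_support(
    isoforms: Sequence[TranscriptModel], sj: pd.DataFrame
) -> pd.DataFrame:
    """Mark each isoform junction supported/unsupported by short reads.

    A junction is supported when the SJ table holds a matching intron
    (chrom, start, end) with >=1 uniquely-mapped read.
    """
    supported = {
        (r.chrom, r.start, r.end)
        for r in sj.itertuples()
        if r.unique_reads >= 1
    }
    rows = []
    for iso in isoforms:
        for up, down in zip(iso.exons, iso.exons[1:]):
            rows.append(
                {
                    "isoform": iso.transcript_id,
                    "chrom": iso.chrom,
                    "intron_start": up.end,
                    "intron_end": down.start,
                    "supported": (iso.chrom, up.end, down.start) in supported,
                }
            )
    return pd.DataFrame(rows)
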