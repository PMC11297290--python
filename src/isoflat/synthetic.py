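"""Synthetic reference genes, isoform catalogs and count matrices.

Every module is testable without external data: this generator emits
multi-transcript reference genes, long-read isoform catalogs with implanted
alternative-splicing events (ES, IR, CE, NE, A5, A3, 5'/3' truncations) and
a ground-truth ledger consistent with the emitted models by construction,
plus negative-binomial count matrices with group (genotype) and
genotype-by-age effects.

Implant geometry keeps events unambiguous: introns are at least 100 bp and
exons at least 80 bp, alternative splice-site offsets are drawn strictly
beyond the 10 bp tolerance (11-30 bp), cryptic exons sit fully inside an
intron with a 20 bp margin, and each event type targets its own exon, so
the truth labels are exactly the labels an event caller should recover.
Reference transcripts are the full exon chain plus variants dropping single
internal exons; only the full-length start/end are therefore annotated
first/last exons and transcription start/end sites.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import (
    Config,
    GenomicInterval,
    TranscriptModel,
    write_counts,
    write_gtf,
)

MIRROR_C = 2_000_000  # reflection constant for '-'-strand construction


@dataclass
class SyntheticGeneSpec:
    """Parameters for one synthetic gene and its isoform catalog.

    Default event probabilities mirror a deeply sequenced targeted panel:
    alternative splice sites and exon skipping are common, intron retention
    and cryptic/novel exons are rare, and 5'-truncated (degradation-like)
    isoforms are a sizeable minority.
    """

    n_exons: int = 8
    exon_len: tuple[int, int] = (80, 200)
    intron_len: tuple[int, int] = (100, 300)
    strand: str = "+"
    n_reference_transcripts: int = 2
    n_isoforms: int = 8
    p_es: float = 0.5
    p_ir: float = 0.05
    p_ce: float = 0.05
    p_ne: float = 0.05
    p_a5: float = 0.4
    p_a3: float = 0.4
    p_trunc5: float = 0.3  # 5'-truncated, degradation-like (ISM) artifacts
    p_trunc3: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exons < 2:
            raise ValueError("junction-bearing genes need n_exons >= 2")
        for p in (self.p_es, self.p_ir, self.p_ce, self.p_ne, self.p_a5,
                  self.p_a3, self.p_trunc5, self.p_trunc3):
            if not 0 <= p <= 1:
                raise ValueError("event probabilities must lie in [0, 1]")
        if self.exon_len[0] < 80 or self.intron_len[0] < 100:
            raise ValueError(
                "exons must be >= 80 bp and introns >= 100 bp so implanted "
                "events cannot collide within the splice tolerance"
            )
        if self.p_ce > 0 and self.intron_len[0] < 100:
            raise ValueError("cryptic exons need introns of >= 100 bp")


@dataclass
class IsoformTruth:
    """Ground-truth labels for one synthetic isoform."""

    isoform_id: str
    af: bool = False
    al: bool = False
    ap: bool = False
    at: bool = False
    a5: list[tuple[int, int]] = field(default_factory=list)
    a3: list[tuple[int, int]] = field(default_factory=list)
    es: list[int] = field(default_factory=list)
    ir: list[tuple[int, int, int]] = field(default_factory=list)
    ce: list[tuple[int, tuple[int, int]]] = field(default_factory=list)
    ne: list[tuple[str, tuple[int, int]]] = field(default_factory=list)
    category: str = "FSM"
    matched_reference: str | None = None


@dataclass
class SyntheticGene:
    gene_id: str
    chrom: str
    strand: str
    reference: list[TranscriptModel]
    isoforms: list[TranscriptModel]
    truths: dict[str, IsoformTruth]
    flat_exon_coords: list[tuple[int, int]]  # transcription order, pre-mirror on '-'


def mirror_interval(iv: GenomicInterval, c: int = MIRROR_C) -> GenomicInterval:
    flip = {"+": "-", "-": "+"}[iv.strand]
    return GenomicInterval(iv.chrom, c - iv.end, c - iv.start, flip)


def mirror_transcript(tx: TranscriptModel, c: int = MIRROR_C) -> TranscriptModel:
    return TranscriptModel(
        tx.transcript_id, tx.gene_id, [mirror_interval(e, c) for e in tx.exons], tx.source
    )


def _mirror_pair(p: tuple[int, int], c: int) -> tuple[int, int]:
    return (c - p[1], c - p[0])


def _subchain(chain: tuple, sub: tuple) -> bool:
    return bool(sub) and any(
        chain[i : i + len(sub)] == sub for i in range(len(chain) - len(sub) + 1)
    )


def _categorize(
    exons: list[tuple[int, int]], ref_chains: dict[str, tuple], donors: set, acceptors: set
) -> tuple[str, str | None]:
    """Junction-chain category of a pre-mirror ('+'-oriented) exon list."""
    chain = tuple((a[1], b[0]) for a, b in zip(exons, exons[1:]))
    for rid in sorted(ref_chains):
        if chain == ref_chains[rid]:
            return "FSM", rid
    for rid in sorted(ref_chains):
        if _subchain(ref_chains[rid], chain):
            return "ISM", rid
    if {d for d, _ in chain} <= donors and {a for _, a in chain} <= acceptors:
        return "NIC", None
    return "NNC", None


def make_gene(spec: SyntheticGeneSpec, gene_id: str = "GSYN1", chrom: str | None = None) -> SyntheticGene:
    """Build one gene: reference transcripts, isoforms and their truths.

    Deterministic under ``spec.seed``. Construction happens on the '+'
    strand with transcription order equal to genomic order; '-'-strand
    genes are produced by reflecting every coordinate, which preserves all
    transcription-order labels.
    """
    rng = np.random.default_rng(spec.seed)
    chrom = chrom or f"chr_{gene_id}"
    tau = Config().splice_tolerance_bp

    # lay out flat exons left to right (transcription order pre-mirror)
    coords: list[tuple[int, int]] = []
    pos = 1000
    for _ in range(spec.n_exons):
        length = int(rng.integers(spec.exon_len[0], spec.exon_len[1] + 1))
        coords.append((pos, pos + length))
        pos += length + int(rng.integers(spec.intron_len[0], spec.intron_len[1] + 1))
    n = spec.n_exons

    # reference transcripts: full chain + single-internal-exon drops
    ref_exon_lists: dict[str, list[tuple[int, int]]] = {f"{gene_id}.ref1": list(coords)}
    droppable = list(range(1, n - 1))
    rng.shuffle(droppable)
    for j in range(1, spec.n_reference_transcripts):
        if not droppable:
            break
        k = droppable.pop()
        ref_exon_lists[f"{gene_id}.ref{j + 1}"] = [c for i, c in enumerate(coords) if i != k]
    ref_chains = {
        rid: tuple((a[1], b[0]) for a, b in zip(exs, exs[1:]))
        for rid, exs in ref_exon_lists.items()
    }
    donors = {d for ch in ref_chains.values() for d, _ in ch}
    acceptors = {a for ch in ref_chains.values() for _, a in ch}

    isoforms: list[TranscriptModel] = []
    truths: dict[str, IsoformTruth] = {}
    for i in range(spec.n_isoforms):
        iso_id = f"{gene_id}.iso{i + 1}"
        truth = IsoformTruth(isoform_id=iso_id)
        # entries: (flat_indices 1-based tx order, start, end)
        entries: list[list] = [[[k + 1], s, e] for k, (s, e) in enumerate(coords)]

        if rng.random() < spec.p_trunc5 and len(entries) > 2:
            drop = int(rng.integers(1, min(3, len(entries) - 1)))
            entries = entries[drop:]
            truth.af = truth.ap = True
            if rng.random() < 0.5:  # degraded 5' end inside the new first exon
                shave = int(rng.integers(5, 40))
                if entries[0][2] - entries[0][1] - shave >= 20:
                    entries[0][1] += shave
        if rng.random() < spec.p_trunc3 and len(entries) > 2:
            drop = int(rng.integers(1, min(3, len(entries) - 1)))
            entries = entries[:-drop]
            truth.al = truth.at = True

        first_flat = entries[0][0][0]
        last_flat = entries[-1][0][0]
        pool = [k for k in range(first_flat + 1, last_flat)]
        rng.shuffle(pool)

        ir_run: list[int] = []
        if rng.random() < spec.p_ir:
            m = int(rng.integers(2, 4))
            candidates = [
                k for k in pool if all((k + d) in pool for d in range(m))
            ]
            if candidates:
                k0 = candidates[int(rng.integers(len(candidates)))]
                ir_run = [k0 + d for d in range(m)]
                for k in ir_run:
                    pool.remove(k)

        es_targets: list[int] = []
        if rng.random() < spec.p_es and pool:
            m = min(int(rng.integers(1, 3)), len(pool))
            es_targets = sorted(pool[:m])
            pool = pool[m:]

        a5_target = a3_target = None
        if rng.random() < spec.p_a5 and pool:
            a5_target = pool.pop()
        if rng.random() < spec.p_a3 and pool:
            a3_target = pool.pop()

        # apply exon-level edits
        if ir_run:
            keep = [e for e in entries if e[0][0] not in ir_run[1:]]
            for e in keep:
                if e[0][0] == ir_run[0]:
                    e[0] = list(ir_run)
                    e[2] = coords[ir_run[-1] - 1][1]
            entries = keep
            truth.ir = [(ir_run[0], ir_run[-1], len(ir_run))]
        if es_targets:
            entries = [e for e in entries if e[0][0] not in es_targets]
            truth.es = sorted(es_targets)
        if a5_target is not None:
            off = int(rng.integers(tau + 1, 31))
            sign = 1 if rng.random() < 0.5 else -1
            for e in entries:
                if e[0] == [a5_target]:
                    e[2] += sign * off
            truth.a5 = [(a5_target, off)]
        if a3_target is not None:
            off = int(rng.integers(tau + 1, 31))
            sign = 1 if rng.random() < 0.5 else -1
            for e in entries:
                if e[0] == [a3_target]:
                    e[1] += sign * off
            truth.a3 = [(a3_target, off)]

        if rng.random() < spec.p_ce:
            present = {e[0][0] for e in entries} | {
                k for e in entries for k in e[0]
            }
            cands = [
                j
                for j in range(first_flat, last_flat)
                if j in present
                and (j + 1) in present
                and not (j in ir_run and (j + 1) in ir_run)
                and j not in truth.es
                and (j + 1) not in truth.es
                # an A5/A3 shift on a flanking exon may reach into this intron
                and j != a5_target
                and (j + 1) != a3_target
            ]
            if cands:
                j = cands[int(rng.integers(len(cands)))]
                intron_lo = coords[j - 1][1]
                ce_len = int(rng.integers(20, 61))
                ce = (intron_lo + 20, intron_lo + 20 + ce_len)
                entries.append([[], ce[0], ce[1]])
                entries.sort(key=lambda e: e[1])
                truth.ce = [(j, ce)]

        if not truth.af and rng.random() < spec.p_ne:
            lo = coords[0][0]
            ne = (lo - 300, lo - 300 + int(rng.integers(40, 80)))
            entries.insert(0, [[], ne[0], ne[1]])
            truth.ne = [("upstream", ne)]
            truth.af = truth.ap = True

        plain = [(e[1], e[2]) for e in entries]
        truth.category, truth.matched_reference = _categorize(
            plain, ref_chains, donors, acceptors
        )
        ivs = [GenomicInterval(chrom, s, e, "+") for s, e in plain]
        isoforms.append(TranscriptModel(iso_id, gene_id, ivs, source="long_read"))
        truths[iso_id] = truth

    reference = [
        TranscriptModel(rid, gene_id, [GenomicInterval(chrom, s, e, "+") for s, e in exs])
        for rid, exs in ref_exon_lists.items()
    ]
    if spec.strand == "-":
        reference = [mirror_transcript(t) for t in reference]
        isoforms = [mirror_transcript(t) for t in isoforms]
        for truth in truths.values():
            truth.ce = [(j, _mirror_pair(iv, MIRROR_C)) for j, iv in truth.ce]
            truth.ne = [(side, _mirror_pair(iv, MIRROR_C)) for side, iv in truth.ne]
    return SyntheticGene(
        gene_id=gene_id,
        chrom=chrom,
        strand=spec.strand,
        reference=reference,
        isoforms=isoforms,
        truths=truths,
        flat_exon_coords=coords,
    )


def make_counts(
    isoform_ids: list[str],
    n_per_group: tuple[int, int] = (10, 10),
    baseline_mean: float = 100.0,
    dispersion: float = 0.1,
    fold_changes: dict[str, float] | None = None,
    group_names: tuple[str, str] = ("WT", "TG"),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with multiplicative group effects.

    ``dispersion`` is the NB overdispersion alpha (variance = mu + alpha
    mu^2); alpha = 0 degenerates to Poisson. ``fold_changes`` multiplies
    the second group's mean for the named isoforms. Returns (counts,
    sample metadata with group and age columns).
    """
    if baseline_mean <= 0 or dispersion < 0:
        raise ValueError("baseline_mean must be > 0 and dispersion >= 0")
    rng = np.random.default_rng(seed)
    fold_changes = fold_changes or {}
    samples, groups = [], []
    for gname, n in zip(group_names, n_per_group):
        for j in range(n):
            samples.append(f"{gname}_{j + 1}")
            groups.append(gname)
    X = np.zeros((len(isoform_ids), len(samples)), dtype=int)
    for r, iso in enumerate(isoform_ids):
        for c, gname in enumerate(groups):
            mu = baseline_mean * (fold_changes.get(iso, 1.0) if gname == group_names[1] else 1.0)
            if dispersion == 0:
                X[r, c] = rng.poisson(mu)
            else:
                size = 1.0 / dispersion
                X[r, c] = rng.negative_binomial(size, size / (size + mu))
    counts = pd.DataFrame(X, index=isoform_ids, columns=samples)
    ages = rng.choice([2, 4, 6, 8], size=len(samples))
    meta = pd.DataFrame({"sample": samples, "group": groups, "age": ages}).set_index("sample")
    return counts, meta


def make_counts_with_means(
    group_means: pd.DataFrame,
    n_per_group: tuple[int, int] = (10, 10),
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB counts with explicit per-isoform, per-group means.

    ``group_means`` is isoform x group (two columns, column order = group
    order). Used to implant exact isoform-fraction configurations.
    """
    rng = np.random.default_rng(seed)
    gnames = list(group_means.columns)
    samples, groups = [], []
    for gname, n in zip(gnames, n_per_group):
        for j in range(n):
            samples.append(f"{gname}_{j + 1}")
            groups.append(gname)
    X = np.zeros((group_means.shape[0], len(samples)), dtype=int)
    for r in range(group_means.shape[0]):
        for c, gname in enumerate(groups):
            mu = float(group_means.iloc[r][gname])
            if dispersion == 0:
                X[r, c] = rng.poisson(mu)
            else:
                size = 1.0 / dispersion
                X[r, c] = rng.negative_binomial(size, size / (size + mu))
    counts = pd.DataFrame(X, index=group_means.index, columns=samples)
    meta = pd.DataFrame({"sample": samples, "group": groups}).set_index("sample")
    return counts, meta


def random_genome(chrom_lengths: dict[str, int], seed: int = 0) -> dict[str, str]:
    """Random A/C/G/T sequence per chromosome."""
    rng = np.random.default_rng(seed)
    return {
        chrom: "".join(rng.choice(list("ACGT"), size=length))
        for chrom, length in chrom_lengths.items()
    }


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as out:
        for chrom, seq in genome.items():
            out.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


@dataclass
class SyntheticPanel:
    genes: list[SyntheticGene]
    counts: pd.DataFrame
    metadata: pd.DataFrame
    genome: dict[str, str]

    @property
    def gene_map(self) -> pd.Series:
        return pd.Series(
            {iso.transcript_id: g.gene_id for g in self.genes for iso in g.isoforms}
        )


def make_panel(
    n_genes: int = 5,
    seed: int = 0,
    spec: SyntheticGeneSpec | None = None,
    n_per_group: tuple[int, int] = (10, 10),
    baseline_mean: float = 100.0,
    dispersion: float = 0.1,
    ir_burden_fold: float = 1.0,
) -> SyntheticPanel:
    """A full synthetic targeted panel: genes, isoforms, counts, genome.

    ``ir_burden_fold`` multiplies the second group's mean for every
    IR-carrying isoform, emulating a group-level burden of retained
    introns.
    """
    rng = np.random.default_rng(seed)
    genes = []
    for gi in range(n_genes):
        base = spec or SyntheticGeneSpec()
        gspec = SyntheticGeneSpec(
            **{
                **asdict(base),
                "seed": int(rng.integers(0, 2**31 - 1)),
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
        genes.append(make_gene(gspec, gene_id=f"GSYN{gi + 1}"))
    iso_ids = [iso.transcript_id for g in genes for iso in g.isoforms]
    fold = {
        iso.transcript_id: ir_burden_fold
        for g in genes
        for iso in g.isoforms
        if g.truths[iso.transcript_id].ir
    } if ir_burden_fold != 1.0 else None
    counts, meta = make_counts(
        iso_ids,
        n_per_group=n_per_group,
        baseline_mean=baseline_mean,
        dispersion=dispersion,
        fold_changes=fold,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    chrom_lengths = {
        g.chrom: max(e.end for t in g.reference + g.isoforms for e in t.exons) + 100
        for g in genes
    }
    genome = random_genome(chrom_lengths, seed=int(rng.integers(0, 2**31 - 1)))
    return SyntheticPanel(genes=genes, counts=counts, metadata=meta, genome=genome)


def write_panel(panel: SyntheticPanel, outdir: str | Path) -> dict[str, Path]:
    """Write a panel to disk (reference GTF, isoform GTF, counts, metadata,
    genome FASTA, truth JSON); round-trips through annotation_io."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference_gtf": outdir / "reference.gtf",
        "isoforms_gtf": outdir / "isoforms.gtf",
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "samples.tsv",
        "genome": outdir / "genome.fa",
        "truth": outdir / "truth.json",
    }
    write_gtf([t for g in panel.genes for t in g.reference], paths["reference_gtf"])
    write_gtf([t for g in panel.genes for t in g.isoforms], paths["isoforms_gtf"])
    write_counts(panel.counts, paths["counts"])
    panel.metadata.to_csv(paths["metadata"], sep="\t")
    write_fasta(panel.genome, paths["genome"])
    truth = {
        g.gene_id: {iid: asdict(t) for iid, t in g.truths.items()} for g in panel.genes
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
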