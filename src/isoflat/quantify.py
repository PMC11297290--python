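"""Filtering, normalization, isoform-usage and differential-usage metrics.

Full-length read counts act as direct proxies of transcript abundance.
The module implements the rare-transcript filter ("read count >= 10 across
any five samples"), CPM and median-of-ratios normalization, isoform
fractions (an isoform's normalized reads over its gene's total), dominant/
major isoform definitions, a minor-isoform pre-filter, and differential
transcript usage (DTU) metrics: total change (half-L1 distance between
group-mean isoform-fraction vectors, in percentage points), podium change
(a switch of the dominant isoform) and a label-permutation p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .annotation_io import Config

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    n_input: int
    n_removed: int
    semantics: str

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    @property
    def pct_removed(self) -> float:
        return round(100.0 * self.n_removed / self.n_input, 1) if self.n_input else 0.0


def filter_rare(
    counts: pd.DataFrame,
    cfg: Config | None = None,
    semantics: str = "top_n_sum",
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove rare transcripts by full-length read support.

    Default semantics ("top_n_sum"): retain an isoform iff the sum of its
    ``rare_n_samples`` largest per-sample counts reaches ``rare_min_reads``.
    Alternative ("per_sample"): retain iff at least ``rare_n_samples``
    samples each hold ``rare_min_reads`` reads.
    """
    cfg = cfg or Config()
    n_samp = min(cfg.rare_n_samples, counts.shape[1])
    if counts.shape[1] < cfg.rare_n_samples:
        log.warning(
            "only %d samples available for the rare filter (wanted %d); using all",
            counts.shape[1],
            cfg.rare_n_samples,
        )
    X = counts.to_numpy()
    if semantics == "top_n_sum":
        top = np.sort(X, axis=1)[:, ::-1][:, :n_samp]
        keep = top.sum(axis=1) >= cfg.rare_min_reads
    elif semantics == "per_sample":
        keep = (X >= cfg.rare_min_reads).sum(axis=1) >= n_samp
    else:
        raise ValueError(f"unknown filter semantics {semantics!r}")
    report = FilterReport(
        n_input=len(counts), n_removed=int((~keep).sum()), semantics=semantics
    )
    return counts.loc[keep], report


def normalize(
    counts: pd.DataFrame, method: str = "median_of_ratios"
) -> tuple[pd.DataFrame, pd.Series]:
    """Normalize a count matrix; returns (normalized matrix, size factors).

    ``cpm``: size factor = column sum / 1e6. ``median_of_ratios``: per
    sample, the median over rows with no zero count of the ratio to the
    row geometric mean (the DESeq-style estimator). Normalized value =
    count / factor.
    """
    if method == "cpm":
        factors = counts.sum(axis=0) / 1e6
    elif method == "median_of_ratios":
        X = counts.to_numpy(dtype=float)
        eligible = (X > 0).all(axis=1)
        if not eligible.any():
            raise ValueError("median-of-ratios: no row is free of zeros")
        logX = np.log(X[eligible])
        log_geomean = logX.mean(axis=1, keepdims=True)
        factors = pd.Series(
            np.exp(np.median(logX - log_geomean, axis=0)), index=counts.columns
        )
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if (factors <= 0).any():
        raise ValueError("non-positive size factor estimated")
    return counts / factors, factors


def isoform_fractions(
    counts: pd.DataFrame, gene_map: pd.Series
) -> pd.DataFrame:
    """Per-sample isoform fractions (IF): count / gene total, NaN when the
    gene has zero reads in a sample (undefined, excluded from means)."""
    genes = gene_map.reindex(counts.index)
    if genes.isna().any():
        missing = counts.index[genes.isna()].tolist()
        raise ValueError(f"isoforms without gene assignment: {missing}")
    totals = counts.groupby(genes).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts / totals
    return frac.where(totals > 0)


def group_mean_if(if_df: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Mean IF per group (isoform x group), skipping undefined samples."""
    g = groups.reindex(if_df.columns)
    if g.isna().any():
        raise ValueError(f"samples without group label: {if_df.columns[g.isna()].tolist()}")
    return if_df.T.groupby(g).mean().T


def dominant_and_major(
    mean_if: pd.Series, gene_map: pd.Series, cfg: Config | None = None
) -> pd.DataFrame:
    """Dominant (most abundant) isoform and the major set per gene.

    Major = isoforms whose mean IF relative to the dominant's strictly
    exceeds ``major_fraction``; the dominant is always major. Ties for
    dominant resolve to the lexicographically first isoform id (logged).
    """
    cfg = cfg or Config()
    rows = []
    for gene, sub in mean_if.groupby(gene_map.reindex(mean_if.index)):
        sub = sub.sort_index()
        top = sub.max()
        dominant = sub.idxmax()  # first-by-index on ties
        if (sub == top).sum() > 1:
            log.info("gene %s: tie for dominant isoform, kept %s", gene, dominant)
        if top > 0:
            major = set(sub.index[(sub / top) > cfg.major_fraction])
        else:
            major = set()
        major.add(dominant)
        rows.append({"gene": gene, "dominant": dominant, "major": sorted(major)})
    return pd.DataFrame(rows).set_index("gene")


def minor_isoform_filter(
    mean_if: pd.Series, gene_map: pd.Series, fc: float | None = None, cfg: Config | None = None
) -> pd.Index:
    """Pre-DTU minor-isoform filter: keep isoforms whose proportion relative
    to their gene's dominant isoform strictly exceeds ``fc`` (default from
    config, 0.5); the dominant isoform itself always survives."""
    cfg = cfg or Config()
    if fc is None:
        fc = cfg.minor_filter_fc
    keep: list[str] = []
    for _gene, sub in mean_if.groupby(gene_map.reindex(mean_if.index)):
        sub = sub.sort_index()
        top = sub.max()
        dominant = sub.idxmax()
        for iso, v in sub.items():
            if iso == dominant or (top > 0 and v > 0 and v / top > fc):
                keep.append(iso)
    return pd.Index(sorted(keep))


@dataclass
class DTUResult:
    gene_id: str
    total_change: float  # percentage points, in [0, 100]
    podium_change: bool
    dominant_a: str
    dominant_b: str
    permutation_p: float


def _total_change(if_mat: np.ndarray, in_a: np.ndarray, in_b: np.ndarray) -> tuple[float, int, int]:
    """Half-L1 distance x100 between group-mean IF vectors; NaN-aware."""
    with np.errstate(invalid="ignore"):
        mask = ~np.isnan(if_mat)
        filled = np.where(mask, if_mat, 0.0)
        na = (mask & in_a).sum(axis=1)
        nb = (mask & in_b).sum(axis=1)
        mean_a = np.where(na > 0, (filled * in_a).sum(axis=1) / np.maximum(na, 1), 0.0)
        mean_b = np.where(nb > 0, (filled * in_b).sum(axis=1) / np.maximum(nb, 1), 0.0)
    tc = 50.0 * np.abs(mean_a - mean_b).sum()
    return tc, int(np.argmax(mean_a)), int(np.argmax(mean_b))


def dtu_metrics(
    if_df: pd.DataFrame,
    gene_map: pd.Series,
    groups: pd.Series,
    n_permutations: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene DTU: total change, podium change, permutation p-value.

    The p-value permutes sample group labels (seeded) and counts permuted
    total-change values at least as large as the observed one, with the
    +1 correction so p is never zero.
    """
    levels = pd.unique(groups.reindex(if_df.columns).dropna())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    g = groups.reindex(if_df.columns)
    in_a = (g == levels[0]).to_numpy()
    in_b = (g == levels[1]).to_numpy()
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    rng = np.random.default_rng(seed)
    n_samples = if_df.shape[1]
    perms = [rng.permutation(n_samples) for _ in range(n_permutations)]
    rows = []
    for gene, sub in if_df.groupby(gene_map.reindex(if_df.index)):
        sub = sub.sort_index()
        mat = sub.to_numpy()
        tc, ia, ib = _total_change(mat, in_a, in_b)
        hits = 0
        for p in perms:
            ptc, _, _ = _total_change(mat, in_a[p], in_b[p])
            if ptc >= tc:
                hits += 1
        rows.append(
            DTUResult(
                gene_id=gene,
                total_change=tc,
                podium_change=sub.index[ia] != sub.index[ib],
                dominant_a=sub.index[ia],
                dominant_b=sub.index[ib],
                permutation_p=(1 + hits) / (1 + n_permutations),
            )
        )
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("gene_id")
    out["permutation_q"] = false_discovery_control(out["permutation_p"], method="bh")
    return out


def gene_level_counts(counts: pd.DataFrame, gene_map: pd.Series) -> pd.DataFrame:
    """Gene x sample counts: the sum of all isoform counts, computed on the
    pre-filter matrix (gene expression aggregates before rare filtering)."""
    genes = gene_map.reindex(counts.index)
    if genes.isna().any():
        missing = counts.index[genes.isna()].tolist()
        raise ValueError(f"isoforms without gene assignment: {missing}")
    return counts.groupby(genes).sum()


def cumulative_read_proportion(counts: pd.DataFrame) -> pd.Series:
    """Cumulative fraction of total reads over isoforms sorted by abundance
    (descending; ties in id order). The last value is exactly 1."""
    totals = counts.sum(axis=1)
    grand = totals.sum()
    if grand == 0:
        raise ValueError("all counts are zero")
    ordered = totals.sort_index().sort_values(ascending=False, kind="stable")
    return (ordered.cumsum() / grand).rename("cumulative_fraction")


@dataclass
class OverlapStats:
    unique_a: int
    unique_b: int
    common: int

    @property
    def fold_change(self) -> float:
        denom = self.unique_b + self.common
        if denom == 0:
            return math.inf
        return round((self.unique_a + self.common) / denom, 2)

    @property
    def jaccard(self) -> float:
        total = self.unique_a + self.unique_b + self.common
        return self.common / total if total else 0.0


def detection_overlap(ids_a, ids_b) -> OverlapStats:
    """Detection overlap between two isoform id sets."""
    a, b = set(ids_a), set(ids_b)
    if not a and not b:
        raise ValueError("both id sets are empty")
    return OverlapStats(
        unique_a=len(a - b), unique_b=len(b - a), common=len(a & b)
    )


def event_burden_by_group(
    norm_counts: pd.DataFrame,
    carrier_isoforms: dict[str, set[str]],
    gene_map: pd.Series,
    groups: pd.Series,
) -> pd.DataFrame:
    """Summed normalized abundance of event-carrying isoforms per sample,
    with the between-group log2 fold change (pseudocount 1).

    ``carrier_isoforms`` maps an event type (e.g. IR, CE, NMD) to the set
    of isoform ids carrying it.
    """
    levels = pd.unique(groups.reindex(norm_counts.columns).dropna())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    g = groups.reindex(norm_counts.columns)
    rows = []
    genes = gene_map.reindex(norm_counts.index)
    for etype, carriers in carrier_isoforms.items():
        for gene in pd.unique(genes.dropna()):
            sel = norm_counts.loc[(genes == gene) & norm_counts.index.isin(carriers)]
            burden = sel.sum(axis=0)
            mean_a = burden[g == levels[0]].mean() if len(burden) else 0.0
            mean_b = burden[g == levels[1]].mean() if len(burden) else 0.0
            rows.append(
                {
                    "gene": gene,
                    "event_type": etype,
                    f"mean_{levels[0]}": mean_a,
                    f"mean_{levels[1]}": mean_b,
                    "log2fc": float(np.log2((mean_b + 1) / (mean_a + 1))),
                    **{s: burden.get(s, 0.0) for s in norm_counts.columns},
                }
            )
    return pd.DataFrame(rows)
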