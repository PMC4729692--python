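"""Region-level ChIP enrichment, browser tracks, k-means mark calling,
cross-cell-type differential enrichment and metagene profiles.

Enrichment is quantified as Log2(normalized ChIP / normalized input) where
a replicate's density is (count + pseudocount) per million mapped reads per
kB of region, and replicates are averaged after the log transform.  Regions
are split into three clusters on their enrichment values and the cluster
with the highest mean is designated "marked".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .diffexpr import fisher_combine, nb_tail_test, P_FLOOR
from .genome_io import GeneModel, GenomicInterval, intersect, make_tiles

__all__ = [
    "RegionCountTable",
    "EnrichmentTrack",
    "MarkCallSet",
    "DegenerateInputError",
    "log2_enrichment",
    "sliding_track",
    "write_bedgraph",
    "tile_summary",
    "kmeans_1d",
    "call_marked",
    "differential_enrichment",
    "metagene_profile",
    "scale_absolute",
]


class DegenerateInputError(ValueError):
    """Fewer distinct values than clusters; caller should relax k."""


@dataclass
class RegionCountTable:
    """ChIP and input read counts per region per replicate for one mark."""

    regions: list[GenomicInterval]
    chip_counts: np.ndarray  # (n_regions, n_reps)
    input_counts: np.ndarray  # (n_regions, n_reps)
    chip_lib_totals: np.ndarray  # (n_reps,)
    input_lib_totals: np.ndarray  # (n_reps,)
    mark: str = ""
    cell_type: str = ""

    def __post_init__(self) -> None:
        self.chip_counts = np.atleast_2d(np.asarray(self.chip_counts))
        self.input_counts = np.atleast_2d(np.asarray(self.input_counts))
        self.chip_lib_totals = np.atleast_1d(np.asarray(self.chip_lib_totals))
        self.input_lib_totals = np.atleast_1d(np.asarray(self.input_lib_totals))
        n = len(self.regions)
        if self.chip_counts.shape[0] != n or self.input_counts.shape[0] != n:
            raise ValueError("count row count != region count")
        if self.chip_counts.shape != self.input_counts.shape:
            raise ValueError("chip/input replicate shapes differ")
        if np.any(self.chip_counts < 0) or np.any(self.input_counts < 0):
            raise ValueError("negative counts")

    @property
    def n_replicates(self) -> int:
        return self.chip_counts.shape[1]

    @property
    def lengths_kb(self) -> np.ndarray:
        return np.array([r.length for r in self.regions], dtype=float) / 1000.0


@dataclass
class EnrichmentTrack:
    """Replicate-averaged Log2(ChIP/input) per region."""

    regions: list[GenomicInterval]
    values: np.ndarray
    n_replicates: int
    mark: str = ""
    cell_type: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "region_id": [r.id for r in self.regions],
            "chrom": [r.chrom for r in self.regions],
            "start": [r.start for r in self.regions],
            "end": [r.end for r in self.regions],
            "log2_enrichment": self.values,
        })


@dataclass
class MarkCallSet:
    """Marked/unmarked status per region for one mark in one cell type."""

    region_ids: list[str]
    marked: np.ndarray  # bool per region
    cluster_means: np.ndarray  # ascending
    mark: str = ""
    cell_type: str = ""

    def marked_ids(self) -> set[str]:
        return {rid for rid, m in zip(self.region_ids, self.marked) if m}


def log2_enrichment(
    table: RegionCountTable, pseudocount: float = 0.5
) -> EnrichmentTrack:
    """Average per-replicate Log2(normalized ChIP/input) densities.

    density = (count + pseudocount) / (lib_total / 1e6) / (length / 1000);
    the pseudocount keeps zero-count regions finite.
    """
    if np.any(table.chip_lib_totals <= 0) or np.any(table.input_lib_totals <= 0):
        raise ValueError("zero library total")
    len_kb = table.lengths_kb[:, None]
    chip_dens = (table.chip_counts + pseudocount) / (
        table.chip_lib_totals[None, :] / 1e6
    ) / len_kb
    input_dens = (table.input_counts + pseudocount) / (
        table.input_lib_totals[None, :] / 1e6
    ) / len_kb
    values = np.log2(chip_dens / input_dens).mean(axis=1)
    return EnrichmentTrack(table.regions, values, table.n_replicates,
                           table.mark, table.cell_type)


def sliding_track(
    chip_coverage: dict[str, np.ndarray],
    input_coverage: dict[str, np.ndarray],
    chip_lib_total: float,
    input_lib_total: float,
    window: int = 200,
    step: int = 50,
    pseudocount: float = 0.5,
) -> list[tuple[str, int, int, float]]:
    """Browser-track bedGraph records of windowed Log2 enrichment.

    Coverages are per-bp read-coverage arrays (one per chromosome); windows
    follow the tiling rule of :func:`genome_io.make_tiles` and each window's
    value is the Log2 ratio of pseudocounted per-million per-kB densities.
    """
    sizes = {c: len(v) for c, v in chip_coverage.items()}
    records: list[tuple[str, int, int, float]] = []
    csum_chip = {c: np.concatenate([[0], np.cumsum(v)]) for c, v in chip_coverage.items()}
    csum_inp = {c: np.concatenate([[0], np.cumsum(v)]) for c, v in input_coverage.items()}
    for tile in make_tiles(sizes, window, step):
        c, s, e = tile.chrom, tile.start, tile.end
        len_kb = (e - s) / 1000.0
        chip = csum_chip[c][e] - csum_chip[c][s]
        inp = csum_inp[c][e] - csum_inp[c][s]
        cd = (chip + pseudocount) / (chip_lib_total / 1e6) / len_kb
        id_ = (inp + pseudocount) / (input_lib_total / 1e6) / len_kb
        records.append((c, s, e, float(np.log2(cd / id_))))
    return records


def write_bedgraph(records: Sequence[tuple[str, int, int, float]],
                   path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def tile_summary(
    track: EnrichmentTrack,
    annotation: Sequence[GenomicInterval],
    fraction: float = 0.2,
) -> dict[str, dict[str, float]]:
    """Feature-kind composition of the top and bottom ``fraction`` of tiles.

    A tile overlapping k distinct annotation kinds contributes 1/k to each;
    tiles overlapping nothing count as 'intergenic'.  Fractions within each
    extreme set sum to 1.
    """
    n = len(track.regions)
    n_sel = max(1, int(round(fraction * n)))
    order = np.argsort(track.values, kind="mergesort")
    sets = {"bottom": order[:n_sel], "top": order[::-1][:n_sel]}
    out: dict[str, dict[str, float]] = {}
    for name, idx in sets.items():
        tiles = [track.regions[i] for i in idx]
        kinds_per_tile: dict[str, set[str]] = {t.id: set() for t in tiles}
        for tile, ann in intersect(tiles, list(annotation)):
            kinds_per_tile[tile.id].add(ann.kind)
        comp: dict[str, float] = {}
        for tile in tiles:
            kinds = kinds_per_tile[tile.id] or {"intergenic"}
            w = 1.0 / len(kinds)
            for k in kinds:
                comp[k] = comp.get(k, 0.0) + w
        total = sum(comp.values())
        out[name] = {k: v / total for k, v in sorted(comp.items())}
    return out


def kmeans_1d(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Globally optimal 1-D k-means by dynamic programming.

    Optimal 1-D clusters are contiguous in sorted order, so the exact SSE
    minimum is found by DP over split points.  Returns (labels, means) with
    clusters numbered in ascending order of mean.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if len(np.unique(values)) < k:
        raise DegenerateInputError(
            f"need >= {k} distinct values for {k} clusters; relax k"
        )
    order = np.argsort(values, kind="mergesort")
    x = values[order]
    cs = np.concatenate([[0.0], np.cumsum(x)])
    css = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # SSE of x[i..j] inclusive, vectorized over i
        cnt = j - i + 1
        s = cs[j + 1] - cs[i]
        ss = css[j + 1] - css[i]
        return ss - s * s / cnt

    dp = np.full((k, n), np.inf)
    back = np.zeros((k, n), dtype=int)
    cnt0 = np.arange(1, n + 1)
    dp[0] = css[1:] - cs[1:] ** 2 / cnt0  # cost of x[0..j] as one cluster
    for m in range(1, k):
        for j in range(m, n):
            i = np.arange(m, j + 1)  # start of last cluster
            costs = dp[m - 1, i - 1] + seg_cost(i, j)
            best = int(np.argmin(costs))
            dp[m, j] = costs[best]
            back[m, j] = i[best]
    # recover boundaries
    bounds = []
    j = n - 1
    for m in range(k - 1, 0, -1):
        i = back[m, j]
        bounds.append(i)
        j = i - 1
    bounds = sorted(bounds)
    labels_sorted = np.zeros(n, dtype=int)
    for b in bounds:
        labels_sorted[b:] += 1
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    means = np.array([values[labels == c].mean() for c in range(k)])
    return labels, means


def call_marked(
    regions: Sequence[GenomicInterval] | Sequence[str],
    values: np.ndarray,
    k: int = 3,
    restarts: int = 50,
    seed: int | None = None,
    mark: str = "",
    cell_type: str = "",
    min_marked_mean: float | None = None,
) -> MarkCallSet:
    """Cluster enrichment values into ``k`` groups; the most highly enriched
    cluster is designated marked.

    The clustering is the exact 1-D k-means optimum (see :func:`kmeans_1d`),
    so the result is deterministic; ``restarts``/``seed`` are accepted for
    API compatibility and unused.  ``min_marked_mean`` (log2 units) guards
    against mark-free data: k-means always produces a top cluster, so when
    no region is truly enriched the top noise cluster would be called
    marked; with the guard, a top cluster whose mean enrichment falls below
    the floor yields an empty marked set.
    """
    del restarts, seed
    region_ids = [r.id if isinstance(r, GenomicInterval) else str(r) for r in regions]
    values = np.asarray(values, dtype=float)
    if len(region_ids) != len(values):
        raise ValueError("regions/values length mismatch")
    labels, means = kmeans_1d(values, k)
    marked = labels == (k - 1)  # clusters ordered by ascending mean
    if min_marked_mean is not None and means[k - 1] < min_marked_mean:
        marked = np.zeros_like(marked)
    return MarkCallSet(region_ids, marked, means, mark, cell_type)


def differential_enrichment(
    table_a: RegionCountTable,
    table_b: RegionCountTable,
    calls_a: MarkCallSet,
    calls_b: MarkCallSet,
    p_max: float = 0.05,
    min_abs_log2fc: float = 2.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Classify each region as both / A_only / B_only / neither.

    Significance comes from NB tail tests of each cell type's replicate
    per-million counts against the other cell type's mean (combined by
    Fisher), with a method-of-moments dispersion pooled across replicates
    (floored at 0.01); the fold change is the difference of replicate-mean
    Log2 enrichments.  A_only means marked in A and either unmarked in B or
    significantly higher in A (p < p_max and FC > min_abs_log2fc);
    symmetric for B_only; both means marked in both without a significant
    difference.
    """
    ids_a = [r.id for r in table_a.regions]
    ids_b = [r.id for r in table_b.regions]
    if ids_a != ids_b:
        raise ValueError("tables must cover the same regions in order")
    enr_a = log2_enrichment(table_a, pseudocount).values
    enr_b = log2_enrichment(table_b, pseudocount).values
    fc = enr_a - enr_b

    # per-million chip counts per replicate
    pm_a = table_a.chip_counts / (table_a.chip_lib_totals[None, :] / 1e6)
    pm_b = table_b.chip_counts / (table_b.chip_lib_totals[None, :] / 1e6)
    mean_a = pm_a.mean(axis=1)
    mean_b = pm_b.mean(axis=1)

    def _disp(x: np.ndarray) -> np.ndarray:
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1) if x.shape[1] > 1 else np.zeros_like(m)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / (m * m)
        return np.where(np.isfinite(a), a, 0.0)

    alpha = np.maximum((_disp(pm_a) + _disp(pm_b)) / 2.0, 0.01)

    n = len(ids_a)
    pvals = np.ones(n)
    for g in range(n):
        ps = []
        mu_b = max(mean_b[g], 0.5)
        mu_a = max(mean_a[g], 0.5)
        for rep in range(pm_a.shape[1]):
            ps.append(nb_tail_test(int(round(pm_a[g, rep])), mu_b, alpha[g]))
        for rep in range(pm_b.shape[1]):
            ps.append(nb_tail_test(int(round(pm_b[g, rep])), mu_a, alpha[g]))
        pvals[g] = fisher_combine(np.maximum(ps, P_FLOOR))

    marked_a = np.asarray(calls_a.marked)
    marked_b = np.asarray(calls_b.marked)
    sig_up_a = (pvals < p_max) & (fc > min_abs_log2fc)
    sig_up_b = (pvals < p_max) & (fc < -min_abs_log2fc)
    cls = np.full(n, "neither", dtype=object)
    cls[marked_a & (~marked_b | sig_up_a)] = "A_only"
    cls[marked_b & (~marked_a | sig_up_b)] = "B_only"
    cls[marked_a & marked_b & ~sig_up_a & ~sig_up_b] = "both"
    return pd.DataFrame({
        "region_id": ids_a,
        "class": cls,
        "log2fc": fc,
        "p": pvals,
        "marked_a": marked_a,
        "marked_b": marked_b,
    })


def metagene_profile(
    values_by_chrom: dict[str, np.ndarray],
    genes: Sequence[GeneModel],
    groups: dict[str, Sequence[str]],
    body_bins: int = 100,
    flank_bp: int = 5000,
    flank_bins: int = 25,
) -> pd.DataFrame:
    """Mean signal over scaled gene bodies plus fixed-width flanks per group.

    Each gene body is linearly rescaled to ``body_bins`` bins; flanks are
    fixed-width.  Profiles of minus-strand genes are flipped so bin 0 is
    always the 5' flank.  Rows: groups; columns: bins.
    """
    total_bins = body_bins + 2 * flank_bins
    by_id = {g.gene_id: g for g in genes}

    def gene_profile(g: GeneModel) -> np.ndarray | None:
        arr = values_by_chrom.get(g.chrom)
        if arr is None:
            return None
        iv = g.interval
        prof = np.empty(total_bins)
        flank_w = flank_bp / flank_bins
        # upstream flank (in genome orientation), body, downstream flank
        for b in range(flank_bins):
            lo = iv.start - flank_bp + b * flank_w
            hi = lo + flank_w
            prof[b] = _window_mean(arr, lo, hi)
        bounds = np.linspace(iv.start, iv.end, body_bins + 1)
        for b in range(body_bins):
            prof[flank_bins + b] = _window_mean(arr, bounds[b], bounds[b + 1])
        for b in range(flank_bins):
            lo = iv.end + b * flank_w
            prof[flank_bins + body_bins + b] = _window_mean(arr, lo, lo + flank_w)
        if iv.strand == "-":
            prof = prof[::-1]
        return prof

    rows = {}
    for group, gene_ids in groups.items():
        profs = []
        for gid in gene_ids:
            g = by_id.get(gid)
            if g is None:
                continue
            p = gene_profile(g)
            if p is not None:
                profs.append(p)
        rows[group] = (np.mean(profs, axis=0) if profs
                       else np.full(total_bins, np.nan))
    return pd.DataFrame.from_dict(rows, orient="index")


def _window_mean(arr: np.ndarray, lo: float, hi: float) -> float:
    i = max(0, int(np.floor(lo)))
    j = min(len(arr), max(i + 1, int(np.ceil(hi))))
    if i >= len(arr) or j <= 0:
        return np.nan
    return float(arr[i:j].mean())


def scale_absolute(track: EnrichmentTrack, factor: float) -> EnrichmentTrack:
    """Shift a relative track onto an absolute scale by log2(factor).

    The factor is the externally measured global mark-abundance ratio
    (e.g. total ChIP DNA over input); factor 1 is the identity.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    return EnrichmentTrack(track.regions, track.values + np.log2(factor),
                           track.n_replicates, track.mark, track.cell_type)
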