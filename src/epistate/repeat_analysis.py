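"""Unique-locus transposable-element quantification and regulated-subfamily
detection.

Repeat locus counts come from uniquely mapping reads, so they are
normalized by the number of reads aligned to protein-coding genes (per
million) and by locus length (per kB) rather than by within-repeat size
factors.  A subfamily is called "regulated by" a mark when both its marked
locus fraction and its KO-upregulated locus fraction are significantly
above the genome-wide background (one-sided Fisher exact tests,
BH-adjusted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import DECallConfig, ExpressionMatrix, call_de
from .stats_util import ContingencyTable2x2, bh_adjust, fisher_exact_2x2

__all__ = [
    "RepeatLocusTable",
    "normalize_repeats",
    "de_repeat_loci",
    "subfamily_scan",
]

MIN_TOTAL_READS = 5  # loci below this total coverage are never tested


@dataclass
class RepeatLocusTable:
    """Repeat locus counts plus the protein-coding normalizers."""

    matrix: ExpressionMatrix  # rows are repeat loci
    subfamilies: list[str]
    classes: list[str]
    pc_read_totals: np.ndarray  # per-sample reads on protein-coding genes

    def __post_init__(self) -> None:
        n = len(self.matrix.gene_ids)
        if len(self.subfamilies) != n:
            raise ValueError("subfamily label missing for some locus")
        if any(not s for s in self.subfamilies):
            raise ValueError("empty subfamily label")
        self.pc_read_totals = np.asarray(self.pc_read_totals)
        if len(self.pc_read_totals) != self.matrix.counts.shape[1]:
            raise ValueError("pc_read_totals length != sample count")


def normalize_repeats(
    counts: np.ndarray,
    pc_read_totals: np.ndarray,
    locus_lengths: np.ndarray,
) -> np.ndarray:
    """count / (pc_total/1e6) / (length/1000), per locus per sample."""
    counts = np.asarray(counts, dtype=float)
    pc = np.asarray(pc_read_totals, dtype=float)
    if np.any(pc <= 0):
        raise ValueError("non-positive protein-coding read total")
    len_kb = np.asarray(locus_lengths, dtype=float) / 1000.0
    return counts / (pc[None, :] / 1e6) / len_kb[:, None]


def de_repeat_loci(
    table: RepeatLocusTable,
    config: DECallConfig | None = None,
    min_total_reads: int = MIN_TOTAL_READS,
) -> pd.DataFrame:
    """Upregulated-locus calls reusing the per-embryo Fisher-combined DE
    machinery, with protein-coding-anchored size factors.

    Loci with fewer than ``min_total_reads`` reads across samples are
    reported 'unchanged' without testing (insufficient coverage).
    """
    pc = np.asarray(table.pc_read_totals, dtype=float)
    factors = pc / np.exp(np.mean(np.log(pc)))  # geometric mean 1
    res = call_de(table.matrix, config, factors=factors)
    low = table.matrix.counts.sum(axis=1) < min_total_reads
    res.loc[low, "status"] = "unchanged"
    res["subfamily"] = table.subfamilies
    return res


def subfamily_scan(
    table: RepeatLocusTable,
    marked_ids: set[str],
    upregulated_ids: set[str],
    min_loci: int = 20,
    alpha: float = 0.05,
    mark: str = "H3K9me2",
) -> pd.DataFrame:
    """Per-subfamily summaries and the regulated flag.

    For each subfamily with >= ``min_loci`` loci, two one-sided Fisher
    exact tests compare its marked and upregulated locus fractions with the
    genome-wide fractions over all other loci; the flag requires both
    BH-adjusted p-values (adjusted within each test family) below ``alpha``.
    """
    ids = table.matrix.gene_ids
    sub = np.asarray(table.subfamilies)
    marked = np.array([i in marked_ids for i in ids])
    up = np.array([i in upregulated_ids for i in ids])

    names = []
    rows = []
    for name in sorted(set(table.subfamilies)):
        in_sub = sub == name
        n_loci = int(in_sub.sum())
        if n_loci < min_loci:
            continue
        a_m = int((in_sub & marked).sum())
        a_u = int((in_sub & up).sum())
        out_m = int((~in_sub & marked).sum())
        out_u = int((~in_sub & up).sum())
        n_out = int((~in_sub).sum())
        p_marked = fisher_exact_2x2(
            ContingencyTable2x2(a_m, n_loci - a_m, out_m, n_out - out_m),
            alternative="greater",
        )
        p_up = fisher_exact_2x2(
            ContingencyTable2x2(a_u, n_loci - a_u, out_u, n_out - out_u),
            alternative="greater",
        )
        names.append(name)
        rows.append({
            "subfamily": name,
            "class": table.classes[list(sub).index(name)] if table.classes else "",
            "n_loci": n_loci,
            f"frac_marked_{mark}": a_m / n_loci,
            "frac_upregulated": a_u / n_loci,
            "p_marked": p_marked,
            "p_upregulated": p_up,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        df["q_marked"] = df["q_upregulated"] = df["regulated"] = []
        return df
    df["q_marked"] = bh_adjust(df["p_marked"].to_numpy())
    df["q_upregulated"] = bh_adjust(df["p_upregulated"].to_numpy())
    df["regulated"] = (df["q_marked"] < alpha) & (df["q_upregulated"] < alpha)
    return df
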