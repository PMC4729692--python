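"""Active-enhancer calling and epigenetic-state classification.

Active enhancers are p300 peaks that overlap at least one H3K27ac peak and
one H3K4me1 peak but no annotated promoter; the emitted region is the peak
summit +/- 800 bp (1601 bp unless clipped at a chromosome edge).  Across
cell types, each enhancer's state is classified from the mark calls with an
explicit precedence (dual H3K9me2+H3K27ac > H3K9me2 > H3K27me3-poised >
active > inactive) so calls are deterministic.

Nearest-gene assignment links enhancers to the genes they presumably
regulate; this proxy can mis-assign elements that act on distant promoters,
a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GenomicInterval, intersect, nearest_gene
from .stats_util import RankTestResult, wilcoxon_rank_sum

__all__ = [
    "EnhancerCall",
    "ENHANCER_STATES",
    "call_active_enhancers",
    "classify_enhancer_states",
    "enhancer_class_fractions",
    "proximal_expression_contrast",
]

HALF_WIDTH = 800  # summit +/- 800 nt
ENHANCER_STATES = ("active", "k9_marked", "k27_poised", "dual_k9_k27ac", "inactive")


@dataclass
class EnhancerCall:
    """One called enhancer: its region, provenance and per-cell-type state."""

    region: GenomicInterval
    source_peak_id: str
    states: dict[str, str] = field(default_factory=dict)
    nearest_gene_id: str = ""
    distance: int = -1


def call_active_enhancers(
    p300_peaks: Sequence[GenomicInterval],
    k27ac_peaks: Sequence[GenomicInterval],
    k4me1_peaks: Sequence[GenomicInterval],
    promoters: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int] | None = None,
    half_width: int = HALF_WIDTH,
) -> list[EnhancerCall]:
    """Keep p300 peaks with K27ac AND K4me1 overlap and no promoter overlap.

    Summit is the peak midpoint.  Regions are summit +/- half_width
    (half-open, width 2*half_width + 1), clipped to chromosome bounds when
    ``chrom_sizes`` is given; output order follows sorted p300 peak ids so
    the call set is invariant to input order.
    """
    with_k27ac = {p.id for p, _ in intersect(list(p300_peaks), list(k27ac_peaks))}
    with_k4me1 = {p.id for p, _ in intersect(list(p300_peaks), list(k4me1_peaks))}
    with_prom = {p.id for p, _ in intersect(list(p300_peaks), list(promoters))}
    calls = []
    for peak in sorted(p300_peaks, key=lambda p: p.id):
        if peak.id not in with_k27ac or peak.id not in with_k4me1:
            continue
        if peak.id in with_prom:
            continue
        summit = peak.midpoint
        start = max(0, summit - half_width)
        end = summit + half_width + 1
        if chrom_sizes is not None:
            end = min(end, chrom_sizes[peak.chrom])
        region = GenomicInterval(peak.chrom, start, end, ".",
                                 f"enh_{peak.id}", "enhancer")
        calls.append(EnhancerCall(region, peak.id))
    return calls


def classify_enhancer_states(
    enhancer_ids: Sequence[str],
    k9_marked: set[str],
    k27me3_marked: set[str],
    k27ac_marked: set[str],
) -> dict[str, str]:
    """State per enhancer from the three mark-call sets.

    Precedence: dual_k9_k27ac (H3K9me2 and H3K27ac co-marked, the transient
    state of enhancers undergoing inactivation) > k9_marked > k27_poised >
    active > inactive.
    """
    states: dict[str, str] = {}
    for eid in enhancer_ids:
        k9 = eid in k9_marked
        k27 = eid in k27me3_marked
        ac = eid in k27ac_marked
        if k9 and ac:
            states[eid] = "dual_k9_k27ac"
        elif k9:
            states[eid] = "k9_marked"
        elif k27:
            states[eid] = "k27_poised"
        elif ac:
            states[eid] = "active"
        else:
            states[eid] = "inactive"
    return states


def enhancer_class_fractions(
    states_a: Mapping[str, str],
    states_b: Mapping[str, str],
) -> pd.DataFrame:
    """Among stage-A-active enhancers, counts/fractions per stage-B state.

    H3K9me2-gaining enhancers are those in the k9_marked or dual class at B.
    """
    active_a = [e for e, s in states_a.items() if s == "active"]
    n = len(active_a)
    rows = []
    for state in ENHANCER_STATES:
        count = sum(1 for e in active_a if states_b.get(e) == state)
        rows.append({"state_b": state, "count": count,
                     "fraction": count / n if n else 0.0})
    df = pd.DataFrame(rows)
    k9_gain = df.loc[df["state_b"].isin(["k9_marked", "dual_k9_k27ac"]),
                     "count"].sum()
    df.attrs["n_active_a"] = n
    df.attrs["frac_k9_gaining"] = k9_gain / n if n else 0.0
    return df


def proximal_expression_contrast(
    states: Mapping[str, str],
    enhancers: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    expression: Mapping[str, float],
    reference_state: str = "active",
) -> pd.DataFrame:
    """Nearest-gene expression per enhancer state, tested against the
    reference (active) class by rank-sum with effect size r.

    Rows: one per state present, with n, median expression, and (p, r,
    stars) vs the reference; classes with fewer than 2 genes get NaN p.
    """
    by_state: dict[str, list[float]] = {}
    for enh in enhancers:
        state = states.get(enh.id)
        if state is None:
            continue
        gene, _dist = nearest_gene(enh, genes)
        expr = expression.get(gene.gene_id)
        if expr is None:
            continue
        by_state.setdefault(state, []).append(float(expr))
    ref = by_state.get(reference_state, [])
    rows = []
    for state in ENHANCER_STATES:
        vals = by_state.get(state)
        if not vals:
            continue
        row = {"state": state, "n": len(vals),
               "median_expression": float(np.median(vals))}
        if state == reference_state or len(vals) < 2 or len(ref) < 2:
            row.update({"p": np.nan, "r": np.nan, "stars": ""})
        else:
            res: RankTestResult = wilcoxon_rank_sum(vals, ref)
            row.update({"p": res.p, "r": res.r, "stars": res.stars})
        rows.append(row)
    return pd.DataFrame(rows)
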