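"""Per-embryo differential expression with Fisher p-value combination.

Single-embryo RNA-seq from knockout litters is too heterogeneous for a
pooled two-group test, so each KO embryo is compared with all control
samples separately under a negative-binomial model, the per-comparison
p-values are combined by Fisher's combined probability test
(X = -2 sum ln p_i ~ chi-square with 2k df), and calls are filtered by a
cascade: combined p below threshold, the fold change reached in every
comparison, and a minimal expression level in each replicate of the
upregulated sample.

Counts are normalized by median-of-ratios size factors; RPKM is computed
from the size-factor-normalized counts.  The NB test is a two-sided tail by
probability-mass ordering with a method-of-moments dispersion estimated
from the control replicates (floored at 0.01); dispersion 0 degenerates to
Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ExpressionMatrix",
    "size_factors",
    "rpkm",
    "estimate_dispersion",
    "nb_tail_test",
    "fisher_combine",
    "call_de",
    "call_state_transition",
    "chromosome_enrichment",
]

P_FLOOR = 1e-300  # floor before taking logs in the Fisher combination
DISPERSION_FLOOR = 0.01
FC_PSEUDOCOUNT = 0.5  # normalized reads added to both sides of a fold change


@dataclass
class ExpressionMatrix:
    """Raw gene x sample counts with lengths and group labels."""

    counts: np.ndarray  # (n_genes, n_samples) non-negative ints
    gene_ids: list[str]
    gene_lengths: np.ndarray  # bp
    sample_labels: list[str]  # e.g. 'control'/'ko' or stage names
    sample_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
        n_genes, n_samples = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.gene_lengths) != n_genes:
            raise ValueError("gene dimension mismatch")
        if len(self.sample_labels) != n_samples:
            raise ValueError("sample dimension mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if np.any(self.gene_lengths <= 0):
            raise ValueError("non-positive gene length")
        if not self.sample_names:
            self.sample_names = [
                f"{lab}_{i}" for i, lab in enumerate(self.sample_labels)
            ]

    @property
    def lib_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        header = "\t".join(["gene_id", "length"] +
                           [f"{n}:{l}" for n, l in
                            zip(self.sample_names, self.sample_labels)])
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for gid, length, row in zip(self.gene_ids, self.gene_lengths, self.counts):
                fh.write(gid + f"\t{int(length)}\t" +
                         "\t".join(str(int(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            names, labels = [], []
            for col in header[2:]:
                name, _, label = col.partition(":")
                names.append(name)
                labels.append(label or name)
            gene_ids, lengths, rows = [], [], []
            for line in fh:
                if not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                gene_ids.append(cols[0])
                lengths.append(float(cols[1]))
                rows.append([int(v) for v in cols[2:]])
        return cls(np.array(rows, dtype=np.int64), gene_ids,
                   np.array(lengths), labels, names)


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The pseudo-reference is the per-gene geometric mean across samples;
    each sample's factor is the median ratio to the reference over genes
    where the reference is nonzero.
    """
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        log_ref = np.mean(np.log(counts), axis=1)  # -inf where any zero
    usable = np.isfinite(log_ref)
    if not np.any(usable):
        raise ValueError("no gene with nonzero counts in all samples")
    log_ratios = np.log(counts[usable]) - log_ref[usable, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def rpkm(
    counts: np.ndarray,
    factors: np.ndarray,
    gene_lengths: np.ndarray,
) -> np.ndarray:
    """Reads per kB per million, computed on size-factor-normalized counts.

    The per-million anchor is the normalized library total (column sum of
    normalized counts), so RPKM is invariant under a common rescaling of
    all library sizes.
    """
    counts = np.asarray(counts, dtype=float)
    norm = counts / np.asarray(factors, dtype=float)[None, :]
    norm_lib = norm.sum(axis=0)
    if np.any(norm_lib <= 0):
        raise ValueError("zero normalized library total")
    lengths_kb = np.asarray(gene_lengths, dtype=float) / 1000.0
    return norm / lengths_kb[:, None] / (norm_lib[None, :] / 1e6)


def estimate_dispersion(norm_counts: np.ndarray, floor: float = DISPERSION_FLOOR):
    """Method-of-moments NB dispersion per gene from replicate columns.

    alpha = (var - mean) / mean^2, floored at ``floor``; genes with zero
    mean get the floor.
    """
    norm_counts = np.asarray(norm_counts, dtype=float)
    m = norm_counts.mean(axis=1)
    v = norm_counts.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m) / (m * m)
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    return np.maximum(alpha, floor)


def nb_tail_test(observed: int, mu: float, dispersion: float) -> float:
    """Two-sided NB tail p-value by probability-mass ordering.

    p is the total probability of all counts whose point mass does not
    exceed that of ``observed`` under NB(mean=mu, var=mu+dispersion*mu^2);
    dispersion 0 uses the Poisson limit.  The observed mode gives p = 1.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    observed = int(observed)
    if dispersion == 0:
        dist = sps.poisson(mu)
        sd = np.sqrt(mu)
    else:
        r = 1.0 / dispersion
        dist = sps.nbinom(r, r / (r + mu))
        sd = np.sqrt(mu + dispersion * mu * mu)
    hi = int(max(observed, mu + 10 * sd + 10, dist.ppf(1 - 1e-13))) + 1
    support = np.arange(0, hi + 1)
    pmf = dist.pmf(support)
    p_obs = pmf[observed] if observed <= hi else dist.pmf(observed)
    p = pmf[pmf <= p_obs * (1 + 1e-12)].sum()
    # mass beyond the computed support is below 1e-13 by construction
    return float(min(1.0, max(p, 0.0)))


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's combined probability: chi2_{2k} upper tail of -2 sum ln p."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0):
        raise ValueError("p-values must be > 0 (floor them first)")
    if np.any(p > 1):
        raise ValueError("p-values must be <= 1")
    x = -2.0 * np.log(p).sum()
    return float(sps.chi2.sf(x, df=2 * p.size))


@dataclass
class DECallConfig:
    p_combined_max: float = 0.05
    min_log2fc: float = 1.4
    min_log2rpkm_up: float = 1.0
    dispersion_floor: float = DISPERSION_FLOOR
    zero_mu_floor: float = 0.5  # normalized reads, when all controls are zero


def call_de(
    matrix: ExpressionMatrix,
    config: DECallConfig | None = None,
    factors: np.ndarray | None = None,
    control_label: str = "control",
    ko_label: str = "ko",
) -> pd.DataFrame:
    """Per-embryo-vs-all-controls DE calls with Fisher combination.

    For each gene and each KO sample j: p_j is the NB tail test of the
    (rounded) normalized KO count against the control mean with the
    control-replicate dispersion, and log2fc_j uses a 0.5-read pseudocount.
    status 'up' requires combined p < p_combined_max AND every log2fc_j >
    min_log2fc AND Log2(RPKM) > min_log2rpkm_up in every KO replicate;
    'down' is mirrored with the controls as the upregulated sample.
    """
    cfg = config or DECallConfig()
    labels = np.asarray(matrix.sample_labels)
    ctrl_idx = np.where(labels == control_label)[0]
    ko_idx = np.where(labels == ko_label)[0]
    if len(ctrl_idx) < 2 or len(ko_idx) < 1:
        raise ValueError("need >= 2 controls and >= 1 KO sample")
    if factors is None:
        factors = size_factors(matrix.counts)
    norm = matrix.counts / factors[None, :]
    rpkm_all = rpkm(matrix.counts, factors, matrix.gene_lengths)
    ctrl_norm = norm[:, ctrl_idx]
    ko_norm = norm[:, ko_idx]
    ctrl_mean = ctrl_norm.mean(axis=1)
    # Dispersion: per-gene method-of-moments, shared conservatively as the
    # maximum of the gene-wise and the global median estimate (the few
    # control replicates make gene-wise estimates noisy, and downward noise
    # is anti-conservative).  The test variance is further inflated by
    # (1 + 1/n_ctrl) plus a 1/(n_ctrl * mu) term because the control mean
    # is itself estimated from n_ctrl replicates.
    alpha = estimate_dispersion(ctrl_norm, floor=cfg.dispersion_floor)
    alpha = np.maximum(alpha, np.median(alpha))
    n_ctrl = len(ctrl_idx)

    n_genes = norm.shape[0]
    n_ko = len(ko_idx)
    pvals = np.ones((n_genes, n_ko))
    log2fc = np.zeros((n_genes, n_ko))
    nonzero = (matrix.counts.sum(axis=1) > 0)
    for g in range(n_genes):
        if not nonzero[g]:
            continue
        mu = max(ctrl_mean[g], cfg.zero_mu_floor)
        alpha_test = alpha[g] * (1 + 1 / n_ctrl) + 1 / (n_ctrl * mu)
        for j in range(n_ko):
            obs = int(round(ko_norm[g, j]))
            pvals[g, j] = nb_tail_test(obs, mu, alpha_test)
            log2fc[g, j] = np.log2(
                (ko_norm[g, j] + FC_PSEUDOCOUNT) / (ctrl_mean[g] + FC_PSEUDOCOUNT)
            )
    combined = np.array([
        fisher_combine(np.maximum(pvals[g], P_FLOOR)) for g in range(n_genes)
    ])

    log2rpkm_ko = np.log2(rpkm_all[:, ko_idx] + 1e-9)
    log2rpkm_ctrl = np.log2(rpkm_all[:, ctrl_idx] + 1e-9)
    sig = combined < cfg.p_combined_max
    up = (
        sig
        & nonzero
        & np.all(log2fc > cfg.min_log2fc, axis=1)
        & np.all(log2rpkm_ko > cfg.min_log2rpkm_up, axis=1)
    )
    down = (
        sig
        & nonzero
        & np.all(log2fc < -cfg.min_log2fc, axis=1)
        & np.all(log2rpkm_ctrl > cfg.min_log2rpkm_up, axis=1)
    )
    status = np.where(up, "up", np.where(down, "down", "unchanged"))

    out = pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "status": status,
        "combined_p": combined,
        "ctrl_mean_norm": ctrl_mean,
        "mean_log2rpkm_ko": log2rpkm_ko.mean(axis=1),
        "mean_log2rpkm_ctrl": log2rpkm_ctrl.mean(axis=1),
    })
    for j in range(n_ko):
        out[f"p_{matrix.sample_names[ko_idx[j]]}"] = pvals[:, j]
        out[f"log2fc_{matrix.sample_names[ko_idx[j]]}"] = log2fc[:, j]
    return out


def _directional_increase(
    matrix: ExpressionMatrix,
    from_label: str,
    to_label: str,
    p_max: float,
    min_log2fc: float,
    max_log2rpkm_low: float,
) -> set[str]:
    """Genes significantly higher in ``to_label`` than ``from_label`` whose
    expression in the lower stage stays below ``max_log2rpkm_low``."""
    cfg = DECallConfig(p_combined_max=p_max, min_log2fc=min_log2fc,
                       min_log2rpkm_up=-np.inf)
    res = call_de(matrix, cfg, control_label=from_label, ko_label=to_label)
    low_ok = res["mean_log2rpkm_ctrl"] < max_log2rpkm_low
    return set(res.loc[(res["status"] == "up") & low_ok, "gene_id"])


def call_state_transition(
    matrix: ExpressionMatrix,
    stage_a: str,
    stage_b: str,
    p_max: float = 0.05,
    min_log2fc: float = 1.0,
    max_log2rpkm_low: float = 4.0,
) -> tuple[set[str], set[str]]:
    """(activated, repressed) gene sets going from stage A to stage B.

    Activated genes increase significantly in B with Log2(RPKM) < 4 in A
    (the lower stage); repressed genes are the activated set of the swapped
    comparison, so repressed(A,B) == activated(B,A) holds exactly.
    """
    activated = _directional_increase(matrix, stage_a, stage_b,
                                      p_max, min_log2fc, max_log2rpkm_low)
    repressed = _directional_increase(matrix, stage_b, stage_a,
                                      p_max, min_log2fc, max_log2rpkm_low)
    return activated, repressed


def chromosome_enrichment(
    de_gene_ids: Sequence[str],
    all_genes_chroms: dict[str, str],
    chrom: str = "chrX",
) -> tuple[float, float]:
    """Fraction of DE genes on ``chrom`` and hypergeometric upper-tail p.

    Population: all annotated genes; successes: genes on ``chrom``;
    draws: the DE set.  p = P(X >= observed).
    """
    n_pop = len(all_genes_chroms)
    n_chrom = sum(1 for c in all_genes_chroms.values() if c == chrom)
    de = [g for g in de_gene_ids if g in all_genes_chroms]
    n_draw = len(de)
    obs = sum(1 for g in de if all_genes_chroms[g] == chrom)
    if n_draw == 0:
        return 0.0, 1.0
    p = float(sps.hypergeom.sf(obs - 1, n_pop, n_chrom, n_draw))
    return obs / n_draw, min(1.0, p)
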