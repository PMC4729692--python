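"""Seeded generators for every pipeline input, with planted ground truth.

The generators emulate the statistical structure of the study's datasets:
negative-binomially dispersed RNA-seq counts from 4 knockout and 4 control
embryos with planted log2 fold-changes, Poisson ChIP/input region counts
with planted enrichment at marked regions (two replicates), repeat
subfamilies with elevated marked/upregulated locus fractions, sequences
with motif occurrences planted in H3K9me2-class enhancers, and
beta-distributed CpG methylation (high at H3K9me2-marked, low at
H3K27me3-marked regions).

Everything is deterministic given ``SimulationConfig.seed``; stage-specific
substreams are derived from it so generators can be called independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .diffexpr import ExpressionMatrix
from .genome_io import AnnotationSet, GeneModel, GenomicInterval, promoter_of
from .chip_enrichment import RegionCountTable

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "child_rng",
    "simulate_genome",
    "simulate_chip_counts",
    "simulate_expression",
    "simulate_repeats",
    "simulate_sequences",
    "simulate_methylation",
    "simulate_genome_sequence",
    "random_sequences",
]

ENHANCER_HALF_WIDTH = 800  # summit +/- 800 -> 1601 bp regions


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic datasets.

    Replicate structure mirrors the study design: two ChIP biological
    replicates; four KO and four control single epiblasts (three + three
    for the Ezh2 line, via the fields).  Marking fractions are mutually
    exclusive between the two repressive marks by default.
    """

    seed: int  # mandatory
    n_chroms: int = 4  # last chromosome is named chrX
    chrom_len_bp: int = 3_000_000
    n_genes: int = 800
    gene_len_range_bp: tuple[int, int] = (2_000, 10_000)
    frac_genes_chrx: float = 0.05
    n_enhancers: int = 300
    n_repeat_subfamilies: int = 20
    loci_per_subfamily: int = 100
    repeat_len_range_bp: tuple[int, int] = (300, 600)
    n_ctrl_embryos: int = 4
    n_ko_embryos: int = 4
    n_chip_replicates: int = 2
    frac_marked_k9: float = 0.10
    frac_marked_k27: float = 0.10
    planted_chip_log2fc: float = 2.0
    planted_de_log2fc: float = 3.0
    frac_de: float = 0.04
    de_chrx_bias: float = 0.3  # fraction of planted DE genes drawn X-linked
    # fraction of autosomal DE genes drawn from targets of the deleted
    # writer's mark (K9 for an Ehmt2-like KO); cross-mark overlap stays null
    de_from_marked_frac: float = 0.6
    nb_dispersion: float = 0.1
    baseline_mean: float = 100.0
    baseline_log2_sd: float = 0.75
    lib_factor_log_sd: float = 0.2
    mean_depth_per_region: float = 50.0  # input reads per region per kb unit
    chip_nb_dispersion: float = 0.0  # 0 -> Poisson ChIP noise
    # enhancer state transitions (stage A active -> stage B)
    frac_enh_k9_gaining: float = 0.12
    frac_enh_k27_poised: float = 0.15
    frac_decoy_p300: float = 0.25
    # repeats
    n_regulated_subfamilies: int = 3
    reg_frac_marked: float = 0.6
    reg_frac_up: float = 0.3
    bg_frac_marked: float = 0.1
    bg_frac_up: float = 0.01
    # motifs; consensus width >= 10 keeps site p = 1e-5 achievable under a
    # uniform background (min tail mass 0.25^w must be below the threshold)
    motif_consensus: str = "TGACGTCATC"
    planted_motif_rate: float = 0.5
    # methylation
    beta_params_meth_high: tuple[float, float] = (8.0, 2.0)
    beta_params_meth_low: tuple[float, float] = (2.0, 8.0)
    beta_params_meth_neutral: tuple[float, float] = (6.0, 4.0)
    cpgs_per_region: int = 20
    promoter_upstream: int = 2000
    promoter_downstream: int = 500

    def __post_init__(self) -> None:
        fracs = [self.frac_marked_k9, self.frac_marked_k27, self.frac_de,
                 self.frac_enh_k9_gaining, self.frac_enh_k27_poised,
                 self.reg_frac_marked, self.reg_frac_up,
                 self.bg_frac_marked, self.bg_frac_up]
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_marked_k9 + self.frac_marked_k27 > 1.0:
            raise ValueError("frac_marked_k9 + frac_marked_k27 must be <= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators."""

    gene_marks: dict[str, str | None] = field(default_factory=dict)  # K9/K27/None
    de_genes: dict[str, str] = field(default_factory=dict)  # gene_id -> 'up'
    enhancers: list[GenomicInterval] = field(default_factory=list)
    enhancer_states: dict[str, str] = field(default_factory=dict)
    true_enhancer_peak_ids: set[str] = field(default_factory=set)
    p300_peaks: list[GenomicInterval] = field(default_factory=list)
    k27ac_peaks: list[GenomicInterval] = field(default_factory=list)
    k4me1_peaks: list[GenomicInterval] = field(default_factory=list)
    repeat_marked: dict[str, bool] = field(default_factory=dict)  # locus, K9
    repeat_up: dict[str, bool] = field(default_factory=dict)
    regulated_subfamilies: set[str] = field(default_factory=set)
    motif_positions: dict[str, list[int]] = field(default_factory=dict)


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Named substream: a generator seeded from (seed, crc32(stage))."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


def child_seed(seed: int, stage: str) -> int:
    """A derived integer seed below 2**31 for APIs that want a plain int."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# genome / annotation
# ---------------------------------------------------------------------------


def simulate_genome(config: SimulationConfig) -> tuple[AnnotationSet, PlantedTruth]:
    """Non-overlapping genes, intergenic enhancers with their peak evidence,
    and subfamily-labelled repeat loci, all with planted truth."""
    rng = child_rng(config.seed, "genome")
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms - 1)] + ["chrX"]
    sizes = {c: config.chrom_len_bp for c in chroms}

    # assign gene counts per chromosome (~frac_genes_chrx on chrX)
    n_x = max(1, int(round(config.frac_genes_chrx * config.n_genes)))
    autosomes = chroms[:-1]
    per_auto = np.full(len(autosomes), (config.n_genes - n_x) // len(autosomes))
    per_auto[: (config.n_genes - n_x) % len(autosomes)] += 1

    genes: list[GeneModel] = []
    gaps: list[GenomicInterval] = []  # intergenic space for enhancers/repeats
    gi = 0
    for chrom, n_on_chrom in zip(chroms, list(per_auto) + [n_x]):
        lens = rng.integers(config.gene_len_range_bp[0],
                            config.gene_len_range_bp[1] + 1, n_on_chrom)
        total_gap = sizes[chrom] - int(lens.sum())
        if total_gap <= n_on_chrom:
            raise ValueError("chromosome too short for requested genes")
        gap_sizes = rng.multinomial(total_gap, np.ones(n_on_chrom + 1) / (n_on_chrom + 1))
        pos = 0
        for j in range(n_on_chrom):
            pos += int(gap_sizes[j])
            start, end = pos, pos + int(lens[j])
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"g{gi:05d}"
            cpg = rng.choice(["HCP", "ICP", "LCP"], p=[0.6, 0.2, 0.2])
            genes.append(GeneModel(
                GenomicInterval(chrom, start, end, strand, gid, "gene_body"),
                gid, f"Gene{gi}", str(cpg),
            ))
            if gap_sizes[j] > 2 * ENHANCER_HALF_WIDTH + 10:
                gaps.append(GenomicInterval(chrom, pos - int(gap_sizes[j]), pos))
            pos = end
            gi += 1
        if gap_sizes[n_on_chrom] > 2 * ENHANCER_HALF_WIDTH + 10:
            gaps.append(GenomicInterval(chrom, pos, sizes[chrom]))

    truth = PlantedTruth()

    # planted promoter marks, mutually exclusive
    n_k9 = int(round(config.frac_marked_k9 * config.n_genes))
    n_k27 = int(round(config.frac_marked_k27 * config.n_genes))
    perm = rng.permutation(config.n_genes)
    for idx in perm[:n_k9]:
        truth.gene_marks[genes[idx].gene_id] = "K9"
    for idx in perm[n_k9 : n_k9 + n_k27]:
        truth.gene_marks[genes[idx].gene_id] = "K27"
    for g in genes:
        truth.gene_marks.setdefault(g.gene_id, None)

    # planted DE genes (upregulated in KO): drawn preferentially from
    # repressive-mark targets (loss of the writer de-represses them) and
    # X-biased, mirroring the X-linked cluster de-repression
    n_de = int(round(config.frac_de * config.n_genes))
    x_ids = [g.gene_id for g in genes if g.chrom == "chrX"]
    n_de_x = min(len(x_ids), int(round(config.de_chrx_bias * n_de)))
    de_ids = list(rng.choice(x_ids, n_de_x, replace=False)) if n_de_x else []
    marked_auto = [g.gene_id for g in genes
                   if g.chrom != "chrX" and truth.gene_marks[g.gene_id] == "K9"]
    unmarked_auto = [g.gene_id for g in genes
                     if g.chrom != "chrX" and truth.gene_marks[g.gene_id] != "K9"]
    n_rest = n_de - n_de_x
    n_de_marked = min(len(marked_auto),
                      int(round(config.de_from_marked_frac * n_rest)))
    de_ids += list(rng.choice(marked_auto, n_de_marked, replace=False))
    de_ids += list(rng.choice(unmarked_auto, n_rest - n_de_marked, replace=False))
    for gid in de_ids:
        truth.de_genes[gid] = "up"

    # enhancers in intergenic gaps, plus peak evidence; all are stage-A
    # active.  The margin keeps enhancer regions (and their peaks) clear of
    # promoter windows extending into the gap from the flanking genes.
    margin = ENHANCER_HALF_WIDTH + config.promoter_upstream + 10
    usable = [g for g in gaps if g.length > 2 * margin]
    weights = np.array([g.length - 2 * margin for g in usable], dtype=float)
    weights /= weights.sum()
    state_p = [1 - config.frac_enh_k9_gaining - config.frac_enh_k27_poised,
               config.frac_enh_k9_gaining, config.frac_enh_k27_poised]
    for e in range(config.n_enhancers):
        gap = usable[int(rng.choice(len(usable), p=weights))]
        summit = int(rng.integers(gap.start + margin, gap.end - margin))
        eid = f"enh{e:04d}"
        region = GenomicInterval(gap.chrom, summit - ENHANCER_HALF_WIDTH,
                                 summit + ENHANCER_HALF_WIDTH + 1, ".", eid,
                                 "enhancer")
        truth.enhancers.append(region)
        truth.enhancer_states[eid] = str(rng.choice(
            ["active", "k9_gaining", "k27_poised"], p=state_p))
        pid = f"p300_{e:04d}"
        truth.true_enhancer_peak_ids.add(pid)
        for peaks, name in ((truth.p300_peaks, pid),
                            (truth.k27ac_peaks, f"k27ac_{e:04d}"),
                            (truth.k4me1_peaks, f"k4me1_{e:04d}")):
            half = int(rng.integers(150, 400))
            jitter = int(rng.integers(-100, 101))
            peaks.append(GenomicInterval(gap.chrom, summit + jitter - half,
                                         summit + jitter + half, ".", name, "peak"))

    # decoy p300 peaks: promoter-overlapping or lacking co-marks
    n_decoy = int(round(config.frac_decoy_p300 * config.n_enhancers))
    for d in range(n_decoy):
        pid = f"p300_decoy{d:04d}"
        if rng.random() < 0.5 and genes:
            g = genes[int(rng.integers(len(genes)))]
            summit = g.tss + int(rng.integers(-200, 201))
            chrom = g.chrom
        else:
            gap = usable[int(rng.choice(len(usable), p=weights))]
            summit = int(rng.integers(gap.start + margin, gap.end - margin))
            chrom = gap.chrom
        half = int(rng.integers(150, 400))
        summit = max(summit, half + 1)  # keep the peak inside the chromosome
        truth.p300_peaks.append(
            GenomicInterval(chrom, summit - half, summit + half, ".", pid, "peak"))
        # decoys carry no K27ac/K4me1 evidence, so the three-way rule drops them

    # repeat loci: uniform placement, may overlap genes (introns)
    repeats: list[GenomicInterval] = []
    subfams: list[str] = []
    classes: list[str] = []
    class_cycle = ["ERV-L", "ERV-LMaLR", "ERVK", "LINE-L1", "SINE-B1"]
    reg = set()
    for s in range(config.n_repeat_subfamilies):
        name = f"subfam{s:02d}"
        if s < config.n_regulated_subfamilies:
            reg.add(name)
        for l in range(config.loci_per_subfamily):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(*config.repeat_len_range_bp))
            start = int(rng.integers(0, sizes[chrom] - length))
            lid = f"{name}_locus{l:03d}"
            repeats.append(GenomicInterval(chrom, start, start + length,
                                           "+" if rng.random() < 0.5 else "-",
                                           lid, "repeat_locus"))
            subfams.append(name)
            classes.append(class_cycle[s % len(class_cycle)])
            f_marked = config.reg_frac_marked if name in reg else config.bg_frac_marked
            f_up = config.reg_frac_up if name in reg else config.bg_frac_up
            truth.repeat_marked[lid] = bool(rng.random() < f_marked)
            truth.repeat_up[lid] = bool(rng.random() < f_up)
    truth.regulated_subfamilies = reg

    ann = AnnotationSet(genes, sizes, repeats, subfams, classes)
    ann.validate()
    return ann, truth


# ---------------------------------------------------------------------------
# ChIP counts
# ---------------------------------------------------------------------------


def simulate_chip_counts(
    regions: Sequence[GenomicInterval],
    marked_ids: set[str],
    config: SimulationConfig,
    mark: str = "H3K9me2",
    cell_type: str = "epiblast",
    rng: np.random.Generator | None = None,
    log2fc: float | None = None,
) -> RegionCountTable:
    """Poisson ChIP/input counts with planted enrichment at marked regions.

    input ~ Poisson(depth * length_kb); chip ~ Poisson(depth * length_kb *
    2^log2fc) at marked regions and Poisson(depth * length_kb) elsewhere,
    independently per replicate.  Library totals are the nominal genome-wide
    read count (depth per kB times total region kB), identical for ChIP and
    input, so the per-million normalization is neutral and the planted
    log2FC is recovered on the enrichment scale.
    """
    if rng is None:
        rng = child_rng(config.seed, f"chip:{mark}:{cell_type}")
    if log2fc is None:
        log2fc = config.planted_chip_log2fc
    depth = config.mean_depth_per_region
    len_kb = np.array([r.length for r in regions], dtype=float) / 1000.0
    marked = np.array([r.id in marked_ids for r in regions])
    base_mu = depth * len_kb
    chip_mu = base_mu * np.where(marked, 2.0 ** log2fc, 1.0)
    n_rep = config.n_chip_replicates
    if config.chip_nb_dispersion > 0:
        r = 1.0 / config.chip_nb_dispersion

        def draw(mu: np.ndarray) -> np.ndarray:
            return rng.negative_binomial(r, r / (r + mu), size=(n_rep, len(mu))).T

    else:

        def draw(mu: np.ndarray) -> np.ndarray:
            return rng.poisson(mu, size=(n_rep, len(mu))).T

    chip = draw(chip_mu) if depth > 0 else np.zeros((len(regions), n_rep), dtype=int)
    inp = draw(base_mu) if depth > 0 else np.zeros((len(regions), n_rep), dtype=int)
    nominal = max(1, int(round(depth * len_kb.sum())))
    if depth == 0:
        nominal_arr = np.zeros(n_rep, dtype=int)
        # zero-depth: all-zero counts; library totals of 0 are recorded as-is
        return RegionCountTable(list(regions), chip, inp, nominal_arr,
                                nominal_arr, mark, cell_type)
    totals = np.full(n_rep, nominal, dtype=int)
    return RegionCountTable(list(regions), chip, inp, totals, totals,
                            mark, cell_type)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float
             ) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


def simulate_expression(
    annotation: AnnotationSet,
    truth: PlantedTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """NB counts for control and KO embryos with planted upregulation.

    counts ~ NB(mean = baseline_i * lib_j * 2^(log2fc_i * is_ko_j),
    dispersion = nb_dispersion); library factors are log-normal (sd
    ``lib_factor_log_sd``); baselines log-normal around ``baseline_mean``.
    """
    if rng is None:
        rng = child_rng(config.seed, "expression")
    genes = annotation.genes
    n = len(genes)
    baselines = config.baseline_mean * 2.0 ** rng.normal(
        0.0, config.baseline_log2_sd, n)
    n_samples = config.n_ctrl_embryos + config.n_ko_embryos
    libs = np.exp(rng.normal(0.0, config.lib_factor_log_sd, n_samples))
    is_ko = np.array([0] * config.n_ctrl_embryos + [1] * config.n_ko_embryos)
    lfc = np.array([
        config.planted_de_log2fc if truth.de_genes.get(g.gene_id) == "up" else 0.0
        for g in genes
    ])
    mu = baselines[:, None] * libs[None, :] * 2.0 ** (lfc[:, None] * is_ko[None, :])
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    labels = ["control"] * config.n_ctrl_embryos + ["ko"] * config.n_ko_embryos
    names = [f"ctrl_{i + 1}" for i in range(config.n_ctrl_embryos)] + [
        f"ko_{i + 1}" for i in range(config.n_ko_embryos)
    ]
    lengths = np.array([g.interval.length for g in genes], dtype=float)
    return ExpressionMatrix(counts.astype(np.int64),
                            [g.gene_id for g in genes], lengths, labels, names)


def simulate_repeats(
    annotation: AnnotationSet,
    truth: PlantedTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    baseline_mean: float = 50.0,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Unique-locus repeat counts plus per-sample protein-coding totals.

    Loci flagged upregulated in the truth get the planted DE log2FC in KO
    samples.  Returns (matrix, pc_read_totals); the matrix sample labels
    mirror the embryo design.
    """
    if rng is None:
        rng = child_rng(config.seed, "repeats")
    loci = annotation.repeats
    n = len(loci)
    n_samples = config.n_ctrl_embryos + config.n_ko_embryos
    libs = np.exp(rng.normal(0.0, config.lib_factor_log_sd, n_samples))
    is_ko = np.array([0] * config.n_ctrl_embryos + [1] * config.n_ko_embryos)
    baselines = baseline_mean * 2.0 ** rng.normal(0.0, 0.5, n)
    lfc = np.array([
        config.planted_de_log2fc if truth.repeat_up.get(l.id) else 0.0
        for l in loci
    ])
    mu = baselines[:, None] * libs[None, :] * 2.0 ** (lfc[:, None] * is_ko[None, :])
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    labels = ["control"] * config.n_ctrl_embryos + ["ko"] * config.n_ko_embryos
    names = [f"ctrl_{i + 1}" for i in range(config.n_ctrl_embryos)] + [
        f"ko_{i + 1}" for i in range(config.n_ko_embryos)
    ]
    lengths = np.array([l.length for l in loci], dtype=float)
    pc_totals = np.round(1e6 * libs).astype(np.int64)
    matrix = ExpressionMatrix(counts.astype(np.int64), [l.id for l in loci],
                              lengths, labels, names)
    return matrix, pc_totals


# ---------------------------------------------------------------------------
# sequences / motifs
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def random_sequences(
    widths: Sequence[int],
    rng: np.random.Generator,
    base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> list[str]:
    """IID background sequences of the given widths."""
    probs = np.asarray(base_probs, dtype=float)
    probs = probs / probs.sum()
    return [
        bytes(_BASES[rng.choice(4, int(w), p=probs)]).decode()
        for w in widths
    ]


def simulate_sequences(
    truth: PlantedTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], PlantedTruth]:
    """Enhancer-region sequences with the consensus motif planted in
    H3K9me2-class enhancers at ``planted_motif_rate``.

    Planted occurrence offsets are recorded in ``truth.motif_positions``.
    """
    if rng is None:
        rng = child_rng(config.seed, "sequences")
    motif = config.motif_consensus.upper()
    w = len(motif)
    seqs: dict[str, str] = {}
    truth.motif_positions = {}
    for region in truth.enhancers:
        eid = region.id
        seq = random_sequences([region.length], rng)[0]
        positions: list[int] = []
        if (truth.enhancer_states.get(eid) == "k9_gaining"
                and rng.random() < config.planted_motif_rate):
            off = int(rng.integers(0, region.length - w + 1))
            if rng.random() < 0.5:
                planted = motif
            else:
                planted = "".join(_COMP[b] for b in reversed(motif))
            seq = seq[:off] + planted + seq[off + w:]
            positions.append(off)
        seqs[eid] = seq
        truth.motif_positions[eid] = positions
    return seqs, truth


def simulate_genome_sequence(
    annotation: AnnotationSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Uniform-composition chromosome sequences matching chrom_sizes."""
    if rng is None:
        rng = child_rng(config.seed, "genome_sequence")
    return {
        chrom: bytes(_BASES[rng.integers(0, 4, size)]).decode()
        for chrom, size in annotation.chrom_sizes.items()
    }


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------


def simulate_methylation(
    annotation: AnnotationSet,
    truth: PlantedTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Per-CpG methylation fractions for each gene promoter.

    K9-marked regions draw Beta(8,2) (hypermethylated), K27-marked Beta(2,8)
    (hypomethylated), unmarked Beta(6,4); returns a mapping
    region_id -> array of CpG methylation fractions.
    """
    if rng is None:
        rng = child_rng(config.seed, "methylation")
    out: dict[str, np.ndarray] = {}
    for g in annotation.genes:
        mark = truth.gene_marks.get(g.gene_id)
        if mark == "K9":
            a, b = config.beta_params_meth_high
        elif mark == "K27":
            a, b = config.beta_params_meth_low
        else:
            a, b = config.beta_params_meth_neutral
        out[f"{g.gene_id}_promoter"] = rng.beta(a, b, config.cpgs_per_region)
    return out


def promoters_of(annotation: AnnotationSet, config: SimulationConfig
                 ) -> list[GenomicInterval]:
    """Promoter windows for every gene, using the configured window."""
    return [
        promoter_of(g, config.promoter_upstream, config.promoter_downstream,
                    annotation.chrom_sizes.get(g.chrom))
        for g in annotation.genes
    ]
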