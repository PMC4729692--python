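"""Region data model, interval arithmetic and flat-file readers/writers.

All coordinates are 0-based half-open internally (BED native); any 1-based
display is formatting only.  Every other module consumes the types defined
here: :class:`GenomicInterval` is the unit of all region math,
:class:`GeneModel` adds a transcription start site and CpG-density class,
and :class:`AnnotationSet` bundles genes, chromosome sizes and repeat loci.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "BedParseError",
    "GenomicInterval",
    "GeneModel",
    "AnnotationSet",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gene_table",
    "write_gene_table",
    "make_tiles",
    "promoter_of",
    "intersect",
    "merge_intervals",
    "nearest_gene",
    "cpg_class_from_sequence",
    "read_fasta",
    "write_fasta",
]

REGION_KINDS = {
    "gene_body",
    "promoter",
    "tile",
    "enhancer",
    "repeat_locus",
    "peak",
    "other",
}


class BedParseError(ValueError):
    """Raised for malformed BED/TSV input, naming the offending line."""


@dataclass
class GenomicInterval:
    """A 0-based half-open genomic region.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded); ``kind`` is one
    of :data:`REGION_KINDS` and records what the region annotates.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""
    kind: str = "other"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not self.id:
            self.id = f"{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene body plus the attributes the analyses key on.

    The TSS is derived from the strand: ``interval.start`` on ``+`` and
    ``interval.end - 1`` on ``-``.  ``cpg_class`` is the promoter CpG
    density class (HCP/ICP/LCP), supplied as an input label.
    """

    interval: GenomicInterval
    gene_id: str
    gene_name: str = ""
    cpg_class: str = "HCP"

    def __post_init__(self) -> None:
        if self.cpg_class not in ("HCP", "ICP", "LCP"):
            raise ValueError(f"cpg_class must be HCP/ICP/LCP, got {self.cpg_class!r}")
        if self.interval.strand not in ("+", "-"):
            raise ValueError("genes must be stranded")
        if not self.gene_name:
            self.gene_name = self.gene_id

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


@dataclass
class AnnotationSet:
    """Genes, chromosome sizes and repeat loci for one genome build."""

    genes: list[GeneModel] = field(default_factory=list)
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    repeats: list[GenomicInterval] = field(default_factory=list)
    # parallel to `repeats`: RepeatMasker-style subfamily and class labels
    repeat_subfamilies: list[str] = field(default_factory=list)
    repeat_classes: list[str] = field(default_factory=list)

    def validate(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene ids in annotation")
        for g in self.genes:
            size = self.chrom_sizes.get(g.chrom)
            if size is None or g.interval.end > size:
                raise ValueError(f"gene {g.gene_id} outside chromosome bounds")
        if self.repeats:
            if len(self.repeats) != len(self.repeat_subfamilies):
                raise ValueError("repeat subfamily labels missing")
            if any(not s for s in self.repeat_subfamilies):
                raise ValueError("empty repeat subfamily label")

    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, kind: str = "other") -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals, preserving order and coordinates."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = cols[3] if len(cols) > 3 and cols[3] != "." else ""
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
            try:
                out.append(
                    GenomicInterval(cols[0], start, end, strand, name, kind)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6; round-trips with :func:`read_bed` on coordinates, ids, strands."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t0\t{iv.strand}\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise BedParseError(f"{path}: line {lineno}: expected 2 columns")
            sizes[cols[0]] = int(cols[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


_GENE_COLS = ["gene_id", "gene_name", "chrom", "start", "end", "strand", "cpg_class"]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read the flat gene annotation TSV (a deliberate simplification of GTF)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GENE_COLS:
            raise BedParseError(f"{path}: unexpected gene table header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            gid, name, chrom, start, end, strand, cpg = line.rstrip("\n").split("\t")
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand, gid, "gene_body")
                genes.append(GeneModel(iv, gid, name, cpg))
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLS) + "\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{g.gene_id}\t{g.gene_name}\t{iv.chrom}\t{iv.start}\t{iv.end}"
                f"\t{iv.strand}\t{g.cpg_class}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id (order-preserving dict)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------


def make_tiles(
    chrom_sizes: dict[str, int], tile_len: int = 1000, offset: int = 500
) -> list[GenomicInterval]:
    """Genome-wide tiles of ``tile_len`` bp at starts 0, offset, 2*offset, ...

    A tile is emitted iff it fits entirely in the chromosome; one final
    truncated tile is appended when the full tiles do not already reach
    the chromosome end, so base coverage is conserved.
    """
    if tile_len <= 0:
        raise ValueError("tile_len must be positive")
    if not (0 < offset <= tile_len):
        raise ValueError("require 0 < offset <= tile_len")
    tiles: list[GenomicInterval] = []
    for chrom, size in chrom_sizes.items():
        covered_to = 0
        start = 0
        i = 0
        while start < size:
            if start + tile_len <= size:
                tiles.append(
                    GenomicInterval(chrom, start, start + tile_len, ".",
                                    f"{chrom}_tile{i}", "tile")
                )
                covered_to = start + tile_len
            else:
                if size > covered_to:
                    tiles.append(
                        GenomicInterval(chrom, start, size, ".",
                                        f"{chrom}_tile{i}", "tile")
                    )
                break
            start += offset
            i += 1
    return tiles


def promoter_of(
    gene: GeneModel,
    upstream: int = 2000,
    downstream: int = 500,
    chrom_size: int | None = None,
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped to the chromosome.

    On ``+`` the window is [tss - upstream, tss + downstream); on ``-`` it is
    mirrored around the TSS.
    """
    tss = gene.tss
    if gene.interval.strand == "+":
        start, end = tss - upstream, tss + downstream
    else:
        # mirrored: `downstream` bases into the gene, `upstream` past the TSS
        start, end = tss - downstream, tss + upstream
    start = max(0, start)
    if chrom_size is not None:
        end = min(end, chrom_size)
    return GenomicInterval(
        gene.chrom, start, end, gene.interval.strand,
        f"{gene.gene_id}_promoter", "promoter",
    )


def intersect(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All pairs (x, y) with x from a, y from b sharing a chromosome and
    half-open overlap (x.start < y.end and y.start < x.end)."""
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in b:
        by_chrom[iv.chrom].append(iv)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    for x in a:
        cand = by_chrom.get(x.chrom)
        if not cand:
            continue
        starts = [iv.start for iv in cand]
        hi = bisect.bisect_left(starts, x.end)
        for y in cand[:hi]:
            if y.end > x.start:
                pairs.append((x, y))
    return pairs


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of disjoint merged blocks."""
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def nearest_gene(
    interval: GenomicInterval, genes: Sequence[GeneModel]
) -> tuple[GeneModel, int]:
    """Closest gene by edge distance (0 if overlapping); ties break to the
    lexicographically smaller gene_id."""
    if not genes:
        raise ValueError("empty gene list")
    best: tuple[int, str, GeneModel] | None = None
    for g in genes:
        if g.chrom != interval.chrom:
            continue
        iv = g.interval
        if interval.overlaps(iv):
            d = 0
        elif iv.start >= interval.end:
            d = iv.start - interval.end
        else:
            d = interval.start - iv.end
        key = (d, g.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (d, g.gene_id, g)
    if best is None:
        raise ValueError(f"no gene on chromosome {interval.chrom}")
    return best[2], best[0]


# ---------------------------------------------------------------------------
# CpG promoter classes
# ---------------------------------------------------------------------------


def cpg_class_from_sequence(
    seq: str,
    window: int = 500,
    hcp_oe: float = 0.75,
    hcp_gc: float = 0.55,
    lcp_oe: float = 0.48,
) -> str:
    """Weber-style CpG promoter classification from sequence.

    HCP if any ``window`` bp stretch has CpG observed/expected > ``hcp_oe``
    and GC fraction > ``hcp_gc``; LCP if no window reaches ``lcp_oe``
    observed/expected; ICP otherwise.  Sequences shorter than ``window``
    are scored as a single window.
    """
    s = seq.upper()
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    win = min(window, n)
    best_oe = 0.0
    is_hcp = False
    step = max(1, win // 5)
    for start in range(0, n - win + 1, step):
        sub = s[start : start + win]
        c = sub.count("C")
        g = sub.count("G")
        cpg = sub.count("CG")
        exp = c * g / win
        oe = cpg / exp if exp > 0 else 0.0
        gc = (c + g) / win
        best_oe = max(best_oe, oe)
        if oe > hcp_oe and gc > hcp_gc:
            is_hcp = True
    if is_hcp:
        return "HCP"
    if best_oe < lcp_oe:
        return "LCP"
    return "ICP"
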