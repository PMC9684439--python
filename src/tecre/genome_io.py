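"""Genomic annotations, interval arithmetic and file I/O.

All coordinates are kept 0-based half-open internally.  GTF input
(1-based, inclusive) is converted on read and back on write; BED is
native.  TE integrants carry their subfamily, family/class and an
evolutionary-age category in the BED name field using the dialect
``subfamily|family|age[|locus_id]`` (the locus id is optional on read
and regenerated from the line number when absent).
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_STRANDS = {"+", "-", "."}


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need end > start >= 0)"
            )
        if self.strand not in _STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Genome:
    """Chromosome name -> length table."""

    sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.sizes.items():
            if length <= 0:
                raise AnnotationError(f"chromosome {chrom} has length {length}")

    @property
    def chroms(self) -> list[str]:
        return list(self.sizes)

    @property
    def total_size(self) -> int:
        return sum(self.sizes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]

    def contains_interval(self, iv: GenomicInterval) -> bool:
        return iv.chrom in self.sizes and iv.end <= self.sizes[iv.chrom]

    @classmethod
    def read(cls, path: str | Path) -> "Genome":
        sizes: dict[str, int] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise AnnotationError(f"{path}:{i}: expected 'chrom<TAB>length'")
            chrom, length = parts[0], parts[1]
            if chrom in sizes:
                raise AnnotationError(f"{path}:{i}: duplicate chromosome {chrom}")
            sizes[chrom] = int(length)
        return cls(sizes)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self.sizes.items():
                fh.write(f"{chrom}\t{length}\n")


@dataclass(frozen=True)
class TEIntegrant:
    """One genomic copy of a transposable element."""

    interval: GenomicInterval
    locus_id: str
    subfamily: str
    family_class: str = ""
    age_category: str = ""
    merged_children: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.subfamily:
            raise AnnotationError(f"integrant {self.locus_id} has empty subfamily")


class TEAnnotation:
    """A sorted collection of TE integrants on a genome, indexed by subfamily."""

    def __init__(self, genome: Genome, integrants: Iterable[TEIntegrant]):
        self.genome = genome
        self.integrants = sorted(
            integrants, key=lambda t: (t.interval.chrom, t.interval.start, t.interval.end)
        )
        seen: set[str] = set()
        for te in self.integrants:
            if not genome.contains_interval(te.interval):
                raise AnnotationError(
                    f"integrant {te.locus_id} at {te.interval.chrom}:"
                    f"{te.interval.start}-{te.interval.end} exceeds chromosome bounds"
                )
            if te.locus_id in seen:
                raise AnnotationError(f"duplicate locus_id {te.locus_id}")
            seen.add(te.locus_id)
        self._by_subfamily: dict[str, list[TEIntegrant]] = {}
        for te in self.integrants:
            self._by_subfamily.setdefault(te.subfamily, []).append(te)

    def __len__(self) -> int:
        return len(self.integrants)

    def __iter__(self) -> Iterator[TEIntegrant]:
        return iter(self.integrants)

    @property
    def subfamilies(self) -> list[str]:
        return sorted(self._by_subfamily)

    def by_subfamily(self, subfamily: str) -> list[TEIntegrant]:
        return self._by_subfamily.get(subfamily, [])

    def by_locus_id(self) -> dict[str, TEIntegrant]:
        return {te.locus_id: te for te in self.integrants}

    def intervals(self) -> list[GenomicInterval]:
        return [te.interval for te in self.integrants]

    def subset(self, predicate) -> "TEAnnotation":
        return TEAnnotation(self.genome, [t for t in self.integrants if predicate(t)])

    @classmethod
    def read_bed(cls, path: str | Path, genome: Genome) -> "TEAnnotation":
        integrants = []
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise AnnotationError(f"{path}:{i}: need >=6 BED columns")
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{i}: non-integer coordinate") from exc
            if end_i <= start_i:
                raise AnnotationError(f"{path}:{i}: end <= start")
            fields = name.split("|")
            subfamily = fields[0]
            family = fields[1] if len(fields) > 1 else ""
            age = fields[2] if len(fields) > 2 else ""
            locus_id = fields[3] if len(fields) > 3 and fields[3] else f"{subfamily}_{i}"
            try:
                iv = GenomicInterval(chrom, start_i, end_i, strand)
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{i}: {exc}") from exc
            integrants.append(TEIntegrant(iv, locus_id, subfamily, family, age))
        return cls(genome, integrants)

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for te in self.integrants:
                name = (
                    f"{te.subfamily}|{te.family_class}|{te.age_category}|{te.locus_id}"
                )
                fh.write(
                    f"{te.interval.chrom}\t{te.interval.start}\t{te.interval.end}"
                    f"\t{name}\t0\t{te.interval.strand}\n"
                )


@dataclass(frozen=True)
class Gene:
    """Protein-coding (or other biotype) gene model with strand-aware TSS."""

    gene_id: str
    biotype: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        for ex in self.exons:
            if not (
                ex.chrom == self.interval.chrom
                and ex.start >= self.interval.start
                and ex.end <= self.interval.end
            ):
                raise AnnotationError(f"gene {self.gene_id}: exon outside gene body")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """5' end of the gene model: start on +, end-1 on -."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1


class GeneAnnotation:
    """Sorted gene models on a genome."""

    def __init__(self, genome: Genome, genes: Iterable[Gene]):
        self.genome = genome
        self.genes = sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start))
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            if not genome.contains_interval(g.interval):
                raise AnnotationError(f"gene {g.gene_id} exceeds chromosome bounds")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def protein_coding(self) -> "GeneAnnotation":
        return GeneAnnotation(
            self.genome, [g for g in self.genes if g.biotype == "protein_coding"]
        )

    def exon_intervals(self) -> list[GenomicInterval]:
        return [ex for g in self.genes for ex in g.exons]

    @classmethod
    def read_gtf(cls, path: str | Path, genome: Genome) -> "GeneAnnotation":
        """Parse gene and exon features from a GTF2.2 file (1-based inclusive)."""
        attr_re = re.compile(r'(\w+)\s+"([^"]*)"')
        gene_rows: dict[str, dict] = {}
        exon_rows: dict[str, list[GenomicInterval]] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise AnnotationError(f"{path}:{i}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts
            if feature not in ("gene", "exon"):
                continue
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{i}: non-integer coordinate") from exc
            if end0 <= start0:
                raise AnnotationError(f"{path}:{i}: end < start")
            attr_map = dict(attr_re.findall(attrs))
            gene_id = attr_map.get("gene_id")
            if gene_id is None:
                raise AnnotationError(f"{path}:{i}: missing gene_id attribute")
            iv = GenomicInterval(chrom, start0, end0, strand)
            if feature == "gene":
                gene_rows[gene_id] = {
                    "interval": iv,
                    "biotype": attr_map.get("gene_biotype", attr_map.get("gene_type", "")),
                }
            else:
                exon_rows.setdefault(gene_id, []).append(iv)
        genes = []
        for gene_id, row in gene_rows.items():
            exons = tuple(
                sorted(exon_rows.get(gene_id, []), key=lambda e: (e.start, e.end))
            )
            genes.append(Gene(gene_id, row["biotype"], row["interval"], exons))
        return cls(genome, genes)

    def write_gtf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                iv = g.interval
                attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
                fh.write(
                    f"{iv.chrom}\ttecre\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )
                for ex in g.exons:
                    fh.write(
                        f"{ex.chrom}\ttecre\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{iv.strand}\t.\t{attrs}\n"
                    )


def read_annotations(
    te_path: str | Path, gene_path: str | Path, genome_path: str | Path
) -> tuple[TEAnnotation, GeneAnnotation, Genome]:
    """Read TE BED, gene GTF and chrom-sizes files into validated objects."""
    genome = Genome.read(genome_path)
    tes = TEAnnotation.read_bed(te_path, genome)
    genes = GeneAnnotation.read_gtf(gene_path, genome)
    return tes, genes, genome


def merge_fragmented_integrants(
    tes: TEAnnotation,
    pairings: Mapping[str, str],
    max_gap: int = 100,
) -> TEAnnotation:
    """Merge fragmented LTR / internal segments into single integrants.

    ERV proviruses are usually annotated as separate fragments
    (5'LTR, internal segment, 3'LTR).  Adjacent fragments on the same
    chromosome and strand are merged when their subfamilies form a
    declared internal/LTR pairing and the gap between them is at most
    ``max_gap`` bp.  ``pairings`` maps an internal-segment subfamily
    (e.g. ``HERVK-int``) to its LTR subfamily (e.g. ``LTR5Hs``); merged
    spans take the LTR subfamily label and keep the child locus ids.
    The operation is idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    ltr_names = set(pairings.values())

    def compatible(a: TEIntegrant, b: TEIntegrant) -> bool:
        sa, sb = a.subfamily, b.subfamily
        return (
            pairings.get(sa) == sb
            or pairings.get(sb) == sa
            or (sa == sb and sa in pairings)
        )

    merged: list[TEIntegrant] = []
    n_merges = 0
    group: list[TEIntegrant] = []

    def flush() -> None:
        nonlocal n_merges
        if not group:
            return
        if len(group) == 1:
            merged.append(group[0])
        else:
            n_merges += len(group) - 1
            ltr = next((t for t in group if t.subfamily in ltr_names), group[0])
            iv = GenomicInterval(
                group[0].interval.chrom,
                group[0].interval.start,
                max(t.interval.end for t in group),
                group[0].interval.strand,
            )
            merged.append(
                TEIntegrant(
                    iv,
                    group[0].locus_id,
                    ltr.subfamily,
                    ltr.family_class,
                    ltr.age_category,
                    merged_children=tuple(t.locus_id for t in group),
                )
            )
        group.clear()

    for te in tes.integrants:
        if group:
            prev = group[-1]
            gap = te.interval.start - prev.interval.end
            same = (
                te.interval.chrom == prev.interval.chrom
                and te.interval.strand == prev.interval.strand
            )
            if same and gap <= max_gap and compatible(prev, te):
                group.append(te)
                continue
            flush()
        group.append(te)
    flush()
    logger.info("merge_fragmented_integrants: %d fragments merged", n_merges)
    return TEAnnotation(tes.genome, merged)


def _as_arrays(
    intervals: Sequence[GenomicInterval],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    chroms = np.array([iv.chrom for iv in intervals], dtype=object)
    starts = np.array([iv.start for iv in intervals], dtype=np.int64)
    ends = np.array([iv.end for iv in intervals], dtype=np.int64)
    return chroms, starts, ends


def overlaps(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    genome: Genome | None = None,
) -> list[tuple[int, int]]:
    """All (query_index, subject_index) pairs with >=1 bp overlap.

    Half-open semantics, strand-agnostic.  With a ``genome`` given,
    query chromosomes are validated against it.
    """
    if genome is not None:
        for iv in query:
            if iv.chrom not in genome:
                raise AnnotationError(f"unknown chromosome {iv.chrom!r} in query")
    if not query or not subject:
        return []
    qc, qs, qe = _as_arrays(query)
    sc, ss, se = _as_arrays(subject)
    pairs: list[tuple[int, int]] = []
    for chrom in sorted(set(qc) & set(sc)):
        qi = np.flatnonzero(qc == chrom)
        si = np.flatnonzero(sc == chrom)
        # broadcast in query chunks to bound memory
        for lo in range(0, len(qi), 1024):
            qblock = qi[lo : lo + 1024]
            hit = (qs[qblock][:, None] < se[si][None, :]) & (
                ss[si][None, :] < qe[qblock][:, None]
            )
            for a, b in zip(*np.nonzero(hit)):
                pairs.append((int(qblock[a]), int(si[b])))
    pairs.sort()
    return pairs


def count_overlapping(
    window_start: int,
    window_end: int,
    starts_sorted: np.ndarray,
    ends_sorted: np.ndarray,
) -> int:
    """Count intervals intersecting [window_start, window_end).

    ``starts_sorted`` and ``ends_sorted`` are the interval starts and
    ends, each sorted independently.  The count is exact for any
    interval set:  #(start < we) - #(end <= ws).
    """
    return int(
        np.searchsorted(starts_sorted, window_end, side="left")
        - np.searchsorted(ends_sorted, window_start, side="right")
    )


class _NonOverlapTracker:
    """Incremental non-overlap test for interval placement on one chromosome."""

    def __init__(self) -> None:
        self._starts: list[int] = []
        self._ends: list[int] = []

    def fits(self, start: int, end: int) -> bool:
        i = bisect_right(self._starts, start)
        if i > 0 and self._ends[i - 1] > start:
            return False
        if i < len(self._starts) and self._starts[i] < end:
            return False
        return True

    def add(self, start: int, end: int) -> None:
        i = bisect_left(self._starts, start)
        self._starts.insert(i, start)
        self._ends.insert(i, end)
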