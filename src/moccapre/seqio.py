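"""Sequence and region I/O with a single internal coordinate convention.

All genomic intervals inside the package are 0-based, half-open
``[start, end)``.  Conversions to and from 1-based closed conventions
(GFF3) happen only at file boundaries.  Soft-masked (lowercase) bases are
uppercased on ingest and used; any symbol outside {A, C, G, T, N} is mapped
to N with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO as _BioSeqIO
from pyfaidx import Fasta as _FaidxFasta

logger = logging.getLogger("moccapre")

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised for malformed FASTA/BED/GFF3 input."""


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    name: str
    bases: str

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "Sequence":
        return Sequence(self.name, self.bases.translate(_COMPLEMENT)[::-1])


@dataclass(frozen=True)
class GenomicRegion:
    """A 0-based half-open genomic interval, optionally scored/labelled."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    label: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its genomic footprint and strand."""

    gene_id: str
    region: GenomicRegion
    strand: str = "."  # '+', '-' or '.' (unknown)


def normalize_bases(raw: str, name: str = "?") -> str:
    """Uppercase and map non-ACGTN symbols to N (with a warning)."""
    bases = raw.upper()
    if set(bases) - _VALID:
        bad = sorted(set(bases) - _VALID)
        warnings.warn(
            f"sequence {name!r}: non-ACGTN symbols {bad} replaced by N",
            stacklevel=2,
        )
        bases = "".join(b if b in _VALID else "N" for b in bases)
    return bases


def read_fasta(path: Union[str, Path]) -> list[Sequence]:
    """Read a (multi-record) FASTA file into a list of Sequence.

    Record order is preserved; bases are uppercased; degenerate symbols
    become N.  An empty file or a file not starting with a header raises
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        lineno = 0
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                first = line
                break
        if not first:
            raise ParseError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise ParseError(f"{path}: line {lineno}: expected '>' header")
    records = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        records.append(Sequence(rec.id, normalize_bases(str(rec.seq), rec.id)))
    return records


def write_fasta(seqs: Iterable[Sequence], path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.name}\n")
            for i in range(0, max(len(s.bases), 1), width):
                fh.write(s.bases[i : i + width] + "\n")


def read_regions(path: Union[str, Path], dialect: str = "bed") -> list[GenomicRegion]:
    """Read genomic regions from BED (verbatim) or GFF3 (start-1).

    BED is already 0-based half-open.  GFF3 is 1-based closed and is
    converted by subtracting 1 from the start.  Records that are empty
    after conversion are rejected with a warning.
    """
    if dialect not in ("bed", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            try:
                if dialect == "bed":
                    chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                    label = cols[3] if len(cols) > 3 and cols[3] != "." else None
                    score = (
                        float(cols[4]) if len(cols) > 4 and cols[4] != "." else None
                    )
                else:
                    if len(cols) < 5:
                        raise ParseError(
                            f"{path}: line {lineno}: GFF3 needs >=5 columns"
                        )
                    chrom = cols[0]
                    start, end = int(cols[3]) - 1, int(cols[4])
                    label = cols[2]
                    score = float(cols[5]) if len(cols) > 5 and cols[5] != "." else None
            except (ValueError, IndexError) as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if start >= end or start < 0:
                warnings.warn(
                    f"{path}: line {lineno}: rejected region "
                    f"{chrom}:{start}-{end} (start >= end)"
                )
                continue
            regions.append(GenomicRegion(chrom, start, end, score=score, label=label))
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: Union[str, Path]) -> None:
    """Write regions as BED6 (name/score filled with '.' when absent)."""
    with open(path, "w") as fh:
        for r in regions:
            name = r.label if r.label is not None else "."
            score = f"{r.score:g}" if r.score is not None else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\t.\n")


def read_genes_gff3(path: Union[str, Path], feature: str = "gene") -> list[GeneAnnotation]:
    """Read gene annotations (rows of the given feature type) from GFF3."""
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9 or cols[2] != feature:
                continue
            chrom, start, end, strand, attrs = (
                cols[0],
                int(cols[3]) - 1,
                int(cols[4]),
                cols[6],
                cols[8],
            )
            if start >= end:
                warnings.warn(f"{path}: line {lineno}: rejected empty gene")
                continue
            gene_id = None
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    if k.strip() in ("ID", "gene_id", "Name"):
                        gene_id = v.strip()
                        break
            if gene_id is None:
                gene_id = f"{chrom}:{start}-{end}"
            if strand not in ("+", "-"):
                strand = "."
            genes.append(
                GeneAnnotation(gene_id, GenomicRegion(chrom, start, end), strand)
            )
    return genes


class Genome:
    """Random access to an indexed FASTA genome (via pyfaidx)."""

    def __init__(self, path: Union[str, Path]):
        self._fa = _FaidxFasta(str(path), sequence_always_upper=True)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(rec) for name, rec in self._fa.items()}

    def chromosomes(self) -> list[str]:
        return list(self._fa.keys())

    def extract(self, region: GenomicRegion) -> Sequence:
        return extract_sequence(self, region)


def extract_sequence(genome: Genome, region: GenomicRegion) -> Sequence:
    """Extract the bases of ``region`` from an indexed genome.

    Regions extending past either chromosome end are clamped with a
    warning; an unknown chromosome raises KeyError.
    """
    sizes = genome.chrom_sizes
    if region.chrom not in sizes:
        raise KeyError(f"unknown chromosome {region.chrom!r}")
    size = sizes[region.chrom]
    start, end = max(0, region.start), min(size, region.end)
    if (start, end) != (region.start, region.end):
        warnings.warn(
            f"region {region.chrom}:{region.start}-{region.end} clamped to "
            f"[{start},{end}) ({size} bp chromosome)"
        )
    raw = str(genome._fa[region.chrom][start:end])
    name = f"{region.chrom}:{start}-{end}"
    return Sequence(name, normalize_bases(raw, name))
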