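"""Genome-wide prediction and genomic region analytics.

A trained scorer is slid across each chromosome (default step 10 bp);
windows scoring strictly above the calibrated threshold are kept and
overlapping windows merged into non-overlapping candidate regions whose
score is the maximum constituent window score.  Merged predictions can
be refined to a core fragment: the maximally scoring window over a
ladder of sizes (500 bp to 3 kb, step 50 bp), with the score normalized
by window length.  Region utilities cover resizing, overlap sensitivity,
signal-based filtering and nearest/overlapping target-gene assignment.
"""

from __future__ import annotations

import ast
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol

import numpy as np

from .seqio import GeneAnnotation, GenomicRegion, Genome, Sequence

CORE_LADDER = (500, 600, 750, 1000, 1500, 2000, 2500, 3000)
CORE_STEP = 50


class WindowScorer(Protocol):
    window_bp: int

    def window_scores(
        self, seq: Sequence, window_bp: int | None = None, step: int = 10
    ) -> tuple[np.ndarray, np.ndarray]: ...


@dataclass
class PredictionSet:
    """Merged, non-overlapping genome-wide predictions."""

    regions: list[GenomicRegion]
    model_id: str
    threshold: float
    window_bp: int
    step_bp: int


@dataclass
class CoreFragment:
    """The maximally scoring length-normalized sub-window of a prediction."""

    parent: GenomicRegion
    core: GenomicRegion
    normalized_score: float


def merge_regions(regions: Iterable[GenomicRegion]) -> list[GenomicRegion]:
    """Merge regions overlapping by >= 1 bp (touching regions stay apart).

    The merged score is the maximum of the constituents'.
    """
    out: list[GenomicRegion] = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        if out and out[-1].chrom == r.chrom and r.start < out[-1].end:
            prev = out[-1]
            scores = [s for s in (prev.score, r.score) if s is not None]
            out[-1] = GenomicRegion(
                prev.chrom,
                prev.start,
                max(prev.end, r.end),
                score=max(scores) if scores else None,
                label=prev.label,
            )
        else:
            out.append(r)
    return out


def scan_genome(
    scorer: WindowScorer,
    genome: Genome | Mapping[str, Sequence],
    threshold: float,
    window_bp: int | None = None,
    step_bp: int = 10,
    chromosomes: list[str] | None = None,
    model_id: str = "model",
) -> PredictionSet:
    """Sliding-window scan; windows scoring strictly above threshold are
    kept and merged into non-overlapping candidate regions."""
    W = scorer.window_bp if window_bp is None else window_bp
    if isinstance(genome, Genome):
        chroms = chromosomes or genome.chromosomes()
        seqs = {c: genome.extract(GenomicRegion(c, 0, genome.chrom_sizes[c])) for c in chroms}
    else:
        seqs = dict(genome)
        if chromosomes:
            seqs = {c: seqs[c] for c in chromosomes}
    kept: list[GenomicRegion] = []
    for chrom, seq in seqs.items():
        starts, scores = scorer.window_scores(seq, window_bp=W, step=step_bp)
        win = min(W, len(seq.bases))
        for s, sc in zip(starts, scores):
            if sc > threshold:
                kept.append(GenomicRegion(chrom, int(s), int(s) + win, score=float(sc)))
    return PredictionSet(merge_regions(kept), model_id, threshold, W, step_bp)


def core_fragment(
    scorer: WindowScorer,
    parent_seq: Sequence,
    parent_region: GenomicRegion,
    ladder: tuple[int, ...] = CORE_LADDER,
    step: int = CORE_STEP,
) -> CoreFragment:
    """Locate the core: best score/length window over the size ladder.

    For each ladder size that fits in the parent, windows slide at
    ``step`` bp and the top raw score is kept; the winner maximizes
    score/length, with ties resolved toward the smaller size, then the
    leftmost start.  A parent shorter than every ladder size is its own
    core.
    """
    L = len(parent_seq.bases)
    sizes = [w for w in sorted(ladder) if w <= L]
    if not sizes:
        sizes = [L]
    best = None  # (normalized, size, start, raw)
    for size in sizes:
        starts, scores = scorer.window_scores(parent_seq, window_bp=size, step=step)
        k = int(np.argmax(scores))  # argmax returns the leftmost maximum
        norm = float(scores[k]) / size
        if best is None or norm > best[0] + 1e-12:
            best = (norm, size, int(starts[k]), float(scores[k]))
    norm, size, start, raw = best
    core = GenomicRegion(
        parent_region.chrom,
        parent_region.start + start,
        parent_region.start + start + min(size, L),
        score=raw,
    )
    return CoreFragment(parent_region, core, norm)


def resize_regions(
    regions: Iterable[GenomicRegion],
    length: int,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GenomicRegion]:
    """Resize each region to ``length`` bp around its center.

    With chromosome sizes supplied, out-of-bounds regions are clamped
    (with a warning), possibly becoming shorter than requested.
    """
    if length <= 0:
        raise ValueError("length must be > 0")
    out = []
    for r in regions:
        start = (r.start + r.end - length) // 2
        end = start + length
        if chrom_sizes is not None or start < 0:
            size = chrom_sizes.get(r.chrom) if chrom_sizes else None
            lo = max(0, start)
            hi = min(size, end) if size is not None else end
            if (lo, hi) != (start, end):
                warnings.warn(
                    f"resized region {r.chrom}:{start}-{end} clamped to [{lo},{hi})"
                )
            start, end = lo, hi
        out.append(GenomicRegion(r.chrom, start, end, score=r.score, label=r.label))
    return out


# ---------------------------------------------------------------------------
# overlap analytics


def _by_chrom(regions: Iterable[GenomicRegion]) -> dict[str, list[GenomicRegion]]:
    d: dict[str, list[GenomicRegion]] = {}
    for r in regions:
        d.setdefault(r.chrom, []).append(r)
    return d


class _OverlapIndex:
    """Sorted-interval index answering 'does r overlap anything?'."""

    def __init__(self, regions: Iterable[GenomicRegion], extend: int = 0):
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, rs in _by_chrom(regions).items():
            starts = np.array([max(0, r.start - extend) for r in rs])
            ends = np.array([r.end + extend for r in rs])
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            self._chrom[chrom] = (starts, np.maximum.accumulate(ends))
    def overlaps(self, r: GenomicRegion) -> bool:
        if r.chrom not in self._chrom:
            return False
        starts, maxends = self._chrom[r.chrom]
        k = int(np.searchsorted(starts, r.end, side="left"))
        return k > 0 and maxends[k - 1] > r.start


def overlap_sensitivity(
    a: list[GenomicRegion], b: list[GenomicRegion], extend_b: int = 1000
) -> float:
    """Fraction of regions in ``a`` overlapping >= 1 bp of (extended) ``b``.

    ``b`` regions are first extended bidirectionally by ``extend_b``
    (default 1 kb, accounting for distancing between recruited factors
    and recruiting sequences).
    """
    if not a:
        raise ValueError("set a must be non-empty")
    index = _OverlapIndex(b, extend=extend_b)
    return sum(index.overlaps(r) for r in a) / len(a)


def assign_target_genes(
    regions: list[GenomicRegion], genes: list[GeneAnnotation]
) -> dict[GenomicRegion, list[str]]:
    """Candidate target genes per region.

    All genes overlapping a region are assigned; a region overlapping no
    gene gets the gene(s) minimizing the endpoint-to-endpoint distance
    (exact ties are all kept).  A region on a chromosome without genes
    gets an empty list and a warning.
    """
    genes_by_chrom = _by_chrom([g.region for g in genes])
    ids_by_chrom: dict[str, list[tuple[GenomicRegion, str]]] = {}
    for g in genes:
        ids_by_chrom.setdefault(g.region.chrom, []).append((g.region, g.gene_id))
    out: dict[GenomicRegion, list[str]] = {}
    for r in regions:
        cand = ids_by_chrom.get(r.chrom, [])
        if not cand:
            warnings.warn(f"region {r.chrom}:{r.start}-{r.end}: no genes on chromosome")
            out[r] = []
            continue
        hits = [gid for greg, gid in cand if greg.overlaps(r)]
        if not hits:
            def dist(greg: GenomicRegion) -> int:
                if greg.end <= r.start:
                    return r.start - greg.end
                return greg.start - r.end
            dmin = min(dist(greg) for greg, _ in cand)
            hits = [gid for greg, gid in cand if dist(greg) == dmin]
        out[r] = hits
    return out


def _parse_rule(rule: str, names: set[str]):
    """Compile a boolean overlap rule like 'A AND (B OR C)'."""
    py = re.sub(r"\bAND\b", "and", rule)
    py = re.sub(r"\bOR\b", "or", py)
    py = re.sub(r"\bNOT\b", "not", py)
    tree = ast.parse(py, mode="eval")
    for node in ast.walk(tree):
        if isinstance(node, ast.Name):
            if node.id not in names:
                raise KeyError(f"rule references unknown signal set {node.id!r}")
        elif not isinstance(
            node,
            (ast.Expression, ast.BoolOp, ast.UnaryOp, ast.And, ast.Or, ast.Not, ast.Load),
        ):
            raise ValueError(f"unsupported syntax in rule {rule!r}")
    return compile(tree, "<rule>", "eval")


def filter_by_signals(
    predictions: PredictionSet | list[GenomicRegion],
    signal_sets: Mapping[str, list[GenomicRegion]],
    rule: str,
    extend: int = 0,
) -> list[GenomicRegion]:
    """Keep predictions whose signal overlaps satisfy a boolean rule.

    ``rule`` is a boolean expression over the signal-set names with
    AND/OR/NOT and parentheses, e.g. ``"H3K27me3 AND (Pc OR Psc OR
    Sfmbt)"``; a prediction's name evaluates true iff it overlaps at
    least one region of that set.
    """
    regions = predictions.regions if isinstance(predictions, PredictionSet) else predictions
    code = _parse_rule(rule, set(signal_sets))
    indexes = {name: _OverlapIndex(rs, extend=extend) for name, rs in signal_sets.items()}
    kept = []
    for r in regions:
        env = {name: idx.overlaps(r) for name, idx in indexes.items()}
        if eval(code, {"__builtins__": {}}, env):
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# derived region helpers (reporting)


def promoters(
    genes: list[GeneAnnotation],
    upstream: int = 3000,
    downstream: int = 500,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GenomicRegion]:
    """TSS-anchored promoter regions (-upstream/+downstream, stranded).

    Genes of unknown strand are treated as '+'.
    """
    out = []
    for g in genes:
        if g.strand == "-":
            start, end = g.region.end - downstream, g.region.end + upstream
        else:
            start, end = g.region.start - upstream, g.region.start + downstream
        start = max(0, start)
        if chrom_sizes is not None and g.region.chrom in chrom_sizes:
            end = min(end, chrom_sizes[g.region.chrom])
        if start < end:
            out.append(GenomicRegion(g.region.chrom, start, end, label=g.gene_id))
    return out


def shrink_regions(regions: Iterable[GenomicRegion], by: int = 250) -> list[GenomicRegion]:
    """Shrink regions bidirectionally; too-small regions are omitted."""
    out = []
    for r in regions:
        if len(r) > 2 * by:
            out.append(GenomicRegion(r.chrom, r.start + by, r.end - by, score=r.score, label=r.label))
    return out
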