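"""IUPAC motif definitions, mismatch-tolerant scanning and pair counting.

Motifs are degenerate IUPAC strings with a per-motif mismatch allowance.
Scanning reports every window on either strand whose Hamming distance to
the (possibly degenerate) pattern is within the allowance; an N in the
sequence always counts as a mismatch.  Motif pairs are counted between
occurrence midpoints within a distance cutoff; the 219 bp default follows
the PREdictor lineage this tool reimplements.

Nucleotides are represented internally as bitmasks (A=1, C=2, G=4, T=8,
N=0) so that IUPAC membership is a single bitwise AND.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .seqio import Sequence

# bitmask per IUPAC code; N in a *sequence* is encoded as 0 (matches nothing)
IUPAC_MASKS: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 1 | 2 | 4 | 8,
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# sequence-encoding lookup: byte value of base -> bitmask (N -> 0)
_SEQ_MASK = np.zeros(256, dtype=np.uint8)
for _b, _m in (("A", 1), ("C", 2), ("G", 4), ("T", 8)):
    _SEQ_MASK[ord(_b)] = _m

DEFAULT_PAIR_CUTOFF = 219  # bp, midpoint-to-midpoint


def iupac_complement(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern."""
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


def iupac_match(code: str, base: str) -> bool:
    """True iff ``base`` is in the nucleotide set of IUPAC ``code``.

    Base N matches nothing (a sequence N always costs a mismatch).
    """
    if code not in IUPAC_MASKS:
        raise ValueError(f"invalid IUPAC code {code!r}")
    base_mask = IUPAC_MASKS.get(base, 0) if base in "ACGT" else 0
    return bool(IUPAC_MASKS[code] & base_mask)


def encode(bases: str) -> np.ndarray:
    """Encode a DNA string as a uint8 bitmask array."""
    return _SEQ_MASK[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Motif:
    """A named IUPAC motif with a mismatch allowance."""

    name: str
    pattern: str
    max_mismatches: int = 0

    def __post_init__(self):
        if not self.pattern:
            raise ValueError(f"motif {self.name!r}: empty pattern")
        bad = set(self.pattern) - set(IUPAC_MASKS)
        if bad:
            raise ValueError(f"motif {self.name!r}: invalid IUPAC codes {sorted(bad)}")
        if not 0 <= self.max_mismatches < len(self.pattern):
            raise ValueError(
                f"motif {self.name!r}: max_mismatches must be in [0, {len(self.pattern)})"
            )

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def is_palindromic(self) -> bool:
        """True if the pattern equals its own reverse complement."""
        return self.pattern == iupac_complement(self.pattern)


@dataclass(frozen=True)
class MotifSet:
    """An ordered collection of motifs; order fixes feature indices."""

    motifs: tuple[Motif, ...]
    name: str = "custom"

    def __post_init__(self):
        names = [m.name for m in self.motifs]
        if len(set(names)) != len(names):
            raise ValueError("motif names must be unique")

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def __getitem__(self, i):
        return self.motifs[i]

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.motifs]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def pair_names(self) -> list[tuple[str, str]]:
        """All |M|(|M|+1)/2 unordered motif pairs (incl. self-pairs), set order."""
        n = self.names
        return [(n[i], n[j]) for i in range(len(n)) for j in range(i, len(n))]


@dataclass(frozen=True)
class MotifOccurrence:
    """One motif hit: 0-based half-open interval plus strand."""

    motif_name: str
    seq_name: str
    start: int
    end: int
    strand: str

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class PairCount:
    motif_a: str
    motif_b: str
    count: int


# ---------------------------------------------------------------------------
# scanning


def _mismatch_profile(seq_masks: np.ndarray, pattern: str) -> np.ndarray:
    """Mismatch count of every window of len(pattern) against the pattern."""
    L = len(pattern)
    n = len(seq_masks) - L + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int16)
    mm = np.zeros(n, dtype=np.int16)
    for j, code in enumerate(pattern):
        mm += (seq_masks[j : j + n] & IUPAC_MASKS[code]) == 0
    return mm


def scan_starts(seq_masks: np.ndarray, motif: Motif) -> tuple[np.ndarray, np.ndarray]:
    """Return (starts_plus, starts_minus) for a pre-encoded sequence.

    A palindromic pattern would hit identically on both strands, so it is
    scanned on + only.
    """
    fwd = _mismatch_profile(seq_masks, motif.pattern)
    plus = np.flatnonzero(fwd <= motif.max_mismatches)
    if motif.is_palindromic:
        return plus, np.zeros(0, dtype=np.intp)
    rev = _mismatch_profile(seq_masks, iupac_complement(motif.pattern))
    minus = np.flatnonzero(rev <= motif.max_mismatches)
    return plus, minus


def scan(seq: Sequence, motif: Motif) -> list[MotifOccurrence]:
    """All occurrences of ``motif`` in ``seq`` on both strands.

    Overlapping occurrences are all reported; output is sorted by start,
    then strand (+ before -).
    """
    masks = encode(seq.bases)
    plus, minus = scan_starts(masks, motif)
    L = len(motif)
    occs = [
        MotifOccurrence(motif.name, seq.name, int(s), int(s) + L, "+") for s in plus
    ] + [
        MotifOccurrence(motif.name, seq.name, int(s), int(s) + L, "-") for s in minus
    ]
    occs.sort(key=lambda o: (o.start, o.strand))
    return occs


def scan_all(seq: Sequence, motif_set: MotifSet) -> list[MotifOccurrence]:
    """Occurrences of every motif in the set, concatenated in set order."""
    masks = encode(seq.bases)
    out: list[MotifOccurrence] = []
    for motif in motif_set:
        plus, minus = scan_starts(masks, motif)
        L = len(motif)
        occs = [
            MotifOccurrence(motif.name, seq.name, int(s), int(s) + L, "+")
            for s in plus
        ] + [
            MotifOccurrence(motif.name, seq.name, int(s), int(s) + L, "-")
            for s in minus
        ]
        occs.sort(key=lambda o: (o.start, o.strand))
        out.extend(occs)
    return out


# ---------------------------------------------------------------------------
# pair counting


def pair_index(i: int, j: int, n: int) -> int:
    """Flat index of unordered pair (i<=j) among the n(n+1)/2 pairs."""
    if i > j:
        i, j = j, i
    return i * n - i * (i - 1) // 2 + (j - i)


def close_pairs(
    occs: list[MotifOccurrence], motif_set: MotifSet, cutoff_bp: int = DEFAULT_PAIR_CUTOFF
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Enumerate unordered occurrence pairs with midpoint distance <= cutoff.

    Returns (span_start, span_end, pair_idx): the extent covered by the
    two occurrences (min start, max end — what a window must contain to
    count the pair) and the flat unordered motif-pair index.
    """
    n = len(motif_set)
    idx_of = {name: i for i, name in enumerate(motif_set.names)}
    if len(occs) < 2:
        z = np.zeros(0)
        return z, z, np.zeros(0, dtype=np.int64)
    mids = np.array([o.midpoint for o in occs])
    starts = np.array([o.start for o in occs])
    ends = np.array([o.end for o in occs])
    midx = np.array([idx_of[o.motif_name] for o in occs])
    order = np.argsort(mids, kind="stable")
    mids, starts, ends, midx = mids[order], starts[order], ends[order], midx[order]
    right = np.searchsorted(mids, mids + cutoff_bp, side="right")
    s_lo, e_hi, pidx = [], [], []
    for a in range(len(mids)):
        for b in range(a + 1, right[a]):
            s_lo.append(min(starts[a], starts[b]))
            e_hi.append(max(ends[a], ends[b]))
            pidx.append(pair_index(int(midx[a]), int(midx[b]), n))
    return np.array(s_lo), np.array(e_hi), np.array(pidx, dtype=np.int64)


def pair_count_vector(
    occs: list[MotifOccurrence], motif_set: MotifSet, cutoff_bp: int = DEFAULT_PAIR_CUTOFF
) -> np.ndarray:
    """Counts of all unordered motif pairs with midpoint distance <= cutoff.

    Self-pairs count unordered occurrence pairs: k mutually close
    occurrences of one motif contribute C(k,2).
    """
    n = len(motif_set)
    counts = np.zeros(n * (n + 1) // 2, dtype=np.int64)
    _, _, pidx = close_pairs(occs, motif_set, cutoff_bp)
    np.add.at(counts, pidx, 1)
    return counts


def count_pairs(
    occs: list[MotifOccurrence], motif_set: MotifSet, cutoff_bp: int = DEFAULT_PAIR_CUTOFF
) -> list[PairCount]:
    """As :func:`pair_count_vector`, but as named PairCount records."""
    vec = pair_count_vector(occs, motif_set, cutoff_bp)
    return [
        PairCount(a, b, int(c)) for (a, b), c in zip(motif_set.pair_names(), vec)
    ]


# ---------------------------------------------------------------------------
# presets

# The seven classical PRE motifs plus GTGT.  EN1 and G10 allow one mismatch.
_CORE_MOTIFS = [
    ("EN1", "GSNMACGCCCC", 1),
    ("G10", "GAGAGAGAGA", 1),
    ("GAF", "GAGAG", 0),
    ("PF", "GCCATHWY", 0),
    ("PM", "CNGCCATNDNND", 0),
    ("PS", "GCCAT", 0),
    ("Z", "YGAGYG", 0),
]

_GTGT = ("GTGT", "GTGT", 0)

# additional published motifs used for comparison runs
_COMPARISON_MOTIFS = [
    ("Z2", "BGAGTGV", 0),
    ("SP1KLF", "RRGGYG", 0),
    ("DSP1", "GAAAA", 0),
    ("GRH1", "TGTTTTTT", 0),
    ("GRH2", "WCHGGTT", 0),
    ("SITEA", "GAACNG", 0),
]

_PRESETS = {
    "ringrose7": _CORE_MOTIFS,
    "ringrose7+gtgt": _CORE_MOTIFS + [_GTGT],
    "comparison": _CORE_MOTIFS + [_GTGT] + _COMPARISON_MOTIFS,
}


def builtin_motif_presets(name: str = "ringrose7+gtgt") -> MotifSet:
    """Built-in motif sets: 'ringrose7', 'ringrose7+gtgt', 'comparison'."""
    if name not in _PRESETS:
        raise KeyError(
            f"unknown motif preset {name!r}; available: {sorted(_PRESETS)}"
        )
    return MotifSet(
        tuple(Motif(n, p, mm) for n, p, mm in _PRESETS[name]), name=name
    )


def read_motifs_tsv(path) -> MotifSet:
    """Read a motif file: ``name<TAB>pattern<TAB>mismatches`` per line."""
    motifs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, pattern, mm = line.split("\t")
            motifs.append(Motif(name, pattern.upper(), int(mm)))
    return MotifSet(tuple(motifs), name="file")


def write_motifs_tsv(motif_set: MotifSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# name\tpattern\tmismatches\n")
        for m in motif_set:
            fh.write(f"{m.name}\t{m.pattern}\t{m.max_mismatches}\n")


def random_kmers(
    k: int, n: int, exclude: MotifSet | None = None, seed: int = 0
) -> list[Motif]:
    """Draw n random k-mers, unique also under reverse complement.

    Each drawn k-mer is distinct from previously drawn k-mers and their
    reverse complements, and from every excluded pattern and its reverse
    complement.  Deterministic under ``seed``; raises if n such k-mers do
    not exist.
    """
    rng = np.random.default_rng(seed)
    taken: set[str] = set()
    if exclude is not None:
        for m in exclude:
            taken.add(m.pattern)
            taken.add(iupac_complement(m.pattern))
    # feasibility: count rc-equivalence classes with neither member taken
    if 4**k <= 1 << 16:
        avail = 0
        seen: set[str] = set()
        for tup in itertools.product("ACGT", repeat=k):
            s = "".join(tup)
            key = min(s, iupac_complement(s))
            if key in seen:
                continue
            seen.add(key)
            if s not in taken and iupac_complement(s) not in taken:
                avail += 1
        if n > avail:
            raise ValueError(
                f"cannot draw {n} rc-unique {k}-mers (only {avail} available)"
            )
    out: list[Motif] = []
    while len(out) < n:
        s = "".join(rng.choice(list("ACGT"), size=k))
        if s in taken or iupac_complement(s) in taken:
            continue
        taken.add(s)
        taken.add(iupac_complement(s))
        out.append(Motif(f"random{len(out) + 1}_{s}", s, 0))
    return out
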