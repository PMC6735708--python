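"""Sequence-generating nth-order Markov chains and synthetic corpora.

The chain stores, for every n-mer context, counts of the nucleotide that
follows it.  Training is double-stranded (counts are accumulated on each
sequence and its reverse complement), windows containing N are skipped,
and a pseudocount of 1 is added for each nucleotide in each context so no
transition has probability zero.  Generation draws the first n bases from
the context marginal and every subsequent base from the conditional of
the last n generated bases.

These chains produce the negative/control sets used throughout: "dummy
PREs" (chain trained on the positive set) and "dummy genomic" sequences
(chain trained on a genome), plus a planted-motif synthetic corpus used
as ground truth in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .motifs import IUPAC_MASKS, Motif, MotifSet
from .seqio import Sequence

_CODE = np.full(256, 4, dtype=np.int8)  # 4 = invalid (N or other)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def _encode(bases: str) -> np.ndarray:
    return _CODE[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


@dataclass
class MarkovModel:
    """Order-n Markov chain over {A,C,G,T}.

    ``counts`` has shape (4**order, 4): pseudocounted transition counts
    for every context (row) and next nucleotide (column, ACGT order).
    The initial-context marginal is proportional to the row sums, i.e.
    observed context frequency plus the uniform pseudocount mass.
    """

    order: int
    counts: np.ndarray

    def __post_init__(self):
        expected = (4**self.order, 4)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")

    @property
    def conditionals(self) -> np.ndarray:
        """P(next | context): each row sums to 1."""
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    @property
    def context_marginal(self) -> np.ndarray:
        """Initial-context distribution (sums to 1)."""
        row = self.counts.sum(axis=1)
        return row / row.sum()

    # -- persistence -------------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# order={self.order}\n")
            fh.write("context\tcountA\tcountC\tcountG\tcountT\n")
            for idx in range(self.counts.shape[0]):
                ctx = _decode(_context_codes(idx, self.order))
                a, c, g, t = self.counts[idx]
                fh.write(f"{ctx or '.'}\t{a:g}\t{c:g}\t{g:g}\t{t:g}\n")

    @classmethod
    def from_tsv(cls, path) -> "MarkovModel":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("# order="):
                raise ValueError(f"{path}: missing '# order=' header")
            order = int(header.split("=", 1)[1])
            fh.readline()  # column names
            counts = np.zeros((4**order, 4))
            for line in fh:
                ctx, *vals = line.rstrip("\n").split("\t")
                idx = 0 if ctx == "." else _context_index(ctx)
                counts[idx] = [float(v) for v in vals]
        return cls(order, counts)

    def generate(self, length: int, seed: int | np.random.Generator = 0) -> Sequence:
        return generate(self, length, seed)


def _context_index(ctx: str) -> int:
    idx = 0
    for b in ctx:
        idx = idx * 4 + int(_CODE[ord(b)])
    return idx


def _context_codes(idx: int, order: int) -> np.ndarray:
    codes = np.zeros(order, dtype=np.int8)
    for j in range(order - 1, -1, -1):
        codes[j] = idx % 4
        idx //= 4
    return codes


def train_markov(seqs: list[Sequence], order: int) -> MarkovModel:
    """Train an order-n chain on the sequences and their reverse complements.

    Windows containing N are skipped.  Empty input yields the pure
    pseudocount model (every conditional uniform).
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    counts = np.zeros((4**order, 4))
    for seq in seqs:
        codes = _encode(seq.bases)
        for strand_codes in (codes, _RC[codes][::-1]):
            _accumulate(counts, strand_codes, order)
    counts += 1.0  # pseudocount: 1 per nucleotide per context
    return MarkovModel(order, counts)


def _accumulate(counts: np.ndarray, codes: np.ndarray, order: int) -> None:
    L = len(codes)
    if L < order + 1:
        return
    valid = codes < 4
    nwin = L - order
    ok = np.ones(nwin, dtype=bool)
    for j in range(order + 1):
        ok &= valid[j : j + nwin]
    ctx = np.zeros(nwin, dtype=np.int64)
    for j in range(order):
        ctx = ctx * 4 + np.where(valid[j : j + nwin], codes[j : j + nwin], 0)
    nxt = codes[order:]
    np.add.at(counts, (ctx[ok], nxt[ok].astype(np.int64)), 1.0)


@njit(cache=False)
def _gen_loop(cum: np.ndarray, ctx: int, order: int, us: np.ndarray, out: np.ndarray, start: int):
    mod = 4 ** (order - 1) if order > 0 else 1
    for t in range(start, out.shape[0]):
        r = us[t - start]
        row = cum[ctx]
        b = 0
        while r >= row[b] and b < 3:
            b += 1
        out[t] = b
        if order > 0:
            ctx = (ctx % mod) * 4 + b


def generate(
    model: MarkovModel, length: int, seed: int | np.random.Generator = 0
) -> Sequence:
    """Generate one sequence of the given length (deterministic under seed)."""
    if length < model.order:
        raise ValueError(f"length {length} < order {model.order}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.zeros(length, dtype=np.int8)
    ctx = int(rng.choice(len(model.counts), p=model.context_marginal))
    start = model.order
    out[:start] = _context_codes(ctx, model.order)[: length]
    if length > start:
        cond = model.conditionals
        cum = np.cumsum(cond, axis=1)
        cum[:, 3] = 1.0
        us = rng.random(length - start)
        _gen_loop(cum, ctx, model.order, us, out, start)
    return Sequence(f"markov{model.order}_{length}bp", _decode(out))


def make_dummy_set(
    positives: list[Sequence],
    multiplier: int = 100,
    length: int = 3000,
    order: int = 4,
    seed: int = 0,
    name_prefix: str = "dummy",
) -> list[Sequence]:
    """Generate multiplier x |positives| background sequences.

    An order-n chain is trained on the positives and used to generate the
    set; defaults (100x, 3 kb, order 4) produce the standard "dummy"
    negative sets.
    """
    if not positives:
        raise ValueError("positives must be non-empty")
    model = train_markov(positives, order)
    rng = np.random.default_rng(seed)
    n = multiplier * len(positives)
    return [
        Sequence(f"{name_prefix}_{i}", generate(model, length, rng).bases)
        for i in range(n)
    ]


def fragment_coding(cds_seqs: list[Sequence], fragment: int = 3000) -> list[Sequence]:
    """Concatenate coding sequences and cut into full-length fragments.

    Only complete fragments are returned (a 2999 bp tail is dropped).
    """
    if fragment <= 0:
        raise ValueError("fragment must be > 0")
    concat = "".join(s.bases for s in cds_seqs)
    nfrag = len(concat) // fragment
    return [
        Sequence(f"coding_{i}", concat[i * fragment : (i + 1) * fragment])
        for i in range(nfrag)
    ]


# ---------------------------------------------------------------------------
# synthetic planted-motif corpus (ground-truth fixture generator)


@dataclass
class SyntheticCorpusSpec:
    """Specification of a planted-motif synthetic corpus.

    Positives are background sequences overwritten with planted motif
    instances clustered inside one window; negatives are plain background.
    ``planted_motifs`` is a list of (motif, copies per sequence, max pair
    spacing in bp); all copies of all motifs are placed inside a single
    cluster window whose width is the minimum of the spacings, so that
    every planted pair is mutually within range.
    """

    n_pos: int
    n_neg: int
    length: int
    background: MarkovModel
    planted_motifs: list[tuple[Motif, int, int]] = field(default_factory=list)
    seed: int = 0


def _realize_pattern(pattern: str, rng: np.random.Generator) -> str:
    """Draw a concrete ACGT instance of an IUPAC pattern."""
    out = []
    for code in pattern:
        mask = IUPAC_MASKS[code]
        choices = [b for i, b in enumerate("ACGT") if mask & (1 << i)]
        out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def make_synthetic_corpus(
    spec: SyntheticCorpusSpec,
) -> tuple[list[Sequence], list[Sequence], list[list[tuple[str, int]]]]:
    """Generate (positives, negatives, placements).

    ``placements[i]`` lists (motif_name, start) for positive i — the
    planted ground truth.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    total_len = sum(len(m.pattern) * c for m, c, _ in spec.planted_motifs)
    if spec.planted_motifs:
        window = min(s for _, _, s in spec.planted_motifs)
        window = min(window, spec.length)
        if total_len > window:
            raise ValueError(
                f"planted motifs ({total_len} bp) cannot fit in a "
                f"{window} bp cluster window"
            )
    positives, placements = [], []
    for i in range(spec.n_pos):
        seq = generate(spec.background, spec.length, rng)
        bases = list(seq.bases)
        placed: list[tuple[str, int, int]] = []  # (name, start, end)
        if spec.planted_motifs:
            anchor = int(rng.integers(0, spec.length - window + 1))
            for motif, copies, _ in spec.planted_motifs:
                L = len(motif.pattern)
                for _c in range(copies):
                    for _try in range(1000):
                        s = anchor + int(rng.integers(0, window - L + 1))
                        if all(s + L <= a or s >= b for _, a, b in placed):
                            break
                    else:
                        raise ValueError("could not place planted motifs")
                    placed.append((motif.name, s, s + L))
                    bases[s : s + L] = _realize_pattern(motif.pattern, rng)
        positives.append(Sequence(f"pos_{i}", "".join(bases)))
        placements.append([(n, s) for n, s, _ in placed])
    negatives = [
        Sequence(f"neg_{i}", generate(spec.background, spec.length, rng).bases)
        for i in range(spec.n_neg)
    ]
    return positives, negatives, placements
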