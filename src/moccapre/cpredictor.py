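"""The PREdictor algorithm: motif-pair log-odds scoring of sequence windows.

A window is scored as a linear combination of motif-pair occurrence
counts, with each unordered motif pair weighted by the log-odds of its
mean per-sequence count in positive versus negative training sets:

    w_p = ln[(mean count in positives + a) / (mean count in negatives + a)]

The Dummy PREdictor is the same scorer with every weight set to 1, so a
window's score is simply its total number of close motif pairs.  A whole
sequence is scored by the maximum over sliding windows (default 500 bp,
step 10 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motifs import (
    DEFAULT_PAIR_CUTOFF,
    MotifSet,
    builtin_motif_presets,
    close_pairs,
    pair_count_vector,
    read_motifs_tsv,
    scan_all,
)
from .seqio import Sequence
from .windowing import scores_over_windows, window_grid

DEFAULT_WINDOW = 500  # bp; the window size found to generalize best


@dataclass
class PairWeightModel:
    """Motif-pair log-odds weights (flat vector in pair-index order)."""

    motif_set: MotifSet
    weights: np.ndarray
    cutoff_bp: int = DEFAULT_PAIR_CUTOFF
    pseudocount: float = 1.0
    window_bp: int = DEFAULT_WINDOW

    def pair_weight(self, motif_a: str, motif_b: str) -> float:
        names = self.motif_set.pair_names()
        key = tuple(
            sorted(
                (motif_a, motif_b), key=lambda x: self.motif_set.index(x)
            )
        )
        return float(self.weights[names.index(key)])

    # -- scoring -----------------------------------------------------------

    def score_window(self, window: Sequence) -> float:
        """Sum over pairs of (pair count in window) x weight."""
        occs = scan_all(window, self.motif_set)
        counts = pair_count_vector(occs, self.motif_set, self.cutoff_bp)
        return float(counts @ self.weights)

    def window_scores(
        self, seq: Sequence, window_bp: int | None = None, step: int = 10
    ) -> tuple[np.ndarray, np.ndarray]:
        """(window starts, window scores) over a sliding grid.

        The sequence is scanned once; every close motif pair contributes
        its weight to the windows that contain both occurrences.
        """
        W = self.window_bp if window_bp is None else window_bp
        grid = window_grid(len(seq.bases), W, step)
        occs = scan_all(seq, self.motif_set)
        s_lo, e_hi, pidx = close_pairs(occs, self.motif_set, self.cutoff_bp)
        if len(pidx) == 0:
            return grid, np.zeros(len(grid))
        # pair counted iff the window [s, s+W) contains both occurrences:
        # e_hi - W <= s <= s_lo
        scores = scores_over_windows(grid, e_hi - W - 0.5, s_lo, self.weights[pidx])
        return grid, scores

    def score_sequence(self, seq: Sequence, step: int = 10) -> float:
        """Max window score over the sequence (the test-sequence score)."""
        _, scores = self.window_scores(seq, step=step)
        return float(scores.max())

    # -- persistence -------------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# cutoff={self.cutoff_bp} window={self.window_bp} "
                f"alpha={self.pseudocount} preset={self.motif_set.name}\n"
            )
            fh.write("motif_a\tmotif_b\tweight\n")
            for (a, b), w in zip(self.motif_set.pair_names(), self.weights):
                fh.write(f"{a}\t{b}\t{float(w)!r}\n")

    @classmethod
    def from_tsv(cls, path, motif_set: MotifSet | None = None) -> "PairWeightModel":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ")
            meta = dict(kv.split("=", 1) for kv in header.split())
            fh.readline()
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        if motif_set is None:
            preset = meta.get("preset", "custom")
            try:
                motif_set = builtin_motif_presets(preset)
            except KeyError as exc:
                raise ValueError(
                    f"{path}: non-builtin preset {preset!r}: pass motif_set"
                ) from exc
        expected = motif_set.pair_names()
        got = {(a, b): float(w) for a, b, w in rows}
        weights = np.array([got[p] for p in expected])
        return cls(
            motif_set,
            weights,
            cutoff_bp=int(meta["cutoff"]),
            pseudocount=float(meta["alpha"]),
            window_bp=int(meta["window"]),
        )


def mean_pair_counts(
    seqs: list[Sequence], motif_set: MotifSet, cutoff_bp: int
) -> np.ndarray:
    """Mean per-sequence pair-count vector over whole sequences."""
    total = np.zeros(len(motif_set) * (len(motif_set) + 1) // 2)
    for s in seqs:
        total += pair_count_vector(scan_all(s, motif_set), motif_set, cutoff_bp)
    return total / len(seqs)


def train_pair_model(
    pos: list[Sequence],
    neg: list[Sequence],
    motif_set: MotifSet,
    cutoff_bp: int = DEFAULT_PAIR_CUTOFF,
    pseudocount: float = 1.0,
    window_bp: int = DEFAULT_WINDOW,
) -> PairWeightModel:
    """Fit pair log-odds weights from positive/negative training sets."""
    if not pos or not neg:
        raise ValueError("both training sets must be non-empty")
    mp = mean_pair_counts(pos, motif_set, cutoff_bp)
    mn = mean_pair_counts(neg, motif_set, cutoff_bp)
    weights = np.log((mp + pseudocount) / (mn + pseudocount))
    return PairWeightModel(
        motif_set, weights, cutoff_bp=cutoff_bp,
        pseudocount=pseudocount, window_bp=window_bp,
    )


def dummy_predictor(
    motif_set: MotifSet,
    cutoff_bp: int = DEFAULT_PAIR_CUTOFF,
    window_bp: int = DEFAULT_WINDOW,
) -> PairWeightModel:
    """Uniformly weighted pair clustering: every pair weight is 1.

    The score of a window is then exactly its total pair count.
    """
    npairs = len(motif_set) * (len(motif_set) + 1) // 2
    return PairWeightModel(
        motif_set, np.ones(npairs), cutoff_bp=cutoff_bp, window_bp=window_bp
    )
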