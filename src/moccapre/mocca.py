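"""SVM-MOCCA: per-motif SVM classification of local motif landscapes.

One multi-class SVM is trained per motif.  Each occurrence of a motif is
represented by its *local landscape*: counts of every motif of the set
and of the 16 ordered dinucleotides within +-flank (default 250 bp) of
the occurrence midpoint, a vector in |M| + 16 dimensions.  Training
sequences come in classes (positive PREs and one or more control
classes); each occurrence inherits its sequence's class label, and the
SVM learns to predict it (one-vs-one binary machines with majority vote,
as implemented in libsvm).

After the SVMs are trained, each motif m receives a log-odds weight over
positively classified occurrence frequencies f(m, s):

    w_m = ln[(sum_p f(m,p)/|P| + a) / (sum_n f(m,n)/|N| + a)]

and a sequence is scored as S = sum_m w_m f(m).  Long sequences are
scored by the maximum over sliding windows (default 3 kb, step 10 bp).

For interpretation, the quadratic-kernel decision functions can be
expanded into explicit weighted feature pairs and condensed across all
positive-vs-negative class boundaries, merging reverse-complement
dinucleotides and reversed pair order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .motifs import MotifSet, iupac_complement, scan_all
from .seqio import Sequence
from .windowing import scores_over_windows, window_grid

DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]
DEFAULT_FLANK = 250
DEFAULT_WINDOW = 3000
DEFAULT_CLASSES = ("PRE", "dummy-PRE", "dummy-genomic", "coding")

_KERNEL_DEGREE = {"linear": 1, "quadratic": 2, "cubic": 3}

_DI_CODE = {d: i for i, d in enumerate(DINUCLEOTIDES)}
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# landscape vectors


def _dinuc_cumsum(bases: str) -> np.ndarray:
    """cum[k, d] = number of dinucleotides d starting at positions < k.

    Dinucleotides containing N are not counted.
    """
    L = len(bases)
    cum = np.zeros((L, 16), dtype=np.int32)
    if L < 2:
        return cum
    codes = np.array([_BASE_IDX.get(b, 4) for b in bases], dtype=np.int8)
    a, b = codes[:-1], codes[1:]
    ok = (a < 4) & (b < 4)
    di = np.where(ok, a.astype(np.int32) * 4 + b, 0)
    ind = np.zeros((L - 1, 16), dtype=np.int32)
    rows = np.flatnonzero(ok)
    ind[rows, di[rows]] = 1
    cum[1:] = np.cumsum(ind, axis=0)
    return cum


class _SeqLandscapes:
    """All landscape vectors of one sequence, computed in one pass.

    For each motif: the list of occurrence midpoints (sorted) and the
    (n_occ, |M|+16) landscape matrix of its occurrences.
    """

    def __init__(self, seq: Sequence, motif_set: MotifSet, flank: int = DEFAULT_FLANK):
        self.seq = seq
        self.motif_set = motif_set
        self.flank = flank
        L = len(seq.bases)
        occs = scan_all(seq, motif_set)
        self.mids_by_motif: dict[str, np.ndarray] = {}
        for name in motif_set.names:
            mids = np.array(
                sorted(o.midpoint for o in occs if o.motif_name == name)
            )
            self.mids_by_motif[name] = mids
        dcum = _dinuc_cumsum(seq.bases)
        self.X_by_motif: dict[str, np.ndarray] = {}
        nm = len(motif_set)
        for name in motif_set.names:
            mids = self.mids_by_motif[name]
            X = np.zeros((len(mids), nm + 16))
            for i, name2 in enumerate(motif_set.names):
                other = self.mids_by_motif[name2]
                X[:, i] = np.searchsorted(
                    other, mids + flank, side="right"
                ) - np.searchsorted(other, mids - flank, side="left")
            if len(mids):
                # dinucleotide start positions within [mid-flank, mid+flank],
                # clamped; only complete (non-N) dinucleotides are counted
                lo = np.maximum(0, np.ceil(mids - flank)).astype(np.int64)
                hi = np.minimum(L - 2, np.floor(mids + flank)).astype(np.int64)
                lo = np.minimum(lo, L - 1)
                valid = hi >= lo
                X[valid, nm:] = dcum[hi[valid] + 1] - dcum[lo[valid]]
            self.X_by_motif[name] = X


def landscape(
    seq: Sequence, occ, motif_set: MotifSet, flank: int = DEFAULT_FLANK
) -> np.ndarray:
    """Landscape vector (|M|+16) of one motif occurrence.

    Motif components count occurrences (of each motif, the occurrence
    itself included) whose midpoint is within +-flank of the occurrence
    midpoint; dinucleotide components count dinucleotides starting in the
    clamped base window [mid-flank, mid+flank].
    """
    if not (0 <= occ.start and occ.end <= len(seq.bases)):
        raise ValueError(f"occurrence {occ} outside sequence {seq.name!r}")
    ls = _SeqLandscapes(seq, motif_set, flank)
    mids = ls.mids_by_motif[occ.motif_name]
    idx = int(np.searchsorted(mids, occ.midpoint))
    if idx >= len(mids) or mids[idx] != occ.midpoint:
        raise ValueError(f"occurrence {occ} not found by scan")
    return ls.X_by_motif[occ.motif_name][idx]


# ---------------------------------------------------------------------------
# model


@dataclass
class MoccaModel:
    """Trained SVM-MOCCA state: one SVM per motif, plus weights w_m."""

    motif_set: MotifSet
    class_roster: tuple[str, ...]
    positive_label: str
    kernel: str = "quadratic"
    flank: int = DEFAULT_FLANK
    window_bp: int = DEFAULT_WINDOW
    svms: dict[str, SVC | None] = field(default_factory=dict)
    w: dict[str, float] = field(default_factory=dict)
    C: float = 1.0
    gamma: float | None = None
    coef0: float = 0.0

    def __post_init__(self):
        if self.positive_label not in self.class_roster:
            raise ValueError("positive label must be in the class roster")
        if self.kernel not in _KERNEL_DEGREE:
            raise ValueError(f"kernel must be one of {sorted(_KERNEL_DEGREE)}")

    @property
    def dim(self) -> int:
        return len(self.motif_set) + 16

    def _positive_counts(self, ls: _SeqLandscapes) -> dict[str, int]:
        f: dict[str, int] = {}
        for name in self.motif_set.names:
            X = ls.X_by_motif[name]
            svm = self.svms.get(name)
            if svm is None or len(X) == 0:
                f[name] = 0
            else:
                f[name] = int(np.sum(svm.predict(X) == 0))
        return f

    def classify_occurrences(self, seq: Sequence) -> dict[str, int]:
        """f(m): positively classified occurrence counts per motif."""
        return self._positive_counts(_SeqLandscapes(seq, self.motif_set, self.flank))

    def score_sequence(self, seq: Sequence, step: int = 10) -> float:
        """Max windowed S = sum_m w_m f(m); whole-sequence S if it fits."""
        _, scores = self.window_scores(seq, step=step)
        return float(scores.max())

    def window_scores(
        self, seq: Sequence, window_bp: int | None = None, step: int = 10
    ) -> tuple[np.ndarray, np.ndarray]:
        """(window starts, S per window) over a sliding grid.

        Occurrences are landscape-classified once against the full
        sequence; each positively classified occurrence of motif m then
        contributes w_m to every window fully containing it.
        """
        W = self.window_bp if window_bp is None else window_bp
        grid = window_grid(len(seq.bases), W, step)
        ls = _SeqLandscapes(seq, self.motif_set, self.flank)
        lo_list, hi_list, weights_list = [], [], []
        for motif in self.motif_set:
            name = motif.name
            X = ls.X_by_motif[name]
            svm = self.svms.get(name)
            wm = self.w.get(name, 0.0)
            if svm is None or len(X) == 0 or wm == 0.0:
                continue
            pos_mask = svm.predict(X) == 0
            mids = ls.mids_by_motif[name][pos_mask]
            half = len(motif.pattern) / 2
            lo_list.append(mids + half - W - 0.5)  # end - W, exclusive bound
            hi_list.append(mids - half)  # start
            weights_list.append(np.full(len(mids), wm))
        if not lo_list:
            return grid, np.zeros(len(grid))
        scores = scores_over_windows(
            grid,
            np.concatenate(lo_list),
            np.concatenate(hi_list),
            np.concatenate(weights_list),
        )
        return grid, scores


def train_mocca(
    classes: dict[str, list[Sequence]],
    positive_label: str,
    motif_set: MotifSet,
    kernel: str = "quadratic",
    flank: int = DEFAULT_FLANK,
    window_bp: int = DEFAULT_WINDOW,
    C: float = 1.0,
    gamma: float | None = None,
    coef0: float = 0.0,
    alpha: float = 1.0,
) -> MoccaModel:
    """Train one multi-class SVM per motif and the per-motif weights w_m.

    ``classes`` maps class label -> training sequences; the positive
    label must be present and every class non-empty.  Class order in the
    dict fixes the internal class codes (the positive class is always
    code 0), which also resolves majority-vote ties deterministically in
    favour of earlier classes.
    """
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not in classes")
    for label, seqs in classes.items():
        if not seqs:
            raise ValueError(f"class {label!r} is empty")
    roster = (positive_label,) + tuple(
        lbl for lbl in classes if lbl != positive_label
    )
    code = {lbl: i for i, lbl in enumerate(roster)}
    model = MoccaModel(
        motif_set, roster, positive_label, kernel=kernel, flank=flank,
        window_bp=window_bp, C=C, gamma=gamma, coef0=coef0,
    )
    # default gamma is variance-scaled (libsvm 'scale'): dinucleotide counts
    # are O(flank/16), so 1/(dim * var) keeps polynomial kernel values O(1),
    # which conditions the optimization far better than a fixed 1/dim
    gamma_val = gamma if gamma is not None else "scale"

    # one landscape pass per training sequence, reused for w_m below
    landscapes: list[tuple[int, _SeqLandscapes]] = []
    for label, seqs in classes.items():
        for seq in seqs:
            landscapes.append((code[label], _SeqLandscapes(seq, motif_set, flank)))

    for name in motif_set.names:
        X = np.vstack([ls.X_by_motif[name] for _, ls in landscapes])
        y = np.concatenate(
            [np.full(len(ls.X_by_motif[name]), c) for c, ls in landscapes]
        )
        if len(X) == 0 or len(np.unique(y)) < 2:
            warnings.warn(
                f"motif {name!r}: no occurrences in >=2 classes; SVM absent, w=0"
            )
            model.svms[name] = None
            continue
        svm = SVC(
            kernel="poly",
            degree=_KERNEL_DEGREE[kernel],
            C=C,
            gamma=gamma_val,
            coef0=coef0,
        )
        svm.fit(X, y)
        model.svms[name] = svm

    # w_m from positively classified occurrence frequencies
    n_pos = len(classes[positive_label])
    n_neg = sum(len(s) for lbl, s in classes.items() if lbl != positive_label)
    for name in motif_set.names:
        if model.svms[name] is None:
            model.w[name] = 0.0
            continue
        svm = model.svms[name]
        fp = fn = 0.0
        for c, ls in landscapes:
            X = ls.X_by_motif[name]
            if len(X) == 0:
                continue
            f = int(np.sum(svm.predict(X) == 0))
            if c == 0:
                fp += f
            else:
                fn += f
        model.w[name] = math.log((fp / n_pos + alpha) / (fn / n_neg + alpha))
    return model


def score_sequence_mocca(model: MoccaModel, seq: Sequence, step: int = 10) -> float:
    return model.score_sequence(seq, step=step)


def save_mocca(model: MoccaModel, directory) -> None:
    """Write a model bundle: motif TSV, weights TSV, pickled SVMs, meta."""
    import json
    from pathlib import Path

    import joblib

    from .motifs import write_motifs_tsv

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_motifs_tsv(model.motif_set, d / "motifs.tsv")
    with open(d / "weights.tsv", "w") as fh:
        fh.write("motif\tw\n")
        for name in model.motif_set.names:
            fh.write(f"{name}\t{model.w[name]!r}\n")
    meta = {
        "classes": list(model.class_roster),
        "positive": model.positive_label,
        "kernel": model.kernel,
        "flank": model.flank,
        "window_bp": model.window_bp,
        "C": model.C,
        "gamma": model.gamma,
        "coef0": model.coef0,
    }
    with open(d / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    for name in model.motif_set.names:
        svm = model.svms.get(name)
        if svm is not None:
            joblib.dump(svm, d / f"svm_{name}.joblib")


def load_mocca(directory) -> MoccaModel:
    import json
    from pathlib import Path

    import joblib

    from .motifs import read_motifs_tsv

    d = Path(directory)
    motif_set = read_motifs_tsv(d / "motifs.tsv")
    meta = json.load(open(d / "meta.json"))
    model = MoccaModel(
        motif_set,
        tuple(meta["classes"]),
        meta["positive"],
        kernel=meta["kernel"],
        flank=meta["flank"],
        window_bp=meta["window_bp"],
        C=meta["C"],
        gamma=meta["gamma"],
        coef0=meta["coef0"],
    )
    with open(d / "weights.tsv") as fh:
        fh.readline()
        for line in fh:
            name, w = line.rstrip("\n").split("\t")
            model.w[name] = float(w)
    for name in motif_set.names:
        p = d / f"svm_{name}.joblib"
        model.svms[name] = joblib.load(p) if p.exists() else None
    return model


# ---------------------------------------------------------------------------
# quadratic-kernel expansion into feature pairs


@dataclass
class PairExpansion:
    """Condensed quadratic-kernel weights over merged feature pairs."""

    merged_features: list[str]
    pair_weights: dict[tuple[str, str], float]
    linear_weights: dict[str, float]
    constant: float


def merged_feature_names(motif_set: MotifSet) -> tuple[list[str], list[int]]:
    """Merge reverse-complement dinucleotides into single features.

    Returns (merged feature names, mapping raw feature index -> merged
    index).  Motifs are kept as-is; the 16 dinucleotides collapse to 10
    (4 self-complementary + 6 complement pairs).
    """
    names = list(motif_set.names)
    mapping = list(range(len(names)))
    seen: dict[str, int] = {}
    for d in DINUCLEOTIDES:
        rc = iupac_complement(d)
        key = min(d, rc)
        if key not in seen:
            seen[key] = len(names)
            names.append(d if d == rc else f"{key}/{max(d, rc)}")
        mapping.append(seen[key])
    return names, mapping


def ovo_machines(svm: SVC):
    """Reconstruct libsvm's one-vs-one binary machines from a fitted SVC.

    Yields (class_i, class_j, alphas, support_vectors, intercept) for
    every class pair i < j; a positive decision value votes class_i.
    """
    cs = svm.classes_
    n_sv = svm.n_support_
    starts = np.concatenate([[0], np.cumsum(n_sv)])
    k = 0
    for i in range(len(cs)):
        for j in range(i + 1, len(cs)):
            sv_i = svm.support_vectors_[starts[i] : starts[i + 1]]
            sv_j = svm.support_vectors_[starts[j] : starts[j + 1]]
            a_i = svm.dual_coef_[j - 1, starts[i] : starts[i + 1]]
            a_j = svm.dual_coef_[i, starts[j] : starts[j + 1]]
            yield (
                int(cs[i]),
                int(cs[j]),
                np.concatenate([a_i, a_j]),
                np.vstack([sv_i, sv_j]),
                float(svm.intercept_[k]),
            )
            k += 1


def quadratic_form(
    alphas: np.ndarray, sv: np.ndarray, gamma: float, coef0: float, intercept: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Expand sum_s a_s (g<x_s, x> + c0)^2 + b into (Q, linear, const).

    The decision value is x^T Q x + linear . x + const.
    """
    Q = gamma**2 * (sv.T * alphas) @ sv
    lin = 2 * gamma * coef0 * (alphas @ sv)
    const = coef0**2 * alphas.sum() + intercept
    return Q, lin, const


def expand_quadratic(model: MoccaModel) -> PairExpansion:
    """Condense all PRE-vs-non-PRE quadratic machines into pair weights.

    For every motif SVM, every binary machine separating the positive
    class from a negative class is expanded into an explicit quadratic
    form (oriented so positive values favour the positive class) and the
    quadratic coefficients are summed.  Feature pairs duplicated by
    dinucleotide reverse complementation or by reversed pairing order are
    added together.
    """
    if model.kernel != "quadratic":
        raise ValueError(f"expansion requires a quadratic kernel, got {model.kernel!r}")
    dim = model.dim
    Q_total = np.zeros((dim, dim))
    lin_total = np.zeros(dim)
    const_total = 0.0
    for name in model.motif_set.names:
        svm = model.svms.get(name)
        if svm is None:
            continue
        gamma_val = float(svm._gamma)  # resolved value ('scale' or explicit)
        for ci, cj, alphas, sv, b in ovo_machines(svm):
            if ci != 0:  # only positive-vs-negative boundaries
                continue
            Q, lin, const = quadratic_form(alphas, sv, gamma_val, model.coef0, b)
            Q_total += Q
            lin_total += lin
            const_total += const

    # unordered raw pairs: symmetrize off-diagonals
    S = Q_total + Q_total.T
    merged, mapping = merged_feature_names(model.motif_set)
    pair_weights: dict[tuple[str, str], float] = {}
    linear_weights: dict[str, float] = {}
    for i in range(dim):
        mi = merged[mapping[i]]
        linear_weights[mi] = linear_weights.get(mi, 0.0) + float(lin_total[i])
        for j in range(i, dim):
            mj = merged[mapping[j]]
            key = tuple(
                sorted((mi, mj), key=lambda nm: merged.index(nm))
            )
            w = float(Q_total[i, i]) if i == j else float(S[i, j])
            pair_weights[key] = pair_weights.get(key, 0.0) + w
    return PairExpansion(merged, pair_weights, linear_weights, const_total)


def expansion_decision_value(
    Q: np.ndarray, lin: np.ndarray, const: float, x: np.ndarray
) -> float:
    """Evaluate the expanded quadratic form at x (for oracle checks)."""
    return float(x @ Q @ x + lin @ x + const)
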