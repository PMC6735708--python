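"""Per-motif SVM landscapes, scoring, and the quadratic-kernel expansion."""

import math

import numpy as np
import pytest

from moccapre import (
    Motif,
    MotifSet,
    Sequence,
    builtin_motif_presets,
    expand_quadratic,
    landscape,
    merged_feature_names,
    pr_curve,
    train_mocca,
)
from moccapre.mocca import (
    MoccaModel,
    _SeqLandscapes,
    expansion_decision_value,
    ovo_machines,
    quadratic_form,
)
from moccapre.motifs import scan, scan_all


@pytest.fixture(scope="module")
def trained(landscape_fixture, motif_set8):
    pos, neg = landscape_fixture
    return train_mocca(
        {"PRE": pos[:20], "dummy-PRE": neg[:100], "dummy-genomic": neg[100:150]},
        "PRE",
        motif_set8,
        kernel="quadratic",
    )


def test_landscape_dimension_is_m_plus_16(motif_set8):
    seq = Sequence("s", "T" * 100 + "GAGAG" + "T" * 100)
    occ = scan(seq, motif_set8[motif_set8.index("GAF")])[0]
    v = landscape(seq, occ, motif_set8, flank=250)
    assert v.shape == (24,)


def test_landscape_homopolymer_dinucleotides():
    # occurrence centered in a 501 bp poly-A: the +-250 bp base window
    # holds 500 AA dinucleotides and nothing else
    ms = MotifSet((Motif("A4", "AAAA", 0),))
    seq = Sequence("s", "A" * 501)
    occs = scan(seq, ms[0])
    occ = next(o for o in occs if o.midpoint == 250)
    v = landscape(seq, occ, ms, flank=250)
    dinucs = v[1:]
    assert dinucs[0] == 500  # AA
    assert dinucs[1:].sum() == 0


def test_landscape_includes_own_occurrence(motif_set8):
    seq = Sequence("s", "T" * 300 + "GCCAT" + "T" * 300)
    occ = scan(seq, motif_set8[motif_set8.index("PS")])[0]
    v = landscape(seq, occ, motif_set8, flank=250)
    assert v[motif_set8.index("PS")] >= 1


def test_landscape_occurrence_outside_sequence_errors(motif_set8):
    from moccapre.motifs import MotifOccurrence

    seq = Sequence("s", "ACGT" * 10)
    occ = MotifOccurrence("GAF", "s", 50, 55, "+")
    with pytest.raises(ValueError):
        landscape(seq, occ, motif_set8)


def test_w_closed_form(motif_set8, landscape_fixture):
    """w_m = ln[(f-mean pos + a)/(f-mean neg + a)] from classified counts."""
    pos, neg = landscape_fixture
    model = train_mocca(
        {"PRE": pos[:10], "dummy-PRE": neg[:40]}, "PRE", motif_set8
    )
    fp = sum(model.classify_occurrences(s)["GAF"] for s in pos[:10]) / 10
    fn = sum(model.classify_occurrences(s)["GAF"] for s in neg[:40]) / 40
    assert model.w["GAF"] == pytest.approx(math.log((fp + 1) / (fn + 1)))


def test_separable_fixture_training_accuracy(motif_set8):
    """Disjoint landscape distributions give 100% training accuracy.

    A/T backgrounds contain no GAF hits on either strand, so the only
    occurrences are the planted ones: CA-flanked in positives,
    plain-flanked in negatives — perfectly separable landscapes.
    """
    rng = np.random.default_rng(17)

    def seq(cls, i, rich):
        bg = "".join(rng.choice(list("AT"), size=150))
        flank = "CACACACACA" if rich else "TTTTTTTTTT"
        return Sequence(f"{cls}{i}", bg + flank + "GAGAG" + flank + bg)

    pos = [seq("p", i, True) for i in range(6)]
    neg = [seq("n", i, False) for i in range(12)]
    # large-margin C: with so few occurrences the default C=1 trades the
    # tiny training set's accuracy for margin
    model = train_mocca({"PRE": pos, "bg": neg}, "PRE", motif_set8, C=100.0)
    svm = model.svms["GAF"]
    for cls_code, seqs in ((0, pos), (1, neg)):
        for s in seqs:
            X = _SeqLandscapes(s, motif_set8).X_by_motif["GAF"]
            assert len(X) >= 1
            assert np.all(svm.predict(X) == cls_code)


def test_classify_bounds_and_empty(trained, motif_set8):
    f = trained.classify_occurrences(Sequence("e", "T" * 500))
    assert all(v == 0 for v in f.values())
    seq = Sequence("s", "T" * 200 + "GAGAG" + "T" * 200)
    f = trained.classify_occurrences(seq)
    occs = scan_all(seq, motif_set8)
    for name in motif_set8.names:
        assert 0 <= f[name] <= sum(o.motif_name == name for o in occs)


def test_score_is_weighted_sum_of_f(trained):
    seq = Sequence("s", "T" * 100 + "GAGAG" + "T" * 50 + "GCCAT" + "T" * 100)
    f = trained.classify_occurrences(seq)
    expected = sum(trained.w[m] * f[m] for m in trained.motif_set.names)
    assert trained.score_sequence(seq) == pytest.approx(expected)


def test_score_linearity_in_w(trained, landscape_fixture):
    pos, _ = landscape_fixture
    seq = pos[-1]
    s1 = trained.score_sequence(seq)
    saved = dict(trained.w)
    try:
        for k in trained.w:
            trained.w[k] *= 2
        assert trained.score_sequence(seq) == pytest.approx(2 * s1)
    finally:
        trained.w.update(saved)


def test_positive_class_separation_on_fixture(trained, landscape_fixture):
    pos, neg = landscape_fixture
    f_pos = [trained.classify_occurrences(s)["GAF"] for s in pos[20:30]]
    f_neg = [trained.classify_occurrences(s)["GAF"] for s in neg[150:200]]
    assert np.median(f_pos) > np.median(f_neg)


def test_motif_without_occurrences_is_absent():
    ms = MotifSet((Motif("GAF", "GAGAG", 0), Motif("X", "CCCCCCCCCC", 0)))
    pos = [Sequence("p", "T" * 100 + "GAGAG" + "T" * 100)] * 3
    neg = [Sequence("n", "A" * 100 + "GAGAG" + "A" * 100)] * 3
    with pytest.warns(UserWarning, match="SVM absent"):
        model = train_mocca({"PRE": pos, "bg": neg}, "PRE", ms)
    assert model.svms["X"] is None
    assert model.w["X"] == 0.0


def test_kernel_degrees_exposed(landscape_fixture, motif_set8):
    pos, neg = landscape_fixture
    for kernel, degree in (("linear", 1), ("cubic", 3)):
        model = train_mocca(
            {"PRE": pos[:5], "bg": neg[:20]}, "PRE", motif_set8, kernel=kernel
        )
        fitted = [s for s in model.svms.values() if s is not None]
        assert fitted and all(s.degree == degree for s in fitted)


# ---------------------------------------------------------------------------
# quadratic expansion


def test_expansion_reproduces_decision_values(trained):
    """Expanded quadratic form == libsvm kernel decision values (oracle)."""
    rng = np.random.default_rng(0)
    for name in ("GAF", "PS", "GTGT"):
        svm = trained.svms[name]
        if svm is None:
            continue
        X = rng.random((100, trained.dim)) * 30
        svm.decision_function_shape = "ovo"
        ref = svm.decision_function(X)
        machines = list(ovo_machines(svm))
        assert ref.shape[1] == len(machines)
        for k, (ci, cj, alphas, sv, b) in enumerate(machines):
            Q, lin, c = quadratic_form(alphas, sv, float(svm._gamma), svm.coef0, b)
            mine = np.array([expansion_decision_value(Q, lin, c, x) for x in X])
            rel = np.abs(mine - ref[:, k]) / np.maximum(np.abs(ref[:, k]), 1e-9)
            assert rel.max() < 1e-6


def test_expansion_requires_quadratic(landscape_fixture, motif_set8):
    pos, neg = landscape_fixture
    model = train_mocca(
        {"PRE": pos[:5], "bg": neg[:20]}, "PRE", motif_set8, kernel="linear"
    )
    with pytest.raises(ValueError):
        expand_quadratic(model)


def test_merged_features_and_pair_counts(motif_set8):
    merged, mapping = merged_feature_names(motif_set8)
    # 8 motifs + 10 rc-merged dinucleotides
    assert len(merged) == 18
    assert len(mapping) == 24
    n = len(merged)
    assert n * (n + 1) // 2 == 171


def test_two_feature_pair_count():
    ms = MotifSet((Motif("a", "AAAAA", 0), Motif("b", "CCCCC", 0)))
    merged, _ = merged_feature_names(ms)
    # motifs + 10 dinuc classes; restricting to the 2 motifs alone:
    # C(2,2) + 2 self = 3 unordered pairs
    pairs = [(i, j) for i in range(2) for j in range(i, 2)]
    assert len(pairs) == 3


def test_condensed_expansion_has_171_pairs(trained):
    exp = expand_quadratic(trained)
    assert len(exp.merged_features) == 18
    assert len(exp.pair_weights) == 171
    assert all(np.isfinite(w) for w in exp.pair_weights.values())


def test_model_bundle_round_trip(tmp_path, trained, landscape_fixture):
    from moccapre.mocca import load_mocca, save_mocca

    pos, _ = landscape_fixture
    save_mocca(trained, tmp_path / "bundle")
    back = load_mocca(tmp_path / "bundle")
    for s in pos[30:33]:
        assert back.score_sequence(s) == pytest.approx(trained.score_sequence(s))
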