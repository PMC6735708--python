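"""Genome scanning, merging, core fragments, and region analytics."""

import numpy as np
import pytest

from moccapre import (
    GeneAnnotation,
    GenomicRegion,
    Sequence,
    assign_target_genes,
    core_fragment,
    dummy_predictor,
    filter_by_signals,
    merge_regions,
    overlap_sensitivity,
    promoters,
    resize_regions,
    scan_genome,
    shrink_regions,
    train_pair_model,
)


def R(start, end, chrom="c", **kw):
    return GenomicRegion(chrom, start, end, **kw)


def test_merge_overlapping_not_touching():
    merged = merge_regions([R(0, 500, score=1.0), R(400, 900, score=2.0)])
    assert [(m.start, m.end, m.score) for m in merged] == [(0, 900, 2.0)]
    merged = merge_regions([R(0, 500), R(500, 900)])
    assert len(merged) == 2  # book-ended regions share no base


def test_merged_regions_sorted_nonoverlapping():
    rng = np.random.default_rng(0)
    regs = [R(int(s), int(s) + int(l)) for s, l in zip(rng.integers(0, 5000, 100), rng.integers(1, 300, 100))]
    merged = merge_regions(regs)
    for a, b in zip(merged, merged[1:]):
        assert a.end <= b.start


@pytest.fixture(scope="module")
def synthetic_chromosome(motif_set8, background, planted_corpus):
    from moccapre.markov import generate

    pos, neg, _ = planted_corpus
    rng = np.random.default_rng(21)
    left = generate(background, 4000, rng).bases
    right = generate(background, 4000, rng).bases
    plant = pos[0].bases
    chrom = Sequence("synthchr", left + plant + right)
    model = train_pair_model(pos[1:20], neg[:100], motif_set8)
    return chrom, model, (len(left), len(left) + len(plant))


def test_scan_finds_single_planted_cluster(synthetic_chromosome):
    chrom, model, (lo, hi) = synthetic_chromosome
    starts, scores = model.window_scores(chrom)
    near_plant = (starts + model.window_bp > lo) & (starts < hi)
    assert scores[near_plant].max() > scores[~near_plant].max()
    thr = (scores[near_plant].max() + scores[~near_plant].max()) / 2
    preds = scan_genome(model, {"synthchr": chrom}, thr)
    assert len(preds.regions) == 1
    (p,) = preds.regions
    assert p.start < hi and lo < p.end  # overlaps the plant site
    assert p.score > thr


def test_scan_empty_when_threshold_high(synthetic_chromosome):
    chrom, model, _ = synthetic_chromosome
    preds = scan_genome(model, {"synthchr": chrom}, 1e9)
    assert preds.regions == []


def test_threshold_is_strict(motif_set8):
    model = dummy_predictor(motif_set8)
    chrom = Sequence("c", "T" * 2000)  # all window scores are exactly 0
    assert scan_genome(model, {"c": chrom}, 0.0).regions == []


def test_step1_coverage_dominates_step10(synthetic_chromosome):
    chrom, model, _ = synthetic_chromosome
    thr = 1.0
    p10 = scan_genome(model, {"synthchr": chrom}, thr, step_bp=10)
    p1 = scan_genome(model, {"synthchr": chrom}, thr, step_bp=1)
    fine = p1.regions
    for r in p10.regions:
        assert any(f.start <= r.start and r.end <= f.end for f in fine)


def test_core_fragment_within_parent_and_rescorable(synthetic_chromosome):
    chrom, model, (lo, hi) = synthetic_chromosome
    parent = GenomicRegion("synthchr", max(0, lo - 500), hi + 500)
    pseq = Sequence("parent", chrom.bases[parent.start : parent.end])
    frag = core_fragment(model, pseq, parent)
    assert parent.start <= frag.core.start < frag.core.end <= parent.end
    core_seq = Sequence("core", chrom.bases[frag.core.start : frag.core.end])
    # raw core score equals independent rescoring of the core sequence
    assert model.score_window(core_seq) == pytest.approx(frag.core.score)
    assert frag.normalized_score == pytest.approx(frag.core.score / len(frag.core))


def test_core_fragment_compact_island_picks_smallest_size(motif_set8, background):
    from moccapre.markov import generate

    model = dummy_predictor(motif_set8)
    rng = np.random.default_rng(5)
    base = generate(background, 2000, rng).bases
    island = ("GAGAG" + "T" * 15 + "GCCAT" + "A" * 15) * 10  # 400 bp signal
    pseq = Sequence("p", base[:800] + island + base[800 + len(island) :])
    parent = GenomicRegion("c", 0, 2000)
    frag = core_fragment(model, pseq, parent)
    assert len(frag.core) == 500
    assert frag.core.start <= 800 <= frag.core.end


def test_core_fragment_uniform_parent_tie_break(motif_set8):
    model = dummy_predictor(motif_set8)
    pseq = Sequence("p", "T" * 1200)  # zero everywhere
    frag = core_fragment(model, pseq, GenomicRegion("c", 0, 1200))
    assert (frag.core.start, len(frag.core)) == (0, 500)


def test_core_fragment_short_parent_is_itself(motif_set8):
    model = dummy_predictor(motif_set8)
    pseq = Sequence("p", "T" * 300)
    frag = core_fragment(model, pseq, GenomicRegion("c", 100, 400))
    assert (frag.core.start, frag.core.end) == (100, 400)


def test_resize_regions():
    (r,) = resize_regions([R(1000, 2000)], 3000)
    assert (r.start, r.end) == (0, 3000)
    (r,) = resize_regions([R(5000, 8000)], 3000)
    assert (r.start, r.end) == (5000, 8000)
    with pytest.warns(UserWarning, match="clamped"):
        (r,) = resize_regions([R(100, 200)], 3000, {"c": 10000})
    assert (r.start, r.end) == (0, 1650)


def test_overlap_sensitivity_edges():
    assert overlap_sensitivity([R(0, 10)], [R(9, 20)], extend_b=0) == 1.0
    assert overlap_sensitivity([R(0, 10)], [R(10, 20)], extend_b=0) == 0.0
    a = [R(0, 10), R(20, 30), R(40, 50), R(60, 70)]
    b = [R(5, 25)]
    assert overlap_sensitivity(a, b, extend_b=0) == 0.5
    assert overlap_sensitivity(a, b, extend_b=20) == 0.75
    assert overlap_sensitivity(a, b, extend_b=40) == 1.0
    with pytest.raises(ValueError):
        overlap_sensitivity([], b)


def test_overlap_agrees_with_exhaustive_oracle():
    rng = np.random.default_rng(8)

    def rand_regions(n, chroms=("c1", "c2")):
        out = []
        for _ in range(n):
            s = int(rng.integers(0, 2000))
            out.append(R(s, s + int(rng.integers(1, 100)), chrom=str(rng.choice(chroms))))
        return out

    for _ in range(10):
        a, b = rand_regions(40), rand_regions(30)
        got = overlap_sensitivity(a, b, extend_b=0)
        brute = sum(any(x.overlaps(y) for y in b) for x in a) / len(a)
        assert got == pytest.approx(brute)


def test_assign_target_genes():
    genes = [
        GeneAnnotation("g1", R(100, 200), "+"),
        GeneAnnotation("g2", R(300, 400), "+"),
        GeneAnnotation("g3", R(1000, 1100), "-"),
    ]
    inside = R(150, 160)
    spanning = R(180, 350)
    between = R(600, 700)  # 200 from g2 end, 300 to g3 start
    tied = R(450, 950)  # 50 from g2, 50 to g3
    out = assign_target_genes([inside, spanning, between, tied], genes)
    assert out[inside] == ["g1"]
    assert sorted(out[spanning]) == ["g1", "g2"]
    assert out[between] == ["g2"]
    assert sorted(out[tied]) == ["g2", "g3"]


def test_assign_target_genes_no_genes_on_chromosome():
    genes = [GeneAnnotation("g1", R(0, 10, chrom="c1"))]
    r = R(0, 5, chrom="c2")
    with pytest.warns(UserWarning, match="no genes"):
        out = assign_target_genes([r], genes)
    assert out[r] == []


def test_filter_by_signals():
    preds = [R(i * 100, i * 100 + 50) for i in range(5)]
    sets = {
        "A": [R(0, 250)],  # covers preds 0,1,2
        "B": [R(150, 450)],  # covers preds 2,3,4 (pred 1 ends at 150)
    }
    assert filter_by_signals(preds, {"A": [R(0, 10_000)]}, "A") == preds
    assert filter_by_signals(preds, sets, "A AND B") == [preds[2]]
    got = filter_by_signals(preds, sets, "A OR B")
    assert got == preds
    disjoint = {"A": [R(0, 10)], "B": [R(5000, 5010)]}
    assert filter_by_signals(preds, disjoint, "A AND B") == []
    with pytest.raises(KeyError):
        filter_by_signals(preds, sets, "A AND C")


def test_promoters_and_shrink():
    genes = [
        GeneAnnotation("plus", R(5000, 9000), "+"),
        GeneAnnotation("minus", R(5000, 9000), "-"),
    ]
    prom = promoters(genes)
    assert (prom[0].start, prom[0].end) == (2000, 5500)
    assert (prom[1].start, prom[1].end) == (8500, 12000)
    assert shrink_regions([R(0, 600)], 250) == [R(250, 350)]
    assert shrink_regions([R(0, 500)], 250) == []
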