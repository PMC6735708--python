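"""Shared fixtures: Markov backgrounds and planted-motif corpora.

All fixtures are generated programmatically with fixed seeds; nothing is
read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from moccapre import (
    Motif,
    Sequence,
    SyntheticCorpusSpec,
    builtin_motif_presets,
    make_synthetic_corpus,
    train_markov,
)
from moccapre.markov import generate


def biased_background(seed: int = 0, order: int = 4, size: int = 100_000):
    """Order-n chain trained on an AT-rich random sequence."""
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=size))
    return train_markov([Sequence("bg", base)], order)


@pytest.fixture(scope="session")
def background():
    return biased_background()


@pytest.fixture(scope="session")
def motif_set8():
    return builtin_motif_presets("ringrose7+gtgt")


@pytest.fixture(scope="session")
def planted_corpus(background):
    """Pair-clustered corpus: GAF+PS clusters in positives, plain negatives."""
    spec = SyntheticCorpusSpec(
        n_pos=40,
        n_neg=300,
        length=1000,
        background=background,
        planted_motifs=[
            (Motif("GAF", "GAGAG", 0), 4, 200),
            (Motif("PS", "GCCAT", 0), 4, 200),
        ],
        seed=11,
    )
    return make_synthetic_corpus(spec)


def landscape_corpus(background, n_pos, n_neg, length=2000, seed=5):
    """Both classes carry 4 planted GAF copies; only positives embed them
    in CA-rich local flanks, so the classes differ by landscape, not by
    motif-pair content."""
    g = np.random.default_rng(seed)
    out = {}
    for cls, n, rich in (("pos", n_pos, True), ("neg", n_neg, False)):
        lst = []
        for i in range(n):
            bases = list(generate(background, length, g).bases)
            anchor = int(g.integers(100, length - 300))
            offs = g.choice(np.arange(0, 195, 8), size=4, replace=False)
            for o in sorted(int(x) for x in offs):
                s = anchor + o
                bases[s : s + 5] = "GAGAG"
                if rich:
                    fl = "".join(g.choice(list("CA"), size=30))
                    lo = max(0, s - 35)
                    bases[lo : s - 5] = list(fl)[: max(0, s - 5 - lo)]
                    bases[s + 5 : s + 35] = list(fl)
            lst.append(Sequence(f"{cls}_{i}", "".join(bases)))
        out[cls] = lst
    return out["pos"], out["neg"]


@pytest.fixture(scope="session")
def landscape_fixture(background):
    return landscape_corpus(background, 40, 400)
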