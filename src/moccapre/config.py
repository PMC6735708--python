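"""Run configuration with the standard parameter defaults.

Defaults follow the study conditions this toolkit implements: order-4
background chains, 100x dummy multipliers, 3 kb training sequences,
10 bp scan step, 219 bp pair cutoff, 500 bp CPREdictor / 3 kb SVM-MOCCA
windows, +-250 bp landscape flank, 80% target precision, 50
cross-validation repetitions.  Configs are flat ``key=value`` text files
so runs stay diffable; CLI flags override file values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, fields


@dataclass
class RunConfig:
    motifs: str = "ringrose7+gtgt"  # preset name or motif TSV path
    model: str = "cpredictor"  # cpredictor | dummy | mocca
    kernel: str = "quadratic"
    window_bp: int = 0  # 0 = model default (500 cpredictor, 3000 mocca)
    step_bp: int = 10
    cutoff_bp: int = 219
    pair_pseudocount: float = 1.0
    w_pseudocount: float = 1.0
    markov_order: int = 4
    dummy_multiplier: int = 100
    seq_length: int = 3000
    flank_bp: int = 250
    target_precision: float = 0.80
    cv_repetitions: int = 50
    calibration_repetitions: int = 10
    seed: int = 1

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, v = line.split("=", 1)
                kv[k.strip()] = v.strip()
        kwargs = {}
        for f in cls.__dataclass_fields__.values():
            if f.name in kv:
                kwargs[f.name] = type(f.default)(kv[f.name])
        return cls(**kwargs)


def derive_seed(seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (seed * 1000003 + zlib.crc32(stage.encode()) + index) % (2**31)
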