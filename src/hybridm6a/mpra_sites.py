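"""Synthetic reporter-site sequences.

Generates 101-nt inserts each carrying exactly one DRACH motif with the
methylated A at the insert center, standing in for experimentally curated
m6A site windows when designing and validating reporter libraries.
"""

from __future__ import annotations

import numpy as np

from . import motif as motif_mod
from .mpra import INSERT_LEN


def synthetic_site_sequences(n: int, seed: int = 0,
                             pattern: str = "DRACH") -> dict:
    """n synthetic single-DRACH 101-nt inserts, keyed ``site####``."""
    rng = np.random.default_rng(seed)
    out = {}
    center = INSERT_LEN // 2  # 0-based A position
    for i in range(n):
        for _attempt in range(100):
            seq = ["ACGU"[b] for b in rng.integers(0, 4, INSERT_LEN)]
            seq[center - 2:center + 3] = list("GGACU")
            # remove accidental extra motifs deterministically
            for a in motif_mod.find_motif_positions("".join(seq), pattern):
                if a != center:
                    seq[a] = "C"
            hits = motif_mod.find_motif_positions("".join(seq), pattern)
            if hits == [center]:
                out[f"site{i:04d}"] = "".join(seq)
                break
        else:  # pragma: no cover - rejection loop essentially always succeeds
            raise RuntimeError("could not construct a single-motif insert")
    return out
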