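"""Synthetic demonstration matrices for the six TF families of interest.

These count matrices are constructed in-package to *emulate* the binding
preferences of the factor families relevant to notochord induction — an
Ets-family matrix and an RBPJ-family matrix that share a GGAA core, plus
Zic-, FoxA-, Brachyury- and Fos/Jun-like matrices.  They are synthetic
stand-ins for database matrices, intended for examples, simulations and
tests; they are not JASPAR entries and carry SYN_ ids to make that
unmistakable.
"""

from __future__ import annotations

import numpy as np

from .design import MotifLibrary
from .motifs import Background, PWM

__all__ = ["demo_motifs", "demo_library"]


def _pwm(motif_id: str, name: str, cols: list[tuple[int, int, int, int]]) -> PWM:
    return PWM(motif_id=motif_id, factor_name=name, counts=np.array(cols, float).T)


def demo_motifs() -> list[PWM]:
    """Six synthetic matrices; columns are (A, C, G, T) counts per position."""
    ets = _pwm(
        "SYN_ETS", "Ets-family (synthetic)",
        [
            (60, 10, 20, 10),   # a
            (10, 60, 10, 20),   # c
            (1, 1, 97, 1),      # G
            (1, 1, 97, 1),      # G
            (97, 1, 1, 1),      # A
            (85, 5, 5, 5),      # A
            (10, 10, 70, 10),   # g
            (15, 15, 10, 60),   # t
        ],
    )
    rbpj = _pwm(
        "SYN_RBPJ", "RBPJ/Su(H)-family (synthetic)",
        [
            (10, 60, 15, 15),   # c
            (10, 10, 70, 10),   # g
            (5, 5, 5, 85),      # T
            (1, 1, 97, 1),      # G
            (1, 1, 97, 1),      # G  } shares the GGAA core with SYN_ETS,
            (1, 1, 97, 1),      # G  } so the consensus embeds a complete
            (97, 1, 1, 1),      # A  } relaxed-threshold Ets-family match
            (90, 3, 3, 4),      # A
            (60, 10, 15, 15),   # a
            (20, 15, 15, 50),   # t
        ],
    )
    zic = _pwm(
        "SYN_ZIC", "Zic-family (synthetic)",
        [
            (10, 70, 10, 10),
            (5, 85, 5, 5),
            (10, 10, 10, 70),
            (5, 5, 85, 5),
            (5, 75, 10, 10),
            (10, 10, 10, 70),
            (10, 10, 70, 10),
        ],
    )
    foxa = _pwm(
        "SYN_FOXA", "FoxA-family (synthetic)",
        [
            (10, 10, 10, 70),
            (5, 5, 85, 5),
            (5, 5, 5, 85),
            (5, 5, 5, 85),
            (5, 5, 5, 85),
            (85, 5, 5, 5),
            (10, 70, 10, 10),
            (60, 10, 15, 15),
        ],
    )
    bra = _pwm(
        "SYN_BRA", "Brachyury/T-box (synthetic)",
        [
            (15, 15, 15, 55),
            (10, 10, 10, 70),
            (5, 75, 10, 10),
            (85, 5, 5, 5),
            (5, 75, 10, 10),
            (85, 5, 5, 5),
            (5, 75, 10, 10),
            (10, 70, 10, 10),
            (10, 10, 10, 70),
            (55, 15, 15, 15),
        ],
    )
    fosjun = _pwm(
        "SYN_FOSJUN", "Fos/Jun AP-1 (synthetic)",
        [
            (5, 5, 5, 85),
            (5, 5, 85, 5),
            (85, 5, 5, 5),
            (5, 85, 5, 5),
            (5, 5, 5, 85),
            (5, 85, 5, 5),
            (85, 5, 5, 5),
        ],
    )
    return [ets, rbpj, zic, foxa, bra, fosjun]


def demo_library(bg: Background | None = None, pseudocount: float = 0.1) -> MotifLibrary:
    """The synthetic matrices compiled against a background."""
    return MotifLibrary.build(demo_motifs(), bg or Background.uniform(), pseudocount)
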