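"""Bundled worked example: a published 13-TF master-regulator summary.

The table below reproduces the headline statistics of thirteen candidate
master regulators of an 85-gene colorectal-cancer prognostic signature (34
low-risk, 51 high-risk genes): the union of the top-10 TFs ranked by raw
regulon/signature coverage (MRA) and of the top-10 after stepwise-regression
edge filtering (MRA+SLR).  It is used in the documentation and tests as a
self-contained exercise of the competition-ranking and set arithmetic that
the selection step performs.
"""

from __future__ import annotations

import pandas as pd

# columns: tf, effect, regulon_size, mra_rank, mra_coverage, fdr,
#          slr_rank, slr_coverage  (printed ranks are over all 67
#          significant TFs, so later ranks skip unlisted competitors)
_ROWS = [
    ("PLAGL2", "+", 575, 1, 32, 7.73e-25, 1, 20),
    ("PRRX1", "-", 327, 4, 22, 2.10e-18, 2, 17),
    ("SPDEF", "-", 304, 6, 18, 6.50e-14, 3, 16),
    ("SATB2", "+", 264, 3, 23, 1.28e-21, 4, 15),
    ("ASCL2", "+", 537, 2, 28, 6.12e-21, 5, 11),
    ("AEBP1", "-", 465, 15, 12, 2.21e-05, 6, 10),
    ("TCF7", "+", 408, 9, 15, 9.47e-09, 7, 9),
    ("TCEAL1", "+", 276, 16, 10, 1.08e-05, 7, 9),
    ("HIF1A", "-", 371, 4, 22, 2.58e-17, 7, 9),
    ("GTF2IRD1", "+", 429, 16, 10, 0.000334, 7, 9),
    ("BCL6", "-", 455, 7, 16, 4.50e-09, 11, 8),
    ("TFCP2L1", "+", 364, 9, 15, 2.26e-09, 14, 7),
    ("FOSL2", "-", 421, 7, 16, 1.70e-09, 19, 6),
]


def colorectal_tf_example() -> pd.DataFrame:
    """The 13-TF worked example as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "tf",
            "effect",
            "regulon_size",
            "mra_rank",
            "mra_coverage",
            "fdr",
            "slr_rank",
            "slr_coverage",
        ],
    )
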