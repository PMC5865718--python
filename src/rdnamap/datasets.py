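"""Published read-mining totals for seven human Hi-C corpora.

These are the raw, post-QC, and rDNA-anchored read counts for the two
deep cell-line corpora (LCL from GSE63525, K562) and five H1-ESC
derived cell types (SRP033089): H1 embryonic stem cells (ESC),
mesendoderm (Mesod), mesenchymal stem cells (Mesec), neuronal
progenitors (Neuro) and trophoblast-like ectoderm cells (Ectod).  The
counts are inputs to the bookkeeping in
:func:`rdnamap.readprep.summarize_mining`; the derived percentages are
always recomputed, never stored.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["published_read_counts"]

_ROWS = [
    # dataset, total reads, reads after trimming+QC, 45S-anchored, 5S-anchored
    ("ESC", 1_965_460_504, 293_548_127, 300_903, 1_627),
    ("Mesod", 1_453_457_218, 282_703_604, 160_118, 1_217),
    ("Mesec", 1_946_805_860, 375_059_953, 167_365, 765),
    ("Neuro", 1_478_607_926, 284_198_790, 287_756, 1_449),
    ("Ectod", 936_917_416, 181_739_870, 179_897, 2_309),
    ("K562", 1_366_228_845, 903_837_936, 1_698_063, 47_691),
    ("LCL", 6_017_877_658, 5_356_990_189, 13_528_436, 105_147),
]


def published_read_counts() -> pd.DataFrame:
    """Per-dataset Hi-C read totals and rDNA-anchored read counts."""
    return pd.DataFrame(
        _ROWS, columns=["dataset", "total_reads", "qc_reads", "reads_45s", "reads_5s"]
    )
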