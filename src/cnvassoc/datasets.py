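"""Published dCN count tables used as regression fixtures.

These are the digitized copy-number (dCN) distributions of nine
immunity-related genes in a published Korean SLE case-control cohort
(338 controls, 327 cases after QC), entered from the study's printed
per-gene count table.  TLR7 is X-linked and reported separately by sex;
the high-copy tail of the CCL3L genes is pooled into a "4-6" display bin
as printed.

The published headline statistics computed from these counts are an odds
ratio of 1.6051 for single-copy C4B and a zero-cell lower bound of
18.5355 for CCL3L3-null status.
"""

from __future__ import annotations

import numpy as np

from .association import ContingencyTable
from .hwe import CNHistogram

__all__ = [
    "PUBLISHED_DCN_COUNTS",
    "PUBLISHED_BINARY_TABLES",
    "N_CONTROLS",
    "N_CASES",
    "published_contingency",
    "published_histogram",
]

N_CONTROLS = 338
N_CASES = 327

# gene -> (category labels, control counts, case counts); pooled display
# bins keep their printed labels
PUBLISHED_DCN_COUNTS: dict[str, tuple[tuple, tuple, tuple]] = {
    "TNFAIP3": (("1", "2"), (1, 337), (0, 327)),
    "TNIP1": (("1", "2"), (0, 338), (2, 325)),
    "IL12B": (("1", "2"), (0, 338), (3, 324)),
    "TBX21": (("1", "2"), (0, 338), (3, 324)),
    "TLR7_M": (("1", "2"), (131, 0), (34, 1)),
    "TLR7_F": (("1", "2"), (0, 307), (0, 292)),
    "C4A": (("1", "2", "3-4"), (39, 250, 49), (47, 242, 38)),
    "C4B": (("1", "2", "3", "4"), (43, 223, 41, 31), (62, 193, 51, 21)),
    "CCL3L1": (("0", "1", "2", "3", "4-6"), (17, 98, 125, 56, 42), (18, 92, 134, 41, 42)),
    "CCL3L3": (("0", "1", "2", "3", "4-6"), (0, 83, 141, 91, 23), (17, 74, 118, 84, 34)),
}

# the two headline binary contrasts: exposure category first
PUBLISHED_BINARY_TABLES: dict[str, tuple[tuple, tuple, tuple]] = {
    "C4B_low": (("1", "2-4"), (43, 295), (62, 265)),
    "CCL3L3_null": (("0", "1-6"), (0, 338), (17, 310)),
}


def published_contingency(name: str) -> ContingencyTable:
    """The printed 2xk count table for a gene (or binary contrast)."""
    source = PUBLISHED_DCN_COUNTS if name in PUBLISHED_DCN_COUNTS else PUBLISHED_BINARY_TABLES
    if name not in source:
        raise KeyError(name)
    labels, control, case = source[name]
    return ContingencyTable(np.array([control, case]), col_labels=labels)


def published_histogram(gene: str, group: str) -> CNHistogram:
    """Per-group dCN histogram on an integer grid.

    Pooled display bins ("3-4", "4-6") are read at their lower edge,
    which is the convention available from the printed counts alone.
    """
    labels, control, case = PUBLISHED_DCN_COUNTS[gene]
    counts = control if group == "control" else case
    kmax = max(int(str(l).split("-")[0]) for l in labels)
    hist = np.zeros(kmax + 1)
    for label, c in zip(labels, counts):
        hist[int(str(label).split("-")[0])] += c
    return CNHistogram(hist)
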