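"""Published layout metadata of the released cereal core panels.

``HvCoreSet_v1`` (barley, 768 markers on 7 chromosomes of the IBSC v2
reference) and ``TaCoreSet_v1`` (wheat, 960 markers on the 21 chromosomes of
IWGSC RefSeq v1.0) are released genotyping platforms.  This module records
their per-chromosome composition — marker count, first/last marker position,
and reference chromosome length, all in Mb — so the platform summary
statistics (covered span, coverage percentage, mean marker interval) can be
recomputed from the panel layout alone.  Unplaced ("Un") scaffolds contribute
reference length and, for wheat, eight panel markers without positions.
"""

from __future__ import annotations

import pandas as pd

from .markers import PlatformSummary, summary_from_endpoints

# chrom, n_markers, start_mb, end_mb, refseq_mb
_BARLEY_ROWS = [
    ("1H", 104, 1.4, 556.5, 558.5),
    ("2H", 109, 2.3, 766.3, 768.1),
    ("3H", 110, 0.1, 699.1, 699.7),
    ("4H", 109, 0.1, 646.0, 647.1),
    ("5H", 116, 0.4, 669.6, 670.0),
    ("6H", 115, 0.3, 582.4, 583.4),
    ("7H", 105, 0.6, 656.1, 657.2),
]
BARLEY_UNPLACED_MARKERS = 0
BARLEY_UNPLACED_REFSEQ_MB = 249.8

_WHEAT_ROWS = [
    ("1A", 47, 3.4, 591.2, 594.1),
    ("2A", 51, 2.5, 778.4, 780.8),
    ("3A", 42, 13.9, 743.8, 750.8),
    ("4A", 46, 2.9, 742.4, 744.6),
    ("5A", 49, 0.3, 689.9, 709.8),
    ("6A", 39, 0.6, 615.5, 618.1),
    ("7A", 52, 8.4, 733.4, 736.7),
    ("1B", 43, 4.3, 687.7, 689.9),
    ("2B", 51, 4.6, 789.9, 801.3),
    ("3B", 51, 0.2, 822.2, 830.8),
    ("4B", 41, 1.8, 670.4, 673.6),
    ("5B", 47, 7.7, 712.7, 713.1),
    ("6B", 52, 0.2, 718.9, 721.0),
    ("7B", 44, 2.9, 730.2, 750.6),
    ("1D", 38, 0.9, 494.2, 495.5),
    ("2D", 49, 0.4, 648.5, 651.9),
    ("3D", 40, 5.0, 613.4, 615.6),
    ("4D", 38, 1.3, 506.1, 509.9),
    ("5D", 50, 0.6, 562.7, 566.1),
    ("6D", 43, 0.8, 473.4, 473.6),
    ("7D", 39, 1.3, 631.8, 638.7),
]
WHEAT_UNPLACED_MARKERS = 8
WHEAT_UNPLACED_REFSEQ_MB = 481.0

_COLS = ["chrom", "n_markers", "start_mb", "end_mb", "refseq_mb"]


def barley_panel_endpoints() -> pd.DataFrame:
    """HvCoreSet_v1 per-chromosome layout (IBSC v2 coordinates, Mb)."""
    return pd.DataFrame(_BARLEY_ROWS, columns=_COLS)


def wheat_panel_endpoints() -> pd.DataFrame:
    """TaCoreSet_v1 per-chromosome layout (IWGSC RefSeq v1.0 coordinates, Mb)."""
    return pd.DataFrame(_WHEAT_ROWS, columns=_COLS)


def barley_panel_summary(decimals: int = 1) -> PlatformSummary:
    """Recompute the HvCoreSet_v1 platform summary from its layout."""
    return summary_from_endpoints(
        barley_panel_endpoints(),
        n_unplaced=BARLEY_UNPLACED_MARKERS,
        unplaced_refseq_mb=BARLEY_UNPLACED_REFSEQ_MB,
        decimals=decimals,
    )


def wheat_panel_summary(decimals: int = 1) -> PlatformSummary:
    """Recompute the TaCoreSet_v1 platform summary from its layout."""
    return summary_from_endpoints(
        wheat_panel_endpoints(),
        n_unplaced=WHEAT_UNPLACED_MARKERS,
        unplaced_refseq_mb=WHEAT_UNPLACED_REFSEQ_MB,
        decimals=decimals,
    )


def barley_chrom_sizes() -> pd.DataFrame:
    """Barley reference chromosome sizes (Mb), placed chromosomes only."""
    df = barley_panel_endpoints()[["chrom", "refseq_mb"]].rename(columns={"refseq_mb": "size_mb"})
    return df


def wheat_chrom_sizes() -> pd.DataFrame:
    """Wheat reference chromosome sizes (Mb), placed chromosomes only."""
    return wheat_panel_endpoints()[["chrom", "refseq_mb"]].rename(columns={"refseq_mb": "size_mb"})
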