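"""Core marker panel construction and platform summary statistics.

A core marker set is a small panel of amplicon-sequencing markers chosen from a
larger candidate catalog so that the panel tiles each chromosome at near-uniform
physical spacing while preferring highly polymorphic, well-mapping, low-missing
markers.  This module filters the candidate catalog, performs the windowed
selection, and computes the per-chromosome / whole-genome interval and coverage
statistics that summarize a genotyping platform.

Catalogs are plain :class:`pandas.DataFrame` objects with the columns

``marker_id, chrom, pos_bp, missing_rate, maf, map_class, n_extra_polymorphisms``

where ``chrom == "Un"`` marks unplaced markers (``pos_bp`` is then NA) and
``map_class`` is an ordinal mapping-quality class (1 = cleanest mapping, no
off-target or homoeologous interference).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNPLACED = "Un"

CATALOG_COLUMNS = [
    "marker_id",
    "chrom",
    "pos_bp",
    "missing_rate",
    "maf",
    "map_class",
    "n_extra_polymorphisms",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round ``x`` half-up (away from zero on ties) to ``decimals`` places.

    Platform summary tables use conventional half-up rounding, not the
    round-half-even rule of :func:`numpy.round`.
    """
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return np.nan
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SelectionConfig:
    """Tuning knobs for core-set construction.

    Parameters
    ----------
    max_missing:
        Strict upper bound on the candidate missing rate (candidates with
        ``missing_rate < max_missing`` survive).
    allowed_classes:
        Mapping-quality classes accepted into the panel.
    target_spacing_mb:
        Window length in Mb used to tile each chromosome; one marker is chosen
        per window, so this is the target inter-marker spacing.
    min_maf_dense, min_maf_sparse:
        MAF floors applied inside marker-rich and marker-poor windows.  The
        relaxed floor keeps coverage in regions where few candidates exist.
    dense_min_candidates:
        A window with at least this many candidates is "dense" and uses
        ``min_maf_dense``; below it the relaxed ``min_maf_sparse`` applies.
    """

    max_missing: float = 0.3
    allowed_classes: frozenset = frozenset({1, 2, 3})
    target_spacing_mb: float = 6.0
    min_maf_dense: float = 0.2
    min_maf_sparse: float = 0.05
    dense_min_candidates: int = 3

    def __post_init__(self):
        if self.target_spacing_mb <= 0:
            raise ValueError("target_spacing_mb must be positive")
        if self.min_maf_sparse > self.min_maf_dense:
            raise ValueError("min_maf_sparse must be <= min_maf_dense")


@dataclass
class CoreSet:
    """An ordered marker panel (sorted by chromosome, then position)."""

    markers: pd.DataFrame
    name: str = "CoreSet_v1"

    def __post_init__(self):
        if self.markers["marker_id"].duplicated().any():
            dup = self.markers.loc[self.markers["marker_id"].duplicated(), "marker_id"]
            raise ValueError(f"duplicate marker ids in core set: {list(dup.unique())[:5]}")

    def __len__(self) -> int:
        return len(self.markers)


@dataclass
class PlatformSummary:
    """Per-chromosome and total interval/coverage statistics of a panel.

    ``per_chrom`` has one row per placed chromosome with columns
    ``chrom, n_markers, max_interval_mb, mean_interval_mb, start_mb, end_mb,
    cover_mb, refseq_mb, coverage_pct`` (values rounded as reported).
    Chromosomes with fewer than two markers have undefined interval fields
    (NaN) and are listed in ``flagged``.
    """

    per_chrom: pd.DataFrame
    n_unplaced: int
    total_markers: int
    total_cover_mb: float
    total_refseq_mb: float
    total_coverage_pct: float
    overall_mean_interval_mb: float
    overall_max_interval_mb: float
    flagged: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Summary as one table: per-chromosome rows plus a totals row."""
        total = pd.DataFrame(
            [
                {
                    "chrom": "Total",
                    "n_markers": self.total_markers,
                    "max_interval_mb": self.overall_max_interval_mb,
                    "mean_interval_mb": self.overall_mean_interval_mb,
                    "start_mb": np.nan,
                    "end_mb": np.nan,
                    "cover_mb": self.total_cover_mb,
                    "refseq_mb": self.total_refseq_mb,
                    "coverage_pct": self.total_coverage_pct,
                }
            ]
        )
        return pd.concat([self.per_chrom, total], ignore_index=True)


def _validate_catalog(catalog: pd.DataFrame) -> None:
    missing_cols = [c for c in ("marker_id", "chrom", "missing_rate", "map_class") if c not in catalog.columns]
    if missing_cols:
        raise ValueError(f"catalog lacks required columns: {missing_cols}")
    bad = catalog[(catalog["missing_rate"] < 0) | (catalog["missing_rate"] > 1)]
    if len(bad):
        raise ValueError(
            "missing_rate outside [0, 1] for rows: "
            + ", ".join(str(m) for m in bad["marker_id"].head(10))
        )
    if "maf" in catalog.columns:
        bad_maf = catalog[(catalog["maf"] < 0) | (catalog["maf"] > 0.5)]
        if len(bad_maf):
            raise ValueError(
                "maf outside [0, 0.5] for rows: "
                + ", ".join(str(m) for m in bad_maf["marker_id"].head(10))
            )


def filter_candidates(catalog: pd.DataFrame, config: SelectionConfig | None = None) -> pd.DataFrame:
    """Apply the catalog-level quality filters.

    Keeps exactly the candidates with ``missing_rate`` strictly below
    ``config.max_missing`` and ``map_class`` in ``config.allowed_classes``;
    input row order is preserved.  Malformed rows (rates outside [0, 1]) raise
    a :class:`ValueError` naming the offending markers.
    """
    if config is None:
        config = SelectionConfig()
    if len(catalog) == 0:
        raise ValueError("candidate catalog is empty")
    _validate_catalog(catalog)
    keep = (catalog["missing_rate"] < config.max_missing) & catalog["map_class"].isin(
        config.allowed_classes
    )
    out = catalog.loc[keep].copy()
    if len(out) == 0:
        logger.warning("filter_candidates removed every candidate")
    return out


def select_core_set(
    filtered: pd.DataFrame,
    chrom_sizes: pd.DataFrame,
    config: SelectionConfig | None = None,
    name: str = "CoreSet_v1",
) -> CoreSet:
    """Choose a near-uniformly spaced, highly polymorphic panel.

    Each chromosome is tiled into consecutive windows of
    ``config.target_spacing_mb``.  Within every non-empty window the
    highest-MAF candidate passing the applicable MAF floor is selected
    (``min_maf_dense`` in windows holding at least ``dense_min_candidates``
    candidates, the relaxed ``min_maf_sparse`` otherwise — the floor relaxes
    where candidates are scarce so that coverage is retained across the
    genome).  Ties on MAF break by lower missing rate, then lower map class,
    then lower position, which makes the output invariant to input row order.
    The first and last candidate on each chromosome are always retained to
    maximize terminal coverage.

    ``chrom_sizes`` must contain columns ``chrom`` and ``size_mb`` covering
    every placed chromosome present in ``filtered``.  Unplaced (``"Un"``)
    candidates cannot be spaced and are excluded with a warning.
    """
    if config is None:
        config = SelectionConfig()
    sizes = chrom_sizes.set_index("chrom")["size_mb"]

    placed = filtered[filtered["chrom"] != UNPLACED]
    n_unplaced = len(filtered) - len(placed)
    if n_unplaced:
        warnings.warn(f"{n_unplaced} unplaced candidates excluded from spacing-based selection")

    missing_chroms = set(placed["chrom"]) - set(sizes.index)
    if missing_chroms:
        raise KeyError(f"chromosome(s) absent from chrom_sizes: {sorted(missing_chroms)}")

    window_bp = config.target_spacing_mb * 1e6
    chosen_idx: list = []
    for chrom, grp in placed.groupby("chrom", sort=False):
        grp = grp.sort_values(["pos_bp", "marker_id"])
        size_bp = float(sizes[chrom]) * 1e6
        n_windows = max(1, int(np.ceil(size_bp / window_bp)))
        win = np.minimum((grp["pos_bp"].to_numpy() // window_bp).astype(int), n_windows - 1)
        for w in range(n_windows):
            cand = grp[win == w]
            if len(cand) == 0:
                continue
            floor = (
                config.min_maf_dense
                if len(cand) >= config.dense_min_candidates
                else config.min_maf_sparse
            )
            passing = cand[cand["maf"] >= floor]
            if len(passing) == 0:
                warnings.warn(
                    f"window {w} on {chrom}: {len(cand)} candidate(s) but none pass "
                    f"MAF floor {floor}; gap left"
                )
                continue
            best = passing.sort_values(
                ["maf", "missing_rate", "map_class", "pos_bp"],
                ascending=[False, True, True, True],
                kind="mergesort",
            ).iloc[0]
            chosen_idx.append(best.name)
        # terminal retention: keep chromosome ends covered
        chosen_idx.append(grp.index[0])
        chosen_idx.append(grp.index[-1])

    selected = placed.loc[pd.unique(pd.Index(chosen_idx))]
    selected = selected.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)
    return CoreSet(markers=selected, name=name)


def _assemble_summary(
    endpoints: pd.DataFrame,
    n_unplaced: int,
    unplaced_refseq_mb: float,
    decimals: int,
    max_intervals: dict | None,
) -> PlatformSummary:
    """Shared arithmetic for endpoint-based and full-panel summaries.

    ``endpoints`` columns: chrom, n_markers, start_mb, end_mb, refseq_mb
    (unrounded).  ``max_intervals`` maps chrom -> largest adjacent gap in Mb,
    or None when positions are not available.
    """
    rows = []
    flagged = []
    covers, intervals, max_ints = [], [], []
    for _, r in endpoints.iterrows():
        n = int(r["n_markers"])
        if n < 2:
            flagged.append(r["chrom"])
            rows.append(
                {
                    "chrom": r["chrom"],
                    "n_markers": n,
                    "max_interval_mb": np.nan,
                    "mean_interval_mb": np.nan,
                    "start_mb": np.nan,
                    "end_mb": np.nan,
                    "cover_mb": np.nan,
                    "refseq_mb": round_half_up(r["refseq_mb"], decimals),
                    "coverage_pct": np.nan,
                }
            )
            continue
        cover = r["end_mb"] - r["start_mb"]
        mean_int = cover / (n - 1)
        max_int = max_intervals.get(r["chrom"], np.nan) if max_intervals else np.nan
        coverage = 100.0 * cover / r["refseq_mb"]
        covers.append(cover)
        intervals.append(n - 1)
        if max_intervals:
            max_ints.append(max_int)
        rows.append(
            {
                "chrom": r["chrom"],
                "n_markers": n,
                "max_interval_mb": round_half_up(max_int, decimals),
                "mean_interval_mb": round_half_up(mean_int, decimals),
                "start_mb": round_half_up(r["start_mb"], decimals),
                "end_mb": round_half_up(r["end_mb"], decimals),
                "cover_mb": round_half_up(cover, decimals),
                "refseq_mb": round_half_up(r["refseq_mb"], decimals),
                "coverage_pct": round_half_up(coverage, decimals),
            }
        )
    if flagged:
        warnings.warn(f"chromosome(s) with < 2 markers, interval fields undefined: {flagged}")

    total_cover = float(np.sum(covers))
    total_refseq = float(endpoints["refseq_mb"].sum()) + float(unplaced_refseq_mb)
    total_markers = int(endpoints["n_markers"].sum()) + int(n_unplaced)
    n_intervals = int(np.sum(intervals))
    return PlatformSummary(
        per_chrom=pd.DataFrame(rows),
        n_unplaced=int(n_unplaced),
        total_markers=total_markers,
        total_cover_mb=round_half_up(total_cover, decimals),
        total_refseq_mb=round_half_up(total_refseq, decimals),
        total_coverage_pct=round_half_up(100.0 * total_cover / total_refseq, decimals),
        overall_mean_interval_mb=round_half_up(total_cover / n_intervals, decimals)
        if n_intervals
        else np.nan,
        overall_max_interval_mb=round_half_up(max(max_ints), decimals) if max_ints else np.nan,
        flagged=flagged,
    )


def summarize_platform(
    core: CoreSet,
    chrom_sizes: pd.DataFrame,
    unplaced_refseq_mb: float = 0.0,
    decimals: int = 1,
) -> PlatformSummary:
    """Compute the platform summary table for a core set.

    Per chromosome: first/last marker position (Mb), covered span
    ``end - start``, mean adjacent interval ``cover / (n - 1)``, largest
    adjacent gap, and coverage as percent of the reference chromosome length.
    Totals: unplaced markers count toward the panel size only; the total
    coverage divides the summed covered span by the full reference length
    including unplaced scaffolds; the overall mean interval divides the summed
    cover by the summed interval count over placed chromosomes.  Reported
    values are rounded half-up to ``decimals``.
    """
    sizes = chrom_sizes.set_index("chrom")["size_mb"]
    placed = core.markers[core.markers["chrom"] != UNPLACED]
    n_unplaced = len(core.markers) - len(placed)

    missing = set(placed["chrom"]) - set(sizes.index)
    if missing:
        raise KeyError(f"chromosome(s) absent from chrom_sizes: {sorted(missing)}")

    ep_rows, max_ints = [], {}
    chrom_order = [c for c in sizes.index if c in set(placed["chrom"])]
    for chrom in chrom_order:
        pos_mb = np.sort(placed.loc[placed["chrom"] == chrom, "pos_bp"].to_numpy()) / 1e6
        ep_rows.append(
            {
                "chrom": chrom,
                "n_markers": len(pos_mb),
                "start_mb": pos_mb[0],
                "end_mb": pos_mb[-1],
                "refseq_mb": float(sizes[chrom]),
            }
        )
        if len(pos_mb) >= 2:
            max_ints[chrom] = float(np.max(np.diff(pos_mb)))
    return _assemble_summary(
        pd.DataFrame(ep_rows), n_unplaced, unplaced_refseq_mb, decimals, max_ints
    )


def summary_from_endpoints(
    endpoints: pd.DataFrame,
    n_unplaced: int = 0,
    unplaced_refseq_mb: float = 0.0,
    decimals: int = 1,
) -> PlatformSummary:
    """Platform summary from per-chromosome endpoint data alone.

    ``endpoints`` needs columns ``chrom, n_markers, start_mb, end_mb,
    refseq_mb``.  Useful for recomputing published platform tables where only
    counts and terminal positions are given; the per-chromosome maximum
    interval is then unavailable (NaN).
    """
    required = {"chrom", "n_markers", "start_mb", "end_mb", "refseq_mb"}
    if not required.issubset(endpoints.columns):
        raise ValueError(f"endpoints table needs columns {sorted(required)}")
    return _assemble_summary(endpoints, n_unplaced, unplaced_refseq_mb, decimals, None)


def count_secondary_polymorphic(core: CoreSet | pd.DataFrame) -> tuple[int, float]:
    """Markers whose amplicon carries polymorphisms besides the target site.

    Returns ``(count, fraction_of_panel)``.  Such markers support multi-allelic
    haplotype analysis and are more informative than single-SNP markers.
    """
    markers = core.markers if isinstance(core, CoreSet) else core
    if "n_extra_polymorphisms" not in markers.columns:
        raise ValueError("n_extra_polymorphisms column is not populated")
    count = int((markers["n_extra_polymorphisms"] > 0).sum())
    return count, count / len(markers) if len(markers) else 0.0


# ---------------------------------------------------------------------------
# I/O helpers (tab-separated, headered)

def read_catalog(path) -> pd.DataFrame:
    """Read a candidate catalog from a tab-separated file."""
    df = pd.read_csv(path, sep="\t")
    _validate_catalog(df)
    return df


def read_chrom_sizes(path) -> pd.DataFrame:
    """Read a chromosome-size table (columns ``chrom``, ``size_mb``)."""
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "size_mb"}.issubset(df.columns):
        raise ValueError("chrom sizes table needs columns 'chrom' and 'size_mb'")
    return df


def write_core_set(core: CoreSet, path) -> None:
    core.markers.to_csv(path, sep="\t", index=False)


def write_summary(summary: PlatformSummary, path) -> None:
    summary.to_frame().to_csv(path, sep="\t", index=False)
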