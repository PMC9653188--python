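"""Genotype-matrix ingestion, site QC filters, and MAF chromosome scans.

Genotypes live in a :class:`GenotypeMatrix`: an accessions x sites dosage
matrix (count of the alternate allele, 0/1/2, ``NaN`` for missing) with
per-site metadata (id, chromosome, position, alleles) and per-accession
metadata (id, breeding-station code, harvest year).  Only biallelic sites are
kept; the material is assumed mostly homozygous (inbred cereal lines), which
is why the QC filter treats a high heterozygous-call rate as a technical
artifact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Accessions x sites alternate-allele dosage matrix with metadata."""

    dosages: np.ndarray  # float array, entries in {0, 1, 2, NaN}
    site_meta: pd.DataFrame  # marker_id, chrom, pos_bp, ref, alt
    accession_meta: pd.DataFrame  # accession_id, station, year

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.accession_meta), len(self.site_meta)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with metadata "
                f"({len(self.accession_meta)} accessions, {len(self.site_meta)} sites)"
            )

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def subset_sites(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.dosages[:, mask],
            self.site_meta.loc[mask].reset_index(drop=True),
            self.accession_meta,
        )

    def subset_accessions(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.dosages[mask],
            self.site_meta,
            self.accession_meta.loc[mask].reset_index(drop=True),
        )


@dataclass
class MafProfile:
    """Raw per-site MAF points and per-chromosome smoothed curves.

    ``points`` columns: chrom, pos_mb, maf.  ``curves`` maps chromosome name to
    a frame with columns pos_mb, fit, ci_half (95% pointwise half-width);
    chromosomes with too few sites for smoothing carry points only.
    """

    points: pd.DataFrame
    curves: dict = field(default_factory=dict)


def _is_vcf(path) -> bool:
    with open(path, "rt") as fh:
        first = fh.readline()
    return first.startswith("##fileformat=VCF")


def load_genotypes(path, accession_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Load genotypes from a VCF (GT field) or a tab-separated dosage table.

    VCF: multi-allelic records are dropped with a warning (count logged);
    ``./.`` becomes missing; phasing is ignored.  Dosage table: one row per
    site with columns ``marker_id, chrom, pos_bp, ref, alt`` followed by one
    column per accession holding 0/1/2 or NA.

    ``accession_meta`` (accession_id, station, year) is attached when given;
    otherwise placeholder metadata is created from the sample names.
    """
    if _is_vcf(path):
        dosages, site_meta, samples = _load_vcf(path)
    else:
        dosages, site_meta, samples = _load_dosage_table(path)

    if len(samples) == 0:
        raise ValueError("no samples in genotype input")
    if dosages.shape[1] == 0 or np.all(np.isnan(dosages)):
        raise ValueError("no usable (biallelic, non-all-missing) sites in genotype input")

    if accession_meta is None:
        accession_meta = pd.DataFrame(
            {"accession_id": samples, "station": pd.NA, "year": pd.NA}
        )
    else:
        accession_meta = (
            accession_meta.set_index("accession_id").loc[samples].reset_index()
        )
    return GenotypeMatrix(dosages, site_meta, accession_meta)


def _load_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.genotypes  # [a0, a1, phased] per sample
        dos = np.array(
            [a + b if (a >= 0 and b >= 0) else np.nan for a, b, *_ in gts], dtype=float
        )
        rows.append(dos)
        meta.append(
            {
                "marker_id": var.ID or f"{var.CHROM}_{var.POS}",
                "chrom": var.CHROM,
                "pos_bp": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    if n_multi:
        logger.warning("dropped %d multi-allelic record(s)", n_multi)
    dosages = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return dosages, pd.DataFrame(meta, columns=["marker_id", "chrom", "pos_bp", "ref", "alt"]), samples


def _load_dosage_table(path):
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["marker_id", "chrom", "pos_bp", "ref", "alt"]
    if not set(meta_cols).issubset(df.columns):
        raise ValueError(f"dosage table needs leading columns {meta_cols}")
    samples = [c for c in df.columns if c not in meta_cols]
    dosages = df[samples].to_numpy(dtype=float).T
    return dosages, df[meta_cols].copy(), samples


def compute_site_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site MAF, missing rate, and heterozygous-call rate.

    MAF is allele-count based: with h heterozygotes and a alt-homozygotes among
    n non-missing calls, the alt-allele frequency is p = (h + 2a) / (2n) and
    MAF = min(p, 1 - p).  A heterozygote therefore contributes one alternate
    allele.  Sites with zero non-missing calls get NaN stats and are flagged.
    """
    d = gm.dosages
    n_total = d.shape[0]
    n_missing = np.isnan(d).sum(axis=0)
    n_obs = n_total - n_missing
    with np.errstate(invalid="ignore"):
        alt_count = np.nansum(d, axis=0)
        p = np.where(n_obs > 0, alt_count / (2 * np.maximum(n_obs, 1)), np.nan)
        het = (d == 1).sum(axis=0)
        het_rate = np.where(n_obs > 0, het / np.maximum(n_obs, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    stats = pd.DataFrame(
        {
            "marker_id": gm.site_meta["marker_id"].to_numpy(),
            "maf": maf,
            "missing_rate": n_missing / n_total,
            "het_rate": het_rate,
        }
    )
    n_undef = int((n_obs == 0).sum())
    if n_undef:
        warnings.warn(f"{n_undef} site(s) with zero non-missing calls; stats undefined")
    return stats


def site_filter(
    gm: GenotypeMatrix,
    max_missing: float = 0.5,
    max_het: float = 0.2,
    combine: str = "or",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove low-quality sites; returns (filtered matrix, removal report).

    A site fails the missing criterion when its missing rate is strictly above
    ``max_missing`` and the heterozygosity criterion when its het-call rate is
    strictly above ``max_het``.  With ``combine="or"`` (default) failing either
    criterion removes the site — the standard QC reading for mostly-inbred
    material; ``combine="and"`` requires both.
    """
    if combine not in ("or", "and"):
        raise ValueError("combine must be 'or' or 'and'")
    stats = compute_site_stats(gm)
    fail_miss = stats["missing_rate"].to_numpy() > max_missing
    fail_het = stats["het_rate"].to_numpy() > max_het
    removed = (fail_miss | fail_het) if combine == "or" else (fail_miss & fail_het)

    reasons = np.select(
        [fail_miss & fail_het, fail_miss, fail_het],
        ["missing+het", "missing", "het"],
        default="",
    )
    report = pd.DataFrame(
        {
            "marker_id": gm.site_meta.loc[removed, "marker_id"].to_numpy(),
            "reason": reasons[removed],
        }
    )
    if removed.all():
        raise ValueError(
            "site_filter removed every site; review thresholds "
            f"(max_missing={max_missing}, max_het={max_het})"
        )
    return gm.subset_sites(~removed), report


# ---------------------------------------------------------------------------
# LOESS-style MAF chromosome scan

def _loess(x, y, x_grid, span):
    """Local-linear tri-cube-weighted regression with pointwise SEs.

    At each grid point the k = ceil(span * n) nearest data points get tri-cube
    weights on scaled distance; the fit is the intercept of a weighted linear
    regression.  The fit is a linear smoother fit(x0) = l(x0)' y, so its
    pointwise variance is sigma^2 * ||l(x0)||^2 with sigma^2 estimated from the
    residuals at the data points (denominator n - trace of the smoother).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = max(2, int(np.ceil(span * n)))

    def weight_vec(x0):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = np.max(d) if np.max(d) > 0 else 1.0
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        return w

    def smoother_row(x0):
        w = weight_vec(x0)
        X = np.column_stack([np.ones(n), x - x0])
        XtW = X.T * w
        A = XtW @ X
        A[np.diag_indices_from(A)] += 1e-12  # guard near-singular windows
        # fit(x0) = e1' (X'WX)^-1 X'W y
        l = np.linalg.solve(A, XtW)[0]
        return l

    # residual variance from in-sample fits
    fits_data = np.empty(n)
    trace_l = 0.0
    for i, xi in enumerate(x):
        l = smoother_row(xi)
        fits_data[i] = l @ y
        trace_l += l[i]
    dof = max(n - trace_l, 1.0)
    sigma2 = float(np.sum((y - fits_data) ** 2) / dof)

    fit = np.empty(len(x_grid))
    se = np.empty(len(x_grid))
    for j, x0 in enumerate(x_grid):
        l = smoother_row(x0)
        fit[j] = l @ y
        se[j] = np.sqrt(sigma2 * np.sum(l**2))
    return fit, se


def maf_profile(
    gm: GenotypeMatrix,
    span: float = 0.3,
    grid_points: int = 200,
    min_sites: int = 10,
    accession_mask=None,
) -> MafProfile:
    """Smoothed MAF-vs-position profile per chromosome.

    Computes per-site MAF (optionally on an accession subset, e.g. one breeding
    station) and fits a locally weighted regression of MAF on position for
    every chromosome with at least ``min_sites`` sites, evaluated on an even
    ``grid_points`` grid with a pointwise 95% interval.  Fitted values are
    clipped to the attainable MAF range [0, 0.5].  Chromosomes below
    ``min_sites`` contribute raw points only.
    """
    sub = gm if accession_mask is None else gm.subset_accessions(accession_mask)
    stats = compute_site_stats(sub)
    pts = pd.DataFrame(
        {
            "chrom": gm.site_meta["chrom"].to_numpy(),
            "pos_mb": gm.site_meta["pos_bp"].to_numpy() / 1e6,
            "maf": stats["maf"].to_numpy(),
        }
    ).dropna(subset=["maf"])

    curves = {}
    for chrom, grp in pts.groupby("chrom", sort=False):
        if len(grp) < min_sites:
            logger.warning("chromosome %s: %d sites < %d, no curve fitted", chrom, len(grp), min_sites)
            continue
        grp = grp.sort_values("pos_mb")
        grid = np.linspace(grp["pos_mb"].min(), grp["pos_mb"].max(), grid_points)
        fit, se = _loess(grp["pos_mb"].to_numpy(), grp["maf"].to_numpy(), grid, span)
        curves[chrom] = pd.DataFrame(
            {"pos_mb": grid, "fit": np.clip(fit, 0.0, 0.5), "ci_half": 1.96 * se}
        )
    return MafProfile(points=pts.reset_index(drop=True), curves=curves)
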