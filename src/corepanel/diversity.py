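"""Population structure and linkage-disequilibrium decay.

Structure is summarized by principal component analysis of the accession x
dosage matrix using the covariance matrix (sites centered, not variance
scaled), the convention that weights common variants by their variance.  LD is
measured as the squared Pearson correlation of genotype dosages between
intra-chromosomal site pairs — for essentially inbred material this coincides
with the haplotype r² — and summarized over eight fixed physical-distance
classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .genotype import GenotypeMatrix

logger = logging.getLogger(__name__)

#: distance-class boundaries in Mb; classes are half-open [low, high)
LD_CLASS_EDGES_MB = (0.0, 1.0, 5.0, 10.0, 50.0, 100.0, 200.0, 400.0, np.inf)


@dataclass
class PCAResult:
    """Accession scores and percent variance explained per component."""

    scores: np.ndarray
    explained_pct: np.ndarray

    @property
    def labels(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.scores.shape[1])]

    def to_frame(self, accession_ids=None) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.labels)
        if accession_ids is not None:
            df.insert(0, "accession_id", np.asarray(accession_ids))
        return df


class CovariancePCA(TransformerMixin, BaseEstimator):
    """PCA of a dosage matrix on the covariance (not correlation) matrix.

    Missing dosages are mean-imputed per site, sites are centered but not
    variance-scaled, and the decomposition is of the resulting covariance.
    ``explained_pct_`` holds the percentage of total variance per retained
    component; over a full decomposition it sums to 100.

    Parameters
    ----------
    n_components : int or None
        Components to retain; None keeps the full decomposition.  A request
        beyond the matrix rank is truncated with a warning.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = self._impute(np.asarray(X, dtype=float), fit=True)
        n, m = X.shape
        if n < 2 or m < 2:
            raise ValueError("need at least 2 accessions and 2 sites for PCA")
        k = self.n_components
        max_k = min(n, m)
        if k is not None and k > max_k:
            warnings.warn(f"n_components={k} exceeds max rank {max_k}; truncated")
            k = max_k
        self._pca = PCA(n_components=k, svd_solver="full")
        self._pca.fit(X)
        self.components_ = self._pca.components_
        self.mean_ = self._pca.mean_
        self.explained_pct_ = 100.0 * self._pca.explained_variance_ratio_
        self.n_features_in_ = m
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = self._impute(np.asarray(X, dtype=float), fit=False)
        return self._pca.transform(X)

    def _impute(self, X, fit):
        if fit:
            col_means = np.nanmean(np.where(np.isnan(X).all(axis=0), 0.0, X), axis=0)
            col_means = np.where(np.isnan(col_means), 0.0, col_means)
            self.impute_means_ = col_means
        idx = np.where(np.isnan(X))
        if len(idx[0]):
            X = X.copy()
            X[idx] = self.impute_means_[idx[1]]
        return X


def pca_covariance(gm: GenotypeMatrix, k: int = 3) -> PCAResult:
    """Covariance-matrix PCA of a genotype matrix; top-``k`` scores.

    ``explained_pct`` is reported against the total variance (trace of the
    covariance), so the percentages match a full decomposition.
    """
    full = CovariancePCA(n_components=None).fit(gm.dosages)
    scores = full.transform(gm.dosages)[:, :k]
    return PCAResult(scores=scores, explained_pct=full.explained_pct_[:k])


# ---------------------------------------------------------------------------
# LD

def _pair_r2(a: np.ndarray, b: np.ndarray, min_obs: int) -> float:
    """Squared Pearson correlation over pairwise-complete observations."""
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < min_obs:
        return np.nan
    x, y = a[ok], b[ok]
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return np.nan
    c = np.corrcoef(x, y)[0, 1]
    return float(c * c)


def ld_pairwise(
    gm: GenotypeMatrix,
    max_pairs_per_chrom: int | None = None,
    seed: int | None = None,
    min_obs: int = 20,
) -> pd.DataFrame:
    """r² for intra-chromosomal site pairs.

    Returns a frame with columns ``site_a, site_b, chrom, distance_bp, r2``.
    Pairs with fewer than ``min_obs`` complete observations or a monomorphic
    member are skipped (logged).  When a chromosome has more than
    ``max_pairs_per_chrom`` pairs, a seeded uniform subsample is taken.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_skipped = 0
    meta = gm.site_meta
    for chrom in meta["chrom"].unique():
        idx = np.flatnonzero((meta["chrom"] == chrom).to_numpy())
        m = len(idx)
        if m < 2:
            continue
        iu, ju = np.triu_indices(m, k=1)
        n_pairs = len(iu)
        if max_pairs_per_chrom is not None and n_pairs > max_pairs_per_chrom:
            take = rng.choice(n_pairs, size=max_pairs_per_chrom, replace=False)
            take.sort()
            iu, ju = iu[take], ju[take]
        pos = meta["pos_bp"].to_numpy()[idx]
        ids = meta["marker_id"].to_numpy()[idx]
        block = gm.dosages[:, idx]
        has_nan = np.isnan(block).any()
        if not has_nan:
            # fast path: one correlation matrix per chromosome
            with np.errstate(invalid="ignore"):
                cc = np.corrcoef(block.T)
            r2_all = cc[iu, ju] ** 2
        for a, b, k in zip(iu, ju, range(len(iu))):
            r2 = r2_all[k] if not has_nan else _pair_r2(block[:, a], block[:, b], min_obs)
            if not has_nan and block.shape[0] < min_obs:
                r2 = np.nan
            if np.isnan(r2):
                n_skipped += 1
                continue
            rows.append((ids[a], ids[b], chrom, int(abs(pos[b] - pos[a])), r2))
    if n_skipped:
        logger.info("ld_pairwise skipped %d pair(s) (few observations or monomorphic)", n_skipped)
    return pd.DataFrame(rows, columns=["site_a", "site_b", "chrom", "distance_bp", "r2"])


def bin_distance_classes(records: pd.DataFrame) -> pd.DataFrame:
    """Attach the 8-level physical-distance class to LD records.

    Classes are half-open in bp: 1 = [0, 1 Mb), 2 = [1, 5), 3 = [5, 10),
    4 = [10, 50), 5 = [50, 100), 6 = [100, 200), 7 = [200, 400),
    8 = [400 Mb, inf).
    """
    if (records["distance_bp"] <= 0).any():
        raise ValueError("distances must be positive")
    edges_bp = np.array(LD_CLASS_EDGES_MB[1:-1]) * 1e6
    out = records.copy()
    out["distance_class"] = np.digitize(out["distance_bp"].to_numpy(), edges_bp) + 1
    return out


def class_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per distance class: pair count, median r², and quartiles."""
    if "distance_class" not in records.columns:
        records = bin_distance_classes(records)
    g = records.groupby("distance_class")["r2"]
    return pd.DataFrame(
        {
            "n": g.size(),
            "median_r2": g.median(),
            "q1_r2": g.quantile(0.25),
            "q3_r2": g.quantile(0.75),
        }
    ).reset_index()


def ld_threshold_percentile(records: pd.DataFrame, threshold: float = 0.1) -> float:
    """Empirical percentile rank of an r² threshold in the LD distribution.

    Returns 100 x fraction of pairs with r² <= ``threshold``.  A threshold
    sitting at a high percentile (e.g. the 90th) marks r² values above it as
    unusually strong associations.
    """
    if len(records) < 100:
        warnings.warn(f"only {len(records)} LD records; percentile estimate is unstable")
    r2 = records["r2"].to_numpy()
    return 100.0 * float(np.mean(r2 <= threshold))


def _compact_letter_display(levels, significant_pairs) -> dict:
    """Insert-and-absorb compact letter display.

    Levels sharing a letter do not differ significantly; levels sharing no
    letter differ.
    """
    columns = [set(levels)]
    for a, b in significant_pairs:
        for col in list(columns):
            if a in col and b in col:
                columns.remove(col)
                ca, cb = col - {b}, col - {a}
                for c in (ca, cb):
                    if not any(c <= other for other in columns):
                        columns.append(c)
    # absorb duplicates/subsets
    columns = [c for c in columns if not any(c < other for other in columns)]
    columns.sort(key=lambda c: sorted(c)[0] if c else "")
    letters = {lv: "" for lv in levels}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for lv in sorted(col):
            letters[lv] += letter
    return letters


def compare_distance_classes(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD comparison of r² across distance classes.

    One-way ANOVA across classes followed by Tukey honest-significant-
    difference pairwise tests at ``alpha``; returns one row per class with its
    compact-letter-display group (classes sharing no letter differ
    significantly).  Classes with fewer than two records are excluded.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if "distance_class" not in records.columns:
        records = bin_distance_classes(records)
    counts = records["distance_class"].value_counts()
    keep = counts[counts >= 2].index
    sub = records[records["distance_class"].isin(keep)]
    levels = sorted(sub["distance_class"].unique())
    if len(levels) < 2:
        raise ValueError("need at least two distance classes with >= 2 records")

    res = pairwise_tukeyhsd(sub["r2"].to_numpy(), sub["distance_class"].to_numpy(), alpha=alpha)
    tbl = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    sig_pairs = [
        (row["group1"], row["group2"]) for _, row in tbl.iterrows() if row["reject"]
    ]
    letters = _compact_letter_display(levels, sig_pairs)
    med = sub.groupby("distance_class")["r2"].median()
    return pd.DataFrame(
        {
            "distance_class": levels,
            "n": [int(counts[lv]) for lv in levels],
            "median_r2": [med[lv] for lv in levels],
            "letters": [letters[lv] for lv in levels],
        }
    )
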