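"""Genomic prediction: group scaling, RR-BLUP with spectral REML, validation.

The model is the standard ridge-regression BLUP (equivalently GBLUP):

    y = 1 mu + Z u + e,   u ~ N(0, I sigma_u^2),   e ~ N(0, I sigma_e^2)

with Z the column-centered dosage matrix.  The variance ratio
lambda = sigma_e^2 / sigma_u^2 is estimated by restricted maximum likelihood
profiled on the eigendecomposition of Z Z' (a single one-dimensional search
over log-lambda), after which the marker effects have the closed form
u = Z' (Z Z' + lambda I)^-1 (y - mu) — numerically identical to the primal
ridge solution (Z'Z + lambda I)^-1 Z' (y - mu).

Phenotypes from multiple breeding stations and harvest years are made
comparable beforehand by z-scaling within each (station, year) group, which
removes location/scale differences due to growth conditions, evaluation
procedures and equipment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .genotype import GenotypeMatrix

logger = logging.getLogger(__name__)

PHENO_COLUMNS = ["accession_id", "station", "year", "trait", "value"]


def scale_by_group(pheno: pd.DataFrame) -> pd.DataFrame:
    """Z-scale trait values within each (station, year) group.

    Long-format input with columns ``accession_id, station, year, trait,
    value``.  Within every (station, year, trait) group the values are
    centered by the group mean and divided by the group sample standard
    deviation (n-1 denominator).  Groups with fewer than two records or zero
    spread are passed through centered-only with a warning.
    """
    missing = [c for c in PHENO_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")
    if pheno["station"].isna().any() or pheno["year"].isna().any():
        raise ValueError("station and year must be non-null for group scaling")

    out = pheno.copy()
    degenerate = []
    for key, grp in pheno.groupby(["station", "year", "trait"]):
        v = grp["value"].to_numpy(dtype=float)
        mean = v.mean()
        sd = v.std(ddof=1) if len(v) > 1 else 0.0
        if len(v) < 2 or sd == 0 or not np.isfinite(sd):
            degenerate.append(key)
            out.loc[grp.index, "value"] = v - mean
        else:
            out.loc[grp.index, "value"] = (v - mean) / sd
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} (station, year, trait) group(s) degenerate; centered only: "
            f"{degenerate[:5]}"
        )
    out.attrs["scaled"] = True
    return out


def _reml_lambda(K: np.ndarray, y: np.ndarray, log10_bounds, grid_points):
    """Profile REML for lambda = sigma_e^2 / sigma_u^2 with intercept-only X.

    Projects out the intercept, eigendecomposes the projected kinship, and
    maximizes the restricted log-likelihood over log10(lambda) on a grid
    followed by bounded Brent refinement.  Returns (lambda, sigma_u^2,
    sigma_e^2).
    """
    n = len(y)
    J = np.full((n, n), 1.0 / n)
    S = np.eye(n) - J
    A = S @ K @ S
    A = (A + A.T) / 2
    xi, U = np.linalg.eigh(A)
    # Drop one zero-eigenvalue slot for the projected-out intercept.  The
    # null space of A may have higher multiplicity (rank-deficient genotypes);
    # its eigenbasis is arbitrary and can mix in the intercept direction, so
    # eta must come from the centered phenotype, which is orthogonal to it.
    order = np.argsort(xi)[::-1]
    xi = np.clip(xi[order][: n - 1], 0.0, None)
    U = U[:, order][:, : n - 1]
    eta2 = (U.T @ (y - y.mean())) ** 2
    df = n - 1

    def neg_restricted_ll(log10_lam):
        lam = 10.0**log10_lam
        denom = xi + lam
        s = np.sum(eta2 / denom)
        if s <= 0 or not np.isfinite(s):
            return np.inf
        ll = 0.5 * (df * (np.log(df / (2 * np.pi)) - 1 - np.log(s)) - np.sum(np.log(denom)))
        return -ll

    grid = np.linspace(log10_bounds[0], log10_bounds[1], grid_points)
    vals = np.array([neg_restricted_ll(g) for g in grid])
    if not np.isfinite(vals).any():
        raise FloatingPointError("REML surface is non-finite over the search interval")
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(lo, hi), method="bounded")
    lam = 10.0**res.x
    sigma_u2 = float(np.sum(eta2 / (xi + lam)) / df)
    sigma_e2 = lam * sigma_u2
    return float(lam), sigma_u2, sigma_e2


class RRBLUP(RegressorMixin, BaseEstimator):
    """Ridge-regression BLUP genomic prediction model.

    Fit takes an accessions x markers dosage matrix ``X`` (NaN allowed;
    imputed with training column means) and a phenotype vector ``y``.  With
    ``ridge_lambda=None`` the variance ratio is estimated by spectral REML;
    a fixed ``ridge_lambda`` skips REML and solves the plain ridge system.

    Parameters
    ----------
    ridge_lambda : float or None
        Fixed sigma_e^2 / sigma_u^2; None (default) estimates it by REML.
    log10_lambda_bounds : tuple
        REML search interval on log10(lambda); the default (-5, 5) covers
        heritabilities from ~0.001 to ~0.999 for standardized phenotypes.
    grid_points : int
        Coarse grid size before Brent refinement.

    Attributes
    ----------
    mu_ : float
        Generalized-least-squares intercept.
    marker_effects_ : ndarray, shape (n_markers,)
        BLUP marker effects u.
    sigma2_u_, sigma2_e_, lambda_ : float
        Variance components and their ratio.
    h2_ : float
        Genomic heritability sigma_u^2 c / (sigma_u^2 c + sigma_e^2) with
        c the mean diagonal of Z Z'.
    col_means_ : ndarray
        Training column means used for centering and imputation.
    """

    def __init__(
        self,
        ridge_lambda: float | None = None,
        log10_lambda_bounds: tuple = (-5.0, 5.0),
        grid_points: int = 101,
    ):
        self.ridge_lambda = ridge_lambda
        self.log10_lambda_bounds = log10_lambda_bounds
        self.grid_points = grid_points

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, m = X.shape
        if n != len(y):
            raise ValueError("X and y have inconsistent numbers of accessions")
        if n < 10:
            warnings.warn(f"only {n} training accessions; estimates will be unstable")

        col_means = np.nanmean(np.where(np.isnan(X).all(axis=0), 0.0, X), axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        self.col_means_ = col_means
        Z = self._center(X)

        self.n_features_in_ = m
        self.constant_y_ = bool(np.all(y == y[0])) if n else True
        if self.constant_y_:
            logger.warning("phenotype has zero variance; returning a constant model")
            self.mu_ = float(y[0]) if n else 0.0
            self.marker_effects_ = np.zeros(m)
            self.sigma2_u_ = 0.0
            self.sigma2_e_ = 0.0
            self.lambda_ = np.inf
            self.h2_ = 0.0
            return self

        K = Z @ Z.T
        if self.ridge_lambda is None:
            lam, s_u, s_e = _reml_lambda(K, y, self.log10_lambda_bounds, self.grid_points)
        else:
            lam = float(self.ridge_lambda)
            if lam <= 0:
                raise ValueError("ridge_lambda must be positive")
            s_u, s_e = np.nan, np.nan
        H = K + lam * np.eye(n)
        ones = np.ones(n)
        Hi_y = np.linalg.solve(H, y)
        Hi_1 = np.linalg.solve(H, ones)
        mu = float(ones @ Hi_y) / float(ones @ Hi_1)
        alpha = np.linalg.solve(H, y - mu * ones)
        self.mu_ = mu
        self.marker_effects_ = Z.T @ alpha
        self.lambda_ = lam
        if self.ridge_lambda is None:
            self.sigma2_u_ = s_u
            self.sigma2_e_ = s_e
            c = float(np.mean(np.diag(K)))
            self.h2_ = s_u * c / (s_u * c + s_e) if (s_u * c + s_e) > 0 else 0.0
        else:
            self.sigma2_u_ = np.nan
            self.sigma2_e_ = np.nan
            self.h2_ = np.nan
        return self

    def _center(self, X):
        X = np.asarray(X, dtype=float)
        idx = np.where(np.isnan(X))
        if len(idx[0]):
            X = X.copy()
            X[idx] = self.col_means_[idx[1]]
        return X - self.col_means_

    def predict(self, X):
        check_is_fitted(self, "marker_effects_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"test matrix has {X.shape[1]} markers, model was trained on "
                f"{self.n_features_in_} (sites must match in id and order)"
            )
        return self.mu_ + self._center(X) @ self.marker_effects_


def fit_rrblup(X, y, **kwargs) -> RRBLUP:
    """Functional wrapper: fit an :class:`RRBLUP` model."""
    return RRBLUP(**kwargs).fit(X, y)


# ---------------------------------------------------------------------------
# Validation protocols

@dataclass
class CVResult:
    """Repeated hold-out validation accuracies for one trait."""

    trait: str
    correlations: np.ndarray
    n_reps: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.correlations))

    @property
    def sd(self) -> float:
        return float(np.std(self.correlations, ddof=1))


def _accuracy(pred, obs, method):
    if method == "pearson":
        return float(stats.pearsonr(pred, obs)[0])
    if method == "spearman":
        return float(stats.spearmanr(pred, obs)[0])
    raise ValueError("accuracy must be 'pearson' or 'spearman'")


def cross_validate(
    X,
    y,
    trait: str = "trait",
    k: int = 5,
    reps: int = 100,
    seed: int | None = None,
    scheme: str = "holdout",
    accuracy: str = "pearson",
    model_params: dict | None = None,
) -> CVResult:
    """Repeated k-fold-style validation of prediction accuracy.

    With ``scheme="holdout"`` (default) each repetition holds out one random
    1/k of the accessions, trains on the rest, and records the correlation of
    predicted with observed values on the held-out fraction.  With
    ``scheme="rotating"`` each repetition partitions the accessions into k
    folds, predicts every fold from the other k-1, and records the mean fold
    correlation.  Results are bit-reproducible for a fixed ``seed``.
    Repetitions whose held-out observations are constant are redrawn (logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 5 * k:
        raise ValueError(f"need at least {5 * k} phenotyped accessions for k={k}")
    if scheme not in ("holdout", "rotating"):
        raise ValueError("scheme must be 'holdout' or 'rotating'")
    rng = np.random.default_rng(seed)
    params = model_params or {}
    n_test = n // k

    cors = []
    for _ in range(reps):
        for _attempt in range(20):
            perm = rng.permutation(n)
            if scheme == "holdout":
                test = perm[:n_test]
                if np.var(y[test]) == 0:
                    logger.info("degenerate hold-out (constant observed); redrawn")
                    continue
                train = perm[n_test:]
                model = RRBLUP(**params).fit(X[train], y[train])
                cors.append(_accuracy(model.predict(X[test]), y[test], accuracy))
            else:
                folds = np.array_split(perm, k)
                if any(np.var(y[f]) == 0 for f in folds):
                    continue
                fold_cors = []
                for f in folds:
                    train = np.setdiff1d(perm, f)
                    model = RRBLUP(**params).fit(X[train], y[train])
                    fold_cors.append(_accuracy(model.predict(X[f]), y[f], accuracy))
                cors.append(float(np.mean(fold_cors)))
            break
        else:
            raise RuntimeError("could not draw a non-degenerate validation split")
    return CVResult(trait=trait, correlations=np.array(cors), n_reps=reps)


def cross_year_predict(X, y, years, train_year, test_year, model_params: dict | None = None) -> float:
    """Train on one harvest year's accessions, predict the other's.

    ``years`` is the per-accession harvest year aligned with the rows of
    ``X``/``y``.  Returns the Pearson correlation of predicted and observed
    values in the test year.
    """
    years = np.asarray(years)
    train = years == train_year
    test = years == test_year
    if not train.any():
        raise ValueError(f"no accessions in training year {train_year}")
    if not test.any():
        raise ValueError(f"no accessions in test year {test_year}")
    model = RRBLUP(**(model_params or {})).fit(np.asarray(X)[train], np.asarray(y)[train])
    return _accuracy(model.predict(np.asarray(X)[test]), np.asarray(y)[test], "pearson")


@dataclass
class PredictionReport:
    """Per-trait validation accuracies for a panel of traits.

    ``table`` has one row per trait with columns ``trait, cv_mean, cv_sd,
    n_reps`` and, when cross-year prediction ran, one column per direction
    (e.g. ``2018>2019``) plus ``cross_year_mean``.
    """

    table: pd.DataFrame
    cv_results: dict = field(default_factory=dict)


def predict_report(
    gm: GenotypeMatrix,
    pheno_scaled: pd.DataFrame,
    traits: list[str] | None = None,
    k: int = 5,
    reps: int = 100,
    seed: int | None = None,
    cross_years: tuple | None = None,
    model_params: dict | None = None,
) -> PredictionReport:
    """Run repeated hold-out CV (and optionally cross-year prediction) per trait.

    Phenotypes are matched to genotype rows by ``accession_id``; accessions
    lacking a trait value are excluded for that trait.  ``cross_years`` is an
    ordered pair such as ``(2018, 2019)``: both directions and their mean are
    reported.
    """
    if traits is None:
        traits = sorted(pheno_scaled["trait"].unique())
    acc_index = pd.Index(gm.accession_meta["accession_id"])
    rows, cv_results = [], {}
    for trait in traits:
        sub = pheno_scaled[pheno_scaled["trait"] == trait]
        if len(sub) == 0:
            raise ValueError(f"trait {trait!r} absent from phenotype table")
        sub = sub[sub["accession_id"].isin(acc_index)]
        loc = acc_index.get_indexer(sub["accession_id"])
        Xt = gm.dosages[loc]
        yt = sub["value"].to_numpy(dtype=float)
        cv = cross_validate(
            Xt, yt, trait=trait, k=k, reps=reps, seed=seed, model_params=model_params
        )
        cv_results[trait] = cv
        row = {"trait": trait, "cv_mean": cv.mean, "cv_sd": cv.sd, "n_reps": reps}
        if cross_years is not None:
            y1, y2 = cross_years
            yrs = sub["year"].to_numpy()
            fwd = cross_year_predict(Xt, yt, yrs, y1, y2, model_params)
            rev = cross_year_predict(Xt, yt, yrs, y2, y1, model_params)
            row[f"{y1}>{y2}"] = fwd
            row[f"{y2}>{y1}"] = rev
            row["cross_year_mean"] = (fwd + rev) / 2.0
        rows.append(row)
    return PredictionReport(table=pd.DataFrame(rows), cv_results=cv_results)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a long-format phenotype table (tab-separated)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")
    return df
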