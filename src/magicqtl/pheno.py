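"""Phenotype preparation and trait-level statistics.

Covers the phenotype side of the analysis: derived phenology intervals
(d1 = GS55 - GS39, d2 = GS65 - GS55, d3 = FLS - GS55, all in days),
multiple imputation by chained equations (m completed tables averaged),
replicate averaging, pairwise trait correlations, trait PCA on
unit-variance data, the marker-based relationship (kinship) matrix with
its eigen-spectrum as a population-structure check, and the multiple
linear regression screen for predictors of flag-leaf senescence (FLS).

Replicate averaging happens after imputation; correlations are offered
both pairwise-complete (pre-imputation) and on the completed table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .simulate import MISSING, GenotypeMatrix

__all__ = [
    "derive_intervals",
    "mice_impute",
    "average_replicates",
    "correlation_matrix",
    "trait_pca",
    "kinship_matrix",
    "kinship_pca",
    "mlrm_fls",
    "flag_outliers",
    "KinshipResult",
    "TraitPCAResult",
    "MLRMResult",
]

logger = logging.getLogger(__name__)

ID_COLS = ("line_id", "rep")

#: Derived interval traits and their (minuend, subtrahend) growth stages.
DERIVED_INTERVALS: dict[str, tuple[str, str]] = {
    "d1": ("GS55", "GS39"),
    "d2": ("GS65", "GS55"),
    "d3": ("FLS", "GS55"),
}


def _trait_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLS]


def derive_intervals(table: pd.DataFrame) -> pd.DataFrame:
    """Append the d1/d2/d3 phenology intervals (days between growth stages).

    Missing operands propagate to missing intervals. Negative intervals
    (possible scoring errors) are kept but logged.
    """
    out = table.copy()
    for name, (a, b) in DERIVED_INTERVALS.items():
        if a not in table.columns or b not in table.columns:
            raise ValueError(f"cannot derive {name}: needs columns {a} and {b}")
        vals = table[a] - table[b]
        n_neg = int((vals < 0).sum())
        if n_neg:
            logger.warning("%s: %d negative interval(s) kept, flagged for QC", name, n_neg)
        out[name] = vals
    return out


def flag_outliers(table: pd.DataFrame, n_sd: float = 4.0) -> pd.DataFrame:
    """Report cells more than ``n_sd`` SDs from their trait mean.

    Values are only flagged, never altered: correcting suspicious scores
    is a manual curation step.
    """
    rows = []
    for c in _trait_columns(table):
        v = pd.to_numeric(table[c], errors="coerce")
        mu, sd = v.mean(), v.std()
        if not np.isfinite(sd) or sd == 0:
            continue
        z = (v - mu) / sd
        for i in np.flatnonzero(z.abs().to_numpy() > n_sd):
            rows.append({"row": int(i), "trait": c, "value": float(v.iloc[i]),
                         "z": float(z.iloc[i])})
    return pd.DataFrame(rows, columns=["row", "trait", "value", "z"])


def mice_impute(
    table: pd.DataFrame, m: int = 5, seed: int = 0, max_iter: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chained-equation imputation, m stochastic completions averaged per cell.

    Each incomplete trait column is iteratively regressed on all the
    others with posterior sampling, repeated ``m`` times from distinct
    random states; the completed tables are combined by averaging.
    Observed cells are never altered. Returns (completed table, report of
    imputed cells).
    """
    traits = _trait_columns(table)
    X = table[traits].apply(pd.to_numeric, errors="coerce")
    missing = X.isna()
    if missing.to_numpy().all(axis=0).any():
        bad = [c for c in traits if missing[c].all()]
        raise ValueError(f"column(s) entirely missing, cannot impute: {bad}")
    heavy = [c for c in traits if missing[c].mean() > 0.5]
    if heavy:
        logger.warning("column(s) more than 50%% missing: %s", heavy)

    if not missing.to_numpy().any():
        return table.copy(), pd.DataFrame(columns=["row", "trait", "imputed"])

    stacks = []
    for k in range(m):
        imp = IterativeImputer(
            sample_posterior=True, max_iter=max_iter,
            random_state=(seed + k) % (2 ** 31), keep_empty_features=True,
        )
        stacks.append(imp.fit_transform(X.to_numpy(float)))
    avg = np.mean(stacks, axis=0)

    filled = X.to_numpy(float).copy()
    mask = missing.to_numpy()
    filled[mask] = avg[mask]
    out = table.copy()
    out[traits] = filled

    rr, cc = np.nonzero(mask)
    report = pd.DataFrame({
        "row": rr, "trait": [traits[j] for j in cc], "imputed": filled[rr, cc],
    })
    return out, report


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate rows to one line-level mean per trait."""
    if "line_id" not in table.columns:
        raise ValueError("phenotype table needs a line_id column")
    traits = _trait_columns(table)
    return (
        table.groupby("line_id", sort=False)[traits].mean().reset_index()
    )


def correlation_matrix(table: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between trait columns.

    Pairs with fewer than ``min_pairs`` complete observations, and
    constant columns, come back as NaN.
    """
    traits = _trait_columns(table)
    X = table[traits].apply(pd.to_numeric, errors="coerce")
    R = X.corr(method="pearson", min_periods=min_pairs)
    return R


@dataclass(frozen=True)
class TraitPCAResult:
    scores: pd.DataFrame = field(repr=False)
    loadings: pd.DataFrame = field(repr=False)
    variance_fractions: np.ndarray = field(repr=False)


def trait_pca(table: pd.DataFrame) -> TraitPCAResult:
    """PCA of the line x trait matrix, traits scaled to unit variance.

    Requires a complete table (run imputation first). Returns line scores,
    trait loadings, and per-component variance fractions (which sum to 1).
    """
    traits = _trait_columns(table)
    if len(traits) < 2:
        raise ValueError("trait PCA needs at least 2 traits")
    X = table[traits].apply(pd.to_numeric, errors="coerce")
    if X.isna().to_numpy().any():
        raise ValueError("trait PCA requires a complete table; impute first")
    Z = (X - X.mean()) / X.std(ddof=1).replace(0.0, 1.0)
    pca = PCA()
    scores = pca.fit_transform(Z.to_numpy(float))
    pcs = [f"PC{i + 1}" for i in range(scores.shape[1])]
    idx = table["line_id"] if "line_id" in table.columns else table.index
    return TraitPCAResult(
        scores=pd.DataFrame(scores, columns=pcs, index=idx),
        loadings=pd.DataFrame(pca.components_.T, index=traits, columns=pcs),
        variance_fractions=pca.explained_variance_ratio_,
    )


@dataclass(frozen=True)
class KinshipResult:
    """Marker-based relationship matrix A with its eigen-spectrum."""

    A: pd.DataFrame = field(repr=False)
    eigenvalues: np.ndarray = field(repr=False)
    scores: pd.DataFrame = field(repr=False)

    @property
    def variance_fractions(self) -> np.ndarray:
        w = np.clip(self.eigenvalues, 0.0, None)
        return w / w.sum()

    @property
    def pc1_fraction(self) -> float:
        return float(self.variance_fractions[0])


def kinship_matrix(genotypes: GenotypeMatrix | pd.DataFrame) -> pd.DataFrame:
    """Genomic relationship matrix from frequency-centered marker dosages.

    VanRaden scaling: A = W W' / (2 sum p(1-p)) with W the 0/1/2 dosage
    matrix centered by twice the allele frequency. Missing calls are
    replaced by the marker mean dosage (they contribute no deviation).
    Monomorphic markers carry no information and are dropped; an all-
    monomorphic input is an error.
    """
    if isinstance(genotypes, GenotypeMatrix):
        G = genotypes.matrix.astype(float)
        G[G == MISSING] = np.nan
        ids = list(genotypes.line_ids)
    else:
        G = genotypes.to_numpy(float)
        ids = list(genotypes.index)
    p = np.nanmean(G, axis=0) / 2.0
    poly = (p > 0) & (p < 1) & (np.nanvar(G, axis=0) > 0)
    if not poly.any():
        raise ValueError("no polymorphic markers: kinship undefined")
    G = G[:, poly]
    p = p[poly]
    W = np.where(np.isnan(G), 0.0, G - 2.0 * p)
    denom = 2.0 * np.sum(p * (1.0 - p))
    A = W @ W.T / denom
    return pd.DataFrame(A, index=ids, columns=ids)


def kinship_pca(genotypes: GenotypeMatrix | pd.DataFrame) -> KinshipResult:
    """Eigen-decomposition of the kinship matrix as a structure check.

    The leading eigenvalue's share of the (non-negative) spectrum is the
    reported structure statistic: an unstructured multi-parent population
    shows no dominant component.
    """
    A = kinship_matrix(genotypes)
    w, V = np.linalg.eigh(A.to_numpy())
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pcs = [f"PC{i + 1}" for i in range(len(w))]
    scores = pd.DataFrame(
        V * np.sqrt(np.clip(w, 0.0, None)), index=A.index, columns=pcs
    )
    return KinshipResult(A=A, eigenvalues=w, scores=scores)


@dataclass(frozen=True)
class MLRMResult:
    """Multiple-linear-regression screen of FLS predictors."""

    summary: pd.DataFrame = field(repr=False)
    significant: tuple[str, ...] = ()
    dropped: tuple[str, ...] = ()

    def coefficient(self, trait: str) -> float:
        return float(self.summary.loc[trait, "coef"])


def mlrm_fls(
    table: pd.DataFrame,
    response: str = "FLS",
    exclude_derived: bool = False,
    alpha: float = 0.05,
) -> MLRMResult:
    """OLS of FLS on all other traits; flag predictors with p < alpha.

    By default the derived interval d3 = FLS - GS55 stays in the predictor
    set (it is the screen's headline predictor) even though it contains
    the response arithmetically; a circularity warning is logged, and
    ``exclude_derived=True`` gives the stricter model without d1/d2/d3.
    Perfectly collinear predictors are dropped with a warning.
    """
    traits = _trait_columns(table)
    if response not in traits:
        raise ValueError(f"response {response!r} not in the table")
    predictors = [t for t in traits if t != response]
    if exclude_derived:
        predictors = [t for t in predictors if t not in DERIVED_INTERVALS]
    elif "d3" in predictors:
        logger.warning(
            "predictor d3 is an arithmetic function of %s (d3 = FLS - GS55): "
            "its coefficient reflects circularity, not biology", response,
        )

    X = table[predictors].apply(pd.to_numeric, errors="coerce")
    y = pd.to_numeric(table[response], errors="coerce")
    keep = y.notna() & X.notna().all(axis=1)
    X, y = X[keep], y[keep]
    if len(y) <= len(predictors) + 1:
        raise ValueError(
            f"unidentifiable model: {len(y)} rows for {len(predictors)} predictors; "
            "reduce the predictor set or regularize"
        )

    # drop perfectly collinear predictors (constant columns included)
    dropped: list[str] = []
    kept: list[str] = []
    basis = np.ones((len(y), 1))
    for t in predictors:
        cand = np.hstack([basis, X[t].to_numpy(float)[:, None]])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(basis):
            kept.append(t)
            basis = cand
        else:
            dropped.append(t)
            logger.warning("dropping perfectly collinear predictor %s", t)

    design = sm.add_constant(X[kept])
    fit = sm.OLS(y, design).fit()
    summary = pd.DataFrame({
        "coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues,
    }).drop(index="const")
    significant = tuple(summary.index[summary["p"] < alpha])
    return MLRMResult(summary=summary, significant=significant, dropped=tuple(dropped))
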