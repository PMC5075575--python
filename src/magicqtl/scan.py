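"""Haplotype-regression genome scans.

Second stage of the haplotype-based QTL analysis: at every mapped locus
the phenotype is regressed on the expected founder dosages from the
forward-backward posteriors, and the locus is tested with a nested-model
ANOVA F-test against the covariate-only null.

With haploid dosage coding the design rows sum to one, so the intercept is
absorbed by the dosage columns and the fitted coefficients read directly
as per-founder trait-mean predictions (the scale on which founder effects
are conventionally reported). The full interaction model adds one column
per unordered founder pair, S(S-1)/2 + S in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .hmm import FounderProbabilities

__all__ = [
    "LocusFit",
    "ScanResult",
    "additive_design",
    "full_design",
    "fit_locus",
    "genome_scan",
    "HaplotypeScan",
]

_LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def additive_design(F_locus: np.ndarray) -> np.ndarray:
    """Expected founder dosages at one locus (haploid coding).

    ``F_locus`` is the (n_lines, S) posterior slice; rows already sum to
    one and are returned as-is after validation.
    """
    X = np.asarray(F_locus, dtype=float)
    if X.ndim != 2:
        raise ValueError("founder-probability slice must be 2-D (lines x founders)")
    if np.any(X < -1e-9) or np.any(np.abs(X.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("rows must be founder probability vectors summing to 1")
    return X


def full_design(F_pairs: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Unordered founder-pair expectation design at one locus.

    ``F_pairs`` is the (n_lines, S, S) symmetric diplotype posterior.
    Returns the (n_lines, S(S-1)/2 + S) design and the (s, t) pair labels,
    diagonal pairs first.
    """
    P = np.asarray(F_pairs, dtype=float)
    if P.ndim != 3 or P.shape[1] != P.shape[2]:
        raise ValueError(
            "full model needs diplotype probabilities (n, S, S); "
            "rerun inference with inbred_mode=False"
        )
    s = P.shape[1]
    pairs = [(i, i) for i in range(s)] + [
        (i, j) for i in range(s) for j in range(i + 1, s)
    ]
    cols = [P[:, i, j] if i == j else P[:, i, j] + P[:, j, i] for i, j in pairs]
    return np.column_stack(cols), pairs


# ---------------------------------------------------------------------------
# single-locus fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusFit:
    """ANOVA result at one locus.

    ``effects`` are founder trait-mean predictions (trait units);
    ``var_explained`` is the incremental variance fraction of the locus
    term (omega-squared with the dosage-information disattenuation,
    clipped to [0, 1]); ``r2`` is the plain incremental R-squared.
    """

    effects: np.ndarray
    f_stat: float
    df1: int
    df2: int
    neg_log10_p: float
    var_explained: float
    r2: float


def _orth_basis(A: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthonormal column basis and numerical rank via SVD."""
    if A.size == 0:
        return np.zeros((A.shape[0], 0)), 0
    U, sv, _ = np.linalg.svd(A, full_matrices=False)
    tol = sv.max(initial=0.0) * max(A.shape) * np.finfo(float).eps
    r = int((sv > tol).sum())
    return U[:, :r], r


def _dosage_information(X: np.ndarray) -> float:
    """Mean squared norm of the dosage rows: the locus information score.

    Regressing on posterior expected dosages instead of the (unobserved)
    true founder states attenuates the locus variance share by roughly
    the posterior certainty; dividing by this score disattenuates it, the
    same device as imputation-INFO corrections in dosage-based
    association. Equals 1 for fully certain inbred assignments, so exact
    designs are untouched.
    """
    info = float((X * X).sum(axis=1).mean())
    return max(min(info, 1.0), 1e-3)


def _f_test(rss0: float, rss1: float, df1: int, df2: int) -> tuple[float, float]:
    """F statistic and -log10 p for a nested-model comparison."""
    if df1 <= 0 or df2 <= 0 or rss1 <= 0:
        return 0.0, 0.0
    f = max(rss0 - rss1, 0.0) / df1 / (rss1 / df2)
    if f <= 0:
        return 0.0, 0.0
    neglogp = -stats.f.logsf(f, df1, df2) / _LN10
    return float(f), float(max(neglogp, 0.0))


def fit_locus(
    y: np.ndarray,
    X: np.ndarray,
    covariates: np.ndarray | None = None,
) -> LocusFit:
    """Least-squares fit and ANOVA of one locus term.

    Lines with missing phenotype are dropped casewise. The null model is
    intercept plus covariates; the alternative adds the locus design. Rank
    deficiency (collinear columns) is handled by pseudo-inverse effects
    and rank-adjusted degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n_all = len(y)
    if X.shape[0] != n_all:
        raise ValueError("y and design have different numbers of lines")
    keep = np.isfinite(y)
    y, X = y[keep], X[keep]
    C = None if covariates is None else np.asarray(covariates, float)[keep]
    n = len(y)

    ones = np.ones((n, 1))
    null_cols = ones if C is None else np.hstack([ones, C])
    Q0, r0 = _orth_basis(null_cols)
    full_cols = np.hstack([null_cols, X])
    Q1, r1 = _orth_basis(full_cols)

    yty = float(y @ y)
    rss0 = yty - float((Q0.T @ y) @ (Q0.T @ y))
    rss1 = yty - float((Q1.T @ y) @ (Q1.T @ y))
    df1 = r1 - r0
    df2 = n - r1
    tss = float(((y - y.mean()) ** 2).sum())

    if tss <= 1e-12 * max(1.0, yty):           # constant phenotype
        f, neglogp, omega, r2 = 0.0, 0.0, 0.0, 0.0
    else:
        f, neglogp = _f_test(rss0, rss1, df1, df2)
        ss_locus = max(rss0 - rss1, 0.0)
        mse = rss1 / df2 if df2 > 0 else 0.0
        info = _dosage_information(X)
        omega = float(np.clip((ss_locus - df1 * mse) / (tss + mse) / info, 0.0, 1.0))
        r2 = float(np.clip(ss_locus / tss, 0.0, 1.0))

    # founder-mean effects: coefficients on the dosage columns, with
    # centered covariates so predictions are at the covariate mean
    reg = X if C is None else np.hstack([X, C - C.mean(axis=0)])
    beta = np.linalg.pinv(reg) @ y
    effects = beta[: X.shape[1]]
    return LocusFit(effects, f, int(df1), int(df2), neglogp, omega, r2)


# ---------------------------------------------------------------------------
# whole-genome scan
# ---------------------------------------------------------------------------

class ScanEngine:
    """Precomputed per-locus orthonormal bases for fast repeated scans.

    Built once per (founder probabilities, covariates, line subset); every
    phenotype vector (observed or permuted) then scans in a single matrix
    product, which is what makes 200+ permutation scans affordable.
    """

    def __init__(
        self,
        F: FounderProbabilities,
        covariates: np.ndarray | None = None,
        keep: np.ndarray | None = None,
        model: str = "additive",
    ):
        if model not in ("additive", "full"):
            raise ValueError("model must be 'additive' or 'full'")
        n_total = F.n_lines
        keep = np.ones(n_total, bool) if keep is None else keep
        self.keep = keep
        n = int(keep.sum())
        self.n = n
        m = F.gmap.n_markers
        C = None if covariates is None else np.asarray(covariates, float)[keep]

        ones = np.ones((n, 1))
        null_cols = ones if C is None else np.hstack([ones, C])
        self.Q0, self.r0 = _orth_basis(null_cols)

        designs = []
        for L in range(m):
            if model == "additive":
                XL = F.probs[keep, L, :]
            else:
                XL, _ = full_design(F.diplotype[keep, L, :, :])
            designs.append(XL)
        self.designs = designs

        rmax = max(self.r0 + d.shape[1] for d in designs)
        Q = np.zeros((m, n, rmax))
        df1 = np.zeros(m, dtype=int)
        df2 = np.zeros(m, dtype=int)
        for L, XL in enumerate(designs):
            QL, rL = _orth_basis(np.hstack([null_cols, XL]))
            Q[L, :, :rL] = QL
            df1[L] = rL - self.r0
            df2[L] = n - rL
        self.Q = Q
        self.df1 = df1
        self.df2 = df2
        self.C = C

    def scan_stats(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(f_stats, neg_log10_p) across loci for one complete phenotype."""
        y = np.asarray(y, dtype=float)
        yty = float(y @ y)
        rss0 = yty - float((self.Q0.T @ y) @ (self.Q0.T @ y))
        proj = np.einsum("lnr,n->lr", self.Q, y)
        rss1 = np.maximum(yty - (proj ** 2).sum(axis=1), 0.0)
        df1 = np.maximum(self.df1, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((rss0 - rss1) / df1) / (rss1 / self.df2)
        f = np.where((self.df1 > 0) & (self.df2 > 0) & (rss1 > 0), f, 0.0)
        f = np.maximum(np.nan_to_num(f, nan=0.0, posinf=0.0), 0.0)
        if rss0 <= 1e-12 * max(1.0, yty):
            f = np.zeros_like(f)
        ok = (f > 0) & (self.df1 > 0) & (self.df2 > 0)
        neglogp = np.zeros_like(f)
        if ok.any():
            neglogp[ok] = -stats.f.logsf(f[ok], df1[ok], self.df2[ok]) / _LN10
        return f, np.maximum(neglogp, 0.0)

    def max_neglogp(self, y: np.ndarray) -> float:
        """Genome-wide maximum scan statistic for one phenotype vector."""
        _, neglogp = self.scan_stats(y)
        return float(neglogp.max())

    def batch_max_neglogp(self, Y: np.ndarray) -> np.ndarray:
        """Genome-wide maxima for many phenotype columns at once.

        ``Y`` is (n_lines, B); returns (B,). One tensor contraction and
        one vectorized F-tail evaluation serve all columns, which is what
        keeps 1000-permutation nulls cheap.
        """
        Y = np.asarray(Y, dtype=float)
        yty = (Y * Y).sum(axis=0)                               # (B,)
        rss0 = yty - ((self.Q0.T @ Y) ** 2).sum(axis=0)         # (B,)
        T = np.tensordot(self.Q, Y, axes=(1, 0))                # (m, r, B)
        rss1 = np.maximum(yty[None, :] - (T ** 2).sum(axis=1), 0.0)
        df1 = np.maximum(self.df1, 1)[:, None]
        df2 = self.df2[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((rss0[None, :] - rss1) / df1) / (rss1 / df2)
        valid = (self.df1[:, None] > 0) & (df2 > 0) & (rss1 > 0)
        f = np.where(valid, np.nan_to_num(f, nan=0.0, posinf=0.0), 0.0)
        f = np.maximum(f, 0.0)
        neglogp = np.zeros_like(f)
        ok = f > 0
        if ok.any():
            d1 = np.broadcast_to(df1, f.shape)
            d2 = np.broadcast_to(df2, f.shape)
            neglogp[ok] = -stats.f.logsf(f[ok], d1[ok], d2[ok]) / _LN10
        return np.maximum(neglogp, 0.0).max(axis=0)


@dataclass(frozen=True)
class ScanResult:
    """Per-marker scan results in map order.

    ``table`` columns: marker, chrom, cM, f_stat, df1, df2, neg_log10_p,
    var_explained, r2, and one effect column per founder.
    """

    table: pd.DataFrame = field(repr=False)
    trait: str = ""
    model: str = "additive"
    covariate_markers: tuple[str, ...] = ()

    @property
    def neg_log10_p(self) -> np.ndarray:
        return self.table["neg_log10_p"].to_numpy()

    def top_marker(self, chrom: str | None = None) -> pd.Series:
        t = self.table if chrom is None else self.table[self.table["chrom"] == chrom]
        if t.empty:
            raise KeyError(f"no markers on chromosome {chrom!r}")
        return t.loc[t["neg_log10_p"].idxmax()]

    def top_markers_per_chromosome(self) -> pd.DataFrame:
        idx = self.table.groupby("chrom", sort=False)["neg_log10_p"].idxmax()
        return self.table.loc[idx].reset_index(drop=True)

    def peak_interval(self, chrom: str) -> tuple[str, str]:
        """Flanking markers of the chromosome's peak (the marker interval)."""
        t = self.table[self.table["chrom"] == chrom].reset_index(drop=True)
        k = int(t["neg_log10_p"].idxmax())
        lo = t.iloc[max(k - 1, 0)]["marker"]
        hi = t.iloc[min(k + 1, len(t) - 1)]["marker"]
        return str(lo), str(hi)


def _align_phenotype(y, F: FounderProbabilities) -> np.ndarray:
    if isinstance(y, pd.Series):
        return y.reindex(list(F.line_ids)).to_numpy(float)
    arr = np.asarray(y, dtype=float)
    if arr.shape != (F.n_lines,):
        raise ValueError("phenotype vector does not align with the scanned lines")
    return arr


def genome_scan(
    y,
    F: FounderProbabilities,
    model: str = "additive",
    covariates: np.ndarray | None = None,
    trait: str = "",
    covariate_markers: tuple[str, ...] = (),
    engine: ScanEngine | None = None,
) -> ScanResult:
    """Scan every mapped marker for association with one phenotype.

    ``y`` may be an ndarray aligned with ``F.line_ids`` or a pandas Series
    indexed by line id (one value per line; replicates are averaged
    upstream). Missing phenotypes are dropped casewise.
    """
    yv = _align_phenotype(y, F)
    keep = np.isfinite(yv)
    if engine is None:
        engine = ScanEngine(F, covariates=covariates, keep=keep, model=model)
    yk = yv[keep]
    f, neglogp = engine.scan_stats(yk)

    # effects and variance fractions per locus (reporting pass)
    n_loci = F.gmap.n_markers
    s = F.n_founders
    effects = np.empty((n_loci, s))
    omega = np.empty(n_loci)
    r2 = np.empty(n_loci)
    yc = yk - yk.mean()
    tss = float(yc @ yc)
    proj0 = engine.Q0.T @ yk
    rss0 = float(yk @ yk) - float(proj0 @ proj0)
    for L in range(n_loci):
        XL = F.probs[keep, L, :]
        projL = engine.Q[L].T @ yk
        rss1 = max(float(yk @ yk) - float(projL @ projL), 0.0)
        ss_locus = max(rss0 - rss1, 0.0)
        df2 = engine.df2[L]
        mse = rss1 / df2 if df2 > 0 else 0.0
        if tss <= 1e-12:
            omega[L] = r2[L] = 0.0
        else:
            info = _dosage_information(XL)
            omega[L] = np.clip(
                (ss_locus - engine.df1[L] * mse) / (tss + mse) / info, 0, 1
            )
            r2[L] = np.clip(ss_locus / tss, 0, 1)
        reg = XL if engine.C is None else np.hstack(
            [XL, engine.C - engine.C.mean(axis=0)]
        )
        beta = np.linalg.pinv(reg) @ yk
        effects[L] = beta[:s]

    tab = F.gmap.table.copy()
    tab = tab.rename(columns={"marker": "marker"})
    tab["f_stat"] = f
    tab["df1"] = engine.df1
    tab["df2"] = engine.df2
    tab["neg_log10_p"] = neglogp
    tab["var_explained"] = omega
    tab["r2"] = r2
    for j, name in enumerate(F.founder_names):
        tab[f"effect_{name}"] = effects[:, j]
    return ScanResult(tab, trait=trait, model=model,
                      covariate_markers=tuple(covariate_markers))


class HaplotypeScan(BaseEstimator):
    """Genome scan as a scikit-learn-style estimator.

    ``fit(F, y)`` runs the scan and exposes fitted attributes:
    ``result_`` (the :class:`ScanResult`), ``neg_log10_p_``, ``effects_``
    and ``top_marker_``.
    """

    def __init__(self, model: str = "additive", trait: str = ""):
        self.model = model
        self.trait = trait

    def fit(self, F: FounderProbabilities, y, covariates: np.ndarray | None = None):
        self.result_ = genome_scan(
            y, F, model=self.model, covariates=covariates, trait=self.trait
        )
        self.neg_log10_p_ = self.result_.neg_log10_p
        eff_cols = [c for c in self.result_.table.columns if c.startswith("effect_")]
        self.effects_ = self.result_.table[eff_cols].to_numpy()
        self.top_marker_ = str(self.result_.top_marker()["marker"])
        return self

    def transform(self, F: FounderProbabilities) -> pd.DataFrame:
        if not hasattr(self, "result_"):
            raise RuntimeError("HaplotypeScan is not fitted")
        return self.result_.table
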