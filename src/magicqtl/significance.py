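"""Genome-wide significance: phenotype permutation and Storey q-values.

The permutation null breaks only the line-phenotype linkage (genotypes and
map are untouched): the phenotype vector is shuffled across lines, the
whole-genome scan repeated, and the genome-wide maximum -log10 P recorded.
The empirical distribution of those maxima gives family-wise thresholds
and an add-one empirical p-value for an observed scan maximum.

False-discovery control uses Storey q-values with the smoother estimate of
pi0, and reports the p-value corresponding to q = 0.05 by interpolation
(absent when no q-value falls below 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import FounderProbabilities
from .scan import ScanEngine, ScanResult, _align_phenotype

__all__ = [
    "PermutationNull",
    "FDRResult",
    "permutation_null",
    "empirical_pvalue",
    "qvalues",
    "call_qtls",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationNull:
    """Genome-wide maxima of -log10 P under phenotype permutation."""

    max_scores: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        ms = np.asarray(self.max_scores, dtype=float)
        if ms.ndim != 1 or ms.size == 0:
            raise ValueError("max_scores must be a non-empty vector")
        if np.any(ms < 0):
            raise ValueError("scan maxima cannot be negative")
        object.__setattr__(self, "max_scores", ms)

    @property
    def n_perm(self) -> int:
        return len(self.max_scores)

    def threshold(self, alpha: float = 0.05) -> float:
        """Empirical genome-wide (1 - alpha) threshold on -log10 P.

        Uses the 'higher' order statistic so that a fresh null draw exceeds
        the threshold with probability ~alpha.
        """
        return float(np.quantile(self.max_scores, 1.0 - alpha, method="higher"))


def permutation_null(
    y,
    F: FounderProbabilities,
    n_perm: int = 1000,
    seed: int = 0,
    covariates: np.ndarray | None = None,
    model: str = "additive",
) -> PermutationNull:
    """Permutation distribution of the genome-wide maximum scan statistic.

    The phenotype (with its covariate rows, if any, as a unit) is permuted
    uniformly across lines each iteration and the full scan repeated via
    the cached per-locus bases, so 1000 permutations cost one matrix
    product each.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    yv = _align_phenotype(y, F)
    keep = np.isfinite(yv)
    yk = yv[keep]
    rng = np.random.default_rng(seed)
    engine = ScanEngine(F, covariates=covariates, keep=keep, model=model)
    # Manly-style raw-data permutation: y is shuffled against the fixed
    # genotype (and covariate) bases; exact without covariates, a standard
    # approximation with them
    Y = np.empty((len(yk), n_perm))
    for b in range(n_perm):
        Y[:, b] = yk[rng.permutation(len(yk))]
    maxima = engine.batch_max_neglogp(Y)
    return PermutationNull(maxima, seed=seed)


def empirical_pvalue(observed_max: float, null: PermutationNull) -> float:
    """Add-one empirical tail probability of an observed scan maximum."""
    r = int((null.max_scores >= observed_max).sum())
    return (r + 1) / (null.n_perm + 1)


@dataclass(frozen=True)
class FDRResult:
    """Storey q-values aligned with the input p-values."""

    qvalues: np.ndarray = field(repr=False)
    pi0: float = 1.0
    p_at_q05: float | None = None


def _estimate_pi0(pvals: np.ndarray) -> float:
    """Smoother estimate of the null proportion pi0 (cubic fit over lambda).

    Falls back to the conservative pi0 = 1 when the p-vector is too short
    or the fit is unstable.
    """
    m = len(pvals)
    lam = np.arange(0.05, 0.96, 0.05)
    if m < 100:
        logger.info("short p-vector (%d): using conservative pi0 = 1", m)
        return 1.0
    pi0_lam = np.array([(pvals > la).mean() / (1.0 - la) for la in lam])
    try:
        coef = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.polyval(coef, lam.max()))
    except np.linalg.LinAlgError:
        pi0 = 1.0
    if not np.isfinite(pi0) or pi0 <= 0:
        logger.info("pi0 smoother unstable (%.3f): falling back to 1", pi0)
        pi0 = 1.0
    return min(pi0, 1.0)


def qvalues(pvals: np.ndarray) -> FDRResult:
    """Storey q-values with smoother pi0 and the p at q = 0.05.

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j over the sorted p-values;
    monotone non-decreasing in p by construction. ``p_at_q05`` is linearly
    interpolated on the sorted (q, p) pairs and is None when min(q) > 0.05.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    pi0 = _estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate((pi0 * m * ps / ranks)[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted

    p_at = None
    if q_sorted.min() <= 0.05:
        if q_sorted.max() <= 0.05:
            p_at = float(ps[-1])
        else:
            k = int(np.searchsorted(q_sorted, 0.05, side="right")) - 1
            k = max(k, 0)
            q0, q1 = q_sorted[k], q_sorted[k + 1]
            p0, p1 = ps[k], ps[k + 1]
            if q1 > q0:
                p_at = float(p0 + (0.05 - q0) * (p1 - p0) / (q1 - q0))
            else:
                p_at = float(p0)
    return FDRResult(q, pi0=pi0, p_at_q05=p_at)


def call_qtls(
    scan: ScanResult,
    fdr: FDRResult | None = None,
    threshold_logp: float = 4.0,
    q_threshold: float = 0.05,
    gap: int = 1,
) -> pd.DataFrame:
    """Group super-threshold markers into QTL regions with peak markers.

    A marker qualifies when its -log10 P meets ``threshold_logp`` and (if
    an FDR result is supplied) its q-value is at or below ``q_threshold``.
    Qualifying markers on one chromosome separated by at most ``gap``
    sub-threshold markers merge into a single region, reflecting that a
    run of close peaks typically represents one QTL. Returns one row per
    region: chrom, start/end cM, flanking markers, peak marker and its
    statistics, ordered by chromosome then position.
    """
    t = scan.table.reset_index(drop=True)
    ok = t["neg_log10_p"].to_numpy() >= threshold_logp
    if fdr is not None:
        if len(fdr.qvalues) != len(t):
            raise ValueError("FDR result is not aligned with the scan")
        ok &= np.asarray(fdr.qvalues) <= q_threshold

    regions = []
    for chrom, sub in t.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        hits = idx[ok[idx]]
        if hits.size == 0:
            continue
        # merge hits separated by <= gap + 1 map-consecutive markers
        breaks = np.flatnonzero(np.diff(hits) > gap + 1)
        groups = np.split(hits, breaks + 1)
        for grp in groups:
            block = t.loc[grp[0]: grp[-1]]
            peak = block.loc[block["neg_log10_p"].idxmax()]
            row = {
                "trait": scan.trait,
                "chrom": chrom,
                "start_cM": float(t.loc[grp[0], "cM"]),
                "end_cM": float(t.loc[grp[-1], "cM"]),
                "n_markers": int(len(grp)),
                "peak_marker": peak["marker"],
                "peak_cM": float(peak["cM"]),
                "neg_log10_p": float(peak["neg_log10_p"]),
                "var_explained": float(peak["var_explained"]),
            }
            for c in t.columns:
                if c.startswith("effect_"):
                    row[c] = float(peak[c])
            regions.append(row)
    cols = ["trait", "chrom", "start_cM", "end_cM", "n_markers", "peak_marker",
            "peak_cM", "neg_log10_p", "var_explained"] + [
        c for c in t.columns if c.startswith("effect_")
    ]
    out = pd.DataFrame(regions, columns=cols)
    return out.sort_values(["chrom", "start_cM"], kind="stable").reset_index(drop=True)
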