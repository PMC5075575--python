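"""Phenotype simulation for the wheat phenology trait suite.

Traits are generated at the line level from planted QTL effects plus a
Gaussian-copula residual structure, then expanded into replicates with
independent measurement noise and optional missingness.

Model, per trait:

* a trait with a planted QTL gets the genetic value ``g_i`` = mean of the
  two founder means carried by line *i* at the QTL marker (alleles act
  additively, so a residual heterozygote scores halfway);
* residual variance is scaled so the locus explains ``h2_locus`` of the
  variance of *replicate-averaged* phenotypes: the line-level value is the
  replicate mean by construction, and within-line replicate deviations are
  centered per line (they add measurement spread without perturbing line
  means), so planted h2 and correlation targets hold exactly at the level
  on which the published statistics were computed;
* companion traits with no QTL are drawn from the conditional Gaussian
  copula given the standardized line values of the QTL traits, so the
  target phenotypic correlation matrix is honoured between QTL and
  non-QTL traits;
* the stress score SM is discretized onto a right-skewed 0-4 ordinal scale.

Default means/SDs and the default correlation matrix emulate the published
phenotypic summaries of the NIAB MAGIC glasshouse screen (e.g. the strong
FLS-GS39 correlation of 0.79).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gmap import GeneticMap
from .simulate import FounderSet, MosaicGenome

__all__ = [
    "QTLSpec",
    "TRAITS",
    "TRAIT_STATS",
    "default_trait_corr",
    "simulate_phenotypes",
    "REP_NOISE_SHARE",
]

#: Trait codes of the measured suite (derived d1/d2/d3 are added downstream).
TRAITS: tuple[str, ...] = (
    "GS39", "GS55", "GS65", "FLS", "PW", "TN", "SH", "TIL",
    "FEL", "SEL", "TEL", "FEW", "OEW", "TEW", "FFLL", "SM", "HI",
)

#: Default per-trait (mean, SD) on the measurement scale: growth stages and
#: FLS in days after sowing, lengths/heights in cm, weights in g, HI a ratio.
TRAIT_STATS: dict[str, tuple[float, float]] = {
    "GS39": (126.0, 5.0),
    "GS55": (136.0, 5.5),
    "GS65": (146.0, 5.5),
    "FLS": (170.0, 8.0),
    "PW": (73.0, 8.0),
    "TN": (25.0, 5.0),
    "SH": (52.0, 6.0),
    "TIL": (28.0, 3.0),
    "FEL": (11.5, 1.0),
    "SEL": (11.0, 1.0),
    "TEL": (10.5, 1.0),
    "FEW": (2.5, 0.5),
    "OEW": (38.0, 5.0),
    "TEW": (41.0, 5.0),
    "FFLL": (20.0, 3.0),
    "SM": (0.0, 1.0),   # latent scale; discretized to the 0-4 ordinal score
    "HI": (0.55, 0.05),
}

#: Within-line replicate variance as a fraction of the residual (non-QTL)
#: line-mean variance; deviations are centered per line, so this adds
#: realistic replicate scatter without touching line-mean statistics.
REP_NOISE_SHARE: float = 0.5

#: Cumulative probabilities of stress scores 0..4 (right-skewed: most lines 0-2).
_SM_CUM = np.array([0.35, 0.65, 0.85, 0.95, 1.0])


@dataclass(frozen=True)
class QTLSpec:
    """A planted QTL: marker, per-founder trait means, and locus heritability."""

    trait: str
    marker_id: str
    founder_means: np.ndarray
    h2_locus: float

    def __post_init__(self) -> None:
        fm = np.asarray(self.founder_means, dtype=float)
        if fm.ndim != 1:
            raise ValueError("founder_means must be a 1-D vector")
        if not 0.0 < self.h2_locus < 1.0:
            raise ValueError("h2_locus must be in (0, 1)")
        object.__setattr__(self, "founder_means", fm)


def default_trait_corr(traits: tuple[str, ...] = TRAITS) -> pd.DataFrame:
    """Target phenotypic correlation matrix for the trait suite.

    Entries follow the reported pairwise correlations where available
    (phenology block, ear lengths, TIL-SH, PW-OEW/TEW) and plausible mild
    values elsewhere; the matrix is projected to the nearest valid
    correlation matrix.
    """
    pairs = {
        ("GS39", "GS55"): 0.85, ("GS39", "GS65"): 0.78, ("GS55", "GS65"): 0.85,
        ("FLS", "GS39"): 0.79, ("FLS", "GS55"): 0.73, ("FLS", "GS65"): 0.69,
        ("FEL", "SEL"): 0.87, ("FEL", "TEL"): 0.86, ("SEL", "TEL"): 0.88,
        ("TIL", "SH"): 0.76, ("PW", "OEW"): 0.87, ("TEW", "PW"): 0.87,
        ("OEW", "TEW"): 0.90, ("FEW", "TEW"): 0.50, ("FEW", "OEW"): 0.40,
        ("TN", "GS39"): 0.30, ("TN", "GS55"): 0.30, ("TN", "FLS"): 0.30,
        ("FFLL", "FLS"): -0.35, ("FFLL", "GS39"): -0.25,
        ("SM", "FLS"): -0.30, ("SM", "GS39"): -0.25, ("SM", "GS55"): -0.25,
        ("SM", "GS65"): -0.20, ("HI", "SM"): 0.20, ("HI", "FLS"): -0.15,
    }
    k = len(traits)
    R = np.eye(k)
    pos = {t: i for i, t in enumerate(traits)}
    for (a, b), r in pairs.items():
        if a in pos and b in pos:
            R[pos[a], pos[b]] = R[pos[b], pos[a]] = r
    R = nearest_correlation(R)
    return pd.DataFrame(R, index=list(traits), columns=list(traits))


def nearest_correlation(R: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalue clipping followed by unit-diagonal rescaling (one pass of
    Higham's alternating projections, sufficient for mildly indefinite
    targets).
    """
    R = (R + R.T) / 2.0
    w, V = np.linalg.eigh(R)
    w = np.clip(w, eps, None)
    A = (V * w) @ V.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return A


def _genetic_values(
    qtl: QTLSpec,
    mosaics: list[MosaicGenome],
    gmap: GeneticMap,
    n_founders: int,
) -> np.ndarray:
    if len(qtl.founder_means) != n_founders:
        raise ValueError(
            f"QTL {qtl.marker_id!r}: founder_means length {len(qtl.founder_means)} "
            f"!= {n_founders} founders"
        )
    try:
        chrom, pos = gmap.locus(qtl.marker_id)
    except KeyError:
        raise ValueError(f"QTL marker {qtl.marker_id!r} is not in the map") from None
    g = np.empty(len(mosaics))
    for i, mos in enumerate(mosaics):
        f0, f1 = mos.founders_at(chrom, np.array([pos]))[0]
        g[i] = 0.5 * (qtl.founder_means[f0] + qtl.founder_means[f1])
    return g


def simulate_phenotypes(
    mosaics: list[MosaicGenome],
    founders: FounderSet,
    qtls: list[QTLSpec],
    trait_corr: pd.DataFrame | None = None,
    traits: tuple[str, ...] = TRAITS,
    trait_stats: dict[str, tuple[float, float]] | None = None,
    n_reps: int = 2,
    missing_rate: float = 0.0219,
    seed: int | np.random.Generator = 0,
    line_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate the replicate-level phenotype table for a set of RIL mosaics.

    Returns a long-format DataFrame with columns ``line_id``, ``rep`` and
    one column per trait code; cells are NaN with probability
    ``missing_rate`` (default the study's reported 2.19%).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    gmap = founders.gmap
    stats = dict(TRAIT_STATS if trait_stats is None else trait_stats)
    R = default_trait_corr(traits) if trait_corr is None else trait_corr
    R = R.loc[list(traits), list(traits)].to_numpy(float)
    w_eig = np.linalg.eigvalsh((R + R.T) / 2)
    if w_eig.min() < -1e-8:
        raise ValueError("trait_corr must be positive semi-definite")

    n = len(mosaics)
    by_trait: dict[str, list[QTLSpec]] = {}
    for q in qtls:
        if q.trait not in traits:
            raise ValueError(f"QTL trait {q.trait!r} not in the simulated suite")
        by_trait.setdefault(q.trait, []).append(q)

    qtl_traits = [t for t in traits if t in by_trait]
    free_traits = [t for t in traits if t not in by_trait]
    idx = {t: i for i, t in enumerate(traits)}

    line_vals = np.empty((n, len(traits)))
    rep_sd = np.zeros(len(traits))

    # QTL traits: genetic value + scaled residual so the loci jointly explain
    # their planted h2 of replicate-averaged phenotypic variance.
    u_q = np.empty((n, len(qtl_traits)))
    for k, t in enumerate(qtl_traits):
        specs = by_trait[t]
        g = np.zeros(n)
        var_g = 0.0
        for j, q in enumerate(specs):
            gq = _genetic_values(q, mosaics, gmap, founders.n_founders)
            # additional loci enter centered so the trait keeps the first
            # locus's founder-mean scale; loci assumed unlinked for variance
            g = g + (gq if j == 0 else gq - gq.mean())
            var_g += float(np.var(gq))
        h2 = sum(q.h2_locus for q in specs)
        if h2 >= 1.0:
            raise ValueError(f"trait {t!r}: combined locus h2 must be < 1")
        var_resid = var_g * (1.0 - h2) / h2
        rep_sd[idx[t]] = np.sqrt(REP_NOISE_SHARE * var_resid)
        v = g + rng.normal(0.0, np.sqrt(var_resid), size=n)
        line_vals[:, idx[t]] = v
        u_q[:, k] = (v - v.mean()) / max(v.std(), 1e-12)

    # companion traits: conditional Gaussian copula given the QTL traits
    if free_traits:
        qi = [idx[t] for t in qtl_traits]
        fi = [idx[t] for t in free_traits]
        if qtl_traits:
            Rqq = R[np.ix_(qi, qi)]
            Rfq = R[np.ix_(fi, qi)]
            B = Rfq @ np.linalg.pinv(Rqq)
            cond_mean = u_q @ B.T
            cond_cov = R[np.ix_(fi, fi)] - B @ Rfq.T
        else:
            cond_mean = np.zeros((n, len(fi)))
            cond_cov = R[np.ix_(fi, fi)]
        w, V = np.linalg.eigh((cond_cov + cond_cov.T) / 2)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        u_f = cond_mean + rng.standard_normal((n, len(fi))) @ L.T
        for k, t in enumerate(free_traits):
            mu, sd = stats[t]
            line_vals[:, idx[t]] = mu + sd * u_f[:, k]
            rep_sd[idx[t]] = sd * np.sqrt(REP_NOISE_SHARE)

    # expand to replicates; within-line deviations are centered per line so
    # replicate means reproduce the line values exactly
    if line_ids is None:
        line_ids = [f"MEL_{i + 1:03d}" for i in range(n)]
    rows = np.repeat(np.arange(n), n_reps)
    reps = np.tile(np.arange(1, n_reps + 1), n)
    eps = rng.standard_normal((n, n_reps, len(traits))) * rep_sd
    eps -= eps.mean(axis=1, keepdims=True)
    data = line_vals[rows] + eps.reshape(n * n_reps, len(traits))

    # stress score: discretize the (noisy, standardized) latent onto 0..4
    if "SM" in idx:
        j = idx["SM"]
        z = data[:, j]
        z = (z - z.mean()) / max(z.std(), 1e-12)
        cuts = norm.ppf(_SM_CUM[:-1])
        data[:, j] = np.searchsorted(cuts, z, side="left").astype(float)

    if missing_rate > 0:
        data[rng.random(data.shape) < missing_rate] = np.nan

    out = pd.DataFrame(data, columns=list(traits))
    out.insert(0, "rep", reps)
    out.insert(0, "line_id", np.asarray(line_ids, object)[rows])
    return out
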