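"""Founder-descent probability reconstruction by forward-backward decoding.

Each RIL genome is modelled as a hidden Markov chain along every
chromosome whose hidden state is the founder of origin. Transitions over a
map distance of d cM follow an exchangeable switching process calibrated
by an effective meiosis count g (funnel crossing plus selfing):

    P(stay)  = exp(-g d / 100) + (1 - exp(-g d / 100)) / S
    P(s -> t) = (1 - exp(-g d / 100)) / S          (t != s)

i.e. with probability 1 - exp(-g d/100) the ancestry is redrawn uniformly
from the S founders. Emissions compare the observed biallelic genotype
call against the founder's allele with a symmetric genotyping error rate.

The default haploid state space (S states) treats lines as inbred, which
the F5+ RILs nearly are; a diplotype mode (S x S ordered-pair states) is
available for lines with residual heterozygosity. Posteriors are exact and
computed with per-locus rescaling, so no underflow occurs even for maps
with tens of thousands of loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .gmap import GeneticMap
from .simulate import (
    MISSING,
    FounderSet,
    GenotypeMatrix,
    HaplotypeTrack,
    MosaicGenome,
)

__all__ = [
    "HMMParams",
    "FounderProbabilities",
    "transition_matrix",
    "emission_prob",
    "forward_backward",
    "viterbi_mosaic",
    "FounderHMM",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HMMParams:
    """Transition/emission parameters of the founder-descent chain.

    generations : effective meiosis count g scaling recombination distance
        (default 8: three funnel crosses plus five selfing rounds).
    error_rate : symmetric allele-flip probability of a genotype call.
    inbred_mode : haploid S-state chain if True, else S^2 diplotype chain.
    """

    generations: float = 8.0
    error_rate: float = 0.01
    inbred_mode: bool = True

    def __post_init__(self) -> None:
        if self.generations <= 0:
            raise ValueError("generations must be > 0")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


def transition_matrix(d: float, params: HMMParams, n_founders: int = 8) -> np.ndarray:
    """S x S founder-switch matrix over a map distance of ``d`` cM."""
    if d < 0:
        raise ValueError("map distance must be >= 0")
    s = n_founders
    p_switch_total = 1.0 - np.exp(-params.generations * d / 100.0)
    off = p_switch_total / s
    T = np.full((s, s), off)
    np.fill_diagonal(T, np.exp(-params.generations * d / 100.0) + off)
    return T


def emission_prob(observed: int, founder_allele: int, error_rate: float) -> float:
    """Haploid-mode emission: P(observed genotype call | founder allele).

    Homozygous calls match the founder allele with probability 1 - eps;
    heterozygous calls are uninformative under residual heterozygosity
    (0.5); missing calls contribute 1.
    """
    if observed == MISSING:
        return 1.0
    if observed not in (0, 1, 2):
        raise ValueError(f"invalid genotype code {observed!r}")
    if founder_allele not in (0, 1):
        raise ValueError(f"invalid founder allele {founder_allele!r}")
    if observed == 1:
        return 0.5
    match = (observed == 2) == (founder_allele == 1)
    return 1.0 - error_rate if match else error_rate


def _haploid_emissions(G: np.ndarray, H: np.ndarray, eps: float) -> np.ndarray:
    """(n_lines, m, S) emission probabilities for one chromosome.

    G is (n_lines, m) int codes, H is (S, m) founder alleles.
    """
    n, m = G.shape
    s = H.shape[0]
    E = np.ones((n, m, s))
    hom_alt = H.T[None, :, :] == 1                          # (1, m, S)
    obs = G[:, :, None]                                     # (n, m, 1)
    match = (obs == 2) == hom_alt
    hom_mask = (obs == 0) | (obs == 2)
    E = np.where(hom_mask, np.where(match, 1.0 - eps, eps), E)
    E = np.where(obs == 1, 0.5, E)
    return E


def _dosage_emission_table(eps: float) -> np.ndarray:
    """(3 true dosages, 3 observed) call probabilities under allele flips."""
    q = 1.0 - eps
    return np.array([
        [q * q, 2 * eps * q, eps * eps],
        [eps * q, q * q + eps * eps, eps * q],
        [eps * eps, 2 * eps * q, q * q],
    ])


def _chain_pass(E: np.ndarray, pos: np.ndarray, params: HMMParams):
    """Scaled forward-backward over one chromosome, vectorized over lines.

    E : (n, m, S) emissions; pos : (m,) cM positions.
    Returns posterior (n, m, S), log-likelihood (n,), and the per-step
    rescaled forward/backward arrays for reuse.
    """
    n, m, s = E.shape
    stay = np.exp(-params.generations * np.diff(pos) / 100.0)   # (m-1,)

    alpha = np.empty_like(E)
    scale = np.empty((n, m))
    a = E[:, 0, :] / s
    c = a.sum(axis=1)
    c = np.where(c <= 0, 1.0, c)
    alpha[:, 0, :] = a / c[:, None]
    scale[:, 0] = c
    for k in range(1, m):
        prev = alpha[:, k - 1, :]
        # rank-one transition: stay*prev + (1-stay) * uniform redraw
        pred = stay[k - 1] * prev + (1.0 - stay[k - 1]) / s * prev.sum(1, keepdims=True)
        a = pred * E[:, k, :]
        c = a.sum(axis=1)
        c = np.where(c <= 0, 1.0, c)
        alpha[:, k, :] = a / c[:, None]
        scale[:, k] = c

    beta = np.empty_like(E)
    beta[:, m - 1, :] = 1.0
    for k in range(m - 2, -1, -1):
        nxt = beta[:, k + 1, :] * E[:, k + 1, :]
        b = stay[k] * nxt + (1.0 - stay[k]) / s * nxt.sum(1, keepdims=True)
        beta[:, k, :] = b / scale[:, k + 1, None]

    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    loglik = np.log(scale).sum(axis=1)
    return post, loglik


@dataclass(frozen=True)
class FounderProbabilities:
    """Posterior founder-descent probabilities for every line and locus.

    ``probs`` is (n_lines, n_markers, S), each vector summing to one. In
    diplotype mode the symmetric ordered-pair posterior ``diplotype``
    (n, m, S, S) is also stored; ``probs`` is then its row-sum marginal.
    """

    probs: np.ndarray = field(repr=False)
    line_ids: tuple[str, ...]
    founder_names: tuple[str, ...]
    gmap: GeneticMap = field(repr=False)
    loglik: np.ndarray = field(repr=False, default=None)
    diplotype: np.ndarray | None = field(repr=False, default=None)

    def __post_init__(self) -> None:
        P = np.asarray(self.probs, dtype=float)
        n, m, s = P.shape
        if m != self.gmap.n_markers or s != len(self.founder_names):
            raise ValueError("probability array shape does not match map/founders")
        if n != len(self.line_ids):
            raise ValueError("probability array shape does not match line ids")
        object.__setattr__(self, "probs", P)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_founders(self) -> int:
        return len(self.founder_names)

    def at_marker(self, marker: str) -> np.ndarray:
        """(n_lines, S) posterior slice at one mapped marker."""
        return self.probs[:, self.gmap.index_of(marker), :]

    def diplotype_at_marker(self, marker: str) -> np.ndarray:
        if self.diplotype is None:
            raise ValueError(
                "diplotype probabilities unavailable: rerun with inbred_mode=False"
            )
        return self.diplotype[:, self.gmap.index_of(marker), :, :]


class FounderHMM(BaseEstimator, TransformerMixin):
    """Founder-probability reconstruction as a scikit-learn transformer.

    ``fit`` stores the founder haplotypes and map; ``transform`` maps a
    :class:`GenotypeMatrix` (or raw (n_lines, n_markers) coded array) to
    :class:`FounderProbabilities`.

    Parameters
    ----------
    generations : effective meioses for transition scaling (default 8).
    error_rate : genotyping error rate epsilon (default 0.01).
    inbred_mode : haploid state space if True (default), diplotype otherwise.
    """

    def __init__(self, generations: float = 8.0, error_rate: float = 0.01,
                 inbred_mode: bool = True):
        self.generations = generations
        self.error_rate = error_rate
        self.inbred_mode = inbred_mode

    # -- sklearn plumbing ---------------------------------------------------
    def fit(self, founders: FounderSet, y=None) -> "FounderHMM":
        if not isinstance(founders, FounderSet):
            raise TypeError("FounderHMM.fit expects a FounderSet")
        self.params_ = HMMParams(self.generations, self.error_rate, self.inbred_mode)
        self.founders_ = founders
        self.n_founders_ = founders.n_founders
        return self

    def transform(self, genotypes: GenotypeMatrix) -> FounderProbabilities:
        self._check_fitted()
        G, line_ids = self._coerce(genotypes)
        return _posterior_all(G, line_ids, self.founders_, self.params_)

    def viterbi(self, genotypes: GenotypeMatrix) -> list[MosaicGenome]:
        """Most probable founder mosaic per line (haploid path, both homologs)."""
        self._check_fitted()
        G, _ = self._coerce(genotypes)
        return [
            viterbi_mosaic(G[i], self.founders_, self.founders_.gmap, self.params_)
            for i in range(G.shape[0])
        ]

    def _check_fitted(self) -> None:
        if not hasattr(self, "founders_"):
            raise RuntimeError("FounderHMM is not fitted: call fit(founders) first")

    def _coerce(self, genotypes) -> tuple[np.ndarray, tuple[str, ...]]:
        if isinstance(genotypes, GenotypeMatrix):
            if genotypes.gmap.n_markers != self.founders_.gmap.n_markers:
                raise ValueError("genotype matrix map does not match founders")
            return genotypes.matrix, genotypes.line_ids
        G = np.asarray(genotypes)
        if G.ndim == 1:
            G = G[None, :]
        if G.shape[1] != self.founders_.gmap.n_markers:
            raise ValueError("genotype array width does not match the map")
        return G, tuple(f"line{i}" for i in range(G.shape[0]))


def _posterior_all(
    G: np.ndarray,
    line_ids: tuple[str, ...],
    founders: FounderSet,
    params: HMMParams,
) -> FounderProbabilities:
    gmap = founders.gmap
    n = G.shape[0]
    s = founders.n_founders
    m = gmap.n_markers
    probs = np.empty((n, m, s))
    loglik = np.zeros(n)
    dip = np.empty((n, m, s, s)) if not params.inbred_mode else None

    for chrom in gmap.chromosomes:
        sl = gmap.chrom_slice(chrom)
        pos = gmap.positions(chrom)
        Gc = G[:, sl]
        Hc = founders.haplotypes[:, sl]
        if (Gc == MISSING).all():
            logger.warning(
                "chromosome %s has no genotype calls: posteriors are uniform", chrom
            )
        if params.inbred_mode:
            E = _haploid_emissions(Gc, Hc, params.error_rate)
            post, ll = _chain_pass(E, pos, params)
            probs[:, sl, :] = post
        else:
            E2 = _diplotype_emissions(Gc, Hc, params.error_rate)
            post2, ll = _diplotype_pass(E2, pos, params)
            dip[:, sl, :, :] = post2
            probs[:, sl, :] = post2.sum(axis=3)
        loglik += ll
    return FounderProbabilities(
        probs, tuple(line_ids), founders.names, gmap, loglik=loglik, diplotype=dip
    )


def _diplotype_emissions(G: np.ndarray, H: np.ndarray, eps: float) -> np.ndarray:
    """(n, m, S, S) emissions for ordered founder pairs via true dosage."""
    table = _dosage_emission_table(eps)
    n, m = G.shape
    dosage = (H[:, None, :] + H[None, :, :]).transpose(2, 0, 1)   # (m, S, S)
    # tmp[dv, i, k] = P(observe G[i,k] | true dosage dv)
    tmp = table[:, np.clip(G, 0, 2)]                               # (3, n, m)
    E = tmp[
        dosage[None, :, :, :],
        np.arange(n)[:, None, None, None],
        np.arange(m)[None, :, None, None],
    ]                                                              # (n, m, S, S)
    return np.where((G >= 0)[:, :, None, None], E, 1.0)


def _diplotype_pass(E: np.ndarray, pos: np.ndarray, params: HMMParams):
    """Forward-backward on the ordered-pair state space.

    Transitions factorize over the two homologs, each following the
    haploid rank-one switching kernel.
    """
    n, m, s, _ = E.shape
    stay = np.exp(-params.generations * np.diff(pos) / 100.0)

    def spread(x: np.ndarray, a: float) -> np.ndarray:
        # apply the haploid kernel along both founder axes of (n, S, S)
        x = a * x + (1 - a) / s * x.sum(axis=1, keepdims=True)
        x = a * x + (1 - a) / s * x.sum(axis=2, keepdims=True)
        return x

    alpha = np.empty_like(E)
    scale = np.empty((n, m))
    a0 = E[:, 0] / (s * s)
    c = a0.sum(axis=(1, 2))
    c = np.where(c <= 0, 1.0, c)
    alpha[:, 0] = a0 / c[:, None, None]
    scale[:, 0] = c
    for k in range(1, m):
        pred = spread(alpha[:, k - 1], stay[k - 1])
        a = pred * E[:, k]
        c = a.sum(axis=(1, 2))
        c = np.where(c <= 0, 1.0, c)
        alpha[:, k] = a / c[:, None, None]
        scale[:, k] = c

    beta = np.empty_like(E)
    beta[:, m - 1] = 1.0
    for k in range(m - 2, -1, -1):
        nxt = beta[:, k + 1] * E[:, k + 1]
        beta[:, k] = spread(nxt, stay[k]) / scale[:, k + 1, None, None]

    post = alpha * beta
    post /= post.sum(axis=(2, 3), keepdims=True)
    # symmetrize: ordered pairs (s,t) and (t,s) are exchangeable
    post = 0.5 * (post + post.transpose(0, 1, 3, 2))
    return post, np.log(scale).sum(axis=1)


def forward_backward(
    genotypes: np.ndarray,
    founders: FounderSet,
    gmap: GeneticMap | None = None,
    params: HMMParams | None = None,
) -> tuple[np.ndarray, float]:
    """Posterior founder probabilities for a single line.

    Returns the (n_markers, S) posterior and the genotype log-likelihood.
    Thin functional wrapper over :class:`FounderHMM`.
    """
    params = params or HMMParams()
    if gmap is not None and gmap.n_markers != founders.gmap.n_markers:
        raise ValueError("map does not match founder haplotypes")
    fp = _posterior_all(
        np.asarray(genotypes, dtype=np.int8)[None, :], ("line0",), founders, params
    )
    return fp.probs[0], float(fp.loglik[0])


def viterbi_mosaic(
    genotypes: np.ndarray,
    founders: FounderSet,
    gmap: GeneticMap | None = None,
    params: HMMParams | None = None,
) -> MosaicGenome:
    """Most probable founder path per chromosome, as a homozygous mosaic.

    Ties are broken toward the lower founder index. The returned mosaic
    duplicates the haploid path on both homolog tracks (inbred reading).
    """
    params = params or HMMParams()
    gmap = gmap or founders.gmap
    G = np.asarray(genotypes, dtype=np.int8)
    tracks: dict[str, tuple[HaplotypeTrack, HaplotypeTrack]] = {}
    s = founders.n_founders
    for chrom in gmap.chromosomes:
        sl = gmap.chrom_slice(chrom)
        pos = gmap.positions(chrom)
        E = _haploid_emissions(G[None, sl], founders.haplotypes[:, sl],
                               params.error_rate)[0]
        with np.errstate(divide="ignore"):
            logE = np.log(E)
        m = len(pos)
        delta = np.full(s, -np.log(s)) + logE[0]
        ptr = np.zeros((m, s), dtype=np.int64)
        for k in range(1, m):
            T = transition_matrix(pos[k] - pos[k - 1], params, s)
            with np.errstate(divide="ignore"):
                scores = delta[:, None] + np.log(T)
            ptr[k] = scores.argmax(axis=0)       # argmax -> lowest index on ties
            delta = scores.max(axis=0) + logE[k]
        path = np.empty(m, dtype=np.int64)
        path[-1] = int(delta.argmax())
        for k in range(m - 1, 0, -1):
            path[k - 1] = ptr[k, path[k]]

        lo, hi = gmap.chrom_span(chrom)
        hi = max(hi, lo + 1e-9)
        # segment boundaries at midpoints between adjacent differing markers
        change = np.flatnonzero(path[1:] != path[:-1])
        ends = np.append((pos[change] + pos[change + 1]) / 2.0, hi)
        fnd = path[np.append(change, m - 1)]
        ends = np.maximum.accumulate(ends)
        keep = np.append(np.diff(ends) > 0, True)
        trk = HaplotypeTrack(lo, ends[keep], fnd[keep])
        tracks[chrom] = (trk, trk)
    return MosaicGenome(tracks)
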