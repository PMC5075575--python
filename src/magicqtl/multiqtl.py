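"""Composite scanning: forward selection of marker covariates.

Mirrors the covariate-assisted validation analysis used with multi-parent
interval mapping: the genome is scanned conditional on the additive
founder-dosage blocks of already-selected markers, the top conditional
marker enters the model if it clears the entry threshold (-log10 P >= 4
by default, the same threshold used for single-locus calling), and the
process repeats up to ``max_covariates`` markers. Conditioning on a
marker removes its own signal, so linked QTL hidden behind a stronger
peak become visible in later rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import FounderProbabilities
from .scan import ScanResult, _align_phenotype, _orth_basis, genome_scan

__all__ = ["CovariateModel", "conditional_scan", "forward_select"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CovariateModel:
    """Result of forward covariate selection.

    ``selection`` has one row per entered marker (order preserved) with
    its conditional F statistic and -log10 P at entry; ``final_scan`` is
    the genome scan conditional on the full selected set.
    """

    selection: pd.DataFrame = field(repr=False)
    final_scan: ScanResult = field(repr=False)

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.selection["marker"])


def _dosage_block(F: FounderProbabilities, marker: str) -> np.ndarray:
    """Covariate columns for one marker: founder dosages, reference dropped.

    The S dosage columns sum to one, so the first founder's column is
    dropped to avoid forced collinearity with the intercept.
    """
    return F.at_marker(marker)[:, 1:]


def conditional_scan(
    y,
    F: FounderProbabilities,
    covariate_markers: tuple[str, ...] | list[str] = (),
    model: str = "additive",
    trait: str = "",
) -> ScanResult:
    """Genome scan with selected markers' dosage blocks in both models.

    With an empty covariate set this is exactly the single-locus scan.
    """
    for mk in covariate_markers:
        F.gmap.index_of(mk)  # raises on unmapped covariates
    C = (
        np.hstack([_dosage_block(F, mk) for mk in covariate_markers])
        if covariate_markers else None
    )
    return genome_scan(
        y, F, model=model, covariates=C, trait=trait,
        covariate_markers=tuple(covariate_markers),
    )


def forward_select(
    y,
    F: FounderProbabilities,
    max_covariates: int = 10,
    entry_threshold_logp: float = 4.0,
    exclusion_cm: float = 10.0,
    model: str = "additive",
    trait: str = "",
) -> CovariateModel:
    """Forward selection of marker covariates by conditional scanning.

    Each round scans conditional on the current covariate set and admits
    the genome-wide top marker if its conditional -log10 P clears the
    entry threshold. Markers within ``exclusion_cm`` of an already
    selected covariate are not eligible (they re-describe the same QTL),
    and a candidate whose dosage block adds no rank to the model
    (collinear with the current covariates) is skipped with a warning in
    favour of the next-best eligible marker.
    """
    if max_covariates < 0:
        raise ValueError("max_covariates must be >= 0")
    yv = _align_phenotype(y, F)
    keep = np.isfinite(yv)
    tab = F.gmap.table
    chroms = tab["chrom"].to_numpy()
    pos = tab["cM"].to_numpy(float)

    selected: list[str] = []
    rows = []
    scan = conditional_scan(y, F, (), model=model, trait=trait)
    while len(selected) < max_covariates:
        eligible = np.ones(len(tab), dtype=bool)
        for mk in selected:
            c, p = F.gmap.locus(mk)
            eligible &= ~((chroms == c) & (np.abs(pos - p) <= exclusion_cm))
        scores = np.where(eligible, scan.neg_log10_p, -np.inf)

        entered = False
        for L in np.argsort(scores)[::-1]:
            if scores[L] < entry_threshold_logp or not np.isfinite(scores[L]):
                break
            cand = str(tab.loc[L, "marker"])
            base = [np.ones((int(keep.sum()), 1))] + [
                _dosage_block(F, mk)[keep] for mk in selected
            ]
            _, r_base = _orth_basis(np.hstack(base))
            _, r_new = _orth_basis(
                np.hstack(base + [_dosage_block(F, cand)[keep]])
            )
            if r_new <= r_base:
                logger.warning(
                    "covariate %s is collinear with the selected set; skipping", cand
                )
                continue
            selected.append(cand)
            row = scan.table.loc[L]
            rows.append({
                "step": len(selected),
                "marker": cand,
                "chrom": row["chrom"],
                "cM": float(row["cM"]),
                "f_stat": float(row["f_stat"]),
                "neg_log10_p": float(row["neg_log10_p"]),
            })
            entered = True
            break
        if not entered:
            break
        scan = conditional_scan(y, F, tuple(selected), model=model, trait=trait)

    sel = pd.DataFrame(
        rows, columns=["step", "marker", "chrom", "cM", "f_stat", "neg_log10_p"]
    )
    return CovariateModel(sel, scan)
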