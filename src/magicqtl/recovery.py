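"""Parameter-recovery and calibration studies on simulated populations.

These are the package's validation experiments: plant published QTL rows
(founder means and locus h2) into simulated MAGIC populations, run the
inference pipeline, and measure how well the planted quantities are
recovered; and calibrate the permutation threshold's genome-wide type-I
error on null datasets. Both tests and the reproduction script drive
these entry points.

Default problem sizes are desk-scale: 208 lines on the three-chromosome
~1 cM map for recovery (the published population size), and 100-line
populations on a sparser map for the null-calibration sweep.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gmap import GeneticMap, demo_map
from .hmm import FounderHMM
from .pheno import average_replicates
from .phenosim import QTLSpec, simulate_phenotypes
from .presets import qtl_spec
from .scan import ScanEngine, genome_scan
from .simulate import emit_genotypes, simulate_founders, simulate_population_mosaics

__all__ = ["recovery_study", "permutation_calibration"]

#: Default planted rows: the two headline phenology QTLs (both at the same
#: 5A marker) and the height QTL on 4D.
DEFAULT_ROWS: tuple[tuple[str, str], ...] = (
    ("GS39", "BS00009369_51"),
    ("GS55", "BS00009369_51"),
    ("SH", "RAC875_c1673_193"),
)


def _one_replicate(
    seed: int,
    qtls: list[QTLSpec],
    gmap: GeneticMap,
    n_lines: int,
    divergence: float,
    geno_error: float,
    geno_missing: float,
    n_reps: int,
    pheno_missing: float,
    hmm_generations: float,
    hmm_error: float,
) -> list[dict]:
    base = (seed * 1000) % (2 ** 31 - 5000)
    founders = simulate_founders(gmap, 8, divergence, seed=base + 1)
    mosaics, ids = simulate_population_mosaics(founders, gmap, n_lines, seed=base + 2)
    geno = emit_genotypes(mosaics, founders, geno_error, geno_missing,
                          seed=base + 3, line_ids=ids)
    pheno = simulate_phenotypes(mosaics, founders, qtls, n_reps=n_reps,
                                missing_rate=pheno_missing, seed=base + 4,
                                line_ids=ids)
    F = FounderHMM(hmm_generations, hmm_error).fit(founders).transform(geno)
    means = average_replicates(pheno).set_index("line_id")

    out = []
    for q in qtls:
        scan = genome_scan(means[q.trait], F, trait=q.trait)
        top = scan.top_marker()
        true_chrom, true_pos = gmap.locus(q.marker_id)
        row = {
            "seed": seed,
            "trait": q.trait,
            "planted_marker": q.marker_id,
            "top_marker": top["marker"],
            "top_chrom": top["chrom"],
            "top_cM": float(top["cM"]),
            "hit_chrom": top["chrom"] == true_chrom,
            "dist_cM": abs(float(top["cM"]) - true_pos)
            if top["chrom"] == true_chrom else np.inf,
            "neg_log10_p": float(top["neg_log10_p"]),
            "var_explained": float(top["var_explained"]),
        }
        for j, name in enumerate(F.founder_names):
            row[f"effect_{name}"] = float(top[f"effect_{name}"])
        out.append(row)
    return out


def recovery_study(
    n_replicates: int = 100,
    base_seed: int = 1,
    rows: tuple[tuple[str, str], ...] = DEFAULT_ROWS,
    n_lines: int = 208,
    markers_per_chrom: int = 100,
    divergence: float = 0.5,
    geno_error: float = 0.005,
    geno_missing: float = 0.0219,
    n_reps: int = 2,
    pheno_missing: float = 0.0219,
    hmm_generations: float = 8.0,
    hmm_error: float = 0.01,
) -> pd.DataFrame:
    """Replicate plant-and-recover simulations of published QTL rows.

    Each replicate simulates a fresh population (seeds ``base_seed`` ...
    ``base_seed + n_replicates - 1``), plants every requested row, runs
    inference plus the additive scan, and records the genome-wide top
    marker with its effects and variance fraction. Returns one row per
    replicate x trait.
    """
    gmap = demo_map(markers_per_chrom)
    qtls = [qtl_spec(t, m) for t, m in rows]
    records: list[dict] = []
    for k in range(n_replicates):
        records.extend(_one_replicate(
            base_seed + k, qtls, gmap, n_lines, divergence, geno_error,
            geno_missing, n_reps, pheno_missing, hmm_generations, hmm_error,
        ))
    return pd.DataFrame(records)


def summarize_recovery(study: pd.DataFrame) -> pd.DataFrame:
    """Per-trait means and Monte-Carlo standard errors of the estimates."""
    rows = []
    eff_cols = [c for c in study.columns if c.startswith("effect_")]
    for trait, sub in study.groupby("trait", sort=False):
        n = len(sub)
        row = {"trait": trait, "n_replicates": n,
               "hit_rate_5cM": float((sub["dist_cM"] <= 5).mean()),
               "var_explained_mean": float(sub["var_explained"].mean()),
               "var_explained_se": float(sub["var_explained"].std(ddof=1) / np.sqrt(n))}
        for c in eff_cols:
            row[f"{c}_mean"] = float(sub[c].mean())
            row[f"{c}_se"] = float(sub[c].std(ddof=1) / np.sqrt(n))
        rows.append(row)
    return pd.DataFrame(rows)


def permutation_calibration(
    n_datasets: int = 400,
    n_perm: int = 200,
    base_seed: int = 0,
    n_lines: int = 100,
    markers_per_chrom: int = 50,
    divergence: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genome-wide type-I error of the permutation threshold on null data.

    Each dataset is a fresh simulated population with a phenotype drawn
    independently of the genotypes; the dataset's own ``n_perm``
    permutations set the (1 - alpha) threshold, and the observed scan
    maximum is compared against it. The exceedance rate over datasets
    estimates the family-wise error, which should sit near ``alpha``.
    """
    gmap = demo_map(markers_per_chrom)
    rows = []
    for k in range(n_datasets):
        base = (base_seed + 7919 * k) % (2 ** 31 - 100)
        founders = simulate_founders(gmap, 8, divergence, seed=base + 1)
        mosaics, ids = simulate_population_mosaics(founders, gmap, n_lines,
                                                   seed=base + 2)
        geno = emit_genotypes(mosaics, founders, 0.005, 0.0219,
                              seed=base + 3, line_ids=ids)
        F = FounderHMM().fit(founders).transform(geno)
        rng = np.random.default_rng(base + 4)
        y = rng.standard_normal(n_lines)

        engine = ScanEngine(F)
        observed = float(engine.batch_max_neglogp(y[:, None])[0])
        Y = np.empty((n_lines, n_perm))
        for b in range(n_perm):
            Y[:, b] = y[rng.permutation(n_lines)]
        maxima = engine.batch_max_neglogp(Y)
        threshold = float(np.quantile(maxima, 1 - alpha, method="higher"))
        rows.append({"dataset": k, "observed_max": observed,
                     "threshold": threshold,
                     "exceeds": observed > threshold})
    return pd.DataFrame(rows)
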