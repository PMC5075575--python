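"""End-to-end pipeline: simulate -> prep -> infer -> scan -> perm -> report.

A single YAML-configurable entry point that wires the simulator, the
phenotype preparation stages, founder-probability inference, the genome
scans and the permutation/FDR machinery together, writing every
intermediate artifact plus a SHA-256 manifest. All randomness derives
from explicit per-stage seeds computed from the master seed, so a config
run twice produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .gmap import demo_map
from .hmm import FounderHMM
from .phenosim import QTLSpec, simulate_phenotypes
from .pheno import (
    average_replicates,
    correlation_matrix,
    derive_intervals,
    flag_outliers,
    kinship_pca,
    mice_impute,
    mlrm_fls,
    trait_pca,
)
from .presets import QTL_ROWS, qtl_spec
from .scan import genome_scan
from .significance import call_qtls, empirical_pvalue, permutation_null, qvalues
from .simulate import emit_genotypes, simulate_founders, simulate_population_mosaics

__all__ = ["PipelineConfig", "QTLReport", "run_pipeline"]

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the study-scale defaults.

    ``qtls`` entries are mappings with at least ``trait`` and ``marker``;
    ``founder_means`` and ``h2`` default to the published row for that
    pair when omitted.
    """

    seed: int = 1
    n_lines: int = 208
    n_self: int = 5
    markers_per_chrom: int = 100
    divergence: float = 0.5
    geno_error_rate: float = 0.005
    geno_missing_rate: float = 0.0219
    n_reps: int = 2
    pheno_missing_rate: float = 0.0219
    qtls: list[dict] = field(default_factory=lambda: [
        {"trait": "GS39", "marker": "BS00009369_51"},
        {"trait": "SH", "marker": "RAC875_c1673_193"},
    ])
    hmm_generations: float = 8.0
    hmm_error_rate: float = 0.01
    model: str = "additive"
    n_perm: int = 200
    threshold_logp: float = 4.0
    q_threshold: float = 0.05
    mice_m: int = 5

    def __post_init__(self) -> None:
        if self.threshold_logp <= 0 or not 0 < self.q_threshold <= 1:
            raise ValueError("thresholds must be positive")
        if self.n_perm < 0:
            raise ValueError("n_perm must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def resolve_qtls(self) -> list[QTLSpec]:
        specs = []
        for q in self.qtls:
            trait, marker = q["trait"], q["marker"]
            if "founder_means" in q or "h2" in q:
                specs.append(QTLSpec(
                    trait=trait, marker_id=marker,
                    founder_means=np.asarray(q["founder_means"], float),
                    h2_locus=float(q["h2"]),
                ))
            elif (trait, marker) in QTL_ROWS:
                specs.append(qtl_spec(trait, marker))
            else:
                raise ValueError(
                    f"QTL ({trait}, {marker}) has no published row: "
                    "give founder_means and h2 explicitly"
                )
        return specs

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class QTLReport:
    """Called QTLs across traits plus a complete provenance block."""

    table: pd.DataFrame = field(repr=False)
    provenance: dict = field(default_factory=dict)


def _stage_seed(master: int, stage: int) -> int:
    return (master * 1000 + stage) % (2 ** 31)


def run_pipeline(config: PipelineConfig, out_dir) -> QTLReport:
    """Run every stage and write all artifacts under ``out_dir``.

    Raises with the failing stage's name on any error. Returns the final
    report, which is also written as ``report.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "configure"
    try:
        qtls = config.resolve_qtls()

        stage = "simulate"
        gmap = demo_map(config.markers_per_chrom)
        founders = simulate_founders(
            gmap, 8, config.divergence, seed=_stage_seed(config.seed, 1)
        )
        mosaics, line_ids = simulate_population_mosaics(
            founders, gmap, config.n_lines, config.n_self,
            seed=_stage_seed(config.seed, 2),
        )
        geno = emit_genotypes(
            mosaics, founders, config.geno_error_rate, config.geno_missing_rate,
            seed=_stage_seed(config.seed, 3), line_ids=line_ids,
        )
        pheno = simulate_phenotypes(
            mosaics, founders, qtls, n_reps=config.n_reps,
            missing_rate=config.pheno_missing_rate,
            seed=_stage_seed(config.seed, 4), line_ids=line_ids,
        )
        mio.write_map(gmap, out / "map.csv")
        mio.write_founders(founders, out / "founders.csv")
        mio.write_genotypes(geno, out / "genotypes.csv")
        mio.write_phenotypes(pheno, out / "phenotypes.csv")
        mio.write_mosaics(mosaics, line_ids, out / "mosaics_truth.tsv")
        mio.write_qtl_truth(qtls, founders.names, out / "qtl_truth.tsv")
        artifacts.update({
            "map": "map.csv", "founders": "founders.csv",
            "genotypes": "genotypes.csv", "phenotypes": "phenotypes.csv",
            "mosaics_truth": "mosaics_truth.tsv", "qtl_truth": "qtl_truth.tsv",
        })

        stage = "prep"
        pheno = derive_intervals(pheno)
        qc = flag_outliers(pheno)
        qc.to_csv(out / "qc_outliers.tsv", sep="\t", index=False)
        corr_pre = correlation_matrix(pheno)
        corr_pre.to_csv(out / "correlations_pairwise.tsv", sep="\t", na_rep="NA")
        imputed, _ = mice_impute(pheno, m=config.mice_m,
                                 seed=_stage_seed(config.seed, 5))
        line_means = average_replicates(imputed)
        corr_post = correlation_matrix(line_means)
        corr_post.to_csv(out / "correlations_imputed.tsv", sep="\t", na_rep="NA")
        pca = trait_pca(line_means)
        pca.scores.to_csv(out / "trait_pca_scores.tsv", sep="\t")
        pca.loadings.to_csv(out / "trait_pca_loadings.tsv", sep="\t")
        kin = kinship_pca(geno)
        mlrm = mlrm_fls(line_means) if "FLS" in line_means.columns else None
        if mlrm is not None:
            mlrm.summary.to_csv(out / "mlrm_fls.tsv", sep="\t")
        artifacts.update({
            "qc_outliers": "qc_outliers.tsv",
            "correlations_pairwise": "correlations_pairwise.tsv",
            "correlations_imputed": "correlations_imputed.tsv",
            "trait_pca_scores": "trait_pca_scores.tsv",
            "trait_pca_loadings": "trait_pca_loadings.tsv",
        })
        if mlrm is not None:
            artifacts["mlrm_fls"] = "mlrm_fls.tsv"

        stage = "infer"
        hmm = FounderHMM(config.hmm_generations, config.hmm_error_rate,
                         inbred_mode=config.model != "full").fit(founders)
        F = hmm.transform(geno)
        np.save(out / "founder_probs.npy", F.probs)
        pd.DataFrame({"line_id": list(F.line_ids)}).to_csv(
            out / "founder_probs_lines.tsv", sep="\t", index=False
        )
        pd.DataFrame({"founder": list(F.founder_names)}).to_csv(
            out / "founder_probs_founders.tsv", sep="\t", index=False
        )
        artifacts["founder_probs_lines"] = "founder_probs_lines.tsv"
        artifacts["founder_probs_founders"] = "founder_probs_founders.tsv"

        stage = "scan"
        traits = list(dict.fromkeys(q.trait for q in qtls))
        called = []
        perm_rows = []
        for i, trait in enumerate(traits):
            y = line_means.set_index("line_id")[trait]
            scan = genome_scan(y, F, model=config.model, trait=trait)
            mio.write_scan(scan, out / f"scan_{trait}.tsv")
            artifacts[f"scan_{trait}"] = f"scan_{trait}.tsv"
            pvals = np.power(10.0, -scan.neg_log10_p)
            fdr = qvalues(pvals)
            pd.DataFrame({
                "marker": scan.table["marker"], "p": pvals, "q": fdr.qvalues,
            }).to_csv(out / f"qvalues_{trait}.tsv", sep="\t", index=False)
            artifacts[f"qvalues_{trait}"] = f"qvalues_{trait}.tsv"
            if config.n_perm > 0:
                null = permutation_null(
                    y, F, n_perm=config.n_perm,
                    seed=_stage_seed(config.seed, 10 + i), model=config.model,
                )
                pd.DataFrame({"max_neg_log10_p": null.max_scores}).to_csv(
                    out / f"permnull_{trait}.tsv", sep="\t", index=False
                )
                artifacts[f"permnull_{trait}"] = f"permnull_{trait}.tsv"
                gw_p = empirical_pvalue(float(scan.neg_log10_p.max()), null)
                perm_rows.append({"trait": trait,
                                  "threshold_95": null.threshold(0.05),
                                  "gw_p_of_max": gw_p})
            called.append(call_qtls(scan, fdr, config.threshold_logp,
                                    config.q_threshold))
        nonempty = [c for c in called if not c.empty]
        if nonempty:
            report_table = pd.concat(nonempty, ignore_index=True)
        elif called:
            report_table = called[0]
        else:
            report_table = pd.DataFrame()

        stage = "report"
        report_path = out / "report.tsv"
        report_table.to_csv(report_path, sep="\t", index=False, na_rep="NA")
        artifacts["report"] = "report.tsv"
        if perm_rows:
            pd.DataFrame(perm_rows).to_csv(out / "permutation_summary.tsv",
                                           sep="\t", index=False)
            artifacts["permutation_summary"] = "permutation_summary.tsv"
        provenance = {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "version": __version__,
            "permutation_null": config.n_perm > 0,
        }
        if config.n_perm == 0:
            provenance["note"] = "no permutation null: threshold-only calls"
        mio.write_manifest(out, artifacts, extra={"provenance": provenance})
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (config {config.content_hash()}): {err}"
        ) from err
    return QTLReport(report_table, provenance)
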