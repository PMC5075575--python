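"""Readers and writers for the package's delimited-text formats.

Conventions: UTF-8 throughout; comma-separated data files with a header
row; tab-separated result files; "NA" as the missing sentinel; genotype
codes 0/1/2 count alternate-allele copies; positions are chromosome-local
cM. Every reader validates structure and names the offending file and
entity in its error messages; read(write(x)) round-trips exactly for all
types.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .gmap import GeneticMap
from .phenosim import QTLSpec
from .simulate import MISSING, FounderSet, GenotypeMatrix, MosaicGenome, HaplotypeTrack

__all__ = [
    "read_map", "write_map",
    "read_founders", "write_founders",
    "read_genotypes", "write_genotypes",
    "read_phenotypes", "write_phenotypes",
    "read_mosaics", "write_mosaics",
    "read_qtl_truth", "write_qtl_truth",
    "write_scan", "write_manifest",
]

logger = logging.getLogger(__name__)

NA = "NA"

#: Trait codes the phenotype reader recognizes without a warning.
KNOWN_TRAITS = {
    "GS39", "GS55", "GS65", "FLS", "PW", "TN", "SH", "TIL", "FEL", "SEL",
    "TEL", "FEW", "OEW", "TEW", "FFLL", "SM", "HI", "d1", "d2", "d3",
}


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: malformed header, missing column(s) {missing}")


# -- map --------------------------------------------------------------------

def write_map(gmap: GeneticMap, path) -> None:
    out = gmap.table.rename(columns={"marker": "marker_id", "chrom": "chrom", "cM": "cM"})
    out.to_csv(path, index=False)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path)
    _require_columns(df, ["marker_id", "chrom", "cM"], path)
    if df["marker_id"].duplicated().any():
        dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ValueError(f"{path}: duplicated marker id {dup!r}")
    return GeneticMap(df.rename(columns={"marker_id": "marker"})
                        .astype({"chrom": str}))


# -- founders ---------------------------------------------------------------

def write_founders(founders: FounderSet, path) -> None:
    df = pd.DataFrame(
        founders.haplotypes.T, columns=list(founders.names),
    )
    df.insert(0, "marker_id", founders.gmap.markers)
    df.to_csv(path, index=False)


def read_founders(path, gmap: GeneticMap) -> FounderSet:
    df = pd.read_csv(path)
    _require_columns(df, ["marker_id"], path)
    if list(df["marker_id"]) != list(gmap.markers):
        raise ValueError(f"{path}: marker order does not match the map")
    names = [c for c in df.columns if c != "marker_id"]
    H = df[names].to_numpy()
    return FounderSet(tuple(names), H.T, gmap)


# -- genotypes --------------------------------------------------------------

def write_genotypes(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.matrix.astype(object), columns=list(geno.gmap.markers))
    df = df.mask(df == MISSING, NA)
    df.insert(0, "line_id", list(geno.line_ids))
    df.to_csv(path, index=False)


def read_genotypes(path, gmap: GeneticMap) -> GenotypeMatrix:
    df = pd.read_csv(path, na_values=[NA])
    _require_columns(df, ["line_id"], path)
    if df["line_id"].duplicated().any():
        dup = df.loc[df["line_id"].duplicated(), "line_id"].iloc[0]
        raise ValueError(f"{path}: duplicated line id {dup!r}")
    markers = [c for c in df.columns if c != "line_id"]
    unknown = sorted(set(markers) - set(gmap.markers))
    if unknown:
        raise ValueError(f"{path}: marker {unknown[0]!r} is absent from the map")
    if len(markers) != gmap.n_markers:
        absent = sorted(set(gmap.markers) - set(markers))
        raise ValueError(f"{path}: mapped marker {absent[0]!r} missing from genotypes")
    G = df[list(gmap.markers)].to_numpy(float)
    G = np.where(np.isnan(G), MISSING, G).astype(np.int8)
    return GenotypeMatrix(tuple(df["line_id"].astype(str)), G, gmap)


# -- phenotypes -------------------------------------------------------------

def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep=NA)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[NA])
    _require_columns(df, ["line_id", "rep"], path)
    unknown = [c for c in df.columns if c not in KNOWN_TRAITS
               and c not in ("line_id", "rep")]
    if unknown:
        logger.warning("%s: unknown trait column(s) %s carried through untouched",
                       path, unknown)
    return df


# -- mosaics (truth) --------------------------------------------------------

def write_mosaics(mosaics: list[MosaicGenome], line_ids: list[str], path) -> None:
    parts = [m.segment_table(lid) for m, lid in zip(mosaics, line_ids)]
    pd.concat(parts, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_mosaics(path) -> tuple[list[MosaicGenome], list[str]]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["chrom", "start_cM", "end_cM", "founder", "homolog",
                          "line_id"], path)
    mosaics, ids = [], []
    for lid, sub in df.groupby("line_id", sort=False):
        tracks = {}
        for chrom, csub in sub.groupby("chrom", sort=False):
            pair = []
            for h in (0, 1):
                t = csub[csub["homolog"] == h].sort_values("start_cM")
                pair.append(HaplotypeTrack(
                    float(t["start_cM"].iloc[0]),
                    t["end_cM"].to_numpy(float),
                    t["founder"].to_numpy(int),
                ))
            tracks[str(chrom)] = (pair[0], pair[1])
        mosaics.append(MosaicGenome(tracks))
        ids.append(str(lid))
    return mosaics, ids


# -- QTL truth --------------------------------------------------------------

def write_qtl_truth(qtls: list[QTLSpec], founder_names: tuple[str, ...], path) -> None:
    rows = []
    for q in qtls:
        row = {"trait": q.trait, "marker_id": q.marker_id, "h2_locus": q.h2_locus}
        row.update({f"mean_{n}": v for n, v in zip(founder_names, q.founder_means)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_qtl_truth(path) -> list[QTLSpec]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["trait", "marker_id", "h2_locus"], path)
    mean_cols = [c for c in df.columns if c.startswith("mean_")]
    return [
        QTLSpec(
            trait=str(r["trait"]), marker_id=str(r["marker_id"]),
            founder_means=np.array([r[c] for c in mean_cols], float),
            h2_locus=float(r["h2_locus"]),
        )
        for _, r in df.iterrows()
    ]


# -- results ----------------------------------------------------------------

def write_scan(scan, path) -> None:
    """Scan TSV with the conventional report layout.

    Columns: Phenotype, Marker, Chr, cM, -logP, h2, then one column per
    founder effect.
    """
    t = scan.table
    out = pd.DataFrame({
        "Phenotype": scan.trait, "Marker": t["marker"], "Chr": t["chrom"],
        "cM": t["cM"], "-logP": t["neg_log10_p"], "h2": t["var_explained"],
    })
    for c in t.columns:
        if c.startswith("effect_"):
            out[c.removeprefix("effect_")] = t[c]
    out.to_csv(path, sep="\t", index=False, na_rep=NA)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, entries: dict[str, str], extra: dict | None = None) -> Path:
    """JSON manifest with SHA-256 of every artifact (no timestamps, so
    identical runs produce identical manifests)."""
    out_dir = Path(out_dir)
    manifest = {
        "artifacts": {
            name: {"path": str(rel), "sha256": sha256_of(out_dir / rel)}
            for name, rel in entries.items()
        },
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
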