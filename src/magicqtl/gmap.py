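"""Genetic maps in centimorgan coordinates.

Positions are chromosome-local cM floats; marker order within a chromosome
follows map position. This is the only positional system in the package
(no base-pair coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "demo_map", "wheat_like_map"]


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map: one row per marker with chromosome and cM position.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``marker``, ``chrom``, ``cM``. Markers must be unique and
        sorted by position within each chromosome (chromosomes keep their
        first-appearance order). At least two markers per chromosome.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "chrom", "cM"}
        if not required.issubset(t.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicated marker id: {dup!r}")
        for chrom, sub in t.groupby("chrom", sort=False):
            pos = sub["cM"].to_numpy(float)
            if len(pos) < 2:
                raise ValueError(f"chromosome {chrom!r} has fewer than 2 markers")
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not sorted on chromosome {chrom!r}")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    # -- basic accessors ----------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def markers(self) -> np.ndarray:
        return self.table["marker"].to_numpy()

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def positions(self, chrom: str) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "cM"].to_numpy(float)

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous row slice of `table` covered by one chromosome."""
        idx = np.flatnonzero((self.table["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def chrom_span(self, chrom: str) -> tuple[float, float]:
        pos = self.positions(chrom)
        return float(pos[0]), float(pos[-1])

    def index_of(self, marker: str) -> int:
        hits = np.flatnonzero(self.table["marker"].to_numpy() == marker)
        if hits.size == 0:
            raise KeyError(f"marker {marker!r} not in map")
        return int(hits[0])

    def locus(self, marker: str) -> tuple[str, float]:
        i = self.index_of(marker)
        row = self.table.iloc[i]
        return str(row["chrom"]), float(row["cM"])

    def __len__(self) -> int:
        return self.n_markers

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneticMap) and self.table.equals(other.table)


def _grid_chrom(chrom: str, start: float, end: float, n: int,
                named: dict[str, float] | None = None) -> pd.DataFrame:
    """Evenly spaced markers on [start, end] with optional named insertions."""
    pos = list(np.linspace(start, end, n))
    marker = [f"{chrom}_m{i:03d}" for i in range(n)]
    if named:
        for mid, p in named.items():
            pos.append(p)
            marker.append(mid)
    order = np.argsort(pos, kind="stable")
    return pd.DataFrame(
        {"marker": np.asarray(marker, object)[order],
         "chrom": chrom,
         "cM": np.asarray(pos, float)[order]}
    )


#: Published positions of the mapped QTL peak markers used as planting sites.
TABLE2_MARKERS: dict[str, tuple[str, float]] = {
    "BS00009369_51": ("5A", 201.36),
    "BS00021942_51": ("5A", 212.52),
    "wsnp_Ex_c37943_45584325": ("5A", 216.05),
    "wsnp_Ex_c5978_10478584": ("5A", 224.64),
    "Excalibur_c7729_144": ("5A", 227.66),
    "RAC875_c6922_291": ("4D", 26.97),
    "RAC875_c1673_193": ("4D", 32.24),
    "wsnp_Ex_c6548_11355524": ("5B", 60.65),
    "BS00001101_51": ("5B", 66.38),
    "wsnp_Ku_c2185_4218722": ("5B", 90.8),
    "RAC875_c19099_434": ("5B", 92.31),
}


def demo_map(markers_per_chrom: int = 100) -> GeneticMap:
    """Desk-scale three-chromosome map (5A, 4D, 5B) at ~1 marker/cM.

    Each chromosome spans 100 cM and additionally carries the named QTL
    peak markers at their published positions, so simulations can plant
    effects at those exact loci.
    """
    named: dict[str, dict[str, float]] = {"5A": {}, "4D": {}, "5B": {}}
    for mid, (chrom, pos) in TABLE2_MARKERS.items():
        named[chrom][mid] = pos
    parts = [
        _grid_chrom("5A", 151.0, 251.0, markers_per_chrom, named["5A"]),
        _grid_chrom("4D", 0.0, 100.0, markers_per_chrom, named["4D"]),
        _grid_chrom("5B", 0.0, 100.0, markers_per_chrom, named["5B"]),
    ]
    return GeneticMap(pd.concat(parts, ignore_index=True))


def wheat_like_map(markers_per_chrom: int = 15, chrom_length: float = 100.0) -> GeneticMap:
    """Sparse 21-chromosome map with hexaploid-wheat chromosome names.

    Intended for genome-wide statistics (e.g. the kinship structure check)
    where the number of independently segregating segments, not marker
    density, is what matters.
    """
    chroms = [f"{n}{g}" for n in range(1, 8) for g in "ABD"]
    parts = [_grid_chrom(c, 0.0, chrom_length, markers_per_chrom) for c in chroms]
    return GeneticMap(pd.concat(parts, ignore_index=True))
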