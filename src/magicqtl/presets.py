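"""Published QTL rows of the NIAB MAGIC phenology screen.

Each entry gives, for one trait x peak-marker pair: chromosome, map
position (cM), the scan score (-log10 P), the locus variance fraction h2,
and the eight founder trait-mean predictions in the canonical founder
order (Alchemy, Brompton, Claire, Hereward, Rialto, Robigus, Soissons,
Xi-19). Growth stages and FLS are in days after sowing; heights/lengths
in cm; weights in g; HI is a ratio.

These rows serve as planting inputs for parameter-recovery simulations:
a simulated population plants a row's founder means and h2 at its marker,
and the inference pipeline should recover them.
"""

from __future__ import annotations

from .phenosim import QTLSpec

__all__ = ["QTL_ROWS", "qtl_spec", "founder_mean"]

#: (trait, marker) -> (chrom, cM, neg_log10_p, h2, founder_means)
QTL_ROWS: dict[tuple[str, str], tuple[str, float, float, float, tuple[float, ...]]] = {
    ("GS39", "BS00009369_51"): ("5A", 201.36, 8.04, 0.35,
        (127.34, 127.15, 125.21, 128.42, 128.01, 125.13, 127.07, 111.46)),
    ("GS39", "BS00021942_51"): ("5A", 212.52, 4.44, 0.24,
        (126.75, 127.32, 125.39, 127.76, 129.01, 125.5, 126.79, 116.98)),
    ("GS39", "wsnp_Ex_c5978_10478584"): ("5A", 224.64, 9.14, 0.38,
        (126.54, 127.01, 126.27, 127.48, 128.24, 125.8, 126.92, 112.83)),
    ("GS55", "BS00009369_51"): ("5A", 201.36, 7.13, 0.33,
        (136.79, 135.89, 134.09, 138.57, 136.96, 134.49, 136.99, 119.18)),
    ("GS55", "wsnp_Ex_c37943_45584325"): ("5A", 216.05, 4.64, 0.25,
        (135.3, 135.57, 134.37, 138.38, 137.99, 134.57, 136.39, 127.6)),
    ("GS55", "Excalibur_c7729_144"): ("5A", 227.66, 8.32, 0.36,
        (135.6, 135.43, 135.9, 137.54, 137.82, 135.01, 136.59, 120.31)),
    ("HI", "Kukri_c27309_590"): ("2D", 55.4, 4.97, 0.01,
        (0.55, 0.55, 0.55, 0.55, 0.55, 0.55, 0.6, 0.55)),
    ("OEW", "RAC875_c6922_291"): ("4D", 26.97, 4.09, 0.21,
        (37.4, 37.14, 37.17, 36.3, 36.81, 42.6, 39.2, 35.57)),
    ("PW", "RAC875_c1673_193"): ("4D", 32.24, 4.79, 0.24,
        (70.96, 71.2, 71.48, 71.33, 68.74, 88.5, 82.52, 71.26)),
    ("SEL", "wsnp_Ex_c6548_11355524"): ("5B", 60.65, 3.99, 0.22,
        (11.2, 11.18, 11.21, 11.18, 11.16, 11.18, 10.45, 10.02)),
    ("SEL", "BS00001101_51"): ("5B", 66.38, 4.01, 0.22,
        (11.12, 11.19, 11.19, 11.13, 11.17, 11.33, 10.36, 10.0)),
    ("SEL", "wsnp_Ku_c2185_4218722"): ("5B", 90.8, 4.15, 0.23,
        (11.08, 11.16, 11.1, 11.08, 11.14, 11.48, 10.36, 10.2)),
    ("SEL", "RAC875_c19099_434"): ("5B", 92.31, 3.97, 0.22,
        (11.05, 11.12, 11.05, 11.1, 11.02, 11.27, 10.49, 10.3)),
    ("SH", "RAC875_c1673_193"): ("4D", 32.24, 9.52, 0.38,
        (49.88, 51.63, 49.92, 50.13, 49.98, 63.89, 60.82, 47.34)),
    ("TEW", "RAC875_c6922_291"): ("4D", 26.97, 4.02, 0.085,
        (41.14, 40.41, 40.93, 40.15, 40.66, 46.71, 43.58, 39.47)),
    ("TIL", "RAC875_c1673_193"): ("4D", 32.24, 7.09, 0.31,
        (27.78, 28.2, 27.8, 27.59, 27.64, 32.11, 32.4, 26.25)),
}

#: Canonical founder order of the mean columns above.
FOUNDER_ORDER: tuple[str, ...] = (
    "Alchemy", "Brompton", "Claire", "Hereward",
    "Rialto", "Robigus", "Soissons", "Xi-19",
)


def qtl_spec(trait: str, marker: str) -> QTLSpec:
    """Build a planting spec from a published trait x marker row."""
    try:
        _, _, _, h2, means = QTL_ROWS[(trait, marker)]
    except KeyError:
        raise KeyError(f"no published QTL row for ({trait!r}, {marker!r})") from None
    return QTLSpec(trait=trait, marker_id=marker, founder_means=means, h2_locus=h2)


def founder_mean(trait: str, marker: str, founder: str) -> float:
    """Published founder-mean prediction for one founder at one QTL row."""
    means = QTL_ROWS[(trait, marker)][4]
    return means[FOUNDER_ORDER.index(founder)]
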