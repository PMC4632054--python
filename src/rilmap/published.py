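"""Published summary statistics of the two pepper RIL maps.

The printed per-linkage-group statistics of the interspecific FA map
(C. frutescens BG2814-6 x C. annuum 'NuMex RNaky', 119 F7:F8 RILs) and the
intraspecific NM map (C. annuum 'Early Jalapeno' x 'CM334', 63 F6:F7 RILs),
together with the SPP-detection and genome-anchoring totals. These are
inputs for the arithmetic summary functions below and for cross-checking a
reconstruction of the pipeline; they are not recomputable without the
original array data.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "map_table",
    "detection_totals",
    "genome_totals",
    "mean_bin_interval",
    "mean_spps_per_unigene",
    "mapped_fraction",
    "length_difference",
    "nonrecombining_percent",
]

_LG = ["P1", "P2", "P3", "P4", "P5", "P6",
       "P7", "P8", "P9", "P10", "P11", "P12"]

_FA = {
    "bins": [303, 183, 244, 186, 151, 197, 155, 62, 148, 166, 135, 176],
    "markers": [3137, 1701, 2044, 1229, 968, 1435, 1226, 242, 986, 1078,
                1001, 1120],
    "size_cM": [199, 106, 145, 132, 99, 136, 107, 52, 116, 101, 91, 96],
}

_NM = {
    "bins": [97, 63, 75, 55, 52, 70, 49, 66, 63, 71, 62, 60],
    "markers": [451, 407, 416, 245, 246, 283, 143, 260, 527, 310, 363, 227],
    "size_cM": [177, 95, 120, 114, 93, 138, 115, 98, 100, 128, 98, 123],
}

# SPP detection and mapping totals
DETECTION = {
    "NM": {"n_spps": 39515, "n_unigenes": 5587, "n_rils": 63,
           "n_mapped_markers": 3876},
    "FA": {"n_spps": 173149, "n_unigenes": 16780, "n_rils": 119,
           "n_mapped_markers": 16154},
}

# physical-genome totals (Gb): assembled chromosome length and the portion
# classified nonrecombining from the FA-anchored rate landscape
GENOME = {"assembled_Gb": 3.02, "nonrecombining_Gb": 1.39}


def map_table(population: str) -> pd.DataFrame:
    """Per-linkage-group bins/markers/length for ``"FA"`` or ``"NM"``."""
    data = {"FA": _FA, "NM": _NM}[population]
    return pd.DataFrame(data, index=pd.Index(_LG, name="linkage_group"))


def detection_totals(population: str) -> dict:
    return dict(DETECTION[population])


def genome_totals() -> dict:
    return dict(GENOME)


def mean_bin_interval(table: pd.DataFrame) -> float:
    """Mean interval between genetic bins: total length / total bins (cM)."""
    return float(table["size_cM"].sum() / table["bins"].sum())


def mean_spps_per_unigene(population: str) -> float:
    d = DETECTION[population]
    return d["n_spps"] / d["n_unigenes"]


def mapped_fraction(population: str) -> float:
    """Fraction of polymorphic unigenes assigned to genetic bins."""
    d = DETECTION[population]
    return d["n_mapped_markers"] / d["n_unigenes"]


def length_difference(table_a: pd.DataFrame, table_b: pd.DataFrame) -> dict:
    """Total-length delta between two maps, absolute and percent of the longer."""
    la = float(table_a["size_cM"].sum())
    lb = float(table_b["size_cM"].sum())
    delta = abs(la - lb)
    return {"length_a": la, "length_b": lb, "delta_cM": delta,
            "delta_percent": 100.0 * delta / max(la, lb)}


def nonrecombining_percent() -> float:
    return 100.0 * GENOME["nonrecombining_Gb"] / GENOME["assembled_Gb"]
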