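"""Readers and writers for the pipeline's TSV dialects.

All formats are header-first TSV. Genetic positions serialize as decimal cM
with two decimals; physical positions are base pairs internally and Mb in
reports. Readers validate hard (unknown call symbols, duplicate marker ids,
ragged rows, decreasing cM within a linkage group) and report the offending
line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binmap import GeneticMap, HetRegion
from .synteny import HIT_COLUMNS

__all__ = [
    "read_marker_matrix", "write_marker_matrix",
    "read_spp_table", "write_spp_table",
    "read_map", "write_map",
    "write_het_regions", "read_het_regions",
    "read_hits", "write_hits",
    "read_intensities", "write_intensities",
    "write_truth", "read_truth",
    "write_heat_matrix",
]

_VALID_CALLS = {"A", "B", "H", "-"}


def _read_tsv(path) -> list[list[str]]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    rows = [ln.split("\t") for ln in lines]
    width = len(rows[0])
    for ln_no, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(f"{path}: ragged row at line {ln_no} "
                             f"({len(row)} fields, expected {width})")
    return rows


def read_marker_matrix(path) -> pd.DataFrame:
    """Marker call matrix: header ``marker`` + line ids; calls in {A,B,H,-}."""
    rows = _read_tsv(path)
    header = rows[0]
    if header[0] != "marker":
        raise ValueError(f"{path}: first column must be 'marker'")
    lines = header[1:]
    seen = set()
    index, data = [], []
    for ln_no, row in enumerate(rows[1:], start=2):
        mid = row[0]
        if mid in seen:
            raise ValueError(f"{path}: duplicate marker id {mid!r} at line {ln_no}")
        seen.add(mid)
        for call in row[1:]:
            if call not in _VALID_CALLS:
                raise ValueError(
                    f"{path}: unknown call symbol {call!r} at line {ln_no}")
        index.append(mid)
        data.append(row[1:])
    df = pd.DataFrame(data, index=pd.Index(index, name="marker"), columns=lines)
    return df


def write_marker_matrix(matrix: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for mid, row in matrix.iterrows():
            fh.write(str(mid) + "\t" + "\t".join(row.astype(str)) + "\n")


def write_spp_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_spp_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"unigene": str})
    required = {"unigene", "start", "end", "avg_sppdev", "n_valid_probes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: SPP table missing columns {sorted(missing)}")
    return df


def write_map(gmap: GeneticMap, path) -> None:
    df = gmap.to_frame()
    df["cM"] = df["cM"].map(lambda v: f"{v:.2f}")
    df.to_csv(path, sep="\t", index=False)


def read_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"marker", "linkage_group", "cM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: map missing columns {sorted(missing)}")
    for lg, sub in df.groupby("linkage_group"):
        cms = sub["cM"].to_numpy(dtype=float)
        if np.any(np.diff(cms) < -1e-9):
            bad = int(np.argmax(np.diff(cms) < -1e-9))
            raise ValueError(
                f"{path}: cM decreasing within {lg} near line "
                f"{sub.index[bad + 1] + 2}")
    return df


def write_het_regions(regions: list[HetRegion], path) -> None:
    with open(path, "w") as fh:
        fh.write("ril\tlinkage_group\tstart_cM\tend_cM\tn_missing"
                 "\tn_double_crossovers\n")
        for r in regions:
            fh.write(f"{r.ril_id}\t{r.linkage_group}\t{r.start_cM:.2f}"
                     f"\t{r.end_cM:.2f}\t{r.n_missing}"
                     f"\t{r.n_double_crossovers}\n")


def read_het_regions(path) -> list[HetRegion]:
    df = pd.read_csv(path, sep="\t")
    return [HetRegion(row["ril"], row["linkage_group"],
                      float(row["start_cM"]), float(row["end_cM"]),
                      int(row["n_missing"]), int(row["n_double_crossovers"]))
            for _, row in df.iterrows()]


def read_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: hit table missing columns {missing}")
    return df


def write_hits(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def write_intensities(intensities: pd.DataFrame, path) -> None:
    """Intensity TSV: rows keyed ``unigene:start:end``, columns ``sample:rep``."""
    flat = intensities.copy()
    flat.index = [f"{u}:{s}:{e}" for u, s, e in intensities.index]
    flat.columns = [f"{s}:{r}" for s, r in intensities.columns]
    flat.to_csv(path, sep="\t", index_label="probe", float_format="%.5f")


def read_intensities(path) -> pd.DataFrame:
    flat = pd.read_csv(path, sep="\t", index_col="probe")
    idx = pd.MultiIndex.from_tuples(
        [(u, int(s), int(e)) for u, s, e in
         (k.rsplit(":", 2) for k in flat.index)],
        names=["unigene", "probe_start", "probe_end"])
    cols = pd.MultiIndex.from_tuples(
        [(s, int(r)) for s, r in (c.rsplit(":", 1) for c in flat.columns)],
        names=["sample", "replicate"])
    flat.index, flat.columns = idx, cols
    return flat


def write_truth(truth, path) -> None:
    doc = {
        "true_order": {str(c): [[m, round(p, 4)] for m, p in lst]
                       for c, lst in truth.true_order.items()},
        "het_regions": [[r, c, round(a, 4), round(b, 4)]
                        for r, c, a, b in truth.het_regions],
        "breakpoint": list(truth.breakpoint) if truth.breakpoint else None,
        "monomorphic": truth.monomorphic,
        "marker_Mb": {m: round(v, 6) for m, v in truth.marker_Mb.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_heat_matrix(recomb, ordered_markers: list[str], path) -> None:
    """Square r-hat matrix in the given order (CheckMatrix-style heat table)."""
    sub = recomb.submatrix(ordered_markers)
    df = pd.DataFrame(sub.r_hat, index=ordered_markers, columns=ordered_markers)
    df.to_csv(path, sep="\t", index_label="marker", float_format="%.4f")
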