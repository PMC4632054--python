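"""Genome anchoring: alignment-hit filtering and map-genome concordance.

Mapped unigenes are anchored on a genome assembly by filtering spliced
alignment hit tables. Same-species anchoring keeps hits at >= 98% identity,
>= 200 aligned nt and <= 50 unaligned nt at either end, then requires the
top-scoring hit to be unique (equal-score ties are ambiguous and dropped).
Cross-species anchoring keeps hits at >= 80% identity, >= 75% coverage and
>= 200 nt, and retains the hit that simultaneously maximizes identity and
coverage; when no hit Pareto-dominates, the unigene is excluded.

Hit tables are TSV with 1-based inclusive coordinates and columns: unigene,
chrom, start, end, strand, identity, aligned_length, q_unaligned_left,
q_unaligned_right, coverage, score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "filter_same_species",
    "filter_cross_species",
    "map_genome_concordance",
]

HIT_COLUMNS = ["unigene", "chrom", "start", "end", "strand", "identity",
               "aligned_length", "q_unaligned_left", "q_unaligned_right",
               "coverage", "score"]


def _validate(hits: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    if (hits["start"] > hits["end"]).any():
        raise ValueError("hit with start > end")
    return hits


def filter_same_species(
    hits: pd.DataFrame,
    min_identity: float = 98.0,
    min_length: int = 200,
    max_unaligned_end: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unique same-species anchors plus a dropped/ambiguous report.

    Applies the identity/length/end-overhang thresholds (the overhang cap is
    per end: the larger of the two unaligned ends must not exceed it), then
    keeps a unigene only if its top score after filtering is unique;
    equal-score ties make the position ambiguous and drop the unigene.
    """
    hits = _validate(hits)
    unaligned = hits[["q_unaligned_left", "q_unaligned_right"]].max(axis=1)
    ok = ((hits["identity"] >= min_identity)
          & (hits["aligned_length"] >= min_length)
          & (unaligned <= max_unaligned_end))
    passed = hits[ok]
    dropped_rows = []
    anchors = []
    for ug in hits["unigene"].unique():
        sub = passed[passed["unigene"] == ug]
        if len(sub) == 0:
            dropped_rows.append({"unigene": ug, "reason": "no_passing_hit"})
            continue
        top = sub["score"].max()
        best = sub[sub["score"] == top]
        if len(best) > 1:
            dropped_rows.append({"unigene": ug, "reason": "ambiguous_equal_score"})
            continue
        anchors.append(best.iloc[0])
    anchors_df = (pd.DataFrame(anchors).reset_index(drop=True)
                  if anchors else pd.DataFrame(columns=HIT_COLUMNS))
    return anchors_df, pd.DataFrame(dropped_rows,
                                    columns=["unigene", "reason"])


def filter_cross_species(
    hits: pd.DataFrame,
    min_identity: float = 80.0,
    min_coverage: float = 0.75,
    min_length: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unique cross-species anchors plus a dropped report.

    After thresholding, a unigene is anchored at the hit that maximizes both
    identity and coverage simultaneously; if no single hit dominates, the
    unigene is excluded. The retained hit is therefore never
    Pareto-dominated by a dropped hit of the same unigene.
    """
    hits = _validate(hits)
    ok = ((hits["identity"] >= min_identity)
          & (hits["coverage"] >= min_coverage)
          & (hits["aligned_length"] >= min_length))
    passed = hits[ok]
    dropped_rows = []
    anchors = []
    for ug in hits["unigene"].unique():
        sub = passed[passed["unigene"] == ug]
        if len(sub) == 0:
            dropped_rows.append({"unigene": ug, "reason": "no_passing_hit"})
            continue
        best_ident = sub["identity"].max()
        best_cov = sub["coverage"].max()
        dom = sub[(sub["identity"] == best_ident) & (sub["coverage"] == best_cov)]
        if len(dom) == 0:
            dropped_rows.append({"unigene": ug, "reason": "no_dominating_hit"})
            continue
        if len(dom) > 1:
            dropped_rows.append({"unigene": ug, "reason": "ambiguous_equal_hit"})
            continue
        anchors.append(dom.iloc[0])
    anchors_df = (pd.DataFrame(anchors).reset_index(drop=True)
                  if anchors else pd.DataFrame(columns=HIT_COLUMNS))
    return anchors_df, pd.DataFrame(dropped_rows,
                                    columns=["unigene", "reason"])


@dataclass
class ConcordanceResult:
    contingency: pd.DataFrame  # LG x chromosome anchor counts
    dominant_pairing: dict[str, str]
    dot_plot: pd.DataFrame  # per anchor: marker, lg, cM, chrom, Mb
    candidate_translocations: list[dict]
    scaffold_assignments: pd.DataFrame


def map_genome_concordance(
    gmap_frame: pd.DataFrame,
    anchors: pd.DataFrame,
    min_markers: int = 5,
    max_gap_cM: float = 5.0,
    max_gap_Mb: float = 5.0,
    scaffold_window_cM: float = 5.0,
    bp_per_unit: float = 1e6,
) -> ConcordanceResult:
    """Cross-tabulate linkage groups against chromosomes and find outliers.

    ``gmap_frame`` has columns marker/linkage_group/cM; ``anchors`` is a
    filtered hit table. Off-diagonal clusters of at least ``min_markers``
    anchors from one map interval onto one foreign chromosome interval
    (split at gaps above ``max_gap_cM``/``max_gap_Mb``) are reported as
    candidate translocations. Anchors on unplaced scaffolds (chromosome
    names not dominant for any group) with >= 2 mapped markers within
    ``scaffold_window_cM`` assign the scaffold a linkage group and position.
    """
    placed = gmap_frame.set_index("marker")
    merged = anchors.join(placed, on="unigene", how="inner")
    merged = merged.assign(Mb=(merged["start"] + merged["end"]) / 2.0 / bp_per_unit)

    contingency = pd.crosstab(merged["linkage_group"], merged["chrom"])
    dominant = {lg: contingency.loc[lg].idxmax() for lg in contingency.index}

    dot = merged[["unigene", "linkage_group", "cM", "chrom", "Mb"]].copy()

    candidates = []
    for lg in contingency.index:
        sub = merged[merged["linkage_group"] == lg]
        for chrom in sub["chrom"].unique():
            if chrom == dominant[lg]:
                continue
            off = sub[sub["chrom"] == chrom].sort_values("cM")
            if len(off) < min_markers:
                continue
            # split into clusters at large gaps in either coordinate
            gap = ((off["cM"].diff() > max_gap_cM)
                   | (off["Mb"].diff() > max_gap_Mb)).fillna(False)
            for _, cluster in off.groupby(gap.cumsum()):
                if len(cluster) >= min_markers:
                    candidates.append({
                        "linkage_group": lg,
                        "chrom": chrom,
                        "n_markers": int(len(cluster)),
                        "cM_start": float(cluster["cM"].min()),
                        "cM_end": float(cluster["cM"].max()),
                        "Mb_start": float(cluster["Mb"].min()),
                        "Mb_end": float(cluster["Mb"].max()),
                    })

    dominant_chroms = set(dominant.values())
    scaffold_rows = []
    for chrom in merged["chrom"].unique():
        if chrom in dominant_chroms:
            continue
        sub = merged[merged["chrom"] == chrom]
        for lg, lg_sub in sub.groupby("linkage_group"):
            if len(lg_sub) >= 2 and \
                    lg_sub["cM"].max() - lg_sub["cM"].min() <= scaffold_window_cM:
                scaffold_rows.append({
                    "scaffold": chrom,
                    "linkage_group": lg,
                    "cM": float(lg_sub["cM"].mean()),
                    "n_markers": int(len(lg_sub)),
                })
    scaffolds = pd.DataFrame(
        scaffold_rows, columns=["scaffold", "linkage_group", "cM", "n_markers"])
    return ConcordanceResult(
        contingency=contingency,
        dominant_pairing=dominant,
        dot_plot=dot,
        candidate_translocations=candidates,
        scaffold_assignments=scaffolds,
    )
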