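"""Consensus unigene haplotype markers from per-unigene SPP calls.

Multiple SPPs detected within one unigene should carry the same segregation
pattern; they are collapsed into a single consensus marker by per-line
majority vote. When the SPP call vectors are discordant beyond a threshold
— e.g., the unigene's probes cross-hybridize with a paralog segregating
elsewhere — the SPPs are partitioned into the two most internally
concordant groups (2-medoid partition on pairwise call mismatch distance)
and each group emits its own marker, suffixed ``.1``/``.2``.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

__all__ = [
    "mismatch_distance",
    "consensus_haplotype",
    "consensus_markers",
    "marker_stats",
]


def mismatch_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of lines where two call vectors are both non-missing and differ."""
    both = (a != "-") & (b != "-")
    n = int(both.sum())
    return float((a[both] != b[both]).sum() / n) if n else 0.0


def _majority(calls: np.ndarray) -> np.ndarray:
    """Per-line majority call (> 50% of non-missing member calls, else missing)."""
    n_a = (calls == "A").sum(axis=0)
    n_b = (calls == "B").sum(axis=0)
    out = np.full(calls.shape[1], "-", dtype="U1")
    out[n_a > n_b] = "A"
    out[n_b > n_a] = "B"
    return out


def consensus_haplotype(
    spp_calls: pd.DataFrame,
    split_threshold: float = 0.2,
) -> list[tuple[np.ndarray, list]]:
    """Collapse the SPPs of one unigene into one or two consensus markers.

    ``spp_calls``: rows = SPPs of the unigene, columns = lines, values in
    {A,B,-}. If every pairwise mismatch distance is at most
    ``split_threshold`` a single majority consensus is returned. Otherwise
    the SPPs are split by an exhaustive 2-medoid partition (assign each SPP
    to the nearer medoid, over all medoid pairs, minimizing total
    within-group distance); an exact tie between the best split and no-split
    keeps the single consensus. Returns ``[(consensus calls, member SPP
    labels), ...]`` with one or two entries.
    """
    vals = spp_calls.to_numpy(dtype="U1")
    labels = list(spp_calls.index)
    n = vals.shape[0]
    if n == 1:
        return [(vals[0].copy(), labels)]
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = mismatch_distance(vals[i], vals[j])
    if D.max() <= split_threshold:
        return [(_majority(vals), labels)]
    best = None
    for i, j in itertools.combinations(range(n), 2):
        assign = D[i] <= D[j]  # ties go to the first medoid
        assign[i], assign[j] = True, False
        cost = D[i][assign].sum() + D[j][~assign].sum()
        if best is None or cost < best[0]:
            best = (cost, assign)
    _, assign = best
    if assign.all() or not assign.any():
        return [(_majority(vals), labels)]
    g1 = [k for k in range(n) if assign[k]]
    g2 = [k for k in range(n) if not assign[k]]
    return [(_majority(vals[g1]), [labels[k] for k in g1]),
            (_majority(vals[g2]), [labels[k] for k in g2])]


def consensus_markers(
    spp_table: pd.DataFrame,
    call_columns: list[str],
    split_threshold: float = 0.2,
) -> tuple[pd.DataFrame, dict[str, list]]:
    """Build the marker matrix from an SPP table.

    ``spp_table`` needs a ``unigene`` column plus one call column per line
    (``call_columns``). Returns (markers x lines call matrix, provenance
    mapping marker id -> member SPP row labels). Split unigenes get ``.1`` /
    ``.2`` suffixes; at most two markers per unigene.
    """
    rows, prov = {}, {}
    for ug, grp in spp_table.groupby("unigene", sort=True):
        res = consensus_haplotype(grp[call_columns], split_threshold)
        if len(res) == 1:
            rows[str(ug)] = res[0][0]
            prov[str(ug)] = res[0][1]
        else:
            for k, (calls, members) in enumerate(res, start=1):
                rows[f"{ug}.{k}"] = calls
                prov[f"{ug}.{k}"] = members
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=call_columns)
    mat.index.name = "marker"
    return mat, prov


def marker_stats(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-marker missing fraction and A-allele frequency (over non-missing)."""
    vals = matrix.to_numpy(dtype="U1")
    n = vals.shape[1]
    n_miss = (vals == "-").sum(axis=1)
    n_a = (vals == "A").sum(axis=1)
    n_b = (vals == "B").sum(axis=1)
    nonmiss = n_a + n_b + (vals == "H").sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_a + n_b > 0, n_a / np.maximum(n_a + n_b, 1), np.nan)
    return pd.DataFrame({
        "missing_fraction": n_miss / n,
        "n_A": n_a,
        "n_B": n_b,
        "allele_freq_A": freq,
        "n_nonmissing": nonmiss,
    }, index=matrix.index)
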