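"""Map-level statistics: segregation distortion, collinearity, comparison,
and recombination-rate landscapes.

Segregation distortion is tested per genetic bin with a χ² goodness-of-fit
test against the 1:1 Mendelian expectation of a RIL population (df = 1, no
continuity correction); contiguous significant bins merge into skewed
regions. Collinearity between two maps is the coefficient of determination
R² of a linear fit between the rank orders of their common markers, with
within-bin ties broken by the other map's order. Recombination-rate
landscapes come from a Gaussian-kernel smooth of genetic (cM) against
physical (Mb) position, monotonized by isotonic regression (a genetic map is
monotone in physical order by construction), differentiated on an even
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "DistortionRecord",
    "distortion_scan",
    "CollinearityResult",
    "collinearity",
    "compare_maps",
    "RateProfile",
    "rate_profile",
    "nonrecombining_fraction",
]


# ---------------------------------------------------------------------------
# Segregation distortion


@dataclass
class DistortionRecord:
    bin_id: str
    lg: str
    cM: float
    n_A: int
    n_B: int
    chi2: float
    p_value: float
    skew_direction: str  # "A", "B", or ""


def chi2_1to1(n_a: int, n_b: int) -> tuple[float, float]:
    """χ² goodness of fit against 1:1, df=1, no continuity correction."""
    n = n_a + n_b
    e = n / 2.0
    chi2 = (n_a - e) ** 2 / e + (n_b - e) ** 2 / e
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def distortion_scan(
    gmap,
    matrix: pd.DataFrame,
    alpha: float = 0.01,
) -> tuple[list[DistortionRecord], list[dict]]:
    """Scan every genetic bin for segregation distortion.

    Counts A and B calls of each bin's representative marker (H and missing
    excluded); bins with p < ``alpha`` are flagged and contiguous flagged
    bins with the same direction merge into skewed regions. Bins with no
    scorable calls are skipped.
    """
    records: list[DistortionRecord] = []
    regions: list[dict] = []
    for lg, bins in gmap.groups.items():
        lg_records = []
        for b in bins:
            calls = matrix.loc[b.representative].to_numpy(dtype="U1")
            n_a = int((calls == "A").sum())
            n_b = int((calls == "B").sum())
            if n_a + n_b == 0:
                continue
            chi2, p = chi2_1to1(n_a, n_b)
            direction = "A" if n_a > n_b else ("B" if n_b > n_a else "")
            lg_records.append(DistortionRecord(
                bin_id=b.bin_id, lg=lg, cM=b.cM, n_A=n_a, n_B=n_b,
                chi2=chi2, p_value=p, skew_direction=direction))
        records.extend(lg_records)
        run: list[DistortionRecord] = []
        for rec in lg_records + [None]:
            flagged = rec is not None and rec.p_value < alpha
            if flagged and (not run or rec.skew_direction == run[0].skew_direction):
                run.append(rec)
            else:
                if run:
                    regions.append({
                        "lg": lg,
                        "start_cM": run[0].cM,
                        "end_cM": run[-1].cM,
                        "direction": run[0].skew_direction,
                        "n_bins": len(run),
                    })
                run = [rec] if flagged else []
    return records, regions


# ---------------------------------------------------------------------------
# Collinearity


@dataclass
class CollinearityResult:
    lg_pair: tuple[str, str]
    n_common: int
    r_squared: float | None


def _tie_broken_ranks(pos_self: pd.Series, pos_other: pd.Series) -> np.ndarray:
    """Ranks by own position; ties (same bin) broken by the other map's order."""
    df = pd.DataFrame({"a": pos_self, "b": pos_other})
    order = df.sort_values(["a", "b"], kind="stable").index
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order)
    return ranks.reindex(pos_self.index).to_numpy(dtype=float)


def collinearity(
    map_a: pd.DataFrame,
    map_b: pd.DataFrame,
) -> tuple[list[CollinearityResult], dict]:
    """Rank-order collinearity between two maps.

    Each map is a frame with columns ``marker``, ``linkage_group``, ``cM``.
    For every matched linkage-group pair the common markers are ranked by
    position in each map (within-bin ties broken by the other map's order)
    and R² of the linear rank-vs-rank fit is reported; group pairs with
    fewer than two common markers get ``r_squared=None``. Markers whose two
    maps disagree on the linkage group are counted in the ``other_lg`` class.
    The summary carries both the pooled-rank overall R² (ranks computed
    within groups, fit across all common markers) and the mean of the
    per-group values.
    """
    a = map_a.set_index("marker")
    b = map_b.set_index("marker")
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    same_lg = a["linkage_group"] == b["linkage_group"]
    other_lg = int((~same_lg).sum())
    results: list[CollinearityResult] = []
    pooled_x, pooled_y = [], []
    for lg in sorted(a.loc[same_lg, "linkage_group"].unique()):
        sel = same_lg & (a["linkage_group"] == lg)
        if int(sel.sum()) < 2:
            results.append(CollinearityResult(
                (lg, lg), int(sel.sum()), None))
            continue
        ra = _tie_broken_ranks(a.loc[sel, "cM"], b.loc[sel, "cM"])
        rb = _tie_broken_ranks(b.loc[sel, "cM"], a.loc[sel, "cM"])
        r = np.corrcoef(ra, rb)[0, 1]
        results.append(CollinearityResult((lg, lg), int(sel.sum()),
                                          float(r ** 2)))
        pooled_x.append(ra)
        pooled_y.append(rb)
    if pooled_x:
        x = np.concatenate(pooled_x)
        y = np.concatenate(pooled_y)
        pooled_r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    else:
        pooled_r2 = None
    vals = [r.r_squared for r in results if r.r_squared is not None]
    summary = {
        "pooled_r_squared": pooled_r2,
        "mean_per_lg_r_squared": float(np.mean(vals)) if vals else None,
        "n_common": int(same_lg.sum()),
        "n_other_lg": other_lg,
    }
    return results, summary


# ---------------------------------------------------------------------------
# Map comparison


def compare_maps(map_a: pd.DataFrame, map_b: pd.DataFrame) -> dict:
    """Per-group and total length deltas plus coverage-extension report.

    Lengths are the cM spans of each map's groups. For groups present in
    both maps, the extension report gives, per map, the cM span beyond the
    outermost markers common to both maps (coverage the other map lacks).
    """
    def spans(df):
        g = df.groupby("linkage_group")["cM"]
        return (g.max() - g.min()).to_dict()

    span_a, span_b = spans(map_a), spans(map_b)
    groups = sorted(set(span_a) | set(span_b))
    per_lg = []
    a_idx = map_a.set_index("marker")
    b_idx = map_b.set_index("marker")
    common = a_idx.index.intersection(b_idx.index)
    for lg in groups:
        la, lb = span_a.get(lg), span_b.get(lg)
        row = {"linkage_group": lg, "length_a": la, "length_b": lb,
               "delta": None if la is None or lb is None else la - lb,
               "extension_a": 0.0, "extension_b": 0.0}
        if la is not None and lb is not None:
            ca = a_idx.loc[a_idx["linkage_group"] == lg]
            cb = b_idx.loc[b_idx["linkage_group"] == lg]
            shared = ca.index.intersection(cb.index).intersection(common)
            if len(shared) >= 2:
                lo_a, hi_a = ca.loc[shared, "cM"].min(), ca.loc[shared, "cM"].max()
                lo_b, hi_b = cb.loc[shared, "cM"].min(), cb.loc[shared, "cM"].max()
                row["extension_a"] = float((lo_a - ca["cM"].min())
                                           + (ca["cM"].max() - hi_a))
                row["extension_b"] = float((lo_b - cb["cM"].min())
                                           + (cb["cM"].max() - hi_b))
        per_lg.append(row)
    tot_a = float(sum(v for v in span_a.values()))
    tot_b = float(sum(v for v in span_b.values()))
    return {
        "per_lg": per_lg,
        "total_a": tot_a,
        "total_b": tot_b,
        "delta_total": tot_a - tot_b,
        "delta_percent": (100.0 * abs(tot_a - tot_b) / max(tot_a, tot_b)
                          if max(tot_a, tot_b) > 0 else 0.0),
        "n_common_markers": int(len(common)),
    }


# ---------------------------------------------------------------------------
# Recombination-rate landscape


@dataclass
class RateProfile:
    chromosome: str
    grid_Mb: np.ndarray
    smoothed_cM: np.ndarray
    rate: np.ndarray  # cM/Mb
    bandwidth_Mb: float = field(default=0.0)


def rate_profile(
    genetic_cM: np.ndarray,
    physical_Mb: np.ndarray,
    bandwidth: float | None = None,
    n_grid: int = 200,
    chromosome: str = "",
) -> RateProfile:
    """Recombination rate (cM/Mb) along a chromosome.

    Local-linear Gaussian-kernel smooth of cM against Mb on an even grid
    (default bandwidth: chromosome span / 30; the local-linear fit is free
    of the boundary bias and peak attenuation of a plain kernel average),
    isotonic monotonization, then a centered finite-difference first
    derivative. Anchors at duplicate physical positions are averaged first;
    at least five anchors are required.
    """
    mb = np.asarray(physical_Mb, dtype=float)
    cm = np.asarray(genetic_cM, dtype=float)
    df = pd.DataFrame({"mb": mb, "cm": cm}).groupby("mb", as_index=False).mean()
    mb, cm = df["mb"].to_numpy(), df["cm"].to_numpy()
    if mb.size < 5:
        raise ValueError("need at least 5 anchored markers")
    order = np.argsort(mb)
    mb, cm = mb[order], cm[order]
    span = mb[-1] - mb[0]
    h = span / 30.0 if bandwidth is None else float(bandwidth)
    grid = np.linspace(mb[0], mb[-1], n_grid)
    # local-linear fit at each grid point: weighted least squares of cm on
    # (mb - g), keeping the intercept
    w = np.exp(-0.5 * ((grid[:, None] - mb[None, :]) / h) ** 2)
    dx = mb[None, :] - grid[:, None]
    s0 = w.sum(axis=1)
    s1 = (w * dx).sum(axis=1)
    s2 = (w * dx ** 2).sum(axis=1)
    t0 = (w * cm[None, :]).sum(axis=1)
    t1 = (w * dx * cm[None, :]).sum(axis=1)
    denom = s0 * s2 - s1 ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        smoothed = np.where(np.abs(denom) > 1e-12 * np.maximum(s0, 1) ** 2,
                            (s2 * t0 - s1 * t1) / denom, t0 / s0)
    iso = IsotonicRegression(increasing=True)
    smoothed = iso.fit_transform(grid, smoothed)
    rate = np.gradient(smoothed, grid)
    rate = np.maximum(rate, 0.0)
    return RateProfile(chromosome=chromosome, grid_Mb=grid,
                       smoothed_cM=smoothed, rate=rate, bandwidth_Mb=h)


def nonrecombining_fraction(
    profiles: list[RateProfile],
    threshold: float = 0.05,
) -> float:
    """Fraction of total physical length with rate below ``threshold`` cM/Mb."""
    below = total = 0.0
    for p in profiles:
        widths = np.diff(p.grid_Mb)
        mid_rate = (p.rate[:-1] + p.rate[1:]) / 2.0
        below += float(widths[mid_rate < threshold].sum())
        total += float(widths.sum())
    return below / total if total > 0 else 0.0
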