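"""Single-position polymorphism (SPP) detection from array intensities.

A tiling array interrogates each unigene with overlapping 25-nt probes. At a
polymorphic 2-bp position, samples carrying the two alleles hybridize with
different efficiency, so the standardized per-sample deviation of the
weighted probe intensity (SPPdev) is bimodal across samples. Calling
proceeds position by position: standardize, find the variance-minimizing
two-class split, orient the modes by the parental replicates (the cultivated
parent defines allele A), call each sample by mode membership with a dead
zone around the threshold, require the two replicate hybridizations of each
line to agree, then merge contiguous concordant positions into SPP ranges
and filter them on separation, missingness, probe support, span and minor
allele frequency.

Because a heterozygous line resolves to either mode independently per
replicate, the replicate-consistency rule converts true heterozygotes into
missing/A/B calls at the characteristic 2:1:1 ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SPPRecord",
    "sppdev_profile",
    "call_position",
    "replicate_consensus",
    "summarize_and_filter",
    "call_unigene",
    "call_spp_table",
    "SPPFilter",
]


def sppdev_profile(intensities: pd.DataFrame, unigene_id: str) -> pd.DataFrame:
    """Per-position, per-sample SPPdev values for one unigene.

    ``intensities`` rows are indexed by (unigene, probe_start, probe_end)
    (1-based inclusive), columns by (sample, replicate). For every 2-bp
    window (odd start, stride 2) covered by at least two probes, the probe
    intensities are averaged with weights proportional to probe overlap with
    the window, then standardized across samples:

        SPPdev = (weighted mean - across-sample mean) / across-sample SD.

    Positions with zero across-sample SD are nonpolymorphic and returned as
    NaN rows. Result rows are indexed by window start; columns match the
    sample columns.
    """
    sub = intensities.loc[unigene_id]
    starts = sub.index.get_level_values("probe_start").to_numpy()
    ends = sub.index.get_level_values("probe_end").to_numpy()
    vals = sub.to_numpy()
    lo = int(starts.min())
    if lo % 2 == 0:
        lo += 1
    hi = int(ends.max())
    rows = {}
    for p in range(lo, hi, 2):
        # overlap of each probe with window [p, p+1]
        ov = np.minimum(ends, p + 1) - np.maximum(starts, p) + 1
        w = np.clip(ov, 0, 2) / 2.0
        covered = w > 0
        if covered.sum() < 2:
            continue
        wmean = (w[covered, None] * vals[covered]).sum(axis=0) / w[covered].sum()
        mu, sd = wmean.mean(), wmean.std(ddof=0)
        if sd <= 1e-9 * max(1.0, abs(mu)):
            rows[p] = np.full(wmean.size, np.nan)
        else:
            rows[p] = (wmean - mu) / sd
    return pd.DataFrame.from_dict(rows, orient="index", columns=sub.columns)


@dataclass
class PositionCall:
    """Outcome of calling one 2-bp position.

    ``separation`` is the bimodality statistic |mode1 - mode2| / pooled
    within-mode SD. A variance-minimizing split of even a unimodal Gaussian
    yields about 2.7 on this scale, so the polymorphism gate sits above
    that baseline. ``sppdev_ratio`` is the mode separation on the
    standardized SPPdev axis (across-sample SD = 1, so at most 2 for a
    balanced split); it is the per-position quality that the record-level
    1.1 filter averages.
    """

    polymorphic: bool
    calls: pd.Series | None = None  # per (sample, replicate) in {A,B,-}
    separation: float = 0.0
    sppdev_ratio: float = 0.0
    reason: str = ""


def _best_split(x: np.ndarray) -> tuple[float, float]:
    """Variance-minimizing 1-D two-class split.

    Returns (threshold, separation ratio); threshold is the midpoint between
    the two classes' extreme members, separation = |mean1 - mean2| / pooled
    within-class SD (inf when both classes are constant).
    """
    xs = np.sort(x)
    n = xs.size
    best = None
    csum = np.cumsum(xs)
    csq = np.cumsum(xs ** 2)
    for k in range(1, n):
        n1, n2 = k, n - k
        s1, s2 = csum[k - 1], csum[-1] - csum[k - 1]
        q1, q2 = csq[k - 1], csq[-1] - csq[k - 1]
        ss = (q1 - s1 ** 2 / n1) + (q2 - s2 ** 2 / n2)
        if best is None or ss < best[0]:
            best = (ss, k)
    ss, k = best
    m1 = csum[k - 1] / k
    m2 = (csum[-1] - csum[k - 1]) / (n - k)
    pooled = np.sqrt(ss / n)
    sep = np.inf if pooled == 0 else abs(m1 - m2) / pooled
    thr = (xs[k - 1] + xs[k]) / 2.0
    return thr, float(sep)


def call_position(
    sppdev: pd.Series,
    cultivated: str,
    wild: str,
    min_separation: float = 3.3,
    dead_zone: float = 0.25,
) -> PositionCall:
    """Call one position's samples from its SPPdev values.

    ``sppdev`` is indexed by (sample, replicate). The two modes come from
    the variance-minimizing split; the mode containing the cultivated
    parent's replicates is allele A. Samples whose SPPdev lies within
    ``dead_zone`` x mode-separation of the split threshold are missing.
    Rejected positions carry a reason code: ``"unimodal"`` (separation below
    ``min_separation``) or ``"parents_same_mode"``.

    The default gate of 3.3 sits between the ~2.7 a forced split of
    unimodal noise produces on this scale and the 4.0 of a two-allele
    signal whose modes are four within-mode SDs apart.
    """
    x = sppdev.to_numpy(dtype=float)
    if np.isnan(x).all():
        return PositionCall(False, reason="zero_variance")
    thr, sep = _best_split(x)
    hi = x > thr
    m_hi = x[hi].mean()
    m_lo = x[~hi].mean()
    ratio = float(abs(m_hi - m_lo))
    if sep < min_separation:
        return PositionCall(False, separation=sep, sppdev_ratio=ratio,
                            reason="unimodal")
    samples = sppdev.index.get_level_values(0)
    cult_side = hi[samples == cultivated]
    wild_side = hi[samples == wild]
    if cult_side.size == 0 or wild_side.size == 0:
        return PositionCall(False, separation=sep, sppdev_ratio=ratio,
                            reason="parents_missing")
    if (cult_side.mean() > 0.5) == (wild_side.mean() > 0.5) \
            or cult_side.mean() == 0.5 or wild_side.mean() == 0.5:
        return PositionCall(False, separation=sep, sppdev_ratio=ratio,
                            reason="parents_same_mode")
    a_is_hi = cult_side.mean() > 0.5
    dz = dead_zone * abs(m_hi - m_lo)
    calls = np.where(np.abs(x - thr) <= dz, "-",
                     np.where(hi == a_is_hi, "A", "B"))
    return PositionCall(True, calls=pd.Series(calls, index=sppdev.index),
                        separation=sep, sppdev_ratio=ratio)


def replicate_consensus(rep1: pd.Series, rep2: pd.Series) -> pd.Series:
    """Per-line call requiring both replicate hybridizations to agree.

    Equal non-missing calls are kept; unequal calls, or any missing
    replicate, give missing. A heterozygous line whose replicates resolve
    independently to either mode therefore comes out missing:A:B = 2:1:1.
    """
    if not rep1.index.equals(rep2.index):
        raise ValueError("replicate call vectors must cover the same lines")
    a = rep1.to_numpy(dtype="U1")
    b = rep2.to_numpy(dtype="U1")
    out = np.where((a == b) & (a != "-"), a, "-")
    return pd.Series(out, index=rep1.index)


@dataclass
class SPPRecord:
    """One filtered SPP range of a unigene."""

    unigene_id: str
    start_pos: int
    end_pos: int
    avg_sppdev: float
    calls: pd.Series  # per line, {A,B,-}
    n_valid_probes: int
    span_bases: int = 2

    @property
    def missing_fraction(self) -> float:
        return float((self.calls == "-").mean())

    @property
    def allele_frequency(self) -> float:
        """Frequency of A among non-missing calls (NaN if all missing)."""
        non = self.calls[self.calls != "-"]
        return float((non == "A").mean()) if len(non) else float("nan")


@dataclass
class SPPFilter:
    """Record-level retention thresholds."""

    min_sppdev: float = 1.1
    max_missing: float = 0.10
    min_probes: int = 2
    min_span: int = 2
    max_allele_freq: float = 0.90

    def keep(self, rec: SPPRecord) -> bool:
        af = rec.allele_frequency
        if np.isnan(af):
            return False
        maf_ok = (1.0 - self.max_allele_freq) <= af <= self.max_allele_freq
        return (rec.avg_sppdev >= self.min_sppdev
                and rec.missing_fraction <= self.max_missing
                and rec.n_valid_probes >= self.min_probes
                and rec.span_bases >= self.min_span
                and maf_ok)


def _compatible(a: np.ndarray, b: np.ndarray) -> bool:
    both = (a != "-") & (b != "-")
    return bool((a[both] == b[both]).all())


def summarize_and_filter(
    positions: list[tuple[int, float, int, pd.Series]],
    unigene_id: str,
    spp_filter: SPPFilter | None = None,
) -> list[SPPRecord]:
    """Merge contiguous concordant positions into SPP ranges, then filter.

    ``positions`` holds ``(start, separation, n_probes, per-line calls)``
    tuples for the polymorphic 2-bp positions of one unigene, in coordinate
    order. Adjacent positions (starts two bases apart) with identical call
    vectors up to missing merge into one range; the merged call per line is
    the unique non-missing value. Records are then filtered on average
    separation, missing fraction, probe support, span, and minor allele
    frequency.
    """
    if spp_filter is None:
        spp_filter = SPPFilter()
    records: list[SPPRecord] = []
    group: list[tuple[int, float, int, pd.Series]] = []

    def flush():
        if not group:
            return
        seps = [g[1] for g in group]
        arrs = np.vstack([g[3].to_numpy(dtype="U1") for g in group])
        merged = np.full(arrs.shape[1], "-", dtype="U1")
        for row in arrs:
            take = (merged == "-") & (row != "-")
            merged[take] = row[take]
        records.append(SPPRecord(
            unigene_id=unigene_id,
            start_pos=group[0][0],
            end_pos=group[-1][0] + 1,
            avg_sppdev=float(np.mean(seps)),
            calls=pd.Series(merged, index=group[0][3].index),
            n_valid_probes=min(g[2] for g in group),
            span_bases=2 * len(group),
        ))
        group.clear()

    for pos in positions:
        if group and (pos[0] != group[-1][0] + 2 or not _compatible(
                group[-1][3].to_numpy(dtype="U1"), pos[3].to_numpy(dtype="U1"))):
            flush()
        group.append(pos)
    flush()
    return [r for r in records if spp_filter.keep(r)]


def call_unigene(
    intensities: pd.DataFrame,
    unigene_id: str,
    cultivated: str = "P_A",
    wild: str = "P_B",
    min_separation: float = 3.3,
    dead_zone: float = 0.25,
    spp_filter: SPPFilter | None = None,
) -> list[SPPRecord]:
    """Full SPP calling for one unigene: SPPdev, mode split, replicate
    consensus, range merging and filtering."""
    prof = sppdev_profile(intensities, unigene_id)
    samples = prof.columns.get_level_values(0)
    rils = sorted({s for s in samples if s not in (cultivated, wild)})
    positions = []
    for p, row in prof.iterrows():
        res = call_position(row, cultivated, wild,
                            min_separation=min_separation, dead_zone=dead_zone)
        if not res.polymorphic:
            continue
        per_rep = res.calls
        reps = sorted({r for s, r in per_rep.index if s in rils})
        r1 = per_rep.loc[[(s, reps[0]) for s in rils]]
        r1.index = rils
        r2 = per_rep.loc[[(s, reps[1]) for s in rils]]
        r2.index = rils
        cons = replicate_consensus(r1, r2)
        n_probes = int(((intensities.loc[unigene_id].index
                         .get_level_values("probe_start") <= p + 1)
                        & (intensities.loc[unigene_id].index
                           .get_level_values("probe_end") >= p)).sum())
        positions.append((int(p), res.sppdev_ratio, n_probes, cons))
    return summarize_and_filter(positions, unigene_id, spp_filter)


def call_spp_table(
    intensities: pd.DataFrame,
    cultivated: str = "P_A",
    wild: str = "P_B",
    **kwargs,
) -> tuple[pd.DataFrame, list[SPPRecord]]:
    """Call SPPs for every unigene in an intensity matrix.

    Returns (table, records): the table holds one row per retained SPP with
    quality fields followed by one call column per line.
    """
    records: list[SPPRecord] = []
    for ug in intensities.index.get_level_values("unigene").unique():
        records.extend(call_unigene(intensities, ug, cultivated, wild, **kwargs))
    if not records:
        return pd.DataFrame(), records
    meta = pd.DataFrame({
        "unigene": [r.unigene_id for r in records],
        "start": [r.start_pos for r in records],
        "end": [r.end_pos for r in records],
        "avg_sppdev": [r.avg_sppdev for r in records],
        "n_valid_probes": [r.n_valid_probes for r in records],
        "span_bases": [r.span_bases for r in records],
    })
    calls = pd.DataFrame([r.calls for r in records]).reset_index(drop=True)
    return pd.concat([meta, calls], axis=1), records
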