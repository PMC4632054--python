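"""Genetic bins, recombination-count-minimizing ordering, and map iteration.

A genetic bin is a set of markers showing zero observed recombination in the
population; bins are the map's unit of resolution. Bins within a linkage
group are ordered by minimizing COUNT — the total number of obligate
crossover events the order implies across all lines, with missing calls
skipped so that a crossover is scored between the nearest non-missing
flanking calls. The optimizer is a seeded multi-restart greedy insertion
build followed by exhaustive sliding-window reshuffles, the strategy of the
RECORD family of ordering tools.

Because intensity-based genotyping emits heterozygotes as missing/A/B at
2:1:1, raw maps are inflated by spurious crossovers inside residual
heterozygous tracts. :func:`iterate_map` runs the four-iteration correction:
detect heterozygous regions with a 5-cM sliding window, mask them, reorder,
convert refined regions to explicit H calls, remove remaining apparent
double crossovers, optionally restore double crossovers backed by unanimous
multi-SPP support, and merge bins that no longer recombine.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grouping import (
    RecombinationMatrix,
    encode_calls,
    pairwise_recombination,
    ril_correction,
    ril_correction_finite,
)

__all__ = [
    "GeneticBin",
    "GeneticMap",
    "HetRegion",
    "count_crossovers",
    "build_bins",
    "order_bins",
    "exhaustive_order",
    "haldane",
    "kosambi",
    "compute_distances",
    "detect_het_regions",
    "bin_consensus_alleles",
    "build_map",
    "iterate_map",
]


# ---------------------------------------------------------------------------
# COUNT machinery


def count_crossovers(X: np.ndarray) -> int:
    """COUNT criterion for an ordered call matrix.

    ``X`` is (n_bins, n_lines) int8 with A=0, B=1, missing=-1 (H must already
    be encoded missing). Per line, crossovers are transitions in the
    missing-stripped call sequence: an interval of k missing bins between
    discordant flanks contributes exactly one crossover.
    """
    n = X.shape[0]
    if n < 2:
        return 0
    pos = np.where(X >= 0, np.arange(n)[:, None], -1)
    pos = np.maximum.accumulate(pos, axis=0)
    prev_pos = pos[:-1]
    prev_valid = prev_pos >= 0
    F_prev = np.take_along_axis(X, np.maximum(prev_pos, 0), axis=0)
    cur = X[1:]
    trans = (cur >= 0) & prev_valid & (cur != F_prev)
    return int(trans.sum())


def _count_many(Xs: np.ndarray) -> np.ndarray:
    """COUNT for a stack of ordered matrices, shape (P, n, m)."""
    P, n, m = Xs.shape
    if n < 2:
        return np.zeros(P, dtype=np.int64)
    pos = np.where(Xs >= 0, np.arange(n)[None, :, None], -1)
    pos = np.maximum.accumulate(pos, axis=1)
    prev_pos = pos[:, :-1]
    F_prev = np.take_along_axis(Xs, np.maximum(prev_pos, 0), axis=1)
    cur = Xs[:, 1:]
    trans = (cur >= 0) & (prev_pos >= 0) & (cur != F_prev)
    return trans.sum(axis=(1, 2))


def _prev_next(X: np.ndarray):
    """Forward/backward fill context arrays for incremental COUNT.

    Returns (prevval, nextval), each (n+1, m): ``prevval[p]`` is the last
    non-missing call strictly above insertion slot p, ``nextval[p]`` the
    first non-missing call at or below slot p; -1 where none.
    """
    n, m = X.shape
    pos = np.where(X >= 0, np.arange(n)[:, None], -1)
    fpos = np.maximum.accumulate(pos, axis=0)
    prevval = np.full((n + 1, m), -1, dtype=np.int8)
    if n:
        filled = np.take_along_axis(X, np.maximum(fpos, 0), axis=0)
        filled[fpos < 0] = -1
        prevval[1:] = filled
    bpos = np.where(X >= 0, np.arange(n)[:, None], n)
    bpos = np.minimum.accumulate(bpos[::-1], axis=0)[::-1]
    nextval = np.full((n + 1, m), -1, dtype=np.int8)
    if n:
        filledb = np.take_along_axis(X, np.minimum(bpos, n - 1), axis=0)
        filledb[bpos >= n] = -1
        nextval[:-1] = filledb
    return prevval, nextval


def _greedy_build(calls: np.ndarray, insert_order: np.ndarray) -> list[int]:
    """Greedy best-insertion order, starting from the first two bins given."""
    order = [int(insert_order[0]), int(insert_order[1])]
    for raw in insert_order[2:]:
        X = calls[order]
        A, B = _prev_next(X)
        c = calls[int(raw)][None, :]
        valid_c = c >= 0
        old = (A >= 0) & (B >= 0) & (A != B)
        new = ((A >= 0) & (A != c)).astype(np.int32) + \
              ((B >= 0) & (B != c)).astype(np.int32)
        delta = ((new - old.astype(np.int32)) * valid_c).sum(axis=1)
        p = int(np.argmin(delta))
        order.insert(p, int(raw))
    return order


def _window_polish(calls: np.ndarray, order: list[int], window_max: int,
                   max_sweeps: int = 50) -> list[int]:
    """Sliding-window exhaustive reshuffles until no improvement."""
    order = list(order)
    perms_by_w = {w: np.array(list(itertools.permutations(range(w))))
                  for w in range(2, window_max + 1)}
    improved = True
    sweeps = 0
    while improved and sweeps < max_sweeps:
        improved = False
        sweeps += 1
        n = len(order)
        for w in range(2, window_max + 1):
            if n < w:
                continue
            X = calls[order]
            A, B = _prev_next(X)
            perms = perms_by_w[w]
            i = 0
            while i <= n - w:
                seg = X[i:i + w]
                ctx_top = A[i][None, :]
                ctx_bot = B[i + w][None, :]
                stack = np.concatenate(
                    [np.broadcast_to(ctx_top, (len(perms), 1, seg.shape[1])),
                     seg[perms],
                     np.broadcast_to(ctx_bot, (len(perms), 1, seg.shape[1]))],
                    axis=1)
                costs = _count_many(stack)
                best = int(np.argmin(costs))
                if costs[best] < costs[0]:
                    order[i:i + w] = [order[i + k] for k in perms[best]]
                    improved = True
                    X = calls[order]
                    A, B = _prev_next(X)
                i += 1
    return order


def order_bins(
    calls: np.ndarray,
    bin_ids: list[str] | None = None,
    seed: int = 0,
    n_restarts: int = 10,
    window_max: int = 5,
) -> tuple[list[int], int]:
    """Order bins to minimize COUNT.

    ``calls`` is (n_bins, n_lines) int8 (A=0, B=1, missing=-1). Runs
    ``n_restarts`` seeded greedy-insertion builds (each starting from the
    tightest-linked pair, remaining bins in shuffled order) followed by
    sliding-window polishing, and returns the best order (as indices into
    ``calls``) and its COUNT. The order is canonicalized against reflection:
    the end with the smaller bin id (or index) comes first.
    """
    n = calls.shape[0]
    if n < 2:
        return list(range(n)), 0
    rng = np.random.default_rng(seed)

    # tightest-linked pair: fewest recombinants per informative line
    valid = (calls >= 0).astype(np.float32)
    a = np.where(calls >= 0, calls, 0).astype(np.float32)
    n_inf = valid @ valid.T
    same = a @ a.T + (valid - a) @ (valid - a).T
    with np.errstate(divide="ignore", invalid="ignore"):
        Rm = np.where(n_inf > 0, (n_inf - same) / np.maximum(n_inf, 1), 1.0)
    np.fill_diagonal(Rm, np.inf)
    i0, j0 = np.unravel_index(int(np.argmin(Rm)), Rm.shape)

    best_order, best_cost = None, None
    for _ in range(max(1, n_restarts)):
        rest = [k for k in range(n) if k not in (i0, j0)]
        rng.shuffle(rest)
        insert_order = np.array([i0, j0] + rest)
        order = _greedy_build(calls, insert_order)
        order = _window_polish(calls, order, window_max)
        cost = count_crossovers(calls[order])
        if best_cost is None or cost < best_cost:
            best_order, best_cost = order, cost

    keys = bin_ids if bin_ids is not None else list(range(n))
    if keys[best_order[-1]] < keys[best_order[0]]:
        best_order = best_order[::-1]
    return best_order, int(best_cost)


def exhaustive_order(calls: np.ndarray) -> tuple[list[int], int]:
    """Brute-force optimal order over all permutations (oracle; n <= 9)."""
    n = calls.shape[0]
    if n > 9:
        raise ValueError("exhaustive search limited to 9 bins")
    perms = np.array(list(itertools.permutations(range(n))))
    costs = _count_many(calls[perms])
    best = int(np.argmin(costs))
    return list(perms[best]), int(costs[best])


# ---------------------------------------------------------------------------
# Bins


@dataclass
class GeneticBin:
    """A set of markers with zero observed recombination."""

    bin_id: str
    members: list[str]
    representative: str
    calls: np.ndarray  # per-line int8 calls used for ordering/distance
    cM: float = 0.0
    ambiguous: set[str] = field(default_factory=set)


def build_bins(
    matrix: pd.DataFrame,
    recomb: RecombinationMatrix | None = None,
    min_informative: int = 2,
) -> list[GeneticBin]:
    """Group markers of one linkage group into zero-recombination bins.

    Markers are merged transitively when they show zero observed
    recombination over at least ``min_informative`` shared lines. A marker
    that is zero-recombinant with members of two bins that recombine with
    each other is ambiguous: it is attached to the bin with which it shares
    more informative lines (tie: the earlier bin) and flagged. The bin
    representative is the member with fewest missing calls (tie: lexical
    marker id); its calls are carried as the bin's calls.
    """
    if recomb is None:
        recomb = pairwise_recombination(matrix, min_informative=min_informative)
    names = recomb.markers
    idx = {m: i for i, m in enumerate(names)}
    enc = encode_calls(matrix.loc[names])
    n_missing = (enc < 0).sum(axis=1)
    proc = sorted(names, key=lambda m: (int(n_missing[idx[m]]), m))

    n_inf, n_rec = recomb.n_informative, recomb.n_recombinant
    bins: list[dict] = []  # {"members": [...], "ambiguous": set()}

    def link_conflict(mi: int, members: list[str]) -> tuple[bool, bool, int]:
        link = conflict = False
        shared = 0
        for mb in members:
            j = idx[mb]
            ninf = n_inf[mi, j]
            shared += int(ninf)
            if ninf >= min_informative:
                if n_rec[mi, j] == 0:
                    link = True
                else:
                    conflict = True
        return link, conflict, shared

    for m in proc:
        mi = idx[m]
        cands = []
        for b, binfo in enumerate(bins):
            link, conflict, shared = link_conflict(mi, binfo["members"])
            if link and not conflict:
                cands.append((b, shared))
        if not cands:
            bins.append({"members": [m], "ambiguous": set()})
        elif len(cands) == 1:
            bins[cands[0][0]]["members"].append(m)
        else:
            # do the candidate bins recombine with each other?
            recombine = False
            for (b1, _), (b2, _) in itertools.combinations(cands, 2):
                for x in bins[b1]["members"]:
                    for y in bins[b2]["members"]:
                        xi, yi = idx[x], idx[y]
                        if n_inf[xi, yi] >= min_informative and n_rec[xi, yi] > 0:
                            recombine = True
            if not recombine:
                # transitivity: merge all candidates plus the marker
                target = cands[0][0]
                for b, _ in sorted(cands[1:], key=lambda t: -t[0]):
                    bins[target]["members"].extend(bins[b]["members"])
                    bins[target]["ambiguous"] |= bins[b]["ambiguous"]
                    del bins[b]
                bins[target]["members"].append(m)
            else:
                cands.sort(key=lambda t: (-t[1], t[0]))
                bins[cands[0][0]]["members"].append(m)
                bins[cands[0][0]]["ambiguous"].add(m)

    out = []
    for binfo in bins:
        members = sorted(binfo["members"])
        rep = min(members, key=lambda m: (int(n_missing[idx[m]]), m))
        out.append(GeneticBin(
            bin_id=rep, members=members, representative=rep,
            calls=enc[idx[rep]].copy(), ambiguous=set(binfo["ambiguous"])))
    out.sort(key=lambda b: b.bin_id)
    return out


# ---------------------------------------------------------------------------
# Distances

_DIST_CAP_DEFAULT = 50.0


def haldane(r: float) -> float:
    """Haldane map distance (cM) for recombination fraction r."""
    if r >= 0.5:
        return float("inf")
    return -50.0 * np.log(1.0 - 2.0 * r)


def kosambi(r: float) -> float:
    """Kosambi map distance (cM) for recombination fraction r."""
    if r >= 0.5:
        return float("inf")
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def compute_distances(
    ordered_calls: np.ndarray,
    mapping_function: str = "haldane",
    cap_cM: float = _DIST_CAP_DEFAULT,
    min_informative: int = 2,
    generation: int | None = None,
) -> np.ndarray:
    """Cumulative cM positions for ordered bins from adjacent-interval r.

    Per line, a recombination event is scored between the nearest
    non-missing calls flanking each interval; an event whose flanks span k
    intervals (because the intervening calls are missing) contributes 1/k
    to each spanned interval, so crossovers of partially missing lines
    still enter the total map length (locally smoothed, globally unbiased).
    Observed fractions are RIL-corrected — with the exact finite-generation
    selfing relation when ``generation`` is given, else the fixation formula
    R = 2r/(1+2r) — then mapped through the Haldane (default) or Kosambi
    function; unlinked or uninformative adjacencies
    are capped at ``cap_cM`` with a warning. Positions start at 0.
    """
    fun = {"haldane": haldane, "kosambi": kosambi}[mapping_function]
    X = ordered_calls
    n, m = X.shape
    pos = np.zeros(n)
    if n < 2:
        return pos
    idx = np.arange(n)[:, None]
    fpos = np.where(X >= 0, idx, -1)
    fpos = np.maximum.accumulate(fpos, axis=0)
    bpos = np.where(X >= 0, idx, n)
    bpos = np.minimum.accumulate(bpos[::-1], axis=0)[::-1]
    cols = np.arange(m)
    for i in range(1, n):
        L = fpos[i - 1]
        Rp = bpos[i]
        valid = (L >= 0) & (Rp < n)
        ninf = int(valid.sum())
        if ninf < min_informative:
            warnings.warn(f"adjacent bins {i-1},{i} uninformative; "
                          f"distance capped at {cap_cM} cM")
            d = cap_cM
        else:
            span = (Rp - L).astype(float)
            differ = X[np.maximum(L, 0), cols] != X[np.minimum(Rp, n - 1), cols]
            R = float((differ[valid] / span[valid]).sum()) / ninf
            if generation is None:
                r = float(ril_correction(np.minimum(R, 1.0)))
            else:
                r = float(ril_correction_finite(np.minimum(R, 1.0), generation))
            d = fun(r)
            if not np.isfinite(d) or d > cap_cM:
                warnings.warn(f"adjacent bins {i-1},{i} at r=0.5; "
                              f"distance capped at {cap_cM} cM")
                d = cap_cM
        pos[i] = pos[i - 1] + d
    return pos


# ---------------------------------------------------------------------------
# Map container


@dataclass
class GeneticMap:
    """Linkage groups of ordered genetic bins with cM positions."""

    groups: dict[str, list[GeneticBin]]
    lines: list[str]
    iteration: int = 1

    def length(self, lg: str) -> float:
        bins = self.groups[lg]
        return bins[-1].cM if bins else 0.0

    @property
    def total_length(self) -> float:
        return float(sum(self.length(lg) for lg in self.groups))

    @property
    def n_bins(self) -> int:
        return sum(len(b) for b in self.groups.values())

    def marker_positions(self) -> pd.DataFrame:
        rows = []
        for lg, bins in self.groups.items():
            for k, b in enumerate(bins):
                for m in b.members:
                    rows.append({
                        "marker": m, "linkage_group": lg, "bin_id": b.bin_id,
                        "bin_index": k, "cM": b.cM,
                        "representative": m == b.representative,
                        "ambiguous": m in b.ambiguous,
                    })
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        df = self.marker_positions()
        return df.sort_values(["linkage_group", "cM", "marker"],
                              kind="stable").reset_index(drop=True)


@dataclass
class HetRegion:
    """A heterozygous tract inferred for one line on one linkage group."""

    ril_id: str
    linkage_group: str
    start_cM: float
    end_cM: float
    n_missing: int = 0
    n_double_crossovers: int = 0
    members: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Het-region detection


def _transitions(stripped: np.ndarray) -> int:
    if stripped.size < 2:
        return 0
    return int((stripped[1:] != stripped[:-1]).sum())


def detect_het_regions(
    gmap: GeneticMap,
    matrix: pd.DataFrame,
    window_cM: float = 5.0,
    min_windows: int = 2,
    miss_thresh: float = 0.4,
    min_crossovers: int = 2,
    expand_skip: int = 1,
    min_bins_per_window: int = 2,
) -> list[HetRegion]:
    """Detect residual-heterozygosity tracts per line per linkage group.

    A window of ``window_cM`` slides bin-by-bin along each group; for a given
    line it is het-suspicious if the fraction of missing bin calls reaches
    ``miss_thresh`` or it contains at least ``min_crossovers`` apparent
    crossovers. At least ``min_windows`` contiguous suspicious windows are
    merged into one region, trimmed to the outermost bins carrying evidence
    (missing calls or crossover flanks), then expanded outward while
    adjacent bins keep carrying evidence (tolerating ``expand_skip``
    consecutive clean bins, since a heterozygous tract emits a clean-looking
    call about a quarter of the time). Overlapping or sub-window-gapped
    regions merge.
    """
    regions: list[HetRegion] = []
    line_pos = {l: i for i, l in enumerate(matrix.columns)}
    for lg, bins in gmap.groups.items():
        if len(bins) < 2:
            continue
        cms = np.array([b.cM for b in bins])
        # bin call per line: representative-marker calls from the matrix
        reps = [b.representative for b in bins]
        enc = encode_calls(matrix.loc[reps])
        nb = len(bins)
        # a window spans window_cM but never fewer than min_bins_per_window
        # bins: spurious het recombination locally inflates the map, so a
        # fixed-cM window can otherwise starve exactly where hets sit
        win_members = []
        for i in range(nb):
            j = int(np.searchsorted(cms, cms[i] + window_cM, side="right"))
            j = min(max(j, i + min_bins_per_window), nb)
            win_members.append(np.arange(i, max(j, i + 1)))
        for line in matrix.columns:
            col = enc[:, line_pos[line]]
            # loose evidence (for trimming region bounds): missing or
            # discordant with either non-missing neighbour. strict evidence
            # (for outward expansion): missing or discordant with both — a
            # lone crossover flank is not strict evidence, so a genuine
            # single crossover next to a tract is not swallowed.
            evid_any = col < 0
            evid = col < 0
            nmi = np.flatnonzero(col >= 0)
            for a, b in zip(nmi[:-1], nmi[1:]):
                if col[a] != col[b]:
                    evid_any[a] = evid_any[b] = True
            for a, b, c in zip(nmi[:-2], nmi[1:-1], nmi[2:]):
                if col[b] != col[a] and col[b] != col[c]:
                    evid[b] = True
            suspicious = np.zeros(nb, dtype=bool)
            for i, mem in enumerate(win_members):
                sub = col[mem]
                miss = float((sub < 0).mean())
                xo = _transitions(sub[sub >= 0])
                suspicious[i] = (miss >= miss_thresh) or (xo >= min_crossovers)
            # contiguous runs of suspicious window starts
            i = 0
            while i < nb:
                if not suspicious[i]:
                    i += 1
                    continue
                j = i
                while j + 1 < nb and suspicious[j + 1]:
                    j += 1
                if j - i + 1 >= min_windows:
                    lo_bin = i
                    hi_bin = int(win_members[j][-1])
                    seg_ev = evid_any[lo_bin:hi_bin + 1]
                    if seg_ev.any():
                        ev = np.flatnonzero(seg_ev)
                        lo, hi = lo_bin + ev[0], lo_bin + ev[-1]
                    else:
                        lo, hi = lo_bin, hi_bin
                    # expand outward over contiguous evidence
                    skipped, k = 0, lo - 1
                    while k >= 0:
                        if evid[k]:
                            lo, skipped = k, 0
                        else:
                            skipped += 1
                            if skipped > expand_skip:
                                break
                        k -= 1
                    skipped, k = 0, hi + 1
                    while k < nb:
                        if evid[k]:
                            hi, skipped = k, 0
                        else:
                            skipped += 1
                            if skipped > expand_skip:
                                break
                        k += 1
                    seg = col[lo:hi + 1]
                    regions.append(HetRegion(
                        ril_id=line, linkage_group=lg,
                        start_cM=float(cms[lo]), end_cM=float(cms[hi]),
                        n_missing=int((seg < 0).sum()),
                        n_double_crossovers=max(_transitions(seg[seg >= 0]) - 1, 0),
                        members=[m for b in bins[lo:hi + 1] for m in b.members],
                    ))
                i = j + 1
    return _merge_het_regions(regions, window_cM)


def _merge_het_regions(regions: list[HetRegion],
                       window_cM: float) -> list[HetRegion]:
    """Merge overlapping or sub-window-gapped regions (per line per group).

    Gaps smaller than the detection window are below the method's
    resolution, and regions per line per group must be disjoint.
    """
    out: list[HetRegion] = []
    key = lambda r: (r.ril_id, r.linkage_group, r.start_cM, r.end_cM)
    by_group: dict[tuple, list[HetRegion]] = {}
    for r in sorted(regions, key=key):
        by_group.setdefault((r.ril_id, r.linkage_group), []).append(r)
    for regs in by_group.values():
        cur = regs[0]
        for nxt in regs[1:]:
            if nxt.start_cM - cur.end_cM < window_cM:
                cur = HetRegion(
                    ril_id=cur.ril_id, linkage_group=cur.linkage_group,
                    start_cM=cur.start_cM, end_cM=max(cur.end_cM, nxt.end_cM),
                    n_missing=cur.n_missing + nxt.n_missing,
                    n_double_crossovers=(cur.n_double_crossovers
                                         + nxt.n_double_crossovers),
                    members=sorted(set(cur.members) | set(nxt.members)))
            else:
                out.append(cur)
                cur = nxt
        out.append(cur)
    out.sort(key=key)
    return out


def _combine_regions(gmap: GeneticMap, region_lists: list[list[HetRegion]],
                     window_cM: float) -> list[HetRegion]:
    """Union het regions detected on different map iterations.

    Fragments of the same line whose member-marker sets overlap merge
    transitively; each merged region is re-expressed on ``gmap`` (majority
    linkage group of its members, span = their cM extent there), then
    sub-window gaps are closed.
    """
    placed = {}
    for lg, bins in gmap.groups.items():
        for b in bins:
            for m in b.members:
                placed[m] = (lg, b.cM)
    frags: dict[str, list[HetRegion]] = {}
    for regs in region_lists:
        for r in regs:
            if r.members:
                frags.setdefault(r.ril_id, []).append(r)
    out: list[HetRegion] = []
    for ril, regs in frags.items():
        sets = [set(r.members) for r in regs]
        parent = list(range(len(regs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(regs)):
            for j in range(i + 1, len(regs)):
                if sets[i] & sets[j]:
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in range(len(regs)):
            groups.setdefault(find(i), []).append(i)
        for idxs in groups.values():
            members = sorted(set().union(*(sets[i] for i in idxs)))
            spots = [placed[m] for m in members if m in placed]
            if not spots:
                continue
            lgs = [s[0] for s in spots]
            lg = max(set(lgs), key=lgs.count)
            cms = [s[1] for s in spots if s[0] == lg]
            out.append(HetRegion(
                ril_id=ril, linkage_group=lg,
                start_cM=float(min(cms)), end_cM=float(max(cms)),
                n_missing=sum(regs[i].n_missing for i in idxs),
                n_double_crossovers=sum(regs[i].n_double_crossovers
                                        for i in idxs),
                members=[m for m in members
                         if m in placed and placed[m][0] == lg]))
    return _merge_het_regions(out, window_cM)


# ---------------------------------------------------------------------------
# Bin consensus from SPP-level calls


def bin_consensus_alleles(
    spp_calls: pd.DataFrame,
    spp_to_bin: pd.Series | dict,
    max_missing: float = 0.80,
    min_majority: float = 0.66,
) -> pd.DataFrame:
    """Consensus allele per bin per line from member SPP calls.

    A line gets an allele for a bin iff the missing fraction among member
    SPPs is below ``max_missing`` and the majority allele reaches
    ``min_majority`` of the non-missing calls; otherwise missing. Idempotent:
    re-running on its own output changes nothing.
    """
    mapping = pd.Series(spp_to_bin)
    out = {}
    for bin_id, group in spp_calls.groupby(mapping.reindex(spp_calls.index)):
        vals = group.to_numpy(dtype="U1")
        n = vals.shape[0]
        n_miss = (vals == "-").sum(axis=0)
        n_a = (vals == "A").sum(axis=0)
        n_b = (vals == "B").sum(axis=0)
        nonmiss = np.maximum(n - n_miss, 1)
        call = np.full(vals.shape[1], "-", dtype="U1")
        ok = (n_miss / n) < max_missing
        call[ok & (n_a / nonmiss >= min_majority)] = "A"
        call[ok & (n_b / nonmiss >= min_majority)] = "B"
        out[bin_id] = call
    return pd.DataFrame.from_dict(out, orient="index",
                                  columns=spp_calls.columns)


# ---------------------------------------------------------------------------
# Map building and iteration


def _split_on_gaps(bins: list[GeneticBin], max_gap_cM: float) -> list[list[GeneticBin]]:
    """Split an ordered group where adjacent bins are further than the gap."""
    parts, cur = [], [bins[0]]
    for prev, b in zip(bins, bins[1:]):
        if b.cM - prev.cM > max_gap_cM:
            parts.append(cur)
            cur = [b]
        else:
            cur.append(b)
    parts.append(cur)
    # re-zero each part
    for part in parts[1:]:
        base = part[0].cM
        for b in part:
            b.cM -= base
    return parts


def _build_group(matrix: pd.DataFrame, members: list[str], seed: int,
                 n_restarts: int, window_max: int, mapping_function: str,
                 min_informative: int, max_gap_cM: float | None,
                 cap_cM: float = _DIST_CAP_DEFAULT,
                 generation: int | None = None):
    sub = matrix.loc[members]
    recomb = pairwise_recombination(sub, min_informative=min_informative)
    bins = build_bins(sub, recomb, min_informative=min_informative)
    calls = np.vstack([b.calls for b in bins])
    order, cost = order_bins(calls, [b.bin_id for b in bins], seed=seed,
                             n_restarts=n_restarts, window_max=window_max)
    bins = [bins[i] for i in order]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pos = compute_distances(np.vstack([b.calls for b in bins]),
                                mapping_function=mapping_function,
                                min_informative=min_informative,
                                cap_cM=cap_cM, generation=generation)
    for b, p in zip(bins, pos):
        b.cM = float(p)
    if max_gap_cM is not None:
        return _split_on_gaps(bins, max_gap_cM), cost
    return [bins], cost


def build_map(
    matrix: pd.DataFrame,
    groups: dict[str, list[str]],
    seed: int = 0,
    n_restarts: int = 10,
    window_max: int = 5,
    mapping_function: str = "haldane",
    min_informative: int = 2,
    max_gap_cM: float | None = 30.0,
    iteration: int = 1,
    generation: int | None = None,
) -> GeneticMap:
    """Build an ordered, positioned map for the given linkage groups.

    ``groups`` maps group names to marker lists (from
    :func:`rilmap.grouping.cluster_linkage_groups` or an anchor file).
    Ordered groups are split at adjacent-bin gaps above ``max_gap_cM``
    (suffixing ``.2``, ``.3``, ... to the group name).
    """
    out: dict[str, list[GeneticBin]] = {}
    for gi, (name, members) in enumerate(sorted(groups.items())):
        parts, _ = _build_group(matrix, members, seed + gi, n_restarts,
                                window_max, mapping_function, min_informative,
                                max_gap_cM, generation=generation)
        for k, part in enumerate(parts):
            out[name if k == 0 else f"{name}.{k + 1}"] = part
    return GeneticMap(groups=out, lines=list(matrix.columns),
                      iteration=iteration)


def _mask_regions(matrix: pd.DataFrame, gmap: GeneticMap,
                  regions: list[HetRegion], symbol: str) -> pd.DataFrame:
    """Set calls inside het regions to ``symbol`` ('-' or 'H')."""
    out = matrix.copy()
    placed = gmap.marker_positions().set_index("marker")
    for reg in regions:
        in_lg = placed[placed["linkage_group"] == reg.linkage_group]
        sel = set(in_lg[(in_lg["cM"] >= reg.start_cM - 1e-9)
                        & (in_lg["cM"] <= reg.end_cM + 1e-9)].index)
        sel |= {m for m in reg.members if m in out.index}
        out.loc[sorted(sel), reg.ril_id] = symbol
    return out


def _apparent_dcos(matrix: pd.DataFrame, gmap: GeneticMap) -> list[tuple[str, str]]:
    """(marker, line) cells whose call disagrees with both agreeing flanks.

    Scans each line along each ordered group at bin resolution: a
    non-missing bin call whose nearest non-missing neighbours on both sides
    agree with each other but not with it is an apparent double crossover.
    All member markers of the offending bin that carry the discordant call
    are reported.
    """
    cells = []
    for lg, bins in gmap.groups.items():
        if len(bins) < 3:
            continue
        reps = [b.representative for b in bins]
        enc = encode_calls(matrix.loc[reps])
        for ci, line in enumerate(matrix.columns):
            col = enc[:, ci]
            nm = np.flatnonzero(col >= 0)
            for a, b, c in zip(nm[:-2], nm[1:-1], nm[2:]):
                if col[a] == col[c] != col[b]:
                    bad = "AB"[col[b]]
                    for m in bins[b].members:
                        if matrix.at[m, line] == bad:
                            cells.append((m, line))
    return cells


def _purge_weak_runs(matrix: pd.DataFrame, gmap: GeneticMap,
                     support: pd.DataFrame, min_support: int = 2,
                     max_run: int = 3) -> tuple[pd.DataFrame, int]:
    """Mask short call-runs backed only by discordant member SPPs.

    A maximal run of at most ``max_run`` identical non-missing calls, every
    one of which has SPP support below ``min_support``, that is flanked by
    calls of the other allele (or sits at a chromosome end) is the
    signature of a heterozygous or erroneous consensus call rather than a
    crossover; such runs are set to missing. This is the automated
    counterpart of removing SPP haplotypes inconsistent with their bin
    haplotype during visual curation.
    """
    out = matrix.copy()
    n_masked = 0
    for lg, bins in gmap.groups.items():
        ordered = [m for b in bins for m in sorted(b.members)]
        enc = encode_calls(out.loc[ordered])
        sup = support.reindex(index=ordered, columns=matrix.columns).fillna(0)
        sup = sup.to_numpy()
        for ci, line in enumerate(matrix.columns):
            col = enc[:, ci]
            nm = np.flatnonzero(col >= 0)
            if nm.size < 2:
                continue
            calls = col[nm]
            run_starts = np.flatnonzero(np.diff(calls) != 0) + 1
            bounds = np.concatenate([[0], run_starts, [calls.size]])
            for a, b in zip(bounds[:-1], bounds[1:]):
                if b - a > max_run:
                    continue
                idx = nm[a:b]
                if np.all(sup[idx, ci] < min_support):
                    for k in idx:
                        out.iat[out.index.get_loc(ordered[k]),
                                ci] = "-"
                        n_masked += 1
    return out, n_masked


def _reposition(gmap: GeneticMap, mapping_function: str,
                min_informative: int, generation: int) -> None:
    """Recompute bin positions with the exact finite-generation correction.

    Ordering and binning are scale-free; only the cM positions change, so
    the correction is applied once to the maps that are reported.
    """
    for bins in gmap.groups.values():
        if len(bins) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pos = compute_distances(np.vstack([b.calls for b in bins]),
                                    mapping_function=mapping_function,
                                    min_informative=min_informative,
                                    generation=generation)
        for b, p in zip(bins, pos):
            b.cM = float(p)


@dataclass
class MapIterationLog:
    iteration: int
    total_length: float
    n_bins: int
    n_masked: int = 0
    note: str = ""


@dataclass
class MapResult:
    """Final map plus per-iteration history."""

    final: GeneticMap
    iteration1: GeneticMap
    het_regions: list[HetRegion]
    log: list[MapIterationLog]
    corrected_matrix: pd.DataFrame


def iterate_map(
    matrix: pd.DataFrame,
    groups: dict[str, list[str]],
    seed: int = 0,
    n_restarts: int = 10,
    window_max: int = 5,
    mapping_function: str = "haldane",
    min_informative: int = 2,
    max_gap_cM: float | None = 30.0,
    window_cM: float = 5.0,
    min_windows: int = 2,
    miss_thresh: float = 0.4,
    min_crossovers: int = 2,
    spp_support: pd.DataFrame | None = None,
    min_support_spps: int = 2,
    generation: int | None = None,
) -> MapResult:
    """Run the four-iteration mapping loop with heterozygosity correction.

    Iteration 1 maps the raw calls. Iteration 2 masks calls inside detected
    heterozygous regions as missing and remaps. Iteration 3 re-detects the
    regions on the corrected order, writes them as explicit H calls, turns
    remaining apparent double crossovers into missing, and remaps.
    Iteration 4 restores double crossovers backed by unanimous multi-SPP
    support (``spp_support``: markers x lines, number of concordant
    no-missing member SPPs; 0/absent means unsupported), remaps, and merges
    bins that no longer recombine. If ordering oscillates between
    iterations 3 and 4, the iteration-4 result is kept with a warning.
    """
    log: list[MapIterationLog] = []

    map1 = build_map(matrix, groups, seed=seed, n_restarts=n_restarts,
                     window_max=window_max, mapping_function=mapping_function,
                     min_informative=min_informative, max_gap_cM=max_gap_cM,
                     iteration=1)
    log.append(MapIterationLog(1, map1.total_length, map1.n_bins))

    regions = detect_het_regions(map1, matrix, window_cM=window_cM,
                                 min_windows=min_windows,
                                 miss_thresh=miss_thresh,
                                 min_crossovers=min_crossovers)
    m2 = _mask_regions(matrix, map1, regions, "-")
    n_masked2 = int((m2.to_numpy() != matrix.to_numpy()).sum())
    map2 = build_map(m2, groups, seed=seed + 101, n_restarts=n_restarts,
                     window_max=window_max, mapping_function=mapping_function,
                     min_informative=min_informative, max_gap_cM=max_gap_cM,
                     iteration=2)
    log.append(MapIterationLog(2, map2.total_length, map2.n_bins, n_masked2,
                               f"{len(regions)} het regions masked"))

    regions3 = detect_het_regions(map2, matrix, window_cM=window_cM,
                                  min_windows=min_windows,
                                  miss_thresh=miss_thresh,
                                  min_crossovers=min_crossovers)
    regions3 = _combine_regions(map2, [regions3, regions], window_cM)
    m3 = _mask_regions(matrix, map2, regions3, "H")
    dcos = _apparent_dcos(m3, map2)
    for m, line in dcos:
        m3.at[m, line] = "-"
    map3 = build_map(m3, groups, seed=seed + 202, n_restarts=n_restarts,
                     window_max=window_max, mapping_function=mapping_function,
                     min_informative=min_informative, max_gap_cM=max_gap_cM,
                     iteration=3)
    log.append(MapIterationLog(3, map3.total_length, map3.n_bins, len(dcos),
                               f"{len(regions3)} regions set H, "
                               f"{len(dcos)} double crossovers removed"))

    m4 = m3.copy()
    restored = 0
    n_purged = 0
    if spp_support is not None:
        m4, n_purged = _purge_weak_runs(m4, map3, spp_support,
                                        min_support=min_support_spps)
        for m, line in dcos:
            try:
                sup = int(spp_support.at[m, line])
            except (KeyError, ValueError):
                sup = 0
            if sup >= min_support_spps:
                m4.at[m, line] = matrix.at[m, line]
                restored += 1
    map4 = build_map(m4, groups, seed=seed + 303, n_restarts=n_restarts,
                     window_max=window_max, mapping_function=mapping_function,
                     min_informative=min_informative, max_gap_cM=max_gap_cM,
                     iteration=4)
    if map4.total_length > map3.total_length + 1e-6 and restored == 0:
        warnings.warn("ordering oscillated between iterations 3 and 4; "
                      "keeping the iteration-4 result")
    if generation is not None:
        _reposition(map1, mapping_function, min_informative, generation)
        _reposition(map4, mapping_function, min_informative, generation)
    log.append(MapIterationLog(4, map4.total_length, map4.n_bins, restored,
                               f"{restored} double crossovers restored, "
                               f"{n_purged} weak calls purged"))

    return MapResult(final=map4, iteration1=map1, het_regions=regions3,
                     log=log, corrected_matrix=m4)
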