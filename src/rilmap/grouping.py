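"""Pairwise recombination, linkage grouping, and pseudolinkage detection.

Recombination between marker pairs in a selfed RIL population is observed as
the fraction R of lines recombinant between the pair; the per-meiosis
recombination fraction r follows from the RIL-at-fixation relation
R = 2r/(1+2r). Markers are clustered into linkage groups by single-linkage
transitive closure over pairs passing both an r and a LOD threshold.

A reciprocal translocation segregating in the cross suppresses recovery of
recombinants across the breakpoints and fuses two chromosomes into one
apparent cluster (pseudolinkage); :func:`detect_pseudolinkage` scans the
ordered recombination heat matrix for the characteristic pattern — a cut
with mostly-unlinked blocks joined only through a localized low-r block —
and splits the cluster, localizing the breakpoint.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "RecombinationMatrix",
    "LinkageGroupSet",
    "PseudolinkageReport",
    "encode_calls",
    "pairwise_recombination",
    "ril_correction",
    "ril_observed",
    "ril_observed_finite",
    "ril_correction_finite",
    "cluster_linkage_groups",
    "detect_pseudolinkage",
]


def encode_calls(matrix: pd.DataFrame, het_as_missing: bool = True) -> np.ndarray:
    """Encode {A,B,H,-} calls as int8 (A=0, B=1, missing=-1).

    H is treated as missing for recombination counting in a RIL design
    unless ``het_as_missing`` is False (then H encodes as 2).
    """
    vals = matrix.to_numpy(dtype="U1")
    out = np.full(vals.shape, -1, dtype=np.int8)
    out[vals == "A"] = 0
    out[vals == "B"] = 1
    if not het_as_missing:
        out[vals == "H"] = 2
    bad = ~np.isin(vals, np.array(["A", "B", "H", "-"]))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"unknown call {vals[i, j]!r} at marker {matrix.index[i]!r}, "
            f"line {matrix.columns[j]!r}")
    return out


def ril_correction(R: np.ndarray | float) -> np.ndarray | float:
    """Map observed RIL recombinant fraction R to per-meiosis r.

    Inverts R = 2r/(1+2r) (selfed RILs at fixation): r = R/(2-2R),
    clamped to [0, 0.5].
    """
    R = np.asarray(R, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(R >= 1.0, 0.5, R / (2.0 - 2.0 * R))
    return np.minimum(r, 0.5)


def ril_observed(r: np.ndarray | float) -> np.ndarray | float:
    """Expected observed RIL recombinant fraction for per-meiosis r."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


def _selfing_states(r: float, generations: int) -> np.ndarray:
    """Two-locus genotype distribution after ``generations`` selfings from F1.

    Exact recursion over the ten unordered two-locus diploid genotypes,
    starting from the coupling double heterozygote AB/ab. Gametes: index
    0=AB, 1=Ab, 2=aB, 3=ab.
    """
    pairs = [(i, j) for i in range(4) for j in range(i, 4)]
    pair_index = {p: k for k, p in enumerate(pairs)}

    def gametes(i, j):
        g = np.zeros(4)
        if (i, j) == (0, 3):  # coupling double het
            g[[0, 3]] = (1 - r) / 2
            g[[1, 2]] = r / 2
        elif (i, j) == (1, 2):  # repulsion double het
            g[[1, 2]] = (1 - r) / 2
            g[[0, 3]] = r / 2
        else:
            g[i] += 0.5
            g[j] += 0.5
        return g

    T = np.zeros((len(pairs), len(pairs)))
    for k, (i, j) in enumerate(pairs):
        g = gametes(i, j)
        off = np.outer(g, g)
        for a in range(4):
            for b in range(4):
                T[k, pair_index[(min(a, b), max(a, b))]] += off[a, b]
    p = np.zeros(len(pairs))
    p[pair_index[(0, 3)]] = 1.0
    for _ in range(generations):
        p = p @ T
    return p


def ril_observed_finite(r: float, generation: int) -> float:
    """Expected recombinant fraction among double-homozygous F_t lines.

    Lines are scored only when homozygous at both loci (heterozygous calls
    are missing in this assay); ``generation`` is the filial generation
    (F7 means six selfings after the F1).
    """
    p = _selfing_states(float(r), generation - 1)
    # unordered pairs: 0=(AB,AB) 4=(Ab,Ab) 7=(aB,aB) 9=(ab,ab)
    hom = p[0] + p[4] + p[7] + p[9]
    rec = p[4] + p[7]
    return float(rec / hom) if hom > 0 else 0.0


@lru_cache(maxsize=8)
def _finite_grid(generation: int) -> tuple[tuple[float, ...], tuple[float, ...]]:
    grid_r = np.linspace(0.0, 0.5, 201)
    grid_R = np.array([ril_observed_finite(v, generation) for v in grid_r])
    return tuple(grid_r), tuple(grid_R)


def ril_correction_finite(R: np.ndarray | float, generation: int):
    """Invert the exact finite-generation RIL relation (per-meiosis r from R)."""
    grid_r, grid_R = _finite_grid(int(generation))
    R = np.asarray(R, dtype=float)
    out = np.interp(R, np.array(grid_R), np.array(grid_r))
    return np.minimum(out, 0.5)


@dataclass
class RecombinationMatrix:
    """Pairwise recombination estimates over a marker set."""

    markers: list[str]
    n_informative: np.ndarray  # (m, m) int
    n_recombinant: np.ndarray  # (m, m) int
    R_hat: np.ndarray  # observed fraction, NaN where uninformative
    r_hat: np.ndarray  # RIL-corrected, in [0, 0.5]
    lod: np.ndarray  # linkage LOD (<= 0 when R_hat >= 0.5)
    min_informative: int = 2

    def index_of(self, marker: str) -> int:
        return self.markers.index(marker)

    def submatrix(self, subset: list[str]) -> "RecombinationMatrix":
        idx = np.array([self.markers.index(m) for m in subset])
        return RecombinationMatrix(
            markers=list(subset),
            n_informative=self.n_informative[np.ix_(idx, idx)],
            n_recombinant=self.n_recombinant[np.ix_(idx, idx)],
            R_hat=self.R_hat[np.ix_(idx, idx)],
            r_hat=self.r_hat[np.ix_(idx, idx)],
            lod=self.lod[np.ix_(idx, idx)],
            min_informative=self.min_informative,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of the upper triangle."""
        m = len(self.markers)
        iu, ju = np.triu_indices(m, k=1)
        return pd.DataFrame({
            "marker1": [self.markers[i] for i in iu],
            "marker2": [self.markers[j] for j in ju],
            "n_informative": self.n_informative[iu, ju],
            "n_recombinant": self.n_recombinant[iu, ju],
            "R_hat": self.R_hat[iu, ju],
            "r_hat": self.r_hat[iu, ju],
            "lod": self.lod[iu, ju],
        })


def _linkage_lod(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    """One-sided linkage LOD: binomial LR of R_hat vs 0.5, signed.

    Positive for R_hat < 0.5, non-positive for R_hat >= 0.5 (repulsion or
    free recombination carries no linkage evidence).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        R = k / n
        term1 = np.where(k > 0, k * np.log10(np.where(R > 0, R, 1.0) / 0.5), 0.0)
        term2 = np.where(n - k > 0,
                         (n - k) * np.log10(np.where(R < 1, 1.0 - R, 1.0) / 0.5),
                         0.0)
        lod = term1 + term2
    return np.where(R < 0.5, lod, -np.abs(lod))


def pairwise_recombination(
    matrix: pd.DataFrame,
    min_informative: int = 2,
) -> RecombinationMatrix:
    """Estimate R, r and LOD for every marker pair.

    H calls are treated as missing. Pairs with fewer than ``min_informative``
    jointly non-missing lines get NaN estimates. Markers with no non-missing
    calls at all are excluded with a warning.
    """
    enc = encode_calls(matrix)
    nonmiss_counts = (enc >= 0).sum(axis=1)
    keep = nonmiss_counts > 0
    if not keep.all():
        dropped = list(matrix.index[~keep])
        warnings.warn(f"markers with no calls excluded: {dropped}")
        enc = enc[keep]
    names = list(matrix.index[keep])

    valid = (enc >= 0).astype(np.float32)
    a = np.where(enc >= 0, enc, 0).astype(np.float32)
    n_inf = valid @ valid.T
    # recombinant count = pairs where both valid and calls differ
    same = a @ a.T + (valid - a) @ (valid - a).T
    n_rec = n_inf - same
    n_inf = np.rint(n_inf).astype(np.int64)
    n_rec = np.rint(n_rec).astype(np.int64)

    with np.errstate(divide="ignore", invalid="ignore"):
        R_hat = np.where(n_inf > 0, n_rec / np.maximum(n_inf, 1), np.nan)
    R_hat = np.where(n_inf >= min_informative, R_hat, np.nan)
    r_hat = np.where(np.isnan(R_hat), np.nan, ril_correction(np.nan_to_num(R_hat)))
    lod = np.where(n_inf >= min_informative,
                   _linkage_lod(np.maximum(n_inf, 1), n_rec), np.nan)
    np.fill_diagonal(R_hat, 0.0)
    np.fill_diagonal(r_hat, 0.0)
    return RecombinationMatrix(
        markers=names, n_informative=n_inf, n_recombinant=n_rec,
        R_hat=R_hat, r_hat=r_hat, lod=lod, min_informative=min_informative)


@dataclass
class LinkageGroupSet:
    """Disjoint marker clusters plus unassociated singletons."""

    clusters: list[list[str]]
    singletons: list[str] = field(default_factory=list)
    pseudolinkage_flags: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.clusters)


def cluster_linkage_groups(
    recomb: RecombinationMatrix,
    max_r: float = 0.3,
    min_lod: float = 5.0,
) -> LinkageGroupSet:
    """Single-linkage transitive closure over pairs with r <= max_r, LOD >= min_lod.

    Cluster membership is invariant to marker input order; clusters are
    reported sorted by size (descending) then by smallest member id, with
    members in input order. Single-marker components are reported as
    unassociated singletons.
    """
    m = len(recomb.markers)
    g = nx.Graph()
    g.add_nodes_from(range(m))
    good = (recomb.r_hat <= max_r) & (recomb.lod >= min_lod)
    iu, ju = np.triu_indices(m, k=1)
    for i, j in zip(iu[good[iu, ju]], ju[good[iu, ju]]):
        g.add_edge(int(i), int(j))
    comps = [sorted(c) for c in nx.connected_components(g)]
    clusters, singles = [], []
    for comp in comps:
        names = [recomb.markers[i] for i in comp]
        if len(names) == 1:
            singles.append(names[0])
        else:
            clusters.append(names)
    clusters.sort(key=lambda c: (-len(c), min(c)))
    singles.sort()
    return LinkageGroupSet(clusters=clusters, singletons=singles)


@dataclass
class PseudolinkageReport:
    """Result of scanning one ordered cluster for a translocation signature."""

    split: bool
    groups: tuple[list[str], list[str]] | None = None
    cut_index: int | None = None
    median_cross_r: float | None = None
    linking_fraction: float | None = None
    linking_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    breakpoint_markers: tuple[str, str] | None = None
    breakpoint_bin: str | None = None


def _arms_at(d: np.ndarray, j: int, neighbors: np.ndarray,
             tol_cM: float) -> list[list[int]]:
    """Partition bins linked to candidate junction ``j`` into arms.

    Two neighbours lie on the same arm iff their mutual map distance is
    consistent with collinearity through ``j``: d(x,y) ~ |d(j,x) - d(j,y)|.
    Assignment grows arms tip-first (descending distance from the
    junction), where different arms are maximally separated; each bin joins
    the arm with the smallest median discrepancy against existing members —
    robust to single noisy pairs. Bins close to the junction are ambiguous
    by construction and attach to whichever arm fits best.
    """
    order = neighbors[np.argsort(-d[j, neighbors])]
    arms: list[list[int]] = []
    for x in order:
        best_arm, best_dev = None, None
        for arm in arms:
            devs = [abs(d[x, m] - abs(d[j, x] - d[j, m])) for m in arm]
            dev = float(np.median(devs))
            if dev <= tol_cM and (best_dev is None or dev < best_dev):
                best_arm, best_dev = arm, dev
        if best_arm is None:
            arms.append([int(x)])
        else:
            best_arm.append(int(x))
    return arms


def detect_pseudolinkage(
    recomb: RecombinationMatrix,
    ordered_markers: list[str],
    link_r: float = 0.30,
    break_r: float = 0.35,
    min_arm_cM: float = 10.0,
    tol_cM: float = 8.0,
    cap_cM: float = 60.0,
    arm_radius_cM: float = 20.0,
    min_arm_members: int = 3,
    max_residual_cM: float = 6.0,
) -> PseudolinkageReport:
    """Scan a marker cluster for a pseudolinkage junction.

    A cluster holding one real chromosome is metrically a path: for any bin
    J, its linked neighbours fall on at most two collinear arms. A
    reciprocal translocation heterozygous in the cross transmits only
    parental configurations, so the breakpoint-flanking markers of both
    chromosomes co-segregate: the cluster becomes a star of up to four arms
    meeting at a (marker-dense) junction bin, with map distances additive
    through it. The detector scores every bin as a candidate junction,
    partitioning its linked neighbours (r <= ``link_r``) into collinear
    arms; a junction with three or more arms spanning at least
    ``min_arm_cM``, or with two such arms whose cross pairs are unlinked
    (median r >= ``break_r``, a localized linking block joining otherwise
    separate blocks), flags the cluster. The best junction (most arms, then
    smallest additivity residual) is the breakpoint bin, and the cluster is
    split into two groups by arm membership.
    """
    sub = recomb.submatrix(ordered_markers)
    r = sub.r_hat
    m = len(ordered_markers)
    if m < 8:
        return PseudolinkageReport(split=False)
    with np.errstate(invalid="ignore"):
        d = np.where(np.isfinite(r) & (r < 0.5),
                     -50.0 * np.log(np.maximum(1.0 - 2.0 * np.minimum(r, 0.49),
                                               1e-9)),
                     cap_cM)
    d = np.minimum(d, cap_cM)
    np.fill_diagonal(d, 0.0)

    best = None  # (n_big_arms, -residual, j, arms)
    for j in range(m):
        linked = np.flatnonzero(np.isfinite(r[j]) & (r[j] <= link_r)
                                & (d[j] <= arm_radius_cM))
        linked = linked[linked != j]
        if linked.size < 4:
            continue
        arms = _arms_at(d, j, linked, tol_cM)
        big = [a for a in arms if len(a) >= min_arm_members
               and max(d[j, x] for x in a) >= min_arm_cM]
        if len(big) < 2:
            continue
        ok = False
        if len(big) >= 3:
            ok = True
        elif len(big) == 2:
            cross = np.array([r[x, y] for x in big[0] for y in big[1]
                              if np.isfinite(r[x, y])])
            ok = cross.size > 0 and float(np.median(cross)) >= break_r
        if not ok:
            continue
        pair_resids = []
        collinear_pair = False
        for a1, a2 in itertools.combinations(big, 2):
            resid, coll = [], []
            for x in a1:
                for y in a2:
                    if np.isfinite(r[x, y]) and r[x, y] < 0.45:
                        resid.append(abs(d[x, y] - (d[j, x] + d[j, y])))
                        coll.append(abs(d[x, y] - abs(d[j, x] - d[j, y])))
            if not resid:
                pair_resids.append(cap_cM)
                continue
            pair_resids.append(float(np.median(resid)))
            # a fake arm split off a collinear neighbour fits the
            # collinear model at least as well as the additive one
            if np.median(resid) >= np.median(coll):
                collinear_pair = True
        # every pair of arms must be additive through j; the worst pair is
        # the gate
        residual = max(pair_resids) if pair_resids else cap_cM
        if len(big) >= 3 and collinear_pair:
            continue
        # additivity residual is the sharp localizer: it grows linearly with
        # the candidate's offset from the true junction, and a fake star
        # produced by noise-splitting one collinear arm is far from
        # additive. Arm count only separates the star (>=3) from the
        # two-block pattern; beyond three arms it reflects noise splits, so
        # it is capped.
        if len(big) >= 3 and residual > max_residual_cM:
            continue
        key = (min(len(big), 3), -residual)
        if best is None or key > best[0]:
            best = (key, j, big)
    if best is None:
        return PseudolinkageReport(split=False)
    _, j, big = best
    hub = ordered_markers[j]
    # two-group split: largest arm on one side, second largest on the other;
    # remaining arms and unassigned bins join the nearer of the two. Pairing
    # arms into the original chromosomes needs external anchors.
    big.sort(key=len, reverse=True)
    g1 = set(big[0])
    g2 = set(big[1])
    for arm in big[2:]:
        tips = {1: np.median([d[x, y] for x in arm for y in big[0]]),
                2: np.median([d[x, y] for x in arm for y in big[1]])}
        (g1 if tips[1] >= tips[2] else g2).update(arm)
    for x in range(m):
        if x == j or x in g1 or x in g2:
            continue
        d1 = np.median([d[x, y] for y in g1])
        d2 = np.median([d[x, y] for y in g2])
        (g1 if d1 <= d2 else g2).add(x)
    g1.add(j)
    groups = ([ordered_markers[i] for i in sorted(g1)],
              [ordered_markers[i] for i in sorted(g2)])
    cross_vals = np.array([r[x, y] for x in g1 for y in g2
                           if np.isfinite(r[x, y])])
    linking = [(ordered_markers[x], ordered_markers[y], float(r[x, y]))
               for x in g1 for y in g2
               if np.isfinite(r[x, y]) and r[x, y] <= 0.25]
    linking.sort(key=lambda t: t[2])
    return PseudolinkageReport(
        split=True,
        groups=groups,
        cut_index=j,
        median_cross_r=(float(np.median(cross_vals))
                        if cross_vals.size else None),
        linking_fraction=(len(linking) / max(cross_vals.size, 1)),
        linking_pairs=linking,
        breakpoint_markers=(hub, hub),
        breakpoint_bin=hub,
    )
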