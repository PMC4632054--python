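"""Synthetic recombinant-inbred-line (RIL) populations with array genotyping.

Emulates biparental RIL populations produced by single-seed descent (SSD)
from an F2, genotyped on a tiling expression array: per-unigene probe
intensity signals with bimodal allele separation, replicate hybridizations,
residual heterozygosity, and (optionally) a reciprocal translocation
segregating in the cross, which induces pseudolinkage between the two
chromosomes involved.

The generator returns both the true genotypes (ground truth for
parameter-recovery tests) and the observable layers: a noisy probe-intensity
matrix, or a marker call matrix carrying the characteristic artifact of
intensity-based genotyping of heterozygotes (missing:A:B at 2:1:1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "CrossDesign",
    "SimTruth",
    "pericentromeric_profile",
    "simulate_population",
    "emit_intensities",
    "emit_call_matrix",
]

CALLS = ("A", "B", "H", "-")


def pericentromeric_profile(width: float = 0.5, suppression: float = 0.05) -> Callable:
    """Relative recombination intensity along a chromosome.

    Returns ``f(x)`` for physical fraction ``x`` in [0, 1]: intensity 1 on the
    chromosome arms and ``suppression`` inside the central window of the given
    fractional ``width``, modelling pericentromeric crossover suppression.
    """
    lo, hi = 0.5 - width / 2.0, 0.5 + width / 2.0

    def profile(x):
        x = np.asarray(x, dtype=float)
        return np.where((x >= lo) & (x <= hi), suppression, 1.0)

    return profile


@dataclass(frozen=True)
class GenomeModel:
    """Map-level genome description for the simulator.

    ``recomb_profile`` gives, per chromosome, relative crossover intensity as
    a function of physical fraction; internally it is normalized so that its
    integral over the chromosome equals the chromosome's genetic length.
    ``None`` means a uniform rate.
    """

    chrom_lengths_cM: tuple[float, ...]
    chrom_lengths_Mb: tuple[float, ...] | None = None
    recomb_profile: tuple[Callable | None, ...] | None = None

    def __post_init__(self):
        cm = tuple(float(v) for v in self.chrom_lengths_cM)
        object.__setattr__(self, "chrom_lengths_cM", cm)
        if any(v <= 0 for v in cm):
            raise ValueError("chromosome cM lengths must be positive")
        if self.chrom_lengths_Mb is None:
            object.__setattr__(
                self, "chrom_lengths_Mb", tuple(v / 2.0 for v in cm)
            )
        else:
            mb = tuple(float(v) for v in self.chrom_lengths_Mb)
            if len(mb) != len(cm):
                raise ValueError("chrom_lengths_Mb length mismatch")
            if any(v <= 0 for v in mb):
                raise ValueError("chromosome Mb lengths must be positive")
            object.__setattr__(self, "chrom_lengths_Mb", mb)
        if self.recomb_profile is not None and len(self.recomb_profile) != len(cm):
            raise ValueError("recomb_profile must give one entry per chromosome")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths_cM)

    def physical_to_genetic(self, chrom: int, mb: np.ndarray) -> np.ndarray:
        """Convert physical positions (Mb) on ``chrom`` to cM via the profile."""
        L_mb = self.chrom_lengths_Mb[chrom]
        L_cm = self.chrom_lengths_cM[chrom]
        mb = np.asarray(mb, dtype=float)
        prof = None if self.recomb_profile is None else self.recomb_profile[chrom]
        if prof is None:
            return mb / L_mb * L_cm
        # numeric CDF of the profile on a fine grid
        grid = np.linspace(0.0, 1.0, 2001)
        dens = np.maximum(np.asarray(prof(grid), dtype=float), 0.0)
        if not np.all(np.isfinite(dens)):
            raise ValueError("recomb_profile must be finite and nonnegative")
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0)])
        if cdf[-1] <= 0:
            raise ValueError("recomb_profile integrates to zero")
        cdf = cdf / cdf[-1] * L_cm
        return np.interp(mb / L_mb, grid, cdf)


@dataclass(frozen=True)
class CrossDesign:
    """Design of the biparental cross.

    ``final_generation`` counts filial generations: F7 RILs have undergone six
    rounds of selfing after the F1, giving per-locus residual heterozygosity
    (1/2)^6. ``translocation`` is ``(chromA, chromB, breakA_cM, breakB_cM)``
    for a reciprocal translocation carried by parent B.
    """

    n_rils: int
    final_generation: int = 7
    translocation: tuple[int, int, float, float] | None = None
    polymorphic_fraction: float = 1.0
    suppress_cM: float = 5.0  # crossover suppression radius around a breakpoint
    # in translocation heterozygotes

    def __post_init__(self):
        if self.n_rils < 1:
            raise ValueError("n_rils must be positive")
        if self.final_generation < 3:
            raise ValueError("final_generation must be >= 3 (F2 is the first selfed)")
        if not (0.0 < self.polymorphic_fraction <= 1.0):
            raise ValueError("polymorphic_fraction must be in (0, 1]")


@dataclass
class SimTruth:
    """Ground truth of one simulated population."""

    true_genotypes: pd.DataFrame  # markers x RILs, {A,B,H}
    true_order: dict[int, list[tuple[str, float]]]  # chrom -> [(marker, cM)]
    marker_chrom: dict[str, int]
    marker_cM: dict[str, float]
    marker_Mb: dict[str, float]
    het_regions: list[tuple[str, int, float, float]]  # (ril, chrom, start, end)
    breakpoint: tuple[int, float] | None = None
    monomorphic: list[str] = field(default_factory=list)


def _meiosis_origins(pos: np.ndarray, length_cM: float, hap0: np.ndarray,
                     hap1: np.ndarray, rng: np.random.Generator,
                     forbidden: list[tuple[float, float]] | None = None,
                     phase_at: float | None = None,
                     phase_value: int | None = None) -> np.ndarray:
    """One gamete from a pair of haplotypes.

    Crossover count ~ Poisson(length/100), positions uniform in cM (no
    interference). ``forbidden`` intervals reject crossovers (quadrivalent
    suppression); ``phase_at``/``phase_value`` pins which haplotype the gamete
    follows at a given position (alternate segregation of a translocation).
    """
    n_xo = rng.poisson(length_cM / 100.0)
    xo = np.sort(rng.uniform(0.0, length_cM, n_xo))
    if forbidden:
        keep = np.ones(xo.size, dtype=bool)
        for lo, hi in forbidden:
            keep &= ~((xo >= lo) & (xo <= hi))
        xo = xo[keep]
    k = np.searchsorted(xo, pos, side="right")
    if phase_at is None:
        start = int(rng.integers(2))
    else:
        k_at = int(np.searchsorted(xo, phase_at, side="right"))
        start = (phase_value + k_at) % 2
    phase = (start + k) % 2
    return np.where(phase == 0, hap0, hap1)


def _self_once(haps: dict, struct: list[int], design: CrossDesign,
               chrom_pos: dict[int, np.ndarray], lengths: Sequence[float],
               rng: np.random.Generator) -> tuple[dict, list[int]]:
    """One round of selfing: two independent meioses, then union.

    ``haps[c]`` is a (2, n_markers_c) origin array; ``struct`` holds the
    translocation-configuration allele of each haplotype (0 = normal,
    1 = translocated), or [0, 0] when no translocation segregates.
    """
    tr = design.translocation
    new_haps = {c: np.empty_like(haps[c]) for c in haps}
    new_struct = [0, 0]
    for g in range(2):  # the two gametes
        if tr is None or struct[0] == struct[1] == 0:
            for c in haps:
                new_haps[c][g] = _meiosis_origins(
                    chrom_pos[c], lengths[c], haps[c][0], haps[c][1], rng)
            new_struct[g] = struct[0] if tr is not None else 0
        else:
            ca, cb, bpa, bpb = tr
            others = [c for c in haps if c not in (ca, cb)]
            for c in others:
                new_haps[c][g] = _meiosis_origins(
                    chrom_pos[c], lengths[c], haps[c][0], haps[c][1], rng)
            if struct[0] != struct[1]:
                # rearrangement heterozygote: quadrivalent, alternate
                # segregation. The gamete takes one parental configuration Z;
                # near both breakpoints it must follow the haplotype carrying
                # that configuration, and crossovers are suppressed within
                # suppress_cM of the breakpoints.
                z = int(rng.integers(2))
                h_star = 0 if struct[0] == z else 1
                s = design.suppress_cM
                for c, bp in ((ca, bpa), (cb, bpb)):
                    new_haps[c][g] = _meiosis_origins(
                        chrom_pos[c], lengths[c], haps[c][0], haps[c][1], rng,
                        forbidden=[(bp - s, bp + s)],
                        phase_at=bp, phase_value=h_star)
                new_struct[g] = z
            else:
                # translocation homozygote: meiosis on the rearranged
                # chromosomes T1 = A[0,bpA) + B[bpB,endB] and
                # T2 = B[0,bpB) + A[bpA,endA].
                pa, pb = chrom_pos[ca], chrom_pos[cb]
                la, lb = lengths[ca], lengths[cb]
                in_a_left = pa < bpa
                in_b_left = pb < bpb
                t1_pos = np.concatenate([pa[in_a_left],
                                         bpa + (pb[~in_b_left] - bpb)])
                t2_pos = np.concatenate([pb[in_b_left],
                                         bpb + (pa[~in_a_left] - bpa)])
                t1_len = bpa + (lb - bpb)
                t2_len = bpb + (la - bpa)
                h1_0 = np.concatenate([haps[ca][0][in_a_left],
                                       haps[cb][0][~in_b_left]])
                h1_1 = np.concatenate([haps[ca][1][in_a_left],
                                       haps[cb][1][~in_b_left]])
                g1 = _meiosis_origins(t1_pos, t1_len, h1_0, h1_1, rng)
                h2_0 = np.concatenate([haps[cb][0][in_b_left],
                                       haps[ca][0][~in_a_left]])
                h2_1 = np.concatenate([haps[cb][1][in_b_left],
                                       haps[ca][1][~in_a_left]])
                g2 = _meiosis_origins(t2_pos, t2_len, h2_0, h2_1, rng)
                na_left = int(in_a_left.sum())
                nb_left = int(in_b_left.sum())
                ga = np.empty(pa.size, dtype=haps[ca].dtype)
                gb = np.empty(pb.size, dtype=haps[cb].dtype)
                ga[in_a_left] = g1[:na_left]
                gb[~in_b_left] = g1[na_left:]
                gb[in_b_left] = g2[:nb_left]
                ga[~in_a_left] = g2[nb_left:]
                new_haps[ca][g] = ga
                new_haps[cb][g] = gb
                new_struct[g] = struct[0]
    return new_haps, new_struct


def _default_positions(genome: GenomeModel, markers_per_chrom, rng,
                       placement: str):
    """Marker physical positions (Mb); cM follows via the recomb profile."""
    positions = {}
    for c in range(genome.n_chromosomes):
        n = markers_per_chrom[c] if not np.isscalar(markers_per_chrom) \
            else int(markers_per_chrom)
        L = genome.chrom_lengths_Mb[c]
        if n == 0:
            positions[c] = np.array([])
            continue
        if placement == "grid":
            mb = np.linspace(0.0, L, n) if n > 1 else np.array([L / 2.0])
        else:
            mb = np.sort(rng.uniform(0.0, L, n))
        positions[c] = mb
    return positions


def simulate_population(
    genome: GenomeModel,
    design: CrossDesign,
    seed: int,
    markers_per_chrom: int | Sequence[int] = 50,
    marker_positions_Mb: dict[int, np.ndarray] | None = None,
    placement: str = "grid",
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a RIL population by single-seed descent.

    Returns the true genotype matrix (markers x RILs, values in {A,B,H}) and
    the :class:`SimTruth` record. Markers are placed on each chromosome
    either on an even physical grid (default), uniformly at random
    (``placement="random"``), or at the supplied physical positions;
    co-positioned markers are legal and yield identical genotype columns.
    """
    rng = np.random.default_rng(seed)
    if marker_positions_Mb is None:
        marker_positions_Mb = _default_positions(
            genome, markers_per_chrom, rng, placement)

    chrom_pos_cM: dict[int, np.ndarray] = {}
    names: dict[int, list[str]] = {}
    marker_chrom, marker_cM, marker_Mb = {}, {}, {}
    true_order: dict[int, list[tuple[str, float]]] = {}
    for c in range(genome.n_chromosomes):
        mb = np.asarray(marker_positions_Mb.get(c, np.array([])), dtype=float)
        if mb.size == 0:
            warnings.warn(f"chromosome {c} has no markers and is omitted")
            continue
        if mb.min() < 0 or mb.max() > genome.chrom_lengths_Mb[c]:
            raise ValueError(f"marker positions outside chromosome {c}")
        order = np.argsort(mb, kind="stable")
        mb = mb[order]
        cm = genome.physical_to_genetic(c, mb)
        chrom_pos_cM[c] = cm
        names[c] = [f"UG{c + 1:02d}_{i:04d}" for i in range(mb.size)]
        true_order[c] = list(zip(names[c], cm.tolist()))
        for nm, p_cm, p_mb in zip(names[c], cm, mb):
            marker_chrom[nm] = c
            marker_cM[nm] = float(p_cm)
            marker_Mb[nm] = float(p_mb)

    tr = design.translocation
    if tr is not None:
        ca, cb, bpa, bpb = tr
        if ca not in chrom_pos_cM or cb not in chrom_pos_cM:
            raise ValueError("translocation chromosome has no markers")
        for c, bp in ((ca, bpa), (cb, bpb)):
            if not (0.0 < bp < genome.chrom_lengths_cM[c]):
                raise ValueError("translocation breakpoint outside chromosome")

    chroms = sorted(chrom_pos_cM)
    lengths = genome.chrom_lengths_cM
    n_selfings = design.final_generation - 1

    ril_names = [f"RIL{i + 1:03d}" for i in range(design.n_rils)]
    geno_cols = {}
    het_regions: list[tuple[str, int, float, float]] = []
    for ril in ril_names:
        # F1: haplotype 0 from parent A (origin 0), haplotype 1 from parent B
        haps = {c: np.vstack([np.zeros(chrom_pos_cM[c].size, dtype=np.int8),
                              np.ones(chrom_pos_cM[c].size, dtype=np.int8)])
                for c in chroms}
        struct = [0, 1] if tr is not None else [0, 0]
        for _ in range(n_selfings):
            haps, struct = _self_once(haps, struct, design, chrom_pos_cM,
                                      lengths, rng)
        calls = []
        for c in chroms:
            h0, h1 = haps[c]
            col = np.where(h0 == h1, np.where(h0 == 0, "A", "B"), "H")
            calls.append(col)
            het = col == "H"
            if het.any():
                idx = np.flatnonzero(het)
                splits = np.flatnonzero(np.diff(idx) > 1)
                starts = np.concatenate([[0], splits + 1])
                ends = np.concatenate([splits, [idx.size - 1]])
                for s, e in zip(starts, ends):
                    het_regions.append(
                        (ril, c, float(chrom_pos_cM[c][idx[s]]),
                         float(chrom_pos_cM[c][idx[e]])))
        geno_cols[ril] = np.concatenate(calls)

    all_names = [nm for c in chroms for nm in names[c]]
    truth_df = pd.DataFrame(geno_cols, index=pd.Index(all_names, name="marker"))

    monomorphic: list[str] = []
    if design.polymorphic_fraction < 1.0:
        mono_mask = rng.random(len(all_names)) > design.polymorphic_fraction
        monomorphic = [nm for nm, m in zip(all_names, mono_mask) if m]
        truth_df = truth_df.drop(index=monomorphic)

    truth = SimTruth(
        true_genotypes=truth_df,
        true_order=true_order,
        marker_chrom=marker_chrom,
        marker_cM=marker_cM,
        marker_Mb=marker_Mb,
        het_regions=het_regions,
        breakpoint=(tr[0], tr[2]) if tr is not None else None,
        monomorphic=monomorphic,
    )
    return truth_df, truth


def emit_call_matrix(
    truth: pd.DataFrame,
    miss_rate: float = 0.025,
    error_rate: float = 1e-4,
    seed: int = 0,
    spps_per_marker: int = 7,
    return_support: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Observable marker calls from true genotypes.

    Homozygous calls are flipped with ``error_rate`` and masked with
    ``miss_rate``; heterozygous truth is emitted as missing/A/B with
    probabilities 1/2, 1/4, 1/4 — the artifact of requiring two intensity
    replicates, each of which resolves a heterozygote to either homozygous
    mode, to agree.

    With ``return_support`` a second matrix gives the number of concordant
    non-missing member SPPs behind each call: a faithfully emitted
    homozygous call is backed by all ``spps_per_marker`` SPPs of its
    unigene, while calls arising from a heterozygote or a consensus error
    carry support 1 (their member SPPs disagree) and missing calls 0. The
    map-iteration loop uses this to restore genuine double crossovers.
    """
    for name, rate in (("miss_rate", miss_rate), ("error_rate", error_rate)):
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    vals = truth.to_numpy(dtype="U1")
    out = vals.copy()
    hom = (vals == "A") | (vals == "B")
    flip = hom & (rng.random(vals.shape) < error_rate)
    out[flip & (vals == "A")] = "B"
    out[flip & (vals == "B")] = "A"
    out[hom & (rng.random(vals.shape) < miss_rate)] = "-"
    het = vals == "H"
    if het.any():
        u = rng.random(vals.shape)
        out[het & (u < 0.5)] = "-"
        out[het & (u >= 0.5) & (u < 0.75)] = "A"
        out[het & (u >= 0.75)] = "B"
    result = pd.DataFrame(out, index=truth.index, columns=truth.columns)
    if not return_support:
        return result
    support = np.zeros(vals.shape, dtype=int)
    faithful = hom & ~flip & (out != "-")
    support[faithful] = spps_per_marker
    support[(out != "-") & ~faithful] = 1
    return result, pd.DataFrame(support, index=truth.index,
                                columns=truth.columns)


def emit_intensities(
    truth: pd.DataFrame,
    probes_per_position: int = 4,
    allele_effect: float = 1.0,
    noise_sd: float = 0.25,
    n_replicates: int = 2,
    n_parent_replicates: int = 3,
    sites_per_unigene: int = 1,
    seed: int = 0,
    monomorphic: Sequence[str] = (),
) -> pd.DataFrame:
    """Probe-level log2 hybridization intensities for each unigene.

    Each unigene carries ``sites_per_unigene`` polymorphic sites (2-bp
    windows); every site is covered by ``probes_per_position`` 25-nt probes
    whose starts are staggered across the window. Samples carrying the B
    allele hybridize weaker by ``allele_effect`` log2 units on probes
    overlapping the site; heterozygous samples resolve, independently per
    replicate, to either allelic mode with probability 1/2. Parent samples
    ``P_A``/``P_B`` are emitted with ``n_parent_replicates`` replicates each.

    Rows are indexed by (unigene, probe_start, probe_end) (1-based,
    inclusive); columns by (sample, replicate).
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if allele_effect < 0:
        raise ValueError("allele_effect must be nonnegative")
    if n_replicates < 2:
        raise ValueError("RILs need at least duplicate hybridizations")
    rng = np.random.default_rng(seed)

    rils = list(truth.columns)
    samples = ([("P_A", r) for r in range(1, n_parent_replicates + 1)]
               + [("P_B", r) for r in range(1, n_parent_replicates + 1)]
               + [(s, r) for s in rils for r in range(1, n_replicates + 1)])
    col_index = pd.MultiIndex.from_tuples(samples, names=["sample", "replicate"])

    unigenes = list(truth.index) + list(monomorphic)
    site_coords = [30 + 40 * k for k in range(sites_per_unigene)]
    probe_len = 25

    rows = []
    blocks = []
    for ug in unigenes:
        if ug in truth.index:
            geno = truth.loc[ug].to_numpy(dtype="U1")
        else:
            geno = np.full(len(rils), "A", dtype="U1")
        for site in site_coords:
            # probe starts staggered so every probe spans [site, site+1]
            starts = np.unique(np.linspace(
                site - probe_len + 2, site, probes_per_position).astype(int))
            # B-mode indicator per (sample, replicate)
            is_b = np.zeros(len(samples), dtype=bool)
            for j, (s, _r) in enumerate(samples):
                if s == "P_B":
                    is_b[j] = True
                elif s == "P_A":
                    is_b[j] = False
                else:
                    g = geno[rils.index(s)]
                    if g == "B":
                        is_b[j] = True
                    elif g == "H":
                        is_b[j] = rng.random() < 0.5
            for st in starts:
                baseline = 10.0 + rng.normal(0.0, 0.5)  # probe affinity
                vals = baseline + rng.normal(0.0, noise_sd, len(samples))
                vals = vals - allele_effect * is_b
                rows.append((ug, int(st), int(st + probe_len - 1)))
                blocks.append(vals)
    index = pd.MultiIndex.from_tuples(
        rows, names=["unigene", "probe_start", "probe_end"])
    return pd.DataFrame(np.vstack(blocks), index=index, columns=col_index)
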