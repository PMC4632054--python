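# Methods

`rilmap` reconstructs ultra-high-density genetic linkage maps for
recombinant inbred line (RIL) populations genotyped on expression tiling
arrays, and ships a population simulator that generates the same data
structures with known ground truth. This note describes the models, the
estimators, the tunable parameters and the deliberate design choices, and
what the synthetic benchmarks do and do not demonstrate.

## The population model

A biparental RIL population is simulated by single-seed descent (SSD): the
F1 is heterozygous at every locus; each subsequent generation is one round
of selfing, so an F*t* line has undergone *t* − 1 meioses per lineage and
retains residual heterozygosity (1/2)^(t−1) per locus (F7 → 1.56%).
Meiosis follows the Haldane model: crossover count per chromosome is
Poisson(L/100) for map length L in cM, positions uniform on the genetic
scale, no interference. Marker positions are specified physically (Mb) and
translated to cM through a per-chromosome recombination-intensity profile
(`recomb_profile`), which models pericentromeric suppression; the default
profile is flat, and `pericentromeric_profile(width, suppression)` builds
the step profile used in the rate-landscape tests.

A reciprocal translocation carried by one parent is modelled through the
standard quadrivalent mechanics. While a lineage is heterozygous for the
rearrangement, only the two balanced parental configurations are
transmitted (alternate segregation): the gamete draws one configuration Z
and must follow the Z-carrying haplotype at the breakpoint region of *both*
chromosomes, with crossovers suppressed within ±5 cM (`suppress_cM`) of
each breakpoint. Once a lineage fixes the translocated configuration,
meiosis proceeds on the rearranged chromosomes (the two fusion products),
so markers distal to the breakpoints remain genuinely linked across the
original chromosomes in roughly half of the final lines. Together these
produce the two signatures seen in real interspecific maps: pseudolinkage
(the two chromosomes cluster as one linkage group) and a marker-dense bin
at the breakpoint where flanking markers of all four arms co-segregate.

## The observation model

Array genotyping cannot call heterozygotes. Each 2-bp single-position
polymorphism (SPP) is read per replicate hybridization from a bimodal
intensity distribution; a heterozygous sample falls into either homozygous
mode with probability ½ per replicate, and the replicate-consistency rule
(both replicates must agree, else missing) therefore converts true
heterozygotes into missing : A : B at 2 : 1 : 1. The simulator offers two
observation layers:

* `emit_intensities` — probe-level log2 intensities (per-probe affinity
  baseline N(10, 0.5), allele effect 1.0 log2 units, Gaussian noise
  SD 0.25, duplicate RIL hybridizations, triplicate parents). This feeds
  the full SPP-calling stack.
* `emit_call_matrix` — marker-level calls directly: homozygotes flipped
  with `error_rate` (default 1 × 10⁻⁴) and masked with `miss_rate`
  (default 0.025, matching the 2.4–2.7% missing-call rates of the arrays
  this emulates), heterozygotes emitted at the 2:1:1 artifact ratio. The
  error default is small because these calls model the *output* of
  replicate consistency and multi-SPP consensus, which suppress raw
  per-chip errors quadratically. Optionally it also returns the number of
  concordant member SPPs behind each call (`spps_per_marker`, default 7 —
  the average SPP count per unigene in the intraspecific population this
  emulates): faithful homozygous calls carry full support, het-derived or
  erroneous calls carry support 1. The map-iteration loop uses this layer
  exactly where the original pipeline consulted its SPP table.

## SPP calling

SPPdev at a 2-bp window is the across-sample standardized, overlap-weighted
mean intensity of the probes spanning the window (weights = probe overlap
fraction; windows with fewer than two probes are skipped; zero
across-sample variance means nonpolymorphic). Calling a position:

1. Variance-minimizing two-class split of the SPPdev values (exhaustive
   over the sorted gaps).
2. Bimodality gate on |mode₁ − mode₂| / pooled within-mode SD. A forced
   split of unimodal Gaussian noise scores ≈ 2.7 on this scale, and the
   generator's design point (allele effect = 4 × noise SD) scores ≈ 4.0;
   the default gate 3.3 sits between them.
3. Orientation by the parents (cultivated parent's mode = allele A;
   parents in one mode rejects the position).
4. Dead zone: samples within 0.25 × mode separation of the threshold are
   missing.
5. Replicate consensus (agreement required).

Contiguous polymorphic windows with compatible calls merge into an SPP
range. The record quality `avg_sppdev` is the mean mode separation on the
standardized SPPdev axis (range ≈ [0, 2] for balanced splits); records are
retained iff avg_sppdev ≥ 1.1, missing fraction ≤ 0.10, ≥ 2 valid probes,
span ≥ 2 bases, and minor allele frequency ≥ 0.10. On this axis the 1.1
threshold corresponds to a mode separation of ≈ 1.3 within-mode SDs for a
balanced split, which is what makes it a meaningful quality cut.

Multiple SPPs of one unigene collapse to a consensus haplotype marker by
per-line majority; if any pairwise mismatch distance exceeds 0.2 the SPPs
are partitioned by an exhaustive 2-medoid split and each group emits a
marker (`.1`/`.2`), at most two markers per unigene.

## Recombination, grouping, and the translocation detector

For marker pairs, R̂ = recombinants / jointly informative lines (H counts
as missing in a RIL design), and the per-meiosis fraction is
r̂ = R̂/(2 − 2R̂), the inversion of the selfed-RIL-at-fixation relation
R = 2r/(1 + 2r), clamped to ≤ 0.5. The linkage LOD is the one-sided
binomial likelihood ratio against R = 0.5 (non-positive in repulsion).
Linkage groups are single-linkage transitive closures over pairs with
r̂ ≤ 0.3 and LOD ≥ 5; singletons are reported separately.

Because the fixation relation is only asymptotic, the package also
implements the exact finite-generation relation R_t(r) via the ten-state
two-locus selfing recursion, inverted on a grid. At F7 the fixation formula
under-corrects every interval by ≈ 6% (Δ ≈ 0.25 cM on a 4 cM interval),
which accumulates to ≈ 20 cM over a 300 cM genome — far from negligible at
this map density. When the generation is known, `generation=` applies the
exact correction; it repositions the reported maps only, so the 5-cM
heterozygosity window keeps a single calibration scale.

`detect_pseudolinkage` tests metric topology rather than scanning cuts. A
single chromosome is metrically a path: seen from any bin, its linked
neighbours lie on at most two collinear arms. A segregating reciprocal
translocation turns the fused cluster into a star of up to four arms whose
pairwise distances are additive through the junction. Each bin is scored
as a candidate junction: neighbours with r̂ ≤ 0.30 within 20 cM are grown
into arms tip-first (a bin joins the arm minimizing the median discrepancy
|d(x,y) − |d(j,x) − d(j,y)||, tolerance 8 cM), and the candidate qualifies
if ≥ 3 arms (≥ 3 members, span ≥ 10 cM) are pairwise additive through it
(worst arm-pair median residual ≤ 6 cM, additive fit strictly better than
collinear), or if exactly 2 such arms have essentially unlinked cross
pairs (median r̂ ≥ 0.35) — the two-block pattern of clusters joined only
through a localized linking block. The minimal-residual junction is the
breakpoint bin; the additivity residual grows linearly with a candidate's
offset from the true junction, which is what localizes it to within a
couple of bins. Arms are paired into two output groups by size; assigning
arms to their original chromosomes requires external anchors (orthologous
markers or a second map), exactly as in practice.

## Bins, ordering, distances

Markers with zero observed recombination over ≥ 2 shared informative lines
merge transitively into genetic bins; a marker that is zero-recombinant
with members of two mutually recombining bins is attached to the bin
sharing more informative lines (tie → earlier bin) and flagged ambiguous.
The representative is the member with fewest missing calls.

Ordering minimizes COUNT — the total number of obligate crossovers across
lines, scored between nearest non-missing flanking calls. The optimizer is
a seeded multi-restart greedy insertion build (starting from the
tightest-linked pair, insertion position by an O(lines) incremental delta)
followed by exhaustive sliding-window reshuffles (window sizes 2…5) until
no improvement, best of 10 restarts, reflection canonicalized. On random
instances of ≤ 7 bins it attains the exhaustive optimum in 200/200 trials.

Distances: for each adjacent interval, recombination events are scored
between the nearest non-missing flanks, and an event whose flanks span k
intervals contributes 1/k to each — so crossovers of lines masked across a
region (heterozygous tracts) still enter the total, which keeps map length
unbiased (locally smoothed). The interval fractions are RIL-corrected and
mapped through Haldane (default) or Kosambi; unlinked or uninformative
adjacencies are capped at 50 cM with a warning; ordered groups split at
adjacent gaps above 30 cM.

## Heterozygosity correction (four iterations)

Residual heterozygous tracts emit 2:1:1 noise that inflates the raw map.
Iteration 1 maps the raw calls. Heterozygous regions are detected per line
and group with a 5-cM window sliding bin-by-bin (never fewer than 2 bins):
a window is suspicious if its missing fraction ≥ 0.4 or it contains ≥ 2
apparent crossovers; ≥ 2 contiguous suspicious windows form a region,
trimmed to the outermost evidence bins (missing or discordant with a
neighbour), then expanded outward over bins that are missing or discordant
with *both* neighbours (tolerating one clean bin — a het tract emits a
clean-looking call about ¼ of the time, while a genuine single crossover
flank is one-sided and is deliberately not evidence, so real crossovers
next to a tract are not swallowed). Regions with sub-window gaps merge.

Iteration 2 masks region calls as missing and remaps. Iteration 3
re-detects regions on the corrected order, unions them with the iteration-1
detections (by member overlap — remapping scrambles tract neighbourhoods),
writes them as explicit H calls, turns remaining apparent double crossovers
(a call disagreeing with both agreeing nearest flanks) into missing, and
remaps. Iteration 4 restores double crossovers backed by ≥ 2 unanimous
no-missing member SPPs, purges short runs (≤ 3 calls) supported only by
discordant member SPPs — the automated counterpart of removing SPP
haplotypes inconsistent with their bin during visual curation — and merges
bins that no longer recombine. The final map is never longer than the
iteration-1 map on het-carrying data.

Detection resolution is bounded below by the window: tracts shorter than
5 cM are not reliably delimited, and the recovery benchmarks therefore
score tracts of at least one window length.

## Map statistics and genome anchoring

Segregation distortion: per-bin χ² against 1:1 (df = 1, no continuity
correction — standard at n ≈ 60–120 lines), flagged at P < 0.01,
contiguous same-direction bins merged into skewed regions. Collinearity:
common markers ranked per map with within-bin ties broken by the other
map's order, R² of the rank-rank fit per group; the overall value is
reported both as pooled ranks and as the per-group mean, since either
convention is defensible. Map comparison reports per-group and total
length deltas plus the coverage extension beyond the outermost common
markers. Recombination-rate landscapes: local-linear Gaussian-kernel
regression of cM on Mb (default bandwidth span/30, grid of 200 points;
local-linear is used because a plain kernel average has boundary bias and
attenuates derivative peaks), isotonic monotonization (a genetic map is
monotone in physical order; negative raw slopes are smoothing artifacts),
centred finite-difference derivative, and the nonrecombining fraction is
the physical length below 0.05 cM/Mb.

Genome anchoring filters alignment hit tables: same-species anchors need
identity ≥ 98%, aligned length ≥ 200 nt and ≤ 50 unaligned nt at either
end, with a unique top score (equal scores → ambiguous, dropped);
cross-species anchors need identity ≥ 80%, coverage ≥ 75%, length ≥ 200
nt, and a hit that simultaneously maximizes identity and coverage
(no Pareto dominator → excluded). Concordance cross-tabulates linkage
groups against chromosomes, reports off-diagonal clusters of ≥ 5 anchors
(split at 5 cM / 5 Mb gaps) as candidate translocations, and assigns
unplaced scaffolds carrying ≥ 2 mapped markers within 5 cM to that group
and position.

## What the synthetic benchmarks show — and what they do not

The generator reproduces the *structure* of array-genotyped RIL data: SSD
pedigrees, the 2:1:1 heterozygote artifact, replicate hybridizations,
multi-SPP markers, pseudolinkage. It does not model probe sequence
effects, GC bias, cross-hybridization between paralogs (beyond the
discordant-SPP split path), segregation distortion from selection, or
crossover interference. Passing the recovery benchmarks therefore shows
the estimators are correct under the stated stochastic model at realistic
sizes (60–120 lines, 1–4 cM marker spacing), not that real arrays would
yield maps of the benchmark accuracy. Benchmark problem sizes — three
100-cM chromosomes, 50–100 markers each, 120 lines, 10 translocation
replicates — were chosen as the smallest configurations at which the
statistical expectations quoted in the tests are sharp.

## Numerical conventions

Calls are encoded A=0, B=1, missing=−1 (H is missing for counting);
positions serialize as cM with two decimals; hit coordinates are 1-based
inclusive in files and half-open internally; every stochastic stage takes
an explicit seed and identical config + seed reproduces byte-identical
outputs; ordering ties break toward the lower insertion index and the
reflection with the smaller leading bin id.
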