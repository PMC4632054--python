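"""Stage orchestration: simulate -> call -> markers -> map -> stats.

Each stage reads the previous stage's in-memory product (or a file, for
prefix runs), writes its TSV artifacts to the output directory, and logs
marker counts in and out. A provenance manifest records the configuration,
its hash, the seeds, and the package version.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd

from . import __version__ as _version
from . import binmap, grouping, io, mapstats, simpop, sppcall
from . import markers as markers_mod
from .config import PipelineConfig


def _assign_lg_names(clusters, truth=None):
    """Name clusters LG01.. by size; with truth, by majority true chromosome."""
    named = {}
    for i, c in enumerate(sorted(clusters, key=lambda c: (-len(c), min(c)))):
        if truth is not None:
            chroms = pd.Series([truth.marker_chrom.get(m.split(".")[0])
                                for m in c]).dropna()
            if len(chroms):
                named[f"LG{int(chroms.mode()[0]) + 1:02d}.{i}"] = c
                continue
        named[f"LG{i + 1:02d}"] = c
    return named


def run_pipeline(config: PipelineConfig, out_dir,
                 marker_matrix: pd.DataFrame | None = None,
                 stages: tuple[str, ...] = ("simulate", "callspp", "markers",
                                            "map", "stats")) -> dict:
    """Run the pipeline (or a prefix) and write all artifacts.

    With ``marker_matrix`` given, the simulation and calling stages are
    skipped and mapping starts from the supplied calls. Returns a dict of
    in-memory products keyed by stage name. Identical config + seed gives
    byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    products: dict = {}
    log: list[dict] = []
    cfg_json = config.to_json()
    seed = config.seed

    truth = None
    if marker_matrix is None and "simulate" in stages:
        sim = config.sim
        genome = simpop.GenomeModel(
            chrom_lengths_cM=tuple([sim.chrom_length_cM] * sim.n_chromosomes))
        design = simpop.CrossDesign(
            n_rils=sim.n_rils, final_generation=sim.final_generation,
            translocation=sim.translocation,
            polymorphic_fraction=sim.polymorphic_fraction)
        truth_df, truth = simpop.simulate_population(
            genome, design, seed=seed, markers_per_chrom=sim.markers_per_chrom)
        io.write_truth(truth, out / "truth.json")
        matrix, spp_support = simpop.emit_call_matrix(
            truth_df, miss_rate=sim.miss_rate, error_rate=sim.error_rate,
            seed=seed + 1, return_support=True)
        products["spp_support"] = spp_support
        io.write_marker_matrix(matrix, out / "markers.tsv")
        products["simulate"] = (truth_df, truth)
        products["markers"] = matrix
        log.append({"stage": "simulate", "n_markers": len(matrix),
                    "n_rils": matrix.shape[1]})
    elif marker_matrix is not None:
        matrix = marker_matrix
        products["markers"] = matrix
        log.append({"stage": "markers", "n_markers": len(matrix),
                    "n_rils": matrix.shape[1], "source": "input"})
    else:
        raise ValueError("either simulate stage or a marker matrix is required")

    if "map" in stages:
        g = config.group
        recomb = grouping.pairwise_recombination(
            matrix, min_informative=g.min_informative)
        lgs = grouping.cluster_linkage_groups(
            recomb, max_r=g.max_r, min_lod=g.min_lod)
        groups = _assign_lg_names(lgs.clusters, truth)
        m = config.map
        result = binmap.iterate_map(
            matrix, groups, seed=seed + 2, n_restarts=m.n_restarts,
            window_max=m.window_max, mapping_function=m.mapping_function,
            min_informative=g.min_informative, max_gap_cM=m.max_gap_cM,
            window_cM=m.window_cM, min_windows=m.min_windows,
            miss_thresh=m.miss_thresh, min_crossovers=m.min_crossovers,
            spp_support=products.get("spp_support"),
            generation=(config.sim.final_generation
                        if truth is not None else m.generation))
        io.write_map(result.final, out / "map.tsv")
        io.write_het_regions(result.het_regions, out / "het_regions.tsv")
        products["map"] = result
        products["groups"] = lgs
        log.append({"stage": "map",
                    "n_groups": len(result.final.groups),
                    "n_bins": result.final.n_bins,
                    "n_singletons": len(lgs.singletons),
                    "total_length_cM": round(result.final.total_length, 2),
                    "iterations": [vars(e) for e in result.log]})

    if "stats" in stages and "map" in products:
        result = products["map"]
        records, regions = mapstats.distortion_scan(
            result.final, result.corrected_matrix,
            alpha=config.map.alpha_distortion)
        dist = pd.DataFrame([vars(r) for r in records])
        dist.to_csv(out / "distortion.tsv", sep="\t", index=False,
                    float_format="%.4g")
        products["stats"] = (records, regions)
        log.append({"stage": "stats", "n_bins_tested": len(records),
                    "n_skewed": sum(r.p_value < config.map.alpha_distortion
                                    for r in records)})

    manifest = {
        "version": _version,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": json.loads(cfg_json),
        "stages": log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    products["manifest"] = manifest
    return products


def call_markers_from_intensities(intensities: pd.DataFrame,
                                  config: PipelineConfig) -> pd.DataFrame:
    """Intensity-level prefix: SPP calling then consensus markers."""
    c = config.call
    table, _ = sppcall.call_spp_table(
        intensities, cultivated=c.cultivated, wild=c.wild,
        min_separation=c.min_separation, dead_zone=c.dead_zone,
        spp_filter=sppcall.SPPFilter(
            min_sppdev=c.min_sppdev, max_missing=c.max_missing,
            min_probes=c.min_probes, min_span=c.min_span,
            max_allele_freq=c.max_allele_freq))
    if table.empty:
        warnings.warn("no SPPs retained")
        return pd.DataFrame()
    call_cols = [c for c in table.columns
                 if c not in ("unigene", "start", "end", "avg_sppdev",
                              "n_valid_probes", "span_bases")]
    matrix, _prov = markers_mod.consensus_markers(
        table, call_cols, split_threshold=config.map.split_threshold)
    return matrix
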