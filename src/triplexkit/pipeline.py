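"""Reproducible end-to-end runs: config, seeding, stage execution, manifest.

A run goes from synthetic inputs to a screened candidate lncRNA, a
discovered triplex-forming region and classified melting curves, writing
every intermediate as FASTA/BED/TSV/CSV plus a JSON manifest with the
effective configuration, the seed-derivation trace and SHA-256 checksums
of all outputs. One global seed feeds per-stage child seeds derived with
``numpy.random.SeedSequence(seed).generate_state``, so each stage is also
reproducible standalone.
"""

from __future__ import annotations

import copy
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, melting, qpcr, screen, sequences, synthetic, tfr, triplex

logger = logging.getLogger("triplexkit")

#: Demo-scale defaults: every stage finishes quickly on one CPU while still
#: carrying a recoverable planted signal at the study's filter settings.
DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {
        "genome": {"n_chroms": 1, "chrom_len": 3000, "gc_fraction": 0.5},
        "tts": {"n_sites": 6, "mismatch_rate": 0.0},
        "lncrna": {"length": 120},
        "peaks": {"n_lncrnas": 500, "n_enriched": 5,
                  "background_lambda": 5.0, "enriched_fold": 20.0},
        "ct": {"true_fold_changes": [1.0, 2.0, 4.0], "base_ct": 25.0,
               "noise_sd": 0.0},
        "melting": {"noise_sd": 0.02},
    },
    "scan": {"min_len": 12, "max_error_rate": 0.2,
             "motifs": ["antiparallel_purine", "parallel_pyrimidine"]},
    "enrich": {"n_randomizations": 100, "alpha": 0.05,
               "region_pad": 15, "n_decoy_regions": 4},
    "screen": {"fold_cut": 10.0, "logp_cut": 20.0, "coding_cut": 0.364},
    "qpcr": {"efficiency": 2.0},
    "melt_fit": {"aicc_margin": 10.0, "min_separation": 5.0},
}

_STAGES = ("simulate", "screen", "scan", "enrich", "qpcr", "melt_fit")


def _merge_config(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown configuration key {where!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"configuration key {where!r} must be a mapping")
            out[key] = _merge_config(defaults[key], value, where)
        else:
            out[key] = value
    return out


def load_config(overrides: dict | None = None, seed: int | None = None) -> dict:
    """Effective run configuration: defaults + overrides, unknown keys rejected."""
    cfg = _merge_config(DEFAULT_CONFIG, overrides or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds from the global seed."""
    state = np.random.SeedSequence(seed).generate_state(len(_STAGES))
    return {stage: int(s & 0x7FFFFFFF) for stage, s in zip(_STAGES, state)}


def _transition_rows(calls) -> pd.DataFrame:
    rows = []
    for call in calls:
        best = call.best
        rows.append({
            "curve_id": call.curve_id, "model": call.model,
            "tm1": best.tm1, "tm2": best.tm2 if best.tm2 is not None else np.nan,
            "a": best.a, "b": best.b, "c": best.c, "d": best.d,
            "residual_sse": best.residual_sse,
            "delta_aicc": call.delta_aicc, "separation": call.separation,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: dict | None = None, out_dir=".", seed: int | None = None) -> dict:
    """Execute simulate -> screen -> scan -> enrich -> qpcr -> melt-fit.

    Returns the manifest (also written to ``<out_dir>/manifest.json``).
    Any stage failure raises with the stage name attached.
    """
    cfg = load_config(config if isinstance(config, dict) else None, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg["seed"])
    files: dict[str, Path] = {}
    stage = "setup"
    tfo = sequences.TFO2_23
    try:
        # ---------------- simulate ----------------
        stage = "simulate"
        logger.info("stage %s (seed %d)", stage, seeds[stage])
        sim = cfg["simulate"]
        genome, _ = synthetic.make_genome(seed=seeds[stage], **sim["genome"])
        genome, tts_truth = synthetic.plant_tts(
            genome, tfo, seed=seeds[stage] + 1, **sim["tts"])
        rna, tfr_span = synthetic.make_lncrna(
            sim["lncrna"]["length"], tfo, seed=seeds[stage] + 2)
        peaks, peak_truth = synthetic.make_peak_table(seed=seeds[stage] + 3,
                                                      **sim["peaks"])
        candidates = synthetic.make_candidate_table(peaks, peak_truth,
                                                    seed=seeds[stage] + 4)
        ct_table, ct_truth = synthetic.make_ct_table(seed=seeds[stage] + 5,
                                                     **sim["ct"])
        tm_bi = sequences.PUBLISHED_TM["EPHA2_hairpin_triplex"]
        tm_mono = sequences.PUBLISHED_TM["EPHA2_duplex"][0]
        curves = [
            synthetic.make_melting_curve(
                x0=tm_bi[0], x2=tm_bi[1], noise_sd=sim["melting"]["noise_sd"],
                seed=seeds[stage] + 6, curve_id="triplex_like"),
            synthetic.make_melting_curve(
                a=1.0, c=0.0, x0=tm_mono, x2=tm_mono,
                noise_sd=sim["melting"]["noise_sd"],
                seed=seeds[stage] + 7, curve_id="duplex_like"),
        ]
        truth = synthetic.SyntheticTruth(
            genome_id="synthetic", seed=cfg["seed"], planted_tts=tts_truth,
            planted_tfr=(rna.id, *tfr_span),
            peak_truth=[tuple(r) for r in peak_truth.itertuples(index=False)],
            melt_truth=[("triplex_like", 0.5, tm_bi[0], 3.0, 0.5, tm_bi[1], 3.0,
                         sim["melting"]["noise_sd"]),
                        ("duplex_like", 1.0, tm_mono, 3.0, 0.0, tm_mono, 1.0,
                         sim["melting"]["noise_sd"])],
            ct_truth=[tuple(r) for r in ct_truth.itertuples(index=False)],
        )
        truth.validate(genome)
        files["genome.fasta"] = out / "genome.fasta"
        io.write_genome_fasta(files["genome.fasta"], genome)
        files["lncrna.fasta"] = out / "lncrna.fasta"
        io.write_fasta(files["lncrna.fasta"], [rna])
        files["tts_truth.bed"] = out / "tts_truth.bed"
        io.write_bed(files["tts_truth.bed"],
                     [io.BedInterval(c, s, e, "planted_tts", 0, st)
                      for c, s, e, st in tts_truth])
        files["peaks.tsv"] = out / "peaks.tsv"
        io.write_tsv(files["peaks.tsv"], peaks)
        files["candidates.tsv"] = out / "candidates.tsv"
        io.write_tsv(files["candidates.tsv"], candidates)
        files["ct.tsv"] = out / "ct.tsv"
        io.write_tsv(files["ct.tsv"], ct_table)
        files["melting.csv"] = out / "melting.csv"
        io.write_melting_csv(files["melting.csv"], curves)
        files["truth.json"] = out / "truth.json"
        truth.write(files["truth.json"])

        # ---------------- screen ----------------
        stage = "screen"
        logger.info("stage %s", stage)
        annotated = screen.annotate_peaks(candidates)
        rows = annotated.rename(columns={
            "fold_enrichment": "best_fold_enrichment",
            "neg_log10_p": "best_neg_log10_p",
        })
        thresholds = screen.ScreenThresholds(
            fold_cut=cfg["screen"]["fold_cut"], logp_cut=cfg["screen"]["logp_cut"],
            coding_cut=cfg["screen"]["coding_cut"])
        retained, attrition = screen.apply_screen(rows, thresholds)
        files["screened.tsv"] = out / "screened.tsv"
        io.write_tsv(files["screened.tsv"], retained)
        files["attrition.tsv"] = out / "attrition.tsv"
        io.write_tsv(files["attrition.tsv"], attrition)
        logger.info("screen retained %d of %d rows", len(retained), len(rows))

        # ---------------- scan ----------------
        stage = "scan"
        logger.info("stage %s", stage)
        scan_params = dict(cfg["scan"])
        scan_params["motifs"] = tuple(scan_params["motifs"])
        hits = []
        for chrom, seq in sorted(genome.items()):
            hits.extend(triplex.find_tts(
                tfo, triplex.NucleicSeq(chrom, "DNA", seq), **scan_params))
        files["tts_hits.bed"] = out / "tts_hits.bed"
        io.write_bed(files["tts_hits.bed"], io.hits_to_bed(hits))
        files["tts_hits.tsv"] = out / "tts_hits.tsv"
        io.write_tsv(files["tts_hits.tsv"], io.hits_to_table(hits))
        logger.info("scan found %d hits", len(hits))

        # ---------------- enrich ----------------
        stage = "enrich"
        logger.info("stage %s (seed %d)", stage, seeds[stage])
        pad = cfg["enrich"]["region_pad"]
        bounds = {c: len(s) for c, s in genome.items()}
        regions = [
            (c, max(0, s - pad), min(bounds[c], e + pad))
            for c, s, e, _ in tts_truth
        ]
        rng = np.random.default_rng(seeds[stage])
        decoy_len = len(tfo) + 2 * pad
        for _ in range(cfg["enrich"]["n_decoy_regions"]):
            chrom = sorted(bounds)[int(rng.integers(len(bounds)))]
            start = int(rng.integers(0, bounds[chrom] - decoy_len))
            regions.append((chrom, start, start + decoy_len))
        region_set = tfr.RegionSet(tuple(regions), bounds)
        tfrs = tfr.discover_tfrs(
            rna, region_set, genome, scan_params=scan_params,
            n_randomizations=cfg["enrich"]["n_randomizations"],
            alpha=cfg["enrich"]["alpha"], seed=seeds[stage] + 1)
        files["tfrs.tsv"] = out / "tfrs.tsv"
        io.write_tsv(files["tfrs.tsv"], pd.DataFrame([
            {"rna_id": t.rna_id, "start": t.start, "end": t.end,
             "n_target_regions_hit": t.n_target_regions_hit,
             "empirical_p": t.empirical_p,
             "n_randomizations": t.n_randomizations}
            for t in tfrs
        ], columns=["rna_id", "start", "end", "n_target_regions_hit",
                    "empirical_p", "n_randomizations"]))
        logger.info("enrich reported %d TFRs", len(tfrs))

        # ---------------- qpcr ----------------
        stage = "qpcr"
        logger.info("stage %s", stage)
        folds = qpcr.analyze_ct_table(ct_table, efficiency=cfg["qpcr"]["efficiency"])
        files["qpcr_folds.tsv"] = out / "qpcr_folds.tsv"
        io.write_tsv(files["qpcr_folds.tsv"], folds)

        # ---------------- melt-fit ----------------
        stage = "melt_fit"
        logger.info("stage %s", stage)
        calls = [melting.classify_transition(
            c, aicc_margin=cfg["melt_fit"]["aicc_margin"],
            min_separation=cfg["melt_fit"]["min_separation"]) for c in curves]
        files["melt_fits.tsv"] = out / "melt_fits.tsv"
        io.write_tsv(files["melt_fits.tsv"], _transition_rows(calls))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": cfg["seed"],
        "stage_seeds": seeds,
        "config": cfg,
        "checksums": io.checksum_tree(files),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def setup_logging(verbosity: int = 0) -> None:
    """Human-readable log lines to standard error."""
    level = logging.WARNING
    if verbosity == 1:
        level = logging.INFO
    elif verbosity >= 2:
        level = logging.DEBUG
    logging.basicConfig(stream=sys.stderr, level=level,
                        format="%(levelname)s %(name)s: %(message)s")
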