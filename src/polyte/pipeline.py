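"""Umbrella pipeline: simulate -> detect -> landscape -> stats -> clades ->
expression.

Each stage writes its artifacts into a sub-directory of the run
directory together with a JSON snapshot of the configuration slice it
depends on; on re-run, a stage whose snapshot and outputs are intact is
skipped, so changing one stage's parameters re-executes only it and its
downstream stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import clades as clades_mod
from . import detect as detect_mod
from . import expression as expr_mod
from . import landscape as land_mod
from . import popstats as stats_mod
from . import simdata
from .annotation import CategoryMap
from .config import DetectParams, SimConfig
from .io import (ensure_dir, read_sample_sheet, read_te_library, read_tsv,
                 write_bed, write_centromere_bed, write_fasta, write_gff3,
                 write_sample_sheet, write_te_library, write_tsv)

log = logging.getLogger("polyte")


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    detect: DetectParams = field(default_factory=DetectParams)
    arm_threshold: int = 1_000_000  # scaled for the default 10-Mb chromosomes
    subsample_n: int = 10
    subsample_reps: int = 100
    out_dir: str = "polyte_run"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = SimConfig.from_dict(d.get("sim", {}))
        det = DetectParams(**d.get("detect", {}))
        extra = {k: v for k, v in d.items() if k not in ("sim", "detect")}
        return cls(sim=sim, detect=det, **extra)

    def to_dict(self) -> dict:
        d = {"sim": self.sim.to_dict(),
             "detect": dataclasses.asdict(self.detect)}
        for k in ("arm_threshold", "subsample_n", "subsample_reps",
                  "out_dir", "log_level"):
            d[k] = getattr(self, k)
        return d


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _stage_fresh(run_dir, name, cfg_slice, outputs) -> bool:
    marker = os.path.join(run_dir, f".stage_{name}.json")
    if not os.path.exists(marker):
        return False
    with open(marker) as fh:
        if json.load(fh).get("digest") != _digest(cfg_slice):
            return False
    return all(os.path.exists(os.path.join(run_dir, o)) for o in outputs)


def _stage_done(run_dir, name, cfg_slice) -> None:
    with open(os.path.join(run_dir, f".stage_{name}.json"), "w") as fh:
        json.dump({"digest": _digest(cfg_slice), "time": time.time()}, fh)


def _read_states(path) -> pd.DataFrame:
    df = read_tsv(path, keep_default_na=False)  # 'NA' is a state, not NaN
    return df.set_index("site_id").astype(str)


def _write_states(path, states: pd.DataFrame) -> None:
    write_tsv(path, states.reset_index())


def run_pipeline(config: RunConfig) -> str:
    """Execute all stages in dependency order; returns the run directory."""
    logging.basicConfig(level=config.log_level)
    run_dir = ensure_dir(config.out_dir)
    with open(os.path.join(run_dir, "resolved_config.yaml"), "w") as fh:
        yaml.safe_dump(_yamlable(config.to_dict()), fh, sort_keys=False)

    sim_cfg = config.sim.to_dict()
    sim_outputs = ["genome.fa", "annotation.gff3", "centromeres.bed",
                   "te_library.fa", "samples.tsv", "truth_insertions.tsv",
                   "truth_dosages.tsv", "expression.tsv", "junction_log.tsv"]
    if not _stage_fresh(run_dir, "simulate", sim_cfg, sim_outputs):
        t0 = time.time()
        stage_simulate(config.sim, run_dir)
        _stage_done(run_dir, "simulate", sim_cfg)
        log.info("simulate: %.1fs", time.time() - t0)
    else:
        log.info("simulate: up to date, skipped")

    det_cfg = {"detect": dataclasses.asdict(config.detect), "sim": sim_cfg}
    det_outputs = ["sites.tsv", "states.tsv", "evidence.tsv", "sites.bed"]
    if not _stage_fresh(run_dir, "detect", det_cfg, det_outputs):
        t0 = time.time()
        stage_detect(config.detect, run_dir)
        _stage_done(run_dir, "detect", det_cfg)
        log.info("detect: %.1fs", time.time() - t0)
    else:
        log.info("detect: up to date, skipped")

    land_cfg = {**det_cfg, "arm_threshold": config.arm_threshold}
    if not _stage_fresh(run_dir, "landscape", land_cfg,
                        ["annotated_sites.tsv", "density.tsv"]):
        stage_landscape(config, run_dir)
        _stage_done(run_dir, "landscape", land_cfg)

    stats_cfg = {**land_cfg, "subsample_n": config.subsample_n,
                 "subsample_reps": config.subsample_reps}
    if not _stage_fresh(run_dir, "stats", stats_cfg,
                        ["content_table.tsv", "mlm_report.tsv",
                         "subsample.tsv", "burst.tsv"]):
        stage_stats(config, run_dir)
        _stage_done(run_dir, "stats", stats_cfg)

    if not _stage_fresh(run_dir, "clades", land_cfg,
                        ["clade_classes.tsv", "clade_contrast.tsv"]):
        stage_clades(config, run_dir)
        _stage_done(run_dir, "clades", land_cfg)

    if not _stage_fresh(run_dir, "expression", land_cfg,
                        ["cnc_genic.tsv", "cnc_intergenic.tsv",
                         "cnc_tests.json"]):
        stage_expression(config, run_dir)
        _stage_done(run_dir, "expression", land_cfg)
    return run_dir


def _yamlable(obj):
    if isinstance(obj, dict):
        return {k: _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: SimConfig, run_dir) -> None:
    sequences, annotation = simdata.simulate_genome(cfg)
    catmap = CategoryMap(annotation)
    truth = simdata.simulate_population(cfg, annotation, catmap)
    write_fasta(os.path.join(run_dir, "genome.fa"), sequences)
    write_gff3(os.path.join(run_dir, "annotation.gff3"), annotation)
    write_centromere_bed(os.path.join(run_dir, "centromeres.bed"),
                         annotation.centromeres)
    write_te_library(os.path.join(run_dir, "te_library.fa"), truth.te_library)
    write_sample_sheet(os.path.join(run_dir, "samples.tsv"), truth.samples)
    write_tsv(os.path.join(run_dir, "truth_insertions.tsv"), truth.insertions)
    write_tsv(os.path.join(run_dir, "truth_dosages.tsv"),
              truth.dosages.reset_index())
    expr = simdata.simulate_expression(truth, annotation, cfg)
    expr_out = expr.reset_index().rename(columns={"index": "gene_id"})
    write_tsv(os.path.join(run_dir, "expression.tsv"), expr_out)
    _paths, jlog = simdata.simulate_reads(
        truth, sequences, cfg, os.path.join(run_dir, "bams"))
    write_tsv(os.path.join(run_dir, "junction_log.tsv"), jlog)


def stage_detect(params: DetectParams, run_dir) -> None:
    samples = read_sample_sheet(os.path.join(run_dir, "samples.tsv"))
    library = read_te_library(os.path.join(run_dir, "te_library.fa"))
    bam_paths = {i: os.path.join(run_dir, "bams", f"{i}.bam")
                 for i in samples["id"]}
    result = detect_mod.detect_pipeline(bam_paths, library, samples, params)
    write_tsv(os.path.join(run_dir, "sites.tsv"), result["sites"])
    _write_states(os.path.join(run_dir, "states.tsv"), result["states"])
    write_tsv(os.path.join(run_dir, "evidence.tsv"), result["evidence"])
    write_bed(os.path.join(run_dir, "sites.bed"),
              [(s.chrom, s.start, s.end, s.site_id)
               for s in result["sites"].itertuples()])


def _load_annotated(config: RunConfig, run_dir):
    from .io import read_centromere_bed, read_gff3
    samples = read_sample_sheet(os.path.join(run_dir, "samples.tsv"))
    centromeres = read_centromere_bed(os.path.join(run_dir, "centromeres.bed"))
    annotation = read_gff3(os.path.join(run_dir, "annotation.gff3"),
                           centromeres=centromeres)
    states = _read_states(os.path.join(run_dir, "states.tsv"))
    return samples, annotation, states


def stage_landscape(config: RunConfig, run_dir) -> None:
    samples, annotation, states = _load_annotated(config, run_dir)
    sites = read_tsv(os.path.join(run_dir, "sites.tsv"))
    catmap = CategoryMap(annotation)
    annotated = land_mod.annotate_sites(sites, states, samples, catmap,
                                        arm_threshold=config.arm_threshold)
    write_tsv(os.path.join(run_dir, "annotated_sites.tsv"), annotated)
    density = land_mod.density_profile(annotated, annotation.chrom_lengths)
    write_tsv(os.path.join(run_dir, "density.tsv"), density)


def stage_stats(config: RunConfig, run_dir) -> None:
    samples, _annotation, states = _load_annotated(config, run_dir)
    annotated = read_tsv(os.path.join(run_dir, "annotated_sites.tsv"))
    content = stats_mod.build_content_table(states, annotated, samples)
    write_tsv(os.path.join(run_dir, "content_table.tsv"), content)
    fit = stats_mod.fit_stepwise_mlm(content)
    write_tsv(os.path.join(run_dir, "mlm_report.tsv"), fit.coefficients)
    with open(os.path.join(run_dir, "mlm_trace.log"), "w") as fh:
        fh.write("\n".join(fit.trace) + "\n")
    sub = stats_mod.subsampled_content(states, annotated, samples,
                                      n_per_group=config.subsample_n,
                                      reps=config.subsample_reps,
                                      seed=config.sim.seed)
    write_tsv(os.path.join(run_dir, "subsample.tsv"), sub)
    burst = stats_mod.burst_family_test(annotated, states, samples)
    write_tsv(os.path.join(run_dir, "burst.tsv"), burst)


def stage_clades(config: RunConfig, run_dir) -> None:
    samples, _annotation, states = _load_annotated(config, run_dir)
    annotated = read_tsv(os.path.join(run_dir, "annotated_sites.tsv"))
    cc = clades_mod.classify_by_clade(states, samples)
    write_tsv(os.path.join(run_dir, "clade_classes.tsv"), cc)
    contrast = clades_mod.local_selection_contrast(cc, annotated, samples,
                                                   states)
    write_tsv(os.path.join(run_dir, "clade_contrast.tsv"), contrast)


def stage_expression(config: RunConfig, run_dir) -> None:
    samples, _annotation, states = _load_annotated(config, run_dir)
    annotated = read_tsv(os.path.join(run_dir, "annotated_sites.tsv"))
    expr = read_tsv(os.path.join(run_dir, "expression.tsv"))
    expr = expr.set_index("gene_id")
    genic = expr_mod.cnc_ratios(expr, annotated, states, samples,
                                tier="genic_near")
    inter = expr_mod.cnc_ratios(expr, annotated, states, samples,
                                tier="intergenic")
    write_tsv(os.path.join(run_dir, "cnc_genic.tsv"), genic)
    write_tsv(os.path.join(run_dir, "cnc_intergenic.tsv"), inter)
    results = {"n_genic": len(genic), "n_intergenic": len(inter)}
    try:
        results.update(expr_mod.cnc_tests(genic, inter, expr, samples,
                                          seed=config.sim.seed))
    except ValueError as exc:
        results["skipped"] = str(exc)
    with open(os.path.join(run_dir, "cnc_tests.json"), "w") as fh:
        json.dump(results, fh, indent=2)
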