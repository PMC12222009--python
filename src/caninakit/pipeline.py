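"""Umbrella pipelines chaining the stages into the three headline analyses.

Each run writes one output directory with the echoed configuration, a
machine-readable ``summary.json`` and the stage outputs; every file
header names the configuration hash, and all randomness flows from the
run seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import centromere as cen
from . import dosage as dos
from . import io
from . import ltr as ltrmod
from . import meiosis, sco, simulate
from .errors import PipelineError

logger = logging.getLogger("caninakit")

ANALYSES = ("pollen-bivalent", "hybrid-dosage", "centromere-bimodality")


@dataclass
class RunConfig:
    seed: int = 0
    analysis: str = "pollen-bivalent"
    # generator scale
    linkage_groups: int = 7
    chromosome_length: int = 1_000_000
    centromere_length: int = 80_000
    n_sco_loci: int = 8
    duplicated_subgenome: str = "S1"
    # stage thresholds
    alt_hits: str = "==1"
    margin_threshold: float = 0.5
    coverage: float = 20.0
    window_size: int = 100_000
    chip_window: int = 10_000
    threshold_k: float = 2.0
    merge_gap: int = 100_000
    dosage_tolerance: float = 0.25
    mother: str = "canina"
    father: str = "rubiginosa"
    snr: float = 8.0
    noise_sd: float = 0.15

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @property
    def hash(self) -> str:
        return io.config_hash(self.as_dict())


_TAXA = {
    "canina": ("R. canina", "S1"),
    "corymbifera": ("R. corymbifera", "S1"),
    "rubiginosa": ("R. rubiginosa", "R4"),
    "agrestis": ("R. agrestis", "R4"),
}


def karyotype_for(name: str) -> meiosis.Karyotype:
    try:
        taxon, biv = _TAXA[name]
    except KeyError:
        raise PipelineError(f"unknown taxon {name!r}; choose from {sorted(_TAXA)}") \
            from None
    return meiosis.pentaploid_karyotype(taxon, bivalent_subgenome=biv)


def _simulate(config: RunConfig) -> simulate.GenomeBundle:
    spec = simulate.GenomeSpec(
        seed=config.seed,
        linkage_groups=config.linkage_groups,
        chromosome_length=config.chromosome_length,
        centromere_length=config.centromere_length,
        n_sco_loci=config.n_sco_loci,
        duplicated_subgenome=config.duplicated_subgenome,
    )
    return simulate.generate_pentaploid(spec)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run one analysis end to end; returns the summary dict."""
    if config.analysis not in ANALYSES:
        raise PipelineError(f"unknown analysis {config.analysis!r}; "
                            f"choose from {ANALYSES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.hash
    io.write_json({"config": config.as_dict()}, outdir / "config.json",
                  header={"config_hash": h})
    stage = "simulate"
    try:
        bundle = _simulate(config)
        if config.analysis == "pollen-bivalent":
            stage = "sco-infer"
            summary = _run_pollen(config, bundle, outdir, h)
        elif config.analysis == "hybrid-dosage":
            stage = "hybrid-dosage"
            summary = _run_dosage(config, bundle, outdir, h)
        else:
            stage = "centromeres"
            summary = _run_centromeres(config, bundle, outdir, h)
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(f"stage {stage} failed: {exc}") from exc
    summary["config_hash"] = h
    summary["seed"] = config.seed
    io.write_json(summary, outdir / "summary.json", header={"config_hash": h})
    return summary


def _run_pollen(config, bundle, outdir, h) -> dict:
    truth_sco = bundle.truth.sco
    biv = bundle.truth.bivalent_subgenome
    regions = truth_sco[truth_sco["subgenome"] == biv][["chrom", "start0", "end"]]
    reads = simulate.generate_reads(bundle, source="bivalent",
                                    coverage=config.coverage, seed=config.seed,
                                    regions=regions)
    call, table, retained = sco.pollen_bivalent_pipeline(
        bundle, reads, alt_rule=config.alt_hits,
        margin_threshold=config.margin_threshold, taxon="synthetic")
    io.write_tsv(table.to_long_frame(bundle.genome_map),
                 outdir / "sco_hits_long.tsv", header_comment=f"config {h}")
    io.write_json({"bivalent_call": {
        "subgenome": call.subgenome, "support": call.support,
        "margin": call.margin, "status": call.status, "counts": call.counts}},
        outdir / "bivalent_call.json", header={"config_hash": h})
    return {"analysis": "pollen-bivalent",
            "bivalent_subgenome_truth": biv,
            "bivalent_subgenome_called": call.subgenome,
            "status": call.status, "support": call.support,
            "n_retained": len(retained)}


def _run_dosage(config, bundle, outdir, h) -> dict:
    mother = karyotype_for(config.mother)
    father = karyotype_for(config.father)
    expected = meiosis.predict_hybrid_dosage(mother, father)
    reads = simulate.generate_reads(bundle, source=dict(expected),
                                    coverage=config.coverage, seed=config.seed,
                                    with_sequences=False)
    collapse = simulate.haplotype_collapse_map(bundle.genome_map)
    aln = reads.alignments(collapse=collapse)
    ref_lens = {c: l for c, l in bundle.chrom_lengths().items()
                if not c.endswith("_h2")}
    track = dos.window_coverage(aln, ref_lens, window_size=config.window_size)
    repeat_ann = bundle.features[bundle.features["type"] == "repeat"]
    baseline = [s for s in bundle.genome_map.subgenomes if expected.get(s) == 1]
    call = dos.call_dosage(track, bundle.genome_map, baseline=baseline,
                           repeat_annotation=repeat_ann,
                           tolerance=config.dosage_tolerance)
    track.to_bedgraph(outdir / "coverage.bedgraph", header_comment=f"config {h}")
    io.write_json({"dosage_call": call.as_dict(),
                   "expected": dict(expected)},
                  outdir / "dosage_call.json", header={"config_hash": h})
    return {"analysis": "hybrid-dosage",
            "cross": f"{config.mother} x {config.father}",
            "expected": dict(expected),
            "called": call.copy_number,
            "recovered": call.copy_number == dict(expected),
            "confident": all(call.confident.values())}


def _run_centromeres(config, bundle, outdir, h) -> dict:
    cenh3, h3, meth = simulate.generate_chip_tracks(
        bundle, window=config.chip_window, snr=config.snr,
        noise_sd=config.noise_sd, seed=config.seed)
    track = cen.enrichment_track(cenh3, h3)
    calls = cen.call_centromere(track, threshold_k=config.threshold_k,
                                merge_gap=config.merge_gap)
    profiles = [cen.classify_centromere(
        cen.repeat_composition(c, bundle.features)) for c in calls]
    prof_df = cen.profiles_frame(profiles)
    reg = cen.canr4_cenh3_regression(profiles)
    mp = cen.metaplot({"cenh3_log2": track}, calls, bundle.genome_map)
    io.write_bed(prof_df.assign(name=prof_df["class"]),
                 outdir / "centromeres.bed", header_comment=f"config {h}")
    io.write_tsv(prof_df, outdir / "centromere_profiles.tsv",
                 header_comment=f"config {h}")
    io.write_tsv(cen.metaplot_frame(mp), outdir / "metaplot.tsv",
                 header_comment=f"config {h}")
    io.write_json({"regression": {
        "slope": reg.slope, "intercept": reg.intercept,
        "r_squared": reg.r_squared, "spearman_rho": reg.spearman_rho,
        "n": reg.n}}, outdir / "regression.json", header={"config_hash": h})
    truth = bundle.truth.centromeres.set_index("chrom")
    n_class = sum(p.cls == truth.loc[p.interval.chrom, "class"] for p in profiles)
    return {"analysis": "centromere-bimodality",
            "n_centromeres": len(calls),
            "n_class_recovered": int(n_class),
            "spearman_rho": reg.spearman_rho,
            "r_squared": reg.r_squared}
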