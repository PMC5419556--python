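"""End-to-end orchestration: simulate -> qc -> gapsites -> prefilter ->
maldr -> express, with a hashed run manifest for reproducibility.

Every stage writes normalised text outputs (LF line endings, floats with
6 significant digits) whose SHA-256 digests are recorded in
``manifest.json``; re-running with an identical configuration and seed
reproduces identical hashes, and :func:`verify_manifest` detects any
tampered intermediate file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from maldr_age import expression, prefilter, qc, synthetic_data
from maldr_age import maldr as maldr_mod
from maldr_age.gapsites import CountMatrix, write_bed
from maldr_age.params import MaldrParameters

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "gapsites", "prefilter", "maldr", "express")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full synthetic-cohort run."""

    outdir: Path
    seed: int = 0
    factor: str = "age"  # age | gender | location
    genome: synthetic_data.SyntheticGenomeSpec = field(
        default_factory=synthetic_data.SyntheticGenomeSpec)
    cohort: synthetic_data.CohortSpec = field(
        default_factory=synthetic_data.CohortSpec)
    effects: List[synthetic_data.EffectSpec] = field(default_factory=list)
    params: MaldrParameters = field(default_factory=MaldrParameters)
    qc_reads_per_sample: int = 200
    qc_threshold_mad: float = 3.5

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.factor not in ("age", "gender", "location"):
            raise ValueError(f"unknown factor {self.factor!r}")

    @classmethod
    def from_yaml(cls, path, outdir=None, seed=None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        kwargs["outdir"] = Path(outdir if outdir is not None
                                else raw.get("outdir", "maldr_run"))
        kwargs["seed"] = int(seed if seed is not None else raw.get("seed", 0))
        kwargs["factor"] = raw.get("factor", "age")
        if "genome" in raw:
            kwargs["genome"] = synthetic_data.SyntheticGenomeSpec(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in raw["genome"].items()})
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "age_groups" in c:
                c["age_groups"] = [synthetic_data.AgeGroupSpec(**g)
                                   for g in c["age_groups"]]
            if "lib_size" in c:
                c["lib_size"] = tuple(c["lib_size"])
            kwargs["cohort"] = synthetic_data.CohortSpec(**c)
        kwargs["effects"] = [
            synthetic_data.EffectSpec(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in e.items()})
            for e in raw.get("effects", [])]
        if "params" in raw:
            kwargs["params"] = MaldrParameters(**raw["params"])
        for k in ("qc_reads_per_sample", "qc_threshold_mad"):
            if k in raw:
                kwargs[k] = raw[k]
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_full(config: RunConfig) -> dict:
    """Execute all six stages and return the run manifest.

    Any stage failure raises :class:`StageError` naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "factor": config.factor,
                      "stages": {}}
    state: dict = {}

    def record(stage: str, files: Dict[str, Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "outputs": {name: _sha256(p) for name, p in sorted(files.items())},
            "seconds": round(time.time() - t0, 3),
        }
        logger.info("stage %s done (%.2fs)", stage,
                    manifest["stages"][stage]["seconds"])

    for stage in STAGES:
        t0 = time.time()
        try:
            files = _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise StageError(stage, exc) from exc
        record(stage, files, t0)

    _write_json({k: v for k, v in manifest.items()}, out / "manifest.json")
    return manifest


# --- stage implementations -------------------------------------------------


def _stage_simulate(config: RunConfig, out: Path, state: dict):
    genes = synthetic_data.generate_gene_models(config.genome, config.seed)
    cohort = synthetic_data.CohortSpec(
        **{**config.cohort.__dict__, "seed": config.seed})
    samples = synthetic_data.simulate_cohort(cohort)
    counts = synthetic_data.simulate_counts(
        genes, samples, config.effects, seed=config.seed)
    depths = synthetic_data.simulate_depth_profiles(
        genes, samples, config.effects, seed=config.seed)
    state.update(genes=genes, samples=samples, counts=counts, depths=depths)
    synthetic_data.write_gtf(genes, out / "genes.gtf")
    synthetic_data.write_sample_table(samples, out / "samples.tsv")
    counts.to_tsv(out / "gapsite_counts.tsv")
    return {"genes.gtf": out / "genes.gtf",
            "samples.tsv": out / "samples.tsv",
            "gapsite_counts.tsv": out / "gapsite_counts.tsv"}


def _stage_qc(config: RunConfig, out: Path, state: dict):
    samples = state["samples"]
    spectra = []
    for i, sid in enumerate(samples.index):
        reads = synthetic_data.simulate_fastq_reads(
            config.qc_reads_per_sample, seed=config.seed * 100003 + i)
        spectra.append(qc.kmer_spectrum(reads, k=6, sample_id=sid))
    dist = qc.spectrum_distance_matrix(spectra)
    flagged = qc.flag_outlier_samples(dist, config.qc_threshold_mad)
    qc.write_spectra_tsv(spectra, out / "kmer_spectra.tsv")
    report = pd.DataFrame({
        "median_distance": [float(pd.Series(
            dist.loc[sid].drop(sid)).median()) for sid in dist.index],
        "flagged": [sid in flagged for sid in dist.index],
    }, index=dist.index)
    report.to_csv(out / "qc_report.tsv", sep="\t", index_label="sample_id",
                  float_format="%.6g", lineterminator="\n")
    state["qc_flagged"] = flagged
    return {"kmer_spectra.tsv": out / "kmer_spectra.tsv",
            "qc_report.tsv": out / "qc_report.tsv"}


def _stage_gapsites(config: RunConfig, out: Path, state: dict):
    genes = state["genes"]
    sites = [s for g in genes for s in g.annotated_gap_sites()]
    write_bed(sites, out / "gapsites.bed")
    state["gene_gap_sites"] = {g.gene_id: g.annotated_gap_sites()
                               for g in genes}
    return {"gapsites.bed": out / "gapsites.bed"}


def _stage_prefilter(config: RunConfig, out: Path, state: dict):
    counts: CountMatrix = state["counts"]
    samples = state["samples"]
    if config.factor == "age":
        res = prefilter.run_prefilter(counts, samples, "age_group",
                                      levels=("Young", "Old"),
                                      params=config.params)
    else:
        res = prefilter.run_prefilter(counts, samples, config.factor,
                                      params=config.params)
    res.to_csv(out / "prefilter_results.tsv", sep="\t", index=False,
               float_format="%.6g", lineterminator="\n")
    state["prefilter_results"] = res
    state["prefiltered_genes"] = prefilter.select_prefiltered_genes(
        res, config.params)
    return {"prefilter_results.tsv": out / "prefilter_results.tsv"}


def _stage_maldr(config: RunConfig, out: Path, state: dict):
    res, curves = maldr_mod.run_maldr(
        state["prefiltered_genes"], state["depths"],
        state["gene_gap_sites"], state["samples"], config.params,
        return_curves=True)
    res.to_csv(out / "maldr_results.tsv", sep="\t",
               float_format="%.6g", lineterminator="\n")
    maldr_mod.write_curves_tsv(curves, out / "maldr_curves.tsv")
    state["maldr_results"] = res
    return {"maldr_results.tsv": out / "maldr_results.tsv",
            "maldr_curves.tsv": out / "maldr_curves.tsv"}


def _stage_express(config: RunConfig, out: Path, state: dict):
    counts: CountMatrix = state["counts"]
    gene_counts = counts.counts.groupby(counts.feature_genes).sum()
    cpm_values = expression.cpm(gene_counts)
    cpm_values.to_csv(out / "cpm.tsv", sep="\t", index_label="gene_id",
                      float_format="%.6g", lineterminator="\n")
    maldr_res = state["maldr_results"]
    passing = list(maldr_res.index[maldr_res["passes"]])
    summary: dict = {"n_prefiltered": len(state["prefiltered_genes"]),
                     "n_maldr_pass": len(passing),
                     "maldr_pass_genes": sorted(passing)}
    files = {"cpm.tsv": out / "cpm.tsv"}
    if len(passing) >= 2:
        corr = expression.pairwise_correlation(cpm_values, passing)
        corr.to_csv(out / "correlations.tsv", sep="\t",
                    index_label="gene_id", float_format="%.6g",
                    lineterminator="\n")
        summary["correlated_set"] = expression.correlated_set(
            corr, config.params.correlation_threshold)
        files["correlations.tsv"] = out / "correlations.tsv"
    gender_res = prefilter.run_prefilter(counts, state["samples"], "gender",
                                         params=config.params)
    summary["gender_bias"] = expression.bias_summary(
        gender_res, fdr_threshold=config.params.prefilter_fdr)
    _write_json(summary, out / "expression_summary.json")
    files["expression_summary.json"] = out / "expression_summary.json"
    state["summary"] = summary
    return files


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "gapsites": _stage_gapsites,
    "prefilter": _stage_prefilter,
    "maldr": _stage_maldr,
    "express": _stage_express,
}


# --- manifest checking and reporting ---------------------------------------


def verify_manifest(outdir) -> List[str]:
    """Return the names of manifest outputs whose hashes no longer match."""
    out = Path(outdir)
    manifest = json.loads((out / "manifest.json").read_text())
    bad = []
    for stage, info in manifest["stages"].items():
        for name, digest in info["outputs"].items():
            p = out / name
            if not p.exists() or _sha256(p) != digest:
                bad.append(name)
    return bad


def report(outdir) -> str:
    """Deterministic human-readable summary of a completed run."""
    out = Path(outdir)
    manifest = json.loads((out / "manifest.json").read_text())
    summary = json.loads((out / "expression_summary.json").read_text())
    pre = pd.read_csv(out / "prefilter_results.tsv", sep="\t")
    mal = pd.read_csv(out / "maldr_results.tsv", sep="\t")
    lines = ["MALDR age-expression run report",
             "===============================",
             f"seed: {manifest['seed']}   factor: {manifest['factor']}",
             f"stages completed: {len(manifest['stages'])}",
             "",
             f"gap-sites tested: {len(pre)}",
             f"genes passing pre-filter (FDR): {summary['n_prefiltered']}",
             f"genes evaluated by MALDR: {len(mal)}",
             f"age-MAR genes (MALDR pass): {summary['n_maldr_pass']} genes"]
    if summary.get("maldr_pass_genes"):
        lines.append("  " + ", ".join(summary["maldr_pass_genes"]))
    if "correlated_set" in summary:
        cs = summary["correlated_set"]
        lines.append(f"largest correlated set (r > threshold): "
                     f"{len(cs)} genes: {', '.join(cs)}")
    gb = summary.get("gender_bias") or {}
    if gb:
        lines.append(
            f"gender DE: {gb['n_significant']} genes "
            f"({gb['pct_male_biased']}% male-biased / "
            f"{gb['pct_female_biased']}% female-biased)")
    else:
        lines.append("gender DE: 0 genes")
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text


def write_yaml_config(config: RunConfig, path) -> None:
    """Serialise a RunConfig back to YAML (documented schema)."""
    raw = {
        "seed": config.seed,
        "factor": config.factor,
        "outdir": str(config.outdir),
        "genome": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in config.genome.__dict__.items()},
        "cohort": {
            "n_donors": config.cohort.n_donors,
            "age_groups": [g.__dict__ for g in config.cohort.age_groups],
            "genders": list(config.cohort.genders),
            "locations": list(config.cohort.locations),
            "lib_size": list(config.cohort.lib_size),
            "seed": config.cohort.seed,
        },
        "effects": [{k: list(v) if isinstance(v, tuple) else v
                     for k, v in e.__dict__.items()}
                    for e in config.effects],
        "params": config.params.to_dict(),
        "qc_reads_per_sample": config.qc_reads_per_sample,
        "qc_threshold_mad": config.qc_threshold_mad,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
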